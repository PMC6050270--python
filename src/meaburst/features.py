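"""Per-unit, per-epoch spike-train features.

Three features summarise each sorted single unit, which is the unit of
analysis throughout (population summaries are computed over units, never
over pooled spikes): overall firing rate, mean interspike interval (ISI),
and the percentage of spikes falling outside detected bursts.

The ISI comes in two modes.  ``intra_burst`` (the default) averages only
the intervals between consecutive spikes inside the same burst -- the
quantity that characterises burst structure and is bounded above by the
detector's ``max_end_isi``.  ``all`` averages every consecutive interval
in the train, which for a sparse tonic unit is dominated by the firing
rate (mean ~ 1/rate) rather than by burstiness.

Features that are undefined for a unit (ISI of a single-spike train,
percent-out-of-burst of a silent unit) are reported as missing values and
excluded listwise per feature, not per unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bursts import Burst, BurstParams, detect_bursts
from .io import Recording, SpikeTrain

ISI_MODES = ("intra_burst", "all")


@dataclass(frozen=True)
class UnitFeatures:
    unit_id: str
    epoch: str
    n_spikes: int
    firing_rate: float
    mean_isi: float  # NaN when undefined
    isi_mode: str
    pct_out_of_burst: float  # NaN when undefined
    n_bursts: int


def firing_rate(train: SpikeTrain) -> float:
    """Spike count over the full epoch duration, in Hz."""
    return train.n_spikes / train.epoch_duration


def interspike_intervals(train: SpikeTrain, bursts: list[Burst],
                         mode: str = "intra_burst") -> tuple[np.ndarray, float]:
    """ISIs and their arithmetic mean under the given mode.

    ``all``: consecutive differences over the whole train (needs >= 2
    spikes).  ``intra_burst``: differences between spikes inside the same
    burst only; intervals spanning a burst boundary are excluded (needs
    >= 1 burst).  When the preconditions fail the mean is NaN and the
    interval array empty -- undefined, not zero.
    """
    if mode not in ISI_MODES:
        raise ValueError(f"mode must be one of {ISI_MODES}")
    times = train.spike_times
    if mode == "all":
        if train.n_spikes < 2:
            return np.empty(0), math.nan
        isis = np.diff(times)
    else:
        if not bursts:
            return np.empty(0), math.nan
        isis = np.concatenate([
            np.diff(times[b.first_spike_index:b.last_spike_index + 1])
            for b in bursts
        ])
    return isis, float(isis.mean())


def pct_spikes_out_of_bursts(train: SpikeTrain, bursts: list[Burst]) -> float:
    """Percentage of the unit's spikes not assigned to any burst.

    100 when no bursts were detected, 0 when every spike is in a burst,
    NaN for a silent train.
    """
    if train.n_spikes == 0:
        return math.nan
    in_burst = sum(b.n_spikes for b in bursts)
    return 100.0 * (train.n_spikes - in_burst) / train.n_spikes


def unit_features(train: SpikeTrain, bursts: list[Burst] | None = None,
                  params: BurstParams | None = None,
                  isi_mode: str = "intra_burst") -> UnitFeatures:
    """All three features for one train; detects bursts if not supplied."""
    if bursts is None:
        bursts = detect_bursts(train, params)
    _, mean_isi = interspike_intervals(train, bursts, isi_mode)
    return UnitFeatures(
        unit_id=train.unit_id,
        epoch=train.epoch,
        n_spikes=train.n_spikes,
        firing_rate=firing_rate(train),
        mean_isi=mean_isi,
        isi_mode=isi_mode,
        pct_out_of_burst=pct_spikes_out_of_bursts(train, bursts),
        n_bursts=len(bursts),
    )


def features_table(recording: Recording, params: BurstParams | None = None,
                   isi_mode: str = "intra_burst") -> pd.DataFrame:
    """Feature rows for every train in a recording.

    Columns: ``unit_id, epoch, n_spikes, firing_rate_hz, mean_isi_s,
    isi_mode, pct_out_of_burst, n_bursts``.
    """
    rows = [unit_features(t, params=params, isi_mode=isi_mode)
            for t in recording]
    return pd.DataFrame({
        "unit_id": [f.unit_id for f in rows],
        "epoch": [f.epoch for f in rows],
        "n_spikes": [f.n_spikes for f in rows],
        "firing_rate_hz": [f.firing_rate for f in rows],
        "mean_isi_s": [f.mean_isi for f in rows],
        "isi_mode": [f.isi_mode for f in rows],
        "pct_out_of_burst": [f.pct_out_of_burst for f in rows],
        "n_bursts": [f.n_bursts for f in rows],
    })


def summarize_features(table: pd.DataFrame) -> pd.DataFrame:
    """Population mean +- SEM per epoch and feature, missing values dropped
    listwise per feature (each unit is one data point)."""
    out = []
    for epoch, grp in table.groupby("epoch"):
        for col in ("firing_rate_hz", "mean_isi_s", "pct_out_of_burst"):
            vals = grp[col].dropna()
            n = len(vals)
            out.append({
                "epoch": epoch,
                "feature": col,
                "mean": vals.mean() if n else math.nan,
                "sem": vals.std(ddof=1) / math.sqrt(n) if n > 1 else math.nan,
                "n": n,
            })
    return pd.DataFrame(out)
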