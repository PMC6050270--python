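"""Synthetic spike-train cohorts with exact burst ground truth.

The generator emulates the two baseline regimes seen on multi-electrode
arrays -- bursty cortical cultures (in vitro: ~2 Hz, roughly a quarter of
spikes inside bursts, intra-burst ISI ~0.061 s) and tonic cortical units
in the awake animal (in vivo: ~1 Hz, ~6 % of spikes in bursts, intra-burst
ISI ~0.079 s) -- plus per-unit multiplicative drug effects on the exposure
epoch, including complete cessation (multiplier 0).

Construction is geometric rather than biophysical, so that burst ground
truth is *exact* under the default Max-Interval parameters:

* every intra-burst ISI is drawn on ``(0, max_begin_isi]`` (a scaled Beta
  with the preset's mean), so each burst opens and extends itself;
* bursts are separated by at least ``min_ibi + burst_margin``, so
  candidates never merge across true bursts;
* tonic spikes come from a dead-time renewal process (hard minimum gap
  ``tonic_min_gap`` > ``max_end_isi``) conditioned on the budgeted spike
  count, and are kept at least ``max_end_isi + burst_margin`` away from
  every burst spike, so they can neither seed nor extend a candidate.

Conditioning the renewal process on its count (uniform order statistics
in gap-removed coordinates over the free intervals) pins the per-unit
spike budget, which keeps cohort firing-rate and percent-out-of-burst
calibration unbiased.

Per-unit rates are jittered around the preset target with a lognormal
factor (sigma 0.3), truncated at +-2 sigma in log space and renormalised
to unit mean: the truncation keeps extreme rate draws from exceeding the
packing capacity of the dead-time tonic process, and the renormalisation
keeps the cohort mean rate exactly on target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .bursts import BurstParams
from .io import DEFAULT_EPOCH_DURATION_S, Recording, SpikeTrain


class InfeasiblePresetError(ValueError):
    """The requested spike budget cannot be placed in the epoch."""


@dataclass(frozen=True)
class SynthPreset:
    """Generative parameters for one cohort regime plus injected effect."""

    name: str
    system: str = "in_vitro"
    n_units: int = 100
    epoch_duration: float = DEFAULT_EPOCH_DURATION_S
    target_rate: float = 2.0  # Hz
    burst_spike_fraction: float = 0.27
    spikes_per_burst: tuple[int, int] = (10, 15)  # uniform, inclusive
    intra_burst_isi_mean: float = 0.061  # s
    intra_burst_isi_concentration: float = 10.0  # Beta concentration
    tonic_min_gap: float = 0.25  # s; must exceed max_end_isi
    burst_margin: float = 0.1  # s; extra separation beyond min_ibi
    effect_mix: tuple[tuple[float, float], ...] = ((1.0, 1.0),)
    rate_jitter_sigma: float = 0.3
    drug: str = ""
    dose_uM: float = 0.0
    seed: int = 0

    def validate(self, params: BurstParams) -> None:
        if not 0 <= self.burst_spike_fraction < 1:
            raise ValueError("burst_spike_fraction must be in [0, 1)")
        if self.tonic_min_gap <= params.max_end_isi:
            raise ValueError("tonic_min_gap must exceed max_end_isi")
        if not 0 < self.intra_burst_isi_mean <= params.max_begin_isi:
            raise ValueError("intra_burst_isi_mean must lie in (0, max_begin_isi]")
        if self.spikes_per_burst[0] < params.min_spikes:
            raise ValueError("spikes_per_burst minimum must be >= min_spikes")
        if abs(sum(p for p, _ in self.effect_mix) - 1.0) > 1e-9:
            raise ValueError("effect_mix proportions must sum to 1")
        if any(m < 0 for _, m in self.effect_mix):
            raise ValueError("effect multipliers must be non-negative")


@dataclass
class GroundTruth:
    """Exact generator-side labels: per-spike burst membership and
    per-unit rate / burst fraction / effect multiplier."""

    in_burst: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    units: pd.DataFrame = field(default_factory=pd.DataFrame)

    def spikes_frame(self, recording: Recording) -> pd.DataFrame:
        rows = []
        for train in recording:
            mask = self.in_burst[(train.unit_id, train.epoch)]
            for t, flag in zip(train.spike_times, mask):
                rows.append((train.unit_id, train.epoch, t, bool(flag)))
        return pd.DataFrame(rows, columns=["unit_id", "epoch", "spike_time_s",
                                           "in_burst"])


# ---------------------------------------------------------------------------
# shipped presets, calibrated to the two baseline regimes and the strongest
# drug-challenge outcome (90 uM ketamine)

PRESETS: dict[str, SynthPreset] = {}


def _register(p: SynthPreset) -> SynthPreset:
    PRESETS[p.name] = p
    return p


INVITRO_BASELINE = _register(SynthPreset(
    name="invitro-baseline", system="in_vitro",
    target_rate=2.0, burst_spike_fraction=0.27, intra_burst_isi_mean=0.061,
))
INVIVO_BASELINE = _register(SynthPreset(
    name="invivo-baseline", system="in_vivo",
    target_rate=1.06, burst_spike_fraction=0.061, intra_burst_isi_mean=0.079,
))
KETAMINE90_INVITRO = _register(replace(
    INVITRO_BASELINE, name="ketamine90-invitro",
    drug="ketamine", dose_uM=90.0,
    effect_mix=((1.0, 0.0),),  # complete cessation in every unit
))
KETAMINE90_INVIVO = _register(replace(
    INVIVO_BASELINE, name="ketamine90-invivo",
    drug="ketamine", dose_uM=90.0,
    effect_mix=((0.561, 2.0), (0.378, 0.5), (0.061, 1.0)),
))


def get_preset(name: str, **overrides) -> SynthPreset:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides) if overrides else PRESETS[name]


# ---------------------------------------------------------------------------
# epoch construction


def _draw_intra_burst_isis(rng: np.random.Generator, n: int,
                           preset: SynthPreset,
                           params: BurstParams) -> np.ndarray:
    """ISIs on (0, max_begin_isi] from a scaled Beta with the preset mean."""
    hi = params.max_begin_isi
    mu = preset.intra_burst_isi_mean / hi
    kappa = preset.intra_burst_isi_concentration
    isis = hi * rng.beta(mu * kappa, (1 - mu) * kappa, size=n)
    return np.clip(isis, 1e-9, hi)


def _place_blocks(rng: np.random.Generator, durations: np.ndarray,
                  sep: float, total: float) -> np.ndarray:
    """Uniformly place non-overlapping blocks with minimum separation.

    Standard gap-removal construction: draw sorted uniforms in the
    reduced interval, then re-insert block lengths and separations.
    Returns block start times; raises if the blocks do not fit.
    """
    n = durations.size
    if n == 0:
        return np.empty(0)
    occupied = durations.sum() + sep * (n - 1)
    free = total - occupied
    if free <= 0:
        raise InfeasiblePresetError(
            f"cannot place {n} bursts totalling {occupied:.1f}s of span "
            f"in a {total:.1f}s epoch"
        )
    offsets = np.sort(rng.uniform(0.0, free, size=n))
    starts = offsets + np.concatenate(([0.0], np.cumsum(durations[:-1] + sep)))
    return starts


def _free_intervals(total: float, zones: list[tuple[float, float]]
                    ) -> list[tuple[float, float]]:
    """Complement of the (sorted, disjoint) exclusion zones within [0, total]."""
    out = []
    cursor = 0.0
    for a, b in zones:
        if a > cursor:
            out.append((cursor, min(a, total)))
        cursor = max(cursor, b)
    if cursor < total:
        out.append((cursor, total))
    return [(a, b) for a, b in out if b > a]


def _place_tonic(rng: np.random.Generator, n: int,
                 intervals: list[tuple[float, float]], gap: float) -> np.ndarray:
    """Dead-time renewal spikes conditioned on count ``n``.

    Equivalent to sampling the renewal process (ISI = gap + exponential)
    given that exactly ``n`` events land in the free time: uniform order
    statistics in gap-removed coordinates, mapped back through the free
    intervals.
    """
    if n == 0:
        return np.empty(0)
    lengths = np.array([b - a for a, b in intervals])
    f_total = lengths.sum()
    reduced = f_total - n * gap
    if reduced <= 0:
        raise InfeasiblePresetError(
            f"cannot place {n} tonic spikes with dead time {gap}s in "
            f"{f_total:.1f}s of free epoch time"
        )
    pts = np.sort(rng.uniform(0.0, reduced, size=n)) + gap * np.arange(n)
    # map reduced coordinates into the concatenated free intervals
    cum = np.concatenate(([0.0], np.cumsum(lengths)))
    idx = np.searchsorted(cum, pts, side="right") - 1
    starts = np.array([a for a, _ in intervals])
    return starts[idx] + (pts - cum[idx])


def _truncated_lognormal_factor(rng: np.random.Generator, sigma: float,
                                k: float = 2.0) -> float:
    """Mean-one lognormal rate jitter, truncated at +-k sigma in log space."""
    if sigma == 0:
        return 1.0
    mu = -0.5 * sigma ** 2
    z = rng.standard_normal()
    while abs(z) > k:
        z = rng.standard_normal()
    # renormalise so the truncated factor has mean exactly 1
    mean_trunc = (norm.cdf(k - sigma) - norm.cdf(-k - sigma)) / (
        norm.cdf(k) - norm.cdf(-k))
    return math.exp(mu + sigma * z) / mean_trunc


def _stochastic_round(rng: np.random.Generator, x: float) -> int:
    """Round x up with probability equal to its fractional part.

    Plain round() of per-unit spike budgets leaves a small systematic
    bias in cohort means; dithered rounding is exactly unbiased.
    """
    base = math.floor(x)
    return base + (1 if rng.random() < x - base else 0)


def generate_epoch(rng: np.random.Generator, rate: float, preset: SynthPreset,
                   params: BurstParams, unit_id: str, electrode_id: str,
                   epoch: str) -> tuple[SpikeTrain, np.ndarray]:
    """One epoch's spike train at the given rate, with its in-burst mask."""
    T = preset.epoch_duration
    if rate <= 0:
        train = SpikeTrain(unit_id=unit_id, electrode_id=electrode_id,
                           epoch=epoch, spike_times=np.empty(0),
                           epoch_duration=T)
        return train, np.empty(0, dtype=bool)

    lo, hi = preset.spikes_per_burst
    mean_spb = (lo + hi) / 2.0
    burst_budget = preset.burst_spike_fraction * rate * T
    n_bursts = _stochastic_round(rng, burst_budget / mean_spb)

    burst_times: list[np.ndarray] = []
    if n_bursts:
        spb = rng.integers(lo, hi + 1, size=n_bursts)
        all_isis = []
        for count in spb:
            isis = _draw_intra_burst_isis(rng, count - 1, preset, params)
            while isis.sum() < params.min_duration:  # pragma: no cover
                isis = _draw_intra_burst_isis(rng, count - 1, preset, params)
            all_isis.append(isis)
        durations = np.array([i.sum() for i in all_isis])
        sep = params.min_ibi + preset.burst_margin
        starts = _place_blocks(rng, durations, sep, T)
        burst_times = [s + np.concatenate(([0.0], np.cumsum(i)))
                       for s, i in zip(starts, all_isis)]

    excl = params.max_end_isi + preset.burst_margin
    zones = [(bt[0] - excl, bt[-1] + excl) for bt in burst_times]
    free = _free_intervals(T, zones)
    n_tonic = _stochastic_round(
        rng, (1.0 - preset.burst_spike_fraction) * rate * T)
    tonic = _place_tonic(rng, n_tonic, free, preset.tonic_min_gap)

    times = np.concatenate(burst_times + [tonic]) if burst_times else tonic
    mask = np.concatenate(
        [np.ones(bt.size, dtype=bool) for bt in burst_times]
        + [np.zeros(tonic.size, dtype=bool)]
    ) if burst_times else np.zeros(tonic.size, dtype=bool)
    order = np.argsort(times)
    train = SpikeTrain(unit_id=unit_id, electrode_id=electrode_id,
                       epoch=epoch, spike_times=times[order],
                       epoch_duration=T)
    return train, mask[order]


def generate_unit(preset: SynthPreset, rng: np.random.Generator,
                  params: BurstParams | None = None,
                  unit_id: str = "u0", electrode_id: str = "e0",
                  multiplier: float | None = None,
                  ) -> tuple[SpikeTrain, SpikeTrain, dict]:
    """Baseline + exposure trains for one unit, with exact ground truth.

    The unit's rate is the preset target times a lognormal jitter factor;
    its effect multiplier is drawn from ``effect_mix`` unless supplied.
    Returns ``(baseline, exposure, truth)`` where ``truth`` has keys
    ``rate``, ``multiplier``, ``in_burst`` (per-epoch masks) and
    ``burst_fraction`` (realised, baseline epoch).
    """
    if params is None:
        params = BurstParams()
    preset.validate(params)
    rate = preset.target_rate * _truncated_lognormal_factor(
        rng, preset.rate_jitter_sigma)
    if multiplier is None:
        props = np.array([p for p, _ in preset.effect_mix])
        multiplier = preset.effect_mix[rng.choice(props.size, p=props)][1]
    base, base_mask = generate_epoch(rng, rate, preset, params,
                                     unit_id, electrode_id, "baseline")
    expo, expo_mask = generate_epoch(rng, rate * multiplier, preset, params,
                                     unit_id, electrode_id, "exposure")
    truth = {
        "rate": rate,
        "multiplier": multiplier,
        "in_burst": {"baseline": base_mask, "exposure": expo_mask},
        "burst_fraction": (base_mask.mean() if base_mask.size else 0.0),
    }
    return base, expo, truth


def _allocate_multipliers(preset: SynthPreset, n: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder allocation of effect multipliers to units.

    Deterministic counts (so small cohorts realise the preset mix
    exactly, as printed response proportions do), shuffled across units.
    """
    props = np.array([p for p, _ in preset.effect_mix])
    mults = np.array([m for _, m in preset.effect_mix])
    raw = props * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    if remainder:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:remainder]] += 1
    assigned = np.repeat(mults, counts)
    return assigned[rng.permutation(n)]


def generate_cohort(preset: SynthPreset,
                    params: BurstParams | None = None,
                    seed: int | None = None,
                    epochs: tuple[str, ...] = ("baseline", "exposure"),
                    ) -> tuple[Recording, GroundTruth]:
    """A full cohort of ``preset.n_units`` independent units.

    Deterministic given the seed (``preset.seed`` unless overridden).
    ``epochs`` may be restricted to ``("baseline",)`` for baseline-only
    studies, halving the work.
    """
    if params is None:
        params = BurstParams()
    preset.validate(params)
    rng = np.random.default_rng(preset.seed if seed is None else seed)
    rec = Recording(system=preset.system, drug=preset.drug,
                    dose_uM=preset.dose_uM)
    truth = GroundTruth()
    multipliers = _allocate_multipliers(preset, preset.n_units, rng)
    unit_rows = []
    width = len(str(max(preset.n_units - 1, 1)))
    for i in range(preset.n_units):
        unit_id = f"u{i:0{width}d}"
        electrode_id = f"e{i:0{width}d}"
        mult = float(multipliers[i])
        rate = preset.target_rate * _truncated_lognormal_factor(
            rng, preset.rate_jitter_sigma)
        base_mask = expo_mask = None
        bfrac = 0.0
        if "baseline" in epochs:
            base, base_mask = generate_epoch(rng, rate, preset, params,
                                             unit_id, electrode_id, "baseline")
            rec.add(base)
            truth.in_burst[(unit_id, "baseline")] = base_mask
            bfrac = base_mask.mean() if base_mask.size else 0.0
        if "exposure" in epochs:
            expo, expo_mask = generate_epoch(rng, rate * mult, preset, params,
                                             unit_id, electrode_id, "exposure")
            rec.add(expo)
            truth.in_burst[(unit_id, "exposure")] = expo_mask
        unit_rows.append({"unit_id": unit_id, "true_rate_hz": rate,
                          "true_multiplier": mult,
                          "true_burst_fraction": bfrac})
    truth.units = pd.DataFrame(unit_rows)
    return rec, truth
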