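"""Spike-table data model and readers/writers.

A recording is a set of sorted single units, each contributing one spike
train per epoch (``baseline`` before drug challenge, ``exposure`` after).
On disk a recording is a CSV spike table with columns
``unit_id,electrode_id,epoch,spike_time_s`` plus a JSON metadata sidecar
carrying ``system``, ``drug``, ``dose_uM`` and ``epoch_duration_s``.

Timestamps are seconds stored as decimal text: the two acquisition systems
the format serves run at different sampling rates, so sample indices are
not portable.  Epoch duration lives in metadata rather than being inferred
from the last spike, because firing rate must be computed over the full
recording window even for sparse units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

EPOCHS = ("baseline", "exposure")
SYSTEMS = ("in_vitro", "in_vivo")

SPIKE_TABLE_COLUMNS = ["unit_id", "electrode_id", "epoch", "spike_time_s"]

#: default epoch length: recordings are 20-minute windows
DEFAULT_EPOCH_DURATION_S = 1200.0


class SpikeTableFormatError(ValueError):
    """The on-disk table is structurally malformed (e.g. missing column)."""


class SpikeValidationError(ValueError):
    """Spike data violate an invariant (ordering, range, duplicates)."""


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike timestamps of one unit within one epoch.

    Invariants: ``spike_times`` strictly increasing, all within
    ``[0, epoch_duration]``, and ``epoch_duration > 0``.
    """

    unit_id: str
    electrode_id: str
    epoch: str
    spike_times: np.ndarray
    epoch_duration: float = DEFAULT_EPOCH_DURATION_S

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", times)
        if self.epoch not in EPOCHS:
            raise SpikeValidationError(
                f"unit {self.unit_id!r}: unknown epoch label {self.epoch!r} "
                f"(expected one of {EPOCHS})"
            )
        if not self.epoch_duration > 0:
            raise SpikeValidationError(
                f"unit {self.unit_id!r}: epoch_duration must be > 0, "
                f"got {self.epoch_duration}"
            )
        if times.ndim != 1:
            raise SpikeValidationError(
                f"unit {self.unit_id!r}: spike_times must be 1-D"
            )
        if times.size:
            if times[0] < 0 or times[-1] > self.epoch_duration:
                bad = times[(times < 0) | (times > self.epoch_duration)][0]
                raise SpikeValidationError(
                    f"unit {self.unit_id!r} epoch {self.epoch}: spike time "
                    f"{bad} outside [0, {self.epoch_duration}]"
                )
            diffs = np.diff(times)
            if np.any(diffs == 0):
                t = times[:-1][diffs == 0][0]
                raise SpikeValidationError(
                    f"unit {self.unit_id!r} epoch {self.epoch}: duplicate "
                    f"spike time {t} (sorting artifact upstream?)"
                )
            if np.any(diffs < 0):
                raise SpikeValidationError(
                    f"unit {self.unit_id!r} epoch {self.epoch}: spike times "
                    "not strictly increasing"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_spikes


@dataclass
class Recording:
    """A cohort of spike trains keyed by ``(unit_id, epoch)`` plus metadata."""

    system: str
    drug: str = ""
    dose_uM: float = 0.0
    trains: dict[tuple[str, str], SpikeTrain] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.system not in SYSTEMS:
            raise SpikeValidationError(
                f"unknown system {self.system!r} (expected one of {SYSTEMS})"
            )
        if self.dose_uM < 0:
            raise SpikeValidationError("dose_uM must be non-negative")

    def add(self, train: SpikeTrain) -> None:
        key = (train.unit_id, train.epoch)
        if key in self.trains:
            raise SpikeValidationError(
                f"unit {train.unit_id!r} appears more than once in epoch "
                f"{train.epoch!r}"
            )
        self.trains[key] = train

    def unit_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for unit_id, _ in self.trains:
            seen.setdefault(unit_id)
        return sorted(seen)

    def epoch_trains(self, epoch: str) -> list[SpikeTrain]:
        return [t for (_, ep), t in sorted(self.trains.items()) if ep == epoch]

    def get(self, unit_id: str, epoch: str) -> SpikeTrain | None:
        return self.trains.get((unit_id, epoch))

    def __iter__(self) -> Iterable[SpikeTrain]:
        return iter(t for _, t in sorted(self.trains.items()))


def _epoch_duration(meta: Mapping, epoch: str) -> float:
    dur = meta["epoch_duration_s"]
    if isinstance(dur, Mapping):
        if epoch not in dur:
            raise SpikeTableFormatError(
                f"metadata epoch_duration_s lacks entry for epoch {epoch!r}"
            )
        return float(dur[epoch])
    return float(dur)


def read_spike_table(path: str | Path, metadata_path: str | Path) -> Recording:
    """Read a spike-table CSV and its JSON metadata sidecar.

    Rows may appear in any order; trains come back sorted by time.
    Non-monotonic input order is fine, but duplicate timestamps within one
    unit/epoch, out-of-range times, or unknown epoch labels raise
    :class:`SpikeValidationError`.
    """
    with open(metadata_path) as fh:
        meta = json.load(fh)
    for key in ("system", "drug", "dose_uM", "epoch_duration_s"):
        if key not in meta:
            raise SpikeTableFormatError(f"metadata is missing key {key!r}")

    # round_trip parsing keeps the decimal-text timestamps bit-exact
    df = pd.read_csv(path, dtype={"unit_id": str, "electrode_id": str, "epoch": str},
                     float_precision="round_trip")
    for col in SPIKE_TABLE_COLUMNS:
        if col not in df.columns:
            raise SpikeTableFormatError(f"spike table is missing column {col!r}")

    rec = Recording(system=meta["system"], drug=meta["drug"],
                    dose_uM=float(meta["dose_uM"]))

    if not df.empty:
        bad_epoch = set(df["epoch"]) - set(EPOCHS)
        if bad_epoch:
            raise SpikeValidationError(
                f"unknown epoch label(s) {sorted(bad_epoch)} (expected {EPOCHS})"
            )
        for (unit_id, epoch), grp in df.groupby(["unit_id", "epoch"], sort=True):
            times = np.sort(grp["spike_time_s"].to_numpy(dtype=float))
            electrode = str(grp["electrode_id"].iloc[0])
            rec.add(SpikeTrain(unit_id=str(unit_id), electrode_id=electrode,
                               epoch=str(epoch), spike_times=times,
                               epoch_duration=_epoch_duration(meta, str(epoch))))

    # Units listed in metadata but absent from the CSV recorded zero spikes
    # in that epoch (e.g. complete cessation under drug); materialise them
    # as empty trains so they are not conflated with unrecorded units.
    for entry in meta.get("units", []):
        for epoch in entry.get("epochs", []):
            if rec.get(str(entry["unit_id"]), str(epoch)) is None:
                rec.add(SpikeTrain(unit_id=str(entry["unit_id"]),
                                   electrode_id=str(entry["electrode_id"]),
                                   epoch=str(epoch),
                                   spike_times=np.empty(0),
                                   epoch_duration=_epoch_duration(meta, str(epoch))))
    return rec


def write_spike_table(recording: Recording, path: str | Path,
                      metadata_path: str | Path) -> None:
    """Write a recording as CSV + JSON sidecar.

    Round-trip guarantee: timestamps are written as decimal text via
    ``repr`` (shortest exact float representation), so
    ``read_spike_table(write_spike_table(r))`` reproduces every timestamp
    bit-identically.
    """
    rows = []
    durations: dict[str, float] = {}
    units: dict[str, dict] = {}
    for train in recording:
        durations[train.epoch] = train.epoch_duration
        entry = units.setdefault(train.unit_id, {
            "unit_id": train.unit_id,
            "electrode_id": train.electrode_id,
            "epochs": [],
        })
        entry["epochs"].append(train.epoch)
        for t in train.spike_times:
            rows.append((train.unit_id, train.electrode_id, train.epoch,
                         repr(float(t))))
    with open(path, "w", newline="") as fh:
        fh.write(",".join(SPIKE_TABLE_COLUMNS) + "\n")
        for row in rows:
            fh.write(",".join(row) + "\n")
    meta = {
        "system": recording.system,
        "drug": recording.drug,
        "dose_uM": recording.dose_uM,
        "epoch_duration_s": durations if durations else DEFAULT_EPOCH_DURATION_S,
        "units": list(units.values()),
    }
    with open(metadata_path, "w") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")
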