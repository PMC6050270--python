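"""Max-Interval burst detection.

The detector is the classic five-parameter Max-Interval algorithm
(NeuroExplorer-style): a burst opens on an interspike interval (ISI) no
longer than ``max_begin_isi``, extends while ISIs stay within
``max_end_isi``, nearby candidates closer than ``min_ibi`` are merged, and
candidates shorter than ``min_duration`` or sparser than ``min_spikes``
are discarded.  Defaults are the standard cortical-culture parameter set:
begin ISI 0.1 s, end ISI 0.2 s, inter-burst interval 0.5 s, duration
0.05 s, 10 spikes.

Threshold strictness follows the common convention: ISI tests are
inclusive (<=) and the merge test is exclusive (IBI strictly below
``min_ibi`` merges).  Merging runs before filtering, so sub-threshold
fragments may legitimately combine into a retained burst; because merged
candidates are contiguous runs of spikes, retained bursts always end up
>= ``min_ibi`` apart, which is asserted as a post-condition.  The
alternative filter-then-merge order is available via ``merge_order`` for
comparison with implementations that chose differently.

``detect_bursts_bruteforce`` is a deliberately literal re-implementation
(explicit candidate enumeration, fixed-point merge loop) kept as an
independent oracle for the test suite; it is never used in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SpikeTrain

MERGE_ORDERS = ("merge_then_filter", "filter_then_merge")


@dataclass(frozen=True)
class BurstParams:
    """Five-parameter Max-Interval definition (seconds / counts)."""

    max_begin_isi: float = 0.1
    max_end_isi: float = 0.2
    min_ibi: float = 0.5
    min_duration: float = 0.05
    min_spikes: int = 10
    merge_order: str = "merge_then_filter"

    def __post_init__(self) -> None:
        if not (self.max_begin_isi > 0 and self.max_end_isi > 0
                and self.min_ibi > 0 and self.min_duration > 0):
            raise ValueError("all burst parameters must be positive")
        if self.max_begin_isi > self.max_end_isi:
            raise ValueError("max_begin_isi must not exceed max_end_isi")
        if self.min_spikes < 2:
            raise ValueError("min_spikes must be at least 2")
        if self.merge_order not in MERGE_ORDERS:
            raise ValueError(f"merge_order must be one of {MERGE_ORDERS}")


@dataclass(frozen=True)
class Burst:
    """A detected burst: an index span into the train plus derived times."""

    first_spike_index: int
    last_spike_index: int
    start_time: float
    end_time: float

    @property
    def n_spikes(self) -> int:
        return self.last_spike_index - self.first_spike_index + 1

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


def _make_burst(times: np.ndarray, first: int, last: int) -> Burst:
    return Burst(first_spike_index=first, last_spike_index=last,
                 start_time=float(times[first]), end_time=float(times[last]))


def _candidates(times: np.ndarray, params: BurstParams) -> list[tuple[int, int]]:
    """Phase 1: left-to-right scan producing candidate index spans.

    A candidate opens at spike i when ISI(i -> i+1) <= max_begin_isi and
    extends while each subsequent ISI <= max_end_isi; the first ISI
    > max_end_isi closes it.  A closed candidate never reopens; a later
    qualifying ISI opens a new candidate.
    """
    n = times.size
    isi = np.diff(times)
    spans: list[tuple[int, int]] = []
    i = 0
    while i < n - 1:
        if isi[i] <= params.max_begin_isi:
            j = i + 1
            while j < n - 1 and isi[j] <= params.max_end_isi:
                j += 1
            spans.append((i, j))
            i = j + 1
        else:
            i += 1
    return spans


def _merge(spans: list[tuple[int, int]], times: np.ndarray,
           params: BurstParams) -> list[tuple[int, int]]:
    """Phase 2: merge consecutive candidates with IBI < min_ibi (transitive)."""
    if not spans:
        return spans
    merged = [spans[0]]
    for first, last in spans[1:]:
        prev_first, prev_last = merged[-1]
        if times[first] - times[prev_last] < params.min_ibi:
            merged[-1] = (prev_first, last)
        else:
            merged.append((first, last))
    return merged


def _filter(spans: list[tuple[int, int]], times: np.ndarray,
            params: BurstParams) -> list[tuple[int, int]]:
    """Phase 3: retain spans meeting the duration and spike-count minima."""
    return [(f, l) for f, l in spans
            if l - f + 1 >= params.min_spikes
            and times[l] - times[f] >= params.min_duration]


def detect_bursts(train: SpikeTrain,
                  params: BurstParams | None = None) -> list[Burst]:
    """Detect bursts in one spike train with the Max-Interval algorithm.

    Returns disjoint, time-ordered bursts, each with at least
    ``min_spikes`` spikes and duration at least ``min_duration``.
    """
    if params is None:
        params = BurstParams()
    times = train.spike_times
    spans = _candidates(times, params)
    if params.merge_order == "merge_then_filter":
        spans = _filter(_merge(spans, times, params), times, params)
        # merged candidates are contiguous, so retained bursts are >= min_ibi
        # apart; assert the documented post-condition
        for (_, l0), (f1, _) in zip(spans, spans[1:]):
            assert times[f1] - times[l0] >= params.min_ibi
    else:
        spans = _merge(_filter(spans, times, params), times, params)
    return [_make_burst(times, f, l) for f, l in spans]


def detect_bursts_bruteforce(train: SpikeTrain,
                             params: BurstParams | None = None) -> list[Burst]:
    """Literal re-derivation of the Max-Interval contract (test oracle).

    Enumerates candidate spans by explicitly testing every possible start
    and extension, then merges by re-scanning all pairs to a fixed point,
    then filters.  O(n^2); intended for trains of at most a few hundred
    spikes in tests.
    """
    if params is None:
        params = BurstParams()
    times = train.spike_times
    n = times.size

    # candidate enumeration: for each spike, check whether it starts a
    # candidate (short enough ISI to the next spike, and not already inside
    # a candidate), then extend one spike at a time
    spans: list[tuple[int, int]] = []
    claimed_until = -1
    for i in range(n - 1):
        if i <= claimed_until:
            continue
        if times[i + 1] - times[i] <= params.max_begin_isi:
            j = i + 1
            while j + 1 < n and times[j + 1] - times[j] <= params.max_end_isi:
                j += 1
            spans.append((i, j))
            claimed_until = j

    def merge_fixed_point(ss: list[tuple[int, int]]) -> list[tuple[int, int]]:
        ss = list(ss)
        changed = True
        while changed:
            changed = False
            for a in range(len(ss) - 1):
                (f0, l0), (f1, l1) = ss[a], ss[a + 1]
                if times[f1] - times[l0] < params.min_ibi:
                    ss[a:a + 2] = [(f0, l1)]
                    changed = True
                    break
        return ss

    def keep(span: tuple[int, int]) -> bool:
        f, l = span
        return (l - f + 1 >= params.min_spikes
                and times[l] - times[f] >= params.min_duration)

    if params.merge_order == "merge_then_filter":
        spans = [s for s in merge_fixed_point(spans) if keep(s)]
    else:
        spans = merge_fixed_point([s for s in spans if keep(s)])
    return [_make_burst(times, f, l) for f, l in spans]


def bursts_to_frame(unit_id: str, epoch: str, bursts: list[Burst]):
    """Burst list as a DataFrame in the standard burst-table layout."""
    import pandas as pd

    return pd.DataFrame({
        "unit_id": unit_id,
        "epoch": epoch,
        "burst_index": range(len(bursts)),
        "start_time_s": [b.start_time for b in bursts],
        "end_time_s": [b.end_time for b in bursts],
        "n_spikes": [b.n_spikes for b in bursts],
        "duration_s": [b.duration for b in bursts],
    })


def burst_spike_mask(train: SpikeTrain, bursts: list[Burst]) -> np.ndarray:
    """Boolean mask over the train's spikes: True for spikes inside a burst."""
    mask = np.zeros(train.n_spikes, dtype=bool)
    for b in bursts:
        mask[b.first_spike_index:b.last_spike_index + 1] = True
    return mask
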