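"""Baseline-vs-exposure response computation and classification.

For every analyzable unit the relative change of a feature from the
baseline epoch to the drug-exposure epoch is computed as a percentage.
Two rules from standard MEA drug-challenge practice apply:

* cessation rule -- a unit whose activity stops entirely under drug is
  assigned exactly -100 % change;
* exclusion rule -- a unit whose feature changes by more than +1000 % is
  excluded from the response tabulation (one-sided: decreases are bounded
  at -100 %, so no lower exclusion is needed).

Classified units fall into exactly one of increase / decrease /
no_change; the no-change band is a symmetric relative threshold
(default +-10 %), configurable because published protocols rarely state
it.  Units silent at baseline are not analyzable (relative change is
undefined) and are reported in a separate bucket rather than silently
dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import features_table
from .io import Recording

RESPONSE_CLASSES = ("increase", "decrease", "no_change")

DEFAULT_NO_CHANGE_EPSILON = 10.0
DEFAULT_EXCLUSION_LIMIT = 1000.0

FEATURE_COLUMNS = {
    "firing_rate": "firing_rate_hz",
    "mean_isi": "mean_isi_s",
    "pct_out_of_burst": "pct_out_of_burst",
}


@dataclass(frozen=True)
class ResponseRecord:
    unit_id: str
    feature: str
    baseline_value: float
    exposure_value: float
    pct_change: float  # NaN when not analyzable
    response_class: str  # increase | decrease | no_change | excluded | not_analyzable


def percent_change(baseline_value: float, exposure_value: float) -> float:
    """Relative change from baseline, in percent.

    ``exposure_value == 0`` maps to exactly -100 (cessation rule).
    A zero (or undefined) baseline makes the change undefined -> NaN;
    the unit is flagged not-analyzable downstream, distinct from excluded.
    """
    if math.isnan(baseline_value) or math.isnan(exposure_value):
        return math.nan
    if baseline_value <= 0:
        return math.nan
    if exposure_value == 0:
        return -100.0
    return 100.0 * (exposure_value - baseline_value) / baseline_value


def classify_unit(pct_change: float,
                  no_change_epsilon: float = DEFAULT_NO_CHANGE_EPSILON,
                  exclusion_limit: float = DEFAULT_EXCLUSION_LIMIT) -> str:
    """Map a percent change to increase / decrease / no_change / excluded."""
    if not exclusion_limit > no_change_epsilon >= 0:
        raise ValueError("need exclusion_limit > no_change_epsilon >= 0")
    if math.isnan(pct_change):
        return "not_analyzable"
    if pct_change > exclusion_limit:
        return "excluded"
    if abs(pct_change) <= no_change_epsilon:
        return "no_change"
    return "increase" if pct_change > 0 else "decrease"


def response_records(recording: Recording,
                     feature: str = "firing_rate",
                     no_change_epsilon: float = DEFAULT_NO_CHANGE_EPSILON,
                     exclusion_limit: float = DEFAULT_EXCLUSION_LIMIT,
                     features: pd.DataFrame | None = None) -> list[ResponseRecord]:
    """Per-unit baseline->exposure response records for one feature.

    Only units present in both epochs are considered.  ``features`` may
    supply a precomputed feature table to avoid re-detecting bursts.
    """
    if feature not in FEATURE_COLUMNS:
        raise ValueError(f"unknown feature {feature!r}")
    col = FEATURE_COLUMNS[feature]
    table = features_table(recording) if features is None else features
    wide = table.pivot(index="unit_id", columns="epoch", values=col)
    records = []
    for unit_id, row in wide.iterrows():
        if "baseline" not in row or "exposure" not in row:
            continue
        base, expo = row.get("baseline", math.nan), row.get("exposure", math.nan)
        if math.isnan(base) and math.isnan(expo):
            continue
        pct = percent_change(base, expo)
        records.append(ResponseRecord(
            unit_id=str(unit_id), feature=feature,
            baseline_value=float(base), exposure_value=float(expo),
            pct_change=pct,
            response_class=classify_unit(pct, no_change_epsilon, exclusion_limit),
        ))
    return records


def tabulate_responses(records_by_system: dict[str, list[ResponseRecord]]) -> pd.DataFrame:
    """2x3 contingency table of response classes per system.

    Rows are systems, columns increase / decrease / no_change; excluded
    and not-analyzable records do not appear.  Raises on empty input.
    """
    counted = {}
    for system, records in records_by_system.items():
        counts = {cls: 0 for cls in RESPONSE_CLASSES}
        for r in records:
            if r.response_class in counts:
                counts[r.response_class] += 1
        counted[system] = counts
    if not counted or all(sum(c.values()) == 0 for c in counted.values()):
        raise ValueError("no classified records to tabulate")
    return pd.DataFrame.from_dict(counted, orient="index",
                                  columns=list(RESPONSE_CLASSES)).astype(int)


def responses_to_frame(records: list[ResponseRecord]) -> pd.DataFrame:
    """Response records as the standard response-table CSV layout."""
    return pd.DataFrame({
        "unit_id": [r.unit_id for r in records],
        "feature": [r.feature for r in records],
        "baseline": [r.baseline_value for r in records],
        "exposure": [r.exposure_value for r in records],
        "pct_change": [r.pct_change for r in records],
        "response_class": [r.response_class for r in records],
    })


def class_proportions(records: list[ResponseRecord]) -> dict[str, float]:
    """Proportions of increase / decrease / no_change among classified units."""
    kept = [r for r in records if r.response_class in RESPONSE_CLASSES]
    n = len(kept)
    if n == 0:
        return {cls: math.nan for cls in RESPONSE_CLASSES}
    return {cls: sum(r.response_class == cls for r in kept) / n
            for cls in RESPONSE_CLASSES}
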