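# Methods

## Scope and data model

The pipeline starts from sorted single-unit spike timestamps; spike
sorting, raw-voltage handling and network-level (multi-electrode) burst
measures are out of scope. A recording is a set of units, each with one
spike train per epoch (`baseline`, `exposure`), stored as a CSV spike
table plus a JSON sidecar. Timestamps are seconds as decimal text —
acquisition systems differ in sampling rate, so sample indices are not
portable — and are written with `repr` and re-parsed with round-trip
float precision, making the round trip bit-exact. Epoch duration lives
in metadata rather than being inferred from the last spike, because
firing rate must use the full recording window even for sparse units.
The sidecar also carries a unit roster so that a unit with *zero* spikes
in an epoch (complete cessation under drug) survives a round trip and is
distinguishable from a unit that was never recorded. Duplicate
timestamps within a unit/epoch are treated as upstream sorting artifacts
and rejected, not silently deduplicated.

## Max-Interval burst detection

Five parameters, defaults: `max_begin_isi` 0.1 s, `max_end_isi` 0.2 s,
`min_ibi` 0.5 s, `min_duration` 0.05 s, `min_spikes` 10 — the standard
parameter set for cortical cultures on planar MEAs. Three phases:

1. **Detect** — scan ISIs left to right; open a candidate on
   ISI ≤ `max_begin_isi`, extend while ISI ≤ `max_end_isi`, close at the
   first longer ISI. A closed candidate never reopens; a later
   qualifying ISI starts a new candidate.
2. **Merge** — consecutive candidates whose inter-burst interval (last
   spike of one to first spike of the next) is strictly below `min_ibi`
   merge, transitively, including any intervening spikes.
3. **Filter** — retain candidates with duration ≥ `min_duration` *and*
   spike count ≥ `min_spikes`.

Choices the literature leaves open, fixed here and exposed as
configuration:

* **Strictness**: ISI and retention thresholds inclusive (≤ / ≥), the
  merge test exclusive (< `min_ibi`). This matches the common
  NeuroExplorer-style convention.
* **Phase order**: merge before filter, because filtering first would
  discard sub-threshold fragments that legitimately combine into a
  retained burst. Since merged candidates are contiguous spike runs,
  retained bursts are always ≥ `min_ibi` apart; this is asserted as a
  post-condition at run time. The alternative order is available via
  `merge_order="filter_then_merge"`.
* **Duration** is first-spike-to-last-spike — the only definition
  computable from timestamps alone.

`detect_bursts_bruteforce` re-derives the same contract as literally as
possible (explicit candidate enumeration, fixed-point merge loop,
O(n²)); the test suite asserts exact span equivalence on hundreds of
randomized trains and parameter sets, plus translation invariance,
monotonicity in the retention thresholds, and idempotence of burst
membership.

## Features

Per unit and epoch: firing rate (count / full epoch duration), mean ISI,
and percent of spikes outside bursts. Mean ISI defaults to
**intra-burst mode** — intervals between consecutive spikes inside the
same burst, excluding boundary-spanning intervals — because whole-train
mean ISI at ~1 Hz is ≈ 1 s, dominated by the firing rate, whereas the
intra-burst mean (≤ `max_end_isi` by construction) characterises burst
structure; whole-train mode (`all`) is selectable. Undefined values
(ISI of a train with < 2 spikes or no bursts in intra-burst mode;
percent-out-of-burst of a silent train) are missing values, excluded
listwise per feature, never zeros. Population summaries are mean ± SEM
across units; spikes are never pooled across units.

## Response classification

Percent change of a feature from baseline:
`100·(exposure − baseline)/baseline`, with two fixed rules — cessation
(exposure activity exactly zero) maps to exactly −100 %, and changes
> +1000 % are excluded (one-sided: decreases are bounded at −100 %, so
a lower limit would be vacuous). Units silent at *baseline* have no
defined relative change and go to a separate `not_analyzable` bucket.
The `no_change` band is a symmetric relative threshold, default ±10 %:
published protocols report a no-change class without stating its
criterion, so the simplest defensible rule is used and surfaced
prominently in configuration (`no_change_epsilon_pct`). Classification
uses firing rate by default; other features carry changes without
classes unless requested. Exclusions apply per feature.

## Statistics

* **Mann-Whitney U**: two-sided; exact null enumeration when
  min(n) ≤ 8 with no ties (verified in tests against an exhaustive
  permutation oracle), otherwise normal approximation with midrank tie
  correction and continuity correction.
* **Pearson chi-square** on the system × response-class table, no
  Yates correction, df = (r−1)(c−1); columns observed in neither group
  are dropped (reducing df) before testing. The uncorrected statistic is
  the one that reproduces published table statistics exactly.
* **Kruskal-Wallis** with tie correction `H / (1 − Σ(t³−t)/(N³−N))`,
  referred to χ²(k−1).
* **Dunn's post hoc**:
  `z_ab = (R̄_a − R̄_b) / sqrt[(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_a + 1/n_b)]`
  on pooled midranks; p-values Bonferroni-multiplied by the number of
  pairs (capped at 1), the adjustment reported by mainstream commercial
  statistics packages; `adjustment="none"` is available. Implemented
  in-house because neither scipy nor statsmodels provides Dunn's test;
  Mann-Whitney, Kruskal-Wallis and the chi-square computation delegate
  to `scipy.stats`.

Type-I error calibration of all three omnibus tests is asserted in the
acceptance suite: 2000 null replicates each at group size 100 (the scale
of the real cohorts), rejection rate within 3 binomial standard errors
of α = 0.05.

## Synthetic cohorts

The generator emulates the *statistical structure* the analysis assumes,
not biophysics: no network coupling, electrode noise, waveforms or
sorting errors. Its purpose is parameter recovery — known inputs pushed
through the full pipeline.

Construction per unit and epoch, given a unit rate `r` and epoch length
`T` (default 1200 s):

1. The burst spike budget is `f·r·T` (`f` = burst spike fraction);
   the number of bursts is the budget over the mean spikes-per-burst
   (uniform 10–15), stochastically rounded — dithered rounding removes
   the small systematic bias plain rounding leaves in cohort means.
2. Intra-burst ISIs are drawn from a Beta distribution scaled to
   (0, `max_begin_isi`], with the preset mean and concentration 10. A
   truncated exponential cannot reach the required means (its mean on
   (0, 0.1] is below 0.05 s, the presets need 0.061 and 0.079 s); any
   distribution on that support with the stated mean satisfies the
   contracts, and the scaled Beta is the simplest such family.
3. Bursts are placed uniformly at random with inter-burst gaps
   ≥ `min_ibi` + 0.1 s margin (gap-removal construction).
4. Tonic spikes fill the remaining budget (stochastically rounded
   `(1−f)·r·T`) from a dead-time renewal process (hard minimum gap
   0.25 s > `max_end_isi`), *conditioned on that count*: uniform order
   statistics in gap-removed coordinates over the free intervals, which
   is exactly the renewal process given its event count. Tonic spikes
   are kept ≥ `max_end_isi` + 0.1 s away from every burst spike.

These margins make ground truth exact: every burst opens and extends
itself (all ISIs ≤ `max_begin_isi`), no tonic spike can open or extend a
candidate, and no two bursts can merge. Hence the detector provably
returns the generator's labels, asserted per-train in tests.

Per-unit rates are jittered with a lognormal factor (σ = 0.3, a
realistic between-unit spread consistent with the greater variability
reported in culture recordings), truncated at ±2σ in log space so
extreme draws cannot exceed the packing capacity of the dead-time tonic
process, and renormalised to mean exactly 1 so cohort mean rates stay on
target. Infeasible combinations (spike budget unplaceable in the epoch)
raise a diagnostic error rather than degrading silently.

Drug effects are per-unit rate multipliers on the exposure epoch
(0 ⇒ empty train ⇒ −100 % change). Multipliers are allocated to units by
largest-remainder proportional counts and then shuffled, rather than
drawn i.i.d., so a small cohort realises its preset mix exactly — the
published proportions a preset mirrors are themselves realised counts,
not expectations. At n = 196 the `ketamine90-invivo` mix
(56.1/37.8/6.1 %) allocates 110/74/12 units.

Shipped presets: `invitro-baseline` (2.0 Hz, f = 0.27, ISI mean
0.061 s), `invivo-baseline` (1.06 Hz, f = 0.061, ISI mean 0.079 s),
`ketamine90-invitro` (cessation in all units), `ketamine90-invivo`
(56.1 % ×2.0, 37.8 % ×0.5, 6.1 % ×1.0).

What passing recovery tests does **not** show about real data: real
trains have refractory-period ISI structure, nonstationarity, network
synchrony and sorting contamination, none of which the generator
produces; calibration recovery validates the *pipeline's arithmetic and
bookkeeping*, not the biological fidelity of the presets.

## Pipeline

`run_baseline_comparison` (two cohorts: per-feature mean ± SEM + n and
Mann-Whitney per feature) and `run_drug_comparison` (per-unit response
records, 2×3 table + chi-square, per-class percent-change summaries,
Kruskal-Wallis + Dunn when more than two groups are supplied) emit JSON
reports plus companion CSVs; every number in a report traces to one of
the operations above. Exposure windows span the full exposure epoch,
matching baseline; vehicle runs are dose 0 through the same path. Unit
counts, exclusions and not-analyzable tallies are logged at stage
boundaries so the n bookkeeping stays auditable. Runs are deterministic
given config and seed.

## Problem sizes and numerical choices

Acceptance-level checks use 500-unit cohorts for baseline calibration
(each quantity checked within 2 SEM of the simulated cohort), 33- and
196-unit cohorts for effect-mix recovery (binomial error), 500
randomized trains for detector-oracle equivalence, and 2000 null
replicates for test calibration; these sizes give standard errors well
below the effects being checked while keeping a full run in seconds.
Ties in all rank tests use midranks. Burst detection on an empty or
single-spike train returns no bursts. The acceptance script derives
independent child seeds for each simulated cohort from the single
`--seed` argument via `numpy.random.SeedSequence`.

## Known limitations

* The generator's tonic process is a dead-time renewal, deliberately
  unrealistic (no ISIs below 0.25 s outside bursts) to keep ground truth
  exact.
* Intra-burst ISI means above 0.05 s force a left-skewed Beta; real
  intra-burst ISI distributions are typically right-skewed with a sharp
  refractory onset.
* The no-change band (±10 %) is a convention, not an estimate; response
  proportions near the band edge are sensitive to it.
* No alternative burst detectors (Poisson surprise, CMA), no
  network-burst or synchrony measures, no dose-response curve fitting.
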