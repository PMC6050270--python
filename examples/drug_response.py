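"""Classify drug responses and compare the class distributions.

Simulates the strongest drug-challenge scenario: an in vitro cohort
(33 units) in which every unit ceases firing under drug, and an in vivo
cohort (196 units) with a mixed response (56.1 % doubling, 37.8 %
halving, 6.1 % unchanged).  Classifies each unit's firing-rate change
from baseline, tabulates the 2x3 response table, and runs the chi-square
test of homogeneity.
"""

from meaburst import (generate_cohort, get_preset, pearson_chi_square,
                      response_records, tabulate_responses)
from meaburst.response import class_proportions

records = {}
for label, preset, n in (("in_vitro", "ketamine90-invitro", 33),
                         ("in_vivo", "ketamine90-invivo", 196)):
    rec, _ = generate_cohort(get_preset(preset, n_units=n), seed=1)
    records[label] = response_records(rec)  # firing-rate classification
    props = class_proportions(records[label])
    print(f"{label} (n={n}): " + ", ".join(
        f"{cls} {100 * p:.1f}%" for cls, p in props.items()))

table = tabulate_responses(records)
print("\nresponse table (rows: system; cols: increase/decrease/no_change)")
print(table.to_string())
res = pearson_chi_square(table.to_numpy())
print(f"\nchi-square({res.df:.0f}, n={res.details['n_total']}) "
      f"= {res.statistic:.2f}, p = {res.p_value:.2e}")
# The cessation cohort is 100 % decrease (each unit at exactly -100 %
# change); the mixed cohort recovers its injected 56.1/37.8/6.1 split,
# and the two distributions differ overwhelmingly (p << 0.0001).
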