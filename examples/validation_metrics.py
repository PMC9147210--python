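"""Truth-set comparison on a synthetic fixture with planted errors.

Generates a 1000-base target with 100 truth SNVs, drops 5 (planted
false negatives) and adds 3 spurious calls (planted false positives),
then recomputes the confusion counts and the five performance metrics.
"""

from panelval.simulate import make_truth_pair
from panelval.stats import compare_callsets, metrics_table

pair = make_truth_pair(
    n_targeted_bases=1000, n_snv=100, n_indel=0,
    fp_rate=0.03, fn_rate=0.05, seed=42,
)
counts = compare_callsets(pair.truth, pair.observed, pair.confident)
print(metrics_table(counts).to_string())
print(
    "\nThe SNV column recovers exactly the planted design: TP 95, FN 5,"
    "\nFP 3, and TN 897 reference bases (1000 targeted minus the 103"
    "\nvariant-bearing positions). Sensitivity 95% reflects the 5 planted"
    "\nmisses; specificity ~99.7% the 3 spurious calls."
)
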