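"""Full protocol on a user-supplied UCI-arrhythmia-layout table.

Pass the path to the CSV or ARFF file (279 feature columns, trailing class
column with labels 1-16, '?' for missing) as the first argument.  The
script cleans the table, binarizes the target (1 = normal -> 0, any
arrhythmia -> 1), runs all fifteen pipelines under stratified 4-fold CV
and reports mean accuracies and paired tests against M4.  Values are
reported, not asserted.  Expect a long run: the dCor stage alone is
O(p * n^2) per fold.
"""

import sys

from dcorselect import (
    METHOD_IDS,
    binarize_target,
    clean_features,
    load_table,
    method_spec,
    run_comparison,
)

if len(sys.argv) < 2:
    sys.exit("usage: python 05_arrhythmia_protocol.py <arrhythmia.csv|.arff>")

raw = load_table(sys.argv[1])
X, target, report = clean_features(raw)
print(f"loaded {raw.n_samples} rows; cleaning: {report.summary()}")
y = binarize_target(target)
print(f"binary target: {int((y == 0).sum())} normal / {int((y == 1).sum())} pathological")

specs = [method_spec(m, k_final=14, seed=0) for m in METHOD_IDS]
rep = run_comparison(specs, X.to_numpy(), y, n_folds=4, seed=0, reference="M4")
print(rep.summary[["method", "mean_accuracy", "sd_accuracy"]].round(4).to_string(index=False))
print("\nPaired tests vs M4:")
print(rep.tests.round(4).to_string(index=False))
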