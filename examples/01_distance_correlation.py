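"""Distance correlation vs Pearson on non-monotonic class signals.

Builds a small synthetic table whose quadratic-family features carry a
variance-coded class signal (zero linear correlation by symmetry) and
prints both statistics per feature family.  dCor separates every relevant
family from noise; Pearson only sees the linear ones.
"""

import numpy as np

from dcorselect import SyntheticSpec, generate, score_features

X, y, truth = generate(SyntheticSpec(n=500, seed=0))
scores = score_features(X.to_numpy(), y.astype(float)).scores
pearson = np.array([abs(np.corrcoef(X.to_numpy()[:, j], y)[0, 1])
                    for j in range(X.shape[1])])

print(f"{'family':<18}{'mean dCor':>10}{'mean |r|':>10}")
for fam in ("linear", "quadratic", "sinusoidal", "redundant_cluster", "noise"):
    m = truth.family == fam
    print(f"{fam:<18}{scores[m].mean():>10.3f}{pearson[m].mean():>10.3f}")

print("\nQuadratic/sinusoidal features: dCor well above the noise level while")
print("|Pearson r| stays near zero - the dependence is real but non-monotonic.")
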