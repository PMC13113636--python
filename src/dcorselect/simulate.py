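"""Synthetic tabular benchmarks with known feature relevance structure.

The generator emulates the dependency structure the selection pipelines
are designed to exploit, with a binary target and four feature families:

* ``linear`` — mean shift with the class: ``effect·(2y−1) + N(0, noise_sd²)``;
  visible to both Pearson correlation and dCor.
* ``quadratic`` — class-modulated spread: ``(1 + effect·y)·z`` with
  ``z ~ N(0,1)``.  Symmetric about zero, so the linear correlation with the
  class is ≈ 0 while dCor remains positive.
* ``sinusoidal`` — a bounded non-monotonic version of the same idea:
  ``(1 + effect·y)·sin(3u)`` with ``u ~ U(−π, π)``; again zero linear
  correlation by symmetry.
* ``redundant_cluster`` — one strong linear signal plus near-copies
  (within-cluster Pearson ≥ 0.95 by construction), the multicollinearity
  trap that greedy top-score selection falls into.
* ``noise`` — independent ``N(0, noise_sd²)``.

Ground truth records each feature's family, relevance and cluster id so
recovery precision/recall and selection diversity can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._validation import ValidationError

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "selection_quality", "to_csv"]

# near-copy jitter: corr = 1/sqrt(1 + δ²) with unit-variance base ⇒ δ=0.15 → r ≈ 0.989
CLUSTER_JITTER = 0.15


@dataclass
class SyntheticSpec:
    n: int = 500
    n_linear: int = 5
    n_quadratic: int = 5
    n_sinusoidal: int = 3
    n_clusters: int = 2
    cluster_size: int = 5
    n_noise: int = 30
    effect: float = 1.0
    noise_sd: float = 1.0
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValidationError("need n >= 2")
        if min(self.n_linear, self.n_quadratic, self.n_sinusoidal,
               self.n_clusters, self.n_noise) < 0 or self.cluster_size < 1:
            raise ValidationError("feature counts must be nonnegative")
        if self.total_features < 1:
            raise ValidationError("at least one feature required")
        if self.effect < 0 or self.noise_sd < 0:
            raise ValidationError("effect and noise_sd must be nonnegative")
        if not (0 < self.class_balance < 1):
            raise ValidationError("class_balance must be in (0, 1)")

    @property
    def total_features(self) -> int:
        return (self.n_linear + self.n_quadratic + self.n_sinusoidal
                + self.n_clusters * self.cluster_size + self.n_noise)


@dataclass
class GroundTruth:
    relevant: np.ndarray      # bool mask per feature
    family: np.ndarray        # family label per feature
    cluster: np.ndarray       # cluster id per feature, -1 outside clusters
    feature_names: list[str] = field(default_factory=list)

    def relevant_indices(self) -> np.ndarray:
        return np.flatnonzero(self.relevant)


def generate(spec: SyntheticSpec) -> tuple[pd.DataFrame, np.ndarray, GroundTruth]:
    """Draw one dataset: feature table, binary target, ground truth."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    y = (rng.random(n) < spec.class_balance).astype(int)
    s = 2.0 * y - 1.0

    cols, names, family, cluster = [], [], [], []

    def add(col, name, fam, cl=-1):
        cols.append(col)
        names.append(name)
        family.append(fam)
        cluster.append(cl)

    for i in range(spec.n_linear):
        add(spec.effect * s + rng.normal(0, spec.noise_sd, n), f"lin{i}", "linear")
    for i in range(spec.n_quadratic):
        z = rng.normal(0, 1, n)
        add((1.0 + spec.effect * y) * z, f"quad{i}", "quadratic")
    for i in range(spec.n_sinusoidal):
        u = rng.uniform(-np.pi, np.pi, n)
        add((1.0 + spec.effect * y) * np.sin(3 * u), f"sin{i}", "sinusoidal")
    for c in range(spec.n_clusters):
        base = spec.effect * s + rng.normal(0, spec.noise_sd, n)
        base_sd = base.std() if base.std() > 0 else 1.0
        add(base, f"clu{c}_0", "redundant_cluster", c)
        for m in range(1, spec.cluster_size):
            add(base + rng.normal(0, CLUSTER_JITTER * base_sd, n),
                f"clu{c}_{m}", "redundant_cluster", c)
    for i in range(spec.n_noise):
        add(rng.normal(0, spec.noise_sd, n), f"noise{i}", "noise")

    X = pd.DataFrame(np.column_stack(cols), columns=names)
    fam = np.array(family)
    truth = GroundTruth(
        relevant=(fam != "noise") & (spec.effect > 0),
        family=fam,
        cluster=np.array(cluster),
        feature_names=names,
    )
    return X, y, truth


def selection_quality(selected, truth: GroundTruth, X=None) -> dict:
    """Recovery precision/recall of relevant features, plus a diversity score.

    The diversity score is the mean absolute pairwise Pearson correlation
    among the selected columns (needs ``X``); lower means a less redundant
    subset.
    """
    sel = np.asarray(selected, dtype=int)
    if sel.size == 0:
        raise ValidationError("empty selection")
    if sel.min() < 0 or sel.max() >= truth.relevant.size:
        raise ValidationError("selected index out of range")
    rel = set(truth.relevant_indices().tolist())
    hit = sum(1 for j in sel if j in rel)
    out = {
        "precision": hit / sel.size,
        "recall": hit / len(rel) if rel else 0.0,
        "n_selected": int(sel.size),
    }
    if X is not None and sel.size > 1:
        M = np.asarray(X, dtype=float)[:, sel]
        C = np.corrcoef(M, rowvar=False)
        C = np.nan_to_num(C)
        out["diversity"] = float(np.abs(C[np.triu_indices(sel.size, 1)]).mean())
    return out


def to_csv(X: pd.DataFrame, y, path, truth: GroundTruth | None = None) -> None:
    """Write the table with a trailing ``class`` column; optional sidecar truth file."""
    df = X.copy()
    df["class"] = np.asarray(y, dtype=int)
    df.to_csv(path, index=False)
    if truth is not None:
        side = pd.DataFrame({
            "feature": truth.feature_names,
            "family": truth.family,
            "relevant": truth.relevant.astype(int),
            "cluster": truth.cluster,
        })
        side.to_csv(str(path) + ".truth.csv", index=False)
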