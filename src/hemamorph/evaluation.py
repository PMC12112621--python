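"""Validation protocol: stratified k-fold splits, held-out sizing, and
paired statistical testing of fold-wise metrics.

The split construction is deliberately deterministic: per class, indices
are shuffled with the seeded generator and dealt to folds by
largest-remainder allocation, so validation folds differ in size by at
most one and per-fold class proportions stay within one item of the
global proportions.  At k = 5 this realizes the 80:20 train/validation
ratio per fold.

Statistics: two-sided paired t-tests on fold-wise metrics with Bonferroni
correction, and Cohen's d for paired designs computed on the difference
series (d_z = mean(diff) / sd(diff), sample sd).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class SplitPlan:
    """k-fold plan: fold i validates on ``folds[i]`` and trains on the rest."""

    folds: list[list[int]]
    seed: int
    k: int
    n: int

    def train_indices(self, fold: int) -> list[int]:
        val = set(self.folds[fold])
        return [i for i in range(self.n) if i not in val]

    def to_dict(self) -> dict:
        return {"k": self.k, "seed": self.seed, "n": self.n, "folds": self.folds}


def stratified_kfold(labels, k: int = 5, seed: int = 42) -> SplitPlan:
    """Deterministic stratified k-fold split plan.

    Every class must have at least k members.  Per class, the seeded
    shuffle is dealt round-robin across folds starting at a per-class
    rotating offset, which keeps both overall fold sizes and per-fold
    class counts within one of each other.
    """
    labels = np.asarray(labels)
    n = len(labels)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    classes = sorted(set(labels.tolist()), key=str)
    offset = 0
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ValueError(f"class {cls!r} has fewer than k={k} members")
        idx = idx[rng.permutation(len(idx))]
        for j, i in enumerate(idx):
            folds[(j + offset) % k].append(int(i))
        offset = (offset + len(idx)) % k
    for f in folds:
        f.sort()
    return SplitPlan(folds=folds, seed=seed, k=k, n=n)


def holdout_split(n: int, fraction: float = 0.2) -> tuple[int, int]:
    """(held_out, remaining) sizes; held_out = round-half-up(n * fraction)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    held = int(math.floor(n * fraction + 0.5))
    return held, n - held


@dataclass
class StatEntry:
    t: float | None
    p_raw: float | None
    p_adjusted: float | None
    significant: bool | None
    cohens_d: float | None
    degenerate: bool = False
    alpha: float = 0.05
    n_comparisons: int = 1


def paired_ttest(
    metrics_a,
    metrics_b,
    alpha: float = 0.05,
    n_comparisons: int = 1,
) -> StatEntry:
    """Two-sided paired t-test with Bonferroni-adjusted p.

    Zero-variance difference series (all diffs equal) make the statistic
    undefined; the entry comes back flagged degenerate with no p value.
    """
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("metric series must be 1-d and equal length")
    if len(a) < 2:
        raise ValueError("need at least two paired observations")
    diffs = a - b
    if diffs.std(ddof=1) < 1e-15:
        return StatEntry(None, None, None, None, None, degenerate=True,
                         alpha=alpha, n_comparisons=n_comparisons)
    t, p = stats.ttest_rel(a, b)
    p_adj = min(1.0, float(p) * n_comparisons)
    return StatEntry(
        t=float(t),
        p_raw=float(p),
        p_adjusted=p_adj,
        significant=bool(p_adj < alpha),
        cohens_d=cohens_d(a, b),
        alpha=alpha,
        n_comparisons=n_comparisons,
    )


def cohens_d(metrics_a, metrics_b) -> float:
    """Paired-design effect size d_z = mean(diff) / sd(diff) (sample sd)."""
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("series must be equal length >= 2")
    diffs = a - b
    sd = diffs.std(ddof=1)
    if sd < 1e-15:
        raise ValueError("zero-variance differences: d undefined")
    return float(diffs.mean() / sd)


@dataclass
class StatReport:
    """Bundle of named pairwise comparisons with shared Bonferroni family."""

    alpha: float = 0.05
    entries: dict[str, StatEntry] = field(default_factory=dict)

    @classmethod
    def from_comparisons(
        cls, comparisons: dict[str, tuple[list, list]], alpha: float = 0.05
    ) -> "StatReport":
        m = len(comparisons)
        report = cls(alpha=alpha)
        for name, (a, b) in comparisons.items():
            report.entries[name] = paired_ttest(a, b, alpha=alpha, n_comparisons=m)
        return report
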