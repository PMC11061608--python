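"""Group-comparison statistics: normality-gated two-group tests, Kruskal-Wallis
with Dunn's post-hoc z-tests, and Pearson correlation.

Two-group comparisons are gated on per-group Shapiro-Wilk normality (normal
means p > 0.05): if any group fails the gate a two-sided Mann-Whitney test is
used — exact when both groups have n <= 20 and the pooled values are tie-free,
otherwise asymptotic with tie and continuity correction. When both groups pass
the gate a two-sided Welch t-test is used and flagged as the parametric branch.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def stars(p: float) -> str:
    for cutoff, mark in STAR_LEVELS:
        if p < cutoff:
            return mark
    return "ns"


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    group_sizes: dict[str, int]
    normality_p: dict[str, float | None]
    alpha: float
    parametric: bool = False
    comparisons: pd.DataFrame | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _as_groups(values: Sequence[float], groups: Sequence) -> dict[object, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups differ in length")
    return {g: values[groups == g] for g in pd.unique(groups)}


def compare_two_groups(
    values: Sequence[float],
    groups: Sequence,
    alpha: float = 0.05,
    force: str = "auto",
) -> TestResult:
    """Normality-gated two-sided comparison of two groups (see module docstring).

    ``force="nonparametric"`` bypasses the Shapiro-Wilk gate and always runs
    the Mann-Whitney branch; ``force="auto"`` (default) applies the gate.
    """
    if force not in ("auto", "nonparametric"):
        raise ValueError(f"force must be 'auto' or 'nonparametric', got {force!r}")
    split = _as_groups(values, groups)
    if len(split) != 2:
        raise ValueError(f"expected exactly 2 group labels, got {len(split)}")
    (la, a), (lb, b) = split.items()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    normality: dict[str, float | None] = {}
    gate_possible = True
    for label, vec in ((la, a), (lb, b)):
        if len(vec) < 3:
            warnings.warn(
                f"group {label!r} has n={len(vec)} < 3; normality gate skipped, "
                "nonparametric branch forced"
            )
            normality[str(label)] = None
            gate_possible = False
        else:
            normality[str(label)] = float(sps.shapiro(vec).pvalue)
    both_normal = (
        force == "auto" and gate_possible and all(p > alpha for p in normality.values())
    )
    sizes = {str(la): len(a), str(lb): len(b)}
    if both_normal:
        res = sps.ttest_ind(a, b, equal_var=False)
        return TestResult(
            test="welch-t",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            group_sizes=sizes,
            normality_p=normality,
            alpha=alpha,
            parametric=True,
        )
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    if tie_free and len(a) <= 20 and len(b) <= 20:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        name = "mann-whitney-exact"
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        name = "mann-whitney-asymptotic"
    return TestResult(
        test=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_sizes=sizes,
        normality_p=normality,
        alpha=alpha,
    )


def _dunn_comparisons(
    split: dict[object, np.ndarray], adjust: str
) -> pd.DataFrame:
    """Dunn's pairwise z-tests on the pooled ranks with tie correction."""
    labels = list(split)
    pooled = np.concatenate([split[g] for g in labels])
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_rank: dict[object, float] = {}
    start = 0
    for g in labels:
        size = len(split[g])
        mean_rank[g] = float(ranks[start : start + size].mean())
        start += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n - 1)))
    rows = []
    for ga, gb in itertools.combinations(labels, 2):
        na, nb = len(split[ga]), len(split[gb])
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
        z = (mean_rank[ga] - mean_rank[gb]) / se if se > 0 else 0.0
        p = float(2.0 * sps.norm.sf(abs(z)))
        rows.append({"group_a": str(ga), "group_b": str(gb), "z": float(z), "p_raw": p})
    df = pd.DataFrame(rows)
    m = len(df)
    if adjust == "bonferroni":
        df["p_adj"] = np.minimum(df["p_raw"] * m, 1.0)
    elif adjust == "holm":
        order = np.argsort(df["p_raw"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * df["p_raw"].iloc[idx])
            adj[idx] = min(running, 1.0)
        df["p_adj"] = adj
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    df["stars"] = df["p_adj"].map(stars)
    return df


def compare_multi_groups(
    values: Sequence[float],
    groups: Sequence,
    alpha: float = 0.05,
    adjust: str = "bonferroni",
) -> TestResult:
    """Kruskal-Wallis (tie-corrected) across >= 3 groups with Dunn's pairwise
    post-hoc z-tests; adjusted p-values carry Prism-style star codes."""
    split = _as_groups(values, groups)
    if len(split) < 3:
        raise ValueError(f"need >= 3 groups, got {len(split)}")
    for label, vec in split.items():
        if len(vec) == 0:
            raise ValueError(f"group {label!r} is empty")
    arrays = list(split.values())
    try:
        kw = sps.kruskal(*arrays)
        statistic, p = float(kw.statistic), float(kw.pvalue)
    except ValueError:
        # all values identical across every group: no evidence of difference
        statistic, p = 0.0, 1.0
    comparisons = _dunn_comparisons(split, adjust)
    normality = {
        str(g): (float(sps.shapiro(v).pvalue) if len(v) >= 3 else None)
        for g, v in split.items()
    }
    return TestResult(
        test="kruskal-wallis+dunn",
        statistic=statistic,
        p_value=p,
        group_sizes={str(g): len(v) for g, v in split.items()},
        normality_p=normality,
        alpha=alpha,
        comparisons=comparisons,
    )


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with the two-sided p-value from the t-distribution
    on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y differ in length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
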