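"""Statistical test battery used by the reporting layer.

Standard tests (Pearson chi-squared without continuity correction, Wilcoxon
rank-sum, Kruskal-Wallis) delegate to :mod:`scipy.stats`; the module's own
logic is Dunn's rank-based post-hoc comparison (with Bonferroni family
correction) and the paired block-mean comparison of two shore profiles.
All p-values are two-tailed; the conventional significance level is 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "chi2_contingency",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "dunn_posthoc",
    "paired_t_profiles",
]

ALPHA = 0.05


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    inputs: str = ""
    two_tailed: bool = True
    alpha: float = ALPHA
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def chi2_contingency(table) -> TestResult:
    """Pearson chi-squared on an r x c count table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return TestResult("chi-squared", float(chi2), float(p),
                      inputs=f"{table.shape[0]}x{table.shape[1]} table, n={int(table.sum())}",
                      extra={"dof": int(dof)})


def wilcoxon_rank_sum(a, b) -> TestResult:
    stat, p = sps.ranksums(a, b)
    return TestResult("Wilcoxon rank-sum", float(stat), float(p),
                      inputs=f"n1={len(a)}, n2={len(b)}")


def kruskal_wallis(*groups) -> TestResult:
    stat, p = sps.kruskal(*groups)
    return TestResult("Kruskal-Wallis", float(stat), float(p),
                      inputs=f"k={len(groups)}, n={sum(len(g) for g in groups)}")


def dunn_posthoc(groups: dict, p_adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise rank comparisons after a Kruskal-Wallis test.

    ``groups`` maps label -> sample.  Uses the pooled-rank z statistic with
    tie correction; p-values are two-tailed and Bonferroni-adjusted over the
    number of pairs.
    """
    labels = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    pooled = np.concatenate(samples)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    ties = (counts**3 - counts).sum()
    tie_term = ties / (12.0 * (n - 1))
    mean_ranks = {}
    start = 0
    for lab, s in zip(labels, samples):
        mean_ranks[lab] = ranks[start : start + len(s)].mean()
        start += len(s)
    m = len(labels) * (len(labels) - 1) // 2
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            na, nb = len(samples[i]), len(samples[j])
            sd = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
            z = (mean_ranks[a] - mean_ranks[b]) / sd
            p = 2.0 * sps.norm.sf(abs(z))
            if p_adjust == "bonferroni":
                p = min(1.0, p * m)
            elif p_adjust is not None and p_adjust != "none":
                raise ValueError(f"unknown adjustment {p_adjust!r}")
            rows.append({"group_a": a, "group_b": b, "z": z, "p_value": p})
    return pd.DataFrame(rows)


def paired_t_profiles(
    profile_a: pd.DataFrame,
    profile_b: pd.DataFrame,
    window: int = 20,
    span: int = 2000,
) -> TestResult:
    """Paired t over matched block means of two smoothed border profiles.

    Both raw profiles (``distance``/``rate`` frames) are smoothed on the
    same non-overlapping ``window``-position block grid, matched on the
    block label within ``+/-span`` bp of the border; blocks missing on
    either side are dropped pairwise.  Fewer than 3 complete pairs is an
    error.  Identical profiles give t = 0, p = 1 (zero-variance guard).
    """
    from .rates import smooth_profile

    a = smooth_profile(profile_a, window=window)
    b = smooth_profile(profile_b, window=window)
    a = a[np.abs(a["distance"]) <= span]
    b = b[np.abs(b["distance"]) <= span]
    merged = a.merge(b, on="distance", suffixes=("_a", "_b")).dropna(
        subset=["rate_a", "rate_b"]
    )
    if len(merged) < 3:
        raise ValueError(f"only {len(merged)} complete block pairs; need >= 3")
    diff = merged["rate_a"].to_numpy() - merged["rate_b"].to_numpy()
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            stat, p = 0.0, 1.0
        else:  # constant nonzero shift: infinitely strong evidence
            stat, p = float(np.sign(diff.mean()) * np.inf), 0.0
    else:
        stat, p = sps.ttest_rel(merged["rate_a"], merged["rate_b"])
    return TestResult("paired t", float(stat), float(p),
                      inputs=f"{len(merged)} block pairs, window={window}")
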