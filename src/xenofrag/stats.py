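"""Marker statistics: orientation-folded AUC, permutation null, group tests.

A marker's AUC between two groups is the Mann-Whitney pair statistic
(wins + half-ties over all cross-group pairs) folded to ``max(A, 1 - A)``,
matching the auto-direction behavior of standard ROC tooling and making
the permutation null symmetric.  Markers with AUC above a threshold are
"informative" (0.9 for observed reporting, 0.8 inside the permutation
null).  The permutation test shuffles group labels among balanced
assignments, recomputes all marker AUCs per iteration, and compares the
observed informative count to the null counts:
``p = #(null >= observed) / n_perm``, with the 95% quantile of the null as
the one-sided reference bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import leaves_list, linkage
from statsmodels.stats.multitest import multipletests

from .genome import InvalidSpecError
from .cna import DegenerateInputError, cna_pca

DEFAULT_AUC_REPORTING = 0.9
DEFAULT_AUC_PERMUTATION = 0.8
DEFAULT_N_PERM = 1000


def _rank_auc(ranks: np.ndarray, mask: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Folded AUC per column from midranks and a group-1 membership mask."""
    r1 = ranks[mask].sum(axis=0)
    auc = (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n2)
    return np.maximum(auc, 1.0 - auc)


def marker_auc(values: Iterable[float], labels: Iterable) -> float:
    """Orientation-folded AUC of one marker between two groups."""
    v = np.asarray(list(values), dtype=float)
    lab = np.asarray(list(labels))
    levels = pd.unique(lab)
    if len(levels) != 2:
        raise InvalidSpecError(f"need exactly two groups, got {len(levels)}")
    mask = lab == levels[0]
    n1, n2 = int(mask.sum()), int((~mask).sum())
    if n1 == 0 or n2 == 0:
        raise InvalidSpecError("both groups must be non-empty")
    ranks = sps.rankdata(v)[:, None]
    return float(_rank_auc(ranks, mask, n1, n2)[0])


def marker_auc_series(matrix: pd.DataFrame, labels: Sequence) -> pd.Series:
    """Folded AUC for every marker (column) of a samples x markers matrix."""
    lab = np.asarray(labels)
    levels = pd.unique(lab)
    if len(levels) != 2:
        raise InvalidSpecError(f"need exactly two groups, got {len(levels)}")
    mask = lab == levels[0]
    n1, n2 = int(mask.sum()), int((~mask).sum())
    if n1 == 0 or n2 == 0:
        raise InvalidSpecError("both groups must be non-empty")
    ranks = sps.rankdata(matrix.to_numpy(dtype=float), axis=0)
    return pd.Series(_rank_auc(ranks, mask, n1, n2), index=matrix.columns, name="auc")


def count_informative(
    matrix: pd.DataFrame, labels: Sequence, threshold: float = DEFAULT_AUC_REPORTING
) -> tuple[int, list]:
    """Markers with AUC strictly above ``threshold``: count and identities."""
    if not (0.5 < threshold <= 1.0):
        raise InvalidSpecError("threshold must be in (0.5, 1]")
    auc = marker_auc_series(matrix, labels)
    informative = auc.index[auc.to_numpy() > threshold].tolist()
    return len(informative), informative


@dataclass
class PermutationResult:
    observed_informative: int
    null_counts: np.ndarray
    p_value: float
    null_q95: float
    auc_threshold: float
    informative_markers: list

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "observed": self.observed_informative,
                "p_value": self.p_value,
                "null_q95": self.null_q95,
                "auc_threshold": self.auc_threshold,
                "n_perm": len(self.null_counts),
            }
        )


def permutation_test(
    matrix: pd.DataFrame,
    labels: Sequence,
    n_perm: int = DEFAULT_N_PERM,
    threshold: float = DEFAULT_AUC_PERMUTATION,
    seed: int = 0,
    add_one: bool = False,
) -> PermutationResult:
    """Balanced label-shuffling null for the informative-marker count.

    Requires a balanced two-level design (the study design is 6 vs 6).
    Each iteration draws a uniformly random balanced relabeling (with
    replacement across iterations), recomputes all marker AUCs, and counts
    markers above ``threshold``.  ``p = #(null >= observed) / n_perm`` by
    default; ``add_one`` switches to the (count+1)/(n_perm+1) estimator.
    """
    lab = np.asarray(labels)
    levels = pd.unique(lab)
    if len(levels) != 2:
        raise InvalidSpecError(f"need exactly two groups, got {len(levels)}")
    mask = lab == levels[0]
    n1, n2 = int(mask.sum()), int((~mask).sum())
    if n1 != n2:
        raise InvalidSpecError(f"permutation test requires balanced groups, got {n1} vs {n2}")
    n = n1 + n2
    ranks = sps.rankdata(matrix.to_numpy(dtype=float), axis=0)
    auc_obs = _rank_auc(ranks, mask, n1, n2)
    observed = int((auc_obs > threshold).sum())
    informative = matrix.columns[auc_obs > threshold].tolist()

    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_perm, dtype=np.int64)
    perm_mask = np.zeros(n, dtype=bool)
    for i in range(n_perm):
        perm_mask[:] = False
        perm_mask[rng.choice(n, size=n1, replace=False)] = True
        auc = _rank_auc(ranks, perm_mask, n1, n2)
        null_counts[i] = int((auc > threshold).sum())

    ge = int((null_counts >= observed).sum())
    p = (ge + 1) / (n_perm + 1) if add_one else ge / n_perm
    q95 = float(np.quantile(null_counts, 0.95))
    return PermutationResult(observed, null_counts, float(p), q95, threshold, informative)


@lru_cache(maxsize=64)
def _u_cdf(n1: int, n2: int) -> np.ndarray:
    """Exact null CDF of the Mann-Whitney U statistic (no ties).

    Positional DP: walk the pooled sample in increasing rank order; placing
    a group-2 value after k group-1 values adds the n1 - k group-1 values
    still to come (all larger) to U.
    """
    max_u = n1 * n2
    dp = np.zeros((n1 + 1, max_u + 1))
    dp[0, 0] = 1.0
    for pos in range(n1 + n2):
        new = np.zeros_like(dp)
        for k in range(min(pos, n1) + 1):
            row = dp[k]
            if not row.any():
                continue
            if k < n1:  # next value belongs to group 1
                new[k + 1] += row
            if pos - k < n2:  # next value belongs to group 2
                add = n1 - k
                if add:
                    new[k, add:] += row[: max_u + 1 - add]
                else:
                    new[k] += row
        dp = new
    counts = dp[n1]
    return np.cumsum(counts) / counts.sum()


def _exact_u_quantile(n1: int, n2: int, alpha: float) -> int:
    """Largest k with P(U <= k) <= alpha under the exact null; -1 if none."""
    cdf = _u_cdf(n1, n2)
    ks = np.flatnonzero(cdf <= alpha + 1e-12)
    return int(ks[-1]) if ks.size else -1


@dataclass
class TestResult:
    p_value: float
    statistic: float
    method: str
    shift_estimate: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    degenerate: bool = False


def two_group_test(
    values_a: Iterable[float],
    values_b: Iterable[float],
    paired: bool = False,
    test: str = "utest",
) -> TestResult:
    """Rank-sum (U) or t test between two samples, with a 95% shift CI.

    For the unpaired U test the p-value is exact when ``n1*n2 <= 400`` and
    the data are tie-free, otherwise the normal approximation is used; the
    confidence interval is the Hodges-Lehmann interval on the location
    shift (a - b).  Zero-variance degenerate inputs yield p = 1 with the
    ``degenerate`` flag set.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidSpecError("need at least 2 observations per group")
    if paired and a.size != b.size:
        raise InvalidSpecError("paired test requires equal-length samples")

    if test == "ttest":
        if paired:
            d = a - b
            if np.allclose(d.var(), 0):
                return TestResult(1.0, 0.0, "paired t-test", float(np.mean(d)), degenerate=True)
            r = sps.ttest_rel(a, b)
        else:
            if np.allclose(a.var(), 0) and np.allclose(b.var(), 0) and a.mean() == b.mean():
                return TestResult(1.0, 0.0, "t-test", 0.0, degenerate=True)
            r = sps.ttest_ind(a, b)
        ci = r.confidence_interval(0.95)
        return TestResult(
            float(r.pvalue), float(r.statistic),
            "paired t-test" if paired else "t-test",
            float(a.mean() - b.mean()), float(ci.low), float(ci.high),
        )
    if test != "utest":
        raise InvalidSpecError(f"unknown test {test!r}")

    if paired:
        d = a - b
        if np.allclose(d, 0):
            return TestResult(1.0, 0.0, "paired rank test", 0.0, degenerate=True)
        r = sps.wilcoxon(a, b)
        walsh = np.sort(((d[:, None] + d[None, :]) / 2.0)[np.triu_indices(d.size)])
        hl = float(np.median(walsh))
        return TestResult(float(r.pvalue), float(r.statistic), "paired rank test", hl)

    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size * b.size <= 400 and not ties) else "asymptotic"
    r = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    diffs = np.sort((a[:, None] - b[None, :]).ravel())
    hl = float(np.median(diffs))
    m = a.size * b.size
    if method == "exact":
        k = _exact_u_quantile(a.size, b.size, 0.025)
    else:
        mu = m / 2.0
        sigma = np.sqrt(m * (a.size + b.size + 1) / 12.0)
        k = int(np.floor(mu + sps.norm.ppf(0.025) * sigma))
    if k < 0:
        ci_low, ci_high = float(diffs[0]), float(diffs[-1])
    else:
        ci_low, ci_high = float(diffs[k]), float(diffs[m - 1 - k])
    return TestResult(
        float(r.pvalue), float(r.statistic), f"U-test ({method})", hl, ci_low, ci_high
    )


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with monotonicity enforcement."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise InvalidSpecError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cluster_and_project(
    matrix: pd.DataFrame,
) -> tuple[list, np.ndarray, pd.DataFrame, np.ndarray]:
    """Hierarchical clustering + PCA of a samples x markers matrix.

    Markers are z-scored (constant markers dropped); clustering is average
    linkage on Euclidean distances; PCA matches :func:`xenofrag.cna.cna_pca`.
    Returns (leaf order as sample labels, linkage matrix, PCA scores,
    variance-explained percentages).
    """
    if len(matrix) < 3:
        raise InvalidSpecError("clustering needs at least 3 samples")
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise DegenerateInputError("constant matrix: nothing to cluster")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    link = linkage(Z, method="average", metric="euclidean")
    order = [matrix.index[i] for i in leaves_list(link)]
    scores, var_pct = cna_pca(matrix.loc[:, matrix.columns[keep]])
    return order, link, scores, var_pct
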