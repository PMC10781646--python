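"""Shared statistical kernels.

Every hypothesis test in the package funnels through here: the two-sided
Wilcoxon rank-sum test (exact by enumeration for small groups, tie-corrected
normal approximation otherwise), Benjamini-Hochberg FDR adjustment, the
upper-tail hypergeometric test, and the log2 fold-change convention used for
log1p-normalized single-cell expression.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: largest per-group size for which the exact enumeration path is used
EXACT_MAX = 8

_TOL = 1e-9


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs are passed through."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def _exact_rank_sum_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Exact two-sided rank-sum p for every column, by full enumeration.

    Enumerates all C(n1+n2, n1) assignments of the pooled (tied) ranks to
    group 1 and counts assignments whose rank-sum deviates from its mean at
    least as much as the observed one.  Ties are handled naturally because
    the pooled mid-ranks are fixed under relabeling.
    """
    n1, n2 = X.shape[0], Y.shape[0]
    n = n1 + n2
    pooled = np.vstack([X, Y])
    ranks = sps.rankdata(pooled, axis=0)
    mu = n1 * (n + 1) / 2.0
    observed = np.abs(ranks[:n1].sum(axis=0) - mu)
    idx = np.fromiter(
        (i for combo in combinations(range(n), n1) for i in combo), dtype=np.intp
    ).reshape(-1, n1)
    selector = np.zeros((idx.shape[0], n))
    selector[np.arange(idx.shape[0])[:, None], idx] = 1.0
    sums = selector @ ranks  # (n_combos, n_cols)
    return (np.abs(sums - mu) >= observed - _TOL).mean(axis=0)


def rank_sum_matrix(X, Y, exact_max: int = EXACT_MAX) -> np.ndarray:
    """Column-wise two-sided Wilcoxon rank-sum p-values.

    Parameters
    ----------
    X, Y
        Arrays of shape (n1, G) and (n2, G); each column is one variable
        (gene) tested between the two groups of rows.
    exact_max
        When both groups have at most this many rows, p-values come from
        exhaustive enumeration of label assignments; otherwise from the
        tie-corrected normal approximation with continuity correction.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must have the same number of columns")
    if X.shape[0] == 0 or Y.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    if X.shape[0] <= exact_max and Y.shape[0] <= exact_max:
        return _exact_rank_sum_matrix(X, Y)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.mannwhitneyu(X, Y, axis=0, alternative="two-sided",
                               method="asymptotic")
        p = np.atleast_1d(np.asarray(res.pvalue, dtype=float))
    # all-tied columns have zero variance; no evidence either way
    p[~np.isfinite(p)] = 1.0
    return np.minimum(p, 1.0)


def rank_sum_p(x, y, exact_max: int = EXACT_MAX) -> float:
    """Two-sided rank-sum p-value for a single pair of samples."""
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    return float(rank_sum_matrix(x, y, exact_max=exact_max)[0])


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric P(X >= k) for overlap k out of n draws,
    with K marked items in a population of N."""
    if k <= 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def log2_fold_change(x_log, y_log, pseudocount: float = 1.0):
    """log2 fold change between two groups of log1p-normalized values.

    De-logs to the normalized scale, averages within each group, and takes
    ``log2((mean_x + c) / (mean_y + c))`` — the convention common in
    single-cell pipelines.  Accepts 1-D (one gene) or 2-D (cells x genes)
    input; returns a scalar or a per-gene vector.
    """
    x = np.asarray(x_log, dtype=float)
    y = np.asarray(y_log, dtype=float)
    scalar = x.ndim == 1
    if scalar:  # one gene, many cells
        x, y = x[:, None], y[:, None]
    mx = np.expm1(x).mean(axis=0)
    my = np.expm1(y).mean(axis=0)
    lfc = np.log2((mx + pseudocount) / (my + pseudocount))
    return float(lfc[0]) if scalar else lfc


def pairwise_auc(pos, neg) -> float:
    """Probability that a positive score exceeds a negative one, ties
    counting half — the Mann-Whitney estimate of the ROC AUC."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)
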