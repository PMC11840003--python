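"""Count preprocessing: CPM scaling, expression filtering, smooth
group-aware quantile normalization and a PCA overview."""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "cpm",
    "filter_expressed",
    "qsmooth_normalize",
    "log_cpm",
    "pca_overview",
]

log = logging.getLogger(__name__)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: count / library size x 1e6, per sample column."""
    libsize = counts.sum(axis=0)
    zero = libsize[libsize <= 0]
    if len(zero) > 0:
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return counts / libsize * 1e6


def filter_expressed(
    cpm_matrix: pd.DataFrame, min_cpm: float = 10.0, min_samples: int = 3
) -> pd.Index:
    """Genes with CPM strictly above ``min_cpm`` in >= ``min_samples`` samples."""
    if min_cpm <= 0 or min_samples <= 0:
        raise ValueError("thresholds must be > 0")
    keep = (cpm_matrix > min_cpm).sum(axis=1) >= min_samples
    return cpm_matrix.index[keep]


def log_cpm(counts: pd.DataFrame, prior_count: float = 0.5) -> pd.DataFrame:
    """log2 CPM with a library-size-scaled prior count keeping zeros finite."""
    if prior_count <= 0:
        raise ValueError("prior_count must be > 0")
    libsize = counts.sum(axis=0)
    zero = libsize[libsize <= 0]
    if len(zero) > 0:
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    # prior scaled per sample as in standard log-CPM practice
    adj_lib = libsize + 2 * prior_count
    return np.log2((counts + prior_count) / adj_lib * 1e6)


def qsmooth_normalize(
    matrix: pd.DataFrame,
    group_factor: pd.Series | Sequence = None,
    window_frac: float = 0.05,
) -> pd.DataFrame:
    """Smooth quantile normalization with group-aware reference quantiles.

    For every quantile level q the normalized value interpolates between the
    overall mean quantile O_q (full quantile normalization) and the group
    mean quantile G_gq, weighted by w_q = SST_within / (SST_within +
    SST_between) across groups at q, with w smoothed by a centered running
    median over a window of ``window_frac`` of the quantile levels. Values
    are mapped back through each sample's rank order; ties receive the mean
    of their tied normalized quantiles.

    A single group degenerates to plain quantile normalization (w = 1
    everywhere since there is no between-group variation).
    """
    X = matrix.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 2:
        raise ValueError("need >= 2 samples")
    if group_factor is None:
        groups = np.zeros(n_samples, dtype=int)
    else:
        groups = pd.factorize(pd.Series(list(group_factor)))[0]
        if len(groups) != n_samples:
            raise ValueError("group_factor length must match sample count")

    Q = np.sort(X, axis=0)  # quantiles per sample, rows = levels
    overall = Q.mean(axis=1)
    uniq = np.unique(groups)
    group_means = np.column_stack([Q[:, groups == g].mean(axis=1) for g in uniq])
    group_sizes = np.array([(groups == g).sum() for g in uniq])

    sst = ((Q - overall[:, None]) ** 2).sum(axis=1)
    ssb = (group_sizes[None, :] * (group_means - overall[:, None]) ** 2).sum(axis=1)
    ssw = np.clip(sst - ssb, 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(sst > 0, ssw / sst, 1.0)
    w = _running_median(w, max(3, int(round(window_frac * n_genes)) | 1))
    w = np.clip(w, 0.0, 1.0)

    norm_q = w[:, None] * overall[:, None] + (1.0 - w[:, None]) * group_means

    out = np.empty_like(X)
    for j in range(n_samples):
        nq = norm_q[:, uniq.tolist().index(groups[j])]
        out[:, j] = _map_through_ranks(X[:, j], nq)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running median with edge shrinkage (odd window)."""
    if window <= 1 or x.size <= 2:
        return x
    half = window // 2
    out = np.empty_like(x)
    for i in range(x.size):
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        out[i] = np.median(x[lo:hi])
    return out


def _map_through_ranks(x: np.ndarray, sorted_ref: np.ndarray) -> np.ndarray:
    """Replace values by reference quantiles at their ranks; ties get the
    mean of the tied quantile positions."""
    order = np.argsort(x, kind="stable")
    out = np.empty_like(x)
    out[order] = sorted_ref
    # average reference values over tied input values
    s = pd.Series(out).groupby(x).transform("mean")
    return s.to_numpy()


def pca_overview(expr: pd.DataFrame, n_components: int | None = None):
    """Sample-space PCA of a genes x samples expression matrix.

    Returns ``(scores, variance_fractions)`` where scores is a samples x
    components frame and fractions sum to 1 (all zero for a constant
    matrix).
    """
    if expr.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    X = expr.to_numpy(dtype=float)
    Xc = (X - X.mean(axis=1, keepdims=True)).T  # samples x genes, gene-centered
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    total = (s**2).sum()
    if total <= 0:
        frac = np.zeros(s.size)
    else:
        frac = s**2 / total
    scores = U * s
    k = n_components or s.size
    cols = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(scores[:, :k], index=expr.columns, columns=cols),
        frac[:k],
    )
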