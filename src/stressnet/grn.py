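"""Sliding-window lagged random-forest causal network inference.

For each window of the (optionally replicated) multivariate time series and
each candidate lag, a seeded tree ensemble predicts every target from the
lagged values of all other nodes; impurity importances are ranked per window
and delay, averaged across windows per delay and then across delays
(mean-mean aggregation), and the top fraction of supported edges is kept.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "SwingParams",
    "zscore_series",
    "make_windows",
    "lagged_importance",
    "aggregate_mean_mean",
    "finalize_edges",
    "theoretical_edge_count",
    "infer_network",
]

log = logging.getLogger(__name__)


@dataclass
class SwingParams:
    min_lag: int = 0
    max_lag: int = 1
    window_w: int = 4
    n_trees: int = 500
    top_fraction: float = 0.001
    max_features: float | str = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.min_lag <= self.max_lag:
            raise ValueError("need 0 <= min_lag <= max_lag")
        if self.window_w < self.max_lag + 1:
            raise ValueError("window_w must be >= max_lag + 1")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")

    @property
    def lags(self) -> list[int]:
        return list(range(self.min_lag, self.max_lag + 1))


def zscore_series(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores (population sd); constant rows dropped with a log
    entry."""
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=1)
    keep = sd > 0
    if (~keep).any():
        log.info("zscore_series: dropped %d constant row(s)", int((~keep).sum()))
    X = X[keep]
    mu = X.mean(axis=1, keepdims=True)
    return pd.DataFrame(
        (X - mu) / X.std(axis=1, keepdims=True),
        index=matrix.index[keep],
        columns=matrix.columns,
    )


def make_windows(n_timepoints: int, window_w: int) -> list[range]:
    """All contiguous index runs of length ``window_w`` with stride 1."""
    if window_w > n_timepoints:
        raise ValueError(
            f"window ({window_w}) exceeds series length ({n_timepoints})"
        )
    return [range(s, s + window_w) for s in range(n_timepoints - window_w + 1)]


def lagged_importance(
    window_data: np.ndarray,
    params: SwingParams,
    window_index: int = 0,
) -> np.ndarray:
    """Importance tensor (regulator, target, lag) for one window.

    ``window_data`` has shape (n_replicates, n_nodes, window_w). Per target
    a seeded random forest regresses the target at time t on all candidate
    regulators at t - k for every lag k; the target's own lagged copies are
    excluded. Importances are normalized to sum to 1 per target.
    """
    data = np.asarray(window_data, dtype=float)
    if data.ndim == 2:
        data = data[None]
    n_rep, n_nodes, w = data.shape
    if w <= params.max_lag:
        raise ValueError("window length must exceed max_lag")
    lags = params.lags
    n_rows = (w - params.max_lag) * n_rep
    if n_rows < 2:
        log.info("window %d skipped: fewer than 2 usable rows", window_index)
        return np.zeros((n_nodes, n_nodes, len(lags)))
    t_idx = np.arange(params.max_lag, w)
    # design block: rows = (replicate, time), cols = (node, lag)
    X_full = np.concatenate(
        [
            data[:, :, t_idx - k].transpose(0, 2, 1).reshape(n_rows, n_nodes)
            for k in lags
        ],
        axis=1,
    )
    imp = np.zeros((n_nodes, n_nodes, len(lags)))
    for tgt in range(n_nodes):
        y = data[:, tgt, t_idx].reshape(n_rows)
        cols = [
            k_i * n_nodes + reg
            for k_i in range(len(lags))
            for reg in range(n_nodes)
            if reg != tgt
        ]
        rf = RandomForestRegressor(
            n_estimators=params.n_trees,
            max_features=params.max_features,
            random_state=(params.seed * 1_000_003 + window_index * 1_009 + tgt)
            % (2**32),
            n_jobs=1,
        )
        rf.fit(X_full[:, cols], y)
        raw = rf.feature_importances_
        total = raw.sum()
        if total > 0:
            raw = raw / total
        for c, v in zip(cols, raw):
            k_i, reg = divmod(c, n_nodes)
            imp[reg, tgt, k_i] = v
    return imp


def aggregate_mean_mean(
    importances: list[np.ndarray], node_ids: list[str] | None = None
) -> pd.DataFrame:
    """Mean-mean rank aggregation of per-window importance tensors.

    Edges are ranked (descending importance, average ranks for ties) within
    each window and delay; ranks are averaged across windows per delay and
    then across delays. Returns a frame with columns (source, target, score,
    rank, support), ordered ascending by score with deterministic
    lexicographic tie-break; ``support`` counts windows with non-zero
    importance at any delay. Final ranks are a permutation of 1..E.
    """
    if not importances:
        raise ValueError("need >= 1 window")
    n_nodes = importances[0].shape[0]
    n_lags = importances[0].shape[2]
    if node_ids is None:
        node_ids = [f"n{i:03d}" for i in range(n_nodes)]
    mask = ~np.eye(n_nodes, dtype=bool)  # ordered pairs, no self-loops
    src_idx, tgt_idx = np.where(mask)

    per_delay_means = []
    for k in range(n_lags):
        ranks = []
        for imp in importances:
            vals = imp[:, :, k][mask]
            ranks.append(rankdata(-vals, method="average"))
        per_delay_means.append(np.mean(ranks, axis=0))
    score = np.mean(per_delay_means, axis=0)

    support = np.zeros(src_idx.size, dtype=int)
    for imp in importances:
        support += (imp.max(axis=2)[mask] > 0).astype(int)

    df = pd.DataFrame(
        {
            "source": [node_ids[i] for i in src_idx],
            "target": [node_ids[i] for i in tgt_idx],
            "score": score,
            "support": support,
        }
    )
    df = df.sort_values(
        ["score", "source", "target"], ignore_index=True, kind="stable"
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def finalize_edges(ranked: pd.DataFrame, top_fraction: float = 0.001) -> pd.DataFrame:
    """Drop zero-support edges, keep the best ceil(fraction x remaining)."""
    nonzero = ranked[ranked["support"] > 0]
    if len(nonzero) == 0:
        return nonzero.copy()
    n_keep = math.ceil(top_fraction * len(nonzero))
    return nonzero.nsmallest(n_keep, "rank").reset_index(drop=True)


def theoretical_edge_count(n_nodes: int) -> int:
    """Ordered node pairs without self-loops: n (n - 1)."""
    if n_nodes < 0:
        raise ValueError("n_nodes must be >= 0")
    return n_nodes * (n_nodes - 1)


def infer_network(
    series: np.ndarray,
    node_ids: list[str] | None = None,
    params: SwingParams | None = None,
) -> pd.DataFrame:
    """End-to-end windowed inference on a (replicates, nodes, T) array.

    Rows of each replicate are z-scored jointly per node before windowing.
    Returns the aggregated ranked edge list (see
    :func:`aggregate_mean_mean`); apply :func:`finalize_edges` to filter.
    """
    params = params or SwingParams()
    data = np.asarray(series, dtype=float)
    if data.ndim == 2:
        data = data[None]
    # per-node z-score across the pooled replicate series
    flat = data.transpose(1, 0, 2).reshape(data.shape[1], -1)
    mu = flat.mean(axis=1)
    sd = flat.std(axis=1)
    sd[sd == 0] = 1.0
    data = (data - mu[None, :, None]) / sd[None, :, None]
    windows = make_windows(data.shape[2], params.window_w)
    tensors = [
        lagged_importance(data[:, :, list(w)], params, window_index=wi)
        for wi, w in enumerate(windows)
    ]
    return aggregate_mean_mean(tensors, node_ids)
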