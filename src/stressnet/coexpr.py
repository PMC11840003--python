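"""Signed weighted co-expression networks.

Biweight midcorrelation -> signed soft-threshold adjacency -> signed
topological overlap -> hierarchical module detection -> eigengene merging,
module-trait correlation and intramodular hub ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "CoexprParams",
    "ModuleSet",
    "bicor_matrix",
    "signed_adjacency",
    "scale_free_fit",
    "pick_soft_threshold",
    "signed_tom",
    "detect_modules",
    "module_eigengene",
    "merge_close_modules",
    "module_trait_cor",
    "top_hubs",
    "fit_modules",
]

log = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class CoexprParams:
    beta: float = 20.0
    merge_threshold: float = 0.20
    min_module_size: int = 30
    max_p_outliers: float = 0.05
    hub_k: int = 20
    #: None = largest-gap heuristic; a float cuts at that quantile of merge heights
    cut_height_quantile: float | None = None

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0 < self.merge_threshold < 1:
            raise ValueError("merge_threshold must be in (0, 1)")
        if self.hub_k < 1:
            raise ValueError("hub_k must be >= 1")


@dataclass
class ModuleSet:
    labels: pd.Series  # gene -> module label ("m01", ... or "unassigned")
    eigengenes: pd.DataFrame  # modules x samples, unit norm rows
    variance_explained: dict[str, float]
    hubs: dict[str, list[str]] = field(default_factory=dict)

    @property
    def modules(self) -> list[str]:
        return [m for m in self.eigengenes.index]

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


def _bicor_transform(X: np.ndarray, max_p_outliers: float) -> tuple[np.ndarray, np.ndarray]:
    """Rows -> normalized robust deviations; flags rows needing Pearson fallback."""
    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    fallback = (mad[:, 0] == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (X - med) / (9.0 * mad)
    u[fallback] = 0.0
    # rescale so that at most max_p_outliers of each row exceeds |u| = 1
    if max_p_outliers < 1.0:
        q = np.quantile(np.abs(u), 1.0 - max_p_outliers, axis=1, keepdims=True)
        scale = np.where(q > 1.0, q, 1.0)
        u = u / scale
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    g = w * (X - med)
    # Pearson fallback: centered values (equivalent weights all one)
    if fallback.any():
        g[fallback] = X[fallback] - X[fallback].mean(axis=1, keepdims=True)
    norm = np.sqrt((g**2).sum(axis=1, keepdims=True))
    norm[norm == 0] = 1.0
    return g / norm, fallback


def bicor_matrix(expr: pd.DataFrame, max_p_outliers: float = 0.05) -> pd.DataFrame:
    """Biweight midcorrelation between all gene rows.

    Weights w_i = (1-u_i^2)^2 1(|u_i|<1) with u = (x - med) / (9 mad),
    rescaled so at most ``max_p_outliers`` of the observations in a row are
    treated as outliers. Rows with zero MAD fall back to Pearson (logged).
    """
    if expr.shape[1] < 4:
        raise ValueError("need >= 4 samples for a stable bicor estimate")
    G, fallback = _bicor_transform(expr.to_numpy(dtype=float), max_p_outliers)
    if fallback.any():
        log.info(
            "bicor: %d gene(s) with zero MAD fell back to Pearson", int(fallback.sum())
        )
    C = np.clip(G @ G.T, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=expr.index, columns=expr.index)


def signed_adjacency(cor: pd.DataFrame | np.ndarray, beta: float) -> np.ndarray:
    """Signed adjacency a_ij = ((1 + cor_ij) / 2)^beta, in [0, 1]."""
    c = np.asarray(cor, dtype=float)
    if np.any(c < -1 - 1e-9) or np.any(c > 1 + 1e-9):
        raise ValueError("correlations must lie in [-1, 1]")
    return ((1.0 + np.clip(c, -1, 1)) / 2.0) ** beta


def _connectivity(adj: np.ndarray) -> np.ndarray:
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    return a.sum(axis=1)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution fit.

    Bins connectivity into equal-width bins, regresses log10 p(k) on
    log10 mean(k) and returns -sign(slope) * R^2, so scale-free decay gives
    a value near +1.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.ptp(k) == 0:
        raise ValueError("degenerate connectivity: constant or empty")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 3:
        log.warning("scale_free_fit: only %d usable bins", len(xs))
    if len(xs) < 2:
        raise ValueError("under-determined fit: fewer than 2 non-empty bins")
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r**2)


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers: Sequence[int] | None = None,
    target_mean_connectivity: float = 50.0,
    r2_min: float = 0.8,
    max_p_outliers: float = 0.05,
    n_bins: int = 10,
) -> tuple[float, pd.DataFrame]:
    """Scan soft powers; report scale-free fit and connectivity diagnostics.

    Chooses, among powers reaching signed R^2 >= ``r2_min``, the one whose
    mean connectivity is closest to ``target_mean_connectivity`` (ties to the
    lower power). If none qualifies, the best-R^2 power is returned with a
    warning.
    """
    if expr.shape[0] < 50:
        raise ValueError("need >= 50 genes to assess scale-free topology")
    powers = list(powers) if powers is not None else list(range(1, 51))
    cor = bicor_matrix(expr, max_p_outliers).to_numpy()
    rows = []
    for b in powers:
        k = _connectivity(signed_adjacency(cor, b))
        try:
            r2 = scale_free_fit(k, n_bins=n_bins)
        except ValueError:
            r2 = np.nan
        rows.append(
            {
                "power": b,
                "signed_r2": r2,
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
            }
        )
    diag = pd.DataFrame(rows)
    ok = diag[diag["signed_r2"] >= r2_min]
    if len(ok):
        gap = (ok["mean_k"] - target_mean_connectivity).abs()
        chosen = ok.loc[gap.round(12).idxmin(), "power"]
    else:
        log.warning("no power reached signed R^2 >= %.2f; using best fit", r2_min)
        chosen = diag.loc[diag["signed_r2"].idxmax(), "power"]
    return float(chosen), diag


def signed_tom(adjacency: np.ndarray) -> np.ndarray:
    """Signed topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    unit diagonal; input adjacency must be symmetric in [0, 1].
    """
    a = np.asarray(adjacency, dtype=float).copy()
    if np.any(a < 0) or np.any(a > 1 + 1e-9):
        raise ValueError("adjacency must lie in [0, 1]")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + a) / (kmin + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(
    tom: np.ndarray,
    gene_ids: Sequence[str],
    min_module_size: int = 30,
    cut_height_quantile: float | None = None,
) -> pd.Series:
    """Average-linkage clustering on 1 - TOM with a static height cut.

    By default the tree is cut in the middle of the largest gap between
    consecutive sorted merge heights (separating tight within-module merges
    from the loose merges that join modules); passing
    ``cut_height_quantile`` cuts at that quantile of merge heights instead.
    Clusters below ``min_module_size`` become "unassigned". Labels are
    "m01", "m02", ... ordered by decreasing module size.
    """
    diss = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(diss, 0.0)
    condensed = squareform(diss, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    heights = np.sort(Z[:, 2])
    if cut_height_quantile is not None:
        cut = float(np.quantile(heights, cut_height_quantile))
    elif heights.size == 1:
        cut = float(heights[0]) + 1e-12
    else:
        gaps = np.diff(heights)
        i = int(np.argmax(gaps))
        cut = float((heights[i] + heights[i + 1]) / 2.0)
    raw = hierarchy.fcluster(Z, t=cut, criterion="distance")
    return _relabel(raw, gene_ids, min_module_size)


def _relabel(raw: np.ndarray, gene_ids: Sequence[str], min_size: int) -> pd.Series:
    counts = pd.Series(raw).value_counts()
    keep = [c for c in counts.index if counts[c] >= min_size]
    order = sorted(keep, key=lambda c: (-counts[c], c))
    name = {c: f"m{i + 1:02d}" for i, c in enumerate(order)}
    labels = [name.get(c, UNASSIGNED) for c in raw]
    return pd.Series(labels, index=list(gene_ids), name="module")


def module_eigengene(
    expr: pd.DataFrame, members: Sequence[str]
) -> tuple[np.ndarray, float]:
    """First PC of the standardized member submatrix, sign-anchored.

    Returns (unit-norm eigengene over samples, variance explained). The sign
    is chosen so the mean correlation with member profiles is positive.
    A single-gene module returns its standardized, unit-norm profile.
    """
    if len(members) == 0:
        raise ValueError("empty module")
    X = expr.loc[list(members)].to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    if Z.shape[0] == 1:
        v = Z[0]
        nrm = np.linalg.norm(v)
        return (v / nrm if nrm > 0 else v), 1.0
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = Vt[0]
    var_exp = float(s[0] ** 2 / (s**2).sum()) if (s**2).sum() > 0 else 0.0
    if np.mean(Z @ eig) < 0:
        eig = -eig
    return eig, var_exp


def _eigengene_frame(
    expr: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, dict[str, float]]:
    mods = sorted(m for m in labels.unique() if m != UNASSIGNED)
    rows, ve = [], {}
    for m in mods:
        members = labels.index[labels == m]
        e, v = module_eigengene(expr, members)
        rows.append(e)
        ve[m] = v
    eg = pd.DataFrame(rows, index=mods, columns=expr.columns)
    return eg, ve


def merge_close_modules(
    labels: pd.Series,
    expr: pd.DataFrame,
    merge_threshold: float = 0.20,
) -> ModuleSet:
    """Iteratively merge modules whose eigengene dissimilarity 1 - cor is
    below ``merge_threshold``; eigengenes are recomputed after every merge.
    Final labels are reassigned by size ("m01" largest)."""
    labels = labels.copy()
    while True:
        eg, _ = _eigengene_frame(expr, labels)
        mods = list(eg.index)
        if len(mods) < 2:
            break
        C = np.corrcoef(eg.to_numpy())
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        if 1.0 - C[i, j] >= merge_threshold:
            break
        a, b = mods[i], mods[j]
        labels[labels == b] = a
    # canonical size-ordered names
    counts = labels[labels != UNASSIGNED].value_counts()
    order = sorted(counts.index, key=lambda m: (-counts[m], m))
    rename = {m: f"m{i + 1:02d}" for i, m in enumerate(order)}
    labels = labels.map(lambda m: rename.get(m, UNASSIGNED))
    eg, ve = _eigengene_frame(expr, labels)
    return ModuleSet(labels=labels, eigengenes=eg, variance_explained=ve)


def module_trait_cor(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided p between eigengenes and numeric traits.

    Rows are modules, columns traits; constant traits yield NaN (logged).
    """
    shared = [s for s in eigengenes.columns if s in traits.index]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples")
    E = eigengenes[shared].to_numpy(dtype=float)
    n = len(shared)
    r = np.full((E.shape[0], traits.shape[1]), np.nan)
    p = np.full_like(r, np.nan)
    for j, trait in enumerate(traits.columns):
        y = traits.loc[shared, trait].to_numpy(dtype=float)
        if np.std(y) == 0:
            log.info("trait %s constant; correlation undefined", trait)
            continue
        yc = (y - y.mean()) / (np.std(y) * np.sqrt(n))
        for i in range(E.shape[0]):
            x = E[i]
            if np.std(x) == 0:
                continue
            xc = (x - x.mean()) / (np.std(x) * np.sqrt(n))
            rij = float(np.clip(np.sum(xc * yc), -1.0, 1.0))
            r[i, j] = rij
            if abs(rij) >= 1.0:
                p[i, j] = 0.0
            else:
                t = rij * np.sqrt(n - 2) / np.sqrt(1 - rij**2)
                p[i, j] = 2.0 * stats.t.sf(abs(t), n - 2)
    idx, cols = eigengenes.index, traits.columns
    return pd.DataFrame(r, idx, cols), pd.DataFrame(p, idx, cols)


def top_hubs(
    adjacency: np.ndarray,
    labels: pd.Series,
    hub_k: int = 20,
    include_unassigned: bool = False,
) -> dict[str, list[str]]:
    """Top ``hub_k`` members per module by intramodular connectivity.

    kWithin_i = sum of adjacency to co-members; ties break by gene id.
    """
    a = np.asarray(adjacency, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    genes = list(labels.index)
    pos = {g: i for i, g in enumerate(genes)}
    hubs: dict[str, list[str]] = {}
    for m in sorted(labels.unique()):
        if m == UNASSIGNED and not include_unassigned:
            continue
        members = [g for g in genes if labels[g] == m]
        rows = [pos[g] for g in members]
        sub = a[np.ix_(rows, rows)]
        kwithin = sub.sum(axis=1)
        ranked = sorted(zip(members, kwithin), key=lambda t: (-t[1], t[0]))
        hubs[m] = [g for g, _ in ranked[:hub_k]]
    return hubs


def fit_modules(
    expr: pd.DataFrame,
    params: CoexprParams | None = None,
) -> tuple[ModuleSet, np.ndarray]:
    """Run the whole module pipeline; returns (ModuleSet, adjacency)."""
    params = params or CoexprParams()
    cor = bicor_matrix(expr, params.max_p_outliers).to_numpy()
    adj = signed_adjacency(cor, params.beta)
    tom = signed_tom(adj)
    labels = detect_modules(
        tom, expr.index, params.min_module_size, params.cut_height_quantile
    )
    modules = merge_close_modules(labels, expr, params.merge_threshold)
    modules.hubs = top_hubs(adj, modules.labels, params.hub_k)
    return modules, adj
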