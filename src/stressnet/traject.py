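"""Dirichlet-process Gaussian-process mixture clustering of log2FC time
courses, with posterior co-clustering and tightness filtering.

The sampler is a collapsed Gibbs scan over cluster assignments under a
Chinese-restaurant-process prior. Cluster likelihoods are GP posterior
predictives with a squared-exponential kernel on the shared time grid; all
Gaussian algebra runs in the kernel eigenbasis, where every coordinate is an
independent scalar random-effects model, making each evaluation O(T^2).
GP hyperparameters (lengthscale and signal fraction, with sigma_f^2 +
sigma_n^2 = 1 on standardized rows) are shared by all clusters and
refreshed each sweep by maximizing the summed cluster marginal likelihood
over a small fixed grid, keeping runs deterministic given the seed.
Per-cluster hyperparameters were tried and rejected: they let the sampler
profit from splitting homogeneous clusters by amplitude.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrajectorySet",
    "DPGPResult",
    "build_trajectories",
    "gp_log_marginal",
    "dpgp_gibbs",
    "consensus_partition",
    "tightness_filter",
]

log = logging.getLogger(__name__)

LENGTHSCALE_MULTIPLIERS = (0.5, 1.0, 2.0, 4.0)
SIGNAL_FRACTIONS = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))


def build_trajectories(
    contrast_results: pd.DataFrame, treatment: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Fold-change trajectories of genes significant somewhere in a treatment.

    Takes the long output of :func:`stressnet.diffexpr.run_contrasts`,
    keeps genes with adjusted p <= ``alpha`` at >= 1 time point of the
    treatment and returns a genes x time_h matrix of log2FC values.
    """
    sub = contrast_results[contrast_results["condition"] == treatment]
    times = sorted(sub["time_h"].unique())
    if len(times) < 3:
        raise ValueError(
            f"treatment {treatment!r} has {len(times)} time points; need >= 3"
        )
    sig_genes = sub.loc[sub["adj_p"] <= alpha, "gene"].unique()
    if len(sig_genes) == 0:
        warnings.warn(f"no significant genes for treatment {treatment!r}")
        return pd.DataFrame(columns=times)
    wide = sub.pivot(index="gene", columns="time_h", values="log2fc")
    wide = wide.loc[sorted(sig_genes), times]
    if wide.isna().any().any():
        raise ValueError("missing time points after trajectory construction")
    return wide


def _sqexp(t: np.ndarray, lengthscale: float) -> np.ndarray:
    d = np.subtract.outer(t, t)
    return np.exp(-(d**2) / (2.0 * lengthscale**2))


def gp_log_marginal(
    y: np.ndarray,
    t: np.ndarray,
    sigma_f: float,
    lengthscale: float,
    sigma_n: float,
) -> float:
    """log N(y | 0, sigma_f^2 K + sigma_n^2 I), SE kernel on times ``t``.

    Adds 1e-8 jitter (logged) if the covariance is not positive definite.
    """
    y = np.asarray(y, float)
    t = np.asarray(t, float)
    if y.size != t.size or y.size < 1:
        raise ValueError("y and t must have equal, positive length")
    if sigma_f < 0 or sigma_n < 0 or lengthscale <= 0:
        raise ValueError("hyperparameters must be positive")
    K = sigma_f**2 * _sqexp(t, lengthscale) + sigma_n**2 * np.eye(t.size)
    try:
        L = np.linalg.cholesky(K)
    except np.linalg.LinAlgError:
        log.info("gp_log_marginal: covariance not PD, adding 1e-8 jitter")
        L = np.linalg.cholesky(K + 1e-8 * np.eye(t.size))
    alpha = np.linalg.solve(L, y)
    return float(
        -0.5 * alpha @ alpha - np.log(np.diag(L)).sum() - 0.5 * t.size * np.log(2 * np.pi)
    )


@dataclass
class TrajectorySet:
    """Standardized trajectories plus the shared time grid."""

    values: pd.DataFrame  # genes x time points (z-scored rows)
    times: np.ndarray

    @classmethod
    def from_matrix(cls, matrix: pd.DataFrame) -> "TrajectorySet":
        X = matrix.to_numpy(dtype=float)
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd
        return cls(
            values=pd.DataFrame(Z, index=matrix.index, columns=matrix.columns),
            times=np.asarray(matrix.columns, dtype=float),
        )


@dataclass
class DPGPResult:
    labels: pd.Series  # gene -> final cluster id (0-based, relabeled by size)
    tightness: pd.Series  # gene -> mean posterior co-clustering with cluster
    coclustering: pd.DataFrame  # genes x genes posterior co-clustering
    cluster_means: pd.DataFrame  # cluster x time posterior mean trajectory
    chain: list[np.ndarray] = field(default_factory=list)
    settings: dict = field(default_factory=dict)


class _GPBasis:
    """Eigendecompositions of the unit-amplitude SE kernel per lengthscale."""

    def __init__(self, times: np.ndarray):
        self.times = times
        spacing = np.diff(np.sort(times))
        self.median_dt = float(np.median(spacing)) if spacing.size else 1.0
        self.lengthscales = [m * self.median_dt for m in LENGTHSCALE_MULTIPLIERS]
        self.U: list[np.ndarray] = []
        self.evals: list[np.ndarray] = []
        for ls in self.lengthscales:
            w, U = np.linalg.eigh(_sqexp(times, ls))
            self.U.append(U)
            self.evals.append(np.clip(w, 0.0, None))

    def project(self, Y: np.ndarray, li: int) -> np.ndarray:
        return Y @ self.U[li]


def _cluster_marginal(Z: np.ndarray, shat: np.ndarray, sf2: float, sn2: float) -> float:
    """Joint marginal log-lik of n member trajectories in the eigenbasis."""
    n = Z.shape[0]
    s = sf2 * shat
    tot = Z.sum(axis=0)
    ss = (Z**2).sum(axis=0)
    ll = (
        -0.5 * n * Z.shape[1] * np.log(2 * np.pi * sn2)
        - 0.5 * np.log1p(n * s / sn2).sum()
        - 0.5 / sn2 * (ss - s * tot**2 / (sn2 + n * s)).sum()
    )
    return float(ll)


def _predictive_logpdf(
    z: np.ndarray, sum_z: np.ndarray, n: int, shat: np.ndarray, sf2: float, sn2: float
) -> float:
    """GP posterior predictive of one trajectory given n cluster members."""
    s = sf2 * shat
    if n > 0:
        mean = (s * sum_z) / (sn2 + n * s)
        var = s * sn2 / (sn2 + n * s) + sn2
    else:
        mean = 0.0
        var = s + sn2
    return float(
        (-0.5 * (np.log(2 * np.pi * var) + (z - mean) ** 2 / var)).sum()
    )


class _Cluster:
    __slots__ = ("members",)

    def __init__(self):
        self.members: set[int] = set()


def dpgp_gibbs(
    ts: TrajectorySet | pd.DataFrame,
    alpha: float = 1.0,
    n_iter: int = 500,
    burn_in: int = 250,
    seed: int = 0,
    likelihood: str = "gp",
) -> DPGPResult:
    """Collapsed Gibbs sampling of the DP-GP mixture.

    ``likelihood="none"`` disables the data term (pure CRP; for prior
    diagnostics). Assignments are recorded after ``burn_in``; the returned
    partition is the least-squares consensus over the recorded chain.
    """
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    if likelihood not in ("gp", "none"):
        raise ValueError("likelihood must be 'gp' or 'none'")
    if isinstance(ts, pd.DataFrame):
        ts = TrajectorySet.from_matrix(ts)
    genes = list(ts.values.index)
    Y = ts.values.to_numpy(dtype=float)
    n_genes = len(genes)
    if n_genes == 0:
        raise ValueError("empty trajectory set")
    rng = np.random.default_rng(seed)
    basis = _GPBasis(ts.times)
    li, fi = 2, 4  # lengthscale 2x median dt, sf2 = 0.5
    use_lik = likelihood == "gp"

    # projections of every gene in every lengthscale basis, cached
    proj = [basis.project(Y, li) for li in range(len(basis.lengthscales))]

    clusters: dict[int, _Cluster] = {}
    assign = np.zeros(n_genes, dtype=int)
    c0 = _Cluster()
    c0.members = set(range(n_genes))
    clusters[0] = c0
    next_id = 1

    def refresh_hypers(li: int, fi: int) -> tuple[int, int]:
        best, best_ll = (li, fi), -np.inf
        for li_try in range(len(basis.lengthscales)):
            for fi_try, sf2 in enumerate(SIGNAL_FRACTIONS):
                ll = 0.0
                for c in clusters.values():
                    idx = sorted(c.members)
                    ll += _cluster_marginal(
                        proj[li_try][idx], basis.evals[li_try], sf2, 1.0 - sf2
                    )
                if ll > best_ll:
                    best_ll, best = ll, (li_try, fi_try)
        return best

    chain: list[np.ndarray] = []
    for sweep in range(n_iter):
        sf2 = SIGNAL_FRACTIONS[fi]
        for i in range(n_genes):
            old = clusters[assign[i]]
            old.members.discard(i)
            if not old.members:
                del clusters[assign[i]]
            keys = sorted(clusters)
            logp = np.empty(len(keys) + 1)
            for j, k in enumerate(keys):
                c = clusters[k]
                n_k = len(c.members)
                if use_lik:
                    idx = sorted(c.members)
                    lp = _predictive_logpdf(
                        proj[li][i],
                        proj[li][idx].sum(axis=0),
                        n_k,
                        basis.evals[li],
                        sf2,
                        1.0 - sf2,
                    )
                else:
                    lp = 0.0
                logp[j] = np.log(n_k) + lp
            if use_lik:
                lp0 = _predictive_logpdf(
                    proj[li][i],
                    np.zeros(Y.shape[1]),
                    0,
                    basis.evals[li],
                    sf2,
                    1.0 - sf2,
                )
            else:
                lp0 = 0.0
            logp[-1] = np.log(alpha) + lp0
            prob = np.exp(logp - logp.max())
            prob /= prob.sum()
            choice = rng.choice(len(prob), p=prob)
            if choice == len(keys):
                c = _Cluster()
                clusters[next_id] = c
                assign[i] = next_id
                next_id += 1
            else:
                c = clusters[keys[choice]]
                assign[i] = keys[choice]
            c.members.add(i)
        if use_lik:
            li, fi = refresh_hypers(li, fi)
        if sweep >= burn_in:
            chain.append(assign.copy())

    pi = np.zeros((n_genes, n_genes))
    for part in chain:
        pi += (part[:, None] == part[None, :]).astype(float)
    pi /= len(chain)

    final = consensus_partition(chain, pi)
    final = _relabel_by_size(final)
    tight = _tightness(final, pi)

    # posterior mean trajectory per final cluster under the final hypers
    means = {}
    sf2 = SIGNAL_FRACTIONS[fi]
    sn2 = 1.0 - sf2
    s = sf2 * basis.evals[li]
    for k in sorted(set(final)):
        idx = np.where(final == k)[0]
        sum_z = proj[li][idx].sum(axis=0)
        post = (s * sum_z) / (sn2 + len(idx) * s)
        means[k] = basis.U[li] @ post
    cluster_means = pd.DataFrame.from_dict(means, orient="index")
    cluster_means.columns = ts.times

    return DPGPResult(
        labels=pd.Series(final, index=genes, name="cluster"),
        tightness=pd.Series(tight, index=genes, name="tightness"),
        coclustering=pd.DataFrame(pi, index=genes, columns=genes),
        cluster_means=cluster_means,
        chain=chain,
        settings={
            "alpha": alpha,
            "n_iter": n_iter,
            "burn_in": burn_in,
            "seed": seed,
            "likelihood": likelihood,
        },
    )


def consensus_partition(chain: list[np.ndarray], pi: np.ndarray) -> np.ndarray:
    """Least-squares consensus: the sampled partition whose co-membership
    matrix is closest (Frobenius) to the posterior co-clustering."""
    if not chain:
        raise ValueError("empty chain")
    best, best_score = None, np.inf
    for part in chain:
        B = (part[:, None] == part[None, :]).astype(float)
        score = ((B - pi) ** 2).sum()
        if score < best_score - 1e-12:
            best_score, best = score, part
    return best.copy()


def _relabel_by_size(assign: np.ndarray) -> np.ndarray:
    sizes = pd.Series(assign).value_counts()
    order = sorted(sizes.index, key=lambda k: (-sizes[k], k))
    remap = {k: i for i, k in enumerate(order)}
    return np.array([remap[k] for k in assign])


def _tightness(final: np.ndarray, pi: np.ndarray) -> np.ndarray:
    out = np.ones(final.size)
    for k in set(final):
        idx = np.where(final == k)[0]
        if idx.size == 1:
            continue
        sub = pi[np.ix_(idx, idx)]
        out[idx] = (sub.sum(axis=1) - 1.0) / (idx.size - 1)
    return out


def tightness_filter(result: DPGPResult, threshold: float = 0.7) -> dict[int, list]:
    """Per final cluster, the members with tightness >= threshold (inclusive)."""
    out: dict[int, list] = {}
    for k in sorted(result.labels.unique()):
        members = result.labels.index[result.labels == k]
        keep = [g for g in members if result.tightness[g] >= threshold]
        out[int(k)] = keep
    return out
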