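"""HOG-level conserved network construction and topology statistics.

Per-species finalized edge lists are lifted to directed orthogroup (HOG)
pairs, intersected across species, optionally filtered by temporal-cluster
conservation, and summarized with degree/HITS hub metrics, a scale-free
check and printed-precision count reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .coexpr import scale_free_fit
from .grn import theoretical_edge_count

__all__ = [
    "ConservedNetwork",
    "NetworkReport",
    "edges_to_hog_pairs",
    "intersect_conserved",
    "dpgp_conservation_filter",
    "node_metrics",
    "hits_scores",
    "powerlaw_check",
    "rank_stability",
    "report_counts",
    "round_sig",
]

log = logging.getLogger(__name__)


@dataclass
class ConservedNetwork:
    edges: set[tuple[str, str]]  # directed HOG pairs supported in all species
    species: list[str]
    provenance: dict = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        out = set()
        for s, t in self.edges:
            out.add(s)
            out.add(t)
        return out


def edges_to_hog_pairs(
    edge_list: pd.DataFrame, hog_table: pd.DataFrame
) -> tuple[set[tuple[str, str]], int]:
    """Lift gene edges (source, target) to unique directed HOG pairs.

    Edges with an unmapped endpoint (or mapping to a self-pair) are dropped;
    the dropped count is returned alongside the pair set.
    """
    mapping = hog_table.set_index("gene_id")["hog_id"].to_dict()
    pairs: set[tuple[str, str]] = set()
    dropped = 0
    for src, tgt in zip(edge_list["source"], edge_list["target"]):
        hs = mapping.get(src, "")
        ht = mapping.get(tgt, "")
        if not hs or not ht or hs == ht:
            dropped += 1
            continue
        pairs.add((hs, ht))
    return pairs, dropped


def intersect_conserved(
    hog_pair_sets: dict[str, set[tuple[str, str]]]
) -> set[tuple[str, str]]:
    """Directed HOG pairs present in every species (direction must match)."""
    if len(hog_pair_sets) < 2:
        raise ValueError("need >= 2 species edge sets")
    sets = list(hog_pair_sets.values())
    out = set(sets[0])
    for s in sets[1:]:
        out &= s
    return out


def dpgp_conservation_filter(
    conserved_pairs: set[tuple[str, str]],
    tight_genes_by_species: dict[str, set[str]],
    hog_table: pd.DataFrame,
) -> set[tuple[str, str]]:
    """Keep pairs whose endpoint HOGs hold a tight conserved-cluster member
    in every species.

    ``tight_genes_by_species`` maps species -> genes that belong to a
    conserved temporal cluster with tightness >= the chosen threshold.
    """
    hog_of = hog_table.set_index("gene_id")["hog_id"].to_dict()
    qualifying: dict[str, set[str]] = {}  # species -> HOGs with a tight member
    for sp, genes in tight_genes_by_species.items():
        hs = {hog_of.get(g, "") for g in genes}
        hs.discard("")
        qualifying[sp] = hs
    everywhere = set.intersection(*qualifying.values()) if qualifying else set()
    return {
        (s, t) for (s, t) in conserved_pairs if s in everywhere and t in everywhere
    }


def hits_scores(
    edges: set[tuple[str, str]],
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[dict[str, float], dict[str, float]]:
    """HITS hub/authority scores by L2-normalized power iteration."""
    nodes = sorted({n for e in edges for n in e})
    if not nodes:
        return {}, {}
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for s, t in edges:
        A[idx[s], idx[t]] = 1.0
    hub = np.ones(n) / np.sqrt(n)
    auth = np.ones(n) / np.sqrt(n)
    for _ in range(max_iter):
        new_auth = A.T @ hub
        na = np.linalg.norm(new_auth)
        new_auth = new_auth / na if na > 0 else new_auth
        new_hub = A @ new_auth
        nh = np.linalg.norm(new_hub)
        new_hub = new_hub / nh if nh > 0 else new_hub
        if (
            np.abs(new_auth - auth).max() < tol
            and np.abs(new_hub - hub).max() < tol
        ):
            auth, hub = new_auth, new_hub
            break
        auth, hub = new_auth, new_hub
    return (
        {nd: float(hub[i]) for nd, i in idx.items()},
        {nd: float(auth[i]) for nd, i in idx.items()},
    )


def node_metrics(network: ConservedNetwork) -> pd.DataFrame:
    """Degrees plus HITS hub/authority per node (all zero for empty nets)."""
    nodes = sorted(network.nodes)
    if not network.edges:
        return pd.DataFrame(
            0.0,
            index=nodes,
            columns=["in_degree", "out_degree", "total_degree", "hub", "authority"],
        )
    indeg = {n: 0 for n in nodes}
    outdeg = {n: 0 for n in nodes}
    for s, t in network.edges:
        outdeg[s] += 1
        indeg[t] += 1
    hub, auth = hits_scores(network.edges)
    return pd.DataFrame(
        {
            "in_degree": [indeg[n] for n in nodes],
            "out_degree": [outdeg[n] for n in nodes],
            "total_degree": [indeg[n] + outdeg[n] for n in nodes],
            "hub": [hub[n] for n in nodes],
            "authority": [auth[n] for n in nodes],
        },
        index=nodes,
    )


def powerlaw_check(degree_sequence, n_bins: int = 10) -> float:
    """Signed R^2 of the binned log-log degree-distribution fit."""
    k = np.asarray(list(degree_sequence), dtype=float)
    if (k >= 1).sum() < 10:
        log.warning("powerlaw_check: fewer than 10 nodes with degree >= 1")
    return scale_free_fit(k, n_bins=n_bins)


def rank_stability(
    metrics_by_variant: dict[str, pd.DataFrame],
    reference: str,
    top_n: int = 50,
    by: str = "total_degree",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank concordance of the reference's top nodes across network variants.

    Returns (per-node rank table restricted to the reference's top ``top_n``
    by ``by``, Spearman correlation matrix between variant rank vectors).
    """
    if reference not in metrics_by_variant:
        raise ValueError(f"unknown reference variant {reference!r}")
    ref = metrics_by_variant[reference]
    top = ref[by].sort_values(ascending=False).head(top_n).index
    ranks = {}
    for name, df in metrics_by_variant.items():
        r = df[by].rank(ascending=False, method="average")
        ranks[name] = r.reindex(top)
    table = pd.DataFrame(ranks)
    shared = table.dropna()
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared nodes across variants")
    names = list(table.columns)
    C = np.ones((len(names), len(names)))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rho = spearmanr(shared[names[i]], shared[names[j]]).statistic
            C[i, j] = C[j, i] = rho
    return table, pd.DataFrame(C, index=names, columns=names)


def round_sig(x: float, sig: int = 7) -> float:
    """Round to ``sig`` significant digits (0 stays 0)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


@dataclass
class NetworkReport:
    counts: dict[str, int]
    percentages: dict[str, float]
    theoretical: dict[str, int]


def report_counts(
    stage_counts: dict[str, int],
    reference: int,
    n_nodes: int | None = None,
    sig_digits: int = 7,
) -> NetworkReport:
    """Percentages of each stage count against a reference, at printed
    precision (default 7 significant digits), plus theoretical maxima."""
    if reference <= 0:
        raise ValueError("reference must be > 0")
    if any(v < 0 for v in stage_counts.values()):
        raise ValueError("counts must be >= 0")
    pct = {
        k: round_sig(100.0 * v / reference, sig_digits)
        for k, v in stage_counts.items()
    }
    theo = {}
    if n_nodes is not None:
        theo["max_edges"] = theoretical_edge_count(n_nodes)
    return NetworkReport(counts=dict(stage_counts), percentages=pct, theoretical=theo)
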