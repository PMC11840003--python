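"""Projection of gene clusters to hierarchical orthogroups (HOGs) and
cross-species conservation via Jaccard distances."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HogSetProjection",
    "project_to_hogs",
    "jaccard_distance",
    "similarity_matrix",
    "conserved_cluster_sets",
]

log = logging.getLogger(__name__)


@dataclass
class HogSetProjection:
    """HOG content of one cluster: species tag, cluster id, HOG set."""

    species: str
    cluster: str
    hogs: frozenset
    n_dropped: int = 0  # member genes without a HOG

    @property
    def key(self) -> str:
        return f"{self.species}:{self.cluster}"


def project_to_hogs(
    genes, hog_table: pd.DataFrame, species: str, cluster: str = ""
) -> HogSetProjection:
    """Distinct HOG ids of a gene set; genes without a HOG are dropped and
    counted."""
    mapping = hog_table.set_index("gene_id")["hog_id"]
    hogs = set()
    dropped = 0
    for g in genes:
        h = mapping.get(g, "")
        if isinstance(h, str) and h:
            hogs.add(h)
        else:
            dropped += 1
    return HogSetProjection(
        species=species, cluster=str(cluster), hogs=frozenset(hogs), n_dropped=dropped
    )


def jaccard_distance(set_a, set_b) -> float:
    """1 - |A ∩ B| / |A ∪ B|; two empty sets give distance 1 (logged)."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        log.info("jaccard_distance of two empty sets defined as 1")
        return 1.0
    return 1.0 - len(a & b) / len(union)


def similarity_matrix(
    projections: list[HogSetProjection],
    top_k: int = 50,
    display_cap: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Jaccard distance matrix plus the top-k closest pairs.

    The matrix is symmetric with zero diagonal. The top-k list ranks
    cross-projection pairs ascending by distance with lexicographic
    tie-break on the pair of keys. ``display_cap`` (e.g. 0.9) caps values
    for display output only; the returned matrix is never capped.
    """
    if len(projections) < 2:
        raise ValueError("need >= 2 clusters")
    keys = [p.key for p in projections]
    n = len(keys)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = jaccard_distance(projections[i].hogs, projections[j].hogs)
        D[i, j] = D[j, i] = d
    mat = pd.DataFrame(D, index=keys, columns=keys)
    pairs = sorted(
        (
            (D[i, j], keys[i], keys[j])
            for i, j in itertools.combinations(range(n), 2)
        ),
        key=lambda t: (t[0], t[1], t[2]),
    )[:top_k]
    top = pd.DataFrame(pairs, columns=["distance", "cluster_a", "cluster_b"])
    if display_cap is not None:
        top["display_distance"] = top["distance"].clip(upper=display_cap)
    return mat, top


def conserved_cluster_sets(
    projections: list[HogSetProjection],
    mode: str = "mutual_nearest",
    threshold: float = 0.9,
) -> dict[str, list[str]]:
    """Per-species lists of clusters conserved across all species.

    ``mutual_nearest``: a cluster is conserved iff, for every other species,
    its nearest cluster there has it back as its own nearest in the original
    species (a mutual-nearest triple for three species).
    ``threshold``: conserved iff distance <= ``threshold`` to at least one
    cluster in every other species.
    """
    if mode not in ("mutual_nearest", "threshold"):
        raise ValueError(f"unknown mode {mode!r}")
    by_species: dict[str, list[HogSetProjection]] = {}
    for p in projections:
        by_species.setdefault(p.species, []).append(p)
    species = sorted(by_species)
    if len(species) < 2:
        raise ValueError("need clusters from >= 2 species")

    def nearest(p: HogSetProjection, other_species: str) -> HogSetProjection | None:
        cands = by_species[other_species]
        if not cands:
            return None
        return min(
            cands, key=lambda q: (jaccard_distance(p.hogs, q.hogs), q.cluster)
        )

    conserved: dict[str, list[str]] = {sp: [] for sp in species}
    for sp in species:
        for p in by_species[sp]:
            ok = True
            for other in species:
                if other == sp:
                    continue
                q = nearest(p, other)
                if q is None:
                    ok = False
                    break
                if mode == "mutual_nearest":
                    back = nearest(q, sp)
                    if back is None or back.cluster != p.cluster:
                        ok = False
                        break
                else:
                    if jaccard_distance(p.hogs, q.hogs) > threshold:
                        ok = False
                        break
            if ok:
                conserved[sp].append(p.cluster)
    return conserved
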