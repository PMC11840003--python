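"""Seeded synthetic multi-species stress time-course datasets.

Generates count matrices, sample designs, orthogroup (HOG) tables, planted
trajectory archetypes, lagged causal series and metabolite channels with the
statistical structure the downstream pipeline stages assume, so the whole
pipeline can run and be validated without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "PlantedTruth",
    "DEFAULT_TIME_GRID",
    "make_design",
    "make_hog_table",
    "make_archetypes",
    "assign_clusters",
    "simulate_counts",
    "simulate_var_series",
    "simulate_metabolites",
    "generate_dataset",
]

#: Default condition -> sampling times (hours). The initial time point is the
#: 0 h control; 29 condition-time combinations in total.
DEFAULT_TIME_GRID: dict[str, tuple[float, ...]] = {
    "control": (0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 24.0),
    "cold": (0.5, 1.0, 2.0, 4.0, 6.0, 24.0),
    "heat": (0.5, 1.0, 2.0, 4.0, 6.0, 24.0),
    "highlight": (0.5, 1.0, 2.0, 4.0, 6.0),
    "recovery": (7.0, 8.0, 10.0),
}

CONTROL = "control"


@dataclass
class SimConfig:
    """Parameters of the synthetic data generator.

    Defaults mimic the scale of the motivating design: 3 species, 29
    condition-time combinations each, triplicates (initial time point in
    sextuplicate) for 270 samples in total, and 24 metabolite channels.
    """

    n_species: int = 3
    genes_per_species: int = 1500
    n_hogs: int = 500
    p_ortholog_conserved: float = 0.8
    time_grid: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_TIME_GRID.items()}
    )
    replicates: int = 3
    t0_replicates: int = 6
    n_clusters: int = 8
    gp_lengthscale_h: float = 4.0
    gp_amplitude: float = 2.0
    nb_dispersion: float = 0.1
    baseline_logmean: float = 3.5
    baseline_logsd: float = 1.2
    libsize_logmean: float = 0.0
    libsize_logsd: float = 0.15
    dup_rate: float = 0.0
    loss_rate: float = 0.0
    n_regulators: int = 5
    n_causal_edges: int = 10
    causal_coef: float = 0.6
    causal_lag: int = 1
    n_metabolites: int = 24
    metabolite_link_prob: float = 0.8
    metabolite_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_species",
            "genes_per_species",
            "n_hogs",
            "replicates",
            "t0_replicates",
            "n_clusters",
            "n_metabolites",
        ):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("p_ortholog_conserved", "dup_rate", "loss_rate", "metabolite_link_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.causal_lag < 1:
            raise ValueError(f"causal_lag must be >= 1, got {self.causal_lag}")
        if self.n_hogs > self.genes_per_species:
            raise ValueError("n_hogs may not exceed genes_per_species")
        for cond, times in self.time_grid.items():
            if len(set(times)) != len(tuple(times)):
                raise ValueError(f"overlapping condition/time labels in {cond!r}")

    @property
    def species(self) -> list[str]:
        return [f"sp{i + 1}" for i in range(self.n_species)]

    def treatment_times(self) -> np.ndarray:
        """Sorted union of all non-control sampling times."""
        times: set[float] = set()
        for cond, ts in self.time_grid.items():
            if cond != CONTROL:
                times.update(float(t) for t in ts)
        return np.array(sorted(times))

    def rng(self, tag: str) -> np.random.Generator:
        """Independent deterministic stream for one generator stage."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, abs(hash2(tag))])
        )


def hash2(tag: str) -> int:
    """Stable (non-salted) string hash used to derive per-stage seeds."""
    h = 2166136261
    for ch in tag.encode():
        h = ((h ^ ch) * 16777619) % (1 << 32)
    return h


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator, for recovery tests."""

    assignments: dict[str, int]  # gene_id -> archetype cluster id
    archetypes: pd.DataFrame  # clusters x treatment time points, log2FC units
    causal_edges: list[tuple[str, str, float]]  # (source, target, coefficient)
    metabolite_links: dict[str, int | None]  # metabolite -> archetype (None = noise)

    def __post_init__(self) -> None:
        for src, tgt, _ in self.causal_edges:
            if src == tgt:
                raise ValueError("causal edges may not be self-loops")

    def to_json(self) -> str:
        return json.dumps(
            {
                "assignments": self.assignments,
                "archetypes": {
                    "index": [int(i) for i in self.archetypes.index],
                    "columns": [float(c) for c in self.archetypes.columns],
                    "values": self.archetypes.to_numpy().tolist(),
                },
                "causal_edges": self.causal_edges,
                "metabolite_links": self.metabolite_links,
            },
            indent=1,
        )


def make_design(config: SimConfig) -> pd.DataFrame:
    """Build the sample design table.

    One sample per (species, condition, time, replicate); the 0 h control is
    sampled at ``t0_replicates``, every other combination at ``replicates``.
    With the default grid this yields 3 x (28 x 3 + 6) = 270 samples.
    """
    rows = []
    for sp in config.species:
        for cond, times in config.time_grid.items():
            for t in times:
                n_rep = (
                    config.t0_replicates
                    if (cond == CONTROL and float(t) == 0.0)
                    else config.replicates
                )
                for r in range(1, n_rep + 1):
                    rows.append(
                        {
                            "sample_id": f"{sp}_{cond}_{_fmt_time(t)}_r{r}",
                            "species": sp,
                            "condition": cond,
                            "time_h": float(t),
                            "replicate": r,
                        }
                    )
    design = pd.DataFrame(rows)
    if design["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in design")
    return design


def _fmt_time(t: float) -> str:
    return f"{float(t):g}h".replace(".", "p")


def make_hog_table(
    config: SimConfig,
) -> tuple[pd.DataFrame, dict[str, dict[str, list[str]]]]:
    """Build a gene -> HOG mapping table plus an ortholog map.

    By default each HOG receives exactly one gene in every species. A loss
    rate removes a species from a HOG at random; a duplication rate adds a
    second gene from the species-specific pool. Remaining genes carry an
    empty ``hog_id``.
    """
    rng = config.rng("hogs")
    genes = {
        sp: [f"{sp}_g{i:05d}" for i in range(config.genes_per_species)]
        for sp in config.species
    }
    rows = []
    ortho_map: dict[str, dict[str, list[str]]] = {}
    cursors = {sp: 0 for sp in config.species}
    for h in range(config.n_hogs):
        hog_id = f"HOG{h:05d}"
        members: dict[str, list[str]] = {}
        for sp in config.species:
            if config.loss_rate > 0 and rng.random() < config.loss_rate:
                continue
            members[sp] = [genes[sp][cursors[sp]]]
            cursors[sp] += 1
            if config.dup_rate > 0 and rng.random() < config.dup_rate:
                if cursors[sp] < config.genes_per_species:
                    members[sp].append(genes[sp][cursors[sp]])
                    cursors[sp] += 1
        for sp, gs in members.items():
            for g in gs:
                rows.append({"gene_id": g, "species": sp, "hog_id": hog_id})
        ortho_map[hog_id] = members
    for sp in config.species:
        for g in genes[sp][cursors[sp]:]:
            rows.append({"gene_id": g, "species": sp, "hog_id": ""})
    table = pd.DataFrame(rows, columns=["gene_id", "species", "hog_id"])
    if table["gene_id"].duplicated().any():
        raise AssertionError("gene mapped to more than one HOG")
    return table, ortho_map


def sqexp_kernel(
    t: np.ndarray, amplitude: float, lengthscale: float
) -> np.ndarray:
    """Squared-exponential kernel k(t,t') = a^2 exp(-(t-t')^2 / (2 l^2))."""
    if lengthscale <= 0:
        raise ValueError(f"lengthscale must be > 0, got {lengthscale}")
    d = np.subtract.outer(t, t)
    return amplitude**2 * np.exp(-(d**2) / (2.0 * lengthscale**2))


def make_archetypes(config: SimConfig) -> pd.DataFrame:
    """Draw trajectory archetypes from a zero-mean GP on the treatment grid.

    Returns a (n_clusters x time points) frame in log2 fold-change units.
    """
    t = config.treatment_times()
    rng = config.rng("archetypes")
    K = sqexp_kernel(t, config.gp_amplitude, config.gp_lengthscale_h)
    if config.gp_amplitude == 0:
        draws = np.zeros((config.n_clusters, t.size))
    else:
        L = np.linalg.cholesky(K + 1e-10 * np.eye(t.size))
        draws = rng.standard_normal((config.n_clusters, t.size)) @ L.T
    return pd.DataFrame(draws, index=np.arange(config.n_clusters), columns=t)


def assign_clusters(
    config: SimConfig, hog_table: pd.DataFrame
) -> dict[str, int]:
    """Assign each gene an archetype; orthologs share with prob ``p_ortholog_conserved``.

    Every HOG draws a reference archetype; each member gene inherits it with
    probability ``p_ortholog_conserved`` and otherwise redraws uniformly.
    Genes without a HOG draw uniformly.
    """
    rng = config.rng("assignments")
    assignments: dict[str, int] = {}
    k = config.n_clusters
    for hog_id, grp in hog_table.groupby("hog_id", sort=True):
        if hog_id == "":
            for g in sorted(grp["gene_id"]):
                assignments[g] = int(rng.integers(k))
            continue
        ref = int(rng.integers(k))
        for g in sorted(grp["gene_id"]):
            if rng.random() < config.p_ortholog_conserved:
                assignments[g] = ref
            else:
                assignments[g] = int(rng.integers(k))
    return assignments


def simulate_counts(
    design: pd.DataFrame, truth: PlantedTruth, config: SimConfig
) -> dict[str, pd.DataFrame]:
    """Simulate negative-binomial gene counts per species.

    mean = libsize factor x log-normal baseline x 2^(archetype log2FC in the
    sample's treatment at the sample's time); control samples carry no
    archetype effect. ``nb_dispersion`` -> 0 recovers Poisson sampling.
    """
    rng = config.rng("counts")
    grid = np.asarray(truth.archetypes.columns, dtype=float)
    arch = truth.archetypes.to_numpy()
    out: dict[str, pd.DataFrame] = {}
    for sp in config.species:
        sub = design[design["species"] == sp]
        genes = sorted(g for g in truth.assignments if g.startswith(f"{sp}_"))
        if not genes:
            raise ValueError(f"no genes assigned for species {sp}")
        cl = np.array([truth.assignments[g] for g in genes])
        baseline = np.exp(
            config.baseline_logmean
            + config.baseline_logsd * rng.standard_normal(len(genes))
        )
        counts = np.empty((len(genes), len(sub)), dtype=np.int64)
        for j, (_, row) in enumerate(sub.iterrows()):
            lib = np.exp(
                config.libsize_logmean + config.libsize_logsd * rng.standard_normal()
            )
            if row["condition"] == CONTROL:
                lfc = np.zeros(len(genes))
            else:
                prof = np.array(
                    [np.interp(row["time_h"], grid, arch[c]) for c in range(arch.shape[0])]
                )
                lfc = prof[cl]
            mean = lib * baseline * np.exp2(lfc)
            if config.nb_dispersion <= 1e-12:
                counts[:, j] = rng.poisson(mean)
            else:
                shape = 1.0 / config.nb_dispersion
                lam = rng.gamma(shape, mean / shape)
                counts[:, j] = rng.poisson(lam)
        out[sp] = pd.DataFrame(counts, index=genes, columns=sub["sample_id"].tolist())
    return out


def simulate_var_series(
    config: SimConfig,
    n_nodes: int = 30,
    n_timepoints: int = 20,
    n_series: int = 3,
    noise_sd: float = 0.25,
    burn_in: int = 50,
    series_seed: int | None = None,
) -> tuple[list[tuple[int, int, float]], np.ndarray]:
    """Simulate a lagged vector-autoregressive benchmark series.

    x_t = A x_{t-lag} + eps with eps ~ N(0, noise_sd^2). Planted directed
    edges are the non-zero entries of A, drawn with sources restricted to the
    first ``n_regulators`` nodes and signs alternating at |coef| =
    ``causal_coef``. Raises if the coefficient matrix is unstable.

    ``series_seed`` redraws only the innovation noise while keeping A fixed
    by the config seed — e.g. to emulate several species sharing one planted
    network. Returns ``(edges, series)`` with edges as (source, target,
    coef) node indices and series of shape (n_series, n_nodes,
    n_timepoints).
    """
    rng = config.rng("var")
    n_reg = min(config.n_regulators, n_nodes)
    pairs = [(s, t) for s in range(n_reg) for t in range(n_nodes) if s != t]
    if config.n_causal_edges > len(pairs):
        raise ValueError("n_causal_edges exceeds available regulator-target pairs")
    idx = rng.choice(len(pairs), size=config.n_causal_edges, replace=False)
    A = np.zeros((n_nodes, n_nodes))
    edges = []
    for j, i in enumerate(sorted(int(x) for x in idx)):
        s, t = pairs[i]
        coef = config.causal_coef * (1 if j % 2 == 0 else -1)
        A[t, s] = coef
        edges.append((s, t, coef))
    rho = max(abs(np.linalg.eigvals(A)))
    if rho >= 1.0:
        raise ValueError(
            f"unstable coefficient matrix: spectral radius {rho:.3f} >= 1"
        )
    lag = config.causal_lag
    if series_seed is not None:
        rng = config.rng(f"var_noise_{series_seed}")
    total = burn_in + n_timepoints
    series = np.zeros((n_series, n_nodes, total))
    for r in range(n_series):
        x = np.zeros((n_nodes, total))
        x[:, :lag] = noise_sd * rng.standard_normal((n_nodes, lag))
        for t in range(lag, total):
            x[:, t] = A @ x[:, t - lag] + noise_sd * rng.standard_normal(n_nodes)
        series[r] = x
    return edges, series[:, :, burn_in:]


def simulate_metabolites(
    truth: PlantedTruth, design: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Simulate metabolite channels as noisy copies of archetype trajectories.

    Each metabolite is linked to one archetype with probability
    ``metabolite_link_prob`` (otherwise pure noise); its per-sample value is
    the linked archetype trajectory at the sample time (0 under control) plus
    Gaussian noise. Returns a samples x metabolites frame.
    """
    rng = config.rng("metabolites")
    names = [f"met{i + 1:02d}" for i in range(config.n_metabolites)]
    links: dict[str, int | None] = {}
    for m in names:
        if rng.random() < config.metabolite_link_prob:
            links[m] = int(rng.integers(config.n_clusters))
        else:
            links[m] = None
    truth.metabolite_links.update(links)
    grid = np.asarray(truth.archetypes.columns, dtype=float)
    arch = truth.archetypes.to_numpy()
    vals = np.zeros((len(design), len(names)))
    for j, m in enumerate(names):
        c = links[m]
        base = np.zeros(len(design))
        if c is not None:
            treated = (design["condition"] != CONTROL).to_numpy()
            base[treated] = np.interp(
                design.loc[treated, "time_h"].to_numpy(), grid, arch[c]
            )
        vals[:, j] = base + config.metabolite_noise_sd * rng.standard_normal(len(design))
    return pd.DataFrame(vals, index=design["sample_id"].tolist(), columns=names)


def generate_dataset(config: SimConfig) -> dict:
    """Run the full generator: design, HOGs, truth, counts and metabolites."""
    design = make_design(config)
    hog_table, ortho_map = make_hog_table(config)
    archetypes = make_archetypes(config)
    assignments = assign_clusters(config, hog_table)
    truth = PlantedTruth(
        assignments=assignments,
        archetypes=archetypes,
        causal_edges=[],
        metabolite_links={},
    )
    counts = simulate_counts(design, truth, config)
    metabolites = simulate_metabolites(truth, design, config)
    return {
        "config": config,
        "design": design,
        "hog_table": hog_table,
        "ortholog_map": ortho_map,
        "truth": truth,
        "counts": counts,
        "metabolites": metabolites,
    }


def write_dataset(dataset: dict, outdir) -> None:
    """Write a generated dataset as plain-text TSV/JSON files."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dataset["design"].to_csv(out / "design.tsv", sep="\t", index=False)
    dataset["hog_table"].to_csv(out / "hogs.tsv", sep="\t", index=False)
    for sp, mat in dataset["counts"].items():
        mat.to_csv(out / f"counts_{sp}.tsv", sep="\t", index_label="gene_id")
    dataset["metabolites"].to_csv(out / "metabolites.tsv", sep="\t", index_label="sample_id")
    (out / "truth.json").write_text(dataset["truth"].to_json())
    cfg = asdict(dataset["config"])
    cfg["time_grid"] = {k: list(v) for k, v in cfg["time_grid"].items()}
    (out / "config.json").write_text(json.dumps(cfg, indent=1))
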