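"""Moderated differential expression against matched controls, plus
hypergeometric over-representation analysis.

Per treatment-time contrast a group-means linear model yields ordinary
log2 fold changes and residual variances; variances are then shrunk with an
empirical-Bayes scaled inverse-chi-square prior fitted by moment matching
on the log scale, giving moderated t-statistics with augmented degrees of
freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "Contrast",
    "GeneModelFit",
    "ModeratedStats",
    "build_contrasts",
    "fit_gene_models",
    "moderate_variance",
    "bh_adjust",
    "call_degs",
    "hypergeom_ora",
    "run_contrasts",
]

log = logging.getLogger(__name__)

CONTROL = "control"


@dataclass(frozen=True)
class Contrast:
    condition: str
    time_h: float

    @property
    def name(self) -> str:
        return f"{self.condition}_{self.time_h:g}h"


def build_contrasts(
    design: pd.DataFrame, control: str = CONTROL, on_missing: str = "raise"
) -> list[Contrast]:
    """One contrast per (treatment, time) against the same-time control.

    A treatment time point with no matching control raises by default;
    ``on_missing="skip"`` drops it with a log entry instead (useful for
    grids that sample recovery at times never sampled under control).
    """
    if on_missing not in ("raise", "skip"):
        raise ValueError("on_missing must be 'raise' or 'skip'")
    control_times = set(design.loc[design["condition"] == control, "time_h"])
    contrasts: list[Contrast] = []
    treat = design[design["condition"] != control]
    for (cond, t), _ in treat.groupby(["condition", "time_h"], sort=True):
        if t not in control_times:
            if on_missing == "raise":
                raise ValueError(
                    f"no control at time {t:g} h to match treatment {cond!r}"
                )
            log.info("skipping %s at %g h: no matching control", cond, t)
            continue
        contrasts.append(Contrast(cond, float(t)))
    return contrasts


@dataclass
class GeneModelFit:
    """Per-gene OLS summaries of the condition-time group-means model."""

    coefficients: pd.DataFrame  # genes x contrasts, log2FC units
    s2: np.ndarray  # pooled residual variance per gene
    df_residual: int  # n_samples - n_groups
    contrast_var: dict[str, float]  # unscaled variance 1/n1 + 1/n2 per contrast


def fit_gene_models(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    contrasts: list[Contrast],
    control: str = CONTROL,
) -> GeneModelFit:
    """Fit the saturated (condition, time) group-means model per gene.

    The fold change for a contrast is the difference of group means; the
    pooled residual variance uses all design cells, with df = n - #groups.
    """
    design = design.set_index("sample_id").loc[expr.columns]
    groups = list(zip(design["condition"], design["time_h"]))
    uniq = sorted(set(groups))
    if len(uniq) >= len(groups):
        raise ValueError("singular design: need >= 2 replicates overall")
    X = expr.to_numpy(dtype=float)
    means: dict[tuple[str, float], np.ndarray] = {}
    sizes: dict[tuple[str, float], int] = {}
    sse = np.zeros(X.shape[0])
    for g in uniq:
        cols = [i for i, gg in enumerate(groups) if gg == g]
        sub = X[:, cols]
        m = sub.mean(axis=1)
        means[g] = m
        sizes[g] = len(cols)
        sse += ((sub - m[:, None]) ** 2).sum(axis=1)
    df = len(groups) - len(uniq)
    s2 = sse / df if df > 0 else np.full(X.shape[0], np.nan)

    coefs = {}
    cvar = {}
    for c in contrasts:
        tkey, ckey = (c.condition, c.time_h), (control, c.time_h)
        if tkey not in means or ckey not in means:
            raise ValueError(f"contrast {c.name}: missing design cell")
        coefs[c.name] = means[tkey] - means[ckey]
        cvar[c.name] = 1.0 / sizes[tkey] + 1.0 / sizes[ckey]
    return GeneModelFit(
        coefficients=pd.DataFrame(coefs, index=expr.index),
        s2=s2,
        df_residual=df,
        contrast_var=cvar,
    )


@dataclass
class ModeratedStats:
    d0: float
    s0_sq: float
    s2_post: np.ndarray
    df_total: float


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def moderate_variance(
    s2: np.ndarray,
    df: float,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> ModeratedStats:
    """Empirical-Bayes shrinkage of per-gene variances.

    Fits a scaled inverse-chi-square prior (d0, s0^2) to the observed s^2 by
    moment matching on log s^2 (digamma/trigamma closed forms), then returns
    posterior variances (d0 s0^2 + d s^2) / (d0 + d). Passing ``d0`` (with
    ``s0_sq``) overrides the fit, e.g. d0=0 disables shrinkage entirely and
    d0=inf forces every posterior variance to the prior value.
    """
    s2 = np.asarray(s2, dtype=float)
    if d0 is not None:
        if s0_sq is None:
            raise ValueError("s0_sq required when forcing d0")
        if d0 == 0:
            return ModeratedStats(0.0, s0_sq, s2.copy(), df)
        if np.isinf(d0):
            return ModeratedStats(np.inf, s0_sq, np.full_like(s2, s0_sq), np.inf)
        post = (d0 * s0_sq + df * s2) / (d0 + df)
        return ModeratedStats(float(d0), s0_sq, post, df + d0)
    pos = s2 > 0
    if not pos.any():
        warnings.warn("all residual variances are zero; no moderation possible")
        return ModeratedStats(0.0, 0.0, s2.copy(), df)
    z = np.log(s2[pos])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    if np.isfinite(d0):
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    else:
        s2_post = np.full_like(s2, s0_sq)
    return ModeratedStats(d0=float(d0), s0_sq=s0_sq, s2_post=s2_post, df_total=df + d0)


def moderated_t(
    beta: np.ndarray, mod: ModeratedStats, contrast_var: float
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t and two-sided p for one contrast."""
    denom = np.sqrt(mod.s2_post * contrast_var)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, beta / denom, np.where(beta == 0, 0.0, np.inf * np.sign(beta)))
    df = mod.df_total
    if not np.isfinite(df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, np.clip(p, 0.0, 1.0)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def call_degs(
    results: pd.DataFrame, lfc_min: float = 1.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Flag DEGs: |log2FC| >= lfc_min AND adjusted p <= alpha (inclusive)."""
    out = results.copy()
    out["is_deg"] = (out["log2fc"].abs() >= lfc_min) & (out["adj_p"] <= alpha)
    return out


def run_contrasts(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    contrasts: list[Contrast] | None = None,
    lfc_min: float = 1.0,
    alpha: float = 0.05,
    control: str = CONTROL,
    on_missing: str = "raise",
) -> pd.DataFrame:
    """Full DE pass: fit, moderate, test, adjust and flag, all contrasts.

    Returns a long frame with columns (gene, contrast, condition, time_h,
    log2fc, t, p, adj_p, is_deg); BH adjustment is applied within contrast.
    """
    if contrasts is None:
        contrasts = build_contrasts(design, control=control, on_missing=on_missing)
    fit = fit_gene_models(expr, design, contrasts, control=control)
    mod = moderate_variance(fit.s2, fit.df_residual)
    frames = []
    for c in contrasts:
        beta = fit.coefficients[c.name].to_numpy()
        t, p = moderated_t(beta, mod, fit.contrast_var[c.name])
        frames.append(
            pd.DataFrame(
                {
                    "gene": expr.index,
                    "contrast": c.name,
                    "condition": c.condition,
                    "time_h": c.time_h,
                    "log2fc": beta,
                    "t": t,
                    "p": p,
                    "adj_p": bh_adjust(p),
                }
            )
        )
    return call_degs(pd.concat(frames, ignore_index=True), lfc_min, alpha)


def hypergeom_ora(
    query: set[str],
    annotation: pd.DataFrame,
    background: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms in a query set.

    ``annotation`` has columns (gene_id, term_id). Genes outside the
    background are ignored; p = P(X >= k) with N = |background|,
    K = |term ∩ background|, n = |query|. BH across terms; rows passing
    ``alpha`` are flagged.
    """
    query = set(query)
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    ann = annotation[annotation["gene_id"].isin(background)]
    N, n = len(background), len(query)
    rows = []
    for term, grp in ann.groupby("term_id", sort=True):
        members = set(grp["gene_id"])
        K = len(members)
        if K == 0:
            log.info("term %s absent from background; skipped", term)
            continue
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    res = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "p"])
    if len(res):
        res["adj_p"] = bh_adjust(res["p"].to_numpy())
        res["significant"] = res["adj_p"] <= alpha
        res = res.sort_values(["p", "term_id"], ignore_index=True)
    else:
        res["adj_p"] = []
        res["significant"] = []
    return res
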