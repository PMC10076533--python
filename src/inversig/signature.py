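"""Disease gene-expression signature from a multi-study meta-analysis.

Each study is a genes x samples matrix of log2 expression with case/control
labels.  Per study, gene-wise differences are tested with a moderated
t-statistic (empirical-Bayes variance shrinkage); studies are then combined
under a fixed-effect model by inverse-variance weighting.  Genes passing the
configured adjusted-p and fold-change thresholds form the up/down disease
signature used for reversal scoring downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionStudy",
    "DiseaseSignature",
    "normalize_study",
    "collapse_probes",
    "moderated_t",
    "combine_fixed_effect",
    "select_degs",
]


@dataclass
class ExpressionStudy:
    """One expression study: log2 matrix (genes x samples) + labels.

    ``labels`` is a Series indexed by sample id with values 'case'/'control'.
    """

    study_id: str
    matrix: pd.DataFrame
    labels: pd.Series

    def __post_init__(self):
        missing = [s for s in self.matrix.columns if s not in self.labels.index]
        if missing:
            raise ValueError(f"{self.study_id}: samples without labels: {missing[:5]}")
        counts = self.labels.loc[list(self.matrix.columns)].value_counts()
        for arm in ("case", "control"):
            if counts.get(arm, 0) < 2:
                raise ValueError(f"{self.study_id}: fewer than 2 '{arm}' samples")


@dataclass
class DiseaseSignature:
    """Up/down-regulated gene sets with their meta-analysis statistics."""

    up_genes: tuple[str, ...]
    down_genes: tuple[str, ...]
    table: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    def __post_init__(self):
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError("up and down gene sets overlap")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.up_genes) + tuple(self.down_genes)


def normalize_study(study: ExpressionStudy, log_threshold: float = 50.0) -> ExpressionStudy:
    """Bring a study onto the log2 scale and median-centre each sample.

    Values are assumed already log-scale unless the matrix maximum exceeds
    ``log_threshold``, in which case log2(x+1) is applied first.
    """
    m = study.matrix
    if m.to_numpy().max() > log_threshold:
        m = np.log2(m + 1.0)
    m = m - m.median(axis=0)
    if not np.isfinite(m.to_numpy()).all():
        raise ValueError(f"{study.study_id}: non-finite values after normalization")
    return ExpressionStudy(study.study_id, m, study.labels)


def collapse_probes(matrix: pd.DataFrame, probe_gene_map: pd.Series) -> pd.DataFrame:
    """Collapse a probes x samples matrix to one row per gene.

    For each gene the probe with the largest interquartile range across
    samples is kept; IQR ties go to the lexicographically smallest probe id.
    Probes absent from the map are dropped (count logged).
    """
    if len(probe_gene_map) == 0:
        raise ValueError("empty probe->gene map")
    mapped = matrix.index.intersection(probe_gene_map.index)
    n_dropped = len(matrix.index) - len(mapped)
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    sub = matrix.loc[mapped]
    q75 = sub.quantile(0.75, axis=1)
    q25 = sub.quantile(0.25, axis=1)
    info = pd.DataFrame(
        {"gene": probe_gene_map.loc[mapped].to_numpy(), "iqr": (q75 - q25).to_numpy()},
        index=mapped,
    )
    # stable sort from ascending probe id: winner per gene is max IQR,
    # ties falling to the lexicographically smallest probe
    info = info.sort_index(kind="mergesort").sort_values(
        ["gene", "iqr"], ascending=[True, False], kind="mergesort"
    )
    winners = info.groupby("gene", sort=True).head(1)
    out = sub.loc[winners.index]
    out.index = winners["gene"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0."""
    if x <= 0:
        return np.inf
    # trigamma ~ 1/y for large y, ~ 1/y^2 for small y: good starting bracket
    lo, hi = 1e-8, 1e8
    return optimize.brentq(lambda y: special.polygamma(1, y) - x, lo, hi, xtol=1e-12)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) of the scaled inverse-chi-square variance prior.

    Moment matching on log sample variances: under the hierarchical model
    the log variances are shifted log-F, with known digamma/trigamma mean
    and variance contributions from the residual df; the excess spread
    identifies d0 and the location identifies s0^2.  Returns
    ``(inf, s0^2)`` when the observed spread is at or below the pure
    sampling spread (no evidence of variance heterogeneity).
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size == 0:
        raise ValueError("all gene variances are zero")
    z = np.log(pos)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    n = e.size
    if n < 2:
        warnings.warn("too few genes to estimate the variance prior; no moderation")
        return 0.0, float(np.exp(np.mean(e)))
    ev = float(np.var(e, ddof=1))
    excess = ev - special.polygamma(1, df / 2.0)
    if excess <= 0:
        d0 = np.inf
        s0sq = float(np.exp(np.mean(e)))
    else:
        d0 = 2.0 * _trigamma_inverse(float(excess))
        s0sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0sq


def moderated_t(study: ExpressionStudy, d0_override: float | None = None) -> pd.DataFrame:
    """Gene-wise moderated two-sample t-test for one study.

    The gene variance is shrunk toward a common prior value,
    ``s~^2 = (d0*s0^2 + d*s^2) / (d0 + d)`` with (d0, s0^2) estimated from
    the gene-wise variance distribution; the t statistic uses the shrunk
    variance with d0 + d degrees of freedom.  ``d0_override=0`` recovers the
    ordinary pooled-variance t-test exactly.

    Returns a DataFrame indexed by gene with columns effect (Hedges' g),
    se (its standard error), log2fc, t, df, p, s2.
    """
    labels = study.labels.loc[list(study.matrix.columns)]
    case = study.matrix.loc[:, (labels == "case").to_numpy()]
    ctrl = study.matrix.loc[:, (labels == "control").to_numpy()]
    n1, n2 = case.shape[1], ctrl.shape[1]
    d = n1 + n2 - 2
    m1 = case.mean(axis=1).to_numpy()
    m2 = ctrl.mean(axis=1).to_numpy()
    v1 = case.var(axis=1, ddof=1).to_numpy()
    v2 = ctrl.var(axis=1, ddof=1).to_numpy()
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d
    if np.all(s2 == 0):
        raise ValueError(f"{study.study_id}: zero variance in every gene")

    if d0_override is not None:
        d0 = float(d0_override)
        s0sq = 0.0 if d0 == 0 else fit_variance_prior(s2, d)[1]
    elif len(s2) < 2:
        warnings.warn(f"{study.study_id}: single gene; falling back to no moderation")
        d0, s0sq = 0.0, 0.0
    else:
        d0, s0sq = fit_variance_prior(s2, d)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0sq + d * s2) / (d0 + d)
        df_total = d0 + d

    diff = m1 - m2
    se_diff = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se_diff > 0, diff / se_diff, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(diff == 0, 1.0, p)

    # Hedges' g (bias-corrected SMD) for the meta-analysis effect scale
    j = 1.0 - 3.0 / (4.0 * d - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(s2 > 0, j * diff / np.sqrt(s2), 0.0)
    se_g = np.sqrt((n1 + n2) / (n1 * n2) + g**2 / (2.0 * (n1 + n2)))

    return pd.DataFrame(
        {
            "effect": g,
            "se": se_g,
            "log2fc": diff,
            "t": t,
            "df": df_total,
            "p": p,
            "s2": s2,
        },
        index=study.matrix.index,
    )


# ---------------------------------------------------------------------------
# fixed-effect meta-analysis
# ---------------------------------------------------------------------------

def combine_fixed_effect(
    per_study: dict[str, pd.DataFrame] | list[pd.DataFrame],
    min_studies: int | None = None,
) -> pd.DataFrame:
    """Combine per-study gene results under a fixed-effect model.

    Effects are pooled by inverse-variance weights ``w = 1/se^2`` giving
    ``effect = sum(w*theta)/sum(w)`` and ``se = sqrt(1/sum(w))``; log2 fold
    changes are pooled with the same weights.  The combined p-value is
    reported two ways: from the z of the pooled effect (``p``, used for
    thresholds) and by Fisher's method on the per-study moderated-t
    p-values (``p_fisher``).  BH adjustment over all genes gives ``p_adj``.

    Genes must be present in at least ``min_studies`` studies (default: all).
    """
    if isinstance(per_study, dict):
        frames = list(per_study.values())
    else:
        frames = list(per_study)
    if not frames:
        raise ValueError("no studies to combine")
    k = len(frames)
    need = k if min_studies is None else int(min_studies)

    counts = pd.concat([f["effect"].notna() for f in frames], axis=1).sum(axis=1)
    genes = counts.index[counts >= need].sort_values()
    n_excluded = int((counts < need).sum())
    if n_excluded:
        logger.info("combine_fixed_effect: excluded %d genes below min_studies", n_excluded)
    if len(genes) == 0:
        raise ValueError("no gene present in enough studies")

    eff = np.column_stack([f["effect"].reindex(genes).to_numpy() for f in frames])
    se = np.column_stack([f["se"].reindex(genes).to_numpy() for f in frames])
    fc = np.column_stack([f["log2fc"].reindex(genes).to_numpy() for f in frames])
    pv = np.column_stack([f["p"].reindex(genes).to_numpy() for f in frames])

    present = ~np.isnan(eff)
    w = np.where(present, 1.0 / se**2, 0.0)
    wsum = w.sum(axis=1)
    effect = np.nansum(np.where(present, w * eff, 0.0), axis=1) / wsum
    log2fc = np.nansum(np.where(present, w * fc, 0.0), axis=1) / wsum
    se_comb = np.sqrt(1.0 / wsum)
    z = effect / se_comb
    p = 2.0 * stats.norm.sf(np.abs(z))

    # Fisher: -2 sum log p_i ~ chi2 with 2*(studies present) df
    logp = np.where(present, np.log(np.clip(pv, 1e-300, 1.0)), 0.0)
    fisher_stat = -2.0 * logp.sum(axis=1)
    fisher_df = 2 * present.sum(axis=1)
    p_fisher = stats.chi2.sf(fisher_stat, fisher_df)

    p_adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "effect": effect,
            "se": se_comb,
            "log2fc": log2fc,
            "z": z,
            "p": p,
            "p_fisher": p_fisher,
            "p_adj": p_adj,
            "n_studies": present.sum(axis=1),
        },
        index=genes,
    )


def select_degs(
    meta: pd.DataFrame,
    alpha: float = 0.001,
    up_cut: float = 1.5,
    down_cut: float = -2.0,
) -> DiseaseSignature:
    """Select the up/down disease signature at the configured thresholds.

    Up: p_adj < alpha and log2fc > up_cut.  Down: p_adj < alpha and
    log2fc < down_cut.  The default cuts are deliberately asymmetric
    (+1.5 / -2.0); a stricter "core" signature is obtained by calling again
    with ``up_cut=2.5, down_cut=-2.5``.
    """
    if up_cut <= 0 or down_cut >= 0:
        raise ValueError("up_cut must be positive and down_cut negative")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    sig = meta["p_adj"] < alpha
    up = meta.index[sig & (meta["log2fc"] > up_cut)]
    down = meta.index[sig & (meta["log2fc"] < down_cut)]
    table = meta.loc[up.union(down)].copy()
    table["direction"] = np.where(table["log2fc"] > 0, "up", "down")
    return DiseaseSignature(tuple(sorted(up)), tuple(sorted(down)), table)
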