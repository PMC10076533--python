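"""Integration of reversal scores with inverse signals and potency data.

Three analyses close the loop:

* rank correlation of per-compound sRGES against each inverse-signal
  activity value (ROR upper bound, IC 97.5th percentile, EBGM 95th
  percentile) — both quantities decrease with stronger effect, so a
  positive Spearman rho links reversal strength to the inverse signal;
* leave-one-compound-out identification of *reversal genes*: genes whose
  rank across compound signatures tracks drug activity at FDR < 0.25 in
  every trial;
* validation against IC50 potency summaries joined by InChIKey.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "spearman",
    "correlate_signals",
    "representative_ranks",
    "loocv_reversal_genes",
    "ic50_validate",
    "ReversalGeneCalls",
]

ACTIVITY_COLUMNS = ("ror_uci", "ic975", "ebgm95")


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a t-approximation p-value.

    Average ranks + product-moment correlation of the ranks; requires at
    least 3 paired finite values and non-degenerate vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: Spearman rho undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def correlate_signals(
    activity: pd.DataFrame,
    srges_col: str = "srges",
    methods: tuple[str, ...] = ACTIVITY_COLUMNS,
) -> pd.DataFrame:
    """Spearman of sRGES against each available inverse-signal column.

    Pairwise-complete per method; methods without at least 3 overlapping
    compounds (or missing entirely) are skipped with a warning.
    """
    rows = []
    for col in methods:
        if col not in activity.columns:
            logger.warning("activity column %r absent; skipped", col)
            continue
        sub = activity[[srges_col, col]].dropna()
        if len(sub) < 3:
            logger.warning("activity column %r: only %d paired values; skipped", col, len(sub))
            continue
        rho, p = spearman(sub[srges_col], sub[col])
        rows.append({"method": col, "rho": rho, "p": p, "n": len(sub)})
    return pd.DataFrame(rows, columns=["method", "rho", "p", "n"])


# ---------------------------------------------------------------------------
# LOOCV reversal genes
# ---------------------------------------------------------------------------

def representative_ranks(profiles, reference_dose: float = 10.0,
                         reference_time: float = 24.0) -> pd.DataFrame:
    """One representative rank vector per compound (genes x compounds).

    The reference-condition profile is used when present; otherwise the
    profile nearest the reference by (|log10 dose - 1|, |time - 24|),
    compared lexicographically.
    """
    best: dict[str, tuple] = {}
    for p in profiles:
        key = (
            abs(np.log10(p.dose_um) - np.log10(reference_dose)),
            abs(p.time_h - reference_time),
            p.cell_line,
        )
        cur = best.get(p.compound_id)
        if cur is None or key < cur[0]:
            best[p.compound_id] = (key, p)
    cols = {cid: pair[1].ranks for cid, pair in sorted(best.items())}
    return pd.DataFrame(cols)


def _spearman_rows(mat: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Spearman of a matrix against a vector (t-approximation p).

    Rows with zero rank variance get rho = NaN, p = 1.
    """
    m = mat.shape[1]
    rr = stats.rankdata(mat, axis=1)
    yr = stats.rankdata(y)
    rc = rr - rr.mean(axis=1, keepdims=True)
    yc = yr - yr.mean()
    denom = np.sqrt((rc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, rc @ yc / denom, np.nan)
        rho = np.clip(rho, -1.0, 1.0)
        tstat = rho * np.sqrt((m - 2) / np.clip(1.0 - rho**2, 1e-300, None))
    p = np.where(np.isnan(rho), 1.0, 2.0 * stats.t.sf(np.abs(tstat), m - 2))
    p = np.where(np.abs(rho) == 1.0, 0.0, p)
    return rho, p


@dataclass
class ReversalGeneCalls:
    """Per-gene LOOCV outcome plus the normalised rank matrix for plotting."""

    table: pd.DataFrame
    normalized_ranks: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)

    @property
    def selected(self) -> tuple[str, ...]:
        return tuple(self.table.index[self.table["selected"]])


def loocv_reversal_genes(
    ranks: pd.DataFrame,
    activity: pd.Series,
    fdr_threshold: float = 0.25,
    min_trial_fraction: float = 1.0,
) -> ReversalGeneCalls:
    """Leave-one-compound-out identification of reversal genes.

    ``ranks`` is genes x compounds (one representative rank per compound);
    ``activity`` gives each compound's inverse-signal value.  In each of the
    n_compounds trials one compound is excluded and, per gene, the Spearman
    correlation between its ranks and the remaining activities is tested
    (two-sided), with BH-FDR adjustment across genes within the trial.  A
    gene is selected iff its adjusted p is below ``fdr_threshold`` in at
    least ``min_trial_fraction`` of the trials (default: all of them).

    The returned normalised rank matrix (selected genes x compounds,
    positions divided by the universe size, compounds ordered by increasing
    activity) is the conventional heat-map input.
    """
    compounds = [c for c in ranks.columns if c in activity.index]
    if len(compounds) < 4:
        raise ValueError("need at least 4 compounds with activity values")
    sub = ranks[compounds]
    act = activity.loc[compounds].to_numpy(float)
    if np.ptp(act) == 0:
        raise ValueError("constant activity vector")
    mat = sub.to_numpy(float)
    n_trials = len(compounds)
    n_genes = mat.shape[0]
    hits = np.zeros(n_genes, dtype=int)
    rho_min = np.full(n_genes, np.inf)
    rho_max = np.full(n_genes, -np.inf)
    padj_worst = np.zeros(n_genes)
    for k in range(n_trials):
        keep = np.ones(n_trials, dtype=bool)
        keep[k] = False
        rho, p = _spearman_rows(mat[:, keep], act[keep])
        padj = multipletests(p, method="fdr_bh")[1]
        hits += padj < fdr_threshold
        rho_min = np.minimum(rho_min, np.where(np.isnan(rho), np.inf, rho))
        rho_max = np.maximum(rho_max, np.where(np.isnan(rho), -np.inf, rho))
        padj_worst = np.maximum(padj_worst, padj)
    rho_min = np.where(np.isinf(rho_min), np.nan, rho_min)
    rho_max = np.where(np.isinf(rho_max), np.nan, rho_max)
    selected = hits >= int(np.ceil(min_trial_fraction * n_trials))
    table = pd.DataFrame(
        {
            "rho_min": rho_min,
            "rho_max": rho_max,
            "padj_max": padj_worst,
            "n_trials_significant": hits,
            "selected": selected,
        },
        index=sub.index,
    )
    order = list(pd.Series(act, index=compounds).sort_values(kind="mergesort").index)
    norm = sub.loc[selected, order] / float(n_genes)
    logger.info("LOOCV: %d of %d genes selected at FDR < %g in all %d trials",
                int(selected.sum()), n_genes, fdr_threshold, n_trials)
    return ReversalGeneCalls(table, norm)


# ---------------------------------------------------------------------------
# IC50 validation
# ---------------------------------------------------------------------------

def summarize_ic50(ic50: pd.DataFrame, key_len: int = 14) -> pd.DataFrame:
    """Median/min/max IC50 (nM) per compound key.

    ``key_len=14`` joins on the InChIKey connectivity block; pass 27 for the
    full key.
    """
    t = ic50.copy()
    t["key"] = t["inchikey"].str[:key_len]
    g = t.groupby("key")["ic50_nm"]
    return pd.DataFrame({
        "ic50_median": g.median(),
        "ic50_min": g.min(),
        "ic50_max": g.max(),
        "n_assays": g.size(),
    })


def ic50_validate(
    summaries: pd.DataFrame,
    ic50: pd.DataFrame,
    key_len: int = 14,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate sRGES with per-compound IC50 summaries.

    ``summaries`` needs columns compound_id, inchikey, srges.  Returns
    (correlation table with one row per summary statistic, joined
    per-compound table).  An empty key overlap is an error carrying sample
    keys from both sides.
    """
    per_key = summarize_ic50(ic50, key_len=key_len)
    s = summaries.copy()
    s["key"] = s["inchikey"].str[:key_len]
    joined = s.merge(per_key, left_on="key", right_index=True, how="inner")
    n_unmatched = len(s) - len(joined)
    if joined.empty:
        raise ValueError(
            "no shared InChIKeys between sRGES and IC50 tables; "
            f"sRGES keys e.g. {sorted(s['key'])[:5]}, IC50 keys e.g. {sorted(per_key.index)[:5]}"
        )
    if n_unmatched:
        logger.info("ic50_validate: %d compounds without IC50 rows excluded", n_unmatched)
    rows = []
    for stat in ("ic50_median", "ic50_min", "ic50_max"):
        rho, p = spearman(joined["srges"], joined[stat])
        rows.append({"statistic": stat, "rho": rho, "p": p, "n": len(joined)})
    return pd.DataFrame(rows), joined
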