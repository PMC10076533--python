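"""Reverse gene-expression scoring of drug rank signatures.

A drug profile ranks the gene universe from most up-regulated (rank 1) to
most down-regulated (rank N) after compound treatment.  A KS-type enrichment
score locates the disease's up- and down-gene sets within that ranking, and
the reverse gene-expression score

    RGES = ES_up - ES_down   (0 when both sets fall on the same side)

is negative when the compound pushes disease-up genes to the bottom and
disease-down genes to the top — i.e. when it reverses the disease signature.
Per-compound summaries (sRGES) are anchored to the 10 uM / 24 h reference
condition, with a global additive offset correction for off-reference dose
and time classes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .signature import DiseaseSignature

logger = logging.getLogger(__name__)

__all__ = [
    "DrugProfile",
    "RgesResult",
    "enrichment_score",
    "rges",
    "rges_table",
    "summarize_rges",
    "ranks_from_values",
]


@dataclass
class DrugProfile:
    """One compound x condition rank signature.

    ``ranks`` maps every gene in the universe to a rank in 1..N forming a
    bijection; rank 1 = most up-regulated by the compound.
    """

    compound_id: str
    inchikey: str
    cell_line: str
    dose_um: float
    time_h: float
    ranks: pd.Series

    def __post_init__(self):
        if self.dose_um <= 0 or self.time_h <= 0:
            raise ValueError("dose and time must be positive")
        n = len(self.ranks)
        r = np.sort(self.ranks.to_numpy())
        if n == 0 or not np.array_equal(r, np.arange(1, n + 1)):
            raise ValueError(f"{self.compound_id}: ranks are not a permutation of 1..{n}")


@dataclass(frozen=True)
class RgesResult:
    compound_id: str
    cell_line: str
    dose_um: float
    time_h: float
    es_up: float
    es_down: float
    rges: float


def ranks_from_values(values: pd.Series) -> pd.Series:
    """Convert signature values to a strict 1..N rank permutation.

    Higher value = more up-regulated = smaller rank.  Ties get average rank
    first, then are broken stably by gene id, yielding a strict permutation.
    """
    df = pd.DataFrame({"avg": stats.rankdata(-values.to_numpy(), method="average")},
                      index=values.index)
    df = df.sort_index(kind="mergesort").sort_values("avg", kind="mergesort")
    out = pd.Series(np.arange(1, len(df) + 1), index=df.index, name="rank")
    return out.loc[values.index]


def enrichment_score(gene_set, ranks: pd.Series, n_total: int | None = None) -> float:
    """Weighted-KS enrichment score of ``gene_set`` within a ranked list.

    With V(1) < ... < V(s) the sorted rank positions of the set in a
    universe of N genes,

        a = max_j ( j/s - V(j)/N ),   b = max_j ( V(j)/N - (j-1)/s )

    and ES = a if a >= b else -b.  ES near +1: the set sits at the top of
    the ranking; near -1: at the bottom.
    """
    genes = list(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    missing = [g for g in genes if g not in ranks.index]
    if missing:
        raise ValueError(f"genes outside the ranked universe: {missing[:5]}")
    n = int(n_total) if n_total is not None else len(ranks)
    v = np.sort(ranks.loc[genes].to_numpy(dtype=float))
    s = len(v)
    j = np.arange(1, s + 1, dtype=float)
    a = np.max(j / s - v / n)
    b = np.max(v / n - (j - 1.0) / s)
    return float(a) if a >= b else float(-b)


def rges(profile: DrugProfile, signature: DiseaseSignature) -> RgesResult:
    """Reverse gene-expression score of one profile against the signature.

    Signature genes absent from the profile's universe are dropped with a
    warning; an empty intersection in either direction is an error.  When
    ES_up and ES_down share a sign the profile does not discriminate the two
    sets and the score is 0.
    """
    universe = set(profile.ranks.index)
    up = [g for g in signature.up_genes if g in universe]
    down = [g for g in signature.down_genes if g in universe]
    if len(up) < len(signature.up_genes) or len(down) < len(signature.down_genes):
        warnings.warn(
            f"{profile.compound_id}: signature only partially covered "
            f"(up {len(up)}/{len(signature.up_genes)}, down {len(down)}/{len(signature.down_genes)})",
            stacklevel=2,
        )
    if not up or not down:
        raise ValueError("signature does not intersect the profile universe in both directions")
    es_up = enrichment_score(up, profile.ranks)
    es_down = enrichment_score(down, profile.ranks)
    val = es_up - es_down if np.sign(es_up) != np.sign(es_down) else 0.0
    return RgesResult(
        profile.compound_id, profile.cell_line, profile.dose_um, profile.time_h,
        es_up, es_down, val,
    )


def rges_table(profiles, signature: DiseaseSignature) -> pd.DataFrame:
    """RGES for every profile, as a tidy table (one row per profile)."""
    rows = [rges(p, signature) for p in profiles]
    return pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in rows],
            "cell_line": [r.cell_line for r in rows],
            "dose_um": [r.dose_um for r in rows],
            "time_h": [r.time_h for r in rows],
            "es_up": [r.es_up for r in rows],
            "es_down": [r.es_down for r in rows],
            "rges": [r.rges for r in rows],
        }
    )


def _condition_class(dose: np.ndarray, time: np.ndarray,
                     ref_dose: float, ref_time: float) -> np.ndarray:
    """Two-way condition class: dose below/at-or-above 10 uM x time below/at-or-above 24 h."""
    d = np.where(dose >= ref_dose, "hi", "lo")
    t = np.where(time >= ref_time, "hi", "lo")
    return np.char.add(np.char.add(d.astype("U2"), "-"), t.astype("U2"))


def summarize_rges(
    table: pd.DataFrame,
    reference_dose: float = 10.0,
    reference_time: float = 24.0,
    w0: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Summarise per-profile RGES to one sRGES per compound.

    Profiles are bucketed into four dose/time classes split at the reference
    condition (10 uM, 24 h); the reference class is dose >= 10 and
    time >= 24.  For each non-reference class a global additive offset is
    estimated as the mean difference between that class's profiles and the
    reference-class profiles within compounds carrying both; the offset is
    subtracted before averaging.  The per-compound summary is a weighted
    mean with weight 1 for reference-class profiles and ``w0`` otherwise.

    Returns (per-compound DataFrame with srges and n_profiles, offsets dict).
    """
    if table.empty:
        raise ValueError("no profiles to summarize")
    t = table.copy()
    t["cls"] = _condition_class(
        t["dose_um"].to_numpy(float), t["time_h"].to_numpy(float),
        reference_dose, reference_time,
    )
    ref_cls = "hi-hi"
    offsets: dict[str, float] = {}
    cls_means = t.groupby(["compound_id", "cls"])["rges"].mean().unstack()
    for cls in sorted(t["cls"].unique()):
        if cls == ref_cls:
            offsets[cls] = 0.0
            continue
        if ref_cls in cls_means.columns and cls in cls_means.columns:
            paired = cls_means[[cls, ref_cls]].dropna()
        else:
            paired = pd.DataFrame()
        if paired.empty:
            logger.warning("no compound pairs class %s with the reference; offset set to 0", cls)
            offsets[cls] = 0.0
        else:
            offsets[cls] = float((paired[cls] - paired[ref_cls]).mean())
    t["rges_corrected"] = t["rges"] - t["cls"].map(offsets)
    t["weight"] = np.where(t["cls"] == ref_cls, 1.0, float(w0))
    grp = t.groupby("compound_id", sort=True)
    srges = grp.apply(
        lambda g: np.average(g["rges_corrected"], weights=g["weight"]),
        include_groups=False,
    )
    out = pd.DataFrame({
        "compound_id": srges.index,
        "srges": srges.to_numpy(float),
        "n_profiles": grp.size().to_numpy(int),
    }).reset_index(drop=True)
    return out, offsets
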