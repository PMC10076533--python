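"""Adverse-event report ingestion, cleaning and contingency construction.

Reads the quarterly ASCII dialect of spontaneous-report databases
(``$``-delimited DEMO/DRUG/REAC tables), deduplicates case versions,
applies the standard pharmacovigilance filters (primary-suspect drugs only,
uninformative event terms excluded, combination products dropped), maps
event terms to ICD-10 and builds the per-pair 2x2 contingency cells the
disproportionality statistics consume.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CaseReport",
    "read_reports",
    "deduplicate",
    "filter_reports",
    "normalize_drug_name",
    "is_combination_drug",
    "pairs_from_reports",
    "build_contingency",
    "map_events_to_icd10",
    "select_target_event",
]

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})  # primary/secondary suspect, concomitant, interacting
DEFAULT_EXCLUDED_PTS = frozenset({"drug ineffective", "medication error"})
DEFAULT_EXCLUDED_ICD10_CHAPTERS = frozenset({"A", "B", "R"})

_DOSAGE_SUFFIX = re.compile(r"\s+\d+(\.\d+)?\s*(MG|MCG|G|ML|MG/ML|%)\.?$")
_COMBO_SEP = re.compile(r"[A-Z0-9)]\s*[/\\+]\s*[A-Z0-9(]")


@dataclass(frozen=True)
class CaseReport:
    """One report version.  FAERS reports may list several drugs; when they
    do, the primary-suspect row (else the first row) is carried here."""

    primary_id: str
    case_id: str
    event_date: str  # YYYYMMDD
    drug_name: str
    role_code: str
    pt_terms: tuple[str, ...]


def _read_table(path: str | Path, required: tuple[str, ...], delimiter: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, dtype=str, engine="python",
                     keep_default_na=False)
    df.columns = [c.strip().upper() for c in df.columns]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col}")
    if df.empty:
        logger.warning("%s: empty file", path)
    return df


def read_reports(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    delimiter: str = "$",
) -> list[CaseReport]:
    """Parse DEMO/DRUG/REAC tables into one CaseReport per PRIMARYID.

    Malformed rows (empty drug name, missing event term, DRUG/REAC rows
    without a matching DEMO row) are skipped; skip counts are logged.
    """
    demo = _read_table(demo_path, ("PRIMARYID", "CASEID", "EVENT_DT"), delimiter)
    drug = _read_table(drug_path, ("PRIMARYID", "ROLE_COD", "DRUGNAME"), delimiter)
    reac = _read_table(reac_path, ("PRIMARYID", "PT"), delimiter)

    n_bad_drug = int((drug["DRUGNAME"].str.strip() == "").sum())
    drug = drug[drug["DRUGNAME"].str.strip() != ""]
    n_bad_reac = int((reac["PT"].str.strip() == "").sum())
    reac = reac[reac["PT"].str.strip() != ""]

    drugs_by_id: dict[str, list[tuple[str, str]]] = {}
    for pid, role, name in drug[["PRIMARYID", "ROLE_COD", "DRUGNAME"]].itertuples(index=False):
        drugs_by_id.setdefault(pid, []).append((role.strip().upper(), name.strip()))
    pts_by_id: dict[str, list[str]] = {}
    for pid, pt in reac[["PRIMARYID", "PT"]].itertuples(index=False):
        pts_by_id.setdefault(pid, []).append(pt.strip())

    reports: list[CaseReport] = []
    n_skipped = 0
    for pid, caseid, dt in demo[["PRIMARYID", "CASEID", "EVENT_DT"]].itertuples(index=False):
        dr = drugs_by_id.get(pid)
        pts = pts_by_id.get(pid)
        if not dr or not pts:
            n_skipped += 1
            continue
        role, name = next(((r, n) for r, n in dr if r == "PS"), dr[0])
        reports.append(CaseReport(pid.strip(), caseid.strip(), dt.strip(), name, role,
                                  tuple(dict.fromkeys(pts))))
    total_skipped = n_skipped + n_bad_drug + n_bad_reac
    if total_skipped:
        logger.info("read_reports: skipped %d malformed/unmatched rows "
                    "(%d demo, %d drug, %d reac)", total_skipped, n_skipped, n_bad_drug, n_bad_reac)
    ids = [r.primary_id for r in reports]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate PRIMARYID rows in DEMO file")
    return reports


def deduplicate(reports: list[CaseReport]) -> list[CaseReport]:
    """Keep one report per case: the most recent version.

    The retained report maximises (event_date, primary_id)
    lexicographically; output is sorted by case_id, so the operation is
    idempotent and deterministic.
    """
    best: dict[str, CaseReport] = {}
    for r in reports:
        cur = best.get(r.case_id)
        if cur is None or (r.event_date, r.primary_id) > (cur.event_date, cur.primary_id):
            best[r.case_id] = r
    out = [best[cid] for cid in sorted(best)]
    logger.info("deduplicate: %d reports -> %d cases", len(reports), len(out))
    return out


def normalize_drug_name(name: str) -> str:
    """Uppercase, trim, collapse whitespace, strip trailing dosage tokens."""
    s = re.sub(r"\s+", " ", name.strip().upper())
    while True:
        new = _DOSAGE_SUFFIX.sub("", s)
        if new == s:
            return s
        s = new


def is_combination_drug(name: str, curated: frozenset[str] = frozenset()) -> bool:
    """Heuristic multi-ingredient detection on the normalised name.

    A separator among / \\ + or the word AND between alphabetic tokens, or
    membership of a curated multi-ingredient list.
    """
    s = normalize_drug_name(name)
    if s in curated:
        return True
    if _COMBO_SEP.search(s):
        return True
    return bool(re.search(r"[A-Z]\s+AND\s+[A-Z]", s))


def filter_reports(
    reports: list[CaseReport],
    excluded_pts: frozenset[str] = DEFAULT_EXCLUDED_PTS,
    combination_list: frozenset[str] = frozenset(),
) -> tuple[list[CaseReport], dict[str, int]]:
    """Apply the three report-level filters; returns (kept, attrition log).

    1. only primary-suspect drug reports are retained;
    2. event terms in the exclusion list (case-insensitive) are removed,
       dropping the report if nothing remains;
    3. combination products (multi-ingredient names) are dropped.

    The filters act on disjoint fields, so their order does not matter.
    """
    excl = {p.lower() for p in excluded_pts}
    log = {"not_primary_suspect": 0, "excluded_pt_only": 0, "combination_drug": 0}
    out: list[CaseReport] = []
    for r in reports:
        if r.role_code != "PS":
            log["not_primary_suspect"] += 1
            continue
        if is_combination_drug(r.drug_name, combination_list):
            log["combination_drug"] += 1
            continue
        pts = tuple(p for p in r.pt_terms if p.lower() not in excl)
        if not pts:
            log["excluded_pt_only"] += 1
            continue
        if pts != r.pt_terms:
            r = CaseReport(r.primary_id, r.case_id, r.event_date,
                           r.drug_name, r.role_code, pts)
        out.append(r)
    for name, cnt in log.items():
        logger.info("filter_reports: %s removed %d reports", name, cnt)
    return out, log


def pairs_from_reports(reports: list[CaseReport]) -> pd.DataFrame:
    """Count unique (report, drug, event) triplets into per-pair counts.

    Each report contributes at most one count per (drug, event) pair; the
    drug name is normalised first.  Returns columns drug, event, a.
    """
    rows = []
    for r in reports:
        drug = normalize_drug_name(r.drug_name)
        for pt in set(r.pt_terms):
            rows.append((drug, pt))
    if not rows:
        return pd.DataFrame(columns=["drug", "event", "a"])
    df = pd.DataFrame(rows, columns=["drug", "event"])
    out = df.groupby(["drug", "event"], sort=True).size().rename("a").reset_index()
    return out


def build_contingency(pairs: pd.DataFrame, full_grid: bool = True) -> pd.DataFrame:
    """2x2 cells for every (drug, event): a, b, c, d, n, expected.

    Marginals are computed on the full pair set: b = n_drug - a,
    c = n_event - a, d = n - a - b - c, expected = (a+b)(a+c)/n.  With
    ``full_grid`` the cross of observed drugs x observed events is emitted,
    so zero-count cells (needed by IC and EBGM) are retained.
    """
    if pairs.empty or pairs["a"].sum() == 0:
        raise ValueError("no drug-event pairs: cannot build contingency tables")
    n_total = int(pairs["a"].sum())
    n_drug = pairs.groupby("drug")["a"].sum()
    n_event = pairs.groupby("event")["a"].sum()
    if full_grid:
        grid = pd.MultiIndex.from_product(
            [sorted(n_drug.index), sorted(n_event.index)], names=["drug", "event"]
        ).to_frame(index=False)
        out = grid.merge(pairs, on=["drug", "event"], how="left").fillna({"a": 0})
    else:
        out = pairs.copy()
    out["a"] = out["a"].astype(int)
    out["b"] = out["drug"].map(n_drug).astype(int) - out["a"]
    out["c"] = out["event"].map(n_event).astype(int) - out["a"]
    out["d"] = n_total - out["a"] - out["b"] - out["c"]
    out["n"] = n_total
    out["expected"] = (out["a"] + out["b"]) * (out["a"] + out["c"]) / n_total
    bad = (out[["a", "b", "c", "d"]] < 0).any(axis=1)
    if bad.any():
        raise AssertionError("negative contingency cell — marginals inconsistent")
    return out


def map_events_to_icd10(
    events,
    mapping: pd.DataFrame,
    excluded_chapters: frozenset[str] = DEFAULT_EXCLUDED_ICD10_CHAPTERS,
) -> tuple[pd.DataFrame, list[str]]:
    """Attach ICD-10 codes to event terms.

    ``mapping`` is two columns (PT term, ICD-10 code).  Terms whose code
    falls in an excluded chapter (default A, B, R: infectious diseases and
    symptoms/signs) are flagged ``excluded``.  Conflicting duplicate rows
    are an error; coverage is logged.  Returns (table, unmapped terms).
    """
    m = mapping.copy()
    m.columns = ["pt", "icd10"]
    m["pt_key"] = m["pt"].str.strip().str.lower()
    m["icd10"] = m["icd10"].str.strip().str.upper()
    dup = m.drop_duplicates().groupby("pt_key")["icd10"].nunique()
    conflicts = dup.index[dup > 1].tolist()
    if conflicts:
        raise ValueError(f"conflicting ICD-10 mappings for PTs: {conflicts[:10]}")
    lut = m.drop_duplicates("pt_key").set_index("pt_key")["icd10"]

    events = list(dict.fromkeys(events))
    codes = [lut.get(e.strip().lower()) for e in events]
    mapped = [c is not None for c in codes]
    excluded = [bool(c) and c[0].upper() in excluded_chapters for c in codes]
    table = pd.DataFrame({
        "event": events,
        "icd10": [c if c is not None else "" for c in codes],
        "mapped": mapped,
        "excluded": excluded,
    })
    unmapped = [e for e, ok in zip(events, mapped) if not ok]
    coverage = float(np.mean(mapped)) if events else 0.0
    logger.info("map_events_to_icd10: coverage %.2f%% (%d of %d terms)",
                100 * coverage, sum(mapped), len(events))
    return table, unmapped


def select_target_event(
    signals: pd.DataFrame,
    mapping_table: pd.DataFrame,
    method: str = "ror",
    synonyms: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Rank mapped, non-excluded events by their number of inverse drugs.

    Related event terms may be grouped through ``synonyms`` (term -> group
    label, e.g. the disease's clinical variants onto one disease name).
    Events are ordered by descending inverse-drug count, ties broken
    alphabetically.  An empty result (no flagged pairs) yields an empty
    table with a warning.
    """
    flag_col = f"inverse_{method}"
    if flag_col not in signals.columns:
        raise ValueError(f"signals table lacks {flag_col}")
    eligible = set(mapping_table.loc[
        mapping_table["mapped"] & ~mapping_table["excluded"], "event"
    ])
    syn = {k.lower(): v for k, v in (synonyms or {}).items()}
    sub = signals[signals[flag_col] & signals["event"].isin(eligible)].copy()
    if sub.empty:
        logger.warning("select_target_event: no inverse-flagged pairs among eligible events")
        return pd.DataFrame(columns=["event", "n_inverse_drugs"])
    sub["group"] = [syn.get(e.lower(), e) for e in sub["event"]]
    counts = sub.groupby("group")["drug"].nunique().rename("n_inverse_drugs").reset_index()
    counts = counts.rename(columns={"group": "event"})
    counts = counts.sort_values(["n_inverse_drugs", "event"],
                                ascending=[False, True], kind="mergesort")
    return counts.reset_index(drop=True)
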