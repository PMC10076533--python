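"""Synthetic inputs with known ground truth for every pipeline stage.

Five input classes are emulated, shaped like their real-world counterparts:

* spontaneous adverse-event report tables (``$``-delimited DEMO/DRUG/REAC)
  with planted relative-reporting ratios per drug-event pair — a pair's
  multinomial cell probability is its independence probability scaled by
  lambda, so expected counts stay analytically computable;
* multi-study gene-expression matrices with planted up/down genes of known
  standardised effect and study-level baseline noise;
* drug rank signatures whose reversal of the planted disease genes is
  monotone in a latent compound activity (truncated-geometric rank shifts
  toward the appropriate end of the list);
* IC50 potency tables whose log10 values decrease linearly in the same
  latent activity plus lognormal noise;
* a PT -> ICD-10 mapping table.

Fixed seeds give byte-identical outputs; every planted quantity is returned
in a truth table.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .reversal import DrugProfile
from .signature import DiseaseSignature, ExpressionStudy
from ._util import write_tsv

__all__ = [
    "AerSimConfig",
    "ExprSimConfig",
    "DrugSimConfig",
    "SimulatedReports",
    "simulate_reports",
    "simulate_expression",
    "simulate_drug_signatures",
    "simulate_ic50",
    "write_faers",
    "write_drug_signatures",
    "read_drug_signatures",
]

_LETTERS = np.array(list(string.ascii_uppercase))


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class AerSimConfig:
    """Adverse-event report simulation settings.

    ``planted_associations`` holds (drug name, event name, lambda) triples;
    lambda is the relative reporting ratio of the pair (lambda < 1 plants an
    inverse association, lambda = 1 is the independence null).
    """

    n_drugs: int
    n_events: int
    n_reports: int
    baseline_event_probs: np.ndarray | None = None
    planted_associations: list[tuple[str, str, float]] = field(default_factory=list)
    duplicate_fraction: float = 0.0
    combo_fraction: float = 0.0
    seed: int = 0
    drug_names: list[str] | None = None
    event_names: list[str] | None = None

    def __post_init__(self):
        if min(self.n_drugs, self.n_events, self.n_reports) <= 0:
            raise ValueError("n_drugs, n_events, n_reports must be positive")
        if self.drug_names is None:
            self.drug_names = [f"DRUG{i:04d}" for i in range(self.n_drugs)]
        if self.event_names is None:
            self.event_names = [f"EVENT{j:04d}" for j in range(self.n_events)]
        if len(self.drug_names) != self.n_drugs or len(self.event_names) != self.n_events:
            raise ValueError("name lists must match n_drugs / n_events")
        if self.baseline_event_probs is None:
            self.baseline_event_probs = np.full(self.n_events, 1.0 / self.n_events)
        self.baseline_event_probs = np.asarray(self.baseline_event_probs, dtype=float)
        if self.baseline_event_probs.shape != (self.n_events,) or np.any(
            self.baseline_event_probs < 0
        ) or abs(self.baseline_event_probs.sum() - 1.0) > 1e-9:
            raise ValueError("baseline_event_probs must be a probability vector over events")
        for drug, event, lam in self.planted_associations:
            if lam <= 0:
                raise ValueError(f"lambda must be > 0 (got {lam} for {drug}/{event})")
            if drug not in self.drug_names or event not in self.event_names:
                raise ValueError(f"planted pair ({drug}, {event}) not in the name lists")
        for frac in (self.duplicate_fraction, self.combo_fraction):
            if not 0.0 <= frac < 1.0:
                raise ValueError("fractions must lie in [0, 1)")


@dataclass
class ExprSimConfig:
    """Multi-study expression simulation settings.

    Effects are in standardised-mean-difference units with unit residual
    standard deviation, so the planted SMD is also the planted log2 fold
    change.  Planted down genes get effect ``-effect_size_mean``.
    """

    n_studies: int
    genes: list[str]
    n_case: int
    n_control: int
    planted_up: list[str] = field(default_factory=list)
    planted_down: list[str] = field(default_factory=list)
    effect_size_mean: float = 2.5
    study_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_studies <= 0:
            raise ValueError("n_studies must be positive")
        if min(self.n_case, self.n_control) < 2:
            raise ValueError("need at least 2 samples per arm")
        if set(self.planted_up) & set(self.planted_down):
            raise ValueError("planted up/down sets overlap")
        unknown = (set(self.planted_up) | set(self.planted_down)) - set(self.genes)
        if unknown:
            raise ValueError(f"planted genes outside the universe: {sorted(unknown)[:5]}")


@dataclass
class DrugSimConfig:
    """Drug signature + IC50 simulation settings.

    Each compound carries a latent activity t in [0, 1]; the rank-shift
    strength of the disease genes and the (negated) log10 IC50 are both
    monotone in t.  ``conditions`` lists (cell line, dose uM, time h)
    profiles emitted per compound; sub-reference conditions (dose < 10 or
    time < 24) attenuate the effective activity by
    ``sub_reference_factor``.
    """

    n_compounds: int
    genes: list[str]
    conditions: list[tuple[str, float, float]] = field(
        default_factory=lambda: [("A375", 10.0, 24.0)]
    )
    activity_link: Callable[[np.ndarray], np.ndarray] | None = None
    activities: np.ndarray | None = None
    sub_reference_factor: float = 0.7
    rank_spread: float = 0.1  # geometric offset scale, fraction of the list length
    ic50_intercept: float = 4.0  # log10(nM) at activity 0
    ic50_slope: float = 3.0
    ic50_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_compounds <= 0:
            raise ValueError("n_compounds must be positive")
        if not self.conditions:
            raise ValueError("at least one condition per compound is required")
        if self.activities is not None:
            self.activities = np.asarray(self.activities, dtype=float)
            if self.activities.shape != (self.n_compounds,):
                raise ValueError("activities must have length n_compounds")
            if np.any((self.activities < 0) | (self.activities > 1)):
                raise ValueError("latent activities must lie in [0, 1]")
        if self.ic50_slope <= 0:
            raise ValueError("ic50_slope must be positive")


# ---------------------------------------------------------------------------
# adverse-event reports
# ---------------------------------------------------------------------------

@dataclass
class SimulatedReports:
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    truth: pd.DataFrame  # drug, event, lam, p_cell, expected_a


def cell_probabilities(cfg: AerSimConfig) -> pd.DataFrame:
    """Per-(drug, event) multinomial probabilities with lambdas applied."""
    p_drug = np.full(cfg.n_drugs, 1.0 / cfg.n_drugs)
    base = np.outer(p_drug, cfg.baseline_event_probs)
    lam = np.ones_like(base)
    di = {d: i for i, d in enumerate(cfg.drug_names)}
    ei = {e: j for j, e in enumerate(cfg.event_names)}
    for drug, event, l in cfg.planted_associations:
        lam[di[drug], ei[event]] = l
    p = base * lam
    p /= p.sum()
    return pd.DataFrame(p, index=cfg.drug_names, columns=cfg.event_names)


def simulate_reports(cfg: AerSimConfig) -> SimulatedReports:
    """Draw spontaneous reports as a multinomial over drug-event cells.

    Each report carries one primary-suspect drug row and one reaction row.
    ``duplicate_fraction`` of the cases are emitted twice (a second case
    version with a later event date); ``combo_fraction`` of the cases carry
    a multi-ingredient drug name.
    """
    rng = np.random.default_rng(cfg.seed)
    p = cell_probabilities(cfg)
    flat = p.to_numpy().ravel()
    counts = rng.multinomial(cfg.n_reports, flat)
    cell_idx = np.repeat(np.arange(flat.size), counts)
    cell_idx = rng.permutation(cell_idx)
    drug_idx, event_idx = np.divmod(cell_idx, cfg.n_events)

    n = cfg.n_reports
    case_id = np.array([f"{10_000_000 + i}" for i in range(n)])
    years = rng.integers(2015, 2020, size=n)
    months = rng.integers(1, 13, size=n)
    days = rng.integers(1, 29, size=n)
    dates = np.array([f"{y}{m:02d}{d:02d}" for y, m, d in zip(years, months, days)])

    drug_names = np.array(cfg.drug_names, dtype=object)[drug_idx]
    n_combo = int(round(cfg.combo_fraction * n))
    if n_combo:
        combo_rows = rng.choice(n, size=n_combo, replace=False)
        partners = np.array(cfg.drug_names, dtype=object)[
            rng.integers(0, cfg.n_drugs, size=n_combo)
        ]
        drug_names = drug_names.copy()
        drug_names[combo_rows] = [
            f"{a}/{b}" for a, b in zip(drug_names[combo_rows], partners)
        ]
    event_names = np.array(cfg.event_names, dtype=object)[event_idx]

    primary_v1 = np.char.add(case_id, "1")
    n_dup = int(round(cfg.duplicate_fraction * n))
    dup_rows = rng.choice(n, size=n_dup, replace=False) if n_dup else np.array([], dtype=int)

    def with_dups(values, dup_values=None):
        if n_dup == 0:
            return values
        extra = values[dup_rows] if dup_values is None else dup_values
        return np.concatenate([values, extra])

    dup_dates = np.array(
        [f"{int(d[:4]) + 1}{d[4:]}" for d in dates[dup_rows]]
    ) if n_dup else np.array([])
    demo = pd.DataFrame({
        "PRIMARYID": with_dups(primary_v1, np.char.add(case_id[dup_rows], "2")),
        "CASEID": with_dups(case_id),
        "EVENT_DT": with_dups(dates, dup_dates),
    })
    drug = pd.DataFrame({
        "PRIMARYID": demo["PRIMARYID"],
        "CASEID": demo["CASEID"],
        "ROLE_COD": "PS",
        "DRUGNAME": with_dups(drug_names),
    })
    reac = pd.DataFrame({
        "PRIMARYID": demo["PRIMARYID"],
        "CASEID": demo["CASEID"],
        "PT": with_dups(event_names),
    })

    truth = pd.DataFrame(
        [
            {
                "drug": d,
                "event": e,
                "lam": l,
                "p_cell": p.loc[d, e],
                "expected_a": cfg.n_reports * p.loc[d, e],
            }
            for d, e, l in cfg.planted_associations
        ],
        columns=["drug", "event", "lam", "p_cell", "expected_a"],
    )
    return SimulatedReports(demo, drug, reac, truth)


def write_faers(sim: SimulatedReports, outdir: str | Path, delimiter: str = "$") -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("DEMO", sim.demo), ("DRUG", sim.drug), ("REAC", sim.reac)):
        path = outdir / f"{name}.txt"
        df.to_csv(path, sep=delimiter, index=False, lineterminator="\n")
        paths[name.lower()] = path
    truth_path = outdir / "truth_associations.tsv"
    write_tsv(sim.truth, truth_path)
    paths["truth"] = truth_path
    return paths


# ---------------------------------------------------------------------------
# expression studies
# ---------------------------------------------------------------------------

def simulate_expression(cfg: ExprSimConfig) -> tuple[list[ExpressionStudy], pd.DataFrame]:
    """Simulate per-study log2 expression matrices with planted DEGs.

    Gene baselines are shared across studies; each study adds a per-gene
    baseline shift with sd ``study_noise_sd`` and unit-variance sample
    noise.  Planted up genes shift case means by +effect_size_mean, planted
    down genes by -effect_size_mean (SMD units = log2 units here).

    Returns (studies, truth table with per-gene true effect).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = list(cfg.genes)
    g = len(genes)
    baseline = rng.normal(7.0, 1.0, size=g)
    delta = np.zeros(g)
    gi = {gene: i for i, gene in enumerate(genes)}
    for gene in cfg.planted_up:
        delta[gi[gene]] = cfg.effect_size_mean
    for gene in cfg.planted_down:
        delta[gi[gene]] = -cfg.effect_size_mean

    studies = []
    for s in range(cfg.n_studies):
        study_id = f"GSE9{80000 + s}"
        shift = rng.normal(0.0, cfg.study_noise_sd, size=g)
        n_tot = cfg.n_case + cfg.n_control
        noise = rng.normal(0.0, 1.0, size=(g, n_tot))
        means = baseline + shift
        mat = means[:, None] + noise
        mat[:, : cfg.n_case] += delta[:, None]
        samples = [f"GSM{7_000_000 + s * 1000 + k}" for k in range(n_tot)]
        matrix = pd.DataFrame(mat, index=genes, columns=samples)
        labels = pd.Series(
            ["case"] * cfg.n_case + ["control"] * cfg.n_control, index=samples
        )
        studies.append(ExpressionStudy(study_id, matrix, labels))

    truth = pd.DataFrame({
        "gene": genes,
        "true_effect": delta,
        "planted": np.where(delta > 0, "up", np.where(delta < 0, "down", "background")),
    })
    return studies, truth


# ---------------------------------------------------------------------------
# drug signatures
# ---------------------------------------------------------------------------

def reversal_success_prob(activity: float, n: int, spread: float = 0.1) -> float:
    """Geometric success probability for a given reversal activity.

    The offset scale (mean displacement from the list end) is
    ``spread * n * (1 - t) / t`` positions, i.e. ``p = t / (t + spread*n*(1-t))``:
    t = 0 gives p = 0 (uniform ranks), t = 1 gives p = 1 (the exact extreme
    block), and the shift strength is strictly monotone in t in between.
    """
    t = float(activity)
    if not 0.0 <= t <= 1.0:
        raise ValueError("activity must lie in [0, 1]")
    if t == 0.0:
        return 0.0
    return t / (t + spread * n * (1.0 - t))


def truncated_geometric_icdf(u: np.ndarray, p: float, n: int) -> np.ndarray:
    """Inverse CDF of the geometric(p) distribution truncated to {0..n-1}.

    p = 0 degenerates to the discrete uniform; p = 1 to a point mass at 0.
    Monotone non-increasing in p for fixed u, which makes rank shifts
    monotone in activity under common random numbers.
    """
    u = np.asarray(u, dtype=float)
    if p <= 0.0:
        return np.minimum((u * n).astype(int), n - 1)
    if p >= 1.0:
        return np.zeros(u.shape, dtype=int)
    q = 1.0 - p
    k = np.floor(np.log1p(-u * (1.0 - q**n)) / np.log(q)).astype(int)
    return np.clip(k, 0, n - 1)


def _place_signature_ranks(
    genes: Sequence[str],
    up: Sequence[str],
    down: Sequence[str],
    p: float,
    u_up: np.ndarray,
    u_down: np.ndarray,
    rest_order: np.ndarray,
) -> pd.Series:
    """Deterministic rank assembly from pre-drawn uniforms.

    Up genes draw offsets from the bottom of the list, down genes from the
    top, via the truncated geometric with success probability ``p``;
    collisions take the nearest free slot toward the intended end.
    Remaining genes fill the free slots in ``rest_order``.
    """
    n = len(genes)
    taken = np.zeros(n, dtype=bool)
    slot_of: dict[str, int] = {}

    def claim(desired: int, toward_bottom: bool) -> int:
        scan = (
            list(range(desired, n)) + list(range(desired - 1, -1, -1))
            if toward_bottom
            else list(range(desired, -1, -1)) + list(range(desired + 1, n))
        )
        for s in scan:
            if not taken[s]:
                taken[s] = True
                return s
        raise RuntimeError("no free slot")

    offs_up = truncated_geometric_icdf(u_up, p, n)
    for gene, off in zip(up, offs_up):
        slot_of[gene] = claim(n - 1 - int(off), toward_bottom=True)
    offs_down = truncated_geometric_icdf(u_down, p, n)
    for gene, off in zip(down, offs_down):
        slot_of[gene] = claim(int(off), toward_bottom=False)

    free = np.flatnonzero(~taken)
    rest = [g for g in np.asarray(genes, dtype=object)[rest_order] if g not in slot_of]
    for gene, s in zip(rest, free):
        slot_of[gene] = int(s)
        taken[s] = True
    ranks = pd.Series({g: slot_of[g] + 1 for g in genes}, name="rank")
    return ranks.loc[list(genes)]


def _random_inchikey(rng: np.random.Generator) -> str:
    a = "".join(rng.choice(_LETTERS, size=14))
    b = "".join(rng.choice(_LETTERS, size=10))
    return f"{a}-{b}-N"


def simulate_drug_signatures(
    cfg: DrugSimConfig, signature: DiseaseSignature
) -> tuple[list[DrugProfile], pd.DataFrame]:
    """Simulate rank profiles whose signature reversal is monotone in activity.

    For a compound of latent activity t the disease's up genes are drawn
    toward the bottom of the ranking and its down genes toward the top by a
    truncated geometric with success probability (the condition-scaled)
    ``activity_link(t)``: t = 0 gives uniform random ranks, t = 1 packs the
    sets into the exact extreme blocks.

    Returns (profiles, truth table: compound_id, inchikey, activity).
    """
    if not signature.up_genes and not signature.down_genes:
        raise ValueError("empty disease signature")
    rng = np.random.default_rng(cfg.seed)
    t = (
        cfg.activities
        if cfg.activities is not None
        else rng.uniform(0.0, 1.0, size=cfg.n_compounds)
    )
    link = cfg.activity_link or (lambda x: x)
    genes = list(cfg.genes)
    up = [g for g in signature.up_genes if g in set(genes)]
    down = [g for g in signature.down_genes if g in set(genes)]

    profiles: list[DrugProfile] = []
    truth_rows = []
    for i in range(cfg.n_compounds):
        cid = f"CPD{i:04d}"
        key = _random_inchikey(rng)
        truth_rows.append({"compound_id": cid, "inchikey": key, "activity": float(t[i])})
        for cell, dose, time in cfg.conditions:
            eff = float(np.clip(link(np.asarray(t[i]))[()], 0.0, 1.0))
            if dose < 10.0 or time < 24.0:
                eff *= cfg.sub_reference_factor
            p_shift = reversal_success_prob(eff, len(genes), cfg.rank_spread)
            ranks = _place_signature_ranks(
                genes, up, down, p_shift,
                rng.uniform(size=len(up)), rng.uniform(size=len(down)),
                rng.permutation(len(genes)),
            )
            profiles.append(DrugProfile(cid, key, cell, dose, time, ranks))
    return profiles, pd.DataFrame(truth_rows)


def write_drug_signatures(profiles: list[DrugProfile], path: str | Path) -> None:
    """Long-format TSV: compound, inchikey, cell_line, dose_um, time_h, gene, rank_value."""
    frames = []
    for p in profiles:
        frames.append(pd.DataFrame({
            "compound": p.compound_id,
            "inchikey": p.inchikey,
            "cell_line": p.cell_line,
            "dose_um": p.dose_um,
            "time_h": p.time_h,
            "gene": p.ranks.index,
            "rank_value": p.ranks.to_numpy(),
        }))
    write_tsv(pd.concat(frames, ignore_index=True), path)


def read_drug_signatures(path: str | Path) -> list[DrugProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"compound": str, "inchikey": str, "cell_line": str})
    profiles = []
    keys = ["compound", "inchikey", "cell_line", "dose_um", "time_h"]
    for (cid, key, cell, dose, time), grp in df.groupby(keys, sort=True):
        ranks = pd.Series(grp["rank_value"].to_numpy(int), index=grp["gene"].to_numpy())
        profiles.append(DrugProfile(cid, key, cell, float(dose), float(time), ranks))
    return profiles


# ---------------------------------------------------------------------------
# IC50 tables
# ---------------------------------------------------------------------------

def simulate_ic50(truth: pd.DataFrame, cfg: DrugSimConfig) -> pd.DataFrame:
    """IC50 rows per compound: log10(nM) linear-decreasing in activity.

    ``log10 IC50 = intercept - slope * activity + Normal(0, ic50_noise_sd)``.
    Compounds receive one to three assay rows so that the median/min/max
    summarisation is exercised.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    assay = 0
    for cid, key, t in truth[["compound_id", "inchikey", "activity"]].itertuples(index=False):
        n_rows = int(rng.integers(1, 4))
        logv = (
            cfg.ic50_intercept
            - cfg.ic50_slope * float(t)
            + rng.normal(0.0, cfg.ic50_noise_sd, size=n_rows)
        )
        for v in logv:
            rows.append({"inchikey": key, "ic50_nm": 10.0**v, "assay_id": f"ASSAY{assay:06d}"})
            assay += 1
    return pd.DataFrame(rows)
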