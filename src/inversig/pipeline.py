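"""End-to-end orchestration of the inverse-signal repositioning pipeline.

A single configuration drives the synthetic study: simulate the five input
classes, preprocess the report tables, compute disproportionality signals,
pick the target event, build the disease signature, score and summarise
drug reversal, and integrate (signal correlations, LOOCV reversal genes,
IC50 validation).  Each stage writes TSV outputs plus a JSON manifest
(parameters, input hashes, seed); deterministic stages are byte-identical
under a fixed master seed.  Per-stage seeds are derived from the master
seed by hashing ``"<seed>:<stage>"`` so stages can be rerun in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import aer, disproportionality as dsp, integration, reversal, signature as sigmod
from . import synthetic
from ._util import sha256_file, stage_seed, write_manifest, write_tsv

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "report", "demo_config", "full_config"]

STAGES = ("simulate", "preprocess", "signals", "target", "signature", "rges", "integrate")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """All thresholds, scales and paths for one pipeline run."""

    out_dir: str = "run"
    seed: int = 7
    stages: tuple[str, ...] = STAGES

    # report simulation
    n_compounds: int = 100
    n_events: int = 30
    n_reports: int = 300_000
    target_event: str = "Psoriasis"
    target_event_prob: float = 0.05
    duplicate_fraction: float = 0.1
    combo_fraction: float = 0.05
    inverse_lambda_decades: float = 1.0  # lambda = 10**(-decades * activity)

    # expression simulation
    n_genes: int = 978
    n_planted_up: int = 12
    n_planted_down: int = 8
    n_studies: int = 6
    n_case: int = 20
    n_control: int = 20
    effect_size_mean: float = 2.5
    study_noise_sd: float = 0.3

    # drug signature simulation
    conditions: tuple[tuple[str, float, float], ...] = (
        ("A375", 10.0, 24.0),
        ("A375", 1.0, 6.0),
        ("MCF7", 10.0, 24.0),
    )

    # thresholds
    alpha: float = 0.001
    up_cut: float = 1.5
    down_cut: float = -2.0
    core_cut: float = 2.5
    fdr_threshold: float = 0.25
    reference_dose: float = 10.0
    reference_time: float = 24.0
    w0: float = 0.5
    activity_method: str = "ror"

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.fdr_threshold < 1:
            raise ConfigError(f"fdr_threshold must be in (0, 1), got {self.fdr_threshold}")
        if self.up_cut <= 0 or self.down_cut >= 0:
            raise ConfigError("up_cut must be positive and down_cut negative")
        if self.reference_dose <= 0 or self.reference_time <= 0:
            raise ConfigError("reference dose/time must be positive")
        if min(self.n_compounds, self.n_events, self.n_reports, self.n_genes) <= 0:
            raise ConfigError("scales must be positive")
        if self.n_planted_up + self.n_planted_down > self.n_genes:
            raise ConfigError("more planted genes than the universe holds")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        if self.activity_method not in ("ror", "ic", "ebgm"):
            raise ConfigError(f"unknown activity method {self.activity_method}")


def demo_config(seed: int = 7, out_dir: str = "demo_run") -> PipelineConfig:
    """A small, fast configuration for the one-command synthetic demo."""
    return PipelineConfig(
        out_dir=out_dir, seed=seed,
        n_compounds=40, n_events=20, n_reports=60_000,
        n_genes=300, n_planted_up=8, n_planted_down=5,
        n_studies=3, n_case=10, n_control=10,
    )


def full_config(seed: int = 7, out_dir: str = "run") -> PipelineConfig:
    """The study-scale configuration (defaults of :class:`PipelineConfig`)."""
    return PipelineConfig(out_dir=out_dir, seed=seed)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _manifest(run_dir: Path, stage: str, cfg: PipelineConfig,
              inputs: dict[str, Path], outputs: dict[str, Path]) -> None:
    payload = {
        "stage": stage,
        "seed": cfg.seed,
        "stage_seed": stage_seed(cfg.seed, stage),
        "parameters": {k: v for k, v in asdict(cfg).items()
                       if k != "out_dir" and not isinstance(v, (list, dict))},
        "inputs": {k: sha256_file(p) for k, p in inputs.items()},
        "outputs": {k: str(Path(p).relative_to(run_dir)) for k, p in outputs.items()},
    }
    write_manifest(run_dir / f"manifest_{stage}.json", payload)


def _planted_signature(cfg: PipelineConfig) -> tuple[list[str], list[str], list[str]]:
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    up = genes[: cfg.n_planted_up]
    down = genes[cfg.n_planted_up : cfg.n_planted_up + cfg.n_planted_down]
    return genes, up, down


def stage_simulate(cfg: PipelineConfig, run_dir: Path) -> dict[str, Path]:
    """Generate every synthetic input class + truth tables."""
    sdir = run_dir / "inputs"
    sdir.mkdir(parents=True, exist_ok=True)
    seed = stage_seed(cfg.seed, "simulate")
    rng = np.random.default_rng(seed)

    # latent compound activities drive reports, drug signatures and IC50s
    activities = rng.uniform(0.0, 1.0, size=cfg.n_compounds)
    compounds = [f"CPD{i:04d}" for i in range(cfg.n_compounds)]

    # --- adverse-event reports ---------------------------------------------
    other_events = [f"EVENT{j:04d}" for j in range(cfg.n_events - 2)]
    events = [cfg.target_event, "Hypertension"] + other_events
    probs = np.empty(len(events))
    probs[0] = cfg.target_event_prob
    probs[1:] = (1.0 - cfg.target_event_prob) / (len(events) - 1)
    planted = [
        (c, cfg.target_event, float(10.0 ** (-cfg.inverse_lambda_decades * t)))
        for c, t in zip(compounds, activities)
    ]
    aer_cfg = synthetic.AerSimConfig(
        n_drugs=cfg.n_compounds, n_events=len(events), n_reports=cfg.n_reports,
        baseline_event_probs=probs, planted_associations=planted,
        duplicate_fraction=cfg.duplicate_fraction, combo_fraction=cfg.combo_fraction,
        seed=seed, drug_names=compounds, event_names=events,
    )
    sim = synthetic.simulate_reports(aer_cfg)
    paths = synthetic.write_faers(sim, sdir / "faers")

    # --- PT -> ICD-10 mapping ----------------------------------------------
    mapping = pd.DataFrame({
        "pt": [cfg.target_event, "Hypertension", "EVENT0000", "EVENT0001"],
        "icd10": ["L40", "I10", "R51", "A09"],
    })
    paths["mapping"] = sdir / "pt_icd10.tsv"
    write_tsv(mapping, paths["mapping"])

    # --- expression studies ------------------------------------------------
    genes, up, down = _planted_signature(cfg)
    expr_cfg = synthetic.ExprSimConfig(
        n_studies=cfg.n_studies, genes=genes, n_case=cfg.n_case, n_control=cfg.n_control,
        planted_up=up, planted_down=down, effect_size_mean=cfg.effect_size_mean,
        study_noise_sd=cfg.study_noise_sd, seed=stage_seed(cfg.seed, "expression"),
    )
    studies, expr_truth = synthetic.simulate_expression(expr_cfg)
    edir = sdir / "expression"
    edir.mkdir(exist_ok=True)
    for st in studies:
        write_tsv(st.matrix.reset_index(names="gene"), edir / f"{st.study_id}.tsv")
        write_tsv(
            pd.DataFrame({"sample": st.labels.index, "label": st.labels.to_numpy()}),
            edir / f"{st.study_id}_labels.tsv",
        )
    paths["expression_truth"] = sdir / "truth_genes.tsv"
    write_tsv(expr_truth, paths["expression_truth"])

    # --- drug signatures + IC50 --------------------------------------------
    planted_sig = sigmod.DiseaseSignature(tuple(up), tuple(down))
    drug_cfg = synthetic.DrugSimConfig(
        n_compounds=cfg.n_compounds, genes=genes, conditions=list(cfg.conditions),
        activities=activities, seed=stage_seed(cfg.seed, "drugsig"),
    )
    profiles, drug_truth = synthetic.simulate_drug_signatures(drug_cfg, planted_sig)
    paths["drug_signatures"] = sdir / "drug_signatures.tsv"
    synthetic.write_drug_signatures(profiles, paths["drug_signatures"])
    paths["drug_truth"] = sdir / "truth_compounds.tsv"
    write_tsv(drug_truth, paths["drug_truth"])
    ic50 = synthetic.simulate_ic50(drug_truth, drug_cfg)
    paths["ic50"] = sdir / "ic50.tsv"
    write_tsv(ic50, paths["ic50"])

    _manifest(run_dir, "simulate", cfg, {}, paths)
    return paths


def stage_preprocess(cfg: PipelineConfig, run_dir: Path) -> dict[str, Path]:
    """Read, deduplicate and filter the report tables; build 2x2 cells."""
    fdir = run_dir / "inputs" / "faers"
    reports = aer.read_reports(fdir / "DEMO.txt", fdir / "DRUG.txt", fdir / "REAC.txt")
    n_read = len(reports)
    reports = aer.deduplicate(reports)
    n_dedup = len(reports)
    reports, attrition = aer.filter_reports(reports)
    pairs = aer.pairs_from_reports(reports)
    cells = aer.build_contingency(pairs)
    out = {
        "pairs": run_dir / "pairs.tsv",
        "contingency": run_dir / "contingency.tsv",
    }
    write_tsv(pairs, out["pairs"])
    write_tsv(cells, out["contingency"])
    payload_inputs = {k: fdir / f"{k.upper()}.txt" for k in ("demo", "drug", "reac")}
    _manifest(run_dir, "preprocess", cfg, payload_inputs, out)
    write_manifest(run_dir / "attrition.json", {
        "n_report_versions": n_read, "n_after_dedup": n_dedup,
        "n_after_filters": len(reports), **attrition,
    })
    return out


def stage_signals(cfg: PipelineConfig, run_dir: Path) -> dict[str, Path]:
    """ROR / IC / EBGM with inverse flags for every cell."""
    cells = pd.read_csv(run_dir / "contingency.tsv", sep="\t")
    signals = dsp.flag_signals(cells, mgps_seed=stage_seed(cfg.seed, "signals"))
    out = {"signals": run_dir / "signals.tsv"}
    write_tsv(signals, out["signals"])
    _manifest(run_dir, "signals", cfg, {"contingency": run_dir / "contingency.tsv"}, out)
    return out


def stage_target(cfg: PipelineConfig, run_dir: Path) -> dict[str, Path]:
    """Map events to ICD-10 and rank them by inverse-drug count."""
    signals = pd.read_csv(run_dir / "signals.tsv", sep="\t")
    mapping = pd.read_csv(run_dir / "inputs" / "pt_icd10.tsv", sep="\t")
    table, _ = aer.map_events_to_icd10(signals["event"].unique(), mapping)
    ranking = aer.select_target_event(signals, table, method=cfg.activity_method)
    out = {
        "event_mapping": run_dir / "event_mapping.tsv",
        "target_ranking": run_dir / "target_ranking.tsv",
    }
    write_tsv(table, out["event_mapping"])
    write_tsv(ranking, out["target_ranking"])
    _manifest(run_dir, "target", cfg, {"signals": run_dir / "signals.tsv"}, out)
    return out


def stage_signature(cfg: PipelineConfig, run_dir: Path) -> dict[str, Path]:
    """Per-study moderated t + fixed-effect meta-analysis + DEG selection."""
    edir = run_dir / "inputs" / "expression"
    per_study = {}
    for mpath in sorted(edir.glob("GSE*.tsv")):
        if mpath.name.endswith("_labels.tsv"):
            continue
        sid = mpath.stem
        matrix = pd.read_csv(mpath, sep="\t", index_col="gene")
        lab = pd.read_csv(edir / f"{sid}_labels.tsv", sep="\t", index_col="sample")["label"]
        study = sigmod.normalize_study(sigmod.ExpressionStudy(sid, matrix, lab))
        per_study[sid] = sigmod.moderated_t(study)
    meta = sigmod.combine_fixed_effect(per_study)
    sig = sigmod.select_degs(meta, alpha=cfg.alpha, up_cut=cfg.up_cut, down_cut=cfg.down_cut)
    core = sigmod.select_degs(meta, alpha=cfg.alpha, up_cut=cfg.core_cut, down_cut=-cfg.core_cut)
    out = {
        "meta": run_dir / "meta_results.tsv",
        "signature": run_dir / "disease_signature.tsv",
        "core_signature": run_dir / "core_signature.tsv",
    }
    write_tsv(meta.reset_index(names="gene"), out["meta"])
    for key, s in (("signature", sig), ("core_signature", core)):
        write_tsv(
            pd.DataFrame({
                "gene": list(s.up_genes) + list(s.down_genes),
                "direction": ["up"] * len(s.up_genes) + ["down"] * len(s.down_genes),
            }),
            out[key],
        )
    _manifest(run_dir, "signature", cfg, {}, out)
    logger.info("disease signature: %d up / %d down genes", len(sig.up_genes), len(sig.down_genes))
    return out


def _load_signature(run_dir: Path) -> sigmod.DiseaseSignature:
    df = pd.read_csv(run_dir / "disease_signature.tsv", sep="\t")
    return sigmod.DiseaseSignature(
        tuple(df.loc[df["direction"] == "up", "gene"]),
        tuple(df.loc[df["direction"] == "down", "gene"]),
    )


def stage_rges(cfg: PipelineConfig, run_dir: Path) -> dict[str, Path]:
    """Per-profile RGES against the estimated signature + per-compound sRGES."""
    profiles = synthetic.read_drug_signatures(run_dir / "inputs" / "drug_signatures.tsv")
    sig = _load_signature(run_dir)
    table = reversal.rges_table(profiles, sig)
    srges, offsets = reversal.summarize_rges(
        table, reference_dose=cfg.reference_dose,
        reference_time=cfg.reference_time, w0=cfg.w0,
    )
    keys = {p.compound_id: p.inchikey for p in profiles}
    srges["inchikey"] = srges["compound_id"].map(keys)
    out = {"rges": run_dir / "rges.tsv", "srges": run_dir / "srges.tsv"}
    write_tsv(table, out["rges"])
    write_tsv(srges, out["srges"])
    _manifest(run_dir, "rges", cfg,
              {"drug_signatures": run_dir / "inputs" / "drug_signatures.tsv"}, out)
    write_manifest(run_dir / "condition_offsets.json", offsets)
    return out


def stage_integrate(cfg: PipelineConfig, run_dir: Path) -> dict[str, Path]:
    """Correlations with inverse signals, LOOCV reversal genes, IC50 checks."""
    srges = pd.read_csv(run_dir / "srges.tsv", sep="\t")
    signals = pd.read_csv(run_dir / "signals.tsv", sep="\t")
    target = signals[signals["event"] == cfg.target_event]
    activity = srges.merge(
        target[["drug", "ror_uci", "ic975", "ebgm95"]],
        left_on="compound_id", right_on="drug", how="left",
    )
    corr = integration.correlate_signals(activity)

    profiles = synthetic.read_drug_signatures(run_dir / "inputs" / "drug_signatures.tsv")
    ranks = integration.representative_ranks(
        profiles, reference_dose=cfg.reference_dose, reference_time=cfg.reference_time
    )
    act_col = {"ror": "ror_uci", "ic": "ic975", "ebgm": "ebgm95"}[cfg.activity_method]
    act = activity.set_index("compound_id")[act_col].dropna()
    calls = integration.loocv_reversal_genes(ranks, act, fdr_threshold=cfg.fdr_threshold)

    ic50 = pd.read_csv(run_dir / "inputs" / "ic50.tsv", sep="\t")
    ic50_corr, joined = integration.ic50_validate(srges, ic50)

    out = {
        "signal_correlations": run_dir / "signal_correlations.tsv",
        "reversal_genes": run_dir / "reversal_genes.tsv",
        "normalized_ranks": run_dir / "normalized_ranks.tsv",
        "ic50_correlations": run_dir / "ic50_correlations.tsv",
        "ic50_joined": run_dir / "ic50_joined.tsv",
    }
    write_tsv(corr, out["signal_correlations"])
    write_tsv(calls.table.reset_index(names="gene"), out["reversal_genes"])
    write_tsv(calls.normalized_ranks.reset_index(names="gene"), out["normalized_ranks"])
    write_tsv(ic50_corr, out["ic50_correlations"])
    write_tsv(joined.drop(columns=["key"]), out["ic50_joined"])
    _manifest(run_dir, "integrate", cfg,
              {"srges": run_dir / "srges.tsv", "signals": run_dir / "signals.tsv"}, out)
    return out


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "signals": stage_signals,
    "target": stage_target,
    "signature": stage_signature,
    "rges": stage_rges,
    "integrate": stage_integrate,
}


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the configured stages in dependency order.

    Halts on the first failing stage (its name is in the raised error);
    outputs of completed stages are retained.
    """
    cfg.validate()
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        logger.info("=== stage %s ===", stage)
        try:
            _STAGE_FUNCS[stage](cfg, run_dir)
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
    return run_dir


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed (or partial) run."""
    run_dir = Path(run_dir)
    lines = ["# Inverse-signal repositioning run summary", ""]

    def _maybe(path: Path):
        return pd.read_csv(path, sep="\t") if path.exists() else None

    signals = _maybe(run_dir / "signals.tsv")
    if signals is not None:
        lines.append("## Inverse signals")
        for m in ("ror", "ic", "ebgm"):
            col = f"inverse_{m}"
            if col in signals:
                lines.append(f"- {m.upper()}: {int(signals[col].sum())} inverse pairs "
                             f"of {len(signals)} cells")
    else:
        lines.append("WARNING: signals stage incomplete")

    ranking = _maybe(run_dir / "target_ranking.tsv")
    if ranking is not None and not ranking.empty:
        top = ranking.iloc[0]
        lines += ["", "## Target event",
                  f"- {top['event']} ({int(top['n_inverse_drugs'])} inversely associated drugs)"]

    sig = _maybe(run_dir / "disease_signature.tsv")
    if sig is not None:
        lines += ["", "## Disease signature",
                  f"- {int((sig['direction'] == 'up').sum())} up / "
                  f"{int((sig['direction'] == 'down').sum())} down genes"]

    srges = _maybe(run_dir / "srges.tsv")
    if srges is not None:
        lines += ["", "## Top compounds by sRGES (most reversing first)"]
        top20 = srges.sort_values("srges").head(20)
        for row in top20.itertuples(index=False):
            lines.append(f"- {row.compound_id}: sRGES {row.srges:+.3f} ({row.n_profiles} profiles)")

    calls = _maybe(run_dir / "reversal_genes.tsv")
    if calls is not None:
        sel = calls[calls["selected"]]
        lines += ["", "## Reversal genes (LOOCV)"]
        lines.append("- none selected" if sel.empty
                     else "- " + ", ".join(sorted(sel["gene"])))

    for name, path in (("Inverse-signal correlations", "signal_correlations.tsv"),
                       ("IC50 correlations", "ic50_correlations.tsv")):
        tab = _maybe(run_dir / path)
        if tab is not None:
            lines += ["", f"## {name}"]
            key = "method" if "method" in tab.columns else "statistic"
            for row in tab.itertuples(index=False):
                lines.append(f"- {getattr(row, key)}: rho = {row.rho:+.3f}, "
                             f"p = {row.p:.3g}, n = {int(row.n)}")
    incomplete = [s for s in STAGES
                  if not (run_dir / f"manifest_{s}.json").exists()]
    if incomplete:
        lines += ["", f"WARNING: stages without manifests: {', '.join(incomplete)}"]
    return "\n".join(lines) + "\n"
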