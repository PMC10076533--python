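"""Tests for the synthetic generators: determinism, planted truth, formats."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from inversig import aer
from inversig.signature import DiseaseSignature
from inversig.synthetic import (
    AerSimConfig,
    DrugSimConfig,
    ExprSimConfig,
    cell_probabilities,
    read_drug_signatures,
    reversal_success_prob,
    simulate_drug_signatures,
    simulate_expression,
    simulate_ic50,
    simulate_reports,
    truncated_geometric_icdf,
    write_drug_signatures,
    write_faers,
)


class TestConfigValidation:
    def test_bad_probability_vector(self):
        with pytest.raises(ValueError, match="probability vector"):
            AerSimConfig(2, 2, 10, baseline_event_probs=np.array([0.5, 0.6]))

    def test_nonpositive_lambda(self):
        with pytest.raises(ValueError, match="lambda"):
            AerSimConfig(2, 2, 10, planted_associations=[("DRUG0000", "EVENT0000", 0.0)])

    def test_fraction_ranges(self):
        with pytest.raises(ValueError, match="fractions"):
            AerSimConfig(2, 2, 10, duplicate_fraction=1.0)

    def test_overlapping_planted_gene_sets(self):
        with pytest.raises(ValueError, match="overlap"):
            ExprSimConfig(2, ["g1", "g2"], 3, 3, planted_up=["g1"], planted_down=["g1"])

    def test_empty_condition_list(self):
        with pytest.raises(ValueError, match="condition"):
            DrugSimConfig(3, ["g1"], conditions=[])

    def test_activities_out_of_range(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            DrugSimConfig(2, ["g1"], activities=np.array([0.5, 1.5]))


class TestSimulateReports:
    def test_fixed_seed_byte_identical(self):
        cfg = AerSimConfig(5, 4, 2000, duplicate_fraction=0.1, combo_fraction=0.1, seed=3)
        s1, s2 = simulate_reports(cfg), simulate_reports(cfg)
        for a, b in ((s1.demo, s2.demo), (s1.drug, s2.drug), (s1.reac, s2.reac)):
            pd.testing.assert_frame_equal(a, b)

    def test_truth_round_trip(self):
        planted = [("DRUG0000", "EVENT0001", 0.2), ("DRUG0002", "EVENT0000", 3.0)]
        cfg = AerSimConfig(4, 3, 500, planted_associations=planted, seed=1)
        sim = simulate_reports(cfg)
        assert len(sim.truth) == 2
        assert set(zip(sim.truth["drug"], sim.truth["event"], sim.truth["lam"])) == set(planted)

    def test_no_duplicates_means_dedup_removes_nothing(self):
        cfg = AerSimConfig(4, 3, 1000, duplicate_fraction=0.0, seed=2)
        sim = simulate_reports(cfg)
        assert sim.demo["CASEID"].is_unique

    def test_duplicate_fraction_produces_versions(self, tmp_path):
        cfg = AerSimConfig(6, 4, 5000, duplicate_fraction=0.2, seed=4)
        sim = simulate_reports(cfg)
        paths = write_faers(sim, tmp_path)
        reports = aer.read_reports(paths["demo"], paths["drug"], paths["reac"])
        deduped = aer.deduplicate(reports)
        assert len(reports) == 6000
        assert len(deduped) == sim.demo["CASEID"].nunique() == 5000
        # the retained version is always the later one
        assert all(r.primary_id.endswith("2") for r in deduped
                   if r.case_id in set(sim.demo["CASEID"][5000:]))

    def test_combo_fraction_within_binomial_bounds(self):
        n, frac = 10_000, 0.1
        cfg = AerSimConfig(6, 4, n, combo_fraction=frac, seed=5)
        sim = simulate_reports(cfg)
        n_combo = sim.drug["DRUGNAME"].str.contains("/").sum()
        sd = np.sqrt(n * frac * (1 - frac))
        assert abs(n_combo - n * frac) <= 3 * sd  # exact by construction, bound is generous

    def test_planted_inverse_lambda_recovered(self):
        # one planted pair with lambda = 0.1 at n = 200,000
        lam = 0.1
        cfg = AerSimConfig(
            10, 5, 200_000,
            planted_associations=[("DRUG0000", "EVENT0000", lam)], seed=6,
        )
        sim = simulate_reports(cfg)
        a = ((sim.drug["DRUGNAME"] == "DRUG0000")
             & (sim.reac["PT"] == "EVENT0000")).sum()
        expected_indep = 200_000 / (10 * 5)
        assert 0.07 <= a / expected_indep <= 0.13

    def test_cell_probabilities_scale_with_lambda(self):
        cfg = AerSimConfig(4, 4, 100,
                           planted_associations=[("DRUG0001", "EVENT0002", 0.5)])
        p = cell_probabilities(cfg)
        base = 1.0 / 16
        # ratio of planted to unplanted cell equals lambda exactly
        assert p.loc["DRUG0001", "EVENT0002"] / p.loc["DRUG0000", "EVENT0000"] == (
            pytest.approx(0.5)
        )

    def test_independence_null_centers_log_ror_at_zero(self):
        cfg = AerSimConfig(20, 12, 150_000, seed=8)
        sim = simulate_reports(cfg)
        pairs = pd.DataFrame({"drug": sim.drug["DRUGNAME"], "event": sim.reac["PT"]})
        counts = pairs.groupby(["drug", "event"]).size().rename("a").reset_index()
        cells = aer.build_contingency(counts)
        from inversig.disproportionality import compute_ror
        ror, _, _ = compute_ror(cells["a"], cells["b"], cells["c"], cells["d"])
        assert abs(np.nanmean(np.log(ror))) < 0.02


class TestSimulateExpression:
    def test_planted_effects_and_determinism(self):
        genes = [f"g{i}" for i in range(30)]
        cfg = ExprSimConfig(3, genes, 8, 8, planted_up=genes[:3],
                            planted_down=genes[3:5], effect_size_mean=2.0, seed=9)
        studies, truth = simulate_expression(cfg)
        studies2, _ = simulate_expression(cfg)
        assert len(studies) == 3
        pd.testing.assert_frame_equal(studies[0].matrix, studies2[0].matrix)
        t = truth.set_index("gene")
        assert (t.loc[genes[:3], "true_effect"] == 2.0).all()
        assert (t.loc[genes[3:5], "true_effect"] == -2.0).all()
        assert (t.loc[genes[5:], "true_effect"] == 0.0).all()
        # every planted gene appears exactly once in the truth table
        assert truth["gene"].is_unique

    def test_case_means_shifted_in_every_study(self):
        genes = [f"g{i}" for i in range(10)]
        cfg = ExprSimConfig(4, genes, 30, 30, planted_up=[genes[0]],
                            effect_size_mean=2.0, study_noise_sd=0.0, seed=10)
        studies, _ = simulate_expression(cfg)
        for st in studies:
            diff = (st.matrix.iloc[0, :30].mean() - st.matrix.iloc[0, 30:].mean())
            assert diff == pytest.approx(2.0, abs=0.8)  # n=30/arm, sd 1


class TestTruncatedGeometric:
    def test_zero_p_is_uniform(self):
        u = np.linspace(0.001, 0.999, 999)
        k = truncated_geometric_icdf(u, 0.0, 10)
        counts = np.bincount(k, minlength=10)
        assert counts.min() >= 95 and counts.max() <= 105

    def test_unit_p_is_degenerate(self):
        assert (truncated_geometric_icdf(np.random.uniform(size=50), 1.0, 10) == 0).all()

    def test_monotone_in_p_under_common_uniforms(self):
        u = np.random.default_rng(1).uniform(size=200)
        prev = truncated_geometric_icdf(u, 0.01, 100)
        for p in (0.05, 0.2, 0.5, 0.9):
            cur = truncated_geometric_icdf(u, p, 100)
            assert (cur <= prev).all()
            prev = cur

    def test_success_prob_endpoints(self):
        assert reversal_success_prob(0.0, 978) == 0.0
        assert reversal_success_prob(1.0, 978) == 1.0
        grid = [reversal_success_prob(t, 978) for t in np.linspace(0, 1, 21)]
        assert all(b > a for a, b in zip(grid, grid[1:]))


class TestSimulateDrugSignatures:
    SIG = DiseaseSignature(("g0", "g1", "g2"), ("g3", "g4"))
    GENES = [f"g{i}" for i in range(40)]

    def test_zero_activity_gives_unshifted_ranks(self):
        cfg = DrugSimConfig(300, self.GENES, activities=np.zeros(300), seed=11)
        profiles, _ = simulate_drug_signatures(cfg, self.SIG)
        mean_up = np.mean([p.ranks[list(self.SIG.up_genes)].mean() for p in profiles])
        assert mean_up == pytest.approx((40 + 1) / 2, abs=1.5)

    def test_full_activity_packs_extreme_blocks(self):
        cfg = DrugSimConfig(3, self.GENES, activities=np.ones(3), seed=12)
        profiles, _ = simulate_drug_signatures(cfg, self.SIG)
        for p in profiles:
            assert sorted(p.ranks[list(self.SIG.up_genes)]) == [38, 39, 40]
            assert sorted(p.ranks[list(self.SIG.down_genes)]) == [1, 2]

    def test_truth_and_determinism_and_inchikey_shape(self):
        cfg = DrugSimConfig(10, self.GENES, seed=13)
        p1, t1 = simulate_drug_signatures(cfg, self.SIG)
        p2, t2 = simulate_drug_signatures(cfg, self.SIG)
        pd.testing.assert_frame_equal(t1, t2)
        assert (p1[0].ranks == p2[0].ranks).all()
        assert t1["compound_id"].is_unique and len(t1) == 10
        assert t1["inchikey"].str.fullmatch(r"[A-Z]{14}-[A-Z]{10}-N").all()

    def test_round_trip_through_long_tsv(self, tmp_path):
        cfg = DrugSimConfig(4, self.GENES, seed=14,
                            conditions=[("A375", 10.0, 24.0), ("HA1E", 1.0, 6.0)])
        profiles, _ = simulate_drug_signatures(cfg, self.SIG)
        path = tmp_path / "sigs.tsv"
        write_drug_signatures(profiles, path)
        back = read_drug_signatures(path)
        assert len(back) == len(profiles) == 8
        orig = {(p.compound_id, p.cell_line, p.dose_um, p.time_h): p.ranks for p in profiles}
        for p in back:
            pd.testing.assert_series_equal(
                p.ranks.sort_index(),
                orig[(p.compound_id, p.cell_line, p.dose_um, p.time_h)].sort_index(),
                check_names=False, check_dtype=False,
            )

    def test_empty_signature_rejected(self):
        cfg = DrugSimConfig(2, self.GENES, seed=15)
        with pytest.raises(ValueError):
            simulate_drug_signatures(cfg, DiseaseSignature((), ()))


class TestSimulateIc50:
    def _truth(self, activities):
        return pd.DataFrame({
            "compound_id": [f"C{i}" for i in range(len(activities))],
            "inchikey": [f"{chr(65 + i) * 14}-{chr(65 + i) * 10}-N" for i in range(len(activities))],
            "activity": activities,
        })

    def test_noiseless_rank_correlation_is_minus_one(self):
        cfg = DrugSimConfig(20, ["g"], ic50_noise_sd=0.0, seed=16)
        truth = self._truth(np.linspace(0.01, 0.99, 20))
        ic50 = simulate_ic50(truth, cfg)
        med = ic50.groupby("inchikey")["ic50_nm"].median()
        merged = truth.set_index("inchikey").join(med)
        rho = stats.spearmanr(merged["activity"], merged["ic50_nm"]).statistic
        assert rho == pytest.approx(-1.0)

    def test_multiple_assay_rows_present(self):
        cfg = DrugSimConfig(50, ["g"], seed=17)
        ic50 = simulate_ic50(self._truth(np.linspace(0, 1, 50)), cfg)
        sizes = ic50.groupby("inchikey").size()
        assert sizes.max() > 1
        assert ic50["assay_id"].is_unique
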