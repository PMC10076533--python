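"""Tests for report ingestion, dedup/filter rules and contingency building."""

import itertools

import numpy as np
import pandas as pd
import pytest

from inversig import aer
from conftest import make_report


class TestReadReports:
    def test_three_row_fixture(self, faers_files):
        reports = aer.read_reports(
            faers_files["demo"], faers_files["drug"], faers_files["reac"]
        )
        assert len(reports) == 3
        assert {r.drug_name for r in reports} == {"ASPIRIN", "IBUPROFEN", "NAPROXEN"}
        assert all(r.role_code == "PS" for r in reports)

    def test_missing_column_is_hard_error(self, faers_files, tmp_path):
        bad = tmp_path / "DEMO_bad.txt"
        pd.DataFrame({"PRIMARYID": ["1"], "CASEID": ["1"]}).to_csv(bad, sep="$", index=False)
        with pytest.raises(ValueError, match="EVENT_DT"):
            aer.read_reports(bad, faers_files["drug"], faers_files["reac"])

    def test_empty_drugname_row_skipped(self, faers_files, tmp_path):
        drug = pd.read_csv(faers_files["drug"], sep="$", dtype=str)
        drug.loc[0, "DRUGNAME"] = " "
        p = tmp_path / "DRUG2.txt"
        drug.to_csv(p, sep="$", index=False)
        reports = aer.read_reports(faers_files["demo"], p, faers_files["reac"])
        assert len(reports) == 2

    def test_duplicate_primaryid_rejected(self, faers_files, tmp_path):
        demo = pd.read_csv(faers_files["demo"], sep="$", dtype=str)
        demo.loc[1, "PRIMARYID"] = demo.loc[0, "PRIMARYID"]
        demo.loc[1, "CASEID"] = demo.loc[0, "CASEID"]
        p = tmp_path / "DEMO2.txt"
        demo.to_csv(p, sep="$", index=False)
        with pytest.raises(ValueError, match="PRIMARYID"):
            aer.read_reports(p, faers_files["drug"], faers_files["reac"])


class TestDeduplicate:
    def test_most_recent_date_kept(self):
        old = make_report(primary_id="421", case_id="42", event_date="20190101")
        new = make_report(primary_id="422", case_id="42", event_date="20200101")
        kept = aer.deduplicate([old, new])
        assert kept == [new]

    def test_same_date_higher_version_kept(self):
        v100 = make_report(primary_id="100", case_id="42", event_date="20200101")
        v101 = make_report(primary_id="101", case_id="42", event_date="20200101")
        assert aer.deduplicate([v100, v101]) == [v101]

    def test_idempotent_and_sorted(self):
        reports = [make_report(primary_id=str(i), case_id=str(i % 3)) for i in range(9)]
        once = aer.deduplicate(reports)
        assert aer.deduplicate(once) == once
        assert [r.case_id for r in once] == sorted(r.case_id for r in once)


class TestFilters:
    def test_excluded_pt_only_report_dropped(self):
        r = make_report(pts=("Drug ineffective",))
        kept, log = aer.filter_reports([r])
        assert kept == [] and log["excluded_pt_only"] == 1

    def test_excluded_pt_removed_but_report_kept(self):
        r = make_report(pts=("Drug ineffective", "Rash"))
        kept, _ = aer.filter_reports([r])
        assert len(kept) == 1 and kept[0].pt_terms == ("Rash",)

    def test_combination_drug_dropped(self):
        r = make_report(drug="AMOXICILLIN\\CLAVULANATE")
        kept, log = aer.filter_reports([r])
        assert kept == [] and log["combination_drug"] == 1

    def test_non_primary_suspect_dropped(self):
        r = make_report(role="C")
        kept, log = aer.filter_reports([r])
        assert kept == [] and log["not_primary_suspect"] == 1

    @pytest.mark.parametrize("name,combo", [
        ("ASPIRIN", False),
        ("ASPIRIN/CAFFEINE", True),
        ("LOPERAMIDE + SIMETHICONE", True),
        ("HYDROCODONE AND ACETAMINOPHEN", True),
        ("ASPIRIN 100 MG", False),
    ])
    def test_combination_detection(self, name, combo):
        assert aer.is_combination_drug(name) is combo

    def test_drug_name_normalization(self):
        assert aer.normalize_drug_name("  aspirin   500 mg ") == "ASPIRIN"
        assert aer.normalize_drug_name("Tylenol\t Extra") == "TYLENOL EXTRA"

    def test_filters_commute(self):
        reports = [
            make_report(primary_id="1", case_id="1", role="C"),
            make_report(primary_id="2", case_id="2", drug="A/B"),
            make_report(primary_id="3", case_id="3", pts=("Medication error",)),
            make_report(primary_id="4", case_id="4"),
        ]
        kept, _ = aer.filter_reports(reports)
        # filters touch disjoint fields: any subset order yields the same set
        for perm in itertools.permutations(reports):
            kept_perm, _ = aer.filter_reports(list(perm))
            assert {r.primary_id for r in kept_perm} == {r.primary_id for r in kept}
        assert [r.primary_id for r in kept] == ["4"]


class TestContingency:
    def test_direct_construction(self):
        pairs = pd.DataFrame({
            "drug": ["D1", "D1", "D2", "D2"],
            "event": ["E1", "E2", "E1", "E2"],
            "a": [10, 90, 100, 900],
        })
        cells = aer.build_contingency(pairs).set_index(["drug", "event"])
        row = cells.loc[("D1", "E1")]
        assert (row["a"], row["b"], row["c"], row["d"]) == (10, 90, 100, 900)
        assert row["n"] == 1100

    def test_single_pair_degenerate(self):
        pairs = pd.DataFrame({"drug": ["D"], "event": ["E"], "a": [7]})
        cells = aer.build_contingency(pairs)
        assert (cells.loc[0, ["a", "b", "c", "d"]] == [7, 0, 0, 0]).all()

    def test_expected_matches_closed_form(self, rng):
        drugs = [f"D{i}" for i in range(8)]
        events = [f"E{j}" for j in range(5)]
        pairs = pd.DataFrame(
            [(d, e, int(rng.integers(0, 50))) for d in drugs for e in events],
            columns=["drug", "event", "a"],
        )
        pairs = pairs[pairs["a"] > 0]
        cells = aer.build_contingency(pairs)
        expect = (cells["a"] + cells["b"]) * (cells["a"] + cells["c"]) / cells["n"]
        assert np.allclose(cells["expected"], expect, atol=1e-9)
        # conservation: the a-cells sum to the total retained pair count
        assert cells["a"].sum() == pairs["a"].sum()

    def test_empty_pairs_error(self):
        with pytest.raises(ValueError):
            aer.build_contingency(pd.DataFrame(columns=["drug", "event", "a"]))


class TestIcd10Mapping:
    MAPPING = pd.DataFrame({
        "pt": ["Psoriasis", "Headache", "Cholera"],
        "icd10": ["L40", "R51", "A00"],
    })

    def test_chapter_rules(self):
        table, unmapped = aer.map_events_to_icd10(
            ["Psoriasis", "Headache", "Cholera", "Unknownia"], self.MAPPING
        )
        t = table.set_index("event")
        assert t.loc["Psoriasis", "icd10"] == "L40" and not t.loc["Psoriasis", "excluded"]
        assert t.loc["Headache", "excluded"]  # chapter R
        assert t.loc["Cholera", "excluded"]  # chapter A
        assert unmapped == ["Unknownia"]

    def test_coverage_fraction(self):
        mapping = pd.DataFrame({
            "pt": [f"PT{i}" for i in range(100, 105)],
            "icd10": ["L40", "L41", "L42", "L43", "L44"],
        })
        events = [f"PT{i}" for i in range(100, 150)]  # 50 events, 5 mapped
        table, _ = aer.map_events_to_icd10(events, mapping)
        assert table["mapped"].mean() == pytest.approx(0.10)

    def test_conflicting_mapping_rows_rejected(self):
        bad = pd.DataFrame({"pt": ["Psoriasis", "Psoriasis"], "icd10": ["L40", "L41"]})
        with pytest.raises(ValueError, match="conflicting"):
            aer.map_events_to_icd10(["Psoriasis"], bad)


class TestSelectTargetEvent:
    def _signals(self, counts: dict[str, int]) -> pd.DataFrame:
        rows = []
        for event, k in counts.items():
            for i in range(k):
                rows.append({"drug": f"D{i}", "event": event, "inverse_ror": True})
            rows.append({"drug": "D_none", "event": event, "inverse_ror": False})
        return pd.DataFrame(rows)

    def _mapping(self, events):
        return pd.DataFrame({"event": events, "icd10": "L40",
                             "mapped": True, "excluded": False})

    def test_highest_count_first(self):
        signals = self._signals({"X": 5, "Y": 2})
        out = aer.select_target_event(signals, self._mapping(["X", "Y"]))
        assert list(out["event"]) == ["X", "Y"]
        assert list(out["n_inverse_drugs"]) == [5, 2]

    def test_tie_broken_alphabetically(self):
        signals = self._signals({"Beta": 3, "Alpha": 3})
        out = aer.select_target_event(signals, self._mapping(["Alpha", "Beta"]))
        assert list(out["event"]) == ["Alpha", "Beta"]

    def test_synonym_grouping(self):
        signals = pd.DataFrame({
            "drug": ["D1", "D2", "D3"],
            "event": ["Psoriasis", "Pustular psoriasis", "Other"],
            "inverse_ror": [True, True, True],
        })
        mapping = self._mapping(["Psoriasis", "Pustular psoriasis", "Other"])
        out = aer.select_target_event(
            signals, mapping, synonyms={"Pustular psoriasis": "Psoriasis"}
        )
        assert out.loc[0, "event"] == "Psoriasis"
        assert out.loc[0, "n_inverse_drugs"] == 2

    def test_no_flagged_pairs_gives_empty_table(self):
        signals = pd.DataFrame({"drug": ["D1"], "event": ["X"], "inverse_ror": [False]})
        out = aer.select_target_event(signals, self._mapping(["X"]))
        assert out.empty
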