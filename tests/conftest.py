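import numpy as np
import pandas as pd
import pytest

from inversig.aer import CaseReport


def make_report(primary_id="1001", case_id="100", event_date="20190101",
                drug="DRUGA", role="PS", pts=("Rash",)):
    return CaseReport(primary_id, case_id, event_date, drug, role, tuple(pts))


@pytest.fixture
def faers_files(tmp_path):
    """Write a tiny 3-report DEMO/DRUG/REAC fixture; returns the three paths."""
    demo = pd.DataFrame({
        "PRIMARYID": ["10011", "10021", "10031"],
        "CASEID": ["1001", "1002", "1003"],
        "EVENT_DT": ["20180105", "20190212", "20200330"],
    })
    drug = pd.DataFrame({
        "PRIMARYID": ["10011", "10021", "10031"],
        "CASEID": ["1001", "1002", "1003"],
        "ROLE_COD": ["PS", "PS", "PS"],
        "DRUGNAME": ["ASPIRIN", "IBUPROFEN", "NAPROXEN"],
    })
    reac = pd.DataFrame({
        "PRIMARYID": ["10011", "10021", "10031"],
        "CASEID": ["1001", "1002", "1003"],
        "PT": ["Rash", "Nausea", "Psoriasis"],
    })
    paths = {}
    for name, df in (("DEMO", demo), ("DRUG", drug), ("REAC", reac)):
        p = tmp_path / f"{name}.txt"
        df.to_csv(p, sep="$", index=False)
        paths[name.lower()] = p
    return paths


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
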