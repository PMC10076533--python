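"""Preprocess the report tables and compute inverse disproportionality signals.

Deduplicates case versions, applies the primary-suspect / excluded-PT /
combination-drug filters, builds per-pair 2x2 cells, computes ROR, IC and
EBGM with interval bounds, flags inverse signals, and ranks ICD-10-mapped
events by their number of inversely associated drugs.
"""

import json

import pandas as pd

from _config import RUN_DIR, config
from inversig import pipeline

cfg = config()
cfg.stages = ("preprocess", "signals", "target")
pipeline.run_pipeline(cfg)

att = json.loads((RUN_DIR / "attrition.json").read_text())
print(f"report versions: {att['n_report_versions']}, after dedup: {att['n_after_dedup']}, "
      f"after filters: {att['n_after_filters']}")
signals = pd.read_csv(RUN_DIR / "signals.tsv", sep="\t")
for m in ("ror", "ic", "ebgm"):
    print(f"inverse signals by {m.upper()}: {int(signals[f'inverse_{m}'].sum())} "
          f"of {len(signals)} cells")
ranking = pd.read_csv(RUN_DIR / "target_ranking.tsv", sep="\t")
print("target event ranking:")
print(ranking.to_string(index=False))
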