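"""Score drug signatures against the disease signature (RGES and sRGES).

Each compound x condition rank profile gets a reverse gene-expression score;
per-compound summaries are anchored to the 10 uM / 24 h reference condition
with additive offset correction for off-reference dose/time classes.
"""

import json

import pandas as pd

from _config import RUN_DIR, config
from inversig import pipeline

cfg = config()
cfg.stages = ("rges",)
pipeline.run_pipeline(cfg)

rges = pd.read_csv(RUN_DIR / "rges.tsv", sep="\t")
srges = pd.read_csv(RUN_DIR / "srges.tsv", sep="\t")
offsets = json.loads((RUN_DIR / "condition_offsets.json").read_text())
print(f"{len(rges)} profiles scored, {len(srges)} compounds summarised")
print("condition-class offsets vs reference:",
      {k: round(v, 3) for k, v in offsets.items()})
top = srges.sort_values("srges").head(10)
print("top 10 reversing compounds:")
print(top[["compound_id", "srges", "n_profiles"]].to_string(index=False))
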