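"""Generate the synthetic study inputs with known ground truth.

Emits FAERS-dialect report tables with planted inverse associations for the
target event, six expression studies with 12 up / 8 down planted genes,
LINCS-like drug rank signatures whose reversal strength is monotone in each
compound's latent activity, matching IC50 tables, and a PT->ICD-10 map.
"""

import pandas as pd

from _config import RUN_DIR, config
from inversig import pipeline

cfg = config()
cfg.stages = ("simulate",)
pipeline.run_pipeline(cfg)

truth = pd.read_csv(RUN_DIR / "inputs" / "truth_compounds.tsv", sep="\t")
genes = pd.read_csv(RUN_DIR / "inputs" / "truth_genes.tsv", sep="\t")
print(f"simulated {len(truth)} compounds (latent activity "
      f"{truth['activity'].min():.2f}-{truth['activity'].max():.2f})")
print(f"planted genes: {(genes['planted'] == 'up').sum()} up / "
      f"{(genes['planted'] == 'down').sum()} down of {len(genes)}")
print(f"inputs under {RUN_DIR / 'inputs'}")
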