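"""Build the disease signature by moderated-t fixed-effect meta-analysis.

Per study, gene-wise case/control differences are tested with
empirical-Bayes-moderated t statistics; effects are pooled by inverse
variance across the six studies and genes passing adjusted p < 0.001 with
log2 fold change > 1.5 (up) or < -2.0 (down) enter the signature.
"""

import pandas as pd

from _config import RUN_DIR, config
from inversig import pipeline

cfg = config()
cfg.stages = ("signature",)
pipeline.run_pipeline(cfg)

sig = pd.read_csv(RUN_DIR / "disease_signature.tsv", sep="\t")
truth = pd.read_csv(RUN_DIR / "inputs" / "truth_genes.tsv", sep="\t")
planted = set(truth.loc[truth["planted"].isin(["up", "down"]), "gene"])
found = set(sig["gene"])
print(f"signature: {(sig['direction'] == 'up').sum()} up / "
      f"{(sig['direction'] == 'down').sum()} down genes")
print(f"planted-gene recovery: {len(found & planted)}/{len(planted)}; "
      f"false calls: {len(found - planted)}")
core = pd.read_csv(RUN_DIR / "core_signature.tsv", sep="\t")
print(f"core signature at |log2fc| > 2.5: {len(core)} genes")
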