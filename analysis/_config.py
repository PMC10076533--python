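"""Shared configuration for the numbered analysis scripts.

One study-scale synthetic run under results/study: 100 compounds, a 978-gene
universe with 20 planted disease genes, 6 expression studies of 20+20, and
300k adverse-event reports with planted inverse associations.
"""

from pathlib import Path

from inversig import pipeline

SEED = 7
RUN_DIR = Path(__file__).resolve().parent.parent / "results" / "study"


def config() -> pipeline.PipelineConfig:
    return pipeline.full_config(seed=SEED, out_dir=str(RUN_DIR))
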