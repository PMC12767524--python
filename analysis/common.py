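"""Shared configuration for the numbered analysis drivers.

All drivers use one seeded configuration at the default study conditions
(100 promoters per class, 10^4 reads per factor, 2 bp footprint peaks,
1 bp CAGE kernel) and write under results/pipeline; run them in order
(01 first) since later stages consume the simulated artifacts.
"""

from pathlib import Path

from nexuskit.pipeline import PipelineConfig
from nexuskit.synthetic import SyntheticConfig

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"


def default_config() -> PipelineConfig:
    cfg = PipelineConfig(outdir=RESULTS / "pipeline", seed=SEED)
    cfg.synthetic = SyntheticConfig(seed=SEED)
    return cfg
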