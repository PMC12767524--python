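#!/usr/bin/env python
"""Transcription-normalized occupancy and binding-level correlation.

Divides each factor's promoter signal ([-50, +50] window sum) by the
promoter's CAGE score, compares the normalized distributions between
promoter types with rank-sum tests, and clusters factors by Pearson
correlation of log2(x+1) binding levels (Ward linkage on 1-r).
"""

import pandas as pd

from common import default_config
from nexuskit.pipeline import run_pipeline


def main() -> None:
    cfg = default_config()
    run_pipeline(cfg, stages=("occupancy",))
    d = cfg.outdir / "occupancy"
    tests = pd.read_csv(d / "type_comparisons.tsv", sep="\t")
    print("between-type rank-sum tests on normalized occupancy:")
    print(tests.to_string(index=False))
    corr = pd.read_csv(d / "binding_correlation.tsv", sep="\t", index_col=0)
    print("\nbinding-level Pearson correlations (log2(x+1)):")
    print(corr.round(3).to_string())
    print("\ndendrogram:", (d / "binding_dendrogram.nwk").read_text().strip())


if __name__ == "__main__":
    main()
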