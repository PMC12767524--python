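#!/usr/bin/env python
"""Build RPM-normalized stop-base coverage and TSS-anchored average profiles.

Reads the simulated bedGraph pairs, normalizes each factor to reads per
million, extracts promoter x offset profile matrices in transcription
sense, and writes the per-factor average stranded profiles.
"""

import pandas as pd

from common import default_config
from nexuskit.pipeline import run_pipeline


def main() -> None:
    cfg = default_config()
    run_pipeline(cfg, stages=("coverage",))
    for factor in cfg.factors:
        prof = pd.read_csv(
            cfg.outdir / "coverage" / f"{factor}_average_profile.tsv", sep="\t"
        )
        peak = prof.loc[prof["positive_strand"].idxmax()]
        print(
            f"{factor}: strongest positive-strand stop base at offset "
            f"{int(peak['offset'])} ({peak['positive_strand']:.2f} RPM/promoter)"
        )


if __name__ == "__main__":
    main()
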