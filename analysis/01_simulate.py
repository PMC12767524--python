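#!/usr/bin/env python
"""Generate the synthetic study data with planted ground truth.

Writes promoter contigs (FASTA), TSS annotations (BED6), stranded
stop-base footprints per factor (bedGraph pairs), replicated CAGE tag
counts (CTSS TSV), a Pol II decay time course, and the truth table that
downstream drivers score against.
"""

import pandas as pd

from common import default_config
from nexuskit.pipeline import run_pipeline


def main() -> None:
    cfg = default_config()
    run_pipeline(cfg, stages=("simulate",))
    truth = pd.read_csv(cfg.outdir / "simulate" / "truth.tsv", sep="\t")
    print(f"simulated {len(truth)} promoters "
          f"({truth['class_label'].value_counts().to_dict()})")
    print(f"strand balance: {truth['strand'].value_counts().to_dict()}")
    print(f"outputs under {cfg.outdir / 'simulate'}")


if __name__ == "__main__":
    main()
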