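#!/usr/bin/env python
"""Type promoters from their core promoter elements and score the recovery.

Scans each sense-oriented promoter for the canonical elements (TATA with
up to one mismatch, all others exact) inside their TSS-relative windows,
applies the TATA/DPR/TCT/HK rules, compares against the planted classes,
and builds position probability matrices for the upstream, initiator and
downstream regions of each class.
"""

import json

import pandas as pd

from common import default_config
from nexuskit.pipeline import run_pipeline


def main() -> None:
    cfg = default_config()
    run_pipeline(cfg, stages=("classify",))
    d = cfg.outdir / "classify"
    report = json.loads((d / "concordance.json").read_text())
    print(f"planted-class recovery: {100 * report['concordance']:.1f}% "
          f"of {report['n']} promoters")
    classes = pd.read_csv(d / "promoter_classes.tsv", sep="\t")
    print(classes.groupby(["true_class", "exclusive_label"]).size())
    pwms = pd.read_csv(d / "pwms.tsv", sep="\t")
    ic = pwms.groupby("pwm")["ic_bits"].max().sort_values(ascending=False)
    print("\nmost informative PWM positions per class/region (bits):")
    print(ic.head(6).to_string())


if __name__ == "__main__":
    main()
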