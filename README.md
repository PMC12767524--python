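# nexuskit

Base-resolution analysis of ChIP-nexus/ChIP-exo footprints at promoters,
for regulatory genomicists studying how general transcription factors
(TFIID, TBP, Pol II and friends) engage different core promoter types.

ChIP-nexus digests formaldehyde-crosslinked chromatin with a 5'→3'
exonuclease until it hits a protein–DNA crosslink, so the 5'-most aligned
base of each read — the *stop base* — marks a contact at single-base,
strand-specific resolution.  A crosslink leaves a positive-strand peak
upstream and a negative-strand peak downstream; the contact position is
the midpoint of the pair.  `nexuskit` implements the full analysis chain
around this signal:

- **coverage** — stop-base coverage from deduplicated reads, RPM scaling,
  replicate pooling, and TSS-anchored stranded profile matrices (minus
  promoters flipped into transcription sense);
- **cage** — CAGE-based TSS annotation: power-law normalization onto a
  referent law (α = 1.19, T = 10⁶, fit over 3–40,000 counts),
  distance-based tag clustering (30 bp), 10th/90th-percentile cluster
  boundaries, cross-replicate consensus clusters with a dominant TSS, and
  narrow-promoter selection (interquantile width < 11 bp);
- **elements** — IUPAC consensus scanning in TSS-relative windows (TATA
  box with ≤ 1 mismatch, all other elements exact) and rule-based
  TATA/DPR/TCT/HK promoter typing, plus position weight matrices with
  information content 2 + Σ p·log₂p bits;
- **footprints** — contact-midpoint detection from paired strand peaks
  and PCA (centered, unscaled) + k-means grouping of factor profiles into
  binding modules;
- **clustering** — per-promoter TBP-profile shape clustering: top-90%
  signal selection in the 81 bp TSS window, per-row rank transform,
  k-means (k = 4, 100 starts, ≤ 30 iterations), and per-cluster
  core-promoter-element enrichment (two-sided Fisher exact,
  Benjamini–Hochberg corrected);
- **occupancy** — transcription-normalized occupancy (window signal /
  CAGE score), Wilcoxon rank-sum comparisons between promoter types,
  Pearson correlation of log2(x+1) binding levels with Ward clustering,
  and control-vs-treated ΔPCC for upstream/downstream TBP;
- **pausing** — paused-promoter selection (average signal > 20,
  strand-peak distance < 80 bp, pause position < +80 bp), exponential
  decay fits s(t) = s₀·2^(−t/h) with a 60 min floor, and quintile
  binning;
- **synthetic** — a first-class generator of promoter sequences with
  planted elements, stranded footprints with known contact positions,
  replicated CAGE tags with controllable initiation-window width, and
  Pol II decay time courses — so every stage is tested against planted
  ground truth.

## Worked example

The numbered drivers under `analysis/` run the pipeline on synthetic data
(seed 1; 400 promoters, 100 per class) and score recovery of the planted
truth.  Run them in order from `analysis/`:

```bash
cd analysis
python 01_simulate.py
python 04_footprint_modules.py
python 06_tbp_clusters.py
```

`01_simulate.py` reports the study conditions:

```
simulated 400 promoters ({'TATA': 100, 'DPR': 100, 'TCT': 100, 'HK': 100})
strand balance: {'-': 202, '+': 198}
```

`04_footprint_modules.py` detects the DNA contacts of the generic TFIID
subunit from the averaged stranded profile — all five planted contacts
are recovered exactly:

```
detected contact midpoints: [-30, -18, 10, 19, 32]
planted contact midpoints: [-30, -18, 10, 19, 32]
```

`06_tbp_clusters.py` clusters promoters by rank-transformed TBP footprint
shape and recovers the planted promoter types perfectly, with each
cluster enriched for its class-defining elements:

```
cluster composition (rows: k-means cluster, cols: planted class):
class_label  DPR   HK  TATA  TCT
cluster
1            100    0     0    0
2              0    0   100    0
3              0  100     0    0
4              0    0     0   60

elements enriched at q < 0.05:
 cluster element  ratio            q
       1     INR  130.0 9.245229e-87
       1     DPE    inf 6.652118e-35
       ...
       2    TATA    inf 3.589683e-90
       4     TCT    inf 8.524877e-69
```

(Cluster 4 holds 60 of the 100 TCT promoters because the low-signal TCT
archetype loses most of the bottom-decile cut before clustering.)  The
same stages are available as a console command — `nexuskit all --seed 1
--outdir out/` — or individually (`nexuskit simulate`, `nexuskit tss`,
…), with YAML config override and JSON provenance records per stage.

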