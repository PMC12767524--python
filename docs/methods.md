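# Methods

`nexuskit` re-implements, as a tested pipeline, the base-resolution
analysis of ChIP-nexus footprints at promoters: stop-base coverage, CAGE
TSS annotation, footprint-midpoint detection, core-promoter-element
classification, TBP-profile clustering with element enrichment,
transcription-normalized occupancy statistics, and paused Pol II
half-life kinetics.  Because the real measurements require deposited
sequencing data, every stage is exercised on synthetic data with planted
ground truth; this note records the models, the parameters that matter,
and the design choices made where the procedure description left them
open.

## Stop-base coverage and profiles

ChIP-nexus digests crosslinked chromatin with a 5'→3' exonuclease, so the
5'-most aligned base of each read (the "stop base") marks the exonuclease
arrest point adjacent to a protein-DNA crosslink.  Coverage is built by
counting one stop base per deduplicated read, per strand: `start` for +
reads, `end − 1` for − reads.  The negative-strand convention is not
forced by the file formats; it is chosen to match the λ-exonuclease
geometry (the 5' end of a − read is its highest coordinate).
Deduplication keys on (chrom, start, end, strand, fixed barcode, random
barcode) — the stricter reading that treats the fixed ligation barcode as
part of the molecular identity.

Replicates are scaled to reads per million (grand total 10⁶ over both
strands) before pooling by per-position arithmetic mean, with missing
positions treated as zero rather than missing.  Profile matrices anchor
each promoter at its dominant TSS (offset 0) with an inclusive symmetric
window; wherever a "100 bp" or "101 bp" window is needed the symmetric
[−50, +50] window (101 positions) is used.  Minus-strand promoters are
mirrored (offset o reads genomic TSS − o) with the strand planes swapped,
so "sense-positive" always means the transcribed-strand-upstream
footprint.  Coordinates are 0-based half-open throughout.

## CAGE TSS annotation

Raw CTSS counts are normalized onto a referent power law with slope
α = 1.19 and total T = 10⁶, fitted by least squares to the log-log
reverse-cumulative count distribution over the range 3–40,000 counts.
The referent reverse cumulative is N_ref(x) = T(α−1)·x^(−α), whose
integral total is T; each raw count maps to the count occupying the same
reverse-cumulative rank under the referent.  The mapping is monotone
(rank-preserving) and is the identity, up to fit noise, for data already
on the referent law.

Per-strand positions cluster by distance (gap ≤ 30 bp joins).  Each
cluster's central activity region spans the positions where cumulative
signal crosses the 10th and 90th percentiles of the cluster total; widths
are inclusive (end − start + 1), so the "narrow promoter" cutoff
width < 11 excludes an 11-position spread.  Tag clusters reaching
TPM ≥ 0.5 in at least one replicate merge across replicates when their
central regions fall within 100 bp; the consensus span is the union of
central regions, quantiles are recomputed on the summed replicate signal,
and the dominant TSS is the position of maximum summed signal (5'-most
base on ties).  Narrow-promoter selection keeps interquantile width
< 11 bp, requires TPM ≥ 3 for single-position clusters, and retains only
the highest-TPM cluster per gene; genes are assigned by the nearest
same-strand annotated TSS within 500 bp.

## Footprint midpoints and profile modules

A DNA contact produces a positive-strand stop-base peak upstream and a
negative-strand peak downstream of the crosslink; the contact position is
the midpoint of the pair.  Candidate peaks are local maxima at least 20%
of the strand maximum and ≥ 3 bp apart; each positive peak pairs with the
nearest unused negative peak strictly downstream within 40 bp, ties going
to the higher negative peak.  These three thresholds are not part of the
published procedure — they are exposed as parameters, and midpoint
detection is checked to be translation-equivariant and scale-invariant.

For module assignment, each factor's concatenated (positive ‖ negative)
average profile is min–max normalized (constant profiles map to zeros
with a warning) and decomposed by PCA (centered, not variance-scaled).
Because the original grouping of profiles into four modules appears
visual, module labels here come from seeded k-means on the first two PC
coordinates; only the partition, not the label values, is meaningful.

## Promoter classification

Elements are scanned as IUPAC consensi inside TSS-relative windows
(TATA STATAWAWR in [−40, −20], Inr TCAKTY in [−5, 5], DPE GGWYV in
[25, 35], MTE CSARCSSA in [10, 30], PB KCGRWCG in [20, 50], DRE WATCGATW
in [−70, −10], Ohler1/6/7 and TCT in their windows), with up to one
mismatch for the TATA box and exact matches otherwise; enrichment-mode
scanning uses exact matches for every element including TATA.  A window
bounds the motif *start* offset (the laxer reading of the window
semantics; full containment is configurable).  Type rules: TATA and TCT
promoters only require their element; DPR promoters need ≥ 1 of
MTE/DPE/PB and none of TATA, TCT, Ohler1/6/7, DRE; housekeeping
promoters need ≥ 1 of DRE/Ohler1/6/7 and none of TATA, MTE, DPE, PB,
TCT.  Both the multi-label set and an exclusive label (priority
TATA > TCT > DPR > HK, an ordering the source sets did not need to
resolve) are emitted.  PWMs are pseudocount-free base frequencies with
per-position information content 2 + Σ p·log₂p bits.

## TBP profile clustering and enrichment

Promoters keep the top 90% by total TBP signal (both strands) in the
81 bp window [−40, +40]; ties at the cut are kept.  Each row of the
concatenated two-strand feature matrix over the same window is replaced
by average ranks divided by the column count, mapping into (0, 1] and
discarding amplitude.  K-means uses k = 4, the best of 100 random
initializations, and at most 30 Lloyd iterations (the cap is the chosen
reading of the procedure's third clustering argument); cluster ids are
relabeled by descending size for run-to-run comparability.  Per
(cluster, element), enrichment compares in-cluster against all other
promoters: ratio of presence fractions (∞ when the element is
cluster-exclusive, undefined at 0/0), two-sided Fisher exact p, and
Benjamini–Hochberg q over all pairs jointly.

## Occupancy statistics

Normalized occupancy divides a promoter's both-strand signal sum over
[−50, +50] by its CAGE expression score; promoters without a positive
score are excluded with a logged count rather than an error.  Group
comparisons use the two-sided Wilcoxon rank-sum test on all observations
(outlier trimming is treated as plot-only): the exact Mann–Whitney null
distribution when the pooled sample is small and tie-free, otherwise the
normal approximation with tie correction and no continuity correction —
so identical groups give exactly p = 1 while small tie-free cases match
exact enumeration.  Binding-level similarity is the Pearson correlation
of log2(x+1) window sums; constant columns are dropped with a warning.
The 1−r dissimilarity is clustered with the classic Ward criterion
applied directly to the dissimilarities (R's `ward.D`), implemented
through the merge-order equivalence ward.D(d) = ward(√d); dendrograms
export as Newick.  Condition-difference correlations (ΔPCC) compare
control and treated correlations between window-summed TBP signal and
each factor; the upstream [−25, −10] and downstream [+25, +40] TBP
windows bracket the −18 and +32 footprints and are configurable, since
the originals are unstated.

## Pausing kinetics

Paused promoters satisfy three conjunctive filters: average per-base
signal > 20 (both strands over [−50, +50] — the averaging window is a
package choice), positive-to-negative strand-maximum distance in
(0, 80) bp, and pause midpoint < +80 bp.  The decay model
s(t) = s₀·2^(−t/h) is fitted by bounded nonlinear least squares without a
baseline offset, initialized from the log-linear closed form (a fit
failure falls back to that estimate with a flag); ĥ > 60 min is floored
to 60 with a `floored` flag.  Quintile binning ranks ascending by
half-life (ties by promoter id) and sends remainder promoters to the
outermost bins first, so n = 1307 yields sizes (262, 261, 261, 261, 262).

## Synthetic data

The generator plants ground truth for every stage.  Each promoter is its
own contig (601 bp, odd so the TSS is the exact center); about half are
emitted on the minus strand to exercise strand flipping everywhere.
Sequences are uniform-random backgrounds with concrete IUPAC expansions
planted in the canonical windows per class (TATA box; one of MTE/DPE/PB
plus an Inr; a TCT; one of DRE/Ohler1/6/7).  In scrubbed mode the
background re-samples (up to 1,000 attempts, then an error) until no
foreign class-defining element occurs at classification tolerance —
including 1-mismatch TATA instances — which guarantees exact class
recovery.

Footprints are symmetric Gaussian peak pairs around each contact
midpoint m: positive-strand stops ~ N(m − 4, 2 bp), negative-strand
~ N(m + 4, 2 bp), rounded to integers.  The generative shape, the 4 bp
strand half-offset and the 2 bp peak width are package choices (no
quantitative footprint shape is published); they produce clean paired
peaks at the documented contact positions.  Default contact geometries:
a generic TFIID subunit carries the five well-separated contacts
(−30, −18, +10, +19, +32); TBP is promoter-type-specific (sharp −18 at
TATA, downstream +32 at DPR, diffuse multi-contact at HK, low signal at
TCT); Pol II pauses at +30.  Per-promoter read totals are
`reads_per_factor` (10⁴) scaled by the promoter's expression level
(lognormal, σ_log = 0.6 — a realistic dynamic range), any per-class
factor scale, and a lognormal measurement-noise factor (σ = 0.25,
emulating ChIP efficiency variation); with unit expression and zero
noise the totals are exact, which the conservation tests use.

CAGE tags are drawn per replicate around the TSS with a 1 bp Gaussian
kernel (interquantile widths ≈ 3 bp, comfortably under the 11 bp
cutoff); widening the kernel to ≥ 10 bp pushes promoters out of the
narrow set, and both regimes are tested.  Pausing time courses decay the
expected (noiseless) t = 0 footprint by 2^(−t/h) per promoter, with
half-lives drawn log-uniformly from 2–120 min so some estimates engage
the 60 min floor; Poisson sampling is optional.  Every generator is a
pure function of (inputs, seed): independent deterministic substreams
derive from the root seed per purpose.

### What the synthetic data does not emulate

Real genomes with overlapping promoters, mappability artifacts and
nucleosomes; enhancer contacts and SAGA cross-talk; sequencing depth
variation within a library; correlated replicate noise; promoter-type
differences in initiation-window shape beyond the kernel width; and any
coupling between sequence elements and footprint amplitude beyond the
planted class geometry.  Passing tests therefore demonstrate that the
computational procedures recover what they are defined to recover — not
that the biological conclusions would reproduce on new sequencing data.

## Problem sizes and determinism

The shipped analysis drivers and the acceptance script use 100 promoters
per class (400 total), 10⁴ reads per factor and promoter, two CAGE
replicates of 10³ tags per promoter, and a five-point time course
(0–40 min) — sizes chosen so each analysis completes in seconds while
leaving planted-truth recovery statistically unambiguous.  All stages
write provenance records with parameter values and output checksums;
re-running any stage with an identical configuration is byte-identical,
which the test suite asserts over the whole pipeline tree.

## Known limitations

The power-law fit uses ordinary least squares on log-log
reverse-cumulative points, which is one of several defensible CAGE
normalization recipes; it is validated through its invariants (monotone,
rank-preserving, fixed point on referent-law data) rather than against a
specific external implementation.  The exponential decay fit carries no
baseline term, so a constant background biases long half-lives upward
(partly absorbed by the 60 min floor).  Whether tag-cluster TPM
filtering precedes or follows boundary refinement is ambiguous in the
source description; it is applied before merging here.  The k-means
module labels are arbitrary; only partitions should be compared.
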