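# Methods

This note documents the models, conventions and design choices behind
`piezoreg`, and what the synthetic-data generator does and does not emulate.

## Promoter definition and coordinates

A promoter is the fixed-length window (default 200 bp) immediately upstream
of a CDS start codon, reported 5'→3' on the gene's coding strand so its last
base abuts the first base of the start codon. Coordinates are 1-based
inclusive internally (GFF3 convention); BED output is 0-based half-open.
Choices where the convention was genuinely open:

- **No masking.** Promoters may overlap upstream genes or other promoters;
  the 200-bp window is taken literally. In dense prokaryotic genomes this
  means divergent gene pairs can share intergenic sequence and one physical
  motif can appear in two promoters.
- **Truncation, not skipping.** A gene closer than 200 bp to a contig edge
  yields a shorter (possibly empty) promoter flagged `truncated`, never an
  error. Replicons are treated as linear; no origin wrap-around.
- **Annotation is trusted.** The first codon is not validated; a warning is
  logged when it is not ATG/GTG/TTG. For multi-segment CDS the segment
  containing the start codon is kept (lowest start on +, highest end on −).

## Motif model

A pattern is an ordered list of conserved DNA blocks separated by
fixed-length unconstrained gaps (`GTTn{3}AACn{5}GTT` = blocks GTT, AAC, GTT
with gaps 3 and 5; span 17), plus a mismatch budget counted over
conserved-block positions only. Scanning reports every window within budget;
`N` never matches a conserved position. Both strands are scanned by default
and reverse-strand hits are mapped to forward offsets; the short SurR element
is its own reverse complement, so for it both-strand scanning is a no-op
(verified by brute force over all 4⁹ nine-mers). A window matching on both
strands is reported once with strand `promoter`.

**Distance convention.** The reported distance is the 1-based position of
the motif's 5'-most base counting backwards from the base immediately before
the start codon (a motif occupying the promoter's last `span` bases has
distance = span). This anchor is not universal in the literature, so the
alternative 3'-anchored convention is available via `distance_from="3prime"`.

**Mutated motifs.** Hits with exactly one conserved-position mismatch are
available as a separate report (`mutated_motif_report`) and are excluded
from the motif-bearing promoter set by default. Indel-tolerant matching is
not implemented.

## Normalization

- **TPM**: counts are divided by gene length in kb, then each sample column
  is scaled to sum to 10⁶. Used for visualization (z-score heatmap, PCA).
- **RLE / median-of-ratios**: per-gene geometric means are computed over
  genes with no zero counts; a sample's size factor is the median ratio of
  its counts to those means, and factors are rescaled to geometric mean 1 so
  fitted expression levels stay on the counts scale.
- **Filtering**: keep genes with CPM ≥ 1 (raw library sizes) in at least 3
  samples — one full replicate group of the 3×3 design. Both thresholds are
  configurable; the choice is ordinary practice for small-replicate bulk
  RNA-seq.

## Differential expression

The test is a deliberately transparent negative-binomial Wald pipeline with
every constant stated, rather than a wrapper around an existing DE package:

1. **Dispersion.** Per gene and condition, method of moments on
   size-factor-normalized counts: `alpha = max(0, (s² − mu)/mu²)`, averaged
   across conditions. A trend `alpha(mu) = a0 + a1/mu` is fit by ordinary
   least squares over genes with positive estimates, and the final
   dispersion is `0.5·trend + 0.5·genewise`, floored at 1e-8. The 50%
   shrinkage stabilizes the very noisy 3-replicate moment estimates while
   keeping genuinely high-dispersion genes conservative.
2. **Wald test.** Per condition, `q = mean(normalized counts) + 0.5`; the
   0.5 pseudocount makes all-zero genes well-defined (log2fc = 0, p = 1).
   `Var(ln q) = sum_j (1/(s_j q) + alpha)/n²` by the delta method; the
   two-sided normal p-value is computed on `(ln q_B − ln q_A)/SE`. The
   statistic is exactly antisymmetric in (A, B).
3. **Multiple testing.** Benjamini–Hochberg step-up (via statsmodels);
   significance at adjusted p < 1% (the stricter of the two thresholds in
   circulation for this kind of design; 5% is a config option).
4. **No outlier removal.** PCA is provided as a diagnostic plot only.

Calibration measured by the test suite and acceptance script at the design
scale (2,000–5,000 genes, 3 conditions × 3 replicates, dispersion 0.1): null
raw-p rate at 0.05 ≈ 0.06, KS distance from uniform < 0.05, pooled realized
FDR at adjusted p < 0.01 ≈ 0.02 with 10% planted 4-fold changes.

**Known limitation — fold-change precision at n = 3.** With three
replicates per group the per-gene log2 fold-change estimator has standard
deviation at least `sqrt(2·alpha/3)/ln 2` regardless of expression level
(≈ 0.26 at dispersion 0.05, ≈ 0.37 at 0.1). Individual planted log2fc = 2
estimates therefore scatter with sd ≈ 0.27 at mean counts 200, and only
~70% of genes land within ±0.3 of the truth; detection (calling) is far more
reliable than point estimation at this replicate number. The acceptance
suite reports this recovery fraction as measured.

## Clustering

Per-gene z-scores (mean 0, sd 1 across samples; zero-variance genes
dropped), agglomerative clustering of samples with Euclidean distance and
average linkage. Samples are sorted by id before clustering so leaf order is
deterministic under ties. Verified against a brute-force O(n³)
agglomeration.

## Regulon summaries

- **Locus-tag ranges** (`A7C91_RS04230-04165`) expand by the annotation's
  uniform tag increment (default 5, auto-detectable); the second endpoint
  may abbreviate the numeric suffix; descending ranges are preserved. A span
  that is not a multiple of the step is an error (wrong step).
- **Overlap percentages** are rounded half-up to one decimal and printed
  without the decimal when integral (8, 8.7, 70).
- **Cluster tables** count member genes in each directional overexpression
  set; zero cells render as "nd".
- **EASE** is the one-tailed Fisher exact (hypergeometric tail) p-value with
  one gene removed from the overlap cell (floored at 0), so 0- or 1-gene
  overlaps are never significant; the cluster enrichment score is −log10 of
  the geometric mean of member EASE p-values. The surrounding fuzzy
  annotation clustering of DAVID is out of scope; EASE operates on
  user-supplied term membership counts.

## Synthetic data

The generator emulates the study design so every stage has planted ground
truth: a single contig; ~2,000 CDS with log-normal lengths (median 900 bp,
ln-sd 0.6 — a typical archaeal CDS spread; bounds 150–6,000 bp, multiples
of 3 with start/stop codons written in); geometric intergenic gaps (mean
120 bp); Bernoulli(1/2) strands; locus tags in uniform increments of 5.
Motifs are planted by overwriting promoter bases at a distance drawn
uniformly from [span, 200] (coordinates stay fixed; realizations recorded
verbatim). Counts are NB with log-normal baselines (ln-mean 4, ln-sd 1.5),
dispersion 0.1, 10% planted |log2fc| = 2 in one random condition, and
log-uniform [0.5, 2] per-sample size-factor distortions. All randomness
flows from one seeded generator; a fixed seed reproduces every file
byte-for-byte.

Two structural details keep the planted truth exact. First, an intergenic
gap that hosts the promoters of two divergent genes is widened to two
promoter lengths when either gene carries a planted motif, so planted
windows never collide with or leak into a neighbouring promoter. Second, an
optional `clean_background` mode disrupts chance pattern occurrences in
non-planted promoters by single point substitutions, which makes the
motif-bearing promoter set equal the planted set exactly — used for
screen-scale runs where an exact promoter count is asserted
(`surr_screen_simulation`: 2,126 CDS, 170 planted promoters including the
flagship multi-motif placements at distances 21/127, 29/62/98, 69 and
49/103).

What the generator does **not** emulate: operon structure and correlated
expression of neighbouring genes, rRNA contamination, GC bias or any
sequence composition beyond i.i.d. uniform background, read-level effects
(no FASTQ, no alignment), and between-replicate batch effects. Passing
tests therefore demonstrate correctness of the algorithms under the stated
model, not robustness to those real-data phenomena.

## Problem sizes

The test suite and acceptance script run at 2,000–5,000 genes, 10,000
random promoters for the chance-hit rate, 20 seeded replicates for the FDR
measurement, and one 2,126-CDS screen-scale genome — sizes chosen to give
stable statistics for every asserted band while keeping a full run fast on
one CPU.
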