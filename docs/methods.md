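# Methods

`circsponge` re-implements, at desk scale, the computational chain used in
developmental circRNA studies of bulk RNA-seq: back-splice junction (BSJ)
detection from reads that fail linear mapping, classification and RPM
quantification of the resulting circRNA catalog, pairwise negative-binomial
differential expression across three ordered stages, short-series trend
profiling, and inference of a circRNA–miRNA–mRNA (ceRNA) network through
correlation filters and a hypergeometric shared-sponge test. Every stage is
validated end-to-end on synthetic data with planted ground truth.

## Back-splice junction detection

A circRNA is diagnosed by its back-splice junction: a read that crosses the
joint between a downstream splice donor and an upstream acceptor cannot be
placed contiguously on the genome. The detector follows the classic
anchor-split strategy:

1. **Linear filter.** Reads that occur verbatim (either orientation) in a
   chromosome or in any annotated spliced transcript are discarded.
2. **Anchoring.** The two terminal 20-mers of each surviving read are
   looked up in an exact k-mer index built over both strands of every
   chromosome. Both anchors must place *uniquely* genome-wide, on the same
   chromosome and strand, with the right-end anchor upstream of the
   left-end anchor (the reversed order characteristic of back-splicing).
3. **Breakpoint extension.** Every split position `b` (between 20 and
   read-length − 20) is tested: the read prefix must extend the left anchor
   contiguously up to the donor coordinate and the suffix must run from the
   acceptor coordinate through the right anchor. The flanking dinucleotides
   must be the canonical GT (after the donor) and AG (before the acceptor)
   on the read's strand, and the genomic span is capped at 100 kb.
4. **Aggregation.** Junctions identical in (chromosome, start, end, strand)
   are pooled; those supported by at least 2 distinct reads are reported.

Alignment is exact-match by design: the archetypal tool delegates mapping
to an external aligner, whereas here exactness keeps the whole detector
equivalent to a brute-force oracle that enumerates every donor/acceptor
placement and split position (this equivalence is asserted on ≤ 10 kb
genomes in the test suite). When several breakpoints reconstruct the same
read, the one with the leftmost donor is chosen, making calls
deterministic. Minus-strand junctions are found by running the same
procedure on the reverse-complemented chromosome view and mapping
coordinates back.

Detected junctions are named `circ_000001…` in genomic sort order and
classified by their breakpoints: **exonic** when both coincide with exon
boundaries of one same-strand gene (spliced length = sum of the
circularized exons), **intronic** when wholly inside a single intron,
**antisense** when overlapping opposite-strand genes only, **intergenic**
otherwise. Abundance is reads per million mapped (RPM):
`count / mapped_total × 10⁶`.

## Differential expression

Counts are compared between stage groups with a negative-binomial exact
test under a single common dispersion φ (variance = μ + φμ²):

* **Normalization.** Per-sample size factors are median-of-ratios against
  the per-feature geometric mean (features observed in all samples), scaled
  to geometric mean 1. Raw column totals are deliberately not used: a
  minority of strongly differential features can dominate totals and bias
  every null feature in the opposite direction, which is exactly the
  situation the planted data create. With fewer than 10 all-positive
  features the estimator falls back to total-count scaling. RPM
  quantification, by contrast, keeps the plain mapped-total denominator,
  since that is what the unit means.
* **Dispersion.** A pooled method-of-moments estimate,
  φ̂ = Σ(v − m) / Σ m² over all feature × group cells of normalized counts
  (group variance v, mean m), floored at 10⁻⁶. On Poisson data the
  estimate collapses to the floor; at φ = 0.1 with 4 replicates and 2,000
  features it lands within a factor ~1.2 of truth.
* **Exact test.** Normalized counts are summed per group. Given the pooled
  total s, the group-A sum of NB counts with sizes n_A/φ and n_B/φ has a
  conditional law free of the mean; the two-sided p-value sums the
  probability of every outcome whose conditional probability does not
  exceed the observed one ("small-p" rule). A log-space tie tolerance of
  10⁻⁸ absorbs floating-point noise between exactly mirrored outcomes.
  The implementation agrees with a direct enumeration oracle and with
  edgeR's `exactTest(rejection.region="smallp")` to ~10⁻⁹ on shared inputs.
* **Significance.** |fold change| > 2 and p < 0.05, with fold change
  computed on normalized group means with pseudocount 1 (the source
  analysis states the rule but not its pseudocount). Raw p-values are used
  by default to mirror that printed rule; a Benjamini–Hochberg switch is
  available (`fdr=True`).

Under a null simulation (φ = 0.1, 4 vs 4, 2,000 features) the fraction of
p < 0.05 sits near 0.05; planted 4-fold features with mean ≥ 100 are
recovered with sensitivity ≈ 1.

## Trend profiles

Each feature significant in at least one adjacent-stage contrast receives a
transition sign pair over (3M→1Y, 1Y→3Y): −1/+1 when that contrast is
significantly down/up, else 0. Signs come from contrast significance rather
than raw means so that "no change" means statistically flat. The profile id
is the rank of the sign pattern in lexicographic order (−1 < 0 < +1) with
the all-flat pattern excluded: (−1,−1)→0, (−1,0)→1, (−1,+1)→2, (0,−1)→3,
(0,+1)→4, (+1,−1)→5, (+1,0)→6, (+1,+1)→7. Thus "continuously
down-regulated" is profile 0, "down then no change" profile 1, "up then no
change" profile 6. Per-profile over-representation is a one-sided binomial
test of observed membership against the uniform 1/8 expectation, Bonferroni
corrected over the 8 profiles; the method behind the emulated study's
"significant profiles" is not published, so this simple calibrated stand-in
is a documented choice.

## ceRNA network

Target prediction is transparent seed matching: an edge exists when a
transcript contains at least one exact reverse-complement match to miRNA
positions 2–8 (7mer-m8) or to positions 2–7 followed by an A opposite
position 1 (7mer-A1). circRNA sequences are scanned circularly (a 6 nt wrap
of the junction), so junction-crossing sites are found. No free-energy or
context scoring is attempted; the generator plants exactly these site
types, which keeps target recovery deterministic and oracle-checkable.

Candidate triplets (circ, miR, mRNA) — one miRNA with edges to both
transcripts, all three differentially expressed in ≥ 1 contrast unless
all-feature mode is requested — must pass four filters:

1. Spearman(circ, miR) < −0.7 on log2(RPM + 1),
2. Spearman(mRNA, miR) < −0.7,
3. Pearson(circ, mRNA) > +0.9,
4. shared-sponge p < 0.05, where p = P(X ≥ x) for
   X ~ Hypergeometric(N, K, n): N = miRNAs expressed in ≥ 1 sample,
   K and n = expressed miRNAs targeting the circRNA and the mRNA, x =
   shared. The tail is evaluated exactly in log space; impossible terms
   (n − k > N − K) are skipped. Thresholds are strict inequalities as
   printed in the emulated criteria; the correlation scale (log2 RPM + 1)
   and the background universe (expressed miRNAs) are this package's
   choices since neither is stated at the source.

Correlations are computed by the package's own mid-rank Spearman and
product-moment Pearson (validated against independent oracles to 10⁻¹²);
a feature constant across samples has undefined correlation and its
triplets simply fail. The passing subgraph is exported as SIF and GraphML.
The same hypergeometric upper tail, with Benjamini–Hochberg FDR across
sets, powers the annotation-agnostic gene-set over-representation module
(gene sets supplied by the user in GMT format; no GO/KEGG content ships
with the package).

## Synthetic data

The generator emulates the study design: 3 ordered stages (3M, 1Y, 3Y) × 4
replicates, 150 nt single-end reads, and a two-chromosome 100 kb genome
with 40 multi-exon genes whose introns all carry GT..AG. Thirty genes host
a planted circle: an internal exon run whose spliced length is drawn from a
triangular distribution on [200, 700] nt peaking at 430, so the modal
100 nt bin of realized lengths contains 400 nt — the length profile the
emulated study reports. Terminal circularized exons are at least 100 nt so
that a junction read's two flanks fit inside them; this is the regime the
anchor-extension detector (like its archetype) can recover, and junction
reads are drawn accordingly (each flank ≥ anchor length). Linear reads are
exact substrings of spliced transcripts; sequencing error is off by default
and, when enabled, applies uniform substitutions only.

Expression matrices are NB counts (common dispersion 0.1) around per-stage
means, with per-sample library factors ~ U(0.7, 1.3) and lognormal mean
jitter (σ = 0.1) as the correlation noise. Planted structure:

* **Triplets** (default 10): circRNA and mRNA means proportional and
  monotone with an 8-fold step per stage; the miRNA mirrors them in the
  opposite direction, so pre-noise Spearman → −1 and Pearson → +1.
  Directions alternate between triplets so features of different triplets
  do not correlate spuriously. The triplet's miRNA seed site is written
  into both the circ and mRNA transcript sequences (a quarter of circ
  sites wrap the junction).
* **Trend features**: circRNAs realizing profiles 0, 1 and 6 with 4-fold
  steps.
* **Plain DE features**: one 4-fold step at a random transition, per omic.
* Remaining features have flat means, log-uniform in [50, 2000].

Background transcript sequences are scrubbed of accidental seed-site
matches (single-base mutations that never touch a planted site), so target
edges equal planted edges exactly; a switch disables scrubbing for null
calibration, where candidate triplets arise from chance sites alone.
The truth manifest records stage means, per-contrast DE flags (the |fold| >
2 rule applied to noiseless means), trend profiles and triplet membership
for every feature, and is closed over the emitted matrices.

What the generator does **not** emulate: paired-end reads, quality-score
structure, adapter/rRNA artifacts, tagwise dispersion, multi-mapping, or a
real genome's repeat content. Passing tests therefore demonstrate
correctness of the algorithms under their stated model, not performance on
real sheep testis libraries.

## Numerical and design choices

* Coordinates are 0-based half-open internally; GTF I/O converts to/from
  1-based inclusive; BED output is 0-based half-open.
* A fixed seed makes every artifact byte-identical across runs (TSV floats
  are formatted with `%.6g`; manifests avoid timestamps).
* Problem sizes used by the test suite and the acceptance script (2 × 50 kb
  genome, 30 circles, 2,000-feature DE simulations, 10–25 seeds for
  stochastic metrics) were chosen as the smallest designs at which the
  planted effects are unambiguous; they run in well under a minute each.
* `estimate_dispersion` warns and floors when all features are constant;
  `quantify_rpm` raises on a zero library; an empty candidate set yields an
  empty network with a warning rather than an error.

## Known limitations

* The exact-match aligner cannot absorb sequencing errors inside anchors or
  extensions; with error rates > 0 recovery degrades (a max-mismatch knob
  exists but defaults to 0 and is intentionally simple).
* Junction reads whose flanks cross an internal exon boundary of a
  multi-exon circle are invisible to contiguous breakpoint extension; the
  generator does not produce them, and a spliced-extension detector would
  be needed to find them in real data.
* The common-dispersion exact test is a stand-in for edgeR's tagwise
  empirical-Bayes machinery, not a clone; it matches edgeR only in the
  equal-library, common-dispersion regime.
* With scrubbed backgrounds each planted transcript has exactly one
  targeting miRNA, so the sponge test reduces to p = 1/N for planted
  triplets; richer shared-target structure would exercise larger overlaps.
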