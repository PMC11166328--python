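# Methods

## Edit-calling model

ADAR-fusion (TRIBE) editing converts adenosine to inosine on the sense
strand of a bound transcript; sequencing reads inosine as guanosine. The
caller therefore considers only columns whose annotated-sense reference
base is A: genomic A columns inside plus-strand genes (edited reads carry
G) and genomic T columns inside minus-strand genes (edited reads carry C,
the genomic representation of a sense G). Other mismatches are ignored by
design — they are sequencing error or non-ADAR variation.

A column becomes an edit site when `coverage >= c_min` (default 20
reads) and `edited/coverage >= f_min` (default 0.15). Both boundaries
are inclusive; `inclusive=False` switches to strict inequalities for
sensitivity analyses. Coverage counts A/C/G/T only; N bases are
excluded. Thresholds are applied per replicate *before* replicate
intersection, so a high-confidence site must independently clear both
thresholds in every replicate.

Strand is resolved from the annotation (`strand_mode="annotation"`).
Because a column's reference base can be A or T but not both, a position
covered by genes on both strands admits at most one A→G interpretation;
the site is assigned to the strand that yields it. Threshold-passing
columns outside any annotated transcript are dropped and counted in a
log line. A `read-flag` strand mode is declared but not implemented: it
would require per-strand pileup state that nothing downstream consumes.

"Uniquely mapped" is operationalized as: primary, mapped, MAPQ > 0, not
secondary or supplementary. Aligner-specific multimapper conventions
vary; this is the conventional reading and the filter is a single flag
(`unique_only`) at the SAM boundary.

## Target sets, ratios, correlations

Replicate intersection keys sites by exact (contig, position, strand).
Windowed matching was considered and rejected: the simulator plants
sites at exact coordinates, and real TRIBE replicates report coordinates
from a common alignment, so exact matching is well defined; a window
would only blur the contract.

The editing-efficiency ratio at a site shared between genotypes is the
replicate-combined fraction in the mutant divided by that in the
wild-type. The combiner is the replicate mean by default (`min` and
`pooled` — summed edited over summed coverage — are available); shared
sites have fraction ≥ f_min in every replicate, so the denominator is
never zero. Swapping the genotypes inverts every ratio exactly.

Correlations between two samples are Pearson r of per-site edit
fractions over the *union* of their called sites, with absent sites
contributing fraction 0. Zero-fill is deliberate and logged: comparing
samples with non-identical site sets requires a convention, and
zero-fill makes disjointness visible as low (negative) correlation
rather than silently restricting to shared sites. A corollary worth
knowing: when all true fractions within a genotype are equal (as in the
demo, where every WT site has true fraction 0.5), the between-site
variance among shared sites is pure binomial noise, independent between
replicates, so within-genotype r is near 0 — still systematically above
cross-genotype r, which zero-fill pushes negative. With heterogeneous
per-site fractions (supported via `edit_fraction=(lo, hi)`),
within-genotype r becomes strongly positive.

## Metagene and expression

Each gene's canonical transcript is the one with the longest CDS (ties
by transcript id). Sites are classified by interval membership in the
canonical transcript's 5'UTR/CDS/3'UTR; relative position is the
stranded transcript offset divided by transcript length, in [0, 1).
Transcripts without UTR annotation are flagged CDS-only and their sites
are "unresolvable", excluded from class fractions but counted. The
positional histogram uses 20 bins by default.

FPKM uses the standard single-end convention: one fragment per read
record, assignment by read midpoint within a unique gene span,
union-exon gene length. The simulator is intronless, so length variants
coincide. The target-expression profile reports medians and a two-sided
Mann–Whitney rank-sum p comparing target against non-target FPKM — a
descriptive diagnostic (no threshold is applied): targets drawn from
across the expression spectrum give large p, expression-biased targets
give small p.

## Granule colocalization

Granules are segmented by Otsu threshold and connected components
(area ≥ 5 px); a seeded random subsample emulates randomised granule
selection. For each granule a line profile is sampled through the
centroid at unit-pixel spacing (bilinear interpolation), at a seeded
random angle per granule (fixed-angle mode for tests). The profile's
total length defaults to 6× the granule diameter — comfortably above
the 3× contract — so the background window contains mostly
granule-free samples.

Bleed-through is removed by linear unmixing: corrected marker = marker −
c × granule channel, clipped at 0. The coefficient c can be supplied or
estimated from a single-stain control image as the least-squares slope
of marker on granule intensity. Subtraction (rather than gating) is an
interpretation choice; it is exact for a linear leak model.

Scoring: background is the median of corrected-marker samples beyond
1.5× the granule radius from the centroid (local, per-granule;
per-image background would be an easy variant but local background is
robust to uneven illumination); the signal is the maximum within one
radius (`peak_mode="mean"` available). A granule is colocalized iff
peak/background ≥ 1.10, inclusive, with a 1e-9 relative tolerance
absorbing float rounding at the boundary. Because the call is a ratio,
it is invariant to global rescaling of the marker channel.

## Synthetic-data generator

The generator is first-class, tested code; its defaults define the
conditions under which the analysis guarantees are verified.

- **Genes.** Intronless single-transcript genes, one per contig,
  alternating strands; default 5'UTR/CDS/3'UTR lengths 100/600/300 bp
  (fixed or per-gene ranges). Each contig carries a read-length flank on
  both sides of the transcript so read coverage is uniform across the
  whole transcript — without it, coverage ramps down near transcript
  ends and edge sites fall below the coverage threshold for depth
  reasons unrelated to editing.
- **Expression.** Per-gene mean depth is log-uniform over (1, 1000) by
  default — three orders of magnitude, so lowly expressed targets are
  genuinely uncallable at 20× and the FPKM diagnostics have dynamic
  range. Read count per gene is Poisson; read starts are uniform.
- **Editing.** Each planted site sits on a sense-strand A; every
  covering read independently carries the edited base with the site's
  true fraction. `utr3_only` placement samples sense-A positions
  strictly inside the 3'UTR; `uniform` samples over the whole
  transcript. True fractions are a single value per genotype or a
  per-site (lo, hi) uniform draw. Sequencing errors are uniform
  substitutions (default 1e-3) applied after editing; realized per-site
  edited/total counts are recorded from the final read matrix, over all
  reads and over unique reads, so caller output can be checked exactly.
- **Multimappers.** A configurable fraction of reads is emitted as
  MAPQ-0 secondary records, giving the unique-mapper filter something
  concrete to reject (default 0).
- **Granule images.** Granules are *truncated* Gaussians (zero beyond
  3σ) with integer-pixel centers on constant background. Compact support
  and exact centers are what make the closed-form checks exact: the
  profile sample at the centroid equals background × enrichment, and
  background samples beyond the truncation radius are exactly the
  background, so the 10% decision flips exactly at planted enrichment
  1.10. Channel 2 adds (enrichment − 1) × background at granule centers,
  a linear bleed of channel 1, and optional Gaussian noise.

What the generator does **not** emulate: splicing and indels, PCR
duplicates, base-quality structure, strand-specific library artifacts,
SNP/SNV background (a blacklist hook exists), overlapping genes, 3-D
imaging, non-Gaussian granule shapes, uneven illumination. Passing
tests therefore demonstrate correctness of the *computations* under the
stated statistical model, not robustness to every artifact of real
libraries or microscopes.

## Determinism and problem sizes

Every random draw derives from one integer seed through
`numpy.random.Generator` seed sequences namespaced per component and per
sample; equal-seed runs are byte-identical, and the pipeline manifest
records a SHA-256 of every output. SAM records are emitted
coordinate-sorted with a fixed header (no timestamps or tool-version
lines).

The demo defaults follow the study design (320 genes, 250 WT-like and
100 dPAM2-like target genes with 36 shared, two replicates, depth
log-uniform over 1–1000×); the test suite exercises the same code paths
at reduced sizes (60–150 genes, depths 20–200×) chosen so the full
suite completes in about a minute while keeping binomial tolerances
meaningful.

## Error handling conventions

Configuration problems raise `ConfigError`, malformed or inconsistent
data raise `DataError`, and the pipeline wraps any stage failure in
`StageError` naming the stage. The CLI maps these to exit codes 2 and 3
respectively. Degenerate inputs are defined, not guessed: zero mapped
fragments, zero profile background, all-unresolvable metagene input and
single-replicate intersection are errors; empty target sets and empty
detections warn and return empty results.
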