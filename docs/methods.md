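# Methods

## Coding-region handling

Coding regions are defined by PTT annotation rows (1-based inclusive
`start..end`, strand); that coordinate convention is kept end-to-end to
avoid off-by-one drift.  Plus-strand genes are the literal substring,
minus-strand genes its reverse complement.  Genes whose length is not a
multiple of 3 are eliminated; genes running off their replicon or with
`start > end` (origin-spanning genes of circular replicons, which the
analysis does not model) are excluded with a logged warning.  Genes
containing non-ACGT characters are dropped from usage statistics only —
their replicon still contributes to genomic GC, which is computed over
all replicons of a genome (chromosome plus plasmids combined, one GC
value per organism) with ambiguity letters excluded from numerator and
denominator.

## Usage vectors

Per gene, codons are counted once into a 64-vector (codon-table order:
lexicographic over T, C, A, G by position); the 12-dim base-position
vector and the 20-dim amino-acid vector are exact marginalisations of
that count — base *b* at position *p* sums the codons with *b* in slot
*p*, and each amino acid sums its synonymous sense codons.  Stop codons
(TAA, TAG, TGA under the bacterial/archaeal code, NCBI table 11) are
kept in the codon and base vectors but excluded from both numerator and
denominator of the amino-acid vector.  Translation is literal table-11
(no forced Met at GTG/TTG starts, no selenocysteine/pyrrolysine
recoding).

The genome profile is the **unweighted arithmetic mean of the per-gene
vectors**: every gene counts once, so a 300-codon gene and a 3000-codon
gene carry equal weight.  The pooled-count alternative (frequencies over
the concatenated codons) coincides with it only for equal gene lengths;
the test suite uses pooling as an independent oracle in exactly that
case.

## Distances and regression

Distances are plain Euclidean norms between genome-mean vectors,
computed for all M(M−1)/2 unordered pairs over the cohort sorted by GC
ascending (ties broken lexicographically by genome id — the sort key for
heat maps, where each genome occupies one equal-width slot regardless of
its GC).  Condensed upper-triangle storage follows the SciPy `pdist`
convention.  For unit-sum vectors the distances are bounded by √2
(codon, amino acid) and √6 (base: three independent position simplices).

Fits are ordinary least squares with intercept; SSE = Σ(y−ŷ)² and
R² = 1 − SSE/SST (clipped into [0, 1] against floating-point round-off).
At least 3 points and non-constant x are required; a constant x raises a
degenerate-fit error.  The distance-vs-ΔGC fit treats all pairs as
independent points even though pairs sharing a genome are dependent —
this matches the analysis the package reproduces; the fits are
descriptive and no p-values or confidence intervals are produced.
GC-difference bin summaries use half-open bins [lo, hi); an empty bin
reports count 0 with an undefined range.

## Section variances

Two partitions into sections are compared: one section per phylum
(genomes with a missing or "unclassified" phylum are excluded and
reported), and `n_bins` (default 34) equal-width GC bins.  The bin width
is x = (gc_max − gc_min)/n_bins with GC g mapped to section
⌊(g − gc_min)/x⌋ + 1 and g = gc_max clamped into the last section, i.e.
disjoint consecutive intervals; by default the range is the observed
cohort minimum/maximum, with explicit bounds available for
fixed-cohort replication.  Per section, the variance of the
within-section pairwise distances is computed; sections with M ≤ 2
genomes have variance fixed at 0 (a single pair has no spread), and
sections with M < 5 are flagged as small samples.  The variance
denominator is the n−1 sample variance by default (configurable to n;
recorded in each summary).  Zero-variance sections are retained in the
output tables but never enter range summaries.

The grouping comparison reports, per partition, the nonzero variances
sorted ascending (the line-chart data) and their range with and without
small-sample sections.  "GC bins narrower" is defined as the GC-bin
partition having both the smaller maximum variance and the smaller
(max − min) spread over all nonzero sections; the minimum alone is not
compared, since a partition whose sections are all tightly homogeneous
necessarily undercuts the other partition's minimum as well.

## The synthetic cohort generator

The generator emulates the one structural assumption the analysis
rests on — composition that varies linearly with genomic GC — with the
minimal model that has it exactly:

* **Independent codon positions.**  Each position draws its base with
  P(G) = P(C) = gc/2, P(A) = P(T) = (1 − gc)/2, making every base
  frequency exactly linear in GC (slopes ±1/2) and codon frequencies
  products of base probabilities.
* **Stop removal preserving marginals.**  Genes must be stop-free, so
  each stop codon's probability is redistributed within its
  first-two-base codon family (TAA, TAG → TAT/TAC; TGA → TGT/TGC/TGG,
  proportional to the base-model probabilities of the receiving codons).
  Redistributing within the family keeps the position-1 and position-2
  base marginals exact — A at position 1 stays (1 − gc)/2 with analytic
  slope −0.5 — and shifts the expected coding GC by < 0.004 across the
  0.15–0.75 range (verified analytically and by Monte Carlo in the test
  suite).  A naive proportional redistribution over all 61 sense codons
  would inflate A1 by the GC-dependent factor 1/(1 − p_stop) and steepen
  the analytic slope to ≈ −0.58.
* **Per-genome noise.**  Each genome's codon distribution is perturbed
  by i.i.d. Gaussian noise on the log scale (default scale 0.05) and
  renormalised — enough scatter that fits are non-trivial, small enough
  that the linear signal dominates.
* **Genome assembly.**  Genes (default 500 per genome, 300 codons each)
  are sampled codon-wise and laid head-to-tail on a single replicon with
  random 10–50 bp GC-balanced spacers; each gene lands on the minus
  strand with probability 1/2 and is stored reverse-complemented.  All
  gene lengths are multiples of 3, so the length filter removes nothing.
  Realised genomic GC tracks the target within ±0.02 at default sizes
  (coding GC within ±0.004; spacers at GC 0.5 pull mid-range genomes
  slightly toward 0.5, which also steepens the realised A1 slope from
  −0.50 to about −0.52 in the file-based pipeline).
* **Phylum labels.**  `gc_uncorrelated` (default) assigns phyla
  round-robin across the GC-sorted cohort so each phylum spans the full
  GC range; since GC is the model's only usage driver, GC-bin sections
  are then necessarily more homogeneous than phylum sections — the
  synthetic restatement of "similar GC implies similar usage regardless
  of lineage".  `gc_correlated` assigns contiguous GC blocks for
  studying the confounded case.

Default cohort: 100 genomes on an even GC grid 0.15–0.75 (the
prokaryotic range), 10 phyla.  These sizes keep the full file-based
pipeline (generate → parse → profile → fit → sections) under ten
seconds while leaving ≈ 3 genomes per GC bin at 34 bins, enough for
nonzero section variances.

All randomness flows from one integer seed through NumPy
`SeedSequence.spawn`, one child per genome: cohorts and every derived
table reproduce byte-identically for the same spec.

What the generator does **not** emulate: phylogenetic correlation
structure (no tree, no substitution model), amino-acid-level selection,
translational selection or expression-level effects, operon structure,
genes spanning the origin, ambiguity characters, and real stop-codon
usage at gene ends.  Passing tests on synthetic cohorts therefore
demonstrate correctness of the pipeline's arithmetic and the
recoverability of a GC-driven linear signal — not that real genomes
follow the model.

## Numerical choices

* Genome means and distances are double precision throughout; usage
  normalisation invariants are asserted to 1e−9 for computed vectors
  and relaxed to 1e−3 when ingesting published tables, which are
  rounded to a few decimals.
* OLS uses `scipy.stats.linregress`; tests check it against the
  closed-form mean-centred normal equations to 1e−10 relative error.
* GC-bin assignment uses floor division with an explicit clamp at the
  upper boundary, so `gc == gc_max` lands in the last bin rather than a
  phantom bin n+1.
* Log-scale noise subtracts the maximum before exponentiating
  (softmax-style) to avoid overflow at large noise scales.

## Known limitations

* The ingestion path for published supplementary tables validates
  column counts and normalisation but cannot reconstruct per-gene
  information (gene counts are unknown, `n_genes = None`).
* Heat-map rendering subsamples cohorts beyond a configurable genome
  budget (default 400) evenly along the GC order; fits and tables never
  subsample.
* The variance comparison is purely descriptive; no test of the
  variance difference is performed.
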