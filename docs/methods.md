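# Methods

This note records the statistical model, the conventions the implementation
commits to where several were defensible, the synthetic study conditions,
and the known limits of what the test suite demonstrates.

## Scanning and canonicalization

A microsatellite locus is a *maximal perfect run*: a tandem repetition of a
2–6 bp unit that cannot be extended by one base on either side.  The repeat
count is the number of complete units, `floor(run_length / unit_length)`;
a trailing partial unit lengthens the span but not the count.  Motif
classes merge all rotations of the unit and of its reverse complement, and
are named by the lexicographically smallest member — the standard SSR
convention, which reproduces the familiar probe names (AC, AG, AAC, AAG,
ACG, AGG, ACAT, AGAT).  Whether reverse complements should be merged is
not a settled convention everywhere; merging is adopted here because the
probe names are only consistent under it.  Soft-masked (lowercase) bases
are uppercased and scanned normally, since whole published assemblies are
scanned without a masking policy; any non-ACGT character terminates a run
and never matches.  Runs of different classes may overlap; each is a
separate locus.  The scanner is linear-time per unit length (positions
where `seq[i] == seq[i+m]` are found vectorially; maximal stretches of such
positions correspond one-to-one to maximal period-m runs), and is checked
exactly against a quadratic brute-force reference on random sequences.

## Digestion and attribution order

RsaI digestion is complete (every GTAC cut between T and A) on linear
chromosomes; partial digestion, other enzymes and circular topologies are
out of scope.  The genome reference is built by **digesting first and
scanning each fragment independently**: an SSR spanning a cut site is
truncated per fragment and must independently satisfy the minimum repeat
count.  The alternative (scan first, then attribute) differs only for loci
straddling cut sites; digest-first is chosen so the genome reference and
the read pipeline share identical semantics, since a sequenced fragment
can only ever contain the truncated run.

## Tabulation conventions

* Counting unit: one count per maximal locus.  A fragment or read carrying
  two qualifying loci contributes two counts; a per-sequence mode (at most
  one count per motif class per fragment/read) is available as a switch
  because published "number of microsatellites" phrasing does not fix the
  convention.
* Position summary: the real-valued interval midpoint, symmetric under
  strand flips.  Genome loci are binned by the locus midpoint; mapped reads
  by the midpoint of the oriented subject interval.
* Regions: ten per chromosome with real-valued boundaries
  ((m−1)·L/10, m·L/10], computed in exact integer arithmetic, so no region
  is empty or overfull for lengths not divisible by ten.
* Length classes: five 80-bp bands labelled by their lower bound, 81–160 →
  "80" … 401–480 → "400"; lengths ≤ 80 bp (unreliable alignments) and
  > 480 bp (absent from the sequencing chemistry) are excluded.
* The equiprobability null is uniform per category by default, with
  optional per-axis weights (e.g. physical chromosome lengths); both
  variants exist because the uniform/weighted choice is a modelling
  decision, not a derived fact.

## Read pipeline

Reads strictly longer than 80 bp are kept (matching the "> 80 bp" summary
column and the 81-bp lower class bound); reads are then required to carry a
qualifying SSR of *any* 2–6 bp class, not only probe classes, and each is
flagged target/non-target.  Mapping hits (12-column tabular) are filtered
at e-value ≤ 1e-40 and alignment length ≥ 90% of the read; among survivors
the single best hit by bit score wins, and an exact bit-score tie between
different subject locations discards the read — bit score is used because
e-values are scale-degenerate at this threshold, and the tie rule avoids
double-counting repetitive placements.  Summary percentages round half-up
to one decimal, the convention under which all eighteen published summary
cells are reproduced exactly from their printed counts.  Primer-design
counts are external inputs, never computed.

## Statistical battery

* One-way comparisons are χ² goodness-of-fit tests of an observed marginal
  against the reference marginal, statistic Σ(O−E)²/E over cells with
  p > 0, df = #{p > 0} − 1.  An observation in a zero-probability cell is
  an *incompatible* outcome (infinite statistic), reported as such.
* Two-way comparisons are independence tests with margins re-estimated,
  df = (rows−1)(cols−1) after dropping all-zero rows/columns.
* Monte-Carlo nulls replace the asymptotic p whenever any expected count is
  below 5 (a common rule; the trigger and B are not externally fixed).
  B = 9,999 by default, p = (1 + #{draws ≥ observed})/(B + 1).  Draws are
  multinomial from the reference (goodness of fit) or from the
  product-of-margins distribution with per-draw margin re-estimation
  (independence).  Goodness-of-fit draws are generated in
  sorted-probability order: numpy's multinomial sampler is category-order
  dependent, and sorting makes the p-value exactly invariant under joint
  permutation of (observed, reference) categories.  Every stochastic
  operation requires an explicit seed; there is no global random state.
* Per-cell tests are exact two-sided binomial tests of O against
  Binomial(n, p_cell), minimum-likelihood two-sided convention (sum of
  outcome probabilities ≤ the observed outcome's, with the same relative
  tolerance scipy's `binomtest` uses), vectorised with a binary search on
  the monotone flanks of the pmf.  Standardized-residual z-tests are
  available behind a switch.  BH step-up adjustment is applied across all
  cells of a table; directions (over/under) are assigned only below the
  FDR level.
* Expected-count envelopes are central binomial quantile intervals per
  category — marginal, not simultaneous, bands: the simplest model
  consistent with drawing n loci independently with probability p.
* The chromosome bootstrap resamples r of S chromosomes *with replacement*
  and stacks the drawn chromosome × region rows with multiplicity.  The χ²
  of the stacked table equals that of the multiplicity-summed table, and
  df counts drawn rows: (r−1)(cols−1) for independence, support cells with
  multiplicity for the reference-comparison mode.  This keeps df
  deterministic per replicate; basing df on *distinct* rows inflates χ²/df
  by a random factor and can even reverse the expected narrowing of the
  interval with growing r.  Degenerate replicates are dropped and counted;
  more than half dropped aborts.
* Two-sample KS comparisons across libraries act on the per-cell χ²
  contributions of the chromosome × region comparison (asymptotic p).  The
  per-cell χ² values are conventionally judged against the upper 5% point
  of χ²(1), 3.84.

### Reference-support restriction

Reads are binned by mapped-interval midpoint while genome loci are binned
by locus midpoint.  A read whose fragment midpoint falls in a different
chromosome decile than its locus midpoint can therefore land in a cell with
zero reference probability even under perfectly neutral sampling — a
discretisation artefact, not an enrichment bias.  The *global* four-way
comparison consequently restricts both distributions to the reference
support and renormalizes, reporting the (typically zero or single-digit)
count outside the support separately.  `chi2_gof` itself retains the strict
incompatible flag for callers who want it.

## Synthetic data: what it emulates, and what it does not

`simulate_genome` plants maximal perfect SSRs and GTAC sites *into* a
random background by insertion, so truth coordinates are exact.  Planted
loci are spaced ≥ 8 bp apart; the one background base flanking each locus
is adjusted when needed so the locus stays maximal and no GTAC occurrence
covers the boundary (at most three of the four bases are ever excluded, so
a valid base always exists).  Incidental background repeats and GTAC
occurrences remain and are intentional — truth-based tests therefore check
containment (every planted locus recovered exactly), not equality.

Default densities are motif-specific, mirroring the order of magnitude
reported for real insect and fish genomes (common dinucleotides ~250
loci/Mb, rare trinucleotides like ACG ~2.5–5/Mb): AC and AG 250, AAC, AAG
and AGG 25, ACG 5, ACAT and AGAT 10 per Mb.  Repeat counts are 4 plus a
geometric tail (success 0.5, mean 5 units).  Heterogeneity is configurable
at three levels: per-(region, motif) factors, whole-chromosome scales, and
per-chromosome regional hotspot factors.

`simulate_enriched_reads` samples restriction fragments with replacement,
with probability ∝ capture weight (25× for probe-bearing fragments by
default) × length-class multiplier (default 3× for the 161–320 bp classes,
the distortion direction of real pyrosequenced libraries; zero weight
outside 81–480 bp, the analysis window).  Each draw yields one read — the
full fragment on a random strand — plus a noiseless synthetic mapping hit,
so the pipeline runs without an aligner.  Not emulated: base-calling
errors, homopolymer artefacts, quality scores, adapter remnants, chimeras,
partial digestion, and alignment ambiguity.  Passing tests therefore
demonstrate the correctness and calibration of the *analysis*, not
robustness to sequencing noise.

With-replacement fragment sampling makes per-cell counts approximately
independent Poisson (hence multinomial given the total), which is what
makes the neutral-library null exact up to two small effects: loci sharing
a fragment are observed together (negligible at the default densities),
and the midpoint discretisation above.

## Study conditions of the experiment harnesses

Chosen once as realistic desk-scale conditions and fixed:

* Planted-bias recovery: 10 Mb genome (4 × 2.5 Mb), default densities, one
  (region 7, AC) cell at 3× intensity, neutral enrichment, 20,000 reads,
  20 runs.  Detection = the planted cell flagged over-represented at
  BH-FDR 0.05 in the region × motif independence analysis.  Each run
  derives three independent sub-seeds (genome, library, Monte-Carlo);
  reusing one seed for both the library and the Monte-Carlo null couples
  the two random streams and visibly distorts the null.
* Neutral-null calibration: 4 × 0.5 Mb, flat 30 loci/Mb/motif, 5,000
  reads, 100 runs; global four-way GOF on the reference support.
* Bootstrap narrowing: 10 × 350 kb chromosomes with graded regional
  hotspots on five (factors 8/6/4/3/2 in distinct regions), 500
  replicates, 20 seeds.  Heterogeneity must be *uneven* across chromosomes
  for the r = 2 interval to dwarf the r = S one; evenly distributed
  hotspots make all chromosome pairs equally dissimilar and the effect
  disappears.
* Null calibration of the GOF test: 2,000 multinomial datasets, n = 5,000,
  20 categories; FDR control: 1,000 such tables.

## Known limitations

* Genome-scale published quantities (whole-assembly motif densities, the
  KS statistics between real probe-set libraries, fractions of per-cell χ²
  below 3.84) require the real assemblies and read sets and are not
  reproduced at desk scale.
* The species-level enrichment-efficiency χ² comparison (df = 9) has no
  unambiguous construction from the published table shapes and is not
  implemented.
* The equiprobability null's weighting convention (uniform vs
  length-weighted) is a user choice; results under the two can differ
  materially for genomes with very unequal chromosome sizes.
* Simultaneous (family-wise) envelopes, Bayesian alternatives and spatial
  autocorrelation of loci along chromosomes are out of scope.
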