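# Methods

This note records the models, parameter choices and numerical decisions
behind `oakbes`, and what the synthetic-data experiments do and do not
demonstrate about real BAC-end data.

## Coverage model

Clone recovery follows the Clarke–Carbon model: inserts are placed
independently and uniformly, so a locus is missed by one clone with
probability `1 − I/GS` and by the library with `(1 − I/GS)^N`. Both
directions (clones needed for a target probability, and probability for
a given clone count) are evaluated with `log1p`/`expm1` so that
probabilities within 1e-9 of 0 or 1 remain accurate. Fold coverage
multiplies the clone count by `(1 − empty_fraction)` and
`(1 − organelle_fraction)` before scaling by `I/GS`: empty and
organelle-derived clones contribute no nuclear coverage. Published
libraries sometimes print a coverage figure below this formula value;
the package always reports the formula value and leaves any further
discounting to the caller. Contamination rates from PCR screens carry an
optional exact (Clopper–Pearson) binomial interval, computed from beta
quantiles.

## Repeat-call null model

The self-comparison treats two aligned 100-bp windows as 100 independent
position pairs; a position matches with probability `Σᵢ fᵢ²` (two
independent draws from base frequencies `fᵢ`), so the probability of
≥ 90% identity is approximated by the probability of the required 90
matches, `p0 = (Σᵢ fᵢ²)⁹⁰`, evaluated in log space. This deliberately
ignores the combinatorial choice of which 10 positions mismatch and
alignment gaps — it is an order-of-magnitude null, and conclusions are
insensitive to it because p0 is ~50 orders of magnitude below any
actionable threshold. `Σᵢ fᵢ²` is minimized at uniform frequencies, so
any skewed composition only raises p0 (tested as a property). The
match-count threshold *T* is the smallest integer whose binomial upper
tail falls below α, found by binary search over the monotone tail; for
`n·p0 < 1e-3` the exact tail is replaced by the analytic
`1 − (1−p0)ⁿ` (for T = 1) or a Poisson tail, avoiding double-precision
underflow. The default comparison count is `n_reads − 1`, overridable to
any fixed trial count. Defaults: window 100, 90 required matches,
α = 0.05.

## Built-in aligner

`local_align` gates each strand on a shared exact 11-mer (the BLAST-style
word size) and then computes an exact Smith–Waterman local alignment via
Biopython's C `PairwiseAligner` with match +1, mismatch −2, and affine
gaps costing 5 for the first gap column and 2 per further column; hits
below score 28 are discarded. Because the extension is exact DP, the
reported best hit provably equals the Smith–Waterman optimum whenever a
seed exists; the test suite cross-checks this against an independently
written, numba-jitted DP oracle on 220 random pairs (mutated copies and
unrelated pairs, 60–500 bp, both strands). The known sensitivity limit
is the seed gate: a pair whose best alignment contains no exact 11-mer
is not aligned at all. At ≤ 10% pairwise divergence and ≥ 100 bp of
shared sequence this is vanishingly rare. N is scored as a hard mismatch
against everything including itself, which is also how masking works:
known-repeat intervals are N-substituted, removing them from both
seeding and window identity.

The window rule is applied to the alignment's per-column match vector
(gap columns count as mismatches, the conservative reading): a hit
passes only if it spans ≥ 100 columns and every 100-column window has
≥ 90 matches. Alignments shorter than one window never pass. External
tabular hits (BLAST outfmt-6 dialect) carry no alignment string; in
approximate mode a match vector is reconstructed by spreading the
non-identical columns evenly, which is exact for the window rule when
mismatches are in fact dispersed and conservative-to-neutral otherwise.

## Repeat families and extrapolation

Reads matching ≥ 6 distinct other reads (after masking) are repeat
candidates. Families are single-linkage connected components of the
passing-hit graph restricted to candidates — a transparent, testable
surrogate for motif discovery. Per family, covered bp is the union of
passing-hit spans over member reads, and the representative is the
largest covered block of the most-covered member. Genome copy number
extrapolates the member count by `GS / total_BES_bp`, i.e. it assumes
the read set is an unbiased genomic sample.

A structural assumption matters here: BES sets cover their genome at
≪ 1×, so two reads almost never overlap genomically and self-matches are
attributable to repeats. The planted-recovery experiment honours this
(1.78 Mb genome, 890 planted copies of a 199-bp element at 2%
divergence, 1,180 reads ≈ 0.13× coverage) and recovers the planted copy
number within 15%. At high simulated coverage the same machinery would
report genomic-overlap redundancy as repetition — as it would on real
data from a tiny genome.

## Synthetic data

The generator emulates: background genome of i.i.d. bases at the
dataset's composition (default GC 35.33%); repeat families as a random
consensus with independent per-base substitutions per copy; perfect SSR
loci; gene-sized truth intervals (2 kb default — their coordinates, not
their composition, are what the gene estimator consumes); a chloroplast
molecule (150 kb default) sampled by a Bernoulli fraction of clones
(2.2% default); clone inserts from a truncated normal (135 ± 30 kb in
[50, 205] kb by default) placed uniformly; 7% empty clones; fixed-length
inward-facing end reads (599 bp) each retained with probability 0.6696.
Features are placed without overlap by rejection sampling; everything is
deterministic given the seed. Deliberately not modelled: sequencing
error and quality values, restriction-site (EcoRI) cloning bias,
chimeric clones, nested/fragmented repeats, compositional heterogeneity.
Passing planted-truth tests therefore demonstrates the correctness of
the inference chain under its own assumptions, not robustness to those
real-data effects.

Read retention is modelled as a Bernoulli thinning — the package never
recomputes quality trimming from chromatograms.

## Gene-content estimation

The estimator scales the genic fraction of BES nucleotides
(`n_hit × L̄ / total_bp`) to the genome and divides by a mean gene
length. In the planted-recovery experiment a read counts as a hit when
it overlaps a planted gene by ≥ 100 bp (the window-rule analogue), and
the estimator is fed the effective detectable footprint
`gene_len + read_len − 2·100 + 1` as its gene-length parameter; with the
nominal 2 kb instead, the estimate would be biased upward by the ratio
footprint/gene_len (~1.2 at 600-bp reads), which is an inherent property
of hit-counting estimators, not of this implementation. The
homology-blind correction divides by `(1 − novel_fraction)` (default
0.11): if a fraction f of genes leaves no homology signal, hit counting
sees only `1 − f` of them.

## SSRs

Detection enumerates, per period p = 1..6, maximal runs of
`s[i] == s[i+p]`, reporting a locus when the motif is primitive and the
span meets the per-period threshold (di 16, tri 15, tetra 16, penta 15,
hexa 18 bp; mono 10 bp, detected but excluded from period 2–6 statistics
by default). Trailing partial copies are allowed, so copy numbers may be
fractional; runs break at N; a locus fully inside a smaller-period locus
is suppressed so each position reports under its smallest period.
Primitivity already prevents the common double-reports (an AT array is
never also an ATAT array). The detector is verified against an
exhaustive start-and-extend oracle on SSR-salted random sequences up to
5 kb, and planted loci are recovered exactly up to chance extension by
flanking background bases. Motif classes are the lexicographic minimum
over rotations of the motif and of its reverse complement. GC-only
motifs receive no special treatment: their absence in real data is an
observation, not a filter.

## Synteny classification

Categories are assigned most-specific-first: no_hit, single_end,
paired_end (both ends hit somewhere), colocalized (some forward/reverse
combination on one target), then gapped vs non_gapped by whether any
same-target combination spans 15–250 kb (bounds inclusive; span is the
footprint between outermost hit coordinates, approximating the insert).
Among in-range combinations the best (maximal summed aligned length,
ties to the lowest target coordinate — deterministic) decides collinear
vs rearranged: collinear requires opposite strands with the plus-strand
hit 5′ of the minus-strand hit, the inward-facing geometry of BAC ends.
This rule keys on strands, not on which read is labelled forward, so
classification is invariant under relabelling the ends. Summary counts
are cumulative down the hierarchy, so `colocalized = gapped + non_gapped`
and `non_gapped = collinear + rearranged` hold on every input (asserted
on randomized hit tables).

## GO category comparison

Per-category tests are one-vs-rest 2-cell goodness-of-fit chi-squares
(df = 1): observed `[x, n−x]` against expected `[np, n(1−p)]`, i.e.
statistic `(x − np)² / (np(1−p))`. Per-category tests (rather than one
multinomial test) are required to call individual categories over- or
under-represented. No multiple-testing correction is applied by default,
matching common practice for descriptive annotation comparisons; a
Bonferroni option exists. Categories with an expected cell below 5 are
flagged as unreliable rather than dropped. The reference distribution is
always an input file — it is database-version dependent and never
fetched.

## Pipeline and problem sizes

The orchestrator derives one sub-seed per stochastic stage from the
global seed via `numpy.random.SeedSequence`, runs stages in dependency
order, and writes a manifest (config, seed, SHA-256 of every output) so
reruns are verifiable. The default synthetic configuration uses a 2 Mb
genome, 150 clones at study-scale insert parameters, two 200-copy repeat
families, 300 SSR loci and 15 genes — large enough for every stage to
produce non-trivial output while the full run stays under a minute; the
dedicated recovery experiments in the test suite choose their own sizes
as described above. Reports contain only numbers produced by module
operations; the pipeline never does report-side arithmetic.

## Known limitations

* The repeat-family surrogate (connected components) can chain two
  distinct families into one if a read happens to contain elements of
  both; at realistic planting densities this does not occur in the test
  genomes, but it is a real possibility on repeat-dense data.
* The seed gate bounds aligner sensitivity at high divergence (no shared
  11-mer, no alignment); the 100-bp/90% window rule makes this moot for
  the repeat pipeline, which only consumes high-identity hits.
* E-values on external hits are compared against cutoffs, never
  recomputed; the built-in aligner reports raw scores only.
* Copy-number extrapolation and the gene estimator both assume the read
  set is an unbiased sample of the genome; cloning-enzyme bias violates
  this on real libraries and is not modelled.
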