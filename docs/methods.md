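# Methods

## The haplotype-sharing model

All analyses operate on a matrix of phased haplotypes: one row per
phased chromosome, one column per biallelic SNP marker, allele codes in
{0, 1}.  Input VCFs must be fully phased and biallelic; unphased,
missing, haploid or multiallelic records are rejected with an error
rather than repaired.  Multiallelic sites in particular are not
auto-split, because the branch order of a tree depends on the order of
the split records; pre-splitting with standard tools keeps that choice
explicit and reproducible.  Coordinates are 1-based and inclusive
throughout.

### Tree construction

A haplotype sharing tree summarizes *continuous* sharing around a focal
marker.  The root holds every row.  A node scans away from the start
marker; columns where all of its rows agree are absorbed into the
node's shared haplotype, and the first contradictory column splits the
rows into children, each child inheriting the parent's haplotype plus
the contradictory marker with its own allele.  Unidirectional trees
scan one direction and split two ways; the bidirectional tree scans
both directions until a contradiction is found on *each* side (a side
that reaches the data end falls back to a one-sided two-way split, so
trees extend to the contig ends) and partitions rows by their (left
allele, right allele) pair into two to four children.  Branching stops
when a node holds a single row, fewer than `min_size` rows, or the data
ends.  Nodes below `min_size` are still created (so children always
partition their parent) but never expanded; `prune` removes them
entirely, which is also the privacy filter used before publishing a
tree.

Children are ordered by size, largest first, so the leftmost
root-to-leaf path is the majority branch.  Ties are broken by allele
pattern — lower allele code first, lexicographic (left, right) pair for
bidirectional splits — so identical input always yields a structurally
identical tree.  Two further conventions close gaps the verbal
algorithm leaves open: (1) the root always keeps an empty haplotype;
uniform columns scanned from the root (or a single-row matrix) become a
single chain child holding all rows; (2) in the bidirectional scan the
start marker belongs to the rightward side, and the leftward scan
begins one marker below it.  Construction uses an explicit work stack,
never recursion, so cohort-sized trees cannot hit interpreter depth
limits.

### Ancestral and core haplotypes

The majority-based ancestral haplotype is the haplotype of the deepest
majority-branch node still holding at least two rows, including uniform
columns absorbed inside that node but excluding its children's
contradictory markers.  The two unidirectional ancestral haplotypes
both include the start marker and are merged into one, counting the
shared marker once; any overlap disagreement is an error.  The core
haplotype is the maximal contiguous marker run through the start marker
at which *all* rows carry the same allele — in both directions; it is
empty when the start column itself is not uniform.

### Comparison, selection and switch errors

Each row's shared segment with the ancestral haplotype is the maximal
contiguous matching run through the start marker.  Breakpoints are the
positions of the first *mismatching* marker on each side (the
conservative choice; the true recombination event lies between the last
match and that marker).  A run reaching the end of the comparable range
is censored: the flag is carried on the segment and no row is excluded,
since the estimator deliberately uses raw lengths.  Segment length is
carried both in markers (robust to marker density, used for selection)
and in bp/Mb (used for reporting); selection ties fall back to bp
length and then to the first row, with a logged warning.

Per diploid sample, the row sharing the longer segment is kept as the
carrier haplotype.  Runs of at least `min_run` consecutive matches
*beyond* a breakpoint are flagged as suspected switch or genotyping
errors.  The default `min_run` of 20 markers is far above chance
matching at typical array densities (at background allele frequencies
in [0.05, 0.95] the chance of 20 consecutive matches is well below
1e-2 per position); flags are configurable and never auto-corrected.

## MRCA estimation

The genetic length of a carrier's retained founder segment shrinks with
each meiosis.  Under a star genealogy each per-side length is
Exponential(τ) in Morgans, so with n carriers the two-sided sum
S = Σ l_i is Gamma(2n, τ).  The package uses the bias-corrected point
estimate τ̂ = (2n − 1)/S and the exact interval
[q_Γ(2n)(α/2)/S, q_Γ(2n)(1 − α/2)/S], with α = 0.05 by default.
Breakpoint bp positions are translated to centimorgans by linear
interpolation of a PLINK-format genetic map (clamping outside the
mapped range); the single cM→Morgan division by 100 happens in
`segment_genetic_lengths` and nowhere else.  No chance-sharing
correction is applied: background haplotypes that happen to match the
ancestral haplotype past the true breakpoint lengthen l slightly and
bias τ̂ downward; conversely, segments censored at the data ends
shorten l and bias τ̂ upward, which is why analyses (and the demo
pipeline) should use panels several mean segment lengths wide.

The correlated mode relaxes the independence assumption with an
exchangeable pairwise correlation ρ between per-haplotype lengths.
Moment matching gives S an effective gamma shape 2n/(1 + (n − 1)ρ), the
point estimate (shape − 1)·(2n/shape)/S and correspondingly wider
quantile intervals.  At ρ = 0 this reduces *exactly* to the independent
estimator (property-tested); ρ defaults to 0.5 as a conservative
mid-range genealogical correlation and is exposed as a parameter.  This
moment-matched form is this package's own construction; the independent
mode is the tested default, and the correlated mode is pinned only by
its limiting behaviour (reduction at ρ → 0, monotone CI widening in ρ).

Generations convert to years by a plain multiplication (default 25
years/generation).

## Cohort comparisons

Cross-cohort analyses first intersect marker panels on (contig, pos).
Same-position records with swapped ref/alt invert the query's allele
codes; strand flips are rescued by reverse complement; A/T and C/G
markers are dropped because their strand cannot be decided.  Sharing
with a foreign ancestral haplotype is then computed on the intersection
(marker counts over intersected markers only; Mb lengths from
breakpoint positions), with the intersection size always reported.
Comparing a cohort to a tree counts, per node, the query rows matching
the node's haplotype restricted to the intersection; a node whose
restricted haplotype is empty matches vacuously and is flagged
uninformative, and the root, having no haplotype, is reported as not
applicable.  On full marker overlap the self-comparison is an exact
identity (count = node size), and counts are monotone non-increasing
along any root-to-leaf path.

Repeat-class grouping assigns each sample to the bin of its larger
repeat allele (default bins 2–6, 7–9, 10–14, 15–19, 20–45; the shortest
allele class starts at 2 repeats) and reports per-bin mean segment
length and, when a map is supplied, a per-bin MRCA estimate.  Whether
the averages run over all haplotypes or only carrier-selected ones is a
flag, since both summaries are scientifically meaningful.

## The simulator

`simulate_cohort` emulates exactly the inheritance model the estimator
assumes: a founder haplotype drawn from per-marker background
frequencies (uniform on [0.05, 0.95]); per carrier, per side, a
breakpoint at Exponential(τ) genetic distance from the focal locus,
converted to bp through a uniform map (1 cM/Mb by default, so analytic
expectations are exact; any map can be supplied to exercise
interpolation); founder alleles between the breakpoints, background
elsewhere.  Each carrier haplotype is paired with a background
haplotype into a diploid sample on a random strand, controls are
background diploids, and optional switch errors swap the two strand
suffixes of a sample from a random marker on.  Ref/alt pairs are drawn
from non-complementary combinations so cross-array harmonization never
drops simulated markers.  Everything is deterministic given the seed,
and the truth files carry the founder, the exact (continuous)
breakpoints and genetic lengths, and the planted switch positions.

What the simulator does **not** model: background linkage
disequilibrium (markers are independent, so chance sharing is minimal —
matching the no-chance-sharing estimator but flattering it relative to
real LD-rich data), genotyping error beyond switch errors, marker
ascertainment, and genealogical correlation between carriers (the star
assumption).  Tests passing on simulated cohorts therefore validate the
algorithms and the estimator under their stated assumptions, not
robustness to LD-driven chance sharing.

## Problem sizes and numerical choices

The test suite and acceptance script use desk-scale problems chosen as
the package's own verification conditions: 100 random 50×200 matrices
for the tree/oracle equivalence; 50 replicates of 200 carriers × 2,000
markers (τ = 30) for founder recovery; 500 replicates of 100 carriers
(τ = 50) for estimator recovery and CI coverage; a 6,000-marker, 30 Mb
panel for the end-to-end demo so that segments rarely hit the panel
ends.  Replicate seeds derive from a single base seed via numpy's
`SeedSequence`.  Gamma quantiles come from scipy; the test suite
cross-checks them against R's `qgamma` to 1e-9.  Tree serialization
pins the gzip mtime and filename fields so identical trees are
byte-identical on disk.

## Known limitations

- BCF, multi-contig matrices, phasing/imputation and liftover are out
  of scope; inputs must be pre-phased single-contig VCFs.
- The bidirectional tree is shaped more by the side with earlier
  recombinations, and unequal marker density left and right of the
  locus biases its splits.
- Trees only measure *continuous* sharing; at loci without a founder
  haplotype the majority branch walks chance sharing.
- The correlated-genealogy mode is a moment-matched approximation
  parameterized by ρ, not an estimate of genealogical correlation from
  the data.
- Segment censoring at panel ends biases τ̂ upward; the censoring flags
  are reported so users can judge exposure.
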