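# Methods

This note records the models, parameter conventions and numerical choices
behind each module, plus known limitations.

## Homology search and alignment

Local alignment is affine-gap Smith–Waterman on encoded sequences with a
numba kernel; an optional diagonal band restricts the DP when a seed
constrains the alignment's placement. Nucleotide scoring is +2/−3 with gap
open −5 and extend −2; protein scoring is BLOSUM62 with gap open −11 and
extend −1 (the open penalty includes the first extension). Significance uses
Karlin–Altschul statistics with fixed parameters: λ = 0.610, K = 0.35 for the
nucleotide scheme and λ = 0.267, K = 0.041 for BLOSUM62; E = K·m·n·e^(−λS)
with m, n the query and target lengths.

Seeded search builds a k-mer index of the target (word size 11 for
nucleotide, 5 for protein), triggers on one ungapped extension reaching
25 bits (nucleotide) or 22 bits (protein), then runs the banded SW inside a
window around the seeded diagonal. An `exhaustive=True` mode runs the
unseeded DP over the full target and is the oracle used in tests: the seeded
and exhaustive hit sets at E ≤ 0.01 are verified equal on the tested
instances. Like any exact-word seeding scheme, the heuristic can in
principle miss a short borderline hit whose mismatches break every exact
run below the word size (e.g. a 22 nt hit with 2 interior mismatches near
E = 0.01); no finite word size eliminates this, and shrinking the word
multiplies seed noise genome-wide, so the word sizes are fixed and the
exhaustive mode remains available where completeness matters.

Two search directions mirror a blastn/tblastn design:

1. every reference CDS (nucleotide) against each target assembly, both
   strands, keeping hits with E ≤ 0.01;
2. every target protein against the six-frame translation of the reference
   genome, keeping hits with E ≤ 0.01 **and** ≥ 50% identity **and** ≥ 50%
   query coverage. The identity/coverage filters apply to this protein
   direction only.

Protein-direction hits are credited to a reference gene when the hit's
nucleotide span overlaps the gene's CDS by at least half of the shorter
interval.

## Pan-genome

A reference gene is called present in a target genome if either direction
supports it; per-cell evidence (`nt`, `prot`, `both`) is retained. With n
ingroup genomes, the core is the set of reference genes present in ≥ n−1 of
them (one-genome allowance for assembly/annotation artifacts); the strict
core requires all n; the unique core is the core minus genes detected in
either outgroup. A three-way Venn partition over {core, outgroup 1,
outgroup 2} is reported.

## Phylogeny and likelihood

Trees are built by neighbor joining on p-distances or JC-corrected distances
(trifurcating root). The likelihood engine implements GTR+Γ(+I) Felsenstein
pruning: the rate matrix is normalized to one expected substitution per unit
time; eigendecomposition uses the √π similarity transform so a symmetric
solver applies; discrete gamma uses the mean of each of `ncat` quantile
intervals (default 4), rescaled so non-invariant sites have mean rate
1/(1−p_inv). Alignment columns are compressed to unique patterns. Missing
data (gaps/ambiguity) contribute all-ones tip partials.

Branch lengths are optimized coordinate-wise with bounded Brent. For speed,
each edge's objective is expressed through cached inside (below-edge) and
outside (rest-of-tree) conditional likelihoods per rate category, so a trial
length costs one 4×4 contraction per site pattern; partials are refreshed
after every edge update and an update is accepted only if it does not lower
the likelihood, keeping the ascent exact and monotone. Bootstrap support
resamples sites with replacement and counts recovered bipartitions.

## Topology congruence (HGT)

The Shimodaira–Hasegawa test is computed by RELL resampling: per-site
log-likelihood vectors for each candidate topology are bootstrap-resampled
(B ≥ 100, default 1000), replicate totals are centered per topology, and the
p-value of topology T is the fraction of replicates in which the maximum
centered total minus T's centered total reaches the observed ΔlnL. The HGT
procedure builds one topology from the species alignment and one from the
gene alignment (restricted to the ≥ 4 shared taxa), optimizes both sets of
branch lengths on the gene alignment, and reports "incongruent (consistent
with HGT)" when the species topology is rejected at α = 0.05.

## Trait reconstruction

Binary traits use Hartigan's generalization of Fitch parsimony, which is
exact on multifurcating trees (e.g. the trifurcating NJ root); unknown tips
are free. The down pass emits a concrete gain/loss event per state change and
asserts the labelling realizes the parsimony count. Dollo reconstruction
allows at most one origin: the trait is gained once on the edge to the MRCA
of the present tips (or is ancestral, if the root is inferred or forced
present) and lost as needed below; the MRCA is computed by walking up from a
present tip.

## Profile clustering

Functional-category count profiles (optionally normalized to fractions or
z-scores) are clustered by average linkage on Euclidean distances. Cluster
support is pvclust-style multiscale bootstrap: categories are resampled at
scales 0.5–1.4× the original count, bootstrap probabilities per cluster are
fit by weighted least squares to Φ⁻¹(1−BP) = dσ + c/σ, and the AU value is
Φ(c/σ₀ − dσ₀) at σ₀ = 1. Support is reported per internal node of the
dendrogram.

## Growth

OD time series are log-transformed and the growth rate is the slope of the
best exponential window: among contiguous windows of ≥ 4 points with
R² ≥ 0.95, the longest (then steepest) wins. A series must sustain at least
3 population doublings overall to yield a rate; otherwise it is reported as
`no-sustained-growth`. Rate comparisons between strain/treatment groups use
Welch's t-test; groups with < 2 replicate rates are excluded from the family
as `not-comparable`; the remaining raw p-values are Benjamini–Hochberg
adjusted (step-up) within the family.

## Synthetic data generator

One seeded generator produces the full study design: a birth-process ingroup
tree scaled to 0.03 root-to-tip substitutions/site (≤ 10% pairwise
divergence) with two deeper outgroups; ancestral genes evolve by GTR+Γ with
CDS-aware handling that reverts in-frame stop codons; gene gain/loss events
are placed on branches (Poisson rates per gene per unit length); a
plasmid-like block and a 3-gene HGT cassette are transferred from an
outgroup donor to an ingroup clade, plus a secondary within-ingroup
transfer so the cassette's gene tree is topologically distinguishable from
the species tree among carriers. The ingroup tree shape is resampled until a
3-tip clade exists so the cassette has ≥ 4 carriers (the minimum for an
informative congruence contrast). Trait events are placed by rejection
sampling until the implied labelling is the unique minimum-change labelling,
making parsimony recovery well-defined. OD curves follow a logistic model
with lag and a 0.001 floor. Every output is a pure function of the seed;
pipeline reruns are byte-identical.

## Limitations

- Karlin–Altschul parameters are fixed constants for the two built-in
  scoring schemes rather than estimated per scheme; E-values for other
  schemes would need new constants.
- The likelihood engine is nucleotide-only (4 states) and assumes the
  alignment is trusted; there is no alignment-uncertainty handling.
- The SH implementation evaluates the supplied candidate topologies only; it
  does not search topology space, and RELL avoids re-optimizing branch
  lengths per bootstrap replicate (standard, slightly conservative).
- Dollo reconstruction assumes irreversibility of the gain; it is
  inappropriate for traits plausibly gained more than once.
- The AU extrapolation uses scales in a fixed default range; with very few
  categories the normal approximation underlying AU can be coarse.
- The generator's gene gain model plants novel sequence (no duplication
  model), and transfers are single events, so detection power estimates
  generalize only to similar regimes.
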