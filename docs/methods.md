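# Methods

`mttransect` implements the matrilineal (mtDNA) population-transect
analyses used to place an ancient cohort in the genetic history of its
region: within-population diversity, haplogroup-frequency ordination,
sequence-level genetic distances, hierarchical molecular-variance
partitioning with a grouping-optimality search, shared-haplotype lineage
attribution, median-joining networks, consensus quality control and
genetic sexing. This note records the models, the defaults and why, the
numerical choices, and what the synthetic transect generator does and
does not emulate.

## Coordinates and windows

All sequences live on the 16,569-position rCRS coordinate system,
1-based, with windows closed on both ends. Four canonical hypervariable
windows are used, matching the published analysis design:

| window | positions | used for |
|---|---|---|
| HVS-I-diversity | 16033–16365 | haplotype diversity (concatenated with HVS-II) |
| HVS-II | 73–340 | haplotype diversity |
| HVS-I-pi | 16000–16410 | nucleotide diversity |
| HVS-I-distance | 16064–16400 | Fst, AMOVA, haplotype sharing, attribution |

`N` and `-` are both treated as missing for identity comparisons and are
pairwise-deleted in distances and diversity; a configuration flag can
score `-` as a fifth state for uncorrected p-distances only, since the
model corrections are defined on nucleotide states.

## Consensus QC

A consensus base is called at a site when depth ≥ 3 and one base carries
at least a 3/5 read majority; everything else, including sites absent
from the pileup (capture dropout is expected, not an error), is `N`. A
sample fails QC when ≥ 5% of the genome is missing or any `N` falls
inside HVS-I (16033–16365).

## Duplicate individuals

Whole-genome identical pairs are detected by exact string identity
(missing symbols unified). One member of each pair is removed before the
frequency analyses; which member is dropped is a free choice that does
not affect bin frequencies (pair members share a haplogroup), so the
default is the deterministic one — drop the lexicographically later
sample id — overridable by an explicit removal list.

## Diversity

Haplotype (gene) diversity uses Nei's unbiased estimator
HD = n/(n−1)·(1 − Σ p_i²) over the concatenated HVS-I + HVS-II windows,
with Nei's (1987) sampling variance. HD equals the fraction of unordered
individual pairs carrying different haplotypes, which is the oracle the
tests check against.

Nucleotide diversity π is the mean pairwise difference per site over
np 16000–16410 with pairwise deletion; its standard deviation uses
Tajima's (1983) total variance
V(π) = (n+1)/(3(n−1))·π/L + 2(n²+n+3)/(9n(n−1))·π². The estimator behind
a printed "±" is rarely stated in applied reports; Tajima's total
variance is what the standard population-genetics software reports, and
it reproduces the reference cohort's printed values at n = 25, which is
also why the package computes diversity on the deduplicated set by
default (both sets are reported).

## Substitution models

p-distance, JC69, K2P and TN93 are implemented with the customary
closed forms; gamma rate heterogeneity replaces each −ln(w) term with
α(w^(−1/α) − 1). TN93 base frequencies default to the empirical
frequencies of the compared pair and can be fixed explicitly. Distances
are undefined past saturation (log argument ≤ 0); this raises rather
than returning a clamped value. Model choice is configuration — the
package deliberately does not do model selection; the default for the
shipped analyses is the uncorrected p-distance, appropriate for the very
short, closely related HVS fragments involved, with TN93+gamma available
when an external selection step supplies parameters.

## Φst and AMOVA

Pairwise Φst comes from a two-level analysis of molecular variance on
squared model distances with unequal-sample-size coefficients; negative
estimates are reported as 0 (raw values retained for diagnostics), and
Slatkin's linearization d = Fst/(1−Fst) feeds the MDS. The three-level
design partitions variance among groups (σ²_a), among populations within
groups (σ²_b) and within populations (σ²_c):

    Fct = σ²_a/σ²_T,  Fsc = σ²_b/(σ²_b+σ²_c),  Fst = (σ²_a+σ²_b)/σ²_T.

Permutation nulls follow the customary schemes — individuals among
populations for Fst, individuals among populations within groups for
Fsc, whole populations among groups for Fct — with the positively biased
estimator p = (1+x)/(N+1) so p is never zero. Permutation counts are
configurable; the shipped runs use 99–999 rather than 10,000 to keep the
default analysis interactive, which widens the attainable p floor but
does not change any point estimate.

A grouping is "optimal" when Fct is maximal and Fsc minimal. No single
scalar combines the two objectives, so the search reports the Pareto
front over (max Fct, min Fsc) and ranks the nondominated candidates by
Fct, ties broken by Fsc — a documented interpretation, configurable.
Candidate partitions come from input files in the conventional
`(A,B) + (C,D)` notation or from an enumerator that respects locked
population blocks (e.g. an Early/Middle-Neolithic block forced into one
group). The squared-distance matrix is computed once per search and
shared across candidates.

## Lineage attribution and sharing

Haplotype identity is exact string match over np 16064–16400. Each focal
haplotype is attributed to the earliest chronological stratum
(HG < EN < MN < LN < EBA < IA) containing an identical haplotype among
the reference populations; ties within a stratum list every carrier
population; haplotypes matching nothing are "novel". Percentages are
over distinct focal haplotypes (not individuals). The LN/EBA summary
reports, among haplotypes attributed to LN/EBA or earlier, the share
present in ≥ 1 named LN/EBA population and in all members of a named
triple, plus the share of all focal haplotypes absent from every LN/EBA
population. Any chronology weighting beyond era order is out of scope.

## Median-joining networks

The network starts from the ε-relaxed minimum-spanning network over
collapsed observed haplotypes (an edge of weight w is feasible if its
endpoints are disconnected using edges of weight < w − ε; ε defaults
to 0). Quasi-median vectors of triplets adjacent in the network are
inserted iteratively when their links do not exceed the current feasible
weight plus ε; sites where the three states are all different keep the
first sequence's state (a deterministic simplification of the full
quasi-median set, which matters only for highly reticulate data).
Latent nodes of degree ≤ 1, and degree-2 latent nodes that shorten
nothing, are pruned, and the final network is the minimum-spanning
network over the augmented node set — hence it always contains a minimum
spanning tree of its nodes, and of the observed haplotypes whenever no
medians were needed. Sites with missing symbols are excluded with a
logged count. All tie-breaking is lexicographic, so output is invariant
under input reordering.

## Genetic sexing

Ry = nY/(nX+nY) over sex-chromosome reads (mapping-quality filtering is
upstream; counts are the input). Samples under 3,000 sex-chromosome
reads are not called. The default calls M when the 95% interval
Ry ± 1.96·SE lies entirely above 0.075 and F when entirely below 0.016 —
the cited method's thresholds; the ratio rule and the 3,000-read floor
are fixed by the analysis design, the thresholds are configurable, and
point-estimate gating is available.

## The synthetic transect generator

The generator plants, rather than simulates, the structures the analyses
measure: founder haplotypes are defined by disjoint variant motifs on a
seeded synthetic 16,569-base backbone, populations draw founders from
era-ordered pools (optionally via haplogroup-bin target frequencies),
and individual private mutations are Poisson(μ·L) at non-motif sites so
haplogroup labels and founder identity stay truthful. Because motifs are
disjoint, pairwise differences are sums of motif sizes and the planted
diversity is exact, not merely expected.

The shipped demo transect emulates the focal study conditions: 27
Iron Age individuals (25 distinct haplotypes plus two whole-genome
duplicate pairs), ten era-tagged reference populations (HG through EBA)
sharing founders along the era order, and three-carrier background
lineages per reference population so between-population distances are
non-degenerate. The founder motif sizes (sixteen founders with 3 variant
sites, nine with 4, all within np 16070–16360) were chosen analytically
so the deduplicated cohort reproduces the reference values this kind of
cohort prints: HD = 1.0 with Nei sd 0.0113 and π = 2·84/(25·411) =
0.016350 (within 0.6% of the reported 0.016263). The planted attribution
fractions are the closest integer-representable design at 25 focal
haplotypes: EN 44%, MN 20%, HG 16%, LN 12%, EBA 8%; 80% of inherited
haplotypes occur in ≥ 1 LN/EBA population, 28% in all of the named
triple, 20% of focal haplotypes in none.

What the generator does **not** emulate: post-mortem damage and
contamination, sequencing error, phylogenetic realism within haplogroups
(founders are star-like around the backbone), recombination-free
coalescent genealogy, and real haplogroup-geography covariance. Passing
tests on generated data therefore demonstrate correctness of the
estimators and the pipeline plumbing on data with known truth — they do
not validate inferences about any real population.

A separate planted-structure transect (three groups of populations with
six group-defining sites each) gives the AMOVA grouping search a ground
truth; recovery of the planted partition is part of the acceptance
checks.

## Problem sizes and determinism

The shipped analyses run at deliberately interactive sizes: 1,000
bootstrap replicates for Ward clade support (the classical reference
uses 10,000), 99–999 permutations for p-values, 102 individuals in the
demo transect, 122 enumerated candidate partitions for the demo search.
Every stochastic step takes an explicit seed, bootstrap resampling of
within-population individuals is implemented as a multinomial redraw of
bin counts (equivalent and fast), PCA component signs are fixed by
making each component's largest-magnitude loading positive, and the
non-metric MDS takes the best of one classical-scaling start plus random
restarts, so repeated runs are byte-identical.

## Known limitations

* Ward linkage on non-Euclidean dissimilarities (the Manhattan option)
  uses the Lance–Williams update on the given dissimilarities — the
  standard heuristic, not a centroid-consistent method.
* Bootstrap clade support is the plain bootstrap proportion; no
  multiscale/AU correction.
* The quasi-median simplification above can omit median candidates on
  three-state sites; for HVS-scale data this is rarely reachable.
* The grouping search is exhaustive over supplied candidates only; the
  enumerator caps the candidate count rather than sampling.
* π's variance formula assumes no recombination (appropriate for mtDNA)
  and complete windows; pairwise deletion makes L an average.
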