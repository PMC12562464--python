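# Methods

## Data model

A `LocusPanel` fixes an ordered set of Y-STR markers with per-locus mutation
rates.  The default panel is the union of the Yfiler Plus and PowerPlex Y23
marker sets plus eight further single markers: 35 named loci of which two
(DYS385, DYF387S1) carry two repeat values each, i.e. L = 37 repeat values.
The default rate is a uniform μ = 0.0039 mutations/locus/generation — the
published average for panels of this size — and the generation interval is
31.5 years.  Both are configuration, not constants: per-locus rates and any
panel file can be supplied.  Exactly which 37 markers enter the published
average rate is not fixed by the kits alone, so the shipped panel is a
reconstruction and deliberately user-overridable.

Repeat values are stored as positive integers; two-copy markers as unordered
pairs, expanded internally into two sorted columns so that column-wise
comparison realizes the minimum-cost assignment between the multisets.
Intermediate (fractional) alleles such as "15.2" are treated as missing at
that locus and logged — never rounded — because a step metric is undefined
for partial repeats.  A locus missing in either haplotype is skipped in
distances and in ASD, with the locus count rescaled to the compared columns;
this preserves per-locus averaging without imputation.

## Median-joining networks

Distances are weighted single-step counts, `d(a,b) = Σ_l w_l |a_l − b_l|`,
uniform weight 10 by default.  The construction iterates:

1. an ε-relaxed minimum spanning network over the current states — an edge
   enters iff its length is within ε of the minimax-path distance between
   its endpoints (for ε = 0 this is exactly the union of all minimum
   spanning trees, computed from one MST by the cycle property);
2. candidate medians: the per-locus median of every state triplet connected
   in that network (the classical feasibility rule; full quasi-median
   closure is deliberately out of scope);
3. candidates are processed in ascending connection-cost order and inserted
   whenever insertion strictly shortens the minimal spanning length
   (computed incrementally: the new MST is contained in the old MST plus
   the new node's star);
4. at a fixed point, obsolete inferred nodes are pruned: medians of network
   degree ≤ 1, and pass-through medians whose two neighbours are as close
   directly, iterated until stable.

All tie-breaks are lexicographic on canonical state labels, so results are
invariant under permutation of the input samples.  The number of inferred
medians is capped at 3× the number of distinct observed states — a
numerical bound that matters only for extremely diverse inputs.  The
closed-source desktop tool that popularized this construction does not
document its post-processing; this implementation is a faithful
reconstruction of the published algorithm, not a bit-exact clone.

**Parsimony resolution.**  Reticulations are resolved by a deterministic
minimum spanning tree over the network's edges (Kruskal with lexicographic
tie-break), which attains the minimum total length over all spanning-tree
resolutions — verified against exhaustive enumeration on small instances.
The tree is rooted at the cluster founder.

**Founder inference.**  The founder is the network node (observed or
median) minimizing the multiplicity-weighted sum of distances to the
observed members.  If an ancient sample's node scores within one mutation
step of the optimum it is preferred: an ancient state is direct evidence of
the ancestral haplotype.  Founder inference from modern data is slightly
biased toward the sample cloud, which makes both clocks mildly conservative
(younger); the dating calibration below therefore separates estimator
behaviour (true founder) from pipeline behaviour (inferred founder).

## The two clocks

With founder state f, members x_1..x_n and compared columns L′:

- **ASD**: `ASD = (1/L′) Σ_l mean_i (x_il − f_l)²`, age
  `t = ASD / mean(μ)` generations.  Under the symmetric single-step SMM the
  net displacement after t generations is Skellam(μt/2, μt/2) per locus, so
  `E[ASD] = μt` exactly — ASD is unbiased at any age.  Its SE comes from a
  seeded bootstrap over loci (1000 resamples by default).
- **rho**: `ρ` = multiplicity-weighted mean mutation count on root-to-tip
  paths of the parsimony tree; `t = ρ / (L·mean(μ))`;
  `σ_ρ² = (1/n²) Σ_branches m_b n_b²` (genealogy/Saillard-type SE, the
  standard choice where no SE formula is otherwise specified).

Whether published "±" values are SEs or intervals is often unstated; this
package emits standard errors and labels them as such.  Ages are years
before the analysis date — no calibration offset.  A pairwise (founderless)
ASD variant is available behind a flag for comparison; the founder-based
form is the primary estimator, matching the convention of dating clusters
from an ancestral node.

**Known limitation — rho saturation.**  rho counts *observed* steps, so a
back mutation on a single lineage is invisible.  The expected observed
fraction `E|Skellam(μt/2, μt/2)| / μt` falls below 1 as μt grows: with
μ = 0.0039 the downward bias of rho is ≈3–7% at 1000 y, ≈9–11% at 2000 y
and ≈14–15% at 3000 y (measured on 200 simulated star genealogies per
condition in the acceptance suite; path lengths through inferred medians
recover a little of it at larger n).  ASD shows no such bias.  No
saturation correction is applied — the method is reported as practiced —
but old rho ages should be read as conservative, and the screening filter
uses the *minimum* of the two clocks precisely so that optimistic ages
never admit a cluster.

## Informative-cluster screen

A cluster is informative iff (1) every required population group (default:
one Slavic-labeled and one Finnic-labeled group) is represented by at least
one member, and (2) min(ASD age, rho age) exceeds the threshold (default
1000 years BP, from the colonization horizon; configurable — it is a
parenthetical bound, not a calibrated date).  Taking the minimum of the two
point estimates is the conservative reading of "dated before the horizon":
both clocks must agree the cluster is old.  The screen is monotone in both
criteria.  Cluster delimitation defaults to terminal Y-SNP labels, which is
how such clusters are validated in practice.

For data without fine SNP labels a **subtree mode** is provided (our
addition, clearly flagged as such): the group's parsimony tree is re-rooted
at its Jordan centroid — the node minimizing the largest remaining
component by sample multiplicity — and each root-adjacent subtree with at
least 3 samples becomes a cluster; smaller offshoots and the root's own
samples form the root cluster.  Centroid rooting (rather than founder
rooting) keeps distinct radiations in distinct subtrees when the
distance-minimizing founder falls inside one radiation; the 3-sample floor
absorbs the root's own satellite states but also means clusters smaller
than 3 cannot be delimited in this mode.  On three planted star radiations
with founders ≥ 6 steps apart this recovers membership with ~95% mean
agreement (100 replicates in the test suite).

## Frequency statistics and maps

Pooled frequencies are sample-size-weighted means reported at one decimal.
The chi-square homogeneity test is Pearson's on the group × haplogroup
count table; categories whose pooled expected count is below 1 are merged
into "other" first (our rule; the approximation is unreliable in sparse
cells).  Frequencies are carried as percentages end to end to match how
such tables are printed, and cells above 100% are flagged rather than
guessed at (decimal-point misprints occur in print).

Frequency surfaces use average-weighted (inverse-distance) interpolation:
weights `1/max(d, d_floor)^power` over observations within the search
radius (defaults 400 km, power 2), with the distance floor at half the
grid spacing to keep coincident points finite — the reference desktop
implementation's internal handling is unpublished, so the floor is our
documented choice.  Grid cells with no observation in radius are NA.
Output is a plain lon/lat/value raster; no GIS dependency.

## Synthetic data

The simulators implement the symmetric single-step SMM: per generation and
locus a mutation occurs with probability μ and moves the repeat count ±1
with equal probability.  No multi-step mutations, allele-range constraints
or rate heterogeneity beyond the per-locus rates — the idealization under
which μ-based dating is calibrated.  Mutation counts per lineage and locus
are drawn Poisson(μt) with a signed random walk of steps (distributionally
equivalent to per-generation simulation for μt ≪ 1 and far faster); the
exact per-generation mode is retained behind a flag and agrees in its
moments.  The coalescent generator uses haploid Kingman scaling
(coalescence rate k(k−1)/2 per Ne generations, so E[TMRCA] = Ne generations
for n = 2) with Poisson mutations on branches.

The regional scenario emulates the screening study's conditions: ~400
haplotypes on the 37-value panel; one Slavic-labeled population and three
Finnic-labeled subgroups (60/29/11 relative weights); ten informative
clusters with true ages uniform on 1600–2900 y and sizes 15–45; two young
mixed decoys (ages 150–550 y) and two old single-population decoys (sizes
15–35); founders pairwise ≥ 6 mutation steps apart; cluster branch labels
distributed over five search groups.  Mixed clusters draw each member's
group with a per-cluster Slavic fraction uniform on 0.30–0.60 and force at
least one member from each group, so planted informative clusters satisfy
the screen's membership criterion by construction.  All randomness flows
from one seeded generator recorded in the output provenance.

What the generator does **not** emulate: population structure within
clusters, SNP genotyping error, locus dropout, multi-step mutations, and
the shared internal branching of real genealogies inside clusters (planted
clusters are star radiations).  Passing tests therefore demonstrate the
pipeline's correctness under the model that justifies its clocks, not its
robustness to every artefact of real data; the coalescent generator exists
precisely to probe the star assumption separately.

## Numerical and reproducibility choices

- All tie-breaks (MST edges, candidate medians, founder scores, BFS child
  order) are lexicographic on canonical state labels; pipelines rerun
  byte-identically under a fixed seed and configuration.
- The ASD bootstrap seed is an explicit, logged parameter.
- Distances, medians and MSTs are computed on dense numpy matrices with an
  absolute tolerance of 1e-9 for equality of integer-valued lengths.
- Degenerate inputs: single-state clusters date to age 0 with their own
  state as founder; samples without a SNP label fall into an "unassigned"
  bin with a warning; empty tables, duplicate sample ids and negative
  repeat counts are errors.
- Problem sizes in the test and acceptance suites (200 replicates per
  recovery condition, 50 scenario seeds, 100 subtree replicates) were
  chosen to keep Monte-Carlo error well below the effect sizes being
  checked while the whole suite stays fast on a single CPU.
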