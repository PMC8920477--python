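# Methods

This note documents the models and procedures implemented in `humgut`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Community dissimilarity

All comparisons are membership-based. Counts are rarefied to a common depth
by uniform subsampling without replacement (multivariate hypergeometric, the
convention of standard rarefaction tools), with an explicit seed; samples
below the depth are dropped and reported rather than silently discarded.
ASV columns that become all-zero are retained so column indices stay stable
across stages — presence/absence statistics are unaffected by empty columns.

The binary Sorensen–Dice dissimilarity d(A,B) = 1 − 2|A∩B|/(|A|+|B|) is
computed on presence sets. A pair of empty communities is defined to be at
distance 0 (indistinguishable); the case cannot arise after rarefaction,
which guarantees non-empty samples, but the definition keeps the matrix
total on degenerate inputs.

PCoA is classical metric scaling: Gower-center the squared distances
(−½ J D² J), eigendecompose, scale eigenvectors by √eigenvalue. No
Cailliez/Lingoes correction is applied; negative eigenvalues are reported so
users can judge the distortion, and their axes are simply omitted from the
coordinates. Axis signs follow a fixed convention (first non-negligible
loading positive) so output is reproducible across BLAS implementations.
Proportion explained is computed over the sum of the positive eigenvalues.

## Phylosymbiosis

Family profiles are produced by *mean-ceiling* grouping (ceil of the
arithmetic mean of member counts per ASV), then binarised. Humans are always
collapsed into a single Hominidae profile; by default the mean is over all
human individuals, with an option to average the per-population means first
(the two differ when populations have unequal sizes — the choice is exposed
because neither is canonical).

UPGMA clusters the profile distance matrix with unweighted average linkage
(the mean over all cross pairs, maintained by the size-weighted
Lance–Williams update) and places each merge node at half the merge
distance, giving an ultrametric dendrogram. Ties are broken by the
lexicographic order of each cluster's smallest member label; this makes
dendrograms deterministic where generic implementations are
platform-dependent.

Congruence with the host phylogeny uses the **rooted** Robinson–Foulds
distance: the symmetric difference of the two trees' sets of non-trivial
clades (singletons and the full leaf set carry no information and are
excluded). The score is normalised by the total clade count of both trees —
2(n − 2) for two binary trees on n leaves — giving a hard [0, 1] range with
0 = identical clade sets. An alternative normalisation by the mean RF of
random tree pairs is provided (`random_pair_normalized_rf`) since some
tree-comparison tools report that form; it is not bounded by 1 and is not
the default.

The null distribution is the normalised score of `n_random` random rooted
topologies against the host tree. Two null generators are available:
uniform sequential coalescence (each step merges a uniformly chosen pair of
lineages; the default) and leaf-label shuffles of the observed dendrogram
(which preserve its shape). The p-value uses the add-one (permutation)
correction p = (1 + #{null ≤ observed})/(1 + n_random), so p > 0 always;
the uncorrected #{null ≤ observed}/n_random is also reported because some
published analyses use the plain convention.

## Humanization tests

For each family the distances captive-to-human and wild-to-human are
compared by a pooled-variance two-sample t statistic, with significance from
Monte-Carlo permutation of the pooled distances (re-split into the original
group sizes; 999 permutations by default). Both tails are available:
two-sided (default) and the directional "captive-lower" tail, which is the
humanization hypothesis. Degenerate inputs are defined explicitly: both
groups constant with equal means gives t = 0 (p = 1); constant with unequal
means gives signed infinity.

**Caveat — the permutation unit.** Permuting individual pairwise distances
treats the n_samples × n_humans distances as exchangeable, but distances
sharing a mammal sample are positively dependent. The test is therefore
liberal when the number of samples per group is small. Measured on the
generator's default conditions (5 wild / 5 captive per family), the
captive-lower tail flags untouched families at a rate of about 0.23 at
α = 0.05 — roughly 4–5× nominal. The package therefore also provides a
sample-label permutation mode (`permute="labels"`), which shuffles
wild/captive status within the family and rebuilds both distance lists per
permutation; this mode is calibrated (measured ≈ 0.03 at α = 0.05) and is
the recommended sensitivity check before interpreting borderline p-values
from the classic distance-unit mode. Planted humanization signals at
h = 0.3 are detected by the distance-unit test in ≥ 99% of replicates, so
power is not the concern; false-positive control is.

## Sharing classification

Within a family, an ASV's category is a pure function of three presence
bits: present in ≥ 1 wild sample (W), ≥ 1 captive sample (C), ≥ 1 human
sample (H), all assessed post-rarefaction. `captive_human_exclusive`
(C ∧ H ∧ ¬W) is the transfer signature; the mirror category
`wild_human_exclusive` is its control. No abundance or prevalence floor is
applied by default (a configurable minimum prevalence exists for sensitivity
analysis). Taxon-restricted counts first subset columns by exact,
case-insensitive match at one lineage rank — deliberately not substring
matching, so Silva labels like "Clostridium sensu stricto 1" and "… 13" are
never merged.

## Synthetic data generator

The generator emulates a multi-family survey with two planted signals.

*Phylosymbiosis.* A host tree over the mammal families plus Hominidae is
drawn by a uniform coalescent (exponential waiting times) and rescaled to
height 1. Each ASV's presence evolves independently along it as a two-state
continuous-time Markov chain with gain and loss rates per unit branch
length; the root state is stationary (gain/(gain+loss), 0.5 when both rates
are 0). Low rates make closely related families share more ASVs, which is
exactly the signal the phylosymbiosis test measures. Presence/absence CTMC
was chosen over abundance Brownian motion because every downstream statistic
is membership-based.

*Humanization.* The last `n_human_pool` ASVs are forced absent from every
family repertoire and present in every human sample; each captive sample of
family F additionally acquires each pool ASV independently with probability
h(F). Pool bits are never touched by presence noise, so pool sharing is
unambiguous ground truth (`leak_rate` deliberately relaxes the disjointness
for robustness experiments). Per-sample noise flips each non-pool bit with
probability 0.01, mimicking individual repertoire variation.

*Counts.* Present ASVs get log-normal relative abundances (σ =
`abundance_dispersion`, default 1.0) and counts are multinomial at `depth`,
so low-abundance ASVs are stochastically lost exactly as in real rarefied
data. The `min_one_read` option instead guarantees every present ASV at
least one read (requires depth ≥ per-sample richness); it exists so that
exactness tests of the sharing classification have a regime with no
presence loss.

Defaults — 8 families, 5 wild + 5 captive each, 20 humans (3 populations),
2,000 ASVs, gain = loss = 0.3, pool of 300 ASVs, depth 1,000, first four
families humanized at h = 0.3 — reproduce the small-group regime of real
multi-family surveys (family sample sizes of order 2–30) at a scale where
the full pipeline runs in under a second. The pool size (15% of ASVs) and
dispersion were fixed once as plausible for human-associated gut taxa; they
are configuration, not fitted values.

What the generator does **not** emulate: sequencing error and chimeras (no
read-level simulation), compositional count correlations beyond the shared
multinomial constraint, abundance phylogenetic signal, within-family host
structure, or uneven group sizes (configurable but uniform by default).
Passing the synthetic benchmarks therefore demonstrates correctness of the
statistics and recoverability of membership-level signals, not performance
under real-world noise sources the generator omits.

## Pipeline and reproducibility

`run_pipeline` executes rarefaction → presence/absence → Sorensen–Dice →
PCoA, the two condition dendrograms and phylosymbiosis tests, the per-family
humanization scan, and the sharing classifications, writing TSV/newick/JSON
outputs plus a run log of versions, seeds and applied defaults. One master
seed spawns independent substreams (`numpy.random.SeedSequence`) for
rarefaction, random trees and permutations, so stages are individually
reproducible and reordering one does not perturb another. Outputs contain no
timestamps; two runs with the same configuration are byte-identical
(hash-checked in the test suite).

Validation runs before any computation: samples present in the table but
missing from metadata, and metadata families missing from the host tree,
are fatal; orphan metadata samples, empty strata and missing taxonomy are
warnings.

## Test and benchmark problem sizes

The oracle checks use exhaustive or brute-force references: all 105 rooted
binary topologies on 5 leaves (RF), naive re-averaging average linkage on
100 random 6 × 6 matrices (UPGMA, heights to 1e−10), and the set formula on
200 random binary tables (Sorensen–Dice, exact). Calibration uses 200
null-phylosymbiosis replicates (500 random trees each, one-sided KS at
α = 0.01) and 2,000 i.i.d.-normal permutation tests (199 permutations,
rejection rate vs. the 5% level). Signal recovery uses 25 replicates for
phylosymbiosis (1,000 random trees, p ≤ 0.01) and 3 × 50 replicates for
humanization (999 permutations) across h ∈ {0, 0.1, 0.3}. These sizes keep
the whole battery under a minute while leaving Monte-Carlo error well below
the asserted margins.

## Known limitations

- The distance-unit permutation test is anti-conservative at small group
  sizes (see above); its p-values should be read jointly with the
  label-permutation mode.
- Rooted-RF congruence is coarse on few leaves: with 8–9 families the
  normalised score takes only a handful of values, so the null p-value is
  discrete and the add-one correction matters.
- Mean-ceiling collapsing makes a family profile's presence set the union of
  its members' presences; rare per-sample noise therefore accumulates into
  profiles as family size grows.
- BIOM support covers the JSON (1.0) flavor only; HDF5 BIOM files should be
  converted upstream.
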