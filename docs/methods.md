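# Methods

This note documents the models implemented in `omuecol`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the design decisions taken where more than one reasonable
construction existed.

## Near-neutral model (`omuecol.sloan`)

### Model

Local communities of size `I_T` assemble from a source community by
births, deaths and immigration. The probability that OMU *i*, at local
abundance `I_i`, gains or loses one individual in one step is

    Pr(+1) = (1 − I_i/I_T) [ m p_i + (1 − m) I_i/(I_T − 1) ]
    Pr(−1) = (I_i/I_T) [ m (1 − p_i) + (1 − m)(I_T − I_i)/(I_T − 1) ]

with `p_i` the source-community frequency and `m` the immigration
probability. In the diffusion limit the stationary law of
`x_i = I_i/I_T` is `Beta(I_T m p_i, I_T m (1 − p_i))`.
`simulate_birth_death` implements the chain exactly (asserting at every
state that the three transition probabilities sum to 1) and is the
package's internal oracle for the closed form: the lattice chain at
`I_T = 50` matches the beta CDF to Kolmogorov distance < 0.05 after 10^5
post-burn-in steps. Because the chain lives on `I_T + 1` atoms, the
comparison applies a midpoint continuity correction (empirical CDF at
the atoms against the beta CDF at atom midpoints); without it the atom
jumps alone contribute ≈ pdf/(2 I_T) of spurious distance.

### Fitting

`estimate_m` minimizes the squared error between the observed occurrence
frequency `x_i` (fraction of samples where OMU *i* has a nonzero count)
and the model's expected occurrence frequency as a function of the mean
relative abundance `p_i`. The community size is `N_T` = mean sample read
total; `m` is the single free parameter, found by bounded scalar
minimization probed from three starts (deterministic).

Two detection models are available:

* `reads` (default). A sample of `D = round(N_T)` reads is drawn from the
  local community, so the OMU is missed only when all `D` reads miss it.
  Marginalizing over the beta law gives the exact closed form
  `F(p) = 1 − B(a, b + D)/B(a, b)`, `a = N_T m p`, `b = N_T m (1 − p)`.
  This is the correct observation model for count tables produced by
  sequencing at finite depth; on synthetic read tables it recovers the
  generating `m` to within a few percent for `m` between 0.1 and 1.
* `threshold`. The classical form `F(p) = 1 − BetaCDF(d; a, b)` with a
  hard detection limit `d = 1/N_T`. It treats detection as a sharp cut
  on the latent relative abundance; on read-sampled tables this
  mis-specification biases `m̂` upward by roughly a third at `m = 0.3`,
  which is why it is not the default. It is retained because it is the
  standard fit in the occurrence-frequency literature and appropriate
  when the table's entries are not read counts.

OMUs never observed across all samples carry no information about the
occurrence curve; they are excluded from the fit and reported separately.

### Classification

Each fitted OMU is called **neutral** when its observed occurrence
frequency falls inside the central 95% band of
`Binomial(n_samples, F(p_i))/n_samples` (bounds inclusive),
**above-neutral** above the band, **below-neutral** below it. The band is
an exact prediction interval for an observed proportion, not an
estimation interval: a Wilson score interval (available as
`method="wilson"`) under-covers at predicted frequencies near 0 and 1 —
e.g. with `F = 0.99` and 100 samples the Wilson upper bound excludes the
observable value 100/100 and mislabels ~25% of a purely neutral
assemblage as above-neutral, while the binomial band keeps the neutral
fraction of pure-neutral simulations at ≈ 95–100%. Observed frequencies
exactly on a bound count as neutral.

`fit_source_to_destination` repeats the fit with `p` taken from one
treatment (source) and `x` from another (destination), outer-joining the
OMU id spaces with zeros.

## Stochasticity ratio (`omuecol.nsr`)

Ružička similarity between two samples' relative-abundance columns is
`Σ min / Σ max`; it is 1 exactly for identical relative-abundance vectors
and 0 for disjoint supports. Two all-zero columns are defined to have
similarity 0 (with a warning).

### Null model

`null_expected_similarity` simulates metacommunities in which assembly is
purely stochastic *given the regional pool*: each sample keeps its
observed richness and read total; its occupied OMUs are re-drawn without
replacement with probability proportional to regional occurrence
frequency; its reads are then distributed multinomially over the
occupants proportionally to regional mean relative abundance. `Ē` is the
mean pairwise Ružička matrix over the simulated draws (default 1000;
analyses at desk scale use 50–200, where two independent 150-draw batches
agree to < 0.05 per pair).

The alternative null that permutes each sample's observed abundance
multiset over the drawn occupants is available as
`null_model="permute"` but is not the default: by destroying the shared
regional abundance profile it makes even dispersal from a common source
pool look deterministic (fully neutral simulations score NSR ≈ 0.2 under
it, versus ≈ 0.7–0.9 under the regional null), inverting the statistic's
intended meaning.

### SR and NSR

For each sample pair, `C > Ē` (determinism toward similarity) contributes
`SR^A = Ē/C`; `C < Ē` (determinism toward dissimilarity) contributes
`SR^B = (1 − Ē)/(1 − C)`; ties contribute 1 and are booked as type A.
SR is the mean over contributing pairs and equals 1 when every observed
similarity matches its null expectation, 0 when similarity is observed
where none is expected. Pairs whose branch denominator vanishes are
excluded with a warning.

The normalized ratio rescales each pair by its distance to the
deterministic extreme — `NSR_ij = (1 − C)/(1 − Ē)` for type A pairs and
`C/Ē` for type B — and averages; each pair contributes a value in [0, 1]
that is 1 exactly at `C = Ē`, so NSR is bounded by construction and does
not inherit SR's known overestimation of determinism when `Ē` is close
to 0 or 1. The final value is clamped to [0, 1] defensively.

`compare_nsr` evaluates three schemes for a treatment pair — intra-
healthy, intra-diseased, and inter (cross-treatment sample pairs of the
pooled metacommunity only).

## Co-occurrence networks (`omuecol.networks`)

Edges are Spearman rank correlations between OMU rows, tested over all
pairs, Benjamini–Hochberg adjusted, retained at `q ≤ α` (default 0.05)
with their sign; constant rows are excluded with a warning. Edge weights
for path computations are `1/|ρ|`, so strongly correlated OMUs are
"close".

### Core/periphery

The ideal core/periphery graph has a fully linked core and a periphery
fully connected to the core with no periphery–periphery links, i.e.
ideal adjacency `P_ij = 1` iff *i* or *j* is core. The raw match score
`ρ = Σ A_ij P_ij` is reported, but the quantity maximized is the Pearson
correlation between the off-diagonal entries of `A` and `P` (the
normalized core strength): the raw sum is maximized trivially by
declaring every node core, so it cannot serve as the objective. A
variant flag treats the core–periphery block as "don't care" for
sensitivity analysis.

Search is exhaustive over all non-trivial membership vectors for graphs
up to 12 nodes (this doubles as the test oracle) and simulated annealing
above (geometric cooling 0.995, 200·n proposals, greedy refinement, 5
restarts, seeded and deterministic). Reported block properties: 2×2
block densities, core/(core+periphery) ratio, NODF nestedness (row- and
column-pair percentage overlap of sparser into denser, ties scoring 0),
and the positive/negative link ratio per block.

### Link salience and skeleton

For each root node *x*, the shortest-path tree `T(x)` contains every
edge lying on at least one minimum-weight path from *x* (the "tight
edge" / shortest-path-DAG criterion `d(x,u) + w(u,v) = d(x,v)` up to
relative tolerance 1e−9). Salience `s_ij` is the fraction of roots whose
tree contains the edge; roots are the nodes of the edge's connected
component, keeping `s ∈ [0, 1]` on disconnected graphs. The
at-least-one-path reading avoids an arbitrary predecessor tie-break and
lets an exhaustive path-enumeration oracle verify the implementation
edge-for-edge. Salience is invariant to rescaling all weights.

The skeleton keeps edges with `s ≥ s*` (default 0.9; empirical salience
distributions are bimodal near 0 and 1) and reports the skeleton
fraction, salience moments, and degree assortativity of both the full
network and the skeleton subgraph (both, because either convention is
encountered in practice).

## Trio motifs and PN ratio (`omuecol.motifs`)

The most abundant OMU (MAO) is the row with maximal total abundance
(occurrence count for presence/absence tables; lexicographic
tie-break). Connected 3-node subgraphs are censused in two modes:
**member** (MAO inside the trio) and **handle** (MAO outside but
adjacent to at least one trio node). Classes are keyed by topology
(chain/triangle), the MAO's position (central or terminal in a chain)
and the edge signs: 6 member triangles × 3 MAO-central chains × 4
MAO-terminal chains = 13 distinguishable member classes, plus
topology-by-sign-multiset handle classes. The catalog is data-driven;
unknown keys land in an explicit `unclassified` bucket rather than being
dropped. The PN ratio is simply `n_positive/n_negative` with an infinity
sentinel when no negative links exist.

## Randomization tests (`omuecol.randomize`)

* **A2 (remix of samples)** pools the two treatments' samples and
  reassigns labels at random preserving group sizes; every sample column
  survives exactly, so any label-blind statistic is invariant.
* **A1 (remix of OMUs)** permutes, within each sample, which OMU id
  carries which abundance; each sample's abundance multiset and total
  are preserved. (The algorithm named "remix of OMUs" in the literature
  this follows is not specified in detail; this within-sample
  permutation reading is an interpretation and is labeled as such.)

Pseudo p-values use the add-one estimator
`(1 + #{|null| ≥ |observed|})/(1 + B)` (two-sided on the difference;
never exactly zero). Under the null generative law the type-I rate at
nominal 0.05 calibrates to 0.02–0.08 over 100 replicates at B = 200.
Default B = 1000; the statistic failing on more than 10% of permutations
aborts the test.

`shared_core_periphery` recomputes networks and core/periphery splits on
every permuted pair and reports decline and rise pseudo p-values per
category (core, periphery, total); `fast=True` instead permutes node
labels of the fixed networks, a labeled approximation for large B.
`integrate_sloan_cpn` splits the table into core-OMU and periphery-OMU
subtables and runs the neutral-model classification independently on
each; a side with fewer than 5 OMUs is skipped with a warning.

## Synthetic assemblages (`omuecol.simulate`)

The generator emulates, with known ground truth:

* a lognormal source community (σ = 2 on the log scale by default —
  several orders of magnitude of abundance heterogeneity, typical of
  functional-unit profiles; σ = 0 degenerates to uniform);
* neutral local communities: per-OMU beta draws
  `Beta(I_T m p_i, I_T m (1 − p_i))`, jointly renormalized per sample,
  then multinomial read sampling at the target depth. The marginals of
  the beta law do not define a joint distribution, so renormalization is
  the simplest consistent choice; it distorts the marginals by the
  relative sd of the per-sample sum (small for hundreds of OMUs);
* planted selection on the occurrence axis: above-neutral OMUs have zero
  cells re-seeded at rate `boost`; below-neutral OMUs have occupied
  cells zeroed at rate `suppress` with the removed reads redistributed
  over surviving cells (row totals preserved), so the planted signal
  lives where the classifier looks;
* within-function competitive turnover (`plant_functional_turnover`):
  paired members of a redundant function re-split their joint abundance
  per sample by a `Beta(switching, switching)` weight, leaving every
  functional aggregate bit-identical while members acquire strong
  presence/absence turnover. This is the mechanism used for the
  coarse-graining experiments: gene-level rows classify mostly
  non-neutral and score NSR ≈ 0.6 while their aggregates classify ~100%
  neutral and score NSR ≈ 0.94 — the qualitative redundancy ordering,
  asserted as an ordering only;
* planted core/periphery correlation structure: core OMUs share a latent
  factor (pairwise correlation ≈ `loading`); each periphery OMU couples
  to one standardized core signal at strength `0.45·loading`, so it
  correlates detectably with the core but periphery–periphery
  correlations scale with the coupling squared (≈ 0.16 at loading 0.9)
  and fall below FDR significance at ~100 samples. The full pipeline
  (table → network → core/periphery detection) recovers the planted
  core with ≥ 95% node accuracy under those conditions;
* planted treatment effects: the diseased copy multiplies affected rows
  by a fold change and re-draws reads at the original depths.

Default study conditions are the functional-cluster scale: 300 OMUs, 100
samples, `I_T` = depth = 50,000, `m` = 0.3. Oracle and recovery
experiments in the tests use 10,000 reads and 10–100 samples so the
whole suite runs in about a minute; the acceptance batch uses 200 OMUs ×
10 samples with 100 null simulations per metacommunity.

What the generator does **not** emulate: real read-level noise (FASTQ,
mapping error), phylogenetic or genomic linkage between OMUs,
longitudinal dynamics, compositional biases beyond the fixed sequencing
depth, and the million-gene scale of real MG tables. Passing tests
demonstrate internal correctness of the estimators and algorithms under
the stated generative models, not their external validity on real gut
metagenomes.

## Degenerate inputs and edge cases

* All-zero sample columns stay zero in the relative-abundance view (with
  a warning); all-zero tables are rejected where an analysis needs mass.
* Saturated aggregates (every OMU present everywhere) have no occurrence
  variance: the fit reports R² = 0 and flags itself poor while the
  classification (everything neutral) remains well-defined.
* Networks with constant rows, graphs with no edges, fewer than 4 nodes,
  or a core/periphery side smaller than 5 OMUs raise or skip with
  explicit messages rather than returning silent defaults.
* Determinism: every stochastic routine takes a seed; the pipeline
  derives per-stage substreams by hashing the stage name into the global
  seed, so disabling one stage does not shift another's draws.
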