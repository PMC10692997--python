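# Methods

## The model

`pleiosim` simulates a haploid population of constant size *N* in which each
individual carries two classes of heritable, real-valued genes:

* a weight vector **a** of length `n_a` (default 4): gene *j* has effect
  magnitude *a<sub>j</sub>*;
* a contribution matrix **c** of shape `n_traits × n_a` (default 4 × 4):
  entry *c<sub>ij</sub>* routes the effect of weight gene *j* onto trait *i*.
  Every entry is an independently mutating gene, so the default genome has
  4 + 16 = 20 genes and the eight-trait variant 8 + 64 = 72.

Phenotypes are the linear read-out *z<sub>i</sub>* = Σ<sub>j</sub>
*c<sub>ij</sub> a<sub>j</sub>*. Because **c** itself evolves, the degree and
pattern of pleiotropy of the weight genes is an evolvable property of the
genotype–phenotype map, which is the object of study.

Fitness is Gaussian and multiplicative across traits around a moving optimum
**z°**: *w*(**z**) = exp[−Σ<sub>i</sub> (*z<sub>i</sub>* −
*z°<sub>i</sub>*)² / 2], with per-trait selection variance fixed at 1. There
is no correlational selection within a generation: any genetic covariance
that evolves must come from the *temporal* correlation of the optima.

Reproduction follows a Moran birth–death scheme: each event draws one parent
with probability proportional to fitness (two in the sexual model, combined
by free recombination — every gene from either parent with probability ½),
mutates the offspring, and replaces one uniformly chosen individual. *N*
events constitute one generation. Mutation hits each weight gene with
probability μ<sub>a</sub> = 1.25 × 10⁻³ and each contribution gene with
μ<sub>c</sub> = 3.125 × 10⁻⁴ per birth, adding a Normal(0, 0.5) increment;
at the default *N* = 1000 this supplies five mutations of each class to the
population per generation. Populations start genetically uniform at
**a** = **c** = 0.

## Environments

Every `period_generations` (default 10) generations each trait optimum steps
±0.2 with equal probability. The three regimes differ only in the coupling
of the coin tosses: `correlated` (one coin for all traits), `independent`
(one per trait), `block_correlated` (one per declared block of traits). In
the bounded case (default [−1, 1]) an optimum at a boundary stays with
probability ½ or moves one step inward — a lazy reflection whose stationary
distribution is exactly uniform over the 11-point lattice, so no position is
favoured in the long run. Trajectories are pre-drawn per replicate from a
dedicated random stream, so the identical environment can be replayed
against any engine or analysis.

## Estimators

**Total (co)variance.** The population covariance (denominator *N*) of
phenotypes at a recorded time point. The model has no environmental noise,
so phenotypic equals total genetic (co)variance. Matrices are averaged
elementwise over a replicate's recorded snapshots (by default the last tenth
of the run, every ten generations — 50 snapshots at the full 5,000-generation
scale).

**Pleiotropy / linkage-disequilibrium split.** Each locus (each *a* gene and
each *c* gene separately) is permuted among individuals, destroying
between-locus associations while preserving each locus's allele frequencies
and effects. The covariance of the shuffled population is the pleiotropy
component; total minus shuffled is the LD component, so the decomposition is
exact by construction. The default is one shuffle per snapshot; `n_shuffles`
averages several for lower estimator noise.

**Additive (co)variance (sexual model).** Random couples (uniform, fitness
ignored) produce free-recombinant offspring without mutation;
`n_offspring_per_pair` (default 10) offspring are averaged per pair. The
heritability of trait *i* is the OLS slope of mean offspring on midparent —
equal to V<sub>A</sub>/V<sub>P</sub>, since the midparent–offspring
covariance and the midparent variance each carry a factor ½ — and the
additive variance is that slope times the trait's phenotypic variance.
Cross-trait entries use the slope of offspring trait *j* on midparent trait
*i* times the variance of trait *i*. Note the multiplier: using the variance
*of the midparent values* here would halve V<sub>A</sub>, and the estimator
would no longer recover the total matrix on a purely additive
(fixed-**c**) map. The raw estimator is asymmetric in (*i*, *j*); the raw
matrix and its symmetrised average are both reported. Traits with zero
midparent variance yield NaN (missing), never a fabricated zero.

**Mutational moments.** M*<sub>ij</sub>, the change in trait (co)variance
caused by one mutation, is estimated by sampling individuals (uniformly,
with replacement, pooled over snapshots), perturbing one uniformly chosen
gene of the class of interest by Normal(0, 0.5), and combining plain sample
covariances of (**z**, Δ**z**): M*<sub>ii</sub> = Var(Δz<sub>i</sub>) +
2 Cov(Δz<sub>i</sub>, z<sub>i</sub>) and M*<sub>ij</sub> =
Cov(Δz<sub>i</sub>, Δz<sub>j</sub>) + Cov(z<sub>i</sub>, Δz<sub>j</sub>) +
Cov(Δz<sub>i</sub>, z<sub>j</sub>) — finite-sample identities for
Var(z′) − Var(z) and Cov(z′) − Cov(z) over the same draws. The phenotype
change of a single perturbation is computed analytically from the linear map
(an *a<sub>j</sub>* perturbation of size δ shifts **z** by δ **c**<sub>·j</sub>;
a *c<sub>ij</sub>* perturbation shifts *z<sub>i</sub>* by δ *a<sub>j</sub>*),
so stored populations are never modified. The total matrix weights the
classes by mutation supply: M<sub>tot</sub> = n<sub>a</sub> μ<sub>a</sub>
M*<sub>a</sub> + (n<sub>traits</sub> n<sub>a</sub>) μ<sub>c</sub>
M*<sub>c</sub>.

**Treatment comparisons.** Welch two-sample t-tests across per-replicate
time-averaged values (a matrix entry, the diagonal mean, or the
off-diagonal mean), reporting t, degrees of freedom, p, group means and
their ratio. Ratios whose denominators are near-zero covariances are noisy
and should be read together with the group means.

**Fixed-pleiotropy transplant.** After phase 1, each contribution locus is
frozen at its modal allele value (alleles arise as discrete mutational
lineages, so exact-value frequencies are meaningful; ties go to the value
carried by the lowest-indexed individual). Each replicate is copied once per
test regime and evolved for phase 2 with μ<sub>c</sub> = 0 under unbounded
optima starting from the zero optimum; mean fitness is recorded every ten
generations and each replicate is summarised by its mean over the last tenth
of the series.

## Numerical and design choices

* **Engine.** The event loop is a compiled (numba) kernel. Fitness values
  are cached per individual and refreshed only at births and environment
  changes; the fitness total is re-summed in index order every event so that
  a naive oracle engine — which recomputes every phenotype and fitness from
  the genotypes at each event while consuming the identical random stream —
  produces bit-identical populations at the same seed. This bit-identity is
  asserted in the test suite for both asexual and sexual models.
* **Seed tree.** One master seed per run spawns per-replicate sub-seeds;
  each replicate's seed splits into an environment stream and an event
  stream, so analyses can be re-run on stored snapshots without perturbing
  simulation randomness. All derived seeds stay below 2³¹.
* **Parent selection edge case.** If all fitnesses underflow to zero the
  parent is drawn uniformly; this signals a population far off optimum and
  preserves the process rather than aborting.
* **Moran conventions.** Parent and death slot are drawn independently (the
  parent may die; the offspring replaces the dead slot). In the sexual model
  the two parents are drawn independently and may coincide (selfing
  possible). Mutation acts at birth, after recombination.
* **Covariance denominators.** Population covariance (1/N) everywhere, and
  1/n sample covariances in the mutational moments, applied identically to
  all treatments so ratios are unaffected.
* **Snapshot schedule.** Last tenth of the run, every ten generations, end
  inclusive: a 5,000-generation run records generations 4,510 … 5,000 (50
  snapshots); a 1,000-generation run records 910 … 1,000 (10).
* **Statistical checks on walk occupancy.** Successive optimum positions are
  autocorrelated (the 11-state chain mixes in tens of steps), so chi-square
  uniformity tests run on a thinned subsample (every 250th state); the raw
  occupancy is additionally bounded directly against 1/11.

## Scales

The full design (N = 1000, 5,000 + 2,000 generations, 500 replicates per
regime, 10⁶ mutational samples) reproduces the published experiment grid and
is a multi-CPU-hour batch. The test suite and the acceptance script run the
desk scale: N = 200, 1,000 phase-1 and 500 phase-2 generations, 20
replicates per regime for the (co)variance batteries and 60 for the
transplant assay, chosen as the smallest sizes at which the directional
signatures are visible on a single CPU in minutes. `ExperimentDesign`
exposes `full_scale()`, `desk_scale()` and `smoke()` presets.

## What the desk scale does and does not show

At N = 200 and 1,000 generations the qualitative signatures all point the
right way — correlated optima build positive covariance while independent
optima do not; within-block covariance exceeds between-block covariance
under block-correlated change; transplanted populations tend to do best
under their ancestral pattern of change — but per-replicate covariances are
dominated by temporal fluctuation over the short recording window, so
significance tests at these sample sizes are underpowered relative to the
full 500-replicate design, and ratios of group means are unstable whenever
the denominator is a near-zero covariance. Validation runs at N = 1000 and
5,000 generations (10 replicates per regime) reproduce the full-scale
pattern: strong positive correlated-regime covariance dominated by
pleiotropy with a small negative LD part, higher total variance under
independent change, higher and positive a-class mutational covariance under
correlated change, regime-insensitive c-class moments, and a within/between
block covariance ratio around an order of magnitude.

## Limitations

* Haploid genetics only: no dominance, no diploidy, no linkage map (free
  recombination), no migration or spatial structure.
* The synthetic populations used as estimator fixtures (uniform, no-LD,
  perfect-coupling, fixed-**c**) are constructed, not evolved; they validate
  the estimators' algebra, not the evolutionary dynamics.
* The environment is a lattice random walk; continuous or autocorrelated
  optimum processes are out of scope.
* Mean-fitness summaries of the transplant use the recorded 10-generation
  grid, not per-event fitness.
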