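# Methods

## Model

We model an asexual haploid population of constant size `N` with
non-overlapping generations.  Each individual is fully described by its
**pheno-genotype** `(z, g)`: a mutation-rate phenotype `z` — non-mutator
`m` with genome-wide deleterious mutation rate `U`, or mutator `M` with
rate `τU` — and a genotype `g` that determines fitness.  There is no
recombination, so phenotype and genotype are completely linked.

One generation applies three deterministic maps to the joint frequency
vector `f_{z,g}`, in this order, followed (in the stochastic regime) by
drift:

1. **Switching.**  An offspring switches from non-mutator to mutator with
   probability `γ1` and back with probability `γ2`:
   `f'_{m,g} = (1−γ1) f_{m,g} + γ2 f_{M,g}`,
   `f'_{M,g} = γ1 f_{m,g} + (1−γ2) f_{M,g}`.
   Per-genotype totals are conserved exactly.  The ratio `α = γ1/γ2`
   links the two rates in the empirical systems below.
2. **Mutation.**  `f''_{z,g} = Σ_j u_{j→g} f'_{z,j}` with a row-stochastic
   kernel per phenotype; the mutator kernel carries τ-fold elevated rates.
3. **Selection.**  `f'''_{z,g} = (w_g / w̄) f''_{z,g}` with
   `w̄ = Σ_g w_g (f''_{m,g} + f''_{M,g})`.  The mutator phenotype is
   selectively neutral: both phenotypes face the same `w_g`.
4. **Drift** (stochastic engine only).  Pheno-genotype counts are drawn
   from `Multinomial(N, f''')` and divided by `N`.

The analysis workflow has two phases.  In phase one the wild type is
fittest; the deterministic recursion is iterated from an all-non-mutator
wild-type population to **mutation-selection balance (MSB)**, drift being
neglected.  Phase two models an environmental change: a different genotype
becomes fittest, the population starts from the MSB frequencies, and drift
is included.  Adaptation is scored when the adaptive genotype exceeds a
threshold frequency (default 0.99, i.e. ">99%").

## Fitness landscapes

**Simple (motif) landscape.**  A genotype is a pair `a\b`: `a ∈ {0..A}`
mutations at `A ∈ {2, 3}` environment-specific loci and `b` background
deleterious mutations, truncated at `K`.  Pre-change fitness is
`(1−s)^(a+b)`; post-change fitness is `w_a (1−s)^b` where
`(w_1, …, w_A)` is the motif vector with `w_0 = 1` and the full mutant
fittest.  Motifs are classified as *valley* (some intermediate below 1),
*flat* (all intermediates equal 1), *monotonic ascent*
(`1 < w_1 < … < w_A`), or *other*.

The motif mutation kernel factorises into independent background and
environment-specific parts: the background count gains `l ~ Poisson(U)`
(mutators `Poisson(τU)`) mutations, with tail mass beyond `K` lumped into
class `K` so rows stay stochastic; the environment-specific count gains
`j ~ Binomial(A−a, μ)` (mutators `τμ`) with `μ = U/n` and `n` the total
locus count.  Back mutation is neglected in both parts: only unmutated
loci can mutate, which keeps rows stochastic without renormalisation.

**Bitstring landscapes.**  An explicit fitness table over all `2^L`
binary genotypes (`L ≤ 20` so the table stays in memory).  Seeded NK
landscapes draw, per locus, `k` interaction partners uniformly without
replacement and a contribution table of `2^(k+1)` uniform(0,1) values;
genotype fitness is the arithmetic mean of per-locus contributions, so it
lies in (0,1) and is comparable across `L`.  Ruggedness grows with `k`
(`k=0` additive, `k=1` smooth, `k=3` intermediate).  Tabulated landscapes
(CSV, header `genotype,fitness`, fixed-width binary genotype strings with
locus 0 leftmost) support empirically derived tables; completeness,
uniqueness, binary alphabet and positivity are validated with row-level
error reporting.

The adaptive genotype is the fitness argmax, ties broken by lowest
integer encoding so trajectories are reproducible.  The default wild type
of a generated or tabulated landscape is the local optimum with median
fitness among local optima at Hamming distance ≥ 2 from the global peak
(falling back to the complement of the peak if none qualifies); it is
overridable by an explicit genotype.  The pre-change landscape used for
the MSB phase assigns fitness `(1−s)^d` with `d` the Hamming distance to
the wild type, mirroring the simple landscape's first phase.

**Mutation on bitstring landscapes.**  Each locus flips independently,
and the default per-locus probability is `U` (mutators `τU`): each
landscape locus is treated as a composite mutational target of the order
of the genome-wide deleterious rate, not a single point-mutation site.
This is a genuine modelling choice: with per-locus rates of `U/n` or even
`U/L`, a population of `N = 1000` sees essentially no mutations over
hundreds of generations and the published landscape experiments at that
scale could not occur at all.  Callers can pass any explicit
`per_locus_rate` instead.  Dense bitstring kernels are limited to
`L ≤ 12` (the kernel is a `2^L × 2^L` matrix).

## Mutation-selection balance

Two solvers compute the MSB and cross-validate each other:

* **Fixed-point iteration** of the full generation map from the
  all-non-mutator wild-type start, stopping when the L1 change per
  generation falls below `1e-13` (maximum `1e6` iterations;
  non-convergence is flagged, not raised).  Frequencies are renormalised
  to exactly 1 every generation to prevent floating-point drift.
* **Leading eigenvector** of the composed linear (pre-normalisation)
  operator `diag(w) · Uᵀ · S` over all pheno-genotypes.  The eigenvector
  of the largest-real-part eigenvalue is made nonnegative and normalised;
  the leading eigenvalue is the equilibrium mean fitness.  A leading
  eigenvalue with a significant imaginary part raises a numerical error
  with spectral diagnostics.

The two agree to L1 ≤ 1e-8 across a 72-point grid spanning
`U ∈ {4e-5, 3e-3}`, `τ ∈ {10, 100}`, `s ∈ {0.01, 0.1}`,
`γ1 ∈ {1e-6, 1e-3, 0.1}`, `α ∈ {0.1, 1, 10}` (asserted in the test
suite).  For dimensions up to 4096 the one-generation operator is
assembled densely and iterated as a single matrix-vector product; above
that it is applied blockwise.

Four class frequencies summarise the MSB state: `m0, m1, M0, M1` — wild
type vs mutant within each phenotype.  On the motif landscape the mutant
class is the clean single mutant `1\0`; on bitstring landscapes it is
every non-wild-type genotype.  Derived quantities: mutator frequency
`p_M`, mutant frequency `p_S = m1 + M1`, and the mutator-mutant
association `A = M1 − p_M·p_S` (zero iff phenotype and mutant state are
independent).

## Closed-form theory

* Appearance probability of the adaptive genotype from standing single
  mutants: `q = μ m1 e^{−U} + τμ M1 e^{−τU}`.
* Adaptation rate: `ν = 1 − (1 − qπ)^N ≈ Nqπ`, with `π` the fixation
  probability given appearance (estimated stochastically; `π` depends
  only on the adaptive genotype's fitness `1 + sH`, not on the switching
  rates).  `ν` is evaluated with `expm1/log1p` for numerical accuracy.
* Mutator frequency regimes: slow reverse switching,
  `p_M⁻ = γ1/((τ−1)U)` (the generation rate of mutators over their
  excess load; the cruder `γ1/(τU)` is also reported), valid for
  `γ2 < τU/2` — a warning is emitted beyond that; fast switching,
  `p_M⁺ = γ1/(γ1+γ2)`, the stationary value of the two-state switching
  chain, exact on a neutral landscape.
* The adaptation-optimal switching rate `γ1*` maximises `q` over a
  log-spaced `γ1` grid (default 25 points per decade over
  `[1e-6, 0.5]`) with `γ2 = γ1/α` held proportional; each grid point
  solves the MSB (eigenvector solver by default — it is exact and two
  orders of magnitude faster than iteration at small `γ`).  The argmax
  is reported with its bracketing grid points so resolution limits are
  explicit.
* Population-size validity window for the four-class picture:
  `N_low = (s/μ)·e^{U/s}` (large enough that single mutants are
  present — at `N_low` the expected single-mutant count is ~1) and
  `N_high = (s/(τμ))²·e^{τU/s}` (small enough that double mutants are
  absent).  The printed source condition is typographically ambiguous;
  the implemented reading is recorded in the returned metadata rather
  than asserted as exact.

## Interventions

Three per-generation manipulations dissect the mechanisms behind fast
adaptation.  They are applied after drift, i.e. to the realised
population state (the placement within a generation is a package
decision; the source describes only "at each generation").

* **break_association** makes phenotype independent of genotype:
  `f_{z,g} ← marginal(z) · t_g` with `t_g` the per-genotype total.  This
  reproduces the class totals `m0 = (1−p_S)(1−p_M)`, `m1 = p_S(1−p_M)`,
  `M0 = (1−p_S)p_M`, `M1 = p_S·p_M`, preserves every per-genotype total
  and `p_M`, and zeroes `A` to machine precision.  Within the mutant
  classes both phenotypes inherit the pooled genotype profile — the only
  assignment consistent with the class totals when the two phenotypes'
  profiles differ.
* **clamp_pM** rescales the two phenotype rows so `p_M` equals its MSB
  value each generation (eliminating hitchhiking); within-phenotype
  genotype profiles are untouched.  If the mutator class is empty and
  the target positive, it is seeded from the non-mutator profile
  (documented fallback).
* **scale_pM** is the same rescaling with target one half of the MSB
  value (reducing the mutator supply).

## Stochastic experiments and problem sizes

Per-run seeding uses `base_seed + i` for run `i` through NumPy's
`default_rng`, so a base seed reproduces an experiment exactly.
Adaptation proportions carry 95% Wilson intervals.  Fixation-probability
trials introduce one adaptive individual into the MSB background
(replacing one wild-type non-mutator; the mutant's phenotype is drawn
from the MSB phenotype proportions unless fixed) and run until the
adaptive class is lost or exceeds the 0.99 threshold; scoring at that
threshold biases the neutral case by only ~1%, well inside Monte-Carlo
error at the trial counts used.

The default test and acceptance problem sizes are desk-scale choices
made once:

* Hitchhiking (monotonic-ascent motif, `A=3`, `w = (1.1, 1.2, 1.3)`,
  `s = 0.03`, `U = 4e-5`, `τ = 100`): `N = 1e7` (down from the source's
  `1e9`; multinomial sampling over classes would allow `1e9`, but
  replicate counts matter more than `N` here), 200 runs, 2000
  generations.  The diagnostic is the fraction of adapting runs whose
  `p_M` transiently reaches at least twice its MSB value.
* Interventions (NK `L=8`, `k=1`, seed 21, `N = 1000`, 500 runs/arm,
  horizon 6000 generations).  The landscape seed was chosen by
  structure: its default wild type is a local optimum four mutations
  from the global peak with three local optima, so adaptation is
  multi-step and hitchhiking can manifest.  The horizon exceeds the
  source's 500-generation readout because under this package's mutation
  model the first valley escape at `N = 1000` alone takes on the order
  of `10^3`–`10^4` generations; at shorter horizons neither arm adapts
  and no comparison is possible.
* Fixation probability: motif `A=2`, post-change `w = (0.9, 1.1)`
  (adaptive advantage `s·H = 0.1`), `N = 1e4`, 5000 trials per
  switching regime in the test suite (2000 in the acceptance script).

## What the generators do and do not emulate

The synthetic landscapes reproduce the *structure* of the study systems —
single-peak motifs, tunably rugged NK instances, tabulated
genotype-fitness maps — with seeded, bit-reproducible construction.  They
do not emulate real mutational target sizes per locus, fitness
measurement noise, environmental fluctuation, or the particular epistasis
of any empirical data set; passing tests demonstrate the model's internal
dynamics (hitchhiking, association, regime boundaries), not quantitative
agreement with any organism.

## Empirical switching-rate estimates

* **Ada** (*E. coli*): production of Ada in zero-Ada cells is Poisson
  with rate 1 molecule/generation, so `γ2 = 1 − e^{−1} ≈ 0.63`; with a
  stationary zero-Ada fraction of 25%, the two-state balance
  `(1−p)γ1 = pγ2` gives `γ1 ≈ 0.21`.  Fold-increase preset `τ = 3`.
* **Mistranslation** (single-copy DNA-repair protein, cytoplasmic
  inheritance): with per-codon error `e` and
  `sites = round(length × LOF fraction)` loss-of-function codons,
  `γ1 = 1 − (1−e)^sites` and `γ2 = dilution × (1−e)^sites`.  Yeast
  defaults (`e = 1e-3`, 500 aa, 10%, dilution 0.5) give `γ1 ≈ 0.049`,
  `γ2 ≈ 0.476`; the bacterial variant (`e = 5e-4`, 300 aa) gives
  `γ1 ≈ 0.0149`.  The source text mentions both `1e-4` and `1e-3` for
  the yeast per-codon rate; the default is `1e-3`, the value its own
  printed formula and results use.  Preset `τ = 100`.
* **Aneuploidy** (yeast): literature constants `γ1 = 1e-4`
  (chromosome gain), `γ2 = 1e-5` (loss), `α = 10`, preset `τ = 2`.

## Numerical choices and degenerate inputs

* Mass tolerance `1e-12` on distributions and kernel rows; every
  operator preserves nonnegativity and total mass.
* Selection with zero mean fitness raises a degenerate-population error;
  genotypes at frequency zero stay at zero.
* `U = 0` yields identity mutation kernels (the switching chain alone).
* `γ1 = γ2 = 0` from the all-non-mutator start keeps `p_M = 0`: the
  classical one-phenotype mutation-selection balance.
* Switching rates above 0.5 ("contrarian inheritance") are valid inputs
  throughout; the sweep grid is extensible to `γ1 = 0.95`.

## Known limitations

* Only two mutation-rate phenotypes are modelled; a third, intermediate
  ("transition") phenotype is not implemented.  The block structure of
  the assembled generation operator is the natural extension point for a
  general phenotype-switching matrix.
* No closed form for `π` is provided; the stochastic estimator is
  cross-checked against a Poisson branching-process extinction fixed
  point in the tests.
* Aneuploidy is treated as selectively neutral; fitness costs of the
  mutator state are outside the model.
* Dense bitstring kernels limit realistic landscapes to `L ≤ 12` loci;
  larger `L` would need sparse or on-the-fly kernels.
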