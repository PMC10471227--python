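"""Stochastic Wright-Fisher dynamics: drift, adaptation runs, interventions.

After the environmental change the population starts from the
mutation-selection balance reached in the old environment and evolves by
the deterministic generation map (switching, mutation, selection) followed
by multinomial resampling of ``N`` individuals.  Adaptation is scored as
the adaptive genotype exceeding a fixation threshold (default 99%).

Three per-generation interventions dissect the mechanisms behind fast
adaptation: breaking the mutator-mutant association, clamping the mutator
frequency at its balance value (eliminating hitchhiking), and halving it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .deterministic import (
    MSBResult,
    MutationKernel,
    PhenoGenotypeDistribution,
    SwitchingRates,
    generation_step,
)
from .errors import ParameterError, StructuralError

InterventionMode = Literal["none", "break_association", "clamp_pM", "scale_pM"]


# ---------------------------------------------------------------------------
# Drift
# ---------------------------------------------------------------------------

def drift_step(dist: PhenoGenotypeDistribution, N: int,
               rng: np.random.Generator) -> PhenoGenotypeDistribution:
    """Multinomial resampling of ``N`` individuals from the current
    pheno-genotype frequencies; returned frequencies are counts / N and
    sum to 1 exactly."""
    if N < 1:
        raise ParameterError(f"population size must be >= 1, got {N}")
    probs = np.clip(dist.freqs.reshape(-1), 0.0, None)
    probs = probs / probs.sum()
    counts = rng.multinomial(N, probs)
    return PhenoGenotypeDistribution(
        counts.reshape(dist.freqs.shape) / N, check=False
    )


# ---------------------------------------------------------------------------
# Interventions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InterventionSpec:
    """Per-generation population manipulation.

    ``break_association``: redistribute phenotypes over genotypes so the
    mutator-mutant association is exactly zero while every per-genotype
    total and the mutator frequency are preserved.

    ``clamp_pM`` / ``scale_pM``: reset the mutator frequency each
    generation to ``target_pM`` (the MSB value for clamping; half of it for
    scaling), preserving the relative genotype frequencies within each
    phenotype.
    """

    mode: InterventionMode = "none"
    target_pM: float | None = None

    def __post_init__(self):
        if self.mode not in ("none", "break_association", "clamp_pM", "scale_pM"):
            raise ParameterError(f"unknown intervention mode {self.mode!r}")
        if self.mode in ("clamp_pM", "scale_pM"):
            if self.target_pM is None or not 0.0 < self.target_pM < 1.0:
                raise ParameterError(
                    f"{self.mode} needs target_pM in (0, 1), got {self.target_pM}"
                )

    @classmethod
    def none(cls) -> "InterventionSpec":
        return cls(mode="none")

    @classmethod
    def break_association(cls) -> "InterventionSpec":
        return cls(mode="break_association")

    @classmethod
    def clamp_pM(cls, msb_pM: float) -> "InterventionSpec":
        return cls(mode="clamp_pM", target_pM=msb_pM)

    @classmethod
    def scale_pM(cls, msb_pM: float, factor: float = 0.5) -> "InterventionSpec":
        return cls(mode="scale_pM", target_pM=factor * msb_pM)


def apply_intervention(dist: PhenoGenotypeDistribution,
                       spec: InterventionSpec) -> PhenoGenotypeDistribution:
    if spec.mode == "none":
        return dist
    fm, fM = dist.freqs
    if spec.mode == "break_association":
        # phenotype made independent of genotype: f_zg = marginal(z) * t_g.
        # Per-genotype totals and p_M are conserved; the class totals become
        # m0=(1-pS)(1-pM), m1=pS(1-pM), M0=(1-pS)pM, M1=pS pM, i.e. A = 0.
        t = fm + fM
        p_M = float(fM.sum())
        out = np.vstack([(1.0 - p_M) * t, p_M * t])
        return PhenoGenotypeDistribution(out, check=False)
    # clamp_pM / scale_pM: rescale each phenotype row to the target mutator
    # frequency; within-phenotype genotype profiles are untouched.
    target = spec.target_pM
    p_M = float(fM.sum())
    if p_M == 0.0:
        # documented fallback: seed the mutator class from the non-mutator
        # genotype profile
        profile = fm / fm.sum()
        out = np.vstack([(1.0 - target) * profile, target * profile])
    elif p_M == 1.0:
        profile = fM / fM.sum()
        out = np.vstack([(1.0 - target) * profile, target * profile])
    else:
        out = np.vstack([fm * ((1.0 - target) / (1.0 - p_M)),
                         fM * (target / p_M)])
    return PhenoGenotypeDistribution(out, check=False)


# ---------------------------------------------------------------------------
# Adaptation runs
# ---------------------------------------------------------------------------

@dataclass
class AdaptationRun:
    """One stochastic trajectory after the environmental change."""

    success: bool
    fixation_generation: int | None
    pM_trajectory: np.ndarray
    adaptive_trajectory: np.ndarray
    wbar_trajectory: np.ndarray
    seed: int | None = None

    @property
    def generations(self) -> int:
        return len(self.adaptive_trajectory) - 1  # entry 0 is the initial state

    def max_pM(self) -> float:
        return float(self.pM_trajectory.max())

    def to_dict(self) -> dict:
        return {
            "success": bool(self.success),
            "fixation_generation": self.fixation_generation,
            "seed": self.seed,
            "generations": self.generations,
            "max_pM": self.max_pM(),
            "final_adaptive_freq": float(self.adaptive_trajectory[-1]),
        }


def _adaptive_frequency(dist: PhenoGenotypeDistribution, landscape) -> float:
    return float(dist.freqs[:, landscape.adaptive_class_indices()].sum())


def run_adaptation(msb: MSBResult, post_landscape, rates: SwitchingRates,
                   kernel: MutationKernel, N: int, generations: int,
                   threshold: float = 0.99,
                   intervention: InterventionSpec | None = None,
                   seed: int | None = None,
                   rng: np.random.Generator | None = None,
                   stop_at_fixation: bool = True) -> AdaptationRun:
    """Simulate adaptation from MSB on the post-change landscape.

    Each generation applies the deterministic map, then multinomial drift,
    then the intervention (if any).  Success is the adaptive genotype class
    exceeding ``threshold`` in frequency.
    """
    if kernel.n_genotypes != post_landscape.n_genotypes:
        raise StructuralError("kernel and post-change landscape genotype sets differ")
    if msb.distribution.n_genotypes != post_landscape.n_genotypes:
        raise StructuralError("MSB distribution and post-change landscape differ")
    if rng is None:
        rng = np.random.default_rng(seed)
    intervention = intervention or InterventionSpec.none()

    dist = msb.distribution.copy()
    pM_traj = [dist.p_M]
    adapt_traj = [_adaptive_frequency(dist, post_landscape)]
    wbar_traj = [msb.w_bar]
    success = adapt_traj[0] > threshold
    fixation_generation: int | None = 0 if success else None

    if not success:
        for t in range(1, generations + 1):
            dist, wbar = generation_step(dist, rates, kernel, post_landscape)
            dist = drift_step(dist, N, rng)
            dist = apply_intervention(dist, intervention)
            pM_traj.append(dist.p_M)
            adapt_traj.append(_adaptive_frequency(dist, post_landscape))
            wbar_traj.append(wbar)
            if adapt_traj[-1] > threshold:
                success = True
                fixation_generation = t
                if stop_at_fixation:
                    break
    return AdaptationRun(
        success=success,
        fixation_generation=fixation_generation,
        pM_trajectory=np.array(pM_traj),
        adaptive_trajectory=np.array(adapt_traj),
        wbar_trajectory=np.array(wbar_traj),
        seed=seed,
    )


@dataclass
class ProportionEstimate:
    """Proportion of successful runs with a 95% Wilson interval."""

    proportion: float
    ci_low: float
    ci_high: float
    n_runs: int
    successes: int
    runs: list[AdaptationRun] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "proportion": self.proportion, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "n_runs": self.n_runs,
            "successes": self.successes,
        }


def _wilson_ci(successes: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    ci = stats.binomtest(successes, n).proportion_ci(
        confidence_level=confidence, method="wilson"
    )
    return float(ci.low), float(ci.high)


def adaptation_proportion(msb: MSBResult, post_landscape, rates: SwitchingRates,
                          kernel: MutationKernel, N: int, n_runs: int,
                          horizon: int, threshold: float = 0.99,
                          intervention: InterventionSpec | None = None,
                          base_seed: int = 0,
                          keep_runs: bool = False) -> ProportionEstimate:
    """Proportion of independent runs that adapt within ``horizon``
    generations.  Run ``i`` uses seed ``base_seed + i``, so a base seed
    fully reproduces the estimate."""
    if n_runs < 1:
        raise ParameterError(f"n_runs must be >= 1, got {n_runs}")
    successes = 0
    runs: list[AdaptationRun] = []
    for i in range(n_runs):
        run = run_adaptation(
            msb, post_landscape, rates, kernel, N, horizon,
            threshold=threshold, intervention=intervention, seed=base_seed + i,
        )
        successes += run.success
        if keep_runs:
            runs.append(run)
    lo, hi = _wilson_ci(successes, n_runs)
    return ProportionEstimate(successes / n_runs, lo, hi, n_runs, successes, runs)


# ---------------------------------------------------------------------------
# Fixation probability
# ---------------------------------------------------------------------------

@dataclass
class PiEstimate:
    """Fixation probability of an introduced adaptive genotype, with CI."""

    pi: float
    ci_low: float
    ci_high: float
    n_trials: int
    fixations: int

    def overlaps(self, other: "PiEstimate") -> bool:
        return self.ci_low <= other.ci_high and other.ci_low <= self.ci_high

    def to_dict(self) -> dict:
        return {
            "pi": self.pi, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "n_trials": self.n_trials, "fixations": self.fixations,
        }


def estimate_fixation_probability(post_landscape, rates: SwitchingRates,
                                  kernel: MutationKernel, N: int, n_trials: int,
                                  seed: int, msb: MSBResult,
                                  threshold: float = 0.99,
                                  max_generations: int = 100_000,
                                  initial_phenotype: str | None = None) -> PiEstimate:
    """Estimate pi, the fixation probability of a single adaptive-genotype
    individual introduced into an MSB background population.

    Each trial replaces one wild-type non-mutator with one adaptive
    individual (phenotype drawn from the MSB phenotype proportions unless
    fixed via ``initial_phenotype``) and simulates until the adaptive
    class is lost or exceeds ``threshold``.
    """
    if n_trials < 1:
        raise ParameterError(f"n_trials must be >= 1, got {n_trials}")
    if N < 2:
        raise ParameterError(f"need N >= 2 to introduce a mutant, got {N}")
    rng = np.random.default_rng(seed)
    base = msb.distribution.freqs.copy()
    wt = post_landscape.wild_type_index
    adaptive_idx = post_landscape.adaptive_class_indices()
    pM = msb.p_M

    fixations = 0
    for _ in range(n_trials):
        f = base.copy()
        if initial_phenotype is not None:
            z = 0 if initial_phenotype == "m" else 1
        else:
            z = int(rng.random() < pM)
        f[0, wt] -= 1.0 / N
        f[z, post_landscape.adaptive_index] += 1.0 / N
        if f[0, wt] < 0:  # MSB wild-type class held less than one individual
            raise ParameterError(
                "N too small: wild-type non-mutator class holds < 1 individual"
            )
        dist = PhenoGenotypeDistribution(f, check=False)
        for _t in range(max_generations):
            dist, _ = generation_step(dist, rates, kernel, post_landscape)
            dist = drift_step(dist, N, rng)
            freq = float(dist.freqs[:, adaptive_idx].sum())
            if freq == 0.0:
                break
            if freq >= threshold:
                fixations += 1
                break
    lo, hi = _wilson_ci(fixations, n_trials)
    return PiEstimate(fixations / n_trials, lo, hi, n_trials, fixations)


def branching_fixation_probability(growth_rate: float, tol: float = 1e-12,
                                   max_iter: int = 10_000) -> float:
    """Branching-process establishment probability for a beneficial lineage
    with Poisson offspring of mean ``growth_rate`` (= 1 + s_effective).

    Solves the extinction fixed point ``x = exp(r (x - 1))`` and returns
    ``1 - x``; used as an independent oracle for the stochastic estimator.
    """
    if growth_rate <= 1.0:
        return 0.0
    x = 0.0
    for _ in range(max_iter):
        nxt = np.exp(growth_rate * (x - 1.0))
        if abs(nxt - x) < tol:
            return 1.0 - nxt
        x = nxt
    return 1.0 - x
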