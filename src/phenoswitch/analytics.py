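"""Closed-form and semi-analytic results of the switching-mutator model.

The adaptation rate factorises as nu = 1 - (1 - q pi)^N ~ N q pi, where q
is the per-generation probability that the adaptive genotype appears by
mutation from the standing single-mutant classes,

    q = mu m1 exp(-U) + tau mu M1 exp(-tau U),

and pi the fixation probability given appearance (independent of the
switching rates).  Two regimes approximate the mutator frequency at
mutation-selection balance: low reverse switching, p_M- = gamma1/((tau-1)U),
and fast switching, p_M+ = gamma1/(gamma1+gamma2).  The mutator-mutant
association is A = M1 - p_M p_S.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deterministic import (
    MutationParams,
    SwitchingRates,
    build_mutation_kernel,
    solve_msb_eigen,
    solve_msb_iterate,
)
from .errors import ParameterError
from .landscapes import MotifLandscape


# ---------------------------------------------------------------------------
# Appearance and adaptation rate
# ---------------------------------------------------------------------------

def appearance_probability(m1: float, M1: float, params: MutationParams) -> float:
    """Per-generation probability q that the adaptive genotype appears by a
    single further mutation in a standing single mutant:
    ``q = mu m1 e^{-U} + tau mu M1 e^{-tau U}`` (the exponential factors
    are the probabilities of no accompanying deleterious mutation)."""
    mu, tau, U = params.mu, params.tau, params.U
    return mu * m1 * np.exp(-U) + tau * mu * M1 * np.exp(-tau * U)


@dataclass(frozen=True)
class AdaptationRate:
    """Exact adaptation rate, its linear approximation, and their gap."""

    nu: float
    approximation: float  # N q pi
    relative_gap: float

    def __float__(self) -> float:
        return self.nu


def adaptation_rate(q: float, pi: float, N: int) -> AdaptationRate:
    """Adaptation rate ``nu = 1 - (1 - q pi)^N``, with the small-rate
    approximation ``N q pi`` reported alongside."""
    if not 0.0 <= q * pi <= 1.0:
        raise ParameterError(f"q*pi must be in [0, 1], got {q * pi}")
    if N < 1:
        raise ParameterError(f"N must be >= 1, got {N}")
    exact = -np.expm1(N * np.log1p(-q * pi)) if q * pi < 1.0 else 1.0
    approx = N * q * pi
    gap = 0.0 if approx == 0 else (approx - exact) / approx
    return AdaptationRate(nu=float(exact), approximation=float(approx),
                          relative_gap=float(gap))


# ---------------------------------------------------------------------------
# Mutator-frequency regimes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LowSwitchingMutatorFreq:
    """Mutator frequency in the low-reverse-switching regime.

    ``exact`` uses the (tau - 1) U denominator (mutator generation rate over
    excess mutational load); ``approx`` uses tau U.
    """

    exact: float
    approx: float

    def __float__(self) -> float:
        return self.exact


def mutator_freq_low_switching(rates: SwitchingRates,
                               params: MutationParams) -> LowSwitchingMutatorFreq:
    """p_M- = gamma1 / ((tau - 1) U): valid when the reverse switching rate
    gamma2 is small relative to the mutator's excess load.  A warning is
    emitted when gamma2 > tau U / 2, beyond which the balance is no longer
    of this form."""
    if params.tau == 1 or params.U == 0:
        raise ParameterError("p_M- undefined without excess mutator load "
                             "(needs tau > 1 and U > 0)")
    if rates.gamma2 > params.tau * params.U / 2:
        warnings.warn(
            f"gamma2 = {rates.gamma2} exceeds tau*U/2 = {params.tau * params.U / 2}: "
            "the low-switching approximation p_M- no longer applies",
            stacklevel=2,
        )
    return LowSwitchingMutatorFreq(
        exact=rates.gamma1 / ((params.tau - 1.0) * params.U),
        approx=rates.gamma1 / (params.tau * params.U),
    )


def mutator_freq_high_switching(rates: SwitchingRates) -> float:
    """p_M+ = gamma1 / (gamma1 + gamma2): the stationary mutator frequency
    of the phenotype-switching Markov chain, valid when both switching
    rates dominate selection against mutators."""
    if rates.gamma1 + rates.gamma2 == 0:
        raise ParameterError("p_M+ undefined for gamma1 = gamma2 = 0")
    return rates.gamma1 / (rates.gamma1 + rates.gamma2)


def association(M1: float, p_M: float, p_S: float) -> float:
    """Mutator-mutant association A = M1 - p_M * p_S (zero under
    independence of phenotype and mutant state)."""
    return M1 - p_M * p_S


def association_from_distribution(dist, landscape) -> float:
    return dist.summaries(landscape)["A"]


# ---------------------------------------------------------------------------
# Optimal switching-rate sweep
# ---------------------------------------------------------------------------

@dataclass
class OptimalGamma1Result:
    """Adaptation-optimal switching rate gamma1* with the full q profile."""

    gamma1_opt: float
    q_opt: float
    bracket: tuple[float, float]
    profile: pd.DataFrame = field(repr=False)


def default_gamma1_grid(low: float = 1e-6, high: float = 0.5,
                        points_per_decade: int = 25) -> np.ndarray:
    decades = np.log10(high / low)
    n = int(np.ceil(decades * points_per_decade)) + 1
    return np.geomspace(low, high, n)


def optimal_gamma1(params: MutationParams, alpha: float,
                   gamma1_grid: np.ndarray | None = None,
                   landscape: MotifLandscape | None = None,
                   method: str = "eigen") -> OptimalGamma1Result:
    """Sweep gamma1 (with gamma2 = gamma1 / alpha), solve the MSB at each
    grid point, and evaluate the appearance probability q from the
    resulting single-mutant frequencies.  Returns the argmax with its
    bracketing grid points (so the grid resolution is explicit) and the
    full tidy profile."""
    if gamma1_grid is None:
        gamma1_grid = default_gamma1_grid()
    gamma1_grid = np.asarray(gamma1_grid, dtype=float)
    if landscape is None:
        landscape = MotifLandscape(A=2, s=params.s, K=30, phase="pre")
    kernel = build_mutation_kernel(params, landscape)
    solver = solve_msb_eigen if method == "eigen" else solve_msb_iterate
    rows = []
    for g1 in gamma1_grid:
        rates = SwitchingRates.from_alpha(g1, alpha)
        try:
            msb = solver(rates, kernel, landscape)
            ok = msb.converged
        except Exception:
            msb, ok = None, False
        if ok:
            q = appearance_probability(msb.m1, msb.M1, params)
            rows.append({"gamma1": g1, "gamma2": rates.gamma2, "q": q,
                         "pM": msb.p_M, "pS": msb.p_S, "M1": msb.M1,
                         "A": msb.A, "converged": True})
        else:
            rows.append({"gamma1": g1, "gamma2": rates.gamma2, "q": np.nan,
                         "pM": np.nan, "pS": np.nan, "M1": np.nan,
                         "A": np.nan, "converged": False})
    profile = pd.DataFrame(rows)
    valid = profile[profile["converged"]]
    if valid.empty:
        raise ParameterError("no MSB solve converged on the gamma1 grid")
    i = int(valid["q"].idxmax())
    lo = profile["gamma1"].iloc[max(i - 1, 0)]
    hi = profile["gamma1"].iloc[min(i + 1, len(profile) - 1)]
    return OptimalGamma1Result(
        gamma1_opt=float(profile["gamma1"].iloc[i]),
        q_opt=float(profile["q"].iloc[i]),
        bracket=(float(lo), float(hi)),
        profile=profile,
    )


# ---------------------------------------------------------------------------
# Population-size validity window
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSizeWindow:
    """Population sizes for which the four-class MSB picture applies:
    large enough to hold single mutants, small enough not to hold
    standing double mutants.

    The implemented reading of the window is
    ``N_low = (s / mu) e^{U/s}`` and ``N_high = (s / (tau mu))^2 e^{tau U / s}``;
    the source condition is typographically ambiguous, which the ``note``
    field records.
    """

    N_low: float
    N_high: float
    note: str = (
        "interpreted bounds: N_low=(s/mu)*exp(U/s), "
        "N_high=(s/(tau*mu))**2*exp(tau*U/s); source formula ambiguous"
    )

    @property
    def nonempty(self) -> bool:
        return self.N_low < self.N_high

    def contains(self, N: float) -> bool:
        return self.N_low < N < self.N_high

    def to_dict(self) -> dict:
        return {"N_low": self.N_low, "N_high": self.N_high,
                "nonempty": self.nonempty, "note": self.note}


def population_size_window(params: MutationParams) -> PopulationSizeWindow:
    s, mu, tau, U = params.s, params.mu, params.tau, params.U
    return PopulationSizeWindow(
        N_low=(s / mu) * np.exp(U / s),
        N_high=(s / (tau * mu)) ** 2 * np.exp(tau * U / s),
    )


__all__ = [
    "AdaptationRate", "LowSwitchingMutatorFreq", "OptimalGamma1Result",
    "PopulationSizeWindow", "adaptation_rate", "appearance_probability",
    "association", "association_from_distribution", "default_gamma1_grid",
    "mutator_freq_high_switching", "mutator_freq_low_switching",
    "optimal_gamma1", "population_size_window",
]
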