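"""Deterministic pheno-genotype recursion and mutation-selection balance.

The population state is a joint frequency distribution over pheno-genotypes
``(z, g)`` with ``z`` the mutation-rate phenotype (``m`` non-mutator, ``M``
mutator) and ``g`` a genotype of the landscape.  One generation applies, in
order,

1. phenotype switching:  ``f'_mg = (1-g1) f_mg + g2 f_Mg`` and
   ``f'_Mg = g1 f_mg + (1-g2) f_Mg``,
2. mutation:  ``f''_zg = sum_j u_{j->g} f'_zj`` with the mutator kernel
   carrying a tau-fold elevated rate,
3. selection:  ``f'''_zg = (w_g / wbar) f''_zg`` — the mutator phenotype is
   selectively neutral, so both phenotypes face the same ``w_g``.

Mutation-selection balance (MSB) is the fixed point of that map, obtained
either by iterating it from an all-non-mutator wild-type start, or as the
leading eigenvector of the composed linear (pre-normalisation) operator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .errors import (
    DegeneratePopulationError,
    NumericalError,
    ParameterError,
    StructuralError,
)
from .landscapes import BitstringLandscape, MotifLandscape

MASS_TOL = 1e-12

# assembled one-generation matrices above this size are applied blockwise
_DENSE_OPERATOR_LIMIT = 4096


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SwitchingRates:
    """Per-generation phenotype switching probabilities.

    ``gamma1``: non-mutator -> mutator; ``gamma2``: mutator -> non-mutator.
    The ratio ``alpha = gamma1 / gamma2`` links the two rates in the
    empirical inheritance systems.
    """

    gamma1: float
    gamma2: float

    def __post_init__(self):
        for name in ("gamma1", "gamma2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")

    @property
    def alpha(self) -> float:
        if self.gamma2 == 0:
            raise ParameterError("alpha undefined for gamma2 = 0")
        return self.gamma1 / self.gamma2

    @classmethod
    def from_alpha(cls, gamma1: float, alpha: float) -> "SwitchingRates":
        """Rates with ``gamma1 = alpha * gamma2``."""
        if alpha <= 0:
            raise ParameterError(f"alpha must be positive, got {alpha}")
        return cls(gamma1=gamma1, gamma2=gamma1 / alpha)


@dataclass(frozen=True)
class MutationParams:
    """Mutation model parameters.

    ``U``: genome-wide deleterious mutation rate per generation (non-mutator);
    ``tau``: fold-increase of the mutator's rate; ``n``: total locus count,
    so the per-locus rate is ``mu = U / n``; ``s``: selection coefficient
    per deleterious mutation.
    """

    U: float
    tau: float
    n: int
    s: float

    def __post_init__(self):
        if not self.U >= 0:
            raise ParameterError(f"U must be nonnegative, got {self.U}")
        if not self.tau >= 1:
            raise ParameterError(f"tau must be >= 1, got {self.tau}")
        if not self.n >= 1:
            raise ParameterError(f"n must be >= 1, got {self.n}")
        if not 0.0 < self.s < 1.0:
            raise ParameterError(f"s must be in (0, 1), got {self.s}")

    @property
    def mu(self) -> float:
        return self.U / self.n


# ---------------------------------------------------------------------------
# Distribution
# ---------------------------------------------------------------------------

PHENOTYPES = ("m", "M")


class PhenoGenotypeDistribution:
    """Joint frequencies ``f[z, g]`` over phenotype x genotype.

    ``freqs`` has shape (2, G): row 0 is the non-mutator phenotype ``m``,
    row 1 the mutator ``M``; the genotype axis follows the landscape's
    genotype ordering.
    """

    __slots__ = ("freqs",)

    def __init__(self, freqs: np.ndarray, normalize: bool = False, check: bool = True):
        freqs = np.asarray(freqs, dtype=float)
        if freqs.ndim != 2 or freqs.shape[0] != 2:
            raise StructuralError(f"freqs must have shape (2, G), got {freqs.shape}")
        if check and np.any(freqs < -MASS_TOL):
            raise StructuralError("frequencies must be nonnegative")
        if normalize:
            total = freqs.sum()
            if total <= 0:
                raise DegeneratePopulationError("total frequency is zero")
            freqs = freqs / total
        elif check and abs(freqs.sum() - 1.0) > 1e-9:
            raise StructuralError(f"frequencies must sum to 1, got {freqs.sum()}")
        self.freqs = freqs

    @classmethod
    def delta(cls, landscape, genotype_index: int | None = None,
              phenotype: str = "m") -> "PhenoGenotypeDistribution":
        """All mass on one pheno-genotype (default: non-mutator wild type)."""
        if genotype_index is None:
            genotype_index = landscape.wild_type_index
        freqs = np.zeros((2, landscape.n_genotypes))
        freqs[PHENOTYPES.index(phenotype), genotype_index] = 1.0
        return cls(freqs)

    @property
    def n_genotypes(self) -> int:
        return self.freqs.shape[1]

    @property
    def p_M(self) -> float:
        """Total mutator frequency."""
        return float(self.freqs[1].sum())

    def genotype_marginal(self) -> np.ndarray:
        return self.freqs.sum(axis=0)

    def copy(self) -> "PhenoGenotypeDistribution":
        return PhenoGenotypeDistribution(self.freqs.copy(), check=False)

    def summaries(self, landscape) -> dict[str, float]:
        """Four-class summaries and the mutator-mutant association.

        On a motif landscape the mutant class is the single mutant ``1\\0``
        (one environment-specific mutation, clean background); on a
        bitstring landscape it is every non-wild-type genotype.  ``p_M`` is
        the total mutator frequency, ``p_S = m1 + M1``, and the association
        is ``A = M1 - p_M * p_S``.
        """
        wt = landscape.wild_type_index
        mut = landscape.mutant_class_indices()
        m0 = float(self.freqs[0, wt])
        M0 = float(self.freqs[1, wt])
        m1 = float(self.freqs[0, mut].sum())
        M1 = float(self.freqs[1, mut].sum())
        p_M = self.p_M
        p_S = m1 + M1
        return {
            "m0": m0, "m1": m1, "M0": M0, "M1": M1,
            "p_M": p_M, "p_S": p_S, "A": M1 - p_M * p_S,
        }

    def l1_distance(self, other: "PhenoGenotypeDistribution") -> float:
        return float(np.abs(self.freqs - other.freqs).sum())


# ---------------------------------------------------------------------------
# Operators
# ---------------------------------------------------------------------------

def apply_switching(dist: PhenoGenotypeDistribution,
                    rates: SwitchingRates) -> PhenoGenotypeDistribution:
    """Phenotype switching; conserves per-genotype totals exactly."""
    g1, g2 = rates.gamma1, rates.gamma2
    fm, fM = dist.freqs
    out = np.empty_like(dist.freqs)
    out[0] = (1.0 - g1) * fm + g2 * fM
    out[1] = g1 * fm + (1.0 - g2) * fM
    return PhenoGenotypeDistribution(out, check=False)


@dataclass(frozen=True)
class MutationKernel:
    """Row-stochastic genotype transition matrices, rows = source genotype.

    ``u`` applies to non-mutators, ``u_tilde`` to mutators (tau-fold rate).
    """

    u: np.ndarray
    u_tilde: np.ndarray

    def __post_init__(self):
        u = np.asarray(self.u, dtype=float)
        ut = np.asarray(self.u_tilde, dtype=float)
        if u.shape != ut.shape or u.ndim != 2 or u.shape[0] != u.shape[1]:
            raise StructuralError("kernels must be square matrices of equal shape")
        for name, mat in (("u", u), ("u_tilde", ut)):
            rowsums = mat.sum(axis=1)
            if np.any(np.abs(rowsums - 1.0) > MASS_TOL):
                raise StructuralError(f"{name} rows must sum to 1 (max dev "
                                      f"{np.abs(rowsums - 1).max():.2e})")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "u_tilde", ut)

    @property
    def n_genotypes(self) -> int:
        return self.u.shape[0]


def _motif_background_kernel(U: float, K: int) -> np.ndarray:
    """Background-class transitions b -> b + l, l ~ Poisson(U), no back
    mutation; tail mass beyond the truncation bound K is lumped into
    class K so rows stay stochastic."""
    B = np.zeros((K + 1, K + 1))
    pmf = stats.poisson.pmf(np.arange(K + 1), U)
    for b in range(K + 1):
        B[b, b:K] = pmf[: K - b]
        B[b, K] = 1.0 - pmf[: K - b].sum()
    return B


def _motif_env_kernel(mu: float, A: int) -> np.ndarray:
    """Environment-specific transitions a -> a + j, j ~ Binomial(A - a, mu):
    only the unmutated loci can mutate (no back mutation)."""
    E = np.zeros((A + 1, A + 1))
    for a in range(A + 1):
        E[a, a:] = stats.binom.pmf(np.arange(A + 1 - a), A - a, mu)
    return E


def build_mutation_kernel(params: MutationParams, landscape,
                          per_locus_rate: float | None = None) -> MutationKernel:
    """Mutation kernel pair for a landscape.

    Simple (motif) landscapes: the background count gains ``l ~ Poisson(U)``
    (mutators: ``Poisson(tau U)``) mutations, the environment-specific count
    gains ``j ~ Binomial(A - a, mu)`` (mutators: ``tau mu``) with
    ``mu = U / n``; the two are independent, so the joint kernel is their
    product.  No back mutation.

    Bitstring landscapes: each locus flips independently with probability
    ``per_locus_rate`` (mutators: tau-fold higher).  The default rate is
    ``U``: each landscape locus is treated as a composite mutational target
    of the order of the genome-wide rate, the regime in which a
    moderate-size population adapts on such a landscape within hundreds of
    generations.  Pass ``per_locus_rate`` explicitly for other readings
    (e.g. ``params.mu`` for point mutations at single loci).
    """
    if isinstance(landscape, MotifLandscape):
        mu = params.mu if per_locus_rate is None else per_locus_rate
        tmu = params.tau * mu
        if mu > 1 or tmu > 1:
            raise ParameterError(
                f"per-locus rates must be <= 1, got mu={mu}, tau*mu={tmu}"
            )
        A, K = landscape.A, landscape.K
        u = np.kron(_motif_env_kernel(mu, A), _motif_background_kernel(params.U, K))
        ut = np.kron(_motif_env_kernel(tmu, A),
                     _motif_background_kernel(params.tau * params.U, K))
        return MutationKernel(u=u, u_tilde=ut)
    if isinstance(landscape, BitstringLandscape):
        mu = params.U if per_locus_rate is None else per_locus_rate
        tmu = params.tau * mu
        if mu > 1 or tmu > 1:
            raise ParameterError(
                f"per-locus rates must be <= 1, got mu={mu}, tau*mu={tmu}"
            )
        L = landscape.L
        if L > 12:
            raise ParameterError(
                f"dense bitstring kernels are limited to L <= 12, got L={L}"
            )
        g = np.arange(2 ** L, dtype=np.int64)
        d = np.bitwise_count((g[:, None] ^ g[None, :]).astype(np.uint64)).astype(int)
        u = mu ** d * (1.0 - mu) ** (L - d)
        ut = tmu ** d * (1.0 - tmu) ** (L - d)
        return MutationKernel(u=u, u_tilde=ut)
    raise StructuralError(f"unsupported landscape type {type(landscape).__name__}")


def apply_mutation(dist: PhenoGenotypeDistribution,
                   kernel: MutationKernel) -> PhenoGenotypeDistribution:
    """Mutation step; mass-conserving because the kernels are row-stochastic."""
    if kernel.n_genotypes != dist.n_genotypes:
        raise StructuralError(
            f"kernel is over {kernel.n_genotypes} genotypes, "
            f"distribution over {dist.n_genotypes}"
        )
    out = np.empty_like(dist.freqs)
    out[0] = kernel.u.T @ dist.freqs[0]
    out[1] = kernel.u_tilde.T @ dist.freqs[1]
    return PhenoGenotypeDistribution(out, check=False)


def apply_selection(dist: PhenoGenotypeDistribution,
                    landscape) -> tuple[PhenoGenotypeDistribution, float]:
    """Selection step: reweight by genotype fitness and renormalise.

    Returns the post-selection distribution and the mean fitness ``wbar``.
    The mutator phenotype is neutral: both phenotype rows see the same
    fitness vector.
    """
    w = landscape.fitness_vector()
    if w.shape[0] != dist.n_genotypes:
        raise StructuralError("landscape genotype set does not match distribution")
    weighted = dist.freqs * w[None, :]
    wbar = float(weighted.sum())
    if wbar <= 0.0:
        raise DegeneratePopulationError("mean fitness is zero")
    return PhenoGenotypeDistribution(weighted / wbar, check=False), wbar


def generation_step(dist: PhenoGenotypeDistribution, rates: SwitchingRates,
                    kernel: MutationKernel,
                    landscape) -> tuple[PhenoGenotypeDistribution, float]:
    """One deterministic generation: switching -> mutation -> selection."""
    dist = apply_switching(dist, rates)
    dist = apply_mutation(dist, kernel)
    dist, wbar = apply_selection(dist, landscape)
    # renormalise to exactly 1 to prevent floating-point drift over many steps
    dist.freqs /= dist.freqs.sum()
    return dist, wbar


# ---------------------------------------------------------------------------
# Mutation-selection balance
# ---------------------------------------------------------------------------

@dataclass
class MSBResult:
    """Equilibrium pheno-genotype distribution with derived summaries."""

    distribution: PhenoGenotypeDistribution
    p_M: float
    p_S: float
    m1: float
    M1: float
    A: float
    w_bar: float
    converged: bool
    iterations: int
    method: Literal["iterate", "eigen"] = "iterate"
    genotype_labels: list[str] = field(default_factory=list)

    @classmethod
    def _from_distribution(cls, dist, landscape, w_bar, converged, iterations,
                           method) -> "MSBResult":
        s = dist.summaries(landscape)
        return cls(
            distribution=dist, p_M=s["p_M"], p_S=s["p_S"], m1=s["m1"],
            M1=s["M1"], A=s["A"], w_bar=w_bar, converged=converged,
            iterations=iterations, method=method,
            genotype_labels=landscape.genotype_labels(),
        )

    def to_dict(self) -> dict:
        """JSON-serialisable form: genotype-keyed frequency maps + summaries."""
        labels = self.genotype_labels or [
            str(i) for i in range(self.distribution.n_genotypes)
        ]
        return {
            "frequencies": {
                z: dict(zip(labels, self.distribution.freqs[zi].tolist()))
                for zi, z in enumerate(PHENOTYPES)
            },
            "p_M": self.p_M, "p_S": self.p_S, "m1": self.m1, "M1": self.M1,
            "A": self.A, "w_bar": self.w_bar, "converged": self.converged,
            "iterations": self.iterations, "method": self.method,
        }


def assemble_generation_operator(rates: SwitchingRates, kernel: MutationKernel,
                                 landscape) -> np.ndarray:
    """The composed linear (pre-normalisation) one-generation operator.

    Acting on the stacked vector ``[f_m; f_M]`` it applies switching, then
    mutation, then fitness weighting; its leading eigenvector is the MSB
    distribution and the leading eigenvalue the equilibrium mean fitness.
    """
    G = kernel.n_genotypes
    w = landscape.fitness_vector()
    if w.shape[0] != G:
        raise StructuralError("landscape genotype set does not match kernel")
    g1, g2 = rates.gamma1, rates.gamma2
    M = np.zeros((2 * G, 2 * G))
    wu = w[:, None] * kernel.u.T      # (diag(w) @ u^T)
    wut = w[:, None] * kernel.u_tilde.T
    M[:G, :G] = (1.0 - g1) * wu
    M[:G, G:] = g2 * wu
    M[G:, :G] = g1 * wut
    M[G:, G:] = (1.0 - g2) * wut
    return M


def solve_msb_iterate(rates: SwitchingRates, kernel: MutationKernel, landscape,
                      tol: float = 1e-13, max_iter: int = 10 ** 6,
                      start: PhenoGenotypeDistribution | None = None) -> MSBResult:
    """MSB by fixed-point iteration of the full generation map.

    Starts from an all-non-mutator wild-type population and iterates until
    the L1 change per generation drops below ``tol``.  Non-convergence is
    reported through the ``converged`` flag, not raised.
    """
    G = kernel.n_genotypes
    if start is None:
        start = PhenoGenotypeDistribution.delta(landscape)
    if start.n_genotypes != G:
        raise StructuralError("start distribution does not match kernel")
    f = start.freqs.reshape(-1).copy()
    dense = 2 * G <= _DENSE_OPERATOR_LIMIT
    if dense:
        M = assemble_generation_operator(rates, kernel, landscape)
    w = landscape.fitness_vector()
    g1, g2 = rates.gamma1, rates.gamma2
    wbar = float("nan")
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        if dense:
            nxt = M @ f
        else:
            fm, fM = f[:G], f[G:]
            fpm = (1.0 - g1) * fm + g2 * fM
            fpM = g1 * fm + (1.0 - g2) * fM
            nxt = np.concatenate([w * (kernel.u.T @ fpm), w * (kernel.u_tilde.T @ fpM)])
        wbar = nxt.sum()
        if wbar <= 0:
            raise DegeneratePopulationError("mean fitness is zero")
        nxt /= wbar
        if np.abs(nxt - f).sum() < tol:
            f = nxt
            converged = True
            break
        f = nxt
    dist = PhenoGenotypeDistribution(f.reshape(2, G), check=False)
    return MSBResult._from_distribution(dist, landscape, float(wbar), converged,
                                        iterations, "iterate")


def solve_msb_eigen(rates: SwitchingRates, kernel: MutationKernel, landscape,
                    imag_tol: float = 1e-9) -> MSBResult:
    """MSB as the leading eigenvector of the mutation-selection operator.

    The eigenvector of the largest-real-part eigenvalue is made nonnegative
    and normalised to sum 1; the leading eigenvalue is the equilibrium mean
    fitness.  A leading eigenvalue with significant imaginary part raises
    :class:`NumericalError`.
    """
    M = assemble_generation_operator(rates, kernel, landscape)
    eigvals, eigvecs = np.linalg.eig(M)
    lead = int(np.argmax(eigvals.real))
    lam = eigvals[lead]
    if abs(lam.imag) > imag_tol * max(1.0, abs(lam.real)):
        raise NumericalError(
            f"leading eigenvalue is complex: {lam} (spectrum head "
            f"{np.sort_complex(eigvals)[-3:]})"
        )
    vec = eigvecs[:, lead].real
    if vec.sum() < 0:
        vec = -vec
    if vec.min() < -1e-8 * max(abs(vec).max(), 1e-300):
        raise NumericalError(
            f"leading eigenvector has significant negative entries "
            f"(min {vec.min():.2e}, max {vec.max():.2e})"
        )
    vec = np.clip(vec, 0.0, None)
    total = vec.sum()
    if total <= 0:
        raise NumericalError("leading eigenvector has zero mass")
    vec /= total
    G = kernel.n_genotypes
    dist = PhenoGenotypeDistribution(vec.reshape(2, G), check=False)
    return MSBResult._from_distribution(dist, landscape, float(lam.real), True, 0,
                                        "eigen")
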