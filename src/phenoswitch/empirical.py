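"""Switching-rate estimates for empirically described inheritance systems.

Three biological mechanisms can non-genetically transmit a mutator
phenotype across generations, each with its own per-generation switching
rates (gamma1: non-mutator -> mutator, gamma2: mutator -> non-mutator) and
fold-increase tau of the mutator's mutation rate:

* **Ada** — stochastic partitioning of the *E. coli* Ada DNA-repair
  protein; cells with zero Ada molecule are mutators.
* **Mistranslation** — cytoplasmic inheritance of a loss-of-function
  mistranslated DNA-repair protein.
* **Aneuploidy** — whole-chromosome gain/loss in yeast, associated with an
  elevated mutation rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ParameterError


@dataclass(frozen=True)
class SystemEstimate:
    """Estimated switching rates for one inheritance system."""

    system: str
    gamma1: float
    gamma2: float
    tau_preset: float

    def __post_init__(self):
        for name in ("gamma1", "gamma2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")

    @property
    def alpha(self) -> float:
        return self.gamma1 / self.gamma2

    def to_dict(self) -> dict:
        return {
            "system": self.system, "gamma1": self.gamma1, "gamma2": self.gamma2,
            "alpha": self.alpha, "tau_preset": self.tau_preset,
        }


def ada_rates(production_rate: float = 1.0,
              stationary_zero_fraction: float = 0.25) -> SystemEstimate:
    """Switching rates of the Ada system.

    Ada production in zero-Ada cells is a Poisson process with
    ``production_rate`` molecules per generation, so the mutator ->
    non-mutator rate is ``gamma2 = 1 - exp(-production_rate)`` (~0.63 at
    rate 1).  Given the observed stationary fraction ``p`` of zero-Ada
    cells, the forward rate solves the two-state stationary balance
    ``(1 - p) gamma1 = p gamma2``, giving gamma1 ~ 0.21 at p = 0.25.
    The mutator's fold-increase preset is tau = 3.
    """
    if production_rate <= 0:
        raise ParameterError(f"production_rate must be positive, got {production_rate}")
    p = stationary_zero_fraction
    if not 0.0 < p < 1.0:
        raise ParameterError(f"stationary_zero_fraction must be in (0, 1), got {p}")
    gamma2 = 1.0 - math.exp(-production_rate)
    gamma1 = p * gamma2 / (1.0 - p)
    return SystemEstimate("ada", gamma1=gamma1, gamma2=gamma2, tau_preset=3.0)


def mistranslation_rates(per_codon_error: float = 1e-3,
                         protein_length: int = 500,
                         lof_fraction: float = 0.1,
                         dilution: float = 0.5) -> SystemEstimate:
    """Switching rates from mistranslation of a single-copy DNA-repair
    protein with cytoplasmic inheritance.

    With ``sites = round(protein_length * lof_fraction)`` loss-of-function
    codons, a newly synthesised copy is defective with probability
    ``gamma1 = 1 - (1 - per_codon_error)^sites``.  A mutator cell reverts
    when the faulty copy is diluted out (probability ``dilution`` per
    division) and the replacement is translated correctly:
    ``gamma2 = dilution * (1 - per_codon_error)^sites``.  The defaults are
    the yeast estimate (error 1e-3, 500 aa, 10% LOF sites, dilution 0.5:
    gamma1 ~ 0.05, gamma2 ~ 0.476); the bacterial variant uses error 5e-4
    and 300 aa.  The fold-increase preset is tau = 100.
    """
    if not 0.0 <= per_codon_error <= 1.0:
        raise ParameterError(f"per_codon_error must be in [0, 1], got {per_codon_error}")
    if not 0.0 <= dilution <= 1.0:
        raise ParameterError(f"dilution must be in [0, 1], got {dilution}")
    if protein_length < 1 or not 0.0 < lof_fraction <= 1.0:
        raise ParameterError("protein_length must be >= 1 and lof_fraction in (0, 1]")
    sites = round(protein_length * lof_fraction)
    correct = (1.0 - per_codon_error) ** sites
    return SystemEstimate(
        "mistranslation", gamma1=1.0 - correct, gamma2=dilution * correct,
        tau_preset=100.0,
    )


def aneuploidy_rates() -> SystemEstimate:
    """Switching rates of the aneuploidy system: whole-chromosome gain at
    ~1e-4 per generation (gamma1) and loss at ~1e-5 (gamma2), literature
    constants; alpha = 10 and fold-increase preset tau = 2."""
    return SystemEstimate("aneuploidy", gamma1=1e-4, gamma2=1e-5, tau_preset=2.0)


SYSTEMS = {
    "ada": ada_rates,
    "mistranslation": mistranslation_rates,
    "aneuploidy": aneuploidy_rates,
}
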