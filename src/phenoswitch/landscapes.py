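"""Fitness landscapes for the mutator phenotype-switching model.

Two families of genotype -> fitness maps are supported:

* :class:`MotifLandscape` — the simple landscape: A environment-specific
  loci (A = 2 or 3) plus a truncated count of background deleterious
  mutations.  A genotype is a pair ``(a, b)``: the number of mutations at
  environment-specific loci and at background loci.  Before the
  environmental change every mutation is deleterious with multiplicative
  effect ``(1-s)`` per mutation; after the change the environment-specific
  classes take fitness from a motif vector ``(w_1, ..., w_A)`` with the
  full mutant fittest.

* :class:`BitstringLandscape` — an explicit table over all ``2**L`` binary
  genotypes: seeded NK landscapes of tunable ruggedness, or tabulated
  (CSV) landscapes of the kind derived from empirical data sets such as
  the *Aspergillus niger* landscape.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import numpy as np

from .errors import InvalidMotifError, LandscapeFormatError, ParameterError

MAX_BITSTRING_LOCI = 20  # full 2**L tabulation must stay in memory

Phase = Literal["pre", "post"]
MotifClass = Literal["valley", "flat", "monotonic_ascent", "other"]


# ---------------------------------------------------------------------------
# Simple motif landscape
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimpleGenotype:
    """Genotype on the simple landscape: ``a`` mutations at the
    environment-specific loci and ``b`` background deleterious mutations.

    The pair is written ``a\\b`` in the model's notation (e.g. ``2\\3``).
    """

    a: int
    b: int

    def __post_init__(self):
        if self.a < 0 or self.b < 0:
            raise ParameterError(f"genotype counts must be nonnegative, got {self}")

    def label(self) -> str:
        return f"{self.a}\\{self.b}"


@dataclass(frozen=True)
class MotifLandscape:
    """Simple fitness landscape with environment-specific and background loci.

    Parameters
    ----------
    A:
        Number of environment-specific loci (2 or 3).
    s:
        Selection coefficient per deleterious mutation, 0 < s < 1.
    K:
        Truncation bound on the background-mutation count; genotypes with
        more than ``K`` background mutations are lumped into class ``K``.
    phase:
        ``"pre"``: wild type fittest, every mutation deleterious with
        multiplicative effect ``(1-s)``.  ``"post"``: the environment has
        changed and the class-``a`` fitness comes from ``w_env``.
    w_env:
        Motif fitness vector ``(w_1, ..., w_A)`` for genotypes with
        ``a = 1..A`` mutations and no background mutations.  Required in
        the post-change phase; ``w_0 = 1`` always.
    """

    A: int
    s: float
    K: int = 30
    phase: Phase = "pre"
    w_env: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.A not in (2, 3):
            raise ParameterError(f"A must be 2 or 3, got {self.A}")
        if not 0.0 < self.s < 1.0:
            raise ParameterError(f"s must be in (0, 1), got {self.s}")
        if self.K < 0:
            raise ParameterError(f"K must be nonnegative, got {self.K}")
        if self.phase not in ("pre", "post"):
            raise ParameterError(f"phase must be 'pre' or 'post', got {self.phase!r}")
        if self.phase == "post":
            if self.w_env is None or len(self.w_env) != self.A:
                raise ParameterError(
                    f"post-change phase needs a length-{self.A} w_env vector"
                )
            object.__setattr__(self, "w_env", tuple(float(w) for w in self.w_env))
            classify_motif(self.w_env)  # raises InvalidMotifError if malformed
        elif self.w_env is not None:
            object.__setattr__(self, "w_env", tuple(float(w) for w in self.w_env))

    # -- genotype indexing ---------------------------------------------------

    @property
    def n_genotypes(self) -> int:
        return (self.A + 1) * (self.K + 1)

    def index(self, g: SimpleGenotype) -> int:
        if not (0 <= g.a <= self.A and 0 <= g.b <= self.K):
            raise ParameterError(f"genotype {g.label()} out of bounds for {self}")
        return g.a * (self.K + 1) + g.b

    def genotype(self, idx: int) -> SimpleGenotype:
        a, b = divmod(int(idx), self.K + 1)
        return SimpleGenotype(a, b)

    def genotypes(self) -> Iterator[SimpleGenotype]:
        for a in range(self.A + 1):
            for b in range(self.K + 1):
                yield SimpleGenotype(a, b)

    def genotype_labels(self) -> list[str]:
        return [g.label() for g in self.genotypes()]

    @property
    def wild_type_index(self) -> int:
        return self.index(SimpleGenotype(0, 0))

    @property
    def adaptive_index(self) -> int:
        """Index of the adaptive genotype A\\0 (post-change peak)."""
        return self.index(SimpleGenotype(self.A, 0))

    def mutant_class_indices(self) -> np.ndarray:
        """Genotype indices counted as 'single mutants' in the four-class
        summaries (class 1\\0: one environment-specific mutation, clean
        background)."""
        return np.array([self.index(SimpleGenotype(1, 0))])

    def adaptive_class_indices(self) -> np.ndarray:
        """All genotypes carrying the full complement of environment-specific
        mutations (a = A, any background)."""
        return np.arange(self.A * (self.K + 1), (self.A + 1) * (self.K + 1))

    # -- fitness -------------------------------------------------------------

    def fitness(self, g: SimpleGenotype) -> float:
        return motif_fitness(self, g)

    def fitness_vector(self) -> np.ndarray:
        b = np.arange(self.K + 1, dtype=float)
        rows = []
        for a in range(self.A + 1):
            if self.phase == "pre":
                rows.append((1.0 - self.s) ** (a + b))
            else:
                wa = 1.0 if a == 0 else self.w_env[a - 1]
                rows.append(wa * (1.0 - self.s) ** b)
        return np.concatenate(rows)

    def to_post(self, w_env: tuple[float, ...]) -> "MotifLandscape":
        """The same genotype space after the environmental change."""
        return MotifLandscape(A=self.A, s=self.s, K=self.K, phase="post", w_env=w_env)

    def to_pre(self) -> "MotifLandscape":
        return MotifLandscape(A=self.A, s=self.s, K=self.K, phase="pre")


def motif_fitness(landscape: MotifLandscape, g: SimpleGenotype) -> float:
    """Relative fitness of genotype ``a\\b`` on a simple landscape.

    Pre-change: ``(1-s)**(a+b)`` (all mutations deleterious, multiplicative).
    Post-change: ``w_a * (1-s)**b`` with ``w_0 = 1``.
    """
    if not (0 <= g.a <= landscape.A and 0 <= g.b <= landscape.K):
        raise ParameterError(
            f"genotype {g.label()} out of bounds (A={landscape.A}, K={landscape.K})"
        )
    if landscape.phase == "pre":
        return (1.0 - landscape.s) ** (g.a + g.b)
    wa = 1.0 if g.a == 0 else landscape.w_env[g.a - 1]
    return wa * (1.0 - landscape.s) ** g.b


def classify_motif(w_env: tuple[float, ...] | list[float]) -> MotifClass:
    """Classify a motif fitness vector ``(w_1, ..., w_A)``.

    The wild type has fitness 1 and the full mutant must be fittest.
    ``valley``: some intermediate class is less fit than the wild type.
    ``flat``: every intermediate class has exactly wild-type fitness.
    ``monotonic_ascent``: ``1 < w_1 < ... < w_A``.
    ``other``: none of the above (e.g. an intermediate plateau above 1).
    """
    w = tuple(float(x) for x in w_env)
    if len(w) < 1:
        raise InvalidMotifError("motif vector must have at least one entry")
    if w[-1] <= max((1.0, *w[:-1])):
        raise InvalidMotifError(
            f"full mutant must be strictly fittest: got w_env={w} (w_0=1)"
        )
    intermediates = w[:-1]
    if any(x < 1.0 for x in intermediates):
        return "valley"
    if all(x == 1.0 for x in intermediates):
        return "flat"
    ascent = all(a < b for a, b in zip((1.0, *w[:-1]), w))
    if ascent and all(x > 1.0 for x in intermediates):
        return "monotonic_ascent"
    return "other"


# ---------------------------------------------------------------------------
# Bitstring landscapes (NK and tabulated)
# ---------------------------------------------------------------------------

def _popcount(x: np.ndarray) -> np.ndarray:
    return np.bitwise_count(x.astype(np.uint64)).astype(np.int64)


@dataclass(frozen=True)
class BitstringLandscape:
    """Fitness table over all binary genotypes of ``L`` loci.

    Genotypes are encoded as integers in ``[0, 2**L)``; locus 0 is the
    most significant bit, so the integer encoding matches the fixed-width
    binary string with locus 0 leftmost.  The adaptive genotype is the
    fitness argmax (ties broken by lowest integer encoding).
    """

    L: int
    fitness: np.ndarray
    wild_type: int = 0
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if not 1 <= self.L <= MAX_BITSTRING_LOCI:
            raise ParameterError(
                f"L must be in [1, {MAX_BITSTRING_LOCI}], got {self.L}"
            )
        fit = np.asarray(self.fitness, dtype=float)
        if fit.shape != (2 ** self.L,):
            raise ParameterError(
                f"fitness must have 2**L = {2**self.L} entries, got {fit.shape}"
            )
        if not np.all(fit > 0):
            raise ParameterError("all fitness values must be positive")
        object.__setattr__(self, "fitness", fit)
        if not 0 <= self.wild_type < 2 ** self.L:
            raise ParameterError(f"wild_type {self.wild_type} out of range")

    def __eq__(self, other) -> bool:
        if not isinstance(other, BitstringLandscape):
            return NotImplemented
        return (
            self.L == other.L
            and self.wild_type == other.wild_type
            and np.array_equal(self.fitness, other.fitness)
        )

    # -- genotype indexing ---------------------------------------------------

    @property
    def n_genotypes(self) -> int:
        return 2 ** self.L

    @property
    def adaptive(self) -> int:
        return int(np.argmax(self.fitness))

    @property
    def wild_type_index(self) -> int:
        return self.wild_type

    @property
    def adaptive_index(self) -> int:
        return self.adaptive

    def genotype_labels(self) -> list[str]:
        return [format(g, f"0{self.L}b") for g in range(2 ** self.L)]

    def mutant_class_indices(self) -> np.ndarray:
        """Every genotype other than the wild type (the 'mutant' class of
        the four-class summaries on realistic landscapes)."""
        idx = np.arange(2 ** self.L)
        return idx[idx != self.wild_type]

    def adaptive_class_indices(self) -> np.ndarray:
        return np.array([self.adaptive])

    def fitness_vector(self) -> np.ndarray:
        return self.fitness

    def to_pre(self, s: float) -> "BitstringLandscape":
        """The pre-change landscape over the same genotype set: the wild
        type is fittest and every mutation away from it is deleterious with
        multiplicative effect ``(1 - s)`` per locus, mirroring the simple
        landscape's first phase.  The population equilibrates here before
        the environment changes to this landscape's own fitness table."""
        if not 0.0 < s < 1.0:
            raise ParameterError(f"s must be in (0, 1), got {s}")
        d = _popcount(np.arange(2 ** self.L) ^ self.wild_type)
        return BitstringLandscape(
            L=self.L, fitness=(1.0 - s) ** d, wild_type=self.wild_type,
            meta={**self.meta, "phase": "pre", "s": s},
        )

    # -- structure -----------------------------------------------------------

    def neighbors(self, g: int) -> np.ndarray:
        """The L genotypes one mutation away from ``g``."""
        return g ^ (1 << np.arange(self.L))

    def local_optima(self) -> np.ndarray:
        """Genotypes strictly fitter than all single-mutation neighbors,
        found by exhaustive neighborhood scan."""
        idx = np.arange(2 ** self.L)
        best = np.ones(2 ** self.L, dtype=bool)
        for i in range(self.L):
            best &= self.fitness > self.fitness[idx ^ (1 << i)]
        return idx[best]

    def hamming(self, g: int, h: int) -> int:
        return int(_popcount(np.array(g ^ h)))


def _default_wild_type(L: int, fitness: np.ndarray) -> int:
    """Default wild-type rule for generated/tabulated bitstring landscapes.

    The wild type is the local optimum with median fitness among local
    optima at Hamming distance >= 2 from the global optimum (so the
    pre-change population is not already adjacent to the peak).  If no
    local optimum qualifies, the bitwise complement of the global optimum
    is used.
    """
    tmp = BitstringLandscape(L=L, fitness=fitness, wild_type=0)
    peak = tmp.adaptive
    optima = tmp.local_optima()
    dist = _popcount(optima ^ peak)
    candidates = optima[(optima != peak) & (dist >= 2)]
    if candidates.size == 0:
        return int(peak ^ (2 ** L - 1))
    order = np.argsort(fitness[candidates], kind="stable")
    return int(candidates[order[(candidates.size - 1) // 2]])


def generate_nk(L: int, k: int, seed: int, wild_type: int | None = None) -> BitstringLandscape:
    """Generate a seeded NK landscape over ``L`` binary loci.

    Each locus has ``k`` interaction partners drawn uniformly without
    replacement among the other loci, and a contribution table of
    ``2**(k+1)`` values drawn uniform(0, 1).  Genotype fitness is the
    arithmetic mean of the per-locus contributions, so it lies in (0, 1)
    and is comparable across ``L``.  ``k = 0`` gives an additive
    (epistasis-free) landscape; ruggedness grows with ``k``.

    Identical ``(L, k, seed)`` yield a bit-identical landscape.
    """
    if not 0 <= k < L:
        raise ParameterError(f"need 0 <= k < L, got k={k}, L={L}")
    if not L <= MAX_BITSTRING_LOCI:
        raise ParameterError(f"L must be <= {MAX_BITSTRING_LOCI}, got {L}")
    rng = np.random.default_rng(seed)
    partners = np.empty((L, k), dtype=np.int64)
    for i in range(L):
        others = np.array([j for j in range(L) if j != i])
        partners[i] = rng.choice(others, size=k, replace=False)
    tables = rng.random((L, 2 ** (k + 1)))

    genotypes = np.arange(2 ** L, dtype=np.int64)
    # bit of locus j in the integer encoding (locus 0 = most significant)
    bit = lambda j: (genotypes >> (L - 1 - j)) & 1  # noqa: E731
    total = np.zeros(2 ** L)
    for i in range(L):
        idx = bit(i) << k
        for pos, j in enumerate(partners[i]):
            idx = idx | (bit(j) << (k - 1 - pos))
        total += tables[i, idx]
    fitness = total / L
    if wild_type is None:
        wild_type = _default_wild_type(L, fitness)
    meta = {"kind": "nk", "L": L, "k": k, "seed": seed}
    return BitstringLandscape(L=L, fitness=fitness, wild_type=wild_type, meta=meta)


# ---------------------------------------------------------------------------
# Tabulated landscape I/O
# ---------------------------------------------------------------------------

def write_tabulated(landscape: BitstringLandscape, path: str | Path) -> None:
    """Write a bitstring landscape as CSV with header ``genotype,fitness``.

    Genotypes are fixed-width binary strings (locus 0 leftmost); fitness
    values are written with full precision so a read round-trips exactly.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["genotype", "fitness"])
        for g in range(landscape.n_genotypes):
            writer.writerow([format(g, f"0{landscape.L}b"), repr(float(landscape.fitness[g]))])


def read_tabulated(path: str | Path, wild_type: int | None = None) -> BitstringLandscape:
    """Read a tabulated bitstring landscape (CSV, header ``genotype,fitness``).

    The table must enumerate all ``2**L`` genotypes exactly once with
    positive fitness; violations raise :class:`LandscapeFormatError` with
    the offending 1-based row number.  If ``wild_type`` is not given, the
    default wild-type rule (median-fitness local optimum at Hamming
    distance >= 2 from the peak) is applied.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise LandscapeFormatError("empty file", row=1) from None
        if [h.strip() for h in header] != ["genotype", "fitness"]:
            raise LandscapeFormatError(
                f"expected header 'genotype,fitness', got {','.join(header)!r}", row=1
            )
        L = None
        entries: dict[int, float] = {}
        for row_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2:
                raise LandscapeFormatError(f"expected 2 columns, got {len(row)}", row=row_no)
            geno, fit_str = row[0].strip(), row[1].strip()
            if not geno or set(geno) - {"0", "1"}:
                raise LandscapeFormatError(f"non-binary genotype {geno!r}", row=row_no)
            if L is None:
                L = len(geno)
                if L > MAX_BITSTRING_LOCI:
                    raise LandscapeFormatError(
                        f"genotype length {L} exceeds maximum {MAX_BITSTRING_LOCI}",
                        row=row_no,
                    )
            elif len(geno) != L:
                raise LandscapeFormatError(
                    f"genotype length {len(geno)} != {L}", row=row_no
                )
            g = int(geno, 2)
            if g in entries:
                raise LandscapeFormatError(f"duplicate genotype {geno!r}", row=row_no)
            try:
                fit = float(fit_str)
            except ValueError:
                raise LandscapeFormatError(
                    f"cannot parse fitness {fit_str!r}", row=row_no
                ) from None
            if not fit > 0:
                raise LandscapeFormatError(
                    f"fitness must be positive, got {fit}", row=row_no
                )
            entries[g] = fit
    if L is None:
        raise LandscapeFormatError("no data rows", row=2)
    if len(entries) != 2 ** L:
        missing = 2 ** L - len(entries)
        raise LandscapeFormatError(
            f"incomplete table: {missing} of {2**L} genotypes missing"
        )
    fitness = np.array([entries[g] for g in range(2 ** L)])
    if wild_type is None:
        wild_type = _default_wild_type(L, fitness)
    return BitstringLandscape(
        L=L, fitness=fitness, wild_type=wild_type, meta={"kind": "tabulated", "path": str(path)}
    )
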