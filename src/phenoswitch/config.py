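"""Run configuration and result serialization.

A :class:`RunConfig` collects everything one simulation experiment needs —
landscape specification, mutation and switching parameters, population
size, horizon, replicates, intervention, and a base seed — in a single
JSON-serialisable unit.  Every CLI run echoes its full configuration into
a manifest so results are reproducible from the manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .deterministic import MSBResult, MutationParams, SwitchingRates
from .empirical import SYSTEMS
from .errors import ConfigError
from .landscapes import MotifLandscape, generate_nk, read_tabulated
from .stochastic import AdaptationRun, InterventionSpec


@dataclass
class RunConfig:
    """One executable experiment: parameters, landscape, and seeding.

    ``landscape`` is a mapping with a ``kind`` key:
    ``{"kind": "motif", "A", "s", "K", "w_env"}`` (post-change motif vector),
    ``{"kind": "nk", "L", "k", "seed"}``, or
    ``{"kind": "tabulated", "path"}``.
    Switching rates come either from explicit ``gamma1``/``gamma2`` or from
    a named empirical ``system`` (ada, mistranslation, aneuploidy).
    """

    landscape: dict
    U: float = 4e-5
    tau: float = 100.0
    n: int | None = None
    s: float = 0.1
    gamma1: float | None = None
    gamma2: float | None = None
    system: str | None = None
    N: int = 10 ** 7
    generations: int = 2000
    replicates: int = 1000
    threshold: float = 0.99
    intervention: dict = field(default_factory=lambda: {"mode": "none"})
    base_seed: int = 0
    output_dir: str = "."

    # -- builders ------------------------------------------------------------

    def build_landscape(self):
        spec = dict(self.landscape)
        kind = spec.pop("kind", None)
        try:
            if kind == "motif":
                w_env = spec.get("w_env")
                return MotifLandscape(
                    A=spec.get("A", 2), s=spec.get("s", self.s),
                    K=spec.get("K", 30),
                    phase="post" if w_env is not None else "pre",
                    w_env=tuple(w_env) if w_env is not None else None,
                )
            if kind == "nk":
                return generate_nk(spec["L"], spec["k"], spec["seed"],
                                   wild_type=spec.get("wild_type"))
            if kind == "tabulated":
                path = Path(spec["path"])
                if not path.exists():
                    raise ConfigError(f"landscape file not found: {path}")
                return read_tabulated(path, wild_type=spec.get("wild_type"))
        except ConfigError:
            raise
        except (KeyError, ValueError, TypeError) as exc:
            raise ConfigError(f"invalid landscape spec {self.landscape}: {exc}") from exc
        raise ConfigError(f"unknown landscape kind {kind!r}")

    def build_params(self) -> MutationParams:
        n = self.n if self.n is not None else 5000
        try:
            return MutationParams(U=self.U, tau=self.tau, n=n, s=self.s)
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    def build_rates(self) -> SwitchingRates:
        if self.system is not None:
            if self.system not in SYSTEMS:
                raise ConfigError(
                    f"unknown system {self.system!r}; choose from {sorted(SYSTEMS)}"
                )
            est = SYSTEMS[self.system]()
            return SwitchingRates(gamma1=est.gamma1, gamma2=est.gamma2)
        if self.gamma1 is None or self.gamma2 is None:
            raise ConfigError("either a system name or both gamma1 and gamma2 required")
        try:
            return SwitchingRates(gamma1=self.gamma1, gamma2=self.gamma2)
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    def build_intervention(self) -> InterventionSpec:
        spec = dict(self.intervention or {"mode": "none"})
        try:
            return InterventionSpec(mode=spec.get("mode", "none"),
                                    target_pM=spec.get("target_pM"))
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "landscape" not in data:
            raise ConfigError("config must define a landscape")
        return cls(**data)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ConfigError(f"invalid JSON in {path}: {exc}") from exc
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------

def write_json(obj: dict, path: str | Path) -> None:
    """Deterministic JSON dump (sorted keys, no timestamps) so identical
    runs produce byte-identical files."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_msb_json(msb: MSBResult, path: str | Path) -> None:
    write_json(msb.to_dict(), path)


def read_msb_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def trajectory_frame(run: AdaptationRun) -> pd.DataFrame:
    return pd.DataFrame({
        "generation": np.arange(len(run.adaptive_trajectory)),
        "pM": run.pM_trajectory,
        "adaptive_freq": run.adaptive_trajectory,
        "mean_fitness": run.wbar_trajectory,
    })


def write_trajectory_csv(run: AdaptationRun, path: str | Path) -> None:
    trajectory_frame(run).to_csv(path, index=False)


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_runs_jsonl(runs: list[AdaptationRun], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for run in runs:
            fh.write(json.dumps(run.to_dict(), sort_keys=True) + "\n")
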