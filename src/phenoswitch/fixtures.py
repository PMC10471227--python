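"""Seeded fixture generators: small landscapes written to disk.

Every fixture is generated programmatically from a seed, so tests and
examples are fully self-contained and offline.  ``tabulated-tiny`` and
``nk-small`` stand in for empirically tabulated landscapes (such as the
*A. niger*-style genotype-fitness tables) — they are synthetic.
"""

from __future__ import annotations

import json
from pathlib import Path

from .errors import ParameterError
from .landscapes import MotifLandscape, generate_nk, write_tabulated

FIXTURE_KINDS = ("motif-valley", "motif-flat", "motif-ascent", "nk-small",
                 "tabulated-tiny")

_MOTIF_VECTORS = {
    # post-change motif fitness vectors (w_1, ..., w_A); s, K are defaults
    "motif-valley": (0.9, 1.5),
    "motif-flat": (1.0, 1.5),
    "motif-ascent": (1.1, 1.2, 1.3),
}


def motif_fixture(kind: str, s: float = 0.1, K: int = 30) -> MotifLandscape:
    """In-memory post-change motif landscape for a named fixture kind."""
    if kind not in _MOTIF_VECTORS:
        raise ParameterError(f"unknown motif fixture kind {kind!r}")
    w_env = _MOTIF_VECTORS[kind]
    return MotifLandscape(A=len(w_env), s=s, K=K, phase="post", w_env=w_env)


def make_fixture_landscape(kind: str, seed: int, outdir: str | Path) -> dict:
    """Write a fixture landscape plus a JSON manifest of its construction
    parameters; returns the manifest (with file paths)."""
    if kind not in FIXTURE_KINDS:
        raise ParameterError(
            f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind in _MOTIF_VECTORS:
        w_env = _MOTIF_VECTORS[kind]
        spec = {"kind": "motif", "A": len(w_env), "s": 0.1, "K": 30,
                "w_env": list(w_env)}
        landscape_path = outdir / f"{kind}.json"
        landscape_path.write_text(json.dumps(spec, indent=2, sort_keys=True) + "\n")
        manifest = {"kind": kind, "seed": seed, "landscape": str(landscape_path),
                    "spec": spec}
    else:
        if kind == "nk-small":
            L, k = 6, 1
        else:  # tabulated-tiny
            L, k = 4, 1
        landscape = generate_nk(L, k, seed)
        landscape_path = outdir / f"{kind}.csv"
        write_tabulated(landscape, landscape_path)
        manifest = {"kind": kind, "seed": seed, "landscape": str(landscape_path),
                    "spec": {"kind": "nk", "L": L, "k": k, "seed": seed,
                             "wild_type": landscape.wild_type}}
    manifest_path = outdir / f"{kind}.manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest["manifest"] = str(manifest_path)
    return manifest
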