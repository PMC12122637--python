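"""Serialization helpers: CSV for tabular artifacts, JSON for verdicts.

All writers are deterministic (fixed float formatting, sorted keys) so that
fixture bundles regenerate byte-identically under a fixed seed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .solver import SolutionField, SpaceTimeGrid
from .spectral import EigenPair

__all__ = [
    "eigenpairs_to_csv",
    "eigenfunctions_to_csv",
    "field_to_csv",
    "field_from_csv",
    "dataset_to_csv",
    "write_json",
    "write_manifest",
]

_FLOAT_FMT = "%.12g"


def eigenpairs_to_csv(pairs: Sequence[EigenPair], path: str | Path) -> None:
    df = pd.DataFrame({
        "index": [p.index for p in pairs],
        "eigenvalue": [p.eigenvalue for p in pairs],
        "multiplicity": [p.multiplicity for p in pairs],
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def eigenfunctions_to_csv(pairs: Sequence[EigenPair], x: np.ndarray,
                          path: str | Path) -> None:
    data = {"x": np.asarray(x, dtype=float)}
    for p in pairs:
        for k, f in enumerate(p.eigenfunctions):
            name = f"phi_{p.index}" + (f"_{k}" if p.multiplicity > 1 else "")
            data[name] = f(x)
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


def field_to_csv(field: SolutionField, path: str | Path) -> None:
    """Long format: one row per (x, t) node."""
    T, X = np.meshgrid(field.grid.t, field.grid.x, indexing="ij")
    df = pd.DataFrame({"x": X.ravel(), "t": T.ravel(), "u": field.values.ravel()})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def field_from_csv(path: str | Path) -> SolutionField:
    df = pd.read_csv(path)
    x = np.unique(df["x"].to_numpy())
    t = np.unique(df["t"].to_numpy())
    vals = df.sort_values(["t", "x"])["u"].to_numpy().reshape(len(t), len(x))
    return SolutionField(SpaceTimeGrid(x, t), vals, provenance="csv")


def dataset_to_csv(dataset, prefix: str | Path) -> tuple[Path, Path]:
    """Write observations as ``<prefix>.csv`` (columns x, t, y) plus a JSON
    sidecar with the ground truth and seed."""
    prefix = Path(prefix)
    # append rather than with_suffix: the prefix may contain dots (omega0.3)
    csv_path = prefix.parent / (prefix.name + ".csv")
    meta_path = prefix.parent / (prefix.name + ".meta.json")
    T, X = np.meshgrid(dataset.grid.t, dataset.grid.x, indexing="ij")
    pd.DataFrame({"x": X.ravel(), "t": T.ravel(),
                  "y": dataset.observations.ravel()}
                 ).to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    meta = {
        "true_c": dataset.truth[0],
        "true_d": dataset.truth[1],
        "omega": dataset.ic.omega,
        "coefficients": list(map(float, dataset.ic.coefficients)),
        "sigma": dataset.noise.sigma,
        "eta": dataset.noise.eta,
        "seed": dataset.seed,
    }
    write_json(meta, meta_path)
    return csv_path, meta_path


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_jsonable) + "\n")


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def write_manifest(outdir: str | Path, *, seed: int, config_digest: str,
                   extra: dict | None = None) -> Path:
    """Record seed, config hash and library versions alongside outputs."""
    import scipy
    manifest = {
        "seed": seed,
        "config_digest": config_digest,
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__},
    }
    if extra:
        manifest.update(extra)
    path = Path(outdir) / "manifest.json"
    write_json(manifest, path)
    return path
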