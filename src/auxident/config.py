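"""YAML run configuration with validated defaults.

A ``RunConfig`` collects everything a scripted analysis needs: the model
(domain + boundary condition), numerical tolerances, method-of-lines
resolution, the synthetic-experiment settings, and a seed.  Unknown keys
are rejected rather than ignored so that typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .domain import BoundarySpec, DomainSpec, ModelSpec, Topology

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    # model
    boundary: str = "dirichlet"
    robin_sigma: float | None = None
    length: float = 1.0
    topology: str = "interval"
    # tolerances
    eigen_match_rtol: float = 1e-8
    kernel_tol: float = 1e-6
    residual_tol: float = 1e-8
    # method-of-lines resolution
    mol_nx: int = 201
    mol_rtol: float = 1e-8
    mol_atol: float = 1e-10
    # synthetic experiment
    omega: float = 0.3
    n_modes: int = 8
    true_c: float = 1.0
    true_d: float = 0.05
    noise_sigma: float = 0.3
    noise_eta: float = 10.0
    c_grid: tuple[float, float, int] = (0.0, 4.0, 41)
    d_grid: tuple[float, float, int] = (1e-3, 1.0, 41)  # logarithmic
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("eigen_match_rtol", "kernel_tol", "residual_tol",
                     "mol_rtol", "mol_atol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # delegate boundary/domain validation
        self.model_spec()

    def model_spec(self) -> ModelSpec:
        domain = DomainSpec(length=self.length, topology=Topology(self.topology))
        boundary = BoundarySpec(self.boundary, robin_sigma=self.robin_sigma)
        return ModelSpec(domain, boundary)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML config; missing keys take defaults, unknown keys raise."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    known = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    for key in ("c_grid", "d_grid"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    data = asdict(cfg)
    data["c_grid"] = list(data["c_grid"])
    data["d_grid"] = list(data["d_grid"])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
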