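"""Core value types shared across the package.

The scalar model under study is the homogeneous parabolic equation

    u_t = L[A] u,   L[A] = d d²/dx² + b d/dx + c,

on an interval (0, l) or a torus, with a homogeneous Dirichlet, Neumann,
Robin, or periodic boundary condition.  A parameter point ``A = (d, b, c)``
collects the diffusivity ``d`` (length²/time, nonnegative), drift ``b``
(length/time), and the growth/decay rate ``c`` (1/time).  The operator is
linear in its parameters: L[A1]u + L[A2]u = L[A1 + A2]u, which is the single
structural property the whole identifiability framework relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Topology(str, Enum):
    INTERVAL = "interval"
    TORUS = "torus"


class BoundaryKind(str, Enum):
    DIRICHLET = "dirichlet"
    NEUMANN = "neumann"
    ROBIN = "robin"
    PERIODIC = "periodic"


@dataclass(frozen=True)
class DomainSpec:
    """A 1-D spatial domain: the interval (0, length) or a torus.

    For the torus, ``length`` is the circumference; the default torus
    circumference is 2π, on which the no-drift periodic eigenvalues take the
    simple form d·n².
    """

    length: float = 1.0
    topology: Topology = Topology.INTERVAL

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValueError(f"domain length must be positive, got {self.length}")

    @staticmethod
    def interval(length: float = 1.0) -> "DomainSpec":
        return DomainSpec(length=length, topology=Topology.INTERVAL)

    @staticmethod
    def torus(circumference: float = 2 * math.pi) -> "DomainSpec":
        return DomainSpec(length=circumference, topology=Topology.TORUS)


@dataclass(frozen=True)
class BoundarySpec:
    """Homogeneous boundary condition attached to the elliptic operator.

    Robin uses the outward-normal convention B u = u + σ ∂u/∂ν, i.e.
    u - σ u_x = 0 at x = 0 and u + σ u_x = 0 at x = l.  σ → 0 recovers the
    Dirichlet condition and σ → ±∞ the Neumann condition, so for σ > 0 the
    spectrum interlaces between the two.
    """

    kind: BoundaryKind = BoundaryKind.DIRICHLET
    robin_sigma: Optional[float] = None

    def __post_init__(self) -> None:
        kind = BoundaryKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind is BoundaryKind.ROBIN:
            if self.robin_sigma is None:
                raise ValueError("robin boundary condition requires robin_sigma")
            if self.robin_sigma == 0:
                raise ValueError("robin_sigma must be nonzero (0 is Dirichlet)")
        elif self.robin_sigma is not None:
            raise ValueError(f"robin_sigma is only valid for robin, not {kind.value}")

    @staticmethod
    def dirichlet() -> "BoundarySpec":
        return BoundarySpec(BoundaryKind.DIRICHLET)

    @staticmethod
    def neumann() -> "BoundarySpec":
        return BoundarySpec(BoundaryKind.NEUMANN)

    @staticmethod
    def robin(sigma: float) -> "BoundarySpec":
        return BoundarySpec(BoundaryKind.ROBIN, robin_sigma=sigma)

    @staticmethod
    def periodic() -> "BoundarySpec":
        return BoundarySpec(BoundaryKind.PERIODIC)


@dataclass(frozen=True)
class ModelSpec:
    """Domain + boundary condition defining the well-posed parabolic problem."""

    domain: DomainSpec = field(default_factory=DomainSpec)
    boundary: BoundarySpec = field(default_factory=BoundarySpec)

    def __post_init__(self) -> None:
        periodic = self.boundary.kind is BoundaryKind.PERIODIC
        torus = self.domain.topology is Topology.TORUS
        if periodic != torus:
            raise ValueError("periodic boundary requires (and is required by) a torus domain")

    @staticmethod
    def dirichlet(length: float = 1.0) -> "ModelSpec":
        return ModelSpec(DomainSpec.interval(length), BoundarySpec.dirichlet())

    @staticmethod
    def neumann(length: float = 1.0) -> "ModelSpec":
        return ModelSpec(DomainSpec.interval(length), BoundarySpec.neumann())

    @staticmethod
    def robin(sigma: float, length: float = 1.0) -> "ModelSpec":
        return ModelSpec(DomainSpec.interval(length), BoundarySpec.robin(sigma))

    @staticmethod
    def periodic(circumference: float = 2 * math.pi) -> "ModelSpec":
        return ModelSpec(DomainSpec.torus(circumference), BoundarySpec.periodic())


@dataclass(frozen=True)
class ParameterPoint:
    """A point A = (d, b, c) in the parameter domain [0, ∞) × R × R."""

    d: float
    b: float = 0.0
    c: float = 0.0

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError(f"diffusivity must be nonnegative, got {self.d}")

    def __sub__(self, other: "ParameterPoint") -> tuple[float, float, float]:
        return (self.d - other.d, self.b - other.b, self.c - other.c)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.d, self.b, self.c)


@dataclass(frozen=True)
class OperatorSpec:
    """The second-order part L1[A] = d d²/dx² + b d/dx restricted by a boundary
    condition; the zeroth-order coefficient c lives with the parameter point."""

    d: float
    b: float
    domain: DomainSpec
    boundary: BoundarySpec

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError(f"diffusivity must be nonnegative, got {self.d}")

    @staticmethod
    def from_model(d: float, b: float, spec: ModelSpec) -> "OperatorSpec":
        return OperatorSpec(d=d, b=b, domain=spec.domain, boundary=spec.boundary)
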