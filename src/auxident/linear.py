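"""Indistinguishability analysis of the homogeneous linear parabolic model.

The procedure operationalized here:

1.  Form the auxiliary point A = A1 - A2 (roles swapped so the diffusivity
    difference is nonnegative).
2.  Decide membership of A in the set 𝒜 = {A : ker(L[A]) ≠ {0}}, which by
    the Fredholm alternative reduces to: the zeroth-order coefficient c of
    A is an eigenvalue of -L1[A].  Points outside 𝒜 are unconditionally
    distinguishable.
3.  For A ∈ 𝒜, non-identifiability additionally requires the initial
    condition to lie in ker(L[A]) and, when drift is present, the ratio
    constraint d1/d2 = b1/b2; when both hold an explicit common solution
    u(x, t) = c0 e^{μ t} φ_n(x) of both parabolic problems is constructed
    as the witness.
4.  Optionally filter families by sign: only the sign-definite kernel mode
    (n = 1 for Dirichlet/Robin, the constant mode for Neumann/periodic) is
    compatible with nonnegative data.

Along a drift-constrained family the auxiliary eigenvalue scales linearly,
λ_n(d1 - d2, b1 - b2) = (1 - d2/d1) λ_n(d1, b1), so every partner family is
parametrized by the free diffusivity d2 with

    b2 = b1 d2/d1,     c2 = c1 - (1 - d2/d1) λ_n(d1, b1).

For b = 0 this is the familiar invariant c - d λ̄_n = const (λ̄_n the
unit-diffusivity eigenvalue; c - d π² on the unit Dirichlet domain).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Optional, Sequence

import numpy as np

from .domain import BoundaryKind, ModelSpec, OperatorSpec, ParameterPoint
from . import spectral
from .spectral import INFINITE_DIMENSIONAL, degenerate_kernel, eigenpairs

__all__ = [
    "AuxiliaryPoint",
    "SetAMembership",
    "InitialCondition",
    "IndistinguishableFamily",
    "NonidentifiableSolution",
    "Verdict",
    "ClassificationResult",
    "auxiliary_point",
    "in_set_A",
    "aux_eigenvalue",
    "indistinguishable_partners",
    "is_in_kernel",
    "construct_nonidentifiable_solution",
    "classify",
    "step4_filter",
]

_KERNEL_TOL = 1e-8


# ---------------------------------------------------------------------------
# Step 1: the auxiliary point


@dataclass(frozen=True)
class AuxiliaryPoint:
    """Difference A = A1 - A2 with roles swapped so that d >= 0."""

    d: float
    b: float
    c: float
    swapped: bool = False

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.d, self.b, self.c)


def auxiliary_point(A1: ParameterPoint, A2: ParameterPoint) -> AuxiliaryPoint:
    if A1 == A2:
        raise ValueError("points must be distinct")
    if A1.d >= A2.d:
        dd, db, dc = A1 - A2
        return AuxiliaryPoint(dd, db, dc, swapped=False)
    dd, db, dc = A2 - A1
    return AuxiliaryPoint(dd, db, dc, swapped=True)


# ---------------------------------------------------------------------------
# Step 2: membership in 𝒜


@dataclass(frozen=True)
class SetAMembership:
    in_A: bool
    index: Optional[int] = None      # matched eigen index when d > 0 (0 = constant mode)
    tag: str = ""                    # "eigen", "constant", "degenerate-neumann",
                                     # "degenerate-robin", "degenerate-zero", or ""


def in_set_A(A: AuxiliaryPoint, spec: ModelSpec,
             rtol: float = _KERNEL_TOL) -> SetAMembership:
    """Does the auxiliary elliptic problem L[A]φ = 0, Bφ = 0 admit a
    nontrivial solution?  Returns the matched eigen index (or degenerate
    tag) for downstream construction."""
    kind = spec.boundary.kind
    if A.d == 0:
        ker = degenerate_kernel(A.b, A.c, spec.boundary, spec.domain, rtol)
        if ker.dimension == INFINITE_DIMENSIONAL:
            # A1 = A2 in every coefficient: excluded upstream, but a zero
            # auxiliary operator technically has full kernel
            return SetAMembership(True, None, "degenerate-zero")
        if ker.dimension >= 1:
            tag = ("degenerate-robin" if kind is BoundaryKind.ROBIN
                   else "degenerate-neumann" if kind is BoundaryKind.NEUMANN
                   else "constant")
            return SetAMembership(True, 0 if kind is not BoundaryKind.ROBIN else None,
                                  tag)
        return SetAMembership(False)
    op = OperatorSpec.from_model(A.d, A.b, spec)
    try:
        n = spectral.matched_eigen_index(op, A.c, rtol)
    except NotImplementedError:
        raise
    if n is None:
        return SetAMembership(False)
    tag = "constant" if n == 0 else "eigen"
    return SetAMembership(True, n, tag)


def aux_eigenvalue(d: float, b: float, n: int, spec: ModelSpec) -> float:
    """n-th eigenvalue λ_n(d, b) of -L1[(d, b)] under ``spec``'s boundary
    condition (n = 0 is the zero/constant mode for Neumann/periodic)."""
    kind = spec.boundary.kind
    length = spec.domain.length
    if n == 0:
        if kind in (BoundaryKind.NEUMANN, BoundaryKind.PERIODIC):
            return 0.0
        raise ValueError(f"{kind.value} has no index-0 mode")
    if d <= 0:
        raise ValueError("aux_eigenvalue requires d > 0")
    if kind in (BoundaryKind.DIRICHLET, BoundaryKind.NEUMANN):
        return b * b / (4.0 * d) + d * (n * math.pi / length) ** 2
    if kind is BoundaryKind.PERIODIC:
        if b != 0:
            raise NotImplementedError("drifted periodic spectra are not supported")
        return d * (2.0 * math.pi * n / length) ** 2
    # Robin: numeric
    op = OperatorSpec.from_model(d, b, spec)
    for pair in eigenpairs(op, n):
        if pair.index == n:
            return pair.eigenvalue
    raise RuntimeError(f"eigen index {n} not found")


# ---------------------------------------------------------------------------
# initial conditions


class InitialCondition:
    """An initial profile u0, supplied as a callable, grid samples, or
    eigen-coefficients against a parameter point's eigenbasis.

    Must not be identically zero for identifiability queries.
    """

    def __init__(self, f: Callable[[np.ndarray], np.ndarray], label: str = "u0"):
        self._f = f
        self.label = label

    @staticmethod
    def from_callable(f: Callable[[np.ndarray], np.ndarray],
                      label: str = "u0") -> "InitialCondition":
        return InitialCondition(lambda x: np.asarray(f(np.asarray(x, dtype=float)),
                                                     dtype=float), label)

    @staticmethod
    def from_grid(x: np.ndarray, values: np.ndarray,
                  label: str = "u0-grid") -> "InitialCondition":
        x = np.asarray(x, dtype=float)
        values = np.asarray(values, dtype=float)
        return InitialCondition(lambda xx: np.interp(np.asarray(xx, dtype=float),
                                                     x, values), label)

    @staticmethod
    def from_coefficients(coeffs: Sequence[float], A: ParameterPoint,
                          spec: ModelSpec) -> "InitialCondition":
        op = OperatorSpec.from_model(A.d, A.b, spec)
        pairs = eigenpairs(op, len(coeffs) + 2)
        basis = [f for p in pairs for f in p.eigenfunctions][:len(coeffs)]
        coeffs = np.asarray(coeffs, dtype=float)

        def f(x):
            x = np.asarray(x, dtype=float)
            out = np.zeros_like(x)
            for C, g in zip(coeffs, basis):
                out += C * g(x)
            return out

        return InitialCondition(f, "u0-eigen")

    def __call__(self, x) -> np.ndarray:
        return self._f(np.asarray(x, dtype=float))

    def samples(self, spec: ModelSpec, n: int = 2001) -> tuple[np.ndarray, np.ndarray]:
        x = np.linspace(0.0, spec.domain.length, n)
        return x, self(x)

    def is_trivial(self, spec: ModelSpec, tol: float = 1e-14) -> bool:
        _, v = self.samples(spec, 513)
        return bool(np.max(np.abs(v)) <= tol)

    def satisfies_boundary(self, spec: ModelSpec, tol: float = 1e-8) -> bool:
        l = spec.domain.length
        kind = spec.boundary.kind
        h = 1e-6 * l
        u0, ul = float(self(0.0)), float(self(l))
        du0 = (float(self(h)) - u0) / h
        dul = (ul - float(self(l - h))) / h
        scale = max(1.0, abs(u0), abs(ul))
        if kind is BoundaryKind.DIRICHLET:
            return abs(u0) <= tol * scale and abs(ul) <= tol * scale
        if kind is BoundaryKind.NEUMANN:
            return abs(du0) <= 1e-4 * scale and abs(dul) <= 1e-4 * scale
        if kind is BoundaryKind.ROBIN:
            s = spec.boundary.robin_sigma
            return (abs(u0 - s * du0) <= 1e-4 * scale
                    and abs(ul + s * dul) <= 1e-4 * scale)
        return abs(u0 - ul) <= tol * scale  # periodic

    def is_nonnegative(self, spec: ModelSpec, tol: float = 1e-12) -> bool:
        _, v = self.samples(spec, 1001)
        return bool(np.min(v) >= -tol)


# ---------------------------------------------------------------------------
# kernel projection (Theorem-level membership test)


def _weight(A: AuxiliaryPoint, x: np.ndarray) -> np.ndarray:
    # e^{bx/d} symmetrizes d φ'' + b φ'; with it the eigenfunctions of the
    # drifted operator are orthogonal, making the projection well-defined
    if A.d > 0 and A.b != 0:
        return np.exp(A.b * x / A.d)
    return np.ones_like(x)


def is_in_kernel(u0: InitialCondition, A: AuxiliaryPoint, spec: ModelSpec,
                 tol: float = 1e-6) -> bool:
    """Is u0 (up to relative residual ``tol``) in ker(L[A])?

    Projects u0 onto the kernel basis under the weighted L² inner product
    that symmetrizes the drifted operator, then compares the projection
    residual against ``tol``.
    """
    if u0.is_trivial(spec):
        raise ValueError("initial condition must not be identically zero")
    op = OperatorSpec(A.d, A.b, spec.domain, spec.boundary)
    if A.d == 0:
        ker = degenerate_kernel(A.b, A.c, spec.boundary, spec.domain)
        if ker.dimension == INFINITE_DIMENSIONAL:
            return True
        basis = ker.functions
    else:
        basis = spectral.kernel_functions(op, A.c)
    if not basis:
        return False
    x, v = u0.samples(spec, 2001)
    w = _weight(A, x)
    B = np.column_stack([f(x) for f in basis])
    # weighted Gram projection via trapezoid quadrature
    wq = w * np.gradient(x)
    G = B.T @ (wq[:, None] * B)
    rhs = B.T @ (wq * v)
    coef = np.linalg.solve(G, rhs)
    resid = v - B @ coef
    num = math.sqrt(float(np.sum(wq * resid ** 2)))
    den = math.sqrt(float(np.sum(wq * v ** 2)))
    return num <= tol * den


def kernel_coefficients(u0: InitialCondition, A: AuxiliaryPoint, spec: ModelSpec
                        ) -> tuple[np.ndarray, list[Callable]]:
    """Weighted-projection coefficients of u0 on the kernel basis of L[A]."""
    op = OperatorSpec(A.d, A.b, spec.domain, spec.boundary)
    basis = (degenerate_kernel(A.b, A.c, spec.boundary, spec.domain).functions
             if A.d == 0 else spectral.kernel_functions(op, A.c))
    if not basis:
        raise ValueError("kernel of L[A] is trivial")
    x, v = u0.samples(spec, 2001)
    w = _weight(A, x)
    B = np.column_stack([f(x) for f in basis])
    wq = w * np.gradient(x)
    G = B.T @ (wq[:, None] * B)
    coef = np.linalg.solve(G, B.T @ (wq * v))
    return coef, basis


# ---------------------------------------------------------------------------
# Step 3: explicit non-identifiable solutions


class _Mode:
    """e^{-βx}(a·cq(q, x) + m·sq(q, x)) with closed-form derivatives.

    Covers every interval eigenfunction used here: sin/cos modes (q < 0),
    boundary-layer exponentials (q >= 0), and constants (β = 0, q = 0).
    """

    def __init__(self, beta: float, q: float, a: float, m: float,
                 scale: float = 1.0):
        self.beta, self.q, self.a, self.m, self.scale = beta, q, a, m, scale

    def _w(self, x):
        return self.a * spectral._cq(self.q, x) + self.m * spectral._sq(self.q, x)

    def _wp(self, x):
        # cq' = q sq, sq' = cq
        return self.a * self.q * spectral._sq(self.q, x) + self.m * spectral._cq(self.q, x)

    def f(self, x):
        x = np.asarray(x, dtype=float)
        return self.scale * np.exp(-self.beta * x) * self._w(x)

    def fx(self, x):
        x = np.asarray(x, dtype=float)
        return self.scale * np.exp(-self.beta * x) * (self._wp(x) - self.beta * self._w(x))

    def fxx(self, x):
        x = np.asarray(x, dtype=float)
        w, wp = self._w(x), self._wp(x)
        return self.scale * np.exp(-self.beta * x) * (
            self.q * w - 2 * self.beta * wp + self.beta ** 2 * w)

    def sup_normalized(self, length: float) -> "_Mode":
        g = np.linspace(0.0, length, 801)
        s = spectral._sup_scale(self.f(g))
        return _Mode(self.beta, self.q, self.a, self.m, self.scale / s)


def _kernel_modes(A: AuxiliaryPoint, n: Optional[int], spec: ModelSpec) -> list[_Mode]:
    """Analytic kernel modes of L[A] (eigenfunctions at λ = c), with
    derivatives, sup-normalized."""
    kind = spec.boundary.kind
    length = spec.domain.length
    if A.d == 0:
        if kind is BoundaryKind.ROBIN:
            return [_Mode(1.0 / spec.boundary.robin_sigma, 0.0, 1.0, 0.0)]
        return [_Mode(0.0, 0.0, 1.0, 0.0)]  # constant (Neumann/periodic)
    if n == 0:
        return [_Mode(0.0, 0.0, 1.0, 0.0)]
    beta = A.b / (2.0 * A.d)
    lam = aux_eigenvalue(A.d, A.b, n, spec)
    q = beta * beta - lam / A.d
    if kind is BoundaryKind.DIRICHLET:
        k = n * math.pi / length
        return [_Mode(beta, q, 0.0, k).sup_normalized(length)]
    if kind is BoundaryKind.NEUMANN:
        return [_Mode(beta, q, 1.0, beta).sup_normalized(length)]
    if kind is BoundaryKind.ROBIN:
        s = spec.boundary.robin_sigma
        return [_Mode(beta, q, s, s * beta + 1.0).sup_normalized(length)]
    # periodic, b = 0: cos and sin
    k = 2.0 * math.pi * n / length
    return [_Mode(0.0, -k * k, 1.0, 0.0), _Mode(0.0, -k * k, 0.0, k)]


class NonidentifiableSolution:
    """Closed-form u(x, t) = e^{μt} Σ γ_i φ_i(x) solving the parabolic
    problem under both parameter points simultaneously."""

    def __init__(self, A1: ParameterPoint, A2: ParameterPoint, spec: ModelSpec,
                 exponent: float, modes: list[_Mode], gammas: Sequence[float]):
        self.A1, self.A2, self.spec = A1, A2, spec
        self.exponent = exponent
        self.modes = modes
        self.gammas = np.asarray(gammas, dtype=float)

    def _space(self, x, deriv: int = 0) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for g, m in zip(self.gammas, self.modes):
            out += g * (m.f(x) if deriv == 0 else m.fx(x) if deriv == 1 else m.fxx(x))
        return out

    def __call__(self, x, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.exp(self.exponent * t)[..., None] * self._space(x)[None, ...] \
            if t.ndim else math.exp(self.exponent * float(t)) * self._space(x)

    def residual(self, A: ParameterPoint, grid_x: np.ndarray,
                 grid_t: np.ndarray) -> float:
        """sup |u_t - (d u_xx + b u_x + c u)| on the grid, by closed form."""
        phi = self._space(grid_x)
        lap = self._space(grid_x, 2)
        drv = self._space(grid_x, 1)
        spatial = self.exponent * phi - (A.d * lap + A.b * drv + A.c * phi)
        tmax = float(np.max(np.exp(self.exponent * np.asarray(grid_t, dtype=float))))
        return float(np.max(np.abs(spatial))) * tmax

    def on_grid(self, grid) -> "np.ndarray":
        from .solver import SolutionField
        vals = np.exp(self.exponent * grid.t)[:, None] * self._space(grid.x)[None, :]
        return SolutionField(grid, vals, provenance="analytic",
                             params=self.A1.as_tuple())


def _drift_constraint_ok(A1: ParameterPoint, A2: ParameterPoint,
                         rtol: float = 1e-9) -> bool:
    # d1/d2 = b1/b2 <=> b1 d2 = b2 d1; trivially satisfied when both drifts vanish
    if A1.b == 0.0 and A2.b == 0.0:
        return True
    if (A1.b == 0.0) != (A2.b == 0.0):
        return False
    return math.isclose(A1.b * A2.d, A2.b * A1.d,
                        rel_tol=rtol, abs_tol=1e-12)


def construct_nonidentifiable_solution(A1: ParameterPoint, A2: ParameterPoint,
                                       n: Optional[int], c0: float,
                                       spec: ModelSpec,
                                       gammas: Optional[Sequence[float]] = None,
                                       rtol: float = 1e-6
                                       ) -> NonidentifiableSolution:
    """Explicit common solution of the parabolic problem under A1 and A2.

    For eigen index n >= 1 the solution is c0 e^{μt} φ_n with
    μ = c1 - (d1/d) λ_n(d, b) evaluated at the auxiliary point (d, b);
    for the constant mode μ = c1 = c2; for the degenerate Robin family
    μ = d1/σ² - b1/σ + c1.  ``gammas`` selects the mixture for multiplicity
    two (periodic) kernels.
    """
    A = auxiliary_point(A1, A2)
    member = in_set_A(A, spec, max(rtol, _KERNEL_TOL))
    if not member.in_A:
        raise ValueError(f"A1 - A2 = {A.as_tuple()} is not in the set 𝒜; "
                         "no common solution exists")
    base, other = (A2, A1) if A.swapped else (A1, A2)
    kind = spec.boundary.kind
    if member.tag == "degenerate-robin":
        s = spec.boundary.robin_sigma
        mu = base.d / s ** 2 - base.b / s + base.c
        modes = _kernel_modes(A, None, spec)
    elif member.tag in ("constant", "degenerate-neumann", "degenerate-zero"):
        mu = base.c
        modes = _kernel_modes(A, 0, spec)
    else:
        if n is None:
            n = member.index
        elif member.index != n:
            raise ValueError(f"requested eigen index {n} does not match the "
                             f"auxiliary point's kernel (matched index {member.index})")
        if A.b != 0 and not _drift_constraint_ok(A1, A2):
            raise ValueError(
                "drift constraint d1/d2 = b1/b2 violated: "
                f"b1*d2 = {A1.b * A2.d:g} != b2*d1 = {A2.b * A1.d:g}")
        lam = aux_eigenvalue(A.d, A.b, n, spec)
        mu = base.c - (base.d / A.d) * lam
        modes = _kernel_modes(A, n, spec)
    if gammas is None:
        gammas = [c0] + [0.0] * (len(modes) - 1)
    else:
        gammas = [c0 * g for g in gammas]
        if len(gammas) != len(modes):
            raise ValueError(f"expected {len(modes)} mixture coefficients")
    return NonidentifiableSolution(A1, A2, spec, mu, modes, gammas)


# ---------------------------------------------------------------------------
# partner families


@dataclass
class IndistinguishableFamily:
    """The slice of 𝒜 through a base point A1 at eigen index n: all A2 with
    A1 - A2 in 𝒜 via that index, parametrized by the free diffusivity d2."""

    base: ParameterPoint
    spec: ModelSpec
    index: Optional[int]               # eigen index; None for degenerate Robin
    tag: str = "eigen"                 # "eigen" | "constant" | "degenerate-robin"
    classification: str = "A_NI"
    base_eigenvalue: float = 0.0       # λ_n(d1, b1), 0 for constant mode

    @property
    def nonnegative_compatible(self) -> bool:
        kind = self.spec.boundary.kind
        if self.tag in ("constant", "degenerate-robin"):
            return True
        if kind in (BoundaryKind.DIRICHLET, BoundaryKind.ROBIN):
            return self.index == 1
        return self.index == 0

    def partner_from_d(self, d2: float) -> ParameterPoint:
        if d2 < 0:
            raise ValueError("partner diffusivity must be nonnegative")
        A1 = self.base
        if self.tag == "constant":
            return ParameterPoint(d2, A1.b, A1.c)
        if self.tag == "degenerate-robin":
            raise ValueError("the degenerate Robin family is parametrized by "
                             "drift; use partner_from_b")
        if d2 == A1.d:
            raise ValueError("partner must differ from the base point")
        b2 = A1.b * d2 / A1.d
        c2 = A1.c - (1.0 - d2 / A1.d) * self.base_eigenvalue
        return ParameterPoint(d2, b2, c2)

    def partner_from_c(self, c2: float) -> ParameterPoint:
        A1 = self.base
        if self.tag == "constant":
            raise ValueError("the constant-mode family fixes c2 = c1; "
                             "parametrize by (d2, b2) instead")
        if self.tag == "degenerate-robin":
            s = self.spec.boundary.robin_sigma
            b2 = A1.b - s * (A1.c - c2)
            return ParameterPoint(A1.d, b2, c2)
        if self.base_eigenvalue == 0:
            raise ValueError("zero eigenvalue cannot be inverted for d2")
        d2 = A1.d * (1.0 - (A1.c - c2) / self.base_eigenvalue)
        if d2 < 0:
            raise ValueError(f"requested c2 = {c2:g} needs negative diffusivity "
                             f"d2 = {d2:g}")
        return self.partner_from_d(d2)

    def partner_from_b(self, b2: float) -> ParameterPoint:
        if self.tag != "degenerate-robin":
            raise ValueError("drift parametrization only for the degenerate "
                             "Robin family")
        A1 = self.base
        s = self.spec.boundary.robin_sigma
        c2 = A1.c - (A1.b - b2) / s
        return ParameterPoint(A1.d, b2, c2)

    def sample(self, k: int = 5, seed: int = 0,
               span: tuple[float, float] = (0.25, 4.0)) -> list[ParameterPoint]:
        """k partners on a logarithmic grid of d2/d1 (skipping 1)."""
        if self.tag == "degenerate-robin":
            offsets = np.linspace(0.5, 2.0, k)
            return [self.partner_from_b(self.base.b + o) for o in offsets]
        if self.tag == "constant":
            rng = np.random.default_rng(seed)
            return [ParameterPoint(float(d2), self.base.b, self.base.c)
                    for d2 in rng.uniform(0.1, 2.0, k) * max(self.base.d, 1.0)]
        ratios = np.geomspace(span[0], span[1], k + 1)
        ratios = ratios[np.abs(ratios - 1.0) > 1e-9][:k]
        return [self.partner_from_d(self.base.d * float(r)) for r in ratios]

    def to_dict(self) -> dict:
        return {
            "base": self.base.as_tuple(),
            "boundary": self.spec.boundary.kind.value,
            "index": self.index,
            "tag": self.tag,
            "classification": self.classification,
            "base_eigenvalue": self.base_eigenvalue,
            "nonnegative_compatible": self.nonnegative_compatible,
            "constraints": {
                "b2": f"b1 * d2 / d1",
                "c2": "c1 - (1 - d2/d1) * lambda_n(d1, b1)",
            },
        }


def indistinguishable_partners(A1: ParameterPoint, spec: ModelSpec,
                               n: Optional[int] = 1, *,
                               drift: bool = False,
                               degenerate_robin: bool = False
                               ) -> IndistinguishableFamily:
    """Family of partners A2 indistinguishable from A1 via eigen index n.

    With ``drift`` and b1 = 0 the drift family collapses onto the no-drift
    one (the ratio constraint forces b2 = 0); requesting a drifted partner
    of a drift-free base point is impossible, mirroring the sign constraint
    that b1 and b2 must agree.
    """
    kind = spec.boundary.kind
    if degenerate_robin:
        if kind is not BoundaryKind.ROBIN:
            raise ValueError("degenerate family requires a Robin boundary")
        return IndistinguishableFamily(A1, spec, None, tag="degenerate-robin")
    if n == 0:
        if kind not in (BoundaryKind.NEUMANN, BoundaryKind.PERIODIC):
            raise ValueError(f"{kind.value} has no constant mode")
        if A1.c != 0.0 and kind is BoundaryKind.NEUMANN:
            # the constant-mode family exists for every c1 (c2 = c1); only
            # the auxiliary c vanishes
            pass
        return IndistinguishableFamily(A1, spec, 0, tag="constant")
    if A1.d <= 0:
        raise ValueError("eigen families require a base point with d > 0")
    lam = aux_eigenvalue(A1.d, A1.b, n, spec)
    fam = IndistinguishableFamily(A1, spec, n, tag="eigen", base_eigenvalue=lam)
    if drift and A1.b == 0.0:
        raise ValueError("the sign of b1 and b2 must be the same: a drift-free "
                         "base point admits no drifted partners")
    return fam


def step4_filter(families: Sequence[IndistinguishableFamily]
                 ) -> list[IndistinguishableFamily]:
    """Keep only families whose kernel mode has no sign change, i.e. those
    compatible with nonnegative measurements (Step 4)."""
    return [f for f in families if f.nonnegative_compatible]


# ---------------------------------------------------------------------------
# classification (Theorem-level verdicts)


class Verdict(str, Enum):
    DISTINGUISHABLE_R = "distinguishable_R"
    DISTINGUISHABLE_AI = "distinguishable_AI"
    INDISTINGUISHABLE_ANI = "indistinguishable_ANI"


@dataclass
class ClassificationResult:
    verdict: Verdict
    auxiliary: AuxiliaryPoint
    membership: SetAMembership
    witness: Optional[NonidentifiableSolution] = None
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict.value,
            "auxiliary_point": self.auxiliary.as_tuple(),
            "in_A": self.membership.in_A,
            "matched_index": self.membership.index,
            "tag": self.membership.tag,
            "note": self.note,
            "witness_exponent": None if self.witness is None
            else self.witness.exponent,
        }


def classify(A1: ParameterPoint, A2: ParameterPoint, u0: InitialCondition,
             spec: ModelSpec, tol: float = 1e-6) -> ClassificationResult:
    """Classify the pair (A1, A2) with respect to the initial condition u0.

    * ``distinguishable_R``: A1 - A2 outside 𝒜 — unconditionally
      distinguishable, no initial condition can hide the difference;
    * ``distinguishable_AI``: the auxiliary kernel is nontrivial but u0 is
      not in it (or the drift ratio constraint fails), so the solutions
      still separate;
    * ``indistinguishable_ANI``: u0 lies in the kernel and a common
      solution of both problems exists — returned as the witness.

    Symmetric in (A1, A2).
    """
    if u0.is_trivial(spec):
        raise ValueError("initial condition must not be identically zero")
    A = auxiliary_point(A1, A2)
    member = in_set_A(A, spec)
    if not member.in_A:
        return ClassificationResult(Verdict.DISTINGUISHABLE_R, A, member)
    if A.d > 0 and A.b != 0 and not _drift_constraint_ok(A1, A2):
        return ClassificationResult(
            Verdict.DISTINGUISHABLE_AI, A, member,
            note="auxiliary kernel nontrivial but drift ratio d1/d2 = b1/b2 fails")
    if not is_in_kernel(u0, A, spec, tol):
        return ClassificationResult(
            Verdict.DISTINGUISHABLE_AI, A, member,
            note="u0 is not in ker(L[A])")
    coef, basis = kernel_coefficients(u0, A, spec)
    if member.tag == "degenerate-zero":
        witness = None
        note = "auxiliary operator is zero (identical coefficients)"
    else:
        lead = float(coef[0]) if len(coef) else 1.0
        gammas = (coef / lead) if lead != 0 else coef
        witness = construct_nonidentifiable_solution(
            A1, A2, member.index, lead, spec,
            gammas=list(gammas) if len(coef) > 1 else None)
        note = "common solution constructed from the kernel projection of u0"
    return ClassificationResult(Verdict.INDISTINGUISHABLE_ANI, A, member,
                                witness=witness, note=note)
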