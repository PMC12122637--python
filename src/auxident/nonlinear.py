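"""Identifiability of reaction-diffusion models with logistic-type reactions.

For u_t - d1 Δu = f(x, u; B1) with f linear in B, assuming two parameter
points share a solution leads to the auxiliary *nonlinear* elliptic problem

    -(d1 - d2) Δψ = f(x, ψ; B1 - B2),   Bψ = 0.

Identifiability is then read off the solution set of that problem: if it is
a single point (only ψ ≡ 0) or a discrete set, any shared solution would
have to be a steady state, contradicting temporal variation in the data —
so the pair is distinguishable whenever u_t ≢ 0.  For the logistic reaction
aψ - bψ² the solution set is always discrete (classical uniqueness of the
positive steady state, plus the ψ ↦ -ψ, b ↦ -b symmetry), so the logistic
model is unconditionally identifiable away from steady-state data.

Steady profiles are found by shooting with a log-spaced multistart over the
free endpoint value/slope, followed by sup-norm deduplication; the number
of distinct profiles decides the spectrum type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .domain import BoundaryKind, ModelSpec
from .solver import SpaceTimeGrid, solve_mol

__all__ = [
    "ReactionSpec",
    "SteadyProfile",
    "EllipticSolutionSet",
    "solve_auxiliary_elliptic",
    "classify_nonlinear_pair",
    "heterogeneous_logistic_check",
]


@dataclass(frozen=True)
class ReactionSpec:
    """f(x, u; B): ``logistic`` is a·u - b·u² with B = (a, b);
    ``heterogeneous_logistic`` is m(x)·u - b·u² with B = (m(·), b).
    Both satisfy f(x, 0; B) = 0 and are linear in B."""

    form: str
    a: float | None = None
    b: float | None = None
    m: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.form not in ("logistic", "heterogeneous_logistic"):
            raise ValueError(f"unknown reaction form {self.form!r}")
        if self.form == "logistic" and (self.a is None or self.b is None):
            raise ValueError("logistic reaction needs (a, b)")
        if self.form == "heterogeneous_logistic" and (self.m is None or self.b is None):
            raise ValueError("heterogeneous logistic needs (m(x), b)")

    def __call__(self, x: np.ndarray, u: np.ndarray) -> np.ndarray:
        if self.form == "logistic":
            return self.a * u - self.b * u * u
        return self.m(x) * u - self.b * u * u

    @staticmethod
    def logistic(a: float, b: float) -> "ReactionSpec":
        return ReactionSpec("logistic", a=a, b=b)

    @staticmethod
    def heterogeneous(m: Callable, b: float) -> "ReactionSpec":
        return ReactionSpec("heterogeneous_logistic", m=m, b=b)


@dataclass
class SteadyProfile:
    x: np.ndarray
    values: np.ndarray

    def sup_distance(self, other: "SteadyProfile") -> float:
        return float(np.max(np.abs(self.values - other.values)))

    @property
    def is_trivial(self) -> bool:
        return bool(np.max(np.abs(self.values)) < 1e-9)


@dataclass
class EllipticSolutionSet:
    """Solutions of -dΔψ = f(x, ψ; B) under the boundary condition, found by
    multistart shooting and deduplicated; classifies the auxiliary point."""

    profiles: list[SteadyProfile]
    spectrum_type: str        # "unique_trivial" | "discrete" | "continuous"
    classification: str       # "R" | "A_I" | "A_NI"
    degenerate: bool = False  # reaction vanished identically

    @property
    def count(self) -> int:
        return len(self.profiles)


_DEDUP_TOL = 1e-6


def _shoot(d: float, reaction: ReactionSpec, spec: ModelSpec, free: float,
           nx: int = 401) -> Optional[SteadyProfile]:
    """Integrate the steady ODE -dψ'' = f(x, ψ) from x = 0 with the left
    boundary condition folded in; ``free`` is the unconstrained left datum
    (slope for Dirichlet, value for Neumann, slope for Robin)."""
    length = spec.domain.length
    kind = spec.boundary.kind
    if kind is BoundaryKind.DIRICHLET:
        y0 = [0.0, free]
    elif kind is BoundaryKind.NEUMANN:
        y0 = [free, 0.0]
    elif kind is BoundaryKind.ROBIN:
        y0 = [spec.boundary.robin_sigma * free, free]  # u(0) = σ u'(0)
    else:
        raise ValueError("shooting is defined on the interval, not the torus")

    def rhs(x, y):
        return [y[1], -reaction(np.asarray(x), np.asarray(y[0])) / d]

    def blowup(x, y):
        return 1e6 - abs(y[0])
    blowup.terminal = True

    xs = np.linspace(0.0, length, nx)
    sol = solve_ivp(rhs, (0.0, length), y0, t_eval=xs, rtol=1e-10, atol=1e-12,
                    events=blowup, dense_output=False)
    if sol.status != 0 or sol.t[-1] < length:
        return None
    return SteadyProfile(xs, sol.y[0]), float(sol.y[1, -1])


def _right_residual(profile_slope, spec: ModelSpec) -> float:
    if profile_slope is None:
        return math.nan
    profile, slope_end = profile_slope
    kind = spec.boundary.kind
    if kind is BoundaryKind.DIRICHLET:
        return float(profile.values[-1])
    if kind is BoundaryKind.NEUMANN:
        return slope_end
    s = spec.boundary.robin_sigma
    return float(profile.values[-1]) + s * slope_end


def solve_auxiliary_elliptic(d: float, reaction: ReactionSpec, spec: ModelSpec,
                             *, n_starts: int = 41,
                             start_range: tuple[float, float] = (1e-3, 1e2),
                             dedup_tol: float = _DEDUP_TOL,
                             nonnegative: bool = True
                             ) -> EllipticSolutionSet:
    """Solve -dΔψ = f(x, ψ; B), Bψ = 0 and classify the auxiliary point.

    d = 0 reduces to the pointwise algebraic equation f(x, ψ) = 0; d > 0
    uses shooting with a log-spaced multistart over positive and negative
    left data.  Solution counts: 1 (trivial only) → R; finitely many → A_I;
    a continuum (vanishing reaction) → degenerate/continuous.

    ``nonnegative`` (default) keeps only sign-compatible profiles: a shared
    solution of two density models must itself be a nonnegative profile, so
    sign-changing steady states are not admissible witnesses.  Pass False to
    enumerate every steady state the multistart finds.
    """
    length = spec.domain.length
    xs = np.linspace(0.0, length, 401)
    zero = SteadyProfile(xs, np.zeros_like(xs))
    if reaction.form == "logistic" and reaction.a == 0 and reaction.b == 0:
        return EllipticSolutionSet([zero], "continuous", "A_NI", degenerate=True)
    if d == 0:
        profiles = [zero]
        if reaction.form == "logistic":
            if reaction.b != 0:
                val = reaction.a / reaction.b
                cand = SteadyProfile(xs, np.full_like(xs, val))
                if _constant_admissible(val, spec) and cand.sup_distance(zero) > dedup_tol:
                    profiles.append(cand)
        else:
            mv = reaction.m(xs)
            if np.ptp(mv) < 1e-12 and reaction.b != 0:
                val = float(mv[0]) / reaction.b   # nonzero root of mψ - bψ²
                if val != 0 and _constant_admissible(val, spec):
                    profiles.append(SteadyProfile(xs, np.full_like(xs, val)))
        spectrum = "unique_trivial" if len(profiles) == 1 else "discrete"
        return EllipticSolutionSet(profiles, spectrum,
                                   "R" if len(profiles) == 1 else "A_I")
    if d < 0:
        raise ValueError("auxiliary diffusivity must be nonnegative")

    lo, hi = start_range
    half = max(3, n_starts // 2)
    pos = np.geomspace(lo, hi, half)
    starts = np.concatenate([[0.0], pos, -pos])
    starts.sort()
    residuals = []
    for s in starts:
        residuals.append(_right_residual(_shoot(d, reaction, spec, s), spec))
    residuals = np.array(residuals)

    roots: list[float] = [0.0] if spec.boundary.kind is not BoundaryKind.ROBIN else []
    # ψ ≡ 0 corresponds to free datum 0 for Dirichlet/Neumann; keep it and
    # bracket the rest
    def res_of(s: float) -> float:
        return _right_residual(_shoot(d, reaction, spec, s), spec)

    for i in range(len(starts) - 1):
        s0, s1 = float(starts[i]), float(starts[i + 1])
        r0, r1 = residuals[i], residuals[i + 1]
        if math.isnan(r0) and math.isnan(r1):
            continue
        if math.isnan(r1):
            # shrink toward the finite end until the integration survives
            s0f, r0f = s0, r0
            for _ in range(40):
                mid = 0.5 * (s0f + s1)
                rm = res_of(mid)
                if math.isnan(rm):
                    s1 = mid
                else:
                    s0f, r0f = mid, rm
            s0, s1, r0, r1 = s0, s0f, r0, r0f
        elif math.isnan(r0):
            s1f, r1f = s1, r1
            for _ in range(40):
                mid = 0.5 * (s0 + s1f)
                rm = res_of(mid)
                if math.isnan(rm):
                    s0 = mid
                else:
                    s1f, r1f = mid, rm
            s0, s1, r0, r1 = s1f, s1, r1f, r1
        if r0 == 0.0 and abs(s0) > 1e-12:
            roots.append(s0)
        elif r0 * r1 < 0:
            try:
                root = brentq(res_of, s0, s1, xtol=1e-12, rtol=1e-12)
            except ValueError:
                continue
            roots.append(root)
    profiles: list[SteadyProfile] = []
    for s in roots:
        shot = _shoot(d, reaction, spec, s)
        if shot is None:
            continue
        prof = shot[0]
        if nonnegative and float(np.min(prof.values)) < -1e-9 * max(
                1.0, float(np.max(np.abs(prof.values)))):
            continue
        if all(prof.sup_distance(p) > dedup_tol * max(1.0, np.max(np.abs(prof.values)))
               for p in profiles):
            profiles.append(prof)
    if not any(p.is_trivial for p in profiles):
        profiles.insert(0, zero)
    spectrum = "unique_trivial" if len(profiles) == 1 else "discrete"
    return EllipticSolutionSet(profiles, spectrum,
                               "R" if len(profiles) == 1 else "A_I")


def _constant_admissible(val: float, spec: ModelSpec) -> bool:
    # a nonzero constant satisfies Neumann/periodic but not Dirichlet/Robin
    return spec.boundary.kind in (BoundaryKind.NEUMANN, BoundaryKind.PERIODIC)


@dataclass
class NonlinearVerdict:
    verdict: str                      # "distinguishable" | "inconclusive-steady"
    auxiliary_d: float
    solution_set: Optional[EllipticSolutionSet]
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "auxiliary_d": self.auxiliary_d,
            "spectrum_type": None if self.solution_set is None
            else self.solution_set.spectrum_type,
            "n_profiles": None if self.solution_set is None
            else self.solution_set.count,
            "note": self.note,
        }


def _temporally_constant(U, dt_tol: float = 1e-8) -> bool:
    du = np.abs(np.diff(U.values, axis=0)) / np.diff(U.grid.t)[:, None]
    return bool(np.max(du) <= dt_tol)


def classify_nonlinear_pair(d1: float, B1: tuple[float, float],
                            d2: float, B2: tuple[float, float],
                            spec: ModelSpec,
                            u0: Callable[[np.ndarray], np.ndarray],
                            *, grid: Optional[SpaceTimeGrid] = None,
                            nx: int = 201) -> NonlinearVerdict:
    """Classify a pair of logistic reaction-diffusion parameter points.

    A forward method-of-lines solve from u0 first checks the temporal
    variation hypothesis u_t ≢ 0 (steady data is inconclusive); the verdict
    then follows from the solution set of the auxiliary elliptic problem
    with (d, a, b) = (d1 - d2, a1 - a2, b1 - b2): unique or discrete means
    distinguishable.
    """
    if grid is None:
        grid = SpaceTimeGrid.regular(spec.domain.length, 1.0, 21, 11)
    U = solve_mol("logistic", B1, d1, 0.0, u0, spec, grid, nx=nx)
    if _temporally_constant(U):
        return NonlinearVerdict("inconclusive-steady", abs(d1 - d2), None,
                                "u_t ≡ 0: the identifiability argument "
                                "requires temporal variation in the data")
    if (d1, *B1) == (d2, *B2):
        raise ValueError("parameter points must be distinct")
    d = d1 - d2
    a, b = B1[0] - B2[0], B1[1] - B2[1]
    if d < 0:
        d, a, b = -d, -a, -b
    if b < 0:
        # ψ -> -ψ maps (a, b) to (a, -b): same solution count
        a_eff, b_eff = -a, -b
    else:
        a_eff, b_eff = a, b
    sol_set = solve_auxiliary_elliptic(d, ReactionSpec.logistic(a_eff, b_eff), spec)
    if sol_set.spectrum_type in ("unique_trivial", "discrete"):
        return NonlinearVerdict("distinguishable", d, sol_set,
                                "auxiliary solution set is "
                                f"{sol_set.spectrum_type} ({sol_set.count} profiles)")
    return NonlinearVerdict("potentially-nonidentifiable", d, sol_set,
                            "auxiliary problem admits a continuum")


def heterogeneous_logistic_check(m1: Callable, b1: float, m2: Callable, b2: float,
                                 d1: float, d2: float, spec: ModelSpec
                                 ) -> NonlinearVerdict:
    """Spatially heterogeneous logistic reaction m(x)u - bu² under Neumann
    boundary conditions: the auxiliary problem with m = m1 - m2, b = b1 - b2
    has at most one positive profile, so distinct pairs are distinguishable
    (away from steady data)."""
    if spec.boundary.kind is not BoundaryKind.NEUMANN:
        raise ValueError("the heterogeneous-logistic analysis assumes Neumann "
                         "boundary conditions")
    d = d1 - d2
    m = lambda x: np.asarray(m1(x), dtype=float) - np.asarray(m2(x), dtype=float)
    b = b1 - b2
    if d < 0:
        d = -d
        m_eff = lambda x: -m(x)
        b_eff = -b
    else:
        m_eff, b_eff = m, b
    if b_eff < 0:
        m_inner = m_eff
        m_eff = lambda x: -m_inner(x)
        b_eff = -b_eff
    xs = np.linspace(0.0, spec.domain.length, 401)
    if np.max(np.abs(m_eff(xs))) < 1e-14 and b_eff == 0:
        return NonlinearVerdict("degenerate", d, None,
                                "auxiliary reaction vanishes identically; "
                                "any constant is a steady profile")
    reaction = ReactionSpec.heterogeneous(m_eff, b_eff)
    sol_set = solve_auxiliary_elliptic(d, reaction, spec)
    return NonlinearVerdict("distinguishable", d, sol_set,
                            f"{sol_set.count} steady profiles "
                            f"({sol_set.spectrum_type})")
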