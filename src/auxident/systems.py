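"""Non-identifiable solutions of a two-species cell motility model.

The coupled linear system

    u_t - d_u Δu =  a11 u - a12 v,
    v_t - d_v Δv = -a21 u + a22 v,       a_ij > 0,

inherits non-identifiability from the scalar theory: take a scalar
indistinguishable pair (d1, c1) ~ (d2, c2) (so both scalar problems share
the solution u1), set (u, v) = (κ_u u1, κ_v u1), and for *any* positive
constants δ1, δ2 the parameters

    d_u = d1, a11 = c1 + δ1, a12 = δ1 κ_u/κ_v,
    d_v = d2, a22 = c2 + δ2, a21 = δ2 κ_v/κ_u,

reproduce exactly the same trajectory — a continuum of indistinguishable
parameter sets indexed by (δ1, δ2).  The δ_i must exceed max(0, -c_i) so
that every a_ij stays positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .domain import ModelSpec, ParameterPoint
from .linear import NonidentifiableSolution, construct_nonidentifiable_solution
from .solver import SolutionField, SpaceTimeGrid, build_space_operator

__all__ = [
    "TwoSpeciesParams",
    "ConstructionInputs",
    "TwoSpeciesSolution",
    "build_two_species",
    "family_sweep",
    "solve_mol_two_species",
]


@dataclass(frozen=True)
class TwoSpeciesParams:
    d_u: float
    d_v: float
    a11: float
    a12: float
    a21: float
    a22: float

    def __post_init__(self) -> None:
        if self.d_u < 0 or self.d_v < 0:
            raise ValueError("diffusivities must be nonnegative")
        for name in ("a11", "a12", "a21", "a22"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.d_u, self.d_v, self.a11, self.a12, self.a21, self.a22)


@dataclass(frozen=True)
class ConstructionInputs:
    """Scalar indistinguishable pair plus the free construction constants."""

    d1: float
    c1: float
    d2: float
    c2: float
    kappa_u: float = 1.0
    kappa_v: float = 1.0
    delta1: float = 1.0
    delta2: float = 1.0
    eigen_index: int = 1

    def __post_init__(self) -> None:
        if self.kappa_u <= 0 or self.kappa_v <= 0:
            raise ValueError("amplitudes κ must be positive")
        if self.delta1 <= max(0.0, -self.c1) or self.delta2 <= max(0.0, -self.c2):
            raise ValueError("δ_i must exceed max(0, -c_i) so that a_ii > 0")


@dataclass
class TwoSpeciesSolution:
    params: TwoSpeciesParams
    scalar: NonidentifiableSolution
    kappa_u: float
    kappa_v: float

    def u(self, x, t):
        return self.kappa_u * self.scalar(x, t)

    def v(self, x, t):
        return self.kappa_v * self.scalar(x, t)

    def residuals(self, grid_x: np.ndarray, grid_t: np.ndarray) -> tuple[float, float]:
        """sup-norm residuals of both PDEs on the grid, from the closed form."""
        p = self.params
        mu = self.scalar.exponent
        phi = self.scalar._space(grid_x)
        lap = self.scalar._space(grid_x, 2)
        ku, kv = self.kappa_u, self.kappa_v
        # u_t - d_u u_xx - a11 u + a12 v, with (u, v) = (κ_u, κ_v) e^{μt} φ
        r1 = ku * (mu * phi - p.d_u * lap) - p.a11 * ku * phi + p.a12 * kv * phi
        r2 = kv * (mu * phi - p.d_v * lap) + p.a21 * ku * phi - p.a22 * kv * phi
        tmax = float(np.max(np.exp(mu * np.asarray(grid_t, dtype=float))))
        return (float(np.max(np.abs(r1))) * tmax, float(np.max(np.abs(r2))) * tmax)


def build_two_species(inputs: ConstructionInputs, spec: ModelSpec,
                      rtol: float = 1e-8) -> TwoSpeciesSolution:
    """Assemble the two-species parameters and the shared closed-form
    trajectory from a scalar indistinguishable pair.

    Raises if the scalar pair is not indistinguishable (the construction
    hinges on u1 solving both scalar problems).
    """
    A1 = ParameterPoint(inputs.d1, 0.0, inputs.c1)
    A2 = ParameterPoint(inputs.d2, 0.0, inputs.c2)
    try:
        scalar = construct_nonidentifiable_solution(
            A1, A2, inputs.eigen_index, 1.0, spec, rtol=rtol)
    except ValueError as err:
        raise ValueError(
            f"scalar pair (d1, c1) = ({inputs.d1:g}, {inputs.c1:g}), "
            f"(d2, c2) = ({inputs.d2:g}, {inputs.c2:g}) is not "
            f"indistinguishable: {err}") from err
    params = TwoSpeciesParams(
        d_u=inputs.d1, d_v=inputs.d2,
        a11=inputs.c1 + inputs.delta1,
        a12=inputs.delta1 * inputs.kappa_u / inputs.kappa_v,
        a22=inputs.c2 + inputs.delta2,
        a21=inputs.delta2 * inputs.kappa_v / inputs.kappa_u,
    )
    return TwoSpeciesSolution(params, scalar, inputs.kappa_u, inputs.kappa_v)


def family_sweep(inputs: ConstructionInputs, spec: ModelSpec,
                 delta_grid: Sequence[tuple[float, float]],
                 grid: Optional[SpaceTimeGrid] = None,
                 tol: float = 1e-8) -> dict:
    """Sweep (δ1, δ2) over ``delta_grid``: every member yields a distinct
    parameter set solved by the *same* trajectory (u, v).

    Returns the parameter sets, the shared trajectory evaluated on the
    grid, the per-member PDE residual maxima, and the maximal cross-member
    trajectory gap (identically zero by construction, reported as evidence).
    """
    if len(delta_grid) < 1:
        raise ValueError("delta grid must be nonempty")
    if grid is None:
        grid = SpaceTimeGrid.regular(spec.domain.length, 1.0, 41, 11)
    members: list[TwoSpeciesSolution] = []
    for (dl1, dl2) in delta_grid:
        member_inputs = ConstructionInputs(
            inputs.d1, inputs.c1, inputs.d2, inputs.c2,
            inputs.kappa_u, inputs.kappa_v, dl1, dl2, inputs.eigen_index)
        members.append(build_two_species(member_inputs, spec))
    tuples = [m.params.as_tuple() for m in members]
    for i in range(len(tuples)):
        for j in range(i + 1, len(tuples)):
            if np.allclose(tuples[i], tuples[j], rtol=0, atol=1e-12):
                raise ValueError(f"delta grid entries {i} and {j} give "
                                 "identical parameter sets")
    fields = [np.stack([m.u(grid.x, t_) for t_ in grid.t]) for m in members]
    cross_gap = max(float(np.max(np.abs(fields[i] - fields[0])))
                    for i in range(len(fields)))
    residuals = [m.residuals(grid.x, grid.t) for m in members]
    return {
        "members": members,
        "parameter_sets": tuples,
        "trajectory_u": fields[0],
        "grid": grid,
        "residual_max": max(max(r) for r in residuals),
        "residuals": residuals,
        "cross_trajectory_gap": cross_gap,
        "within_tol": cross_gap <= tol and max(max(r) for r in residuals) <= tol,
    }


def solve_mol_two_species(params: TwoSpeciesParams,
                          u0: Callable[[np.ndarray], np.ndarray],
                          v0: Callable[[np.ndarray], np.ndarray],
                          spec: ModelSpec, grid: SpaceTimeGrid, *,
                          nx: int = 201, rtol: float = 1e-8,
                          atol: float = 1e-10) -> tuple[SolutionField, SolutionField]:
    """Method-of-lines forward solve of the coupled system; the numerical
    cross-check that distinct δ-parameter sets really do share a trajectory
    (and stop doing so once the initial condition is perturbed)."""
    x, Gu, mask = build_space_operator(params.d_u, 0.0, spec, nx)
    _, Gv, _ = build_space_operator(params.d_v, 0.0, spec, nx)
    xs = x[mask]
    n = len(xs)
    y0 = np.concatenate([np.asarray(u0(xs), dtype=float),
                         np.asarray(v0(xs), dtype=float)])

    def rhs(t, y):
        u, v = y[:n], y[n:]
        du = Gu @ u + params.a11 * u - params.a12 * v
        dv = Gv @ v - params.a21 * u + params.a22 * v
        return np.concatenate([du, dv])

    sol = solve_ivp(rhs, (0.0, grid.t[-1]), y0, t_eval=grid.t, method="LSODA",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"two-species integration failed: {sol.message}")
    fu = np.zeros((len(grid.t), len(x)))
    fv = np.zeros_like(fu)
    fu[:, mask] = sol.y[:n].T
    fv[:, mask] = sol.y[n:].T
    U = np.vstack([np.interp(grid.x, x, fu[j]) for j in range(len(grid.t))])
    V = np.vstack([np.interp(grid.x, x, fv[j]) for j in range(len(grid.t))])
    return (SolutionField(grid, U, "numeric", params.as_tuple()),
            SolutionField(grid, V, "numeric", params.as_tuple()))
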