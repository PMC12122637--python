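"""Finite-dimensional analogue: indistinguishable linear ODE systems.

For Ẋ = M₁X, X(0) = X₀, a second coefficient matrix M₂ = M₁ + M produces
the identical trajectory whenever the perturbation M is (i) singular and
nontrivial, (ii) commutes with M₁, and (iii) annihilates the initial state
(X₀ ∈ ker M).  The commutant is the null space of the commutator map
M ↦ M₁M - MM₁, computed by brute-force linear algebra on the vectorized
4 (or n²) dimensional system; trajectory comparison uses matrix
exponentials so that integrator error never enters the verdict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm, null_space

__all__ = [
    "CommutantFamily",
    "SingularMember",
    "commutant_family",
    "singular_members",
    "verify_indistinguishable",
]


@dataclass
class CommutantFamily:
    """Basis of {M : M M1 = M1 M}; members are linear combinations of
    ``basis`` (each n×n, Frobenius-orthonormal)."""

    M1: np.ndarray
    basis: list[np.ndarray]

    @property
    def dimension(self) -> int:
        return len(self.basis)

    def member(self, coeffs) -> np.ndarray:
        coeffs = np.asarray(coeffs, dtype=float)
        if len(coeffs) != self.dimension:
            raise ValueError(f"expected {self.dimension} coefficients")
        return sum(c * B for c, B in zip(coeffs, self.basis))


@dataclass
class SingularMember:
    """A singular, nontrivial commuting perturbation with its kernel."""

    M: np.ndarray
    kernel: np.ndarray  # columns span ker(M)

    @property
    def kernel_vector(self) -> np.ndarray:
        return self.kernel[:, 0]


def commutant_family(M1: np.ndarray) -> CommutantFamily:
    """All matrices commuting with M1, via the null space of the vectorized
    commutator operator K = I ⊗ M1 - M1ᵀ ⊗ I (so K vec(M) = vec(M1 M - M M1))."""
    M1 = np.asarray(M1, dtype=float)
    if M1.ndim != 2 or M1.shape[0] != M1.shape[1]:
        raise ValueError("M1 must be square")
    n = M1.shape[0]
    K = np.kron(np.eye(n), M1) - np.kron(M1.T, np.eye(n))
    ns = null_space(K)
    basis = [ns[:, j].reshape(n, n, order="F") for j in range(ns.shape[1])]
    return CommutantFamily(M1, basis)


def singular_members(family: CommutantFamily, *, tol: float = 1e-10,
                     n_samples: int = 360) -> list[SingularMember]:
    """Singular (det = 0) nontrivial members of a commutant family.

    For a two-parameter family the singular set is the zero level of a
    quadratic form in the coefficients; it is located by a sign-change scan
    of det over coefficient directions plus bisection, which also covers
    higher-dimensional families direction-by-direction.  The all-zero member
    is excluded.
    """
    k = family.dimension
    if k == 0:
        return []
    rng_angles = np.linspace(0.0, np.pi, n_samples, endpoint=False)
    members: list[SingularMember] = []

    def try_add(M: np.ndarray) -> None:
        if np.max(np.abs(M)) < tol:
            return
        M = M / np.max(np.abs(M))
        if abs(np.linalg.det(M)) > 1e-8:
            return
        ker = null_space(M, rcond=1e-10)
        if ker.shape[1] == 0:
            return
        for prev in members:
            if np.max(np.abs(prev.M - M)) < 1e-6 or np.max(np.abs(prev.M + M)) < 1e-6:
                return
        members.append(SingularMember(M, ker))

    if k == 1:
        try_add(family.basis[0])
        return members
    # scan great circles through pairs of basis directions
    for i in range(k):
        for j in range(i + 1, k):
            Bi, Bj = family.basis[i], family.basis[j]
            dets = np.array([np.linalg.det(np.cos(a) * Bi + np.sin(a) * Bj)
                             for a in rng_angles])
            for idx in range(len(rng_angles)):
                a0 = rng_angles[idx]
                a1 = rng_angles[(idx + 1) % len(rng_angles)] \
                    if idx + 1 < len(rng_angles) else np.pi
                d0, d1 = dets[idx], dets[(idx + 1) % len(rng_angles)]
                if abs(d0) < tol:
                    try_add(np.cos(a0) * Bi + np.sin(a0) * Bj)
                elif d0 * d1 < 0:
                    lo, hi = a0, a1
                    for _ in range(80):
                        mid = 0.5 * (lo + hi)
                        dm = np.linalg.det(np.cos(mid) * Bi + np.sin(mid) * Bj)
                        if d0 * dm <= 0:
                            hi = mid
                        else:
                            lo = mid
                    a = 0.5 * (lo + hi)
                    try_add(np.cos(a) * Bi + np.sin(a) * Bj)
    return members


def singular_member_from_coeffs(family: CommutantFamily, coeffs,
                                tol: float = 1e-9) -> SingularMember:
    """Validate that the member at ``coeffs`` is singular and return it with
    its kernel (raises if the determinant is not numerically zero)."""
    M = family.member(coeffs)
    if np.max(np.abs(M)) == 0:
        raise ValueError("the zero member is excluded (perturbation must be nontrivial)")
    scale = np.max(np.abs(M))
    if abs(np.linalg.det(M / scale)) > tol:
        raise ValueError(f"member has det = {np.linalg.det(M):g}, not singular")
    ker = null_space(M, rcond=1e-10)
    return SingularMember(M, ker)


def verify_indistinguishable(M1: np.ndarray, M2: np.ndarray, X0,
                             T: float = 2.0, tol: float = 1e-10,
                             n_times: int = 101) -> tuple[bool, float]:
    """Compare the trajectories e^{M1 t}X0 and e^{M2 t}X0 on [0, T].

    Returns (gap <= tol, gap) with gap the sup-norm trajectory difference
    over ``n_times`` sample times.  Matrix exponentials make the comparison
    exact up to linear-algebra round-off.
    """
    M1 = np.asarray(M1, dtype=float)
    M2 = np.asarray(M2, dtype=float)
    X0 = np.asarray(X0, dtype=float)
    gap = 0.0
    for t in np.linspace(0.0, T, n_times):
        x1 = expm(M1 * t) @ X0
        x2 = expm(M2 * t) @ X0
        gap = max(gap, float(np.max(np.abs(x1 - x2))))
    return gap <= tol, gap
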