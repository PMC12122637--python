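"""Spectrum and kernel of the auxiliary elliptic operator -L1[A].

The eigenproblem throughout is

    -L1[A] φ = -(d φ'' + b φ') = λ φ,   Bφ = 0,

on the interval (0, l) or the torus.  Substituting φ = e^{-βx} w with
β = b/2d reduces the equation to w'' = q w with q = β² - λ/d, so every
boundary condition leads to a characteristic function built from the
entire-in-λ fundamental solutions

    cq(x) = cosh(√q x),      sq(x) = sinh(√q x)/√q,

which degenerate smoothly to cos/sinc for q < 0 and to (1, x) at q = 0.
Dirichlet and Neumann spectra come out in closed form; Robin eigenvalues are
roots of a transcendental characteristic equation solved by bracketing and
Brent's method.

The zeroth-order coefficient c enters only through kernel queries: the
kernel of L[A] = L1[A] + c is nontrivial exactly when c is an eigenvalue of
-L1[A], and its dimension is the geometric multiplicity of that eigenvalue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .domain import BoundaryKind, BoundarySpec, DomainSpec, OperatorSpec

__all__ = [
    "EigenPair",
    "DegenerateKernel",
    "eigenpairs",
    "degenerate_kernel",
    "kernel_dimension",
    "kernel_functions",
    "INFINITE_DIMENSIONAL",
]

#: Sentinel dimension for the degenerate zero operator (b = c = 0, d = 0),
#: whose kernel is the whole boundary-compatible function space.
INFINITE_DIMENSIONAL = math.inf

_DEFAULT_MATCH_RTOL = 1e-8


@dataclass
class EigenPair:
    """One eigenvalue of -L1[A] with its eigenfunction(s).

    ``eigenfunctions`` are vectorized callables normalized to unit supremum
    on the domain (so nonnegativity of a mode can be read off directly);
    ``multiplicity`` equals ``len(eigenfunctions)``.
    """

    index: int
    eigenvalue: float
    eigenfunctions: list[Callable[[np.ndarray], np.ndarray]]

    @property
    def multiplicity(self) -> int:
        return len(self.eigenfunctions)


@dataclass
class DegenerateKernel:
    """Kernel of the first-order operator L0[A] = b d/dx + c (the d = 0 case)."""

    functions: list[Callable[[np.ndarray], np.ndarray]]
    dimension: float  # 0, 1, or INFINITE_DIMENSIONAL
    description: str


# ---------------------------------------------------------------------------
# entire fundamental solutions of w'' = q w


def _cq(q: float, x: np.ndarray) -> np.ndarray:
    if q > 0:
        return np.cosh(np.sqrt(q) * x)
    if q < 0:
        return np.cos(np.sqrt(-q) * x)
    return np.ones_like(np.asarray(x, dtype=float))


def _sq(q: float, x: np.ndarray) -> np.ndarray:
    # sinh(sqrt(q) x)/sqrt(q); entire in q, so safe to cross q = 0
    if q > 1e-12:
        r = np.sqrt(q)
        return np.sinh(r * x) / r
    if q < -1e-12:
        k = np.sqrt(-q)
        return np.sin(k * x) / k
    x = np.asarray(x, dtype=float)
    return x * (1.0 + q * x * x / 6.0)


def _sup_scale(vals: np.ndarray) -> float:
    """Signed sup-normalization constant: the supremum, carrying the sign of
    the first significant lobe so normalized modes start positive."""
    m = float(np.max(np.abs(vals)))
    if m == 0:
        raise ValueError("cannot normalize an identically-zero eigenfunction")
    first = next(v for v in vals if abs(v) >= 0.5 * m)
    return m if first > 0 else -m


def _sup_normalize(f: Callable[[np.ndarray], np.ndarray], length: float
                   ) -> Callable[[np.ndarray], np.ndarray]:
    grid = np.linspace(0.0, length, 801)
    scale = _sup_scale(f(grid))
    return lambda x, _f=f, _s=scale: _f(np.asarray(x, dtype=float)) / _s


# ---------------------------------------------------------------------------
# closed-form spectra


def _dirichlet_pairs(d: float, b: float, length: float, n_max: int) -> list[EigenPair]:
    beta = b / (2.0 * d)
    pairs = []
    for n in range(1, n_max + 1):
        lam = b * b / (4.0 * d) + d * (n * math.pi / length) ** 2
        k = n * math.pi / length

        def phi(x, _beta=beta, _k=k):
            x = np.asarray(x, dtype=float)
            return np.exp(-_beta * x) * np.sin(_k * x)

        # b = 0: sin(nπx/l) is already sup-normalized with a positive first lobe
        pairs.append(EigenPair(n, lam, [phi if b == 0.0
                                        else _sup_normalize(phi, length)]))
    return pairs


def _neumann_pairs(d: float, b: float, length: float, n_max: int) -> list[EigenPair]:
    # λ0 = 0 with constant eigenfunction exists for every drift; the rest of
    # the spectrum coincides in form with the Dirichlet one but with
    # eigenfunctions built from the fundamental solution C (φ'(0) = 0).
    beta = b / (2.0 * d)
    pairs = [EigenPair(0, 0.0, [lambda x: np.ones_like(np.asarray(x, dtype=float))])]
    for n in range(1, n_max + 1):
        lam = b * b / (4.0 * d) + d * (n * math.pi / length) ** 2
        q = beta * beta - lam / d

        def phi(x, _beta=beta, _q=q):
            x = np.asarray(x, dtype=float)
            return np.exp(-_beta * x) * (_cq(_q, x) + _beta * _sq(_q, x))

        pairs.append(EigenPair(n, lam, [_sup_normalize(phi, length)]))
    return pairs


def _periodic_pairs(d: float, b: float, circumference: float, n_max: int
                    ) -> list[EigenPair]:
    if b != 0:
        raise NotImplementedError(
            "drifted periodic spectra (complex, via a transcendental equation) "
            "are not supported; only the no-drift torus case is implemented")
    pairs = [EigenPair(0, 0.0, [lambda x: np.ones_like(np.asarray(x, dtype=float))])]
    k0 = 2.0 * math.pi / circumference
    for n in range(1, n_max + 1):
        lam = d * (n * k0) ** 2
        kn = n * k0
        cos_n = lambda x, _k=kn: np.cos(_k * np.asarray(x, dtype=float))
        sin_n = lambda x, _k=kn: np.sin(_k * np.asarray(x, dtype=float))
        pairs.append(EigenPair(n, lam, [cos_n, sin_n]))
    return pairs


# ---------------------------------------------------------------------------
# Robin: transcendental characteristic equation


def _robin_char(d: float, b: float, length: float, sigma: float
                ) -> Callable[[float], float]:
    """Characteristic function whose roots are the Robin eigenvalues.

    Left condition u - σ u_x = 0 is satisfied by φ = σ C + S (φ(0) = σ,
    φ'(0) = 1); the root condition is the right-end residual φ + σ φ_x at l.
    The common positive factor e^{-βl} is dropped.
    """
    beta = b / (2.0 * d)

    def g(lam: float) -> float:
        q = beta * beta - lam / d
        if q > 1e-12:
            # rescale by e^{-√q l} (positive) so deep-negative λ do not overflow
            r = math.sqrt(q)
            cqv = 0.5 * (1.0 + math.exp(-2.0 * r * length))
            sqv = 0.5 * (1.0 - math.exp(-2.0 * r * length)) / r
        else:
            cqv = float(_cq(q, np.asarray(length)))
            sqv = float(_sq(q, np.asarray(length)))
        # φ(l) = e^{-βl}(σ cq + (1 + σβ) sq);  C' = -(λ/d) e^{-βx} sq,
        # S' = e^{-βx}(cq - β sq)
        phi = sigma * cqv + (1.0 + sigma * beta) * sqv
        dphi = -sigma * (lam / d) * sqv + cqv - beta * sqv
        return phi + sigma * dphi

    return g


def _robin_eigenfunction(d: float, b: float, lam: float, length: float, sigma: float
                         ) -> Callable[[np.ndarray], np.ndarray]:
    beta = b / (2.0 * d)
    q = beta * beta - lam / d

    def phi(x, _beta=beta, _q=q, _sigma=sigma):
        x = np.asarray(x, dtype=float)
        return np.exp(-_beta * x) * (_sigma * (_cq(_q, x) + _beta * _sq(_q, x))
                                     + _sq(_q, x))

    return _sup_normalize(phi, length)


def _robin_pairs(d: float, b: float, length: float, sigma: float, n_max: int
                 ) -> list[EigenPair]:
    g = _robin_char(d, b, length, sigma)
    lam_hi = b * b / (4.0 * d) + d * ((n_max + 1.5) * math.pi / length) ** 2
    # σ > 0 gives a positive semi-definite form; only σ < 0 admits
    # boundary-layer modes near -d/σ², so only then pad the lower end.
    lam_lo = -b * b / (4.0 * d) - 10.0 * d / length ** 2 - 1.0
    if sigma < 0:
        lam_lo -= 2.0 * d / sigma ** 2
    grid = np.linspace(lam_lo, lam_hi, max(4000, 200 * n_max))
    vals = np.array([g(lam) for lam in grid])
    roots: list[float] = []
    for i in range(len(grid) - 1):
        a, bb = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(grid[i])
        elif a * bb < 0:
            roots.append(brentq(g, grid[i], grid[i + 1], xtol=1e-13, rtol=1e-14))
    if not roots:
        raise RuntimeError(
            f"no Robin eigenvalues bracketed in [{lam_lo:.3g}, {lam_hi:.3g}]; "
            "widen the search interval")
    roots = sorted(roots)
    dedup: list[float] = []
    for r in roots:
        if not dedup or abs(r - dedup[-1]) > 1e-9 * max(1.0, abs(r)):
            dedup.append(r)
    pairs = []
    for n, lam in enumerate(dedup[:n_max], start=1):
        pairs.append(EigenPair(n, lam,
                               [_robin_eigenfunction(d, b, lam, length, sigma)]))
    return pairs


# ---------------------------------------------------------------------------
# public operations


def eigenpairs(op: OperatorSpec, n_max: int) -> list[EigenPair]:
    """First eigenpairs of -L1[A] = -(d d²/dx² + b d/dx) under ``op``'s
    boundary condition, sorted by ascending eigenvalue.

    Indices run from 1 for Dirichlet/Robin and from 0 (the constant or
    zero mode) for Neumann/periodic, so ``n_max`` is the largest index
    returned.  Requires d > 0; the degenerate d = 0 operator is handled by
    :func:`degenerate_kernel`.
    """
    if n_max < 1:
        raise ValueError(f"n_max must be >= 1, got {n_max}")
    if op.d <= 0:
        raise ValueError("eigenpairs requires d > 0; use degenerate_kernel for d = 0")
    kind = op.boundary.kind
    length = op.domain.length
    if kind is BoundaryKind.DIRICHLET:
        return _dirichlet_pairs(op.d, op.b, length, n_max)
    if kind is BoundaryKind.NEUMANN:
        return _neumann_pairs(op.d, op.b, length, n_max)
    if kind is BoundaryKind.PERIODIC:
        return _periodic_pairs(op.d, op.b, length, n_max)
    if kind is BoundaryKind.ROBIN:
        return _robin_pairs(op.d, op.b, length, op.boundary.robin_sigma, n_max)
    raise ValueError(f"unsupported boundary kind {kind}")


def degenerate_kernel(b: float, c: float, boundary: BoundarySpec,
                      domain: DomainSpec, rtol: float = _DEFAULT_MATCH_RTOL
                      ) -> DegenerateKernel:
    """Kernel of the degenerate operator L0[A] = b d/dx + c under the given
    boundary condition.

    Nonzero solutions of b φ' + c φ = 0 are exponentials φ ∝ e^{-cx/b},
    which leaves very little room once a boundary condition is imposed:

    * Dirichlet: empty unless b = c = 0, in which case the operator is zero
      and the kernel is the whole space of functions vanishing at both ends
      (reported with ``dimension = INFINITE_DIMENSIONAL``);
    * Neumann/periodic: constants, and only when c = 0;
    * Robin(σ): span{e^{-x/σ}}, and only when c = b/σ, since that
      exponential satisfies u + σ u_x = 0 identically.
    """
    kind = boundary.kind
    if kind is BoundaryKind.ROBIN and boundary.robin_sigma == 0:
        raise ValueError("robin_sigma must be nonzero")
    const = lambda x: np.ones_like(np.asarray(x, dtype=float))
    if b == 0.0 and c == 0.0:
        return DegenerateKernel([], INFINITE_DIMENSIONAL,
                                "zero operator: every boundary-compatible "
                                "function is in the kernel")
    if kind is BoundaryKind.DIRICHLET:
        return DegenerateKernel([], 0, "exponential solutions never vanish at "
                                       "both endpoints")
    if kind in (BoundaryKind.NEUMANN, BoundaryKind.PERIODIC):
        if abs(c) <= rtol * max(1.0, abs(b)):
            return DegenerateKernel([const], 1, "constant mode (c = 0)")
        return DegenerateKernel([], 0, "nonzero c excludes constants; "
                                       "exponentials violate the boundary condition")
    # Robin
    sigma = boundary.robin_sigma
    if abs(c - b / sigma) <= rtol * max(1.0, abs(b / sigma)):
        phi = lambda x, _s=sigma: np.exp(-np.asarray(x, dtype=float) / _s)
        return DegenerateKernel([phi], 1, f"span{{e^(-x/σ)}} with c = b/σ = {b / sigma:g}")
    return DegenerateKernel([], 0, "c != b/σ")


def _cutoff_index(d: float, c: float, length: float) -> int:
    return max(50, math.ceil(length * math.sqrt(abs(c) / d) / math.pi) + 5)


def kernel_functions(op: OperatorSpec, c: float,
                     rtol: float = _DEFAULT_MATCH_RTOL
                     ) -> list[Callable[[np.ndarray], np.ndarray]]:
    """Basis of ker(L[A]) = ker(L1[A] + c): the eigenfunctions of -L1[A]
    whose eigenvalue matches c to relative tolerance ``rtol``."""
    if op.d == 0:
        return degenerate_kernel(op.b, c, op.boundary, op.domain, rtol).functions
    funcs: list[Callable[[np.ndarray], np.ndarray]] = []
    matched_indices: list[int] = []
    for pair in eigenpairs(op, _cutoff_index(op.d, c, op.domain.length)):
        if abs(c - pair.eigenvalue) <= rtol * max(1.0, abs(pair.eigenvalue)):
            funcs.extend(pair.eigenfunctions)
            matched_indices.append(pair.index)
    if len(matched_indices) > 1:
        import warnings
        warnings.warn(
            f"c = {c:g} matches eigenvalues at several indices {matched_indices} "
            "within tolerance; all matching eigenfunctions are returned",
            stacklevel=2)
    return funcs


def kernel_dimension(op: OperatorSpec, c: float,
                     rtol: float = _DEFAULT_MATCH_RTOL) -> float:
    """Dimension of ker(L[A]), i.e. the geometric multiplicity of the
    eigenvalue λ = c of -L1[A]; 0 when c misses the spectrum.

    For d = 0 this delegates to :func:`degenerate_kernel` (and may report
    ``INFINITE_DIMENSIONAL`` for the zero operator).
    """
    if not rtol > 0:
        raise ValueError("tolerance must be positive")
    if op.d == 0:
        return degenerate_kernel(op.b, c, op.boundary, op.domain, rtol).dimension
    dim = 0
    for pair in eigenpairs(op, _cutoff_index(op.d, c, op.domain.length)):
        if abs(c - pair.eigenvalue) <= rtol * max(1.0, abs(pair.eigenvalue)):
            dim += pair.multiplicity
    return dim


def matched_eigen_index(op: OperatorSpec, c: float,
                        rtol: float = _DEFAULT_MATCH_RTOL) -> int | None:
    """Lowest eigen index n with λ_n = c (to tolerance), or None."""
    if op.d == 0:
        raise ValueError("matched_eigen_index requires d > 0")
    for pair in eigenpairs(op, _cutoff_index(op.d, c, op.domain.length)):
        if abs(c - pair.eigenvalue) <= rtol * max(1.0, abs(pair.eigenvalue)):
            return pair.index
    return None
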