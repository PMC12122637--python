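"""Shared fixtures and independent oracles for the test suite.

The finite-difference eigensolver below is a brute-force oracle: it
discretizes -(d u'' + b u') with second-order central differences on a
dense grid, folds in each boundary condition via ghost nodes or unknown
elimination, and diagonalizes the dense matrix.  It shares no code with
the package's analytic/transcendental spectral routines.
"""

import math

import numpy as np
import pytest

from auxident import ModelSpec, ParameterPoint


def fd_eigenvalues(d, b, length, kind, sigma=None, N=400):
    """Sorted eigenvalues of the dense FD discretization of -(d∂² + b∂)."""
    if kind == "dirichlet":
        h = length / (N + 1)
        A = np.zeros((N, N))
        for i in range(N):
            A[i, i] = 2 * d / h**2
            if i > 0:
                A[i, i - 1] = -d / h**2 + b / (2 * h)
            if i < N - 1:
                A[i, i + 1] = -d / h**2 - b / (2 * h)
        return np.sort(np.linalg.eigvals(A).real)
    if kind in ("neumann", "robin"):
        M = N + 1
        h = length / N
        A = np.zeros((M, M))
        lo = -d / h**2 + b / (2 * h)
        hi = -d / h**2 - b / (2 * h)
        for i in range(1, M - 1):
            A[i, i] = 2 * d / h**2
            A[i, i - 1] = lo
            A[i, i + 1] = hi
        if kind == "neumann":
            A[0, 0] = 2 * d / h**2
            A[0, 1] = lo + hi
            A[-1, -1] = 2 * d / h**2
            A[-1, -2] = lo + hi
        else:
            s = sigma
            # u - σu_x = 0 at x=0 (outward normal is -x): ghost = u1 - 2h u0/σ
            A[0, 0] = 2 * d / h**2 + lo * (-2 * h / s)
            A[0, 1] = lo + hi
            # u + σu_x = 0 at x=l: ghost = u_{M-2} - 2h u_{M-1}/σ
            A[-1, -1] = 2 * d / h**2 + hi * (-2 * h / s)
            A[-1, -2] = lo + hi
        return np.sort(np.linalg.eigvals(A).real)
    if kind == "periodic":
        h = length / N
        A = np.zeros((N, N))
        for i in range(N):
            A[i, i] = 2 * d / h**2
            A[i, (i - 1) % N] = -d / h**2 + b / (2 * h)
            A[i, (i + 1) % N] = -d / h**2 - b / (2 * h)
        return np.sort(np.linalg.eigvals(A).real)
    raise ValueError(kind)


def fd_kernel_count(d, b, c, length, kind, sigma=None, N=400, tol=1e-3):
    """Oracle for kernel dimension: number of numerically-zero singular
    values of the dense discretization of L[A] = d∂² + b∂ + c."""
    lam = fd_eigenvalues(d, b, length, kind, sigma=sigma, N=N)
    return int(np.sum(np.abs(lam - c) <= tol * np.maximum(1.0, np.abs(lam))))


@pytest.fixture(scope="session")
def dirichlet_spec():
    return ModelSpec.dirichlet()


@pytest.fixture(scope="session")
def fig_pair():
    """The worked indistinguishable pair on the unit Dirichlet domain."""
    A1 = ParameterPoint(0.05, 0.0, 1.0)
    A2 = ParameterPoint(0.05 + 1.0 / math.pi**2, 0.0, 2.0)
    return A1, A2
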