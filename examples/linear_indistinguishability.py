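"""Construct an indistinguishable parameter pair for the linear model.

For u_t = d u_xx + c u on (0, 1) with u = 0 at the boundary and
u0 = sin(πx), every pair on the line c - dπ² = const produces the same
solution.  Starting from (c, d) = (1, 0.05) we solve for the partner with
growth rate 2, classify the pair, and confirm the trajectories coincide.
"""

import numpy as np

from auxident import (InitialCondition, ModelSpec, ParameterPoint,
                      SpaceTimeGrid, classify, indistinguishable_partners,
                      solution_distance, solve_linear_analytic)

spec = ModelSpec.dirichlet()
A1 = ParameterPoint(d=0.05, b=0.0, c=1.0)

family = indistinguishable_partners(A1, spec, n=1)
A2 = family.partner_from_c(2.0)
print(f"base point        (c, d) = ({A1.c:g}, {A1.d:g})")
print(f"partner point     (c, d) = ({A2.c:g}, {A2.d:.4f})")
print(f"shared invariant  c - d*pi^2 = {A1.c - A1.d * np.pi**2:.6f}")

u0 = InitialCondition.from_callable(lambda x: np.sin(np.pi * x))
result = classify(A1, A2, u0, spec)
print(f"verdict: {result.verdict.value}  (witness exponent "
      f"mu = {result.witness.exponent:.6f})")

grid = SpaceTimeGrid.observation()
gap = solution_distance(solve_linear_analytic(A1, [1.0], spec, grid),
                        solve_linear_analytic(A2, [1.0], spec, grid))
print(f"sup-norm trajectory gap from sin(pi x): {gap:.2e}")

u0b = InitialCondition.from_callable(
    lambda x: np.sin(np.pi * x) + 0.2 * np.sin(2 * np.pi * x))
print("perturbed initial condition ->",
      classify(A1, A2, u0b, spec).verdict.value)
# The gap ~1e-15 says the two parameter points are observationally identical
# from the dominant eigenfunction; any second-mode admixture restores
# distinguishability.
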