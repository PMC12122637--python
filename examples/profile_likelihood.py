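"""Practical identifiability: bivariate profile likelihood of (c, d).

Synthetic data from a Gaussian-bump initial condition (truncated to eight
sine modes, spatially correlated noise) are profiled over the coefficients
at each (c, d).  A wide bump (ω = 0.3) is nearly the dominant eigenfunction
and the 95% region stretches along c - dπ² = const across orders of
magnitude in d; a narrow bump (ω = 0.1) excites higher modes and bounds d
from below.  Runs at a reduced 21 x 21 grid (~3 s).
"""

import math

import numpy as np

from auxident import (NoiseSpec, confidence_threshold, gaussian_ic_coefficients,
                      profile_surface, simulate_dataset)

truth = (1.0, 0.05)
c_grid = np.linspace(0.0, 4.0, 21)
d_grid = np.geomspace(1e-3, 1.0, 21)
print(f"confidence threshold (chi^2, 2 dof, 95%): "
      f"{confidence_threshold():.4f}")

for omega in (0.1, 0.3):
    ic = gaussian_ic_coefficients(omega, N=8)
    ds = simulate_dataset(*truth, ic, NoiseSpec(sigma=0.3, eta=10.0), seed=7)
    surf = profile_surface(ds, c_grid, d_grid)
    cols = np.where(surf.mask.any(axis=0))[0]
    lo, hi = surf.d_grid[cols[0]], surf.d_grid[cols[-1]]
    print(f"omega = {omega}:")
    print(f"  leading coefficients C1..C3 = "
          f"{np.round(ic.coefficients[:3], 3).tolist()}")
    print(f"  grid MLE (c, d) = {surf.mle}")
    print(f"  95% region spans d in [{lo:.3g}, {hi:.3g}] "
          f"({math.log10(hi / lo):.1f} decades)")
# For omega = 0.3 the lower end of the d-range sits at the smallest grid
# value: the diffusivity is practically non-identifiable from below, exactly
# as the structural ridge c - d*pi^2 = const predicts.
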