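"""Spectra of the auxiliary operator -(d u'' + b u') across boundary
conditions, and the kernel dimensions that decide membership in the
indistinguishable set.
"""

import numpy as np

from auxident import ModelSpec, OperatorSpec, eigenpairs, kernel_dimension

for label, spec, b in [
    ("Dirichlet", ModelSpec.dirichlet(), 0.0),
    ("Dirichlet + drift b=2", ModelSpec.dirichlet(), 2.0),
    ("Neumann", ModelSpec.neumann(), 0.0),
    ("Robin sigma=0.5", ModelSpec.robin(0.5), 0.0),
]:
    op = OperatorSpec.from_model(1.0, b, spec)
    lams = [f"{p.eigenvalue:.4f}" for p in eigenpairs(op, 4)]
    print(f"{label:24s} lambda = {', '.join(lams)}")

# periodic torus: every nonzero eigenvalue carries TWO eigenfunctions
spec = ModelSpec.periodic()
op = OperatorSpec.from_model(1.0, 0.0, spec)
for p in eigenpairs(op, 3):
    print(f"periodic n={p.index}: lambda={p.eigenvalue:g}, "
          f"multiplicity={p.multiplicity}")

# kernel dimension = geometric multiplicity of c as an eigenvalue;
# on the torus c = n^2 gives dimension 2, so ruling out non-identifiability
# needs multiplicity + 1 = 3 independent initial conditions
print("kernel dim on torus at c=4:", kernel_dimension(op, 4.0))
print("kernel dim (Dirichlet) at c=pi^2:",
      kernel_dimension(OperatorSpec.from_model(1.0, 0.0, ModelSpec.dirichlet()),
                       float(np.pi**2)))
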