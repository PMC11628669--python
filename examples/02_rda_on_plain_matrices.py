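"""Fit a redundancy analysis on plain numpy matrices.

RDA = multivariate regression of a centered response matrix on
standardized predictors, then an eigendecomposition of the fitted
values.  Here 30 samples x 50 'loci' with two planted environmental
gradients of unequal strength.
"""

import numpy as np

from karyorda import fit_rda, pseudo_f
from karyorda.significance import test_axes, test_global

rng = np.random.default_rng(0)
n, L = 30, 50
g1, g2 = rng.normal(size=n), rng.normal(size=n)
X = np.column_stack([g1, g2, rng.normal(size=n)])
Y = (np.outer(g1, rng.normal(size=L) * 1.5)
     + np.outer(g2, rng.normal(size=L) * 0.8)
     + rng.normal(size=(n, L)))

model = fit_rda(Y, X)
print(f"total inertia       {model.total_inertia:8.2f}")
print(f"constrained inertia {model.constrained_inertia:8.2f} "
      f"({100 * model.proportion_constrained:.1f}% explained)")
print("eigenvalues", np.round(model.eigenvalues, 3),
      " PVE", np.round(model.pve, 3))
print("pseudo-F", round(pseudo_f(model).statistic, 3),
      " global p =", test_global(Y, X, n_perm=999, seed=1).p_value)
for r in test_axes(Y, X, n_perm=999, seed=2, alpha=0.05):
    print(f"  {r.target}: F = {r.observed_F:.2f}, p = {r.p_value:.4f}")
# Two planted gradients -> two significant axes; the third axis tests
# null and stops the forward scan.
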