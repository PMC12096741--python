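"""Apportion PAH mass to sources with positive matrix factorization.

Fits the uncertainty-weighted factorization x = G F on a 150-sample
synthetic campaign with known ground truth, then compares recovered
profiles to the true ones.
"""

import numpy as np
from scipy.optimize import linear_sum_assignment

from pahkit import SyntheticSpec, fit_pmf, generate_samples, label_factors
from pahkit.pmf import records_to_matrix
from pahkit.synthetic import FACTOR_NAMES

spec = SyntheticSpec(n_days=75, n_sites=2, noise_cv=0.10, censor=False, seed=1)
records, g_true, f_true = generate_samples(spec)
x = records_to_matrix(records)
s = np.maximum(0.10 * x, 1e-4)   # 10% multiplicative uncertainty

model = fit_pmf(x, s, n_factors=5, n_starts=20, seed=0)
print(f"Q = {model.q:.1f} (degrees-of-freedom reference {model.q_expected:.0f})")
print("factor contributions:",
      ", ".join(f"{p:.1f}%" for p in model.contribution_pct))

fn = f_true / np.linalg.norm(f_true, axis=1, keepdims=True)
rn = model.f / np.linalg.norm(model.f, axis=1, keepdims=True)
sim = fn @ rn.T
ri, ci = linear_sum_assignment(-sim)
print("\nprofile recovery (cosine similarity to truth):")
for i, j in zip(ri, ci):
    print(f"  {FACTOR_NAMES[i]:18s} -> recovered factor {j + 1}: {sim[i, j]:.3f}")

print("\nmarker-based labels of the recovered factors:")
print(label_factors(model).to_string(index=False))
# Cosines near 1 and matching labels show the solver identifies the
# five sources; Q near its expected value means the 10% uncertainty
# model is consistent with the residuals.
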