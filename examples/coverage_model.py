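"""Fit the two-Poisson coverage mixture that separates erroneous from
correct de Bruijn graph nodes, and place the coverage cutoff at the
crossing of the two weighted distributions.

Run:  python examples/coverage_model.py
"""

import numpy as np

from polycor import fit_coverage_model, poisson_intersection

# A node-coverage histogram like a real cluster's: many erroneous nodes
# near coverage 1-3, correct nodes around the extracted coverage C_k = 30.
rng = np.random.default_rng(0)
covs = np.concatenate([rng.poisson(2, 1200), rng.poisson(30, 800)]).astype(float)
model = fit_coverage_model([(c, 1.0) for c in covs])

print(f"erroneous component: mean {model.lambda_e:.2f}, weight {model.w_e:.2f}")
print(f"correct   component: mean {model.lambda_c:.2f}, weight {model.w_c:.2f}")
print(f"EM iterations: {model.n_iter}")
print(f"coverage cutoff (pmf crossing): {model.cutoff:.3f}")
# the crossing has a closed form; the EM cutoff must agree with it
closed = poisson_intersection(model.lambda_e, model.lambda_c, model.w_e, model.w_c)
print(f"closed-form crossing:          {closed:.3f}")
# nodes below the cutoff that are also short tips/bubbles get removed;
# everything above is treated as genuine sequence
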