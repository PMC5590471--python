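"""Quantify the flux bias caused by omitting one reaction.

Generates a random 20-metabolite network with known internal fluxes, removes
one reaction, and compares the closed-form specification bias
(S_I'S_I)^-1 S_I'S_O v_O with the actual error of a misspecified fit on
noise-free data.  The bias can be large even when the omitted flux is small,
whenever the omitted stoichiometry is correlated with retained reactions.
"""

import numpy as np

from fluxdiag import (NetworkSpec, attach_exchanges, noise_free_measurements,
                      ols_fit, random_stoichiometry, sample_internal_fluxes,
                      specification_bias, RegressionProblem)

spec = NetworkSpec(m=20, n_internal=12, n_exchange=10, seed=4)
model = random_stoichiometry(spec, seed=4)
blocks = attach_exchanges(model, spec.n_exchange)
v_true = sample_internal_fluxes(blocks.S_I_NE, seed=4)
y = noise_free_measurements(v_true, blocks)

# omit a moderately active reaction (3rd-largest |flux|); around half the
# reactions in such sparse networks carry structurally zero flux and their
# omission would be invisible by construction
order = np.argsort(np.abs(v_true))
j = int(order[-3])
keep = [i for i in range(model.n_reactions) if i != j]
res = specification_bias(model.S[:, keep], model.S[:, [j]], [v_true[j]],
                         reference=v_true[keep])

est = ols_fit(RegressionProblem(y=y, X=model.S[:, keep]))
actual_error = est.beta_hat - v_true[keep]

print(f"omitted reaction {model.reaction_ids[j]} with true flux {v_true[j]:.4f}")
print(f"predicted bias (closed form), largest 3 entries: "
      f"{np.sort(np.abs(res.bias))[-3:]}")
print(f"actual estimation error on noise-free data,  largest 3: "
      f"{np.sort(np.abs(actual_error))[-3:]}")
print(f"max |predicted - actual| = {np.max(np.abs(res.bias - actual_error)):.2e}")
print("summary of |bias| in % of the true fluxes:", res.summary)
print("On noise-free data the fit error IS the specification bias -- the")
print("two columns above agree to machine precision.")
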