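"""The Wiener first-passage-time density and its samplers.

Evaluates the signed-RT density, verifies that it integrates to one over
both boundaries, and compares the exact-style sampler against the analytic
absorption probability.
"""

import numpy as np
from scipy.integrate import quad

from rlddm import wfpt

alpha, tau, v = 1.2, 0.3, 1.5  # boundary separation, non-decision time, drift

up = quad(lambda t: wfpt.wfpt_pdf(t, alpha, tau, v), tau, tau + 100)[0]
lo = quad(lambda t: wfpt.wfpt_pdf(-t, alpha, tau, v), tau, tau + 100)[0]
print(f"integral over upper boundary: {up:.6f}")
print(f"integral over lower boundary: {lo:.6f}   (sum = {up + lo:.6f})")
print(f"closed-form P(upper):         {wfpt.prob_upper(alpha, v):.6f}")

x = wfpt.sample_ddm(alpha, tau, v, size=50_000, seed=1)
print(f"sampled   P(upper):           {(x > 0).mean():.4f}")
print(f"mean decision time:           {np.abs(x).mean() - tau:.3f} s")
print("\nPositive times are optimal (upper-boundary) responses, negative times")
print("suboptimal ones; a positive drift pushes mass toward the upper boundary.")
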