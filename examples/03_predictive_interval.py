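"""Build the Student-t predictive interval for a new treatment effect.

999 effects are drawn from the population; the 95% predictive interval
constructed from them should contain a held-out 1000th draw about 95% of
the time.
"""

import numpy as np

from predex import NIGHyperparams, credibility_interval, default_beta, posterior_update

rng = np.random.default_rng(1)
y = rng.normal(0.0, 0.63, 1000)  # effects of null genes at n_c=n_t=4, sigma_c^2=0.8
ref, held_out = y[:999], y[999]

prior = NIGHyperparams(mu0=0.0, lam=1e-2, tau=3.0)
prior = prior.with_beta(default_beta(ref, prior.tau))
post = posterior_update(ref, prior)
lo, hi = credibility_interval(post, alpha=0.05)

print(f"posterior location mu*    : {post.mu_star:+.4f}")
print(f"degrees of freedom tau*   : {post.tau_star:.0f}")
print(f"95% predictive interval   : ({lo:+.3f}, {hi:+.3f})")
print(f"held-out 1000th effect    : {held_out:+.3f}  covered={lo <= held_out <= hi}")

covered = 0
for _ in range(500):
    z = rng.normal(0.0, 0.63, 1000)
    p = posterior_update(z[:999], prior.with_beta(default_beta(z[:999], 3.0)))
    a, b = credibility_interval(p, 0.05)
    covered += a <= z[999] <= b
print(f"coverage over 500 rounds  : {covered / 500:.3f}  (nominal 0.95)")
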