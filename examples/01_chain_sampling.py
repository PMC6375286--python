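"""Completion times of chains of memory-less steps.

Samples completion times for chains of different depth and shows that the
timing precision (CV = sd/mean) follows 1/sqrt(n): more rate-limiting steps
give sharper timing.  Inverting that relation turns a measured timing ratio
into a lower bound on the number of steps.
"""

import numpy as np

from stresstiming import ChainSpec, randomness_and_steps, sample_erlang

for n in (1, 4, 8, 37):
    x = sample_erlang(ChainSpec(n_steps=n, mean_time=2.0), 100_000, seed=1)
    cv = x.std(ddof=1) / x.mean()
    print(f"n={n:>2d} steps: mean {x.mean():.3f} h, CV {cv:.3f} (analytic {1/np.sqrt(n):.3f})")

# measured timing ratio -> lower bound on the number of rate-limiting steps
for ratio in (0.36, 0.54, 0.165):
    est = randomness_and_steps(mu_t=1.0, sigma_t=ratio)
    print(
        f"sigma_t/mu_t = {ratio:5.3f} -> randomness R = {est.randomness:.4f}, "
        f"n >= {est.n_min_real:.1f}, rounded up: {est.n_steps} steps"
    )
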