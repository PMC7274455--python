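"""Choosing the community budget k.

The model caps the number of communities at k; if the posterior occupies
strictly fewer than k communities, the cap is demonstrably not binding.
Here data with two true communities is fit with k = 4 and k = 6: both
should occupy ~2 communities, so the smaller budget is chosen.
"""

import numpy as np

import gpsbm
from gpsbm import KernelParams

panel = gpsbm.sample_tsbm(
    k=2, alpha=1.0,
    kernel_in=KernelParams(0.25, 3.0, 0.01),
    kernel_out=KernelParams(0.25, 3.0, 0.01),
    divs=[11, 14, 18, 21], n_nodes=14, n_devices=2, seed=0,
    beta=np.array([[1.5, -2.5], [-2.5, 1.5]]),
    z=np.repeat([0, 1], 7),
).panel

mcmc = gpsbm.MCMCConfig(n_chains=1, n_samples=200, n_warmup=400, seed=0)
chosen, report = gpsbm.select_k(panel, k_grid=(4, 6), mcmc=mcmc)

for k, entry in report.items():
    print(f"k={k}: occupied communities {entry['occupied_k']}, "
          f"DIC {entry['dic']:.1f}")
print(f"chosen k = {chosen}  (smallest budget the data does not saturate)")
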