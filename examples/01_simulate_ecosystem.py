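"""Generate a synthetic two-level ecosystem and inspect its parts.

A trait-matching feasibility kernel (Gaussian in corolla-bill difference,
with a colour-mismatch penalty) defines which interactions are possible;
species get disk ranges on a 0.5-degree grid and site networks are
sampled with imperfect detection.
"""

import numpy as np

from rewirenet import synthdata as sd

config = sd.SynthConfig(seed=1)
eco = sd.simulate(config)

print(f"resources: {len(eco.resource.data)}, consumers: {len(eco.consumer.data)}")
print("resource traits:", ", ".join(eco.resource.trait_names))
print("consumer traits:", ", ".join(eco.consumer.trait_names))
print(f"grid: {config.grid_nx} x {config.grid_ny} cells of {config.cell_size} deg")
print(f"sites sampled: {len(eco.networks)}")
print(
    "mean site richness: "
    f"{np.mean([len(n.resource_ids) for n in eco.networks]):.1f} resources x "
    f"{np.mean([len(n.consumer_ids) for n in eco.networks]):.1f} consumers"
)
print(f"observed interactions across sites: {sum(len(n.edges) for n in eco.networks)}")
print(
    "true feasibility (p >= 0.5) pairs: "
    f"{int((eco.truth.p.to_numpy() >= 0.5).sum())} of {eco.truth.p.size}"
)
# the per-consumer tolerance sigma is the latent quantity the pipeline
# later tries to recover as rewiring capacity
print(
    f"consumer tolerance sigma: median {eco.truth.sigma.median():.2f}, "
    f"range {eco.truth.sigma.min():.2f}-{eco.truth.sigma.max():.2f}"
)
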