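"""Gene co-expression network -> MCL modules -> node roles.

Simulates two co-expression programmes (plus one cross-talking gene whose
profile mixes both), links genes with |Pearson r| > 0.8, clusters with MCL,
and prints each gene's module, participation coefficient and role region.
The mixing gene is the one to watch: it keeps correlated links into both
programmes, so its P rises above the others'.
"""

import numpy as np

from cartonet import (CoexpressionRule, ExpressionMatrix, MCLConfig,
                      build_cartography, coexpression_network, mcl_partition)

rng = np.random.default_rng(1)
n_samples = 30
base_a = rng.normal(size=n_samples)
base_b = rng.normal(size=n_samples)

genes, profiles = [], []
for i in range(6):
    genes.append(f"progA_{i}")
    profiles.append(base_a + rng.normal(scale=0.15, size=n_samples))
for i in range(6):
    genes.append(f"progB_{i}")
    profiles.append(base_b + rng.normal(scale=0.15, size=n_samples))
genes.append("crosstalk")
profiles.append(0.72 * base_a + 0.72 * base_b + rng.normal(scale=0.1, size=n_samples))

# a gene mixing two programmes can correlate at most ~0.7 with each (the
# squared correlations sum to <= 1), so this small demo uses a looser
# threshold than the 0.8 typical for genome-wide data
expr = ExpressionMatrix(genes, [f"s{j}" for j in range(n_samples)], np.array(profiles))
net = coexpression_network(expr, CoexpressionRule(threshold=0.6))
part = mcl_partition(net, MCLConfig(inflation=2.0))
records = build_cartography(net, part)

print(f"co-expression network: {net.n_nodes} genes, {net.n_edges} links, "
      f"{part.n_modules} MCL modules")
for r in records:
    print(f"  {r.node:<10s} module={r.module} k={r.k:2d} kappa={r.kappa:2d} "
          f"P={r.P:.3f} region={r.region}")
print("-> genes with P=0 are confined to one programme; the crosstalk gene's "
      "higher P flags it as a candidate inter-programme regulator.")
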