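"""Simulate metacommunities under the five assembly regimes.

Builds one small scenario per regime and prints summary statistics of the
resulting ASV tables. Row sums always equal the configured sequencing
depth; regimes differ in how composition varies across sites.
"""

import numpy as np

from ecoassembly import REGIMES, ScenarioSpec, bray_curtis_matrix, simulate_scenario, standardize_table

for regime in REGIMES:
    spec = ScenarioSpec.for_regime(regime, n_taxa=40, n_sites=8,
                                   reads_per_sample=2000, seed=1)
    tree, traits, meta, table = simulate_scenario(spec)
    rel = standardize_table(table, "relative")
    bc = bray_curtis_matrix(rel)
    tri = bc.to_numpy()[np.triu_indices(8, 1)]
    richness = (table.data.to_numpy() > 0).sum(axis=1)
    print(f"{regime:22s} mean richness {richness.mean():5.1f}   "
          f"between-site Bray-Curtis {tri.mean():.3f} ± {tri.std():.3f}")

print()
print("Homogenizing dispersal should show the lowest between-site dissimilarity")
print("(sites are near-copies of one shared community); dispersal limitation the")
print("highest (sites draw from disjoint-biased species pools).")
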