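"""Quantify assembly processes with the βNTI + Raup-Crick null models.

Simulates a dispersal-limited metacommunity, computes abundance-weighted
βMNTD/βNTI against the tip-shuffle null and abundance-based Raup-Crick
against the richness/reads-preserving null, classifies every sample pair,
and prints the process fractions. The generating regime should dominate
the classification.
"""

import numpy as np

from ecoassembly import (
    PROCESSES,
    ScenarioSpec,
    bnti_matrix,
    classify_assembly,
    rc_bray_matrix,
    simulate_scenario,
    standardize_table,
    summarize_process_fractions,
)

spec = ScenarioSpec.for_regime("dispersal_limitation", n_taxa=60, n_sites=12,
                               reads_per_sample=5000, seed=2016)
tree, traits, meta, table = simulate_scenario(spec)
rel = standardize_table(table, "relative")

bnti = bnti_matrix(rel, tree, n_null=299, seed=7)
rc = rc_bray_matrix(table, n_null=299, seed=8)
result = classify_assembly(bnti, rc)
summary = summarize_process_fractions(result)

tri = bnti.values.to_numpy()[np.triu_indices(table.n_samples, 1)]
print(f"βNTI over {len(tri)} pairs: median {np.nanmedian(tri):+.2f} "
      f"(|βNTI| > 2 ⇒ selection; within ±2 the Raup-Crick value decides)")
print(f"excluded pairs (zero null sd): {result.n_excluded}\n")
print("process fractions (entire stratum):")
row = summary.loc["entire"]
for process in PROCESSES:
    print(f"  {process:24s} {row[process]:.2f}")
print("\nUnder dispersal limitation most pairs should combine |βNTI| ≤ 2")
print("(no phylogenetic signal) with RC > +0.95 (less species overlap than")
print("the regional null expects).")
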