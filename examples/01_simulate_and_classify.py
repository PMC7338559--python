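"""Simulate a community under a known assembly regime and recover it.

Builds a 30-site community table under the 'variable_selection' preset
(strong niche selection along a spatial environmental gradient), runs both
null models and classifies every sample pair into one of the five assembly
processes.
"""

import numpy as np

from assemblyscape import (NullConfig, RcConfig, bnti_matrix, build_pair_table,
                           cophenetic_matrix, rarefy, rc_bray_fast,
                           scenario_preset, simulate_scenario)

cfg = scenario_preset("variable_selection", seed=1, n_sites=30, n_otus=300)
table, tree, frame, truth = simulate_scenario(cfg)
print(f"simulated {table.n_samples} sites x {table.n_otus} OTUs "
      f"({cfg.reads_per_sample} reads each) under '{truth.label}'")

bnti = bnti_matrix(table, cophenetic_matrix(tree), NullConfig(n_reps=999, seed=2))
rc = rc_bray_fast(rarefy(table, seed=3), RcConfig(n_reps=999, seed=4))
pairs = build_pair_table(table.sample_ids, bnti.bnti, rc, frame)

print("\nper-pair process fractions (should be dominated by the generating "
      "process):")
for label, frac in pairs["process"].value_counts(normalize=True).items():
    print(f"  {label:28s} {frac:6.1%}")

iu = np.triu_indices(table.n_samples, 1)
print(f"\nmedian betaNTI {np.nanmedian(bnti.bnti[iu]):+.2f} "
      "(> +2 means more phylogenetic turnover than the tip-shuffle null, "
      "i.e. heterogeneous selection)")
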