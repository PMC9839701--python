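"""Diversity, local network-parameter tests and the pathway screen.

Shannon diversity per sample; one-sample one-sided t tests of local network
parameters (modularity, TC, N:P) against the fitted-normal median; and a
Kruskal-Wallis screen of pathway CPMs across the nine design cells.
"""

import pandas as pd

from gutnet import (default_config, generate_cohort, generate_pathway_table,
                    network_param_tests, pathway_screen, shannon,
                    spinglass_modules, subset_networks, cohesion,
                    connectedness, filter_species)
from gutnet.io import cpm_normalize

table, metadata, truth = generate_cohort(default_config(seed=7))

div = pd.Series({s: shannon(table.loc[s]) for s in table.index})
print("mean Shannon diversity by group:")
print(div.groupby(metadata["group"]).mean().round(3).to_string())

# network parameters per local network
filtered = filter_species(table)
rows = []
for i, net in enumerate(subset_networks(table, metadata,
                                        "per_group_timepoint")):
    part = spinglass_modules(net, seed=100 + i)
    coh = cohesion(filtered.loc[list(net.samples)], connectedness(net))
    group, tp = net.name.rsplit("_", 1)
    rows.append((group, part.modularity, coh.total_cohesion, coh.np_ratio))
panel = pd.DataFrame(rows, columns=["group", "modularity",
                                    "total_cohesion", "np_ratio"])
# in this synthetic cohort the pathobiont bloom concentrates cohesion in
# its own block, so the planted expectation is TC below the pooled median
# in the undisturbed EN arm and above it under PN with prophylaxis
alts = {"total_cohesion": {"EN": "less", "PN_LVX_PLUS": "greater"}}
tests = network_param_tests(panel, alts, drop_nonfinite=True)
sel = tests[tests["alternative"] != "two-sided"]
print("\none-sided t tests of total cohesion vs the fitted median:")
print(sel[sel.parameter == "total_cohesion"]
      [["group", "t", "p", "alternative"]].round(4).to_string(index=False))

# pathway screen: one pathway coupled to the pathobiont block, several
# loaded on random filler species
pathobionts = [sp for sp, b in truth.block_labels.items() if b == 2]
fillers = [sp for sp in table.columns if sp not in truth.block_labels]
cols = ["pathobiont_pwy"] + [f"filler_pwy_{i}" for i in range(4)]
loadings = pd.DataFrame(0.0, index=table.columns, columns=cols)
loadings.loc[pathobionts, "pathobiont_pwy"] = 1.0
for i in range(4):
    loadings.loc[fillers[8 * i:8 * (i + 1)], f"filler_pwy_{i}"] = 1.0
pw = cpm_normalize(generate_pathway_table(table, loadings, noise_sd=0.3,
                                          seed=7))
screen = pathway_screen(pw, metadata)
print("\npathway screen (Kruskal-Wallis across the 9 design cells, BH):")
print(screen.sort_values("H", ascending=False)
      [["H", "p", "q", "passed"]].round(4).to_string())
print("the pathway loaded on the blooming pathobiont block separates the "
      "design cells most strongly; filler pathways inherit a weaker "
      "compositional echo of the bloom.")
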