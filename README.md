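# gutnet

Global-to-local co-occurrence network analysis of gut microbiome species
profiles, built for longitudinal multi-arm cohort designs (e.g. pediatric
hematopoietic stem cell transplantation patients stratified by nutritional
support and antibiotic prophylaxis, sampled pre-transplant, at engraftment
and pre-discharge).

Given a MetaPhlAn-style species relative-abundance table and sample
metadata, the pipeline:

1. **Filters** species (relative abundance > 0.3% in ≥ 5% of samples).
2. **Builds signed networks**: pairwise Spearman ρ, Benjamini–Hochberg FDR
   over each network's correlation tests, edges retained when q < 0.05 and
   |ρ| > 0.3 — one *global* network over all samples, one per treatment
   group, and one *local* network per group × timepoint cell.
3. **Detects modules** by simulated annealing of the signed spin-glass
   Hamiltonian

   H(σ) = −Σ_{i<j} [(w⁺_ij − γ⁺ p⁺_ij) − (w⁻_ij − γ⁻ p⁻_ij)] δ(σ_i, σ_j),

   with configuration-model null expectations p± computed separately per
   sign layer, and reports Newman modularity Q on the positive layer.
4. **Flags hubs**: nodes whose degree, betweenness and closeness all exceed
   the mean of a maximum-likelihood normal fit to each centrality.
5. **Computes cohesion** (per Herren & McMahon): per-taxon positive and
   negative connectedness c±_i (mean retained edge weights by sign),
   per-sample cohesion C±_j = Σ_i a_ij·c±_i with abundances as fractions,
   network totals P, N, total cohesion TC = P + |N| and the N:P ratio.
6. **Scans for keystones**: brute-force leave-one-out — zero one species'
   abundance everywhere, rebuild the network, recompute TC; species whose
   removal cuts TC by > 50% are keystones.
7. **Statistics**: Shannon diversity, Kruskal–Wallis + BH and pairwise
   Wilcoxon rank-sum comparisons, one-sample one-sided t tests of local
   network parameters (Q, TC, N:P) against the fitted-normal median, a
   Kendall-correlation screen linking pathway CPMs to species abundances,
   and KO/metabolism-class summaries of functional profiles.

A synthetic cohort generator (Gaussian copula with planted co-occurrence
blocks, antagonist block pairs, group × timepoint fold changes, dominant
keystones, zero inflation and compositional closure) provides ground truth
for every stage, so the whole pipeline is testable without sequencing data.

## Worked example

```python
from gutnet import (default_config, generate_cohort, spinglass_modules,
                    subset_networks)

table, metadata, truth = generate_cohort(default_config(seed=7))
net = subset_networks(table, metadata, "global")[0]
part = spinglass_modules(net, seed=7)
print(len(net.nodes), net.n_edges, round(part.modularity, 3))
```

prints `60 225 0.662`: the global network over 90 samples keeps 60 species
and 225 signed edges, and the spin-glass partition has modularity
Q = 0.662.  Its three largest modules (15, 13 and 11 species) reproduce the
three planted abundance blocks exactly — 325/325 planted species pairs are
correctly co-assigned or separated (`examples/02_global_network.py`).  The
keystone scan in `examples/04_cohesion_keystones.py` reports
`species_000: delta TC = 85.8% <- keystone` for the planted dominant taxon,
with the runner-up at 6.5%, far below the 50% rule.

Each script in `examples/` is a short narrative of one capability:
simulation, global networks, hubs, cohesion/keystones, and the statistical
layer.  The `gutnet` command exposes the same stages as subcommands
(`gutnet all --seed 7 --outdir run/`, or `simulate`, `network`, `modules`,
`hubs`, `cohesion`, `keystones`, `stats` individually) with YAML config
support, writing TSV/GraphML outputs plus a manifest that reproduces the
run bit-for-bit.

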