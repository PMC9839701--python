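# Methods

## Scope and data model

`gutnet` analyses species-level relative-abundance tables (MetaPhlAn
convention: percent scale, samples in columns on disk; samples × species
DataFrames in memory) together with sample metadata assigning each sample
to a patient, a treatment group (enteral nutrition `EN`, parenteral
nutrition without levofloxacin `PN_LVX_MINUS`, parenteral nutrition with
levofloxacin `PN_LVX_PLUS`) and a timepoint (`T0` pre-transplant, `T1`
engraftment, `T2` pre-discharge).  Functional profiles (HUMAnN convention,
CPM-normalised to 1e6 per sample) and a gene-family → KO → metabolism-class
mapping are optional side inputs.

## Network construction

Species are filtered once on the full cohort: relative abundance > 0.3%
(strict) in at least ⌈0.05 · n⌉ samples.  The roster is shared by the
global and all local networks so the same species can be compared across
networks; subsets are *not* re-filtered.  For each network's sample subset
we compute Spearman ρ as Pearson correlation of average ranks (computed
directly rather than through a library call so that constant columns —
common in sparse, zero-inflated subsets — degrade to ρ = 0, p = 1 with a
flag instead of poisoning the whole matrix), p-values via the
t-approximation on n − 2 degrees of freedom, and Benjamini–Hochberg
q-values over the strict upper triangle of each network's own p-matrix
(each network is corrected separately; FDR is not pooled across networks).
Edges are retained when q < 0.05 and |ρ| > 0.3; both thresholds are
configurable.  Isolated nodes stay in the network.

## Module detection

Modules minimise the signed spin-glass Hamiltonian with separate
configuration-model null models per sign layer: the coupling of a pair is
J_ij = (w⁺_ij − γ⁺ s⁺_i s⁺_j / 2m⁺) − (w⁻_ij − γ⁻ s⁻_i s⁻_j / 2m⁻), and
H(σ) = −Σ_{i<j} J_ij δ(σ_i, σ_j).  Optimisation is single-node spin-flip
simulated annealing: 25 available spins, γ⁺ = γ⁻ = 1, geometric cooling
from T = 1 to T = 0.01 with factor 0.99, one sweep of single-node proposals
per temperature with the candidate spin drawn uniformly, Metropolis
acceptance, and the best-encountered state returned.  The run is
deterministic given its seed.  A network with no edges returns singleton
modules with Q = 0 and a flag.

Modularity is classical Newman weighted modularity computed on the
positive-weight layer only: negative correlations have no agreed
configuration-model expectation in the classical Q, and they already shape
the partition through the signed Hamiltonian.  Module ids are relabelled by
decreasing size.

## Centralities and hubs

Degree, betweenness (unnormalised pair counts) and closeness are computed
on the unweighted undirected skeleton of retained edges — a signed
correlation is not a path length, and no weight-to-distance transform is
assumed.  Closeness of node i is r_i / Σ_j dist(i, j) over its reachable
set (r_i nodes), which treats components separately; isolated nodes score
0 on all three metrics.  Each metric's values are fitted to a normal by
maximum likelihood (μ̂ = mean, σ̂ = ML standard deviation) and a node is a
hub iff it strictly exceeds μ̂ on *all three* metrics.  For a normal the
estimated median equals μ̂, so "above the median of the fitted
distribution" and "above the fitted mean" coincide; the implementation
uses μ̂.  With a zero-variance metric no node can strictly exceed its
mean, so no hubs arise — flagged rather than erroring.

## Cohesion, total cohesion, N:P

Connectedness follows the cohesion framework of Herren & McMahon:
c⁺_i (c⁻_i) is the mean of the retained positive (negative) edge weights
incident to taxon i, zero when there are none.  The original null-model
correction of the correlation matrix is deliberately not applied:
cohesion here is computed on the same FDR- and |ρ|-thresholded networks
used everywhere else, so the thresholding plays the role of noise
suppression.  Per-sample cohesion is C±_j = Σ_i a_ij · c±_i with
abundances as fractions (percent / 100).  Network-level aggregates are
P = mean_j C⁺_j, N = mean_j C⁻_j, total cohesion TC = P + |N| and
N:P = |N| / P (0 when both vanish, +inf flag when P = 0 with N ≠ 0).
The arithmetic mean over the samples defining the network yields a single
parameter value per network, as required for the per-network comparisons.

## Keystone scan

For each taxon, its abundance is set to zero in every sample — without
re-closing the remaining abundances, so that the perturbation stays
attributable to that taxon alone — and the Spearman matrix, BH correction,
thresholded network, connectedness and TC are recomputed on the same
roster.  The taxon is a keystone when ΔTC% = 100 · (TC_full − TC_loo) /
TC_full exceeds 50 (configurable).  A rebuilt network with no edges gives
TC_loo = 0 and ΔTC% = 100.  Note that zeroing any column perturbs the
shared BH p-value pool, so even an uncorrelated taxon can shift TC by a
few percent through borderline edges elsewhere; this is inherent to
FDR-thresholded networks and stays far below the 50% rule.

## Statistical layer

Shannon diversity H′ = −Σ p_i ln p_i uses the natural log (the ecology
convention; base configurable) on the unfiltered table.  Group
comparisons use Kruskal–Wallis (tie-corrected) with BH correction and
pairwise Wilcoxon rank-sum tests (Mann–Whitney U: exact for small untied
samples, continuity-corrected normal approximation otherwise).  Pathway
screens test each pathway's CPMs across the nine group × timepoint design
cells and correct over pathways; the default gate is BH q < 0.05, with a
raw-p mode available.  Species–pathway association uses tie-corrected
Kendall τ-b.  Local network parameters (Q, TC, N:P; nine values each) are
fitted to a normal and each group's three values are tested with a
one-sample one-sided t test against the fitted median (= μ̂).  The
directional alternatives must be supplied explicitly in configuration —
the direction is a scientific hypothesis, and auto-selecting it from the
observed trend would be post hoc; no default direction is applied.

## Synthetic cohort generator

The generator is a Gaussian copula.  Latent block factors (one per planted
block, cross-correlated for antagonist pairs by φ_ab = ρ_neg / √(ρ_a ρ_b),
validated positive-definite with an error naming the offending blocks) are
shared by block members: member i's latent is √ρ_b f_b + √(1 − ρ_b) ε_i,
so member–member latent correlation is ρ_b and cross-antagonist
correlation is ρ_neg.  A planted keystone *is* its block's factor
(loading 1), so members load on the keystone at √ρ_b.  Latents map through
log-normal marginals exp(base_i + dispersion · z) with per-species base
scales exp(N(0, 1)); a keystone's scale is pinned deterministically to
dominance × E[scale] so its expected community share is set by the
dominance weight alone.  Group × timepoint log2 fold changes multiply
block members' raw abundances (emulating pathobiont bloom and commensal
depletion under parenteral nutrition), zeros are injected independently
per cell at the configured probability (never zeroing a whole sample), and
each sample is closed to 100%.

Defaults emulate the study design: 10 subjects × 3 groups × 3 timepoints,
60 species, two commensal blocks (10 and 8 species, latent ρ = 0.8), one
pathobiont block (8 species, ρ = 0.85) antagonistic to the larger
commensal block at −0.5, a keystone of dominance 20 (~15–30% community
share, a dominant commensal) in the commensal block, zero inflation 0.05,
dispersion 1.0, and ±1 to ±2 log2-unit group effects at T1/T2.  No
effect-size estimates exist for the real cohort, so these are calibration
choices representing a clearly detectable but not degenerate signal.  For
keystone-recovery validation the dominance is derived from the
construction's requirement — the keystone must carry the majority of
cohesion, i.e. an expected relative abundance of ~60%, the magnitude of
single-taxon blooms in dysbiotic gut communities — giving
w = 1.5 · n_other · e^{1/2}.

What the generator does *not* emulate: longitudinal autocorrelation within
patients (samples are independent draws), strain-level structure,
read-level noise, and the compositional biases of profilers.  Passing
recovery tests therefore demonstrate correctness of the network machinery
on data with known rank structure, not profiler-level robustness.
Compositional closure is emulated, and matters: a dominant keystone
suppresses the closed abundances of everything else, which attenuates (and
can inverse) its rank correlation to its own block members — the keystone's
ΔTC nevertheless stays high because its abundance share carries the
cohesion sum.

The pathway generator produces Σ_s loading · abundance plus additive
log-normal noise; `noise_sd = 0` means exactly no noise so that identity
loadings reproduce a species column verbatim.

## Numerical and design choices

* BH q-values: step-up q_(i) = min_{j≥i} m · p_(j) / j, stable sort,
  capped at 1; validated against the quadratic textbook definition.
* Annealing tie-breaks: candidate spins drawn uniformly from all 25 spins
  (a proposal equal to the current spin is a no-op); best state tracked
  across the whole run, not just the final state.
* Leave-one-out and subset networks reuse the cohort-level species roster;
  re-filtering per subset would make parameter values incomparable across
  networks.
* Problem sizes for validation: recovery checks use 90-sample cohorts with
  24–30 species and 10 independent seeds — large enough for the ρ ≥ 0.85
  planted signal to clear the q < 0.05, |ρ| > 0.3 edge gate with margin,
  small enough to keep the full brute-force keystone scans comfortable.
* Determinism: every stochastic component takes a `numpy` Generator seed;
  pipeline outputs embed the seed in a comment header and are
  bit-reproducible for a given config (output-directory path excluded from
  the manifest so runs in different locations compare equal).

## Known limitations

* Spearman on compositional data is not compositionality-aware (no
  SparCC/SPIEC-EASI style correction); spurious closure-induced negative
  correlations are part of the method being reproduced.
* Classical modularity ignores the negative layer; signed alternatives
  exist but would not match the reported quantity.
* The spin-glass annealer is a stochastic optimiser; the exhaustive-oracle
  guarantees hold for the small fixtures tested, while large instances
  rely on the annealing schedule.
* Local networks at n = 10 samples are sparse and unstable under the FDR
  gate — mirrored by wide seed-to-seed variation in local keystone lists,
  which is a property of the design, not a bug.
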