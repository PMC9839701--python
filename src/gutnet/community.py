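"""Signed spin-glass module detection, modularity, centralities and hubs.

Module detection minimises the signed spin-glass Hamiltonian

    H(sigma) = - sum_{i<j} [ (w+_ij - gamma+ p+_ij)
                             - (w-_ij - gamma- p-_ij) ] delta(sigma_i, sigma_j)

where ``w+``/``w-`` are the magnitudes of positive/negative edge weights and
``p+``/``p-`` their configuration-model null expectations computed separately
from the positive and negative strength sequences (the signed null model of
Traag & Bruggeman).  Grouping positively linked nodes lowers the energy;
grouping negatively linked nodes raises it.  Optimisation is single-node
spin-flip simulated annealing with Metropolis acceptance and geometric
cooling, tracking the best state encountered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import SignedNetwork

__all__ = [
    "ModulePartition",
    "CentralityProfile",
    "signed_coupling_matrix",
    "spinglass_energy",
    "spinglass_modules",
    "modularity",
    "centralities",
    "identify_hubs",
]


@dataclass
class ModulePartition:
    """Spin assignment per node plus modularity of the partition."""

    labels: dict[str, int]
    n_modules: int
    modularity: float
    energy: float
    trace: dict = field(default_factory=dict)
    no_edges: bool = False

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"module": pd.Series(self.labels)}).rename_axis("species")


@dataclass
class CentralityProfile:
    """Degree / betweenness / closeness per node, the fitted normal for each
    metric, and the hub flags."""

    table: pd.DataFrame            # columns: degree, betweenness, closeness, hub
    fits: dict[str, tuple[float, float]]  # metric -> (mu_hat, sigma_hat)

    @property
    def hubs(self) -> list[str]:
        return self.table.index[self.table["hub"]].tolist()


def signed_coupling_matrix(network: SignedNetwork,
                           gamma_pos: float = 1.0,
                           gamma_neg: float = 1.0
                           ) -> tuple[np.ndarray, list[str]]:
    """Pair coupling J_ij = (w+_ij - gamma+ p+_ij) - (w-_ij - gamma- p-_ij).

    The null expectations use the configuration model on each sign layer:
    p+_ij = s+_i s+_j / (2 m+), with s+ the positive strengths and m+ the
    total positive weight (and likewise for the negative layer).  A layer
    with no edges contributes zero.
    """
    nodes = list(network.graph.nodes)
    idx = {n: k for k, n in enumerate(nodes)}
    n = len(nodes)
    wpos = np.zeros((n, n))
    wneg = np.zeros((n, n))
    for u, v, d in network.graph.edges(data=True):
        w = float(d["weight"])
        i, j = idx[u], idx[v]
        if w >= 0:
            wpos[i, j] = wpos[j, i] = w
        else:
            wneg[i, j] = wneg[j, i] = -w
    J = np.zeros((n, n))
    for w, gamma, sign in ((wpos, gamma_pos, 1.0), (wneg, gamma_neg, -1.0)):
        total = w.sum() / 2.0
        if total > 0:
            s = w.sum(axis=1)
            null = np.outer(s, s) / (2.0 * total)
            J += sign * (w - gamma * null)
        # layer absent: no contribution
    np.fill_diagonal(J, 0.0)
    return J, nodes


def spinglass_energy(J: np.ndarray, labels: np.ndarray) -> float:
    """H = -1/2 sum_{i != j} J_ij [sigma_i == sigma_j] (diagonal is zero)."""
    same = labels[:, None] == labels[None, :]
    return -0.5 * float((J * same).sum())


def spinglass_modules(network: SignedNetwork,
                      spins: int = 25,
                      gamma_pos: float = 1.0,
                      gamma_neg: float = 1.0,
                      t_start: float = 1.0,
                      t_stop: float = 0.01,
                      cooling: float = 0.99,
                      sweeps_per_temp: int = 1,
                      seed: int = 0) -> ModulePartition:
    """Detect modules by annealing the signed spin-glass Hamiltonian.

    Defaults follow the classical setup: 25 spins, unit resolution on both
    sign layers, geometric cooling from T=1 to T=0.01 with factor 0.99, and
    the simple single-node update rule (uniformly random candidate spin,
    Metropolis acceptance).  Deterministic for a given seed.  Networks with
    zero edges return every node in its own module with Q = 0 and a flag.
    """
    nodes = list(network.graph.nodes)
    if not nodes:
        raise ValueError("empty network")
    if network.n_edges == 0:
        labels = {n: k for k, n in enumerate(nodes)}
        return ModulePartition(labels=labels, n_modules=len(nodes),
                               modularity=0.0, energy=0.0,
                               trace={"t_start": t_start, "t_stop": t_stop,
                                      "accepted": 0},
                               no_edges=True)

    rng = np.random.default_rng(seed)
    J, nodes = signed_coupling_matrix(network, gamma_pos, gamma_neg)
    n = len(nodes)
    labels = rng.integers(0, spins, size=n)
    energy = spinglass_energy(J, labels)
    best_labels, best_energy = labels.copy(), energy
    accepted = 0

    t = t_start
    while t >= t_stop:
        for _ in range(sweeps_per_temp):
            order = rng.permutation(n)
            cand = rng.integers(0, spins, size=n)
            unif = rng.random(n)
            for k in range(n):
                v = order[k]
                new = cand[k]
                old = labels[v]
                if new == old:
                    continue
                row = J[v]
                # dH = S_v(old) - S_v(new) where S_v(c) = sum_{u: sigma_u=c} J_vu
                d_h = (row[labels == old].sum()
                       - row[labels == new].sum())
                if d_h <= 0 or unif[k] < np.exp(-d_h / t):
                    labels[v] = new
                    energy += d_h
                    accepted += 1
                    if energy < best_energy - 1e-12:
                        best_energy = energy
                        best_labels = labels.copy()
        t *= cooling

    # relabel modules 0..k-1, stable-sorted by decreasing size
    uniq, counts = np.unique(best_labels, return_counts=True)
    order = sorted(range(len(uniq)), key=lambda i: (-counts[i], uniq[i]))
    remap = {uniq[i]: rank for rank, i in enumerate(order)}
    label_map = {nodes[i]: remap[best_labels[i]] for i in range(n)}
    q = modularity(network, label_map)
    return ModulePartition(
        labels=label_map,
        n_modules=len(uniq),
        modularity=q,
        energy=float(best_energy),
        trace={"t_start": t_start, "t_stop": t_stop, "cooling": cooling,
               "accepted": accepted, "seed": seed},
    )


def modularity(network: SignedNetwork, labels: dict[str, int]) -> float:
    """Newman weighted modularity on the positive-weight edges only.

    Q = 1/(2m) sum_ij (w_ij - k_i k_j / 2m) delta(sigma_i, sigma_j) with w
    the positive edge weights and k the positive strengths.  Classical
    modularity is undefined for signed graphs, so negative edges — already
    handled by the spin-glass Hamiltonian during detection — are excluded
    here.  Returns 0 if the network has no positive edges.
    """
    missing = [n for n in network.graph.nodes if n not in labels]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    nodes = list(network.graph.nodes)
    idx = {n: k for k, n in enumerate(nodes)}
    n = len(nodes)
    w = np.zeros((n, n))
    for u, v, d in network.graph.edges(data=True):
        if d["weight"] > 0:
            w[idx[u], idx[v]] = w[idx[v], idx[u]] = d["weight"]
    two_m = w.sum()
    if two_m == 0:
        return 0.0
    k = w.sum(axis=1)
    lab = np.array([labels[x] for x in nodes])
    same = lab[:, None] == lab[None, :]
    q = ((w - np.outer(k, k) / two_m) * same).sum() / two_m
    return float(q)


def centralities(network: SignedNetwork) -> pd.DataFrame:
    """Degree, betweenness and closeness on the unweighted skeleton.

    Signed correlation weights are not distances, so shortest paths are
    computed on the unweighted undirected skeleton of retained edges.
    Betweenness is the unnormalised pair count; closeness of node i is
    r_i / sum of distances to its reachable set (r_i nodes), which treats
    components separately; isolated nodes score 0 on all three.
    """
    g = network.graph
    deg = dict(g.degree())
    btw = nx.betweenness_centrality(g, normalized=False)
    clo = nx.closeness_centrality(g, wf_improved=False)
    table = pd.DataFrame({
        "degree": pd.Series(deg, dtype=float),
        "betweenness": pd.Series(btw, dtype=float),
        "closeness": pd.Series(clo, dtype=float),
    }).loc[list(g.nodes)]
    table.index.name = "species"
    return table


def identify_hubs(table: pd.DataFrame) -> CentralityProfile:
    """Flag hub nodes from a centrality table.

    Each metric's distribution is fitted to a normal by maximum likelihood
    (mu_hat = sample mean, sigma_hat = ML standard deviation); a node is a
    hub iff its degree, betweenness and closeness all *strictly* exceed the
    respective mu_hat.  With zero variance in a metric no node can exceed
    its mean, so no hubs arise through that metric.
    """
    if len(table) < 2:
        raise ValueError("need >= 2 nodes to fit centrality distributions")
    fits: dict[str, tuple[float, float]] = {}
    above = np.ones(len(table), dtype=bool)
    for metric in ("degree", "betweenness", "closeness"):
        vals = table[metric].to_numpy(dtype=float)
        mu = float(vals.mean())
        sigma = float(vals.std(ddof=0))
        fits[metric] = (mu, sigma)
        above &= vals > mu
    out = table.copy()
    out["hub"] = above
    return CentralityProfile(table=out, fits=fits)
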