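"""Connectedness, cohesion, total cohesion (TC), N:P ratio and the
leave-one-out keystone scan.

Connectedness follows the microbial-community cohesion framework of Herren &
McMahon: each taxon's positive (negative) connectedness is the mean of the
positive (negative) correlations it retains in the thresholded network, and a
sample's positive (negative) cohesion is the abundance-weighted sum of those
connectedness values.  Here connectedness averages the retained (FDR- and
|rho|-thresholded) observed Spearman correlations directly; the original
null-model correction of the correlation matrix is not applied, because
cohesion is computed on the same thresholded networks used everywhere else
in the pipeline.

A *keystone* is a taxon whose removal (abundance set to zero everywhere,
network re-estimated) reduces network-level total cohesion by more than a
configurable percentage (default 50%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SignedNetwork
from .network import build_network, spearman_matrix

__all__ = [
    "connectedness",
    "CohesionResult",
    "cohesion",
    "keystone_scan",
]


def connectedness(network: SignedNetwork) -> pd.DataFrame:
    """Per-taxon mean retained positive and negative edge weights.

    Returns a DataFrame indexed by species with columns ``c_pos`` (mean of
    incident positive weights, 0 if none) and ``c_neg`` (mean of incident
    negative weights, 0 if none, always <= 0).
    """
    rows = {}
    for node in network.graph.nodes:
        pos = [d["weight"] for _, _, d in network.graph.edges(node, data=True)
               if d["weight"] > 0]
        neg = [d["weight"] for _, _, d in network.graph.edges(node, data=True)
               if d["weight"] < 0]
        rows[node] = (float(np.mean(pos)) if pos else 0.0,
                      float(np.mean(neg)) if neg else 0.0)
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=["c_pos", "c_neg"])
    out.index.name = "species"
    return out


@dataclass
class CohesionResult:
    """Per-sample positive/negative cohesion and network-level aggregates.

    ``per_sample`` has columns ``cohesion_pos`` (>= 0) and ``cohesion_neg``
    (<= 0).  ``P`` and ``N`` are their means over the samples defining the
    network; ``total_cohesion`` is P + |N| and ``np_ratio`` |N| / P
    (``inf`` if P = 0 with N != 0, 0 if both are 0).
    """

    per_sample: pd.DataFrame
    P: float
    N: float
    total_cohesion: float
    np_ratio: float


def cohesion(table: pd.DataFrame, conn: pd.DataFrame) -> CohesionResult:
    """Abundance-weighted cohesion per sample and network-level TC and N:P.

    ``table`` is a samples x species table in percent whose species equal the
    connectedness roster; abundances enter the sums as fractions
    (percent / 100).
    """
    if set(table.columns) != set(conn.index):
        raise ValueError("abundance species do not match connectedness roster")
    conn = conn.loc[table.columns]
    frac = table.to_numpy(dtype=float) / 100.0
    c_pos = frac @ conn["c_pos"].to_numpy()
    c_neg = frac @ conn["c_neg"].to_numpy()
    per_sample = pd.DataFrame(
        {"cohesion_pos": c_pos, "cohesion_neg": c_neg}, index=table.index)
    P = float(c_pos.mean())
    N = float(c_neg.mean())
    tc = P + abs(N)
    if P > 0:
        np_ratio = abs(N) / P
    else:
        np_ratio = 0.0 if N == 0 else float("inf")
    return CohesionResult(per_sample=per_sample, P=P, N=N,
                          total_cohesion=tc, np_ratio=np_ratio)


def _network_tc(table: pd.DataFrame, q_max: float, rho_min: float) -> float:
    corr = spearman_matrix(table)
    net = build_network(corr, q_max=q_max, rho_min=rho_min, abundances=table)
    conn = connectedness(net)
    return cohesion(table, conn).total_cohesion


def keystone_scan(table: pd.DataFrame,
                  q_max: float = 0.05,
                  rho_min: float = 0.3,
                  keystone_cut: float = 50.0) -> pd.DataFrame:
    """Brute-force leave-one-out keystone scan.

    For each taxon, its abundance is set to zero in every sample (without
    re-closing the remaining abundances), the Spearman matrix, BH correction,
    thresholded network and cohesion are recomputed on the same roster, and
    the percent reduction in total cohesion is reported:

        delta_tc_pct = 100 * (TC_full - TC_loo) / TC_full

    A taxon is flagged keystone when delta_tc_pct > ``keystone_cut``.
    ``table`` should already be restricted to the network roster (filtered
    species) and to the samples defining the network of interest.
    """
    if not 0.0 < keystone_cut < 100.0:
        raise ValueError("keystone_cut must be in (0, 100)")
    tc_full = _network_tc(table, q_max, rho_min)
    if tc_full <= 0:
        raise ValueError("total cohesion of the full network is zero; "
                         "keystone percentages are undefined")
    records = []
    for sp in table.columns:
        reduced = table.copy()
        reduced[sp] = 0.0
        tc_loo = _network_tc(reduced, q_max, rho_min)
        delta = 100.0 * (tc_full - tc_loo) / tc_full
        records.append((sp, tc_full, tc_loo, delta, delta > keystone_cut))
    out = pd.DataFrame(
        records,
        columns=["species", "tc_full", "tc_loo", "delta_tc_pct", "keystone"],
    ).set_index("species")
    return out
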