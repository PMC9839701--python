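"""Species filtering, Spearman correlation with FDR control, and signed
co-occurrence network construction (global and local)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import SignedNetwork, check_samples_match

__all__ = [
    "CorrelationResult",
    "filter_species",
    "spearman_matrix",
    "bh_fdr",
    "build_network",
    "subset_networks",
]


@dataclass
class CorrelationResult:
    """Pairwise Spearman result: symmetric rho / p / q DataFrames over one
    sample subset.  q is Benjamini-Hochberg over the strict upper triangle."""

    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    samples: tuple[str, ...]
    constant_species: tuple[str, ...] = ()

    @property
    def species(self) -> list[str]:
        return list(self.rho.index)


def filter_species(table: pd.DataFrame,
                   min_abundance_pct: float = 0.3,
                   min_prevalence: float = 0.05) -> pd.DataFrame:
    """Keep species whose relative abundance exceeds ``min_abundance_pct``
    percent in at least ``min_prevalence`` of the samples (at least
    ``ceil(min_prevalence * n_samples)`` samples).  The sample set is
    unchanged."""
    if table.empty:
        raise ValueError("empty abundance table")
    n = len(table.index)
    need = int(np.ceil(min_prevalence * n))
    hits = (table.to_numpy() > min_abundance_pct).sum(axis=0)
    keep = table.columns[hits >= need]
    if len(keep) == 0:
        warnings.warn("no species survive the abundance/prevalence filter")
    return table[keep]


def spearman_matrix(table: pd.DataFrame) -> CorrelationResult:
    """Spearman rho/p over all species pairs of one sample subset.

    rho uses average ranks; p-values come from the t approximation on n-2
    degrees of freedom.  Species constant across the subset (e.g. all-zero
    after zero inflation) yield rho = 0, p = 1 and are flagged rather than
    erroring, so that sparse local subsets remain analysable.
    """
    n, m = table.shape
    if n < 4:
        raise ValueError(f"need >= 4 samples for correlation (got {n})")
    if m < 2:
        raise ValueError(f"need >= 2 species (got {m})")
    vals = table.to_numpy(dtype=float)
    const_mask = np.ptp(vals, axis=0) == 0
    constant = table.columns[const_mask].tolist()

    # Spearman = Pearson on average ranks; computed directly so that
    # constant columns degrade gracefully instead of poisoning the matrix.
    ranks = np.apply_along_axis(stats.rankdata, 0, vals)
    centered = ranks - ranks.mean(axis=0)
    norms = np.sqrt((centered ** 2).sum(axis=0))
    safe = np.where(norms == 0, 1.0, norms)
    rho = (centered / safe).T @ (centered / safe)
    rho = np.clip(rho, -1.0, 1.0)
    rho[const_mask, :] = 0.0
    rho[:, const_mask] = 0.0

    # p-values via the t approximation on n - 2 degrees of freedom
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(p), 0.0, p)          # |rho| = 1 -> t = inf -> p = 0
    p[const_mask, :] = 1.0
    p[:, const_mask] = 1.0
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)

    iu = np.triu_indices(m, k=1)
    qv = bh_fdr(p[iu])
    q = np.ones_like(p)
    q[iu] = qv
    q.T[iu] = qv
    np.fill_diagonal(q, 0.0)
    cols = table.columns
    return CorrelationResult(
        rho=pd.DataFrame(rho, index=cols, columns=cols),
        p=pd.DataFrame(p, index=cols, columns=cols),
        q=pd.DataFrame(q, index=cols, columns=cols),
        samples=tuple(table.index),
        constant_species=tuple(constant),
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} m * p_(j) / j on the sorted p-values, mapped back to
    the input order and capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)) or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def build_network(corr: CorrelationResult,
                  q_max: float = 0.05,
                  rho_min: float = 0.3,
                  abundances: pd.DataFrame | None = None,
                  name: str = "network") -> SignedNetwork:
    """Threshold a correlation result into a signed network.

    An edge (i, j) is retained iff ``q_ij < q_max`` and ``|rho_ij| > rho_min``;
    its weight is the signed rho.  Nodes are the full species roster (isolated
    nodes kept) annotated with mean relative abundance over the subset used.
    """
    species = corr.species
    g = nx.Graph()
    if abundances is not None:
        sub = abundances.loc[list(corr.samples), species]
        means = sub.mean(axis=0)
    else:
        means = pd.Series(np.nan, index=species)
    for sp in species:
        g.add_node(sp, mean_abundance=float(means[sp]))
    rho = corr.rho.to_numpy()
    q = corr.q.to_numpy()
    m = len(species)
    for i in range(m):
        for j in range(i + 1, m):
            if q[i, j] < q_max and abs(rho[i, j]) > rho_min:
                g.add_edge(species[i], species[j],
                           weight=float(rho[i, j]), q=float(q[i, j]))
    return SignedNetwork(
        graph=g, name=name, samples=corr.samples,
        thresholds={"q_max": q_max, "rho_min": rho_min},
    )


def subset_networks(table: pd.DataFrame,
                    metadata: pd.DataFrame,
                    mode: str = "global",
                    min_abundance_pct: float = 0.3,
                    min_prevalence: float = 0.05,
                    q_max: float = 0.05,
                    rho_min: float = 0.3) -> list[SignedNetwork]:
    """Build the global network or the per-group / per-group-and-timepoint
    local networks.

    The abundance/prevalence filter is applied once on the full cohort; all
    subsets share that roster so that the same species can be compared across
    networks.  Each subset gets its own correlation matrix and its own BH
    correction.
    """
    check_samples_match(table, metadata)
    filtered = filter_species(table, min_abundance_pct, min_prevalence)

    def _one(samples: list[str], name: str) -> SignedNetwork:
        if len(samples) < 4:
            raise ValueError(f"subset {name!r} has < 4 samples")
        sub = filtered.loc[samples]
        corr = spearman_matrix(sub)
        return build_network(corr, q_max=q_max, rho_min=rho_min,
                             abundances=table, name=name)

    md = metadata.loc[table.index]
    if mode == "global":
        return [_one(list(table.index), "global")]
    if mode == "per_group":
        out = []
        for g in dict.fromkeys(md["group"]):
            samples = md.index[md["group"] == g].tolist()
            out.append(_one(samples, g))
        return out
    if mode == "per_group_timepoint":
        out = []
        for g in dict.fromkeys(md["group"]):
            for t in dict.fromkeys(md["timepoint"]):
                sel = (md["group"] == g) & (md["timepoint"] == t)
                samples = md.index[sel].tolist()
                out.append(_one(samples, f"{g}_{t}"))
        return out
    raise ValueError(f"unknown mode {mode!r}")
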