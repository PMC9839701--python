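"""Readers and writers for the standard profile formats the pipeline touches.

Conventions used throughout the package:

* **Abundance tables** are :class:`pandas.DataFrame` objects with samples as
  rows and species as columns, values in percent relative abundance
  (MetaPhlAn convention).  Cohesion math consumes fractions; the conversion
  (percent / 100) is centralised in :mod:`gutnet.cohesion`.
* **Sample metadata** is a DataFrame indexed by sample id with columns
  ``patient``, ``group`` and ``timepoint`` drawn from closed vocabularies.
* **Pathway / gene-family tables** are DataFrames with samples as rows and
  features as columns, in CPM (copies per million) after normalisation.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "TIMEPOINTS",
    "KOMapping",
    "SignedNetwork",
    "read_metaphlan_table",
    "write_metaphlan_table",
    "read_metadata",
    "write_metadata",
    "check_samples_match",
    "read_pathway_table",
    "write_pathway_table",
    "cpm_normalize",
    "read_ko_mapping",
    "write_network",
    "read_network_graphml",
]

#: Canonical treatment-group tokens: enteral nutrition, parenteral nutrition
#: without levofloxacin prophylaxis, parenteral nutrition with levofloxacin.
GROUPS = ("EN", "PN_LVX_MINUS", "PN_LVX_PLUS")

#: Sampling timepoints: pre-transplant, engraftment, pre-discharge.
TIMEPOINTS = ("T0", "T1", "T2")

# Display spellings accepted on input and mapped onto the canonical tokens.
_GROUP_ALIASES = {
    "EN": "EN",
    "PN_LVX_MINUS": "PN_LVX_MINUS",
    "PN_LVX_PLUS": "PN_LVX_PLUS",
    "PN LVX (-)": "PN_LVX_MINUS",
    "PN LVX (–)": "PN_LVX_MINUS",  # en dash variant
    "PN LVX (+)": "PN_LVX_PLUS",
}

_RANK_PREFIX = {
    "kingdom": "k__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
    "species": "s__",
    "strain": "t__",
}
_ALL_PREFIXES = tuple(_RANK_PREFIX.values())


# ---------------------------------------------------------------------------
# MetaPhlAn-style merged abundance tables
# ---------------------------------------------------------------------------

def read_metaphlan_table(path: str | Path, level: str = "species") -> pd.DataFrame:
    """Read a MetaPhlAn-style merged TSV and extract one taxonomic rank.

    The first column holds taxonomy strings like
    ``k__Bacteria|p__Firmicutes|...|s__Faecalibacterium_prausnitzii``; the
    remaining columns are samples with percent relative abundances.  Rows
    whose *deepest* rank token matches ``level`` are retained (so strain
    ``t__`` rows are not double counted as species), and the name is taken
    from that token.  An optional second NCBI-taxid column (present in some
    profiler versions) is detected and dropped.

    Returns a samples x species DataFrame in percent.
    """
    level = level.lower()
    if level not in _RANK_PREFIX:
        raise ValueError(f"unknown taxonomic level {level!r}")
    prefix = _RANK_PREFIX[level]

    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    # drop profiler banner comments (no tabs); keep a commented header row
    while lines and lines[0].startswith("#") and "\t" not in lines[0]:
        lines.pop(0)
    if not lines:
        raise ValueError(f"{path}: no table content found")
    lines[0] = lines[0].lstrip("#")
    df = pd.read_csv(_io.StringIO("\n".join(lines)), sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected taxonomy column plus sample columns")

    clade_col = df.columns[0]
    sample_cols = list(df.columns[1:])
    # NCBI taxid dialect: second column of pipe-joined integers or named *taxid*
    second = df.columns[1]
    if "taxid" in second.lower() or _looks_like_taxid(df[second]):
        sample_cols = sample_cols[1:]

    names: list[str] = []
    rows: list[np.ndarray] = []
    for clade, vals in zip(df[clade_col], df[sample_cols].to_numpy(dtype=float)):
        tokens = str(clade).split("|")
        if not all(t[:3] in _ALL_PREFIXES for t in tokens):
            warnings.warn(f"skipping malformed taxonomy string {clade!r}")
            continue
        deepest = tokens[-1]
        if not deepest.startswith(prefix):
            continue
        names.append(deepest[3:])
        rows.append(vals)

    dupes = pd.Index(names)[pd.Index(names).duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate {level} names after extraction: {dupes}")
    table = pd.DataFrame(
        np.array(rows, dtype=float).reshape(len(rows), len(sample_cols)),
        index=names, columns=sample_cols,
    ).T
    table.index.name = "sample"
    _validate_abundance(table)
    return table


def _looks_like_taxid(col: pd.Series) -> bool:
    try:
        return all(
            all(part == "" or part.lstrip("-").isdigit() for part in str(v).split("|"))
            for v in col.head(5)
        )
    except Exception:  # pragma: no cover - defensive
        return False


def _validate_abundance(table: pd.DataFrame) -> None:
    vals = table.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("abundance table contains non-finite values")
    if (vals < 0).any():
        raise ValueError("abundance table contains negative values")
    if table.index.duplicated().any():
        raise ValueError("duplicate sample identifiers")
    if table.columns.duplicated().any():
        raise ValueError("duplicate species identifiers")
    sums = vals.sum(axis=1)
    if (sums > 100.0 + 1e-6).any():
        bad = table.index[sums > 100.0 + 1e-6].tolist()
        raise ValueError(f"per-sample abundance exceeds 100%: {bad}")


def write_metaphlan_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a samples x species percent table as a MetaPhlAn-style TSV.

    Species are given a minimal synthetic lineage ``k__Bacteria|s__<name>``
    sufficient to round-trip through :func:`read_metaphlan_table`.
    """
    out = table.T.copy()
    out.index = [f"k__Bacteria|s__{sp}" for sp in out.index]
    out.index.name = "clade_name"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata TSV (sample, patient, group, timepoint).

    Group and timepoint labels are validated against the closed study
    vocabularies; display spellings such as ``PN LVX (+)`` are canonicalised.
    """
    md = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample", "patient", "group", "timepoint"}
    missing = required - set(md.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    md = md.set_index("sample")
    bad_groups = sorted(set(md["group"]) - set(_GROUP_ALIASES))
    if bad_groups:
        raise ValueError(f"unknown group labels: {bad_groups}")
    md["group"] = md["group"].map(_GROUP_ALIASES)
    bad_tp = sorted(set(md["timepoint"]) - set(TIMEPOINTS))
    if bad_tp:
        raise ValueError(f"unknown timepoint labels: {bad_tp}")
    if md.index.duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    return md


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample")


def check_samples_match(table: pd.DataFrame, metadata: pd.DataFrame) -> None:
    """Require a one-to-one sample correspondence between table and metadata."""
    t, m = set(table.index), set(metadata.index)
    if t != m:
        raise ValueError(
            f"sample mismatch: only in table {sorted(t - m)}; "
            f"only in metadata {sorted(m - t)}"
        )


# ---------------------------------------------------------------------------
# Pathway / gene-family tables and KO mapping
# ---------------------------------------------------------------------------

def read_pathway_table(path: str | Path, normalize: bool = False) -> pd.DataFrame:
    """Read a HUMAnN-style feature x sample TSV into samples x features.

    With ``normalize=True`` each sample is rescaled to 1e6 total (CPM).
    """
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    table = df.T.astype(float)
    table.index.name = "sample"
    if (table.to_numpy() < 0).any():
        raise ValueError("pathway table contains negative values")
    if normalize:
        table = cpm_normalize(table)
    return table


def write_pathway_table(table: pd.DataFrame, path: str | Path,
                        feature_label: str = "# Pathway") -> None:
    out = table.T
    out.index.name = feature_label
    out.to_csv(path, sep="\t")


def cpm_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Rescale each sample (row) to a total of 1e6 copies per million."""
    totals = table.sum(axis=1)
    if (totals <= 0).any():
        bad = table.index[totals <= 0].tolist()
        raise ValueError(f"cannot CPM-normalize all-zero samples: {bad}")
    return table.div(totals, axis=0) * 1e6


METABOLISM_CLASSES = ("amino acid", "carbohydrate", "lipid", "xenobiotic", "other")


@dataclass(frozen=True)
class KOMapping:
    """Gene family -> KO -> metabolism class lookup (many-to-one allowed)."""

    gene_to_ko: dict[str, str]
    ko_to_class: dict[str, str]

    def class_of(self, gene_family: str) -> str | None:
        ko = self.gene_to_ko.get(gene_family)
        return None if ko is None else self.ko_to_class.get(ko, "other")


def read_ko_mapping(path: str | Path) -> KOMapping:
    """Read a gene_family / ko / metabolism_class TSV."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"gene_family", "ko", "metabolism_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"KO mapping missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("empty KO mapping")
    multi = df.groupby("gene_family")["ko"].nunique()
    offenders = multi[multi > 1].index.tolist()
    if offenders:
        raise ValueError(f"gene families mapped to multiple KOs: {offenders}")
    bad = sorted(set(df["metabolism_class"]) - set(METABOLISM_CLASSES))
    if bad:
        raise ValueError(f"unknown metabolism classes: {bad}")
    gene_to_ko = dict(zip(df["gene_family"], df["ko"]))
    ko_to_class = dict(zip(df["ko"], df["metabolism_class"]))
    return KOMapping(gene_to_ko, ko_to_class)


# ---------------------------------------------------------------------------
# Signed co-occurrence networks
# ---------------------------------------------------------------------------

@dataclass
class SignedNetwork:
    """A signed, weighted, undirected species co-occurrence network.

    Nodes are the full filtered species roster (isolated nodes included) and
    carry ``mean_abundance`` (percent) and optionally ``module``.  Edges carry
    ``weight`` (the signed Spearman rho of a retained pair) and ``q`` (its
    BH-adjusted p-value).
    """

    graph: nx.Graph
    name: str = "network"
    samples: tuple[str, ...] = ()
    thresholds: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_weights(self) -> dict[tuple[str, str], float]:
        return {(u, v): d["weight"] for u, v, d in self.graph.edges(data=True)}

    def set_modules(self, labels: dict[str, int]) -> None:
        nx.set_node_attributes(self.graph, labels, "module")


def write_network(network: SignedNetwork, path: str | Path,
                  format: str = "tsv") -> None:
    """Export a network for downstream visualisation (e.g. Cytoscape).

    ``tsv`` writes an edge list (source, target, weight, q) to ``path`` and a
    node table (species, mean_abundance, module) to ``<path>.nodes.tsv``;
    ``graphml`` writes a single GraphML document.
    """
    path = Path(path)
    g = network.graph
    if format == "tsv":
        edges = pd.DataFrame(
            [(u, v, d["weight"], d.get("q", np.nan))
             for u, v, d in g.edges(data=True)],
            columns=["source", "target", "weight", "q"],
        )
        edges.to_csv(path, sep="\t", index=False)
        nodes = pd.DataFrame(
            [(n, d.get("mean_abundance", np.nan), d.get("module", ""))
             for n, d in g.nodes(data=True)],
            columns=["species", "mean_abundance", "module"],
        )
        nodes.to_csv(path.with_suffix(path.suffix + ".nodes.tsv"),
                     sep="\t", index=False)
    elif format == "graphml":
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network_graphml(path: str | Path, name: str = "network") -> SignedNetwork:
    g = nx.read_graphml(path)
    return SignedNetwork(graph=nx.Graph(g), name=name)
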