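"""The study's statistical layer: Shannon diversity, rank tests with BH
correction, Kendall species x pathway correlation, KO/metabolism summaries,
and the one-sample t-test procedure for local network parameters."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import METABOLISM_CLASSES, KOMapping
from .network import bh_fdr

__all__ = [
    "TestResult",
    "shannon",
    "kruskal_wallis",
    "wilcoxon_rank_sum",
    "kendall_tau",
    "network_param_tests",
    "pathway_screen",
    "species_pathway_heatmap",
    "ko_metabolism_summary",
]


@dataclass
class TestResult:
    """One hypothesis test: statistic, p, optional BH q, alternative, labels."""

    name: str
    statistic: float
    pvalue: float
    qvalue: float | None = None
    alternative: str = "two-sided"
    groups: tuple[str, ...] = ()
    flag: str | None = None


def shannon(values, base: float | None = None) -> float:
    """Shannon diversity H' = -sum p_i log p_i over taxa with p_i > 0.

    ``values`` are nonnegative abundances of one sample (any scale; they are
    normalised to proportions).  Natural log by default — the convention of
    the classical ecology toolkits — with ``base`` configurable.
    """
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = v.sum()
    if total <= 0:
        raise ValueError("all-zero sample has undefined diversity")
    p = v[v > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def kruskal_wallis(values, groups) -> TestResult:
    """Kruskal-Wallis H test across >= 2 groups (tie-corrected)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    samples = [values[groups == g] for g in labels]
    if np.ptp(values) == 0:
        return TestResult("kruskal_wallis", 0.0, 1.0,
                          groups=tuple(labels), flag="all tied")
    h, p = sps.kruskal(*samples)
    return TestResult("kruskal_wallis", float(h), float(p),
                      groups=tuple(labels))


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> TestResult:
    """Two-sample Wilcoxon rank sum (Mann-Whitney U).

    Exact for small untied samples, otherwise the continuity-corrected
    normal approximation — mirroring R's ``wilcox.test`` defaults.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    if np.ptp(np.concatenate([x, y])) == 0:
        return TestResult("wilcoxon_rank_sum", float(x.size * y.size / 2), 1.0,
                          alternative=alternative, flag="all tied")
    res = sps.mannwhitneyu(x, y, alternative=alternative, method="auto")
    return TestResult("wilcoxon_rank_sum", float(res.statistic),
                      float(res.pvalue), alternative=alternative)


def kendall_tau(x, y) -> TestResult:
    """Kendall rank correlation, tie-corrected (tau-b)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("x and y must be equal-length vectors of size >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult("kendall_tau", 0.0, 1.0, flag="constant input")
    tau, p = sps.kendalltau(x, y)
    return TestResult("kendall_tau", float(tau), float(p))


def network_param_tests(panel: pd.DataFrame,
                        alternatives: dict[str, dict[str, str]],
                        drop_nonfinite: bool = False) -> pd.DataFrame:
    """One-sample one-sided t tests of local network parameters per group.

    ``panel`` has one row per local network with columns ``group`` plus one
    column per parameter (e.g. modularity, total_cohesion, np_ratio; nine
    rows for the full 3-group x 3-timepoint design).  For each parameter,
    all values are fitted to a normal by maximum likelihood and each group's
    values are tested against the estimated median of that fit (= mu_hat for
    a normal) with the group's configured one-sided alternative
    (``alternatives[parameter][group]`` in {"greater", "less"}).

    The alternatives must be supplied explicitly: the direction of each test
    is a scientific choice, not something to auto-select from the data.
    """
    params = [c for c in panel.columns if c != "group"]
    records = []
    for param in params:
        sub = panel[["group", param]]
        finite = np.isfinite(sub[param].to_numpy(dtype=float))
        if not finite.all():
            if not drop_nonfinite:
                raise ValueError(f"non-finite values for parameter {param!r}")
            sub = sub.loc[finite]
        vals = sub[param].to_numpy(dtype=float)
        mu_hat = float(vals.mean())
        sigma_hat = float(vals.std(ddof=0))
        for g in dict.fromkeys(panel["group"]):
            gv = sub.loc[sub["group"] == g, param].to_numpy(dtype=float)
            alt = alternatives.get(param, {}).get(g, "two-sided")
            if gv.size < 2 or np.ptp(gv) == 0:
                records.append((param, g, mu_hat, sigma_hat, np.nan, np.nan,
                                alt, "zero within-group variance"))
                continue
            res = sps.ttest_1samp(gv, popmean=mu_hat, alternative=alt)
            records.append((param, g, mu_hat, sigma_hat,
                            float(res.statistic), float(res.pvalue), alt, None))
    return pd.DataFrame(
        records,
        columns=["parameter", "group", "mu_hat", "sigma_hat",
                 "t", "p", "alternative", "flag"],
    )


def pathway_screen(pathways: pd.DataFrame,
                   metadata: pd.DataFrame,
                   use_fdr: bool = True,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Kruskal-Wallis screen of pathways across the design cells.

    Samples are grouped by group x timepoint (nine cells for the full
    design); each pathway is tested across cells and BH-corrected over
    pathways.  The default gate is BH q < alpha; ``use_fdr=False`` gates on
    the raw p instead.  Pathways constant across all samples are skipped
    with a flag.
    """
    md = metadata.loc[pathways.index]
    cells = (md["group"].astype(str) + ":" + md["timepoint"].astype(str)).to_numpy()
    records = []
    for pw in pathways.columns:
        vals = pathways[pw].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            records.append((pw, np.nan, np.nan, "constant"))
            continue
        res = kruskal_wallis(vals, cells)
        records.append((pw, res.statistic, res.pvalue, res.flag))
    out = pd.DataFrame(records, columns=["pathway", "H", "p", "flag"]
                       ).set_index("pathway")
    tested = out["p"].notna()
    q = np.full(len(out), np.nan)
    if tested.any():
        q[tested.to_numpy()] = bh_fdr(out.loc[tested, "p"].to_numpy())
    out["q"] = q
    gate = out["q"] if use_fdr else out["p"]
    out["passed"] = gate < alpha
    out.loc[~tested, "passed"] = False
    return out


def species_pathway_heatmap(species: pd.DataFrame,
                            pathways: pd.DataFrame) -> pd.DataFrame:
    """Kendall tau matrix (species x pathways) over shared samples."""
    if not species.index.equals(pathways.index):
        raise ValueError("species and pathway tables must share samples "
                         "in the same order")
    mat = np.zeros((species.shape[1], pathways.shape[1]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, sp in enumerate(species.columns):
            x = species[sp].to_numpy(dtype=float)
            for j, pw in enumerate(pathways.columns):
                tau = sps.kendalltau(x, pathways[pw].to_numpy(dtype=float))[0]
                mat[i, j] = 0.0 if np.isnan(tau) else tau
    return pd.DataFrame(mat, index=species.columns, columns=pathways.columns)


def ko_metabolism_summary(gene_families: pd.DataFrame,
                          mapping: KOMapping,
                          metadata: pd.DataFrame,
                          alpha: float = 0.05
                          ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Aggregate gene-family CPMs into metabolism classes and test them.

    Gene families are mapped to KOs and KOs to metabolism classes; unmapped
    families are excluded from the totals and counted in the coverage
    report.  Class totals per sample are compared across the group x
    timepoint design cells with Kruskal-Wallis, BH-corrected over classes;
    classes passing q < alpha get pairwise Wilcoxon rank sum tests between
    design cells.

    Returns ``(class_totals, class_tests, coverage)`` where ``class_tests``
    carries the KW results plus a nested list of pairwise results.
    """
    if not mapping.gene_to_ko:
        raise ValueError("empty KO mapping")
    classes = {c: [] for c in METABOLISM_CLASSES}
    unmapped = []
    for gf in gene_families.columns:
        cls = mapping.class_of(gf)
        if cls is None:
            unmapped.append(gf)
        else:
            classes[cls].append(gf)
    totals = pd.DataFrame(
        {cls: gene_families[cols].sum(axis=1) if cols else 0.0
         for cls, cols in classes.items()},
        index=gene_families.index)
    coverage = {
        "n_features": gene_families.shape[1],
        "n_mapped": gene_families.shape[1] - len(unmapped),
        "unmapped": tuple(unmapped),
    }

    md = metadata.loc[gene_families.index]
    cells = (md["group"].astype(str) + ":" + md["timepoint"].astype(str))
    records = []
    for cls in METABOLISM_CLASSES:
        vals = totals[cls].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            records.append((cls, np.nan, np.nan, "constant"))
            continue
        res = kruskal_wallis(vals, cells.to_numpy())
        records.append((cls, res.statistic, res.pvalue, res.flag))
    tests = pd.DataFrame(records, columns=["class", "H", "p", "flag"]
                         ).set_index("class")
    tested = tests["p"].notna()
    q = np.full(len(tests), np.nan)
    if tested.any():
        q[tested.to_numpy()] = bh_fdr(tests.loc[tested, "p"].to_numpy())
    tests["q"] = q
    tests["significant"] = tests["q"] < alpha

    pairwise: dict[str, list[TestResult]] = {}
    cell_labels = list(dict.fromkeys(cells))
    for cls in tests.index[tests["significant"].fillna(False)]:
        results = []
        for a in range(len(cell_labels)):
            for b in range(a + 1, len(cell_labels)):
                xa = totals.loc[cells == cell_labels[a], cls]
                xb = totals.loc[cells == cell_labels[b], cls]
                r = wilcoxon_rank_sum(xa, xb)
                r.groups = (cell_labels[a], cell_labels[b])
                results.append(r)
        ps = [r.pvalue for r in results]
        qs = bh_fdr(ps)
        for r, qv in zip(results, qs):
            r.qvalue = float(qv)
        pairwise[cls] = results
    tests.attrs["pairwise"] = pairwise
    return totals, tests, coverage
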