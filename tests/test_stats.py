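"""Shannon diversity, rank tests, the network-parameter t-test procedure,
the pathway screen and KO metabolism summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gutnet.io import KOMapping
from gutnet.stats import (kendall_tau, ko_metabolism_summary, kruskal_wallis,
                          network_param_tests, pathway_screen, shannon,
                          species_pathway_heatmap, wilcoxon_rank_sum)


class TestShannon:
    def test_uniform_is_log_k(self):
        assert shannon([25, 25, 25, 25]) == pytest.approx(np.log(4),
                                                          abs=1e-12)

    def test_single_species_zero(self):
        assert shannon([100, 0, 0]) == 0.0

    def test_half_quarter_quarter(self):
        assert shannon([0.5, 0.25, 0.25]) == pytest.approx(1.5 * np.log(2),
                                                           abs=1e-12)

    def test_all_zero_error(self):
        with pytest.raises(ValueError):
            shannon([0.0, 0.0])

    def test_base_conversion(self):
        assert shannon([1, 1], base=2) == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 100), min_size=2, max_size=30))
    def test_bounded_by_log_richness(self, vals):
        assert shannon(vals) <= np.log(len(vals)) + 1e-9


class TestRankTests:
    def test_kendall_perfect_monotone(self):
        res = kendall_tau([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.statistic == pytest.approx(1.0)

    def test_kendall_constant_flagged(self):
        res = kendall_tau([1, 1, 1], [1, 2, 3])
        assert res.flag == "constant input"
        assert res.pvalue == 1.0

    def test_wilcoxon_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = wilcoxon_rank_sum(x, list(x))
        assert res.pvalue >= 0.9

    def test_wilcoxon_shift_detected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 30)
        y = rng.normal(3, 1, 30)
        assert wilcoxon_rank_sum(x, y).pvalue < 1e-6

    def test_kruskal_separated_groups(self):
        vals = np.concatenate([np.arange(10), np.arange(10) + 100,
                               np.arange(10) + 200])
        groups = np.repeat(["a", "b", "c"], 10)
        assert kruskal_wallis(vals, groups).pvalue < 1e-4

    def test_kruskal_all_tied_flag(self):
        res = kruskal_wallis([1.0] * 9, np.repeat(["a", "b", "c"], 3))
        assert res.pvalue == 1.0
        assert res.flag == "all tied"

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 1000))
    def test_monotone_transform_invariance(self, seed):
        """Rank tests are invariant under strictly monotone transforms."""
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 15)
        y = rng.normal(0.5, 1, 15)
        before = wilcoxon_rank_sum(x, y).pvalue
        after = wilcoxon_rank_sum(np.exp(x), np.exp(y)).pvalue
        assert before == pytest.approx(after, abs=1e-12)
        t_before = kendall_tau(x, y).statistic
        t_after = kendall_tau(np.exp(x), 3 * y + 7).statistic
        assert t_before == pytest.approx(t_after, abs=1e-12)


def panel_from(groups, values, param="tc"):
    return pd.DataFrame({"group": groups, param: values})


class TestNetworkParamTests:
    def test_zero_variance_flagged(self):
        panel = panel_from(["g1"] * 3 + ["g2"] * 3,
                           [2.0, 2.0, 2.0, 1.0, 2.0, 3.0])
        out = network_param_tests(panel, {"tc": {"g1": "greater"}})
        row = out[out["group"] == "g1"].iloc[0]
        assert np.isnan(row["t"])
        assert row["flag"] == "zero within-group variance"

    def test_symmetric_case_t_zero(self):
        """Group [1,2,3] against a fitted mean of 2: t = 0, one-sided
        p = 0.5."""
        panel = panel_from(["g1"] * 3 + ["g2"] * 3,
                           [1.0, 2.0, 3.0, 3.0, 2.0, 1.0])
        out = network_param_tests(panel, {"tc": {"g1": "greater"}})
        row = out[out["group"] == "g1"].iloc[0]
        assert row["mu_hat"] == pytest.approx(2.0)
        assert row["t"] == pytest.approx(0.0, abs=1e-9)
        assert row["p"] == pytest.approx(0.5, abs=1e-9)

    def test_textbook_t_value(self):
        """Group [3,4,5] against mu = 2, alternative greater:
        t = 2*sqrt(3), df = 2, p < 0.05."""
        panel = panel_from(["g1"] * 3 + ["g2"] * 3,
                           [3.0, 4.0, 5.0, 1.0, 0.0, -1.0])
        out = network_param_tests(panel, {"tc": {"g1": "greater"}})
        row = out[out["group"] == "g1"].iloc[0]
        assert row["mu_hat"] == pytest.approx(2.0)
        assert row["t"] == pytest.approx(2 * np.sqrt(3), abs=1e-9)
        assert row["p"] < 0.05

    def test_nonfinite_rejected_unless_dropped(self):
        panel = panel_from(["g1"] * 3 + ["g2"] * 3,
                           [1.0, 2.0, np.inf, 3.0, 2.0, 1.0])
        with pytest.raises(ValueError, match="non-finite"):
            network_param_tests(panel, {})
        out = network_param_tests(panel, {}, drop_nonfinite=True)
        assert len(out) == 2


def design_metadata(n_per_cell=5):
    rows = []
    for g in ("EN", "PN_LVX_MINUS", "PN_LVX_PLUS"):
        for t in ("T0", "T1", "T2"):
            for i in range(n_per_cell):
                rows.append((f"{g}_{t}_{i}", f"{g}_p{i}", g, t))
    return pd.DataFrame(rows, columns=["sample", "patient", "group",
                                       "timepoint"]).set_index("sample")


class TestPathwayScreen:
    def test_constant_pathway_skipped(self):
        md = design_metadata()
        pw = pd.DataFrame({"flat": 1.0, "noisy": np.arange(len(md)) % 7},
                          index=md.index, dtype=float)
        out = pathway_screen(pw, md)
        assert out.loc["flat", "flag"] == "constant"
        assert not out.loc["flat", "passed"]

    def test_group_shifted_pathway_passes(self):
        md = design_metadata()
        rng = np.random.default_rng(1)
        base = rng.uniform(10, 12, len(md))
        shifted = base.copy()
        shifted[md["group"] == "PN_LVX_PLUS"] += 50
        pw = pd.DataFrame({"hit": shifted, "null": base}, index=md.index)
        out = pathway_screen(pw, md)
        assert out.loc["hit", "passed"]
        assert not out.loc["null", "passed"]

    def test_raw_p_mode(self):
        md = design_metadata()
        rng = np.random.default_rng(2)
        pw = pd.DataFrame(rng.uniform(0, 1, (len(md), 3)),
                          index=md.index, columns=["a", "b", "c"])
        out_q = pathway_screen(pw, md, use_fdr=True)
        out_p = pathway_screen(pw, md, use_fdr=False)
        assert (out_q["passed"] <= out_p["passed"].reindex(out_q.index) |
                ~out_q["passed"]).all()


class TestSpeciesPathwayHeatmap:
    def test_tau_matrix_shape_and_identity(self):
        rng = np.random.default_rng(3)
        samples = [f"S{i}" for i in range(30)]
        species = pd.DataFrame(rng.uniform(0, 10, (30, 3)), index=samples,
                               columns=["s1", "s2", "s3"])
        pathways = pd.DataFrame({"p1": species["s1"],
                                 "p2": rng.uniform(0, 10, 30)},
                                index=samples)
        mat = species_pathway_heatmap(species, pathways)
        assert mat.shape == (3, 2)
        assert mat.loc["s1", "p1"] == pytest.approx(1.0)


class TestKOMetabolism:
    def _mapping(self):
        return KOMapping(
            gene_to_ko={"gfA": "K1", "gfB": "K1", "gfC": "K2"},
            ko_to_class={"K1": "carbohydrate", "K2": "lipid"})

    def test_class_totals_additive(self):
        md = design_metadata(n_per_cell=2)
        gf = pd.DataFrame({"gfA": 100.0, "gfB": 200.0, "gfC": 50.0,
                           "gfX": 10.0}, index=md.index)
        totals, tests, coverage = ko_metabolism_summary(gf, self._mapping(),
                                                        md)
        assert (totals["carbohydrate"] == 300.0).all()
        assert (totals["lipid"] == 50.0).all()
        assert coverage["unmapped"] == ("gfX",)
        assert coverage["n_mapped"] == 3

    def test_class_totals_bounded_by_sample_total(self):
        md = design_metadata(n_per_cell=2)
        rng = np.random.default_rng(4)
        gf = pd.DataFrame(rng.uniform(0, 100, (len(md), 4)), index=md.index,
                          columns=["gfA", "gfB", "gfC", "gfX"])
        totals, _, _ = ko_metabolism_summary(gf, self._mapping(), md)
        assert (totals.sum(axis=1) <= gf.sum(axis=1) + 1e-9).all()

    def test_significant_class_gets_pairwise_tests(self):
        md = design_metadata(n_per_cell=4)
        rng = np.random.default_rng(5)
        gf = pd.DataFrame({
            "gfA": rng.uniform(10, 11, len(md)),
            "gfC": rng.uniform(10, 11, len(md)),
        }, index=md.index)
        gf.loc[md["group"] == "EN", "gfA"] += 100
        totals, tests, _ = ko_metabolism_summary(gf, self._mapping(), md)
        assert tests.loc["carbohydrate", "significant"]
        pairwise = tests.attrs["pairwise"]["carbohydrate"]
        assert len(pairwise) == 36  # C(9, 2) design-cell pairs
        assert all(r.qvalue is not None for r in pairwise)

    def test_empty_mapping_rejected(self):
        md = design_metadata(n_per_cell=2)
        gf = pd.DataFrame({"gfA": 1.0}, index=md.index)
        with pytest.raises(ValueError, match="empty"):
            ko_metabolism_summary(gf, KOMapping({}, {}), md)
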