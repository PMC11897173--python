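"""Normalization, DE calling, profiles, breadth and the association test."""

import numpy as np
import pandas as pd
import pytest

from ganopan.expression import (
    ExpressionStudy, call_de, category_expression_profile, expression_breadth,
    homolog_counts, single_copy_homologs, sporulation_ratio,
    sv_deg_association,
)
from ganopan.io_formats import OrthogroupTable
from _oracles import bh_stepup, chi2_2x2_corrected, kruskal_wallis, welch_p


def make_study(counts: dict, genomes=None, tissue="mycelium"):
    df = pd.DataFrame(counts)
    rows = []
    for i, s in enumerate(df.columns):
        rows.append({"sample_id": s,
                     "genome_id": (genomes or {}).get(s, "S1"),
                     "tissue": tissue, "replicate": i + 1})
    sheet = pd.DataFrame(rows).set_index("sample_id", drop=False)
    return ExpressionStudy(df, sheet)


class TestNormalize:
    def test_single_gene_cpm(self):
        st = make_study({"a": [10], "b": [3]}, )
        cpm = st.cpm()
        assert (cpm.loc[cpm.index[0]] == 1e6).all()

    def test_two_gene_split(self):
        st = make_study({"a": [10, 30]})
        np.testing.assert_allclose(st.cpm()["a"], [2.5e5, 7.5e5])

    def test_column_sums_are_1e6(self):
        rng = np.random.default_rng(0)
        st = make_study({f"s{i}": rng.integers(0, 500, 50) for i in range(6)})
        np.testing.assert_allclose(st.cpm().sum(axis=0), 1e6)

    def test_zero_total_sample_excluded(self, caplog):
        st = make_study({"a": [5, 5], "dead": [0, 0]})
        with caplog.at_level("WARNING", logger="ganopan"):
            cpm = st.cpm()
        assert "dead" not in cpm.columns

    def test_tpm_column_sums(self):
        st = make_study({f"s{i}": [10, 20, 30] for i in range(3)})
        st.counts.index = ["g1", "g2", "g3"]
        tpm = st.tpm({"g1": 100, "g2": 1000, "g3": 250})
        np.testing.assert_allclose(tpm.sum(axis=0), 1e6)


class TestCallDe:
    def _study(self, a_counts, b_counts):
        data = {}
        for i, col in enumerate(a_counts.T):
            data[f"a{i}"] = col
        for i, col in enumerate(b_counts.T):
            data[f"b{i}"] = col
        return make_study(data)

    def test_identical_groups_null(self):
        c = np.array([[100, 100, 100, 100]] * 3)
        st = self._study(c, c)
        res = call_de(st, ["a0", "a1", "a2", "a3"], ["b0", "b1", "b2", "b3"])
        assert (res.log2_fold_change == 0).all()
        assert not res.is_deg.any()

    def test_fold_change_closed_form_and_independent_p(self):
        """Group means 80 vs 10 CPM with tight replicates: log2FC matches
        log2(80.5/10.5) and the p-value matches an independent Welch
        evaluation via the incomplete beta function."""
        rng = np.random.default_rng(3)
        n_genes, n_rep = 40, 4
        base = rng.integers(50, 2000, size=n_genes)
        a = np.array([base * 4 + rng.integers(-5, 6, n_genes)
                      for _ in range(n_rep)]).T
        b = np.array([base + rng.integers(-5, 6, n_genes)
                      for _ in range(n_rep)]).T
        # plant the 80-vs-10 gene on top of a stable background
        st = self._study(a, b)
        cpm = st.cpm()
        ga, gb = [f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)]
        res = call_de(st, ga, gb)
        for gene in res.index:
            ma = cpm.loc[gene, ga].mean()
            mb = cpm.loc[gene, gb].mean()
            assert res.loc[gene, "log2_fold_change"] == pytest.approx(
                np.log2((ma + 0.5) / (mb + 0.5)))
            p_ref = welch_p(np.log2(cpm.loc[gene, ga] + 0.5),
                            np.log2(cpm.loc[gene, gb] + 0.5))
            assert res.loc[gene, "p_value"] == pytest.approx(p_ref, abs=1e-10)

    def test_explicit_mean_ratio(self):
        # constant library depth so CPM equals a fixed scaling of counts
        a = np.tile([[80], [920]], (1, 4))
        b = np.tile([[10], [990]], (1, 4))
        st = self._study(a, b)
        res = call_de(st, [f"a{i}" for i in range(4)],
                      [f"b{i}" for i in range(4)])
        ma, mb = 80 / 1000 * 1e6, 10 / 1000 * 1e6
        assert res.iloc[0]["log2_fold_change"] == pytest.approx(
            np.log2((ma + 0.5) / (mb + 0.5)))

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 300, (30, 4))
        b = rng.integers(0, 300, (30, 4))
        st = self._study(a, b)
        ga, gb = [f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)]
        fwd = call_de(st, ga, gb)
        rev = call_de(st, gb, ga)
        np.testing.assert_allclose(fwd.log2_fold_change, -rev.log2_fold_change)
        np.testing.assert_allclose(fwd.p_value, rev.p_value)

    def test_requires_two_replicates(self):
        st = make_study({"a0": [1], "a1": [2], "b0": [3]})
        with pytest.raises(ValueError, match="replicates"):
            call_de(st, ["a0", "a1"], ["b0"])

    def test_bh_hand_computed_example(self):
        """BH on (0.01, 0.02, 0.03, 0.04) at m=4 gives 0.04 everywhere."""
        assert bh_stepup([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_bh_matches_stepup_oracle_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(1)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(
                multipletests(p, method="fdr_bh")[1], bh_stepup(p),
                atol=1e-12)


class TestCategoryProfile:
    def test_degenerate_identical_expression(self):
        st = make_study({f"s{i}": [50, 50, 50, 50] for i in range(4)})
        st.counts.index = ["g1", "g2", "g3", "g4"]
        cats = {"g1": "core", "g2": "softcore", "g3": "dispensable",
                "g4": "private"}
        prof, stat, p = category_expression_profile(st, cats, "mycelium")
        assert stat == 0.0 and p == 1.0

    def test_separated_two_groups_match_rank_oracle(self):
        rng = np.random.default_rng(4)
        genes = [f"c{i}" for i in range(5)] + [f"p{i}" for i in range(5)]
        data = {}
        for s in range(4):
            col = list(rng.integers(800, 1000, 5)) + list(rng.integers(1, 50, 5))
            data[f"s{s}"] = col
        st = make_study(data)
        st.counts.index = genes
        cats = {g: ("core" if g.startswith("c") else "private") for g in genes}
        prof, stat, p = category_expression_profile(st, cats, "mycelium")
        mean_cpm = st.cpm().mean(axis=1)
        h_ref, p_ref = kruskal_wallis([
            mean_cpm[[g for g in genes if g.startswith("c")]].tolist(),
            mean_cpm[[g for g in genes if g.startswith("p")]].tolist()])
        assert stat == pytest.approx(h_ref)
        assert p == pytest.approx(p_ref)

    def test_planted_ordering_recovered_in_medians(self):
        rng = np.random.default_rng(6)
        means = {"core": 800, "softcore": 400, "dispensable": 200,
                 "private": 100}
        genes, cats = [], {}
        rows = []
        for cat, m in means.items():
            for i in range(30):
                g = f"{cat}{i}"
                genes.append(g)
                cats[g] = cat
                rows.append(rng.poisson(m, 4))
        data = {f"s{j}": [row[j] for row in rows] for j in range(4)}
        st = make_study(data)
        st.counts.index = genes
        prof, _, p = category_expression_profile(st, cats, "mycelium")
        med = dict(zip(prof.category, prof["median"]))
        assert med["core"] > med["softcore"] > med["dispensable"] > med["private"]
        assert p < 0.001


class TestHomologs:
    TABLES = [
        OrthogroupTable("f1", {"S1": ["a1"], "S2": ["b1"]}),
        OrthogroupTable("f2", {"S1": ["a2", "a3"], "S2": ["b2"]}),
        OrthogroupTable("f3", {"S1": ["a4"], "S2": []}),
    ]

    def test_single_copy_selection(self):
        hom = single_copy_homologs(self.TABLES, ["S1", "S2"])
        assert set(hom) == {"f1"}
        assert hom["f1"] == {"S1": "a1", "S2": "b1"}

    def test_homolog_counts_collapse(self):
        counts = pd.DataFrame({"x1": [7, 1], "y1": [0, 9]},
                              index=["a1", "b1"])
        sheet = pd.DataFrame({
            "sample_id": ["x1", "y1"], "genome_id": ["S1", "S2"],
            "tissue": ["mycelium"] * 2, "replicate": [1, 1],
        }).set_index("sample_id", drop=False)
        hc = homolog_counts(counts, {"f1": {"S1": "a1", "S2": "b1"}}, sheet)
        assert hc.loc["f1", "x1"] == 7 and hc.loc["f1", "y1"] == 9


class TestBreadth:
    def test_extremes_and_threshold(self):
        data = {}
        genomes = {}
        for g_i, genome in enumerate(["S1", "S2", "S3"]):
            s = f"{genome}_m_1"
            # gene rows: hi expressed in every genome, lo in none
            data[s] = [1000 if i == g_i else 0 for i in range(3)] + [0, 0, 0]
            genomes[s] = genome
        df = pd.DataFrame(data, index=["h1", "h2", "h3", "l1", "l2", "l3"])
        sheet = pd.DataFrame([
            {"sample_id": s, "genome_id": g, "tissue": "mycelium", "replicate": 1}
            for s, g in genomes.items()]).set_index("sample_id", drop=False)
        st = ExpressionStudy(df, sheet)
        hom = {"hi": {"S1": "h1", "S2": "h2", "S3": "h3"},
               "lo": {"S1": "l1", "S2": "l2", "S3": "l3"}}
        b = expression_breadth(st, hom, "mycelium", threshold=1.0)
        assert b["hi"] == 3 and b["lo"] == 0

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            expression_breadth(None, {}, "mycelium", threshold=0)


class TestAssociation:
    def _flags(self, table):
        deg, sv = {}, {}
        i = 0
        for sv_f, deg_f, n in [(True, True, table[0][0]),
                               (True, False, table[0][1]),
                               (False, True, table[1][0]),
                               (False, False, table[1][1])]:
            for _ in range(n):
                deg[f"g{i}"] = deg_f
                sv[f"g{i}"] = sv_f
                i += 1
        return deg, sv

    def test_fixed_table_matches_closed_form(self):
        deg, sv = self._flags([[30, 70], [10, 190]])
        res = sv_deg_association(deg, sv)
        assert res.deg_proportion_sv == pytest.approx(0.30)
        assert res.deg_proportion_no_sv == pytest.approx(0.05)
        stat_ref, p_ref = chi2_2x2_corrected([[30, 70], [10, 190]])
        assert res.statistic == pytest.approx(stat_ref)
        assert res.p_value == pytest.approx(p_ref)
        assert res.method == "chi2"

    def test_equal_proportions_not_significant(self):
        deg, sv = self._flags([[20, 80], [20, 80]])
        res = sv_deg_association(deg, sv)
        assert res.p_value > 0.9

    def test_zero_margin_falls_back_to_fisher(self):
        deg, sv = self._flags([[0, 50], [0, 150]])
        res = sv_deg_association(deg, sv)
        assert res.method == "fisher"
        assert res.p_value == 1.0

    def test_mismatched_keys_rejected(self):
        with pytest.raises(ValueError):
            sv_deg_association({"a": True}, {"b": True})


class TestSporulation:
    @pytest.mark.parametrize("spore,dry,expected", [
        (50, 100, 50.0), (3.5, 3.5, 100.0), (1, 4, 25.0),
    ])
    def test_ratio(self, spore, dry, expected):
        assert sporulation_ratio(spore, dry) == pytest.approx(expected)

    def test_unmeasurable_yield_rejected(self):
        with pytest.raises(ValueError):
            sporulation_ratio(0.0, 100)
        with pytest.raises(ValueError):
            sporulation_ratio(10, 0.0)
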