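import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from holosel import (
    GeneCountMatrix,
    MGSCatalog,
    cliffs_delta,
    diff_abundance,
    enrich_pathways,
    generate_shotgun_fixture,
    ko_abundance,
    mgs_abundance,
    taxon_rollup,
)
from holosel.abundance import AbundanceTable


def _genes(counts: dict, lengths: dict) -> GeneCountMatrix:
    return GeneCountMatrix(pd.DataFrame(counts).T, pd.Series(lengths))


def _feature_table(df: pd.DataFrame) -> AbundanceTable:
    t = AbundanceTable.__new__(AbundanceTable)
    t.data = df
    t.kind = "relative"
    return t


class TestMgsAbundance:
    def _catalog_100(self):
        return MGSCatalog(markers={"mspA": [f"g{i}" for i in range(100)]})

    def _matrix(self, nonzero, value=1000):
        counts = {f"g{i}": {"s1": value if i < nonzero else 0} for i in range(100)}
        lengths = {f"g{i}": 1000.0 for i in range(100)}
        return _genes(counts, lengths)

    def test_below_ten_percent_is_null(self):
        out = mgs_abundance(self._matrix(nonzero=5), self._catalog_100())
        assert out.data.loc["s1", "mspA"] == 0.0

    def test_all_markers_equal_gives_that_value(self):
        out = mgs_abundance(self._matrix(nonzero=100), self._catalog_100())
        assert out.data.loc["s1", "mspA"] == pytest.approx(1000.0)

    def test_twenty_percent_mean_includes_zeros(self):
        out = mgs_abundance(self._matrix(nonzero=20, value=1000), self._catalog_100())
        assert out.data.loc["s1", "mspA"] == pytest.approx(200.0)

    def test_length_normalization(self):
        genes = _genes(
            {"g0": {"s1": 100}, "g1": {"s1": 100}},
            {"g0": 1000.0, "g1": 2000.0},
        )
        cat = MGSCatalog(markers={"m": ["g0", "g1"]})
        # 100/1kb and 100/2kb -> mean of (100, 50)
        assert mgs_abundance(genes, cat, min_marker_frac=0).data.loc["s1", "m"] == pytest.approx(75.0)

    def test_homogeneous_in_total_counts(self):
        rng = np.random.default_rng(0)
        counts = {f"g{i}": {"s1": int(rng.integers(0, 50))} for i in range(20)}
        lengths = {f"g{i}": float(rng.integers(500, 3000)) for i in range(20)}
        cat = MGSCatalog(markers={"m": list(counts)})
        a = mgs_abundance(_genes(counts, lengths), cat).data.loc["s1", "m"]
        scaled = {g: {"s1": 3 * v["s1"]} for g, v in counts.items()}
        b = mgs_abundance(_genes(scaled, lengths), cat).data.loc["s1", "m"]
        assert b == pytest.approx(3 * a)

    def test_empty_marker_list_rejected(self):
        with pytest.raises(ValueError):
            MGSCatalog(markers={"m": []})

    def test_unknown_marker_gene_raises(self):
        genes = _genes({"g0": {"s1": 1}}, {"g0": 100.0})
        with pytest.raises(KeyError):
            mgs_abundance(genes, MGSCatalog(markers={"m": ["nope"]}))


class TestRollups:
    def test_taxon_rollup_sums(self):
        mgs = _feature_table(pd.DataFrame({"m1": [3.0], "m2": [4.0], "m3": [5.0]}, index=["s1"]))
        lineage = pd.DataFrame({"genus": ["A", "A", "B"]}, index=["m1", "m2", "m3"])
        cat = MGSCatalog(markers={"m1": ["x"]}, lineage=lineage)
        out = taxon_rollup(mgs, cat, rank="genus")
        assert out.data.loc["s1", "A"] == pytest.approx(7.0)
        assert out.data.loc["s1", "B"] == pytest.approx(5.0)
        assert out.data.sum(axis=1).iloc[0] == pytest.approx(12.0)

    def test_rollup_matches_groupby_oracle(self):
        rng = np.random.default_rng(1)
        mgs = _feature_table(pd.DataFrame(
            rng.uniform(0, 10, size=(4, 5)), columns=[f"m{i}" for i in range(5)]))
        genera = ["A", "B", "A", "B", "A"]
        lineage = pd.DataFrame({"genus": genera}, index=mgs.data.columns)
        cat = MGSCatalog(markers={"m0": ["x"]}, lineage=lineage)
        out = taxon_rollup(mgs, cat, rank="genus")
        oracle = mgs.data.T.groupby(pd.Series(genera, index=mgs.data.columns)).sum().T
        pd.testing.assert_frame_equal(out.data, oracle, check_names=False)

    def test_unknown_rank(self):
        mgs = _feature_table(pd.DataFrame({"m1": [1.0]}))
        cat = MGSCatalog(markers={"m1": ["x"]}, lineage=pd.DataFrame({"genus": ["A"]}, index=["m1"]))
        with pytest.raises(KeyError):
            taxon_rollup(mgs, cat, rank="species")

    def test_ko_abundance_sums_and_skips_unmapped(self):
        genes = _genes(
            {"g0": {"s1": 100}, "g1": {"s1": 200}, "g2": {"s1": 50}},
            {"g0": 1000.0, "g1": 1000.0, "g2": 1000.0},
        )
        cat = MGSCatalog(markers={"m": ["g0"]},
                         gene2ko=pd.Series({"g0": "K1", "g1": "K1"}))
        out = ko_abundance(genes, cat)
        assert out.data.loc["s1", "K1"] == pytest.approx(300.0)
        assert list(out.data.columns) == ["K1"]


class TestCliffsDelta:
    @pytest.mark.parametrize("x,y,expected", [
        ([1, 2, 3], [4, 5, 6], -1.0),
        ([1, 2, 2, 3], [1, 2, 2, 3], 0.0),
        ([1, 2, 3, 4], [2, 3], 0.0),
    ])
    def test_known_values(self, x, y, expected):
        assert cliffs_delta(x, y) == pytest.approx(expected)

    def test_matches_pair_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.integers(0, 10, size=rng.integers(1, 8)).astype(float)
            y = rng.integers(0, 10, size=rng.integers(1, 8)).astype(float)
            gt = sum(1 for a, b in itertools.product(x, y) if a > b)
            lt = sum(1 for a, b in itertools.product(x, y) if a < b)
            assert cliffs_delta(x, y) == pytest.approx((gt - lt) / (len(x) * len(y)))

    def test_antisymmetry_and_monotone_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=6), rng.normal(size=9)
        assert cliffs_delta(x, y) == pytest.approx(-cliffs_delta(y, x))
        assert cliffs_delta(np.exp(x), np.exp(y)) == pytest.approx(cliffs_delta(x, y))

    def test_empty_group(self):
        with pytest.raises(ValueError):
            cliffs_delta([], [1.0])


class TestDiffAbundance:
    def test_bh_hand_worked_example(self):
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")
        assert np.allclose(q, 0.04)

    def test_wilcoxon_matches_exact_enumeration(self):
        # exact rank-sum tail by enumeration for small untied samples
        x = np.array([1.3, 2.7, 0.4, 5.1])
        y = np.array([3.3, 4.9, 6.2, 2.1, 7.7])
        obs = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        obs_stat = ranks[:4].sum()
        n = len(pooled)
        stats_all = np.array([ranks[list(c)].sum() for c in itertools.combinations(range(n), 4)])
        mu = stats_all.mean()
        p_enum = np.mean(np.abs(stats_all - mu) >= abs(obs_stat - mu) - 1e-9)
        assert obs == pytest.approx(p_enum, abs=1e-10)

    def test_global_null_bh_control(self):
        rng = np.random.default_rng(5)
        n_feat, n = 200, 15
        df = pd.DataFrame(rng.lognormal(size=(2 * n, n_feat)),
                          index=[f"s{i}" for i in range(2 * n)],
                          columns=[f"f{i}" for i in range(n_feat)])
        groups = pd.Series(["PM"] * n + ["RT"] * n, index=df.index)
        res = diff_abundance(_feature_table(df), groups, relative=False)
        assert (res["q"] < 0.1).mean() < 0.02

    def test_planted_recovery_with_signs(self):
        genes, cat, truth = generate_shotgun_fixture(n_mgs=30, markers_per_mgs=50, seed=6)
        mgs = mgs_abundance(genes, cat)
        res = diff_abundance(mgs, truth["groups"]).set_index("feature")
        pm_called = set(res.index[res["enriched_in"] == "PM"])
        rt_called = set(res.index[res["enriched_in"] == "RT"])
        assert len(pm_called & set(truth["planted_pm"])) >= 10
        assert len(rt_called & set(truth["planted_rt"])) >= 10
        assert not pm_called & set(truth["planted_rt"])
        assert not rt_called & set(truth["planted_pm"])

    def test_constant_feature_flagged_p_one(self):
        df = pd.DataFrame({"const": [2.0] * 8, "varies": [1, 2, 3, 4, 5, 6, 7, 8.0]},
                          index=[f"s{i}" for i in range(8)])
        groups = pd.Series(["PM"] * 4 + ["RT"] * 4, index=df.index)
        res = diff_abundance(_feature_table(df), groups, relative=False).set_index("feature")
        assert res.loc["const", "p"] == 1.0

    def test_q_at_least_p(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.lognormal(size=(10, 30)), index=[f"s{i}" for i in range(10)])
        df.columns = [f"f{i}" for i in range(30)]
        groups = pd.Series(["PM"] * 5 + ["RT"] * 5, index=df.index)
        res = diff_abundance(_feature_table(df), groups, relative=False)
        assert (res["q"] >= res["p"] - 1e-12).all()


class TestEnrichPathways:
    def test_pathway_equal_background_p_one(self):
        bg = [f"K{i}" for i in range(10)]
        out = enrich_pathways(bg[:3], bg, {"all": bg}, p_max=1.1)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_closed_form_tail(self):
        # all 5 hits inside a 5-member pathway of a 20-KO background
        bg = [f"K{i}" for i in range(20)]
        out = enrich_pathways(bg[:5], bg, {"target": bg[:5]}, p_max=0.05)
        assert out["p"].iloc[0] == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_pathway_without_hits_absent(self):
        bg = [f"K{i}" for i in range(10)]
        out = enrich_pathways(bg[:2], bg, {"hit": bg[:2], "miss": bg[5:]}, p_max=1.1)
        assert "miss" not in set(out["pathway"])

    def test_hits_outside_background_rejected(self):
        with pytest.raises(ValueError):
            enrich_pathways(["K99"], ["K1"], {"p": ["K1"]})

    def test_matches_scipy_survival(self):
        bg = [f"K{i}" for i in range(50)]
        hits = bg[:10]
        pathway = bg[5:20]
        out = enrich_pathways(hits, bg, {"pw": pathway}, p_max=1.1)
        k = len(set(hits) & set(pathway))
        expected = stats.hypergeom.sf(k - 1, 50, len(pathway), 10)
        assert out["p"].iloc[0] == pytest.approx(expected, rel=1e-12)
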