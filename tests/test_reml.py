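import numpy as np
import pandas as pd
import pytest

from holosel import (
    GeneticArchitecture,
    Pedigree,
    bivariate_reml,
    generate_study_phenotypes,
    heritability_binary,
    precorrect_batch,
    reml_fit,
)
from holosel.reml import ai_reml
from holosel.selection import TRAITS


def _half_sib_design(n_sires=80, n_off=6, h2=0.3, seed=0):
    """Balanced half-sib design: unrelated sires, unrelated dams, one offspring
    per dam, no litter sharing."""
    rng = np.random.default_rng(seed)
    rows, pheno = [], []
    sa, sw = np.sqrt(h2), np.sqrt(1 - h2)
    for s in range(n_sires):
        sire = f"S{s:03d}"
        rows.append((sire, "0", "0"))
        bv_s = rng.normal(0, sa)
        for o in range(n_off):
            dam = f"D{s:03d}_{o}"
            rows.append((dam, "0", "0"))
            bv_d = rng.normal(0, sa)
            kid = f"K{s:03d}_{o}"
            rows.append((kid, sire, dam))
            bv = 0.5 * (bv_s + bv_d) + rng.normal(0, np.sqrt(0.5) * sa)
            y = bv + rng.normal(0, sw)
            pheno.append({"animal": kid, "sire_grp": sire, "y": y})
    ped = Pedigree(pd.DataFrame(rows, columns=["animal", "sire", "dam"]))
    return ped, pd.DataFrame(pheno)


def sire_anova_h2(pheno: pd.DataFrame) -> float:
    """Closed-form sire-model ANOVA estimator 4*sigma2_s/(sigma2_s+sigma2_w)."""
    groups = [g["y"].to_numpy() for _, g in pheno.groupby("sire_grp")]
    k = len(groups[0])
    means = np.array([g.mean() for g in groups])
    msb = k * means.var(ddof=1)
    msw = np.mean([g.var(ddof=1) for g in groups])
    s2s = max((msb - msw) / k, 0.0)
    return 4 * s2s / (s2s + msw)


class TestUnivariateREML:
    def test_null_architecture_boundary(self):
        ped, pheno = _half_sib_design(n_sires=100, n_off=10, h2=0.0, seed=1)
        fit = reml_fit(pheno, ped, "y", fixed=(), litter=None)
        assert fit.h2 <= 0.05

    def test_matches_sire_anova_oracle(self):
        ped, pheno = _half_sib_design(n_sires=80, n_off=6, h2=0.3, seed=2)
        fit = reml_fit(pheno, ped, "y", fixed=(), litter=None)
        anova = sire_anova_h2(pheno)
        # balanced one-way design: REML coincides with the ANOVA estimator
        assert fit.h2 == pytest.approx(anova, abs=0.02)

    def test_affine_invariance(self, study_population):
        ped, data = study_population
        base = reml_fit(data, ped, "prevotella")
        scaled = data.copy()
        scaled["prevotella"] = 10.0 * scaled["prevotella"] + 3.0
        other = reml_fit(scaled, ped, "prevotella")
        assert other.h2 == pytest.approx(base.h2, abs=1e-4)
        assert other.c2 == pytest.approx(base.c2, abs=1e-4)
        assert other.sigma2_a == pytest.approx(100.0 * base.sigma2_a, rel=1e-3)

    def test_loglik_nondecreasing(self):
        ped, pheno = _half_sib_design(n_sires=40, n_off=5, h2=0.3, seed=3)
        from holosel.pedigree import a_matrix

        A = a_matrix(ped).loc[pheno["animal"], pheno["animal"]].to_numpy()
        y = pheno["y"].to_numpy()
        X = np.ones((len(y), 1))
        trace: list = []
        ai_reml(y, X, [A, np.eye(len(y))], ll_trace=trace)
        diffs = np.diff(trace)
        assert (diffs >= -1e-7).all()

    def test_recovery_on_study_design(self):
        """Replicate-mean estimates on the simulated study design recover the
        generating h2 = 0.3 (default architecture) within 3 Monte-Carlo SEs."""
        ests, c2s = [], []
        for seed in range(780, 785):
            ped, data = generate_study_phenotypes(seed=seed)
            fit = reml_fit(data, ped, "treponema")
            ests.append(fit.h2)
            c2s.append(fit.c2)
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert np.mean(ests) == pytest.approx(0.3, abs=max(3 * mc_se, 0.1))
        assert np.mean(c2s) < 0.25

    def test_recovery_grid(self):
        """Mean bias below 3 Monte-Carlo SEs across an h2 x c2 grid (scaled-down
        replicate count; the study-size run lives in the acceptance suite)."""
        for h2, c2 in [(0.1, 0.0), (0.5, 0.1)]:
            arch = GeneticArchitecture(
                h2={**{t: 0.3 for t in TRAITS}, "prevotella": h2},
                c2={t: c2 for t in TRAITS},
            )
            ests = []
            for rep in range(4):
                ped, data = generate_study_phenotypes(arch=arch, seed=900 + 10 * rep)
                ests.append(reml_fit(data, ped, "prevotella").h2)
            mc_se = np.std(ests, ddof=1) / 2
            assert np.mean(ests) == pytest.approx(h2, abs=max(3 * mc_se, 0.08))

    def test_requires_two_litters(self):
        ped, pheno = _half_sib_design(n_sires=10, n_off=3, seed=4)
        pheno["litter"] = "L1"
        with pytest.raises(ValueError, match="litter"):
            reml_fit(pheno, ped, "y", fixed=(), litter="litter")


class TestBivariateREML:
    def test_duplicated_trait_gives_rg_one(self, study_population):
        ped, data = study_population
        d = data.copy()
        d["dup"] = d["prevotella"]
        fit = bivariate_reml(d, ped, "prevotella", "dup", compute_se=False)
        assert fit.rG == pytest.approx(1.0, abs=0.02)

    def test_independent_traits_rg_near_zero(self):
        arch = GeneticArchitecture(
            c2={t: 0.0 for t in TRAITS},
            loadings={**{t: 0.0 for t in TRAITS}, "treponema": -0.9},
        )
        ests = []
        for rep in range(4):
            ped, data = generate_study_phenotypes(arch=arch, seed=500 + rep)
            ests.append(bivariate_reml(data, ped, "prevotella", "adg", compute_se=False).rG)
        assert abs(np.mean(ests)) < 0.25

    def test_eigen_and_dense_paths_agree(self):
        """The eigendecomposition shortcut and the generic dense AI-REML are
        two implementations of the same model; they must agree."""
        from holosel.pedigree import a_matrix
        from holosel.reml import _bivariate_dense

        ped, pheno = _half_sib_design(n_sires=25, n_off=4, h2=0.4, seed=6)
        rng = np.random.default_rng(6)
        pheno["y2"] = 0.6 * pheno["y"] + rng.normal(0, 0.8, size=len(pheno))
        fast = bivariate_reml(pheno, ped, "y", "y2", fixed=(), compute_se=False)
        A = a_matrix(ped).loc[pheno["animal"], pheno["animal"]].to_numpy()
        X = np.ones((len(pheno), 1))
        ya = pheno["y"].to_numpy() / np.std(pheno["y"].to_numpy())
        yb = pheno["y2"].to_numpy() / np.std(pheno["y2"].to_numpy())
        dense = _bivariate_dense(pheno, ya, yb, X, A)
        assert dense.rG == pytest.approx(fast.rG, abs=0.02)
        assert dense.loglik == pytest.approx(fast.loglik, abs=0.05)

    def test_rg_se_reported(self, study_population):
        ped, data = study_population
        fit = bivariate_reml(data, ped, "prevotella", "adg", compute_se=True)
        assert fit.rG_se is None or 0.0 < fit.rG_se < 1.0


class TestBinaryHeritability:
    def test_random_labels_near_zero(self, study_population):
        ped, data = study_population
        rng = np.random.default_rng(0)
        d = data.copy()
        d["coin"] = rng.integers(0, 2, size=len(d)).astype(float)
        fit = heritability_binary(d, ped, "coin")
        assert fit.h2 < 0.08

    def test_litter_only_labels(self, study_population):
        # labels constant within litters, random across litters: c2 large, h2 small
        ped, data = study_population
        rng = np.random.default_rng(1)
        litters = data["litter"].unique()
        lab = dict(zip(litters, rng.integers(0, 2, size=len(litters))))
        d = data.copy()
        d["lit_label"] = d["litter"].map(lab).astype(float)
        fit = heritability_binary(d, ped, "lit_label")
        assert fit.c2 > 0.5
        assert fit.h2 < 0.25

    def test_single_class_raises(self, study_population):
        ped, data = study_population
        d = data.copy()
        d["ones"] = 1.0
        with pytest.raises(ValueError, match="single class"):
            heritability_binary(d, ped, "ones")

    def test_liability_conversion_reported(self, study_population):
        ped, data = study_population
        fit = heritability_binary(data, ped, "enterotype01")
        assert 0 < fit.extra["prevalence"] < 1
        assert np.isfinite(fit.extra["h2_liability"])
        # the architecture sets liability h2 = 0.3; observed-scale estimate is
        # in the moderate range
        assert 0.05 < fit.h2 < 0.6


class TestPrecorrectBatch:
    def test_removes_batch_means(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "batch": np.repeat(["a", "b"], 50),
            "y": np.concatenate([rng.normal(5, 1, 50), rng.normal(-5, 1, 50)]),
        })
        resid = precorrect_batch(df, "y")
        assert abs(resid[:50].mean()) < 1e-10
        assert abs(resid[50:].mean()) < 1e-10
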