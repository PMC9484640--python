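import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from rwas.properties import (PropertyModel, PropertyModelSpec, SetModel,
                             adjust_pvalues, attribute_group_test,
                             bonferroni_threshold, fit_property, fit_set,
                             gls_correlation, meta_max_z)


def make_assoc(z, n_snps=None, ids=None):
    n = len(z)
    return pd.DataFrame({
        "enhancer_id": ids if ids is not None else [f"e{i}" for i in range(n)],
        "chrom": "chr1", "start": np.arange(n) * 2000,
        "end": np.arange(n) * 2000 + 1000,
        "n_snps": n_snps if n_snps is not None else np.full(n, 5),
        "stat": 1.0, "p": 0.5, "z": z,
    })


class TestFitProperty:
    def test_recovers_planted_slope(self):
        rng = np.random.default_rng(0)
        c = rng.normal(size=500)
        z = 2.0 * c + rng.normal(scale=0.1, size=500)
        assoc = make_assoc(z)
        cov = pd.DataFrame({"c": c}, index=pd.Index(assoc["enhancer_id"], name="id"))
        res = fit_property(assoc, cov)
        row = res.iloc[0]
        assert 1.98 <= row["beta"] <= 2.02
        assert row["p"] < 1e-10

    def test_null_calibration(self):
        rng = np.random.default_rng(1)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            z = rng.normal(size=120)
            c = rng.normal(size=120)
            assoc = make_assoc(z, n_snps=rng.integers(1, 10, 120))
            cov = pd.DataFrame({"c": c},
                               index=pd.Index(assoc["enhancer_id"], name="id"))
            hits += fit_property(assoc, cov).iloc[0]["p"] < 0.05
        # 99% binomial CI around 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(hits / n_rep - 0.05) < 2.576 * se + 1e-9

    def test_constant_covariate_rejected(self):
        assoc = make_assoc(np.random.default_rng(2).normal(size=50))
        cov = pd.DataFrame({"c": np.ones(50)},
                           index=pd.Index(assoc["enhancer_id"], name="id"))
        with pytest.raises(ValueError, match="zero variance"):
            fit_property(assoc, cov)

    def test_collinear_with_confounders_rejected(self):
        rng = np.random.default_rng(3)
        n_snps = rng.integers(1, 20, 100)
        assoc = make_assoc(rng.normal(size=100), n_snps=n_snps)
        cov = pd.DataFrame({"c": n_snps.astype(float)},
                           index=pd.Index(assoc["enhancer_id"], name="id"))
        with pytest.raises(ValueError, match="collinear"):
            fit_property(assoc, cov)

    def test_listwise_deletion_counted(self):
        rng = np.random.default_rng(4)
        assoc = make_assoc(rng.normal(size=100))
        c = rng.normal(size=100)
        c[:10] = np.nan
        cov = pd.DataFrame({"c": c}, index=pd.Index(assoc["enhancer_id"], name="id"))
        res = fit_property(assoc, cov)
        assert res.iloc[0]["n_used"] == 90

    def test_footprint_total_control(self):
        # covariate effect disappears once the total column is conditioned on
        rng = np.random.default_rng(5)
        total = rng.poisson(20, size=400).astype(float)
        m1 = rng.binomial(total.astype(int), 0.3).astype(float)
        z = 0.1 * total + rng.normal(size=400)
        assoc = make_assoc(z)
        cov = pd.DataFrame({"m1": m1, "total": total},
                           index=pd.Index(assoc["enhancer_id"], name="id"))
        spec = PropertyModelSpec(covariates=("m1",), extra_controls=("total",))
        p_ctrl = fit_property(assoc, cov, spec).iloc[0]["p"]
        spec_no = PropertyModelSpec(covariates=("m1",))
        p_raw = fit_property(assoc, cov[["m1"]], spec_no).iloc[0]["p"]
        assert p_raw < 1e-4 < p_ctrl


class TestFitSet:
    def test_top_half_membership_significant(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=300)
        assoc = make_assoc(z)
        member = pd.Series((z > np.median(z)).astype(int),
                           index=pd.Index(assoc["enhancer_id"], name="id"))
        res = fit_set(assoc, member)
        assert res["p"] < 1e-10 and res["beta"] > 0

    def test_random_membership_null(self):
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(200):
            z = rng.normal(size=100)
            assoc = make_assoc(z)
            member = pd.Series(rng.integers(0, 2, 100),
                               index=pd.Index(assoc["enhancer_id"], name="id"))
            ps.append(fit_set(assoc, member)["p"])
        frac = np.mean(np.array(ps) < 0.05)
        assert abs(frac - 0.05) < 2.576 * np.sqrt(0.05 * 0.95 / 200) + 1e-9

    def test_degenerate_membership_rejected(self):
        assoc = make_assoc(np.random.default_rng(2).normal(size=50))
        member = pd.Series(1, index=pd.Index(assoc["enhancer_id"], name="id"))
        with pytest.raises(ValueError):
            fit_set(assoc, member)

    def test_set_sizes_reported(self):
        rng = np.random.default_rng(3)
        assoc = make_assoc(rng.normal(size=100))
        member = pd.Series(([1] * 30 + [0] * 70),
                           index=pd.Index(assoc["enhancer_id"], name="id"))
        res = fit_set(assoc, member, name="mySet")
        assert res["set"] == "mySet"
        assert 0 < res["set_size"] < res["background_size"]


class TestGlsCorrelation:
    def _panel(self, X):
        from rwas.region import ReferencePanel

        return ReferencePanel(X, [f"s{i}" for i in range(X.shape[1])])

    def test_disjoint_ld_near_zero(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, size=(500, 4)).astype(float)
        C = gls_correlation({"a": ["s0", "s1"], "b": ["s2", "s3"]},
                            self._panel(X))
        assert abs(C.loc["a", "b"]) < 0.1

    def test_identical_snp_sets_one(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 3, size=(200, 2)).astype(float)
        C = gls_correlation({"a": ["s0", "s1"], "b": ["s0", "s1"]},
                            self._panel(X))
        assert C.loc["a", "b"] == pytest.approx(1.0)

    def test_matches_mc_statistic_correlation(self):
        # two enhancers sharing a correlated block: analytic estimate vs the
        # correlation of simulated null statistics
        rng = np.random.default_rng(2)
        n = 4000
        latent = rng.standard_normal((n, 4))
        rho = 0.8
        X = np.empty((n, 4))
        X[:, 0] = latent[:, 0]
        X[:, 1] = rho * latent[:, 0] + np.sqrt(1 - rho**2) * latent[:, 1]
        X[:, 2] = rho * X[:, 1] + np.sqrt(1 - rho**2) * latent[:, 2]
        X[:, 3] = rho * X[:, 2] + np.sqrt(1 - rho**2) * latent[:, 3]
        panel = self._panel(X)
        C = gls_correlation({"a": ["s0", "s1"], "b": ["s2", "s3"]}, panel)
        from rwas.region import ld_matrix

        R = ld_matrix(panel, ["s0", "s1", "s2", "s3"]).R
        L = np.linalg.cholesky(R + 1e-10 * np.eye(4))
        Z = rng.standard_normal((40_000, 4)) @ L.T
        Ta = (Z[:, :2] ** 2).sum(axis=1)
        Tb = (Z[:, 2:] ** 2).sum(axis=1)
        mc = np.corrcoef(Ta, Tb)[0, 1]
        assert C.loc["a", "b"] == pytest.approx(mc, abs=0.05)


class TestMetaMaxZ:
    def _results(self, stats, annotations=None):
        n = len(stats)
        return pd.DataFrame({
            "covariate": ["m"] * n,
            "statistic": stats,
            "p": 2 * norm.sf(np.abs(stats)),
            "annotation": annotations or [f"a{i}" for i in range(n)],
        })

    def test_table_row_reproduced(self):
        # printed motif meta row: Z = 3.46 over 10 annotations -> 5.40E-03
        res = self._results([3.46, 1.0, -0.5] + [0.1] * 7)
        out = meta_max_z(res, n_annotations=10)
        assert out.iloc[0]["p_adj"] == pytest.approx(5.40e-3, rel=0.01)

    def test_zero_statistic_gives_one(self):
        out = meta_max_z(self._results([0.0]), n_annotations=10)
        assert out.iloc[0]["p_adj"] == 1.0

    def test_single_annotation_identity(self):
        z = norm.isf(0.04 / 2)
        out = meta_max_z(self._results([z]), n_annotations=1)
        assert out.iloc[0]["p_adj"] == pytest.approx(0.04, rel=1e-6)

    def test_adjusted_never_below_best_p(self):
        rng = np.random.default_rng(0)
        res = self._results(list(rng.normal(size=10)))
        out = meta_max_z(res, n_annotations=10)
        assert out.iloc[0]["p_adj"] >= out.iloc[0]["p"]

    def test_sign_retained(self):
        res = self._results([-3.2, 1.0, 2.0])
        out = meta_max_z(res, n_annotations=3)
        assert out.iloc[0]["statistic"] == -3.2


class TestAdjustPvalues:
    def test_genomewide_threshold_two_sf(self):
        thr = bonferroni_threshold(0.05, 388_011)
        assert float(f"{thr:.1e}") == pytest.approx(1.3e-7)

    def test_single_test_identity(self):
        assert adjust_pvalues([0.04], "bonferroni")[0] == pytest.approx(0.04)

    def test_bh_step_up_by_hand(self):
        out = adjust_pvalues([0.01, 0.02, 0.03], "bh")
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_bonferroni_dominates_bh(self):
        rng = np.random.default_rng(0)
        ps = rng.uniform(size=50)
        bonf = adjust_pvalues(ps, "bonferroni")
        bh = adjust_pvalues(ps, "bh")
        assert (bonf >= bh - 1e-12).all()

    def test_bh_monotone_after_sorting(self):
        rng = np.random.default_rng(1)
        ps = np.sort(rng.uniform(size=50))
        bh = adjust_pvalues(ps, "bh")
        assert (np.diff(bh) >= -1e-12).all()

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5], "holm-sidak-typo")


class TestAttributeGroupTest:
    def test_exact_enumeration(self):
        out = attribute_group_test([1, 2, 3, 4, 5, 6],
                                   [True, True, True, False, False, False])
        assert out["less"] == pytest.approx(0.05)

    def test_label_swap_symmetry(self):
        vals = [1, 2, 3, 4, 5, 6]
        a = attribute_group_test(vals, [1, 1, 1, 0, 0, 0])
        b = attribute_group_test(vals, [0, 0, 0, 1, 1, 1])
        assert a["less"] == pytest.approx(b["greater"])

    def test_identical_groups_nonsignificant(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=60)
        grp = np.r_[np.ones(30, bool), np.zeros(30, bool)]
        out = attribute_group_test(np.r_[vals[:30], vals[:30]], grp)
        assert out["two-sided"] > 0.9

    def test_large_sample_with_ties_uses_normal_approx(self):
        rng = np.random.default_rng(1)
        vals = np.r_[rng.integers(0, 5, 50), rng.integers(1, 6, 50)].astype(float)
        grp = np.r_[np.ones(50, bool), np.zeros(50, bool)]
        out = attribute_group_test(vals, grp)
        assert 0 < out["two-sided"] <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            attribute_group_test([1.0, 2.0], [True, True])


class TestModelWrappers:
    def test_property_model_summary(self):
        rng = np.random.default_rng(0)
        c = rng.normal(size=200)
        assoc = make_assoc(0.5 * c + rng.normal(size=200))
        cov = pd.DataFrame({"at": c}, index=pd.Index(assoc["enhancer_id"], name="id"))
        res = PropertyModel(assoc, cov).fit()
        assert "at" in res.summary()
        assert res.table.iloc[0]["p"] < 1e-6

    def test_set_model_multiple_sets(self):
        rng = np.random.default_rng(1)
        assoc = make_assoc(rng.normal(size=150))
        idx = pd.Index(assoc["enhancer_id"], name="id")
        mems = pd.DataFrame({"s1": rng.integers(0, 2, 150),
                             "s2": rng.integers(0, 2, 150)}, index=idx)
        out = SetModel(assoc, mems).fit()
        assert list(out["set"]) == ["s1", "s2"]
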