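"""Group statistics: ANOVA, Dunnett, effect sizes, CV, variance components, ANCOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from dscnorm.exceptions import AnalysisError
from dscnorm.group_stats import (
    ancova_volume,
    cohens_d,
    coefficient_of_variation,
    compare_all,
    dunnett_test,
    one_way_anova,
    variance_components,
)
from dscnorm.phantom import default_cohort_spec, lookup_table, simulate_roi_tables
from dscnorm.roi_norm import RegionMapping, normalize_table


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        vals = np.array([1, 2, 3] * 3, float)
        groups = np.repeat(["a", "b", "c"], 3)
        f, p = one_way_anova(vals, groups)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([g + rng.normal(0, 1e-4, 10) for g in (0.0, 1.0, 2.0)])
        groups = np.repeat(["a", "b", "c"], 10)
        _, p = one_way_anova(vals, groups)
        assert p < 1e-6

    def test_matches_sums_of_squares_definition(self):
        """Oracle: F recomputed from the raw between/within sums of squares."""
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 1, 30)
        groups = rng.choice(["a", "b", "c"], 30)
        f, _ = one_way_anova(vals, groups)
        grand = vals.mean()
        ss_b = sum(((vals[groups == g].mean() - grand) ** 2) * (groups == g).sum() for g in "abc")
        ss_w = sum(((vals[groups == g] - vals[groups == g].mean()) ** 2).sum() for g in "abc")
        f_ref = (ss_b / 2) / (ss_w / (30 - 3))
        assert f == pytest.approx(f_ref, abs=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(AnalysisError, match="b"):
            one_way_anova(np.arange(5.0), ["a", "a", "a", "a", "b"])

    def test_invariant_to_constant_shift(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, 24)
        groups = np.repeat(["a", "b", "c"], 8)
        f1, _ = one_way_anova(vals, groups)
        f2, _ = one_way_anova(vals + 100.0, groups)
        assert f1 == pytest.approx(f2, rel=1e-9)


class TestDunnett:
    def test_null_comparison_p_near_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        p = dunnett_test({"t": x.copy()}, x.copy())["t"]
        assert p >= 0.99

    def test_k1_reduces_to_pooled_t(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.4, 1, 15)
        y = rng.normal(0, 1, 20)
        p = dunnett_test({"t": x}, y)["t"]
        p_ref = sps.ttest_ind(x, y).pvalue
        assert p == pytest.approx(p_ref, abs=1e-3)

    def test_cross_check_against_scipy(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.5, 1, 15)
        b = rng.normal(-0.2, 1, 28)
        c = rng.normal(0, 1, 20)
        mine = dunnett_test({"a": a, "b": b}, c)
        ref = sps.dunnett(a, b, control=c)
        assert mine["a"] == pytest.approx(ref.pvalue[0], abs=5e-3)
        assert mine["b"] == pytest.approx(ref.pvalue[1], abs=5e-3)

    def test_adjusted_p_not_below_unadjusted(self):
        rng = np.random.default_rng(4)
        groups = {g: rng.normal(mu, 1, 12) for g, mu in [("a", 0.3), ("b", 0.7)]}
        control = rng.normal(0, 1, 12)
        adj = dunnett_test(groups, control)
        for g in groups:
            raw = sps.ttest_ind(groups[g], control).pvalue
            assert adj[g] >= raw - 5e-3

    def test_monte_carlo_calibration(self):
        """Oracle: the 95th percentile of max |T| from a seeded 10^6-draw
        simulation must map to an adjusted p of 0.05."""
        n, k = 21, 2
        df = (k + 1) * n - (k + 1)
        rs = np.random.default_rng(12345)
        m = 10**6
        z0 = rs.standard_normal(m)
        u = np.sqrt(rs.chisquare(df, m) / df)
        c = np.sqrt(2.0 / n)
        tmax = np.zeros(m)
        for _ in range(k):
            zi = rs.standard_normal(m)
            tmax = np.maximum(tmax, np.abs((zi - z0) / np.sqrt(n)) / (u * c))
        crit = np.quantile(tmax, 0.95)
        rng = np.random.default_rng(0)
        control = rng.standard_normal(n)
        # build treatment samples whose t statistics hit the critical value
        from dscnorm.group_stats import _dunnett_family_prob

        p = 1.0 - _dunnett_family_prob(np.array([crit]), np.array([n, n]), n, df)[0]
        assert p == pytest.approx(0.05, abs=0.005)

    def test_no_treatments_rejected(self):
        with pytest.raises(AnalysisError):
            dunnett_test({}, np.arange(5.0))


class TestEffectSizeAndCV:
    def test_unit_effect(self):
        x = np.array([0.0, 1.0, 2.0])
        assert cohens_d(x + 1.0, x) == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(0, 1, 10), rng.normal(0.5, 2, 12)
        assert cohens_d(x, y) == pytest.approx(-cohens_d(y, x), rel=1e-12)

    def test_sign_convention_hypoperfusion_negative(self):
        """AD below control must give negative d (parietal hypoperfusion)."""
        rng = np.random.default_rng(0)
        control = rng.normal(1.0, 0.1, 20)
        ad = rng.normal(0.85, 0.1, 28)
        assert cohens_d(ad, control) < 0

    def test_cv_example(self):
        assert coefficient_of_variation(np.array([8.0, 10.0, 12.0])) == pytest.approx(20.0)

    def test_cv_constant_vector_zero(self):
        assert coefficient_of_variation(np.full(10, 3.3)) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(scale=st.floats(0.01, 100), seed=st.integers(0, 1000))
    def test_cv_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(1, 2, 20)
        assert coefficient_of_variation(scale * x) == pytest.approx(
            coefficient_of_variation(x), rel=1e-9
        )


class TestVarianceComponents:
    @staticmethod
    def _simulate(var_norm: float, var_diag: float, var_res: float, n_sub: int, seed: int):
        rng = np.random.default_rng(seed)
        diag_levels = ["control", "MCI", "AD"]
        norm_levels = ["cer", "wm", "cgm", "abs"]
        # fixed level effects with exact sample variance (ddof=1)
        def effects(levels, var):
            base = np.linspace(-1, 1, len(levels))
            if var == 0 or base.std(ddof=1) == 0:
                return dict.fromkeys(levels, 0.0)
            return dict(zip(levels, base / base.std(ddof=1) * np.sqrt(var)))

        de = effects(diag_levels, var_diag)
        ne = effects(norm_levels, var_norm)
        diag = rng.choice(diag_levels, n_sub)
        rows = []
        for i in range(n_sub):
            for nl in norm_levels:
                rows.append(
                    {
                        "value": de[diag[i]] + ne[nl] + rng.normal(0, np.sqrt(var_res)),
                        "diagnosis": diag[i],
                        "normalization": nl,
                    }
                )
        return pd.DataFrame(rows)

    def test_recovery_of_generating_proportions(self):
        data = self._simulate(var_norm=9.0, var_diag=0.0, var_res=1.0, n_sub=1000, seed=42)
        vc = variance_components(data)
        props = vc.proportions
        assert props["normalization"] == pytest.approx(0.9, abs=0.05)
        assert props["diagnosis"] == pytest.approx(0.0, abs=0.05)
        assert props["residual"] == pytest.approx(0.1, abs=0.05)

    def test_all_identical_values(self):
        data = pd.DataFrame(
            {
                "value": [1.0] * 12,
                "diagnosis": ["a", "b", "c"] * 4,
                "normalization": ["w", "x", "y", "z"] * 3,
            }
        )
        vc = variance_components(data)
        assert vc.var_diagnosis == vc.var_normalization == vc.var_residual == 0.0

    def test_proportions_sum_to_one(self):
        data = self._simulate(var_norm=2.0, var_diag=1.0, var_res=0.5, n_sub=50, seed=0)
        props = variance_components(data).proportions
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_level_factor_warns(self):
        data = self._simulate(var_norm=1.0, var_diag=0.0, var_res=1.0, n_sub=30, seed=1)
        data["diagnosis"] = "only"
        with pytest.warns(UserWarning):
            vc = variance_components(data)
        assert vc.var_diagnosis == 0.0


class TestAncova:
    def test_constant_age_falls_back_to_anova(self):
        rng = np.random.default_rng(0)
        groups = np.repeat(["control", "MCI", "AD"], 15)
        vols = rng.normal(150, 15, 45) - 10 * (groups == "AD")
        ages = np.full(45, 72.0)
        with pytest.warns(UserWarning):
            res = ancova_volume(vols, groups, ages)
        f, p = one_way_anova(vols, groups)
        assert res.p == pytest.approx(p, abs=1e-12)
        assert not res.used_covariate

    def test_matches_nested_model_oracle(self):
        """Oracle: extra-sum-of-squares F via statsmodels OLS."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(2)
        n = 60
        groups = rng.choice(["control", "MCI", "AD"], n)
        ages = rng.normal(73, 7, n)
        vols = 150 - 8 * (groups == "AD") + 0.5 * (ages - 73) + rng.normal(0, 10, n)
        res = ancova_volume(vols, groups, ages)
        design = np.column_stack(
            [np.ones(n), (groups == "MCI").astype(float), (groups == "AD").astype(float), ages - ages.mean()]
        )
        full = sm.OLS(vols, design).fit()
        red = sm.OLS(vols, np.column_stack([np.ones(n), ages - ages.mean()])).fit()
        f_ref, p_ref, _ = full.compare_f_test(red)
        assert res.f == pytest.approx(f_ref, rel=1e-6)
        assert res.p == pytest.approx(p_ref, rel=1e-6)

    def test_strong_separation_tiny_p(self):
        rng = np.random.default_rng(3)
        groups = np.repeat(["control", "AD"], 20)
        ages = rng.normal(73, 7, 40)
        vols = np.where(groups == "AD", 100.0, 160.0) + rng.normal(0, 1, 40)
        res = ancova_volume(vols, groups, ages)
        assert res.p < 1e-6
        assert res.dunnett_p["AD"] < 1e-6


@pytest.fixture(scope="module")
def cohort_tables():
    spec = default_cohort_spec(seed=0)
    mapping = RegionMapping(lookup_table(spec.tissue_specs))
    tab = simulate_roi_tables(spec, seed=0)
    tables = {"absolute": tab}
    for w in ("cer", "wm", "cgm"):
        tables[w] = normalize_table(tab, w, mapping)
    return tables, mapping


class TestCompareAll:

    def test_report_schema_complete(self, cohort_tables):
        tables, mapping = cohort_tables
        rep = compare_all(tables, mapping)
        gc = rep["group_comparisons"]
        assert len(gc) == 4 * len(mapping.lobe_regions())
        for col in ("anova_F", "anova_p", "p_AD", "p_MCI", "d_AD", "d_MCI"):
            assert gc[col].notna().all()
        assert set(rep["cv_table"]["lobe"]) == set(mapping.lobes)
        assert len(rep["bias_check"]) == 3
        assert (rep["variance_components"]["prop_normalization"] >= 0).all()

    def test_reference_bias_absent_by_construction(self, cohort_tables):
        """The phantom draws the same global factor distribution in every
        group, so the reference regions carry no disease bias."""
        tables, mapping = cohort_tables
        rep = compare_all(tables, mapping)
        assert (rep["bias_check"]["anova_p"] > 0.05).all()

    def test_cohort_mismatch_rejected(self, cohort_tables):
        tables, mapping = cohort_tables
        broken = dict(tables)
        broken["cer"] = broken["cer"].iloc[1:]
        with pytest.raises(AnalysisError):
            compare_all(broken, mapping)

    def test_normalization_variance_dominates_diagnosis(self, cohort_tables):
        """The scale differences between the three normalizations dwarf any
        diagnosis-group effect in the variance decomposition."""
        tables, mapping = cohort_tables
        vc = compare_all(tables, mapping)["variance_components"]
        assert (vc["prop_normalization"] > vc["prop_diagnosis"]).all()
        assert vc["prop_normalization"].mean() > 0.95
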