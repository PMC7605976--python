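"""One-way ANOVA, Pearson correlation with magnitude bands, cohort summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from musclemap import (
    InputError,
    SchemaError,
    StatsError,
    correlation_band,
    generate_cohort,
    one_way_anova,
    pearson,
    reference_cohort_spec,
    summarize_cohort,
)


class TestAnova:
    def test_two_group_example_by_hand(self):
        # SSB = 13.5, SSW = 4, MSW = 1 -> F = 13.5 on df (1, 4)
        res = one_way_anova([[1, 2, 3], [4, 5, 6]])
        assert res.f == pytest.approx(13.5)
        assert (res.df_between, res.df_within) == (1, 4)
        assert res.p == pytest.approx(sps.f.sf(13.5, 1, 4))

    def test_identical_groups_f_zero_p_one(self):
        res = one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.f == 0.0
        assert res.p == 1.0

    def test_fully_constant_data_f_undefined(self):
        res = one_way_anova([[5.0, 5.0], [5.0, 5.0]])
        assert np.isnan(res.f) and np.isnan(res.p)

    def test_zero_within_variance_with_effect(self):
        res = one_way_anova([[1.0, 1.0], [2.0, 2.0]])
        assert np.isinf(res.f) and res.p == 0.0

    @pytest.mark.parametrize("groups", [[[1, 2, 3]], [[1, 2], [3]]])
    def test_degenerate_inputs_rejected(self, groups):
        with pytest.raises(InputError):
            one_way_anova(groups)

    def test_matches_scipy_f_oneway(self, rng):
        """Independent oracle: scipy's implementation on random instances."""
        for _ in range(25):
            groups = [rng.normal(rng.normal(0, 2), 1, size=rng.integers(3, 12))
                      for _ in range(rng.integers(2, 6))]
            res = one_way_anova(groups)
            ref = sps.f_oneway(*groups)
            assert res.f == pytest.approx(ref.statistic, rel=1e-10)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_two_groups_equals_squared_t(self, rng):
        for _ in range(25):
            a = rng.normal(0, 1, size=rng.integers(3, 15))
            b = rng.normal(0.5, 1, size=rng.integers(3, 15))
            res = one_way_anova([a, b])
            t = sps.ttest_ind(a, b, equal_var=True)
            assert res.f == pytest.approx(t.statistic**2, rel=1e-10)
            assert res.p == pytest.approx(t.pvalue, rel=1e-8)


class TestPearson:
    def test_perfect_linearity(self, rng):
        x = rng.normal(size=20)
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.band == "very strong"
        assert res.p == 0.0

    def test_matches_scipy(self, rng):
        for _ in range(25):
            n = rng.integers(5, 50)
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            res = pearson(x, y)
            ref = sps.pearsonr(x, y)
            assert res.r == pytest.approx(ref.statistic, abs=1e-12)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_constant_input_undefined(self):
        with pytest.raises(StatsError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(InputError):
            pearson([1.0, 2.0], [3.0, 4.0])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           a=st.floats(-5, 5, allow_nan=False).filter(lambda v: abs(v) > 1e-3),
           b=st.floats(-10, 10, allow_nan=False))
    def test_symmetry_and_affine_equivariance(self, seed, a, b):
        r = np.random.default_rng(seed)
        x = r.normal(size=12)
        y = x + r.normal(size=12)
        r_xy = pearson(x, y).r
        assert pearson(y, x).r == pytest.approx(r_xy, abs=1e-12)
        r_scaled = pearson(a * x + b, y).r
        assert r_scaled == pytest.approx(np.sign(a) * r_xy, abs=1e-9)


class TestBands:
    @pytest.mark.parametrize(
        "r,band",
        [
            (0.0, "negligible"), (0.05, "negligible"),
            (0.1, "weak"), (0.25, "weak"),            # tie at 0.1 goes up
            (0.4, "moderate"), (0.55, "moderate"),
            (0.7, "strong"), (0.75, "strong"), (-0.833, "strong"),
            (0.9, "very strong"), (1.0, "very strong"), (-1.0, "very strong"),
        ],
    )
    def test_cutpoints_including_ties(self, r, band):
        assert correlation_band(r) == band

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(r=st.floats(-1, 1, allow_nan=False))
    def test_every_r_maps_to_exactly_one_band(self, r):
        assert correlation_band(r) in (
            "negligible", "weak", "moderate", "strong", "very strong"
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            correlation_band(1.5)


class TestSummarizeCohort:
    def test_missing_column_named_in_error(self):
        df = generate_cohort(reference_cohort_spec(seed=1)).drop(columns=["vfa_cm2"])
        with pytest.raises(SchemaError, match="vfa_cm2"):
            summarize_cohort(df)

    def test_detects_manipulated_group_difference(self):
        df = generate_cohort(reference_cohort_spec(sexes=("male",), seed=2))
        tables = summarize_cohort(df)
        anova = tables["anova"].set_index("variable")
        assert anova.loc["nama_cm2", "p"] < 0.05  # strong built-in age trend
        groups = tables["groups"]
        assert set(groups["variable"]) == {
            "tama_cm2", "nama_cm2", "lama_cm2", "imat_cm2", "myosteatosis_cm2"
        }
        assert groups["age_band"].nunique() == 6

    def test_myosteatosis_density_correlation_is_negative(self):
        df = generate_cohort(reference_cohort_spec(seed=3))
        corr = summarize_cohort(df)["correlations"]
        sel = corr[(corr["component"] == "myosteatosis_cm2")
                   & (corr["against"] == "mean_tama_density_hu")]
        assert (sel["r"] < 0).all()

    def test_single_sex_input_emits_single_stratum(self):
        df = generate_cohort(reference_cohort_spec(sexes=("female",), seed=4))
        tables = summarize_cohort(df)
        assert set(tables["groups"]["sex"]) == {"female"}
        assert set(tables["correlations"]["sex"]) == {"female"}
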