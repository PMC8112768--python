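"""Transform selection and mixed-model estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from usualintake import (
    RecallDataset,
    TransformSpec,
    fit_mixed_model,
    fit_one_day,
    fit_transform,
)
from usualintake.errors import (
    DomainError,
    GuidanceError,
    NoVarianceError,
    RankError,
)
from usualintake.recall_model import choose_offset, default_lambda_grid


def profile_loglik(lam, x):
    """Independent Box-Cox profile log-likelihood (variance-profiled form
    with the Jacobian term), written out from the definition."""
    z = np.log(x) if lam == 0 else (x**lam - 1) / lam
    n = x.size
    return -n / 2 * np.log(np.var(z)) + (lam - 1) * np.sum(np.log(x))


class TestFitTransform:
    def test_near_normal_data_selects_lambda_near_one(self):
        rng = np.random.default_rng(5)
        x = rng.normal(10, 1, size=500)
        spec = fit_transform(x)
        assert 0.7 <= spec.lam <= 1.0

    def test_lognormal_data_selects_lambda_near_zero(self):
        rng = np.random.default_rng(6)
        x = np.exp(rng.normal(1.0, 0.5, size=500))
        spec = fit_transform(x)
        assert spec.lam <= 0.1

    @pytest.mark.parametrize("seed", [5, 6, 17])
    def test_selection_matches_exhaustive_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = np.exp(rng.normal(1.0, 0.4, size=300))
        grid = default_lambda_grid()
        oracle = grid[int(np.argmax([profile_loglik(l, x) for l in grid]))]
        assert fit_transform(x).lam == pytest.approx(oracle)

    def test_deterministic_for_fixed_input(self):
        x = np.exp(np.random.default_rng(0).normal(1, 0.3, 200))
        assert fit_transform(x) == fit_transform(x)

    def test_constant_input_raises_no_variance(self):
        with pytest.raises(NoVarianceError):
            fit_transform(np.full(50, 5.0))

    def test_nonpositive_values_with_zero_offset_raise(self):
        x = np.r_[np.ones(20), 0.0, -1.0]
        with pytest.raises(DomainError):
            fit_transform(x)

    def test_offset_policy(self):
        x = np.r_[np.zeros(2), np.full(98, 4.0) + np.arange(98) * 0.01]
        assert choose_offset(x) == pytest.approx(2.0)  # half the smallest positive
        from usualintake.errors import NearlyDailyViolationError
        with pytest.raises(NearlyDailyViolationError):
            choose_offset(np.r_[np.zeros(50), np.ones(50)])


class TestTransformSpec:
    @given(lam=st.sampled_from([0.0, 0.25, 0.5, 1.0]),
           r=st.floats(0.1, 1e3), offset=st.floats(0, 5))
    @settings(max_examples=200, deadline=None)
    def test_inverse_round_trips(self, lam, r, offset):
        t = TransformSpec(lam=lam, offset=offset)
        assert t.inverse(t.apply(r)) == pytest.approx(r, rel=1e-9, abs=1e-9)

    def test_inverse_clamps_undefined_fractional_powers(self):
        # 1/lam non-integer: no real preimage below -1/lam, clamp to 0 intake
        t = TransformSpec(lam=0.3)
        assert t.inverse(-5.0) == 0.0
        with pytest.raises(DomainError):
            t.inverse(-5.0, clamp=False)

    def test_inverse_polynomial_extension_preserves_quadratic(self):
        # 1/lam integer: polynomial inverse evaluated globally
        t = TransformSpec(lam=0.5)
        assert t.inverse(-5.0) == pytest.approx((0.5 * -5.0 + 1) ** 2)

    def test_invalid_parameters(self):
        with pytest.raises(DomainError):
            TransformSpec(lam=1.5)
        with pytest.raises(DomainError):
            TransformSpec(lam=0.5, offset=-1)


def anova_moments_oracle(dataset, transform):
    """Balanced one-way ANOVA method-of-moments estimator (independent route)."""
    long = dataset.to_long()
    y = pd.Series(transform.apply(long["intake"].to_numpy()),
                  index=long["person_id"].to_numpy())
    k = long.groupby("person_id").size().iloc[0]
    person_means = y.groupby(level=0).mean()
    se2 = float(y.groupby(level=0).var(ddof=1).mean())
    su2 = float(person_means.var(ddof=1) - se2 / k)
    return float(person_means.mean()), su2, se2


class TestFitMixedModel:
    def test_recovers_generating_parameters(self, balanced_survey):
        spec, dataset, _ = balanced_survey
        model = fit_mixed_model(dataset, transform=TransformSpec(1.0))
        assert model.converged
        assert model.beta[0] == pytest.approx(spec.beta0, rel=0.10)
        assert model.sigma2_between == pytest.approx(spec.sigma2_between, rel=0.10)
        assert model.sigma2_within == pytest.approx(spec.sigma2_within, rel=0.10)

    def test_agrees_with_moments_oracle(self, balanced_survey):
        _, dataset, _ = balanced_survey
        t = TransformSpec(1.0)
        model = fit_mixed_model(dataset, transform=t)
        b0, su2, se2 = anova_moments_oracle(dataset, t)
        # for balanced intercept-only data REML and ANOVA moments coincide
        assert model.beta[0] == pytest.approx(b0, rel=1e-4)
        assert model.sigma2_between == pytest.approx(su2, rel=1e-3)
        assert model.sigma2_within == pytest.approx(se2, rel=1e-3)

    def test_agrees_with_statsmodels_reml(self):
        from usualintake import SyntheticSpec, generate_population
        import statsmodels.formula.api as smf

        ds, _ = generate_population(SyntheticSpec(
            n_persons=300, n_recalls=3, beta_sex=0.8, seed=9))
        t = TransformSpec(1.0)
        model = fit_mixed_model(ds, covariate_names=["sex"], transform=t)
        long = ds.to_long().assign(y=lambda d: t.apply(d["intake"].to_numpy()))
        sm = smf.mixedlm("y ~ C(sex)", long, groups=long["person_id"]).fit(reml=True)
        assert model.beta == pytest.approx(sm.fe_params.to_numpy(), rel=1e-3, abs=1e-3)
        assert model.sigma2_between == pytest.approx(float(sm.cov_re.iloc[0, 0]), rel=1e-2)
        assert model.sigma2_within == pytest.approx(sm.scale, rel=1e-2)

    def test_identical_recalls_give_zero_within_variance(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(10, 1, 200)
        df = pd.DataFrame({
            "person_id": np.repeat(np.arange(200), 2),
            "recall_index": np.tile([1, 2], 200),
            "intake": np.repeat(vals, 2),
            "weight": 1.0,
        })
        model = fit_mixed_model(RecallDataset.from_long(df), transform=TransformSpec(1.0))
        assert model.sigma2_within <= 1e-8

    def test_iid_recalls_give_negligible_between_variance(self):
        from usualintake import SyntheticSpec, generate_population
        ds, _ = generate_population(SyntheticSpec(
            n_persons=2000, n_recalls=2, sigma2_between=0.0, sigma2_within=2.0, seed=13))
        model = fit_mixed_model(ds, transform=TransformSpec(1.0))
        assert model.sigma2_between <= 0.05 * model.sigma2_within

    def test_no_repeated_recalls_points_to_one_day_mode(self):
        df = pd.DataFrame({"person_id": np.arange(50), "recall_index": 1,
                           "intake": np.random.default_rng(0).normal(10, 1, 50),
                           "weight": 1.0})
        with pytest.raises(GuidanceError, match="one_day|external"):
            fit_mixed_model(RecallDataset.from_long(df), transform=TransformSpec(1.0))

    def test_singular_design_reports_collinear_columns(self, balanced_survey):
        _, dataset, _ = balanced_survey
        ds = RecallDataset(recalls=dataset.recalls.copy(), persons=dataset.persons.copy())
        ds.persons["age_copy"] = ds.persons["age"]
        with pytest.raises(RankError) as err:
            fit_mixed_model(ds, covariate_names=["age", "age_copy"],
                            transform=TransformSpec(1.0))
        assert "age" in str(err.value)

    def test_weights_shift_estimates_toward_upweighted_persons(self):
        # two halves with different means: weighting one half up must move beta
        rng = np.random.default_rng(21)
        n = 400
        mean = np.r_[np.full(n // 2, 8.0), np.full(n // 2, 12.0)]
        df = pd.DataFrame({
            "person_id": np.repeat(np.arange(n), 2),
            "recall_index": np.tile([1, 2], n),
            "intake": np.repeat(mean, 2) + rng.normal(0, 1, 2 * n),
            "weight": np.repeat(np.r_[np.full(n // 2, 1.0), np.full(n // 2, 9.0)], 2),
        })
        ds = RecallDataset.from_long(df)
        weighted = fit_mixed_model(ds, transform=TransformSpec(1.0))
        unweighted = fit_mixed_model(ds, transform=TransformSpec(1.0), use_weights=False)
        assert weighted.beta[0] > unweighted.beta[0] + 1.0


class TestFitOneDay:
    def _dataset(self, n=500, seed=2):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({"person_id": np.arange(n), "recall_index": 1,
                           "intake": rng.normal(10, np.sqrt(2.0), n), "weight": 1.0})
        return RecallDataset.from_long(df)

    def test_variance_split_algebra(self):
        ds = self._dataset()
        model = fit_one_day(ds, external_ratio=3.0, transform=TransformSpec(1.0))
        total = model.sigma2_between + model.sigma2_within
        assert model.sigma2_within == pytest.approx(3.0 * model.sigma2_between)
        assert model.sigma2_between == pytest.approx(total / 4.0)
        assert model.variance_ratio_used == 3.0

    def test_split_matches_stated_example(self):
        # sigma_tot^2 = 2, r = 3 -> (0.5, 1.5)
        ds = self._dataset()
        model = fit_one_day(ds, external_ratio=3.0, transform=TransformSpec(1.0))
        total = model.sigma2_between + model.sigma2_within
        assert model.sigma2_between == pytest.approx(total / (1 + 3))
        assert model.sigma2_within == pytest.approx(total * 3 / (1 + 3))

    def test_ratio_zero_puts_all_variance_between(self):
        model = fit_one_day(self._dataset(), external_ratio=0.0,
                            transform=TransformSpec(1.0))
        assert model.sigma2_within == 0.0
        assert model.sigma2_between > 0

    def test_negative_ratio_rejected(self):
        with pytest.raises(DomainError):
            fit_one_day(self._dataset(), external_ratio=-1.0,
                        transform=TransformSpec(1.0))

    def test_missing_ratio_gives_sensitivity_guidance(self):
        with pytest.raises(GuidanceError, match="sensitivity"):
            fit_one_day(self._dataset(), external_ratio=None,
                        transform=TransformSpec(1.0))

    def test_components_sum_to_total_residual_variance_exactly(self):
        ds = self._dataset(seed=8)
        for r in (0.0, 0.5, 2.0, 10.0):
            m = fit_one_day(ds, external_ratio=r, transform=TransformSpec(1.0))
            total0 = fit_one_day(ds, external_ratio=0.0,
                                 transform=TransformSpec(1.0)).sigma2_between
            assert m.sigma2_between + m.sigma2_within == pytest.approx(total0, rel=1e-12)
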