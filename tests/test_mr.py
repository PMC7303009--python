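"""MR estimators against hand-computed oracles, closed forms and GLS solves."""

import numpy as np
import pytest
from scipy import stats

from causalmr import (
    IVW,
    MREgger,
    ScenarioConfig,
    egger,
    ivw,
    ivw_correlated,
    multivariable_ivw,
    ratio_estimates,
    simulate_mv_sumstats,
    simulate_sumstats,
    to_odds_scale,
    weighted_median,
)
from causalmr.mr import Z95, MREstimate, se_from_or_ci, single_variant_estimate
from causalmr.sumstats import HarmonizedInstrumentSet, MVInstrumentSet


def _hset(bx, by, sy, sx=None, corr=None):
    bx = np.asarray(bx, dtype=float)
    return HarmonizedInstrumentSet(
        variant_ids=[f"rs{i}" for i in range(bx.size)],
        beta_exposure=bx,
        se_exposure=np.full(bx.size, 0.01) if sx is None else np.asarray(sx, dtype=float),
        beta_outcome=np.asarray(by, dtype=float),
        se_outcome=np.asarray(sy, dtype=float),
        correlation=corr,
    )


def _random_hset(rng, j=8):
    return _hset(
        bx=rng.normal(0, 0.1, j),
        by=rng.normal(0, 0.02, j),
        sy=rng.uniform(0.005, 0.03, j),
        sx=rng.uniform(0.002, 0.01, j),
    )


class TestRatio:
    def test_direct_division_and_first_order_se(self):
        ests, skipped = ratio_estimates(_hset([0.2], [0.05], [0.01]))
        assert skipped == []
        assert ests[0].beta == pytest.approx(0.25)
        assert ests[0].se == pytest.approx(0.05)

    def test_orientation_invariance_of_ratio(self):
        ests, _ = ratio_estimates(_hset([-0.2], [-0.05], [0.01]))
        assert ests[0].beta == pytest.approx(0.25)

    def test_zero_exposure_beta_skipped_with_log(self):
        ests, skipped = ratio_estimates(_hset([0.0, 0.2], [0.01, 0.05], [0.01, 0.01]))
        assert skipped == ["rs0"] and len(ests) == 1

    def test_noise_free_simulation_ratios_match_theta(self):
        h = simulate_sumstats(ScenarioConfig(
            true_effect=0.166, se_exposure=1e-8, se_outcome=1e-8, seed=2))
        ests, _ = ratio_estimates(h)
        assert all(e.beta == pytest.approx(0.166, abs=1e-4) for e in ests)


class TestIVW:
    def test_three_variant_weighted_average_oracle(self, three_variant_hset):
        # weights 100, 400, 225; ratios 0.2, 0.25, 0.2 -> 165/725
        est = IVW(three_variant_hset).fit(effects_model="fixed")
        assert est.beta == pytest.approx(165 / 725, abs=1e-12)
        assert est.se == pytest.approx(725**-0.5, abs=1e-12)

    def test_matches_weighted_least_squares_through_origin(self, three_variant_hset):
        import statsmodels.api as sm

        d = three_variant_hset
        wls = sm.WLS(d.beta_outcome, d.beta_exposure[:, None], weights=1 / d.se_outcome**2).fit()
        est = IVW(d).fit(effects_model="fixed")
        assert est.beta == pytest.approx(float(wls.params[0]), abs=1e-10)

    def test_single_variant_reduces_to_ratio(self):
        est = ivw(_hset([0.2], [0.05], [0.01]))
        assert est.beta == pytest.approx(0.25)
        assert est.se == pytest.approx(0.05)

    def test_zero_heterogeneity_random_equals_fixed(self):
        h = _hset([0.1, 0.2, 0.4], [0.05, 0.10, 0.20], [0.01, 0.01, 0.01])
        fe = ivw(h, effects_model="fixed")
        re = ivw(h, effects_model="random")
        assert re.beta == fe.beta
        assert re.se == fe.se  # Q=0 hits the max(1, .) floor

    def test_point_estimate_identical_across_effects_models(self, three_variant_hset):
        assert ivw(three_variant_hset, "fixed").beta == ivw(three_variant_hset, "random").beta


class TestCorrelatedIVW:
    def test_identity_correlation_equals_plain_ivw(self, three_variant_hset):
        d = three_variant_hset
        with_id = HarmonizedInstrumentSet(
            d.variant_ids, d.beta_exposure, d.se_exposure, d.beta_outcome,
            d.se_outcome, correlation=np.eye(3))
        a = ivw_correlated(with_id)
        b = ivw(d, effects_model="fixed")
        assert a.beta == pytest.approx(b.beta, abs=1e-10)
        assert a.se == pytest.approx(b.se, abs=1e-10)

    def test_identity_equivalence_on_random_fixtures(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            h = _random_hset(rng)
            h2 = HarmonizedInstrumentSet(
                h.variant_ids, h.beta_exposure, h.se_exposure, h.beta_outcome,
                h.se_outcome, correlation=np.eye(h.n_variants))
            assert ivw_correlated(h2).beta == pytest.approx(
                ivw(h, "fixed").beta, abs=1e-10)

    def test_near_duplicate_variant_collapses_to_single_copy(self):
        corr = np.array([[1.0, 0.9999], [0.9999, 1.0]])
        dup = _hset([0.2, 0.2], [0.05, 0.05], [0.01, 0.01], corr=corr)
        est = ivw_correlated(dup)
        single = ivw(_hset([0.2], [0.05], [0.01]), "fixed")
        assert est.beta == pytest.approx(single.beta, rel=1e-6)
        assert est.se == pytest.approx(single.se, rel=0.01)

    def test_matches_brute_force_gls_solve(self):
        rho = np.full((3, 3), 0.5)
        np.fill_diagonal(rho, 1.0)
        h = _hset([0.1, 0.2, 0.3], [0.02, 0.05, 0.06], [0.01, 0.01, 0.02], corr=rho)
        omega = np.outer(h.se_outcome, h.se_outcome) * rho
        oi = np.linalg.inv(omega)
        x, y = h.beta_exposure, h.beta_outcome
        theta = (x @ oi @ y) / (x @ oi @ x)
        se = (x @ oi @ x) ** -0.5
        est = ivw_correlated(h)
        assert est.beta == pytest.approx(theta, abs=1e-12)
        assert est.se == pytest.approx(se, abs=1e-12)

    def test_ill_conditioned_panel_advises_pruning(self):
        corr = np.array([[1.0, 1.0 - 1e-13], [1.0 - 1e-13, 1.0]])
        dup = _hset([0.2, 0.2], [0.05, 0.05], [0.01, 0.01], corr=corr)
        with pytest.raises(ValueError, match="prune"):
            ivw_correlated(dup)


class TestEgger:
    def test_collinear_points_through_origin(self):
        h = _hset([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], [0.01, 0.01, 0.01])
        est = egger(h)
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert est.egger_intercept == pytest.approx(0.0, abs=1e-10)
        assert est.egger_intercept_or == pytest.approx(1.0, abs=1e-9)

    def test_requires_three_variants(self):
        with pytest.raises(ValueError):
            MREgger(_hset([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]))

    def test_equal_exposure_betas_unidentified(self):
        h = _hset([0.2, 0.2, 0.2], [0.05, 0.06, 0.07], [0.01, 0.01, 0.01])
        with pytest.raises(ValueError, match="unidentified"):
            egger(h)

    def test_intercept_recovers_directional_pleiotropy(self):
        intercepts, slopes = [], []
        for r in range(300):
            h = simulate_sumstats(ScenarioConfig(
                true_effect=0.0, pleiotropy_mean=0.01, pleiotropy_sd=0.002,
                seed=40_000 + r))
            e = egger(h)
            intercepts.append(e.egger_intercept)
            slopes.append(e.beta)
        assert np.mean(intercepts) == pytest.approx(0.01, abs=0.002)
        # slope stays near the true null while IVW is pushed away
        assert abs(np.mean(slopes)) < 0.1

    def test_constrained_intercept_reproduces_ivw(self, three_variant_hset):
        est = MREgger(three_variant_hset).fit(constrain_intercept=True)
        ref = ivw(three_variant_hset, effects_model="fixed")
        assert est.beta == pytest.approx(ref.beta, abs=1e-12)

    def test_matches_weighted_least_squares_with_intercept(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        h = _random_hset(rng, j=12)
        sign = np.where(h.beta_exposure < 0, -1, 1)
        X = sm.add_constant(sign * h.beta_exposure)
        wls = sm.WLS(sign * h.beta_outcome, X, weights=1 / h.se_outcome**2).fit()
        est = egger(h)
        assert est.beta == pytest.approx(float(wls.params[1]), abs=1e-10)
        assert est.egger_intercept == pytest.approx(float(wls.params[0]), abs=1e-10)


class TestWeightedMedian:
    def test_equal_weights_median_of_three(self):
        h = _hset([1.0, 1.0, 1.0], [0.1, 0.2, 0.9], [1.0, 1.0, 1.0])
        est = weighted_median(h, n_boot=100, seed=0)
        assert est.beta == pytest.approx(0.2, abs=1e-12)

    def test_interpolated_weighted_median_hand_oracle(self):
        # ratios (0.1, 0.2, 0.9), normalized weights (0.2, 0.3, 0.5):
        # cumulative midpoints (0.1, 0.35, 0.75); interpolate at 0.5
        # -> 0.2 + (0.15/0.40) * 0.7 = 0.4625
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.1, 0.2, 0.9])
        sy = 1.0 / np.sqrt(np.array([0.2, 0.3, 0.5]))
        est = weighted_median(_hset(bx, by, sy), n_boot=100, seed=0)
        assert est.beta == pytest.approx(0.4625, abs=1e-12)

    def test_dominant_weight_drags_estimate_to_its_ratio(self):
        # one variant holds 90% of the weight; estimate sits near its ratio
        bx = np.array([1.0, 1.0, 1.0, 1.0])
        by = np.array([0.3, 0.05, 0.5, 0.8])
        w = np.array([0.9, 0.034, 0.033, 0.033])
        sy = 1.0 / np.sqrt(w)
        est = weighted_median(_hset(bx, by, sy), n_boot=100, seed=0)
        assert est.beta == pytest.approx(0.3, abs=0.02)

    def test_same_seed_same_bootstrap_se(self):
        h = _hset([0.1, 0.2, 0.3], [0.02, 0.05, 0.06], [0.01, 0.01, 0.02])
        a = weighted_median(h, n_boot=500, seed=9)
        b = weighted_median(h, n_boot=500, seed=9)
        assert a.se == b.se

    def test_seed_is_mandatory(self):
        h = _hset([0.1, 0.2, 0.3], [0.02, 0.05, 0.06], [0.01, 0.01, 0.02])
        with pytest.raises(ValueError, match="seed"):
            weighted_median(h, n_boot=100)


class TestMultivariable:
    def test_single_exposure_reduces_to_ivw_random(self, three_variant_hset):
        d = three_variant_hset
        mv = MVInstrumentSet(
            variant_ids=d.variant_ids, beta_exposures=d.beta_exposure[:, None],
            beta_outcome=d.beta_outcome, se_outcome=d.se_outcome,
            exposure_labels=["only"])
        est = multivariable_ivw(mv)[0]
        ref = ivw(d, effects_model="random")
        assert est.beta == pytest.approx(ref.beta, abs=1e-10)
        assert est.se == pytest.approx(ref.se, abs=1e-10)

    def test_block_design_recovers_univariable_estimates(self):
        rng = np.random.default_rng(8)
        j = 6
        bx1 = np.concatenate([rng.uniform(0.1, 0.3, j), np.zeros(j)])
        bx2 = np.concatenate([np.zeros(j), rng.uniform(0.1, 0.3, j)])
        sy = np.full(2 * j, 0.01)
        by = 0.3 * bx1 - 0.2 * bx2 + rng.normal(0, 0.005, 2 * j)
        mv = MVInstrumentSet(
            variant_ids=[f"rs{i}" for i in range(2 * j)],
            beta_exposures=np.column_stack([bx1, bx2]),
            beta_outcome=by, se_outcome=sy, exposure_labels=["e1", "e2"])
        ests = multivariable_ivw(mv)
        uni1 = ivw(_hset(bx1[:j], by[:j], sy[:j]), "fixed")
        uni2 = ivw(_hset(bx2[j:], by[j:], sy[j:]), "fixed")
        assert ests[0].beta == pytest.approx(uni1.beta, abs=1e-10)
        assert ests[1].beta == pytest.approx(uni2.beta, abs=1e-10)

    def test_lipid_style_panel_recovers_sparse_effects(self):
        # three exposures, only the third causal (emulating the pattern where
        # triglycerides alone carries effect among the lipid fractions)
        truth = np.array([0.0, 0.0, 0.17])
        mv = simulate_mv_sumstats(185, truth, seed=13,
                                  exposure_labels=["ldl", "hdl", "tg"])
        ests = multivariable_ivw(mv)
        for est, theta in zip(ests, truth):
            assert abs(est.beta - theta) < 3 * est.se

    def test_collinear_exposures_named(self):
        bx = np.random.default_rng(1).uniform(0.1, 0.3, 8)
        mv = MVInstrumentSet(
            variant_ids=[f"rs{i}" for i in range(8)],
            beta_exposures=np.column_stack([bx, 2 * bx]),
            beta_outcome=0.1 * bx, se_outcome=np.full(8, 0.01),
            exposure_labels=["a", "b"])
        with pytest.raises(ValueError, match="collinear"):
            multivariable_ivw(mv)


class TestOrientationInvariance:
    @pytest.mark.parametrize("method", ["ivw", "correlated", "median", "egger"])
    def test_joint_sign_flips_leave_estimates_unchanged(self, method):
        rng = np.random.default_rng(55)
        h = _random_hset(rng, j=9)
        flip = rng.random(9) < 0.5
        s = np.where(flip, -1.0, 1.0)
        h2 = HarmonizedInstrumentSet(
            h.variant_ids, s * h.beta_exposure, h.se_exposure,
            s * h.beta_outcome, h.se_outcome)
        if method == "ivw":
            a, b = ivw(h), ivw(h2)
        elif method == "correlated":
            a, b = ivw_correlated(h), ivw_correlated(h2)
        elif method == "median":
            a = weighted_median(h, n_boot=300, seed=1)
            b = weighted_median(h2, n_boot=300, seed=1)
        else:
            a, b = egger(h), egger(h2)
        assert b.beta == pytest.approx(a.beta, abs=1e-10)
        if method == "median":
            # bootstrap draws are not mirrored under sign flips; the SE is
            # invariant only in distribution
            assert b.se == pytest.approx(a.se, rel=0.25)
        else:
            assert b.se == pytest.approx(a.se, rel=1e-6)


class TestNullCalibration:
    def test_all_methods_cover_null_at_nominal_rate(self):
        """1000 null simulations (theta=0, no pleiotropy, J=51): IVW covers 0
        at the nominal 95% rate; Egger and the weighted median never
        under-cover.  With no true heterogeneity the multiplicative
        random-effects floor max(1, RSE) can only inflate SEs, and the
        bootstrap SE of the median propagates exposure-side noise, so those
        two run mildly conservative (slightly above 0.97) by construction."""
        reps = 1000
        cover = {"ivw": 0, "egger": 0, "wm": 0}
        for r in range(reps):
            h = simulate_sumstats(ScenarioConfig(true_effect=0.0, seed=800_000 + r))
            for key, est in (("ivw", ivw(h)),
                             ("egger", egger(h)),
                             ("wm", weighted_median(h, n_boot=500, seed=r))):
                cover[key] += (est.beta - Z95 * est.se) <= 0 <= (est.beta + Z95 * est.se)
        assert 0.93 <= cover["ivw"] / reps <= 0.97
        for key in ("egger", "wm"):
            assert 0.93 <= cover[key] / reps <= 0.985, (key, cover[key] / reps)


class TestOddsScale:
    def test_null_effect(self):
        or_point, lcl, ucl, p = to_odds_scale(0.0, 1.0)
        assert or_point == 1.0
        assert lcl == pytest.approx(0.1408, abs=1e-3)
        assert ucl == pytest.approx(7.0993, abs=1e-3)
        assert p == pytest.approx(1.0)

    def test_triglycerides_row_reconstruction(self):
        beta, se = se_from_or_ci(1.18, 1.09, 1.27)
        assert beta == pytest.approx(0.1655, abs=1e-3)
        assert se == pytest.approx(0.03899, abs=1e-4)
        *_, p = to_odds_scale(beta, se)
        assert p == pytest.approx(2.2e-5, rel=0.05)

    def test_round_trip_bijection(self):
        beta, se = 0.1655, 0.03898
        or_point, lcl, ucl, _ = to_odds_scale(beta, se)
        b2, s2 = se_from_or_ci(or_point, lcl, ucl)
        assert b2 == pytest.approx(beta, abs=1e-10)
        assert s2 == pytest.approx(se, abs=1e-10)

    def test_estimate_invariants(self):
        est = MREstimate(method="ivw_re", beta=0.1655, se=0.03898, n_variants=51)
        assert est.or_lcl < est.or_point < est.or_ucl
        assert est.or_point == pytest.approx(np.exp(est.beta))
        assert est.pvalue == pytest.approx(2 * stats.norm.sf(0.1655 / 0.03898))

    def test_single_variant_report_is_per_allele(self):
        h = _hset([0.2], [0.05], [0.012])
        est = single_variant_estimate(h)
        assert est.beta == 0.05 and est.se == 0.012
        assert est.method == "single_variant"
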