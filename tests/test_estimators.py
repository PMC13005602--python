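import numpy as np
import pytest

import _oracles as oracle
from survtransport import (
    EstimationError,
    estimate_dr1,
    estimate_dr2,
    estimate_ipw1,
    estimate_ipw2,
    estimate_om,
    estimate_wkm,
    martingale_augmentation,
    taste,
)
from survtransport.estimators import dr2_decomposition

from conftest import cox_censoring, cox_outcome, degenerate_censoring, make_sample


class _ValueOutcome:
    """Stub outcome model returning the covariate column 'h' as H(t|X)."""

    family = "stub"
    covariate_names = ["h"]

    def survival(self, t, X, side="right"):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X[:, 0].copy()

    def survival_matrix(self, times, X, side="right"):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.tile(X[:, [0]], (1, len(np.atleast_1d(times))))


@pytest.fixture
def two_plus_four():
    """Two uncensored trial subjects (one per arm) and four unit-weight
    survey records."""
    return make_sample(
        S=[1, 1, 0, 0, 0, 0],
        A=[1, 0, *([np.nan] * 4)],
        U=[2.0, 2.0, *([np.nan] * 4)],
        delta=[1, 1, *([np.nan] * 4)],
        X={"x": [0.1, -0.2, 0.3, 0.0, -0.1, 0.2]},
    )


def _unit_cens():
    return {a: degenerate_censoring(a, ["x"]) for a in (0, 1)}


class TestIPW1:
    def test_hand_computed_value(self, two_plus_four):
        omega = np.full(6, 0.5)
        est = estimate_ipw1(two_plus_four, omega, _unit_cens(), [1.0])
        assert est.S1[0] == pytest.approx(0.5, abs=1e-12)
        assert est.S0[0] == pytest.approx(0.5, abs=1e-12)
        assert est.delta[0] == pytest.approx(0.0, abs=1e-12)

    def test_not_normalized_at_zero(self, two_plus_four):
        omega = np.full(6, 0.25)  # tau = 3
        est = estimate_ipw1(two_plus_four, omega, _unit_cens(), [0.0])
        # per arm: 3 / (0.5 * 4) = 1.5, not 1
        assert est.S1[0] == pytest.approx(1.5, abs=1e-12)

    def test_zero_beyond_last_time(self, two_plus_four):
        est = estimate_ipw1(two_plus_four, np.full(6, 0.5), _unit_cens(), [5.0])
        assert est.S1[0] == 0.0 and est.S0[0] == 0.0

    def test_pi_scaling(self, two_plus_four, ten_record_sample, ten_record_nuisances):
        omega, cens, _ = ten_record_nuisances
        s = ten_record_sample
        base = estimate_ipw1(s, omega, cens, [1.0])
        alt_sample = make_sample(
            S=s.S, A=s.A, U=s.U, delta=s.delta, X=s.X, w=s.w_survey, pi=0.25
        )
        alt = estimate_ipw1(alt_sample, omega, cens, [1.0])
        assert alt.S1[0] == pytest.approx(base.S1[0] * 0.4 / 0.25, rel=1e-12)
        assert alt.S0[0] == pytest.approx(base.S0[0] * 0.6 / 0.75, rel=1e-12)

    def test_matches_naive_oracle(self, ten_record_sample, ten_record_nuisances):
        omega, cens, _ = ten_record_nuisances
        for t in (0.5, 1.2, 2.5):
            est = estimate_ipw1(ten_record_sample, omega, cens, [t])
            for a, val in ((1, est.S1[0]), (0, est.S0[0])):
                ref = oracle.naive_ipw1(ten_record_sample, omega, cens, a, t)
                assert val == pytest.approx(ref, abs=1e-12)


class TestIPW2:
    def test_single_subject_arm_is_one(self, two_plus_four):
        est = estimate_ipw2(two_plus_four, np.full(6, 0.3), _unit_cens(), [1.0])
        assert est.S1[0] == pytest.approx(1.0, abs=1e-12)
        assert est.S0[0] == pytest.approx(1.0, abs=1e-12)

    def test_constant_omega_gives_empirical_fraction(self):
        s = make_sample(
            S=[1, 1, 1, 1, 0],
            A=[1, 1, 1, 0, np.nan],
            U=[0.5, 1.5, 2.5, 1.0, np.nan],
            delta=[1, 1, 1, 1, np.nan],
            X={"x": [0.0] * 5},
        )
        est = estimate_ipw2(s, np.full(5, 0.4), _unit_cens(), [1.0])
        assert est.S1[0] == pytest.approx(2 / 3, abs=1e-12)

    def test_pi_invariance_bit_identical(self, ten_record_sample, ten_record_nuisances):
        omega, cens, _ = ten_record_nuisances
        s = ten_record_sample
        alt_sample = make_sample(
            S=s.S, A=s.A, U=s.U, delta=s.delta, X=s.X, w=s.w_survey, pi=0.3
        )
        a = estimate_ipw2(s, omega, cens, [0.5, 1.2])
        b = estimate_ipw2(alt_sample, omega, cens, [0.5, 1.2])
        assert np.array_equal(a.S1, b.S1) and np.array_equal(a.S0, b.S0)

    def test_survey_weights_only_enter_via_score(self, ten_record_sample, ten_record_nuisances):
        omega, cens, _ = ten_record_nuisances
        s = ten_record_sample
        reweighted = make_sample(
            S=s.S, A=s.A, U=s.U, delta=s.delta, X=s.X,
            w=np.where(s.trial, 1.0, 3.0 * s.w_survey), pi=s.pi,
        )
        a = estimate_ipw2(s, omega, cens, [1.2])
        b = estimate_ipw2(reweighted, omega, cens, [1.2])
        assert np.array_equal(a.S1, b.S1) and np.array_equal(a.S0, b.S0)

    def test_matches_naive_oracle(self, ten_record_sample, ten_record_nuisances):
        omega, cens, _ = ten_record_nuisances
        for t in (0.5, 1.2, 2.5):
            est = estimate_ipw2(ten_record_sample, omega, cens, [t])
            for a, val in ((1, est.S1[0]), (0, est.S0[0])):
                ref = oracle.naive_ipw2(ten_record_sample, omega, cens, a, t)
                assert val == pytest.approx(ref, abs=1e-12)


class TestOM:
    def test_constant_model(self, two_plus_four):
        outm = {a: _ValueOutcome() for a in (0, 1)}
        s = make_sample(
            S=[1, 1, 0, 0], A=[1, 0, np.nan, np.nan], U=[1, 1, np.nan, np.nan],
            delta=[1, 1, np.nan, np.nan], X={"h": [0.7, 0.7, 0.7, 0.7]},
        )
        est = estimate_om(s, outm, [0.5, 1.5])
        assert np.allclose(est.S1, 0.7) and np.allclose(est.S0, 0.7)

    def test_weighted_mean(self):
        s = make_sample(
            S=[1, 1, 0, 0], A=[1, 0, np.nan, np.nan], U=[1, 1, np.nan, np.nan],
            delta=[1, 1, np.nan, np.nan], X={"h": [0.9, 0.9, 0.8, 0.4]},
            w=[1, 1, 1, 3],
        )
        est = estimate_om(s, {a: _ValueOutcome() for a in (0, 1)}, [1.0])
        assert est.S1[0] == pytest.approx(0.5, abs=1e-12)

    def test_time_zero_is_one(self, weak_cox_sample, weak_cox_fits):
        _, _, out = weak_cox_fits
        est = estimate_om(weak_cox_sample, out, [0.0])
        assert est.S1[0] == pytest.approx(1.0, abs=1e-12)
        assert est.S0[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_naive_oracle(self, ten_record_sample, ten_record_nuisances):
        _, _, out = ten_record_nuisances
        est = estimate_om(ten_record_sample, out, [1.2])
        assert est.S1[0] == pytest.approx(
            oracle.naive_om(ten_record_sample, out, 1, 1.2), abs=1e-12
        )


class TestMartingaleAugmentation:
    def test_event_subject_no_jumps(self):
        cens = degenerate_censoring(1, ["x"])
        out = cox_outcome(1, ["x"], [0.0], [0.5], [0.2])
        assert martingale_augmentation(1.0, 1.0, {"x": 0.3}, cens, out, 2.0) == 0.0

    def test_single_jump_hand_value(self):
        # censored at U=1 <= t=2, K(1-)=1 (no censoring jumps), H(2)/H(1)=0.5
        cens = degenerate_censoring(1, ["x"])
        out = cox_outcome(1, ["x"], [0.0], [0.5, 1.5], [0.2, np.log(2.0)])
        val = martingale_augmentation(1.0, 0.0, {"x": 0.0}, cens, out, 2.0)
        assert val == pytest.approx(0.5, abs=1e-12)

    def test_time_zero_is_zero(self, ten_record_sample, ten_record_nuisances):
        _, cens, out = ten_record_nuisances
        for i in range(6):
            row = ten_record_sample.X.iloc[i]
            a = int(ten_record_sample.A[i])
            val = martingale_augmentation(
                ten_record_sample.U[i], ten_record_sample.delta[i], row,
                cens[a], out[a], 0.0,
            )
            assert val == 0.0

    def test_matches_naive_oracle(self, ten_record_sample, ten_record_nuisances):
        _, cens, out = ten_record_nuisances
        for t in (0.5, 1.2, 2.5):
            for i in range(6):
                a = int(ten_record_sample.A[i])
                row = ten_record_sample.X.iloc[i]
                val = martingale_augmentation(
                    ten_record_sample.U[i], ten_record_sample.delta[i], row,
                    cens[a], out[a], t,
                )
                ref = oracle.naive_aug(ten_record_sample, i, cens[a], out[a], t)
                assert val == pytest.approx(ref, abs=1e-12)


class TestDR1:
    def test_zero_trial_weight_equals_om(self, ten_record_sample, ten_record_nuisances):
        _, cens, out = ten_record_nuisances
        omega_one = np.ones(10)  # tau = 0: trial terms vanish
        dr = estimate_dr1(ten_record_sample, omega_one, cens, out, [1.2])
        om = estimate_om(ten_record_sample, out, [1.2])
        assert dr.S1[0] == pytest.approx(om.S1[0], abs=1e-15)
        assert dr.S0[0] == pytest.approx(om.S0[0], abs=1e-15)

    def test_time_zero_is_one(self, ten_record_sample, ten_record_nuisances):
        omega, cens, out = ten_record_nuisances
        est = estimate_dr1(ten_record_sample, omega, cens, out, [0.0])
        assert est.S1[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_naive_oracle(self, ten_record_sample, ten_record_nuisances):
        omega, cens, out = ten_record_nuisances
        for t in (0.5, 1.2, 2.5):
            est = estimate_dr1(ten_record_sample, omega, cens, out, [t])
            for a, val in ((1, est.S1[0]), (0, est.S0[0])):
                ref = oracle.naive_dr1(ten_record_sample, omega, cens, out, a, t)
                assert val == pytest.approx(ref, abs=1e-12)

    def test_unit_weight_reduction(self, ten_record_sample, ten_record_nuisances):
        # with all survey weights 1, the survey form reduces to the unweighted
        # estimator: the naive oracle with w=1 is exactly the unweighted formula
        omega, cens, out = ten_record_nuisances
        s = ten_record_sample
        unit = make_sample(S=s.S, A=s.A, U=s.U, delta=s.delta, X=s.X, pi=s.pi)
        est = estimate_dr1(unit, omega, cens, out, [1.2])
        ref = oracle.naive_dr1(unit, omega, cens, out, 1, 1.2)
        assert est.S1[0] == pytest.approx(ref, abs=1e-12)


class TestDR2:
    def test_pi_invariance(self, ten_record_sample, ten_record_nuisances):
        omega, cens, out = ten_record_nuisances
        s = ten_record_sample
        alt_sample = make_sample(
            S=s.S, A=s.A, U=s.U, delta=s.delta, X=s.X, w=s.w_survey, pi=0.2
        )
        a = estimate_dr2(s, omega, cens, out, [0.5, 1.2])
        b = estimate_dr2(alt_sample, omega, cens, out, [0.5, 1.2])
        assert np.array_equal(a.S1, b.S1) and np.array_equal(a.S0, b.S0)

    def test_decomposition_identity(self, weak_cox_sample, weak_cox_fits):
        omega, cens, out = weak_cox_fits
        est = estimate_dr2(weak_cox_sample, omega, cens, out, [0.128, 0.331, 0.712])
        for j, t in enumerate([0.128, 0.331, 0.712]):
            for a, val in ((1, est.S1[j]), (0, est.S0[j])):
                nu1, nu2 = dr2_decomposition(weak_cox_sample, omega, cens, out, a, t)
                assert nu1 + nu2 == pytest.approx(val, abs=1e-12)

    def test_matches_naive_oracle(self, ten_record_sample, ten_record_nuisances):
        omega, cens, out = ten_record_nuisances
        for t in (0.5, 1.2, 2.5):
            est = estimate_dr2(ten_record_sample, omega, cens, out, [t])
            for a, val in ((1, est.S1[0]), (0, est.S0[0])):
                ref = oracle.naive_dr2(ten_record_sample, omega, cens, out, a, t)
                assert val == pytest.approx(ref, abs=1e-12)

    def test_survey_weights_enter_outcome_term_only(
        self, ten_record_sample, ten_record_nuisances
    ):
        # reweighting the survey sample changes DR2 (outcome term) but only
        # through that term: nu1 stays fixed
        omega, cens, out = ten_record_nuisances
        s = ten_record_sample
        rew = make_sample(
            S=s.S, A=s.A, U=s.U, delta=s.delta, X=s.X,
            w=np.where(s.trial, 1.0, s.w_survey**2), pi=s.pi,
        )
        nu1_a, nu2_a = dr2_decomposition(s, omega, cens, out, 1, 1.2)
        nu1_b, nu2_b = dr2_decomposition(rew, omega, cens, out, 1, 1.2)
        assert nu1_a == pytest.approx(nu1_b, abs=1e-15)
        assert nu2_a != pytest.approx(nu2_b, abs=1e-6)


class TestWeightPlacement:
    """Survey weights must enter IPW1/DR1/DR2 but not IPW2 (given omega)."""

    def test_reweighting_shifts_all_but_ipw2(self, ten_record_sample, ten_record_nuisances):
        omega, cens, out = ten_record_nuisances
        s = ten_record_sample
        rew = make_sample(
            S=s.S, A=s.A, U=s.U, delta=s.delta, X=s.X,
            w=np.where(s.trial, 1.0, s.w_survey**2), pi=s.pi,
        )
        t = [1.2]
        assert estimate_ipw1(s, omega, cens, t).S1[0] != pytest.approx(
            estimate_ipw1(rew, omega, cens, t).S1[0], abs=1e-9
        )
        assert estimate_dr1(s, omega, cens, out, t).S1[0] != pytest.approx(
            estimate_dr1(rew, omega, cens, out, t).S1[0], abs=1e-9
        )
        assert estimate_dr2(s, omega, cens, out, t).S1[0] != pytest.approx(
            estimate_dr2(rew, omega, cens, out, t).S1[0], abs=1e-9
        )
        assert estimate_ipw2(s, omega, cens, t).S1[0] == pytest.approx(
            estimate_ipw2(rew, omega, cens, t).S1[0], abs=1e-15
        )


class TestWKM:
    def test_equal_weights_is_plain_km(self, weak_cox_sample):
        from lifelines import KaplanMeierFitter

        s = weak_cox_sample
        omega = np.full(s.S.size, 0.3)
        times = [0.2, 0.5, 1.0]
        est = estimate_wkm(s, omega, times)
        for a, vals in ((1, est.S1), (0, est.S0)):
            mask = s.arm(a)
            km = KaplanMeierFitter().fit(s.U[mask], s.delta[mask])
            for t, v in zip(times, vals):
                # left limit: evaluate the right-continuous KM just before t
                assert v == pytest.approx(
                    float(km.predict(t - 1e-9)), abs=1e-10
                )

    def test_no_censoring_weighted_empirical(self):
        s = make_sample(
            S=[1, 1, 1, 1, 0],
            A=[1, 1, 1, 0, np.nan],
            U=[0.5, 1.0, 2.0, 1.0, np.nan],
            delta=[1, 1, 1, 1, np.nan],
            X={"x": [0.0] * 5},
        )
        omega = np.array([0.5, 0.25, 0.2, 0.5, 0.5])  # tau = 1, 3, 4, 1
        est = estimate_wkm(s, omega, [1.0])
        # weighted share of arm-1 subjects with U >= 1: (3+4)/8
        assert est.S1[0] == pytest.approx(7 / 8, abs=1e-12)

    def test_matches_naive_oracle(self, ten_record_sample, ten_record_nuisances):
        omega, _, _ = ten_record_nuisances
        s = ten_record_sample
        est = estimate_wkm(s, omega, [0.5, 1.2, 2.5])
        for a, vals in ((1, est.S1), (0, est.S0)):
            mask = s.arm(a)
            tau = (1 - omega[mask]) / omega[mask]
            for t, v in zip((0.5, 1.2, 2.5), vals):
                ref = oracle.naive_wkm(
                    s.U[mask], s.delta[mask].astype(int), tau, t
                )
                assert v == pytest.approx(ref, abs=1e-12)


class TestCurveProperties:
    def test_weighting_curves_nonincreasing(self, weak_cox_sample, weak_cox_fits):
        omega, cens, _ = weak_cox_fits
        grid = np.linspace(0.0, 2.0, 40)
        for fn, args in (
            (estimate_ipw1, (weak_cox_sample, omega, cens, grid)),
            (estimate_ipw2, (weak_cox_sample, omega, cens, grid)),
            (estimate_wkm, (weak_cox_sample, omega, grid)),
        ):
            est = fn(*args)
            assert np.all(np.diff(est.S1) <= 1e-12)
            assert np.all(np.diff(est.S0) <= 1e-12)

    def test_delta_identity(self, weak_cox_sample, weak_cox_fits):
        omega, cens, out = weak_cox_fits
        est = estimate_dr2(weak_cox_sample, omega, cens, out, [0.128, 0.712])
        assert np.array_equal(est.delta, est.S1 - est.S0)

    def test_dr_not_clipped(self, ten_record_sample, ten_record_nuisances):
        omega, cens, out = ten_record_nuisances
        est = estimate_dr1(ten_record_sample, omega, cens, out, [0.5, 2.9])
        assert est.out_of_range.dtype == bool  # flag exists; no clipping applied


class TestTaste:
    def test_equal_curves_zero(self, two_plus_four):
        est = estimate_ipw2(two_plus_four, np.full(6, 0.5), _unit_cens(), [1.0])
        d, se, (lo, hi) = taste(est, 1.0)
        assert d == 0.0

    def test_difference_value(self):
        from survtransport.estimators import SurvivalCurveEstimate

        est = SurvivalCurveEstimate(
            estimator="OM", times=np.array([1.0]), S1=np.array([0.8]),
            S0=np.array([0.7]), delta=np.array([0.1]), se=np.array([0.05]),
            ci_lo=np.array([0.0]), ci_hi=np.array([0.2]),
            out_of_range=np.array([False]),
        )
        d, se, ci = taste(est, 1.0)
        assert d == pytest.approx(0.1)
        assert se == pytest.approx(0.05)

    def test_wald_width(self, weak_cox_sample, weak_cox_fits):
        omega, cens, out = weak_cox_fits
        est = estimate_dr2(weak_cox_sample, omega, cens, out, [0.712])
        d, se, (lo, hi) = taste(est, 0.712)
        assert hi - lo == pytest.approx(2 * 1.959963984540054 * se, rel=1e-9)

    def test_off_grid_refused(self, two_plus_four):
        est = estimate_ipw2(two_plus_four, np.full(6, 0.5), _unit_cens(), [1.0])
        with pytest.raises(EstimationError):
            taste(est, 0.9)
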