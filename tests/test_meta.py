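"""Tests for the random-effects estimator layer.

The iterative estimators are checked against independent oracles:
brute-force grid maximization of the (restricted) log-likelihood, direct
evaluation of the closed moment forms, residuals of the generalized-Q
equations, and reference values from the metafor R package (version
4.8-0, rma with test="knha" and confint) frozen below.
"""

import io

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from hetsim.meta import (ESTIMATORS, MetaSample, fit, i_squared,
                         kh_inference, pool_effect, read_study_table,
                         tau2_dl, tau2_hs, tau2_ml, tau2_pm, tau2_reml,
                         tau_ci, write_study_table)

from oracles import (eq4_moment_form, grid_argmax, ml_loglik,
                     random_samples, reml_loglik)


# ------------------------------------------------------------ moment forms


class TestMomentEstimators:
    def test_dl_hand_example(self):
        # w=25 each, Q=8, k-1=2, denominator 50
        s = MetaSample([0.1, 0.5, 0.9], [0.04] * 3)
        assert tau2_dl(s) == pytest.approx(0.12, abs=1e-12)

    def test_hs_hand_example(self):
        s = MetaSample([0.1, 0.5, 0.9], [0.04] * 3)
        assert tau2_hs(s) == pytest.approx(5.0 / 75.0, abs=1e-12)

    def test_hs_k2_direct_formula(self):
        s = MetaSample([0.0, 0.2], [0.04, 0.04])
        w = 1 / s.v
        th = (w * s.g).sum() / w.sum()
        expected = max(0.0, ((w * (s.g - th) ** 2).sum() - 2) / w.sum())
        assert tau2_hs(s) == pytest.approx(expected, abs=1e-12)

    def test_zero_dispersion_truncates_to_zero(self):
        s = MetaSample([0.3] * 4, [0.05, 0.08, 0.02, 0.1])
        assert tau2_dl(s) == 0.0
        assert tau2_hs(s) == 0.0
        assert tau2_pm(s)[0] == 0.0
        assert tau2_ml(s)[0] == 0.0
        assert tau2_reml(s)[0] == 0.0

    def test_dl_equals_general_moment_form_with_fe_weights(self):
        for s in random_samples(100, seed=5):
            expected = max(0.0, eq4_moment_form(s.g, s.v, 1.0 / s.v))
            assert tau2_dl(s) == pytest.approx(expected, abs=1e-12)

    def test_pm_is_general_moment_form_at_its_own_weights(self):
        # at the PM solution, plugging random-effects weights into the
        # general moment form returns the same tau^2 (fixed point)
        for s in random_samples(30, seed=6):
            t2, conv = tau2_pm(s)
            assert conv
            if t2 > 0:
                w = 1.0 / (s.v + t2)
                assert eq4_moment_form(s.g, s.v, w) == pytest.approx(
                    t2, abs=1e-7)


class TestIterativeEstimators:
    def test_pm_equal_variance_closed_form(self):
        s = MetaSample([0.1, 0.5, 0.9], [0.04] * 3)
        assert tau2_pm(s)[0] == pytest.approx(0.12, abs=1e-8)

    def test_pm_generalized_q_residual(self):
        for s in random_samples(50, seed=7, k_range=(5, 6)):
            t2, _ = tau2_pm(s)
            if t2 > 0:
                w = 1.0 / (s.v + t2)
                th = (w * s.g).sum() / w.sum()
                q = (w * (s.g - th) ** 2).sum()
                assert q == pytest.approx(s.k - 1, abs=1e-8)

    def test_ml_equal_variance_closed_form(self):
        # mean squared deviation minus v
        s = MetaSample([0.1, 0.5, 0.9], [0.04] * 3)
        assert tau2_ml(s)[0] == pytest.approx(0.32 / 3 - 0.04, abs=1e-8)

    def test_reml_equal_variance_closed_form(self):
        # unbiased between-study variance minus v
        s = MetaSample([0.1, 0.5, 0.9], [0.04] * 3)
        assert tau2_reml(s)[0] == pytest.approx(0.12, abs=1e-8)

    def test_ml_matches_grid_search_likelihood_maximizer(self):
        for s in random_samples(50, seed=8):
            t2, conv = tau2_ml(s)
            assert conv
            oracle = grid_argmax(ml_loglik, s.g, s.v)
            assert t2 == pytest.approx(oracle, abs=1e-4)

    def test_reml_matches_grid_search_likelihood_maximizer(self):
        for s in random_samples(50, seed=9):
            t2, conv = tau2_reml(s)
            assert conv
            oracle = grid_argmax(reml_loglik, s.g, s.v)
            assert t2 == pytest.approx(oracle, abs=1e-4)

    def test_equal_variance_closed_forms_agree_across_estimators(self):
        """On equal-variance samples DL = PM = REML = sample variance of
        effects minus v; ML equals the mean-squared form."""
        for s in random_samples(50, seed=10, equal_v=True):
            dev2 = ((s.g - s.g.mean()) ** 2).sum()
            expected = max(0.0, dev2 / (s.k - 1) - s.v[0])
            ml_expected = max(0.0, dev2 / s.k - s.v[0])
            assert tau2_dl(s) == pytest.approx(expected, abs=1e-10)
            assert tau2_pm(s)[0] == pytest.approx(expected, abs=1e-8)
            assert tau2_reml(s)[0] == pytest.approx(expected, abs=1e-8)
            assert tau2_ml(s)[0] == pytest.approx(ml_expected, abs=1e-8)


@given(st.integers(0, 2 ** 32 - 1))
def test_estimators_nonnegative_and_theta_in_hull(seed):
    s = random_samples(1, seed=seed)[0]
    for est in ESTIMATORS:
        f = fit(s, est, with_tau_ci=False)
        assert f.tau2_hat >= 0.0
        assert s.g.min() - 1e-12 <= f.theta_hat <= s.g.max() + 1e-12
        assert 0.0 <= f.i_squared <= 100.0


# ------------------------------------------------------- pooling/inference


class TestPooling:
    def test_equal_weights_give_unweighted_mean(self):
        s = MetaSample([0.1, 0.5, 0.9], [0.04] * 3)
        th, w = pool_effect(s, 0.3)
        assert th == pytest.approx(0.5, abs=1e-14)
        assert np.allclose(w, w[0])

    def test_hand_computed_weights(self):
        s = MetaSample([0.0, 1.0], [0.01, 0.99])
        th, w = pool_effect(s, 0.0)
        assert w == pytest.approx([100.0, 1.0 / 0.99])
        assert th == pytest.approx((1 / 0.99) / (100 + 1 / 0.99), abs=1e-12)

    def test_single_study_rejected(self):
        with pytest.raises(ValueError):
            MetaSample([0.1], [0.04])


class TestKnappHartung:
    def test_degenerate_sample_gives_p_one(self):
        s = MetaSample([0.4, 0.4, 0.4], [0.04] * 3)
        se, t, p, ci = kh_inference(s, 0.0, 0.4)
        assert p == 1.0
        assert ci == (0.4, 0.4)

    def test_hand_example(self):
        # w=6.25 each at DL tau2=0.12; s2 = 6.25*0.32/2 = 1;
        # Var = 1/18.75; t = 0.5/sqrt(1/18.75); df=2
        s = MetaSample([0.1, 0.5, 0.9], [0.04] * 3)
        se, t, p, ci = kh_inference(s, tau2_dl(s), 0.5)
        assert se == pytest.approx(np.sqrt(1 / 18.75), abs=1e-12)
        assert t == pytest.approx(0.5 / np.sqrt(1 / 18.75), abs=1e-10)
        assert p == pytest.approx(2 * stats.t.sf(t, 2), abs=1e-12)
        tcrit = stats.t.ppf(0.975, 2)
        assert ci[0] == pytest.approx(0.5 - tcrit * se, abs=1e-12)

    def test_k2_allowed(self):
        s = MetaSample([0.0, 0.5], [0.04, 0.06])
        se, t, p, ci = kh_inference(s, 0.0, pool_effect(s, 0.0)[0])
        assert 0 < p <= 1


class TestTauCI:
    def test_homogeneous_sample_lower_bound_zero(self, het_sample):
        s = MetaSample([0.3, 0.3, 0.31], [0.04] * 3)
        lo, hi = tau_ci(s)
        assert lo == 0.0

    def test_q_profile_residuals_at_bounds(self, het_sample):
        s = het_sample
        lo, hi = tau_ci(s)
        for bound, quant in [(lo, stats.chi2.ppf(0.975, s.k - 1)),
                             (hi, stats.chi2.ppf(0.025, s.k - 1))]:
            if bound > 0:
                w = 1.0 / (s.v + bound ** 2)
                th = (w * s.g).sum() / w.sum()
                q = (w * (s.g - th) ** 2).sum()
                assert q == pytest.approx(quant, abs=1e-6)


class TestISquared:
    def test_hand_example(self):
        # Q=8, k=3 -> 75%
        s = MetaSample([0.1, 0.5, 0.9], [0.04] * 3)
        assert i_squared(s) == pytest.approx(75.0, abs=1e-10)

    def test_truncated_at_zero(self):
        s = MetaSample([0.3, 0.31, 0.29], [0.04] * 3)
        assert i_squared(s) == 0.0


# ------------------------------------------------------ external reference

# Reference values computed once with metafor 4.8-0 in R:
#   rma(yi, vi, method=<est>, test="knha"); confint() for the tau^2 CI.
_METAFOR = {
    #        tau2          theta        kh_se        kh_p        ci_lb         ci_ub        tau2_lb tau2_ub
    "DL":   (0.0863386109, 0.3103009226, 0.1635700963, 0.1163025320, -0.1101693958, 0.7307712410, 0.0, 0.9683107478),
    "HS":   (0.0603437388, 0.2999430989, 0.1620183647, 0.1233438823, -0.1165383666, 0.7164245644, 0.0, 0.9683107478),
    "ML":   (0.0637389426, 0.3015263138, 0.1622633505, 0.1222449941, -0.1155849076, 0.7186375352, 0.0, 0.9683107478),
    "PM":   (0.1015895152, 0.3149156081, 0.1642241104, 0.1132772172, -0.1072359071, 0.7370671233, 0.0, 0.9683107478),
    "REML": (0.0929838638, 0.3124174340, 0.1638728123, 0.1149064769, -0.1088310406, 0.7336659086, 0.0, 0.9683107478),
}


@pytest.mark.parametrize("estimator", ESTIMATORS)
def test_full_fit_matches_metafor_reference(estimator, het_sample):
    tau2, b, se, p, lb, ub, t2lo, t2hi = _METAFOR[estimator]
    f = fit(het_sample, estimator)
    tol = 1e-6 if estimator in ("ML", "REML") else 1e-9
    assert f.tau2_hat == pytest.approx(tau2, abs=tol)
    assert f.theta_hat == pytest.approx(b, abs=tol)
    assert f.kh_se == pytest.approx(se, abs=tol)
    assert f.kh_p == pytest.approx(p, abs=tol)
    assert f.kh_ci[0] == pytest.approx(lb, abs=1e-6)
    assert f.kh_ci[1] == pytest.approx(ub, abs=1e-6)
    assert f.tau_ci[0] ** 2 == pytest.approx(t2lo, abs=1e-4)
    assert f.tau_ci[1] ** 2 == pytest.approx(t2hi, abs=1e-4)
    assert f.q_statistic == pytest.approx(12.7242343013, abs=1e-9)


# ------------------------------------------------------------------- I/O


def test_study_table_roundtrip(tmp_path, het_sample):
    path = tmp_path / "studies.csv"
    write_study_table(het_sample, path)
    back = read_study_table(path)
    np.testing.assert_allclose(back.g, het_sample.g)
    np.testing.assert_allclose(back.v, het_sample.v)


def test_study_table_requires_columns():
    with pytest.raises(ValueError):
        read_study_table(io.StringIO("a,b\n1,2\n3,4\n"))
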