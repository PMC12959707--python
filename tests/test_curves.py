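"""beta(t) machinery: difference quotients, LOESS, the adaptive threshold
and the peak / zero-cross / plateau summary with a brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import lymphrisk as lr
from lymphrisk.curves import MA_WINDOW, moving_average

from conftest import competing_exponential, make_cohort


def curve_from(times, raw, smooth=None):
    return lr.BetaCurve(np.asarray(times, float), np.asarray(raw, float),
                        beta_smooth=None if smooth is None else np.asarray(smooth, float))


# ------------------------- brute-force oracle ----------------------------


def brute_force_summary(times, smooth, raw, alpha=0.01, eps_frac=0.03):
    """Independent implementation of the curve summary by exhaustive scan."""
    times = np.asarray(times, float)
    smooth = np.asarray(smooth, float)
    raw = np.asarray(raw, float)
    n = len(times)
    i_peak = int(np.argmax(smooth))

    t_zero = None
    positive_seen = False
    for i in range(n):
        if smooth[i] > 0:
            positive_seen = True
        elif positive_seen:
            t_zero = times[i]
            break

    resid = raw - smooth
    mad = np.median(np.abs(resid - np.median(resid)))
    thr = max(stats.norm.ppf(1 - alpha / 2) * mad, eps_frac * np.max(np.abs(smooth)))

    half = MA_WINDOW // 2
    ok = np.zeros(n, dtype=bool)
    for i in range(half, n - half):
        ok[i] = np.mean(np.abs(smooth[i - half : i + half + 1])) < thr
    ok &= np.arange(n) > i_peak

    best = None  # (length, start, end)
    for i in range(n):
        for j in range(i + MA_WINDOW - 1, n):
            if ok[i : j + 1].all():
                length = times[j] - times[i]
                if best is None or length > best[0] + 1e-15:
                    best = (length, times[i], times[j])
    plateau = (best[1], best[2]) if best else (None, None)
    return times[i_peak], t_zero, plateau, thr


# ----------------------------- derive_beta --------------------------------


class TestDeriveBeta:
    def test_linear_b_gives_constant_beta(self):
        t, c, _ = competing_exponential(100, seed=1)
        cc = lr.fit_aalen(make_cohort(t, c), [])
        cc.B[:, 0] = 0.07 * cc.grid  # overwrite with an exact line
        curve = lr.derive_beta(cc, "intercept")
        np.testing.assert_allclose(curve.beta_raw, 0.07, atol=1e-12)

    def test_single_jump_height_over_interval(self):
        cc = lr.CumulativeCoefficients(
            grid=np.array([2.0, 5.0]),
            B=np.array([[0.0], [0.6]]),
            V=np.zeros((2, 1, 1)),
            covariates=["intercept"],
            estimable_until=5.0,
        )
        curve = lr.derive_beta(cc, "intercept")
        np.testing.assert_allclose(curve.beta_raw, [0.0, 0.2])  # 0.6/3

    def test_two_group_difference_quotient_by_hand(self):
        # 6 subjects, groups of 3; events at 1 (g1), 2 (g0), 4 (g1)
        t = np.array([1.0, 2.0, 4.0, 5.0, 5.5, 6.0])
        c = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        cc = lr.fit_aalen(make_cohort(t, c, x=x), ["x"])
        curve = lr.derive_beta(cc, "x")
        # B_x jumps: +1/3 at t=1; -1/3 at t=2; +1/2 at t=4
        np.testing.assert_allclose(
            curve.beta_raw, [(1 / 3) / 1.0, (-1 / 3) / 1.0, (1 / 2) / 2.0]
        )

    def test_needs_two_grid_points(self):
        cc = lr.CumulativeCoefficients(
            grid=np.array([1.0]), B=np.zeros((1, 1)), V=np.zeros((1, 1, 1)),
            covariates=["intercept"], estimable_until=1.0,
        )
        with pytest.raises(ValueError, match="2 grid points"):
            lr.derive_beta(cc, "intercept")


# ------------------------------- LOESS -------------------------------------


class TestLoess:
    def test_constant_input_reproduced(self):
        t = np.linspace(0, 10, 50)
        out = lr.loess_smooth(curve_from(t, np.full(50, 0.3)))
        np.testing.assert_allclose(out.beta_smooth, 0.3, atol=1e-12)

    def test_linear_input_reproduced_exactly(self):
        t = np.linspace(0, 10, 60)
        y = 0.2 * t - 0.5
        out = lr.loess_smooth(curve_from(t, y))
        np.testing.assert_allclose(out.beta_smooth, y, atol=1e-10)

    def test_matches_reference_implementation_on_noisy_sine(self):
        from statsmodels.nonparametric.smoothers_lowess import lowess

        rng = np.random.default_rng(0)
        n = 200
        x = np.sort(rng.uniform(0, 10, n)) + np.arange(n) * 1e-9
        y = np.sin(x) + rng.normal(0, 0.3, n)
        ours = lr.loess_smooth(curve_from(x, y), span=0.35).beta_smooth
        ref = lowess(y, x, frac=0.35, it=0, return_sorted=False)
        assert np.max(np.abs(ours - ref)) < 1e-6

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            lr.loess_smooth(curve_from([1, 2, 3], [0, 0, 0]))


# --------------------------- adaptive threshold ----------------------------


class TestAdaptiveThreshold:
    def test_zero_residuals_leave_eps_term(self):
        t = np.linspace(0, 5, 20)
        y = np.sin(t)
        thr = lr.adaptive_threshold(curve_from(t, y, smooth=y))
        assert thr == pytest.approx(0.03 * np.max(np.abs(y)))

    def test_zero_curve_gives_zero_threshold(self):
        t = np.linspace(0, 5, 20)
        thr = lr.adaptive_threshold(curve_from(t, np.zeros(20), smooth=np.zeros(20)))
        assert thr == 0.0

    def test_hand_computed_mad_case(self):
        # residuals {-1, 0, 1}: median 0, MAD 1 -> z_{0.995} * 1 wins over
        # 0.03 * 0.1
        smooth = np.array([0.1, 0.05, 0.0])
        raw = smooth + np.array([-1.0, 0.0, 1.0])
        thr = lr.adaptive_threshold(curve_from([1, 2, 3], raw, smooth=smooth))
        z = stats.norm.ppf(0.995)  # ~2.5758
        assert thr == pytest.approx(z, rel=1e-12)
        assert thr == pytest.approx(2.5758, abs=1e-4)


# ------------------------------ summaries ----------------------------------


class TestSummarizeCurve:
    def test_peaked_profile_recovers_analytic_argmax(self):
        tau = 3.0
        t = np.linspace(0.05, 12, 240)
        y = 0.7 * t * np.exp(-t / tau)  # analytic argmax at tau
        s = lr.summarize_curve(curve_from(t, y, smooth=y))
        assert abs(s.t_peak - tau) <= (t[1] - t[0])

    def test_constant_positive_curve_has_no_crossing_or_plateau(self):
        t = np.linspace(0, 10, 40)
        y = np.full(40, 0.5)
        s = lr.summarize_curve(curve_from(t, y, smooth=y))
        assert s.t_zero_cross is None
        assert s.plateau_start is None  # MA = 0.5 >= threshold 0.015

    def test_constructed_zero_crossing_found(self):
        t = np.linspace(0, 8, 80)
        y = np.where(t < 4.0, 1.0, -0.1)
        s = lr.summarize_curve(curve_from(t, y, smooth=y))
        assert s.t_zero_cross == pytest.approx(t[t >= 4.0][0])

    def test_never_positive_curve_has_no_crossing(self):
        t = np.linspace(0, 8, 30)
        y = -np.ones(30)
        s = lr.summarize_curve(curve_from(t, y, smooth=y))
        assert s.t_zero_cross is None

    def test_fewer_than_seven_points_skips_plateau(self):
        t = np.linspace(1, 5, 5)
        y = np.array([0.1, 0.3, 0.2, 0.1, 0.05])
        s = lr.summarize_curve(curve_from(t, y, smooth=y))
        assert s.t_peak == 2.0
        assert s.plateau_start is None and "plateau" in s.notes

    def test_decaying_curve_has_post_peak_plateau(self):
        t = np.linspace(0, 12, 120)
        y = 0.5 * t * np.exp(-t)  # sharp peak then essentially zero
        raw = y + 1e-6 * np.sin(10 * t)
        s = lr.summarize_curve(curve_from(t, raw, smooth=y))
        assert s.plateau_start is not None
        assert s.plateau_start >= s.t_peak
        assert s.plateau_end > s.plateau_start

    @given(seed=st.integers(0, 100_000))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle_on_random_curves(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(7, 120)
        t = np.sort(rng.uniform(0, 12, n))
        t += np.arange(n) * 1e-9
        smooth = rng.normal(0, 0.2, n).cumsum() / np.sqrt(n)
        raw = smooth + rng.normal(0, rng.uniform(0, 0.1), n)
        s = lr.summarize_curve(curve_from(t, raw, smooth=smooth))
        bf_peak, bf_zero, bf_plateau, bf_thr = brute_force_summary(t, smooth, raw)
        assert s.t_peak == bf_peak
        assert s.t_zero_cross == bf_zero
        assert (s.plateau_start, s.plateau_end) == bf_plateau
        assert s.threshold == pytest.approx(bf_thr, rel=1e-12)

    @given(
        seed=st.integers(0, 10_000),
        scale=st.floats(0.1, 50.0),
        shift=st.floats(-3.0, 20.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_scale_and_shift_equivariance(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        n = 40
        t = np.sort(rng.uniform(0, 10, n)) + np.arange(n) * 1e-9
        smooth = np.sin(t / 2) * np.exp(-t / 5)
        raw = smooth + rng.normal(0, 0.05, n)
        base = lr.summarize_curve(curve_from(t, raw, smooth=smooth))
        scaled = lr.summarize_curve(curve_from(t, scale * raw, smooth=scale * smooth))
        assert scaled.threshold == pytest.approx(scale * base.threshold, rel=1e-9)
        assert scaled.t_peak == base.t_peak
        assert scaled.t_zero_cross == base.t_zero_cross
        assert scaled.plateau_start == base.plateau_start
        shifted = lr.summarize_curve(curve_from(t + shift, raw, smooth=smooth))
        assert shifted.t_peak == pytest.approx(base.t_peak + shift, rel=1e-12, abs=1e-9)
        if base.t_zero_cross is not None:
            assert shifted.t_zero_cross == pytest.approx(base.t_zero_cross + shift, abs=1e-9)
        if base.plateau_start is not None:
            assert shifted.plateau_start == pytest.approx(base.plateau_start + shift, abs=1e-9)


class TestMovingAverage:
    def test_truncated_windows_are_nan(self):
        v = np.arange(10.0)
        ma = moving_average(v, 7)
        assert np.isnan(ma[:3]).all() and np.isnan(ma[-3:]).all()
        assert ma[3] == pytest.approx(np.mean(v[0:7]))
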