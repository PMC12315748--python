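"""SUV/SUVR, SRTM forward/fit, and MRTM2 against independent oracles."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from tautrt import (
    ScanMeta,
    SrtmParams,
    TimeActivityCurve,
    mrtm2_fit,
    srtm_fit,
    srtm_forward,
    suv,
    suv_window,
    suvr,
)
from tautrt.trt_stats import rank_association


class TestSuv:
    def test_printed_dose_weight_example(self, meta):
        # 185 MBq / 74 kg -> 2.5 kBq/g, so 1.5 kBq/mL -> 0.6 g/mL
        assert suv(1.5, meta).value == pytest.approx(0.6)

    def test_zero_concentration(self, meta):
        assert suv(0.0, meta).value == 0.0

    def test_unit_dose_per_weight(self):
        m = ScanMeta("s", injected_dose_mbq=100, body_weight_kg=100)
        assert suv(2.5, m).value == pytest.approx(2.5)

    def test_nonpositive_dose_or_weight_rejected(self):
        with pytest.raises(ValueError):
            ScanMeta("s", injected_dose_mbq=0.0)
        with pytest.raises(ValueError):
            ScanMeta("s", body_weight_kg=-1.0)


class TestSuvWindow:
    def test_constant_window(self, schedule, meta):
        vals = np.zeros(schedule.n_frames)
        vals[-8:] = 1.5  # all late frames equal
        tac = TimeActivityCurve(schedule, vals)
        assert suv_window(tac, meta).value == pytest.approx(suv(1.5, meta).value)

    def test_arithmetic_mean_of_window_frames(self, schedule):
        m = ScanMeta("s", injected_dose_mbq=70, body_weight_kg=70)  # 1 kBq/g
        vals = np.zeros(schedule.n_frames)
        vals[31:35] = [1.0, 2.0, 3.0, 4.0]  # the four 90-110 frames
        tac = TimeActivityCurve(schedule, vals)
        assert suv_window(tac, m).value == pytest.approx(2.5)

    def test_window_average_matches_dense_quadrature(self, schedule, ref_tac, meta):
        # AD-like high-binding target: frame-average output vs continuous
        # window mean of the same model evaluated by quadrature
        params = SrtmParams(r1=0.83, k2=0.83 * 0.04, bp=1.66)
        tgt = srtm_forward(ref_tac, params)
        got = suv_window(tgt, meta).value

        k2a = params.k2a
        piecewise = _piecewise_ref(ref_tac)

        def conv(t):
            val, _ = quad(lambda s: piecewise(s) * np.exp(-k2a * (t - s)), 0.0, t, limit=400)
            return val

        def ct(t):
            return params.r1 * piecewise(t) + (params.k2 - params.r1 * k2a) * conv(t)

        ts = np.linspace(90, 110, 81)
        dense = np.trapezoid([ct(t) for t in ts], ts) / 20.0
        expected = suv(dense, meta).value
        assert got == pytest.approx(expected, rel=0.01)


class TestSuvr:
    def test_identity(self, meta):
        x = suv(1.3, meta)
        assert suvr(x, x) == 1.0

    def test_simple_ratio(self, meta):
        assert suvr(suv(0.6 * 2.5, meta), suv(0.5 * 2.5, meta)) == pytest.approx(1.2)

    def test_scales_linearly_and_inversely(self, meta):
        t, r = suv(2.0, meta), suv(1.0, meta)
        assert suvr(suv(2.0 * 3, meta), r) == pytest.approx(3 * suvr(t, r))
        assert suvr(t, suv(1.0 * 2, meta)) == pytest.approx(suvr(t, r) / 2)

    def test_mismatches_rejected(self, meta):
        t = suv(1.0, meta)
        with pytest.raises(ValueError):
            suvr(t, suv(0.0, meta))
        with pytest.raises(ValueError, match="window"):
            suvr(t, suv(1.0, meta, window=(80, 100)))
        with pytest.raises(ValueError, match="PVC"):
            suvr(t, suv(1.0, meta, pvc_applied=True))


def _piecewise_ref(ref_tac):
    """Continuous representation the forward model integrates: piecewise
    constant on frames, linear midpoint bridge across gaps, constant before
    the first frame."""
    sched = ref_tac.schedule
    v = ref_tac.values

    def c(t):
        if t <= sched.starts[0]:
            return v[0]
        i = int(np.searchsorted(sched.ends, t, side="left"))
        i = min(i, sched.n_frames - 1)
        if t >= sched.starts[i]:
            return v[i]
        m0, m1 = sched.midpoints[i - 1], sched.midpoints[i]
        return v[i - 1] + (v[i] - v[i - 1]) * (t - m0) / (m1 - m0)

    return c


class TestSrtmForward:
    def test_identity_parameters_reproduce_reference(self, ref_tac):
        out = srtm_forward(ref_tac, SrtmParams(r1=1.0, k2=0.07, bp=0.0))
        assert np.array_equal(out.values, ref_tac.values)

    def test_zero_reference_gives_zero_target(self, schedule):
        zero = TimeActivityCurve(schedule, np.zeros(schedule.n_frames))
        out = srtm_forward(zero, SrtmParams(0.8, 0.05, 0.5))
        assert np.all(out.values == 0.0)

    def test_nonphysical_parameters_rejected(self):
        with pytest.raises(ValueError):
            SrtmParams(0.8, -0.05, 0.5)
        with pytest.raises(ValueError):
            SrtmParams(0.8, 0.05, -1.0)

    def test_against_ode_oracle(self, ref_tac):
        # independent route: integrate dX/dt = C_R(t) - k2a X with stiff-safe
        # scipy solve_ivp on the same continuous reference representation,
        # then frame-average C_T = R1 C_R + (k2 - R1 k2a) X numerically
        params = SrtmParams(r1=0.8, k2=0.05, bp=0.5)
        got = srtm_forward(ref_tac, params).values
        c = _piecewise_ref(ref_tac)
        k2a = params.k2a
        sched = ref_tac.schedule

        # integrate segment by segment (restart at frame boundaries where the
        # forcing jumps) so the solver only ever sees a smooth RHS
        breaks = np.unique(np.concatenate([[0.0], sched.starts, sched.ends]))
        solutions = []
        x0 = 0.0
        for a, b in zip(breaks[:-1], breaks[1:]):
            sol = solve_ivp(
                lambda t, x: [c(min(t, b - 1e-9)) - k2a * x[0]],
                (a, b),
                [x0],
                method="LSODA",
                dense_output=True,
                rtol=1e-10,
                atol=1e-13,
            )
            solutions.append((a, b, sol.sol))
            x0 = float(sol.y[0, -1])

        def x_of(t):
            for a, b, f in solutions:
                if a - 1e-12 <= t <= b + 1e-12:
                    return float(f(min(max(t, a), b))[0])
            raise AssertionError(f"time {t} outside solution span")

        beta = params.k2 - params.r1 * k2a
        for i in range(sched.n_frames):
            # the reference is constant within a frame, so its frame average
            # is the frame value; the continuous convolution state X is
            # averaged by quadrature
            ts = np.linspace(sched.starts[i], sched.ends[i], 41)
            x_avg = np.trapezoid([x_of(t) for t in ts], ts) / (
                sched.ends[i] - sched.starts[i]
            )
            expected = params.r1 * ref_tac.values[i] + beta * x_avg
            assert got[i] == pytest.approx(expected, rel=5e-3)


class TestSrtmFit:
    @pytest.mark.parametrize("r1,bp", [(0.8, 0.5), (0.66, 0.0), (1.39, 2.0), (1.0, 1.0)])
    def test_noise_free_recovery(self, ref_tac, r1, bp):
        truth = SrtmParams(r1=r1, k2=r1 * 0.04, bp=bp)
        tgt = srtm_forward(ref_tac, truth)
        fit, diag = srtm_fit(tgt, ref_tac)
        assert fit.r1 == pytest.approx(r1, rel=0.01)
        assert fit.bp == pytest.approx(bp, abs=0.02 * (1 + bp))
        assert not diag["boundary"]

    def test_target_equal_reference_is_flagged_unidentifiable(self, ref_tac):
        fit, diag = srtm_fit(ref_tac, ref_tac)
        assert fit.r1 == pytest.approx(1.0, rel=1e-6)
        assert fit.bp == pytest.approx(0.0, abs=1e-6)
        assert diag["k2_unidentifiable"]

    def test_all_zero_target_rejected(self, ref_tac, schedule):
        zero = TimeActivityCurve(schedule, np.zeros(schedule.n_frames))
        with pytest.raises(ValueError, match="degenerate"):
            srtm_fit(zero, ref_tac)

    def test_median_r1_recovery_under_noise(self, ref_tac, rng):
        truth = SrtmParams(r1=0.9, k2=0.9 * 0.04, bp=0.3)
        clean = srtm_forward(ref_tac, truth).values
        r1s = []
        for _ in range(100):
            noisy = clean + 0.05 * np.abs(clean) * rng.standard_normal(clean.size)
            fit, _ = srtm_fit(
                TimeActivityCurve(ref_tac.schedule, noisy), ref_tac
            )
            r1s.append(fit.r1)
        assert np.median(r1s) == pytest.approx(truth.r1, rel=0.03)


class TestMrtm2:
    def test_target_equal_reference_gives_unit_dvr(self, ref_tac):
        fit = mrtm2_fit(ref_tac, ref_tac, t_star=30.0, k2_prime=0.04)
        assert fit.dvr == pytest.approx(1.0, rel=5e-3)
        assert fit.n_frames_used >= 3

    def test_dvr_equals_one_plus_bp_with_matching_k2_prime(self, ref_tac):
        truth = SrtmParams(r1=0.9, k2=0.05, bp=0.8)
        tgt = srtm_forward(ref_tac, truth)
        fit = mrtm2_fit(tgt, ref_tac, t_star=30.0, k2_prime=truth.k2 / truth.r1)
        assert fit.dvr == pytest.approx(1.8, rel=0.02)

    def test_dvr_rank_order_matches_binding(self, ref_tac):
        params = [
            SrtmParams(0.69, 0.69 * 0.04, 0.08),
            SrtmParams(0.91, 0.91 * 0.04, -0.24),
            SrtmParams(0.90, 0.90 * 0.04, 0.00),
            SrtmParams(1.06, 1.06 * 0.04, -0.14),
            SrtmParams(0.83, 0.83 * 0.04, 1.42),
            SrtmParams(1.39, 1.39 * 0.04, -0.35),
        ]
        dvrs = [
            mrtm2_fit(srtm_forward(ref_tac, p), ref_tac, k2_prime=0.04).dvr
            for p in params
        ]
        truth = [1 + p.bp for p in params]
        assert np.array_equal(np.argsort(dvrs), np.argsort(truth))

    def test_too_few_late_frames_rejected(self, ref_tac):
        with pytest.raises(ValueError, match="t\\*"):
            mrtm2_fit(ref_tac, ref_tac, t_star=115.0)

    def test_singular_design_rejected(self, ref_tac):
        # with an enormous k2' the two regressors collapse onto each other
        with pytest.raises(ValueError, match="singular"):
            mrtm2_fit(ref_tac, ref_tac, t_star=30.0, k2_prime=1e12)


def test_suvr_and_dvr_rank_correlated_across_regions(ref_tac, meta):
    """Late-window SUVR and MRTM2 DVR order phantom regions the same way."""
    from tautrt.phantoms import GROUP_PROFILES

    suvrs, dvrs = [], []
    ref_suv = suv_window(ref_tac, meta).value
    for name, (r1, bp) in GROUP_PROFILES["oCN"].items():
        p = SrtmParams(r1, r1 * 0.04, bp)
        tgt = srtm_forward(ref_tac, p)
        suvrs.append(suv_window(tgt, meta).value / ref_suv)
        dvrs.append(mrtm2_fit(tgt, ref_tac, k2_prime=0.04).dvr)
    rho, _ = rank_association(suvrs, dvrs)
    assert rho >= 0.84
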