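"""LOS kinetics: transform arithmetic, segmentation, per-phase inversion,
AUC/HI/EGI, and exact parameter recovery on uniform grids."""

import numpy as np
import pytest

import starchkin as sk
from starchkin.los import LOSPoint


def make_points(xs, ys):
    return [LOSPoint(x=float(x), y=float(y), from_index=i) for i, (x, y) in enumerate(zip(xs, ys))]


class TestLosTransform:
    def test_hand_arithmetic(self):
        curve = sk.DigestionCurve(times=np.array([0.0, 1.0, 2.0]),
                                  C=np.array([0.0, 10.0, 15.0]))
        points, dropped = sk.los_transform(curve)
        assert dropped == 0
        assert points[0].x == pytest.approx(0.5)
        assert points[0].y == pytest.approx(np.log(10.0))
        assert points[1].x == pytest.approx(1.5)
        assert points[1].y == pytest.approx(np.log(5.0))

    def test_exact_curve_collinear_slope_minus_k(self):
        k, c_inf = 0.03, 75.0
        curve = sk.gen_digestion_curve([sk.PhaseSpec(k=k, C_inf=c_inf, t_end=540.0)],
                                       times=sk.UNIFORM_5MIN_GRID)
        points, _ = sk.los_transform(curve)
        xs = np.array([p.x for p in points])
        ys = np.array([p.y for p in points])
        slope, intercept = np.polyfit(xs, ys, 1)
        residual = ys - (slope * xs + intercept)
        assert slope == pytest.approx(-k, rel=1e-10)
        assert np.max(np.abs(residual)) < 1e-6

    def test_flat_increment_dropped(self):
        curve = sk.DigestionCurve(times=np.array([0.0, 5.0, 10.0, 15.0, 20.0]),
                                  C=np.array([0.0, 10.0, 10.0, 18.0, 24.0]))
        points, dropped = sk.los_transform(curve)
        assert dropped == 1
        assert len(points) == 3


class TestFitPhase:
    def test_exact_line_inverts_to_k_and_cinf(self):
        k, c_inf = 0.02, 60.0
        xs = np.linspace(10.0, 100.0, 10)
        ys = -k * xs + np.log(c_inf * k)
        fit = sk.fit_phase(make_points(xs, ys))
        assert fit.k == pytest.approx(k, rel=1e-12)
        assert fit.C_inf == pytest.approx(c_inf, rel=1e-12)

    def test_positive_slope_rejected(self):
        xs = np.linspace(0.0, 10.0, 6)
        with pytest.raises(ValueError, match="slope"):
            sk.fit_phase(make_points(xs, 0.1 * xs))

    def test_cinf_above_100_flagged_not_clamped(self):
        k = 0.01
        xs = np.linspace(10.0, 100.0, 8)
        ys = -k * xs + np.log(150.0 * k)
        with pytest.warns(UserWarning, match="exceeds 100"):
            fit = sk.fit_phase(make_points(xs, ys))
        assert fit.C_inf == pytest.approx(150.0, rel=1e-9)
        assert fit.c_inf_flag


class TestSegmentation:
    def test_single_line_one_phase(self):
        xs = np.linspace(0.0, 100.0, 20)
        breaks = sk.segment_phases(make_points(xs, -0.02 * xs + 1.0))
        assert breaks == []

    def test_two_lines_breakpoint_recovered(self):
        xs = np.linspace(0.0, 200.0, 41)
        ys = np.where(xs <= 100.0, -0.05 * xs, -0.01 * xs - 4.0)
        breaks = sk.segment_phases(make_points(xs, ys))
        assert len(breaks) == 1
        assert xs[breaks[0]] == pytest.approx(102.5, abs=2.6)

    def test_non_decreasing_k_disallowed(self):
        # accelerating (steeper second) segments admit no valid multi-phase
        # model; parsimony must fall back to one phase
        xs = np.linspace(0.0, 200.0, 30)
        ys = np.where(xs <= 100.0, -0.01 * xs, -0.05 * xs + 4.0)
        breaks = sk.segment_phases(make_points(xs, ys))
        assert breaks == []


class TestAUCAndIndices:
    def test_zero_width_interval(self):
        assert sk.auc(50.0, 0.01, 100.0, 100.0) == 0.0

    def test_hand_value(self):
        expected = 5000.0 - 5000.0 * (1.0 - np.exp(-1.0))
        assert sk.auc(50.0, 0.01, 0.0, 100.0) == pytest.approx(1839.397, abs=0.1)
        assert sk.auc(50.0, 0.01, 0.0, 100.0) == pytest.approx(expected)

    def test_fast_kinetics_limit(self):
        assert sk.auc(50.0, 100.0, 0.0, 100.0) == pytest.approx(5000.0, rel=1e-3)

    def test_auc_monotone_in_cinf_and_interval(self):
        assert sk.auc(60.0, 0.02, 0.0, 540.0) > sk.auc(50.0, 0.02, 0.0, 540.0)
        assert sk.auc(50.0, 0.02, 0.0, 540.0) > sk.auc(50.0, 0.02, 0.0, 400.0)

    def test_hydrolysis_index_scale(self):
        assert sk.hydrolysis_index(100.0, 100.0) == pytest.approx(100.0)
        assert sk.hydrolysis_index(0.0, 50.0) == 0.0
        assert sk.hydrolysis_index(71.83, 100.0) == pytest.approx(71.83)

    @pytest.mark.parametrize(("hi", "expected"), [
        (105.30, 97.52), (83.99, 85.82), (71.83, 79.15), (0.0, 39.71),
    ])
    def test_egi_linear_map(self, hi, expected):
        assert sk.egi(hi) == pytest.approx(expected, abs=0.01)


class TestFirstOrderFit:
    def test_recovers_exact_single_phase(self):
        curve = sk.gen_digestion_curve([sk.PhaseSpec(k=0.02, C_inf=60.0, t_end=540.0)],
                                       times=sk.UNIFORM_5MIN_GRID)
        fit = sk.fit_first_order(curve)
        assert fit.k == pytest.approx(0.02, rel=1e-3)
        assert fit.C_inf == pytest.approx(60.0, rel=1e-3)
        assert fit.r_squared > 0.999999

    def test_protocol_grid_recovery(self):
        curve = sk.gen_digestion_curve([sk.PhaseSpec(k=3.20e-2, C_inf=90.13, t_end=540.0)],
                                       times=sk.STANDARD_TIME_GRID)
        fit = sk.fit_first_order(curve)
        assert fit.k == pytest.approx(3.20e-2, rel=0.01)
        assert fit.C_inf == pytest.approx(90.13, rel=0.01)

    def test_all_zero_rejected(self):
        curve = sk.DigestionCurve(times=sk.STANDARD_TIME_GRID,
                                  C=np.zeros_like(sk.STANDARD_TIME_GRID))
        with pytest.raises(ValueError):
            sk.fit_first_order(curve)


class TestFullPipeline:
    def test_ternary_two_phase_recovery(self, ternary_curve_5min):
        res = sk.analyze_digestion(ternary_curve_5min, reference=ternary_curve_5min)
        assert len(res.phases) == 2
        assert res.breakpoints == (200.0,)
        assert res.phases[0].k == pytest.approx(2.43e-2, rel=1e-6)
        assert res.phases[1].k == pytest.approx(1.44e-2, rel=1e-6)
        assert res.HI == pytest.approx(100.0, rel=1e-9)

    def test_cinf_sinh_bias_closed_form(self, ternary_curve_5min):
        # on a uniform grid of spacing Δ the LOS intercept inflates C_inf by
        # exactly sinh(kΔ/2)/(kΔ/2)
        res = sk.analyze_digestion(ternary_curve_5min)
        k = 2.43e-2
        bias = np.sinh(k * 5.0 / 2.0) / (k * 5.0 / 2.0)
        assert res.phases[0].C_inf == pytest.approx(60.21 * bias, rel=1e-6)

    def test_single_phase_classical_matches_phase(self):
        curve = sk.gen_digestion_curve([sk.PhaseSpec(k=0.02, C_inf=60.0, t_end=540.0)],
                                       times=sk.UNIFORM_5MIN_GRID)
        res = sk.analyze_digestion(curve)
        assert len(res.phases) == 1
        assert res.classical.k == pytest.approx(res.phases[0].k, rel=1e-3)

    def test_classical_k_between_phase_ks(self):
        # paste-like curves: the single-exponential k falls between the
        # fast and slow phase constants
        phases = [sk.PhaseSpec(k=7.89e-2, C_inf=89.39, t_end=120.0),
                  sk.PhaseSpec(k=3.20e-2, C_inf=90.13, t_end=540.0)]
        curve = sk.gen_digestion_curve(phases, times=sk.UNIFORM_5MIN_GRID)
        res = sk.analyze_digestion(curve)
        ks = sorted(p.k for p in res.phases)
        assert ks[0] < res.classical.k < ks[-1]

    def test_dropped_points_warning(self):
        # exponential rise truncated to a hard plateau: the flat tail makes
        # >30% of increments unusable but the rest stay first-order
        t = sk.UNIFORM_5MIN_GRID
        c_exact = 60.0 * (1.0 - np.exp(-0.02 * t))
        c = np.minimum(c_exact, 60.0 * (1.0 - np.exp(-0.02 * 350.0)))
        curve = sk.DigestionCurve(times=t, C=c)
        with pytest.warns(UserWarning, match="dropped"):
            res = sk.analyze_digestion(curve)
        assert res.dropped_points >= 0.3 * (len(t) - 1)

    def test_no_reference_no_hi(self, ternary_curve_5min):
        res = sk.analyze_digestion(ternary_curve_5min)
        assert res.HI is None and res.EGI is None

    def test_default_reference_yields_hi_below_100(self, ternary_curve_5min):
        ref = sk.default_reference_curve(sk.UNIFORM_5MIN_GRID)
        res = sk.analyze_digestion(ternary_curve_5min, reference=ref)
        assert 0.0 < res.HI < 100.0
        assert res.EGI == pytest.approx(39.71 + 0.549 * res.HI)
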