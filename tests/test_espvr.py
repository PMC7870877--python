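"""Linear / bilinear ESPVR fits, breakpoint, PRSW, phase landmarks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pvloop import (
    classify_phases,
    fit_bilinear_espvr,
    fit_linear_espvr,
    fit_prsw,
    intersection,
)
from pvloop.elastance import ESPoint
from pvloop.espvr import FitError


def pts(pairs):
    return [ESPoint(beat_idx=i, t_es=float(i), Ves=v, Pes=p, Emax=1.0)
            for i, (v, p) in enumerate(pairs)]


def normal_equations(x, y):
    """Closed-form OLS oracle."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    m = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    b = (sy - m * sx) / n
    return m, b


def brute_force_split(points, min_seg=3):
    """Independent enumeration oracle for the bilinear split."""
    best = None
    n = len(points)
    for k in range(min_seg - 1, n - min_seg):
        f1 = fit_linear_espvr(points[: k + 1])
        f2 = fit_linear_espvr(points[k + 1:])
        gm = np.sqrt(max(f1.r2, 0) * max(f2.r2, 0))
        if best is None or gm > best[0] + 1e-12:
            best = (gm, k)
    return best[1]


class TestLinear:
    def test_exact_line_example(self):
        fit = fit_linear_espvr(pts([(60, 10), (80, 30), (100, 50)]))
        assert fit.Ees == pytest.approx(1.0)
        assert fit.V0 == pytest.approx(50.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        v = rng.uniform(40, 120, 50)
        p = 1.5 * (v - 20) + rng.normal(0, 2, 50)
        fit = fit_linear_espvr(pts(list(zip(v, p))))
        m, b = normal_equations(v, p)
        assert fit.Ees == pytest.approx(m, rel=1e-10)
        assert fit.intercept == pytest.approx(b, rel=1e-10)

    def test_three_collinear_points_r2_exactly_one(self):
        fit = fit_linear_espvr(pts([(50, 0), (60, 20), (70, 40)]))
        assert fit.r2 == 1.0

    def test_residual_orthogonality(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(40, 120, 30)
        p = 1.2 * (v - 10) + rng.normal(0, 3, 30)
        fit = fit_linear_espvr(pts(list(zip(v, p))))
        resid = p - fit.predict(v)
        assert abs(np.dot(resid, v)) / (np.linalg.norm(resid) * np.linalg.norm(v) + 1e-30) < 1e-8

    def test_vertical_raises(self):
        with pytest.raises(FitError):
            fit_linear_espvr(pts([(60, 10), (60, 30), (60, 50)]))

    def test_negative_slope_flagged_not_raised(self):
        fit = fit_linear_espvr(pts([(60, 50), (80, 30), (100, 10)]))
        assert not fit.physiological
        assert fit.Ees < 0


class TestBilinear:
    def two_line_points(self):
        # the lines P = 3.3(V-60) and P = 1.5(V-10) cross at V = 101.67,
        # between the phase-1 and phase-2 volume ranges
        phase1 = [(v, 3.3 * (v - 60)) for v in (92, 94, 96, 98, 100)]
        phase2 = [(v, 1.5 * (v - 10)) for v in (104, 108, 112, 116, 120)]
        return pts(phase1 + phase2)

    def test_two_line_exact_recovery(self):
        fit = fit_bilinear_espvr(self.two_line_points())
        assert fit.split_index == 4
        assert fit.phase1.Ees == pytest.approx(3.3)
        assert fit.phase2.Ees == pytest.approx(1.5)
        assert fit.phase1.r2 == pytest.approx(1.0)
        assert fit.phase2.r2 == pytest.approx(1.0)
        assert fit.gm_r2 == pytest.approx(1.0)

    def test_breakpoint_between_phases(self):
        fit = fit_bilinear_espvr(self.two_line_points())
        v_star, p_star = fit.breakpoint
        assert 100 < v_star < 104  # between phase-1 max and phase-2 min Ves
        assert v_star == pytest.approx(101.666667)
        assert p_star == pytest.approx(3.3 * (v_star - 60))

    def test_single_line_tie_earliest_split(self):
        points = pts([(v, 2.0 * (v - 30)) for v in range(50, 80, 3)])
        fit = fit_bilinear_espvr(points)
        assert fit.split_index == 2  # earliest admissible split
        assert fit.gm_r2 == pytest.approx(1.0)
        assert fit.phase1.Ees == pytest.approx(fit.phase2.Ees)

    def test_too_few_points(self):
        with pytest.raises(FitError):
            fit_bilinear_espvr(pts([(60, 10), (70, 20), (80, 30), (90, 40), (95, 45)]))

    def test_matches_brute_force_on_noisy_data(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(6, 31))
            v = np.sort(rng.uniform(40, 120, n))
            p = np.where(v < 80, 3.0 * (v - 50), 1.2 * (v - 5)) + rng.normal(0, 3, n)
            points = pts(list(zip(v, p)))
            try:
                fit = fit_bilinear_espvr(points)
            except FitError:
                continue
            assert fit.split_index == brute_force_split(points)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_split_equals_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 31))
        v = rng.uniform(30, 130, n)
        v += np.arange(n) * 0.01  # avoid exact duplicates
        p = rng.uniform(10, 150, n)
        points = pts(list(zip(v, p)))
        try:
            fit = fit_bilinear_espvr(points)
        except FitError:
            return
        assert fit.split_index == brute_force_split(points)


class TestIntersection:
    def test_algebra(self):
        (v, p), parallel = intersection((2.0, -100.0), (1.0, -20.0))
        assert not parallel
        assert v == pytest.approx(80.0)
        assert p == pytest.approx(60.0)

    def test_identical_lines_flagged(self):
        _, parallel = intersection((1.5, -10.0), (1.5, -10.0))
        assert parallel


class TestPRSW:
    def test_exact_line_example(self):
        fit = fit_prsw([80, 100, 120], [2000, 4000, 6000])
        assert fit.Mw == pytest.approx(100.0)
        assert fit.Vw == pytest.approx(60.0)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.meaningful

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        ved = rng.uniform(80, 130, 40)
        sw = 80 * (ved - 55) + rng.normal(0, 100, 40)
        fit = fit_prsw(ved, sw)
        m, b = normal_equations(ved, sw)
        assert fit.Mw == pytest.approx(m, rel=1e-10)
        assert fit.intercept == pytest.approx(b, rel=1e-10)

    def test_flat_relation_flagged_not_meaningful(self, pload_on_analysis):
        """Afterload runs give near-horizontal or negative stroke-work
        relations, reported but flagged."""
        _, _, ra = pload_on_analysis
        assert ra.prsw is None or not ra.prsw.meaningful

    def test_no_ved_variation_raises(self):
        with pytest.raises(FitError):
            fit_prsw([100, 100, 100], [1, 2, 3])


class TestClassifyPhases:
    def test_bilinear_landmarks(self):
        points = pts([(v, 3.3 * (v - 60)) for v in (92, 94, 96, 98, 100)]
                     + [(v, 1.5 * (v - 10)) for v in (104, 108, 112, 116, 120)])
        fit = fit_bilinear_espvr(points)
        lm = classify_phases(fit, 10)
        assert (lm.a, lm.b, lm.c) == (0, 4, 9)

    def test_linear_only_has_no_b(self):
        lm = classify_phases(None, 8)
        assert lm.a == 0 and lm.b is None and lm.c == 7


class TestNoiseMonotonicity:
    def test_expected_r2_never_increases_with_noise(self):
        sds = [0.5, 2.0, 8.0]
        means = []
        for sd in sds:
            r2s = []
            for seed in range(12):
                rng = np.random.default_rng(1000 + seed)
                v = np.linspace(50, 100, 12)
                p = 1.5 * (v - 15) + rng.normal(0, sd, 12)
                r2s.append(fit_linear_espvr(pts(list(zip(v, p)))).r2)
            means.append(np.mean(r2s))
        assert means[0] >= means[1] >= means[2]
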