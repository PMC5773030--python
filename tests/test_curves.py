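"""Growth/shape curve contracts: interpolation, invariants, serialization."""

import numpy as np
import pytest
import yaml
from hypothesis import given
from hypothesis import strategies as st

from rosettasim.curves import (CurveConfigError, FunctionCurve,
                               default_function_set, eval_curve, function_set_from_dict,
                               function_set_to_dict, leaf_length, leaf_width,
                               load_function_set, save_function_set)


def _monotone_cubic_reference(points, u):
    """Independent monotone piecewise-cubic Hermite evaluation.

    Interior derivatives use the weighted-harmonic-mean slope rule (zero at
    local extrema), endpoints the one-sided three-point rule with sign and
    magnitude clipping; evaluation is the cubic Hermite basis.  Written
    from the textbook formulas as an oracle for the curve implementation.
    """
    xs = np.array([p[0] for p in points], dtype=float)
    ys = np.array([p[1] for p in points], dtype=float)
    h = np.diff(xs)
    m = np.diff(ys) / h
    n = len(xs)
    d = np.zeros(n)
    for k in range(1, n - 1):
        if m[k - 1] * m[k] <= 0:
            d[k] = 0.0
        else:
            w1 = 2 * h[k] + h[k - 1]
            w2 = h[k] + 2 * h[k - 1]
            d[k] = (w1 + w2) / (w1 / m[k - 1] + w2 / m[k])

    def _edge(h0, h1, m0, m1):
        dd = ((2 * h0 + h1) * m0 - h0 * m1) / (h0 + h1)
        if np.sign(dd) != np.sign(m0):
            return 0.0
        if np.sign(m0) != np.sign(m1) and abs(dd) > 3 * abs(m0):
            return 3 * m0
        return dd

    if n == 2:
        d[0] = d[1] = m[0]
    else:
        d[0] = _edge(h[0], h[1], m[0], m[1])
        d[-1] = _edge(h[-1], h[-2], m[-1], m[-2])

    u = np.atleast_1d(np.clip(u, 0, 1))
    out = np.empty_like(u, dtype=float)
    for idx, uu in enumerate(u):
        k = min(np.searchsorted(xs, uu, side="right") - 1, n - 2)
        k = max(k, 0)
        t = (uu - xs[k]) / h[k]
        h00 = 2 * t**3 - 3 * t**2 + 1
        h10 = t**3 - 2 * t**2 + t
        h01 = -2 * t**3 + 3 * t**2
        h11 = t**3 - t**2
        out[idx] = h00 * ys[k] + h10 * h[k] * d[k] + h01 * ys[k + 1] + h11 * h[k] * d[k + 1]
    return out


class TestFunctionCurve:
    def test_linear_two_point_case(self):
        curve = FunctionCurve([(0, 0), (1, 1)])
        assert eval_curve(curve, 0.5) == pytest.approx(0.5, abs=1e-12)

    def test_control_points_reproduced_exactly(self, fs):
        for curve in (fs.f_lmax, fs.f_l, fs.f_lw, fs.f_ang):
            for u, v in curve.control_points:
                assert eval_curve(curve, u) == v

    def test_matches_independent_monotone_cubic_oracle(self):
        pts = [(0, 0), (0.5, 0.2), (1, 1)]
        curve = FunctionCurve(pts)
        grid = np.linspace(0, 1, 10_000)
        expected = _monotone_cubic_reference(pts, grid)
        np.testing.assert_allclose(curve(grid), expected, atol=1e-10)
        assert eval_curve(curve, 0.25) == pytest.approx(
            _monotone_cubic_reference(pts, 0.25)[0], abs=1e-10)

    def test_evaluation_deterministic_and_clamped(self):
        curve = FunctionCurve([(0, 0.3), (0.4, 0.9), (1, 0.1)])
        a = [eval_curve(curve, 0.37) for _ in range(5)]
        assert len(set(a)) == 1
        assert eval_curve(curve, -3.0) == eval_curve(curve, 0.0)
        assert eval_curve(curve, 7.0) == eval_curve(curve, 1.0)

    def test_configuration_errors(self):
        with pytest.raises(CurveConfigError):
            FunctionCurve([(0, 0)])
        with pytest.raises(CurveConfigError):
            FunctionCurve([(0, 0), (0.5, 1), (0.5, 2), (1, 0)])
        with pytest.raises(CurveConfigError):
            FunctionCurve([(0.1, 0), (1, 1)])

    @given(st.lists(st.floats(0.01, 0.99), min_size=1, max_size=5, unique=True),
           st.floats(0, 1))
    def test_no_overshoot_between_monotone_ordinates(self, inner, u):
        xs = [0.0] + sorted(inner) + [1.0]
        ys = np.linspace(0.0, 1.0, len(xs))  # monotone ordinates
        curve = FunctionCurve(list(zip(xs, ys)))
        v = eval_curve(curve, u)
        assert -1e-12 <= v <= 1 + 1e-12
        grid = np.linspace(0, 1, 101)
        assert np.all(np.diff(curve(grid)) >= -1e-12)


class TestLeafDimensions:
    def test_length_boundary_ages(self, fs):
        assert leaf_length(fs, 5, 0.0) == pytest.approx(0.0, abs=1e-12)
        n_norm = fs.node_norm(5)
        assert leaf_length(fs, 5, 1.0) == pytest.approx(eval_curve(fs.f_lmax, n_norm))

    def test_length_monotone_in_age(self, fs):
        ts = np.linspace(0, 1, 11)
        lens = [leaf_length(fs, 8, t) for t in ts]
        assert np.all(np.diff(lens) >= -1e-12)

    def test_length_requires_positive_multiplier(self, fs):
        with pytest.raises(ValueError):
            leaf_length(fs, 3, 0.5, x_mult=0.0)

    def test_width_contour_endpoints_and_proportionality(self, fs):
        assert leaf_width(fs, 4, 0.8, 0.0) == pytest.approx(0.0, abs=1e-12)
        assert leaf_width(fs, 4, 0.8, 1.0) == pytest.approx(0.0, abs=1e-12)
        for x in (0.2, 0.5, 0.9):
            w1 = leaf_width(fs, 4, 0.8, x, x_mult=1.0)
            w2 = leaf_width(fs, 4, 0.8, x, x_mult=2.0)
            assert w2 == pytest.approx(2 * w1)

    def test_width_profile_is_pointwise_product(self, fs):
        xs = np.linspace(0, 1, 21)
        length = leaf_length(fs, 6, 1.0)
        for x in xs:
            assert leaf_width(fs, 6, 1.0, x) == pytest.approx(length * eval_curve(fs.f_lw, x))

    @given(st.floats(0.05, 1.0), st.floats(0.1, 3.0), st.floats(0, 1))
    def test_contour_shape_invariant_under_growth(self, t, x_mult, x):
        fs = default_function_set()
        length = leaf_length(fs, 7, t, x_mult)
        if length < 1e-9:
            return
        ratio = leaf_width(fs, 7, t, x, x_mult) / length
        assert ratio == pytest.approx(eval_curve(fs.f_lw, x), abs=1e-12)


class TestDefaultFunctionSet:
    def test_invariants(self, fs):
        fs.validate()
        assert eval_curve(fs.f_l, 0.0) == pytest.approx(0.0, abs=1e-12)
        assert eval_curve(fs.f_l, 1.0) == pytest.approx(1.0, abs=1e-12)

    def test_contour_maximum_is_interior(self, fs):
        grid = np.linspace(0, 1, 1001)
        argmax = grid[np.argmax(fs.f_lw(grid))]
        assert 0.05 < argmax < 0.95

    def test_qualitative_shapes(self, fs):
        grid = np.linspace(0, 1, 101)
        lmax = fs.f_lmax(grid)
        peak = grid[np.argmax(lmax)]
        assert 0.2 < peak < 0.8  # mid-rosette maximum
        assert lmax[0] < lmax.max() and lmax[-1] < lmax.max()
        ang = fs.f_ang(grid)
        assert ang[0] > ang[-1]  # inclination decreases with node number
        assert np.all((ang >= 0) & (ang <= 90))

    def test_serialization_roundtrip(self, fs, tmp_path):
        path = tmp_path / "curves.yaml"
        save_function_set(fs, path)
        back = load_function_set(path)
        for name in ("f_lmax", "f_l", "f_lw", "f_ang"):
            assert getattr(back, name).control_points == getattr(fs, name).control_points
            grid = np.linspace(0, 1, 57)
            np.testing.assert_array_equal(getattr(back, name)(grid), getattr(fs, name)(grid))
        assert back.petiole_length_fraction == fs.petiole_length_fraction
        assert back.petiole_width == fs.petiole_width

    def test_dict_roundtrip_preserves_full_precision(self, fs):
        d = yaml.safe_load(yaml.safe_dump(function_set_to_dict(fs)))
        back = function_set_from_dict(d)
        assert back.f_lmax.control_points == fs.f_lmax.control_points
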