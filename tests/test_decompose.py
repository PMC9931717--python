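"""Endpoint estimation, linear inversion, logistic filtering and the
composed decomposition."""

import numpy as np
import pytest

from splitpin import (
    DecompositionParams,
    PinholeStack,
    compute_phasor,
    estimate_endpoints,
    linear_fraction,
    logistic_filter,
    split_pin,
    split_pin_n2_closed_form,
    sum_image,
)
from splitpin.errors import (
    DegenerateModulationError,
    InvalidParametersError,
    NoSignalError,
)

from .conftest import random_stack


def stack_with_modulations(mods, intensity=100.0):
    """A 2-frame stack whose pixels have exactly the given modulations.

    For frames (F1, F2) with F1 + F2 = intensity, M = (F1 - F2)/(F1 + F2),
    so F1 = intensity (1 + M)/2 realizes any M in [0, 1].
    """
    mods = np.asarray(mods, dtype=float)
    f1 = intensity * (1 + mods) / 2
    f2 = intensity - f1
    return PinholeStack(np.stack([f1, f2]))


class TestEstimateEndpoints:
    def test_uniform_population_returns_configured_percentiles(self):
        # 101 evenly spaced modulations: P10 = 0.10, P90 = 0.90 under
        # linear order-statistic interpolation
        mods = np.linspace(0, 1, 101).reshape(1, 101)
        stack = stack_with_modulations(mods)
        phasor = compute_phasor(stack)
        m_in, m_out = estimate_endpoints(phasor, stack, intensity_threshold=0.0)
        assert m_in == pytest.approx(0.10, abs=1e-12)
        assert m_out == pytest.approx(0.90, abs=1e-12)

    def test_two_spike_population(self):
        # 90 pixels at M=0.2, 10 at M=0.8: P10 lands inside the low spike;
        # P90 interpolates between order statistics x[89]=0.2 and x[90]=0.8
        # at fractional index 0.9*99 = 89.1, giving 0.2 + 0.1*0.6 = 0.26
        mods = np.array([0.2] * 90 + [0.8] * 10).reshape(1, 100)
        stack = stack_with_modulations(mods)
        phasor = compute_phasor(stack)
        m_in, m_out = estimate_endpoints(phasor, stack, intensity_threshold=0.0)
        assert m_in == pytest.approx(0.2, abs=1e-12)
        assert m_out == pytest.approx(0.26, abs=1e-12)

    def test_degenerate_histogram_raises(self):
        stack = stack_with_modulations(np.full((4, 4), 0.3))
        phasor = compute_phasor(stack)
        with pytest.raises(DegenerateModulationError):
            estimate_endpoints(phasor, stack, intensity_threshold=0.0)

    def test_threshold_excludes_dim_pixels(self):
        mods = np.array([[0.1, 0.9, 0.5, 0.5]])
        intensity = np.array([[100.0, 100.0, 1.0, 1.0]])
        f1 = intensity * (1 + mods) / 2
        stack = PinholeStack(np.stack([f1, intensity - f1]))
        phasor = compute_phasor(stack)
        m_in, m_out = estimate_endpoints(
            phasor, stack, intensity_threshold=50.0, percentiles=(10, 90)
        )
        # only the two bright pixels form the histogram: P10 interpolates
        # between 0.1 and 0.9 at fractional index 0.1, giving 0.18
        assert 0.1 <= m_in < m_out <= 0.9
        assert m_in == pytest.approx(0.18, abs=1e-12)

    def test_empty_population_raises(self):
        stack = stack_with_modulations(np.array([[0.2, 0.8]]))
        phasor = compute_phasor(stack)
        with pytest.raises(NoSignalError):
            estimate_endpoints(phasor, stack, intensity_threshold=1e9)


class TestFractionMaps:
    def test_linear_fraction_endpoints_and_midpoint(self):
        m = np.array([[0.1, 0.9, 0.5, 1.0]])
        f = linear_fraction(m, 0.1, 0.9)
        np.testing.assert_allclose(f, [[1.0, 0.0, 0.5, -0.125]], atol=1e-12)

    def test_linear_fraction_rejects_bad_endpoints(self):
        with pytest.raises(InvalidParametersError):
            linear_fraction(np.zeros((2, 2)), 0.5, 0.5)

    def test_logistic_fixed_points(self):
        assert logistic_filter(np.array(0.5), 4.0) == pytest.approx(0.5, abs=0)
        assert logistic_filter(np.array(1.0), 4.0) == pytest.approx(
            1 / (1 + np.exp(-2)), abs=1e-12
        )
        assert logistic_filter(np.array(0.0), 4.0) == pytest.approx(
            1 / (1 + np.exp(2)), abs=1e-12
        )

    def test_logistic_complement_symmetry_and_range(self):
        x = np.linspace(-3, 4, 301)
        f = logistic_filter(x, 4.0)
        np.testing.assert_allclose(f + logistic_filter(1 - x, 4.0), 1.0, atol=1e-12)
        assert np.all((f > 0) & (f < 1))

    def test_fraction_strictly_decreasing_in_modulation(self):
        m = np.linspace(0, 1, 500)
        f = logistic_filter(linear_fraction(m, 0.1, 0.9), 4.0)
        assert np.all(np.diff(f) < 0)


class TestSumImage:
    def test_partial_sums(self):
        frames = np.array([5.0, 4.0, 2.0, 1.0]).reshape(4, 1, 1)
        stack = PinholeStack(frames)
        assert sum_image(stack, 1)[0, 0] == 12.0
        assert sum_image(stack, 3)[0, 0] == 3.0
        assert sum_image(stack, 4)[0, 0] == 1.0

    def test_j0_bounds(self):
        stack = PinholeStack(np.ones((3, 2, 2)))
        for bad in (0, 4, -1):
            with pytest.raises(InvalidParametersError):
                sum_image(stack, bad)


class TestSplitPin:
    def test_conservation_on_random_stacks(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            stack = random_stack(rng)
            res = split_pin(
                stack, DecompositionParams(m_in=0.1, m_out=0.9, j0=1)
            )
            np.testing.assert_allclose(
                res.split_pin + res.out_of_focus, res.sum_image, atol=1e-9
            )
            assert np.all((res.f_in > 0) & (res.f_in < 1))

    def test_matches_two_frame_closed_form(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            f1 = rng.uniform(0, 200, (32, 32))
            f2 = rng.uniform(0, 200, (32, 32))
            stack = PinholeStack(np.stack([f1, f2]))
            res = split_pin(stack, DecompositionParams(m_in=0.15, m_out=0.8))
            oracle = split_pin_n2_closed_form(f1, f2, 0.15, 0.8)
            np.testing.assert_allclose(res.split_pin, oracle, atol=1e-10)

    def test_closed_form_hand_values(self):
        # equal frames: M = 0, f_lin with (0, 1) endpoints = 1,
        # weight = 1/(1 + e^-2), output = weight * 2 F1
        out = split_pin_n2_closed_form(
            np.array([[3.0]]), np.array([[3.0]]), 0.0, 1.0
        )
        assert out[0, 0] == pytest.approx(6.0 / (1 + np.exp(-2)), abs=1e-12)
        # pixel (3, 1) with endpoints (0.1, 0.9): M=0.5, f_lin=0.5, weight=0.5
        out = split_pin_n2_closed_form(
            np.array([[3.0]]), np.array([[1.0]]), 0.1, 0.9
        )
        assert out[0, 0] == pytest.approx(2.0, abs=1e-12)

    def test_auto_endpoints_are_ordered_and_recorded(self, default_scene):
        stack, _ = default_scene
        res = split_pin(stack)
        used = res.params_used
        assert used.m_in < used.m_out
        assert used.intensity_threshold is not None
        assert 0 <= used.m_in <= 1 and 0 <= used.m_out <= 1

    def test_out_of_range_fraction_reported(self):
        # endpoints chosen inside the modulation range force f_lin out of [0,1]
        mods = np.linspace(0, 1, 64).reshape(1, 64)
        stack = stack_with_modulations(mods)
        res = split_pin(stack, DecompositionParams(m_in=0.45, m_out=0.55))
        assert res.out_of_range_fraction > 0.5

    def test_j0_last_uses_smallest_pinhole_frame_only(self):
        rng = np.random.default_rng(2)
        stack = random_stack(rng, n_frames=3)
        res = split_pin(stack, DecompositionParams(m_in=0.1, m_out=0.9, j0=3))
        np.testing.assert_allclose(res.sum_image, stack.frames[2], atol=0)
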