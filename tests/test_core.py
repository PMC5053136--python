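"""Core containers, gradient arithmetic and curve operations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iecsaxs.core import (
    BandSpec,
    EmptyBandError,
    FrameSeries,
    GradientProgram,
    GridMismatchError,
    OutOfRangeError,
    ScatteringCurve,
    UndefinedRatioError,
    average_curves,
    band_mean,
    beam_passage_time,
    fraction_at,
    frames_to_volume,
    low_mid_ratio,
    normalize_traces,
    resample_curve,
    salt_at,
    subtract_curves,
)


def make_curve(q, I, sigma=None):
    q = np.asarray(q, dtype=float)
    I = np.asarray(I, dtype=float)
    if sigma is None:
        sigma = np.zeros_like(q)
    return ScatteringCurve(q, I, np.asarray(sigma, dtype=float))


class TestScatteringCurve:
    def test_validation_rejects_bad_input(self):
        q = np.linspace(0.1, 1.0, 10)
        with pytest.raises(ValueError, match="length"):
            ScatteringCurve(q, np.ones(9), np.zeros(10))
        with pytest.raises(ValueError, match="increasing"):
            ScatteringCurve(q[::-1], np.ones(10), np.zeros(10))
        with pytest.raises(ValueError, match="sigma"):
            ScatteringCurve(q, np.ones(10), -np.ones(10))
        with pytest.raises(ValueError, match="finite"):
            ScatteringCurve(q, np.full(10, np.nan), np.zeros(10))


class TestGradientArithmetic:
    def test_linear_ramp_midpoint(self):
        prog = GradientProgram(25, 1000, "linear", (0, 1000, 0.0, 1.0))
        assert fraction_at(prog, 500) == pytest.approx(0.5)

    def test_linear_interpolation_off_grid(self):
        prog = GradientProgram(25, 1000, "linear", (0, 975, 0.0, 1.0))
        assert fraction_at(prog, 98) == pytest.approx(98 / 975)

    def test_step_plateaus_are_right_continuous(self):
        prog = GradientProgram(25, 1000, "step", ((0, 0.0), (1290, 0.12)))
        assert fraction_at(prog, 1289) == 0.0
        assert fraction_at(prog, 1290) == 0.12
        assert fraction_at(prog, 1800) == 0.12

    def test_salt_mapping_for_bsa_buffers(self):
        # 20 mM Tris buffers: A at 25 mM NaCl, B at 1 M; the BSA peaks at
        # 10 % and 16 % B elute at 122.5 and 181 mM NaCl
        prog = GradientProgram(25, 1000, "linear", (0, 1000, 0.0, 1.0))
        assert salt_at(prog, 100) == pytest.approx(122.5)
        assert salt_at(prog, 160) == pytest.approx(181.0)
        assert salt_at(prog, 0) == pytest.approx(25.0)

    def test_salt_monotone_for_monotone_schedule(self):
        prog = GradientProgram(25, 1000, "linear", (100, 900, 0.0, 1.0))
        frames = np.arange(0, 1200)
        salts = salt_at(prog, frames)
        assert np.all(np.diff(salts) >= 0)
        assert salts[0] == 25.0 and salts[-1] == 1000.0

    def test_out_of_range_strict_mode(self):
        prog = GradientProgram(25, 1000, "linear", (100, 900, 0.0, 1.0))
        with pytest.raises(OutOfRangeError):
            fraction_at(prog, 950, clamp=False)

    def test_validation(self):
        with pytest.raises(ValueError):
            GradientProgram(25, 1000, "linear", (0, 1000, 0.0, 1.2))
        with pytest.raises(ValueError):
            GradientProgram(1000, 25, "linear", (0, 1000, 0.0, 1.0))
        with pytest.raises(ValueError):
            GradientProgram(25, 1000, "step", ((100, 0.0), (50, 0.2)))


class TestScalarConversions:
    @pytest.mark.parametrize(
        "n, rate, flow, expected",
        [
            (130, 1.0, 1.0, 130 / 60),   # ~2.17 ml, prints as 2.2
            (60, 1.0, 1.0, 1.0),
            (130, 2.0, 1.0, 130 / 120),  # doubling the frame rate halves it
        ],
    )
    def test_frames_to_volume(self, n, rate, flow, expected):
        assert frames_to_volume(n, rate, flow) == pytest.approx(expected)

    def test_frames_to_volume_linear_in_frames(self):
        v1 = frames_to_volume(7, 1.0, 1.3)
        assert frames_to_volume(21, 1.0, 1.3) == pytest.approx(3 * v1)

    def test_frames_to_volume_rejects_bad_rates(self):
        with pytest.raises(ValueError):
            frames_to_volume(10, 0.0, 1.0)
        with pytest.raises(ValueError):
            frames_to_volume(10, 1.0, -1.0)

    def test_beam_passage_time_standard_geometry(self):
        # 1 ml/min through a 1.8 mm capillary, 700 um beam: ~0.1 s dwell
        t = beam_passage_time(1.0)
        assert t == pytest.approx(0.107, abs=5e-4)


class TestBandMean:
    def test_constant_curve(self):
        c = make_curve([1, 2, 3], [5, 5, 5])
        assert band_mean(c, BandSpec(0.5, 10)).value == 5.0

    def test_identity_curve_inclusive_edges(self):
        c = make_curve([1, 2, 3], [1, 2, 3])
        bm = band_mean(c, BandSpec(1, 3))
        assert bm.value == 2.0 and bm.n_points == 3

    def test_empty_band_error_names_band(self):
        c = make_curve([1, 2, 3], [1, 2, 3])
        with pytest.raises(EmptyBandError, match=r"\[4.*5.*\]"):
            band_mean(c, BandSpec(4, 5))

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_matches_bruteforce_index_selection(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        q = np.sort(rng.uniform(0.01, 5.0, n))
        q += np.arange(n) * 1e-9  # enforce strict monotonicity
        I = rng.normal(size=n)
        lo, hi = np.sort(rng.uniform(0.0, 5.5, 2))
        c = make_curve(q, I)
        idx = [i for i in range(n) if lo <= q[i] <= hi]
        band = BandSpec(lo, hi + 1e-12)
        if not idx:
            with pytest.raises(EmptyBandError):
                band_mean(c, band)
        else:
            assert band_mean(c, band).value == pytest.approx(
                np.mean([I[i] for i in idx]), rel=1e-12
            )


class TestCurveArithmetic:
    def test_self_subtraction_exactly_zero(self):
        q = np.linspace(0.1, 2, 50)
        c = make_curve(q, np.exp(-q), sigma=0.1 * np.ones(50))
        d = subtract_curves(c, c)
        assert np.all(d.I == 0.0)
        np.testing.assert_allclose(d.sigma, math.sqrt(2) * 0.1)

    def test_error_propagation_3_4_5(self):
        q = np.linspace(0.1, 2, 10)
        s = make_curve(q, 10 * np.ones(10), 3 * np.ones(10))
        b = make_curve(q, 4 * np.ones(10), 4 * np.ones(10))
        d = subtract_curves(s, b)
        np.testing.assert_allclose(d.I, 6.0)
        np.testing.assert_allclose(d.sigma, 5.0)

    def test_subtraction_linearity(self):
        q = np.linspace(0.1, 2, 30)
        a = make_curve(q, np.sin(q) + 2)
        b = make_curve(q, np.cos(q) + 2)
        ab = make_curve(q, a.I + b.I)
        np.testing.assert_allclose(subtract_curves(ab, b).I, a.I, rtol=1e-15)

    def test_grid_mismatch_rejected(self):
        a = make_curve(np.linspace(0.1, 2, 10), np.ones(10))
        b = make_curve(np.linspace(0.1, 2.1, 10), np.ones(10))
        with pytest.raises(GridMismatchError):
            subtract_curves(a, b)
        with pytest.raises(GridMismatchError):
            average_curves([a, b])

    def test_average_single_curve_unchanged(self):
        q = np.linspace(0.1, 2, 20)
        c = make_curve(q, np.exp(-q), 0.3 * np.ones(20))
        avg = average_curves([c])
        np.testing.assert_array_equal(avg.I, c.I)
        np.testing.assert_allclose(avg.sigma, c.sigma)

    def test_average_reduces_sigma_sqrt_n(self):
        q = np.linspace(0.1, 2, 20)
        c = make_curve(q, np.ones(20), np.ones(20))
        avg = average_curves([c] * 9)
        np.testing.assert_allclose(avg.sigma, 1.0 / 3.0)

    def test_average_mean_and_permutation_invariance(self):
        q = np.linspace(0.1, 2, 20)
        a = make_curve(q, 2 * np.ones(20))
        b = make_curve(q, 4 * np.ones(20))
        np.testing.assert_allclose(average_curves([a, b]).I, 3.0)
        np.testing.assert_array_equal(
            average_curves([a, b]).I, average_curves([b, a]).I
        )

    def test_average_empty_list(self):
        with pytest.raises(ValueError):
            average_curves([])

    def test_resample_is_explicit_and_bounded(self):
        q = np.linspace(0.1, 2, 50)
        c = make_curve(q, q ** 2)
        new_q = np.linspace(0.2, 1.9, 40)
        r = resample_curve(c, new_q)
        np.testing.assert_allclose(r.I, new_q ** 2, atol=2e-3)
        with pytest.raises(ValueError):
            resample_curve(c, np.linspace(0.0, 1.0, 10))


class TestLowMidRatio:
    def test_constant_curve_gives_one(self):
        q = np.linspace(0.05, 3.0, 300)
        c = make_curve(q, 7 * np.ones(300))
        assert low_mid_ratio(c).value == pytest.approx(1.0)

    def test_matches_bruteforce_band_quotient(self):
        q = np.linspace(0.05, 3.0, 400)
        c = make_curve(q, 1.0 / q ** 2)
        lo = BandSpec(0.11, 0.5)
        mi = BandSpec(1.5, 2.5)
        expected = np.mean(c.I[(q >= 0.11) & (q <= 0.5)]) / np.mean(
            c.I[(q >= 1.5) & (q <= 2.5)]
        )
        assert low_mid_ratio(c, lo, mi).value == pytest.approx(expected, rel=1e-12)

    def test_zero_mid_band_raises(self):
        # perfect subtraction of a flat background leaves 0/0
        q = np.linspace(0.05, 3.0, 300)
        c = make_curve(q, np.zeros(300))
        with pytest.raises(UndefinedRatioError):
            low_mid_ratio(c)


class TestNormalizeTraces:
    def test_constant_trace_becomes_unity(self):
        (out,) = normalize_traces([np.full(5, 7.0)])
        np.testing.assert_allclose(out, 1.0)

    def test_traces_share_mean_over_roi(self):
        out = normalize_traces([np.array([1.0, 2, 3]), np.array([10.0, 20, 30])])
        for t in out:
            np.testing.assert_allclose(t, [0.5, 1.0, 1.5])

    def test_roi_restricted_means(self):
        trace = np.array([1.0, 1.0, 4.0, 4.0, 10.0])
        (out,) = normalize_traces([trace], roi=(2, 4))  # mean there is 4
        np.testing.assert_allclose(out, trace / 4.0)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            normalize_traces([np.array([1.0, -1.0])])


class TestFrameSeries:
    def test_frame_access_and_slicing(self):
        q = np.linspace(0.1, 2, 30)
        I = np.outer(np.arange(5) + 1.0, np.ones(30))
        s = FrameSeries(q, I, np.zeros_like(I), first_frame_index=10)
        assert s.frame(12).I[0] == 3.0
        sub = s.slice_frames(11, 14)
        assert sub.n_frames == 3 and sub.first_frame_index == 11
        with pytest.raises(IndexError):
            s.frame(15)

    def test_average_matches_average_curves(self):
        q = np.linspace(0.1, 2, 30)
        rng = np.random.default_rng(0)
        I = rng.normal(size=(4, 30))
        sig = rng.uniform(0.1, 1, size=(4, 30))
        s = FrameSeries(q, I, sig)
        avg = s.average()
        ref = average_curves([s.frame(i) for i in range(4)])
        np.testing.assert_allclose(avg.I, ref.I)
        np.testing.assert_allclose(avg.sigma, ref.sigma)

    def test_band_trace_matches_per_frame_band_mean(self):
        q = np.linspace(0.1, 2, 30)
        rng = np.random.default_rng(1)
        I = rng.normal(size=(4, 30))
        s = FrameSeries(q, I, np.zeros_like(I))
        band = BandSpec(0.5, 1.5)
        tr = s.band_trace(band)
        for i in range(4):
            assert tr[i] == pytest.approx(band_mean(s.frame(i), band).value)

    def test_mismatched_grid_rejected_in_from_curves(self):
        a = make_curve(np.linspace(0.1, 2, 10), np.ones(10))
        b = make_curve(np.linspace(0.1, 2.2, 10), np.ones(10))
        with pytest.raises(GridMismatchError):
            FrameSeries.from_curves([a, b])
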