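"""The six PAC estimators: frozen arithmetic oracles, invariances, engines."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ndtri

from pacbox.core import BandGrid, EpochedSignal, make_bands
from pacbox.methods import (
    METHODS,
    AmplitudeDistribution,
    amplitude_phase,
    bin_amplitude_by_phase,
    compute_pac,
    copnorm,
    gcpac,
    heights_ratio,
    mi_kl,
    mvl,
    ndpac,
    ndpac_threshold,
    plv,
)
from pacbox.spectral import extract_amplitude, extract_phase

EDGES3 = np.linspace(-np.pi, np.pi, 4)


class TestBinning:
    def test_uniform_amplitude_gives_uniform_distribution(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 50000)
        dist = bin_amplitude_by_phase(phase, np.ones(50000), n=18)
        np.testing.assert_allclose(dist.P, np.full(18, 1 / 18), atol=1e-12)

    def test_delta_amplitude(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 5000)
        amp = np.where((phase >= 0) & (phase < 2 * np.pi / 18), 1.0, 0.0)
        dist = bin_amplitude_by_phase(phase, amp, n=18)
        j = 9  # bin [0, 20deg)
        expected = np.zeros(18)
        expected[j] = 1.0
        np.testing.assert_allclose(dist.P, expected, atol=1e-12)

    def test_hand_computed_six_samples(self):
        dist = bin_amplitude_by_phase(
            [-2, 0, 2, -2, 0, 2], [1, 2, 3, 1, 2, 3], n=3
        )
        np.testing.assert_allclose(dist.P, [1 / 6, 2 / 6, 3 / 6])

    def test_empty_bins_warn(self):
        with pytest.warns(RuntimeWarning, match="empty"):
            dist = bin_amplitude_by_phase([0.1, 0.2], [1.0, 1.0], n=18)
        assert dist.P.sum() == pytest.approx(1.0)

    def test_single_occupied_bin_flagged_degenerate(self):
        with pytest.warns(RuntimeWarning):
            dist = bin_amplitude_by_phase([0.05, 0.06, 0.07], [1, 2, 3], n=18)
        assert dist.degenerate

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            bin_amplitude_by_phase([0.0], [1.0, 2.0])


class TestMvl:
    def test_constant_vector(self):
        assert mvl(np.full(10, 0.3), np.full(10, 2.5)) == pytest.approx(2.5)

    def test_roots_of_unity_cancel(self):
        phase = 2 * np.pi * np.arange(8) / 8 - np.pi
        assert mvl(phase, np.ones(8)) == pytest.approx(0.0, abs=1e-12)

    def test_two_point(self):
        assert mvl([0.0, np.pi], [1.0, 2.0]) == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mvl([], [])

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.floats(0.01, 100.0), st.integers(0, 10_000))
    def test_homogeneous_degree_one(self, c, seed):
        rng = np.random.default_rng(seed)
        phase = rng.uniform(-np.pi, np.pi, 50)
        amp = rng.exponential(1.0, 50)
        assert mvl(phase, c * amp) == pytest.approx(c * mvl(phase, amp), rel=1e-9)


class TestMiAndHr:
    def test_uniform_zero(self):
        d = AmplitudeDistribution(np.full(18, 1 / 18), np.linspace(-np.pi, np.pi, 19))
        assert mi_kl(d) == pytest.approx(0.0, abs=1e-12)
        assert heights_ratio(d) == pytest.approx(0.0, abs=1e-12)

    def test_delta_one(self):
        P = np.zeros(18)
        P[4] = 1.0
        d = AmplitudeDistribution(P, np.linspace(-np.pi, np.pi, 19))
        assert mi_kl(d) == pytest.approx(1.0)
        assert heights_ratio(d) == pytest.approx(1.0)

    def test_mi_arithmetic_oracle(self):
        # 1 + (0.5 ln 0.5 + 2*0.25 ln 0.25)/ln 3 computed by hand
        d = AmplitudeDistribution(np.array([0.5, 0.25, 0.25]), EDGES3)
        assert mi_kl(d) == pytest.approx(0.0536053696, abs=1e-9)

    def test_hr_arithmetic_oracle(self):
        d = AmplitudeDistribution(np.array([0.5, 0.3, 0.2]), EDGES3)
        assert heights_ratio(d) == pytest.approx(0.6)


class TestNdpac:
    def test_threshold_value(self):
        # 2*1000*erfinv(0.95)^2, evaluated numerically
        assert ndpac_threshold(1000, 0.05) == pytest.approx(3841.459, rel=1e-4)

    def test_threshold_monotone_in_p(self):
        assert ndpac_threshold(500, 0.01) > ndpac_threshold(500, 0.05)

    def test_null_mostly_zero(self):
        zeros = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            phase = rng.uniform(-np.pi, np.pi, 2000)
            amp = 5 + rng.standard_normal(2000)
            zeros += ndpac(phase, amp, p=0.05) == 0.0
        assert zeros >= 90

    def test_zero_variance_amplitude_rejected(self):
        with pytest.raises(ValueError, match="z-score"):
            ndpac(np.linspace(-3, 3, 100), np.ones(100))


class TestPlv:
    def test_identical_phases(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 100)
        assert plv(phase, phase) == pytest.approx(1.0)

    def test_uniform_grid_cancels(self):
        d = 2 * np.pi * np.arange(10) / 10
        assert plv(d, np.zeros(10)) == pytest.approx(0.0, abs=1e-12)

    def test_hand_two_point(self):
        assert plv([0.0, np.pi / 2], [0.0, 0.0]) == pytest.approx(np.sqrt(2) / 2)


class TestCopnorm:
    def test_strictly_increasing_definition(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        np.testing.assert_allclose(copnorm(x), ndtri(np.arange(1, 5) / 5))

    def test_rank_invariance_exact(self, rng):
        x = rng.standard_normal(101)
        np.testing.assert_array_equal(copnorm(np.exp(x)), copnorm(x))

    def test_hand_length_three(self):
        np.testing.assert_allclose(
            copnorm(np.array([5.0, 1.0, 3.0])),
            [ndtri(3 / 4), ndtri(1 / 4), ndtri(2 / 4)],
        )

    def test_ties_get_average_ranks(self):
        out = copnorm(np.array([1.0, 1.0, 2.0]))
        assert out[0] == out[1] == ndtri(1.5 / 4)


class TestGcpac:
    def test_independent_near_zero(self):
        rng = np.random.default_rng(0)
        phase = rng.uniform(-np.pi, np.pi, 10000)
        amp = rng.standard_normal(10000)
        assert abs(gcpac(phase, amp, clamp=False)) < 0.01

    def test_monotone_amplitude_invariance_exact(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 500)
        amp = rng.exponential(1.0, 500)
        assert gcpac(phase, amp) == gcpac(phase, amp**3 + 7)

    def test_lower_bounds_histogram_oracle(self):
        """gcPAC is a finite lower bound on MI capturing most of a sinusoidal
        dependence (Miller-Madow 64-bin histogram MI as the oracle)."""
        rng = np.random.default_rng(1)
        n = 20000
        phase = rng.uniform(-np.pi, np.pi, n)
        amp = np.sin(phase) + 0.5 * rng.standard_normal(n)

        counts, _, _ = np.histogram2d(phase, amp, bins=64)
        p = counts / n
        px = p.sum(1, keepdims=True)
        py = p.sum(0, keepdims=True)
        nz = p > 0
        hist_mi = np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz]))
        hist_mi -= (nz.sum() - (px > 0).sum() - (py > 0).sum() + 1) / (2 * n * np.log(2))

        gc = gcpac(phase, amp)
        assert gc <= hist_mi * 1.05
        assert gc >= 0.7 * hist_mi

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            gcpac(np.linspace(-3, 3, 100), np.ones(100))


class TestGrids:
    @pytest.mark.parametrize("method", METHODS)
    def test_tensor_equals_loop(self, method, rng):
        x = EpochedSignal(rng.standard_normal((3, 1200)), 256)
        pbnds = make_bands(4, 12, 4)
        abnds = make_bands(30, 60, 15, role="amplitude")
        rt = compute_pac(x, pbnds, abnds, method=method, engine="tensor")
        rl = compute_pac(x, pbnds, abnds, method=method, engine="loop")
        a = rt.diagnostics.get("raw", rt.pac)
        b = rl.diagnostics.get("raw", rl.pac)
        assert np.max(np.abs(a - b) / np.maximum(np.abs(b), 1e-30)) < 1e-10

    @pytest.mark.parametrize("method", METHODS)
    def test_single_pair_grid_equals_scalar(self, method, small_tort_signal):
        x = small_tort_signal
        pbnds = BandGrid([(8, 12)])
        abnds = BandGrid([(70, 90)], role="amplitude")
        res = compute_pac(x, pbnds, abnds, method=method)
        pha = extract_phase(x, pbnds).values.ravel()
        amp_t = extract_amplitude(x, abnds)
        if method == "plv":
            amp = amplitude_phase(amp_t, pbnds, x.sf)[0, 0].ravel()
        else:
            amp = amp_t.values.ravel()
        scalar = {
            "mvl": lambda: mvl(pha, amp),
            "mi": lambda: mi_kl(bin_amplitude_by_phase(pha, amp)),
            "hr": lambda: heights_ratio(bin_amplitude_by_phase(pha, amp)),
            "ndpac": lambda: ndpac(pha, amp),
            "plv": lambda: plv(pha, amp),
            "gc": lambda: gcpac(pha, amp),
        }[method]()
        assert res.pac[0, 0] == pytest.approx(scalar, rel=1e-10)

    @pytest.mark.parametrize("method", ["mvl", "mi", "hr", "plv", "gc"])
    def test_amplitude_scaling(self, method, small_tort_signal):
        """MI/HR/PLV/gcPAC are amplitude-scale invariant; MVL scales linearly."""
        x = small_tort_signal
        x2 = EpochedSignal(x.data * 3.0, x.sf)
        pbnds = make_bands(6, 14, 4)
        abnds = make_bands(60, 100, 20, role="amplitude")
        g1 = compute_pac(x, pbnds, abnds, method=method).pac
        g2 = compute_pac(x2, pbnds, abnds, method=method).pac
        if method == "mvl":
            np.testing.assert_allclose(g2, 3 * g1, rtol=1e-10)
        else:
            np.testing.assert_allclose(g2, g1, rtol=1e-9, atol=1e-12)

    def test_average_mode_single_epoch_matches_concat(self, rng):
        x = EpochedSignal(rng.standard_normal(2000), 256)
        pbnds = make_bands(4, 12, 4)
        abnds = make_bands(30, 60, 15, role="amplitude")
        g1 = compute_pac(x, pbnds, abnds, method="mi", mode="concat").pac
        g2 = compute_pac(x, pbnds, abnds, method="mi", mode="average").pac
        np.testing.assert_allclose(g1, g2, rtol=1e-12)

    def test_grid_cells_finite_and_bounded(self, small_tort_signal):
        for method in ("mi", "hr", "plv"):
            g = compute_pac(
                small_tort_signal, make_bands(4, 12, 4),
                make_bands(60, 100, 20, role="amplitude"), method=method,
            ).pac
            assert np.isfinite(g).all()
            assert (g >= 0).all() and (g <= 1).all()

    def test_band_above_nyquist_rejected_before_filtering(self, small_tort_signal):
        with pytest.raises(ValueError, match="Nyquist"):
            compute_pac(
                small_tort_signal, make_bands(4, 12, 4),
                make_bands(100, 200, 50, role="amplitude"), method="mi",
            )

    def test_unknown_method_rejected(self, small_tort_signal):
        with pytest.raises(ValueError, match="unknown PAC method"):
            compute_pac(
                small_tort_signal, make_bands(4, 12, 4),
                make_bands(60, 100, 20, role="amplitude"), method="tort",
            )
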