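"""Diagnostics: preferred phase, binned amplitude, PSD, ITC, triangular
search, peak-locked realignment, stationarity."""

import numpy as np
import pytest

from pacbox.core import BandGrid, EpochedSignal, make_bands
from pacbox.methods import compute_pac
from pacbox.signals import SimSpec, simulate_pac_tort
from pacbox.tools import (
    bin_amplitude,
    itc,
    peak_locked_tf,
    preferred_phase,
    psd,
    psd_peak,
    triangular_search,
)
from pacbox.tools import test_stationarity as adf_stationarity  # noqa: avoid pytest collection


class TestPreferredPhase:
    def test_cosine_modulation_recovers_locked_angle(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 20000)
        amp = (1 + np.cos(phase - np.pi / 4))[None, :]
        res = preferred_phase(phase, amp, n_bins=18)
        assert res.pp[0] == pytest.approx(50.0)  # bin [40, 60) contains 45
        assert not res.tie[0]

    def test_constant_amplitude_raises_tie_flag(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 5000)
        res = preferred_phase(phase, np.ones((1, 5000)), n_bins=18)
        assert res.tie[0]
        assert res.pp[0] == res.bin_centers_deg.min()

    def test_argmax_consistency_with_binned_matrix(self, small_tort_signal):
        from pacbox.spectral import extract_amplitude, extract_phase

        pha = extract_phase(small_tort_signal, BandGrid([(8, 12)])).values[0]
        amp = extract_amplitude(
            small_tort_signal, make_bands(60, 100, 20, role="amplitude")
        ).values
        res = preferred_phase(pha.ravel(), amp.reshape(amp.shape[0], -1))
        for i in range(amp.shape[0]):
            if not res.tie[i]:
                assert res.pp[i] == res.bin_centers_deg[res.binned_amp[:, i].argmax()]


class TestBinAmplitude:
    def test_coupling_detected_and_null_calibrated(self):
        """Uniformity retained without coupling, rejected with coupling."""
        not_rejected = 0
        for seed in range(40):
            sig = simulate_pac_tort(
                SimSpec(sf=256, n_epochs=12, n_times=1024, f_pha=10, f_amp=80,
                        coupling=0.0, noise=1.0, seed=seed)
            )
            out = bin_amplitude(sig, (8, 12), (70, 90))
            not_rejected += out["pvalue"] > 0.01
        assert not_rejected >= 36  # approx >= 90% at alpha = 0.01

        sig = simulate_pac_tort(
            SimSpec(sf=256, n_epochs=12, n_times=1024, f_pha=10, f_amp=80,
                    coupling=1.0, noise=1.0, seed=0)
        )
        assert bin_amplitude(sig, (8, 12), (70, 90))["pvalue"] < 0.01


class TestPsd:
    def test_pure_tone_peak(self):
        sf, n = 256, 4096
        t = np.arange(n) / sf
        x = EpochedSignal(np.sin(2 * np.pi * 6 * t)[None, :].repeat(3, 0), sf)
        freqs, power = psd(x)
        assert psd_peak(freqs, power, 2, 20) == pytest.approx(6.0, abs=0.5)

    def test_parseval_total_power(self, rng):
        x = EpochedSignal(rng.standard_normal((4, 4096)), 256)
        freqs, power = psd(x)
        total = np.trapezoid(power, freqs)
        assert abs(total / x.data.var() - 1) < 0.05

    def test_peak_range_empty_rejected(self, rng):
        x = EpochedSignal(rng.standard_normal(1024), 256)
        freqs, power = psd(x)
        with pytest.raises(ValueError, match="no PSD samples"):
            psd_peak(freqs, power, 500, 600)


class TestItc:
    def test_identical_epochs_full_coherence(self, rng):
        row = rng.standard_normal(1024)
        x = EpochedSignal(np.tile(row, (8, 1)), 256)
        vals = itc(x, (8, 12))
        np.testing.assert_allclose(vals, 1.0, atol=1e-9)

    def test_random_phases_rayleigh_scale(self, rng):
        x = EpochedSignal(rng.standard_normal((1000, 512)), 256)
        vals = itc(x, (8, 12))[100:-100]
        # mean resultant length of n random unit vectors ~ sqrt(pi)/2/sqrt(n)
        assert vals.mean() < 3 / np.sqrt(1000)

    def test_amplitude_scaling_invariance(self, small_tort_signal):
        x = small_tort_signal
        scaled = EpochedSignal(x.data * np.linspace(1, 5, x.n_epochs)[:, None], x.sf)
        np.testing.assert_allclose(itc(x, (8, 12)), itc(scaled, (8, 12)), atol=1e-9)


@pytest.fixture(scope="module")
def coupled_6_70():
    return simulate_pac_tort(
        SimSpec(f_pha=6, f_amp=70, sf=256, n_epochs=5, n_times=2048,
                coupling=0.9, noise=1.0, seed=0)
    )


class TestTriangularSearch:

    def test_values_match_individual_pac_calls(self, coupled_6_70):
        grid = triangular_search(
            coupled_6_70, (5, 7), side="amplitude", f_range=(60, 80), step=10
        )
        for (f1, f2), v in zip(grid.pairs, grid.values):
            ref = compute_pac(
                coupled_6_70, BandGrid([(5, 7)]),
                BandGrid([(f1, f2)], role="amplitude"), method="mi",
            ).pac[0, 0]
            assert v == pytest.approx(ref, rel=1e-10)

    def test_lower_triangle_only(self, coupled_6_70):
        grid = triangular_search(
            coupled_6_70, (5, 7), side="amplitude", f_range=(50, 90), step=10
        )
        assert (grid.pairs[:, 0] < grid.pairs[:, 1]).all()

    def test_two_point_range_single_pair(self, coupled_6_70):
        grid = triangular_search(
            coupled_6_70, (5, 7), side="amplitude", f_range=(60, 80), step=20
        )
        assert len(grid.values) == 1

    def test_step_larger_than_range_rejected(self, coupled_6_70):
        with pytest.raises(ValueError, match="step"):
            triangular_search(coupled_6_70, (5, 7), f_range=(60, 70), step=20)


class TestPeakLockedTf:
    def test_identical_epochs_zero_shifts(self):
        sf, n = 256, 1024
        t = np.arange(n) / sf
        row = np.sin(2 * np.pi * 8 * t)
        x = EpochedSignal(np.tile(row, (5, 1)), sf)
        out = peak_locked_tf(x, (6, 10), cue=512, freqs=[40.0])
        # all epochs share the same nearest peak, hence identical shifts
        assert len(set(out["shifts"].tolist())) == 1
        realigned = out["realigned"]
        np.testing.assert_allclose(realigned[0], realigned[-1])

    def test_shifts_bounded_by_half_period(self, small_tort_signal):
        x = small_tort_signal
        out = peak_locked_tf(x, (8, 12), cue=x.n_times // 2, freqs=[80.0])
        half_period = x.sf / 10 / 2
        assert np.abs(out["shifts"]).max() <= half_period

    def test_coupled_map_shows_periodic_bursts(self):
        sig = simulate_pac_tort(
            SimSpec(sf=256, n_epochs=20, n_times=1536, f_pha=8, f_amp=80,
                    coupling=1.0, noise=0.5, seed=2)
        )
        out = peak_locked_tf(sig, (6, 10), cue=768, freqs=[80.0])
        ts = out["tf_mean"][0]
        ts = ts[200:-200] - ts[200:-200].mean()
        period = int(round(256 / 8))
        autocorr = (ts[:-period] @ ts[period:]) / (ts @ ts)
        assert autocorr > 0.3

    def test_bad_cue_rejected(self, small_tort_signal):
        with pytest.raises(ValueError, match="cue"):
            peak_locked_tf(small_tort_signal, (8, 12), cue=10**6, freqs=[80.0])


class TestStationarity:
    def test_white_noise_stationary_random_walk_not(self):
        rng = np.random.default_rng(0)
        walks, whites = 0, 0
        n_rep = 100
        for _ in range(n_rep):
            steps = rng.standard_normal(512)
            walk = EpochedSignal(np.cumsum(steps), 1.0)
            white = EpochedSignal(rng.standard_normal(512), 1.0)
            walks += not adf_stationarity(walk)["stationary_5%"].iloc[0]
            whites += adf_stationarity(white)["stationary_5%"].iloc[0]
        assert walks >= 90
        assert whites >= 90

    def test_one_row_per_epoch(self, small_tort_signal):
        table = adf_stationarity(small_tort_signal)
        assert len(table) == small_tort_signal.n_epochs
        assert {"adf_stat", "pvalue", "crit_5%", "crit_1%"} <= set(table.columns)
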