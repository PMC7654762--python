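"""Cross-frequency companions: preferred phase, binned amplitude, PSD, ITC,
frequency-bound search, peak-locked time-frequency maps, stationarity tests.

These diagnostics support the credibility of a PAC estimate: a clear
spectral peak at the phase frequency, a non-uniform amplitude-by-phase
distribution, stationary epochs, and a data-driven choice of the frequency
bounds are all prerequisites for interpreting a comodulogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.signal import find_peaks, welch
from statsmodels.tsa.stattools import adfuller

from .core import BandGrid, EpochedSignal
from .methods import _bin_index
from .spectral import apply_zero_phase, design_fir_ls, extract_amplitude, extract_phase, morlet_transform

__all__ = [
    "PreferredPhaseResult",
    "preferred_phase",
    "bin_amplitude",
    "psd",
    "psd_peak",
    "itc",
    "TriangularGrid",
    "triangular_search",
    "peak_locked_tf",
    "test_stationarity",
]


# ---------------------------------------------------------------------------
# preferred phase
# ---------------------------------------------------------------------------

@dataclass
class PreferredPhaseResult:
    """Binned amplitude-by-phase matrix and per-band preferred phase.

    ``binned_amp[j, i]`` is the mean amplitude of band i in phase slice j;
    ``pp[i]`` the centre (degrees in [0, 360)) of the maximal slice.
    """

    binned_amp: np.ndarray
    pp: np.ndarray
    bin_centers_deg: np.ndarray
    tie: np.ndarray
    n_bins: int = 18


def preferred_phase(
    phase: np.ndarray, amp: np.ndarray, n_bins: int = 18
) -> PreferredPhaseResult:
    """Preferred phase per amplitude band.

    Parameters
    ----------
    phase : ndarray
        Instantaneous phase samples (any shape; flattened).
    amp : ndarray, shape (n_amp_bands, ...) matching phase
        Amplitude envelopes.
    """
    phase = np.asarray(phase, dtype=float).ravel()
    amp = np.asarray(amp, dtype=float)
    amp2 = amp.reshape(amp.shape[0], -1)
    if amp2.shape[1] != phase.size:
        raise ValueError("phase and amplitude tensors must cover the same samples")
    idx = _bin_index(phase, n_bins)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    binned = np.zeros((n_bins, amp2.shape[0]))
    for i in range(amp2.shape[0]):
        sums = np.bincount(idx, weights=amp2[i], minlength=n_bins)
        occupied = counts > 0
        binned[occupied, i] = sums[occupied] / counts[occupied]
    centers_deg = np.mod(-180.0 + (np.arange(n_bins) + 0.5) * 360.0 / n_bins, 360.0)
    argmax = binned.argmax(axis=0)
    maxima = binned.max(axis=0)
    # tie: several bins within numerical tolerance of the maximum
    near = np.abs(binned - maxima[None, :]) <= 1e-9 * np.maximum(maxima[None, :], 1e-300)
    tie = near.sum(axis=0) > 1
    # ties resolve to the lowest angle
    pp = np.empty(amp2.shape[0])
    for i in range(amp2.shape[0]):
        cand = centers_deg[near[:, i]]
        pp[i] = cand.min() if tie[i] else centers_deg[argmax[i]]
    return PreferredPhaseResult(
        binned_amp=binned, pp=pp, bin_centers_deg=centers_deg, tie=tie, n_bins=n_bins
    )


# ---------------------------------------------------------------------------
# binned amplitude with uniformity check
# ---------------------------------------------------------------------------

def bin_amplitude(
    x: EpochedSignal,
    pha_band: tuple[float, float],
    amp_band: tuple[float, float],
    n_bins: int = 18,
    cycles: tuple[int, int] = (3, 6),
) -> dict:
    """Amplitude binned by phase slices, with a χ²-style uniformity check.

    The per-bin means are computed per epoch; the test statistic studentises
    each grand bin mean by its across-epoch standard error, so its null
    distribution is approximately χ² with ``n_bins − 1`` degrees of freedom
    when epochs are independent. In the absence of coupling the distribution
    is uniform (H0 retained); genuine coupling concentrates amplitude in a
    few slices and rejects H0.
    """
    pha = extract_phase(x, BandGrid([pha_band], role="phase"), cycles=cycles[0]).values[0]
    amp = extract_amplitude(x, BandGrid([amp_band], role="amplitude"), cycles=cycles[1]).values[0]
    n_ep = x.n_epochs
    per_epoch = np.full((n_ep, n_bins), np.nan)
    for e in range(n_ep):
        idx = _bin_index(pha[e], n_bins)
        counts = np.bincount(idx, minlength=n_bins).astype(float)
        sums = np.bincount(idx, weights=amp[e], minlength=n_bins)
        occ = counts > 0
        per_epoch[e, occ] = sums[occ] / counts[occ]
    binned = np.nanmean(per_epoch, axis=0)
    if n_ep > 1:
        se = np.nanstd(per_epoch, axis=0, ddof=1) / np.sqrt(n_ep)
        se[se == 0] = np.nan
        dev = (binned - binned.mean()) / se
        statistic = float(np.nansum(dev**2))
        df = n_bins - 1
        pvalue = float(sstats.chi2.sf(statistic, df))
    else:
        statistic, pvalue, df = np.nan, np.nan, n_bins - 1
    centers_deg = np.mod(-180.0 + (np.arange(n_bins) + 0.5) * 360.0 / n_bins, 360.0)
    return {
        "binned_amp": binned,
        "bin_centers_deg": centers_deg,
        "statistic": statistic,
        "df": df,
        "pvalue": pvalue,
    }


# ---------------------------------------------------------------------------
# PSD and ITC
# ---------------------------------------------------------------------------

def psd(x: EpochedSignal, nperseg: int | None = None, **kwargs):
    """Epoch-averaged Welch power spectral density (Hann window, 50% overlap).

    Returns ``(freqs, power)`` with power averaged over epochs.
    """
    if nperseg is None:
        nperseg = int(min(x.n_times, 4 * x.sf))
    freqs, power = welch(
        x.data, fs=x.sf, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, axis=-1, **kwargs
    )
    return freqs, power.mean(axis=0)


def psd_peak(
    freqs: np.ndarray, power: np.ndarray, fmin: float, fmax: float
) -> float:
    """Frequency of maximal power inside [fmin, fmax]."""
    mask = (freqs >= fmin) & (freqs <= fmax)
    if not mask.any():
        raise ValueError(f"no PSD samples inside [{fmin}, {fmax}] Hz")
    return float(freqs[mask][np.argmax(power[mask])])


def itc(
    x: EpochedSignal,
    band: tuple[float, float],
    dcomplex: Literal["hilbert", "wavelet"] = "hilbert",
    cycles: int = 3,
    width: float = 7.0,
) -> np.ndarray:
    """Inter-trial coherence: ``|mean_trials e^{jφ(t)}|`` per time point, in [0, 1]."""
    pha = extract_phase(
        x, BandGrid([band], role="phase"), method=dcomplex, cycles=cycles, width=width
    ).values[0]
    return np.abs(np.exp(1j * pha).mean(axis=0))


# ---------------------------------------------------------------------------
# triangular frequency-bound search
# ---------------------------------------------------------------------------

@dataclass
class TriangularGrid:
    """PAC over all (f_min, f_max) interval bounds on a step grid."""

    pairs: np.ndarray  # (n_pairs, 2)
    values: np.ndarray  # (n_pairs,)
    target: Literal["phase", "amplitude"]
    fixed_band: tuple[float, float]
    method: str

    @property
    def best(self) -> tuple[float, float]:
        """The (f_min, f_max) interval with maximal coupling."""
        i = int(np.argmax(self.values))
        return tuple(self.pairs[i])


def triangular_search(
    x: EpochedSignal,
    fixed_band: tuple[float, float],
    side: Literal["phase", "amplitude"] = "amplitude",
    f_range: tuple[float, float] = (40.0, 100.0),
    step: float | None = None,
    method: str = "mi",
    **pac_kwargs,
) -> TriangularGrid:
    """Search the best frequency interval for one side of the coupling.

    With ``side='amplitude'`` the phase band is fixed and PAC(F_min, F_max)
    is evaluated for every pair ``F_min < F_max`` on the step grid (default
    step: 2 Hz for the amplitude side, 0.5 Hz for the phase side).
    """
    if step is None:
        step = 2.0 if side == "amplitude" else 0.5
    lo, hi = f_range
    if step > hi - lo:
        raise ValueError(f"step {step} Hz exceeds the search range {f_range}")
    cycles = pac_kwargs.pop("cycles", (3, 6))
    dcomplex = pac_kwargs.pop("dcomplex", "hilbert")
    width = pac_kwargs.pop("width", 7.0)
    edges = np.arange(lo, hi + step / 2, step)
    pairs = [(f1, f2) for k, f1 in enumerate(edges) for f2 in edges[k + 1:]]
    values = np.empty(len(pairs))
    # the fixed side is band-limited once; only the searched side is
    # re-filtered for each candidate interval
    from .methods import amplitude_phase, pac_grid  # avoid an import cycle

    def amp_like(amp_t, pha_grid):
        if method == "plv":
            return amplitude_phase(amp_t, pha_grid, x.sf, cycles=cycles[0])
        return amp_t.values

    if side == "amplitude":
        pha_grid = BandGrid([fixed_band], role="phase")
        pha = extract_phase(x, pha_grid, method=dcomplex, cycles=cycles[0], width=width).values
        for k, (f1, f2) in enumerate(pairs):
            amp_t = extract_amplitude(
                x, BandGrid([(f1, f2)], role="amplitude"),
                method=dcomplex, cycles=cycles[1], width=width,
            )
            values[k] = pac_grid(pha, amp_like(amp_t, pha_grid), method, **pac_kwargs)[0, 0]
    else:
        amp_t = extract_amplitude(
            x, BandGrid([fixed_band], role="amplitude"),
            method=dcomplex, cycles=cycles[1], width=width,
        )
        for k, (f1, f2) in enumerate(pairs):
            pha_grid = BandGrid([(f1, f2)], role="phase")
            pha = extract_phase(x, pha_grid, method=dcomplex, cycles=cycles[0], width=width).values
            values[k] = pac_grid(pha, amp_like(amp_t, pha_grid), method, **pac_kwargs)[0, 0]
    return TriangularGrid(
        pairs=np.asarray(pairs, dtype=float),
        values=values,
        target=side,
        fixed_band=tuple(fixed_band),
        method=method,
    )


# ---------------------------------------------------------------------------
# peak-locked time-frequency realignment
# ---------------------------------------------------------------------------

def peak_locked_tf(
    x: EpochedSignal,
    pha_band: tuple[float, float],
    cue: int,
    freqs,
    cycles: int = 3,
    width: float = 7.0,
) -> dict:
    """Realign epochs on the low-frequency peak nearest a cue, then average
    Morlet amplitude maps.

    Each epoch's band-filtered signal is scanned for local maxima; the peak
    nearest ``cue`` defines a circular shift that aligns all epochs. Epochs
    with no peak within half a driver period of the cue are dropped with a
    warning. Genuine coupling shows up as periodic high-frequency bursts in
    the realigned mean map.
    """
    if not 0 <= cue < x.n_times:
        raise ValueError(f"cue index {cue} outside the epoch (0..{x.n_times - 1})")
    coefs = design_fir_ls(pha_band, x.sf, cycles)
    filtered = apply_zero_phase(x.data, coefs)
    f_center = (pha_band[0] + pha_band[1]) / 2
    half_period = int(round(x.sf / f_center / 2))
    shifts, kept = [], []
    for e in range(x.n_epochs):
        peaks, _ = find_peaks(filtered[e])
        if peaks.size == 0:
            warnings.warn(f"epoch {e}: no phase peak found; dropped", RuntimeWarning)
            continue
        nearest = peaks[np.argmin(np.abs(peaks - cue))]
        shift = int(nearest - cue)
        if abs(shift) > half_period:
            warnings.warn(
                f"epoch {e}: nearest peak {abs(shift)} samples from cue "
                f"(> half driver period {half_period}); dropped",
                RuntimeWarning,
            )
            continue
        shifts.append(shift)
        kept.append(e)
    if not kept:
        raise ValueError("no epoch had a usable phase peak near the cue")
    realigned = np.stack([np.roll(x.data[e], -s) for e, s in zip(kept, shifts)])
    tf = np.abs(morlet_transform(EpochedSignal(realigned, x.sf), freqs, width))
    return {
        "epochs": np.asarray(kept),
        "shifts": np.asarray(shifts),
        "realigned": realigned,
        "tf_mean": tf.mean(axis=1),
        "freqs": np.atleast_1d(np.asarray(freqs, dtype=float)),
    }


# ---------------------------------------------------------------------------
# stationarity
# ---------------------------------------------------------------------------

def test_stationarity(x: EpochedSignal) -> pd.DataFrame:
    """Augmented Dickey-Fuller test per epoch.

    H0 is a unit root (a non-stationary signal); rejection at a given α
    means the epoch can be treated as stationary — a prerequisite for
    time-averaged PAC. One row per epoch with the ADF statistic, p-value,
    the 5% and 1% critical values and reject flags.
    """
    rows = []
    for e in range(x.n_epochs):
        stat, pvalue, usedlag, nobs, crit, _ = adfuller(x.data[e])
        rows.append(
            {
                "epoch": e,
                "adf_stat": stat,
                "pvalue": pvalue,
                "lags": usedlag,
                "nobs": nobs,
                "crit_5%": crit["5%"],
                "crit_1%": crit["1%"],
                "stationary_5%": pvalue < 0.05,
                "stationary_1%": pvalue < 0.01,
            }
        )
    return pd.DataFrame(rows)
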