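"""Phase-amplitude coupling estimators.

Six measures of the statistical dependence between a slow phase φ(t) and a
fast amplitude envelope a(t), over a full (amplitude-band × phase-band) grid:

* ``mvl`` — mean vector length, ``(1/N)|Σ a(k)·e^{jφ(k)}|``.
* ``mi`` — modulation index: KL divergence of the phase-binned amplitude
  distribution P from uniform, normalized by log(n_bins), in [0, 1].
* ``hr`` — heights ratio ``(h_max − h_min)/h_max`` of the same distribution.
* ``ndpac`` — normalized direct PAC: MVL of the z-scored amplitude with a
  closed-form significance threshold ``x_th = 2·N·(erf⁻¹(1−p))²``; values
  whose statistic ``|Σ z(k)e^{jφ(k)}|²`` falls below x_th are set to 0.
* ``plv`` — phase-locking value between φ and the phase of the amplitude
  envelope (the envelope filtered in the phase band, then Hilbert angle).
* ``gc`` — Gaussian-copula PAC: bias-corrected Gaussian mutual information
  (bits) between the copula-normalized amplitude and the 2-D representation
  [sin φ, cos φ] of the phase.

Every measure has two evaluation paths: a vectorized ``tensor`` path built on
einsum/matmul, and a per-band-pair ``loop`` path using the scalar functions.
The two agree to ~1e-10 relative; the loop path serves as the readable
reference, the tensor path is the production one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.special import erfinv, ndtri, psi
from scipy.stats import rankdata

from .core import AmplitudeTensor, BandGrid, EpochedSignal
from .spectral import (
    apply_zero_phase,
    design_fir_ls,
    extract_amplitude,
    extract_phase,
)
from scipy.signal import hilbert as _hilbert

__all__ = [
    "AmplitudeDistribution",
    "PacResult",
    "bin_amplitude_by_phase",
    "mvl",
    "mi_kl",
    "heights_ratio",
    "ndpac",
    "ndpac_threshold",
    "plv",
    "copnorm",
    "gcpac",
    "amplitude_phase",
    "pac_grid",
    "compute_pac",
    "METHODS",
]

METHODS = ("mvl", "mi", "hr", "ndpac", "plv", "gc")

_LN2PIE = np.log(2 * np.pi * np.e)


# ---------------------------------------------------------------------------
# binned amplitude distribution (shared by MI and HR)
# ---------------------------------------------------------------------------

@dataclass
class AmplitudeDistribution:
    """Phase-binned amplitude probability vector over n slices of (−π, π]."""

    P: np.ndarray
    bin_edges: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.ndim != 1 or P.size < 2:
            raise ValueError("P must be a 1-D probability vector with n >= 2 bins")
        if (P < 0).any() or not np.isclose(P.sum(), 1.0):
            raise ValueError("P must be non-negative and sum to 1")
        self.P = P

    @property
    def n(self) -> int:
        return self.P.size

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2


def _phase_bin_edges(n: int) -> np.ndarray:
    return -np.pi + np.arange(n + 1) * (2 * np.pi / n)


def _bin_index(phase: np.ndarray, n: int) -> np.ndarray:
    """Half-open [edge, edge+width) bins from −π; phase == π lands in the last bin."""
    idx = np.floor((np.asarray(phase) + np.pi) / (2 * np.pi / n)).astype(np.intp)
    return np.clip(idx, 0, n - 1)


def bin_amplitude_by_phase(phase: np.ndarray, amp: np.ndarray, n: int = 18) -> AmplitudeDistribution:
    """Mean amplitude per phase slice, normalized to a probability vector.

    Empty bins contribute probability 0 (with a warning — they signal
    too-short data); if only one bin is occupied the distribution is flagged
    degenerate.
    """
    phase = np.asarray(phase, dtype=float).ravel()
    amp = np.asarray(amp, dtype=float).ravel()
    if phase.size != amp.size:
        raise ValueError("phase and amp must have equal lengths")
    if phase.size == 0:
        raise ValueError("empty input")
    if n < 2:
        raise ValueError("need at least 2 phase bins")
    idx = _bin_index(phase, n)
    counts = np.bincount(idx, minlength=n).astype(float)
    sums = np.bincount(idx, weights=amp, minlength=n)
    means = np.zeros(n)
    occupied = counts > 0
    means[occupied] = sums[occupied] / counts[occupied]
    if not occupied.all():
        warnings.warn(
            f"{int((~occupied).sum())} of {n} phase bins are empty; "
            "the data may be too short for this bin count",
            RuntimeWarning,
            stacklevel=2,
        )
    total = means.sum()
    if total <= 0:
        raise ValueError("all-zero amplitude: cannot normalize the distribution")
    return AmplitudeDistribution(
        means / total, _phase_bin_edges(n), degenerate=occupied.sum() == 1
    )


# ---------------------------------------------------------------------------
# scalar estimators (reference / loop path)
# ---------------------------------------------------------------------------

def mvl(phase: np.ndarray, amp: np.ndarray) -> float:
    """Mean vector length ``(1/N)|Σ a(k)·e^{jφ(k)}|``."""
    phase = np.asarray(phase, dtype=float).ravel()
    amp = np.asarray(amp, dtype=float).ravel()
    if phase.size == 0 or phase.size != amp.size:
        raise ValueError("phase and amp must be non-empty and of equal length")
    return float(np.abs(np.sum(amp * np.exp(1j * phase))) / phase.size)


def mi_kl(dist: AmplitudeDistribution) -> float:
    """Modulation index: ``D_KL(P, uniform)/log(n) = 1 + ΣP·logP / log(n)``."""
    P = dist.P
    nz = P > 0
    return float(1.0 + np.sum(P[nz] * np.log(P[nz])) / np.log(dist.n))


def heights_ratio(dist: AmplitudeDistribution) -> float:
    """``(h_max − h_min)/h_max`` of the binned distribution."""
    hmax, hmin = dist.P.max(), dist.P.min()
    return float((hmax - hmin) / hmax)


def ndpac_threshold(n_times: int, p: float = 0.05) -> float:
    """Closed-form significance threshold ``x_th = 2·N·(erf⁻¹(1−p))²``."""
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    return float(2 * n_times * erfinv(1 - p) ** 2)


def _zscore(amp: np.ndarray, axis: int = -1) -> np.ndarray:
    mu = amp.mean(axis=axis, keepdims=True)
    sd = amp.std(axis=axis, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance amplitude: z-score undefined")
    return (amp - mu) / sd


def ndpac(phase: np.ndarray, amp: np.ndarray, p: float = 0.05) -> float:
    """Normalized direct PAC with its closed-form threshold.

    The statistic ``|Σ z(k)·e^{jφ(k)}|²`` (z the z-scored amplitude) is
    compared to ``x_th``; sub-threshold couplings return 0, supra-threshold
    ones return the MVL-scaled value ``|Σ z·e^{jφ}|/N``.
    """
    phase = np.asarray(phase, dtype=float).ravel()
    amp = np.asarray(amp, dtype=float).ravel()
    if phase.size < 2 or phase.size != amp.size:
        raise ValueError("need N >= 2 samples of equal length")
    z = _zscore(amp)
    stat = np.abs(np.sum(z * np.exp(1j * phase))) ** 2
    if stat <= ndpac_threshold(phase.size, p):
        return 0.0
    return float(np.sqrt(stat) / phase.size)


def plv(phase: np.ndarray, amp_phase: np.ndarray) -> float:
    """Phase-locking value ``(1/N)|Σ e^{j(φ(k) − φ_a(k))}|``."""
    phase = np.asarray(phase, dtype=float).ravel()
    amp_phase = np.asarray(amp_phase, dtype=float).ravel()
    if phase.size == 0 or phase.size != amp_phase.size:
        raise ValueError("phase and amp_phase must be non-empty and of equal length")
    return float(np.abs(np.sum(np.exp(1j * (phase - amp_phase)))) / phase.size)


def copnorm(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Copula normalization: Φ⁻¹ of the empirical CDF (ranks / (m+1)).

    Ties receive average ranks; the transform is invariant to strictly
    monotone increasing maps of the input.
    """
    x = np.asarray(x, dtype=float)
    ranks = rankdata(x, axis=axis)
    return ndtri(ranks / (x.shape[axis] + 1))


def _gauss_mi_bias(n: int) -> float:
    """Net additive bias term for I = H(2d) + H(1d) − H(3d) at n samples."""
    dterm = (np.log(2.0) - np.log(n - 1.0)) / 2.0
    psi_half = psi((n - np.arange(1, 4)) / 2.0) / 2.0
    bx = 2 * dterm + psi_half[0] + psi_half[1]
    by = 1 * dterm + psi_half[0]
    bxy = 3 * dterm + psi_half.sum()
    return bx + by - bxy


def gcpac(phase: np.ndarray, amp: np.ndarray, clamp: bool = True) -> float:
    """Gaussian-copula PAC, ``I(a; [sin φ, cos φ])`` in bits.

    Both variables are copula-normalized (rank → standard normal margins)
    before a parametric, bias-corrected Gaussian MI estimate — a lower bound
    on the true MI that is invariant to strictly monotone transforms of the
    amplitude. Small-sample bias correction can push estimates slightly
    negative; those are clamped to 0 unless ``clamp=False``.
    """
    phase = np.asarray(phase, dtype=float).ravel()
    amp = np.asarray(amp, dtype=float).ravel()
    n = phase.size
    if n < 10 or n != amp.size:
        raise ValueError("need N >= 10 samples of equal length")
    if np.ptp(amp) == 0 or np.ptp(phase) == 0:
        raise ValueError("degenerate (constant) input")
    s = copnorm(np.sin(phase))
    c = copnorm(np.cos(phase))
    a = copnorm(amp)
    s = s - s.mean()
    c = c - c.mean()
    a = a - a.mean()
    m = n - 1
    vss, vcc, vaa = s @ s / m, c @ c / m, a @ a / m
    vsc, vas, vac = s @ c / m, a @ s / m, a @ c / m
    detx = vss * vcc - vsc**2
    detxy = (
        vss * (vcc * vaa - vac**2)
        - vsc * (vsc * vaa - vac * vas)
        + vas * (vsc * vac - vcc * vas)
    )
    if detx <= 0 or detxy <= 0 or vaa <= 0:
        raise ValueError("singular joint covariance: MI undefined")
    i_nats = 0.5 * (np.log(detx) + np.log(vaa) - np.log(detxy)) - _gauss_mi_bias(n)
    i_bits = float(i_nats / np.log(2.0))
    return max(i_bits, 0.0) if clamp else i_bits


_SCALAR = {
    "mvl": lambda ph, am, n_bins, p: mvl(ph, am),
    "mi": lambda ph, am, n_bins, p: mi_kl(bin_amplitude_by_phase(ph, am, n_bins)),
    "hr": lambda ph, am, n_bins, p: heights_ratio(bin_amplitude_by_phase(ph, am, n_bins)),
    "ndpac": lambda ph, am, n_bins, p: ndpac(ph, am, p),
    "plv": lambda ph, am, n_bins, p: plv(ph, am),
    "gc": lambda ph, am, n_bins, p: gcpac(ph, am),
}


# ---------------------------------------------------------------------------
# tensorized grid estimators
# ---------------------------------------------------------------------------

def _dist_grid(pha2: np.ndarray, amp2: np.ndarray, n_bins: int) -> np.ndarray:
    """Binned amplitude distributions, shape (n_amp, n_pha, n_bins)."""
    n_pha, m = pha2.shape
    n_amp = amp2.shape[0]
    out = np.empty((n_amp, n_pha, n_bins))
    warned = False
    for j in range(n_pha):
        idx = _bin_index(pha2[j], n_bins)
        counts = np.bincount(idx, minlength=n_bins).astype(float)
        onehot = np.zeros((n_bins, m))
        onehot[idx, np.arange(m)] = 1.0
        sums = onehot @ amp2.T  # (n_bins, n_amp)
        occupied = counts > 0
        means = np.zeros_like(sums)
        means[occupied] = sums[occupied] / counts[occupied, None]
        if not occupied.all() and not warned:
            warnings.warn(
                "empty phase bins in the amplitude distribution; "
                "the data may be too short for this bin count",
                RuntimeWarning,
                stacklevel=3,
            )
            warned = True
        out[:, j, :] = (means / means.sum(axis=0, keepdims=True)).T
    return out


def _grid_tensor(
    method: str, pha2: np.ndarray, amp2: np.ndarray, n_bins: int, p: float
) -> np.ndarray:
    """Vectorized (n_amp, n_pha) grid; for plv ``amp2`` is (n_amp, n_pha, M)."""
    m = pha2.shape[-1]
    if method == "mvl":
        return np.abs(np.einsum("am,pm->ap", amp2, np.exp(1j * pha2))) / m
    if method in ("mi", "hr"):
        P = _dist_grid(pha2, amp2, n_bins)
        if method == "mi":
            logP = np.zeros_like(P)
            nz = P > 0
            logP[nz] = np.log(P[nz])
            return 1.0 + np.sum(P * logP, axis=-1) / np.log(n_bins)
        hmax = P.max(axis=-1)
        return (hmax - P.min(axis=-1)) / hmax
    if method == "ndpac":
        z = _zscore(amp2, axis=-1)
        stat = np.abs(np.einsum("am,pm->ap", z, np.exp(1j * pha2))) ** 2
        out = np.sqrt(stat) / m
        out[stat <= ndpac_threshold(m, p)] = 0.0
        return out
    if method == "plv":
        return np.abs(
            np.einsum("pm,apm->ap", np.exp(1j * pha2), np.exp(-1j * amp2))
        ) / m
    if method == "gc":
        return _gc_grid(pha2, amp2)
    raise ValueError(f"unknown PAC method {method!r}")


def _gc_grid(pha2: np.ndarray, amp2: np.ndarray) -> np.ndarray:
    n_pha, m = pha2.shape
    n = m
    s = copnorm(np.sin(pha2), axis=-1)
    c = copnorm(np.cos(pha2), axis=-1)
    a = copnorm(amp2, axis=-1)
    s = s - s.mean(axis=-1, keepdims=True)
    c = c - c.mean(axis=-1, keepdims=True)
    a = a - a.mean(axis=-1, keepdims=True)
    den = n - 1
    vss = np.einsum("pm,pm->p", s, s) / den
    vcc = np.einsum("pm,pm->p", c, c) / den
    vsc = np.einsum("pm,pm->p", s, c) / den
    vaa = np.einsum("am,am->a", a, a) / den
    vas = a @ s.T / den  # (n_amp, n_pha)
    vac = a @ c.T / den
    detx = vss * vcc - vsc**2  # (n_pha,)
    detxy = (
        vss[None, :] * (vcc[None, :] * vaa[:, None] - vac**2)
        - vsc[None, :] * (vsc[None, :] * vaa[:, None] - vac * vas)
        + vas * (vsc[None, :] * vac - vcc[None, :] * vas)
    )
    if np.any(detx <= 0) or np.any(detxy <= 0):
        raise ValueError("singular joint covariance: MI undefined")
    i_nats = 0.5 * (
        np.log(detx)[None, :] + np.log(vaa)[:, None] - np.log(detxy)
    ) - _gauss_mi_bias(n)
    return i_nats / np.log(2.0)


def _grid_loop(
    method: str, pha2: np.ndarray, amp2: np.ndarray, n_bins: int, p: float
) -> np.ndarray:
    n_pha = pha2.shape[0]
    n_amp = amp2.shape[0]
    out = np.empty((n_amp, n_pha))
    fn = _SCALAR[method]
    for i in range(n_amp):
        for j in range(n_pha):
            am = amp2[i, j] if method == "plv" else amp2[i]
            if method == "gc":
                out[i, j] = gcpac(pha2[j], am, clamp=False)
            else:
                out[i, j] = fn(pha2[j], am, n_bins, p)
    return out


def pac_grid(
    pha: np.ndarray,
    amp: np.ndarray,
    method: str = "mi",
    mode: Literal["concat", "average"] = "concat",
    engine: Literal["tensor", "loop"] = "tensor",
    n_bins: int = 18,
    p: float = 0.05,
) -> np.ndarray:
    """(n_amp × n_pha) coupling grid from extracted tensors.

    Parameters
    ----------
    pha : ndarray (n_pha, n_epochs, n_times)
        Instantaneous phases.
    amp : ndarray (n_amp, n_epochs, n_times), or (n_amp, n_pha, n_epochs, n_times) for plv
        Amplitude envelopes (for ``plv``: the phase of the envelope per
        phase band, see :func:`amplitude_phase`).
    mode : 'concat' | 'average'
        Concatenate epochs along time before estimating (default; the
        measures are defined on a single series), or estimate per epoch and
        average the grids.
    engine : 'tensor' | 'loop'
        Production vectorized path vs per-pair reference path.
    """
    pha = np.asarray(pha, dtype=float)
    amp = np.asarray(amp, dtype=float)
    if pha.ndim != 3:
        raise ValueError("pha must be (n_pha, n_epochs, n_times)")
    run = _grid_tensor if engine == "tensor" else _grid_loop
    if method not in METHODS:
        raise ValueError(f"unknown PAC method {method!r}; choose from {METHODS}")

    def flatten(e=None):
        if e is None:  # concat epochs
            p2 = pha.reshape(pha.shape[0], -1)
            a2 = amp.reshape(*amp.shape[: amp.ndim - 2], -1)
        else:
            p2 = pha[:, e, :]
            a2 = amp[..., e, :]
        return p2, a2

    if mode == "concat":
        p2, a2 = flatten()
        grid = run(method, p2, a2, n_bins, p)
    elif mode == "average":
        grids = []
        for e in range(pha.shape[1]):
            p2, a2 = flatten(e)
            grids.append(run(method, p2, a2, n_bins, p))
        grid = np.mean(grids, axis=0)
    else:
        raise ValueError(f"unknown epoch mode {mode!r}")
    return grid


def amplitude_phase(
    amp: AmplitudeTensor, pha_bands: BandGrid, sf: float, cycles: int = 3
) -> np.ndarray:
    """Phase of the amplitude envelope, filtered in each phase band.

    Returns ``(n_amp, n_pha, n_epochs, n_times)`` radians — the φ_a stream
    the phase-locking value compares against the slow phase.
    """
    vals = amp.values
    out = np.empty((vals.shape[0], pha_bands.n_bands) + vals.shape[1:])
    for j, band in enumerate(pha_bands):
        coefs = design_fir_ls(band, sf, cycles)
        filtered = apply_zero_phase(vals, coefs)
        out[:, j] = np.angle(_hilbert(filtered, axis=-1))
    return out


# ---------------------------------------------------------------------------
# high-level grid computation
# ---------------------------------------------------------------------------

@dataclass
class PacResult:
    """Coupling grid plus (optional) surrogate statistics.

    ``pac[i, j]`` is the coupling between phase band j and amplitude band i.
    """

    pac: np.ndarray
    method: str
    pha_bands: BandGrid
    amp_bands: BandGrid
    mode: str = "concat"
    n_bins: int = 18
    p: float = 0.05
    surrogates: np.ndarray | None = None
    pac_corrected: np.ndarray | None = None
    pvalues: np.ndarray | None = None
    pvalues_corrected: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = (self.amp_bands.n_bands, self.pha_bands.n_bands)
        if self.pac.shape != expected:
            raise ValueError(f"pac grid shape {self.pac.shape} != {expected}")

    def argmax_bands(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """(phase_band, amplitude_band) of the grid maximum."""
        i, j = np.unravel_index(np.argmax(self.pac), self.pac.shape)
        return self.pha_bands.bands[j], self.amp_bands.bands[i]


def compute_pac(
    x: EpochedSignal,
    pha_bands: BandGrid,
    amp_bands: BandGrid,
    method: str = "mi",
    mode: Literal["concat", "average"] = "concat",
    engine: Literal["tensor", "loop"] = "tensor",
    dcomplex: Literal["hilbert", "wavelet"] = "hilbert",
    cycles: tuple[int, int] = (3, 6),
    width: float = 7.0,
    n_bins: int = 18,
    p: float = 0.05,
    edge_discard: int = 0,
) -> PacResult:
    """Full comodulogram: extract phases and amplitudes, then grid a measure.

    ``edge_discard`` drops that many samples from each end of every epoch
    after filtering, excluding filter edge artifacts from the estimate.
    """
    if method not in METHODS:
        raise ValueError(f"unknown PAC method {method!r}; choose from {METHODS}")
    pha_bands.validate_against(x.sf)
    amp_bands.validate_against(x.sf)
    pha = extract_phase(x, pha_bands, method=dcomplex, cycles=cycles[0], width=width)
    amp = extract_amplitude(x, amp_bands, method=dcomplex, cycles=cycles[1], width=width)
    if method == "plv":
        amp_like = amplitude_phase(amp, pha_bands, x.sf, cycles=cycles[0])
    else:
        amp_like = amp.values
    pha_vals = pha.values
    if edge_discard:
        sl = slice(edge_discard, x.n_times - edge_discard)
        pha_vals = pha_vals[..., sl]
        amp_like = amp_like[..., sl]
    grid = pac_grid(pha_vals, amp_like, method, mode, engine, n_bins, p)
    diagnostics: dict = {}
    if method == "gc":
        diagnostics["raw"] = grid.copy()
        grid = np.clip(grid, 0.0, None)
    return PacResult(
        pac=grid,
        method=method,
        pha_bands=pha_bands,
        amp_bands=amp_bands,
        mode=mode,
        n_bins=n_bins,
        p=p,
        diagnostics=diagnostics,
    )
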