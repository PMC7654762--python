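"""Event-related (time-resolved, across-trials) phase-amplitude coupling.

Time-averaged PAC cannot distinguish genuine coupling from non-stationarity
within the averaging window. ERPAC instead asks, at every time sample, how
strongly the amplitude co-varies with the phase *across trials*. Two
statistics are implemented:

* ``circular`` — the circular-linear correlation ρ_cl between the phase
  angle and the (linear) amplitude, built from the three Pearson
  correlations r_sx = c(sin φ, a), r_cx = c(cos φ, a), r_sc = c(sin φ, cos φ):

      ρ_cl = sqrt((r_sx² + r_cx² − 2·r_sx·r_cx·r_sc) / (1 − r_sc²))

* ``gc`` — Gaussian-copula mutual information between the amplitude and
  [sin φ, cos φ] across trials, in bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import BandGrid, EpochedSignal
from .methods import _gauss_mi_bias, copnorm
from .spectral import extract_amplitude, extract_phase
from .surrogates import SurrogateSpec, build_null, pvalues_from_null

__all__ = ["ErpacResult", "circ_corr", "compute_erpac", "gc_erpac"]


def circ_corr(phase: np.ndarray, amp: np.ndarray) -> float:
    """Circular-linear correlation between a phase angle and a linear variable."""
    phase = np.asarray(phase, dtype=float).ravel()
    amp = np.asarray(amp, dtype=float).ravel()
    if phase.size < 3 or phase.size != amp.size:
        raise ValueError("need at least 3 paired samples")
    if np.ptp(amp) == 0:
        raise ValueError("constant amplitude: correlation undefined")
    s, c = np.sin(phase), np.cos(phase)

    def corr(u, v):
        du, dv = u - u.mean(), v - v.mean()
        den = np.sqrt((du @ du) * (dv @ dv))
        if den == 0:
            return 0.0
        return (du @ dv) / den

    r_sx, r_cx, r_sc = corr(s, amp), corr(c, amp), corr(s, c)
    den = 1 - r_sc**2
    if den < 1e-12:
        raise ValueError("degenerate phase sampling: sin and cos are collinear")
    rho2 = (r_sx**2 + r_cx**2 - 2 * r_sx * r_cx * r_sc) / den
    return float(np.sqrt(np.clip(rho2, 0.0, 1.0)))


def _circ_corr_tensor(pha: np.ndarray, amp: np.ndarray) -> np.ndarray:
    """Vectorized ρ_cl across the trial axis.

    pha : (n_epochs, n_times); amp : (n_amp, n_epochs, n_times)
    returns (n_amp, n_times).
    """
    s, c = np.sin(pha), np.cos(pha)

    def standardize(v, axis):
        v = v - v.mean(axis=axis, keepdims=True)
        sd = np.sqrt((v**2).mean(axis=axis, keepdims=True))
        bad = sd == 0
        if bad.any():
            raise ValueError("constant amplitude or phase across trials at some time point")
        return v / sd

    zs = standardize(s, 0)
    zc = standardize(c, 0)
    za = standardize(amp, 1)
    r_sx = np.einsum("et,aet->at", zs, za) / pha.shape[0]
    r_cx = np.einsum("et,aet->at", zc, za) / pha.shape[0]
    r_sc = (zs * zc).mean(axis=0)  # (n_times,)
    den = 1 - r_sc**2
    if np.any(den < 1e-12):
        raise ValueError("degenerate phase sampling: sin and cos are collinear")
    rho2 = (r_sx**2 + r_cx**2 - 2 * r_sx * r_cx * r_sc[None]) / den[None]
    return np.sqrt(np.clip(rho2, 0.0, 1.0))


def gc_erpac(pha: np.ndarray, amp: np.ndarray, clamp: bool = True) -> np.ndarray:
    """Across-trials Gaussian-copula MI per time point, in bits.

    pha : (n_epochs, n_times); amp : (n_amp, n_epochs, n_times)
    returns (n_amp, n_times).
    """
    pha = np.asarray(pha, dtype=float)
    amp = np.asarray(amp, dtype=float)
    n = pha.shape[0]
    if n < 10:
        raise ValueError("need at least 10 trials for the Gaussian-copula estimate")
    s = copnorm(np.sin(pha), axis=0)
    c = copnorm(np.cos(pha), axis=0)
    a = copnorm(amp, axis=1)
    s = s - s.mean(axis=0, keepdims=True)
    c = c - c.mean(axis=0, keepdims=True)
    a = a - a.mean(axis=1, keepdims=True)
    m = n - 1
    vss = np.einsum("et,et->t", s, s) / m
    vcc = np.einsum("et,et->t", c, c) / m
    vsc = np.einsum("et,et->t", s, c) / m
    vaa = np.einsum("aet,aet->at", a, a) / m
    vas = np.einsum("aet,et->at", a, s) / m
    vac = np.einsum("aet,et->at", a, c) / m
    detx = vss * vcc - vsc**2
    detxy = (
        vss[None] * (vcc[None] * vaa - vac**2)
        - vsc[None] * (vsc[None] * vaa - vac * vas)
        + vas * (vsc[None] * vac - vcc[None] * vas)
    )
    if np.any(detx <= 0) or np.any(detxy <= 0) or np.any(vaa <= 0):
        raise ValueError("singular joint covariance: MI undefined")
    i_nats = 0.5 * (np.log(detx)[None] + np.log(vaa) - np.log(detxy)) - _gauss_mi_bias(n)
    i_bits = i_nats / np.log(2.0)
    return np.clip(i_bits, 0.0, None) if clamp else i_bits


@dataclass
class ErpacResult:
    """Time-resolved coupling, ``values[i, t]`` per amplitude band and sample."""

    values: np.ndarray
    method: str
    pha_band: tuple[float, float]
    amp_bands: BandGrid
    sf: float
    pvalues: np.ndarray | None = None
    surrogates: np.ndarray | None = None

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.shape[-1]) / self.sf

    def save_npz(self, path) -> None:
        np.savez(
            path,
            values=self.values,
            times=self.times,
            amp_bands=self.amp_bands.as_array(),
            pha_band=np.asarray(self.pha_band),
            method=self.method,
            sf=self.sf,
        )


def compute_erpac(
    x: EpochedSignal,
    pha_band: tuple[float, float],
    amp_bands: BandGrid,
    method: Literal["circular", "gc"] = "circular",
    engine: Literal["tensor", "loop"] = "tensor",
    dcomplex: Literal["hilbert", "wavelet"] = "hilbert",
    cycles: tuple[int, int] = (3, 6),
    width: float = 7.0,
    n_perm: int = 0,
    seed: int | None = None,
    n_jobs: int = 1,
) -> ErpacResult:
    """Across-trials PAC at every time sample.

    With ``n_perm > 0``, p-values are obtained by re-estimating after random
    trial swaps of the amplitude (the across-trial pairing is destroyed, the
    per-trial content preserved).
    """
    if x.n_epochs < 3:
        raise ValueError("ERPAC needs at least 3 epochs (trials)")
    pha = extract_phase(
        x, BandGrid([pha_band], role="phase"), method=dcomplex, cycles=cycles[0], width=width
    ).values[0]
    amp = extract_amplitude(
        x, amp_bands, method=dcomplex, cycles=cycles[1], width=width
    ).values

    def measure(a):
        if method == "circular":
            return _circ_corr_tensor(pha, a)
        if method == "gc":
            return gc_erpac(pha, a)
        raise ValueError(f"unknown ERPAC method {method!r}")

    if engine == "tensor":
        values = measure(amp)
    elif engine == "loop":
        if method != "circular":
            raise ValueError("loop engine is defined for the circular method")
        values = np.empty((amp.shape[0], x.n_times))
        for i in range(amp.shape[0]):
            for t in range(x.n_times):
                values[i, t] = circ_corr(pha[:, t], amp[i, :, t])
    else:
        raise ValueError(f"unknown engine {engine!r}")

    pvals = surr = None
    if n_perm > 0:
        spec = SurrogateSpec(method="trial_swap", n_perm=n_perm, seed=seed)
        surr = build_null(
            measure, amp, spec, n_times=x.n_times, n_epochs=x.n_epochs, n_jobs=n_jobs
        )
        pvals = pvalues_from_null(values, surr)
    return ErpacResult(
        values=values,
        method=method,
        pha_band=tuple(pha_band),
        amp_bands=amp_bands,
        sf=x.sf,
        pvalues=pvals,
        surrogates=surr,
    )
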