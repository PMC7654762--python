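"""Synthetic signals with a planted phase-amplitude coupling.

Two generators are provided. ``simulate_pac_tort`` builds each epoch from pure
sinusoids: a slow driver at ``f_pha`` plus a fast carrier at ``f_amp`` whose
envelope is a sinusoidal function of the driver's instantaneous phase. The
result is a clean, fully deterministic coupling (given a seed, noise aside)
whose envelope maximum occurs at a controllable driver phase angle.

``simulate_pac_wavelet`` instead derives the slow phase from band-limited
filtered white noise, producing non-sinusoidal, trial-varying drivers — the
appropriate input for across-trial (event-related) coupling analyses, where
the phase must differ between epochs at a fixed time point.

The ``coupling`` knob runs from 0 (the fast envelope is flat, no coupling) to
1 (the envelope is fully modulated by the slow phase).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.signal import fftconvolve

from .core import EpochedSignal

__all__ = ["SimSpec", "simulate_pac_tort", "simulate_pac_wavelet", "save_simulation"]


@dataclass
class SimSpec:
    """Parameters of a planted-coupling simulation.

    Defaults reproduce the standard benchmark condition used throughout the
    test-suite: 20 epochs of ~5.9 s at 512 Hz with a strong 10↔100 Hz
    coupling and unit-variance additive Gaussian noise.

    Attributes
    ----------
    f_pha, f_amp : float
        Driver (phase) and carrier (amplitude) frequencies in Hz.
    sf : float
        Sampling frequency in Hz.
    n_epochs, n_times : int
        Number of epochs and samples per epoch.
    coupling : float
        Coupling strength in [0, 1]; 0 = no modulation, 1 = maximal.
    noise : float
        Standard deviation of additive white Gaussian noise.
    preferred_phase : float
        Driver phase angle (radians) at which the fast envelope peaks.
    seed : int or None
        Seed for all randomness in one call; None = nondeterministic.
    """

    f_pha: float = 10.0
    f_amp: float = 100.0
    sf: float = 512.0
    n_epochs: int = 20
    n_times: int = 3000
    coupling: float = 0.9
    noise: float = 1.0
    preferred_phase: float = 0.0
    seed: int | None = None

    def validate(self) -> None:
        if not 0 <= self.coupling <= 1:
            raise ValueError(f"coupling must lie in [0, 1], got {self.coupling}")
        if not 0 < self.f_pha < self.f_amp:
            raise ValueError(
                f"need 0 < f_pha < f_amp, got f_pha={self.f_pha}, f_amp={self.f_amp}"
            )
        if not self.f_amp < self.sf / 2:
            raise ValueError(
                f"f_amp={self.f_amp} Hz violates the Nyquist bound sf/2={self.sf / 2} Hz"
            )
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if self.n_times < 2 * self.sf / self.f_pha:
            raise ValueError(
                f"n_times={self.n_times} is shorter than 2 slow cycles "
                f"(needs >= {2 * self.sf / self.f_pha:.0f} samples at f_pha={self.f_pha} Hz)"
            )
        if self.noise < 0:
            raise ValueError("noise std must be >= 0")


def _rng(spec: SimSpec) -> np.random.Generator:
    return np.random.default_rng(spec.seed)


def simulate_pac_tort(spec: SimSpec) -> EpochedSignal:
    """Sinusoidal planted coupling.

    Each epoch is::

        x(t) = [c·(sin(2π f_pha t − pp) + 1)/2 + (1 − c)] · sin(2π f_amp t)
               + sin(2π f_pha t) + noise·ε(t)

    with c the coupling strength and pp the preferred phase. With ``c = 0``
    the fast envelope is constant (no modulation); with ``c = 1`` it swings
    between 0 and 1, peaking where the driver's Hilbert phase equals ``pp``.
    """
    spec.validate()
    rng = _rng(spec)
    t = np.arange(spec.n_times) / spec.sf
    driver = np.sin(2 * np.pi * spec.f_pha * t)
    modulator = (
        spec.coupling * (np.sin(2 * np.pi * spec.f_pha * t - spec.preferred_phase) + 1) / 2
        + (1 - spec.coupling)
    )
    carrier = np.sin(2 * np.pi * spec.f_amp * t)
    clean = modulator * carrier + driver
    data = np.tile(clean, (spec.n_epochs, 1))
    if spec.noise > 0:
        data = data + spec.noise * rng.standard_normal(data.shape)
    return EpochedSignal(data, spec.sf)


def _morlet_kernel(f: float, sf: float, width: float = 7.0) -> np.ndarray:
    """Complex Morlet kernel, gain-normalized at its centre frequency."""
    sigma_t = width / (2 * np.pi * f)
    half = int(np.ceil(5 * sigma_t * sf))
    t = np.arange(-half, half + 1) / sf
    gauss = np.exp(-(t**2) / (2 * sigma_t**2))
    kern = gauss * np.exp(2j * np.pi * f * t)
    # a pure cosine at f maps to a unit-modulus analytic output
    return kern / (0.5 * gauss.sum())


def simulate_pac_wavelet(spec: SimSpec) -> EpochedSignal:
    """Stochastic-driver planted coupling.

    The slow component of each epoch is white noise narrow-band filtered with
    a Morlet kernel at ``f_pha``; its analytic angle defines the instantaneous
    phase, which differs between epochs. The fast carrier's envelope is
    ``(1 + c·cos(φ(t) − pp))/2``.
    """
    spec.validate()
    rng = _rng(spec)
    t = np.arange(spec.n_times) / spec.sf
    kern = _morlet_kernel(spec.f_pha, spec.sf, width=7.0)
    white = rng.standard_normal((spec.n_epochs, spec.n_times))
    analytic = fftconvolve(white, kern[None, :], mode="same", axes=1)
    # unit-RMS slow component so the driver dominates the carrier as in the
    # sinusoidal generator
    slow = analytic.real
    rms = np.sqrt(np.mean(slow**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    slow = slow / rms
    phase = np.angle(analytic)
    envelope = (1 + spec.coupling * np.cos(phase - spec.preferred_phase)) / 2
    carrier = np.sin(2 * np.pi * spec.f_amp * t)[None, :]
    data = slow + envelope * carrier
    if spec.noise > 0:
        data = data + spec.noise * rng.standard_normal(data.shape)
    return EpochedSignal(data, spec.sf)


def save_simulation(path: str | Path, sig: EpochedSignal, spec: SimSpec) -> None:
    """Write epochs to ``<path>.npz`` with a JSON sidecar of the spec."""
    path = Path(path)
    npz = path if path.suffix == ".npz" else path.with_suffix(".npz")
    np.savez(npz, data=sig.data, sf=sig.sf)
    sidecar = npz.with_suffix(".json")
    sidecar.write_text(json.dumps(asdict(spec), indent=2))
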