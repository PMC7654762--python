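"""Core containers: epoched signals, frequency-band grids, phase/amplitude tensors.

Every analysis in :mod:`pacbox` starts from an :class:`EpochedSignal` — a plain
``(n_epochs, n_times)`` array of a single channel's voltage trace plus its
sampling frequency — and a :class:`BandGrid` describing the frequency bands in
which instantaneous phases or amplitude envelopes are extracted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "EpochedSignal",
    "BandGrid",
    "PhaseTensor",
    "AmplitudeTensor",
    "make_bands",
]


@dataclass
class EpochedSignal:
    """A single-channel, multi-epoch time series.

    Parameters
    ----------
    data : ndarray, shape (n_epochs, n_times)
        Real-valued signal. A 1-D input is promoted to a single epoch.
    sf : float
        Sampling frequency in Hz.
    """

    data: np.ndarray
    sf: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        if arr.ndim != 2:
            raise ValueError(
                f"data must be 1-D or 2-D (epochs x times), got ndim={arr.ndim}"
            )
        if arr.shape[1] < 2:
            raise ValueError("need at least 2 time points per epoch")
        if not np.isfinite(arr).all():
            bad = int(np.argwhere(~np.isfinite(arr).all(axis=1))[0, 0])
            raise ValueError(f"non-finite values in epoch {bad}")
        if not self.sf > 0:
            raise ValueError(f"sampling frequency must be > 0, got {self.sf}")
        self.data = arr
        self.sf = float(self.sf)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Time vector in seconds, starting at 0."""
        return np.arange(self.n_times) / self.sf

    def save_npz(self, path: str | Path) -> None:
        np.savez(path, data=self.data, sf=self.sf)

    @classmethod
    def from_npz(cls, path: str | Path) -> "EpochedSignal":
        with np.load(path) as f:
            return cls(f["data"], float(f["sf"]))


def _validate_band(band: Sequence[float], sf: float | None, what: str) -> tuple[float, float]:
    f1, f2 = float(band[0]), float(band[1])
    if not 0 < f1 < f2:
        raise ValueError(f"{what} band must satisfy 0 < f_start < f_end, got ({f1}, {f2})")
    if sf is not None and f2 >= sf / 2:
        raise ValueError(
            f"{what} band end {f2} Hz violates the Nyquist bound sf/2 = {sf / 2} Hz"
        )
    return f1, f2


@dataclass
class BandGrid:
    """Ordered list of (f_start, f_end) Hz intervals for phase or amplitude."""

    bands: list[tuple[float, float]]
    role: Literal["phase", "amplitude"] = "phase"

    def __post_init__(self) -> None:
        self.bands = [(_validate_band(b, None, self.role))[0:2] for b in self.bands]
        self.bands = [(float(a), float(b)) for a, b in self.bands]
        if len(self.bands) == 0:
            raise ValueError("empty band grid")

    def validate_against(self, sf: float) -> None:
        for b in self.bands:
            _validate_band(b, sf, self.role)

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def centers(self) -> np.ndarray:
        return np.array([(a + b) / 2 for a, b in self.bands])

    def as_array(self) -> np.ndarray:
        return np.asarray(self.bands, dtype=float)

    def __iter__(self):
        return iter(self.bands)

    def __len__(self) -> int:
        return len(self.bands)


def make_bands(
    start: float,
    stop: float,
    width: float,
    step: float | None = None,
    role: Literal["phase", "amplitude"] = "phase",
) -> BandGrid:
    """Build a contiguous (or overlapping, if ``step < width``) band grid.

    ``make_bands(2, 20, 2)`` gives (2,4), (4,6), ..., (18,20).
    """
    if step is None:
        step = width
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    starts = np.arange(start, stop - width + step / 2, step)
    bands = [(float(s), float(s + width)) for s in starts]
    return BandGrid(bands, role=role)


@dataclass
class PhaseTensor:
    """Instantaneous phase in radians over (band, epoch, time), values in (−π, π]."""

    values: np.ndarray
    bands: BandGrid
    sf: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[0] != self.bands.n_bands:
            raise ValueError("phase tensor must be (n_bands, n_epochs, n_times)")
        self.values = v

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]


@dataclass
class AmplitudeTensor:
    """Non-negative amplitude envelope over (band, epoch, time)."""

    values: np.ndarray
    bands: BandGrid
    sf: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[0] != self.bands.n_bands:
            raise ValueError("amplitude tensor must be (n_bands, n_epochs, n_times)")
        if (v < 0).any():
            raise ValueError("amplitude envelopes must be non-negative")
        self.values = v

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]
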