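"""Model/Results interface for corrected phase-amplitude coupling.

The central object is :class:`PhaseAmplitudeCoupling`: a model built from an
epoched signal and an analysis configuration, whose :meth:`fit` runs the
four-step workflow — (1) extract phases and amplitudes, (2) estimate the
coupling grid, (3) build a surrogate null, (4) normalize the estimate and
derive permutation p-values — and returns a :class:`PacResults` carrying the
grids, the null, the corrected values and their uncertainties.

:class:`EventRelatedPac` and :class:`PreferredPhase` follow the same
pattern for time-resolved coupling and preferred-phase estimation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .core import BandGrid, EpochedSignal, make_bands
from .erpac import ErpacResult, compute_erpac
from .methods import METHODS, PacResult, amplitude_phase, pac_grid
from .spectral import extract_amplitude, extract_phase
from .surrogates import (
    SurrogateSpec,
    build_null,
    maxstat_correction,
    normalize_pac,
    pvalues_from_null,
)
from .tools import PreferredPhaseResult, preferred_phase

logger = logging.getLogger("pacbox")

__all__ = [
    "PacConfig",
    "PhaseAmplitudeCoupling",
    "PacResults",
    "EventRelatedPac",
    "PreferredPhase",
    "run_corrected_pac",
]

DEFAULT_PHA = ((2.0, 20.0), 2.0)  # range, width
DEFAULT_AMP = ((60.0, 160.0), 10.0)


def _grid_from_any(bands, role) -> BandGrid:
    if isinstance(bands, BandGrid):
        return bands
    return BandGrid([tuple(b) for b in bands], role=role)


@dataclass
class PacConfig:
    """Serializable description of a full corrected-PAC computation."""

    method: str = "mi"
    pha_bands: list = field(
        default_factory=lambda: [list(b) for b in make_bands(2, 20, 2)]
    )
    amp_bands: list = field(
        default_factory=lambda: [list(b) for b in make_bands(60, 160, 10, role="amplitude")]
    )
    dcomplex: str = "hilbert"
    cycles: tuple[int, int] = (3, 6)
    width: float = 7.0
    n_bins: int = 18
    mode: str = "concat"
    p: float = 0.05
    edge_discard: int = 0
    surrogate: str = "block_swap"
    n_perm: int = 200
    norm: str = "zscore"
    mcp: str = "maxstat"
    seed: int | None = None
    n_jobs: int = 1

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PacConfig":
        d = json.loads(Path(path).read_text())
        d["cycles"] = tuple(d["cycles"])
        return cls(**d)


class PacResults:
    """Results of a (optionally surrogate-corrected) PAC fit.

    Attributes
    ----------
    pac : ndarray (n_amp, n_pha)
        Uncorrected coupling grid.
    surrogates : ndarray (n_perm, n_amp, n_pha) or None
        Null stack.
    pac_corrected : ndarray or None
        Normalized grid (z-score or mean-subtracted, per config).
    pvalues, pvalues_corrected : ndarray or None
        Per-cell permutation p-values, uncorrected and maxstat-corrected.
    """

    def __init__(self, model: "PhaseAmplitudeCoupling", result: PacResult, elapsed: float):
        self.model = model
        self._result = result
        self.pac = result.pac
        self.surrogates = result.surrogates
        self.pac_corrected = result.pac_corrected
        self.pvalues = result.pvalues
        self.pvalues_corrected = result.pvalues_corrected
        self.diagnostics = result.diagnostics
        self.elapsed = elapsed

    @property
    def pha_bands(self) -> BandGrid:
        return self._result.pha_bands

    @property
    def amp_bands(self) -> BandGrid:
        return self._result.amp_bands

    def argmax_bands(self):
        """(phase_band, amplitude_band) at the grid maximum."""
        return self._result.argmax_bands()

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        r = self._result
        pb, ab = self.argmax_bands()
        lines = [
            "Phase-Amplitude Coupling Results",
            "=" * 40,
            f"method:            {r.method}",
            f"epoch mode:        {r.mode}",
            f"grid:              {self.pac.shape[0]} amplitude x {self.pac.shape[1]} phase bands",
            f"max coupling:      {self.pac.max():.6g}",
            f"  at phase band:   {pb[0]:.6g}-{pb[1]:.6g} Hz",
            f"  amplitude band:  {ab[0]:.6g}-{ab[1]:.6g} Hz",
        ]
        if self.surrogates is not None:
            lines += [
                f"surrogates:        {self.surrogates.shape[0]} ({self.model.config.surrogate})",
                f"normalization:     {self.model.config.norm}",
                f"max corrected:     {np.nanmax(self.pac_corrected):.6g}",
                f"min p (cellwise):  {self.pvalues.min():.6g}",
                f"min p (maxstat):   {self.pvalues_corrected.min():.6g}",
            ]
        lines.append(f"elapsed:           {self.elapsed:.2f} s")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PacResults {self._result.method} grid={self.pac.shape}>"

    # -- export ------------------------------------------------------------
    def plot_data(self) -> dict:
        """Comodulogram arrays + axis metadata (Hz), rendering-agnostic."""
        out = {
            "pac": self.pac,
            "pha_centers_hz": self.pha_bands.centers,
            "amp_centers_hz": self.amp_bands.centers,
            "pha_bands_hz": self.pha_bands.as_array(),
            "amp_bands_hz": self.amp_bands.as_array(),
        }
        for name in ("pac_corrected", "pvalues", "pvalues_corrected"):
            v = getattr(self, name)
            if v is not None:
                out[name] = v
        return out

    def save(self, path: str | Path) -> None:
        """NPZ with the grids + JSON sidecar with the configuration."""
        path = Path(path)
        npz = path if path.suffix == ".npz" else path.with_suffix(".npz")
        payload = {k: v for k, v in self.plot_data().items()}
        if self.surrogates is not None:
            payload["surrogates"] = self.surrogates
        np.savez(npz, **payload)
        self.model.config.to_json(npz.with_suffix(".json"))

    def plot(self, ax=None, corrected: bool = False, **imshow_kw):  # pragma: no cover
        """Render the comodulogram with matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = self.pac_corrected if corrected else self.pac
        pc = self.pha_bands.centers
        ac = self.amp_bands.centers
        im = ax.imshow(
            grid, origin="lower", aspect="auto",
            extent=[pc[0], pc[-1], ac[0], ac[-1]], **imshow_kw,
        )
        ax.set_xlabel("phase frequency (Hz)")
        ax.set_ylabel("amplitude frequency (Hz)")
        ax.figure.colorbar(im, ax=ax, label=self._result.method)
        return ax


class PhaseAmplitudeCoupling:
    """Corrected-PAC model over an epoched signal.

    Parameters
    ----------
    data : ndarray (n_epochs, n_times) or EpochedSignal
    sf : float
        Sampling frequency (ignored if ``data`` is an EpochedSignal).
    pha_bands, amp_bands : BandGrid or sequence of (f_start, f_end)
        Phase/amplitude grids; defaults 2-20 Hz in 2 Hz bands and
        60-160 Hz in 10 Hz bands.
    method : one of 'mvl', 'mi', 'hr', 'ndpac', 'plv', 'gc'
    """

    def __init__(
        self,
        data,
        sf: float | None = None,
        pha_bands=None,
        amp_bands=None,
        method: str = "mi",
        dcomplex: Literal["hilbert", "wavelet"] = "hilbert",
        cycles: tuple[int, int] = (3, 6),
        width: float = 7.0,
        n_bins: int = 18,
        mode: Literal["concat", "average"] = "concat",
        p: float = 0.05,
        edge_discard: int = 0,
    ):
        if isinstance(data, EpochedSignal):
            self.signal = data
        else:
            if sf is None:
                raise ValueError("sf is required when data is a raw array")
            self.signal = EpochedSignal(data, sf)
        if method not in METHODS:
            raise ValueError(f"unknown PAC method {method!r}; choose from {METHODS}")
        if pha_bands is None:
            pha_bands = make_bands(*DEFAULT_PHA[0], DEFAULT_PHA[1], role="phase")
        if amp_bands is None:
            amp_bands = make_bands(*DEFAULT_AMP[0], DEFAULT_AMP[1], role="amplitude")
        self.pha_bands = _grid_from_any(pha_bands, "phase")
        self.amp_bands = _grid_from_any(amp_bands, "amplitude")
        # fail on inconsistent band/sf combinations before any filtering
        self.pha_bands.validate_against(self.signal.sf)
        self.amp_bands.validate_against(self.signal.sf)
        self.method = method
        self.dcomplex = dcomplex
        self.cycles = tuple(cycles)
        self.width = width
        self.n_bins = n_bins
        self.mode = mode
        self.p = p
        self.edge_discard = int(edge_discard)
        self.config = PacConfig(
            method=method,
            pha_bands=[list(b) for b in self.pha_bands],
            amp_bands=[list(b) for b in self.amp_bands],
            dcomplex=dcomplex,
            cycles=self.cycles,
            width=width,
            n_bins=n_bins,
            mode=mode,
            p=p,
            edge_discard=self.edge_discard,
        )

    @classmethod
    def from_config(cls, data, sf: float | None, config: PacConfig) -> "PhaseAmplitudeCoupling":
        return cls(
            data, sf,
            pha_bands=config.pha_bands, amp_bands=config.amp_bands,
            method=config.method, dcomplex=config.dcomplex, cycles=config.cycles,
            width=config.width, n_bins=config.n_bins, mode=config.mode,
            p=config.p, edge_discard=config.edge_discard,
        )

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        n_perm: int = 200,
        surrogate: str = "block_swap",
        norm: Literal["zscore", "mean_sub"] = "zscore",
        mcp: Literal["maxstat", "none"] = "maxstat",
        seed: int | None = None,
        n_jobs: int = 1,
        engine: Literal["tensor", "loop"] = "tensor",
    ) -> PacResults:
        """Estimate the grid and, if ``n_perm > 0``, correct it against a null.

        Identical seeds give identical results regardless of ``n_jobs``.
        """
        t0 = time.time()
        x = self.signal
        self.config.surrogate = surrogate
        self.config.n_perm = n_perm
        self.config.norm = norm
        self.config.mcp = mcp
        self.config.seed = seed
        self.config.n_jobs = n_jobs

        logger.info(
            "extracting phases/amplitudes: %d epochs x %d samples, %d pha x %d amp bands",
            x.n_epochs, x.n_times, self.pha_bands.n_bands, self.amp_bands.n_bands,
        )
        pha = extract_phase(
            x, self.pha_bands, method=self.dcomplex, cycles=self.cycles[0], width=self.width
        ).values
        amp_t = extract_amplitude(
            x, self.amp_bands, method=self.dcomplex, cycles=self.cycles[1], width=self.width
        )
        if self.method == "plv":
            amp_like = amplitude_phase(amp_t, self.pha_bands, x.sf, cycles=self.cycles[0])
        else:
            amp_like = amp_t.values
        if self.edge_discard:
            sl = slice(self.edge_discard, x.n_times - self.edge_discard)
            pha = pha[..., sl]
            amp_like = amp_like[..., sl]

        # In concat mode, time-axis surrogates (block swap / time lag) must cut
        # the concatenated series, so epochs are folded into one pseudo-epoch
        # up-front (the concatenated estimate itself is unchanged). Trial
        # swapping instead needs the epoch axis, so the tensors keep it.
        pha_m, amp_m = pha, amp_like
        if self.mode == "concat" and surrogate != "trial_swap":
            pha_m = pha.reshape(pha.shape[0], 1, -1)
            lead = amp_like.shape[: amp_like.ndim - 2]
            amp_m = amp_like.reshape(*lead, 1, -1)

        def measure(a):
            return pac_grid(
                pha_m, a, self.method, self.mode, engine, self.n_bins, self.p
            )

        t1 = time.time()
        grid = measure(amp_m)
        raw = None
        if self.method == "gc":
            raw = grid.copy()
            grid = np.clip(grid, 0.0, None)
        logger.info("true %s grid computed in %.2f s", self.method, time.time() - t1)

        surr = corrected = pv = pv_mc = None
        if n_perm > 0:
            t2 = time.time()
            spec = SurrogateSpec(method=surrogate, n_perm=n_perm, seed=seed)
            surr = build_null(
                measure, amp_m, spec,
                n_times=amp_m.shape[-1], n_epochs=amp_m.shape[-2], n_jobs=n_jobs,
            )
            if self.method == "gc":
                surr = np.clip(surr, 0.0, None)
            corrected = normalize_pac(grid, surr, mode=norm)
            pv = pvalues_from_null(grid, surr)
            if mcp == "maxstat":
                pv_mc = maxstat_correction(grid, surr)
            logger.info("null of %d permutations built in %.2f s", n_perm, time.time() - t2)

        result = PacResult(
            pac=grid, method=self.method,
            pha_bands=self.pha_bands, amp_bands=self.amp_bands,
            mode=self.mode, n_bins=self.n_bins, p=self.p,
            surrogates=surr, pac_corrected=corrected,
            pvalues=pv, pvalues_corrected=pv_mc,
            diagnostics={} if raw is None else {"raw": raw},
        )
        return PacResults(self, result, elapsed=time.time() - t0)


class EventRelatedPac:
    """Time-resolved across-trials PAC model (see :mod:`pacbox.erpac`)."""

    def __init__(
        self,
        data,
        sf: float | None = None,
        pha_band: tuple[float, float] = (9.0, 11.0),
        amp_bands=None,
        method: Literal["circular", "gc"] = "circular",
        dcomplex: Literal["hilbert", "wavelet"] = "hilbert",
        cycles: tuple[int, int] = (3, 6),
        width: float = 7.0,
    ):
        self.signal = data if isinstance(data, EpochedSignal) else EpochedSignal(data, sf)
        if amp_bands is None:
            amp_bands = make_bands(60, 160, 10, role="amplitude")
        self.pha_band = tuple(pha_band)
        self.amp_bands = _grid_from_any(amp_bands, "amplitude")
        self.method = method
        self.dcomplex = dcomplex
        self.cycles = tuple(cycles)
        self.width = width

    def fit(self, n_perm: int = 0, seed: int | None = None, n_jobs: int = 1) -> ErpacResult:
        return compute_erpac(
            self.signal, self.pha_band, self.amp_bands,
            method=self.method, dcomplex=self.dcomplex,
            cycles=self.cycles, width=self.width,
            n_perm=n_perm, seed=seed, n_jobs=n_jobs,
        )


class PreferredPhase:
    """Preferred-phase model: which driver phase hosts the amplitude maxima."""

    def __init__(
        self,
        data,
        sf: float | None = None,
        pha_band: tuple[float, float] = (5.0, 7.0),
        amp_bands=None,
        n_bins: int = 18,
        dcomplex: Literal["hilbert", "wavelet"] = "hilbert",
        cycles: tuple[int, int] = (3, 6),
        width: float = 7.0,
    ):
        self.signal = data if isinstance(data, EpochedSignal) else EpochedSignal(data, sf)
        if amp_bands is None:
            amp_bands = make_bands(60, 160, 10, role="amplitude")
        self.pha_band = tuple(pha_band)
        self.amp_bands = _grid_from_any(amp_bands, "amplitude")
        self.n_bins = n_bins
        self.dcomplex = dcomplex
        self.cycles = tuple(cycles)
        self.width = width

    def fit(self) -> PreferredPhaseResult:
        x = self.signal
        pha = extract_phase(
            x, BandGrid([self.pha_band], role="phase"),
            method=self.dcomplex, cycles=self.cycles[0], width=self.width,
        ).values[0]
        amp = extract_amplitude(
            x, self.amp_bands, method=self.dcomplex,
            cycles=self.cycles[1], width=self.width,
        ).values
        return preferred_phase(pha, amp.reshape(amp.shape[0], -1), n_bins=self.n_bins)

    @staticmethod
    def polar_data(result: PreferredPhaseResult, amp_bands: BandGrid) -> dict:
        """Arrays for a polar amplitude-by-phase plot (rows = phase bins)."""
        return {
            "binned_amp": result.binned_amp,
            "angles_deg": result.bin_centers_deg,
            "amp_centers_hz": amp_bands.centers,
            "pp_deg": result.pp,
        }


def run_corrected_pac(x: EpochedSignal, config: PacConfig) -> PacResults:
    """Fig-1-style 4-step workflow driven entirely by a config object."""
    model = PhaseAmplitudeCoupling.from_config(x, x.sf, config)
    return model.fit(
        n_perm=config.n_perm, surrogate=config.surrogate, norm=config.norm,
        mcp=config.mcp, seed=config.seed, n_jobs=config.n_jobs,
    )
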