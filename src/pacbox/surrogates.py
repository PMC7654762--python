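"""Surrogate null distributions, PAC correction and non-parametric inference.

A surrogate destroys the phase-amplitude dependence while preserving the
amplitude's sample multiset and (as far as possible) its temporal structure.
Only the amplitude-side stream is ever transformed; the phase stream is left
untouched. Three families are available:

* ``block_swap`` — split the amplitude at a random time point into two
  blocks and swap their order (a circular shift; with only two blocks this
  is the most conservative null).
* ``time_lag`` — circular shift by a random lag.
* ``trial_swap`` — permute the epoch axis (never the identity permutation),
  pairing each phase epoch with another epoch's amplitude.

From the resulting null stack one can z-score or mean-subtract the true
estimate, obtain per-cell permutation p-values, and control the family-wise
error rate over a comodulogram via the maximum-statistics distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from joblib import Parallel, delayed

__all__ = [
    "SurrogateSpec",
    "surrogate_block_swap",
    "surrogate_time_lag",
    "surrogate_trial_swap",
    "build_null",
    "normalize_pac",
    "pvalues_from_null",
    "maxstat_correction",
]

SURROGATE_METHODS = ("block_swap", "time_lag", "trial_swap")


@dataclass
class SurrogateSpec:
    """How to build the null: surrogate family, permutation count, seed."""

    method: Literal["block_swap", "time_lag", "trial_swap"] = "block_swap"
    n_perm: int = 200
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.method not in SURROGATE_METHODS:
            raise ValueError(
                f"unknown surrogate method {self.method!r}; choose from {SURROGATE_METHODS}"
            )
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def surrogate_block_swap(amp: np.ndarray, cut: int) -> np.ndarray:
    """Swap the two time blocks around ``cut``: ``[amp[cut:], amp[:cut]]``."""
    amp = np.asarray(amp)
    n = amp.shape[-1]
    if not 0 < cut < n:
        raise ValueError(f"cut must lie strictly inside (0, {n}), got {cut}")
    return np.concatenate([amp[..., cut:], amp[..., :cut]], axis=-1)


def surrogate_time_lag(amp: np.ndarray, lag: int) -> np.ndarray:
    """Circular shift of the amplitude by ``lag`` samples."""
    return np.roll(np.asarray(amp), int(lag), axis=-1)


def surrogate_trial_swap(amp: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Permute the epoch axis (second-to-last) of the amplitude tensor."""
    amp = np.asarray(amp)
    perm = np.asarray(perm)
    n_ep = amp.shape[-2]
    if sorted(perm.tolist()) != list(range(n_ep)):
        raise ValueError(f"perm must be a permutation of range({n_ep})")
    if n_ep > 1 and np.array_equal(perm, np.arange(n_ep)):
        raise ValueError("identity permutation is not a valid trial swap")
    return amp[..., perm, :]


def _non_identity_permutation(rng: np.random.Generator, n: int) -> np.ndarray:
    if n < 2:
        raise ValueError("trial_swap needs at least 2 epochs")
    while True:
        perm = rng.permutation(n)
        if not np.array_equal(perm, np.arange(n)):
            return perm


def draw_surrogate_params(
    spec: SurrogateSpec, n_times: int, n_epochs: int
) -> list:
    """Pre-draw all random surrogate parameters from the spec's seed.

    Drawing up-front makes the null reproducible and independent of how the
    permutations are later dispatched (serial or parallel).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.method == "block_swap":
        if spec.n_perm > n_times - 1:
            warnings.warn(
                "more permutations than unique cut points; sampling with replacement",
                RuntimeWarning,
                stacklevel=2,
            )
        return [int(rng.integers(1, n_times)) for _ in range(spec.n_perm)]
    if spec.method == "time_lag":
        return [int(rng.integers(1, n_times)) for _ in range(spec.n_perm)]
    return [_non_identity_permutation(rng, n_epochs) for _ in range(spec.n_perm)]


def _transform(method: str, amp: np.ndarray, param) -> np.ndarray:
    if method == "block_swap":
        return surrogate_block_swap(amp, param)
    if method == "time_lag":
        return surrogate_time_lag(amp, param)
    return surrogate_trial_swap(amp, param)


def build_null(
    measure: Callable[[np.ndarray], np.ndarray],
    amp_like: np.ndarray,
    spec: SurrogateSpec,
    n_times: int | None = None,
    n_epochs: int | None = None,
    n_jobs: int = 1,
) -> np.ndarray:
    """Surrogate stack ``(n_perm, *grid_shape)``.

    ``measure`` re-estimates the coupling grid from a transformed amplitude
    stream (the phase stream is fixed inside the closure). ``amp_like`` is
    the amplitude-side tensor with time as the last axis and — when trial
    swapping — epochs as the second-to-last axis.

    Time-axis surrogates (block swap, time lag) act on the concatenated/
    epoch-resolved time axis exactly as the measure consumes it.
    """
    amp_like = np.asarray(amp_like)
    nt = n_times if n_times is not None else amp_like.shape[-1]
    ne = n_epochs if n_epochs is not None else (
        amp_like.shape[-2] if amp_like.ndim >= 2 else 1
    )
    params = draw_surrogate_params(spec, nt, ne)
    jobs = (delayed(measure)(_transform(spec.method, amp_like, p)) for p in params)
    grids = Parallel(n_jobs=n_jobs, prefer="threads")(jobs)
    return np.stack([np.asarray(g) for g in grids], axis=0)


def normalize_pac(
    pac: np.ndarray, null: np.ndarray, mode: Literal["zscore", "mean_sub"] = "zscore"
) -> np.ndarray:
    """Correct the true estimate against its null.

    ``zscore``: ``(pac − mean(null))/std(null)``; ``mean_sub``: ``pac − mean(null)``.
    """
    pac = np.asarray(pac, dtype=float)
    null = np.asarray(null, dtype=float)
    mean = null.mean(axis=0)
    if mode == "mean_sub":
        return pac - mean
    if mode == "zscore":
        std = null.std(axis=0, ddof=1)
        if np.any(std == 0):
            cell = tuple(int(i) for i in np.argwhere(std == 0)[0])
            raise ValueError(f"zero surrogate variance in grid cell {cell}")
        return (pac - mean) / std
    raise ValueError(f"unknown normalization mode {mode!r}")


def pvalues_from_null(pac: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Per-cell permutation p-values, ``(#{null >= pac} + 1)/(n_perm + 1)``."""
    pac = np.asarray(pac, dtype=float)
    null = np.asarray(null, dtype=float)
    n_perm = null.shape[0]
    exceed = (null >= pac[None]).sum(axis=0)
    return (exceed + 1) / (n_perm + 1)


def maxstat_correction(pac: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Family-wise-error-controlled p-values via the maximum statistics.

    Each cell is compared against the distribution of per-permutation grid
    maxima; corrected p-values dominate the uncorrected ones cellwise.
    """
    pac = np.asarray(pac, dtype=float)
    null = np.asarray(null, dtype=float)
    n_perm = null.shape[0]
    maxima = null.reshape(n_perm, -1).max(axis=1)
    shape = (n_perm,) + (1,) * pac.ndim
    exceed = (maxima.reshape(shape) >= pac[None]).sum(axis=0)
    return (exceed + 1) / (n_perm + 1)
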