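# Methods

## Signal model and extraction

All analyses start from a single-channel epoched signal x(t), shape
(n_epochs × n_times), with sampling frequency sf. Instantaneous phase and
amplitude per frequency band are obtained in one of two ways:

- **FIR + Hilbert** (default). Each band (f₁, f₂) is isolated with a
  linear-phase band-pass FIR designed by least squares on the grid
  {0, 0.75·f₁, f₁, f₂, min(1.25·f₂, midpoint to Nyquist), sf/2} with desired
  response {0,0,1,1,0,0}. The filter order is frequency dependent,
  `round(cycles·sf/f₁)` forced even (3 cycles for phase bands, 6 for
  amplitude bands by default): slower bands need longer kernels to resolve
  their cycles. The filter is applied forward and backward (squaring the
  magnitude response and cancelling group delay exactly); phase and
  amplitude are the angle and modulus of the analytic (Hilbert) signal.
  The 25% transition-band fraction is a documented design choice; the exact
  transition geometry only weakly affects the estimators, which consume
  phases and envelope shapes, not absolute gains.
- **Morlet wavelets**: convolution with a complex Morlet kernel at the band
  centre, σ_t = width/(2πf), default width 7 cycles. The kernel is
  normalized so that a pure cosine at the centre frequency yields a
  unit-modulus output — outputs stay in signal units, so envelope
  amplitudes are directly interpretable (an alternative unit-energy
  normalization would rescale every band by an arbitrary factor).

Filtering is never trimmed implicitly; an `edge_discard` parameter lets
callers drop contaminated samples from each epoch end before estimation.

## Estimators

Six measures of the dependence between φ(k) and a(k) (N samples, epochs
concatenated along time by default; an `average` mode estimates per epoch
and averages the grids):

- **MVL** `(1/N)|Σ a e^{jφ}|` — sensitive, but scales with amplitude.
- **MI** — the amplitude is averaged within n=18 phase bins of 20°
  (half-open bins from −π), normalized into a distribution P; MI is the KL
  divergence of P from uniform divided by log n, so MI ∈ [0,1]. Empty bins
  contribute 0 (the 0·log 0 limit) and trigger a warning, since they signal
  data too short for the bin count.
- **HR** `(h_max − h_min)/h_max` of the same P.
- **ndPac** — the amplitude is z-scored over time (sample std); the
  statistic `|Σ z e^{jφ}|²` is compared with the closed-form threshold
  `x_th = 2N(erf⁻¹(1−p))²` (default p = 0.05), derived under a normal
  amplitude and uniform phase. Sub-threshold cells are set to 0;
  supra-threshold cells are reported on the MVL scale `|Σ z e^{jφ}|/N` so
  magnitudes are comparable across methods. Under the null the exceedance
  probability is exp(−2·erf⁻¹(1−p)²) ≈ 0.02 at p = 0.05 — conservative.
- **PLV** — the envelope is filtered in the *phase* band and its Hilbert
  angle φ_a extracted; PLV = `(1/N)|Σ e^{j(φ−φ_a)}|`.
- **gcPAC** — amplitude, sin φ and cos φ are copula-normalized (average
  ranks for ties, then Φ⁻¹(r/(N+1))); the mutual information
  I(a; [sin φ, cos φ]) is computed from the Gaussian entropies of the
  copula-normalized covariances with digamma small-sample bias correction,
  in bits. This is a lower bound on the true MI, exactly invariant to
  strictly monotone transforms of the amplitude; bias correction can push
  estimates slightly negative, which are clamped to 0 with the raw value
  kept in `diagnostics["raw"]`.

MI, HR, PLV and gcPAC are invariant to amplitude scaling; MVL is
homogeneous of degree 1 — the classic argument for preferring the former
when power changes between conditions.

### Tensor vs loop evaluation

Every estimator has a vectorized path (einsum/matmul over the band axes)
and a per-pair scalar loop. The two agree to better than 1e-10 relative on
all methods and grid sizes tested; the loop is the legible reference, the
tensor path the production one (an order of magnitude faster on realistic
grids, and the only practical option once hundreds of surrogate
re-estimations are needed).

## Surrogate correction and inference

Only the amplitude-side stream is transformed; the phase stream is never
modified. Defaults follow the most conservative choice: **block swap** —
the amplitude is split at a cut drawn uniformly on [1, N−1] and the two
blocks are swapped (a circular shift). Alternatives: random circular
**time lag**, and **trial swap** (a non-identity permutation of the epoch
axis). In concatenated mode the cut is drawn on the concatenated time axis.
For PLV the permuted stream is the derived amplitude-phase φ_a rather than
the raw envelope: a circular shift commutes with the (time-invariant)
band-filtering that produced φ_a except at the cut itself, and permuting
the derived stream keeps each permutation O(grid) instead of O(filtering).

All surrogate parameters are pre-drawn from one seeded generator, so null
stacks are reproducible and bitwise independent of how permutations are
dispatched (`n_jobs` uses joblib threads; serial and parallel results are
identical).

From a null stack of n_perm grids: `zscore` correction
(pac − mean)/std(null) or `mean_sub`; per-cell p-values
`(#{null ≥ pac} + 1)/(n_perm + 1)` (never exactly 0); family-wise control
via **maximum statistics** — each cell is ranked against the distribution
of per-permutation grid maxima. Monte-Carlo calibration (500 no-coupling
simulations): single-cell p-values are KS-uniform, and the maxstat
family-wise error over 10×10 grids at α = 0.05 is 0.052.

**Limitation — periodic drivers.** If the slow driver is strictly
sinusoidal and the epoch length is an exact multiple of its period, every
circular shift is a pure phase rotation, and the binned-distribution
measures (MI/HR) are rotation invariant: the surrogate "null" then equals
the true coupling and shift surrogates have no power. This is a property
of the measures, not a bug; real signals (and the stochastic-driver
generator) have aperiodic phase streams for which shifts genuinely destroy
the dependence. Trial swapping is unaffected.

## Event-related PAC

Time-averaged PAC cannot separate genuine coupling from within-window
non-stationarity. ERPAC therefore works across trials at each time sample:
the circular–linear correlation

ρ_cl = sqrt((r_sx² + r_cx² − 2 r_sx r_cx r_sc)/(1 − r_sc²)),

with r_sx = corr(sin φ, a), r_cx = corr(cos φ, a), r_sc = corr(sin φ, cos φ)
across the trial axis — equivalently the multiple correlation of a on
{sin φ, cos φ}, hence invariant to amplitude offset/scale and to phase
rotation. Degenerate phase sampling (1 − r_sc² < 1e-12) raises an error
rather than returning a clipped value. A Gaussian-copula variant computes
the across-trial MI at each time sample. Inference, when requested, uses
trial-swap permutations (the time axis must stay intact). A meaningful
across-trial estimate requires the phase to vary between trials at a fixed
time point — the stochastic-driver generator, not the deterministic
sinusoidal one.

## Diagnostics

- **Preferred phase**: argmax of the binned amplitude-by-phase matrix, in
  degrees ([0°, 360°), bin centres); near-ties (within 1e-9 relative)
  resolve to the lowest angle and raise a tie flag.
- **Binned amplitude uniformity**: per-bin means are computed per epoch;
  the grand bin means are studentised by their across-epoch standard
  errors, giving a χ²-style statistic with n_bins − 1 degrees of freedom
  under independence across epochs. A raw Pearson χ² on summed amplitudes
  would be grossly mis-calibrated because within-epoch samples are strongly
  autocorrelated.
- **PSD**: Welch, Hann window, 50% overlap, segment min(n_times, 4·sf),
  epoch-averaged; a helper returns the argmax in a query range. A visible
  spectral peak at the phase frequency is a prerequisite for trusting a
  PAC estimate.
- **ITC**: modulus of the trial-mean unit phase vector per time sample.
- **Triangular search**: PAC(F_min, F_max) over all pairs F_min < F_max on
  a step grid (default 2 Hz amplitude side, 0.5 Hz phase side), the fixed
  side filtered once. The argmax pair is the data-driven band suggestion.
- **Peak-locked TF**: epochs are circularly shifted so the band-filtered
  signal's local maximum nearest a cue aligns across epochs (epochs with no
  peak within half a driver period are dropped with a warning), then Morlet
  amplitude maps are averaged; genuine coupling appears as bursts repeating
  at the driver period.
- **Stationarity**: augmented Dickey–Fuller test per epoch (statsmodels);
  H0 is a unit root, i.e. non-stationarity.

## Synthetic generators

Both produce (n_epochs × n_times) signals with a planted coupling at
(f_pha, f_amp), strength c ∈ [0, 1], additive Gaussian noise, and a
controllable preferred phase pp:

- **Sinusoidal** ("tort-style"):
  `[c·(sin(2π f_pha t − pp) + 1)/2 + (1 − c)]·sin(2π f_amp t) + sin(2π f_pha t) + σ·ε`.
  At c = 0 the fast envelope is exactly flat; at c = 1 fully modulated,
  peaking where the driver's Hilbert phase equals pp.
- **Stochastic driver** ("wavelet-style"): the slow component is white
  noise Morlet-filtered at f_pha (unit RMS); its analytic angle defines a
  trial-varying, non-sinusoidal phase; the carrier envelope is
  `(1 + c·cos(φ − pp))/2`.

Defaults (20 epochs × 3000 samples at 512 Hz, c = 0.9, σ = 1) are the
benchmark condition used throughout the tests. The generators emulate a
narrow-band driver and a single coupled carrier in white noise; they do
not reproduce 1/f spectra, sharp non-sinusoidal waveforms, or multiple
simultaneous couplings — so passing tests demonstrate estimator
correctness and calibration, not robustness to every spurious-PAC
mechanism known from real recordings.

## Numerical choices and problem sizes

- Phase bins: 18 half-open bins from −π; phase == π folds into the last bin.
- z-scores and covariances use the unbiased (N−1) normalisation.
- Degenerate inputs (constant amplitude, singular copula covariance,
  zero surrogate variance) raise errors naming the offending quantity or
  grid cell rather than returning clipped values.
- Monte-Carlo calibrations in the test-suite use reduced problem sizes
  (128 Hz sampling, short epochs, 100 permutations, 500 repetitions),
  chosen so the full suite completes in about a minute while keeping the
  binomial error of the estimated rates well inside the asserted bands.
- The benchmark quantities recomputed by `scripts/acceptance.py` use
  20–300 epochs of 1–6 s at 256–512 Hz, matching the package's standard
  demonstration protocols.
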