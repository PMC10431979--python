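# Methods

## Pipeline

One run executes, in order: DICOM series ingest → in-plane Gaussian
pre-filter → baseline estimation → SR/PSR maps → signal-to-concentration
conversion → AIF extraction over the vessel mask → optional gamma-variate
refit → discrete deconvolution per brain voxel → CBF/CBV/MTT maps → TIFF
export plus a machine-readable report. All times are seconds internally;
DICOM TE/TR (ms) are converted on ingest. Identical configuration and seed
reproduce every output bit for bit.

## Signal model and conversion

The tracer concentration is `C_m(t) = -(k/TE)·ln(S(t)/S0)` with `S0` the
per-voxel temporal mean over the baseline window (default frames
`[0, bolus_frame - 5)`, `bolus_frame` = 20 at TR 1 s; the margin guards
against early arrival). The proportionality constant `k` defaults to 1: it
multiplies tissue and AIF curves alike and cancels in the CBF/CBV ratios,
so it is a unit choice with no effect on the absolute maps (verified by a
rescaling-invariance test). Voxel-frames with non-positive signal or
baseline are flagged NaN rather than aborting the run; negative
concentrations (signal overshoot) are kept unless `clamp_nonpositive` is
set.

The pre-filter is a separable, discretely normalized Gaussian (support
5 px, σ 0.5 px by default), applied frame-by-frame in-plane only, with
reflect padding to avoid edge darkening on small acquisition matrices. It
is applied in signal space, before conversion.

## AIF handling

The reference curve is the framewise arithmetic mean of concentration over
the vessel mask (non-finite voxel-frames excluded). The interactive
selection of bolus arrival and first-pass end is replaced by config
scalars plus an automatic initializer: arrival = first frame where the
curve exceeds 10% of its peak and stays above for 3 frames; first-pass
end = first local minimum after the peak (grid end if the decay is
monotone). The gamma-variate `C0·(t-t0)^r·e^-(t-t0)/b` (zero for t ≤ t0)
is fitted by ordinary least squares on that window with `t0` bounded
within ±2·TR of the stated arrival and r, b kept positive; up to three
restarts with jittered (r, b) guard against the fit's known
init-sensitivity. The fitted curve replaces the raw AIF for deconvolution
when `aif_fit_enabled` (default on); the residual sum of squares is
reported so a poor fit is visible rather than silently accepted.

A caveat established by the Monte-Carlo tests: the amplitude `C0` is
nearly degenerate with (r, b) — at 2%-of-peak noise its per-parameter
scatter is an order of magnitude larger than that of t0, r, b (the
Cramér–Rao bound for `C0` alone exceeds 30% relative sd under unweighted
least squares), while the fitted curve's peak value and position stay
within a fraction of a percent. Parameter-level comparisons should
therefore pool parameters or compare curves, not `C0` alone.

## Deconvolution

`C_m = k * C_AIF` is discretized with the rectangle rule into a
lower-triangular Toeplitz system `A[i,j] = Δt·C_AIF(t_{i-j})`, solved
through one SVD shared by all voxels. TSVD zeroes reciprocal singular
values below `f·σ_max` (default f = 0.2); Tikhonov applies filter factors
`σ/(σ² + λ²)` with `λ = f·σ_max` (default 0.2). 20% of σ_max is the
conventional operating point for bolus-tracking data; both fractions are
config keys. Delay-insensitive block-circulant variants and leakage
correction are out of scope; taking CBF from the maximum of k(t) over the
whole grid absorbs small bolus delays. Negative excursions of the
regularized solution are retained in k(t); flooring happens at map level.

## Maps and calibration

`k_H = 100·(K_T/K_A)·(1-H_A)/(1-H_T)/ρ_Voi` groups the tissue-to-artery
concentration scale factor ratio (0.136), large-vessel and capillary
hematocrits (0.45, 0.25) and brain density (1.04 g/ml); 9.5897 at
defaults, always derived from its components. CBF carries an explicit ×60
converting the per-second grid to the conventional per-minute unit.

The residue integral in CBV uses the rectangle sum `Δt·Σk` — the
quadrature conjugate to the rectangle-rule operator the deconvolution
inverts, so the discrete identity `∫k = ∫C_m/∫C_AIF` carries over to the
solution and the two CBV routes agree to ~0.03% on the noiseless phantom.
A trapezoid here would halve the first sample, where the regularized
residue peaks, and biased CBV low by ~5% in development measurements. The
curve-integral route (ratio of `∫C_m` to `∫C_AIF`) uses the trapezoid on
the acquired 180-frame window; no tail extrapolation is applied.

Negative CBF/CBV are floored at zero (physical nonnegativity); MTT and PSR
division guards flag NaN instead of clamping (honest undefinedness).
`S_post` is the mean over a 5-frame window centred at arrival + 60 s,
clipped to the grid; `S_min` is the user-supplied minimum-intensity frame
applied globally, or an optional per-voxel minimum search after arrival.
Non-finite map values serialize as 0 in the TIFFs (zero background);
finite values round-trip exactly as 32-bit float.

## Digital phantom

The phantom emulates the preclinical protocol: TR 1 s, 180 repetitions,
TE 6.2 ms, bolus 20 s after acquisition start, on a 40×40 single-slice
grid by default with one circular compartment at CBF 60 ml/100g/min and
CBV 4 ml/100g (MTT 4 s by the central volume identity, satisfied by the
truth maps to machine precision). Per region the residue is
mono-exponential `F·e^(-t/MTT)` with `F = CBF/(60·k_H)`; the tissue curve
is the discrete convolution with the gamma-variate AIF evaluated on a grid
20× finer than TR and sampled at TR — emulating continuous tracer kinetics
rather than generating data with the same coarse operator the
deconvolution inverts. The signal is `S0·e^(-TE·C)` (the exact inverse of
the conversion step) at baseline level 1000, with optional additive
Gaussian noise under a fixed seed. AIF-mask voxels carry the AIF itself
through the same signal model, so AIF extraction and the gamma refit are
exercised rather than bypassed.

The default AIF shape is r = 3, b = 1.5 s with amplitude C0 = 30 (in
concentration units per s^r), chosen so the first-pass signal drop is
roughly 60% in the vessel and 25% in tissue at TE 6.2 ms — typical depths
for a high-dose gadolinium bolus. Masks are eroded 2 px inside the painted
regions (`mask_margin_px`): the 5×5 pre-filter mixes boundary voxels with
background, and ROIs are drawn away from vessel/tissue edges in practice.
The fixture writer stores the series as 32-bit float DICOM so the write →
read round trip is bit-identical.

What the phantom does not emulate: Rician noise statistics (additive
Gaussian is adequate at the SNRs exercised and keeps the inverse model
exact), partial volume, motion, contrast leakage, bolus dispersion/delay
between vessel and tissue, and recirculation. Passing the closed-loop
tests therefore demonstrates the correctness of the numerics and
bookkeeping, not robustness to those in-vivo effects.

## Known limitations

- Standard (non-circulant) truncated-SVD deconvolution at the
  conventional 20% threshold substantially underestimates CBF and hence
  overestimates MTT when the residue decays within a few TR: on the
  MTT 4 s phantom the acceptance sweep measures ~37% median CBF error and
  ~60% median MTT error at SNR 50, against ~2% for CBV, whose integral is
  insensitive to peak broadening. Quantitative CBF work at short MTT
  should lower the threshold (the noiseless pipeline at 1e-6 recovers all
  three within 0.7%) or accept the operating-point bias, which is shared
  by the standard-SVD literature.
- Tikhonov at the same fractional parameter smooths more aggressively
  than TSVD on these kernels.
- The AIF is treated as global; no automatic vessel search, no
  partial-volume correction of the AIF.
- Integrals are truncated to the acquired window; no gamma-tail
  extrapolation (off by default, and the default phantom's first pass is
  fully contained in the window).
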