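# Methods

## The decomposition model

A tunable-pinhole series I_j(x, y), j = 1…N with strictly decreasing
aperture a_1 > … > a_N (Airy Units), encodes axial position in the
*shape* of each pixel's intensity-vs-j series: in-focus signal is nearly
flat, out-of-focus signal decays steeply. The first-harmonic phasor
(g, s) of the series normalizes that shape, and its magnitude
M = √(g² + s²) ∈ [0, 1] is the working observable. The model assumes

1. each pixel's intensity is a sum of exactly two components whose
   series shapes — hence endmember modulations M_IN < M_OUT — are the
   same everywhere in the field;
2. frames are co-registered and photobleaching between frames is
   negligible (no drift or bleach correction is applied);
3. the mixture is intensity-weighted and linear:
   M = f_IN·M_IN + (1 − f_IN)·M_OUT.

Under assumption 3 the linear inversion
f_IN,LIN = 1 − (M − M_IN)/(M_OUT − M_IN) is exact. For N = 2 it is
*identically* exact: with F1 ≥ F2, M = (F1 − F2)/(F1 + F2) and the
intensity-weighted mixture of two fixed series shapes reproduces the
linear law without approximation. Noise and endpoint misestimation push
f_IN,LIN outside [0, 1]; the logistic filter
f_IN = 1/(1 + e^(−k_L(f_IN,LIN − ½))) soft-clamps it while preserving
monotonicity and the midpoint. The pipeline keeps M nonnegative for all
N (phasor magnitude); the signed two-frame ratio (negative where
F2 > F1 under noise) exists only in `modulation_n2` and in no code path
of the decomposition.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `k_l` | 4 | — | logistic steepness; larger → closer to a hard clamp of f_IN,LIN, smaller → stronger shrinkage toward ½. 4 keeps the filter gentle enough that f(1) ≈ 0.88, bounding how close f_IN can get to 1. |
| `j0` | 1 | frame index | first frame of I_SUM. 1 uses all collected photons (best SNR); N keeps only the smallest pinhole (best sectioning). Changes the output intensity scale. |
| `percentiles` | (10, 90) | % | histogram percentiles taken as (M_IN, M_OUT). Inner estimates by construction: they reach the true endmember values only if nearly-pure pixels of both kinds each make up more than the respective tail of the thresholded population. |
| `intensity_threshold` | 5% of max Σ_j I_j | intensity | excludes dim pixels (noise-dominated modulation) from the histogram. Thresholding uses the full stack sum — all collected photons, the most stable per-pixel statistic. User-overridable, recorded in the sidecar. |
| `m_in`, `m_out` | estimated | — | manual override for samples where the histogram rule fails (e.g. no pure-background region). |

Degenerate histograms (P_hi − P_lo < 1e−9) raise an error directing the
user to set endpoints manually; the tolerance is nonzero because a
background-free scene yields per-pixel modulations identical only to
float rounding. Pixels with zero total intensity get g = s = M = 0, are
masked, and never enter histograms or fits. All arithmetic is double
precision regardless of input bit depth.

## QuICS quality metrics

The 2D autocorrelation G_2D(δx, δy) = ⟨I(x,y)I(x+δx,y+δy)⟩/⟨I⟩² − 1 is
computed by FFT with zero-padding to twice the linear size and per-lag
division by the number of contributing pixel pairs — the unbiased,
non-circular estimator (circular wrap biases long lags on structured
images). With an ROI mask, means and pair counts run over selected
pixels only. The radial profile G(δ_r) averages G_2D over annuli
round(√(δx²+δy²)) = δ_r of width 1 px, for δ_r = 0 … min(H, W)/2.

The noise-free Gaussian G_NF(δ) = G_NF(0)e^(−δ²/w²) + G_NF(∞) is fitted
by least squares on δ ∈ [1, δ_max] (zero lag excluded: uncorrelated
noise contributes variance only there). Initialization is scale-free
and deterministic: amplitude from G(1) minus the tail mean, width from
the first lag below half of G(1), offset from the mean of the last 10%
of lags. The automatic δ_max starts at the first lag where G falls
below 20% of G(1) (at least 4 lags), grows to the largest available
lag, and keeps the largest range whose per-lag RMS residual is within
2× the best range's — a deterministic, monotone stand-in for "fit a
single Gaussian component", always overridable via `delta_max`. A
non-positive fitted amplitude is flagged; B and N are then unreliable.

Metrics: R = √(2 ln 2)·w (w is the 1/e² parameter, so R equals the FWHM
of the underlying structure for point-like objects), B = G_NF(0)·I_av,
N = (G(0) − G_NF(0))/G_NF(0) with G(0) the *raw* angularly averaged
zero-lag value, not an extrapolation.

## Synthetic scenes: what they emulate and what they do not

`generate_stack` images two planar layers through a pinhole-dependent
collection model: frame_j = η_in(a_j)·blur(L_in, σ_in) +
η_out(a_j)·blur(L_out, σ_out(a_j)) + noise, with
η_in(a) = a²/(a² + a_half²) (saturating — the Airy core is collected
quickly) and η_out(a) = c_out·a² (grows with aperture area — the
defocused halo keeps leaking in). The in-focus blur is
pinhole-independent by default (`sigma_in_slope = 0`): above ~0.2 AU the
in-focus lateral PSF of a confocal barely changes with the pinhole,
collection efficiency being the dominant effect. This also makes a
background-free scene exactly contrast-free, so the degenerate-histogram
error path is exercised for c_out = 0. The out-of-focus blur widens
mildly with aperture (σ_out = 6 + 1.5·a px).

The reference scene (the defaults of `SceneSpec`) emulates a
calibration acquisition like a field of 200-nm fluorescent spheres:
50 beads of FWHM 4 px at sub-pixel positions, a smooth defocused
background confined to ~60% of the field (`background_sparsity = 0.4` —
real defocused structure varies laterally and vanishes in parts of the
field; this is also precisely the condition under which the percentile
endpoint rule can observe both endmembers), two frames at (2.0, 1.0) AU
as in a typical two-point acquisition, and Poisson noise at a peak of
6000 counts in the widest frame — a photon-rich, fixed-sample
acquisition. Endmember modulations under this model are M_IN ≈ 0.14 and
M_OUT = 0.6. Ground truth is exact: the noiseless per-frame components
are stored, so the true in-focus fraction of any partial sum is
available per pixel.

What the generator does *not* emulate: 3D PSFs and diffraction (layers
are 2D and blur is Gaussian), detector offset/gain structure, sample
drift between frames, photobleaching, depth-dependent attenuation, and
more than two axial components. Passing recovery tests therefore show
that the estimator inverts the stated two-component collection model
under Poisson noise — not that real tissue obeys that model; on real
data the endpoint histogram should always be inspected (the CLI's
`--histogram` export exists for exactly that).

## Numerical and design choices

- Percentile definition: linear interpolation between order statistics
  (numpy default), fixed so the documented examples are deterministic.
- f_IN,LIN is never clamped before the logistic; the logistic is the
  only range control. Runs where more than 5% of valid pixels fall
  outside [0, 1] log a warning (poor endpoints) but do not fail.
- The N = 2 closed-form path (`split_pin_n2_closed_form`) is kept
  purely as a verification oracle and mirrors the pipeline's
  nonnegative-modulation convention so the two agree elementwise on any
  input, including noisy pixels where F2 > F1.
- TIFF pages are trusted in file order (largest pinhole first);
  `--reverse` exists because pinhole size is not recorded in standard
  TIFF tags and the loader refuses to guess.
- Bead phantoms enforce a 3-FWHM minimum separation by default so the
  spot ACF is single-component; placement failure after a bounded retry
  budget is an error, not silent under-filling.
- Problem sizes in the test and acceptance runs (128² scenes, 256²
  phantoms, ≤256² random stacks) are chosen as the smallest fields that
  keep ACF sampling error well below the tested tolerances.

## Known limitations

- Exactly two components: a pixel mixing three distinct axial layers
  is forced onto the in/out axis.
- Percentile endpoints are biased inward whenever pure pixels of either
  class are rare; the result is a compressed f_IN range (the logistic
  ceiling f(1) ≈ 0.88 at k_L = 4 already bounds it). Manual endpoints
  recover accuracy when the user can identify pure regions.
- The automatic δ_max rule assumes the ACF's first decay is the
  structure of interest; strongly periodic samples (regular arrays)
  can mislead it — set `delta_max` explicitly there.
- N declared by QuICS can be slightly negative on noiseless synthetic
  images (fit offset absorbing density correlations); magnitudes below
  ~0.05 should be read as "no detectable noise".
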