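# splitpin

Virtual pinhole closing for point-scanning fluorescence microscopy.

Confocal and STED images always contain some fluorescence from above and
below the focal plane. Closing the physical pinhole rejects it, but at a
steep cost in detected signal — below ~1 Airy Unit (AU) most photons are
thrown away. `splitpin` instead separates the in-focus from the
out-of-focus contribution computationally, from a short series of N ≥ 2
images of the same field acquired at *decreasing* pinhole size: the
result has the optical sectioning of a small pinhole and the photon
budget of a large one. The package targets microscopists with any
tunable-pinhole instrument (most commercial confocal/STED systems) and
ships both a Python library and a batch CLI.

## Method

At each pixel the intensity series I_j (j = 1…N, largest pinhole first)
is projected onto the first Fourier harmonic (phasor analysis):

    g = Σ_j I_j cos(2π(j−1)/N) / Σ_j I_j
    s = Σ_j I_j sin(2π(j−1)/N) / Σ_j I_j
    M = √(g² + s²)

In-focus emitters lose little intensity as the pinhole closes (flat
series, low modulation M); out-of-focus emitters lose a lot (steep
series, high M). Modeling M as a two-component mixture
M = f_IN·M_IN + (1 − f_IN)·M_OUT and inverting gives a raw in-focus
fraction

    f_IN,LIN = 1 − (M − M_IN)/(M_OUT − M_IN)

which is soft-clamped into (0, 1) with a logistic filter
f_IN = 1/(1 + e^(−k_L (f_IN,LIN − ½))), k_L = 4. The output images are

    I_SPLIT-PIN = f_IN · I_SUM        I_out-of-focus = (1 − f_IN) · I_SUM

where I_SUM = Σ_{j=j0}^N I_j sums either the whole stack (j0 = 1, best
SNR) or only the smallest-pinhole frame (j0 = N, best sectioning). The
endpoints M_IN / M_OUT are estimated from the data as the 10%/90%
percentiles of the modulation histogram over bright pixels, and can be
overridden.

Image quality is scored by image correlation spectroscopy (QuICS): the
radially averaged autocorrelation G(δ) of an image is fitted with a
noise-free Gaussian G_NF(δ) = G_NF(0)·e^(−δ²/w²) + G_NF(∞) on δ ≥ 1
(uncorrelated noise lives only at zero lag), giving

- resolution R = √(2 ln 2)·w (R ≥ FWHM, equality for point-like objects),
- brightness B = G_NF(0)·I_av (contrast),
- relative noise N = (G(0) − G_NF(0))/G_NF(0).

A synthetic-scene generator (`splitpin.synth`) produces tunable-pinhole
stacks with exact per-pixel ground truth, so the whole pipeline is
testable without a microscope.

## Worked example

```bash
# make a synthetic two-frame (2 AU, 1 AU) acquisition of beads over a
# defocused background, then decompose it
splitpin simulate --seed 4 --out sim
splitpin split sim/stack.tif --pinhole-sizes 2,1 --quics --out run1
```

prints (abridged):

```
endpoints used: m_in=0.1604 m_out=0.6127
sum image: frames 1..2; threshold=490.7; k_l=4
QuICS: {"R_px": 4.38, "B": 3324.2, "N": -0.10, ...}
wrote split_pin: run1/split_pin.tif
wrote out_of_focus: run1/out_of_focus.tif
wrote modulation: run1/modulation.tif
wrote f_in: run1/f_in.tif
wrote sidecar: run1/splitpin_run.json
```

The estimated endpoints bracket the modulations of purely in-focus
(≈0.14 for this scene's collection model) and purely out-of-focus
(≈0.6) signal; `split_pin.tif` is the background-suppressed image and
the sidecar records every parameter actually used. The QuICS resolution
R ≈ 4.4 px is near the 4-px bead size, and B ≈ 3300 is roughly 3× the
brightness of the smallest-pinhole frame alone (run `splitpin quics` on
any frame to compare). `splitpin selftest --seed 1` runs the same
pipeline plus its internal consistency checks and prints a pass/fail
table.

The same decomposition is available in Python:

```python
from splitpin import load_stack, split_pin, quics_metrics

stack, meta = load_stack("stack.tif", pinhole_sizes=(2.0, 1.0))
result = split_pin(stack)           # auto-estimated endpoints
report = quics_metrics(result.split_pin)
print(result.params_used, report.r_px, report.b, report.n)
```

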