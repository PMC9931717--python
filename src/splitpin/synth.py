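"""Synthetic tunable-pinhole stacks with known ground truth.

The generator emulates the one physical fact the decomposition relies
on: as the confocal pinhole closes, in-focus signal survives while
out-of-focus signal is rejected. Two planar layers are imaged through a
pinhole-dependent collection model:

    frame_j = eta_in(a_j) * blur(L_in, sigma_in(a_j))
            + eta_out(a_j) * blur(L_out, sigma_out(a_j))  (+ noise)

with, for aperture diameter a in Airy Units,

    eta_in(a)  = a^2 / (a^2 + a_half^2)   (saturating: the Airy core is
                                           captured quickly)
    eta_out(a) = c_out * a^2              (grows with pinhole area: the
                                           defocused halo keeps leaking in)

By default the in-focus blur width does not vary with the pinhole — in a
confocal the in-focus lateral PSF is nearly pinhole-independent above
~0.2 AU, collection efficiency being the dominant effect — while the
out-of-focus blur mildly widens with aperture. A ``sigma_in_slope`` knob
reintroduces pinhole-dependent in-focus blur for robustness probes.

The noiseless per-frame components are kept, so every scene carries the
exact per-pixel in-focus intensity fraction against which a recovered
fraction map can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import InvalidInputError, PlacementError
from .stack import PinholeStack

__all__ = [
    "SceneSpec",
    "SyntheticScene",
    "bead_phantom",
    "blob_background",
    "generate_stack",
    "eta_in",
    "eta_out",
    "out_of_focus_energy_fraction",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def eta_in(a: float | np.ndarray, a_half: float = 0.7) -> float | np.ndarray:
    """In-focus collection efficiency: saturates with pinhole area."""
    a = np.asarray(a, dtype=np.float64)
    out = a**2 / (a**2 + a_half**2)
    return float(out) if out.ndim == 0 else out


def eta_out(a: float | np.ndarray, c_out: float = 0.3) -> float | np.ndarray:
    """Out-of-focus collection efficiency: proportional to pinhole area."""
    a = np.asarray(a, dtype=np.float64)
    out = c_out * a**2
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SceneSpec:
    """Conditions of one synthetic acquisition.

    Defaults describe the reference scene used throughout the test
    suite: a two-frame (2.0, 1.0) AU acquisition of bright sub-diffraction
    beads over a laterally confined defocused background (zero over
    ~40% of the field), with Poisson noise at a peak of ~6000 counts in
    the widest-pinhole frame — a photon-rich calibration acquisition of
    fixed fluorescent spheres.
    """

    image_size: int = 128
    pinhole_sizes: tuple[float, ...] = (2.0, 1.0)
    n_beads: int = 50
    bead_fwhm_px: float = 4.0
    in_focus_amplitude: float = 1.0
    out_amplitude: float = 0.25
    background_correlation_px: float = 12.0
    a_half: float = 0.7
    c_out: float = 0.3
    sigma_in_px: float = 0.8
    sigma_in_slope: float = 0.0
    sigma_out_base_px: float = 6.0
    sigma_out_slope: float = 1.5
    background_sparsity: float = 0.4
    poisson: bool = True
    peak_counts: float = 6000.0
    gaussian_sd: float = 0.0

    def sigma_in(self, a: float) -> float:
        return self.sigma_in_px + self.sigma_in_slope * a

    def sigma_out(self, a: float) -> float:
        return self.sigma_out_base_px + self.sigma_out_slope * a


@dataclass(frozen=True)
class SyntheticScene:
    """A generated scene and its ground truth.

    ``in_focus_frames`` / ``out_focus_frames`` are the noiseless
    per-frame components (same intensity scale as the stack), so the
    true in-focus fraction of any partial sum can be formed exactly.
    """

    spec: SceneSpec
    seed: int
    in_focus_layer: np.ndarray
    out_of_focus_layer: np.ndarray
    in_focus_frames: np.ndarray
    out_focus_frames: np.ndarray
    true_f_in: np.ndarray = field(repr=False)
    in_focus_support: np.ndarray = field(repr=False)

    def true_f_in_for(self, j0: int = 1) -> np.ndarray:
        """Ground-truth in-focus fraction of the sum image starting at j0."""
        a = self.in_focus_frames[j0 - 1 :].sum(axis=0)
        b = self.out_focus_frames[j0 - 1 :].sum(axis=0)
        total = a + b
        out = np.zeros_like(total)
        np.divide(a, total, out=out, where=total > 0)
        return out


def bead_phantom(
    n_beads: int,
    bead_fwhm_px: float,
    image_size: int,
    seed: int | np.random.Generator = 0,
    min_separation_px: float | None = None,
    max_retries: int = 5000,
) -> np.ndarray:
    """Field of unit-amplitude Gaussian spots at random non-overlapping positions.

    Stands in for an image of sub-diffraction fluorescent spheres. Spots
    are placed at continuous (sub-pixel) coordinates with a minimum
    center-to-center separation (default 3 FWHM, i.e. well separated)
    and a one-FWHM margin from the border.

    Raises
    ------
    PlacementError
        If the requested count cannot be placed within the retry budget.
    """
    if bead_fwhm_px <= 0:
        raise InvalidInputError("bead FWHM must be positive")
    if n_beads < 0:
        raise InvalidInputError("n_beads must be >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    image = np.zeros((image_size, image_size), dtype=np.float64)
    if n_beads == 0:
        return image

    margin = bead_fwhm_px
    if image_size - 2 * margin <= 0:
        raise PlacementError(
            f"beads of FWHM {bead_fwhm_px} px do not fit in a "
            f"{image_size}x{image_size} image"
        )
    if min_separation_px is None:
        min_separation_px = 3.0 * bead_fwhm_px

    positions: list[tuple[float, float]] = []
    tries = 0
    while len(positions) < n_beads:
        if tries >= max_retries:
            raise PlacementError(
                f"placed only {len(positions)}/{n_beads} beads after "
                f"{max_retries} tries (min separation {min_separation_px:g} px)"
            )
        tries += 1
        y, x = rng.uniform(margin, image_size - margin, size=2)
        if all(
            (y - py) ** 2 + (x - px) ** 2 >= min_separation_px**2
            for py, px in positions
        ):
            positions.append((y, x))

    sigma = bead_fwhm_px * FWHM_TO_SIGMA
    yy = np.arange(image_size)[:, None]
    xx = np.arange(image_size)[None, :]
    for y, x in positions:
        image += np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2.0 * sigma**2))
    return image


def blob_background(
    image_size: int,
    correlation_px: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Smooth nonnegative random field, max-normalized to [0, 1].

    A heavily low-pass-filtered white-noise field mimicking the diffuse
    structure (membranes, dense labeling above/below focus) that feeds
    the out-of-focus halo.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    field_ = gaussian_filter(
        rng.uniform(size=(image_size, image_size)), correlation_px
    )
    field_ -= field_.min()
    peak = field_.max()
    if peak > 0:
        field_ /= peak
    return field_


def generate_stack(
    scene_spec: SceneSpec | None = None, seed: int = 0
) -> tuple[PinholeStack, SyntheticScene]:
    """Simulate one tunable-pinhole acquisition.

    Deterministic given (scene_spec, seed). The returned stack satisfies
    every PinholeStack invariant; the returned scene carries the exact
    noiseless components and per-pixel in-focus fraction.
    """
    spec = scene_spec or SceneSpec()
    sizes = spec.pinhole_sizes
    if len(sizes) < 2:
        raise InvalidInputError("need at least 2 pinhole sizes")
    if any(s2 >= s1 for s1, s2 in zip(sizes, sizes[1:])):
        raise InvalidInputError(
            f"pinhole sizes must be strictly decreasing, got {sizes}"
        )

    rng = np.random.default_rng(seed)
    l_in = spec.in_focus_amplitude * bead_phantom(
        spec.n_beads, spec.bead_fwhm_px, spec.image_size, rng
    )
    l_out = blob_background(
        spec.image_size, spec.background_correlation_px, rng
    )
    if spec.background_sparsity > 0:
        # confine the defocused structure laterally: real out-of-focus
        # signal varies across the field and vanishes in parts of it,
        # which is what makes nearly-pure in-focus pixels observable
        floor = np.quantile(l_out, spec.background_sparsity)
        l_out = np.maximum(l_out - floor, 0.0)
        peak = l_out.max()
        if peak > 0:
            l_out /= peak
    l_out = spec.out_amplitude * l_out
    if l_in.min() < 0 or l_out.min() < 0:
        raise InvalidInputError("layers must be nonnegative")

    a_frames = np.stack(
        [
            eta_in(a, spec.a_half) * gaussian_filter(l_in, spec.sigma_in(a))
            for a in sizes
        ]
    )
    b_frames = np.stack(
        [
            eta_out(a, spec.c_out) * gaussian_filter(l_out, spec.sigma_out(a))
            for a in sizes
        ]
    )
    noiseless = a_frames + b_frames

    if spec.poisson:
        peak = noiseless[0].max()
        scale = spec.peak_counts / peak if peak > 0 else 1.0
        a_frames = a_frames * scale
        b_frames = b_frames * scale
        frames = rng.poisson(noiseless * scale).astype(np.float64)
    else:
        frames = noiseless.copy()
    if spec.gaussian_sd > 0:
        frames = frames + rng.normal(0.0, spec.gaussian_sd, size=frames.shape)
        frames = np.maximum(frames, 0.0)

    total_a = a_frames.sum(axis=0)
    total = total_a + b_frames.sum(axis=0)
    true_f_in = np.zeros_like(total)
    np.divide(total_a, total, out=true_f_in, where=total > 0)
    support = total_a > 0.05 * total_a.max() if total_a.max() > 0 else total_a > 0

    stack = PinholeStack(frames=frames, pinhole_sizes=sizes)
    scene = SyntheticScene(
        spec=spec,
        seed=seed,
        in_focus_layer=l_in,
        out_of_focus_layer=l_out,
        in_focus_frames=a_frames,
        out_focus_frames=b_frames,
        true_f_in=true_f_in,
        in_focus_support=support,
    )
    return stack, scene


def out_of_focus_energy_fraction(
    image: np.ndarray, true_f_in: np.ndarray
) -> float:
    """Fraction of an image's energy attributable to out-of-focus signal.

    Weights each pixel's intensity by the ground-truth out-of-focus
    fraction (1 - f_in) of the signal it derives from; used to score how
    much background a processed image retains.
    """
    image = np.asarray(image, dtype=np.float64)
    total = image.sum()
    if total <= 0:
        raise InvalidInputError("image has no energy")
    return float((image * (1.0 - true_f_in)).sum() / total)
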