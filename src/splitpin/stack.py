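"""The tunable-pinhole image stack container.

A stack is a series of N >= 2 co-registered grayscale frames of the same
field of view, acquired sequentially while closing the confocal pinhole:
frame 1 has the largest aperture (most signal, least optical sectioning)
and frame N the smallest (best sectioning, least signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = ["PinholeStack"]


@dataclass(frozen=True)
class PinholeStack:
    """An ordered series of frames acquired at decreasing pinhole size.

    Parameters
    ----------
    frames : ndarray, shape (N, H, W)
        Nonnegative intensities, frame index j = 0..N-1 in acquisition
        order (largest pinhole first). Stored as float64 regardless of
        the input depth.
    pinhole_sizes : tuple of float
        Aperture diameter of each frame in Airy Units, strictly
        decreasing. When the real sizes are unknown, descending ranks
        (N, N-1, ..., 1) act as symbolic placeholders.
    pixel_size : float or None
        Physical length of one pixel (same unit along x and y); used only
        to report resolution in physical units.
    """

    frames: np.ndarray
    pinhole_sizes: tuple[float, ...] = ()
    pixel_size: float | None = None
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        if frames.ndim != 3:
            raise InvalidInputError(
                f"stack must be a 3D (frame, y, x) array, got ndim={frames.ndim}"
            )
        if frames.shape[0] < 2:
            raise InvalidInputError(
                f"a stack needs at least 2 frames, got {frames.shape[0]}"
            )
        if not np.all(np.isfinite(frames)):
            raise InvalidInputError("stack contains non-finite intensities")
        if frames.min() < 0:
            raise InvalidInputError("stack contains negative intensities")

        sizes = tuple(float(a) for a in self.pinhole_sizes)
        if not sizes:
            sizes = tuple(float(k) for k in range(frames.shape[0], 0, -1))
        if len(sizes) != frames.shape[0]:
            raise InvalidInputError(
                f"{len(sizes)} pinhole sizes for {frames.shape[0]} frames"
            )
        if any(a <= 0 for a in sizes):
            raise InvalidInputError("pinhole sizes must be positive")
        if any(s2 >= s1 for s1, s2 in zip(sizes, sizes[1:])):
            raise InvalidInputError(
                f"pinhole sizes must be strictly decreasing, got {sizes}"
            )
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise InvalidInputError("pixel_size must be positive")

        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "pinhole_sizes", sizes)
        object.__setattr__(self, "_validated", True)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of each frame."""
        return self.frames.shape[1:]
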