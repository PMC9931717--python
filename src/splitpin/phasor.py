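"""Phasor analysis of a tunable-pinhole image stack.

Each pixel carries a short intensity series I_j, j = 1..N, recorded while
the pinhole closes. Projecting that series onto the first Fourier harmonic
gives the phasor coordinates

    g = sum_j I_j cos(2*pi*(j-1)/N) / sum_j I_j
    s = sum_j I_j sin(2*pi*(j-1)/N) / sum_j I_j

and the modulation M = sqrt(g^2 + s^2). In-focus emitters lose little
signal as the pinhole closes, so their series is flat and M is low;
out-of-focus emitters lose signal fast, so M is high. M is the single
per-pixel observable the decomposition works on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .stack import PinholeStack

__all__ = ["PhasorMaps", "compute_phasor", "modulation_n2"]


@dataclass(frozen=True)
class PhasorMaps:
    """Per-pixel phasor coordinates and modulation.

    ``valid_mask`` marks pixels whose total intensity over the stack is
    positive; everywhere else g, s and modulation are defined as 0 and
    must be excluded from histograms and fits downstream.
    """

    g: np.ndarray
    s: np.ndarray
    modulation: np.ndarray
    valid_mask: np.ndarray


def compute_phasor(stack: PinholeStack) -> PhasorMaps:
    """First-harmonic phasor of the per-pixel intensity-vs-pinhole series.

    Parameters
    ----------
    stack : PinholeStack
        Validated stack of N >= 2 frames, largest pinhole first.

    Returns
    -------
    PhasorMaps
        g, s, modulation (all float64, frame-shaped) and the positivity
        mask. On valid pixels 0 <= modulation <= 1; elsewhere all maps
        are 0.
    """
    if not isinstance(stack, PinholeStack):
        stack = PinholeStack(np.asarray(stack))
    frames = stack.frames
    n = stack.n_frames

    phase = 2.0 * np.pi * np.arange(n, dtype=np.float64) / n
    cos_w = np.cos(phase)[:, None, None]
    sin_w = np.sin(phase)[:, None, None]

    total = frames.sum(axis=0)
    valid = total > 0

    g = np.zeros(total.shape, dtype=np.float64)
    s = np.zeros(total.shape, dtype=np.float64)
    np.divide((frames * cos_w).sum(axis=0), total, out=g, where=valid)
    np.divide((frames * sin_w).sum(axis=0), total, out=s, where=valid)
    modulation = np.hypot(g, s)
    # |phasor| of a nonnegative distribution is <= 1; clip float spillover
    np.clip(modulation, 0.0, 1.0, out=modulation)

    return PhasorMaps(g=g, s=s, modulation=modulation, valid_mask=valid)


def modulation_n2(frame1: np.ndarray, frame2: np.ndarray) -> np.ndarray:
    """Signed two-frame modulation (F1 - F2) / (F1 + F2).

    For a two-frame stack the sine component vanishes and the modulation
    reduces to the normalized difference of the frames. This closed form
    is kept as an independent oracle for :func:`compute_phasor`; note it
    is *signed* (negative where F2 > F1, possible under noise), whereas
    the pipeline modulation is the phasor magnitude |g|.
    """
    f1 = np.asarray(frame1, dtype=np.float64)
    f2 = np.asarray(frame2, dtype=np.float64)
    if f1.shape != f2.shape:
        raise InvalidInputError(
            f"frame shapes differ: {f1.shape} vs {f2.shape}"
        )
    if not (np.all(np.isfinite(f1)) and np.all(np.isfinite(f2))):
        raise InvalidInputError("frames contain non-finite values")
    if f1.min() < 0 or f2.min() < 0:
        raise InvalidInputError("frames must be nonnegative")

    total = f1 + f2
    out = np.zeros_like(total)
    np.divide(f1 - f2, total, out=out, where=total > 0)
    return out
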