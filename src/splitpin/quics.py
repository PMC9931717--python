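"""Image-quality metrics by image correlation spectroscopy (QuICS).

Given a single image, the normalized spatial autocorrelation

    G_2D(dx, dy) = <I(x, y) I(x+dx, y+dy)> / <I>^2  -  1

is computed by FFT, angularly averaged into a radial profile G(dr), and a
noise-free Gaussian

    G_nf(d) = G_nf(0) * exp(-d^2 / w^2) + G_nf(inf),   d in [1, d_max]

is fitted while *skipping the zero lag*: uncorrelated (shot/read) noise
contributes variance only at d = 0, so extrapolating the fit back to 0
separates structure from noise. Three quality metrics follow:

    R = sqrt(2 ln 2) * w      resolution proxy (R >= FWHM; equality for
                              point-like objects)
    B = G_nf(0) * <I>         brightness / contrast
    N = (G(0) - G_nf(0)) / G_nf(0)   relative noise variance

The correlation is pair-count normalized (zero-padded FFT, each lag
divided by the number of contributing pixel pairs), i.e. the unbiased
non-circular estimator; with a region-of-interest mask, means and pair
counts run over masked pixels only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.fft import irfft2, rfft2
from scipy.optimize import curve_fit

from .errors import FitFailureError, InvalidInputError

__all__ = [
    "RadialACF",
    "GaussianFit",
    "QuicsReport",
    "image_acf",
    "fit_noise_free",
    "quics_metrics",
]

R_FROM_W = np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class RadialACF:
    """Radially averaged autocorrelation of one image.

    ``lags`` are integer radii in pixels starting at 0; ``values`` the
    angular mean of ``g2d`` over annuli round(sqrt(dx^2+dy^2)) == lag.
    ``g2d`` is centered (zero lag at the array center).
    """

    lags: np.ndarray
    values: np.ndarray
    g2d: np.ndarray
    mean_intensity: float


@dataclass(frozen=True)
class GaussianFit:
    """Noise-free Gaussian fitted to G(d) on d in [1, delta_max].

    ``width`` is the 1/e^2 parameter w of amplitude*exp(-d^2/w^2)+offset;
    ``degenerate`` flags a non-positive fitted amplitude (brightness and
    noise metrics are then unreliable).
    """

    amplitude: float
    width: float
    offset: float
    delta_max: int
    residual_norm: float
    degenerate: bool = False


@dataclass(frozen=True)
class QuicsReport:
    """The three quality metrics plus the objects they came from."""

    r_px: float
    r_physical: float | None
    b: float
    n: float
    fit: GaussianFit
    acf: RadialACF

    def as_dict(self) -> dict:
        return {
            "R_px": self.r_px,
            "R_physical": self.r_physical,
            "B": self.b,
            "N": self.n,
            "w": self.fit.width,
            "G0": float(self.acf.values[0]),
            "GNF0": self.fit.amplitude,
            "offset": self.fit.offset,
            "delta_max": self.fit.delta_max,
            "degenerate_fit": self.fit.degenerate,
        }


def _masked_correlation(image: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pair-count-normalized correlation <I(x) I(x+d)> over the mask.

    Zero-pads to >= 2x linear size so the FFT product is the linear
    (non-circular) correlation; each lag is divided by the number of
    in-mask pixel pairs that realize it.
    """
    h, w = image.shape
    ph, pw = 2 * h, 2 * w
    im = np.where(mask, image, 0.0)
    mk = mask.astype(np.float64)

    f_im = rfft2(im, s=(ph, pw))
    f_mk = rfft2(mk, s=(ph, pw))
    num = irfft2(f_im * np.conj(f_im), s=(ph, pw))
    counts = irfft2(f_mk * np.conj(f_mk), s=(ph, pw))

    num = np.fft.fftshift(num)
    counts = np.fft.fftshift(counts)
    counts = np.round(counts)
    return num, counts


def image_acf(image: np.ndarray, roi_mask: np.ndarray | None = None) -> RadialACF:
    """Normalized 2D autocorrelation and its angular average.

    Parameters
    ----------
    image : 2D ndarray
        Nonnegative intensities with positive mean over the ROI.
    roi_mask : 2D bool ndarray, optional
        Restricts all averages (mean intensity and pixel pairs) to the
        selected pixels.

    Returns
    -------
    RadialACF
        Lags 0..min(H, W)//2 and the angularly averaged G at each.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise InvalidInputError(f"image must be 2D, got ndim={img.ndim}")
    if not np.all(np.isfinite(img)):
        raise InvalidInputError("image contains non-finite values")
    if img.min() < 0:
        raise InvalidInputError("image must be nonnegative")
    if roi_mask is None:
        mask = np.ones(img.shape, dtype=bool)
    else:
        mask = np.asarray(roi_mask, dtype=bool)
        if mask.shape != img.shape:
            raise InvalidInputError(
                f"ROI shape {mask.shape} does not match image {img.shape}"
            )
    n_sel = int(mask.sum())
    if n_sel == 0:
        raise InvalidInputError("ROI selects no pixels")
    mean = float(img[mask].mean())
    if mean <= 0:
        raise InvalidInputError("image mean over the ROI must be positive")

    num, counts = _masked_correlation(img, mask)
    g2d = np.full(num.shape, np.nan)
    ok = counts > 0
    g2d[ok] = num[ok] / counts[ok] / mean**2 - 1.0

    h, w = img.shape
    cy, cx = h, w  # fftshifted zero lag of the (2h, 2w) array
    dy = np.arange(2 * h)[:, None] - cy
    dx = np.arange(2 * w)[None, :] - cx
    radius = np.round(np.hypot(dy, dx)).astype(np.int64)

    max_lag = min(h, w) // 2
    lags = np.arange(max_lag + 1)
    rad_ok = radius[ok]
    g_ok = g2d[ok]
    n_bins = max_lag + 1
    in_range = rad_ok <= max_lag
    counts_r = np.bincount(rad_ok[in_range], minlength=n_bins)
    sums_r = np.bincount(
        rad_ok[in_range], weights=g_ok[in_range], minlength=n_bins
    )
    with np.errstate(invalid="ignore"):
        values = np.where(counts_r > 0, sums_r / np.maximum(counts_r, 1), np.nan)

    # crop the centered 2D map back to +-(max_lag) for reporting
    g2d_crop = g2d[cy - max_lag : cy + max_lag + 1, cx - max_lag : cx + max_lag + 1]
    return RadialACF(lags=lags, values=values, g2d=g2d_crop, mean_intensity=mean)


def _gauss_model(d, amplitude, width, offset):
    return amplitude * np.exp(-(d**2) / width**2) + offset


def _fit_range(acf: RadialACF, delta_max: int) -> GaussianFit:
    lags = acf.lags[1 : delta_max + 1].astype(np.float64)
    vals = acf.values[1 : delta_max + 1]
    finite = np.isfinite(vals)
    lags, vals = lags[finite], vals[finite]
    if lags.size < 4:
        raise FitFailureError(
            f"need at least 4 finite lags in [1, {delta_max}], got {lags.size}",
            delta_max=delta_max,
        )
    # scale-free deterministic starting values
    g1 = vals[0]
    below = np.nonzero(vals < g1 / 2)[0]
    w0 = float(lags[below[0]]) if below.size else float(lags[-1]) / 2
    w0 = max(w0, 1.0)
    tail = vals[-max(1, vals.size // 10) :]
    p0 = (g1 - tail.mean(), w0, float(tail.mean()))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_gauss_model, lags, vals, p0=p0, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(
            f"Gaussian fit failed for delta_max={delta_max}: {exc}",
            delta_max=delta_max,
        ) from exc
    amplitude, width, offset = float(popt[0]), float(abs(popt[1])), float(popt[2])
    resid = vals - _gauss_model(lags, amplitude, width, offset)
    rms = float(np.sqrt(np.mean(resid**2)))
    degenerate = amplitude <= 0
    if degenerate:
        warnings.warn(
            "fitted noise-free amplitude is non-positive; brightness and "
            "noise metrics are unreliable",
            stacklevel=3,
        )
    return GaussianFit(
        amplitude=amplitude,
        width=width,
        offset=offset,
        delta_max=int(delta_max),
        residual_norm=rms,
        degenerate=degenerate,
    )


def _auto_delta_max(acf: RadialACF) -> int:
    """Deterministic fit-range rule approximating "fit a single Gaussian".

    Start at the first lag where G drops below 20% of G(1) (at least 4
    lags so the 3-parameter fit is overdetermined), grow delta_max to the
    largest available lag, and keep the largest range whose per-lag RMS
    residual stays within 2x the best range's.
    """
    vals = acf.values
    g1 = vals[1]
    finite = np.isfinite(vals)
    last = int(acf.lags[finite][-1])
    below = [
        r
        for r in range(1, last + 1)
        if np.isfinite(vals[r]) and vals[r] < 0.2 * g1
    ]
    start = max(4, below[0] if below else last)
    start = min(start, last)

    candidates = list(range(start, last + 1))
    fits: list[GaussianFit] = []
    for dmax in candidates:
        try:
            fits.append(_fit_range(acf, dmax))
        except FitFailureError:
            continue
    if not fits:
        raise FitFailureError(
            "no fit converged for any delta_max", delta_max=last
        )
    best = min(f.residual_norm for f in fits)
    tol = 2.0 * best if best > 0 else np.inf
    admissible = [f for f in fits if f.residual_norm <= tol]
    return max(f.delta_max for f in admissible)


def fit_noise_free(acf: RadialACF, delta_max: int | None = None) -> GaussianFit:
    """Least-squares Gaussian fit of G(d) on d in [1, delta_max].

    The zero lag is excluded so uncorrelated noise does not bias the fit;
    ``delta_max=None`` selects the range by the documented automatic
    rule. Raises :class:`FitFailureError` (carrying the attempted range)
    on non-convergence.
    """
    if delta_max is None:
        delta_max = _auto_delta_max(acf)
    else:
        delta_max = int(delta_max)
        if delta_max < 4:
            raise FitFailureError(
                f"delta_max must be >= 4 (3 parameters + 1 dof), got {delta_max}",
                delta_max=delta_max,
            )
    return _fit_range(acf, delta_max)


def quics_metrics(
    image: np.ndarray,
    pixel_size: float | None = None,
    delta_max: int | None = None,
    roi_mask: np.ndarray | None = None,
) -> QuicsReport:
    """Compute the R / B / N quality metrics of one image.

    R is reported in pixels, and additionally in physical units when
    ``pixel_size`` is given. N uses the raw angularly averaged zero-lag
    value for G(0).
    """
    acf = image_acf(image, roi_mask=roi_mask)
    fit = fit_noise_free(acf, delta_max=delta_max)
    r_px = R_FROM_W * fit.width
    g0 = float(acf.values[0])
    b = fit.amplitude * acf.mean_intensity
    n = (g0 - fit.amplitude) / fit.amplitude if fit.amplitude != 0 else np.nan
    return QuicsReport(
        r_px=float(r_px),
        r_physical=float(r_px * pixel_size) if pixel_size is not None else None,
        b=float(b),
        n=float(n),
        fit=fit,
        acf=acf,
    )
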