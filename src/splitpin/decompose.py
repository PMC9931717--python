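"""Two-component decomposition of the modulation image.

The modulation at a pixel is modeled as a linear mixture of two
endmembers: M = f_in * M_in + (1 - f_in) * M_out, where M_in is the
modulation of purely in-focus signal and M_out of purely out-of-focus
signal. Inverting the mixture gives a raw fraction

    f_in_lin = 1 - (M - M_in) / (M_out - M_in)

which can leave [0, 1] when M falls outside the endpoint interval; a
logistic filter 1 / (1 + exp(-k_L * (f_in_lin - 1/2))) soft-clamps it
into (0, 1). The virtually-closed-pinhole image is then
f_in * I_sum, its complement (1 - f_in) * I_sum being the removed
out-of-focus component; I_sum is the (partial) sum of frames j0..N.

Endpoints are estimated from the data as low/high percentiles (default
10% and 90%) of the modulation histogram over bright pixels, mirroring
the interactive choice a user would make from the histogram; both can be
overridden manually.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    DegenerateModulationError,
    InvalidParametersError,
    NoSignalError,
)
from .phasor import PhasorMaps, compute_phasor, modulation_n2
from .stack import PinholeStack

__all__ = [
    "DecompositionParams",
    "DecompositionResult",
    "default_intensity_threshold",
    "estimate_endpoints",
    "linear_fraction",
    "logistic_filter",
    "sum_image",
    "split_pin",
    "split_pin_n2_closed_form",
]

logger = logging.getLogger(__name__)

#: Default logistic steepness.
DEFAULT_K_L = 4.0
#: Default percentile pair for endpoint estimation.
DEFAULT_PERCENTILES = (10.0, 90.0)
#: Default intensity threshold as a fraction of max(I_sum over all frames).
DEFAULT_THRESHOLD_FRACTION = 0.05
#: m_out - m_in below this is treated as a degenerate (contrast-free) histogram.
ENDPOINT_DEGENERACY_TOL = 1e-9


@dataclass(frozen=True)
class DecompositionParams:
    """Parameters of one decomposition run.

    ``m_in``/``m_out`` of None mean "estimate from the data";
    ``intensity_threshold`` of None means the scale-free default
    (5% of the maximum total intensity). ``j0`` is 1-based: 1 sums the
    whole stack (best SNR), n_frames keeps only the smallest-pinhole
    frame (best sectioning).
    """

    m_in: float | None = None
    m_out: float | None = None
    k_l: float = DEFAULT_K_L
    j0: int = 1
    intensity_threshold: float | None = None
    percentiles: tuple[float, float] = DEFAULT_PERCENTILES

    def __post_init__(self) -> None:
        if self.k_l <= 0:
            raise InvalidParametersError(f"k_l must be positive, got {self.k_l}")
        lo, hi = self.percentiles
        if not (0 < lo < hi < 100):
            raise InvalidParametersError(
                f"percentiles must satisfy 0 < lo < hi < 100, got {self.percentiles}"
            )
        if (self.m_in is None) != (self.m_out is None):
            raise InvalidParametersError(
                "m_in and m_out must be overridden together or not at all"
            )
        if self.m_in is not None and not self.m_in < self.m_out:
            raise InvalidParametersError(
                f"m_in must be < m_out, got {self.m_in} >= {self.m_out}"
            )
        if (
            self.intensity_threshold is not None
            and self.intensity_threshold < 0
        ):
            raise InvalidParametersError("intensity_threshold must be >= 0")


@dataclass(frozen=True)
class DecompositionResult:
    """Output of one decomposition: maps plus the parameters actually used.

    Invariant: ``split_pin + out_of_focus == sum_image`` elementwise, and
    ``f_in`` lies strictly in (0, 1) (range of the logistic). The
    out-of-focus *fraction* is 1 - f_in and is not stored separately.
    """

    f_in: np.ndarray
    f_in_linear: np.ndarray
    split_pin: np.ndarray
    out_of_focus: np.ndarray
    sum_image: np.ndarray
    params_used: DecompositionParams
    phasor: PhasorMaps = field(repr=False)
    out_of_range_fraction: float = 0.0


def default_intensity_threshold(stack: PinholeStack) -> float:
    """Scale-free default histogram threshold: 5% of max total intensity."""
    return DEFAULT_THRESHOLD_FRACTION * float(stack.frames.sum(axis=0).max())


def estimate_endpoints(
    phasor: PhasorMaps,
    stack: PinholeStack,
    intensity_threshold: float | None = None,
    percentiles: tuple[float, float] = DEFAULT_PERCENTILES,
) -> tuple[float, float]:
    """Estimate (m_in, m_out) from the thresholded modulation histogram.

    The histogram population is {M(x, y) : pixel valid and total
    intensity > threshold}, where "total intensity" is the full sum over
    all frames (all collected photons, the most stable per-pixel
    statistic). Percentiles use linear interpolation between order
    statistics (numpy's default rule).

    Raises
    ------
    NoSignalError
        If no pixel passes the threshold.
    DegenerateModulationError
        If the two percentiles coincide (no modulation contrast); set the
        endpoints manually in that case.
    """
    lo, hi = percentiles
    if not lo < hi:
        raise InvalidParametersError(
            f"percentiles must be increasing, got {percentiles}"
        )
    total = stack.frames.sum(axis=0)
    if intensity_threshold is None:
        intensity_threshold = default_intensity_threshold(stack)
    population = phasor.modulation[phasor.valid_mask & (total > intensity_threshold)]
    if population.size < 2:
        raise NoSignalError(
            f"only {population.size} pixels pass the intensity threshold "
            f"{intensity_threshold:g}; lower the threshold"
        )
    m_in, m_out = np.percentile(population, [lo, hi])
    if m_out - m_in < ENDPOINT_DEGENERACY_TOL:
        raise DegenerateModulationError(
            f"modulation histogram is degenerate (P{lo:g} = P{hi:g} = {m_in:.6g}); "
            "there is no axial contrast to decompose — set m_in/m_out manually"
        )
    return float(m_in), float(m_out)


def linear_fraction(
    modulation: np.ndarray, m_in: float, m_out: float
) -> np.ndarray:
    """Linear unmixing of the modulation: 1 - (M - m_in)/(m_out - m_in).

    Values outside [0, 1] (modulation beyond the endpoints) are passed
    through unchanged — soft-clamping is the logistic filter's job.
    """
    if not m_in < m_out:
        raise InvalidParametersError(
            f"m_in must be < m_out, got {m_in} >= {m_out}"
        )
    m = np.asarray(modulation, dtype=np.float64)
    return 1.0 - (m - m_in) / (m_out - m_in)


def logistic_filter(f_linear: np.ndarray, k_l: float = DEFAULT_K_L) -> np.ndarray:
    """Soft-clamp the raw fraction into (0, 1).

    f_in = 1 / (1 + exp(-k_l * (f_linear - 1/2))); the midpoint 0.5 is a
    fixed point and f(x) + f(1 - x) = 1.
    """
    if k_l <= 0:
        raise InvalidParametersError(f"k_l must be positive, got {k_l}")
    x = np.asarray(f_linear, dtype=np.float64)
    return 1.0 / (1.0 + np.exp(-k_l * (x - 0.5)))


def sum_image(stack: PinholeStack, j0: int = 1) -> np.ndarray:
    """Partial sum of frames j0..N (1-based j0).

    j0 = 1 sums the whole stack (best SNR, worst sectioning); j0 = N
    keeps only the smallest-pinhole frame (best sectioning, worst SNR).
    """
    n = stack.n_frames
    if not 1 <= j0 <= n:
        raise InvalidParametersError(f"j0 must be in [1, {n}], got {j0}")
    return stack.frames[j0 - 1 :].sum(axis=0)


def split_pin(
    stack: PinholeStack, params: DecompositionParams | None = None
) -> DecompositionResult:
    """Run the full decomposition: phasor -> endpoints -> fraction -> images.

    When the endpoints are not overridden in ``params`` they are
    estimated by :func:`estimate_endpoints`. The returned result carries
    the parameters actually used (estimated endpoints and resolved
    threshold included) for provenance.
    """
    if params is None:
        params = DecompositionParams()

    phasor = compute_phasor(stack)

    threshold = params.intensity_threshold
    if threshold is None:
        threshold = default_intensity_threshold(stack)

    if params.m_in is None:
        m_in, m_out = estimate_endpoints(
            phasor, stack, threshold, params.percentiles
        )
    else:
        m_in, m_out = params.m_in, params.m_out

    f_lin = linear_fraction(phasor.modulation, m_in, m_out)
    f_in = logistic_filter(f_lin, params.k_l)

    # fraction of pixels whose raw fraction left [0,1]: a poor-endpoint signal
    valid = phasor.valid_mask
    if valid.any():
        out_of_range = float(
            np.mean((f_lin[valid] < 0.0) | (f_lin[valid] > 1.0))
        )
    else:
        out_of_range = 0.0
    if out_of_range > 0.05:
        logger.warning(
            "%.1f%% of pixels have raw in-focus fraction outside [0, 1]; "
            "the endpoints m_in=%.4g, m_out=%.4g may be poorly chosen",
            100 * out_of_range,
            m_in,
            m_out,
        )

    i_sum = sum_image(stack, params.j0)
    used = replace(
        params, m_in=float(m_in), m_out=float(m_out), intensity_threshold=float(threshold)
    )
    return DecompositionResult(
        f_in=f_in,
        f_in_linear=f_lin,
        split_pin=f_in * i_sum,
        out_of_focus=(1.0 - f_in) * i_sum,
        sum_image=i_sum,
        params_used=used,
        phasor=phasor,
        out_of_range_fraction=out_of_range,
    )


def split_pin_n2_closed_form(
    frame1: np.ndarray,
    frame2: np.ndarray,
    m_in: float,
    m_out: float,
    k_l: float = DEFAULT_K_L,
) -> np.ndarray:
    """Two-frame closed form of the virtually-closed-pinhole image.

    Evaluates, with I_dif = F1 - F2 and I_sum = F1 + F2,

        I = I_sum / (1 + exp(-k_l * (1/2 - ((I_dif/I_sum) - m_in)/(m_out - m_in))))

    which is what the composed pipeline reduces to at N = 2 with j0 = 1.
    Exists purely as an independent verification oracle for
    :func:`split_pin`; note the result is *not* a linear combination of
    the two frames — the logistic makes it nonlinear in the data.
    """
    if not m_in < m_out:
        raise InvalidParametersError(
            f"m_in must be < m_out, got {m_in} >= {m_out}"
        )
    m = modulation_n2(frame1, frame2)
    i_sum = np.asarray(frame1, dtype=np.float64) + np.asarray(
        frame2, dtype=np.float64
    )
    weight = 1.0 / (
        1.0 + np.exp(-k_l * (0.5 - (np.abs(m) - m_in) / (m_out - m_in)))
    )
    return weight * i_sum
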