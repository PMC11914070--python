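"""Linear filters and the dendritic nonlinearity of the motion sensor.

Four fixed filters define the sensor: two 1-D temporal filters sampled
at the frame rate (``T_m``, bandpass, feeding the linear branch;
``T_w``, lowpass, feeding the nonlinear branch) and two 2-D spatial
kernels (*m*, an isotropic Gaussian; *w*, a vertically oriented,
horizontally odd Gabor).  The nonlinearity ``sigma_nl`` is an even,
saturating Naka–Rushton-style function of luminance differences.

Temporal filters are returned *unnormalized*: the closed forms are
absolute, and the branch weight ``lam`` is calibrated against them, so
rescaling the taps would silently change the linear/nonlinear balance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError
from .params import ModelParams

__all__ = [
    "SampledFilter",
    "SpatialKernel",
    "sample_tm",
    "sample_tw",
    "make_gaussian",
    "make_gabor",
    "sigma_nl",
    "GABOR_POLARITY",
]

#: Polarity of the odd Gabor *w* (+1 puts the positive lobe at positive x).
#: Fixed once so that the full sensor responds with a POSITIVE sign to the
#: canonical rightward-drifting 2 c/deg, 4 Hz grating; rightward motion is
#: then positive everywhere in the package by convention.
GABOR_POLARITY = 1.0


@dataclass(frozen=True)
class SampledFilter:
    """A 1-D temporal filter sampled at delays u = 0, dt, 2*dt, ...

    ``taps[i]`` is the filter value at delay ``i * dt_ms`` milliseconds.
    """

    taps: np.ndarray
    dt_ms: float
    duration_ms: float

    def __post_init__(self):
        taps = np.asarray(self.taps, dtype=float)
        object.__setattr__(self, "taps", taps)
        expected = int(math.floor(self.duration_ms / self.dt_ms + 1e-9)) + 1
        if taps.ndim != 1 or taps.size != expected:
            raise InvalidParameterError(
                f"expected {expected} taps for duration {self.duration_ms} ms "
                f"at dt {self.dt_ms} ms, got shape {taps.shape}"
            )
        if not np.all(np.isfinite(taps)):
            raise InvalidParameterError("filter taps must be finite")

    @property
    def delays_ms(self) -> np.ndarray:
        return np.arange(self.taps.size) * self.dt_ms

    def __len__(self) -> int:
        return self.taps.size


@dataclass(frozen=True)
class SpatialKernel:
    """A 2-D spatial kernel on a pixel grid with odd side lengths.

    ``center`` is the (row, col) index of the kernel origin, i.e. the
    sensor location the kernel is applied around.
    """

    weights: np.ndarray
    deg_per_px: float
    center: tuple = field(default=None)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[0] % 2 == 0 or w.shape[1] % 2 == 0:
            raise InvalidParameterError(
                f"kernel must be 2-D with odd side lengths, got shape {w.shape}"
            )
        if not np.all(np.isfinite(w)):
            raise InvalidParameterError("kernel weights must be finite")
        if self.center is None:
            object.__setattr__(self, "center", (w.shape[0] // 2, w.shape[1] // 2))

    @property
    def half_height(self) -> int:
        return self.weights.shape[0] // 2

    @property
    def half_width(self) -> int:
        return self.weights.shape[1] // 2


def _delays(params: ModelParams, duration_ms: float) -> np.ndarray:
    if params.fps <= 0:
        raise InvalidParameterError("fps must be positive")
    dt = params.dt_ms
    n_taps = int(math.floor(duration_ms / dt + 1e-9)) + 1
    return np.arange(n_taps) * dt


def tm_continuous(t_ms, params: ModelParams = ModelParams()) -> np.ndarray:
    """Closed form of the bandpass temporal filter T_m at time t (ms).

    T_m(t) = (k t)^n exp(-k t) [ 1/n! - (k t)^2 / (n+2)! ]
    """
    t = np.asarray(t_ms, dtype=float)
    kt = params.k * t
    n = int(params.n)
    return kt**n * np.exp(-kt) * (
        1.0 / math.factorial(n) - kt**2 / math.factorial(n + 2)
    )


def tw_continuous(t_ms, params: ModelParams = ModelParams()) -> np.ndarray:
    """Closed form of the lowpass temporal filter T_w at time t (ms).

    T_w(t) = cos(pi (t + 10) / 120); non-negative on [0, 50] ms.
    """
    t = np.asarray(t_ms, dtype=float)
    return np.cos(np.pi * (t + 10.0) / 120.0)


def sample_tm(params: ModelParams = ModelParams()) -> SampledFilter:
    """Sample T_m at the frame interval over its full support."""
    u = _delays(params, params.tm_duration_ms)
    return SampledFilter(tm_continuous(u, params), params.dt_ms, params.tm_duration_ms)


def sample_tw(params: ModelParams = ModelParams()) -> SampledFilter:
    """Sample T_w at the frame interval over its full support."""
    u = _delays(params, params.tw_duration_ms)
    return SampledFilter(tw_continuous(u, params), params.dt_ms, params.tw_duration_ms)


def make_gaussian(params: ModelParams = ModelParams()) -> SpatialKernel:
    """Isotropic Gaussian kernel *m*, truncated at +-3 sigma, unit sum.

    The unit sum makes the linear branch an unbiased local luminance
    estimate: on a constant image of value c the branch returns c.
    """
    sigma_px = params.m_sigma_deg / params.deg_per_px
    if sigma_px < 1.0:
        warnings.warn(
            f"Gaussian sigma is {sigma_px:.3f} px (< 1 px) at this calibration; "
            "the kernel degenerates toward a delta",
            stacklevel=2,
        )
    half = max(1, int(math.ceil(3.0 * sigma_px)))
    ax = np.arange(-half, half + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    g = np.exp(-(xx**2 + yy**2) / (2.0 * sigma_px**2))
    g /= g.sum()
    return SpatialKernel(g, params.deg_per_px)


def make_gabor(
    params: ModelParams = ModelParams(), max_support_px: int | None = None
) -> SpatialKernel:
    """Vertically oriented, horizontally odd (sine-phase) Gabor kernel *w*.

    The carrier period is twice the printed lobe width, so the kernel has
    exactly two dominant lobes of opposite sign.  The isotropic Gaussian
    envelope has sigma equal to a quarter of the carrier period, which
    keeps any third lobe below 5% of the main lobes; truncation is at
    +-3 sigma.  The grid is antisymmetrized about the vertical axis, so
    zero mean and odd symmetry hold exactly.

    Parameters
    ----------
    max_support_px : int, optional
        If given, raise if the kernel side length exceeds this (e.g. the
        image size the kernel is meant to be applied to).
    """
    period_px = 2.0 * params.w_lobe_width_deg / params.deg_per_px
    sigma_px = period_px / 4.0
    half = max(1, int(math.ceil(3.0 * sigma_px)))
    side = 2 * half + 1
    if max_support_px is not None and side > max_support_px:
        raise InvalidParameterError(
            f"Gabor support ({side} px) exceeds the image size ({max_support_px} px)"
        )
    ax = np.arange(-half, half + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    envelope = np.exp(-(xx**2 + yy**2) / (2.0 * sigma_px**2))
    carrier = np.sin(2.0 * np.pi * xx / period_px)
    w = GABOR_POLARITY * envelope * carrier
    # enforce exact odd symmetry (hence exact zero sum) on the stored grid
    w = 0.5 * (w - w[:, ::-1])
    return SpatialKernel(w, params.deg_per_px)


def sigma_nl(z, params: ModelParams = ModelParams()):
    """Even, saturating dendritic nonlinearity sigma(z) = |z|^p / (|z|^p + q^p).

    Elementwise and total on the reals: sigma(0) = 0, sigma(+-q) = 1/2,
    strictly increasing in |z| and bounded above by 1.
    """
    a = np.abs(np.asarray(z, dtype=float)) ** params.p
    out = a / (a + params.q**params.p)
    if np.isscalar(z) or np.ndim(z) == 0:
        return float(out)
    return out
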