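"""The INRF, stINRF and MS-INRF response computations.

The spatial receptive field combines a linear branch (Gaussian kernel
*m*) with a nonlinear "dendritic" branch (odd Gabor *w* applied to the
saturated luminance differences relative to the sensor's own input):

    INRF(s_i) = sum_j m_j I(s_j)  -  lam * sum_j w_j sigma(I(s_j) - I(s_i))

The spatio-temporal extension convolves each branch with its own
temporal filter (T_m bandpass, T_w lowpass) over delays u; crucially,
the shift inside sigma is the sensor's CURRENT input I(s_i, t), not the
delayed one:

    stINRF(s_i, t) = sum_u T_m(u) sum_j m_j I(s_j, t-u)
                     - lam * sum_u T_w(u) sum_j w_j sigma(I(s_j, t-u) - I(s_i, t))

The motion-sensor readout MS-INRF is the time average of the stINRF
trace over frames with full temporal-filter support.  By the package's
sign convention, rightward motion yields positive values.

Because sigma's shift depends on the sensor location, the nonlinear
branch admits no separable/convolutional shortcut; the optimized path
below only vectorizes the literal sums (and collapses the kernels to
1-D when the input is constant along the vertical axis, which holds for
every built-in stimulus).  A brute-force nested-loop implementation is
provided as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import InvalidInputError, OutOfBoundsError
from .filters import make_gabor, make_gaussian, sample_tm, sample_tw, sigma_nl
from .params import ModelParams
from .stimuli import StimulusSequence

__all__ = [
    "ResponseTrace",
    "SensorResponse",
    "FieldResponse",
    "inrf_spatial",
    "stinrf",
    "stinrf_bruteforce",
    "ms_inrf",
    "stinrf_field",
]


@dataclass(frozen=True)
class ResponseTrace:
    """stINRF output at one location over time.

    ``values`` has one entry per input frame; entries before
    ``valid_from`` (frames without full temporal-filter support) are NaN.
    """

    values: np.ndarray
    valid_from: int
    location: tuple

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_from:]

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class SensorResponse:
    """Scalar MS-INRF readout: the time-mean of a stINRF trace."""

    value: float
    location: tuple
    averaging_window: tuple  # (first frame, last frame + 1)


@dataclass(frozen=True)
class FieldResponse:
    """stINRF traces on a regular spatial grid (time, rows, cols)."""

    values: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    valid_from: int


@lru_cache(maxsize=32)
def _kernels(params: ModelParams):
    tm = sample_tm(params).taps
    tw = sample_tw(params).taps
    m = make_gaussian(params).weights
    w = make_gabor(params).weights
    return tm, tw, m, w


def _check_margins(shape, location, half_m, half_w):
    h, wd = shape[-2:]
    r, c = location
    if not (0 <= r < h and 0 <= c < wd):
        raise OutOfBoundsError(f"location {location} outside a {h}x{wd} image")
    half = max(half_m, half_w)
    if r < half or r >= h - half or c < half or c >= wd - half:
        raise OutOfBoundsError(
            f"location {location} is within a kernel half-width ({half} px) of "
            f"the border of a {h}x{wd} image; use boundary='mirror' or move it"
        )


def inrf_spatial(image: np.ndarray, params: ModelParams, location: tuple) -> float:
    """Spatial INRF response to a single frame at one location."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise InvalidInputError(f"expected a 2-D image, got shape {image.shape}")
    _, _, m, w = _kernels(params)
    hm, hw = m.shape[0] // 2, w.shape[0] // 2
    _check_margins(image.shape, location, hm, hw)
    r, c = location
    win_m = image[r - hm:r + hm + 1, c - hm:c + hm + 1]
    win_w = image[r - hw:r + hw + 1, c - hw:c + hw + 1]
    linear = float(np.sum(m * win_m))
    nonlin = float(np.sum(w * sigma_nl(win_w - image[r, c], params)))
    return linear - params.lam * nonlin


def _mirror_pad(frames: np.ndarray, pad: int) -> np.ndarray:
    return np.pad(frames, ((0, 0), (pad, pad), (pad, pad)), mode="reflect")


def _as_frames(seq) -> tuple:
    if isinstance(seq, StimulusSequence):
        return seq.frames, True
    return np.asarray(seq, dtype=float), False


def stinrf(
    seq: StimulusSequence,
    params: ModelParams,
    location: tuple,
    boundary: str = "strict",
) -> ResponseTrace:
    """Spatio-temporal INRF trace at one sensor location.

    ``boundary='strict'`` (default) requires the kernels to be fully
    supported around ``location``; ``'mirror'`` reflects the stimulus at
    the image borders instead.
    """
    frames, _ = _as_frames(seq)
    tm, tw, m, w = _kernels(params)
    n_taps = tm.size
    t_total = frames.shape[0]
    if t_total < n_taps:
        raise InvalidInputError(
            f"sequence of {t_total} frames is shorter than the temporal filter "
            f"support ({n_taps} frames)"
        )
    hm, hw = m.shape[0] // 2, w.shape[0] // 2
    if boundary == "mirror":
        pad = max(hm, hw)
        frames = _mirror_pad(frames, pad)
        location = (location[0] + pad, location[1] + pad)
    elif boundary != "strict":
        raise InvalidInputError(f"unknown boundary mode {boundary!r}")
    _check_margins(frames.shape, location, hm, hw)
    r, c = location

    x_only = frames.strides[1] == 0
    center = frames[:, r, c]

    if x_only:
        # vertically constant input: collapse the kernels to their column sums
        prof = frames[:, r, :]
        m1 = m.sum(axis=0)
        w1 = w.sum(axis=0)
        lin0 = prof[:, c - hm:c + hm + 1] @ m1
        win_w = prof[:, c - hw:c + hw + 1]
        sw = sliding_window_view(win_w, n_taps, axis=0)  # (T-n+1, K, n)
        z = sw - center[n_taps - 1:, None, None]
        s = sigma_nl(z, params)
        inner = np.einsum("ikn,k->in", s, w1)
    else:
        win_m = frames[:, r - hm:r + hm + 1, c - hm:c + hm + 1]
        lin0 = np.tensordot(win_m, m, axes=([1, 2], [0, 1]))
        win_w = np.ascontiguousarray(frames[:, r - hw:r + hw + 1, c - hw:c + hw + 1])
        sw = sliding_window_view(win_w, n_taps, axis=0)  # (T-n+1, K, K, n)
        z = sw - center[n_taps - 1:, None, None, None]
        s = sigma_nl(z, params)
        inner = np.einsum("ijkn,jk->in", s, w)

    # delay u corresponds to window index n_taps - 1 - u
    tm_rev = tm[::-1].copy()
    tw_rev = tw[::-1].copy()
    lin = sliding_window_view(lin0, n_taps) @ tm_rev
    nl = inner @ tw_rev

    values = np.full(t_total, np.nan)
    values[n_taps - 1:] = lin - params.lam * nl
    return ResponseTrace(values, n_taps - 1, (r, c))


def stinrf_bruteforce(
    seq: StimulusSequence, params: ModelParams, location: tuple
) -> ResponseTrace:
    """Literal nested-summation reference implementation of the stINRF.

    Loops explicitly over delays and kernel offsets with no vectorized
    shortcut; intended only for small inputs (cost is O(T * n_taps *
    kernel area) scalar operations) and as the oracle for equivalence
    tests.
    """
    frames, _ = _as_frames(seq)
    tm, tw, m, w = _kernels(params)
    n_taps = tm.size
    t_total = frames.shape[0]
    if t_total < n_taps:
        raise InvalidInputError("sequence shorter than the temporal filter support")
    hm, hw = m.shape[0] // 2, w.shape[0] // 2
    _check_margins(frames.shape, location, hm, hw)
    r, c = location
    values = np.full(t_total, np.nan)
    for t in range(n_taps - 1, t_total):
        i_now = frames[t, r, c]
        linear = 0.0
        nonlin = 0.0
        for u in range(n_taps):
            acc_m = 0.0
            for dy in range(-hm, hm + 1):
                for dx in range(-hm, hm + 1):
                    acc_m += m[dy + hm, dx + hm] * frames[t - u, r + dy, c + dx]
            linear += tm[u] * acc_m
            acc_w = 0.0
            for dy in range(-hw, hw + 1):
                for dx in range(-hw, hw + 1):
                    acc_w += w[dy + hw, dx + hw] * sigma_nl(
                        frames[t - u, r + dy, c + dx] - i_now, params
                    )
            nonlin += tw[u] * acc_w
        values[t] = linear - params.lam * nonlin
    return ResponseTrace(values, n_taps - 1, (r, c))


def ms_inrf(
    seq: StimulusSequence,
    params: ModelParams = ModelParams(),
    location: tuple | None = None,
    window: tuple | None = None,
    boundary: str = "strict",
) -> SensorResponse:
    """Scalar motion-sensor readout: time-mean of the stINRF trace.

    ``location`` defaults to the central pixel.  ``window`` optionally
    restricts the averaging to a frame range ``(start, stop)``; by
    default all frames with full temporal-filter support are used.
    Positive values indicate rightward motion.
    """
    frames, _ = _as_frames(seq)
    if location is None:
        location = (frames.shape[1] // 2, frames.shape[2] // 2)
    trace = stinrf(seq, params, location, boundary=boundary)
    start, stop = trace.valid_from, trace.values.size
    if window is not None:
        start, stop = max(window[0], trace.valid_from), min(window[1], stop)
    if stop <= start:
        raise InvalidInputError("no valid frames in the averaging window")
    value = float(np.mean(trace.values[start:stop]))
    return SensorResponse(value, tuple(location), (start, stop))


def stinrf_field(
    seq: StimulusSequence,
    params: ModelParams,
    stride: int = 1,
    boundary: str = "strict",
) -> FieldResponse:
    """stINRF traces on a regular spatial grid with the given stride.

    With the default strict boundary, only locations where both kernels
    are fully supported are evaluated.
    """
    if stride < 1:
        raise InvalidInputError(f"stride must be >= 1, got {stride}")
    frames, _ = _as_frames(seq)
    _, _, m, w = _kernels(params)
    half = max(m.shape[0] // 2, w.shape[0] // 2)
    h, wd = frames.shape[1:]
    if boundary == "mirror":
        rows = np.arange(0, h, stride)
        cols = np.arange(0, wd, stride)
    else:
        rows = np.arange(half, h - half, stride)
        cols = np.arange(half, wd - half, stride)
    if rows.size == 0 or cols.size == 0:
        raise OutOfBoundsError("image too small for any fully supported location")
    out = np.empty((frames.shape[0], rows.size, cols.size))
    valid_from = None
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            tr = stinrf(seq, params, (int(r), int(c)), boundary=boundary)
            out[:, i, j] = tr.values
            valid_from = tr.valid_from
    return FieldResponse(out, rows, cols, valid_from)
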