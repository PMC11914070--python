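"""Model parameters of the MS-INRF motion sensor.

A single parameter set drives every simulation in the package: the
temporal filters :math:`T_m` (bandpass, on the linear branch) and
:math:`T_w` (lowpass, on the nonlinear branch), the spatial kernels
*m* (Gaussian) and *w* (vertically oriented odd Gabor), the weight
``lam`` coupling the two branches, and the saturating even nonlinearity
:math:`\\sigma(z) = |z|^p / (|z|^p + q^p)` applied to local luminance
differences.  Defaults are the values used throughout the experiments;
none of them is fitted to data.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

from .errors import InvalidParameterError

__all__ = ["ModelParams", "DEFAULT_DEG_PER_PX", "DEFAULT_FPS"]

#: Default spatial calibration: a 400-px image spans 2 deg of visual angle.
DEFAULT_DEG_PER_PX = 2.0 / 400.0

#: Default frame rate of the stimulus sequences, Hz.
DEFAULT_FPS = 120.0


@dataclass(frozen=True)
class ModelParams:
    """Complete, immutable parameter set of the motion sensor.

    Parameters
    ----------
    k : float
        Rate constant of the bandpass temporal filter ``T_m``, in 1/ms.
    n : int
        Order of the gamma-like factor of ``T_m``.
    tm_duration_ms, tw_duration_ms : float
        Temporal support of ``T_m`` and ``T_w``, in milliseconds.
    m_sigma_deg : float
        Standard deviation of the Gaussian spatial kernel *m*, in degrees.
    w_lobe_width_deg : float
        Horizontal width of each (positive and negative) lobe of the odd
        Gabor kernel *w*, in degrees.  The carrier period is twice this.
    lam : float
        Weight of the nonlinear (dendritic) branch.  Negative by default,
        so the branch adds to the response with a gain of ``-lam``.
    p : float
        Exponent of the saturating nonlinearity.
    q : float
        Half-saturation constant of the nonlinearity, in luminance units:
        ``sigma(q) = 0.5``.
    fps : float
        Frame rate of the input sequences, Hz.  Also sets the temporal
        sampling step of the filters (``dt_ms = 1000 / fps``).
    deg_per_px : float
        Spatial calibration of the input, degrees of visual angle per pixel.
    """

    k: float = 0.4
    n: int = 5
    tm_duration_ms: float = 50.0
    tw_duration_ms: float = 50.0
    m_sigma_deg: float = 0.031
    w_lobe_width_deg: float = 0.125
    lam: float = -30.0
    p: float = 0.4
    q: float = 0.1
    fps: float = DEFAULT_FPS
    deg_per_px: float = DEFAULT_DEG_PER_PX

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise InvalidParameterError(f"fps must be positive, got {self.fps}")
        if self.p <= 0:
            raise InvalidParameterError(f"p must be positive, got {self.p}")
        if self.q <= 0:
            raise InvalidParameterError(f"q must be positive, got {self.q}")
        if self.deg_per_px <= 0:
            raise InvalidParameterError(
                f"deg_per_px must be positive, got {self.deg_per_px}"
            )
        if self.n < 0 or int(self.n) != self.n:
            raise InvalidParameterError(f"n must be a non-negative integer, got {self.n}")
        for name in ("tm_duration_ms", "tw_duration_ms"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.m_sigma_deg <= 0 or self.w_lobe_width_deg <= 0:
            raise InvalidParameterError("spatial kernel sizes must be positive")

    @property
    def dt_ms(self) -> float:
        """Temporal sampling interval in milliseconds (one frame)."""
        return 1000.0 / self.fps

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise InvalidParameterError(
                "unknown model parameter(s): " + ", ".join(sorted(unknown))
            )
        return cls(**d)

    def evolve(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)
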