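"""Synthetic stimulus generation.

Every stimulus is a :class:`StimulusSequence`: a (time, height, width)
luminance stack in [0, 1] with frame-rate and degrees-per-pixel
calibration.  Defaults follow the study conditions used throughout the
experiments: 120 frames of 400 x 400 px spanning 2 deg of visual angle,
played at 120 Hz (1 s).

All recipes here vary only along the horizontal axis (vertical bars,
vertical gratings, vertical strip patterns), so frames are generated as
a (time, width) profile and broadcast along the vertical axis without
copying.  Downstream code may rely only on the 3-D ``frames`` array;
the broadcast layout is an internal optimization.

Sub-pixel motion handling: binary patterns (bars, random strips) are
displaced by integer pixel shifts following the rounded cumulative
displacement (accumulated-remainder schedule), avoiding interpolation
artifacts; sinusoids carry the exact analytic phase instead and need no
rounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .errors import InvalidParameterError
from .params import DEFAULT_DEG_PER_PX, DEFAULT_FPS

__all__ = [
    "StimulusSequence",
    "StimulusRecipe",
    "moving_bar",
    "drifting_grating",
    "masked_grating",
    "random_pattern",
    "square_wave_sequence",
    "contrast_modulated",
    "compound_grating",
    "apply_dog_lgn",
    "apply_optical_blur",
]


@dataclass(frozen=True)
class StimulusRecipe:
    """Geometry and identity of a stimulus: what to generate and on what grid."""

    name: str = ""
    parameters: dict = field(default_factory=dict)
    fps: float = DEFAULT_FPS
    duration_s: float = 1.0
    size_px: int = 400
    deg_per_px: float = DEFAULT_DEG_PER_PX

    def __post_init__(self):
        if self.fps <= 0 or self.duration_s <= 0 or self.size_px <= 0:
            raise InvalidParameterError("fps, duration_s and size_px must be positive")
        if self.deg_per_px <= 0:
            raise InvalidParameterError("deg_per_px must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def nyquist_cpd(self) -> float:
        return 0.5 / self.deg_per_px

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class StimulusSequence:
    """A time-varying 2-D luminance input I(s, t).

    ``frames`` has shape (time, height, width).  Luminance stimuli lie in
    [0, 1]; stacks produced by neural pre-filters (e.g. the DoG LGN
    stage) are tagged ``meta['signal_domain'] = 'neural'`` and are not
    range-restricted.
    """

    frames: np.ndarray
    fps: float = DEFAULT_FPS
    deg_per_px: float = DEFAULT_DEG_PER_PX
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        f = np.asarray(self.frames, dtype=float)
        if f.ndim != 3:
            raise InvalidParameterError(f"frames must be 3-D, got shape {f.shape}")
        object.__setattr__(self, "frames", f)
        if self.meta.get("signal_domain", "luminance") == "luminance":
            # validate on the profile when frames are a vertical broadcast
            v = f[:, f.shape[1] // 2, :] if f.strides[1] == 0 else f
            lo, hi = v.min(), v.max()
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise InvalidParameterError(
                    f"luminance must lie in [0, 1], got range [{lo:.4g}, {hi:.4g}]"
                )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def is_x_only(self) -> bool:
        """True if frames are a vertical broadcast of a (time, width) profile."""
        return self.frames.strides[1] == 0

    def profile(self) -> np.ndarray:
        """The (time, width) horizontal profile (central row)."""
        return self.frames[:, self.frames.shape[1] // 2, :]


def _broadcast(profile: np.ndarray, height: int) -> np.ndarray:
    """Broadcast a (T, W) profile to a read-only (T, H, W) view."""
    t, w = profile.shape
    return np.broadcast_to(profile[:, None, :], (t, height, w))


def _seq_from_profile(profile, recipe: StimulusRecipe, **meta) -> StimulusSequence:
    profile = np.ascontiguousarray(profile, dtype=float)
    meta = {"recipe": recipe.name, "parameters": dict(recipe.parameters), **meta}
    return StimulusSequence(
        _broadcast(profile, recipe.size_px), recipe.fps, recipe.deg_per_px, meta
    )


def _grid(recipe: StimulusRecipe):
    """x in degrees (1-D, width) and t in seconds (1-D, frames)."""
    x = np.arange(recipe.size_px) * recipe.deg_per_px
    t = np.arange(recipe.n_frames) / recipe.fps
    return x, t


def _check_sf(sf_cpd: float, recipe: StimulusRecipe) -> None:
    if sf_cpd < 0:
        raise InvalidParameterError(f"spatial frequency must be >= 0, got {sf_cpd}")
    if sf_cpd > recipe.nyquist_cpd:
        raise InvalidParameterError(
            f"spatial frequency {sf_cpd} c/deg exceeds the Nyquist limit "
            f"{recipe.nyquist_cpd} c/deg at {recipe.deg_per_px} deg/px"
        )


def _integer_shifts(n_frames: int, px_per_frame: float) -> np.ndarray:
    """Accumulated-remainder integer displacement schedule (px per frame)."""
    return np.round(np.arange(n_frames) * px_per_frame).astype(int)


# ---------------------------------------------------------------------------
# recipes


def moving_bar(
    width_deg: float = 0.25,
    speed_deg_s: float = 2.0,
    polarity: str = "white",
    direction: int = 1,
    recipe: StimulusRecipe | None = None,
) -> StimulusSequence:
    """A vertical bar sweeping horizontally at constant speed (with wrap).

    ``polarity`` is ``'white'`` (bright bar on dark background) or
    ``'black'``; ``direction`` +1 moves rightward, -1 leftward.  The
    leftward sequence is the exact horizontal mirror of the rightward one.
    """
    if width_deg <= 0:
        raise InvalidParameterError(f"bar width must be positive, got {width_deg}")
    if polarity not in ("white", "black"):
        raise InvalidParameterError(f"polarity must be 'white' or 'black', got {polarity!r}")
    if direction not in (1, -1):
        raise InvalidParameterError(f"direction must be +1 or -1, got {direction}")
    recipe = recipe or StimulusRecipe(
        "moving_bar",
        dict(width_deg=width_deg, speed_deg_s=speed_deg_s, polarity=polarity,
             direction=direction),
    )
    w_px = recipe.size_px
    width_px = max(1, int(round(width_deg / recipe.deg_per_px)))
    base = np.zeros(w_px)
    base[:width_px] = 1.0
    shifts = _integer_shifts(recipe.n_frames, speed_deg_s / recipe.deg_per_px / recipe.fps)
    profile = np.stack([np.roll(base, s) for s in shifts])
    if direction == -1:
        profile = profile[:, ::-1]
    if polarity == "black":
        profile = 1.0 - profile
    return _seq_from_profile(profile, recipe)


def drifting_grating(
    contrast: float = 0.4,
    sf_cpd: float = 2.0,
    tf_hz: float = 4.0,
    phase: float = 0.0,
    direction: int = 1,
    recipe: StimulusRecipe | None = None,
) -> StimulusSequence:
    """A drifting sinusoidal luminance grating.

    L(x, t) = 0.5 (1 + C sin(2 pi (f_s x - direction f_t t) + phase)),
    mean luminance 0.5, Michelson contrast C.
    """
    if not 0 <= contrast <= 1:
        raise InvalidParameterError(f"contrast must lie in [0, 1], got {contrast}")
    recipe = recipe or StimulusRecipe(
        "drifting_grating",
        dict(contrast=contrast, sf_cpd=sf_cpd, tf_hz=tf_hz, phase=phase,
             direction=direction),
    )
    _check_sf(sf_cpd, recipe)
    x, t = _grid(recipe)
    arg = 2 * np.pi * (sf_cpd * x[None, :] - direction * tf_hz * t[:, None]) + phase
    profile = 0.5 * (1.0 + contrast * np.sin(arg))
    return _seq_from_profile(profile, recipe)


def masked_grating(
    noise_sf_cpd: float,
    noise_contrast: float = 0.4,
    jitter_hz: float = 10.0,
    seed=0,
    signal_sf_cpd: float = 2.5,
    signal_tf_hz: float = 10.0,
    signal_contrast: float = 0.4,
    signal_phase: float = 0.0,
    recipe: StimulusRecipe | None = None,
) -> StimulusSequence:
    """Signal grating plus a phase-jittering noise grating.

    The noise component is a sinusoidal grating whose only temporal
    behaviour is its jitter: the phase is resampled uniformly in
    [-pi, pi] every 1/jitter_hz seconds and held constant in between,
    so the noise carries no coherent motion.  Both modulations are
    summed around mean luminance 0.5; at the default contrasts
    (0.4 + 0.4) the sum never clips.
    """
    recipe = recipe or StimulusRecipe(
        "masked_grating",
        dict(noise_sf_cpd=noise_sf_cpd, noise_contrast=noise_contrast,
             jitter_hz=jitter_hz, seed=seed, signal_sf_cpd=signal_sf_cpd,
             signal_tf_hz=signal_tf_hz, signal_contrast=signal_contrast,
             signal_phase=signal_phase),
    )
    _check_sf(signal_sf_cpd, recipe)
    _check_sf(noise_sf_cpd, recipe)
    hold = recipe.fps / jitter_hz
    hold_frames = int(round(hold))
    if abs(hold - hold_frames) > 1e-9:
        warnings.warn(
            f"jitter frequency {jitter_hz} Hz does not divide the frame rate "
            f"{recipe.fps} Hz; holding each phase for {hold_frames} frames",
            stacklevel=2,
        )
    x, t = _grid(recipe)
    sig = signal_contrast * np.sin(
        2 * np.pi * (signal_sf_cpd * x[None, :] - signal_tf_hz * t[:, None])
        + signal_phase
    )
    rng = np.random.default_rng(seed)
    n_blocks = -(-recipe.n_frames // hold_frames)
    block_phases = rng.uniform(-np.pi, np.pi, size=n_blocks)
    theta = np.repeat(block_phases, hold_frames)[: recipe.n_frames]
    noise = noise_contrast * np.sin(
        2 * np.pi * noise_sf_cpd * x[None, :] + theta[:, None]
    )
    profile, frac = _clip_tracked(0.5 * (1.0 + sig + noise))
    return _seq_from_profile(profile, recipe, seed=seed, clipped_fraction=frac)


def random_pattern(
    reverse_phi: bool = False,
    contrast: float = 0.9,
    speed_deg_s: float = 8.5,
    element_px: int = 10,
    seed=0,
    recipe: StimulusRecipe | None = None,
) -> StimulusSequence:
    """A binary random vertical-strip pattern translating horizontally.

    Strips of ``element_px`` columns take one of two luminance values at
    the given Michelson contrast around mean 0.5.  The pattern wraps
    around.  With ``reverse_phi``, contrast polarity is inverted on every
    odd frame (I -> 1 - I), which reverses the perceived direction.
    """
    if element_px < 1:
        raise InvalidParameterError(f"element_px must be >= 1, got {element_px}")
    recipe = recipe or StimulusRecipe(
        "random_pattern",
        dict(reverse_phi=reverse_phi, contrast=contrast, speed_deg_s=speed_deg_s,
             element_px=element_px, seed=seed),
    )
    rng = np.random.default_rng(seed)
    n_elem = -(-recipe.size_px // element_px)
    bits = rng.integers(0, 2, size=n_elem)
    base = np.repeat(0.5 + contrast * (bits - 0.5), element_px)[: recipe.size_px]
    shifts = _integer_shifts(recipe.n_frames, speed_deg_s / recipe.deg_per_px / recipe.fps)
    profile = np.stack([np.roll(base, s) for s in shifts])
    if reverse_phi:
        odd = np.arange(recipe.n_frames) % 2 == 1
        profile[odd] = 1.0 - profile[odd]
    return _seq_from_profile(profile, recipe, seed=seed)


def _square_wave_modulation(theta: np.ndarray, n_harmonics_max: int,
                            missing_fundamental: bool) -> np.ndarray:
    """Fourier synthesis of a unit square wave; optionally drop harmonic 1."""
    out = np.zeros_like(theta)
    for k in range(1, n_harmonics_max + 1, 2):
        if missing_fundamental and k == 1:
            continue
        out += (4.0 / np.pi) * np.sin(k * theta) / k
    return out


def square_wave_sequence(
    missing_fundamental: bool = False,
    smooth: bool = False,
    contrast: float = 0.9,
    sf_cpd: float = 1.5,
    tf_hz: float = 4.0,
    jump_ms: float = 66.0,
    phase: float = 0.0,
    recipe: StimulusRecipe | None = None,
) -> StimulusSequence:
    """A square-wave grating moving rightward, optionally missing its fundamental.

    The wave is synthesized from its odd-harmonic Fourier series up to the
    spatial Nyquist limit; with ``missing_fundamental`` the first harmonic
    is omitted before synthesis.  Motion is either a quarter-period
    displacement every ``jump_ms`` (default; rounded to whole frames) or a
    continuous drift at ``tf_hz / sf_cpd`` deg/s when ``smooth`` is set.
    """
    recipe = recipe or StimulusRecipe(
        "square_wave",
        dict(missing_fundamental=missing_fundamental, smooth=smooth,
             contrast=contrast, sf_cpd=sf_cpd, tf_hz=tf_hz, jump_ms=jump_ms,
             phase=phase),
    )
    _check_sf(sf_cpd, recipe)
    x, t = _grid(recipe)
    if smooth:
        disp_deg = (tf_hz / sf_cpd) * t
    else:
        jump_frames = max(1, int(round(jump_ms * recipe.fps / 1000.0)))
        implied_tf = 1000.0 / (4.0 * jump_frames / recipe.fps * 1000.0)
        if abs(implied_tf - tf_hz) > 0.5:
            warnings.warn(
                f"{jump_ms} ms quarter-cycle jumps ({jump_frames} frames) imply a "
                f"temporal frequency of {implied_tf:.2f} Hz, not {tf_hz} Hz; "
                "using the jump schedule",
                stacklevel=2,
            )
        period_deg = 1.0 / sf_cpd
        disp_deg = (period_deg / 4.0) * (np.arange(recipe.n_frames) // jump_frames)
    # keep harmonics strictly below the spatial Nyquist frequency
    kmax = int(np.floor((recipe.nyquist_cpd - 1e-12) / sf_cpd))
    theta = 2 * np.pi * sf_cpd * (x[None, :] - disp_deg[:, None]) + phase
    mod = _square_wave_modulation(theta, kmax, missing_fundamental)
    profile, frac = _clip_tracked(0.5 + 0.5 * contrast * mod)
    return _seq_from_profile(profile, recipe, clipped_fraction=frac)


def contrast_modulated(
    direction: int = 1,
    env_sf_cpd: float = 1.0,
    env_tf_hz: float = 7.0,
    env_contrast: float = 0.8,
    carrier_sf_cpd: float = 4.0,
    depth: float = 0.3,
    seed=0,
    phase: float = 0.0,
    recipe: StimulusRecipe | None = None,
) -> StimulusSequence:
    """A second-order (contrast-defined) motion stimulus.

    A static sinusoidal carrier whose phase is resampled uniformly every
    frame (so luminance carries no net directional Fourier energy) is
    multiplied by a drifting contrast envelope:

        c(x, t) = depth (1 + env_contrast sin(2 pi (f_e x - dir f_t t) + phase))
        L(x, t) = 0.5 (1 + c(x, t) sin(2 pi f_c x + theta(t)))

    Only the envelope moves; the motion signal is contrast-defined.
    """
    if depth * (1.0 + env_contrast) > 1.0 + 1e-12:
        raise InvalidParameterError(
            f"local contrast depth*(1+env_contrast) = {depth * (1 + env_contrast)} "
            "exceeds 1; luminance would leave [0, 1]"
        )
    recipe = recipe or StimulusRecipe(
        "contrast_modulated",
        dict(direction=direction, env_sf_cpd=env_sf_cpd, env_tf_hz=env_tf_hz,
             env_contrast=env_contrast, carrier_sf_cpd=carrier_sf_cpd,
             depth=depth, seed=seed, phase=phase),
    )
    _check_sf(env_sf_cpd, recipe)
    _check_sf(carrier_sf_cpd, recipe)
    x, t = _grid(recipe)
    rng = np.random.default_rng(seed)
    theta = rng.uniform(-np.pi, np.pi, size=recipe.n_frames)
    env = depth * (
        1.0 + env_contrast * np.sin(
            2 * np.pi * (env_sf_cpd * x[None, :] - direction * env_tf_hz * t[:, None])
            + phase
        )
    )
    carrier = np.sin(2 * np.pi * carrier_sf_cpd * x[None, :] + theta[:, None])
    profile = 0.5 * (1.0 + env * carrier)
    return _seq_from_profile(profile, recipe, seed=seed)


def compound_grating(
    sf1_cpd: float,
    tf1_hz: float,
    sf2_cpd: float = 8.5,
    tf2_hz: float = 1.0,
    c_each: float | tuple = 0.4,
    phase1: float = 0.0,
    phase2: float = 0.0,
    recipe: StimulusRecipe | None = None,
) -> StimulusSequence:
    """The sum of two rightward-drifting sinusoidal modulations around 0.5.

    ``c_each`` is the Michelson contrast of both components, or a
    ``(c1, c2)`` pair for unequal contrasts.
    """
    c1, c2 = (c_each, c_each) if np.isscalar(c_each) else c_each
    if c1 + c2 > 1.0 + 1e-12:
        raise InvalidParameterError(
            f"summed modulation {c1} + {c2} exceeds 1; luminance would clip"
        )
    recipe = recipe or StimulusRecipe(
        "compound_grating",
        dict(sf1_cpd=sf1_cpd, tf1_hz=tf1_hz, sf2_cpd=sf2_cpd, tf2_hz=tf2_hz,
             c_each=c_each, phase1=phase1, phase2=phase2),
    )
    _check_sf(sf1_cpd, recipe)
    _check_sf(sf2_cpd, recipe)
    x, t = _grid(recipe)
    m1 = c1 * np.sin(2 * np.pi * (sf1_cpd * x[None, :] - tf1_hz * t[:, None]) + phase1)
    m2 = c2 * np.sin(2 * np.pi * (sf2_cpd * x[None, :] - tf2_hz * t[:, None]) + phase2)
    profile = 0.5 * (1.0 + m1 + m2)
    return _seq_from_profile(profile, recipe)


# ---------------------------------------------------------------------------
# pre-filters


def _clip_tracked(profile: np.ndarray) -> tuple:
    frac = float(np.mean((profile < 0) | (profile > 1)))
    if frac > 0.02:
        warnings.warn(f"{100 * frac:.2f}% of pixels clipped to [0, 1]", stacklevel=3)
    return np.clip(profile, 0.0, 1.0), frac


def apply_dog_lgn(
    seq: StimulusSequence,
    center_sigma_deg: float = 0.036,
    surround_sigma_deg: float = 0.18,
    balance: float = 5.0,
) -> StimulusSequence:
    """Center-surround (difference-of-Gaussians) pre-filter emulating the LGN.

    Each frame is convolved with a unit-integral center Gaussian minus a
    surround Gaussian whose integral is ``1/balance`` of the center's.
    The output is a neural signal, not luminance, and is not clipped; a
    uniform input of value c maps to c (1 - 1/balance).
    """
    sc = center_sigma_deg / seq.deg_per_px
    ss = surround_sigma_deg / seq.deg_per_px
    meta = {**seq.meta, "signal_domain": "neural",
            "dog": dict(center_sigma_deg=center_sigma_deg,
                        surround_sigma_deg=surround_sigma_deg, balance=balance)}
    if seq.is_x_only():
        # vertically constant frames: the vertical pass of the separable
        # Gaussian is the identity, so filter the (T, W) profile directly
        prof = seq.profile()
        out = (gaussian_filter1d(prof, sc, axis=1, mode="reflect")
               - gaussian_filter1d(prof, ss, axis=1, mode="reflect") / balance)
        return StimulusSequence(_broadcast(out, seq.frames.shape[1]),
                                seq.fps, seq.deg_per_px, meta)
    out = np.empty_like(seq.frames)
    for i, frame in enumerate(seq.frames):
        out[i] = (gaussian_filter(frame, sc, mode="reflect")
                  - gaussian_filter(frame, ss, mode="reflect") / balance)
    return StimulusSequence(out, seq.fps, seq.deg_per_px, meta)


def apply_optical_blur(seq: StimulusSequence, psf_sigma_deg: float = 0.01) -> StimulusSequence:
    """Optional generic Gaussian pre-blur standing in for the eye's optics.

    Off by default in all experiments; sigma = 0 returns the input unchanged.
    """
    if psf_sigma_deg < 0:
        raise InvalidParameterError("psf sigma must be >= 0")
    if psf_sigma_deg == 0:
        return seq
    s = psf_sigma_deg / seq.deg_per_px
    meta = {**seq.meta, "optical_blur_sigma_deg": psf_sigma_deg}
    if seq.is_x_only():
        out = gaussian_filter1d(seq.profile(), s, axis=1, mode="reflect")
        return StimulusSequence(_broadcast(out, seq.frames.shape[1]),
                                seq.fps, seq.deg_per_px, meta)
    out = np.empty_like(seq.frames)
    for i, frame in enumerate(seq.frames):
        out[i] = gaussian_filter(frame, s, mode="reflect")
    return StimulusSequence(out, seq.fps, seq.deg_per_px, meta)
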