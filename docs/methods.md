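# Methods

## The model

`msinrf` implements a single-stage motion sensor built on an
intrinsically nonlinear receptive field.  The spatial stage at sensor
location $s_i$ is

$$\mathrm{INRF}(s_i) = \sum_j m_j\, I(s_j) \;-\; \lambda \sum_j w_j\,
\sigma\big(I(s_j) - I(s_i)\big),$$

a linear branch (isotropic Gaussian $m$, "passive dendrites") plus a
nonlinear branch in which the saturating even function $\sigma$ is
applied to luminance differences *relative to the sensor's own current
input* — an input-dependent dendritic nonlinearity — and then pooled by
a vertically oriented, horizontally odd Gabor $w$.  The spatio-temporal
sensor convolves each branch with its own temporal filter over delays
$u$:

$$\mathrm{stINRF}(s_i,t) = \sum_u T_m(u) \sum_j m_j I(s_j, t-u)
\;-\; \lambda \sum_u T_w(u) \sum_j w_j\,
\sigma\big(I(s_j, t-u) - I(s_i, t)\big),$$

where the shift inside $\sigma$ is the **current** value $I(s_i,t)$ for
every delay.  The motion readout MS-INRF is the time average of the
stINRF trace; by this package's sign convention rightward motion gives
positive values.

Because $\sigma$ is even, the nonlinear branch is exactly invariant
under luminance inversion $I \to 1-I$ (contrast-polarity invariance),
and because $w$ is horizontally odd, mirroring the stimulus and the
sensor location exactly negates it (motion opponency).  Both identities
are asserted to machine precision in the test suite.

## Parameters

All defaults live in `ModelParams` and are used unchanged in every
experiment; nothing is fitted.

| parameter | default | units | role |
|---|---|---|---|
| `k` | 0.4 | 1/ms | rate constant of $T_m$ |
| `n` | 5 | – | order of $T_m$'s gamma-like factor |
| `tm_duration_ms`, `tw_duration_ms` | 50 | ms | temporal support |
| `m_sigma_deg` | 0.031 | deg | Gaussian width of $m$ |
| `w_lobe_width_deg` | 0.125 | deg | lobe width of $w$ (carrier period 0.25 deg) |
| `lam` | −30 | – | weight of the nonlinear branch |
| `p` | 0.4 | – | exponent of $\sigma(z)=|z|^p/(|z|^p+q^p)$ |
| `q` | 0.1 | luminance | half-saturation of $\sigma$ |
| `fps` | 120 | Hz | frame rate and filter sampling rate |
| `deg_per_px` | 0.005 | deg/px | spatial calibration (400 px = 2 deg) |

$T_m(t) = (kt)^n e^{-kt}\left[\frac{1}{n!} - \frac{(kt)^2}{(n+2)!}\right]$
is biphasic (bandpass), crossing zero once near 16 ms;
$T_w(t) = \cos(\pi(t+10)/120)$ is non-negative on [0, 50] ms (lowpass).

## Numerical choices

- **Temporal sampling.**  Filters are sampled at the frame interval,
  $u = 0, 1000/\mathrm{fps}, \dots, 50$ ms (7 taps at 120 Hz).  The
  stimulus is defined frame-wise, so sub-frame quadrature would add
  nothing.  Taps are *not* normalized: the closed forms are absolute
  and $\lambda$ is calibrated against them.  A consequence worth
  knowing: $\sum_u T_m(u) \approx 7.3\times10^{-3} \neq 0$, so a blank
  field of luminance 0.5 evokes a small DC response
  $0.5\sum_u T_m(u) \approx 3.6\times10^{-3}$ — negligible next to
  grating responses of order $10^3$, but not exactly zero.
- **Gabor construction.**  Only the lobe width is prescribed, so the
  kernel's envelope is a design choice: sine-phase carrier of period
  2 × 0.125 deg, isotropic Gaussian envelope with
  $\sigma = $ period/4 = 0.0625 deg (which keeps any third lobe below
  5% of the main ones), truncated at ±3σ, then antisymmetrized about
  the vertical axis so zero mean and odd symmetry hold exactly in the
  stored grid.
- **Sign calibration.**  Which Gabor lobe is positive is not physically
  determined; the polarity constant is fixed once, such that the
  default sensor responds positively to a canonical rightward 2 c/deg,
  4 Hz grating.  All directional conventions follow from this single
  choice.
- **Gaussian kernel** truncated at ±3σ and renormalized to unit sum, so
  the linear branch is an unbiased local luminance estimate.
- **Boundary handling.**  Strictly causal in time (no padding before
  frame 0; the first 6 frames at 120 Hz lack full filter support, are
  flagged NaN, and are excluded from the readout mean).  Spatially the
  kernels are only evaluated where fully supported; the experiments
  read out the central pixel, so borders never matter.  Mirror padding
  is available for field computations.
- **Averaging window.**  The "recent past" of the readout is taken to
  be all frames with full temporal support (frames 6–119 at defaults).
  The stimuli are statistically stationary over the 1 s sequence, so
  any sufficiently long window converges to the same value; a narrower
  window can be passed explicitly.
- **Readout location.**  Figures-of-merit are single-sensor values at
  the central pixel; after phase averaging the stimuli are spatially
  homogeneous, so a pooled readout would give the same means.
  `stinrf_field` provides grid readouts when needed.
- **Fast path.**  Every built-in stimulus varies only horizontally, so
  frames are broadcast from a (time, width) profile and the kernels are
  collapsed to their column sums; this is an exact algebraic identity,
  verified against the full 2-D path and against a literal nested-loop
  brute-force implementation (`stinrf_bruteforce`) to 1e−10 relative.
  There is no transform-based shortcut for the nonlinear branch: the
  shift $I(s_i,t)$ makes it non-convolutional by construction.
- Double precision throughout.

## Stimuli

All stimuli are 120 frames of 400 × 400 px (2 deg) at 120 Hz, luminance
in [0, 1], mean 0.5 for the grating family:

- **moving_bar** — 0.25 deg bar at 2 deg/s, white-on-black or inverted;
  leftward sequences are exact mirrors of rightward ones.  Binary
  patterns move by rounded-cumulative integer pixel shifts
  (accumulated-remainder schedule) to avoid interpolation artifacts;
  sinusoids instead carry exact analytic phase.
- **drifting_grating** — $0.5(1 + C\sin(2\pi(f_s x - d\, f_t t)+\varphi))$.
- **masked_grating** — signal (2.5 c/deg, 10 Hz, contrast 0.4) plus a
  noise grating of contrast 0.4 whose phase is resampled uniformly
  every 100 ms and held in between.  The noise's 10 Hz "movement" is
  exactly this jitter; adding a coherent 10 Hz drift to the noise would
  make matched-frequency noise cohere with the signal (their sum is a
  single grating per jitter block) and *enhance* rather than mask it.
  At 0.4 + 0.4 the sum never leaves [0, 1].
- **random_pattern** — binary vertical strips (0.05 deg elements,
  contrast 0.9) translating at 8.5 deg/s with wraparound; reverse-phi
  inverts luminance on every odd frame.  Strip width and the strip
  geometry itself are design choices (only "random patterns" is
  prescribed); vertical strips make the motion strictly horizontal,
  matching the sensor's orientation.
- **square_wave_sequence** — Fourier synthesis from odd harmonics up to
  the spatial Nyquist limit (contrast 0.9, 1.5 c/deg); the
  missing-fundamental variant omits harmonic 1 before synthesis.
  Motion is a quarter-period jump every 66 ms (8 frames at 120 Hz) or a
  smooth drift.  Gibbs overshoot at contrast 0.9 clips ≈1.7% of pixels;
  the clipped fraction is recorded in the sequence metadata.
- **contrast_modulated** — second-order motion: a carrier (4 c/deg)
  whose phase is resampled every frame, multiplied by a drifting
  contrast envelope (1 c/deg, 7 Hz, envelope contrast 0.8, mean depth
  0.3), i.e. local contrast $0.3(1 + 0.8\sin(\cdot)) \in [0.06, 0.54]$.
  The per-frame phase scramble removes net directional Fourier energy
  from luminance (asserted spectrally in the tests): only the contrast
  envelope moves.
- **compound_grating** — sum of two rightward sinusoidal modulations
  (0.4 each) around mean 0.5.
- **apply_dog_lgn** — per-frame difference-of-Gaussians (center
  σ = 0.036 deg, unit integral; surround σ = 0.18 deg, integral 1/5 of
  the center's, reading the balance factor 5 as the center/surround
  integral ratio).  Output is a neural signal and is not clipped.
- **apply_optical_blur** — optional generic Gaussian point-spread
  stand-in for ocular optics; **off by default** and unused by the
  experiments.

Every recipe is bit-reproducible from its parameters and seed.

## Experiments and their grids

Phase averaging uses equally spaced starting phases covering
$[-\pi,\pi)$ (duplicating $-\pi$ and $\pi$ would double-count one
phase).  Dispersion is reported as the standard deviation over
phases/seeds.

- first order: 4 bar conditions, no averaging needed (deterministic);
- contrast: 20 contrasts × 10 phases printed; the shipped checks use
  10 × 4, which preserves the monotone, compressive shape;
- masking: 20 noise frequencies × 10 phases printed; shipped checks use
  10 × 6, with and without the LGN stage;
- reverse-phi: 10 random patterns;
- missing fundamental: 10 phases, jump and smooth modes;
- second order: 10 envelope phases per direction, plus a zero-envelope
  control (10 seeds) as the noise floor;
- nonlinearity maps: printed grids are 100 × 100 frequencies × 10
  phases (100 phase pairs for compounds); the package defaults to a
  desk-scale 20 × 20 × 4 (16 pairs), which preserves every sign-based
  conclusion; the full grid is a configuration switch (`--scale full`).

The λ = 0 surrogate used in the nonlinearity check is *affine*, not
linear, in luminance: both components share the mean-0.5 background, so
exact superposition reads
$R(X{+}G) - R(X) - R(G) + R_0 = 0$, with $R_0$ the blank-field response
(the DC remnant noted above).  The package asserts this affine identity
to machine precision.

## What the synthetic stimuli do and do not show

The generators emulate the study's calibrated laboratory stimuli —
deterministic gratings, bars and binary patterns with exact contrast,
frequency and phase control — not natural input: there is no vertical
structure, no luminance drift, no sensor noise, no gamma or display
model, and the optical point-spread of a real eye is at best a generic
Gaussian stand-in.  Passing tests therefore demonstrate the model's
qualitative phenomenology under clean conditions (signs, monotonicity,
tuning shapes), not quantitative neural or psychophysical predictions.

## Known limitations

- Masking tuning without the LGN stage is broadband: because
  $\sigma$ has unbounded slope at 0 and saturates by $|z|\approx0.4$,
  noise of *any* high spatial frequency inside the Gabor window drives
  the branch into saturation, so the bare sensor's suppression deepens
  with noise frequency and plateaus instead of peaking at the signal's
  frequency.  The frequency-matched dip emerges once the DoG LGN stage
  attenuates high frequencies (suppression then peaks one grid step
  from the signal frequency, with >85% recovery at remote
  frequencies).  A modest optical pre-blur (σ ≈ 0.03 deg) restores a
  matched dip without the LGN stage, but the package deliberately keeps
  the pre-blur off by default.
- Single orientation, single sensor: no multi-orientation bank, no 2-D
  motion integration, no spiking dynamics.
- The nonlinear branch's cost is inherently per-location (the
  $\sigma$-shift depends on $s_i$); full-field maps are loops over
  sensors.
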