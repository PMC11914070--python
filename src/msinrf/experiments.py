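"""Scripted, seeded experiments for the six motion phenomena.

Each experiment builds its stimuli from the study recipes, evaluates
the MS-INRF readout at the central sensor, and averages over equally
spaced starting phases (periodic stimuli) or random generations
(stochastic stimuli).  Results are returned as
:class:`ExperimentResult` records that fully describe how to regenerate
them (grids, seeds, model parameters).

The phenomena:

* first-order motion (moving bars): opponent signs, contrast-polarity
  invariance;
* contrast saturation: response magnitude grows but compresses at high
  contrast;
* motion masking: a phase-jittering noise grating suppresses the signal
  response most when its spatial frequency matches the signal's;
* reverse-phi: frame-wise polarity inversion flips the response sign;
* missing fundamental: removing the fundamental of a quarter-cycle
  stepping square wave flips the response sign (smooth motion does not);
* nonlinearity maps: a grating G that alone evokes a negligible response
  still reshapes the response map when added to other gratings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import stimuli
from .errors import InvalidParameterError
from .model import ms_inrf
from .params import ModelParams

__all__ = [
    "ExperimentResult",
    "run_first_order",
    "contrast_response_curve",
    "masking_curve",
    "reverse_phi_experiment",
    "missing_fundamental_experiment",
    "second_order_experiment",
    "nonlinearity_maps",
    "superposition_residual",
    "run_experiment",
    "EXPERIMENTS",
]


@dataclass(frozen=True)
class ExperimentResult:
    """Phase/seed-averaged MS-INRF responses over an independent-variable grid.

    ``variable_grid`` names the independent variable(s); ``responses``
    holds the mean response per grid point (congruent with the grid) and
    ``dispersion`` the standard deviation over phases/seeds.  ``config``
    records everything needed to regenerate the result bit-identically;
    ``extras`` carries experiment-specific side quantities (e.g. the
    unmasked reference response).
    """

    name: str
    variable_grid: dict
    responses: np.ndarray
    dispersion: np.ndarray
    config: dict
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        r = np.asarray(self.responses, dtype=float)
        d = np.asarray(self.dispersion, dtype=float)
        object.__setattr__(self, "responses", r)
        object.__setattr__(self, "dispersion", d)
        if r.shape != d.shape:
            raise InvalidParameterError("responses and dispersion shapes differ")
        n = next(len(v) for v in self.variable_grid.values())
        if r.shape[0] != n:
            raise InvalidParameterError(
                f"responses ({r.shape[0]}) not congruent with variable grid ({n})"
            )


def phase_grid(n: int) -> np.ndarray:
    """n equally spaced starting phases covering [-pi, pi)."""
    return -np.pi + 2.0 * np.pi * np.arange(n) / n


def _mean_std(values) -> tuple:
    v = np.asarray(values, dtype=float)
    return float(v.mean()), float(v.std())


def run_first_order(params: ModelParams | None = None) -> ExperimentResult:
    """Moving-bar responses for {white, black} x {rightward, leftward}.

    Expected pattern: signs (+, +, -, -) and near-identical magnitudes
    across contrast polarity.
    """
    params = params or ModelParams()
    conditions = [("white", 1), ("black", 1), ("white", -1), ("black", -1)]
    responses = []
    for polarity, direction in conditions:
        seq = stimuli.moving_bar(polarity=polarity, direction=direction)
        responses.append(ms_inrf(seq, params).value)
    labels = [f"{p}_{'right' if d == 1 else 'left'}" for p, d in conditions]
    return ExperimentResult(
        "first_order",
        {"condition": labels},
        responses,
        np.zeros(len(responses)),
        {"model": params.to_dict(), "conditions": conditions},
    )


def contrast_response_curve(
    n_contrasts: int = 20,
    n_phases: int = 10,
    sf_cpd: float = 2.0,
    tf_hz: float = 4.0,
    params: ModelParams | None = None,
) -> ExperimentResult:
    """Phase-averaged response to a rightward grating vs Michelson contrast.

    The magnitude grows monotonically with contrast but saturates: the
    log-log slope over the top quartile of contrasts is below the
    bottom-quartile slope.
    """
    params = params or ModelParams()
    contrasts = np.linspace(0.0, 1.0, n_contrasts)
    phases = phase_grid(n_phases)
    means, stds = [], []
    for c in contrasts:
        vals = [
            ms_inrf(stimuli.drifting_grating(c, sf_cpd, tf_hz, phase=ph), params).value
            for ph in phases
        ]
        mu, sd = _mean_std(vals)
        means.append(mu)
        stds.append(sd)
    return ExperimentResult(
        "contrast_response",
        {"contrast": contrasts},
        means,
        stds,
        {"model": params.to_dict(), "sf_cpd": sf_cpd, "tf_hz": tf_hz,
         "n_phases": n_phases},
    )


def masking_curve(
    lgn: bool = False,
    n_noise_sf: int = 20,
    n_phases: int = 10,
    seed: int = 0,
    noise_sf_max: float = 10.0,
    params: ModelParams | None = None,
) -> ExperimentResult:
    """Signal response vs the spatial frequency of a jittering noise mask.

    The signal (2.5 c/deg, 10 Hz, contrast 0.4) is presented alone and
    summed with a phase-jittering noise grating whose spatial frequency
    sweeps [0, noise_sf_max] c/deg.  With ``lgn`` the stimulus first
    passes through the DoG center-surround filter.  ``extras`` holds the
    unmasked reference response and the normalized reciprocal
    (sensitivity-style) curve.
    """
    params = params or ModelParams()
    noise_sfs = np.linspace(0.0, noise_sf_max, n_noise_sf)
    phases = phase_grid(n_phases)

    def respond(seq):
        if lgn:
            seq = stimuli.apply_dog_lgn(seq)
        return ms_inrf(seq, params).value

    unmasked = [
        respond(stimuli.drifting_grating(0.4, 2.5, 10.0, phase=ph)) for ph in phases
    ]
    unmasked_mean, unmasked_std = _mean_std(unmasked)
    means, stds = [], []
    for i, nsf in enumerate(noise_sfs):
        vals = [
            respond(
                stimuli.masked_grating(nsf, seed=[seed, i, j], signal_phase=ph)
            )
            for j, ph in enumerate(phases)
        ]
        mu, sd = _mean_std(vals)
        means.append(mu)
        stds.append(sd)
    reciprocal = 1.0 / np.maximum(np.abs(np.asarray(means)), 1e-12)
    reciprocal /= reciprocal.max()
    return ExperimentResult(
        "masking",
        {"noise_sf_cpd": noise_sfs},
        means,
        stds,
        {"model": params.to_dict(), "lgn": lgn, "seed": seed,
         "n_phases": n_phases, "signal": dict(contrast=0.4, sf_cpd=2.5, tf_hz=10.0)},
        extras={
            "unmasked_response": unmasked_mean,
            "unmasked_dispersion": unmasked_std,
            "reciprocal_normalized": reciprocal,
        },
    )


def reverse_phi_experiment(
    n_seeds: int = 10, seed: int = 0, params: ModelParams | None = None
) -> ExperimentResult:
    """Phi vs reverse-phi responses, averaged across random patterns.

    Expected: phi positive (veridical rightward), reverse-phi negative
    (perceived reversal).
    """
    params = params or ModelParams()
    seeds = [[seed, k] for k in range(n_seeds)]
    means, stds = [], []
    for rp in (False, True):
        vals = [
            ms_inrf(stimuli.random_pattern(reverse_phi=rp, seed=s), params).value
            for s in seeds
        ]
        mu, sd = _mean_std(vals)
        means.append(mu)
        stds.append(sd)
    return ExperimentResult(
        "reverse_phi",
        {"condition": ["phi", "reverse_phi"]},
        means,
        stds,
        {"model": params.to_dict(), "seed": seed, "n_seeds": n_seeds},
    )


def missing_fundamental_experiment(
    smooth: bool = False, n_phases: int = 10, params: ModelParams | None = None
) -> ExperimentResult:
    """Square-wave vs missing-fundamental responses (jump or smooth motion).

    With quarter-cycle jumps the missing-fundamental response flips sign
    (the illusion); with smooth motion both conditions share the
    square wave's sign (the illusion is lost).
    """
    params = params or ModelParams()
    phases = phase_grid(n_phases)
    means, stds = [], []
    for mf in (False, True):
        vals = [
            ms_inrf(
                stimuli.square_wave_sequence(
                    missing_fundamental=mf, smooth=smooth, phase=ph
                ),
                params,
            ).value
            for ph in phases
        ]
        mu, sd = _mean_std(vals)
        means.append(mu)
        stds.append(sd)
    return ExperimentResult(
        "missing_fundamental",
        {"condition": ["square_wave", "missing_fundamental"]},
        means,
        stds,
        {"model": params.to_dict(), "smooth": smooth, "n_phases": n_phases},
    )


def second_order_experiment(
    n_phases: int = 10,
    seed: int = 0,
    n_control_seeds: int = 10,
    params: ModelParams | None = None,
) -> ExperimentResult:
    """Contrast-modulated (second-order) motion: response follows the envelope.

    Responses to rightward and leftward envelope drift, phase-averaged
    with a fresh carrier jitter per presentation.  ``extras`` holds a
    zero-envelope control (static contrast, jittered carrier) whose mean
    should be indistinguishable from zero given its dispersion.
    """
    params = params or ModelParams()
    phases = phase_grid(n_phases)
    means, stds = [], []
    for direction in (1, -1):
        vals = [
            ms_inrf(
                stimuli.contrast_modulated(
                    direction=direction, seed=[seed, direction % 3, j], phase=ph
                ),
                params,
            ).value
            for j, ph in enumerate(phases)
        ]
        mu, sd = _mean_std(vals)
        means.append(mu)
        stds.append(sd)
    control = [
        ms_inrf(
            stimuli.contrast_modulated(env_contrast=0.0, seed=[seed, 7, k]), params
        ).value
        for k in range(n_control_seeds)
    ]
    c_mu, c_sd = _mean_std(control)
    return ExperimentResult(
        "second_order",
        {"condition": ["right", "left"]},
        means,
        stds,
        {"model": params.to_dict(), "seed": seed, "n_phases": n_phases,
         "n_control_seeds": n_control_seeds},
        extras={"control_mean": c_mu, "control_std": c_sd,
                "control_n": n_control_seeds},
    )


def nonlinearity_maps(
    n_sf: int = 20,
    n_tf: int = 20,
    n_phases: int = 4,
    sf_max: float = 10.0,
    tf_max: float = 30.0,
    g_sf: float = 8.5,
    g_tf: float = 1.0,
    c_each: float = 0.4,
    params: ModelParams | None = None,
) -> tuple:
    """Single-grating and compound (plus G) response maps over (sf, tf).

    Map A: phase-averaged responses to a single rightward grating over
    the frequency grid.  Map B: responses to that grating plus the fixed
    component G = (8.5 c/deg, 1 Hz), averaged over all phase pairs.
    G alone evokes a negligible response, yet B differs from A — the
    model has no linear spatio-temporal tuning.

    Returns ``(single, compound)`` ExperimentResults; the compound's
    ``extras`` holds the response to G alone and the violation statistic.
    """
    params = params or ModelParams()
    sfs = np.linspace(0.0, sf_max, n_sf)
    tfs = np.linspace(0.0, tf_max, n_tf)
    phases = phase_grid(n_phases)
    grid = {"sf_cpd": sfs, "tf_hz": tfs}
    config = {"model": params.to_dict(), "n_phases": n_phases, "c_each": c_each,
              "g_sf": g_sf, "g_tf": g_tf}

    g_vals = [
        ms_inrf(stimuli.drifting_grating(c_each, g_sf, g_tf, phase=ph), params).value
        for ph in phases
    ]
    g_mean, g_std = _mean_std(g_vals)

    map_a = np.empty((n_sf, n_tf))
    disp_a = np.empty((n_sf, n_tf))
    map_b = np.empty((n_sf, n_tf))
    disp_b = np.empty((n_sf, n_tf))
    for i, sf in enumerate(sfs):
        for j, tf in enumerate(tfs):
            vals = [
                ms_inrf(stimuli.drifting_grating(c_each, sf, tf, phase=ph), params).value
                for ph in phases
            ]
            map_a[i, j], disp_a[i, j] = _mean_std(vals)
            vals = [
                ms_inrf(
                    stimuli.compound_grating(sf, tf, g_sf, g_tf, c_each,
                                             phase1=p1, phase2=p2),
                    params,
                ).value
                for p1 in phases
                for p2 in phases
            ]
            map_b[i, j], disp_b[i, j] = _mean_std(vals)

    a_max = float(np.abs(map_a).max())
    violation = float(np.abs(map_b - map_a).max())
    single = ExperimentResult(
        "nonlinearity_single", grid, map_a, disp_a, config,
        extras={"g_response": g_mean, "g_dispersion": g_std},
    )
    compound = ExperimentResult(
        "nonlinearity_compound", grid, map_b, disp_b, config,
        extras={"g_response": g_mean, "g_dispersion": g_std,
                "map_a_max": a_max, "violation_max": violation},
    )
    return single, compound


def superposition_residual(
    n_sf: int = 10,
    n_tf: int = 10,
    n_phases: int = 2,
    sf_max: float = 10.0,
    tf_max: float = 30.0,
    g_sf: float = 8.5,
    g_tf: float = 1.0,
    c_each: float = 0.4,
    params: ModelParams | None = None,
) -> float:
    """Max affine-superposition residual of the lam=0 (linear) surrogate.

    With the nonlinear branch removed the model is affine in luminance,
    so for every grating X:  resp(X + G) - resp(X) - resp(G) + resp(blank)
    must vanish (the blank mean-0.5 field is shared by both components).
    Returns the maximum absolute residual over the grid; for the true
    model this quantity is large.
    """
    params = (params or ModelParams()).evolve(lam=0.0)
    sfs = np.linspace(0.0, sf_max, n_sf)
    tfs = np.linspace(0.0, tf_max, n_tf)
    phases = phase_grid(n_phases)
    blank = ms_inrf(stimuli.drifting_grating(0.0, 0.0, 0.0), params).value
    worst = 0.0
    for sf in sfs:
        for tf in tfs:
            for p1 in phases:
                for p2 in phases:
                    b = ms_inrf(
                        stimuli.compound_grating(sf, tf, g_sf, g_tf, c_each,
                                                 phase1=p1, phase2=p2),
                        params,
                    ).value
                    a = ms_inrf(
                        stimuli.drifting_grating(c_each, sf, tf, phase=p1), params
                    ).value
                    g = ms_inrf(
                        stimuli.drifting_grating(c_each, g_sf, g_tf, phase=p2), params
                    ).value
                    worst = max(worst, abs(b - a - g + blank))
    return worst


EXPERIMENTS = {
    "first_order": run_first_order,
    "contrast_response": contrast_response_curve,
    "masking": masking_curve,
    "reverse_phi": reverse_phi_experiment,
    "missing_fundamental": missing_fundamental_experiment,
    "second_order": second_order_experiment,
    "nonlinearity_maps": nonlinearity_maps,
}


def run_experiment(name: str, **kwargs):
    """Dispatch an experiment by name (see :data:`EXPERIMENTS`)."""
    if name not in EXPERIMENTS:
        raise InvalidParameterError(
            f"unknown experiment {name!r}; choose from {sorted(EXPERIMENTS)}"
        )
    return EXPERIMENTS[name](**kwargs)
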