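# msinrf

A motion sensor model for computational visual neuroscience, built on a
spatio-temporal **intrinsically nonlinear receptive field** with
input-dependent dendritic nonlinearities — plus the full synthetic
stimulus suite (bars, gratings, masking noise, reverse-phi patterns,
missing-fundamental square waves, contrast-modulated carriers) and the
scripted experiments that probe it.

Classical motion models (Reichardt correlators, the motion energy
model) are linear-filter cascades with output nonlinearities; they need
extra stages to explain contrast saturation or second-order
(contrast-defined) motion.  The sensor implemented here is a single
stage.  Its spatial core is

```
INRF(s_i) = Σ_j m_j I(s_j)  −  λ Σ_j w_j σ( I(s_j) − I(s_i) )
```

a linear branch (Gaussian kernel *m*) plus a "dendritic" branch where
the even saturating nonlinearity σ(z) = |z|^p / (|z|^p + q^p) acts on
luminance differences relative to the sensor's own current input,
pooled by a horizontally odd Gabor *w*.  The spatio-temporal sensor
convolves the branches with a bandpass filter T_m and a lowpass filter
T_w over delays u:

```
stINRF(s_i,t) = Σ_u T_m(u) Σ_j m_j I(s_j,t−u)
                − λ Σ_u T_w(u) Σ_j w_j σ( I(s_j,t−u) − I(s_i,t) )
MS-INRF(s_i,t) = mean_u stINRF(s_i,t−u)
```

With one fixed parameter set (k = 0.4/ms, n = 5, λ = −30, p = 0.4,
q = 0.1, σ_m = 0.031 deg, Gabor lobe width 0.125 deg, 50 ms temporal
support) the time-averaged readout is signed by motion direction
(rightward positive) and reproduces, qualitatively: first-order motion
detection invariant to contrast polarity, contrast saturation, motion
masking by frequency-matched jittering noise, reverse-phi reversal, the
missing-fundamental illusion, second-order motion detection, and a
strongly non-linear (sf, tf) response map.  See `docs/methods.md` for
the model's assumptions, numerical choices and limitations.

## Worked example

```python
>>> import msinrf
>>> seq = msinrf.drifting_grating(contrast=0.4, sf_cpd=2.0, tf_hz=4.0)
>>> seq.shape                      # 1 s at 120 Hz, 400 px = 2 deg
(120, 400, 400)
>>> msinrf.ms_inrf(seq).value      # rightward drift: positive response
3423.4266289851844
>>> msinrf.ms_inrf(msinrf.drifting_grating(0.4, 2.0, 4.0, direction=-1)).value
-3423.4341313983846
```

The sign encodes direction; the near-exact antisymmetry is the sensor's
motion opponency.  The same readout flips for a polarity-inverting
pattern (reverse-phi), here averaged over 10 random patterns:

```python
>>> r = msinrf.reverse_phi_experiment(n_seeds=10)
>>> dict(zip(r.variable_grid["condition"], r.responses.round(1)))
{'phi': 1484.7, 'reverse_phi': -1003.1}
```

The phi pattern genuinely moves rightward (positive); inverting its
contrast every frame makes the sensor — like a human observer — report
leftward motion (negative), even though the pattern still moves right.

From the shell, the same pipeline:

```sh
msinrf generate-stimulus random_pattern -o phi.npy --seed 3 --xt-png phi.png
msinrf run-model phi.npy
msinrf run-experiment reverse_phi -o results/
```

`run-experiment` writes a CSV (grid, mean, dispersion), a JSON sidecar
with the full seeded configuration, a PNG figure, and the exact config
that reproduces the run bit-identically.

## Layout

- `src/msinrf/filters.py` — temporal filters T_m, T_w; kernels m, w; σ
- `src/msinrf/model.py` — INRF / stINRF / MS-INRF, brute-force oracle
- `src/msinrf/stimuli.py` — all stimulus recipes and pre-filters
- `src/msinrf/experiments.py` — the six phenomena as seeded experiments
- `src/msinrf/config.py`, `cli.py`, `io.py`, `plotting.py` — YAML
  configuration, command line, CSV/JSON/NPY/TIFF round-trips, figures
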