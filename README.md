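# tiltframe

Analysis of how neural units encode self-generated head movements, from
head-mounted inertial sensor recordings:

- **Gravity decomposition** — complementary quaternion orientation filter
  splitting accelerometer signals into gravitational (head tilt) and
  non-gravitational components, with earth-frame re-expression and
  kinematic derivatives.
- **Model-free rate estimation** — jackknife resampling prediction of
  firing rate from nearest neighbors in inertial parameter space, with
  predictability R², independent-estimate robustness checks, shuffle
  nulls, and Ω/A^G selectivity classification.
- **Rotational tuning** — lag-dependent 3D sensitivity vectors,
  gain-vs-lag curves with shuffle significance, inertio-temporal
  receptive fields.
- **Tilt analysis** — spherical tilt rate maps (Fibonacci grid, angular
  caps), Lambert azimuthal equal-area projection, tilt-stability index σ.
- **Reference frames** — tilt-binned sensitivity fields in head-bound vs
  earth-bound coordinates, collinearity profiles, ΔS classification of
  units as internally or externally referenced.
- **Model comparison** — global and tilt-local linear models benchmarked
  against the model-free estimator, paired Wilcoxon summaries.
- **Synthetic data** — session generator with exact ground-truth
  orientation and planted tuning models (head-frame, earth-frame, tilt,
  gravity-gated, untuned) spiking through time-rescaled gamma renewal, so
  every stage is testable without recorded data.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (orientation
accuracy, brute-force estimator oracle, planted-parameter recovery,
reference-frame classification, etc.); the rest are per-module unit and
property tests.

## CLI

```sh
# generate a synthetic session (kinematics TSV, spike files, manifest YAML)
tiltframe simulate --duration 600 --seed 1 --out session/

# run the full analysis -> per-unit report.json
tiltframe run session/session.yaml --out results/ --seed 1

# orientation + gravity decomposition only -> HDF5
tiltframe preprocess session/session.yaml --out orient.h5

# per-unit summary table from a report
tiltframe summary results/report.json
```

`tiltframe run` accepts `--config config.yaml` overriding any
`AnalysisConfig` field (neighbor target, exclusion window, lag grid,
sphere grid size, shuffle counts, seeds, …); the merged config is embedded
in every report.

## Library example

```python
from tiltframe import (
    SimulationConfig, TuningSpec, simulate_head_kinematics, simulate_unit,
    estimate_orientation, instantaneous_rate, predictability_table,
)

kin, truth = simulate_head_kinematics(SimulationConfig(duration=600, seed=1))
orient = estimate_orientation(kin)
spec = TuningSpec(kind="rotation_head_frame", baseline_rate=45, gain=0.5,
                  preferred_axis=(0, 0, 1), isi_cv=0.5)
spikes = simulate_unit(kin, truth, spec, seed=2)
fr = instantaneous_rate(spikes, kin.t)
table = predictability_table(fr, kin.t, kin, orient, sets=("omega", "ag"))
```
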