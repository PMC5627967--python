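# fabricsense

Wearable motion sensors sewn into loose clothing suffer from motion
artefacts — the fabric moves relative to the body — and the usual response
is to engineer those artefacts away. `fabricsense` studies the opposite
idea in a controlled, fully simulated setting: the fabric's own dynamics
can act as a *mechanical feature map* that makes similar motions easier to
tell apart.

The package simulates a bench rig — a weighted 57 cm compound pendulum with
an 18 cm fabric strip at its tip, instrumented with single-axis virtual
accelerometers at 57 cm (rigid tip, `R1`), 66 cm (fabric middle, `F2`) and
75 cm (fabric tip, `F3`), sampled at 600 Hz for 10 s per release — and asks
whether a pendulum weighted with 3 N at the tip can be distinguished from
an unweighted one, from each sensor.

## Model and analyses

- **Dynamics** (`fabricsense.dynamics`): compound-pendulum ODE (adaptive
  RK, rtol 1e-8) driving a serial-link fabric chain (torsional joint
  springs/dampers, quadratic aerodynamic drag, sensor-board point masses)
  with one-way coupling; virtual accelerometers measure tangential specific
  force with Gaussian noise and 16-bit quantization over ±3 g.
- **Similarity** (`fabricsense.similarity`): a motion class is the cluster
  matrix Ψ ∈ R^(P×M) of stacked trials and its column mean ψ; similarity is
  the Euclidean distance s = ‖ψ − φ′‖, min–max normalised over the scored
  collection; group contrasts are tested with one-way ANOVA
  (F = MS_between / MS_within).
- **Classification** (`fabricsense.classify`): signals are cut into
  n-sample windows at stride n/2; per window index a fresh SVM (linear or
  Gaussian kernel, hyperparameters by 5-fold CV) is trained on the raw
  window samples and evaluated by paired leave-one-out over all trials.
- **Experiments** (`fabricsense.experiments`, CLI `fabricsense`): seeded
  end-to-end scenarios — rigid vs fabric, 0.5–3 N weight sweep, material
  sweep (denim/jersey/roma), window-size sweep, fixed 250 ms online run.

## Worked example

```python
import numpy as np
from fabricsense import (ApparatusConfig, generate_dataset,
                         class_separation_report)
from fabricsense.classify import WindowSpec, online_run

# 10 weighted + 10 unweighted releases of the jersey-tipped pendulum
ds = generate_dataset(ApparatusConfig(), trials_per_condition=10,
                      conditions=(0.0, 3.0), master_seed=42)

rep = class_separation_report(ds, ["R1", "F2", "F3"])
print(rep.summary[["sensor", "separation", "p"]].to_string(index=False))

for sensor in ("R1", "F2", "F3"):
    res = online_run(ds, sensor, WindowSpec(150), seed=0)  # 250 ms windows
    print(f"{sensor}: {100 * res.mean_accuracy:.1f} "
          f"± {100 * res.sd_accuracy:.1f}%")
```

prints

```
sensor  separation        p
    R1   -0.040002 0.519854
    F2    0.435868 0.000011
    F3    0.442083 0.000009
R1: 54.5 ± 7.8%
F2: 81.7 ± 22.2%
F3: 80.6 ± 21.6%
```

Read: from the rigidly mounted tip sensor the weighted and unweighted
swings are statistically indistinguishable (negative separation, ANOVA
p = 0.52), while both fabric-mounted sensors separate the classes strongly
(p ≈ 1e-5) — and at 250 ms windows the fabric sensors classify the motion
far better than the rigid one. The same rig, evaluated per material, orders
the class separation roma > jersey > denim: softer, lighter fabric
amplifies the motion difference more.

The CLI wraps the same pipeline:

```
fabricsense simulate --material jersey --tip-load 0 --tip-load 3 \
    --trials 10 --seed 42 --out data/
fabricsense analyze --dataset data/ --sensors R1,F2,F3 --out report/
fabricsense classify --dataset data/ --sensor F2 --window-ms 250 --seed 7
fabricsense run --scenario material_sweep --seed 42 --out out/
```

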