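# myotrack

Longitudinal quantitative muscle MRI of the thigh for slowly progressing
neuromuscular disease, with spinal muscular atrophy (SMA) as the
motivating application.  Clinical strength and motor-function scores are
largely insensitive to one year of disease progression; quantitative MRI
of fatty muscle replacement is not.  `myotrack` implements the full
analysis chain needed to quantify that change from a baseline (A) and a
follow-up (B) scan session:

* **Fat fraction** from 4-echo complex Dixon data by IDEAL variable
  projection — per voxel `S(t) = (W + F·φ(t))·e^{i2πψt}·e^{−R2*t}` with a
  six-peak fat spectrum φ(t), field offset ψ and common decay R2*;
  FF = |F|/(|W|+|F|).
* **Water T2** from a 17-echo spin-echo train by two-compartment
  extended-phase-graph (EPG) fitting,
  `S_n = M0[(1−ff)·EPG(T2w,B1)_n + ff·EPG(T2f,B1)_n]`, robust to imperfect
  refocusing (B1 ≠ 1) and to the fat signal that plain exponential fitting
  mistakes for long T2.
* **Diffusion metrics** (MD, FA) from a 42-volume multi-shell scheme:
  Marchenko–Pastur PCA denoising (which also yields the SNR map),
  motion/eddy correction, and iWLLS tensor estimation with
  REKINDLE-style outlier rejection.
* **Longitudinal mask alignment**: rigid + affine + b-spline registration
  of the session water images, bidirectional segmentation propagation,
  and per-muscle restriction to the common anatomy — analysis always
  happens in native space; only masks move.
* **Statistics**: per-muscle summaries (FF, CSA, contractile CSA, T2, MD,
  FA, SNR), and a mixed-effects model of the change over follow-up with
  crossed random intercepts for subjects and muscle groups, baseline as a
  fixed covariate (SNR added for diffusion outcomes) and Wald inference.

Because the underlying patient scans cannot be redistributed, the package
includes a two-session digital thigh phantom (`myotrack.phantom`) with
known ground truth — bimodal per-muscle fat infiltration, ~1.3 %FF/year
progression in the affected muscles, contractile-area loss, and realistic
inter-session repositioning — against which every stage is validated.
See `docs/methods.md` for models, parameter choices and limitations.

## Worked example

```python
import numpy as np
from myotrack import (PhantomSpec, build_phantom, synthesize_dixon,
                      ideal_fit, fat_fraction, simulate_cohort_records,
                      fit_lmm)

# one subject, two sessions, default study conditions
truth = build_phantom(PhantomSpec(seed=1, matrix=48, n_slices=9))
series = synthesize_dixon(truth, "A")          # complex 4-echo Dixon
ff = fat_fraction(ideal_fit(series))           # FF map in [0, 1]
lab = truth.labels["A"]
for lbl, name in sorted(lab.label_names.items())[:3]:
    est = 100 * np.nanmean(ff.values[lab.labels == lbl])
    true = truth.muscle_values.query(
        "muscle == @name.rsplit('_', 1)[0] and time_point == 'A'").FF.iloc[0]
    print(f"{name:24s} FF {est:5.2f}%  (truth {true:5.2f}%)")

# statistical layer: a 10-subject cohort at a 1.28 %FF/interval slope
rng = np.random.default_rng(0)
res = fit_lmm(simulate_cohort_records(rng, slope_pct=1.28))
print(f"time effect {res.time_effect:+.2f} %FF "
      f"(95% CI {res.time_ci[0]:+.2f} to {res.time_ci[1]:+.2f}), p = {res.time_p:.3f}")
```

prints (seed 1/0):

```
adductor_longus_R        FF 29.65%  (truth 29.65%)
adductor_magnus_R        FF 35.33%  (truth 35.33%)
biceps_femoris_long_R    FF 45.74%  (truth 45.74%)
time effect +1.15 %FF (95% CI +0.27 to +2.03), p = 0.011
```

The noiseless Dixon fit reproduces the generator's truth to the printed
precision; the mixed model recovers a slope statistically compatible with
the simulated 1.28 %FF per follow-up interval.

A full pipeline run (phantom → maps → alignment → summaries → statistics)
is driven by a YAML config:

```bash
myotrack run --config run.yaml      # or: myotrack phantom/dixon/t2/dti/align ...
```

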