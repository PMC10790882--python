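# hemisim

Gaze-contingent hemianopia simulation and analysis for panoramic driving
simulators.

Homonymous hemianopia — loss of the same (left or right) visual hemifield
in both eyes — is common after brain lesions, and its effect on driving is
hard to study in patients because samples are small and heterogeneous.  A
gaze-contingent display (GCD) sidesteps this: a gray mask that tracks the
driver's current gaze occludes the complete left (LHH) or right (RHH) half
of the visual field on a 180° three-panel simulator rig, so healthy
participants experience the deficit while their scanning and lane-keeping
are recorded.  `hemisim` is an offline, fully testable re-implementation of
that method and of its complete analysis pipeline:

* **mask engine** — gaze direction vectors → panel pixel anchors on three
  3400 × 2720 px panels tiling [−90°, +90°]; moving-average anchor buffer
  with large-movement bypass and hold-last-sample on signal loss;
  semitransparent linear fade between the masked and unmasked field;
* **preprocessing** — head-gaze fallback for invalid samples, exclusion of
  blinks and non-driving areas of interest, zero-phase 10 Hz Butterworth
  low-pass on the horizontal gaze channel;
* **event detection** — ISO 15007-style fixations (≤ 2° dispersion within
  ≥ 120 ms windows, < 30°/s) and saccades (≥ 90°/s velocity runs);
* **scenario metrics** — deceleration phase from the first brake press
  within 100 m of the intersection (fallback 41.76 m) to the zebra
  crossing; lane-position mean/variance/crossings, first peripheral scan
  at 30°/45°, missing large scans, horizontal gaze statistics, hemifield
  fixation counts and durations beyond the central 10°, directional
  saccade amplitudes;
* **EAB analysis** — each impaired-condition value *v* is rated against
  the subject's own normal-vision (NV) baseline:

      v ∈ [ v_NV − IQR_NV/2 ,  v_NV + IQR_NV/2 ]  →  equal
      v above / below the band                    →  above / below

  where IQR_NV is the interquartile range of all participants' NV values
  in the same intersection type;
* **synthetic study generator** — 15 subjects × {NV, LHH, RHH} ×
  {straight, left-turn, right-turn intersections} with planted ground
  truth (event lists, scan sides, missing-scan flags, lane crossings,
  deceleration windows), so every stage is validated without recorded
  data.

## Worked example

```python
import hemisim as hs

# EAB: subject's NV value 10, NV sample {8, 10, 12, 14}
band = hs.nv_band(10.0, [8, 10, 12, 14])
print(band.lower, band.upper)                  # 8.5 11.5
print(hs.classify(12.0, band).classification)  # above
print(hs.percentage(25, 84))                   # 29.76

# synthetic study through the full pipeline
study = hs.generate_study(n_subjects=3, master_seed=7)
result = hs.run_pipeline(study["scenarios"])
table = result["metrics"]
print(table.groupby("condition")[
    ["phase_duration", "gaze_mean", "sacc_amp_left", "sacc_amp_right"]
].mean().round(2))
```

prints

```
           phase_duration  gaze_mean  sacc_amp_left  sacc_amp_right
condition
LHH                  6.64      -1.89          21.17           18.83
NV                   8.37      -2.49          30.11           31.62
RHH                  7.53       3.40          28.25           26.97
```

— deceleration phases of 6–8 s, the planted condition-dependent gaze
biases (leftward under NV, rightward under simulated right hemianopia)
and the smaller saccadic amplitudes planted under simulated left
hemianopia, all recovered by the measurement pipeline.

The same pipeline is scriptable from the shell:

```sh
hemisim synth --subjects 15 --seed 42 --out study/
hemisim run --study study/ --out results/
hemisim eab --metrics results/scenario_metrics.csv --metric lane_mean --out eab.csv
```

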