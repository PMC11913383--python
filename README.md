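# circumkin

Quantifying how climbing plants approach and grasp a support.

Climbing plants such as the pea (*Pisum sativum*) locate supports by
**circumnutation**: their apex and tendrils sweep oscillatory, roughly
helical paths while elongating, until the tendrils wrap around a support
or the shoot falls. Experiments probing this behaviour (e.g. presenting a
support only to the roots, only to the shoot, or split between opposite
sides) record plants with a calibrated stereo camera pair at one frame
every 3 minutes (0.0056 Hz), track anatomical landmarks in 2D, and
compare movement kinematics across support conditions.

`circumkin` implements that analysis pipeline end to end for researchers
in plant behaviour and movement ecology:

1. **stereo** — Brown–Conrady undistortion and two-view DLT triangulation
   (optional Gauss–Newton reprojection refinement) turning per-camera 2D
   marker tracks into 3D trajectories, with per-frame reprojection
   residuals.
2. **kinematics** — segmentation of a trajectory into circumnutation
   cycles (2π accumulations of the unwrapped polar angle of the detrended
   trajectory projected orthogonally to the growth axis), and the six
   dependent variables: movement time (min), average velocity (mm/min),
   time of peak velocity (% of movement time), mean cycle duration (min),
   number of cycles, and mean cycle length (mm, the maximum pairwise
   distance within a cycle).
3. **stats** — per metric, the linear mixed model

   `metric ~ condition + (1 | plant)`

   fitted by REML, with type-III Wald χ² tests, Nakagawa–Schielzeth
   marginal/conditional R², and all pairwise contrasts of the estimated
   marginal condition means with Satterthwaite (or Kenward–Roger) degrees
   of freedom and Tukey adjustment. The contrast machinery is
   cross-checked in the test suite against R's `lmerTest` + `emmeans`.
4. **synthetic** — a generator of circumnutation trajectories and whole
   multi-plant experiments with programmed ground truth (cycle counts,
   speeds, condition effects, plant-level random intercepts), plus a
   two-camera rendering of 3D trajectories into pixel tracks, so the
   entire pipeline is testable without any recordings.

Support conditions follow the four-arm design: `US` (undivided support),
`LS` (lifted, shoot-accessible only), `IS` (in-ground, root-accessible
only), `DS` (double/split support).

## Worked example

Simulate a 4×13-plant experiment, summarize each plant, and compare the
conditions:

```python
from circumkin import (simulate_study, summarize, records_to_frame,
                       fit_lmm, wald_type3, pairwise_contrasts)

study = simulate_study(n_plants_per_condition=13, seed=42)
records = records_to_frame([
    summarize(s["trajectory"], s["plant_id"], s["condition"], s["outcome"])
    for s in study
])
fit = fit_lmm(records, "avg_velocity_mm_min")
print(wald_type3(fit).round(3).to_string(index=False))
print(pairwise_contrasts(fit).round(3).to_string(index=False))
```

```
       term    chisq  df   p  R2m  R2c
(Intercept) 3953.917   1 0.0 0.92 0.96
  Condition  584.904   3 0.0 0.92 0.96

contrast  estimate    SE   df      t  p_adj
 US - DS     0.723 0.048 48.0 15.075  0.000
 US - IS     0.895 0.048 48.0 18.667  0.000
 US - LS     1.082 0.048 48.0 22.575  0.000
 DS - IS     0.172 0.048 48.0  3.593  0.004
 DS - LS     0.360 0.048 48.0  7.501  0.000
 IS - LS     0.187 0.048 48.0  3.908  0.002
```

The Wald table says the support condition strongly affects average
tendril velocity (χ²₃ = 584.9), with fixed effects explaining 92% of the
variance (R²m) and 96% jointly with plant identity (R²c). The contrasts
show undivided-support plants moving ~1.1 mm/min faster than
lifted-support plants — the programmed ordering of the simulator's
condition presets (US fastest, LS slowest): estimates are differences of
model-based condition means, `df` are Satterthwaite denominator degrees
of freedom, and `p_adj` is Tukey-adjusted over the six-contrast family.

The same analysis runs from a shell:

```sh
circumkin simulate --seed 42 --out run/
circumkin metrics --traj run/trajectories --annotations run/annotations.csv --out records.csv
circumkin stats --records records.csv --response avg_velocity_mm_min --out stats/
```

and `circumkin triangulate --tracks-a a.csv --tracks-b b.csv --calib
calib.txt --dt 3 --out traj.csv` reconstructs 3D trajectories from real
per-camera track tables plus an INI-style calibration file. Archived
per-observation tables (e.g. a published study's deposited records) can
be analysed directly via `circumkin.io.read_records` with a column
mapping onto the pipeline's tidy schema.

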