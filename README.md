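# flywalk

Kinematic analysis and generative modelling of walking *Drosophila*
locomotion in a circular arena with a central attractive light-zone.

A fly walking in a small arena cannot be described by classical random-walk
or Lévy-walk models: it spends long stretches circling the arena wall, its
"straight" runs are gently curved, and its stops reorient it. `flywalk`
implements the full analysis chain for this setting:

- **Kinematics** — per-frame speed *s*, movement angle *φ*, thrust
  *T = s·cos φ*, slip *S = s·sin φ*, yaw *Y* (body-orientation change) and
  signed path curvature *k* (rotation of the path's normal vector,
  deg/frame) from centroid + orientation tracks.
- **Four-state segmentation** — every frame is labelled *boundary* (within
  half a fly length of the wall), *stop* (speed < 0.5 mm/s), *sharp turn*
  or *curved walk*. Turns and walks are separated by a weighted
  binarization of |k| and |dk/dt| with fitted thresholds
  (curvature 13.843 deg/frame, derivative 4.080 deg/frame², weights
  0.890/0.739, turn/walk multiples 1.365/0.230).
- **State models** — per-state, per-scenario joint densities (stop and
  sharp turn: duration × total curvature; curved walk: speed × duration ×
  mean curvature; boundary: duration × arc angle), fitted as Gaussian-kernel
  KDEs and sampleable.
- **WTSB simulator** — a walk–turn–stop–boundary renewal process: a
  synthetic fly starts at the center, walks with sampled speed/curvature/
  duration, terminates each walk in a turn, a stop or the wall, and repeats
  for six minutes at 30 Hz. The **WTSB+BC+TB** variant adds *border choice*
  (the first two turns after crossing the light border preferentially occur
  at radii drawn from a fitted excess density) and *turn bias* (those turns
  are directed inward — θ_after < θ_before relative to the inward radial
  vector — with a set probability).
- **Border analysis** — inward-turn-bias estimation, optimal-turn
  classification, turn-location pmfs for crossing tracks, and the
  closed-form detrend density for border-crossing walks under uniform
  starts and exponential radial displacements:

  ```
  T(r) = exp(λ(r−b)) − exp(λ(r−1)),   0 ≤ r ≤ b
  T(r) = exp(−λ(r−b)) − exp(−λr),     b < r ≤ 1
  ```

- **Metrics** — attraction index (fraction of time inside the light
  border), radial occupancy (10 bins of 0.1 normalized radius), and the
  area-corrected radial turn density f_R(r) = P_R(r_k)/(π(r²_{k+1} − r²_k)).
- **Synthetic data** — fully parametric ground-truth cohorts (known state
  labels, programmable turn bias and border excess, optional 0.15 mm
  tracking noise) so that every estimator can be validated closed-loop.

## Worked example

```python
from flywalk import (ArenaConfig, GroundTruthSpec, generate_cohort,
                     compute_kinematics, segment_track, SegmentationParams,
                     attraction_index, estimate_turn_bias)

arena = ArenaConfig()                 # 40 mm arena, light border at 12 mm
cohort = generate_cohort(GroundTruthSpec(seed=7, noise_sd_mm=0.0), n=5,
                         build_segments=True)
fly = cohort[0]

kin = compute_kinematics(fly.traj, arena)
seg = segment_track(fly.traj, kin, SegmentationParams(), arena)
print(seg["state"].value_counts().to_dict())
print("attraction index:", round(attraction_index(fly.traj, arena, "after"), 3))
bias = estimate_turn_bias(fly.segments, fly.traj, arena, seed=0)
print("inward fraction:", round(bias["overall"]["bias"], 3))
```

prints

```
{'curved_walk': 140, 'sharp_turn': 71, 'stop': 56, 'boundary': 13}
attraction index: 0.281
inward fraction: 0.618
```

i.e. this six-minute track decomposes into 280 state bouts, the fly spends
28% of its post-entry time inside the light zone, and 62% of its sharp
turns reorient it toward the arena center (an unbiased walker sits near
0.5; the slight excess comes from wall-leaving geometry).

A command-line interface wraps the same functions:

```bash
flywalk synth --n 10 --seed 7 --out synth/          # ground-truth cohort
flywalk segment --in synth/fly0000.csv --out seg.csv
flywalk fit --segments seg.csv --out dists.npz
flywalk simulate --dists dists.npz --n 20 --seed 1 --out sims/
flywalk metrics --in sims/ --out metrics.json
```

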