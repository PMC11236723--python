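# collikinetics

Analysis and simulation code for studying **visuo-motor alignment in the
superior colliculus (SC)**: how the direction a collicular motor unit moves
the head relates, on the visual field, to the direction of visual motion
that same unit prefers — and what that arrangement buys an animal trying to
intercept a moving target.

The package is aimed at systems neuroscientists working with chronic
extracellular recordings from freely moving rodents (spike trains plus
head-mounted IMU Euler-angle traces) combined with head-restrained visual
mapping (drifting gratings, flashing squares, Gabor patches). Because such
recordings are rarely shareable, everything here runs end-to-end on
synthetic sessions with planted ground truth, so every stage of the
pipeline is testable for recovery and false-positive behaviour.

## What it computes

**Motor tuning.** Spike-triggered averages (STAs) of head displacement:
for each spike, the angular head velocity in the 25 bins (0.5 s) before and
50 bins (1 s) after spike onset is cumulatively summed into a displacement
curve, zeroed at the spike. Each Euler axis is summarized by a signed
displacement vector `|v| = max − min` (sign from the temporal order of the
extremes). A unit is motion tuned when some axis exceeds 5° with a rank
above 95% of a wrap-around shuffled null (spike times shifted by 2–180 s,
preserving count and inter-spike structure).

**Visual tuning.** Baseline-normalized responses R(θ_k) at K angles are
reduced to a circular vector sum,

    SI = | Σ_k R(θ_k) e^{imθ_k} / Σ_k R(θ_k) |,

with m = 1 in direction space (DSI, 12 angles) and m = 2 in orientation
space (OSI, periodicity 180°); the preferred angle is the argument of the
sum. A unit is tuned when 2 of 3 criteria hold: SI ≥ 0.1, trial-to-trial
angular deviation of the preferred angle ≤ 0.8 rad, and SI above the 95th
percentile of its shuffled null; DS vs OS by DSI > OSI. Static spatial
receptive fields (ssRFs) are mapped from flashing-square responses on a
15 × 11 grid (z-scored, shuffle-tested, 2D-Gaussian fit).

**Geometry.** Head orientation is a ZYX (yaw–pitch–roll) direction cosine
matrix; a gaze ray fixed in the head is rotated by the STA displacement at
each time bin, intersected with the (vertical, oblique) stimulus-screen
plane, and the track is rotated about the vertical by
β = asin(y₀/√(x₀²+y₀²)) so the screen becomes frontoparallel. The
velocity-weighted mean direction of the resulting 2D track is the unit's
gaze direction θ̄_gaze.

**Alignment.** For units tuned to both head rotation and gratings, the
offset Δ = θ̄_gaze − θ̄_gratings (mod 360°) is computed per unit; Δ = 180°
means anti-alignment. Populations are summarized by the circular mean, a
Rayleigh uniformity test, a 1,000-resample bootstrap of the circular mean,
and Watson–Williams F tests against matched-spread von Mises controls
centred at 0/90/180/270°.

**Network model.** A three-layer rate network (500 neurons per layer:
ssRF → direction-selective (DS) → motor) of one SC, with concentric DS
tuning and a motor layer anti-aligned with the DS layer. Rates follow
`r ← [r + (Δt/τ)(−r + x + ε)]₊` (Δt = 0.5 ms, τ = 10 ms, σ = 0.1); agent
motion is the motor population vector scaled by Δt/τ_m. Two pathway
variants are compared for moving/static target interception: *kinetic*
(DS drive = von Mises in the stimulus angle, scaled by the concentricity
γ = [−ŝ·ṡ̂]₊) and *static* (DS drive = ssRF rates).

## Worked example

```bash
python analysis/01_generate_session.py --seed 1     # plant an anti-aligned population
python analysis/02_tuning_analysis.py  --seed 1     # motion + visual tuning per unit
python analysis/03_alignment_population.py --seed 1 # population alignment
python analysis/04_network_interception.py --seed 1 # interception model
```

The third script prints (seed 1):

```
units entering the alignment analysis: 33
  circular mean offset: 169.5 deg (180 = anti-aligned)
  Rayleigh z = 17.81, p = 9.6e-10
  bootstrap mean 169.3 deg, 95% CI [154.3, 184.1] (1000 resamples)
  Watson-Williams vs matched-spread controls:
    centre     0 deg: F =   170.42 (crit 3.99) -> different
    centre    90 deg: F =    56.93 (crit 3.99) -> different
    centre   180 deg: F =     1.85 (crit 3.99) -> similar
    centre   270 deg: F =     92.65 (crit 3.99) -> different
```

i.e. the pipeline recovers the planted anti-alignment: the population's
visuo-motor offset distribution is non-uniform (Rayleigh p ≪ 0.05), its
mean is statistically indistinguishable only from the 180° control, and the
bootstrap CI contains 180°. The fourth script shows the kinetic pathway
intercepting an approaching target while spending zero energy on a receding
one, the static pathway reaching a static target, and the 12-shift
experiment finding the minimum interception error at zero shift
(anti-alignment).

## Layout

| Path | Contents |
| --- | --- |
| `src/collikinetics/geometry.py` | DCM kinematics, gyro integration, gaze–screen projection |
| `src/collikinetics/tuning.py` | STA, selectivity, shuffled nulls, ssRF maps, latencies |
| `src/collikinetics/alignment.py` | visuo-motor offsets and population circular statistics |
| `src/collikinetics/netsim.py` | three-layer interception model, sweeps, shift experiment |
| `src/collikinetics/synth.py` | stimulus schedules and planted-ground-truth generators |
| `src/collikinetics/session.py` | session I/O, thresholds config, pipeline orchestration |
| `src/collikinetics/validation.py` | Monte Carlo recovery / false-positive benchmarks |
| `analysis/` | numbered driver scripts (see worked example) |
| `docs/methods.md` | model assumptions, parameter choices, limitations |
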