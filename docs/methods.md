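# Methods

This note documents the models, conventions, parameter choices and known
limitations of the package. Angles are radians internally and degrees at
I/O boundaries throughout.

## Head-rotation kinematics and gaze projection

Head orientation uses the aerospace ZYX (intrinsic yaw ψ → pitch θ → roll
φ) direction cosine matrix with entries `R13 = −sinθ, R23 = sinφ cosθ,
R33 = cosφ cosθ`; Euler extraction is `φ = atan2(R23,R33), θ = −asin(R13),
ψ = atan2(R12,R11)`, which is degenerate at |θ| = 90° (a GimbalLockError).
Gyroscope integration applies the first-order update
`Rᵀ(t+dt) = Rᵀ(t)(I + [ω]×dt)`; since this drifts off SO(3), each step is
re-projected to the nearest rotation via SVD polar decomposition. That
projection is the package's choice — it keeps the orthonormality
invariants exact at the cost of O(dt) accuracy identical to the raw update;
sensor-fusion drift correction (magnetometer/accelerometer) is out of
scope.

The stimulus screen is the vertical plane `y₀(x − x₀) + x₀y = 0` (it
contains the lab vertical; parameters x₀, y₀ in cm). A gaze ray — pupil
offset P₀′ plus unit direction d, both fixed in the head frame — is rotated
into the lab frame, intersected with the plane by solving for the ray
parameter m (rays parallel to the plane or with m < 0, i.e. pointing away
from the screen, are rejected rather than mirrored), and the intersection
track is rotated about the vertical by β = asin(y₀/√(x₀²+y₀²)) (Rodrigues
formula) so the screen becomes frontoparallel; screen coordinates are then
(horizontal, vertical) relative to the resting (t = 0) intersection.

Defaults place the resting gaze along the lab +x axis with the pupil at
the head origin and the screen 20 cm away (x₀ = y₀ = 20 cm, so the screen
is oblique at 45° but the resting gaze distance is exactly 20 cm), with
angular extents 31° down / 42° up / 45° nasal / 59° temporal. With this
geometry pure yaw maps exactly to horizontal screen motion and pure pitch
to vertical — the property the alignment analysis relies on. The pupil
offset and resting gaze direction are declared defaults, not measured
quantities; both are overridable in `GeometryConfig`.

Eye-in-head corrections are pluggable models mapping Euler angles to a
rotation applied to the head-frame gaze direction. The packaged
`compensatory_yaw_correction(gain)` counter-rotates the eye against head
yaw (at gain 1 the lab-frame gaze azimuth is invariant to yaw); it is a
stand-in for a measured head–eye coupling, which the package does not fit.

## Spike-triggered motor tuning

The STA uses 25 pre-spike and 50 post-spike bins of one head-trace sample
(20 ms at 50 Hz). Displacements are angle differences relative to the
spike-onset sample — algebraically identical to cumulatively summing
per-bin angular velocities — so the curve is exactly zero at the spike bin.
The displacement vector is max − min of the mean curve with the sign given
by the temporal order of the extremes. Tuning requires, on some Euler
axis, |v| > 5° with a null rank > 0.95; replicate-trial designs
(light1/light2/dark1/dark2) additionally require a consistent sign within
the condition, and "motor" means tuned in both light and dark. No
multiple-comparison correction is applied across axes (a unit passes if
*any* axis passes).

Shuffled nulls rotate spike times by a uniform draw from
[2 s, min(180 s, T − 2 s)] modulo the trial duration, preserving the spike
count and the circular inter-spike-interval multiset. For the
displacement-vector statistic the null is computed exactly but cheaply:
with the trace treated circularly, the shifted-train STA at lag o for a
shift of k samples is `(C[k+o] − C[k])/n` where C is the circular
cross-correlation of the spike histogram with the angle series — one FFT
serves all 1,000 replicates. (Windows crossing the trace boundary wrap
instead of being dropped; this is consistent with the wrap-around shuffle
and differs from the observed-STA computation only at the trace edges.)

## Visual selectivity and classification

Responses are firing rates normalized to baseline; negative values after
normalization are clipped to zero before the vector sum (the modulus
formula assumes non-negative weights). Direction space uses exponent
m = 1 and orientation space m = 2, the standard DSI/OSI convention; the
preferred orientation is the half-argument of the m = 2 sum, reported on
[0°, 180°). The trial-to-trial reliability criterion is the Mardia angular
deviation √(2(1 − R̄)) of per-trial preferred angles (computed on doubled
angles and halved in orientation space), thresholded at 0.8 rad. The
2-of-3 rule (SI ≥ 0.1, deviation ≤ 0.8 rad, null rank > 0.95) is evaluated
in both spaces; a unit tuned in at least one space is DS if DSI > OSI,
else OS.

The 2-of-3 rule is liberal by construction: with three per-trial preferred
angles, pure-noise units satisfy the deviation criterion with probability
≈ 0.29, and its conjunction with the 5%-chance rank criterion across two
angular spaces yields an intrinsic false-positive rate of roughly 10–15%
at the stated thresholds. The benchmark in `validation.py` measures this
rate directly; users wanting stricter control should raise the rank
threshold or require the SI criterion explicitly.

## ssRF mapping

Flash responses are averaged per grid location (15 × 11, each colour
separately), divided by the baseline rate, and z-scored over the grid.
Significance requires max z > 2 *and* a rank above 95% of shuffled
replicates. The shuffle comparison is made on the common response scale —
the statistic is max − grid mean of the response-over-baseline map — rather
than re-z-scoring each shuffled map by its own s.d.: a shuffled map is
typically flat with one relocated response burst, so its own s.d. is tiny
and its max-z explodes, while a genuinely structured RF inflates its own
s.d. and deflates its max-z; per-map re-normalization therefore destroys
power exactly for responsive units (measured recovery collapses to
~10–30%) while the common-scale comparison leaves the false-positive rate
at the nominal ~5% and restores power. Significant maps get an
unconstrained elliptical 2D Gaussian fit (least squares, initialized at
the argmax cell, widths bounded ≥ 0.5 cell); if the fit fails to converge
the argmax cell is reported as the centre with a flag.

## Population alignment statistics

Per-unit offsets Δ = θ̄_gaze − θ̄_gratings are wrapped to [0°, 360°); the
gaze direction is the argument of the summed step vectors of the screen
track (velocity weighting of unit motion vectors reduces to exactly this).
Population summaries: circular mean; Rayleigh test (pingouin's
large-sample approximation); 1,000 bootstrap resamples of the circular
mean with a percentile CI taken on wrapped deviations from the bootstrap
mean; Watson–Williams two-sample F (hand-implemented: no installed package
provides it) against seeded von Mises controls matched in size and
circular s.d. to the data, centred at 0/90/180/270°. The critical value is
computed from the actual sample sizes (F₀.₀₅(1, N−2) ≈ 3.99 at N = 66)
rather than fixed; results flag low-concentration samples (pooled R̄ <
0.45) where the test's assumptions weaken.

## Network model

Positions are normalized field units (degrees/100): the naso-temporal ×
ventro-dorsal extents [0,140]°×[0,70]° become [0,1.4]×[0,0.7], and with
κ = 40 and the 0.6 exponent factor the ssRF half-width is ≈ 0.17 units ≈
17°, a plausible collicular RF size; the unit system is declared in config
and overridable. RF centres tile the field as a 25 × 20 grid of cell
midpoints. Derived angles: θ_DS = θ_RF + π (concentric preference,
toward the gaze centre at the field origin) and θ_M = θ_DS + π + shift,
so zero shift (anti-alignment) makes the motor direction equal the RF
angular position. Per step: ssRF drive `1.5·exp(−0.6κ|s−z|²)`; DS drive
either the relayed ssRF rates (static) or `γ·exp(κ[cos(θ_S − θ_DS + π) −
1])` with concentricity `γ = [−sᵀṡ/(|s||ṡ|)]₊` (kinetic; γ := 0 when s or
ṡ vanishes); motor drive = DS rates; rectified leaky rate updates with
i.i.d. Gaussian input noise per neuron per step; agent displacement
`Δa = (Δt/τ_m)Σᵢ rᵢᴹ mᵢ`; egocentric target update `s ← s + ṡΔt − Δa`.
Termination: 2.5 s timeout, target outside the field extents, agent
motion beyond 200° NT / 100° VD, or interception (|s| ≤ 24°). Energy is
Σₜ|Δaₜ| (arbitrary units).

Relative speed (agent/target) is controlled through τ_m: the agent's
characteristic speed is |Σ x_DS m| / τ_m at the closed-form noise-free
fixed point for a canonical centred stimulus, and τ_m is set so this
equals the requested multiple of the (fixed) target speed. The
model-comparison sweep enumerates 2 pathways × 40 relative speeds × 10
start positions (a ring of radius 0.3 units around the field centre) × 15
directions = 12,000 runs; the 40 speeds are evenly spaced on [0.15, 6.0]
(a step size of 0.13 would be arithmetically inconsistent with 40
values spanning 0–6, and a zero relative speed is degenerate — the grid
used is recorded in every output table). The shift experiment repeats
radially approaching targets under 12 DS→motor shifts in 30° steps.

## Synthetic data

The generators produce exactly the statistical structure the analyses
assume, with ground truth serialized alongside:

* **Stimulus schedules** reproduce the experimental protocols: gratings 12
  directions × 9 presentations (1 s static, 2 s drift, 1 s stop), squares
  15 × 11 × 2 colours × 3 repeats of 750 ms flashes, Gabor 24 locations ×
  8 directions × 3 = 576, spots 8 starts × 9, optotagging 30 bursts of
  30 × 5 ms pulses at 30 Hz with 9 s rests (900 pulses / 300 s).
* **Head traces** are per-axis Ornstein–Uhlenbeck wander (defaults:
  s.d. 8°, autocorrelation time 2 s, 50 Hz — calm foraging) plus planted
  raised-cosine displacement events whose net angle change is exact.
  Planted events alternate in sign so the orientation stays bounded, and
  their onsets are drawn with exponential gaps (minimum 1.5 s): regularly
  spaced events would let circularly shifted spike trains re-lock onto
  other events and inflate the shuffled null.
* **Motor units** fire baseline Poisson spikes plus bursts (gain ×
  baseline) in the 100–300 ms window before each planted event whose
  displacement direction matches the unit's preference (cosine > 0.5) —
  spikes lead movement, so the STA recovers the upcoming displacement.
  Defaults for a tuned unit: 2 Hz baseline, gain 15 (≈ 30 Hz pre-movement
  burst), one movement every ~2 s; vigorous but physiological premotor
  bursting, and enough modulation for the 5° criterion.
* **Visual units** emit per-event Poisson counts with mean `baseline ×
  (1 + gain × tuning)`: one von Mises lobe (DS), two opposite lobes (OS),
  or a 2D Gaussian over the square grid (ssRF). Planted ssRF units are
  luminance-polarity selective (they respond to one square colour), the
  same reason the mapping analysis treats colours separately. Grating
  responses load on the drifting phase of each presentation.
* **Eye traces** counter-rotate with the head (configurable gain ≤ 1.5)
  plus single-sample saccade steps of 10° (500°/s at 50 Hz, above the
  350°/s detection threshold) at Poisson times.
* **Visuo-motor populations** draw a motor direction per unit, plant the
  corresponding yaw/pitch displacement events, compute the implied gaze
  direction through the *noise-free* geometry, and set the planted grating
  preference to that direction + 180° + von Mises jitter. The default
  study condition is n = 33 units with jitter κ = 2 over 80 s traces with
  40 movements.

What the generators do **not** emulate: bursty non-Poisson firing,
rate adaptation, slow drift in baseline rate, eye–head coupling beyond a
fixed gain, correlated noise across units, spike-sorting contamination,
and visual responses with realistic temporal dynamics (transients,
latency). Passing recovery tests therefore demonstrates correctness of
the analysis chain under its own assumptions, not robustness to every
property of real recordings.

## Numerical choices and scale of the validation runs

Rotation matrices are validated to 1e−9 (orthonormality, determinant);
ray–plane solutions must satisfy the plane equation to 1e−9 and agree with
a numeric ray-marching oracle to 1e−6. Gaussian RF fits bound widths at
0.5 cell. The wheel-speed split low-pass filters at 1 Hz (2nd-order
Butterworth, zero-phase). EPSP latencies interpolate the 25–30% / 70–75%
amplitude-band crossings when sampling is coarse. All stochastic
components take explicit seeds; identical seeds give byte-identical
pipeline outputs.

Monte Carlo validation sizes: 100 planted DS units, 200 untuned units,
50 ssRF units, 1,000 random geometry configurations, and 100 seeds × 33
units for the full alignment pipeline (each seed regenerates the session
and runs motion nulls, visual nulls, geometry projection and population
statistics at 1,000 shuffles/resamples). The reduced executed sweep in the
analysis scripts is 2 × 5 × 3 × 5 = 150 runs; the full 12,000-run sweep is
enumerated, and executing it is a matter of passing the full `SweepSpec`.

## Known limitations

* The one-clause-per-axis motion criterion inherits the paper-style
  liberal multiple-comparison stance; a conservative variant would correct
  across axes.
* The alignment pipeline's per-unit gaze direction is only as good as the
  STA; units with weak pre-movement modulation (< ~30% of spikes
  movement-locked) fall below the 5° criterion and drop out.
* With n = 33 units and offset jitter κ = 2, the circular standard error
  of the population mean is ≈ 8.5°, so single-population means scatter
  around the planted 180° by that much — population-level claims need the
  bootstrap CI, not the point estimate.
* The Watson–Williams test assumes concentrated samples; results carry a
  low-concentration flag rather than a hard failure.
* The network model is purely feedforward and rate-based: no recurrence,
  inhibition, learning, or spiking.
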