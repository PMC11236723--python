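"""Synthetic sessions with planted ground truth for every analysis stage.

Generates the data the analyses assume: stimulus schedules with the exact
protocol counts (drifting gratings, flashing squares, moving Gabor patches,
moving spots, optotagging pulse trains); 50 Hz Euler-angle foraging traces
as smooth Ornstein-Uhlenbeck wander with planted stereotyped head
displacements; motor units whose spikes precede those displacements
(inhomogeneous Poisson); visual units with planted von Mises direction or
orientation tuning and Gaussian ssRFs (per-event Poisson counts);
compensatory eye traces with planted saccades; and anti-aligned visuo-motor
populations in which the planted grating preference equals the unit's
screen-projected gaze direction plus 180 degrees plus von Mises jitter.
Ground truth is always carried alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import GeometryConfig, DEFAULT_GEOMETRY, project_displacement_to_gaze_path
from .tuning import HeadTrace, SpikeTrain, compute_sta
from .alignment import gaze_preferred_direction

__all__ = [
    "StimulusSchedule",
    "PlantedUnitSpec",
    "PlantedEvent",
    "SyntheticSession",
    "make_schedule",
    "simulate_head_trace",
    "simulate_motor_unit",
    "simulate_visual_unit",
    "simulate_eye_trace",
    "simulate_visuomotor_population",
    "irregular_event_times",
    "GRID_SHAPE",
]

GRID_SHAPE = (11, 15)  # rows (y) x cols (x): 15 x 11 = 165 square locations


@dataclass
class StimulusSchedule:
    """Ordered stimulus events for one protocol."""

    kind: str
    events: pd.DataFrame   # onset, offset + protocol-specific parameter columns
    duration: float

    def __post_init__(self) -> None:
        ev = self.events
        if len(ev) and np.any(ev["onset"].values[1:] < ev["offset"].values[:-1] - 1e-9):
            raise ValueError("schedule events overlap")


def make_schedule(kind: str, seed: int | np.random.Generator = 0) -> StimulusSchedule:
    """Build a full randomized stimulation protocol.

    * ``gratings``: 12 directions (30 deg steps) x 9 presentations over 3
      trials; each presentation 1 s static, 2 s drifting, 1 s stop.
    * ``squares``: 15 x 11 grid x 2 colours x 3 repeats of 750 ms flashes.
    * ``gabor``: 24 locations x 8 directions x 3 repeats = 576 presentations
      of 1.5 s.
    * ``spots``: 8 start points x 3 per trial x 3 trials of 2.5 s sweeps.
    * ``optotag``: 30 bursts of 30 x 5 ms pulses at 30 Hz with 9 s rests:
      900 pulses over 5 min.
    """
    rng = np.random.default_rng(seed)
    if kind == "gratings":
        dirs = np.arange(12) * 30.0
        rows = []
        t = 0.0
        for rep in range(9):
            order = rng.permutation(12)
            for k in order:
                rows.append(
                    {
                        "onset": t,
                        "offset": t + 4.0,
                        "angle": dirs[k],
                        "trial": rep // 3,
                        "drift_onset": t + 1.0,
                        "drift_offset": t + 3.0,
                    }
                )
                t += 4.0
        return StimulusSchedule(kind, pd.DataFrame(rows), duration=t)

    if kind == "squares":
        ny, nx = GRID_SHAPE
        combos = [
            (c, r, colour)
            for colour in ("black", "white")
            for r in range(ny)
            for c in range(nx)
        ]
        rows = []
        t = 0.0
        for rep in range(3):
            idx = rng.permutation(len(combos))
            for i in idx:
                c, r, colour = combos[i]
                rows.append(
                    {
                        "onset": t,
                        "offset": t + 0.75,
                        "col": c,
                        "row": r,
                        "colour": colour,
                        "repeat": rep,
                    }
                )
                t += 1.0  # 750 ms flash + 250 ms grey
        return StimulusSchedule(kind, pd.DataFrame(rows), duration=t)

    if kind == "gabor":
        locs = [(x, y) for y in range(4) for x in range(6)]
        dirs = np.arange(8) * 45.0
        combos = [(loc, d) for loc in locs for d in dirs]
        rows = []
        t = 0.0
        for rep in range(3):
            for i in rng.permutation(len(combos)):
                (x, y), d = combos[i]
                rows.append(
                    {
                        "onset": t,
                        "offset": t + 1.5,
                        "loc_x": x,
                        "loc_y": y,
                        "angle": d,
                        "repeat": rep,
                    }
                )
                t += 2.0
        return StimulusSchedule(kind, pd.DataFrame(rows), duration=t)

    if kind == "spots":
        # 8 start points: corners and edge midpoints; sweep in, pause, sweep out
        starts = np.arange(8) * 45.0
        rows = []
        t = 0.0
        for trial in range(3):
            block = np.repeat(np.arange(8), 3)
            for i in rng.permutation(block):
                rows.append(
                    {
                        "onset": t,
                        "offset": t + 2.5,
                        "start_angle": starts[i],
                        "angle": (starts[i] + 180.0) % 360.0,  # motion direction
                        "trial": trial,
                    }
                )
                t += 3.0
        return StimulusSchedule(kind, pd.DataFrame(rows), duration=t)

    if kind == "optotag":
        rows = []
        for burst in range(30):
            t0 = burst * 10.0
            for p in range(30):
                onset = t0 + p / 30.0
                rows.append(
                    {"onset": onset, "offset": onset + 0.005, "burst": burst, "pulse": p}
                )
        return StimulusSchedule(kind, pd.DataFrame(rows), duration=300.0)

    raise ValueError(f"unknown schedule kind {kind!r}")


@dataclass
class PlantedEvent:
    """A stereotyped head displacement: onset (s), per-axis amplitude (deg)."""

    t: float
    yaw: float = 0.0
    pitch: float = 0.0
    roll: float = 0.0
    duration: float = 0.5


def _smoothstep(x: np.ndarray) -> np.ndarray:
    """Raised-cosine ramp from 0 to 1 on [0, 1]."""
    x = np.clip(x, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * x))


def simulate_head_trace(
    duration: float,
    seed: int | np.random.Generator = 0,
    ou_sigma: float = 8.0,
    ou_tau: float = 2.0,
    events: Sequence[PlantedEvent] = (),
    fs: float = 50.0,
) -> HeadTrace:
    """Smooth stochastic Euler-angle wander with optional planted displacements.

    Each axis follows an Ornstein-Uhlenbeck process (stationary s.d.
    ``ou_sigma`` deg, autocorrelation time ``ou_tau`` s) sampled at ``fs``;
    planted events superimpose raised-cosine steps whose net angle change
    over the event window equals the requested amplitude exactly.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    dt = 1.0 / fs
    a = np.exp(-dt / ou_tau)
    innov_sd = ou_sigma * np.sqrt(1.0 - a * a)
    angles = np.zeros((3, n))
    if ou_sigma > 0:
        noise = rng.normal(0.0, innov_sd, size=(3, n))
        for i in range(1, n):
            angles[:, i] = a * angles[:, i - 1] + noise[:, i]
    for ev in events:
        ramp = _smoothstep((t - ev.t) / ev.duration)
        for k, ax in enumerate(("yaw", "pitch", "roll")):
            amp = getattr(ev, ax)
            if amp:
                angles[k] += amp * ramp
    return HeadTrace(t=t, yaw=angles[0], pitch=angles[1], roll=angles[2])


def irregular_event_times(
    rng: np.random.Generator,
    duration: float,
    n_events: int,
    min_gap: float = 1.5,
    t_start: float = 1.0,
    t_margin: float = 1.5,
) -> np.ndarray:
    """Irregular (exponential-gap) event onsets with a minimum separation.

    Head movements during foraging are aperiodic; regular spacing would let
    circularly shifted spike trains re-lock onto other events and inflate
    shuffled nulls.
    """
    span = duration - t_start - t_margin
    free = span - n_events * min_gap
    if free <= 0:
        raise ValueError("duration too short for the requested event count")
    raw = rng.exponential(1.0, n_events)
    gaps = min_gap + raw * free / raw.sum()
    times = t_start + np.cumsum(gaps) - gaps[0]
    return times


@dataclass
class PlantedUnitSpec:
    """Ground truth for one synthetic unit."""

    kind: str                       # motor | visual_DS | visual_OS | ssRF | visuo_motor | untuned
    baseline_rate: float = 5.0      # Hz
    gain: float = 3.0               # response gain over baseline
    preferred_angle: float = 0.0    # deg (visual kinds)
    kappa: float = 2.0              # von Mises concentration (visual kinds)
    rf_centre: tuple[float, float] = (7.0, 5.0)   # (col, row) grid cells
    rf_sigma: float = 1.5           # grid cells
    rf_colour: str = "black"        # luminance polarity the unit responds to
    motor_yaw: float = 0.0          # planted displacement amplitudes (deg)
    motor_pitch: float = 0.0
    motor_roll: float = 0.0
    jitter_kappa: float = 2.0       # anti-alignment jitter concentration


def _poisson_spikes(
    rng: np.random.Generator, rate: float, t0: float, t1: float
) -> np.ndarray:
    n = rng.poisson(rate * (t1 - t0))
    return rng.uniform(t0, t1, size=n)


def simulate_motor_unit(
    head: HeadTrace,
    events: Sequence[PlantedEvent],
    spec: PlantedUnitSpec,
    seed: int | np.random.Generator = 0,
    lead_window: tuple[float, float] = (0.1, 0.3),
) -> np.ndarray:
    """Spike train whose emission precedes the planted head displacements.

    Inhomogeneous Poisson: baseline rate everywhere plus ``gain x baseline``
    inside a window ``lead_window`` seconds before each planted event onset
    (spikes lead movement, so the STA recovers the upcoming displacement).
    When the spec carries a preferred displacement (``motor_yaw`` /
    ``motor_pitch`` / ``motor_roll``), only events whose amplitude vector
    points the same way (cosine > 0.5) recruit bursts — the unit decodes one
    movement direction while the head also moves the other way.  With gain 0
    or no events the train is homogeneous Poisson.
    """
    rng = np.random.default_rng(seed)
    duration = float(head.t[-1] + head.dt)
    spikes = [_poisson_spikes(rng, spec.baseline_rate, 0.0, duration)]
    pref = np.array([spec.motor_yaw, spec.motor_pitch, spec.motor_roll])
    if spec.gain > 0:
        burst_rate = spec.gain * spec.baseline_rate
        for ev in events:
            if np.linalg.norm(pref) > 0:
                evv = np.array([ev.yaw, ev.pitch, ev.roll])
                nv = np.linalg.norm(evv)
                if nv == 0 or (pref @ evv) / (np.linalg.norm(pref) * nv) <= 0.5:
                    continue
            t0 = max(ev.t - lead_window[1], 0.0)
            t1 = max(ev.t - lead_window[0], 0.0)
            if t1 > t0:
                spikes.append(_poisson_spikes(rng, burst_rate, t0, t1))
    out = np.sort(np.concatenate(spikes))
    return np.unique(out)


def _direction_tuning(angle_deg: np.ndarray, spec: PlantedUnitSpec, kind: str) -> np.ndarray:
    th = np.deg2rad(angle_deg - spec.preferred_angle)
    vm = np.exp(spec.kappa * (np.cos(th) - 1.0))
    if kind == "visual_OS":
        vm2 = np.exp(spec.kappa * (np.cos(th - np.pi) - 1.0))
        return 0.5 * (vm + vm2)
    return vm


def simulate_visual_unit(
    schedule: StimulusSchedule,
    spec: PlantedUnitSpec,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Spike train responding to a stimulus schedule with planted tuning.

    Baseline homogeneous Poisson over the whole protocol plus per-event
    Poisson counts with mean ``baseline x gain x tuning(event) x duration``:
    von Mises direction tuning (one lobe DS, two opposite lobes OS) for
    angle-carrying events, a 2D Gaussian over grid location for flashing
    squares, nothing for untuned specs.  Grating responses load on the
    drifting phase of each presentation.
    """
    rng = np.random.default_rng(seed)
    spikes = [_poisson_spikes(rng, spec.baseline_rate, 0.0, schedule.duration)]
    ev = schedule.events
    if spec.gain > 0 and spec.kind != "untuned":
        if spec.kind in ("visual_DS", "visual_OS", "visuo_motor"):
            if "angle" not in ev.columns:
                raise ValueError(f"schedule {schedule.kind!r} carries no angles")
            tune = _direction_tuning(
                ev["angle"].to_numpy(float),
                spec,
                "visual_OS" if spec.kind == "visual_OS" else "visual_DS",
            )
            on = ev.get("drift_onset", ev["onset"]).to_numpy(float)
            off = ev.get("drift_offset", ev["offset"]).to_numpy(float)
        elif spec.kind == "ssRF":
            if schedule.kind != "squares":
                raise ValueError("ssRF specs require a squares schedule")
            dx = ev["col"].to_numpy(float) - spec.rf_centre[0]
            dy = ev["row"].to_numpy(float) - spec.rf_centre[1]
            tune = np.exp(-(dx**2 + dy**2) / (2.0 * spec.rf_sigma**2))
            # units are luminance-polarity selective; the map analysis
            # treats each colour separately for the same reason
            tune = tune * (ev["colour"].to_numpy() == spec.rf_colour)
            on = ev["onset"].to_numpy(float)
            off = ev["offset"].to_numpy(float)
        else:
            raise ValueError(f"unknown unit kind {spec.kind!r}")
        extra_rate = spec.baseline_rate * spec.gain * tune
        for r, t0, t1 in zip(extra_rate, on, off):
            if r > 0:
                spikes.append(_poisson_spikes(rng, r, t0, t1))
    out = np.sort(np.concatenate(spikes))
    return np.unique(out)


@dataclass
class EyeTrace:
    """Pupil angular position (deg) on the two eye axes plus planted saccades."""

    t: np.ndarray
    azimuth: np.ndarray
    elevation: np.ndarray
    saccade_times: np.ndarray

    def velocities(self) -> tuple[np.ndarray, np.ndarray]:
        """Forward-difference angular velocity (deg/s) per axis.

        Forward differences keep a single-sample saccade step at its full
        amplitude/dt velocity (central differences would halve it).
        """
        dt = float(self.t[1] - self.t[0])
        va = np.diff(self.azimuth, append=self.azimuth[-1]) / dt
        ve = np.diff(self.elevation, append=self.elevation[-1]) / dt
        return va, ve


def simulate_eye_trace(
    head: HeadTrace,
    gain: float = 1.0,
    saccade_rate: float = 0.1,
    seed: int | np.random.Generator = 0,
    saccade_amplitude: float = 10.0,
    noise_sd: float = 0.0,
) -> EyeTrace:
    """Compensatory eye position with planted saccades.

    Eye position counter-rotates with the head (azimuth = -gain x yaw,
    elevation = -gain x pitch); saccades are single-sample steps of
    ``saccade_amplitude`` deg (well above the 350 deg/s detection threshold
    at 50 Hz) at Poisson-distributed times, alternating in sign.
    """
    if not 0.0 <= gain <= 1.5:
        raise ValueError("gain must lie in [0, 1.5]")
    rng = np.random.default_rng(seed)
    az = -gain * head.yaw.copy()
    el = -gain * head.pitch.copy()
    duration = float(head.t[-1])
    n_sac = rng.poisson(saccade_rate * duration)
    times = np.sort(rng.uniform(1.0, max(duration - 1.0, 1.0), size=n_sac))
    # enforce >= 0.5 s separation so events stay distinct at 50 Hz
    keep = np.concatenate([[True], np.diff(times) > 0.5]) if n_sac else np.array([], bool)
    times = times[keep]
    for i, ts in enumerate(times):
        step = saccade_amplitude * (1 if i % 2 == 0 else -1)
        az[head.t >= ts] += step
    if noise_sd > 0:
        az = az + rng.normal(0.0, noise_sd, az.size)
        el = el + rng.normal(0.0, noise_sd, el.size)
    return EyeTrace(t=head.t, azimuth=az, elevation=el, saccade_times=times)


@dataclass
class SyntheticSession:
    """A full synthetic recording: traces, spikes, schedules, ground truth."""

    head_traces: dict[str, HeadTrace]
    planted_events: dict[str, list[PlantedEvent]]
    motor_spikes: dict[str, np.ndarray]
    grating_schedule: StimulusSchedule
    grating_spikes: dict[str, np.ndarray]
    ground_truth: pd.DataFrame
    geometry: GeometryConfig = dc_field(default_factory=GeometryConfig)
    seed: int = 0


def simulate_visuomotor_population(
    n_units: int = 33,
    jitter_kappa: float = 2.0,
    geometry: GeometryConfig | None = None,
    seed: int = 0,
    trace_duration: float = 80.0,
    n_events: int = 40,
    displacement_deg: float = 20.0,
    baseline_rate: float = 2.0,
    gain: float = 15.0,
) -> SyntheticSession:
    """Anti-aligned visuo-motor population with planted ground truth.

    Each unit decodes a planted 3D head displacement (a yaw/pitch mixture of
    fixed total amplitude at a random motor angle).  The displacement's
    screen-projected gaze direction is computed through the head-rotation
    geometry, and the unit's planted grating preference is set to that gaze
    direction plus 180 degrees plus von Mises(jitter_kappa) jitter — the
    anti-alignment structure the analysis pipeline is meant to recover.
    """
    geometry = geometry if geometry is not None else DEFAULT_GEOMETRY
    rng = np.random.default_rng(seed)
    schedule = make_schedule("gratings", seed=rng.integers(2**31))

    head_traces: dict[str, HeadTrace] = {}
    events_by_unit: dict[str, list[PlantedEvent]] = {}
    motor_spikes: dict[str, np.ndarray] = {}
    grating_spikes: dict[str, np.ndarray] = {}
    truth_rows = []
    for u in range(n_units):
        unit = f"unit{u:03d}"
        motor_angle = rng.uniform(0.0, 360.0)
        yaw_amp = displacement_deg * np.cos(np.deg2rad(motor_angle))
        pitch_amp = displacement_deg * np.sin(np.deg2rad(motor_angle))
        times = irregular_event_times(rng, trace_duration, n_events)
        # alternate movement sign so head orientation stays bounded; the
        # unit's spikes lead only the positive-sign (preferred) movements
        events = [
            PlantedEvent(
                t=float(ts),
                yaw=sgn * yaw_amp,
                pitch=sgn * pitch_amp,
                duration=0.5,
            )
            for ts, sgn in zip(times, np.resize([1.0, -1.0], n_events))
        ]
        pref_events = [ev for ev in events if ev.yaw * yaw_amp + ev.pitch * pitch_amp > 0]
        head = simulate_head_trace(
            trace_duration, seed=rng.integers(2**31), events=events
        )
        spikes = simulate_motor_unit(
            head,
            events,
            PlantedUnitSpec(
                kind="motor",
                baseline_rate=baseline_rate,
                gain=gain,
                motor_yaw=yaw_amp,
                motor_pitch=pitch_amp,
            ),
            seed=rng.integers(2**31),
        )
        # planted gaze direction: project the noiseless planted displacement
        sta = compute_sta(
            np.array([ev.t - 0.05 for ev in pref_events]),
            simulate_head_trace(
                trace_duration, seed=0, ou_sigma=0.0, events=pref_events
            ),
        )
        path = project_displacement_to_gaze_path(
            sta.offsets, sta.mean[0], sta.mean[1], sta.mean[2], geometry
        )
        theta_gaze_true = gaze_preferred_direction(path)
        jitter = np.degrees(rng.vonmises(0.0, jitter_kappa))
        pref = (theta_gaze_true + 180.0 + jitter) % 360.0
        gspikes = simulate_visual_unit(
            schedule,
            PlantedUnitSpec(
                kind="visual_DS",
                baseline_rate=baseline_rate,
                gain=3.0,
                preferred_angle=pref,
                kappa=2.0,
            ),
            seed=rng.integers(2**31),
        )
        head_traces[unit] = head
        events_by_unit[unit] = events
        motor_spikes[unit] = spikes
        grating_spikes[unit] = gspikes
        truth_rows.append(
            {
                "unit_id": unit,
                "motor_angle": motor_angle,
                "yaw_amp": yaw_amp,
                "pitch_amp": pitch_amp,
                "theta_gaze_true": theta_gaze_true,
                "jitter_deg": jitter,
                "grating_pref": pref,
            }
        )

    return SyntheticSession(
        head_traces=head_traces,
        planted_events=events_by_unit,
        motor_spikes=motor_spikes,
        grating_schedule=schedule,
        grating_spikes=grating_spikes,
        ground_truth=pd.DataFrame(truth_rows),
        geometry=geometry,
        seed=seed,
    )
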