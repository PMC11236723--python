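"""Spike-triggered motor tuning, visual selectivity, and significance testing.

Implements the extracellular analysis battery for collicular units:

* spike-triggered averages (STAs) of head or eye displacement and the signed
  displacement vector summarizing each Euler axis;
* direction/orientation selectivity indices from the circular vector sum of
  baseline-normalized responses, with preferred angles;
* circular-shift shuffled nulls preserving spike count and inter-spike
  structure;
* tuning classification rules (motion: >5 deg displacement, consistent sign,
  null rank >95% in replicate trials; visual: 2-of-3 criteria on SI,
  trial-to-trial angular deviation and null rank);
* static spatial receptive-field (ssRF) mapping from flashing-square
  responses with z-scoring, shuffle significance and 2D Gaussian fits;
* locomotion splits, binocular saccade detection, and intracellular latency
  estimators (EPSP mid-slope fit; derivative-threshold visual onset).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize, signal

from .circstats import angular_deviation, wrap_deg

__all__ = [
    "SpikeTrain",
    "HeadTrace",
    "StaResult",
    "SelectivityResult",
    "TuningDecision",
    "RfMap",
    "ShuffleNull",
    "EmptyWindowError",
    "RecordingRejectedError",
    "compute_sta",
    "displacement_vector",
    "shuffle_null",
    "sta_displacement_null",
    "null_rank",
    "classify_motion_tuning",
    "selectivity",
    "classify_visual_tuning",
    "map_ssrf",
    "split_by_running",
    "pupil_to_degrees",
    "eye_movement_tuning",
    "detect_saccades",
    "epsp_latency",
    "visual_onset_latency",
]

EULER_AXES = ("yaw", "pitch", "roll")


class EmptyWindowError(ValueError):
    """No spike carries a complete pre/post analysis window."""


class RecordingRejectedError(ValueError):
    """Recording fails the baseline-noise inclusion rule."""


@dataclass
class SpikeTrain:
    """Spike times (s) for one unit, keyed by trial name."""

    unit_id: str
    trials: dict[str, np.ndarray]
    trial_durations: dict[str, float]

    def __post_init__(self) -> None:
        for name, t in self.trials.items():
            t = np.asarray(t, dtype=float)
            if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
                raise ValueError(f"trial {name!r}: spike times must be "
                                 "non-negative and strictly increasing")
            dur = self.trial_durations.get(name)
            if dur is None:
                raise ValueError(f"trial {name!r} has no duration")
            if t.size and t[-1] > dur:
                raise ValueError(f"trial {name!r}: spike time exceeds duration")
            self.trials[name] = t


@dataclass
class HeadTrace:
    """Euler-angle time series (deg) sampled uniformly (nominally 50 Hz)."""

    t: np.ndarray
    yaw: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in EULER_AXES:
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != self.t.shape:
                raise ValueError("angle arrays must match the time base")
            setattr(self, name, a)
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.ptp(dt) > 1e-6:
                raise ValueError("head trace must be uniformly sampled")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def fs(self) -> float:
        return 1.0 / self.dt

    def angles(self) -> np.ndarray:
        """(3, n) array in the (yaw, pitch, roll) axis order."""
        return np.vstack([self.yaw, self.pitch, self.roll])

    def velocities(self) -> np.ndarray:
        """Per-sample angular velocity (deg/s), (3, n), forward differences."""
        a = self.angles()
        v = np.diff(a, axis=1) / self.dt
        return np.concatenate([v, v[:, -1:]], axis=1)


@dataclass
class StaResult:
    """Spike-triggered average displacement around spike onset.

    ``mean``/``sem`` are (n_axes, pre + post + 1) in degrees on the
    ``offsets`` time base (s, 0 at the spike).  The displacement at the spike
    bin is zero by construction.  ``displacement_vectors`` holds the signed
    max-minus-min summary per axis.
    """

    offsets: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_spikes: int
    axes: tuple[str, ...] = EULER_AXES

    @property
    def displacement_vectors(self) -> np.ndarray:
        return np.array([displacement_vector(c) for c in self.mean])


def displacement_vector(curve: np.ndarray) -> float:
    """Signed displacement summary: max - min, sign from temporal order.

    Positive when the minimum precedes the maximum, negative otherwise.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.size == 0:
        raise ValueError("empty displacement curve")
    imin = int(np.argmin(curve))
    imax = int(np.argmax(curve))
    mag = float(curve[imax] - curve[imin])
    return mag if imin <= imax else -mag


def _sta_displacements(
    spike_times: np.ndarray,
    t0: float,
    dt: float,
    n_samples: int,
    angles: np.ndarray,
    pre_bins: int,
    post_bins: int,
) -> np.ndarray:
    """Per-spike displacement windows, (n_spikes, n_axes, pre+post+1)."""
    idx = np.round((np.asarray(spike_times, dtype=float) - t0) / dt).astype(int)
    ok = (idx - pre_bins >= 0) & (idx + post_bins < n_samples)
    idx = idx[ok]
    if idx.size == 0:
        raise EmptyWindowError("no spike has a complete STA window in the trace")
    offsets = np.arange(-pre_bins, post_bins + 1)
    win = idx[:, None] + offsets[None, :]           # (n_spikes, n_bins)
    gathered = angles[:, win]                        # (n_axes, n_spikes, n_bins)
    disp = gathered - gathered[:, :, pre_bins][:, :, None]
    return np.transpose(disp, (1, 0, 2))


def compute_sta(
    spike_times: np.ndarray,
    head: HeadTrace,
    pre_bins: int = 25,
    post_bins: int = 50,
) -> StaResult:
    """STA of head displacement: 25 bins (0.5 s) before and 50 (1 s) after.

    For each spike the Euler angles in the window are zeroed at spike onset
    (equivalently, the per-bin angular velocities are cumulatively summed
    into a displacement), then averaged over spikes with the s.e.m. per bin.
    Spikes without a complete window are dropped; raises
    :class:`EmptyWindowError` if none remain.
    """
    angles = head.angles()
    disp = _sta_displacements(
        spike_times, head.t[0], head.dt, head.t.size, angles, pre_bins, post_bins
    )
    n = disp.shape[0]
    mean = disp.mean(axis=0)
    sem = disp.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    offsets = np.arange(-pre_bins, post_bins + 1) * head.dt
    return StaResult(offsets=offsets, mean=mean, sem=sem, n_spikes=n)


@dataclass
class ShuffleNull:
    """Null statistic samples from circularly time-shifted spike trains."""

    samples: np.ndarray           # (n_shuffles, ...) statistic values
    shifts: np.ndarray            # the drawn shifts (s)
    min_shift: float
    max_shift: float


def shuffle_null(
    spike_times: np.ndarray,
    duration: float,
    statistic: Callable[[np.ndarray], float | np.ndarray],
    n: int = 1000,
    seed: int | np.random.Generator = 0,
    min_shift: float = 2.0,
    max_shift: float = 180.0,
) -> ShuffleNull:
    """Null distribution by wrap-around time shifts of the spike train.

    Each replicate shifts all spike times by a uniform draw from
    [min_shift, min(max_shift, duration - min_shift)] modulo the trial
    duration — preserving spike count and the circular inter-spike-interval
    multiset — and recomputes ``statistic`` on the shifted train.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    hi = min(max_shift, duration - min_shift)
    if hi <= min_shift:
        raise ValueError(
            f"trial duration {duration} s too short for shifts >= {min_shift} s"
        )
    rng = np.random.default_rng(seed)
    shifts = rng.uniform(min_shift, hi, size=n)
    samples = []
    for s in shifts:
        shifted = np.sort(np.mod(spike_times + s, duration))
        samples.append(np.asarray(statistic(shifted), dtype=float))
    return ShuffleNull(
        samples=np.stack(samples), shifts=shifts, min_shift=min_shift, max_shift=hi
    )


def sta_displacement_null(
    spike_times: np.ndarray,
    head: HeadTrace,
    duration: float,
    n: int = 1000,
    seed: int | np.random.Generator = 0,
    pre_bins: int = 25,
    post_bins: int = 50,
    min_shift: float = 2.0,
    max_shift: float = 180.0,
) -> np.ndarray:
    """Null displacement vectors from circularly shifted spike trains.

    Same null as :func:`shuffle_null` with the STA displacement-vector
    statistic, exploiting the shuffle's own wrap-around structure: with the
    trace treated circularly, the shifted-train STA at bin offset ``o`` for a
    shift of ``k`` samples is (C[k + o] - C[k]) / n_spikes where C is the
    circular cross-correlation of the spike-count histogram with the angle
    series — so every replicate comes from a single FFT.  (Windows crossing
    the trace boundary wrap instead of being dropped, consistent with the
    wrap-around shuffle itself.)  Returns an (n, n_axes) array of signed
    displacement vectors.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    hi = min(max_shift, duration - min_shift)
    if hi <= min_shift:
        raise ValueError("trial too short for the requested shift range")
    rng = np.random.default_rng(seed)
    shifts = rng.uniform(min_shift, hi, size=n)
    angles = head.angles()
    t0, dt, nsamp = head.t[0], head.dt, head.t.size

    idx0 = np.mod(np.round((spike_times - t0) / dt).astype(int), nsamp)
    hist = np.bincount(idx0, minlength=nsamp).astype(float)
    n_spk = float(idx0.size)
    if n_spk == 0:
        raise EmptyWindowError("no spikes to shuffle")
    ks = np.mod(np.round(shifts / dt).astype(int), nsamp)
    offsets = np.arange(-pre_bins, post_bins + 1)
    lag_idx = np.mod(ks[:, None] + offsets[None, :], nsamp)   # (n, n_bins)

    out = np.empty((n, angles.shape[0]))
    fh = np.fft.rfft(hist)
    for ax in range(angles.shape[0]):
        corr = np.fft.irfft(np.fft.rfft(angles[ax]) * np.conj(fh), nsamp)
        curves = (corr[lag_idx] - corr[ks][:, None]) / n_spk
        imin = np.argmin(curves, axis=1)
        imax = np.argmax(curves, axis=1)
        rowi = np.arange(n)
        mag = curves[rowi, imax] - curves[rowi, imin]
        out[:, ax] = np.where(imin <= imax, mag, -mag)
    return out


def null_rank(observed: float, null_samples: np.ndarray) -> float:
    """Fraction of null samples strictly below the observed statistic."""
    null_samples = np.asarray(null_samples, dtype=float)
    return float(np.mean(null_samples < observed))


def classify_motion_tuning(
    stas: Mapping[str, StaResult],
    nulls: Mapping[str, np.ndarray],
    light_trials: Sequence[str] = ("light1", "light2"),
    dark_trials: Sequence[str] = ("dark1", "dark2"),
    threshold_deg: float = 5.0,
    rank_threshold: float = 0.95,
) -> str:
    """Classify head-motion tuning as 'both', 'light', 'dark' or 'none'.

    A unit is tuned in a condition when, for at least one Euler axis, the
    displacement vector exceeds ``threshold_deg`` in magnitude with the same
    sign in both trials of the condition and ranks above ``rank_threshold``
    of the shuffled null in both.  A motor unit is tuned in both light and
    dark ('both').  ``nulls[trial]`` is an (n_shuffles, n_axes) array of null
    displacement-vector values.
    """
    for name in (*light_trials, *dark_trials):
        if name not in stas or name not in nulls:
            raise ValueError(f"missing trial {name!r}")

    def tuned_in(trial_pair: Sequence[str]) -> bool:
        vecs = np.array([stas[t].displacement_vectors for t in trial_pair])
        n_axes = vecs.shape[1]
        for ax in range(n_axes):
            v = vecs[:, ax]
            if np.all(np.abs(v) > threshold_deg) and len(set(np.sign(v))) == 1:
                ranks = [
                    null_rank(abs(stas[t].displacement_vectors[ax]),
                              np.abs(np.asarray(nulls[t])[:, ax]))
                    for t in trial_pair
                ]
                if all(r > rank_threshold for r in ranks):
                    return True
        return False

    light = tuned_in(light_trials)
    dark = tuned_in(dark_trials)
    if light and dark:
        return "both"
    if light:
        return "light"
    if dark:
        return "dark"
    return "none"


@dataclass
class SelectivityResult:
    """Circular vector-sum selectivity of angle-binned responses."""

    si: float
    preferred_angle: float          # deg; [0, 360) direction, [0, 180) orientation
    space: str                      # 'direction' | 'orientation'
    angular_trial_deviation: float | None = None  # rad
    null_rank: float | None = None


def selectivity(
    responses: np.ndarray,
    angles_deg: np.ndarray,
    space: str = "direction",
) -> SelectivityResult:
    """Selectivity index and preferred angle from the circular vector sum.

    SI = |sum_k R(theta_k) e^{i m theta_k} / sum_k R(theta_k)| with m = 1 in
    direction space (360 deg) and m = 2 in orientation space (180 deg); the
    preferred angle is the argument of the sum (halved in orientation space).
    Responses are baseline-normalized rates; negative values are clipped to
    zero before the sum.
    """
    if space not in ("direction", "orientation"):
        raise ValueError("space must be 'direction' or 'orientation'")
    r = np.clip(np.asarray(responses, dtype=float), 0.0, None)
    th = np.deg2rad(np.asarray(angles_deg, dtype=float))
    total = r.sum()
    if total <= 0:
        raise ValueError("all-zero responses: selectivity undefined")
    m = 1 if space == "direction" else 2
    z = np.sum(r * np.exp(1j * m * th)) / total
    ang = np.angle(z) / m
    period = 360.0 if m == 1 else 180.0
    return SelectivityResult(
        si=float(np.abs(z)),
        preferred_angle=float(np.mod(np.degrees(ang), period)),
        space=space,
    )


@dataclass
class TuningDecision:
    """2-of-3 visual tuning decision and DS/OS classification."""

    tuned: bool
    klass: str                                  # 'DS' | 'OS' | 'untuned'
    criteria_met: dict[str, tuple[bool, bool, bool]]  # per space: SI, deviation, rank
    direction: SelectivityResult | None = None
    orientation: SelectivityResult | None = None


def _trial_deviation(
    trial_responses: np.ndarray, angles_deg: np.ndarray, space: str
) -> float:
    """Circular angular deviation (rad) of per-trial preferred angles."""
    prefs = []
    for row in trial_responses:
        if np.clip(row, 0, None).sum() <= 0:
            continue
        prefs.append(selectivity(row, angles_deg, space).preferred_angle)
    if len(prefs) < 2:
        return np.inf
    prefs_rad = np.deg2rad(np.asarray(prefs))
    if space == "orientation":
        return angular_deviation(2.0 * prefs_rad) / 2.0
    return angular_deviation(prefs_rad)


def classify_visual_tuning(
    trial_responses: np.ndarray,
    angles_deg: np.ndarray,
    null_si: Mapping[str, np.ndarray] | None = None,
    si_threshold: float = 0.1,
    deviation_threshold: float = 0.8,
    rank_threshold: float = 0.95,
) -> TuningDecision:
    """Apply the 2-of-3 tuning criteria in direction and orientation space.

    Criteria per space: SI >= ``si_threshold``; trial-to-trial angular
    deviation of the preferred angle <= ``deviation_threshold`` rad; SI null
    rank > ``rank_threshold`` (only evaluable when ``null_si`` provides
    shuffle samples for that space).  A unit tuned in at least one space is
    classified DS if DSI > OSI and OS otherwise.

    ``trial_responses`` is (n_trials, n_angles); row order matches
    repetitions, columns match ``angles_deg`` (direction-space angles).
    """
    trial_responses = np.atleast_2d(np.asarray(trial_responses, dtype=float))
    if trial_responses.shape[0] < 2:
        raise ValueError("at least 2 trials required for the reliability criterion")
    mean_resp = trial_responses.mean(axis=0)

    results: dict[str, SelectivityResult] = {}
    criteria: dict[str, tuple[bool, bool, bool]] = {}
    for space in ("direction", "orientation"):
        res = selectivity(mean_resp, angles_deg, space)
        res.angular_trial_deviation = _trial_deviation(
            trial_responses, angles_deg, space
        )
        rank_ok = False
        if null_si is not None and space in null_si:
            res.null_rank = null_rank(res.si, np.asarray(null_si[space]))
            rank_ok = res.null_rank > rank_threshold
        criteria[space] = (
            res.si >= si_threshold,
            res.angular_trial_deviation <= deviation_threshold,
            rank_ok,
        )
        results[space] = res

    tuned_spaces = [s for s, c in criteria.items() if sum(c) >= 2]
    tuned = bool(tuned_spaces)
    if not tuned:
        klass = "untuned"
    else:
        dsi = results["direction"].si
        osi = results["orientation"].si
        if "direction" in tuned_spaces and "orientation" in tuned_spaces:
            klass = "DS" if dsi > osi else "OS"
        else:
            klass = "DS" if tuned_spaces == ["direction"] else "OS"
    return TuningDecision(
        tuned=tuned,
        klass=klass,
        criteria_met=criteria,
        direction=results["direction"],
        orientation=results["orientation"],
    )


# ---------------------------------------------------------------------------
# static spatial receptive fields


@dataclass
class RfMap:
    """ssRF map for one square colour: z-scored grid, significance, fit."""

    zmap: np.ndarray                    # (n_rows, n_cols) z-scored responses
    significant: bool
    max_z: float
    shuffle_rank: float
    centre: tuple[float, float] | None  # (col, row) grid coordinates
    fit_params: dict[str, float] | None
    fit_converged: bool


def _gauss2d(xy, amp, x0, y0, sx, sy, off):
    x, y = xy
    return amp * np.exp(-((x - x0) ** 2 / (2 * sx**2) + (y - y0) ** 2 / (2 * sy**2))) + off


def _fit_gaussian(zmap: np.ndarray) -> tuple[dict[str, float] | None, bool]:
    ny, nx = zmap.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    iy, ix = np.unravel_index(np.argmax(zmap), zmap.shape)
    p0 = [zmap.max() - zmap.min(), float(ix), float(iy), 1.5, 1.5, float(zmap.min())]
    bounds = (
        [0.0, -1.0, -1.0, 0.5, 0.5, -np.inf],
        [np.inf, nx, ny, nx, ny, np.inf],
    )
    try:
        popt, _ = optimize.curve_fit(
            _gauss2d,
            (xx.ravel(), yy.ravel()),
            zmap.ravel(),
            p0=p0,
            bounds=bounds,
            maxfev=5000,
        )
    except RuntimeError:
        return None, False
    keys = ("amplitude", "x0", "y0", "sigma_x", "sigma_y", "offset")
    return dict(zip(keys, popt)), True


def _square_response_map(
    spike_times: np.ndarray,
    onsets: np.ndarray,
    offsets: np.ndarray,
    cols: np.ndarray,
    rows: np.ndarray,
    baseline_rate: float,
    shape: tuple[int, int],
    standardize: bool = True,
) -> np.ndarray:
    """Mean rate over baseline per grid location, optionally z-scored."""
    counts = np.searchsorted(spike_times, offsets) - np.searchsorted(spike_times, onsets)
    rates = counts / (offsets - onsets)
    grid = np.zeros(shape)
    nrep = np.zeros(shape)
    np.add.at(grid, (rows, cols), rates)
    np.add.at(nrep, (rows, cols), 1)
    with np.errstate(invalid="ignore"):
        grid = np.where(nrep > 0, grid / np.maximum(nrep, 1), 0.0)
    grid = grid / baseline_rate
    if not standardize:
        return grid
    sd = grid.std()
    if sd == 0:
        return np.zeros(shape)
    return (grid - grid.mean()) / sd


def map_ssrf(
    spike_times: np.ndarray,
    duration: float,
    onsets: np.ndarray,
    offsets: np.ndarray,
    cols: np.ndarray,
    rows: np.ndarray,
    baseline_rate: float,
    grid_shape: tuple[int, int] = (11, 15),
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
    z_threshold: float = 2.0,
    rank_threshold: float = 0.95,
) -> RfMap:
    """Map a static spatial receptive field from flashing-square responses.

    The firing rate during each flash, averaged per grid location and
    divided by the baseline rate, gives a response-over-baseline matrix that
    is z-scored over the grid.  The map is significant when the maximal z
    exceeds ``z_threshold`` AND ranks above ``rank_threshold`` of the maxima
    from ``n_shuffles`` circularly time-shifted spike trains; significant
    maps are summarized by a least-squares elliptical 2D Gaussian whose
    centre is the RF centre (falling back to the argmax cell if the fit does
    not converge).  One colour (black or white) is analysed per call.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    cols = np.asarray(cols, dtype=int)
    rows = np.asarray(rows, dtype=int)

    resp = _square_response_map(
        spike_times, onsets, offsets, cols, rows, baseline_rate, grid_shape,
        standardize=False,
    )
    sd = resp.std()
    zmap = (resp - resp.mean()) / sd if sd > 0 else np.zeros_like(resp)
    max_z = float(zmap.max())

    # Rank criterion on the common response scale (max elevation over the
    # grid mean, in response-over-baseline units).  Z-scoring each shuffled
    # map by its own s.d. would let sparse shuffled maps (one relocated
    # burst on a flat background) produce extreme max-z while a genuinely
    # structured RF inflates its own s.d. — destroying power exactly for
    # responsive units while leaving false positives unchanged.
    def stat(shifted: np.ndarray) -> float:
        m = _square_response_map(
            shifted, onsets, offsets, cols, rows, baseline_rate, grid_shape,
            standardize=False,
        )
        return float(m.max() - m.mean())

    null = shuffle_null(spike_times, duration, stat, n=n_shuffles, seed=seed)
    rank = null_rank(float(resp.max() - resp.mean()), null.samples)
    significant = (max_z > z_threshold) and (rank > rank_threshold)

    centre = None
    fit_params = None
    converged = False
    if significant:
        fit_params, converged = _fit_gaussian(zmap)
        if converged:
            centre = (fit_params["x0"], fit_params["y0"])
        else:
            iy, ix = np.unravel_index(np.argmax(zmap), zmap.shape)
            centre = (float(ix), float(iy))
    return RfMap(
        zmap=zmap,
        significant=significant,
        max_z=max_z,
        shuffle_rank=rank,
        centre=centre,
        fit_params=fit_params,
        fit_converged=converged,
    )


# ---------------------------------------------------------------------------
# locomotion, eye movements


def split_by_running(
    windows: np.ndarray,
    wheel_t: np.ndarray,
    wheel_velocity: np.ndarray,
    threshold: float = 20.0,
    cutoff_hz: float = 1.0,
) -> np.ndarray:
    """Label each presentation window as run (True) or rest (False).

    The wheel angular velocity (deg/s) is low-pass filtered (2nd-order
    Butterworth) and averaged over each window; run trials are those whose
    mean exceeds ``threshold`` deg/s.
    """
    windows = np.atleast_2d(np.asarray(windows, dtype=float))
    wheel_t = np.asarray(wheel_t, dtype=float)
    wheel_velocity = np.asarray(wheel_velocity, dtype=float)
    if windows[:, 0].min() < wheel_t[0] or windows[:, 1].max() > wheel_t[-1]:
        raise ValueError("wheel trace does not cover every presentation window")
    fs = 1.0 / np.median(np.diff(wheel_t))
    sos = signal.butter(2, cutoff_hz, fs=fs, output="sos")
    smooth = signal.sosfiltfilt(sos, wheel_velocity)
    labels = np.empty(windows.shape[0], dtype=bool)
    for i, (a, b) in enumerate(windows):
        mask = (wheel_t >= a) & (wheel_t <= b)
        labels[i] = float(np.mean(smooth[mask])) > threshold
    return labels


def pupil_to_degrees(displacement: np.ndarray, eye_radius: float) -> np.ndarray:
    """Angular eye position alpha = atan(d / r) in degrees.

    ``displacement`` is pupil travel in the same length units as the eye
    radius (sphere approximation).
    """
    return np.degrees(np.arctan(np.asarray(displacement, dtype=float) / eye_radius))


@dataclass
class EyeTuningResult:
    tuned: bool
    sta: StaResult
    ranks: np.ndarray


def eye_movement_tuning(
    spike_times: np.ndarray,
    eye_t: np.ndarray,
    pupil_xy: np.ndarray,
    eye_radius: float,
    duration: float,
    pre_bins: int = 25,
    post_bins: int = 50,
    threshold_deg: float = 1.0,
    rank_threshold: float = 0.95,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
) -> EyeTuningResult:
    """STA-based eye-movement tuning on the two pupil axes.

    Pupil positions (length units) are converted to angular position via the
    spherical-eye approximation and run through the same spike-triggered
    machinery as head displacements; the unit is tuned when at least one
    component's displacement vector exceeds ``threshold_deg`` with a null
    rank above ``rank_threshold``.
    """
    eye_t = np.asarray(eye_t, dtype=float)
    pupil_xy = np.atleast_2d(np.asarray(pupil_xy, dtype=float))
    if pupil_xy.shape[0] != 2:
        pupil_xy = pupil_xy.T
    deg = pupil_to_degrees(pupil_xy, eye_radius)
    trace = HeadTrace(t=eye_t, yaw=deg[0], pitch=deg[1], roll=np.zeros_like(eye_t))
    sta = compute_sta(spike_times, trace, pre_bins, post_bins)

    def stat(shifted: np.ndarray) -> np.ndarray:
        s = compute_sta(shifted, trace, pre_bins, post_bins)
        return np.abs(s.displacement_vectors[:2])

    null = shuffle_null(spike_times, duration, stat, n=n_shuffles, seed=seed)
    obs = np.abs(sta.displacement_vectors[:2])
    ranks = np.array(
        [null_rank(obs[i], null.samples[:, i]) for i in range(2)]
    )
    tuned = bool(np.any((obs > threshold_deg) & (ranks > rank_threshold)))
    return EyeTuningResult(tuned=tuned, sta=sta, ranks=ranks)


def detect_saccades(
    t: np.ndarray,
    vel_left: np.ndarray,
    vel_right: np.ndarray,
    threshold: float = 350.0,
) -> np.ndarray:
    """Binocular saccade onsets: both eye speeds exceed 350 deg/s together.

    Consecutive supra-threshold samples merge into a single event; the event
    time is the first sample of each run.
    """
    t = np.asarray(t, dtype=float)
    mask = (np.abs(np.asarray(vel_left, dtype=float)) > threshold) & (
        np.abs(np.asarray(vel_right, dtype=float)) > threshold
    )
    if not mask.any():
        return np.empty(0)
    edges = np.flatnonzero(np.diff(np.concatenate([[False], mask]).astype(int)) == 1)
    return t[edges]


# ---------------------------------------------------------------------------
# intracellular latency extraction


def epsp_latency(
    t_ms: np.ndarray,
    vm: np.ndarray,
    stim_onset_ms: float,
    min_amplitude: float = 0.5,
) -> float | None:
    """EPSP onset latency from a linear fit through the mid-rising slope.

    A line is fit through the samples lying in the 25-30% and 70-75% bands
    of the peak amplitude on the first rising slope after stimulus onset
    (band crossings are interpolated when sampling is coarse); the latency is
    the time where that line crosses the resting potential, minus stimulus
    onset.  Returns None when the peak is below ``min_amplitude`` mV over
    rest (no response).
    """
    t_ms = np.asarray(t_ms, dtype=float)
    vm = np.asarray(vm, dtype=float)
    pre = t_ms < stim_onset_ms
    if not pre.any():
        raise ValueError("no baseline samples before stimulus onset")
    rest = float(vm[pre].mean())
    post = t_ms >= stim_onset_ms
    rel = vm[post] - rest
    tt = t_ms[post]
    peak_idx = int(np.argmax(rel))
    peak = float(rel[peak_idx])
    if peak < min_amplitude:
        return None
    # restrict to the first rising slope: up to first crossing of 75% of peak
    frac = rel / peak
    above75 = np.flatnonzero(frac >= 0.75)
    end = above75[0] if above75.size else peak_idx
    seg_t, seg_f = tt[: end + 1], frac[: end + 1]

    pts_t: list[float] = []
    pts_v: list[float] = []
    for lo, hi in ((0.25, 0.30), (0.70, 0.75)):
        in_band = (seg_f >= lo) & (seg_f <= hi)
        pts_t.extend(seg_t[in_band])
        pts_v.extend(seg_f[in_band] * peak)
        for level in (lo, hi):
            cross = np.flatnonzero((seg_f[:-1] < level) & (seg_f[1:] >= level))
            for c in cross[:1]:
                tc = np.interp(level, [seg_f[c], seg_f[c + 1]], [seg_t[c], seg_t[c + 1]])
                pts_t.append(float(tc))
                pts_v.append(level * peak)
    if len(pts_t) < 2:
        return None
    slope, intercept = np.polyfit(pts_t, pts_v, 1)
    if slope <= 0:
        return None
    t_cross = -intercept / slope  # where the fit line meets rest (rel = 0)
    return float(t_cross - stim_onset_ms)


def visual_onset_latency(
    t_ms: np.ndarray,
    vm_repeats: np.ndarray,
    baseline_window_ms: tuple[float, float],
    stim_onset_ms: float = 0.0,
    min_slope: float = 0.5,
    sd_factor: float = 3.0,
    max_baseline_sd: float = 1.5,
) -> np.ndarray:
    """Per-repeat visual response latency from a derivative threshold.

    The membrane-potential derivative during the baseline window gives the
    s.d. of baseline presynaptic activity; recordings with s.d. above
    ``max_baseline_sd`` are rejected.  For each repeat the latency is the
    first post-stimulus time where the derivative exceeds
    max(``sd_factor`` x s.d., ``min_slope`` mV/ms); repeats with no such
    event yield NaN.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    vm_repeats = np.atleast_2d(np.asarray(vm_repeats, dtype=float))
    dt = float(np.median(np.diff(t_ms)))
    deriv = np.gradient(vm_repeats, dt, axis=1)
    base = (t_ms >= baseline_window_ms[0]) & (t_ms < baseline_window_ms[1])
    if not base.any():
        raise ValueError("empty baseline window")
    sd = float(deriv[:, base].std())
    if sd > max_baseline_sd:
        raise RecordingRejectedError(
            f"baseline derivative s.d. {sd:.2f} mV/ms exceeds {max_baseline_sd}"
        )
    thr = max(sd_factor * sd, min_slope)
    post = t_ms >= stim_onset_ms
    out = np.full(vm_repeats.shape[0], np.nan)
    for i, d in enumerate(deriv):
        hits = np.flatnonzero(post & (d > thr))
        if hits.size:
            out[i] = t_ms[hits[0]] - stim_onset_ms
    return out
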