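"""Session I/O, analysis configuration, and pipeline orchestration.

A session directory holds delimited-text tables (head traces, spike trains,
stimulus events, ground truth) plus a YAML config and a seed manifest; all
tables share a master clock.  The pipeline runs the extracellular analysis
stages in dependency order — motion tuning (STA + shuffled null), visual
tuning (grating selectivity + shuffled null), and visuo-motor alignment
(gaze projection + population circular statistics) — and writes per-unit
results and a population summary with a versioned header recording the
package version, config hash and seeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import (
    alignment_offset,
    gaze_preferred_direction,
    population_stats,
    watson_williams_vs_controls,
)
from .geometry import GeometryConfig, project_displacement_to_gaze_path
from .synth import StimulusSchedule, SyntheticSession
from .tuning import (
    HeadTrace,
    classify_visual_tuning,
    compute_sta,
    null_rank,
    selectivity,
    shuffle_null,
    sta_displacement_null,
)

__all__ = [
    "AnalysisConfig",
    "SessionBundle",
    "save_session",
    "load_session",
    "grating_trial_responses",
    "analyze_session",
    "run_pipeline",
    "write_results",
    "config_hash",
]

STAGES = ("motion", "visual", "alignment")


@dataclass
class AnalysisConfig:
    """Every analysis threshold in one place (defaults are the study values)."""

    motion_threshold_deg: float = 5.0
    eye_threshold_deg: float = 1.0
    si_threshold: float = 0.1
    deviation_threshold_rad: float = 0.8
    rank_threshold: float = 0.95
    rf_z_threshold: float = 2.0
    run_speed_threshold: float = 20.0      # deg/s
    saccade_threshold: float = 350.0       # deg/s
    n_shuffles_motion: int = 1000
    n_shuffles_visual: int = 1000
    n_boot: int = 1000
    sta_pre_bins: int = 25
    sta_post_bins: int = 50

    def to_dict(self) -> dict:
        return asdict(self)


def config_hash(cfg: AnalysisConfig) -> str:
    """Stable hash over the canonicalized config (changes with any threshold)."""
    canon = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class SessionBundle:
    """Validated handle on a session directory's tables."""

    path: Path
    head_traces: dict[str, HeadTrace]
    motor_spikes: dict[str, np.ndarray]
    grating_spikes: dict[str, np.ndarray]
    grating_schedule: StimulusSchedule
    ground_truth: pd.DataFrame | None
    geometry: GeometryConfig
    seed: int


def save_session(session: SyntheticSession, path: str | Path) -> Path:
    """Write a synthetic session to a directory of delimited-text tables."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    head_rows = []
    for unit, tr in session.head_traces.items():
        head_rows.append(
            pd.DataFrame(
                {"unit_id": unit, "t": tr.t, "yaw": tr.yaw, "pitch": tr.pitch,
                 "roll": tr.roll}
            )
        )
    pd.concat(head_rows, ignore_index=True).to_csv(path / "head.csv", index=False)

    spike_rows = []
    for unit, s in session.motor_spikes.items():
        spike_rows.append(pd.DataFrame({"unit_id": unit, "trial": "foraging", "t": s}))
    for unit, s in session.grating_spikes.items():
        spike_rows.append(pd.DataFrame({"unit_id": unit, "trial": "gratings", "t": s}))
    pd.concat(spike_rows, ignore_index=True).to_csv(path / "spikes.csv", index=False)

    ev = session.grating_schedule.events.copy()
    ev.insert(0, "kind", session.grating_schedule.kind)
    ev.to_csv(path / "events.csv", index=False)

    session.ground_truth.to_csv(path / "ground_truth.csv", index=False)

    geo = session.geometry
    config = {
        "geometry": {
            "screen_distance": geo.screen_distance,
            "screen_x0": geo.screen_plane.x0,
            "screen_y0": geo.screen_plane.y0,
            "pupil_offset": list(geo.pupil_offset),
            "gaze_direction": list(geo.gaze_direction),
        },
        "grating_duration": session.grating_schedule.duration,
    }
    (path / "config.yaml").write_text(yaml.safe_dump(config))
    (path / "manifest.json").write_text(json.dumps({"seed": session.seed}))
    return path


def load_session(path: str | Path) -> SessionBundle:
    """Load and validate a session directory.

    Raises a descriptive error naming the offending file/column on schema
    violations (missing tables, unsorted spike times).
    """
    from .geometry import ScreenPlane

    path = Path(path)
    for fname in ("head.csv", "spikes.csv", "events.csv", "config.yaml",
                  "manifest.json"):
        if not (path / fname).exists():
            raise FileNotFoundError(f"session table missing: {fname}")

    config = yaml.safe_load((path / "config.yaml").read_text())
    g = config["geometry"]
    geometry = GeometryConfig(
        screen_distance=g["screen_distance"],
        screen_plane=ScreenPlane(g["screen_x0"], g["screen_y0"]),
        pupil_offset=tuple(g["pupil_offset"]),
        gaze_direction=tuple(g["gaze_direction"]),
    )
    seed = int(json.loads((path / "manifest.json").read_text())["seed"])

    head = pd.read_csv(path / "head.csv")
    traces = {}
    for unit, grp in head.groupby("unit_id"):
        traces[unit] = HeadTrace(
            t=grp["t"].to_numpy(),
            yaw=grp["yaw"].to_numpy(),
            pitch=grp["pitch"].to_numpy(),
            roll=grp["roll"].to_numpy(),
        )

    spikes = pd.read_csv(path / "spikes.csv")
    motor, gratings = {}, {}
    for (unit, trial), grp in spikes.groupby(["unit_id", "trial"]):
        t = grp["t"].to_numpy(float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError(f"spikes.csv: unsorted spike times for {unit}/{trial}")
        (motor if trial == "foraging" else gratings)[unit] = t

    ev = pd.read_csv(path / "events.csv")
    kind = str(ev["kind"].iloc[0]) if len(ev) else "gratings"
    schedule = StimulusSchedule(
        kind=kind,
        events=ev.drop(columns=["kind"]),
        duration=float(config["grating_duration"]),
    )
    truth = None
    if (path / "ground_truth.csv").exists():
        truth = pd.read_csv(path / "ground_truth.csv")
    return SessionBundle(
        path=path,
        head_traces=traces,
        motor_spikes=motor,
        grating_spikes=gratings,
        grating_schedule=schedule,
        ground_truth=truth,
        geometry=geometry,
        seed=seed,
    )


def grating_trial_responses(
    spike_times: np.ndarray,
    schedule: StimulusSchedule,
    baseline_rate: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Baseline-normalized per-trial grating responses.

    Firing rate during the drifting phase of each presentation, averaged per
    (trial, direction), divided by the baseline rate.  When no baseline is
    supplied it is estimated from the static (pre-drift) phases of all
    presentations.  Returns (responses (n_trials, n_angles), angles_deg,
    baseline_rate).
    """
    ev = schedule.events
    spike_times = np.asarray(spike_times, dtype=float)
    on = ev["drift_onset"].to_numpy(float)
    off = ev["drift_offset"].to_numpy(float)
    counts = np.searchsorted(spike_times, off) - np.searchsorted(spike_times, on)
    rates = counts / (off - on)
    if baseline_rate is None:
        s_on = ev["onset"].to_numpy(float)
        s_off = ev["drift_onset"].to_numpy(float)
        base_counts = np.searchsorted(spike_times, s_off) - np.searchsorted(
            spike_times, s_on
        )
        baseline_rate = float(base_counts.sum() / (s_off - s_on).sum())
    if baseline_rate <= 0:
        baseline_rate = 1e-9
    df = pd.DataFrame(
        {"trial": ev["trial"].to_numpy(int), "angle": ev["angle"].to_numpy(float),
         "rate": rates}
    )
    pivot = df.pivot_table(index="trial", columns="angle", values="rate", aggfunc="mean")
    angles = pivot.columns.to_numpy(float)
    responses = pivot.to_numpy(float) / baseline_rate
    return responses, angles, baseline_rate


def _grating_si_null(
    spike_times: np.ndarray,
    schedule: StimulusSchedule,
    baseline_rate: float,
    n: int,
    seed,
) -> dict[str, np.ndarray]:
    """Shuffled-SI null distributions in both angular spaces.

    Same circular-shift null as :func:`collikinetics.tuning.shuffle_null`
    with the SI statistic, with the per-replicate response binning done in
    numpy for speed.
    """
    ev = schedule.events
    on = ev["drift_onset"].to_numpy(float)
    off = ev["drift_offset"].to_numpy(float)
    angles = ev["angle"].to_numpy(float)
    uniq, group = np.unique(angles, return_inverse=True)
    th = np.deg2rad(uniq)
    e1 = np.exp(1j * th)
    e2 = np.exp(2j * th)
    n_per_group = np.bincount(group).astype(float)
    dur = off - on

    def stat(shifted: np.ndarray) -> np.ndarray:
        rates = (
            np.searchsorted(shifted, off) - np.searchsorted(shifted, on)
        ) / dur
        mean = np.bincount(group, weights=rates) / n_per_group / baseline_rate
        total = mean.sum()
        if total <= 0:
            return np.zeros(2)
        return np.array(
            [abs(mean @ e1) / total, abs(mean @ e2) / total]
        )

    null = shuffle_null(spike_times, schedule.duration, stat, n=n, seed=seed)
    return {"direction": null.samples[:, 0], "orientation": null.samples[:, 1]}


def analyze_session(
    bundle: SessionBundle | SyntheticSession,
    cfg: AnalysisConfig | None = None,
    seed: int = 0,
    stages: tuple[str, ...] = STAGES,
) -> dict:
    """Run the requested analysis stages on a session.

    Stages: ``motion`` (STA, displacement vectors, shuffled-null tuning
    decision), ``visual`` (grating selectivity, 2-of-3 tuning decision),
    ``alignment`` (gaze projection, per-unit offsets, population circular
    statistics; requires the other two).  Returns a dict with the per-unit
    table (``units``), and — when alignment ran — ``population`` and
    ``watson_williams``.
    """
    cfg = cfg if cfg is not None else AnalysisConfig()
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if "alignment" in stages and not {"motion", "visual"} <= set(stages):
        raise ValueError("alignment requires the motion and visual stages")

    geometry = bundle.geometry
    units = sorted(
        set(bundle.motor_spikes) | set(bundle.grating_spikes)
    )
    rng = np.random.default_rng(seed)
    rows = []
    for unit in units:
        row: dict = {"unit_id": unit}
        theta_gaze = np.nan
        if "motion" in stages and unit in bundle.motor_spikes:
            head = bundle.head_traces[unit]
            duration = float(head.t[-1] + head.dt)
            sta = compute_sta(
                bundle.motor_spikes[unit], head, cfg.sta_pre_bins, cfg.sta_post_bins
            )
            null = sta_displacement_null(
                bundle.motor_spikes[unit],
                head,
                duration,
                n=cfg.n_shuffles_motion,
                seed=rng.integers(2**31),
                pre_bins=cfg.sta_pre_bins,
                post_bins=cfg.sta_post_bins,
            )
            vecs = sta.displacement_vectors
            ranks = np.array(
                [null_rank(abs(v), np.abs(null[:, i])) for i, v in enumerate(vecs)]
            )
            motion_tuned = bool(
                np.any(
                    (np.abs(vecs) > cfg.motion_threshold_deg)
                    & (ranks > cfg.rank_threshold)
                )
            )
            row.update(
                yaw_vector=vecs[0], pitch_vector=vecs[1], roll_vector=vecs[2],
                motion_ranks=float(ranks.max()), motion_tuned=motion_tuned,
                n_spikes=sta.n_spikes,
            )
            try:
                path = project_displacement_to_gaze_path(
                    sta.offsets, sta.mean[0], sta.mean[1], sta.mean[2], geometry
                )
                theta_gaze = gaze_preferred_direction(path)
            except ValueError:
                theta_gaze = np.nan
            row["theta_gaze"] = theta_gaze
        if "visual" in stages and unit in bundle.grating_spikes:
            resp, angles, base = grating_trial_responses(
                bundle.grating_spikes[unit], bundle.grating_schedule
            )
            null_si = _grating_si_null(
                bundle.grating_spikes[unit],
                bundle.grating_schedule,
                base,
                cfg.n_shuffles_visual,
                rng.integers(2**31),
            )
            decision = classify_visual_tuning(
                resp, angles, null_si,
                si_threshold=cfg.si_threshold,
                deviation_threshold=cfg.deviation_threshold_rad,
                rank_threshold=cfg.rank_threshold,
            )
            row.update(
                dsi=decision.direction.si,
                osi=decision.orientation.si,
                theta_gratings=decision.direction.preferred_angle,
                visual_tuned=decision.tuned,
                visual_class=decision.klass,
            )
            if "alignment" in stages and np.isfinite(theta_gaze):
                row["delta"] = alignment_offset(
                    theta_gaze, decision.direction.preferred_angle
                )
        rows.append(row)

    units_df = pd.DataFrame(rows)
    out: dict = {"units": units_df, "config": cfg, "seed": seed}
    if "alignment" in stages and "delta" in units_df.columns:
        mask = (
            units_df.get("motion_tuned", False)
            & units_df.get("visual_tuned", False)
            & units_df["delta"].notna()
        )
        deltas = units_df.loc[mask, "delta"].to_numpy(float)
        out["n_aligned_units"] = int(deltas.size)
        if deltas.size >= 5:
            out["population"] = population_stats(
                deltas, n_boot=cfg.n_boot, seed=rng.integers(2**31)
            )
            out["watson_williams"] = watson_williams_vs_controls(
                deltas, seed=rng.integers(2**31)
            )
    return out


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    cfg: AnalysisConfig,
    seed: int,
) -> list[Path]:
    """Write result tables as delimited text with a versioned header.

    Each file starts with comment lines recording the package version, the
    config hash and the seed; ``pd.read_csv(..., comment='#')`` round-trips
    the table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = (
        f"# collikinetics {__version__}\n"
        f"# config_hash: {config_hash(cfg)}\n"
        f"# seed: {seed}\n"
    )
    written = []
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        with open(p, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
        written.append(p)
    return written


def run_pipeline(
    bundle: SessionBundle | SyntheticSession,
    out_dir: str | Path,
    stages: tuple[str, ...] = STAGES,
    cfg: AnalysisConfig | None = None,
    seed: int = 0,
) -> dict:
    """Analyze a session and write the per-unit and population tables."""
    cfg = cfg if cfg is not None else AnalysisConfig()
    result = analyze_session(bundle, cfg, seed=seed, stages=stages)
    tables = {"units": result["units"]}
    if "population" in result:
        pop = result["population"]
        tables["population"] = pd.DataFrame(
            [
                {
                    "n": pop.n,
                    "circular_mean_deg": pop.circular_mean,
                    "rayleigh_z": pop.rayleigh_z,
                    "rayleigh_p": pop.rayleigh_p,
                    "boot_mean_deg": pop.boot_mean,
                    "boot_ci_low": pop.boot_ci[0],
                    "boot_ci_high": pop.boot_ci[1],
                    "n_boot": pop.n_boot,
                }
            ]
        )
    if "watson_williams" in result:
        tables["watson_williams"] = pd.DataFrame(
            [
                {
                    "centre_deg": c,
                    "f_stat": r.f_stat,
                    "p_value": r.p_value,
                    "critical_value": r.critical_value,
                    "similar": r.similar,
                }
                for c, r in result["watson_williams"].items()
            ]
        )
    result["written"] = write_results(tables, out_dir, cfg, seed)
    return result
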