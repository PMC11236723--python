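"""End-to-end recovery and false-positive-rate benchmarks on planted data.

Monte Carlo studies exercising each analysis stage against the synthetic
ground truth: direction-selectivity recovery, false-positive rates on
untuned units, ssRF-centre recovery, geometric agreement with a numeric
ray-marching oracle, and full-pipeline recovery of a planted anti-aligned
visuo-motor population.  Used by the test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np

from . import circstats as cs
from .geometry import (
    BehindScreenError,
    EulerAngles,
    GazeRay,
    NoIntersectionError,
    ScreenPlane,
    euler_from_rotation,
    gaze_screen_intersection,
    rotation_from_euler,
)
from .session import AnalysisConfig, _grating_si_null, analyze_session, grating_trial_responses
from .synth import (
    PlantedUnitSpec,
    make_schedule,
    simulate_visual_unit,
    simulate_visuomotor_population,
)
from .tuning import classify_visual_tuning, map_ssrf

__all__ = [
    "ds_recovery_benchmark",
    "visual_fpr_benchmark",
    "ssrf_recovery_benchmark",
    "geometry_agreement_benchmark",
    "alignment_recovery_benchmark",
]


def ds_recovery_benchmark(
    n_units: int = 100,
    seed: int = 0,
    kappa: float = 2.0,
    gain: float = 3.0,
    n_shuffles: int = 1000,
) -> dict:
    """Recovery of planted direction-selective units from grating responses.

    Each unit gets a random preferred direction (von Mises tuning, Poisson
    spiking); success requires classification as tuned with the preferred
    direction recovered within 15 degrees.
    """
    rng = np.random.default_rng(seed)
    schedule = make_schedule("gratings", seed=rng.integers(2**31))
    hits, errs = 0, []
    for _ in range(n_units):
        pref = rng.uniform(0.0, 360.0)
        spec = PlantedUnitSpec(
            kind="visual_DS", baseline_rate=5.0, gain=gain,
            preferred_angle=pref, kappa=kappa,
        )
        spikes = simulate_visual_unit(schedule, spec, seed=rng.integers(2**31))
        resp, angles, base = grating_trial_responses(spikes, schedule)
        nulls = _grating_si_null(spikes, schedule, base, n_shuffles,
                                 rng.integers(2**31))
        dec = classify_visual_tuning(resp, angles, nulls)
        err = abs(cs.circ_distance(dec.direction.preferred_angle, pref, degrees=True))
        errs.append(err)
        if dec.tuned and err <= 15.0:
            hits += 1
    return {
        "rate": hits / n_units,
        "median_error_deg": float(np.median(errs)),
        "n": n_units,
    }


def visual_fpr_benchmark(
    n_units: int = 200, seed: int = 0, n_shuffles: int = 1000
) -> dict:
    """False-positive rate of the 2-of-3 tuning decision on untuned units."""
    rng = np.random.default_rng(seed)
    schedule = make_schedule("gratings", seed=rng.integers(2**31))
    fp = 0
    for _ in range(n_units):
        spec = PlantedUnitSpec(kind="untuned", baseline_rate=5.0, gain=0.0)
        spikes = simulate_visual_unit(schedule, spec, seed=rng.integers(2**31))
        resp, angles, base = grating_trial_responses(spikes, schedule)
        nulls = _grating_si_null(spikes, schedule, base, n_shuffles,
                                 rng.integers(2**31))
        if classify_visual_tuning(resp, angles, nulls).tuned:
            fp += 1
    return {"rate": fp / n_units, "n": n_units}


def ssrf_recovery_benchmark(
    n_units: int = 50, seed: int = 0, n_shuffles: int = 1000
) -> dict:
    """Recovery of planted Gaussian ssRF centres within one grid cell."""
    rng = np.random.default_rng(seed)
    schedule = make_schedule("squares", seed=rng.integers(2**31))
    ev = schedule.events
    black = ev[ev["colour"] == "black"]
    hits = 0
    for _ in range(n_units):
        centre = (rng.uniform(2.0, 12.0), rng.uniform(2.0, 8.0))
        spec = PlantedUnitSpec(
            kind="ssRF", baseline_rate=5.0, gain=5.0,
            rf_centre=centre, rf_sigma=1.5,
        )
        spikes = simulate_visual_unit(schedule, spec, seed=rng.integers(2**31))
        rf = map_ssrf(
            spikes,
            schedule.duration,
            black["onset"].to_numpy(),
            black["offset"].to_numpy(),
            black["col"].to_numpy(),
            black["row"].to_numpy(),
            baseline_rate=5.0,
            n_shuffles=n_shuffles,
            seed=rng.integers(2**31),
        )
        if (
            rf.significant
            and rf.centre is not None
            and abs(rf.centre[0] - centre[0]) <= 1.0
            and abs(rf.centre[1] - centre[1]) <= 1.0
        ):
            hits += 1
    return {"rate": hits / n_units, "n": n_units}


def _raymarch(ray: GazeRay, R: np.ndarray, plane: ScreenPlane, m_max: float = 500.0):
    """Numeric oracle: bracket the plane-residual sign change, then refine."""
    p0 = R @ ray.origin_head
    d = R @ ray.direction_head
    lo, hi = 0.0, m_max
    for _ in range(4):
        ms = np.linspace(lo, hi, 4096)
        res = plane.y0 * (p0[0] + ms * d[0] - plane.x0) + plane.x0 * (
            p0[1] + ms * d[1]
        )
        i = np.flatnonzero(np.sign(res[:-1]) != np.sign(res[1:]))
        if i.size == 0:
            return None
        lo, hi = ms[i[0]], ms[i[0] + 1]
    return p0 + 0.5 * (lo + hi) * d


def geometry_agreement_benchmark(n_configs: int = 1000, seed: int = 0) -> dict:
    """Ray-plane intersections vs the marching oracle; Euler round trips."""
    rng = np.random.default_rng(seed)
    max_isect = 0.0
    checked = 0
    while checked < n_configs:
        R = rotation_from_euler(EulerAngles(*rng.uniform(-0.6, 0.6, 3)))
        plane = ScreenPlane(rng.uniform(5, 40), rng.uniform(5, 40))
        ray = GazeRay(rng.uniform(-2, 2, 3), np.array([1.0, 0.0, 0.0]))
        try:
            p = gaze_screen_intersection(ray, R, plane)
        except (NoIntersectionError, BehindScreenError):
            continue
        q = _raymarch(ray, R, plane)
        if q is None:
            continue
        max_isect = max(max_isect, float(np.linalg.norm(p - q)))
        checked += 1

    max_euler = 0.0
    for _ in range(n_configs):
        phi, psi = rng.uniform(-np.pi + 1e-3, np.pi - 1e-3, 2)
        theta = rng.uniform(-np.pi / 2 + 1e-3, np.pi / 2 - 1e-3)
        R = rotation_from_euler(EulerAngles(phi, theta, psi))
        R2 = rotation_from_euler(euler_from_rotation(R))
        max_euler = max(max_euler, float(np.abs(R2 - R).max()))
    return {
        "max_intersection_error": max_isect,
        "max_roundtrip_error": max_euler,
        "n": n_configs,
    }


def alignment_recovery_benchmark(
    n_seeds: int = 100,
    n_units: int = 33,
    jitter_kappa: float = 2.0,
    seed: int = 0,
    cfg: AnalysisConfig | None = None,
) -> dict:
    """Full-pipeline recovery of a planted anti-aligned population.

    For each seed, generates the population, runs the complete analysis
    (motion STA + null, gaze projection, grating selectivity + null,
    population circular statistics, Watson-Williams controls) and scores:
    bootstrap circular mean within 10 degrees of 180; Rayleigh p < 0.05;
    Watson-Williams F at the 180-degree control below the F at 0 degrees.
    """
    cfg = cfg if cfg is not None else AnalysisConfig()
    rng = np.random.default_rng(seed)
    within10, rayleigh_sig, ww_order, means = 0, 0, 0, []
    for _ in range(n_seeds):
        s = int(rng.integers(2**31))
        sess = simulate_visuomotor_population(
            n_units=n_units, jitter_kappa=jitter_kappa, seed=s
        )
        res = analyze_session(sess, cfg, seed=s)
        pop = res.get("population")
        if pop is None:
            continue
        err = abs(cs.circ_distance(pop.boot_mean, 180.0, degrees=True))
        means.append(pop.boot_mean)
        if err <= 10.0:
            within10 += 1
        if pop.rayleigh_p < 0.05:
            rayleigh_sig += 1
        ww = res.get("watson_williams", {})
        if ww and ww[180.0].f_stat < ww[0.0].f_stat:
            ww_order += 1
    mean_of_means = float(
        np.degrees(cs.circ_mean(np.deg2rad(np.asarray(means))))
    )
    return {
        "within_10deg_rate": within10 / n_seeds,
        "rayleigh_sig_rate": rayleigh_sig / n_seeds,
        "ww_order_rate": ww_order / n_seeds,
        "population_mean_deg": mean_of_means,
        "n_seeds": n_seeds,
    }
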