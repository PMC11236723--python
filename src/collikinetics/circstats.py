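"""Circular statistics: means, deviations, Rayleigh, Watson-Williams, bootstrap.

Wraps pingouin for the standard quantities (circular mean, resultant length,
Rayleigh test) and adds what it lacks: circular angular deviation, a
von Mises concentration estimate, the two-sample Watson-Williams test, and a
seeded bootstrap of the circular mean.  Angles are radians throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pingouin as pg
from scipy import optimize, special, stats

__all__ = [
    "circ_mean",
    "circ_r",
    "angular_deviation",
    "rayleigh_test",
    "kappa_from_r",
    "circ_std",
    "bootstrap_circ_mean",
    "watson_williams",
    "WatsonWilliamsResult",
    "wrap_deg",
    "wrap_rad",
    "circ_distance",
]


def wrap_rad(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) to [0, 2*pi)."""
    return np.mod(a, 2.0 * np.pi)


def wrap_deg(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) to [0, 360)."""
    return np.mod(a, 360.0)


def circ_distance(a: float, b: float, degrees: bool = False) -> float:
    """Signed circular difference a - b wrapped to (-half, half]."""
    full = 360.0 if degrees else 2.0 * np.pi
    d = np.mod(a - b + full / 2.0, full) - full / 2.0
    return float(d)


def _pm_pi(alpha: np.ndarray) -> np.ndarray:
    """Map angles to (-pi, pi] (pingouin's expected range)."""
    return np.angle(np.exp(1j * np.asarray(alpha, dtype=float)))


def circ_mean(alpha: np.ndarray, w: np.ndarray | None = None) -> float:
    """Circular mean direction in [0, 2*pi)."""
    alpha = np.asarray(alpha, dtype=float)
    if w is None:
        return float(wrap_rad(pg.circ_mean(_pm_pi(alpha))))
    w = np.asarray(w, dtype=float)
    s = np.sum(w * np.exp(1j * alpha))
    return float(wrap_rad(np.angle(s)))


def circ_r(alpha: np.ndarray, w: np.ndarray | None = None) -> float:
    """Mean resultant length in [0, 1]."""
    alpha = np.asarray(alpha, dtype=float)
    if w is None:
        return float(pg.circ_r(_pm_pi(alpha)))
    w = np.asarray(w, dtype=float)
    return float(np.abs(np.sum(w * np.exp(1j * alpha))) / np.sum(w))


def angular_deviation(alpha: np.ndarray) -> float:
    """Mardia angular deviation sqrt(2 (1 - R)), in radians (range [0, 2])."""
    return float(np.sqrt(2.0 * (1.0 - circ_r(alpha))))


def circ_std(alpha: np.ndarray) -> float:
    """Circular standard deviation sqrt(-2 ln R)."""
    r = circ_r(alpha)
    r = min(max(r, 1e-12), 1.0 - 1e-15)
    return float(np.sqrt(-2.0 * np.log(r)))


def rayleigh_test(alpha: np.ndarray) -> tuple[float, float]:
    """Rayleigh uniformity test; returns (z statistic, p value)."""
    z, p = pg.circ_rayleigh(_pm_pi(alpha))
    return float(z), float(p)


def kappa_from_r(r: float) -> float:
    """Invert the von Mises A1(kappa) = I1/I0 relation for the concentration.

    Uses the Fisher approximations as a bracket and refines by root-finding.
    """
    r = float(np.clip(r, 0.0, 1.0 - 1e-12))
    if r < 1e-9:
        return 0.0

    def a1(k: float) -> float:
        return special.i1e(k) / special.i0e(k)

    lo, hi = 1e-9, 2.0
    while a1(hi) < r:
        hi *= 2.0
        if hi > 1e9:
            return hi
    return float(optimize.brentq(lambda k: a1(k) - r, lo, hi, xtol=1e-10))


@dataclass
class WatsonWilliamsResult:
    """Two-sample Watson-Williams comparison of mean directions."""

    f_stat: float
    p_value: float
    critical_value: float  # F(0.95; 1, N-2)
    df1: int
    df2: int
    kappa: float
    low_concentration: bool  # pooled R below the test's validity range

    @property
    def similar(self) -> bool:
        """True when F is below the 5% critical value (means not distinguishable)."""
        return self.f_stat < self.critical_value


def watson_williams(alpha1: np.ndarray, alpha2: np.ndarray) -> WatsonWilliamsResult:
    """Watson-Williams F test for equality of two circular mean directions.

    Classical one-way circular ANOVA with the 1 + 3/(8 kappa) correction
    factor.  Validity assumes reasonably concentrated samples; a pooled mean
    resultant length below 0.45 sets ``low_concentration`` (result still
    reported, with caveat).
    """
    a1 = np.asarray(alpha1, dtype=float)
    a2 = np.asarray(alpha2, dtype=float)
    n1, n2 = a1.size, a2.size
    n = n1 + n2
    r1 = n1 * circ_r(a1)
    r2 = n2 * circ_r(a2)
    r_all = n * circ_r(np.concatenate([a1, a2]))
    rw = (r1 + r2) / n
    kappa = kappa_from_r(rw)
    correction = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else np.inf
    denom = n - r1 - r2
    if denom <= 0:
        f = 0.0 if (r1 + r2 - r_all) <= 0 else np.inf
    else:
        f = correction * (n - 2) * (r1 + r2 - r_all) / denom
        f = max(f, 0.0)
    df1, df2 = 1, n - 2
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    crit = float(stats.f.ppf(0.95, df1, df2))
    return WatsonWilliamsResult(
        f_stat=float(f),
        p_value=p,
        critical_value=crit,
        df1=df1,
        df2=df2,
        kappa=kappa,
        low_concentration=rw < 0.45,
    )


def bootstrap_circ_mean(
    alpha: np.ndarray, n_boot: int = 1000, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Circular means of ``n_boot`` resamples (with replacement) of ``alpha``."""
    rng = np.random.default_rng(seed)
    alpha = np.asarray(alpha, dtype=float)
    idx = rng.integers(0, alpha.size, size=(n_boot, alpha.size))
    z = np.exp(1j * alpha[idx]).mean(axis=1)
    return np.mod(np.angle(z), 2.0 * np.pi)
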