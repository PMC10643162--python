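"""Bulk-assay kinetics of actin polymerization and phosphate release.

The assay follows seeded actin polymerization through pyrene fluorescence
and the subsequent release of inorganic phosphate (P_i) through a
phosphate-sensor (MDCC-PBP) channel.  Both channels are normalized to
[0, 1] and interpreted with a three-state kinetic scheme

    A --k_poly--> B --k_release--> C + P_i      (rebinding: k_bind)

where A is monomeric ATP-actin, B filamentous ADP-P_i-actin and C
filamentous ADP-actin.  ``k_poly`` lumps polymerization and ATP
hydrolysis into a single observed first-order rate; ``k_release``
(k-Pi) is the first-order core P_i-release rate and ``k_bind`` (k+Pi)
the second-order rebinding constant.  Free P_i is potently sequestered
by the sensor (default 30 uM, K_D 0.1 uM), which is why rebinding
barely influences the fitted release rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

__all__ = [
    "BulkTrace",
    "NormalizedTrace",
    "ReleaseModelFit",
    "EnhancementBound",
    "normalize_trace",
    "fit_kpoly",
    "simulate_release_model",
    "fit_k_release",
    "estimate_enhancement_bound",
]

#: second-order P_i rebinding constant, uM^-1 s^-1 (fixed in all fits)
DEFAULT_K_BIND = 2e-6
#: phosphate-sensor concentration in the assay, uM
SENSOR_TOTAL = 30.0
#: sensor-P_i dissociation constant, uM
SENSOR_KD = 0.1


@dataclass
class BulkTrace:
    """Two-channel fluorescence timecourse (arbitrary units)."""

    time: np.ndarray
    pyrene: np.ndarray
    mdcc: np.ndarray
    variant: str = "wild-type"
    replicate: int = 0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pyrene = np.asarray(self.pyrene, dtype=float)
        self.mdcc = np.asarray(self.mdcc, dtype=float)
        if not (len(self.time) == len(self.pyrene) == len(self.mdcc)):
            raise ValueError("channel lengths differ")
        if self.time[0] < 0:
            raise ValueError("time must start at t >= 0")


@dataclass
class NormalizedTrace:
    """Single normalized channel, baseline ~0 and saturation ~1."""

    time: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)


@dataclass
class ReleaseModelFit:
    """Result of fitting the release model to a normalized MDCC trace."""

    k_poly: float
    k_release: float
    k_release_se: float
    k_bind: float
    residual_norm: float
    k_poly_se: float = 0.0
    at_bounds: bool = False

    @property
    def half_time(self) -> float:
        """Half-time of P_i release, ln 2 / k_release (s)."""
        return math.log(2.0) / self.k_release


@dataclass
class EnhancementBound:
    """Lower bound on the fold rate enhancement over wild type."""

    bound: float
    open_upper: bool
    margin: float
    fold_grid: np.ndarray = field(repr=False, default=None)


def normalize_trace(
    raw: BulkTrace,
    channel: Literal["pyrene", "mdcc"],
    t_sat: float = 900.0,
    baseline_window: float = 10.0,
) -> NormalizedTrace:
    """Normalize one channel of a bulk trace.

    The baseline is the minimal signal within the first ``baseline_window``
    seconds; the scale is the signal at saturation (``t_sat``, default
    900 s) minus that baseline.
    """
    y = getattr(raw, channel)
    t = raw.time
    if t[-1] < t_sat:
        raise ValueError(f"trace ends at {t[-1]:g} s, before t_sat={t_sat:g} s")
    base = float(np.min(y[t <= max(baseline_window, t[0])]))
    sat = float(np.interp(t_sat, t, y))
    rng = sat - base
    if rng <= 0 or not np.isfinite(rng):
        raise ValueError("zero dynamic range: saturation does not exceed baseline")
    return NormalizedTrace(time=t, value=(y - base) / rng)


def _mono_exp(t, k):
    return 1.0 - np.exp(-k * t)


def fit_kpoly(
    trace: NormalizedTrace | Sequence[NormalizedTrace],
) -> tuple[float, float]:
    """Fit I(t) = 1 - exp(-k_poly t) to normalized pyrene trace(s).

    A sequence of replicates is fitted individually and the estimates
    averaged; the standard error is then the SD across replicates over
    sqrt(n).  A single trace reports the asymptotic fit SE.
    """
    if isinstance(trace, NormalizedTrace):
        popt, pcov = curve_fit(
            _mono_exp, trace.time, trace.value, p0=[0.01], maxfev=10000
        )
        return float(popt[0]), float(np.sqrt(pcov[0, 0]))
    ks = [fit_kpoly(tr)[0] for tr in trace]
    k = float(np.mean(ks))
    se = float(np.std(ks, ddof=1) / np.sqrt(len(ks))) if len(ks) > 1 else 0.0
    return k, se


def _analytic_released(t, k_poly, k_release, actin_total):
    """Closed-form released P_i for the sequential scheme (no rebinding)."""
    t = np.asarray(t, dtype=float)
    kp, kr = k_poly, k_release
    if kr == 0.0:
        return np.zeros_like(t)
    if kp == 0.0:
        return np.zeros_like(t)
    if abs(kr - kp) < 1e-12 * max(kr, kp):
        return actin_total * (1.0 - (1.0 + kp * t) * np.exp(-kp * t))
    return actin_total * (
        1.0 - (kr * np.exp(-kp * t) - kp * np.exp(-kr * t)) / (kr - kp)
    )


def _sensor_bound(pi_total, sensor_total=SENSOR_TOTAL, kd=SENSOR_KD):
    """P_i bound to the sensor at rapid equilibrium (quadratic isotherm)."""
    p = np.asarray(pi_total, dtype=float)
    b = p + sensor_total + kd
    return (b - np.sqrt(b * b - 4.0 * p * sensor_total)) / 2.0


def simulate_release_model(
    k_poly: float,
    k_release: float,
    times: np.ndarray,
    actin_total: float = 10.0,
    k_bind: float = DEFAULT_K_BIND,
    mode: Literal["analytic", "ode"] = "analytic",
    sensor_total: float = SENSOR_TOTAL,
    sensor_kd: float = SENSOR_KD,
) -> dict[str, np.ndarray]:
    """Simulate the three-state release scheme.

    ``analytic`` ignores P_i rebinding (sequential first-order closed
    form); ``ode`` integrates the scheme with rebinding of free P_i,
    where free P_i is total released minus the sensor-bound amount
    (rapid sensor equilibrium).  Concentrations in uM, time in s.

    Returns a dict with A, B, C, released (total P_i in solution) and
    sensor_bound arrays; A + B + C equals ``actin_total`` identically.
    """
    if k_poly < 0 or k_release < 0 or k_bind < 0:
        raise ValueError("rates must be non-negative")
    if not np.all(np.isfinite([k_poly, k_release, k_bind, actin_total])):
        raise ValueError("non-finite parameters")
    t = np.asarray(times, dtype=float)
    if mode == "analytic":
        A = actin_total * np.exp(-k_poly * t)
        C = _analytic_released(t, k_poly, k_release, actin_total)
        B = actin_total - A - C
        released = C.copy()
    elif mode == "ode":
        def rhs(_t, y):
            A_, B_ = y
            C_ = actin_total - A_ - B_
            free = C_ - _sensor_bound(C_, sensor_total, sensor_kd)
            dA = -k_poly * A_
            dB = k_poly * A_ - k_release * B_ + k_bind * C_ * free
            return [dA, dB]

        sol = solve_ivp(
            rhs,
            (t[0], t[-1]),
            [actin_total, 0.0],
            t_eval=t,
            method="LSODA",
            rtol=1e-10,
            atol=1e-12,
        )
        A, B = sol.y
        C = actin_total - A - B
        released = C.copy()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {
        "A": A,
        "B": B,
        "C": C,
        "released": released,
        "sensor_bound": _sensor_bound(released, sensor_total, sensor_kd),
    }


def fit_k_release(
    mdcc: NormalizedTrace,
    k_poly: float,
    k_bind: float = DEFAULT_K_BIND,
    actin_total: float = 10.0,
    mode: Literal["analytic", "ode"] = "analytic",
    t_sat: float = 900.0,
    bounds: tuple[float, float] = (1e-6, 10.0),
) -> ReleaseModelFit:
    """Fit the single free rate k_release to a normalized MDCC trace.

    ``k_poly`` (from :func:`fit_kpoly`) and ``k_bind`` are fixed, as in
    the assay analysis.  The model prediction is normalized the same way
    as the data, by its value at ``t_sat``.
    """
    t = mdcc.time

    def model(t_, kr):
        sim = simulate_release_model(
            k_poly, kr, t_, actin_total=actin_total, k_bind=k_bind, mode=mode
        )
        obs = sim["sensor_bound"] if mode == "ode" else sim["released"]
        ref = float(np.interp(t_sat, t_, obs))
        if ref <= 0:
            return np.zeros_like(t_)
        return obs / ref

    popt, pcov = curve_fit(
        model, t, mdcc.value, p0=[0.01], bounds=([bounds[0]], [bounds[1]]),
        maxfev=10000,
    )
    kr = float(popt[0])
    resid = mdcc.value - model(t, kr)
    at_bounds = kr <= bounds[0] * 1.01 or kr >= bounds[1] * 0.99
    return ReleaseModelFit(
        k_poly=k_poly,
        k_release=kr,
        k_release_se=float(np.sqrt(pcov[0, 0])),
        k_bind=k_bind,
        residual_norm=float(np.linalg.norm(resid)),
        at_bounds=at_bounds,
    )


def _release_poly_gap(k_poly: float, k_release: float) -> float:
    """Max gap between the released-P_i and polymerization fractions."""
    kp, kr = k_poly, k_release
    if kr <= 0:
        return 1.0
    # gap(t) = kp (e^{-kp t} - e^{-kr t}) / (kr - kp), maximal where the
    # two exponentials' slopes cross; evaluated on a dense grid for
    # robustness near kr ~ kp.
    t_hi = 10.0 / min(kp, kr)
    t = np.linspace(0.0, t_hi, 4000)
    if abs(kr - kp) < 1e-12 * max(kr, kp):
        gap = kp * t * np.exp(-kp * t)
    else:
        gap = kp * (np.exp(-kp * t) - np.exp(-kr * t)) / (kr - kp)
    return float(np.max(gap))


def estimate_enhancement_bound(
    times: np.ndarray,
    mdcc_obs: np.ndarray,
    k_poly: float,
    k_poly_se: float,
    wildtype_k_release: float,
    fold_grid: np.ndarray | None = None,
) -> EnhancementBound:
    """Minimal fold rate enhancement consistent with release that tracks
    polymerization.

    When the observed release timecourse is indistinguishable from the
    polymerization timecourse, only a lower bound on k_release can be
    stated.  The error margin is taken from the data themselves: the
    maximal deviation of the observed (normalized) MDCC signal from the
    mono-exponential polymerization curve, widened by the k_poly
    uncertainty band.  The bound is the smallest fold ``f`` on the grid
    for which the simulated release curve at ``f * wildtype_k_release``
    deviates from the polymerization curve by no more than that margin
    (the deviation is strictly decreasing in ``f``).
    """
    if fold_grid is None:
        fold_grid = np.logspace(0.0, 3.0, 400)
    fold_grid = np.asarray(fold_grid, dtype=float)
    if fold_grid.max() / fold_grid.min() < 100.0:
        raise ValueError("fold grid must span at least two decades")
    t = np.asarray(times, dtype=float)
    poly = 1.0 - np.exp(-k_poly * t)
    margin = float(np.max(np.abs(np.asarray(mdcc_obs, dtype=float) - poly)))
    if k_poly_se > 0:
        band = np.exp(-max(k_poly - k_poly_se, 0.0) * t) - np.exp(
            -(k_poly + k_poly_se) * t
        )
        margin += float(np.max(band))
    for f in np.sort(fold_grid):
        if _release_poly_gap(k_poly, f * wildtype_k_release) <= margin:
            return EnhancementBound(
                bound=float(f), open_upper=False, margin=margin,
                fold_grid=fold_grid,
            )
    return EnhancementBound(
        bound=float(fold_grid.max()), open_upper=True, margin=margin,
        fold_grid=fold_grid,
    )
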