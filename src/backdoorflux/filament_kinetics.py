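"""Single-filament depolymerization analysis.

Length-vs-time traces from flow-out experiments are averaged, turned
into instantaneous depolymerization velocities by local linear
regression over several window sizes, mapped to filament age, and
fitted with the exponential aging model

    1 / v_depol(tau) = a * exp(-b * tau) + c

whose parameters carry the kinetics:  b = k-Pi (core P_i-release rate),
c = 1 / v_depol,ADP and a + c = 1 / v_depol,ADP-Pi.  The barbed-end
P_i-release rate follows from the two limiting velocities, and for
mutants whose velocity profile is flat within the frame resolution a
lower bound on the core release rate is derived instead.

Filament lengths are in subunits throughout; micrograph lengths convert
at 370 subunits per micrometre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "SUBUNITS_PER_UM",
    "FilamentTrace",
    "PauseEvent",
    "VelocityProfile",
    "DepolFit",
    "LowerBoundResult",
    "detect_pauses",
    "average_traces",
    "instantaneous_velocity",
    "select_windows",
    "filament_age",
    "fit_depol_model",
    "barbed_end_release_rate",
    "lower_bound_k_release",
]

#: conversion factor for imaging-derived lengths
SUBUNITS_PER_UM = 370.0

DEFAULT_WINDOWS = (17, 19, 21, 23, 25, 27, 29)


@dataclass
class FilamentTrace:
    """Length of one filament over time (subunits), with phase labels."""

    time: np.ndarray
    length: np.ndarray
    depol_start: float
    filament_id: int = 0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.length = np.asarray(self.length, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.length < 0):
            raise ValueError("length must be non-negative")

    @property
    def phase(self) -> np.ndarray:
        return np.where(
            self.time < self.depol_start, "polymerization", "depolymerization"
        )

    def depol_segment(self) -> tuple[np.ndarray, np.ndarray]:
        """(time since depol start, length) of the depolymerization phase."""
        m = self.time >= self.depol_start
        return self.time[m] - self.depol_start, self.length[m]


@dataclass
class PauseEvent:
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("pause end must follow its start")


@dataclass
class VelocityProfile:
    """Inverse depolymerization velocity vs filament age."""

    tau: np.ndarray            # filament age, s
    inv_v: np.ndarray          # 1/v_depol, s/subunit
    sd: np.ndarray             # SD across window sizes
    window_sizes: tuple[int, ...]
    t: np.ndarray = None       # time since depol start, s


@dataclass
class DepolFit:
    """Exponential aging fit and the rates it encodes."""

    a: float
    b: float
    c: float
    a_se: float = 0.0
    b_se: float = 0.0
    c_se: float = 0.0
    flat: bool = False
    k_off_ADPPi: float = 0.2

    @property
    def k_release_core(self) -> float:
        return self.b

    @property
    def v_depol_ADP(self) -> float:
        return 1.0 / self.c

    @property
    def v_depol_ADPPi(self) -> float:
        return 1.0 / (self.a + self.c)

    @property
    def k_release_BE(self) -> float:
        return barbed_end_release_rate(
            self.v_depol_ADP, self.v_depol_ADPPi, self.k_off_ADPPi
        )


@dataclass
class LowerBoundResult:
    """'k_release_core >= bound' estimate for flat velocity profiles."""

    bound: float
    assumption: str
    detectable_excess: float
    noise_floor: float
    degenerate: bool = False


def detect_pauses(
    trace: FilamentTrace,
    v_threshold: float = 0.5,
    min_duration: float = 15.0,
) -> tuple[list[PauseEvent], FilamentTrace]:
    """Find zero-velocity plateaus in the depolymerization phase and
    truncate the trace at the first pause onset.

    A pause is a run of frames whose frame-to-frame depolymerization
    speed stays below ``v_threshold`` (subunits/s) for at least
    ``min_duration`` seconds.  Pause-free traces are returned unchanged.
    """
    td, ld = trace.depol_segment()
    if len(td) < 2:
        raise ValueError("no depolymerization phase to analyze")
    v = -np.diff(ld) / np.diff(td)  # positive while shrinking
    slow = v < v_threshold
    pauses: list[PauseEvent] = []
    i = 0
    while i < len(slow):
        if slow[i]:
            j = i
            while j < len(slow) and slow[j]:
                j += 1
            if td[j] - td[i] >= min_duration:
                pauses.append(PauseEvent(start=float(td[i]), end=float(td[j])))
            i = j
        else:
            i += 1
    if not pauses:
        return [], trace
    cut = pauses[0].start + trace.depol_start
    keep = trace.time <= cut
    if keep.sum() < 2 or not np.any(
        trace.time[keep] >= trace.depol_start
    ):
        raise ValueError("trace is entirely paused; no analyzable segment")
    truncated = FilamentTrace(
        time=trace.time[keep],
        length=trace.length[keep],
        depol_start=trace.depol_start,
        filament_id=trace.filament_id,
    )
    return pauses, truncated


def average_traces(
    traces: Sequence[FilamentTrace],
    align_to: Literal["depol_start"] = "depol_start",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Average depolymerization-phase lengths across filaments.

    Traces are aligned at their depolymerization start; at each aligned
    time point the mean and SD are taken over the filaments still being
    tracked then.  Returns (t, mean, sd, n).
    """
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    segs = [tr.depol_segment() for tr in traces]
    n_pts = max(len(t) for t, _ in segs)
    t_ref = max(segs, key=lambda s: len(s[0]))[0]
    stack = np.full((len(segs), n_pts), np.nan)
    for i, (t, length) in enumerate(segs):
        stack[i, : len(length)] = length
    n = np.sum(~np.isnan(stack), axis=0)
    mean = np.nanmean(stack, axis=0)
    sd = np.zeros(n_pts)
    multi = n > 1
    if np.any(multi):
        sd[multi] = np.nanstd(stack[:, multi], axis=0, ddof=1)
    return t_ref[: n_pts], mean, sd, n


def _window_slopes(t: np.ndarray, y: np.ndarray, w: int) -> np.ndarray:
    """Slope of a centered w-point linear regression at each interior point
    (NaN where a full window does not fit)."""
    n = len(t)
    half = w // 2
    slopes = np.full(n, np.nan)
    for i in range(half, n - half):
        ts = t[i - half : i + half + 1]
        ys = y[i - half : i + half + 1]
        tm = ts - ts.mean()
        slopes[i] = np.dot(tm, ys - ys.mean()) / np.dot(tm, tm)
    return slopes


def instantaneous_velocity(
    t: np.ndarray,
    mean_length: np.ndarray,
    window_sizes: Sequence[int] = DEFAULT_WINDOWS,
) -> VelocityProfile:
    """Window-averaged instantaneous depolymerization velocity.

    For every odd window size the depolymerization velocity at a time
    point is minus the slope of the centered linear regression; the
    profile averages over the window sizes, dropping edge points where
    the largest window does not fit and masking points with non-positive
    velocity (transient growth).
    """
    window_sizes = tuple(int(w) for w in window_sizes)
    if any(w % 2 == 0 or w < 3 for w in window_sizes):
        raise ValueError("window sizes must be odd and >= 3")
    wmax = max(window_sizes)
    if len(t) < wmax:
        raise ValueError(
            f"depolymerization segment ({len(t)} frames) shorter than the "
            f"largest window ({wmax})"
        )
    all_v = np.stack(
        [-_window_slopes(t, mean_length, w) for w in window_sizes]
    )
    half = wmax // 2
    core = slice(half, len(t) - half)
    v = np.nanmean(all_v[:, core], axis=0)
    sd = np.nanstd(all_v[:, core], axis=0, ddof=1) if len(window_sizes) > 1 \
        else np.zeros_like(v)
    valid = v > 0
    inv_v = np.full_like(v, np.nan)
    inv_v[valid] = 1.0 / v[valid]
    inv_sd = np.full_like(v, np.nan)
    inv_sd[valid] = sd[valid] / v[valid] ** 2  # delta method on 1/v
    return VelocityProfile(
        tau=t[core].copy(),  # placeholder until filament_age is applied
        inv_v=inv_v,
        sd=inv_sd,
        window_sizes=window_sizes,
        t=t[core].copy(),
    )


def filament_age(
    t: np.ndarray, length: np.ndarray, v_pol: float
) -> np.ndarray:
    """Filament age of the depolymerizing region.

    tau = t + (L0 - L_t) / v_pol, with t the time since depolymerization
    started, L0 the length at flow-out and v_pol the polymerization
    velocity; the subunits currently exposed at the barbed end were laid
    down (L0 - L_t)/v_pol before flow-out.
    """
    if v_pol <= 0:
        raise ValueError("v_pol must be positive")
    t = np.asarray(t, dtype=float)
    length = np.asarray(length, dtype=float)
    L0 = length[0]
    if np.any(length > L0 + 1e-9):
        raise ValueError("length exceeds its value at depolymerization start")
    return t + (L0 - length) / v_pol


def _aging_model(tau, a, b, c):
    return a * np.exp(-b * tau) + c


def fit_depol_model(
    profile: VelocityProfile,
    flat_ratio: float = 0.05,
    b_bounds: tuple[float, float] = (1e-5, 5.0),
) -> DepolFit:
    """Fit 1/v_depol = a exp(-b tau) + c by nonlinear least squares.

    Profiles without a resolvable maturation transient (fitted
    a < ``flat_ratio`` * c, or b pinned at its bounds) are flagged flat;
    for those only c (hence v_depol,ADP) is meaningful and a lower bound
    on the release rate applies (:func:`lower_bound_k_release`).
    """
    m = np.isfinite(profile.inv_v)
    tau, y = profile.tau[m], profile.inv_v[m]
    if len(tau) < 10:
        raise ValueError("need at least 10 age points")
    c0 = float(np.min(y))
    a0 = max(float(y[0] - c0), 1e-6)
    p0 = [a0, 0.01, c0]
    try:
        popt, pcov = curve_fit(
            _aging_model, tau, y, p0=p0,
            bounds=([0.0, b_bounds[0], 1e-12], [np.inf, b_bounds[1], np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        # no curvature at all: pure flat profile
        c = float(np.mean(y))
        return DepolFit(a=0.0, b=b_bounds[0], c=c, flat=True)
    a, b, c = (float(v) for v in popt)
    ses = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    # the maturation transient is unresolved when its amplitude is small
    # against the ADP plateau, statistically insignificant, or when the
    # decay rate pins at the search bounds
    flat = (
        a < flat_ratio * c
        or b <= b_bounds[0] * 1.01
        or b >= b_bounds[1] * 0.99
        or not np.isfinite(ses[0])
        or a <= 2.0 * ses[0]
    )
    flat = bool(flat)
    if flat:
        # with no resolvable transient the exponential term is degenerate
        # and can soak up part of the plateau; the ADP plateau is then
        # simply the profile mean
        c = float(np.mean(y))
        a = 0.0
    return DepolFit(
        a=a, b=b, c=c,
        a_se=float(ses[0]), b_se=float(ses[1]), c_se=float(ses[2]),
        flat=flat,
    )


def select_windows(
    t: np.ndarray,
    mean_length: np.ndarray,
    v_pol: float,
    candidate_windows: Sequence[int] = DEFAULT_WINDOWS,
    max_rel_sd: float = 0.10,
) -> dict[int, dict[str, float | bool]]:
    """Window-size selection report.

    Each candidate window is used alone to build a velocity profile and
    fit the aging model; the mean relative standard error of (a, b, c)
    is the prediction-uncertainty score, and windows scoring below
    ``max_rel_sd`` are admissible.  The production profile averages the
    admissible windows.
    """
    report: dict[int, dict[str, float | bool]] = {}
    for w in candidate_windows:
        try:
            prof = instantaneous_velocity(t, mean_length, window_sizes=[w])
            prof.tau = filament_age(
                prof.t, np.interp(prof.t, t, mean_length), v_pol
            )
            fit = fit_depol_model(prof)
            rel = np.array([
                fit.a_se / fit.a if fit.a > 0 else np.inf,
                fit.b_se / fit.b if fit.b > 0 else np.inf,
                fit.c_se / fit.c if fit.c > 0 else np.inf,
            ])
            score = float(np.mean(rel))
            report[w] = {"rel_sd": score, "admissible": bool(score < max_rel_sd)}
        except (ValueError, RuntimeError):
            report[w] = {"rel_sd": float("inf"), "admissible": False}
    return report


def barbed_end_release_rate(
    v_ADP: float, v_ADPPi: float, k_off_ADPPi: float = 0.2
) -> float:
    """Barbed-end P_i-release rate from the two limiting depolymerization
    velocities.

    k-Pi,BE = v_ADP * (k_off^ADP-Pi - v_ADPPi) / (v_ADPPi - v_ADP),
    with the direct ADP-P_i dissociation rate k_off^ADP-Pi fixed to
    0.2 s^-1.  Velocities in subunits/s, used interchangeably with s^-1.
    """
    if v_ADPPi == v_ADP:
        raise ZeroDivisionError("v_ADPPi equals v_ADP; rate undefined")
    return v_ADP * (k_off_ADPPi - v_ADPPi) / (v_ADPPi - v_ADP)


def lower_bound_k_release(
    profile: VelocityProfile,
    fit: DepolFit,
    wildtype_fit: DepolFit,
    assumption: Literal["1x", "2x"] = "1x",
) -> LowerBoundResult:
    """Lower bound on the core P_i-release rate for a flat profile.

    Assuming the mutant's ADP-P_i depolymerization velocity equals (1x)
    or doubles (2x) the wild-type value, the maturation transient would
    raise 1/v at the first analyzable age point by
    a_pred * exp(-k * tau_1).  The largest k for which that excess still
    exceeds twice the empirical SD of 1/v is the detectability limit;
    the true rate must be at least that large.
    """
    if not fit.flat:
        raise ValueError(
            "profile shows a resolvable transient; use fit_depol_model"
        )
    factor = {"1x": 1.0, "2x": 2.0}[assumption]
    v_adppi = wildtype_fit.v_depol_ADPPi * factor
    a_pred = 1.0 / v_adppi - fit.c
    m = np.isfinite(profile.inv_v)
    sigma = float(np.nanmedian(profile.sd[m]))
    tau1 = float(profile.tau[m][0])
    if a_pred <= 0:
        raise ValueError(
            "assumed ADP-Pi velocity not slower than observed ADP velocity"
        )
    if sigma <= 0:
        return LowerBoundResult(
            bound=float("inf"), assumption=assumption,
            detectable_excess=a_pred, noise_floor=0.0, degenerate=True,
        )
    if tau1 <= 0:
        return LowerBoundResult(
            bound=float("inf"), assumption=assumption,
            detectable_excess=a_pred, noise_floor=2 * sigma, degenerate=True,
        )
    if a_pred <= 2.0 * sigma:
        return LowerBoundResult(
            bound=0.0, assumption=assumption,
            detectable_excess=a_pred, noise_floor=2 * sigma, degenerate=True,
        )
    bound = math.log(a_pred / (2.0 * sigma)) / tau1
    return LowerBoundResult(
        bound=bound, assumption=assumption,
        detectable_excess=a_pred, noise_floor=2 * sigma,
    )
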