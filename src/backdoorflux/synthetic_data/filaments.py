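"""Stochastic single-filament traces with nucleotide-state aging.

Event-driven (Gillespie-style) realization of the two-route barbed-end
scheme: during growth, ADP-P_i subunits are added at ``v_pol`` and each
core subunit converts to ADP at ``k_release_core``; during
depolymerization the terminal subunit leaves at ``v_depol_ADP`` when it
is ADP, whereas a terminal ADP-P_i subunit either dissociates directly
at ``v_depol_ADPPi`` or first releases its P_i at the barbed-end rate
``k_release_BE`` and then leaves as ADP.  Because recently added
subunits sit closest to the barbed end, the depolymerization velocity
matures from the ADP-P_i to the ADP value as the exposed region ages —
exactly the transient the aging fit in
:mod:`backdoorflux.filament_kinetics` quantifies.

Optional pauses (photo-induced dimerization-like) freeze the length for
a while; their onsets follow a logistic distribution in time, so the
cohort's cumulative pause probability is a logistic CDF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ..filament_kinetics import FilamentTrace

__all__ = ["PauseModel", "FilamentSimConfig", "gen_filament_traces"]


@dataclass
class PauseModel:
    """Logistic pause-onset model (times from depolymerization start)."""

    onset_loc: float = 300.0    # s, logistic location
    onset_scale: float = 60.0   # s, logistic scale
    duration: float = 60.0      # s, mean of exponential pause duration


@dataclass
class FilamentSimConfig:
    """Study conditions for the filament generator.

    Wild-type-like defaults: polymerization at 15 subunits/s for 300 s,
    ADP depolymerization velocity 6.7 subunits/s, direct ADP-P_i
    dissociation 0.2 subunits/s (the fixed k_off^ADP-Pi), core release
    0.006 s^-1, barbed-end release 2 s^-1, lengths reported every 5 s.

    ``v_depol_ADPPi`` is the *direct* dissociation rate of a terminal
    ADP-P_i subunit; the *observed* ADP-P_i depolymerization velocity
    also includes the release-then-dissociate route and is given by
    :meth:`observed_v_adppi`.
    """

    v_pol: float = 15.0
    v_depol_ADP: float = 6.7
    v_depol_ADPPi: float = 0.2
    k_release_core: float = 0.006
    k_release_BE: float = 2.0
    frame_interval: float = 5.0
    t_growth: float = 300.0
    n_filaments: int = 50
    pause_model: Optional[PauseModel] = None
    seed: int = 0

    def __post_init__(self) -> None:
        vels = (self.v_pol, self.v_depol_ADP, self.v_depol_ADPPi)
        if any(v < 0 for v in vels):
            raise ValueError("velocities must be non-negative")
        if self.k_release_core < 0 or self.k_release_BE < 0:
            raise ValueError("release rates must be non-negative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.t_growth <= 0 or self.n_filaments < 1:
            raise ValueError("invalid growth time or filament count")

    def observed_v_adppi(self) -> float:
        """Observed depolymerization velocity of the ADP-P_i region.

        A terminal ADP-P_i subunit waits 1/(k_BE + v_Pi) for the first
        event and, with probability k_BE/(k_BE + v_Pi), continues as ADP
        for another 1/v_ADP; the observed velocity is the inverse mean
        dwell.  This is the quantity 1/(a + c) of the aging fit."""
        r = self.k_release_BE + self.v_depol_ADPPi
        if r <= 0:
            return 0.0
        dwell = 1.0 / r + (self.k_release_BE / r) / self.v_depol_ADP
        return 1.0 / dwell


def _simulate_one(cfg: FilamentSimConfig, rng: np.random.Generator) -> FilamentTrace:
    # --- growth: Poisson additions until t_growth -------------------------
    n_expect = cfg.v_pol * cfg.t_growth
    n_draw = int(n_expect + 6.0 * np.sqrt(n_expect) + 10)
    gaps = rng.exponential(1.0 / cfg.v_pol, size=n_draw)
    add_times = np.cumsum(gaps)
    while add_times[-1] < cfg.t_growth:
        extra = rng.exponential(1.0 / cfg.v_pol, size=n_draw)
        add_times = np.concatenate([add_times, add_times[-1] + np.cumsum(extra)])
    add_times = add_times[add_times <= cfg.t_growth]
    n_sub = len(add_times)
    if n_sub == 0:
        raise ValueError("no subunits polymerized; raise v_pol or t_growth")

    # scheduled interior P_i-release time per subunit
    if cfg.k_release_core > 0:
        conv_times = add_times + rng.exponential(
            1.0 / cfg.k_release_core, size=n_sub
        )
    else:
        conv_times = np.full(n_sub, np.inf)

    # --- depolymerization: remove subunits from the barbed end ------------
    # Subunit n_sub-1 is terminal first.  A terminal ADP-P_i subunit faces
    # competing risks: direct dissociation vs barbed-end release followed
    # by ADP dissociation.  Its interior-release clock is superseded while
    # terminal (the barbed-end rate dominates under all study conditions).
    removal_times = np.empty(n_sub)
    t = cfg.t_growth
    r_pi = cfg.k_release_BE + cfg.v_depol_ADPPi
    for j in range(n_sub - 1, -1, -1):
        if conv_times[j] <= t:  # already ADP when it becomes terminal
            dwell = rng.exponential(1.0 / cfg.v_depol_ADP)
        else:
            if r_pi <= 0:
                dwell = np.inf
            else:
                dwell = rng.exponential(1.0 / r_pi)
                if rng.random() < cfg.k_release_BE / r_pi:
                    dwell += rng.exponential(1.0 / cfg.v_depol_ADP)
        t += dwell
        removal_times[j] = t
    removal_times = removal_times[::-1]  # ascending in time

    # --- optional pause: freeze length for a while ------------------------
    if cfg.pause_model is not None:
        pm = cfg.pause_model
        onset = rng.logistic(pm.onset_loc, pm.onset_scale)
        duration = rng.exponential(pm.duration)
        if onset > 0:
            abs_onset = cfg.t_growth + onset
            shift = removal_times > abs_onset
            removal_times[shift] += duration

    # --- sample on the frame grid -----------------------------------------
    t_end = removal_times[-1]
    frames = np.arange(0.0, t_end + cfg.frame_interval, cfg.frame_interval)
    grown = np.searchsorted(add_times, frames, side="right")
    removed = np.searchsorted(removal_times, frames, side="right")
    length = (grown - removed).astype(float)
    # trace ends when the filament has fully depolymerized (first zero
    # after the growth phase); leading zeros before the first addition
    # are kept as part of the growth record
    first_pos = int(np.argmax(length > 0))
    zeros = np.nonzero((length <= 0) & (np.arange(len(length)) > first_pos))[0]
    last = int(zeros[0]) if len(zeros) else len(frames)
    frames, length = frames[:last], length[:last]
    return FilamentTrace(time=frames, length=length, depol_start=cfg.t_growth)


def gen_filament_traces(cfg: FilamentSimConfig) -> list[FilamentTrace]:
    """Simulate a cohort of filament traces; bit-reproducible per seed."""
    rng = np.random.default_rng(cfg.seed)
    traces = []
    for i in range(cfg.n_filaments):
        tr = _simulate_one(cfg, rng)
        tr.filament_id = i
        traces.append(tr)
    return traces
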