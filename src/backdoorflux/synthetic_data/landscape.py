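"""Toy free-energy landscape and metadynamics-driven escape sampler.

The landscape stands in for the solvated filament environment of the
bound P_i ion: a Gaussian binding well at the origin, surrounded by a
spherical barrier shell whose height drops inside a few narrow angular
"channels" (the egress gates).  One gate is tagged as the R177-N111
backdoor and is flanked by anchors labeled with those residue ids.

An overdamped Langevin particle explores the landscape; three
independent one-dimensional history-dependent Gaussian biases (one per
Cartesian coordinate of the P atom, hill height W = 1 kJ/mol, width
0.05 nm, deposited at 0.125 ps^-1) progressively flood the well until
the particle crosses the 1.4-nm escape cutoff.  The parameters capture
escape events; they are not meant to reconstruct a converged free-energy
profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from ..backdoor_classifier import N_ANCHORS, RESIDUE_IDS, AnchorSet
from ..egress_paths import ESCAPE_CUTOFF_NM, EgressTrajectory

__all__ = [
    "Channel",
    "ToyLandscape",
    "MetadynamicsConfig",
    "gen_egress_swarm",
    "run_langevin",
]

BACKDOOR_CHANNEL = "R177-N111"


@dataclass
class Channel:
    direction: np.ndarray           # unit vector
    half_width: float = 0.35        # rad
    name: str = "channel"

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if not math.isclose(n, 1.0, rel_tol=1e-6):
            raise ValueError("channel direction must be a unit vector")


@dataclass
class ToyLandscape:
    """Binding well + gated barrier shell, with 48 labeled anchors.

    Energies in kJ/mol, lengths in nm; kT defaults to 310 K.  Well depth
    and barrier height are calibration knobs of the toy model, chosen so
    that unbiased escape over the ~10-kT gate is negligible on the
    10-ns timescale while the biased sampler escapes within it.
    """

    well_depth: float = 20.0
    shell_radius: float = 0.6
    barrier_height: float = 25.0
    wall_extra: float = 35.0            # added barrier away from gates
    well_sigma: float = 0.22
    barrier_sigma: float = 0.10
    kT: float = 2.577                   # kJ/mol at 310 K
    diffusion: float = 0.005            # nm^2/ps
    channels: list[Channel] = field(default_factory=list)
    anchors: AnchorSet = None

    def __post_init__(self) -> None:
        if self.shell_radius >= ESCAPE_CUTOFF_NM:
            raise ValueError("shell radius must lie inside the escape cutoff")
        if not self.channels:
            self.channels = _default_channels()
        if self.anchors is None:
            self.anchors = build_anchors(self)
        if len(self.anchors.residue_ids) != N_ANCHORS:
            raise ValueError("landscape requires exactly 48 anchors")

    @property
    def backdoor_index(self) -> int:
        for i, c in enumerate(self.channels):
            if c.name == BACKDOOR_CHANNEL:
                return i
        raise ValueError("landscape lacks a tagged backdoor gate")

    def potential(self, x: np.ndarray) -> float:
        """Landscape energy (kJ/mol) at position x (nm), bias excluded."""
        dirs = np.stack([c.direction for c in self.channels])
        hws = np.array([c.half_width for c in self.channels])
        return _potential(
            np.asarray(x, dtype=float), dirs, hws, self.well_depth,
            self.well_sigma, self.barrier_height, self.wall_extra,
            self.barrier_sigma, self.shell_radius,
        )


def _default_channels() -> list[Channel]:
    s = 1.0 / math.sqrt(3.0)
    dirs = [
        (s, s, s), (s, -s, -s), (-s, s, -s), (-s, -s, s),
    ]
    names = [BACKDOOR_CHANNEL, "N115-R116", "T120-V370", "H73-R183"]
    return [Channel(direction=np.array(d), name=n)
            for d, n in zip(dirs, names)]


def _orthonormal_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(helper, u)) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, helper)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(u, e1)


def build_anchors(landscape: "ToyLandscape") -> AnchorSet:
    """Deterministic 48-anchor layout.

    Four anchors ring every gate inside its escape corridor, just
    outside the barrier shell (for the backdoor gate these carry the
    R177 and N111 labels) — mimicking pathway residues that line the
    egress channels, so contacts record which channel was traversed.
    The remaining anchors tile a sphere farther out on a Fibonacci
    lattice.
    """
    R = landscape.shell_radius
    coords: list[np.ndarray] = []
    tags: list[str] = []
    gate_residues = {
        BACKDOOR_CHANNEL: (177, 111, 110, 112),
        "N115-R116": (115, 116, 114, 113),
        "T120-V370": (120, 370, 374, 161),
        "H73-R183": (73, 183, 71, 72),
    }
    used: dict[int, tuple[np.ndarray, str]] = {}
    corridor_r = 0.5 * (R + ESCAPE_CUTOFF_NM)   # inside the escape corridor
    for ch in landscape.channels:
        u = ch.direction
        e1, e2 = _orthonormal_frame(u)
        ring = [e1, -e1, e2, -e2]
        residues = gate_residues.get(ch.name, (None,) * 4)
        half = 0.5 * ch.half_width
        for e, rid in zip(ring, residues):
            p = corridor_r * (math.cos(half) * u + math.sin(half) * e)
            tag = ch.name if rid not in (177, 111) else f"R{rid}" if rid == 177 \
                else "N111"
            if rid is not None and rid not in used:
                used[rid] = (p, tag)
    remaining = [rid for rid in RESIDUE_IDS if rid not in used]
    n_rest = len(remaining)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    for i, rid in enumerate(remaining):
        z = 1.0 - 2.0 * (i + 0.5) / n_rest
        rho = math.sqrt(max(0.0, 1.0 - z * z))
        phi = golden * i
        p = 1.3 * np.array(
            [rho * math.cos(phi), rho * math.sin(phi), z]
        )
        used[rid] = (p, "")
    for rid in RESIDUE_IDS:
        p, tag = used[rid]
        coords.append(p)
        tags.append(tag)
    return AnchorSet(
        residue_ids=tuple(RESIDUE_IDS),
        coords=np.stack(coords),
        tags=tuple(tags),
    )


@dataclass
class MetadynamicsConfig:
    """Bias and integration settings for the toy sampler."""

    hill_height: float = 1.0        # W, kJ/mol
    hill_sd: float = 0.05           # sigma, nm
    deposition_rate: float = 0.125  # 1/ps
    max_time: float = 10.0          # ns
    swarm_size: int = 50
    dt: float = 0.01                # ps
    sample_every: float = 1.0       # ps between stored frames
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hill_height <= 0 or self.hill_sd <= 0:
            raise ValueError("hill height and width must be positive")
        if self.swarm_size < 1:
            raise ValueError("swarm_size must be >= 1")
        if self.dt <= 0 or self.max_time <= 0:
            raise ValueError("dt and max_time must be positive")


@njit(cache=True)
def _potential(x, dirs, hws, well_depth, well_sigma, barrier_h, wall_h,
               barrier_sig, shell_r):
    r2 = x[0] * x[0] + x[1] * x[1] + x[2] * x[2]
    r = math.sqrt(r2)
    v = -well_depth * math.exp(-r2 / (2.0 * well_sigma * well_sigma))
    if r > 1e-9:
        gmax = 0.0
        for c in range(dirs.shape[0]):
            cosang = (x[0] * dirs[c, 0] + x[1] * dirs[c, 1] +
                      x[2] * dirs[c, 2]) / r
            if cosang > 1.0:
                cosang = 1.0
            elif cosang < -1.0:
                cosang = -1.0
            ang = math.acos(cosang)
            g = math.exp(-ang * ang / (2.0 * hws[c] * hws[c]))
            if g > gmax:
                gmax = g
        height = barrier_h + wall_h * (1.0 - gmax)
        dr = r - shell_r
        v += height * math.exp(-dr * dr / (2.0 * barrier_sig * barrier_sig))
    return v


_GRID_LIM = 2.0      # nm, bias grid half-extent
_GRID_H = 0.005      # nm, bias grid spacing


@njit(cache=True)
def _integrate(seed, dirs, hws, well_depth, well_sigma, barrier_h, wall_h,
               barrier_sig, shell_r, kT, D, dt, n_steps, dep_every, W,
               hill_sd, sample_stride, cutoff, bias_on):
    np.random.seed(seed)
    max_hills = n_steps // dep_every + 2
    hills = np.zeros((3, max_hills))
    n_hills = 0
    # per-coordinate bias force tabulated on a fine grid; hills are added
    # to the table at deposition time, so the per-step cost is a single
    # linear interpolation per coordinate
    n_grid = int(2.0 * _GRID_LIM / _GRID_H) + 1
    fgrid = np.zeros((3, n_grid))
    n_samp_max = n_steps // sample_stride + 3
    out_pos = np.zeros((n_samp_max, 3))
    out_t = np.zeros(n_samp_max)
    x = np.zeros(3)
    out_pos[0] = x
    out_t[0] = 0.0
    n_out = 1
    eps = 1e-4
    pref = D / kT * dt
    noise = math.sqrt(2.0 * D * dt)
    inv_s2 = 1.0 / (hill_sd * hill_sd)
    cut6 = 6.0 * hill_sd
    escaped = False
    xp = np.zeros(3)
    xm = np.zeros(3)
    for step in range(1, n_steps + 1):
        for d in range(3):
            # landscape force: central differences on the potential
            for k in range(3):
                xp[k] = x[k]
                xm[k] = x[k]
            xp[d] += eps
            xm[d] -= eps
            vp = _potential(xp, dirs, hws, well_depth, well_sigma, barrier_h,
                            wall_h, barrier_sig, shell_r)
            vm = _potential(xm, dirs, hws, well_depth, well_sigma, barrier_h,
                            wall_h, barrier_sig, shell_r)
            f = -(vp - vm) / (2.0 * eps)
            if bias_on and n_hills > 0:
                g = (x[d] + _GRID_LIM) / _GRID_H
                if 0.0 <= g <= n_grid - 1.001:
                    i0 = int(g)
                    w1 = g - i0
                    f += fgrid[d, i0] * (1.0 - w1) + fgrid[d, i0 + 1] * w1
            x[d] = x[d] + pref * f + noise * np.random.normal()
        if bias_on and step % dep_every == 0:
            for d in range(3):
                c = x[d]
                hills[d, n_hills] = c
                lo = max(0, int((c - cut6 + _GRID_LIM) / _GRID_H))
                hi = min(n_grid - 1, int((c + cut6 + _GRID_LIM) / _GRID_H) + 1)
                for i in range(lo, hi + 1):
                    dx = (i * _GRID_H - _GRID_LIM) - c
                    fgrid[d, i] += W * dx * inv_s2 * math.exp(
                        -0.5 * dx * dx * inv_s2
                    )
            n_hills += 1
        if step % sample_stride == 0:
            out_pos[n_out] = x
            out_t[n_out] = step * dt
            n_out += 1
        if x[0] * x[0] + x[1] * x[1] + x[2] * x[2] > cutoff * cutoff:
            if step % sample_stride != 0:
                out_pos[n_out] = x
                out_t[n_out] = step * dt
                n_out += 1
            escaped = True
            break
    return out_pos[:n_out], out_t[:n_out], escaped, hills[:, :n_hills]


def run_langevin(
    landscape: ToyLandscape,
    meta: MetadynamicsConfig,
    seed: int,
    bias: bool = True,
    cutoff: float = ESCAPE_CUTOFF_NM,
) -> tuple[EgressTrajectory, np.ndarray]:
    """One biased (or unbiased) Langevin trajectory from the well center.

    Returns the trajectory (frames every ``sample_every`` ps, truncated
    at the escape crossing) and the deposited hill centers, shape
    (3, n_hills).
    """
    dirs = np.stack([c.direction for c in landscape.channels])
    hws = np.array([c.half_width for c in landscape.channels])
    n_steps = int(round(meta.max_time * 1000.0 / meta.dt))
    dep_every = max(1, int(round(1.0 / (meta.deposition_rate * meta.dt))))
    stride = max(1, int(round(meta.sample_every / meta.dt)))
    pos, t, escaped, hills = _integrate(
        seed, dirs, hws, landscape.well_depth, landscape.well_sigma,
        landscape.barrier_height, landscape.wall_extra,
        landscape.barrier_sigma, landscape.shell_radius, landscape.kT,
        landscape.diffusion, meta.dt, n_steps, dep_every, meta.hill_height,
        meta.hill_sd, stride, cutoff, bias,
    )
    channel = None
    if escaped:
        u = pos[-1] / np.linalg.norm(pos[-1])
        scores = dirs @ u
        channel = landscape.channels[int(np.argmax(scores))].name
    traj = EgressTrajectory(
        times=t, positions=pos, escaped=bool(escaped),
        escape_frame=len(pos) - 1 if escaped else None,
        channel=channel if escaped else "no-escape",
    )
    return traj, hills


def gen_egress_swarm(
    landscape: ToyLandscape,
    meta: MetadynamicsConfig,
    bias: bool = True,
) -> list[EgressTrajectory]:
    """Swarm of independent biased escape trajectories with ground-truth
    channel labels (nearest gate at shell crossing); non-escaping runs
    are labeled 'no-escape' and kept."""
    rng = np.random.default_rng(meta.seed)
    seeds = rng.integers(0, 2**31 - 1, size=meta.swarm_size)
    trajs = []
    for i, s in enumerate(seeds):
        traj, _ = run_langevin(landscape, meta, int(s), bias=bias)
        traj.traj_id = i
        trajs.append(traj)
    return trajs
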