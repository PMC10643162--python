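"""Geometry of P_i-egress trajectories: escape detection, spline
discretization, path clustering and the longitudinal path collective
variable.

A trajectory is the time series of the P_i phosphorus-atom position in
the internal frame of the filament.  Escape is declared when the P atom
moves more than 1.4 nm from its initial position; frames after the
first crossing are discarded.  Escaped trajectories are smoothed with
B-splines and resampled to 100 points uniform in arc length, clustered
hierarchically on the Euclidean distance between discretized paths, and
projected onto a 30-point reference path through the Gaussian-weighted
longitudinal variable s in [0, 1] (lambda = 325 nm^-2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import interp1d, make_smoothing_spline, splev, splprep
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import AgglomerativeClustering

__all__ = [
    "EgressTrajectory",
    "ReferencePath",
    "PathClustering",
    "detect_escape",
    "smooth_and_discretize",
    "make_reference_path",
    "path_distance_matrix",
    "cluster_paths",
    "compute_pathcv",
    "backdoor_fraction",
]

ESCAPE_CUTOFF_NM = 1.4
N_PATH_POINTS = 100
N_REF_POINTS = 30
DEFAULT_LAMBDA = 325.0  # nm^-2


@dataclass
class EgressTrajectory:
    """P_i position time series (nm) in the filament frame."""

    times: np.ndarray               # ps
    positions: np.ndarray           # (n, 3) nm
    escaped: bool = False
    escape_frame: int | None = None
    channel: str | None = None      # ground-truth label when synthetic
    traj_id: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frames must be time-ordered")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def origin(self) -> np.ndarray:
        return self.positions[0]


@dataclass
class ReferencePath:
    """Discretized reference path for the longitudinal pathCV."""

    points: np.ndarray                  # (30, 3) nm
    lam: float = DEFAULT_LAMBDA        # nm^-2

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_REF_POINTS, 3):
            raise ValueError(f"reference path must have {N_REF_POINTS} points")


@dataclass
class PathClustering:
    labels: np.ndarray                  # cluster id per path
    centroids: np.ndarray               # (k, n_points, 3) mean paths
    representatives: np.ndarray         # member index per cluster
    k: int = field(default=0)

    def __post_init__(self) -> None:
        self.k = int(self.labels.max()) + 1 if len(self.labels) else 0


def detect_escape(
    traj: EgressTrajectory, cutoff: float = ESCAPE_CUTOFF_NM
) -> EgressTrajectory:
    """Flag escape and truncate strictly after the first cutoff crossing.

    Escape means the P atom's distance from its initial position exceeds
    ``cutoff`` (nm).  The crossing frame is kept; non-escape is a valid
    outcome and leaves the trajectory untouched.  Idempotent.
    """
    if len(traj.times) < 2:
        raise ValueError("need at least 2 frames")
    r = np.linalg.norm(traj.positions - traj.positions[0], axis=1)
    over = np.nonzero(r > cutoff)[0]
    if len(over) == 0:
        return EgressTrajectory(
            times=traj.times, positions=traj.positions, escaped=False,
            channel=traj.channel, traj_id=traj.traj_id,
        )
    i = int(over[0])
    return EgressTrajectory(
        times=traj.times[: i + 1],
        positions=traj.positions[: i + 1],
        escaped=True,
        escape_frame=i,
        channel=traj.channel,
        traj_id=traj.traj_id,
    )


def _spline_curve(positions: np.ndarray, smoothing):
    """Cubic B-spline fit of each coordinate against frame index.

    ``smoothing=None`` (default) uses a FITPACK smoothing factor scaled
    to the noise level estimated from second differences of the
    trajectory (s = m * sigma^2); ``"gcv"`` selects the penalty of a
    smoothing spline by generalized cross-validation (slower); a number
    is passed to FITPACK directly, with 0 interpolating.
    """
    n = len(positions)
    x = np.arange(n, dtype=float)
    if n < 4:
        raise ValueError("need at least 4 frames for spline smoothing")
    if smoothing == "gcv":
        splines = [
            make_smoothing_spline(x, positions[:, d]) for d in range(3)
        ]

        def evaluate(u: np.ndarray) -> np.ndarray:
            return np.stack([s(u) for s in splines], axis=1)

        return evaluate
    if smoothing is None:
        d2 = np.diff(positions, 2, axis=0)
        sigma2 = float((d2 ** 2).mean()) / 6.0  # second-difference noise var
        # FITPACK bounds the residual summed over all 3 coordinates
        smoothing = n * 3.0 * sigma2
    with warnings.catch_warnings():
        # a near-zero smoothing factor on noiseless input makes FITPACK
        # grumble while returning the interpolating spline, which is
        # exactly what is wanted there
        warnings.filterwarnings(
            "ignore", message=".*theoretically impossible.*"
        )
        tck, _ = splprep(positions.T, u=x, s=float(smoothing), k=3)

    def evaluate(u: np.ndarray) -> np.ndarray:
        return np.stack(splev(u, tck), axis=1)

    return evaluate


def _resample_arclength(curve: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate zero-length path")
    targets = np.linspace(0.0, total, n)
    return np.stack(
        [interp1d(s, curve[:, d])(targets) for d in range(3)], axis=1
    )


def smooth_and_discretize(
    traj: EgressTrajectory | np.ndarray,
    n: int = N_PATH_POINTS,
    smoothing: float | str | None = None,
    dense: int = 10_000,
    max_frames: int | None = 512,
) -> np.ndarray:
    """B-spline smooth a trajectory and resample it to ``n`` points
    equally spaced in arc length.

    The spline is parameterized by frame index; uniform arc-length
    spacing is obtained by evaluating the spline on a dense grid and
    interpolating at equal cumulative chord lengths.  Long trajectories
    are first decimated to ``max_frames`` evenly spaced frames (the
    sub-frame jitter carries no path information).
    """
    positions = traj.positions if isinstance(traj, EgressTrajectory) else \
        np.asarray(traj, dtype=float)
    if max_frames is not None and len(positions) > max_frames:
        idx = np.unique(
            np.linspace(0, len(positions) - 1, max_frames).round().astype(int)
        )
        positions = positions[idx]
    evaluate = _spline_curve(positions, smoothing)
    u = np.linspace(0.0, len(positions) - 1.0, dense)
    return _resample_arclength(evaluate(u), n)


def make_reference_path(
    traj: EgressTrajectory | np.ndarray,
    n: int = N_REF_POINTS,
    lam: float = DEFAULT_LAMBDA,
    smoothing: float | str | None = None,
) -> ReferencePath:
    """Reference path for the pathCV: the trajectory's own B-spline,
    discretized into ``n`` equally spaced points."""
    return ReferencePath(
        points=smooth_and_discretize(traj, n=n, smoothing=smoothing), lam=lam
    )


def path_distance_matrix(paths: Sequence[np.ndarray]) -> np.ndarray:
    """Euclidean distance matrix between discretized paths.

    Each path is flattened to a 3*n-vector; entry (i, j) is the
    Euclidean norm of the difference.  All paths must share the same
    discretization.
    """
    shapes = {p.shape for p in paths}
    if len(shapes) != 1:
        raise ValueError(f"mixed discretizations: {sorted(shapes)}")
    flat = np.stack([np.asarray(p).ravel() for p in paths])
    return squareform(pdist(flat))


def cluster_paths(
    paths: Sequence[np.ndarray],
    k: int = 4,
    matrix: np.ndarray | None = None,
) -> PathClustering:
    """Average-linkage agglomerative clustering of discretized paths.

    Cut at ``k`` clusters; each cluster's centroid is the arithmetic
    mean in discretized-path space and its representative is the member
    closest to that centroid (ties broken by lowest index).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(paths):
        raise ValueError("k exceeds the number of paths")
    stack = np.stack([np.asarray(p) for p in paths])
    if matrix is None:
        matrix = path_distance_matrix(paths)
    if k == len(paths):
        labels = np.arange(len(paths))
    else:
        model = AgglomerativeClustering(
            n_clusters=k, metric="precomputed", linkage="average"
        )
        labels = model.fit_predict(matrix)
    centroids = np.stack(
        [stack[labels == c].mean(axis=0) for c in range(k)]
    )
    reps = np.empty(k, dtype=int)
    for c in range(k):
        members = np.nonzero(labels == c)[0]
        d = np.linalg.norm(
            (stack[members] - centroids[c]).reshape(len(members), -1), axis=1
        )
        reps[c] = members[np.argmin(d)]
    return PathClustering(labels=labels, centroids=centroids,
                          representatives=reps)


def compute_pathcv(
    positions: np.ndarray | EgressTrajectory, ref: ReferencePath
) -> np.ndarray:
    """Longitudinal path collective variable s(t) in [0, 1].

    For a frame x,  s = [sum_i (i-1) w_i / sum_i w_i] / (N-1)  with
    Gaussian weights w_i = exp(-lambda ||x - x_i||^2) over the N
    reference nodes (1-based i).  When every weight underflows, the
    nearest node decides (dominant-term limit).
    """
    x = positions.positions if isinstance(positions, EgressTrajectory) else \
        np.asarray(positions, dtype=float)
    d2 = ((x[:, None, :] - ref.points[None, :, :]) ** 2).sum(axis=2)
    # stabilize: subtract the row-minimum exponent; equivalent to the
    # nearest-node fallback in the full-underflow limit
    expo = -ref.lam * d2
    expo -= expo.max(axis=1, keepdims=True)
    w = np.exp(expo)
    idx = np.arange(len(ref.points), dtype=float)
    s = (w @ idx) / w.sum(axis=1) / (len(ref.points) - 1)
    return s


def backdoor_fraction(
    trajs: Sequence[EgressTrajectory],
    predictor: Callable[[EgressTrajectory], int],
) -> float:
    """Fraction p_BD of escaped trajectories predicted to leave through
    the R177-N111 backdoor.  Undefined (ValueError) without escapes."""
    escaped = [t for t in trajs if t.escaped]
    if not escaped:
        raise ValueError("p_BD undefined: no escaped trajectories")
    return sum(int(predictor(t)) for t in escaped) / len(escaped)
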