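"""Contact-map featurization and logistic classification of backdoor
escapes.

Each escaped P_i trajectory is summarized as a 48-residue x 4-bin
contact-occupancy map: per frame, the P atom is in contact with a
residue when it lies within 0.75 nm of that residue's CA anchor; frames
are grouped into four equal bins of the longitudinal pathCV s, and the
mean contact value per residue and bin is recorded.  The flattened
192-vector feeds an L2-regularized logistic regression that returns 1
when the trajectory escapes through the R177-N111 backdoor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .egress_paths import EgressTrajectory, compute_pathcv, make_reference_path

__all__ = [
    "RESIDUE_RANGES",
    "RESIDUE_IDS",
    "AnchorSet",
    "ContactFeatureMap",
    "LabeledPathDataset",
    "BackdoorModel",
    "featurize",
    "featurize_dataset",
    "split_dataset",
    "train",
    "predict",
]

#: residue ranges whose CA atoms line the typical egress pathways
RESIDUE_RANGES: tuple[tuple[int, int], ...] = (
    (12, 18), (71, 74), (106, 116), (120, 120), (134, 138), (141, 141),
    (154, 161), (177, 177), (183, 183), (300, 301), (334, 338),
    (370, 370), (374, 374),
)

RESIDUE_IDS: tuple[int, ...] = tuple(
    rid for lo, hi in RESIDUE_RANGES for rid in range(lo, hi + 1)
)

N_ANCHORS = 48
N_BINS = 4
CONTACT_CUTOFF_NM = 0.75


@dataclass
class AnchorSet:
    """48 labeled CA anchor points (nm), keyed by residue id."""

    residue_ids: tuple[int, ...]
    coords: np.ndarray              # (48, 3) static anchors
    tags: tuple[str, ...] = None    # e.g. "R177", "N111", channel tags

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.residue_ids) != N_ANCHORS:
            raise ValueError(f"anchor set must hold {N_ANCHORS} residues")
        if self.coords.shape != (N_ANCHORS, 3):
            raise ValueError("coords must be (48, 3)")
        if self.tags is None:
            self.tags = ("",) * N_ANCHORS


@dataclass
class ContactFeatureMap:
    """48 x 4 contact occupancies in [0, 1] plus an empty-bin mask."""

    occupancy: np.ndarray           # (48, 4)
    empty_bins: np.ndarray          # (4,) bool

    def flatten(self) -> np.ndarray:
        """Residue-major 192-vector (rows are residues, columns s-bins)."""
        return self.occupancy.ravel()

    @classmethod
    def from_flat(cls, v: np.ndarray) -> "ContactFeatureMap":
        occ = np.asarray(v, dtype=float).reshape(N_ANCHORS, N_BINS)
        return cls(occupancy=occ, empty_bins=np.zeros(N_BINS, dtype=bool))


@dataclass
class LabeledPathDataset:
    """Feature vectors with binary backdoor labels and a stratified split."""

    features: np.ndarray            # (n, 192)
    labels: np.ndarray              # (n,) int 0/1
    train_idx: np.ndarray | None = None
    test_idx: np.ndarray | None = None
    trajectories: list = field(default_factory=list, repr=False)


@dataclass
class BackdoorModel:
    weights: np.ndarray
    intercept: float
    seed: int = 0
    threshold: float = 0.5

    def decision(self, features: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(features) @ self.weights + self.intercept
        return 1.0 / (1.0 + np.exp(-z))


def featurize(
    traj: EgressTrajectory | np.ndarray,
    anchors: AnchorSet,
    s_series: np.ndarray,
    cutoff: float = CONTACT_CUTOFF_NM,
) -> ContactFeatureMap:
    """Contact-occupancy map of one escaped trajectory.

    ``s_series`` is the pathCV value per frame; frames fall into four
    equal s-bins ([0, .25), ..., [.75, 1]).  An empty bin contributes
    zeros and is flagged in the mask rather than dropping the
    trajectory.
    """
    pos = traj.positions if isinstance(traj, EgressTrajectory) else \
        np.asarray(traj, dtype=float)
    s = np.asarray(s_series, dtype=float)
    if len(s) != len(pos):
        raise ValueError("s_series must align with trajectory frames")
    d = np.linalg.norm(pos[:, None, :] - anchors.coords[None, :, :], axis=2)
    contact = d <= cutoff                       # (frames, 48)
    bins = np.clip((s * N_BINS).astype(int), 0, N_BINS - 1)
    occ = np.zeros((N_ANCHORS, N_BINS))
    empty = np.zeros(N_BINS, dtype=bool)
    for b in range(N_BINS):
        m = bins == b
        if not np.any(m):
            empty[b] = True
            continue
        occ[:, b] = contact[m].mean(axis=0)
    return ContactFeatureMap(occupancy=occ, empty_bins=empty)


def trajectory_features(
    traj: EgressTrajectory, anchors: AnchorSet,
    cutoff: float = CONTACT_CUTOFF_NM,
) -> np.ndarray:
    """Feature vector of one escaped trajectory: pathCV against the
    trajectory's own spline reference, then contact occupancies."""
    ref = make_reference_path(traj)
    s = compute_pathcv(traj, ref)
    return featurize(traj, anchors, s, cutoff=cutoff).flatten()


def featurize_dataset(
    trajs: Sequence[EgressTrajectory],
    labels: Sequence[int],
    anchors: AnchorSet,
    cutoff: float = CONTACT_CUTOFF_NM,
) -> LabeledPathDataset:
    X = np.stack([trajectory_features(t, anchors, cutoff) for t in trajs])
    return LabeledPathDataset(
        features=X, labels=np.asarray(labels, dtype=int),
        trajectories=list(trajs),
    )


def split_dataset(
    dataset: LabeledPathDataset,
    train_frac: float = 0.75,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random train/test split preserving class proportions.

    The total test size is round((1 - train_frac) * n); per-class test
    counts follow largest-remainder rounding, which floors the minority
    class on ties (300 samples with 70 positives give a 75-sample test
    set holding 17 positives).
    """
    y = dataset.labels
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("both classes need at least 2 members")
    n = len(y)
    n_test = int(round((1.0 - train_frac) * n))
    ideal = (1.0 - train_frac) * counts
    base = np.floor(ideal).astype(int)
    remainder = ideal - base
    short = n_test - base.sum()
    # largest remainder first; ties favor the majority class
    order = np.lexsort((-counts, -remainder))
    for i in range(short):
        base[order[i % len(classes)]] += 1
    base = np.maximum(base, 1)  # every class is represented in the test set
    rng = np.random.default_rng(seed)
    test_idx = []
    for cls, n_cls_test in zip(classes, base):
        members = np.nonzero(y == cls)[0]
        test_idx.append(rng.choice(members, size=n_cls_test, replace=False))
    test_idx = np.sort(np.concatenate(test_idx))
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    dataset.train_idx, dataset.test_idx = train_idx, test_idx
    return train_idx, test_idx


def train(
    dataset: LabeledPathDataset,
    seed: int = 0,
    C: float = 1.0,
) -> tuple[BackdoorModel, np.ndarray]:
    """Fit the logistic classifier on the training split and evaluate the
    confusion matrix [[TN, FP], [FN, TP]] on the test split.

    L2 regularization (inverse strength ``C``) keeps the fit defined on
    linearly separable data.
    """
    if dataset.train_idx is None:
        split_dataset(dataset, seed=seed)
    clf = LogisticRegression(C=C, max_iter=5000, random_state=seed)
    clf.fit(dataset.features[dataset.train_idx],
            dataset.labels[dataset.train_idx])
    model = BackdoorModel(
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        seed=seed,
    )
    y_true = dataset.labels[dataset.test_idx]
    y_pred = (model.decision(dataset.features[dataset.test_idx]) >=
              model.threshold).astype(int)
    cm = np.zeros((2, 2), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[t, p] += 1
    return model, cm


def predict(
    model: BackdoorModel,
    traj: EgressTrajectory,
    anchors: AnchorSet,
    s_series: np.ndarray | None = None,
    cutoff: float = CONTACT_CUTOFF_NM,
) -> int:
    """1 if the trajectory is classified as a backdoor escape, else 0."""
    if s_series is None:
        x = trajectory_features(traj, anchors, cutoff)
    else:
        x = featurize(traj, anchors, s_series, cutoff=cutoff).flatten()
    return int(model.decision(x)[0] >= model.threshold)
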