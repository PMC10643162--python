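"""Labeled egress-trajectory datasets with ground-truth channel labels.

Mixes biased escape trajectories that leave through the tagged
R177-N111 backdoor gate (positives) with escapes through the other
channels (negatives), to requested counts — the synthetic counterpart
of a manually labeled training corpus.
"""

from __future__ import annotations

import numpy as np

from ..backdoor_classifier import LabeledPathDataset, featurize_dataset
from .landscape import (
    BACKDOOR_CHANNEL,
    MetadynamicsConfig,
    ToyLandscape,
    run_langevin,
)

__all__ = ["gen_labeled_path_dataset"]


def gen_labeled_path_dataset(
    n_total: int,
    n_positive: int,
    landscape: ToyLandscape | None = None,
    meta: MetadynamicsConfig | None = None,
    seed: int = 0,
    max_attempts: int | None = None,
) -> LabeledPathDataset:
    """Generate ``n_total`` labeled escape trajectories, ``n_positive``
    of which exit through the backdoor gate.

    Trajectories are simulated in batches until both class quotas are
    filled; surplus escapes are discarded.  Featurization (pathCV
    binning + contact occupancies) happens against the landscape's
    anchors.  Reproducible per seed.
    """
    if n_positive > n_total:
        raise ValueError("n_positive exceeds n_total")
    landscape = landscape or ToyLandscape()
    meta = meta or MetadynamicsConfig()
    landscape.backdoor_index  # raises if no tagged gate
    if max_attempts is None:
        max_attempts = max(8 * n_total, 50)
    rng = np.random.default_rng(seed)
    pos, neg = [], []
    n_negative = n_total - n_positive
    for _ in range(max_attempts):
        if len(pos) >= n_positive and len(neg) >= n_negative:
            break
        s = int(rng.integers(0, 2**31 - 1))
        traj, _ = run_langevin(landscape, meta, s, bias=True)
        if not traj.escaped:
            continue
        if traj.channel == BACKDOOR_CHANNEL:
            if len(pos) < n_positive:
                pos.append(traj)
        elif len(neg) < n_negative:
            neg.append(traj)
    if len(pos) < n_positive or len(neg) < n_negative:
        raise RuntimeError(
            f"could not fill quotas within {max_attempts} trajectories "
            f"({len(pos)}/{n_positive} positives, {len(neg)}/{n_negative} "
            "negatives)"
        )
    trajs = pos + neg
    labels = [1] * len(pos) + [0] * len(neg)
    for i, t in enumerate(trajs):
        t.traj_id = i
    return featurize_dataset(trajs, labels, landscape.anchors)
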