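"""CSV/JSON interchange for traces, trajectories, anchors and fits."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .backdoor_classifier import AnchorSet
from .bulk_kinetics import BulkTrace, ReleaseModelFit
from .egress_paths import EgressTrajectory
from .filament_kinetics import DepolFit, FilamentTrace, VelocityProfile

__all__ = [
    "write_bulk_trace", "read_bulk_trace",
    "write_filament_trace", "read_filament_trace",
    "write_trajectory", "read_trajectory",
    "write_anchors", "read_anchors",
    "write_labels", "write_velocity_profile", "write_depol_fit",
    "write_release_fit",
]


def write_bulk_trace(trace: BulkTrace, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": trace.time, "pyrene": trace.pyrene, "mdcc": trace.mdcc}
    ).to_csv(path, index=False)


def read_bulk_trace(path: str | Path, variant: str = "", replicate: int = 0
                    ) -> BulkTrace:
    df = pd.read_csv(path)
    return BulkTrace(
        time=df["time_s"].to_numpy(), pyrene=df["pyrene"].to_numpy(),
        mdcc=df["mdcc"].to_numpy(), variant=variant, replicate=replicate,
    )


def write_filament_trace(trace: FilamentTrace, path: str | Path) -> None:
    pd.DataFrame({
        "time_s": trace.time,
        "length_subunits": trace.length,
        "phase": trace.phase,
    }).to_csv(path, index=False)


def read_filament_trace(path: str | Path, filament_id: int = 0) -> FilamentTrace:
    df = pd.read_csv(path)
    depol = df.loc[df["phase"] == "depolymerization", "time_s"]
    depol_start = float(depol.iloc[0]) if len(depol) else float(
        df["time_s"].iloc[-1]
    )
    return FilamentTrace(
        time=df["time_s"].to_numpy(),
        length=df["length_subunits"].to_numpy(),
        depol_start=depol_start,
        filament_id=filament_id,
    )


def write_trajectory(traj: EgressTrajectory, path: str | Path) -> None:
    pd.DataFrame({
        "t_ps": traj.times,
        "x_nm": traj.positions[:, 0],
        "y_nm": traj.positions[:, 1],
        "z_nm": traj.positions[:, 2],
    }).to_csv(path, index=False)


def read_trajectory(path: str | Path, traj_id: int = 0) -> EgressTrajectory:
    df = pd.read_csv(path)
    return EgressTrajectory(
        times=df["t_ps"].to_numpy(),
        positions=df[["x_nm", "y_nm", "z_nm"]].to_numpy(),
        traj_id=traj_id,
    )


def write_anchors(anchors: AnchorSet, path: str | Path) -> None:
    pd.DataFrame({
        "anchor_id": anchors.residue_ids,
        "tag": anchors.tags,
        "x_nm": anchors.coords[:, 0],
        "y_nm": anchors.coords[:, 1],
        "z_nm": anchors.coords[:, 2],
    }).to_csv(path, index=False)


def read_anchors(path: str | Path) -> AnchorSet:
    df = pd.read_csv(path)
    return AnchorSet(
        residue_ids=tuple(int(i) for i in df["anchor_id"]),
        coords=df[["x_nm", "y_nm", "z_nm"]].to_numpy(),
        tags=tuple(df["tag"].fillna("")),
    )


def write_labels(trajs: Sequence[EgressTrajectory], labels: Sequence[int],
                 path: str | Path) -> None:
    pd.DataFrame({
        "traj_id": [t.traj_id for t in trajs],
        "label": list(labels),
        "channel": [t.channel or "" for t in trajs],
    }).to_csv(path, index=False)


def write_velocity_profile(profile: VelocityProfile, path: str | Path) -> None:
    pd.DataFrame({
        "tau_s": profile.tau, "inv_v": profile.inv_v, "sd": profile.sd,
    }).to_csv(path, index=False)


def write_depol_fit(fit: DepolFit, path: str | Path) -> None:
    payload = {
        "a": fit.a, "b": fit.b, "c": fit.c,
        "a_se": fit.a_se, "b_se": fit.b_se, "c_se": fit.c_se,
        "flat": fit.flat,
        "k_release_core": fit.k_release_core,
        "v_depol_ADP": fit.v_depol_ADP,
        "v_depol_ADPPi": fit.v_depol_ADPPi,
        "k_release_BE": None if fit.flat else fit.k_release_BE,
        "k_off_ADPPi": fit.k_off_ADPPi,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_release_fit(fit: ReleaseModelFit, variant: str, path: str | Path
                      ) -> None:
    payload = {
        "variant": variant,
        "k_poly": fit.k_poly, "k_poly_se": fit.k_poly_se,
        "k_release": fit.k_release, "k_release_se": fit.k_release_se,
        "k_bind": fit.k_bind, "half_time_s": fit.half_time,
        "residual_norm": fit.residual_norm, "at_bounds": fit.at_bounds,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
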