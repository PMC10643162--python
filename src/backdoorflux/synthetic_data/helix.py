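"""Ideal helical stacks of a template subunit, for validating the
helical-parameter estimator (rise ~27.5 A, twist ~-166.5 deg for the
actin genetic helix)."""

from __future__ import annotations

import math
import string

import numpy as np

from ..structure_observables import StructureSnapshot

__all__ = ["make_template", "gen_ideal_helix"]


def make_template(n_atoms: int = 12, seed: int = 7) -> StructureSnapshot:
    """Synthetic single-chain CA template: a deterministic, chirally
    asymmetric point cloud standing in for one filament subunit."""
    rng = np.random.default_rng(seed)
    coords = rng.normal(0.0, 8.0, size=(n_atoms, 3)) + np.array([15.0, 0.0, 0.0])
    return StructureSnapshot.from_arrays(
        chain=["A"] * n_atoms,
        res_id=list(range(1, n_atoms + 1)),
        res_name=["ALA"] * n_atoms,
        atom_name=["CA"] * n_atoms,
        coords=coords,
    )


def gen_ideal_helix(
    rise: float,
    twist: float,
    n_subunits: int,
    template: StructureSnapshot,
) -> list[StructureSnapshot]:
    """Stack ``n_subunits`` copies of ``template``: subunit i+1 is
    subunit i rotated by ``twist`` degrees about z and translated by
    ``rise`` Angstrom along z."""
    if n_subunits < 2:
        raise ValueError("need at least 2 subunits")
    if template.atoms.array_length() == 0:
        raise ValueError("empty template")
    th = math.radians(twist)
    R = np.array([
        [math.cos(th), -math.sin(th), 0.0],
        [math.sin(th), math.cos(th), 0.0],
        [0.0, 0.0, 1.0],
    ])
    chains = string.ascii_uppercase
    out = []
    for i in range(n_subunits):
        Ri = np.linalg.matrix_power(R, i)
        ti = np.array([0.0, 0.0, rise * i])
        s = template.transformed(Ri, ti)
        s.atoms.chain_id = np.full(s.atoms.array_length(), chains[i % 26])
        out.append(s)
    return out
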