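"""Structural observables: distances, torsions, ΔRMSD/SMD, helical screw."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from backdoorflux.structure_observables import (
    SMDParams,
    StructureSnapshot,
    atom_distance,
    chi1,
    delta_rmsd,
    group_distance,
    helical_parameters,
    kabsch_rmsd,
    smd_potential,
)
from backdoorflux.synthetic_data import gen_ideal_helix, make_template


def snapshot(coords, atom_names=None, res_ids=None, chain="A"):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return StructureSnapshot.from_arrays(
        chain=[chain] * n,
        res_id=res_ids or list(range(1, n + 1)),
        res_name=["ALA"] * n,
        atom_name=atom_names or ["CA"] * n,
        coords=coords,
    )


def random_rigid(seed):
    rng = np.random.default_rng(seed)
    R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
    t = rng.normal(0, 10.0, size=3)
    return R, t


class TestDistances:
    def test_atom_distance_simple(self):
        s = snapshot([[0, 0, 0], [5, 0, 0]])
        d = atom_distance(
            s, dict(res_ids=1, atom_names="CA"), dict(res_ids=2, atom_names="CA")
        )
        assert d == pytest.approx(5.0)

    def test_ambiguous_selection_rejected(self):
        s = snapshot([[0, 0, 0], [1, 0, 0]], res_ids=[1, 1])
        with pytest.raises(ValueError, match="expected 1"):
            atom_distance(
                s, dict(res_ids=1), dict(res_ids=1)
            )

    def test_rigid_invariance(self):
        s = snapshot([[0, 0, 0], [3, 4, 0], [1, 1, 1]])
        R, t = random_rigid(0)
        s2 = s.transformed(R, t)
        d1 = atom_distance(s, dict(res_ids=1), dict(res_ids=2))
        d2 = atom_distance(s2, dict(res_ids=1), dict(res_ids=2))
        assert d1 == pytest.approx(d2, abs=1e-9)

    def test_group_distance_point_masses(self):
        s = snapshot([[0, 0, 0], [0, 3, 4]])
        d = group_distance(s, dict(res_ids=1), dict(res_ids=2))
        assert d == pytest.approx(5.0)

    def test_group_centroid_matches_brute_force(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(0, 5, size=(10, 3))
        s = snapshot(coords, res_ids=[1] * 5 + [2] * 5)
        d = group_distance(s, dict(res_ids=1), dict(res_ids=2))
        expected = np.linalg.norm(
            coords[:5].mean(axis=0) - coords[5:].mean(axis=0)
        )
        assert d == pytest.approx(expected)


def dihedral_brute(p0, p1, p2, p3):
    """Independent four-point dihedral via plane normals and atan2."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return math.degrees(math.atan2(np.dot(m, n2), np.dot(n1, n2)))


def residue_with_chi1(angle_deg):
    """Four atoms N, CA, CB, CG constructed for a given chi1."""
    a = math.radians(angle_deg)
    coords = np.array([
        [1.0, 0.0, 1.0],                       # N (off-axis)
        [0.0, 0.0, 0.0],                       # CA
        [0.0, 0.0, -1.5],                      # CB (axis along z)
        [math.cos(a), math.sin(a), -2.5],      # CG rotated by chi1
    ])
    # place N so the zero reference of the dihedral is the +x direction
    return StructureSnapshot.from_arrays(
        chain=["A"] * 4, res_id=[161] * 4, res_name=["HIS"] * 4,
        atom_name=["N", "CA", "CB", "CG"], coords=coords,
    )


class TestChi1:
    @pytest.mark.parametrize("angle", [60.0, -60.0, 170.0])
    def test_constructed_rotamer(self, angle):
        s = residue_with_chi1(angle)
        got = chi1(s, "A", 161)
        brute = dihedral_brute(*s.xyz)
        assert got == pytest.approx(brute, abs=1e-9)
        # mirror image flips the sign
        m = StructureSnapshot.from_arrays(
            chain=["A"] * 4, res_id=[161] * 4, res_name=["HIS"] * 4,
            atom_name=["N", "CA", "CB", "CG"],
            coords=s.xyz * np.array([1.0, -1.0, 1.0]),
        )
        assert chi1(m, "A", 161) == pytest.approx(-got, abs=1e-9)

    def test_matches_brute_force_on_random_coordinates(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            coords = rng.normal(0, 3, size=(4, 3))
            s = StructureSnapshot.from_arrays(
                chain=["A"] * 4, res_id=[7] * 4, res_name=["SER"] * 4,
                atom_name=["N", "CA", "CB", "OG"], coords=coords,
            )
            assert chi1(s, "A", 7) == pytest.approx(
                dihedral_brute(*coords), abs=1e-9
            )

    def test_missing_gamma_atom_rejected(self):
        s = snapshot([[0, 0, 0], [1, 0, 0], [1, 1, 0]],
                     atom_names=["N", "CA", "CB"], res_ids=[5, 5, 5])
        with pytest.raises(ValueError, match="gamma"):
            chi1(s, "A", 5)


def kabsch_brute(mobile, reference):
    """Independent Kabsch RMSD: SVD on the covariance, explicit algebra."""
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)
    U, S, Vt = np.linalg.svd(P.T @ Q)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    aligned = P @ R.T
    return float(np.sqrt(((aligned - Q) ** 2).sum(axis=1).mean()))


@pytest.fixture
def fit_structures():
    """Three 20-residue CA chains sharing numbering, covering range 8-21
    plus padding so the reduced fit ranges resolve identically."""
    rng = np.random.default_rng(3)
    base = rng.normal(0, 5, size=(20, 3))
    core = snapshot(base, res_ids=list(range(8, 28)))
    be = snapshot(base + rng.normal(0, 1.0, size=base.shape),
                  res_ids=list(range(8, 28)))
    x = snapshot(base + rng.normal(0, 0.5, size=base.shape),
                 res_ids=list(range(8, 28)))
    return x, core, be


FIT = ((8, 21), (22, 27))


class TestDeltaRmsdAndSMD:
    def test_reference_structures_give_signed_extremes(self, fit_structures):
        _, core, be = fit_structures
        R = kabsch_rmsd(
            core.xyz, be.xyz
        ) / 10.0
        assert delta_rmsd(core, core, be, FIT) == pytest.approx(-R, abs=1e-9)
        assert delta_rmsd(be, core, be, FIT) == pytest.approx(R, abs=1e-9)

    def test_kabsch_matches_brute_force(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 3, size=(10, 3))
        b = rng.normal(0, 3, size=(10, 3))
        assert kabsch_rmsd(a, b) == pytest.approx(kabsch_brute(a, b), abs=1e-9)

    def test_fitted_rmsd_never_exceeds_unfitted(self):
        rng = np.random.default_rng(5)
        for seed in range(5):
            a = rng.normal(0, 3, size=(12, 3))
            R, t = random_rigid(seed)
            b = a @ R.T + t + rng.normal(0, 0.3, size=a.shape)
            raw = float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))
            assert kabsch_rmsd(a, b) <= raw + 1e-12

    def test_rigid_invariance_of_delta_rmsd(self, fit_structures):
        x, core, be = fit_structures
        R, t = random_rigid(6)
        assert delta_rmsd(x.transformed(R, t), core, be, FIT) == \
            pytest.approx(delta_rmsd(x, core, be, FIT), abs=1e-9)

    def test_smd_conventions(self, fit_structures):
        _, core, be = fit_structures
        R = kabsch_rmsd(core.xyz, be.xyz) / 10.0
        zero = SMDParams(fit_ranges=FIT)
        printed = SMDParams(fit_ranges=FIT, offset_convention="as_printed")
        assert smd_potential(core, 0.0, zero, core, be) == \
            pytest.approx(0.0, abs=1e-12)
        assert smd_potential(core, 0.0, printed, core, be) == \
            pytest.approx(0.5 * printed.k * (2 * R) ** 2, rel=1e-9)

    def test_smd_quadratic_in_time(self, fit_structures):
        x, core, be = fit_structures
        p = SMDParams(fit_ranges=FIT)
        arg0 = delta_rmsd(x, core, be, FIT) + kabsch_rmsd(
            core.xyz, be.xyz
        ) / 10.0
        for t in (0.0, 10.0, 20.0, 40.0):
            u = smd_potential(x, t, p, core, be)
            assert u == pytest.approx(
                0.5 * p.k * (arg0 - p.v * t) ** 2, rel=1e-9
            )


class TestHelicalParameters:
    def test_actin_like_helix_recovered(self):
        subs = gen_ideal_helix(27.58, -166.5, 5, make_template())
        hp = helical_parameters(subs)
        assert hp.rise == pytest.approx(27.58, abs=1e-6)
        assert hp.twist == pytest.approx(-166.5, abs=1e-6)
        assert hp.rise_sd == pytest.approx(0.0, abs=1e-6)
        assert len(hp.per_interface) == 4

    def test_barbed_end_interface_two_subunits(self):
        subs = gen_ideal_helix(27.47, -165.7, 2, make_template())
        hp = helical_parameters(subs)
        assert hp.rise == pytest.approx(27.47, abs=1e-6)
        assert hp.twist == pytest.approx(-165.7, abs=1e-6)

    def test_pure_translation_stack(self):
        subs = gen_ideal_helix(12.0, 0.0, 3, make_template())
        hp = helical_parameters(subs)
        assert hp.twist == pytest.approx(0.0, abs=1e-9)
        assert hp.rise == pytest.approx(12.0, abs=1e-9)

    def test_rigid_invariance(self):
        subs = gen_ideal_helix(27.58, -166.5, 5, make_template())
        R, t = random_rigid(7)
        moved = [s.transformed(R, t) for s in subs]
        hp = helical_parameters(moved)
        assert hp.rise == pytest.approx(27.58, abs=1e-9)
        assert hp.twist == pytest.approx(-166.5, abs=1e-9)

    def test_screw_round_trip(self):
        # re-composing the decomposed screw motion reproduces the
        # fitted transform
        from backdoorflux.structure_observables import (
            _kabsch_transform,
            _screw_decompose,
        )
        subs = gen_ideal_helix(27.58, -166.5, 2, make_template())
        a, b = subs[0].xyz, subs[1].xyz
        R, t = _kabsch_transform(a, b)
        assert np.allclose(a @ R.T + t, b, atol=1e-9)
        rise, twist = _screw_decompose(R, t)
        rotvec = Rotation.from_matrix(R).as_rotvec()
        axis = rotvec / np.linalg.norm(rotvec)
        if np.dot(t, axis) < 0:
            axis = -axis
        R2 = Rotation.from_rotvec(
            axis * math.radians(twist)
        ).as_matrix()
        assert np.allclose(R2, R, atol=1e-9)

    def test_too_few_subunits_rejected(self):
        with pytest.raises(ValueError, match="2 subunits"):
            helical_parameters([make_template()])
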