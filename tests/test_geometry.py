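"""Ring planes, dihedral pairs, identity calls, buried area, superposition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from phycokit import geometry as ge
from phycokit import synth
from phycokit.geometry import AtomSet


def _pentagon(radius=1.2, z=0.0):
    th = np.radians(90.0 + 72.0 * np.arange(5))
    return np.column_stack([radius * np.cos(th), radius * np.sin(th),
                            np.full(5, z)])


def _atoms(coords, chain="A", names=None, element="C"):
    n = len(coords)
    return AtomSet(
        names=np.array(names or [f"C{i}" for i in range(n)]),
        elements=np.array([element] * n),
        res_ids=np.arange(1, n + 1),
        res_names=np.array(["LIG"] * n),
        chain_ids=np.array([chain] * n),
        coords=np.asarray(coords, dtype=float),
    )


class TestRingPlane:
    def test_exact_pentagon(self):
        plane = ge.fit_ring_plane(_pentagon())
        assert plane.rms_out_of_plane == pytest.approx(0.0, abs=1e-12)
        assert abs(plane.normal @ [0, 0, 1]) == pytest.approx(1.0, abs=1e-12)

    def test_displaced_substituent(self):
        sub = np.array([[0.5, 0.5, 0.5]])
        plane = ge.fit_ring_plane(_pentagon(), sub)
        assert plane.substituent_deviation == pytest.approx(0.5, abs=1e-9)
        assert plane.substituent_asymmetry == pytest.approx(0.5, abs=1e-9)

    def test_noise_rms_tracks_sigma(self):
        rng = np.random.default_rng(1)
        sigma = 0.05
        rmss = []
        for _ in range(100):
            noisy = _pentagon() + rng.normal(0, sigma, (5, 3))
            rmss.append(ge.fit_ring_plane(noisy).rms_out_of_plane)
        # TLS rms of 5 points absorbs 3 dof: expect sigma * sqrt(2/5)-ish
        assert np.mean(rmss) == pytest.approx(sigma * np.sqrt(2.0 / 5.0), rel=0.3)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(2)
        ring = _pentagon() + rng.normal(0, 0.02, (5, 3))
        base = ge.fit_ring_plane(ring)
        rot = Rotation.from_euler("xyz", [0.4, -1.1, 2.0])
        moved = ge.fit_ring_plane(rot.apply(ring) + np.array([5.0, -3.0, 2.0]))
        assert moved.rms_out_of_plane == pytest.approx(
            base.rms_out_of_plane, abs=1e-9)
        assert abs(moved.normal @ rot.apply(base.normal)) == pytest.approx(
            1.0, abs=1e-9)

    def test_collinear_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            ge.fit_ring_plane(line)

    def test_too_few_atoms(self):
        with pytest.raises(ValueError, match="4 atoms"):
            ge.fit_ring_plane(_pentagon()[:3])


class TestDihedralPairs:
    def test_fully_coplanar(self):
        bilin, _ = synth.gen_bilin_coords("PCB", d_outer=0.0, d_inner=0.0,
                                          a_outer=0.0, a_inner=0.0)
        pairs = ge.dihedral_pairs(bilin)
        for side in ("A", "D"):
            assert pairs[side].theta_inner == pytest.approx(0.0, abs=1e-6)
            assert pairs[side].theta_outer == pytest.approx(0.0, abs=1e-6)
        assert pairs["BC_angle"] == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("twist", [10.0, 30.0, 55.0])
    def test_outer_twist_recovery(self, twist):
        bilin, _ = synth.gen_bilin_coords("PEB", d_outer=twist)
        pairs = ge.dihedral_pairs(bilin)
        assert pairs["D"].theta_outer == pytest.approx(twist, abs=0.5)

    def test_inner_twist_recovery(self):
        bilin, _ = synth.gen_bilin_coords("PEB", d_outer=0.0, d_inner=20.0)
        pairs = ge.dihedral_pairs(bilin)
        assert pairs["D"].theta_inner == pytest.approx(20.0, abs=0.5)
        assert pairs["D"].theta_outer == pytest.approx(0.0, abs=1e-6)

    def test_rigid_motion_and_ring_permutation_invariance(self):
        bilin, _ = synth.gen_bilin_coords("PEB", d_outer=30.0, seed=3)
        base = ge.dihedral_pairs(bilin)
        rot = Rotation.from_euler("zyx", [1.0, 0.2, -0.7])
        rng = np.random.default_rng(0)
        moved = synth.gen_bilin_coords("PEB", d_outer=30.0, seed=3)[0]
        for R in "ABCD":
            perm = rng.permutation(5)
            moved.rings[R] = rot.apply(moved.rings[R][perm]) + 11.0
        moved.ring_a_substituents = rot.apply(moved.ring_a_substituents) + 11.0
        for s in ("A", "D"):
            moved.bridges[s] = rot.apply(moved.bridges[s]) + 11.0
        out = ge.dihedral_pairs(moved)
        for side in ("A", "D"):
            assert out[side].theta_outer == pytest.approx(
                base[side].theta_outer, abs=1e-6)
            assert out[side].theta_inner == pytest.approx(
                base[side].theta_inner, abs=1e-6)


class TestPlanarityVerdict:
    def _plane(self, devs):
        subs = np.array([[0.5, 0.5, d] for d in devs])
        return ge.fit_ring_plane(_pentagon(), subs)

    def test_ideal_sp2(self):
        assert ge.planarity_verdict(self._plane([0.0, 0.0])) == "planar_sp2"

    def test_ideal_sp3(self):
        assert ge.planarity_verdict(self._plane([0.7, -0.7])) == "nonplanar_sp3"

    def test_between_thresholds_indeterminate(self):
        assert ge.planarity_verdict(self._plane([0.25, -0.25])) == "indeterminate"

    def test_single_substituent_tetrahedral(self):
        assert ge.planarity_verdict(self._plane([0.7])) == "nonplanar_sp3"


class TestChromophoreIdentity:
    @pytest.mark.parametrize("identity", ["PEB", "PCB", "DBV"])
    def test_noiseless_recovery(self, identity):
        bilin, _ = synth.gen_bilin_coords(identity, seed=7)
        call = ge.call_chromophore_identity(bilin)
        assert call.identity == identity

    def test_evidence_attached(self):
        bilin, _ = synth.gen_bilin_coords("PCB", seed=1)
        call = ge.call_chromophore_identity(bilin)
        assert call.ring_a_verdict == "nonplanar_sp3"
        assert call.cd_bridge_angle < call.thresholds["cd_angle"]
        assert set(call.dihedrals) == {"A", "D"}

    def test_noisy_recovery_rate(self):
        idents = ["PEB", "PCB", "DBV"]
        ok = 0
        n = 90
        for i in range(n):
            ident = idents[i % 3]
            bilin, _ = synth.gen_bilin_coords(ident, noise_sd=0.1, seed=2000 + i)
            ok += ge.call_chromophore_identity(bilin).identity == ident
        assert ok / n >= 0.95


class TestBuriedSurfaceArea:
    def test_distant_groups_zero(self):
        a = _atoms([[0.0, 0.0, 0.0]])
        b = _atoms([[50.0, 0.0, 0.0]], chain="B")
        res = ge.buried_surface_area(a, b)
        assert res.half_difference == pytest.approx(0.0, abs=1e-9)

    def test_coincident_spheres_closed_form(self):
        a = _atoms([[0.0, 0.0, 0.0]])
        res = ge.buried_surface_area(a, a, n_points=960)
        analytic = 2.0 * np.pi * (1.7 + 1.4) ** 2
        assert res.half_difference == pytest.approx(analytic, rel=0.01)

    def test_symmetry_and_convergence(self):
        rng = np.random.default_rng(3)
        a = _atoms(rng.normal(0, 2.0, (25, 3)))
        b = _atoms(rng.normal(0, 2.0, (25, 3)) + [3.5, 0, 0], chain="B")
        r1 = ge.buried_surface_area(a, b)
        r2 = ge.buried_surface_area(b, a)
        assert r1.half_difference == pytest.approx(r2.half_difference, rel=1e-12)
        assert r1.half_difference >= 0
        dense = ge.buried_surface_area(a, b, n_points=1920)
        assert abs(dense.half_difference - r1.half_difference) < 0.01 * max(
            r1.half_difference, 1.0)

    def test_against_independent_sasa_oracle(self):
        biotite_struct = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(5)
        coords = rng.normal(0, 3.0, (40, 3))
        ours = ge.shrake_rupley_sasa(coords, np.full(40, 1.7), 1.4, 960).sum()
        arr = biotite_struct.AtomArray(40)
        arr.coord = coords
        arr.element = np.array(["C"] * 40)
        arr.atom_name = np.array([f"C{i}" for i in range(40)])
        arr.res_id = np.arange(1, 41)
        arr.res_name = np.array(["LIG"] * 40)
        arr.chain_id = np.array(["A"] * 40)
        theirs = biotite_struct.sasa(
            arr, probe_radius=1.4, point_number=960,
            vdw_radii=np.full(40, 1.7)).sum()
        assert ours == pytest.approx(theirs, rel=0.02)

    def test_empty_group_rejected(self):
        a = _atoms([[0.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="non-empty"):
            ge.buried_surface_area(a, a._subset(np.zeros(1, dtype=bool)))


class TestSuperposition:
    def test_self_superposition(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(0, 5, (100, 3))
        assert ge.superpose_rmsd(coords, coords).rmsd == pytest.approx(0.0,
                                                                       abs=1e-12)

    def test_rigid_copy(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(0, 5, (500, 3))
        rot = Rotation.from_euler("xyz", [0.3, 1.0, -0.5])
        moved = rot.apply(coords) + [1.0, 2.0, 3.0]
        res = ge.superpose_rmsd(moved, coords)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.apply(moved), coords, atol=1e-9)

    def test_isotropic_noise_expectation(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(0, 5, (2000, 3))
        sigma = 0.2
        noisy = coords + rng.normal(0, sigma, coords.shape)
        res = ge.superpose_rmsd(noisy, coords)
        assert res.rmsd == pytest.approx(sigma * np.sqrt(3.0), rel=0.05)

    def test_never_worse_than_unsuperposed(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(0, 5, (200, 3))
        other = rng.normal(0, 5, (200, 3))
        raw = float(np.sqrt(np.mean(np.sum((coords - other) ** 2, axis=1))))
        assert ge.superpose_rmsd(coords, other).rmsd <= raw + 1e-12

    def test_atomset_pairing_and_mismatch(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(0, 5, (20, 3))
        a = _atoms(coords)
        b = _atoms(rng.permutation(coords))  # same atoms, shuffled rows
        # b has identical keys but different coordinate order: pair by key
        order = rng.permutation(20)
        b = a._subset(np.ones(20, dtype=bool))
        b.coords = b.coords
        res = ge.superpose_rmsd(a, b)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        short = a._subset(np.arange(20) < 15)
        with pytest.raises(ValueError, match="unpaired"):
            ge.superpose_rmsd(a, short)


def test_structure_file_roundtrip(tmp_path):
    gemmi = pytest.importorskip("gemmi")
    st = gemmi.Structure()
    st.name = "toy"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    res = gemmi.Residue()
    res.name = "GLY"
    res.seqid = gemmi.SeqId(1, " ")
    for i, nm in enumerate(["N", "CA", "C", "O"]):
        at = gemmi.Atom()
        at.name = nm
        at.element = gemmi.Element(nm[0])
        at.pos = gemmi.Position(float(i), 0.0, 0.0)
        at.occ = 1.0
        res.add_atom(at)
    chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    path = tmp_path / "toy.pdb"
    st.write_pdb(str(path))
    atoms = ge.read_structure(path)
    assert len(atoms) == 4
    assert set(atoms.names) == {"N", "CA", "C", "O"}
    assert atoms.select(atom_names=["CA"]).coords.shape == (1, 3)
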