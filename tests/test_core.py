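"""Structure model: superposition, RMSD, accessible surface area, masses."""

import math

import numpy as np
import pytest

from mutadyn.core import (SelectionError, Structure, TrajectorySeries,
                          apply_substitutions, extract_construct,
                          kabsch_superpose, parse_selection, read_pdb,
                          rmsd_series, sequence_mass, shrake_rupley_asa,
                          write_pdb)
from mutadyn.synthetic import (SYNTHETIC_FIRST_RES_ID,
                               SYNTHETIC_VPS9_LIKE_SEQUENCE)

rng = np.random.default_rng(42)


def _random_rotation():
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(
        int(rng.integers(2**31)))).as_matrix()


def _toy_structure(n=8, seed=0):
    r = np.random.default_rng(seed)
    coords = r.normal(size=(n, 3)) * 3.0
    return Structure(["CA"] * n, ["C"] * n, np.arange(1, n + 1),
                     ["ALA"] * n, ["A"] * n, coords)


class TestKabsch:
    def test_identity(self):
        x = rng.normal(size=(6, 3))
        _, _, r = kabsch_superpose(x, x)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        x = rng.normal(size=(10, 3))
        rot = _random_rotation()
        moved = x @ rot.T + np.array([3.0, -2.0, 7.0])
        _, _, r = kabsch_superpose(moved, x)
        assert r == pytest.approx(0.0, abs=1e-9)

    def test_matches_scipy_oracle(self):
        """Optimal 4-point alignment equals scipy's independent solver."""
        from scipy.spatial.transform import Rotation

        a = np.array([[0, 0, 0], [1.5, 0, 0], [0, 2.0, 0], [0.3, 0.4, 1.7]])
        b = a @ _random_rotation().T + 5.0 + rng.normal(size=(4, 3)) * 0.3
        _, _, r = kabsch_superpose(a, b)
        est, rssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
        assert r == pytest.approx(rssd / math.sqrt(len(a)), abs=1e-9)

    def test_symmetry(self):
        a = rng.normal(size=(7, 3))
        b = rng.normal(size=(7, 3))
        _, _, r1 = kabsch_superpose(a, b)
        _, _, r2 = kabsch_superpose(b, a)
        assert r1 == pytest.approx(r2, abs=1e-9)

    @pytest.mark.parametrize("bad", [
        np.zeros((2, 3)),
        np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]),  # collinear
    ])
    def test_degenerate_selections_raise(self, bad):
        ref = rng.normal(size=bad.shape)
        with pytest.raises(SelectionError):
            kabsch_superpose(bad, ref)


class TestRmsdSeries:
    def test_identical_and_rigidly_moved_frames_are_zero(self):
        s = _toy_structure()
        frames = np.stack([s.coords,
                           s.coords @ _random_rotation().T + [1.0, 2.0, 3.0]])
        traj = TrajectorySeries(s, frames, np.array([0.0, 1.0]))
        vals = rmsd_series(traj, s).values
        assert np.allclose(vals, 0.0, atol=1e-9)

    def test_matches_per_frame_superposition(self):
        """Two-frame toy trajectory equals frame-by-frame Kabsch calls."""
        s = _toy_structure()
        frames = s.coords[None] + rng.normal(size=(2, s.n_atoms, 3))
        traj = TrajectorySeries(s, frames, np.array([0.0, 1.0]))
        vals = rmsd_series(traj, s).values
        expected = [kabsch_superpose(f, s.coords)[2] for f in frames]
        assert vals == pytest.approx(expected, abs=1e-12)

    def test_selection_mismatch_raises(self):
        s = _toy_structure()
        traj = TrajectorySeries(s, s.coords[None], np.array([0.0]))
        with pytest.raises(SelectionError):
            rmsd_series(traj, s, fit_selection=np.array([99]))


class TestShrakeRupley:
    def test_isolated_atom_is_analytic_sphere(self):
        s = Structure(["O"], ["O"], [1], ["HOH"], ["A"], [[0.0, 0.0, 0.0]])
        per_atom, _, _ = shrake_rupley_asa(s, probe_radius=1.4, n_sphere_points=960)
        assert per_atom[0] == pytest.approx(4 * math.pi * (1.52 + 1.4) ** 2, rel=1e-12)

    def test_buried_atom_is_zero(self):
        # central atom inside a tight shell of 26 neighbours
        shell = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if (dx, dy, dz) != (0, 0, 0):
                        shell.append(np.array([dx, dy, dz], dtype=float) * 2.0)
        coords = [np.zeros(3)] + shell
        n = len(coords)
        s = Structure(["C"] * n, ["C"] * n, np.arange(1, n + 1), ["ALA"] * n,
                      ["A"] * n, np.array(coords))
        per_atom, _, _ = shrake_rupley_asa(s, n_sphere_points=960)
        assert per_atom[0] == pytest.approx(0.0, abs=1e-9)

    def test_two_spheres_match_cap_formula(self):
        """Partially overlapping equal spheres: accessible area equals the
        closed-form spherical-cap result within discretization error."""
        d = 2.0
        s = Structure(["C", "C"], ["C", "C"], [1, 2], ["ALA", "ALA"],
                      ["A", "A"], [[0.0, 0, 0], [d, 0, 0]])
        per_atom, _, _ = shrake_rupley_asa(s, n_sphere_points=8000)
        r = 1.7 + 1.4
        cap_h = r - d / 2.0
        analytic = 4 * math.pi * r**2 - 2 * math.pi * r * cap_h
        assert per_atom[0] == pytest.approx(analytic, rel=2e-3)

    def test_discretization_error_shrinks(self):
        d = 2.5
        s = Structure(["N", "O"], ["N", "O"], [1, 2], ["ALA", "ALA"],
                      ["A", "A"], [[0.0, 0, 0], [d, 0, 0]])
        r1, r2 = 1.55 + 1.4, 1.52 + 1.4
        cap_h = r1 - (d**2 + r1**2 - r2**2) / (2 * d)
        analytic = 4 * math.pi * r1**2 - 2 * math.pi * r1 * cap_h
        errs = []
        for n in (240, 960, 3840):
            per_atom, _, _ = shrake_rupley_asa(s, n_sphere_points=n)
            errs.append(abs(per_atom[0] - analytic))
        assert errs[2] < errs[0]

    def test_unknown_element_raises(self):
        s = Structure(["X1"], ["Xx"], [1], ["UNK"], ["A"], [[0.0, 0, 0]])
        with pytest.raises(ValueError, match="van der Waals"):
            shrake_rupley_asa(s)


class TestSequenceMass:
    def test_glycine(self):
        """Free glycine: C2H5NO2 average mass 75.07 Da."""
        assert sequence_mass("G") == pytest.approx(0.07507, abs=2e-5)

    def test_permutation_invariance(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        assert sequence_mass(seq) == pytest.approx(sequence_mass(seq[::-1]), abs=1e-12)

    def test_additivity(self):
        water = 0.01801528
        a, b = "MGSSHH", "KLVPRG"
        assert sequence_mass(a + b) == pytest.approx(
            sequence_mass(a) + sequence_mass(b) - water, abs=1e-6)

    @pytest.mark.parametrize("bad", ["", "AXZ1", "B"])
    def test_invalid_input_raises(self, bad):
        with pytest.raises(ValueError):
            sequence_mass(bad)

    def test_construct_editing_machinery(self):
        """Slice + point substitutions in author numbering on the synthetic
        stand-in sequence (the natural construct is user-supplied)."""
        full = "X" * (SYNTHETIC_FIRST_RES_ID - 1) + SYNTHETIC_VPS9_LIKE_SEQUENCE
        core = extract_construct(full, SYNTHETIC_FIRST_RES_ID, 1657,
                                 substitutions=("C1551S", "C1558S", "C1647S"))
        assert len(core) == 145
        assert core[1551 - 1513] == "S" and core[1647 - 1513] == "S"
        assert "C" not in (core[1551 - 1513], core[1558 - 1513])
        # wrong original residue is rejected
        with pytest.raises(ValueError, match="found"):
            apply_substitutions(SYNTHETIC_VPS9_LIKE_SEQUENCE, ("A1551S",),
                                first_res_id=SYNTHETIC_FIRST_RES_ID)
        tagged = extract_construct(full, SYNTHETIC_FIRST_RES_ID, 1657,
                                   tag="MGSSHHHHHHSSGLVPRGSHM")
        assert tagged.startswith("MGSSHH") and tagged.endswith(core[-10:])


class TestPdbIO:
    def test_trajectory_round_trip(self, tmp_path, small_two_state):
        _, traj, _ = small_two_state
        sub = TrajectorySeries(traj.topology, traj.coords[:3], traj.times[:3])
        path = tmp_path / "t.pdb"
        write_pdb(path, sub)
        back = read_pdb(path)
        assert isinstance(back, TrajectorySeries)
        assert back.n_frames == 3
        assert np.array_equal(back.topology.res_ids, traj.topology.res_ids)
        assert np.array_equal(back.topology.atom_names, traj.topology.atom_names)
        assert np.allclose(back.coords, sub.coords, atol=5e-3)

    def test_element_inference_from_names(self, tmp_path):
        """Readers tolerate missing element columns (inferred from names)."""
        path = tmp_path / "noelem.pdb"
        path.write_text(
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00\n"
            "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00\n"
            "END\n")
        s = read_pdb(path)
        assert list(s.elements) == ["N", "C"]


class TestSelection:
    def test_parse_selection(self, small_two_state):
        _, traj, _ = small_two_state
        top = traj.topology
        idx = parse_selection(top, "name CA and resid 1532-1542")
        assert len(idx) == 11
        assert set(top.atom_names[idx]) == {"CA"}
        with pytest.raises(SelectionError):
            parse_selection(top, "name ZZ")
        with pytest.raises(SelectionError):
            parse_selection(top, "chain A")
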