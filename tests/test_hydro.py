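"""Structure model parsing and the convex-hull hydrodynamic panel."""

import math

import numpy as np
import pytest
from scipy.spatial import Delaunay

import polyscfv as p
from polyscfv.hydro import HydroConstants, write_pdb


def cloud(coords, masses=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    masses = np.ones(n) if masses is None else np.asarray(masses, float)
    return p.StructureModel(
        coords=coords,
        masses=masses,
        elements=["C"] * n,
        residues=["G"] * n,
        chains=["A"] * n,
    )


def random_cloud(rng, n=100):
    return cloud(rng.normal(scale=10.0, size=(n, 3)), rng.uniform(1, 20, n))


class TestRadiusOfGyration:
    def test_point_and_dumbbell(self):
        assert p.radius_of_gyration(cloud([[1.0, 2.0, 3.0]])) == 0.0
        two = cloud([[0, 0, 0], [4, 0, 0]])
        assert p.radius_of_gyration(two) == pytest.approx(2.0)

    def test_matches_direct_summation(self, rng):
        for _ in range(20):
            model = random_cloud(rng)
            w = model.masses / model.masses.sum()
            com = (model.coords * w[:, None]).sum(axis=0)
            expected = math.sqrt(
                (w * ((model.coords - com) ** 2).sum(axis=1)).sum()
            )
            assert p.radius_of_gyration(model) == pytest.approx(
                expected, abs=1e-9
            )


class TestConvexHull:
    def test_unit_cube(self):
        pts = [
            [x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)
        ]
        volume, dmax, _, degenerate = p.convex_hull_metrics(cloud(pts))
        assert volume == pytest.approx(1.0)
        assert dmax == pytest.approx(math.sqrt(3))
        assert not degenerate

    def test_collinear_degenerate(self):
        pts = [[i, 0, 0] for i in range(5)]
        volume, dmax, _, degenerate = p.convex_hull_metrics(cloud(pts))
        assert volume == 0.0
        assert degenerate
        assert dmax == pytest.approx(4.0)

    def test_volume_matches_delaunay_decomposition(self, rng):
        """Independent oracle: sum of Delaunay simplex volumes equals the
        hull volume for a point cloud."""
        for _ in range(10):
            model = random_cloud(rng, n=40)
            volume, dmax, _, _ = p.convex_hull_metrics(model)
            tri = Delaunay(model.coords)
            total = 0.0
            for simplex in tri.simplices:
                a, b, c, d = model.coords[simplex]
                total += abs(np.linalg.det(np.array([b - a, c - a, d - a]))) / 6
            assert volume == pytest.approx(total, rel=1e-6)
            # Dmax against brute-force all-pairs
            diffs = model.coords[:, None, :] - model.coords[None, :, :]
            assert dmax == pytest.approx(
                np.sqrt((diffs**2).sum(-1)).max(), abs=1e-9
            )

    def test_adding_a_point_is_monotone(self, rng):
        model = random_cloud(rng, n=30)
        v0, d0, _, _ = p.convex_hull_metrics(model)
        extra = np.vstack([model.coords, [[30.0, 0.0, 0.0]]])
        bigger = cloud(extra)
        v1, d1, _, _ = p.convex_hull_metrics(bigger)
        assert v1 >= v0 and d1 >= d0


class TestAsphericity:
    def test_isotropic_cube_is_zero(self):
        pts = [[x, y, z] for x in (-1, 1) for y in (-1, 1) for z in (-1, 1)]
        assert p.asphericity(cloud(pts)) == pytest.approx(0.0, abs=1e-12)

    def test_collinear_is_one(self):
        pts = [[i, 0, 0] for i in range(6)]
        assert p.asphericity(cloud(pts)) == pytest.approx(1.0)

    def test_matches_eigendecomposition(self, rng):
        for _ in range(20):
            model = random_cloud(rng)
            w = model.masses / model.masses.sum()
            com = (model.coords * w[:, None]).sum(axis=0)
            d = model.coords - com
            T = np.einsum("i,ij,ik->jk", w, d, d)
            lam = np.linalg.eigvalsh(T)
            expected = 1 - 3 * (
                lam[0] * lam[1] + lam[1] * lam[2] + lam[2] * lam[0]
            ) / lam.sum() ** 2
            a = p.asphericity(model)
            assert a == pytest.approx(expected, abs=1e-9)
            assert 0.0 <= a <= 1.0


class TestPanel:
    def test_sphere_limit(self, rng):
        # dense uniform ball: axial ratio ~ 1, f/f0 near its floor
        u = rng.normal(size=(4000, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = 20.0 * rng.random(4000) ** (1 / 3)
        model = cloud(u * r[:, None], masses=np.full(4000, 110.0))
        panel = p.hydrodynamic_panel(model)
        assert panel.axial_ratio == pytest.approx(1.0, abs=0.05)
        assert panel.asphericity < 0.01

    def test_scaling_law(self, synthetic_structured):
        records, _ = synthetic_structured
        model = records[0].structure
        doubled = cloud(model.coords * 2.0, model.masses)
        doubled.residues = model.residues
        a = p.hydrodynamic_panel(model)
        b = p.hydrodynamic_panel(doubled)
        assert b.Rg == pytest.approx(2 * a.Rg, rel=1e-9)
        assert b.Dmax == pytest.approx(2 * a.Dmax, rel=1e-9)
        assert b.vbar == pytest.approx(a.vbar, rel=1e-12)

    def test_stokes_einstein_self_consistency(self, rng):
        consts = HydroConstants()
        products = set()
        for _ in range(5):
            panel = p.hydrodynamic_panel(random_cloud(rng), consts)
            products.add(round(panel.Dt * panel.Rtrans, 18))
            assert panel.f_f0 >= 1.0
            # tauC (ns) must invert 6*Dr exactly
            assert panel.tauC == pytest.approx(
                1e9 / (6 * panel.Dr), rel=1e-9
            )
        assert len(products) == 1  # Dt * Rtrans == kT / (6 pi eta), fixed

    def test_rigid_motion_invariance(self, rng):
        model = random_cloud(rng, n=60)
        theta = 0.7
        R = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0],
                [math.sin(theta), math.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = cloud(model.coords @ R.T + np.array([5.0, -3.0, 8.0]),
                      model.masses)
        a = p.hydrodynamic_panel(model)
        b = p.hydrodynamic_panel(moved)
        for attr in ("Rg", "Dmax", "asphericity", "axial_ratio"):
            assert getattr(b, attr) == pytest.approx(
                getattr(a, attr), rel=1e-9
            )

    def test_panel_deterministic(self, synthetic_structured):
        records, _ = synthetic_structured
        model = records[0].structure
        a = p.hydrodynamic_panel(model).to_dict()
        b = p.hydrodynamic_panel(model).to_dict()
        assert a == b


class TestPdbIO:
    def test_three_atom_fixture(self, tmp_path):
        pdb = tmp_path / "toy.pdb"
        pdb.write_text(
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000"
            "  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1       1.500   0.000   0.000"
            "  1.00  0.00           C\n"
            "ATOM      3  C   ALA A   1       2.000   1.000   0.000"
            "  1.00  0.00           C\n"
            "END\n"
        )
        model = p.read_pdb(pdb)
        assert model.n_atoms == 3
        assert model.coords[1] == pytest.approx([1.5, 0.0, 0.0])
        assert model.elements == ["N", "C", "C"]

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        pdb = tmp_path / "alt.pdb"
        pdb.write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000"
            "  0.40  0.00           C\n"
            "ATOM      2  CA BALA A   1       9.000   0.000   0.000"
            "  0.60  0.00           C\n"
            "END\n"
        )
        model = p.read_pdb(pdb)
        assert model.n_atoms == 1
        assert model.coords[0][0] == pytest.approx(9.0)

    def test_hydrogens_dropped_by_default(self, tmp_path):
        pdb = tmp_path / "h.pdb"
        pdb.write_text(
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000"
            "  1.00  0.00           C\n"
            "ATOM      2  H   GLY A   1       1.000   0.000   0.000"
            "  1.00  0.00           H\n"
            "END\n"
        )
        assert p.read_pdb(pdb).n_atoms == 1
        assert p.read_pdb(pdb, drop_hydrogens=False).n_atoms == 2

    def test_round_trip_preserves_coordinates(
        self, tmp_path, synthetic_structured
    ):
        records, _ = synthetic_structured
        model = records[0].structure
        path = tmp_path / "out.pdb"
        write_pdb(model, path)
        back = p.read_pdb(path)
        assert back.n_atoms == model.n_atoms
        assert np.abs(back.coords - model.coords).max() < 1e-3

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(IOError):
            p.read_pdb(path)
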