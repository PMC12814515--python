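"""RDF normalization, Shrake-Rupley SASA, and observable time series."""

import numpy as np
import pytest

from cgnano import (
    Box,
    Frame,
    MoleculeMap,
    Trajectory,
    generate_ideal_gas,
    metric_timeseries,
    rdf,
    sasa,
)
from cgnano.structure import fibonacci_sphere


class TestRDF:
    def test_ideal_gas_is_unity(self, box10):
        frame = generate_ideal_gas(5000, box10, seed=3)
        prof = rdf(frame, np.arange(5000), np.arange(5000),
                   bin_width=0.1, box=box10)
        sel = prof.bin_centers > 0.5
        assert np.abs(prof.g[sel] - 1).mean() < 0.05
        assert np.abs(prof.g[sel] - 1).max() < 0.1

    def test_ideal_gas_within_3_se_per_bin(self, box10):
        """Counting statistics: every bin within 3 standard errors of 1."""
        frame = generate_ideal_gas(5000, box10, seed=3)
        bw, rmax = 0.1, 4.9
        prof = rdf(frame, np.arange(5000), np.arange(5000),
                   bin_width=bw, r_max=rmax, box=box10)
        n = 5000
        rho = (n - 1) / box10.volume_nm3  # ordered-pair partner density
        shell = 4 * np.pi * prof.bin_centers**2 * bw
        expected_counts = n * rho * shell
        se = np.sqrt(2 * expected_counts) / expected_counts  # pairs counted twice
        sel = prof.bin_centers > 0.5
        assert np.all(np.abs(prof.g[sel] - 1) < 3.5 * se[sel])
        assert np.abs(prof.g[sel] - 1).mean() < 3 * se[sel].mean()

    def test_two_bead_analytic_normalization(self, box10):
        """All mass in the bin holding the separation; hand-computed value."""
        d = 1.23
        frame = Frame(coords=[[2, 2, 2], [2 + d, 2, 2]],
                      masses=[1, 1], radii=[0.1, 0.1])
        bw, rmax = 0.05, 3.0
        prof = rdf(frame, np.array([0]), np.array([1]),
                   bin_width=bw, r_max=rmax, box=box10)
        k = int(d / bw)
        # one ordered pair; rho_local = 1 / (4/3 pi rmax^3); N_A = 1
        shell = 4 * np.pi * prof.bin_centers[k] ** 2 * bw
        rho_local = 1.0 / (4 / 3 * np.pi * rmax**3)
        assert prof.g[k] == pytest.approx(1.0 / (shell * rho_local))
        assert prof.g.sum() == pytest.approx(prof.g[k])  # single occupied bin

    def test_symmetry_between_selections(self, box10):
        rng = np.random.default_rng(8)
        frame = Frame(coords=rng.uniform(0, 10, (60, 3)),
                      masses=np.ones(60), radii=np.full(60, 0.1))
        a, b = np.arange(30), np.arange(30, 60)
        ga = rdf(frame, a, b, bin_width=0.25, box=box10)
        gb = rdf(frame, b, a, bin_width=0.25, box=box10)
        assert np.allclose(ga.g, gb.g)

    def test_single_shared_bead_yields_empty_profile(self, box10):
        frame = Frame(coords=[[5, 5, 5]], masses=[1], radii=[0.1])
        prof = rdf(frame, np.array([0]), np.array([0]), bin_width=0.1, box=box10)
        assert np.all(prof.g == 0)

    def test_rmax_beyond_half_box_errors(self, box10):
        frame = generate_ideal_gas(10, box10, seed=0)
        with pytest.raises(ValueError):
            rdf(frame, np.arange(10), np.arange(10), bin_width=0.1,
                r_max=6.0, box=box10)

    def test_empty_selection_errors(self, box10):
        frame = generate_ideal_gas(10, box10, seed=0)
        with pytest.raises(ValueError):
            rdf(frame, np.array([], dtype=int), np.arange(10),
                bin_width=0.1, box=box10)


class TestSASA:
    def test_lone_sphere_closed_form_any_n_points(self, box10):
        frame = Frame(coords=[[5, 5, 5]], masses=[1], radii=[0.23])
        for n_points in (32, 960):
            res = sasa(frame, [0], probe_radius=0.14, n_points=n_points, box=box10)
            assert res.total == pytest.approx(4 * np.pi * 0.37**2, rel=1e-12)

    def test_non_overlapping_additivity(self, box10):
        frame = Frame(coords=[[2, 2, 2], [2, 2, 4]], masses=[1, 1],
                      radii=[0.23, 0.23])
        res = sasa(frame, None, 0.14, 960, box=box10)
        assert res.total == pytest.approx(2 * 4 * np.pi * 0.37**2, rel=1e-12)

    def test_buried_bead_has_zero_area(self, box10):
        frame = Frame(coords=[[5, 5, 5], [5, 5, 5.01]], masses=[1, 1],
                      radii=[0.1, 1.0])
        res = sasa(frame, None, 0.14, 960, box=box10)
        assert res.per_bead_area[0] == 0.0
        assert res.per_bead_area[1] > 0

    def test_two_overlapping_spheres_match_refinement_oracle(self, box10):
        frame = Frame(coords=[[5, 5, 5], [5, 5, 5.3]], masses=[1, 1],
                      radii=[0.23, 0.23])
        coarse = sasa(frame, None, 0.14, 960, box=box10).total
        fine = sasa(frame, None, 0.14, 1_000_000, box=box10).total
        assert coarse == pytest.approx(fine, rel=0.005)

    def test_upper_bound_and_convergence(self, box10):
        rng = np.random.default_rng(12)
        n = 100
        frame = Frame(coords=5 + rng.normal(scale=0.5, size=(n, 3)),
                      masses=np.ones(n), radii=np.full(n, 0.23))
        res1 = sasa(frame, None, 0.14, 960, box=box10)
        bound = (4 * np.pi * (frame.radii + 0.14) ** 2).sum()
        assert res1.total <= bound
        res2 = sasa(frame, None, 0.14, 1920, box=box10)
        assert abs(res2.total - res1.total) / res2.total < 0.005

    def test_matches_mdtraj_on_nonperiodic_cluster(self):
        """Independent oracle: mdtraj's Shrake-Rupley on the same blob."""
        md = pytest.importorskip("mdtraj")
        rng = np.random.default_rng(4)
        n = 20
        coords = 10 + rng.normal(scale=0.3, size=(n, 3))
        radius = 0.2
        box = Box([40] * 3)  # huge box: periodicity irrelevant
        frame = Frame(coords=coords, masses=np.ones(n), radii=np.full(n, radius))
        ours = sasa(frame, None, 0.14, 5000, box=box).total
        top = md.Topology()
        chain = top.add_chain()
        res = top.add_residue("X", chain)
        for _ in range(n):
            top.add_atom("C", md.element.carbon, res)
        traj = md.Trajectory(coords[None], top)
        theirs = md.shrake_rupley(
            traj, probe_radius=0.14, n_sphere_points=5000,
            change_radii={"C": radius},
        ).sum()
        assert ours == pytest.approx(float(theirs), rel=0.01)

    def test_fibonacci_points_lie_on_unit_sphere(self):
        pts = fibonacci_sphere(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        assert np.linalg.norm(pts.mean(axis=0)) < 1e-2  # nearly centroid-free

    def test_too_few_points_error(self, box10):
        frame = Frame(coords=[[5, 5, 5]], masses=[1], radii=[0.2])
        with pytest.raises(ValueError):
            sasa(frame, [0], 0.14, 16, box=box10)


class TestTimeseries:
    def make_traj(self, coords_list, box, mol_types=("PEG",), bead_mol=None):
        frames = []
        n = len(coords_list[0])
        for t, c in enumerate(coords_list):
            frames.append(Frame(coords=c, masses=np.full(n, 2.0),
                                radii=np.full(n, 0.2), time=float(t)))
        mmap = MoleculeMap(
            bead_mol if bead_mol is not None else np.zeros(n, dtype=int),
            np.array(mol_types, dtype=object),
        )
        return Trajectory(frames=frames, boxes=[box] * len(frames), mmap=mmap)

    def test_constant_trajectory_constant_series(self, box10):
        rng = np.random.default_rng(0)
        c = rng.uniform(2, 4, (8, 3))
        traj = self.make_traj([c, c.copy(), c.copy()], box10)
        for metric in ("rg", "density", "sasa"):
            ts = metric_timeseries(traj, metric)
            assert np.allclose(ts.values, ts.values[0])

    def test_rg_doubles_with_coordinates_and_box(self):
        rng = np.random.default_rng(1)
        c = rng.uniform(2, 4, (8, 3))
        f1 = Frame(coords=c, masses=np.ones(8), radii=np.full(8, 0.2), time=0.0)
        f2 = Frame(coords=2 * c, masses=np.ones(8), radii=np.full(8, 0.2), time=1.0)
        mmap = MoleculeMap(np.zeros(8, dtype=int), np.array(["PEG"], dtype=object))
        traj = Trajectory(frames=[f1, f2], boxes=[Box([10] * 3), Box([20] * 3)],
                          mmap=mmap)
        ts = metric_timeseries(traj, "rg")
        assert ts.values[1] == pytest.approx(2 * ts.values[0])

    def test_scripted_burial_makes_drug_sasa_non_increasing(self, box10):
        """Drugs sinking into a polymer blob lose solvent exposure."""
        rng = np.random.default_rng(6)
        blob = 5 + rng.normal(scale=0.4, size=(40, 3))
        frames = []
        for t, r in enumerate([3.0, 1.5, 0.5, 0.0]):
            drug = np.array([[5 + r, 5, 5], [5, 5 + r, 5]])
            frames.append(np.vstack([blob, drug]))
        bead_mol = np.array([0] * 40 + [1, 2])
        traj = self.make_traj(frames, box10, ("PEG", "HINA", "HINA"), bead_mol)
        ts = metric_timeseries(traj, "sasa", selection="HINA")
        assert np.all(np.diff(ts.values) <= 1e-9)
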