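import numpy as np
import pytest

from ionscape.core import Atom, Topology, Trajectory
from ionscape.distributions import (
    DistributionResult,
    charge_accumulation,
    compute_cdf,
    compute_rdf,
    convergence_series,
    coordination_number,
    first_minimum_after_peak,
    first_peak,
)
from ionscape.helix import HelixFrame
from ionscape.synthetic import build_duplex, hydration_shell_trajectory

from conftest import make_ion_gas

_M_PER_INV_A3 = 1e27 / 6.02214076e23


def _axis_through(box, half_height=15.0):
    o = np.full(3, box / 2.0)
    return HelixFrame(
        origin=o,
        direction=np.array([0.0, 0, 1]),
        pair_centers=np.array([o - [0, 0, half_height], o + [0, 0, half_height]]),
        axial_extent=(-half_height, half_height),
    )


class TestCDF:
    def test_uniform_gas_is_flat(self):
        traj = make_ion_gas(300, 60.0, 300, seed=1, site_atom=False)
        hf = _axis_through(60.0)
        dist = compute_cdf(traj, "Na+", [hf] * traj.n_frames, r_max=20, dr=2.0, block_ps=100.0)
        rho_M = 300 / 60.0**3 * _M_PER_INV_A3
        dev = np.abs(dist.values - rho_M)
        assert np.all(dev <= 3.0 * dist.stderr + 1e-12)

    def test_zero_ions(self):
        traj = make_ion_gas(5, 40.0, 10, seed=2, site_atom=False)
        traj.species["K+"] = np.array([], dtype=int)
        hf = _axis_through(40.0)
        dist = compute_cdf(traj, "K+", [hf] * 10, r_max=15, dr=1.0)
        assert np.all(dist.values == 0.0)

    def test_mass_conservation_oracle(self):
        traj = make_ion_gas(100, 50.0, 50, seed=3, site_atom=False)
        hf = _axis_through(50.0, half_height=12.0)
        dist = compute_cdf(traj, "Na+", [hf] * 50, r_max=18, dr=0.5)
        # independent oracle: direct min-image counting inside the cylinder
        box = np.array([50.0] * 3)
        counts = []
        for f in range(50):
            d = traj.coordinates[f][traj.species["Na+"]] - hf.origin
            d -= box * np.round(d / box)
            r = np.hypot(d[:, 0], d[:, 1])
            counts.append(np.sum((r < 18) & (np.abs(d[:, 2]) <= 12.0)))
        oracle = np.mean(counts)
        integrated = np.sum(dist.values * dist.meta["shell_volumes"]) / _M_PER_INV_A3
        assert integrated == pytest.approx(oracle, rel=1e-9)
        assert dist.meta["mean_in_cylinder_count"] == pytest.approx(oracle, rel=1e-9)

    def test_translation_invariance(self):
        traj = make_ion_gas(50, 40.0, 20, seed=4, site_atom=False)
        hf = _axis_through(40.0)
        d1 = compute_cdf(traj, "Na+", [hf] * 20, r_max=15, dr=1.0)
        shift = np.array([7.0, -3.0, 11.0])
        traj2 = Trajectory(
            traj.topology,
            np.mod(traj.coordinates + shift, 40.0),
            traj.box,
            times=traj.times,
            species=traj.species,
        )
        hf2 = HelixFrame(
            origin=hf.origin + shift,
            direction=hf.direction,
            pair_centers=hf.pair_centers + shift,
            axial_extent=hf.axial_extent,
        )
        d2 = compute_cdf(traj2, "Na+", [hf2] * 20, r_max=15, dr=1.0)
        assert np.allclose(d1.values, d2.values, rtol=1e-9)

    def test_oversized_r_max_warns(self):
        traj = make_ion_gas(10, 30.0, 5, seed=5, site_atom=False)
        hf = _axis_through(30.0)
        dist = compute_cdf(traj, "Na+", [hf] * 5, r_max=25, dr=1.0)
        assert "warning" in dist.meta

    def test_empty_window_errors(self):
        traj = make_ion_gas(10, 30.0, 5, seed=6, site_atom=False)
        hf = _axis_through(30.0)
        with pytest.raises(ValueError):
            compute_cdf(traj, "Na+", [hf] * 5, r_max=10, dr=1.0, window=(1e6, 2e6))


class TestRDF:
    def test_ideal_gas_is_unity(self):
        traj = make_ion_gas(150, 40.0, 150, seed=7)
        dist = compute_rdf(traj, "Na+", np.array([0]), r_max=12, dr=0.25, block_ps=100.0)
        sel = dist.bin_centers > 2.0
        dev = np.abs(dist.values[sel] - 1.0)
        pooled_se = np.sqrt(np.mean(dist.stderr[sel] ** 2))
        assert dev.mean() < 3.0 * pooled_se

    def test_hydration_shell_peak_location(self):
        traj = hydration_shell_trajectory(
            600, n_shell=6, d0=2.43, sigma=0.05, rho_bulk=0.001, box=20.0, seed=8
        )
        dist = compute_rdf(traj, "WAT-O", np.array([0]), r_max=6.0, dr=0.02)
        peak = first_peak(dist)
        assert peak is not None
        assert abs(peak[0] - 2.43) <= 0.02

    def test_hand_enumerated_fixture(self):
        # 2 frames, 1 site, 3 ions: per-bin counts equal hand-computed distances
        box = 10.0
        site = np.array([5.0, 5.0, 5.0])
        ions_f0 = np.array([[6.0, 5.0, 5.0], [5.0, 8.0, 5.0], [9.5, 5.0, 5.0]])
        ions_f1 = np.array([[5.0, 5.0, 6.5], [0.5, 5.0, 5.0], [5.0, 5.0, 5.2]])
        atoms = [Atom("O6", "O", 1, "G", "A")] + [
            Atom("Na", "Na", i + 2, "", "X", 1.0) for i in range(3)
        ]
        coords = np.stack([np.vstack([site, ions_f0]), np.vstack([site, ions_f1])])
        traj = Trajectory(
            Topology(atoms), coords, np.array([box] * 3), dt=1.0,
            species={"Na+": np.array([1, 2, 3])},
        )
        dist = compute_rdf(traj, "Na+", np.array([0]), r_max=5.0, dr=0.5)
        # min-image distances by hand: f0: 1.0, 3.0, 4.5; f1: 1.5, 4.5, 0.2
        hand = [1.0, 3.0, 4.5, 1.5, 4.5, 0.2]
        expected_counts, _ = np.histogram(hand, bins=dist.bin_edges)
        assert np.array_equal(dist.raw_counts, expected_counts)

    def test_empty_site_errors(self):
        traj = make_ion_gas(5, 20.0, 3, seed=9)
        with pytest.raises(ValueError, match="empty"):
            compute_rdf(traj, "Na+", np.array([], dtype=int))

    def test_zero_density_errors(self):
        traj = make_ion_gas(5, 20.0, 3, seed=10)
        traj.species["K+"] = np.array([], dtype=int)
        with pytest.raises(ValueError, match="zero"):
            compute_rdf(traj, "K+", np.array([0]))


class TestFirstPeak:
    def _dist(self, values, dr=0.1):
        n = len(values)
        edges = np.arange(n + 1) * dr
        return DistributionResult(
            bin_edges=edges, values=np.asarray(values, float),
            raw_counts=np.zeros(n, int), n_frames=1, species="Na+", kind="rdf",
        )

    def test_gaussian_profile_at_2p4(self):
        r = np.arange(0, 6, 0.1) + 0.05
        values = 5.0 * np.exp(-((r - 2.4) ** 2) / (2 * 0.3**2)) + 1.0
        peak = first_peak(self._dist(values))
        assert peak[0] == pytest.approx(2.45, abs=0.1)

    def test_monotone_decreasing_is_none(self):
        assert first_peak(self._dist(np.linspace(10, 0, 50))) is None

    def test_first_of_two_peaks(self):
        r = np.arange(0, 8, 0.1) + 0.05
        values = (
            4.0 * np.exp(-((r - 4.1) ** 2) / 0.1)
            + 8.0 * np.exp(-((r - 6.5) ** 2) / 0.1)
            + 0.5
        )
        peak = first_peak(self._dist(values))
        assert peak[0] == pytest.approx(4.15, abs=0.1)

    def test_wrong_kind_errors(self):
        dist = self._dist(np.ones(5))
        dist.kind = "charge"
        with pytest.raises(ValueError):
            first_peak(dist)


class TestCoordinationNumber:
    def test_six_point_shell(self):
        traj = hydration_shell_trajectory(
            400, n_shell=6, d0=2.43, sigma=0.05, rho_bulk=0.001, box=20.0, seed=11
        )
        dist = compute_rdf(traj, "WAT-O", np.array([0]), r_max=6.0, dr=0.02)
        r_min = first_minimum_after_peak(dist)
        assert r_min is not None
        assert coordination_number(dist, r_min) == pytest.approx(6.0, abs=0.1)

    def test_ideal_gas_analytic(self):
        traj = make_ion_gas(200, 40.0, 100, seed=12)
        dist = compute_rdf(traj, "Na+", np.array([0]), r_max=10, dr=0.1)
        r_cut = 8.0
        expected = 200 / 40.0**3 * 4.0 / 3.0 * np.pi * r_cut**3
        assert coordination_number(dist, r_cut) == pytest.approx(expected, rel=0.1)

    def test_counting_oracle(self):
        traj = make_ion_gas(50, 30.0, 40, seed=13)
        dist = compute_rdf(traj, "Na+", np.array([0]), r_max=10, dr=0.25)
        r_cut = 6.0
        box = np.array([30.0] * 3)
        counts = []
        for f in range(traj.n_frames):
            d = traj.coordinates[f][traj.species["Na+"]] - traj.coordinates[f][0]
            d -= box * np.round(d / box)
            counts.append(np.sum(np.linalg.norm(d, axis=1) < r_cut))
        assert coordination_number(dist, r_cut) == pytest.approx(np.mean(counts), rel=1e-9)

    def test_out_of_range_errors(self):
        traj = make_ion_gas(10, 20.0, 5, seed=14)
        dist = compute_rdf(traj, "Na+", np.array([0]), r_max=5)
        with pytest.raises(ValueError):
            coordination_number(dist, 50.0)


class TestChargeAccumulation:
    def _neutral_system(self, n_frames=20, seed=0, box=40.0):
        duplex = build_duplex(form="B-DNA", box=box)
        topo = duplex.topology
        rng = np.random.default_rng(seed)
        cat = rng.uniform(0, box, (n_frames, 22, 3))
        dup = np.broadcast_to(duplex.coordinates[0], (n_frames, topo.n_atoms, 3))
        coords = np.concatenate([dup, cat], axis=1)
        atoms = list(topo.atoms) + [
            Atom("Na", "Na", i + 1, "", "X", 1.0) for i in range(22)
        ]
        return Trajectory(
            Topology(atoms), coords, np.array([box] * 3), dt=1.0,
            species={"Na+": np.arange(topo.n_atoms, topo.n_atoms + 22)},
        )

    def test_neutral_box_asymptote(self):
        from ionscape.helix import helix_frames

        traj = self._neutral_system()
        hf = helix_frames(traj)
        dist = charge_accumulation(
            traj, hf, {"Na+": 1.0}, r_max=40.0, dr=1.0, axial="full_box"
        )
        assert dist.values[-1] == pytest.approx(1.0, abs=1e-12)
        assert "warning" in dist.meta  # r_max beyond half box recorded

    def test_cations_only_monotone(self):
        from ionscape.helix import helix_frames

        traj = self._neutral_system(seed=1)
        hf = helix_frames(traj)
        dist = charge_accumulation(traj, hf, {"Na+": 1.0}, r_max=20.0, dr=0.5)
        assert np.all(np.diff(dist.values) >= -1e-12)
        assert np.all(np.abs(dist.values) <= 1.0 + 1e-12)

    def test_brute_force_cumulative_oracle(self):
        from ionscape.helix import helix_frames

        box = 40.0
        duplex = build_duplex(form="B-DNA", box=box)
        topo = duplex.topology
        rng = np.random.default_rng(2)
        n_cat, n_an, F = 30, 8, 10
        ions = rng.uniform(0, box, (F, n_cat + n_an, 3))
        dup = np.broadcast_to(duplex.coordinates[0], (F, topo.n_atoms, 3))
        atoms = list(topo.atoms)
        atoms += [Atom("Na", "Na", i + 1, "", "X", 1.0) for i in range(n_cat)]
        atoms += [Atom("Cl", "Cl", i + 1, "", "Y", -1.0) for i in range(n_an)]
        traj = Trajectory(
            Topology(atoms), np.concatenate([dup, ions], axis=1),
            np.array([box] * 3), dt=1.0,
            species={
                "Na+": np.arange(topo.n_atoms, topo.n_atoms + n_cat),
                "Cl-": np.arange(topo.n_atoms + n_cat, topo.n_atoms + n_cat + n_an),
            },
        )
        hf = helix_frames(traj)
        dist = charge_accumulation(
            traj, hf, {"Na+": 1.0, "Cl-": -1.0}, r_max=15.0, dr=0.5
        )
        # oracle: direct cumulative counting at every bin edge
        for b, edge in enumerate(dist.bin_edges[1:]):
            totals = []
            for f in range(F):
                h = hf[f]
                q = 0.0
                for label, z in (("Na+", 1.0), ("Cl-", -1.0)):
                    pts = traj.coordinates[f][traj.species[label]]
                    d = pts - h.origin
                    d -= box * np.round(d / box)
                    r = np.hypot(d[:, 0], d[:, 1])
                    zc = d[:, 2]  # axis is z for the ideal build
                    z0, z1 = h.axial_extent
                    inside = (r <= edge) & (zc >= z0) & (zc <= z1)
                    q += z * inside.sum()
                totals.append(q / 22.0)
            assert dist.values[b] == pytest.approx(np.mean(totals), abs=1e-9)

    def test_undefined_species_errors(self):
        from ionscape.helix import helix_frames

        traj = self._neutral_system(seed=3)
        hf = helix_frames(traj)
        with pytest.raises(ValueError, match="species"):
            charge_accumulation(traj, hf, {"K+": 1.0}, r_max=10.0, dr=1.0)


class TestConvergenceSeries:
    def _compute(self, traj, hf):
        def inner(window):
            return compute_cdf(traj, "Na+", hf, r_max=15, dr=1.0, window=window)

        return inner

    def test_stationary_shrinks(self):
        from scipy.stats import spearmanr

        traj = make_ion_gas(100, 40.0, 600, seed=20, site_atom=False)
        hf = [_axis_through(40.0)] * traj.n_frames
        windows = [(0.0, t) for t in (1000.0, 2000.0, 3000.0, 4000.0, 5990.0)]
        series = convergence_series(windows, self._compute(traj, hf))
        rho = spearmanr(np.arange(len(series.sup_diffs)), series.sup_diffs).statistic
        assert rho < 0

    def test_consistency_with_direct_call(self):
        traj = make_ion_gas(50, 40.0, 100, seed=21, site_atom=False)
        hf = [_axis_through(40.0)] * traj.n_frames
        windows = [(0.0, 400.0), (0.0, 990.0)]
        series = convergence_series(windows, self._compute(traj, hf))
        direct = compute_cdf(traj, "Na+", hf, r_max=15, dr=1.0, window=(0.0, 400.0))
        assert np.array_equal(series.profiles[0].values, direct.values)

    def test_drifting_process_flagged(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(22)
        box, F = 40.0, 600
        # density doubles mid-trace inside r<5: non-stationary
        coords = rng.uniform(0, box, (F, 60, 3))
        near = rng.uniform(-4, 4, (F // 2, 20, 3)) + box / 2
        coords[F // 2:, :20, :] = near
        traj = make_ion_gas(60, box, F, seed=23, site_atom=False)
        traj.coordinates[:] = coords
        hf = [_axis_through(box)] * F
        windows = [(0.0, t) for t in (1000.0, 2000.0, 3000.0, 4000.0, 5990.0)]
        series = convergence_series(windows, self._compute(traj, hf))
        rho = spearmanr(np.arange(len(series.sup_diffs)), series.sup_diffs).statistic
        assert rho >= 0

    def test_window_validation(self):
        fn = lambda w: None
        with pytest.raises(ValueError):
            convergence_series([(0.0, 10.0)], fn)
        with pytest.raises(ValueError, match="share a start"):
            convergence_series([(0.0, 10.0), (5.0, 20.0)], fn)
        with pytest.raises(ValueError, match="increasing"):
            convergence_series([(0.0, 10.0), (0.0, 10.0)], fn)
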