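import numpy as np
import pandas as pd
import pytest
from types import SimpleNamespace

from condensago import analysis as ana
from condensago import fixtures as fx


class TestQFraction:
    def test_counting(self):
        # 10 contacts at unit native distance; stretch 7 of them
        n = 20
        pos = np.zeros((n, 3))
        pairs = np.array([[i, i + 10] for i in range(10)])
        r0 = np.full(10, 1.0)
        for i in range(10):
            pos[i + 10, 0] = 1.0 if i < 3 else 5.0
        q = ana.q_fraction(pos, pairs, r0, box_length=100.0)
        assert q == pytest.approx(0.3)

    def test_limits(self):
        pos = np.zeros((4, 3))
        pos[2:] += [1.0, 0, 0]
        pairs = np.array([[0, 2], [1, 3]])
        r0 = np.full(2, 1.0)
        assert ana.q_fraction(pos, pairs, r0, 100.0) == 1.0
        far = pos.copy()
        far[2:] += [10.0, 0, 0]
        assert ana.q_fraction(far, pairs, r0, 100.0) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ana.q_fraction(np.zeros((2, 3)), np.zeros((0, 2)),
                           np.zeros(0), 10.0)

    def test_monotone_under_uniform_expansion(self, tiny_system, big_box):
        system, _ = tiny_system
        pos = system.positions
        center = pos.mean(axis=0)
        qs = []
        for scale in (1.0, 1.3, 1.8, 2.5):
            qs.append(ana.q_monomer(center + scale * (pos - center),
                                    system))
        assert all(a >= b - 1e-12 for a, b in zip(qs, qs[1:]))


class TestClassification:
    @pytest.mark.parametrize("qm,qd,expect", [
        (0.5, 0.6, "dimer_ord"),
        (0.2, 0.1, "mono_dis"),
        (0.36, 0.31, "dimer_ord"),
        (0.2, 0.6, "dimer_dis"),
        (0.9, 0.0, "mono_ord"),
    ])
    def test_default_thresholds(self, qm, qd, expect):
        assert ana.classify_variant(qm, qd) == expect

    def test_stricter_dimer_criterion_reclassifies(self):
        assert ana.classify_variant(0.5, 0.4) == "dimer_ord"
        assert ana.classify_variant(
            0.5, 0.4, q_dimer_threshold=0.5) == "mono_ord"

    def test_invalid_q_rejected(self):
        with pytest.raises(ValueError):
            ana.classify_variant(1.4, 0.2)


@pytest.fixture()
def big_box(tiny_system):
    """Temporarily enlarge the box so hand-placed frames are unwrapped."""
    system, _ = tiny_system
    old = system.config.box_length
    system.config.box_length = 200.0
    yield system
    system.config.box_length = old


class TestOligomerPartners:
    def test_bound_pairs_and_free_chains(self, tiny_system, big_box):
        system, cset = tiny_system
        pos = _dimer_frame(system, [(0, 1), (2, 3)])
        cutoff = ana.default_partner_cutoff(cset)
        mean = ana.oligomer_partners([pos], system, cutoff)
        # 4 of 10 peptides have exactly one partner
        assert mean == pytest.approx(4 / 10)
        assert mean == pytest.approx(
            np.mean(_brute_force_degrees(pos, system, cutoff)))

    def test_dispersed_gas_zero_partners(self, tiny_system, big_box):
        system, cset = tiny_system
        pos = _dimer_frame(system, [])
        cutoff = ana.default_partner_cutoff(cset)
        assert ana.oligomer_partners([pos], system, cutoff) == 0.0

    def test_matches_brute_force_graph_degrees(self, tiny_system, big_box):
        system, cset = tiny_system
        pos = _dimer_frame(system, [(0, 1), (2, 3), (4, 5), (6, 7)])
        cutoff = ana.default_partner_cutoff(cset)
        mean = ana.oligomer_partners([pos], system, cutoff)
        degrees = _brute_force_degrees(pos, system, cutoff)
        assert mean == pytest.approx(np.mean(degrees))

    def test_nonnegative_cutoff_rejected(self, tiny_system):
        system, _ = tiny_system
        with pytest.raises(ValueError):
            ana.oligomer_partners([system.positions], system, 0.5)


def _dimer_frame(system, pairs):
    from condensago.fixtures import make_hhh_dimer_reference

    n_res = len(system.chain_atoms(system.peptide_chains()[0]))
    ref, _ = make_hhh_dimer_reference(n_res)
    pos = system.positions.copy()
    spot = np.array([2.0, 2.0, 2.0])
    used = set()
    for (a, b) in pairs:
        pos[system.chain_atoms(a)] = ref[:n_res] + spot
        pos[system.chain_atoms(b)] = ref[n_res:] + spot
        spot = spot + np.array([0.0, 0.0, 20.0])
        used.update((a, b))
    free = np.array([40.0, 40.0, 5.0])
    for c in system.peptide_chains():
        if c not in used:
            pos[system.chain_atoms(c)] = (
                ref[:n_res] - ref[:n_res].mean(axis=0) + free)
            free = free + np.array([0.0, 0.0, 25.0])
    for c in system.rna_chains():
        idx = system.chain_atoms(c)
        pos[idx] = pos[idx] - pos[idx].mean(axis=0) + [70.0, 70.0, 30.0]
    return pos


def _brute_force_degrees(pos, system, cutoff):
    """Independent O(n^2) partner-graph oracle."""
    from condensago.potentials import lj1210_energy, minimum_image

    pep = system.peptide_chains()
    mask = system.contact_class == 1
    pairs = system.contacts[mask]
    r0 = system.contact_params[mask, 0]
    eps = system.contact_params[mask, 1]
    deg = {c: 0 for c in pep}
    for a in pep:
        for b in pep:
            if b <= a:
                continue
            e = 0.0
            for (i, j), rr, ee in zip(pairs, r0, eps):
                ca, cb = system.chain_id[i], system.chain_id[j]
                if {ca, cb} != {a, b}:
                    continue
                d = minimum_image(pos[j] - pos[i], system.box_length)
                e += float(lj1210_energy(max(np.linalg.norm(d), 1e-6),
                                         ee, rr)[0])
            if e <= cutoff:
                deg[a] += 1
                deg[b] += 1
    return [deg[c] for c in pep]


class TestClusterAnalysis:
    def test_droplet_plus_free_chains(self):
        frame = fx.make_two_phase_frame(400.0, 0.0, box_length=12.0,
                                        seed=1, droplet_radius=3.0)
        # add two isolated far-away single-bead chains
        members = ana.condensate_members(frame.positions, frame)
        assert len(members) == frame.n_chains  # everything is the droplet

    def test_dispersed_gas_single_chain_cluster(self):
        pos = np.array([[1.0, 1, 1], [5, 5, 5], [9, 9, 9.]])
        frame = fx.FrameSystem(pos, [(0, 1), (1, 2), (2, 3)], 30.0,
                               np.full(3, 100.0))
        members = ana.condensate_members(frame.positions, frame,
                                         cluster_cutoff=1.0)
        assert len(members) == 1

    def test_equal_clusters_tie_break_lowest_index(self):
        pos = np.array([[1.0, 1, 1], [1.5, 1, 1],
                        [20, 20, 20], [20.5, 20, 20.]])
        frame = fx.FrameSystem(pos, [(i, i + 1) for i in range(4)], 50.0,
                               np.full(4, 100.0))
        members = ana.condensate_members(frame.positions, frame)
        assert members == [0, 1]


class TestDensity:
    def test_arithmetic(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 5, size=(1000, 3))
        masses = np.full(1000, 100.0)
        from scipy.spatial import ConvexHull
        hull = ConvexHull(pts)
        expect = 1000 * 100.0 / (hull.volume + hull.area * 0.25)
        got = ana.condensate_density(pts, masses, bead_radius=0.25,
                                     units="Da/nm^3")
        assert got == pytest.approx(expect)

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 4, size=(300, 3))
        m = np.full(300, 80.0)
        a = ana.condensate_density(pts, m)
        b = ana.condensate_density(pts + [13.0, -7.0, 2.0], m)
        assert a == pytest.approx(b)

    def test_lattice_closed_form(self):
        # cubic lattice: density -> m / a^3 as the hull boundary error
        # shrinks with size
        a = 0.5
        k = 12
        grid = np.stack(np.meshgrid(*[np.arange(k) * a] * 3),
                        axis=-1).reshape(-1, 3)
        m = np.full(len(grid), 100.0)
        got = ana.condensate_density(grid, m, bead_radius=a / 2,
                                     units="Da/nm^3")
        expect = 100.0 / a ** 3
        assert got == pytest.approx(expect, rel=0.15)

    def test_too_few_beads_rejected(self):
        with pytest.raises(ValueError):
            ana.condensate_density(np.zeros((3, 3)), np.ones(3))


class TestRadiusOfGyration:
    def test_two_beads(self):
        d = 1.4
        coords = np.array([[0, 0, 0], [d, 0, 0.]])
        assert ana.radius_of_gyration(coords) == pytest.approx(d / 2)

    def test_coincident_beads(self):
        assert ana.radius_of_gyration(np.zeros((5, 3))) == 0.0

    def test_unit_square(self):
        sq = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.]])
        assert ana.radius_of_gyration(sq) == pytest.approx(np.sqrt(2) / 2)

    def test_wrapped_chain_rejected(self):
        coords = np.array([[0.1, 0, 0], [5.9, 0, 0.]])
        with pytest.raises(ValueError, match="unwrap"):
            ana.radius_of_gyration(coords, box_length=6.0)

    def test_rigid_motion_invariance(self, rng):
        coords = rng.normal(size=(30, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = coords @ q.T + [4.0, 5.0, 6.0]
        assert ana.radius_of_gyration(moved) == pytest.approx(
            ana.radius_of_gyration(coords))


class TestDiffusion:
    def test_brownian_recovery(self):
        D_true = 1e-3
        times, pos = fx.make_diffusion_trajectory(
            "brownian", 20_000, 1.0, seed=42, D=D_true, n_walkers=10)
        fit = ana.msd_and_fit(times, pos, fit_window=(1.0, 300.0))
        assert fit.D == pytest.approx(D_true, rel=0.10)
        assert abs(fit.alpha - 1.0) < 0.05
        assert fit.normal_diffusion

    def test_immobile_rejected(self):
        times = np.arange(100.0)
        pos = np.zeros((100, 2, 3))
        with pytest.raises(ValueError, match="degenerate"):
            ana.msd_and_fit(times, pos)

    def test_fbm_subdiffusive_exponent(self):
        times, pos = fx.make_diffusion_trajectory(
            "fbm", 8192, 1.0, seed=7, hurst=0.3, n_walkers=6)
        fit = ana.msd_and_fit(times, pos, fit_window=(1.0, 800.0))
        assert abs(fit.alpha - 0.6) < 0.05
        assert not fit.normal_diffusion

    def test_window_outside_lags_rejected(self):
        times, pos = fx.make_diffusion_trajectory(
            "brownian", 100, 1.0, seed=1)
        with pytest.raises(ValueError, match="window"):
            ana.msd_and_fit(times, pos, fit_window=(500.0, 900.0))


class TestNematicOrder:
    def test_aligned_rods(self):
        e = np.tile([0, 0, 1.0], (50, 1))
        assert ana.nematic_order(e) == pytest.approx(1.0)

    def test_three_axis_frame_vanishes(self):
        e = np.array([[1, 0, 0]] * 10 + [[0, 1, 0]] * 10
                     + [[0, 0, 1]] * 10, dtype=float)
        assert ana.nematic_order(e) == pytest.approx(0.0, abs=1e-12)

    def test_antiparallel_headless_symmetry(self):
        e = np.array([[0, 0, 1.0]] * 25 + [[0, 0, -1.0]] * 25)
        assert ana.nematic_order(e) == pytest.approx(1.0)

    def test_isotropic_large_sample(self):
        frame = fx.make_rod_frame(10_000, np.pi, seed=3)
        s = ana.nematic_order_frame(frame.positions, frame)
        assert s < 0.05

    def test_point_chain_skipped_with_warning(self):
        pos = np.vstack([np.zeros((3, 3)),
                         np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2.]])])
        frame = fx.FrameSystem(pos, [(0, 3), (3, 6)], 50.0,
                               np.full(6, 100.0))
        with pytest.warns(UserWarning):
            s = ana.nematic_order_frame(frame.positions, frame)
        assert s == pytest.approx(1.0)


class TestEnergyMeans:
    def _traj(self, rows):
        return SimpleNamespace(energies=pd.DataFrame(rows))

    def test_constant(self):
        t = self._traj([{"V_pep_pep": -5.0, "V_pep_rna": -2.0}] * 4)
        assert ana.energy_means(t) == (-5.0, -2.0)

    def test_two_frames(self):
        t = self._traj([{"V_pep_pep": -10.0, "V_pep_rna": 0.0},
                        {"V_pep_pep": -20.0, "V_pep_rna": -4.0}])
        assert ana.energy_means(t) == (-15.0, -2.0)

    def test_missing_log_rejected(self):
        with pytest.raises(ValueError):
            ana.energy_means(self._traj([{"V_pep_pep": 0.0}]))


class TestHelicityProxy:
    def _setup(self, tiny_system):
        system, cset = tiny_system
        # designate the first-helix intramolecular contacts of chain 0
        mask = system.contact_class == 0
        pairs = system.contacts[mask]
        chain0 = system.chain_id[pairs[:, 0]] == 0
        return system, pairs[chain0], system.contact_params[mask][chain0, 0]

    def test_native_frame_fully_helical(self, tiny_system, big_box):
        system, pairs, r0 = self._setup(tiny_system)
        assert ana.helicity_proxy(system.positions, system, pairs, r0) == 1.0

    def test_extended_chain_no_helix_contacts(self, tiny_system, big_box):
        system, pairs, r0 = self._setup(tiny_system)
        pos = system.positions.copy()
        idx = system.chain_atoms(0)
        pos[idx] = np.column_stack([np.arange(len(idx)) * 0.38,
                                    np.zeros(len(idx)), np.zeros(len(idx))])
        assert ana.helicity_proxy(pos, system, pairs, r0) == 0.0

    def test_half_formed(self, tiny_system, big_box):
        system, _, _ = self._setup(tiny_system)
        pairs = np.array([[0, 1], [2, 3], [4, 5], [6, 7]])
        r0 = np.full(4, 0.5)
        pos = system.positions.copy()
        for k, (i, j) in enumerate(pairs):
            pos[i] = [3.0 * k, 0.0, 0.0]
            pos[j] = pos[i] + [0.5 if k < 2 else 5.0, 0.0, 0.0]
        assert ana.helicity_proxy(pos, system, pairs, r0) == 0.5

    def test_empty_subset_rejected(self, tiny_system):
        system, _ = tiny_system
        with pytest.raises(ValueError):
            ana.helicity_proxy(system.positions, system,
                               np.zeros((0, 2)), np.zeros(0))


class TestCoexistenceAndBinodal:
    def test_planted_two_phase_recovery(self):
        rho_d, rho_l = 800.0, 10.0
        frame = fx.make_two_phase_frame(rho_d, rho_l, box_length=14.0,
                                        seed=5, units="mg/mL")
        traj = fx.single_frame_trajectory(frame.positions, 150.0)
        point = ana.coexistence_densities(traj, frame)
        assert point.coexists
        assert point.rho_dense == pytest.approx(rho_d, rel=0.05)
        assert point.rho_dilute == pytest.approx(rho_l, rel=0.3)

    def test_pure_droplet_no_dilute_phase(self):
        frame = fx.make_two_phase_frame(500.0, 0.0, box_length=12.0, seed=2)
        traj = fx.single_frame_trajectory(frame.positions, 100.0)
        point = ana.coexistence_densities(traj, frame)
        assert point.rho_dilute == 0.0

    def test_fit_tc_noiseless_exact(self):
        pts = fx.make_binodal(300.0, 600.0, np.linspace(200, 290, 8),
                              rho_c=300.0, diameter_slope=80.0)
        fit = ana.fit_tc(pts)
        assert fit.Tc == pytest.approx(300.0, abs=0.5)
        assert fit.amplitude == pytest.approx(600.0, rel=1e-3)

    def test_fit_tc_noisy_mean_within_2pct(self):
        tcs = []
        for seed in range(10):
            pts = fx.make_binodal(300.0, 600.0, np.linspace(200, 285, 8),
                                  rho_c=300.0, diameter_slope=80.0,
                                  noise=0.02, seed=seed)
            tcs.append(ana.fit_tc(pts).Tc)
        assert np.mean(tcs) == pytest.approx(300.0, rel=0.02)

    def test_single_temperature_rejected(self):
        pts = fx.make_binodal(300.0, 600.0, [250.0])
        with pytest.raises(ValueError):
            ana.fit_tc(pts)

    def test_tc_above_coexisting_temperatures(self):
        pts = fx.make_binodal(330.0, 500.0, np.linspace(230, 310, 6))
        fit = ana.fit_tc(pts)
        assert fit.Tc > max(p.temperature for p in pts)


class TestRelativeStability:
    @pytest.mark.parametrize("a,b,expect", [
        (240.0, 300.0, -20.0),
        (300.0, 300.0, 0.0),
        (180.0, 300.0, -40.0),
    ])
    def test_examples(self, a, b, expect):
        assert ana.relative_stability(a, b) == pytest.approx(expect)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            ana.relative_stability(100.0, 0.0)
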