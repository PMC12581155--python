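import numpy as np
import pytest

import condensago as cg
from condensago import model_setup as ms, potentials as pot
from condensago.units import COULOMB


class TestLJ1210:
    def test_value_at_sigma(self):
        v, _ = pot.lj1210_energy(1.0, epsilon=2.0, sigma=1.0)
        assert v == pytest.approx(-2.0)

    def test_minimum_at_sigma(self):
        _, dvdr = pot.lj1210_energy(0.5, epsilon=1.3, sigma=0.5)
        assert dvdr == pytest.approx(0.0, abs=1e-12)
        # finite-difference curvature: sigma is a true minimum
        h = 1e-5
        vm, _ = pot.lj1210_energy(0.5 - h, 1.3, 0.5)
        vp, _ = pot.lj1210_energy(0.5 + h, 1.3, 0.5)
        v0, _ = pot.lj1210_energy(0.5, 1.3, 0.5)
        assert vm > v0 and vp > v0

    def test_repulsive_inside(self):
        # direct evaluation of the printed form at r = 0.9 sigma
        expect = 5.0 * (1 / 0.9) ** 12 - 6.0 * (1 / 0.9) ** 10
        v, _ = pot.lj1210_energy(0.9, epsilon=1.0, sigma=1.0)
        assert v == pytest.approx(expect)
        assert v == pytest.approx(0.4960, abs=5e-4)

    def test_rejects_nonpositive_r(self):
        with pytest.raises(ValueError):
            pot.lj1210_energy(0.0, 1.0, 1.0)


class TestWangFrenkel:
    @pytest.mark.parametrize("mu,nu", [(2.0, 1.0), (1.0, 1.0), (3.0, 2.0)])
    def test_zeros_and_minimum(self, mu, nu):
        eps, sig, rc = 0.7, 0.6, 1.8
        v_rc, _ = pot.wang_frenkel_energy(rc, eps, sig, mu, nu, rc)
        assert v_rc == pytest.approx(0.0, abs=1e-12)
        v_sig, _ = pot.wang_frenkel_energy(sig, eps, sig, mu, nu, rc)
        assert v_sig == pytest.approx(0.0, abs=1e-12)
        rmin = pot.wf_minimum_location(sig, mu, nu, rc)
        v_min, dv_min = pot.wang_frenkel_energy(rmin, eps, sig, mu, nu, rc)
        assert v_min == pytest.approx(-eps, rel=1e-9)
        assert dv_min == pytest.approx(0.0, abs=1e-9)

    def test_continuous_at_cutoff(self):
        eps, sig, rc = 0.5, 0.6, 1.8
        inside, _ = pot.wang_frenkel_energy(rc - 1e-9, eps, sig, 2.0, 1.0, rc)
        outside, _ = pot.wang_frenkel_energy(rc + 1e-9, eps, sig, 2.0, 1.0, rc)
        assert inside == pytest.approx(outside, abs=1e-6)

    def test_fast_path_matches_general_form(self):
        r = np.linspace(0.3, 2.0, 50)
        v1, f1 = pot.wang_frenkel_energy(r, 0.8, 0.55, 2.0, 1.0, 1.65)
        # nudge mu off the fast path by an invisible epsilon
        v2, f2 = pot.wang_frenkel_energy(r, 0.8, 0.55, 2.0 + 1e-13, 1.0, 1.65)
        assert np.allclose(v1, v2, atol=1e-8)
        assert np.allclose(f1, f2, atol=1e-6)


class TestDebyeHuckel:
    def test_zero_charge(self):
        v, _ = pot.debye_huckel_energy(0.7, 0.0, 1.0)
        assert v == 0.0

    def test_opposite_charges_attract(self):
        r = np.linspace(0.2, 3.4, 30)
        v, _ = pot.debye_huckel_energy(r, 1.0, -1.0)
        assert np.all(v < 0)

    def test_screening_at_debye_length(self):
        lam = 0.8
        v, _ = pot.debye_huckel_energy(lam, 1.0, 1.0, dielectric=80.0,
                                       debye_length=lam, shifted=False)
        bare = COULOMB / 80.0 / lam
        assert v / bare == pytest.approx(np.exp(-1.0))


def _random_system(seed=0, n_pep=2, with_contacts=True):
    import dataclasses

    from condensago.experiments import PRESETS, build_variant_system
    from condensago.contacts import VariantSpec

    preset = dataclasses.replace(PRESETS["tiny"], n_peptides=n_pep,
                                 n_rna=1, rna_length=4, box_length=9.0)
    return build_variant_system(
        VariantSpec(2.5, 2.0) if with_contacts else VariantSpec(1.0, 0.0),
        preset, 150.0, seed=seed)[0]


class TestBondedTerms:
    def test_zero_at_equilibrium(self):
        coords = np.array([[0, 0, 0], [0.38, 0, 0.]])
        cfg = ms.SystemConfig(box_length=9.0, n_peptides=1, n_rna=0)
        topo = ms.Topology(
            beads=ms.build_peptide_topology("AA").beads,
            bonds=[(0, 1, 0.38, 8000.0)], angles=[], torsions=[])
        sys_ = ms.assemble_system(cfg, topo)
        sys_.positions = coords
        v, _ = pot.bonded_energy_forces(coords, sys_)
        assert v == pytest.approx(0.0, abs=1e-20)

    def test_single_bond_stretch_closed_form(self):
        cfg = ms.SystemConfig(box_length=9.0, n_peptides=1, n_rna=0)
        topo = ms.Topology(
            beads=ms.build_peptide_topology("AA").beads,
            bonds=[(0, 1, 0.38, 8000.0)], angles=[], torsions=[])
        sys_ = ms.assemble_system(cfg, topo)
        delta = 0.07
        coords = np.array([[0, 0, 0], [0.38 + delta, 0, 0.]])
        v, _ = pot.bonded_energy_forces(coords, sys_)
        assert v == pytest.approx(8000.0 * delta ** 2)

    def test_gradient_matches_finite_differences(self):
        sys_ = _random_system(seed=4)
        pos = sys_.positions
        _, F = pot.bonded_energy_forces(pos, sys_)
        rng = np.random.default_rng(0)
        for _ in range(12):
            i = int(rng.integers(sys_.n_beads))
            d = int(rng.integers(3))
            h = 1e-6
            pp = pos.copy(); pp[i, d] += h
            pm = pos.copy(); pm[i, d] -= h
            vp, _ = pot.bonded_energy_forces(pp, sys_, compute_forces=False)
            vm, _ = pot.bonded_energy_forces(pm, sys_, compute_forces=False)
            fd = -(vp - vm) / (2 * h)
            scale = max(abs(fd), 1.0)
            assert abs(fd - F[i, d]) / scale < 1e-6


class TestTotalEnergy:
    def test_far_apart_peptides_no_interaction(self):
        import dataclasses

        from condensago.experiments import PRESETS, build_variant_system
        from condensago.contacts import VariantSpec

        preset = dataclasses.replace(
            PRESETS["tiny"], n_peptides=2, n_rna=0, box_length=20.0)
        sys_, _ = build_variant_system(VariantSpec(1.0, 0.0), preset, 150.0,
                                       seed=0, droplet=False)
        # move chains to opposite corners, far beyond all cutoffs
        pos = sys_.positions.copy()
        a = sys_.chain_atoms(0)
        b = sys_.chain_atoms(1)
        pos[a] = pos[a] - pos[a].mean(axis=0) + 3.0
        pos[b] = pos[b] - pos[b].mean(axis=0) + 13.0
        brk = pot.total_energy(pos, sys_)
        assert brk.V_pep_pep == 0.0

    def test_translation_invariance(self):
        sys_ = _random_system(seed=7)
        pos = sys_.positions
        a = pot.total_energy(pos, sys_)
        b = pot.total_energy(pos + np.array([1.7, -2.3, 0.9]), sys_)
        for ch in pot.EnergyBreakdown.CHANNELS:
            assert getattr(a, ch) == pytest.approx(getattr(b, ch),
                                                   rel=1e-9, abs=1e-9)

    def test_two_bead_hand_summed_oracle(self):
        cfg = ms.SystemConfig(box_length=9.0, n_peptides=1, n_rna=1,
                              rna_length=1)
        pep = ms.build_peptide_topology("R")
        rna = ms.Topology(beads=ms.build_rna_topology(1).beads[:1],
                          bonds=[], angles=[], torsions=[])
        sys_ = ms.assemble_system(cfg, pep, rna)
        r = 0.5
        pos = np.array([[1, 1, 1], [1 + r, 1, 1.]])
        sys_.positions = pos
        brk = pot.total_energy(pos, sys_)
        pt = sys_.pair_table
        e = pt.entry("R", ms.PHOSPHATE_CODE)
        v_wf, _ = pot.wang_frenkel_energy(
            r, e["epsilon"], e["sigma"], e["mu"], e["nu"],
            cfg.wf_cutoff_factor * e["sigma"])
        el = cfg.electrostatics
        v_dh, _ = pot.debye_huckel_energy(r, 1.0, -1.0, el.dielectric,
                                          el.debye_length, el.cutoff)
        assert brk.V_pep_rna == pytest.approx(v_wf + v_dh, rel=1e-12)
        assert brk.total == pytest.approx(v_wf + v_dh, rel=1e-12)

    def test_decomposition_closure(self):
        sys_ = _random_system(seed=9, n_pep=3)
        brk = pot.total_energy(sys_.positions, sys_)
        channels = sum(getattr(brk, c) for c in pot.EnergyBreakdown.CHANNELS)
        assert brk.total == pytest.approx(channels, rel=1e-12)


class TestKernelPaths:
    def test_fused_kernel_matches_reference_path(self, monkeypatch):
        sys_ = _random_system(seed=11, n_pep=3)
        pos = sys_.positions
        fast_brk, fast_F = pot.energy_and_forces(pos, sys_)
        monkeypatch.setattr(pot, "_HAVE_NUMBA", False)
        monkeypatch.setattr(sys_.pair_table, "uniform_fast", False)
        slow_brk, slow_F = pot.energy_and_forces(pos, sys_)
        for ch in pot.EnergyBreakdown.CHANNELS:
            assert getattr(fast_brk, ch) == pytest.approx(
                getattr(slow_brk, ch), rel=1e-9, abs=1e-9)
        assert np.allclose(fast_F, slow_F, atol=1e-8)


class TestForces:
    def test_isolated_bead_zero_force(self):
        cfg = ms.SystemConfig(box_length=9.0, n_peptides=1, n_rna=0)
        pep = ms.build_peptide_topology("A")
        sys_ = ms.assemble_system(cfg, pep)
        F = pot.forces(sys_.positions, sys_)
        assert np.allclose(F, 0.0)

    def test_newtons_third_law_two_beads(self):
        cfg = ms.SystemConfig(box_length=9.0, n_peptides=2, n_rna=0)
        pep = ms.build_peptide_topology("R")
        sys_ = ms.assemble_system(cfg, pep)
        pos = np.array([[1, 1, 1], [1.8, 1, 1.]])
        F = pot.forces(pos, sys_)
        assert np.allclose(F[0], -F[1])
        assert abs(F[0][1]) < 1e-12 and abs(F[0][2]) < 1e-12

    def test_random_20_bead_finite_differences(self):
        sys_ = _random_system(seed=5)
        assert sys_.n_beads >= 20
        pos = sys_.positions
        _, F = pot.energy_and_forces(pos, sys_)
        rng = np.random.default_rng(3)
        h = 1e-6
        for _ in range(25):
            i = int(rng.integers(sys_.n_beads))
            d = int(rng.integers(3))
            pp = pos.copy(); pp[i, d] += h
            pm = pos.copy(); pm[i, d] -= h
            fd = -(pot.total_energy(pp, sys_).total
                   - pot.total_energy(pm, sys_).total) / (2 * h)
            scale = max(abs(F[i, d]), 1.0)
            assert abs(fd - F[i, d]) / scale < 1e-4

    def test_net_force_vanishes(self):
        sys_ = _random_system(seed=6, n_pep=3)
        F = pot.forces(sys_.positions, sys_)
        assert np.allclose(F.sum(axis=0), 0.0, atol=1e-6)
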