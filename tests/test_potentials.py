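"""Force-field terms: printed constants, analytic derivatives, PBC."""

import numpy as np
import pytest

from cgslab import (
    ChainSpec,
    ForceFieldParams,
    NeighborList,
    bond_energy_force,
    build_chain,
    dh_energy_force,
    kappa_from_salt,
    lj_energy_force,
    topology_from_chain,
    total_energy_forces,
)
from cgslab.potentials import OverlapError, numerical_gradient_check
from conftest import brute_force_energy_forces


@pytest.fixture
def params():
    return ForceFieldParams()


class TestBond:
    def test_zero_at_equilibrium(self, params):
        u, f = bond_energy_force(0.38, params)
        assert u == 0.0 and f == 0.0

    def test_printed_constant_value(self, params):
        # Kb (r - r0)^2 = 20000 * 0.01^2 = 2.0 kJ/mol at r = 0.39 nm
        u, f = bond_energy_force(0.39, params)
        assert u == pytest.approx(2.0)
        assert f == pytest.approx(-2 * 20000 * 0.01)

    def test_symmetric_about_r0(self, params):
        u_plus, _ = bond_energy_force(0.39, params)
        u_minus, _ = bond_energy_force(0.37, params)
        assert u_plus == pytest.approx(u_minus)


class TestLennardJones:
    def test_zero_at_sigma_before_shift(self, params):
        u, _ = lj_energy_force(1.0, params.eps, params, shifted=False)
        assert u == pytest.approx(0.0, abs=1e-15)

    def test_minimum_is_quarter_eps_in_printed_form(self, params):
        rmin = 2.0 ** (1.0 / 6.0) * params.sigma
        u, f = lj_energy_force(rmin, params.eps, params, shifted=False)
        assert u == pytest.approx(-params.eps / 4.0)  # -0.00025 kJ/mol
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_standard_mode_is_four_times_printed(self, params):
        import dataclasses

        std = dataclasses.replace(params, lj_prefactor_mode="standard_4eps")
        r = np.linspace(0.5, 2.9, 40)
        u1, f1 = lj_energy_force(r, params.eps, params)
        u4, f4 = lj_energy_force(r, params.eps, std)
        assert np.allclose(4 * u1, u4)
        assert np.allclose(4 * f1, f4)

    def test_shifted_to_zero_at_cutoff(self, params):
        u, f = lj_energy_force(params.r_cut_lj - 1e-9, params.eps, params)
        assert abs(u) < 1e-12
        u, f = lj_energy_force(params.r_cut_lj + 0.1, params.eps, params)
        assert u == 0.0 and f == 0.0

    def test_overlap_flagged(self, params):
        with pytest.raises(OverlapError):
            lj_energy_force(1e-9, params.eps, params)


class TestDebyeHueckel:
    def test_unscreened_coulomb_value(self, params):
        # K_coulomb / dielectric = 138.94 / 80 at r = 1 nm, kappa = 0
        u, _ = dh_energy_force(1.0, 1, 1, params, shifted=False)
        assert u == pytest.approx(1.73675)

    def test_zero_charge_pair_skipped(self, params):
        u, f = dh_energy_force(0.5, 1, 0, params)
        assert u == 0.0 and f == 0.0

    def test_screened_attraction_value(self):
        p = ForceFieldParams(kappa=0.32)
        u, _ = dh_energy_force(1.0, 1, -1, p, shifted=False)
        assert u == pytest.approx(-1.73675 * np.exp(-0.32))

    def test_reduces_to_coulomb_as_kappa_to_zero(self, params):
        r = np.linspace(0.4, 3.0, 30)
        u0, f0 = dh_energy_force(r, 1, -1, params, shifted=False)
        p = ForceFieldParams(kappa=1e-12)
        u, f = dh_energy_force(r, 1, -1, p, shifted=False)
        assert np.allclose(u, u0, rtol=1e-9)
        coulomb = 138.94 / 80 * (-1) / r
        assert np.allclose(u0, coulomb)


@pytest.mark.parametrize("c_salt,expected", [
    (0.01, 0.32), (0.0, 0.0), (1.0, 3.2),
])
def test_kappa_from_salt(c_salt, expected):
    assert kappa_from_salt(c_salt) == pytest.approx(expected)


def test_negative_salt_rejected():
    with pytest.raises(ValueError):
        kappa_from_salt(-0.1)


def test_param_invariants_enforced():
    with pytest.raises(ValueError):
        ForceFieldParams(eps=0.001, eps_insert=0.01)
    with pytest.raises(ValueError):
        ForceFieldParams(kappa=-1.0)
    with pytest.raises(ValueError):
        ForceFieldParams(sigma=0.0)
    with pytest.raises(ValueError):
        ForceFieldParams(lj_prefactor_mode="bogus")


class TestTotalEnergyForces:
    def test_two_isolated_beads_at_sigma(self):
        """Two neutral unbonded beads at r = sigma: pure (unshifted) LJ = 0;
        with the cutoff shift the energy equals minus the shift term."""
        chain = build_chain(ChainSpec("G", 1.0))
        topo = topology_from_chain(chain, 2, (50.0, 50.0, 50.0))
        coords = np.array([[10.0, 10.0, 10.0], [11.0, 10.0, 10.0]])
        p = ForceFieldParams()
        e, f = total_energy_forces(topo, coords, p, charge_mode="no_charge")
        sc6 = (p.sigma / p.r_cut_lj) ** 6
        assert e == pytest.approx(-p.eps * (sc6 * sc6 - sc6), rel=1e-12)

    def test_straight_chain_at_r0_zero_bond_energy(self):
        chain = build_chain(ChainSpec("GGG", 1.0))
        topo = topology_from_chain(chain, 1, (50.0, 50.0, 50.0))
        coords = np.array([[1.0, 1.0, 1.0], [1.38, 1.0, 1.0],
                           [1.76, 1.0, 1.0]])
        p = ForceFieldParams(eps=1e-30, eps_insert=1e-31)
        e, _ = total_energy_forces(topo, coords, p, charge_mode="no_charge")
        assert e == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("charge_mode", ["no_charge", "salt_10mM"])
    def test_matches_brute_force_oracle_30_beads(self, small_charged_system,
                                                 charge_mode):
        topo, coords = small_charged_system
        p = ForceFieldParams(kappa=0.32, eps=0.5, eps_insert=0.005)
        e, f = total_energy_forces(topo, coords, p, charge_mode=charge_mode)
        e_ref, f_ref = brute_force_energy_forces(topo, coords, p,
                                                 charge_mode)
        assert e == pytest.approx(e_ref, rel=1e-10)
        np.testing.assert_allclose(f, f_ref, rtol=1e-10, atol=1e-10)

    def test_neighbor_list_matches_oracle_500_beads(self, medium_system):
        topo, coords = medium_system
        p = ForceFieldParams(kappa=0.32, r_cut_lj=2.0, r_cut_dh=2.5)
        nlist = NeighborList(topo, coords, p)
        e, f = total_energy_forces(topo, coords, p, nlist, "salt_10mM")
        e_ref, f_ref = brute_force_energy_forces(topo, coords, p,
                                                 "salt_10mM")
        assert e == pytest.approx(e_ref, rel=1e-12)
        np.testing.assert_allclose(f, f_ref, rtol=1e-9, atol=1e-12)

    def test_numba_kernel_matches_numpy_path(self, medium_system):
        """The production (numba) force kernel agrees with the library's
        numpy evaluation on the same neighbor list cutoffs."""
        from cgslab import _kernels
        from cgslab.simulator import _exclusions

        topo, coords = medium_system
        p = ForceFieldParams(kappa=0.32, r_cut_lj=2.0, r_cut_dh=2.5)
        e_np, f_np = total_energy_forces(topo, coords, p,
                                         charge_mode="salt_10mM")
        excl = _exclusions(topo.n_beads, topo.bonds)
        cap = 200000
        pairs = np.empty((cap, 2), np.int64)
        peps = np.empty(cap)
        qq = np.empty(cap)
        wrapped = np.mod(coords, topo.box)
        m = _kernels.build_pairs(wrapped, topo.box, 2.5, excl, pairs)
        assert m < cap
        _kernels.pair_coefficients(pairs, m, topo.is_insert,
                                   topo.charges.astype(float),
                                   p.eps, p.eps_insert, peps, qq)
        forces = np.zeros_like(coords)
        e = _kernels.bond_forces(coords, topo.box, topo.bonds, p.kb, p.r0,
                                 forces)
        e += _kernels.nonbonded_forces(
            coords, topo.box, pairs, m, peps, qq, p.sigma, p.lj_prefactor,
            p.r_cut_lj, p.r_cut_dh,
            p.k_coulomb * p.b_kappa / p.dielectric, p.kappa, forces)
        assert e == pytest.approx(e_np, rel=1e-9)
        np.testing.assert_allclose(forces, f_np, rtol=1e-8, atol=1e-9)

    def test_analytic_forces_match_numerical_gradient(self,
                                                      small_charged_system):
        topo, coords = small_charged_system
        p = ForceFieldParams(kappa=0.32, eps=0.5, eps_insert=0.005)
        dev = numerical_gradient_check(topo, coords, p, "salt_10mM",
                                       rng=1, n_probe=40)
        assert dev < 1e-6

    def test_energy_invariant_under_rigid_and_lattice_translations(
            self, small_charged_system):
        topo, coords = small_charged_system
        p = ForceFieldParams(kappa=0.32, eps=0.5, eps_insert=0.005)
        e0, f0 = total_energy_forces(topo, coords, p,
                                     charge_mode="salt_10mM")
        shifted = coords + np.array([1.234, -0.77, 2.5])
        e1, f1 = total_energy_forces(topo, shifted, p,
                                     charge_mode="salt_10mM")
        assert e1 == pytest.approx(e0, rel=1e-10)
        np.testing.assert_allclose(f1, f0, rtol=1e-8, atol=1e-10)

        lattice = coords.copy()
        lattice[5] += topo.box * np.array([2.0, -1.0, 3.0])
        e2, f2 = total_energy_forces(topo, lattice, p,
                                     charge_mode="salt_10mM")
        assert e2 == pytest.approx(e0, rel=1e-10)
        np.testing.assert_allclose(f2, f0, rtol=1e-8, atol=1e-10)

    def test_no_charge_mode_zeroes_electrostatics(self,
                                                  small_charged_system):
        topo, coords = small_charged_system
        p = ForceFieldParams(kappa=0.32)
        e_salt, _ = total_energy_forces(topo, coords, p,
                                        charge_mode="salt_10mM")
        e_off, _ = total_energy_forces(topo, coords, p,
                                       charge_mode="no_charge")
        assert e_salt != pytest.approx(e_off)
        p_nodh = ForceFieldParams(kappa=0.32, k_coulomb=138.94)
        e_brute, _ = brute_force_energy_forces(topo, coords, p_nodh,
                                               "no_charge")
        assert e_off == pytest.approx(e_brute, rel=1e-10)


def test_neighbor_list_rebuild_contract(small_charged_system):
    topo, coords = small_charged_system
    p = ForceFieldParams()
    nlist = NeighborList(topo, coords, p, skin=0.4)
    assert not nlist.needs_rebuild(coords)
    moved = coords.copy()
    moved[0] += 0.3
    assert nlist.needs_rebuild(moved)
    e_auto, _ = total_energy_forces(topo, moved, p, nlist, "no_charge")
    fresh = NeighborList(topo, moved, p)
    e_fresh, _ = total_energy_forces(topo, moved, p, fresh, "no_charge")
    assert e_auto == pytest.approx(e_fresh, rel=1e-12)


def test_insert_pairs_use_insert_epsilon():
    """Any pair touching at least one inserted bead interacts at
    eps_insert; normal-normal pairs keep eps (checked at the kernel's
    pair-coefficient level for every pair of a tail10 chain)."""
    from cgslab import _kernels

    chain = build_chain(ChainSpec("GG", 1.0, "tail10"))
    topo = topology_from_chain(chain, 1, (50.0, 50.0, 50.0))
    n = topo.n_beads
    ii, jj = np.triu_indices(n, k=1)
    pairs = np.column_stack([ii, jj]).astype(np.int64)
    peps = np.empty(len(pairs))
    qq = np.empty(len(pairs))
    p = ForceFieldParams()
    _kernels.pair_coefficients(pairs, len(pairs), topo.is_insert,
                               topo.charges.astype(float),
                               p.eps, p.eps_insert, peps, qq)
    expect = np.where(topo.is_insert[ii] | topo.is_insert[jj],
                      p.eps_insert, p.eps)
    np.testing.assert_allclose(peps, expect)
    # normal-normal pair (0,1) keeps eps; insert-insert (10,11) and
    # mixed (0,11) use eps_insert
    lookup = {tuple(pr): pe for pr, pe in zip(map(tuple, pairs), peps)}
    assert lookup[(0, 1)] == p.eps
    assert lookup[(0, 11)] == p.eps_insert
    assert lookup[(10, 11)] == p.eps_insert
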