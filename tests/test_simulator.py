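"""Integrator and protocol: determinism, thermostat, energy conservation."""

import numpy as np
import pytest

from cgslab import (
    ChainSpec,
    ForceFieldParams,
    SimulationConfig,
    build_chain,
    initialize_velocities,
    langevin_step,
    run_protocol,
    topology_from_chain,
)
from cgslab.potentials import NeighborList, total_energy_forces
from cgslab.simulator import (
    DESK_FF,
    IntegrationError,
    integrate,
    kinetic_temperature,
    slab_box_for,
)
from cgslab.units import KB, kbt


def free_bead_topology(n=1, mass=1.0, box=(50.0, 50.0, 50.0)):
    chain = build_chain(ChainSpec("G", mass))
    return topology_from_chain(chain, n, box)


#: force field with nonbonded terms switched off entirely (bonds only)
BONDS_ONLY = ForceFieldParams(eps=0.0, eps_insert=0.0)


class TestVelocityInitialization:
    def test_t_to_zero_limit(self):
        topo = free_bead_topology(100)
        v = initialize_velocities(topo.masses, 1e-12, seed=1)
        assert np.abs(v).max() < 1e-5

    def test_kinetic_temperature_at_target(self):
        """10,000 beads at 2.0 T0: instantaneous kinetic temperature
        concentrates within 3% (chi-square with 30,000 dof)."""
        masses = np.tile([1.0, 1.2, 1.5], 3334)[:10000]
        v = initialize_velocities(masses, 2.0, seed=2)
        t_kin = kinetic_temperature(masses, v)
        assert abs(t_kin - 2.0) / 2.0 < 0.03

    def test_determinism_and_zero_momentum(self):
        topo = free_bead_topology(50, mass=1.3)
        v1 = initialize_velocities(topo.masses, 1.5, seed=9)
        v2 = initialize_velocities(topo.masses, 1.5, seed=9)
        assert np.array_equal(v1, v2)
        p = (topo.masses[:, None] * v1).sum(axis=0)
        assert np.abs(p).max() < 1e-10

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            initialize_velocities(np.array([1.0, 0.0]), 1.0, 1)


class TestLangevinStep:
    def test_ballistic_free_bead_without_friction(self):
        """gamma = 0, no interactions: exact straight-line motion."""
        topo = free_bead_topology(1)
        x = np.array([[10.0, 10.0, 10.0]])
        v = np.array([[0.3, -0.2, 0.5]])
        rng = np.random.default_rng(0)
        dt = 0.002
        xs, vs = x.copy(), v.copy()
        forces = None
        for _ in range(1000):
            xs, vs, forces = langevin_step(
                xs, vs, topo, BONDS_ONLY, dt, 0.0, 1.0, rng, forces,
                "no_charge")
        np.testing.assert_allclose(xs, x + v * 1000 * dt, rtol=1e-12)
        np.testing.assert_allclose(vs, v, rtol=1e-12)

    def test_kernel_matches_reference_step_without_noise(self):
        """One deterministic (gamma = 0) kernel segment reproduces the
        numpy reference BAOAB step by step."""
        chain = build_chain(ChainSpec("GGGG", 1.2))
        topo = topology_from_chain(chain, 2, (20.0, 20.0, 20.0))
        rng = np.random.default_rng(3)
        coords = rng.uniform(5, 15, (8, 3))
        coords[1::2] = coords[::2] + 0.38  # keep bonds reasonable
        v = initialize_velocities(topo.masses, 1.0, seed=4)
        p = ForceFieldParams(eps=0.5, eps_insert=0.005)

        ref_x, ref_v = coords.copy(), v.copy()
        forces = None
        for _ in range(20):
            ref_x, ref_v, forces = langevin_step(
                ref_x, ref_v, topo, p, 0.002, 0.0, 1.0, rng, forces,
                "no_charge")
        ker_x, ker_v = coords.copy(), v.copy()
        integrate(topo, ker_x, ker_v, p, 20, 0.002, 0.0, 1.0, seed=1,
                  charge_mode="no_charge")
        np.testing.assert_allclose(ker_x, ref_x, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(ker_v, ref_v, rtol=1e-9, atol=1e-12)

    def test_dimer_energy_conservation_at_gamma_zero(self):
        """Bonded dimer in the velocity-Verlet limit shows no secular
        total-energy drift over 1e5 steps: window-averaged energies at
        the start and end of the run agree to 1e-4 relative (sampled
        incommensurately with the bond period so the bounded shadow-
        energy oscillation averages out)."""
        chain = build_chain(ChainSpec("GG", 1.0))
        topo = topology_from_chain(chain, 1, (20.0, 20.0, 20.0))
        coords = np.array([[5.0, 5.0, 5.0], [5.42, 5.0, 5.0]])
        v = np.array([[0.0, 0.05, 0.0], [0.0, -0.05, 0.0]])
        p = ForceFieldParams(kb=200.0, eps=0.0, eps_insert=0.0)

        def total_energy(x, vel):
            e, _ = total_energy_forces(topo, x, p, charge_mode="no_charge")
            return e + 0.5 * (topo.masses[:, None] * vel**2).sum()

        x, vel = coords.copy(), v.copy()
        energies = []
        for k in range(1600):  # 1600 x 61 steps = ~1e5 steps
            integrate(topo, x, vel, p, 61, 0.002, 0.0, 1.0, seed=1,
                      charge_mode="no_charge")
            energies.append(total_energy(x, vel))
        energies = np.array(energies)
        first = energies[:300].mean()
        last = energies[-300:].mean()
        assert abs(last - first) / abs(first) < 1e-4

    def test_nonfinite_halt_diagnostic(self):
        """Non-finite coordinates are reported, not silently propagated."""
        chain = build_chain(ChainSpec("GG", 1.0))
        topo = topology_from_chain(chain, 1, (20.0, 20.0, 20.0))
        coords = np.array([[5.0, 5.0, 5.0], [np.nan, 5.0, 5.0]])
        v = np.zeros((2, 3))
        with pytest.raises(IntegrationError):
            integrate(topo, coords, v, ForceFieldParams(), 10,
                      0.002, 0.0, 1.0, seed=1, charge_mode="no_charge")


class TestThermostat:
    @pytest.mark.parametrize("mass", [1.0, 1.1, 1.2, 1.3, 1.5])
    def test_ideal_gas_fluctuation_dissipation(self, mass):
        """<T_kin> equals the set point within 3 SE for every mass scale
        (free beads, >= 1e5 total steps)."""
        topo = free_bead_topology(200, mass=mass, box=(20.0, 20.0, 20.0))
        rng = np.random.default_rng(10)
        coords = rng.uniform(0, 20, (200, 3))
        v = initialize_velocities(topo.masses, 1.0, seed=11)
        samples = []
        for k in range(60):
            integrate(topo, coords, v, BONDS_ONLY, 2000, 0.01, 1.0, 1.0,
                      seed=1000 + k, charge_mode="no_charge")
            samples.append(kinetic_temperature(topo.masses, v))
        samples = np.array(samples[10:])
        se = samples.std(ddof=1) / np.sqrt(len(samples))
        assert abs(samples.mean() - 1.0) < 3 * max(se, 1e-4)

    def test_bond_length_distribution_variance(self):
        """Equilibrium bond-length variance approaches kB*T/(2 Kb)."""
        chain = build_chain(ChainSpec("G" * 20, 1.0))
        topo = topology_from_chain(chain, 1, (30.0, 30.0, 30.0))
        coords = np.zeros((20, 3)) + 15.0
        coords[:, 0] += np.arange(20) * 0.38
        p = ForceFieldParams(kb=1000.0, eps=1e-30, eps_insert=1e-31)
        v = initialize_velocities(topo.masses, 1.0, seed=12)
        lengths = []
        for k in range(400):
            integrate(topo, coords, v, p, 200, 0.002, 1.0, 1.0,
                      seed=2000 + k, charge_mode="no_charge")
            lengths.extend(
                np.linalg.norm(np.diff(coords, axis=0), axis=1))
        lengths = np.array(lengths[1000:])
        expected = kbt(1.0) / (2 * 1000.0)
        # radial sampling in 3D shifts the raw variance slightly; 5%
        assert lengths.var() == pytest.approx(expected, rel=0.05)

    def test_free_bead_msd_decreases_with_mass(self):
        """In the inertial regime the z MSD per unit time falls with bead
        mass at fixed T and gamma -- the mobility mechanism."""
        msds = []
        for mass in (1.0, 1.1, 1.2, 1.3, 1.5):
            topo = free_bead_topology(400, mass=mass,
                                      box=(50.0, 50.0, 50.0))
            coords = np.random.default_rng(19).uniform(0, 50, (400, 3))
            start = coords.copy()
            v = initialize_velocities(topo.masses, 1.0, seed=20)
            # 2 ps at gamma = 1/ps: still partly inertial
            integrate(topo, coords, v, BONDS_ONLY, 1000, 0.002, 1.0, 1.0,
                      seed=21, charge_mode="no_charge")
            msds.append(((coords - start)[:, 2] ** 2).mean())
        assert all(a > b for a, b in zip(msds, msds[1:]))


class TestProtocol:
    def test_slab_box_rule(self):
        assert np.allclose(slab_box_for(10000), [31.0, 31.0, 300.0])
        assert np.allclose(slab_box_for(12000), [34.0, 34.0, 300.0])
        assert slab_box_for(600) is None

    def test_frame_count_arithmetic_and_cadence(self):
        cfg = SimulationConfig(duration_tau=50.0, frame_interval_tau=0.5,
                               dt_ps=0.01)
        assert cfg.n_frames == 100
        assert cfg.steps_per_frame == 50000
        with pytest.raises(ValueError, match="integer multiple"):
            SimulationConfig(frame_interval_tau=0.0005, dt_ps=0.3)

    def test_desk_protocol_emits_requested_frames(self):
        chain = build_chain(ChainSpec("G" * 5, 1.0))
        topo = topology_from_chain(chain, 6, (6.0, 6.0, 24.0))
        cfg = SimulationConfig(
            temperature=2.0, dt_ps=0.01, friction=0.5, duration_tau=0.02,
            equil_tau=0.005, frame_interval_tau=0.002, seed=3,
            slab_box=(6.0, 6.0, 24.0), relax_steps=200,
        )
        traj = run_protocol(topo, DESK_FF, cfg)
        assert traj.n_frames == 11  # initial frame + 10 intervals
        assert traj.times_tau[-1] == pytest.approx(0.02)
        assert np.isfinite(traj.coords).all()
        assert traj.coords.shape == (11, 30, 3)

    def test_protocol_reproducible_for_fixed_seed(self):
        chain = build_chain(ChainSpec("G" * 5, 1.0))
        cfg = SimulationConfig(
            temperature=1.5, dt_ps=0.01, friction=0.5, duration_tau=0.01,
            equil_tau=0.0, frame_interval_tau=0.002, seed=8,
            slab_box=(6.0, 6.0, 24.0), relax_steps=100,
        )
        runs = []
        for _ in range(2):
            topo = topology_from_chain(chain, 6, (6.0, 6.0, 24.0))
            runs.append(run_protocol(topo, DESK_FF, cfg).coords)
        assert np.array_equal(runs[0], runs[1])

    def test_cube_then_slab_rewraps_into_slab_box(self):
        chain = build_chain(ChainSpec("G" * 5, 1.0))
        topo = topology_from_chain(chain, 6, (6.0, 6.0, 24.0))
        cfg = SimulationConfig(
            temperature=1.5, dt_ps=0.01, friction=0.5, duration_tau=0.01,
            equil_tau=0.002, frame_interval_tau=0.002, seed=8,
            slab_box=(6.0, 6.0, 24.0), protocol="cube_then_slab",
            relax_steps=100,
        )
        traj = run_protocol(topo, DESK_FF, cfg)
        wrapped = traj.wrapped(traj.n_frames - 1)
        assert (wrapped >= 0).all()
        assert (wrapped <= np.array([6.0, 6.0, 24.0])).all()


def test_chain_cm_mass_weighting():
    chain = build_chain(ChainSpec("GG", 1.0, "tail10"))  # mixed masses? no
    topo = topology_from_chain(chain, 1, (10.0, 10.0, 10.0))
    topo.masses[0] = 3.0  # make weighting visible
    coords = np.zeros((1, 12, 3))
    coords[0, :, 2] = np.arange(12.0)
    from cgslab.simulator import TrajectorySeries

    traj = TrajectorySeries(np.zeros(1), coords, topo.box, topo)
    cm = traj.chain_cm()
    expected = (coords[0, :, 2] * topo.masses).sum() / topo.masses.sum()
    assert cm[0, 0, 2] == pytest.approx(expected)
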