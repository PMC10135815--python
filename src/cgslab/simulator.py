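"""Langevin dynamics in the slab geometry.

The integrator is BAOAB splitting with friction gamma and a Maxwell-
Boltzmann thermostat; the bead mass enters both the inertia and the
thermostat drag, so at equal temperature heavier beads move and diffuse
more slowly -- the central mechanism by which mass changes act on phase
separation.

The default protocol builds a compact slab of chains in the middle of the
elongated box, relaxes it briefly at reduced time step, re-draws
velocities, equilibrates, and then runs production, saving bead
coordinates and chain centers of mass on a fixed frame grid.  A literal
cube-then-slab variant (equilibrate in a cube, then stretch z and rewrap)
is available via ``protocol="cube_then_slab"``.

Presets
-------
``desk``   : 20-bead chains with a bead-spring force field whose critical
             temperature falls inside the 1-4 T0 grid; minutes per run.
``medium`` : 50 chains x 50 beads, 500 tau.
``production`` : 200 chains x 50/60 beads, 5000 tau, full force field.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from . import _kernels
from .chain_models import SystemTopology, random_walk_coordinates
from .potentials import CHARGE_MODES, ForceFieldParams, kappa_from_salt
from .units import KB, TAU_PS, kbt


def slab_box_for(n_beads: int) -> Optional[np.ndarray]:
    """The production slab box rule: 31x31x300 nm for 10,000-bead systems,
    34x34x300 nm for 12,000-bead systems, None otherwise."""
    if n_beads == 10000:
        return np.array([31.0, 31.0, 300.0])
    if n_beads == 12000:
        return np.array([34.0, 34.0, 300.0])
    return None


@dataclass(frozen=True)
class SimulationConfig:
    """Run parameters.  Times are in tau (= 1 ns), dt in ps, T in T0 units."""

    temperature: float = 2.0
    dt_ps: float = 0.002
    friction: float = 1.0          # ps^-1
    duration_tau: float = 50.0     # production length
    equil_tau: float = 1.0
    frame_interval_tau: float = 0.5
    seed: int = 0
    charge_mode: str = "no_charge"
    salt_molar: float = 0.01
    slab_box: Optional[tuple] = None
    protocol: str = "slab_start"   # or "cube_then_slab"
    slab_density: float = 0.6      # beads/nm^3 for the constructed start
    relax_steps: int = 4000
    neighbor_skin: float = 0.4

    def __post_init__(self):
        if self.dt_ps <= 0 or self.temperature <= 0:
            raise ValueError("dt and temperature must be positive")
        if self.charge_mode not in CHARGE_MODES:
            raise ValueError(f"charge_mode must be one of {CHARGE_MODES}")
        steps = self.frame_interval_tau * TAU_PS / self.dt_ps
        if abs(steps - round(steps)) > 1e-9 or round(steps) < 1:
            raise ValueError(
                "frame_interval must be a positive integer multiple of dt"
            )

    @property
    def steps_per_frame(self) -> int:
        return int(round(self.frame_interval_tau * TAU_PS / self.dt_ps))

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_tau / self.frame_interval_tau))


@dataclass(frozen=True)
class Preset:
    name: str
    n_chains: int
    chain_length: int
    forcefield: ForceFieldParams
    config: SimulationConfig
    box: tuple
    boundary_nm: float           # flux boundary |z| plane for analysis
    analysis_fraction: float = 0.2


#: Desk-scale force field: a bead-spring LJ polymer (bond length = sigma)
#: whose printed-form well depth (eps/4 = 0.6 kJ/mol) puts the critical
#: temperature just above the lowest grid temperature, so T = 1 T0 shows
#: obvious but unsaturated phase separation (populated dilute phase) and
#: the rest of the 1-4 T0 grid covers the dissolution.
DESK_FF = ForceFieldParams(
    kb=100.0, r0=1.0, sigma=1.0, eps=2.4, eps_insert=0.024,
    r_cut_lj=2.0, r_cut_dh=2.5,
)

PRODUCTION_FF = ForceFieldParams()

PRESETS = {
    "desk": Preset(
        name="desk", n_chains=20, chain_length=20, forcefield=DESK_FF,
        config=SimulationConfig(
            dt_ps=0.0125, friction=0.25, duration_tau=0.5, equil_tau=0.3,
            frame_interval_tau=0.0125, relax_steps=4000, slab_density=0.8,
        ),
        box=(13.0, 13.0, 60.0), boundary_nm=12.0, analysis_fraction=0.8,
    ),
    "medium": Preset(
        name="medium", n_chains=50, chain_length=50, forcefield=PRODUCTION_FF,
        config=SimulationConfig(
            dt_ps=0.002, friction=1.0, duration_tau=500.0, equil_tau=10.0,
        ),
        box=(20.0, 20.0, 150.0), boundary_nm=15.0,
    ),
    "production": Preset(
        name="production", n_chains=200, chain_length=50, forcefield=PRODUCTION_FF,
        config=SimulationConfig(
            dt_ps=0.002, friction=1.0, duration_tau=5000.0, equil_tau=10.0,
        ),
        box=(31.0, 31.0, 300.0), boundary_nm=25.0,
    ),
}


@dataclass
class TrajectorySeries:
    """Frames of a slab run: times in tau, unwrapped bead coordinates in nm."""

    times_tau: np.ndarray          # (F,)
    coords: np.ndarray             # (F, N, 3), unwrapped
    box: np.ndarray                # (3,)
    topology: SystemTopology

    @property
    def n_frames(self) -> int:
        return len(self.times_tau)

    def wrapped(self, frame: int) -> np.ndarray:
        return np.mod(self.coords[frame], self.box)

    def chain_cm(self) -> np.ndarray:
        """Mass-weighted chain centers of mass, (F, n_chains, 3), unwrapped."""
        topo = self.topology
        L = topo.chain_length
        m = topo.masses.reshape(topo.n_chains, L)
        w = (m / m.sum(axis=1, keepdims=True))[None, :, :, None]
        shaped = self.coords.reshape(self.n_frames, topo.n_chains, L, 3)
        return (shaped * w).sum(axis=2)


def initialize_velocities(masses: np.ndarray, temperature: float,
                          seed: int) -> np.ndarray:
    """Maxwell-Boltzmann velocities (nm/ps) at T (T0 units), zero net momentum."""
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    rng = np.random.default_rng(seed)
    kt = kbt(temperature)
    v = rng.normal(size=(len(masses), 3)) * np.sqrt(kt / masses)[:, None]
    p = (masses[:, None] * v).sum(axis=0) / masses.sum()
    return v - p[None, :]


def kinetic_temperature(masses: np.ndarray, velocities: np.ndarray) -> float:
    """Instantaneous kinetic temperature in T0 units."""
    ke = 0.5 * (masses[:, None] * velocities**2).sum()
    n_dof = velocities.size
    return 2.0 * ke / (n_dof * KB) / 100.0


def langevin_step(coords, velocities, topology, params: ForceFieldParams,
                  dt: float, gamma: float, temperature: float,
                  rng: np.random.Generator, forces=None,
                  charge_mode: str = "no_charge", neighbor_list=None):
    """One BAOAB step (reference numpy path; the production loop is numba).

    Returns updated (coords, velocities, forces).  With gamma = 0 this is
    velocity Verlet.  Used for unit tests and tiny systems.
    """
    from .potentials import total_energy_forces

    m = topology.masses[:, None]
    if forces is None:
        _, forces = total_energy_forces(topology, coords, params,
                                        neighbor_list, charge_mode)
    v = velocities + 0.5 * dt * forces / m
    x = coords + 0.5 * dt * v
    if gamma > 0:
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt(1.0 - c1 * c1)
        noise = rng.normal(size=v.shape)
        v = c1 * v + c2 * np.sqrt(kbt(temperature) / topology.masses)[:, None] * noise
    x = x + 0.5 * dt * v
    _, forces = total_energy_forces(topology, x, params, neighbor_list,
                                    charge_mode)
    v = v + 0.5 * dt * forces / m
    return x, v, forces


class IntegrationError(RuntimeError):
    pass


def _exclusions(n: int, bonds: np.ndarray) -> np.ndarray:
    excl = np.full((n, 2), -1, dtype=np.int64)
    slot = np.zeros(n, dtype=np.int64)
    for i, j in bonds:
        excl[i, slot[i]] = j
        slot[i] += 1 if slot[i] < 1 else 0
        excl[j, slot[j]] = i
        slot[j] += 1 if slot[j] < 1 else 0
    return excl


def _effective_ff(params: ForceFieldParams, config: SimulationConfig):
    if config.charge_mode == "salt_10mM" and params.kappa == 0.0:
        params = replace(params, kappa=kappa_from_salt(config.salt_molar))
    return params


def integrate(topology, coords, velocities, params: ForceFieldParams,
              n_steps: int, dt: float, gamma: float, temperature: float,
              seed: int, charge_mode: str = "no_charge",
              skin: float = 0.4, _buffers=None):
    """Advance the system n_steps with the numba BAOAB kernel (in place)."""
    n = topology.n_beads
    excl = _exclusions(n, topology.bonds)
    kc = (params.k_coulomb * params.b_kappa / params.dielectric
          if charge_mode == "salt_10mM" else 0.0)
    cap = max(8192, 128 * n) if _buffers is None else _buffers[0].shape[0]
    while True:
        if _buffers is None or _buffers[0].shape[0] < cap:
            pairs = np.empty((cap, 2), dtype=np.int64)
            peps = np.empty(cap)
            qq = np.empty(cap)
            _buffers = (pairs, peps, qq)
        pairs, peps, qq = _buffers
        status, needed = _kernels.baoab_segment(
            coords, velocities, topology.masses, topology.bonds, excl,
            topology.is_insert, topology.charges.astype(np.float64),
            topology.box, params.kb, params.r0, params.sigma, params.eps,
            params.eps_insert, params.lj_prefactor, params.r_cut_lj,
            params.r_cut_dh, kc, params.kappa,
            n_steps, dt, gamma, kbt(temperature), seed, skin,
            pairs, peps, qq,
        )
        if status == _kernels.STATUS_PAIR_OVERFLOW:
            cap = int(needed * 1.5) + 1024
            _buffers = None
            continue
        if (status == _kernels.STATUS_NOT_FINITE
                or not np.isfinite(coords).all()
                or not np.isfinite(velocities).all()):
            raise IntegrationError(
                "non-finite coordinates or velocities during integration "
                "(time step too large for the force field?)"
            )
        return coords, velocities, _buffers


def _segment_seeds(seed: int, n: int) -> np.ndarray:
    return (np.random.SeedSequence(seed).generate_state(max(n, 1))
            % np.uint32(2**31)).astype(np.int64)


def run_protocol(topology: SystemTopology, params: ForceFieldParams,
                 config: SimulationConfig,
                 initial_coords: Optional[np.ndarray] = None,
                 r0_walk: Optional[float] = None) -> TrajectorySeries:
    """Equilibrate and run slab production, returning a TrajectorySeries.

    The slab box follows the bead-count rule (10,000 beads -> 31x31x300 nm,
    12,000 -> 34x34x300) unless ``config.slab_box`` overrides it.  With
    ``protocol='slab_start'`` chains start packed in a central z-slab of
    the final box at ``config.slab_density`` and are relaxed at reduced
    time step before velocities are redrawn; ``'cube_then_slab'``
    equilibrates in a cube first and then stretches z, mirroring the
    elongation protocol.
    """
    params = _effective_ff(params, config)
    box = slab_box_for(topology.n_beads)
    if config.slab_box is not None:
        box = np.asarray(config.slab_box, dtype=float)
    if box is None:
        box = np.asarray(topology.box, dtype=float)
    topology.box = box
    n = topology.n_beads
    walk_r0 = params.r0 if r0_walk is None else r0_walk
    seeds = _segment_seeds(config.seed, config.n_frames + 4)

    if initial_coords is not None:
        coords = np.array(initial_coords, dtype=float)
    elif config.protocol == "cube_then_slab":
        side = (n / config.slab_density) ** (1.0 / 3.0)
        cube = np.array([box[0], box[1], max(side, box[0])])
        topology.box = cube
        coords = random_walk_coordinates(
            topology.n_chains, topology.chain_length, cube,
            int(seeds[0]), r0=walk_r0, min_dist=0.8 * params.sigma)
        vel = initialize_velocities(topology.masses, config.temperature,
                                    int(seeds[1]))
        integrate(topology, coords, vel, params,
                  config.relax_steps, config.dt_ps / 5, 10.0,
                  config.temperature, int(seeds[2]), config.charge_mode,
                  config.neighbor_skin)
        topology.box = box
        coords = np.mod(coords, cube)
        coords[:, 2] += 0.5 * (box[2] - cube[2])
    else:
        h = min(n / (config.slab_density * box[0] * box[1]), box[2])
        zc = 0.5 * box[2]
        coords = random_walk_coordinates(
            topology.n_chains, topology.chain_length, box, int(seeds[0]),
            r0=walk_r0, min_dist=0.8 * params.sigma,
            z_extent=(zc - h / 2, zc + h / 2))

    # short relaxation at reduced dt and high friction to remove any
    # residual close contacts from the constructed start
    vel = initialize_velocities(topology.masses, config.temperature,
                                int(seeds[1]))
    integrate(topology, coords, vel, params, config.relax_steps,
              config.dt_ps / 5, 10.0, config.temperature, int(seeds[2]),
              config.charge_mode, config.neighbor_skin)

    vel = initialize_velocities(topology.masses, config.temperature,
                                int(seeds[3]))
    equil_steps = int(round(config.equil_tau * TAU_PS / config.dt_ps))
    buffers = None
    if equil_steps:
        _, _, buffers = integrate(
            topology, coords, vel, params, equil_steps, config.dt_ps,
            config.friction, config.temperature, int(seeds[2]) ^ 0x5A5A,
            config.charge_mode, config.neighbor_skin)

    frames = np.empty((config.n_frames + 1, n, 3))
    frames[0] = coords
    times = np.arange(config.n_frames + 1) * config.frame_interval_tau
    for f in range(config.n_frames):
        _, _, buffers = integrate(
            topology, coords, vel, params, config.steps_per_frame,
            config.dt_ps, config.friction, config.temperature,
            int(seeds[4 + f] if 4 + f < len(seeds) else seeds[-1] + f),
            config.charge_mode, config.neighbor_skin, _buffers=buffers)
        frames[f + 1] = coords
    return TrajectorySeries(times_tau=times, coords=frames, box=box,
                            topology=topology)
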