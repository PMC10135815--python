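"""Deterministic generators with ground-truth sidecars.

Every generator used to exercise the analysis stack records, at
construction time and by construction (never by calling the code under
test), the quantities a downstream metric should reproduce: charge
censuses for sequences, crossing counts and |dz| sums for scripted
trajectories, window occupancies for slab configurations, and the exact
power-law parameters for binodal series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chain_models import ChainSpec, build_chain, topology_from_chain
from .critical_point import BinodalSeries
from .simulator import TrajectorySeries
from .units import NM_TO_ANGSTROM


def make_sequence(length: int, n_neg: int, n_pos: int, seed: int,
                  neg_pool: str = "DE", pos_pool: str = "KR",
                  fill: str = "G") -> str:
    """Random sequence with an exact charge census (n_neg D/E, n_pos K/R)."""
    if n_neg + n_pos > length:
        raise ValueError("more charged residues than positions")
    rng = np.random.default_rng(seed)
    letters = (
        [str(rng.choice(list(neg_pool))) for _ in range(n_neg)]
        + [str(rng.choice(list(pos_pool))) for _ in range(n_pos)]
        + [fill] * (length - n_neg - n_pos)
    )
    rng.shuffle(letters)
    return "".join(letters)


@dataclass
class ScriptedTrajectory:
    """A hand-scripted trajectory plus its ground truth.

    Chains are single beads moving along piecewise-linear z(t) paths, so
    the chain CM equals the bead position and every motion observable can
    be counted by hand.  ``truth`` holds, computed at construction:
    ``z_motion_rate`` (A/tau), ``crossings`` (total boundary crossings for
    the recorded boundary), ``flux_mean`` (chains/tau) and the bead-count
    density profile of the final frame.
    """

    traj: TrajectorySeries
    truth: dict = field(default_factory=dict)


def make_scripted_trajectory(z_paths_nm, dt_tau: float = 0.5,
                             box=(10.0, 10.0, 300.0),
                             z_boundary_nm: float = 25.0,
                             center_nm: float | None = None
                             ) -> ScriptedTrajectory:
    """Build a trajectory from explicit per-chain z series (nm, unwrapped).

    ``z_paths_nm`` has shape (F, C): frame f, chain c.  x and y are held
    at the box center.  The ground truth treats ``center_nm`` (default
    Lz/2) as the condensed-phase center for crossing counts.
    """
    z = np.asarray(z_paths_nm, dtype=float)
    f_count, c_count = z.shape
    box = np.asarray(box, dtype=float)
    zc = 0.5 * box[2] if center_nm is None else center_nm

    coords = np.zeros((f_count, c_count, 3))
    coords[:, :, 0] = 0.5 * box[0]
    coords[:, :, 1] = 0.5 * box[1]
    coords[:, :, 2] = z
    chain = build_chain(ChainSpec("G", 1.0))
    topo = topology_from_chain(chain, c_count, box)
    traj = TrajectorySeries(
        times_tau=np.arange(f_count) * dt_tau,
        coords=coords, box=box, topology=topo,
    )

    dz = np.abs(np.diff(z, axis=0)) * NM_TO_ANGSTROM
    rate = float(dz.sum() / (c_count * (f_count - 1) * dt_tau))
    rel = z - zc
    a, b = rel[:-1], rel[1:]
    crossings = int((((a - z_boundary_nm) * (b - z_boundary_nm) < 0)
                     | ((a + z_boundary_nm) * (b + z_boundary_nm) < 0)).sum())
    total_time = (f_count - 1) * dt_tau
    truth = {
        "z_motion_rate": rate,
        "crossings": crossings,
        "flux_mean": crossings / total_time if total_time else 0.0,
        "z_boundary_nm": z_boundary_nm,
        "center_nm": zc,
        "final_profile_counts": np.histogram(
            np.mod(z[-1], box[2]), bins=np.linspace(0, box[2], 31))[0],
    }
    return ScriptedTrajectory(traj=traj, truth=truth)


def make_slab_configuration(n_chains: int, chain_length: int,
                            slab_fraction: float, box, seed: int,
                            r0: float = 0.38):
    """Chains packed into the central z-fraction of the box.

    Returns ``(coords, record)``; the record stores the per-window bead
    counts of the constructed configuration (30 windows over Lz), computed
    directly with a histogram at construction.
    """
    if not 0.0 < slab_fraction <= 1.0:
        raise ValueError("slab_fraction must be in (0, 1]")
    from .chain_models import random_walk_coordinates

    box = np.asarray(box, dtype=float)
    lz = box[2]
    h = slab_fraction * lz
    # align the slab to the 30-window grid so a 1/30 slab fills exactly
    # one window
    w = lz / 30.0
    lo = np.round((lz - h) / 2.0 / w) * w
    z_extent = (None if slab_fraction >= 1.0
                else (lo, min(lo + h, lz) - 1e-9))
    coords = random_walk_coordinates(
        n_chains, chain_length, box, seed, r0=r0,
        min_dist=min(0.5, 0.8 * r0), z_extent=z_extent,
    )
    counts, _ = np.histogram(np.mod(coords[:, 2], lz),
                             bins=np.linspace(0, lz, 31))
    record = {
        "window_counts": counts,
        "occupied_windows": int((counts > 0).sum()),
        "slab_fraction": slab_fraction,
    }
    return coords, record


def make_binodal(amplitude: float, t_cr: float, beta: float, t_grid,
                 noise_sd: float = 0.0, seed: int = 0) -> BinodalSeries:
    """Binodal series from the critical power law, optionally with noise.

    Values are A (T_Cr - T)^beta for T < T_Cr and exactly 0 above, plus
    Gaussian noise of ``noise_sd``, clipped at 0.  Ground truth is stored
    on the returned series as ``.truth``.
    """
    t = np.asarray(t_grid, dtype=float)
    rng = np.random.default_rng(seed)
    clean = np.where(t < t_cr, amplitude * np.clip(t_cr - t, 0, None)**beta,
                     0.0)
    noisy = clean + (rng.normal(0.0, noise_sd, len(t)) if noise_sd else 0.0)
    series = BinodalSeries(temperatures=t, values=np.clip(noisy, 0.0, None))
    series.truth = {  # type: ignore[attr-defined]
        "amplitude": amplitude, "t_cr": t_cr, "beta": beta,
        "clean_values": clean,
    }
    return series
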