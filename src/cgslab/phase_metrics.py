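"""Phase-separation observables on slab trajectories.

The slab's z axis is cut into 30 windows; the occupancy fraction
P_gamma = m_gamma / N of beads per window defines the density profile,
and the spread P_H - P_L = max P_gamma - min P_gamma is the order
parameter for phase separation (near 0 for a homogeneous solution, large
when a dense slab coexists with a dilute phase).

Chain-level observables are computed after re-centering: the condensed
phase center z_c is the circular (periodic) mean of all bead z
coordinates, each chain's coordinate is the minimum-image displacement of
its center of mass from z_c, and |z| is binned into 30 windows spanning
[0, Lz/2].  The z motion rate is the mean absolute chain-CM z
displacement per unit time on the frame grid (reported in Angstrom/tau),
and the flux counts chain crossings of the two boundary planes at
|z - z_c| = z_boundary per unit time (chains/tau).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import NM_TO_ANGSTROM

N_DENSITY_WINDOWS = 30
N_ABSZ_WINDOWS = 30


@dataclass
class DensityProfile:
    edges: np.ndarray   # (n_windows + 1,) nm
    p: np.ndarray       # (n_windows,) occupancy fractions, sums to 1


@dataclass
class CenteredChainSeries:
    """Chain CM coordinates relative to the condensed-phase center.

    ``rel_z`` is the signed minimum-image displacement in nm, per frame and
    chain; ``abs_z`` its magnitude.  ``z_center`` records the per-frame
    circular center used.
    """

    times_tau: np.ndarray   # (F,)
    rel_z: np.ndarray       # (F, C) nm, in [-Lz/2, Lz/2)
    abs_z: np.ndarray       # (F, C) nm
    z_center: np.ndarray    # (F,)
    lz: float


def density_profile(z, lz: float, n_windows: int = N_DENSITY_WINDOWS
                    ) -> DensityProfile:
    """Occupancy-fraction profile of one frame's bead z coordinates.

    Windows are half-open [edge, next_edge) spanning [0, Lz) exactly;
    coordinates are wrapped first.
    """
    z = np.mod(np.asarray(z, dtype=float), lz)
    edges = np.linspace(0.0, lz, n_windows + 1)
    counts, _ = np.histogram(z, bins=edges)
    return DensityProfile(edges=edges, p=counts / len(z))


def density_profile_series(coords, lz: float,
                           n_windows: int = N_DENSITY_WINDOWS) -> np.ndarray:
    """Per-frame profiles, (F, n_windows), for (F, N, 3) coordinates."""
    out = np.empty((len(coords), n_windows))
    for f, frame in enumerate(coords):
        out[f] = density_profile(frame[:, 2], lz, n_windows).p
    return out


def ph_pl(profile):
    """(P_H, P_L, P_H - P_L) of a profile or of a time-averaged series.

    Accepts a DensityProfile, a 1-D occupancy vector, or a 2-D (frames x
    windows) array which is averaged over frames before taking max/min.
    """
    p = profile.p if isinstance(profile, DensityProfile) else np.asarray(profile)
    if p.ndim == 2:
        p = p.mean(axis=0)
    ph = float(p.max())
    pl = float(p.min())
    return ph, pl, ph - pl


def circular_center(z, lz: float) -> float:
    """Periodic (circular-mean) center of a set of z coordinates in [0, Lz)."""
    theta = 2.0 * np.pi * np.asarray(z) / lz
    mean = np.arctan2(np.sin(theta).mean(), np.cos(theta).mean())
    return float(np.mod(mean / (2.0 * np.pi) * lz, lz))


def center_condensed_phase(traj, mode: str = "frame") -> CenteredChainSeries:
    """Re-center chain CMs on the condensed phase.

    The center z_c is the circular mean of bead z coordinates (well
    defined under the periodic boundary even when the slab straddles the
    box edge); each chain's coordinate is the minimum-image displacement
    of its CM from z_c.  ``mode="frame"`` recomputes z_c per frame;
    ``mode="window"`` uses one center from all frames pooled -- a fixed
    boundary frame, which crossing-flux analysis needs (a per-frame
    center of a nearly homogeneous system fluctuates strongly and would
    inject spurious coherent crossings).
    """
    if mode not in ("frame", "window"):
        raise ValueError("mode must be 'frame' or 'window'")
    times = traj.times_tau
    lz = float(traj.box[2])
    cm_z = traj.chain_cm()[:, :, 2]
    bead_z = traj.coords[:, :, 2]
    f_count = len(times)
    rel = np.empty((f_count, cm_z.shape[1]))
    zc = np.empty(f_count)
    if mode == "window":
        zc[:] = circular_center(np.mod(bead_z, lz).ravel(), lz)
    for f in range(f_count):
        if mode == "frame":
            zc[f] = circular_center(np.mod(bead_z[f], lz), lz)
        d = np.mod(cm_z[f], lz) - zc[f]
        rel[f] = d - lz * np.rint(d / lz)
    return CenteredChainSeries(times_tau=np.asarray(times), rel_z=rel,
                               abs_z=np.abs(rel), z_center=zc, lz=lz)


def _grid_check(times, dt_tau):
    dt = np.diff(times)
    if len(dt) and not np.allclose(dt, dt_tau, rtol=1e-6, atol=1e-9):
        raise ValueError(
            f"frames are not on a uniform {dt_tau} tau grid"
        )


def z_motion_rate(cm_z, times, t0: float = 4000.0, t_end: float = 5000.0,
                  dt_tau: float = 0.5) -> float:
    """Mean |Delta z| of chain CMs per unit time, in Angstrom/tau.

    ``cm_z`` is the unwrapped chain-CM z series (F, C) in nm on a uniform
    ``dt_tau`` frame grid; only frames with t0 <= t <= t_end contribute.
    Equals sum_t sum_n |z_n(t+dt) - z_n(t)| / (C * K * dt) for K intervals.
    """
    times = np.asarray(times)
    sel = (times >= t0 - 1e-9) & (times <= t_end + 1e-9)
    t_sel = times[sel]
    if len(t_sel) < 2:
        raise ValueError("need at least two frames in the analysis window")
    _grid_check(t_sel, dt_tau)
    z = np.asarray(cm_z)[sel] * NM_TO_ANGSTROM
    dz = np.abs(np.diff(z, axis=0))
    n_intervals, n_chains = dz.shape
    return float(dz.sum() / (n_chains * n_intervals * dt_tau))


def flux(rel_z, times, z_boundary_nm: float = 25.0, dt_tau: float = 0.5,
         window: tuple | None = None):
    """Boundary-crossing flux of chains, in chains/tau.

    A chain contributes a crossing in interval (t, t+dt) when its
    re-centered signed z changes side of either boundary plane at
    +z_boundary or -z_boundary.  Returns (interval mid-times, per-interval
    flux N_t, mean over the analysis window).
    """
    times = np.asarray(times)
    _grid_check(times, dt_tau)
    z = np.asarray(rel_z)
    a, b = z[:-1], z[1:]
    cross_hi = (a - z_boundary_nm) * (b - z_boundary_nm) < 0
    cross_lo = (a + z_boundary_nm) * (b + z_boundary_nm) < 0
    crossings = (cross_hi | cross_lo).sum(axis=1)
    n_t = crossings / dt_tau
    mid = 0.5 * (times[:-1] + times[1:])
    if window is not None:
        sel = (mid >= window[0] - 1e-9) & (mid <= window[1] + 1e-9)
    else:
        sel = np.ones(len(mid), bool)
    mean = float(n_t[sel].mean()) if sel.any() else float("nan")
    return mid, n_t, mean


def flux_raw_printed(cm_z_angstrom, times, dt_tau: float = 0.5,
                     z_boundary_angstrom: float = 250.0,
                     box_z_angstrom: float = 3000.0,
                     center_angstrom: float = 2750.0):
    """Literal box-coordinate form of the flux rule, for comparison.

    Counts sign changes about the planes at center - z_boundary,
    center + z_boundary, and 0 (the far periodic image of the
    center + z_boundary plane in a 3000 A box with the center at 2750 A).
    Coordinates must be given continuously in that frame (center at
    2750 A, no re-wrapping between consecutive frames); under that
    convention the rule counts the same events as the two re-centered
    boundary planes of :func:`flux`.
    """
    z = np.asarray(cm_z_angstrom)
    a, b = z[:-1], z[1:]
    p1 = center_angstrom - z_boundary_angstrom
    p2 = center_angstrom + z_boundary_angstrom
    crossed = (((a - p1) * (b - p1) < 0)
               | ((a - p2) * (b - p2) < 0)
               | (a * b < 0)).sum(axis=1)
    return crossed / dt_tau


def absz_windows(lz: float, n_windows: int = N_ABSZ_WINDOWS) -> np.ndarray:
    """Window edges for |z|, spanning [0, Lz/2] (5 nm each at Lz = 300)."""
    return np.linspace(0.0, lz / 2.0, n_windows + 1)


def chain_probability_profile(series: CenteredChainSeries,
                              window: tuple | None = None,
                              n_windows: int = N_ABSZ_WINDOWS) -> np.ndarray:
    """Fraction of chain-frame observations per |z| window; sums to 1."""
    absz = series.abs_z
    if window is not None:
        sel = ((series.times_tau >= window[0] - 1e-9)
               & (series.times_tau <= window[1] + 1e-9))
        absz = absz[sel]
    edges = absz_windows(series.lz, n_windows)
    vals = np.clip(absz.ravel(), 0.0, series.lz / 2.0 - 1e-12)
    counts, _ = np.histogram(vals, bins=edges)
    return counts / counts.sum()


def phpl_over_window(traj, fraction: float = 0.2,
                     n_windows: int = N_DENSITY_WINDOWS):
    """(P_H, P_L, P_H - P_L) from the time-averaged profile over the run tail.

    The analysis window is the last ``fraction`` of the trajectory (the
    production convention of averaging the final fifth, e.g. the last
    1000 tau of a 5000 tau run).
    """
    t_end = traj.times_tau[-1]
    t0 = t_end * (1.0 - fraction)
    sel = traj.times_tau >= t0 - 1e-9
    profiles = density_profile_series(traj.coords[sel], float(traj.box[2]),
                                      n_windows)
    return ph_pl(profiles)
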