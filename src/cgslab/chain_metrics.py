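"""Per-chain conformation and electrostatic-contact observables.

The head-to-tail distance D is the distance between the first and last
non-insert beads of a chain (so glycine-inserted chains are compared on
the same underlying segment as their parents).  E_intra counts
opposite-charge bead pairs within the same chain closer than 12 A;
E_inter counts opposite-charge pairs across chains closer than 15 A,
attributed to both partner chains.  These contact metrics are meaningful
only for charge-bearing systems (the RGG segment) in the screened-salt
condition; a system without charges yields all zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phase_metrics import CenteredChainSeries, absz_windows
from .potentials import minimum_image
from .units import NM_TO_ANGSTROM


@dataclass(frozen=True)
class ContactParams:
    intra_cutoff_angstrom: float = 12.0
    inter_cutoff_angstrom: float = 15.0

    def __post_init__(self):
        if self.intra_cutoff_angstrom <= 0 or self.inter_cutoff_angstrom <= 0:
            raise ValueError("contact cutoffs must be positive")


def end_to_end(chain_coords: np.ndarray, box=None,
               is_insert: np.ndarray | None = None,
               exclude_inserts: bool = True) -> float:
    """Head-to-tail distance D of one chain, in Angstrom.

    With ``exclude_inserts`` the endpoints are the first and last beads
    whose insert flag is False; otherwise the literal termini.  Distance
    uses the minimum image when a box is given.
    """
    coords = np.asarray(chain_coords)
    if exclude_inserts and is_insert is not None and is_insert.any():
        keep = np.flatnonzero(~np.asarray(is_insert))
        if len(keep) == 0:
            raise ValueError("chain has no non-insert beads")
        i, j = keep[0], keep[-1]
    else:
        i, j = 0, len(coords) - 1
    d = coords[i] - coords[j]
    if box is not None:
        d = minimum_image(d, np.asarray(box, dtype=float))
    return float(np.linalg.norm(d)) * NM_TO_ANGSTROM


def end_to_end_series(traj, exclude_inserts: bool = True) -> np.ndarray:
    """D for every frame and chain, (F, C), in Angstrom (unwrapped coords)."""
    topo = traj.topology
    L = topo.chain_length
    ins = topo.is_insert[:L]
    if exclude_inserts and ins.any():
        keep = np.flatnonzero(~ins)
        i, j = keep[0], keep[-1]
    else:
        i, j = 0, L - 1
    shaped = traj.coords.reshape(traj.n_frames, topo.n_chains, L, 3)
    d = shaped[:, :, i, :] - shaped[:, :, j, :]
    return np.linalg.norm(d, axis=-1) * NM_TO_ANGSTROM


def electrostatic_contacts(coords: np.ndarray, topology,
                           params: ContactParams = ContactParams(),
                           box=None):
    """(E_intra, E_inter) per chain for one frame.

    E_intra: opposite-charge pairs (q_i q_j = -1) within one chain closer
    than the intra cutoff.  E_inter: opposite-charge pairs across chains
    closer than the inter cutoff, counted once per pair but credited to
    both chains.  Minimum-image distances.  Systems without any charged
    beads return zeros (with a notice).
    """
    box = np.asarray(topology.box if box is None else box, dtype=float)
    charged = np.flatnonzero(topology.charges != 0)
    e_intra = np.zeros(topology.n_chains)
    e_inter = np.zeros(topology.n_chains)
    if len(charged) == 0:
        warnings.warn("system has no charged beads; contact counts are zero",
                      stacklevel=2)
        return e_intra, e_inter
    q = topology.charges[charged]
    cid = topology.chain_id[charged]
    x = np.asarray(coords)[charged]
    ii, jj = np.triu_indices(len(charged), k=1)
    opp = q[ii] * q[jj] == -1
    ii, jj = ii[opp], jj[opp]
    d = minimum_image(x[ii] - x[jj], box)
    r = np.linalg.norm(d, axis=1) * NM_TO_ANGSTROM
    same = cid[ii] == cid[jj]
    hit_intra = same & (r < params.intra_cutoff_angstrom)
    hit_inter = ~same & (r < params.inter_cutoff_angstrom)
    np.add.at(e_intra, cid[ii[hit_intra]], 1.0)
    np.add.at(e_inter, cid[ii[hit_inter]], 1.0)
    np.add.at(e_inter, cid[jj[hit_inter]], 1.0)
    return e_intra, e_inter


def contacts_series(traj, params: ContactParams = ContactParams(),
                    window: tuple | None = None):
    """(E_intra, E_inter) arrays (F_sel, C) over trajectory frames."""
    sel = np.ones(traj.n_frames, bool)
    if window is not None:
        sel = ((traj.times_tau >= window[0] - 1e-9)
               & (traj.times_tau <= window[1] + 1e-9))
    frames = np.flatnonzero(sel)
    e_i = np.empty((len(frames), traj.topology.n_chains))
    e_e = np.empty_like(e_i)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, f in enumerate(frames):
            e_i[k], e_e[k] = electrostatic_contacts(
                traj.coords[f], traj.topology, params)
    return e_i, e_e


def profile_by_absz(values: np.ndarray, series: CenteredChainSeries,
                    max_absz_nm: float | None = 140.0,
                    n_windows: int = 30) -> pd.DataFrame:
    """Mean and standard error of a per-(frame, chain) quantity vs |z| window.

    ``values`` must align with ``series.abs_z``.  Windows whose center
    exceeds ``max_absz_nm`` are omitted (edge-of-box exclusion; default
    140 nm for the 300 nm production box -- scale down for smaller boxes).
    """
    edges = absz_windows(series.lz, n_windows)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(series.abs_z.ravel(), edges) - 1,
                  0, n_windows - 1)
    v = np.asarray(values).ravel()
    rows = []
    for w in range(n_windows):
        if max_absz_nm is not None and centers[w] > max_absz_nm:
            continue
        vw = v[idx == w]
        if len(vw) == 0:
            continue
        se = vw.std(ddof=1) / np.sqrt(len(vw)) if len(vw) > 1 else 0.0
        rows.append({"absz_nm": centers[w], "mean": vw.mean(),
                     "se": se, "n": len(vw)})
    return pd.DataFrame(rows)


def d_vs_absz(traj, series: CenteredChainSeries,
              window: tuple | None = None,
              max_absz_nm: float | None = 140.0,
              exclude_inserts: bool = True) -> pd.DataFrame:
    """Mean head-to-tail distance (A) with SE per |z| window."""
    d = end_to_end_series(traj, exclude_inserts)
    absz = series.abs_z
    if window is not None:
        sel = ((series.times_tau >= window[0] - 1e-9)
               & (series.times_tau <= window[1] + 1e-9))
        d = d[sel]
        sub = CenteredChainSeries(series.times_tau[sel], series.rel_z[sel],
                                  absz[sel], series.z_center[sel], series.lz)
    else:
        sub = series
    return profile_by_absz(d, sub, max_absz_nm)


def d_vs_temperature(results: dict[float, np.ndarray]) -> pd.DataFrame:
    """Aggregate {temperature: per-(frame, chain) D array} into mean +- SE."""
    rows = []
    for t, d in sorted(results.items()):
        d = np.asarray(d).ravel()
        rows.append({
            "temperature_T0": t, "mean_D_angstrom": d.mean(),
            "se": d.std(ddof=1) / np.sqrt(len(d)) if len(d) > 1 else 0.0,
            "n": len(d),
        })
    return pd.DataFrame(rows)
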