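"""Trajectory, topology and table readers/writers.

Trajectories round-trip through two formats: binary DCD (via mdtraj's raw
DCD layer, coordinates in Angstrom, float32 -- sub-1e-6 nm round-trip
precision only for coordinates up to ~15 nm) and a plain-text extended
XYZ with a ``Lattice=...`` box and ``time_tau=`` field per frame, written
at full double precision.  Topologies serialize to a documented JSON
schema; analysis tables are TSV via pandas.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .chain_models import SystemTopology
from .simulator import TrajectorySeries
from .units import NM_TO_ANGSTROM


class TrajectoryIOError(IOError):
    pass


def save_topology(topology: SystemTopology, path) -> None:
    Path(path).write_text(topology.to_json())


def load_topology(path) -> SystemTopology:
    return SystemTopology.from_json(Path(path).read_text())


def write_xyz(traj: TrajectorySeries, path) -> None:
    """Extended-XYZ writer: one block per frame, full precision."""
    topo = traj.topology
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{topo.n_beads}\n")
            bx, by, bz = (float(v) for v in traj.box)
            fh.write(
                f'Lattice="{bx!r} 0 0 0 {by!r} 0 0 0 {bz!r}" '
                f"time_tau={float(traj.times_tau[f])!r}\n"
            )
            for res, xyz in zip(topo.residues, traj.coords[f]):
                fh.write(f"{res} {float(xyz[0])!r} {float(xyz[1])!r} "
                         f"{float(xyz[2])!r}\n")


def read_xyz(path, topology: SystemTopology) -> TrajectorySeries:
    frames, times = [], []
    box = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i])
            header = lines[i + 1]
            lat = header.split('Lattice="')[1].split('"')[0].split()
            box = np.array([float(lat[0]), float(lat[4]), float(lat[8])])
            times.append(float(header.split("time_tau=")[1].split()[0]))
            block = lines[i + 2: i + 2 + n]
            coords = np.array(
                [[float(v) for v in ln.split()[1:4]] for ln in block])
            if len(coords) != n:
                raise IndexError
        except (ValueError, IndexError) as exc:
            raise TrajectoryIOError(
                f"malformed XYZ frame {frame_no} at line {i + 1}"
            ) from exc
        frames.append(coords)
        i += 2 + n
        frame_no += 1
    if not frames:
        raise TrajectoryIOError("no frames in XYZ file")
    return TrajectorySeries(times_tau=np.array(times),
                            coords=np.array(frames), box=box,
                            topology=topology)


def write_dcd(traj: TrajectorySeries, path) -> None:
    """DCD writer (Angstrom, float32) via mdtraj's raw DCD interface."""
    from mdtraj.formats import DCDTrajectoryFile

    n = traj.n_frames
    cell = np.tile(traj.box * NM_TO_ANGSTROM, (n, 1)).astype(np.float32)
    angles = np.full((n, 3), 90.0, dtype=np.float32)
    with DCDTrajectoryFile(str(path), "w") as fh:
        fh.write((traj.coords * NM_TO_ANGSTROM).astype(np.float32),
                 cell_lengths=cell, cell_angles=angles)


def read_dcd(path, topology: SystemTopology,
             frame_interval_tau: float = 0.5) -> TrajectorySeries:
    """Read a DCD written by :func:`write_dcd` (or GROMACS-converted).

    DCD stores no time axis; frame times are reconstructed from
    ``frame_interval_tau``.  A truncated file is reported with the index
    of the last complete frame.
    """
    from mdtraj.formats import DCDTrajectoryFile

    try:
        with DCDTrajectoryFile(str(path)) as fh:
            xyz, cell_lengths, _ = fh.read()
    except Exception as exc:
        raise TrajectoryIOError(f"unreadable DCD file {path}: {exc}") from exc
    if xyz is None or len(xyz) == 0:
        raise TrajectoryIOError(f"no complete frames in {path}")
    coords = xyz.astype(np.float64) / NM_TO_ANGSTROM
    if coords.shape[1] != topology.n_beads:
        raise TrajectoryIOError(
            f"frame has {coords.shape[1]} beads, topology expects "
            f"{topology.n_beads} (last good frame {len(coords) - 1})"
        )
    box = (cell_lengths[0].astype(np.float64) / NM_TO_ANGSTROM
           if cell_lengths is not None else topology.box)
    return TrajectorySeries(
        times_tau=np.arange(len(coords)) * frame_interval_tau,
        coords=coords, box=np.asarray(box), topology=topology)


def write_chain_cm_tsv(traj: TrajectorySeries, path) -> None:
    """Chain center-of-mass time series as TSV (time_tau, chain, x, y, z)."""
    import pandas as pd

    cm = traj.chain_cm()
    f_idx, c_idx = np.meshgrid(range(traj.n_frames), range(cm.shape[1]),
                               indexing="ij")
    pd.DataFrame({
        "time_tau": traj.times_tau[f_idx.ravel()],
        "chain": c_idx.ravel(),
        "x_nm": cm[:, :, 0].ravel(),
        "y_nm": cm[:, :, 1].ravel(),
        "z_nm": cm[:, :, 2].ravel(),
    }).to_csv(path, sep="\t", index=False)


def write_table(df, path) -> None:
    df.to_csv(path, sep="\t", index=False)
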