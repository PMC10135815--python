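"""Bead-per-residue chain construction for FUS-segment models.

Each residue is a single bead at its C-alpha position.  Three families of
chain models are supported:

* normal chains -- every bead carries the same mass ``mass_scale`` (the
  isotope surrogate: 1.0 for unlabeled, 1.1-1.5 for labeled protein);
* glycine-inserted chains -- 10 extra non-interacting glycine beads are
  appended to the tail (``tail10``) or split 5/5 between head and tail
  (``head5tail5``); inserted beads always carry mass 1.0, so a 60-bead
  insertion chain has the same total mass (60 m0) as a 50-bead mass-1.2
  chain;
* arbitrary custom sequences for scaled-down studies.

Charges follow the minimal IDP rule: D/E -> -1 e, K/R -> +1 e, all other
residues neutral.  The packaged PLD fragment (FUS 1-50) carries 2 negative
and 0 positive charges; the packaged RGG-style fragment carries 6 negative
and 9 positive charges over 50 residues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
NEGATIVE_AA = set("DE")
POSITIVE_AA = set("KR")

INSERTION_MODES = ("none", "tail10", "head5tail5")

#: default random-walk bond length, nm (the equilibrium bond length r0)
DEFAULT_BOND_LENGTH = 0.38

#: minimum inter-chain bead-bead distance enforced at placement, nm
MIN_PLACEMENT_DIST = 0.5


class SequenceError(ValueError):
    """Raised for residues outside the 20 standard one-letter codes."""


class PlacementError(RuntimeError):
    """Raised when random chain placement cannot satisfy the clash criterion."""


@dataclass(frozen=True)
class ChainSpec:
    """A chain model: sequence plus mass scale and glycine-insertion mode."""

    sequence: str
    mass_scale: float = 1.0
    insertion_mode: str = "none"

    def __post_init__(self):
        if self.insertion_mode not in INSERTION_MODES:
            raise ValueError(
                f"insertion_mode must be one of {INSERTION_MODES}, "
                f"got {self.insertion_mode!r}"
            )
        if self.mass_scale <= 0:
            raise ValueError("mass_scale must be positive")


@dataclass(frozen=True)
class BeadRecord:
    residue: str
    mass: float
    charge: int
    is_insert: bool
    chain_id: int
    index_in_chain: int


@dataclass
class SystemTopology:
    """Beads, bonds and box for a system of identical linear chains.

    Bead attributes are stored as flat arrays ordered chain-by-chain; bonds
    are the (i, i+1) pairs within each chain, never spanning chains.
    """

    residues: np.ndarray        # (N,) unicode length-1
    masses: np.ndarray          # (N,) float, m0 units
    charges: np.ndarray         # (N,) int, e units
    is_insert: np.ndarray       # (N,) bool
    chain_id: np.ndarray        # (N,) int
    index_in_chain: np.ndarray  # (N,) int
    bonds: np.ndarray           # (M, 2) int
    n_chains: int
    box: np.ndarray = field(default_factory=lambda: np.zeros(3))  # (3,) nm

    @property
    def n_beads(self) -> int:
        return len(self.masses)

    @property
    def chain_length(self) -> int:
        return self.n_beads // self.n_chains

    def chain_slice(self, c: int) -> slice:
        L = self.chain_length
        return slice(c * L, (c + 1) * L)

    def to_json(self) -> str:
        return json.dumps(
            {
                "residues": "".join(self.residues.tolist()),
                "masses": self.masses.tolist(),
                "charges": self.charges.tolist(),
                "is_insert": self.is_insert.astype(int).tolist(),
                "chain_id": self.chain_id.tolist(),
                "index_in_chain": self.index_in_chain.tolist(),
                "bonds": self.bonds.tolist(),
                "n_chains": self.n_chains,
                "box": self.box.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SystemTopology":
        d = json.loads(text)
        n = len(d["masses"])
        bonds = np.asarray(d["bonds"], dtype=np.int64).reshape(-1, 2)
        if bonds.size and (bonds.min() < 0 or bonds.max() >= n):
            raise ValueError("topology JSON contains a dangling bond index")
        return cls(
            residues=np.array(list(d["residues"])),
            masses=np.asarray(d["masses"], dtype=float),
            charges=np.asarray(d["charges"], dtype=np.int64),
            is_insert=np.asarray(d["is_insert"], dtype=bool),
            chain_id=np.asarray(d["chain_id"], dtype=np.int64),
            index_in_chain=np.asarray(d["index_in_chain"], dtype=np.int64),
            bonds=bonds,
            n_chains=int(d["n_chains"]),
            box=np.asarray(d["box"], dtype=float),
        )


def assign_charges(sequence: str) -> np.ndarray:
    """Per-residue charge vector in elementary-charge units.

    D and E map to -1, K and R to +1, every other standard residue to 0.
    A non-standard letter raises :class:`SequenceError` naming its position.
    """
    charges = np.zeros(len(sequence), dtype=np.int64)
    for i, aa in enumerate(sequence):
        if aa not in STANDARD_AA:
            raise SequenceError(
                f"unknown residue {aa!r} at position {i} (0-based)"
            )
        if aa in NEGATIVE_AA:
            charges[i] = -1
        elif aa in POSITIVE_AA:
            charges[i] = 1
    return charges


def apply_insertion(sequence: str, mode: str) -> tuple[str, np.ndarray]:
    """Return the post-insertion sequence and a boolean insert-flag vector."""
    if mode == "none":
        return sequence, np.zeros(len(sequence), dtype=bool)
    if mode == "tail10":
        flags = np.r_[np.zeros(len(sequence), bool), np.ones(10, bool)]
        return sequence + "G" * 10, flags
    if mode == "head5tail5":
        flags = np.r_[np.ones(5, bool), np.zeros(len(sequence), bool),
                      np.ones(5, bool)]
        return "G" * 5 + sequence + "G" * 5, flags
    raise ValueError(f"unknown insertion mode {mode!r}")


def build_chain(spec: ChainSpec) -> list[BeadRecord]:
    """Expand a :class:`ChainSpec` into an ordered list of bead records.

    Non-insert beads carry mass ``mass_scale``; inserted glycines always
    carry mass 1.0 (so total chain mass of a tail10/head5tail5 chain at
    mass_scale 1.0 equals that of a plain mass-1.2 chain).
    """
    seq, flags = apply_insertion(spec.sequence, spec.insertion_mode)
    charges = assign_charges(seq)
    beads = []
    for i, (aa, q, ins) in enumerate(zip(seq, charges, flags)):
        beads.append(
            BeadRecord(
                residue=aa,
                mass=1.0 if ins else spec.mass_scale,
                charge=int(q),
                is_insert=bool(ins),
                chain_id=0,
                index_in_chain=i,
            )
        )
    return beads


def topology_from_chain(
    chain: Sequence[BeadRecord], n_chains: int, box
) -> SystemTopology:
    """Replicate one chain's bead records into an N-chain topology."""
    L = len(chain)
    res = np.tile(np.array([b.residue for b in chain]), n_chains)
    masses = np.tile(np.array([b.mass for b in chain]), n_chains)
    charges = np.tile(np.array([b.charge for b in chain], dtype=np.int64),
                      n_chains)
    is_ins = np.tile(np.array([b.is_insert for b in chain]), n_chains)
    chain_id = np.repeat(np.arange(n_chains), L)
    idx = np.tile(np.arange(L), n_chains)
    intra = np.column_stack([np.arange(L - 1), np.arange(1, L)])
    bonds = np.concatenate([intra + c * L for c in range(n_chains)])
    return SystemTopology(
        residues=res, masses=masses, charges=charges, is_insert=is_ins,
        chain_id=chain_id, index_in_chain=idx, bonds=bonds,
        n_chains=n_chains, box=np.asarray(box, dtype=float),
    )


def _random_walk(rng, length: int, r0: float, start: np.ndarray) -> np.ndarray:
    """Freely-jointed random walk with fixed bond length r0."""
    steps = rng.normal(size=(length - 1, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    return start + np.vstack([np.zeros(3), np.cumsum(steps * r0, axis=0)])


def _reflect(z, lo, hi):
    span = hi - lo
    zz = np.mod(z - lo, 2 * span)
    return lo + np.where(zz < span, zz, 2 * span - zz)


def random_walk_coordinates(
    n_chains: int,
    chain_length: int,
    box,
    seed: int,
    r0: float = DEFAULT_BOND_LENGTH,
    min_dist: float = MIN_PLACEMENT_DIST,
    z_extent: tuple[float, float] | None = None,
    max_chain_retries: int = 200,
) -> np.ndarray:
    """Place n_chains random-walk chains without inter-chain clashes.

    Chains are grown as freely-jointed walks of bond length ``r0``; a chain
    is rejected and regrown whenever any of its beads comes within
    ``min_dist`` of a bead of an already-placed chain (periodic minimum
    image).  ``z_extent`` optionally confines the walk's z coordinates to a
    sub-interval of the box by reflection, which is how dense starting
    slabs are built.  Deterministic under ``seed``.
    """
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    placed: list[np.ndarray] = []
    tree = None
    step_retries = 40

    def clashes(points) -> bool:
        if tree is None:
            return False
        hits = tree.query_ball_point(np.mod(points, box), r=min_dist)
        if points.ndim == 1:
            return bool(len(hits))
        return any(len(h) for h in hits)

    intra_min = min(min_dist, 0.9 * r0)

    def self_clash(coords, b, cand) -> bool:
        if b < 2:
            return False
        d = cand - coords[: b - 1]
        d -= box * np.rint(d / box)
        return bool(((d * d).sum(axis=1) < intra_min**2).any())

    for c in range(n_chains):
        for attempt in range(max_chain_retries):
            start = rng.uniform(0.0, 1.0, 3) * box
            if z_extent is not None:
                start[2] = rng.uniform(z_extent[0], z_extent[1])
            if clashes(start):
                continue
            coords = np.empty((chain_length, 3))
            coords[0] = start
            ok = True
            for b in range(1, chain_length):
                for _ in range(step_retries):
                    step = rng.normal(size=3)
                    cand = coords[b - 1] + step / np.linalg.norm(step) * r0
                    if z_extent is not None:
                        cand[2] = _reflect(cand[2], *z_extent)
                    if not clashes(cand) and not self_clash(coords, b, cand):
                        coords[b] = cand
                        break
                else:
                    ok = False
                    break
            if not ok:
                continue
            placed.append(coords)
            tree = cKDTree(np.mod(np.vstack(placed), box), boxsize=box)
            break
        else:
            density = sum(len(p) for p in placed) / np.prod(box)
            raise PlacementError(
                f"could not place chain {c} after {max_chain_retries} "
                f"retries at bead density {density:.3f} nm^-3"
            )
    return np.vstack(placed)


def replicate_system(
    chain: Sequence[BeadRecord],
    n_chains: int,
    box,
    seed: int,
    r0: float = DEFAULT_BOND_LENGTH,
    min_dist: float = MIN_PLACEMENT_DIST,
    z_extent: tuple[float, float] | None = None,
) -> tuple[SystemTopology, np.ndarray]:
    """Build an N-chain topology plus clash-free random initial coordinates.

    Returns ``(topology, coords)`` with coordinates in nm, unwrapped (chain
    connectivity is preserved across the periodic boundary; wrap with
    ``np.mod(coords, box)`` when a wrapped view is needed).
    """
    topo = topology_from_chain(chain, n_chains, box)
    coords = random_walk_coordinates(
        n_chains, len(chain), box, seed, r0=r0, min_dist=min_dist,
        z_extent=z_extent,
    )
    return topo, coords


def load_fasta(path_or_handle) -> dict[str, str]:
    """Read a FASTA file into an {id: sequence} dict (Biopython parser)."""
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq) for rec in SeqIO.parse(path_or_handle, "fasta")
    }


def load_segment(name: str) -> str:
    """Load a packaged FUS segment sequence by name ('PLD' or 'RGG').

    PLD is FUS residues 1-50.  RGG is a synthetic RGG-style stand-in with
    the same charge composition as FUS 453-502 (6 negative, 9 positive
    charges over 50 residues); the fixture file is editable so a verified
    UniProt subsequence can be dropped in without code changes.
    """
    files = {"PLD": "fus_pld.fasta", "RGG": "fus_rgg_synthetic.fasta"}
    try:
        fname = files[name.upper()]
    except KeyError:
        raise KeyError(f"unknown segment {name!r}; choose from {list(files)}")
    ref = resources.files("cgslab.data").joinpath(fname)
    with ref.open() as fh:
        seqs = load_fasta(fh)
    return next(iter(seqs.values()))
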