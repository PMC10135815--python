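"""Potential energy terms and force evaluation under periodic boundaries.

The model energy is a sum of three terms:

* harmonic bonds        U_b(r)  = Kb (r - r0)^2
* Lennard-Jones         U_LJ(r) = eps [ (sigma/r)^12 - (sigma/r)^6 ]
* Debye-Hueckel         U_DH(r) = K_coulomb B(kappa) q_i q_j exp(-kappa r) / (eps_r r)

The LJ term is written here exactly as the model defines it, i.e. WITHOUT
the conventional prefactor 4 (well depth eps/4 at r = 2^(1/6) sigma); the
textbook convention is available through ``lj_prefactor_mode =
"standard_4eps"``.  Any pair involving at least one inserted (glycine)
bead interacts with ``eps_insert`` instead of ``eps``, which is how the
insertion is made non-interacting.

Nonbonded terms are truncated and energy-shifted to zero at their cutoffs.
Directly bonded (1-2) pairs are excluded from the nonbonded sums; 1-3 and
more distant pairs are included.  All pair distances use the minimum-image
convention for an orthorhombic box.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

OVERLAP_FLOOR = 1e-6  # nm; below this two beads are considered overlapping

CHARGE_MODES = ("no_charge", "salt_10mM")


class OverlapError(FloatingPointError):
    """Two beads closer than the hard overlap floor."""


@dataclass(frozen=True)
class ForceFieldParams:
    """All force-field constants.

    Units: Kb kJ nm^-2 mol^-1; r0, sigma, cutoffs nm; eps, eps_insert
    kJ/mol; k_coulomb kJ mol^-1 nm e^-2; kappa nm^-1; b_kappa and
    dielectric dimensionless.
    """

    kb: float = 20000.0
    r0: float = 0.38
    sigma: float = 1.0
    eps: float = 0.001
    eps_insert: float = 0.00001
    dielectric: float = 80.0
    k_coulomb: float = 138.94
    kappa: float = 0.0
    b_kappa: float = 1.0
    r_cut_lj: float = 3.0
    r_cut_dh: float = 3.5
    lj_prefactor_mode: str = "as_printed"

    def __post_init__(self):
        if self.lj_prefactor_mode not in ("as_printed", "standard_4eps"):
            raise ValueError(
                "lj_prefactor_mode must be 'as_printed' or 'standard_4eps'"
            )
        for name in ("kb", "r0", "sigma", "dielectric", "k_coulomb",
                     "b_kappa", "r_cut_lj", "r_cut_dh"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if self.eps_insert > self.eps:
            raise ValueError("eps_insert must not exceed eps")

    @property
    def lj_prefactor(self) -> float:
        return 4.0 if self.lj_prefactor_mode == "standard_4eps" else 1.0

    def with_salt(self, c_salt: float) -> "ForceFieldParams":
        """Copy of the parameters with kappa set from a salt concentration."""
        return replace(self, kappa=kappa_from_salt(c_salt))


def kappa_from_salt(c_salt: float) -> float:
    """Inverse Debye length, kappa ~= 3.2 sqrt(C_salt) nm^-1 (C_salt in M)."""
    if c_salt < 0:
        raise ValueError("salt concentration must be non-negative")
    return 3.2 * np.sqrt(c_salt)


def bond_energy_force(r: float, params: ForceFieldParams):
    """Harmonic bond energy and scalar force magnitude -dU/dr at distance r."""
    dr = r - params.r0
    return params.kb * dr * dr, -2.0 * params.kb * dr


def lj_energy_force(r, pair_eps: float, params: ForceFieldParams,
                    shifted: bool = True):
    """Lennard-Jones energy and force -dU/dr for one pair.

    ``pair_eps`` is eps or eps_insert depending on the pair's insert flags.
    With ``shifted`` the energy is shifted to zero at r_cut_lj and both
    energy and force vanish beyond the cutoff.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < OVERLAP_FLOOR):
        raise OverlapError(f"bead pair at r < {OVERLAP_FLOOR} nm")
    pref = pair_eps * params.lj_prefactor
    s6 = (params.sigma / r) ** 6
    u = pref * (s6 * s6 - s6)
    f = pref * (12.0 * s6 * s6 - 6.0 * s6) / r
    if shifted:
        sc6 = (params.sigma / params.r_cut_lj) ** 6
        u = u - pref * (sc6 * sc6 - sc6)
        cut = r >= params.r_cut_lj
        u = np.where(cut, 0.0, u)
        f = np.where(cut, 0.0, f)
    return u, f


def dh_energy_force(r, qi, qj, params: ForceFieldParams,
                    shifted: bool = True):
    """Debye-Hueckel energy and force -dU/dr for one charged pair."""
    r = np.asarray(r, dtype=float)
    qq = np.asarray(qi, dtype=float) * np.asarray(qj, dtype=float)
    if np.all(qq == 0):
        return np.zeros_like(r), np.zeros_like(r)
    if np.any(r < OVERLAP_FLOOR):
        raise OverlapError(f"bead pair at r < {OVERLAP_FLOOR} nm")
    c = params.k_coulomb * params.b_kappa / params.dielectric
    u = c * qq * np.exp(-params.kappa * r) / r
    f = u * (params.kappa + 1.0 / r)
    if shifted:
        rc = params.r_cut_dh
        u = u - c * qq * np.exp(-params.kappa * rc) / rc
        cut = r >= params.r_cut_dh
        u = np.where(cut, 0.0, u)
        f = np.where(cut, 0.0, f)
    return u, f


def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.rint(d / box)


class NeighborList:
    """Verlet pair list with a skin, built with a periodic k-d tree.

    Contains every non-bonded (1-2-excluded) pair within
    ``max(r_cut_lj, r_cut_dh) + skin``; rebuild is needed once any bead has
    moved more than skin/2 since the list was built.
    """

    def __init__(self, topology, coords, params: ForceFieldParams,
                 skin: float = 0.4):
        self.skin = float(skin)
        self.r_list = max(params.r_cut_lj, params.r_cut_dh) + self.skin
        self._bonded = set(map(tuple, np.sort(topology.bonds, axis=1)))
        self._topology = topology
        self.build(coords)

    def build(self, coords: np.ndarray) -> None:
        box = self._topology.box
        wrapped = np.mod(coords, box)
        if np.all(box > 2.0 * self.r_list):
            tree = cKDTree(wrapped, boxsize=box)
            raw = tree.query_pairs(self.r_list, output_type="ndarray")
        else:  # box too small for the tree's wrap assumption: O(N^2)
            n = len(wrapped)
            ii, jj = np.triu_indices(n, k=1)
            d = minimum_image(wrapped[ii] - wrapped[jj], box)
            keep = (d * d).sum(axis=1) < self.r_list**2
            raw = np.column_stack([ii[keep], jj[keep]])
        raw = np.sort(raw, axis=1)
        keep = np.array(
            [tuple(p) not in self._bonded for p in raw], dtype=bool
        ) if len(raw) else np.zeros(0, bool)
        self.pairs = raw[keep] if len(raw) else raw.reshape(0, 2)
        self._ref = coords.copy()

    def needs_rebuild(self, coords: np.ndarray) -> bool:
        disp2 = ((coords - self._ref) ** 2).sum(axis=1).max() if len(coords) else 0.0
        return disp2 > (0.5 * self.skin) ** 2

    def ensure_current(self, coords: np.ndarray) -> None:
        if self.needs_rebuild(coords):
            self.build(coords)


def total_energy_forces(
    topology,
    coords: np.ndarray,
    params: ForceFieldParams,
    neighbor_list: NeighborList | None = None,
    charge_mode: str = "salt_10mM",
):
    """Total potential energy and per-bead forces.

    Bonds plus neighbor-listed LJ and (unless ``charge_mode ==
    'no_charge'``) Debye-Hueckel terms, minimum-image convention
    throughout.  A stale neighbor list is rebuilt automatically before
    evaluation.  Returns ``(energy, forces)`` with forces in kJ mol^-1
    nm^-1.
    """
    if charge_mode not in CHARGE_MODES:
        raise ValueError(f"charge_mode must be one of {CHARGE_MODES}")
    box = topology.box
    n = len(coords)
    forces = np.zeros_like(coords)
    energy = 0.0

    # bonds
    if len(topology.bonds):
        bi, bj = topology.bonds[:, 0], topology.bonds[:, 1]
        d = minimum_image(coords[bi] - coords[bj], box)
        r = np.linalg.norm(d, axis=1)
        u, f = bond_energy_force(r, params)
        energy += u.sum()
        fv = (f / r)[:, None] * d
        np.add.at(forces, bi, fv)
        np.add.at(forces, bj, -fv)

    if neighbor_list is None:
        neighbor_list = NeighborList(topology, coords, params)
    else:
        neighbor_list.ensure_current(coords)
    pairs = neighbor_list.pairs
    if len(pairs):
        pi, pj = pairs[:, 0], pairs[:, 1]
        d = minimum_image(coords[pi] - coords[pj], box)
        r = np.linalg.norm(d, axis=1)
        if np.any(r < OVERLAP_FLOOR):
            raise OverlapError("overlapping beads in nonbonded evaluation")
        pair_eps = np.where(
            topology.is_insert[pi] | topology.is_insert[pj],
            params.eps_insert, params.eps,
        )
        u, f = lj_energy_force(r, pair_eps, params)
        energy += u.sum()
        fv = (f / r)[:, None] * d
        np.add.at(forces, pi, fv)
        np.add.at(forces, pj, -fv)
        if charge_mode != "no_charge":
            qq = topology.charges[pi] * topology.charges[pj]
            sel = qq != 0
            if np.any(sel):
                u, f = dh_energy_force(
                    r[sel], topology.charges[pi][sel],
                    topology.charges[pj][sel], params,
                )
                energy += u.sum()
                fv = (f / r[sel])[:, None] * d[sel]
                np.add.at(forces, pi[sel], fv)
                np.add.at(forces, pj[sel], -fv)
    return energy, forces


def numerical_gradient_check(
    topology, coords, params, charge_mode="salt_10mM", h: float = 1e-6,
    rng=None, n_probe: int = 30,
):
    """Max relative deviation between analytic forces and -dE/dx.

    Central differences on ``n_probe`` randomly chosen coordinates
    (normalised by the RMS force); used by the `check-forces` CLI and the
    force-correctness tests.
    """
    rng = np.random.default_rng(rng)
    nlist = NeighborList(topology, coords, params)
    _, forces = total_energy_forces(topology, coords, params, nlist,
                                    charge_mode)
    scale = np.sqrt((forces**2).mean()) or 1.0
    flat = coords.reshape(-1)
    idx = rng.choice(flat.size, size=min(n_probe, flat.size), replace=False)
    worst = 0.0
    for k in idx:
        x = flat.copy()
        x[k] += h
        ep, _ = total_energy_forces(
            topology, x.reshape(coords.shape), params, None, charge_mode)
        x[k] -= 2 * h
        em, _ = total_energy_forces(
            topology, x.reshape(coords.shape), params, None, charge_mode)
        f_num = -(ep - em) / (2 * h)
        worst = max(worst, abs(f_num - forces.reshape(-1)[k]) / scale)
    return worst
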