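import numpy as np
import pytest

from cgslab import ChainSpec, build_chain, replicate_system, topology_from_chain
from cgslab.potentials import ForceFieldParams
from cgslab.synthetic_data import make_sequence


@pytest.fixture(scope="session")
def small_charged_system():
    """30-bead, 3-chain charged system with random clash-free coordinates."""
    seq = make_sequence(10, 2, 2, seed=11)
    chain = build_chain(ChainSpec(seq, 1.0))
    topo, coords = replicate_system(chain, 3, (6.0, 6.0, 6.0), seed=5)
    return topo, coords


@pytest.fixture(scope="session")
def medium_system():
    """500-bead neutral+charged mixed system for neighbor-list checks."""
    seq = make_sequence(20, 3, 4, seed=3)
    chain = build_chain(ChainSpec(seq, 1.2))
    topo, coords = replicate_system(chain, 25, (9.0, 9.0, 9.0), seed=7)
    return topo, coords


@pytest.fixture(scope="session")
def production_params():
    return ForceFieldParams(kappa=0.32)


def brute_force_energy_forces(topology, coords, params, charge_mode):
    """O(N^2) double-loop oracle for energies and forces.

    Independent of the package's neighbor-listed path: plain python loops
    over all pairs, minimum image applied per pair, 1-2 bonded exclusion,
    energy-shifted cutoffs.
    """
    box = topology.box
    n = len(coords)
    bonded = {tuple(sorted(b)) for b in topology.bonds.tolist()}
    f = np.zeros_like(coords)
    e = 0.0
    for (i, j) in bonded:
        d = coords[i] - coords[j]
        d = d - box * np.round(d / box)
        r = np.sqrt((d * d).sum())
        e += params.kb * (r - params.r0) ** 2
        fs = -2.0 * params.kb * (r - params.r0) / r
        f[i] += fs * d
        f[j] -= fs * d
    pref = params.lj_prefactor
    sc6 = (params.sigma / params.r_cut_lj) ** 6
    lj_shift = pref * (sc6 * sc6 - sc6)
    for i in range(n - 1):
        for j in range(i + 1, n):
            if (i, j) in bonded:
                continue
            d = coords[i] - coords[j]
            d = d - box * np.round(d / box)
            r = np.sqrt((d * d).sum())
            peps = (params.eps_insert
                    if topology.is_insert[i] or topology.is_insert[j]
                    else params.eps)
            if r < params.r_cut_lj:
                s6 = (params.sigma / r) ** 6
                e += peps * pref * (s6 * s6 - s6) - peps * lj_shift
                fs = peps * pref * (12 * s6 * s6 - 6 * s6) / (r * r)
                f[i] += fs * d
                f[j] -= fs * d
            qq = topology.charges[i] * topology.charges[j]
            if charge_mode != "no_charge" and qq != 0 \
                    and r < params.r_cut_dh:
                c = params.k_coulomb * params.b_kappa / params.dielectric
                u = c * qq * np.exp(-params.kappa * r) / r
                u_cut = c * qq * np.exp(
                    -params.kappa * params.r_cut_dh) / params.r_cut_dh
                e += u - u_cut
                fs = u * (params.kappa + 1.0 / r) / r
                f[i] += fs * d
                f[j] -= fs * d
    return e, f
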