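"""Numba kernels for the Langevin integrator hot loop.

Everything here operates on plain arrays; the public API lives in
:mod:`cgslab.simulator` and :mod:`cgslab.potentials`.  Positions handed to
these kernels are unwrapped; the minimum-image convention (general form,
valid for arbitrarily distant images, implemented as floor(d/L + 1/2) with
a precomputed reciprocal box) is applied to every pair distance, and a
wrapped copy is made only when the cell list is rebuilt.

The integrator is BAOAB splitting: half kick (B), half drift (A), full
Ornstein-Uhlenbeck velocity update (O), half drift (A), force recompute,
half kick (B).  Friction gamma = 0 reduces it to velocity Verlet, which is
used by the energy-conservation checks.
"""

import math

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_PAIR_OVERFLOW = 1
STATUS_NOT_FINITE = 2

_EMPTY = np.zeros(0)


@njit(cache=True, fastmath=True)
def build_pairs(wrapped, box, r_list, excl, pairs):
    """Fill ``pairs`` with all non-excluded pairs within r_list.

    Returns the pair count (may exceed ``pairs`` capacity, in which case
    the caller must grow the buffer and retry).  Uses a cell list when the
    box accommodates at least 3 cells per dimension, otherwise an O(N^2)
    double loop.
    """
    n = wrapped.shape[0]
    cap = pairs.shape[0]
    r2max = r_list * r_list
    lx, ly, lz = box[0], box[1], box[2]
    ix, iy, iz = 1.0 / lx, 1.0 / ly, 1.0 / lz
    ncx = int(lx / r_list)
    ncy = int(ly / r_list)
    ncz = int(lz / r_list)
    m = 0
    if ncx < 3 or ncy < 3 or ncz < 3:
        for i in range(n - 1):
            e0 = excl[i, 0]
            e1 = excl[i, 1]
            xi, yi, zi = wrapped[i, 0], wrapped[i, 1], wrapped[i, 2]
            for j in range(i + 1, n):
                if j == e0 or j == e1:
                    continue
                dx = xi - wrapped[j, 0]
                dx -= lx * math.floor(dx * ix + 0.5)
                dy = yi - wrapped[j, 1]
                dy -= ly * math.floor(dy * iy + 0.5)
                dz = zi - wrapped[j, 2]
                dz -= lz * math.floor(dz * iz + 0.5)
                if dx * dx + dy * dy + dz * dz < r2max:
                    if m < cap:
                        pairs[m, 0] = i
                        pairs[m, 1] = j
                    m += 1
        return m

    ncell = ncx * ncy * ncz
    head = np.full(ncell, -1, np.int64)
    nxt = np.empty(n, np.int64)
    for i in range(n):
        # clamp both sides: protects indexing even for non-finite inputs
        # (the integrator reports those via its own finite check)
        cx = min(max(int(wrapped[i, 0] * ix * ncx), 0), ncx - 1)
        cy = min(max(int(wrapped[i, 1] * iy * ncy), 0), ncy - 1)
        cz = min(max(int(wrapped[i, 2] * iz * ncz), 0), ncz - 1)
        c = (cx * ncy + cy) * ncz + cz
        nxt[i] = head[c]
        head[c] = i

    # half neighbor stencil: self cell + 13 neighbor cells
    offs = np.array(
        [[0, 0, 1], [0, 1, -1], [0, 1, 0], [0, 1, 1],
         [1, -1, -1], [1, -1, 0], [1, -1, 1], [1, 0, -1], [1, 0, 0],
         [1, 0, 1], [1, 1, -1], [1, 1, 0], [1, 1, 1]],
        np.int64,
    )
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                for k in range(14):
                    if k == 13:
                        c2 = c
                    else:
                        c2x = (cx + offs[k, 0]) % ncx
                        c2y = (cy + offs[k, 1]) % ncy
                        c2z = (cz + offs[k, 2]) % ncz
                        c2 = (c2x * ncy + c2y) * ncz + c2z
                    i = head[c]
                    while i != -1:
                        e0 = excl[i, 0]
                        e1 = excl[i, 1]
                        xi, yi, zi = wrapped[i, 0], wrapped[i, 1], wrapped[i, 2]
                        j = nxt[i] if k == 13 else head[c2]
                        while j != -1:
                            if j != e0 and j != e1:
                                dx = xi - wrapped[j, 0]
                                dx -= lx * math.floor(dx * ix + 0.5)
                                dy = yi - wrapped[j, 1]
                                dy -= ly * math.floor(dy * iy + 0.5)
                                dz = zi - wrapped[j, 2]
                                dz -= lz * math.floor(dz * iz + 0.5)
                                if dx * dx + dy * dy + dz * dz < r2max:
                                    if m < cap:
                                        if i < j:
                                            pairs[m, 0] = i
                                            pairs[m, 1] = j
                                        else:
                                            pairs[m, 0] = j
                                            pairs[m, 1] = i
                                    m += 1
                            j = nxt[j]
                        i = nxt[i]
    return m


@njit(cache=True, fastmath=True)
def pair_coefficients(pairs, m, is_insert, charges, eps, eps_insert,
                      peps, qq):
    for k in range(m):
        i = pairs[k, 0]
        j = pairs[k, 1]
        peps[k] = eps_insert if (is_insert[i] or is_insert[j]) else eps
        qq[k] = charges[i] * charges[j]


@njit(cache=True, fastmath=True)
def nonbonded_forces(pos, box, pairs, m, peps, qq, sigma, lj_pref,
                     rc_lj, rc_dh, kc, kappa, forces):
    """Accumulate LJ + Debye-Hueckel forces; returns the (shifted) energy.

    ``kc`` is K_coulomb * B(kappa) / dielectric; pass 0.0 to disable
    electrostatics entirely.
    """
    e = 0.0
    rc_lj2 = rc_lj * rc_lj
    rc_dh2 = rc_dh * rc_dh
    sig2 = sigma * sigma
    sc6 = (sig2 / rc_lj2) ** 3
    lj_shift_unit = lj_pref * (sc6 * sc6 - sc6)
    dh_shift_unit = math.exp(-kappa * rc_dh) / rc_dh
    rc_out2 = rc_lj2 if rc_lj2 > rc_dh2 else rc_dh2
    lx, ly, lz = box[0], box[1], box[2]
    ix, iy, iz = 1.0 / lx, 1.0 / ly, 1.0 / lz
    for k in range(m):
        i = pairs[k, 0]
        j = pairs[k, 1]
        dx = pos[i, 0] - pos[j, 0]
        dx -= lx * math.floor(dx * ix + 0.5)
        dy = pos[i, 1] - pos[j, 1]
        dy -= ly * math.floor(dy * iy + 0.5)
        dz = pos[i, 2] - pos[j, 2]
        dz -= lz * math.floor(dz * iz + 0.5)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc_out2:
            continue
        if r2 < 1e-12:  # overlap floor; explosion is caught by finite check
            r2 = 1e-12
        fs = 0.0
        inv_r2 = 1.0 / r2
        if r2 < rc_lj2:
            s2 = sig2 * inv_r2
            s6 = s2 * s2 * s2
            s12 = s6 * s6
            pe = peps[k] * lj_pref
            e += pe * (s12 - s6) - peps[k] * lj_shift_unit
            fs = pe * (12.0 * s12 - 6.0 * s6) * inv_r2
        if kc != 0.0 and qq[k] != 0.0 and r2 < rc_dh2:
            r = math.sqrt(r2)
            u = kc * qq[k] * math.exp(-kappa * r) / r
            e += u - kc * qq[k] * dh_shift_unit
            fs += u * (kappa + 1.0 / r) / r
        if fs != 0.0:
            forces[i, 0] += fs * dx
            forces[i, 1] += fs * dy
            forces[i, 2] += fs * dz
            forces[j, 0] -= fs * dx
            forces[j, 1] -= fs * dy
            forces[j, 2] -= fs * dz
    return e


@njit(cache=True, fastmath=True)
def bond_forces(pos, box, bonds, kb, r0, forces):
    e = 0.0
    lx, ly, lz = box[0], box[1], box[2]
    ix, iy, iz = 1.0 / lx, 1.0 / ly, 1.0 / lz
    for k in range(bonds.shape[0]):
        i = bonds[k, 0]
        j = bonds[k, 1]
        dx = pos[i, 0] - pos[j, 0]
        dx -= lx * math.floor(dx * ix + 0.5)
        dy = pos[i, 1] - pos[j, 1]
        dy -= ly * math.floor(dy * iy + 0.5)
        dz = pos[i, 2] - pos[j, 2]
        dz -= lz * math.floor(dz * iz + 0.5)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-6:
            r = 1e-6
        dr = r - r0
        e += kb * dr * dr
        fs = -2.0 * kb * dr / r
        forces[i, 0] += fs * dx
        forces[i, 1] += fs * dy
        forces[i, 2] += fs * dz
        forces[j, 0] -= fs * dx
        forces[j, 1] -= fs * dy
        forces[j, 2] -= fs * dz
    return e


@njit(cache=True, fastmath=True)
def _wrap_into(pos, box, out):
    n = pos.shape[0]
    for d in range(3):
        l = box[d]
        il = 1.0 / l
        for i in range(n):
            out[i, d] = pos[i, d] - l * math.floor(pos[i, d] * il)


@njit(cache=True, fastmath=True)
def baoab_segment(pos, vel, masses, bonds, excl, is_insert, charges,
                  box, kb, r0, sigma, eps, eps_insert, lj_pref,
                  rc_lj, rc_dh, kc, kappa,
                  n_steps, dt, gamma, kt, seed, skin,
                  pairs, peps, qq):
    """Advance (pos, vel) by n_steps of BAOAB in place.

    Returns (status, n_pairs_needed).  The neighbor list is rebuilt
    whenever any bead has moved more than skin/2 since the last build.
    Deterministic for a fixed seed (single thread).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    r_list = (rc_lj if kc == 0.0 else max(rc_lj, rc_dh)) + skin

    wrapped = np.empty_like(pos)
    _wrap_into(pos, box, wrapped)
    m = build_pairs(wrapped, box, r_list, excl, pairs)
    if m > pairs.shape[0]:
        return STATUS_PAIR_OVERFLOW, m
    pair_coefficients(pairs, m, is_insert, charges, eps, eps_insert,
                      peps, qq)
    ref = pos.copy()

    forces = np.zeros_like(pos)
    bond_forces(pos, box, bonds, kb, r0, forces)
    nonbonded_forces(pos, box, pairs, m, peps, qq, sigma, lj_pref,
                     rc_lj, rc_dh, kc, kappa, forces)

    if gamma > 0.0:
        c1 = math.exp(-gamma * dt)
        c2 = math.sqrt(1.0 - c1 * c1)
    else:
        c1 = 1.0
        c2 = 0.0
    half = 0.5 * dt
    thermal = np.empty(n)
    winv = np.empty(n)
    for i in range(n):
        thermal[i] = c2 * math.sqrt(kt / masses[i])
        winv[i] = half / masses[i]
    lim2 = (0.5 * skin) ** 2

    chunk = 8  # steps of gaussian noise drawn per allocation
    noise = _EMPTY
    for step in range(n_steps):
        if c2 > 0.0:
            o = (step % chunk) * 3 * n
            if o == 0:
                left = min(chunk, n_steps - step)
                noise = np.random.standard_normal(3 * n * left)
        else:
            o = 0
        for i in range(n):
            w = winv[i]
            vx = vel[i, 0] + w * forces[i, 0]
            vy = vel[i, 1] + w * forces[i, 1]
            vz = vel[i, 2] + w * forces[i, 2]
            if c2 > 0.0:
                s = thermal[i]
                px = pos[i, 0] + half * vx
                py = pos[i, 1] + half * vy
                pz = pos[i, 2] + half * vz
                vx = c1 * vx + s * noise[o + 3 * i]
                vy = c1 * vy + s * noise[o + 3 * i + 1]
                vz = c1 * vz + s * noise[o + 3 * i + 2]
                pos[i, 0] = px + half * vx
                pos[i, 1] = py + half * vy
                pos[i, 2] = pz + half * vz
            else:
                pos[i, 0] += dt * vx
                pos[i, 1] += dt * vy
                pos[i, 2] += dt * vz
            vel[i, 0] = vx
            vel[i, 1] = vy
            vel[i, 2] = vz

        maxdisp2 = 0.0
        for i in range(n):
            tx = pos[i, 0] - ref[i, 0]
            ty = pos[i, 1] - ref[i, 1]
            tz = pos[i, 2] - ref[i, 2]
            dd = tx * tx + ty * ty + tz * tz
            if dd > maxdisp2:
                maxdisp2 = dd
        if maxdisp2 > lim2:
            _wrap_into(pos, box, wrapped)
            m = build_pairs(wrapped, box, r_list, excl, pairs)
            if m > pairs.shape[0]:
                return STATUS_PAIR_OVERFLOW, m
            pair_coefficients(pairs, m, is_insert, charges, eps,
                              eps_insert, peps, qq)
            for i in range(n):
                ref[i, 0] = pos[i, 0]
                ref[i, 1] = pos[i, 1]
                ref[i, 2] = pos[i, 2]

        for i in range(n):
            forces[i, 0] = 0.0
            forces[i, 1] = 0.0
            forces[i, 2] = 0.0
        bond_forces(pos, box, bonds, kb, r0, forces)
        nonbonded_forces(pos, box, pairs, m, peps, qq, sigma, lj_pref,
                         rc_lj, rc_dh, kc, kappa, forces)
        for i in range(n):
            w = winv[i]
            vel[i, 0] += w * forces[i, 0]
            vel[i, 1] += w * forces[i, 1]
            vel[i, 2] += w * forces[i, 2]

    # finiteness is checked by the python driver: fastmath elides isfinite
    return STATUS_OK, m
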