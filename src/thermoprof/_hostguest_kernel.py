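"""Numba inner loop for the host-guest Metropolis sampler.

The kernel consumes pre-generated proposal displacements and acceptance
uniforms so the caller owns the random stream; it updates positions and
orientations in place and returns the number of accepted moves.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard runtime dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco


_R_MIN = 0.5


@njit(cache=True)
def _particle_energy(
    pos_b,
    ori_b,
    j,
    x,
    y,
    z,
    ux,
    uy,
    uz,
    lamb,
    eps0,
    eps1,
    sig0,
    sig1,
    mumu0,
    mumu1,
    oriented,
    ori_index,
    is_guest,
    anchors,
    nh,
    restraint_k,
    has_bond,
    bond_ka,
    bond_r0a,
    bond_kb,
    bond_r0b,
):
    n = pos_b.shape[0]
    e_a = 0.0
    e_b = 0.0
    j_or = oriented[j]
    for i in range(n):
        if i == j:
            continue
        dx = pos_b[i, 0] - x
        dy = pos_b[i, 1] - y
        dz = pos_b[i, 2] - z
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < _R_MIN:
            r = _R_MIN
        if j_or and oriented[i]:
            oi = ori_index[i]
            g = ux * ori_b[oi, 0] + uy * ori_b[oi, 1] + uz * ori_b[oi, 2]
        elif j_or:
            g = (ux * dx + uy * dy + uz * dz) / r
        elif oriented[i]:
            oi = ori_index[i]
            g = -(ori_b[oi, 0] * dx + ori_b[oi, 1] * dy + ori_b[oi, 2] * dz) / r
        else:
            g = 1.0
        inv_r3 = 1.0 / (r * r * r)
        e = eps0[j, i]
        if e > 0.0:
            sr6 = (sig0[j, i] / r) ** 6
            e_a += 4.0 * e * (sr6 * sr6 - sr6)
        e_a -= mumu0[j, i] * g * inv_r3
        e = eps1[j, i]
        if e > 0.0:
            sr6 = (sig1[j, i] / r) ** 6
            e_b += 4.0 * e * (sr6 * sr6 - sr6)
        e_b -= mumu1[j, i] * g * inv_r3
    if is_guest[j] and has_bond:
        gk = j - nh
        if gk == 0 or gk == 1:
            partner = nh + (1 - gk)
            dx = pos_b[partner, 0] - x
            dy = pos_b[partner, 1] - y
            dz = pos_b[partner, 2] - z
            rb = np.sqrt(dx * dx + dy * dy + dz * dz)
            e_a += 0.5 * bond_ka * (rb - bond_r0a) ** 2
            e_b += 0.5 * bond_kb * (rb - bond_r0b) ** 2
    e = (1.0 - lamb) * e_a + lamb * e_b
    if is_guest[j] and restraint_k > 0.0:
        gk = j - nh
        dx = x - anchors[gk, 0]
        dy = y - anchors[gk, 1]
        dz = z - anchors[gk, 2]
        e += 0.5 * restraint_k * (dx * dx + dy * dy + dz * dz)
    return e


@njit(cache=True)
def sweep(
    pos,
    ori,
    lam,
    beta,
    eps0,
    eps1,
    sig0,
    sig1,
    mumu0,
    mumu1,
    oriented,
    ori_index,
    is_guest,
    anchors,
    nh,
    ng,
    restraint_k,
    has_bond,
    bond_ka,
    bond_r0a,
    bond_kb,
    bond_r0b,
    sphere_radius,
    mobile,
    trans_disp,
    trans_u,
    rot_disp,
    rot_u,
):
    nb = pos.shape[0]
    ns = ori.shape[1]
    n_acc = 0
    for m in range(mobile.shape[0]):
        j = mobile[m]
        for b in range(nb):
            x0 = pos[b, j, 0]
            y0 = pos[b, j, 1]
            z0 = pos[b, j, 2]
            if oriented[j]:
                oi = ori_index[j]
                ux = ori[b, oi, 0]
                uy = ori[b, oi, 1]
                uz = ori[b, oi, 2]
            else:
                ux = uy = uz = 0.0
            x1 = x0 + trans_disp[m, b, 0]
            y1 = y0 + trans_disp[m, b, 1]
            z1 = z0 + trans_disp[m, b, 2]
            r = np.sqrt(x1 * x1 + y1 * y1 + z1 * z1)
            if r > sphere_radius:
                scale = (2.0 * sphere_radius - r) / r
                if scale < 0.0:
                    scale = 0.0
                x1 *= scale
                y1 *= scale
                z1 *= scale
            e0 = _particle_energy(
                pos[b], ori[b], j, x0, y0, z0, ux, uy, uz, lam[b],
                eps0, eps1, sig0, sig1, mumu0, mumu1, oriented, ori_index,
                is_guest, anchors, nh, restraint_k,
                has_bond, bond_ka, bond_r0a, bond_kb, bond_r0b,
            )
            e1 = _particle_energy(
                pos[b], ori[b], j, x1, y1, z1, ux, uy, uz, lam[b],
                eps0, eps1, sig0, sig1, mumu0, mumu1, oriented, ori_index,
                is_guest, anchors, nh, restraint_k,
                has_bond, bond_ka, bond_r0a, bond_kb, bond_r0b,
            )
            du = e1 - e0
            if du <= 0.0 or trans_u[m, b] < np.exp(-beta[b] * du):
                pos[b, j, 0] = x1
                pos[b, j, 1] = y1
                pos[b, j, 2] = z1
                n_acc += 1
    for oj in range(ns):
        j = nh + ng + oj
        for b in range(nb):
            x0 = pos[b, j, 0]
            y0 = pos[b, j, 1]
            z0 = pos[b, j, 2]
            ux0 = ori[b, oj, 0]
            uy0 = ori[b, oj, 1]
            uz0 = ori[b, oj, 2]
            ux1 = ux0 + rot_disp[oj, b, 0]
            uy1 = uy0 + rot_disp[oj, b, 1]
            uz1 = uz0 + rot_disp[oj, b, 2]
            norm = np.sqrt(ux1 * ux1 + uy1 * uy1 + uz1 * uz1)
            ux1 /= norm
            uy1 /= norm
            uz1 /= norm
            e0 = _particle_energy(
                pos[b], ori[b], j, x0, y0, z0, ux0, uy0, uz0, lam[b],
                eps0, eps1, sig0, sig1, mumu0, mumu1, oriented, ori_index,
                is_guest, anchors, nh, restraint_k,
                has_bond, bond_ka, bond_r0a, bond_kb, bond_r0b,
            )
            e1 = _particle_energy(
                pos[b], ori[b], j, x0, y0, z0, ux1, uy1, uz1, lam[b],
                eps0, eps1, sig0, sig1, mumu0, mumu1, oriented, ori_index,
                is_guest, anchors, nh, restraint_k,
                has_bond, bond_ka, bond_r0a, bond_kb, bond_r0b,
            )
            du = e1 - e0
            if du <= 0.0 or rot_u[oj, b] < np.exp(-beta[b] * du):
                ori[b, oj, 0] = ux1
                ori[b, oj, 1] = uy1
                ori[b, oj, 2] = uz1
                n_acc += 1
    return n_acc
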