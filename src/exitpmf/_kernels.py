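"""Numba-compiled fast path of the Langevin integrator.

The kernels mirror :func:`exitpmf.dynamics.potential_energy_forces` and the
BAOAB update exactly (same functional forms, same noise stream); the generic
numpy implementation remains the reference and the two are cross-checked in
the test suite.  Supported here: bonds, anchors, one axial external potential
(channel / harmonic / double-well), ligand×protein nonbonded, one umbrella
restraint (batched d_eq, k), and one TMD bias with a linear RMSD schedule.
"""

import math

import numpy as np
from numba import njit

# external-potential codes
EXT_NONE = 0
EXT_CHANNEL = 1
EXT_HARMONIC = 2
EXT_DOUBLEWELL = 3


@njit(cache=True, inline="always")
def _ext_profile_grad(code, p, s):
    """Axial profile value and derivative at s for potential code `code`."""
    if code == EXT_CHANNEL:
        d, sw, bp, sb, ap, am = p[0], p[1], p[2], p[3], p[4], p[5]
        ew = math.exp(-s * s / (2.0 * sw * sw))
        ep = math.exp(-(s - bp) * (s - bp) / (2.0 * sb * sb))
        em = math.exp(-(s + bp) * (s + bp) / (2.0 * sb * sb))
        f = -d * ew + ap * ep + am * em
        g = d * s / (sw * sw) * ew \
            - ap * (s - bp) / (sb * sb) * ep \
            - am * (s + bp) / (sb * sb) * em
        return f, g
    elif code == EXT_HARMONIC:
        kappa, s0 = p[0], p[1]
        return 0.5 * kappa * (s - s0) * (s - s0), kappa * (s - s0)
    elif code == EXT_DOUBLEWELL:
        h, c, w = p[0], p[1], p[2]
        u = ((s - c) / w) ** 2 - 1.0
        return h * u * u, h * 4.0 * u * (s - c) / (w * w)
    return 0.0, 0.0


@njit(cache=True)
def compute_forces(coords, forces,
                   bond_i, bond_j, bond_kk, bond_r0,
                   anchor_ids, anchor_k, anchor_ref,
                   lig, prot, sig2, eps, qq, lig_w,
                   ext_code, ext_params, ext_kperp, ext_axis, ext_origin,
                   umb_on, umb_com, umb_w, umb_rep, umb_deq, umb_k,
                   tmd_on, tmd_ids, tmd_target, tmd_kpa, tmd_r0, tmd_rate,
                   t, energy):
    B = coords.shape[0]
    forces[:, :, :] = 0.0
    for b in range(B):
        e = 0.0
        # bonds
        for k in range(bond_i.shape[0]):
            i = bond_i[k]
            j = bond_j[k]
            dx = coords[b, j, 0] - coords[b, i, 0]
            dy = coords[b, j, 1] - coords[b, i, 1]
            dz = coords[b, j, 2] - coords[b, i, 2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            dr = r - bond_r0[k]
            e += 0.5 * bond_kk[k] * dr * dr
            c = bond_kk[k] * dr / max(r, 1e-12)
            fx = c * dx
            fy = c * dy
            fz = c * dz
            forces[b, i, 0] += fx
            forces[b, i, 1] += fy
            forces[b, i, 2] += fz
            forces[b, j, 0] -= fx
            forces[b, j, 1] -= fy
            forces[b, j, 2] -= fz
        # anchors
        if anchor_k > 0.0:
            for k in range(anchor_ids.shape[0]):
                i = anchor_ids[k]
                dx = coords[b, i, 0] - anchor_ref[k, 0]
                dy = coords[b, i, 1] - anchor_ref[k, 1]
                dz = coords[b, i, 2] - anchor_ref[k, 2]
                e += 0.5 * anchor_k * (dx * dx + dy * dy + dz * dz)
                forces[b, i, 0] -= anchor_k * dx
                forces[b, i, 1] -= anchor_k * dy
                forces[b, i, 2] -= anchor_k * dz
        # axial external potential on the ligand centre of mass
        if ext_code != EXT_NONE:
            cx = 0.0
            cy = 0.0
            cz = 0.0
            for k in range(lig.shape[0]):
                cx += lig_w[k] * coords[b, lig[k], 0]
                cy += lig_w[k] * coords[b, lig[k], 1]
                cz += lig_w[k] * coords[b, lig[k], 2]
            px = cx - ext_origin[0]
            py = cy - ext_origin[1]
            pz = cz - ext_origin[2]
            s = px * ext_axis[0] + py * ext_axis[1] + pz * ext_axis[2]
            ppx = px - s * ext_axis[0]
            ppy = py - s * ext_axis[1]
            ppz = pz - s * ext_axis[2]
            f, df = _ext_profile_grad(ext_code, ext_params, s)
            e += f + 0.5 * ext_kperp * (ppx * ppx + ppy * ppy + ppz * ppz)
            gx = df * ext_axis[0] + ext_kperp * ppx
            gy = df * ext_axis[1] + ext_kperp * ppy
            gz = df * ext_axis[2] + ext_kperp * ppz
            for k in range(lig.shape[0]):
                forces[b, lig[k], 0] -= lig_w[k] * gx
                forces[b, lig[k], 1] -= lig_w[k] * gy
                forces[b, lig[k], 2] -= lig_w[k] * gz
        # ligand × protein nonbonded
        for a in range(lig.shape[0]):
            ia = lig[a]
            for cj in range(prot.shape[0]):
                j = prot[cj]
                dx = coords[b, ia, 0] - coords[b, j, 0]
                dy = coords[b, ia, 1] - coords[b, j, 1]
                dz = coords[b, ia, 2] - coords[b, j, 2]
                r2 = dx * dx + dy * dy + dz * dz
                r = math.sqrt(r2)
                sr6 = (sig2[a, cj] / r2) ** 3
                e += 4.0 * eps[a, cj] * (sr6 * sr6 - sr6) + qq[a, cj] / r
                dudr = (-24.0 * eps[a, cj] * (2.0 * sr6 * sr6 - sr6) / r) - qq[a, cj] / r2
                coef = -dudr / r
                fx = coef * dx
                fy = coef * dy
                fz = coef * dz
                forces[b, ia, 0] += fx
                forces[b, ia, 1] += fy
                forces[b, ia, 2] += fz
                forces[b, j, 0] -= fx
                forces[b, j, 1] -= fy
                forces[b, j, 2] -= fz
        # umbrella restraint
        if umb_on:
            cx = 0.0
            cy = 0.0
            cz = 0.0
            for k in range(umb_com.shape[0]):
                cx += umb_w[k] * coords[b, umb_com[k], 0]
                cy += umb_w[k] * coords[b, umb_com[k], 1]
                cz += umb_w[k] * coords[b, umb_com[k], 2]
            dx = coords[b, umb_rep, 0] - cx
            dy = coords[b, umb_rep, 1] - cy
            dz = coords[b, umb_rep, 2] - cz
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            gap = d - umb_deq[b]
            e += 0.5 * umb_k[b] * gap * gap
            if d > 0.0:
                ux = dx / d
                uy = dy / d
                uz = dz / d
            else:
                ux = 1.0
                uy = 0.0
                uz = 0.0
            g = umb_k[b] * gap
            forces[b, umb_rep, 0] -= g * ux
            forces[b, umb_rep, 1] -= g * uy
            forces[b, umb_rep, 2] -= g * uz
            for k in range(umb_com.shape[0]):
                forces[b, umb_com[k], 0] += umb_w[k] * g * ux
                forces[b, umb_com[k], 1] += umb_w[k] * g * uy
                forces[b, umb_com[k], 2] += umb_w[k] * g * uz
        # TMD bias with linear schedule
        if tmd_on:
            ns = tmd_ids.shape[0]
            ss = 0.0
            for k in range(ns):
                i = tmd_ids[k]
                dx = coords[b, i, 0] - tmd_target[k, 0]
                dy = coords[b, i, 1] - tmd_target[k, 1]
                dz = coords[b, i, 2] - tmd_target[k, 2]
                ss += dx * dx + dy * dy + dz * dz
            rmsd = math.sqrt(ss / ns)
            targ = tmd_r0 - tmd_rate * t
            if targ < 0.0:
                targ = 0.0
            gap = rmsd - targ
            if gap > 0.0 and rmsd > 0.0:
                e += 0.5 * tmd_kpa * ns * gap * gap
                c = tmd_kpa * gap / rmsd
                for k in range(ns):
                    i = tmd_ids[k]
                    forces[b, i, 0] -= c * (coords[b, i, 0] - tmd_target[k, 0])
                    forces[b, i, 1] -= c * (coords[b, i, 1] - tmd_target[k, 1])
                    forces[b, i, 2] -= c * (coords[b, i, 2] - tmd_target[k, 2])
        energy[b] = e


@njit(cache=True)
def baoab_chunk(coords, vel, forces, energy, masses, dt, c1, c2, noise, stochastic,
                bond_i, bond_j, bond_kk, bond_r0,
                anchor_ids, anchor_k, anchor_ref,
                lig, prot, sig2, eps, qq, lig_w,
                ext_code, ext_params, ext_kperp, ext_axis, ext_origin,
                umb_on, umb_com, umb_w, umb_rep, umb_deq, umb_k,
                tmd_on, tmd_ids, tmd_target, tmd_kpa, tmd_r0, tmd_rate,
                step_start, record_every,
                rc_on, rc_rep, rc_com, rc_w,
                out_times, out_rc, out_energy, out_frames, frames_on,
                out_ftrace, ftrace_on, rec_start):
    """Advance the batch by ``noise.shape[0]`` BAOAB steps, recording along
    the way.  Returns the number of records written in this chunk."""
    B = coords.shape[0]
    n = coords.shape[1]
    chunk = noise.shape[0]
    rec_i = rec_start
    for st in range(chunk):
        step = step_start + st + 1
        t = step * dt
        for b in range(B):
            for i in range(n):
                for d3 in range(3):
                    vel[b, i, d3] += 0.5 * dt * forces[b, i, d3] / masses[i]
                    coords[b, i, d3] += 0.5 * dt * vel[b, i, d3]
            if stochastic:
                for i in range(n):
                    for d3 in range(3):
                        vel[b, i, d3] = c1 * vel[b, i, d3] + c2[i] * noise[st, b, i, d3]
            elif c1 != 1.0:
                for i in range(n):
                    for d3 in range(3):
                        vel[b, i, d3] = c1 * vel[b, i, d3]
            for i in range(n):
                for d3 in range(3):
                    coords[b, i, d3] += 0.5 * dt * vel[b, i, d3]
        compute_forces(coords, forces,
                       bond_i, bond_j, bond_kk, bond_r0,
                       anchor_ids, anchor_k, anchor_ref,
                       lig, prot, sig2, eps, qq, lig_w,
                       ext_code, ext_params, ext_kperp, ext_axis, ext_origin,
                       umb_on, umb_com, umb_w, umb_rep, umb_deq, umb_k,
                       tmd_on, tmd_ids, tmd_target, tmd_kpa, tmd_r0, tmd_rate,
                       t, energy)
        for b in range(B):
            for i in range(n):
                for d3 in range(3):
                    vel[b, i, d3] += 0.5 * dt * forces[b, i, d3] / masses[i]

        if step % record_every == 0:
            out_times[rec_i] = t
            for b in range(B):
                out_energy[b, rec_i] = energy[b]
            if rc_on:
                for b in range(B):
                    cx = 0.0
                    cy = 0.0
                    cz = 0.0
                    for k in range(rc_com.shape[0]):
                        cx += rc_w[k] * coords[b, rc_com[k], 0]
                        cy += rc_w[k] * coords[b, rc_com[k], 1]
                        cz += rc_w[k] * coords[b, rc_com[k], 2]
                    dx = coords[b, rc_rep, 0] - cx
                    dy = coords[b, rc_rep, 1] - cy
                    dz = coords[b, rc_rep, 2] - cz
                    out_rc[b, rec_i] = math.sqrt(dx * dx + dy * dy + dz * dz)
            if frames_on:
                for i in range(n):
                    for d3 in range(3):
                        out_frames[rec_i, i, d3] = coords[0, i, d3]
            if ftrace_on and tmd_on:
                ns = tmd_ids.shape[0]
                ss = 0.0
                for k in range(ns):
                    i = tmd_ids[k]
                    dx = coords[0, i, 0] - tmd_target[k, 0]
                    dy = coords[0, i, 1] - tmd_target[k, 1]
                    dz = coords[0, i, 2] - tmd_target[k, 2]
                    ss += dx * dx + dy * dy + dz * dz
                rmsd = math.sqrt(ss / ns)
                targ = tmd_r0 - tmd_rate * t
                if targ < 0.0:
                    targ = 0.0
                gap = rmsd - targ
                if gap > 0.0 and rmsd > 0.0:
                    out_ftrace[rec_i] = tmd_kpa * gap * math.sqrt(ss) / rmsd
                else:
                    out_ftrace[rec_i] = 0.0
            rec_i += 1
    return rec_i
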