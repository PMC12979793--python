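"""Numba kernels for the bead-spring Langevin engine.

All kernels are nopython-compiled and operate on flat float64/int64
arrays. The pair list is a Verlet list with a skin, rebuilt inside the
integration loop on a fixed stride chosen so thermal displacement cannot
exceed half the skin between rebuilds.

Status codes returned by force/integration kernels:
0 = ok, 1 = FENE bond at or beyond R0, 2 = non-finite force,
3 = pair-list overflow.
"""
from __future__ import annotations

import numpy as np
from numba import njit

WCA_CUT = 2.0 ** (1.0 / 6.0)

# energy-breakdown slots
E_WCA, E_ATTR, E_BOND, E_FENE, E_BEND, E_REST, E_COMREST, E_COMWCA = range(8)
N_TERMS = 8


@njit(cache=True)
def build_pairs(
    pos, diam, is_nuc, eps_nn, rc_nn_factor, skin, skip_keys,
    pair_i, pair_j, pair_sig, pair_kind,
):
    """Fill Verlet pair arrays; returns pair count (or -1 on overflow).

    kind 0 = WCA (cutoff 2^(1/6) sigma_ij), kind 1 = attractive LJ between
    nucleosome beads (cutoff rc_nn_factor * sigma_ij). ``skip_keys`` is a
    sorted array of i*n+j keys for pairs exempt from non-bonded forces
    (restrained pairs, per the model definition).
    """
    n = pos.shape[0]
    cap = pair_i.shape[0]
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            sig = 0.5 * (diam[i] + diam[j])
            if eps_nn > 0.0 and is_nuc[i] == 1 and is_nuc[j] == 1:
                cut = rc_nn_factor * sig
                kind = 1
            else:
                cut = WCA_CUT * sig
                kind = 0
            rl = cut + skin
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 >= rl * rl:
                continue
            key = i * n + j
            k = np.searchsorted(skip_keys, key)
            if k < skip_keys.shape[0] and skip_keys[k] == key:
                continue
            if count >= cap:
                return -1
            pair_i[count] = i
            pair_j[count] = j
            pair_sig[count] = sig
            pair_kind[count] = kind
            count += 1
    return count


@njit(cache=True)
def compute_forces(
    pos,
    forces,
    energies,
    # non-bonded pair list
    pair_i, pair_j, pair_sig, pair_kind, n_pairs, eps, eps_nn, rc_nn_factor,
    # bonds: kind 0 harmonic(r0), 1 FENE(R0); per-bond stiffness bond_k
    bond_i, bond_j, bond_kind, bond_r0, bond_R0, bond_k,
    # bending on consecutive triplets (middle bead j)
    ang_i, ang_j, ang_k, k_bend,
    # flat-bottom contact restraints with force cap
    rest_i, rest_j, rest_rc, k_contact, f_cap,
    # domain COM terms
    dom_id, n_dom, dom_count,
    crest_a, crest_b, crest_rc, k_com,
    cwca_a, cwca_b, sigma_com,
):
    """Total forces and per-term energies; returns a status code."""
    forces[:] = 0.0
    energies[:] = 0.0
    n = pos.shape[0]

    # --- non-bonded pairs -------------------------------------------------
    for p in range(n_pairs):
        i = pair_i[p]
        j = pair_j[p]
        sig = pair_sig[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 <= 0.0:
            return 2
        if pair_kind[p] == 0:
            cut = WCA_CUT * sig
            if r2 >= cut * cut:
                continue
            s2 = sig * sig / r2
            s6 = s2 * s2 * s2
            s12 = s6 * s6
            energies[E_WCA] += 4.0 * eps * (s12 - s6) + eps
            fmag = 24.0 * eps * (2.0 * s12 - s6) / r2  # F = fmag * r_vec
        else:
            cut = rc_nn_factor * sig
            if r2 >= cut * cut:
                continue
            s2 = sig * sig / r2
            s6 = s2 * s2 * s2
            s12 = s6 * s6
            c2 = sig * sig / (cut * cut)
            c6 = c2 * c2 * c2
            shift = 4.0 * eps_nn * (c6 * c6 - c6)
            energies[E_ATTR] += 4.0 * eps_nn * (s12 - s6) - shift
            fmag = 24.0 * eps_nn * (2.0 * s12 - s6) / r2
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz

    # --- bonds ------------------------------------------------------------
    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if bond_kind[b] == 0:
            dr = r - bond_r0[b]
            energies[E_BOND] += 0.5 * bond_k[b] * dr * dr
            fmag = -bond_k[b] * dr / max(r, 1e-12)
        else:
            R0 = bond_R0[b]
            if r >= R0:
                return 1
            x = r * r / (R0 * R0)
            energies[E_FENE] += -0.5 * bond_k[b] * R0 * R0 * np.log(1.0 - x)
            fmag = -bond_k[b] / (1.0 - x)  # F = fmag * r_vec (attractive)
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz

    # --- bending: U = k_bend (1 + cos phi), phi the i-j-k bond angle ------
    for a in range(ang_i.shape[0]):
        i = ang_i[a]
        j = ang_j[a]
        k = ang_k[a]
        b1x = pos[i, 0] - pos[j, 0]
        b1y = pos[i, 1] - pos[j, 1]
        b1z = pos[i, 2] - pos[j, 2]
        b2x = pos[k, 0] - pos[j, 0]
        b2y = pos[k, 1] - pos[j, 1]
        b2z = pos[k, 2] - pos[j, 2]
        n1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
        n2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if n1 < 1e-12 or n2 < 1e-12:
            return 2
        e1x, e1y, e1z = b1x / n1, b1y / n1, b1z / n1
        e2x, e2y, e2z = b2x / n2, b2y / n2, b2z / n2
        c = e1x * e2x + e1y * e2y + e1z * e2z
        energies[E_BEND] += k_bend * (1.0 + c)
        # dU/dc = k_bend; F = -k_bend * grad(c)
        gix = (e2x - c * e1x) / n1
        giy = (e2y - c * e1y) / n1
        giz = (e2z - c * e1z) / n1
        gkx = (e1x - c * e2x) / n2
        gky = (e1y - c * e2y) / n2
        gkz = (e1z - c * e2z) / n2
        forces[i, 0] -= k_bend * gix
        forces[i, 1] -= k_bend * giy
        forces[i, 2] -= k_bend * giz
        forces[k, 0] -= k_bend * gkx
        forces[k, 1] -= k_bend * gky
        forces[k, 2] -= k_bend * gkz
        forces[j, 0] += k_bend * (gix + gkx)
        forces[j, 1] += k_bend * (giy + gky)
        forces[j, 2] += k_bend * (giz + gkz)

    # --- flat-bottom contact restraints (force-capped) --------------------
    xc = f_cap / k_contact
    for t in range(rest_i.shape[0]):
        i = rest_i[t]
        j = rest_j[t]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        x = r - rest_rc[t]
        if x <= 0.0:
            continue
        if x <= xc:
            energies[E_REST] += 0.5 * k_contact * x * x
            fmag = -k_contact * x / max(r, 1e-12)
        else:
            energies[E_REST] += 0.5 * k_contact * xc * xc + f_cap * (x - xc)
            fmag = -f_cap / max(r, 1e-12)
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz

    # --- domain COM terms ---------------------------------------------------
    if n_dom > 0:
        com = np.zeros((n_dom, 3))
        for i in range(n):
            d = dom_id[i]
            com[d, 0] += pos[i, 0]
            com[d, 1] += pos[i, 1]
            com[d, 2] += pos[i, 2]
        for d in range(n_dom):
            com[d, 0] /= dom_count[d]
            com[d, 1] /= dom_count[d]
            com[d, 2] /= dom_count[d]
        com_force = np.zeros((n_dom, 3))

        for t in range(crest_a.shape[0]):
            a = crest_a[t]
            b = crest_b[t]
            dx = com[a, 0] - com[b, 0]
            dy = com[a, 1] - com[b, 1]
            dz = com[a, 2] - com[b, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            x = r - crest_rc[t]
            if x <= 0.0:
                continue
            xcc = f_cap / k_com
            if x <= xcc:
                energies[E_COMREST] += 0.5 * k_com * x * x
                fmag = -k_com * x / max(r, 1e-12)
            else:
                energies[E_COMREST] += 0.5 * k_com * xcc * xcc + f_cap * (x - xcc)
                fmag = -f_cap / max(r, 1e-12)
            com_force[a, 0] += fmag * dx
            com_force[a, 1] += fmag * dy
            com_force[a, 2] += fmag * dz
            com_force[b, 0] -= fmag * dx
            com_force[b, 1] -= fmag * dy
            com_force[b, 2] -= fmag * dz

        for t in range(cwca_a.shape[0]):
            a = cwca_a[t]
            b = cwca_b[t]
            dx = com[a, 0] - com[b, 0]
            dy = com[a, 1] - com[b, 1]
            dz = com[a, 2] - com[b, 2]
            r2 = dx * dx + dy * dy + dz * dz
            cut = WCA_CUT * sigma_com
            if r2 >= cut * cut or r2 <= 0.0:
                continue
            s2 = sigma_com * sigma_com / r2
            s6 = s2 * s2 * s2
            s12 = s6 * s6
            energies[E_COMWCA] += 4.0 * eps * (s12 - s6) + eps
            fmag = 24.0 * eps * (2.0 * s12 - s6) / r2
            com_force[a, 0] += fmag * dx
            com_force[a, 1] += fmag * dy
            com_force[a, 2] += fmag * dz
            com_force[b, 0] -= fmag * dx
            com_force[b, 1] -= fmag * dy
            com_force[b, 2] -= fmag * dz

        # distribute COM forces equally over domain members
        for i in range(n):
            d = dom_id[i]
            forces[i, 0] += com_force[d, 0] / dom_count[d]
            forces[i, 1] += com_force[d, 1] / dom_count[d]
            forces[i, 2] += com_force[d, 2] / dom_count[d]

    for i in range(n):
        for c in range(3):
            if not np.isfinite(forces[i, c]):
                return 2
    return 0


@njit(cache=True)
def run_chunk(
    pos, vel, noise, dt, gamma, kT,
    diam, is_nuc, skin, rebuild_every, skip_keys,
    pair_i, pair_j, pair_sig, pair_kind,
    eps, eps_nn, rc_nn_factor,
    bond_i, bond_j, bond_kind, bond_r0, bond_R0, bond_k,
    ang_i, ang_j, ang_k, k_bend,
    rest_i, rest_j, rest_rc, k_contact, f_cap,
    dom_id, n_dom, dom_count,
    crest_a, crest_b, crest_rc, k_com,
    cwca_a, cwca_b, sigma_com,
    forces, energies,
):
    """BAOAB Langevin integration of noise.shape[0] steps (in place).

    gamma = 0 with zeroed noise reduces to plain velocity Verlet (NVE).
    Returns a status code (see module docstring).
    """
    n_steps = noise.shape[0]
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(kT * (1.0 - c1 * c1)) if gamma > 0.0 else 0.0
    n = pos.shape[0]
    n_pairs = -1
    for step in range(n_steps):
        if step % rebuild_every == 0:
            n_pairs = build_pairs(
                pos, diam, is_nuc, eps_nn, rc_nn_factor, skin, skip_keys,
                pair_i, pair_j, pair_sig, pair_kind,
            )
            if n_pairs < 0:
                return 3
            if step == 0:
                status = compute_forces(
                    pos, forces, energies,
                    pair_i, pair_j, pair_sig, pair_kind, n_pairs,
                    eps, eps_nn, rc_nn_factor,
                    bond_i, bond_j, bond_kind, bond_r0, bond_R0, bond_k,
                    ang_i, ang_j, ang_k, k_bend,
                    rest_i, rest_j, rest_rc, k_contact, f_cap,
                    dom_id, n_dom, dom_count,
                    crest_a, crest_b, crest_rc, k_com,
                    cwca_a, cwca_b, sigma_com,
                )
                if status != 0:
                    return status
        # B: half kick
        for i in range(n):
            for c in range(3):
                vel[i, c] += 0.5 * dt * forces[i, c]
        # A: half drift
        for i in range(n):
            for c in range(3):
                pos[i, c] += 0.5 * dt * vel[i, c]
        # O: thermostat
        if gamma > 0.0:
            for i in range(n):
                for c in range(3):
                    vel[i, c] = c1 * vel[i, c] + c2 * noise[step, i, c]
        # A: half drift
        for i in range(n):
            for c in range(3):
                pos[i, c] += 0.5 * dt * vel[i, c]
        # force at new positions
        status = compute_forces(
            pos, forces, energies,
            pair_i, pair_j, pair_sig, pair_kind, n_pairs,
            eps, eps_nn, rc_nn_factor,
            bond_i, bond_j, bond_kind, bond_r0, bond_R0, bond_k,
            ang_i, ang_j, ang_k, k_bend,
            rest_i, rest_j, rest_rc, k_contact, f_cap,
            dom_id, n_dom, dom_count,
            crest_a, crest_b, crest_rc, k_com,
            cwca_a, cwca_b, sigma_com,
        )
        if status != 0:
            return status
        # B: half kick
        for i in range(n):
            for c in range(3):
                vel[i, c] += 0.5 * dt * forces[i, c]
    return 0
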