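"""Compiled inner loops for pair energies and Metropolis sweeps.

All kernels assume a fully periodic orthorhombic box and operate on plain
float64 / int64 / uint8 arrays unpacked from a :class:`~hydrosorb.model.Configuration`.
The engine runs in reduced Lennard-Jones units (sigma = epsilon = k_B = 1).

Mixing rules: Lorentz-Berthelot (geometric epsilon, arithmetic sigma); when
exactly one member of a pair is water, epsilon is additionally multiplied by
the product of the two affinity factors (water carries affinity 1, so this is
the bead's hydrophilicity multiplier).

The single partially coupled molecule (index ``lam_idx``, coupling ``lam``)
interacts through a separation-shifted soft-core form,
``r_eff^2 = r^2 + ALPHA * (1 - lam) * sigma_ij^2``, and its pair sum is scaled
by ``lam``.  At ``lam == 1`` this is exactly the plain potential; at
``lam == 0`` the molecule is an ideal-gas ghost.  ``lam_idx == -1`` means no
coupling particle.
"""

import numpy as np
from numba import njit

#: soft-core separation shift prefactor (dimensionless)
SOFTCORE_ALPHA = 0.5


@njit(cache=True, inline="always")
def _mi(d, length):
    # minimum image component in [-L/2, L/2)
    return d - length * np.floor(d / length + 0.5)


@njit(cache=True)
def pair_and_coupling_energy(pos, eps, sig, aff, is_w, box, rcut, lam_idx, lam):
    """Total pair energy split into (fully coupled pairs, lam-scaled coupling part)."""
    n = pos.shape[0]
    rc2 = rcut * rcut
    e_pair = 0.0
    e_coup = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = _mi(pos[i, 0] - pos[j, 0], box[0])
            dy = _mi(pos[i, 1] - pos[j, 1], box[1])
            dz = _mi(pos[i, 2] - pos[j, 2], box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc2:
                continue
            e = np.sqrt(eps[i] * eps[j])
            if e == 0.0:
                continue
            if is_w[i] != is_w[j]:
                e *= aff[i] * aff[j]
            s = 0.5 * (sig[i] + sig[j])
            s2 = s * s
            if i == lam_idx or j == lam_idx:
                r2e = r2 + SOFTCORE_ALPHA * (1.0 - lam) * s2
                sr6 = (s2 / r2e) ** 3
                e_coup += lam * 4.0 * e * (sr6 * sr6 - sr6)
            else:
                sr6 = (s2 / r2) ** 3
                e_pair += 4.0 * e * (sr6 * sr6 - sr6)
    return e_pair, e_coup


@njit(cache=True)
def one_particle_pair_energy(i, xi, yi, zi, pos, eps, sig, aff, is_w, box, rcut,
                             lam_idx, lam):
    """Pair energy of particle ``i`` placed at (xi, yi, zi) against all others.

    Coupling-aware: pairs involving the coupling particle (either as ``i`` or
    as a partner) use the lam-scaled soft-core form, so that the returned value
    is exactly the contribution of particle ``i`` to the total energy.
    """
    n = pos.shape[0]
    rc2 = rcut * rcut
    e_sum = 0.0
    for j in range(n):
        if j == i:
            continue
        dx = _mi(xi - pos[j, 0], box[0])
        dy = _mi(yi - pos[j, 1], box[1])
        dz = _mi(zi - pos[j, 2], box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        e = np.sqrt(eps[i] * eps[j])
        if e == 0.0:
            continue
        if is_w[i] != is_w[j]:
            e *= aff[i] * aff[j]
        s = 0.5 * (sig[i] + sig[j])
        s2 = s * s
        if i == lam_idx or j == lam_idx:
            r2e = r2 + SOFTCORE_ALPHA * (1.0 - lam) * s2
            sr6 = (s2 / r2e) ** 3
            e_sum += lam * 4.0 * e * (sr6 * sr6 - sr6)
        else:
            if r2 < 1e-24:
                return np.inf
            sr6 = (s2 / r2) ** 3
            e_sum += 4.0 * e * (sr6 * sr6 - sr6)
    return e_sum


@njit(cache=True)
def bonded_energy(pos, box, bond_pairs, bond_k, bond_r0, teth_k, teth_anchor):
    """Harmonic bond/crosslink energy plus per-particle tether energy.

    ``teth_k`` has one entry per particle (0 = no tether); tether energy is
    0.5 * k * |min_image(r - anchor)|^2.
    """
    e = 0.0
    for b in range(bond_pairs.shape[0]):
        i = bond_pairs[b, 0]
        j = bond_pairs[b, 1]
        dx = _mi(pos[i, 0] - pos[j, 0], box[0])
        dy = _mi(pos[i, 1] - pos[j, 1], box[1])
        dz = _mi(pos[i, 2] - pos[j, 2], box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        e += 0.5 * bond_k[b] * dr * dr
    for i in range(teth_k.shape[0]):
        if teth_k[i] > 0.0:
            dx = _mi(pos[i, 0] - teth_anchor[i, 0], box[0])
            dy = _mi(pos[i, 1] - teth_anchor[i, 1], box[1])
            dz = _mi(pos[i, 2] - teth_anchor[i, 2], box[2])
            e += 0.5 * teth_k[i] * (dx * dx + dy * dy + dz * dz)
    return e


@njit(cache=True, inline="always")
def _particle_bonded(i, xi, yi, zi, pos, box, adj_off, adj_nbr, adj_k, adj_r0,
                     teth_k, teth_anchor):
    e = 0.0
    for a in range(adj_off[i], adj_off[i + 1]):
        j = adj_nbr[a]
        dx = _mi(xi - pos[j, 0], box[0])
        dy = _mi(yi - pos[j, 1], box[1])
        dz = _mi(zi - pos[j, 2], box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - adj_r0[a]
        e += 0.5 * adj_k[a] * dr * dr
    if teth_k[i] > 0.0:
        dx = _mi(xi - teth_anchor[i, 0], box[0])
        dy = _mi(yi - teth_anchor[i, 1], box[1])
        dz = _mi(zi - teth_anchor[i, 2], box[2])
        e += 0.5 * teth_k[i] * (dx * dx + dy * dy + dz * dz)
    return e


@njit(cache=True)
def mc_sweeps(pos, eps, sig, aff, is_w, box, rcut, lam_idx, lam,
              adj_off, adj_nbr, adj_k, adj_r0, teth_k, teth_anchor,
              beta, max_disp, teleport_prob, rand):
    """Sequential single-particle Metropolis sweeps; mutates ``pos`` in place.

    ``rand`` has shape (n_sweeps, n_particles, 5): move-type draw, three
    proposal draws, acceptance draw.  Water particles attempt a box-uniform
    reposition with probability ``teleport_prob`` (a symmetric proposal),
    otherwise a cubic displacement of half-width ``max_disp``; matrix beads
    only move locally.  Returns the number of accepted moves.
    """
    n = pos.shape[0]
    n_acc = 0
    for s in range(rand.shape[0]):
        for i in range(n):
            u_type = rand[s, i, 0]
            u1 = rand[s, i, 1]
            u2 = rand[s, i, 2]
            u3 = rand[s, i, 3]
            u_acc = rand[s, i, 4]
            if is_w[i] != 0 and u_type < teleport_prob:
                xn = u1 * box[0]
                yn = u2 * box[1]
                zn = u3 * box[2]
            else:
                xn = pos[i, 0] + (2.0 * u1 - 1.0) * max_disp
                yn = pos[i, 1] + (2.0 * u2 - 1.0) * max_disp
                zn = pos[i, 2] + (2.0 * u3 - 1.0) * max_disp
                xn -= box[0] * np.floor(xn / box[0])
                yn -= box[1] * np.floor(yn / box[1])
                zn -= box[2] * np.floor(zn / box[2])
            e_old = one_particle_pair_energy(
                i, pos[i, 0], pos[i, 1], pos[i, 2], pos, eps, sig, aff, is_w,
                box, rcut, lam_idx, lam)
            e_old += _particle_bonded(i, pos[i, 0], pos[i, 1], pos[i, 2], pos,
                                      box, adj_off, adj_nbr, adj_k, adj_r0,
                                      teth_k, teth_anchor)
            e_new = one_particle_pair_energy(
                i, xn, yn, zn, pos, eps, sig, aff, is_w, box, rcut, lam_idx, lam)
            e_new += _particle_bonded(i, xn, yn, zn, pos, box, adj_off, adj_nbr,
                                      adj_k, adj_r0, teth_k, teth_anchor)
            du = e_new - e_old
            if du <= 0.0 or u_acc < np.exp(-beta * du):
                pos[i, 0] = xn
                pos[i, 1] = yn
                pos[i, 2] = zn
                n_acc += 1
    return n_acc


@njit(cache=True)
def ghost_insertion_energies(pos, eps, sig, aff, is_w, box, rcut,
                             eps_w, sig_w, trials):
    """Energy change of inserting a fully coupled ghost water at each trial point.

    The ghost never modifies the configuration; pairs with matrix beads pick up
    the bead's affinity multiplier.  Exact overlap (r = 0) yields +inf.
    """
    rc2 = rcut * rcut
    n = pos.shape[0]
    m = trials.shape[0]
    out = np.empty(m)
    for t in range(m):
        e_sum = 0.0
        for j in range(n):
            dx = _mi(trials[t, 0] - pos[j, 0], box[0])
            dy = _mi(trials[t, 1] - pos[j, 1], box[1])
            dz = _mi(trials[t, 2] - pos[j, 2], box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc2:
                continue
            if r2 < 1e-24:
                e_sum = np.inf
                break
            e = np.sqrt(eps_w * eps[j])
            if e == 0.0:
                continue
            if is_w[j] == 0:
                e *= aff[j]
            s = 0.5 * (sig_w + sig[j])
            sr6 = (s * s / r2) ** 3
            e_sum += 4.0 * e * (sr6 * sr6 - sr6)
        out[t] = e_sum
    return out


@njit(cache=True)
def particle_interaction_energies(pos, eps, sig, aff, is_w, box, rcut,
                                  lam_idx, lam, idxs):
    """Interaction (pair) energy of each listed particle with the rest."""
    out = np.empty(idxs.shape[0])
    for k in range(idxs.shape[0]):
        i = idxs[k]
        out[k] = one_particle_pair_energy(
            i, pos[i, 0], pos[i, 1], pos[i, 2], pos, eps, sig, aff, is_w,
            box, rcut, lam_idx, lam)
    return out
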