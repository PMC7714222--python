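"""Numba-compiled numerical kernels.

These are the hot loops shared by the energy module and both
optimizers: chain construction from internal coordinates (the NeRF
recurrence) and the flat-bottom restraint energy/gradient.  All angles
are radians here; degree<->radian conversion happens at the API
boundary in :mod:`dgfold.geometry`.
"""
import numpy as np
from numba import njit

__all__ = [
    "build_chain",
    "restraint_energy",
    "connectivity_energy",
    "energy_and_gradient",
    "restraint_energy_reg",
    "gd_run_reg",
]


@njit(cache=True)
def build_chain(bonds, theta, tau):
    """Cartesian coordinates from internal coordinates, canonical frame.

    Residue 0 at the origin, residue 1 on +x, residue 2 in the xy-plane
    with y > 0.  ``theta[k]`` is the planar angle at residue k+1,
    ``tau[k]`` the dihedral of residues k..k+3 in the right-handed
    (IUPAC) sign convention.
    """
    L = bonds.shape[0] + 1
    X = np.zeros((L, 3))
    X[1, 0] = bonds[0]
    if L > 2:
        X[2, 0] = X[1, 0] - bonds[1] * np.cos(theta[0])
        X[2, 1] = bonds[1] * np.sin(theta[0])
    for k in range(3, L):
        b = bonds[k - 1]
        ct = np.cos(theta[k - 2])
        st = np.sin(theta[k - 2])
        cp = np.cos(tau[k - 3])
        sp = np.sin(tau[k - 3])
        # frame at residue k-1: bc along previous bond, n normal to the
        # previous three residues' plane, m completes the right-handed set
        bcx = X[k - 1, 0] - X[k - 2, 0]
        bcy = X[k - 1, 1] - X[k - 2, 1]
        bcz = X[k - 1, 2] - X[k - 2, 2]
        nb = np.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
        bcx /= nb
        bcy /= nb
        bcz /= nb
        abx = X[k - 2, 0] - X[k - 3, 0]
        aby = X[k - 2, 1] - X[k - 3, 1]
        abz = X[k - 2, 2] - X[k - 3, 2]
        nx = aby * bcz - abz * bcy
        ny = abz * bcx - abx * bcz
        nz = abx * bcy - aby * bcx
        nn = np.sqrt(nx * nx + ny * ny + nz * nz)
        nx /= nn
        ny /= nn
        nz /= nn
        mx = ny * bcz - nz * bcy
        my = nz * bcx - nx * bcz
        mz = nx * bcy - ny * bcx
        # negative n-component makes the measured IUPAC dihedral equal tau
        d0 = -b * ct
        d1 = b * st * cp
        d2 = -b * st * sp
        X[k, 0] = X[k - 1, 0] + d0 * bcx + d1 * mx + d2 * nx
        X[k, 1] = X[k - 1, 1] + d0 * bcy + d1 * my + d2 * ny
        X[k, 2] = X[k - 1, 2] + d0 * bcz + d1 * mz + d2 * nz
    return X


@njit(cache=True)
def restraint_energy(X, i_idx, j_idx, lower, upper, weight):
    """Flat-bottom squared-hinge restraint energy.

    Returns ``(energy, n_violated)`` where a restraint is violated when
    its distance falls strictly outside [lower, upper].
    """
    e = 0.0
    nv = 0
    for k in range(i_idx.shape[0]):
        i = i_idx[k]
        j = j_idx[k]
        dx = X[i, 0] - X[j, 0]
        dy = X[i, 1] - X[j, 1]
        dz = X[i, 2] - X[j, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        v = 0.0
        if d < lower[k]:
            v = lower[k] - d
        elif d > upper[k]:
            v = d - upper[k]
        if v > 0.0:
            nv += 1
            e += weight[k] * v * v
    return e, nv


@njit(cache=True)
def connectivity_energy(X, k_bond, bond_length):
    """Harmonic restraint keeping consecutive residues at bond_length."""
    e = 0.0
    for i in range(X.shape[0] - 1):
        dx = X[i + 1, 0] - X[i, 0]
        dy = X[i + 1, 1] - X[i, 1]
        dz = X[i + 1, 2] - X[i, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        dev = d - bond_length
        e += k_bond * dev * dev
    return e


@njit(cache=True)
def energy_and_gradient(X, i_idx, j_idx, lower, upper, weight,
                        k_bond, bond_length):
    """Total energy and its exact Cartesian gradient.

    Coincident restrained pairs (d == 0) contribute their hinge energy
    but a zero (sub)gradient; their count is returned so the caller can
    warn.  Returns
    ``(total, restraint_term, connectivity_term, grad, n_violated, n_coincident)``.
    """
    L = X.shape[0]
    grad = np.zeros((L, 3))
    er = 0.0
    nv = 0
    nz = 0
    for k in range(i_idx.shape[0]):
        i = i_idx[k]
        j = j_idx[k]
        dx = X[i, 0] - X[j, 0]
        dy = X[i, 1] - X[j, 1]
        dz = X[i, 2] - X[j, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        v = 0.0
        sgn = 1.0
        if d < lower[k]:
            v = lower[k] - d
            sgn = -1.0
        elif d > upper[k]:
            v = d - upper[k]
        if v > 0.0:
            nv += 1
            er += weight[k] * v * v
            if d <= 0.0:
                nz += 1
                continue
            c = 2.0 * weight[k] * v * sgn / d
            grad[i, 0] += c * dx
            grad[i, 1] += c * dy
            grad[i, 2] += c * dz
            grad[j, 0] -= c * dx
            grad[j, 1] -= c * dy
            grad[j, 2] -= c * dz
    ec = 0.0
    for i in range(L - 1):
        dx = X[i + 1, 0] - X[i, 0]
        dy = X[i + 1, 1] - X[i, 1]
        dz = X[i + 1, 2] - X[i, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        dev = d - bond_length
        ec += k_bond * dev * dev
        if d > 0.0:
            c = 2.0 * k_bond * dev / d
            grad[i + 1, 0] += c * dx
            grad[i + 1, 1] += c * dy
            grad[i + 1, 2] += c * dz
            grad[i, 0] -= c * dx
            grad[i, 1] -= c * dy
            grad[i, 2] -= c * dz
    return er + ec, er, ec, grad, nv, nz


@njit(cache=True)
def restraint_energy_reg(X, i_idx, j_idx, lower, upper, weight, eps):
    """Optimizer objective: flat-bottom hinge plus a weak (weight eps)
    harmonic pull toward the bound midpoint.

    The centering term selects the central solution of the feasible
    region; it breaks the degeneracy the flat bottom leaves within the
    bounds.  Returns (energy, n_violated) like restraint_energy.
    """
    e = 0.0
    nv = 0
    for k in range(i_idx.shape[0]):
        i = i_idx[k]
        j = j_idx[k]
        dx = X[i, 0] - X[j, 0]
        dy = X[i, 1] - X[j, 1]
        dz = X[i, 2] - X[j, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        v = 0.0
        if d < lower[k]:
            v = lower[k] - d
        elif d > upper[k]:
            v = d - upper[k]
        if v > 0.0:
            nv += 1
        mid = 0.5 * (lower[k] + upper[k])
        e += weight[k] * (v * v + eps * (d - mid) * (d - mid))
    return e, nv


@njit(cache=True)
def gd_run_reg(X, n_steps, step, i_idx, j_idx, lower, upper, weight,
               k_bond, bond_length, eps, divergence_limit):
    """n_steps of steepest descent on the regularized objective, in
    place; returns (energy_before_first_step, failed_iteration or -1).
    """
    L = X.shape[0]
    e0 = 0.0
    for it in range(n_steps):
        grad = np.zeros((L, 3))
        er = 0.0
        for k in range(i_idx.shape[0]):
            a = i_idx[k]
            b = j_idx[k]
            dx = X[a, 0] - X[b, 0]
            dy = X[a, 1] - X[b, 1]
            dz = X[a, 2] - X[b, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            v = 0.0
            sgn = 1.0
            if d < lower[k]:
                v = lower[k] - d
                sgn = -1.0
            elif d > upper[k]:
                v = d - upper[k]
            mid = 0.5 * (lower[k] + upper[k])
            er += weight[k] * (v * v + eps * (d - mid) * (d - mid))
            if d > 0.0:
                c = (2.0 * weight[k] * v * sgn
                     + 2.0 * eps * weight[k] * (d - mid)) / d
                grad[a, 0] += c * dx
                grad[a, 1] += c * dy
                grad[a, 2] += c * dz
                grad[b, 0] -= c * dx
                grad[b, 1] -= c * dy
                grad[b, 2] -= c * dz
        ec = 0.0
        for a in range(L - 1):
            dx = X[a + 1, 0] - X[a, 0]
            dy = X[a + 1, 1] - X[a, 1]
            dz = X[a + 1, 2] - X[a, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            dev = d - bond_length
            ec += k_bond * dev * dev
            if d > 0.0:
                c = 2.0 * k_bond * dev / d
                grad[a + 1, 0] += c * dx
                grad[a + 1, 1] += c * dy
                grad[a + 1, 2] += c * dz
                grad[a, 0] -= c * dx
                grad[a, 1] -= c * dy
                grad[a, 2] -= c * dz
        total = er + ec
        if it == 0:
            e0 = total
        if not np.isfinite(total) or total > divergence_limit:
            return e0, it
        for a in range(L):
            X[a, 0] -= step * grad[a, 0]
            X[a, 1] -= step * grad[a, 1]
            X[a, 2] -= step * grad[a, 2]
    return e0, -1
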