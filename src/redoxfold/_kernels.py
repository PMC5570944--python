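"""JIT-compiled force and integration kernels.

Everything here operates on flat numpy arrays prepared by
:mod:`redoxfold.forcefield`; no domain objects cross this boundary.  The
Langevin propagator consumes a pre-drawn Gaussian noise block so that the
RNG state lives entirely outside the kernel (bitwise replay is then a
matter of restoring the numpy Generator state).

Energy conventions: harmonic terms are E = k * deviation² (no 1/2), the
Amber convention the restraint constants are quoted in; LJ is the r-min
form ε((r0/r)¹² − 2(r0/r)⁶) truncated (not shifted) at the cutoff.
"""

import numpy as np
from numba import njit

__all__ = ["compute_forces", "run_chunk"]


@njit(cache=True, fastmath=False)
def _wrap_angle(x):
    """Wrap an angle in radians to (-pi, pi]."""
    twopi = 2.0 * np.pi
    x = x - twopi * np.round(x / twopi)
    if x <= -np.pi:
        x += twopi
    return x


@njit(cache=True, fastmath=False)
def compute_forces(
    pos,
    forces,
    # bonds
    bond_i, bond_j, bond_k, bond_r0,
    # angles
    ang_i, ang_j, ang_k, ang_kf, ang_t0,
    # dihedrals
    dih_i, dih_j, dih_k, dih_l, dih_kf, dih_t0,
    # LJ pair table
    pair_i, pair_j, pair_eps, pair_r0, pair_masked,
    cutoff, mask_onset,
    # restraints (scaled by alpha)
    rd_i, rd_j, rd_k, rd_t,
    ra_i, ra_j, ra_k, ra_kf, ra_t0,
    rq_i, rq_j, rq_k, rq_l, rq_kf, rq_t0,
    alpha,
):
    """Fill `forces` with -grad E and return the energy breakdown
    (bond, angle, dihedral, lj, restraint)."""
    forces[:] = 0.0
    e_bond = 0.0
    e_angle = 0.0
    e_dih = 0.0
    e_lj = 0.0
    e_res = 0.0

    # ---- harmonic bonds: E = k (r - r0)^2 -------------------------------
    for t in range(bond_i.shape[0]):
        i = bond_i[t]
        j = bond_j[t]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dev = r - bond_r0[t]
        e_bond += bond_k[t] * dev * dev
        if r > 1e-12:
            f = -2.0 * bond_k[t] * dev / r
            forces[i, 0] += f * dx
            forces[i, 1] += f * dy
            forces[i, 2] += f * dz
            forces[j, 0] -= f * dx
            forces[j, 1] -= f * dy
            forces[j, 2] -= f * dz

    # ---- harmonic angles: E = k (theta - theta0)^2 ----------------------
    for t in range(ang_i.shape[0]):
        e_angle += _angle_term(
            pos, forces, ang_i[t], ang_j[t], ang_k[t], ang_kf[t], ang_t0[t]
        )

    # ---- harmonic dihedrals: E = k * wrap(phi - phi0)^2 -----------------
    for t in range(dih_i.shape[0]):
        e_dih += _dihedral_term(
            pos, forces, dih_i[t], dih_j[t], dih_k[t], dih_l[t], dih_kf[t], dih_t0[t]
        )

    # ---- Lennard-Jones, truncated at cutoff -----------------------------
    for t in range(pair_i.shape[0]):
        i = pair_i[t]
        j = pair_j[t]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= cutoff * cutoff:
            continue
        r = np.sqrt(r2)
        if pair_masked[t] == 1 and r < mask_onset:
            continue  # reactive S–S pair: no short-range LJ wall
        s = pair_r0[t] / r
        s6 = s ** 6
        s12 = s6 * s6
        e_lj += pair_eps[t] * (s12 - 2.0 * s6)
        # dE/dr = eps * (-12 s12 + 12 s6) / r
        f = -pair_eps[t] * 12.0 * (s6 - s12) / r2  # = -(dE/dr)/r
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
        forces[j, 2] -= f * dz

    # ---- artificial restraints, scaled by alpha -------------------------
    if alpha > 0.0:
        for t in range(rd_i.shape[0]):
            i = rd_i[t]
            j = rd_j[t]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            dev = r - rd_t[t]
            kk = alpha * rd_k[t]
            e_res += kk * dev * dev
            if r > 1e-12:
                f = -2.0 * kk * dev / r
                forces[i, 0] += f * dx
                forces[i, 1] += f * dy
                forces[i, 2] += f * dz
                forces[j, 0] -= f * dx
                forces[j, 1] -= f * dy
                forces[j, 2] -= f * dz
        for t in range(ra_i.shape[0]):
            e_res += _angle_term(
                pos, forces, ra_i[t], ra_j[t], ra_k[t], alpha * ra_kf[t], ra_t0[t]
            )
        for t in range(rq_i.shape[0]):
            e_res += _dihedral_term(
                pos, forces, rq_i[t], rq_j[t], rq_k[t], rq_l[t],
                alpha * rq_kf[t], rq_t0[t],
            )

    return e_bond, e_angle, e_dih, e_lj, e_res


@njit(cache=True, fastmath=False)
def _angle_term(pos, forces, i, j, k, kf, t0):
    """Accumulate forces of one harmonic angle term; return its energy.
    t0 in radians."""
    ux = pos[i, 0] - pos[j, 0]
    uy = pos[i, 1] - pos[j, 1]
    uz = pos[i, 2] - pos[j, 2]
    vx = pos[k, 0] - pos[j, 0]
    vy = pos[k, 1] - pos[j, 1]
    vz = pos[k, 2] - pos[j, 2]
    nu = np.sqrt(ux * ux + uy * uy + uz * uz)
    nv = np.sqrt(vx * vx + vy * vy + vz * vz)
    if nu < 1e-12 or nv < 1e-12:
        return 0.0
    c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    theta = np.arccos(c)
    dev = theta - t0
    e = kf * dev * dev
    s = np.sqrt(1.0 - c * c)
    if s < 1e-8:
        return e  # collinear: gradient direction ill-defined, skip force
    dedt = 2.0 * kf * dev
    # F_i = -dE/dtheta * dtheta/dri ; dtheta/dri = -(1/sin) dcos/dri,
    # dcos/dri = v/(nu nv) - c u/nu^2  =>  F_i = (dE/dtheta / sin) * dcos/dri
    coef = dedt / s
    gix = coef * (vx / (nu * nv) - c * ux / (nu * nu))
    giy = coef * (vy / (nu * nv) - c * uy / (nu * nu))
    giz = coef * (vz / (nu * nv) - c * uz / (nu * nu))
    gkx = coef * (ux / (nu * nv) - c * vx / (nv * nv))
    gky = coef * (uy / (nu * nv) - c * vy / (nv * nv))
    gkz = coef * (uz / (nu * nv) - c * vz / (nv * nv))
    forces[i, 0] += gix
    forces[i, 1] += giy
    forces[i, 2] += giz
    forces[k, 0] += gkx
    forces[k, 1] += gky
    forces[k, 2] += gkz
    forces[j, 0] -= gix + gkx
    forces[j, 1] -= giy + gky
    forces[j, 2] -= giz + gkz
    return e


@njit(cache=True, fastmath=False)
def _dihedral_term(pos, forces, i, j, k, l, kf, t0):
    """Accumulate forces of one harmonic dihedral; deviation on the shortest
    arc.  t0 in radians.  Returns the term energy."""
    b1x = pos[j, 0] - pos[i, 0]
    b1y = pos[j, 1] - pos[i, 1]
    b1z = pos[j, 2] - pos[i, 2]
    b2x = pos[k, 0] - pos[j, 0]
    b2y = pos[k, 1] - pos[j, 1]
    b2z = pos[k, 2] - pos[j, 2]
    b3x = pos[l, 0] - pos[k, 0]
    b3y = pos[l, 1] - pos[k, 1]
    b3z = pos[l, 2] - pos[k, 2]
    # n1 = b1 x b2, n2 = b2 x b3
    n1x = b1y * b2z - b1z * b2y
    n1y = b1z * b2x - b1x * b2z
    n1z = b1x * b2y - b1y * b2x
    n2x = b2y * b3z - b2z * b3y
    n2y = b2z * b3x - b2x * b3z
    n2z = b2x * b3y - b2y * b3x
    n1sq = n1x * n1x + n1y * n1y + n1z * n1z
    n2sq = n2x * n2x + n2y * n2y + n2z * n2z
    b2n = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
    if n1sq < 1e-16 or n2sq < 1e-16 or b2n < 1e-12:
        return 0.0
    # phi = atan2((n1 x n2) . b2hat, n1 . n2)
    mx = n1y * n2z - n1z * n2y
    my = n1z * n2x - n1x * n2z
    mz = n1x * n2y - n1y * n2x
    y = (mx * b2x + my * b2y + mz * b2z) / b2n
    x = n1x * n2x + n1y * n2y + n1z * n2z
    phi = np.arctan2(y, x)
    dev = _wrap_angle(phi - t0)
    e = kf * dev * dev
    dedphi = 2.0 * kf * dev
    # gradients of phi (standard result)
    gix = -b2n / n1sq * n1x
    giy = -b2n / n1sq * n1y
    giz = -b2n / n1sq * n1z
    glx = b2n / n2sq * n2x
    gly = b2n / n2sq * n2y
    glz = b2n / n2sq * n2z
    t1 = (b1x * b2x + b1y * b2y + b1z * b2z) / (b2n * b2n)
    t2 = (b3x * b2x + b3y * b2y + b3z * b2z) / (b2n * b2n)
    gjx = -(1.0 + t1) * gix + t2 * glx
    gjy = -(1.0 + t1) * giy + t2 * gly
    gjz = -(1.0 + t1) * giz + t2 * glz
    gkx = -(1.0 + t2) * glx + t1 * gix
    gky = -(1.0 + t2) * gly + t1 * giy
    gkz = -(1.0 + t2) * glz + t1 * giz
    forces[i, 0] -= dedphi * gix
    forces[i, 1] -= dedphi * giy
    forces[i, 2] -= dedphi * giz
    forces[j, 0] -= dedphi * gjx
    forces[j, 1] -= dedphi * gjy
    forces[j, 2] -= dedphi * gjz
    forces[k, 0] -= dedphi * gkx
    forces[k, 1] -= dedphi * gky
    forces[k, 2] -= dedphi * gkz
    forces[l, 0] -= dedphi * glx
    forces[l, 1] -= dedphi * gly
    forces[l, 2] -= dedphi * glz
    return e


@njit(cache=True, fastmath=False)
def run_chunk(
    pos, vel,
    accel_per_force,      # FORCE_TO_ACCEL / m, per particle
    sigma_v,              # OU noise amplitude sqrt((1-c1^2) kB T conv / m)
    c1,                   # exp(-gamma dt)
    dt, n_steps,
    noise,                # (n_steps, N, 3) standard normals
    sphere_radius,
    # force-field arrays (passed straight through to compute_forces)
    bond_i, bond_j, bond_k, bond_r0,
    ang_i, ang_j, ang_k, ang_kf, ang_t0,
    dih_i, dih_j, dih_k, dih_l, dih_kf, dih_t0,
    pair_i, pair_j, pair_eps, pair_r0, pair_masked,
    cutoff, mask_onset,
    rd_i, rd_j, rd_k, rd_t,
    ra_i, ra_j, ra_k, ra_kf, ra_t0,
    rq_i, rq_j, rq_k, rq_l, rq_kf, rq_t0,
    alpha,
):
    """BAOAB Langevin splitting, in place.  Returns 0 on success, the
    (1-based) step number at which coordinates went non-finite otherwise."""
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    compute_forces(
        pos, forces,
        bond_i, bond_j, bond_k, bond_r0,
        ang_i, ang_j, ang_k, ang_kf, ang_t0,
        dih_i, dih_j, dih_k, dih_l, dih_kf, dih_t0,
        pair_i, pair_j, pair_eps, pair_r0, pair_masked,
        cutoff, mask_onset,
        rd_i, rd_j, rd_k, rd_t,
        ra_i, ra_j, ra_k, ra_kf, ra_t0,
        rq_i, rq_j, rq_k, rq_l, rq_kf, rq_t0,
        alpha,
    )
    half = 0.5 * dt
    for step in range(n_steps):
        for p in range(n):
            a = accel_per_force[p]
            for d in range(3):
                vel[p, d] += half * forces[p, d] * a        # B
                pos[p, d] += half * vel[p, d]               # A
                vel[p, d] = c1 * vel[p, d] + sigma_v[p] * noise[step, p, d]  # O
                pos[p, d] += half * vel[p, d]               # A
        # reflective spherical container
        for p in range(n):
            r2 = pos[p, 0] ** 2 + pos[p, 1] ** 2 + pos[p, 2] ** 2
            if r2 > sphere_radius * sphere_radius:
                r = np.sqrt(r2)
                scale = (2.0 * sphere_radius - r) / r
                vr = (vel[p, 0] * pos[p, 0] + vel[p, 1] * pos[p, 1]
                      + vel[p, 2] * pos[p, 2]) / r
                if vr > 0.0:
                    for d in range(3):
                        vel[p, d] -= 2.0 * vr * pos[p, d] / r
                for d in range(3):
                    pos[p, d] *= scale
        compute_forces(
            pos, forces,
            bond_i, bond_j, bond_k, bond_r0,
            ang_i, ang_j, ang_k, ang_kf, ang_t0,
            dih_i, dih_j, dih_k, dih_l, dih_kf, dih_t0,
            pair_i, pair_j, pair_eps, pair_r0, pair_masked,
            cutoff, mask_onset,
            rd_i, rd_j, rd_k, rd_t,
            ra_i, ra_j, ra_k, ra_kf, ra_t0,
            rq_i, rq_j, rq_k, rq_l, rq_kf, rq_t0,
            alpha,
        )
        for p in range(n):
            a = accel_per_force[p]
            for d in range(3):
                vel[p, d] += half * forces[p, d] * a        # B
        if not np.isfinite(pos).all():
            return step + 1
    return 0
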