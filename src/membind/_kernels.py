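"""Compiled inner loops of the overdamped Langevin engine.

These kernels duplicate the force expressions of :mod:`membind.restraints`
for speed; a unit test cross-checks them against the pure-numpy reference
implementation. All arrays are float64; distances nm, energies kJ/mol,
angles handled in degrees exactly as in the reference module.
"""

import math

import numpy as np
from numba import njit

_RAD2DEG = 180.0 / math.pi
_EPS = 1e-12


@njit(cache=False)
def _wrap_deg(a):
    w = -((-a + 180.0) % 360.0 - 180.0)
    return w


@njit(cache=False)
def compute_forces(pos, forces,
                   plane_z, depth, inv2w2, com_coupling,
                   bond_k, bond_r0,
                   use_restraints, K_a, theta0, sigma_a, K_d, phi0, sigma_d):
    """Accumulate bond + membrane + restraint forces into ``forces``."""
    n = pos.shape[0]
    for i in range(n):
        for c in range(3):
            forces[i, c] = 0.0

    # harmonic bonds between consecutive beads
    if bond_k > 0.0:
        for i in range(n - 1):
            dx = pos[i + 1, 0] - pos[i, 0]
            dy = pos[i + 1, 1] - pos[i, 1]
            dz = pos[i + 1, 2] - pos[i, 2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            if r > _EPS:
                f = bond_k * (r - bond_r0) / r
                forces[i, 0] += f * dx
                forces[i, 1] += f * dy
                forces[i, 2] += f * dz
                forces[i + 1, 0] -= f * dx
                forces[i + 1, 1] -= f * dy
                forces[i + 1, 2] -= f * dz

    # implicit membrane: attractive Gaussian well in z
    if depth > 0.0:
        if com_coupling:
            zc = 0.0
            for i in range(n):
                zc += pos[i, 2]
            zc /= n
            d = zc - plane_z
            g = math.exp(-d * d * inv2w2)
            fz = -2.0 * inv2w2 * depth * d * g / n
            for i in range(n):
                forces[i, 2] += fz
        else:
            for i in range(n):
                d = pos[i, 2] - plane_z
                g = math.exp(-d * d * inv2w2)
                forces[i, 2] += -2.0 * inv2w2 * depth * d * g

    if use_restraints:
        # angle restraints on consecutive triplets
        for i in range(n - 2):
            ax = pos[i, 0] - pos[i + 1, 0]
            ay = pos[i, 1] - pos[i + 1, 1]
            az = pos[i, 2] - pos[i + 1, 2]
            bx = pos[i + 2, 0] - pos[i + 1, 0]
            by = pos[i + 2, 1] - pos[i + 1, 1]
            bz = pos[i + 2, 2] - pos[i + 1, 2]
            na = math.sqrt(ax * ax + ay * ay + az * az)
            nb = math.sqrt(bx * bx + by * by + bz * bz)
            if na < _EPS or nb < _EPS:
                continue
            c = (ax * bx + ay * by + az * bz) / (na * nb)
            if c > 1.0:
                c = 1.0
            elif c < -1.0:
                c = -1.0
            s2 = 1.0 - c * c
            if s2 < _EPS:
                s2 = _EPS
            s = math.sqrt(s2)
            theta = math.degrees(math.acos(c))
            dev = theta - theta0
            dVdth = 2.0 * K_a * dev / sigma_a * math.exp(-dev * dev / sigma_a)
            pref = -dVdth * _RAD2DEG
            inab = 1.0 / (na * nb)
            ina2 = c / (na * na)
            inb2 = c / (nb * nb)
            gix = -(bx * inab - ax * ina2) / s
            giy = -(by * inab - ay * ina2) / s
            giz = -(bz * inab - az * ina2) / s
            gkx = -(ax * inab - bx * inb2) / s
            gky = -(ay * inab - by * inb2) / s
            gkz = -(az * inab - bz * inb2) / s
            forces[i, 0] += pref * gix
            forces[i, 1] += pref * giy
            forces[i, 2] += pref * giz
            forces[i + 1, 0] += pref * (-(gix + gkx))
            forces[i + 1, 1] += pref * (-(giy + gky))
            forces[i + 1, 2] += pref * (-(giz + gkz))
            forces[i + 2, 0] += pref * gkx
            forces[i + 2, 1] += pref * gky
            forces[i + 2, 2] += pref * gkz

        # dihedral restraints on consecutive quadruplets
        for i in range(n - 3):
            b1x = pos[i + 1, 0] - pos[i, 0]
            b1y = pos[i + 1, 1] - pos[i, 1]
            b1z = pos[i + 1, 2] - pos[i, 2]
            b2x = pos[i + 2, 0] - pos[i + 1, 0]
            b2y = pos[i + 2, 1] - pos[i + 1, 1]
            b2z = pos[i + 2, 2] - pos[i + 1, 2]
            b3x = pos[i + 3, 0] - pos[i + 2, 0]
            b3y = pos[i + 3, 1] - pos[i + 2, 1]
            b3z = pos[i + 3, 2] - pos[i + 2, 2]
            n1x = b1y * b2z - b1z * b2y
            n1y = b1z * b2x - b1x * b2z
            n1z = b1x * b2y - b1y * b2x
            n2x = b2y * b3z - b2z * b3y
            n2y = b2z * b3x - b2x * b3z
            n2z = b2x * b3y - b2y * b3x
            nb2 = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
            n1sq = n1x * n1x + n1y * n1y + n1z * n1z
            n2sq = n2x * n2x + n2y * n2y + n2z * n2z
            if nb2 < _EPS or n1sq < _EPS or n2sq < _EPS:
                continue
            cosp = n1x * n2x + n1y * n2y + n1z * n2z
            cx = n1y * n2z - n1z * n2y
            cy = n1z * n2x - n1x * n2z
            cz = n1x * n2y - n1y * n2x
            sinp = (cx * b2x + cy * b2y + cz * b2z) / nb2
            phi = math.degrees(math.atan2(sinp, cosp))
            dev = _wrap_deg(phi - phi0)
            dVdph = 2.0 * K_d * dev / sigma_d * math.exp(-dev * dev / sigma_d)
            pref = -dVdph * _RAD2DEG
            fa = -nb2 / n1sq
            fl = nb2 / n2sq
            gax = fa * n1x
            gay = fa * n1y
            gaz = fa * n1z
            glx = fl * n2x
            gly = fl * n2y
            glz = fl * n2z
            s12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
            s32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
            gjx = -(1.0 + s12) * gax + s32 * glx
            gjy = -(1.0 + s12) * gay + s32 * gly
            gjz = -(1.0 + s12) * gaz + s32 * glz
            gkx = s12 * gax - (1.0 + s32) * glx
            gky = s12 * gay - (1.0 + s32) * gly
            gkz = s12 * gaz - (1.0 + s32) * glz
            forces[i, 0] += pref * gax
            forces[i, 1] += pref * gay
            forces[i, 2] += pref * gaz
            forces[i + 1, 0] += pref * gjx
            forces[i + 1, 1] += pref * gjy
            forces[i + 1, 2] += pref * gjz
            forces[i + 2, 0] += pref * gkx
            forces[i + 2, 1] += pref * gky
            forces[i + 2, 2] += pref * gkz
            forces[i + 3, 0] += pref * glx
            forces[i + 3, 1] += pref * gly
            forces[i + 3, 2] += pref * glz
    return 0


@njit(cache=False)
def run_steps(pos, noise, mobility_dt,
              box_x, box_y, box_z,
              plane_z, depth, inv2w2, com_coupling,
              bond_k, bond_r0,
              use_restraints, K_a, theta0, sigma_a, K_d, phi0, sigma_d):
    """Advance ``noise.shape[0]`` Euler-Maruyama steps in place.

    ``noise`` must already be scaled to sqrt(2 kB T dt / gamma);
    ``mobility_dt`` is dt/gamma. xy is wrapped periodically, z reflects
    at 0 and ``box_z``. Returns 1 if a non-finite force appeared.
    """
    n_steps = noise.shape[0]
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    for t in range(n_steps):
        compute_forces(pos, forces,
                       plane_z, depth, inv2w2, com_coupling,
                       bond_k, bond_r0,
                       use_restraints, K_a, theta0, sigma_a, K_d, phi0, sigma_d)
        for i in range(n):
            for c in range(3):
                f = forces[i, c]
                if not math.isfinite(f):
                    return 1
                pos[i, c] += f * mobility_dt + noise[t, i, c]
            # periodic xy
            pos[i, 0] = pos[i, 0] % box_x
            pos[i, 1] = pos[i, 1] % box_y
            # reflecting walls in z
            if pos[i, 2] < 0.0:
                pos[i, 2] = -pos[i, 2]
            elif pos[i, 2] > box_z:
                pos[i, 2] = 2.0 * box_z - pos[i, 2]
    return 0
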