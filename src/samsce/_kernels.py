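"""Numba kernels for force assembly and explicit Euler integration.

All node state lives in flat arrays (see :mod:`samsce.tissue`).  Each ring
edge is treated as a single linear spring of stiffness ``k_lin``; each wall
node carries a rotational spring acting on the angle formed with its two ring
neighbours.  Morse interactions run over precomputed pair lists.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def compute_forces(pos, ring_prev, ring_next, k_bend, theta_eq,
                   k_lin, ell,
                   iw_pairs, iwU, iwW, iwXi, iwGa,
                   ii_pairs, iiU, iiW, iiXi, iiGa,
                   wwd_pairs, wwdU, wwdW, wwdXi, wwdGa, wwd_cutoff,
                   adh_pairs, k_adh, ell_adh,
                   out):
    n = pos.shape[0]
    for i in range(n):
        out[i, 0] = 0.0
        out[i, 1] = 0.0

    # linear wall springs (each edge once, from node j to its ring successor)
    for j in range(n):
        nx = ring_next[j]
        if nx < 0:
            continue
        dx = pos[nx, 0] - pos[j, 0]
        dy = pos[nx, 1] - pos[j, 1]
        r = math.sqrt(dx * dx + dy * dy)
        if r < 1e-12:
            continue
        f = k_lin * (r - ell) / r
        out[j, 0] += f * dx
        out[j, 1] += f * dy
        out[nx, 0] -= f * dx
        out[nx, 1] -= f * dy

    # rotational springs at each wall node
    for j in range(n):
        p = ring_prev[j]
        q = ring_next[j]
        if p < 0 or k_bend[j] == 0.0:
            continue
        ax = pos[p, 0] - pos[j, 0]
        ay = pos[p, 1] - pos[j, 1]
        bx = pos[q, 0] - pos[j, 0]
        by = pos[q, 1] - pos[j, 1]
        ra = math.sqrt(ax * ax + ay * ay)
        rb = math.sqrt(bx * bx + by * by)
        if ra < 1e-12 or rb < 1e-12:
            continue
        cosT = (ax * bx + ay * by) / (ra * rb)
        if cosT > 1.0:
            cosT = 1.0
        elif cosT < -1.0:
            cosT = -1.0
        theta = math.acos(cosT)
        sinT = math.sqrt(max(1.0 - cosT * cosT, 0.0))
        if sinT < 1e-8:
            continue
        coef = -k_bend[j] * (theta - theta_eq[j])
        inv = 1.0 / sinT
        gax = (cosT * ax / ra - bx / rb) / ra * inv
        gay = (cosT * ay / ra - by / rb) / ra * inv
        gbx = (cosT * bx / rb - ax / ra) / rb * inv
        gby = (cosT * by / rb - ay / ra) / rb * inv
        out[p, 0] += coef * gax
        out[p, 1] += coef * gay
        out[q, 0] += coef * gbx
        out[q, 1] += coef * gby
        out[j, 0] -= coef * (gax + gbx)
        out[j, 1] -= coef * (gay + gby)

    # Morse interactions: internal-wall (turgor), internal-internal
    # (cytoplasm pressure), cross-cell wall-wall (volume exclusion)
    for t in range(3):
        if t == 0:
            pairs, U, W, xi, ga, cut = iw_pairs, iwU, iwW, iwXi, iwGa, 1e30
        elif t == 1:
            pairs, U, W, xi, ga, cut = ii_pairs, iiU, iiW, iiXi, iiGa, 1e30
        else:
            pairs, U, W, xi, ga, cut = (wwd_pairs, wwdU, wwdW, wwdXi, wwdGa,
                                        wwd_cutoff)
        for k in range(pairs.shape[0]):
            a = pairs[k, 0]
            b = pairs[k, 1]
            dx = pos[a, 0] - pos[b, 0]
            dy = pos[a, 1] - pos[b, 1]
            r = math.sqrt(dx * dx + dy * dy)
            if r < 1e-12 or r > cut:
                continue
            # dE/dr; force on a = -dE/dr * (a-b)/r
            dEdr = -U / xi * math.exp(-r / xi) + W / ga * math.exp(-r / ga)
            f = -dEdr / r
            out[a, 0] += f * dx
            out[a, 1] += f * dy
            out[b, 0] -= f * dx
            out[b, 1] -= f * dy

    # middle-lamella adhesion springs
    for k in range(adh_pairs.shape[0]):
        a = adh_pairs[k, 0]
        b = adh_pairs[k, 1]
        dx = pos[b, 0] - pos[a, 0]
        dy = pos[b, 1] - pos[a, 1]
        r = math.sqrt(dx * dx + dy * dy)
        if r < 1e-12:
            continue
        f = k_adh * (r - ell_adh) / r
        out[a, 0] += f * dx
        out[a, 1] += f * dy
        out[b, 0] -= f * dx
        out[b, 1] -= f * dy


@njit(cache=True, fastmath=True)
def integrate(pos, eta, n_steps, dt,
              ring_prev, ring_next, k_bend, theta_eq, k_lin, ell,
              iw_pairs, iwU, iwW, iwXi, iwGa,
              ii_pairs, iiU, iiW, iiXi, iiGa,
              wwd_pairs, wwdU, wwdW, wwdXi, wwdGa, wwd_cutoff,
              adh_pairs, k_adh, ell_adh,
              forces):
    """Overdamped explicit Euler: pos += (dt/eta) * force, n_steps times."""
    n = pos.shape[0]
    for _ in range(n_steps):
        compute_forces(pos, ring_prev, ring_next, k_bend, theta_eq,
                       k_lin, ell,
                       iw_pairs, iwU, iwW, iwXi, iwGa,
                       ii_pairs, iiU, iiW, iiXi, iiGa,
                       wwd_pairs, wwdU, wwdW, wwdXi, wwdGa, wwd_cutoff,
                       adh_pairs, k_adh, ell_adh,
                       forces)
        for i in range(n):
            s = dt / eta[i]
            pos[i, 0] += s * forces[i, 0]
            pos[i, 1] += s * forces[i, 1]
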