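"""Numba-jitted photon transport kernel.

Serial weighted-packet Monte Carlo on a tetrahedral mesh: straight-segment
ray tracing across element faces, absorption-weighted deposition at
interaction sites (spread to the containing element's nodes by barycentric
coordinates), Henyey-Greenstein scattering, Russian roulette, and Fresnel
reflection at the external boundary.  All state is float64 and the run is
bit-reproducible for a given seed.
"""

import numpy as np
from numba import njit

C_MM_PER_PS = 0.299792458


@njit(cache=True, inline="always", fastmath=True)
def _hg_cosine(g, xi):
    if g < 1e-12:
        return 2.0 * xi - 1.0
    f = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    ct = (1.0 + g * g - f * f) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True, inline="always", fastmath=True)
def _fresnel_r(cos_i, n1, n2):
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = (n1 / n2) * (n1 / n2) * sin_i2
    if sin_t2 >= 1.0:
        return 1.0
    cos_t = np.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, fastmath=True)
def run_photons(
    elements,      # (M,4) int64
    face_n,        # (M,4,3) outward face normals
    face_off,      # (M,4) plane offsets n.x = off
    neighbors,     # (M,4) int64, -1 = boundary
    tinv,          # (M,3,3) barycentric inverse maps
    v0,            # (M,3) element first vertices
    n_nodes,
    mu_a, mu_s, g, n_refr,
    x0, y0, z0, ux0, uy0, uz0, start_elem,
    n_photons, seed,
    gate_width, n_gates, t0_gate,
    w_floor, survive_p,
):
    np.random.seed(seed)
    mu_t = mu_a + mu_s
    inv_c = n_refr / C_MM_PER_PS  # ps per mm of path
    t_max = t0_gate + gate_width * n_gates
    dep = np.zeros((n_nodes, n_gates))
    w_dep = 0.0
    w_exit = 0.0
    w_kill = 0.0
    w_expire = 0.0
    w_lost = 0.0
    lost_x = 0.0
    lost_y = 0.0
    lost_z = 0.0

    for _ in range(n_photons):
        px, py, pz = x0, y0, z0
        ux, uy, uz = ux0, uy0, uz0
        elem = start_elem
        w = 1.0
        t = 0.0
        alive = True
        while alive:
            s = -np.log(np.random.random()) / mu_t  # scattering step, mm
            # --- trace the straight segment across faces ---
            while s > 0.0 and alive:
                t_exit = 1e308
                f_hit = -1
                for f in range(4):
                    nx = face_n[elem, f, 0]
                    ny = face_n[elem, f, 1]
                    nz = face_n[elem, f, 2]
                    denom = nx * ux + ny * uy + nz * uz
                    if denom > 1e-12:
                        d = (face_off[elem, f] - (nx * px + ny * py + nz * pz)) / denom
                        if d < -1e-9:
                            continue
                        if d < 0.0:
                            d = 0.0
                        if d < t_exit:
                            t_exit = d
                            f_hit = f
                if s < t_exit:
                    px += s * ux
                    py += s * uy
                    pz += s * uz
                    t += s * inv_c
                    s = 0.0
                elif f_hit < 0:
                    # geometry inconsistency: record and drop the packet
                    w_lost += w
                    lost_x, lost_y, lost_z = px, py, pz
                    alive = False
                else:
                    px += t_exit * ux
                    py += t_exit * uy
                    pz += t_exit * uz
                    t += t_exit * inv_c
                    s -= t_exit
                    if t >= t_max:
                        w_expire += w
                        alive = False
                        break
                    nb = neighbors[elem, f_hit]
                    if nb >= 0:
                        elem = nb
                    else:
                        # external boundary: Fresnel reflect or escape
                        nx = face_n[elem, f_hit, 0]
                        ny = face_n[elem, f_hit, 1]
                        nz = face_n[elem, f_hit, 2]
                        cos_i = ux * nx + uy * ny + uz * nz
                        if cos_i < 0.0:
                            cos_i = 0.0
                        refl = _fresnel_r(cos_i, n_refr, 1.0)
                        if np.random.random() < refl:
                            ux -= 2.0 * cos_i * nx
                            uy -= 2.0 * cos_i * ny
                            uz -= 2.0 * cos_i * nz
                            # nudge off the face to avoid re-hitting it
                            px -= 1e-9 * nx
                            py -= 1e-9 * ny
                            pz -= 1e-9 * nz
                        else:
                            w_exit += w
                            alive = False
            if not alive:
                break
            # --- interaction: absorb a fraction, then scatter ---
            if t >= t_max:
                w_expire += w
                break
            gate = int((t - t0_gate) / gate_width)
            if gate < 0:
                gate = 0
            if gate >= n_gates:
                gate = n_gates - 1
            dw = w * mu_a / mu_t
            dx = px - v0[elem, 0]
            dy = py - v0[elem, 1]
            dz = pz - v0[elem, 2]
            b1 = tinv[elem, 0, 0] * dx + tinv[elem, 0, 1] * dy + tinv[elem, 0, 2] * dz
            b2 = tinv[elem, 1, 0] * dx + tinv[elem, 1, 1] * dy + tinv[elem, 1, 2] * dz
            b3 = tinv[elem, 2, 0] * dx + tinv[elem, 2, 1] * dy + tinv[elem, 2, 2] * dz
            b0 = 1.0 - b1 - b2 - b3
            dep[elements[elem, 0], gate] += dw * b0
            dep[elements[elem, 1], gate] += dw * b1
            dep[elements[elem, 2], gate] += dw * b2
            dep[elements[elem, 3], gate] += dw * b3
            w_dep += dw
            w -= dw
            if w < w_floor:
                if np.random.random() < survive_p:
                    w /= survive_p
                else:
                    w_kill += w
                    break
            # scatter: HG polar angle, uniform azimuth
            ct = _hg_cosine(g, np.random.random())
            st = np.sqrt(1.0 - ct * ct)
            phi = 2.0 * np.pi * np.random.random()
            cp = np.cos(phi)
            sp = np.sin(phi)
            if abs(uz) > 0.99999:
                nux = st * cp
                nuy = st * sp
                nuz = ct * (1.0 if uz > 0.0 else -1.0)
            else:
                den = np.sqrt(1.0 - uz * uz)
                nux = st * (ux * uz * cp - uy * sp) / den + ux * ct
                nuy = st * (uy * uz * cp + ux * sp) / den + uy * ct
                nuz = -st * cp * den + uz * ct
            nrm = np.sqrt(nux * nux + nuy * nuy + nuz * nuz)
            ux = nux / nrm
            uy = nuy / nrm
            uz = nuz / nrm
    return dep, w_dep, w_exit, w_kill, w_expire, w_lost, lost_x, lost_y, lost_z
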