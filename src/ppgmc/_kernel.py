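"""Numba kernel for voxel photon transport.

Semantics (MCML-family voxel transport, survival-weighting variant): scattering
distances are sampled as a dimensionless depth s ~ Exp(1) consumed against
the per-voxel scattering coefficient, while absorption attenuates the
photon weight continuously as exp(-mua * dl) along every traversed segment
(the microscopic Beer-Lambert rule).  This removes all absorption-event
randomness: a detected photon's weight is exactly
exp(-sum_i mua_i * l_i) given its geometric path, which is what makes small
systole/diastole reflectance differences resolvable at desk-scale photon
budgets.  Fresnel reflection/refraction is applied at the z = 0 air-tissue
face only; lateral and bottom faces terminate photons as escapes.
"""

import numpy as np
from numba import njit

# ledger slots
DETECTED, ABSORBED, ESC_TOP, ESC_SIDE, SPECULAR, ROULETTE = 0, 1, 2, 3, 4, 5
N_LEDGER = 6

_BIG = 1.0e30


@njit(cache=True)
def hg_cos(g, u):
    """Inverse-CDF sample of the Henyey-Greenstein deflection cosine."""
    if abs(g) < 1e-7:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True)
def hg_mean(g, n, seed):
    """Empirical mean deflection cosine over n Henyey-Greenstein draws."""
    np.random.seed(seed)
    s = 0.0
    for _ in range(n):
        s += hg_cos(g, np.random.random())
    return s / n


@njit(cache=True)
def fresnel_R(cos_i, n1, n2):
    """Unpolarized Fresnel reflectance for incidence cosine cos_i (n1 -> n2)."""
    if n1 == n2:
        return 0.0
    if cos_i > 1.0:
        cos_i = 1.0
    sin_t2 = (n1 / n2) * (n1 / n2) * (1.0 - cos_i * cos_i)
    if sin_t2 >= 1.0:
        return 1.0  # total internal reflection
    cos_t = np.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def run_batch(labels, h, mua_a, mus_a, g_a, n_a, n_ambient,
              src_x, src_y, sigma, ux0, uy0, uz0,
              n_photons, seed,
              det_cx, det_cy, det_r2, det_pool, det_accept,
              r_thresh, r_surv,
              rec_w, rec_path, rec_total, rec_x, rec_y, rec_det,
              hist, hist_dr,
              fluence, use_fluence):
    """Trace one batch; fills record buffers, returns (n_records, ledger)."""
    np.random.seed(seed)
    nx, ny, nz = labels.shape
    lx = nx * h
    ly = ny * h
    n_media = mua_a.shape[0]
    n_det = det_cx.shape[0]
    n_hist = hist.shape[0]
    ledger = np.zeros(N_LEDGER)
    ppath = np.zeros(n_media)
    n_rec = 0

    for _ in range(n_photons):
        # --- launch: Gaussian lateral profile, fixed incidence direction
        x = src_x + sigma * np.random.standard_normal()
        y = src_y + sigma * np.random.standard_normal()
        while x <= 0.0 or x >= lx or y <= 0.0 or y >= ly:
            x = src_x + sigma * np.random.standard_normal()
            y = src_y + sigma * np.random.standard_normal()
        z = 0.0
        ix = int(x / h)
        iy = int(y / h)
        iz = 0
        if ix >= nx:
            ix = nx - 1
        if iy >= ny:
            iy = ny - 1
        lab = labels[ix, iy, iz]
        # deterministic specular split at entry
        n_med = n_a[lab]
        cos_i = uz0
        R = fresnel_R(cos_i, n_ambient, n_med)
        w = 1.0 - R
        ledger[SPECULAR] += R
        if n_ambient != n_med:
            eta = n_ambient / n_med
            sin_t2 = eta * eta * (1.0 - cos_i * cos_i)
            cos_t = np.sqrt(1.0 - sin_t2)
            ux = ux0 * eta
            uy = uy0 * eta
            uz = cos_t
        else:
            ux, uy, uz = ux0, uy0, uz0

        for m in range(n_media):
            ppath[m] = 0.0
        p_abs = 0.0
        p_tot = 0.0
        alive = True

        while alive:
            s = -np.log(np.random.random())  # dimensionless scattering depth
            while s > 0.0 and alive:
                lab = labels[ix, iy, iz]
                mus_v = mus_a[lab]
                mua_v = mua_a[lab]
                # distances to the three voxel faces ahead
                if ux > 0.0:
                    tx = ((ix + 1) * h - x) / ux
                elif ux < 0.0:
                    tx = (ix * h - x) / ux
                else:
                    tx = _BIG
                if uy > 0.0:
                    ty = ((iy + 1) * h - y) / uy
                elif uy < 0.0:
                    ty = (iy * h - y) / uy
                else:
                    ty = _BIG
                if uz > 0.0:
                    tz = ((iz + 1) * h - z) / uz
                elif uz < 0.0:
                    tz = (iz * h - z) / uz
                else:
                    tz = _BIG
                axis = 0
                t_b = tx
                if ty < t_b:
                    t_b = ty
                    axis = 1
                if tz < t_b:
                    t_b = tz
                    axis = 2
                if t_b < 0.0:
                    t_b = 0.0
                if mus_v > 0.0:
                    d_int = s / mus_v
                else:
                    d_int = _BIG
                if d_int < t_b:
                    step = d_int
                    hit_boundary = False
                else:
                    step = t_b
                    hit_boundary = True
                if mua_v > 0.0 and step > 0.0:
                    w_new = w * np.exp(-mua_v * step)
                    d_dep = w - w_new
                    p_abs += d_dep
                    if use_fluence:
                        fluence[ix, iy, iz] += d_dep
                    w = w_new
                ppath[lab] += step
                p_tot += step
                x += ux * step
                y += uy * step
                z += uz * step
                if hit_boundary:
                    s -= step * mus_v
                    if axis == 0:
                        if ux > 0.0:
                            ix += 1
                            if ix >= nx:
                                ledger[ESC_SIDE] += w
                                alive = False
                        else:
                            ix -= 1
                            if ix < 0:
                                ledger[ESC_SIDE] += w
                                alive = False
                    elif axis == 1:
                        if uy > 0.0:
                            iy += 1
                            if iy >= ny:
                                ledger[ESC_SIDE] += w
                                alive = False
                        else:
                            iy -= 1
                            if iy < 0:
                                ledger[ESC_SIDE] += w
                                alive = False
                    else:
                        if uz > 0.0:
                            iz += 1
                            if iz >= nz:
                                ledger[ESC_SIDE] += w
                                alive = False
                        else:
                            if iz == 0:
                                # air-tissue surface
                                cos_i = -uz
                                n1 = n_a[lab]
                                R = fresnel_R(cos_i, n1, n_ambient)
                                if R > 0.0 and np.random.random() < R:
                                    uz = -uz  # internal reflection
                                else:
                                    # transmit into ambient
                                    if n1 != n_ambient:
                                        eta = n1 / n_ambient
                                        sin_t2 = eta * eta * (1.0 - cos_i * cos_i)
                                        cos_t = np.sqrt(1.0 - sin_t2)
                                    else:
                                        cos_t = cos_i
                                    alive = False
                                    det_id = -1
                                    for k in range(n_det):
                                        dx = x - det_cx[k]
                                        dy = y - det_cy[k]
                                        if (dx * dx + dy * dy <= det_r2[k]
                                                and cos_t >= det_accept[k]):
                                            det_id = det_pool[k]
                                            break
                                    if det_id >= 0:
                                        ledger[DETECTED] += w
                                        rec_w[n_rec] = w
                                        for m in range(n_media):
                                            rec_path[n_rec, m] = ppath[m]
                                        rec_total[n_rec] = p_tot
                                        rec_x[n_rec] = x
                                        rec_y[n_rec] = y
                                        rec_det[n_rec] = det_id
                                        n_rec += 1
                                    else:
                                        ledger[ESC_TOP] += w
                                        if n_hist > 0:
                                            dxs = x - src_x
                                            dys = y - src_y
                                            rb = int(np.sqrt(dxs * dxs + dys * dys) / hist_dr)
                                            if rb < n_hist:
                                                hist[rb] += w
                            else:
                                iz -= 1
                else:
                    # scattering event
                    s = 0.0
                    g = g_a[lab]
                    cost = hg_cos(g, np.random.random())
                    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
                    phi = 2.0 * np.pi * np.random.random()
                    cosp = np.cos(phi)
                    sinp = np.sin(phi)
                    if abs(uz) > 0.99999:
                        ux = sint * cosp
                        uy = sint * sinp
                        uz = cost if uz > 0.0 else -cost
                    else:
                        den = np.sqrt(1.0 - uz * uz)
                        ux_n = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
                        uy_n = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
                        uz_n = -sint * cosp * den + uz * cost
                        norm = np.sqrt(ux_n * ux_n + uy_n * uy_n + uz_n * uz_n)
                        ux = ux_n / norm
                        uy = uy_n / norm
                        uz = uz_n / norm
                    # Russian roulette on low weight
                    if w < r_thresh:
                        if np.random.random() < r_surv:
                            gain = w / r_surv - w
                            ledger[ROULETTE] -= gain
                            w = w / r_surv
                        else:
                            ledger[ROULETTE] += w
                            alive = False
        ledger[ABSORBED] += p_abs
    return n_rec, ledger
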