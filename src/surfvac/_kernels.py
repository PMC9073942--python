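"""Numba-compiled scalar kernels: model potentials and the Langevin propagator.

The potential presets are dispatched on an integer id so a single compiled
propagator serves all model systems:

    0  double_well_1d    U(x) = a (x^2 - 1)^2
    1  three_basin_2d    quartic confinement minus three Gaussian wells
    2  detachment_3d     coupled (coordination, distance, angle) landscape

Parameter vectors (``pp``) are packed by :mod:`surfvac.model_systems`; the
layouts are documented there next to the builders.
"""

import math

import numba as nb
import numpy as np

TWO_PI = 2.0 * math.pi

# hills with exponent beyond this are skipped (tail < 2.4e-16 of the height)
_EXP_CUT = 36.0


@nb.njit(cache=True, inline="always")
def _wrap(x):
    return (x + math.pi) % TWO_PI - math.pi


@nb.njit(cache=True)
def pot_energy(pid, pp, s):
    if pid == 0:
        x = s[0]
        return pp[0] * (x * x - 1.0) ** 2
    elif pid == 1:
        # pp: [k_conf, L, d1,x1,y1, d2,x2,y2, d3,x3,y3, sigma]
        x, y = s[0], s[1]
        L = pp[1]
        e = pp[0] * ((x / L) ** 4 + (y / L) ** 4)
        sig2 = pp[11] * pp[11]
        for i in range(3):
            dx = x - pp[3 + 3 * i]
            dy = y - pp[4 + 3 * i]
            e -= pp[2 + 3 * i] * math.exp(-(dx * dx + dy * dy) / (2.0 * sig2))
        return e
    else:
        return _detach_energy(pp, s[0], s[1], s[2])


@nb.njit(cache=True)
def _detach_energy(pp, c, z, th):
    # pp layout: [0] k_couple [1] cmax [2] zc [3] wz
    #            [4] a_cryst [5] wc [6] wzw [7] wth [8] c0
    #            [9] a_flip
    #            [10] a_dis [11] dis_c [12] dis_z [13] dis_wc [14] dis_wz
    #            [15] a_det [16] det_z [17] det_wc [18] det_wz
    #            [19] wall_k [20] z_lo [21] z_hi [22] c_lo [23] c_hi
    mu = pp[1] * 0.5 * (1.0 - math.tanh((z - pp[2]) / pp[3]))
    e = pp[0] * (c - mu) ** 2
    dc = (c - pp[8]) / pp[5]
    dz = z / pp[6]
    base = -0.5 * (dc * dc + dz * dz)
    # angular localisation via a von Mises factor (exactly periodic, smooth
    # at the antipode); kappa = 1/wth^2 matches a Gaussian of width wth
    kappa = 1.0 / (pp[7] * pp[7])
    e -= pp[4] * math.exp(base + kappa * (math.cos(th - math.pi) - 1.0))
    e -= pp[9] * math.exp(base + kappa * (math.cos(th) - 1.0))
    ddc = (c - pp[11]) / pp[13]
    ddz = (z - pp[12]) / pp[14]
    e -= pp[10] * math.exp(-0.5 * (ddc * ddc + ddz * ddz))
    tdc = c / pp[17]
    tdz = (z - pp[16]) / pp[18]
    e -= pp[15] * math.exp(-0.5 * (tdc * tdc + tdz * tdz))
    # quartic walls
    if z < pp[20]:
        e += pp[19] * (pp[20] - z) ** 4
    elif z > pp[21]:
        e += pp[19] * (z - pp[21]) ** 4
    if c < pp[22]:
        e += pp[19] * (pp[22] - c) ** 4
    elif c > pp[23]:
        e += pp[19] * (c - pp[23]) ** 4
    return e


@nb.njit(cache=True)
def pot_grad(pid, pp, s, g):
    if pid == 0:
        x = s[0]
        g[0] = 4.0 * pp[0] * x * (x * x - 1.0)
    elif pid == 1:
        x, y = s[0], s[1]
        L = pp[1]
        g[0] = pp[0] * 4.0 * x**3 / L**4
        g[1] = pp[0] * 4.0 * y**3 / L**4
        sig2 = pp[11] * pp[11]
        for i in range(3):
            dx = x - pp[3 + 3 * i]
            dy = y - pp[4 + 3 * i]
            w = pp[2 + 3 * i] * math.exp(-(dx * dx + dy * dy) / (2.0 * sig2))
            g[0] += w * dx / sig2
            g[1] += w * dy / sig2
    else:
        _detach_grad(pp, s[0], s[1], s[2], g)


@nb.njit(cache=True)
def _detach_grad(pp, c, z, th, g):
    sech2 = 1.0 / math.cosh((z - pp[2]) / pp[3]) ** 2
    mu = pp[1] * 0.5 * (1.0 - math.tanh((z - pp[2]) / pp[3]))
    dmu_dz = -pp[1] * 0.5 * sech2 / pp[3]
    gc = 2.0 * pp[0] * (c - mu)
    gz = -2.0 * pp[0] * (c - mu) * dmu_dz
    gth = 0.0

    dc = (c - pp[8]) / pp[5]
    dz = z / pp[6]
    base = -0.5 * (dc * dc + dz * dz)
    kappa = 1.0 / (pp[7] * pp[7])

    w = pp[4] * math.exp(base + kappa * (math.cos(th - math.pi) - 1.0))
    gc += w * dc / pp[5]
    gz += w * dz / pp[6]
    gth += w * kappa * math.sin(th - math.pi)

    w = pp[9] * math.exp(base + kappa * (math.cos(th) - 1.0))
    gc += w * dc / pp[5]
    gz += w * dz / pp[6]
    gth += w * kappa * math.sin(th)

    ddc = (c - pp[11]) / pp[13]
    ddz = (z - pp[12]) / pp[14]
    w = pp[10] * math.exp(-0.5 * (ddc * ddc + ddz * ddz))
    gc += w * ddc / pp[13]
    gz += w * ddz / pp[14]

    tdc = c / pp[17]
    tdz = (z - pp[16]) / pp[18]
    w = pp[15] * math.exp(-0.5 * (tdc * tdc + tdz * tdz))
    gc += w * tdc / pp[17]
    gz += w * tdz / pp[18]

    if z < pp[20]:
        gz -= 4.0 * pp[19] * (pp[20] - z) ** 3
    elif z > pp[21]:
        gz += 4.0 * pp[19] * (z - pp[21]) ** 3
    if c < pp[22]:
        gc -= 4.0 * pp[19] * (pp[22] - c) ** 3
    elif c > pp[23]:
        gc += 4.0 * pp[19] * (c - pp[23]) ** 3

    g[0] = gc
    g[1] = gz
    g[2] = gth


@nb.njit(cache=True)
def pot_energy_many(pid, pp, pts, out):
    for i in range(pts.shape[0]):
        out[i] = pot_energy(pid, pp, pts[i])


@nb.njit(cache=True)
def pot_grad_many(pid, pp, pts, out):
    for i in range(pts.shape[0]):
        pot_grad(pid, pp, pts[i], out[i])


@nb.njit(cache=True)
def _bias_energy_at(s, periodic, hill_c, hill_w, hill_h, n_hills):
    nd = s.shape[0]
    V = 0.0
    for k in range(n_hills):
        e = 0.0
        for d in range(nd):
            dx = s[d] - hill_c[k, d]
            if periodic[d]:
                dx = _wrap(dx)
            zz = dx / hill_w[k, d]
            e += 0.5 * zz * zz
        if e < _EXP_CUT:
            V += hill_h[k] * math.exp(-e)
    return V


@nb.njit(cache=True)
def simulate(
    pid,
    pp,
    periodic,
    lo,
    hi,
    s0,
    dt,
    kT,
    D,
    n_steps,
    stride,
    seed,
    pace,
    widths,
    height0,
    gamma,
    hill_c,
    hill_w,
    hill_h,
    hill_t,
    n_hills0,
    stop_lo,
    stop_hi,
    stop_count,
    rec_t,
    rec_s,
):
    """Euler-Maruyama overdamped Langevin propagation with optional on-the-fly
    well-tempered hill deposition.

    Returns (status, n_recorded, n_hills). status: 0 ok, 1 stopped in the stop
    box, -step on divergence at that step. Hill arrays must be pre-allocated
    large enough for n_hills0 + n_steps // pace + 1 entries.
    """
    np.random.seed(seed)
    nd = s0.shape[0]
    s = s0.copy()
    g = np.empty(nd)
    n_hills = n_hills0
    guard = 1.0
    rec_t[0] = 0.0
    for d in range(nd):
        rec_s[0, d] = s[d]
    irec = 1
    in_stop = 0
    status = 0
    for step in range(1, n_steps + 1):
        pot_grad(pid, pp, s, g)
        # accumulate bias force on top of the physical force
        for k in range(n_hills):
            e = 0.0
            for d in range(nd):
                dx = s[d] - hill_c[k, d]
                if periodic[d]:
                    dx = _wrap(dx)
                zz = dx / hill_w[k, d]
                e += 0.5 * zz * zz
            if e < _EXP_CUT:
                ge = hill_h[k] * math.exp(-e)
                for d in range(nd):
                    dx = s[d] - hill_c[k, d]
                    if periodic[d]:
                        dx = _wrap(dx)
                    g[d] += -ge * dx / (hill_w[k, d] * hill_w[k, d])
        for d in range(nd):
            s[d] += (
                -(D[d] / kT) * g[d] * dt
                + math.sqrt(2.0 * D[d] * dt) * np.random.normal()
            )
            if periodic[d]:
                s[d] = (s[d] - lo[d]) % (hi[d] - lo[d]) + lo[d]
                if s[d] >= hi[d]:  # float modulo can land exactly on hi
                    s[d] = lo[d]
            elif s[d] < lo[d] - guard or s[d] > hi[d] + guard:
                return -step, irec, n_hills
        if pace > 0 and step % pace == 0:
            V = _bias_energy_at(s, periodic, hill_c, hill_w, hill_h, n_hills)
            h = height0 * math.exp(-V / ((gamma - 1.0) * kT))
            for d in range(nd):
                hill_c[n_hills, d] = s[d]
                hill_w[n_hills, d] = widths[d]
            hill_h[n_hills] = h
            hill_t[n_hills] = step * dt
            n_hills += 1
        if step % stride == 0:
            rec_t[irec] = step * dt
            for d in range(nd):
                rec_s[irec, d] = s[d]
            irec += 1
        if stop_count > 0:
            inside = True
            for d in range(nd):
                if s[d] < stop_lo[d] or s[d] >= stop_hi[d]:
                    inside = False
                    break
            if inside:
                in_stop += 1
                if in_stop >= stop_count:
                    status = 1
                    break
            else:
                in_stop = 0
    return status, irec, n_hills
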