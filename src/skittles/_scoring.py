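"""Vectorised throw-scoring kernel.

Scores batches of ball launches against the damped two-spring flight model:
for each launch the flight is sampled coarsely at 1 ms over one oscillation
period, truncated at the first contact with the post, and the minimum
distance to the target is refined per local basin by golden-section search
on the squared distance (well below 1e-4 s resolution).  Post contact is
located by bisection; grazing contacts that fall between coarse samples are
caught by refining local minima of the post distance.

The kernel is strictly per-row scalar code, so scoring a state alone or
inside any batch yields bit-identical results.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_COARSE_DT = 1e-3  # s
_GOLDEN_ITERS = 40  # shrinks a 2 ms bracket below 1e-11 s
_BISECT_ITERS = 50
_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0
_MAX_BASINS = 64


@njit(cache=True)
def _d2(x0, kx, y0, ky, om, tau, t, cx, cy):
    e = math.exp(-t / tau)
    s = e * math.sin(om * t)
    c = e * math.cos(om * t)
    dx = x0 * c + kx * s - cx
    dy = y0 * c + ky * s - cy
    return dx * dx + dy * dy


@njit(cache=True)
def _golden(x0, kx, y0, ky, om, tau, a, b, cx, cy):
    """Golden-section minimum of the squared distance on [a, b]."""
    h = b - a
    x1 = b - _INVPHI * h
    x2 = a + _INVPHI * h
    f1 = _d2(x0, kx, y0, ky, om, tau, x1, cx, cy)
    f2 = _d2(x0, kx, y0, ky, om, tau, x2, cx, cy)
    for _ in range(_GOLDEN_ITERS):
        if f1 < f2:
            b = x2
            x2 = x1
            f2 = f1
            h = b - a
            x1 = b - _INVPHI * h
            f1 = _d2(x0, kx, y0, ky, om, tau, x1, cx, cy)
        else:
            a = x1
            x1 = x2
            f1 = f2
            h = b - a
            x2 = a + _INVPHI * h
            f2 = _d2(x0, kx, y0, ky, om, tau, x2, cx, cy)
    if f1 < f2:
        return x1, f1
    return x2, f2


@njit(cache=True)
def _bisect_contact(x0, kx, y0, ky, om, tau, a, b, cx, cy, r2):
    """Crossing time of the contact circle: d2(a) >= r2 > d2(b)."""
    for _ in range(_BISECT_ITERS):
        mid = 0.5 * (a + b)
        if _d2(x0, kx, y0, ky, om, tau, mid, cx, cy) < r2:
            b = mid
        else:
            a = mid
    return 0.5 * (a + b)


@njit(cache=True)
def _score_kernel(
    x0a, y0a, kxa, kya, om, tau, T, C, S,
    check_post, pxc, pyc, r2, txc, tyc,
    err, tcl, tcon,
):
    n = x0a.size
    m = C.size
    dt = _COARSE_DT
    d2p_row = np.empty(m)
    d2t_row = np.empty(m)
    for i in range(n):
        x0 = x0a[i]
        y0 = y0a[i]
        kx = kxa[i]
        ky = kya[i]

        # -- coarse scan, stopping at the first coarse post contact ---------
        first = m  # index of first coarse sample inside the post
        jend = m
        for j in range(m):
            x = x0 * C[j] + kx * S[j]
            y = y0 * C[j] + ky * S[j]
            dxt = x - txc
            dyt = y - tyc
            d2t_row[j] = dxt * dxt + dyt * dyt
            if check_post:
                dxp = x - pxc
                dyp = y - pyc
                d2p = dxp * dxp + dyp * dyp
                d2p_row[j] = d2p
                if d2p < r2:
                    first = j
                    jend = j + 1
                    break

        # -- contact time ---------------------------------------------------
        t_contact = T
        if check_post:
            if first == 0:
                t_contact = 0.0
            elif first < m:
                t_contact = _bisect_contact(
                    x0, kx, y0, ky, om, tau, (first - 1) * dt, first * dt, pxc, pyc, r2
                )
            # grazing contact between coarse samples, before the first coarse one
            jmax = first if first < m else m
            for j in range(1, jmax - 1):
                v = d2p_row[j]
                if v >= r2 and v <= d2p_row[j - 1] and v <= d2p_row[j + 1] and (
                    v < d2p_row[j - 1] or v < d2p_row[j + 1]
                ):
                    tg, fg = _golden(
                        x0, kx, y0, ky, om, tau, (j - 1) * dt, (j + 1) * dt, pxc, pyc
                    )
                    if fg < r2:
                        tc = _bisect_contact(
                            x0, kx, y0, ky, om, tau, (j - 1) * dt, tg, pxc, pyc, r2
                        )
                        if tc < t_contact:
                            t_contact = tc
        post_hit = t_contact < T
        tcon[i] = t_contact

        # -- minimum distance to the target on [0, t_contact] ---------------
        jv = jend
        if post_hit:
            lastj = int(t_contact / dt + 1e-12) + 1  # samples with t <= t_contact
            if lastj < jv:
                jv = lastj
        if jv < 1:
            jv = 1
        best_f = d2t_row[0]
        best_t = 0.0
        for j in range(1, jv):
            if d2t_row[j] < best_f:
                best_f = d2t_row[j]
                best_t = j * dt
        tend = t_contact if post_hit else T

        # interior basins
        for j in range(1, jv - 1):
            v = d2t_row[j]
            if v <= d2t_row[j - 1] and v <= d2t_row[j + 1] and (
                v < d2t_row[j - 1] or v < d2t_row[j + 1]
            ):
                b = (j + 1) * dt
                if b > t_contact:
                    b = t_contact
                tg, fg = _golden(x0, kx, y0, ky, om, tau, (j - 1) * dt, b, txc, tyc)
                if fg < best_f:
                    best_f = fg
                    best_t = tg
        # start boundary
        if jv >= 2 and d2t_row[0] <= d2t_row[1]:
            b = dt
            if b > tend:
                b = tend
            tg, fg = _golden(x0, kx, y0, ky, om, tau, 0.0, b, txc, tyc)
            if fg < best_f:
                best_f = fg
                best_t = tg
        # end boundary (truncation point or end of the period)
        jl = jv - 1
        a = (jl - 1) * dt if jl >= 1 else 0.0
        if jl == 0 or d2t_row[jl] <= d2t_row[jl - 1] or post_hit:
            tg, fg = _golden(x0, kx, y0, ky, om, tau, a, tend, txc, tyc)
            if fg < best_f:
                best_f = fg
                best_t = tg
            fe = _d2(x0, kx, y0, ky, om, tau, tend, txc, tyc)
            if fe < best_f:
                best_f = fe
                best_t = tend

        err[i] = math.sqrt(best_f)
        tcl[i] = best_t


def score_launches(x0, y0, vx0, vy0, config):
    """Score launches given as parallel arrays; returns (error, post_hit,
    t_closest, t_contact) float/bool arrays."""
    om = config.omega
    tau = config.tau
    T = config.period
    m = int(math.floor(T / _COARSE_DT)) + 1
    tt = np.arange(m) * _COARSE_DT
    env = np.exp(-tt / tau)
    S = env * np.sin(om * tt)
    C = env * np.cos(om * tt)
    kx = (vx0 + x0 / tau) / om
    ky = (vy0 + y0 / tau) / om
    n = x0.size
    err = np.empty(n)
    tcl = np.empty(n)
    tcon = np.empty(n)
    check_post = config.post_radius > 0
    r2 = config.contact_radius**2 if check_post else 0.0
    pxc, pyc = config.post_center
    txc, tyc = config.target_center
    _score_kernel(
        x0, y0, kx, ky, om, tau, T, C, S,
        check_post, pxc, pyc, r2, txc, tyc,
        err, tcl, tcon,
    )
    post_hit = tcon < T
    return err, post_hit, tcl, tcon
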