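"""Compiled per-dt update loop for the coupled motors + cargo system.

One fixed-step iteration performs, in order: (1) spring forces and signed
motor loads from start-of-step positions, (2) Monte Carlo motor events in
random motor order (detach / forward / backward with lattice exclusion and
uniform branch choice at crossing sites), (3) reattachment trials for
detached motors, (4) the Euler-Maruyama cargo update, (5) time advance and
recording/first-passage bookkeeping.

While *all* motors are detached the system is exactly a free Brownian cargo
plus independent Bernoulli(Pi*dt) reattachment trials, so the loop leaps
over such stretches in one move: the number of steps to the next attach
trial is geometric (memoryless, so truncation at recording boundaries and
resampling is exact), and the accumulated thermal displacement over k steps
is N(0, k * 2 kBT dt / gamma) per axis.  This changes no statistics; it only
skips per-dt work.  First passage is detected at dt resolution whenever a
motor is attached and at leap-segment ends (<= one recording stride) during
all-detached free diffusion.

Event probabilities are capped at 1 (an event whose rate times dt exceeds 1
fires with certainty) so that the extreme transient loads that can occur
right after initialization saturate instead of aborting the run; exponents
are clamped to avoid overflow.

All randomness comes from numba's internal Mersenne Twister stream, seeded
once per call and mostly consumed through pre-filled buffers (a speed
optimization), so trajectories are bit-reproducible per seed.
"""

import math

import numpy as np
from numba import njit

DETACHED = -1
_NBUF = 65536  # RNG buffer length (bulk refills are cheaper than scalar draws)


@njit(cache=True)
def _try_attach(
    i, cx, cy, m_mt, m_site,
    minus_x, minus_y, ux, uy,
    n_sites, spacing, seg_len, r0sq,
    cand_mt, cand_proj,
):
    """Reattachment attempt for detached motor i at the current cargo position.

    Uniform choice among MTs within reach r0 of the cargo; attach at the
    lattice site nearest the cargo's projection unless the other motor
    occupies it.  Rare (O(Pi) per second), so scalar RNG draws are fine.
    """
    n_mts = minus_x.shape[0]
    n_motors = m_mt.shape[0]
    cnt = 0
    for m in range(n_mts):
        rx = cx - minus_x[m]
        ry = cy - minus_y[m]
        t = rx * ux[m] + ry * uy[m]
        if t < 0.0:
            t = 0.0
        elif t > seg_len:
            t = seg_len
        ddx = rx - t * ux[m]
        ddy = ry - t * uy[m]
        if ddx * ddx + ddy * ddy <= r0sq:
            cand_mt[cnt] = m
            cand_proj[cnt] = t
            cnt += 1
    if cnt == 0:
        return
    c = int(np.random.random() * cnt)
    m = cand_mt[c]
    xs = cand_proj[c] / spacing
    lo = math.floor(xs)
    s = int(lo) if (xs - lo) <= 0.5 else int(lo) + 1
    if s > n_sites - 1:
        s = n_sites - 1
    for j in range(n_motors):
        if j != i and m_mt[j] == m and m_site[j] == s:
            return
    m_mt[i] = m
    m_site[i] = s


@njit(cache=True, fastmath=True)
def run_core(
    # network geometry (uniform lattice assumed: n_sites sites of 8 nm each)
    minus_x,
    minus_y,
    ux,
    uy,
    n_sites,
    spacing,
    # crossing CSR keyed by mt * n_sites + site
    cs_start,
    cs_mt,
    cs_site,
    # motor parameters
    a1,
    a2,
    a3,
    a4,
    A,
    F0,
    Fd,
    Ad,
    pi_attach,
    # cargo parameters
    k,
    r0,
    gamma,
    kBT,
    dt,
    # initial state
    init_mt,
    init_site,
    cargo0_x,
    cargo0_y,
    # run control
    n_steps,
    stride,
    fpt_target,
    stop_at_target,
    seed,
):
    np.random.seed(seed)

    n_mts = minus_x.shape[0]
    n_motors = init_mt.shape[0]
    seg_len = spacing * n_sites

    m_mt = init_mt.copy()
    m_site = init_site.copy()
    cx = cargo0_x
    cy = cargo0_y
    cx0 = cargo0_x

    lnA = math.log(A)
    tau0 = a1 + a2 * (1.0 + math.tanh(-a3 * a4))
    fr0 = 1.0 / (1.0 + math.exp(-lnA))
    pf0 = fr0 / tau0 * dt
    pb0 = (1.0 - fr0) / tau0 * dt
    pdet0 = 1.0 / (Ad * tau0) * dt
    if pdet0 > 1.0:
        pdet0 = 1.0
    noise_amp = math.sqrt(2.0 * kBT * dt / gamma)
    pi_dt = pi_attach * dt
    # log(1 - p) for geometric sampling of steps to the next attach trial
    lg1mp = math.log1p(-pi_dt) if pi_dt < 1.0 else -1.0
    r0sq = r0 * r0
    inv_gamma_dt = dt / gamma

    loads = np.zeros(n_motors)
    order = np.zeros(n_motors, dtype=np.int64)
    ksteps = np.zeros(n_motors, dtype=np.int64)
    cand_mt = np.zeros(n_mts, dtype=np.int64)
    cand_proj = np.zeros(n_mts)

    ubuf = np.random.random(_NBUF)
    ui = 0
    nbuf = np.random.standard_normal(_NBUF)
    ni = 0

    n_rec = int(n_steps // stride) + 1
    rec_t = np.zeros(n_rec)
    rec_cx = np.zeros(n_rec)
    rec_cy = np.zeros(n_rec)
    rec_mt = np.zeros((n_rec, n_motors), dtype=np.int64)
    rec_site = np.zeros((n_rec, n_motors), dtype=np.int64)
    rec_x = np.zeros((n_rec, n_motors))
    rec_y = np.zeros((n_rec, n_motors))
    rec_load = np.zeros((n_rec, n_motors))
    rec_f = np.zeros((n_rec, n_motors))

    fpt = -1.0
    max_sep = 0.0

    ri = _snapshot(
        0, 0.0, cx, cy, m_mt, m_site, minus_x, minus_y, ux, uy,
        spacing, k, r0, rec_t, rec_cx, rec_cy, rec_mt, rec_site,
        rec_x, rec_y, rec_load, rec_f,
    )
    countdown = stride
    step = 0

    while step < n_steps:
        n_att = 0
        for i in range(n_motors):
            if m_mt[i] >= 0:
                n_att += 1

        # ---- all-detached leap: free diffusion until the next attach trial,
        # recording boundary or end of run, whichever comes first
        if n_att == 0:
            kmin = n_steps  # upper bound
            for i in range(n_motors):
                if ui >= _NBUF:
                    ubuf = np.random.random(_NBUF)
                    ui = 0
                u = ubuf[ui]
                ui += 1
                if pi_dt <= 0.0:
                    kg = n_steps
                else:
                    kg = 1 + int(math.log(1.0 - u) / lg1mp)
                ksteps[i] = kg
                if kg < kmin:
                    kmin = kg
            kk = kmin
            if kk > countdown:
                kk = countdown
            if kk > n_steps - step:
                kk = n_steps - step
            if ni + 2 > _NBUF:
                nbuf = np.random.standard_normal(_NBUF)
                ni = 0
            amp = noise_amp * math.sqrt(kk)
            cx += amp * nbuf[ni]
            cy += amp * nbuf[ni + 1]
            ni += 2
            step += kk
            countdown -= kk
            tnow = step * dt
            if fpt_target > 0.0 and fpt < 0.0 and (cx - cx0) >= fpt_target:
                fpt = tnow
                if stop_at_target:
                    ri = _snapshot(
                        ri, tnow, cx, cy, m_mt, m_site, minus_x, minus_y, ux,
                        uy, spacing, k, r0, rec_t, rec_cx, rec_cy, rec_mt,
                        rec_site, rec_x, rec_y, rec_load, rec_f,
                    )
                    break
            if countdown == 0:
                countdown = stride
                ri = _snapshot(
                    ri, tnow, cx, cy, m_mt, m_site, minus_x, minus_y, ux, uy,
                    spacing, k, r0, rec_t, rec_cx, rec_cy, rec_mt, rec_site,
                    rec_x, rec_y, rec_load, rec_f,
                )
            if kk == kmin:
                # attach trial(s) due this step (ties are ~Pi^2 dt^2, but exact)
                for i in range(n_motors):
                    if ksteps[i] == kmin:
                        _try_attach(
                            i, cx, cy, m_mt, m_site, minus_x, minus_y, ux, uy,
                            n_sites, spacing, seg_len, r0sq, cand_mt, cand_proj,
                        )
            continue

        # ---- regular per-dt iteration
        # (1) forces and loads from start-of-step positions
        totfx = 0.0
        totfy = 0.0
        for i in range(n_motors):
            if m_mt[i] >= 0:
                m = m_mt[i]
                mxp = minus_x[m] + m_site[i] * spacing * ux[m]
                myp = minus_y[m] + m_site[i] * spacing * uy[m]
                dxi = mxp - cx
                dyi = myp - cy
                d2 = dxi * dxi + dyi * dyi
                if d2 > r0sq:
                    d = math.sqrt(d2)
                    if d > max_sep:
                        max_sep = d
                    f = k * (d - r0)
                    fx = f * dxi / d
                    fy = f * dyi / d
                    totfx += fx
                    totfy += fy
                    loads[i] = fx * ux[m] + fy * uy[m]
                else:
                    loads[i] = 0.0
            else:
                loads[i] = 0.0

        # (2)+(3) motor Monte Carlo in random motor order (Fisher-Yates;
        # a two-motor team needs a single coin flip)
        if n_motors == 2:
            if ui >= _NBUF:
                ubuf = np.random.random(_NBUF)
                ui = 0
            first = 0 if ubuf[ui] < 0.5 else 1
            ui += 1
            order[0] = first
            order[1] = 1 - first
        else:
            for i in range(n_motors):
                order[i] = i
            for i in range(n_motors - 1, 0, -1):
                if ui >= _NBUF:
                    ubuf = np.random.random(_NBUF)
                    ui = 0
                j = int(ubuf[ui] * (i + 1))
                ui += 1
                tmp = order[i]
                order[i] = order[j]
                order[j] = tmp

        for oi in range(n_motors):
            i = order[oi]
            if ui >= _NBUF:
                ubuf = np.random.random(_NBUF)
                ui = 0
            u = ubuf[ui]
            ui += 1
            if m_mt[i] >= 0:
                F = loads[i]
                if F == 0.0:
                    pdet = pdet0
                    pf = pf0
                    pb = pb0
                else:
                    tau = a1 + a2 * (1.0 + math.tanh(a3 * (F - a4)))
                    z = lnA * (1.0 - F / F0)
                    if z >= 0.0:
                        fr = 1.0 / (1.0 + math.exp(-z))
                    else:
                        ez = math.exp(z)
                        fr = ez / (1.0 + ez)
                    pf = fr / tau * dt
                    pb = (1.0 - fr) / tau * dt
                    e = -F / Fd
                    if e > 600.0:
                        e = 600.0
                    pdet = math.exp(e) / (Ad * tau) * dt
                    if pdet > 1.0:
                        pdet = 1.0
                if u < pdet:
                    m_mt[i] = DETACHED
                    m_site[i] = -1
                elif u < pdet + pf + pb:
                    direction = 1 if u < pdet + pf else -1
                    m = m_mt[i]
                    s = m_site[i]
                    # branch choice at a crossing site: uniform among the
                    # current MT and every MT registered at the crossing
                    key = m * n_sites + s
                    nb = cs_start[key + 1] - cs_start[key]
                    tm = m
                    ts = s
                    if nb > 0:
                        if ui >= _NBUF:
                            ubuf = np.random.random(_NBUF)
                            ui = 0
                        c = int(ubuf[ui] * (nb + 1))
                        ui += 1
                        if c > 0:
                            idx = cs_start[key] + c - 1
                            tm = cs_mt[idx]
                            ts = cs_site[idx]
                    tgt = ts + direction
                    if 0 <= tgt < n_sites:
                        occupied = False
                        for j2 in range(n_motors):
                            if j2 != i and m_mt[j2] == tm and m_site[j2] == tgt:
                                occupied = True
                        if not occupied:
                            m_mt[i] = tm
                            m_site[i] = tgt
                    # blocked or terminal -> hold
            else:
                # detached motor rides the cargo; Bernoulli reattachment trial
                if u < pi_dt:
                    _try_attach(
                        i, cx, cy, m_mt, m_site, minus_x, minus_y, ux, uy,
                        n_sites, spacing, seg_len, r0sq, cand_mt, cand_proj,
                    )

        # (4) cargo Euler-Maruyama update
        if ni + 2 > _NBUF:
            nbuf = np.random.standard_normal(_NBUF)
            ni = 0
        cx += totfx * inv_gamma_dt + noise_amp * nbuf[ni]
        cy += totfy * inv_gamma_dt + noise_amp * nbuf[ni + 1]
        ni += 2

        # (5) time, first passage, recording
        step += 1
        tnow = step * dt
        if fpt_target > 0.0 and fpt < 0.0 and (cx - cx0) >= fpt_target:
            fpt = tnow
            if stop_at_target:
                ri = _snapshot(
                    ri, tnow, cx, cy, m_mt, m_site, minus_x, minus_y, ux, uy,
                    spacing, k, r0, rec_t, rec_cx, rec_cy, rec_mt, rec_site,
                    rec_x, rec_y, rec_load, rec_f,
                )
                break
        countdown -= 1
        if countdown == 0:
            countdown = stride
            ri = _snapshot(
                ri, tnow, cx, cy, m_mt, m_site, minus_x, minus_y, ux, uy,
                spacing, k, r0, rec_t, rec_cx, rec_cy, rec_mt, rec_site,
                rec_x, rec_y, rec_load, rec_f,
            )

    return (
        rec_t[:ri],
        rec_cx[:ri],
        rec_cy[:ri],
        rec_mt[:ri],
        rec_site[:ri],
        rec_x[:ri],
        rec_y[:ri],
        rec_load[:ri],
        rec_f[:ri],
        fpt,
        max_sep,
    )


@njit(cache=True)
def _snapshot(
    ri, tnow, cx, cy, m_mt, m_site, minus_x, minus_y, ux, uy, spacing, k, r0,
    rec_t, rec_cx, rec_cy, rec_mt, rec_site, rec_x, rec_y, rec_load, rec_f,
):
    n_motors = m_mt.shape[0]
    rec_t[ri] = tnow
    rec_cx[ri] = cx
    rec_cy[ri] = cy
    for i in range(n_motors):
        rec_mt[ri, i] = m_mt[i]
        rec_site[ri, i] = m_site[i]
        if m_mt[i] >= 0:
            m = m_mt[i]
            mxp = minus_x[m] + m_site[i] * spacing * ux[m]
            myp = minus_y[m] + m_site[i] * spacing * uy[m]
            rec_x[ri, i] = mxp
            rec_y[ri, i] = myp
            dxi = mxp - cx
            dyi = myp - cy
            d = math.sqrt(dxi * dxi + dyi * dyi)
            if d > r0:
                rec_f[ri, i] = k * (d - r0)
                rec_load[ri, i] = rec_f[ri, i] * (dxi * ux[m] + dyi * uy[m]) / d
            else:
                rec_f[ri, i] = 0.0
                rec_load[ri, i] = 0.0
        else:
            rec_x[ri, i] = cx
            rec_y[ri, i] = cy
            rec_f[ri, i] = 0.0
            rec_load[ri, i] = 0.0
    return ri + 1
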