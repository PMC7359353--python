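"""Numba inner loops for the overdamped bead-spring simulation.

Everything here operates on the flat arrays owned by
:class:`melanosim.state.SystemState`.  The per-step phase order is fixed
and observable at large dt:

    turnover -> nucleation -> growth -> motor unbind -> motor bind
    -> motor walk -> mechanics (Euler-Maruyama + wall projection)

All stochastic draws come from one numpy ``Generator`` consumed in
ascending entity-id order within each phase, so a run is bit-reproducible
for a fixed (config, seed).

``stats`` layout (int64):
    0 nucleations, 1 deletions, 2 binds, 3 unbinds, 4 end detachments,
    5..8 exposure counts (organelle-, filament-, free-motor-,
    bound-motor- trial counts, incremented immediately before each
    Bernoulli draw so that event counts are exactly Binomial(exposure, p)),
    9 polarity violations (arc coordinate decreased within an episode),
    10 events logged, 11 nucleation overflows (capacity exhausted),
    12 non-finite error flag (1 + entity id).
"""

import numpy as np
from numba import njit

# stats indices
S_NUC, S_DEL, S_BIND, S_UNBIND, S_ENDDET = 0, 1, 2, 3, 4
S_EXPO_NUC, S_EXPO_FIL, S_EXPO_FREE, S_EXPO_BOUND = 5, 6, 7, 8
S_POLARITY, S_NEV, S_OVERFLOW, S_ERROR = 9, 10, 11, 12
N_STATS = 13

# event kinds
EV_NUCLEATE, EV_DELETE, EV_BIND, EV_UNBIND, EV_ENDDET = 0, 1, 2, 3, 4

FREE = -1


# ----------------------------------------------------------------------
# elementary force laws
# ----------------------------------------------------------------------
@njit(cache=True)
def pair_repulsion_kernel(ax, ay, bx, by, ra, rb, k_rep):
    """Force on A from soft-disk overlap with B (B gets the negative)."""
    dx = ax - bx
    dy = ay - by
    d = np.sqrt(dx * dx + dy * dy)
    overlap = ra + rb - d
    if overlap <= 0.0:
        return 0.0, 0.0
    if d < 1e-12:
        # coincident centres: deterministic fallback axis (+x)
        return k_rep * overlap, 0.0
    f = k_rep * overlap / d
    return f * dx, f * dy


@njit(cache=True)
def confinement_kernel(px, py, rad, R, k_wall):
    """Inward radial force once the disk pokes beyond the wall."""
    r = np.sqrt(px * px + py * py)
    exc = r + rad - R
    if exc <= 0.0 or k_wall <= 0.0:
        return 0.0, 0.0
    if r < 1e-12:
        return 0.0, 0.0
    f = -k_wall * exc / r
    return f * px, f * py


@njit(cache=True)
def filament_forces_kernel(nv, x, rest, s0, kappa, k_seg, f):
    """Stretch + bend forces on one filament; adds into ``f[:nv]``.

    Stretch: Hookean k_seg*(l - rest) along each segment.
    Bend: -grad of (kappa/s0) * sum_j (1 - cos theta_j).
    Returns 1 on a degenerate zero-length segment.
    """
    for i in range(nv - 1):
        dx = x[i + 1, 0] - x[i, 0]
        dy = x[i + 1, 1] - x[i, 1]
        l = np.sqrt(dx * dx + dy * dy)
        if l < 1e-12:
            return 1
        c = k_seg * (l - rest[i]) / l
        f[i, 0] += c * dx
        f[i, 1] += c * dy
        f[i + 1, 0] -= c * dx
        f[i + 1, 1] -= c * dy
    if kappa > 0.0:
        pref = kappa / s0
        for j in range(1, nv - 1):
            ux = x[j, 0] - x[j - 1, 0]
            uy = x[j, 1] - x[j - 1, 1]
            vx = x[j + 1, 0] - x[j, 0]
            vy = x[j + 1, 1] - x[j, 1]
            lu = np.sqrt(ux * ux + uy * uy)
            lv = np.sqrt(vx * vx + vy * vy)
            if lu < 1e-12 or lv < 1e-12:
                return 1
            cth = (ux * vx + uy * vy) / (lu * lv)
            # dc/du and dc/dv
            dcux = (vx / lv - cth * ux / lu) / lu
            dcuy = (vy / lv - cth * uy / lu) / lu
            dcvx = (ux / lu - cth * vx / lv) / lv
            dcvy = (uy / lu - cth * vy / lv) / lv
            # F = -dE/dp = +pref * dc/dp;  u = p_j - p_{j-1}, v = p_{j+1} - p_j
            f[j - 1, 0] -= pref * dcux
            f[j - 1, 1] -= pref * dcuy
            f[j, 0] += pref * (dcux - dcvx)
            f[j, 1] += pref * (dcuy - dcvy)
            f[j + 1, 0] += pref * dcvx
            f[j + 1, 1] += pref * dcvy
    return 0


@njit(cache=True)
def locate_arc(s, nv, rest):
    """Map contour coordinate ``s`` to (segment index, fraction in [0,1])."""
    cum = 0.0
    for j in range(nv - 1):
        if s <= cum + rest[j] or j == nv - 2:
            frac = (s - cum) / rest[j]
            if frac < 0.0:
                frac = 0.0
            elif frac > 1.0:
                frac = 1.0
            return j, frac
        cum += rest[j]
    return nv - 2, 1.0


# ----------------------------------------------------------------------
# full-system force assembly
# ----------------------------------------------------------------------
@njit(cache=True)
def compute_forces(
    org_pos, org_rad,
    motor_host, motor_offset, motor_fil, motor_s,
    fil_active, fil_nv, fil_x, fil_rest, fil_host, fil_anchor, n_fil,
    R, k_wall, k_rep, k_seg, k_link, k_motor, kappa, s0,
    f_org, f_fil,
):
    n = org_pos.shape[0]
    for i in range(n):
        f_org[i, 0] = 0.0
        f_org[i, 1] = 0.0
    for f in range(n_fil):
        if fil_active[f]:
            for v in range(fil_nv[f]):
                f_fil[f, v, 0] = 0.0
                f_fil[f, v, 1] = 0.0

    # organelle-organelle steric repulsion
    if k_rep > 0.0:
        for i in range(n):
            for j in range(i + 1, n):
                fx, fy = pair_repulsion_kernel(
                    org_pos[i, 0], org_pos[i, 1],
                    org_pos[j, 0], org_pos[j, 1],
                    org_rad[i], org_rad[j], k_rep,
                )
                if fx != 0.0 or fy != 0.0:
                    f_org[i, 0] += fx
                    f_org[i, 1] += fy
                    f_org[j, 0] -= fx
                    f_org[j, 1] -= fy

    # wall confinement
    if k_wall > 0.0:
        for i in range(n):
            fx, fy = confinement_kernel(
                org_pos[i, 0], org_pos[i, 1], org_rad[i], R, k_wall
            )
            f_org[i, 0] += fx
            f_org[i, 1] += fy

    # filament internal + pointed-end tether
    err = 0
    for f in range(n_fil):
        if not fil_active[f]:
            continue
        nv = fil_nv[f]
        bad = filament_forces_kernel(
            nv, fil_x[f], fil_rest[f], s0, kappa, k_seg, f_fil[f]
        )
        if bad != 0:
            err = 1 + f
        h = fil_host[f]
        if h != FREE and k_link > 0.0:
            axw = org_pos[h, 0] + fil_anchor[f, 0]
            ayw = org_pos[h, 1] + fil_anchor[f, 1]
            dx = axw - fil_x[f, 0, 0]
            dy = ayw - fil_x[f, 0, 1]
            f_fil[f, 0, 0] += k_link * dx
            f_fil[f, 0, 1] += k_link * dy
            f_org[h, 0] -= k_link * dx
            f_org[h, 1] -= k_link * dy

    # motor springs
    if k_motor > 0.0:
        for m in range(motor_host.shape[0]):
            f = motor_fil[m]
            if f == FREE:
                continue
            h = motor_host[m]
            nv = fil_nv[f]
            j, frac = locate_arc(motor_s[m], nv, fil_rest[f])
            tx = fil_x[f, j, 0] + frac * (fil_x[f, j + 1, 0] - fil_x[f, j, 0])
            ty = fil_x[f, j, 1] + frac * (fil_x[f, j + 1, 1] - fil_x[f, j, 1])
            axw = org_pos[h, 0] + motor_offset[m, 0]
            ayw = org_pos[h, 1] + motor_offset[m, 1]
            fx = k_motor * (axw - tx)   # force pulling the filament to anchor
            fy = k_motor * (ayw - ty)
            f_fil[f, j, 0] += (1.0 - frac) * fx
            f_fil[f, j, 1] += (1.0 - frac) * fy
            f_fil[f, j + 1, 0] += frac * fx
            f_fil[f, j + 1, 1] += frac * fy
            f_org[h, 0] -= fx
            f_org[h, 1] -= fy
    return err


# ----------------------------------------------------------------------
# kinetic phases
# ----------------------------------------------------------------------
@njit(cache=True)
def _log_event(stats, ev_time, ev_kind, ev_id1, ev_id2, t, kind, id1, id2):
    k = stats[S_NEV]
    if k < ev_time.shape[0]:
        ev_time[k] = t
        ev_kind[k] = kind
        ev_id1[k] = id1
        ev_id2[k] = id2
        stats[S_NEV] = k + 1


@njit(cache=True)
def turnover_phase(
    t, p_del,
    fil_active, fil_host, n_fil, motor_fil, motor_s,
    rng, stats, log_events, ev_time, ev_kind, ev_id1, ev_id2,
):
    for f in range(n_fil):
        if not fil_active[f]:
            continue
        stats[S_EXPO_FIL] += 1
        if rng.random() < p_del:
            fil_active[f] = 0
            fil_host[f] = FREE
            stats[S_DEL] += 1
            for m in range(motor_fil.shape[0]):
                if motor_fil[m] == f:
                    motor_fil[m] = FREE
                    motor_s[m] = 0.0
            if log_events:
                _log_event(stats, ev_time, ev_kind, ev_id1, ev_id2,
                           t, EV_DELETE, f, FREE)


@njit(cache=True)
def nucleation_phase(
    t, p_nuc, ell0, attached, iso_nuc,
    org_pos, org_rad, org_nucleates,
    fil_active, fil_nv, fil_x, fil_rest, fil_length,
    fil_host, fil_anchor, fil_origin, fil_age, n_fil,
    rng, stats, log_events, ev_time, ev_kind, ev_id1, ev_id2,
):
    cap = fil_active.shape[0]
    for i in range(org_pos.shape[0]):
        if not org_nucleates[i]:
            continue
        stats[S_EXPO_NUC] += 1
        if rng.random() >= p_nuc:
            continue
        if n_fil >= cap:
            stats[S_OVERFLOW] += 1
            continue
        phi = 2.0 * np.pi * rng.random()
        nx = np.cos(phi)
        ny = np.sin(phi)
        bx = org_pos[i, 0] + org_rad[i] * nx
        by = org_pos[i, 1] + org_rad[i] * ny
        if iso_nuc:
            psi = 2.0 * np.pi * rng.random()
            dx = np.cos(psi)
            dy = np.sin(psi)
        else:
            dx = nx   # outward surface normal
            dy = ny
        f = n_fil
        fil_active[f] = 1
        fil_nv[f] = 2
        fil_x[f, 0, 0] = bx
        fil_x[f, 0, 1] = by
        fil_x[f, 1, 0] = bx + ell0 * dx
        fil_x[f, 1, 1] = by + ell0 * dy
        fil_rest[f, 0] = ell0
        fil_length[f] = ell0
        fil_origin[f] = i
        fil_age[f] = 0.0
        if attached:
            fil_host[f] = i
            fil_anchor[f, 0] = org_rad[i] * nx
            fil_anchor[f, 1] = org_rad[i] * ny
        else:
            fil_host[f] = FREE
        n_fil += 1
        stats[S_NUC] += 1
        if log_events:
            _log_event(stats, ev_time, ev_kind, ev_id1, ev_id2,
                       t, EV_NUCLEATE, f, i)
    return n_fil


@njit(cache=True)
def growth_phase(
    dt, v_g, L_max, s0,
    fil_active, fil_nv, fil_x, fil_rest, fil_length, fil_age, n_fil,
):
    for f in range(n_fil):
        if not fil_active[f]:
            continue
        fil_age[f] += dt
        L = fil_length[f]
        if v_g <= 0.0 or L >= L_max:
            continue
        dL = v_g * dt
        if L + dL > L_max:
            dL = L_max - L
        nv = fil_nv[f]
        k = nv - 2   # barbed-end segment
        ex = fil_x[f, nv - 1, 0] - fil_x[f, k, 0]
        ey = fil_x[f, nv - 1, 1] - fil_x[f, k, 1]
        el = np.sqrt(ex * ex + ey * ey)
        if el < 1e-12:
            ex, ey = 1.0, 0.0
        else:
            ex /= el
            ey /= el
        fil_x[f, nv - 1, 0] += dL * ex
        fil_x[f, nv - 1, 1] += dL * ey
        fil_rest[f, k] += dL
        fil_length[f] = L + dL
        if fil_rest[f, k] > 1.5 * s0 and nv < fil_x.shape[1]:
            # split the end segment: interior part gets rest length s0
            old = fil_rest[f, k]
            w = s0 / old
            mx = fil_x[f, k, 0] + w * (fil_x[f, nv - 1, 0] - fil_x[f, k, 0])
            my = fil_x[f, k, 1] + w * (fil_x[f, nv - 1, 1] - fil_x[f, k, 1])
            fil_x[f, nv, 0] = fil_x[f, nv - 1, 0]
            fil_x[f, nv, 1] = fil_x[f, nv - 1, 1]
            fil_x[f, nv - 1, 0] = mx
            fil_x[f, nv - 1, 1] = my
            fil_rest[f, k] = s0
            fil_rest[f, nv - 1] = old - s0
            fil_nv[f] = nv + 1


@njit(cache=True)
def unbind_phase(
    t, dt, k_off, bell, bell_scale, k_motor,
    org_pos, motor_host, motor_offset, motor_fil, motor_s,
    fil_nv, fil_x, fil_rest,
    rng, stats, log_events, ev_time, ev_kind, ev_id1, ev_id2,
):
    p_off = 1.0 - np.exp(-k_off * dt)
    for m in range(motor_fil.shape[0]):
        f = motor_fil[m]
        if f == FREE:
            continue
        stats[S_EXPO_BOUND] += 1
        p = p_off
        if bell:
            j, frac = locate_arc(motor_s[m], fil_nv[f], fil_rest[f])
            tx = fil_x[f, j, 0] + frac * (fil_x[f, j + 1, 0] - fil_x[f, j, 0])
            ty = fil_x[f, j, 1] + frac * (fil_x[f, j + 1, 1] - fil_x[f, j, 1])
            h = motor_host[m]
            dx = org_pos[h, 0] + motor_offset[m, 0] - tx
            dy = org_pos[h, 1] + motor_offset[m, 1] - ty
            fmag = k_motor * np.sqrt(dx * dx + dy * dy)
            p = 1.0 - np.exp(-k_off * np.exp(fmag / bell_scale) * dt)
        if rng.random() < p:
            motor_fil[m] = FREE
            motor_s[m] = 0.0
            stats[S_UNBIND] += 1
            if log_events:
                _log_event(stats, ev_time, ev_kind, ev_id1, ev_id2,
                           t, EV_UNBIND, m, f)


@njit(cache=True)
def bind_phase(
    t, dt, k_on, r_cap, allow_self,
    org_pos, motor_host, motor_offset, motor_fil, motor_s,
    fil_active, fil_nv, fil_x, fil_rest, fil_origin, n_fil,
    rng, stats, log_events, ev_time, ev_kind, ev_id1, ev_id2,
):
    """Free motors bind the closest in-range filament point.

    The Bernoulli draw (success prob. 1 - exp(-k_on*dt)) is taken before
    the geometric candidate search; the two orders give the same law and
    this one keeps RNG consumption independent of the geometry.
    """
    p_on = 1.0 - np.exp(-k_on * dt)
    r2cap = r_cap * r_cap
    for m in range(motor_fil.shape[0]):
        if motor_fil[m] != FREE:
            continue
        stats[S_EXPO_FREE] += 1
        if rng.random() >= p_on:
            continue
        h = motor_host[m]
        axw = org_pos[h, 0] + motor_offset[m, 0]
        ayw = org_pos[h, 1] + motor_offset[m, 1]
        best_d2 = r2cap
        best_f = FREE
        best_s = 0.0
        for f in range(n_fil):
            if not fil_active[f]:
                continue
            if not allow_self and fil_origin[f] == h:
                continue
            nv = fil_nv[f]
            cum = 0.0
            for j in range(nv - 1):
                px = fil_x[f, j, 0]
                py = fil_x[f, j, 1]
                qx = fil_x[f, j + 1, 0]
                qy = fil_x[f, j + 1, 1]
                ex = qx - px
                ey = qy - py
                e2 = ex * ex + ey * ey
                if e2 < 1e-24:
                    u = 0.0
                else:
                    u = ((axw - px) * ex + (ayw - py) * ey) / e2
                    if u < 0.0:
                        u = 0.0
                    elif u > 1.0:
                        u = 1.0
                cx = px + u * ex - axw
                cy = py + u * ey - ayw
                d2 = cx * cx + cy * cy
                if d2 <= best_d2:
                    best_d2 = d2
                    best_f = f
                    best_s = cum + u * fil_rest[f, j]
                cum += fil_rest[f, j]
        if best_f != FREE:
            motor_fil[m] = best_f
            motor_s[m] = best_s
            stats[S_BIND] += 1
            if log_events:
                _log_event(stats, ev_time, ev_kind, ev_id1, ev_id2,
                           t, EV_BIND, m, best_f)


@njit(cache=True)
def walk_phase(
    t, dt, v_m, f_stall, k_motor,
    org_pos, motor_host, motor_offset, motor_fil, motor_s,
    fil_nv, fil_x, fil_rest, fil_length,
    stats, log_events, ev_time, ev_kind, ev_id1, ev_id2,
):
    """Linear force-velocity stepping toward the barbed end.

    ds = v_m * max(0, 1 - F_par/F_stall) * dt with F_par the spring-force
    component opposing barbed-end-directed motion; assisting load is
    capped at the unloaded speed.  ds >= 0 always, so the arc coordinate
    is non-decreasing within a binding episode.  Reaching the barbed end
    detaches the motor.
    """
    for m in range(motor_fil.shape[0]):
        f = motor_fil[m]
        if f == FREE:
            continue
        nv = fil_nv[f]
        j, frac = locate_arc(motor_s[m], nv, fil_rest[f])
        px = fil_x[f, j, 0]
        py = fil_x[f, j, 1]
        qx = fil_x[f, j + 1, 0]
        qy = fil_x[f, j + 1, 1]
        ex = qx - px
        ey = qy - py
        el = np.sqrt(ex * ex + ey * ey)
        if el < 1e-12:
            continue
        ex /= el
        ey /= el
        h = motor_host[m]
        tx = px + frac * (qx - px)
        ty = py + frac * (qy - py)
        fx = k_motor * (org_pos[h, 0] + motor_offset[m, 0] - tx)
        fy = k_motor * (org_pos[h, 1] + motor_offset[m, 1] - ty)
        c = fx * ex + fy * ey   # along barbed-end direction
        if c >= 0.0:
            ds = v_m * dt
        else:
            load = -c
            if load >= f_stall:
                ds = 0.0
            else:
                ds = v_m * (1.0 - load / f_stall) * dt
        if ds < 0.0:
            stats[S_POLARITY] += 1   # unreachable by construction
            ds = 0.0
        s_new = motor_s[m] + ds
        if s_new >= fil_length[f]:
            motor_fil[m] = FREE
            motor_s[m] = 0.0
            stats[S_ENDDET] += 1
            if log_events:
                _log_event(stats, ev_time, ev_kind, ev_id1, ev_id2,
                           t, EV_ENDDET, m, f)
        else:
            motor_s[m] = s_new


@njit(cache=True)
def mechanics_phase(
    dt, kT, R, k_wall,
    org_pos, org_rad, org_gamma, gamma_fil,
    fil_active, fil_nv, fil_x, n_fil,
    f_org, f_fil, rng,
):
    """Euler-Maruyama update, then radial projection of organelles.

    Returns 1 + entity index on a non-finite position, else 0.
    """
    n = org_pos.shape[0]
    for i in range(n):
        g = org_gamma[i]
        dx = f_org[i, 0] / g * dt
        dy = f_org[i, 1] / g * dt
        if kT > 0.0:
            amp = np.sqrt(2.0 * kT * dt / g)
            dx += amp * rng.standard_normal()
            dy += amp * rng.standard_normal()
        org_pos[i, 0] += dx
        org_pos[i, 1] += dy
        if not (np.isfinite(org_pos[i, 0]) and np.isfinite(org_pos[i, 1])):
            return 1 + i
        if k_wall > 0.0:
            r = np.sqrt(org_pos[i, 0] ** 2 + org_pos[i, 1] ** 2)
            rmax = R - org_rad[i]
            if r > rmax and r > 0.0:
                s = rmax / r
                org_pos[i, 0] *= s
                org_pos[i, 1] *= s
    if gamma_fil > 0.0:
        amp = np.sqrt(2.0 * kT * dt / gamma_fil) if kT > 0.0 else 0.0
        for f in range(n_fil):
            if not fil_active[f]:
                continue
            for v in range(fil_nv[f]):
                dx = f_fil[f, v, 0] / gamma_fil * dt
                dy = f_fil[f, v, 1] / gamma_fil * dt
                if kT > 0.0:
                    dx += amp * rng.standard_normal()
                    dy += amp * rng.standard_normal()
                fil_x[f, v, 0] += dx
                fil_x[f, v, 1] += dy
                if not (np.isfinite(fil_x[f, v, 0])
                        and np.isfinite(fil_x[f, v, 1])):
                    return 1 + n + f
    return 0


# ----------------------------------------------------------------------
@njit(cache=True)
def run_steps(
    nsteps, time0, dt, kT,
    R, k_wall, k_rep, k_seg, k_link, k_motor, kappa, s0, gamma_fil,
    v_m, f_stall, k_on, k_off, r_cap, allow_self, bell, bell_scale,
    p_nuc, ell0, v_g, L_max, p_del, attached, iso_nuc,
    org_pos, org_rad, org_gamma, org_nucleates,
    motor_host, motor_offset, motor_fil, motor_s,
    fil_active, fil_nv, fil_x, fil_rest, fil_length,
    fil_host, fil_anchor, fil_origin, fil_age, n_fil,
    rng, stats, log_events, ev_time, ev_kind, ev_id1, ev_id2,
    f_org, f_fil,
):
    t = time0
    for _ in range(nsteps):
        if p_del > 0.0:
            turnover_phase(
                t, p_del, fil_active, fil_host, n_fil, motor_fil, motor_s,
                rng, stats, log_events, ev_time, ev_kind, ev_id1, ev_id2,
            )
        if p_nuc > 0.0:
            n_fil = nucleation_phase(
                t, p_nuc, ell0, attached, iso_nuc,
                org_pos, org_rad, org_nucleates,
                fil_active, fil_nv, fil_x, fil_rest, fil_length,
                fil_host, fil_anchor, fil_origin, fil_age, n_fil,
                rng, stats, log_events, ev_time, ev_kind, ev_id1, ev_id2,
            )
        growth_phase(
            dt, v_g, L_max, s0,
            fil_active, fil_nv, fil_x, fil_rest, fil_length, fil_age, n_fil,
        )
        if k_off > 0.0:
            unbind_phase(
                t, dt, k_off, bell, bell_scale, k_motor,
                org_pos, motor_host, motor_offset, motor_fil, motor_s,
                fil_nv, fil_x, fil_rest,
                rng, stats, log_events, ev_time, ev_kind, ev_id1, ev_id2,
            )
        if k_on > 0.0:
            bind_phase(
                t, dt, k_on, r_cap, allow_self,
                org_pos, motor_host, motor_offset, motor_fil, motor_s,
                fil_active, fil_nv, fil_x, fil_rest, fil_origin, n_fil,
                rng, stats, log_events, ev_time, ev_kind, ev_id1, ev_id2,
            )
        if v_m > 0.0:
            walk_phase(
                t, dt, v_m, f_stall, k_motor,
                org_pos, motor_host, motor_offset, motor_fil, motor_s,
                fil_nv, fil_x, fil_rest, fil_length,
                stats, log_events, ev_time, ev_kind, ev_id1, ev_id2,
            )
        err = compute_forces(
            org_pos, org_rad,
            motor_host, motor_offset, motor_fil, motor_s,
            fil_active, fil_nv, fil_x, fil_rest, fil_host, fil_anchor, n_fil,
            R, k_wall, k_rep, k_seg, k_link, k_motor, kappa, s0,
            f_org, f_fil,
        )
        if err != 0:
            stats[S_ERROR] = err
            return n_fil, t
        err = mechanics_phase(
            dt, kT, R, k_wall,
            org_pos, org_rad, org_gamma, gamma_fil,
            fil_active, fil_nv, fil_x, n_fil,
            f_org, f_fil, rng,
        )
        t += dt
        if err != 0:
            stats[S_ERROR] = err
            return n_fil, t
    return n_fil, t
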