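"""Numba-compiled inner loops for force accumulation and time stepping.

These kernels are the hot path; the reference (scalar, readable) force law
lives in :mod:`celldem.mechanics` and the two are cross-checked by the test
suite.  All arrays are float64; species codes index the 4x4 pair-coefficient
tables.  ``L0`` is the length unit (1 um) in which the linear attraction
branch is evaluated (see mechanics module docs).
"""

import numpy as np
from numba import njit

__all__ = ["accumulate_pairs", "boundary_forces", "finalize"]


@njit(cache=True)
def accumulate_pairs(
    x, v, r, sp, pi, pj,
    ka_t, kr_t, fa_t, dmin_t, enab_t, dspec, L0,
    F, vsum, ncnt, f_clip,
):
    """Elastic pair forces + drag neighbour bookkeeping over a pair list.

    For each candidate pair (i, j): a particle counts the other as a drag
    neighbour when the overlap alpha >= -delta of its *own* species; the
    elastic force acts when the pair is enabled and alpha >= -min(delta_i,
    delta_j), and is accumulated antisymmetrically (Newton's third law).
    ``f_clip`` bounds each pair's contribution to the accumulated *motion*
    force (pass inf for exact sums): near-tangent Hertz contacts are so stiff
    that transient deep overlaps (e.g. a freshly divided pair) otherwise
    produce astronomically large forces whose direction hijacks the
    overdamped descent and fires particles through membrane rings.
    """
    for k in range(pi.shape[0]):
        i = pi[k]
        j = pj[k]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dist = np.sqrt(dx * dx + dy * dy)
        alpha = r[i] + r[j] - dist
        si = sp[i]
        sj = sp[j]
        if alpha >= -dspec[si]:
            vsum[i, 0] += v[j, 0]
            vsum[i, 1] += v[j, 1]
            ncnt[i] += 1
        if alpha >= -dspec[sj]:
            vsum[j, 0] += v[i, 0]
            vsum[j, 1] += v[i, 1]
            ncnt[j] += 1
        if enab_t[si, sj] and alpha >= -dmin_t[si, sj] and dist > 1e-18:
            nx = dx / dist
            ny = dy / dist
            req = r[i] * r[j] / (r[i] + r[j])
            if alpha < 0.0:
                p = ka_t[si, sj] * (alpha / L0)
            else:
                a = alpha / L0
                p = kr_t[si, sj] * np.sqrt(req / L0) * a * np.sqrt(a)
            f = fa_t[si, sj] - p
            if f > f_clip:
                f = f_clip
            elif f < -f_clip:
                f = -f_clip
            F[i, 0] += f * nx
            F[i, 1] += f * ny
            F[j, 0] -= f * nx
            F[j, 1] -= f * ny


@njit(cache=True)
def boundary_forces(
    x, v, r, sp,
    bpoint, bnormal, bvel,
    b_ka, b_kr, b_fa, b_delta, b_enab, L0,
    F, vsum, ncnt, react, f_clip,
):
    """Particle-boundary forces; boundaries are spheres of infinite radius.

    The unit vector from a particle toward the boundary "centre" is the
    negated domain normal; the equivalent radius degenerates to the particle
    radius.  A contacting boundary also joins the particle's drag-neighbour
    average with its scheduled velocity, weight 1.  ``react`` accumulates the
    reaction force on each boundary (minus the force exerted on particles).
    """
    nb = bpoint.shape[0]
    n = x.shape[0]
    for b in range(nb):
        px = bpoint[b, 0]
        py = bpoint[b, 1]
        nxb = bnormal[b, 0]
        nyb = bnormal[b, 1]
        for i in range(n):
            si = sp[i]
            if not b_enab[b, si]:
                continue
            d = (x[i, 0] - px) * nxb + (x[i, 1] - py) * nyb
            alpha = r[i] - d
            if alpha < -b_delta[b, si]:
                continue
            req = r[i]
            if alpha < 0.0:
                p = b_ka[b, si] * (alpha / L0)
            else:
                a = alpha / L0
                p = b_kr[b, si] * np.sqrt(req / L0) * a * np.sqrt(a)
            f = b_fa[b, si] - p
            # reaction bookkeeping uses the exact force; the motion force is
            # clipped like the pair contributions
            react[b, 0] += f * nxb
            react[b, 1] += f * nyb
            if f > f_clip:
                f = f_clip
            elif f < -f_clip:
                f = -f_clip
            F[i, 0] += -f * nxb
            F[i, 1] += -f * nyb
            vsum[i, 0] += bvel[b, 0]
            vsum[i, 1] += bvel[b, 1]
            ncnt[i] += 1


@njit(cache=True)
def project_overlaps(x, r, sp, pi, pj, enab_t, mobile, relax, iters):
    """Gauss-Seidel projection of pair overlaps toward tangency.

    Initialisation helper: the near-tangent contact regime of the calibrated
    parameters is so stiff that force-based relaxation parks assemblies in
    force-balanced but deeply overlapped states.  Moving each overlapping
    enabled pair apart along its axis (by ``relax`` of the overlap per
    sweep, immobile partners taking no share) resolves residual overlaps
    geometrically, which is the infinite-stiffness limit of the contact law.
    Used only while building cells, never during measurements.
    """
    for _ in range(iters):
        moved = 0.0
        for k in range(pi.shape[0]):
            i = pi[k]
            j = pj[k]
            if not enab_t[sp[i], sp[j]]:
                continue
            dx = x[j, 0] - x[i, 0]
            dy = x[j, 1] - x[i, 1]
            dist = np.sqrt(dx * dx + dy * dy)
            if dist < 1e-18:
                continue
            alpha = r[i] + r[j] - dist
            if alpha <= 0.0:
                continue
            wi = 1.0 if mobile[i] else 0.0
            wj = 1.0 if mobile[j] else 0.0
            wsum = wi + wj
            if wsum == 0.0:
                continue
            corr = relax * alpha / (dist * wsum)
            x[i, 0] -= corr * wi * dx
            x[i, 1] -= corr * wi * dy
            x[j, 0] += corr * wj * dx
            x[j, 1] += corr * wj * dy
            moved += alpha
    return moved


@njit(cache=True)
def overdamped_update(x, v, F, ext, vsum, ncnt, beta_p, dt, dmax, mobile, leak):
    """Explicit update of the overdamped (massless) equation of motion.

    Force balance with the neighbour-relative drag gives ``v_i = v_bar_i +
    F_i / beta_i`` with ``v_bar`` the mean neighbour velocity taken one step
    behind (collective advection).  The per-step displacement is clamped to
    ``dmax``: near-tangent contacts are far stiffer than any affordable
    explicit step, so clamped particles park in a narrow band around force
    balance instead of overshooting; their stored velocity is zeroed so the
    bounded contact jitter does not advect neighbours.  ``leak`` bleeds a
    small fraction of the advected velocity per step: the relative-velocity
    drag leaves rigid-body drift of detached bodies undamped, and the leak
    provides the weak absolute-frame dissipation that keeps quasi-static
    assemblies from coasting.  On return ``F`` holds
    the net non-drag force (elastic + boundary + external), which is the
    quasi-static residual.  Returns (max displacement^2, all-finite flag).
    """
    n = x.shape[0]
    maxd2 = 0.0
    finite = True
    for i in range(n):
        fx = F[i, 0] + ext[i, 0]
        fy = F[i, 1] + ext[i, 1]
        F[i, 0] = fx
        F[i, 1] = fy
        if not (np.isfinite(fx) and np.isfinite(fy)):
            finite = False
            continue
        if not mobile[i]:
            continue
        vbx = 0.0
        vby = 0.0
        if ncnt[i] > 0:
            inv = 1.0 / ncnt[i]
            vbx = vsum[i, 0] * inv
            vby = vsum[i, 1] * inv
        vx = (1.0 - leak) * vbx + fx / beta_p[i]
        vy = (1.0 - leak) * vby + fy / beta_p[i]
        ddx = vx * dt
        ddy = vy * dt
        d2 = ddx * ddx + ddy * ddy
        clamped = False
        if d2 > dmax * dmax:
            s = dmax / np.sqrt(d2)
            ddx *= s
            ddy *= s
            d2 = dmax * dmax
            clamped = True
        if d2 > maxd2:
            maxd2 = d2
        x[i, 0] += ddx
        x[i, 1] += ddy
        if clamped:
            v[i, 0] = 0.0
            v[i, 1] = 0.0
        else:
            v[i, 0] = ddx / dt
            v[i, 1] = ddy / dt
    return maxd2, finite


@njit(cache=True)
def finalize(
    x, xprev, v, F, ext, vsum, ncnt, beta_p, m, dt, advance, dmax, mobile,
    f_switch, f_strong,
):
    """Add drag and external forces; optionally advance the positions.

    Drag on particle i is -beta_i * (v_i - mean neighbour velocity), with the
    velocities lagged one step behind the displacements.  On return ``F``
    holds the *total* force on each particle.

    Particles in the stable-stiffness regime (net force below ``f_switch``,
    which equals the force cap the time step was designed for) follow the
    position-Verlet update.  Near-tangent contacts stiffen far beyond any
    affordable explicit step, so particles pushed harder than ``f_switch``
    are instead moved by an overdamped descent of length ``dmax * min(1,
    |F| / f_strong)`` along the net force, with no stored momentum; they park
    within a tiny band around force balance and re-enter the Verlet regime.
    ``dmax`` also caps the Verlet displacement as a last-resort guard.
    Particles with ``mobile == 0`` accumulate forces but do not move (used to
    pin membrane rings while a cell interior fills).  Returns (max
    displacement^2 this step, all-finite flag).
    """
    n = x.shape[0]
    maxd2 = 0.0
    finite = True
    for i in range(n):
        fx = F[i, 0] + ext[i, 0]
        fy = F[i, 1] + ext[i, 1]
        if ncnt[i] > 0:
            inv = 1.0 / ncnt[i]
            fx -= beta_p[i] * (v[i, 0] - vsum[i, 0] * inv)
            fy -= beta_p[i] * (v[i, 1] - vsum[i, 1] * inv)
        F[i, 0] = fx
        F[i, 1] = fy
        if not (np.isfinite(fx) and np.isfinite(fy)):
            finite = False
            continue
        if advance and mobile[i]:
            fmag = np.sqrt(fx * fx + fy * fy)
            if f_switch > 0.0 and fmag > f_switch:
                # overdamped strong-contact regime
                s = dmax if fmag >= f_strong else dmax * fmag / f_strong
                ddx = fx / fmag * s
                ddy = fy / fmag * s
                newx = x[i, 0] + ddx
                newy = x[i, 1] + ddy
                if s * s > maxd2:
                    maxd2 = s * s
                xprev[i, 0] = newx
                xprev[i, 1] = newy
                v[i, 0] = 0.0
                v[i, 1] = 0.0
                x[i, 0] = newx
                x[i, 1] = newy
                continue
            axdt2 = fx / m[i] * dt * dt
            aydt2 = fy / m[i] * dt * dt
            newx = 2.0 * x[i, 0] - xprev[i, 0] + axdt2
            newy = 2.0 * x[i, 1] - xprev[i, 1] + aydt2
            if not (np.isfinite(newx) and np.isfinite(newy)):
                finite = False
                continue
            ddx = newx - x[i, 0]
            ddy = newy - x[i, 1]
            d2 = ddx * ddx + ddy * ddy
            capped = False
            if dmax > 0.0 and d2 > dmax * dmax:
                s = dmax / np.sqrt(d2)
                ddx *= s
                ddy *= s
                newx = x[i, 0] + ddx
                newy = x[i, 1] + ddy
                d2 = dmax * dmax
                capped = True
            if d2 > maxd2:
                maxd2 = d2
            if capped:
                xprev[i, 0] = newx
                xprev[i, 1] = newy
                v[i, 0] = 0.0
                v[i, 1] = 0.0
            else:
                xprev[i, 0] = x[i, 0]
                xprev[i, 1] = x[i, 1]
                v[i, 0] = ddx / dt
                v[i, 1] = ddy / dt
            x[i, 0] = newx
            x[i, 1] = newy
    return maxd2, finite
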