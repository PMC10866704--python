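"""Numba kernels for force evaluation, Brownian dynamics, and bond kinetics.

All kernels operate on a flat packed representation of the network (see
``mechanics.pack_state``):

* ``pos (n,3)`` bead coordinates; ``anchored (n,)`` 0=free, 1=−y wall, 2=+y wall
* segments: ``seg_i, seg_j`` bead indices, ``seg_l0`` rest lengths,
  ``seg_fib`` owning fibril index
* bending triples ``trip (nt,3)`` of consecutive beads within a fibril
* connectors: attachment = (lower bead index of the containing segment,
  interpolation weight in [0,1]); ``c_kind`` 0=crosslinker, 1=bundler.

Everything is single-threaded and draws randomness from one
``numpy.random.Generator``, so trajectories are bit-reproducible.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _mi(d, L, periodic):
    """Minimum-image fold of a scalar displacement into (-L/2, L/2]."""
    if periodic:
        d -= L * math.ceil(d / L - 0.5)
    return d


@njit(cache=True)
def compute_forces(pos, anchored,
                   seg_i, seg_j, seg_l0,
                   trip,
                   c_kind, c_bound, c_b1, c_w1, c_b2, c_w2, c_rest,
                   kappa_s, kappa_b, kappa_c,
                   Lx, Lz, perx, perz,
                   F, tension):
    """Fill per-bead forces ``F`` and per-connector tensions ``tension``.

    Forces are the negative gradient of the total potential
    (harmonic segment stretching + angular bending + connector springs).
    Anchored beads accumulate force like any other bead — it is reported
    (for the boundary-stress estimator) but never applied to their motion.
    """
    n = pos.shape[0]
    for i in range(n):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0

    # --- segment stretching: E = 1/2 kappa_s (l - l0)^2
    for s in range(seg_i.shape[0]):
        i = seg_i[s]
        j = seg_j[s]
        dx = _mi(pos[j, 0] - pos[i, 0], Lx, perx)
        dy = pos[j, 1] - pos[i, 1]
        dz = _mi(pos[j, 2] - pos[i, 2], Lz, perz)
        l = math.sqrt(dx * dx + dy * dy + dz * dz)
        if l < 1e-12:
            continue
        f = kappa_s * (l - seg_l0[s]) / l
        F[i, 0] += f * dx
        F[i, 1] += f * dy
        F[i, 2] += f * dz
        F[j, 0] -= f * dx
        F[j, 1] -= f * dy
        F[j, 2] -= f * dz

    # --- bending: E = 1/2 kappa_b phi^2 at each interior bead
    for t in range(trip.shape[0]):
        i1 = trip[t, 0]
        i2 = trip[t, 1]
        i3 = trip[t, 2]
        ax = _mi(pos[i2, 0] - pos[i1, 0], Lx, perx)
        ay = pos[i2, 1] - pos[i1, 1]
        az = _mi(pos[i2, 2] - pos[i1, 2], Lz, perz)
        bx = _mi(pos[i3, 0] - pos[i2, 0], Lx, perx)
        by = pos[i3, 1] - pos[i2, 1]
        bz = _mi(pos[i3, 2] - pos[i2, 2], Lz, perz)
        la = math.sqrt(ax * ax + ay * ay + az * az)
        lb = math.sqrt(bx * bx + by * by + bz * bz)
        if la < 1e-12 or lb < 1e-12:
            continue
        eax = ax / la
        eay = ay / la
        eaz = az / la
        ebx = bx / lb
        eby = by / lb
        ebz = bz / lb
        c = eax * ebx + eay * eby + eaz * ebz
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        phi = math.acos(c)
        sphi = math.sqrt(max(1.0 - c * c, 1e-24))
        # F = -dE/dr = kappa_b * phi / sin(phi) * d(cos phi)/dr
        coef = kappa_b * (phi / sphi if sphi > 1e-8 else 1.0)
        g1x = -(ebx - c * eax) / la
        g1y = -(eby - c * eay) / la
        g1z = -(ebz - c * eaz) / la
        g3x = (eax - c * ebx) / lb
        g3y = (eay - c * eby) / lb
        g3z = (eaz - c * ebz) / lb
        F[i1, 0] += coef * g1x
        F[i1, 1] += coef * g1y
        F[i1, 2] += coef * g1z
        F[i3, 0] += coef * g3x
        F[i3, 1] += coef * g3y
        F[i3, 2] += coef * g3z
        F[i2, 0] -= coef * (g1x + g3x)
        F[i2, 1] -= coef * (g1y + g3y)
        F[i2, 2] -= coef * (g1z + g3z)

    # --- connector springs: E = 1/2 kappa_c (d - rest)^2, bound only
    for k in range(c_kind.shape[0]):
        tension[k] = 0.0
        if c_bound[k] == 0:
            continue
        b1 = c_b1[k]
        w1 = c_w1[k]
        b2 = c_b2[k]
        w2 = c_w2[k]
        # attachment points via minimum-image interpolation inside a segment
        s1x = _mi(pos[b1 + 1, 0] - pos[b1, 0], Lx, perx)
        s1y = pos[b1 + 1, 1] - pos[b1, 1]
        s1z = _mi(pos[b1 + 1, 2] - pos[b1, 2], Lz, perz)
        p1x = pos[b1, 0] + w1 * s1x
        p1y = pos[b1, 1] + w1 * s1y
        p1z = pos[b1, 2] + w1 * s1z
        s2x = _mi(pos[b2 + 1, 0] - pos[b2, 0], Lx, perx)
        s2y = pos[b2 + 1, 1] - pos[b2, 1]
        s2z = _mi(pos[b2 + 1, 2] - pos[b2, 2], Lz, perz)
        p2x = pos[b2, 0] + w2 * s2x
        p2y = pos[b2, 1] + w2 * s2y
        p2z = pos[b2, 2] + w2 * s2z
        dx = _mi(p2x - p1x, Lx, perx)
        dy = p2y - p1y
        dz = _mi(p2z - p1z, Lz, perz)
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        T = kappa_c * (d - c_rest[k])
        tension[k] = T
        if d < 1e-12:
            continue
        f = T / d
        fx = f * dx
        fy = f * dy
        fz = f * dz
        F[b1, 0] += (1.0 - w1) * fx
        F[b1, 1] += (1.0 - w1) * fy
        F[b1, 2] += (1.0 - w1) * fz
        F[b1 + 1, 0] += w1 * fx
        F[b1 + 1, 1] += w1 * fy
        F[b1 + 1, 2] += w1 * fz
        F[b2, 0] -= (1.0 - w2) * fx
        F[b2, 1] -= (1.0 - w2) * fy
        F[b2, 2] -= (1.0 - w2) * fz
        F[b2 + 1, 0] -= w2 * fx
        F[b2 + 1, 1] -= w2 * fy
        F[b2 + 1, 2] -= w2 * fz


@njit(cache=True)
def total_energy(pos,
                 seg_i, seg_j, seg_l0,
                 trip,
                 c_kind, c_bound, c_b1, c_w1, c_b2, c_w2, c_rest,
                 kappa_s, kappa_b, kappa_c,
                 Lx, Lz, perx, perz):
    """Total potential energy (pN·µm) of the packed configuration."""
    E = 0.0
    for s in range(seg_i.shape[0]):
        i = seg_i[s]
        j = seg_j[s]
        dx = _mi(pos[j, 0] - pos[i, 0], Lx, perx)
        dy = pos[j, 1] - pos[i, 1]
        dz = _mi(pos[j, 2] - pos[i, 2], Lz, perz)
        l = math.sqrt(dx * dx + dy * dy + dz * dz)
        E += 0.5 * kappa_s * (l - seg_l0[s]) ** 2
    for t in range(trip.shape[0]):
        i1 = trip[t, 0]
        i2 = trip[t, 1]
        i3 = trip[t, 2]
        ax = _mi(pos[i2, 0] - pos[i1, 0], Lx, perx)
        ay = pos[i2, 1] - pos[i1, 1]
        az = _mi(pos[i2, 2] - pos[i1, 2], Lz, perz)
        bx = _mi(pos[i3, 0] - pos[i2, 0], Lx, perx)
        by = pos[i3, 1] - pos[i2, 1]
        bz = _mi(pos[i3, 2] - pos[i2, 2], Lz, perz)
        la = math.sqrt(ax * ax + ay * ay + az * az)
        lb = math.sqrt(bx * bx + by * by + bz * bz)
        if la < 1e-12 or lb < 1e-12:
            continue
        c = (ax * bx + ay * by + az * bz) / (la * lb)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        phi = math.acos(c)
        E += 0.5 * kappa_b * phi * phi
    for k in range(c_kind.shape[0]):
        if c_bound[k] == 0:
            continue
        b1 = c_b1[k]
        w1 = c_w1[k]
        b2 = c_b2[k]
        w2 = c_w2[k]
        s1x = _mi(pos[b1 + 1, 0] - pos[b1, 0], Lx, perx)
        s1y = pos[b1 + 1, 1] - pos[b1, 1]
        s1z = _mi(pos[b1 + 1, 2] - pos[b1, 2], Lz, perz)
        p1x = pos[b1, 0] + w1 * s1x
        p1y = pos[b1, 1] + w1 * s1y
        p1z = pos[b1, 2] + w1 * s1z
        s2x = _mi(pos[b2 + 1, 0] - pos[b2, 0], Lx, perx)
        s2y = pos[b2 + 1, 1] - pos[b2, 1]
        s2z = _mi(pos[b2 + 1, 2] - pos[b2, 2], Lz, perz)
        p2x = pos[b2, 0] + w2 * s2x
        p2y = pos[b2, 1] + w2 * s2y
        p2z = pos[b2, 2] + w2 * s2z
        dx = _mi(p2x - p1x, Lx, perx)
        dy = p2y - p1y
        dz = _mi(p2z - p1z, Lz, perz)
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        E += 0.5 * kappa_c * (d - c_rest[k]) ** 2
    return E


@njit(cache=True)
def kinetics_step(pos,
                  seg_i, seg_j, seg_fib,
                  c_kind, c_bound, c_b1, c_w1, c_b2, c_w2, c_rest,
                  c_fib1, c_fib2,
                  tension,
                  k0, bell_lambda, kBT,
                  rebind_enabled, rebind_rate, capture_radius,
                  dt_kin,
                  Lx, Lz, perx, perz,
                  do_unbind, do_rebind,
                  rng):
    """One stochastic bind/unbind sweep over all crosslinkers.

    Bound crosslinkers unbind with probability ``1 - exp(-k dt)`` where
    ``k = k0 exp(|T| lambda / kBT)`` (Bell's law; ``kBT = 0`` means the
    unloaded rate is used only at zero tension, otherwise instant).
    Unbound crosslinkers keep their first attachment; if the nearest point
    on any *other* fibril lies within the capture radius they rebind there
    at the rebind rate, with rest length equal to the current separation.
    Bundlers are never touched.
    """
    nseg = seg_i.shape[0]
    for k in range(c_kind.shape[0]):
        if c_kind[k] != 0:
            continue
        if c_bound[k] == 1:
            if do_unbind == 0 or k0 <= 0.0:
                continue
            Tmag = abs(tension[k])
            if kBT > 0.0:
                expo = Tmag * bell_lambda / kBT
                if expo > 50.0:
                    expo = 50.0
                rate = k0 * math.exp(expo)
            else:
                rate = k0 if Tmag == 0.0 else 1e30
            p = 1.0 - math.exp(-rate * dt_kin)
            if rng.random() < p:
                c_bound[k] = 0
        else:
            if do_rebind == 0 or rebind_enabled == 0 or rebind_rate <= 0.0:
                continue
            b1 = c_b1[k]
            w1 = c_w1[k]
            s1x = _mi(pos[b1 + 1, 0] - pos[b1, 0], Lx, perx)
            s1y = pos[b1 + 1, 1] - pos[b1, 1]
            s1z = _mi(pos[b1 + 1, 2] - pos[b1, 2], Lz, perz)
            px = pos[b1, 0] + w1 * s1x
            py = pos[b1, 1] + w1 * s1y
            pz = pos[b1, 2] + w1 * s1z
            best = 1e30
            best_seg = -1
            best_t = 0.0
            for s in range(nseg):
                if seg_fib[s] == c_fib1[k]:
                    continue
                i = seg_i[s]
                j = seg_j[s]
                ax = _mi(pos[i, 0] - px, Lx, perx)
                ay = pos[i, 1] - py
                az = _mi(pos[i, 2] - pz, Lz, perz)
                vx = _mi(pos[j, 0] - pos[i, 0], Lx, perx)
                vy = pos[j, 1] - pos[i, 1]
                vz = _mi(pos[j, 2] - pos[i, 2], Lz, perz)
                vv = vx * vx + vy * vy + vz * vz
                if vv < 1e-24:
                    continue
                tproj = -(ax * vx + ay * vy + az * vz) / vv
                if tproj < 0.0:
                    tproj = 0.0
                elif tproj > 1.0:
                    tproj = 1.0
                ddx = ax + tproj * vx
                ddy = ay + tproj * vy
                ddz = az + tproj * vz
                d2 = ddx * ddx + ddy * ddy + ddz * ddz
                if d2 < best:
                    best = d2
                    best_seg = s
                    best_t = tproj
            if best_seg >= 0 and best <= capture_radius * capture_radius:
                p = 1.0 - math.exp(-rebind_rate * dt_kin)
                if rng.random() < p:
                    c_bound[k] = 1
                    c_b2[k] = seg_i[best_seg]
                    c_w2[k] = best_t
                    c_fib2[k] = seg_fib[best_seg]
                    c_rest[k] = math.sqrt(best)


@njit(cache=True)
def run_sim(pos, anchored, base_x,
            seg_i, seg_j, seg_l0, seg_fib,
            trip,
            c_kind, c_bound, c_b1, c_w1, c_b2, c_w2, c_rest, c_fib1, c_fib2,
            kappa_s, kappa_b, kappa_c, zeta, kBT, kBT_mech, dt,
            k0, bell_lambda, capture_radius,
            rebind_enabled, rebind_rate, kin_every,
            n_steps, step0, eq_steps, ramp_steps, gamma_max, Ly,
            Lx, Lz, perx, perz,
            sample_every, hold_sample, stop_below,
            times_out, stress_out, nbound_out,
            rng):
    """Shear-and-hold Brownian dynamics loop.

    The system first equilibrates at zero strain for ``eq_steps`` (thermal
    annealing of the as-assembled geometry), then the +y wall anchors
    translate along x by ``gamma(t)·Ly`` with a linear ramp over
    ``ramp_steps`` followed by a hold; −y anchors never move.
    Boundary stress ``sigma = -(sum F_x on +y anchors)/(Lx·Lz)`` is
    accumulated every step and recorded as its average over each sampling
    window (as a lock-in rheometer would, suppressing thermal force noise
    whose correlation time ~zeta/kappa is far below the window); the
    bound-crosslinker count is sampled at window ends.  If ``stop_below``
    > 0 the loop terminates once the held stress falls below
    ``stop_below`` times the stress of the reference window
    (``hold_sample``).  Returns the number of samples written.
    """
    n = pos.shape[0]
    F = np.zeros((n, 3))
    tension = np.zeros(c_kind.shape[0])
    noise_sd = (math.sqrt(2.0 * kBT_mech * dt / zeta)
                if kBT_mech > 0.0 else 0.0)
    area = Lx * Lz
    n_samp = 0
    sigma_ref = 0.0
    acc_fx = 0.0
    acc_n = 0

    for t in range(n_steps + 1):
        compute_forces(pos, anchored, seg_i, seg_j, seg_l0, trip,
                       c_kind, c_bound, c_b1, c_w1, c_b2, c_w2, c_rest,
                       kappa_s, kappa_b, kappa_c, Lx, Lz, perx, perz,
                       F, tension)

        fx = 0.0
        for i in range(n):
            if anchored[i] == 2:
                fx += F[i, 0]
        acc_fx += fx
        acc_n += 1

        if (step0 + t) % sample_every == 0:
            nb = 0
            for k in range(c_kind.shape[0]):
                if c_bound[k] == 1:
                    nb += 1
            sigma = -(acc_fx / acc_n) / area
            acc_fx = 0.0
            acc_n = 0
            if not math.isfinite(sigma):
                return -1
            times_out[n_samp] = (step0 + t) * dt
            stress_out[n_samp] = sigma
            nbound_out[n_samp] = nb
            if n_samp == hold_sample:
                sigma_ref = sigma
            n_samp += 1
            if (stop_below > 0.0 and n_samp - 1 > hold_sample
                    and sigma_ref > 0.0 and sigma < stop_below * sigma_ref):
                break

        if t == n_steps:
            break

        # bond kinetics on the current (pre-move) tensions
        if kin_every > 0 and (step0 + t) % kin_every == 0:
            kinetics_step(pos, seg_i, seg_j, seg_fib,
                          c_kind, c_bound, c_b1, c_w1, c_b2, c_w2, c_rest,
                          c_fib1, c_fib2, tension,
                          k0, bell_lambda, kBT,
                          rebind_enabled, rebind_rate, capture_radius,
                          kin_every * dt, Lx, Lz, perx, perz,
                          1, 1, rng)

        # Euler update of the overdamped Langevin equation
        g = step0 + t
        gamma = gamma_max
        if g + 1 < eq_steps:
            gamma = 0.0
        elif ramp_steps > 0 and g + 1 < eq_steps + ramp_steps:
            gamma = gamma_max * (g + 1 - eq_steps) / ramp_steps
        inv_zeta_dt = dt / zeta
        for i in range(n):
            a = anchored[i]
            if a == 0:
                if noise_sd > 0.0:
                    pos[i, 0] += F[i, 0] * inv_zeta_dt + noise_sd * rng.normal()
                    pos[i, 1] += F[i, 1] * inv_zeta_dt + noise_sd * rng.normal()
                    pos[i, 2] += F[i, 2] * inv_zeta_dt + noise_sd * rng.normal()
                else:
                    pos[i, 0] += F[i, 0] * inv_zeta_dt
                    pos[i, 1] += F[i, 1] * inv_zeta_dt
                    pos[i, 2] += F[i, 2] * inv_zeta_dt
                if perx:
                    pos[i, 0] %= Lx
                if perz:
                    pos[i, 2] %= Lz
            elif a == 2:
                pos[i, 0] = base_x[i] + gamma * Ly
            # a == 1: fixed −y anchor

        if not math.isfinite(pos[0, 0]):
            return -1

    return n_samp
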