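"""Numba kernels for neighbour search and contact-force assembly.

These mirror the scalar reference laws in :mod:`mcdem.contact_laws`
(the unit tests assert agreement) but operate on flat arrays for speed.
Conventions inside the kernels:

* the contact normal ``n`` points from body j (or the wall) towards
  particle i; compressive normal forces are positive along ``n``;
* per-particle stress is accumulated compression-positive,
  ``sigma_i += a * sym(n (x) F_on_i) / V_i`` with ``a`` the
  centre-to-contact distance;
* the multi-contact correction ``beta * nu * (pi R* dn) * P_ij`` uses
  the stress traces of the *previous* step (explicit lagging) and is
  applied to particle-particle contacts only.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

TSUJI = 2.0 * math.sqrt(5.0 / 6.0)
TWO_THIRDS = 2.0 / 3.0


@njit(cache=True)
def build_pairs(pos, radii, Lx, Ly, zlo, zhi, cell_size, skin, out_i, out_j):
    """Cell-list broad phase; returns pair count or -1 if out_* overflow.

    Pairs (i < j) are all those with centre distance < r_i + r_j + skin
    under x/y minimum image.  Cell size must be >= max diameter + skin.
    """
    n = pos.shape[0]
    ncx = max(1, int(Lx / cell_size))
    ncy = max(1, int(Ly / cell_size))
    h = zhi - zlo
    ncz = max(1, int(h / cell_size)) if h > 0 else 1
    ncell = ncx * ncy * ncz

    head = np.full(ncell, -1, np.int64)
    nxt = np.full(n, -1, np.int64)
    cx_of = np.empty(n, np.int64)
    cy_of = np.empty(n, np.int64)
    cz_of = np.empty(n, np.int64)
    for i in range(n):
        cx = int(pos[i, 0] / Lx * ncx) % ncx
        cy = int(pos[i, 1] / Ly * ncy) % ncy
        cz = int((pos[i, 2] - zlo) / h * ncz) if h > 0 else 0
        if cz < 0:
            cz = 0
        if cz >= ncz:
            cz = ncz - 1
        cx_of[i] = cx
        cy_of[i] = cy
        cz_of[i] = cz
        c = (cz * ncy + cy) * ncx + cx
        nxt[i] = head[c]
        head[c] = i

    cap = out_i.shape[0]
    count = 0
    ncells_nb = np.empty(27, np.int64)
    for i in range(n):
        # distinct neighbour cells of particle i (wrap-deduplicated)
        nnb = 0
        for dz in range(-1, 2):
            cz = cz_of[i] + dz
            if cz < 0 or cz >= ncz:
                continue
            for dy in range(-1, 2):
                cy = (cy_of[i] + dy) % ncy
                for dx in range(-1, 2):
                    cx = (cx_of[i] + dx) % ncx
                    c = (cz * ncy + cy) * ncx + cx
                    seen = False
                    for k in range(nnb):
                        if ncells_nb[k] == c:
                            seen = True
                            break
                    if not seen:
                        ncells_nb[nnb] = c
                        nnb += 1
        for k in range(nnb):
            j = head[ncells_nb[k]]
            while j != -1:
                if j > i:
                    dxp = pos[i, 0] - pos[j, 0]
                    dxp -= Lx * math.floor(dxp / Lx + 0.5)
                    dyp = pos[i, 1] - pos[j, 1]
                    dyp -= Ly * math.floor(dyp / Ly + 0.5)
                    dzp = pos[i, 2] - pos[j, 2]
                    cut = radii[i] + radii[j] + skin
                    if dxp * dxp + dyp * dyp + dzp * dzp < cut * cut:
                        if count >= cap:
                            return -1
                        out_i[count] = i
                        out_j[count] = j
                        count += 1
                j = nxt[j]
    return count


@njit(cache=True, inline="always")
def _hysteretic_elastic(dn, dmax, k1, k2r, kcr, phif, rstar, f0):
    """Branch-selected elastic normal force and updated max overlap."""
    if dn > dmax:
        dmax = dn
    if k2r > 1.0:
        k2 = k2r * k1
        dstar = k2 / (k2 - k1) * phif * 2.0 * rstar
        if dmax >= dstar:
            k2s = k2
        else:
            k2s = k1 + (k2 - k1) * dmax / dstar
        d0 = (1.0 - k1 / k2s) ** TWO_THIRDS * dmax
    else:
        k2s = k1
        d0 = 0.0
    p15 = dn**1.5
    t_load = k1 * p15
    t_unld = k2s * (p15 - d0**1.5)
    t_adh = -kcr * k1 * p15
    # virgin branch wins at equality (tolerance absorbs round-off at dn == dmax)
    if t_unld >= t_load - 1e-12 * (abs(t_load) + abs(t_unld)):
        fe = t_load
    elif t_adh >= t_unld:
        fe = t_adh
    else:
        fe = t_unld
    return f0 + fe, dmax


@njit(cache=True)
def compute_forces(
    pos,
    vel,
    angvel,
    radii,
    masses,
    inv_vol,
    pairs_i,
    pairs_j,
    dmax,
    tspr,
    wall_dmax,
    wall_tspr,
    trace_prev,
    Lx,
    Ly,
    zb,
    zt,
    vz_top,
    e43_pp,
    g_pp,
    zeta_pp,
    mu_pp,
    mur_pp,
    e43_pw,
    g_pw,
    zeta_pw,
    mu_pw,
    mur_pw,
    k2r,
    kcr,
    phif,
    beta_mc,
    f0,
    nu_bar,
    dt,
    eta_visc,
    alpha_local,
    grav,
    contact_damping,
    F,
    T,
    stress,
):
    """Assemble forces, torques, per-particle stress and plate reactions.

    Returns (elastic_energy, top_plate_fz, bottom_plate_fz, n_contacts,
    max_overlap_fraction, summed_overlap).  F, T, stress must be zeroed
    by the caller; history arrays (dmax, tspr, wall_*) are updated in
    place.
    """
    n = pos.shape[0]
    m = pairs_i.shape[0]
    ee = 0.0
    top_fz = 0.0
    bot_fz = 0.0
    ncon = 0
    max_ofrac = 0.0
    sum_ov = 0.0

    # ---- particle-particle contacts ----
    for p in range(m):
        i = pairs_i[p]
        j = pairs_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dx -= Lx * math.floor(dx / Lx + 0.5)
        dy = pos[i, 1] - pos[j, 1]
        dy -= Ly * math.floor(dy / Ly + 0.5)
        dz = pos[i, 2] - pos[j, 2]
        ri = radii[i]
        rj = radii[j]
        rsum = ri + rj
        d2 = dx * dx + dy * dy + dz * dz
        if d2 >= rsum * rsum or d2 <= 0.0:
            dmax[p] = 0.0
            tspr[p, 0] = 0.0
            tspr[p, 1] = 0.0
            tspr[p, 2] = 0.0
            continue
        dist = math.sqrt(d2)
        if dist < 0.05 * rsum:
            # centres nearly coincident: the normal is about to become
            # singular -- flag as an instability via the overlap ratio
            max_ofrac = 1e9
            continue
        dn = rsum - dist
        inv = 1.0 / dist
        nx = dx * inv
        ny = dy * inv
        nz = dz * inv
        rstar = ri * rj / rsum
        k1 = e43_pp * math.sqrt(rstar)

        fe, dmax[p] = _hysteretic_elastic(dn, dmax[p], k1, k2r, kcr, phif, rstar, f0)
        if beta_mc > 0.0:
            area = math.pi * rstar * dn
            pij = (trace_prev[i] + trace_prev[j]) / 3.0
            fe += beta_mc * nu_bar * area * pij

        rvx = vel[i, 0] - vel[j, 0]
        rvy = vel[i, 1] - vel[j, 1]
        rvz = vel[i, 2] - vel[j, 2]
        vn = rvx * nx + rvy * ny + rvz * nz

        fn = fe
        mstar = masses[i] * masses[j] / (masses[i] + masses[j])
        if contact_damping and zeta_pp > 0.0:
            sn = 1.5 * e43_pp * math.sqrt(rstar * dn)
            fn -= TSUJI * zeta_pp * math.sqrt(sn * mstar) * vn

        ofrac = dn / min(ri, rj)
        if ofrac > max_ofrac:
            max_ofrac = ofrac
        sum_ov += dn
        ncon += 1
        if fe > 0.0:
            ee += 0.4 * fe * dn

        ai = ri - 0.5 * dn
        aj = rj - 0.5 * dn

        ftx = 0.0
        fty = 0.0
        ftz = 0.0
        if mu_pp > 0.0 and fn > 0.0:
            wsx = ai * angvel[i, 0] + aj * angvel[j, 0]
            wsy = ai * angvel[i, 1] + aj * angvel[j, 1]
            wsz = ai * angvel[i, 2] + aj * angvel[j, 2]
            vsx = rvx - (wsy * nz - wsz * ny)
            vsy = rvy - (wsz * nx - wsx * nz)
            vsz = rvz - (wsx * ny - wsy * nx)
            vtn = vsx * nx + vsy * ny + vsz * nz
            vtx = vsx - vtn * nx
            vty = vsy - vtn * ny
            vtz = vsz - vtn * nz

            tsx = tspr[p, 0]
            tsy = tspr[p, 1]
            tsz = tspr[p, 2]
            dot = tsx * nx + tsy * ny + tsz * nz
            tsx = tsx - dot * nx + vtx * dt
            tsy = tsy - dot * ny + vty * dt
            tsz = tsz - dot * nz + vtz * dt
            tmag = math.sqrt(tsx * tsx + tsy * tsy + tsz * tsz)
            if tmag > 0.0:
                kt = 8.0 * g_pp * math.sqrt(rstar)
                fel = kt * tmag**1.5
                fcap = mu_pp * fn
                if fel >= fcap:
                    scale = (fcap / kt) ** TWO_THIRDS / tmag
                    tsx *= scale
                    tsy *= scale
                    tsz *= scale
                    tm = tmag * scale
                    coef = -fcap / tm
                    ftx = coef * tsx
                    fty = coef * tsy
                    ftz = coef * tsz
                else:
                    coef = -kt * math.sqrt(tmag)
                    ftx = coef * tsx
                    fty = coef * tsy
                    ftz = coef * tsz
                    if contact_damping and zeta_pp > 0.0:
                        st = 8.0 * g_pp * math.sqrt(rstar * dn)
                        gt = TSUJI * zeta_pp * math.sqrt(st * mstar)
                        ftx -= gt * vtx
                        fty -= gt * vty
                        ftz -= gt * vtz
                    fm = math.sqrt(ftx * ftx + fty * fty + ftz * ftz)
                    if fm > fcap:
                        s = fcap / fm
                        ftx *= s
                        fty *= s
                        ftz *= s
            tspr[p, 0] = tsx
            tspr[p, 1] = tsy
            tspr[p, 2] = tsz
        else:
            tspr[p, 0] = 0.0
            tspr[p, 1] = 0.0
            tspr[p, 2] = 0.0

        fx = fn * nx + ftx
        fy = fn * ny + fty
        fz = fn * nz + ftz
        F[i, 0] += fx
        F[i, 1] += fy
        F[i, 2] += fz
        F[j, 0] -= fx
        F[j, 1] -= fy
        F[j, 2] -= fz

        # torque from tangential force: tau_i = (-ai n) x Ft, tau_j = -aj (n x Ft)
        cxf_x = ny * ftz - nz * fty
        cxf_y = nz * ftx - nx * ftz
        cxf_z = nx * fty - ny * ftx
        T[i, 0] -= ai * cxf_x
        T[i, 1] -= ai * cxf_y
        T[i, 2] -= ai * cxf_z
        T[j, 0] -= aj * cxf_x
        T[j, 1] -= aj * cxf_y
        T[j, 2] -= aj * cxf_z

        if mur_pp > 0.0 and fn > 0.0:
            wrx = angvel[i, 0] - angvel[j, 0]
            wry = angvel[i, 1] - angvel[j, 1]
            wrz = angvel[i, 2] - angvel[j, 2]
            wn = math.sqrt(wrx * wrx + wry * wry + wrz * wrz)
            if wn > 1e-30:
                coef = -mur_pp * rstar * fn / wn
                T[i, 0] += coef * wrx
                T[i, 1] += coef * wry
                T[i, 2] += coef * wrz
                T[j, 0] -= coef * wrx
                T[j, 1] -= coef * wry
                T[j, 2] -= coef * wrz

        # Love-Weber stress, compression-positive
        sxx = nx * fx
        syy = ny * fy
        szz = nz * fz
        sxy = 0.5 * (nx * fy + ny * fx)
        sxz = 0.5 * (nx * fz + nz * fx)
        syz = 0.5 * (ny * fz + nz * fy)
        wi = ai * inv_vol[i]
        wj = aj * inv_vol[j]
        stress[i, 0] += wi * sxx
        stress[i, 1] += wi * syy
        stress[i, 2] += wi * szz
        stress[i, 3] += wi * sxy
        stress[i, 4] += wi * sxz
        stress[i, 5] += wi * syz
        stress[j, 0] += wj * sxx
        stress[j, 1] += wj * syy
        stress[j, 2] += wj * szz
        stress[j, 3] += wj * sxy
        stress[j, 4] += wj * sxz
        stress[j, 5] += wj * syz

    # ---- particle-wall contacts (bottom w=0 at zb, top w=1 at zt) ----
    for i in range(n):
        r = radii[i]
        for w in range(2):
            if w == 0:
                dn = r - (pos[i, 2] - zb)
                nz = 1.0
                vwz = 0.0
            else:
                dn = r - (zt - pos[i, 2])
                nz = -1.0
                vwz = vz_top
            if dn <= 0.0:
                wall_dmax[i, w] = 0.0
                wall_tspr[i, w, 0] = 0.0
                wall_tspr[i, w, 1] = 0.0
                wall_tspr[i, w, 2] = 0.0
                continue
            k1 = e43_pw * math.sqrt(r)
            fe, wall_dmax[i, w] = _hysteretic_elastic(
                dn, wall_dmax[i, w], k1, k2r, kcr, phif, r, f0
            )
            vn = (vel[i, 2] - vwz) * nz
            fn = fe
            if contact_damping and zeta_pw > 0.0:
                sn = 1.5 * e43_pw * math.sqrt(r * dn)
                fn -= TSUJI * zeta_pw * math.sqrt(sn * masses[i]) * vn

            ofrac = dn / r
            if ofrac > max_ofrac:
                max_ofrac = ofrac
            sum_ov += dn
            ncon += 1
            if fe > 0.0:
                ee += 0.4 * fe * dn

            a = r - 0.5 * dn
            ftx = 0.0
            fty = 0.0
            ftz = 0.0
            if mu_pw > 0.0 and fn > 0.0:
                # surface velocity: v_i - a * (omega_i x n) - v_wall; n = (0,0,nz)
                vsx = vel[i, 0] - a * (angvel[i, 1] * nz)
                vsy = vel[i, 1] - a * (-angvel[i, 0] * nz)
                vsz = vel[i, 2] - vwz
                vtx = vsx
                vty = vsy
                vtz = 0.0  # tangent plane is x-y

                tsx = wall_tspr[i, w, 0] + vtx * dt
                tsy = wall_tspr[i, w, 1] + vty * dt
                tsz = 0.0
                tmag = math.sqrt(tsx * tsx + tsy * tsy)
                if tmag > 0.0:
                    kt = 8.0 * g_pw * math.sqrt(r)
                    fel = kt * tmag**1.5
                    fcap = mu_pw * fn
                    if fel >= fcap:
                        scale = (fcap / kt) ** TWO_THIRDS / tmag
                        tsx *= scale
                        tsy *= scale
                        tm = tmag * scale
                        coef = -fcap / tm
                        ftx = coef * tsx
                        fty = coef * tsy
                    else:
                        coef = -kt * math.sqrt(tmag)
                        ftx = coef * tsx
                        fty = coef * tsy
                        if contact_damping and zeta_pw > 0.0:
                            st = 8.0 * g_pw * math.sqrt(r * dn)
                            gt = TSUJI * zeta_pw * math.sqrt(st * masses[i])
                            ftx -= gt * vtx
                            fty -= gt * vty
                        fm = math.sqrt(ftx * ftx + fty * fty)
                        if fm > fcap:
                            s = fcap / fm
                            ftx *= s
                            fty *= s
                wall_tspr[i, w, 0] = tsx
                wall_tspr[i, w, 1] = tsy
                wall_tspr[i, w, 2] = tsz
            else:
                wall_tspr[i, w, 0] = 0.0
                wall_tspr[i, w, 1] = 0.0
                wall_tspr[i, w, 2] = 0.0

            fx = ftx
            fy = fty
            fz = fn * nz + ftz
            F[i, 0] += fx
            F[i, 1] += fy
            F[i, 2] += fz
            if w == 0:
                bot_fz += fn
            else:
                top_fz += fn

            # torque: tau_i = (-a n) x Ft ; n = (0,0,nz)
            T[i, 0] -= a * (nz * -fty)
            T[i, 1] -= a * (nz * ftx)
            # z-component vanishes

            if mur_pw > 0.0 and fn > 0.0:
                wx = angvel[i, 0]
                wy = angvel[i, 1]
                wz = angvel[i, 2]
                wn = math.sqrt(wx * wx + wy * wy + wz * wz)
                if wn > 1e-30:
                    coef = -mur_pw * r * fn / wn
                    T[i, 0] += coef * wx
                    T[i, 1] += coef * wy
                    T[i, 2] += coef * wz

            wgt = a * inv_vol[i]
            stress[i, 0] += 0.0
            stress[i, 1] += 0.0
            stress[i, 2] += wgt * nz * fz
            stress[i, 4] += wgt * 0.5 * nz * fx
            stress[i, 5] += wgt * 0.5 * nz * fy

    # ---- body forces: background damping and gravity ----
    if grav != 0.0:
        for i in range(n):
            F[i, 2] -= masses[i] * grav
    if eta_visc > 0.0:
        # mass-proportional viscous damping (packing growth / testing)
        c = eta_visc / dt
        for i in range(n):
            F[i, 0] -= c * masses[i] * vel[i, 0]
            F[i, 1] -= c * masses[i] * vel[i, 1]
            F[i, 2] -= c * masses[i] * vel[i, 2]
    if alpha_local > 0.0:
        # Cundall local damping: force-proportional, hence intensive --
        # it does not pollute the measured stress with a size- or
        # rate-dependent viscous contribution
        for i in range(n):
            for k in range(3):
                if vel[i, k] > 0.0:
                    F[i, k] -= alpha_local * abs(F[i, k])
                elif vel[i, k] < 0.0:
                    F[i, k] += alpha_local * abs(F[i, k])

    return ee, top_fz, bot_fz, ncon, max_ofrac, sum_ov


@njit(cache=True)
def project_overlaps(pos, radii, Lx, Ly, zb, zt, pairs_i, pairs_j, relax):
    """One Gauss-Seidel overlap-removal sweep (packing relaxation).

    Each overlapping pair is moved apart along its normal by
    ``relax * overlap``, split in inverse proportion to particle volume;
    wall overlaps push the particle back inside.  With ``relax = 0`` the
    sweep only measures.  Returns (summed overlap, contact count,
    max overlap fraction) evaluated before the moves.
    """
    m = pairs_i.shape[0]
    n = pos.shape[0]
    sum_ov = 0.0
    ncon = 0
    max_of = 0.0
    for p in range(m):
        i = pairs_i[p]
        j = pairs_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dx -= Lx * math.floor(dx / Lx + 0.5)
        dy = pos[i, 1] - pos[j, 1]
        dy -= Ly * math.floor(dy / Ly + 0.5)
        dz = pos[i, 2] - pos[j, 2]
        ri = radii[i]
        rj = radii[j]
        rsum = ri + rj
        d2 = dx * dx + dy * dy + dz * dz
        if d2 >= rsum * rsum or d2 <= 0.0:
            continue
        dist = math.sqrt(d2)
        dn = rsum - dist
        sum_ov += dn
        ncon += 1
        of = dn / min(ri, rj)
        if of > max_of:
            max_of = of
        if relax > 0.0:
            inv = 1.0 / dist
            nx = dx * inv
            ny = dy * inv
            nz = dz * inv
            vi = ri * ri * ri
            vj = rj * rj * rj
            wi = vj / (vi + vj)
            si = relax * dn * wi
            sj = relax * dn * (1.0 - wi)
            pos[i, 0] = (pos[i, 0] + si * nx) % Lx
            pos[i, 1] = (pos[i, 1] + si * ny) % Ly
            pos[i, 2] += si * nz
            pos[j, 0] = (pos[j, 0] - sj * nx) % Lx
            pos[j, 1] = (pos[j, 1] - sj * ny) % Ly
            pos[j, 2] -= sj * nz
    for i in range(n):
        r = radii[i]
        db = r - (pos[i, 2] - zb)
        if db > 0.0:
            sum_ov += db
            ncon += 1
            if db / r > max_of:
                max_of = db / r
            if relax > 0.0:
                pos[i, 2] += relax * db
        dtp = r - (zt - pos[i, 2])
        if dtp > 0.0:
            sum_ov += dtp
            ncon += 1
            if dtp / r > max_of:
                max_of = dtp / r
            if relax > 0.0:
                pos[i, 2] -= relax * dtp
    return sum_ov, ncon, max_of
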