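"""Minimal restricted Hartree–Fock engine.

This is the host SCF that the pressure model couples to: closed-shell RHF
over contracted Cartesian Gaussians, with one- and two-electron integrals
evaluated by McMurchie–Davidson recursions (numba-compiled), DIIS
convergence acceleration, and analytic nuclear gradients.

The engine accepts an ``extra_fock`` callback so that an environment term
(here: the surface-Gaussian pressure potential) can add its energy and Fock
contribution each iteration; with the callback absent or inert the engine
reproduces plain gas-phase RHF exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.linalg
from numba import njit

from .basis import BasisSet, build_basis, cart_components, component_scale
from .geometry import Molecule

# ---------------------------------------------------------------------------
# Cartesian component tables (l = 0..4) as flat arrays for the kernels
# ---------------------------------------------------------------------------

_MAXL = 4
_comp_off = [0]
_lx, _ly, _lz, _cscale = [], [], [], []
for _l in range(_MAXL + 1):
    for (_a, _b, _c) in cart_components(_l):
        _lx.append(_a); _ly.append(_b); _lz.append(_c)
        _cscale.append(component_scale(_a, _b, _c))
    _comp_off.append(len(_lx))
COMP_OFF = np.array(_comp_off, dtype=np.int64)
COMP_LX = np.array(_lx, dtype=np.int64)
COMP_LY = np.array(_ly, dtype=np.int64)
COMP_LZ = np.array(_lz, dtype=np.int64)
COMP_SCALE = np.array(_cscale, dtype=np.float64)


# ---------------------------------------------------------------------------
# McMurchie–Davidson primitives
# ---------------------------------------------------------------------------

@njit(cache=False)
def _fill_E(la: int, lb: int, a: float, b: float, ab: float, E: np.ndarray) -> None:
    """Hermite expansion coefficients E[i, j, t] for one Cartesian direction.

    ab = A - B.  E[0,0,0] carries the Gaussian-product prefactor for this
    direction, so the product over x,y,z reconstructs exp(-mu |AB|^2).
    """
    p = a + b
    mu = a * b / p
    PA = -(b / p) * ab
    PB = (a / p) * ab
    E[:, :, :] = 0.0
    E[0, 0, 0] = np.exp(-mu * ab * ab)
    for i in range(la):
        for t in range(i + 2):
            v = PA * E[i, 0, t]
            if t > 0:
                v += E[i, 0, t - 1] / (2.0 * p)
            if t + 1 <= i:
                v += (t + 1) * E[i, 0, t + 1]
            E[i + 1, 0, t] = v
    for i in range(la + 1):
        for j in range(lb):
            for t in range(i + j + 2):
                v = PB * E[i, j, t]
                if t > 0:
                    v += E[i, j, t - 1] / (2.0 * p)
                if t + 1 <= i + j:
                    v += (t + 1) * E[i, j, t + 1]
                E[i, j + 1, t] = v


@njit(cache=False)
def _boys(nmax: int, T: float, out: np.ndarray) -> None:
    """Boys functions F_0..F_nmax at T."""
    if T < 1e-13:
        for n in range(nmax + 1):
            out[n] = 1.0 / (2 * n + 1) - T / (2 * n + 3)
        return
    if T < 35.0:
        # series for F_nmax, then downward recursion
        em = np.exp(-T)
        s = 1.0 / (2 * nmax + 1)
        term = s
        k = 1
        while True:
            term *= 2.0 * T / (2 * nmax + 2 * k + 1)
            s += term
            if term < 1e-17 * s or k > 300:
                break
            k += 1
        out[nmax] = em * s
        for n in range(nmax - 1, -1, -1):
            out[n] = (2.0 * T * out[n + 1] + em) / (2 * n + 1)
    else:
        em = np.exp(-T)
        out[0] = 0.5 * np.sqrt(np.pi / T)
        for n in range(nmax):
            out[n + 1] = ((2 * n + 1) * out[n] - em) / (2.0 * T)


@njit(cache=False)
def _fill_R(L: int, p: float, X: float, Y: float, Z: float, R: np.ndarray) -> None:
    """Hermite Coulomb integrals R[t,u,v] (order 0) up to t+u+v <= L."""
    T = p * (X * X + Y * Y + Z * Z)
    F = np.empty(L + 1)
    _boys(L, T, F)
    # Rn[n, t, u, v]
    Rn = np.zeros((L + 1, L + 1, L + 1, L + 1))
    m2p = -2.0 * p
    fac = 1.0
    for n in range(L + 1):
        Rn[n, 0, 0, 0] = fac * F[n]
        fac *= m2p
    for total in range(1, L + 1):
        for n in range(L - total + 1):
            for t in range(total + 1):
                for u in range(total - t + 1):
                    v = total - t - u
                    if t > 0:
                        val = X * Rn[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * Rn[n + 1, t - 2, u, v]
                    elif u > 0:
                        val = Y * Rn[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * Rn[n + 1, t, u - 2, v]
                    else:
                        val = Z * Rn[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * Rn[n + 1, t, u, v - 2]
                    Rn[n, t, u, v] = val
    R[:L + 1, :L + 1, :L + 1] = Rn[0, :L + 1, :L + 1, :L + 1]


# ---------------------------------------------------------------------------
# One-electron integrals (and their nuclear derivatives)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _int1e_kernel(centers, ls, offsets, pidx, exps, coefs, zcoords, zvals,
                  comp_off, comp_lx, comp_ly, comp_lz, comp_scale,
                  S, T, V):
    ns = len(ls)
    maxl = int(ls.max())
    nE = maxl + 3
    Ex = np.zeros((nE, nE, 2 * nE))
    Ey = np.zeros((nE, nE, 2 * nE))
    Ez = np.zeros((nE, nE, 2 * nE))
    LR = 2 * maxl
    R = np.zeros((LR + 1, LR + 1, LR + 1))
    nz = len(zvals)
    for A in range(ns):
        la = ls[A]
        nca = comp_off[la + 1] - comp_off[la]
        for B in range(A + 1):
            lb = ls[B]
            ncb = comp_off[lb + 1] - comp_off[lb]
            ABx = centers[A, 0] - centers[B, 0]
            ABy = centers[A, 1] - centers[B, 1]
            ABz = centers[A, 2] - centers[B, 2]
            Sblk = np.zeros((nca, ncb))
            Tblk = np.zeros((nca, ncb))
            Vblk = np.zeros((nca, ncb))
            for ka in range(pidx[A], pidx[A + 1]):
                a = exps[ka]
                ca = coefs[ka]
                for kb in range(pidx[B], pidx[B + 1]):
                    b = exps[kb]
                    cb = coefs[kb]
                    p = a + b
                    cc = ca * cb
                    _fill_E(la, lb + 2, a, b, ABx, Ex)
                    _fill_E(la, lb + 2, a, b, ABy, Ey)
                    _fill_E(la, lb + 2, a, b, ABz, Ez)
                    sq = np.sqrt(np.pi / p)
                    Px = (a * centers[A, 0] + b * centers[B, 0]) / p
                    Py = (a * centers[A, 1] + b * centers[B, 1]) / p
                    Pz = (a * centers[A, 2] + b * centers[B, 2]) / p
                    for ia in range(nca):
                        ix = comp_lx[comp_off[la] + ia]
                        iy = comp_ly[comp_off[la] + ia]
                        iz = comp_lz[comp_off[la] + ia]
                        sa = comp_scale[comp_off[la] + ia]
                        for ib in range(ncb):
                            jx = comp_lx[comp_off[lb] + ib]
                            jy = comp_ly[comp_off[lb] + ib]
                            jz = comp_lz[comp_off[lb] + ib]
                            sb = comp_scale[comp_off[lb] + ib]
                            w = cc * sa * sb
                            sx = Ex[ix, jx, 0] * sq
                            sy = Ey[iy, jy, 0] * sq
                            sz = Ez[iz, jz, 0] * sq
                            Sblk[ia, ib] += w * sx * sy * sz
                            # kinetic 1-D factors
                            tx = -2.0 * b * b * Ex[ix, jx + 2, 0] * sq \
                                + b * (2 * jx + 1) * sx
                            if jx >= 2:
                                tx -= 0.5 * jx * (jx - 1) * Ex[ix, jx - 2, 0] * sq
                            ty = -2.0 * b * b * Ey[iy, jy + 2, 0] * sq \
                                + b * (2 * jy + 1) * sy
                            if jy >= 2:
                                ty -= 0.5 * jy * (jy - 1) * Ey[iy, jy - 2, 0] * sq
                            tz = -2.0 * b * b * Ez[iz, jz + 2, 0] * sq \
                                + b * (2 * jz + 1) * sz
                            if jz >= 2:
                                tz -= 0.5 * jz * (jz - 1) * Ez[iz, jz - 2, 0] * sq
                            Tblk[ia, ib] += w * (tx * sy * sz + sx * ty * sz + sx * sy * tz)
                    # nuclear attraction
                    for kc in range(nz):
                        if zvals[kc] == 0.0:
                            continue
                        _fill_R(la + lb, p, Px - zcoords[kc, 0],
                                Py - zcoords[kc, 1], Pz - zcoords[kc, 2], R)
                        pref = -zvals[kc] * 2.0 * np.pi / p
                        for ia in range(nca):
                            ix = comp_lx[comp_off[la] + ia]
                            iy = comp_ly[comp_off[la] + ia]
                            iz = comp_lz[comp_off[la] + ia]
                            sa = comp_scale[comp_off[la] + ia]
                            for ib in range(ncb):
                                jx = comp_lx[comp_off[lb] + ib]
                                jy = comp_ly[comp_off[lb] + ib]
                                jz = comp_lz[comp_off[lb] + ib]
                                sb = comp_scale[comp_off[lb] + ib]
                                acc = 0.0
                                for t in range(ix + jx + 1):
                                    for u in range(iy + jy + 1):
                                        for v in range(iz + jz + 1):
                                            acc += Ex[ix, jx, t] * Ey[iy, jy, u] \
                                                * Ez[iz, jz, v] * R[t, u, v]
                                Vblk[ia, ib] += cc * sa * sb * pref * acc
            for ia in range(nca):
                for ib in range(ncb):
                    mu = offsets[A] + ia
                    nu = offsets[B] + ib
                    S[mu, nu] = Sblk[ia, ib]; S[nu, mu] = Sblk[ia, ib]
                    T[mu, nu] = Tblk[ia, ib]; T[nu, mu] = Tblk[ia, ib]
                    V[mu, nu] = Vblk[ia, ib]; V[nu, mu] = Vblk[ia, ib]


# ---------------------------------------------------------------------------
# Two-electron integrals
# ---------------------------------------------------------------------------

@njit(cache=False)
def _eri_quartet(la, lb, lc, ld, Acen, Bcen, Ccen, Dcen,
                 ea, ca, eb, cb, ec, cc_, ed, cd,
                 comp_off, comp_lx, comp_ly, comp_lz, comp_scale, out):
    """(ab|cd) block over Cartesian components."""
    nca = comp_off[la + 1] - comp_off[la]
    ncb = comp_off[lb + 1] - comp_off[lb]
    ncc = comp_off[lc + 1] - comp_off[lc]
    ncd = comp_off[ld + 1] - comp_off[ld]
    out[:nca, :ncb, :ncc, :ncd] = 0.0
    L1 = la + lb
    L2 = lc + ld
    L = L1 + L2
    E1x = np.zeros((la + 1, lb + 1, L1 + 1))
    E1y = np.zeros((la + 1, lb + 1, L1 + 1))
    E1z = np.zeros((la + 1, lb + 1, L1 + 1))
    E2x = np.zeros((lc + 1, ld + 1, L2 + 1))
    E2y = np.zeros((lc + 1, ld + 1, L2 + 1))
    E2z = np.zeros((lc + 1, ld + 1, L2 + 1))
    R = np.zeros((L + 1, L + 1, L + 1))
    ABx = Acen[0] - Bcen[0]; ABy = Acen[1] - Bcen[1]; ABz = Acen[2] - Bcen[2]
    CDx = Ccen[0] - Dcen[0]; CDy = Ccen[1] - Dcen[1]; CDz = Ccen[2] - Dcen[2]
    for ka in range(len(ea)):
        for kb in range(len(eb)):
            a = ea[ka]; b = eb[kb]
            p = a + b
            cab = ca[ka] * cb[kb]
            _fill_E(la, lb, a, b, ABx, E1x)
            _fill_E(la, lb, a, b, ABy, E1y)
            _fill_E(la, lb, a, b, ABz, E1z)
            Px = (a * Acen[0] + b * Bcen[0]) / p
            Py = (a * Acen[1] + b * Bcen[1]) / p
            Pz = (a * Acen[2] + b * Bcen[2]) / p
            for kc in range(len(ec)):
                for kd in range(len(ed)):
                    c = ec[kc]; d = ed[kd]
                    q = c + d
                    cabcd = cab * cc_[kc] * cd[kd]
                    _fill_E(lc, ld, c, d, CDx, E2x)
                    _fill_E(lc, ld, c, d, CDy, E2y)
                    _fill_E(lc, ld, c, d, CDz, E2z)
                    Qx = (c * Ccen[0] + d * Dcen[0]) / q
                    Qy = (c * Ccen[1] + d * Dcen[1]) / q
                    Qz = (c * Ccen[2] + d * Dcen[2]) / q
                    alpha = p * q / (p + q)
                    _fill_R(L, alpha, Px - Qx, Py - Qy, Pz - Qz, R)
                    pref = cabcd * 2.0 * np.pi**2.5 / (p * q * np.sqrt(p + q))
                    for ia in range(nca):
                        ix = comp_lx[comp_off[la] + ia]
                        iy = comp_ly[comp_off[la] + ia]
                        iz = comp_lz[comp_off[la] + ia]
                        sa = comp_scale[comp_off[la] + ia]
                        for ib in range(ncb):
                            jx = comp_lx[comp_off[lb] + ib]
                            jy = comp_ly[comp_off[lb] + ib]
                            jz = comp_lz[comp_off[lb] + ib]
                            sb = comp_scale[comp_off[lb] + ib]
                            for ic in range(ncc):
                                kx = comp_lx[comp_off[lc] + ic]
                                ky = comp_ly[comp_off[lc] + ic]
                                kz = comp_lz[comp_off[lc] + ic]
                                sc = comp_scale[comp_off[lc] + ic]
                                for id_ in range(ncd):
                                    mx = comp_lx[comp_off[ld] + id_]
                                    my = comp_ly[comp_off[ld] + id_]
                                    mz = comp_lz[comp_off[ld] + id_]
                                    sd = comp_scale[comp_off[ld] + id_]
                                    acc = 0.0
                                    for t in range(ix + jx + 1):
                                        for u in range(iy + jy + 1):
                                            for v in range(iz + jz + 1):
                                                e1 = E1x[ix, jx, t] * E1y[iy, jy, u] * E1z[iz, jz, v]
                                                if e1 == 0.0:
                                                    continue
                                                for tt in range(kx + mx + 1):
                                                    for uu in range(ky + my + 1):
                                                        for vv in range(kz + mz + 1):
                                                            e2 = E2x[kx, mx, tt] * E2y[ky, my, uu] * E2z[kz, mz, vv]
                                                            if e2 == 0.0:
                                                                continue
                                                            sgn = 1.0 if (tt + uu + vv) % 2 == 0 else -1.0
                                                            acc += e1 * e2 * sgn * R[t + tt, u + uu, v + vv]
                                    out[ia, ib, ic, id_] += pref * sa * sb * sc * sd * acc


@njit(cache=False)
def _eri_kernel(centers, ls, offsets, pidx, exps, coefs,
                comp_off, comp_lx, comp_ly, comp_lz, comp_scale,
                eri, schwarz_thresh):
    ns = len(ls)
    maxnc = 0
    for A in range(ns):
        nc = comp_off[ls[A] + 1] - comp_off[ls[A]]
        if nc > maxnc:
            maxnc = nc
    blk = np.zeros((maxnc, maxnc, maxnc, maxnc))
    # Schwarz factors per shell pair
    Q = np.zeros((ns, ns))
    for A in range(ns):
        for B in range(A + 1):
            _eri_quartet(ls[A], ls[B], ls[A], ls[B],
                         centers[A], centers[B], centers[A], centers[B],
                         exps[pidx[A]:pidx[A + 1]], coefs[pidx[A]:pidx[A + 1]],
                         exps[pidx[B]:pidx[B + 1]], coefs[pidx[B]:pidx[B + 1]],
                         exps[pidx[A]:pidx[A + 1]], coefs[pidx[A]:pidx[A + 1]],
                         exps[pidx[B]:pidx[B + 1]], coefs[pidx[B]:pidx[B + 1]],
                         comp_off, comp_lx, comp_ly, comp_lz, comp_scale, blk)
            m = 0.0
            nca = comp_off[ls[A] + 1] - comp_off[ls[A]]
            ncb = comp_off[ls[B] + 1] - comp_off[ls[B]]
            for ia in range(nca):
                for ib in range(ncb):
                    v = abs(blk[ia, ib, ia, ib])
                    if v > m:
                        m = v
            Q[A, B] = np.sqrt(m)
            Q[B, A] = Q[A, B]
    # main loop over unique quartets
    for A in range(ns):
        for B in range(A + 1):
            pab = A * (A + 1) // 2 + B
            for C in range(A + 1):
                for D in range(C + 1):
                    pcd = C * (C + 1) // 2 + D
                    if pcd > pab:
                        continue
                    if Q[A, B] * Q[C, D] < schwarz_thresh:
                        continue
                    _eri_quartet(ls[A], ls[B], ls[C], ls[D],
                                 centers[A], centers[B], centers[C], centers[D],
                                 exps[pidx[A]:pidx[A + 1]], coefs[pidx[A]:pidx[A + 1]],
                                 exps[pidx[B]:pidx[B + 1]], coefs[pidx[B]:pidx[B + 1]],
                                 exps[pidx[C]:pidx[C + 1]], coefs[pidx[C]:pidx[C + 1]],
                                 exps[pidx[D]:pidx[D + 1]], coefs[pidx[D]:pidx[D + 1]],
                                 comp_off, comp_lx, comp_ly, comp_lz, comp_scale, blk)
                    nca = comp_off[ls[A] + 1] - comp_off[ls[A]]
                    ncb = comp_off[ls[B] + 1] - comp_off[ls[B]]
                    ncc = comp_off[ls[C] + 1] - comp_off[ls[C]]
                    ncd = comp_off[ls[D] + 1] - comp_off[ls[D]]
                    for ia in range(nca):
                        mu = offsets[A] + ia
                        for ib in range(ncb):
                            nu = offsets[B] + ib
                            for ic in range(ncc):
                                lm = offsets[C] + ic
                                for id_ in range(ncd):
                                    sg = offsets[D] + id_
                                    v = blk[ia, ib, ic, id_]
                                    eri[mu, nu, lm, sg] = v
                                    eri[nu, mu, lm, sg] = v
                                    eri[mu, nu, sg, lm] = v
                                    eri[nu, mu, sg, lm] = v
                                    eri[lm, sg, mu, nu] = v
                                    eri[sg, lm, mu, nu] = v
                                    eri[lm, sg, nu, mu] = v
                                    eri[sg, lm, nu, mu] = v


# ---------------------------------------------------------------------------
# Derivative integrals (small systems; used for nuclear gradients)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _d1e_kernel(centers, ls, atoms, offsets, pidx, exps, coefs, zcoords, zvals,
                zatom, comp_off, comp_lx, comp_ly, comp_lz, comp_scale,
                dS, dT, dV):
    """dS, dT, dV of shape (natom, 3, n, n).

    Bra/ket derivatives via Hermite-coefficient shifts; the nuclear-attraction
    operator-center derivative from translational invariance of each
    three-center term.
    """
    ns = len(ls)
    maxl = int(ls.max())
    nE = maxl + 4
    Ex = np.zeros((nE, nE, 2 * nE))
    Ey = np.zeros((nE, nE, 2 * nE))
    Ez = np.zeros((nE, nE, 2 * nE))
    LR = 2 * maxl + 1
    R = np.zeros((LR + 1, LR + 1, LR + 1))
    nz = len(zvals)
    for A in range(ns):
        la = ls[A]
        nca = comp_off[la + 1] - comp_off[la]
        for B in range(ns):
            lb = ls[B]
            ncb = comp_off[lb + 1] - comp_off[lb]
            ABx = centers[A, 0] - centers[B, 0]
            ABy = centers[A, 1] - centers[B, 1]
            ABz = centers[A, 2] - centers[B, 2]
            for ka in range(pidx[A], pidx[A + 1]):
                a = exps[ka]
                for kb in range(pidx[B], pidx[B + 1]):
                    b = exps[kb]
                    p = a + b
                    cc = coefs[ka] * coefs[kb]
                    # E tables big enough for i+1 and j+2
                    _fill_E(la + 1, lb + 2, a, b, ABx, Ex)
                    _fill_E(la + 1, lb + 2, a, b, ABy, Ey)
                    _fill_E(la + 1, lb + 2, a, b, ABz, Ez)
                    sq = np.sqrt(np.pi / p)
                    Px = (a * centers[A, 0] + b * centers[B, 0]) / p
                    Py = (a * centers[A, 1] + b * centers[B, 1]) / p
                    Pz = (a * centers[A, 2] + b * centers[B, 2]) / p
                    for ia in range(nca):
                        ix = comp_lx[comp_off[la] + ia]
                        iy = comp_ly[comp_off[la] + ia]
                        iz = comp_lz[comp_off[la] + ia]
                        sa = comp_scale[comp_off[la] + ia]
                        mu = offsets[A] + ia
                        for ib in range(ncb):
                            jx = comp_lx[comp_off[lb] + ib]
                            jy = comp_ly[comp_off[lb] + ib]
                            jz = comp_lz[comp_off[lb] + ib]
                            sb = comp_scale[comp_off[lb] + ib]
                            nu = offsets[B] + ib
                            w = cc * sa * sb
                            # 1-D overlap and kinetic factors; da = bra derivative
                            # d/dAx f_i = 2a f_{i+1} - i f_{i-1}
                            for axis in range(3):
                                if axis == 0:
                                    i0, j0 = ix, jx
                                    Eax = Ex
                                elif axis == 1:
                                    i0, j0 = iy, jy
                                    Eax = Ey
                                else:
                                    i0, j0 = iz, jz
                                    Eax = Ez
                                s_i = Eax[i0, j0, 0] * sq
                                ds_i = 2.0 * a * Eax[i0 + 1, j0, 0] * sq
                                if i0 > 0:
                                    ds_i -= i0 * Eax[i0 - 1, j0, 0] * sq
                                # kinetic 1-D on this axis and its bra derivative
                                t_i = -2.0 * b * b * Eax[i0, j0 + 2, 0] * sq \
                                    + b * (2 * j0 + 1) * s_i
                                if j0 >= 2:
                                    t_i -= 0.5 * j0 * (j0 - 1) * Eax[i0, j0 - 2, 0] * sq
                                dt_i = -2.0 * b * b * (2.0 * a * Eax[i0 + 1, j0 + 2, 0] * sq) \
                                    + b * (2 * j0 + 1) * 2.0 * a * Eax[i0 + 1, j0, 0] * sq
                                if i0 > 0:
                                    dt_i += 2.0 * b * b * i0 * Eax[i0 - 1, j0 + 2, 0] * sq \
                                        - b * (2 * j0 + 1) * i0 * Eax[i0 - 1, j0, 0] * sq
                                if j0 >= 2:
                                    dt_i -= 0.5 * j0 * (j0 - 1) * 2.0 * a * Eax[i0 + 1, j0 - 2, 0] * sq
                                    if i0 > 0:
                                        dt_i += 0.5 * j0 * (j0 - 1) * i0 * Eax[i0 - 1, j0 - 2, 0] * sq
                                # other axes full factors
                                if axis == 0:
                                    o1s = Ey[iy, jy, 0] * sq; o2s = Ez[iz, jz, 0] * sq
                                    o1t = -2.0 * b * b * Ey[iy, jy + 2, 0] * sq + b * (2 * jy + 1) * o1s
                                    if jy >= 2:
                                        o1t -= 0.5 * jy * (jy - 1) * Ey[iy, jy - 2, 0] * sq
                                    o2t = -2.0 * b * b * Ez[iz, jz + 2, 0] * sq + b * (2 * jz + 1) * o2s
                                    if jz >= 2:
                                        o2t -= 0.5 * jz * (jz - 1) * Ez[iz, jz - 2, 0] * sq
                                elif axis == 1:
                                    o1s = Ex[ix, jx, 0] * sq; o2s = Ez[iz, jz, 0] * sq
                                    o1t = -2.0 * b * b * Ex[ix, jx + 2, 0] * sq + b * (2 * jx + 1) * o1s
                                    if jx >= 2:
                                        o1t -= 0.5 * jx * (jx - 1) * Ex[ix, jx - 2, 0] * sq
                                    o2t = -2.0 * b * b * Ez[iz, jz + 2, 0] * sq + b * (2 * jz + 1) * o2s
                                    if jz >= 2:
                                        o2t -= 0.5 * jz * (jz - 1) * Ez[iz, jz - 2, 0] * sq
                                else:
                                    o1s = Ex[ix, jx, 0] * sq; o2s = Ey[iy, jy, 0] * sq
                                    o1t = -2.0 * b * b * Ex[ix, jx + 2, 0] * sq + b * (2 * jx + 1) * o1s
                                    if jx >= 2:
                                        o1t -= 0.5 * jx * (jx - 1) * Ex[ix, jx - 2, 0] * sq
                                    o2t = -2.0 * b * b * Ey[iy, jy + 2, 0] * sq + b * (2 * jy + 1) * o2s
                                    if jy >= 2:
                                        o2t -= 0.5 * jy * (jy - 1) * Ey[iy, jy - 2, 0] * sq
                                # two-center integrals depend on A - B only,
                                # so the ket derivative is minus the bra one
                                dsv = w * ds_i * o1s * o2s
                                dtv = w * (dt_i * o1s * o2s + ds_i * o1t * o2s
                                           + ds_i * o1s * o2t)
                                dS[atoms[A], axis, mu, nu] += dsv
                                dS[atoms[B], axis, mu, nu] -= dsv
                                dT[atoms[A], axis, mu, nu] += dtv
                                dT[atoms[B], axis, mu, nu] -= dtv
                    # nuclear attraction derivatives
                    for kc in range(nz):
                        if zvals[kc] == 0.0:
                            continue
                        _fill_R(la + lb + 1, p, Px - zcoords[kc, 0],
                                Py - zcoords[kc, 1], Pz - zcoords[kc, 2], R)
                        pref = -zvals[kc] * 2.0 * np.pi / p
                        for ia in range(nca):
                            ix = comp_lx[comp_off[la] + ia]
                            iy = comp_ly[comp_off[la] + ia]
                            iz = comp_lz[comp_off[la] + ia]
                            sa = comp_scale[comp_off[la] + ia]
                            mu = offsets[A] + ia
                            for ib in range(ncb):
                                jx = comp_lx[comp_off[lb] + ib]
                                jy = comp_ly[comp_off[lb] + ib]
                                jz = comp_lz[comp_off[lb] + ib]
                                sb = comp_scale[comp_off[lb] + ib]
                                nu = offsets[B] + ib
                                w = cc * sa * sb * pref
                                for axis in range(3):
                                    accA = 0.0  # bra derivative
                                    accC = 0.0  # operator-center derivative
                                    for t in range(ix + jx + 2):
                                        for u in range(iy + jy + 2):
                                            for v in range(iz + jz + 2):
                                                if axis == 0:
                                                    if u <= iy + jy and v <= iz + jz and t <= ix + jx + 1:
                                                        dE = 2.0 * a * Ex[ix + 1, jx, t]
                                                        if ix > 0:
                                                            dE -= ix * Ex[ix - 1, jx, t]
                                                        accA += dE * Ey[iy, jy, u] * Ez[iz, jz, v] * R[t, u, v]
                                                    if t <= ix + jx and u <= iy + jy and v <= iz + jz:
                                                        accC += Ex[ix, jx, t] * Ey[iy, jy, u] \
                                                            * Ez[iz, jz, v] * R[t + 1, u, v]
                                                elif axis == 1:
                                                    if t <= ix + jx and v <= iz + jz and u <= iy + jy + 1:
                                                        dE = 2.0 * a * Ey[iy + 1, jy, u]
                                                        if iy > 0:
                                                            dE -= iy * Ey[iy - 1, jy, u]
                                                        accA += Ex[ix, jx, t] * dE * Ez[iz, jz, v] * R[t, u, v]
                                                    if t <= ix + jx and u <= iy + jy and v <= iz + jz:
                                                        accC += Ex[ix, jx, t] * Ey[iy, jy, u] \
                                                            * Ez[iz, jz, v] * R[t, u + 1, v]
                                                else:
                                                    if t <= ix + jx and u <= iy + jy and v <= iz + jz + 1:
                                                        dE = 2.0 * a * Ez[iz + 1, jz, v]
                                                        if iz > 0:
                                                            dE -= iz * Ez[iz - 1, jz, v]
                                                        accA += Ex[ix, jx, t] * Ey[iy, jy, u] * dE * R[t, u, v]
                                                    if t <= ix + jx and u <= iy + jy and v <= iz + jz:
                                                        accC += Ex[ix, jx, t] * Ey[iy, jy, u] \
                                                            * Ez[iz, jz, v] * R[t, u, v + 1]
                                    # d/dC of R^0: derivative w.r.t. P shifts sign:
                                    # dR/dCx = -dR/dPx and dV/dP enters bra+ket; use
                                    # translational invariance: dV/dB = -(dV/dA + dV/dC)
                                    dV[atoms[A], axis, mu, nu] += w * accA
                                    dV[zatom[kc], axis, mu, nu] -= w * accC
                                    # ket derivative = -(bra + operator) for this term
                                    dV[atoms[B], axis, mu, nu] += w * (accC - accA)


@njit(cache=False)
def _dE1d(i, j, t, two_exp_a, Etab, on_bra):
    """d/d(center) of a 1-D Hermite-expanded pair factor.

    on_bra=True differentiates the first index (coefficient two_exp_a = 2a),
    otherwise the second (two_exp_a = 2b).
    """
    if on_bra:
        v = two_exp_a * Etab[i + 1, j, t]
        if i > 0:
            v -= i * Etab[i - 1, j, t]
    else:
        v = two_exp_a * Etab[i, j + 1, t]
        if j > 0:
            v -= j * Etab[i, j - 1, t]
    return v


@njit(cache=False)
def _deri_kernel(centers, ls, atoms, offsets, pidx, exps, coefs,
                 comp_off, comp_lx, comp_ly, comp_lz, comp_scale, dERI):
    """dERI of shape (natom, 3, n, n, n, n); small systems only.

    Derivatives with respect to the first three centers are evaluated from
    shifted Hermite expansions; the fourth follows from translational
    invariance, so the per-element tensor is exact.
    """
    ns = len(ls)
    for A in range(ns):
        la = ls[A]
        nca = comp_off[la + 1] - comp_off[la]
        for B in range(ns):
            lb = ls[B]
            ncb = comp_off[lb + 1] - comp_off[lb]
            ABx = centers[A, 0] - centers[B, 0]
            ABy = centers[A, 1] - centers[B, 1]
            ABz = centers[A, 2] - centers[B, 2]
            for C in range(ns):
                lc = ls[C]
                ncc = comp_off[lc + 1] - comp_off[lc]
                for D in range(ns):
                    ld = ls[D]
                    ncd = comp_off[ld + 1] - comp_off[ld]
                    CDx = centers[C, 0] - centers[D, 0]
                    CDy = centers[C, 1] - centers[D, 1]
                    CDz = centers[C, 2] - centers[D, 2]
                    L1 = la + lb + 1
                    L2 = lc + ld + 1
                    L = L1 + L2
                    E1x = np.zeros((la + 2, lb + 2, L1 + 2))
                    E1y = np.zeros((la + 2, lb + 2, L1 + 2))
                    E1z = np.zeros((la + 2, lb + 2, L1 + 2))
                    E2x = np.zeros((lc + 2, ld + 2, L2 + 2))
                    E2y = np.zeros((lc + 2, ld + 2, L2 + 2))
                    E2z = np.zeros((lc + 2, ld + 2, L2 + 2))
                    R = np.zeros((L + 1, L + 1, L + 1))
                    for ka in range(pidx[A], pidx[A + 1]):
                        a = exps[ka]
                        for kb in range(pidx[B], pidx[B + 1]):
                            b = exps[kb]
                            p = a + b
                            cab = coefs[ka] * coefs[kb]
                            _fill_E(la + 1, lb + 1, a, b, ABx, E1x)
                            _fill_E(la + 1, lb + 1, a, b, ABy, E1y)
                            _fill_E(la + 1, lb + 1, a, b, ABz, E1z)
                            Px = (a * centers[A, 0] + b * centers[B, 0]) / p
                            Py = (a * centers[A, 1] + b * centers[B, 1]) / p
                            Pz = (a * centers[A, 2] + b * centers[B, 2]) / p
                            for kc in range(pidx[C], pidx[C + 1]):
                                c = exps[kc]
                                for kd in range(pidx[D], pidx[D + 1]):
                                    d = exps[kd]
                                    q = c + d
                                    w0 = cab * coefs[kc] * coefs[kd]
                                    _fill_E(lc + 1, ld + 1, c, d, CDx, E2x)
                                    _fill_E(lc + 1, ld + 1, c, d, CDy, E2y)
                                    _fill_E(lc + 1, ld + 1, c, d, CDz, E2z)
                                    Qx = (c * centers[C, 0] + d * centers[D, 0]) / q
                                    Qy = (c * centers[C, 1] + d * centers[D, 1]) / q
                                    Qz = (c * centers[C, 2] + d * centers[D, 2]) / q
                                    alpha = p * q / (p + q)
                                    _fill_R(L, alpha, Px - Qx, Py - Qy, Pz - Qz, R)
                                    pref = w0 * 2.0 * np.pi**2.5 / (p * q * np.sqrt(p + q))
                                    for ia in range(nca):
                                        ix = comp_lx[comp_off[la] + ia]
                                        iy = comp_ly[comp_off[la] + ia]
                                        iz = comp_lz[comp_off[la] + ia]
                                        sa = comp_scale[comp_off[la] + ia]
                                        mu = offsets[A] + ia
                                        for ib in range(ncb):
                                            jx = comp_lx[comp_off[lb] + ib]
                                            jy = comp_ly[comp_off[lb] + ib]
                                            jz = comp_lz[comp_off[lb] + ib]
                                            sb = comp_scale[comp_off[lb] + ib]
                                            nu = offsets[B] + ib
                                            for ic in range(ncc):
                                                kx = comp_lx[comp_off[lc] + ic]
                                                ky = comp_ly[comp_off[lc] + ic]
                                                kz = comp_lz[comp_off[lc] + ic]
                                                sc = comp_scale[comp_off[lc] + ic]
                                                lm = offsets[C] + ic
                                                for id_ in range(ncd):
                                                    mx = comp_lx[comp_off[ld] + id_]
                                                    my = comp_ly[comp_off[ld] + id_]
                                                    mz = comp_lz[comp_off[ld] + id_]
                                                    sd = comp_scale[comp_off[ld] + id_]
                                                    sg = offsets[D] + id_
                                                    wp = pref * sa * sb * sc * sd
                                                    for axis in range(3):
                                                        accA = 0.0
                                                        accB = 0.0
                                                        accC = 0.0
                                                        # bra-side derivatives (A and B)
                                                        for t in range(ix + jx + 2):
                                                            for u in range(iy + jy + 2):
                                                                for v in range(iz + jz + 2):
                                                                    if axis == 0:
                                                                        eA = _dE1d(ix, jx, t, 2.0 * a, E1x, True) \
                                                                            * E1y[iy, jy, u] * E1z[iz, jz, v]
                                                                        eB = _dE1d(ix, jx, t, 2.0 * b, E1x, False) \
                                                                            * E1y[iy, jy, u] * E1z[iz, jz, v]
                                                                    elif axis == 1:
                                                                        eA = E1x[ix, jx, t] * _dE1d(iy, jy, u, 2.0 * a, E1y, True) \
                                                                            * E1z[iz, jz, v]
                                                                        eB = E1x[ix, jx, t] * _dE1d(iy, jy, u, 2.0 * b, E1y, False) \
                                                                            * E1z[iz, jz, v]
                                                                    else:
                                                                        eA = E1x[ix, jx, t] * E1y[iy, jy, u] \
                                                                            * _dE1d(iz, jz, v, 2.0 * a, E1z, True)
                                                                        eB = E1x[ix, jx, t] * E1y[iy, jy, u] \
                                                                            * _dE1d(iz, jz, v, 2.0 * b, E1z, False)
                                                                    if eA == 0.0 and eB == 0.0:
                                                                        continue
                                                                    for tt in range(kx + mx + 1):
                                                                        for uu in range(ky + my + 1):
                                                                            for vv in range(kz + mz + 1):
                                                                                e2 = E2x[kx, mx, tt] * E2y[ky, my, uu] * E2z[kz, mz, vv]
                                                                                if e2 == 0.0:
                                                                                    continue
                                                                                sgn = 1.0 if (tt + uu + vv) % 2 == 0 else -1.0
                                                                                r = sgn * R[t + tt, u + uu, v + vv]
                                                                                accA += eA * e2 * r
                                                                                accB += eB * e2 * r
                                                        # third-center derivative
                                                        for t in range(ix + jx + 1):
                                                            for u in range(iy + jy + 1):
                                                                for v in range(iz + jz + 1):
                                                                    e1 = E1x[ix, jx, t] * E1y[iy, jy, u] * E1z[iz, jz, v]
                                                                    if e1 == 0.0:
                                                                        continue
                                                                    for tt in range(kx + mx + 2):
                                                                        for uu in range(ky + my + 2):
                                                                            for vv in range(kz + mz + 2):
                                                                                if axis == 0:
                                                                                    e2 = _dE1d(kx, mx, tt, 2.0 * c, E2x, True) \
                                                                                        * E2y[ky, my, uu] * E2z[kz, mz, vv]
                                                                                elif axis == 1:
                                                                                    e2 = E2x[kx, mx, tt] * _dE1d(ky, my, uu, 2.0 * c, E2y, True) \
                                                                                        * E2z[kz, mz, vv]
                                                                                else:
                                                                                    e2 = E2x[kx, mx, tt] * E2y[ky, my, uu] \
                                                                                        * _dE1d(kz, mz, vv, 2.0 * c, E2z, True)
                                                                                if e2 == 0.0:
                                                                                    continue
                                                                                sgn = 1.0 if (tt + uu + vv) % 2 == 0 else -1.0
                                                                                accC += e1 * e2 * sgn * R[t + tt, u + uu, v + vv]
                                                        dERI[atoms[A], axis, mu, nu, lm, sg] += wp * accA
                                                        dERI[atoms[B], axis, mu, nu, lm, sg] += wp * accB
                                                        dERI[atoms[C], axis, mu, nu, lm, sg] += wp * accC
                                                        dERI[atoms[D], axis, mu, nu, lm, sg] -= wp * (accA + accB + accC)


# ---------------------------------------------------------------------------
# Python-level driver
# ---------------------------------------------------------------------------

@dataclass
class SCFResult:
    """Converged (or final) state of an SCF run."""

    energy: float                 # total energy incl. nuclear repulsion + extras
    e_electronic: float           # HF electronic energy
    e_nuc: float
    e_extra: float                # environment-term energy (0 for gas phase)
    mo_coeff: np.ndarray
    mo_energy: np.ndarray
    density: np.ndarray           # total density matrix D = 2 C_occ C_occ^T
    fock: np.ndarray
    n_iter: int
    converged: bool
    history: list = field(default_factory=list)


class RHF:
    """Closed-shell restricted Hartree–Fock on a fixed geometry and basis."""

    def __init__(self, mol: Molecule, basis: str = "sto-3g",
                 schwarz_thresh: float = 1e-14):
        if mol.n_electrons % 2 != 0:
            raise ValueError(
                f"RHF needs an even electron count, got {mol.n_electrons}")
        self.mol = mol
        self.basis: BasisSet = build_basis(mol, basis)
        self.n_ao = self.basis.n_ao
        self.n_occ = mol.n_electrons // 2
        self.schwarz_thresh = schwarz_thresh
        self._ints = None

    # -- integrals --------------------------------------------------------

    def integrals(self):
        """(S, T, V, ERI); computed once and cached."""
        if self._ints is None:
            centers, ls, atoms, offsets, pidx, exps, coefs = self.basis.flat_arrays()
            n = self.n_ao
            S = np.zeros((n, n)); T = np.zeros((n, n)); V = np.zeros((n, n))
            _int1e_kernel(centers, ls, offsets, pidx, exps, coefs,
                          self.mol.coords, self.mol.charges,
                          COMP_OFF, COMP_LX, COMP_LY, COMP_LZ, COMP_SCALE,
                          S, T, V)
            eri = np.zeros((n, n, n, n))
            _eri_kernel(centers, ls, offsets, pidx, exps, coefs,
                        COMP_OFF, COMP_LX, COMP_LY, COMP_LZ, COMP_SCALE,
                        eri, self.schwarz_thresh)
            self._ints = (S, T, V, eri)
        return self._ints

    def fock_2e(self, D: np.ndarray) -> np.ndarray:
        _, _, _, eri = self.integrals()
        J = np.einsum("pqrs,rs->pq", eri, D, optimize=True)
        K = np.einsum("prqs,rs->pq", eri, D, optimize=True)
        return J - 0.5 * K

    # -- SCF ---------------------------------------------------------------

    def scf(self, extra_fock: Callable[[np.ndarray], tuple[float, np.ndarray]] | None = None,
            conv_tol: float = 1e-7, max_iter: int = 200,
            d0: np.ndarray | None = None,
            diis_size: int = 8, log: Callable[[str], None] | None = None) -> SCFResult:
        """Iterate to self-consistency.

        extra_fock(D) must return ``(E_extra(D), F_extra(D))`` where F_extra is
        the derivative of E_extra with respect to the density matrix.
        Convergence requires |dE| < conv_tol on the total energy and a small
        DIIS error.
        """
        S, T, V, _ = self.integrals()
        hcore = T + V
        e_nuc = self.mol.nuclear_repulsion()
        # symmetric orthogonalization
        sev, svec = np.linalg.eigh(S)
        X = svec @ np.diag(sev**-0.5) @ svec.T

        if d0 is not None:
            D = d0.copy()
        else:
            e, C = scipy.linalg.eigh(hcore, S)
            Cocc = C[:, :self.n_occ]
            D = 2.0 * Cocc @ Cocc.T

        diis_F: list[np.ndarray] = []
        diis_err: list[np.ndarray] = []
        e_old = 0.0
        history = []
        C = None
        eps = None
        e_extra = 0.0
        converged = False
        n_done = 0
        for it in range(1, max_iter + 1):
            F = hcore + self.fock_2e(D)
            e_hf = 0.5 * np.einsum("pq,pq->", D, hcore + F)
            if extra_fock is not None:
                e_extra, F_extra = extra_fock(D)
                F = F + F_extra
            else:
                e_extra = 0.0
            e_tot = e_hf + e_nuc + e_extra

            err = X.T @ (F @ D @ S - S @ D @ F) @ X
            err_norm = np.max(np.abs(err))
            diis_F.append(F.copy())
            diis_err.append(err)
            if len(diis_F) > diis_size:
                diis_F.pop(0); diis_err.pop(0)
            if len(diis_F) > 1:
                m = len(diis_F)
                Bm = -np.ones((m + 1, m + 1)); Bm[m, m] = 0.0
                for i in range(m):
                    for j in range(m):
                        Bm[i, j] = np.sum(diis_err[i] * diis_err[j])
                rhs = np.zeros(m + 1); rhs[m] = -1.0
                try:
                    cvec = np.linalg.solve(Bm, rhs)[:m]
                    F = sum(c * f for c, f in zip(cvec, diis_F))
                except np.linalg.LinAlgError:
                    pass

            eps, C = scipy.linalg.eigh(F, S)
            Cocc = C[:, :self.n_occ]
            D = 2.0 * Cocc @ Cocc.T

            de = e_tot - e_old
            history.append({"iter": it, "energy": e_tot, "dE": de,
                            "err": err_norm, "e_extra": e_extra})
            if log is not None:
                log(f"iter {it:3d}  E = {e_tot:+.10f}  dE = {de:+.3e}  "
                    f"err = {err_norm:.3e}")
            n_done = it
            if it > 1 and abs(de) < conv_tol and err_norm < 1e-5:
                converged = True
                break
            e_old = e_tot

        # final energy at the converged density
        F = hcore + self.fock_2e(D)
        e_hf = 0.5 * np.einsum("pq,pq->", D, hcore + F)
        if extra_fock is not None:
            e_extra, F_extra = extra_fock(D)
            F_full = F + F_extra
        else:
            e_extra = 0.0
            F_full = F
        eps, C = scipy.linalg.eigh(F_full, S)
        e_tot = e_hf + e_nuc + e_extra
        return SCFResult(energy=e_tot, e_electronic=e_hf, e_nuc=e_nuc,
                         e_extra=e_extra, mo_coeff=C, mo_energy=eps,
                         density=D, fock=F_full, n_iter=n_done,
                         converged=converged, history=history)

    # -- gradients ---------------------------------------------------------

    def gradient_hf(self, res: SCFResult) -> np.ndarray:
        """Nuclear gradient of the HF energy (electronic + nuclear repulsion).

        Uses the energy-weighted density built from the *full* Fock matrix of
        `res`, so environment (pressure) orbital-response terms are folded in;
        the environment's explicit geometry derivative must be added by the
        caller.
        """
        centers, ls, atoms, offsets, pidx, exps, coefs = self.basis.flat_arrays()
        n = self.n_ao
        natom = self.mol.n_atoms
        dS = np.zeros((natom, 3, n, n))
        dT = np.zeros((natom, 3, n, n))
        dV = np.zeros((natom, 3, n, n))
        zatom = np.arange(natom, dtype=np.int64)
        _d1e_kernel(centers, ls, atoms, offsets, pidx, exps, coefs,
                    self.mol.coords, self.mol.charges, zatom,
                    COMP_OFF, COMP_LX, COMP_LY, COMP_LZ, COMP_SCALE,
                    dS, dT, dV)
        dERI = np.zeros((natom, 3, n, n, n, n))
        _deri_kernel(centers, ls, atoms, offsets, pidx, exps, coefs,
                     COMP_OFF, COMP_LX, COMP_LY, COMP_LZ, COMP_SCALE, dERI)

        D = res.density
        occ = slice(0, self.n_occ)
        C = res.mo_coeff
        W = 2.0 * (C[:, occ] * res.mo_energy[occ]) @ C[:, occ].T

        g = self.mol.nuclear_repulsion_gradient()
        g += np.einsum("axpq,pq->ax", dT + dV, D, optimize=True)
        g -= np.einsum("axpq,pq->ax", dS, W, optimize=True)
        g += 0.5 * np.einsum("axpqrs,pq,rs->ax", dERI, D, D, optimize=True)
        g -= 0.25 * np.einsum("axpqrs,pr,qs->ax", dERI, D, D, optimize=True)
        return g
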