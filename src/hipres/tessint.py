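"""Three-center overlap integrals between basis pairs and tessera Gaussians.

The surface Gaussian of tessera j is an s-type normalized Gaussian
G_j(r) = N_j exp(-omega_j |r - r_j|^2).  The integrals needed are

    g_{mu nu, j} = <mu| G_j |nu>                       (value type)
    f_{mu nu, j} = n_j . grad_{r_j} <mu| G_j |nu>      (normal-derivative type)

plus, for nuclear gradients, their derivatives with respect to the tessera
exponent at fixed normalization (s/d- and p/f-type surface Gaussians) and
with respect to the bra shell center (ket- and tessera-center derivatives
follow from translational invariance).

Evaluation applies the Gaussian product theorem to collapse the three
Gaussians into one and Gauss-Hermite quadrature per Cartesian direction,
which is exact for the polynomial prefactors.  A conservative distance-based
screening bound allows distant (shell-pair, tessera) combinations to be
skipped without ever changing a kept value.

Two code paths exist: a generic vectorized numpy path (any angular momentum
up to g shells, all derivative types) and numba sweep kernels used by the
SCF coupling for the density contractions and Fock assembly (integral-direct:
nothing of size N_basis^2 x N_tess is ever stored).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb as _comb
from math import gamma as _gamma

import numpy as np
from numba import njit

from .basis import Shell, cart_components, component_scale

__all__ = [
    "TesseraBatch", "g_integrals", "f_integrals",
    "exponent_derivative_integrals", "bra_derivative_integrals",
    "pair_blocks", "screen_batches", "sweep_aux_vectors", "sweep_fock",
    "MAX_ANGULAR_MOMENTUM",
]

MAX_ANGULAR_MOMENTUM = 4

# Gauss-Hermite nodes/weights (physicists', weight e^{-x^2}) for orders 1..8,
# flattened for the numba kernels.
_GH_MAX = 8
_gh_x, _gh_w, _gh_off = [], [], [0]
for _n in range(1, _GH_MAX + 1):
    _x, _w = np.polynomial.hermite.hermgauss(_n)
    _gh_x.extend(_x); _gh_w.extend(_w)
    _gh_off.append(len(_gh_x))
GH_X = np.array(_gh_x)
GH_W = np.array(_gh_w)
GH_OFF = np.array(_gh_off, dtype=np.int64)


@dataclass
class TesseraBatch:
    """A contiguous batch of tesserae in kernel-friendly array form."""

    centers: np.ndarray   # (nt, 3)
    omegas: np.ndarray    # (nt,)
    norms: np.ndarray     # (nt,)  normalizations N_j
    normals: np.ndarray   # (nt, 3)
    areas: np.ndarray     # (nt,)

    @classmethod
    def from_cavity(cls, cav, sl: slice = slice(None)) -> "TesseraBatch":
        return cls(cav.centers[sl], cav.omegas[sl], cav.norms[sl],
                   cav.normals[sl], cav.areas[sl])

    @property
    def n(self) -> int:
        return len(self.omegas)


def _check_l(*shells: Shell) -> None:
    for s in shells:
        if s.l > MAX_ANGULAR_MOMENTUM:
            raise NotImplementedError(
                f"angular momentum {s.l} beyond implemented maximum "
                f"{MAX_ANGULAR_MOMENTUM}")


def pair_blocks(sha: Shell, shb: Shell, tess: TesseraBatch,
                want: tuple[str, ...] = ("g", "f")) -> dict[str, np.ndarray]:
    """All requested integral blocks for one shell pair and a tessera batch.

    Returns a dict with (subsets of) keys:
      g     (nca, ncb, nt)
      f     (nca, ncb, nt)
      dgdw  (nca, ncb, nt)     d g / d omega at fixed N_j
      dfdw  (nca, ncb, nt)     d f / d omega at fixed N_j
      dgdA  (3, nca, ncb, nt)  d g / d (bra center)
      dfdA  (3, nca, ncb, nt)
    """
    _check_l(sha, shb)
    la, lb = sha.l, shb.l
    compa = cart_components(la)
    compb = cart_components(lb)
    nca, ncb = len(compa), len(compb)
    nt = tess.n
    need_bra = any(k in want for k in ("dgdA", "dfdA"))
    need_k3 = any(k in want for k in ("dgdw", "dfdw"))
    ni = la + 2 if need_bra else la + 1
    nj = lb + 1
    nk = 4 if need_k3 else 2
    deg = (ni - 1) + (nj - 1) + (nk - 1)
    ngh = deg // 2 + 1
    hx, hw = np.polynomial.hermite.hermgauss(ngh)

    out = {k: np.zeros(((3, nca, ncb, nt) if k.endswith("dA") else (nca, ncb, nt)))
           for k in want}

    A, B = sha.center, shb.center
    om = tess.omegas
    C = tess.centers
    nrm = tess.normals

    for a, ca in zip(sha.exps, sha.coefs):
        for b, cb in zip(shb.exps, shb.coefs):
            sp = a + b
            P = (a * A + b * B) / sp
            kab = np.exp(-a * b / sp * np.dot(A - B, A - B))
            q = sp + om                              # (nt,)
            Q = (sp * P[None, :] + om[:, None] * C) / q[:, None]
            d2 = np.sum((P[None, :] - C) ** 2, axis=1)
            pref = ca * cb * kab * tess.norms * np.exp(-sp * om / q * d2) \
                * q ** -1.5                          # (nt,)
            rq = 1.0 / np.sqrt(q)
            # I[d][i, j, k, t]: per-direction Gauss-Hermite sums
            I = []
            for d in range(3):
                x = Q[:, d][None, :] + hx[:, None] * rq[None, :]   # (ngh, nt)
                pa = np.stack([(x - A[d]) ** i for i in range(ni)])
                pb = np.stack([(x - B[d]) ** j for j in range(nj)])
                pc = np.stack([(x - C[:, d][None, :]) ** k for k in range(nk)])
                I.append(np.einsum("n,ant,bnt,cnt->abct", hw, pa, pb, pc,
                                   optimize=True))

            def I3(ii, jj, kk):
                return I[0][ii[0], jj[0], kk[0]] * I[1][ii[1], jj[1], kk[1]] \
                    * I[2][ii[2], jj[2], kk[2]]

            for ia, ca_comp in enumerate(compa):
                sa = component_scale(*ca_comp)
                for ib, cb_comp in enumerate(compb):
                    sb = component_scale(*cb_comp)
                    w = pref * sa * sb
                    ii, jj = ca_comp, cb_comp
                    k0 = (0, 0, 0)
                    if "g" in out:
                        out["g"][ia, ib] += w * I3(ii, jj, k0)
                    if "f" in out or "dfdw" in out:
                        fsum = np.zeros(nt)
                        for be in range(3):
                            kk = [0, 0, 0]; kk[be] = 1
                            fsum += nrm[:, be] * I3(ii, jj, kk)
                        if "f" in out:
                            out["f"][ia, ib] += 2.0 * om * w * fsum
                    if "dgdw" in out:
                        ssum = np.zeros(nt)
                        for ga in range(3):
                            kk = [0, 0, 0]; kk[ga] = 2
                            ssum += I3(ii, jj, kk)
                        out["dgdw"][ia, ib] -= w * ssum
                    if "dfdw" in out:
                        acc = 2.0 * fsum.copy()
                        for be in range(3):
                            for ga in range(3):
                                kk = [0, 0, 0]; kk[be] += 1; kk[ga] += 2
                                acc -= 2.0 * om * nrm[:, be] * I3(ii, jj, kk)
                        out["dfdw"][ia, ib] += w * acc
                    if need_bra:
                        for d in range(3):
                            iu = list(ii); iu[d] += 1
                            idn = list(ii); idn[d] -= 1
                            if "dgdA" in out:
                                v = 2.0 * a * I3(iu, jj, k0)
                                if ii[d] > 0:
                                    v -= ii[d] * I3(idn, jj, k0)
                                out["dgdA"][d, ia, ib] += w * v
                            if "dfdA" in out:
                                v = np.zeros(nt)
                                for be in range(3):
                                    kk = [0, 0, 0]; kk[be] = 1
                                    t = 2.0 * a * I3(iu, jj, kk)
                                    if ii[d] > 0:
                                        t -= ii[d] * I3(idn, jj, kk)
                                    v += nrm[:, be] * t
                                out["dfdA"][d, ia, ib] += 2.0 * om * w * v
    return out


def g_integrals(sha: Shell, shb: Shell, tess: TesseraBatch) -> np.ndarray:
    """<mu|G_j|nu> block, shape (nca, ncb, nt)."""
    return pair_blocks(sha, shb, tess, want=("g",))["g"]


def f_integrals(sha: Shell, shb: Shell, tess: TesseraBatch) -> np.ndarray:
    """n_j . grad_{r_j} <mu|G_j|nu> block, shape (nca, ncb, nt)."""
    return pair_blocks(sha, shb, tess, want=("f",))["f"]


def exponent_derivative_integrals(sha: Shell, shb: Shell,
                                  tess: TesseraBatch) -> tuple[np.ndarray, np.ndarray]:
    """(dg/domega, df/domega) at fixed N_j; shapes (nca, ncb, nt)."""
    r = pair_blocks(sha, shb, tess, want=("dgdw", "dfdw"))
    return r["dgdw"], r["dfdw"]


def bra_derivative_integrals(sha: Shell, shb: Shell,
                             tess: TesseraBatch) -> tuple[np.ndarray, np.ndarray]:
    """(dg/dA, df/dA) with A the bra shell center; shapes (3, nca, ncb, nt).

    Ket and tessera-center derivatives follow from translational invariance:
    d/dA + d/dB + d/dr_j = 0 for every block.
    """
    r = pair_blocks(sha, shb, tess, want=("dgdA", "dfdA"))
    return r["dgdA"], r["dfdA"]


# ---------------------------------------------------------------------------
# Conservative screening
# ---------------------------------------------------------------------------

def screen_batches(sha: Shell, shb: Shell, tess: TesseraBatch,
                   threshold: float) -> tuple[bool, float]:
    """Decide whether a (shell pair, tessera batch) can be skipped.

    Returns ``(keep, bound)`` where `bound` is a provable upper bound on
    max |g_{mu nu, j}| and max |f_{mu nu, j}| over the batch.  The bound uses
    the Gaussian-product distance between the pair-overlap center and the
    tessera center:  collapsing |mu nu| G_j exactly yields the factor
    exp(-xi d^2) with xi = sp*omega/(sp+omega), and the remaining polynomial
    integral is bounded by binomial expansion around the combined center with
    closed-form absolute Gaussian moments.  Skip only when bound < threshold;
    never a false skip.
    """
    if threshold < 0:
        raise ValueError("screening threshold must be >= 0")
    _check_l(sha, shb)
    la, lb = sha.l, shb.l
    A, B = sha.center, shb.center
    om = tess.omegas
    C = tess.centers
    bound_g = np.zeros(tess.n)
    bound_f = np.zeros(tess.n)
    smax_a = max(component_scale(*c) for c in cart_components(la))
    smax_b = max(component_scale(*c) for c in cart_components(lb))
    for a, ca in zip(sha.exps, sha.coefs):
        for b, cb in zip(shb.exps, shb.coefs):
            sp = a + b
            P = (a * A + b * B) / sp
            kab = np.exp(-a * b / sp * np.dot(A - B, A - B))
            q = sp + om
            Q = (sp * P[None, :] + om[:, None] * C) / q[:, None]
            d2 = np.sum((P[None, :] - C) ** 2, axis=1)
            decay = np.exp(-sp * om / q * d2)
            cc = abs(ca * cb) * smax_a * smax_b * kab
            # per-direction worst-case absolute Gaussian moment, with (k=1)
            # and without (k=0) one extra factor |x - C_d| (for the f bound)
            QA = np.abs(Q - A[None, :])
            QB = np.abs(Q - B[None, :])
            QC = np.abs(Q - C)
            mom = np.ones(tess.n)
            for d in range(3):
                best = np.zeros(tess.n)
                for i in range(la + 1):
                    for j in range(lb + 1):
                        for kex in (0, 1):
                            m = np.zeros(tess.n)
                            for k in range(i + 1):
                                for l in range(j + 1):
                                    for kc in range(kex + 1):
                                        n_mom = k + l + kc
                                        gmom = _gamma((n_mom + 1) / 2.0) \
                                            / q ** ((n_mom + 1) / 2.0)
                                        m += _comb(i, k) * _comb(j, l) * _comb(kex, kc) \
                                            * QA[:, d] ** (i - k) * QB[:, d] ** (j - l) \
                                            * QC[:, d] ** (kex - kc) * gmom
                            best = np.maximum(best, m)
                mom *= best
            bound_g += cc * tess.norms * decay * mom
            bound_f += cc * tess.norms * decay * mom * 2.0 * om * 3.0
    bound = float(max(bound_g.max(initial=0.0), bound_f.max(initial=0.0)))
    return bound >= threshold, bound


# ---------------------------------------------------------------------------
# numba sweep kernels (integral-direct contractions for the SCF)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _sweep_kernel(centers, ls, offsets, pidx, exps, coefs,
                  comp_off, comp_lx, comp_ly, comp_lz, comp_scale,
                  gh_x, gh_w, gh_off,
                  tc, tom, tnorm, tnormal,
                  mode, D, w1, w2, thresh,
                  gt, ft, F):
    """One pass over all (shell pair, tessera) combinations.

    mode 0: contract the density D into the auxiliary vectors
            gt_j += sum_{mu nu} D g_{mu nu j};  ft_j likewise with f.
    mode 1: accumulate the Fock contribution
            F_{mu nu} += sum_j (w1_j g_{mu nu j} + w2_j f_{mu nu j}).

    Screening: per (pair, tessera) a conservative distance bound (see
    screen_batches) is evaluated from per-primitive data; combinations whose
    g and f bounds both fall below `thresh` are skipped.
    """
    ns = len(ls)
    nt = len(tom)
    maxprim = 0
    for s in range(ns):
        if pidx[s + 1] - pidx[s] > maxprim:
            maxprim = pidx[s + 1] - pidx[s]
    npp = maxprim * maxprim
    Pp = np.empty((npp, 3))
    spp = np.empty(npp)
    ccp = np.empty(npp)
    ap = np.empty(npp)
    pa_pow = np.empty((6, _GH_MAX))
    pb_pow = np.empty((6, _GH_MAX))
    pc_pow = np.empty((2, _GH_MAX))
    Ix = np.empty((6, 6, 2))
    Iy = np.empty((6, 6, 2))
    Iz = np.empty((6, 6, 2))
    sqrt_pi = np.sqrt(np.pi)

    for A in range(ns):
        la = ls[A]
        nca = comp_off[la + 1] - comp_off[la]
        for B in range(A + 1):
            lb = ls[B]
            ncb = comp_off[lb + 1] - comp_off[lb]
            sym = 1.0 if A == B else 2.0
            deg = la + lb + 1
            ngh = deg // 2 + 1
            go = gh_off[ngh - 1]
            ABx = centers[A, 0] - centers[B, 0]
            ABy = centers[A, 1] - centers[B, 1]
            ABz = centers[A, 2] - centers[B, 2]
            ab2 = ABx * ABx + ABy * ABy + ABz * ABz
            # per-primitive pair data
            np_pair = 0
            smax = 0.0
            for ia in range(nca):
                s = comp_scale[comp_off[la] + ia]
                if s > smax:
                    smax = s
            for ib in range(ncb):
                s = comp_scale[comp_off[lb] + ib]
                if s > smax:
                    smax = s
            for ka in range(pidx[A], pidx[A + 1]):
                for kb in range(pidx[B], pidx[B + 1]):
                    a = exps[ka]; b = exps[kb]
                    sp = a + b
                    spp[np_pair] = sp
                    ap[np_pair] = a
                    for d in range(3):
                        Pp[np_pair, d] = (a * centers[A, d] + b * centers[B, d]) / sp
                    ccp[np_pair] = coefs[ka] * coefs[kb] * np.exp(-a * b / sp * ab2)
                    np_pair += 1

            for j in range(nt):
                om = tom[j]
                Nj = tnorm[j]
                # conservative pre-screen over primitives
                if thresh > 0.0:
                    bnd = 0.0
                    for kp in range(np_pair):
                        sp = spp[kp]
                        dx = Pp[kp, 0] - tc[j, 0]
                        dy = Pp[kp, 1] - tc[j, 1]
                        dz = Pp[kp, 2] - tc[j, 2]
                        dd = dx * dx + dy * dy + dz * dz
                        q = sp + om
                        decay = np.exp(-sp * om / q * dd)
                        # worst absolute Gaussian moment per direction:
                        # m_n = Gamma((n+1)/2)/q^{(n+1)/2}, n <= la+lb+1
                        mstar = 0.0
                        for n_mom in range(la + lb + 2):
                            gm = _gamma_half(n_mom) / q ** ((n_mom + 1) / 2.0)
                            if gm > mstar:
                                mstar = gm
                        dpa = np.sqrt(dd)
                        pax = np.sqrt((Pp[kp, 0] - centers[A, 0]) ** 2
                                      + (Pp[kp, 1] - centers[A, 1]) ** 2
                                      + (Pp[kp, 2] - centers[A, 2]) ** 2)
                        pbx = np.sqrt((Pp[kp, 0] - centers[B, 0]) ** 2
                                      + (Pp[kp, 1] - centers[B, 1]) ** 2
                                      + (Pp[kp, 2] - centers[B, 2]) ** 2)
                        poly = (1.0 + pax + dpa) ** la * (1.0 + pbx + dpa) ** lb
                        bg = abs(ccp[kp]) * smax * smax * Nj * decay \
                            * mstar ** 3 * poly
                        bf = bg * 2.0 * om * 3.0 * (1.0 + dpa) * max(1.0, mstar)
                        bnd += bg if bg > bf else bf
                    if bnd < thresh:
                        continue

                # accumulate g and f components for the block
                for kp in range(np_pair):
                    sp = spp[kp]
                    a = ap[kp]
                    q = sp + om
                    rq = 1.0 / np.sqrt(q)
                    dd = 0.0
                    for d in range(3):
                        dl = Pp[kp, d] - tc[j, d]
                        dd += dl * dl
                    pref = ccp[kp] * Nj * np.exp(-sp * om / q * dd) * rq * rq * rq
                    if mode == 1 and abs(pref) < 1e-300:
                        continue
                    # per-direction GH sums I[i, jj, k]
                    for d in range(3):
                        Qd = (sp * Pp[kp, d] + om * tc[j, d]) / q
                        for t in range(ngh):
                            x = Qd + gh_x[go + t] * rq
                            va = 1.0
                            xa = x - centers[A, d]
                            for i in range(la + 1):
                                pa_pow[i, t] = va
                                va *= xa
                            vb = 1.0
                            xb = x - centers[B, d]
                            for i in range(lb + 1):
                                pb_pow[i, t] = vb
                                vb *= xb
                            pc_pow[0, t] = 1.0
                            pc_pow[1, t] = x - tc[j, d]
                        for i in range(la + 1):
                            for jj in range(lb + 1):
                                s0 = 0.0
                                s1 = 0.0
                                for t in range(ngh):
                                    w = gh_w[go + t] * pa_pow[i, t] * pb_pow[jj, t]
                                    s0 += w
                                    s1 += w * pc_pow[1, t]
                                if d == 0:
                                    Ix[i, jj, 0] = s0; Ix[i, jj, 1] = s1
                                elif d == 1:
                                    Iy[i, jj, 0] = s0; Iy[i, jj, 1] = s1
                                else:
                                    Iz[i, jj, 0] = s0; Iz[i, jj, 1] = s1
                    nx = tnormal[j, 0]; ny = tnormal[j, 1]; nz = tnormal[j, 2]
                    for ia in range(nca):
                        ixp = comp_lx[comp_off[la] + ia]
                        iyp = comp_ly[comp_off[la] + ia]
                        izp = comp_lz[comp_off[la] + ia]
                        sa = comp_scale[comp_off[la] + ia]
                        mu = offsets[A] + ia
                        for ib in range(ncb):
                            jxp = comp_lx[comp_off[lb] + ib]
                            jyp = comp_ly[comp_off[lb] + ib]
                            jzp = comp_lz[comp_off[lb] + ib]
                            sb = comp_scale[comp_off[lb] + ib]
                            nu = offsets[B] + ib
                            w = pref * sa * sb
                            gx = Ix[ixp, jxp, 0]
                            gy = Iy[iyp, jyp, 0]
                            gz = Iz[izp, jzp, 0]
                            gval = w * gx * gy * gz
                            fval = 2.0 * om * w * (
                                nx * Ix[ixp, jxp, 1] * gy * gz
                                + ny * gx * Iy[iyp, jyp, 1] * gz
                                + nz * gx * gy * Iz[izp, jzp, 1])
                            if mode == 0:
                                dmn = D[mu, nu]
                                gt[j] += sym * dmn * gval
                                ft[j] += sym * dmn * fval
                            else:
                                # A == B blocks are traversed in full, so only
                                # mirror across distinct shell pairs
                                v = w1[j] * gval + w2[j] * fval
                                F[mu, nu] += v
                                if A != B:
                                    F[nu, mu] += v
    return 0


@njit(cache=False)
def _gamma_half(n: int) -> float:
    """Gamma((n+1)/2) for small integer n."""
    # Gamma(1/2)=sqrt(pi), Gamma(1)=1, recursion Gamma(x+1)=x Gamma(x)
    if n % 2 == 0:
        v = np.sqrt(np.pi)
        x = 0.5
    else:
        v = 1.0
        x = 1.0
    while x < (n + 1) / 2.0 - 1e-9:
        v *= x
        x += 1.0
    return v


def _flat(basis):
    c, ls, at, off, pidx, ex, co = basis.flat_arrays()
    return c, ls, off, pidx, ex, co


def sweep_aux_vectors(basis, cavity, D: np.ndarray,
                      threshold: float = 1e-12,
                      batch_size: int = 2048,
                      accounting: dict | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Auxiliary vectors g~_j = sum_{mu nu} D g_{mu nu j} and f~ likewise.

    Integral-direct: tesserae are processed in batches, integrals recomputed
    on the fly, nothing of size N_basis^2 x N_tess stored.
    """
    from .hf import COMP_OFF, COMP_LX, COMP_LY, COMP_LZ, COMP_SCALE
    centers, ls, off, pidx, ex, co = _flat(basis)
    nt = cavity.n_tesserae
    gt = np.zeros(nt)
    ft = np.zeros(nt)
    dummy = np.zeros(1)
    Fdummy = np.zeros((1, 1))
    for start in range(0, nt, batch_size):
        sl = slice(start, min(start + batch_size, nt))
        if accounting is not None:
            nbatch = sl.stop - sl.start
            accounting["peak_batch_bytes"] = max(
                accounting.get("peak_batch_bytes", 0), 8 * 6 * nbatch)
        _sweep_kernel(centers, ls, off, pidx, ex, co,
                      COMP_OFF, COMP_LX, COMP_LY, COMP_LZ, COMP_SCALE,
                      GH_X, GH_W, GH_OFF,
                      cavity.centers[sl], cavity.omegas[sl],
                      cavity.norms[sl], cavity.normals[sl],
                      0, D, dummy, dummy, threshold,
                      gt[sl], ft[sl], Fdummy)
    return gt, ft


def sweep_fock(basis, cavity, w1: np.ndarray, w2: np.ndarray,
               threshold: float = 1e-12, batch_size: int = 2048) -> np.ndarray:
    """Fock-type accumulation F_{mu nu} = sum_j (w1_j g + w2_j f)_{mu nu j}."""
    from .hf import COMP_OFF, COMP_LX, COMP_LY, COMP_LZ, COMP_SCALE
    centers, ls, off, pidx, ex, co = _flat(basis)
    n = basis.n_ao
    F = np.zeros((n, n))
    dummy = np.zeros(1)
    Ddummy = np.zeros((1, 1))
    _sweep_kernel(centers, ls, off, pidx, ex, co,
                  COMP_OFF, COMP_LX, COMP_LY, COMP_LZ, COMP_SCALE,
                  GH_X, GH_W, GH_OFF,
                  cavity.centers, cavity.omegas,
                  cavity.norms, cavity.normals,
                  1, Ddummy, w1, w2, threshold,
                  dummy, dummy, F)
    return F
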