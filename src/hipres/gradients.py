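"""Analytic nuclear gradients of the pressure energy and geometry optimization.

At SCF convergence the pressure energy is E_G = sum_j p_j g~_j with
p_j = -p_inp a_j / f~_j, so its explicit geometry derivative (density
response is carried by the host engine's energy-weighted density) is

    dE_G = sum_j p_j [ (g~_j/a_j) da_j  +  dg~_j  -  (g~_j/f~_j) df~_j ].

The auxiliary-vector derivatives split into constant-exponent integral
derivatives (bra-center differentiation only; ket- and tessera-center parts
follow from translational invariance) and an exponent-variation part routed
through the edge-halving condition, d omega_j / d a_j = -omega_j / a_j,
using the exponent-derivative integrals contracted into two additional
per-tessera vectors (dg/domega and df/domega analogues of g~ and f~).
Cavity geometry enters through the tessera-area derivative table and the
rigid attachment of tessera centers to their parent atoms.

Normalization-constant derivatives are never formed: E_G depends on the
ratio g~_j/f~_j and the product a_j g~_j / f~_j, from which N_j cancels
exactly, so holding N_j fixed in all derivative integrals is not an
approximation at the level of the total gradient (the test suite verifies
this against finite differences rather than trusting it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cavity import Cavity, cavity_derivatives
from .geometry import Molecule
from .pressure import PressureSCFRecord, run_scf
from .tessint import TesseraBatch, pair_blocks
from .units import ANGSTROM_PER_BOHR

__all__ = ["GradientBlock", "AuxDerivativeVectors", "exponent_aux_vectors",
           "aux_vector_gradients", "amplitude_gradients", "total_gradient",
           "molecular_gradient", "optimize_geometry", "OptimizationResult"]


@dataclass
class GradientBlock:
    """Pressure-term contribution to the nuclear gradient (hartree/bohr)."""

    total: np.ndarray                 # (natom, 3)
    integral_part: np.ndarray         # constant-exponent integral derivatives
    exponent_area_part: np.ndarray    # d omega/d a routed exponent terms
    amplitude_part: np.ndarray        # g~_j dp_j/dR terms

    def check_decomposition(self) -> float:
        return float(np.abs(self.total - self.integral_part
                            - self.exponent_area_part
                            - self.amplitude_part).max())


@dataclass
class AuxDerivativeVectors:
    """Precomputable exponent-derivative contractions, per tessera."""

    dg_domega: np.ndarray    # sum_{mu nu} D (d g_{mu nu j} / d omega_j)
    df_domega: np.ndarray


def _require_darea(cavity: Cavity, mol: Molecule) -> np.ndarray:
    if cavity.darea is None:
        cavity_derivatives(cavity, mol)
    return cavity.darea


def exponent_aux_vectors(D: np.ndarray, basis, cavity: Cavity) -> AuxDerivativeVectors:
    """Contract the exponent-derivative integrals with the density."""
    tb = TesseraBatch.from_cavity(cavity)
    nt = cavity.n_tesserae
    g1 = np.zeros(nt)
    f1 = np.zeros(nt)
    shells = basis.shells
    for i, sa in enumerate(shells):
        for sb in shells[:i + 1]:
            sym = 1.0 if sa is sb else 2.0
            blk = pair_blocks(sa, sb, tb, want=("dgdw", "dfdw"))
            Db = D[sa.ao_offset:sa.ao_offset + sa.n_func,
                   sb.ao_offset:sb.ao_offset + sb.n_func]
            g1 += sym * np.einsum("abt,ab->t", blk["dgdw"], Db)
            f1 += sym * np.einsum("abt,ab->t", blk["dfdw"], Db)
    return AuxDerivativeVectors(g1, f1)


def _pairwise_center_contractions(D: np.ndarray, basis, cavity: Cavity,
                                  include_tessera_motion: bool = True):
    """Per-tessera, per-atom constant-exponent derivative contractions.

    Returns (dg_c, df_c) of shape (natom, 3, nt): the contribution of the
    bra/ket/tessera-center movement to dg~_j/dR and df~_j/dR at constant
    exponents, assembled with translational invariance (the tessera-center
    derivative is minus the sum of bra and ket derivatives).  With
    `include_tessera_motion=False` only the basis-function movement is kept
    (frozen-cavity picture).
    """
    tb = TesseraBatch.from_cavity(cavity)
    nt = cavity.n_tesserae
    natom = len(cavity.radii)
    dg_c = np.zeros((natom, 3, nt))
    df_c = np.zeros((natom, 3, nt))
    shells = basis.shells
    parents = cavity.parents
    for i, sa in enumerate(shells):
        for sb in shells[:i + 1]:
            sym = 1.0 if sa is sb else 2.0
            Db = D[sa.ao_offset:sa.ao_offset + sa.n_func,
                   sb.ao_offset:sb.ao_offset + sb.n_func]
            ba = pair_blocks(sa, sb, tb, want=("dgdA", "dfdA"))
            vAg = sym * np.einsum("dabt,ab->dt", ba["dgdA"], Db)
            vAf = sym * np.einsum("dabt,ab->dt", ba["dfdA"], Db)
            bb = pair_blocks(sb, sa, tb, want=("dgdA", "dfdA"))
            vBg = sym * np.einsum("dbat,ab->dt", bb["dgdA"], Db)
            vBf = sym * np.einsum("dbat,ab->dt", bb["dfdA"], Db)
            dg_c[sa.atom] += vAg
            df_c[sa.atom] += vAf
            dg_c[sb.atom] += vBg
            df_c[sb.atom] += vBf
            # tessera-center part: - (bra + ket), attributed to parent atoms
            if include_tessera_motion:
                tidx = np.arange(nt)
                for d in range(3):
                    np.subtract.at(dg_c, (parents, d, tidx), (vAg + vBg)[d])
                    np.subtract.at(df_c, (parents, d, tidx), (vAf + vBf)[d])
    return dg_c, df_c


def aux_vector_gradients(D: np.ndarray, basis, cavity: Cavity,
                         mol: Molecule,
                         frozen_cavity: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Full derivatives dg~_j/dR_I,alpha and df~_j/dR_I,alpha.

    Shapes (natom, 3, nt).  Density-matrix derivatives are excluded (they
    belong to the host's energy-weighted density term).  With
    `frozen_cavity=True` all cavity-geometry variation (tessera positions,
    areas, exponents, normalizations) is dropped and only the movement of
    the basis functions remains — the picture probed by finite differences
    at a fixed cavity.
    """
    from .tessint import sweep_aux_vectors

    if frozen_cavity:
        return _pairwise_center_contractions(D, basis, cavity,
                                             include_tessera_motion=False)
    darea = _require_darea(cavity, mol)          # (nt, natom, 3)
    aux1 = exponent_aux_vectors(D, basis, cavity)
    dg_c, df_c = _pairwise_center_contractions(D, basis, cavity)
    domega_da = -cavity.omegas / cavity.areas    # (nt,)
    # exponent part: (d aux / d omega at fixed N) * (d omega/d a) * (d a / dR)
    dg = dg_c + np.einsum("t,tIa->Iat", aux1.dg_domega * domega_da, darea)
    df = df_c + np.einsum("t,tIa->Iat", aux1.df_domega * domega_da, darea)
    # normalization variation: both vectors are proportional to N_j, and
    # dN/da = (3/2)(N/omega)(d omega/d a) = -(3/2) N / a.  This term cancels
    # exactly in the total energy gradient but belongs in the true vector
    # derivatives.
    gt, ft = sweep_aux_vectors(basis, cavity, D, threshold=0.0)
    dg += np.einsum("t,tIa->Iat", -1.5 * gt / cavity.areas, darea)
    df += np.einsum("t,tIa->Iat", -1.5 * ft / cavity.areas, darea)
    return dg, df


def amplitude_gradients(record: PressureSCFRecord) -> np.ndarray:
    """dp_j/dR_I,alpha at convergence, shape (natom, 3, nt).

    Chain rule through the tessera area and f~:
    dp_j = p_j [ da_j/a_j - df~_j/f~_j ].
    """
    st = record.coupling.state
    cavity = record.cavity
    darea = _require_darea(cavity, record.mol)
    _, df = aux_vector_gradients(record.scf.density, record.engine.basis,
                                 cavity, record.mol)
    p = st.amplitudes
    nz = p != 0.0
    out = np.zeros_like(df)
    ratio_a = np.where(nz, p / cavity.areas, 0.0)
    ratio_f = np.where(nz, p / np.where(nz, st.f_aux, 1.0), 0.0)
    out += np.einsum("t,tIa->Iat", ratio_a, darea)
    out -= ratio_f[None, None, :] * df
    return out


def total_gradient(record: PressureSCFRecord) -> GradientBlock:
    """Pressure-term contribution to the nuclear gradient at convergence."""
    if not record.converged:
        raise RuntimeError("SCF is not converged; gradients are defined only "
                           "at a converged state")
    mol = record.mol
    natom = mol.n_atoms
    if record.pressure_gpa == 0.0:
        z = np.zeros((natom, 3))
        return GradientBlock(z, z.copy(), z.copy(), z.copy())
    st = record.coupling.state
    cavity = record.cavity
    basis = record.engine.basis
    D = record.scf.density
    darea = _require_darea(cavity, mol)

    p = st.amplitudes
    nz = p != 0.0
    gf_ratio = np.where(nz, st.g_aux / np.where(nz, st.f_aux, 1.0), 0.0)
    wg = p                      # weight of dg~_j
    wf = -p * gf_ratio          # weight of df~_j

    aux1 = exponent_aux_vectors(D, basis, cavity)
    dg_c, df_c = _pairwise_center_contractions(D, basis, cavity)
    domega_da = -cavity.omegas / cavity.areas

    integral_part = np.einsum("t,Iat->Ia", wg, dg_c)
    # split df~ between the amplitude chain-rule term (wf) and its own parts
    amp_const = np.einsum("t,Iat->Ia", wf, df_c)
    expo_g = np.einsum("t,tIa->Ia", wg * aux1.dg_domega * domega_da, darea)
    expo_f = np.einsum("t,tIa->Ia", wf * aux1.df_domega * domega_da, darea)
    area_amp = np.einsum("t,tIa->Ia", np.where(nz, p * st.g_aux / cavity.areas, 0.0),
                         darea)

    amplitude_part = amp_const + expo_f + area_amp
    exponent_area_part = expo_g
    total = integral_part + exponent_area_part + amplitude_part
    return GradientBlock(total, integral_part, exponent_area_part,
                         amplitude_part)


def molecular_gradient(record: PressureSCFRecord) -> np.ndarray:
    """Total nuclear gradient: host HF gradient + pressure block (hartree/bohr)."""
    g_host = record.engine.gradient_hf(record.scf)
    return g_host + total_gradient(record).total


# ---------------------------------------------------------------------------
# Geometry optimization
# ---------------------------------------------------------------------------

@dataclass
class OptimizationResult:
    mol: Molecule
    energy: float
    trajectory: list          # per-step dicts: energy, dE, grad_norm, coords
    converged: bool
    record: PressureSCFRecord


def optimize_geometry(mol: Molecule, pressure_gpa: float = 0.0,
                      basis: str = "sto-3g",
                      conv_energy: float = 1e-6,
                      conv_grad: float = 1e-3,       # hartree/Å, max component
                      max_steps: int = 200,
                      **scf_kwargs) -> OptimizationResult:
    """Quasi-Newton (BFGS) optimization driven by energy+gradient callbacks.

    Convergence: energy change <= `conv_energy` hartree and gradient max
    component <= `conv_grad` hartree/Å.  The cavity is rebuilt at every
    geometry; tesserae may appear or vanish between steps, which can leave
    tiny discontinuities that BFGS tolerates.
    """
    from scipy.optimize import minimize

    cache: dict[bytes, tuple[float, np.ndarray, PressureSCFRecord]] = {}
    last_density = {"d0": None}
    trajectory: list[dict] = []

    def evaluate(x: np.ndarray):
        key = x.tobytes()
        if key not in cache:
            m = mol.with_coords(x.reshape(-1, 3))
            rec = run_scf(m, pressure_gpa, basis=basis,
                          d0=last_density["d0"], **scf_kwargs)
            if not rec.converged:  # retry from scratch
                rec = run_scf(m, pressure_gpa, basis=basis, **scf_kwargs)
            last_density["d0"] = rec.scf.density
            g = molecular_gradient(rec)
            cache[key] = (rec.energy, g.ravel(), rec)
            if len(cache) > 8:
                cache.pop(next(iter(cache)))
        return cache[key]

    def fun(x):
        return evaluate(x)[0]

    def jac(x):
        return evaluate(x)[1]

    state = {"prev_e": None, "converged": False}

    def callback(x):
        e, g, _ = evaluate(x)
        gmax_per_ang = np.abs(g).max() / ANGSTROM_PER_BOHR
        de = None if state["prev_e"] is None else e - state["prev_e"]
        trajectory.append({"step": len(trajectory) + 1, "energy": e,
                           "dE": de, "grad_max": gmax_per_ang,
                           "coords": x.reshape(-1, 3).copy()})
        if de is not None and abs(de) <= conv_energy and gmax_per_ang <= conv_grad:
            state["converged"] = True
            raise StopIteration
        state["prev_e"] = e

    x0 = mol.coords.ravel().copy()
    try:
        res = minimize(fun, x0, jac=jac, method="BFGS", callback=callback,
                       options={"gtol": conv_grad * ANGSTROM_PER_BOHR,
                                "maxiter": max_steps})
        xfin = res.x
        converged = state["converged"] or bool(res.success)
    except StopIteration:
        xfin = trajectory[-1]["coords"].ravel()
        converged = True
    e, g, rec = evaluate(xfin)
    return OptimizationResult(mol.with_coords(xfin.reshape(-1, 3)), e,
                              trajectory, converged, rec)
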