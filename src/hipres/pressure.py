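"""Self-consistent coupling of the surface-Gaussian pressure model to the SCF.

The repulsive potential sum_j p_j G_j(r) compresses the electron density.
Per SCF iteration, two integral-direct passes are made:

pass 1  auxiliary vectors from the current density D,
            g~_j = sum_{mu nu} D_{mu nu} <mu|G_j|nu>
            f~_j = sum_{mu nu} D_{mu nu} n_j . grad_{r_j} <mu|G_j|nu>,
        then amplitudes from the semiclassical force balance -- the force the
        tessera potential exerts on the density through tessera j equals the
        external pressure times the tessera area:
            p_j = - p_inp a_j / f~_j,
        the energy E_G = sum_j p_j g~_j and the effective volume
        V_eff = E_G / p_inp;

pass 2  the Fock contribution F = dE_G/dD (amplitude response included),
            F_{mu nu} = sum_j p_j [ g_{mu nu j} - (g~_j/f~_j) f_{mu nu j} ].

For a well-formed cavity f~_j < 0 (the density decays outward along the
normal), making every amplitude positive.  Negative amplitudes are kept,
counted and reported: they diagnose ill-defined cavity regions (crevices).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cavity import Cavity, build_cavity
from .geometry import Molecule
from .hf import RHF, SCFResult
from .tessint import sweep_aux_vectors, sweep_fock
from .units import AU_PRESSURE_PER_GPA, BOHR_PER_ANGSTROM

logger = logging.getLogger("hipres")

AMPLITUDE_FLOOR = 1e-12        # |f~_j| below this: amplitude regularized to 0
DEFAULT_SCREEN_THRESH = 1e-12
DEFAULT_BATCH_SIZE = 2048


@dataclass
class PressureState:
    """Per-iteration state of the pressure coupling."""

    p_inp_gpa: float
    p_inp_au: float               # hartree/bohr^3
    g_aux: np.ndarray             # g~_j
    f_aux: np.ndarray             # f~_j
    amplitudes: np.ndarray        # p_j
    energy: float                 # E_G, hartree
    n_regularized: int

    @property
    def n_negative(self) -> int:
        return int(np.sum(self.amplitudes < 0.0))

    @property
    def effective_volume(self) -> float:
        return effective_volume(self.energy, self.p_inp_au)


def compute_aux_vectors(D: np.ndarray, basis, cavity: Cavity,
                        screen_thresh: float = DEFAULT_SCREEN_THRESH,
                        batch_size: int = DEFAULT_BATCH_SIZE,
                        accounting: dict | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Density-contracted auxiliary vectors (g~, f~), integral-direct."""
    if D.shape != (basis.n_ao, basis.n_ao):
        raise ValueError(f"density shape {D.shape} does not match basis "
                         f"dimension {basis.n_ao}")
    return sweep_aux_vectors(basis, cavity, D, threshold=screen_thresh,
                             batch_size=batch_size, accounting=accounting)


def compute_amplitudes(p_inp_au: float, areas: np.ndarray,
                       f_aux: np.ndarray) -> tuple[np.ndarray, int]:
    """Amplitudes p_j = -p_inp a_j / f~_j, with near-singular f~ regularized.

    Returns (amplitudes, number of regularized entries).  Negative amplitudes
    are returned unmodified (cavity-quality diagnostic).
    """
    p = np.zeros_like(areas)
    if p_inp_au == 0.0:
        return p, 0
    ok = np.abs(f_aux) >= AMPLITUDE_FLOOR
    n_reg = int(len(p) - ok.sum())
    if n_reg:
        logger.warning("%d tesserae with |f~| below %.1e regularized to p_j = 0",
                       n_reg, AMPLITUDE_FLOOR)
    p[ok] = -p_inp_au * areas[ok] / f_aux[ok]
    return p, n_reg


def gostshyp_energy(amplitudes: np.ndarray, g_aux: np.ndarray) -> float:
    """E_G = sum_j p_j g~_j (hartree)."""
    return float(np.dot(amplitudes, g_aux))


def effective_volume(e_gost: float, p_inp_au: float) -> float:
    """V_eff = E_G / p_inp (bohr^3); undefined at zero pressure."""
    if p_inp_au == 0.0:
        raise ZeroDivisionError("effective volume is undefined at zero pressure")
    return e_gost / p_inp_au


def fock_contribution(state: PressureState, basis, cavity: Cavity,
                      D: np.ndarray,
                      screen_thresh: float = DEFAULT_SCREEN_THRESH) -> np.ndarray:
    """F = dE_G/dD assembled in a second integral pass.

    Raises if the auxiliary vectors in `state` are stale for `D`.
    """
    # cheap staleness check against a fingerprint of D
    if state._density_tag is not None and state._density_tag != _density_tag(D):
        raise ValueError("auxiliary vectors are stale for this density; "
                         "recompute them before the Fock pass")
    p = state.amplitudes
    w1 = p.copy()
    w2 = np.zeros_like(p)
    nz = p != 0.0
    w2[nz] = -p[nz] * state.g_aux[nz] / state.f_aux[nz]
    return sweep_fock(basis, cavity, w1, w2, threshold=screen_thresh)


def _density_tag(D: np.ndarray) -> tuple:
    return (float(D.trace()), float(np.abs(D).sum()), float(D[0, 0]))


# staleness tag lives on the state object
PressureState._density_tag = None


class PressureCoupling:
    """Callable extra-Fock hook: D -> (E_G(D), dE_G/dD(D)).

    Holds the cavity fixed during the SCF (vdW / vdW-OCC cavities are
    geometry-only constructions) and records the last PressureState.
    """

    def __init__(self, basis, cavity: Cavity, pressure_gpa: float,
                 screen_thresh: float = DEFAULT_SCREEN_THRESH,
                 batch_size: int = DEFAULT_BATCH_SIZE):
        self.basis = basis
        self.cavity = cavity
        self.pressure_gpa = float(pressure_gpa)
        self.p_au = float(pressure_gpa) * AU_PRESSURE_PER_GPA
        self.screen_thresh = screen_thresh
        self.batch_size = batch_size
        self.state: PressureState | None = None
        self.accounting: dict = {}

    def __call__(self, D: np.ndarray) -> tuple[float, np.ndarray]:
        n = self.basis.n_ao
        if self.p_au == 0.0:
            self.state = PressureState(self.pressure_gpa, 0.0,
                                       np.zeros(self.cavity.n_tesserae),
                                       np.zeros(self.cavity.n_tesserae),
                                       np.zeros(self.cavity.n_tesserae),
                                       0.0, 0)
            self.state._density_tag = _density_tag(D)
            return 0.0, np.zeros((n, n))
        gt, ft = compute_aux_vectors(D, self.basis, self.cavity,
                                     self.screen_thresh, self.batch_size,
                                     accounting=self.accounting)
        p, n_reg = compute_amplitudes(self.p_au, self.cavity.areas, ft)
        e_g = gostshyp_energy(p, gt)
        st = PressureState(self.pressure_gpa, self.p_au, gt, ft, p, e_g, n_reg)
        st._density_tag = _density_tag(D)
        self.state = st
        F = fock_contribution(st, self.basis, self.cavity, D,
                              self.screen_thresh)
        return e_g, F


@dataclass
class PressureSCFRecord:
    """Result of one pressure-coupled SCF run."""

    mol: Molecule
    pressure_gpa: float
    energy: float                 # total energy, hartree
    e_gost: float                 # pressure-term energy, hartree
    v_eff: float | None           # bohr^3, None at zero pressure
    amplitudes: np.ndarray
    n_negative: int
    n_regularized: int
    n_iter: int
    converged: bool
    n_tesserae: int
    scf: SCFResult = field(repr=False, default=None)
    coupling: PressureCoupling = field(repr=False, default=None)
    cavity: Cavity = field(repr=False, default=None)
    engine: RHF = field(repr=False, default=None)


def run_scf(mol: Molecule, pressure_gpa: float = 0.0, basis: str = "sto-3g",
            method: str = "hf",
            cavity_type: str = "vdw", r_ext: float = 0.25,
            grid_points: int | None = None,
            radii: dict[str, float] | None = None,
            conv_tol: float = 1e-7, max_iter: int = 200,
            screen_thresh: float = DEFAULT_SCREEN_THRESH,
            batch_size: int = DEFAULT_BATCH_SIZE,
            engine: RHF | None = None, cavity: Cavity | None = None,
            d0: np.ndarray | None = None,
            log: bool = False) -> PressureSCFRecord:
    """Pressure-coupled SCF: cavity built once, then two integral passes per
    iteration.

    Parameters in user units: `r_ext` in Å, `radii` element->Å,
    `pressure_gpa` in GPa.  `engine`/`cavity` may be passed to reuse
    integrals across runs on the same geometry.
    """
    if method.lower() != "hf":
        raise ValueError("only method='hf' is supported by the built-in SCF "
                         "engine")
    if cavity_type not in ("vdw", "vdw_occ"):
        raise ValueError(
            f"cavity type {cavity_type!r} is not supported; smooth analytic "
            "derivatives exist only for 'vdw' and 'vdw_occ' cavities here "
            "(solvent-excluded, isodensity and pseudo-isodensity surfaces "
            "are out of scope)")
    if engine is None:
        engine = RHF(mol, basis=basis)
    if cavity is None:
        r_ext_bohr = r_ext * BOHR_PER_ANGSTROM if cavity_type == "vdw_occ" else 0.0
        kw = {} if grid_points is None else {"grid_points": grid_points}
        cavity = build_cavity(mol.real_subset() if mol.ghost.any() else mol,
                              radii=radii, r_ext=r_ext_bohr, **kw)

    coupling = PressureCoupling(engine.basis, cavity, pressure_gpa,
                                screen_thresh, batch_size)
    logfun = (lambda s: logger.info("%s", s)) if log else None

    def log_iteration(msg: str) -> None:
        if coupling.state is not None:
            msg += f"  n_p<0 = {coupling.state.n_negative}"
        if logfun:
            logfun(msg)

    res = engine.scf(extra_fock=coupling, conv_tol=conv_tol, max_iter=max_iter,
                     d0=d0, log=log_iteration if log else None)
    st = coupling.state
    if not res.converged:
        amp_hist = "n/a"
        logger.warning("SCF did not converge in %d cycles at %.3g GPa "
                       "(last |p_j<0| count: %s)", max_iter, pressure_gpa,
                       st.n_negative if st else amp_hist)
    v_eff = st.effective_volume if pressure_gpa != 0.0 else None
    return PressureSCFRecord(
        mol=mol, pressure_gpa=pressure_gpa, energy=res.energy,
        e_gost=st.energy if st else 0.0, v_eff=v_eff,
        amplitudes=st.amplitudes if st is not None else np.zeros(0),
        n_negative=st.n_negative if st else 0,
        n_regularized=st.n_regularized if st else 0,
        n_iter=res.n_iter, converged=res.converged,
        n_tesserae=cavity.n_tesserae, scf=res, coupling=coupling,
        cavity=cavity, engine=engine)
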