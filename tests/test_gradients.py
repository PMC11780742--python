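"""Analytic nuclear gradients of the pressure energy and geometry optimization."""

import numpy as np
import pytest

from hipres import (RHF, build_cavity, molecular_gradient, optimize_geometry,
                    run_scf, total_gradient)
from hipres.gradients import amplitude_gradients, aux_vector_gradients
from hipres.pressure import compute_amplitudes
from hipres.tessint import sweep_aux_vectors
from hipres.units import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM


def test_zero_pressure_gradient_block_is_zero(h2o, engines):
    rec = run_scf(h2o.mol, 0.0, engine=engines(h2o), conv_tol=1e-10)
    blk = total_gradient(rec)
    assert np.all(blk.total == 0)
    assert np.all(amplitude_gradients(rec) == 0)


def test_gradient_block_invariants(h2o_occ_10gpa):
    blk = total_gradient(h2o_occ_10gpa)
    # component decomposition sums to the total exactly
    assert blk.check_decomposition() < 1e-15
    # translational invariance of the block
    assert np.abs(blk.total.sum(axis=0)).max() < 1e-10


def test_gradient_vanishes_linearly_at_small_pressure(h2o, engines):
    """The pressure-gradient block scales linearly with p_inp as p -> 0."""
    eng = engines(h2o)
    rec1 = run_scf(h2o.mol, 0.2, engine=eng, cavity_type="vdw_occ",
                   conv_tol=1e-11)
    rec2 = run_scf(h2o.mol, 0.1, engine=eng, cavity_type="vdw_occ",
                   conv_tol=1e-11)
    g1 = total_gradient(rec1).total
    g2 = total_gradient(rec2).total
    assert np.abs(g1).max() < 1e-3
    assert np.allclose(g1, 2.0 * g2, rtol=2e-3, atol=1e-9)


def test_nonconverged_state_rejected(h2o, engines):
    rec = run_scf(h2o.mol, 10.0, engine=engines(h2o), conv_tol=1e-7,
                  max_iter=2)
    assert not rec.converged
    with pytest.raises(RuntimeError, match="not converged"):
        total_gradient(rec)


def test_aux_gradients_frozen_cavity(h2o, engines, h2o_occ_10gpa):
    """With the cavity frozen the aux-vector gradients reduce to the
    basis-motion part, matching finite differences at a fixed cavity."""
    eng = engines(h2o)
    rec = h2o_occ_10gpa
    cav = rec.cavity
    D = rec.scf.density
    dg, df = aux_vector_gradients(D, eng.basis, cav, h2o.mol,
                                  frozen_cavity=True)
    step = 1e-5
    for I in range(3):
        for x in range(3):
            gs, fs = [], []
            for s in (+1, -1):
                c = h2o.mol.coords.copy()
                c[I, x] += s * step
                disp = RHF(h2o.mol.with_coords(c))
                gt, ft = sweep_aux_vectors(disp.basis, cav, D, threshold=0.0)
                gs.append(gt)
                fs.append(ft)
            assert np.abs((gs[0] - gs[1]) / (2 * step) - dg[I, x]).max() < 1e-6
            assert np.abs((fs[0] - fs[1]) / (2 * step) - df[I, x]).max() < 1e-6


def test_aux_and_amplitude_gradients_full_finite_difference(h2, engines):
    """H2 at 20 GPa: aux-vector and amplitude gradients match finite
    differences with the cavity rebuilt at each displaced geometry."""
    eng = engines(h2)
    rec = run_scf(h2.mol, 20.0, engine=eng, cavity_type="vdw_occ",
                  conv_tol=1e-11)
    D = rec.scf.density
    dg, df = aux_vector_gradients(D, eng.basis, rec.cavity, h2.mol)
    dp = amplitude_gradients(rec)
    step = 1e-5
    for I in range(2):
        for x in range(3):
            gs, fs, ps = [], [], []
            for s in (+1, -1):
                c = h2.mol.coords.copy()
                c[I, x] += s * step
                m = h2.mol.with_coords(c)
                cv = build_cavity(m, r_ext=0.25 * BOHR_PER_ANGSTROM,
                                  with_derivatives=False)
                assert cv.n_tesserae == rec.cavity.n_tesserae
                disp = RHF(m)
                gt, ft = sweep_aux_vectors(disp.basis, cv, D, threshold=0.0)
                gs.append(gt)
                fs.append(ft)
                pj, _ = compute_amplitudes(rec.coupling.p_au, cv.areas, ft)
                ps.append(pj)
            assert np.abs((gs[0] - gs[1]) / (2 * step) - dg[I, x]).max() < 1e-5
            assert np.abs((fs[0] - fs[1]) / (2 * step) - df[I, x]).max() < 1e-5
            fd_p = (ps[0] - ps[1]) / (2 * step)
            scale = np.maximum(np.abs(fd_p), 1e-3 * np.abs(fd_p).max())
            assert (np.abs(fd_p - dp[I, x]) / scale).max() < 1e-6


def test_isolated_atom_amplitude_gradient_reduces_to_f_term(engines):
    """A lone atom's areas are translation invariant, so dp comes only from
    the f~ derivative."""
    from hipres import from_angstrom
    ne = from_angstrom(["Ne"], [[0, 0, 0]])
    rec = run_scf(ne, 10.0, conv_tol=1e-11)
    assert np.abs(rec.cavity.darea).max() == 0.0
    dp = amplitude_gradients(rec)
    _, df = aux_vector_gradients(rec.scf.density, rec.engine.basis,
                                 rec.cavity, ne)
    p, f = rec.amplitudes, rec.coupling.state.f_aux
    expected = -(p / f)[None, None, :] * df
    assert np.allclose(dp, expected, atol=1e-15)


def test_total_gradient_matches_finite_difference_h2(h2, engines):
    eng = engines(h2)
    rec = run_scf(h2.mol, 20.0, engine=eng, cavity_type="vdw_occ",
                  conv_tol=1e-12)
    g = molecular_gradient(rec)
    step = 1e-3
    for I in range(2):
        for x in range(3):
            e = []
            for s in (+1, -1):
                c = h2.mol.coords.copy()
                c[I, x] += s * step
                rr = run_scf(h2.mol.with_coords(c), 20.0,
                             cavity_type="vdw_occ", conv_tol=1e-12)
                assert rr.converged
                e.append(rr.energy)
            assert g[I, x] == pytest.approx((e[0] - e[1]) / (2 * step),
                                            abs=1e-5)


def test_h2_optimization_compresses_under_pressure(h2):
    bonds = {}
    for p in (0.0, 50.0):
        res = optimize_geometry(h2.mol, p, cavity_type="vdw_occ",
                                conv_tol=1e-10)
        assert res.converged
        bonds[p] = np.linalg.norm(res.mol.coords[1] - res.mol.coords[0]) \
            * ANGSTROM_PER_BOHR
    # gas-phase optimum of this basis is 0.712 Å; pressure shortens the bond
    assert bonds[0.0] == pytest.approx(0.712, abs=2e-3)
    assert bonds[50.0] < bonds[0.0] - 1e-3


def test_h2o_zero_pressure_optimization_hits_gas_phase_optimum(h2o):
    """At 0 GPa the optimizer must land on the plain-SCF equilibrium
    (r_OH about 0.99 Å, angle about 100 degrees in this basis)."""
    res = optimize_geometry(h2o.mol, 0.0, cavity_type="vdw_occ",
                            conv_tol=1e-10)
    assert res.converged
    c = res.mol.coords
    r1 = np.linalg.norm(c[1] - c[0]) * ANGSTROM_PER_BOHR
    r2 = np.linalg.norm(c[2] - c[0]) * ANGSTROM_PER_BOHR
    cosang = np.dot(c[1] - c[0], c[2] - c[0]) / np.linalg.norm(c[1] - c[0]) \
        / np.linalg.norm(c[2] - c[0])
    ang = np.degrees(np.arccos(cosang))
    assert r1 == pytest.approx(0.989, abs=5e-3)
    assert r2 == pytest.approx(0.989, abs=5e-3)
    assert ang == pytest.approx(100.0, abs=1.5)
    # pressure block really was inert
    assert total_gradient(res.record).total.max() == 0.0


def test_ch4_trajectory_monotone_at_5gpa(ch4):
    """Smooth vdW/OCC surface: the optimization energy decreases
    monotonically after the first step."""
    res = optimize_geometry(ch4.mol, 5.0, cavity_type="vdw_occ",
                            conv_tol=1e-10, max_steps=30)
    energies = [s["energy"] for s in res.trajectory]
    assert len(energies) >= 2
    assert all(e2 <= e1 + 1e-8 for e1, e2 in zip(energies[1:], energies[2:]))
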