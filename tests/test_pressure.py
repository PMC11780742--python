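"""Self-consistent pressure coupling: aux vectors, amplitudes, energy, Fock."""

import numpy as np
import pytest

from hipres import (PressureCoupling, build_cavity, compute_amplitudes,
                    compute_aux_vectors, effective_volume, fock_contribution,
                    gostshyp_energy, run_scf)
from hipres.fixtures import quadrature_oracle
from hipres.pressure import PressureState
from hipres.units import AU_PRESSURE_PER_GPA


def test_aux_vectors_zero_density_and_linearity(h2o, engines):
    eng = engines(h2o)
    cav = build_cavity(h2o.mol)
    n = eng.n_ao
    z = np.zeros((n, n))
    gt, ft = compute_aux_vectors(z, eng.basis, cav)
    assert np.all(gt == 0) and np.all(ft == 0)
    D = eng.scf(conv_tol=1e-9).density
    g1, f1 = compute_aux_vectors(D, eng.basis, cav)
    g2, f2 = compute_aux_vectors(2 * D, eng.basis, cav)
    assert np.allclose(g2, 2 * g1, atol=1e-13)
    assert np.allclose(f2, 2 * f1, atol=1e-13)
    # nonnegative density contraction with a nonnegative weight
    assert np.all(g1 >= 0)


def test_aux_vector_against_density_quadrature(h2, engines):
    """g~_j equals the quadrature of rho(r) G_j(r), tessera by tessera.

    The reference decomposes rho G_j into primitive-pair products and
    integrates each numerically — a route fully independent of the
    product-theorem evaluation in the production code.
    """
    eng = engines(h2)
    cav = build_cavity(h2.mol)
    D = eng.scf(conv_tol=1e-10).density
    gt, _ = compute_aux_vectors(D, eng.basis, cav, screen_thresh=0.0)
    shells = eng.basis.shells          # H2/STO-3G: s shells only
    for j in (0, cav.n_tesserae // 2):
        om, C, N = cav.omegas[j], cav.centers[j], cav.norms[j]
        ref = 0.0
        for sa in shells:
            for sb in shells:
                dmn = D[sa.ao_offset, sb.ao_offset]
                for a, ca in zip(sa.exps, sa.coefs):
                    for b, cb in zip(sb.exps, sb.coefs):
                        val = quadrature_oracle(
                            lambda pts, a=a, b=b:
                                np.exp(-a * np.sum((pts - sa.center) ** 2, axis=1))
                                * np.exp(-b * np.sum((pts - sb.center) ** 2, axis=1))
                                * N * np.exp(-om * np.sum((pts - C) ** 2, axis=1)),
                            [(a, sa.center), (b, sb.center), (om, C)])
                        ref += dmn * ca * cb * val
        assert gt[j] == pytest.approx(ref, rel=1e-9)


def test_amplitude_equation():
    areas = np.array([2.0, 3.0, 4.0])
    f_aux = np.array([-0.5, 1e-14, -2.0])
    p_au = 5.0 * AU_PRESSURE_PER_GPA
    p, n_reg = compute_amplitudes(p_au, areas, f_aux)
    # regularization floor zeroes the near-singular entry
    assert n_reg == 1 and p[1] == 0.0
    assert p[0] == pytest.approx(-p_au * 2.0 / -0.5)
    # zero pressure -> zero amplitudes
    p0, _ = compute_amplitudes(0.0, areas, f_aux)
    assert np.all(p0 == 0)
    # homogeneity of degree 1 in the input pressure
    p2, _ = compute_amplitudes(3.0 * p_au, areas, f_aux)
    assert np.allclose(p2, 3.0 * p, atol=1e-18)


def test_energy_and_effective_volume_arithmetic():
    # single tessera with p_1 = 2, g~_1 = 0.5 -> E = 1 hartree
    assert gostshyp_energy(np.array([2.0]), np.array([0.5])) == 1.0
    assert gostshyp_energy(np.zeros(5), np.ones(5)) == 0.0
    assert effective_volume(1.0, 0.5) == 2.0
    with pytest.raises(ZeroDivisionError):
        effective_volume(1.0, 0.0)


def test_zero_pressure_scf_is_exact_gas_phase(h2o, engines):
    eng = engines(h2o)
    gas = eng.scf(conv_tol=1e-12)
    rec = run_scf(h2o.mol, 0.0, engine=eng, conv_tol=1e-12)
    assert abs(rec.energy - gas.energy) <= 1e-10
    assert rec.e_gost == 0.0
    assert np.all(rec.amplitudes == 0)


def test_pressure_raises_energy_and_compresses_veff(h2o, engines):
    eng = engines(h2o)
    prev_e, prev_v = None, None
    for p in (1.0, 5.0, 10.0, 20.0):
        rec = run_scf(h2o.mol, p, engine=eng, cavity_type="vdw_occ",
                      conv_tol=1e-9)
        assert rec.converged and rec.n_negative == 0
        if prev_e is not None:
            assert rec.energy > prev_e
            assert rec.v_eff < prev_v
        prev_e, prev_v = rec.energy, rec.v_eff


def test_fock_contribution_contracts(h2o, engines, h2o_occ_10gpa):
    eng = engines(h2o)
    rec = h2o_occ_10gpa
    F = rec.scf.fock
    assert np.abs(F - F.T).max() < 1e-14
    # stale-density contract violation
    st = rec.coupling.state
    with pytest.raises(ValueError, match="stale"):
        fock_contribution(st, eng.basis, rec.cavity,
                          rec.scf.density + 0.01)
    # dimension mismatch
    with pytest.raises(ValueError, match="density shape"):
        compute_aux_vectors(np.zeros((3, 3)), eng.basis, rec.cavity)


def test_fock_is_density_derivative_of_energy(h2o, engines, rng):
    """tr(F dD) equals the directional derivative of E_G — the central
    self-consistency contract of the coupling."""
    eng = engines(h2o)
    cav = build_cavity(h2o.mol, r_ext=0.25 * 1.8897261246)
    coup = PressureCoupling(eng.basis, cav, 10.0)
    D = eng.scf(conv_tol=1e-10).density
    for _ in range(5):
        dD = rng.normal(size=D.shape)
        dD = (dD + dD.T) / 2
        _, F = coup(D)
        eps = 1e-6
        ep, _ = coup(D + eps * dD)
        em, _ = coup(D - eps * dD)
        fd = (ep - em) / (2 * eps)
        assert np.sum(F * dD) == pytest.approx(fd, rel=1e-7)


def test_zero_pressure_fock_is_zero(h2o, engines):
    eng = engines(h2o)
    cav = build_cavity(h2o.mol)
    coup = PressureCoupling(eng.basis, cav, 0.0)
    D = np.eye(eng.n_ao)
    e, F = coup(D)
    assert e == 0.0 and np.all(F == 0)


def test_restart_from_converged_density(h2o, engines, h2o_occ_10gpa):
    rec = h2o_occ_10gpa
    rec2 = run_scf(h2o.mol, 10.0, engine=engines(h2o), cavity=rec.cavity,
                   cavity_type="vdw_occ", conv_tol=1e-11,
                   d0=rec.scf.density)
    assert rec2.n_iter <= 2
    assert rec2.energy == pytest.approx(rec.energy, abs=1e-9)


def test_screening_threshold_safe_on_energies(h2o, engines):
    eng = engines(h2o)
    e = {}
    for thr in (1e-12, 0.0):
        rec = run_scf(h2o.mol, 10.0, engine=eng, cavity_type="vdw_occ",
                      conv_tol=1e-11, screen_thresh=thr)
        e[thr] = rec.energy
    assert abs(e[1e-12] - e[0.0]) < 1e-9


def test_memory_stays_batch_bounded(h2o, engines):
    """Peak extra working-set memory scales with the tessera batch, never
    with N_basis^2 x N_tess."""
    eng = engines(h2o)
    D = eng.scf(conv_tol=1e-9).density
    peaks = []
    for grid in (26, 110, 194):
        cav = build_cavity(h2o.mol, grid_points=grid, with_derivatives=False)
        acc = {}
        compute_aux_vectors(D, eng.basis, cav, batch_size=512, accounting=acc)
        peaks.append(acc["peak_batch_bytes"])
    # batch-bounded: the working set is capped by the batch size, not by
    # N_basis^2 x N_tess, so it cannot grow once N_tess exceeds one batch
    cap = 8 * 6 * 512
    assert all(p <= cap for p in peaks)
    nts = [build_cavity(h2o.mol, grid_points=g, with_derivatives=False
                        ).n_tesserae for g in (26, 110, 194)]
    assert nts[-1] > nts[0]          # the sweep really did grow
    assert peaks[-1] <= peaks[0] * 2 + cap


def test_unsupported_cavity_and_method(h2o):
    with pytest.raises(ValueError, match="not supported"):
        run_scf(h2o.mol, 1.0, cavity_type="ses")
    with pytest.raises(ValueError, match="method"):
        run_scf(h2o.mol, 1.0, method="b3lyp")


def test_negative_amplitude_count_matches_definition():
    st = PressureState(1.0, 1.0 * AU_PRESSURE_PER_GPA,
                       np.ones(4), -np.ones(4),
                       np.array([0.5, -0.2, 0.0, -1e-30]), 0.3, 0)
    assert st.n_negative == 2
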