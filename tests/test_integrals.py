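"""Three-center basis-pair x surface-Gaussian integrals."""

import numpy as np
import pytest

from hipres.basis import Shell, cart_components, component_scale
from hipres.cavity import build_cavity
from hipres.fixtures import quadrature_oracle
from hipres.tessint import (TesseraBatch, bra_derivative_integrals,
                            exponent_derivative_integrals, f_integrals,
                            g_integrals, pair_blocks, screen_batches,
                            sweep_aux_vectors, sweep_fock)


def _tessera(C, omega, n=None):
    n = np.array([0.0, 0.0, 1.0]) if n is None else np.asarray(n, float)
    n = n / np.linalg.norm(n)
    return TesseraBatch(np.asarray(C, float).reshape(1, 3),
                        np.array([omega]),
                        np.array([(omega / np.pi) ** 1.5]),
                        n.reshape(1, 3),
                        np.array([np.pi * np.log(2) / omega]))


def _random_shell(rng, l, atom=0):
    nprim = rng.integers(1, 3)
    return Shell(atom, l, rng.normal(size=3) * 0.8,
                 np.exp(rng.normal(size=nprim) * 0.5),
                 rng.uniform(0.3, 1.0, size=nprim))


def _shell_value(sh, comp, pts):
    lx, ly, lz = comp
    d = pts - sh.center
    rad = np.zeros(len(pts))
    for a, c in zip(sh.exps, sh.coefs):
        rad += c * np.exp(-a * np.sum(d**2, axis=1))
    return component_scale(lx, ly, lz) * d[:, 0]**lx * d[:, 1]**ly * d[:, 2]**lz * rad


def test_concentric_closed_forms():
    """All Gaussians on one center: g, dg/domega from the closed form; f = 0."""
    alpha, beta, omega = 0.7, 1.3, 2.1
    N = (omega / np.pi) ** 1.5
    c = np.zeros(3)
    sha = Shell(0, 0, c, np.array([alpha]), np.array([1.0]))
    shb = Shell(0, 0, c, np.array([beta]), np.array([1.0]))
    t = _tessera(c, omega)
    q = alpha + beta + omega
    assert g_integrals(sha, shb, t)[0, 0, 0] == pytest.approx(
        N * (np.pi / q) ** 1.5, rel=1e-14)
    dg, _ = exponent_derivative_integrals(sha, shb, t)
    assert dg[0, 0, 0] == pytest.approx(-N * 1.5 * np.pi**1.5 * q**-2.5,
                                        rel=1e-13)
    assert f_integrals(sha, shb, t)[0, 0, 0] == 0.0


@pytest.mark.parametrize("la,lb", [(0, 0), (1, 0), (1, 1), (2, 1), (2, 2), (3, 2)])
def test_blocks_match_quadrature_oracle(la, lb, rng):
    """g/f/exponent-derivative blocks agree with brute-force quadrature."""
    for _ in range(3):
        sha = _random_shell(rng, la)
        shb = _random_shell(rng, lb, atom=1)
        C = rng.normal(size=3)
        omega = np.exp(rng.normal() * 0.5 + 0.3)
        nvec = rng.normal(size=3)
        t = _tessera(C, omega, nvec)
        blocks = pair_blocks(sha, shb, t, want=("g", "f", "dgdw"))
        ia = rng.integers(0, len(cart_components(la)))
        ib = rng.integers(0, len(cart_components(lb)))
        ca = cart_components(la)[ia]
        cb = cart_components(lb)[ib]
        # reference decay for the oracle grid: the most diffuse primitive of
        # each contracted shell (a faster declared decay than the integrand's
        # slowest term would leave growing residuals on the grid)
        gaussians = [(sha.exps.min(), sha.center),
                     (shb.exps.min(), shb.center), (omega, C)]
        N = t.norms[0]
        nrm = t.normals[0]

        def base(pts):
            return _shell_value(sha, ca, pts) * _shell_value(shb, cb, pts) \
                * N * np.exp(-omega * np.sum((pts - C) ** 2, axis=1))

        ref_g = quadrature_oracle(base, gaussians)
        assert blocks["g"][ia, ib, 0] == pytest.approx(ref_g, rel=1e-9,
                                                       abs=1e-14)
        ref_f = quadrature_oracle(
            lambda pts: 2.0 * omega * ((pts - C) @ nrm) * base(pts), gaussians)
        assert blocks["f"][ia, ib, 0] == pytest.approx(ref_f, rel=1e-9,
                                                       abs=1e-14)
        ref_dg = quadrature_oracle(
            lambda pts: -np.sum((pts - C) ** 2, axis=1) * base(pts), gaussians)
        assert blocks["dgdw"][ia, ib, 0] == pytest.approx(ref_dg, rel=1e-9,
                                                          abs=1e-14)


def test_bra_ket_symmetry(rng):
    """mu <-> nu exchange: block of (b,a) is the transpose of (a,b)."""
    sha = _random_shell(rng, 2)
    shb = _random_shell(rng, 1, atom=1)
    t = _tessera(rng.normal(size=3), 1.4, rng.normal(size=3))
    for key in ("g", "f", "dgdw", "dfdw"):
        ab = pair_blocks(sha, shb, t, want=(key,))[key]
        ba = pair_blocks(shb, sha, t, want=(key,))[key]
        assert np.abs(ab - ba.transpose(1, 0, 2)).max() < 1e-13


def test_normal_flip_negates_f(rng):
    sha = _random_shell(rng, 1)
    shb = _random_shell(rng, 0, atom=1)
    C = rng.normal(size=3)
    n = rng.normal(size=3)
    f1 = f_integrals(sha, shb, _tessera(C, 1.1, n))
    f2 = f_integrals(sha, shb, _tessera(C, 1.1, -n))
    assert np.abs(f1 + f2).max() < 1e-15


def test_distant_tessera_vanishes(rng):
    sha = _random_shell(rng, 1)
    shb = _random_shell(rng, 1, atom=1)
    t = _tessera(np.array([50.0, 0.0, 0.0]), 1.0)
    blocks = pair_blocks(sha, shb, t, want=("g", "f", "dgdw", "dfdw"))
    for key in blocks:
        assert np.abs(blocks[key]).max() < 1e-15


def test_derivatives_match_finite_differences(rng):
    sha = _random_shell(rng, 2)
    shb = _random_shell(rng, 1, atom=1)
    C = rng.normal(size=3) * 0.5
    omega = 1.3
    nvec = rng.normal(size=3)
    t = _tessera(C, omega, nvec)
    nrm = t.norms[0]
    blocks = pair_blocks(sha, shb, t, want=("g", "f", "dgdw", "dfdw",
                                            "dgdA", "dfdA"))
    # f is the normal-directional derivative of g in the tessera center
    eps = 1e-5
    n = t.normals[0]
    gp = pair_blocks(sha, shb, _tessera_fixed(C + eps * n, omega, nrm, n),
                     want=("g",))["g"]
    gm = pair_blocks(sha, shb, _tessera_fixed(C - eps * n, omega, nrm, n),
                     want=("g",))["g"]
    assert np.abs(blocks["f"] - (gp - gm) / (2 * eps)).max() < 1e-7
    # exponent derivatives at fixed N
    eps = 1e-6
    bp = pair_blocks(sha, shb, _tessera_fixed(C, omega + eps, nrm, n),
                     want=("g", "f"))
    bm = pair_blocks(sha, shb, _tessera_fixed(C, omega - eps, nrm, n),
                     want=("g", "f"))
    assert np.abs(blocks["dgdw"] - (bp["g"] - bm["g"]) / (2 * eps)).max() < 1e-7
    assert np.abs(blocks["dfdw"] - (bp["f"] - bm["f"]) / (2 * eps)).max() < 1e-7
    # bra-center derivative
    eps = 1e-5
    for d in range(3):
        e = np.zeros(3)
        e[d] = eps
        shp = Shell(0, sha.l, sha.center + e, sha.exps, sha.coefs)
        shm = Shell(0, sha.l, sha.center - e, sha.exps, sha.coefs)
        fd = (pair_blocks(shp, shb, t, want=("g",))["g"]
              - pair_blocks(shm, shb, t, want=("g",))["g"]) / (2 * eps)
        assert np.abs(blocks["dgdA"][d] - fd).max() < 1e-7


def _tessera_fixed(C, omega, N, n):
    return TesseraBatch(np.asarray(C, float).reshape(1, 3),
                        np.array([float(omega)]), np.array([float(N)]),
                        np.asarray(n, float).reshape(1, 3),
                        np.array([np.pi * np.log(2) / omega]))


def test_translational_invariance_of_derivative_blocks(rng):
    """Bra + ket + tessera-center derivatives sum to zero componentwise.

    The tessera-center derivative is evaluated directly as a p-type surface
    Gaussian integral (the f machinery with Cartesian unit normals), an
    independent route from the bra-shift code.
    """
    for la, lb in [(0, 0), (1, 1), (2, 1)]:
        sha = _random_shell(rng, la)
        shb = _random_shell(rng, lb, atom=1)
        C = rng.normal(size=3)
        omega = 0.9
        t = _tessera(C, omega)
        dA = pair_blocks(sha, shb, t, want=("dgdA",))["dgdA"]
        dB = pair_blocks(shb, sha, t, want=("dgdA",))["dgdA"].transpose(0, 2, 1, 3)
        for d in range(3):
            e = np.zeros(3)
            e[d] = 1.0
            td = _tessera_fixed(C, omega, t.norms[0], e)
            dC = f_integrals(sha, shb, td)
            assert np.abs(dA[d] + dB[d] + dC).max() < 1e-12


def test_screening_is_conservative(rng):
    """Bound >= true max always; far batches are skipped correctly."""
    for _ in range(25):
        la, lb = rng.integers(0, 3), rng.integers(0, 2)
        sha = _random_shell(rng, la)
        shb = _random_shell(rng, lb, atom=1)
        C = rng.normal(size=3) * rng.uniform(0.5, 8.0)
        t = _tessera(C, np.exp(rng.normal()))
        keep, bound = screen_batches(sha, shb, t, threshold=0.0)
        assert keep  # threshold zero never skips
        blocks = pair_blocks(sha, shb, t, want=("g", "f"))
        true_max = max(np.abs(blocks["g"]).max(), np.abs(blocks["f"]).max())
        assert bound >= true_max
    # far batch: skipped, and the true values really are below threshold
    sha = _random_shell(rng, 1)
    shb = _random_shell(rng, 1, atom=1)
    t = _tessera(np.array([50.0, 0, 0]), 1.0)
    keep, bound = screen_batches(sha, shb, t, threshold=1e-12)
    assert not keep
    blocks = pair_blocks(sha, shb, t, want=("g", "f"))
    assert max(np.abs(blocks["g"]).max(), np.abs(blocks["f"]).max()) < 1e-12


def test_sweep_kernels_match_generic_path(h2o, engines, rng):
    """The numba sweep kernels reproduce the vectorized reference blocks."""
    eng = engines(h2o)
    cav = build_cavity(h2o.mol)
    n = eng.n_ao
    D = rng.normal(size=(n, n))
    D = D + D.T
    gt, ft = sweep_aux_vectors(eng.basis, cav, D, threshold=1e-12)
    tb = TesseraBatch.from_cavity(cav)
    gt_ref = np.zeros(cav.n_tesserae)
    ft_ref = np.zeros(cav.n_tesserae)
    for i, sa in enumerate(eng.basis.shells):
        for sb in eng.basis.shells[:i + 1]:
            sym = 1.0 if sa is sb else 2.0
            blk = pair_blocks(sa, sb, tb, want=("g", "f"))
            Db = D[sa.ao_offset:sa.ao_offset + sa.n_func,
                   sb.ao_offset:sb.ao_offset + sb.n_func]
            gt_ref += sym * np.einsum("abt,ab->t", blk["g"], Db)
            ft_ref += sym * np.einsum("abt,ab->t", blk["f"], Db)
    assert np.abs(gt - gt_ref).max() < 1e-11
    assert np.abs(ft - ft_ref).max() < 1e-11
    # screening must not alter kept values
    gt0, ft0 = sweep_aux_vectors(eng.basis, cav, D, threshold=0.0)
    assert np.abs(gt - gt0).max() < 1e-12 * max(1.0, np.abs(gt0).max())
    # Fock-type accumulation
    w1 = rng.normal(size=cav.n_tesserae) * 1e-3
    w2 = rng.normal(size=cav.n_tesserae) * 1e-3
    F = sweep_fock(eng.basis, cav, w1, w2, threshold=1e-12)
    assert np.abs(F - F.T).max() < 1e-14


def test_unsupported_angular_momentum(rng):
    bad = Shell(0, 5, np.zeros(3), np.array([1.0]), np.array([1.0]))
    ok = _random_shell(rng, 0)
    with pytest.raises(NotImplementedError):
        g_integrals(bad, ok, _tessera(np.zeros(3), 1.0))


def test_bra_derivative_api(rng):
    sha = _random_shell(rng, 1)
    shb = _random_shell(rng, 1, atom=1)
    t = _tessera(rng.normal(size=3), 1.0)
    dg, df = bra_derivative_integrals(sha, shb, t)
    assert dg.shape == (3, 3, 3, 1)
    assert df.shape == (3, 3, 3, 1)
    assert np.all(np.isfinite(dg)) and np.all(np.isfinite(df))
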