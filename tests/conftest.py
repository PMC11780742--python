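"""Shared fixtures: geometries, cached SCF engines and heavy shared runs."""

from __future__ import annotations

import numpy as np
import pytest

from hipres import RHF, make_fixture, run_scf


@pytest.fixture(scope="session")
def h2():
    return make_fixture("h2")


@pytest.fixture(scope="session")
def h2o():
    return make_fixture("h2o")


@pytest.fixture(scope="session")
def ch4():
    return make_fixture("ch4")


@pytest.fixture(scope="session")
def ne2():
    return make_fixture("ne2")


@pytest.fixture(scope="session")
def engines():
    """Cache of RHF engines keyed by fixture name (integrals are expensive)."""
    cache = {}

    def get(fx):
        if fx.name not in cache:
            cache[fx.name] = RHF(fx.mol, basis=fx.basis)
        return cache[fx.name]

    return get


@pytest.fixture(scope="session")
def h2o_occ_10gpa(h2o, engines):
    """Converged pressure-coupled SCF on water, vdW/OCC, 10 GPa."""
    rec = run_scf(h2o.mol, 10.0, engine=engines(h2o), cavity_type="vdw_occ",
                  conv_tol=1e-11)
    assert rec.converged
    return rec


@pytest.fixture(scope="session")
def crevice_runs(engines):
    """Crevice-fixture SCF at 5 GPa with plain vdW and with OCC.

    Shared between the diagnostic acceptance test and unit tests; this is the
    most expensive computation in the suite.
    """
    fx = make_fixture("benzene_dimer_crevice")
    eng = engines(fx)
    out = {}
    for ctype in ("vdw", "vdw_occ"):
        out[ctype] = run_scf(fx.mol, 5.0, engine=eng, cavity_type=ctype,
                             r_ext=fx.r_ext, radii=fx.radii,
                             conv_tol=1e-7, max_iter=200)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
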