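"""Tessellated van der Waals surfaces and their nuclear derivatives."""

import numpy as np
import pytest

from hipres import apply_occ, build_cavity, build_vdw_cavity, from_angstrom
from hipres.fixtures import mc_union_sphere_area, quadrature_oracle
from hipres.geometry import Molecule
from hipres.units import BOHR_PER_ANGSTROM

A2B = BOHR_PER_ANGSTROM


def _he(radius_bohr=2.0):
    mol = from_angstrom(["He"], [[0, 0, 0]])
    return mol, {"He": radius_bohr / A2B}


def test_isolated_sphere_area_and_count():
    """A lone atom keeps every grid point; areas sum to 4 pi r^2 exactly."""
    mol, radii = _he(2.0)
    cav = build_vdw_cavity(mol, radii=radii, grid_points=110)
    assert cav.n_tesserae == 110
    assert cav.areas.sum() == pytest.approx(16 * np.pi, rel=1e-12)
    assert np.allclose(np.linalg.norm(cav.normals, axis=1), 1.0, atol=1e-12)
    # centers on the sphere
    r = np.linalg.norm(cav.centers - mol.coords[0], axis=1)
    assert np.abs(r - 2.0).max() < 1e-12


def test_tessera_gaussian_contracts():
    """Edge-halving and unit normalization hold for every tessera."""
    mol, radii = _he(2.0)
    cav = build_vdw_cavity(mol, radii=radii)
    # G(sqrt(a/pi)) = G(0)/2  <=>  exp(-omega a / pi) = 1/2
    assert np.abs(np.exp(-cav.omegas * cav.areas / np.pi) - 0.5).max() < 1e-12
    # quadrature of N exp(-omega r^2) over space = 1
    for j in (0, 57, 109):
        om, N, c = cav.omegas[j], cav.norms[j], cav.centers[j]
        val = quadrature_oracle(
            lambda pts, om=om, N=N, c=c:
                N * np.exp(-om * np.sum((pts - c) ** 2, axis=1)),
            [(om, c)])
        assert val == pytest.approx(1.0, abs=1e-10)


def test_separated_atoms_equal_union_of_isolated():
    """Beyond the switching margin the dimer cavity is two intact spheres."""
    r = 2.0 / A2B
    far = Molecule(["He", "He"], np.array([[0, 0, 0], [0, 0, 10.0]]))
    cav = build_vdw_cavity(far, radii={"He": r})
    iso = build_vdw_cavity(from_angstrom(["He"], [[0, 0, 0]]), radii={"He": r})
    assert cav.n_tesserae == 2 * iso.n_tesserae
    assert cav.areas.sum() == pytest.approx(2 * iso.areas.sum(), rel=1e-12)
    assert np.all(cav.weights == 1.0)


def test_overlapping_atoms_area_matches_monte_carlo():
    """At 1.5 r separation the smoothed area tracks the true union area.

    The switching band (width 0.1 r around each seam) smears the sharp
    intersection, so agreement is expected only to a few percent.
    """
    rb = 2.5
    mol = Molecule(["He", "He"], np.array([[0, 0, 0], [0, 0, 1.5 * rb]]))
    cav = build_vdw_cavity(mol, radii={"He": rb / A2B}, grid_points=194)
    mc = mc_union_sphere_area(mol.coords, np.array([rb, rb]),
                              n_samples=400_000, seed=11)
    assert cav.areas.sum() < 2 * 4 * np.pi * rb**2
    assert cav.areas.sum() == pytest.approx(mc, rel=0.03)


def test_occ_degenerate_and_isolated_limits():
    mol, radii = _he(2.0)
    vdw = build_vdw_cavity(mol, radii=radii)
    occ0 = apply_occ(mol, 0.0, radii=radii)
    assert occ0.n_tesserae == vdw.n_tesserae
    assert np.allclose(occ0.areas, vdw.areas)
    # isolated atom: any extension changes nothing (no neighbors to screen)
    occ = apply_occ(mol, 0.5 * A2B, radii=radii)
    assert np.allclose(occ.areas, vdw.areas)
    assert np.allclose(occ.centers, vdw.centers)


def test_occ_screens_monotonically_with_extension_radius():
    """Larger r_ext screens away at least as many crevice points."""
    rb = 2.5
    mol = Molecule(["He", "He"], np.array([[0, 0, 0], [0, 0, 2.1 * rb]]))
    radii = {"He": rb / A2B}
    n_vdw = build_vdw_cavity(mol, radii=radii).n_tesserae
    n_small = apply_occ(mol, 0.25 * A2B, radii=radii).n_tesserae
    n_large = apply_occ(mol, 0.5 * A2B, radii=radii).n_tesserae
    assert n_large <= n_small <= n_vdw


@pytest.mark.parametrize("r_ext_angstrom", [0.0, 0.25])
def test_area_derivatives_match_finite_differences(h2o, r_ext_angstrom):
    mol = h2o.mol
    r_ext = r_ext_angstrom * A2B
    cav = build_cavity(mol, r_ext=r_ext)
    da = cav.darea
    # rigid-translation consistency: per-tessera rows sum to zero
    assert np.abs(da.sum(axis=1)).max() < 1e-12
    step = 1e-5
    for I in range(mol.n_atoms):
        for x in range(3):
            ap = []
            for s in (+1, -1):
                c = mol.coords.copy()
                c[I, x] += s * step
                cv = build_cavity(mol.with_coords(c), r_ext=r_ext,
                                  with_derivatives=False)
                assert cv.n_tesserae == cav.n_tesserae
                ap.append(cv.areas)
            fd = (ap[0] - ap[1]) / (2 * step)
            scale = np.maximum(np.abs(fd), 1e-4)
            assert (np.abs(fd - da[:, I, x]) / scale).max() < 1e-6


def test_rigid_translation_preserves_areas():
    rb = 2.5
    mol = Molecule(["He", "He"], np.array([[0, 0, 0], [0, 0, 1.6 * rb]]))
    radii = {"He": rb / A2B}
    cav = build_vdw_cavity(mol, radii=radii)
    shift = np.array([0.3, -0.2, 0.15])
    cav2 = build_vdw_cavity(mol.with_coords(mol.coords + shift), radii=radii)
    assert np.allclose(cav2.areas, cav.areas, atol=1e-13)
    assert np.allclose(cav2.centers, cav.centers + shift, atol=1e-12)


def test_smoothness_under_small_displacement():
    """Moving one atom by 1e-3 bohr changes every retained area by O(1e-3)."""
    rb = 2.5
    mol = Molecule(["He", "He"], np.array([[0, 0, 0], [0, 0, 1.5 * rb]]))
    radii = {"He": rb / A2B}
    cav = build_vdw_cavity(mol, radii=radii, grid_points=194)
    c = mol.coords.copy()
    c[1, 2] += 1e-3
    cav2 = build_vdw_cavity(mol.with_coords(c), radii=radii, grid_points=194)
    assert cav2.n_tesserae == cav.n_tesserae
    assert np.abs(cav2.areas - cav.areas).max() < 5e-3


def test_configuration_errors():
    with pytest.raises(ValueError, match="radius"):
        build_vdw_cavity(from_angstrom(["He"], [[0, 0, 0]]), radii={"He": -1.0})
    with pytest.raises(ValueError, match="unsupported"):
        build_vdw_cavity(from_angstrom(["He"], [[0, 0, 0]]), grid_points=100)
    with pytest.raises(ValueError, match=">= 0"):
        build_cavity(from_angstrom(["He"], [[0, 0, 0]]), r_ext=-0.1)


def test_cavity_dump_is_parseable(h2o):
    cav = build_cavity(h2o.mol)
    text = cav.dump()
    rows = [ln.split() for ln in text.splitlines()[1:]]
    assert len(rows) == cav.n_tesserae
    assert float(rows[0][5]) == pytest.approx(cav.areas[0])
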