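"""Test fixtures and independent brute-force oracles.

The oracles deliberately share no code with the production integral and
gradient routines: the quadrature oracle evaluates integrands numerically on
escalating Gauss-Hermite product grids, the finite-difference oracle
differentiates arbitrary callables, and the Monte-Carlo oracle estimates
union-of-spheres surface areas by rejection sampling.  Fixture geometries are
small deterministic molecules; the crevice fixture stacks two benzene rings
closely enough (with enlarged carbon spheres) that the plain vdW surface
develops the inter-ring crevice artifacts that the outer-cavity correction
is designed to remove.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Molecule, from_angstrom

__all__ = ["Fixture", "make_fixture", "fixture_names", "quadrature_oracle",
           "finite_difference_oracle", "mc_union_sphere_area"]


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

class OracleError(RuntimeError):
    """Raised when an oracle cannot reach its requested tolerance."""


def quadrature_oracle(integrand, gaussians: list[tuple[float, np.ndarray]],
                      rtol: float = 1e-10, atol: float = 1e-14,
                      max_order: int = 96) -> float:
    """Numerically integrate ``integrand`` over R^3.

    `integrand(points)` maps an (n, 3) array to values and must be a product
    of the Gaussians listed in `gaussians` (pairs of exponent, center) times
    a polynomial.  A Gauss-Hermite product grid is centered at the combined
    Gaussian center; the combined Gaussian is divided out of the integrand
    and re-applied through the quadrature weights, so the rule converges as
    soon as the order covers the polynomial degree.  The order is escalated
    until two successive orders agree to tolerance; failure raises rather
    than returning a silently inaccurate value.
    """
    exps = np.array([g[0] for g in gaussians], dtype=float)
    cens = np.array([g[1] for g in gaussians], dtype=float).reshape(-1, 3)
    if np.any(exps <= 0):
        raise ValueError("Gaussian exponents must be positive")
    q = exps.sum()
    Q = (exps[:, None] * cens).sum(axis=0) / q

    prev = None
    orders = [o for o in (6, 8, 12, 16, 24, 32, 48, 64, 96) if o < max_order]
    orders.append(max_order)
    for order in orders:
        x, w = np.polynomial.hermite.hermgauss(order)
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        pts = Q[None, :] + np.stack([X, Y, Z], axis=-1).reshape(-1, 3) / np.sqrt(q)
        W = (w[:, None, None] * w[None, :, None] * w[None, None, :]).ravel()
        vals = np.asarray(integrand(pts), dtype=float)
        # divide out the combined Gaussian at the nodes (re-applied via the
        # Hermite weight e^{-|u|^2}); guard the exponential overflow
        u2 = q * np.sum((pts - Q) ** 2, axis=1)
        terms = W * vals * np.exp(np.minimum(u2, 700.0))
        est = float(terms.sum() * q ** -1.5)
        # roundoff floor of the summation, from the absolute-value integral
        floor = 1e-14 * float(np.abs(terms).sum() * q ** -1.5)
        if prev is not None and abs(est - prev) <= max(rtol * abs(est), atol,
                                                       floor):
            return est
        prev, prev2 = est, prev
    raise OracleError(
        f"quadrature did not converge to rtol={rtol}, atol={atol} by order "
        f"{max_order}: last two estimates {prev2}, {prev}")


def finite_difference_oracle(fun, x0: float, step: float = 1e-5,
                             richardson: bool = True,
                             drift_tol: float = 0.01) -> dict:
    """Central-difference derivative of a scalar function of one variable.

    Returns a dict with the estimate, the coarse/fine stencil values, the
    step-halving drift, and a reliability flag.  For a smooth function the
    drift between the full-step and half-step stencils shrinks like step^2;
    the estimate is flagged unreliable when the drift exceeds `drift_tol`
    times the derivative scale, which signals noise or non-smoothness at the
    working step.  With richardson=True the two stencils are
    Richardson-extrapolated.
    """
    def central(h):
        return (fun(x0 + h) - fun(x0 - h)) / (2.0 * h)

    d1 = central(step)
    d2 = central(step / 2.0)
    drift = abs(d2 - d1)
    est = (4.0 * d2 - d1) / 3.0 if richardson else d2
    scale = max(abs(d1), abs(d2))
    reliable = drift <= drift_tol * scale + 1e-12
    return {"derivative": est, "coarse": d1, "fine": d2,
            "drift": drift, "reliable": bool(reliable)}


def mc_union_sphere_area(centers: np.ndarray, radii: np.ndarray,
                         n_samples: int = 200_000, seed: int = 0) -> float:
    """Monte-Carlo surface area of a union of spheres.

    Samples points uniformly on each sphere and counts the fraction exposed
    (outside every other sphere); independent of the Lebedev/switching
    machinery.
    """
    rng = np.random.default_rng(seed)
    centers = np.asarray(centers, dtype=float)
    radii = np.asarray(radii, dtype=float)
    total = 0.0
    for i in range(len(radii)):
        v = rng.normal(size=(n_samples, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        pts = centers[i] + radii[i] * v
        exposed = np.ones(n_samples, dtype=bool)
        for k in range(len(radii)):
            if k == i:
                continue
            exposed &= np.linalg.norm(pts - centers[k], axis=1) >= radii[k]
        total += 4.0 * np.pi * radii[i] ** 2 * exposed.mean()
    return total


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    """A named test system: geometry plus cavity/SCF configuration."""

    name: str
    mol: Molecule
    basis: str = "sto-3g"
    radii: dict[str, float] | None = None      # element -> Å override
    r_ext: float = 0.25                        # Å, for vdw_occ runs
    grid_points: int = 110
    pressures_gpa: tuple[float, ...] = (0.0, 5.0)
    tags: tuple[str, ...] = ()

    def scf_kwargs(self, cavity_type: str = "vdw_occ") -> dict:
        return {"cavity_type": cavity_type, "r_ext": self.r_ext,
                "grid_points": self.grid_points, "radii": self.radii,
                "basis": self.basis}


def _benzene_ring(z_angstrom: float) -> tuple[list[str], list[list[float]]]:
    rc, rh = 1.39, 2.48
    symbols, coords = [], []
    for k in range(6):
        th = np.pi / 3.0 * k
        symbols.append("C")
        coords.append([rc * np.cos(th), rc * np.sin(th), z_angstrom])
    for k in range(6):
        th = np.pi / 3.0 * k
        symbols.append("H")
        coords.append([rh * np.cos(th), rh * np.sin(th), z_angstrom])
    return symbols, coords


def make_fixture(name: str) -> Fixture:
    """Deterministic fixture geometries.

    Names: h2, h2o, ch4, ne2, benzene_dimer_crevice.
    """
    if name == "h2":
        mol = from_angstrom(["H", "H"], [[0, 0, 0], [0, 0, 0.74]])
        return Fixture(name, mol, pressures_gpa=(0.0, 5.0, 20.0, 50.0))
    if name == "h2o":
        mol = from_angstrom(
            ["O", "H", "H"],
            [[0.0, 0.0, 0.1173], [0.0, 0.7572, -0.4692], [0.0, -0.7572, -0.4692]])
        return Fixture(name, mol, pressures_gpa=(0.0, 1.0, 5.0, 10.0, 20.0))
    if name == "ch4":
        d = 1.089 / np.sqrt(3.0)
        mol = from_angstrom(
            ["C", "H", "H", "H", "H"],
            [[0, 0, 0], [d, d, d], [d, -d, -d], [-d, d, -d], [-d, -d, d]])
        return Fixture(name, mol, pressures_gpa=(0.0, 5.0, 25.0))
    if name == "ne2":
        mol = from_angstrom(["Ne", "Ne"], [[0, 0, 0], [0, 0, 3.1]])
        return Fixture(name, mol, pressures_gpa=(0.0, 5.0))
    if name == "benzene_dimer_crevice":
        # stacked eclipsed rings; with the enlarged aromatic radii the carbon
        # spheres of the two rings barely interpenetrate at 3.6 Å, leaving a
        # narrow surviving wedge of surface points between the rings whose
        # Gaussians overlap the opposite ring's density -- the crevice regime
        # (at much closer stacking the wedge is screened away entirely and
        # the artifact disappears)
        s1, c1 = _benzene_ring(0.0)
        s2, c2 = _benzene_ring(3.6)
        mol = from_angstrom(s1 + s2, c1 + c2)
        return Fixture(name, mol, radii={"H": 1.4, "C": 2.1},
                       pressures_gpa=(0.0, 5.0),
                       tags=("crevice",))
    raise ValueError(f"unknown fixture {name!r}; available: {fixture_names()}")


def fixture_names() -> tuple[str, ...]:
    return ("h2", "h2o", "ch4", "ne2", "benzene_dimer_crevice")
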