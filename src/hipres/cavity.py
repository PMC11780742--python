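"""Discretized van der Waals molecular surfaces.

Each non-ghost atom carries a sphere of its van der Waals radius, sampled
with a Lebedev angular grid.  A grid point on atom I that penetrates a
neighboring sphere is faded out by a smooth switching function so that the
surface (and everything derived from it) stays differentiable as atoms move;
points whose total switching weight falls below a discard cutoff are removed.

Each retained point becomes a *tessera*: a surface element with a center
r_j (rigidly attached to its parent atom), an area

    a_j = (Lebedev weight) * 4 pi r_I^2 * (switching weight),

an outward unit normal (the radial direction from the parent atom), a
Gaussian exponent from the edge-halving condition omega_j = pi ln2 / a_j
(the surface Gaussian drops to half its peak at the tessera edge radius
sqrt(a_j/pi)), and the normalization N_j = (omega_j/pi)^(3/2) making the
Gaussian integrate to one.

The outer cavity correction (OCC) removes crevice artifacts: a second
surface is built at radii r_vdW + r_ext with the same Lebedev directions
(one-to-one point mapping) and each inner tessera is assigned the switching
weight of its *outer* counterpart.  Crevice points that survive on the inner
surface but are buried on the outer one are thereby screened away, at the
price of small holes in the parametrization (dropped, not re-normalized).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Molecule
from .lebedev import lebedev_grid
from .units import BOHR_PER_ANGSTROM, BONDI_RADII_ANGSTROM

__all__ = ["Cavity", "build_vdw_cavity", "apply_occ", "build_cavity",
           "cavity_derivatives", "resolve_radii"]

DEFAULT_GRID_POINTS = 110
DEFAULT_SWITCH_WIDTH = 0.1   # fraction of the penetrated sphere's radius
DEFAULT_DISCARD_CUTOFF = 1e-8


def _smoothstep(x: np.ndarray) -> np.ndarray:
    """C^2 quintic smooth-step: 0 for x<=0, 1 for x>=1, 6x^5-15x^4+10x^3 between."""
    xc = np.clip(x, 0.0, 1.0)
    return xc**3 * (10.0 + xc * (-15.0 + 6.0 * xc))


def _smoothstep_deriv(x: np.ndarray) -> np.ndarray:
    xc = np.clip(x, 0.0, 1.0)
    d = 30.0 * xc**2 * (1.0 - xc) ** 2
    return np.where((x <= 0.0) | (x >= 1.0), 0.0, d)


def resolve_radii(mol: Molecule, radii: dict[str, float] | None = None) -> np.ndarray:
    """Per-atom cavity sphere radii in bohr.

    `radii` maps element symbols to radii in Å and overrides the built-in
    Bondi table.  Ghost atoms get radius 0 (no sphere).
    """
    out = np.zeros(mol.n_atoms)
    for i, sym in enumerate(mol.symbols):
        if mol.ghost[i]:
            continue
        r = None
        if radii and sym in radii:
            r = radii[sym]
        elif sym in BONDI_RADII_ANGSTROM:
            r = BONDI_RADII_ANGSTROM[sym]
        if r is None:
            raise ValueError(f"no cavity radius known for element {sym!r}; "
                             "pass it explicitly via `radii`")
        if r <= 0:
            raise ValueError(f"cavity radius for {sym} must be positive, got {r}")
        out[i] = r * BOHR_PER_ANGSTROM
    return out


@dataclass
class Cavity:
    """A tessellated molecular surface (all quantities in bohr-based units)."""

    centers: np.ndarray        # (nt, 3) tessera centers
    areas: np.ndarray          # (nt,)   tessera areas
    normals: np.ndarray        # (nt, 3) outward unit normals
    weights: np.ndarray        # (nt,)   switching weights in (cutoff, 1]
    parents: np.ndarray        # (nt,)   parent atom index
    omegas: np.ndarray         # (nt,)   Gaussian exponents pi*ln2/a_j
    norms: np.ndarray          # (nt,)   normalizations (omega/pi)^(3/2)
    radii: np.ndarray          # (natom,) sphere radii (0 for ghosts)
    grid_points: int
    r_ext: float               # OCC extension radius (bohr); 0 = plain vdW
    switch_width: float
    discard_cutoff: float
    atom_coords: np.ndarray    # geometry the cavity was built from
    darea: np.ndarray | None = field(default=None, repr=False)  # (nt, natom, 3)

    @property
    def n_tesserae(self) -> int:
        return len(self.areas)

    @property
    def kind(self) -> str:
        return "vdw_occ" if self.r_ext > 0 else "vdw"

    def dcenter(self, j: int, atom: int) -> np.ndarray:
        """d r_j / d R_atom — identity for the parent atom, zero otherwise."""
        return np.eye(3) if self.parents[j] == atom else np.zeros((3, 3))

    def dump(self) -> str:
        """Plain-text table of the tesserae (debugging aid)."""
        lines = ["# idx parent  cx cy cz [bohr]  area [bohr^2]  nx ny nz  weight"]
        for j in range(self.n_tesserae):
            c = self.centers[j]; n = self.normals[j]
            lines.append(
                f"{j:5d} {self.parents[j]:4d}  "
                f"{c[0]:+.8f} {c[1]:+.8f} {c[2]:+.8f}  {self.areas[j]:.10f}  "
                f"{n[0]:+.6f} {n[1]:+.6f} {n[2]:+.6f}  {self.weights[j]:.8f}")
        return "\n".join(lines)


def _switch_weights(points: np.ndarray, parents: np.ndarray,
                    coords: np.ndarray, radii: np.ndarray,
                    switch_width: float) -> np.ndarray:
    """Product switching weight of each point against all foreign spheres."""
    npt = len(points)
    w = np.ones(npt)
    for k in range(len(radii)):
        rk = radii[k]
        if rk <= 0.0:
            continue
        mask = parents != k
        if not mask.any():
            continue
        d = np.linalg.norm(points[mask] - coords[k], axis=1)
        lo = rk * (1.0 - switch_width)
        x = (d - lo) / (rk - lo)
        w[mask] *= _smoothstep(x)
    return w


def build_cavity(mol: Molecule, radii: dict[str, float] | None = None,
                 grid_points: int = DEFAULT_GRID_POINTS, r_ext: float = 0.0,
                 switch_width: float = DEFAULT_SWITCH_WIDTH,
                 discard_cutoff: float = DEFAULT_DISCARD_CUTOFF,
                 with_derivatives: bool = True) -> Cavity:
    """Build a vdW (r_ext = 0) or vdW/OCC (r_ext > 0, in bohr) cavity.

    Ghost atoms carry no sphere and do not screen anything.
    """
    if r_ext < 0:
        raise ValueError(f"OCC extension radius must be >= 0, got {r_ext}")
    atom_radii = resolve_radii(mol, radii)
    dirs, leb_w = lebedev_grid(grid_points)
    coords = mol.coords

    centers_l, areas_l, normals_l, weights_l, parents_l = [], [], [], [], []
    for i in range(mol.n_atoms):
        ri = atom_radii[i]
        if ri <= 0.0:
            continue
        pts_in = coords[i] + ri * dirs
        par = np.full(len(dirs), i)
        if r_ext > 0.0:
            # weight of the one-to-one mapped outer point against outer spheres
            pts_sw = coords[i] + (ri + r_ext) * dirs
            radii_sw = np.where(atom_radii > 0, atom_radii + r_ext, 0.0)
        else:
            pts_sw = pts_in
            radii_sw = atom_radii
        w = _switch_weights(pts_sw, par, coords, radii_sw, switch_width)
        keep = w >= discard_cutoff
        centers_l.append(pts_in[keep])
        normals_l.append(dirs[keep])
        weights_l.append(w[keep])
        areas_l.append(leb_w[keep] * 4.0 * np.pi * ri**2 * w[keep])
        parents_l.append(par[keep])

    if not centers_l:
        raise ValueError("cavity has no tesserae (no real atoms?)")
    centers = np.vstack(centers_l)
    areas = np.concatenate(areas_l)
    normals = np.vstack(normals_l)
    weights = np.concatenate(weights_l)
    parents = np.concatenate(parents_l)
    omegas = np.pi * np.log(2.0) / areas
    norms = (omegas / np.pi) ** 1.5
    cav = Cavity(centers, areas, normals, weights, parents, omegas, norms,
                 atom_radii, grid_points, float(r_ext), switch_width,
                 discard_cutoff, coords.copy())
    if with_derivatives:
        cavity_derivatives(cav, mol)
    return cav


def build_vdw_cavity(mol: Molecule, radii: dict[str, float] | None = None,
                     grid_points: int = DEFAULT_GRID_POINTS,
                     **kw) -> Cavity:
    """Plain van der Waals cavity (no outer-cavity correction)."""
    return build_cavity(mol, radii=radii, grid_points=grid_points, r_ext=0.0, **kw)


def apply_occ(mol: Molecule, r_ext: float,
              radii: dict[str, float] | None = None,
              grid_points: int = DEFAULT_GRID_POINTS, **kw) -> Cavity:
    """vdW cavity with outer-cavity correction at extension radius r_ext (bohr)."""
    return build_cavity(mol, radii=radii, grid_points=grid_points, r_ext=r_ext, **kw)


def cavity_derivatives(cav: Cavity, mol: Molecule) -> np.ndarray:
    """Analytic nuclear derivatives of the tessera areas, da_j/dR_I,alpha.

    Tessera centers are rigidly attached to their parent atom, so center
    derivatives are handled by :meth:`Cavity.dcenter`; only the switching
    weights (through the point-to-sphere distances, on the outer surface for
    OCC) depend nontrivially on the geometry.  The result is cached on the
    cavity and returned: shape (n_tesserae, n_atoms, 3).
    """
    coords = mol.coords
    natom = mol.n_atoms
    nt = cav.n_tesserae
    darea = np.zeros((nt, natom, 3))
    r_ext = cav.r_ext
    radii_sw = np.where(cav.radii > 0, cav.radii + r_ext, 0.0)
    # switch evaluation points (outer counterparts for OCC)
    pts = cav.centers + r_ext * cav.normals

    for k in range(natom):
        rk = radii_sw[k]
        if rk <= 0.0:
            continue
        mask = cav.parents != k
        if not mask.any():
            continue
        idx = np.nonzero(mask)[0]
        diff = pts[idx] - coords[k]
        d = np.linalg.norm(diff, axis=1)
        lo = rk * (1.0 - cav.switch_width)
        x = (d - lo) / (rk - lo)
        wk = _smoothstep(x)
        dwk = _smoothstep_deriv(x) / (rk - lo)
        # a_j includes the factor w_k; d a_j / d(d) = (a_j / w_k) * dw_k
        safe = wk > 0.0
        idx = idx[safe]
        if len(idx) == 0:
            continue
        fac = cav.areas[idx] / wk[safe] * dwk[safe]
        unit = diff[safe] / d[safe, None]
        # moving atom k toward the point decreases d;
        # moving the parent atom moves the point rigidly, increasing d
        contrib = fac[:, None] * unit
        np.add.at(darea, (idx, np.full(len(idx), k)), -contrib)
        np.add.at(darea, (idx, cav.parents[idx]), contrib)

    cav.darea = darea
    return darea
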