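"""Gaussian basis sets for the built-in SCF engine.

Ships STO-3G for the elements the fixtures need.  Basis functions are
contracted Cartesian Gaussians; shells are stored in flat arrays so the
numba integral kernels can consume them directly.

Component ordering within a shell of angular momentum l: lx runs from l down
to 0, then ly from (l - lx) down to 0, lz = l - lx - ly.  For p shells this is
the conventional x, y, z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# STO-3G exponents and contraction coefficients (coefficients refer to
# unit-normalized primitives).  Second-row atoms use shared sp exponents.
_STO3G_1S_COEF = (0.15432897, 0.53532814, 0.44463454)
_STO3G_2S_COEF = (-0.09996723, 0.39951283, 0.70011547)
_STO3G_2P_COEF = (0.15591627, 0.60768372, 0.39195739)

_STO3G: dict[str, list[tuple[int, tuple[float, ...], tuple[float, ...]]]] = {
    "H": [(0, (3.42525091, 0.62391373, 0.16885540), _STO3G_1S_COEF)],
    "He": [(0, (6.36242139, 1.15892300, 0.31364979), _STO3G_1S_COEF)],
    "C": [
        (0, (71.6168370, 13.0450960, 3.5305122), _STO3G_1S_COEF),
        (0, (2.9412494, 0.6834831, 0.2222899), _STO3G_2S_COEF),
        (1, (2.9412494, 0.6834831, 0.2222899), _STO3G_2P_COEF),
    ],
    "N": [
        (0, (99.1061690, 18.0523120, 4.8856602), _STO3G_1S_COEF),
        (0, (3.7804559, 0.8784966, 0.2857144), _STO3G_2S_COEF),
        (1, (3.7804559, 0.8784966, 0.2857144), _STO3G_2P_COEF),
    ],
    "O": [
        (0, (130.7093200, 23.8088610, 6.4436083), _STO3G_1S_COEF),
        (0, (5.0331513, 1.1695961, 0.3803890), _STO3G_2S_COEF),
        (1, (5.0331513, 1.1695961, 0.3803890), _STO3G_2P_COEF),
    ],
    "F": [
        (0, (166.6791300, 30.3608120, 8.2168207), _STO3G_1S_COEF),
        (0, (4.4369957, 1.0242227, 0.3161167), _STO3G_2S_COEF),
        (1, (4.4369957, 1.0242227, 0.3161167), _STO3G_2P_COEF),
    ],
    "Ne": [
        (0, (207.0156100, 37.7081510, 10.2052970), _STO3G_1S_COEF),
        (0, (8.2463151, 1.9162662, 0.6232293), _STO3G_2S_COEF),
        (1, (8.2463151, 1.9162662, 0.6232293), _STO3G_2P_COEF),
    ],
}

_BASIS_SETS = {"sto-3g": _STO3G}

_DFACT = [1.0, 1.0, 3.0, 15.0, 105.0, 945.0]  # (2n-1)!! for n = 0..5


def n_cart(l: int) -> int:
    return (l + 1) * (l + 2) // 2


def cart_components(l: int) -> list[tuple[int, int, int]]:
    return [(lx, ly, l - lx - ly)
            for lx in range(l, -1, -1)
            for ly in range(l - lx, -1, -1)]


def component_scale(lx: int, ly: int, lz: int) -> float:
    """Angular part of the primitive norm relative to the (l,0,0) component."""
    l = lx + ly + lz
    return np.sqrt(_DFACT[l] / (_DFACT[lx] * _DFACT[ly] * _DFACT[lz]))


def primitive_radial_norm(alpha: float, l: int) -> float:
    """Norm of an (l,0,0) Cartesian primitive Gaussian."""
    return ((2.0 * alpha / np.pi) ** 0.75
            * (4.0 * alpha) ** (l / 2.0)
            / np.sqrt(_DFACT[l]))


@dataclass
class Shell:
    """One contracted Cartesian shell."""

    atom: int
    l: int
    center: np.ndarray           # (3,), bohr
    exps: np.ndarray             # primitive exponents
    coefs: np.ndarray            # coefficients incl. primitive + contracted norm
    ao_offset: int = 0           # first AO index of this shell

    @property
    def n_func(self) -> int:
        return n_cart(self.l)


@dataclass
class BasisSet:
    """All shells of a molecule, plus flat arrays for the numba kernels."""

    shells: list[Shell]
    n_ao: int
    name: str

    def flat_arrays(self):
        ns = len(self.shells)
        centers = np.array([s.center for s in self.shells])
        ls = np.array([s.l for s in self.shells], dtype=np.int64)
        atoms = np.array([s.atom for s in self.shells], dtype=np.int64)
        offsets = np.array([s.ao_offset for s in self.shells], dtype=np.int64)
        pidx = np.zeros(ns + 1, dtype=np.int64)
        for i, s in enumerate(self.shells):
            pidx[i + 1] = pidx[i] + len(s.exps)
        exps = np.concatenate([s.exps for s in self.shells])
        coefs = np.concatenate([s.coefs for s in self.shells])
        return centers, ls, atoms, offsets, pidx, exps, coefs


def available_basis_sets() -> tuple[str, ...]:
    return tuple(_BASIS_SETS)


def build_basis(mol, name: str = "sto-3g") -> BasisSet:
    """Construct the shell list for `mol` (ghost atoms included)."""
    key = name.lower()
    if key not in _BASIS_SETS:
        raise ValueError(f"unknown basis set {name!r}; available: {available_basis_sets()}")
    table = _BASIS_SETS[key]
    shells: list[Shell] = []
    ao = 0
    for ia, sym in enumerate(mol.symbols):
        if sym not in table:
            raise ValueError(f"basis {name!r} has no parameters for element {sym}")
        for l, exps, coefs in table[sym]:
            e = np.array(exps, dtype=float)
            c = np.array(coefs, dtype=float) * np.array(
                [primitive_radial_norm(a, l) for a in exps])
            # renormalize the contraction (overlap of the (l,0,0) component)
            p = e[:, None] + e[None, :]
            s = (np.pi / p) ** 1.5 * _DFACT[l] / (2.0 * p) ** l
            norm = np.einsum("i,j,ij->", c, c, s)
            c /= np.sqrt(norm)
            shells.append(Shell(ia, l, mol.coords[ia].copy(), e, c, ao_offset=ao))
            ao += n_cart(l)
    return BasisSet(shells, ao, key)
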