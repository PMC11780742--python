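"""Molecular geometries and XYZ file I/O.

Coordinates are stored in bohr internally; XYZ files are read and written in Å
(line 1: atom count, line 2: comment, then ``El x y z``).  Atoms can be marked
as ghosts: they carry basis functions but no nuclear charge, no electrons and
no cavity sphere (used for counterpoise corrections).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .units import ANGSTROM_PER_BOHR, ATOMIC_NUMBERS, BOHR_PER_ANGSTROM


@dataclass
class Molecule:
    """A molecule: element symbols plus Cartesian coordinates in bohr."""

    symbols: list[str]
    coords: np.ndarray  # (n_atoms, 3), bohr
    charge: int = 0
    ghost: np.ndarray = field(default=None)  # bool mask, True = ghost atom

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(len(self.symbols), 3)
        if self.ghost is None:
            self.ghost = np.zeros(len(self.symbols), dtype=bool)
        else:
            self.ghost = np.asarray(self.ghost, dtype=bool)
        for s in self.symbols:
            if s not in ATOMIC_NUMBERS:
                raise ValueError(f"unknown element symbol {s!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def charges(self) -> np.ndarray:
        """Nuclear charges; ghosts carry zero charge."""
        z = np.array([ATOMIC_NUMBERS[s] for s in self.symbols], dtype=float)
        z[self.ghost] = 0.0
        return z

    @property
    def n_electrons(self) -> int:
        return int(round(self.charges.sum())) - self.charge

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        return Molecule(list(self.symbols), np.array(coords, dtype=float),
                        charge=self.charge, ghost=self.ghost.copy())

    def real_subset(self) -> "Molecule":
        """The molecule restricted to its non-ghost atoms."""
        mask = ~self.ghost
        return Molecule([s for s, m in zip(self.symbols, mask) if m],
                        self.coords[mask], charge=self.charge)

    def nuclear_repulsion(self) -> float:
        z = self.charges
        e = 0.0
        for i in range(self.n_atoms):
            for j in range(i + 1, self.n_atoms):
                r = np.linalg.norm(self.coords[i] - self.coords[j])
                if z[i] and z[j]:
                    e += z[i] * z[j] / r
        return e

    def nuclear_repulsion_gradient(self) -> np.ndarray:
        z = self.charges
        g = np.zeros_like(self.coords)
        for i in range(self.n_atoms):
            for j in range(self.n_atoms):
                if i == j or not (z[i] and z[j]):
                    continue
                d = self.coords[i] - self.coords[j]
                r = np.linalg.norm(d)
                g[i] -= z[i] * z[j] * d / r**3
        return g


def from_angstrom(symbols: list[str], coords_angstrom, charge: int = 0) -> Molecule:
    coords = np.asarray(coords_angstrom, dtype=float) * BOHR_PER_ANGSTROM
    return Molecule(list(symbols), coords, charge=charge)


def read_xyz(path: str | Path, charge: int = 0) -> Molecule:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"empty XYZ file {path}")
    n = int(lines[0].split()[0])
    symbols, coords = [], []
    for ln in lines[2:2 + n]:
        parts = ln.split()
        symbols.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    if len(symbols) != n:
        raise ValueError(f"XYZ file {path} declares {n} atoms, found {len(symbols)}")
    return from_angstrom(symbols, coords, charge=charge)


def write_xyz(mol: Molecule, path: str | Path, comment: str = "") -> None:
    lines = [str(mol.n_atoms), comment]
    for s, xyz in zip(mol.symbols, mol.coords * ANGSTROM_PER_BOHR):
        lines.append(f"{s} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f}")
    Path(path).write_text("\n".join(lines) + "\n")
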