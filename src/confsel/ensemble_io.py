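"""Multi-frame XYZ ensemble I/O and geometric bond perception.

A :class:`Structure` is one conformer (elements, Cartesian coordinates in
Angstrom, optional free energy in kcal/mol); an :class:`Ensemble` is an
ordered list of composition-identical structures.  Bond perception uses a
covalent-radii distance criterion and returns a :mod:`networkx` graph with
element-labeled nodes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import (
    CompositionError,
    ConfigurationError,
    ContractError,
    ParseError,
    UnknownElementError,
)

__all__ = [
    "HARTREE_TO_KCAL",
    "COVALENT_RADII",
    "Structure",
    "Ensemble",
    "parse_comment_energy",
    "read_xyz_ensemble",
    "write_xyz_ensemble",
    "perceive_bonds",
]

#: CODATA conversion factor, kcal/mol per Hartree.
HARTREE_TO_KCAL = 627.5094740631

#: Single-bond covalent radii in Angstrom (Cordero-style consensus values).
#: Membership in this table is also what "valid element symbol" means here.
COVALENT_RADII = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Sc": 1.70, "Ti": 1.60, "V": 1.53, "Cr": 1.39,
    "Mn": 1.39, "Fe": 1.32, "Co": 1.26, "Ni": 1.24, "Cu": 1.32, "Zn": 1.22,
    "Ga": 1.22, "Ge": 1.20, "As": 1.19, "Se": 1.20, "Br": 1.20, "Kr": 1.16,
    "Rb": 2.20, "Sr": 1.95, "Y": 1.90, "Zr": 1.75, "Nb": 1.64, "Mo": 1.54,
    "Tc": 1.47, "Ru": 1.46, "Rh": 1.42, "Pd": 1.39, "Ag": 1.45, "Cd": 1.44,
    "In": 1.42, "Sn": 1.39, "Sb": 1.39, "Te": 1.38, "I": 1.39, "Xe": 1.40,
    "Cs": 2.44, "Ba": 2.15, "La": 2.07, "Ce": 2.04, "W": 1.62, "Re": 1.51,
    "Os": 1.44, "Ir": 1.41, "Pt": 1.36, "Au": 1.36, "Hg": 1.32, "Tl": 1.45,
    "Pb": 1.46, "Bi": 1.48,
}


@dataclass
class Structure:
    """A single conformer geometry.

    Parameters
    ----------
    elements
        Element symbols, one per atom.
    coords
        ``(N, 3)`` Cartesian coordinates in Angstrom.
    energy
        Free energy in kcal/mol, or ``None`` when unknown.
    label
        Free-text identifier used in reports and file comments.
    """

    elements: list[str]
    coords: np.ndarray
    energy: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ContractError(f"coords must be (N, 3), got {self.coords.shape}")
        if len(self.elements) != self.coords.shape[0]:
            raise ContractError(
                f"{len(self.elements)} elements for {self.coords.shape[0]} coordinate rows"
            )
        if len(self.elements) < 1:
            raise ContractError("a structure needs at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ContractError("coordinates must be finite")
        for el in self.elements:
            if el not in COVALENT_RADII:
                raise UnknownElementError(f"unknown element symbol {el!r}")
        if self.energy is not None and not np.isfinite(self.energy):
            raise ContractError("energy must be finite or None")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def heavy_indices(self) -> list[int]:
        """Indices of non-hydrogen atoms, in original order."""
        return [i for i, el in enumerate(self.elements) if el != "H"]

    def copy(self) -> "Structure":
        return Structure(list(self.elements), self.coords.copy(), self.energy, self.label)


@dataclass
class Ensemble:
    """Ordered collection of conformers of one molecule."""

    structures: list[Structure]
    name: str = "ensemble"

    def __post_init__(self) -> None:
        if not self.structures:
            raise ContractError("an ensemble must contain at least one structure")
        ref = self.structures[0].elements
        for i, s in enumerate(self.structures):
            if s.elements != ref:
                raise CompositionError(
                    f"frame {i} ({s.label!r}) has element order {s.elements}, "
                    f"expected {ref}"
                )

    def __len__(self) -> int:
        return len(self.structures)

    def __iter__(self):
        return iter(self.structures)

    def __getitem__(self, i: int) -> Structure:
        return self.structures[i]

    @property
    def energies(self) -> list[float | None]:
        return [s.energy for s in self.structures]

    def has_energies(self) -> bool:
        return all(s.energy is not None for s in self.structures)


_NUM = r"[-+]?\d*\.?\d+(?:[eEdD][-+]?\d+)?"
_TAGGED_ENERGY = re.compile(rf"(?:energy|e)\s*=\s*({_NUM})", re.IGNORECASE)
_BARE_FLOAT = re.compile(rf"^\s*({_NUM})\s*$")


def parse_comment_energy(comment: str, energy_unit: str = "auto") -> float | None:
    """Extract an energy in kcal/mol from an XYZ comment line.

    Recognizes a bare float, ``Energy= X`` and ``E = X``.  Under
    ``energy_unit="auto"`` a magnitude above 100 is taken to be Hartree
    (absolute electronic energies) and converted; smaller values are read as
    kcal/mol.  ``"kcal/mol"`` and ``"hartree"`` force the unit.  Returns
    ``None`` when no number is found.
    """
    if energy_unit not in ("auto", "kcal/mol", "kcal", "hartree"):
        raise ConfigurationError(f"unknown energy unit {energy_unit!r}")
    m = _TAGGED_ENERGY.search(comment) or _BARE_FLOAT.match(comment)
    if m is None:
        return None
    value = float(m.group(1).replace("d", "e").replace("D", "e"))
    if energy_unit == "hartree":
        return value * HARTREE_TO_KCAL
    if energy_unit in ("kcal/mol", "kcal"):
        return value
    return value * HARTREE_TO_KCAL if abs(value) > 100.0 else value


def read_xyz_ensemble(path, energy_unit: str = "auto", name: str | None = None) -> Ensemble:
    """Read a multi-frame XYZ file into an :class:`Ensemble`.

    Each frame is ``natoms`` / comment / ``natoms`` coordinate lines; an
    energy is parsed from the comment line when present (see
    :func:`parse_comment_energy`).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    structures: list[Structure] = []
    pos, frame = 0, 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError:
            raise ParseError(
                f"{path.name}, frame {frame}: expected an atom count, got {lines[pos]!r}"
            ) from None
        if natoms < 1:
            raise ParseError(f"{path.name}, frame {frame}: atom count must be >= 1")
        if pos + 1 >= len(lines):
            raise ParseError(f"{path.name}, frame {frame}: truncated frame")
        comment = lines[pos + 1]
        elements, coords = [], []
        for k in range(natoms):
            idx = pos + 2 + k
            if idx >= len(lines):
                raise ParseError(f"{path.name}, frame {frame}: truncated frame")
            parts = lines[idx].split()
            if len(parts) < 4:
                raise ParseError(
                    f"{path.name}, frame {frame}, atom {k}: malformed line {lines[idx]!r}"
                )
            try:
                xyz = [float(p) for p in parts[1:4]]
            except ValueError:
                raise ParseError(
                    f"{path.name}, frame {frame}, atom {k}: non-numeric coordinate "
                    f"in {lines[idx]!r}"
                ) from None
            elements.append(parts[0])
            coords.append(xyz)
        energy = parse_comment_energy(comment, energy_unit)
        label = comment.strip() or f"frame_{frame}"
        structures.append(Structure(elements, np.array(coords), energy, label))
        pos += 2 + natoms
        frame += 1
    if not structures:
        raise ParseError(f"{path.name}: no frames found")
    return Ensemble(structures, name=name or path.stem)


def write_xyz_ensemble(e: Ensemble, path) -> None:
    """Write an ensemble as multi-frame XYZ; inverse of :func:`read_xyz_ensemble`.

    Comment lines carry the structure label and, when present, an
    ``Energy= X`` tag in kcal/mol so that round-tripping preserves energies.
    """
    path = Path(path)
    out: list[str] = []
    for s in e:
        comment = s.label or ""
        if s.energy is not None:
            comment = (comment + f" Energy= {s.energy:.10f}").strip()
        out.append(str(s.n_atoms))
        out.append(comment)
        for el, (x, y, z) in zip(s.elements, s.coords):
            out.append(f"{el:<3s} {x:18.10f} {y:18.10f} {z:18.10f}")
    path.write_text("\n".join(out) + "\n")


def perceive_bonds(s: Structure, tolerance: float = 1.25) -> nx.Graph:
    """Perceive a molecular bond graph from interatomic distances.

    Atoms ``i`` and ``j`` are bonded iff
    ``d(i, j) <= tolerance * (r_cov(i) + r_cov(j))``.  Nodes are atom
    indices with an ``element`` attribute; edges are undirected bonds.
    """
    if tolerance <= 0:
        raise ContractError("tolerance must be positive")
    radii = np.array([COVALENT_RADII[el] for el in s.elements])
    g = nx.Graph()
    for i, el in enumerate(s.elements):
        g.add_node(i, element=el)
    diff = s.coords[:, None, :] - s.coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    cutoff = tolerance * (radii[:, None] + radii[None, :])
    ii, jj = np.where((dist <= cutoff) & (dist > 0))
    for i, j in zip(ii, jj):
        if i < j:
            g.add_edge(int(i), int(j))
    return g
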