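"""Synthetic conformer ensembles with planted family structure.

The generator builds ensembles of a small rigid-core rotor molecule:
families differ by a large torsion about the single rotatable bond, members
within a family differ by Gaussian coordinate jitter and a small energy
noise around the family offset, and a chosen fraction of members have their
symmetry-equivalent atom indices permuted by a bond-graph automorphism.
This plants a known partition so clustering and selectivity pipelines can
be validated without external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .dissimilarity import detect_torsions, dihedral_angle, enumerate_isomorphisms
from .ensemble_io import Ensemble, Structure, perceive_bonds
from .errors import ContractError

__all__ = ["Family", "PlantedSpec", "make_rotor_template", "set_torsion", "generate"]

#: Energy noise within a family, kcal/mol.
ENERGY_NOISE_SIGMA = 0.05


class Family(NamedTuple):
    angle: float  # target torsion in degrees
    offset: float  # family free-energy offset in kcal/mol
    count: int


@dataclass
class PlantedSpec:
    families: list[Family]
    jitter_sigma: float = 0.05
    permute_fraction: float = 0.0
    seed: int = 0
    name: str = "planted"

    def __post_init__(self) -> None:
        self.families = [Family(*f) for f in self.families]
        if not self.families:
            raise ContractError("at least one family is required")
        if any(f.count < 1 for f in self.families):
            raise ContractError("family member counts must be >= 1")
        if self.jitter_sigma < 0:
            raise ContractError("jitter_sigma must be >= 0")
        if not 0.0 <= self.permute_fraction <= 1.0:
            raise ContractError("permute_fraction must be in [0, 1]")

    @property
    def total(self) -> int:
        return sum(f.count for f in self.families)


def make_rotor_template() -> tuple[Structure, nx.Graph]:
    """Deterministic 5-heavy-atom rotor: carbonyl on a cyclopropane ring.

    Atoms: O0=C1-C2<(C3-C4 ring).  The C1-C2 bond is the single rotatable
    bond (one detected torsion, O0-C1-C2-C3) and the ring carbons C3/C4 are
    symmetry-equivalent, giving the bond graph two automorphisms.
    """
    elements = ["O", "C", "C", "C", "C"]
    coords = np.array(
        [
            [-2.11, 1.057, 0.0],  # O0, carbonyl oxygen on C1
            [-1.50, 0.000, 0.0],  # C1
            [0.00, 0.000, 0.0],  # C2, ring attachment
            [0.75, 1.0607, 0.75],  # C3, ring
            [0.75, 1.0607, -0.75],  # C4, ring (equivalent to C3)
        ]
    )
    s = Structure(elements, coords, label="rotor_template")
    return s, perceive_bonds(s)


def _side_atoms(g: nx.Graph, j: int, k: int) -> list[int]:
    """Atoms on the j side of bond j-k (j included, k side excluded)."""
    h = g.copy()
    h.remove_edge(j, k)
    return sorted(nx.node_connected_component(h, j))


def set_torsion(
    s: Structure, g: nx.Graph, quad: tuple[int, int, int, int], target: float
) -> Structure:
    """Return a copy of ``s`` with torsion i-j-k-l rotated to ``target`` degrees.

    The connected fragment on the j side of the j-k bond is rotated rigidly
    about the bond axis.
    """
    i, j, k, l = quad
    out = s.copy()
    current = dihedral_angle(out.coords, quad)
    axis = out.coords[k] - out.coords[j]
    axis = axis / np.linalg.norm(axis)
    movers = _side_atoms(g, j, k)

    def rotate(by_deg: float) -> None:
        rot = Rotation.from_rotvec(np.radians(by_deg) * axis)
        pivot = out.coords[j]
        out.coords[movers] = rot.apply(out.coords[movers] - pivot) + pivot

    delta = target - current
    rotate(delta)
    # Rotation sense depends on which side moves; correct empirically.
    got = dihedral_angle(out.coords, quad)
    err = (got - target + 180.0) % 360.0 - 180.0
    if abs(err) > 1e-6:
        rotate(-2.0 * delta)
    got = dihedral_angle(out.coords, quad)
    err = (got - target + 180.0) % 360.0 - 180.0
    if abs(err) > 1e-6:
        raise ContractError(f"failed to set torsion to {target} deg (got {got})")
    return out


def _angular_jitter_deg(template: Structure, quad: tuple[int, int, int, int], sigma: float) -> float:
    """Rough torsion-angle scatter (degrees) induced by coordinate jitter sigma."""
    i, j, k, _ = quad
    axis = template.coords[k] - template.coords[j]
    axis = axis / np.linalg.norm(axis)
    rel = template.coords[i] - template.coords[j]
    radius = np.linalg.norm(rel - (rel @ axis) * axis)
    if radius <= 0:
        return 180.0
    return float(np.degrees(sigma / radius))


def generate(spec: PlantedSpec) -> tuple[Ensemble, pd.DataFrame]:
    """Generate a planted ensemble and its ground truth.

    Returns the ensemble and a table with columns ``label``, ``family``,
    ``energy``, ``permuted``.  Fully reproducible from ``spec.seed``; exactly
    ``round(permute_fraction * total)`` members get a random non-identity
    automorphism applied to their atom indices.
    """
    rng = np.random.default_rng(spec.seed)
    template, graph = make_rotor_template()
    tset = detect_torsions(template, graph)
    quad = tset.torsions[0]

    jitter_deg = _angular_jitter_deg(template, quad, spec.jitter_sigma)
    angles = [f.angle for f in spec.families]
    for a in range(len(angles)):
        for b in range(a + 1, len(angles)):
            gap = abs(angles[a] - angles[b]) % 360.0
            gap = min(gap, 360.0 - gap)
            if gap < 5.0 * jitter_deg:
                warnings.warn(
                    f"family angles {angles[a]} and {angles[b]} deg are closer than "
                    f"5x the angular jitter ({jitter_deg:.2f} deg); planted structure "
                    "may be unrecoverable",
                    stacklevel=2,
                )

    autos = enumerate_isomorphisms(graph, graph)
    identity = {i: i for i in range(template.n_atoms)}
    nontrivial = [m for m in autos if m.as_dict() != identity]

    total = spec.total
    n_perm = int(round(spec.permute_fraction * total))
    permuted_idx = set(rng.choice(total, size=n_perm, replace=False).tolist()) if n_perm else set()

    structures: list[Structure] = []
    rows = []
    idx = 0
    for fam_id, fam in enumerate(spec.families):
        base = set_torsion(template, graph, quad, fam.angle)
        for _ in range(fam.count):
            coords = base.coords + rng.normal(0.0, spec.jitter_sigma, size=base.coords.shape)
            energy = fam.offset + rng.normal(0.0, ENERGY_NOISE_SIGMA)
            elements = list(base.elements)
            permuted = idx in permuted_idx and bool(nontrivial)
            if permuted:
                sigma = nontrivial[rng.integers(len(nontrivial))].as_dict()
                new_coords = np.empty_like(coords)
                for a_old, a_new in sigma.items():
                    new_coords[a_new] = coords[a_old]
                coords = new_coords
            label = f"{spec.name}_f{fam_id}_{idx}"
            structures.append(Structure(elements, coords, energy=energy, label=label))
            rows.append(
                {"label": label, "family": fam_id, "energy": energy, "permuted": permuted}
            )
            idx += 1
    ensemble = Ensemble(structures, name=spec.name)
    return ensemble, pd.DataFrame(rows)
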