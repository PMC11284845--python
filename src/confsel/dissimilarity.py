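"""Pairwise dissimilarity metrics and their fusion into a compound matrix.

Three per-pair metrics are supported:

* ``rmsd`` — heavy-atom RMSD after optimal rigid superposition (Kabsch,
  proper rotations only), minimized over all element-preserving graph
  isomorphisms so that permutations of symmetry-equivalent atoms do not
  inflate the distance;
* ``dihedral`` — mean circular distance between torsion-angle vectors over
  the rotatable bonds of the molecule;
* ``energy`` — absolute free-energy difference in kcal/mol.

Each requested component is min-max normalized to [0, 1] and the compound
matrix is their weighted mean.  The normalization is recorded in the result
metadata because raw Angstrom / degree / kcal-per-mol scales are not
commensurate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .ensemble_io import Ensemble, Structure, perceive_bonds
from .errors import ConfigurationError, ContractError, StructuralMismatchError

__all__ = [
    "AtomMap",
    "TorsionSet",
    "DissimilarityMatrix",
    "kabsch_rmsd",
    "enumerate_isomorphisms",
    "symmetry_rmsd",
    "detect_torsions",
    "dihedral_angle",
    "torsion_distance",
    "compound_matrix",
    "DEFAULT_ISOMORPHISM_CAP",
]

DEFAULT_ISOMORPHISM_CAP = 10_000

METRICS = ("rmsd", "dihedral", "energy")


@dataclass(frozen=True)
class AtomMap:
    """Element-preserving bijection between heavy-atom indices of two structures."""

    mapping: tuple[tuple[int, int], ...]

    @classmethod
    def from_dict(cls, d: dict[int, int]) -> "AtomMap":
        return cls(tuple(sorted(d.items())))

    def as_dict(self) -> dict[int, int]:
        return dict(self.mapping)

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass
class TorsionSet:
    """Canonical torsions of a molecule plus per-structure angle vectors.

    ``torsions`` holds ``(i, j, k, l)`` atom quadruples, one per rotatable
    bond ``j-k``; ``angles`` maps each structure (by ensemble position) to a
    vector of dihedral angles in degrees, each in (-180, 180].
    """

    torsions: list[tuple[int, int, int, int]]
    angles: np.ndarray | None = None  # shape (n_structures, n_torsions)

    def __len__(self) -> int:
        return len(self.torsions)


@dataclass
class DissimilarityMatrix:
    """Compound pairwise dissimilarity with its per-metric components."""

    values: np.ndarray
    metric_components: dict[str, np.ndarray]
    weights: dict[str, float]
    labels: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path, component: str | None = None) -> None:
        """Export the compound matrix (or one raw component) as square CSV."""
        import pandas as pd

        m = self.values if component is None else self.metric_components[component]
        labels = self.labels or [str(i) for i in range(self.n)]
        pd.DataFrame(m, index=labels, columns=labels).to_csv(path)


def _check_heavy_map(A: Structure, B: Structure, amap: AtomMap) -> None:
    heavy_a = set(A.heavy_indices())
    heavy_b = set(B.heavy_indices())
    d = amap.as_dict()
    if set(d) != heavy_a or set(d.values()) != heavy_b:
        raise ContractError("atom map must cover exactly the heavy atoms of both structures")
    for ia, ib in d.items():
        if A.elements[ia] != B.elements[ib]:
            raise ContractError(
                f"map sends {A.elements[ia]}{ia} to {B.elements[ib]}{ib}; "
                "element labels must be preserved"
            )


def kabsch_rmsd(A: Structure, B: Structure, amap: AtomMap) -> float:
    """Minimal heavy-atom RMSD of B onto A under the given atom map.

    Both point sets are translated to their centroids and the optimal proper
    rotation (determinant +1; mirror images are never superimposed) is found
    by SVD.  Returns the RMSD in Angstrom.
    """
    _check_heavy_map(A, B, amap)
    pairs = amap.mapping
    P = A.coords[[ia for ia, _ in pairs]]
    Q = B.coords[[ib for _, ib in pairs]]
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    H = Q.T @ P
    U, S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(U @ Vt))
    # Flip the smallest singular direction to stay a proper rotation.
    D = np.diag([1.0, 1.0, sign])
    R = U @ D @ Vt
    diff = Q @ R - P
    return float(np.sqrt((diff**2).sum() / len(pairs)))


def _heavy_subgraph(g: nx.Graph) -> nx.Graph:
    keep = [n for n, d in g.nodes(data=True) if d.get("element") != "H"]
    return g.subgraph(keep).copy()


def enumerate_isomorphisms(
    gA: nx.Graph, gB: nx.Graph, cap: int = DEFAULT_ISOMORPHISM_CAP
) -> list[AtomMap]:
    """All element-preserving isomorphisms between heavy-atom subgraphs.

    Enumeration order is deterministic (VF2 over sorted node sets).  At most
    ``cap`` maps are returned; an empty list means the graphs are not
    isomorphic.
    """
    if cap < 1:
        raise ContractError("cap must be >= 1")
    hA, hB = _heavy_subgraph(gA), _heavy_subgraph(gB)
    if hA.number_of_nodes() != hB.number_of_nodes():
        return []
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        hA, hB, node_match=lambda a, b: a["element"] == b["element"]
    )
    maps: list[AtomMap] = []
    for m in matcher.isomorphisms_iter():
        maps.append(AtomMap.from_dict(m))
        if len(maps) >= cap:
            break
    return maps


def _identity_like_map(A: Structure, B: Structure) -> AtomMap | None:
    """Positional heavy-atom map (i-th heavy atom of A to i-th of B), if legal."""
    ha, hb = A.heavy_indices(), B.heavy_indices()
    if len(ha) != len(hb):
        return None
    if any(A.elements[a] != B.elements[b] for a, b in zip(ha, hb)):
        return None
    return AtomMap(tuple(zip(ha, hb)))


def symmetry_rmsd(
    A: Structure,
    B: Structure,
    gA: nx.Graph | None = None,
    gB: nx.Graph | None = None,
    cap: int = DEFAULT_ISOMORPHISM_CAP,
    full_output: bool = False,
):
    """Heavy-atom RMSD minimized over graph isomorphisms (symmetry-corrected).

    Parameters
    ----------
    gA, gB
        Pre-perceived bond graphs; perceived from the structures when omitted.
    cap
        Maximum number of isomorphisms to consider.  When the cap truncates
        enumeration, the positional identity-like map is always included and
        the result is flagged as truncated.
    full_output
        When true, return ``(rmsd, best_map, truncated)``.

    Raises
    ------
    StructuralMismatchError
        When the heavy-atom graphs are not isomorphic.
    """
    gA = perceive_bonds(A) if gA is None else gA
    gB = perceive_bonds(B) if gB is None else gB
    maps = enumerate_isomorphisms(gA, gB, cap=cap)
    if not maps:
        raise StructuralMismatchError(
            f"structures {A.label!r} and {B.label!r} have non-isomorphic heavy-atom graphs"
        )
    truncated = len(maps) >= cap
    if truncated:
        warnings.warn(
            f"isomorphism enumeration truncated at cap={cap}; RMSD is an upper bound",
            stacklevel=2,
        )
        ident = _identity_like_map(A, B)
        if ident is not None and ident not in maps:
            maps.append(ident)
    best_r, best_m = np.inf, None
    for m in maps:
        r = kabsch_rmsd(A, B, m)
        if r < best_r:
            best_r, best_m = r, m
    if full_output:
        return best_r, best_m, truncated
    return best_r


def _ring_edges(g: nx.Graph) -> set[frozenset]:
    bridges = {frozenset(e) for e in nx.bridges(g)}
    return {frozenset(e) for e in g.edges} - bridges


def detect_torsions(s: Structure, g: nx.Graph) -> TorsionSet:
    """One canonical torsion per rotatable bond of the heavy-atom skeleton.

    A bond is rotatable when it is not in a ring and both atoms have at least
    two heavy neighbors.  Reference atoms ``i`` and ``l`` are the
    lowest-index heavy neighbors of ``j`` and ``k`` (excluding each other);
    quadruples are ordered with ``j < k``.
    """
    h = _heavy_subgraph(g)
    rings = _ring_edges(h)
    torsions: list[tuple[int, int, int, int]] = []
    for j, k in sorted(tuple(sorted(e)) for e in h.edges):
        if frozenset((j, k)) in rings:
            continue
        nj = sorted(n for n in h.neighbors(j) if n != k)
        nk = sorted(n for n in h.neighbors(k) if n != j)
        if not nj or not nk:
            continue  # terminal bond
        torsions.append((nj[0], j, k, nk[0]))
    return TorsionSet(torsions=torsions)


def dihedral_angle(coords: np.ndarray, quad: tuple[int, int, int, int]) -> float:
    """Signed dihedral angle i-j-k-l in degrees, in (-180, 180]."""
    p = coords[list(quad)]
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = n1 @ n2
    y = m @ n2
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def torsion_angles(s: Structure, tset: TorsionSet) -> np.ndarray:
    """Angle vector of one structure over a torsion set."""
    return np.array([dihedral_angle(s.coords, q) for q in tset.torsions])


def torsion_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Mean circular distance between two angle vectors, in degrees [0, 180]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ContractError(f"angle vectors differ in length: {a.shape} vs {b.shape}")
    if a.size == 0:
        return 0.0
    d = np.abs(a - b) % 360.0
    return float(np.minimum(d, 360.0 - d).mean())


def _min_max_normalize(m: np.ndarray) -> np.ndarray:
    lo, hi = m.min(), m.max()
    if hi - lo < 1e-300:
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


def compound_matrix(
    e: Ensemble,
    metrics: tuple[str, ...] = METRICS,
    weights: dict[str, float] | None = None,
    isomorphism_cap: int = DEFAULT_ISOMORPHISM_CAP,
) -> DissimilarityMatrix:
    """Fuse per-metric pairwise dissimilarities into one compound matrix.

    Each requested component is min-max normalized to [0, 1] (constant
    components map to all-zero) and the compound values are the
    weight-normalized mean of the components.  The ``energy`` metric requires
    every structure to carry an energy.

    Torsions are detected once on the first structure's bond graph and the
    same atom quadruples are evaluated on every frame, so the dihedral
    component assumes consistent atom indexing across frames.
    """
    metrics = tuple(metrics)
    if not metrics:
        raise ConfigurationError("at least one metric is required")
    for m in metrics:
        if m not in METRICS:
            raise ConfigurationError(f"unknown metric {m!r}; choose from {METRICS}")
    if weights is None:
        weights = {m: 1.0 for m in metrics}
    if any(w < 0 for w in weights.values()):
        raise ConfigurationError("metric weights must be nonnegative")
    wtot = sum(weights.get(m, 0.0) for m in metrics)
    if wtot <= 0:
        raise ConfigurationError("metric weights must not all be zero")

    n = len(e)
    components: dict[str, np.ndarray] = {}
    metadata: dict = {"normalization": "min-max per component", "truncated_pairs": []}

    if "rmsd" in metrics:
        graphs = [perceive_bonds(s) for s in e]
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                r, _, trunc = symmetry_rmsd(
                    e[i], e[j], graphs[i], graphs[j], cap=isomorphism_cap, full_output=True
                )
                mat[i, j] = mat[j, i] = r
                if trunc:
                    metadata["truncated_pairs"].append((i, j))
        components["rmsd"] = mat

    if "dihedral" in metrics:
        g0 = perceive_bonds(e[0])
        tset = detect_torsions(e[0], g0)
        angles = np.array([torsion_angles(s, tset) for s in e]).reshape(n, len(tset))
        tset.angles = angles
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                mat[i, j] = mat[j, i] = torsion_distance(angles[i], angles[j])
        components["dihedral"] = mat
        metadata["n_torsions"] = len(tset)

    if "energy" in metrics:
        if not e.has_energies():
            raise ConfigurationError(
                "energy metric requested but some structures carry no energy; "
                "drop the metric or supply energies"
            )
        en = np.array([s.energy for s in e], dtype=float)
        components["energy"] = np.abs(en[:, None] - en[None, :])

    used = {m: weights.get(m, 0.0) / wtot for m in metrics}
    values = np.zeros((n, n))
    for m in metrics:
        values += used[m] * _min_max_normalize(components[m])

    return DissimilarityMatrix(
        values=values,
        metric_components=components,
        weights=used,
        labels=[s.label for s in e],
        metadata=metadata,
    )
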