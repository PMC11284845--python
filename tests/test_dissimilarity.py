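import numpy as np
import pytest
from conftest import (
    brute_force_isomorphisms,
    brute_force_min_rmsd,
    exhaustive_permutation_rmsd,
    random_rigid_motion,
)

from confsel.dissimilarity import (
    AtomMap,
    compound_matrix,
    detect_torsions,
    dihedral_angle,
    enumerate_isomorphisms,
    kabsch_rmsd,
    symmetry_rmsd,
    torsion_distance,
)
from confsel.ensemble_io import Ensemble, Structure, perceive_bonds
from confsel.errors import ConfigurationError, ContractError, StructuralMismatchError
from confsel.synthetic_ensembles import PlantedSpec, generate


def identity_map(s):
    h = s.heavy_indices()
    return AtomMap(tuple(zip(h, h)))


def chain(elements, spacing=1.5):
    coords = [[i * spacing, 0.0, 0.0] for i in range(len(elements))]
    return Structure(elements, coords)


def ring(n, element="C", radius=None):
    # radius chosen so edge length ~1.4 A
    radius = radius or 1.4 / (2 * np.sin(np.pi / n))
    ang = 2 * np.pi * np.arange(n) / n
    coords = np.stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(n)], axis=1)
    return Structure([element] * n, coords)


class TestKabsch:
    def test_identity(self):
        s = chain(["C", "N", "O"])
        assert kabsch_rmsd(s, s, identity_map(s)) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_invariance(self, rng):
        s = chain(["C", "N", "O", "C"])
        s2 = Structure(s.elements, random_rigid_motion(s.coords, rng))
        assert kabsch_rmsd(s, s2, identity_map(s)) == pytest.approx(0.0, abs=1e-6)

    def test_against_rotation_search_oracle(self, rng):
        # toy 3-atom structures, one atom displaced
        A = Structure(["C", "C", "C"], [[0, 0, 0], [1.5, 0, 0], [0, 1.5, 0]])
        B = Structure(["C", "C", "C"], [[0, 0, 0], [1.5, 0, 0], [0.4, 1.8, 0.3]])
        got = kabsch_rmsd(A, B, identity_map(A))
        oracle = brute_force_min_rmsd(A.coords, B.coords)
        assert got == pytest.approx(oracle, abs=1e-5)

    @pytest.mark.parametrize("seed", range(3))
    def test_oracle_random_structures(self, seed):
        rng = np.random.default_rng(seed)
        A = Structure(["C"] * 5, rng.normal(size=(5, 3)))
        B = Structure(["C"] * 5, rng.normal(size=(5, 3)))
        got = kabsch_rmsd(A, B, identity_map(A))
        oracle = brute_force_min_rmsd(A.coords, B.coords, seed=seed)
        assert got == pytest.approx(oracle, abs=1e-5)

    def test_no_improper_rotation(self):
        # mirror image: proper-rotation RMSD must stay > 0
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(4, 3))
        A = Structure(["C"] * 4, coords)
        B = Structure(["C"] * 4, coords * np.array([1.0, 1.0, -1.0]))
        r = kabsch_rmsd(A, B, identity_map(A))
        oracle = brute_force_min_rmsd(A.coords, B.coords)
        assert r == pytest.approx(oracle, abs=1e-5)
        assert r > 0.1

    def test_element_mismatch_raises(self):
        A = chain(["C", "N"])
        B = chain(["N", "C"])
        with pytest.raises(ContractError):
            kabsch_rmsd(A, B, identity_map(A))

    def test_hydrogens_excluded(self):
        A = Structure(["C", "C", "H"], [[0, 0, 0], [1.5, 0, 0], [2.0, 1.0, 0]])
        B = Structure(["C", "C", "H"], [[0, 0, 0], [1.5, 0, 0], [9.9, 9.9, 9.9]])
        assert kabsch_rmsd(A, B, identity_map(A)) == pytest.approx(0.0, abs=1e-12)


class TestIsomorphisms:
    def test_benzene_ring_automorphisms(self):
        s = ring(6)
        g = perceive_bonds(s)
        maps = enumerate_isomorphisms(g, g)
        adj = {frozenset(e) for e in g.edges}
        oracle = brute_force_isomorphisms(s.elements, adj, s.elements, adj)
        assert len(oracle) == 12  # 6 rotations x 2 reflections
        assert {m.mapping for m in maps} == {tuple(sorted(o.items())) for o in oracle}

    def test_linear_cco(self):
        s = chain(["C", "C", "O"], spacing=1.4)
        g = perceive_bonds(s)
        maps = enumerate_isomorphisms(g, g)
        adj = {frozenset(e) for e in g.edges}
        oracle = brute_force_isomorphisms(s.elements, adj, s.elements, adj)
        assert len(maps) == len(oracle) == 1

    def test_ring_vs_path_empty(self):
        r = ring(3, radius=0.9)
        p = chain(["C", "C", "C"])
        assert enumerate_isomorphisms(perceive_bonds(r), perceive_bonds(p)) == []

    def test_cap_truncates(self):
        s = ring(6)
        g = perceive_bonds(s)
        assert len(enumerate_isomorphisms(g, g, cap=5)) == 5

    def test_cap_contract(self):
        g = perceive_bonds(chain(["C", "C"]))
        with pytest.raises(ContractError):
            enumerate_isomorphisms(g, g, cap=0)

    def test_maps_element_preserving(self):
        s = chain(["C", "O", "C", "O"], spacing=1.4)
        g = perceive_bonds(s)
        for m in enumerate_isomorphisms(g, g):
            for a, b in m.mapping:
                assert s.elements[a] == s.elements[b]


class TestSymmetryRmsd:
    def test_identical(self, rotor_template):
        s, g = rotor_template
        assert symmetry_rmsd(s, s, g, g) == pytest.approx(0.0, abs=1e-10)

    def test_swapped_equivalent_atoms(self, rotor_template):
        s, g = rotor_template
        coords = s.coords.copy()
        coords[[3, 4]] = coords[[4, 3]]  # swap the symmetry-equivalent ring atoms
        s2 = Structure(list(s.elements), coords)
        naive = kabsch_rmsd(s, s2, identity_map(s))
        assert naive > 0.1
        assert symmetry_rmsd(s, s2, g, perceive_bonds(s2)) == pytest.approx(0.0, abs=1e-8)

    def test_leq_identity_map(self, rotor_template, rng):
        s, g = rotor_template
        s2 = Structure(list(s.elements), s.coords + rng.normal(0, 0.1, s.coords.shape))
        sym = symmetry_rmsd(s, s2, g, perceive_bonds(s2))
        assert sym <= kabsch_rmsd(s, s2, identity_map(s)) + 1e-12

    def test_symmetric_in_arguments(self, rotor_template, rng):
        s, g = rotor_template
        s2 = Structure(list(s.elements), s.coords + rng.normal(0, 0.08, s.coords.shape))
        g2 = perceive_bonds(s2)
        assert symmetry_rmsd(s, s2, g, g2) == pytest.approx(
            symmetry_rmsd(s2, s, g2, g), abs=1e-8
        )

    def test_invariant_under_automorphism_relabeling(self, rotor_template, rng):
        s, g = rotor_template
        s2 = Structure(list(s.elements), s.coords + rng.normal(0, 0.05, s.coords.shape))
        base = symmetry_rmsd(s, s2, g, perceive_bonds(s2))
        for auto in enumerate_isomorphisms(g, g):
            perm = auto.as_dict()
            coords = np.empty_like(s2.coords)
            for old, new in perm.items():
                coords[new] = s2.coords[old]
            s3 = Structure(list(s2.elements), coords)
            assert symmetry_rmsd(s, s3, g, perceive_bonds(s3)) == pytest.approx(base, abs=1e-8)

    def test_matches_exhaustive_oracle_small(self):
        # <= 6 heavy atoms: symmetry RMSD equals the exhaustive-permutation min
        spec = PlantedSpec([(0.0, 0.0, 2), (150.0, 1.0, 2)], jitter_sigma=0.03,
                           permute_fraction=0.5, seed=3)
        e, _ = generate(spec)
        for i in range(len(e)):
            for j in range(i + 1, len(e)):
                got = symmetry_rmsd(e[i], e[j])
                oracle = exhaustive_permutation_rmsd(e[i], e[j])
                assert got == pytest.approx(oracle, abs=1e-8)

    def test_non_isomorphic_raises(self):
        r = ring(3, radius=0.9)
        p = chain(["C", "C", "C"])
        with pytest.raises(StructuralMismatchError):
            symmetry_rmsd(r, p)

    def test_truncation_flag_and_identity_fallback(self):
        s = ring(6)
        g = perceive_bonds(s)
        with pytest.warns(UserWarning, match="truncated"):
            r, best, truncated = symmetry_rmsd(s, s, g, g, cap=2, full_output=True)
        assert truncated
        assert r == pytest.approx(0.0, abs=1e-10)


class TestTorsions:
    def test_butane_one_torsion(self):
        # heavy-atom zig-zag chain of 4 carbons
        coords = [[0, 0, 0], [1.4, 0.6, 0], [2.8, 0, 0], [4.2, 0.6, 0]]
        s = Structure(["C"] * 4, coords)
        ts = detect_torsions(s, perceive_bonds(s))
        assert ts.torsions == [(0, 1, 2, 3)]

    def test_ethane_no_torsion(self):
        s = chain(["C", "C"])
        assert detect_torsions(s, perceive_bonds(s)).torsions == []

    def test_cyclohexane_no_torsion(self):
        s = ring(6)
        assert detect_torsions(s, perceive_bonds(s)).torsions == []

    def test_hydrogen_neighbors_ignored(self):
        # H on the chain ends must not make terminal C-C bonds rotatable
        coords = [[0, 0, 0], [1.5, 0, 0], [-0.6, 0.9, 0], [2.1, 0.9, 0]]
        s = Structure(["C", "C", "H", "H"], coords)
        assert detect_torsions(s, perceive_bonds(s)).torsions == []

    def test_dihedral_angle_right_angle(self):
        coords = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 0, 1]], dtype=float)
        assert abs(dihedral_angle(coords, (0, 1, 2, 3))) == pytest.approx(90.0)

    def test_dihedral_trans(self):
        coords = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]], dtype=float)
        assert dihedral_angle(coords, (0, 1, 2, 3)) == pytest.approx(180.0)


class TestTorsionDistance:
    def test_zero_for_equal(self):
        a = np.array([10.0, -170.0])
        assert torsion_distance(a, a) == 0.0

    def test_wraparound(self):
        assert torsion_distance([10.0], [350.0]) == pytest.approx(20.0)

    def test_mean_of_two(self):
        assert torsion_distance([0.0, 90.0], [180.0, 90.0]) == pytest.approx(90.0)

    def test_range(self, rng):
        a = rng.uniform(-180, 180, size=8)
        b = rng.uniform(-180, 180, size=8)
        assert 0.0 <= torsion_distance(a, b) <= 180.0

    def test_length_mismatch(self):
        with pytest.raises(ContractError):
            torsion_distance([0.0], [0.0, 1.0])


class TestCompoundMatrix:
    @pytest.fixture
    def planted(self):
        e, _ = generate(PlantedSpec([(0.0, 0.0, 3), (180.0, 2.0, 3)],
                                    jitter_sigma=0.02, seed=11))
        return e

    def test_single_metric_equals_component(self, planted):
        D = compound_matrix(planted, metrics=("rmsd",))
        comp = D.metric_components["rmsd"]
        lo, hi = comp.min(), comp.max()
        assert np.allclose(D.values, (comp - lo) / (hi - lo))

    def test_identical_structures_zero(self):
        s = Structure(["C", "C"], [[0, 0, 0], [1.5, 0, 0]], energy=1.0)
        e = Ensemble([s.copy() for _ in range(4)])
        D = compound_matrix(e, metrics=("rmsd", "energy"))
        assert np.allclose(D.values, 0.0)

    def test_weighted_average_oracle(self):
        # 3 structures with handcrafted rmsd (geometry) and energy components
        coords = [np.array([[0, 0, 0], [1.5, 0, 0]]),
                  np.array([[0, 0, 0], [1.5, 0.3, 0]]),
                  np.array([[0, 0, 0], [1.5, 0, 0.7]])]
        energies = [0.0, 1.0, 3.0]
        e = Ensemble([Structure(["C", "C"], c, energy=g) for c, g in zip(coords, energies)])
        w = {"rmsd": 2.0, "energy": 1.0}
        D = compound_matrix(e, metrics=("rmsd", "energy"), weights=w)

        def norm(m):
            lo, hi = m.min(), m.max()
            return (m - lo) / (hi - lo) if hi > lo else np.zeros_like(m)

        expected = (2 / 3) * norm(D.metric_components["rmsd"]) + (1 / 3) * norm(
            D.metric_components["energy"]
        )
        assert np.allclose(D.values, expected)

    def test_symmetric_zero_diagonal_nonnegative(self, planted):
        D = compound_matrix(planted)
        assert np.allclose(D.values, D.values.T)
        assert np.allclose(np.diag(D.values), 0.0)
        assert (D.values >= 0).all()
        for comp in D.metric_components.values():
            assert np.allclose(comp, comp.T)
            assert np.allclose(np.diag(comp), 0.0)
            assert (comp >= 0).all()

    def test_values_in_unit_interval(self, planted):
        D = compound_matrix(planted)
        assert D.values.max() <= 1.0 + 1e-12

    def test_energy_metric_requires_energies(self):
        s = Structure(["C", "C"], [[0, 0, 0], [1.5, 0, 0]])
        e = Ensemble([s.copy(), s.copy()])
        with pytest.raises(ConfigurationError):
            compound_matrix(e, metrics=("energy",))

    def test_bad_weights(self, planted):
        with pytest.raises(ConfigurationError):
            compound_matrix(planted, metrics=("rmsd",), weights={"rmsd": 0.0})
        with pytest.raises(ConfigurationError):
            compound_matrix(planted, metrics=("rmsd",), weights={"rmsd": -1.0})

    def test_unknown_metric(self, planted):
        with pytest.raises(ConfigurationError):
            compound_matrix(planted, metrics=("usr",))

    def test_csv_export(self, planted, tmp_path):
        import pandas as pd

        D = compound_matrix(planted, metrics=("rmsd", "energy"))
        D.to_csv(tmp_path / "m.csv")
        D.to_csv(tmp_path / "m_rmsd.csv", component="rmsd")
        m = pd.read_csv(tmp_path / "m.csv", index_col=0)
        assert np.allclose(m.values, D.values)
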