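import itertools

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from confsel.dissimilarity import AtomMap, kabsch_rmsd
from confsel.ensemble_io import Structure
from confsel.synthetic_ensembles import make_rotor_template


@pytest.fixture
def rotor_template():
    return make_rotor_template()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rigid_motion(coords, rng):
    """Apply a random proper rotation plus translation."""
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    t = rng.uniform(-5, 5, size=3)
    return coords @ R.as_matrix().T + t


def brute_force_min_rmsd(P, Q, restarts=24, seed=0):
    """Independent oracle: minimize RMSD over proper rotations numerically.

    P and Q are centered point sets; returns min over rotations of
    ||Q R - P|| / sqrt(N) found by multi-start optimization over rotation
    vectors.
    """
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    n = len(P)

    def cost(rv):
        R = Rotation.from_rotvec(rv).as_matrix()
        return np.sqrt(((Q @ R.T - P) ** 2).sum() / n)

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(restarts):
        rv0 = rng.uniform(-np.pi, np.pi, size=3)
        res = minimize(cost, rv0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        best = min(best, res.fun)
    return best


def brute_force_isomorphisms(elements_a, adj_a, elements_b, adj_b):
    """Oracle: all element-preserving permutations mapping graph A onto graph B.

    adjacency given as sets of frozenset pairs over node indices 0..n-1.
    """
    n = len(elements_a)
    if n != len(elements_b):
        return []
    found = []
    for perm in itertools.permutations(range(n)):
        if any(elements_a[i] != elements_b[perm[i]] for i in range(n)):
            continue
        mapped = {frozenset((perm[i], perm[j])) for i, j in (tuple(e) for e in adj_a)}
        if mapped == adj_b:
            found.append({i: perm[i] for i in range(n)})
    return found


def exhaustive_permutation_rmsd(A: Structure, B: Structure):
    """Oracle: min Kabsch RMSD over ALL element-preserving heavy-atom bijections."""
    ha, hb = A.heavy_indices(), B.heavy_indices()
    assert sorted(A.elements[i] for i in ha) == sorted(B.elements[i] for i in hb)
    best = np.inf
    for perm in itertools.permutations(hb):
        if any(A.elements[a] != B.elements[b] for a, b in zip(ha, perm)):
            continue
        r = kabsch_rmsd(A, B, AtomMap(tuple(zip(ha, perm))))
        best = min(best, r)
    return best
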