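"""Shared fixtures: small synthetic node sets and standard configurations."""

import itertools

import numpy as np
import pytest

from snapindex.geometry import NodeSet
from snapindex.lattice import IndexingConfig, LatticeBasis
from snapindex.search import SearchVolume


def lattice_nodes(basis: LatticeBasis, hkl: np.ndarray) -> NodeSet:
    """Exact reciprocal-lattice nodes of a basis for given integer triples."""
    q = np.asarray(hkl, dtype=float) @ basis.reciprocal_rows
    return NodeSet(q)


def hkl_ball(radius: int) -> np.ndarray:
    """All nonzero integer triples with components in [-radius, radius]."""
    grid = np.array(
        list(itertools.product(range(-radius, radius + 1), repeat=3)), dtype=int
    )
    return grid[np.any(grid != 0, axis=1)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cubic_basis():
    return LatticeBasis.from_parameters(40.0, 40.0, 40.0, 90.0, 90.0, 90.0)


@pytest.fixture
def cubic_nodes(cubic_basis, rng):
    """25 exact nodes of a randomly oriented 40 A cubic lattice (full 3D)."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=rng).as_matrix()
    basis = LatticeBasis(cubic_basis.matrix @ rot.T)
    hkl = hkl_ball(2)
    pick = rng.choice(len(hkl), size=25, replace=False)
    return basis, lattice_nodes(basis, hkl[pick])


@pytest.fixture
def bench_volume():
    """Unknown-cell search shell sized for protein-scale test cells."""
    return SearchVolume(mode="unknown_cell", r_min=20.0, r_max=100.0)


@pytest.fixture
def bench_config(bench_volume):
    return IndexingConfig(volume=bench_volume)


def random_reduced_lattice(rng) -> LatticeBasis:
    """Random moderately conditioned lattice whose shortest vectors have
    small coefficients in the generating basis (so a boxed brute-force
    successive-minima search is a valid oracle)."""
    while True:
        lengths = np.sort(rng.uniform(20.0, 60.0, 3))
        if lengths[2] / lengths[0] > 2.5:
            continue
        angles = rng.uniform(75.0, 105.0, 3)
        try:
            b0 = LatticeBasis.from_parameters(*lengths, *angles)
        except ValueError:
            continue
        u = np.eye(3)
        for _ in range(3):
            i, j = rng.choice(3, 2, replace=False)
            e = np.eye(3)
            e[i, j] = rng.choice([-1.0, 1.0])
            u = u @ e
        return LatticeBasis(u @ b0.matrix)


def brute_force_minima(matrix: np.ndarray, box: int = 4) -> np.ndarray:
    """Successive minima of a 3D lattice by enumeration over a coefficient box."""
    coeffs = np.array(
        [
            c
            for c in itertools.product(range(-box, box + 1), repeat=3)
            if c != (0, 0, 0)
        ]
    )
    vecs = coeffs @ matrix
    norms = np.linalg.norm(vecs, axis=1)
    order = np.argsort(norms)
    chosen: list[np.ndarray] = []
    for i in order:
        v = vecs[i]
        if len(chosen) == 0:
            chosen.append(v)
        elif len(chosen) == 1:
            if np.linalg.norm(np.cross(chosen[0], v)) > 1e-8 * norms[i] * np.linalg.norm(
                chosen[0]
            ):
                chosen.append(v)
        else:
            if abs(np.linalg.det(np.array([*chosen, v]))) > 1e-8 * norms[i] * np.prod(
                [np.linalg.norm(x) for x in chosen]
            ):
                chosen.append(v)
                break
    return np.sort(np.linalg.norm(np.array(chosen), axis=1))
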