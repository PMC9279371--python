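"""Shared fixtures: kernel parameters, toy chains, reduced point sets.

Expensive objects (rotation sets, simulated maps, mean-shift reductions)
are session-scoped so the suite builds each of them once.
"""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mcbuild.fitting import generate_rotations
from mcbuild.fixtures import make_helix, make_random_walk
from mcbuild.grid import resolution_params
from mcbuild.probfield import reduce_map_to_points, simulate_probability_map
from mcbuild.structure import ChainModel, Residue


@pytest.fixture(scope="session")
def rp4():
    return resolution_params(4.0)


@pytest.fixture(scope="session")
def rp6():
    return resolution_params(6.0)


@pytest.fixture(scope="session")
def rots30():
    """Reduced 30-degree rotation set used by the heavier fitting tests."""
    return generate_rotations(30.0)


@pytest.fixture(scope="session")
def helix40():
    return make_helix(40)


@pytest.fixture(scope="session")
def walk40():
    return make_random_walk(40, seed=7)


@pytest.fixture(scope="session")
def helix40_selfmap(helix40, rp6):
    """Probability map simulated from the in-place helix."""
    return simulate_probability_map([helix40], rp6, spacing=1.0)


@pytest.fixture(scope="session")
def helix40_points(helix40_selfmap, rp6):
    return reduce_map_to_points(helix40_selfmap, rp6)


def tiny_chain(coords, chain_id="A", start=1):
    """Chain of CA-only residues at the given coordinates."""
    coords = np.atleast_2d(np.asarray(coords, float))
    residues = [Residue(start + i, "A", {"CA": coords[i].copy()})
                for i in range(len(coords))]
    return ChainModel(chain_id, residues)


def rmsd(a, b):
    a, b = np.asarray(a), np.asarray(b)
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def random_rotation(seed):
    return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()


def brute_force_best_clique(graph):
    """Exhaustive-subset clique oracle using the production tie-break key
    (total weight, then more vertices, then lexicographic)."""
    import itertools

    nodes = list(graph.nodes)
    best = None
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            if all(graph.has_edge(u, v)
                   for u, v in itertools.combinations(subset, 2)):
                total = sum(graph.nodes[v]["weight"] for v in subset)
                key = (total, -len(subset), tuple(sorted(subset)))
                if best is None or key < best:
                    best = key
    return [] if best is None else list(best[2])
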