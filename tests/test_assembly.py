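"""Clash scores, compatibility graph, clique selection, iterative assembly."""

import itertools

import numpy as np
import pytest

from mcbuild.assembly import (AssemblyConfig, AssemblyGraph, ClashParams,
                              atom_clash, build_assembly_graph, chain_clash,
                              iterative_assemble, max_weight_clique,
                              update_point_probabilities)
from mcbuild.domains import MultiDomainPose
from mcbuild.errors import AssemblyError
from mcbuild.fitting import Pose, generate_rotations
from mcbuild.fixtures import FixtureSpec, make_complex_fixture, \
    make_random_walk
from mcbuild.probfield import MainChainPointSet, reduce_map_to_points
from mcbuild.structure import ChainModel

import networkx as nx

from conftest import rmsd


@pytest.fixture
def cp4(rp4):
    return ClashParams(lam=rp4.lam)


@pytest.fixture
def cp6(rp6):
    return ClashParams(lam=rp6.lam)


def half_life_offset(lam):
    """Distance beyond d_clash at which the clash decays to 0.5."""
    return float(np.sqrt(np.log(2.0) / lam))


class TestAtomClash:
    def test_saturates_at_cutoff(self, cp4):
        B = np.array([[cp4.d_clash, 0.0, 0.0]])
        assert atom_clash(np.zeros(3), B, cp4) == 1.0
        inside = np.array([[0.5, 0.0, 0.0]])
        assert atom_clash(np.zeros(3), inside, cp4) == 1.0

    def test_half_decay_offset(self, rp4, cp4):
        off = half_life_offset(rp4.lam)
        assert off == pytest.approx(1.484, abs=2e-3)
        B = np.array([[cp4.d_clash + off, 0.0, 0.0]])
        assert atom_clash(np.zeros(3), B, cp4) == pytest.approx(0.5,
                                                                rel=1e-12)

    def test_far_atom_scores_zero(self, cp4):
        B = np.array([[200.0, 0.0, 0.0]])
        assert atom_clash(np.zeros(3), B, cp4) < 1e-12
        assert atom_clash(np.zeros(3), np.empty((0, 3)), cp4) == 0.0


class TestChainClash:
    def test_identical_chains_fully_clash(self, cp6):
        A = np.random.default_rng(0).normal(size=(10, 3)) * 5
        assert chain_clash(A, A.copy(), cp6) == 1.0

    def test_distant_chains_no_clash(self, cp6):
        A = np.zeros((5, 3))
        B = np.full((5, 3), 300.0)
        assert chain_clash(A, B, cp6) == 0.0

    def test_half_in_half_out_averages(self, cp6):
        B = np.zeros((4, 3))
        A = np.vstack([np.zeros((3, 3)), np.full((3, 3), 300.0)])
        assert chain_clash(A, B, cp6) == pytest.approx(0.5)

    def test_asymmetry(self, cp6):
        A = np.zeros((1, 3))
        B = np.vstack([np.zeros((1, 3)), np.full((9, 3), 300.0)])
        assert chain_clash(A, B, cp6) == 1.0
        assert chain_clash(B, A, cp6) == pytest.approx(0.1)


def fake_fits(coords_by_copy, scores_by_copy):
    """fits dict as produced by the assembly loop: copy -> [(model, coords)]."""
    fits = {}
    for cid, (coords_list, scores) in enumerate(zip(coords_by_copy,
                                                    scores_by_copy)):
        entries = []
        for coords, score in zip(coords_list, scores):
            pose = Pose(np.eye(3), np.zeros(3), score)
            model = MultiDomainPose({1: pose}, score, None, pose)
            entries.append((model, np.atleast_2d(np.asarray(coords, float))))
        fits[cid] = entries
    return fits


def blob(center, n=6, spread=2.0, seed=0):
    rng = np.random.default_rng(seed)
    return np.asarray(center, float) + rng.normal(size=(n, 3)) * spread


class TestAssemblyGraph:
    def test_two_nonclashing_copies_connected(self, cp6):
        fits = fake_fits([[blob([0, 0, 0])], [blob([40, 0, 0])]],
                         [[-5.0], [-4.0]])
        g = build_assembly_graph(fits, cp6)
        assert g.graph.number_of_nodes() == 2
        assert g.graph.number_of_edges() == 1

    def test_same_copy_poses_never_connected(self, cp6):
        fits = fake_fits([[blob([0, 0, 0]), blob([40, 0, 0])]],
                         [[-5.0, -4.0]])
        g = build_assembly_graph(fits, cp6)
        assert g.graph.number_of_edges() == 0

    def test_overlapping_poses_not_connected(self, cp6):
        fits = fake_fits([[blob([0, 0, 0])], [blob([0.5, 0, 0])]],
                         [[-5.0], [-4.0]])
        g = build_assembly_graph(fits, cp6)
        assert g.graph.number_of_edges() == 0


from conftest import brute_force_best_clique  # noqa: E402


class TestMaxWeightClique:
    def test_triangle_selects_all_three(self, cp6):
        fits = fake_fits(
            [[blob([0, 0, 0])], [blob([40, 0, 0])], [blob([80, 0, 0])]],
            [[-5.0], [-4.0], [-3.0]])
        g = build_assembly_graph(fits, cp6)
        clique = max_weight_clique(g)
        assert sorted(clique) == [(0, 0), (1, 0), (2, 0)]
        total = sum(g.graph.nodes[v]["weight"] for v in clique)
        assert total == -12.0

    def test_compatible_pair_beats_stronger_single(self, cp6):
        """A -9 pose of copy 1 clashes with everything; the compatible
        (-5, -5) pair wins on total score."""
        fits = fake_fits(
            [[blob([0, 0, 0]), blob([50, 0, 0])], [blob([0.4, 0, 0])]],
            [[-9.0, -5.0], [-5.0]])
        g = build_assembly_graph(fits, cp6)
        clique = max_weight_clique(g)
        assert sorted(clique) == [(0, 1), (1, 0)]

    def test_matches_exhaustive_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for trial in range(12):
            n = int(rng.integers(4, 16))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1 << 30)))
            graph = nx.Graph()
            for v in g.nodes:
                graph.add_node((v, 0), weight=float(-rng.uniform(1, 10)))
            for u, v in g.edges:
                graph.add_edge((u, 0), (v, 0))
            ag = AssemblyGraph(graph, {})
            assert sorted(max_weight_clique(ag)) == \
                sorted(brute_force_best_clique(graph))

    def test_empty_graph_gives_empty_clique(self):
        assert max_weight_clique(AssemblyGraph(nx.Graph(), {})) == []


class TestUpdateProbabilities:
    def test_fully_clashed_point_zeroed(self, cp6):
        Z = MainChainPointSet(np.zeros((1, 3)), np.array([0.7]))
        out = update_point_probabilities(Z, np.zeros((3, 3)), cp6)
        assert out.prob[0] == 0.0

    def test_distant_point_unchanged(self, cp6):
        Z = MainChainPointSet(np.array([[500.0, 0, 0]]), np.array([0.7]))
        out = update_point_probabilities(Z, np.zeros((3, 3)), cp6)
        assert out.prob[0] == pytest.approx(0.7)

    def test_partial_clash_scales_probability(self, rp6, cp6):
        d = cp6.d_clash + half_life_offset(rp6.lam)
        Z = MainChainPointSet(np.array([[d, 0.0, 0.0]]), np.array([0.8]))
        out = update_point_probabilities(Z, np.zeros((1, 3)), cp6)
        assert out.prob[0] == pytest.approx(0.4, rel=1e-12)


class TestIterativeAssemble:
    def test_single_chain_reduces_to_fit_and_commit(self, rp6, rots30, cp6):
        chain = make_random_walk(30, seed=19)
        from mcbuild.probfield import simulate_probability_map
        g = simulate_probability_map([chain], rp6, spacing=1.0)
        Z = reduce_map_to_points(g, rp6)
        cfg = AssemblyConfig(rp=rp6, rots=rots30, clash=cp6, keep_poses=5,
                             graph_poses=3, refine_domains=False)
        state = iterative_assemble([chain], Z, cfg)
        assert state.n_cycles == 1
        assert len(state.placed) == 1 and not state.remaining
        assert rmsd(state.placed[0].chain.ca_coords(), chain.ca_coords()) < 1.0

    def test_empty_input_rejected(self, rp6, rots30, cp6):
        Z = MainChainPointSet(np.zeros((1, 3)), np.ones(1))
        cfg = AssemblyConfig(rp=rp6, rots=rots30, clash=cp6)
        with pytest.raises(AssemblyError):
            iterative_assemble([], Z, cfg)

    def test_placed_pairs_respect_clash_threshold(self, rp6, rots30, cp6):
        spec = FixtureSpec(seed=4, chain_lengths=(30, 30),
                           fold_types=("walk", "walk"))
        fx = make_complex_fixture(spec)
        Z = reduce_map_to_points(fx.prob_map, rp6)
        cfg = AssemblyConfig(rp=rp6, rots=rots30, clash=cp6, keep_poses=5,
                             graph_poses=3, refine_domains=False)
        state = iterative_assemble(fx.input_chains, Z, cfg)
        assert len(state.placed) == 2
        A = state.placed[0].chain.main_chain_coords()
        B = state.placed[1].chain.main_chain_coords()
        assert max(chain_clash(A, B, cp6), chain_clash(B, A, cp6)) <= cp6.c_thr
        # probabilities only ever decrease
        for a, b in zip(state.prob_history, state.prob_history[1:]):
            assert (b <= a + 1e-12).all()
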