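"""Clash-aware assembly of fitted chains by maximum-weight clique search.

Candidate poses of all chain copies become vertices of a compatibility
graph; two candidates are connected when neither direction of the pairwise
chain clash score exceeds the threshold (poses of the same copy are never
connected).  The best mutually compatible combination — the maximal clique
with the most negative total match score — is selected by Bron-Kerbosch
enumeration.  Copies that cannot be placed in one round are fitted again
against points whose probabilities were down-weighted around the partial
complex:

    P'(z; D) = P(z) * (1 - c(z; D))

so occupied regions stop attracting further chains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .domains import MultiDomainPose, apply_multidomain, enumerate_refined_models
from .errors import AssemblyError
from .fitting import Pose, RotationSet, exhaustive_fit, simplex_refine
from .grid import ResolutionParams
from .probfield import MainChainPointSet
from .structure import ChainModel

__all__ = [
    "ClashParams", "AssemblyGraph", "AssemblyState", "AssemblyConfig",
    "atom_clash", "chain_clash", "build_assembly_graph", "max_weight_clique",
    "update_point_probabilities", "iterative_assemble",
]


@dataclass(frozen=True)
class ClashParams:
    """Steric-overlap scoring constants.

    ``d_clash`` is the hard cutoff within which the clash score saturates at
    1.0; beyond it the score decays as exp(-lam (d - d_clash)^2) with the
    map's kernel constant.
    """

    lam: float
    d_clash: float = 3.0
    c_thr: float = 0.1

    def __post_init__(self) -> None:
        if self.d_clash <= 0:
            raise ValueError("d_clash must be positive")
        if not (0 < self.c_thr < 1):
            raise ValueError("clash threshold must be in (0, 1)")


def atom_clash(a: np.ndarray, B: np.ndarray, cp: ClashParams) -> float:
    """Clash of one atom against all atoms of another chain.

    c(a; B) = max_b exp(-lam (max(||a-b|| - d_clash, 0))^2); exactly 1.0
    whenever the nearest atom of B is within d_clash.  Empty B gives 0.
    """
    B = np.atleast_2d(B) if B is not None and len(B) else None
    if B is None:
        return 0.0
    d = float(np.min(np.linalg.norm(B - np.asarray(a, float), axis=1)))
    return float(np.exp(-cp.lam * max(d - cp.d_clash, 0.0) ** 2))


def _clash_vector(A: np.ndarray, B: np.ndarray, cp: ClashParams,
                  tree_B: Optional[cKDTree] = None) -> np.ndarray:
    """Per-atom clash scores of all atoms of A against B (vectorized; the
    nearest neighbor maximizes the decaying kernel)."""
    if B is None or len(B) == 0:
        return np.zeros(len(A))
    if tree_B is None:
        tree_B = cKDTree(np.atleast_2d(B))
    d, _ = tree_B.query(np.atleast_2d(A))
    return np.exp(-cp.lam * np.maximum(d - cp.d_clash, 0.0) ** 2)


def chain_clash(A: np.ndarray, B: np.ndarray, cp: ClashParams) -> float:
    """Directed chain clash C(A; B): mean atom clash of A's atoms against B.

    Asymmetric in general; the undirected edge test uses the max of both
    directions.
    """
    A = np.atleast_2d(A)
    if len(A) == 0:
        raise AssemblyError("chain A has no atoms for clash scoring")
    return float(_clash_vector(A, B, cp).mean())


@dataclass
class _Candidate:
    copy_id: int
    pose_idx: int
    model: MultiDomainPose
    coords: np.ndarray            # placed main-chain coordinates

    @property
    def key(self) -> tuple[int, int]:
        return (self.copy_id, self.pose_idx)


@dataclass
class AssemblyGraph:
    graph: nx.Graph               # nodes: (copy_id, pose_idx), weight=score
    candidates: dict              # key -> _Candidate


def build_assembly_graph(fits: dict, cp: ClashParams) -> AssemblyGraph:
    """Compatibility graph over candidate placements.

    ``fits`` maps copy id -> list of (MultiDomainPose, placed main-chain
    coords).  Vertices carry the pose match score; edges connect candidates
    of *different* copies whose mutual clash max(C(A;B), C(B;A)) stays at or
    below the threshold.
    """
    g = nx.Graph()
    cands: dict = {}
    for copy_id, models in fits.items():
        for pose_idx, (model, coords) in enumerate(models):
            c = _Candidate(copy_id, pose_idx, model, coords)
            cands[c.key] = c
            g.add_node(c.key, weight=float(model.score))
    keys = list(cands)
    trees = {k: cKDTree(cands[k].coords) for k in keys}
    for i, ki in enumerate(keys):
        for kj in keys[i + 1:]:
            if ki[0] == kj[0]:
                continue            # poses of the same chain copy
            ci, cj = cands[ki], cands[kj]
            cij = float(_clash_vector(ci.coords, cj.coords, cp,
                                      trees[kj]).mean())
            cji = float(_clash_vector(cj.coords, ci.coords, cp,
                                      trees[ki]).mean())
            if max(cij, cji) <= cp.c_thr:
                g.add_edge(ki, kj)
    return AssemblyGraph(g, cands)


def max_weight_clique(g: AssemblyGraph) -> list[tuple[int, int]]:
    """Best mutually compatible candidate combination.

    Maximal cliques are enumerated with Bron-Kerbosch (networkx
    ``find_cliques``, pivoting variant); the clique minimizing the summed
    (negative-better) match score wins.  Ties prefer more chains placed,
    then the lexicographically smallest vertex set.
    """
    if g.graph.number_of_nodes() == 0:
        return []
    best: Optional[tuple] = None
    for clique in nx.find_cliques(g.graph):
        total = sum(g.graph.nodes[v]["weight"] for v in clique)
        key = (total, -len(clique), tuple(sorted(clique)))
        if best is None or key < best:
            best = key
    return list(best[2])


def update_point_probabilities(Z: MainChainPointSet, D: np.ndarray,
                               cp: ClashParams) -> MainChainPointSet:
    """Down-weight points occupied by the partial complex D (atom coords)."""
    if D is None or len(D) == 0:
        raise AssemblyError("cannot update probabilities against an empty complex")
    c = _clash_vector(Z.points, np.atleast_2d(D), cp)
    return MainChainPointSet(Z.points.copy(), Z.prob * (1.0 - c))


@dataclass
class AssemblyConfig:
    rp: ResolutionParams
    rots: RotationSet
    clash: ClashParams
    keep_poses: int = 10          # M rigid poses kept per chain
    graph_poses: int = 10         # K candidates per copy entering the graph
    top_per_rotation: int = 3
    refine_domains: bool = True
    max_cycles: int = 10
    min_point_prob: float = 1e-12  # drop fully suppressed points from fitting


@dataclass
class PlacedChain:
    copy_id: int
    chain: ChainModel             # placed coordinates
    model: MultiDomainPose
    cycle: int


@dataclass
class AssemblyState:
    placed: list
    remaining: list               # copy ids never placed
    points: MainChainPointSet     # final updated point probabilities
    prob_history: list            # per-cycle P arrays (before each cycle)
    n_cycles: int

    def placed_chains(self) -> list[ChainModel]:
        return [p.chain for p in self.placed]

    def report(self) -> dict:
        return {
            "n_cycles": self.n_cycles,
            "placed": [{"copy_id": p.copy_id,
                        "chain_id": p.chain.chain_id,
                        "cycle": p.cycle,
                        "score": float(p.model.score),
                        "seed_domain": p.model.seed_domain}
                       for p in self.placed],
            "unplaced_copy_ids": list(self.remaining),
        }


def _fit_candidates(chain: ChainModel, Z: MainChainPointSet,
                    cfg: AssemblyConfig) -> list[MultiDomainPose]:
    poses = exhaustive_fit(chain, Z, cfg.rots, cfg.rp,
                           keep=cfg.keep_poses,
                           top_per_rotation=cfg.top_per_rotation)
    poses = [simplex_refine(p, chain, Z, cfg.rp) for p in poses]
    poses.sort(key=lambda p: p.score)
    if cfg.refine_domains and len(chain.domains) > 1:
        return enumerate_refined_models(poses, chain, Z, cfg.rp)
    rigid = []
    for p in poses:
        transforms = {d.id: Pose(p.rotation.copy(), p.translation.copy())
                      for d in chain.domains}
        rigid.append(MultiDomainPose(transforms, p.score, None, p))
    return rigid


def iterative_assemble(chains: Sequence[ChainModel],
                       Z0: MainChainPointSet,
                       cfg: AssemblyConfig) -> AssemblyState:
    """Fit -> clique -> commit cycles until every chain copy is placed.

    Identical chain copies (same sequence and geometry) share one fitting
    run per cycle.  Already-placed chains leave the vertex set but still
    clash-screen new candidates; after each commit the point probabilities
    are updated, so later cycles fit into the unoccupied map regions only.
    """
    if not chains:
        raise AssemblyError("no chain copies to assemble")
    remaining = {i: c for i, c in enumerate(chains)}
    placed: list[PlacedChain] = []
    Z = MainChainPointSet(Z0.points.copy(), Z0.prob.copy())
    prob_history = [Z.prob.copy()]
    cycle = 0
    while remaining and cycle < cfg.max_cycles:
        cycle += 1
        live = Z.prob > cfg.min_point_prob
        if not live.any():
            break
        Z_live = MainChainPointSet(Z.points[live], Z.prob[live])
        # one fitting run per group of identical copies
        by_fp: dict = {}
        for cid, chain in remaining.items():
            by_fp.setdefault(chain.fingerprint(), []).append(cid)
        fits: dict = {}
        for fp, cids in by_fp.items():
            chain = remaining[cids[0]]
            models = _fit_candidates(chain, Z_live, cfg)[:cfg.graph_poses]
            entries = []
            for m in models:
                coords = apply_multidomain(chain, m).main_chain_coords()
                entries.append((m, coords))
            for cid in cids:
                fits[cid] = entries
        # placed chains as fixed clash context (pairwise rule per chain)
        if placed:
            ctx = [(p.chain.main_chain_coords(),) for p in placed]
            ctx = [(c[0], cKDTree(c[0])) for c in ctx]
            for cid in list(fits):
                ok = []
                for m, coords in fits[cid]:
                    tree_new = cKDTree(coords)
                    compatible = all(
                        max(float(_clash_vector(coords, c_coords, cfg.clash,
                                                c_tree).mean()),
                            float(_clash_vector(c_coords, coords, cfg.clash,
                                                tree_new).mean()))
                        <= cfg.clash.c_thr
                        for c_coords, c_tree in ctx)
                    if compatible:
                        ok.append((m, coords))
                fits[cid] = ok
        fits = {cid: models for cid, models in fits.items() if models}
        if not fits:
            break
        graph = build_assembly_graph(fits, cfg.clash)
        clique = max_weight_clique(graph)
        if not clique:
            break
        for key in clique:
            cand = graph.candidates[key]
            chain = remaining.pop(cand.copy_id)
            placed_chain = apply_multidomain(chain, cand.model)
            placed.append(PlacedChain(cand.copy_id, placed_chain,
                                      cand.model, cycle))
        complex_coords = np.vstack([p.chain.main_chain_coords()
                                    for p in placed])
        Z = update_point_probabilities(Z, complex_coords, cfg.clash)
        prob_history.append(Z.prob.copy())
    if not placed:
        raise AssemblyError("assembly placed no chains in the first cycle")
    return AssemblyState(placed, sorted(remaining), Z, prob_history, cycle)
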