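"""Semi-flexible domain refinement of a rigidly fitted chain.

A fitted chain is split into its structural domains; domains sharing
covalently connecting residues are linked in an undirected domain graph.
Starting from a seed domain, domains are visited in breadth-first order and
each is rigidly re-optimized (simplex over its own 6 parameters, all other
domains frozen) against the main-chain points.  Running the procedure from
every seed domain and pooling with the rigid parents gives the
M*n + M candidate models per chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .errors import DomainError
from .fitting import Pose, match_score, simplex_refine
from .grid import ResolutionParams
from .probfield import MainChainPointSet
from .structure import ChainModel

__all__ = [
    "DomainGraph", "MultiDomainPose",
    "build_domain_graph", "bfs_order", "refine_domains",
    "enumerate_refined_models", "apply_multidomain",
]


@dataclass
class DomainGraph:
    graph: nx.Graph

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[int, int]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)


@dataclass
class MultiDomainPose:
    """Per-domain rigid transforms derived from one rigid parent pose."""

    transforms: dict                   # domain id -> Pose (absolute, y = Rx+t)
    score: float                       # aggregate continuous match score
    seed_domain: Optional[int]         # None for a purely rigid model
    parent: Pose

    @property
    def refined(self) -> bool:
        return self.seed_domain is not None

    def junction_distances(self, chain: ChainModel) -> dict:
        """C(i)-N(i+1) distances across domain boundaries (chain-break
        report; refinement imposes no covalent restraint)."""
        out = {}
        placed = apply_multidomain(chain, self)
        for a, b in zip(placed.residues, placed.residues[1:]):
            da = chain.domain_of(a.index).id
            db = chain.domain_of(b.index).id
            if da != db and "C" in a.atoms and "N" in b.atoms:
                out[(a.index, b.index)] = float(
                    np.linalg.norm(a.atoms["C"] - b.atoms["N"]))
        return out

    def to_dict(self) -> dict:
        return {"seed_domain": self.seed_domain, "score": float(self.score),
                "parent": self.parent.to_dict(),
                "transforms": {str(k): v.to_dict()
                               for k, v in self.transforms.items()}}


def build_domain_graph(c: ChainModel) -> DomainGraph:
    """Domains sharing sequence-adjacent residues become graph neighbors."""
    if not c.domains:
        raise DomainError(f"chain {c.chain_id} has no domain assignment")
    g = nx.Graph()
    g.add_nodes_from(d.id for d in c.domains)
    for r1, r2 in zip(c.residues, c.residues[1:]):
        d1 = c.domain_of(r1.index).id
        d2 = c.domain_of(r2.index).id
        if d1 != d2:
            g.add_edge(d1, d2)
    return DomainGraph(g)


def bfs_order(g: DomainGraph, seed: int) -> list[int]:
    """Breadth-first visit order from the seed; same-depth ties broken by
    ascending domain id.  Disconnected components are appended in id order
    (each restarted from its smallest id)."""
    if seed not in g.graph:
        raise DomainError(f"seed domain {seed} not in domain graph")
    order: list[int] = []
    visited: set[int] = set()
    pending = [seed]
    while True:
        queue = list(pending)
        pending = []
        while queue:
            node = queue.pop(0)
            if node in visited:
                continue
            visited.add(node)
            order.append(node)
            queue.extend(sorted(n for n in g.graph.neighbors(node)
                                if n not in visited))
        rest = sorted(set(g.graph.nodes) - visited)
        if not rest:
            return order
        pending = [rest[0]]


def apply_multidomain(chain: ChainModel, mdp: MultiDomainPose) -> ChainModel:
    """Place the chain with per-domain rigid transforms (side chains move
    rigidly with their residue's domain)."""
    out = chain.copy()
    for res in out.residues:
        pose = mdp.transforms[chain.domain_of(res.index).id]
        for name, p in res.atoms.items():
            res.atoms[name] = pose.rotation @ p + pose.translation
    return out


def _aggregate_score(chain: ChainModel, mdp_transforms: dict,
                     Z: MainChainPointSet, rp: ResolutionParams,
                     tree: cKDTree) -> float:
    total = 0.0
    for dom in chain.domains:
        coords = chain.domain_main_chain_coords(dom.id)
        if len(coords) == 0:
            continue
        pose = mdp_transforms[dom.id]
        total += match_score(pose.apply(coords), Z, rp, tree=tree)
    return total


def refine_domains(p: Pose, c: ChainModel, Z: MainChainPointSet,
                   rp: ResolutionParams, seed: int,
                   **simplex_kwargs) -> MultiDomainPose:
    """One BFS pass of per-domain simplex optimization from a seed domain.

    Each domain is visited once and frozen afterwards; the per-domain
    simplex never worsens that domain's partial score, so the aggregate
    score is at most the rigid parent's.
    """
    graph = build_domain_graph(c)
    order = bfs_order(graph, seed)
    tree = cKDTree(Z.points)
    transforms = {d.id: Pose(p.rotation.copy(), p.translation.copy())
                  for d in c.domains}
    for dom_id in order:
        coords = c.domain_main_chain_coords(dom_id)
        if len(coords) == 0:
            continue
        refined = simplex_refine(transforms[dom_id], c, Z, rp,
                                 atom_subset=coords, **simplex_kwargs)
        transforms[dom_id] = refined
    score = _aggregate_score(c, transforms, Z, rp, tree)
    return MultiDomainPose(transforms, score, seed, p)


def enumerate_refined_models(poses: Sequence[Pose], c: ChainModel,
                             Z: MainChainPointSet, rp: ResolutionParams,
                             **simplex_kwargs) -> list[MultiDomainPose]:
    """All M*n refined models plus the M rigid parents, ranked by score.

    M rigid poses x n seed-domain choices, pooled with the rigid poses
    themselves (represented as uniform-transform models), sorted ascending
    by aggregate match score.
    """
    tree = cKDTree(Z.points)
    models: list[MultiDomainPose] = []
    for pose in poses:
        rigid_transforms = {d.id: Pose(pose.rotation.copy(),
                                       pose.translation.copy())
                            for d in c.domains}
        rigid_score = _aggregate_score(c, rigid_transforms, Z, rp, tree)
        models.append(MultiDomainPose(rigid_transforms, rigid_score, None,
                                      pose))
        for dom in c.domains:
            models.append(refine_domains(pose, c, Z, rp, dom.id,
                                         **simplex_kwargs))
    models.sort(key=lambda m: m.score)
    return models
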