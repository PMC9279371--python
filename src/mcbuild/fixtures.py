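"""Deterministic synthetic structures, complexes, and probability maps.

Everything downstream is testable at desk scale with these generators: ideal
alpha-helices and self-avoiding random-walk backbones (N, CA, C atoms),
multi-chain complexes with known ground-truth poses, optional per-domain
hinge perturbations emulating a predicted model that deviates from the
deposited structure, and probability maps simulated from the ground truth.
Fixtures default to R = 6.0 Å, the middle of the intermediate-resolution
regime the method targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .assembly import ClashParams, chain_clash
from .errors import McBuildError
from .grid import DensityGrid, resolution_params
from .probfield import simulate_probability_map
from .structure import ChainModel, Domain, Residue

__all__ = [
    "FixtureSpec", "make_helix", "make_random_walk", "make_complex_fixture",
    "rigid_transform",
]

HELIX_RISE = 1.5            # Å per residue
HELIX_TWIST = 100.0         # degrees per residue
HELIX_CA_RADIUS = 2.3       # Å

DEFAULT_RESOLUTION = 6.0
DEFAULT_SPACING = 1.0


def rigid_transform(rotvec_deg: Sequence[float] = (0, 0, 0),
                    translation: Sequence[float] = (0, 0, 0)
                    ) -> tuple[np.ndarray, np.ndarray]:
    """(R, t) from a rotation-vector in degrees and a translation in Å."""
    R = Rotation.from_rotvec(np.asarray(rotvec_deg, float),
                             degrees=True).as_matrix()
    return R, np.asarray(translation, float)


def _helix_backbone(n_res: int) -> list[dict]:
    """Backbone atoms of an ideal alpha-helix along +z.

    CA on a 2.3 Å radius helix with 1.5 Å rise and 100 deg twist per
    residue; N and C at fixed offsets in each residue's local frame so the
    three atoms trace the familiar tight backbone spiral.
    """
    atoms = []
    for i in range(n_res):
        theta = np.radians(HELIX_TWIST * i)
        z = HELIX_RISE * i
        ca = np.array([HELIX_CA_RADIUS * np.cos(theta),
                       HELIX_CA_RADIUS * np.sin(theta), z])
        th_n = theta - np.radians(28.0)
        th_c = theta + np.radians(28.0)
        n = np.array([1.6 * np.cos(th_n), 1.6 * np.sin(th_n), z - 0.9])
        c = np.array([1.7 * np.cos(th_c), 1.7 * np.sin(th_c), z + 0.9])
        atoms.append({"N": n, "CA": ca, "C": c})
    return atoms


def make_helix(n_res: int, chain_id: str = "A",
               start_index: int = 1) -> ChainModel:
    """Ideal alpha-helix chain (all residues labeled H). Deterministic."""
    if n_res < 4:
        raise McBuildError("a helix fixture needs at least 4 residues")
    residues = [Residue(start_index + i, "A", atoms, ss="H")
                for i, atoms in enumerate(_helix_backbone(n_res))]
    return ChainModel(chain_id, residues)


def make_random_walk(n_res: int, seed: int = 0, chain_id: str = "A",
                     start_index: int = 1,
                     min_separation: float = 4.0,
                     max_tries: int = 20000) -> ChainModel:
    """Self-avoiding random-walk backbone with 3.8 Å CA-CA virtual bonds.

    Non-consecutive CA pairs are kept at least ``min_separation`` apart by
    rejection; N and C are placed on the bonds to the previous/next CA.
    Deterministic for a given seed.
    """
    if n_res < 4:
        raise McBuildError("a random-walk fixture needs at least 4 residues")
    rng = np.random.default_rng(seed)
    ca = [np.zeros(3)]
    tries = 0
    while len(ca) < n_res:
        step = rng.normal(size=3)
        step *= 3.8 / np.linalg.norm(step)
        cand = ca[-1] + step
        prior = np.asarray(ca[:-1]) if len(ca) > 1 else None
        if prior is None or np.linalg.norm(prior - cand, axis=1).min() >= min_separation:
            ca.append(cand)
        tries += 1
        if tries > max_tries:
            raise McBuildError("random walk failed to satisfy excluded volume")
    ca = np.asarray(ca)
    residues = []
    for i in range(n_res):
        atoms = {"CA": ca[i].copy()}
        if i > 0:
            u = ca[i - 1] - ca[i]
            atoms["N"] = ca[i] + 1.45 * u / np.linalg.norm(u)
        else:
            atoms["N"] = ca[i] + np.array([-1.45, 0, 0])
        if i < n_res - 1:
            u = ca[i + 1] - ca[i]
            atoms["C"] = ca[i] + 1.52 * u / np.linalg.norm(u)
        else:
            atoms["C"] = ca[i] + np.array([1.52, 0, 0])
        residues.append(Residue(start_index + i, "G", atoms))
    return ChainModel(chain_id, residues)


@dataclass
class FixtureSpec:
    """Recipe for a synthetic complex with known ground truth.

    ``hinge_perturbations`` maps (chain position, domain id) to a rotation
    vector in degrees applied about the domain centroid of the *input*
    model, emulating a predicted structure whose domains deviate from the
    deposited conformation by rigid hinge motions.
    """

    seed: int = 0
    chain_lengths: tuple = (40, 40)
    fold_types: tuple = ("helix", "walk")
    fold_seeds: Optional[tuple] = None     # same seed twice = identical copies
    ground_truth_poses: Optional[list] = None   # list of (R, t)
    domain_splits: Optional[dict] = None        # chain position -> n domains
    hinge_perturbations: dict = field(default_factory=dict)
    resolution: float = DEFAULT_RESOLUTION
    spacing: float = DEFAULT_SPACING
    d_clash: float = 3.0
    max_ground_truth_clash: float = 0.01


@dataclass
class ComplexFixture:
    input_chains: list            # canonical-frame (possibly hinged) models
    ground_truth: list            # placed ChainModels
    prob_map: DensityGrid
    spec: FixtureSpec


def _default_poses(n: int, gap: float = 24.0) -> list:
    """Well-separated translations along x with varied orientations."""
    poses = []
    for i in range(n):
        rotvec = (0, 0, 0) if i == 0 else (30.0 * i, 45.0, 15.0 * i)
        poses.append(rigid_transform(rotvec, (gap * i, 0.0, 0.0)))
    return poses


def _split_domains(chain: ChainModel, n: int) -> ChainModel:
    out = chain.copy()
    bounds = np.linspace(0, len(out), n + 1).round().astype(int)
    out.domains = [
        Domain(i + 1, [(out.residues[bounds[i]].index,
                        out.residues[bounds[i + 1] - 1].index)])
        for i in range(n)
    ]
    return out


def make_complex_fixture(spec: FixtureSpec) -> ComplexFixture:
    """Build (input chains, ground-truth complex, probability map).

    The ground truth assembles the canonical chains at the ground-truth
    poses and must be clash-free; the probability map is simulated from it.
    Input chains are returned centered at the origin in canonical
    orientation, with any hinge perturbations applied — the pipeline under
    test never sees the ground-truth poses.
    """
    if len(spec.chain_lengths) != len(spec.fold_types):
        raise McBuildError("chain_lengths and fold_types differ in length")
    chains = []
    for i, (n, fold) in enumerate(zip(spec.chain_lengths, spec.fold_types)):
        cid = chr(ord("A") + i)
        fold_seed = (spec.fold_seeds[i] if spec.fold_seeds is not None
                     else spec.seed * 101 + i)
        if fold == "helix":
            chain = make_helix(n, chain_id=cid)
        elif fold == "walk":
            chain = make_random_walk(n, seed=fold_seed, chain_id=cid)
        else:
            raise McBuildError(f"unknown fold type {fold!r}")
        if spec.domain_splits and i in spec.domain_splits:
            chain = _split_domains(chain, spec.domain_splits[i])
        chains.append(chain)
    poses = (spec.ground_truth_poses if spec.ground_truth_poses is not None
             else _default_poses(len(chains)))
    ground_truth = [c.transformed(R, t) for c, (R, t) in zip(chains, poses)]
    rp = resolution_params(spec.resolution)
    cp = ClashParams(lam=rp.lam, d_clash=spec.d_clash)
    for i in range(len(ground_truth)):
        for j in range(i + 1, len(ground_truth)):
            cc = chain_clash(ground_truth[i].main_chain_coords(),
                             ground_truth[j].main_chain_coords(), cp)
            if cc > spec.max_ground_truth_clash:
                raise McBuildError(
                    f"ground-truth poses clash (chains {i}, {j}: C={cc:.3f})")
    prob_map = simulate_probability_map(ground_truth, rp,
                                        spacing=spec.spacing)
    inputs = []
    for i, chain in enumerate(chains):
        model = chain.copy()
        centroid = model.main_chain_coords().mean(axis=0)
        model = model.transformed(np.eye(3), -centroid)
        for (ci, dom_id), rotvec in spec.hinge_perturbations.items():
            if ci != i:
                continue
            dom_coords = model.domain_main_chain_coords(dom_id)
            dc = dom_coords.mean(axis=0)
            R = Rotation.from_rotvec(np.asarray(rotvec, float),
                                     degrees=True).as_matrix()
            dom = next(d for d in model.domains if d.id == dom_id)
            for res in model.residues:
                if dom.contains(res.index):
                    for name, p in res.atoms.items():
                        res.atoms[name] = R @ (p - dc) + dc
        inputs.append(model)
    return ComplexFixture(inputs, ground_truth, prob_map, spec)
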