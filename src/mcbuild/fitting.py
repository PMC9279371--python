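"""Exhaustive rigid-body fitting of a chain into main-chain points.

The search is two-stage.  A discretized rotation set covers orientation
space; for each rotation, all grid translations are scored at once by an
FFT correlation of two Gaussian-rasterized grids (the point set and the
rotated chain).  Grid scores are used only for candidate harvesting: every
candidate is re-scored with the continuous atom-level match score

    s'(y; Z) = -max_z  theta * P(z) * exp(-lam ||y - z||^2)
    S'(Y; Z) = sum over main-chain atoms of s'

(more negative = better) and the best poses are polished with a Nelder-Mead
simplex over the 6 rigid-body parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import FittingError
from .grid import DensityGrid, ResolutionParams
from .probfield import MainChainPointSet
from .structure import ChainModel

__all__ = [
    "RotationSet", "ScoreVolume", "Pose",
    "generate_rotations", "rasterize_points", "fft_translation_scores",
    "match_score", "exhaustive_fit", "simplex_refine",
]

FIT_GRID_SPACING = 1.5   # Å, translational search grid


@dataclass
class RotationSet:
    matrices: np.ndarray        # (K, 3, 3)
    angle_interval: float       # degrees

    def __len__(self) -> int:
        return len(self.matrices)


@dataclass
class ScoreVolume:
    """Match scores over all circular grid shifts for one rotation."""

    S: np.ndarray               # (nx, ny, nz), negative-better
    spacing: float
    rotation: Optional[np.ndarray] = None


@dataclass
class Pose:
    """Rigid placement y = R x + t with its continuous match score."""

    rotation: np.ndarray        # (3, 3)
    translation: np.ndarray     # (3,)
    score: float = 0.0
    refined: bool = False

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def to_dict(self) -> dict:
        q = Rotation.from_matrix(self.rotation).as_quat()
        return {"quaternion_xyzw": [float(v) for v in q],
                "translation": [float(v) for v in self.translation],
                "score": float(self.score), "refined": bool(self.refined)}

    @classmethod
    def from_dict(cls, d: dict) -> "Pose":
        R = Rotation.from_quat(d["quaternion_xyzw"]).as_matrix()
        return cls(R, np.asarray(d["translation"], float),
                   float(d["score"]), bool(d.get("refined", False)))

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.eye(3), np.zeros(3))


def generate_rotations(angle_interval: float = 15.0,
                       dedup_tol_deg: float = 0.5) -> RotationSet:
    """Discretize orientation space on a sin(beta)-weighted Euler lattice.

    gamma and beta use uniform grids of step ``angle_interval`` over
    [0, 360) and [0, 180); the number of alpha samples per beta ring scales
    with sin(beta) so the set is approximately uniform over SO(3).
    Equivalent rotations are removed by angular-distance dedup.  At the
    default 15 degrees the construction yields exactly 4392 orientations.
    """
    if not (0 < angle_interval <= 90):
        raise ValueError("angle interval must be in (0, 90] degrees")
    if abs(360.0 / angle_interval - round(360.0 / angle_interval)) > 1e-9:
        raise ValueError("angle interval must divide 360 degrees")
    n_full = int(round(360.0 / angle_interval))
    betas = np.arange(0.0, 180.0, angle_interval)
    gammas = np.arange(0.0, 360.0, angle_interval)
    eulers = []
    for beta in betas:
        n_alpha = max(1, int(round(n_full * np.sin(np.radians(beta)))))
        alphas = np.arange(n_alpha) * (360.0 / n_alpha)
        for alpha in alphas:
            for gamma in gammas:
                eulers.append((alpha, beta, gamma))
    rots = Rotation.from_euler("ZYZ", np.asarray(eulers), degrees=True)
    # angular-distance dedup on the quaternion double cover
    quats = rots.as_quat()
    quats *= np.where(quats[:, [3]] < 0, -1.0, 1.0)
    # |q1 . q2| close to 1 <=> small relative rotation angle
    cos_half = np.cos(np.radians(dedup_tol_deg) / 2.0)
    tree = cKDTree(np.vstack([quats, -quats]))
    keep = np.ones(len(quats), bool)
    # chord distance on the unit sphere corresponding to the angular tol
    chord = np.sqrt(max(0.0, 2.0 - 2.0 * cos_half))
    pairs = sorted({tuple(sorted((i % len(quats), j % len(quats))))
                    for i, j in tree.query_pairs(chord)})
    for a, b in pairs:
        if a != b and keep[a] and keep[b]:
            keep[b] = False
    matrices = rots.as_matrix()[keep]
    return RotationSet(matrices, angle_interval)


def rasterize_points(points: np.ndarray, weights: np.ndarray,
                     rp: ResolutionParams, spacing: float,
                     origin: np.ndarray, shape: tuple[int, int, int],
                     wrap: bool = False) -> DensityGrid:
    """Gaussian max-rasterization of weighted points onto a grid.

    Voxel value = max over points of w * exp(-lam d^2), truncated at the
    kernel truncation radius.  With ``wrap`` the kernel footprint wraps
    circularly (used for the FFT chain grid); otherwise points must fall
    inside the grid.
    """
    points = np.atleast_2d(points)
    weights = np.broadcast_to(np.atleast_1d(weights), (len(points),))
    origin = np.asarray(origin, float)
    values = np.zeros(shape)
    shape_arr = np.asarray(shape)
    r_vox = int(np.ceil(rp.truncation_radius / spacing))
    win = np.arange(-r_vox, r_vox + 1)
    if not wrap:
        frac = (points - origin) / spacing
        if (frac < -1e-6).any() or (frac > shape_arr - 1 + 1e-6).any():
            raise FittingError("points fall outside the rasterization grid")
    for pt, w in zip(points, weights):
        center = np.round((pt - origin) / spacing).astype(int)
        idx = [center[d] + win for d in range(3)]
        coords = [origin[d] + spacing * idx[d] for d in range(3)]
        d2 = ((coords[0][:, None, None] - pt[0]) ** 2
              + (coords[1][None, :, None] - pt[1]) ** 2
              + (coords[2][None, None, :] - pt[2]) ** 2)
        kern = w * np.exp(-rp.lam * d2)
        if wrap:
            ix, iy, iz = (np.mod(idx[d], shape[d]) for d in range(3))
            np.maximum.at(values, np.ix_(ix, iy, iz), kern)
        else:
            sel = [(idx[d] >= 0) & (idx[d] < shape[d]) for d in range(3)]
            sub = values[np.ix_(idx[0][sel[0]], idx[1][sel[1]],
                                idx[2][sel[2]])]
            np.maximum(sub, kern[np.ix_(sel[0], sel[1], sel[2])], out=sub)
            values[np.ix_(idx[0][sel[0]], idx[1][sel[1]],
                          idx[2][sel[2]])] = sub
    return DensityGrid(values, np.full(3, float(spacing)), origin)


def fft_translation_scores(A: DensityGrid, B: DensityGrid,
                           rp: ResolutionParams) -> ScoreVolume:
    """Scores S(i,j,k) = -theta sum_lmn A[l,m,n] B[l+i, m+j, n+k].

    All circular shifts are evaluated with one forward/inverse FFT pair;
    equal to the direct triple sum up to floating-point rounding.
    """
    if A.shape != B.shape:
        raise FittingError(f"grid shapes differ: {A.shape} vs {B.shape}")
    if not np.allclose(A.voxel_size, B.voxel_size):
        raise FittingError("grid spacings differ")
    corr = np.fft.irfftn(np.conj(np.fft.rfftn(A.values))
                         * np.fft.rfftn(B.values), s=A.shape,
                         axes=(0, 1, 2))
    return ScoreVolume(-rp.theta * corr, float(A.voxel_size[0]))


def match_score(coords: np.ndarray, Z: MainChainPointSet,
                rp: ResolutionParams,
                tree: Optional[cKDTree] = None,
                per_atom: bool = False):
    """Continuous match score of posed atoms against the point set.

    Per atom: -max_z theta P(z) exp(-lam d^2); atoms beyond the truncation
    radius of every point score 0.  Returns the summed pose score, or the
    per-atom vector with ``per_atom``.
    """
    if len(Z) == 0:
        raise FittingError("empty main-chain point set")
    coords = np.atleast_2d(coords)
    if tree is None:
        tree = cKDTree(Z.points)
    neigh = tree.query_ball_point(coords, rp.truncation_radius)
    scores = np.zeros(len(coords))
    for q, nb in enumerate(neigh):
        if not nb:
            continue
        d2 = ((Z.points[nb] - coords[q]) ** 2).sum(axis=1)
        scores[q] = -rp.theta * np.max(Z.prob[nb] * np.exp(-rp.lam * d2))
    return scores if per_atom else float(scores.sum())


def _search_grid_geometry(Z: MainChainPointSet, chain_radius: float,
                          spacing: float) -> tuple[np.ndarray, tuple]:
    """Zero-padded box: point-set extent plus chain radius on every side."""
    pad = chain_radius + 2.0 * spacing
    lo = Z.points.min(axis=0) - pad
    hi = Z.points.max(axis=0) + pad
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / spacing)) + 1
                  for d in range(3))
    return lo, shape


def exhaustive_fit(chain: ChainModel, Z: MainChainPointSet,
                   rots: RotationSet, rp: ResolutionParams,
                   keep: int = 10, spacing: float = FIT_GRID_SPACING,
                   top_per_rotation: int = 3) -> list[Pose]:
    """FFT translational search over all rotations, continuous re-ranking.

    For every rotation the chain (centered at its centroid) is rasterized
    and scored against the point-set grid for all translations at once; the
    ``top_per_rotation`` best translations per rotation are pooled and
    re-scored with the continuous match score.  Returns the ``keep`` best
    poses sorted ascending (most negative first).
    """
    if keep < 1:
        raise ValueError("keep must be >= 1")
    atoms = chain.main_chain_coords()
    centroid = atoms.mean(axis=0)
    centered = atoms - centroid
    radius = float(np.linalg.norm(centered, axis=1).max())
    origin, shape = _search_grid_geometry(Z, radius, spacing)
    A = rasterize_points(Z.points, Z.prob, rp, spacing, origin, shape)
    A_hat = np.conj(np.fft.rfftn(A.values))
    tree = cKDTree(Z.points)
    shape_arr = np.asarray(shape)
    candidates: list[Pose] = []
    for R in rots.matrices:
        rotated = centered @ R.T
        B = rasterize_points(rotated, 1.0, rp, spacing,
                             np.zeros(3), shape, wrap=True)
        corr = np.fft.irfftn(A_hat * np.fft.rfftn(B.values), s=shape,
                             axes=(0, 1, 2))
        S = -rp.theta * corr
        flat = np.argpartition(S.ravel(), min(top_per_rotation,
                                              S.size - 1))[:top_per_rotation]
        for f in flat:
            ijk = np.array(np.unravel_index(f, shape))
            u = origin + spacing * np.mod(-ijk, shape_arr)
            t = u - R @ centroid
            pose = Pose(R.copy(), t)
            pose.score = match_score(pose.apply(atoms), Z, rp, tree=tree)
            candidates.append(pose)
    candidates.sort(key=lambda p: p.score)
    return candidates[:keep]


def _compose_increment(pose_coords_center: np.ndarray, base: Pose,
                       params: np.ndarray) -> Pose:
    """Pose obtained by rotating the posed chain by a small rotation about
    its current centroid plus a translation increment."""
    R_inc = Rotation.from_rotvec(params[:3]).as_matrix()
    c = pose_coords_center
    # y' = R_inc (y - c) + c + dt  with  y = R x + t
    R_new = R_inc @ base.rotation
    t_new = R_inc @ (base.translation - c) + c + params[3:]
    return Pose(R_new, t_new)


def simplex_refine(pose: Pose, chain: ChainModel, Z: MainChainPointSet,
                   rp: ResolutionParams,
                   step_trans: float = 2.0, step_rot_deg: float = 5.0,
                   max_evals: int = 500, fatol: float = 1e-4,
                   atom_subset: Optional[np.ndarray] = None) -> Pose:
    """Nelder-Mead polish of a pose over 6 rigid-body parameters.

    Rotation increments act about the posed chain's centroid.  The refined
    pose never scores worse than the input: if the search fails or ends
    above the starting score, the input pose is returned (rescored).
    """
    atoms = chain.main_chain_coords() if atom_subset is None else atom_subset
    tree = cKDTree(Z.points)
    center = pose.apply(atoms).mean(axis=0)

    def objective(params: np.ndarray) -> float:
        cand = _compose_increment(center, pose, params)
        val = match_score(cand.apply(atoms), Z, rp, tree=tree)
        return val if np.isfinite(val) else 0.0

    x0 = np.zeros(6)
    start_score = objective(x0)
    steps = np.array([np.radians(step_rot_deg)] * 3 + [step_trans] * 3)
    simplex = np.vstack([x0, x0 + np.diag(steps)])
    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"initial_simplex": simplex, "maxfev": max_evals,
                            "fatol": fatol, "xatol": 1e-3})
    if np.isfinite(res.fun) and res.fun < start_score:
        out = _compose_increment(center, pose, res.x)
        out.score = float(res.fun)
    else:
        out = Pose(pose.rotation.copy(), pose.translation.copy(),
                   float(start_score))
    out.refined = True
    return out
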