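"""Main-chain probability fields and their reduction to weighted points.

A probability map assigns to each voxel the probability that a main-chain
atom (N, CA, C) lies nearby.  When simulated from coordinates it is the
max-of-Gaussians field

    p(x) = max_a exp(-lam ||x - a||^2),   a over all main-chain atoms,

with ``lam`` from the map resolution.  For fitting, the field is reduced to a
sparse set of *main-chain points*: seeds started at high-probability voxels
are mean-shifted to the local maxima of the kernel-smoothed field, then
merged by single linkage; each cluster is represented by its
highest-probability member.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, spline_filter
from scipy.spatial import cKDTree

from .errors import FittingError
from .grid import DensityGrid, ResolutionParams
from .structure import ChainModel

__all__ = [
    "MainChainPointSet", "MeanShiftState",
    "simulate_probability_map", "mean_shift", "cluster_to_points",
    "reduce_map_to_points",
]


@dataclass
class MainChainPointSet:
    """Reduced probability-weighted point representation of a map."""

    points: np.ndarray          # (L, 3) Å
    prob: np.ndarray            # (L,) weights P(z)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, float))
        self.prob = np.atleast_1d(np.asarray(self.prob, float))
        if len(self.points) != len(self.prob):
            raise ValueError("points and probabilities differ in length")
        if len(self.points) < 1:
            raise FittingError("empty main-chain point set")

    def __len__(self) -> int:
        return len(self.points)

    def to_table(self, path) -> None:
        np.savetxt(path, np.column_stack([self.points, self.prob]),
                   fmt="%.4f", header="x y z P")

    @classmethod
    def from_table(cls, path) -> "MainChainPointSet":
        data = np.atleast_2d(np.loadtxt(path))
        return cls(data[:, :3], data[:, 3])


@dataclass
class MeanShiftState:
    """Converged (or iteration-capped) mean-shift seeds."""

    seeds: np.ndarray           # (N', 3) current seed positions
    prob: np.ndarray            # (N',) P(z) of each seed
    converged: np.ndarray       # (N',) bool
    n_iter: int


def simulate_probability_map(chains: Sequence[ChainModel],
                             rp: ResolutionParams,
                             spacing: float = 1.0,
                             margin: float = 5.0) -> DensityGrid:
    """Simulate the main-chain probability map of a (placed) set of chains.

    The grid is padded so every atom sits at least ``margin`` Å from the
    edges; the field is the exact max-of-Gaussians over all main-chain atoms
    (value 1 exactly at atom positions).
    """
    atoms = [c.main_chain_coords() for c in chains]
    atoms = np.vstack([a for a in atoms if len(a)]) if atoms else np.empty((0, 3))
    if len(atoms) == 0:
        raise FittingError("no main-chain atoms to simulate a map from")
    lo = atoms.min(axis=0) - margin
    hi = atoms.max(axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    values = np.zeros(tuple(shape))
    # per-atom local windows; beyond r_cut the Gaussian is < 1e-12 and the
    # voxel keeps whatever larger value another atom contributes
    r_cut = np.sqrt(-np.log(1e-12) / rp.lam)
    r_vox = int(np.ceil(r_cut / spacing))
    win = np.arange(-r_vox, r_vox + 1)
    for atom in atoms:
        center = np.round((atom - lo) / spacing).astype(int)
        idx = [np.clip(center[d] + win, 0, shape[d] - 1) for d in range(3)]
        idx = [np.unique(ix) for ix in idx]
        coords = [lo[d] + spacing * idx[d] for d in range(3)]
        d2 = ((coords[0][:, None, None] - atom[0]) ** 2
              + (coords[1][None, :, None] - atom[1]) ** 2
              + (coords[2][None, None, :] - atom[2]) ** 2)
        sub = values[np.ix_(*idx)]
        np.maximum(sub, np.exp(-rp.lam * d2), out=sub)
        values[np.ix_(*idx)] = sub
    return DensityGrid(values, np.full(3, float(spacing)), lo)


class _KernelFields:
    """Kernel-weighted sums over grid points, as interpolated convolutions.

    For a seed position z the mean-shift update needs

        den(z) = sum_n K(z - x_n) p(x_n)
        num(z) = sum_n K(z - x_n) p(x_n) x_n

    which as functions of continuous z are Gaussian convolutions of p and
    p*x sampled on the grid; they are computed once with separable Gaussian
    filters and evaluated off-grid by cubic-spline interpolation.
    """

    def __init__(self, g: DensityGrid, lam: float, trunc_radius: float):
        h = g.spacing
        sigma_vox = np.sqrt(0.5 / lam) / h
        truncate = trunc_radius / (sigma_vox * h)
        # gaussian_filter normalizes each 1D kernel to sum 1; multiply the
        # discrete kernel sum back so den matches the raw sum_n K p
        k = np.arange(-int(np.ceil(truncate * sigma_vox)),
                      int(np.ceil(truncate * sigma_vox)) + 1)
        self.kernel_sum = float(np.exp(-lam * (h * k) ** 2).sum() ** 3)
        fields = [gaussian_filter(g.values, sigma_vox, truncate=truncate,
                                  mode="constant")]
        axes = g.axis_coordinates()
        for d in range(3):
            shape = [1, 1, 1]
            shape[d] = g.shape[d]
            coord = axes[d].reshape(shape)
            fields.append(gaussian_filter(g.values * coord, sigma_vox,
                                          truncate=truncate, mode="constant"))
        self._splines = [spline_filter(f, order=3, mode="nearest")
                         for f in fields]
        self._origin = g.origin
        self._h = h
        self._max_idx = np.asarray(g.shape, float) - 1.0

    def evaluate(self, seeds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(den, num) at the seed positions; seeds clamped to the grid."""
        frac = np.clip((seeds - self._origin) / self._h, 0.0, self._max_idx).T
        vals = [map_coordinates(s, frac, order=3, prefilter=False,
                                mode="nearest") for s in self._splines]
        den = np.maximum(vals[0], 0.0) * self.kernel_sum
        num = np.stack(vals[1:], axis=1) * self.kernel_sum
        return den, num


def mean_shift(g: DensityGrid, rp: ResolutionParams,
               tol: float = 0.01, max_iter: int = 100,
               seed_threshold: float = 0.1) -> MeanShiftState:
    """Shift seeds to the local maxima of the kernel-smoothed field.

    Seeds start at every voxel with p above ``seed_threshold`` (the positive
    near-zero bulk of a continuous field carries no extra maxima and is
    skipped for cost); the update is the Gaussian-kernel weighted mean over
    grid points, iterated until the displacement drops below ``tol`` Å or
    ``max_iter`` sweeps.  The per-seed probability is
    P(z) = (1/N) sum_n K(z - x_n) p(x_n) with N the total voxel count.
    """
    p = g.values
    if not (p > 0).any():
        raise FittingError("probability map has no positive voxels")
    pos_all = g.voxel_positions()
    seeds = pos_all[(p > seed_threshold).ravel()]
    if len(seeds) == 0:
        seeds = pos_all[p.argmax()][None, :]
    fields = _KernelFields(g, rp.lam, rp.truncation_radius)
    N = g.values.size
    current = seeds.copy()
    converged = np.zeros(len(seeds), bool)
    it = 0
    for it in range(1, max_iter + 1):
        active = ~converged
        if not active.any():
            break
        den, num = fields.evaluate(current[active])
        good = den > 0
        shifted = current[active].copy()
        shifted[good] = num[good] / den[good, None]
        disp = np.linalg.norm(shifted - current[active], axis=1)
        disp[~good] = 0.0
        current[active] = np.where(good[:, None], shifted, current[active])
        newly = np.nonzero(active)[0][disp < tol]
        converged[newly] = True
    den, _ = fields.evaluate(current)
    return MeanShiftState(current, den / N, converged, it)


def cluster_to_points(ms: MeanShiftState, g: DensityGrid,
                      merge_dist: float = 1.0) -> MainChainPointSet:
    """Reduce seeds to representatives by greedy probability suppression.

    Seeds are visited in decreasing P(z); each kept seed suppresses every
    remaining seed within ``merge_dist``.  The output points are therefore
    pairwise at least ``merge_dist`` apart and each carries its own P(z).
    (On smooth fields the mean-shift endpoints line up densely along
    quasi-degenerate ridges; transitive merging would collapse a whole
    ridge into one representative, whereas suppression keeps a covering
    set.)
    """
    seeds, prob = ms.seeds, ms.prob
    order = np.argsort(-prob, kind="stable")
    alive = np.ones(len(seeds), bool)
    tree = cKDTree(seeds)
    keep: list[int] = []
    for i in order:
        if not alive[i]:
            continue
        keep.append(int(i))
        alive[tree.query_ball_point(seeds[i], merge_dist)] = False
    keep_arr = np.asarray(keep, int)
    return MainChainPointSet(seeds[keep_arr], prob[keep_arr])


def reduce_map_to_points(g: DensityGrid, rp: ResolutionParams,
                         tol: float = 0.01, max_iter: int = 100,
                         seed_threshold: float = 0.1,
                         merge_dist: float = 1.0) -> MainChainPointSet:
    """Convenience pipeline: mean shift followed by clustering."""
    ms = mean_shift(g, rp, tol=tol, max_iter=max_iter,
                    seed_threshold=seed_threshold)
    return cluster_to_points(ms, g, merge_dist=merge_dist)
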