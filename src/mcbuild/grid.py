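"""3D density / probability grids: MRC/CCP4 I/O, resampling, normalization.

A :class:`DensityGrid` is the single grid container used by every stage of the
pipeline.  Geometry conventions (fixed across the package):

* ``values[i, j, k]`` is the sample at Cartesian position
  ``origin + voxel_size * (i, j, k)`` — axis 0 is x, axis 1 is y, axis 2 is z,
  regardless of how the axes were permuted on disk.
* ``origin`` is the position (Å) of the *center* of voxel ``(0, 0, 0)``.
* Raw maps may have anisotropic voxels; everything downstream of
  :func:`resample_cubic` assumes isotropic spacing and uses ``grid.spacing``.

Resolution-dependent kernel constants follow the Gaussian model used
throughout the scoring: ``lam = (pi / (2.4 + 0.8 R))**2`` for a map of nominal
resolution ``R`` (Å), with the dimensionless prefactor
``theta = (lam / pi)**1.5``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.interpolate import make_interp_spline

from .errors import MapFormatError, UnsupportedMapError

__all__ = [
    "DensityGrid",
    "ResolutionParams",
    "resolution_params",
    "read_map",
    "write_map",
    "resample_cubic",
    "normalize_density",
]

#: relative kernel weight below which Gaussian contributions are truncated
KERNEL_TRUNCATION = 1e-4

NORMALIZE_PERCENTILE = 99.999


@dataclass
class DensityGrid:
    """A scalar field on a regular orthogonal 3D grid."""

    values: np.ndarray            # (nx, ny, nz) float array
    voxel_size: np.ndarray        # (3,) voxel edge lengths in Å
    origin: np.ndarray            # (3,) position of voxel (0,0,0) center, Å

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("grid values must be a 3D array")
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3).copy()
        if not np.all(self.voxel_size > 0):
            raise ValueError("voxel size must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> float:
        """Isotropic voxel edge length; raises if the grid is anisotropic."""
        if not np.allclose(self.voxel_size, self.voxel_size[0], rtol=1e-6):
            raise ValueError(
                "grid is anisotropic; resample to isotropic spacing first"
            )
        return float(self.voxel_size[0])

    def axis_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-center coordinates in Å."""
        return tuple(
            self.origin[d] + self.voxel_size[d] * np.arange(self.shape[d])
            for d in range(3)
        )  # type: ignore[return-value]

    def voxel_positions(self) -> np.ndarray:
        """(N, 3) Cartesian positions of all voxel centers, C-order."""
        ax = self.axis_coordinates()
        xx, yy, zz = np.meshgrid(*ax, indexing="ij")
        return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)

    def copy(self) -> "DensityGrid":
        return DensityGrid(self.values.copy(), self.voxel_size.copy(),
                           self.origin.copy())


@dataclass(frozen=True)
class ResolutionParams:
    """Resolution-dependent Gaussian kernel constants.

    ``lam`` (Å^-2) controls the kernel width, ``theta`` is the dimensionless
    score prefactor ``(lam/pi)**1.5``; both decrease the fuzzier the map.
    """

    R: float
    lam: float = field(init=False)
    theta: float = field(init=False)

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("map resolution R must be positive")
        lam = (np.pi / (2.4 + 0.8 * self.R)) ** 2
        object.__setattr__(self, "lam", float(lam))
        object.__setattr__(self, "theta", float((lam / np.pi) ** 1.5))

    @property
    def truncation_radius(self) -> float:
        """Distance beyond which exp(-lam r^2) < KERNEL_TRUNCATION."""
        return float(np.sqrt(-np.log(KERNEL_TRUNCATION) / self.lam))


def resolution_params(R: float) -> ResolutionParams:
    """Kernel constants for a map of nominal resolution ``R`` in Å."""
    return ResolutionParams(R=float(R))


def _check_orthogonal(cell: gemmi.UnitCell) -> None:
    for angle in (cell.alpha, cell.beta, cell.gamma):
        if abs(angle - 90.0) > 1e-3:
            raise UnsupportedMapError(
                f"nonorthogonal map axes (cell angles {cell.alpha:.2f}, "
                f"{cell.beta:.2f}, {cell.gamma:.2f}); only orthogonal cells "
                "are supported"
            )


def read_map(path) -> DensityGrid:
    """Read an MRC/CCP4 map and normalize it to the internal convention.

    Axis order is normalized to (x, y, z) whatever the file's
    mapc/mapr/maps permutation.  The origin is taken from the MRC ORIGIN
    header record when any component is nonzero, otherwise from
    nstart * voxel_size (common CCP4 deposition practice).
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise MapFormatError(f"cannot read MRC/CCP4 map {path}: {exc}") from exc
    _check_orthogonal(ccp4.grid.unit_cell)
    # header words read before setup(): nstart (5-7) follows the file's
    # column/row/section order and must be unpermuted via mapc/mapr/maps;
    # mx/my/mz (8-10) and ORIGIN (50-52) are always in crystallographic xyz.
    axis_of = [ccp4.header_i32(w) - 1 for w in (17, 18, 19)]
    nstart_file = [ccp4.header_i32(w) for w in (5, 6, 7)]
    nstart = np.zeros(3)
    for file_axis, xyz_axis in enumerate(axis_of):
        nstart[xyz_axis] = nstart_file[file_axis]
    mx = ccp4.header_i32(8), ccp4.header_i32(9), ccp4.header_i32(10)
    origin = np.array([ccp4.header_float(50), ccp4.header_float(51),
                       ccp4.header_float(52)], dtype=float)
    # reorder axes to X-fastest internal layout without padding to a full cell
    ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    values = np.array(ccp4.grid, copy=True, dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise MapFormatError(f"map {path} contains non-finite values")
    cell = ccp4.grid.unit_cell
    voxel = np.array([cell.a / mx[0], cell.b / mx[1], cell.c / mx[2]])
    if np.all(origin == 0.0):
        origin = nstart * voxel
    return DensityGrid(values, voxel, origin)


def write_map(g: DensityGrid, path) -> None:
    """Write the grid as an MRC/CCP4 2014 map (mode 2, float32)."""
    data = np.ascontiguousarray(g.values, dtype=np.float32)
    grid = gemmi.FloatGrid(data)
    nx, ny, nz = g.shape
    grid.set_unit_cell(gemmi.UnitCell(
        nx * g.voxel_size[0], ny * g.voxel_size[1], nz * g.voxel_size[2],
        90.0, 90.0, 90.0))
    grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for word, val in zip((50, 51, 52), g.origin):
        ccp4.set_header_float(word, float(val))
    ccp4.write_ccp4_map(str(path))


def resample_cubic(g: DensityGrid, target_spacing: float) -> DensityGrid:
    """Resample onto an isotropic grid by piecewise-cubic interpolation.

    The new grid covers the same physical extent (span of voxel centers) and
    keeps the same origin.  Interpolation is a tensor-product cubic spline
    with not-a-knot boundary conditions, applied axis by axis; it is exact at
    the original samples and reproduces polynomials up to degree 3,
    including at the boundary.
    """
    if target_spacing <= 0:
        raise ValueError("target spacing must be positive")
    if any(n < 4 for n in g.shape):
        raise ValueError(
            f"cubic resampling needs >= 4 samples per axis, got shape {g.shape}"
        )
    axes = g.axis_coordinates()
    span = [(g.shape[d] - 1) * g.voxel_size[d] for d in range(3)]
    new_shape = [int(np.floor(span[d] / target_spacing + 1e-9)) + 1
                 for d in range(3)]
    new_axes = [g.origin[d] + target_spacing * np.arange(new_shape[d])
                for d in range(3)]
    values = g.values
    for d in range(3):
        spline = make_interp_spline(axes[d], values, k=3, axis=d)
        values = spline(new_axes[d])
    return DensityGrid(values, np.full(3, float(target_spacing)),
                       g.origin.copy())


def normalize_density(g: DensityGrid) -> DensityGrid:
    """Clip negatives and scale to [0, 1] by the 99.999-percentile value.

    The percentile is computed by linear interpolation between order
    statistics (numpy's default estimator).  Values above the percentile are
    clipped to 1.0, so a handful of outlier voxels cannot compress the
    dynamic range of the whole map.
    """
    clipped = np.clip(g.values, 0.0, None)
    scale = float(np.percentile(clipped, NORMALIZE_PERCENTILE))
    if scale <= 0.0:
        raise ValueError("map has no positive density; nothing to normalize")
    values = np.clip(clipped / scale, 0.0, 1.0)
    return DensityGrid(values, g.voxel_size.copy(), g.origin.copy())
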