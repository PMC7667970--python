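"""Two-channel confocal z-stack analysis: tissue surface and bead centroids.

A stack holds a tissue channel (calcein-stained epithelium, signal at and
below the tissue surface) and a bead channel (1-µm fluorescent beads).  The
tissue isosurface is approximated per (x, y) column by the topmost voxel
above an intensity threshold; beads are segmented as 3D connected
components and reduced to intensity-weighted centroids.  Distances between
bead centroids and the interpolated tissue surface along z feed the
penetrability statistic.

Coordinate convention: voxel indices are 0-based, physical position of a
voxel is ``index * step + step / 2`` (voxel centers), z increases away from
the tissue in the apical direction, all positions in µm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .penetrability import DistanceSet

__all__ = [
    "VoxelStack",
    "TissueSurfaceMap",
    "BeadCentroids",
    "extract_tissue_surface",
    "detect_beads",
    "compute_bead_distances",
]

_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class VoxelStack:
    """Two-channel 3D intensity grid with physical voxel spacing.

    ``intensities`` is (channel, z, y, x); ``voxel_size_um`` is (dz, dy, dx).
    """

    intensities: np.ndarray
    voxel_size_um: tuple[float, float, float]
    channel_roles: dict[str, int] = field(
        default_factory=lambda: {"tissue": 0, "beads": 1}
    )

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 4:
            raise ValueError("stack must be (channel, z, y, x)")
        if min(self.intensities.shape) < 1:
            raise ValueError("all stack dimensions must be >= 1")
        if any(s <= 0 for s in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")

    def channel(self, role: str) -> np.ndarray:
        return self.intensities[self.channel_roles[role]]

    # -- TIFF round-trip (multi-page TIFF + JSON sidecar with voxel sizes) --

    def to_tiff(self, path: str | Path) -> None:
        path = Path(path)
        tifffile.imwrite(path, self.intensities.astype(np.float32))
        sidecar = {
            "voxel_size_um": list(self.voxel_size_um),
            "channel_roles": self.channel_roles,
            "axes": "CZYX",
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_tiff(cls, path: str | Path) -> "VoxelStack":
        path = Path(path)
        data = tifffile.imread(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            intensities=np.asarray(data),
            voxel_size_um=tuple(meta["voxel_size_um"]),
            channel_roles={k: int(v) for k, v in meta["channel_roles"].items()},
        )


@dataclass
class TissueSurfaceMap:
    """Tissue surface height per (x, y) grid cell.

    ``surface_z_um`` is (ny, nx); cells where no tissue was detected carry
    ``valid_mask == False`` and an undefined height.  ``pixel_size_um`` is
    (dy, dx); cell centers sit at ``(index + 0.5) * pixel``.
    """

    surface_z_um: np.ndarray
    valid_mask: np.ndarray
    pixel_size_um: tuple[float, float]

    def __post_init__(self) -> None:
        self.surface_z_um = np.asarray(self.surface_z_um, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.surface_z_um.shape != self.valid_mask.shape:
            raise ValueError("surface and mask shapes must match")
        if not np.all(np.isfinite(self.surface_z_um[self.valid_mask])):
            raise ValueError("surface heights must be finite where valid")

    @property
    def extent_um(self) -> tuple[float, float]:
        """(y, x) physical field size."""
        ny, nx = self.surface_z_um.shape
        return ny * self.pixel_size_um[0], nx * self.pixel_size_um[1]

    def interpolator(self) -> RegularGridInterpolator:
        """Bilinear interpolator over cell centers; NaN at invalid cells.

        Extrapolates linearly outside the center grid so beads within half
        a pixel of the field border still get a height.
        """
        ny, nx = self.surface_z_um.shape
        yc = (np.arange(ny) + 0.5) * self.pixel_size_um[0]
        xc = (np.arange(nx) + 0.5) * self.pixel_size_um[1]
        z = np.where(self.valid_mask, self.surface_z_um, np.nan)
        return RegularGridInterpolator(
            (yc, xc), z, method="linear", bounds_error=False, fill_value=None
        )


@dataclass
class BeadCentroids:
    """Detected beads: physical centroid, component size, peak intensity."""

    x_um: np.ndarray
    y_um: np.ndarray
    z_um: np.ndarray
    voxel_count: np.ndarray
    peak_intensity: np.ndarray

    def __len__(self) -> int:
        return self.x_um.size


def extract_tissue_surface(
    stack: VoxelStack, threshold_fraction: float = 0.5
) -> TissueSurfaceMap:
    """Per-column tissue surface: topmost voxel above a fractional threshold.

    The threshold is ``threshold_fraction`` of the tissue channel maximum.
    Columns with no supra-threshold voxel are masked invalid; an
    all-background channel yields an empty mask and a warning, not a
    failure.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    ch = stack.channel("tissue")
    dz, dy, dx = stack.voxel_size_um
    peak = float(ch.max())
    if peak <= 0:
        warnings.warn("tissue channel is all background; surface map is empty")
        empty = np.zeros(ch.shape[1:])
        return TissueSurfaceMap(empty, np.zeros_like(empty, bool), (dy, dx))
    above = ch >= threshold_fraction * peak
    valid = above.any(axis=0)
    # topmost supra-threshold plane per column
    top_idx = ch.shape[0] - 1 - np.argmax(above[::-1], axis=0)
    surface = (top_idx + 0.5) * dz
    if not valid.any():
        warnings.warn("no supra-threshold tissue voxels; surface map is empty")
    return TissueSurfaceMap(np.where(valid, surface, 0.0), valid, (dy, dx))


def detect_beads(
    stack: VoxelStack,
    threshold_fraction: float = 0.5,
    min_voxels: int = 2,
    threshold_abs: float | None = None,
) -> BeadCentroids:
    """Segment beads as 3D connected components and return their centroids.

    The bead channel is thresholded at ``threshold_fraction`` of its
    maximum (or at ``threshold_abs`` intensity units when given, which is
    robust when a field of view contains no beads at all), components are
    labeled with 26-connectivity, components smaller than ``min_voxels``
    are rejected as noise, and each surviving component is reduced to its
    intensity-weighted centroid in physical µm.  Zero beads is a valid
    result.
    """
    ch = stack.channel("beads").astype(float)
    dz, dy, dx = stack.voxel_size_um
    thr = threshold_abs if threshold_abs is not None else threshold_fraction * ch.max()
    mask = ch >= thr if ch.max() > 0 else np.zeros_like(ch, bool)
    labels, n = ndimage.label(mask, structure=_STRUCTURE_26)
    if n == 0:
        z = np.zeros(0)
        return BeadCentroids(z, z.copy(), z.copy(), np.zeros(0, int), z.copy())
    idx = np.arange(1, n + 1)
    sizes = ndimage.sum_labels(mask, labels, idx).astype(int)
    keep = sizes >= min_voxels
    idx = idx[keep]
    if idx.size == 0:
        z = np.zeros(0)
        return BeadCentroids(z, z.copy(), z.copy(), np.zeros(0, int), z.copy())
    weights = np.where(mask, ch, 0.0)
    coms = np.array(ndimage.center_of_mass(weights, labels, idx))
    peaks = ndimage.maximum(ch, labels, idx)
    return BeadCentroids(
        x_um=(coms[:, 2] + 0.5) * dx,
        y_um=(coms[:, 1] + 0.5) * dy,
        z_um=(coms[:, 0] + 0.5) * dz,
        voxel_count=sizes[keep],
        peak_intensity=np.asarray(peaks, dtype=float),
    )


def compute_bead_distances(
    beads: BeadCentroids,
    surface: TissueSurfaceMap,
    mouse_id: str = "",
    stack_id: str = "",
) -> DistanceSet:
    """Axial tissue-to-bead distances: ``d = bead_z − surface_z(x, y)``.

    The surface height under each bead is bilinearly interpolated between
    valid cells; ``d > 0`` means the bead sits above the tissue.  Beads
    over invalid (no-tissue) cells are excluded and counted in the
    returned set's ``n_excluded``.
    """
    if not surface.valid_mask.any():
        raise ValueError("surface map has no valid cells")
    if len(beads) == 0:
        return DistanceSet(np.zeros(0), mouse_id, stack_id)
    interp = surface.interpolator()
    surf_z = interp(np.column_stack([beads.y_um, beads.x_um]))
    ok = np.isfinite(surf_z)
    d = beads.z_um[ok] - surf_z[ok]
    return DistanceSet(
        d, mouse_id, stack_id, n_excluded=int(np.count_nonzero(~ok))
    )
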