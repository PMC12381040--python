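"""Spatial partition of a cell's voxel set around its centroid.

Each cell's 3D mask is split into 8 octants by the sign of each coordinate
relative to the centroid, and into half-spaces and fixed-thickness slabs along
each axis.  Octants 1-4 form the apical half (away from the coverslip), 5-8
the basolateral half.

Conventions (fixed so results are reproducible; the underlying study does not
pin them down beyond the apical/basal split):

* Plane index increases away from the coverslip, so apical means z >= centroid
  z.  ``z_orientation='low'`` flips this for stacks acquired top-down.
* Within the apical half, quadrants 1-4 run counterclockwise (in x right /
  y up sense) starting from (x >= cx, y >= cy); octant k+4 sits directly below
  octant k.
* Ties: a voxel exactly at the centroid coordinate goes to the progressive /
  apical side (coordinate >= centroid), so no voxel is dropped or counted
  twice.
* "Progressive" = increasing pixel coordinate, "regressive" = decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ValidationError
from .morphology import CellMask

__all__ = ["OctantLabeling", "AxisSections", "octant_labels", "axis_halves", "axis_slabs"]

_AXES = ("x", "y", "z")


@dataclass
class OctantLabeling:
    """Per-voxel octant index 1-8 (0 outside the mask) and the 8 voxel counts."""

    cell_id: str
    labels: np.ndarray  # (plane, row, col) uint8
    counts: np.ndarray  # shape (8,), counts[k-1] = voxels in octant k

    def region_mask(self, octant: int) -> np.ndarray:
        if not 1 <= octant <= 8:
            raise ValidationError("octant index must be in 1..8")
        return self.labels == octant


@dataclass
class AxisSections:
    """Half-space split of a mask along one axis.

    ``progressive`` holds voxels with coordinate >= centroid coordinate,
    ``regressive`` the rest.  Along z these are the apical and basolateral
    halves respectively (under the default orientation).
    """

    cell_id: str
    axis: str
    progressive: np.ndarray  # boolean (plane, row, col)
    regressive: np.ndarray


def _coordinate_grids(mask: CellMask):
    nz = mask.n_planes
    ny, nx = mask.mask2d.shape
    z = np.arange(nz)[:, None, None]
    y = np.arange(ny)[None, :, None]
    x = np.arange(nx)[None, None, :]
    return x, y, z


def octant_labels(
    mask: CellMask,
    centroid: tuple[float, float, float],
    z_orientation: str = "high",
) -> OctantLabeling:
    """Label every mask voxel with its octant 1-8 around ``centroid``.

    Octants 1-4 are apical, 5-8 basolateral; counts conserve TPN by
    construction (every voxel gets exactly one label).
    """
    if z_orientation not in ("high", "low"):
        raise ValidationError("z_orientation must be 'high' or 'low'")
    cx, cy, cz = centroid
    x, y, z = _coordinate_grids(mask)
    m3 = mask.mask3d
    apical = (z >= cz) if z_orientation == "high" else (z < cz)
    xp = x >= cx  # progressive in x
    yp = y >= cy
    # quadrant 1: (x>=cx, y>=cy); 2: (x<cx, y>=cy); 3: (x<cx, y<cy); 4: (x>=cx, y<cy)
    quad = np.where(yp, np.where(xp, 1, 2), np.where(xp, 4, 3))
    labels = np.where(m3, np.where(apical, quad, quad + 4), 0).astype(np.uint8)
    counts = np.bincount(labels[m3].ravel(), minlength=9)[1:]
    return OctantLabeling(cell_id=mask.cell_id, labels=labels, counts=counts)


def axis_halves(
    mask: CellMask,
    centroid: tuple[float, float, float],
    axis: str,
    z_orientation: str = "high",
) -> AxisSections:
    """Split the mask into progressive/regressive halves along ``axis``.

    For z the progressive half is the apical one (see module conventions).
    The two halves partition the mask exactly.
    """
    if axis not in _AXES:
        raise ValidationError(f"unknown axis {axis!r}")
    cx, cy, cz = centroid
    x, y, z = _coordinate_grids(mask)
    coord, c = {"x": (x, cx), "y": (y, cy), "z": (z, cz)}[axis]
    m3 = mask.mask3d
    prog = m3 & (coord >= c)
    if axis == "z" and z_orientation == "low":
        prog = m3 & (coord < c)
    return AxisSections(
        cell_id=mask.cell_id, axis=axis, progressive=prog, regressive=m3 & ~prog
    )


def axis_slabs(
    mask: CellMask,
    axis: str,
    thickness_um: float,
    spacing: tuple[float, float],
) -> list[np.ndarray]:
    """Partition the mask into contiguous slabs of physical thickness along an axis.

    ``spacing`` is (dz_um, dxy_um).  Slabs are ordered by increasing
    coordinate and jointly partition the mask; the first slab starts at the
    mask's minimal occupied coordinate.
    """
    if axis not in _AXES:
        raise ValidationError(f"unknown axis {axis!r}")
    dz_um, dxy_um = spacing
    pitch = dz_um if axis == "z" else dxy_um
    if not thickness_um > 0:
        raise ValidationError("slab thickness must be positive")
    if thickness_um < pitch:
        raise ValidationError(
            f"slab thickness {thickness_um} um is below one voxel pitch {pitch} um"
        )
    x, y, z = _coordinate_grids(mask)
    coord = {"x": x, "y": y, "z": z}[axis]
    m3 = mask.mask3d
    coords = np.broadcast_to(coord, m3.shape)[m3]
    lo = coords.min()
    # floor with a tiny epsilon so an exact multiple starts a new slab
    idx_all = np.floor((coord - lo) * pitch / thickness_um + 1e-12).astype(int)
    idx_all = np.broadcast_to(idx_all, m3.shape)
    n_slabs = int(idx_all[m3].max()) + 1
    return [m3 & (idx_all == i) for i in range(n_slabs)]
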