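"""Grid-based containers shared by every pipeline stage.

Three in-memory objects circulate through the pipeline:

* :class:`LabelVolume` — a 3D grid of non-negative integer region codes
  (0 = background), the unit of segmentation exchange.
* :class:`BinaryMask` — a 3D boolean grid sharing a companion volume's
  geometry (intracranial, tissue and lesion masks).
* :class:`TissueMaps` — per-voxel CSF/GM/WM probabilities.

All carry a ``voxel_size`` in millimetres per axis; voxel volume is always
derived from it (no isotropy assumption). Objects that are combined must
share geometry exactly; :func:`check_same_geometry` enforces this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabelVolume",
    "BinaryMask",
    "TissueMaps",
    "GeometryError",
    "check_same_geometry",
]

#: relative tolerance for comparing voxel spacings
SPACING_RTOL = 1e-6

#: allowed excess of csf+gm+wm over 1.0 per voxel
TISSUE_SUM_TOL = 1e-3


class GeometryError(ValueError):
    """Shapes or voxel spacings of combined volumes do not match."""


def _as_voxel_size(voxel_size) -> tuple[float, float, float]:
    vs = tuple(float(v) for v in np.atleast_1d(voxel_size).ravel())
    if len(vs) == 1:
        vs = vs * 3
    if len(vs) != 3 or any(v <= 0 for v in vs):
        raise ValueError(f"voxel_size must be 3 positive lengths in mm, got {voxel_size!r}")
    return vs


@dataclass
class LabelVolume:
    """3D integer region-code grid with voxel spacing in mm."""

    grid: np.ndarray
    voxel_size: tuple[float, float, float]
    code_table_ref: str | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"label grid must be 3D, got shape {self.grid.shape}")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError(f"label grid must be integer-typed, got {self.grid.dtype}")
        if self.grid.size and self.grid.min() < 0:
            raise ValueError("label codes must be non-negative")
        self.voxel_size = _as_voxel_size(self.voxel_size)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    def codes(self) -> np.ndarray:
        """Sorted nonzero codes present in the grid."""
        u = np.unique(self.grid)
        return u[u != 0]

    def region_mask(self, code: int) -> "BinaryMask":
        return BinaryMask(self.grid == code, self.voxel_size)

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.grid.copy(), self.voxel_size, self.code_table_ref)


@dataclass
class BinaryMask:
    """3D boolean grid with voxel spacing in mm."""

    grid: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"mask grid must be 3D, got shape {self.grid.shape}")
        if self.grid.dtype != bool:
            if np.issubdtype(self.grid.dtype, np.integer) and np.isin(self.grid, (0, 1)).all():
                self.grid = self.grid.astype(bool)
            else:
                raise ValueError("mask grid must be boolean or 0/1 integer")
        self.voxel_size = _as_voxel_size(self.voxel_size)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def count(self) -> int:
        """Number of true voxels."""
        return int(self.grid.sum())

    def volume_mm3(self) -> float:
        return self.count() * self.voxel_volume

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.grid.copy(), self.voxel_size)


@dataclass
class TissueMaps:
    """Per-voxel CSF/GM/WM probability maps sharing one geometry.

    Channel values lie in [0, 1] and sum to at most 1 (+ tolerance) per
    voxel; the remainder to 1 is implicit background probability.
    """

    csf: np.ndarray
    gm: np.ndarray
    wm: np.ndarray
    voxel_size: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self) -> None:
        self.csf = np.asarray(self.csf, dtype=float)
        self.gm = np.asarray(self.gm, dtype=float)
        self.wm = np.asarray(self.wm, dtype=float)
        shapes = {self.csf.shape, self.gm.shape, self.wm.shape}
        if len(shapes) != 1 or self.csf.ndim != 3:
            raise GeometryError(f"tissue channels must share one 3D shape, got {shapes}")
        for name, ch in (("csf", self.csf), ("gm", self.gm), ("wm", self.wm)):
            if ch.size and (ch.min() < -TISSUE_SUM_TOL or ch.max() > 1 + TISSUE_SUM_TOL):
                raise ValueError(f"{name} probabilities outside [0, 1]")
        total = self.csf + self.gm + self.wm
        if total.size and total.max() > 1 + TISSUE_SUM_TOL:
            raise ValueError("per-voxel tissue probabilities sum to more than 1")
        self.voxel_size = _as_voxel_size(self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.csf.shape


def _geometry_of(obj):
    if isinstance(obj, TissueMaps):
        return obj.shape, obj.voxel_size
    return obj.grid.shape, obj.voxel_size


def check_same_geometry(*objs) -> None:
    """Raise :class:`GeometryError` unless all objects share shape and spacing."""
    if not objs:
        return
    shape0, vs0 = _geometry_of(objs[0])
    for obj in objs[1:]:
        shape, vs = _geometry_of(obj)
        if shape != shape0:
            raise GeometryError(f"grid shapes differ: {shape0} vs {shape}")
        if not np.allclose(vs, vs0, rtol=SPACING_RTOL):
            raise GeometryError(f"voxel sizes differ: {vs0} vs {vs}")
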