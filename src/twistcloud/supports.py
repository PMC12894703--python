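"""Geometric supports and record filters.

A support is a bounded membership region in the query particle's canonical
frame (post-alignment); it never depends on extrinsic coordinates, which
preserves the rotational-invariance contract of twist descriptors.
Reducing a descriptor keeps exactly the records whose translational part
lies inside the region.  Membership intervals are closed: boundary points
belong to the region.

Supports: sphere, cylinder (symmetric about the origin or with an explicit
axial range, e.g. the one-sided ``[0, h]`` variant used for stacking
analyses), ellipsoid, cone (optionally mirrored about the origin), torus,
and binary voxel masks (nearest-voxel lookup at threshold 0.5, mask center
voxel at the origin).

Filters act on scalar record fields over closed ``[lo, hi]`` ranges;
angular quantities are specified in degrees at this interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .descriptor import TwistDescriptor

__all__ = [
    "Support", "Sphere", "Cylinder", "Ellipsoid", "Cone", "Torus", "MaskSupport",
    "Filter", "axis_deviation", "reduce_descriptor", "support_membership",
    "support_from_config",
]

_ANGULAR_FIELDS = {"angular_distance", "inplane_query", "inplane_neighbor"}


class Support:
    """Base class: a bounded region with decidable membership."""

    orientation_offset: np.ndarray | None = None

    def _local(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self.orientation_offset is not None:
            points = points @ self.orientation_offset  # offset^T applied to each row
        return points

    def contains(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def max_extent(self) -> float:
        """Radius of the smallest origin-centered ball containing the region."""
        raise NotImplementedError


def _with_offset(obj: Support, orientation_offset) -> Support:
    if orientation_offset is not None:
        obj.orientation_offset = np.asarray(orientation_offset, dtype=float)
    return obj


class Sphere(Support):
    def __init__(self, radius: float, orientation_offset=None):
        if radius <= 0:
            raise ValueError("radius must be positive")
        self.radius = float(radius)
        _with_offset(self, orientation_offset)

    def contains(self, points):
        p = self._local(points)
        return np.linalg.norm(p, axis=1) <= self.radius

    @property
    def max_extent(self):
        return self.radius

    def __repr__(self):
        return f"Sphere(radius={self.radius})"


class Cylinder(Support):
    """Cylinder about ``axis`` through the origin.

    By default the height is symmetric about the origin
    (``axial_range = (-height/2, height/2)``); pass an explicit
    ``axial_range`` for one-sided variants such as ``(0, height)``.
    """

    def __init__(self, radius: float, height: float = None, axis=(0, 0, 1),
                 axial_range: tuple[float, float] | None = None, orientation_offset=None):
        if radius <= 0:
            raise ValueError("radius must be positive")
        if axial_range is None:
            if height is None or height <= 0:
                raise ValueError("height must be positive")
            axial_range = (-height / 2.0, height / 2.0)
        self.radius = float(radius)
        self.axial_range = (float(axial_range[0]), float(axial_range[1]))
        self.axis = np.asarray(axis, dtype=float)
        self.axis = self.axis / np.linalg.norm(self.axis)
        _with_offset(self, orientation_offset)

    def contains(self, points):
        p = self._local(points)
        axial = p @ self.axis
        radial = np.linalg.norm(p - np.outer(axial, self.axis), axis=1)
        lo, hi = self.axial_range
        return (axial >= lo) & (axial <= hi) & (radial <= self.radius)

    @property
    def max_extent(self):
        a = max(abs(self.axial_range[0]), abs(self.axial_range[1]))
        return float(np.hypot(a, self.radius))

    def __repr__(self):
        return f"Cylinder(radius={self.radius}, axial_range={self.axial_range}, axis={self.axis.tolist()})"


class Ellipsoid(Support):
    def __init__(self, semi_axes, orientation_offset=None):
        self.semi_axes = np.asarray(semi_axes, dtype=float)
        if self.semi_axes.shape != (3,) or np.any(self.semi_axes <= 0):
            raise ValueError("semi_axes must be three positive lengths")
        _with_offset(self, orientation_offset)

    def contains(self, points):
        p = self._local(points) / self.semi_axes
        return np.sum(p * p, axis=1) <= 1.0

    @property
    def max_extent(self):
        return float(np.max(self.semi_axes))

    def __repr__(self):
        return f"Ellipsoid(semi_axes={self.semi_axes.tolist()})"


class Cone(Support):
    """Points within ``half_angle_deg`` of ``+axis`` with axial component in
    ``[0, height]``; with ``mirror=True`` the reflected cone along
    ``-axis`` is included as well (the double-cone along an intrinsic
    axis, e.g. the DNA entry/exit direction)."""

    def __init__(self, half_angle_deg: float, height: float, axis=(0, 0, 1),
                 mirror: bool = False, orientation_offset=None):
        if not 0 < half_angle_deg < 90:
            raise ValueError("half angle must be in (0, 90) degrees")
        if height <= 0:
            raise ValueError("height must be positive")
        self.half_angle_deg = float(half_angle_deg)
        self.height = float(height)
        self.axis = np.asarray(axis, dtype=float)
        self.axis = self.axis / np.linalg.norm(self.axis)
        self.mirror = bool(mirror)
        _with_offset(self, orientation_offset)

    def _one_side(self, p: np.ndarray, axis: np.ndarray) -> np.ndarray:
        axial = p @ axis
        norm = np.linalg.norm(p, axis=1)
        cos_half = np.cos(np.deg2rad(self.half_angle_deg))
        with np.errstate(invalid="ignore"):
            inside = (axial >= 0) & (axial <= self.height) & (axial >= cos_half * norm)
        inside[norm == 0] = True
        return inside

    def contains(self, points):
        p = self._local(points)
        inside = self._one_side(p, self.axis)
        if self.mirror:
            inside |= self._one_side(p, -self.axis)
        return inside

    @property
    def max_extent(self):
        return self.height / np.cos(np.deg2rad(self.half_angle_deg))

    def __repr__(self):
        return (f"Cone(half_angle_deg={self.half_angle_deg}, height={self.height}, "
                f"axis={self.axis.tolist()}, mirror={self.mirror})")


class Torus(Support):
    """Solid torus: points within ``minor_radius`` of the circle of
    ``major_radius`` about ``axis``."""

    def __init__(self, major_radius: float, minor_radius: float, axis=(0, 0, 1),
                 orientation_offset=None):
        if major_radius <= 0 or minor_radius <= 0:
            raise ValueError("torus radii must be positive")
        self.major_radius = float(major_radius)
        self.minor_radius = float(minor_radius)
        self.axis = np.asarray(axis, dtype=float)
        self.axis = self.axis / np.linalg.norm(self.axis)
        _with_offset(self, orientation_offset)

    def contains(self, points):
        p = self._local(points)
        axial = p @ self.axis
        radial = np.linalg.norm(p - np.outer(axial, self.axis), axis=1)
        return np.hypot(radial - self.major_radius, axial) <= self.minor_radius

    @property
    def max_extent(self):
        return self.major_radius + self.minor_radius

    def __repr__(self):
        return f"Torus(major_radius={self.major_radius}, minor_radius={self.minor_radius})"


class MaskSupport(Support):
    """Binary voxel mask with nearest-voxel membership at threshold 0.5.

    The center voxel of the grid sits at the origin of the query frame;
    ``voxel_size`` converts lengths to voxel indices.  Nearest-voxel
    lookup (no interpolation) keeps membership bit-exact."""

    def __init__(self, grid: np.ndarray, voxel_size: float, orientation_offset=None):
        if not voxel_size or voxel_size <= 0:
            raise ValueError("mask supports require a positive voxel size")
        self.grid = np.asarray(grid, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError("mask grid must be 3D")
        self.voxel_size = float(voxel_size)
        self.center = (np.array(self.grid.shape) - 1) / 2.0
        _with_offset(self, orientation_offset)

    def contains(self, points):
        p = self._local(points)
        idx = np.rint(p / self.voxel_size + self.center).astype(int)
        inside = np.all((idx >= 0) & (idx < np.array(self.grid.shape)), axis=1)
        out = np.zeros(len(p), dtype=bool)
        ii = idx[inside]
        out[inside] = self.grid[ii[:, 0], ii[:, 1], ii[:, 2]] >= 0.5
        return out

    @property
    def max_extent(self):
        half = np.maximum(self.center, np.array(self.grid.shape) - 1 - self.center)
        return float(np.linalg.norm(half + 0.5) * self.voxel_size)

    def __repr__(self):
        return f"MaskSupport(shape={self.grid.shape}, voxel_size={self.voxel_size})"


def support_membership(s: Support, trans: np.ndarray) -> np.ndarray:
    """Membership of twist positions (already in the query canonical
    frame) in the support region."""
    return s.contains(trans)


def reduce_descriptor(td: TwistDescriptor, s: Support) -> TwistDescriptor:
    """Keep exactly the records whose ``trans`` lies inside ``s``.

    The support must fit inside the descriptor's initial spherical
    support, otherwise records the region should see were never computed
    and the reduction would silently lose information."""
    if s.max_extent > td.radius + 1e-9:
        raise ValueError(
            f"support extent {s.max_extent:.3f} exceeds descriptor radius "
            f"{td.radius:.3f}; recompute the descriptor with a larger radius"
        )
    trans = td.records[["trans_x", "trans_y", "trans_z"]].to_numpy()
    keep = s.contains(trans) if len(trans) else np.zeros(0, dtype=bool)
    return td.with_records(td.records[keep], {"support": repr(s)})


def axis_deviation(records: pd.DataFrame, reference_axis: np.ndarray) -> np.ndarray:
    """Angle (degrees, folded to [0, 90]) between each record's relative
    rotation axis and ``reference_axis``.

    The fold absorbs the sign ambiguity of the axis.  Records with an
    undefined axis (identity relative rotation) are axis-agnostic and get
    deviation 0.
    """
    ref = np.asarray(reference_axis, dtype=float)
    ref = ref / np.linalg.norm(ref)
    ax = records[["axis_x", "axis_y", "axis_z"]].to_numpy()
    cosv = np.abs(ax @ ref)
    out = np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0)))
    return np.where(np.isnan(cosv), 0.0, out)


@dataclass
class Filter:
    """Closed-range predicate on a scalar record field.

    ``field`` is a record column (``euclidean_distance``,
    ``angular_distance``, ``inplane_query``, ``inplane_neighbor``) or
    ``"axis_deviation"`` together with a ``reference_axis``.  Angular
    ranges are given in degrees.
    """

    field: str
    lo: float
    hi: float
    reference_axis: np.ndarray | None = None

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValueError("filter range must satisfy lo <= hi")
        if self.field == "axis_deviation" and self.reference_axis is None:
            raise ValueError("axis_deviation filter needs a reference_axis")

    def evaluate(self, records: pd.DataFrame) -> np.ndarray:
        if self.field == "axis_deviation":
            values = axis_deviation(records, self.reference_axis)
        elif self.field in records.columns:
            values = records[self.field].to_numpy(dtype=float)
            if self.field in _ANGULAR_FIELDS:
                values = np.degrees(values)
        else:
            raise ValueError(f"filter field {self.field!r} not present in records")
        return (values >= self.lo) & (values <= self.hi)

    def __repr__(self):
        extra = f", reference_axis={np.asarray(self.reference_axis).tolist()}" if self.reference_axis is not None else ""
        return f"Filter({self.field!r}, [{self.lo}, {self.hi}]{extra})"


def support_from_config(cfg: dict) -> Support:
    """Build a support from a YAML/dict config: ``{kind: ..., params...}``."""
    cfg = dict(cfg)
    kind = cfg.pop("kind")
    classes = {
        "sphere": Sphere, "cylinder": Cylinder, "ellipsoid": Ellipsoid,
        "cone": Cone, "torus": Torus, "mask": MaskSupport,
    }
    if kind not in classes:
        raise ValueError(f"unknown support kind {kind!r}")
    return classes[kind](**cfg)
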