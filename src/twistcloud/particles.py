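"""Particle lists: the oriented point clouds all analyses start from.

A particle is an oriented point: a position in the tomogram, a rotation
matrix mapping the canonical (reference) frame onto the particle, and
bookkeeping identifiers.  ``ParticleList`` stores a whole table of them as
contiguous numpy arrays plus a pandas frame of scalar metadata.

Positions are continuous 0-based coordinates in the list's native unit
(nm, angstrom, or voxel; voxel lists must carry a pixel size in
angstrom/voxel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry

__all__ = ["ParticleList", "clean_duplicates", "shift_along_intrinsic_axis", "convert_unit"]

_UNITS = ("nm", "angstrom", "voxel")


@dataclass
class ParticleList:
    """Positions, orientations and metadata of a set of particles.

    Attributes
    ----------
    positions : (n, 3) float array, native units
    rotations : (n, 3, 3) float array; ``rotations[i]`` maps the canonical
        frame onto particle ``i`` (the pose used directly in relative-pose
        computations).
    meta : DataFrame with columns ``particle_id``, ``tomo_id``,
        ``object_id`` (nullable), ``score`` (nullable float) and
        ``class_label`` (nullable string).
    unit : one of ``nm``, ``angstrom``, ``voxel``.
    pixel_size : angstrom per voxel; required iff ``unit == "voxel"``.
    """

    positions: np.ndarray
    rotations: np.ndarray
    meta: pd.DataFrame
    unit: str = "nm"
    pixel_size: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if len(self) == 0:
            self.positions = self.positions.reshape(0, 3)
        self.rotations = np.asarray(self.rotations, dtype=float).reshape(-1, 3, 3)
        if self.unit not in _UNITS:
            raise ValueError(f"unit must be one of {_UNITS}, got {self.unit!r}")
        if self.unit == "voxel" and not (self.pixel_size and self.pixel_size > 0):
            raise ValueError("voxel-unit lists require a positive pixel_size")
        self.meta = self.meta.reset_index(drop=True)
        ids = self.meta["particle_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("particle_id values must be unique within a list")
        key = pd.MultiIndex.from_arrays(
            [self.meta["tomo_id"], *(self.positions.T)]
        )
        if key.duplicated().any():
            raise ValueError("two particles share (tomo_id, position) exactly")

    @classmethod
    def from_arrays(
        cls,
        positions: np.ndarray,
        rotations: np.ndarray,
        particle_ids: np.ndarray | None = None,
        tomo_ids: np.ndarray | int = 0,
        object_ids=None,
        scores=None,
        class_labels=None,
        unit: str = "nm",
        pixel_size: float | None = None,
        provenance: dict | None = None,
    ) -> "ParticleList":
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        n = len(positions)
        if particle_ids is None:
            particle_ids = np.arange(n)
        if np.isscalar(tomo_ids):
            tomo_ids = np.full(n, int(tomo_ids))
        meta = pd.DataFrame(
            {
                "particle_id": np.asarray(particle_ids, dtype=int),
                "tomo_id": np.asarray(tomo_ids, dtype=int),
                "object_id": pd.array(
                    [None] * n if object_ids is None else object_ids, dtype="Int64"
                ),
                "score": pd.array(
                    [np.nan] * n if scores is None else scores, dtype="float64"
                ),
                "class_label": pd.array(
                    [None] * n if class_labels is None else class_labels,
                    dtype="string",
                ),
            }
        )
        return cls(positions, rotations, meta, unit, pixel_size, provenance or {})

    def __len__(self) -> int:
        return len(self.meta)

    @property
    def particle_ids(self) -> np.ndarray:
        return self.meta["particle_id"].to_numpy()

    @property
    def tomo_ids(self) -> np.ndarray:
        return self.meta["tomo_id"].to_numpy()

    def validate_rotations(self) -> None:
        for i, r in enumerate(self.rotations):
            try:
                geometry.validate_rotation(r)
            except ValueError as exc:
                raise ValueError(f"particle index {i}: {exc}") from exc

    def copy(self) -> "ParticleList":
        return ParticleList(
            self.positions.copy(),
            self.rotations.copy(),
            self.meta.copy(),
            self.unit,
            self.pixel_size,
            dict(self.provenance),
        )

    def select(self, mask_or_indices) -> "ParticleList":
        """Subset preserving row order."""
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ParticleList(
            self.positions[idx],
            self.rotations[idx],
            self.meta.iloc[idx].reset_index(drop=True),
            self.unit,
            self.pixel_size,
            dict(self.provenance),
        )

    def motions(self) -> list[geometry.RigidMotion]:
        return [
            geometry.RigidMotion(r, p)
            for r, p in zip(self.rotations, self.positions)
        ]

    def concat(self, other: "ParticleList") -> "ParticleList":
        if other.unit != self.unit:
            raise ValueError("cannot concatenate lists with different units")
        return ParticleList(
            np.vstack([self.positions, other.positions]),
            np.concatenate([self.rotations, other.rotations]),
            pd.concat([self.meta, other.meta], ignore_index=True),
            self.unit,
            self.pixel_size,
            dict(self.provenance),
        )


def convert_unit(pl: ParticleList, to_unit: str) -> ParticleList:
    """Convert positions between nm, angstrom and voxel.

    Voxel conversions use ``pixel_size`` (angstrom/voxel).  The conversion
    is exact (a single multiplicative factor) and its own inverse.
    """
    if to_unit not in _UNITS:
        raise ValueError(f"unknown unit {to_unit!r}")
    if to_unit == pl.unit:
        return pl.copy()
    to_angstrom = {"nm": 10.0, "angstrom": 1.0, "voxel": pl.pixel_size}
    if pl.unit == "voxel" or to_unit == "voxel":
        if not pl.pixel_size:
            raise ValueError("voxel conversion requires pixel_size")
    factor = to_angstrom[pl.unit] / to_angstrom[to_unit]
    out = pl.copy()
    out.positions = out.positions * factor
    out.unit = to_unit
    return out


def clean_duplicates(pl: ParticleList, min_distance: float) -> ParticleList:
    """Distance-based duplicate removal by greedy score-descending sweep.

    A particle is kept iff no already-kept particle of the same tomogram
    lies within ``min_distance``.  Particles without a score rank last;
    ties break by ascending ``particle_id``.  The survivor set is
    independent of input row order when scores are distinct.
    """
    if min_distance <= 0:
        raise ValueError("min_distance must be positive")
    scores = pl.meta["score"].to_numpy(dtype=float)
    # NaN scores last, then score descending, then particle_id ascending
    order = np.lexsort((pl.particle_ids, -np.nan_to_num(scores, nan=-np.inf), np.isnan(scores)))
    keep_rows: list[int] = []
    kept_by_tomo: dict[int, list[np.ndarray]] = {}
    for row in order:
        tomo = int(pl.tomo_ids[row])
        pos = pl.positions[row]
        others = kept_by_tomo.get(tomo)
        if others:
            d = np.linalg.norm(np.asarray(others) - pos, axis=1)
            if np.any(d < min_distance):
                continue
        keep_rows.append(row)
        kept_by_tomo.setdefault(tomo, []).append(pos)
    keep_rows.sort()  # preserve original row order in the output
    return pl.select(np.asarray(keep_rows, dtype=int))


def shift_along_intrinsic_axis(
    pl: ParticleList, axis: np.ndarray, distance: float
) -> ParticleList:
    """Move every particle by ``distance`` along its own intrinsic ``axis``.

    The intrinsic direction of particle ``i`` is ``rotations[i] @ axis``;
    rotations are unchanged.  Shifting by ``d`` then ``-d`` restores the
    input exactly.
    """
    axis = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
        raise ValueError("axis must be unit-norm")
    out = pl.copy()
    out.positions = out.positions + distance * np.einsum("nij,j->ni", out.rotations, axis)
    return out


def warn_dropped(field_name: str, fmt: str) -> None:
    warnings.warn(
        f"format {fmt!r} cannot represent field {field_name!r}; values dropped",
        UserWarning,
        stacklevel=3,
    )
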