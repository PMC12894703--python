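"""Ground-truth-labeled synthetic particle lists.

Three families of scenes mirror the geometries the analysis pipelines are
designed for: regular planar lattices of C6-symmetric particles, ring
assemblies of Cn subunits (e.g. the eightfold nuclear-pore ring), and
chromatin-like mixtures of stacked nucleosome pairs, trinucleosomes,
helical arrangements, and random mononucleosomes.  A noise model corrupts
positions (Gaussian) and orientations (random-matrix perturbation
projected back to SO(3)) at calibrated levels.

All generators are pure functions of (spec, seed): identical inputs give
bit-identical particle lists.

Chromatin block geometry (parametric; lengths nm, angles degrees)
-----------------------------------------------------------------
* stacked pair: neighbor at ``stack_translation`` along the query's
  intrinsic +y with a relative rotation of ``stack_twist`` about +y
  (defaults 6 nm and 15 degrees — the stacking distance scale of a
  nucleosome and the angular-distance peak stacked pairs produce).
* trinucleosome: a stacked pair plus a third particle at
  ``linker_distance`` (default 24.5 nm) reached by a screw-like linker
  step: relative rotation of ``linker_twist`` about
  ``linker_axis_direction`` (default +z, the DNA entry/exit axis).
* helix: six stacked pairs chained by linker steps, with exactly one
  pair's stack twist inflated by ``helix_wide_factor`` (the deliberately
  widened pair).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .geometry import RigidMotion, compose
from .particles import ParticleList

__all__ = [
    "NoiseModel", "ChromatinSpec", "rotation_about",
    "generate_planar_lattice", "generate_ring", "generate_chromatin",
    "generate_spherical_lattice", "corrupt",
]

# positional level 1 corresponds to deviations up to ~0.8 nm, read as a
# 3-sigma bound of the per-component Gaussian
POSITIONAL_NM_PER_LEVEL = 0.8 / 3.0


def rotation_about(axis, degrees: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return geometry.exp_so3(np.deg2rad(degrees) * axis)


@dataclass
class NoiseModel:
    """Positional/orientational corruption levels.

    ``positional_level`` scales linearly (level 1 ~ deviations up to
    0.8 nm, level 5 up to 4 nm); ``orientational_level`` in [0, 1] scales
    the random matrix added to the rotation before SO(3) projection
    (level 1 ~ angular deviations up to ~60 degrees)."""

    positional_level: float = 0.0
    orientational_level: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.positional_level < 0 or self.orientational_level < 0:
            raise ValueError("noise levels must be non-negative")


def corrupt(pl: ParticleList, noise: NoiseModel) -> ParticleList:
    """Apply the noise model; both levels 0 returns the input exactly.

    Rotations: ``r' = project_to_so3(r + lambda N)`` with ``N`` standard
    normal and ``lambda`` the orientational level (the SVD projection
    guarantees a valid rotation).  Positions: ``p' = p + g`` with ``g``
    isotropic Gaussian of per-component sigma ``0.8/3 * level`` nm.
    """
    out = pl.copy()
    if noise.positional_level == 0 and noise.orientational_level == 0:
        return out
    rng = np.random.default_rng(noise.seed)
    n = len(pl)
    if noise.orientational_level > 0:
        perturb = rng.standard_normal((n, 3, 3)) * noise.orientational_level
        out.rotations = np.stack(
            [geometry.project_to_so3(r + dn) for r, dn in zip(out.rotations, perturb)]
        )
    if noise.positional_level > 0:
        sigma = POSITIONAL_NM_PER_LEVEL * noise.positional_level
        out.positions = out.positions + rng.normal(0.0, sigma, size=(n, 3))
    return out


# ---------------------------------------------------------------------------
# planar lattice

def generate_planar_lattice(
    kind: str = "triangular",
    shells: int = 3,
    spacing: float = 10.0,
    orientation_sampler: str = "c_n_multiples",
    n_fold: int = 6,
    seed: int = 0,
    tomo_id: int = 0,
) -> ParticleList:
    """Triangular (regular hexagonal) planar lattice in the z=0 plane.

    Every interior vertex has six first-shell neighbors at ``spacing``.
    ``shells`` counts hexagonal rings around the center (shells=1 gives 7
    particles).  Orientations are in-plane rotations about +z drawn per
    sampler: ``c_n_multiples`` uniform over multiples of 360/n degrees,
    ``identity``, or ``random`` (Haar).
    """
    if kind != "triangular":
        raise ValueError("only the triangular lattice kind is implemented")
    if shells < 1 or spacing <= 0:
        raise ValueError("shells >= 1 and spacing > 0 required")
    a1 = np.array([spacing, 0.0, 0.0])
    a2 = np.array([spacing / 2.0, spacing * np.sqrt(3) / 2.0, 0.0])
    coords = []
    for i in range(-shells, shells + 1):
        for j in range(-shells, shells + 1):
            # hexagonal ring index in axial coordinates
            if max(abs(i), abs(j), abs(i + j)) <= shells:
                coords.append(i * a1 + j * a2)
    positions = np.array(coords)
    order = np.lexsort((positions[:, 0], positions[:, 1]))
    positions = positions[order]
    rng = np.random.default_rng(seed)
    n = len(positions)
    if orientation_sampler == "identity":
        rotations = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
    elif orientation_sampler == "c_n_multiples":
        k = rng.integers(0, n_fold, size=n)
        rotations = np.stack([rotation_about((0, 0, 1), 360.0 * kk / n_fold) for kk in k])
    elif orientation_sampler == "random":
        rotations = np.stack([geometry.random_rotation(rng) for _ in range(n)])
    else:
        raise ValueError(f"unknown orientation sampler {orientation_sampler!r}")
    return ParticleList.from_arrays(
        positions, rotations, tomo_ids=tomo_id,
        class_labels=["lattice"] * n,
        provenance={"generator": "planar_lattice", "shells": shells, "spacing": spacing,
                    "orientation_sampler": orientation_sampler, "seed": seed},
    )


def generate_spherical_lattice(radius: float = 100.0, subdivisions: int = 2,
                               tomo_id: int = 0) -> ParticleList:
    """Geodesic (icosphere) lattice: a closed triangular lattice on a
    sphere containing exactly 12 fivefold vertices among sixfold ones —
    the boundary-free analogue of a capsid-like hexagonal lattice with
    pentamer defects.

    class_label records the ground-truth vertex degree: ``fivefold`` or
    ``sixfold``.  Orientations point intrinsic z along the outward
    normal.
    """
    import trimesh

    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    positions = np.asarray(mesh.vertices, dtype=float)
    degrees = np.bincount(np.asarray(mesh.edges_unique).ravel(), minlength=len(positions))
    labels = np.where(degrees == 5, "fivefold", "sixfold")
    rotations = []
    for p in positions:
        normal = p / np.linalg.norm(p)
        axis = np.cross([0.0, 0.0, 1.0], normal)
        s = np.linalg.norm(axis)
        if s < 1e-12:
            rotations.append(np.eye(3) if normal[2] > 0 else rotation_about((1, 0, 0), 180.0))
        else:
            angle = np.arctan2(s, normal[2])
            rotations.append(geometry.exp_so3(angle * axis / s))
    return ParticleList.from_arrays(
        positions, np.stack(rotations), tomo_ids=tomo_id, class_labels=labels,
        provenance={"generator": "spherical_lattice", "radius": radius,
                    "subdivisions": subdivisions},
    )


# ---------------------------------------------------------------------------
# ring assemblies

def generate_ring(
    n_subunits: int = 8,
    radius: float = 50.0,
    center=(0.0, 0.0, 0.0),
    tomo_id: int = 0,
    object_id: int = 0,
    id_offset: int = 0,
    jitter: NoiseModel | None = None,
) -> ParticleList:
    """Ring of Cn subunits: ideal positions of the asymmetric units of a
    ring complex such as the eightfold nuclear-pore ring.

    Subunits sit on a circle in the xy-plane, each with intrinsic -x
    pointing at the ring center and intrinsic z along the ring axis, so
    consecutive subunits differ by an in-plane rotation of 360/n degrees
    (45 degrees for n=8) and shifting every subunit by ``radius`` along
    its intrinsic -x collapses the ring onto its center.
    """
    if n_subunits < 3:
        raise ValueError("a ring needs at least 3 subunits")
    phis = 2 * np.pi * np.arange(n_subunits) / n_subunits
    center = np.asarray(center, dtype=float)
    positions = center + radius * np.column_stack([np.cos(phis), np.sin(phis), np.zeros(n_subunits)])
    rotations = np.stack([rotation_about((0, 0, 1), np.degrees(phi)) for phi in phis])
    pl = ParticleList.from_arrays(
        positions, rotations,
        particle_ids=np.arange(n_subunits) + id_offset,
        tomo_ids=tomo_id,
        object_ids=[object_id] * n_subunits,
        class_labels=["ring"] * n_subunits,
        provenance={"generator": "ring", "n_subunits": n_subunits, "radius": radius},
    )
    return corrupt(pl, jitter) if jitter is not None else pl


# ---------------------------------------------------------------------------
# chromatin-like mixtures

@dataclass
class ChromatinSpec:
    """Composition and block geometry of the synthetic chromatin scene.

    Defaults are the study composition: 6 helices of 12 particles, 350
    stacked pairs, 340 trinucleosomes and 3200 mononucleosomes (4992
    particles) in a 600 x 600 x 150 nm box with 10 nm minimum separation
    between blocks.
    """

    n_helix: int = 6
    n_stack: int = 350
    n_tri: int = 340
    n_mono: int = 3200
    box: tuple[float, float, float] = (600.0, 600.0, 150.0)
    min_separation: float = 10.0
    stack_translation: float = 6.0
    stack_twist: float = 15.0
    linker_distance: float = 24.5
    linker_axis_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    linker_twist: float = 60.0
    helix_pairs: int = 6
    helix_wide_factor: float = 3.0
    helix_wide_index: int = 2
    max_attempts: int = 200

    def __post_init__(self):
        if min(self.n_helix, self.n_stack, self.n_tri, self.n_mono) < 0:
            raise ValueError("counts must be non-negative")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")

    def stack_step(self, wide: bool = False) -> RigidMotion:
        twist = self.stack_twist * (self.helix_wide_factor if wide else 1.0)
        return RigidMotion(rotation_about((0, 1, 0), twist),
                           np.array([0.0, self.stack_translation, 0.0]))

    def linker_step(self) -> RigidMotion:
        axis = np.asarray(self.linker_axis_direction, dtype=float)
        axis = axis / np.linalg.norm(axis)
        return RigidMotion(rotation_about(axis, self.linker_twist),
                           self.linker_distance * np.array([0.0, 0.0, 1.0]))


def _stack_block(spec: ChromatinSpec):
    a = RigidMotion(np.eye(3), np.zeros(3))
    b = compose(a, spec.stack_step())
    return [a, b], ["stack", "stack"], [(0, 1)]


def _tri_block(spec: ChromatinSpec):
    a = RigidMotion(np.eye(3), np.zeros(3))
    b = compose(a, spec.stack_step())
    c = compose(a, spec.linker_step())
    return [a, b, c], ["tri"] * 3, [(0, 1)]


def _helix_block(spec: ChromatinSpec):
    poses, pairs = [], []
    current = RigidMotion(np.eye(3), np.zeros(3))
    for k in range(spec.helix_pairs):
        wide = k == spec.helix_wide_index
        a = current
        b = compose(a, spec.stack_step(wide=wide))
        poses += [a, b]
        if not wide:
            pairs.append((2 * k, 2 * k + 1))
        current = compose(b, spec.linker_step())
    return poses, ["helix"] * len(poses), pairs


class _SpatialHash:
    """Uniform-grid hash for minimum-separation checks in O(1) per query."""

    def __init__(self, cell: float):
        self.cell = cell
        self.cells: dict[tuple[int, int, int], list[np.ndarray]] = {}

    def _key(self, p: np.ndarray) -> tuple[int, int, int]:
        return tuple(np.floor(p / self.cell).astype(int))

    def any_within(self, p: np.ndarray, dist: float) -> bool:
        kx, ky, kz = self._key(p)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for q in self.cells.get((kx + dx, ky + dy, kz + dz), ()):
                        if np.linalg.norm(p - q) < dist:
                            return True
        return False

    def add(self, p: np.ndarray) -> None:
        self.cells.setdefault(self._key(p), []).append(p)


def generate_chromatin(spec: ChromatinSpec, seed: int = 0):
    """Assemble the chromatin scene: blocks are instantiated, given a
    uniform random global rotation, and anchored at uniform random
    positions in the box, rejecting placements that bring any block
    particle within ``min_separation`` of an already placed particle;
    mononucleosomes with uniform random positions and orientations are
    added last under the same constraint.

    Returns ``(particle_list, truth)``: the ground-truth frame records
    each particle's block id, class, and intended within-window stacked
    partner (-1 for none), so classifier recall is computable without
    ambiguity.  By construction a trinucleosome has exactly 2 of 3
    particles in a stacked configuration and a helix block 10 of 12 (one
    deliberately widened pair).
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(spec.box, dtype=float)
    hash_ = _SpatialHash(spec.min_separation)
    positions, rotations, classes, object_ids, partners = [], [], [], [], []

    def place_block(builder):
        poses, labels, pairs = builder(spec)
        local_pos = np.array([p.translation for p in poses])
        for _ in range(spec.max_attempts):
            g = geometry.random_rotation(rng)
            anchor = rng.uniform(0, 1, 3) * box
            world = local_pos @ g.T + anchor
            if any(hash_.any_within(p, spec.min_separation) for p in world):
                continue
            base = len(positions)
            for p, pose, lab in zip(world, poses, labels):
                hash_.add(p)
                positions.append(p)
                rotations.append(g @ pose.rotation)
                classes.append(lab)
                object_ids.append(block_counter[0])
                partners.append(-1)
            for i, j in pairs:
                partners[base + i] = base + j
                partners[base + j] = base + i
            block_counter[0] += 1
            return
        raise RuntimeError(
            "block placement failed after max_attempts; use a larger box or "
            "smaller min_separation"
        )

    block_counter = [0]
    for _ in range(spec.n_helix):
        place_block(_helix_block)
    for _ in range(spec.n_stack):
        place_block(_stack_block)
    for _ in range(spec.n_tri):
        place_block(_tri_block)
    for _ in range(spec.n_mono):
        for attempt in range(spec.max_attempts):
            p = rng.uniform(0, 1, 3) * box
            if not hash_.any_within(p, spec.min_separation):
                hash_.add(p)
                positions.append(p)
                rotations.append(geometry.random_rotation(rng))
                classes.append("mono")
                object_ids.append(None)
                partners.append(-1)
                break
        else:
            raise RuntimeError("mononucleosome placement failed; use a larger box")

    n = len(positions)
    pl = ParticleList.from_arrays(
        np.array(positions), np.stack(rotations),
        particle_ids=np.arange(n), tomo_ids=0,
        object_ids=object_ids, class_labels=classes,
        provenance={"generator": "chromatin", "seed": seed,
                    "composition": (spec.n_helix, spec.n_stack, spec.n_tri, spec.n_mono)},
    )
    import pandas as pd

    truth = pd.DataFrame(
        {
            "particle_id": np.arange(n),
            "class_label": classes,
            "block_id": [(-1 if o is None else o) for o in object_ids],
            "stacked_partner": [(-1 if p < 0 else p) for p in partners],
        }
    )
    return pl, truth
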