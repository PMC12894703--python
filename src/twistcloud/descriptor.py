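"""Twist descriptors: relative poses of all particle pairs within a
spherical support, stored as a table that doubles as a graph.

For a query particle ``(w1, p1)`` and a neighbor ``(w2, p2)`` the stored
record is the twist vector of their relative pose
``(w1^T w2, w1^T (p2 - p1))``: the rotational part ``zeta`` (axis-angle
vector of the relative rotation) and the translational part ``trans`` (the
neighbor position in the query's canonical frame), together with the
distances they encode and per-particle in-plane angles.  Because the
relative pose is invariant under any common rigid motion of the scene, so
is every quantity derived from it.

The neighbor search is an exact fixed-radius search on a KD-tree (closed
ball: ties at exactly the radius are included); pairing is restricted to
particles of the same tomogram.
"""

from __future__ import annotations

import io as _io
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from . import geometry
from .particles import ParticleList

__all__ = [
    "TwistDescriptor",
    "compute_twist",
    "nn_stats",
    "proximity_clusters",
    "apply_edge_filters",
    "save_descriptor",
    "load_descriptor",
    "RECORD_COLUMNS",
]

FORMAT_VERSION = 1

RECORD_COLUMNS = [
    "query_id", "neighbor_id", "tomo_id",
    "zeta_x", "zeta_y", "zeta_z",
    "trans_x", "trans_y", "trans_z",
    "euclidean_distance", "angular_distance",
    "axis_x", "axis_y", "axis_z",
    "inplane_query", "inplane_neighbor",
]

_AXIS_EPS = 1e-9  # below this relative-rotation angle the axis is undefined


@dataclass
class TwistDescriptor:
    """Table of twist records plus provenance.

    ``records`` has one row per ordered (query, neighbor) pair with
    ``0 < euclidean_distance <= radius``; ``query_ids`` lists every query
    particle, including those with empty neighborhoods.  In the
    single-list case the record set is symmetric: (a, b) is present iff
    (b, a) is.
    """

    records: pd.DataFrame
    radius: float
    query_ids: np.ndarray
    unit: str = "nm"
    symmetric: bool = True
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def copy(self) -> "TwistDescriptor":
        return TwistDescriptor(
            self.records.copy(), self.radius, self.query_ids.copy(),
            self.unit, self.symmetric, dict(self.provenance),
        )

    def with_records(self, records: pd.DataFrame, extra_provenance: dict | None = None) -> "TwistDescriptor":
        prov = dict(self.provenance)
        if extra_provenance:
            prov.update(extra_provenance)
        out = TwistDescriptor(
            records.reset_index(drop=True), self.radius, self.query_ids.copy(),
            self.unit, self.symmetric, prov,
        )
        out.symmetric = out._check_symmetric()
        return out

    def _check_symmetric(self) -> bool:
        r = self.records
        if len(r) == 0:
            return True
        fwd = set(zip(r["query_id"], r["neighbor_id"]))
        return all((b, a) in fwd for a, b in fwd)

    def particle_ids_present(self) -> np.ndarray:
        """Every particle appearing in a record, as query or neighbor."""
        r = self.records
        return np.unique(np.concatenate([r["query_id"].to_numpy(), r["neighbor_id"].to_numpy()]))


def _inplane_angles(pl: ParticleList) -> np.ndarray:
    out = np.empty(len(pl))
    for i, r in enumerate(pl.rotations):
        out[i], _ = geometry.swing_twist(r, np.array([0.0, 0.0, 1.0]))
    return out


def compute_twist(
    queries: ParticleList,
    neighbors: ParticleList | None = None,
    radius: float = None,
) -> TwistDescriptor:
    """Compute the twist descriptor of ``queries`` against ``neighbors``
    (single-list, symmetric mode when ``neighbors`` is omitted) on a
    spherical support of the given ``radius``.

    Records are ordered deterministically by (query_id, neighbor_id).  An
    empty query list yields an empty descriptor, not an error.
    """
    if radius is None or radius <= 0:
        raise ValueError("a positive support radius is required")
    symmetric = neighbors is None
    nb = queries if symmetric else neighbors
    if nb.unit != queries.unit:
        raise ValueError(f"unit mismatch: queries in {queries.unit}, neighbors in {nb.unit}")

    q_in = _inplane_angles(queries)
    n_in = q_in if symmetric else _inplane_angles(nb)

    rows: list[tuple] = []
    for tomo in np.unique(queries.tomo_ids):
        qi = np.flatnonzero(queries.tomo_ids == tomo)
        ni = np.flatnonzero(nb.tomo_ids == tomo)
        if len(qi) == 0 or len(ni) == 0:
            continue
        tree = cKDTree(nb.positions[ni])
        hits = tree.query_ball_point(queries.positions[qi], r=radius)
        for a, hit in zip(qi, hits):
            wq, pq = queries.rotations[a], queries.positions[a]
            for h in hit:
                b = ni[h]
                d = np.linalg.norm(nb.positions[b] - pq)
                if d < 1e-12:
                    continue  # a particle is never its own neighbor
                rel_r = wq.T @ nb.rotations[b]
                trans = wq.T @ (nb.positions[b] - pq)
                zeta = geometry.log_so3(rel_r)
                ang = np.linalg.norm(zeta)
                if ang > _AXIS_EPS:
                    axis = zeta / ang
                else:
                    axis = np.full(3, np.nan)
                rows.append(
                    (
                        int(queries.particle_ids[a]), int(nb.particle_ids[b]), int(tomo),
                        zeta[0], zeta[1], zeta[2],
                        trans[0], trans[1], trans[2],
                        d, ang, axis[0], axis[1], axis[2],
                        q_in[a], n_in[b],
                    )
                )
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    records = records.sort_values(["query_id", "neighbor_id"], kind="mergesort").reset_index(drop=True)
    return TwistDescriptor(
        records=records,
        radius=float(radius),
        query_ids=queries.particle_ids.copy(),
        unit=queries.unit,
        symmetric=symmetric,
        provenance={
            "query_source": dict(queries.provenance),
            "neighbor_source": dict(nb.provenance),
            "radius": float(radius),
            "unit": queries.unit,
        },
    )


def nn_stats(pl: ParticleList) -> tuple[pd.DataFrame, pd.Series]:
    """First-nearest-neighbor distance summary, per tomogram and global.

    Used to suggest support radii.  Single-particle tomograms are excluded
    with a warning.  Returns ``(summary, per_particle_distances)``.
    """
    dists: dict[int, np.ndarray] = {}
    per_particle = {}
    for tomo in np.unique(pl.tomo_ids):
        idx = np.flatnonzero(pl.tomo_ids == tomo)
        if len(idx) < 2:
            warnings.warn(f"tomo {tomo} has <2 particles; excluded from NN stats")
            continue
        tree = cKDTree(pl.positions[idx])
        d, _ = tree.query(pl.positions[idx], k=2)
        dists[int(tomo)] = d[:, 1]
        for pid, v in zip(pl.particle_ids[idx], d[:, 1]):
            per_particle[int(pid)] = v
    if not dists:
        raise ValueError("no tomogram has at least two particles")

    def _row(v: np.ndarray) -> dict:
        return {
            "n": len(v), "min": np.min(v), "q25": np.quantile(v, 0.25),
            "median": np.median(v), "q75": np.quantile(v, 0.75), "max": np.max(v),
        }

    summary = pd.DataFrame(
        {**{f"tomo_{t}": _row(v) for t, v in dists.items()},
         "global": _row(np.concatenate(list(dists.values())))}
    ).T
    return summary, pd.Series(per_particle, name="first_nn_distance")


def proximity_clusters(td: TwistDescriptor, min_size: int = 1) -> dict[int, int | None]:
    """Affiliate particles to objects as connected components of the pair
    graph (particles are nodes, records are edges).

    Components smaller than ``min_size`` map to ``None`` (filtered out).
    Object ids are assigned in ascending order of the smallest member
    particle_id.  Asymmetric (cross-list) descriptors are refused:
    affiliation is defined on undirected graphs.
    """
    if not td.symmetric:
        raise ValueError("proximity clustering requires a symmetric (single-list) descriptor")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    ids = np.asarray(td.query_ids)
    index = {int(p): k for k, p in enumerate(ids)}
    r = td.records
    if len(r):
        i = r["query_id"].map(index).to_numpy()
        j = r["neighbor_id"].map(index).to_numpy()
        adj = coo_matrix((np.ones(len(r)), (i, j)), shape=(len(ids), len(ids)))
    else:
        adj = coo_matrix((len(ids), len(ids)))
    n_comp, labels = connected_components(adj, directed=False)
    result: dict[int, int | None] = {}
    comps: dict[int, list[int]] = {}
    for pid, lab in zip(ids, labels):
        comps.setdefault(int(lab), []).append(int(pid))
    kept = sorted(
        (members for members in comps.values() if len(members) >= min_size),
        key=lambda m: min(m),
    )
    for obj, members in enumerate(kept):
        for pid in members:
            result[pid] = obj
    for members in comps.values():
        if len(members) < min_size:
            for pid in members:
                result[pid] = None
    return result


def apply_edge_filters(td: TwistDescriptor, filters: list) -> TwistDescriptor:
    """Drop records failing any filter predicate; on symmetric descriptors
    a failing pair is removed in BOTH directions so symmetry is preserved.
    Surviving records are unchanged.  See
    :class:`twistcloud.supports.Filter` for the predicate definition."""
    r = td.records
    keep = np.ones(len(r), dtype=bool)
    for f in filters:
        keep &= f.evaluate(r)
    if td.symmetric and len(r):
        lo = np.minimum(r["query_id"], r["neighbor_id"])
        hi = np.maximum(r["query_id"], r["neighbor_id"])
        pair_key = pd.MultiIndex.from_arrays([lo, hi])
        failing = set(pair_key[~keep])
        keep &= ~pair_key.isin(failing)
    return td.with_records(r[keep], {"filters": [repr(f) for f in filters]})


def save_descriptor(td: TwistDescriptor, path) -> None:
    """Persist a descriptor as CSV with a JSON metadata header block."""
    meta = {
        "format_version": FORMAT_VERSION,
        "radius": td.radius,
        "unit": td.unit,
        "symmetric": td.symmetric,
        "query_ids": [int(q) for q in td.query_ids],
        "provenance": td.provenance,
    }
    buf = _io.StringIO()
    td.records.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write("#twistcloud-descriptor " + json.dumps(meta) + "\n")
        fh.write(buf.getvalue())


def load_descriptor(path) -> TwistDescriptor:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#twistcloud-descriptor "):
            raise ValueError(f"{path}: not a twistcloud descriptor file (bad header)")
        try:
            meta = json.loads(header.split(" ", 1)[1])
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: corrupted descriptor header") from exc
        if meta.get("format_version") != FORMAT_VERSION:
            raise ValueError(
                f"{path}: descriptor format version {meta.get('format_version')} "
                f"!= supported version {FORMAT_VERSION}"
            )
        records = pd.read_csv(fh)
        if len(records) == 0:
            records = pd.DataFrame(columns=RECORD_COLUMNS)
    return TwistDescriptor(
        records=records,
        radius=float(meta["radius"]),
        query_ids=np.asarray(meta["query_ids"], dtype=int),
        unit=meta["unit"],
        symmetric=bool(meta["symmetric"]),
        provenance=meta["provenance"],
    )
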