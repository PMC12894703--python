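"""Fixed-length per-query features computed from (reduced) twist
descriptors, and their assembly into custom descriptors.

Every feature returns one row per query particle of the source descriptor
— including queries with empty neighborhoods, which take documented fill
values (occupancy 0, distance statistics null, footprints all-false) — so
feature columns can always be concatenated into a custom descriptor.

Angular quantities are reported in degrees at this interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .descriptor import TwistDescriptor

__all__ = [
    "FeatureMatrix", "ShellDecomposition",
    "feature_occupancy", "feature_distance_stats", "decompose_shells",
    "shell_angular_profile", "link_features", "rotation_axis_histogram",
    "feature_axis_alignment", "records_axis_alignment", "shot_footprint",
    "build_custom_descriptor", "FEATURE_CATALOG", "fold_axes_to_hemisphere",
]

SHOT_CONE_AXES = np.array(
    [[0, 1, 0], [0, -1, 0], [1, 0, 0], [-1, 0, 0], [0, 0, 1], [0, 0, -1]],
    dtype=float,
)  # cone order: +y, -y, +x, -x, +z, -z


@dataclass
class FeatureMatrix:
    """Named feature columns over a fixed set of query ids."""

    table: pd.DataFrame  # indexed by query_id
    provenance: dict

    @property
    def query_ids(self) -> np.ndarray:
        return self.table.index.to_numpy()

    def merge(self, other: "FeatureMatrix") -> "FeatureMatrix":
        if not np.array_equal(np.sort(self.query_ids), np.sort(other.query_ids)):
            raise ValueError("cannot merge feature matrices over different query sets")
        merged = self.table.join(other.table.loc[self.table.index])
        prov = {**self.provenance, **{f"merged_{k}": v for k, v in other.provenance.items()}}
        return FeatureMatrix(merged, prov)

    def drop(self, columns) -> "FeatureMatrix":
        return FeatureMatrix(self.table.drop(columns=columns), dict(self.provenance))


def _empty_frame(td: TwistDescriptor) -> pd.DataFrame:
    return pd.DataFrame(index=pd.Index(td.query_ids, name="query_id"))


def feature_occupancy(td: TwistDescriptor) -> FeatureMatrix:
    """Neighbor count within the (reduced) support; isolated queries get 0."""
    out = _empty_frame(td)
    counts = td.records.groupby("query_id").size()
    out["occupancy"] = counts.reindex(out.index, fill_value=0).astype(int)
    return FeatureMatrix(out, {"feature": "occupancy"})


_STAT_FUNCS = {"min": "min", "median": "median", "mean": "mean", "std": "std"}


def feature_distance_stats(td: TwistDescriptor, statistics=("min", "median", "mean", "std")) -> FeatureMatrix:
    """Per-query statistics of Euclidean (length units) and angular
    (degrees) distances over the support; empty neighborhoods are null."""
    unknown = [s for s in statistics if s not in _STAT_FUNCS]
    if unknown:
        raise ValueError(f"unknown statistics {unknown}; choose from {sorted(_STAT_FUNCS)}")
    out = _empty_frame(td)
    r = td.records
    grouped = pd.DataFrame(
        {"euclidean": r["euclidean_distance"], "angular": np.degrees(r["angular_distance"]),
         "query_id": r["query_id"]}
    ).groupby("query_id")
    for stat in statistics:
        agg = grouped.agg(_STAT_FUNCS[stat])
        if stat == "std":
            agg = agg.fillna(0.0)  # std of a single neighbor is 0, not null
        out[f"euclidean_{stat}"] = agg["euclidean"].reindex(out.index)
        out[f"angular_{stat}"] = agg["angular"].reindex(out.index)
    return FeatureMatrix(out, {"feature": "distance_stats", "statistics": list(statistics)})


@dataclass
class ShellDecomposition:
    """Concentric distance shells: disjoint ascending closed intervals of
    pair distance, indexed from 1 (a particle's first shell is the
    smallest)."""

    shell_edges: list[tuple[float, float]]
    centers: list[float]

    def assign(self, distances: np.ndarray) -> np.ndarray:
        """Shell index per distance (0 = outside every shell)."""
        distances = np.asarray(distances, dtype=float)
        out = np.zeros(len(distances), dtype=int)
        for k, (lo, hi) in enumerate(self.shell_edges, start=1):
            out[(distances >= lo) & (distances <= hi)] = k
        return out

    def interval(self, shell: int) -> tuple[float, float]:
        return self.shell_edges[shell - 1]


def decompose_shells(td: TwistDescriptor, tolerance_fraction: float = 0.1) -> ShellDecomposition:
    """Group the sorted pair distances into shells whose spread stays
    below ``tolerance_fraction`` of the group center.

    A greedy ascending sweep: a distance opens a new shell when adding it
    would stretch the current group's spread beyond the tolerance.  Raises
    when the resulting intervals would touch (advice: smaller tolerance).
    """
    if not 0 < tolerance_fraction < 0.5:
        raise ValueError("tolerance_fraction must be in (0, 0.5)")
    ds = np.sort(td.records["euclidean_distance"].to_numpy())
    if len(ds) == 0:
        raise ValueError("descriptor has no records; no shells to decompose")
    groups: list[list[float]] = [[ds[0]]]
    for d in ds[1:]:
        g = groups[-1]
        center = (g[0] + d) / 2.0
        if d - g[0] <= tolerance_fraction * center:
            g.append(d)
        else:
            groups.append([d])
    edges = [(g[0], g[-1]) for g in groups]
    for (lo1, hi1), (lo2, hi2) in zip(edges, edges[1:]):
        if lo2 <= hi1:
            raise ValueError("shell groups overlap at this tolerance; use a smaller tolerance_fraction")
    return ShellDecomposition(edges, [float(np.mean(g)) for g in groups])


def shell_angular_profile(
    td: TwistDescriptor, shells: ShellDecomposition, score: np.ndarray | str = "angular_distance"
) -> pd.DataFrame:
    """Distribution summary of a per-pair quantity in each concentric
    shell (mean/median/quartiles/count); empty shells give null rows.

    ``score`` is a record column name (angular quantities reported in
    degrees) or a precomputed per-record array such as an angular score.
    """
    r = td.records
    if isinstance(score, str):
        values = r[score].to_numpy(dtype=float)
        if score == "angular_distance":
            values = np.degrees(values)
    else:
        values = np.asarray(score, dtype=float)
        if len(values) != len(r):
            raise ValueError("score array must have one value per record")
    shell_idx = shells.assign(r["euclidean_distance"].to_numpy())
    rows = []
    for k in range(1, len(shells.shell_edges) + 1):
        v = values[shell_idx == k]
        if len(v) == 0:
            rows.append({"shell": k, "n": 0, "mean": np.nan, "median": np.nan,
                         "q25": np.nan, "q75": np.nan})
        else:
            rows.append({"shell": k, "n": len(v), "mean": np.mean(v), "median": np.median(v),
                         "q25": np.quantile(v, 0.25), "q75": np.quantile(v, 0.75)})
    return pd.DataFrame(rows).set_index("shell")


def _link_type(n_vertices: int, degrees: np.ndarray, n_edges: int, n_components: int) -> str:
    if n_vertices == 0:
        return "empty"
    if n_components == 1 and n_edges == n_vertices and np.all(degrees == 2):
        return "closed_cycle"
    if (
        n_components == 1
        and n_edges == n_vertices - 1
        and np.sum(degrees == 1) == 2
        and np.all(degrees <= 2)
    ):
        return "open_chain"
    return "fragments"


def link_features(td: TwistDescriptor, first_shell: ShellDecomposition) -> FeatureMatrix:
    """Per-query link statistics of the first shell.

    The link of a query is the graph on its first-shell neighbors with an
    edge wherever two neighbors are themselves a first-shell distance
    apart; the central angle of an edge is the angle subtended at the
    query.  For an interior vertex of a regular flat hexagonal lattice the
    link is a closed 6-cycle with central angles of 60 degrees; a regular
    fivefold vertex gives 72 degrees.  Euler characteristic here is
    ``V - E``.
    """
    lo, hi = first_shell.interval(1)
    out = _empty_frame(td)
    cols = {c: [] for c in
            ["n_vertices", "n_edges", "euler_characteristic", "link_type",
             "median_central_angle", "std_central_angle"]}
    r = td.records
    by_query = dict(tuple(r.groupby("query_id")))
    for qid in out.index:
        sub = by_query.get(qid)
        if sub is not None:
            d = sub["euclidean_distance"].to_numpy()
            sel = (d >= lo) & (d <= hi)
            pts = sub[["trans_x", "trans_y", "trans_z"]].to_numpy()[sel]
        else:
            pts = np.zeros((0, 3))
        nv = len(pts)
        if nv == 0:
            for c, v in zip(cols, (0, 0, 0, "empty", np.nan, np.nan)):
                cols[c].append(v)
            continue
        diff = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        adj = (diff >= lo) & (diff <= hi)
        np.fill_diagonal(adj, False)
        iu, ju = np.triu_indices(nv, k=1)
        edge_mask = adj[iu, ju]
        ne = int(np.sum(edge_mask))
        degrees = adj.sum(axis=1)
        # connected components by simple label propagation
        labels = np.arange(nv)
        changed = True
        while changed:
            changed = False
            for a, b in zip(iu[edge_mask], ju[edge_mask]):
                m = min(labels[a], labels[b])
                if labels[a] != m or labels[b] != m:
                    labels[labels == labels[a]] = m
                    labels[labels == labels[b]] = m
                    changed = True
        ncomp = len(np.unique(labels))
        norms = np.linalg.norm(pts, axis=1)
        cosang = (pts @ pts.T) / np.outer(norms, norms)
        angles = np.degrees(np.arccos(np.clip(cosang[iu, ju][edge_mask], -1.0, 1.0)))
        cols["n_vertices"].append(nv)
        cols["n_edges"].append(ne)
        cols["euler_characteristic"].append(nv - ne)
        cols["link_type"].append(_link_type(nv, degrees, ne, ncomp))
        cols["median_central_angle"].append(np.median(angles) if ne else np.nan)
        cols["std_central_angle"].append(np.std(angles) if ne else np.nan)
    for c, v in cols.items():
        out[c] = v
    return FeatureMatrix(out, {"feature": "link", "first_shell": first_shell.interval(1)})


def fold_axes_to_hemisphere(axes: np.ndarray) -> np.ndarray:
    """Fold unit axes to a deterministic hemisphere representative:
    positive z, then positive y on the equator, then positive x."""
    axes = np.array(axes, dtype=float, copy=True)
    flip = (axes[:, 2] < 0) | (
        (axes[:, 2] == 0) & ((axes[:, 1] < 0) | ((axes[:, 1] == 0) & (axes[:, 0] < 0)))
    )
    axes[flip] *= -1.0
    return axes


def rotation_axis_histogram(
    td: TwistDescriptor,
    n_azimuth: int = 16,
    n_rings: int = 8,
    min_angle: float = 1e-6,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Equal-area hemispherical histogram of relative-rotation axes and
    the dominant axis.

    Axes (normalized zeta vectors of records with angular distance above
    ``min_angle`` radians) are folded to the upper hemisphere, then binned
    into ``n_rings`` equal-area rings of polar angle x ``n_azimuth``
    azimuthal sectors.

    The dominant axis is found by cap voting rather than by the modal
    histogram bin: every bin center (plus the pole, which is not a bin
    center) proposes a 15-degree spherical cap, the cap containing most
    axes wins (ties to the lowest candidate index), and the dominant axis
    is the normalized mean of the axes inside the winning cap.  Cap voting
    avoids the azimuthal fragmentation that splits a tight polar axis
    population across every sector of the top ring.
    """
    r = td.records
    eligible = r["angular_distance"].to_numpy() > min_angle
    if not np.any(eligible):
        raise ValueError("no records with a defined rotation axis")
    axes = fold_axes_to_hemisphere(r.loc[eligible, ["axis_x", "axis_y", "axis_z"]].to_numpy())
    cosl = np.clip(axes[:, 2], 0.0, 1.0)
    ring = np.minimum((n_rings * (1.0 - cosl)).astype(int), n_rings - 1)
    az = np.mod(np.arctan2(axes[:, 1], axes[:, 0]), 2 * np.pi)
    azi = np.minimum((n_azimuth * az / (2 * np.pi)).astype(int), n_azimuth - 1)
    counts = np.bincount(ring * n_azimuth + azi, minlength=n_rings * n_azimuth)
    ring_c, az_c = np.divmod(np.arange(n_rings * n_azimuth), n_azimuth)
    cos_c = 1.0 - (ring_c + 0.5) / n_rings
    sin_c = np.sqrt(1.0 - cos_c**2)
    phi_c = (az_c + 0.5) * 2 * np.pi / n_azimuth
    centers = np.column_stack([sin_c * np.cos(phi_c), sin_c * np.sin(phi_c), cos_c])
    table = pd.DataFrame(
        {
            "bin": np.arange(n_rings * n_azimuth),
            "count": counts,
            "center_x": centers[:, 0],
            "center_y": centers[:, 1],
            "center_z": centers[:, 2],
        }
    )
    candidates = np.vstack([centers, [0.0, 0.0, 1.0]])
    # 15-degree caps cover the hemisphere for the default 16 x 8 scheme
    in_cap = (axes @ candidates.T) >= np.cos(np.deg2rad(15.0))
    winner = int(np.argmax(in_cap.sum(axis=0)))
    dominant = axes[in_cap[:, winner]].mean(axis=0)
    dominant /= np.linalg.norm(dominant)
    return table, dominant


def records_axis_alignment(td: TwistDescriptor, axis_hat: np.ndarray, folded: bool = False) -> np.ndarray:
    """Per-record cosine alignment ``zeta . axis_hat / ||zeta||`` in
    [-1, 1] (NaN where zeta vanishes); ``folded=True`` returns the
    absolute value, treating the axis as unsigned."""
    axis_hat = np.asarray(axis_hat, dtype=float)
    if abs(np.linalg.norm(axis_hat) - 1.0) > 1e-9:
        raise ValueError("axis_hat must be unit-norm")
    cosv = td.records[["axis_x", "axis_y", "axis_z"]].to_numpy() @ axis_hat
    return np.abs(cosv) if folded else cosv


def feature_axis_alignment(
    td: TwistDescriptor, axis_hat: np.ndarray, reduction: str = "nearest", folded: bool = False
) -> FeatureMatrix:
    """Per-query axis alignment: the per-record cosine of the selected
    neighbor (``nearest`` by Euclidean distance, or ``extremum`` = max
    absolute alignment).  Null where the query has no neighbor or the
    selected record has zero rotation."""
    if reduction not in ("nearest", "extremum"):
        raise ValueError("reduction must be 'nearest' or 'extremum'")
    values = records_axis_alignment(td, axis_hat, folded=folded)
    r = td.records
    out = _empty_frame(td)
    sel = pd.DataFrame(
        {"query_id": r["query_id"], "value": values, "dist": r["euclidean_distance"]}
    )
    if reduction == "nearest":
        picked = sel.loc[sel.groupby("query_id")["dist"].idxmin()]
    else:
        picked = sel.assign(absval=sel["value"].abs())
        picked = picked.loc[picked.groupby("query_id")["absval"].idxmax()]
    out["axis_alignment"] = picked.set_index("query_id")["value"].reindex(out.index)
    return FeatureMatrix(out, {"feature": "axis_alignment", "reduction": reduction, "folded": folded})


def shot_footprint(td: TwistDescriptor, cone_half_angle: float = 45.0, counts: bool = False) -> FeatureMatrix:
    """Occupancy of six cones along (+y, -y, +x, -x, +z, -z) in the query
    canonical frame.

    Each neighbor belongs to the cone axis of maximal cosine (ties break
    toward the lower cone index) and must exceed ``cos(cone_half_angle)``
    to be assigned at all, so assigned neighbors are partitioned.  The
    footprint id is the binary encoding of the occupancy vector (bit i =
    cone i, starting with the +y cone); ``footprint_rank`` orders
    footprints by frequency over all queries (rank 0 = most common).
    """
    if not 0 < cone_half_angle <= 45:
        raise ValueError("cone_half_angle must be in (0, 45] degrees")
    r = td.records
    out = _empty_frame(td)
    occ = pd.DataFrame(
        0, index=out.index, columns=[f"cone_{i}" for i in range(6)], dtype=int
    )
    if len(r):
        trans = r[["trans_x", "trans_y", "trans_z"]].to_numpy()
        unit = trans / np.linalg.norm(trans, axis=1, keepdims=True)
        cosines = unit @ SHOT_CONE_AXES.T
        best = np.argmax(cosines, axis=1)  # first max wins: lower cone index on ties
        # closed half-angle boundary; epsilon absorbs rounding at exact ties
        assigned = cosines[np.arange(len(best)), best] >= np.cos(np.deg2rad(cone_half_angle)) - 1e-12
        tally = (
            pd.DataFrame({"query_id": r["query_id"].to_numpy()[assigned], "cone": best[assigned]})
            .groupby(["query_id", "cone"]).size().unstack(fill_value=0)
        )
        for c in tally.columns:
            occ.loc[tally.index, f"cone_{c}"] = tally[c].to_numpy()
    occupancy = (occ.to_numpy() > 0).astype(int)
    footprint_id = occupancy @ (1 << np.arange(6))
    if not counts:
        for i in range(6):
            occ[f"cone_{i}"] = occupancy[:, i]
    out = pd.concat([out, occ], axis=1)
    out["footprint_id"] = footprint_id
    freq = out["footprint_id"].value_counts()
    rank = {fp: k for k, fp in enumerate(freq.index)}
    out["footprint_rank"] = out["footprint_id"].map(rank)
    return FeatureMatrix(out, {"feature": "shot_footprint", "cone_half_angle": cone_half_angle,
                               "counts": counts})


FEATURE_CATALOG = {
    "occupancy": feature_occupancy,
    "distance_stats": feature_distance_stats,
    "shot_footprint": shot_footprint,
}


def build_custom_descriptor(
    td: TwistDescriptor, features: list, support=None, filters=None
) -> FeatureMatrix:
    """Apply an optional support and filter stack, then compute and
    column-concatenate the requested features.

    ``features`` entries are catalog names or callables
    ``TwistDescriptor -> FeatureMatrix``; the result can be merged with
    other matrices over the same query ids.
    """
    if not features:
        raise ValueError("at least one feature is required")
    from .descriptor import apply_edge_filters
    from .supports import reduce_descriptor

    if support is not None:
        td = reduce_descriptor(td, support)
    if filters:
        td = apply_edge_filters(td, filters)
    matrices = []
    for f in features:
        func = FEATURE_CATALOG[f] if isinstance(f, str) else f
        matrices.append(func(td))
    result = matrices[0]
    for m in matrices[1:]:
        result = result.merge(m)
    return result
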