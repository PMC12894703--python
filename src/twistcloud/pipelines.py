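"""End-to-end analysis pipelines built from the descriptor machinery:
object affiliation with geometric cleaning, pentamer labeling on
hexagonal lattices, nucleosome stack classification, dinucleosome pattern
mining, footprint-and-axis pattern mining for cross-list descriptors, and
the supporting evaluation utilities (F1 score, PCA report, rank-sum
test).

Every pipeline is deterministic given its configuration and seed: k-means
uses a fixed seed with 10 restarts and clusters are relabeled canonically
by ascending center norm, so re-runs and row permutations reproduce the
same partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .descriptor import TwistDescriptor, apply_edge_filters, compute_twist, proximity_clusters
from .features import (
    decompose_shells,
    link_features,
    records_axis_alignment,
    rotation_axis_histogram,
    shot_footprint,
)
from .particles import ParticleList, shift_along_intrinsic_axis
from .supports import Cone, Cylinder, Filter, reduce_descriptor
from .symmetry import rank_sum_test  # re-exported pipeline utility

__all__ = [
    "f1_score", "EvaluationReport", "affiliate_and_clean", "pentamer_labeling",
    "stack_classifier", "dinucleosome_finder", "footprint_axis_pipeline",
    "run_pca", "rank_sum_test", "seeded_kmeans",
]


def f1_score(tp: int, fp: int, fn: int) -> float:
    """F1 = 2TP / (2TP + FP + FN); undefined (error) when all are zero."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp == 0 and fp == 0 and fn == 0:
        raise ValueError("F1 is undefined when TP = FP = FN = 0")
    return 2.0 * tp / (2.0 * tp + fp + fn)


@dataclass
class EvaluationReport:
    tp: int
    fp: int
    fn: int
    f1: float
    per_tomo: pd.DataFrame

    @property
    def median_f1(self) -> float:
        return float(self.per_tomo["f1"].median())


def _match_to_truth(cleaned: ParticleList, truth: ParticleList) -> EvaluationReport:
    """Greedy one-to-one positional matching within half the truth's
    first-NN distance, per tomogram."""
    rows = []
    tp = fp = fn = 0
    for tomo in np.unique(np.concatenate([cleaned.tomo_ids, truth.tomo_ids])):
        c_idx = np.flatnonzero(cleaned.tomo_ids == tomo)
        t_idx = np.flatnonzero(truth.tomo_ids == tomo)
        if len(t_idx) == 0:
            tomo_tp, tomo_fn, tomo_fp = 0, 0, len(c_idx)
        elif len(c_idx) == 0:
            tomo_tp, tomo_fn, tomo_fp = 0, len(t_idx), 0
        else:
            t_pos = truth.positions[t_idx]
            if len(t_idx) > 1:
                d_nn, _ = cKDTree(t_pos).query(t_pos, k=2)
                tol = float(np.median(d_nn[:, 1])) / 2.0
            else:
                tol = np.inf
            c_pos = cleaned.positions[c_idx]
            pairs = []
            for ci in range(len(c_idx)):
                d = np.linalg.norm(t_pos - c_pos[ci], axis=1)
                for ti in np.flatnonzero(d <= tol):
                    pairs.append((d[ti], ci, ti))
            used_c: set[int] = set()
            used_t: set[int] = set()
            for _, ci, ti in sorted(pairs):
                if ci not in used_c and ti not in used_t:
                    used_c.add(ci)
                    used_t.add(ti)
            tomo_tp = len(used_c)
            tomo_fp = len(c_idx) - tomo_tp
            tomo_fn = len(t_idx) - tomo_tp
        tp, fp, fn = tp + tomo_tp, fp + tomo_fp, fn + tomo_fn
        rows.append({
            "tomo_id": int(tomo), "tp": tomo_tp, "fp": tomo_fp, "fn": tomo_fn,
            "f1": f1_score(tomo_tp, tomo_fp, tomo_fn) if (tomo_tp + tomo_fp + tomo_fn) else np.nan,
        })
    return EvaluationReport(tp, fp, fn, f1_score(tp, fp, fn), pd.DataFrame(rows))


def affiliate_and_clean(
    pl: ParticleList,
    radius: float,
    support=None,
    filters: list | None = None,
    min_component_size: int = 3,
    intrinsic_shift: tuple | None = None,
    ground_truth: ParticleList | None = None,
) -> tuple[ParticleList, EvaluationReport | None]:
    """Affiliation and cleaning in one pass.

    Optionally shift particles along an intrinsic axis (e.g. by a ring
    radius along -x so subunits of the same complex cluster tightly),
    compute the twist descriptor, reduce it by a support, drop edges
    failing the filters, and take connected components; components
    smaller than ``min_component_size`` are removed entirely (cleaning),
    the rest receive object ids.  With a ground-truth list an evaluation
    report (per-tomogram F1) is returned as well.
    """
    working = pl if intrinsic_shift is None else shift_along_intrinsic_axis(pl, *intrinsic_shift)
    td = compute_twist(working, radius=radius)
    if support is not None:
        td = reduce_descriptor(td, support)
    if filters:
        td = apply_edge_filters(td, filters)
    membership = proximity_clusters(td, min_size=min_component_size)
    obj = np.array([membership.get(int(p)) for p in pl.particle_ids], dtype=object)
    keep = np.array([o is not None for o in obj])
    cleaned = pl.select(keep)
    cleaned.meta["object_id"] = pd.array([int(o) for o in obj[keep]], dtype="Int64")
    report = _match_to_truth(cleaned, ground_truth) if ground_truth is not None else None
    return cleaned, report


def seeded_kmeans(features: np.ndarray, k: int, seed: int, n_init: int = 10) -> np.ndarray:
    """K-means with fixed seed and canonical relabeling by ascending
    cluster-center norm, so labels are stable across reruns and row
    permutations of the same point set."""
    if len(features) < k:
        raise ValueError(f"need at least k={k} points, got {len(features)}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(features)
    order = np.argsort([np.linalg.norm(c) for c in km.cluster_centers_], kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[raw]


def run_pca(features: pd.DataFrame, variance_target: float = 0.95):
    """Standardize columns, run PCA, and report the components needed to
    reach the cumulative explained-variance target plus the dominant
    original feature of each retained component.  Constant columns are
    dropped with a warning."""
    if features.shape[0] < 2 or features.shape[1] < 2:
        raise ValueError("PCA needs at least 2 rows and 2 columns")
    X = features.to_numpy(dtype=float)
    std = X.std(axis=0)
    const = std == 0
    if const.any():
        warnings.warn(f"dropping constant columns {list(features.columns[const])}")
        features = features.loc[:, ~const]
        X, std = X[:, ~const], std[~const]
    Z = (X - X.mean(axis=0)) / std
    pca = PCA()
    scores = pca.fit_transform(Z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cum, variance_target) + 1)
    n_keep = min(n_keep, len(cum))
    loadings = pd.DataFrame(
        pca.components_[:n_keep].T, index=features.columns,
        columns=[f"PC{i+1}" for i in range(n_keep)],
    )
    report = pd.DataFrame({
        "component": [f"PC{i+1}" for i in range(n_keep)],
        "explained_variance_ratio": pca.explained_variance_ratio_[:n_keep],
        "cumulative": cum[:n_keep],
        "dominant_feature": [loadings.iloc[:, i].abs().idxmax() for i in range(n_keep)],
    })
    return scores[:, :n_keep], report, loadings


def pentamer_labeling(
    pl: ParticleList,
    radius: float,
    shell_tolerance: float = 0.15,
    variance_target: float = 0.95,
    seed: int = 0,
) -> pd.Series:
    """Label lattice vertices as pentamer or hexamer defects-in-context.

    First-shell link statistics (median and STD of central angles, vertex
    count) are standardized, reduced by PCA to the components explaining
    the variance target, and split by 2-means; the cluster whose median
    central angle is nearer 72 degrees (the regular fivefold value, vs 60
    for flat hexagons) is labeled pentamer.  Degenerate single-cluster
    data comes back all-hexamer with a warning.
    """
    td = compute_twist(pl, radius=radius)
    shells = decompose_shells(td, tolerance_fraction=shell_tolerance)
    fm = link_features(td, shells)
    feats = fm.table[["median_central_angle", "std_central_angle", "n_vertices"]].copy()
    valid = feats.notna().all(axis=1)
    labels = pd.Series("hexamer", index=fm.table.index, name="label")
    sub = feats[valid]
    if len(sub) < 2 or sub.nunique().max() < 2:
        warnings.warn("degenerate lattice features; labeling everything hexamer")
        return labels
    scores, _, _ = run_pca(sub, variance_target)
    if scores.shape[1] == 0 or np.allclose(scores.std(axis=0), 0):
        warnings.warn("degenerate lattice features; labeling everything hexamer")
        return labels
    assign = seeded_kmeans(scores, k=2, seed=seed)
    medians = [sub["median_central_angle"][assign == c].median() for c in (0, 1)]
    pent_cluster = int(np.argmin([abs(m - 72.0) for m in medians]))
    if abs(medians[pent_cluster] - 72.0) > abs(medians[pent_cluster] - 60.0):
        warnings.warn("no cluster centered near 72 degrees; labeling everything hexamer")
        return labels
    labels.loc[sub.index[assign == pent_cluster]] = "pentamer"
    return labels


def stack_classifier(
    pl: ParticleList,
    radius: float = 10.0,
    cylinder_radius: float = 3.0,
    cylinder_height: float = 8.0,
    angular_window: tuple[float, float] = (5.0, 25.0),
    class_labels: pd.Series | None = None,
) -> tuple[pd.Series, dict[str, float]]:
    """Detect stacked particles with a one-sided cylindrical support along
    the intrinsic +y axis and an angular-distance window.

    A surviving record pins down a stacked pair; BOTH its endpoints are
    marked stacked (detection is at the pair level: the one-sided support
    sees the pair from its lower member, the partner is stacked all the
    same).  Returns per-particle boolean labels and, when ground-truth
    class labels are available, the stacked fraction per class in
    percent.
    """
    td = compute_twist(pl, radius=radius)
    cyl = Cylinder(radius=cylinder_radius, axial_range=(0.0, cylinder_height), axis=(0, 1, 0))
    td = reduce_descriptor(td, cyl)
    lo, hi = angular_window
    ang = np.degrees(td.records["angular_distance"].to_numpy())
    td = td.with_records(td.records[(ang >= lo) & (ang <= hi)])
    detected = set(td.particle_ids_present())
    labels = pd.Series(
        [int(p) in detected for p in pl.particle_ids],
        index=pd.Index(pl.particle_ids, name="particle_id"),
        name="stacked",
    )
    if class_labels is None:
        class_labels = pl.meta.set_index("particle_id")["class_label"]
    fractions = {}
    cl = class_labels.reindex(labels.index)
    for c in cl.dropna().unique():
        mask = cl == c
        fractions[str(c)] = float(100.0 * labels[mask].mean())
    return labels, fractions


def dinucleosome_finder(
    pl: ParticleList,
    radius: float = 30.0,
    cone_half_angle: float = 30.0,
    cone_height: float = 25.0,
    k_clusters: int = 15,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mine linker-connected (dinucleosome-like) pairs.

    The twist descriptor is reduced to double-cone supports along the
    intrinsic +/-z axes (the DNA entry/exit direction), the dominant
    relative-rotation axis is found by hemispherical binning, and each
    record is described by three features: Euclidean distance, angular
    distance, and the magnitude of the rotation-axis alignment with the
    dominant axis (folded, since a record and its reverse carry
    opposite-sign axes for the same physical pair).  Features are
    standardized and clustered by seeded k-means.

    Returns ``(records, report)``: the per-record cluster assignments,
    and a per-cluster report with feature medians and — per ground-truth
    class — the percentage of that class's particles having at least one
    record in the cluster.
    """
    td = compute_twist(pl, radius=radius)
    cone = Cone(half_angle_deg=cone_half_angle, height=cone_height, axis=(0, 0, 1), mirror=True)
    td = reduce_descriptor(td, cone)
    if len(td.records) < k_clusters:
        raise ValueError("fewer cone records than clusters; enlarge the support or lower k")
    _, dominant = rotation_axis_histogram(td)
    feats = pd.DataFrame({
        "euclidean_distance": td.records["euclidean_distance"].to_numpy(),
        "angular_distance": np.degrees(td.records["angular_distance"].to_numpy()),
        "axis_alignment": records_axis_alignment(td, dominant, folded=True),
    })
    feats["axis_alignment"] = feats["axis_alignment"].fillna(0.0)
    X = feats.to_numpy()
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    assign = seeded_kmeans(Z, k=k_clusters, seed=seed)
    records = td.records[["query_id", "neighbor_id"]].copy()
    records["cluster"] = assign
    for c in feats.columns:
        records[c] = feats[c].to_numpy()

    class_of = pl.meta.set_index("particle_id")["class_label"]
    class_sizes = class_of.value_counts()
    rows = []
    for c in range(k_clusters):
        sub = records[records["cluster"] == c]
        row = {
            "cluster": c, "n_records": len(sub),
            "median_euclidean": sub["euclidean_distance"].median(),
            "median_angular": sub["angular_distance"].median(),
            "median_alignment": sub["axis_alignment"].median(),
        }
        members = set(sub["query_id"])
        for label, total in class_sizes.items():
            ids = class_of.index[class_of == label]
            row[f"pct_{label}"] = 100.0 * sum(int(i) in members for i in ids) / total
        rows.append(row)
    report = pd.DataFrame(rows).set_index("cluster")
    report.attrs["dominant_axis"] = dominant
    return records, report


def footprint_axis_pipeline(
    queries: ParticleList,
    neighbors: ParticleList,
    radius: float,
    cone_half_angle: float = 45.0,
    n_ranges: int = 5,
    top_footprints: int = 3,
) -> list[dict]:
    """Characterize cross-list neighborhoods by SHOT footprint, dominant
    rotation axis, and rotation-angle sub-bins.

    For each of the most frequent footprints: records of queries showing
    that footprint are pooled, their modal rotation-axis bin is found, and
    the modal bin's records are partitioned into ``n_ranges`` equal-width
    angular-distance ranges; each range reports its medoid record as the
    representative pair.  Footprints with too few records collapse their
    ranges with a warning.
    """
    td = compute_twist(queries, neighbors, radius=radius)
    fm = shot_footprint(td, cone_half_angle=cone_half_angle)
    table = fm.table
    reports: list[dict] = []
    ranked = (
        table[table["footprint_id"] > 0]["footprint_id"].value_counts().index[:top_footprints]
    )
    for fp in ranked:
        qids = table.index[table["footprint_id"] == fp]
        sub = td.with_records(td.records[td.records["query_id"].isin(qids)])
        hist, dominant = rotation_axis_histogram(sub)
        align = records_axis_alignment(sub, dominant, folded=True)
        modal = sub.records[align >= np.cos(np.deg2rad(30.0))]  # records of the modal axis
        ang = np.degrees(modal["angular_distance"].to_numpy())
        n_r = n_ranges
        if len(modal) < n_ranges:
            warnings.warn(f"footprint {fp}: only {len(modal)} modal records; ranges collapsed")
            n_r = 1
        edges = np.linspace(ang.min(), ang.max() + 1e-9, n_r + 1)
        ranges = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            in_range = modal[(ang >= lo) & (ang < hi)]
            if len(in_range) == 0:
                ranges.append({"range_deg": (lo, hi), "n": 0, "representative": None})
                continue
            f = np.column_stack([
                in_range["euclidean_distance"].to_numpy(),
                np.degrees(in_range["angular_distance"].to_numpy()),
            ])
            zf = (f - f.mean(axis=0)) / np.where(f.std(axis=0) == 0, 1, f.std(axis=0))
            cost = np.linalg.norm(zf[:, None, :] - zf[None, :, :], axis=2).sum(axis=1)
            medoid = in_range.iloc[int(np.argmin(cost))]
            ranges.append({
                "range_deg": (float(lo), float(hi)), "n": len(in_range),
                "representative": (int(medoid["query_id"]), int(medoid["neighbor_id"])),
            })
        reports.append({
            "footprint_id": int(fp), "n_queries": int((table["footprint_id"] == fp).sum()),
            "dominant_axis": dominant, "axis_histogram": hist, "ranges": ranges,
        })
    return reports
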