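"""Per-query features: occupancy, distance statistics, shell
decomposition, link statistics, rotation-axis histograms, axis alignment,
SHOT footprints and custom-descriptor assembly."""

import numpy as np
import pandas as pd
import pytest

from twistcloud import geometry
from twistcloud.descriptor import compute_twist
from twistcloud.features import (
    build_custom_descriptor,
    decompose_shells,
    feature_axis_alignment,
    feature_distance_stats,
    feature_occupancy,
    fold_axes_to_hemisphere,
    link_features,
    records_axis_alignment,
    rotation_axis_histogram,
    shell_angular_profile,
    shot_footprint,
)
from twistcloud.particles import ParticleList
from twistcloud.supports import Sphere
from twistcloud.synthetic import generate_planar_lattice, rotation_about

from conftest import random_particle_list


def lattice_descriptor(shells=3, spacing=10.0, radius=None, sampler="identity", seed=0):
    pl = generate_planar_lattice(
        shells=shells, spacing=spacing, orientation_sampler=sampler, seed=seed
    )
    return pl, compute_twist(pl, radius=radius or spacing * 2.05)


class TestOccupancy:
    def test_isolated_particle_zero(self):
        pl = ParticleList.from_arrays(
            np.array([[0.0, 0, 0], [100.0, 0, 0], [100.0, 5, 0]]),
            np.stack([np.eye(3)] * 3),
        )
        td = compute_twist(pl, radius=10.0)
        fm = feature_occupancy(td)
        assert fm.table.loc[0, "occupancy"] == 0
        assert fm.table.loc[1, "occupancy"] == 1
        assert len(fm.table) == 3  # fixed-length contract

    def test_lattice_interior_vertex_has_six(self):
        pl, td = lattice_descriptor(shells=2, radius=10.5)
        fm = feature_occupancy(td)
        center = pl.particle_ids[np.argmin(np.linalg.norm(pl.positions, axis=1))]
        assert fm.table.loc[center, "occupancy"] == 6

    def test_matches_brute_force_count(self, rng):
        pl = random_particle_list(rng, 100, box=50.0)
        td = compute_twist(pl, radius=12.0)
        fm = feature_occupancy(td)
        d = np.linalg.norm(pl.positions[:, None] - pl.positions[None], axis=2)
        np.fill_diagonal(d, np.inf)
        expected = (d <= 12.0).sum(axis=1)
        assert np.array_equal(fm.table["occupancy"].loc[pl.particle_ids].to_numpy(), expected)


class TestDistanceStats:
    def test_single_neighbor(self):
        pl = ParticleList.from_arrays(
            np.array([[0.0, 0, 0], [5.0, 0, 0]]), np.stack([np.eye(3)] * 2)
        )
        td = compute_twist(pl, radius=10.0)
        fm = feature_distance_stats(td)
        row = fm.table.loc[0]
        assert row["euclidean_min"] == row["euclidean_median"] == row["euclidean_mean"] == 5.0
        assert row["euclidean_std"] == 0.0

    def test_empty_neighborhood_is_null(self):
        pl = ParticleList.from_arrays(
            np.array([[0.0, 0, 0], [100.0, 0, 0], [105.0, 0, 0]]),
            np.stack([np.eye(3)] * 3),
        )
        td = compute_twist(pl, radius=10.0)
        fm = feature_distance_stats(td, statistics=("median",))
        assert np.isnan(fm.table.loc[0, "euclidean_median"])

    def test_unknown_statistic_rejected(self, rng):
        pl = random_particle_list(rng, 10, box=10.0)
        td = compute_twist(pl, radius=5.0)
        with pytest.raises(ValueError, match="kurtosis"):
            feature_distance_stats(td, statistics=("kurtosis",))

    def test_matches_direct_computation(self, rng):
        pl = random_particle_list(rng, 60, box=40.0)
        td = compute_twist(pl, radius=15.0)
        fm = feature_distance_stats(td, statistics=("mean",))
        r = td.records
        for qid, sub in r.groupby("query_id"):
            assert np.isclose(fm.table.loc[qid, "euclidean_mean"], sub["euclidean_distance"].mean())
            assert np.isclose(
                fm.table.loc[qid, "angular_mean"], np.degrees(sub["angular_distance"]).mean()
            )


class TestShells:
    def test_triangular_lattice_first_three_shells(self):
        """Exact lattice distance enumeration: shells at a, sqrt(3) a, 2a."""
        _, td = lattice_descriptor(shells=3, spacing=10.0, radius=20.5)
        shells = decompose_shells(td, tolerance_fraction=0.1)
        assert len(shells.centers) == 3
        assert np.allclose(shells.centers, [10.0, 10.0 * np.sqrt(3), 20.0], atol=1e-9)

    def test_single_distance_single_shell(self):
        pl = ParticleList.from_arrays(
            np.array([[0.0, 0, 0], [5.0, 0, 0]]), np.stack([np.eye(3)] * 2)
        )
        shells = decompose_shells(compute_twist(pl, radius=10.0))
        assert len(shells.centers) == 1

    def test_noisy_lattice_same_shell_count(self, rng):
        pl = generate_planar_lattice(shells=3, spacing=10.0, orientation_sampler="identity")
        pl.positions = pl.positions + rng.normal(0, 0.05, pl.positions.shape)
        td = compute_twist(pl, radius=20.5)
        shells = decompose_shells(td, tolerance_fraction=0.1)
        assert len(shells.centers) == 3

    def test_assignment_covers_all_records(self):
        _, td = lattice_descriptor(shells=3, spacing=10.0, radius=20.5)
        shells = decompose_shells(td, tolerance_fraction=0.1)
        idx = shells.assign(td.records["euclidean_distance"].to_numpy())
        assert (idx > 0).all()

    def test_bad_tolerance_rejected(self):
        _, td = lattice_descriptor(shells=2)
        with pytest.raises(ValueError):
            decompose_shells(td, tolerance_fraction=0.7)


class TestShellAngularProfile:
    def test_identical_orientations_score_one_everywhere(self):
        _, td = lattice_descriptor(shells=3, spacing=10.0, radius=20.5, sampler="identity")
        shells = decompose_shells(td)
        ones = np.ones(len(td.records))
        prof = shell_angular_profile(td, shells, score=ones)
        assert np.allclose(prof["mean"], 1.0)

    def test_c6_lattice_supported_on_multiples_of_60(self):
        _, td = lattice_descriptor(
            shells=3, spacing=10.0, radius=20.5, sampler="c_n_multiples", seed=3
        )
        shells = decompose_shells(td)
        prof = shell_angular_profile(td, shells, score="angular_distance")
        ang = np.degrees(td.records["angular_distance"].to_numpy())
        folded = np.min(np.abs(ang[:, None] - np.array([[0, 60, 120, 180]])), axis=1)
        assert folded.max() < 1e-6
        assert prof.loc[1, "n"] > 0

    def test_mean_matches_direct_recomputation(self, rng):
        pl = random_particle_list(rng, 50, box=40.0)
        td = compute_twist(pl, radius=18.0)
        shells = decompose_shells(td, tolerance_fraction=0.45)
        prof = shell_angular_profile(td, shells, score="euclidean_distance")
        idx = shells.assign(td.records["euclidean_distance"].to_numpy())
        for k in prof.index:
            v = td.records["euclidean_distance"].to_numpy()[idx == k]
            if len(v):
                assert np.isclose(prof.loc[k, "mean"], v.mean())


class TestLinkFeatures:
    def test_hexagonal_interior_vertex(self):
        pl, td = lattice_descriptor(shells=2, spacing=10.0, radius=20.5)
        shells = decompose_shells(td)
        fm = link_features(td, shells)
        center = pl.particle_ids[np.argmin(np.linalg.norm(pl.positions, axis=1))]
        row = fm.table.loc[center]
        assert row["n_vertices"] == 6
        assert row["n_edges"] == 6
        assert row["euler_characteristic"] == 0
        assert row["link_type"] == "closed_cycle"
        assert np.isclose(row["median_central_angle"], 60.0, atol=1e-9)
        assert row["std_central_angle"] < 1e-9

    def test_fivefold_vertex(self):
        # regular pentagon of neighbors around the origin
        phis = 2 * np.pi * np.arange(5) / 5
        spacing = 10.0
        pos = np.vstack(
            [[0.0, 0, 0], spacing * np.column_stack([np.cos(phis), np.sin(phis), np.zeros(5)])]
        )
        pl = ParticleList.from_arrays(pos, np.stack([np.eye(3)] * 6))
        td = compute_twist(pl, radius=13.0)
        # pentagon edge (2 a sin 36 ~ 1.18 a) groups with the spoke length a
        shells = decompose_shells(td, tolerance_fraction=0.2)
        fm = link_features(td, shells)
        row = fm.table.loc[0]
        assert row["n_vertices"] == 5
        assert np.isclose(row["median_central_angle"], 72.0, atol=1e-9)

    def test_all_interior_vertices_closed_cycles(self):
        pl, td = lattice_descriptor(shells=3, spacing=10.0, radius=20.5)
        shells = decompose_shells(td)
        fm = link_features(td, shells)
        interior = np.linalg.norm(pl.positions, axis=1) < 2 * 10.0 - 1e-6
        sub = fm.table.loc[pl.particle_ids[interior]]
        assert (sub["link_type"] == "closed_cycle").all()
        assert np.allclose(sub["median_central_angle"], 60.0, atol=1e-9)

    def test_open_chain_detected(self):
        pos = np.array([[0.0, 0, 0], [10.0, 0, 0], [5.0, 8.66, 0], [-5.0, 8.66, 0]])
        pl = ParticleList.from_arrays(pos, np.stack([np.eye(3)] * 4))
        td = compute_twist(pl, radius=10.5)
        shells = decompose_shells(td, tolerance_fraction=0.1)
        fm = link_features(td, shells)
        assert fm.table.loc[0, "link_type"] == "open_chain"


class TestRotationAxisHistogram:
    def _descriptor_with_axes(self, axes, rng=None, wobble_deg=0.0):
        """Descriptor whose records carry exactly the given rotation axes
        (optionally wobbled), built by editing a template record."""
        pl = ParticleList.from_arrays(
            np.array([[0.0, 0, 0], [5.0, 0, 0]]), np.stack([np.eye(3)] * 2)
        )
        td = compute_twist(pl, radius=10.0)
        base = td.records.iloc[0]
        rows = []
        for ax in axes:
            ax = np.asarray(ax, dtype=float)
            if wobble_deg:
                ax = ax + rng.normal(0, np.deg2rad(wobble_deg), 3)
            ax /= np.linalg.norm(ax)
            row = base.copy()
            row["axis_x"], row["axis_y"], row["axis_z"] = ax
            row["angular_distance"] = 0.5
            rows.append(row)
        return td.with_records(pd.DataFrame(rows))

    def test_all_axes_z_dominant_axis_z(self):
        td = self._descriptor_with_axes([[0, 0, 1]] * 6)
        _, dominant = rotation_axis_histogram(td)
        assert abs(dominant @ np.array([0, 0, 1.0])) > 0.999

    def test_majority_axis_wins(self, rng):
        axes = [[0, 0, 1]] * 70 + [[1, 0, 0]] * 30
        td = self._descriptor_with_axes(axes, rng=rng, wobble_deg=3.0)
        _, dominant = rotation_axis_histogram(td)
        assert abs(dominant @ np.array([0, 0, 1.0])) > 0.99

    def test_uniform_axes_no_runaway_bin(self, rng):
        """Counts of a uniform axis distribution stay within 5 sigma of the
        multinomial expectation in every equal-area bin."""
        n_records = 6000
        pl = random_particle_list(rng, 2, box=5.0)
        td = compute_twist(pl, radius=100.0)
        rows = []
        base = td.records.iloc[0]
        for _ in range(n_records):
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            row = base.copy()
            row["axis_x"], row["axis_y"], row["axis_z"] = v
            row["angular_distance"] = 0.5
            rows.append(row)
        td2 = td.with_records(pd.DataFrame(rows))
        table, _ = rotation_axis_histogram(td2, n_azimuth=16, n_rings=8)
        expected = n_records / 128
        sigma = np.sqrt(expected)
        assert table["count"].max() < expected + 5 * sigma

    def test_no_eligible_records_rejected(self):
        pl = ParticleList.from_arrays(
            np.array([[0.0, 0, 0], [5.0, 0, 0]]), np.stack([np.eye(3)] * 2)
        )
        td = compute_twist(pl, radius=10.0)
        with pytest.raises(ValueError, match="axis"):
            rotation_axis_histogram(td)

    def test_fold_convention(self):
        axes = fold_axes_to_hemisphere(np.array([[0, 0, -1.0], [0, -1.0, 0], [-1.0, 0, 0]]))
        assert (axes >= 0).all()


class TestAxisAlignment:
    def test_parallel_and_perpendicular(self):
        pl = ParticleList.from_arrays(
            np.array([[0.0, 0, 0], [5.0, 0, 0], [0.0, 5, 0]]),
            np.stack([np.eye(3), rotation_about((0, 0, 1), 30), rotation_about((1, 0, 0), 30)]),
        )
        td = compute_twist(pl, radius=10.0)
        vals = records_axis_alignment(td, np.array([0, 0, 1.0]))
        r = td.records
        par = vals[(r["query_id"] == 0) & (r["neighbor_id"] == 1)][0]
        perp = vals[(r["query_id"] == 0) & (r["neighbor_id"] == 2)][0]
        assert np.isclose(par, 1.0, atol=1e-9)
        assert np.isclose(perp, 0.0, atol=1e-9)

    def test_matches_dot_product_oracle(self, rng):
        pl = random_particle_list(rng, 40, box=30.0)
        td = compute_twist(pl, radius=15.0)
        axis = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        vals = records_axis_alignment(td, axis)
        zeta = td.records[["zeta_x", "zeta_y", "zeta_z"]].to_numpy()
        expected = zeta @ axis / np.linalg.norm(zeta, axis=1)
        assert np.allclose(vals, expected, atol=1e-9)

    def test_per_query_nearest_reduction(self, rng):
        pl = random_particle_list(rng, 40, box=30.0)
        td = compute_twist(pl, radius=15.0)
        fm = feature_axis_alignment(td, np.array([0, 0, 1.0]), reduction="nearest")
        assert len(fm.table) == len(pl)
        r = td.records
        for qid, sub in r.groupby("query_id"):
            nearest = sub.loc[sub["euclidean_distance"].idxmin()]
            expected = nearest[["zeta_x", "zeta_y", "zeta_z"]].to_numpy() @ [0, 0, 1.0]
            expected /= nearest["angular_distance"]
            assert np.isclose(fm.table.loc[qid, "axis_alignment"], expected, atol=1e-9)


class TestShotFootprint:
    def _pl_with_neighbors(self, offsets):
        pos = np.vstack([[0.0, 0, 0], offsets])
        return ParticleList.from_arrays(pos, np.stack([np.eye(3)] * len(pos)))

    def test_single_neighbor_plus_y(self):
        pl = self._pl_with_neighbors([[0.0, 7.0, 0.0]])
        td = compute_twist(pl, radius=10.0)
        fm = shot_footprint(td, cone_half_angle=45.0)
        row = fm.table.loc[0]
        assert row["cone_0"] == 1 and row[["cone_1", "cone_2", "cone_3", "cone_4", "cone_5"]].sum() == 0
        assert row["footprint_id"] == 1

    def test_tie_break_to_lower_cone_index(self):
        # exactly between +y (cone 0) and +x (cone 2): lower index wins
        pl = self._pl_with_neighbors([[5.0, 5.0, 0.0]])
        td = compute_twist(pl, radius=10.0)
        fm = shot_footprint(td, cone_half_angle=45.0)
        assert fm.table.loc[0, "footprint_id"] == 1

    def test_partition_no_double_counting(self, rng):
        pl = random_particle_list(rng, 60, box=40.0)
        td = compute_twist(pl, radius=15.0)
        fm = shot_footprint(td, cone_half_angle=40.0, counts=True)
        assigned = fm.table[[f"cone_{i}" for i in range(6)]].to_numpy().sum()
        # brute-force cone assignment
        trans = td.records[["trans_x", "trans_y", "trans_z"]].to_numpy()
        unit = trans / np.linalg.norm(trans, axis=1, keepdims=True)
        from twistcloud.features import SHOT_CONE_AXES

        cos = unit @ SHOT_CONE_AXES.T
        expected = (cos.max(axis=1) >= np.cos(np.deg2rad(40.0))).sum()
        assert assigned == expected

    def test_half_angle_validated(self, rng):
        pl = random_particle_list(rng, 5, box=10.0)
        td = compute_twist(pl, radius=5.0)
        with pytest.raises(ValueError):
            shot_footprint(td, cone_half_angle=60.0)


class TestCustomDescriptor:
    def test_single_feature(self, rng):
        pl = random_particle_list(rng, 30, box=30.0)
        td = compute_twist(pl, radius=12.0)
        fm = build_custom_descriptor(td, ["occupancy"])
        assert list(fm.table.columns) == ["occupancy"]

    def test_merge_equals_joint_build(self, rng):
        pl = random_particle_list(rng, 30, box=30.0)
        td = compute_twist(pl, radius=12.0)
        sup = Sphere(8.0)
        joint = build_custom_descriptor(td, ["occupancy", "distance_stats"], support=sup)
        merged = build_custom_descriptor(td, ["occupancy"], support=sup).merge(
            build_custom_descriptor(td, ["distance_stats"], support=sup)
        )
        pd.testing.assert_frame_equal(joint.table, merged.table)

    def test_drop_then_merge_restores(self, rng):
        pl = random_particle_list(rng, 20, box=20.0)
        td = compute_twist(pl, radius=10.0)
        both = build_custom_descriptor(td, ["occupancy", "distance_stats"])
        occ_only = both.drop([c for c in both.table.columns if c != "occupancy"])
        restored = occ_only.merge(build_custom_descriptor(td, ["distance_stats"]))
        pd.testing.assert_frame_equal(restored.table, both.table)

    def test_mismatched_query_sets_rejected(self, rng):
        pl1 = random_particle_list(rng, 20, box=20.0)
        pl2 = random_particle_list(rng, 25, box=20.0)
        fm1 = feature_occupancy(compute_twist(pl1, radius=8.0))
        fm2 = feature_occupancy(compute_twist(pl2, radius=8.0))
        with pytest.raises(ValueError, match="query"):
            fm1.merge(fm2)

    def test_empty_feature_list_rejected(self, rng):
        pl = random_particle_list(rng, 10, box=10.0)
        td = compute_twist(pl, radius=5.0)
        with pytest.raises(ValueError):
            build_custom_descriptor(td, [])


def test_features_invariant_under_global_motion(rng):
    """End-to-end rotational invariance: feature values do not change when
    the whole scene undergoes a rigid motion."""
    from test_twist_engine import apply_global_motion

    pl = random_particle_list(rng, 40, box=30.0)
    moved = apply_global_motion(pl, geometry.random_rotation(rng), rng.normal(size=3) * 20)
    fm1 = build_custom_descriptor(compute_twist(pl, radius=14.0), ["occupancy", "distance_stats"])
    fm2 = build_custom_descriptor(compute_twist(moved, radius=14.0), ["occupancy", "distance_stats"])
    a, b = fm1.table.to_numpy(float), fm2.table.to_numpy(float)
    mask = ~np.isnan(a)
    assert np.abs(a - b)[mask].max() < 1e-8
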