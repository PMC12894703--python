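"""Analysis pipelines: F1 evaluation, affiliation and cleaning, pentamer
labeling, stack classification, dinucleosome mining, footprint mining,
PCA reporting and determinism."""

import numpy as np
import pandas as pd
import pytest

from twistcloud import geometry, pipelines as pp
from twistcloud.particles import ParticleList, shift_along_intrinsic_axis
from twistcloud.supports import Filter
from twistcloud.synthetic import (
    ChromatinSpec,
    generate_chromatin,
    generate_ring,
    generate_spherical_lattice,
    rotation_about,
)

from conftest import random_particle_list


class TestF1:
    def test_closed_form_examples(self):
        assert pp.f1_score(8, 2, 2) == 0.8
        assert pp.f1_score(17, 0, 0) == 1.0

    def test_matches_precision_recall_harmonic_mean(self, rng):
        for _ in range(50):
            tp, fp, fn = rng.integers(1, 100, 3)
            precision = tp / (tp + fp)
            recall = tp / (tp + fn)
            expected = 2 * precision * recall / (precision + recall)
            assert np.isclose(pp.f1_score(tp, fp, fn), expected)

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError):
            pp.f1_score(0, 0, 0)


def outlier_list(rng, n, id_offset, spread=800.0, offset=1500.0):
    pos = rng.uniform(-spread, spread, (n, 3))
    pos[:, 2] += offset  # far from the scene of interest
    return ParticleList.from_arrays(
        pos,
        np.stack([geometry.random_rotation(rng) for _ in range(n)]),
        particle_ids=np.arange(n) + id_offset,
    )


class TestAffiliateAndClean:
    def test_ring_plus_outliers_perfect_f1(self, rng):
        """Affiliation recovers the ring and drops every isolated outlier
        across many seeds (F1 = 1 on construction-perfect scenes)."""
        edge = 2 * 50.0 * np.sin(np.pi / 8)
        for seed in range(50):
            rng_i = np.random.default_rng(seed)
            ring = generate_ring(8, radius=50.0)
            scene = ring.concat(outlier_list(rng_i, 30, id_offset=100))
            cleaned, report = pp.affiliate_and_clean(
                scene, radius=edge * 1.1, min_component_size=3, ground_truth=ring
            )
            assert report.f1 == 1.0
            assert len(cleaned) == 8

    def test_two_rings_two_objects(self):
        r1 = generate_ring(8, radius=50.0, object_id=0)
        r2 = generate_ring(8, radius=50.0, center=(500.0, 0, 0), object_id=1, id_offset=8)
        scene = r1.concat(r2)
        edge = 2 * 50.0 * np.sin(np.pi / 8)
        cleaned, _ = pp.affiliate_and_clean(scene, radius=edge * 1.1, min_component_size=3)
        assert cleaned.meta["object_id"].nunique() == 2

    def test_angular_filter_excludes_misoriented_subunit(self):
        """A ring subunit with a 90-degree-wrong in-plane angle fails a C8
        angular window (multiples of 45 +/- 10 degrees) and is cleaned."""
        ring = generate_ring(8, radius=50.0)
        bad = 3
        ring.rotations[bad] = ring.rotations[bad] @ rotation_about((0, 0, 1), 90 + 22.5)
        edge = 2 * 50.0 * np.sin(np.pi / 8)
        filters = [Filter("angular_distance", 35.0, 55.0)]  # window around 45
        cleaned, _ = pp.affiliate_and_clean(
            ring, radius=edge * 1.1, filters=filters, min_component_size=3
        )
        assert int(ring.particle_ids[bad]) not in set(cleaned.particle_ids)
        assert len(cleaned) == 7

    def test_intrinsic_shift_tightens_ring(self):
        """Shifting subunits inward by (nearly) the ring radius pulls each
        ring together, so a much smaller support suffices for affiliation."""
        r1 = generate_ring(8, radius=50.0, object_id=0)
        r2 = generate_ring(8, radius=50.0, center=(200.0, 0, 0), object_id=1, id_offset=8)
        scene = r1.concat(r2)
        cleaned, _ = pp.affiliate_and_clean(
            scene, radius=5.0, min_component_size=3,
            intrinsic_shift=(np.array([-1.0, 0, 0]), 47.0),
        )
        assert len(cleaned) == 16
        assert cleaned.meta["object_id"].nunique() == 2


class TestPentamerLabeling:
    def test_icosphere_fivefold_vertices_recovered(self):
        sph = generate_spherical_lattice(radius=100.0, subdivisions=2)
        labels = pp.pentamer_labeling(sph, radius=45.0, shell_tolerance=0.2)
        truth = sph.meta.set_index("particle_id")["class_label"]
        assert ((labels == "pentamer").to_numpy() == (truth == "fivefold").to_numpy()).all()

    def test_pure_hexagonal_lattice_no_pentamers(self):
        from twistcloud.synthetic import generate_planar_lattice

        pl = generate_planar_lattice(shells=4, spacing=10.0, orientation_sampler="identity")
        with pytest.warns(UserWarning):
            labels = pp.pentamer_labeling(pl, radius=20.5)
        assert (labels == "hexamer").all()


class TestStackClassifier:
    def test_reference_composition_fractions(self, chromatin_small):
        pl, truth = chromatin_small
        _, fractions = pp.stack_classifier(pl)
        assert np.isclose(fractions["stack"], 100.0)
        assert np.isclose(fractions["tri"], 200.0 / 3.0, atol=1e-9)
        assert np.isclose(fractions["helix"], 1000.0 / 12.0, atol=1e-9)

    def test_mono_false_positive_rate_low(self, chromatin_small):
        pl, _ = chromatin_small
        _, fractions = pp.stack_classifier(pl)
        assert fractions["mono"] < 5.0

    def test_empty_scene_no_labels(self):
        empty = ParticleList.from_arrays(np.zeros((0, 3)), np.zeros((0, 3, 3)))
        labels, fractions = pp.stack_classifier(empty)
        assert len(labels) == 0 and fractions == {}

    def test_detected_particles_come_in_pairs(self, chromatin_small):
        """Pair-level detection: every stacked-labeled particle has its
        ground-truth partner labeled as well (non-widened pairs)."""
        pl, truth = chromatin_small
        labels, _ = pp.stack_classifier(pl)
        partner = truth.set_index("particle_id")["stacked_partner"]
        for pid in labels.index[labels]:
            p = partner.loc[pid]
            if p >= 0:
                assert labels.loc[p]


class TestDinucleosomeFinder:
    def test_helix_and_tri_in_one_cluster(self, chromatin_small):
        pl, _ = chromatin_small
        _, report = pp.dinucleosome_finder(pl, seed=13)
        best = report["pct_helix"].idxmax()
        assert report.loc[best, "pct_helix"] == 100.0
        assert report.loc[best, "pct_tri"] == 100.0
        assert np.isclose(report.loc[best, "median_euclidean"], 24.5, atol=1.5)

    def test_single_block_scene_one_cluster_of_records(self):
        spec = ChromatinSpec(n_helix=0, n_stack=0, n_tri=1, n_mono=0, box=(100.0, 100.0, 100.0))
        pl, _ = generate_chromatin(spec, seed=5)
        records, _ = pp.dinucleosome_finder(pl, k_clusters=2, seed=5)
        # the linker pair's forward and backward records end up together
        linker = records[np.isclose(records["euclidean_distance"], 24.5, atol=0.1)]
        assert linker["cluster"].nunique() == 1

    def test_row_permutation_invariant_partition(self, chromatin_small):
        pl, _ = chromatin_small
        perm = np.random.default_rng(3).permutation(len(pl))
        shuffled = pl.select(perm)
        rec1, _ = pp.dinucleosome_finder(pl, seed=21)
        rec2, _ = pp.dinucleosome_finder(shuffled, seed=21)
        key = ["query_id", "neighbor_id"]
        m1 = rec1.set_index(key)["cluster"].sort_index()
        m2 = rec2.set_index(key)["cluster"].sort_index()
        assert m1.equals(m2)

    def test_too_few_records_rejected(self):
        spec = ChromatinSpec(n_helix=0, n_stack=1, n_tri=0, n_mono=0, box=(100.0, 100.0, 100.0))
        pl, _ = generate_chromatin(spec, seed=5)
        with pytest.raises(ValueError):
            pp.dinucleosome_finder(pl, k_clusters=15, seed=5)


class TestFootprintAxisPipeline:
    def _planted_scene(self, rng, n_pairs, rel_axis, rel_angle, rel_trans, id0=0):
        """Query/neighbor lists with one planted relative pose class."""
        q_pos, q_rot, n_pos, n_rot = [], [], [], []
        rel_rot = rotation_about(rel_axis, rel_angle)
        for k in range(n_pairs):
            g_rot = geometry.random_rotation(rng)
            g_pos = rng.uniform(0, 2000.0, 3)
            q_pos.append(g_pos)
            q_rot.append(g_rot)
            n_pos.append(g_pos + g_rot @ rel_trans)
            n_rot.append(g_rot @ rel_rot)
        mk = lambda pos, rot, off: ParticleList.from_arrays(
            np.array(pos), np.stack(rot), particle_ids=np.arange(n_pairs) + off
        )
        return mk(q_pos, q_rot, id0), mk(n_pos, n_rot, id0 + 10000)

    def test_planted_pose_class_recovered(self, rng):
        axis = np.array([0, 0, 1.0])
        queries, neighbors = self._planted_scene(rng, 40, axis, 50.0, np.array([0.0, 8.0, 0.0]))
        reports = pp.footprint_axis_pipeline(queries, neighbors, radius=12.0)
        assert len(reports) == 1
        rep = reports[0]
        assert rep["footprint_id"] == 1  # +y cone only
        assert abs(rep["dominant_axis"] @ axis) > 0.99
        populated = [r for r in rep["ranges"] if r["n"] > 0]
        assert sum(r["n"] for r in populated) == 40

    def test_two_planted_classes_give_two_footprints(self, rng):
        q1, n1 = self._planted_scene(rng, 30, (0, 0, 1.0), 50.0, np.array([0.0, 8.0, 0.0]))
        q2, n2 = self._planted_scene(
            rng, 30, (1.0, 0, 0), 90.0, np.array([0.0, 0.0, 8.0]), id0=500
        )
        queries, neighbors = q1.concat(q2), n1.concat(n2)
        reports = pp.footprint_axis_pipeline(queries, neighbors, radius=12.0)
        footprints = {r["footprint_id"] for r in reports}
        assert footprints == {1, 16}  # +y cone and +z cone

    def test_empty_neighbor_list_empty_report(self, rng):
        queries = random_particle_list(rng, 10, box=100.0)
        empty = ParticleList.from_arrays(
            np.zeros((0, 3)), np.zeros((0, 3, 3)), particle_ids=np.arange(0)
        )
        assert pp.footprint_axis_pipeline(queries, empty, radius=10.0) == []


class TestRunPCA:
    def test_perfectly_correlated_columns_one_component(self, rng):
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": 3 * x + 1})
        _, report, _ = pp.run_pca(df, 0.95)
        assert len(report) == 1
        assert report["explained_variance_ratio"].iloc[0] >= 0.95

    def test_isotropic_gaussian_needs_all_three(self, rng):
        df = pd.DataFrame(rng.normal(size=(4000, 3)), columns=list("abc"))
        _, report, _ = pp.run_pca(df, 0.95)
        assert len(report) == 3
        assert np.allclose(report["explained_variance_ratio"], 1 / 3, atol=0.05)

    def test_constant_column_dropped_with_warning(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50), "c": 1.0})
        with pytest.warns(UserWarning, match="constant"):
            _, report, loadings = pp.run_pca(df, 0.95)
        assert "c" not in loadings.index

    def test_pentamer_features_three_components_suffice(self):
        sph = generate_spherical_lattice(radius=100.0, subdivisions=2)
        from twistcloud.descriptor import compute_twist
        from twistcloud.features import decompose_shells, link_features

        td = compute_twist(sph, radius=45.0)
        shells = decompose_shells(td, 0.2)
        fm = link_features(td, shells)
        feats = fm.table[["median_central_angle", "std_central_angle", "n_vertices"]].dropna()
        _, report, _ = pp.run_pca(feats, 0.95)
        assert len(report) <= 3


class TestNoiseRobustness:
    def test_structured_recovery_decreases_with_noise(self):
        """Scaled noise grid: stack-classifier recovery of structured
        classes does not increase with noise (trend property, averaged
        over seeds)."""
        from twistcloud.synthetic import NoiseModel, corrupt

        spec = ChromatinSpec(n_helix=1, n_stack=25, n_tri=25, n_mono=150, box=(220.0, 220.0, 110.0))
        levels = [(0.0, 0.0), (2.0, 0.4), (5.0, 1.0)]
        means = []
        for pos_level, ori_level in levels:
            vals = []
            for seed in (0, 1, 2):
                pl, _ = generate_chromatin(spec, seed=seed)
                noisy = corrupt(pl, NoiseModel(pos_level, ori_level, seed=seed + 100))
                _, fr = pp.stack_classifier(noisy)
                vals.append(np.mean([fr["stack"], fr["tri"], fr["helix"]]))
            means.append(np.mean(vals))
        slack = 2.0  # percentage points of Monte-Carlo jitter
        assert means[0] >= means[1] - slack
        assert means[1] >= means[2] - slack
        assert means[0] > means[2]  # strict drop from clean to heavy noise
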