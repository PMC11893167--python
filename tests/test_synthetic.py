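"""Synthetic scene generator: planted geometry, labels, and determinism."""

import numpy as np
import pytest

from mitomorph import (
    chance_import_rate,
    compute_context,
    decorate_particles,
    intermembrane_distance,
    make_mitochondrion,
    summarize_classes,
)


class TestMakeMitochondrion:
    def test_constant_spacing_reproduced(self):
        # spec'd discretization tolerance: <= 2% of spacing at subdivision 4
        omm, imm, _ = make_mitochondrion(radius=3000, spacing=100, subdivisions=4, seed=1)
        field = intermembrane_distance(omm, imm, method="nearest-point")
        np.testing.assert_allclose(field.values, 100.0, rtol=0.02)

    def test_three_wells_three_truth_components(self):
        omm, _, truth = make_mitochondrion(
            radius=3000, spacing=135, n_cj_wells=3, subdivisions=4, seed=2
        )
        comps = omm.label_components(truth.crista_triangles)
        assert len(comps) == 3

    def test_two_level_spacing_field(self):
        # 110 A in marked zones, 135 A elsewhere; check the zone cores and
        # the far field (the rim blends smoothly between the two levels)
        omm, imm, truth = make_mitochondrion(
            radius=3000, spacing=135, n_co_zones=2, spacing_co=110,
            zone_radius=0.35, subdivisions=4, seed=3,
        )
        field = intermembrane_distance(omm, imm, method="nearest-point")
        cdirs = omm.centroids / np.linalg.norm(omm.centroids, axis=1, keepdims=True)
        zc = np.asarray(truth.planted["zone_centers"])
        ang_min = np.arccos(np.clip(cdirs @ zc.T, -1, 1)).min(axis=1)
        core = ang_min < 0.6 * 0.35
        far = ang_min > 1.5 * 0.35
        np.testing.assert_allclose(field.values[core], 110.0, rtol=0.03)
        np.testing.assert_allclose(field.values[far], 135.0, rtol=0.03)

    def test_membrane_intersection_rejected(self):
        with pytest.raises(ValueError):
            make_mitochondrion(radius=200, spacing=250, subdivisions=2)

    def test_same_seed_identical_scene(self):
        a = make_mitochondrion(radius=3000, spacing=135, n_cj_wells=2, subdivisions=3, seed=7)
        b = make_mitochondrion(radius=3000, spacing=135, n_cj_wells=2, subdivisions=3, seed=7)
        np.testing.assert_array_equal(a[1].vertices, b[1].vertices)
        np.testing.assert_array_equal(a[2].crista_triangles, b[2].crista_triangles)


class TestDecorateParticles:
    def test_planted_import_always_satisfies_classifier(self, scene_fine):
        # generator/analyzer Euler-convention consistency: planted
        # import-oriented particles must pass the 95 A rule themselves
        omm, _, _ = scene_fine
        particles, truth = decorate_particles(omm, n=400, import_fraction=1.0, seed=11)
        records = compute_context(particles, omm)
        assert (records["orientation_class"] == "import_oriented").all()

    def test_zero_fraction_matches_chance_rate(self, scene_fine):
        # randomly oriented particles pass the exit rule at the geometric
        # acceptance rate; Monte-Carlo agreement within 3 sigma
        omm, _, _ = scene_fine
        particles, _ = decorate_particles(omm, n=1000, import_fraction=0.0, seed=12)
        records = compute_context(particles, omm)
        rate = summarize_classes(records)["import_fraction"]
        p = chance_import_rate(omm, n=6000, seed=13)
        sigma = np.sqrt(p * (1 - p) / 1000)
        assert abs(rate - p) < 3 * sigma

    def test_chain_end_to_end_geometry(self):
        # near-straight chain of 5 at 300 A spacing: 5'->3' end-to-end is
        # 4 x 300 A plus the two terminal mRNA-site offsets (2 x 80 A)
        omm, _, _ = make_mitochondrion(radius=3000, spacing=135, subdivisions=4, seed=4)
        from mitomorph import RunConfig, detect_chains

        particles, _ = decorate_particles(
            omm, mode="chains", chain_lengths=[5], chain_spacing=300, seed=5
        )
        # 300 A spacing -> ~150 A mRNA gaps and centers right at the 30 nm
        # rule (mesh projection inflates steps slightly); widen both cutoffs
        cfg = RunConfig(adjacency_cutoff=200.0, polysome_neighbor=40.0)
        chains = detect_chains(particles, cfg=cfg)
        assert len(chains) == 1
        assert chains[0]["end_to_end"] == pytest.approx(4 * 300 + 160, rel=0.05)

    def test_same_seed_identical_particles(self, sphere_coarse):
        a, _ = decorate_particles(sphere_coarse, n=50, mode="clustered", seed=9)
        b, _ = decorate_particles(sphere_coarse, n=50, mode="clustered", seed=9)
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_labels_partition(self, sphere_coarse):
        particles, truth = decorate_particles(sphere_coarse, n=80, import_fraction=0.25, seed=10)
        assert set(truth.particle_labels) <= {"import_oriented", "proximal_non_import"}
        assert (truth.particle_labels == "import_oriented").sum() == 20

    def test_region_mask_respected(self, sphere_coarse):
        mask = sphere_coarse.centroids[:, 2] > 0
        particles, _ = decorate_particles(sphere_coarse, n=60, region_mask=mask, seed=14)
        assert (particles["z"] > 0).all()

    def test_packing_capacity_guard(self, sphere_coarse):
        with pytest.raises(ValueError, match="packing"):
            decorate_particles(sphere_coarse, n=10_000_000, seed=1)

    def test_bad_fraction_rejected(self, sphere_coarse):
        with pytest.raises(ValueError):
            decorate_particles(sphere_coarse, n=10, import_fraction=1.5)
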