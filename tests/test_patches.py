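"""Membrane patches, randomization nulls, crista overlap, OMM-IMM distances."""

import numpy as np
import pytest
from scipy.stats import chisquare

from mitomorph import (
    RunConfig,
    TriangleSurface,
    build_patches,
    compute_context,
    crista_associated_omm,
    decorate_particles,
    histogram_peak,
    icosphere,
    intermembrane_distance,
    make_mitochondrion,
    mann_whitney_u,
    overlap_fraction,
    patch_distance_histograms,
    randomize_patches,
)
from conftest import make_grid_surface


class TestBuildPatches:
    def test_radius_zero_seeds_only(self, grid_surface):
        lab = build_patches([5, 17], grid_surface, radius=0.0)
        assert set(np.flatnonzero(lab.member)) == {5, 17}

    def test_matches_brute_force_scan(self, grid_surface):
        seed = [grid_surface.n_triangles // 2]
        lab = build_patches(seed, grid_surface, radius=150.0)
        d = np.linalg.norm(grid_surface.centroids - grid_surface.centroids[seed[0]], axis=1)
        np.testing.assert_array_equal(lab.member, d <= 150.0)

    def test_union_of_overlapping_seeds(self, grid_surface):
        a = build_patches([100], grid_surface, radius=150.0)
        b = build_patches([101], grid_surface, radius=150.0)
        both = build_patches([100, 101], grid_surface, radius=150.0)
        np.testing.assert_array_equal(both.member, a.member | b.member)
        areas = both.areas(grid_surface)
        assert areas["patch"] + areas["complement"] == pytest.approx(areas["total"])

    def test_partition_exact(self, grid_surface):
        lab = build_patches([0, 50, 200], grid_surface, radius=120.0)
        assert np.all(lab.member ^ lab.complement)  # exact partition by count
        areas = lab.areas(grid_surface)
        assert areas["patch"] + areas["complement"] == pytest.approx(areas["total"], rel=1e-12)

    def test_empty_seed_set(self, grid_surface):
        lab = build_patches([], grid_surface, radius=150.0)
        assert not lab.member.any()


class TestRandomizePatches:
    def test_constraints_on_every_draw(self, sphere_coarse):
        obs = build_patches([0, 40, 80, 120, 160], sphere_coarse, radius=150.0)
        for seed in range(50):
            rand = randomize_patches(obs, sphere_coarse, seed=seed)
            assert len(rand.seed_ids) == len(obs.seed_ids)  # count-matching
            c = sphere_coarse.centroids[rand.seed_ids]
            d = np.linalg.norm(c[:, None] - c[None], axis=2)
            iu = np.triu_indices(len(c), 1)
            assert np.all(d[iu] > 150.0)  # strict spacing rule
            assert rand.provenance == "randomized"

    def test_occupancy_proportional_to_area(self):
        # stretched sphere -> unequal areas; single-center draws over many
        # seeds must follow the area weights
        v, f = icosphere(1.0, 1)
        s = TriangleSurface(v * [300.0, 300.0, 1200.0], f)
        obs = build_patches([0], s, radius=0.0)
        counts = np.zeros(s.n_triangles)
        n_draws = 2000
        for seed in range(n_draws):
            counts[randomize_patches(obs, s, seed=seed).seed_ids[0]] += 1
        expected = s.areas / s.total_area * n_draws
        _, p = chisquare(counts, expected)
        assert p > 0.01

    def test_unsatisfiable_packing_raises(self, sphere_coarse):
        obs = build_patches(list(range(300)), sphere_coarse, radius=150.0)
        with pytest.raises(RuntimeError, match="packing"):
            randomize_patches(obs, sphere_coarse, seed=0,
                              min_center_separation=5000.0, max_attempts=10)


class TestIntermembraneDistance:
    def test_parallel_planes_both_methods(self):
        lower = make_grid_surface(nx=16, ny=16, pitch=50.0, z=0.0)
        upper = make_grid_surface(nx=16, ny=16, pitch=50.0, z=100.0)
        for method in ("nearest-point", "normal-cone"):
            field = intermembrane_distance(upper, lower, method=method)
            interior = np.all(np.abs(upper.centroids[:, :2]) < 300, axis=1)
            np.testing.assert_allclose(field.values[interior], 100.0, rtol=0.02)

    def test_concentric_spheres_analytic(self):
        omm, imm, _ = make_mitochondrion(radius=1000, spacing=100, subdivisions=3)
        field = intermembrane_distance(omm, imm, method="nearest-point")
        np.testing.assert_allclose(field.values, 100.0, rtol=0.02)

    def test_cone_miss_is_undefined(self):
        # a source facing away from the target: cone finds nothing -> NaN
        src = TriangleSurface([[0, 0, 0], [10, 0, 0], [0, 10, 0]], [[0, 1, 2]])
        tgt = make_grid_surface(nx=4, ny=4, pitch=20.0, z=500.0)  # above the source
        # src normal is +z, so its inward (-z) cone misses the target above
        field = intermembrane_distance(src, tgt, method="normal-cone")
        assert np.isnan(field.values[0])

    def test_empty_target_rejected(self, grid_surface):
        empty = TriangleSurface(np.zeros((0, 3)), np.zeros((0, 3), int))
        with pytest.raises(ValueError):
            intermembrane_distance(grid_surface, empty)


class TestCristaAssociated:
    def test_wells_recovered_with_good_jaccard(self):
        omm, imm, truth = make_mitochondrion(
            radius=3000, spacing=135, n_cj_wells=3, subdivisions=4, seed=41
        )
        crista = crista_associated_omm(omm, imm)
        for comp in omm.label_components(truth.crista_triangles):
            tm = np.zeros(omm.n_triangles, bool)
            tm[comp] = True
            inter = (tm & crista.member).sum()
            union = (tm | crista.member).sum()
            # per-component overlap: the well must be found
            assert inter / tm.sum() > 0.5

    def test_out_of_band_spacing_gives_empty_set(self):
        omm, imm, _ = make_mitochondrion(radius=3000, spacing=135, subdivisions=3)
        crista = crista_associated_omm(omm, imm)
        assert not crista.member.any()

    def test_zero_expansion_equals_projection(self):
        omm, imm, _ = make_mitochondrion(
            radius=3000, spacing=135, n_cj_wells=2, subdivisions=4, seed=42
        )
        cfg = RunConfig(cj_band=(18, 30), crista_expand=1e-9)
        crista = crista_associated_omm(omm, imm, cfg)
        projected = np.zeros(omm.n_triangles, bool)
        projected[crista.seed_ids] = True
        np.testing.assert_array_equal(crista.member, projected)


class TestOverlapFraction:
    @staticmethod
    def labeling(surface, mask):
        from mitomorph import PatchLabeling
        return PatchLabeling(surface.surface_id, surface.n_triangles,
                             np.flatnonzero(mask)[:1], mask, 150.0)

    def test_subset_is_one(self, sphere_coarse):
        ribo = np.zeros(sphere_coarse.n_triangles, bool)
        ribo[:10] = True
        crista = np.zeros_like(ribo)
        crista[:50] = True
        assert overlap_fraction(self.labeling(sphere_coarse, ribo),
                                self.labeling(sphere_coarse, crista),
                                sphere_coarse) == 1.0

    def test_disjoint_is_zero(self, sphere_coarse):
        ribo = np.zeros(sphere_coarse.n_triangles, bool)
        ribo[:10] = True
        crista = np.zeros_like(ribo)
        crista[10:20] = True
        assert overlap_fraction(self.labeling(sphere_coarse, ribo),
                                self.labeling(sphere_coarse, crista),
                                sphere_coarse) == 0.0

    def test_equal_area_half(self):
        # flat grid: all triangles congruent, so 2 of 4 -> exactly 0.5
        g = make_grid_surface(nx=2, ny=1, pitch=10.0)
        ribo = np.array([True, True, True, True])
        crista = np.array([True, True, False, False])
        assert overlap_fraction(self.labeling(g, ribo), self.labeling(g, crista),
                                g) == pytest.approx(0.5)

    def test_empty_ribo_undefined(self, sphere_coarse):
        ribo = np.zeros(sphere_coarse.n_triangles, bool)
        crista = np.ones_like(ribo)
        assert np.isnan(overlap_fraction(self.labeling(sphere_coarse, ribo),
                                         self.labeling(sphere_coarse, crista),
                                         sphere_coarse))


class TestHistograms:
    def test_constant_distances_peak(self):
        assert histogram_peak(np.full(50, 100.0))["peak"] == 100.0

    def test_counts_conserved(self):
        rng = np.random.default_rng(51)
        v = rng.normal(120, 10, size=500)
        v[::50] = np.nan
        h = histogram_peak(v, bins=100)
        assert h["counts"].sum() == np.isfinite(v).sum() == h["n_defined"]

    def test_too_few_defined_flagged(self):
        assert np.isnan(histogram_peak([5.0])["peak"])

    def test_bimodal_planted_spacings(self):
        """Patch peak near 110 A, complement near 135 A on a two-level scene."""
        omm, imm, truth = make_mitochondrion(
            radius=3000, spacing=135, n_co_zones=3, spacing_co=110,
            subdivisions=4, seed=52,
        )
        field = intermembrane_distance(omm, imm, method="nearest-point")
        # patches grown from the planted zone triangles
        from mitomorph import PatchLabeling
        lab = PatchLabeling(omm.surface_id, omm.n_triangles,
                            np.flatnonzero(truth.zone_triangles)[:1],
                            truth.zone_triangles, 150.0)
        hists = patch_distance_histograms(field, lab, bins=100)
        bin_w = (np.nanmax(field.values) - np.nanmin(field.values)) / 100
        assert abs(hists["patch"]["peak"] - 110.0) <= 2 * bin_w
        assert abs(hists["complement"]["peak"] - 135.0) <= 2 * bin_w
        assert hists["patch"]["peak"] < hists["complement"]["peak"]


def test_overlap_recovery_inside_vs_outside_wells():
    """Ribosome patches planted inside CJ wells overlap the crista-associated
    OMM far more than patches planted elsewhere (20 scenes, Mann-Whitney)."""
    inside, outside = [], []
    for seed in range(20):
        omm, imm, truth = make_mitochondrion(
            radius=3000, spacing=135, n_cj_wells=3, subdivisions=3, seed=seed
        )
        crista = crista_associated_omm(omm, imm)
        for target, mask in ((inside, truth.crista_triangles),
                             (outside, ~truth.crista_triangles)):
            particles, _ = decorate_particles(omm, n=40, region_mask=mask,
                                              seed=1000 + seed)
            from mitomorph import nearest_triangle
            from mitomorph.io import particle_positions
            ids, _ = nearest_triangle(particle_positions(particles), omm)
            lab = build_patches(ids, omm, radius=150.0)
            target.append(overlap_fraction(lab, crista, omm))
    assert np.mean(inside) > np.mean(outside)
    assert mann_whitney_u(inside, outside)["p_two_sided"] < 0.01
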