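"""Ripley's K, the surface-matched CSR null, interval maxima, Mann-Whitney."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from mitomorph import (
    compute_k_curve,
    decorate_particles,
    interval_max_at,
    interval_maxima,
    k_csr_analytic,
    k_csr_null,
    mann_whitney_u,
    ripley_k,
)
from mitomorph.io import particle_positions


def brute_force_k(points, r_grid, volume):
    pts = np.asarray(points, float)
    n = len(pts)
    out = []
    for r in r_grid:
        count = sum(
            1
            for i in range(n)
            for j in range(n)
            if i != j and np.linalg.norm(pts[i] - pts[j]) <= r
        )
        out.append(volume * count / (n * (n - 1)))
    return np.array(out)


class TestRipleyK:
    def test_two_points(self):
        k = ripley_k([[0, 0, 0], [0, 0, 10]], [5.0, 9.99, 10.0, 20.0], domain_volume=1000)
        np.testing.assert_allclose(k, [0.0, 0.0, 1000.0, 1000.0])

    def test_all_points_beyond_max_radius(self):
        pts = np.diag([1000.0, 2000.0, 3000.0])
        assert np.all(ripley_k(pts, [10.0, 100.0], domain_volume=1.0) == 0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(17)
        pts = rng.uniform(0, 100, size=(50, 3))
        r_grid = np.linspace(5, 120, 25)
        np.testing.assert_allclose(
            ripley_k(pts, r_grid, domain_volume=1e6),
            brute_force_k(pts, r_grid, 1e6),
            rtol=1e-12,
        )

    def test_point_order_irrelevant(self):
        rng = np.random.default_rng(18)
        pts = rng.uniform(0, 100, size=(40, 3))
        r = np.linspace(1, 150, 30)
        a = ripley_k(pts, r)
        b = ripley_k(pts[rng.permutation(40)], r)
        np.testing.assert_array_equal(a, b)

    def test_single_point_undefined(self):
        assert np.all(np.isnan(ripley_k([[0, 0, 0]], [1.0, 2.0])))

    def test_k_non_decreasing(self):
        rng = np.random.default_rng(19)
        pts = rng.uniform(0, 50, size=(30, 3))
        k = ripley_k(pts, np.linspace(1, 100, 40))
        assert np.all(np.diff(k) >= 0)


class TestCsrNull:
    def test_analytic_closed_form(self):
        assert k_csr_analytic([10.0])[0] == pytest.approx(4188.790205, rel=1e-6)

    def test_monte_carlo_non_decreasing(self, sphere_coarse):
        k = k_csr_null(sphere_coarse, n=50, r_grid=np.linspace(100, 2000, 20),
                       n_resamples=10, seed=3)
        assert np.all(np.diff(k) >= 0)

    def test_csr_ratio_self_consistent(self, sphere_coarse):
        # CSR points against the surface-uniform null: mean ratio ~ 1
        # (short version; the full 20-seed check lives in the acceptance suite)
        means = []
        for seed in range(5):
            particles, _ = decorate_particles(sphere_coarse, n=300, import_fraction=0,
                                              standoff=0.0, seed=100 + seed)
            curve = compute_k_curve(particle_positions(particles), sphere_coarse,
                                    seed=200 + seed)
            means.append(np.nanmean(curve["ratio"]))
        assert np.mean(means) == pytest.approx(1.0, abs=0.1)


class TestIntervalMaxima:
    @staticmethod
    def curve(r, ratio):
        return pd.DataFrame({"r_nm": r, "ratio": ratio})

    def test_flat_curve(self):
        r = np.linspace(27, 166, 140)
        im = interval_maxima(self.curve(r, np.ones_like(r)))
        assert np.allclose(im["max_ratio"], 1.0)

    def test_single_spike(self):
        r = np.linspace(27, 166, 140)
        ratio = np.ones_like(r)
        ratio[np.argmin(np.abs(r - 35))] = 2.5
        im = interval_maxima(self.curve(r, ratio))
        row = im[(im["r_lo_nm"] == 30.0)].iloc[0]
        assert row["max_ratio"] == 2.5
        assert interval_max_at(self.curve(r, ratio), 30, 40) == 2.5

    def test_matches_brute_force(self):
        rng = np.random.default_rng(23)
        r = np.linspace(27, 166, 140)
        ratio = rng.uniform(0.5, 3.0, size=r.size)
        im = interval_maxima(self.curve(r, ratio))
        for _, row in im.iterrows():
            sel = (r > row["r_lo_nm"]) & (r <= row["r_hi_nm"])
            assert row["max_ratio"] == ratio[sel].max()

    def test_wide_interval_collapses_to_one(self):
        r = np.linspace(27, 40, 20)
        im = interval_maxima(self.curve(r, np.ones_like(r)), interval=50.0)
        assert len(im) == 1

    def test_nan_entries_skipped(self):
        r = np.linspace(27, 46, 20)
        ratio = np.ones_like(r)
        ratio[(r > 30) & (r <= 40)] = np.nan
        im = interval_maxima(self.curve(r, ratio))
        assert 30.0 not in set(im["r_lo_nm"])


class TestMannWhitney:
    def test_exact_small_case(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res["U"] == 0
        assert res["p_two_sided"] == pytest.approx(2 / 6)

    def test_identical_samples(self):
        res = mann_whitney_u([5, 5, 5], [5, 5, 5])
        assert res["U"] == 9 / 2
        assert res["p_two_sided"] == 1.0
        assert res["degenerate"]

    def test_exact_matches_scipy_at_6_plus_6(self):
        rng = np.random.default_rng(31)
        a = rng.normal(size=6)
        b = rng.normal(loc=1.0, size=6)
        mine = mann_whitney_u(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert mine["method"] == "exact"
        assert mine["U"] == pytest.approx(ref.statistic)
        assert mine["p_two_sided"] == pytest.approx(ref.pvalue, rel=1e-9)

    def test_large_sample_asymptotic(self):
        rng = np.random.default_rng(32)
        a = rng.normal(size=40)
        b = rng.normal(loc=1.5, size=40)
        res = mann_whitney_u(a, b)
        assert res["method"] == "asymptotic"
        assert res["p_two_sided"] < 0.001
        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res["p_two_sided"] == pytest.approx(ref.pvalue)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


def test_planted_clustering_detected(sphere_coarse):
    """Thomas-clustered decorations at 35 nm score higher (30,40] interval
    maxima than CSR decorations — the synthetic clustering-recovery check."""
    clustered, csr = [], []
    for seed in range(8):
        pc, _ = decorate_particles(sphere_coarse, n=300, mode="clustered",
                                   cluster_scale=35.0, standoff=0.0, seed=seed)
        pu, _ = decorate_particles(sphere_coarse, n=300, mode="csr",
                                   standoff=0.0, seed=500 + seed)
        cc = compute_k_curve(particle_positions(pc), sphere_coarse, seed=1000 + seed)
        cu = compute_k_curve(particle_positions(pu), sphere_coarse, seed=2000 + seed)
        clustered.append(interval_max_at(cc, 30, 40))
        csr.append(interval_max_at(cu, 30, 40))
    assert np.median(clustered) > np.median(csr)
    assert mann_whitney_u(clustered, csr)["p_two_sided"] < 0.05
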