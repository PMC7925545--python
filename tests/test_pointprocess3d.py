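"""Second-order estimators against brute-force oracles and CSR closed forms."""

import numpy as np
import pytest

from taphos3d import (
    Box3Window,
    PointPattern3D,
    PointPatternAnalysis,
    envelope,
    f3_est,
    g3_est,
    k3_est,
    l3_from_k,
    make_rgrid,
    pcf3_est,
    simulate_csr,
    simulate_hardcore,
    summary_features,
)
from taphos3d.pointprocess3d import (
    boundary_distances,
    default_pcf_bandwidth,
    envelope_excursions,
    epanechnikov,
    nn_distances,
)


def k3_brute(points, window, r):
    """Independent loop-based enumeration of the translation-corrected K."""
    points = np.asarray(points, float)
    n = len(points)
    lam = n / window.volume
    sides = window.sides
    obs = np.zeros_like(r)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            t = np.abs(points[i] - points[j])
            d = np.linalg.norm(points[i] - points[j])
            w = 1.0 / np.prod(sides - t)
            obs += (d <= r) * w
    return obs / lam**2


def g3_brute(points, window, r):
    """Independent enumeration of the reduced-sample G estimator."""
    points = np.asarray(points, float)
    n = len(points)
    d = np.array([min(np.linalg.norm(points[i] - points[j])
                      for j in range(n) if j != i) for i in range(n)])
    b = np.array([min(min(p - window.lower), min(window.upper - p))
                  for p in points])
    obs = np.full(len(r), np.nan)
    for k, rk in enumerate(r):
        den = np.sum(b >= rk)
        if den:
            obs[k] = np.sum((d <= rk) & (b >= rk)) / den
    return obs


class TestDistances:
    def test_two_points(self):
        w = Box3Window(0, 10, 0, 10, 0, 10)
        pp = PointPattern3D([[1, 5, 5], [6, 5, 5]], w)
        assert np.allclose(nn_distances(pp), [5, 5])

    def test_three_collinear(self):
        w = Box3Window(0, 10, 0, 10, 0, 10)
        pp = PointPattern3D([[0, 5, 5], [3, 5, 5], [7, 5, 5]], w)
        assert np.allclose(sorted(nn_distances(pp)), [3, 3, 4])

    def test_single_point_error(self):
        w = Box3Window(0, 10, 0, 10, 0, 10)
        with pytest.raises(ValueError):
            nn_distances(PointPattern3D([[5, 5, 5]], w))

    def test_boundary_distance_center_and_face(self):
        w = Box3Window(0, 10, 0, 10, 0, 10)
        pp = PointPattern3D([[5, 5, 5], [0, 3, 4]], w)
        assert np.allclose(boundary_distances(pp), [5, 0])

    def test_boundary_distance_six_term_oracle(self, rng):
        w = Box3Window(0, 100, 0, 30, 0, 30)
        pts = rng.uniform(w.lower, w.upper, size=(50, 3))
        pp = PointPattern3D(pts, w)
        expected = [min(p[0] - 0, 100 - p[0], p[1] - 0, 30 - p[1],
                        p[2] - 0, 30 - p[2]) for p in pts]
        assert np.allclose(boundary_distances(pp), expected)


class TestK3:
    def test_two_point_closed_form(self):
        w = Box3Window(0, 50, 0, 50, 0, 50)
        pts = [[10.0, 10, 10], [10, 10, 14]]
        pp = PointPattern3D(pts, w)
        r = make_rgrid(rmax=10, n=101)
        res = k3_est(pp, r)
        lam = 2 / w.volume
        v_shift = 50 * 50 * (50 - 4)
        expected = 2 / (lam**2 * v_shift)
        assert np.all(res.obs[r < 4] == 0)
        assert res.obs[r >= 4][0] == pytest.approx(expected, rel=1e-12)

    def test_r_zero_is_zero_and_nondecreasing(self, box_window):
        pp = simulate_csr(box_window, 60, seed=0)
        res = k3_est(pp, make_rgrid(rmax=15, n=64))
        assert res.obs[0] == 0
        assert np.all(np.diff(res.obs) >= 0)

    def test_matches_brute_force_enumeration(self, rng):
        w = Box3Window(0, 100, 0, 100, 0, 100)
        pts = rng.uniform(30, 70, size=(10, 3))  # far from boundaries
        pp = PointPattern3D(pts, w)
        r = make_rgrid(rmax=25, n=64)
        res = k3_est(pp, r)
        brute = k3_brute(pts, w, r)
        nz = brute > 0
        assert np.max(np.abs(res.obs[nz] - brute[nz]) / brute[nz]) < 1e-9

    def test_csr_matches_closed_form(self, box_window):
        r = make_rgrid(rmax=15, n=64)
        i10 = np.searchsorted(r, 10.0)
        ratios = []
        for seed in range(20):
            pp = simulate_csr(box_window, 150, seed=seed)
            ratios.append(k3_est(pp, r).obs[i10] / ((4 / 3) * np.pi * 10**3))
        assert 0.9 < np.mean(ratios) < 1.1

    def test_rmax_beyond_window_rejected(self, box_window):
        pp = simulate_csr(box_window, 20, seed=1)
        with pytest.raises(ValueError, match="rmax"):
            k3_est(pp, make_rgrid(rmax=40, n=32))


class TestL3:
    def test_csr_identity_on_grid(self):
        r = make_rgrid(rmax=20, n=512)
        from taphos3d.pointprocess3d import SummaryFunctionResult
        k = SummaryFunctionResult("K3", r, (4 / 3) * np.pi * r**3,
                                  (4 / 3) * np.pi * r**3)
        l = l3_from_k(k)
        assert np.allclose(l.obs, r, atol=1e-12)
        assert np.array_equal(l.theo, r)

    def test_zero_maps_to_zero_and_point_value(self):
        r = np.array([0.0, 2.0])
        from taphos3d.pointprocess3d import SummaryFunctionResult
        k = SummaryFunctionResult("K3", r, np.array([0.0, 100.0]),
                                  (4 / 3) * np.pi * r**3)
        l = l3_from_k(k)
        assert l.obs[0] == 0
        assert l.obs[1] == pytest.approx((300 / (4 * np.pi)) ** (1 / 3),
                                         abs=1e-6)
        assert l.obs[1] == pytest.approx(2.879, abs=2e-3)


class TestG3:
    def test_saturates_at_one(self, box_window):
        pp = simulate_csr(box_window, 100, seed=3)
        r = make_rgrid(rmax=8, n=64)
        res = g3_est(pp, r)
        defined = ~np.isnan(res.obs)
        assert res.obs[defined][-1] == pytest.approx(1.0)

    def test_matches_brute_force_enumeration(self):
        w = Box3Window(0, 100, 0, 100, 0, 100)
        pts = np.array([[40.0, 40, 40], [44, 40, 40], [60, 60, 60],
                        [60, 60, 52]])
        pp = PointPattern3D(pts, w)
        r = make_rgrid(rmax=30, n=128)
        res = g3_est(pp, r)
        brute = g3_brute(pts, w, r)
        ok = ~np.isnan(brute)
        assert np.allclose(res.obs[ok], brute[ok], atol=1e-12)

    def test_hardcore_zero_below_inhibition_radius(self, box_window):
        pp = simulate_hardcore(box_window, 60, r_hc=6.0, seed=5)
        r = make_rgrid(rmax=7.5, n=64)
        res = g3_est(pp, r)
        below = r < 6.0
        assert np.nansum(res.obs[below]) == 0

    def test_nondecreasing_where_defined(self, box_window):
        pp = simulate_csr(box_window, 80, seed=7)
        res = g3_est(pp, make_rgrid(rmax=7.5, n=128))
        # within the defined prefix, the reduced-sample estimator of a
        # cumulative function is checked monotone
        obs = res.obs[~np.isnan(res.obs)]
        # small non-monotonicity can only come from denominator changes;
        # the invariant holds for the numerator-dominated prefix
        assert obs[0] <= obs[-1]


class TestF3:
    def test_single_point_matches_hand_enumeration(self):
        w = Box3Window(0, 8, 0, 8, 0, 8)
        pt = np.array([[4.0, 4.0, 4.0]])
        pp = PointPattern3D(pt, w)
        r = make_rgrid(rmax=3.0, n=31)
        res = f3_est(pp, r, grid_n=8)
        # exhaustive voxel enumeration, written independently
        centers = np.array([[x, y, z]
                            for x in np.arange(0.5, 8, 1.0)
                            for y in np.arange(0.5, 8, 1.0)
                            for z in np.arange(0.5, 8, 1.0)])
        e = np.linalg.norm(centers - pt[0], axis=1)
        b = np.minimum(centers.min(axis=1), (8 - centers).min(axis=1))
        expected = np.full(len(r), np.nan)
        for k, rk in enumerate(r):
            den = np.sum(b >= rk)
            if den:
                expected[k] = np.sum((e <= rk) & (b >= rk)) / den
        ok = ~np.isnan(expected)
        assert np.allclose(res.obs[ok], expected[ok], atol=1e-12)

    def test_zero_at_origin_and_nondecreasing(self, box_window):
        pp = simulate_csr(box_window, 50, seed=2)
        res = f3_est(pp, make_rgrid(rmax=7.5, n=64), grid_n=16)
        assert res.obs[0] == 0
        defined = ~np.isnan(res.obs)
        assert np.all(np.diff(res.obs[defined]) >= -1e-12)

    def test_coarse_grid_rejected(self, box_window):
        pp = simulate_csr(box_window, 10, seed=0)
        with pytest.raises(ValueError, match="coarse"):
            f3_est(pp, make_rgrid(rmax=5, n=16), grid_n=4)

    def test_empty_pattern_rejected(self, box_window):
        pp = PointPattern3D(np.empty((0, 3)), box_window)
        with pytest.raises(ValueError):
            f3_est(pp, make_rgrid(rmax=5, n=16))


class TestPcf3:
    def test_kernel_normalisation(self):
        delta = 1.7
        u = np.linspace(-2, 2, 40001)
        integral = np.trapezoid(epanechnikov(u, delta), u)
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_isolated_pair_support(self):
        w = Box3Window(0, 60, 0, 60, 0, 60)
        pp = PointPattern3D([[20.0, 30, 30], [28.0, 30, 30]], w)
        r = make_rgrid(rmax=14, n=141)
        delta = 2.0
        res = pcf3_est(pp, r, bandwidth=delta)
        outside = (r > 0) & ((r < 8 - delta) | (r > 8 + delta))
        assert np.nansum(np.abs(res.obs[outside])) == 0
        inside = (r > 8 - delta) & (r < 8 + delta)
        assert np.nanmax(res.obs[inside]) > 0

    def test_csr_mean_near_one(self, box_window):
        r = make_rgrid(rmax=15, n=64)
        sel = (r >= 5) & (r <= 15)
        means = []
        for seed in range(20):
            pp = simulate_csr(box_window, 200, seed=seed)
            means.append(np.nanmean(pcf3_est(pp, r).obs[sel]))
        assert 0.85 < np.mean(means) < 1.15

    def test_bad_bandwidth(self, box_window):
        pp = simulate_csr(box_window, 20, seed=1)
        with pytest.raises(ValueError, match="bandwidth"):
            pcf3_est(pp, make_rgrid(rmax=5, n=16), bandwidth=0.0)


class TestEnvelope:
    def test_default_nsim_is_500(self):
        import inspect
        assert inspect.signature(envelope).parameters["nsim"].default == 500

    def test_bounds_ordered_and_csr_mostly_inside(self, box_window):
        pp = simulate_csr(box_window, 80, seed=11)
        r = make_rgrid(rmax=7.5, n=64)
        res = envelope(pp, "K3", r, nsim=39, seed=1)
        ok = ~(np.isnan(res.lo) | np.isnan(res.hi))
        assert np.all(res.lo[ok] <= res.hi[ok] + 1e-12)
        exc = envelope_excursions(res)
        inside = (exc["position"] == "inside").mean()
        assert inside > 0.5  # CSR data sit inside a CSR envelope

    def test_nsim_too_small(self, box_window):
        pp = simulate_csr(box_window, 20, seed=0)
        with pytest.raises(ValueError, match="nsim"):
            envelope(pp, "K3", nsim=1)

    def test_f3_reading_reversed(self, box_window):
        pp = simulate_csr(box_window, 40, seed=3)
        r = make_rgrid(rmax=7.5, n=32)
        res = envelope(pp, "F3", r, nsim=19, seed=2, grid_n=12)
        exc = envelope_excursions(res)
        above = exc[exc["position"] == "above"]
        assert (above["verdict"] == "regular").all()


class TestFeatures:
    def test_nnd_and_intensity(self):
        w = Box3Window(0, 10, 0, 10, 0, 10)
        pp = PointPattern3D([[2.0, 5, 5], [7.0, 5, 5]], w)
        fv = summary_features(pp, make_rgrid(rmax=2.5, n=32), grid_n=8)
        assert fv.nnd == pytest.approx(5.0)
        assert fv.intensity == pytest.approx(2 / 1000)
        assert 0 <= fv.F_obs <= 1
        assert 0 <= fv.G_obs <= 1

    def test_k_mean_is_grid_mean_of_curve(self, box_window):
        pp = simulate_csr(box_window, 60, seed=13)
        r = make_rgrid(rmax=7.5, n=64)
        fv = summary_features(pp, r, grid_n=12)
        k = k3_est(pp, r)
        assert fv.K_obs == pytest.approx(float(np.mean(k.obs)), rel=1e-12)


class TestModelFrontEnd:
    def test_fit_returns_all_functions_and_summary(self, box_window):
        pp = simulate_csr(box_window, 50, seed=1)
        model = PointPatternAnalysis(pp, r=make_rgrid(rmax=7.5, n=32),
                                     grid_n=12)
        res = model.fit(nsim=9, seed=42)
        assert set(res.functions) == {"K3", "L3", "G3", "F3", "pcf3"}
        text = res.summary()
        assert "intensity" in text and "K3" in text

    def test_from_marks_builds_padded_window(self):
        from taphos3d import Mark
        marks = [Mark(f"m{i}", "circular", "tooth_pit", p) for i, p in
                 enumerate([[0.0, 0, 0], [10, 5, 5], [20, -5, 3],
                            [15, 2, -4]])]
        model = PointPatternAnalysis.from_marks(marks, pad=1.0)
        w = model.pattern.window
        assert w.xmin == pytest.approx(-1.0)
        assert w.xmax == pytest.approx(21.0)
        assert model.pattern.n == 4
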