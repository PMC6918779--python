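"""Geometry descriptors, distribution scores, rates and the fixture generator."""
import numpy as np
import pandas as pd
import pytest

from neurovertex import stats as S


def rect(w, h, angle=0.0):
    pts = np.array([[0.0, 0.0], [w, 0.0], [w, h], [0.0, h]]) - [w / 2, h / 2]
    c, s = np.cos(angle), np.sin(angle)
    return pts @ np.array([[c, s], [-s, c]]).T


class TestShapeDescriptors:
    def test_regular_hexagon_isotropic(self, hex44):
        assert S.cell_elongation(hex44.unwrapped_loop(0)) == pytest.approx(1.0)

    def test_rectangle_elongation_is_aspect(self):
        assert S.cell_elongation(rect(2.0, 1.0)) == pytest.approx(2.0)

    def test_elongation_rotation_invariant(self, rng):
        loop = rect(3.0, 1.0)
        base = S.cell_elongation(loop)
        for a in rng.uniform(0, np.pi, 5):
            assert S.cell_elongation(rect(3.0, 1.0, a)) == pytest.approx(base)

    def test_collinear_loop_rejected(self):
        with pytest.raises(ValueError):
            S.cell_elongation(np.array([[0, 0], [1, 0], [2, 0]]))

    def test_orientation_dv_axis_is_zero(self):
        assert S.cell_orientation_angle(rect(2.0, 1.0)) == pytest.approx(0.0)

    def test_orientation_ap_axis_is_half_pi(self):
        assert S.cell_orientation_angle(rect(1.0, 2.0)) == pytest.approx(np.pi / 2)

    def test_orientation_45_degrees(self):
        got = S.cell_orientation_angle(rect(2.0, 1.0, np.pi / 4))
        assert abs(got) == pytest.approx(np.pi / 4)

    def test_isotropic_orientation_flagged(self):
        with pytest.raises(ValueError, match="isotropic"):
            S.cell_orientation_angle(rect(1.0, 1.0))

    def test_dv_length(self, hex44):
        assert S.cell_dv_length(rect(2.0, 1.0)) == pytest.approx(2.0)
        # regular hexagon with two vertical edges: DV extent = 2s (vertex to vertex)
        side = np.sqrt(1.0 / (1.5 * np.sqrt(3.0)))
        assert S.cell_dv_length(hex44.unwrapped_loop(0)) == pytest.approx(np.sqrt(3) * side)


class TestKS:
    def test_identical_samples_zero(self):
        assert S.ks_statistic([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_supports_one(self):
        assert S.ks_statistic([0, 1], [5, 6]) == 1.0

    def test_enumerated_example(self):
        assert S.ks_statistic([1, 2, 3], [1, 2, 4]) == pytest.approx(1 / 3)

    def test_matches_scipy_on_random_data(self, rng):
        from scipy.stats import ks_2samp

        a, b = rng.normal(size=100), rng.normal(0.4, size=80)
        assert S.ks_statistic(a, b) == pytest.approx(ks_2samp(a, b).statistic)

    def test_mean_ecdf_reduces_to_plain_ks(self, rng):
        a, b = rng.normal(size=50), rng.normal(size=60)
        assert S.mean_ecdf_ks([a], [b]) == pytest.approx(S.ks_statistic(a, b))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            S.ks_statistic([], [1.0])


class TestGeometryScore:
    def make(self, rng, shift=0.0):
        return pd.DataFrame(
            {
                "area": rng.normal(1.0 + shift, 0.2, 50),
                "perimeter": rng.normal(3.7, 0.3, 50),
                "n_neighbours": rng.integers(4, 9, 50),
            }
        )

    def test_self_comparison_zero(self, rng):
        t = self.make(rng)
        assert S.geometry_similarity_score([t], [t]) == 0.0

    def test_shifted_distribution_increases_score(self, rng):
        ref = [self.make(np.random.default_rng(0)) for _ in range(3)]
        near = [self.make(np.random.default_rng(i)) for i in range(3, 6)]
        far = [self.make(np.random.default_rng(i), shift=3.0) for i in range(3, 6)]
        assert S.geometry_similarity_score(far, ref) > S.geometry_similarity_score(near, ref)

    def test_five_component_arithmetic(self):
        """Hand-computed oracle on a tiny table pair."""
        a = pd.DataFrame({"area": [1.0, 2.0], "perimeter": [4.0, 5.0], "n_neighbours": [6, 6]})
        b = pd.DataFrame({"area": [1.0, 3.0], "perimeter": [4.0, 5.0], "n_neighbours": [5, 6]})
        ks_area = 0.5  # ECDFs differ by 1/2 on [2, 3)
        ks_perim = 0.0
        ks_nn = 0.5
        d_sd_area = abs(np.std([1, 3], ddof=1) - np.std([1, 2], ddof=1))  # sqrt2 - 1/sqrt2
        d_sd_perim = 0.0
        expected = np.mean([ks_area, ks_perim, ks_nn, d_sd_area, d_sd_perim])
        assert S.geometry_similarity_score([a], [b]) == pytest.approx(expected)

    def test_unit_mismatch_guard(self, rng):
        sim = self.make(rng)
        ref = self.make(rng)
        ref.attrs["units"] = "um"
        sim.attrs["units"] = "nondimensional"
        with pytest.raises(ValueError, match="units"):
            S.geometry_similarity_score([sim], [ref])
        S.geometry_similarity_score([sim], [ref], area_scale=23.0)  # explicit scale ok


class TestTissueFitScore:
    def test_perfect_match_zero(self):
        assert S.tissue_fit_score([5.0], [0.3], 5.0, 0.3) == 0.0

    def test_doubling_dv_adds_log_two(self):
        assert S.tissue_fit_score([10.0], [0.3], 5.0, 0.3) == pytest.approx(np.log(2))

    def test_two_run_average(self):
        got = S.tissue_fit_score([5.0, 10.0], [0.4, 0.3], 5.0, 0.3)
        assert got == pytest.approx((0.1 + np.log(2)) / 2)

    def test_non_positive_change_rejected(self):
        with pytest.raises(ValueError):
            S.tissue_fit_score([-1.0], [0.3], 5.0, 0.3)


class TestCloneRatio:
    def make(self, ap, dv):
        return pd.DataFrame({"ap_extent": ap, "dv_extent": dv})

    def test_printed_formula(self):
        assert S.clone_spread_ratio(self.make([2.5], [6.0])) == pytest.approx(0.3)

    def test_isotropic_clones_give_one(self):
        assert S.clone_spread_ratio(self.make([3.0, 5.0], [5.0, 3.0])) == pytest.approx(1.0)

    def test_antisymmetry_under_axis_exchange(self, rng):
        ap = rng.uniform(2, 6, 10)
        dv = rng.uniform(2, 6, 10)
        r = S.clone_spread_ratio(self.make(ap, dv))
        r_swapped = S.clone_spread_ratio(self.make(dv, ap))
        assert r_swapped == pytest.approx(1.0 / r)

    def test_too_small_clones_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            S.clone_spread_ratio(self.make([0.5], [0.5]))


class TestRates:
    def test_proliferation_rate_arithmetic(self):
        assert S.proliferation_rate(5, 100.0, 1.0) == pytest.approx(0.05)
        assert S.proliferation_rate(0, 100.0, 1.0) == 0.0

    def test_effective_growth_rate(self):
        assert S.effective_growth_rate(100, 200, 13.0) == pytest.approx(np.log(2) / 13)
        assert S.effective_growth_rate(100, 100, 5.0) == 0.0

    def test_rates_agree_on_pure_birth_process(self, rng):
        """d/(N~ dt) tracks ln(N1/N0)/dt for exponential growth without loss."""
        lam = 0.05  # per hour
        t, n, t_end = 0.0, 400, 10.0
        times = []
        while t < t_end:
            t += rng.exponential(1.0 / (lam * n))
            if t < t_end:
                times.append(t)
                n += 1
        n0, n1 = 400, n
        n_mean = (n1 - n0) / np.log(n1 / n0)  # exact time-average for exponential
        lam_hat = S.proliferation_rate(len(times), n_mean, t_end)
        k_hat = S.effective_growth_rate(n0, n1, t_end)
        assert lam_hat == pytest.approx(k_hat, rel=1e-6)
        assert lam_hat == pytest.approx(lam, abs=3 * np.sqrt(len(times)) / (n_mean * t_end))


class TestEventStatistics:
    def test_t1_rate_arithmetic(self):
        frame = pd.DataFrame({"new_angle": np.zeros(38)})
        rate, hist, _ = S.t1_statistics(frame, window_hours=1.0, n_mean=100.0)
        assert rate == pytest.approx(0.38)
        assert hist[0] == 38  # all new edges along DV -> mass at angle 0

    def test_empty_log_zero_rate(self):
        rate, hist, _ = S.t1_statistics(pd.DataFrame(columns=["new_angle"]), 1.0, 50.0)
        assert rate == 0.0 and hist.sum() == 0

    def test_division_axis_perpendicular_to_new_edge(self):
        df = pd.DataFrame({"new_edge_angle": [0.0]})
        angles, _, _ = S.division_angle_distribution(df)
        assert angles[0] == pytest.approx(np.pi / 2)

    def test_uniformity_test_calibrated(self):
        """Isotropic angles: not rejected at alpha=0.05 in >=95% of draws."""
        rng = np.random.default_rng(99)
        keep = 0
        for _ in range(100):
            df = pd.DataFrame({"new_edge_angle": rng.uniform(0, np.pi, 200)})
            _, _, (stat, p) = S.division_angle_distribution(df)
            keep += p > 0.05
        assert keep >= 95

    def test_concentrated_angles_rejected(self):
        df = pd.DataFrame({"new_edge_angle": np.zeros(200)})
        _, _, (stat, p) = S.division_angle_distribution(df)
        assert p < 1e-6


class TestLewisLaw:
    def test_exactly_linear_class_means(self):
        t = pd.DataFrame({"n_neighbours": [4, 5, 6, 7], "area": [0.5, 0.75, 1.0, 1.25]})
        slope, intercept, r2 = S.lewis_law_fit(t)
        assert r2 == pytest.approx(1.0)
        assert slope > 0

    def test_constant_areas_flat(self):
        t = pd.DataFrame({"n_neighbours": [4, 5, 6, 7], "area": [1.0] * 4})
        slope, _, _ = S.lewis_law_fit(t)
        assert slope == pytest.approx(0.0)

    def test_insufficient_classes(self):
        t = pd.DataFrame({"n_neighbours": [6, 6], "area": [1.0, 2.0]})
        with pytest.raises(ValueError):
            S.lewis_law_fit(t)


class TestAspectBounds:
    def test_equal_drags(self):
        assert S.aspect_ratio_bounds(1.0, 1.0) == (1.0, 1.0)

    def test_default_drags(self):
        fast, slow = S.aspect_ratio_bounds(0.02, 1.0)
        assert fast == pytest.approx(np.sqrt(0.02))
        assert slow == 1.0


class TestSyntheticFixture:
    def test_requested_moments(self):
        t = S.synthetic_geometry_fixture(n_cells=4000, seed=5)
        assert abs(t["area"].mean() - 23.0) < 2 * t["area"].std() / np.sqrt(len(t))
        assert abs(t["n_neighbours"].mean() - 6.0) < 2 * 1.5 / np.sqrt(len(t))
        assert (t["elongation"] >= 1.0).all()
        assert t["n_neighbours"].min() >= 3

    def test_deterministic_per_seed(self):
        a = S.synthetic_geometry_fixture(n_cells=100, seed=3)
        b = S.synthetic_geometry_fixture(n_cells=100, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_infeasible_moments_rejected(self):
        with pytest.raises(ValueError):
            S.synthetic_geometry_fixture(mean_area=-1.0)
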