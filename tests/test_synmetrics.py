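import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from synapse_smlm import render, simulate, synmetrics
from synapse_smlm.synmetrics import (
    EstimatorResult,
    IntensityProfile,
    LineROI,
    RectROI,
    com_1d,
    com_2d_distance,
    com_distance_1d,
    cutoff_sweep,
    extract_line_profiles,
    projection_factor,
    top_fraction_mean,
)


def profile(values, bin_nm=10.0, channel=1):
    values = np.asarray(values, dtype=float)
    centers = (np.arange(len(values)) + 0.5) * bin_nm
    return IntensityProfile(centers, values, channel)


class TestROITypes:
    def test_line_direction_must_be_unit(self):
        with pytest.raises(ValueError, match="unit"):
            LineROI(np.zeros(2), np.array([1.0, 1.0]), 100.0)

    def test_rect_edges_must_be_orthogonal(self):
        with pytest.raises(ValueError, match="orthogonal"):
            RectROI(np.zeros(2), np.array([1.0, 0.0]), np.array([1.0, 1.0]))

    def test_rect_contains(self):
        roi = RectROI.from_bounds(0.0, 100.0, 0.0, 50.0)
        inside = roi.contains(np.array([[50.0, 25.0], [150.0, 25.0], [50.0, -1.0]]))
        assert list(inside) == [True, False, False]

    def test_roi_json_round_trip(self):
        line = LineROI(np.array([1.0, 2.0]), np.array([0.0, 1.0]), 500.0, 300.0, 7)
        rect = RectROI.from_bounds(0, 10, 0, 20, 3)
        for roi in (line, rect):
            back = synmetrics.roi_from_dict(roi.to_dict())
            assert back.synapse_id == roi.synapse_id


class TestExtractLineProfiles:
    def test_single_localization_bin(self, table_factory):
        tab = table_factory([37.0], [0.0], intensity=[5.0])
        roi = LineROI(np.zeros(2), np.array([1.0, 0.0]), 100.0, 300.0)
        profs = extract_line_profiles(tab, roi, channels=(1,))
        p = profs[1]
        assert p.values[3] == pytest.approx(5.0 / 300.0)  # bin [30, 40), width-averaged
        assert p.values.sum() == pytest.approx(5.0 / 300.0)

    def test_uniform_field_flat_profile(self, table_factory):
        # one unit-intensity point per nm^2 on a regular grid => equal bins
        xs, ys = np.meshgrid(np.arange(0.5, 100.0, 1.0), np.arange(-149.5, 150.0, 1.0))
        tab = table_factory(xs.ravel(), ys.ravel())
        roi = LineROI(np.zeros(2), np.array([1.0, 0.0]), 100.0, 300.0)
        p = extract_line_profiles(tab, roi, channels=(1,))[1]
        assert np.allclose(p.values, p.values[0], atol=1e-9)

    def test_rotation_equivariance(self, rng, table_factory):
        n = 400
        xy = rng.uniform(-200, 800, size=(n, 2))
        w = rng.uniform(1, 10, n)
        tab0 = table_factory(xy[:, 0], xy[:, 1], intensity=w)
        roi0 = LineROI(np.array([0.0, 0.0]), np.array([1.0, 0.0]), 600.0, 300.0)

        th = np.deg2rad(30)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        xy_r = xy @ R.T
        tab1 = table_factory(xy_r[:, 0], xy_r[:, 1], intensity=w)
        roi1 = LineROI(R @ roi0.anchor_nm, R @ roi0.direction, 600.0, 300.0)

        p0 = extract_line_profiles(tab0, roi0, channels=(1,))[1]
        p1 = extract_line_profiles(tab1, roi1, channels=(1,))[1]
        assert np.allclose(p0.values, p1.values, atol=1e-9)

    def test_empty_channel_flagged(self, table_factory):
        tab = table_factory([50.0], [0.0], channel=1)
        roi = LineROI(np.zeros(2), np.array([1.0, 0.0]), 100.0)
        profs = extract_line_profiles(tab, roi, channels=(1, 2))
        assert not profs[1].is_empty
        assert profs[2].is_empty

    def test_refuses_blurred_image(self, table_factory):
        tab = table_factory([50.0, 60.0], [0.0, 5.0])
        img = render.gaussian_blur(render.render_sr_image(tab, raster_nm=10.0), sigma_nm=10.0)
        roi = LineROI(np.zeros(2), np.array([1.0, 0.0]), 100.0)
        with pytest.raises(ValueError, match="raw data"):
            extract_line_profiles({1: img, 2: img}, roi)

    def test_image_path_matches_table_path(self, rng, table_factory):
        # pixel-image profiles approximate the table profiles
        n = 2000
        tab = table_factory(
            rng.normal(300, 40, n), rng.normal(0, 40, n), intensity=rng.uniform(1, 5, n)
        )
        roi = LineROI(np.array([0.0, 0.0]), np.array([1.0, 0.0]), 600.0, 300.0)
        p_tab = extract_line_profiles(tab, roi, channels=(1,))[1]
        img = render.render_sr_image(tab, raster_nm=10.0, channel=1)
        p_img = extract_line_profiles({1: img}, roi, channels=(1,))[1]
        assert abs(com_1d(p_tab) - com_1d(p_img)) <= 10.0


class TestCom1d:
    def test_delta(self):
        assert com_1d(profile([0, 1, 0])) == 15.0

    def test_hand_computed(self):
        assert com_1d(profile([1, 3])) == 12.5  # (5*1 + 15*3) / 4

    def test_symmetric(self):
        assert com_1d(profile([1, 2, 5, 2, 1])) == 25.0

    def test_zero_total_raises(self):
        with pytest.raises(ValueError, match="zero total"):
            com_1d(profile([0, 0, 0]))


class TestComDistance1d:
    def test_identical_profiles(self):
        assert com_distance_1d(profile([1, 2, 3]), profile([1, 2, 3], channel=2)) == 0.0

    def test_two_deltas(self):
        a = np.zeros(20)
        b = np.zeros(20)
        a[4] = 1.0  # center 45 -> use bins centered at 40 and 150
        b[15] = 1.0
        pa, pb = profile(a), profile(b, channel=2)
        assert com_distance_1d(pa, pb) == pytest.approx(110.0)

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError, match="bin grid"):
            com_distance_1d(profile([1, 2]), profile([1, 2, 3]))

    def test_noisy_gaussian_profiles_monte_carlo(self, rng):
        # two Gaussian-shaped profiles 107 nm apart plus symmetric noise,
        # checked against an independent direct-arithmetic Monte-Carlo oracle
        centers = (np.arange(60) + 0.5) * 10.0

        def noisy(mu):
            base = np.exp(-0.5 * ((centers - mu) / 50.0) ** 2)
            return np.clip(base + rng.normal(0, 0.01, centers.size), 0, None)

        impl = np.asarray(
            [
                com_distance_1d(
                    IntensityProfile(centers, noisy(250.0), 1),
                    IntensityProfile(centers, noisy(357.0), 2),
                )
                for _ in range(300)
            ]
        )
        # oracle: same noise model, plain weighted-mean arithmetic
        oracle = np.asarray(
            [
                abs(
                    np.average(centers, weights=noisy(250.0))
                    - np.average(centers, weights=noisy(357.0))
                )
                for _ in range(300)
            ]
        )
        sem = math.hypot(
            impl.std(ddof=1) / np.sqrt(impl.size), oracle.std(ddof=1) / np.sqrt(oracle.size)
        )
        assert abs(impl.mean() - oracle.mean()) < 3 * sem + 0.5
        assert impl.mean() == pytest.approx(107.0, abs=5.0)


class TestCom2dDistance:
    def test_three_four_five(self, table_factory):
        tab = pd.concat(
            [table_factory([0.0], [0.0], channel=1), table_factory([30.0], [40.0], channel=2)],
            ignore_index=True,
        )
        roi = RectROI.from_bounds(-100, 100, -100, 100)
        assert com_2d_distance(tab, roi) == pytest.approx(50.0)

    def test_identical_sets(self, rng, table_factory):
        xy = rng.uniform(0, 100, size=(20, 2))
        tab = pd.concat(
            [table_factory(xy[:, 0], xy[:, 1], channel=1), table_factory(xy[:, 0], xy[:, 1], channel=2)],
            ignore_index=True,
        )
        assert com_2d_distance(tab, RectROI.from_bounds(-10, 110, -10, 110)) == 0.0

    def test_empty_channel_names_channel(self, table_factory):
        tab = table_factory([0.0], [0.0], channel=1)
        with pytest.raises(ValueError, match="channel 2"):
            com_2d_distance(tab, RectROI.from_bounds(-10, 10, -10, 10))

    def test_rayleigh_mean_oracle(self, rng):
        # coincident populations, per-channel COM precision 10 nm
        sigma = 10.0
        d = np.linalg.norm(
            rng.normal(scale=sigma, size=(4000, 2)) - rng.normal(scale=sigma, size=(4000, 2)),
            axis=1,
        )
        expected = math.sqrt(2 * sigma**2) * math.sqrt(math.pi / 2)
        assert d.mean() == pytest.approx(expected, rel=0.05)

    def test_zero_separation_bias_decreases_with_locs(self, rng, table_factory):
        # positive bias at zero separation, shrinking with localization count
        means = []
        roi = RectROI.from_bounds(-500, 500, -500, 500)
        for n_locs in (4, 16, 64):
            dists = []
            for _ in range(150):
                t1 = table_factory(rng.normal(0, 40, n_locs), rng.normal(0, 40, n_locs), channel=1)
                t2 = table_factory(rng.normal(0, 40, n_locs), rng.normal(0, 40, n_locs), channel=2)
                dists.append(com_2d_distance(pd.concat([t1, t2], ignore_index=True), roi))
            means.append(np.mean(dists))
        assert means[0] > means[1] > means[2] > 0


class TestTopFractionMean:
    def test_worked_example(self):
        r = top_fraction_mean([10, 20, 30, 40, 50], q=0.4)
        assert r.n_used == 2
        assert r.mean_distance_nm == 45.0
        assert r.sem_nm == pytest.approx(np.std([50.0, 40.0], ddof=1) / np.sqrt(2))

    def test_constant_sample(self):
        for q in (0.2, 0.5, 1.0):
            r = top_fraction_mean([7.0] * 10, q=q)
            assert r.mean_distance_nm == 7.0 and r.sem_nm == 0.0

    def test_q_one_is_plain_mean(self, rng):
        d = rng.uniform(0, 300, 101)
        r = top_fraction_mean(d, q=1.0)
        assert r.mean_distance_nm == pytest.approx(d.mean())
        assert r.n_used == 101

    def test_n_used_is_ceil(self):
        assert top_fraction_mean([1, 2, 3], q=0.4).n_used == 2  # ceil(1.2)
        assert top_fraction_mean([1.0], q=0.01).n_used == 1

    def test_histogram_on_full_set(self):
        r = top_fraction_mean([5.0, 15.0, 25.0, 95.0], q=0.5)
        assert r.histogram_counts.sum() == 4
        assert r.histogram_counts[0] == 1  # [0, 10)
        assert r.histogram_edges_nm[1] - r.histogram_edges_nm[0] == 10.0

    def test_subset_mean_at_least_full_mean(self, rng):
        d = rng.uniform(0, 300, 500)
        assert top_fraction_mean(d, 0.4).mean_distance_nm >= top_fraction_mean(d, 1.0).mean_distance_nm

    def test_errors(self):
        with pytest.raises(ValueError):
            top_fraction_mean([])
        with pytest.raises(ValueError):
            top_fraction_mean([1.0], q=0.0)
        with pytest.raises(ValueError):
            top_fraction_mean([1.0], q=1.5)

    def test_sem_shrinks_with_n(self, rng):
        sems = []
        for n in (100, 1000, 10000):
            d = rng.uniform(0, 300, n)
            sems.append(top_fraction_mean(d, q=0.4).sem_nm)
        assert sems[0] > sems[1] > sems[2]


class TestCutoffSweep:
    def test_strictly_decreasing_for_heterogeneous_sample(self):
        df = cutoff_sweep(np.arange(1.0, 101.0), q_list=(0.2, 0.4, 0.6, 1.0))
        means = df["mean_distance_nm"].to_numpy()
        assert np.all(np.diff(means) < 0)
        assert df.attrs["monotone_nonincreasing"]

    def test_constant_sample_identical_means(self):
        df = cutoff_sweep([5.0] * 20, q_list=(0.2, 0.5, 1.0))
        assert df["mean_distance_nm"].nunique() == 1

    def test_projection_tracking(self):
        # uniform-orientation projections of d = 100 nm track the analytic factor
        rng = np.random.default_rng(8)
        u = rng.uniform(size=5000)
        d = 100.0 * np.sqrt(1.0 - u**2)
        df = cutoff_sweep(d, q_list=(0.2, 0.4, 0.6, 1.0))
        for _, row in df.iterrows():
            expected = 100.0 * projection_factor(row["q"])
            assert abs(row["mean_distance_nm"] - expected) < 3 * max(row["sem_nm"], 0.3)


class TestProjectionFactor:
    def test_limit_q_to_zero(self):
        assert projection_factor(1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_q_one_is_pi_over_four(self):
        assert projection_factor(1.0) == pytest.approx(math.pi / 4)

    def test_q_04_closed_form_and_quadrature(self):
        assert projection_factor(0.4) == pytest.approx(0.97265, abs=5e-6)
        num, _ = quad(lambda u: math.sqrt(1 - u * u), 0.0, 0.4)
        assert projection_factor(0.4) == pytest.approx(num / 0.4, rel=1e-9)

    def test_invalid_q(self):
        for q in (0.0, -0.1, 1.01):
            with pytest.raises(ValueError):
                projection_factor(q)


class TestRigidInvariance:
    def test_distances_invariant_under_rigid_motion(self, rng, table_factory):
        n = 300
        xy1 = rng.normal([200, 0], 40, size=(n, 2))
        xy2 = rng.normal([320, 0], 40, size=(n, 2))
        w1, w2 = rng.uniform(1, 10, n), rng.uniform(1, 10, n)
        tab = pd.concat(
            [
                table_factory(xy1[:, 0], xy1[:, 1], intensity=w1, channel=1),
                table_factory(xy2[:, 0], xy2[:, 1], intensity=w2, channel=2),
            ],
            ignore_index=True,
        )
        roi_line = LineROI(np.array([0.0, 0.0]), np.array([1.0, 0.0]), 600.0, 300.0)
        roi_rect = RectROI.from_bounds(-100, 700, -200, 200)
        d_line = synmetrics.line_com_distance(tab, roi_line)
        d_rect = com_2d_distance(tab, roi_rect)

        th = np.deg2rad(75)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        t = np.array([1234.5, -987.0])
        moved = tab.copy()
        moved[["x_nm", "y_nm"]] = tab[["x_nm", "y_nm"]].to_numpy() @ R.T + t
        roi_line_m = LineROI(R @ roi_line.anchor_nm + t, R @ roi_line.direction, 600.0, 300.0)
        roi_rect_m = RectROI(
            R @ roi_rect.corner_nm + t, R @ roi_rect.edge_u_nm, R @ roi_rect.edge_v_nm
        )
        assert synmetrics.line_com_distance(moved, roi_line_m) == pytest.approx(d_line, abs=1e-6)
        assert com_2d_distance(moved, roi_rect_m) == pytest.approx(d_rect, abs=1e-6)


class TestProposeLineRoi:
    def test_orients_along_population_offset(self, rng, table_factory):
        t1 = table_factory(rng.normal(0, 20, 200), rng.normal(0, 20, 200), channel=1)
        t2 = table_factory(rng.normal(150, 20, 200), rng.normal(0, 20, 200), channel=2)
        tab = pd.concat([t1, t2], ignore_index=True)
        roi = synmetrics.propose_line_roi(tab, (75.0, 0.0), search_radius_nm=400.0)
        assert abs(roi.direction @ np.array([1.0, 0.0])) > 0.95
        d = synmetrics.line_com_distance(tab, roi)
        assert d == pytest.approx(150.0, abs=15.0)

    def test_missing_channel_raises(self, table_factory):
        tab = table_factory([0.0], [0.0], channel=1)
        with pytest.raises(ValueError, match="channel 2"):
            synmetrics.propose_line_roi(tab, (0.0, 0.0))
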