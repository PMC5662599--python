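"""Polarity indices, region-pair series, line scans and heat maps."""

import numpy as np
import pandas as pd
import pytest

import fretpolar as fp
from fretpolar.polarity import detect_crossing, raster_to_um
from fretpolar.run import _half_plane_regions


def straight_track(direction_deg, n=6, step=2.0):
    theta = np.radians(direction_deg)
    pos = np.arange(n)[:, None] * step * np.array([np.cos(theta), np.sin(theta)])
    return fp.Trajectory(cell_id="t", times=np.arange(n) * 15.0, positions=pos)


class TestDeriveAxis:
    @pytest.mark.parametrize("direction,expected", [(0.0, 0.0), (90.0, 90.0),
                                                    (225.0, 225.0)])
    def test_cardinal_directions(self, direction, expected):
        axis = fp.derive_axis_from_track(straight_track(direction), 0)
        assert axis.front_direction == pytest.approx(expected)
        assert axis.source == "from_migration"

    def test_zero_displacement_directs_to_annotation(self):
        track = fp.Trajectory(cell_id="s", times=[0.0, 15.0],
                              positions=np.zeros((2, 2)))
        with pytest.raises(ValueError, match="annotated"):
            fp.derive_axis_from_track(track, 0)

    def test_matches_generator_direction_on_synthetic_movie(self):
        params = fp.SyntheticCellParams(n_frames=6, migration_direction=30.0,
                                        rng_seed=2)
        _, truth = fp.generate_polarized_cell_movie(params)
        track = fp.trajectory_from_ground_truth(truth)
        axis = fp.derive_axis_from_track(track, 0, lookahead=3)
        delta = fp.angle_between_directions(axis.front_direction, 30.0)
        assert delta <= 15.0


class TestBackFrontIndices:
    def test_uniform_field_gives_unit_ratio(self, uniform_ratio):
        axis = fp.PolarityAxis(np.array([32 * 1.0, 32 * 1.0]), 0.0)
        rec = fp.back_front_indices(uniform_ratio, uniform_ratio.defined_mask,
                                    axis, pixel_size=1.0)
        assert rec.back_front_ratio == pytest.approx(1.0)
        assert rec.total_index == pytest.approx(1.5)

    def test_axis_flip_inverts_ratio(self, noisy_movie):
        movie, truth = noisy_movie
        cell, ratio, _ = fp.process_frame(movie.donor_frames[0],
                                          movie.fret_frames[0])[0]
        axis = fp.PolarityAxis(truth.true_centroid_track[0],
                               truth.true_front_axis[0])
        r1 = fp.back_front_indices(ratio, cell, axis, movie.pixel_size)
        r2 = fp.back_front_indices(ratio, cell, axis.flipped(),
                                   movie.pixel_size)
        assert r2.back_front_ratio == pytest.approx(
            1.0 / r1.back_front_ratio, rel=1e-6)
        assert r2.total_index == r1.total_index

    def test_noise_free_polarized_cell_recovers_truth(self, noise_free_movie):
        movie, truth = noise_free_movie
        cfg = fp.RatioConfig(window_size=1, gaussian_width=0)
        cell, ratio, _ = fp.process_frame(movie.donor_frames[0],
                                          movie.fret_frames[0], cfg)[0]
        axis = fp.PolarityAxis(truth.true_centroid_track[0],
                               truth.true_front_axis[0])
        rec = fp.back_front_indices(ratio, cell, axis, movie.pixel_size)
        assert rec.back_front_ratio == pytest.approx(2.0, rel=0.01)

    def test_underpopulated_half_yields_reason_code(self, uniform_ratio):
        # centroid far to one side: the back half holds almost no pixels
        axis = fp.PolarityAxis(np.array([8.0, 32.0]), 0.0)
        rec = fp.back_front_indices(uniform_ratio, uniform_ratio.defined_mask,
                                    axis, pixel_size=1.0)
        assert not rec.defined
        assert "half_underpopulated" in rec.reason

    def test_monotone_rescaling_invariance(self, noisy_movie):
        """Scaling the whole normalized image leaves back/front unchanged:
        the statistic is a ratio of means of one image."""
        movie, truth = noisy_movie
        cell, ratio, _ = fp.process_frame(movie.donor_frames[0],
                                          movie.fret_frames[0])[0]
        axis = fp.PolarityAxis(truth.true_centroid_track[0],
                               truth.true_front_axis[0])
        rec = fp.back_front_indices(ratio, cell, axis, movie.pixel_size)
        scaled = fp.RatioImage(values=ratio.values * 7.5,
                               defined_mask=ratio.defined_mask)
        rec2 = fp.back_front_indices(scaled, cell, axis, movie.pixel_size)
        assert rec2.back_front_ratio == pytest.approx(rec.back_front_ratio,
                                                      rel=1e-12)


class TestRegionPairSeries:
    def test_symmetric_halves_of_uniform_field(self, uniform_ratio):
        shape = uniform_ratio.values.shape
        a = np.zeros(shape, bool)
        a[:, :32] = True
        series = fp.region_pair_series([uniform_ratio] * 4, a, ~a)
        np.testing.assert_allclose(series["b_over_a"], 1.0)

    def test_swapped_regions_give_reciprocal(self, noisy_movie):
        movie, _ = noisy_movie
        _, ratio, _ = fp.process_frame(movie.donor_frames[0],
                                       movie.fret_frames[0])[0]
        shape = ratio.values.shape
        a = np.zeros(shape, bool)
        a[:, :shape[1] // 2] = True
        s1 = fp.region_pair_series([ratio], a, ~a)
        s2 = fp.region_pair_series([ratio], ~a, a)
        np.testing.assert_allclose(s2["b_over_a"], 1.0 / s1["b_over_a"])

    def test_repolarization_crossing_within_two_frames(self):
        params = fp.SyntheticCellParams(
            n_frames=30, repolarization_frame=20, migration_speed=0.0,
            rng_seed=4)
        movie, truth = fp.generate_polarized_cell_movie(params)
        ratios = [fp.process_frame(movie.donor_frames[t],
                                   movie.fret_frames[t])[0][1]
                  for t in range(movie.n_frames)]
        a, b = _half_plane_regions(truth, movie.frame_shape, movie.pixel_size)
        series = fp.region_pair_series(ratios, a, b, times=movie.frame_times)
        crossing = detect_crossing(series)
        assert crossing is not None and abs(crossing - 20) <= 2

    def test_empty_intersection_flagged_not_raised(self, uniform_ratio):
        shape = uniform_ratio.values.shape
        a = np.zeros(shape, bool)
        a[:, :32] = True
        empty = np.zeros(shape, bool)
        empty[0, 0] = True   # misses the disc mask entirely
        series = fp.region_pair_series([uniform_ratio], a, empty)
        assert not series["defined"].iloc[0]
        assert np.isnan(series["b_over_a"].iloc[0])


class TestLineScan:
    def test_scan_along_gradient_is_linear(self):
        img = np.tile(np.arange(30, dtype=float), (30, 1))
        prof = fp.line_scan(img, np.array([[2.0, 15.0], [25.0, 15.0]]),
                            pixel_size=1.0, averaging_width=1)
        slopes = np.diff(prof.intensity) / np.diff(prof.arclength)
        np.testing.assert_allclose(slopes, 1.0, rtol=1e-9)

    def test_scan_perpendicular_to_gradient_is_constant(self):
        img = np.tile(np.arange(30, dtype=float), (30, 1))
        prof = fp.line_scan(img, np.array([[15.0, 3.0], [15.0, 25.0]]),
                            pixel_size=1.0, averaging_width=1)
        np.testing.assert_allclose(prof.intensity, prof.intensity[0],
                                   rtol=1e-9)

    def test_diagonal_scan_matches_bilinear_oracle(self):
        rng = np.random.default_rng(8)
        img = rng.uniform(0, 10, (40, 40))
        px = 0.5
        start, end = np.array([4.0, 5.0]), np.array([14.0, 13.0])
        prof = fp.line_scan(img, np.stack([start, end]), pixel_size=px,
                            averaging_width=1)

        def bilinear(row, col):
            r0, c0 = int(np.floor(row)), int(np.floor(col))
            fr, fc = row - r0, col - c0
            return ((1 - fr) * (1 - fc) * img[r0, c0]
                    + (1 - fr) * fc * img[r0, c0 + 1]
                    + fr * (1 - fc) * img[r0 + 1, c0]
                    + fr * fc * img[r0 + 1, c0 + 1])

        total = np.linalg.norm(end - start)
        for i, s in enumerate(prof.arclength):
            p = start + (end - start) * s / total
            row = (img.shape[0] - 1) - p[1] / px
            col = p[0] / px
            assert prof.intensity[i] == pytest.approx(bilinear(row, col),
                                                      abs=1e-9)

    def test_polyline_shorter_than_step_rejected(self):
        img = np.zeros((10, 10))
        with pytest.raises(ValueError, match="shorter"):
            fp.line_scan(img, np.array([[1.0, 1.0], [1.2, 1.0]]),
                         pixel_size=1.0, step=5.0)


class TestProfileCorrelation:
    def test_anti_parallel_profiles(self):
        s = np.linspace(0, 1, 30)
        p1 = fp.LineScanProfile(arclength=s * 10, intensity=np.sin(s * 3),
                                normalized_position=s)
        p2 = fp.LineScanProfile(arclength=s * 10,
                                intensity=-np.sin(s * 3) + 5.0,
                                normalized_position=s)
        r, n = fp.profile_correlation(p1, p2)
        assert r == pytest.approx(-1.0)
        assert n == 30

    def test_identical_profiles(self):
        s = np.linspace(0, 1, 20)
        p = fp.LineScanProfile(arclength=s * 5, intensity=s ** 2,
                               normalized_position=s)
        r, _ = fp.profile_correlation(p, p)
        assert r == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        s = np.array([0.0, 1.0])
        p = fp.LineScanProfile(arclength=s, intensity=s,
                               normalized_position=s)
        with pytest.raises(ValueError, match="3"):
            fp.profile_correlation(p, p)

    def test_generated_gap_activity_pairs_anticorrelate(self):
        rs = [fp.profile_correlation(
            *fp.generate_intensity_profile_pair(rng_seed=seed))[0]
            for seed in range(10)]
        assert np.mean(rs) < -0.8


class TestHeatmap:
    @staticmethod
    def _records(cell_id, values, times=None):
        times = times if times is not None else np.arange(len(values)) * 15.0
        return [fp.PolarityRecord(cell_id, i, t, back_index=v, front_index=1.0,
                                  back_front_ratio=v, total_index=v)
                for i, (t, v) in enumerate(zip(times, values))]

    def test_single_cell_constant_ratio(self):
        hm = fp.build_heatmap({"c0": self._records("c0", [1.5] * 5)})
        assert hm.values.shape == (1, 5)
        np.testing.assert_allclose(hm.values, 1.5)

    def test_by_mean_row_ordering(self):
        hm = fp.build_heatmap({
            "lo": self._records("lo", [1.2] * 4),
            "hi": self._records("hi", [2.0] * 4),
        }, row_order="by_mean")
        assert hm.rows == ["hi", "lo"]
        hm2 = fp.build_heatmap({
            "lo": self._records("lo", [1.2] * 4),
            "hi": self._records("hi", [2.0] * 4),
        }, row_order="as_given")
        assert set(hm2.rows) == {"lo", "hi"}

    def test_twelve_polarized_cells_all_row_means_above_one(self):
        """Noise-free polarized cells: every heat-map row mean of the
        back/front ratio exceeds 1."""
        cfg = fp.RatioConfig()
        records = {}
        for seed in range(12):
            params = fp.SyntheticCellParams(
                n_frames=2, shot_noise=False, read_noise_sd=0.0,
                rng_seed=seed, migration_direction=seed * 30.0)
            movie, truth = fp.generate_polarized_cell_movie(params)
            recs = []
            for t in range(movie.n_frames):
                cell, ratio, _ = fp.process_frame(
                    movie.donor_frames[t], movie.fret_frames[t], cfg)[0]
                axis = fp.PolarityAxis(truth.true_centroid_track[t],
                                       truth.true_front_axis[t])
                recs.append(fp.back_front_indices(
                    ratio, cell, axis, movie.pixel_size,
                    cell_id=f"c{seed}", frame=t, time=t * 15.0))
            records[f"c{seed}"] = recs
        hm = fp.build_heatmap(records, row_order="by_mean")
        assert hm.values.shape == (12, 2)
        assert (hm.values.mean(axis=1) > 1.0).all()


def test_detect_crossing_plain_series():
    s = np.array([2.0, 1.8, 1.4, 0.9, 0.5])
    assert detect_crossing(s) == 3
    assert detect_crossing(np.array([2.0, 1.5, 1.2])) is None
    assert detect_crossing(pd.DataFrame({
        "frame": [5, 6, 7], "b_over_a": [0.5, np.nan, 1.4]})) == 7
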