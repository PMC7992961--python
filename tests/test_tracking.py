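"""Template matching, sub-pixel refinement and landmark propagation."""

import numpy as np
import pytest

from conftest import brute_force_ncc
from fastlas import (PhantomSpec, TrackerConfig, apply_manual_adjustment,
                     make_la_phantom, match_template, refine_subpixel,
                     track_landmarks)
from fastlas.core import CineSeries
from fastlas.errors import InvariantError, TrackingBoundsError, ZeroVarianceError
from fastlas.strain import compute_distances, compute_strain_curve


class TestMatchTemplate:
    def test_exact_copy_recovers_known_shift(self):
        rng = np.random.default_rng(0)
        image = rng.random((41, 41))
        template = image[17 - 5:17 + 6, 15 - 5:15 + 6]  # center (17, 15)
        window = image[20 - 10:20 + 11, 17 - 10:17 + 11]  # center (20, 17)
        disp, surface = match_template(template, window)
        assert disp == (-3, -2)
        assert surface.max() == pytest.approx(1.0)

    def test_no_shift_gives_zero_displacement(self):
        rng = np.random.default_rng(1)
        window = rng.random((25, 25))
        template = window[5:20, 5:20]  # centred 15x15
        disp, _ = match_template(template, window)
        assert disp == (0, 0)

    def test_flat_template_raises_zero_variance(self):
        with pytest.raises(ZeroVarianceError):
            match_template(np.ones((7, 7)), np.random.default_rng(2).random((15, 15)))

    def test_window_must_exceed_template(self):
        rng = np.random.default_rng(3)
        with pytest.raises(InvariantError):
            match_template(rng.random((15, 15)), rng.random((15, 15)))

    @pytest.mark.parametrize("seed", range(8))
    def test_noisy_match_equals_brute_force_ncc(self, seed):
        """Integer displacement must equal the exhaustive NCC argmax."""
        rng = np.random.default_rng(seed)
        scene = rng.random((61, 61))
        r, c = rng.integers(16, 45, 2)
        template = scene[r - 5:r + 6, c - 5:c + 6].copy()
        template += rng.normal(0, 0.05 * np.ptp(template), template.shape)
        wr, wc = r + rng.integers(-4, 5), c + rng.integers(-4, 5)
        window = scene[wr - 10:wr + 11, wc - 10:wc + 11]
        disp, surface = match_template(template, window)
        oracle_disp, oracle_surface = brute_force_ncc(template, window)
        assert disp == oracle_disp
        np.testing.assert_allclose(surface, oracle_surface, atol=1e-6)


class TestSubpixelRefinement:
    def test_symmetric_saddle_gives_half_pixel(self):
        x = np.arange(5, dtype=float)
        # parabola with true peak at 2.5 along both axes
        f = -(x - 2.5) ** 2
        surface = f[:, None] + f[None, :]
        off = refine_subpixel(surface, (2, 2))
        assert off == (pytest.approx(0.5), pytest.approx(0.5))

    def test_delta_surface_gives_zero_offset(self):
        surface = np.zeros((5, 5))
        surface[2, 2] = 1.0
        assert refine_subpixel(surface, (2, 2)) == (0.0, 0.0)

    def test_border_peak_warns_and_returns_integer(self):
        surface = np.zeros((5, 5))
        surface[0, 2] = 1.0
        with pytest.warns(UserWarning, match="border"):
            assert refine_subpixel(surface, (0, 2)) == (0.0, 0.0)

    def test_recovers_known_fractional_shift(self):
        """Translate a textured patch by a sub-pixel amount and recover it."""
        from scipy.ndimage import shift as nd_shift

        rng = np.random.default_rng(7)
        from scipy.ndimage import gaussian_filter
        scene = gaussian_filter(rng.standard_normal((61, 61)), 1.5)
        true_shift = (2.3, -1.6)
        shifted = nd_shift(scene, true_shift, order=3)
        template = scene[30 - 7:30 + 8, 30 - 7:30 + 8]
        window = shifted[30 - 12:30 + 13, 30 - 12:30 + 13]
        disp, surface = match_template(template, window)
        peak = (disp[0] + (surface.shape[0] - 1) // 2,
                disp[1] + (surface.shape[1] - 1) // 2)
        off = refine_subpixel(surface, peak)
        est = (disp[0] + off[0], disp[1] + off[1])
        assert est[0] == pytest.approx(true_shift[0], abs=0.15)
        assert est[1] == pytest.approx(true_shift[1], abs=0.15)


class TestTrackLandmarks:
    def test_static_phantom_tracks_stay_on_seeds(self, static_phantom):
        _, two, _, truth = static_phantom
        tracked = track_landmarks(two, truth.seed_landmarks("two_chamber"))
        for name, pos in tracked.positions.items():
            err = np.abs(pos - pos[0]).max()
            assert err < 0.1

    def test_frame0_positions_equal_seeds_exactly(self, tracked_phantom, default_phantom):
        _, _, _, truth = default_phantom
        tr2, _ = tracked_phantom
        seeds = truth.seed_landmarks("two_chamber")
        for name, pos in tr2.positions.items():
            assert tuple(pos[0]) == seeds.points[name]

    def test_deforming_phantom_rmse_below_half_pixel(self, tracked_phantom,
                                                     default_phantom):
        _, two, four, truth = default_phantom
        for tracked, series in zip(tracked_phantom, (two, four)):
            sq = []
            for name, pos in tracked.positions.items():
                sq.append(np.sum((pos - truth.landmarks[series.view][name]) ** 2,
                                 axis=1))
            rmse = np.sqrt(np.mean(sq))
            assert rmse <= 0.5

    def test_uniform_series_raises_zero_variance(self):
        frames = np.full((8, 48, 48), 7.0)
        series = CineSeries("two_chamber", frames, np.arange(8) * 40.0, (1, 1), 320.0)
        seeds_points = {"av_anterior": (16.0, 16.0), "av_inferior": (16.0, 32.0),
                        "posterior_mid": (32.0, 24.0)}
        from fastlas.core import LandmarkSet

        with pytest.raises(ZeroVarianceError):
            track_landmarks(series, LandmarkSet("two_chamber", seeds_points))

    def test_search_window_leaving_image_names_frame_and_point(self):
        rng = np.random.default_rng(4)
        frames = rng.random((8, 40, 40))
        from fastlas.core import LandmarkSet

        series = CineSeries("two_chamber", frames, np.arange(8) * 40.0, (1, 1), 320.0)
        seeds = LandmarkSet("two_chamber", {"av_anterior": (5.0, 20.0),
                                            "av_inferior": (20.0, 35.0),
                                            "posterior_mid": (35.0, 20.0)})
        with pytest.raises(TrackingBoundsError) as err:
            track_landmarks(series, seeds)
        assert err.value.point in seeds.points

    def test_rmse_degrades_monotonically_with_noise(self):
        rmses = []
        for sigma in (0.5, 4.0, 12.0):
            spec = PhantomSpec(es=20, ea=11, texture_seed=9, noise_sigma=sigma)
            two, _, truth = make_la_phantom(spec)
            tracked = track_landmarks(two, truth.seed_landmarks("two_chamber"))
            sq = [np.sum((tracked.positions[n] - truth.landmarks["two_chamber"][n]) ** 2,
                         axis=1) for n in tracked.positions]
            rmses.append(float(np.sqrt(np.mean(sq))))
        assert rmses[0] <= rmses[1] <= rmses[2]

    def test_time_reversed_static_series_matches_forward_pass(self, static_phantom):
        _, two, _, truth = static_phantom
        seeds = truth.seed_landmarks("two_chamber")
        fwd = track_landmarks(two, seeds)
        rev_series = CineSeries("two_chamber",
                                np.concatenate([two.frames[:1], two.frames[1:][::-1]]),
                                two.frame_times, two.pixel_spacing, two.rr_interval)
        rev = track_landmarks(rev_series, seeds)
        for name in fwd.positions:
            np.testing.assert_allclose(rev.positions[name][1:][::-1],
                                       fwd.positions[name][1:], atol=0.05)


class TestManualAdjustment:
    def test_adjusting_to_automatic_position_is_idempotent(self, tracked_phantom,
                                                           default_phantom):
        _, two, _, _ = default_phantom
        tr2, _ = tracked_phantom
        auto = tuple(tr2.positions["av_anterior"][5])
        cfg = TrackerConfig(retrack_after_adjustment=False)
        adj = apply_manual_adjustment(tr2, 5, "av_anterior", auto, two, cfg)
        np.testing.assert_allclose(adj.positions["av_anterior"],
                                   tr2.positions["av_anterior"])
        assert adj.adjusted["av_anterior"][5]
        assert not tr2.adjusted["av_anterior"][5]  # input untouched

    def test_adjustment_changes_strain_only_from_that_frame_on(self, default_phantom,
                                                               tracked_phantom):
        _, two, _, _ = default_phantom
        tr2, _ = tracked_phantom
        moved = tr2.positions["av_anterior"][5] + (3.0, 0.0)
        adj = apply_manual_adjustment(tr2, 5, "av_anterior", tuple(moved), two,
                                      TrackerConfig())
        base = compute_strain_curve(compute_distances(tr2, two.pixel_spacing),
                                    smooth=False)
        new = compute_strain_curve(compute_distances(adj, two.pixel_spacing),
                                   smooth=False)
        np.testing.assert_allclose(new.strain["anterior"][:5],
                                   base.strain["anterior"][:5], atol=1e-12)
        assert abs(new.strain["anterior"][5] - base.strain["anterior"][5]) > 0.5

    def test_correcting_a_corrupted_frame_restores_strain(self, default_phantom):
        _, two, _, truth = default_phantom
        tr = track_landmarks(two, truth.seed_landmarks("two_chamber"))
        # corrupt the reservoir-peak frame, then adjust back to ground truth
        pk = truth.peak_frame
        bad = apply_manual_adjustment(
            tr, pk, "av_anterior",
            tuple(tr.positions["av_anterior"][pk] + (6.0, 6.0)), two,
            TrackerConfig(retrack_after_adjustment=False))
        fixed = apply_manual_adjustment(
            bad, pk, "av_anterior",
            tuple(truth.landmarks["two_chamber"]["av_anterior"][pk]), two,
            TrackerConfig())
        curve = compute_strain_curve(
            compute_distances(fixed, two.pixel_spacing, two.frame_times))
        err = abs(curve.view_mean[pk] - truth.strain["two_chamber"][pk])
        assert err < 1.0

    def test_out_of_bounds_adjustment_rejected(self, tracked_phantom, default_phantom):
        _, two, _, _ = default_phantom
        tr2, _ = tracked_phantom
        with pytest.raises(InvariantError, match="bounds"):
            apply_manual_adjustment(tr2, 3, "av_anterior", (-5.0, 10.0), two)


def test_strain_invariant_to_global_intensity_rescale(default_phantom):
    """NCC invariance propagates: a*I + b leaves the strain curve unchanged."""
    _, two, _, truth = default_phantom
    seeds = truth.seed_landmarks("two_chamber")
    base = track_landmarks(two, seeds)
    scaled_series = CineSeries("two_chamber", two.frames * 3.7 + 40.0,
                               two.frame_times, two.pixel_spacing, two.rr_interval)
    scaled = track_landmarks(scaled_series, seeds)
    for name in base.positions:
        np.testing.assert_allclose(scaled.positions[name], base.positions[name],
                                   atol=1e-6)
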