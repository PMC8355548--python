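import numpy as np
import pytest

from ciliaquant import beadcbf
from ciliaquant.errors import InputError
from ciliaquant.movieio import Movie
from ciliaquant.synthdata import SynthMovieParams, make_movie


def _analytic_trajectory(row, n_frames, fps, bead_id=0):
    """Ground-truth centre series of one bead from the generator's table."""
    t = np.arange(n_frames)
    s = row.amplitude * np.sin(2 * np.pi * row.f_true * t / fps + row.phase)
    return beadcbf.Trajectory(
        bead_id,
        t,
        row.x_rest + s * np.cos(row.direction),
        row.y_rest + s * np.sin(row.direction),
    )


class TestRemoveBackground:
    def test_static_scene_gives_zero_residuals(self):
        movie, _ = make_movie(
            SynthMovieParams(amplitude=0.0, noise_sd=0.0, duration=1.0, seed=0)
        )
        res = beadcbf.remove_background(movie)
        np.testing.assert_allclose(res.frames, 0.0, atol=1e-5)

    def test_constant_offset_invariance(self):
        movie, _ = make_movie(SynthMovieParams(duration=1.0, seed=1))
        res1 = beadcbf.remove_background(movie)
        shifted = Movie(movie.frames + 50.0, fps=movie.fps)
        res2 = beadcbf.remove_background(shifted)
        np.testing.assert_allclose(res1.frames, res2.frames, atol=1e-3)

    def test_moving_bead_leaves_localised_residual(self):
        p = SynthMovieParams(n_beads=1, f_true=5.0, duration=2.0, noise_sd=1.0, seed=2)
        movie, truth = make_movie(p)
        res = beadcbf.remove_background(movie)
        # 7 sigma: far enough into the Gaussian tail that no pure-noise pixel
        # crosses it over the whole stack.
        strong = np.abs(res.frames).max(axis=0) > 7 * p.noise_sd
        ys, xs = np.nonzero(strong)
        row = truth.iloc[0]
        dist = np.hypot(xs - row.x_rest, ys - row.y_rest)
        assert dist.max() < p.amplitude + 5 * p.bead_radius + 1
        assert strong.any()

    def test_too_few_frames(self):
        with pytest.raises(InputError):
            beadcbf.remove_background(Movie(np.zeros((5, 8, 8)), fps=10.0))


class TestDetectBeads:
    def test_all_zero_residuals_give_empty_list(self):
        res = Movie(np.zeros((12, 32, 32)), fps=10.0)
        assert beadcbf.detect_beads(res) == []

    def test_noise_free_movie_detects_every_bead_each_frame(self):
        movie, _ = make_movie(
            SynthMovieParams(f_true=5.0, seed=3, duration=3.0, noise_sd=0.0,
                             frame_shape=(256, 256))
        )
        res = beadcbf.remove_background(movie)
        dets = beadcbf.detect_beads(res, polarity="dark")
        per_frame = np.bincount([d.frame_index for d in dets], minlength=movie.n_frames)
        assert (per_frame == 10).all()

    def test_pure_noise_movie_has_negligible_false_positives(self, rng):
        noise = Movie(rng.normal(100, 5, size=(300, 128, 128)), fps=120.0)
        res = beadcbf.remove_background(noise)
        dets = beadcbf.detect_beads(res)
        # Gaussian 5-sigma tail at 128x128: << 0.1 expected min_area-sized
        # components per frame.
        assert len(dets) / 300 < 0.1


class TestLinkTrajectories:
    def test_static_beads_link_into_full_tracks(self):
        movie, _ = make_movie(
            SynthMovieParams(n_beads=3, amplitude=0.0, noise_sd=0.0, duration=1.0,
                             bead_contrast=-50.0, frame_shape=(256, 256), seed=4)
        )
        # Static beads vanish under median subtraction, so detect on the raw
        # movie (bright-field dark beads below background).
        res = Movie(movie.frames - 100.0, fps=movie.fps)
        dets = beadcbf.detect_beads(res, polarity="dark")
        trajs = beadcbf.link_trajectories(dets, n_frames=movie.n_frames)
        assert len(trajs) == 3
        assert all(len(t) == movie.n_frames for t in trajs)

    def test_oscillating_beads_identity_preserved(self):
        movie, truth = make_movie(
            SynthMovieParams(f_true=5.0, seed=3, duration=5.0, noise_sd=0.0,
                             frame_shape=(256, 256))
        )
        res = beadcbf.remove_background(movie)
        dets = beadcbf.detect_beads(res, polarity="dark")
        trajs = beadcbf.link_trajectories(dets, n_frames=movie.n_frames)
        assert len(trajs) == 10
        assert all(len(t) == movie.n_frames for t in trajs)
        for tr in trajs:
            i = int(np.argmin(np.hypot(truth.x_rest - tr.x.mean(),
                                       truth.y_rest - tr.y.mean())))
            ref = _analytic_trajectory(truth.iloc[i], movie.n_frames, movie.fps)
            err = np.hypot(tr.x - ref.x, tr.y - ref.y)
            # The residual centroid carries a small systematic outward bias
            # from the bead's own median footprint; identity and sub-2-px
            # fidelity are what linking must guarantee.
            assert err.max() < 2.0

    def test_gap_filling_interpolates_short_dropouts(self):
        dets = [
            beadcbf.BeadDetection(f, x=10.0 + f, y=5.0, area=5, peak_contrast=30.0)
            for f in range(20) if f not in (7, 8)
        ]
        trajs = beadcbf.link_trajectories(dets, n_frames=20)
        assert len(trajs) == 1
        tr = trajs[0]
        assert len(tr) == 20
        assert tr.x[7] == pytest.approx(17.0)
        assert tr.x[8] == pytest.approx(18.0)


class TestEstimateCbf:
    def test_pure_sinusoid_recovered(self):
        fps, dur = 120.0, 20.0
        t = np.arange(int(fps * dur))
        traj = beadcbf.Trajectory(0, t, 3 * np.sin(2 * np.pi * 5.0 * t / fps),
                                  np.zeros_like(t, dtype=float))
        r = beadcbf.estimate_cbf(traj, fps)
        assert r.f_beat == pytest.approx(5.0, abs=0.05)
        assert r.quality > 5

    def test_axis_with_larger_amplitude_wins(self):
        fps = 120.0
        t = np.arange(2400)
        x = 5 * np.sin(2 * np.pi * 7.0 * t / fps)
        y = 1 * np.sin(2 * np.pi * 13.0 * t / fps)
        r = beadcbf.estimate_cbf(beadcbf.Trajectory(0, t, x, y), fps)
        assert r.f_beat == pytest.approx(r.f_x)
        assert r.f_x == pytest.approx(7.0, abs=0.05)
        assert r.f_y == pytest.approx(13.0, abs=0.05)

    def test_linear_drift_does_not_bias_frequency(self):
        fps = 120.0
        t = np.arange(2400)
        x = 3 * np.sin(2 * np.pi * 9.0 * t / fps) + 0.2 * t
        r = beadcbf.estimate_cbf(beadcbf.Trajectory(0, t, x, np.zeros_like(x)), fps)
        assert r.f_beat == pytest.approx(9.0, abs=0.05)

    def test_never_reports_at_or_above_nyquist(self, rng):
        t = np.arange(600)
        x = rng.normal(size=600)
        r = beadcbf.estimate_cbf(beadcbf.Trajectory(0, t, x, x.copy()), fps=120.0)
        assert r.f_beat < 60.0

    def test_too_short_trajectory_rejected(self):
        t = np.arange(100)
        with pytest.raises(InputError):
            beadcbf.estimate_cbf(
                beadcbf.Trajectory(0, t, np.sin(t / 3), np.zeros(100)),
                fps=120.0,
            )


class TestSummarizeMovie:
    @staticmethod
    def _result(bead_id, f, quality):
        return beadcbf.CBFResult(bead_id, f, f, 1.0, 1.0, f, quality)

    def test_low_quality_beads_excluded(self):
        results = [self._result(i, 15.0, 10.0) for i in range(9)]
        results.append(self._result(9, 40.0, 0.0))
        s = beadcbf.summarize_movie(results)
        assert s["n_beads_used"] == 9
        assert s["median_f_beat"] == pytest.approx(15.0)
        assert s["iqr_f_beat"] == pytest.approx(0.0)

    def test_all_excluded_gives_empty_marker(self):
        s = beadcbf.summarize_movie([self._result(0, 15.0, 1.0)])
        assert s["n_beads_used"] == 0
        assert np.isnan(s["median_f_beat"])

    def test_empty_input_is_error(self):
        with pytest.raises(InputError):
            beadcbf.summarize_movie([])


class TestPipeline:
    def test_oracle_equivalence_noise_free_single_bead(self):
        """Full pipeline frequency matches FFT of the analytic centre series."""
        movie, truth = make_movie(
            SynthMovieParams(n_beads=1, f_true=7.3, seed=5, duration=5.0, noise_sd=0.0)
        )
        res = beadcbf.remove_background(movie)
        trajs = beadcbf.extract_roi_trajectories(res, beadcbf.find_active_rois(res))
        assert len(trajs) == 1
        r = beadcbf.estimate_cbf(trajs[0], movie.fps)
        ref = beadcbf.estimate_cbf(
            _analytic_trajectory(truth.iloc[0], movie.n_frames, movie.fps), movie.fps
        )
        assert r.f_beat == pytest.approx(ref.f_beat, abs=1e-3)

    def test_intensity_offset_and_rescale_invariance(self):
        movie, _ = make_movie(SynthMovieParams(n_beads=3, f_true=11.0, duration=5.0, seed=6))
        base = beadcbf.run_pipeline(movie)[2]["median_f_beat"]
        shifted = Movie(movie.frames + 37.0, fps=movie.fps)
        scaled = Movie(movie.frames * 2.5, fps=movie.fps)
        assert beadcbf.run_pipeline(shifted)[2]["median_f_beat"] == pytest.approx(base, abs=1e-6)
        assert beadcbf.run_pipeline(scaled)[2]["median_f_beat"] == pytest.approx(base, abs=1e-6)

    @pytest.mark.parametrize("f_true,seed", [(15.0, 10), (2.0, 11), (27.0, 12)])
    def test_parameter_recovery_across_band(self, f_true, seed):
        movie, _ = make_movie(SynthMovieParams(f_true=f_true, duration=10.0, seed=seed))
        _, _, summary = beadcbf.run_pipeline(movie)
        assert summary["n_beads_used"] >= 8
        assert summary["median_f_beat"] == pytest.approx(f_true, abs=0.1)

    def test_drift_robustness(self):
        movie, _ = make_movie(
            SynthMovieParams(f_true=8.0, duration=5.0, drift=(0.02, 0.01), seed=13)
        )
        _, _, summary = beadcbf.run_pipeline(movie)
        assert summary["median_f_beat"] == pytest.approx(8.0, abs=0.1)
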