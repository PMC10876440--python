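"""Kymograph construction, directional filtering, tracking, and statistics."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ciliakit import kymo
from ciliakit.synthetic import IFTSimConfig, simulate_ift_movie
from conftest import analyze_movie, single_train_config, straight_path


def _toy_track(frames, positions_um, direction="anterograde", dt=0.12, px=0.13):
    return kymo.TrainTrack(
        id=0,
        direction=direction,
        samples=np.column_stack([frames, positions_um]),
        frame_interval_s=dt,
        pixel_size_um=px,
    )


class TestBuildKymograph:
    def test_moving_pixel_traces_unit_slope_diagonal(self):
        data = np.zeros((12, 5, 16))
        for t in range(12):
            data[t, 2, t + 2] = 100.0
        stack = kymo.MovieStack(data, 0.12, 0.13)
        km = kymo.build_kymograph(stack, straight_path(stack))
        rows, cols = np.nonzero(km.matrix == 100.0)
        assert np.all(np.diff(cols[np.argsort(rows)]) == 1)

    def test_static_movie_gives_identical_rows(self):
        rng = np.random.default_rng(0)
        frame = rng.uniform(0, 50, size=(5, 20))
        data = np.repeat(frame[None], 10, axis=0)
        stack = kymo.MovieStack(data, 0.12, 0.13)
        km = kymo.build_kymograph(stack, straight_path(stack))
        assert np.allclose(km.matrix, km.matrix[0])

    def test_synthetic_streak_slope_matches_configured_speed(self):
        """v = 0.22 um/s at 0.12 s/frame, 0.13 um/px -> 0.203 px/frame."""
        cfg = single_train_config()
        stack, truth = simulate_ift_movie(cfg, apply_noise=False)
        km = kymo.build_kymograph(stack, straight_path(stack))
        rec = truth.true_tracks[0]
        frames = np.array(rec.frames[3:-3])
        cents = []
        for f in frames:
            w = km.matrix[f] - cfg.background
            w = np.clip(w, 0, None)
            cents.append((np.arange(w.size) * w).sum() / w.sum())
        slope = np.polyfit(frames, cents, 1)[0]
        expected = cfg.antero_speed_um_s * cfg.frame_interval_s / cfg.pixel_size_um
        assert slope == pytest.approx(expected, rel=0.02)
        assert expected == pytest.approx(0.203, abs=0.001)

    def test_path_outside_image_names_vertex(self):
        stack = kymo.MovieStack(np.zeros((3, 5, 10)), 0.12, 0.13)
        path = kymo.CiliumPath(np.array([[2.0, 0.0], [2.0, 30.0]]))
        with pytest.raises(ValueError, match="vertex"):
            kymo.build_kymograph(stack, path)


class TestSeparateDirections:
    def test_single_train_energy_in_correct_quadrants(self, single_train):
        cfg, stack, truth = single_train
        km = kymo.build_kymograph(stack, straight_path(stack))
        dk = kymo.separate_directions(km)
        ea = float((dk.anterograde.matrix**2).sum())
        er = float((dk.retrograde.matrix**2).sum())
        assert ea / (ea + er) >= 0.9

    def test_space_flip_swaps_outputs_exactly(self, single_train):
        _, stack, _ = single_train
        km = kymo.build_kymograph(stack, straight_path(stack))
        dk = kymo.separate_directions(km)
        km_f = kymo.Kymograph(km.matrix[:, ::-1], km.pixel_size_um, km.frame_interval_s)
        dkf = kymo.separate_directions(km_f)
        assert np.allclose(dkf.anterograde.matrix, dk.retrograde.matrix[:, ::-1])
        assert np.allclose(dkf.retrograde.matrix, dk.anterograde.matrix[:, ::-1])

    def test_time_constant_band_lands_in_static(self):
        m = np.zeros((32, 32))
        m[:, 10:13] = 50.0
        km = kymo.Kymograph(m, 0.13, 0.12)
        dk = kymo.separate_directions(km)
        assert np.allclose(dk.static.matrix, m)
        assert np.allclose(dk.anterograde.matrix, 0.0, atol=1e-9)

    def test_all_zero_kymograph_gives_zero_outputs(self):
        km = kymo.Kymograph(np.zeros((16, 16)), 0.13, 0.12)
        dk = kymo.separate_directions(km)
        assert np.allclose(dk.anterograde.matrix, 0.0)
        assert np.allclose(dk.retrograde.matrix, 0.0)

    def test_components_sum_to_input_before_clipping(self, single_train):
        """Anterograde + retrograde + static reconstruct the kymograph in the
        interior (windowing affects only what the clip removes)."""
        _, stack, _ = single_train
        km = kymo.build_kymograph(stack, straight_path(stack))
        dk = kymo.separate_directions(km)
        recon = dk.anterograde.matrix + dk.retrograde.matrix + dk.static.matrix
        # clipping discards negative halves, so compare where recon is bright
        bright = km.matrix > np.percentile(km.matrix, 99)
        assert recon[bright] == pytest.approx(km.matrix[bright], rel=0.35)


class TestExtractTracks:
    def test_blank_input_gives_empty_list(self):
        z = kymo.Kymograph(np.zeros((20, 20)), 0.13, 0.12)
        dk = kymo.DirectionalKymographs(z, z, z)
        assert kymo.extract_tracks(dk) == []

    def test_two_nonoverlapping_trains_recovered_with_directions(self):
        cfg = IFTSimConfig(seed=21, antero_injection_rate_hz=0.01,
                           retro_injection_rate_hz=0.01, n_frames=400)
        stack, truth = simulate_ift_movie(cfg)
        km, dk, tracks, _ = analyze_movie(stack)
        truth_dirs = sorted(t.direction for t in truth.true_tracks
                            if len(t.frames) >= 5)
        rec_dirs = sorted(t.direction for t in tracks)
        assert rec_dirs == truth_dirs

    def test_track_count_and_directions_on_busy_movie(self):
        """>= 90% of trains recovered, none with a flipped direction."""
        n_rec = n_truth = 0
        for seed in (31, 32, 33, 34):
            cfg = IFTSimConfig(seed=seed, n_frames=1000, pause_prob=0.3)
            stack, truth = simulate_ift_movie(cfg)
            _, _, tracks, _ = analyze_movie(stack)
            margin = truth.true_quant["margin_px"] * cfg.pixel_size_um
            for tt in truth.true_tracks:
                if len(tt.frames) < 15:
                    continue
                n_truth += 1
                for t in tracks:
                    if t.direction != tt.direction:
                        continue
                    common = np.intersect1d(
                        t.frames.astype(int), np.asarray(tt.frames)
                    )
                    if len(common) < 5:
                        continue
                    rec = np.interp(common, t.frames, t.positions_um)
                    tru = np.interp(
                        common, tt.frames, np.asarray(tt.positions_um) + margin
                    )
                    if np.median(np.abs(rec - tru)) < 2 * cfg.pixel_size_um:
                        n_rec += 1
                        break
        assert n_truth >= 20
        assert n_rec / n_truth >= 0.9


class TestTrackVelocity:
    def test_constant_velocity_arithmetic(self):
        frames = np.arange(10)
        track = _toy_track(frames, frames * 0.0264)
        assert kymo.track_velocity(track) == pytest.approx(0.22, abs=1e-9)

    def test_stationary_track_is_zero(self):
        track = _toy_track(np.arange(8), np.full(8, 1.3))
        assert kymo.track_velocity(track) == pytest.approx(0.0, abs=1e-12)

    def test_velocity_excludes_stalled_samples(self):
        """A pause must not dilute the travel speed into a chord average."""
        f1 = np.arange(10)
        s1 = f1 * 0.144  # 1.2 um/s
        f2 = np.arange(10, 20)
        s2 = np.full(10, s1[-1])  # 10-frame pause
        f3 = np.arange(20, 30)
        s3 = s2[-1] + (f3 - 20) * 0.144
        track = _toy_track(np.r_[f1, f2, f3], np.r_[s1, s2, s3])
        track.stalls = kymo.detect_stalls(track)
        assert kymo.track_velocity(track) == pytest.approx(1.2, rel=0.05)

    def test_degenerate_track_rejected(self):
        with pytest.raises(ValueError):
            kymo.track_velocity(_toy_track(np.arange(3), np.zeros(3)))


class TestDetectStalls:
    def test_constant_motion_has_no_stalls(self):
        track = _toy_track(np.arange(30), np.arange(30) * 0.144)
        assert kymo.detect_stalls(track) == []

    def test_injected_plateau_found_once(self):
        f = np.arange(30)
        s = np.where(f < 10, f * 0.144,
                     np.where(f < 15, 10 * 0.144, (f - 5) * 0.144))
        track = _toy_track(f, s)
        stalls = kymo.detect_stalls(track)
        assert len(stalls) == 1
        start, end = stalls[0]
        assert abs(start - 10) <= 2 and abs(end - 15) <= 2


class TestTrainLength:
    @staticmethod
    def _fwhm_oracle(length_nm, sigma_um):
        """Brute-force convolution of a boxcar with the Gaussian PSF."""
        x = np.linspace(-3, 3, 120001)
        box = (np.abs(x) <= length_nm / 2000.0).astype(float)
        g = np.exp(-(x**2) / (2 * sigma_um**2))
        prof = np.convolve(box, g, mode="same")
        prof /= prof.max()
        above = x[prof >= 0.5]
        return (above[-1] - above[0]) * 1000.0

    def test_boxcar_convolution_widening(self):
        cfg = single_train_config(antero_length_nm=358.0)
        stack, _ = simulate_ift_movie(cfg, apply_noise=False)
        km, _, tracks, _ = analyze_movie(stack)
        measured = kymo.train_length(tracks[0], km)
        assert measured == pytest.approx(
            self._fwhm_oracle(358.0, cfg.psf_sigma_um), rel=0.05
        )

    def test_delta_train_gives_psf_fwhm(self):
        cfg = single_train_config(antero_length_nm=10.0)
        stack, _ = simulate_ift_movie(cfg, apply_noise=False)
        km, _, tracks, _ = analyze_movie(stack)
        psf_fwhm_nm = 2.355 * cfg.psf_sigma_um * 1000.0
        assert kymo.train_length(tracks[0], km) == pytest.approx(
            psf_fwhm_nm, rel=0.07
        )

    def test_length_sweep_monotone(self):
        measured = []
        for length in (150.0, 275.0, 400.0, 525.0, 650.0):
            cfg = single_train_config(antero_length_nm=length)
            stack, _ = simulate_ift_movie(cfg, apply_noise=False)
            km, _, tracks, _ = analyze_movie(stack)
            measured.append(kymo.train_length(tracks[0], km))
        assert np.all(np.diff(measured) > 0)


class TestParticlesPerTrain:
    @pytest.mark.parametrize(
        "length_nm,expected", [(358.0, 58), (237.0, 38), (0.0, 0)]
    )
    def test_worked_examples(self, length_nm, expected):
        assert kymo.particles_per_train(length_nm) == expected

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            kymo.particles_per_train(-1.0)

    @given(length=st.floats(0.0, 5000.0), spacing=st.floats(1.0, 50.0))
    @settings(max_examples=50, deadline=None)
    def test_exact_integer_arithmetic(self, length, spacing):
        n = kymo.particles_per_train(length, spacing)
        assert isinstance(n, int)
        assert abs(n - length / spacing) <= 0.5


class TestFindEncounters:
    def test_crossing_lines_yield_one_event_at_intersection(self):
        f = np.arange(30)
        antero = _toy_track(f, 0.5 + f * 0.0264, "anterograde")
        retro = _toy_track(f, 3.5 - f * 0.144, "retrograde")
        retro.velocity_um_s = -1.2
        events = kymo.find_encounters([antero, retro])
        assert len(events) == 1
        e = events[0]
        # analytic intersection: 0.5 + 0.0264 f = 3.5 - 0.144 f
        t_star = 3.0 / (0.0264 + 0.144)
        assert e.frame == pytest.approx(t_star, abs=0.5)
        assert e.arc_position_um == pytest.approx(0.5 + 0.0264 * t_star, abs=0.05)
        assert e.outcome == "pass"

    def test_parallel_same_direction_tracks_no_events(self):
        f = np.arange(20)
        a = _toy_track(f, f * 0.0264, "anterograde")
        b = _toy_track(f, 1.0 + f * 0.0264, "anterograde")
        assert kymo.find_encounters([a, b]) == []

    def test_stalled_retro_classified_as_pause(self):
        f = np.arange(40)
        antero = _toy_track(f, 0.5 + f * 0.0264, "anterograde")
        s = np.where(f < 15, 3.0 - f * 0.144,
                     np.where(f < 25, 3.0 - 15 * 0.144, 3.0 - (f - 10) * 0.144))
        retro = _toy_track(f, s, "retrograde")
        retro.stalls = kymo.detect_stalls(retro)
        retro.velocity_um_s = -kymo.track_velocity(retro)
        events = kymo.find_encounters([antero, retro])
        assert len(events) == 1
        assert events[0].outcome == "pause"
        assert events[0].pause_duration_s > 0


class TestSummaries:
    def test_empty_input(self):
        stats = kymo.summarize_trains([], [])
        assert stats.per_direction["anterograde"]["n_tracks"] == 0
        assert stats.fraction_retro_with_stall is None
        assert stats.fraction_pause_on_encounter is None

    def test_single_track_median_equals_mean(self):
        track = _toy_track(np.arange(10), np.arange(10) * 0.0264)
        track.velocity_um_s = kymo.track_velocity(track)
        stats = kymo.summarize_trains([track], [])
        d = stats.per_direction["anterograde"]
        assert d["velocity_median_um_s"] == pytest.approx(0.22, abs=1e-6)
        assert d["velocity_mean_um_s"] == pytest.approx(0.22, abs=1e-6)

    def test_stats_frame_has_both_directions(self):
        df = kymo.summarize_trains([], []).to_frame()
        assert set(df["direction"]) == {"anterograde", "retrograde"}
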