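import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radarbreath.radar_model import RadarConfig, wavelength
from radarbreath.range_phase import (
    BinTrack,
    ClutterState,
    RangeCube,
    detect_max_bin,
    extract_phase_trace,
    normalize_trace,
    resample_session,
    select_phase_bin,
    to_range_cube,
    track_bin_window,
    unwrap_phase,
    update_clutter,
)
from radarbreath.synthetic_scene import NoiseSpec, SessionRecord, make_user, simulate_session


def _record(frames, belt=None, fs=20.0):
    n = frames.shape[0]
    return SessionRecord(frames=frames, belt=belt if belt is not None else np.zeros(n),
                         user_id="t", distance_class=30, frame_rate=fs)


class TestResample:
    def test_identity_at_target_length(self, idle_record):
        assert resample_session(idle_record, 660) is idle_record

    def test_downsampling_hits_original_grid_points(self):
        frames = np.arange(1320, dtype=float).reshape(1320, 1, 1, 1)
        rec = resample_session(_record(frames, belt=np.arange(1320.0)), 660)
        # grid points land at stride 2 minus edge effects of linspace
        grid = np.linspace(0, 1319, 660)
        assert np.allclose(rec.belt, grid)
        assert rec.frames.shape[0] == 660

    def test_short_input_zero_padded_at_tail(self):
        frames = np.ones((600, 1, 1, 4))
        rec = resample_session(_record(frames, belt=np.ones(600)), 660)
        assert rec.frames.shape[0] == 660
        assert np.all(rec.frames[600:] == 0)
        assert np.all(rec.belt[600:] == 0)

    def test_empty_session_rejected(self):
        with pytest.raises(ValueError):
            resample_session(_record(np.empty((0, 1, 1, 4))), 660)


class TestRangeCube:
    def test_stationary_target_dominates_its_bin(self, cfg):
        prof = make_user(9, overrides={"motion_rate": 0.0, "breath_amp": 0.0,
                                       "base_range": 0.3})
        rec = simulate_session(prof, cfg, seed=9,
                               noise=NoiseSpec(adc_noise_std=0.0, clutter=()))
        cube = to_range_cube(rec, cfg)
        expected = int(round(0.3 / cube.bin_spacing))
        maxima = {detect_max_bin(cube, m) for m in range(cube.n_frames)}
        assert maxima == {expected}

    def test_zero_frames_zero_cube(self, cfg):
        cube = to_range_cube(_record(np.zeros((8, cfg.n_chirps, cfg.n_rx, cfg.n_samples))), cfg)
        assert np.all(cube.sr == 0)

    def test_constant_offset_removed(self, cfg):
        rng = np.random.default_rng(0)
        frames = rng.normal(0, 1, (8, cfg.n_chirps, cfg.n_rx, cfg.n_samples))
        c1 = to_range_cube(_record(frames), cfg)
        c2 = to_range_cube(_record(frames + 123.4), cfg)
        assert np.allclose(c1.sr, c2.sr, atol=1e-8)

    def test_shape_mismatch_rejected(self, cfg):
        with pytest.raises(ValueError):
            to_range_cube(_record(np.zeros((4, 1, 1, 16))), cfg)


class TestBinSelection:
    def test_detect_max_bin_simple_and_tie(self):
        cube = RangeCube(sr=np.array([[0.0, 1.0, 5.0, 2.0]], dtype=complex),
                         bin_spacing=0.05)
        assert detect_max_bin(cube, 0, min_bin=0) == 2
        tie = RangeCube(sr=np.array([[0.0, 3.0, 3.0, 1.0]], dtype=complex),
                        bin_spacing=0.05)
        assert detect_max_bin(tie, 0, min_bin=0) == 1  # lowest index wins

    def test_detect_max_bin_matches_exhaustive_scan(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            sr = rng.normal(size=(1, 40)) + 1j * rng.normal(size=(1, 40))
            cube = RangeCube(sr=sr, bin_spacing=0.05)
            brute = min(range(2, 40), key=lambda s: (-abs(sr[0, s]), s))
            assert detect_max_bin(cube, 0) == brute

    def test_constant_max_bin_gives_static_window(self):
        sr = np.zeros((30, 64), dtype=complex)
        sr[:, 20] = 10.0
        track = track_bin_window(RangeCube(sr=sr, bin_spacing=0.05))
        assert np.all(track.window_lo == 14) and np.all(track.window_hi == 25)
        assert np.all(track.window_hi - track.window_lo + 1 == 12)

    def test_warm_up_uses_available_history_and_spike_damped(self):
        sr = np.zeros((20, 64), dtype=complex)
        sr[:, 20] = 10.0
        sr[10, 20] = 0.0
        sr[10, 28] = 50.0  # single-frame spike by 8 bins
        track = track_bin_window(RangeCube(sr=sr, bin_spacing=0.05))
        assert track.window_lo[0] == 14  # first frame centred on its own max
        # smoothed centre moves by at most ceil(8/8) = 1 bin at the spike
        assert abs(track.window_lo[10] - track.window_lo[9]) <= 1


class TestClutter:
    def test_single_step(self):
        state = ClutterState(s_bar=np.zeros(1, dtype=complex), alpha=0.4)
        out = update_clutter(state, np.array([1.0 + 0j]))
        assert out.s_bar[0] == pytest.approx(0.4 + 0j)

    def test_two_steps(self):
        state = ClutterState(s_bar=np.zeros(1, dtype=complex), alpha=0.4)
        state = update_clutter(state, np.array([1.0 + 0j]))
        state = update_clutter(state, np.array([1.0 + 0j]))
        assert state.s_bar[0] == pytest.approx(0.64 + 0j)

    def test_geometric_convergence_to_constant_input(self):
        c = 2.0 - 1.5j
        state = ClutterState(s_bar=np.zeros(1, dtype=complex), alpha=0.4)
        for k in range(1, 15):
            state = update_clutter(state, np.array([c]))
            assert abs(state.s_bar[0] - c) == pytest.approx(0.6 ** k * abs(c), rel=1e-9)

    def test_static_scene_residual_decays_below_one_percent(self):
        # ceil(log 0.01 / log 0.6) = 10 frames
        state = ClutterState(s_bar=np.zeros(1, dtype=complex), alpha=0.4)
        c = np.array([3.0 + 4j])
        n = int(np.ceil(np.log(0.01) / np.log(0.6)))
        for _ in range(n):
            state = update_clutter(state, c)
        assert abs(c[0] - state.s_bar[0]) < 0.01 * abs(c[0])

    def test_alpha_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            ClutterState(s_bar=np.zeros(1, dtype=complex), alpha=1.2)


class TestSelectPhaseBin:
    def test_tie_returns_lowest_index(self):
        frame = np.ones(12, dtype=complex)
        clutter = ClutterState(s_bar=np.ones(12, dtype=complex))
        assert select_phase_bin(frame, clutter, 0, 11) == 0

    def test_zero_clutter_reduces_to_magnitude_argmax(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            frame = rng.uniform(0, 5, 12).astype(complex)
            clutter = ClutterState(s_bar=np.zeros(12, dtype=complex))
            assert select_phase_bin(frame, clutter, 0, 11) == int(np.argmax(np.abs(frame)))

    def test_breathing_bin_selected_over_static_clutter(self, cfg):
        prof = make_user(13, overrides={"motion_rate": 0.0, "base_range": 0.3})
        rec = simulate_session(prof, cfg, seed=13,
                               noise=NoiseSpec(adc_noise_std=0.0, belt_noise_std=0.0))
        trace = extract_phase_trace(rec, cfg)
        cube = to_range_cube(rec, cfg)
        target = int(round(0.3 / cube.bin_spacing))
        hit = np.mean(np.abs(trace.selected_bin[20:] - target) <= 1)
        assert hit >= 0.95


class TestUnwrap:
    def test_hand_evaluated_example(self):
        out = unwrap_phase(np.array([0.0, 2.5, -2.9]))
        assert np.allclose(out, [0.0, 2.5, -2.9 + 2 * np.pi], atol=1e-12)

    def test_small_steps_untouched(self):
        x = np.cumsum(np.full(50, 0.05))
        assert np.allclose(unwrap_phase(np.angle(np.exp(1j * x))), x, atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_unwrap_inverts_wrapping_up_to_constant(self, seed):
        rng = np.random.default_rng(seed)
        phi = np.cumsum(rng.uniform(-2.5, 2.5, 200))
        wrapped = np.angle(np.exp(1j * phi))
        rec = unwrap_phase(wrapped)
        offset = rec - phi
        assert np.allclose(offset, offset[0], atol=1e-9)
        assert np.allclose(offset[0] % (2 * np.pi), [0], atol=1e-9) or np.allclose(
            offset[0] % (2 * np.pi), [2 * np.pi], atol=1e-9)


class TestPhaseTrace:
    def test_displacement_recovered_within_five_percent(self, cfg):
        lam = wavelength(cfg)
        for seed in (0, 1, 2):
            prof = make_user(seed, overrides={"motion_rate": 0.0})
            rec = simulate_session(prof, cfg, seed=seed,
                                   noise=NoiseSpec(adc_noise_std=0.0, belt_noise_std=0.0))
            tr = extract_phase_trace(rec, cfg)
            d = tr.raw_phase * lam / (4 * np.pi)
            truth = rec.displacement
            rmse = min(
                np.sqrt(np.mean(((s * d - s * d.mean()) - (truth - truth.mean())) ** 2))
                for s in (1.0, -1.0)
            )
            assert rmse < 0.05 * prof.breath_amp

    def test_normalization_spans_unit_interval(self, idle_record, cfg):
        tr = extract_phase_trace(idle_record, cfg)
        assert tr.x.min() == 0.0 and tr.x.max() == 1.0

    def test_constant_trace_normalizes_to_half(self):
        assert np.all(normalize_trace(np.full(10, 3.3)) == 0.5)
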