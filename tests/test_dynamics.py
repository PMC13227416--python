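import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiodyn import (
    EmbryoMeta,
    EmbryoTracks,
    InsufficientDataError,
    NucleusTrack,
    RunConfig,
    ValidationError,
    contralateral_distance,
    embryo_oscillation_summary,
    estimate_midline,
    gen_tracks,
    medial_velocity,
    migration_speed,
    oscillation_period,
    pair_contralateral,
    per_cardioblast_metrics,
    register_tracks_time,
    step_decomposition,
)
from cardiodyn.simulate import TrackSimParams

from conftest import straight_track


def track_from_x(x, cb_id="t", row="right", y=None, dt_frames=None):
    x = np.asarray(x, dtype=float)
    frames = np.arange(len(x)) if dt_frames is None else dt_frames
    y = np.zeros(len(x)) if y is None else np.asarray(y, dtype=float)
    return NucleusTrack(cardioblast_id=cb_id, row=row, frames=frames,
                        xy=np.column_stack([x, y]))


def row_tracks(n, row, x0, y_positions):
    return [
        straight_track(f"{row[0]}{i}", row, x0, 0.0, y=y)
        for i, y in enumerate(y_positions)
    ]


class TestPairing:
    def test_pairs_by_ap_rank(self, meta):
        left = row_tracks(3, "left", -35.0, [0.0, 10.0, 20.0])
        right = row_tracks(3, "right", 35.0, [21.0, 1.0, 9.0])
        tracks = EmbryoTracks(meta=meta, tracks=left + right)
        pairs = pair_contralateral(tracks)
        assert pairs == [("l0", "r1"), ("l1", "r2"), ("l2", "r0")]

    def test_surplus_tracks_unpaired(self, meta):
        left = row_tracks(4, "left", -35.0, [0.0, 10.0, 20.0, 30.0])
        right = row_tracks(3, "right", 35.0, [0.0, 10.0, 20.0])
        pairs = pair_contralateral(EmbryoTracks(meta=meta, tracks=left + right))
        assert len(pairs) == 3

    def test_order_free(self, meta):
        left = row_tracks(3, "left", -35.0, [0.0, 10.0, 20.0])
        right = row_tracks(3, "right", 35.0, [0.0, 10.0, 20.0])
        p1 = pair_contralateral(EmbryoTracks(meta=meta, tracks=left + right))
        p2 = pair_contralateral(EmbryoTracks(meta=meta, tracks=right[::-1] + left[::-1]))
        assert p1 == p2

    def test_empty_row_rejected(self, meta):
        left = row_tracks(2, "left", -35.0, [0.0, 10.0])
        with pytest.raises(ValidationError):
            pair_contralateral(EmbryoTracks(meta=meta, tracks=left))


class TestDistances:
    def test_straight_rows_distance(self, meta):
        left = row_tracks(2, "left", -35.0, [0.0, 10.0])
        right = row_tracks(2, "right", 35.0, [0.0, 10.0])
        tracks = EmbryoTracks(meta=meta, tracks=left + right)
        series = contralateral_distance(tracks, pair_contralateral(tracks))
        np.testing.assert_allclose(series.mean_distance, 70.0)

    def test_single_pair_pythagoras(self, meta):
        a = track_from_x([0.0, 0.0], cb_id="L", row="left", y=[0.0, 0.0])
        b = track_from_x([3.0, 3.0], cb_id="R", row="right", y=[4.0, 4.0])
        series = contralateral_distance(
            EmbryoTracks(meta=meta, tracks=[a, b]), [("L", "R")]
        )
        np.testing.assert_allclose(series.mean_distance, 5.0)

    def test_no_common_frames_rejected(self, meta):
        a = NucleusTrack("L", "left", np.array([0, 1]), np.zeros((2, 2)))
        b = NucleusTrack("R", "right", np.array([2, 3]), np.ones((2, 2)))
        with pytest.raises(ValidationError):
            contralateral_distance(EmbryoTracks(meta=meta, tracks=[a, b]), [("L", "R")])

    def test_converging_rows_distance_decreases(self, meta):
        tracks = gen_tracks(TrackSimParams(n_per_row=4, seed=5))
        series = contralateral_distance(tracks, pair_contralateral(tracks))
        # monotone within noise: strong negative trend, endpoints well separated
        assert series.mean_distance[-1] < series.mean_distance[0] - 15.0
        assert np.polyfit(np.arange(len(series.mean_distance)), series.mean_distance, 1)[0] < 0

    def test_registration_rule(self, meta):
        left = [track_from_x(x, cb_id="L", row="left") for x in [[-40, -35, -33, -32, -25]]][0]
        right = [track_from_x(x, cb_id="R", row="right") for x in [[40, 35, 33, 32, 25]]][0]
        series = contralateral_distance(
            EmbryoTracks(meta=meta, tracks=[left, right]), [("L", "R")]
        )
        np.testing.assert_allclose(series.mean_distance, [80, 70, 66, 64, 50])
        assert register_tracks_time(series, 65.0) == 2

    def test_registration_fallbacks(self, meta, caplog):
        low = track_from_x([-30, -29], cb_id="L", row="left")
        high = track_from_x([30, 29], cb_id="R", row="right")
        series = contralateral_distance(
            EmbryoTracks(meta=meta, tracks=[low, high]), [("L", "R")]
        )
        with caplog.at_level("WARNING", logger="cardiodyn"):
            assert register_tracks_time(series, 65.0) == 0  # all below: warn + first
        assert register_tracks_time(series, 40.0) == 1  # all above: last


class TestSpeed:
    def test_linear_motion_exact(self):
        t = straight_track("a", "right", 40.0, -23.0, n_frames=30)
        assert migration_speed(t) == pytest.approx(23.0, abs=1e-9)

    def test_stationary_zero(self):
        t = track_from_x(np.full(10, 12.0))
        assert migration_speed(t) == pytest.approx(0.0, abs=1e-12)

    def test_drift_plus_oscillation_slope(self):
        drift = 22.4  # μm/hr
        tmin = np.arange(241) * 0.25  # 60 min
        x = 40.0 - drift / 60.0 * tmin - 1.0 * np.sin(2 * np.pi * tmin / 1.4)
        t = track_from_x(x)
        assert 21.4 <= migration_speed(t) <= 23.4

    def test_too_short_rejected(self):
        with pytest.raises(InsufficientDataError):
            migration_speed(track_from_x([0.0, 1.0]))


class TestMedialVelocity:
    def test_right_row_toward_midline_is_positive(self):
        t = track_from_x([40.0, 30.0], dt_frames=np.array([0, 4]))  # 1 min at 15 s
        v = medial_velocity(t, 0.0, 15.0)
        assert v == pytest.approx([10.0])

    def test_left_row_mirror_symmetry(self):
        t = track_from_x([-40.0, -30.0], row="left", dt_frames=np.array([0, 4]))
        v = medial_velocity(t, 0.0, 15.0)
        assert v == pytest.approx([10.0])

    def test_constant_position_zero(self):
        v = medial_velocity(track_from_x(np.full(6, 25.0)), 0.0, 15.0)
        np.testing.assert_allclose(v, 0.0)


class TestPeriod:
    def test_off_grid_sinusoid_refined(self):
        t = np.arange(0.0, 40.0, 0.25)
        v = np.sin(2 * np.pi * t / 1.7)
        assert oscillation_period(v, 15.0) == pytest.approx(1.70, abs=0.05)

    def test_on_grid_sinusoid(self):
        t = np.arange(0.0, 40.0, 0.25)
        v = np.sin(2 * np.pi * t / 2.0)
        assert oscillation_period(v, 15.0) == pytest.approx(2.0, abs=0.01)

    def test_white_noise_has_no_period(self):
        missing = 0
        for seed in range(50):
            rng = np.random.default_rng(3 + seed)
            v = rng.normal(0.0, 1.0, 160)
            if math.isnan(oscillation_period(v, 15.0)):
                missing += 1
        assert missing >= 45  # >= 90% of seeds

    def test_too_short_rejected(self):
        with pytest.raises(InsufficientDataError):
            oscillation_period(np.ones(7), 15.0)

    @pytest.mark.parametrize("period", [1.0, 1.4, 1.7, 2.5])
    def test_period_recovery_under_noise(self, period):
        """Median |error| <= 0.1 min at 20% velocity noise, 15 s sampling."""
        errors = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            t = np.arange(0.0, 40.0, 0.25)
            v = np.sin(2 * np.pi * t / period + rng.uniform(0, 2 * np.pi))
            v = v + rng.normal(0.0, 0.2, len(t))
            p = oscillation_period(v, 15.0)
            errors.append(abs(p - period))
        assert np.median(errors) <= 0.1


class TestSteps:
    def test_ratchet_exact_recovery(self):
        params = TrackSimParams(
            mode="ratchet", n_per_row=1, medial_step=1.9, lateral_step=0.8,
            position_noise_sd=0.0, n_frames=141, seed=0,
        )
        tracks = gen_tracks(params)
        res = step_decomposition(tracks.tracks[0], 0.0, RunConfig())
        assert res.medial_amp == pytest.approx(1.9, abs=1e-9)
        assert res.lateral_amp == pytest.approx(0.8, abs=1e-9)
        assert res.net_medial_step == res.medial_amp - res.lateral_amp
        assert res.n_medial_steps == 20 and res.n_lateral_steps == 20

    def test_pure_sinusoid_balanced_steps(self):
        t = np.arange(0.0, 40.0, 0.25)
        b = 1.5
        x = 30.0 + b * np.sin(2 * np.pi * t / 2.0)
        res = step_decomposition(track_from_x(x), 0.0, RunConfig())
        assert res.medial_amp == pytest.approx(2 * b, rel=0.05)
        assert res.lateral_amp == pytest.approx(2 * b, rel=0.05)
        assert abs(res.net_medial_step) <= 0.2

    def test_monotone_track_single_step(self):
        x = np.linspace(40.0, 30.0, 20)
        res = step_decomposition(track_from_x(x), 0.0, RunConfig())
        assert res.n_medial_steps == 1 and res.n_lateral_steps == 0
        assert res.medial_amp == pytest.approx(10.0)
        assert res.lateral_amp == 0.0
        assert res.net_medial_step == pytest.approx(10.0)

    def test_amplitude_recovery_under_noise(self):
        """Generated amplitudes recovered within 0.1 μm at 0.1 μm noise."""
        meds, lats = [], []
        for seed in range(20):
            params = TrackSimParams(
                mode="ratchet", n_per_row=1, medial_step=1.9, lateral_step=0.8,
                position_noise_sd=0.1, n_frames=141, seed=seed,
            )
            tracks = gen_tracks(params)
            mid = estimate_midline(tracks)
            res = step_decomposition(tracks.tracks[1], mid, RunConfig())
            meds.append(res.medial_amp)
            lats.append(res.lateral_amp)
        assert np.mean(meds) == pytest.approx(1.9, abs=0.1)
        assert np.mean(lats) == pytest.approx(0.8, abs=0.1)

    @given(st.integers(0, 10**6))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_net_step_identity_and_mirror_symmetry(self, seed):
        params = TrackSimParams(n_per_row=1, seed=seed, n_frames=81)
        tracks = gen_tracks(params)
        mid = estimate_midline(tracks)
        for t in tracks.tracks:
            res = step_decomposition(t, mid, RunConfig())
            if not math.isnan(res.net_medial_step):
                assert res.net_medial_step == res.medial_amp - res.lateral_amp
            # mirror all x about the midline: every metric unchanged
            mirrored = NucleusTrack(
                cardioblast_id=t.cardioblast_id, row=t.row, frames=t.frames,
                xy=np.column_stack([2 * mid - t.x, t.y]),
            )
            res_m = step_decomposition(mirrored, mid, RunConfig())
            np.testing.assert_allclose(
                [res_m.medial_amp, res_m.lateral_amp],
                [res.medial_amp, res.lateral_amp], atol=1e-9,
            )
            assert migration_speed(mirrored) == pytest.approx(migration_speed(t), abs=1e-9)


class TestEmbryoSummary:
    def test_identical_tracks_mean_equals_single_value(self, meta):
        base = TrackSimParams(
            n_per_row=1, position_noise_sd=0.0, sin_amplitude=0.0, seed=1, n_frames=121
        )
        tracks = gen_tracks(base)
        summary = embryo_oscillation_summary(tracks, RunConfig())
        df = per_cardioblast_metrics(tracks, RunConfig())
        # left/right tracks are mirror-identical without noise
        assert summary["speed"] == pytest.approx(df["speed"].iloc[0], abs=1e-9)
        assert summary["n_cardioblasts"] == 2

    def test_default_embryo_has_104_records(self):
        tracks = gen_tracks(TrackSimParams(seed=2, n_frames=41))
        df = per_cardioblast_metrics(tracks, RunConfig())
        assert len(df) == 104

    def test_replicate_embryos_agree_within_spread(self):
        vals = []
        for seed in (11, 12):
            tracks = gen_tracks(TrackSimParams(n_per_row=8, seed=seed))
            vals.append(embryo_oscillation_summary(tracks, RunConfig())["speed"])
        assert vals[0] == pytest.approx(vals[1], abs=2.0)
        for v in vals:
            assert v == pytest.approx(23.0, abs=2.0)
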