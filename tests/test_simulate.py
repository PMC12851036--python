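"""Generative rules of the eyelid-strain simulator: transduction, polarity,
angle monotonicity, magnitude caps, artifacts, determinism."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from gazestrain.constants import CH0, CH45, CH90, DIRECTIONS_8
from gazestrain.simulate import (
    DirectionPrior,
    GazeEvent,
    SensorSpec,
    default_priors,
    gaze_to_strain,
    generate_cohort,
    generate_recording,
    random_events,
    strain_to_resistance,
)


class TestTransduction:
    @pytest.mark.parametrize(
        "strain, expected",
        [(0.10, 0.0169), (0.0, 0.0), (0.15, 0.02535), (-0.10, -0.0169)],
    )
    def test_linear_gauge(self, strain, expected):
        assert strain_to_resistance(strain, SensorSpec()) == pytest.approx(expected)

    def test_out_of_range_strain_rejected(self):
        with pytest.raises(ValueError, match="measurement range"):
            strain_to_resistance(0.2, SensorSpec())

    @given(st.floats(-0.15, 0.15))
    def test_sign_preserving(self, strain):
        out = strain_to_resistance(strain, SensorSpec())
        assert np.sign(out) == np.sign(strain)


class TestDirectionPriors:
    def test_vertical_gaze_leaves_horizontal_unit_near_silent(self):
        priors = default_priors()
        for d in ("up", "down"):
            g = priors[d].unit_gains
            assert abs(g[CH0]) <= 0.1 * abs(g[CH90])
        for d in ("left", "right"):
            g = priors[d].unit_gains
            assert abs(g[CH90]) <= 0.1 * abs(g[CH0])

    def test_magnitude_caps(self):
        for prior in default_priors().values():
            cap = 0.04 if prior.direction == "down" else 0.11
            assert prior.max_eyelid_strain <= cap

    def test_eye_side_flips_horizontal_polarity(self):
        right_eye = default_priors("right")
        left_eye = default_priors("left")
        # gazing right: abduction for the right eye (+), adduction for the left (-)
        assert right_eye["right"].unit_gains[CH0] > 0
        assert left_eye["right"].unit_gains[CH0] < 0

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError):
            DirectionPrior("down", (0.05, 0.6, 1.0), 0.11)  # above the 4% cap
        with pytest.raises(ValueError):
            DirectionPrior("up", (0.5, 0.6, 1.0), 0.11)  # noisy horizontal unit


class TestGazeToStrain:
    def test_zero_angle_is_silent(self):
        ev = GazeEvent(onset=1.0, hold_duration=0.3, direction="up", angle_deg=0.0)
        out = gaze_to_strain(ev, default_priors()["up"], np.linspace(0, 3, 50))
        assert np.all(out == 0)

    def test_upward_hold_compresses_vertical_unit(self):
        ev = GazeEvent(onset=1.0, hold_duration=0.4, direction="up", angle_deg=18.0)
        hold_t = 1.0 + 0.15 + 0.2  # middle of the hold phase
        s = gaze_to_strain(ev, default_priors()["up"], hold_t)
        assert s[CH90] < 0
        assert abs(s[CH0]) <= 0.1 * abs(s[CH90])

    def test_hold_strain_linear_in_angle(self):
        prior = default_priors()["up"]
        hold_t = 1.0 + 0.15 + 0.2
        s5 = gaze_to_strain(
            GazeEvent(onset=1.0, hold_duration=0.4, direction="up", angle_deg=5.0),
            prior, hold_t,
        )
        s10 = gaze_to_strain(
            GazeEvent(onset=1.0, hold_duration=0.4, direction="up", angle_deg=10.0),
            prior, hold_t,
        )
        assert np.allclose(s10, 2.0 * s5)

    def test_returns_to_baseline_after_event(self):
        ev = GazeEvent(onset=1.0, hold_duration=0.3, direction="down", angle_deg=10.0)
        s = gaze_to_strain(ev, default_priors()["down"], ev.end + 0.1)
        assert np.all(s == 0)

    def test_mismatched_prior_rejected(self):
        ev = GazeEvent(onset=1.0, hold_duration=0.3, direction="up", angle_deg=10.0)
        with pytest.raises(ValueError, match="does not match"):
            gaze_to_strain(ev, default_priors()["down"], 1.3)


class TestPolarityTable:
    @pytest.mark.parametrize("direction", DIRECTIONS_8)
    def test_hold_sign_matches_unit_gains(self, direction):
        priors = default_priors()
        ev = GazeEvent(onset=1.0, hold_duration=0.4, direction=direction, angle_deg=15.0)
        s = gaze_to_strain(ev, priors[direction], 1.0 + 0.15 + 0.2)
        for u in range(3):
            expected = np.sign(priors[direction].unit_gains[u])
            assert np.sign(s[u]) == expected

    def test_opposite_directions_have_opposite_signs(self):
        priors = default_priors()
        hold_t = 1.0 + 0.15 + 0.2
        ev = lambda d: GazeEvent(onset=1.0, hold_duration=0.4, direction=d, angle_deg=12.0)
        up = gaze_to_strain(ev("up"), priors["up"], hold_t)
        down = gaze_to_strain(ev("down"), priors["down"], hold_t)
        assert up[CH90] < 0 < down[CH90]
        left = gaze_to_strain(ev("left"), priors["left"], hold_t)
        right = gaze_to_strain(ev("right"), priors["right"], hold_t)
        assert left[CH0] * right[CH0] < 0


class TestMonotonicity:
    @pytest.mark.parametrize("direction", DIRECTIONS_8)
    def test_peak_signal_strictly_increasing_with_angle(self, direction, quiet_sensor):
        peaks = []
        for angle in np.linspace(2.0, 18.0, 6):
            ev = GazeEvent(onset=1.0, hold_duration=0.35, direction=direction,
                           angle_deg=float(angle))
            rec = generate_recording([ev], sensor=quiet_sensor, duration=4.0, seed=0)
            peaks.append(np.abs(rec.channels).max())
        assert np.all(np.diff(peaks) > 0)

    def test_transduced_signal_never_exceeds_gauge_ceiling(self, quiet_sensor):
        rng = np.random.default_rng(0)
        events = random_events(24, rng, directions=DIRECTIONS_8, angle_range=(5, 20))
        rec = generate_recording(events, sensor=quiet_sensor, seed=0)
        assert np.abs(rec.channels).max() <= quiet_sensor.gauge_factor * quiet_sensor.max_strain + 1e-12


class TestGenerateRecording:
    def test_silence_without_events_or_noise(self, quiet_sensor):
        rec = generate_recording([], sensor=quiet_sensor, duration=3.0, seed=0)
        assert np.all(rec.channels == 0)

    def test_vertical_event_leaves_horizontal_channel_near_silent(self, single_event_recordings):
        rec = single_event_recordings["up"]
        peak0 = np.abs(rec.channels[CH0]).max()
        peak90 = np.abs(rec.channels[CH90]).max()
        assert peak0 < 0.1 * peak90

    def test_seeded_determinism(self):
        rng = np.random.default_rng(3)
        events = random_events(10, rng)
        a = generate_recording(events, seed=11)
        b = generate_recording(events, seed=11)
        assert np.array_equal(a.channels, b.channels)
        c = generate_recording(events, seed=12)
        assert not np.array_equal(a.channels, c.channels)

    def test_overlapping_events_rejected(self):
        events = [
            GazeEvent(onset=1.0, hold_duration=2.0, direction="up", angle_deg=10.0),
            GazeEvent(onset=1.5, hold_duration=0.3, direction="down", angle_deg=10.0),
        ]
        with pytest.raises(ValueError, match="overlap"):
            generate_recording(events)

    def test_annotations_preserved_in_onset_order(self):
        rng = np.random.default_rng(5)
        events = random_events(6, rng)
        rec = generate_recording(events, seed=0)
        assert [e.onset for e in rec.annotations] == sorted(e.onset for e in events)

    def test_blink_hits_all_channels_and_dwarfs_gaze_signals(self, quiet_sensor):
        blink = GazeEvent(onset=2.0, hold_duration=0.0, direction="blink")
        gaze = GazeEvent(onset=5.0, hold_duration=0.35, direction="up", angle_deg=15.0)
        rec = generate_recording([blink, gaze], sensor=quiet_sensor, duration=8.0, seed=1)
        t = rec.time
        in_blink = (t >= 2.0) & (t <= 2.3)
        in_gaze = (t >= 5.0) & (t <= 5.7)
        blink_peaks = np.abs(rec.channels[:, in_blink]).max(axis=1)
        gaze_peak = np.abs(rec.channels[:, in_gaze]).max()
        assert np.all(blink_peaks > 0.5 * gaze_peak)
        # both axis units deflect with the same sign at the blink peak: no
        # directional prior produces that pattern
        peak_idx = np.abs(rec.channels[CH90, in_blink]).argmax()
        seg = rec.channels[:, in_blink]
        assert np.sign(seg[CH0, peak_idx]) == np.sign(seg[CH90, peak_idx])


class TestCohort:
    def test_cohort_size_and_distinct_meta(self):
        recs = generate_cohort(7, events_per_subject=4, seed=0)
        assert len(recs) == 7
        ids = [r.subject_meta["subject_id"] for r in recs]
        assert ids == list(range(7))
        gains = {r.subject_meta["unit_gain_multipliers"] for r in recs}
        assert len(gains) == 7

    def test_zero_jitter_gives_identical_generators(self):
        recs = generate_cohort(3, events_per_subject=4, gain_jitter=0.0, seed=1)
        for r in recs:
            assert r.subject_meta["unit_gain_multipliers"] == (1.0, 1.0, 1.0)
            assert r.subject_meta["baseline_offset"] == 0.0

    def test_cohort_reproducible(self):
        a = generate_cohort(3, events_per_subject=5, seed=9)
        b = generate_cohort(3, events_per_subject=5, seed=9)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.channels, rb.channels)

    def test_needs_at_least_one_subject(self):
        with pytest.raises(ValueError):
            generate_cohort(0)
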