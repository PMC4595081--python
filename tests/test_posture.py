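"""Posture analytics: angles, coils, locomotion, eigenworms, events."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from nemapose.posture import (CoilAnnotation, classify_locomotion,
                              classify_spool, cluster_postures,
                              coil_event_stats, detect_coils, eigenworms,
                              extract_events, midline_angles,
                              posterior_body_angle, transition_summaries)
from nemapose.synth import sample_posture, simulate_behavior


def arc_midline(total_turn, n=101, radius_scale=100.0):
    """Constant-curvature arc with the given total turning angle."""
    th = np.linspace(0, total_turn, n)
    if abs(total_turn) < 1e-9:
        return np.stack([np.zeros(n), np.linspace(0, radius_scale, n)], 1)
    r = radius_scale / abs(total_turn)
    return r * np.stack([np.sin(th), 1 - np.cos(th)], axis=1)


class TestMidlineAngles:
    def test_straight_midline_gives_zero_angles(self):
        mid = np.stack([np.zeros(30), np.linspace(0, 100, 30)], 1)
        assert np.allclose(midline_angles(mid).angles, 0.0)

    @pytest.mark.parametrize("turn", [0.5, 1.5, -2.0])
    def test_arc_gives_uniform_angles_of_one_tenth_the_turning(self, turn):
        ang = midline_angles(arc_midline(turn)).angles
        assert np.allclose(ang, turn / 10, atol=1e-3)

    def test_rotation_invariance(self):
        mid = arc_midline(1.2)
        th = 0.77
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        assert np.allclose(midline_angles(mid).angles,
                           midline_angles(mid @ rot.T + 50).angles, atol=1e-9)

    def test_degenerate_midline_rejected(self):
        with pytest.raises(ValueError):
            midline_angles(np.zeros((5, 2)))

    def test_posterior_body_angle_is_the_tailmost_angle(self):
        mid = arc_midline(1.5)
        assert posterior_body_angle(midline_angles(mid)) == pytest.approx(
            0.15, abs=1e-3)
        mirrored = mid.copy()
        mirrored[:, 0] = -mirrored[:, 0]
        assert posterior_body_angle(midline_angles(mirrored)) == \
            pytest.approx(-0.15, abs=1e-3)


class TestDetectCoils:
    def test_straight_worm_has_no_coils(self):
        mid = np.stack([np.zeros(50), np.linspace(0, 100, 50)], 1)
        ann = detect_coils(mid, mid[-1], mid[0])
        assert (ann.anterior, ann.posterior) == (False, False)

    def test_closed_circle_coils_at_both_ends(self):
        th = np.linspace(0, 2 * np.pi * 0.98, 80)
        mid = 16 * np.stack([np.sin(th), np.cos(th)], 1)
        ann = detect_coils(mid, mid[-1], mid[0])
        assert (ann.anterior, ann.posterior) == (True, True)

    def test_omega_coils_at_the_head_only(self):
        post = sample_posture("omega", length=100, width=8, seed=3)
        mid = post.midline()
        ann = detect_coils(mid, mid[-1], mid[0])
        assert (ann.anterior, ann.posterior) == (True, False)

    @given(angle=st.floats(0, 2 * np.pi), scale=st.floats(0.3, 3.0),
           shift=st.floats(-40, 40))
    @settings(max_examples=25, deadline=None)
    def test_invariance_to_rigid_motion_and_scaling(self, angle, scale, shift):
        post = sample_posture("omega", length=100, width=8, seed=3)
        mid = post.midline()
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        tmid = scale * (mid @ rot.T) + shift
        a0 = detect_coils(mid, mid[-1], mid[0])
        a1 = detect_coils(tmid, tmid[-1], tmid[0])
        assert (a0.anterior, a0.posterior) == (a1.anterior, a1.posterior)


def traveling_wave(n_frames=120, fps=10.0, speed=0.5, amp=0.3, sign=+1):
    """Angle series of a bend wave traveling along the body."""
    t = np.arange(n_frames) / fps
    j = np.arange(18) / 18.0
    return amp * np.sin(2 * np.pi * (sign * speed * t[:, None] + 1.5 * j))


class TestClassifyLocomotion:
    def test_forward_wave_is_forward(self):
        states = classify_locomotion(traveling_wave(sign=+1), fps=10)
        interior = states[20:-20]
        assert interior.count("forward") / len(interior) > 0.9

    def test_time_reversal_swaps_direction(self):
        states = classify_locomotion(traveling_wave(sign=+1)[::-1], fps=10)
        interior = states[20:-20]
        assert interior.count("backward") / len(interior) > 0.9

    def test_constant_angles_are_quiescent(self):
        series = np.tile(np.linspace(-0.2, 0.2, 18), (100, 1))
        states = classify_locomotion(series, fps=10)
        assert set(states) == {"quiescent"}

    @pytest.mark.parametrize("speed", [0.15, 0.5, 1.5])
    def test_direction_recovered_across_speeds(self, speed):
        for sign in (+1, -1):
            states = classify_locomotion(
                traveling_wave(speed=speed, sign=sign), fps=10)
            want = "forward" if sign > 0 else "backward"
            interior = states[20:-20]
            assert interior.count(want) / len(interior) > 0.8

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            classify_locomotion(np.zeros((5, 18)), fps=10)


class TestEigenworms:
    def test_two_mode_data_explained_by_two_modes(self):
        rng = np.random.default_rng(0)
        b1 = np.sin(np.linspace(0, np.pi, 18))
        b2 = np.cos(np.linspace(0, 2 * np.pi, 18))
        amps = rng.normal(size=(200, 2))
        data = amps[:, :1] * b1 + amps[:, 1:] * b2
        eig = eigenworms(data)
        assert eig.explained_variance[:2].sum() == pytest.approx(1.0)

    def test_variance_fractions_are_a_distribution(self):
        rng = np.random.default_rng(1)
        eig = eigenworms(rng.normal(size=(100, 18)))
        ev = eig.explained_variance
        assert np.all(np.diff(ev) <= 1e-12)
        assert np.cumsum(ev)[-1] == pytest.approx(1.0)

    def test_projection_reconstruction_roundtrip(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(50, 18))
        eig = eigenworms(data)
        rec = eig.reconstruct(eig.project(data))
        assert np.allclose(rec, data, atol=1e-10)

    def test_band_limited_signal_plus_noise_concentrates_variance(self):
        # b basis functions + relative noise power eps: the leading b modes
        # explain at least 1 - eps of the variance
        rng = np.random.default_rng(3)
        s = np.linspace(0, 1, 18)
        basis = np.stack([np.cos(k * np.pi * s) for k in range(4)])
        amps = rng.normal(size=(500, 4)) * [2.0, 1.5, 1.0, 0.8]
        signal = amps @ basis
        eps = 0.05
        noise_sd = np.sqrt(eps * signal.var())
        eig = eigenworms(signal + rng.normal(0, noise_sd, signal.shape))
        assert eig.explained_variance[:4].sum() >= 1 - eps

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            eigenworms(np.zeros((10, 18)))


class TestClassifySpool:
    @pytest.mark.parametrize("a1,a2,want", [
        (1.5, 1.5, "spool"),          # product 2.25 > 1
        (3.0, 2.0, "severe_spool"),   # product 6 > 4
        (3.0, -2.0, "figure8"),       # product -6 < -4
        (0.5, 0.5, "neither"),
        (-1.0, 2.0, "neither"),
    ])
    def test_taxonomy(self, a1, a2, want):
        assert classify_spool(a1, a2) == want


class TestClusterPostures:
    def test_three_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        data = np.vstack([c + 0.3 * rng.normal(size=(40, 2)) for c in centers])
        cents, labels, counts = cluster_postures(data, k=3, redundancy=3)
        assert sorted(counts.tolist()) == [40, 40, 40]
        for c in cents:
            assert min(np.hypot(*(c - t)) for t in centers) < 1.0

    def test_k_equals_n_gives_zero_inertia(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(12, 3))
        cents, labels, counts = cluster_postures(data, k=12, redundancy=1)
        assert np.all(counts == 1)

    def test_more_restarts_never_worsen_inertia(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(100, 4))

        def inertia(redundancy):
            cents, labels, _ = cluster_postures(data, k=8,
                                                redundancy=redundancy)
            return sum(((data[labels == i] - c) ** 2).sum()
                       for i, c in enumerate(cents))

        assert inertia(5) <= inertia(1) + 1e-9

    def test_fewer_points_than_clusters_rejected(self):
        with pytest.raises(ValueError):
            cluster_postures(np.zeros((5, 2)), k=10)


class TestCoilEvents:
    def test_event_extraction_partitions_positive_frames(self):
        rng = np.random.default_rng(0)
        flags = rng.random(500) < 0.3
        events = extract_events(flags, "anterior", fps=10)
        covered = np.zeros_like(flags)
        for ev in events:
            assert not covered[ev.start:ev.end + 1].any()  # no double count
            covered[ev.start:ev.end + 1] = True
        assert np.array_equal(covered, flags)              # no frame lost

    def test_alternating_flags_give_single_frame_events(self):
        flags = np.tile([True, False], 30)
        stats = coil_event_stats(flags, fps=10)
        assert len(stats.events) == 30
        assert all(ev.duration == pytest.approx(0.1) for ev in stats.events)

    def test_weibull_parameters_recovered_within_ten_percent(self):
        rng = np.random.default_rng(42)
        shape, scale = 1.5, 10.0
        durations = scale * rng.weibull(shape, size=500)
        fps = 10.0
        flags = []
        for d in durations:
            flags.extend([True] * max(2, int(round(d * fps))))
            flags.extend([False] * 5)
        stats = coil_event_stats(np.array(flags), fps=fps)
        assert stats.fit_ok
        assert stats.weibull_shape == pytest.approx(shape, rel=0.10)
        assert stats.weibull_scale == pytest.approx(scale, rel=0.10)

    def test_exponential_durations_give_shape_one_and_scale_mean(self):
        rng = np.random.default_rng(7)
        durations = 8.0 * rng.exponential(size=600)
        fps = 10.0
        flags = []
        for d in durations:
            flags.extend([True] * max(2, int(round(d * fps))))
            flags.extend([False] * 4)
        stats = coil_event_stats(np.array(flags), fps=fps)
        assert stats.weibull_shape == pytest.approx(1.0, rel=0.10)
        mean_dur = np.mean([ev.duration for ev in stats.events
                            if ev.duration >= 2 / fps])
        assert stats.weibull_scale == pytest.approx(mean_dur, rel=0.10)

    def test_too_few_events_skip_the_fit(self):
        flags = np.zeros(100, bool)
        flags[10:20] = True
        stats = coil_event_stats(flags, fps=10)
        assert not stats.fit_ok and stats.weibull_shape is None


class TestTransitionSummaries:
    def test_coils_starting_after_forward_initiation_are_all_counted(self):
        fps = 10.0
        states = ["dwell"] * 1000
        flags = np.zeros(1000, bool)
        for start in (100, 300, 500, 700):
            for i in range(start, start + 50):
                states[i] = "forward"
            flags[start + 20:start + 30] = True   # coil 2 s after initiation
        out = transition_summaries(states, flags, fps, window=5.0)
        assert out.fraction_after_initiation == 1.0
        assert out.n_events == 4

    def test_shuffled_coils_match_baseline_propensities(self):
        rng = np.random.default_rng(0)
        states = list(rng.choice(["forward", "backward", "dwell"],
                                 p=[0.5, 0.3, 0.2], size=4000))
        flags = rng.random(4000) < 0.2   # independent of the states
        out = transition_summaries(states, flags, fps=10)
        for _, row in out.propensities.iterrows():
            # binomial error at n ~ 800 is ~ 2%; allow 4 sigma
            assert abs(row["during_coil"] - row["baseline"]) < 0.08

    def test_no_events_give_baseline_only_output(self):
        states = ["forward"] * 200
        out = transition_summaries(states, np.zeros(200, bool), fps=10)
        assert out.n_events == 0
        assert out.fraction_after_initiation is None
        assert not out.propensities.empty
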