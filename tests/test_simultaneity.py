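import itertools
import warnings

import numpy as np
import pytest

from mibdyn import (
    FpaWindow,
    FpaWindowSet,
    IntervalTrack,
    ObserverProfile,
    PerceptualEvent,
    SimCondition,
    apply_motor_model,
    calibrate_fpa,
    cluster_events,
    count_events,
    extract_events,
    generate_control_session,
    intervals_from_events,
    match_responses_to_schedule,
    simulate_target_states,
    validate_and_repair,
)
from mibdyn.fpa import DISAPPEARANCE, REAPPEARANCE


def window_set(min_a, max_a, observer="o1"):
    """Uniform window for both event types and sizes 2-3."""
    ws = FpaWindowSet(observer_id=observer)
    for ev in (DISAPPEARANCE, REAPPEARANCE):
        for size in (2, 3):
            ws.windows[(ev, size)] = FpaWindow(observer, ev, size, min_a, max_a, 10)
    return ws


def brute_force_max_sim(events, windows, ev_type, mode="strict"):
    """Oracle: enumerate ALL order-respecting partitions of one event-type
    stream into consecutive runs; return the maximal simultaneous-event
    count over partitions whose runs are admissible clusters."""
    evs = sorted(
        (e for e in events if e.event_type == ev_type),
        key=lambda e: (e.time, e.key),
    )
    n = len(evs)
    if n == 0:
        return 0
    best = 0
    # cut points: each subset of the n-1 gaps defines a partition
    for cuts in itertools.product([False, True], repeat=n - 1):
        bounds = [0] + [i + 1 for i, c in enumerate(cuts) if c] + [n]
        score = 0
        ok = True
        for a, b in zip(bounds, bounds[1:]):
            seg = evs[a:b]
            if len(seg) == 1:
                continue
            if len({e.key for e in seg}) != len(seg):
                ok = False
                break
            w = windows.window_for(ev_type, len(seg))
            span = seg[-1].time - seg[0].time
            if span > w.max_asynchrony:
                ok = False
                break
            if w.contains(span, relaxed=(mode == "relaxed")):
                score += len(seg)
        if ok:
            best = max(best, score)
    return best


class TestExtractEvents:
    def test_interval_bounds_become_events(self):
        tracks = [IntervalTrack("T1", [(1.0, 3.0), (5.0, 8.0)])]
        events = extract_events(tracks, 120.0)
        kinds = [(e.event_type, e.time) for e in events]
        assert kinds == [
            (DISAPPEARANCE, 1.0), (REAPPEARANCE, 3.0),
            (DISAPPEARANCE, 5.0), (REAPPEARANCE, 8.0),
        ]

    def test_trial_end_closure_emits_no_reappearance(self):
        tracks = [IntervalTrack("T1", [(100.0, 120.0)])]
        events = extract_events(tracks, 120.0)
        assert [e.event_type for e in events] == [DISAPPEARANCE]

    def test_zero_noise_pipeline_identity(self, zero_noise_observer):
        """Without motor noise, extracted event times equal ground truth."""
        cond = SimCondition(n_targets=2, coupling=0.5, recruit_lag_sd=0.02)
        traj = simulate_target_states(cond, seed=31)
        log = apply_motor_model(traj, zero_noise_observer)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fixed, _ = validate_and_repair(log)
        events = extract_events(intervals_from_events(fixed), cond.trial_duration)
        got = sorted(e.time for e in events if e.event_type == DISAPPEARANCE)
        want = sorted(
            tr.time
            for trs in traj.transitions.values()
            for tr in trs
            if tr.new_state == "invisible"
        )
        assert got == want


class TestClusterEvents:
    def test_pair_within_window_is_simultaneous(self):
        events = [
            PerceptualEvent("T1", DISAPPEARANCE, 10.00),
            PerceptualEvent("T2", DISAPPEARANCE, 10.10),
        ]
        (cluster,) = cluster_events(events, window_set(0.05, 0.30))
        assert cluster.size == 2
        assert cluster.span == pytest.approx(0.10)
        assert cluster.simultaneous

    def test_pair_beyond_max_splits_into_singletons(self):
        events = [
            PerceptualEvent("T1", DISAPPEARANCE, 10.00),
            PerceptualEvent("T2", DISAPPEARANCE, 10.10),
        ]
        clusters = cluster_events(events, window_set(0.05, 0.08))
        assert [c.size for c in clusters] == [1, 1]
        assert not any(c.simultaneous for c in clusters)

    def test_strict_mode_rejects_sub_minimum_span(self):
        events = [
            PerceptualEvent("T1", DISAPPEARANCE, 10.00),
            PerceptualEvent("T2", DISAPPEARANCE, 10.01),
        ]
        strict = cluster_events(events, window_set(0.05, 0.30), mode="strict")
        relaxed = cluster_events(events, window_set(0.05, 0.30), mode="relaxed")
        assert not any(c.simultaneous for c in strict)
        assert any(c.simultaneous for c in relaxed)

    def test_sub_minimum_pair_does_not_shadow_valid_pair(self):
        """A tight same-time pair must not absorb an event that forms a
        within-window pair with a later event (strict mode)."""
        events = [
            PerceptualEvent("T1", DISAPPEARANCE, 0.00),
            PerceptualEvent("T2", DISAPPEARANCE, 0.02),
            PerceptualEvent("T1", DISAPPEARANCE, 0.10),
        ]
        clusters = cluster_events(events, window_set(0.05, 0.30), mode="strict")
        counts = count_events(clusters)
        assert counts.d_sim == 2

    def test_singletons_never_simultaneous(self):
        events = [PerceptualEvent("T1", DISAPPEARANCE, 1.0)]
        (cluster,) = cluster_events(events, window_set(0.0, 0.3))
        assert not cluster.simultaneous

    def test_event_types_cluster_independently(self):
        events = [
            PerceptualEvent("T1", DISAPPEARANCE, 10.00),
            PerceptualEvent("T2", REAPPEARANCE, 10.05),
            PerceptualEvent("T2", DISAPPEARANCE, 10.10),
            PerceptualEvent("T1", REAPPEARANCE, 10.15),
        ]
        clusters = cluster_events(events, window_set(0.0, 0.30))
        by_type = {}
        for c in clusters:
            by_type.setdefault(c.event_type, []).append(c)
        assert all(c.size == 2 for cs in by_type.values() for c in cs)

    def test_counts_invariant_to_input_permutation(self):
        rng = np.random.default_rng(32)
        events = [
            PerceptualEvent(f"T{rng.integers(1, 4)}", DISAPPEARANCE,
                            float(rng.uniform(0, 30)))
            for _ in range(10)
        ]
        ws = window_set(0.0, 0.25)
        base = count_events(cluster_events(sorted(
            events, key=lambda e: (e.time, e.key)), ws))
        for _ in range(5):
            perm = list(events)
            rng.shuffle(perm)
            perm.sort(key=lambda e: (e.time, e.key))
            assert count_events(cluster_events(perm, ws)) == base


class TestCountEvents:
    def test_pair_plus_singleton(self):
        events = [
            PerceptualEvent("T1", DISAPPEARANCE, 10.00),
            PerceptualEvent("T2", DISAPPEARANCE, 10.10),
            PerceptualEvent("T1", DISAPPEARANCE, 50.0),
        ]
        counts = count_events(cluster_events(events, window_set(0.05, 0.30)))
        assert (counts.d_total, counts.d_sim) == (3, 2)

    def test_no_events_all_zero(self):
        assert count_events([]) == (0, 0, 0, 0)

    def test_full_coupling_zero_noise_all_simultaneous(self, zero_noise_observer):
        cond = SimCondition(n_targets=2, coupling=1.0, recruit_lag_sd=0.0)
        traj = simulate_target_states(cond, seed=33)
        log = apply_motor_model(traj, zero_noise_observer)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fixed, _ = validate_and_repair(log)
        events = extract_events(intervals_from_events(fixed), cond.trial_duration)
        counts = count_events(cluster_events(events, window_set(0.0, 0.0)))
        assert counts.d_total > 0
        assert counts.d_sim == counts.d_total
        assert counts.r_sim == counts.r_total


class TestAgainstBruteForce:
    @pytest.mark.parametrize("mode", ["strict", "relaxed"])
    def test_optimal_on_small_synthetic_trials(self, mode):
        """Clustering matches exhaustive partition search on all fixtures
        with at most 12 events (3 targets, calibrated windows)."""
        checked = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            obs = ObserverProfile(f"o{seed}", seed=seed + 500)
            schedule, clogs = generate_control_session(3, obs, 4, rng)
            groups = []
            for log in clogs:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fixed, _ = validate_and_repair(log)
                g, _ = match_responses_to_schedule(schedule, fixed)
                groups += g
            windows = calibrate_fpa(groups)
            cond = SimCondition(
                n_targets=3, mean_invisible_duration=2.0,
                mean_visible_duration=6.0, coupling=0.4,
                recruit_lag_sd=0.03, trial_duration=12.0,
            )
            traj = simulate_target_states(cond, rng)
            log = apply_motor_model(traj, obs, rng=rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fixed, _ = validate_and_repair(log)
            events = extract_events(
                intervals_from_events(fixed), cond.trial_duration
            )
            if not 0 < len(events) <= 12:
                continue
            counts = count_events(cluster_events(events, windows, mode=mode))
            assert counts.d_sim == brute_force_max_sim(
                events, windows, DISAPPEARANCE, mode
            )
            assert counts.r_sim == brute_force_max_sim(
                events, windows, REAPPEARANCE, mode
            )
            checked += 1
        assert checked >= 20


class TestClassificationAccuracy:
    def test_recruited_pairs_detected_and_chance_rejected(self, noisy_observer):
        """With a window calibrated from >= 40 control groups and a recruit
        lag well inside the window, at least 90% of ground-truth recruited
        pairs are labelled simultaneous and at least 90% of far-apart
        coincidences are not."""
        schedule, clogs = generate_control_session(2, noisy_observer, 12, seed=34)
        groups = []
        for log in clogs:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fixed, _ = validate_and_repair(log)
            g, _ = match_responses_to_schedule(schedule, fixed)
            groups += g
        assert sum(g.event_type == DISAPPEARANCE for g in groups) >= 40
        windows = calibrate_fpa(groups)

        hits = n_recruited = far_sim = n_far = 0
        rng = np.random.default_rng(35)
        for _ in range(25):
            cond = SimCondition(
                n_targets=2, coupling=0.5, recruit_lag_sd=0.03,
                mean_visible_duration=4.0,
            )
            traj = simulate_target_states(cond, rng)
            log = apply_motor_model(traj, noisy_observer, rng=rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fixed, _ = validate_and_repair(log)
            events = extract_events(
                intervals_from_events(fixed), cond.trial_duration
            )
            clusters = cluster_events(events, windows)
            sim_times = {
                round(e.time, 6)
                for c in clusters
                if c.simultaneous
                for e in c.events
            }
            # ground-truth recruited groups -> expected response times
            by_group = {}
            for key, trs in traj.transitions.items():
                for tr in trs:
                    by_group.setdefault(tr.group_id, []).append((key, tr))
            max_w = windows.window_for(DISAPPEARANCE, 2).max_asynchrony
            event_times = sorted(e.time for e in events)
            for members in by_group.values():
                if len(members) < 2:
                    continue
                n_recruited += 1
                # detected if any classified-simultaneous event lies near
                # the group's responses
                t0 = min(tr.time for _, tr in members)
                if any(abs(t - t0 - 0.35) < 0.25 for t in sim_times):
                    hits += 1
            # far-apart coincidences: isolated events with no neighbour
            # within the window on the other key
            for c in clusters:
                if c.size == 1:
                    e = c.events[0]
                    others = [
                        t for t in event_times
                        if abs(t - e.time) > 1e-9
                    ]
                    if all(abs(t - e.time) > max_w for t in others):
                        n_far += 1
                        if e.time in sim_times:
                            far_sim += 1
        assert n_recruited >= 50
        assert hits / n_recruited >= 0.90
        assert n_far >= 50
        assert far_sim == 0
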