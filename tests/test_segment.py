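"""Footstep segmentation, seed sensor, footprint model, transitional frames."""

import numpy as np
import pytest

import floorgait as fg
from floorgait.segment import SegmentParams, _contacts_overlap


def make_sample(contacts, sample_id="s"):
    """Build a WalkSample from (x, y, press, release) tuples."""
    events = []
    for x, y, p, r in contacts:
        events.append(fg.SensorEvent(p, x, y, fg.PRESSED))
        events.append(fg.SensorEvent(r, x, y, fg.RELEASED))
    return fg.WalkSample(sample_id, events).sorted()


def closure_oracle(contacts, t_link):
    """Exhaustively close the join relation: repeated O(n^2) merge passes."""
    groups = [{i} for i in range(len(contacts))]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if not groups[i] or not groups[j]:
                    continue
                joined = any(
                    abs(contacts[a][0] - contacts[b][0]) <= 1
                    and abs(contacts[a][1] - contacts[b][1]) <= 1
                    and _contacts_overlap(contacts[a][2:], contacts[b][2:], t_link)
                    for a in groups[i]
                    for b in groups[j]
                )
                if joined:
                    groups[i] |= groups[j]
                    groups[j] = set()
                    changed = True
    return {frozenset((contacts[a][0], contacts[a][1]) for a in g) for g in groups if g}


class TestSegmentation:
    def test_noise_free_walk_recovers_planned_steps_in_order(self, geom):
        profile = fg.sample_profile(fg.PopulationConfig(), "u", rng_seed=1)
        sample, plans = fg.simulate_walk(
            geom, profile, "w", rng_seed=2, n_steps=5, noise=fg.NoiseConfig.none()
        )
        steps = fg.segment_footsteps(sample, geom)
        assert len(steps) == len(plans) == 5
        for step, plan in zip(steps, plans):
            assert step.fStart == pytest.approx(plan.heel_strike, abs=1e-9)
            assert step.fEnd == pytest.approx(plan.toe_off, abs=1e-9)

    def test_isolated_contacts_form_single_footstep(self, geom):
        sample = make_sample([(3, 10, 0.1, 0.5), (4, 10, 0.12, 0.5), (3, 11, 0.1, 0.4)])
        steps = fg.segment_footsteps(sample, geom, SegmentParams(min_sensors=1))
        assert len(steps) == 1
        assert steps[0].fStart == pytest.approx(0.1)

    def test_singleton_contact(self, geom):
        sample = make_sample([(3, 10, 0.1, 0.5)])
        steps = fg.segment_footsteps(sample, geom, SegmentParams(min_sensors=1))
        assert len(steps) == 1 and steps[0].n_sensors == 1

    def test_small_components_discarded_as_noise(self, geom):
        contacts = [(3, 10, 0.1, 0.5), (4, 10, 0.1, 0.5), (3, 11, 0.1, 0.5)]
        contacts += [(12, 80, 0.2, 0.3)]  # lone noise blip far away
        steps = fg.segment_footsteps(make_sample(contacts), geom, SegmentParams())
        assert len(steps) == 1 and steps[0].n_sensors == 3

    def test_temporal_gap_splits_spatially_adjacent_contacts(self, geom):
        contacts = [(3, 10, 0.1, 0.2), (3, 11, 0.5, 0.6)]  # gap 0.3 > t_link
        steps = fg.segment_footsteps(
            make_sample(contacts), geom, SegmentParams(min_sensors=1)
        )
        assert len(steps) == 2

    def test_double_support_separated_by_space_not_time(self, geom):
        left = [(2, y, 0.0, 0.6) for y in (10, 11, 12)]
        right = [(9, y, 0.4, 1.0) for y in (25, 26, 27)]  # overlaps in time
        steps = fg.segment_footsteps(make_sample(left + right), geom, SegmentParams())
        assert len(steps) == 2
        assert steps[0].fStart < steps[1].fStart

    def test_matches_transitive_closure_oracle_on_random_contacts(self, geom):
        rng = np.random.default_rng(0)
        params = SegmentParams(min_sensors=1)
        for trial in range(20):
            n = int(rng.integers(5, 50))
            cells = set()
            while len(cells) < n:
                cells.add((int(rng.integers(0, 16)), int(rng.integers(0, 30))))
            contacts = []
            for x, y in sorted(cells):
                p = float(rng.uniform(0, 1.5))
                contacts.append((x, y, p, p + float(rng.uniform(0.02, 0.6))))
            got = {
                frozenset(f.contacts) for f in
                fg.segment_footsteps(make_sample(contacts), geom, params)
            }
            assert got == closure_oracle(contacts, params.t_link)

    def test_invariant_to_event_permutations_preserving_sensor_order(self, geom):
        profile = fg.sample_profile(fg.PopulationConfig(), "u", rng_seed=1)
        sample, _ = fg.simulate_walk(geom, profile, "w", rng_seed=2, n_steps=5)
        ref = [set(f.contacts) for f in fg.segment_footsteps(sample, geom)]
        # Stable shuffle: reorder by sensor then time, keeping per-sensor order.
        shuffled = fg.WalkSample(
            sample.sample_id,
            sorted(sample.events, key=lambda e: (e.x_idx, e.y_idx, e.time)),
        )
        got = [set(f.contacts) for f in fg.segment_footsteps(shuffled, geom)]
        assert got == ref

    def test_empty_sample_gives_empty_result(self, geom):
        assert fg.segment_footsteps(fg.WalkSample("empty"), geom) == []


class TestSeed:
    def test_backmost_row_wins(self):
        f = fg.Footstep(1, {(5, 12): (0, 1), (4, 10): (0, 1), (3, 11): (0, 1)})
        assert fg.find_seed(f) == (4, 10)

    def test_tie_broken_by_minimal_x(self):
        f = fg.Footstep(1, {(5, 10): (0, 1), (3, 10): (0, 1)})
        assert fg.find_seed(f) == (3, 10)

    def test_noise_free_seed_lies_in_heel_lobe(self, geom):
        from dataclasses import replace

        profile = fg.sample_profile(fg.PopulationConfig(), "u", rng_seed=1)
        profile = replace(profile, foot_angle_mean=0.0, foot_angle_sd=0.0)
        sample, plans = fg.simulate_walk(
            geom, profile, "w", rng_seed=2, n_steps=5, noise=fg.NoiseConfig.none()
        )
        for step, plan in zip(fg.segment_footsteps(sample, geom), plans):
            sx, sy = fg.find_seed(step)
            _, heel_y = fg.sensor_to_physical(geom, sx, sy)
            assert abs(heel_y - plan.anchor[1]) <= profile.foot_width


class TestFootprintModel:
    def test_seed_only_footstep_activates_one_heel_cell(self, geom):
        f = fg.Footstep(1, {(6, 20): (0.0, 0.3)})
        model = fg.fit_footprint_model(f, geom)
        assert model.n_active == 1
        assert model.grid[0].any()  # active cell in the heel row
        assert model.seed == (6, 20)

    def test_typical_foot_fits_without_clipping(self, geom, cohort_footsteps):
        clipped = [
            fg.fit_footprint_model(step, geom).n_clipped
            for steps in cohort_footsteps[:50]
            for step in steps[:5]
        ]
        assert max(clipped) == 0

    def test_active_cells_equal_contact_count_when_unclipped(self, geom):
        f = fg.Footstep(1, {(6, 20): (0, 1), (7, 21): (0, 1), (6, 22): (0, 1)})
        model = fg.fit_footprint_model(f, geom)
        assert model.n_clipped == 0
        assert model.n_active == f.n_sensors

    def test_window_clamped_inside_floor(self, geom):
        f = fg.Footstep(1, {(0, 0): (0, 1), (1, 0): (0, 1)})
        model = fg.fit_footprint_model(f, geom)
        assert model.x_start >= 0 and model.y_start >= 0


class TestFrames:
    @pytest.mark.parametrize(
        "t_max, dt, expected",
        [(0.8, 0.04, 20), (0.8, 0.05, 16), (0.8, 0.06, 13), (0.8, 0.08, 10),
         (0.8, 0.10, 8), (0.8, 0.8, 1)],
    )
    def test_frame_counts(self, t_max, dt, expected):
        assert fg.frame_count(t_max, dt) == expected

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            fg.frame_count(0.8, 0.0)
        with pytest.raises(ValueError):
            fg.frame_count(0.8, -0.1)

    def test_first_frame_is_the_heel_strike_state(self, geom):
        f = fg.Footstep(1, {(6, 20): (0.1, 0.4), (6, 21): (0.1, 0.3), (6, 24): (0.3, 0.4)})
        model = fg.fit_footprint_model(f, geom)
        frames = fg.transitional_frames(f, model, dt=0.04)
        active0 = {
            model.cell_sensor(i, j) for i, j in zip(*np.nonzero(frames.frames[0]))
        }
        assert active0 == {(6, 20), (6, 21)}

    def test_frames_after_toe_off_are_inactive_and_padded(self, geom):
        f = fg.Footstep(1, {(6, 20): (0.0, 0.2)})
        model = fg.fit_footprint_model(f, geom)
        frames = fg.transitional_frames(f, model, dt=0.04)
        assert len(frames.frames) == frames.n_nominal == 20
        for k in range(5, 20):  # 0.2 / 0.04 = 5
            assert not frames.frames[k].any()

    def test_frames_match_full_event_replay(self, geom, cohort):
        """Frame k must equal sensor_state_at(sample, ., fStart + k dt)."""
        sample = cohort.samples[0]
        steps = fg.segment_footsteps(sample, geom)
        for step in steps[:2]:
            model = fg.fit_footprint_model(step, geom)
            frames = fg.transitional_frames(step, model, dt=0.10)
            for k, grid in enumerate(frames.frames):
                t = step.fStart + k * frames.dt
                for i in range(8):
                    for j in range(4):
                        x, y = model.cell_sensor(i, j)
                        expected = fg.sensor_state_at(sample, x, y, t) == fg.PRESSED
                        assert grid[i, j] == expected

    def test_frame_union_is_the_left_footprint(self, geom):
        f = fg.Footstep(1, {(6, 20): (0.0, 0.4), (7, 21): (0.1, 0.5), (5, 22): (0.2, 0.6)})
        model = fg.fit_footprint_model(f, geom)
        frames = fg.transitional_frames(f, model, dt=0.04)  # dt < min duration
        union = np.logical_or.reduce(frames.frames)
        assert (union == model.grid).all()
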