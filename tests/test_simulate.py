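import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from zfsocial import (
    AgentParams,
    ArenaGeometry,
    KnotPathParams,
    StimulusProgram,
    build_schedule,
    generate_length_cohort,
    simulate_agent,
    simulate_dyad,
    simulate_knot_stimulus,
    simulate_loom_session,
)
from zfsocial.dyad import place_preference, phase_table


class TestKnotStimulus:
    def test_smooth_path_closes_over_one_period(self, dish):
        params = KnotPathParams(step_mode="smooth", period=100.0)
        prog = StimulusProgram.single(4.0, 100.0)
        stim = simulate_knot_stimulus(params, prog, fps=10.0, seed=0, arena=dish)
        x0, y0 = params.point(np.array([0.0]))
        xT, yT = params.point(np.array([100.0]))
        assert abs(xT[0] - x0[0]) < 1e-9 and abs(yT[0] - y0[0]) < 1e-9

    def test_single_epoch_structure(self, knot_stimulus):
        diam = knot_stimulus["stim_diam"].to_numpy()
        assert set(np.unique(diam)) <= {0.0, 4.0}
        assert set(knot_stimulus["epoch_id"].unique()) <= {-1, 0}
        on = diam > 0
        assert np.isfinite(knot_stimulus.loc[on, ["stim_x", "stim_y"]].to_numpy()).all()

    def test_boutlike_step_count_in_poisson_interval(self, dish):
        params = KnotPathParams(step_mode="boutlike", bout_rate=1.0)
        prog = StimulusProgram.single(4.0, 300.0)
        stim = simulate_knot_stimulus(params, prog, fps=30.0, seed=4, arena=dish)
        xy = stim[["stim_x", "stim_y"]].to_numpy()
        moved = np.any(np.diff(xy, axis=0) != 0, axis=1)
        n_steps = int(np.nansum(moved))
        lo, hi = sps.poisson.interval(0.99, 300)
        assert lo <= n_steps <= hi

    def test_path_outside_arena_rejected(self):
        small = ArenaGeometry.circle(5.0)
        with pytest.raises(ValueError, match="arena"):
            simulate_knot_stimulus(KnotPathParams(), StimulusProgram.single(4.0, 60.0),
                                   fps=10.0, seed=0, arena=small)

    def test_equal_freqs_rejected(self):
        with pytest.raises(ValueError):
            KnotPathParams(freq_p=2, freq_q=2)


class TestAgent:
    def test_same_seed_bit_identical(self, dish, knot_stimulus):
        a = simulate_agent(AgentParams(attraction_gain=3.0), knot_stimulus, dish, fps=30.0, seed=9)
        b = simulate_agent(AgentParams(attraction_gain=3.0), knot_stimulus, dish, fps=30.0, seed=9)
        pd.testing.assert_frame_equal(a.frames, b.frames)

    def test_agent_never_leaves_arena(self, dish, null_session):
        xy = null_session.xy
        assert dish.contains(xy[:, 0], xy[:, 1]).all()

    def test_per_frame_speed_bounded(self, dish, null_session):
        ag = AgentParams()
        glide_frames = max(1, round(ag.glide_s * null_session.fps))
        step = np.hypot(*np.diff(null_session.xy, axis=0).T)
        assert step.max() <= ag.bout_disp_max / glide_frames + 1e-9

    def test_zero_gain_independent_of_stimulus_onset(self, dish):
        # distance to the dot during stimulus-on frames should not differ
        # systematically from the distance to the same (hidden) path when off
        prog = StimulusProgram(epochs=((4.0, 0.0, 150.0),), tail_s=150.0)
        stim = simulate_knot_stimulus(KnotPathParams(), prog, fps=30.0, seed=1, arena=dish)
        diffs = []
        for s in range(25):
            t = simulate_agent(AgentParams(attraction_gain=0.0), stim, dish, fps=30.0, seed=s)
            xy = t.xy
            r = np.hypot(xy[:, 0], xy[:, 1])
            on = t.frames["stim_diam"].to_numpy() > 0
            diffs.append(r[on].mean() - r[~on].mean())
        assert abs(np.mean(diffs)) < 3 * np.std(diffs) / np.sqrt(len(diffs)) + 0.05

    def test_high_gain_brings_agent_closer_than_null(self, dish, knot_stimulus):
        sxy = knot_stimulus[["stim_x", "stim_y"]].to_numpy()
        on = knot_stimulus["stim_diam"].to_numpy() > 0
        med = {}
        for k in (0.0, 50.0):
            t = simulate_agent(AgentParams(attraction_gain=k), knot_stimulus, dish,
                               fps=30.0, seed=21)
            xy = t.xy
            med[k] = np.median(np.hypot(xy[on, 0] - sxy[on, 0], xy[on, 1] - sxy[on, 1]))
        assert med[50.0] < med[0.0]

    def test_mean_bout_displacement_matches_parameter(self, dish):
        # ~1e4 bouts of free swimming; realized per-bout displacement obeys the LLN
        ag = AgentParams(bout_rate=1.0)
        t = simulate_agent(ag, None, dish, fps=30.0, seed=13, duration=10_000.0)
        step = np.hypot(*np.diff(t.xy, axis=0).T)
        moving = step > 1e-12
        # every bout glides exactly glide_frames frames (the refractory floor),
        # so back-to-back bouts are separated by chunking moving runs
        g = max(1, round(ag.glide_s * t.fps))
        bouts = np.flatnonzero(np.diff(moving.astype(int)) == 1)
        starts = np.concatenate([[0], bouts + 1]) if moving[0] else bouts + 1
        disps = []
        for s in starts:
            e = s
            while e < len(moving) and moving[e]:
                e += 1
            for c in range(s, e, g):
                disps.append(step[c : min(c + g, e)].sum())
        disps = np.asarray(disps)
        # wall reflections shorten a small fraction of bouts; allow 3 SE + 5%
        se = disps.std() / np.sqrt(len(disps))
        assert len(disps) > 8000
        assert abs(disps.mean() - ag.bout_disp_mean) < 3 * se + 0.05 * ag.bout_disp_mean


class TestDyad:
    def test_frame_counts_per_phase(self, tank):
        ta, tb = simulate_dyad(AgentParams(), AgentParams(), tank,
                               phase_duration=300.0, fps=10.0, seed=0)
        for t in (ta, tb):
            assert len(t) == 6000
            assert (t.frames["epoch_id"] == 0).sum() == 3000
            assert (t.frames["epoch_id"] == 1).sum() == 3000

    def test_asocial_pair_centered_both_phases(self, tank):
        pp = {"presocial": [], "social": []}
        for s in range(20):
            ta, _ = simulate_dyad(AgentParams(), AgentParams(), tank,
                                  phase_duration=120.0, fps=10.0, seed=s)
            for phase in pp:
                pp[phase].append(place_preference(phase_table(ta, phase)))
        for phase, vals in pp.items():
            assert abs(np.mean(vals) - 0.5) < 0.06, phase

    def test_one_sided_gain_raises_social_place_pref(self, tank):
        deltas = []
        for s in range(15):
            ta, _ = simulate_dyad(AgentParams(attraction_gain=10.0), AgentParams(), tank,
                                  phase_duration=200.0, fps=10.0, seed=s)
            deltas.append(place_preference(phase_table(ta, "social"))
                          - place_preference(phase_table(ta, "presocial")))
        assert np.mean(deltas) > 0.1

    def test_agents_stay_in_their_tanks(self, tank):
        ta, tb = simulate_dyad(AgentParams(attraction_gain=10.0),
                               AgentParams(attraction_gain=10.0), tank,
                               phase_duration=60.0, fps=10.0, seed=2)
        for t in (ta, tb):
            xy = t.xy
            assert tank.contains(xy[:, 0], xy[:, 1]).all()

    def test_same_seed_reproducible(self, tank):
        a1, b1 = simulate_dyad(AgentParams(), AgentParams(), tank, phase_duration=60.0,
                               fps=10.0, seed=3)
        a2, b2 = simulate_dyad(AgentParams(), AgentParams(), tank, phase_duration=60.0,
                               fps=10.0, seed=3)
        pd.testing.assert_frame_equal(a1.frames, a2.frames)
        pd.testing.assert_frame_equal(b1.frames, b2.frames)


class TestLoomSession:
    def test_zero_size_loom_rarely_escapes(self, dish):
        sched = build_schedule([0.0] * 15, reps=2, seed=1)
        _, truth = simulate_loom_session(AgentParams(), sched, dish, fps=30.0, seed=1)
        frac = np.mean([e.escaped for e in truth.events])
        # logistic(-p50 * slope) = logistic(-6) ~ 0.0025
        assert frac <= 0.1

    def test_planted_escape_fraction_binomial(self, dish):
        # final size at p50 -> planted escape probability exactly 0.5
        ag = AgentParams(escape_p50=6.0, escape_slope=1.0)
        sched = build_schedule([6.0] * 15, reps=2, seed=5)
        _, truth = simulate_loom_session(ag, sched, dish, fps=30.0, seed=5)
        k = sum(e.escaped for e in truth.events)
        lo, hi = sps.binom.interval(0.99, len(truth.events), 0.5)
        assert lo <= k <= hi

    def test_left_loom_escape_moves_right(self, dish):
        ag = AgentParams(escape_p50=0.0, escape_slope=10.0)  # always escape
        sched = build_schedule([12.0] * 10, reps=1, seed=7)
        table, truth = simulate_loom_session(ag, sched, dish, fps=30.0, seed=7)
        t = table.t
        xy = table.xy
        for ev in truth.events:
            assert ev.escaped
            sel = (t >= ev.t_onset) & (t <= ev.t_onset + 1.0)
            dx = xy[sel][-1, 0] - xy[sel][0, 0]
            if ev.side == "left":
                assert dx > 0
            else:
                assert dx < 0

    def test_session_determinism(self, dish):
        sched = build_schedule([0.0, 6.0, 12.0], reps=1, seed=2)
        t1, s1 = simulate_loom_session(AgentParams(), sched, dish, fps=30.0, seed=2)
        t2, s2 = simulate_loom_session(AgentParams(), sched, dish, fps=30.0, seed=2)
        pd.testing.assert_frame_equal(t1.frames, t2.frames)
        assert [e.escaped for e in s1.events] == [e.escaped for e in s2.events]


class TestLengthCohort:
    def test_no_stunting_gives_clean_normals(self):
        df = generate_length_cohort(500, 0, 0, stunt_rates={"wt": 0.0}, seed=3)
        assert not df["stunted_true"].any()
        assert abs(df["length_mm"].mean() - 9.0) < 3 * 0.7 / np.sqrt(500)

    def test_planted_rates_recovered(self):
        df = generate_length_cohort(0, 0, 2000, stunt_rates={"mut": 0.78}, seed=4)
        frac = df["stunted_true"].mean()
        lo, hi = sps.binom.interval(0.999, 2000, 0.78)
        assert lo / 2000 <= frac <= hi / 2000

    def test_empty_stratum_ok(self):
        df = generate_length_cohort(5, 0, 5, seed=0)
        assert set(df["genotype"]) == {"wt", "mut"}
        assert len(df) == 10

    def test_bad_rate_rejected(self):
        with pytest.raises(ValueError):
            generate_length_cohort(1, 1, 1, stunt_rates={"wt": 1.5}, seed=0)
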