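"""Doubling time, time courses, conversion events and grid sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emtconv import morphology
from emtconv.config import RunConfig
from emtconv.kinetics import (
    HIGH_MITOSIS,
    LOW_MITOSIS,
    class_time_course,
    detect_conversions,
    doubling_time,
    estimate_division_prob,
    estimate_motion_sd,
    grid_sample,
    growth_table,
    mitosis_contribution_summary,
)
from emtconv.morphology import NEURON_LIKE, MEF_LIKE, CellObservation
from emtconv.pipeline import analyze_movie
from emtconv.synthetic.movie import ConversionRule, MovieConfig, generate_movie
from emtconv.tracking import LineageForest, TrackNode


class TestDoublingTime:
    @pytest.mark.parametrize(
        "n0,n24,expected",
        [(100, 200, 24.0), (100, 400, 12.0), (100, 50, None)],
    )
    def test_analytic_cases(self, n0, n24, expected):
        td = doubling_time(n0, n24)
        if expected is None:
            assert td is None
        else:
            assert td == pytest.approx(expected)

    def test_no_growth_undefined(self):
        assert doubling_time(100, 100) is None
        assert doubling_time(100, 80) is None

    def test_zero_start_fails(self):
        with pytest.raises(ValueError):
            doubling_time(0, 10)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        n0=st.integers(10, 1000),
        a=st.integers(1, 500),
        b=st.integers(1, 500),
    )
    def test_monotonicity_in_final_count(self, n0, a, b):
        lo, hi = n0 + min(a, b), n0 + max(a, b)
        if lo == hi:
            return
        assert doubling_time(n0, hi) < doubling_time(n0, lo)

    def test_growth_table_on_exponential_counts(self):
        counts = [100 * 2 ** (t / 24) for t in range(49)]
        g = growth_table(counts)
        assert np.allclose(g.Td, 24.0)


def _node(nid, parent, first, last, cls, children=()):
    n = TrackNode(
        node_id=nid, parent=parent, first_frame=first, last_frame=last,
        labels=[(f, nid) for f in range(first, last + 1)],
        classes=[cls] * (last - first + 1),
        children=list(children),
    )
    return n


def hand_forest():
    """1 high-mitosis founder whose subtree reaches 8 final neuron-like
    cells, plus 6 low-mitosis founders contributing 1 each (final frame
    9; 14 final neuron-like cells in total)."""
    nodes = {}
    nodes[1] = _node(1, None, 0, 2, MEF_LIKE, children=[2, 3])
    nodes[2] = _node(2, 1, 3, 4, NEURON_LIKE, children=[4, 5])       # converts at 3
    nodes[3] = _node(3, 1, 3, 9, MEF_LIKE)
    nodes[4] = _node(4, 2, 5, 6, NEURON_LIKE, children=[6, 7])
    nodes[5] = _node(5, 2, 5, 6, NEURON_LIKE, children=[8, 9])
    kid = 10
    for p in (6, 7, 8, 9):
        nodes[p] = _node(p, p // 2 + 2 if p < 8 else p // 2 + 1, 7, 8,
                         NEURON_LIKE, children=[kid, kid + 1])
        kid += 2
    # fix parents for the generation at frames 7-8
    nodes[6].parent, nodes[7].parent = 4, 4
    nodes[8].parent, nodes[9].parent = 5, 5
    for p, ch in ((4, (6, 7)), (5, (8, 9))):
        nodes[p].children = list(ch)
    leaves = []
    for p in (6, 7, 8, 9):
        for c in nodes[p].children:
            nodes[c] = _node(c, p, 9, 9, NEURON_LIKE)
            leaves.append(c)
    # six direct converters (no divisions): MEF until frame 5, neuron after
    for i in range(6):
        nid = 100 + i
        n = TrackNode(
            node_id=nid, parent=None, first_frame=0, last_frame=9,
            labels=[(f, nid) for f in range(10)],
            classes=[MEF_LIKE] * 6 + [NEURON_LIKE] * 4,
        )
        nodes[nid] = n
    return LineageForest(nodes)


class TestConversions:
    def test_single_forced_event_after_division(self):
        forest = hand_forest()
        events = detect_conversions(forest, n_frames=10)
        by_mode = {}
        for e in events:
            by_mode.setdefault(e.mode, []).append(e)
        assert len(by_mode[HIGH_MITOSIS]) == 1
        ev = by_mode[HIGH_MITOSIS][0]
        assert ev.node_id == 2 and ev.frame == 3
        assert ev.divisions_before == 1
        assert ev.descendants_final == 8

    def test_zero_division_conversion_is_low_mitosis(self):
        forest = hand_forest()
        events = detect_conversions(forest, n_frames=10)
        low = [e for e in events if e.mode == LOW_MITOSIS]
        assert len(low) == 6
        assert all(e.divisions_before == 0 and e.frame == 6 for e in low)

    def test_contribution_census_six_versus_eight(self):
        forest = hand_forest()
        events = detect_conversions(forest, n_frames=10)
        summary = mitosis_contribution_summary(events, forest, n_frames=10)
        s = summary.set_index("mode")
        assert s.loc[LOW_MITOSIS, "n_founders"] == 6
        assert s.loc[LOW_MITOSIS, "contribution_pct"] == pytest.approx(100 * 6 / 14)
        assert s.loc[HIGH_MITOSIS, "contribution_pct"] == pytest.approx(100 * 8 / 14)
        assert s.contribution_pct.sum() == pytest.approx(100.0)

    def test_all_low_mitosis_contributes_everything(self):
        nodes = {}
        for i in range(4):
            nodes[i + 1] = TrackNode(
                node_id=i + 1, parent=None, first_frame=0, last_frame=9,
                labels=[(f, i + 1) for f in range(10)],
                classes=[MEF_LIKE] * 5 + [NEURON_LIKE] * 5,
            )
        forest = LineageForest(nodes)
        events = detect_conversions(forest, n_frames=10)
        summary = mitosis_contribution_summary(events, forest, n_frames=10)
        s = summary.set_index("mode")
        assert s.loc[LOW_MITOSIS, "contribution_pct"] == 100.0

    def test_persistence_below_one_rejected(self):
        with pytest.raises(ValueError):
            detect_conversions(hand_forest(), n_frames=10, persistence=0)

    def test_events_match_generator_truth_one_to_one(self):
        zero = {k: 0.0 for k in (morphology.MEF_LIKE, morphology.NEURON_LIKE,
                                 morphology.SHRUNKEN)}
        cfg = MovieConfig(
            seed=13, n_frames=14, n_initial_cells=12, field_size=(1100, 1100),
            division_prob=dict(zero), apoptosis_prob=dict(zero),
            conversion_schedule=[
                ConversionRule(0.5, "with-mitosis", (5, 8)),
                ConversionRule(0.25, "without-mitosis", (6, 9)),
            ],
        )
        labels, nuclei, truth = generate_movie(cfg)
        res = analyze_movie(labels, nuclei, RunConfig(seed=13), truth,
                            motion_step_sd=max(cfg.motion_step_sd.values()))
        detected = {
            (res.forest.label_at(e.node_id, e.frame), e.frame, e.mode)
            for e in res.conversions
        }
        expected = {
            (int(r.cell_id), int(r.frame),
             HIGH_MITOSIS if r["mode"] == "with-mitosis" else LOW_MITOSIS)
            for _, r in truth.conversions.iterrows()
            if r.target == NEURON_LIKE
        }
        assert detected == expected


class TestTimeCourse:
    def test_single_class_is_always_100(self):
        nodes = {
            1: TrackNode(1, None, 0, 47, [(f, 1) for f in range(48)],
                         [MEF_LIKE] * 48)
        }
        tc = class_time_course(LineageForest(nodes), n_frames=48)
        mef = tc[tc.cls == MEF_LIKE]
        assert (mef.percent == 100.0).all()
        assert len(mef) == 2      # two days

    def test_percentages_sum_to_100_each_day(self, demo_analysis):
        tc = demo_analysis.time_course
        for day, grp in tc.groupby("day"):
            assert grp.percent.sum() == pytest.approx(100.0, abs=1e-9)

    def test_final_mix_recovers_generator_truth_exactly(self):
        cfg = MovieConfig(
            seed=21, n_frames=6, n_initial_cells=16, field_size=(1000, 1000),
            archetype_mix={morphology.MEF_LIKE: 0.25,
                           morphology.NEURON_LIKE: 0.5,
                           morphology.SHRUNKEN: 0.25},
            division_prob={k: 0.0 for k in (morphology.MEF_LIKE,
                                            morphology.NEURON_LIKE,
                                            morphology.SHRUNKEN)},
            apoptosis_prob={k: 0.0 for k in (morphology.MEF_LIKE,
                                             morphology.NEURON_LIKE,
                                             morphology.SHRUNKEN)},
            conversion_schedule=[],
            enforce_shape_contract=True,
        )
        labels, nuclei, truth = generate_movie(cfg)
        res = analyze_movie(labels, nuclei, RunConfig(seed=21), truth,
                            motion_step_sd=max(cfg.motion_step_sd.values()))
        tc = res.time_course
        last_day = tc[tc.day == tc.day.max()].set_index("cls")
        final_truth = truth.cells[truth.cells.frame == cfg.n_frames - 1]
        for cls, n_true in final_truth.archetype.value_counts().items():
            assert last_day.loc[cls, "count"] == n_true

    def test_empty_movie_day_is_flagged(self):
        forest = LineageForest({
            1: TrackNode(1, None, 0, 0, [(0, 1)], [MEF_LIKE],
                         end_reason="death")
        })
        tc = class_time_course(forest, n_frames=30)
        day1 = tc[tc.day == 1]
        assert day1.empty is False
        assert day1["empty"].all()


def pooled_division_prob(replicates, cls):
    num = den = 0.0
    for cfg, truth, res in replicates:
        p, n = estimate_division_prob(res.links, res.observations)[cls]
        num += p * n
        den += n
    return num / den, den


def pooled_motion_sd(replicates, cls):
    num = den = 0.0
    for cfg, truth, res in replicates:
        sd, n = estimate_motion_sd(res.links, res.observations)[cls]
        num += sd**2 * n
        den += n
    return math.sqrt(num / den), den


class TestParameterRecovery:
    def test_division_prob_recovered_within_15pct(self, recovery_replicates):
        cfg = recovery_replicates[0][0]
        for cls in (morphology.MEF_LIKE, morphology.NEURON_LIKE):
            p_hat, n = pooled_division_prob(recovery_replicates, cls)
            assert n >= 200
            assert p_hat == pytest.approx(cfg.division_prob[cls], rel=0.15)

    def test_motion_sd_recovered_within_15pct(self, recovery_replicates):
        cfg = recovery_replicates[0][0]
        for cls in (morphology.MEF_LIKE, morphology.NEURON_LIKE,
                    morphology.SHRUNKEN):
            sd_hat, n = pooled_motion_sd(recovery_replicates, cls)
            assert n >= 200
            assert sd_hat == pytest.approx(cfg.motion_step_sd[cls], rel=0.15)

    def test_doubling_time_consistent_with_division_prob(self, recovery_replicates):
        """Td from class counts 24 h apart vs Td = 1/log2(1+p) implied
        by the per-frame division probability (counts pooled over the
        seeded replicates)."""
        cfg = recovery_replicates[0][0]
        n0 = n24 = 0
        for _, truth, _ in recovery_replicates:
            mef = truth.cells[truth.cells.archetype == morphology.MEF_LIKE]
            n0 += (mef.frame == 0).sum()
            n24 += (mef.frame == 24).sum()
        td = doubling_time(n0, n24)
        expected = 1.0 / math.log2(1.0 + cfg.division_prob[morphology.MEF_LIKE])
        assert td == pytest.approx(expected, rel=0.15)


def _o(label, r, c):
    return CellObservation(frame=0, label=label, centroid=(r, c), area=50.0,
                           perimeter=30.0, length=8.0, width=6.0, neurite_count=0)


class TestGridSample:
    def test_cell_at_every_field_center_selects_all(self):
        obs = []
        lab = 1
        for i in range(5):
            for j in range(5):
                obs.append(_o(lab, (i + 0.5) * 20, (j + 0.5) * 20))
                lab += 1
        assert grid_sample(obs, (100, 100), k=5) == list(range(1, 26))

    def test_single_cell_always_selected(self):
        for k in (1, 3, 5, 8):
            assert grid_sample([_o(7, 33, 66)], (100, 100), k=k) == [7]

    def test_matches_exhaustive_per_field_search(self):
        rng = np.random.default_rng(2)
        obs = [_o(i + 1, *rng.uniform(0, 500, 2)) for i in range(80)]
        got = grid_sample(obs, (500, 500), k=5)
        # brute-force oracle
        expect = set()
        for gi in range(5):
            for gj in range(5):
                r0, r1 = gi * 100, (gi + 1) * 100
                c0, c1 = gj * 100, (gj + 1) * 100
                inside = [o for o in obs
                          if r0 <= o.centroid[0] < r1 and c0 <= o.centroid[1] < c1]
                if inside:
                    ctr = ((r0 + r1) / 2, (c0 + c1) / 2)
                    best = min(inside, key=lambda o: (math.hypot(
                        o.centroid[0] - ctr[0], o.centroid[1] - ctr[1]), o.label))
                    expect.add(best.label)
        assert got == sorted(expect)
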