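"""Phase decomposition, per-procedure features and group tables."""

import math

import numpy as np
import pandas as pd
import pytest

import gesturelab as gl
from gesturelab.events import EventLogError, Gesture, Group, Module
from gesturelab.phases import TABLE_METRICS, merge_active_intervals


def ev(start, stop, gesture=Gesture.REGULAR_DISSECTION):
    return gl.GestureEvent(gesture, float(start), float(stop))


def make_log(events, pid="P01", group=Group.NOVICE, module=Module.BLADDER_NECK, rep=1):
    return gl.ProcedureLog(pid, group, module, rep, tuple(events))


def grid_union_length(intervals, resolution=0.001):
    """Brute-force occupancy scan oracle: total covered time on a fine grid."""
    lo = min(a for a, _ in intervals)
    hi = max(b for _, b in intervals)
    n = int(round((hi - lo) / resolution))
    grid = np.zeros(n, dtype=bool)
    for a, b in intervals:
        i = int(round((a - lo) / resolution))
        j = int(round((b - lo) / resolution))
        grid[i:j] = True
    return grid.sum() * resolution


class TestMergeActiveIntervals:
    @pytest.mark.parametrize(
        "spans, expected",
        [
            ([(0, 10), (10, 20)], [(0, 20)]),  # touching merge
            ([(0, 10), (5, 15), (20, 30)], [(0, 15), (20, 30)]),
            ([(3, 7)], [(3, 7)]),
            ([(0, 5), (1, 2), (1.5, 6)], [(0, 6)]),
        ],
    )
    def test_examples(self, spans, expected):
        got = merge_active_intervals([ev(a, b) for a, b in spans])
        assert got == [(float(a), float(b)) for a, b in expected]

    def test_empty_rejected(self):
        with pytest.raises(EventLogError):
            merge_active_intervals([])

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(1, 15)
            starts = rng.uniform(0, 100, n)
            events = [ev(s, s + d) for s, d in zip(starts, rng.uniform(0.1, 20, n))]
            merged = merge_active_intervals(events)
            shuffled = list(events)
            rng.shuffle(shuffled)
            assert merge_active_intervals(shuffled) == merged
            remerged = merge_active_intervals([ev(a, b) for a, b in merged])
            assert remerged == merged

    def test_union_length_matches_grid_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = rng.integers(1, 12)
            spans = [
                (round(s, 2), round(s + d, 2))
                for s, d in zip(rng.uniform(0, 50, n), rng.uniform(0.05, 10, n))
            ]
            merged = merge_active_intervals([ev(a, b) for a, b in spans])
            union = sum(b - a for a, b in merged)
            assert union == pytest.approx(grid_union_length(spans), abs=0.01)


class TestExtractFeatures:
    def test_single_event(self):
        f = gl.extract_features(make_log([ev(0, 10)]))
        assert f.total_duration_s == 10
        assert f.idle_pct == 0
        assert f.n_active_phases == 1
        assert f.n_idle_phases == 0
        assert f.active_phase_mean_s == 10
        assert f.idle_phase_mean_s is None

    def test_overlap_and_gap_example(self):
        log = make_log(
            [
                ev(0, 10, Gesture.REGULAR_DISSECTION),
                ev(5, 15, Gesture.HEMOSTATIC_CONTROL),
                ev(20, 30, Gesture.REGULAR_DISSECTION),
            ]
        )
        f = gl.extract_features(log)
        assert f.total_duration_s == 30
        assert f.n_active_phases == 2
        assert f.active_phase_mean_s == pytest.approx(12.5)
        assert f.n_idle_phases == 1
        assert f.idle_phase_mean_s == pytest.approx(5.0)
        assert f.idle_pct == pytest.approx(100 * 5 / 30)
        assert f.gesture_total_s[Gesture.REGULAR_DISSECTION] == pytest.approx(20.0)
        assert f.gesture_total_s[Gesture.HEMOSTATIC_CONTROL] == pytest.approx(10.0)

    def test_touching_events_form_one_phase(self):
        f = gl.extract_features(make_log([ev(0, 5), ev(5, 9)]))
        assert f.n_active_phases == 1
        assert f.n_idle_phases == 0
        assert f.idle_phase_mean_s is None

    def test_clock_starts_at_first_event(self):
        """Leading un-annotated recording is not idle time."""
        f = gl.extract_features(make_log([ev(100, 110), ev(115, 125)]))
        assert f.total_duration_s == 25
        assert f.idle_pct == pytest.approx(100 * 5 / 25)

    def test_active_plus_idle_equals_total_on_cohort(self, default_cohort):
        for log in default_cohort[:60]:
            f = gl.extract_features(log)
            active = f.n_active_phases * f.active_phase_mean_s
            idle = (f.idle_phase_mean_s or 0.0) * f.n_idle_phases
            assert active + idle == pytest.approx(f.total_duration_s, abs=1e-9)


class TestSummaries:
    def _features(self, rows):
        cols = [
            "participant_id", "group", "module", "repetition",
            "total_duration_s", "idle_pct", "idle_phase_mean_s",
            "n_idle_phases", "n_active_phases", "active_phase_mean_s",
        ]
        df = pd.DataFrame(rows, columns=["participant_id", "group", "module",
                                         "repetition", "total_duration_s"])
        for c in cols:
            if c not in df.columns:
                df[c] = 1.0
        return df

    def test_repetition_mean(self):
        df = self._features(
            [("P1", "novice", "bladder_neck", r, v) for r, v in [(1, 100), (2, 110), (3, 120)]]
        )
        s = gl.summarize_participants(df)
        module_row = s[(s.module == "bladder_neck")].iloc[0]
        assert module_row.total_duration_s == pytest.approx(110)

    def test_overall_pools_modules_with_equal_weight(self):
        rows = []
        for module, mean in [
            ("bladder_neck", 487.0),
            ("neurovascular_bundle", 620.0),
            ("anastomosis", 918.0),
        ]:
            rows.append(("E1", "experienced", module, 1, mean))
        s = gl.summarize_participants(self._features(rows))
        overall = s[s.module == "overall"].iloc[0]
        assert overall.total_duration_s == pytest.approx((487 + 620 + 918) / 3)
        assert overall.total_duration_s == pytest.approx(675)

    def test_missing_repetition_averages_existing(self):
        df = self._features(
            [("P1", "novice", "bladder_neck", r, v) for r, v in [(1, 100), (2, 120)]]
        )
        s = gl.summarize_participants(df)
        assert s[s.module == "bladder_neck"].iloc[0].total_duration_s == pytest.approx(110)

    def test_procedure_mean_weighting_option(self):
        rows = [("P1", "novice", "bladder_neck", r, 100.0) for r in (1, 2)]
        rows += [("P1", "novice", "anastomosis", 1, 400.0)]
        df = self._features(rows)
        eq_mod = gl.summarize_participants(df, overall="module_mean")
        eq_proc = gl.summarize_participants(df, overall="procedure_mean")
        assert eq_mod[eq_mod.module == "overall"].iloc[0].total_duration_s == pytest.approx(250)
        assert eq_proc[eq_proc.module == "overall"].iloc[0].total_duration_s == pytest.approx(200)


class TestGroupTable:
    def _summaries(self, novice_vals, exp_vals):
        rows = []
        for i, v in enumerate(novice_vals):
            rows.append({"participant_id": f"N{i}", "group": "novice",
                         "module": "overall", **{m: v for m in TABLE_METRICS}})
        for i, v in enumerate(exp_vals):
            rows.append({"participant_id": f"E{i}", "group": "experienced",
                         "module": "overall", **{m: v for m in TABLE_METRICS}})
        return pd.DataFrame(rows)

    def test_equal_groups_give_null_t(self):
        t = gl.group_table(self._summaries([1, 2, 3], [1, 2, 3]))
        assert (t.t == 0).all()
        assert (t.p == 1).all()

    def test_degenerate_constant_groups(self):
        t = gl.group_table(self._summaries([2, 2], [1, 1]))
        assert (t.p == 0).all()
        assert np.isinf(t.t).all()

    def test_matches_textbook_two_sample_formula(self):
        a = [4.1, 5.0, 6.2, 5.5]
        b = [3.0, 3.8, 4.1, 3.3]
        t = gl.group_table(self._summaries(a, b)).iloc[0]
        # independent oracle: classical pooled-variance two-sample t
        na, nb = len(a), len(b)
        ma, mb = np.mean(a), np.mean(b)
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
        t_oracle = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
        from scipy.stats import t as tdist

        p_oracle = 2 * tdist.sf(abs(t_oracle), na + nb - 2)
        assert t.t == pytest.approx(t_oracle, abs=1e-12)
        assert t.p == pytest.approx(p_oracle, abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(EventLogError, match=">= 2"):
            gl.group_table(self._summaries([1.0], [1.0, 2.0]))
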