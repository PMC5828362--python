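"""Spot flags, replicate summarization, and array-level control QC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from conftest import make_array
from oracles import brute_force_replicate_summary, oracle_cv
from pmarray.model import (
    ControlLevel,
    ReplicateStatus,
    Settings,
    SpotFlag,
    SpotRecord,
    Verdict,
)
from pmarray.qc import (
    array_control_cv,
    cv_pct,
    evaluate_arrays,
    flag_noisy,
    flag_saturated,
    replicate_summary,
)


def spot(net=0.0, bg_sd=0.0, pct_sat=0.0):
    return SpotRecord(1, 1, 1, "A", "", raw_fg=net, raw_bg=0.0, bg_sd=bg_sd,
                      pct_saturated=pct_sat, corrected_bg=0.0, net=net)


class TestFlagNoisy:
    @pytest.mark.parametrize(
        "net, bg_sd, n, flagged",
        [
            (50.0, 30.0, 2.0, True),   # below the 2-SD floor
            (60.0, 30.0, 2.0, False),  # exactly at threshold: strict, not flagged
            (-5.0, 0.0, 2.0, True),    # negative net, zero-SD background
            (0.0, 0.0, 2.0, False),    # zero net at zero threshold survives
            (61.0, 30.0, 2.0, False),
        ],
    )
    def test_strict_threshold(self, net, bg_sd, n, flagged):
        s = flag_noisy(spot(net=net, bg_sd=bg_sd), n)
        assert (SpotFlag.NOISY in s.flags) is flagged

    def test_raising_n_only_adds_flags(self):
        rng = np.random.default_rng(5)
        nets = rng.uniform(-50, 400, size=200)
        sds = rng.uniform(0, 60, size=200)
        for n_small, n_big in [(1.0, 2.0), (2.0, 3.0)]:
            small = {i for i, (v, sd) in enumerate(zip(nets, sds))
                     if SpotFlag.NOISY in flag_noisy(spot(v, sd), n_small).flags}
            big = {i for i, (v, sd) in enumerate(zip(nets, sds))
                   if SpotFlag.NOISY in flag_noisy(spot(v, sd), n_big).flags}
            assert small <= big


class TestFlagSaturated:
    @pytest.mark.parametrize(
        "pct, threshold, enabled, flagged",
        [
            (15.0, 10.0, True, True),
            (10.0, 10.0, True, False),  # exactly at threshold: strict "above"
            (99.0, 10.0, False, False),  # AGC mode disables the flag
            (10.1, 10.0, True, True),
        ],
    )
    def test_strict_threshold_and_agc(self, pct, threshold, enabled, flagged):
        s = flag_saturated(spot(pct_sat=pct), threshold, enabled)
        assert (SpotFlag.SATURATED in s.flags) is flagged


def unflagged(*values):
    return [(float(v), set()) for v in values]


class TestReplicateSummary:
    def test_low_variance_triplet(self):
        s = replicate_summary(unflagged(100, 102, 98), Settings())
        assert s.status is ReplicateStatus.OK
        assert s.mean == pytest.approx(100.0)
        assert s.cv_pct == pytest.approx(2.0)
        assert s.excluded == []

    def test_single_outlier_removed(self):
        s = replicate_summary(unflagged(100, 102, 500), Settings())
        assert s.status is ReplicateStatus.OK
        assert s.mean == pytest.approx(101.0)
        assert [(e.value, e.reason) for e in s.excluded] == [(500.0, "OUTLIER")]
        assert s.cv_pct == pytest.approx(100 * np.std([100, 102], ddof=1) / 101)

    def test_flagged_replica_dropped_mean_of_valid_pair(self):
        vals = [(100.0, set()), (104.0, set()), (30.0, {SpotFlag.NOISY})]
        s = replicate_summary(vals, Settings())
        assert s.status is ReplicateStatus.OK
        assert s.mean == pytest.approx(102.0)
        assert [(e.value, e.reason) for e in s.excluded] == [(30.0, "NOISY")]

    def test_irreparable_spread_is_high_cv(self):
        s = replicate_summary(unflagged(100, 300, 900), Settings())
        assert s.status is ReplicateStatus.HIGH_CV
        assert s.mean is None and s.cv_pct is None

    def test_too_few_clean_replicas_is_noisy(self):
        vals = [(100.0, {SpotFlag.NOISY}), (104.0, {SpotFlag.SATURATED}),
                (101.0, set())]
        s = replicate_summary(vals, Settings())
        assert s.status is ReplicateStatus.NOISY
        assert s.mean is None
        assert {e.reason for e in s.excluded} == {"NOISY", "SATURATED"}

    def test_all_flagged_group_is_noisy_not_high_cv(self):
        vals = [(v, {SpotFlag.NOISY}) for v in (1.0, 900.0, 5000.0)]
        s = replicate_summary(vals, Settings())
        assert s.status is ReplicateStatus.NOISY

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            replicate_summary([], Settings())

    def test_at_most_one_outlier_removed(self):
        # Two wild values would need two removals: HIGH CV instead.
        s = replicate_summary(unflagged(100, 101, 99, 600, 900), Settings())
        assert s.status is ReplicateStatus.HIGH_CV

    def test_matches_subset_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        cfg = Settings()
        for _ in range(500):
            n = int(rng.integers(2, 7))
            values = []
            for _ in range(n):
                v = float(rng.choice([
                    rng.uniform(50, 150), rng.uniform(0, 2000), rng.uniform(-100, 100)
                ]))
                flags = {SpotFlag.NOISY} if rng.random() < 0.2 else set()
                values.append((v, flags))
            got = replicate_summary(values, cfg)
            status, mean, removed = brute_force_replicate_summary(
                values, cfg.replicate_cv_threshold_pct, cfg.min_replicates
            )
            assert got.status.value == status
            if mean is None:
                assert got.mean is None
            else:
                assert got.mean == pytest.approx(mean)
            got_outliers = sorted(e.value for e in got.excluded if e.reason == "OUTLIER")
            assert got_outliers == sorted(removed)

    @hyp_settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        values=st.lists(st.floats(1.0, 1e5), min_size=2, max_size=6),
        scale=st.floats(0.01, 100.0),
    )
    def test_scale_invariance(self, values, scale):
        cfg = Settings()
        a = replicate_summary(unflagged(*values), cfg)
        b = replicate_summary(unflagged(*(v * scale for v in values)), cfg)
        assert a.status == b.status
        if a.cv_pct is not None:
            assert b.cv_pct == pytest.approx(a.cv_pct, rel=1e-9, abs=1e-9)
        assert len(a.excluded) == len(b.excluded)


class TestArrayControlCV:
    def test_zero_variance_controls(self, tiny_layout):
        nets = {(s.block, s.row, s.col): 500.0 for s in tiny_layout.spots}
        arr = make_array(tiny_layout, nets)
        assert array_control_cv(arr, "PC-MED") == 0.0

    def test_known_cv_values(self, tiny_layout):
        nets = {(s.block, s.row, s.col): 100.0 for s in tiny_layout.spots}
        nets[(1, 1, 2)] = 400.0   # the two med-control replicas
        nets[(2, 1, 2)] = 600.0
        arr = make_array(tiny_layout, nets)
        assert array_control_cv(arr, "PC-MED") == pytest.approx(
            oracle_cv([400.0, 600.0])
        )

    def test_nonpositive_mean_is_infinite(self, tiny_layout):
        nets = {(s.block, s.row, s.col): 100.0 for s in tiny_layout.spots}
        nets[(1, 1, 1)] = -200.0
        nets[(2, 1, 1)] = 100.0
        arr = make_array(tiny_layout, nets)
        assert math.isinf(array_control_cv(arr, "PC-LOW"))

    def test_flagged_control_spots_still_count(self, tiny_layout):
        # Array QC detects printing problems; flags must not mask them.
        nets = {(s.block, s.row, s.col): 100.0 for s in tiny_layout.spots}
        nets[(1, 1, 2)] = 1000.0
        arr = make_array(tiny_layout, nets)
        for s in arr.spots:
            if (s.block, s.row, s.col) == (1, 1, 2):
                s.flags.add(SpotFlag.SATURATED)
        assert array_control_cv(arr, "PC-MED") == pytest.approx(
            oracle_cv([1000.0, 100.0])
        )


class TestEvaluateArrays:
    def make(self, tiny_layout, low, med, high, array_id="a"):
        nets = {(s.block, s.row, s.col): 100.0 for s in tiny_layout.spots}
        for b, vals in ((1, 0), (2, 1)):
            nets[(b, 1, 1)] = low[vals]
            nets[(b, 1, 2)] = med[vals]
            nets[(b, 1, 3)] = high[vals]
        return make_array(tiny_layout, nets, array_id=array_id)

    def test_failing_unselected_control_keeps_array(self, tiny_layout):
        arr = self.make(tiny_layout, low=(100, 500), med=(500, 510), high=(500, 520))
        verdicts = evaluate_arrays([arr], tiny_layout, Settings())
        v = verdicts["a"]
        assert v[ControlLevel.LOW].verdict is Verdict.DISCARD
        assert v[ControlLevel.MED].verdict is Verdict.KEEP
        assert v[ControlLevel.OVERALL].verdict is Verdict.KEEP
        assert v[ControlLevel.OVERALL].cv_pct == v[ControlLevel.MED].cv_pct

    def test_selected_control_drives_overall(self, tiny_layout):
        arr = self.make(tiny_layout, low=(100, 500), med=(500, 510), high=(500, 520))
        verdicts = evaluate_arrays(
            [arr], tiny_layout, Settings(selected_control="LOW")
        )
        assert verdicts["a"][ControlLevel.OVERALL].verdict is Verdict.DISCARD

    def test_all_pass(self, tiny_layout):
        arr = self.make(tiny_layout, low=(100, 101), med=(500, 505), high=(900, 905))
        verdicts = evaluate_arrays([arr], tiny_layout, Settings())
        assert all(v.verdict is Verdict.KEEP for v in verdicts["a"].values())
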