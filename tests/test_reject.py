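import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsreject.criteria import Criterion2Config, Criterion3Config, NoiseFlag
from nirsreject.reject import (
    UNLIMITED,
    AdaptiveEpochRejector,
    RejectionPolicy,
    apply_rejection,
    propagate_rejection,
    rank_and_trim,
    run_rejection,
)

from conftest import make_epoch_set
from oracles import oracle_five_step


def stub_stage(flagged, criterion, severity=1.0):
    """Detector that flags a fixed epoch set (intersected with retained)."""
    def stage(retained):
        sev = severity if callable(severity) else (lambda e: severity)
        return [NoiseFlag(epoch_index=e, criterion=criterion, severity=sev(e))
                for e in flagged if e in retained]
    return stage


class TestStageLogic:
    def test_no_flags_all_retained(self):
        res = run_rejection(6, [stub_stage(set(), 1)], acceptance_rate=3)
        assert res.retained == list(range(6))
        assert res.rejected == {}
        assert res.ledger == []

    def test_overflowing_stage_records_instead_of_rejecting(self):
        """4 of 6 flagged with floor 3: zero rejections, 4 recorded flags."""
        res = run_rejection(6, [stub_stage({0, 1, 2, 3}, 1)], acceptance_rate=3)
        # stage rejection would leave 2 < 3, so it is skipped...
        recorded = [r for r in res.ledger if r.action != "rejected"]
        assert len(recorded) == 4
        # ...but ranking then trims down to exactly the floor
        assert len(res.retained) == 3
        assert set(res.rejected.values()) == {"ranking"}

    def test_all_or_none_within_stage(self):
        # 2 of 6 flagged, floor 3: all flagged epochs go
        res = run_rejection(6, [stub_stage({1, 4}, 1)], acceptance_rate=3)
        assert res.retained == [0, 2, 3, 5]
        assert res.rejected == {1: "criterion_1", 4: "criterion_1"}

    def test_later_stage_sees_only_survivors(self):
        seen = []

        def spy(retained):
            seen.append(tuple(retained))
            return []

        run_rejection(6, [stub_stage({0, 5}, 1), spy], acceptance_rate=3)
        assert seen == [(1, 2, 3, 4)]

    def test_acceptance_above_n_epochs_is_config_error(self):
        with pytest.raises(ValueError):
            run_rejection(6, [stub_stage(set(), 1)], acceptance_rate=7)


class TestRankAndTrim:
    def _records(self, flags):
        from nirsreject.reject import NoiseRecord

        out = []
        for epoch, crits in flags.items():
            for stage, (crit, sev) in enumerate(crits):
                out.append(NoiseRecord(
                    flag=NoiseFlag(epoch_index=epoch, criterion=crit, severity=sev),
                    stage=crit - 1, action="recorded"))
        return out

    def test_two_flags_beat_one_flag(self):
        """Epochs {2: 2 flags, 5: 1 flag}, floor 4 of 6: reject 2 then 5."""
        ledger = self._records({2: [(1, 0.5), (2, 0.04)], 5: [(1, 0.3)]})
        retained, rejected, _ = rank_and_trim(list(range(6)), ledger, 4)
        assert retained == [0, 1, 3, 4]
        assert set(rejected) == {2, 5}

    def test_stops_when_flags_exhausted(self):
        ledger = self._records({1: [(2, 0.05)]})
        retained, rejected, _ = rank_and_trim(list(range(6)), ledger, 3)
        assert retained == [0, 2, 3, 4, 5]  # stops at 5 retained: nothing left
        assert set(rejected) == {1}

    def test_unlimited_is_noop(self):
        ledger = self._records({1: [(1, 0.5)]})
        retained, rejected, _ = rank_and_trim(list(range(6)), ledger, UNLIMITED)
        assert retained == list(range(6))
        assert rejected == {}

    def test_severity_rank_sum_breaks_level_ties(self):
        # same level; epoch 3 has the larger criterion-1 severity -> goes first
        ledger = self._records({1: [(1, 0.3)], 3: [(1, 0.9)]})
        retained, rejected, _ = rank_and_trim(list(range(6)), ledger, 5)
        assert set(rejected) == {3}
        assert 1 in retained

    def test_index_breaks_full_ties(self):
        ledger = self._records({2: [(1, 0.5)], 4: [(1, 0.5)]})
        retained, rejected, _ = rank_and_trim(list(range(6)), ledger, 5)
        assert set(rejected) == {2}  # equal level and severity: lower index


class TestConventionalMode:
    def test_unlimited_equals_unconditional_rejection(self):
        patterns = [{0, 3}, {1}, {2, 4}]
        stages = [stub_stage(p, k + 1) for k, p in enumerate(patterns)]
        res = run_rejection(6, stages, acceptance_rate=UNLIMITED)
        assert res.retained == [5]
        causes = {e: c for e, c in res.rejected.items()}
        assert causes == {0: "criterion_1", 3: "criterion_1", 1: "criterion_2",
                          2: "criterion_3", 4: "criterion_3"}
        assert all(r.action == "rejected" for r in res.ledger)


class TestPropagate:
    def test_complement_applied_to_other_signal_types(self, design):
        rng = np.random.default_rng(0)
        o2 = make_epoch_set(rng.normal(size=(6, 500)))
        res = run_rejection(6, [stub_stage({1, 4}, 1)], acceptance_rate=3)
        hhb = make_epoch_set(rng.normal(size=(6, 500)))
        out, = propagate_rejection(res, [hhb])
        assert list(out.retained_indices) == [0, 2, 3, 5]
        # idempotent
        again, = propagate_rejection(res, [out])
        assert np.array_equal(again.retained, out.retained)

    def test_empty_rejection_keeps_all(self):
        res = run_rejection(6, [stub_stage(set(), 1)], acceptance_rate=3)
        es = make_epoch_set(np.zeros((6, 500)))
        out, = propagate_rejection(res, [es])
        assert out.n_retained == 6

    def test_trial_count_mismatch_raises(self):
        res = run_rejection(6, [stub_stage(set(), 1)], acceptance_rate=3)
        es = make_epoch_set(np.zeros((5, 500)))
        with pytest.raises(ValueError, match="mismatch"):
            propagate_rejection(res, [es])


class TestEngineAgainstOracle:
    @given(
        f1=st.sets(st.integers(0, 5)),
        f2=st.sets(st.integers(0, 5)),
        f3=st.sets(st.integers(0, 5)),
        acc=st.sampled_from([3, 4, None]),
    )
    @settings(derandomize=True, max_examples=300, deadline=None)
    def test_random_patterns_match_five_step_oracle(self, f1, f2, f3, acc):
        sev = lambda e: float((e * 7 + 3) % 11 + 1)
        stages = [stub_stage(f1, 1, sev), stub_stage(f2, 2, sev),
                  stub_stage(f3, 3, sev)]
        res = run_rejection(6, stages, acceptance_rate=acc)
        retained, rejected = oracle_five_step(
            6, [f1, f2, f3], lambda s, e: sev(e), acc)
        assert res.retained == retained
        assert res.rejected == rejected

    @given(
        f1=st.sets(st.integers(0, 5)),
        f2=st.sets(st.integers(0, 5)),
        acc=st.integers(1, 6),
    )
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_floor_invariant_any_pattern(self, f1, f2, acc):
        stages = [stub_stage(f1, 1), stub_stage(f2, 2)]
        res = run_rejection(6, stages, acceptance_rate=acc)
        assert len(res.retained) >= acc


class TestLedger:
    def test_every_flag_appears_with_stage_and_fate(self):
        stages = [stub_stage({0, 1, 2, 3}, 1), stub_stage({4}, 2)]
        res = run_rejection(6, stages, acceptance_rate=3)
        assert {(r.flag.epoch_index, r.stage) for r in res.ledger} == {
            (0, 0), (1, 0), (2, 0), (3, 0), (4, 1)}
        # stage 1 over-floor: recorded; then ranking acts on some of them
        actions = {r.action for r in res.ledger if r.stage == 0}
        assert actions <= {"recorded", "rank_rejected"}
        assert any(r.action == "rank_rejected" for r in res.ledger)

    def test_determinism(self):
        stages = lambda: [stub_stage({0, 2}, 1), stub_stage({1, 2}, 2),
                          stub_stage({3}, 3)]
        a = run_rejection(6, stages(), acceptance_rate=4)
        b = run_rejection(6, stages(), acceptance_rate=4)
        assert a.retained == b.retained and a.rejected == b.rejected


class TestRealPipeline:
    def test_drifting_epoch_rejected_by_criterion_2(self, design):
        rng = np.random.default_rng(11)
        values = rng.normal(0, 0.005, size=(6, 500))
        times = (np.arange(500) - 130) * 0.1
        values[3] += np.where(times < 0, 0.08 * times, 0.0)  # heavy drift
        es = make_epoch_set(values, times=times)
        res = apply_rejection(es, RejectionPolicy())
        assert res.rejected.get(3) == "criterion_2"
        assert 3 not in res.retained

    def test_estimator_front_end_matches_engine(self):
        rng = np.random.default_rng(12)
        X = rng.normal(0, 0.005, size=(6, 500))
        X[2] += np.concatenate([np.zeros(250), np.full(250, 0.5)])  # step artifact
        est = AdaptiveEpochRejector()
        labels = est.fit_predict(X)
        es = make_epoch_set(X)
        res = apply_rejection(es, est._policy())
        assert np.array_equal(labels == 1, res.retained_mask)
        assert list(est.retained_) == res.retained
        assert est.labels_[2] == -1

    def test_estimator_is_cloneable(self):
        from sklearn.base import clone

        est = AdaptiveEpochRejector(k_iqr=1.0, acceptance_rate=4)
        assert clone(est).get_params() == est.get_params()

    def test_empty_epoch_set_raises(self):
        es = make_epoch_set(np.zeros((1, 500)))
        es.values = np.zeros((0, 500))
        es.retained = np.zeros(0, dtype=bool)
        with pytest.raises(ValueError):
            apply_rejection(es, RejectionPolicy())
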