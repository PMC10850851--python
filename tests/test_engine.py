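import itertools
from datetime import datetime, timedelta, timezone

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddst import engine
from ddst.engine import (
    NORMAL,
    POSITIVE,
    PRESENT,
    TERMINAL,
    AssessmentSession,
    SequencingError,
    SessionStateError,
    classify,
    enumerate_outcomes,
    run_scripted,
)
from ddst.item_bank import FEATURES, Feature
from ddst.records import RecordStore, SessionSummary

T0 = datetime(2024, 1, 1, tzinfo=timezone.utc)


def all_normal():
    return {i: NORMAL for i in range(1, 22)}


def answers(*positive_items):
    a = all_normal()
    for i in positive_items:
        a[i] = POSITIVE
    return a


class TestClassify:
    @pytest.mark.parametrize(
        "combo,expected",
        [
            ((True, True, False, True), True),
            ((False, True, True, True), False),  # F1 required
            ((True, False, True, True), False),  # F2 required
            ((True, True, False, False), False),  # F3 or F4 required
            ((False, False, False, False), False),
            ((True, True, True, True), True),
        ],
    )
    def test_rule(self, combo, expected):
        assert classify(combo).delirium is expected

    def test_accepts_state_strings(self):
        assert classify(("present", "present", "absent", "present")).delirium

    def test_accepts_feature_dict(self):
        combo = {f: True for f in FEATURES}
        assert classify(combo).delirium

    def test_monotonicity(self):
        # growing the present set never turns a positive verdict negative
        for a in itertools.product((False, True), repeat=4):
            for b in itertools.product((False, True), repeat=4):
                if all(x <= y for x, y in zip(a, b)) and classify(a).delirium:
                    assert classify(b).delirium


class TestEnumerateOutcomes:
    def test_counts(self):
        cats = enumerate_outcomes()
        assert len(cats) == 16
        assert sum(c.delirium for c in cats) == 3
        assert sum(not c.delirium for c in cats) == 13

    def test_combos_unique_and_labels_stable(self):
        cats = enumerate_outcomes()
        assert len({c.combo for c in cats}) == 16
        assert len({c.label for c in cats}) == 16
        assert enumerate_outcomes() == cats


class TestStepping:
    def test_all_normal_full_mode(self, bank):
        s = AssessmentSession(bank, "P1", "N1", modality="paper", mode="full")
        run_scripted(s, all_normal())
        m = s.metrics()
        assert m["items_administered"] == 21
        assert m["items_skipped"] == 0
        assert s.outcome.combo == (False, False, False, False)
        assert not s.outcome.delirium

    def test_fast_mode_exits_early_on_all_normal(self, bank):
        s = AssessmentSession(bank, "P1", "N1", mode="fast")
        run_scripted(s, all_normal())
        assert s.metrics()["items_administered"] < 21
        assert not s.outcome.delirium

    def test_f2_positive_skips_remaining_f2_items(self, bank):
        s = AssessmentSession(bank, "P1", "N1", modality="paper", mode="full")
        administered = []
        while (iid := s.next_item()) is not TERMINAL:
            administered.append(iid)
            s.submit(iid, POSITIVE if iid == 4 else NORMAL)
        assert 4 in administered
        for f2_item in (5, 6, 7, 18, 19, 20):
            assert f2_item not in administered

    def test_fast_terminal_once_f2_excluded(self, bank):
        # with F3 and F4 resolved absent and F2 still open, answering the
        # last observed-inattention item normal decides the negative verdict
        s = AssessmentSession(bank, "P1", "N1", mode="fast")
        administered = []
        while (iid := s.next_item()) is not TERMINAL:
            administered.append(iid)
            s.submit(iid, NORMAL)
        assert 21 not in administered  # never needed
        assert not s.outcome.delirium

    def test_positives_8_4_1_classify_positive(self, bank):
        s = AssessmentSession(bank, "P1", "N1", modality="paper", mode="full")
        run_scripted(s, answers(8, 4, 1))
        assert s.outcome.combo == (True, True, True, False)
        assert s.outcome.delirium

    def test_fast_and_full_agree_on_positives_8_4_1(self, bank):
        fast = AssessmentSession(bank, "P1", "N1", mode="fast")
        run_scripted(fast, answers(8, 4, 1))
        assert fast.outcome.delirium

    def test_submit_positive_sets_feature_present(self, bank):
        s = AssessmentSession(bank, "P1", "N1", mode="full", modality="paper")
        for iid in (1, 2, 3):
            s.next_item()
            s.submit(iid, NORMAL if iid < 3 else NORMAL)
        nxt = s.next_item()
        assert nxt == 4
        s.submit(4, POSITIVE)
        status = s.feature_status(Feature.F2)
        assert status.state == PRESENT
        assert status.evidence == (4,)

    def test_out_of_order_submission(self, bank):
        s = AssessmentSession(bank, "P1", "N1", mode="full", modality="paper")
        with pytest.raises(SequencingError, match="out-of-order"):
            s.submit(5, NORMAL)

    def test_duplicate_submission(self, bank):
        s = AssessmentSession(bank, "P1", "N1", mode="full", modality="paper")
        s.submit(s.next_item(), NORMAL)
        with pytest.raises(SequencingError, match="already"):
            s.submit(1, POSITIVE)

    def test_next_item_on_terminal_session_errors(self, bank):
        s = AssessmentSession(bank, "P1", "N1", mode="full", modality="paper")
        run_scripted(s, all_normal())
        assert s.is_terminal
        with pytest.raises(SessionStateError):
            s.next_item()

    def test_metrics_on_nonterminal_errors(self, bank):
        s = AssessmentSession(bank, "P1", "N1")
        with pytest.raises(SessionStateError):
            s.metrics()

    def test_bad_value_rejected(self, bank):
        s = AssessmentSession(bank, "P1", "N1")
        s.next_item()
        with pytest.raises(ValueError):
            s.submit(1, "maybe")


class TestSkipSoundness:
    def test_no_item_of_present_feature_administered(self, bank, rng):
        for _ in range(100):
            vals = {i: POSITIVE if rng.random() < 0.3 else NORMAL for i in range(1, 22)}
            mode = "fast" if rng.random() < 0.5 else "full"
            s = AssessmentSession(bank, "P", "N", mode=mode)
            while (iid := s.next_item()) is not TERMINAL:
                feature = bank.item(iid).feature
                assert s.feature_status(feature).state != PRESENT
                s.submit(iid, vals[iid])


class TestConservation:
    def test_administered_plus_skipped_plus_auto_is_22(self, bank, rng):
        for _ in range(300):
            vals = {i: POSITIVE if rng.random() < 0.25 else NORMAL for i in range(1, 22)}
            mode = "fast" if rng.random() < 0.5 else "full"
            s = AssessmentSession(bank, "P", "N", mode=mode)
            run_scripted(s, vals)
            m = s.metrics()
            assert m["items_administered"] + m["items_skipped"] + 1 == 22


class TestFastFullEquivalence:
    def test_exhaustive_feature_pattern_classes(self, bank):
        # one canonical response vector per 2^4 feature pattern: the first
        # display item of each present feature is positive
        from ddst.item_bank import AUTO_ITEM, feature_evidence_map

        fmap = feature_evidence_map(bank)
        for pattern in itertools.product((False, True), repeat=4):
            vals = all_normal()
            for f, present in zip(FEATURES, pattern):
                if present:
                    first = [i for i in fmap[f] if i != AUTO_ITEM][0]
                    vals[first] = POSITIVE
            full = AssessmentSession(bank, "P", "N", modality="paper", mode="full")
            run_scripted(full, vals)
            fast = AssessmentSession(bank, "P", "N", mode="fast")
            run_scripted(fast, vals)
            assert fast.outcome.delirium == full.outcome.delirium

    @settings(max_examples=300, deadline=None)
    @given(st.lists(st.booleans(), min_size=21, max_size=21))
    def test_random_vectors(self, bank, bits):
        vals = {i + 1: POSITIVE if b else NORMAL for i, b in enumerate(bits)}
        full = AssessmentSession(bank, "P", "N", modality="paper", mode="full")
        run_scripted(full, vals)
        fast = AssessmentSession(bank, "P", "N", mode="fast")
        run_scripted(fast, vals)
        assert fast.outcome.delirium == full.outcome.delirium

    @settings(max_examples=150, deadline=None)
    @given(
        st.lists(st.booleans(), min_size=21, max_size=21),
        st.tuples(st.booleans(), st.booleans(), st.booleans(), st.booleans()),
    )
    def test_random_vectors_with_baseline(self, bank, bits, base_combo):
        baseline = SessionSummary(
            patient_id="P",
            timestamp=T0,
            combo=base_combo,
            delirium=classify(base_combo).delirium,
            item_values={i: NORMAL for i in range(1, 8)},
        )
        vals = {i + 1: POSITIVE if b else NORMAL for i, b in enumerate(bits)}
        full = AssessmentSession(
            bank, "P", "N", modality="paper", mode="full",
            baseline=baseline, start_time=T0 + timedelta(days=1),
        )
        run_scripted(full, vals)
        fast = AssessmentSession(
            bank, "P", "N", mode="fast",
            baseline=baseline, start_time=T0 + timedelta(days=1),
        )
        run_scripted(fast, vals)
        assert fast.outcome.delirium == full.outcome.delirium


class TestItem22Derivation:
    def _baseline(self, combo=(False,) * 4, item_values=None):
        if item_values is None:
            item_values = {i: NORMAL for i in range(1, 8)}
        return SessionSummary(
            patient_id="P",
            timestamp=T0,
            combo=combo,
            delirium=classify(combo).delirium,
            item_values=item_values,
        )

    def test_no_history_gives_normal_and_flag(self, bank):
        store = RecordStore()
        s = engine.start_session(bank, "P", "N", history=store)
        assert s.no_baseline
        assert s.value_of(22) == NORMAL
        assert s.responses[0].source == "auto"

    def test_new_deficit_flips_auto_item(self, bank):
        s = AssessmentSession(
            bank, "P", "N", modality="paper", mode="full",
            baseline=self._baseline(), start_time=T0 + timedelta(days=1),
        )
        assert s.value_of(22) == NORMAL
        while (iid := s.next_item()) is not TERMINAL:
            s.submit(iid, POSITIVE if iid == 5 else NORMAL)
            if iid == 5:
                break
        assert s.value_of(22) == POSITIVE

    def test_preexisting_deficit_stays_normal(self, bank):
        baseline = self._baseline(
            combo=(False, True, False, False),
            item_values={**{i: NORMAL for i in range(1, 8)}, 5: POSITIVE},
        )
        s = AssessmentSession(
            bank, "P", "N", modality="paper", mode="full",
            baseline=baseline, start_time=T0 + timedelta(days=1),
        )
        run_scripted(s, answers(5))
        assert s.value_of(22) == NORMAL

    def test_auto_item_drives_f1(self, bank):
        # new F2 and F3 deficits make the record comparison positive, which
        # supplies the F1 evidence needed for a positive diagnosis
        s = AssessmentSession(
            bank, "P", "N", modality="paper", mode="full",
            baseline=self._baseline(), start_time=T0 + timedelta(days=1),
        )
        run_scripted(s, answers(1, 4))
        assert s.value_of(22) == POSITIVE
        assert s.feature_status(Feature.F1).state == PRESENT
        assert s.outcome.delirium

    def test_derive_item22_op(self, bank):
        store = RecordStore()
        store.append(self._baseline())
        s = engine.start_session(
            bank, "P", "N", modality="paper", mode="full",
            history=store, start_time=T0 + timedelta(days=1),
        )
        assert not s.no_baseline
        resp = engine.derive_item22(store, s)
        assert resp.source == "auto"
        assert resp.value == NORMAL

    def test_start_session_before_baseline_sees_no_history(self, bank):
        store = RecordStore()
        store.append(self._baseline())
        s = engine.start_session(bank, "P", "N", history=store, start_time=T0)
        assert s.no_baseline  # strictly-before lookup


class TestModeParity:
    def test_fast_and_full_start_identically(self, bank):
        a = engine.start_session(bank, "P", "N", mode="full", modality="paper",
                                 start_time=T0)
        b = engine.start_session(bank, "P", "N", mode="fast", start_time=T0)
        assert a.next_item() == b.next_item() == 1
        assert a.value_of(22) == b.value_of(22) == NORMAL
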