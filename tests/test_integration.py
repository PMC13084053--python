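"""Modality calls, union combination, detection metrics, ROC, lead times."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ewingsign.fragmentomics import ModalityThresholds
from ewingsign.integrate import (
    DetectionMetrics,
    call_modalities,
    combine,
    detection_metrics,
    lead_time,
    longitudinal_table,
    roc_auc,
    round_half_up,
)
from ewingsign.samples import SampleRecord

THR = ModalityThresholds(tau_p100150=0.1848, tau_dip=-154.31)


class TestCallModalities:
    def test_ichor_limit_of_detection_boundary(self):
        neg = call_modalities("s", {"ichor_tf": 0.029}, THR)
        pos = call_modalities("s", {"ichor_tf": 0.030}, THR)
        assert neg.calls["ichor_tf"] is np.False_ or neg.calls["ichor_tf"] == False  # noqa: E712
        assert pos.calls["ichor_tf"]

    def test_p100_150_strictly_above_threshold(self):
        at = call_modalities("s", {"p100_150": 0.1848}, THR)
        above = call_modalities("s", {"p100_150": 0.1849}, THR)
        assert not at.calls["p100_150"]
        assert above.calls["p100_150"]

    def test_dip_strictly_below_threshold(self):
        at = call_modalities("s", {"dip_area": -154.31}, THR)
        below = call_modalities("s", {"dip_area": -154.32}, THR)
        assert not at.calls["dip_area"]
        assert below.calls["dip_area"]

    def test_all_four_positive(self):
        mc = call_modalities(
            "s",
            {"ichor_tf": 0.05, "p100_150": 0.2, "dip_area": -200.0, "classifier": 0.9},
            THR,
        )
        assert mc.n_positive() == 4

    def test_missing_value_not_evaluable(self):
        mc = call_modalities("s", {"ichor_tf": None, "classifier": 0.2}, THR)
        assert not mc.evaluable("ichor_tf")
        assert not mc.evaluable("p100_150")
        assert mc.evaluable("classifier")


class TestCombine:
    def _calls(self, mapping):
        from ewingsign.integrate import ModalityCalls

        return ModalityCalls("s", {}, dict(mapping), THR)

    def test_union_basic(self):
        assert combine(self._calls({"ichor_tf": True, "p100_150": False}))[0] is True
        assert combine(self._calls({"ichor_tf": False, "p100_150": False}))[0] is False

    def test_no_evaluable_modality(self):
        call, n = combine(self._calls({}))
        assert call is None and n == 0

    @given(
        st.dictionaries(
            st.sampled_from(["ichor_tf", "p100_150", "dip_area", "classifier"]),
            st.booleans(),
            min_size=1,
        ),
        st.booleans(),
    )
    def test_union_monotone_in_added_modalities(self, calls, extra):
        base, _ = combine(self._calls(calls))
        missing = [m for m in ("ichor_tf", "p100_150", "dip_area", "classifier") if m not in calls]
        if missing:
            calls2 = dict(calls)
            calls2[missing[0]] = extra
            grown, _ = combine(self._calls(calls2))
            if base:
                assert grown  # adding a modality never flips positive -> negative


class TestDetectionMetrics:
    def test_study_confusion_arithmetic(self):
        dm = DetectionMetrics(tp=26, fn=8, tn=24, fp=0)
        assert dm.summary() == {"sensitivity": 76.5, "specificity": 100.0, "accuracy": 86.2}

    def test_one_false_positive_of_24_controls(self):
        dm = DetectionMetrics(tp=26, fn=8, tn=23, fp=1)
        assert dm.summary()["specificity"] == 95.8

    def test_perfect_calls(self):
        dm = DetectionMetrics(tp=10, fn=0, tn=5, fp=0)
        assert dm.summary() == {"sensitivity": 100.0, "specificity": 100.0, "accuracy": 100.0}

    @given(
        st.integers(0, 500), st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)
    )
    def test_identities_hold(self, tp, fn, tn, fp):
        if tp + fn == 0 or tn + fp == 0:
            return
        dm = DetectionMetrics(tp=tp, fn=fn, tn=tn, fp=fp)
        assert dm.sensitivity == pytest.approx(100 * tp / (tp + fn))
        assert dm.specificity == pytest.approx(100 * tn / (tn + fp))
        assert dm.accuracy == pytest.approx(100 * (tp + tn) / (tp + fn + tn + fp))

    def test_counts_from_sample_calls(self):
        calls = {"a": True, "b": False, "c": True, "d": False}
        labels = {"a": True, "b": True, "c": False, "d": False}
        dm = detection_metrics(calls, labels)
        assert (dm.tp, dm.fn, dm.fp, dm.tn) == (1, 1, 1, 1)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            detection_metrics({"a": True}, {"a": True})

    def test_round_half_up_matches_report_convention(self):
        assert round_half_up(76.4705, 1) == 76.5
        assert round_half_up(86.25, 1) == 86.3  # half away from zero


def _auc_oracle(scores, labels):
    """Exhaustive pair counting: P(cancer > control) with ties at 0.5."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        auc, curve = roc_auc([0.9, 0.8, 0.1, 0.2], [True, True, False, False])
        assert auc == 1.0
        assert curve["tpr"].iloc[-1] == 1.0 and curve["fpr"].iloc[-1] == 1.0

    def test_worked_pair_example(self):
        # pairs: (0.9 > 0.5) = 1, (0.4 < 0.5) = 0 -> mean 0.5
        auc, _ = roc_auc([0.9, 0.4, 0.5], [True, True, False])
        assert auc == 0.5

    @given(st.data())
    def test_matches_exhaustive_pair_oracle(self, data):
        n = data.draw(st.integers(2, 20))
        scores = data.draw(
            st.lists(st.sampled_from([0.0, 0.1, 0.25, 0.5, 0.5, 0.9, 1.0]), min_size=n, max_size=n)
        )
        labels = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        if not (any(labels) and not all(labels)):
            return
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(_auc_oracle(scores, labels))

    def test_random_labels_near_half(self, rng):
        scores = rng.uniform(size=2000)
        labels = rng.random(2000) < 0.5
        auc, _ = roc_auc(scores, labels)
        assert abs(auc - 0.5) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [True, True])


def _record(sid, pid, tp, day):
    label = "NCC" if tp == "control" else "EwS"
    cohort = "ncc2" if tp == "control" else "patient"
    return SampleRecord(sid, pid, tp, day, label, cohort, None)


def _mk_calls(spec):
    """spec: {sample_id: n_positive_modalities} using classifier slots."""
    from ewingsign.integrate import ModalityCalls

    out = {}
    for sid, n_pos in spec.items():
        mods = ["ichor_tf", "p100_150", "dip_area", "classifier"]
        out[sid] = ModalityCalls(
            sid, {}, {m: (i < n_pos) for i, m in enumerate(mods)}, THR
        )
    return out


class TestLongitudinal:
    def test_counts_and_day_ordering(self):
        records = [
            _record("s3", "p1", "relapse", 119),
            _record("s1", "p1", "diagnosis", 0),
            _record("s2", "p1", "first_line_treatment", 91),
        ]
        calls = _mk_calls({"s1": 4, "s2": 1, "s3": 0})
        tl = longitudinal_table(records, calls)
        assert tl["day"].tolist() == [0, 91, 119]
        assert tl["n_positive_modalities"].tolist() == [4, 1, 0]

    def test_duplicate_sample_rejected(self):
        records = [_record("s1", "p1", "diagnosis", 0)] * 2
        with pytest.raises(ValueError):
            longitudinal_table(records, _mk_calls({"s1": 1}))

    def test_single_sample_patient(self):
        tl = longitudinal_table([_record("s1", "p1", "diagnosis", 5)], _mk_calls({"s1": 2}))
        assert len(tl) == 1


class TestLeadTime:
    def _timeline(self, spec):
        return pd.DataFrame(
            [{"day": d, "n_positive_modalities": n} for d, n in spec]
        )

    def test_printed_exemplar(self):
        # positive on-treatment sample at day 60, clinical relapse at day 179
        tl = self._timeline([(0, 4), (60, 1), (120, 0)])
        assert lead_time(tl, 179) == 119

    def test_latest_positive_rule(self):
        tl = self._timeline([(10, 1), (40, 2)])
        assert lead_time(tl, 100) == 60

    def test_no_pre_relapse_positive(self):
        tl = self._timeline([(10, 0), (40, 0)])
        assert lead_time(tl, 100) is None
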