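"""Confusion metrics, F-beta, Wilson and AUC intervals against independent oracles."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import resectability as rs
from resectability.criteria import PredictedLabel, ReferenceLabel
from resectability.metrics import ConfusionCounts, IntervalMethod, round_half_up

# Published per-assessor rows: counts (tp, fp, fn, tn) and the rendered
# metrics (percent, 1 decimal) Sens, Spec, PPV, NPV, Acc, F1, F0.5 and AUC
# (3 decimals).
PRINTED_ROWS = [
    # 224-patient operable cohort
    ("US/224", (40, 9, 22, 153), (64.5, 94.4, 81.6, 87.4, 86.2, 72.1, 77.5), 0.795),
    ("CT/224", (38, 16, 24, 146), (61.3, 90.1, 70.4, 85.9, 82.1, 65.5, 68.3), 0.757),
    ("SURG/224", (59, 10, 3, 152), (95.2, 93.8, 85.5, 98.1, 94.2, 90.1, 87.3), 0.945),
    # 167-patient complete-case subcohort
    ("US/167", (35, 7, 13, 112), (72.9, 94.1, 83.3, 89.6, 88.0, 77.8, 81.0), 0.835),
    ("CT/167", (30, 14, 18, 105), (62.5, 88.2, 68.2, 85.4, 80.8, 65.2, 67.0), 0.754),
    ("MRI/167", (26, 12, 22, 107), (54.2, 89.9, 68.4, 82.9, 79.6, 60.5, 65.0), 0.720),
    ("SURG/167", (47, 9, 1, 110), (97.9, 92.4, 83.9, 99.1, 94.0, 90.4, 86.4), 0.952),
]

counts_strategy = st.builds(
    ConfusionCounts,
    tp=st.integers(0, 60), fp=st.integers(0, 60),
    fn=st.integers(0, 60), tn=st.integers(0, 60),
).filter(lambda c: c.n_pos > 0 and c.n_neg > 0)


class TestPointMetrics:
    @pytest.mark.parametrize("label,raw,percents,auc", PRINTED_ROWS,
                             ids=[r[0] for r in PRINTED_ROWS])
    def test_printed_rows_reproduced_exactly(self, label, raw, percents, auc):
        tp, fp, fn, tn = raw
        m = rs.point_metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn))
        rendered = (
            m.percent("sensitivity"), m.percent("specificity"), m.percent("ppv"),
            m.percent("npv"), m.percent("accuracy"),
            round_half_up(100 * m.fbeta[1.0], 1), round_half_up(100 * m.fbeta[0.5], 1),
        )
        assert rendered == percents
        assert round_half_up(m.auc, 3) == auc

    def test_zero_denominator_metrics_undefined(self):
        m = rs.point_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=10))
        assert m.sensitivity is None and m.ppv is None
        assert m.fbeta[1.0] is None and m.fbeta[0.5] is None
        assert m.percent("specificity") == 100.0
        assert m.percent("accuracy") == 100.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            rs.point_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=0))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(counts_strategy)
    def test_f1_equals_its_count_form(self, c):
        m = rs.point_metrics(c)
        if m.fbeta[1.0] is not None:
            direct = 2 * c.tp / (2 * c.tp + c.fp + c.fn)
            assert m.fbeta[1.0] == pytest.approx(direct, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(counts_strategy)
    def test_intervals_contain_their_point_estimates(self, c):
        m = rs.point_metrics(c)
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy", "auc"):
            value = getattr(m, name)
            if value is not None and name in m.ci:
                lo, hi = m.ci[name]
                assert lo - 1e-12 <= value <= hi + 1e-12


class TestAUC:
    def test_auc_matches_empirical_roc_oracle(self):
        """Balanced accuracy equals the trapezoidal area of the two-point
        empirical ROC, checked against scikit-learn on expanded 0/1 scores."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        for _ in range(200):
            tp, fp, fn, tn = rng.integers(1, 40, size=4)
            c = ConfusionCounts(tp=int(tp), fp=int(fp), fn=int(fn), tn=int(tn))
            scores = np.r_[np.ones(tp), np.zeros(fn), np.ones(fp), np.zeros(tn)]
            labels = np.r_[np.ones(tp + fn), np.zeros(fp + tn)]
            expected = roc_auc_score(labels, scores)
            auc = rs.point_metrics(c).auc
            assert auc == pytest.approx(expected, abs=1e-12)

    def test_delong_binary_interval_matches_placement_oracle(self):
        """The closed-form SE equals a brute-force evaluation of the DeLong
        structural components on expanded two-valued score vectors."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            tp, fp, fn, tn = (int(v) for v in rng.integers(1, 30, size=4))
            c = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
            x = np.r_[np.ones(tp), np.zeros(fn)]       # diseased scores
            y = np.r_[np.ones(fp), np.zeros(tn)]       # non-diseased scores
            v10 = np.array([np.mean((xi > y) + 0.5 * (xi == y)) for xi in x])
            v01 = np.array([np.mean((x > yi) + 0.5 * (x == yi)) for yi in y])
            var = v10.var(ddof=0) / len(x) + v01.var(ddof=0) / len(y)
            a = (c.tp / c.n_pos + c.tn / c.n_neg) / 2
            z = 1.959963984540054
            lo, hi = rs.auc_interval(c, confidence=0.95)
            assert lo == pytest.approx(max(0.0, a - z * math.sqrt(var)), abs=1e-9)
            assert hi == pytest.approx(min(1.0, a + z * math.sqrt(var)), abs=1e-9)

    def test_perfect_classifier_truncates_at_one(self):
        c = ConfusionCounts(tp=20, fp=0, fn=0, tn=30)
        lo, hi = rs.auc_interval(c)
        assert hi == 1.0
        assert rs.point_metrics(c).auc == 1.0

    def test_hanley_mcneil_uses_q_moments(self):
        c = ConfusionCounts(tp=35, fp=7, fn=13, tn=112)
        a = (35 / 48 + 112 / 119) / 2
        q1, q2 = a / (2 - a), 2 * a * a / (1 + a)
        var = (a * (1 - a) + 47 * (q1 - a * a) + 118 * (q2 - a * a)) / (48 * 119)
        lo, hi = rs.auc_interval(c, IntervalMethod(auc_method="hanley_mcneil"))
        assert hi - lo == pytest.approx(2 * 1.959963984540054 * math.sqrt(var), rel=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rs.auc_interval(ConfusionCounts(tp=0, fp=3, fn=0, tn=7))


class TestWilson:
    @pytest.mark.parametrize(
        "k,n,printed",
        [(35, 48, (59.0, 83.4)), (112, 119, (88.4, 97.1))],
    )
    def test_printed_cis_reproduced(self, k, n, printed):
        lo, hi = rs.wilson_interval(k, n)
        assert (round_half_up(100 * lo, 1), round_half_up(100 * hi, 1)) == printed

    def test_zero_successes_closed_form(self):
        lo, hi = rs.wilson_interval(0, 10)
        z = 1.959963984540054
        assert lo == 0.0
        assert hi == pytest.approx(z * z / (10 + z * z), rel=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 50), st.integers(1, 50))
    def test_matches_closed_form(self, k, n):
        k = min(k, n)
        z = 1.959963984540054
        p = k / n
        center = (p + z * z / (2 * n)) / (1 + z * z / n)
        half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / (1 + z * z / n)
        lo, hi = rs.wilson_interval(k, n)
        assert lo == pytest.approx(center - half, abs=1e-10)
        assert hi == pytest.approx(center + half, abs=1e-10)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rs.wilson_interval(0, 0)


class TestConfusion:
    def test_cross_tabulation(self):
        p = [PredictedLabel.NON_RESECTABLE, PredictedLabel.NON_RESECTABLE,
             PredictedLabel.RESECTABLE, PredictedLabel.RESECTABLE]
        r = [ReferenceLabel.NON_RESECTABLE, ReferenceLabel.RESECTABLE,
             ReferenceLabel.NON_RESECTABLE, ReferenceLabel.RESECTABLE]
        c = rs.confusion(p, r)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_perfect_agreement_has_no_errors(self):
        p = [PredictedLabel.NON_RESECTABLE, PredictedLabel.RESECTABLE]
        r = [ReferenceLabel.NON_RESECTABLE, ReferenceLabel.RESECTABLE]
        c = rs.confusion(p, r)
        assert c.fp == c.fn == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            rs.confusion([PredictedLabel.RESECTABLE], [])

    def test_leftover_special_labels_rejected(self):
        with pytest.raises(ValueError, match="indeterminate"):
            rs.confusion([PredictedLabel.INDETERMINATE], [ReferenceLabel.RESECTABLE])
        with pytest.raises(ValueError, match="inoperable"):
            rs.confusion([PredictedLabel.RESECTABLE], [ReferenceLabel.EXCLUDED_INOPERABLE])


def test_rounding_is_half_up_not_half_even():
    assert round_half_up(72.95, 1) == 73.0
    assert round_half_up(0.8345, 3) == 0.835
    assert round_half_up(2.5) == 3.0
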