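"""Grading rules and evaluation metrics against brute-force oracles."""

import numpy as np
import pytest

from motiongrade.evaluation import (
    GradePrediction,
    evaluate,
    fit_to_shape,
    grade_report,
    predict_grade,
    stack_grade,
)
from motiongrade.nn.model import NetworkConfig, build_network
from motiongrade.volume import Volume


def _pred(scores, id=""):
    return GradePrediction.from_scores(np.asarray(scores, dtype=float), id=id)


def _consistent_scores(grade, rng=None):
    """Scores whose argmax is the given grade."""
    s = np.full(5, 0.1)
    s[grade - 1] = 0.9
    if rng is not None:
        s = np.clip(s + rng.normal(0, 0.01, 5), 0.01, 0.99)
        s[grade - 1] = max(s[grade - 1], 0.9)
    return s


# -- independent loop-based oracles -----------------------------------------


def _oracle_confusion(truths, preds):
    conf = [[0] * 5 for _ in range(5)]
    for t, p in zip(truths, preds):
        conf[t - 1][p - 1] += 1
    return conf


def _oracle_metrics(truths, preds):
    conf = _oracle_confusion(truths, preds)
    n = len(truths)
    acc = sum(conf[i][i] for i in range(5)) / n
    specs, precs = [], []
    for i in range(5):
        support = sum(conf[i])
        if support == 0:
            continue
        tp = conf[i][i]
        fp = sum(conf[r][i] for r in range(5)) - tp
        fn = support - tp
        tn = n - tp - fp - fn
        specs.append(tn / (tn + fp) if tn + fp else float("nan"))
        precs.append(tp / (tp + fp) if tp + fp else 0.0)
    return acc, float(np.nanmean(specs)), float(np.nanmean(precs))


def _oracle_auc(labels, scores):
    """Mann-Whitney U / (n_pos * n_neg), ties at half weight."""
    pos = [s for l, s in zip(labels, scores) if l]
    neg = [s for l, s in zip(labels, scores) if not l]
    if not pos or not neg:
        return None
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------


class TestPredict:
    def test_deterministic(self, small_phantom):
        m = build_network(NetworkConfig(input_shape=(16, 24, 24)))
        a = predict_grade(m, small_phantom)
        b = predict_grade(m, small_phantom)
        assert a == b

    def test_argmax_grade(self):
        assert _pred([0.9, 0.2, 0.1, 0.1, 0.1]).grade == 1
        assert _pred([0.1, 0.2, 0.1, 0.8, 0.1]).grade == 4

    def test_tie_breaks_to_lower_grade(self):
        assert _pred([0.5, 0.5, 0.1, 0.1, 0.1]).grade == 1
        assert _pred([0.1, 0.3, 0.3, 0.3, 0.1]).grade == 2

    def test_fit_to_shape_crop_and_pad(self, rng):
        data = rng.random((10, 30, 20))
        out = fit_to_shape(data, (16, 24, 24))
        assert out.shape == (16, 24, 24)
        # cropped center of the middle axis survives
        np.testing.assert_allclose(out[3:13, :, 2:22], data[:, 3:27, :])

    def test_shape_mismatch_handled_by_padding(self, rng):
        m = build_network(NetworkConfig(input_shape=(16, 24, 24)))
        vol = Volume(rng.random((20, 20, 20)))
        p = predict_grade(m, vol)
        assert 1 <= p.grade <= 5


class TestStackGrade:
    def test_most_severe_wins(self):
        assert stack_grade([1, 1, 4]) == 4

    def test_singleton(self):
        assert stack_grade([2]) == 2

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            stack_grade([])

    def test_1000_random_lists_match_max_oracle(self):
        r = np.random.default_rng(0)
        for _ in range(1000):
            lst = list(r.integers(1, 6, size=r.integers(1, 12)))
            assert stack_grade(lst) == max(lst)

    def test_concatenation_idempotence(self):
        r = np.random.default_rng(1)
        for _ in range(100):
            a = list(r.integers(1, 6, size=4))
            b = list(r.integers(1, 6, size=3))
            assert stack_grade(a + b) == max(stack_grade(a), stack_grade(b))


class TestEvaluate:
    def test_perfect_balanced(self):
        truths = [g for g in range(1, 6) for _ in range(20)]
        preds = [_pred(_consistent_scores(g)) for g in truths]
        rep = evaluate(preds, truths)
        assert rep.accuracy == 1.0
        assert rep.roc_auc == 1.0
        assert rep.specificity == 1.0 and rep.precision == 1.0
        assert np.all(np.diag(rep.confusion) == 20)

    def test_hand_computed_contingency(self):
        truths = [1, 1, 2, 2]
        predicted = [1, 2, 2, 2]
        preds = [_pred(_consistent_scores(p)) for p in predicted]
        rep = evaluate(preds, truths)
        assert rep.accuracy == 0.75
        conf = rep.confusion
        assert conf[0, 0] == 1 and conf[0, 1] == 1 and conf[1, 1] == 2
        # class-1 precision 1/1, class-2 precision 2/3; classes 3-5 unsupported
        assert rep.precision == pytest.approx((1.0 + 2 / 3) / 2)
        assert rep.zero_support_classes == [3, 4, 5]

    def test_row_percentages_sum_to_100(self, rng):
        truths = list(rng.integers(1, 6, size=60))
        preds = [_pred(_consistent_scores(int(g), rng)) for g in rng.integers(1, 6, 60)]
        rep = evaluate(preds, truths)
        sums = np.nansum(rep.confusion_pct, axis=1)
        for i, s in enumerate(sums):
            if i + 1 not in rep.zero_support_classes:
                assert s == pytest.approx(100.0, abs=1e-9)

    def test_matches_loop_oracle_1000_instances(self):
        r = np.random.default_rng(7)
        for _ in range(1000):
            n = int(r.integers(5, 25))
            truths = list(r.integers(1, 6, size=n))
            predicted = list(r.integers(1, 6, size=n))
            preds = [_pred(_consistent_scores(p)) for p in predicted]
            rep = evaluate(preds, truths)
            acc, spec, prec = _oracle_metrics(truths, predicted)
            assert rep.accuracy == pytest.approx(acc)
            assert rep.specificity == pytest.approx(spec)
            assert rep.precision == pytest.approx(prec)
            np.testing.assert_array_equal(
                rep.confusion, _oracle_confusion(truths, predicted)
            )

    def test_auc_matches_mann_whitney_oracle(self):
        r = np.random.default_rng(3)
        n = 60
        truths = list(r.integers(1, 6, size=n))
        scores = r.random((n, 5))
        preds = [GradePrediction.from_scores(s) for s in scores]
        rep = evaluate(preds, truths)
        aucs = []
        for c in range(5):
            labels = [t == c + 1 for t in truths]
            a = _oracle_auc(labels, scores[:, c])
            if a is not None and any(labels) and not all(labels):
                aucs.append(a)
        assert rep.roc_auc == pytest.approx(float(np.mean(aucs)))

    def test_null_scores_give_half_auc(self):
        r = np.random.default_rng(0)
        n = 5000
        truths = [g for g in range(1, 6) for _ in range(n // 5)]
        preds = [GradePrediction.from_scores(r.random(5)) for _ in range(n)]
        rep = evaluate(preds, truths)
        assert abs(rep.roc_auc - 0.5) <= 0.03

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate([_pred(_consistent_scores(1))], [1, 2])


class TestGradeReport:
    @pytest.fixture
    def model(self):
        return build_network(NetworkConfig(input_shape=(16, 24, 24)))

    def test_three_rows_plus_header(self, model, tmp_path, rng):
        vols = [(f"v{i}", Volume(rng.random((16, 24, 24)))) for i in range(3)]
        out = tmp_path / "report.csv"
        failures = grade_report(model, vols, str(out))
        assert failures == 0
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 4
        assert lines[0].startswith("id,grade")

    def test_multistack_applies_max_rule(self, model, tmp_path, rng):
        import csv

        vol = Volume(rng.random((48, 24, 24)))
        out = tmp_path / "stacked.csv"
        grade_report(model, [("scan", vol)], str(out), stack_slices=16)
        with open(out) as fh:
            row = list(csv.DictReader(fh))[0]
        from motiongrade.volume import StackSpec, split_into_stacks

        stacks = split_into_stacks(vol, StackSpec(slices_per_stack=16))
        grades = [predict_grade(model, s).grade for s in stacks]
        assert int(row["grade"]) == max(grades)
        assert "3 stacks" in row["rule"]

    def test_rerun_byte_identical(self, model, tmp_path, rng):
        vols = [(f"v{i}", Volume(rng.random((16, 24, 24)))) for i in range(2)]
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        grade_report(model, vols, str(p1))
        grade_report(model, vols, str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_failed_row_recorded_run_continues(self, model, tmp_path, rng):
        ok = Volume(rng.random((16, 24, 24)))
        bad = Volume(rng.random((16, 24, 24)))
        bad.data = "not an array"  # type: ignore[assignment]
        failures = grade_report(model, [("bad", bad), ("ok", ok)],
                                str(tmp_path / "r.csv"))
        assert failures == 1
        text = (tmp_path / "r.csv").read_text()
        assert "ERROR" in text and "ok" in text
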