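"""Balanced-metric arithmetic, including the shipped benchmark oracle."""

import numpy as np
import pytest
from sklearn.metrics import precision_score, recall_score

from otitext.benchmarks import benchmark_confusion_matrix, benchmark_model_metrics
from otitext.classes import OtitisClass
from otitext.corpus import GeneratorConfig, generate_corpus, keyword_oracle_classify
from otitext.evaluation import (
    ConfusionMatrix,
    accuracy,
    balanced_f1,
    balanced_precision,
    balanced_recall,
    confusion_matrix,
    error_report,
    macro_f1,
    metrics_report,
    round_half_up,
)


def random_labels(rng, n):
    classes = list(OtitisClass)
    return [classes[i] for i in rng.integers(0, 6, size=n)]


def test_diagonal_matrix_from_perfect_predictions():
    labels = random_labels(np.random.default_rng(0), 10)
    cm = confusion_matrix(labels, labels)
    assert cm.total == 10 and cm.n_misclassified == 0
    assert (cm.counts == np.diag(np.diag(cm.counts))).all()


def test_empty_inputs_rejected():
    with pytest.raises(ValueError):
        confusion_matrix([], [])
    with pytest.raises(ValueError, match="length"):
        confusion_matrix([OtitisClass.AOM], [])


def test_matrix_equals_brute_force_tally():
    rng = np.random.default_rng(1)
    pred, gold = random_labels(rng, 100), random_labels(rng, 100)
    cm = confusion_matrix(pred, gold)
    for i in range(6):
        for j in range(6):
            expected = sum(p.index == i and g.index == j for p, g in zip(pred, gold))
            assert cm.counts[i, j] == expected


def test_accuracy_extremes():
    diag = ConfusionMatrix(np.diag([3, 1, 2, 4, 1, 1]))
    assert accuracy(diag) == 100.0
    zero_diag = np.zeros((6, 6), dtype=int)
    zero_diag[0, 1] = 7
    assert accuracy(ConfusionMatrix(zero_diag)) == 0.0


def test_balanced_metrics_on_benchmark_matrix():
    cm = benchmark_confusion_matrix()
    assert cm.total == 880
    assert cm.n_misclassified == 30
    assert round_half_up(accuracy(cm)) == 96.59
    assert round_half_up(balanced_precision(cm)) == 97.03
    assert round_half_up(balanced_recall(cm)) == 93.97
    bf1 = balanced_f1(balanced_precision(cm), balanced_recall(cm))
    assert round_half_up(bf1) == 95.48


def test_macro_f1_differs_from_harmonic_balanced_f1_on_benchmark():
    # the two balanced-F1 readings disagree on the benchmark matrix, which is
    # what pins the harmonic-mean definition down
    cm = benchmark_confusion_matrix()
    assert round_half_up(macro_f1(cm)) == 95.32


def test_balanced_f1_known_pairs():
    assert round_half_up(balanced_f1(97.03, 93.97)) == 95.48
    assert round_half_up(balanced_f1(95.94, 81.26)) == 87.99
    assert balanced_f1(100.0, 100.0) == 100.0


def test_benchmark_model_rows_internally_consistent():
    df = benchmark_model_metrics()
    for _, row in df.iterrows():
        hm = balanced_f1(row["balanced_precision"], row["balanced_recall"])
        assert abs(round_half_up(hm) - row["balanced_f1"]) <= 0.01 + 1e-9


def test_diagonal_only_matrix_gives_100s():
    cm = ConfusionMatrix(np.diag([3, 1, 2, 4, 1, 1]))
    assert balanced_precision(cm) == 100.0
    assert balanced_recall(cm) == 100.0


def test_balanced_f1_identity_and_zero_convention():
    for x in (0.5, 33.3, 100.0):
        assert balanced_f1(x, x) == pytest.approx(x)
    with pytest.warns(UserWarning):
        assert balanced_f1(0.0, 0.0) == 0.0


def test_balanced_metrics_bracketed_by_per_class_extremes():
    rng = np.random.default_rng(3)
    for _ in range(20):
        counts = rng.integers(0, 20, size=(6, 6))
        counts[np.diag_indices(6)] += 1  # avoid empty rows/columns
        cm = ConfusionMatrix(counts)
        from otitext.evaluation import per_class_precision, per_class_recall

        for bal, per in (
            (balanced_precision(cm), per_class_precision(cm)),
            (balanced_recall(cm), per_class_recall(cm)),
        ):
            assert 100 * per.min() - 1e-9 <= bal <= 100 * per.max() + 1e-9
        assert accuracy(cm) <= 100.0


def test_balanced_metrics_match_sklearn_macro_average():
    rng = np.random.default_rng(4)
    pred, gold = random_labels(rng, 300), random_labels(rng, 300)
    cm = confusion_matrix(pred, gold)
    p = [c.index for c in pred]
    g = [c.index for c in gold]
    labels = list(range(6))
    # sklearn's "precision of a predicted class" corresponds to our rows
    sk_prec = precision_score(g, p, labels=labels, average="macro", zero_division=0)
    sk_rec = recall_score(g, p, labels=labels, average="macro", zero_division=0)
    assert balanced_precision(cm) == pytest.approx(100 * sk_prec, abs=1e-9)
    assert balanced_recall(cm) == pytest.approx(100 * sk_rec, abs=1e-9)


def test_empty_predicted_row_contributes_zero_with_warning():
    counts = np.zeros((6, 6), dtype=int)
    counts[0, 0] = 10
    counts[0, 5] = 2  # class 5 never predicted
    with pytest.warns(UserWarning, match="precision"):
        bp = balanced_precision(ConfusionMatrix(counts))
    assert bp < 100.0


def test_error_report_lists_off_diagonal_records_with_confounder_tags():
    corpus = generate_corpus(
        GeneratorConfig(
            n_visits=300, negation_rate=0.6, other_doctor_rate=0.0,
            atypical_term_rate=0.0, typo_rate=0.0, seed=13,
        )
    )
    preds = [keyword_oracle_classify(r) for r in corpus]
    gold = [r.gold_label for r in corpus]
    rep = error_report(corpus, preds, gold)
    cm = confusion_matrix(preds, gold)
    assert rep.n_misclassified == cm.n_misclassified
    assert rep.n_misclassified > 0
    # negation confounders must appear among the errors
    assert any("negation" in r.tags for r in rep.records)
    assert sum(rep.pair_counts.values()) == rep.n_misclassified


def test_perfect_predictions_give_empty_report(clean_corpus):
    preds = [r.gold_label for r in clean_corpus[:50]]
    rep = error_report(clean_corpus[:50], preds)
    assert rep.records == [] and rep.pair_counts == {}


def test_round_half_up_behavior():
    assert round_half_up(95.485) == 95.49
    assert round_half_up(95.4849) == 95.48
    assert round_half_up(0.005) == 0.01
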