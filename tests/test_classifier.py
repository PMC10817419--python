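"""Architecture construction, training behavior, two-stage development and
the logit-mean ensemble."""

import numpy as np
import pytest

from otitext.classes import OtitisClass
from otitext.nn import (
    ArchitectureSpec,
    TrainingConfig,
    accuracy_of,
    build_model,
    default_grid,
    default_spec,
    ensemble_predict,
    predict_logits,
    train_model,
    two_stage_develop,
)
from otitext.nn.layers import BatchNorm, Conv1D, Dense, Dropout, Embedding, GlobalAvgPool, GlobalMaxPool, ParallelConv
from otitext.nn.models import BATCH_SIZE_GRID, HIDDEN_DROPOUT_GRID


def conv_stages(net):
    return [l for l in net.layers if isinstance(l, (Conv1D, ParallelConv))]


@pytest.fixture(scope="module")
def table(encoded_clean):
    return encoded_clean[1]


@pytest.fixture(scope="module")
def encoded(encoded_clean):
    return encoded_clean[2]


def test_default_grid_matches_study_values():
    assert BATCH_SIZE_GRID == (8, 16)
    assert HIDDEN_DROPOUT_GRID == (0.5, 0.7)
    points = default_grid()
    assert {(p["batch_size"], p["hidden_dropout"]) for p in points} == {
        (8, 0.5), (8, 0.7), (16, 0.5), (16, 0.7)
    }


@pytest.mark.parametrize(
    "arch_id,n_stages,parallel",
    [(0, 0, None), (1, 1, False), (2, 2, False), (3, 1, True), (4, 2, True)],
)
def test_architecture_structure(arch_id, n_stages, parallel, table):
    tc = TrainingConfig(seed=0)
    net = build_model(default_spec(arch_id, filters=4), table, tc)
    stages = conv_stages(net)
    assert len(stages) == n_stages
    if parallel is True:
        assert all(isinstance(s, ParallelConv) and len(s.convs) == 3 for s in stages)
    if parallel is False:
        assert all(isinstance(s, Conv1D) for s in stages)
    # common parts: embedding first, 6-unit dense last
    assert isinstance(net.layers[0], Embedding)
    dense = net.layers[-1]
    assert isinstance(dense, Dense) and dense.W.value.shape[1] == 6
    # every hidden stage is followed by batch-norm then dropout
    for i, layer in enumerate(net.layers):
        if isinstance(layer, (Embedding, Conv1D, ParallelConv)):
            assert isinstance(net.layers[i + 1], BatchNorm)
            assert isinstance(net.layers[i + 2], Dropout)
    # pooling: global average for the plain embedding net, global max otherwise
    pool = net.layers[-2]
    assert isinstance(pool, GlobalAvgPool if arch_id == 0 else GlobalMaxPool)


def test_embedding_dropout_rate_is_point_two(table):
    net = build_model(default_spec(1, filters=4), table, TrainingConfig(hidden_dropout=0.7))
    drops = [l.rate for l in net.layers if isinstance(l, Dropout)]
    assert drops[0] == 0.2 and drops[1] == 0.7


def test_invalid_architecture_shapes_rejected():
    with pytest.raises(ValueError):
        ArchitectureSpec(arch_id=5)
    with pytest.raises(ValueError):
        ArchitectureSpec(arch_id=0, kernel_widths=[[3]])
    with pytest.raises(ValueError):
        ArchitectureSpec(arch_id=3, kernel_widths=[[3]])  # parallel needs > 1 kernel


def test_zero_epochs_returns_initialization_with_finite_logits(table, encoded):
    tc = TrainingConfig(max_epochs=0, seed=1)
    net = build_model(default_spec(1, filters=4), table, tc)
    before = net.snapshot()
    trained = train_model(net, encoded[:50], tc)
    after = trained.network.snapshot()
    assert all(np.array_equal(a, b) for a, b in zip(before, after))
    logits = predict_logits(trained, encoded[:10])
    assert logits.shape == (10, 6) and np.isfinite(logits).all()


def test_separable_set_reaches_perfect_training_accuracy(table, encoded):
    tc = TrainingConfig(batch_size=8, max_epochs=50, learning_rate=5e-3, seed=2)
    sub = encoded[:60]
    trained = train_model(build_model(default_spec(1, filters=8), table, tc), sub, tc)
    assert accuracy_of(trained, sub) == 1.0


def test_training_loss_best_so_far_non_increasing(table, encoded):
    tc = TrainingConfig(batch_size=16, max_epochs=8, learning_rate=3e-3, seed=3)
    trained = train_model(build_model(default_spec(0, filters=4), table, tc), encoded[:80], tc)
    losses = trained.history["train_loss"]
    best = np.minimum.accumulate(losses)
    assert (np.diff(best) <= 1e-12).all()
    assert losses[-1] < losses[0]


def test_training_deterministic_given_seed(table, encoded):
    tc = TrainingConfig(batch_size=16, max_epochs=3, seed=4)
    a = train_model(build_model(default_spec(1, filters=4), table, tc), encoded[:60], tc)
    b = train_model(build_model(default_spec(1, filters=4), table, tc), encoded[:60], tc)
    assert np.array_equal(predict_logits(a, encoded[60:80]), predict_logits(b, encoded[60:80]))


def test_predict_logits_shapes_and_determinism(table, encoded):
    tc = TrainingConfig(max_epochs=1, seed=5)
    m = train_model(build_model(default_spec(0, filters=4), table, tc), encoded[:40], tc)
    assert predict_logits(m, []).shape == (0, 6)
    two = predict_logits(m, [encoded[0], encoded[0]])
    assert two.shape == (2, 6)
    assert np.array_equal(two[0], two[1])


def test_label_mismatch_rejected(table, encoded):
    import dataclasses

    tc = TrainingConfig(max_epochs=1, seed=6)
    net = build_model(default_spec(0, filters=4), table, tc)
    unlabeled = [dataclasses.replace(encoded[0], label=None)]
    with pytest.raises(ValueError, match="label"):
        train_model(net, unlabeled, tc)


# -- ensemble algebra -------------------------------------------------------


def test_mean_of_one_matrix_is_identity():
    rng = np.random.default_rng(0)
    logits = rng.normal(size=(20, 6))
    preds, probs = ensemble_predict([logits])
    assert [p.index for p in preds] == list(logits.argmax(axis=1))
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)


def test_logit_mean_arithmetic_example():
    a = np.array([[2.0, 0, 0, 0, 0, 0]])
    b = np.array([[0, 4.0, 0, 0, 0, 0]])
    preds, _ = ensemble_predict([a, b])  # mean = [1, 2, 0, 0, 0, 0]
    assert preds[0] is OtitisClass.OTITIS_NOT_MEDIA


def test_constant_logits_give_uniform_probs_and_lowest_index_tiebreak():
    preds, probs = ensemble_predict([np.zeros((3, 6))])
    assert np.allclose(probs, 1 / 6)
    assert all(p is OtitisClass.NO_OTITIS for p in preds)


def test_argmax_invariant_under_softmax():
    rng = np.random.default_rng(1)
    mats = [rng.normal(size=(50, 6)) for _ in range(4)]
    mean = np.mean(mats, axis=0)
    preds, probs = ensemble_predict(mats)
    assert np.array_equal(probs.argmax(axis=1), mean.argmax(axis=1))
    assert [p.index for p in preds] == list(mean.argmax(axis=1))


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError, match="shape"):
        ensemble_predict([np.zeros((2, 6)), np.zeros((3, 6))])
    with pytest.raises(ValueError):
        ensemble_predict([])


# -- two-stage development --------------------------------------------------


def test_grid_of_one_returns_that_configuration(table, encoded):
    tc = TrainingConfig(max_epochs=2, seed=7)
    res = two_stage_develop(
        [default_spec(0, filters=4)],
        table,
        encoded[:80],
        encoded[80:160],
        grid=[{"batch_size": 16, "hidden_dropout": 0.5}],
        n_transfer=20,
        base_config=tc,
        seed=1,
    )
    model = res[0]["model"]
    assert model.config.batch_size == 16 and model.config.hidden_dropout == 0.5
    stages = [t["stage"] for t in res[0]["trace"]]
    assert stages == [1, 2]


def test_transfer_subset_deterministic_across_reruns(table, encoded):
    kwargs = dict(
        grid=[{"batch_size": 16, "hidden_dropout": 0.5}],
        n_transfer=30,
        base_config=TrainingConfig(max_epochs=1, seed=8),
        seed=3,
    )
    a = two_stage_develop([default_spec(0, filters=4)], table, encoded[:60], encoded[60:160], **kwargs)
    b = two_stage_develop([default_spec(0, filters=4)], table, encoded[:60], encoded[60:160], **kwargs)
    la = predict_logits(a[0]["model"], encoded[160:180])
    lb = predict_logits(b[0]["model"], encoded[160:180])
    assert np.array_equal(la, lb)


def test_validation_smaller_than_transfer_rejected(table, encoded):
    with pytest.raises(ValueError, match="n_transfer"):
        two_stage_develop(
            [default_spec(0, filters=4)], table, encoded[:60], encoded[:100],
            grid=default_grid(), n_transfer=300,
        )


def test_empty_grid_rejected(table, encoded):
    with pytest.raises(ValueError, match="grid"):
        two_stage_develop(
            [default_spec(0, filters=4)], table, encoded[:60], encoded[:100],
            grid=[], n_transfer=10,
        )
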