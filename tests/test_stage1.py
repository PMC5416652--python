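"""First-stage SVM: separable fits, linear inseparability, a hard-margin
oracle solved independently as a constrained QP, support-vector
accounting, and the percentage accuracy rate."""

import numpy as np
import pytest
from scipy.optimize import minimize

from tonguelab import (
    Stage1Label,
    TrainingSet,
    accuracy,
    count_support_vectors,
    predict_stage1,
    train_stage1,
)
from tonguelab.stage1 import LABEL_DEEP_RED, LABEL_RED_OR_LIGHT_RED, load_model, save_model


def _clouds(rng, n=20, gap=2.0):
    """Two linearly separable clouds split by the sign of x1."""
    pos = rng.normal(0, 0.5, size=(n, 2)) + [gap, 0.0]
    neg = rng.normal(0, 0.5, size=(n, 2)) - [gap, 0.0]
    X = np.vstack([pos, neg])
    y = np.array([LABEL_RED_OR_LIGHT_RED] * n + [LABEL_DEEP_RED] * n)
    return X, y


def hard_margin_oracle(X, y):
    """Solve min 1/2||w||^2 s.t. y_i (w.x_i - b) >= 1 directly (SLSQP)."""
    d = X.shape[1]

    def objective(z):
        return 0.5 * np.dot(z[:d], z[:d])

    cons = [
        {"type": "ineq", "fun": (lambda z, xi=xi, yi=yi: yi * (z[:d] @ xi - z[d]) - 1)}
        for xi, yi in zip(X, y)
    ]
    z0 = np.concatenate([(X[y > 0].mean(0) - X[y < 0].mean(0)) * 10, [0.0]])
    res = minimize(objective, z0, constraints=cons, method="SLSQP",
                   options={"maxiter": 500, "ftol": 1e-12})
    assert res.success
    return res.x[:d], res.x[d]


def test_separable_clouds_fit_perfectly(rng):
    X, y = _clouds(rng)
    model = train_stage1(TrainingSet(X=X, y=y), kernel="linear")
    preds = model.pipeline.predict(X)
    assert np.array_equal(preds, y)
    # support vectors sit nearest the separating plane
    svc = model.pipeline.named_steps["svc"]
    margins = np.abs(model.pipeline.decision_function(X))
    sv_margins = margins[svc.support_]
    non_sv = np.setdiff1d(np.arange(len(X)), svc.support_)
    assert sv_margins.max() <= margins[non_sv].min() + 1e-9


def test_xor_is_not_linearly_separable():
    X = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
    y = np.array([1, 1, -1, -1])
    model = train_stage1(TrainingSet(X=X, y=y), kernel="linear")
    acc = (model.pipeline.predict(X) == y).mean()
    assert acc <= 0.75


def test_linear_solution_matches_qp_oracle(rng):
    """With a hard margin (huge C), the fitted plane equals the
    max-margin plane solved independently as a constrained QP."""
    X, y = _clouds(rng, n=8)
    model = train_stage1(TrainingSet(X=X, y=y), kernel="linear", C=1e6,
                         standardize=False)
    w, b = hard_margin_oracle(X, y)
    got = model.pipeline.decision_function(X)
    expected = X @ w - b
    # agreement is limited by the SMO solver's working tolerance
    assert np.allclose(got, expected, atol=5e-3)


@pytest.mark.parametrize("kernel", ["linear", "rbf", "polynomial", "quadratic"])
def test_prediction_sides_and_determinism(rng, kernel):
    X, y = _clouds(rng)
    m1 = train_stage1(TrainingSet(X=X, y=y), kernel=kernel, seed=0)
    m2 = train_stage1(TrainingSet(X=X, y=y), kernel=kernel, seed=0)
    assert m1.support_vector_count == m2.support_vector_count
    assert predict_stage1(m1, X[0]) is Stage1Label.RED_OR_LIGHT_RED
    assert predict_stage1(m1, X[-1]) is Stage1Label.DEEP_RED
    assert predict_stage1(m1, X) == predict_stage1(m2, X)


def test_two_point_training_set_has_two_support_vectors():
    ts = TrainingSet(X=np.array([[0.0, 0.0], [1.0, 1.0]]), y=np.array([-1, 1]))
    model = train_stage1(ts, kernel="linear")
    assert count_support_vectors(model) == 2


def test_wide_separation_gives_sparse_support(rng):
    X, y = _clouds(rng, n=50, gap=5.0)
    model = train_stage1(TrainingSet(X=X, y=y), kernel="linear", C=1.0)
    assert count_support_vectors(model) < len(X) / 3


def test_removing_a_non_support_vector_leaves_the_plane_unchanged(rng):
    X, y = _clouds(rng, n=10, gap=3.0)
    model = train_stage1(TrainingSet(X=X, y=y), kernel="linear", C=1e3,
                         standardize=False)
    svc = model.pipeline.named_steps["svc"]
    non_sv = np.setdiff1d(np.arange(len(X)), svc.support_)
    keep = np.delete(np.arange(len(X)), non_sv[0])
    reduced = train_stage1(TrainingSet(X=X[keep], y=y[keep]), kernel="linear",
                           C=1e3, standardize=False)
    grid = rng.uniform(-4, 4, size=(50, 2))
    assert np.allclose(model.pipeline.decision_function(grid),
                       reduced.pipeline.decision_function(grid), atol=1e-6)


def test_single_class_and_nan_inputs_rejected():
    with pytest.raises(ValueError):
        train_stage1(TrainingSet(X=np.ones((4, 2)), y=np.ones(4)))
    X = np.ones((4, 2)); X[0, 0] = np.nan
    with pytest.raises(ValueError):
        train_stage1(TrainingSet(X=X, y=np.array([1, 1, -1, -1])))
    with pytest.raises(ValueError):
        TrainingSet(X=np.ones((3, 2)), y=np.ones(4))


def test_dimension_mismatch_rejected(rng):
    X, y = _clouds(rng)
    model = train_stage1(TrainingSet(X=X, y=y))
    with pytest.raises(ValueError):
        predict_stage1(model, np.zeros(5))


def test_accuracy_formula_examples():
    preds = ["red_or_light_red"] * 90 + ["deep_red"] * 10 + ["deep_red"] * 98 + ["red_or_light_red"] * 2
    truth = ["red_or_light_red"] * 100 + ["deep_red"] * 100
    res = accuracy(preds, truth)
    assert res.accuracy_pct == pytest.approx(94.0)
    assert res.n_correct == {"deep_red": 98, "red_or_light_red": 90}
    assert res.N == 200
    perfect = accuracy(truth, truth)
    assert perfect.accuracy_pct == 100.0


def test_accuracy_matches_counting_loop(rng):
    labels = np.array(["a", "b", "c"])
    preds = labels[rng.integers(0, 3, 200)]
    truth = labels[rng.integers(0, 3, 200)]
    res = accuracy(preds, truth)
    count = sum(1 for p, t in zip(preds, truth) if p == t)
    assert res.accuracy_pct == pytest.approx(100.0 * count / 200)
    assert res.confusion.to_numpy().sum() == res.N == 200
    assert sum(res.n_correct.values()) == count


def test_accuracy_input_validation():
    with pytest.raises(ValueError):
        accuracy(["a"], ["a", "b"])
    with pytest.raises(ValueError):
        accuracy([], [])


def test_model_round_trips_through_disk(rng, tmp_path):
    X, y = _clouds(rng)
    model = train_stage1(TrainingSet(X=X, y=y))
    path = tmp_path / "stage1.model"
    save_model(model, path)
    back = load_model(path)
    assert back.kernel == model.kernel
    assert back.support_vector_count == model.support_vector_count
    assert predict_stage1(back, X) == predict_stage1(model, X)
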