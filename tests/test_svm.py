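import numpy as np
import pytest

from oracles import qp_primal_objective
from painmvpa.svm import (
    DecisionResult,
    LinearModel,
    SVMError,
    decide,
    decide_batch,
    objective,
    train,
)


@pytest.fixture(scope="module")
def pair_1d():
    return np.array([[-1.0], [1.0]]), np.array([-1, 1])


def test_hard_margin_pair_closed_form(pair_1d):
    X, y = pair_1d
    model = train(X, y, c_param=10)
    assert model.weights[0] == pytest.approx(1.0, abs=1e-8)
    assert model.bias == pytest.approx(0.0, abs=1e-8)
    assert objective(model, X, y) == pytest.approx(0.5, abs=1e-8)


def test_flipped_labels_flip_the_solution(pair_1d):
    X, y = pair_1d
    model = train(X, -y, c_param=10)
    assert model.weights[0] == pytest.approx(-1.0, abs=1e-8)
    assert model.bias == pytest.approx(0.0, abs=1e-8)


def test_zero_model_objective_is_total_hinge(pair_1d):
    X, y = pair_1d
    zero = LinearModel(weights=[0.0], bias=0.0, c_param=10)
    assert objective(zero, X, y) == pytest.approx(20.0)


def test_separable_toy_set_perfectly_classified():
    rng = np.random.default_rng(0)
    X = np.r_[rng.normal(-3, 0.5, (10, 2)), rng.normal(3, 0.5, (10, 2))]
    y = np.r_[-np.ones(10), np.ones(10)].astype(int)
    model = train(X, y, c_param=10)
    pred = [decide(model, row).predicted_label for row in X]
    assert np.array_equal(pred, y)


def test_objective_matches_qp_oracle_on_random_instances():
    rng = np.random.default_rng(3)
    for _ in range(8):
        n = int(rng.integers(4, 21))
        d = int(rng.integers(1, 4))
        X = rng.normal(size=(n, d))
        y = np.where(rng.random(n) < 0.5, -1, 1)
        if len(np.unique(y)) < 2:
            y[0] = -y[0]
        mine = objective(train(X, y, c_param=10), X, y)
        oracle = qp_primal_objective(X, y, 10.0)
        assert mine == pytest.approx(oracle, rel=1e-6)


def test_trained_objective_beats_perturbations():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(12, 3))
    y = np.where(rng.random(12) < 0.5, -1, 1)
    y[:2] = [-1, 1]
    model = train(X, y, c_param=10)
    base = objective(model, X, y)
    for _ in range(20):
        perturbed = LinearModel(
            weights=model.weights + rng.normal(0, 0.1, 3),
            bias=model.bias + rng.normal(0, 0.1),
            c_param=10,
        )
        assert objective(perturbed, X, y) >= base - 1e-9


def test_agreement_with_reference_solver():
    """Independent cross-check against libsvm (scikit-learn)."""
    from sklearn.svm import SVC

    rng = np.random.default_rng(9)
    X = rng.normal(size=(30, 4))
    y = np.where(X[:, 0] + 0.5 * rng.normal(size=30) > 0, 1, -1)
    mine = train(X, y, c_param=10)
    ref = SVC(kernel="linear", C=10, tol=1e-8, max_iter=1_000_000).fit(X, y)
    ref_model = LinearModel(ref.coef_.ravel(), ref.intercept_[0], 10)
    assert objective(mine, X, y) == pytest.approx(objective(ref_model, X, y), rel=1e-5)
    assert np.allclose(mine.weights, ref_model.weights, atol=1e-4)


def test_row_permutation_invariance():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(16, 3))
    y = np.where(rng.random(16) < 0.5, -1, 1)
    y[:2] = [-1, 1]
    model = train(X, y)
    perm = rng.permutation(16)
    shuffled = train(X[perm], y[perm])
    assert np.allclose(model.weights, shuffled.weights, atol=1e-6)
    assert model.bias == pytest.approx(shuffled.bias, abs=1e-6)


def test_hard_margin_scale_covariance():
    rng = np.random.default_rng(13)
    X = np.r_[rng.normal(-2, 0.3, (8, 2)), rng.normal(2, 0.3, (8, 2))]
    y = np.r_[-np.ones(8), np.ones(8)].astype(int)
    w1 = train(X, y, c_param=1e6).weights
    w2 = train(4.0 * X, y, c_param=1e6).weights
    assert np.allclose(w2, w1 / 4.0, rtol=1e-5)


def test_decision_values_and_tie_rule():
    model = LinearModel(weights=[1.0], bias=0.0, c_param=10)
    d = decide(model, [2.0])
    assert d.decision_value == 2.0
    assert d.predicted_label == 1
    assert d.distance == 2.0
    assert d.distance_functional == 2.0
    # on the hyperplane: the conservative call is non-painful
    assert decide(model, [0.0]).predicted_label == -1
    batch = decide_batch(model, [[-0.5], [0.5]])
    assert [b.predicted_label for b in batch] == [-1, 1]


def test_geometric_vs_functional_distance():
    model = LinearModel(weights=[3.0, 4.0], bias=0.0, c_param=10)
    d = decide(model, [1.0, 1.0])
    assert d.distance_functional == pytest.approx(7.0)
    assert d.distance == pytest.approx(7.0 / 5.0)


@pytest.mark.parametrize(
    "bad_call",
    [
        lambda: train(np.array([[1.0], [2.0]]), np.array([1, 1])),
        lambda: train(np.array([[1.0], [1.0]]), np.array([1, -1])),
        lambda: train(np.array([[np.nan], [1.0]]), np.array([1, -1])),
        lambda: decide(LinearModel([1.0, 2.0], 0.0), [1.0]),
        lambda: decide(LinearModel([0.0], 0.0), [1.0]),
    ],
)
def test_contract_violations_raise(bad_call):
    with pytest.raises(SVMError):
        bad_call()


def test_model_serialization_round_trip(tmp_path):
    model = LinearModel(weights=np.array([0.25, -1.5, 3.0]), bias=-0.125, c_param=10)
    model.save(tmp_path / "model")
    back = LinearModel.load(tmp_path / "model")
    assert np.array_equal(back.weights, model.weights)
    assert back.bias == model.bias
    assert back.c_param == model.c_param
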