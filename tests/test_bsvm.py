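"""Biased SVM: kernels, SMO solver vs independent oracles, grid search."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize

from idtp.bsvm import (
    BSVMConfig,
    BSVMError,
    GridSpec,
    dual_objective,
    fit_bsvm,
    grid_search,
    heuristic_ratio,
    kernel_eval,
    kernel_matrix,
    predict,
    score_config,
)
from idtp.feature_table import preprocess
from idtp.synthsim import SimConfig, simulate_dataset


def qp_dual_oracle(K, y, C):
    """Dense generic QP solve of the biased-SVM dual (SLSQP)."""
    n = len(y)
    y = y.astype(float)

    def fun(a):
        return -(a.sum() - 0.5 * (a * y) @ K @ (a * y))

    def jac(a):
        return -(np.ones(n) - y * (K @ (a * y)))

    res = minimize(
        fun, np.zeros(n), jac=jac,
        bounds=[(0.0, c) for c in C],
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP", options={"ftol": 1e-14, "maxiter": 2000},
    )
    assert res.success, res.message
    return res.x, -res.fun


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def test_kernel_examples():
    rbf = BSVMConfig(kernel="rbf", gamma=1.0)
    assert kernel_eval([1.0, 2.0], [1.0, 2.0], rbf) == pytest.approx(1.0)
    assert kernel_eval([0.0], [1.0], rbf) == pytest.approx(np.exp(-1.0))
    lin = BSVMConfig(kernel="linear")
    assert kernel_eval([1.0, 2.0], [3.0, -1.0], lin) == pytest.approx(1.0)
    with pytest.raises(BSVMError):
        kernel_eval([1.0], [1.0, 2.0], rbf)


@given(st.integers(0, 1000))
def test_kernel_symmetry(seed):
    gen = np.random.default_rng(seed)
    a, b = gen.normal(size=3), gen.normal(size=3)
    for config in (BSVMConfig(kernel="rbf", gamma=0.7), BSVMConfig(kernel="linear")):
        assert kernel_eval(a, b, config) == pytest.approx(kernel_eval(b, a, config))


def test_config_validation():
    with pytest.raises(BSVMError):
        BSVMConfig(kernel="rbf", gamma=None)
    with pytest.raises(BSVMError):
        BSVMConfig(kernel="linear", gamma=1.0)
    with pytest.raises(BSVMError):
        BSVMConfig(kernel="rbf", gamma=1.0, C_plus=0.0)


# ---------------------------------------------------------------------------
# solver correctness
# ---------------------------------------------------------------------------

def test_symmetric_separable_pair():
    X = np.array([[-1.0], [1.0]])
    y = np.array([-1, 1])
    config = BSVMConfig(kernel="linear", C_plus=1000.0, C_minus=1000.0)
    model = fit_bsvm(X, y, config, tol=1e-8)
    decision, labels = predict(model, X)
    np.testing.assert_allclose(decision, [-1.0, 1.0], atol=1e-6)
    np.testing.assert_array_equal(labels, y)
    assert model.n_support == 2


@pytest.mark.parametrize("seed", range(6))
def test_dual_matches_dense_qp_oracle(seed):
    gen = np.random.default_rng(seed)
    n = int(gen.integers(6, 31))
    X = gen.normal(size=(n, 3))
    y = np.where(gen.random(n) < 0.4, 1, -1)
    if len(set(y)) < 2:
        y[0] = -y[0]
    config = BSVMConfig(kernel="rbf", gamma=float(gen.uniform(0.2, 2.0)),
                        C_plus=float(gen.uniform(1, 20)), C_minus=float(gen.uniform(0.2, 5)))
    model = fit_bsvm(X, y, config, tol=1e-8)
    K = kernel_matrix(X, X, config)
    C = np.where(y == 1, config.C_plus, config.C_minus)
    _, obj_oracle = qp_dual_oracle(K, y, C)
    assert model.dual_objective_value == pytest.approx(obj_oracle, abs=1e-6)


def test_six_point_fixture_against_qp_oracle():
    X = np.array([[0.0, 0.0], [1.0, 0.2], [0.2, 1.0],
                  [2.5, 2.5], [3.0, 2.0], [2.0, 3.0]])
    y = np.array([-1, -1, -1, 1, 1, 1])
    config = BSVMConfig(kernel="rbf", gamma=1.0, C_plus=10.0, C_minus=1.0)
    model = fit_bsvm(X, y, config, tol=1e-8)
    K = kernel_matrix(X, X, config)
    C = np.where(y == 1, config.C_plus, config.C_minus)
    alpha_oracle, obj_oracle = qp_dual_oracle(K, y, C)
    assert model.dual_objective_value == pytest.approx(obj_oracle, abs=1e-6)
    # decision values agree with the oracle's (offset from its free SVs)
    free = (alpha_oracle > 1e-8) & (alpha_oracle < C - 1e-8)
    g = (alpha_oracle * y) @ K
    b_oracle = float(np.mean(y[free] - g[free]))
    decision, _ = predict(model, X)
    np.testing.assert_allclose(decision, g + b_oracle, atol=1e-5)


@pytest.mark.parametrize("seed", range(4))
def test_kkt_conditions_on_random_fits(seed):
    gen = np.random.default_rng(100 + seed)
    n = int(gen.integers(10, 40))
    X = gen.normal(size=(n, 4))
    y = np.where(gen.random(n) < 0.5, 1, -1)
    if len(set(y)) < 2:
        y[0] = -y[0]
    config = BSVMConfig(kernel="rbf", gamma=0.5, C_plus=8.0, C_minus=2.0)
    model = fit_bsvm(X, y, config, tol=1e-5)
    # equality constraint held exactly by construction
    assert abs(np.sum(model.alpha * y)) < 1e-8
    # per-class box constraints
    C = np.where(y == 1, config.C_plus, config.C_minus)
    assert np.all(model.alpha >= -1e-12)
    assert np.all(model.alpha <= C + 1e-12)
    # residual below solver tolerance (with float headroom)
    assert model.kkt_residual <= 1e-5 * 10


def test_symmetric_penalties_match_reference_svm():
    sklearn = pytest.importorskip("sklearn.svm")
    gen = np.random.default_rng(3)
    X = gen.normal(size=(40, 3))
    y = np.where(X[:, 0] + 0.3 * gen.normal(size=40) > 0, 1, -1)
    if len(set(y)) < 2:
        y[0] = -y[0]
    config = BSVMConfig(kernel="rbf", gamma=0.8, C_plus=2.5, C_minus=2.5)
    model = fit_bsvm(X, y, config, tol=1e-8)
    ref = sklearn.SVC(C=2.5, kernel="rbf", gamma=0.8, tol=1e-8).fit(X, y)
    mine, _ = predict(model, X)
    np.testing.assert_allclose(mine, ref.decision_function(X), atol=1e-6)


def test_asymmetric_penalties_match_weighted_reference_svm():
    sklearn = pytest.importorskip("sklearn.svm")
    gen = np.random.default_rng(4)
    X = gen.normal(size=(50, 3))
    y = np.where(gen.random(50) < 0.3, 1, -1)
    config = BSVMConfig(kernel="rbf", gamma=0.6, C_plus=7.0, C_minus=1.5)
    model = fit_bsvm(X, y, config, tol=1e-8)
    ref = sklearn.SVC(C=1.0, kernel="rbf", gamma=0.6, tol=1e-8)
    ref.fit(X, y, sample_weight=np.where(y == 1, 7.0, 1.5))
    mine, _ = predict(model, X)
    np.testing.assert_allclose(mine, ref.decision_function(X), atol=1e-6)


def test_free_support_vectors_sit_on_margin():
    gen = np.random.default_rng(7)
    X = gen.normal(size=(30, 2))
    y = np.where(X[:, 0] > 0, 1, -1)
    X[:, 0] += 0.3 * gen.normal(size=30)  # overlap
    config = BSVMConfig(kernel="rbf", gamma=1.0, C_plus=5.0, C_minus=5.0)
    model = fit_bsvm(X, y, config, tol=1e-8)
    C = np.where(y == 1, config.C_plus, config.C_minus)
    free = (model.alpha > 1e-8) & (model.alpha < C - 1e-8)
    decision, _ = predict(model, X)
    np.testing.assert_allclose(np.abs(decision[free]), 1.0, atol=1e-5)


def test_single_class_input_rejected():
    with pytest.raises(BSVMError):
        fit_bsvm(np.zeros((3, 2)), np.array([1, 1, 1]), BSVMConfig(kernel="linear"))


def test_recall_non_decreasing_in_penalty_ratio():
    """Raising C+ at fixed C- on an overlapping imbalanced set recovers
    more positives, never fewer."""
    gen = np.random.default_rng(11)
    X = np.vstack([gen.normal(1.0, 1.0, size=(10, 2)), gen.normal(-1.0, 1.0, size=(100, 2))])
    y = np.array([1] * 10 + [-1] * 100)
    recalls = []
    for ratio in (1.0, 3.0, 10.0, 30.0):
        config = BSVMConfig(kernel="rbf", gamma=0.5, C_plus=ratio, C_minus=1.0)
        model = fit_bsvm(X, y, config, tol=1e-5)
        _, pred = predict(model, X)
        recalls.append(np.mean(pred[:10] == 1))
    assert all(b >= a - 1e-12 for a, b in zip(recalls, recalls[1:]))


def test_pu_consistency_low_contamination():
    """With alpha <= 0.05 and well-separated classes, treating unlabeled
    as negative still recovers >= 90% of the hidden positives."""
    ds = simulate_dataset(SimConfig(n_pos=80, n_unl=600, alpha=0.05, effect_size=3.0,
                                    n_continuous=10, nominal_spec=(2,),
                                    informative_fraction=1.0, seed=0))
    fm = preprocess(ds.table)
    y = fm.y_pm
    config = BSVMConfig(kernel="rbf", gamma=0.05,
                        C_plus=heuristic_ratio(80, 600), C_minus=1.0)
    model = fit_bsvm(fm.values, y, config, tol=1e-3)
    _, pred = predict(model, fm.values)
    hidden = np.array([
        ds.hidden_truth[r] == 1 and lab == "unlabeled"
        for r, lab in zip(fm.row_ids, fm.row_labels)
    ])
    assert hidden.sum() > 0
    assert np.mean(pred[hidden] == 1) >= 0.9


# ---------------------------------------------------------------------------
# heuristic and grid search
# ---------------------------------------------------------------------------

def test_heuristic_ratio():
    assert heuristic_ratio(10, 10) == pytest.approx(1.0)
    assert heuristic_ratio(517, 5376) == pytest.approx(10.398, abs=1e-3)
    assert heuristic_ratio(100, 500) > heuristic_ratio(200, 500)
    with pytest.raises(BSVMError):
        heuristic_ratio(0, 5)


@pytest.fixture
def small_pu_data():
    gen = np.random.default_rng(2)
    X = np.vstack([gen.normal(1.5, 1.0, size=(15, 2)), gen.normal(-1.0, 1.0, size=(60, 2))])
    y = np.array([1] * 15 + [-1] * 60)
    return X, y


def test_grid_single_candidate_returned(small_pu_data):
    X, y = small_pu_data
    grid = GridSpec(gamma_values=(1.0,), C_minus_values=(1.0,), criterion="train_f1")
    best, table = grid_search(X, y, grid, seed=0)
    assert best.gamma == 1.0 and best.C_minus == 1.0
    assert len(table) == 1


def test_grid_matches_independent_exhaustive_loop(small_pu_data):
    X, y = small_pu_data
    grid = GridSpec(gamma_values=(0.5, 2.0), C_minus_values=(0.5, 2.0),
                    criterion="train_f1")
    best, table = grid_search(X, y, grid, seed=0)
    # independent re-evaluation of every cell
    scores = {}
    for gamma in (0.5, 2.0):
        for cm in (0.5, 2.0):
            config = BSVMConfig(kernel="rbf", gamma=gamma,
                                C_plus=cm * heuristic_ratio(15, 60), C_minus=cm)
            scores[(gamma, cm)] = score_config(X, y, config, criterion="train_f1", seed=0)
    best_score = max(scores.values())
    assert scores[(best.gamma, best.C_minus)] == pytest.approx(best_score)
    for row in table.itertuples():
        assert row.score == pytest.approx(scores[(row.gamma, row.C_minus)])
    # deterministic tie-break: first cell in (gamma asc, C- asc) order among maxima
    winners = [k for k, v in sorted(scores.items()) if v == pytest.approx(best_score)]
    assert (best.gamma, best.C_minus) == winners[0]


def test_ratio_locked_grid_satisfies_heuristic(small_pu_data):
    X, y = small_pu_data
    grid = GridSpec(gamma_values=(1.0,), C_minus_values=(0.5, 1.0, 2.0),
                    ratio_locked=True, criterion="train_f1")
    _, table = grid_search(X, y, grid, seed=0)
    for row in table.itertuples():
        assert row.C_plus / row.C_minus == pytest.approx(heuristic_ratio(15, 60))
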