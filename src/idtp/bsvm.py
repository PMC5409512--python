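"""Biased support vector machine for positive-unlabeled classification.

The biased SVM is a soft-margin kernel SVM whose slack penalty differs
by class: C+ for the labeled positives and C- for the unlabeled records
treated as negatives.  Choosing C+ >> C- makes margin violations on
positives expensive, biasing the decision surface toward recalling the
positive class even though the "negative" side is contaminated by
hidden positives.  The primal problem is

    min 1/2 w'w + C+ sum_{i in P} zeta_i + C- sum_{i in U} zeta_i
    s.t. y_i (w'phi(x_i) + b) >= 1 - zeta_i,  zeta_i >= 0,

solved here in the dual by sequential minimal optimization (SMO):
pairwise coordinate ascent on alpha with per-class box constraints
alpha_i in [0, C_{class(i)}] and the equality sum alpha_i y_i = 0
maintained exactly by construction.

A useful heuristic to reduce the (C+, C-) search space is the balance
constraint C+ |P| = C- |N|, which equalizes the total penalty budget of
the two classes; it is exposed via :func:`heuristic_ratio` and the
``ratio_locked`` grid mode but never enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import f1_positive
from .splitting import stratified_kfold


class BSVMError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    """SMO failed to satisfy the KKT conditions within the pass budget."""


# ---------------------------------------------------------------------------
# configuration and kernels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BSVMConfig:
    kernel: str = "rbf"
    gamma: float | None = None  # rbf width; required iff kernel == "rbf"
    C_plus: float = 1.0
    C_minus: float = 1.0

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear"):
            raise BSVMError(f"kernel must be 'rbf' or 'linear', got {self.kernel!r}")
        if self.kernel == "rbf":
            if self.gamma is None or self.gamma <= 0:
                raise BSVMError("rbf kernel requires gamma > 0")
        elif self.gamma is not None:
            raise BSVMError("gamma is only meaningful for the rbf kernel")
        if self.C_plus <= 0 or self.C_minus <= 0:
            raise BSVMError("penalties C_plus and C_minus must be strictly positive")


def kernel_matrix(X1: np.ndarray, X2: np.ndarray, config: BSVMConfig) -> np.ndarray:
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise BSVMError(f"dimension mismatch: {X1.shape[1]} vs {X2.shape[1]}")
    if config.kernel == "linear":
        return X1 @ X2.T
    sq = (
        np.sum(X1 * X1, axis=1)[:, None]
        + np.sum(X2 * X2, axis=1)[None, :]
        - 2.0 * (X1 @ X2.T)
    )
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-config.gamma * sq)


def kernel_eval(x1: Sequence[float], x2: Sequence[float], config: BSVMConfig) -> float:
    """Kernel value of one pair: rbf exp(-gamma ||x1-x2||^2) or dot product."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise BSVMError(f"dimension mismatch: {x1.shape} vs {x2.shape}")
    return float(kernel_matrix(x1[None, :], x2[None, :], config)[0, 0])


def dual_objective(alpha: np.ndarray, y: np.ndarray, K: np.ndarray) -> float:
    """SVM dual objective sum(alpha) - 1/2 (alpha y)' K (alpha y)."""
    ay = alpha * y
    return float(np.sum(alpha) - 0.5 * ay @ K @ ay)


# ---------------------------------------------------------------------------
# SMO solver
# ---------------------------------------------------------------------------

_STEP_EPS = 1e-12


class _SMOState:
    def __init__(self, K: np.ndarray, y: np.ndarray, C: np.ndarray, tol: float,
                 rng: np.random.Generator):
        self.K = K
        self.y = y.astype(float)
        self.C = C
        self.tol = tol
        self.rng = rng
        n = len(y)
        self.alpha = np.zeros(n)
        self.b = 0.0
        # error cache E_i = f(x_i) - y_i; with alpha = 0, b = 0: f = 0
        self.E = -self.y.copy()
        self.n_steps = 0

    def take_step(self, i1: int, i2: int) -> bool:
        if i1 == i2:
            return False
        K, y, C, alpha = self.K, self.y, self.C, self.alpha
        a1, a2 = alpha[i1], alpha[i2]
        y1, y2 = y[i1], y[i2]
        E1, E2 = self.E[i1], self.E[i2]
        s = y1 * y2
        if s < 0:
            L = max(0.0, a2 - a1)
            H = min(C[i2], C[i1] + a2 - a1)
        else:
            L = max(0.0, a1 + a2 - C[i1])
            H = min(C[i2], a1 + a2)
        if L >= H:
            return False
        k11, k12, k22 = K[i1, i1], K[i1, i2], K[i2, i2]
        eta = k11 + k22 - 2.0 * k12
        if eta > 0:
            a2_new = a2 + y2 * (E1 - E2) / eta
            a2_new = min(max(a2_new, L), H)
        else:
            # flat or concave direction: the dual gain along the feasible
            # line is W(t) = y2 (E1-E2) t - eta t^2 / 2, maximal at an end
            def gain(t: float) -> float:
                return y2 * (E1 - E2) * t - 0.5 * eta * t * t

            gain_L, gain_H = gain(L - a2), gain(H - a2)
            if max(gain_L, gain_H) <= _STEP_EPS:
                return False
            a2_new = L if gain_L > gain_H else H
        if abs(a2_new - a2) < _STEP_EPS * (a2_new + a2 + _STEP_EPS):
            return False
        a1_new = a1 + s * (a2 - a2_new)
        a1_new = min(max(a1_new, 0.0), C[i1])

        d1 = y1 * (a1_new - a1)
        d2 = y2 * (a2_new - a2)
        b1 = self.b - E1 - d1 * k11 - d2 * k12
        b2 = self.b - E2 - d1 * k12 - d2 * k22
        if 0.0 < a1_new < C[i1]:
            b_new = b1
        elif 0.0 < a2_new < C[i2]:
            b_new = b2
        else:
            b_new = 0.5 * (b1 + b2)

        self.E += d1 * K[i1] + d2 * K[i2] + (b_new - self.b)
        alpha[i1], alpha[i2] = a1_new, a2_new
        self.b = b_new
        self.n_steps += 1
        return True

    def examine(self, i2: int) -> bool:
        y2, a2, E2 = self.y[i2], self.alpha[i2], self.E[i2]
        r2 = E2 * y2
        if not ((r2 < -self.tol and a2 < self.C[i2]) or (r2 > self.tol and a2 > 0.0)):
            return False
        non_bound = np.flatnonzero((self.alpha > 0.0) & (self.alpha < self.C))
        if len(non_bound) > 1:
            i1 = int(non_bound[np.argmax(np.abs(self.E[non_bound] - E2))])
            if self.take_step(i1, i2):
                return True
        start = self.rng.integers(len(self.alpha))
        for i1 in np.roll(non_bound, -int(start % max(len(non_bound), 1))):
            if self.take_step(int(i1), i2):
                return True
        for i1 in np.roll(np.arange(len(self.alpha)), -int(start)):
            if self.take_step(int(i1), i2):
                return True
        return False


@dataclass
class BSVMModel:
    """Fitted biased SVM: decision(x) = sum_i alpha_i y_i K(x_i, x) + b."""

    support_vectors: np.ndarray
    dual_coefficients: np.ndarray  # alpha_i * y_i per support vector
    offset: float
    config: BSVMConfig
    alpha: np.ndarray = field(repr=False, default=None)  # full training alpha
    kkt_residual: float = float("nan")
    n_steps: int = 0
    dual_objective_value: float = float("nan")

    @property
    def n_support(self) -> int:
        return len(self.support_vectors)


def fit_bsvm(
    X: np.ndarray,
    y: Sequence[int],
    config: BSVMConfig,
    tol: float = 1e-3,
    max_passes: int = 10_000,
    seed: int = 0,
) -> BSVMModel:
    """Fit the biased SVM by SMO on the dual with per-class box bounds.

    ``y`` holds +/-1 labels; under the PU convention unlabeled rows carry
    -1.  ``tol`` bounds the per-sample KKT violation at convergence;
    ``max_passes`` caps the number of sweeps over the data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise BSVMError(f"shape mismatch: X {X.shape}, y {y.shape}")
    if not np.all(np.isfinite(X)):
        raise BSVMError("training features contain non-finite values")
    if set(np.unique(y)) != {-1, 1}:
        raise BSVMError("labels must contain both classes, coded +1/-1")

    K = kernel_matrix(X, X, config)
    C = np.where(y == 1, config.C_plus, config.C_minus).astype(float)
    state = _SMOState(K, y, C, tol, np.random.default_rng(seed))

    num_changed = 0
    examine_all = True
    passes = 0
    while num_changed > 0 or examine_all:
        if passes >= max_passes:
            raise ConvergenceError(
                f"SMO did not converge within {max_passes} passes "
                f"({state.n_steps} pair updates, KKT residual "
                f"{_kkt_residual(state):.3g} > tol {tol:g})"
            )
        num_changed = 0
        if examine_all:
            for i in range(len(y)):
                num_changed += state.examine(i)
        else:
            for i in np.flatnonzero((state.alpha > 0.0) & (state.alpha < C)):
                num_changed += state.examine(int(i))
        if examine_all:
            examine_all = False
        elif num_changed == 0:
            examine_all = True
        passes += 1

    alpha = state.alpha
    # recompute the offset from the free support vectors when possible
    g = (alpha * state.y) @ K  # decision values without offset
    free = (alpha > 1e-10) & (alpha < C - 1e-10 * C)
    b = float(np.mean(state.y[free] - g[free])) if np.any(free) else state.b
    state.b = b
    state.E = g + b - state.y

    sv_mask = alpha > 1e-10
    model = BSVMModel(
        support_vectors=X[sv_mask].copy(),
        dual_coefficients=(alpha * y)[sv_mask].copy(),
        offset=b,
        config=config,
        alpha=alpha.copy(),
        kkt_residual=_kkt_residual(state),
        n_steps=state.n_steps,
        dual_objective_value=dual_objective(alpha, state.y, K),
    )
    return model


def _kkt_residual(state: _SMOState) -> float:
    """Largest per-sample violation of the dual KKT conditions."""
    yf = state.y * (state.E + state.y)  # y_i * f(x_i)
    at_zero = state.alpha <= 1e-10
    at_C = state.alpha >= state.C - 1e-10 * state.C
    viol = np.abs(yf - 1.0)  # free SVs should sit exactly on the margin
    viol[at_zero] = np.maximum(0.0, 1.0 - yf[at_zero])
    viol[at_C] = np.maximum(0.0, yf[at_C] - 1.0)
    return float(np.max(viol)) if len(viol) else 0.0


def predict(model: BSVMModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Decision values and +/-1 labels; a decision of exactly 0 maps to -1."""
    if model.support_vectors is None or len(model.support_vectors) == 0:
        raise BSVMError("model has no support vectors; was it fitted?")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.support_vectors.shape[1]:
        raise BSVMError(
            f"feature dimension {X.shape[1]} does not match training "
            f"dimension {model.support_vectors.shape[1]}"
        )
    Kx = kernel_matrix(X, model.support_vectors, model.config)
    decision = Kx @ model.dual_coefficients + model.offset
    labels = np.where(decision > 0.0, 1, -1)
    return decision, labels


def heuristic_ratio(n_pos: int, n_neg: int) -> float:
    """C+/C- ratio implied by the penalty-balance constraint C+|P| = C-|N|."""
    if n_pos <= 0 or n_neg <= 0:
        raise BSVMError("both class counts must be positive")
    return n_neg / n_pos


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Candidate grid for (gamma, C+, C-) selection.

    With ``ratio_locked`` the C+ candidates are derived from each C-
    candidate through the penalty-balance heuristic and
    ``C_plus_values`` is ignored.  ``criterion`` is the F1 of the
    positive class either on the training data itself (``train_f1``) or
    averaged over stratified folds (``cv_f1``).  Cross-validated F1 is
    the default: with a flexible kernel, training-set F1 against PU
    labels increases monotonically as the kernel narrows toward
    memorizing the labeled positives (hidden positives are scored as
    negatives), so it degenerates as a selection criterion, whereas
    held-out folds penalize exactly that regime.
    """

    gamma_values: tuple[float, ...] = (0.5, 2.0, 8.0)
    C_minus_values: tuple[float, ...] = (0.5, 1.0, 5.0)
    C_plus_values: tuple[float, ...] = ()
    ratio_locked: bool = True
    criterion: str = "cv_f1"
    cv_folds: int = 5
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.kernel == "rbf" and not self.gamma_values:
            raise BSVMError("gamma_values must be non-empty for the rbf kernel")
        if not self.C_minus_values:
            raise BSVMError("C_minus_values must be non-empty")
        if not self.ratio_locked and not self.C_plus_values:
            raise BSVMError("C_plus_values required when ratio is not locked")
        if self.criterion not in ("train_f1", "cv_f1"):
            raise BSVMError("criterion must be 'train_f1' or 'cv_f1'")
        if self.criterion == "cv_f1" and self.cv_folds < 2:
            raise BSVMError("cv_f1 needs at least 2 folds")


def _candidates(grid: GridSpec, n_pos: int, n_neg: int):
    gammas = sorted(grid.gamma_values) if grid.kernel == "rbf" else [None]
    for gamma in gammas:
        for c_minus in sorted(grid.C_minus_values):
            if grid.ratio_locked:
                c_plus_list = [c_minus * heuristic_ratio(n_pos, n_neg)]
            else:
                c_plus_list = sorted(grid.C_plus_values)
            for c_plus in c_plus_list:
                yield BSVMConfig(kernel=grid.kernel, gamma=gamma,
                                 C_plus=c_plus, C_minus=c_minus)


def score_config(
    X: np.ndarray,
    y: np.ndarray,
    config: BSVMConfig,
    criterion: str = "train_f1",
    cv_folds: int = 5,
    seed: int = 0,
    tol: float = 1e-3,
) -> float:
    """Positive-class F1 of one candidate under the chosen criterion."""
    y = np.asarray(y, dtype=int)
    if criterion == "train_f1":
        model = fit_bsvm(X, y, config, tol=tol, seed=seed)
        _, pred = predict(model, X)
        return f1_positive(y, pred)
    scores = []
    for k, test_idx in enumerate(stratified_kfold(y, cv_folds, seed)):
        mask = np.zeros(len(y), dtype=bool)
        mask[test_idx] = True
        if len(set(y[~mask])) < 2:
            continue  # degenerate fold
        model = fit_bsvm(X[~mask], y[~mask], config, tol=tol, seed=seed + k)
        _, pred = predict(model, X[mask])
        scores.append(f1_positive(y[mask], pred))
    if not scores:
        raise BSVMError("all cross-validation folds were degenerate")
    return float(np.mean(scores))


def grid_search(
    X: np.ndarray,
    y: Sequence[int],
    grid: GridSpec,
    seed: int = 0,
    tol: float = 1e-3,
) -> tuple[BSVMConfig, pd.DataFrame]:
    """Exhaustive search over the grid; argmax with deterministic ties.

    Iteration order is gamma ascending then C- ascending, and the first
    maximum wins, so ties break toward smaller parameters.  Per-cell fit
    failures are recorded (score NaN) rather than fatal unless every
    cell fails.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == -1))
    rows = []
    best: tuple[float, BSVMConfig] | None = None
    for config in _candidates(grid, n_pos, n_neg):
        try:
            score = score_config(X, y, config, grid.criterion, grid.cv_folds,
                                 seed=seed, tol=tol)
            error = ""
        except (BSVMError, ConvergenceError) as exc:
            score, error = float("nan"), str(exc)
        rows.append({
            "gamma": config.gamma, "C_plus": config.C_plus,
            "C_minus": config.C_minus, "score": score, "error": error,
        })
        if error == "" and (best is None or score > best[0]):
            best = (score, config)
    table = pd.DataFrame(rows)
    if best is None:
        raise BSVMError("every grid cell failed to fit")
    return best[1], table
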