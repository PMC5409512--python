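"""End-to-end PU retrieval experiments.

Orchestrates the full protocol: encode the property table, build the
per-variant representation (stacked auto-encoder embedding, wrapper
feature subset, or the raw encoded matrix), repeat stratified 70/30
train/test iterations with a per-iteration grid search for the biased
SVM, summarize positive-class F1/recall and negative-class precision as
mean(variance) across iterations, and retrieve the "doubtful" records:
unlabeled proteins the fitted classifier predicts as positive, i.e. the
candidate drug-target list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import bsvm as _bsvm
from .bsvm import BSVMConfig, BSVMModel, GridSpec, fit_bsvm, grid_search, heuristic_ratio, predict
from .feature_table import UNLABELED, FeatureMatrix, PropertyTable, preprocess, fit_preprocessor, transform
from .metrics import ConfusionCounts, evaluate, fbeta  # noqa: F401  (re-exported surface)
from .sae_embed import SAETrainConfig, embed, train_sae
from .splitting import stratified_split  # noqa: F401  (re-exported surface)

VARIANTS = ("sae", "wrapper", "origin")
METRICS = ("f1_dtp", "recall_dtp", "precision_ndtp")


class PipelineError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration and result containers
# ---------------------------------------------------------------------------

def default_sae_sizes(d: int) -> tuple[int, ...]:
    """Palindromic layer widths for an input of dimension d.

    The 283-dimensional encoded protein table maps to the reference
    283-140-10-140-283 stack; other widths use a 10-unit bottleneck
    (smaller for very narrow inputs) with one intermediate layer halfway
    in size.
    """
    if d == 283:
        return (283, 140, 10, 140, 283)
    bottleneck = 10 if d >= 20 else max(2, d // 2)
    hidden = max(bottleneck, (d + bottleneck) // 2)
    return (d, hidden, bottleneck, hidden, d)


@dataclass
class ExperimentConfig:
    train_fraction: float = 0.7
    grid: GridSpec = field(default_factory=GridSpec)
    fixed_params: BSVMConfig | None = None  # bypasses the grid search when set
    sae: SAETrainConfig = field(default_factory=SAETrainConfig)
    sae_sizes: tuple[int, ...] | None = None  # None -> default_sae_sizes(d)
    wrapper_min_delta: float = 1e-3
    wrapper_max_features: int | None = 10
    svm_tol: float = 1e-3
    variance_ddof: int = 0  # population variance of the per-iteration metrics
    strict_preprocess: bool = False  # fit scaling on training rows only


@dataclass
class IterationResult:
    iteration: int
    split_seed: int
    sae_seed: int
    svm_seed: int
    best_config: BSVMConfig
    train_counts: ConfusionCounts
    test_counts: ConfusionCounts
    train_metrics: dict[str, float]
    test_metrics: dict[str, float]
    doubtful_ids: list[str]
    doubtful_proportion: float


@dataclass
class ExperimentSummary:
    variant: str
    n_iterations: int
    stats: dict[tuple[str, str], tuple[float, float]]  # (split, metric) -> (mean, variance)
    mean_doubtful_proportion: float

    def mean(self, split: str, metric: str) -> float:
        return self.stats[(split, metric)][0]

    def variance(self, split: str, metric: str) -> float:
        return self.stats[(split, metric)][1]


@dataclass
class RetrievalResult:
    """Unlabeled records predicted positive: the doubtful drug-target list."""

    doubtful_ids: list[str]
    proportion: float
    decision_values: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# wrapper feature selection
# ---------------------------------------------------------------------------

def wrapper_select(
    X: np.ndarray,
    y: Sequence[int],
    seed: int = 0,
    min_delta: float = 1e-3,
    max_features: int | None = None,
    base_config: BSVMConfig | None = None,
    cv_folds: int = 5,
    tol: float = 1e-3,
) -> list[int]:
    """Sequential forward selection scored by cross-validated F1.

    Starting from the empty set, the feature whose addition maximizes
    the biased SVM's stratified 5-fold positive-class F1 is accepted
    while it improves the running score by at least ``min_delta``.
    Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[1] == 0:
        raise PipelineError("wrapper selection needs at least one feature column")
    if base_config is None:
        n_pos = int(np.sum(y == 1))
        n_neg = int(np.sum(y == -1))
        base_config = BSVMConfig(kernel="rbf", gamma=1.0,
                                 C_plus=heuristic_ratio(n_pos, n_neg), C_minus=1.0)
    selected: list[int] = []
    current = -np.inf
    limit = X.shape[1] if max_features is None else min(max_features, X.shape[1])
    while len(selected) < limit:
        best_j, best_score = -1, -np.inf
        for j in range(X.shape[1]):
            if j in selected:
                continue
            cols = selected + [j]
            try:
                score = _bsvm.score_config(
                    X[:, cols], y, base_config, criterion="cv_f1",
                    cv_folds=cv_folds, seed=seed, tol=tol,
                )
            except (_bsvm.BSVMError, _bsvm.ConvergenceError) as exc:
                warnings.warn(f"wrapper candidate {j} failed: {exc}", stacklevel=2)
                continue
            if score > best_score:
                best_j, best_score = j, score
        if best_j < 0:
            break
        improvement = best_score - current if np.isfinite(current) else np.inf
        if improvement < min_delta:
            break
        selected.append(best_j)
        current = best_score
    if not selected:
        raise PipelineError("wrapper selection accepted no feature")
    return selected


# ---------------------------------------------------------------------------
# retrieval
# ---------------------------------------------------------------------------

def retrieve_doubtful(features: FeatureMatrix, model: BSVMModel) -> RetrievalResult:
    """Doubtful drug-target candidates among the unlabeled records.

    Training- and testing-side identifications are merged by predicting
    every row of ``features`` (which spans both splits); the doubtful
    set is the unlabeled rows with predicted label +1, and the
    proportion is taken over all unlabeled rows.  Ids are sorted for
    reproducibility.
    """
    decision, labels = predict(model, features.values)
    obs = np.asarray(features.row_labels)
    unl_mask = obs == UNLABELED
    n_unl = int(unl_mask.sum())
    if n_unl == 0:
        raise PipelineError("no unlabeled records to retrieve from")
    doubtful_mask = unl_mask & (labels == 1)
    ids = sorted(np.asarray(features.row_ids)[doubtful_mask].tolist())
    decisions = {
        rid: float(val)
        for rid, val in zip(np.asarray(features.row_ids)[doubtful_mask], decision[doubtful_mask])
    }
    return RetrievalResult(
        doubtful_ids=ids,
        proportion=len(ids) / n_unl,
        decision_values=decisions,
    )


# ---------------------------------------------------------------------------
# the experiment loop
# ---------------------------------------------------------------------------

def _representation(
    fm: FeatureMatrix,
    variant: str,
    config: ExperimentConfig,
    train_idx: np.ndarray,
    sae_seed: int,
    svm_seed: int,
) -> FeatureMatrix:
    if variant == "origin":
        return fm
    if variant == "sae":
        sizes = config.sae_sizes or default_sae_sizes(fm.d)
        sae_cfg = replace(config.sae, seed=sae_seed)
        source = fm.select_rows(train_idx) if config.strict_preprocess else fm
        model = train_sae(source, sae_cfg, sizes)
        return embed(fm, model)
    if variant == "wrapper":
        y = fm.y_pm
        selected = wrapper_select(
            fm.values[train_idx], y[train_idx], seed=svm_seed,
            min_delta=config.wrapper_min_delta,
            max_features=config.wrapper_max_features, tol=config.svm_tol,
        )
        return fm.select_columns(selected)
    raise PipelineError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


def run_experiment(
    table: PropertyTable,
    variant: str = "sae",
    n_iterations: int = 10,
    config: ExperimentConfig | None = None,
    seed: int = 0,
) -> tuple[ExperimentSummary, list[IterationResult]]:
    """Repeat the full PU classification protocol ``n_iterations`` times.

    Each iteration draws a fresh stratified train/test split, builds the
    variant's representation (the auto-encoder is retrained with a fresh
    seed every iteration), selects biased-SVM parameters by grid search
    on the training split (unless ``config.fixed_params`` pins them),
    refits, and scores both splits against the observed PU labels.  The
    summary reports the mean and (population) variance of each metric
    over iterations.  Bit-reproducible given ``seed``.
    """
    if n_iterations < 1:
        raise PipelineError("n_iterations must be at least 1")
    if variant not in VARIANTS:
        raise PipelineError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    config = config or ExperimentConfig()

    master = np.random.default_rng(seed)
    iter_seeds = master.integers(0, 2**31 - 1, size=(n_iterations, 3))

    results: list[IterationResult] = []
    for it in range(n_iterations):
        split_seed, sae_seed, svm_seed = (int(s) for s in iter_seeds[it])
        labels = np.asarray(table.labels)
        train_idx, test_idx = stratified_split(labels, config.train_fraction, split_seed)

        if config.strict_preprocess:
            stats = fit_preprocessor(_subset_table(table, train_idx))
            fm = transform(table, stats)
        else:
            fm = preprocess(table)

        rep = _representation(fm, variant, config, train_idx, sae_seed, svm_seed)
        y = rep.y_pm
        X_train, y_train = rep.values[train_idx], y[train_idx]

        if config.fixed_params is not None:
            best = config.fixed_params
        else:
            best, _ = grid_search(X_train, y_train, config.grid,
                                  seed=svm_seed, tol=config.svm_tol)
        model = fit_bsvm(X_train, y_train, best, tol=config.svm_tol, seed=svm_seed)

        _, pred_train = predict(model, X_train)
        _, pred_test = predict(model, rep.values[test_idx])
        ev_train = evaluate(labels[train_idx], pred_train)
        ev_test = evaluate(labels[test_idx], pred_test)
        retrieval = retrieve_doubtful(rep, model)

        results.append(
            IterationResult(
                iteration=it,
                split_seed=split_seed,
                sae_seed=sae_seed,
                svm_seed=svm_seed,
                best_config=best,
                train_counts=ev_train["counts"],
                test_counts=ev_test["counts"],
                train_metrics={m: ev_train[m] for m in METRICS},
                test_metrics={m: ev_test[m] for m in METRICS},
                doubtful_ids=retrieval.doubtful_ids,
                doubtful_proportion=retrieval.proportion,
            )
        )

    stats: dict[tuple[str, str], tuple[float, float]] = {}
    for split in ("training", "testing"):
        for metric in METRICS:
            vals = np.asarray([
                (r.train_metrics if split == "training" else r.test_metrics)[metric]
                for r in results
            ])
            stats[(split, metric)] = (
                float(np.mean(vals)),
                float(np.var(vals, ddof=config.variance_ddof)) if len(vals) > config.variance_ddof else 0.0,
            )
    summary = ExperimentSummary(
        variant=variant,
        n_iterations=n_iterations,
        stats=stats,
        mean_doubtful_proportion=float(np.mean([r.doubtful_proportion for r in results])),
    )
    return summary, results


def _subset_table(table: PropertyTable, indices: np.ndarray) -> PropertyTable:
    return PropertyTable(schema=table.schema,
                         records=[table.records[i] for i in indices])


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def summary_frame(summaries: Sequence[ExperimentSummary]) -> pd.DataFrame:
    """Mean(variance) per variant, split and metric, one row per split."""
    rows = []
    for s in summaries:
        for split in ("training", "testing"):
            row: dict[str, object] = {"variant": s.variant, "split": split}
            for metric in METRICS:
                mean, var = s.stats[(split, metric)]
                row[f"{metric}_mean"] = mean
                row[f"{metric}_variance"] = var
            rows.append(row)
    return pd.DataFrame(rows)


def write_summary(summaries: Sequence[ExperimentSummary], path: str | Path) -> None:
    summary_frame(summaries).to_csv(path, sep="\t", index=False)


def write_iterations(results: Sequence[IterationResult], path: str | Path) -> None:
    rows = []
    for r in results:
        row: dict[str, object] = {
            "iteration": r.iteration,
            "split_seed": r.split_seed,
            "sae_seed": r.sae_seed,
            "svm_seed": r.svm_seed,
            "gamma": r.best_config.gamma,
            "C_plus": r.best_config.C_plus,
            "C_minus": r.best_config.C_minus,
            "doubtful_proportion": r.doubtful_proportion,
        }
        for split, metrics in (("training", r.train_metrics), ("testing", r.test_metrics)):
            for metric, value in metrics.items():
                row[f"{split}_{metric}"] = value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_doubtful(result: RetrievalResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tdecision_value\n")
        for rid in result.doubtful_ids:
            fh.write(f"{rid}\t{result.decision_values.get(rid, float('nan')):.6g}\n")
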