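"""Synthetic contaminated positive-unlabeled datasets.

The PU setting assumes unlabeled records are drawn from the mixture
h_u(x) = alpha h+(x) + (1 - alpha) h-(x): a fraction alpha of the
"non-target" pool are in truth hidden positives.  This module draws
mixed continuous/nominal property tables with that structure and known
hidden labels, so every downstream stage (preprocessing, embedding,
biased SVM, retrieval) can be validated against ground truth without
any external dataset.

Class-conditional forms are deliberately simple: informative continuous
properties are unit-variance Gaussians whose means differ by
``effect_size`` standard deviations between classes; informative
nominal properties tilt their state probabilities toward the first
state for positives; everything else is identically distributed in both
classes.  The default shape matches the drug-target study design this
framework targets: 517 labeled positives, 5376 unlabeled records, 31
continuous and 8 nominal properties, contamination 0.23.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .feature_table import (
    POSITIVE,
    UNLABELED,
    Property,
    PropertySchema,
    PropertyTable,
    ProteinRecord,
    write_property_table,
)
from .metrics import ConfusionCounts


class SimError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    n_pos: int = 517
    n_unl: int = 5376
    alpha: float = 0.23          # contamination fraction of the unlabeled pool
    n_continuous: int = 31
    nominal_spec: tuple[int, ...] = (2, 2, 3, 3, 4, 4, 5, 5)  # states per nominal property
    effect_size: float = 1.0     # class mean shift per informative feature, in sd units
    informative_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_unl < 1:
            raise SimError("n_pos and n_unl must be at least 1")
        if not 0.0 <= self.alpha < 1.0:
            raise SimError(f"alpha must be in [0, 1), got {self.alpha}")
        if not 0.0 <= self.informative_fraction <= 1.0:
            raise SimError("informative_fraction must be in [0, 1]")
        if any(s < 1 for s in self.nominal_spec):
            raise SimError("every nominal property needs at least one state")


@dataclass
class SimDataset:
    table: PropertyTable
    hidden_truth: Mapping[str, int]  # id -> +1 (true positive) / -1 (true negative)
    config: SimConfig

    @property
    def hidden_positive_ids(self) -> list[str]:
        return sorted(
            rid
            for rid, truth in self.hidden_truth.items()
            if truth == 1 and rid.startswith("U")
        )


def _make_schema(config: SimConfig) -> PropertySchema:
    props = [
        Property(name=f"cont_{k:02d}", kind="continuous")
        for k in range(config.n_continuous)
    ]
    for j, n_states in enumerate(config.nominal_spec):
        props.append(
            Property(
                name=f"nom_{j:02d}",
                kind="nominal",
                states=tuple(f"s{t}" for t in range(n_states)),
            )
        )
    return PropertySchema(tuple(props))


def _class_state_probs(n_states: int, effect_size: float) -> np.ndarray:
    """Positive-class state distribution: first state up-weighted by
    exp(effect_size), then renormalized (uniform when effect_size = 0)."""
    w = np.ones(n_states)
    w[0] = np.exp(effect_size)
    return w / w.sum()


def simulate_dataset(config: SimConfig | None = None) -> SimDataset:
    """Draw one contaminated PU property table with hidden ground truth.

    Labeled positives come from h+; each unlabeled record is a hidden
    positive (drawn from h+) with probability alpha and a true negative
    (from h-) otherwise.  Deterministic given ``config.seed``.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    schema = _make_schema(config)

    n_inf_cont = int(round(config.informative_fraction * config.n_continuous))
    n_inf_nom = int(round(config.informative_fraction * len(config.nominal_spec)))

    n_total = config.n_pos + config.n_unl
    hidden_unl = rng.random(config.n_unl) < config.alpha  # True = hidden positive
    is_positive = np.concatenate([
        np.ones(config.n_pos, dtype=bool), hidden_unl
    ])

    # continuous block: informative features shift the positive-class mean
    means = np.zeros((n_total, config.n_continuous))
    means[is_positive, :n_inf_cont] = config.effect_size
    cont = rng.normal(loc=means, scale=1.0)

    # nominal block: informative features tilt the positive state probabilities
    nominal_cols = []
    for j, n_states in enumerate(config.nominal_spec):
        p_neg = np.ones(n_states) / n_states
        p_pos = _class_state_probs(n_states, config.effect_size) if j < n_inf_nom else p_neg
        u = rng.random(n_total)
        cdf_pos = np.cumsum(p_pos)
        cdf_neg = np.cumsum(p_neg)
        idx = np.where(
            is_positive,
            np.searchsorted(cdf_pos, u, side="right"),
            np.searchsorted(cdf_neg, u, side="right"),
        )
        idx = np.minimum(idx, n_states - 1)
        nominal_cols.append(idx)

    records = []
    hidden_truth: dict[str, int] = {}
    for i in range(n_total):
        if i < config.n_pos:
            rid, label = f"P{i:05d}", POSITIVE
        else:
            rid, label = f"U{i - config.n_pos:05d}", UNLABELED
        values: dict[str, object] = {
            f"cont_{k:02d}": float(cont[i, k]) for k in range(config.n_continuous)
        }
        for j, n_states in enumerate(config.nominal_spec):
            values[f"nom_{j:02d}"] = f"s{nominal_cols[j][i]}"
        records.append(ProteinRecord(id=rid, label=label, values=values))
        hidden_truth[rid] = 1 if is_positive[i] else -1

    table = PropertyTable(schema=schema, records=records)
    return SimDataset(table=table, hidden_truth=hidden_truth, config=config)


def score_against_truth(
    predictions: Mapping[str, int], dataset: SimDataset
) -> dict[str, float]:
    """Confusion of predictions vs hidden truth over the unlabeled pool.

    ``predictions`` maps every unlabeled id to +/-1.  Recall is the
    fraction of hidden positives recovered; precision the fraction of
    predicted positives that are truly positive.
    """
    unl_ids = [r.id for r in dataset.table.records if r.label == UNLABELED]
    missing = [rid for rid in unl_ids if rid not in predictions]
    if missing:
        raise SimError(
            f"predictions missing for {len(missing)} unlabeled ids "
            f"(first: {missing[:3]})"
        )
    y_true = np.asarray([dataset.hidden_truth[rid] for rid in unl_ids])
    y_pred = np.asarray([int(predictions[rid]) for rid in unl_ids])
    counts = ConfusionCounts.from_predictions(y_true, y_pred)
    recall = counts.TP / (counts.TP + counts.FN) if (counts.TP + counts.FN) else 0.0
    precision = counts.TP / (counts.TP + counts.FP) if (counts.TP + counts.FP) else 0.0
    return {"recall": recall, "precision": precision, "counts": counts}


def write_simulated(dataset: SimDataset, directory: str | Path) -> dict[str, Path]:
    """Emit table CSV + schema YAML + hidden-truth TSV (kept separate so
    pipeline code cannot accidentally consume the truth)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table_path = directory / "properties.csv"
    schema_path = directory / "schema.yaml"
    truth_path = directory / "hidden_truth.tsv"
    write_property_table(dataset.table, table_path)
    dataset.table.schema.to_yaml(schema_path)
    with open(truth_path, "w") as fh:
        fh.write("id\thidden_class\n")
        for rid in dataset.table.ids:
            fh.write(f"{rid}\t{dataset.hidden_truth[rid]}\n")
    return {"table": table_path, "schema": schema_path, "truth": truth_path}
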