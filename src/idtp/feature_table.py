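"""Mixed-type protein property tables and their numeric encoding.

A property table holds one row per protein: an identifier, a PU label
(``positive`` for known drug targets, ``unlabeled`` for the contaminated
non-target pool) and a fixed set of physicochemical properties that are
either continuous (real valued) or nominal (one of a finite list of
states).  This module reads and validates such tables, z-normalizes the
continuous columns, one-hot encodes the nominal ones, and screens
individual properties for between-class distributional differences with
a two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _scipy_stats

POSITIVE = "positive"
UNLABELED = "unlabeled"
LABELS = (POSITIVE, UNLABELED)

ID_COLUMN = "id"
LABEL_COLUMN = "label"


class PropertyTableError(ValueError):
    """Raised for malformed tables, schemas or preprocessing requests."""


# ---------------------------------------------------------------------------
# schema and records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Property:
    """A single protein property: continuous, or nominal with named states."""

    name: str
    kind: str  # "continuous" | "nominal"
    states: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "nominal"):
            raise PropertyTableError(
                f"property {self.name!r}: kind must be 'continuous' or "
                f"'nominal', got {self.kind!r}"
            )
        if self.kind == "nominal":
            if len(self.states) == 0:
                raise PropertyTableError(
                    f"nominal property {self.name!r} needs at least one state"
                )
            if len(set(self.states)) != len(self.states):
                raise PropertyTableError(
                    f"nominal property {self.name!r} has duplicate states"
                )
        elif self.states:
            raise PropertyTableError(
                f"continuous property {self.name!r} must not declare states"
            )


@dataclass(frozen=True)
class PropertySchema:
    """Ordered collection of properties describing one table layout."""

    properties: tuple[Property, ...]

    def __post_init__(self) -> None:
        names = [p.name for p in self.properties]
        if len(set(names)) != len(names):
            raise PropertyTableError("property names must be unique")
        for reserved in (ID_COLUMN, LABEL_COLUMN):
            if reserved in names:
                raise PropertyTableError(
                    f"{reserved!r} is reserved and cannot be a property name"
                )

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.properties]

    @property
    def continuous(self) -> list[Property]:
        return [p for p in self.properties if p.kind == "continuous"]

    @property
    def nominal(self) -> list[Property]:
        return [p for p in self.properties if p.kind == "nominal"]

    @property
    def encoded_dim(self) -> int:
        """Width of the numeric encoding: one column per continuous
        property plus one per nominal state."""
        return len(self.continuous) + sum(len(p.states) for p in self.nominal)

    def __getitem__(self, name: str) -> Property:
        for p in self.properties:
            if p.name == name:
                return p
        raise KeyError(name)

    # -- persistence --------------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PropertySchema":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        try:
            entries = doc["properties"]
        except (TypeError, KeyError):
            raise PropertyTableError(f"{path}: expected a 'properties' list")
        props = []
        for e in entries:
            props.append(
                Property(
                    name=str(e["name"]),
                    kind=str(e["kind"]),
                    states=tuple(str(s) for s in e.get("states", []) or []),
                )
            )
        return cls(tuple(props))

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "properties": [
                {"name": p.name, "kind": p.kind}
                | ({"states": list(p.states)} if p.kind == "nominal" else {})
                for p in self.properties
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    label: str  # POSITIVE | UNLABELED
    values: Mapping[str, object]  # property name -> float | state string


@dataclass
class PropertyTable:
    """Validated protein records plus the schema they conform to."""

    schema: PropertySchema
    records: list[ProteinRecord]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise PropertyTableError(f"duplicate protein id {dup!r}")
        for r in self.records:
            if r.label not in LABELS:
                raise PropertyTableError(
                    f"record {r.id!r}: label must be one of {LABELS}, "
                    f"got {r.label!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    @property
    def n_positive(self) -> int:
        return sum(r.label == POSITIVE for r in self.records)

    @property
    def n_unlabeled(self) -> int:
        return sum(r.label == UNLABELED for r in self.records)

    def column(self, name: str) -> np.ndarray:
        """Raw values of one property across all records (object dtype for
        nominal, float for continuous)."""
        prop = self.schema[name]
        vals = [r.values[name] for r in self.records]
        if prop.kind == "continuous":
            return np.asarray(vals, dtype=float)
        return np.asarray(vals, dtype=object)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {ID_COLUMN: r.id, LABEL_COLUMN: r.label, **dict(r.values)}
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=[ID_COLUMN, LABEL_COLUMN, *self.schema.names])


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _read_raw(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".xlsx", ".xls"):
        return pd.read_excel(path, dtype=object)
    sep = "\t" if suffix in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, dtype=object)


def read_property_table(path: str | Path, schema: PropertySchema) -> PropertyTable:
    """Read a delimited-text (or XLSX) property table and validate it.

    The file must carry an ``id`` and a ``label`` column plus one column per
    schema property.  Errors name the offending row and column.
    """
    df = _read_raw(path)
    return table_from_dataframe(df, schema, source=str(path))


def table_from_dataframe(
    df: pd.DataFrame, schema: PropertySchema, source: str = "<dataframe>"
) -> PropertyTable:
    for col in (ID_COLUMN, LABEL_COLUMN, *schema.names):
        if col not in df.columns:
            raise PropertyTableError(f"{source}: missing column {col!r}")
    records = []
    for pos, (_, row) in enumerate(df.iterrows()):
        rid = str(row[ID_COLUMN])
        label = str(row[LABEL_COLUMN])
        if label not in LABELS:
            raise PropertyTableError(
                f"{source} row {pos} ({rid!r}): bad label {label!r}"
            )
        values: dict[str, object] = {}
        for prop in schema.properties:
            raw = row[prop.name]
            if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                raise PropertyTableError(
                    f"{source} row {pos} ({rid!r}): missing value for "
                    f"property {prop.name!r}"
                )
            if prop.kind == "continuous":
                try:
                    values[prop.name] = float(raw)
                except (TypeError, ValueError):
                    raise PropertyTableError(
                        f"{source} row {pos} ({rid!r}): non-numeric value "
                        f"{raw!r} for continuous property {prop.name!r}"
                    )
            else:
                state = str(raw)
                if state not in prop.states:
                    raise PropertyTableError(
                        f"{source} row {pos} ({rid!r}): unknown state "
                        f"{state!r} for property {prop.name!r} "
                        f"(expected one of {list(prop.states)})"
                    )
                values[prop.name] = state
        records.append(ProteinRecord(id=rid, label=label, values=values))
    return PropertyTable(schema=schema, records=records)


def write_property_table(table: PropertyTable, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table.to_dataframe().to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# preprocessing: z-normalization + one-hot
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreprocessStats:
    """Fitted normalization parameters.

    ``mu``/``sigma`` hold the per-property mean and standard deviation of
    each continuous property (population convention, divisor n, by
    default); ``state_order`` echoes the schema's state lists used for
    one-hot encoding.
    """

    schema: PropertySchema
    mu: Mapping[str, float]
    sigma: Mapping[str, float]
    state_order: Mapping[str, tuple[str, ...]]
    ddof: int = 0


def fit_preprocessor(table: PropertyTable, ddof: int = 0) -> PreprocessStats:
    """Estimate per-property normalization statistics over all rows.

    ``ddof=0`` (the default) uses the population standard deviation.
    A constant continuous property has zero spread, cannot be scaled, and
    raises.
    """
    if len(table) == 0:
        raise PropertyTableError("cannot fit preprocessing on an empty table")
    mu: dict[str, float] = {}
    sigma: dict[str, float] = {}
    for prop in table.schema.continuous:
        col = table.column(prop.name)
        m = float(np.mean(col))
        s = float(np.std(col, ddof=ddof))
        if s <= 0.0:
            raise PropertyTableError(
                f"continuous property {prop.name!r} is constant "
                f"(sigma = 0); it cannot be z-normalized"
            )
        mu[prop.name] = m
        sigma[prop.name] = s
    state_order = {p.name: p.states for p in table.schema.nominal}
    return PreprocessStats(
        schema=table.schema, mu=mu, sigma=sigma, state_order=state_order, ddof=ddof
    )


def zscore(x: Sequence[float] | np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Standard score (x - mu) / sigma, elementwise."""
    if sigma <= 0:
        raise PropertyTableError(f"sigma must be positive, got {sigma}")
    return (np.asarray(x, dtype=float) - mu) / sigma


def one_hot(value: str, states: Sequence[str]) -> np.ndarray:
    """Encode ``value`` as a len(states)-dimensional bit vector."""
    states = list(states)
    try:
        idx = states.index(value)
    except ValueError:
        raise PropertyTableError(
            f"state {value!r} is not among the declared states {states}"
        )
    vec = np.zeros(len(states))
    vec[idx] = 1.0
    return vec


@dataclass
class FeatureMatrix:
    """Fully numeric encoding of a property table.

    ``column_provenance`` records, per column, the source property and
    either ``"zscore"`` (continuous) or the state name (one-hot bit).
    """

    values: np.ndarray  # n x d
    column_provenance: list[tuple[str, str]]
    row_ids: list[str]
    row_labels: list[str]

    def __post_init__(self) -> None:
        n, d = self.values.shape
        if len(self.row_ids) != n or len(self.row_labels) != n:
            raise PropertyTableError("row metadata length mismatch")
        if len(self.column_provenance) != d:
            raise PropertyTableError("column provenance length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise PropertyTableError("feature matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def y_pm(self) -> np.ndarray:
        """PU labels as +/-1: positives +1, unlabeled -1."""
        return np.where(np.asarray(self.row_labels) == POSITIVE, 1, -1)

    def select_columns(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            values=self.values[:, idx].copy(),
            column_provenance=[self.column_provenance[i] for i in idx],
            row_ids=list(self.row_ids),
            row_labels=list(self.row_labels),
        )

    def select_rows(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            values=self.values[idx].copy(),
            column_provenance=list(self.column_provenance),
            row_ids=[self.row_ids[i] for i in idx],
            row_labels=[self.row_labels[i] for i in idx],
        )


def transform(table: PropertyTable, stats: PreprocessStats) -> FeatureMatrix:
    """Apply fitted z-normalization and one-hot encoding to a table.

    Columns follow schema order; a continuous property contributes one
    z-scored column, a nominal property one 0/1 column per state.
    """
    if stats.schema != table.schema:
        raise PropertyTableError("preprocessing statistics fitted on a different schema")
    blocks: list[np.ndarray] = []
    provenance: list[tuple[str, str]] = []
    for prop in table.schema.properties:
        if prop.kind == "continuous":
            col = table.column(prop.name)
            blocks.append(zscore(col, stats.mu[prop.name], stats.sigma[prop.name])[:, None])
            provenance.append((prop.name, "zscore"))
        else:
            states = stats.state_order[prop.name]
            raw = table.column(prop.name)
            enc = np.zeros((len(table), len(states)))
            for i, v in enumerate(raw):
                enc[i] = one_hot(str(v), states)
            blocks.append(enc)
            provenance.extend((prop.name, s) for s in states)
    values = np.hstack(blocks) if blocks else np.zeros((len(table), 0))
    return FeatureMatrix(
        values=values,
        column_provenance=provenance,
        row_ids=table.ids,
        row_labels=table.labels,
    )


def preprocess(table: PropertyTable, ddof: int = 0) -> FeatureMatrix:
    """Fit normalization on ``table`` and encode it in one step."""
    return transform(table, fit_preprocessor(table, ddof=ddof))


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov property screening
# ---------------------------------------------------------------------------

class KSResult(NamedTuple):
    property: str
    statistic: float
    pvalue: float
    significant: bool


def ks_screen(
    table: PropertyTable,
    alpha_level: float = 0.05,
    method: str = "asymp",
) -> list[KSResult]:
    """Two-sample Kolmogorov-Smirnov screen of every property.

    Each property is compared between the labeled positives and the
    unlabeled pool: D = sup |F_pos - F_unl| with an asymptotic p-value by
    default.  Nominal properties are screened on their integer state
    index; the KS test on such discrete data is conservative, so a
    warning is emitted.
    """
    labels = np.asarray(table.labels)
    pos_mask = labels == POSITIVE
    unl_mask = ~pos_mask
    if pos_mask.sum() < 2 or unl_mask.sum() < 2:
        raise PropertyTableError(
            "KS screening needs at least 2 records in each label group "
            f"(got {int(pos_mask.sum())} positive, {int(unl_mask.sum())} unlabeled)"
        )
    results = []
    for prop in table.schema.properties:
        if prop.kind == "continuous":
            col = table.column(prop.name)
        else:
            warnings.warn(
                f"KS screen of nominal property {prop.name!r} uses the integer "
                "state index; the test is conservative on discrete data",
                stacklevel=2,
            )
            state_index = {s: i for i, s in enumerate(prop.states)}
            col = np.asarray([state_index[str(v)] for v in table.column(prop.name)], dtype=float)
        res = _scipy_stats.ks_2samp(col[pos_mask], col[unl_mask], method=method)
        results.append(
            KSResult(
                property=prop.name,
                statistic=float(res.statistic),
                pvalue=float(res.pvalue),
                significant=bool(res.pvalue < alpha_level),
            )
        )
    return results


def write_ks_report(results: Iterable[KSResult], path: str | Path) -> None:
    df = pd.DataFrame(results, columns=["property", "statistic", "pvalue", "significant"])
    df.to_csv(path, sep="\t", index=False)


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    """Write the matrix as CSV preceded by a '#'-commented provenance block."""
    with open(path, "w") as fh:
        for j, (prop, comp) in enumerate(fm.column_provenance):
            fh.write(f"# column {j}: {prop} | {comp}\n")
        df = pd.DataFrame(fm.values, columns=[f"f{j}" for j in range(fm.d)])
        df.insert(0, LABEL_COLUMN, fm.row_labels)
        df.insert(0, ID_COLUMN, fm.row_ids)
        df.to_csv(fh, index=False)


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    provenance: list[tuple[str, str]] = []
    with open(path) as fh:
        lines = fh.readlines()
    data_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        data_start += 1
        _, spec = line[1:].split(":", 1)
        prop, comp = (part.strip() for part in spec.split("|", 1))
        provenance.append((prop, comp))
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[data_start:])))
    return FeatureMatrix(
        values=df.drop(columns=[ID_COLUMN, LABEL_COLUMN]).to_numpy(dtype=float),
        column_provenance=provenance,
        row_ids=[str(v) for v in df[ID_COLUMN]],
        row_labels=[str(v) for v in df[LABEL_COLUMN]],
    )
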