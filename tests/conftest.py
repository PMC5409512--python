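import numpy as np
import pytest
from hypothesis import settings

from idtp.feature_table import (
    Property,
    PropertySchema,
    PropertyTable,
    ProteinRecord,
)

settings.register_profile("suite", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def toy_schema() -> PropertySchema:
    return PropertySchema((
        Property(name="mass", kind="continuous"),
        Property(name="membrane", kind="nominal", states=("yes", "no")),
    ))


@pytest.fixture
def toy_table(toy_schema) -> PropertyTable:
    rows = [
        ("p1", "positive", 2.0, "yes"),
        ("p2", "unlabeled", 4.0, "no"),
        ("p3", "unlabeled", 6.0, "yes"),
    ]
    records = [
        ProteinRecord(id=rid, label=lab, values={"mass": m, "membrane": s})
        for rid, lab, m, s in rows
    ]
    return PropertyTable(schema=toy_schema, records=records)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def s1_shaped_schema() -> PropertySchema:
    """Synthetic stand-in for the study's property layout: 31 continuous
    plus 8 nominal properties whose state counts sum to 252, so the
    encoded width is 31 + 252 = 283.  The real supplementary table is
    not redistributable; only the shape matters here."""
    props = [Property(name=f"c{k:02d}", kind="continuous") for k in range(31)]
    state_counts = (20, 25, 30, 30, 32, 35, 38, 42)
    assert sum(state_counts) == 252
    for j, n in enumerate(state_counts):
        props.append(
            Property(name=f"n{j}", kind="nominal",
                     states=tuple(f"s{t}" for t in range(n)))
        )
    return PropertySchema(tuple(props))
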