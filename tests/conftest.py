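import numpy as np
import pandas as pd
import pytest

from mirpath import synthetic
from mirpath.data_io import (
    ExpressionMatrix,
    Interaction,
    Pathway,
    PathwayDatabase,
    PhenotypeTable,
    TargetPredictionTable,
)
from mirpath.targets import SupportedPairSet


SMALL_SCENARIO = dict(
    n_pathways=20, n_genes=300, n_mirnas=60, size_min=4, size_max=20,
    n_samples_per_group=30,
)


@pytest.fixture(scope="session")
def small_bundle():
    """A scaled-down planted bundle shared by read-only unit tests."""
    return synthetic.generate(synthetic.ScenarioConfig(seed=11, **SMALL_SCENARIO))


@pytest.fixture
def toy_db():
    return PathwayDatabase(
        pathways=(
            Pathway(pathway_id="P1", genes=frozenset({"A", "B", "C"})),
            Pathway(pathway_id="P2", genes=frozenset({"C", "D"})),
            Pathway(pathway_id="P3", genes=frozenset({"E", "F", "G", "H"})),
        )
    )


def make_pairs(pair_genes: dict, M: int | None = None) -> SupportedPairSet:
    """Build a universe-restricted SupportedPairSet from {mirna: genes}."""
    support = {(m, g): 2 for m, genes in pair_genes.items() for g in genes}
    return SupportedPairSet(
        pairs=frozenset(support), support=support, min_tools=2, universe_size=M
    )


@pytest.fixture
def toy_predictions():
    return TargetPredictionTable.from_records(
        [
            ("miR-1", "A", "T1"), ("miR-1", "A", "T2"),
            ("miR-1", "B", "T1"),
            ("miR-2", "C", "T1"), ("miR-2", "C", "T2"), ("miR-2", "C", "T3"),
            ("miR-2", "D", "T2"),
            ("miR-3", "Z", "T1"), ("miR-3", "Z", "T4"),
        ]
    )


@pytest.fixture
def phenotypes_ab():
    rng = np.random.default_rng(0)
    samples = [f"S{i}" for i in range(20)]
    return PhenotypeTable(
        table=pd.DataFrame(
            {
                "group": ["A"] * 10 + ["B"] * 10,
                "time": rng.exponential(500, 20).round(3),
                "event": [True] * 15 + [False] * 5,
            },
            index=pd.Index(samples, name="sample"),
        )
    )
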