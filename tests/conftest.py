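import numpy as np
import pytest

from dualscreen.compound_io import Attribute, AttributeSchema, CompoundDataset, CompoundRecord


@pytest.fixture(scope="session")
def schema3() -> AttributeSchema:
    """Small mixed-path schema: tabular gate + tabular & graph activities."""
    return AttributeSchema(
        (
            Attribute("bbb", "BBB permeability", "tabular", "bbb_gate"),
            Attribute("act_t", "Tabular activity", "tabular", "activity"),
            Attribute("act_g", "Graph activity", "graph", "activity"),
        )
    )


@pytest.fixture(scope="session")
def schema10():
    from dualscreen.synthfix import default_schema

    return default_schema()


def make_dataset(schema, rows):
    """rows: list of (compound_id, smiles, labels tuple[, toxic])."""
    records = []
    for row in rows:
        cid, smi, labels = row[:3]
        toxic = row[3] if len(row) > 3 else None
        records.append(CompoundRecord(cid, smi, tuple(labels), toxic))
    return CompoundDataset(schema, records)


@pytest.fixture(scope="session")
def vocabulary():
    from dualscreen.synthfix import molecule_vocabulary

    return molecule_vocabulary()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
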