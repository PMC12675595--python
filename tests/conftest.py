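import numpy as np
import pytest

from tapb.data import DTIDataset, InteractionRecord, SyntheticConfig, generate_synthetic


def make_dataset(triples):
    """Build a dataset from (drug_key, target_key, label) triples.

    Drug/target keys are small integers; SMILES and sequences are
    synthesized deterministically from them.
    """
    records = []
    for d, t, y in triples:
        records.append(
            InteractionRecord(
                drug_id=f"D{d}",
                smiles="C" * (d + 1) + "N",
                target_id=f"T{t}",
                sequence="ACDEFGHIKL"[(t % 5):] + "MNPQRSTVWY" * (t % 3 + 1),
                label=y,
            )
        )
    return DTIDataset(records)


@pytest.fixture
def tiny_dataset():
    # 3 drugs x 3 targets, mixed labels
    return make_dataset(
        [
            (0, 0, 1), (0, 1, 1), (0, 2, 0),
            (1, 0, 1), (1, 1, 0), (1, 2, 0),
            (2, 0, 1), (2, 1, 1), (2, 2, 1),
        ]
    )


@pytest.fixture(scope="session")
def synthetic_dataset():
    return generate_synthetic(
        SyntheticConfig(n_drugs=60, n_targets=30, n_pairs=400, seed=7)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
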