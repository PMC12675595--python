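"""Interaction tables: records, CSV I/O, splits, and a synthetic generator.

The on-disk format is the delimited layout used by the public DTI
benchmark releases: a header row ``SMILES,Protein,Y`` with one
drug-target pair per line and a binary interaction label. Entity
identity is the exact string: two rows with the same SMILES are the
same drug, two rows with the same amino-acid sequence are the same
target.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "FormatError",
    "InteractionRecord",
    "DTIDataset",
    "SyntheticConfig",
    "read_interactions",
    "write_interactions",
    "random_split",
    "cross_domain_split",
    "generate_synthetic",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: default column names of the public benchmark layout
DEFAULT_DIALECT: Mapping[str, str] = {"smiles": "SMILES", "sequence": "Protein", "label": "Y"}


class FormatError(ValueError):
    """A table does not match the expected delimited layout."""


@dataclass(frozen=True)
class InteractionRecord:
    """One drug-target pair with a binary interaction label."""

    drug_id: str
    smiles: str
    target_id: str
    sequence: str
    label: int

    def __post_init__(self):
        if not self.smiles:
            raise ValueError("smiles must be non-empty")
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


class DTIDataset:
    """An ordered collection of interaction records with entity indices."""

    def __init__(self, records: Sequence[InteractionRecord]):
        self.records: list[InteractionRecord] = list(records)
        self.drug_index: dict[str, list[int]] = OrderedDict()
        self.target_index: dict[str, list[int]] = OrderedDict()
        for pos, rec in enumerate(self.records):
            self.drug_index.setdefault(rec.drug_id, []).append(pos)
            self.target_index.setdefault(rec.target_id, []).append(pos)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, DTIDataset) and self.records == other.records

    @property
    def n_drugs(self) -> int:
        return len(self.drug_index)

    @property
    def n_targets(self) -> int:
        return len(self.target_index)

    @property
    def n_positives(self) -> int:
        return sum(r.label for r in self.records)

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=np.int64)

    def subset(self, positions: Iterable[int]) -> "DTIDataset":
        return DTIDataset([self.records[i] for i in positions])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SMILES": [r.smiles for r in self.records],
                "Protein": [r.sequence for r in self.records],
                "Y": [r.label for r in self.records],
            }
        )


def _assign_ids(keys: Iterable[str], prefix: str) -> dict[str, str]:
    ids: dict[str, str] = {}
    for key in keys:
        if key not in ids:
            ids[key] = f"{prefix}{len(ids)}"
    return ids


def _canonical(smiles: str) -> str:
    from rdkit import Chem  # optional, only behind the canonicalize flag

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"SMILES does not parse: {smiles!r}")
    return Chem.MolToSmiles(mol)


def read_interactions(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    *,
    allow_duplicates: bool = False,
    canonicalize_smiles: bool = False,
) -> DTIDataset:
    """Read a delimited interaction table.

    Parameters
    ----------
    path:
        CSV file with a header row.
    dialect:
        Column-name mapping with keys ``smiles``, ``sequence``, ``label``
        (and optionally ``drug_id``, ``target_id``). Defaults to the
        public benchmark spelling ``SMILES,Protein,Y``.
    allow_duplicates:
        Keep repeated (drug, target, label) triples and pairs that carry
        conflicting labels; by default either situation is an error.
    canonicalize_smiles:
        Canonicalize drug strings with RDKit before identity assignment.
    """
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    frame = pd.read_csv(path)
    for role in ("smiles", "sequence", "label"):
        col = dialect.get(role)
        if col is None or col not in frame.columns:
            raise FormatError(f"missing column for {role!r}: expected {col!r} in {list(frame.columns)}")

    smiles_col = frame[dialect["smiles"]].astype(str)
    if canonicalize_smiles:
        smiles_col = smiles_col.map(_canonical)
    seq_col = frame[dialect["sequence"]].astype(str)
    raw_labels = frame[dialect["label"]]
    labels = []
    for row, value in enumerate(raw_labels):
        try:
            lab = int(value)
        except (TypeError, ValueError):
            lab = -1
        if lab not in (0, 1):
            raise ValueError(f"non-binary label {value!r} at row {row}")
        labels.append(lab)

    if "drug_id" in dialect and dialect["drug_id"] in frame.columns:
        drug_ids = frame[dialect["drug_id"]].astype(str).tolist()
    else:
        mapping = _assign_ids(smiles_col, "D")
        drug_ids = [mapping[s] for s in smiles_col]
    if "target_id" in dialect and dialect["target_id"] in frame.columns:
        target_ids = frame[dialect["target_id"]].astype(str).tolist()
    else:
        mapping = _assign_ids(seq_col, "T")
        target_ids = [mapping[s] for s in seq_col]

    records = [
        InteractionRecord(d, s, t, q, y)
        for d, s, t, q, y in zip(drug_ids, smiles_col, target_ids, seq_col, labels)
    ]
    if not allow_duplicates:
        seen: dict[tuple[str, str], int] = {}
        for row, rec in enumerate(records):
            pair = (rec.drug_id, rec.target_id)
            if pair in seen:
                prior = records[seen[pair]]
                kind = "conflicting labels" if prior.label != rec.label else "duplicate triple"
                raise ValueError(
                    f"{kind} for pair {pair} at rows {seen[pair]} and {row}"
                    " (pass allow_duplicates=True to keep)"
                )
            seen[pair] = row
    return DTIDataset(records)


def write_interactions(dataset: DTIDataset, path: str | Path) -> None:
    """Write a dataset back to the ``SMILES,Protein,Y`` layout."""
    if len(dataset) == 0:
        raise ValueError("refusing to write an empty dataset")
    dataset.to_frame().to_csv(path, index=False)


def random_split(
    dataset: DTIDataset,
    ratios: Sequence[float] = (7, 1, 2),
    seed: int = 0,
    *,
    allow_zero: bool = False,
) -> tuple[DTIDataset, DTIDataset, DTIDataset]:
    """Seeded random partition into train/valid/test.

    Valid and test sizes are the floored ratio shares; the remainder
    (including any off-by-one) goes to train.
    """
    if len(dataset) < 3:
        raise ValueError("need at least 3 records to split")
    ratios = np.asarray(ratios, dtype=float)
    if ratios.shape != (3,) or (ratios < 0).any() or ratios.sum() <= 0:
        raise ValueError("ratios must be three nonnegative reals with positive sum")
    if (ratios == 0).any() and not allow_zero:
        raise ValueError("zero ratio shares require allow_zero=True")
    ratios = ratios / ratios.sum()
    n = len(dataset)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_valid = int(np.floor(ratios[1] * n))
    n_test = int(np.floor(ratios[2] * n))
    n_train = n - n_valid - n_test
    train = dataset.subset(order[:n_train])
    valid = dataset.subset(order[n_train : n_train + n_valid])
    test = dataset.subset(order[n_train + n_valid :])
    return train, valid, test


def cross_domain_split(
    dataset: DTIDataset, fraction_source: float, seed: int = 0
) -> tuple[DTIDataset, DTIDataset]:
    """Partition entities into disjoint source/target pools.

    Source training keeps pairs whose drug AND target fall in the source
    pools; target testing keeps pairs entirely in the target pools;
    straddling pairs are dropped, so no entity is shared across domains.
    """
    if dataset.n_drugs < 2 or dataset.n_targets < 2:
        raise ValueError("need at least 2 drugs and 2 targets")
    rng = np.random.default_rng(seed)
    drugs = list(dataset.drug_index)
    targets = list(dataset.target_index)
    rng.shuffle(drugs)
    rng.shuffle(targets)
    n_sd = int(round(fraction_source * len(drugs)))
    n_st = int(round(fraction_source * len(targets)))
    src_drugs, tgt_drugs = set(drugs[:n_sd]), set(drugs[n_sd:])
    src_targets, tgt_targets = set(targets[:n_st]), set(targets[n_st:])
    if not src_drugs or not tgt_drugs or not src_targets or not tgt_targets:
        raise ValueError(
            "an entity pool came out empty; choose a different fraction_source or seed"
        )
    source = [
        i
        for i, r in enumerate(dataset.records)
        if r.drug_id in src_drugs and r.target_id in src_targets
    ]
    target = [
        i
        for i, r in enumerate(dataset.records)
        if r.drug_id in tgt_drugs and r.target_id in tgt_targets
    ]
    return dataset.subset(source), dataset.subset(target)


# ---------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------

@dataclass
class SyntheticConfig:
    """Conditions for the synthetic biased-DTI generator.

    Per-entity label propensities reproduce the bimodal concentration of
    target label frequencies near 0 and 1 seen in the public benchmark
    training sets: with probability ``target_bias`` a target's propensity
    is extreme (``extreme_eps`` or ``1 - extreme_eps``, fair coin),
    otherwise it is drawn uniformly from (0.35, 0.65); drugs behave
    analogously under ``drug_bias``. Labels mix a latent interaction
    mechanism with the propensity channel via ``mechanism_weight``.
    """

    n_drugs: int = 200
    n_targets: int = 100
    n_pairs: int = 2000
    target_bias: float = 0.9
    drug_bias: float = 0.1
    extreme_eps: float = 0.02
    mechanism_weight: float = 0.5
    latent_dim: int = 8
    seed: int = 0
    smiles_fragments: tuple[int, int] = (3, 9)
    sequence_length: tuple[int, int] = (60, 120)

    def __post_init__(self):
        for name in ("target_bias", "drug_bias", "mechanism_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 0.0 < self.extreme_eps < 0.5:
            raise ValueError("extreme_eps must be in (0, 0.5)")
        if self.n_pairs < max(self.n_drugs, self.n_targets):
            raise ValueError("n_pairs must be at least max(n_drugs, n_targets)")
        if min(self.n_drugs, self.n_targets, self.latent_dim) < 1:
            raise ValueError("counts must be positive")


_FRAGMENTS = (
    "C", "CC", "C(C)", "C(=O)", "N", "O", "c1ccccc1", "C(N)C",
    "C(=O)O", "S", "Cl", "F", "CN", "C=C", "OC", "c1ccncc1",
)


def _random_smiles(rng: np.random.Generator, n_fragments: tuple[int, int], taken: set[str]) -> str:
    for extra in range(64):
        k = int(rng.integers(n_fragments[0], n_fragments[1])) + extra // 8
        parts = [_FRAGMENTS[i] for i in rng.integers(0, len(_FRAGMENTS), size=k)]
        smiles = "".join(parts)
        if smiles[0] in "=)":  # avoid syntactically odd leading tokens
            smiles = "C" + smiles
        if smiles not in taken:
            return smiles
    raise RuntimeError("could not generate a fresh SMILES string")


def _random_sequence(rng: np.random.Generator, length_range: tuple[int, int], taken: set[str]) -> str:
    letters = np.array(list(AMINO_ACIDS))
    for _ in range(64):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(letters[rng.integers(0, 20, size=L)])
        if seq not in taken:
            return seq
    raise RuntimeError("could not generate a fresh sequence")


def _propensities(rng: np.random.Generator, n: int, bias: float, eps: float) -> np.ndarray:
    extreme = rng.random(n) < bias
    high = rng.random(n) < 0.5
    theta = rng.uniform(0.35, 0.65, size=n)
    theta[extreme] = np.where(high[extreme], 1.0 - eps, eps)
    return theta


def generate_synthetic(config: SyntheticConfig) -> DTIDataset:
    """Generate a synthetic interaction table under ``config``.

    Each entity carries a latent unit vector; the latent mechanism says
    a pair interacts when the two vectors' dot product is positive. The
    emitted label is Bernoulli with success probability
    ``w·m(d,t) + (1−w)·(θ_d+θ_t)/2`` where ``w`` is mechanism_weight.
    Fully determined by ``config.seed``.
    """
    cfg = config
    if cfg.n_pairs > cfg.n_drugs * cfg.n_targets:
        raise ValueError(
            f"n_pairs={cfg.n_pairs} exceeds n_drugs*n_targets={cfg.n_drugs * cfg.n_targets}"
        )
    rng = np.random.default_rng(cfg.seed)

    smiles: list[str] = []
    for _ in range(cfg.n_drugs):
        smiles.append(_random_smiles(rng, cfg.smiles_fragments, set(smiles)))
    sequences: list[str] = []
    for _ in range(cfg.n_targets):
        sequences.append(_random_sequence(rng, cfg.sequence_length, set(sequences)))

    theta_d = _propensities(rng, cfg.n_drugs, cfg.drug_bias, cfg.extreme_eps)
    theta_t = _propensities(rng, cfg.n_targets, cfg.target_bias, cfg.extreme_eps)

    vec_d = rng.standard_normal((cfg.n_drugs, cfg.latent_dim))
    vec_d /= np.linalg.norm(vec_d, axis=1, keepdims=True)
    vec_t = rng.standard_normal((cfg.n_targets, cfg.latent_dim))
    vec_t /= np.linalg.norm(vec_t, axis=1, keepdims=True)

    pairs: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    while len(pairs) < cfg.n_pairs:
        d = int(rng.integers(cfg.n_drugs))
        t = int(rng.integers(cfg.n_targets))
        if (d, t) in seen:
            continue
        seen.add((d, t))
        pairs.append((d, t))

    records = []
    for d, t in pairs:
        mech = 1.0 if float(vec_d[d] @ vec_t[t]) > 0 else 0.0
        p = cfg.mechanism_weight * mech + (1.0 - cfg.mechanism_weight) * 0.5 * (
            theta_d[d] + theta_t[t]
        )
        y = int(rng.random() < p)
        records.append(
            InteractionRecord(f"D{d}", smiles[d], f"T{t}", sequences[t], y)
        )
    return DTIDataset(records)
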