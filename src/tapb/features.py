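"""Per-residue target feature providers and an on-disk tensor store.

The model consumes a per-residue feature matrix per target with a
``[cls]`` row prepended, exactly the interface of a pretrained protein
language model whose hidden states have been pre-extracted and cached.
Two providers implement that contract: an HDF5-backed store of
precomputed matrices, and a deterministic toy embedder for desk-scale
work (a seeded per-letter embedding table smoothed by a small local
window, so it is positional, local and reproducible).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import h5py
import numpy as np

from .data import AMINO_ACIDS

__all__ = [
    "ResidueFeatureMatrix",
    "TargetFeatureProvider",
    "ToyTargetEmbedder",
    "FeatureStore",
    "sequence_key",
]

CLS = "[cls]"


@dataclass
class ResidueFeatureMatrix:
    """Feature matrix for one target: [cls] row first, one row per residue."""

    features: np.ndarray  # [L, D_e]
    special_mask: np.ndarray  # [L] bool, True at [cls]/padding rows
    residue_types: list[str] | None = None  # letters, CLS at specials

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        self.special_mask = np.asarray(self.special_mask, dtype=bool)
        if self.features.shape[0] != self.special_mask.shape[0]:
            raise ValueError("features and special_mask lengths differ")
        if self.residue_types is not None and len(self.residue_types) != len(self.special_mask):
            raise ValueError("residue_types length mismatch")

    @property
    def length(self) -> int:
        return self.features.shape[0]

    @property
    def width(self) -> int:
        return self.features.shape[1]

    @property
    def n_residues(self) -> int:
        return int((~self.special_mask).sum())


class TargetFeatureProvider(Protocol):
    """Contract: sequence in, residue feature matrix (with [cls]) out."""

    def features(self, sequence: str) -> ResidueFeatureMatrix: ...


class ToyTargetEmbedder:
    """Deterministic desk-scale residue embedder.

    Each residue letter gets a fixed random vector from a seeded table;
    the per-position feature is the mean of letter vectors in a local
    window of half-width ``context``, so a single-residue substitution
    perturbs only ``2*context + 1`` rows. A fixed [cls] vector is
    prepended.
    """

    def __init__(self, width: int = 32, seed: int = 12345, context: int = 2):
        self.width = width
        self.context = context
        rng = np.random.default_rng(seed)
        letters = AMINO_ACIDS + "X"
        self._table = {
            letter: rng.standard_normal(width) / np.sqrt(width) for letter in letters
        }
        self._cls = rng.standard_normal(width) / np.sqrt(width)

    def features(self, sequence: str) -> ResidueFeatureMatrix:
        unknown = set(sequence) - set(self._table)
        if unknown:
            raise ValueError(f"sequence contains non-amino-acid letters: {sorted(unknown)}")
        L = len(sequence)
        rows = np.empty((L, self.width))
        stacked = np.stack([self._table[c] for c in sequence])
        for i in range(L):
            lo, hi = max(0, i - self.context), min(L, i + self.context + 1)
            rows[i] = stacked[lo:hi].mean(axis=0)
        features = np.vstack([self._cls[None, :], rows])
        special = np.zeros(L + 1, dtype=bool)
        special[0] = True
        return ResidueFeatureMatrix(features, special, [CLS] + list(sequence))


def sequence_key(sequence: str) -> str:
    return hashlib.sha1(sequence.encode()).hexdigest()


class FeatureStore:
    """HDF5-backed store of precomputed residue feature matrices.

    Matrices are keyed by the SHA-1 of the amino-acid sequence, the
    layout used when hidden states of an external protein language
    model are extracted once and reused across training runs.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)

    def save(self, sequence: str, matrix: ResidueFeatureMatrix) -> None:
        key = sequence_key(sequence)
        with h5py.File(self.path, "a") as fh:
            if key in fh:
                del fh[key]
            grp = fh.create_group(key)
            grp.create_dataset("features", data=matrix.features)
            grp.create_dataset("special_mask", data=matrix.special_mask)
            if matrix.residue_types is not None:
                grp.create_dataset(
                    "residue_types",
                    data=np.array(matrix.residue_types, dtype=h5py.string_dtype()),
                )

    def features(self, sequence: str) -> ResidueFeatureMatrix:
        key = sequence_key(sequence)
        with h5py.File(self.path, "r") as fh:
            if key not in fh:
                raise KeyError(f"no stored features for sequence hash {key}")
            grp = fh[key]
            types = None
            if "residue_types" in grp:
                types = [t.decode() for t in grp["residue_types"][()]]
            return ResidueFeatureMatrix(
                grp["features"][()], grp["special_mask"][()], types
            )

    def populate(self, sequences: Sequence[str], provider: TargetFeatureProvider) -> None:
        for seq in sequences:
            self.save(seq, provider.features(seq))
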