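"""Amino-acid randomization of target features and MLM token corruption.

These augmentations disrupt the association between a specific target
(or drug) string and its training labels, the mechanism by which label
prior tendency leaks into a model:

* residue random deletion removes a fixed proportion (default 70%) of
  non-special residue rows per matrix;
* residue feature mutation independently replaces surviving residue
  features (default 20% of positions) with the mean feature vector of a
  uniformly drawn residue type;
* MLM corruption selects a fixed proportion of drug tokens (default
  15%) and applies the classic mask/keep/random trichotomy (80/10/10).

All three are reapplied fresh each training epoch (augmentation, not
preprocessing) and are fully reproducible from an explicit RNG.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np

from .data import AMINO_ACIDS
from .features import ResidueFeatureMatrix
from .tokenizer import SmilesTokenizer

__all__ = [
    "AminoAcidDictionary",
    "build_amino_acid_dictionary",
    "random_residue_deletion",
    "residue_feature_mutation",
    "mlm_corrupt",
]


@dataclass
class AminoAcidDictionary:
    """Mean feature vector per residue letter over a training set."""

    entries: dict[str, np.ndarray]
    source: str = ""

    def __post_init__(self):
        widths = {v.shape for v in self.entries.values()}
        if len(widths) > 1:
            raise ValueError(f"inconsistent vector shapes: {widths}")

    @property
    def letters(self) -> list[str]:
        return sorted(self.entries)

    @property
    def width(self) -> int:
        return next(iter(self.entries.values())).shape[0]

    def matrix(self) -> np.ndarray:
        """Entries stacked in sorted-letter order."""
        return np.stack([self.entries[k] for k in self.letters])

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as fh:
            fh.attrs["source"] = self.source
            for letter, vec in self.entries.items():
                fh.create_dataset(letter, data=vec)

    @classmethod
    def load(cls, path: str | Path) -> "AminoAcidDictionary":
        with h5py.File(path, "r") as fh:
            entries = {k: fh[k][()] for k in fh}
            return cls(entries, source=str(fh.attrs.get("source", "")))


def build_amino_acid_dictionary(
    training_features: Iterable[ResidueFeatureMatrix],
    *,
    required_letters: str = AMINO_ACIDS,
    source: str = "training-set mean pooling",
) -> AminoAcidDictionary:
    """Average-pool every residue type's features across a training set.

    Each letter's entry is the elementwise mean over all non-special
    positions of that letter. Letters beyond the required canonical
    alphabet (e.g. X) are included opportunistically when present.
    """
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for matrix in training_features:
        if matrix.residue_types is None:
            raise ValueError("residue_types are required to build the dictionary")
        for pos in np.flatnonzero(~matrix.special_mask):
            letter = matrix.residue_types[pos]
            if letter in sums:
                sums[letter] += matrix.features[pos]
                counts[letter] += 1
            else:
                sums[letter] = matrix.features[pos].copy()
                counts[letter] = 1
    missing = sorted(set(required_letters) - set(sums))
    if missing:
        raise ValueError(f"residue letters absent from training features: {missing}")
    entries = {letter: sums[letter] / counts[letter] for letter in sums}
    return AminoAcidDictionary(entries, source=source)


def random_residue_deletion(
    matrix: ResidueFeatureMatrix,
    deletion_ratio: float = 0.7,
    rng: np.random.Generator | None = None,
    *,
    bernoulli: bool = False,
) -> ResidueFeatureMatrix:
    """Randomly delete a fixed proportion of non-special residue rows.

    Keeps every special position ([cls], padding) plus a uniformly
    chosen subset of ``round((1 - ratio) * n_residues)`` residues (at
    least one), preserving original order. With ``bernoulli=True`` each
    residue is instead kept independently with probability 1 − ratio.
    """
    if not 0.0 <= deletion_ratio < 1.0:
        raise ValueError("deletion_ratio must be in [0, 1)")
    rng = np.random.default_rng() if rng is None else rng
    residue_pos = np.flatnonzero(~matrix.special_mask)
    if residue_pos.size == 0:
        raise ValueError("matrix has no non-special positions to delete from")
    if bernoulli:
        keep_flags = rng.random(residue_pos.size) >= deletion_ratio
        if not keep_flags.any():
            keep_flags[rng.integers(residue_pos.size)] = True
        kept = residue_pos[keep_flags]
    else:
        n_keep = max(1, int(round((1.0 - deletion_ratio) * residue_pos.size)))
        kept = np.sort(rng.choice(residue_pos, size=n_keep, replace=False))
    keep_mask = matrix.special_mask.copy()
    keep_mask[kept] = True
    idx = np.flatnonzero(keep_mask)
    types = None
    if matrix.residue_types is not None:
        types = [matrix.residue_types[i] for i in idx]
    return ResidueFeatureMatrix(matrix.features[idx], matrix.special_mask[idx], types)


def residue_feature_mutation(
    matrix: ResidueFeatureMatrix,
    mutation_rate: float = 0.2,
    dictionary: AminoAcidDictionary | None = None,
    rng: np.random.Generator | None = None,
) -> ResidueFeatureMatrix:
    """Independently replace residue features with random dictionary entries.

    Each non-special position is, with probability ``mutation_rate``,
    replaced by the dictionary vector of a uniformly sampled residue
    letter; otherwise it is left untouched. Special positions are never
    mutated.
    """
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must be in [0, 1]")
    if dictionary is None or not dictionary.entries:
        raise ValueError("a non-empty amino-acid dictionary is required")
    rng = np.random.default_rng() if rng is None else rng
    letters = dictionary.letters
    table = dictionary.matrix()
    features = matrix.features.copy()
    types = list(matrix.residue_types) if matrix.residue_types is not None else None
    residue_pos = np.flatnonzero(~matrix.special_mask)
    hit = residue_pos[rng.random(residue_pos.size) < mutation_rate]
    choice = rng.integers(0, len(letters), size=hit.size)
    for pos, c in zip(hit, choice):
        features[pos] = table[c]
        if types is not None:
            types[pos] = letters[c]
    return ResidueFeatureMatrix(features, matrix.special_mask.copy(), types)


def mlm_corrupt(
    token_ids: np.ndarray,
    rng: np.random.Generator,
    select_rate: float = 0.15,
    mask_frac: float = 0.8,
    keep_frac: float = 0.1,
    random_frac: float = 0.1,
    vocab: SmilesTokenizer | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Masked-language-model corruption of a drug token sequence.

    ``round(select_rate * n_eligible)`` non-special tokens are selected;
    each selected token is replaced by ``[mask]`` with probability
    ``mask_frac``, left unchanged with ``keep_frac``, or replaced by a
    uniformly drawn non-special vocabulary token with ``random_frac``.
    Returns the corrupted ids and the boolean selection mask (the
    positions whose original tokens the MLM head must recover).
    """
    if vocab is None:
        raise ValueError("a tokenizer vocabulary is required")
    if abs(mask_frac + keep_frac + random_frac - 1.0) > 1e-9:
        raise ValueError("mask/keep/random fractions must sum to 1")
    token_ids = np.asarray(token_ids, dtype=np.int64)
    corrupted = token_ids.copy()
    selection = np.zeros(token_ids.shape, dtype=bool)
    special = np.array(sorted(vocab.special_ids), dtype=np.int64)
    eligible = np.flatnonzero(~np.isin(token_ids, special))
    n_select = int(round(select_rate * eligible.size))
    if n_select == 0:
        return corrupted, selection
    chosen = rng.choice(eligible, size=n_select, replace=False)
    selection[chosen] = True
    u = rng.random(n_select)
    candidates = np.array(
        [i for i in range(len(vocab)) if i not in vocab.special_ids], dtype=np.int64
    )
    for pos, draw in zip(chosen, u):
        if draw < mask_frac:
            corrupted[pos] = vocab.mask_id
        elif draw < mask_frac + keep_frac:
            pass  # unchanged
        else:
            corrupted[pos] = candidates[rng.integers(candidates.size)]
    return corrupted, selection
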