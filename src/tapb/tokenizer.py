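"""Atom-wise regex SMILES tokenizer with a data-built vocabulary."""

from __future__ import annotations

import re
from typing import Iterable, Sequence

import numpy as np

__all__ = ["SMILES_TOKEN_RE", "SmilesTokenizer", "tokenize_smiles"]

# multi-character atoms and bracket atoms first, then single characters
SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|Si|Se|se|@@|%\d{2}|[A-Za-z]|\d|[=#$+\-()/\\.:~*])"
)


def tokenize_smiles(smiles: str) -> list[str]:
    tokens = SMILES_TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise ValueError(f"SMILES contains untokenizable characters: {smiles!r}")
    return tokens


class SmilesTokenizer:
    """Maps SMILES strings to integer id sequences.

    Ids 0..2 are reserved for ``[pad]``, ``[unk]`` and ``[mask]``; the
    rest of the vocabulary is built from a training corpus in first-seen
    order, which makes the mapping reproducible from the data alone.
    """

    PAD, UNK, MASK = "[pad]", "[unk]", "[mask]"

    def __init__(self, vocab: Sequence[str] | None = None):
        base = [self.PAD, self.UNK, self.MASK]
        self.vocab: list[str] = base + [t for t in (vocab or []) if t not in base]
        self.token_to_id = {t: i for i, t in enumerate(self.vocab)}

    @classmethod
    def fit(cls, corpus: Iterable[str]) -> "SmilesTokenizer":
        seen: dict[str, None] = {}
        for smiles in corpus:
            for tok in tokenize_smiles(smiles):
                seen.setdefault(tok, None)
        return cls(list(seen))

    # -- properties ----------------------------------------------------
    @property
    def pad_id(self) -> int:
        return 0

    @property
    def unk_id(self) -> int:
        return 1

    @property
    def mask_id(self) -> int:
        return 2

    @property
    def special_ids(self) -> frozenset[int]:
        return frozenset((0, 1, 2))

    def __len__(self) -> int:
        return len(self.vocab)

    # -- encoding ------------------------------------------------------
    def encode(self, smiles: str, max_len: int | None = None) -> np.ndarray:
        ids = [self.token_to_id.get(t, self.unk_id) for t in tokenize_smiles(smiles)]
        if max_len is not None:
            ids = ids[:max_len]
        return np.asarray(ids, dtype=np.int64)

    def encode_batch(self, smiles_list: Sequence[str], max_len: int | None = None):
        """Pad a batch to its longest member; returns (ids, mask)."""
        encoded = [self.encode(s, max_len) for s in smiles_list]
        L = max(len(e) for e in encoded)
        ids = np.full((len(encoded), L), self.pad_id, dtype=np.int64)
        mask = np.zeros((len(encoded), L), dtype=bool)
        for i, e in enumerate(encoded):
            ids[i, : len(e)] = e
            mask[i, : len(e)] = True
        return ids, mask

    def decode(self, ids: Iterable[int]) -> list[str]:
        return [self.vocab[i] for i in ids]
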