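"""Counter-prior training-set constructions.

Two re-splits of an interaction table that deliberately control which
axis carries a label prior:

* a drug-biased set in which every target sees one positive and one
  negative pair (balanced targets) while every drug is all-positive or
  all-negative (maximal drug prior);
* a fully balanced set in which every drug AND every target sees
  exactly one positive and one negative pair.

Training on these sets demonstrates that prior tendency in the data —
not the model architecture — produces biased predictions.
"""

from __future__ import annotations

import numpy as np

from .data import DTIDataset, InteractionRecord

__all__ = ["select_unique_positives", "build_drug_biased_split", "build_balanced_split"]


def select_unique_positives(dataset: DTIDataset, rng: np.random.Generator) -> list[InteractionRecord]:
    """Greedy maximal set of positive pairs with all-distinct drugs and targets.

    Positives are visited in seeded-shuffled order and kept first-fit;
    the result is one of many maximal (not necessarily maximum) matchings.
    """
    positives = [r for r in dataset.records if r.label == 1]
    if not positives:
        raise ValueError("dataset contains no positive pairs")
    order = rng.permutation(len(positives))
    used_drugs: set[str] = set()
    used_targets: set[str] = set()
    chosen: list[InteractionRecord] = []
    for i in order:
        rec = positives[i]
        if rec.drug_id in used_drugs or rec.target_id in used_targets:
            continue
        used_drugs.add(rec.drug_id)
        used_targets.add(rec.target_id)
        chosen.append(rec)
    return chosen


def build_drug_biased_split(dataset: DTIDataset, seed: int = 0) -> DTIDataset:
    """Construct the drug-biased counter-prior training set.

    Each target of the unique-positive set S_p receives exactly one
    negative pair whose drug comes from the pool of drugs absent from
    S_p (cycled with replacement when the pool is small). The output is
    an exact 50% positive/negative mix where every target's tendency is
    0.5 and every drug's tendency is 0 or 1.
    """
    rng = np.random.default_rng(seed)
    s_p = select_unique_positives(dataset, rng)
    pos_drugs = {r.drug_id for r in s_p}
    leftover = [d for d in dataset.drug_index if d not in pos_drugs]
    if not leftover:
        raise ValueError("no drugs left outside the positive set to build negatives from")
    rng.shuffle(leftover)
    drug_smiles = {r.drug_id: r.smiles for r in dataset.records}

    existing = {(r.drug_id, r.target_id) for r in dataset.records}
    emitted: set[tuple[str, str]] = set()
    negatives: list[InteractionRecord] = []
    cursor = 0
    for rec in s_p:
        placed = False
        for _ in range(len(leftover)):
            d = leftover[cursor % len(leftover)]
            cursor += 1
            pair = (d, rec.target_id)
            if pair in existing or pair in emitted:
                continue
            emitted.add(pair)
            negatives.append(
                InteractionRecord(d, drug_smiles[d], rec.target_id, rec.sequence, 0)
            )
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place a fresh negative for target {rec.target_id}"
            )
    merged = list(s_p) + negatives
    order = rng.permutation(len(merged))
    return DTIDataset([merged[i] for i in order])


def build_balanced_split(dataset: DTIDataset, seed: int = 0, max_retries: int = 10000) -> DTIDataset:
    """Construct the balanced counter-prior training set.

    Negatives are the positives of S_p with the drug column deranged (a
    seeded permutation with no fixed point), so no negative recreates a
    positive pair and every single drug and target ends up with one
    positive and one negative label.
    """
    rng = np.random.default_rng(seed)
    s_p = select_unique_positives(dataset, rng)
    n = len(s_p)
    if n < 2:
        raise ValueError("need at least 2 unique positive pairs to derange drugs")
    for _ in range(max_retries):
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            break
    else:  # pragma: no cover - probability ~ (1 - 1/e)^max_retries
        raise RuntimeError("failed to sample a derangement")
    negatives = [
        InteractionRecord(
            s_p[perm[j]].drug_id,
            s_p[perm[j]].smiles,
            s_p[j].target_id,
            s_p[j].sequence,
            0,
        )
        for j in range(n)
    ]
    merged = list(s_p) + negatives
    order = rng.permutation(len(merged))
    return DTIDataset([merged[i] for i in order])
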