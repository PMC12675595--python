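"""Prior-tendency statistics and the label permutation test.

A drug or target that appears many times in a training table with
mostly-positive (or mostly-negative) labels carries a "prior tendency":
a model can exploit that imbalance to minimise loss without learning
any interaction mechanism. This module quantifies the tendency per
sequence (z_i), dataset-wide (Z), and tests its significance against a
null in which labels are exchangeable across pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .data import DTIDataset

__all__ = [
    "Axis",
    "TendencyTable",
    "PermutationResult",
    "sequence_tendency",
    "overall_tendency",
    "global_proportion",
    "deviation_statistic",
    "permutation_test",
    "bias_report",
]

Axis = Literal["drug", "target"]


@dataclass
class TendencyTable:
    """Per-sequence label tendencies along one axis of a dataset.

    ``z`` holds each unique sequence's exact positive fraction,
    ``n`` its occurrence count; values are never rounded here (the
    one-decimal rounding seen in histograms is display-only).
    """

    axis: Axis
    sequence_ids: list[str]
    n: np.ndarray
    z: np.ndarray

    @property
    def M(self) -> int:
        return len(self.sequence_ids)


@dataclass
class PermutationResult:
    axis: Axis
    T_obs: float
    g: float
    N: int
    B: int
    permuted_T: np.ndarray
    p_value: float
    seed: int


def _groups(dataset: DTIDataset, axis: Axis) -> dict[str, list[int]]:
    if axis == "drug":
        return dataset.drug_index
    if axis == "target":
        return dataset.target_index
    raise ValueError(f"axis must be 'drug' or 'target', got {axis!r}")


def sequence_tendency(dataset: DTIDataset, axis: Axis) -> TendencyTable:
    """Exact positive fraction z_i and count n_i per unique sequence."""
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    index = _groups(dataset, axis)
    labels = dataset.labels()
    ids, counts, fractions = [], [], []
    for seq_id, positions in index.items():
        sub = labels[positions]
        ids.append(seq_id)
        counts.append(len(sub))
        fractions.append(sub.sum() / len(sub))
    return TendencyTable(axis, ids, np.asarray(counts), np.asarray(fractions, dtype=float))


def overall_tendency(table: TendencyTable, *, weighted: bool = False) -> float:
    """Dataset-wide prior tendency Z in [0.5, 1.0].

    Z is the mean absolute deviation of the z_i from 0.5, shifted by
    0.5 so that a perfectly balanced dataset scores 0.5 and a dataset
    whose every sequence is all-positive or all-negative scores 1.0.
    With ``weighted=True`` sequences contribute proportionally to their
    occurrence counts instead of uniformly.
    """
    if table.M == 0:
        raise ValueError("tendency table is empty")
    dev = np.abs(table.z - 0.5)
    if weighted:
        return float(np.average(dev, weights=table.n) + 0.5)
    return float(dev.mean() + 0.5)


def global_proportion(dataset: DTIDataset) -> float:
    """Global positive interaction proportion g = ΣY / N."""
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    labels = dataset.labels()
    return float(labels.sum() / labels.size)


def deviation_statistic(table: TendencyTable, g: float) -> float:
    """Weighted sum of squared deviations T = Σ_i n_i (z_i − g)²."""
    if not 0.0 <= g <= 1.0:
        raise ValueError("g must be in [0,1]")
    return float(np.sum(table.n * (table.z - g) ** 2))


def permutation_test(
    dataset: DTIDataset, axis: Axis, B: int = 1000, seed: int = 0
) -> PermutationResult:
    """One-sided permutation test of per-sequence tendency.

    The pair structure is held fixed while labels are reshuffled across
    all pairs (sampling without replacement) for B iterations; the
    statistic T is recomputed each time and the p-value is
    ``(1 + #{T_b ≥ T_obs}) / (1 + B)``.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    index = _groups(dataset, axis)
    labels = dataset.labels().astype(float)
    N = labels.size
    g = labels.sum() / N

    # integer group index per record for fast bincount-based recompute
    group_of = np.empty(N, dtype=np.int64)
    counts = np.empty(len(index), dtype=np.int64)
    for gi, (_, positions) in enumerate(index.items()):
        group_of[positions] = gi
        counts[gi] = len(positions)

    def statistic(lab: np.ndarray) -> float:
        pos = np.bincount(group_of, weights=lab, minlength=len(counts))
        z = pos / counts
        return float(np.sum(counts * (z - g) ** 2))

    T_obs = statistic(labels)
    rng = np.random.default_rng(seed)
    permuted = np.empty(B)
    for b in range(B):
        permuted[b] = statistic(rng.permutation(labels))
    p = (1.0 + np.sum(permuted >= T_obs)) / (1.0 + B)
    return PermutationResult(axis, T_obs, float(g), int(N), int(B), permuted, float(p), seed)


def _histogram(z: np.ndarray) -> dict[str, int]:
    """Counts of z_i rounded to one decimal (the display convention)."""
    bins = np.round(z.astype(float), 1)
    out: dict[str, int] = {f"{b:.1f}": 0 for b in np.arange(0.0, 1.05, 0.1)}
    for b in bins:
        out[f"{b:.1f}"] += 1
    return out


def bias_report(
    dataset: DTIDataset,
    B: int = 1000,
    seed: int = 0,
    *,
    weighted: bool = False,
    out_json: str | Path | None = None,
    out_plot: str | Path | None = None,
) -> dict:
    """Full bias audit of a dataset: per-axis histogram, Z, T and p-value."""
    report: dict = {"N": len(dataset), "g": global_proportion(dataset), "B": B}
    for axis in ("drug", "target"):
        table = sequence_tendency(dataset, axis)
        perm = permutation_test(dataset, axis, B=B, seed=seed)
        report[axis] = {
            "axis": axis,
            "M": table.M,
            "Z": overall_tendency(table, weighted=weighted),
            "T_obs": perm.T_obs,
            "B": B,
            "p_value": perm.p_value,
            "histogram": _histogram(table.z),
        }
    if out_json is not None:
        Path(out_json).write_text(json.dumps(report, indent=2))
    if out_plot is not None:
        _plot_report(report, out_plot)
    return report


def _plot_report(report: dict, path: str | Path) -> None:  # pragma: no cover
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2))
    for ax, axis in zip(axes, ("drug", "target")):
        hist = report[axis]["histogram"]
        ax.bar([float(k) for k in hist], list(hist.values()), width=0.08)
        ax.set_title(
            f"{axis}s: Z={report[axis]['Z']:.3f}, p={report[axis]['p_value']:.4g}"
        )
        ax.set_xlabel("prior tendency z")
        ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
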