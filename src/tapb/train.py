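"""Training and evaluation loops, checkpointing, and the bias probe."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from sklearn.metrics import roc_auc_score

from .data import DTIDataset
from .features import ResidueFeatureMatrix, TargetFeatureProvider, ToyTargetEmbedder
from .metrics import Metrics, evaluate_scores
from .model import ModelConfig, TAPBModel, build_confounder_dictionary
from .randomization import (
    AminoAcidDictionary,
    build_amino_acid_dictionary,
    mlm_corrupt,
    random_residue_deletion,
    residue_feature_mutation,
)
from .tokenizer import SmilesTokenizer

__all__ = [
    "Adam",
    "Batcher",
    "Checkpoint",
    "ProbeResult",
    "train",
    "predict",
    "evaluate",
    "bias_probe",
]


class Adam:
    """Adam optimizer over the model's named parameter tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Batcher:
    """Builds padded model batches from an interaction table.

    Base residue feature matrices are computed once per unique sequence
    and cached; randomization (deletion + mutation) and MLM corruption
    are applied fresh per batch in training mode, so every epoch sees a
    different corruption of the same pairs.
    """

    def __init__(
        self,
        dataset: DTIDataset,
        tokenizer: SmilesTokenizer,
        provider: TargetFeatureProvider,
        config: ModelConfig,
        aa_dict: AminoAcidDictionary | None = None,
    ):
        self.dataset = dataset
        self.tokenizer = tokenizer
        self.provider = provider
        self.config = config
        self.aa_dict = aa_dict
        self._cache: dict[str, ResidueFeatureMatrix] = {}
        for rec in dataset.records:
            if rec.sequence not in self._cache:
                m = provider.features(rec.sequence)
                if m.length > config.max_target_len:
                    keep = np.arange(config.max_target_len)
                    types = None if m.residue_types is None else [
                        m.residue_types[i] for i in keep
                    ]
                    m = ResidueFeatureMatrix(m.features[keep], m.special_mask[keep], types)
                self._cache[rec.sequence] = m

    def target_matrices(self) -> list[ResidueFeatureMatrix]:
        """One cached matrix per unique target, in first-seen order."""
        return list(self._cache.values())

    def _target_batch(self, matrices: list[ResidueFeatureMatrix]):
        L = max(m.length for m in matrices)
        d = matrices[0].width
        feats = np.zeros((len(matrices), L, d))
        mask = np.zeros((len(matrices), L), dtype=bool)
        for i, m in enumerate(matrices):
            feats[i, : m.length] = m.features
            mask[i, : m.length] = True
        return feats, mask

    def batches(
        self, batch_size: int, rng: np.random.Generator | None = None, train: bool = False
    ) -> Iterator[dict]:
        cfg = self.config
        n = len(self.dataset)
        order = np.arange(n)
        if train:
            assert rng is not None
            order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            records = [self.dataset.records[i] for i in idx]
            ids, dmask = self.tokenizer.encode_batch(
                [r.smiles for r in records], max_len=cfg.max_drug_len
            )
            batch = {
                "labels": np.array([r.label for r in records], dtype=np.int64),
                "drug_mask": dmask,
            }
            if train and cfg.use_mlm:
                corrupted = np.empty_like(ids)
                selection = np.zeros_like(ids, dtype=bool)
                for i in range(len(records)):
                    corrupted[i], selection[i] = mlm_corrupt(
                        ids[i],
                        rng,
                        cfg.mlm_select_rate,
                        cfg.mlm_mask_frac,
                        cfg.mlm_keep_frac,
                        cfg.mlm_random_frac,
                        vocab=self.tokenizer,
                    )
                batch["token_ids"] = corrupted
                batch["mlm_true_ids"] = ids
                batch["mlm_selection"] = selection
            else:
                batch["token_ids"] = ids
            matrices = [self._cache[r.sequence] for r in records]
            if train and cfg.use_randomization:
                randomized = []
                for m in matrices:
                    m = random_residue_deletion(m, cfg.deletion_ratio, rng)
                    m = residue_feature_mutation(m, cfg.mutation_rate, self.aa_dict, rng)
                    randomized.append(m)
                matrices = randomized
            batch["target_features"], batch["target_mask"] = self._target_batch(matrices)
            yield batch


@dataclass
class Checkpoint:
    """A trained model plus everything needed to score new pairs."""

    model: TAPBModel
    tokenizer: SmilesTokenizer
    provider: TargetFeatureProvider
    aa_dict: AminoAcidDictionary | None
    config: ModelConfig
    log: list[dict]
    seed: int


def _forward_batch(model: TAPBModel, batch: dict, **overrides):
    return model.forward(
        batch["token_ids"],
        batch["drug_mask"],
        batch["target_features"],
        batch["target_mask"],
        mlm_selection=batch.get("mlm_selection"),
        mlm_true_ids=batch.get("mlm_true_ids"),
        **overrides,
    )


def train(
    train_set: DTIDataset,
    valid_set: DTIDataset,
    seed: int = 0,
    *,
    epochs: int = 10,
    lr: float = 2e-3,
    batch_size: int = 32,
    provider: TargetFeatureProvider | None = None,
    config_overrides: dict | None = None,
) -> Checkpoint:
    """Train a model and keep the checkpoint with best validation AUROC.

    The tokenizer vocabulary, amino-acid dictionary and confounder
    dictionary are all built from the training set only. Runs are fully
    deterministic given ``seed``.
    """
    if len(train_set) == 0 or len(valid_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    overrides = dict(config_overrides or {})
    tokenizer = SmilesTokenizer.fit([r.smiles for r in train_set.records])
    config = ModelConfig(vocab_size=len(tokenizer), **overrides)
    if provider is None:
        provider = ToyTargetEmbedder(width=config.d_target)

    batcher = Batcher(train_set, tokenizer, provider, config)
    target_matrices = batcher.target_matrices()
    if config.use_randomization:
        letters = sorted(
            {
                t
                for m in target_matrices
                if m.residue_types
                for t, sp in zip(m.residue_types, m.special_mask)
                if not sp
            }
        )
        batcher.aa_dict = build_amino_acid_dictionary(
            target_matrices, required_letters="".join(letters)
        )
    dictionary = None
    if config.use_cam or config.use_backdoor:
        dictionary = build_confounder_dictionary(
            target_matrices, config.dict_size, seed=seed
        )
    model = TAPBModel(config, dictionary=dictionary, seed=seed)
    optimizer = Adam(model.params, lr=lr)
    valid_batcher = Batcher(valid_set, tokenizer, provider, config)
    valid_labels = valid_set.labels()

    rng = np.random.default_rng(seed)
    log: list[dict] = []
    best_auroc, best_state = -np.inf, model.state_dict()
    for epoch in range(epochs):
        losses = []
        for batch in batcher.batches(batch_size, rng, train=True):
            bundle = _forward_batch(model, batch)
            loss_b = model.classification_loss(bundle["prob"], batch["labels"])
            loss_m = None
            if config.use_mlm and batch.get("mlm_selection") is not None:
                loss_m = model.mlm_loss(
                    bundle["drug_hidden"], batch["mlm_selection"], batch["mlm_true_ids"]
                )
            loss = model.total_loss(loss_b, loss_m, config)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: classification={loss_b.data}"
                )
            model.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        val_scores = _score_batches(model, valid_batcher, batch_size)
        val_auroc = (
            float(roc_auc_score(valid_labels, val_scores))
            if np.unique(valid_labels).size > 1
            else float("nan")
        )
        log.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "valid_auroc": val_auroc}
        )
        if not np.isnan(val_auroc) and val_auroc > best_auroc:
            best_auroc = val_auroc
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return Checkpoint(model, tokenizer, provider, batcher.aa_dict, config, log, seed)


def _score_batches(model: TAPBModel, batcher: Batcher, batch_size: int = 64) -> np.ndarray:
    scores = []
    for batch in batcher.batches(batch_size):
        bundle = _forward_batch(model, batch)
        scores.append(bundle["prob"].data[:, 1])
    return np.concatenate(scores)


def predict(checkpoint: Checkpoint, dataset: DTIDataset, batch_size: int = 64) -> np.ndarray:
    """Interaction scores P(Y=1 | pair) for every record."""
    batcher = Batcher(dataset, checkpoint.tokenizer, checkpoint.provider, checkpoint.config)
    return _score_batches(checkpoint.model, batcher, batch_size)


def evaluate(
    checkpoint: Checkpoint,
    test_set: DTIDataset,
    calibration_set: DTIDataset,
    batch_size: int = 64,
) -> Metrics:
    """Threshold-free metrics on the test set; Youden cut from calibration."""
    test_scores = predict(checkpoint, test_set, batch_size)
    cal_scores = predict(checkpoint, calibration_set, batch_size)
    return evaluate_scores(
        test_scores, test_set.labels(), cal_scores, calibration_set.labels(), checkpoint.seed
    )


@dataclass
class ProbeResult:
    mode: str
    score_label_auroc: float
    feature_separation: float
    replicates: int
    seed: int
    embedding_2d: np.ndarray | None = None


def bias_probe(
    checkpoint: Checkpoint,
    dataset: DTIDataset,
    mode: str,
    replicates: int = 3,
    seed: int = 0,
    *,
    batch_size: int = 64,
    export_2d: bool = False,
) -> ProbeResult:
    """Random-feature bias probe.

    ``mode="target_random"`` is the (T,R) probe: the target branch is
    kept and the DRUG feature tensor is replaced by standard-normal
    noise of matching shape, so any residual score-label association
    must come from the target. ``mode="drug_random"`` is the symmetric
    (D,R) probe with the target branch replaced. Scores and pooled
    classification features are averaged over ``replicates`` noise
    draws; the association is summarized by the AUROC of probe scores
    against the true labels and by the normalized distance between
    class centroids in classification-feature space.
    """
    if mode not in ("drug_random", "target_random"):
        raise ValueError(f"unknown probe mode {mode!r}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    cfg = checkpoint.config
    batcher = Batcher(dataset, checkpoint.tokenizer, checkpoint.provider, cfg)
    labels = dataset.labels()
    score_acc = np.zeros(len(dataset))
    feat_acc = None
    for _ in range(replicates):
        scores, feats = [], []
        for batch in batcher.batches(batch_size):
            B, L_d = batch["token_ids"].shape
            L_t = batch["target_mask"].shape[1]
            overrides = {}
            if mode == "target_random":
                overrides["drug_override"] = rng.standard_normal((B, L_d, cfg.d_model))
            else:
                overrides["target_override"] = rng.standard_normal((B, L_t, cfg.d_model))
            bundle = _forward_batch(checkpoint.model, batch, **overrides)
            scores.append(bundle["prob"].data[:, 1])
            feats.append(bundle["pooled"].data)
        score_acc += np.concatenate(scores)
        feats = np.vstack(feats)
        feat_acc = feats if feat_acc is None else feat_acc + feats
    score_mean = score_acc / replicates
    feat_mean = feat_acc / replicates
    auroc = float(roc_auc_score(labels, score_mean))
    mu1 = feat_mean[labels == 1].mean(axis=0)
    mu0 = feat_mean[labels == 0].mean(axis=0)
    spread = float(np.mean(feat_mean.std(axis=0))) + 1e-12
    separation = float(np.linalg.norm(mu1 - mu0)) / spread
    embedding = None
    if export_2d:
        from sklearn.decomposition import PCA

        embedding = PCA(n_components=2, random_state=seed).fit_transform(feat_mean)
    return ProbeResult(mode, auroc, separation, replicates, seed, embedding)
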