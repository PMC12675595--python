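"""The debiasing DTI model: encoders, CAM, aggregator, backdoor adjustment.

Architecture
------------
A dual-tower design. SMILES token ids pass through an embedding and a
stack of transformer blocks with rotary position encoding (the drug
encoder). Target per-residue features arrive from a pluggable provider
(a stand-in for a pretrained protein language model) and go through the
confounder alignment module (CAM), where each attention head attends to
one cluster center of the confounder dictionary, establishing an
explicit path from the raw sequence through the dictionary into the
target representation. A cross-attention aggregator (query = drug,
key/value = target) fuses the towers. Its output is partitioned along
channels into one segment per confounder cluster; a shared head turns
each pooled segment into a conditional probability P(Y|D,T,c_i), and
the prediction is the backdoor adjustment

    P(Y | D, do(T)) = sum_i P(c_i) P(Y | D, T, c_i)

with cluster proportions P(c_i) fixed at dictionary build time. Every
debiasing element (randomization, MLM loss, CAM, backdoor) can be
switched off independently for ablations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .autodiff import Tensor, concat, embedding, layer_norm, relu, softmax
from .features import ResidueFeatureMatrix

__all__ = [
    "ModelConfig",
    "ConfounderDictionary",
    "build_confounder_dictionary",
    "pool_target_features",
    "backdoor_predict",
    "TAPBModel",
]

LOG_FLOOR = 1e-12

#: parameters and activations are kept in single precision for speed;
#: reference-grade quantities (dictionary weights, the pure-numpy
#: backdoor function) stay in double precision.
DTYPE = np.float32


@dataclass
class ModelConfig:
    """Hyperparameters and ablation switches.

    The number of aggregator attention heads must equal the confounder
    dictionary size: each head's channel block approximates one
    cluster-conditioned feature segment.
    """

    vocab_size: int
    d_model: int = 32  # model width D_m
    d_target: int = 32  # provider feature width D_e
    n_heads: int = 4  # aggregator heads H (= dictionary size I)
    dict_size: int = 4  # confounder dictionary size I
    n_encoder_layers: int = 3
    n_aggregator_layers: int = 3
    d_ff: int = 64
    max_drug_len: int = 64
    max_target_len: int = 160
    # ablation switches (full model: all True)
    use_randomization: bool = True
    use_mlm: bool = True
    use_cam: bool = True
    use_backdoor: bool = True
    # variants exposed for the open design points
    cam_full_dictionary: bool = False  # every head attends to all centers
    partition_pre_ffn: bool = False  # partition before the last FFN
    # randomization rates
    deletion_ratio: float = 0.7
    mutation_rate: float = 0.2
    mlm_select_rate: float = 0.15
    mlm_mask_frac: float = 0.8
    mlm_keep_frac: float = 0.1
    mlm_random_frac: float = 0.1
    rope_base: float = 10000.0

    def __post_init__(self):
        if self.n_heads != self.dict_size:
            raise ValueError("n_heads must equal dict_size (one head per cluster)")
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.d_target % self.n_heads:
            raise ValueError("d_target must be divisible by n_heads")
        if min(self.n_encoder_layers, self.n_aggregator_layers) < 1:
            raise ValueError("depths must be at least 1")

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads


@dataclass
class ConfounderDictionary:
    """K-Means cluster centers of training-target features plus weights."""

    centers: np.ndarray  # [I, D_e]
    weights: np.ndarray  # [I], sums to 1
    fit_seed: int = 0
    n_samples: int = 0

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.centers.ndim != 2 or self.centers.shape[0] != self.weights.shape[0]:
            raise ValueError("centers and weights are inconsistent")
        if (self.weights < 0).any() or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")

    @property
    def size(self) -> int:
        return self.centers.shape[0]


def pool_target_features(matrix: ResidueFeatureMatrix) -> np.ndarray:
    """Masked mean over non-special residue rows -> one D_e vector."""
    rows = matrix.features[~matrix.special_mask]
    if rows.shape[0] == 0:
        raise ValueError("matrix has no residue rows to pool")
    return rows.mean(axis=0)


def build_confounder_dictionary(
    training_features: Sequence[ResidueFeatureMatrix],
    I: int,
    seed: int = 0,
    *,
    per_residue: bool = False,
) -> ConfounderDictionary:
    """Cluster training-target features into the confounder dictionary.

    Each target is reduced to one vector by masked mean pooling (or,
    with ``per_residue=True``, every residue row enters clustering);
    K-Means with k-means++ initialisation yields the centers, and the
    cluster membership proportions become the adjustment weights.
    """
    if per_residue:
        X = np.vstack([m.features[~m.special_mask] for m in training_features])
    else:
        X = np.stack([pool_target_features(m) for m in training_features])
    if X.shape[0] < I:
        raise ValueError(f"need at least {I} samples to fit {I} clusters, got {X.shape[0]}")
    km = KMeans(n_clusters=I, random_state=seed, n_init=10)
    labels = km.fit_predict(X)
    weights = np.bincount(labels, minlength=I) / labels.size
    return ConfounderDictionary(km.cluster_centers_, weights, fit_seed=seed, n_samples=X.shape[0])


def backdoor_predict(conditional: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Exact backdoor adjustment: weights^T @ conditional rows.

    ``conditional`` is [I, 2] (or [B, I, 2]); the result is the
    probability row P(Y|D,do(T)) = sum_i P(c_i) P(Y|D,T,c_i). No
    geometric-mean approximation is involved.
    """
    conditional = np.asarray(conditional, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if conditional.shape[-2] != weights.shape[0]:
        raise ValueError(
            f"weight count {weights.shape[0]} does not match rows {conditional.shape[-2]}"
        )
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    return np.tensordot(conditional, weights, axes=([-2], [0])) if conditional.ndim == 2 else np.einsum(
        "bic,i->bc", conditional, weights
    )


# ---------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------

class TAPBModel:
    """Numpy implementation of the full interventional model."""

    def __init__(
        self,
        config: ModelConfig,
        dictionary: ConfounderDictionary | None = None,
        seed: int = 0,
    ):
        self.config = config
        if config.use_cam or config.use_backdoor:
            if dictionary is None:
                raise ValueError("CAM/backdoor require a confounder dictionary")
            if dictionary.size != config.dict_size:
                raise ValueError("dictionary size does not match config.dict_size")
        self.dictionary = dictionary
        self.params: dict[str, Tensor] = {}
        self._rope_cache: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        self._rng = np.random.default_rng(seed)
        self._build()

    # -- parameter management ------------------------------------------
    def _param(self, name: str, shape: tuple[int, ...], scale: float | None = None) -> Tensor:
        if scale is None:
            scale = 1.0 / np.sqrt(shape[0])
        t = Tensor((self._rng.standard_normal(shape) * scale).astype(DTYPE), requires_grad=True)
        self.params[name] = t
        return t

    def _zeros(self, name: str, shape: tuple[int, ...]) -> Tensor:
        t = Tensor(np.zeros(shape, dtype=DTYPE), requires_grad=True)
        self.params[name] = t
        return t

    def _ones(self, name: str, shape: tuple[int, ...]) -> Tensor:
        t = Tensor(np.ones(shape, dtype=DTYPE), requires_grad=True)
        self.params[name] = t
        return t

    def _linear_params(self, name: str, d_in: int, d_out: int) -> None:
        self._param(f"{name}.W", (d_in, d_out))
        self._zeros(f"{name}.b", (d_out,))

    def _ln_params(self, name: str, d: int) -> None:
        self._ones(f"{name}.g", (d,))
        self._zeros(f"{name}.b", (d,))

    def _build(self) -> None:
        cfg = self.config
        self._param("embed", (cfg.vocab_size, cfg.d_model), scale=1.0 / np.sqrt(cfg.d_model))
        for i in range(cfg.n_encoder_layers):
            p = f"enc{i}"
            for proj in ("q", "k", "v", "o"):
                self._linear_params(f"{p}.self.{proj}", cfg.d_model, cfg.d_model)
            self._ln_params(f"{p}.ln1", cfg.d_model)
            self._linear_params(f"{p}.ffn.1", cfg.d_model, cfg.d_ff)
            self._linear_params(f"{p}.ffn.2", cfg.d_ff, cfg.d_model)
            self._ln_params(f"{p}.ln2", cfg.d_model)
        if cfg.use_cam:
            self._linear_params("cam.q", cfg.d_target, cfg.d_target)
            self._linear_params("cam.k", cfg.d_target, cfg.d_target)
            self._linear_params("cam.v", cfg.d_target, cfg.d_target)
            self._linear_params("cam.g", cfg.d_target, cfg.d_model)
        else:
            self._linear_params("tproj", cfg.d_target, cfg.d_model)
        for i in range(cfg.n_aggregator_layers):
            p = f"agg{i}"
            for proj in ("q", "k", "v", "o"):
                self._linear_params(f"{p}.self.{proj}", cfg.d_model, cfg.d_model)
            self._ln_params(f"{p}.ln1", cfg.d_model)
            for proj in ("q", "k", "v", "o"):
                self._linear_params(f"{p}.cross.{proj}", cfg.d_model, cfg.d_model)
            self._ln_params(f"{p}.ln2", cfg.d_model)
            self._linear_params(f"{p}.ffn.1", cfg.d_model, cfg.d_ff)
            self._linear_params(f"{p}.ffn.2", cfg.d_ff, cfg.d_model)
            self._ln_params(f"{p}.ln3", cfg.d_model)
        self._linear_params("gy", cfg.d_k, 2)  # shared per-segment head
        self._linear_params("gy_plain", cfg.d_model, 2)  # ablation path
        self._linear_params("gm", cfg.d_model, cfg.vocab_size)  # MLM head

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = np.asarray(v, dtype=self.params[k].data.dtype)

    # -- building blocks -----------------------------------------------
    def _linear(self, name: str, x: Tensor) -> Tensor:
        return x @ self.params[f"{name}.W"] + self.params[f"{name}.b"]

    def _ln(self, name: str, x: Tensor) -> Tensor:
        return layer_norm(x, self.params[f"{name}.g"], self.params[f"{name}.b"])

    def _rope_tables(self, L: int, d_head: int) -> tuple[np.ndarray, np.ndarray]:
        key = (L, d_head)
        if key not in self._rope_cache:
            half = d_head // 2
            freqs = self.config.rope_base ** (-np.arange(half) / half)
            angles = np.outer(np.arange(L), freqs)  # [L, half]
            self._rope_cache[key] = (
                np.cos(angles)[None, None].astype(DTYPE),
                np.sin(angles)[None, None].astype(DTYPE),
            )
        return self._rope_cache[key]

    @staticmethod
    def _apply_rope(x: Tensor, cos: np.ndarray, sin: np.ndarray) -> Tensor:
        # x: [B, H, L, d_head]; rotate channel pairs (half-split layout)
        half = x.shape[-1] // 2
        x1 = x[..., :half]
        x2 = x[..., half:]
        return concat([x1 * cos - x2 * sin, x2 * cos + x1 * sin], axis=-1)

    def _split_heads(self, x: Tensor, H: int) -> Tensor:
        B, L, D = x.shape
        return x.reshape(B, L, H, D // H).transpose(0, 2, 1, 3)

    def _merge_heads(self, x: Tensor) -> Tensor:
        B, H, L, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, L, H * dh)

    def _mha(
        self,
        name: str,
        query: Tensor,
        kv: Tensor,
        key_mask: np.ndarray,
        *,
        rope: bool = False,
    ) -> tuple[Tensor, np.ndarray]:
        """Multi-head attention; returns output and attention weights."""
        cfg = self.config
        H = cfg.n_heads
        q = self._split_heads(self._linear(f"{name}.q", query), H)
        k = self._split_heads(self._linear(f"{name}.k", kv), H)
        v = self._split_heads(self._linear(f"{name}.v", kv), H)
        if rope:
            cos_q, sin_q = self._rope_tables(q.shape[2], q.shape[3])
            q = self._apply_rope(q, cos_q, sin_q)
            cos_k, sin_k = self._rope_tables(k.shape[2], k.shape[3])
            k = self._apply_rope(k, cos_k, sin_k)
        scale = 1.0 / np.sqrt(q.shape[-1])
        scores = (q @ k.swapaxes(-1, -2)) * scale  # [B, H, Lq, Lk]
        mask = key_mask[:, None, None, :]
        attn = softmax(scores, axis=-1, mask=mask)
        out = self._merge_heads(attn @ v)
        return self._linear(f"{name}.o", out), attn.data

    def _ffn(self, name: str, x: Tensor) -> Tensor:
        return self._linear(f"{name}.2", relu(self._linear(f"{name}.1", x)))

    # -- core operations -----------------------------------------------
    def encode_drug(self, token_ids: np.ndarray, mask: np.ndarray) -> Tensor:
        """Token embedding plus rotary-position transformer blocks."""
        cfg = self.config
        token_ids = np.asarray(token_ids, dtype=np.int64)
        if token_ids.max(initial=0) >= cfg.vocab_size or token_ids.min(initial=0) < 0:
            raise ValueError("token id outside vocabulary")
        h = embedding(self.params["embed"], token_ids)
        for i in range(cfg.n_encoder_layers):
            p = f"enc{i}"
            attn_out, _ = self._mha(f"{p}.self", h, h, mask, rope=True)
            h = self._ln(f"{p}.ln1", h + attn_out)
            h = self._ln(f"{p}.ln2", h + self._ffn(f"{p}.ffn", h))
        return h

    def confounder_align(self, E: Tensor, target_mask: np.ndarray) -> Tensor:
        """CAM: inject cluster centers into target features head-by-head.

        Queries come from E split into I heads; keys/values are the
        projected cluster centers. In the literal (default) reading,
        head i sees only center c_i — a singleton key, whose softmax
        weight is identically 1, so head i's output is V_i broadcast
        over positions. With ``cam_full_dictionary`` every head attends
        over all I centers. Heads are concatenated, residually added to
        E, and mapped D_e -> D_m by the linear g.
        """
        cfg = self.config
        if not cfg.use_cam:
            return self._linear("tproj", E)
        I = cfg.dict_size
        d_e = cfg.d_target
        dh = d_e // I
        B, L, _ = E.shape
        q = self._split_heads(self._linear("cam.q", E), I)  # [B, I, L, dh]
        C = Tensor(self.dictionary.centers.astype(DTYPE))  # [I, D_e], constant
        k_full = C @ self.params["cam.k.W"] + self.params["cam.k.b"]  # [I, D_e]
        v_full = C @ self.params["cam.v.W"] + self.params["cam.v.b"]
        scale = 1.0 / np.sqrt(dh)
        if cfg.cam_full_dictionary:
            # head h attends over all I centers' head-h slices
            k = k_full.reshape(I, I, dh).transpose(1, 0, 2)  # [head, center, dh]
            v = v_full.reshape(I, I, dh).transpose(1, 0, 2)
            scores = (q @ k.swapaxes(-1, -2).reshape(1, I, dh, I)) * scale  # [B, I, L, I]
            attn = softmax(scores, axis=-1)
            heads = attn @ v.reshape(1, I, I, dh)  # [B, I, L, dh]
        else:
            # head i: singleton key/value = head-i slice of projected c_i
            idx = np.arange(I)
            k = k_full.reshape(I, I, dh)[idx, idx]  # [I, dh]
            v = v_full.reshape(I, I, dh)[idx, idx]
            scores = (q @ k.reshape(1, I, dh, 1)) * scale  # [B, I, L, 1]
            attn = softmax(scores, axis=-1)  # identically 1 over singleton
            heads = attn @ v.reshape(1, I, 1, dh)  # [B, I, L, dh]
        aligned = self._merge_heads(heads)  # [B, L, D_e]
        return self._linear("cam.g", aligned + E)

    def aggregate(
        self, D: Tensor, T: Tensor, drug_mask: np.ndarray, target_mask: np.ndarray
    ) -> tuple[Tensor, dict[str, np.ndarray]]:
        """Stacked self-attention / cross-attention / FFN fusion blocks.

        Returns the fused feature F (or, under ``partition_pre_ffn``,
        the pre-FFN output of the last block) and the final block's
        attention maps for interpretability.
        """
        cfg = self.config
        F = D
        maps: dict[str, np.ndarray] = {}
        pre_ffn = None
        for i in range(cfg.n_aggregator_layers):
            p = f"agg{i}"
            self_out, self_map = self._mha(f"{p}.self", F, F, drug_mask, rope=True)
            F = self._ln(f"{p}.ln1", F + self_out)
            cross_out, cross_map = self._mha(f"{p}.cross", F, T, target_mask)
            F = self._ln(f"{p}.ln2", F + cross_out)
            if i == cfg.n_aggregator_layers - 1:
                pre_ffn = F
                maps["self"] = self_map
                maps["cross"] = cross_map
            F = self._ln(f"{p}.ln3", F + self._ffn(f"{p}.ffn", F))
        if cfg.partition_pre_ffn:
            return pre_ffn, maps
        return F, maps

    def partition_by_confounder(self, F: Tensor) -> list[Tensor]:
        """Split F channel-wise into I contiguous head-order segments."""
        cfg = self.config
        if F.shape[-1] % cfg.dict_size:
            raise ValueError("feature width is not divisible by the dictionary size")
        dk = F.shape[-1] // cfg.dict_size
        return [F[..., i * dk : (i + 1) * dk] for i in range(cfg.dict_size)]

    @staticmethod
    def _masked_pool(x: Tensor, mask: np.ndarray) -> Tensor:
        counts = mask.sum(axis=-1)
        if (counts == 0).any():
            raise ValueError("cannot pool an all-padding sequence")
        w = (mask / counts[:, None]).astype(DTYPE)  # [B, L]
        return (x * w[:, :, None]).sum(axis=1)

    def conditional_probabilities(
        self, segments: Sequence[Tensor], drug_mask: np.ndarray
    ) -> Tensor:
        """Masked-pool each segment and apply the shared two-class head."""
        rows = []
        for seg in segments:
            pooled = self._masked_pool(seg, drug_mask)  # [B, d_k]
            logits = self._linear("gy", pooled)
            rows.append(softmax(logits, axis=-1).reshape(-1, 1, 2))
        return concat(rows, axis=1)  # [B, I, 2]

    def backdoor(self, conditional: Tensor) -> Tensor:
        """P(Y|D,do(T)) as the exact weighted sum over cluster rows."""
        w = self.dictionary.weights.astype(DTYPE)
        return (conditional * w[None, :, None]).sum(axis=1)

    # -- losses --------------------------------------------------------
    @staticmethod
    def classification_loss(probs: Tensor, labels: np.ndarray) -> Tensor:
        """Mean cross-entropy on probability rows, log clamped at 1e-12."""
        labels = np.asarray(labels, dtype=np.int64)
        p_true = probs[np.arange(labels.size), labels]
        return -(p_true.clip_min(LOG_FLOOR).log().mean())

    def mlm_loss(
        self, hidden: Tensor, selection: np.ndarray, true_ids: np.ndarray
    ) -> Tensor:
        """Mean negative log-likelihood of true tokens at selected positions."""
        if not selection.any():
            return Tensor(0.0)
        logits = self._linear("gm", hidden)  # [B, L, V]
        probs = softmax(logits, axis=-1)
        b, l = np.nonzero(selection)
        p_true = probs[b, l, true_ids[b, l]]
        return -(p_true.clip_min(LOG_FLOOR).log().mean())

    @staticmethod
    def total_loss(loss_b: Tensor, loss_mlm: Tensor | None, config: ModelConfig) -> Tensor:
        """Unit-weight sum; the MLM term is dropped when its switch is off."""
        if loss_mlm is None or not config.use_mlm:
            return loss_b
        return loss_b + loss_mlm

    # -- forward -------------------------------------------------------
    def forward(
        self,
        token_ids: np.ndarray,
        drug_mask: np.ndarray,
        target_features: np.ndarray,
        target_mask: np.ndarray,
        *,
        mlm_selection: np.ndarray | None = None,
        mlm_true_ids: np.ndarray | None = None,
        drug_override: np.ndarray | None = None,
        target_override: np.ndarray | None = None,
    ) -> dict:
        """Full forward pass.

        ``drug_override`` / ``target_override`` replace the respective
        branch's feature tensor (shape [B, L, D_m]) before fusion — the
        mechanism of the random-feature bias probe. Returns a bundle
        with conditional rows, the backdoor and plain probability rows,
        the prediction path actually in use, pooled classification
        features, attention maps and branch features.
        """
        cfg = self.config
        if drug_override is not None:
            D = Tensor(np.asarray(drug_override, dtype=DTYPE))
        else:
            D = self.encode_drug(token_ids, drug_mask)
        if target_override is not None:
            T = Tensor(np.asarray(target_override, dtype=DTYPE))
        else:
            E = Tensor(np.asarray(target_features, dtype=DTYPE))
            T = self.confounder_align(E, target_mask)
        F, maps = self.aggregate(D, T, drug_mask, target_mask)
        pooled_full = self._masked_pool(F, drug_mask)  # [B, D_m]
        plain = softmax(self._linear("gy_plain", pooled_full), axis=-1)
        conditional = None
        backdoor = None
        if cfg.use_backdoor:
            segments = self.partition_by_confounder(F)
            conditional = self.conditional_probabilities(segments, drug_mask)
            backdoor = self.backdoor(conditional)
            prob = backdoor
        else:
            prob = plain
        bundle = {
            "conditional": conditional,
            "backdoor": backdoor,
            "plain": plain,
            "prob": prob,
            "pooled": pooled_full,
            "attention": maps,
            "drug_features": D,
            "target_features": T,
        }
        if cfg.use_mlm and mlm_selection is not None and mlm_true_ids is not None:
            bundle["drug_hidden"] = D
            bundle["mlm_selection"] = mlm_selection
            bundle["mlm_true_ids"] = mlm_true_ids
        return bundle

    # -- persistence ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"param:{k}": v.data for k, v in self.params.items()}
        if self.dictionary is not None:
            arrays["dict:centers"] = self.dictionary.centers
            arrays["dict:weights"] = self.dictionary.weights
        np.savez(path, config=json.dumps(asdict(self.config)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TAPBModel":
        with np.load(path, allow_pickle=False) as data:
            cfg = ModelConfig(**json.loads(str(data["config"])))
            dictionary = None
            if "dict:centers" in data:
                dictionary = ConfounderDictionary(data["dict:centers"], data["dict:weights"])
            model = cls(cfg, dictionary=dictionary, seed=0)
            state = {
                k.removeprefix("param:"): data[k]
                for k in data.files
                if k.startswith("param:")
            }
            model.load_state_dict(state)
        return model
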