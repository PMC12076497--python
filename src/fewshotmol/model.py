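"""The few-shot activity predictor.

Architecture, given a support set of labeled molecules and query
molecules:

1. **Encoder** — a row-wise two-layer perceptron maps each molecule's
   feature vector to a d-dimensional embedding (layer-normalized).
2. **Context module** — each embedding is enriched independently by
   retrieving from a large frozen *context set* of reference-molecule
   embeddings.  Retrieval is one step of a modern-Hopfield-network
   update, i.e. scaled dot-product attention over the context memory
   with inverse temperature ``beta = retrieval_beta / sqrt(d)``,
   followed by a residual connection and layer normalization.
3. **Cross-attention module** — for each query separately, joint
   self-attention over the token set {query} ∪ support shares
   information between the query and the support molecules.  Labels are
   *not* visible at this stage.
4. **Similarity module** — the predicted activity is
   ``sigmoid((scale / S) * sum_s cos(q', s'_s) * (2 y_s - 1))``:
   cosine similarities to the support embeddings weight the support
   labels (mapped to ±1), averaged so the logit scale is stable in the
   support size; ``scale`` is a learnable positive scalar
   (softplus-parameterized).

Because labels enter only in step 4 as ±1 weights, flipping every
support label maps each score p to exactly 1 - p; the test suite
asserts this as a contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import _autodiff as ad
from .chem_io import FeatureStandardizer, Featurizer
from .exceptions import (
    DimensionMismatch,
    EmptyContext,
    EmptySupportClass,
    ZeroVector,
)

CHECKPOINT_VERSION = 1


@dataclass
class ModelConfig:
    """Architecture hyperparameters (sized for CPU training)."""

    feature_dim: int
    embed_dim: int = 8
    hidden_dim: int = 128
    context_heads: int = 1
    cross_heads: int = 1
    retrieval_beta: float = 1.0
    similarity_scale_init: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.embed_dim <= 0 or self.feature_dim <= 0:
            raise DimensionMismatch("dims must be positive")
        if self.embed_dim % self.context_heads or self.embed_dim % self.cross_heads:
            raise DimensionMismatch("embed_dim must be divisible by head counts")
        if self.retrieval_beta <= 0 or self.similarity_scale_init <= 0:
            raise ValueError("retrieval_beta and similarity_scale_init must be > 0")


@dataclass
class ContextSet:
    """Frozen matrix of reference-molecule embeddings [M x d]."""

    embeddings: np.ndarray
    frozen: bool = True

    def __post_init__(self):
        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)
        if self.embeddings.ndim != 2 or self.embeddings.shape[0] < 1:
            raise EmptyContext("context set needs at least one embedding row")


@dataclass
class SupportSet:
    """Labeled support molecules conditioning one prediction."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.features = np.asarray(self.features)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.features.ndim != 2 or len(self.features) != len(self.labels):
            raise DimensionMismatch("support features/labels misaligned")
        if len(self.labels) < 2:
            raise EmptySupportClass("support set needs at least 2 molecules")
        if self.labels.min() == self.labels.max():
            raise EmptySupportClass(
                "support set needs at least one active and one inactive"
            )


@dataclass
class PredictionTable:
    """Per-query predicted activity scores, aligned with input SMILES."""

    smiles: list
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.smiles) != len(self.scores):
            raise DimensionMismatch("one score per query required")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("scores must lie in [0, 1]")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"smiles": self.smiles, "prediction": self.scores})

    def sorted_by_score(self) -> "PredictionTable":
        # descending score; ties keep input order (stable sort)
        order = np.argsort(-self.scores, kind="stable")
        return PredictionTable(
            [self.smiles[i] for i in order], self.scores[order]
        )


# ---------------------------------------------------------------------------
# parameter initialization
# ---------------------------------------------------------------------------


def init_params(config: ModelConfig) -> dict:
    """Glorot-initialized parameter tensors, deterministic in config.seed."""
    rng = np.random.default_rng([int(config.seed), 0x1A17])
    D, d, h = config.feature_dim, config.embed_dim, config.hidden_dim

    def glorot(fan_in, fan_out):
        s = np.sqrt(2.0 / (fan_in + fan_out))
        return ad.Tensor(rng.normal(0.0, s, size=(fan_in, fan_out)), requires_grad=True)

    def zeros(*shape):
        return ad.Tensor(np.zeros(shape), requires_grad=True)

    def ones(*shape):
        return ad.Tensor(np.ones(shape), requires_grad=True)

    params = {
        "enc_W1": glorot(D, h),
        "enc_b1": zeros(h),
        "enc_W2": glorot(h, d),
        "enc_b2": zeros(d),
        "enc_ln_g": ones(d),
        "enc_ln_b": zeros(d),
        "sim_raw_scale": ad.Tensor(
            np.array([np.log(np.expm1(config.similarity_scale_init))]),
            requires_grad=True,
        ),
    }
    for block in ("ctx", "cross"):
        for w in ("Wq", "Wk", "Wv", "Wo"):
            params[f"{block}_{w}"] = glorot(d, d)
        params[f"{block}_ln_g"] = ones(d)
        params[f"{block}_ln_b"] = zeros(d)
    return params


# ---------------------------------------------------------------------------
# forward pass (autodiff tensors; used for both training and inference)
# ---------------------------------------------------------------------------


def _split_heads(x: ad.Tensor, heads: int) -> ad.Tensor:
    """[..., T, d] -> [..., heads, T, d/heads]."""
    *lead, T, d = x.shape
    x = ad.reshape(x, (*lead, T, heads, d // heads))
    axes = tuple(range(len(lead))) + (
        len(lead) + 1,
        len(lead),
        len(lead) + 2,
    )
    return ad.transpose(x, axes)


def _merge_heads(x: ad.Tensor) -> ad.Tensor:
    """[..., heads, T, dh] -> [..., T, heads*dh]."""
    *lead, h, T, dh = x.shape
    axes = tuple(range(len(lead))) + (len(lead) + 1, len(lead), len(lead) + 2)
    x = ad.transpose(x, axes)
    return ad.reshape(x, (*lead, T, h * dh))


def _attention_block(x, memory, params, prefix, heads, beta):
    """One attention update with residual + layer norm.

    x: [..., T, d]; memory: [..., M, d] (may broadcast against x's batch).
    """
    Q = _split_heads(ad.matmul(x, params[f"{prefix}_Wq"]), heads)
    K = _split_heads(ad.matmul(memory, params[f"{prefix}_Wk"]), heads)
    V = _split_heads(ad.matmul(memory, params[f"{prefix}_Wv"]), heads)
    scores = ad.mul(
        ad.matmul(Q, ad.transpose(K, tuple(range(K.ndim - 2)) + (K.ndim - 1, K.ndim - 2))),
        beta,
    )
    A = ad.softmax(scores, axis=-1)
    out = _merge_heads(ad.matmul(A, V))
    out = ad.matmul(out, params[f"{prefix}_Wo"])
    return ad.layer_norm(
        ad.add(x, out), params[f"{prefix}_ln_g"], params[f"{prefix}_ln_b"]
    )


def encode_t(params, X: ad.Tensor) -> ad.Tensor:
    """Row-wise encoder: [N x D] -> [N x d]."""
    h = ad.relu(ad.add(ad.matmul(X, params["enc_W1"]), params["enc_b1"]))
    h = ad.add(ad.matmul(h, params["enc_W2"]), params["enc_b2"])
    return ad.layer_norm(h, params["enc_ln_g"], params["enc_ln_b"])


def context_enrich_t(params, config: ModelConfig, Z: ad.Tensor, C: ad.Tensor):
    """Enrich each embedding row independently from the context memory."""
    if C.shape[0] < 1:
        raise EmptyContext("context set is empty")
    beta = config.retrieval_beta / np.sqrt(config.embed_dim)
    N, d = Z.shape
    x = ad.reshape(Z, (N, 1, d))  # each molecule is its own batch element
    y = _attention_block(x, C, params, "ctx", config.context_heads, beta)
    return ad.reshape(y, (N, d))


def cross_attend_t(params, config: ModelConfig, tokens: ad.Tensor) -> ad.Tensor:
    """Joint self-attention over [B x (S+1) x d] token sets."""
    beta = 1.0 / np.sqrt(config.embed_dim)
    return _attention_block(
        tokens, tokens, params, "cross", config.cross_heads, beta
    )


def similarity_logits_t(q: ad.Tensor, s: ad.Tensor, labels: np.ndarray, scale):
    """Cosine-weighted label aggregation -> logits [B].

    q: [B x d]; s: [B x S x d]; labels: binary [S]; scale: Tensor (1,).
    """
    B, d = q.shape
    S = s.shape[1]
    qn = _l2_normalize(q)
    sn = _l2_normalize(s)
    cos = ad.tsum(ad.mul(ad.reshape(qn, (B, 1, d)), sn), axis=-1)  # [B, S]
    signs = (2.0 * np.asarray(labels, dtype=np.float64) - 1.0)
    weighted = ad.tmean(ad.mul(cos, signs), axis=-1)  # [B]
    return ad.mul(weighted, ad.reshape(scale, ()))


def _l2_normalize(x: ad.Tensor) -> ad.Tensor:
    norm2 = ad.tsum(ad.mul(x, x), axis=-1, keepdims=True)
    if np.any(norm2.value <= 1e-24):
        raise ZeroVector("zero-norm embedding: cosine similarity undefined")
    return ad.mul(x, ad.power(norm2, -0.5))


def forward_scores_t(params, config, support_X, support_y, query_X, context_emb):
    """Full pipeline -> logits Tensor [Q]. All inputs may be Tensors or arrays."""
    support_X = ad.as_tensor(support_X)
    query_X = ad.as_tensor(query_X)
    context_emb = ad.as_tensor(context_emb)
    if support_X.shape[1] != config.feature_dim:
        raise DimensionMismatch(
            f"feature dim {support_X.shape[1]} != config {config.feature_dim}"
        )
    E_s = encode_t(params, support_X)
    E_q = encode_t(params, query_X)
    Z_s = context_enrich_t(params, config, E_s, context_emb)
    Z_q = context_enrich_t(params, config, E_q, context_emb)
    Q, d = Z_q.shape
    S = Z_s.shape[0]
    tokens = ad.concat(
        [
            ad.reshape(Z_q, (Q, 1, d)),
            ad.broadcast_to(ad.reshape(Z_s, (1, S, d)), (Q, S, d)),
        ],
        axis=1,
    )
    T = cross_attend_t(params, config, tokens)
    q_prime = ad.reshape(T[:, 0:1, :], (Q, d))
    s_prime = T[:, 1:, :]
    scale = ad.softplus(params["sim_raw_scale"])
    return similarity_logits_t(q_prime, s_prime, support_y, scale)


# ---------------------------------------------------------------------------
# user-facing model object
# ---------------------------------------------------------------------------


class FewShotModel:
    """A trained (or freshly initialized) few-shot predictor.

    Bundles architecture config, weights, the frozen context set, and the
    featurizer whose standardizer statistics were frozen at training time.
    """

    def __init__(
        self,
        config: ModelConfig,
        params: dict | None = None,
        context: ContextSet | None = None,
        featurizer: Featurizer | None = None,
    ):
        self.config = config
        self.params = params if params is not None else init_params(config)
        self.context = context
        self.featurizer = featurizer

    # -- spec operation surfaces (numpy in / numpy out) ------------------
    def encode(self, features: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if X.shape[1] != self.config.feature_dim:
            raise DimensionMismatch(
                f"feature dim {X.shape[1]} != config {self.config.feature_dim}"
            )
        return encode_t(self.params, ad.Tensor(X)).value

    def context_enrich(self, embeddings: np.ndarray) -> np.ndarray:
        if self.context is None:
            raise EmptyContext("model has no context set")
        Z = np.atleast_2d(np.asarray(embeddings, dtype=np.float64))
        if Z.shape[1] != self.config.embed_dim:
            raise DimensionMismatch("embedding dim mismatch")
        return context_enrich_t(
            self.params, self.config, ad.Tensor(Z), ad.Tensor(self.context.embeddings)
        ).value

    def cross_attend(self, query_emb: np.ndarray, support_emb: np.ndarray):
        q = np.asarray(query_emb, dtype=np.float64).reshape(1, -1)
        S = np.atleast_2d(np.asarray(support_emb, dtype=np.float64))
        if S.shape[0] < 2:
            raise DimensionMismatch("cross-attention expects S >= 2 support rows")
        tokens = np.concatenate([q[:, None, :], S[None, :, :]], axis=1)
        out = cross_attend_t(self.params, self.config, ad.Tensor(tokens)).value
        return out[0, 0], out[0, 1:]

    def similarity_predict(self, query_emb, support_emb, labels, scale=None):
        q = np.asarray(query_emb, dtype=np.float64).reshape(1, -1)
        S = np.atleast_2d(np.asarray(support_emb, dtype=np.float64))
        scale_t = (
            ad.softplus(self.params["sim_raw_scale"])
            if scale is None
            else ad.Tensor(np.array([float(scale)]))
        )
        logits = similarity_logits_t(
            ad.Tensor(q), ad.Tensor(S[None, :, :]), labels, scale_t
        )
        return float(ad.sigmoid(logits).value[0])

    # -- scoring -----------------------------------------------------------
    def predict_scores(
        self, support_X: np.ndarray, support_y: np.ndarray, query_X: np.ndarray
    ) -> np.ndarray:
        """Scores in (0,1) for query feature rows given a labeled support."""
        SupportSet(support_X, support_y)  # validates the invariant
        if self.context is None:
            raise EmptyContext("model has no context set")
        logits = forward_scores_t(
            self.params,
            self.config,
            np.asarray(support_X, dtype=np.float64),
            np.asarray(support_y),
            np.atleast_2d(np.asarray(query_X, dtype=np.float64)),
            self.context.embeddings,
        )
        return ad.sigmoid(logits).value

    def predict(self, actives, inactives, queries) -> PredictionTable:
        """Predict activities for query molecules given labeled records.

        All inputs are lists of :class:`~fewshotmol.chem_io.MoleculeRecord`
        (featurized, or featurizable through the model's featurizer).
        """
        return _predict_records(self, actives, inactives, queries)

    # -- persistence --------------------------------------------------------
    def _meta(self) -> dict:
        return {
            "config": asdict(self.config),
            "standardizer": (
                self.featurizer.standardizer.to_dict()
                if self.featurizer is not None
                and self.featurizer.standardizer.fitted
                else None
            ),
        }

    def _arrays(self, prefix: str = "") -> dict:
        arrays = {f"{prefix}param__{k}": t.value for k, t in self.params.items()}
        if self.context is not None:
            arrays[f"{prefix}context_embeddings"] = self.context.embeddings
        return arrays

    def save(self, path) -> None:
        """Write a single-archive checkpoint (.npz with a JSON header)."""
        meta = {"version": CHECKPOINT_VERSION, **self._meta()}
        np.savez(path, meta=np.bytes_(json.dumps(meta).encode()), **self._arrays())

    @classmethod
    def _from_archive(cls, z, meta, prefix: str = "") -> "FewShotModel":
        config = ModelConfig(**meta["config"])
        start = f"{prefix}param__"
        params = {
            k[len(start):]: ad.Tensor(z[k], requires_grad=True)
            for k in z.files
            if k.startswith(start)
        }
        context = (
            ContextSet(z[f"{prefix}context_embeddings"])
            if f"{prefix}context_embeddings" in z.files
            else None
        )
        featurizer = None
        if meta.get("standardizer") is not None:
            featurizer = Featurizer(
                FeatureStandardizer.from_dict(meta["standardizer"])
            )
        return cls(config, params, context, featurizer)

    @classmethod
    def load(cls, path) -> "FewShotModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            if meta["version"] != CHECKPOINT_VERSION:
                raise ValueError(
                    f"unsupported checkpoint version {meta['version']}"
                )
            if meta.get("n_members"):
                raise ValueError(
                    "checkpoint holds an ensemble; use load_model()"
                )
            return cls._from_archive(z, meta)


class FewShotEnsemble:
    """Average of independently trained few-shot predictors.

    Score averaging preserves every algebraic contract of the single
    model (support-permutation invariance, per-query independence,
    context-permutation invariance, and exact label-flip antisymmetry,
    since mean(1 - p_i) = 1 - mean(p_i)) while reducing the variance of
    the learned metric.
    """

    def __init__(self, members: list):
        if not members:
            raise ValueError("ensemble needs at least one member")
        self.members = list(members)

    @property
    def featurizer(self):
        return self.members[0].featurizer

    @property
    def config(self):
        return self.members[0].config

    def predict_scores(self, support_X, support_y, query_X) -> np.ndarray:
        scores = [
            m.predict_scores(support_X, support_y, query_X)
            for m in self.members
        ]
        return np.mean(scores, axis=0)

    def predict(self, actives, inactives, queries) -> PredictionTable:
        return _predict_records(self, actives, inactives, queries)

    def save(self, path) -> None:
        meta = {
            "version": CHECKPOINT_VERSION,
            "n_members": len(self.members),
            "members": [m._meta() for m in self.members],
            **self.members[0]._meta(),
        }
        arrays = {}
        for i, m in enumerate(self.members):
            arrays.update(m._arrays(prefix=f"m{i}__"))
        np.savez(path, meta=np.bytes_(json.dumps(meta).encode()), **arrays)

    @classmethod
    def load(cls, path) -> "FewShotEnsemble":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            if not meta.get("n_members"):
                raise ValueError("checkpoint holds a single model")
            members = [
                FewShotModel._from_archive(z, mmeta, prefix=f"m{i}__")
                for i, mmeta in enumerate(meta["members"])
            ]
        return cls(members)


def load_model(path):
    """Load a checkpoint, dispatching on single model vs ensemble."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
    if meta.get("n_members"):
        return FewShotEnsemble.load(path)
    return FewShotModel.load(path)


def _predict_records(scorer, actives, inactives, queries) -> PredictionTable:
    if len(actives) < 1 or len(inactives) < 1:
        raise EmptySupportClass(
            "need at least one active and one inactive support molecule"
        )
    if len(queries) < 1:
        raise EmptySupportClass("need at least one query molecule")

    def feats(records):
        rows = []
        for r in records:
            if r.features is not None:
                rows.append(np.asarray(r.features, dtype=np.float64))
            elif scorer.featurizer is not None:
                rows.append(
                    np.asarray(
                        scorer.featurizer.transform(r.canonical_smiles),
                        dtype=np.float64,
                    )
                )
            else:
                raise DimensionMismatch(
                    "record lacks features and model has no featurizer"
                )
        return np.stack(rows)

    support_X = np.concatenate([feats(actives), feats(inactives)])
    support_y = np.concatenate(
        [np.ones(len(actives), dtype=int), np.zeros(len(inactives), dtype=int)]
    )
    scores = scorer.predict_scores(support_X, support_y, feats(queries))
    return PredictionTable([q.canonical_smiles for q in queries], scores)
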