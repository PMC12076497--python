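"""Episodic meta-training of the few-shot predictor.

Each training step samples one *episode*: a task from the training task
database, a support set drawn without replacement at one of the
evaluation compositions, and held-out labeled queries from the same
task.  The loss is mean binary cross-entropy of the query scores.
Optimization is Adam; after every epoch the median per-task ROC-AUC on
held-out validation tasks is computed, and the parameters with the best
validation score are returned (early stopping on a patience window).

All randomness flows from one integer seed through named substreams
(initialization, episode sampling, validation draws), so a fixed seed
reproduces the loss trajectory bit-for-bit on one platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _autodiff as ad
from . import metrics as M
from .exceptions import (
    DimensionMismatch,
    InsufficientTask,
    NonFiniteLoss,
    NoValidTasks,
)
from .model import (
    ContextSet,
    FewShotEnsemble,
    FewShotModel,
    ModelConfig,
    SupportSet,
    encode_t,
    forward_scores_t,
    init_params,
)
from .taskbench import TaskDB


@dataclass
class Episode:
    """One training unit: support set + disjoint labeled queries."""

    support: SupportSet
    query_features: np.ndarray
    query_labels: np.ndarray
    task_id: str


@dataclass
class TrainConfig:
    """Training-loop settings (YAML/JSON-loadable)."""

    support_size: int = 8
    ratios: tuple = ((1, 7), (2, 6), (4, 4))
    epochs: int = 60
    episodes_per_epoch: int = 100
    lr: float = 1e-3
    lr_min_factor: float = 0.05  # cosine decay floor as a fraction of lr
    weight_decay: float = 3e-3
    patience: int = 60
    n_members: int = 2  # independently trained members averaged at prediction
    ema_decay: float = 0.995  # Polyak averaging of weights; 0 disables
    query_cap: int = 64
    val_query_cap: int = 128
    context_size: int = 512
    embed_dim: int = 8
    hidden_dim: int = 128
    context_heads: int = 1
    cross_heads: int = 1
    retrieval_beta: float = 1.0
    similarity_scale_init: float = 5.0

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if "ratios" in d:
            d["ratios"] = tuple(tuple(r) for r in d["ratios"])
        return cls(**d)


def sample_episode(
    taskdb: TaskDB,
    support_size: int,
    ratio: tuple,
    rng: np.random.Generator,
    featurizer=None,
    feature_lookup=None,
    query_cap: int | None = None,
) -> Episode:
    """Sample one episode at an exact support composition.

    The support is drawn without replacement; queries come from the
    remainder (optionally capped).  Reproducible given the generator
    state.
    """
    n_act, n_inact = ratio
    if n_act + n_inact != support_size:
        raise DimensionMismatch("ratio does not sum to support_size")
    eligible = [
        tid
        for tid in sorted(taskdb.tasks)
        if taskdb.class_counts(tid)[0] >= n_act + 1
        and taskdb.class_counts(tid)[1] >= n_inact + 1
    ]
    if not eligible:
        raise InsufficientTask(
            f"no task can supply a {n_act}:{n_inact} support plus queries"
        )
    task_id = eligible[int(rng.integers(0, len(eligible)))]
    mols, y = taskdb.tasks[task_id]
    act = rng.choice(np.flatnonzero(y == 1), size=n_act, replace=False)
    inact = rng.choice(np.flatnonzero(y == 0), size=n_inact, replace=False)
    sup = np.concatenate([act, inact])
    mask = np.zeros(len(y), dtype=bool)
    mask[sup] = True
    qry = np.flatnonzero(~mask)
    if query_cap is not None and len(qry) > query_cap:
        qry = rng.choice(qry, size=query_cap, replace=False)

    def feats(idx):
        if feature_lookup is not None:
            return np.stack(
                [feature_lookup[mols[i]] for i in idx]
            ).astype(np.float64)
        return np.stack(
            [featurizer.transform(mols[i]) for i in idx]
        ).astype(np.float64)

    return Episode(
        support=SupportSet(feats(sup), y[sup]),
        query_features=feats(qry),
        query_labels=y[qry].copy(),
        task_id=task_id,
    )


def episode_loss(scores, labels) -> float:
    """Mean binary cross-entropy of probabilistic scores."""
    scores = np.clip(np.asarray(scores, dtype=np.float64), 1e-12, 1 - 1e-12)
    labels = np.asarray(labels, dtype=np.float64)
    if scores.shape != labels.shape:
        raise DimensionMismatch("scores and labels must have equal length")
    return float(
        -np.mean(labels * np.log(scores) + (1 - labels) * np.log(1 - scores))
    )


class _Adam:
    """Adam with decoupled weight decay and an externally set step size."""

    def __init__(self, params: dict, lr: float, weight_decay: float = 0.0):
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}

    def step(self, params: dict) -> None:
        self.t += 1
        for k, p in params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and k.endswith(("W1", "W2", "Wq", "Wk", "Wv", "Wo")):
                p.value -= self.lr * self.weight_decay * p.value
            p.grad = None


def _build_feature_lookup(taskdbs, featurizer):
    lookup = {}
    for db in taskdbs:
        for mols, _ in db.tasks.values():
            for s in mols:
                if s not in lookup:
                    lookup[s] = np.asarray(featurizer.transform(s))
    return lookup


def _validation_auc(params, model_config, cfg, val_db, feature_lookup, context_X, seed):
    """Median per-task AUC over validation tasks with fixed support draws."""
    aucs = []
    context_emb = None  # computed lazily, once per call, under current weights
    half = cfg.support_size // 2
    for tid in sorted(val_db.tasks):
        rng = np.random.default_rng([int(seed), 0x7A1, hash_str(tid)])
        try:
            ep = sample_episode(
                _single_task_db(val_db, tid),
                cfg.support_size,
                (half, cfg.support_size - half),
                rng,
                feature_lookup=feature_lookup,
                query_cap=cfg.val_query_cap,
            )
        except InsufficientTask:
            continue
        if ep.query_labels.min() == ep.query_labels.max():
            continue
        if context_emb is None:
            context_emb = encode_t(params, ad.Tensor(context_X)).value
        logits = forward_scores_t(
            params,
            model_config,
            ep.support.features,
            ep.support.labels,
            ep.query_features,
            context_emb,
        )
        aucs.append(M.auc(ad.sigmoid(logits).value, ep.query_labels))
    if not aucs:
        raise NoValidTasks("no validation task produced an AUC")
    return float(np.median(aucs)), len(aucs)


def hash_str(s: str) -> int:
    import zlib

    return zlib.crc32(s.encode())


def _single_task_db(db: TaskDB, tid: str) -> TaskDB:
    return TaskDB(mode=db.mode, tasks={tid: db.tasks[tid]})


def train(
    train_db: TaskDB,
    val_db: TaskDB,
    featurizer,
    context_smiles,
    config: TrainConfig,
    seed: int = 0,
):
    """Run the episodic loop; return ``(FewShotModel, log_frame)``.

    The returned model carries the weights of the epoch with the best
    median validation AUC and a frozen context set computed under those
    weights.
    """
    feature_lookup = _build_feature_lookup([train_db, val_db], featurizer)
    for s in context_smiles:
        if s not in feature_lookup:
            feature_lookup[s] = np.asarray(featurizer.transform(s))
    feature_dim = next(iter(feature_lookup.values())).shape[0]

    model_config = ModelConfig(
        feature_dim=feature_dim,
        embed_dim=config.embed_dim,
        hidden_dim=config.hidden_dim,
        context_heads=config.context_heads,
        cross_heads=config.cross_heads,
        retrieval_beta=config.retrieval_beta,
        similarity_scale_init=config.similarity_scale_init,
        seed=seed,
    )
    context_X = np.stack(
        [feature_lookup[s] for s in context_smiles]
    ).astype(np.float64)

    params = init_params(model_config)
    opt = _Adam(params, config.lr, config.weight_decay)
    # Polyak (EMA) average of the weights: validation and the shipped
    # checkpoint use the averaged weights, which damps episode noise
    ema = (
        {k: p.value.copy() for k, p in params.items()}
        if config.ema_decay
        else None
    )
    rng_episode = np.random.default_rng([int(seed), 0xE9])

    ratios = tuple(tuple(r) for r in config.ratios)
    usable = [
        r
        for r in ratios
        if any(
            train_db.class_counts(t)[0] >= r[0] + 1
            and train_db.class_counts(t)[1] >= r[1] + 1
            for t in train_db.tasks
        )
    ]
    if len(train_db) < 2 or not usable:
        raise NoValidTasks("training task database cannot serve any ratio")

    log_rows = []
    best = {"auc": -np.inf, "epoch": -1, "params": None}
    epochs_since_best = 0
    for epoch in range(config.epochs):
        # cosine decay of the step size over the epoch budget
        frac = epoch / max(config.epochs - 1, 1)
        floor = config.lr * config.lr_min_factor
        opt.lr = floor + (config.lr - floor) * 0.5 * (1 + np.cos(np.pi * frac))
        losses = []
        for _ in range(config.episodes_per_epoch):
            ratio = usable[int(rng_episode.integers(0, len(usable)))]
            ep = sample_episode(
                train_db,
                config.support_size,
                ratio,
                rng_episode,
                feature_lookup=feature_lookup,
                query_cap=config.query_cap,
            )
            # context memory under current weights, detached: gradients
            # reach the retrieval projections through attention, while the
            # encoder trains through the support/query rows
            context_emb = encode_t(params, ad.Tensor(context_X)).value
            logits = forward_scores_t(
                params,
                model_config,
                ep.support.features,
                ep.support.labels,
                ep.query_features,
                context_emb,
            )
            loss = ad.bce_with_logits(logits, ep.query_labels.astype(np.float64))
            if not np.isfinite(loss.value):
                raise NonFiniteLoss(
                    f"non-finite loss at epoch {epoch}, task {ep.task_id}"
                )
            loss.backward()
            opt.step(params)
            if ema is not None:
                a = config.ema_decay
                for k, p in params.items():
                    ema[k] = a * ema[k] + (1.0 - a) * p.value
            losses.append(float(loss.value))
        eval_params = (
            {k: ad.Tensor(v) for k, v in ema.items()} if ema is not None else params
        )
        val_auc, n_val = _validation_auc(
            eval_params, model_config, config, val_db, feature_lookup, context_X, seed
        )
        log_rows.append(
            {
                "epoch": epoch,
                "mean_loss": float(np.mean(losses)),
                "val_median_auc": val_auc,
                "n_val_tasks": n_val,
            }
        )
        if val_auc > best["auc"]:
            best = {
                "auc": val_auc,
                "epoch": epoch,
                "params": {
                    k: ad.Tensor(p.value.copy(), requires_grad=True)
                    for k, p in eval_params.items()
                },
            }
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best > config.patience:
                break

    final_params = best["params"] if best["params"] is not None else params
    context_emb = encode_t(final_params, ad.Tensor(context_X)).value
    model = FewShotModel(
        config=model_config,
        params=final_params,
        context=ContextSet(context_emb, frozen=True),
        featurizer=featurizer,
    )
    log = pd.DataFrame(log_rows)
    log.attrs["best_epoch"] = best["epoch"]
    log.attrs["best_val_auc"] = best["auc"]
    return model, log


def train_ensemble(
    train_db: TaskDB,
    val_db: TaskDB,
    featurizer,
    context_smiles,
    config: TrainConfig,
    seed: int = 0,
):
    """Train ``config.n_members`` members with derived seeds.

    Returns ``(predictor, log)`` where the predictor is a
    :class:`~fewshotmol.model.FewShotEnsemble` (or the bare model when
    n_members == 1) and the log concatenates per-member logs with a
    ``member`` column.
    """
    members, logs = [], []
    for m in range(max(1, int(config.n_members))):
        member_seed = (int(seed) + 1_000_003 * m) % (2**31)
        model, log = train(
            train_db, val_db, featurizer, context_smiles, config, seed=member_seed
        )
        log = log.assign(member=m)
        members.append(model)
        logs.append(log)
    full_log = pd.concat(logs, ignore_index=True)
    full_log.attrs["best_epoch"] = logs[-1].attrs["best_epoch"]
    full_log.attrs["best_val_auc"] = float(
        np.mean([lg.attrs["best_val_auc"] for lg in logs])
    )
    predictor = members[0] if len(members) == 1 else FewShotEnsemble(members)
    return predictor, full_log
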