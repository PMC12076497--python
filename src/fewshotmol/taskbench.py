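"""Recast a long-format bioactivity table into few-shot tasks and run the
paired benchmark.

The task-construction pipeline applies, in order:

a) drop records from very large high-throughput sources (more than
   ``hts_cap`` data points in the source group);
b) drop data points whose raw molecule string carries conflicting labels
   within a group;
c) keep only molecules whose SMILES the preprocessing accepts
   (canonicalization succeeds); conflicts and duplicates arising after
   canonicalization are resolved the same way as (b);
d) keep only groups with enough actives AND inactives (by-target mode:
   50/50; by-assay mode: 30/30).

Evaluation draws support sets of fixed size and active:inactive ratio
(8 -> 1:7, 2:6, 4:4; 16 -> 2:14, 4:12, 8:8), three draws per cell, and
serves the *identical* support draw to every compared method (paired
design).  The query set is the full remainder of the task.  Method
comparison reports per-cell medians and a two-sided paired Wilcoxon
p-value across (task, draw) pairs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as M
from .chem_io import parse_smiles
from .exceptions import (
    EmptyInput,
    InsufficientTask,
    InvalidSmiles,
    MissingColumn,
    NoTasksSurvive,
    OneClassSupport,
)

#: Ratio labels -> active share of the support set.
RATIO_LABELS = ("1:7", "1:3", "1:1")
_RATIO_PARTS = {"1:7": (1, 7), "1:3": (1, 3), "1:1": (1, 1)}

DEFAULT_MIN_COUNTS = {"by_target": (50, 50), "by_assay": (30, 30)}
DEFAULT_HTS_CAP = 100_000
N_DRAWS = 3


def ratio_counts(support_size: int, ratio: str) -> tuple[int, int]:
    """(n_active, n_inactive) for a support size and ratio label."""
    a, b = _RATIO_PARTS[ratio]
    n_act = support_size * a // (a + b)
    return n_act, support_size - n_act


@dataclass
class AssayRecord:
    """One bioactivity data point in the long-format input table."""

    molecule: str
    group_id: str
    label: int
    source_size: int = 0


@dataclass
class TaskDB:
    """Few-shot tasks surviving the construction filters."""

    mode: str
    tasks: dict  # group_id -> (list of canonical smiles, np.ndarray labels)
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.tasks)

    def class_counts(self, task_id):
        y = self.tasks[task_id][1]
        return int(y.sum()), int(len(y) - y.sum())


def read_assay_csv(path) -> list:
    """Read ``smiles,group_id,label[,source_size]`` into records."""
    from .chem_io import read_table

    df = read_table(path)
    for col in ("smiles", "group_id", "label"):
        if col not in df.columns:
            raise MissingColumn(f"column {col!r} missing from {path}")
    bad = df.index[~df["label"].isin((0, 1))]
    if len(bad):
        raise ValueError(
            f"non-binary label at data row(s) {[int(i) + 1 for i in bad[:5]]}"
        )
    sizes = df["source_size"] if "source_size" in df.columns else np.zeros(len(df))
    return [
        AssayRecord(str(s), str(g), int(l), int(z))
        for s, g, l, z in zip(df["smiles"], df["group_id"], df["label"], sizes)
    ]


def build_taskdb(
    records,
    mode: str = "by_target",
    min_active: int | None = None,
    min_inactive: int | None = None,
    hts_cap: int = DEFAULT_HTS_CAP,
) -> TaskDB:
    """Apply filters a -> d (see module docstring) and assemble tasks."""
    if mode not in DEFAULT_MIN_COUNTS:
        raise ValueError(f"mode must be by_target or by_assay, got {mode!r}")
    if min_active is None:
        min_active = DEFAULT_MIN_COUNTS[mode][0]
    if min_inactive is None:
        min_inactive = DEFAULT_MIN_COUNTS[mode][1]
    records = list(records)
    prov = {"input_records": len(records)}

    # a) HTS-source cap
    kept = [r for r in records if r.source_size <= hts_cap]
    prov["removed_hts"] = len(records) - len(kept)

    # b) conflicting labels on the raw molecule string within a group
    seen_labels: dict = {}
    for r in kept:
        seen_labels.setdefault((r.group_id, r.molecule), set()).add(r.label)
    kept2 = [r for r in kept if len(seen_labels[(r.group_id, r.molecule)]) == 1]
    prov["removed_conflict"] = len(kept) - len(kept2)

    # c) SMILES must canonicalize
    kept3, invalid = [], 0
    for r in kept2:
        try:
            canonical = parse_smiles(r.molecule)
        except (InvalidSmiles, EmptyInput):
            invalid += 1
            continue
        kept3.append(
            AssayRecord(canonical, r.group_id, r.label, r.source_size)
        )
    prov["removed_invalid_smiles"] = invalid

    # post-canonicalization conflicts / duplicates within a group
    canon_labels: dict = {}
    for r in kept3:
        canon_labels.setdefault((r.group_id, r.molecule), set()).add(r.label)
    groups: dict = {}
    seen_in_group: set = set()
    dup_conflicts = 0
    for r in kept3:
        labels = canon_labels[(r.group_id, r.molecule)]
        if len(labels) != 1:
            dup_conflicts += 1
            continue
        if (r.group_id, r.molecule) in seen_in_group:  # dedupe, keep first
            continue
        seen_in_group.add((r.group_id, r.molecule))
        mols, ys = groups.setdefault(r.group_id, ([], []))
        mols.append(r.molecule)
        ys.append(r.label)
    prov["removed_canonical_conflict"] = dup_conflicts

    # d) minimum class counts per group
    tasks = {}
    for gid in sorted(groups):
        mols, ys = groups[gid]
        y = np.asarray(ys, dtype=int)
        if y.sum() >= min_active and (len(y) - y.sum()) >= min_inactive:
            tasks[gid] = (mols, y)
    prov["removed_small_tasks"] = len(groups) - len(tasks)
    prov["kept_tasks"] = len(tasks)

    if not tasks:
        raise NoTasksSurvive(
            f"no group survives the filters (provenance: {prov})"
        )
    return TaskDB(mode=mode, tasks=tasks, provenance=prov)


@dataclass
class SupportDraw:
    """One support/query split of a task (SMILES level)."""

    task_id: str
    support_smiles: list
    support_labels: np.ndarray
    query_smiles: list
    query_labels: np.ndarray


def _cell_rng(seed, task_id, support_size, n_act, n_inact, draw_index):
    # task id enters through a stable hash so adding tasks never
    # reshuffles existing draws
    return np.random.default_rng(
        [int(seed), support_size, n_act, n_inact, draw_index,
         zlib.crc32(task_id.encode())]
    )


def draw_support(
    taskdb: TaskDB,
    task_id: str,
    support_size: int,
    ratio: str,
    draw_index: int,
    seed: int,
) -> SupportDraw:
    """Draw a support set at an exact composition; queries = remainder."""
    n_act, n_inact = ratio_counts(support_size, ratio)
    mols, y = taskdb.tasks[task_id]
    act_idx = np.flatnonzero(y == 1)
    inact_idx = np.flatnonzero(y == 0)
    if len(act_idx) < n_act + 1 or len(inact_idx) < n_inact + 1:
        raise InsufficientTask(
            f"task {task_id}: {len(act_idx)} actives/{len(inact_idx)} inactives "
            f"cannot supply {n_act}:{n_inact} plus leftover queries"
        )
    rng = _cell_rng(seed, task_id, support_size, n_act, n_inact, draw_index)
    sup_act = rng.choice(act_idx, size=n_act, replace=False)
    sup_inact = rng.choice(inact_idx, size=n_inact, replace=False)
    sup = np.concatenate([sup_act, sup_inact])
    in_support = np.zeros(len(y), dtype=bool)
    in_support[sup] = True
    qry = np.flatnonzero(~in_support)
    return SupportDraw(
        task_id=task_id,
        support_smiles=[mols[i] for i in sup],
        support_labels=y[sup].copy(),
        query_smiles=[mols[i] for i in qry],
        query_labels=y[qry].copy(),
    )


def rf_baseline(support_X, support_y, query_X, seed: int = 0) -> np.ndarray:
    """Random-forest baseline fit from scratch on the support set.

    Uses the library default hyperparameters; only the seed is fixed so a
    cell is reproducible.  Returns the positive-class probability.
    """
    from sklearn.ensemble import RandomForestClassifier

    support_y = np.asarray(support_y, dtype=int)
    if support_y.min() == support_y.max():
        raise OneClassSupport("RF baseline needs both classes in the support")
    clf = RandomForestClassifier(random_state=int(seed))
    clf.fit(np.asarray(support_X), support_y)
    proba = clf.predict_proba(np.atleast_2d(np.asarray(query_X)))
    return proba[:, list(clf.classes_).index(1)]


def make_model_method(model):
    """Adapter: a trained few-shot model as a benchmark method."""

    def method(support_X, support_y, query_X, cell_seed):
        return model.predict_scores(support_X, support_y, query_X)

    return method


def make_rf_method():
    """Adapter: the from-scratch RF baseline as a benchmark method."""

    def method(support_X, support_y, query_X, cell_seed):
        return rf_baseline(support_X, support_y, query_X, seed=cell_seed)

    return method


def evaluate(
    taskdb: TaskDB,
    methods: dict,
    featurizer,
    sizes=(8,),
    ratios=RATIO_LABELS,
    seed: int = 0,
    n_draws: int = N_DRAWS,
    bedroc_alpha: float = M.DEFAULT_BEDROC_ALPHA,
):
    """Full factorial benchmark: task x size x ratio x draw x method.

    Every method sees the identical support draw per cell.  Tasks that
    cannot supply a composition are skipped and logged.  Returns
    ``(results_frame, skip_log)``.
    """
    rows, skips = [], []
    feature_cache: dict[str, np.ndarray] = {}

    def feats(smiles_list):
        missing = [s for s in smiles_list if s not in feature_cache]
        for s in missing:
            feature_cache[s] = np.asarray(
                featurizer.transform(s), dtype=np.float64
            )
        return np.stack([feature_cache[s] for s in smiles_list])

    for size in sizes:
        for ratio in ratios:
            n_act, n_inact = ratio_counts(size, ratio)
            for task_id in sorted(taskdb.tasks):
                try:
                    draws = [
                        draw_support(taskdb, task_id, size, ratio, k, seed)
                        for k in range(n_draws)
                    ]
                except InsufficientTask as err:
                    skips.append((task_id, size, ratio, str(err)))
                    continue
                for k, draw in enumerate(draws):
                    sup_X = feats(draw.support_smiles)
                    qry_X = feats(draw.query_smiles)
                    cell_seed = int(
                        _cell_rng(seed, task_id, size, n_act, n_inact, k)
                        .integers(0, 2**31)
                    )
                    for name, method in methods.items():
                        scores = np.asarray(
                            method(sup_X, draw.support_labels, qry_X, cell_seed)
                        )
                        mv = M.metric_vector(
                            scores, draw.query_labels, alpha=bedroc_alpha
                        )
                        rows.append(
                            {
                                "task_id": task_id,
                                "draw_index": k,
                                "method": name,
                                "support_size": size,
                                "ratio": ratio,
                                **mv,
                            }
                        )
    return pd.DataFrame(rows), skips


def compare(results: pd.DataFrame, metric_names, method_a: str, method_b: str):
    """Per (size, ratio, metric): medians, paired Wilcoxon p, star, winner."""
    if isinstance(metric_names, str):
        metric_names = [metric_names]
    out = []
    keys = ["task_id", "draw_index", "support_size", "ratio"]
    a = results[results["method"] == method_a].set_index(keys)
    b = results[results["method"] == method_b].set_index(keys)
    common = a.index.intersection(b.index)
    a, b = a.loc[common], b.loc[common]
    for (size, ratio), idx in a.groupby(["support_size", "ratio"]).groups.items():
        for metric in metric_names:
            va = a.loc[idx, metric].to_numpy(dtype=float)
            vb = b.loc[idx, metric].to_numpy(dtype=float)
            try:
                p = M.paired_wilcoxon(va, vb)
            except Exception as err:
                p, note = np.nan, type(err).__name__
            else:
                note = ""
            med_a, med_b = float(np.median(va)), float(np.median(vb))
            star = bool(np.isfinite(p) and p < 0.05)
            winner = ""
            if star:
                winner = method_a if med_a > med_b else method_b
                if med_a == med_b:  # direction from the mean difference
                    winner = method_a if va.mean() > vb.mean() else method_b
            out.append(
                {
                    "support_size": size,
                    "ratio": ratio,
                    "metric": metric,
                    f"median_{method_a}": med_a,
                    f"median_{method_b}": med_b,
                    "n_pairs": len(va),
                    "p_value": p,
                    "significant": star,
                    "winner": winner,
                    "note": note,
                }
            )
    return pd.DataFrame(out)


def plot_metric_boxes(results: pd.DataFrame, metric: str, path) -> None:
    """Box plots of a metric across tasks/draws, per (size, ratio, method)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sizes = sorted(results["support_size"].unique())
    fig, axes = plt.subplots(
        1, len(sizes), figsize=(5 * len(sizes), 4), squeeze=False
    )
    for ax, size in zip(axes[0], sizes):
        sub = results[results["support_size"] == size]
        labels, data = [], []
        for ratio in RATIO_LABELS:
            for method in sorted(sub["method"].unique()):
                vals = sub[(sub["ratio"] == ratio) & (sub["method"] == method)][
                    metric
                ]
                if len(vals):
                    labels.append(f"{ratio}\n{method}")
                    data.append(vals.to_numpy())
        ax.boxplot(data, tick_labels=labels)
        ax.set_title(f"support size {size}")
        ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
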