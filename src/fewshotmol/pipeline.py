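"""End-to-end orchestration: synthetic corpus -> meta-training -> benchmark.

Shared by the command-line interface, the acceptance script, and the
test suite so that the whole pipeline is deterministic under one master
seed.

Note on task filtering: the strict task-construction thresholds
(50 actives *and* 50 inactives per target; 30/30 per assay) are the
defaults of :func:`fewshotmol.taskbench.build_taskdb` and describe
recast public bioassay data.  The synthetic corpus is built so that
every task can serve the evaluation support compositions, so the
pipeline builds its task databases with the composition-driven minimum
(enough molecules of each class for the largest support draw plus
leftover queries) rather than the public-data thresholds.
"""

from __future__ import annotations

import numpy as np

from . import taskbench as tb
from .chem_io import Featurizer
from .synthdata import SynthConfig, generate_context, generate_database
from .training import TrainConfig, train_ensemble

#: minimum class counts so every ratio at the largest support size works
PIPELINE_MIN_ACTIVE = 10
PIPELINE_MIN_INACTIVE = 16


def split_taskdbs(records, manifest, min_active=PIPELINE_MIN_ACTIVE,
                  min_inactive=PIPELINE_MIN_INACTIVE):
    """Build one TaskDB per split from a generated corpus."""
    dbs = {}
    for split, task_ids in manifest["splits"].items():
        ids = set(task_ids)
        subset = [r for r in records if r.group_id in ids]
        dbs[split] = tb.build_taskdb(
            subset,
            mode="by_target",
            min_active=min_active,
            min_inactive=min_inactive,
            hts_cap=tb.DEFAULT_HTS_CAP,
        )
    return dbs


def fit_featurizer(records, manifest) -> Featurizer:
    """Featurizer with descriptor statistics frozen on the training split."""
    train_ids = set(manifest["splits"]["train"])
    train_mols = sorted({r.molecule for r in records if r.group_id in train_ids})
    return Featurizer().fit(train_mols)


def run_training(records, manifest, train_config: TrainConfig | None = None,
                 seed: int = 0):
    """Meta-train on a generated corpus; return (model, log, taskdbs)."""
    cfg = train_config or TrainConfig()
    dbs = split_taskdbs(records, manifest)
    featurizer = fit_featurizer(records, manifest)
    context_smiles = generate_context(records, manifest, cfg.context_size, seed)
    model, log = train_ensemble(
        dbs["train"], dbs["val"], featurizer, context_smiles, cfg, seed=seed
    )
    return model, log, dbs


def run_benchmark(taskdb, model, sizes=(8,), ratios=tb.RATIO_LABELS,
                  seed: int = 0, n_draws: int = tb.N_DRAWS):
    """Paired evaluation of the few-shot model vs the RF baseline."""
    methods = {
        "fewshot": tb.make_model_method(model),
        "rf": tb.make_rf_method(),
    }
    results, skips = tb.evaluate(
        taskdb,
        methods,
        model.featurizer,
        sizes=sizes,
        ratios=ratios,
        seed=seed,
        n_draws=n_draws,
    )
    from . import metrics as M

    report = tb.compare(results, list(M.METRIC_NAMES), "fewshot", "rf")
    return results, report, skips


def run_full_pipeline(synth_config: SynthConfig | None = None,
                      train_config: TrainConfig | None = None,
                      sizes=(8,), seed: int = 0):
    """synth -> train -> benchmark on the held-out test split.

    Returns a dict with the corpus, manifest, model, training log,
    benchmark results and comparison report.
    """
    scfg = synth_config or SynthConfig(seed=seed)
    records, manifest = generate_database(scfg)
    model, log, dbs = run_training(records, manifest, train_config, seed=seed)
    results, report, skips = run_benchmark(
        dbs["test"], model, sizes=sizes, seed=seed
    )
    return {
        "records": records,
        "manifest": manifest,
        "taskdbs": dbs,
        "model": model,
        "log": log,
        "results": results,
        "report": report,
        "skips": skips,
    }


def shuffle_task_labels(records, seed: int = 0):
    """Negative control: permute observed labels within every task."""
    rng = np.random.default_rng([int(seed), 0x5F])
    by_task: dict = {}
    for i, r in enumerate(records):
        by_task.setdefault(r.group_id, []).append(i)
    out = list(records)
    for task_id in sorted(by_task):
        idx = by_task[task_id]
        labels = [records[i].label for i in idx]
        perm = rng.permutation(len(labels))
        for j, i in enumerate(idx):
            r = records[i]
            out[i] = type(r)(
                molecule=r.molecule,
                group_id=r.group_id,
                label=labels[perm[j]],
                source_size=r.source_size,
            )
    return out
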