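"""Synthetic bioactivity databases with latent task structure.

Emulates a recast public bioassay corpus so that training, benchmarking,
and the whole test suite run with no external download:

* Molecules are valid SMILES assembled from a small fragment grammar
  (scaffold/substituent pieces concatenated into chains and validated
  with RDKit), diverse enough for circular fingerprints to carry signal.
* Each task ``t`` has a latent direction ``w_t`` drawn inside one of a
  few *task families*; a molecule's clean label is
  ``1{ <proj(fp(mol)), w_t> > threshold_t }`` with the threshold set to
  hit a target active fraction, and the observed label flips with a
  configurable noise probability.
* The family structure is what makes transfer possible: held-out tasks
  share a family with training tasks, so a meta-learned model can beat a
  from-scratch baseline at tiny support sizes.

A ground-truth manifest (task directions, thresholds, flip masks, and
the projection seed) suffices to recompute every clean label exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from rdkit import Chem

from .chem_io import Featurizer
from .exceptions import ConfigError, TooFewMolecules
from .taskbench import AssayRecord

#: Fragments safe at any chain position (tail atom can accept one more bond).
CHAIN_FRAGMENTS = (
    "C",
    "CC",
    "CCC",
    "CO",
    "CN",
    "OC",
    "NC",
    "CS",
    "C(C)C",
    "C(=O)N",
    "C(=O)C",
    "C(=O)OC",
    "C=CC",
    "c1ccccc1",
    "c1ccc(F)cc1",
    "c1ccc(Cl)cc1",
    "c1ccncc1",
    "c1ccc(C)nc1",
    "c1cncnc1",
    "c1ccsc1",
    "c1ccoc1",
    "C1CCCCC1",
    "C1CCNCC1",
    "C1CCOCC1",
    "C1CCCC1",
)

#: Fragments only valid as the final piece (tail atom at full valence).
TERMINAL_FRAGMENTS = (
    "C(F)(F)F",
    "C#N",
    "Cl",
    "F",
    "Br",
    "O",
    "N",
    "C(=O)O",
)


@dataclass
class SynthConfig:
    """Generator settings; defaults define the reference synthetic corpus."""

    n_train_tasks: int = 200
    n_val_tasks: int = 20
    n_test_tasks: int = 50
    molecules_per_task: tuple = (120, 300)
    n_task_families: int = 5
    latent_dim: int = 12
    label_noise: float = 0.1
    active_fraction: float = 0.3
    fragment_vocab_size: int = 30
    train_pool_size: int = 6000
    family_spread: float = 0.1
    seed: int = 0

    def __post_init__(self):
        counts = (
            self.n_train_tasks,
            self.n_val_tasks,
            self.n_test_tasks,
            self.n_task_families,
            self.latent_dim,
            self.fragment_vocab_size,
            self.train_pool_size,
        )
        if any(int(c) <= 0 for c in counts):
            raise ConfigError("all counts must be positive")
        if not (0.0 <= self.label_noise < 0.5):
            raise ConfigError("label_noise must lie in [0, 0.5)")
        if not (0.0 < self.active_fraction < 1.0):
            raise ConfigError("active_fraction must lie in (0, 1)")
        lo, hi = self.molecules_per_task
        if lo < 4 or hi < lo:
            raise ConfigError("molecules_per_task range invalid")
        if self.fragment_vocab_size > len(CHAIN_FRAGMENTS) + len(TERMINAL_FRAGMENTS):
            raise ConfigError("fragment_vocab_size exceeds the curated grammar")

    @property
    def n_tasks(self) -> int:
        return self.n_train_tasks + self.n_val_tasks + self.n_test_tasks


def _vocab(config: SynthConfig):
    n_chain = min(len(CHAIN_FRAGMENTS), max(2, config.fragment_vocab_size * 3 // 4))
    n_term = min(len(TERMINAL_FRAGMENTS), config.fragment_vocab_size - n_chain)
    return CHAIN_FRAGMENTS[:n_chain], TERMINAL_FRAGMENTS[: max(n_term, 1)]


def _sample_molecule(rng, chain, terminal) -> str | None:
    """Assemble 2-4 fragments into a chain; return canonical SMILES or None."""
    k = int(rng.integers(2, 5))
    pieces = [chain[int(i)] for i in rng.integers(0, len(chain), size=k - 1)]
    tail_pool = chain + terminal
    pieces.append(tail_pool[int(rng.integers(0, len(tail_pool)))])
    mol = Chem.MolFromSmiles("".join(pieces))
    return None if mol is None else Chem.MolToSmiles(mol)


def _generate_unique(rng, chain, terminal, n, taken: set, max_tries=None) -> list:
    out = []
    tries = 0
    limit = max_tries or 200 * n + 1000
    while len(out) < n:
        tries += 1
        if tries > limit:
            raise TooFewMolecules(
                f"fragment grammar exhausted after {tries} tries "
                f"({len(out)}/{n} molecules)"
            )
        smi = _sample_molecule(rng, chain, terminal)
        if smi is None or smi in taken:
            continue
        taken.add(smi)
        out.append(smi)
    return out


def _projection(seed: int, latent_dim: int, fp_bits: int = 1024) -> np.ndarray:
    """Fixed random projection fingerprint-space -> latent space."""
    rng = np.random.default_rng([int(seed), 0x50])
    return rng.normal(0.0, 1.0 / np.sqrt(fp_bits), size=(fp_bits, latent_dim))


def latent_coords(smiles_list, seed: int, latent_dim: int) -> np.ndarray:
    """Project fingerprints of molecules into the labeling latent space."""
    feat = Featurizer()
    P = _projection(seed, latent_dim)
    fps = np.stack([feat.fingerprint(s) for s in smiles_list]).astype(np.float64)
    return fps @ P


def generate_database(config: SynthConfig):
    """Generate the corpus.

    Returns ``(records, manifest)``: a flat list of
    :class:`~fewshotmol.taskbench.AssayRecord` and a JSON-serializable
    manifest with the full ground truth (task directions ``w_t``,
    thresholds, flipped-record ids, split membership, projection seed).
    """
    rng_mol = np.random.default_rng([int(config.seed), 1])
    rng_task = np.random.default_rng([int(config.seed), 2])
    rng_noise = np.random.default_rng([int(config.seed), 3])
    chain, terminal = _vocab(config)

    taken: set = set()
    train_pool = _generate_unique(rng_mol, chain, terminal, config.train_pool_size, taken)

    feat = Featurizer()
    P = _projection(config.seed, config.latent_dim)
    fp_cache: dict[str, np.ndarray] = {}

    def latent(smiles_list):
        rows = []
        for s in smiles_list:
            z = fp_cache.get(s)
            if z is None:
                z = feat.fingerprint(s).astype(np.float64) @ P
                fp_cache[s] = z
            rows.append(z)
        return np.stack(rows)

    centers = rng_task.normal(size=(config.n_task_families, config.latent_dim))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)

    split_of = (
        ["train"] * config.n_train_tasks
        + ["val"] * config.n_val_tasks
        + ["test"] * config.n_test_tasks
    )
    records: list[AssayRecord] = []
    manifest_tasks = {}
    lo, hi = config.molecules_per_task
    for t in range(config.n_tasks):
        split = split_of[t]
        task_id = f"{split}-task-{t:04d}"
        n_mol = int(rng_task.integers(lo, hi + 1))
        if split == "train":
            idx = rng_task.choice(len(train_pool), size=n_mol, replace=False)
            mols = [train_pool[int(i)] for i in idx]
        else:
            mols = _generate_unique(rng_mol, chain, terminal, n_mol, taken)
        family = int(rng_task.integers(0, config.n_task_families))
        w = centers[family] + config.family_spread * rng_task.normal(
            size=config.latent_dim
        )
        w /= np.linalg.norm(w)
        scores = latent(mols) @ w
        thr = float(np.quantile(scores, 1.0 - config.active_fraction))
        clean = (scores > thr).astype(int)
        flips = rng_noise.random(n_mol) < config.label_noise
        observed = np.where(flips, 1 - clean, clean)
        start = len(records)
        for m, y in zip(mols, observed):
            records.append(
                AssayRecord(
                    molecule=m, group_id=task_id, label=int(y), source_size=n_mol
                )
            )
        manifest_tasks[task_id] = {
            "split": split,
            "family": family,
            "w": w.tolist(),
            "threshold": thr,
            "n_molecules": n_mol,
            "record_start": start,
            "flipped_records": [int(start + i) for i in np.flatnonzero(flips)],
        }

    manifest = {
        "config": asdict(config),
        "projection_seed": int(config.seed),
        "latent_dim": config.latent_dim,
        "splits": {
            s: [tid for tid, m in manifest_tasks.items() if m["split"] == s]
            for s in ("train", "val", "test")
        },
        "tasks": manifest_tasks,
    }
    return records, manifest


def clean_labels_from_manifest(records, manifest, task_id: str) -> np.ndarray:
    """Recompute the noise-free labels of one task from the manifest alone."""
    info = manifest["tasks"][task_id]
    mols = [r.molecule for r in records if r.group_id == task_id]
    Z = latent_coords(mols, manifest["projection_seed"], manifest["latent_dim"])
    return (Z @ np.asarray(info["w"]) > info["threshold"]).astype(int)


def generate_context(records, manifest, m: int, seed: int) -> list:
    """Sample m distinct context molecules from the *training* split only.

    Never samples from validation/test tasks (leakage guard).
    """
    train_ids = set(manifest["splits"]["train"])
    pool = sorted({r.molecule for r in records if r.group_id in train_ids})
    if m > len(pool):
        raise TooFewMolecules(
            f"requested {m} context molecules, only {len(pool)} available"
        )
    rng = np.random.default_rng([int(seed), 0xC0])
    idx = rng.choice(len(pool), size=m, replace=False)
    return [pool[int(i)] for i in sorted(idx)]


def database_to_frame(records):
    """Long-format table ``smiles,group_id,label,source_size``."""
    import pandas as pd

    return pd.DataFrame(
        {
            "smiles": [r.molecule for r in records],
            "group_id": [r.group_id for r in records],
            "label": [r.label for r in records],
            "source_size": [r.source_size for r in records],
        }
    )
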