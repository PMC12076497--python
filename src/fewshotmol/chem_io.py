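"""Molecule parsing, canonicalization, featurization, and CSV exchange.

Molecules enter as SMILES strings.  Each valid molecule is mapped to a
fixed-length numeric vector: a 1024-bit circular substructure fingerprint
(Morgan, radius 2) concatenated with ~40 physicochemical descriptors that
are z-scored against statistics frozen from a reference corpus and clipped
to [-10, 10].  Descriptor dimensions with zero variance in the reference
corpus standardize to 0.

Invalid SMILES are reportable outcomes, never silent drops: CSV readers
return a rejection report naming the offending data rows.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator

from .exceptions import (
    EmptyFile,
    EmptyInput,
    FeaturizationError,
    InvalidSmiles,
    MissingColumn,
)

RDLogger.DisableLog("rdApp.*")

#: Descriptor block: a fixed list of robust, cheap RDKit descriptors.
DESCRIPTOR_NAMES = (
    "MolWt",
    "ExactMolWt",
    "HeavyAtomCount",
    "HeavyAtomMolWt",
    "MolLogP",
    "MolMR",
    "TPSA",
    "LabuteASA",
    "NumHAcceptors",
    "NumHDonors",
    "NumRotatableBonds",
    "NumHeteroatoms",
    "NumValenceElectrons",
    "NOCount",
    "NHOHCount",
    "RingCount",
    "NumAromaticRings",
    "NumAliphaticRings",
    "NumSaturatedRings",
    "NumAromaticCarbocycles",
    "NumAromaticHeterocycles",
    "NumAliphaticCarbocycles",
    "NumAliphaticHeterocycles",
    "NumSaturatedCarbocycles",
    "NumSaturatedHeterocycles",
    "FractionCSP3",
    "BalabanJ",
    "BertzCT",
    "HallKierAlpha",
    "Kappa1",
    "Kappa2",
    "Kappa3",
    "Chi0",
    "Chi1",
    "Chi0n",
    "Chi1n",
    "Chi2n",
    "Chi0v",
    "Chi1v",
    "Chi2v",
)

FP_BITS = 1024
FP_RADIUS = 2


@dataclass
class MoleculeRecord:
    """One molecule: raw input, canonical form, optional feature vector."""

    input_smiles: str
    canonical_smiles: str
    features: np.ndarray | None = None


@dataclass
class RejectionReport:
    """Rows rejected while reading molecules, with 1-based data-row numbers."""

    rows: list = field(default_factory=list)  # (row_number, smiles, reason)

    def add(self, row_number: int, smiles: str, reason: str) -> None:
        self.rows.append((row_number, smiles, reason))

    def __len__(self) -> int:
        return len(self.rows)

    def __bool__(self) -> bool:
        return bool(self.rows)


def parse_smiles(smiles: str) -> str:
    """Canonicalize a SMILES string.

    Raises
    ------
    EmptyInput
        For blank/whitespace input.
    InvalidSmiles
        For strings RDKit cannot parse.
    """
    if smiles is None or not str(smiles).strip():
        raise EmptyInput("empty SMILES string")
    mol = Chem.MolFromSmiles(str(smiles).strip())
    if mol is None:
        raise InvalidSmiles(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


class FeatureStandardizer:
    """Frozen z-score statistics for the descriptor block.

    Constant dimensions (zero variance at fit time) standardize to 0.
    Standardized values are clipped to ``[-clip, clip]``.
    """

    def __init__(self, clip: float = 10.0):
        self.clip = float(clip)
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.mean_ is not None

    def fit(self, descriptors: np.ndarray) -> "FeatureStandardizer":
        X = np.asarray(descriptors, dtype=np.float64)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        # zero-variance dims: divide by 1 after zeroing the centered value
        self.scale_ = np.where(sd > 1e-12, sd, np.inf)
        return self

    def transform(self, descriptors: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise FeaturizationError("standardizer not fitted")
        X = np.asarray(descriptors, dtype=np.float64)
        Z = (X - self.mean_) / self.scale_
        Z = np.clip(Z, -self.clip, self.clip)
        return np.nan_to_num(Z, nan=0.0, posinf=self.clip, neginf=-self.clip)

    def to_dict(self) -> dict:
        return {
            "clip": self.clip,
            "mean": self.mean_.tolist(),
            "scale": [
                None if not np.isfinite(s) else float(s) for s in self.scale_
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureStandardizer":
        obj = cls(clip=d["clip"])
        obj.mean_ = np.asarray(d["mean"], dtype=np.float64)
        obj.scale_ = np.asarray(
            [np.inf if s is None else s for s in d["scale"]], dtype=np.float64
        )
        return obj


class Featurizer:
    """Deterministic SMILES -> feature-vector map with an internal cache.

    Layout: ``[fingerprint bits (FP_BITS) | standardized descriptors]``.
    The descriptor standardizer must be fitted (``fit``) before
    ``transform`` is called; its statistics are frozen with the model so
    prediction-time featurization matches training exactly.
    """

    def __init__(self, standardizer: FeatureStandardizer | None = None):
        self.standardizer = standardizer or FeatureStandardizer()
        self._gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=FP_RADIUS, fpSize=FP_BITS
        )
        self._desc_fns = [getattr(Descriptors, n) for n in DESCRIPTOR_NAMES]
        self._cache: dict[str, np.ndarray] = {}

    @property
    def n_features(self) -> int:
        return FP_BITS + len(DESCRIPTOR_NAMES)

    def fingerprint(self, canonical_smiles: str) -> np.ndarray:
        mol = Chem.MolFromSmiles(canonical_smiles)
        if mol is None:
            raise InvalidSmiles(f"unparsable SMILES: {canonical_smiles!r}")
        return self._gen.GetFingerprintAsNumPy(mol).astype(np.float32)

    def descriptors(self, canonical_smiles: str) -> np.ndarray:
        mol = Chem.MolFromSmiles(canonical_smiles)
        if mol is None:
            raise InvalidSmiles(f"unparsable SMILES: {canonical_smiles!r}")
        try:
            vals = np.asarray(
                [fn(mol) for fn in self._desc_fns], dtype=np.float64
            )
        except Exception as err:  # pragma: no cover - rdkit internal failure
            raise FeaturizationError(
                f"descriptor computation failed for {canonical_smiles!r}: {err}"
            ) from err
        return vals

    def fit(self, canonical_smiles_list) -> "Featurizer":
        """Freeze descriptor statistics from a reference corpus."""
        D = np.stack([self.descriptors(s) for s in canonical_smiles_list])
        self.standardizer.fit(D)
        self._cache.clear()
        return self

    def transform(self, canonical_smiles: str) -> np.ndarray:
        cached = self._cache.get(canonical_smiles)
        if cached is not None:
            return cached
        fp = self.fingerprint(canonical_smiles)
        desc = self.standardizer.transform(
            self.descriptors(canonical_smiles)[None, :]
        )[0]
        vec = np.concatenate([fp, desc.astype(np.float32)])
        if not np.all(np.isfinite(vec)):
            raise FeaturizationError(
                f"non-finite feature values for {canonical_smiles!r}"
            )
        self._cache[canonical_smiles] = vec
        return vec

    def transform_many(self, canonical_smiles_list) -> np.ndarray:
        return np.stack([self.transform(s) for s in canonical_smiles_list])


def featurize(canonical_smiles: str, featurizer: Featurizer) -> np.ndarray:
    """Feature vector for one canonical SMILES (thin wrapper)."""
    return featurizer.transform(canonical_smiles)


def _open_source(source):
    """Interpret *source* as a path, file object, or literal CSV text."""
    if hasattr(source, "read"):
        return source
    s = str(source)
    if "\n" in s or (not os.path.exists(s) and "," in s):
        return io.StringIO(s)
    return s  # a path; pandas opens it


def read_table(source, **read_csv_kwargs) -> pd.DataFrame:
    """Read a CSV, skipping leading ``#``-prefixed reproducibility-header
    lines only.  (A column-wide ``comment='#'`` would corrupt rows whose
    SMILES contain ``#`` — triple bonds.)"""
    src = _open_source(source)
    if hasattr(src, "read"):
        text = src.read()
    else:
        with open(src) as fh:
            text = fh.read()
    lines = text.splitlines()
    n_skip = 0
    while n_skip < len(lines) and lines[n_skip].startswith("#"):
        n_skip += 1
    return pd.read_csv(
        io.StringIO(text), skiprows=n_skip, **read_csv_kwargs
    )


def read_molecule_csv(source, column: str = "smiles"):
    """Read molecules from CSV, preserving order.

    Returns ``(records, report)``: valid molecules as
    :class:`MoleculeRecord` (without features) and a
    :class:`RejectionReport` naming invalid rows (1-based data rows).
    """
    try:
        df = read_table(source, dtype=str)
    except pd.errors.EmptyDataError as err:
        raise EmptyFile(f"no data in {source!r}") from err
    if column not in df.columns:
        raise MissingColumn(
            f"column {column!r} not found (have: {list(df.columns)})"
        )
    records, report = [], RejectionReport()
    for i, raw in enumerate(df[column].tolist(), start=1):
        try:
            canonical = parse_smiles(raw)
        except (InvalidSmiles, EmptyInput) as err:
            report.add(i, raw, type(err).__name__)
            continue
        records.append(MoleculeRecord(input_smiles=raw, canonical_smiles=canonical))
    return records, report


def records_from_smiles(smiles_list, featurizer: Featurizer | None = None):
    """Canonicalize (and optionally featurize) a list of SMILES strings."""
    records = []
    for s in smiles_list:
        canonical = parse_smiles(s)
        feats = featurizer.transform(canonical) if featurizer is not None else None
        records.append(
            MoleculeRecord(
                input_smiles=s, canonical_smiles=canonical, features=feats
            )
        )
    return records


def write_predictions_csv(table, path) -> None:
    """Write a prediction table as ``smiles,prediction`` with 6 decimals."""
    df = table.to_dataframe() if hasattr(table, "to_dataframe") else table
    if len(df) == 0:
        raise EmptyFile("refusing to write an empty prediction table")
    df.to_csv(path, index=False, float_format="%.6f")
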