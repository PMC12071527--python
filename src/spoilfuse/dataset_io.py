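"""Tabular spectral dataset I/O, modality alignment, and train/test partitions.

One physical sample yields one row per sensor modality (FTIR absorbance
spectrum; MSI / MSIF per-band mean and standard deviation of reflectance),
matched across files by a shared ``sample_id`` naming scheme
``<meat>_<condition>_<tempC>_<timeH>_<batch>_<rep>``. Alignment is a strict
inner join on that ID, with dropped-row counts logged.

Partitioning supports the two evaluation designs used throughout:

* ``batch_on_batch`` — train on sourcing batch 1, test on sourcing batch 2 (a
  robustness probe against batch effects), optionally restricted to one
  packaging condition, with the other conditions' batch-2 rows kept as
  auxiliary cross-condition test sets;
* ``combined_conditions`` — batch-on-batch over all conditions pooled, with
  per-condition test subsets retained for per-condition reporting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralBlock",
    "MultiModalDataset",
    "PartitionPlan",
    "load_dataset",
    "save_dataset",
    "make_partition",
]

METADATA_COLUMNS = (
    "sample_id",
    "meat_type",
    "condition",
    "temperature",
    "time",
    "batch",
    "replicate",
    "tvc",
)

#: number of significant digits used when serialising matrices, chosen so a
#: write/load round trip is exact for float64.
FLOAT_FORMAT = "%.17g"


@dataclass
class SpectralBlock:
    """One modality's observations-by-features matrix.

    ``feature_axis`` holds ordered feature labels: wavenumbers (floats,
    strictly monotone) for FTIR, band-and-statistic names for MSI/MSIF.
    """

    modality: str
    feature_axis: list
    matrix: np.ndarray
    sample_ids: list

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.feature_axis = list(self.feature_axis)
        self.sample_ids = list(self.sample_ids)
        if self.matrix.ndim != 2:
            raise ValueError(f"{self.modality}: matrix must be 2-d")
        if self.matrix.shape[0] != len(self.sample_ids):
            raise ValueError(f"{self.modality}: row count != sample_id count")
        if self.matrix.shape[1] != len(self.feature_axis):
            raise ValueError(f"{self.modality}: column count != feature_axis length")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError(f"{self.modality}: matrix contains missing/non-finite values")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def numeric_axis(self) -> np.ndarray:
        """Feature axis as floats (valid for FTIR-type wavenumber axes)."""
        try:
            return np.asarray([float(v) for v in self.feature_axis], dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"{self.modality}: feature axis is not numeric"
            ) from exc

    def select_rows(self, indices: np.ndarray) -> "SpectralBlock":
        return SpectralBlock(
            modality=self.modality,
            feature_axis=list(self.feature_axis),
            matrix=self.matrix[indices],
            sample_ids=[self.sample_ids[i] for i in np.atleast_1d(indices)],
        )


@dataclass
class MultiModalDataset:
    """Aligned per-modality spectral blocks plus sample metadata.

    All blocks share identical ``sample_ids`` in identical order, and the
    metadata table covers exactly those IDs (validated on construction).
    """

    blocks: dict
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.metadata = self.metadata.reset_index(drop=True)
        ids = list(self.metadata["sample_id"])
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample IDs in metadata")
        for name, block in self.blocks.items():
            if block.sample_ids != ids:
                raise ValueError(f"block {name!r} IDs do not match metadata order")

    @property
    def sample_ids(self) -> list:
        return list(self.metadata["sample_id"])

    @property
    def n_samples(self) -> int:
        return len(self.metadata)

    @property
    def y(self) -> np.ndarray:
        """The regression target: TVC in log CFU/g."""
        return self.metadata["tvc"].to_numpy(dtype=float)

    def select(self, indices: Sequence[int]) -> "MultiModalDataset":
        indices = np.asarray(indices, dtype=int)
        return MultiModalDataset(
            blocks={m: b.select_rows(indices) for m, b in self.blocks.items()},
            metadata=self.metadata.iloc[indices].reset_index(drop=True),
        )

    def subset_ids(self, ids: Sequence[str]) -> "MultiModalDataset":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"sample IDs not in dataset: {missing[:5]}")
        return self.select(np.asarray([pos[s] for s in ids], dtype=int))

    def block_matrices(self, modalities: Sequence[str]) -> dict:
        return {m: self.blocks[m].matrix for m in modalities}


def _block_to_frame(block: SpectralBlock) -> pd.DataFrame:
    cols = []
    for v in block.feature_axis:
        cols.append(f"{v:.4f}" if isinstance(v, (int, float, np.floating)) else str(v))
    df = pd.DataFrame(block.matrix, columns=cols)
    df.insert(0, "sample_id", block.sample_ids)
    return df


def save_dataset(dataset: MultiModalDataset, directory) -> dict:
    """Write one CSV per modality plus ``metadata.csv``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    meta_path = directory / "metadata.csv"
    dataset.metadata.to_csv(meta_path, index=False, float_format=FLOAT_FORMAT)
    paths["metadata"] = meta_path
    for name, block in dataset.blocks.items():
        p = directory / f"{name.lower()}.csv"
        _block_to_frame(block).to_csv(p, index=False, float_format=FLOAT_FORMAT)
        paths[name] = p
    return paths


def _read_block_csv(modality: str, path) -> pd.DataFrame:
    # round_trip parsing keeps write/load exact at full float64 precision
    df = pd.read_csv(path, float_precision="round_trip")
    if "sample_id" not in df.columns:
        raise ValueError(f"{modality} file {path} lacks a sample_id column")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"duplicate sample IDs in {modality} file {path}")
    return df.set_index("sample_id")


def load_dataset(block_paths: Mapping[str, object], metadata_path) -> MultiModalDataset:
    """Load per-modality CSVs plus a metadata CSV and align them by sample ID.

    Strict inner join across all requested modalities; rows present in the
    metadata but missing from any block are dropped with a logged count. Row
    order is normalised by sorting on sample ID, so shuffled input files load
    to an identical dataset.
    """
    meta = pd.read_csv(metadata_path, float_precision="round_trip")
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata lacks columns: {sorted(missing_cols)}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample IDs in metadata")

    frames = {m: _read_block_csv(m, p) for m, p in block_paths.items()}
    common = set(meta["sample_id"])
    for m, df in frames.items():
        common &= set(df.index)
    if not common:
        raise ValueError("empty sample-ID intersection across files")
    dropped = len(meta) - len(common)
    if dropped:
        logger.warning(
            "dropped %d metadata row(s) missing from at least one modality block",
            dropped,
        )
    order = sorted(common)
    meta = meta.set_index("sample_id").loc[order].reset_index()

    blocks = {}
    for m, df in frames.items():
        sub = df.loc[order]
        axis: list = []
        for c in sub.columns:
            try:
                axis.append(float(c))
            except ValueError:
                axis.append(c)
        blocks[m] = SpectralBlock(
            modality=m,
            feature_axis=axis,
            matrix=sub.to_numpy(dtype=float),
            sample_ids=order,
        )
    return MultiModalDataset(blocks=blocks, metadata=meta)


@dataclass
class PartitionPlan:
    """A train/test split, with auxiliary test sets keyed by condition."""

    scheme: str
    train_ids: list
    test_ids: list
    aux_test_ids: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "scheme": self.scheme,
                "train_ids": list(self.train_ids),
                "test_ids": list(self.test_ids),
                "aux_test_ids": {k: list(v) for k, v in self.aux_test_ids.items()},
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "PartitionPlan":
        d = json.loads(s)
        return cls(
            scheme=d["scheme"],
            train_ids=d["train_ids"],
            test_ids=d["test_ids"],
            aux_test_ids=d.get("aux_test_ids", {}),
        )


def make_partition(
    dataset: MultiModalDataset,
    scheme: str = "batch_on_batch",
    conditions: Sequence[str] | None = None,
) -> PartitionPlan:
    """Build the batch-on-batch (optionally per-condition) train/test split.

    ``batch_on_batch``: train = batch 1 of the selected condition(s), test =
    batch 2; batch-2 rows of every condition are also kept as auxiliary test
    sets for cross-condition assessment. ``combined_conditions``: all
    conditions pooled, with the per-condition batch-2 subsets retained (they
    partition the combined test set).
    """
    meta = dataset.metadata
    all_conditions = list(dict.fromkeys(meta["condition"]))
    if scheme == "combined_conditions":
        selected = all_conditions
    elif scheme == "batch_on_batch":
        selected = list(conditions) if conditions is not None else all_conditions
        unknown = set(selected) - set(all_conditions)
        if unknown:
            raise ValueError(f"unknown condition label(s): {sorted(unknown)}")
    else:
        raise ValueError(f"unknown partition scheme: {scheme!r}")

    sel = meta[meta["condition"].isin(selected)]
    batches = set(sel["batch"])
    if not {1, 2} <= batches:
        raise ValueError("batch_on_batch partitioning requires both batches 1 and 2")

    train_ids = list(sel.loc[sel["batch"] == 1, "sample_id"])
    test_ids = list(sel.loc[sel["batch"] == 2, "sample_id"])
    aux = {}
    for cond in all_conditions:
        rows = meta[(meta["condition"] == cond) & (meta["batch"] == 2)]
        aux[cond] = list(rows["sample_id"])
    return PartitionPlan(
        scheme=scheme, train_ids=train_ids, test_ids=test_ids, aux_test_ids=aux
    )
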