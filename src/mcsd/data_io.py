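"""Reading, aligning and normalizing expression matrices.

An expression matrix is a probes x samples table of real values: rows are
molecular features (miRNA or mRNA probes), columns are patients/samples.
Multiple data types measured on the same patients are combined by *cascading*:
stacking the blocks row-wise into one tall matrix per sample, so a patient's
combined profile is the concatenation of their per-block profiles.

Row normalization maps every feature to [0, 1] using statistics derived from
the training samples only (the default), so that a fitted model can be applied
to single new samples without re-deriving statistics; a ``joint`` mode that
pools training and testing columns is available for replication of workflows
that normalized both together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DuplicateIdError,
    InputError,
    ParseError,
    SampleMismatchError,
)

__all__ = [
    "ExpressionMatrix",
    "LabeledDataset",
    "BlockMap",
    "RowStats",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_labels",
    "write_labels",
    "make_labeled_dataset",
    "cascade",
    "normalize_rows",
    "apply_row_stats",
]


@dataclass
class ExpressionMatrix:
    """A probes x samples matrix with unique row and column identifiers."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise InputError("values must be a 2-D array")
        if len(self.probe_ids) != self.values.shape[0]:
            raise InputError(
                f"{len(self.probe_ids)} probe ids for {self.values.shape[0]} rows"
            )
        if len(self.sample_ids) != self.values.shape[1]:
            raise InputError(
                f"{len(self.sample_ids)} sample ids for {self.values.shape[1]} columns"
            )
        for name, ids in (("probe", self.probe_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if ids.count(x) > 1})
                raise DuplicateIdError(f"duplicate {name} id(s): {dupes}")
        if not np.all(np.isfinite(self.values)):
            raise InputError("expression values must be finite")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``sample_ids``, in that order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise SampleMismatchError(f"samples not present: {missing}")
        idx = [pos[s] for s in sample_ids]
        return ExpressionMatrix(
            list(self.probe_ids), list(sample_ids), self.values[:, idx].copy()
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)


@dataclass
class LabeledDataset:
    """An expression matrix plus a class label for every sample.

    Labels are stored as 0-based class indices into ``class_names``.
    """

    matrix: ExpressionMatrix
    labels: dict[str, int]
    class_names: list[str]

    def __post_init__(self) -> None:
        if len(self.class_names) < 2:
            raise InputError("at least two classes are required")
        n = len(self.class_names)
        for sid in self.matrix.sample_ids:
            if sid not in self.labels:
                raise InputError(f"sample {sid!r} has no label")
            k = self.labels[sid]
            if not (0 <= k < n):
                raise InputError(f"label {k} for sample {sid!r} out of range")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def y(self) -> np.ndarray:
        """Class indices aligned with ``matrix.sample_ids``."""
        return np.array([self.labels[s] for s in self.matrix.sample_ids], dtype=int)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.y, minlength=self.n_classes)

    def subset_samples(self, sample_ids: list[str]) -> "LabeledDataset":
        return LabeledDataset(
            self.matrix.subset_samples(sample_ids),
            {s: self.labels[s] for s in sample_ids},
            list(self.class_names),
        )


@dataclass
class BlockMap:
    """Provenance of a cascaded matrix: which rows came from which block."""

    block_names: list[str]
    block_row_ranges: list[tuple[int, int]]

    def __post_init__(self) -> None:
        stop = 0
        for (a, b) in self.block_row_ranges:
            if a != stop or b < a:
                raise InputError("block ranges must be contiguous and ordered")
            stop = b

    def slice_block(self, cascaded: ExpressionMatrix, name: str) -> ExpressionMatrix:
        """Extract one original block from a cascaded matrix."""
        i = self.block_names.index(name)
        a, b = self.block_row_ranges[i]
        return ExpressionMatrix(
            cascaded.probe_ids[a:b], list(cascaded.sample_ids), cascaded.values[a:b]
        )


@dataclass
class RowStats:
    """Per-row (min, max) from the normalization reference set."""

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=np.float64)
        self.maxs = np.asarray(self.maxs, dtype=np.float64)
        if self.mins.shape != self.maxs.shape or self.mins.ndim != 1:
            raise InputError("row stats must be matching 1-D arrays")


def read_expression_matrix(path, sep: str = "\t") -> ExpressionMatrix:
    """Read a delimited expression table.

    The first header cell names the probe-id column; the remaining header
    cells are sample ids. Non-numeric cells are rejected with their location.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    if len(set(header[1:])) != len(header[1:]):
        dupes = sorted({h for h in header[1:] if header[1:].count(h) > 1})
        raise DuplicateIdError(f"duplicate sample id(s) in {path}: {dupes}")
    # na_filter off so sentinel strings like "NA" surface as parse errors
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, na_filter=False)
    probe_ids = [str(p) for p in df.index]
    sample_ids = [str(s) for s in df.columns]
    values = np.empty(df.shape, dtype=np.float64)
    raw = df.to_numpy()
    for j in range(df.shape[1]):
        col = pd.to_numeric(raw[:, j], errors="coerce")
        bad = ~np.isfinite(col.astype(float))
        if np.any(bad):
            i = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"non-numeric value {raw[i, j]!r} at probe {probe_ids[i]!r}, "
                f"sample {sample_ids[j]!r} in {path}"
            )
        values[:, j] = col
    return ExpressionMatrix(probe_ids, sample_ids, values)


def write_expression_matrix(path, matrix: ExpressionMatrix, sep: str = "\t") -> None:
    matrix.to_frame().to_csv(
        path,
        sep=sep,
        index_label="probe_id",
        float_format=lambda v: repr(float(v)),
    )


def read_labels(path, sep: str = "\t") -> dict[str, str]:
    """Read a two-column (sample_id, class_name) table; header optional-free."""
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ParseError(f"label file {path} needs two columns")
    # Tolerate a header row such as "sample_id\tclass".
    first = str(df.iloc[0, 0]).lower()
    if first in {"sample", "sample_id", "id"}:
        df = df.iloc[1:]
    sids = [str(s) for s in df.iloc[:, 0]]
    if len(set(sids)) != len(sids):
        raise DuplicateIdError("duplicate sample id in label file")
    return dict(zip(sids, (str(c) for c in df.iloc[:, 1])))


def write_labels(path, labels: dict[str, str], sep: str = "\t") -> None:
    with open(path, "w") as fh:
        for sid, cls in labels.items():
            fh.write(f"{sid}{sep}{cls}\n")


def make_labeled_dataset(
    matrix: ExpressionMatrix,
    label_names: dict[str, str],
    class_names: list[str] | None = None,
) -> LabeledDataset:
    """Attach string class labels to a matrix.

    ``class_names`` fixes the class-index order; by default classes are
    sorted alphabetically for determinism.
    """
    missing = [s for s in matrix.sample_ids if s not in label_names]
    if missing:
        raise InputError(f"samples without labels: {missing}")
    present = {label_names[s] for s in matrix.sample_ids}
    if class_names is None:
        class_names = sorted(present)
    unknown = present - set(class_names)
    if unknown:
        raise InputError(f"labels not in class list: {sorted(unknown)}")
    index = {c: k for k, c in enumerate(class_names)}
    labels = {s: index[label_names[s]] for s in matrix.sample_ids}
    return LabeledDataset(matrix, labels, list(class_names))


def cascade(
    blocks: list[ExpressionMatrix],
    sample_order: list[str] | None = None,
) -> tuple[ExpressionMatrix, BlockMap]:
    """Stack data blocks row-wise over a shared, ordered sample set.

    Every block must contain every sample in ``sample_order``; extra samples
    in a block are dropped (with a warning). When ``sample_order`` is omitted
    it defaults to the first block's samples restricted to the intersection
    of all blocks.
    """
    if not blocks:
        raise InputError("cascade needs at least one block")
    if sample_order is None:
        common = set(blocks[0].sample_ids)
        for b in blocks[1:]:
            common &= set(b.sample_ids)
        sample_order = [s for s in blocks[0].sample_ids if s in common]
        if len(sample_order) < len(blocks[0].sample_ids):
            warnings.warn(
                "samples absent from some block were dropped; "
                f"using the {len(sample_order)}-sample intersection",
                stacklevel=2,
            )
    missing_all: dict[int, list[str]] = {}
    for i, b in enumerate(blocks):
        missing = [s for s in sample_order if s not in set(b.sample_ids)]
        if missing:
            missing_all[i] = missing
    if missing_all:
        raise SampleMismatchError(f"samples missing per block: {missing_all}")

    aligned = [b.subset_samples(list(sample_order)) for b in blocks]
    probe_ids: list[str] = []
    ranges: list[tuple[int, int]] = []
    start = 0
    for i, b in enumerate(aligned):
        # Disambiguate probe ids that collide across blocks.
        ids = b.probe_ids
        if set(ids) & set(probe_ids):
            ids = [f"b{i}:{p}" for p in ids]
        probe_ids.extend(ids)
        ranges.append((start, start + b.n_probes))
        start += b.n_probes
    values = np.vstack([b.values for b in aligned])
    names = [f"block{i}" for i in range(len(blocks))]
    return ExpressionMatrix(probe_ids, list(sample_order), values), BlockMap(names, ranges)


def normalize_rows(
    train: ExpressionMatrix,
    test: ExpressionMatrix | None = None,
    mode: str = "train",
) -> tuple[ExpressionMatrix, ExpressionMatrix | None, RowStats]:
    """Min-max normalize each row to [0, 1].

    mode="train": statistics come from the training matrix only and test
    values outside the training range are clipped into [0, 1].
    mode="joint": statistics come from train and test pooled (replication
    mode; leaks test information into the scaling).

    Rows that are constant in the reference set map to all-zeros.
    """
    if test is not None and test.probe_ids != train.probe_ids:
        raise AlignmentError("train/test probe ids differ or are reordered")
    if mode == "train":
        ref = train.values
    elif mode == "joint":
        if test is None:
            raise InputError("joint normalization requires a test matrix")
        ref = np.hstack([train.values, test.values])
    else:
        raise InputError(f"unknown normalization mode {mode!r}")
    stats = RowStats(ref.min(axis=1), ref.max(axis=1))
    train_n = ExpressionMatrix(
        list(train.probe_ids),
        list(train.sample_ids),
        _scale(train.values, stats),
    )
    test_n = None
    if test is not None:
        test_n = ExpressionMatrix(
            list(test.probe_ids), list(test.sample_ids), _scale(test.values, stats)
        )
    return train_n, test_n, stats


def apply_row_stats(matrix: ExpressionMatrix, stats: RowStats) -> ExpressionMatrix:
    """Normalize a matrix with previously derived row statistics (clipping)."""
    if matrix.n_probes != stats.mins.size:
        raise AlignmentError(
            f"matrix has {matrix.n_probes} rows but stats cover {stats.mins.size}"
        )
    return ExpressionMatrix(
        list(matrix.probe_ids), list(matrix.sample_ids), _scale(matrix.values, stats)
    )


def _scale(values: np.ndarray, stats: RowStats) -> np.ndarray:
    span = stats.maxs - stats.mins
    out = np.zeros_like(values, dtype=np.float64)
    ok = span > 0
    out[ok] = (values[ok] - stats.mins[ok, None]) / span[ok, None]
    np.clip(out, 0.0, 1.0, out=out)
    return out
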