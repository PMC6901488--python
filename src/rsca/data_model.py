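"""Multi-block data container, preprocessing, and delimited-text I/O.

A multi-block dataset consists of K numeric blocks X_k of shape I x J_k that
share the same I rows (subjects / samples / experimental units) but carry
different variables.  All downstream routines operate on the column-wise
concatenation X_C = [X_1, ..., X_K] of shape I x sum(J_k) together with the
block column partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MultiBlockData",
    "preprocess",
    "concatenate",
    "read_block_csvs",
    "read_wide_csv",
    "write_block_csvs",
]

PREPROCESS_MODES = ("center", "center+norm1", "center+blockscale")


class ValidationError(ValueError):
    """Raised when input data violate the multi-block contract."""


class DegenerateColumnError(ValidationError):
    """Raised when a constant column makes a scaling mode undefined."""


@dataclass(frozen=True)
class MultiBlockData:
    """K row-aligned numeric blocks plus bookkeeping.

    Parameters
    ----------
    blocks
        List of K arrays, each of shape (I, J_k).
    block_names
        One identifier per block; defaults to ``block1..blockK``.
    column_labels
        Per-block variable names; default ``v1..vJk``.
    preprocessing
        Record of the preprocessing applied so far (``"none"`` on raw data).
    """

    blocks: tuple[np.ndarray, ...]
    block_names: tuple[str, ...] = ()
    column_labels: tuple[tuple[str, ...], ...] = ()
    preprocessing: str = "none"

    def __init__(
        self,
        blocks: Sequence[np.ndarray],
        block_names: Sequence[str] | None = None,
        column_labels: Sequence[Sequence[str]] | None = None,
        preprocessing: str = "none",
    ):
        blocks = tuple(np.asarray(b, dtype=float) for b in blocks)
        if len(blocks) < 1:
            raise ValidationError("at least one block is required")
        I = blocks[0].shape[0]
        for i, b in enumerate(blocks):
            if b.ndim != 2:
                raise ValidationError(f"block {i} is not a 2-d matrix")
            if b.shape[0] != I:
                raise ValidationError(
                    f"block {i} has {b.shape[0]} rows, expected {I}: "
                    "all blocks must share the same subjects"
                )
            if b.shape[1] < 1:
                raise ValidationError(f"block {i} has no columns")
            if not np.all(np.isfinite(b)):
                raise ValidationError(f"block {i} contains non-finite entries")
        if block_names is None:
            block_names = tuple(f"block{k + 1}" for k in range(len(blocks)))
        else:
            block_names = tuple(str(n) for n in block_names)
            if len(block_names) != len(blocks):
                raise ValidationError("block_names length mismatch")
        if column_labels is None:
            column_labels = tuple(
                tuple(f"v{j + 1}" for j in range(b.shape[1])) for b in blocks
            )
        else:
            column_labels = tuple(tuple(map(str, c)) for c in column_labels)
            for k, (labels, b) in enumerate(zip(column_labels, blocks)):
                if len(labels) != b.shape[1]:
                    raise ValidationError(f"column_labels mismatch for block {k}")
        object.__setattr__(self, "blocks", blocks)
        object.__setattr__(self, "block_names", block_names)
        object.__setattr__(self, "column_labels", column_labels)
        object.__setattr__(self, "preprocessing", preprocessing)

    # --- geometry -----------------------------------------------------
    @property
    def K(self) -> int:
        return len(self.blocks)

    @property
    def I(self) -> int:  # noqa: E743 - established symbol for the row count
        return self.blocks[0].shape[0]

    @property
    def J(self) -> tuple[int, ...]:
        return tuple(b.shape[1] for b in self.blocks)

    @property
    def total_columns(self) -> int:
        return int(sum(self.J))

    @property
    def block_starts(self) -> np.ndarray:
        """Start offset of each block within the concatenated column axis."""
        return np.concatenate([[0], np.cumsum(self.J)[:-1]]).astype(int)

    def block_slices(self) -> list[slice]:
        starts = self.block_starts
        return [slice(int(s), int(s + j)) for s, j in zip(starts, self.J)]

    def flat_labels(self) -> list[str]:
        """``block:variable`` labels in concatenation order."""
        return [
            f"{name}:{lab}"
            for name, labels in zip(self.block_names, self.column_labels)
            for lab in labels
        ]

    def with_blocks(self, blocks: Sequence[np.ndarray], preprocessing: str) -> "MultiBlockData":
        return MultiBlockData(
            blocks,
            block_names=self.block_names,
            column_labels=self.column_labels,
            preprocessing=preprocessing,
        )


def concatenate(data: MultiBlockData) -> np.ndarray:
    """Column-wise concatenation X_C = [X_1, ..., X_K] (I x sum J_k)."""
    return np.concatenate(data.blocks, axis=1)


def split(X_C: np.ndarray, data: MultiBlockData) -> list[np.ndarray]:
    """Slice a concatenated matrix back into the block partition of *data*."""
    return [X_C[:, s] for s in data.block_slices()]


def preprocess(data: MultiBlockData, mode: str = "center+norm1") -> MultiBlockData:
    """Column-center the blocks and optionally rescale columns.

    Modes
    -----
    ``center``
        Subtract each column mean.
    ``center+norm1``
        Additionally scale every column to Euclidean norm 1.  This is the
        default and gives every variable equal weight regardless of block.
    ``center+blockscale``
        Scale each column of block k so its squared norm is 1/J_k, giving
        every *block* total squared norm 1.

    Raises a degenerate-column error when a scaling mode meets a constant
    column (zero variance), naming the block and column.
    """
    if mode not in PREPROCESS_MODES:
        raise ValidationError(f"unknown preprocessing mode {mode!r}; valid: {PREPROCESS_MODES}")
    if data.I < 2:
        raise ValidationError("preprocessing needs at least 2 rows")
    out = []
    for name, labels, block in zip(data.block_names, data.column_labels, data.blocks):
        centered = block - block.mean(axis=0, keepdims=True)
        if mode == "center":
            out.append(centered)
            continue
        norms = np.linalg.norm(centered, axis=0)
        bad = np.flatnonzero(norms == 0)
        if bad.size:
            raise DegenerateColumnError(
                f"column {labels[bad[0]]!r} of block {name!r} is constant; "
                f"cannot scale under mode {mode!r}"
            )
        scaled = centered / norms
        if mode == "center+blockscale":
            scaled = scaled / np.sqrt(block.shape[1])
        out.append(scaled)
    return data.with_blocks(out, preprocessing=mode)


# --- delimited-text I/O ----------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep)
    numeric = frame.select_dtypes(include=[np.number])
    if numeric.shape[1] != frame.shape[1]:
        non_num = [c for c in frame.columns if c not in numeric.columns]
        raise ValidationError(f"{path}: non-numeric columns {non_num}")
    return frame


def read_block_csvs(
    paths: Sequence[str | Path], block_names: Sequence[str] | None = None
) -> MultiBlockData:
    """Load one CSV/TSV per block (header row = variable names)."""
    frames = [_read_table(p) for p in paths]
    if block_names is None:
        block_names = [Path(p).stem for p in paths]
    return MultiBlockData(
        [f.to_numpy(dtype=float) for f in frames],
        block_names=block_names,
        column_labels=[tuple(f.columns) for f in frames],
    )


def read_wide_csv(path: str | Path, block_map: dict[str, Sequence[str]]) -> MultiBlockData:
    """Load a single wide table plus a block -> column-names assignment."""
    frame = _read_table(path)
    blocks, names, labels = [], [], []
    seen: set[str] = set()
    for name, cols in block_map.items():
        cols = list(cols)
        missing = [c for c in cols if c not in frame.columns]
        if missing:
            raise ValidationError(f"block {name!r}: columns {missing} not in {path}")
        dup = seen.intersection(cols)
        if dup:
            raise ValidationError(f"columns assigned to more than one block: {sorted(dup)}")
        seen.update(cols)
        blocks.append(frame[cols].to_numpy(dtype=float))
        names.append(name)
        labels.append(tuple(cols))
    return MultiBlockData(blocks, block_names=names, column_labels=labels)


def write_block_csvs(data: MultiBlockData, directory: str | Path) -> list[Path]:
    """Write one CSV per block into *directory*; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, labels, block in zip(data.block_names, data.column_labels, data.blocks):
        p = directory / f"{name}.csv"
        pd.DataFrame(block, columns=list(labels)).to_csv(p, index=False)
        paths.append(p)
    return paths
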