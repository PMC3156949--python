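"""Shared tabular containers: features, signal tracks and expression tables.

All genomic coordinates are 0-based half-open base-pair intervals (BED
convention); megabase values are bp / 1e6 exactly.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["FeatureTable", "SignalTrack", "ExpressionTable", "FEATURE_CLASSES"]

FEATURE_CLASSES = ("gene", "cgi", "sine", "line", "other")

_FEATURE_COLS = ["chrom", "start", "end", "feature_class"]
_EXPR_COLS = ["gene_id", "chrom", "pos", "value"]


@dataclasses.dataclass
class FeatureTable:
    """Genomic interval features (genes, CpG islands, repeats).

    ``df`` has columns ``chrom, start, end, feature_class`` with 0-based
    half-open bp coordinates.  If ``chrom_length_bp`` is declared, all
    records must lie within it.
    """

    df: pd.DataFrame
    chrom_length_bp: int | None = None

    def __post_init__(self) -> None:
        missing = [c for c in _FEATURE_COLS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"FeatureTable missing columns {missing}")
        self.df = self.df[_FEATURE_COLS].reset_index(drop=True)
        self.df["start"] = self.df["start"].astype(np.int64)
        self.df["end"] = self.df["end"].astype(np.int64)
        bad = self.df.index[self.df["start"] >= self.df["end"]]
        if len(bad):
            raise ValidationError(f"start >= end at rows {list(bad[:10])}")
        if (self.df["start"] < 0).any():
            raise ValidationError("negative start coordinate")
        if self.chrom_length_bp is not None:
            out = self.df.index[self.df["end"] > self.chrom_length_bp]
            if len(out):
                raise ValidationError(
                    f"{len(out)} records beyond declared chromosome length "
                    f"(rows {list(out[:10])})"
                )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def midpoints_bp(self) -> np.ndarray:
        return (self.df["start"].to_numpy() + self.df["end"].to_numpy()) / 2.0


@dataclasses.dataclass
class SignalTrack:
    """Step-function coverage over one chromosome.

    Non-overlapping sorted intervals with nonnegative values; positions not
    covered by any interval are implicitly zero.
    """

    chrom: str
    start: np.ndarray
    end: np.ndarray
    value: np.ndarray
    step_bp: int | None = None

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.value = np.asarray(self.value, dtype=float)
        if not (len(self.start) == len(self.end) == len(self.value)):
            raise ValidationError("start/end/value length mismatch")
        if (self.start >= self.end).any():
            raise ValidationError("interval with start >= end")
        if (self.value < 0).any():
            raise ValidationError("negative signal value")
        order = np.argsort(self.start, kind="stable")
        self.start, self.end, self.value = (
            self.start[order],
            self.end[order],
            self.value[order],
        )
        if len(self.start) > 1 and (self.end[:-1] > self.start[1:]).any():
            raise ValidationError("overlapping intervals in signal track")

    def __len__(self) -> int:
        return len(self.start)


@dataclasses.dataclass
class ExpressionTable:
    """Per-gene normalised expression values at representative positions.

    ``df`` has columns ``gene_id, chrom, pos, value``; one record per gene,
    values nonnegative, positions in bp.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _EXPR_COLS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"ExpressionTable missing columns {missing}")
        self.df = self.df[_EXPR_COLS].reset_index(drop=True)
        if self.df["gene_id"].duplicated().any():
            dups = self.df.loc[self.df["gene_id"].duplicated(), "gene_id"]
            raise ValidationError(f"duplicate gene ids: {list(dups[:5])}")
        if (self.df["value"] < 0).any():
            raise ValidationError("negative expression value")

    def __len__(self) -> int:
        return len(self.df)
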