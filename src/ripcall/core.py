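"""Genomic primitives shared by all pipeline stages.

Coordinates are 0-based, half-open throughout (`start` inclusive, `end`
exclusive), i.e. native BED semantics.  Collections of intervals and
fragments are plain :class:`pandas.DataFrame` objects with at least the
columns ``chrom, start, end, strand`` (fragments add ``unique``); the light
dataclasses here describe single records and sample identity.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")

#: default mate-join limit: paired mates farther apart are not a fragment
DEFAULT_JOIN_LIMIT = 3000

INTERVAL_COLUMNS = ["chrom", "start", "end", "strand"]
FRAGMENT_COLUMNS = INTERVAL_COLUMNS + ["unique"]


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SampleKey:
    """Identity of one sequencing library: genotype x assay x replicate."""

    genotype: str
    assay: str = "RIP"
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")

    def __str__(self) -> str:
        return f"{self.genotype}_{self.assay}_rep{self.replicate}"

    def seed_offset(self) -> int:
        """Stable 31-bit integer derived from the key, for replicate seeding."""
        return zlib.crc32(str(self).encode()) & 0x7FFFFFFF


@dataclass
class FragmentSet:
    """Mapped fragments of one library plus its bookkeeping.

    ``frame`` holds one row per retained fragment (chrom, start, end,
    strand, unique); ``library_size`` is the count of retained fragments
    and is the RPM denominator; ``dropped`` counts records discarded for
    exceeding the mate-join limit.
    """

    frame: pd.DataFrame
    sample: SampleKey
    dropped: int = 0
    _library_size: int | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in FRAGMENT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"fragment frame missing columns {missing}")

    @property
    def library_size(self) -> int:
        if self._library_size is not None:
            return self._library_size
        return len(self.frame)

    @library_size.setter
    def library_size(self, value: int) -> None:
        if value <= 0 and len(self.frame):
            raise ValueError("library size must be positive")
        self._library_size = int(value)

    def __len__(self) -> int:
        return len(self.frame)


def empty_fragment_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "unique": pd.Series(dtype=bool),
        }
    )


def validate_intervals(frame: pd.DataFrame) -> None:
    """Raise on any row violating the interval invariants."""
    if len(frame) == 0:
        return
    if (frame["start"] < 0).any():
        raise ValueError("negative start coordinate")
    if (frame["end"] <= frame["start"]).any():
        bad = frame.index[frame["end"] <= frame["start"]][0]
        raise ValueError(f"end <= start at row {bad}")
    bad_strand = ~frame["strand"].isin(STRANDS)
    if bad_strand.any():
        raise ValueError(f"invalid strand value {frame.loc[bad_strand.idxmax(), 'strand']!r}")


def sort_intervals(frame: pd.DataFrame) -> pd.DataFrame:
    """Deterministic (chrom, start, end, strand) ordering used by all writers."""
    return frame.sort_values(
        ["chrom", "start", "end", "strand"], kind="mergesort"
    ).reset_index(drop=True)


def rpm(count, library_size: int):
    """Reads-per-million normalization: count * 1e6 / library_size."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return np.multiply(count, 1e6) / library_size
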