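"""Readers and writers for the flat genomic formats the pipeline consumes.

BED6 carries fragments and called regions (score field = mapping
uniqueness for fragments); GFF3 carries gene / transposon annotations
(coordinates converted to 0-based half-open on read); bedGraph carries
signal tracks; plain TSV carries per-cytosine methylation and chromosome
sizes.  All writers emit deterministic (chrom, start, end, strand) order so
identical inputs give byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_JOIN_LIMIT,
    FragmentSet,
    SampleKey,
    empty_fragment_frame,
    sort_intervals,
    validate_intervals,
)
from .intervals import SignalTrack

_BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_fragments(
    path: str | Path,
    sample: SampleKey,
    join_limit: int = DEFAULT_JOIN_LIMIT,
) -> FragmentSet:
    """Read mapped fragments from a BED6 file.

    The score field encodes mapping uniqueness (1 = uniquely mapped,
    0 = multi-mapped).  Fragments longer than ``join_limit`` (the mate-join
    limit: paired mates mapped farther apart are not a valid fragment) are
    dropped and tallied in ``FragmentSet.dropped``.  Malformed lines raise
    with the offending line number.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED fields, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
                score = int(float(parts[4]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if end <= start or start < 0:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            if parts[5] not in ("+", "-", "."):
                raise ValueError(f"{path}:{lineno}: invalid strand {parts[5]!r}")
            rows.append((parts[0], start, end, parts[5], score != 0))
    if not rows:
        return FragmentSet(empty_fragment_frame(), sample, dropped=0)
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "unique"])
    too_long = (frame["end"] - frame["start"]) > join_limit
    dropped = int(too_long.sum())
    frame = frame[~too_long].reset_index(drop=True)
    return FragmentSet(frame, sample, dropped=dropped)


def write_fragments(frags: FragmentSet | pd.DataFrame, path: str | Path) -> None:
    frame = frags.frame if isinstance(frags, FragmentSet) else frags
    validate_intervals(frame)
    frame = sort_intervals(frame)
    out = pd.DataFrame(
        {
            "chrom": frame["chrom"],
            "start": frame["start"],
            "end": frame["end"],
            "name": [f"frag{i}" for i in range(len(frame))],
            "score": frame["unique"].astype(int) if "unique" in frame else 0,
            "strand": frame["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED6 file of regions into an interval frame (keeps name/score)."""
    frame = pd.read_csv(
        path, sep="\t", header=None, names=_BED6_COLS, comment="#",
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    validate_intervals(frame)
    return frame


def write_bed(frame: pd.DataFrame, path: str | Path, score_col: str | None = None) -> None:
    """Write an interval frame as BED6 in deterministic order."""
    validate_intervals(frame)
    frame = sort_intervals(frame)
    score = frame[score_col] if score_col and score_col in frame else pd.Series(0, index=frame.index)
    name = frame["name"] if "name" in frame else pd.Series(
        [f"region{i}" for i in range(len(frame))], index=frame.index
    )
    out = pd.DataFrame(
        {
            "chrom": frame["chrom"], "start": frame["start"], "end": frame["end"],
            "name": name, "score": score, "strand": frame["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


_GFF3_COLS = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]


def read_gff3(path: str | Path, feature_types: list[str] | None = None) -> pd.DataFrame:
    """Read a GFF3 annotation into an interval frame.

    GFF3 is 1-based closed; coordinates are converted to 0-based half-open.
    ``feature_types`` restricts to e.g. ["gene"] or ["transposable_element"].
    The ID attribute is exposed as ``name``, the feature type as ``feature``.
    """
    raw = pd.read_csv(
        path, sep="\t", header=None, names=_GFF3_COLS, comment="#",
        dtype={"seqid": str, "start": np.int64, "end": np.int64},
    )
    if feature_types is not None:
        raw = raw[raw["type"].isin(feature_types)]
    ids = raw["attributes"].str.extract(r"ID=([^;]+)", expand=False)
    frame = pd.DataFrame(
        {
            "chrom": raw["seqid"],
            "start": raw["start"] - 1,
            "end": raw["end"],
            "strand": raw["strand"].where(raw["strand"].isin(["+", "-"]), "."),
            "name": ids.fillna(""),
            "feature": raw["type"],
        }
    ).reset_index(drop=True)
    validate_intervals(frame)
    return frame


def write_gff3(frame: pd.DataFrame, path: str | Path, source: str = "ripcall") -> None:
    """Write an interval frame as GFF3 (converting back to 1-based closed)."""
    validate_intervals(frame)
    frame = sort_intervals(frame)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, row in frame.iterrows():
            feat = row["feature"] if "feature" in frame.columns else "region"
            name = row["name"] if "name" in frame.columns and row.get("name") else f"{feat}{i}"
            attrs = f"ID={name}"
            for extra in ("enrichment", "strand_mix"):
                if extra in frame.columns:
                    attrs += f";{extra}={row[extra]:.6g}"
            fh.write(
                f"{row['chrom']}\t{source}\t{feat}\t{row['start'] + 1}\t{row['end']}\t."
                f"\t{row['strand']}\t.\t{attrs}\n"
            )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    frame = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"],
                        dtype={"chrom": str, "size": np.int64})
    return dict(zip(frame["chrom"], frame["size"]))


def write_chrom_sizes(chrom_sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(chrom_sizes):
            fh.write(f"{chrom}\t{chrom_sizes[chrom]}\n")


def read_bedgraph(path: str | Path, chrom_sizes: dict[str, int]) -> SignalTrack:
    """Read a bedGraph into a per-base SignalTrack."""
    track = SignalTrack.zeros(chrom_sizes)
    frame = pd.read_csv(path, sep="\t", header=None,
                        names=["chrom", "start", "end", "value"], comment="#")
    for chrom, sub in frame.groupby("chrom"):
        arr = track.data.get(str(chrom))
        if arr is None:
            continue
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            arr[s:e] = v
    return track


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Write a SignalTrack as run-length-compressed bedGraph (zeros omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


_METH_COLS = ["chrom", "pos", "strand", "context", "meth_count", "total_count"]


def read_methylation(path: str | Path) -> pd.DataFrame:
    """Read a per-cytosine methylation TSV
    (chrom, pos, strand, context, meth_count, total_count)."""
    frame = pd.read_csv(path, sep="\t", header=None, names=_METH_COLS, comment="#",
                        dtype={"chrom": str, "pos": np.int64, "context": str})
    if (frame["meth_count"] > frame["total_count"]).any():
        raise ValueError("methylated_count exceeds total_count")
    if (frame["total_count"] <= 0).any():
        raise ValueError("total_count must be positive")
    if not frame["context"].isin(["CG", "CHG", "CHH"]).all():
        raise ValueError("context must be CG, CHG or CHH")
    return frame


def write_methylation(frame: pd.DataFrame, path: str | Path) -> None:
    frame = frame.sort_values(["chrom", "pos", "strand"], kind="mergesort")
    frame[_METH_COLS].to_csv(path, sep="\t", header=False, index=False)
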