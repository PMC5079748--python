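"""Interval algebra, window tiling, overlap counting, and coverage tracks.

All operations take and return :class:`pandas.DataFrame` interval frames
(columns ``chrom, start, end, strand``) and are vectorized with numpy
``searchsorted`` on per-chromosome sorted coordinate arrays; property tests
compare them with an O(n*m) brute-force scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import sort_intervals, validate_intervals


# ---------------------------------------------------------------------------
# window tiling

def make_windows(chrom_sizes: dict[str, int], width: int, step: int | None = None) -> pd.DataFrame:
    """Tile each chromosome with sliding windows of ``width`` every ``step`` bp.

    Successive windows start every ``step`` bp; the tiling stops with the
    first window reaching the chromosome end, which is truncated there if
    needed.  ``step > width`` is rejected because a gapped tiling would
    break the domain caller.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    step = width if step is None else step
    if step <= 0 or step > width:
        raise ValueError("step must satisfy 0 < step <= width")
    frames = []
    for chrom, length in chrom_sizes.items():
        length = int(length)
        if length <= 0:
            continue
        starts = np.arange(0, length, step, dtype=np.int64)
        ends = np.minimum(starts + width, length)
        # stop after the first window that reaches the chromosome end
        hit_end = np.flatnonzero(ends == length)
        if hit_end.size:
            starts = starts[: hit_end[0] + 1]
            ends = ends[: hit_end[0] + 1]
        frames.append(
            pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "strand": "."})
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "strand"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# interval set algebra

def merge_within_gap(frame: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Merge intervals on the same chromosome whose gap (next.start - prev.end)
    is <= ``gap``.  Strand is preserved when uniform within a merged run,
    otherwise set to '.'.  Idempotent for any gap >= 0."""
    if len(frame) == 0:
        return frame.copy()
    validate_intervals(frame)
    out_rows = []
    frame = sort_intervals(frame)
    for chrom, sub in frame.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        strands = sub["strand"].to_numpy()
        run_end = np.maximum.accumulate(ends)
        # a new run starts where the gap to everything before exceeds `gap`
        new_run = np.ones(len(sub), dtype=bool)
        new_run[1:] = starts[1:] - run_end[:-1] > gap
        run_id = np.cumsum(new_run) - 1
        for rid in range(run_id[-1] + 1):
            sel = run_id == rid
            s_set = set(strands[sel])
            out_rows.append(
                (chrom, starts[sel].min(), ends[sel].max(),
                 s_set.pop() if len(s_set) == 1 else ".")
            )
    return pd.DataFrame(out_rows, columns=["chrom", "start", "end", "strand"])


def intersect(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Pairwise intersection intervals of two sets (strand ignored)."""
    rows = []
    b_by_chrom = {c: s for c, s in b.groupby("chrom")}
    for _, ra in a.iterrows():
        sub = b_by_chrom.get(ra["chrom"])
        if sub is None:
            continue
        lo = np.maximum(sub["start"].to_numpy(), ra["start"])
        hi = np.minimum(sub["end"].to_numpy(), ra["end"])
        keep = hi > lo
        for s, e in zip(lo[keep], hi[keep]):
            rows.append((ra["chrom"], s, e, "."))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])


def contains(outer, inner) -> bool:
    """True iff ``inner`` lies entirely within ``outer`` (same chromosome)."""
    return (
        outer.chrom == inner.chrom
        and outer.start <= inner.start
        and inner.end <= outer.end
    )


def overlap_fraction(a, b) -> float:
    """Overlap length divided by the length of the *shorter* interval."""
    if a.chrom != b.chrom:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return ov / min(a.end - a.start, b.end - b.start)


def overlaps_any(query: pd.DataFrame, reference: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: does it overlap any reference interval (strand
    ignored)?  Reference intervals are merged per chromosome first."""
    result = np.zeros(len(query), dtype=bool)
    if len(query) == 0 or len(reference) == 0:
        return result
    merged = merge_within_gap(reference[["chrom", "start", "end", "strand"]], gap=0)
    for chrom, sub in merged.groupby("chrom"):
        mask = (query["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        r_starts = sub["start"].to_numpy()
        r_ends = sub["end"].to_numpy()
        q_start = query.loc[mask, "start"].to_numpy()
        q_end = query.loc[mask, "end"].to_numpy()
        # overlap with some merged ref iff #(ref.start < q.end) > #(ref.end <= q.start)
        n_before_end = np.searchsorted(r_starts, q_end, side="left")
        n_ended = np.searchsorted(r_ends, q_start, side="right")
        result[mask] = n_before_end > n_ended
    return result


def contains_any(outer: pd.DataFrame, inner: pd.DataFrame) -> np.ndarray:
    """Boolean per ``outer`` row: does it fully contain some ``inner`` interval?"""
    result = np.zeros(len(outer), dtype=bool)
    if len(outer) == 0 or len(inner) == 0:
        return result
    for chrom, sub in inner.groupby("chrom"):
        mask = (outer["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        order = np.argsort(sub["start"].to_numpy(), kind="mergesort")
        i_starts = sub["start"].to_numpy()[order]
        i_ends = sub["end"].to_numpy()[order]
        # suffix-min of ends over intervals sorted by start: the smallest end
        # among inner intervals starting at or after position i
        suffix_min_end = np.minimum.accumulate(i_ends[::-1])[::-1]
        o_start = outer.loc[mask, "start"].to_numpy()
        o_end = outer.loc[mask, "end"].to_numpy()
        first = np.searchsorted(i_starts, o_start, side="left")
        res = np.zeros(len(o_start), dtype=bool)
        valid = first < len(i_starts)
        res[valid] = suffix_min_end[first[valid]] <= o_end[valid]
        # the contained interval must also start before the outer end
        res[valid] &= i_starts[first[valid]] < o_end[valid]
        result[mask] = res
    return result


# ---------------------------------------------------------------------------
# overlap counting

def count_overlaps(
    features: pd.DataFrame,
    fragments: pd.DataFrame,
    mode: str = "any",
    stranded: str = "ignore",
    chrom_sizes: dict[str, int] | None = None,
) -> np.ndarray:
    """Count fragments per feature under half-open overlap semantics.

    mode 'any' counts every fragment intersecting the feature; 'contained'
    counts only fragments lying entirely within it.  ``stranded`` restricts
    fragments to the same / opposite strand as each feature, or ignores
    strand.  A fragment overlapping several features counts toward each.
    Fragments on chromosomes absent from the feature namespace (as given by
    ``chrom_sizes`` or the feature frame) trigger a warning and are skipped.
    """
    if mode not in ("any", "contained"):
        raise ValueError(f"unknown mode {mode!r}")
    if stranded not in ("same", "opposite", "ignore"):
        raise ValueError(f"unknown stranded setting {stranded!r}")
    counts = np.zeros(len(features), dtype=np.int64)
    if len(features) == 0 or len(fragments) == 0:
        return counts
    known = set(chrom_sizes) if chrom_sizes else set(features["chrom"].unique())
    unknown = set(fragments["chrom"].unique()) - known
    if unknown:
        warnings.warn(f"skipping fragments on unknown chromosomes: {sorted(unknown)}")
        fragments = fragments[~fragments["chrom"].isin(unknown)]

    def strand_subsets(frag_sub):
        """chrom-local fragment coordinate arrays keyed by strand filter."""
        out = {}
        for key in ("+", "-", None):
            sel = frag_sub if key is None else frag_sub[frag_sub["strand"] == key]
            starts = sel["start"].to_numpy()
            ends = sel["end"].to_numpy()
            order_s = np.sort(starts)
            order_by_start = np.argsort(starts, kind="mergesort")
            out[key] = (order_s, np.sort(ends), starts[order_by_start], ends[order_by_start])
        return out

    for chrom, frag_sub in fragments.groupby("chrom"):
        f_mask = (features["chrom"] == chrom).to_numpy()
        if not f_mask.any():
            continue
        subsets = strand_subsets(frag_sub)
        feat = features.loc[f_mask]
        f_start = feat["start"].to_numpy()
        f_end = feat["end"].to_numpy()
        f_strand = feat["strand"].to_numpy()
        sub_counts = np.zeros(len(feat), dtype=np.int64)
        if stranded == "ignore":
            keys = np.array([""] * len(feat))
        elif stranded == "same":
            keys = f_strand
        else:
            flip = {"+": "-", "-": "+", ".": "."}
            keys = np.array([flip[s] for s in f_strand])
        for key_label in np.unique(keys):
            ksel = keys == key_label
            key = None if key_label in ("", ".") else key_label
            sorted_starts, sorted_ends, starts_by_start, ends_by_start = subsets[key]
            if mode == "any":
                a = np.searchsorted(sorted_starts, f_end[ksel], side="left")
                b = np.searchsorted(sorted_ends, f_start[ksel], side="right")
                sub_counts[ksel] = a - b
            else:
                lo = np.searchsorted(starts_by_start, f_start[ksel], side="left")
                hi = np.searchsorted(starts_by_start, f_end[ksel], side="left")
                vals = np.zeros(int(ksel.sum()), dtype=np.int64)
                for i, (l, h, fe) in enumerate(zip(lo, hi, f_end[ksel])):
                    vals[i] = int(np.count_nonzero(ends_by_start[l:h] <= fe))
                sub_counts[ksel] = vals
        counts[f_mask] = sub_counts
    return counts


# ---------------------------------------------------------------------------
# signal tracks

@dataclass
class SignalTrack:
    """Per-base numeric signal, one numpy array per chromosome.

    Queries outside the stored range return zeros, so flank extraction at
    chromosome ends is safe.
    """

    data: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def zeros(cls, chrom_sizes: dict[str, int]) -> "SignalTrack":
        return cls({c: np.zeros(int(n)) for c, n in chrom_sizes.items()})

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        out = np.zeros(end - start)
        arr = self.data.get(chrom)
        if arr is None:
            return out
        lo, hi = max(start, 0), min(end, len(arr))
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    def total(self) -> float:
        return float(sum(a.sum() for a in self.data.values()))

    def __add__(self, other: "SignalTrack") -> "SignalTrack":
        chroms = set(self.data) | set(other.data)
        return SignalTrack(
            {c: self.values(c, 0, max(len(self.data.get(c, ())), len(other.data.get(c, ()))))
                + other.values(c, 0, max(len(self.data.get(c, ())), len(other.data.get(c, ()))))
             for c in chroms}
        )


def coverage_track(
    fragments: pd.DataFrame,
    chrom_sizes: dict[str, int],
    strand: str | None = None,
    normalize_per_million: int | None = None,
) -> SignalTrack:
    """Per-base fragment coverage; optionally restricted to one strand and/or
    RPM-scaled by ``normalize_per_million`` (a library size)."""
    track = SignalTrack.zeros(chrom_sizes)
    sub = fragments if strand is None else fragments[fragments["strand"] == strand]
    for chrom, g in sub.groupby("chrom"):
        arr = track.data.get(chrom)
        if arr is None:
            continue
        delta = np.zeros(len(arr) + 1)
        starts = np.clip(g["start"].to_numpy(), 0, len(arr))
        ends = np.clip(g["end"].to_numpy(), 0, len(arr))
        np.add.at(delta, starts, 1.0)
        np.add.at(delta, ends, -1.0)
        arr += np.cumsum(delta[:-1])
    if normalize_per_million:
        if normalize_per_million <= 0:
            raise ValueError("library size must be positive")
        for arr in track.data.values():
            arr *= 1e6 / normalize_per_million
    return track
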