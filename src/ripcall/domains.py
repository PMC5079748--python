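"""Heterochromatic-domain calling and edge-aligned analyses.

Domains are assembled from H3K9me2 ChIP fragment counts in 100 bp sliding
windows (50 bp step): windows exceeding the genome-wide median count are
kept, sequentially located (overlapping or abutting) kept windows are
merged, and merged regions longer than 1 kb are returned.  Edge profiles
align both domain ends (right ends mirrored so "inside" is positive); the
inside/outside analysis relates a target ChIP signal's log2 inside/outside
ratio at the domain's left end to nucleosome (H3) density groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import SignalTrack, count_overlaps, make_windows, merge_within_gap


def call_domains(
    fragments: pd.DataFrame,
    chrom_sizes: dict[str, int],
    width: int = 100,
    step: int = 50,
    min_len: int = 1000,
    include_empty_windows: bool = True,
) -> pd.DataFrame:
    """Call heterochromatic domains from ChIP fragments.

    The median is computed over all genome windows, including zero-count
    ones by default (``include_empty_windows=False`` restricts it to
    windows with at least one fragment).  Windows with counts strictly
    greater than the median are merged when they overlap or abut, and only
    merged regions with length > ``min_len`` are returned.
    """
    windows = make_windows(chrom_sizes, width, step)
    counts = count_overlaps(windows, fragments, mode="any", stranded="ignore",
                            chrom_sizes=chrom_sizes)
    pool = counts if include_empty_windows else counts[counts > 0]
    median = float(np.median(pool)) if pool.size else 0.0
    kept = windows[counts > median]
    if len(kept) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "strand"])
    merged = merge_within_gap(kept, gap=0)
    out = merged[(merged["end"] - merged["start"]) > min_len].reset_index(drop=True)
    out["strand"] = "."
    return out


@dataclass
class EdgeProfile:
    """Averaged edge-aligned signal: position 0 is the domain end, negative
    positions are outside the domain, positive inside."""

    positions: np.ndarray
    mean_signal: np.ndarray
    n_edges: int


def edge_profile(
    track: SignalTrack,
    domains: pd.DataFrame,
    flank: int = 300,
    ends: str = "both",
) -> EdgeProfile:
    """Average a signal track over domain ends aligned at position 0.

    Both ends contribute by default; right ends are mirrored so that
    positive positions point into the domain for every edge.  Domains
    shorter than the inward extent contribute their interior truncated
    (flanks are always kept).  ``ends`` may be 'both', 'left' or 'right'.
    """
    if ends not in ("both", "left", "right"):
        raise ValueError("ends must be 'both', 'left' or 'right'")
    span = 2 * flank  # flank bp outside and flank bp inside each end
    total = np.zeros(span)
    weight = np.zeros(span)
    n_edges = 0
    for row in domains.itertuples():
        length = row.end - row.start
        inward = min(flank, length)
        if ends in ("both", "left"):
            vals = track.values(row.chrom, row.start - flank, row.start + inward)
            total[: flank + inward] += vals
            weight[: flank + inward] += 1
            n_edges += 1
        if ends in ("both", "right"):
            vals = track.values(row.chrom, row.end - inward, row.end + flank)[::-1]
            total[: flank + inward] += vals
            weight[: flank + inward] += 1
            n_edges += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(weight > 0, total / np.maximum(weight, 1), 0.0)
    return EdgeProfile(positions=np.arange(-flank, flank), mean_signal=mean, n_edges=n_edges)


@dataclass
class InsideOutsideResult:
    table: pd.DataFrame          # per-domain H3 level and target log-ratio
    groups: pd.DataFrame         # per-group median H3 vs mean log-ratio
    slope: float
    correlation: float
    p_value: float
    n_skipped: int               # domains too close to the chromosome start


def inside_outside_ratio(
    target_track: SignalTrack,
    h3_track: SignalTrack,
    domains: pd.DataFrame,
    n_groups: int = 100,
    inner: tuple[int, int] = (50, 250),
    outer: tuple[int, int] = (50, 250),
    pseudocount: float = 0.1,
    ends: str = "left",
) -> InsideOutsideResult:
    """Target-signal log2(inside/outside) at domain edges vs H3 density.

    Inside is [start+50, start+250) of the domain, outside is
    [start-250, start-50) upstream of its left end (mirrored for right
    ends when ``ends='both'``).  Domains are ranked by mean H3 signal in
    the inside window and split into ``n_groups`` equal-size groups; per
    group the median H3 level and the mean log-ratio are reported, with a
    linear fit across groups.
    """
    lo_in, hi_in = inner
    lo_out, hi_out = outer
    rows = []
    n_skipped = 0
    for row in domains.itertuples():
        edges = []
        if ends in ("left", "both"):
            edges.append((row.start, +1))
        if ends in ("right", "both"):
            edges.append((row.end, -1))
        for edge, sign in edges:
            in_lo = edge + sign * lo_in if sign > 0 else edge - hi_in
            in_hi = edge + sign * hi_in if sign > 0 else edge - lo_in
            out_lo = edge - hi_out if sign > 0 else edge + lo_out
            out_hi = edge - lo_out if sign > 0 else edge + hi_out
            if out_lo < 0 or in_lo < 0:
                n_skipped += 1
                continue
            inside = target_track.values(row.chrom, in_lo, in_hi).mean()
            outside = target_track.values(row.chrom, out_lo, out_hi).mean()
            h3 = h3_track.values(row.chrom, in_lo, in_hi).mean()
            rows.append((row.chrom, edge,
                         np.log2((inside + pseudocount) / (outside + pseudocount)), h3))
    table = pd.DataFrame(rows, columns=["chrom", "edge", "log2_ratio", "h3"])
    if len(table) < max(n_groups, 2):
        n_groups = max(1, min(n_groups, len(table)))
    table = table.sort_values("h3", kind="mergesort").reset_index(drop=True)
    table["group"] = np.minimum(
        (np.arange(len(table)) * n_groups) // max(len(table), 1), n_groups - 1
    )
    groups = table.groupby("group").agg(
        h3_median=("h3", "median"), mean_log2_ratio=("log2_ratio", "mean"),
        n=("log2_ratio", "size"),
    ).reset_index()
    if len(groups) >= 2 and groups["h3_median"].nunique() > 1:
        fit = sps.linregress(groups["h3_median"], groups["mean_log2_ratio"])
        slope, corr, p = float(fit.slope), float(fit.rvalue), float(fit.pvalue)
    else:
        slope = corr = p = float("nan")
    return InsideOutsideResult(table, groups, slope, corr, p, n_skipped)
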