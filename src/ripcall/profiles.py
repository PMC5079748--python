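"""Scaled metagene machinery and positional analyses.

Features are scaled to a uniform body length (``body_bins`` columns, exact
fractional-base rebinning) with fixed-size flanks at native resolution;
minus-strand features are reversed so every row reads 5'->3'.  On top of
that sit strand-bias profiles (log2 sense/antisense), transposon-edge
analyses (length quartiles and >4 kb euchromatic TE edges), feature-class
enrichment against randomized regions, end-to-end distance distributions,
and chromosome-scale density in fixed windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import rpm
from .intervals import SignalTrack, coverage_track, make_windows, overlaps_any
from .stats import randomize_regions_test


# ---------------------------------------------------------------------------
# rebinning

def rebin(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Rebin a per-base vector to ``n_bins`` means with fractional-base
    weighting at bin boundaries.  Conserves total signal:
    sum(out) * len(values) / n_bins == sum(values)."""
    values = np.asarray(values, dtype=float)
    L = len(values)
    if L == 0:
        return np.zeros(n_bins)
    cum = np.concatenate(([0.0], np.cumsum(values)))

    def integral(x):
        i = np.minimum(np.floor(x).astype(int), L - 1)
        return cum[i] + (x - i) * values[i]

    edges = np.linspace(0.0, float(L), n_bins + 1)
    edges[-1] = float(L)
    sums = integral(edges[1:]) - integral(edges[:-1])
    sums[-1] = cum[-1] - integral(edges[-2:-1])[0]
    return sums / (L / n_bins)


@dataclass
class MetaProfileMatrix:
    """Per-feature binned signal: flank + scaled body + flank columns."""

    matrix: np.ndarray
    feature_ids: list[str]
    lengths: np.ndarray
    body_bins: int
    flank: int
    flank_bins: int
    signal: str = "raw"

    @property
    def average(self) -> np.ndarray:
        return self.matrix.mean(axis=0) if len(self.matrix) else np.zeros(self.n_cols)

    @property
    def n_cols(self) -> int:
        return self.body_bins + 2 * self.flank_bins

    def column_kind(self) -> np.ndarray:
        return np.array(
            ["5p_flank"] * self.flank_bins + ["body"] * self.body_bins
            + ["3p_flank"] * self.flank_bins
        )

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{k}_{i}" for k in ("up",) for i in range(self.flank_bins)]
        cols += [f"body_{i}" for i in range(self.body_bins)]
        cols += [f"down_{i}" for i in range(self.flank_bins)]
        frame = pd.DataFrame(self.matrix, columns=cols)
        frame.insert(0, "feature", self.feature_ids)
        frame.insert(1, "length", self.lengths)
        return frame

    def sorted_by_length(self) -> "MetaProfileMatrix":
        """Heatmap row order: features sorted by length."""
        order = np.argsort(self.lengths, kind="mergesort")
        return MetaProfileMatrix(
            self.matrix[order], [self.feature_ids[i] for i in order],
            self.lengths[order], self.body_bins, self.flank, self.flank_bins,
            self.signal,
        )


def _feature_row(track, chrom, start, end, strand, body_bins, flank, flank_bins, mask):
    body = track.values(chrom, start, end)
    left = track.values(chrom, start - flank, start)
    right = track.values(chrom, end, end + flank)
    if mask is not None:
        body = body * mask.values(chrom, start, end)
        left = left * mask.values(chrom, start - flank, start)
        right = right * mask.values(chrom, end, end + flank)
    row = np.concatenate([rebin(left, flank_bins), rebin(body, body_bins),
                          rebin(right, flank_bins)])
    if strand == "-":
        row = row[::-1]
    return row


def scaled_profile(
    track: SignalTrack,
    features: pd.DataFrame,
    body_bins: int = 100,
    flank: int = 300,
    flank_bins: int | None = None,
    signal: str = "raw",
    mutant_track: SignalTrack | None = None,
    pseudocount: float = 0.1,
    restrict_to: SignalTrack | None = None,
) -> MetaProfileMatrix:
    """Scale feature bodies to ``body_bins`` and keep ``flank`` bp flanks.

    signal 'raw' profiles ``track`` alone; 'ratio' divides by
    ``mutant_track`` bin-wise (pseudocounted); 'difference' subtracts it
    (the methylation convention).  ``restrict_to`` is a 0/1 mask track
    (e.g. differentially methylated regions); positions outside it
    contribute no signal.  Minus-strand features are reversed so all rows
    read 5'->3'.
    """
    if signal not in ("raw", "ratio", "difference"):
        raise ValueError(f"unknown signal {signal!r}")
    if signal != "raw" and mutant_track is None:
        raise ValueError(f"signal {signal!r} requires a mutant_track")
    flank_bins = flank if flank_bins is None else flank_bins
    rows, ids, lengths = [], [], []
    for i, row in enumerate(features.itertuples()):
        args = (row.chrom, row.start, row.end, row.strand, body_bins, flank,
                flank_bins, restrict_to)
        r = _feature_row(track, *args)
        if signal == "ratio":
            r = (r + pseudocount) / (_feature_row(mutant_track, *args) + pseudocount)
        elif signal == "difference":
            r = r - _feature_row(mutant_track, *args)
        rows.append(r)
        ids.append(getattr(row, "name", None) or f"feature{i}")
        lengths.append(row.end - row.start)
    matrix = np.vstack(rows) if rows else np.zeros((0, body_bins + 2 * flank_bins))
    return MetaProfileMatrix(matrix, ids, np.asarray(lengths), body_bins, flank,
                             flank_bins, signal)


# ---------------------------------------------------------------------------
# strand bias

@dataclass
class StrandBiasResult:
    sense: MetaProfileMatrix
    antisense: MetaProfileMatrix
    log2_ratio: np.ndarray        # averaged profile of log2(sense/antisense)
    pseudocount: float


def strand_bias_profile(
    fragments: pd.DataFrame,
    features: pd.DataFrame,
    chrom_sizes: dict[str, int],
    library_size: int,
    body_bins: int = 100,
    flank: int = 300,
    flank_bins: int | None = None,
) -> StrandBiasResult:
    """RPM coverage split into sense / antisense relative to each feature's
    strand, plus the log2 ratio of the averaged profiles.  The pseudocount
    is the RPM equivalent of one fragment, so the ratio is finite where one
    strand is empty."""
    if (features["strand"] == ".").any():
        raise ValueError("strand-bias profiles require stranded features")
    plus = coverage_track(fragments, chrom_sizes, strand="+",
                          normalize_per_million=library_size)
    minus = coverage_track(fragments, chrom_sizes, strand="-",
                           normalize_per_million=library_size)
    kw = dict(body_bins=body_bins, flank=flank, flank_bins=flank_bins)
    prof_plus = scaled_profile(plus, features, **kw)
    prof_minus = scaled_profile(minus, features, **kw)
    is_plus = (features["strand"] == "+").to_numpy()
    sense_m = np.where(is_plus[:, None], prof_plus.matrix, prof_minus.matrix)
    anti_m = np.where(is_plus[:, None], prof_minus.matrix, prof_plus.matrix)
    sense = MetaProfileMatrix(sense_m, prof_plus.feature_ids, prof_plus.lengths,
                              prof_plus.body_bins, flank, prof_plus.flank_bins, "sense_rpm")
    anti = MetaProfileMatrix(anti_m, prof_plus.feature_ids, prof_plus.lengths,
                             prof_plus.body_bins, flank, prof_plus.flank_bins, "antisense_rpm")
    pc = rpm(1, library_size)
    log2_ratio = np.log2((sense.average + pc) / (anti.average + pc))
    return StrandBiasResult(sense, anti, log2_ratio, pc)


# ---------------------------------------------------------------------------
# transposon edges

def select_euchromatic_tes(
    tes: pd.DataFrame,
    genes: pd.DataFrame,
    chrom_sizes: dict[str, int],
    min_len: int = 4000,
    tile: int = 100_000,
) -> pd.DataFrame:
    """TEs longer than ``min_len`` whose midpoint falls in a euchromatic
    tile, i.e. a fixed window containing more genes than TEs (midpoint
    counting)."""
    tiles = make_windows(chrom_sizes, tile, tile)
    gene_counts = _midpoint_counts(tiles, genes)
    te_counts = _midpoint_counts(tiles, tes)
    eu = tiles[gene_counts > te_counts]
    big = tes[(tes["end"] - tes["start"]) > min_len]
    if len(eu) == 0 or len(big) == 0:
        return big.iloc[0:0]
    mid = (big["start"] + big["end"]) // 2
    keep = overlaps_any(
        pd.DataFrame({"chrom": big["chrom"], "start": mid, "end": mid + 1,
                      "strand": "."}),
        eu,
    )
    return big[keep].reset_index(drop=True)


def te_edge_profiles(
    track: SignalTrack,
    tes: pd.DataFrame,
    span: int = 4000,
    window: int = 50,
) -> pd.DataFrame:
    """Average signal around TE 5' and 3' ends in fixed windows, TE
    orientation respected (positions increase 5'->3' along each TE; at the
    5' edge negative positions are outside the TE, at the 3' edge positive
    positions are outside)."""
    if len(tes) == 0:
        raise ValueError("no transposons left after filtering")
    n_win = 2 * span // window
    acc5 = np.zeros(n_win)
    acc3 = np.zeros(n_win)
    for row in tes.itertuples():
        if row.strand == "-":
            five = track.values(row.chrom, row.end - span, row.end + span)[::-1]
            three = track.values(row.chrom, row.start - span, row.start + span)[::-1]
        else:
            five = track.values(row.chrom, row.start - span, row.start + span)
            three = track.values(row.chrom, row.end - span, row.end + span)
        acc5 += five.reshape(n_win, window).mean(axis=1)
        acc3 += three.reshape(n_win, window).mean(axis=1)
    pos = np.arange(-span, span, window) + window // 2
    return pd.DataFrame({
        "position": pos,
        "five_prime": acc5 / len(tes),
        "three_prime": acc3 / len(tes),
    })


def te_edge_strand_table(
    fragments: pd.DataFrame,
    tes: pd.DataFrame,
    chrom_sizes: dict[str, int],
    library_size: int,
    extent: int = 500,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Per-TE log2 sense/antisense RPM ratio in the first and last
    ``extent`` bp of the TE body (sense = fragment strand equals TE
    strand).  Transcription directed into the TE gives positive ratios at
    5' edges and negative ones at 3' edges."""
    plus = coverage_track(fragments, chrom_sizes, strand="+",
                          normalize_per_million=library_size)
    minus = coverage_track(fragments, chrom_sizes, strand="-",
                           normalize_per_million=library_size)
    pc = rpm(1, library_size) if pseudocount is None else pseudocount
    rows = []
    for row in tes.itertuples():
        ext = min(extent, row.end - row.start)
        left = (row.start, row.start + ext)
        right = (row.end - ext, row.end)
        five, three = (left, right) if row.strand != "-" else (right, left)
        sense_tr, anti_tr = (plus, minus) if row.strand != "-" else (minus, plus)
        r5 = np.log2((sense_tr.values(row.chrom, *five).mean() + pc)
                     / (anti_tr.values(row.chrom, *five).mean() + pc))
        r3 = np.log2((sense_tr.values(row.chrom, *three).mean() + pc)
                     / (anti_tr.values(row.chrom, *three).mean() + pc))
        rows.append((row.chrom, row.start, row.end, row.strand, r5, r3))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                       "log2_sense_antisense_5p",
                                       "log2_sense_antisense_3p"])


def edge_direction_sign_test(table: pd.DataFrame) -> dict[str, float]:
    """Sign tests for into-TE transcription: 5'-edge ratios > 0 and
    3'-edge ratios < 0 across TEs (zeros dropped)."""
    out = {}
    for col, side in (("log2_sense_antisense_5p", "greater"),
                      ("log2_sense_antisense_3p", "less")):
        vals = table[col].to_numpy()
        vals = vals[vals != 0]
        k = int((vals > 0).sum())
        res = sps.binomtest(k, len(vals), 0.5, alternative=side)
        out[col] = float(res.pvalue)
    return out


def te_quartile_profiles(
    track: SignalTrack,
    tes: pd.DataFrame,
    calls: pd.DataFrame | None = None,
    body_bins: int = 100,
    flank: int = 300,
    flank_bins: int | None = None,
) -> dict[int, MetaProfileMatrix]:
    """Scaled profiles of TEs split into length quartiles (smallest = 1).
    When ``calls`` is given, TEs are first filtered to those overlapping
    any called transcript."""
    sub = tes
    if calls is not None:
        sub = tes[overlaps_any(tes, calls)]
    if len(sub) == 0:
        raise ValueError("no transposons overlap the called transcripts")
    lengths = (sub["end"] - sub["start"]).to_numpy()
    q = np.searchsorted(np.quantile(lengths, [0.25, 0.5, 0.75]), lengths, side="left") + 1
    return {
        quartile: scaled_profile(track, sub[q == quartile], body_bins=body_bins,
                                 flank=flank, flank_bins=flank_bins)
        for quartile in (1, 2, 3, 4)
    }


def te_edge_analysis(
    track_or_fragments,
    tes: pd.DataFrame,
    mode: str,
    chrom_sizes: dict[str, int] | None = None,
    genes: pd.DataFrame | None = None,
    calls: pd.DataFrame | None = None,
    span: int = 4000,
    window: int = 50,
    **kw,
):
    """Dispatch: 'quartiles' -> per-length-quartile scaled profiles of TEs
    overlapping calls; 'large-edges' -> 5'/3'-aligned fixed-window profiles
    of >4 kb TEs in euchromatic (gene-majority) tiles."""
    if mode == "quartiles":
        return te_quartile_profiles(track_or_fragments, tes, calls=calls, **kw)
    if mode == "large-edges":
        sub = select_euchromatic_tes(tes, genes, chrom_sizes) if genes is not None else tes
        if len(sub) == 0:
            raise ValueError("no TEs > 4 kb in euchromatic (gene-majority) tiles")
        return te_edge_profiles(track_or_fragments, sub, span=span, window=window)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# feature-class enrichment

def promoters(genes: pd.DataFrame, upstream: int = 1000) -> pd.DataFrame:
    """1 kb (by default) upstream of each gene's transcription start site."""
    plus = genes["strand"] != "-"
    start = np.where(plus, genes["start"] - upstream, genes["end"])
    end = np.where(plus, genes["start"], genes["end"] + upstream)
    out = pd.DataFrame({"chrom": genes["chrom"], "start": np.maximum(start, 0),
                        "end": end, "strand": genes["strand"]})
    return out[out["end"] > out["start"]].reset_index(drop=True)


def gene_methylation_classes(
    genes: pd.DataFrame,
    methylation: pd.DataFrame,
    chh_cut: float = 0.02,
    cg_cut: float = 0.10,
) -> pd.DataFrame:
    """Mean CHH and CG methylation per gene body and the resulting class
    labels (high/low CHH x high/low CG at the 2% / 10% cutoffs)."""
    out = genes.copy().reset_index(drop=True)
    chh = np.zeros(len(out))
    cg = np.zeros(len(out))
    by_chrom = {c: s.sort_values("pos") for c, s in methylation.groupby("chrom")}
    for i, row in enumerate(out.itertuples()):
        sub = by_chrom.get(row.chrom)
        if sub is None:
            continue
        lo, hi = np.searchsorted(sub["pos"].to_numpy(), [row.start, row.end])
        win = sub.iloc[lo:hi]
        for ctx, arr in (("CHH", chh), ("CG", cg)):
            c = win[win["context"] == ctx]
            tot = c["total_count"].sum()
            arr[i] = c["meth_count"].sum() / tot if tot else 0.0
    out["mean_chh"] = chh
    out["mean_cg"] = cg
    out["meth_class"] = np.where(chh > chh_cut, "high_chh", "low_chh")
    out["meth_class"] = out["meth_class"] + np.where(cg > cg_cut, "_high_cg", "_low_cg")
    return out


def feature_class_enrichment(
    calls: pd.DataFrame,
    classes: dict[str, pd.DataFrame],
    chrom_sizes: dict[str, int],
    n_random: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per class: members overlapping any call vs the same count for
    randomized calls; ratio = observed / mean(null); empirical p-values
    from the randomization."""
    import warnings
    rows = []
    for name, members in classes.items():
        if len(members) == 0:
            warnings.warn(f"class {name!r} has no members; skipped")
            continue
        res = randomize_regions_test(calls, members, chrom_sizes, n=n_random, seed=seed)
        rows.append((name, len(members), res.observed, float(res.null.mean()),
                     res.enrichment_ratio, res.p_enrichment, res.p_depletion))
    return pd.DataFrame(rows, columns=["class", "n_members", "observed", "null_mean",
                                       "ratio", "p_enrichment", "p_depletion"])


# ---------------------------------------------------------------------------
# end distances

def _pos5(start, end, strand):
    return start if strand != "-" else end


def _pos3(start, end, strand):
    return end if strand != "-" else start


def end_distances(
    set_a: pd.DataFrame,
    set_b: pd.DataFrame,
    min_overlap: float = 0.5,
    orientation: str = "same",
) -> pd.DataFrame:
    """Signed 5'-5' and 3'-3' end distances between overlapping feature
    pairs.

    Pairs must overlap with overlap fraction (relative to the shorter
    feature) >= min_overlap, and have equal strands (orientation 'same')
    or opposite strands ('opposite').  Distances are signed in set_a's
    orientation: positive means the set_b end lies downstream of the
    set_a end.
    """
    if orientation not in ("same", "opposite"):
        raise ValueError("orientation must be 'same' or 'opposite'")
    rows = []
    b_by_chrom = {c: s for c, s in set_b.groupby("chrom")}
    for a in set_a.itertuples():
        sub = b_by_chrom.get(a.chrom)
        if sub is None:
            continue
        for b in sub.itertuples():
            if orientation == "same" and a.strand != b.strand:
                continue
            if orientation == "opposite" and (
                a.strand == b.strand or "." in (a.strand, b.strand)
            ):
                continue
            ov = min(a.end, b.end) - max(a.start, b.start)
            if ov <= 0:
                continue
            shorter = min(a.end - a.start, b.end - b.start)
            if ov / shorter < min_overlap:
                continue
            sign = 1 if a.strand != "-" else -1
            d5 = sign * (_pos5(b.start, b.end, b.strand) - _pos5(a.start, a.end, a.strand))
            d3 = sign * (_pos3(b.start, b.end, b.strand) - _pos3(a.start, a.end, a.strand))
            rows.append((a.chrom, a.start, b.start, d5, d3))
    return pd.DataFrame(rows, columns=["chrom", "a_start", "b_start",
                                       "d5", "d3"])


# ---------------------------------------------------------------------------
# chromosome density

def _midpoint_counts(windows: pd.DataFrame, features: pd.DataFrame) -> np.ndarray:
    mid = (features["start"] + features["end"]) // 2
    points = pd.DataFrame({"chrom": features["chrom"], "start": mid,
                           "end": mid + 1, "strand": "."})
    from .intervals import count_overlaps
    return count_overlaps(windows, points, mode="any", stranded="ignore",
                          chrom_sizes=None)


def chromosome_density(
    feature_classes: dict[str, pd.DataFrame],
    chrom_sizes: dict[str, int],
    window: int = 500_000,
) -> pd.DataFrame:
    """Feature midpoints counted per fixed window, per class (a feature
    straddling a window boundary counts once, in its midpoint's window)."""
    windows = make_windows(chrom_sizes, window, window)
    out = windows[["chrom", "start", "end"]].copy()
    for name, feats in feature_classes.items():
        out[name] = _midpoint_counts(windows, feats) if len(feats) else 0
    return out
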