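"""Calling polymerase-associated transcription regions from replicated
RIP-seq fragments.

The pipeline mirrors the published procedure: pooled unique, non-genic
wild-type fragments are chained into candidate regions (fragments no more
than ``merge_gap`` apart, minimum combined read count), then filtered by
read density, by wild-type/mutant fold enrichment on unique reads and
again on all reads, stripped of candidates containing annotated genes,
tested with an exact conditional negative-binomial test across replicates
with BH-FDR correction, and finally required to show the fold enrichment
and a minimum read count in every replicate separately.

An AGO4-RIP variant uses relaxed read thresholds, a stricter fold cutoff
and no NB stage (single replicate), and classifies each call as
polymerase-dependent or -independent from RPM ratios across genotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import FragmentSet, rpm
from .intervals import contains_any, count_overlaps, overlaps_any
from .stats import bh_fdr, estimate_dispersion, nb_two_group_test


@dataclass
class CallerConfig:
    """Thresholds of the region caller.

    ``strict`` switches the combined-read and density cutoffs from
    inclusive (>=) to strict (>); the fold cutoffs are strict (>) always.
    """

    merge_gap: int = 200          # bp between chained fragments
    min_reads_combined: int = 8   # pooled unique WT reads per candidate
    min_density: float = 1.0      # unique WT reads per 100 bp
    min_fold: float = 4.0         # WT/mutant RPM ratio, unique and all reads
    min_fold_per_rep: float = 4.0
    min_reads_per_rep: int = 2    # strictly more than this per WT replicate
    alpha_p: float = 0.05
    alpha_fdr: float = 0.05
    pseudocount: int = 1          # fragments added to both counts before RPM
    strict: bool = False
    gene_removal: str = "containment"  # or "overlap"
    variant: str = "polV"

    def __post_init__(self) -> None:
        for name in ("merge_gap", "min_reads_combined", "min_density", "min_fold",
                     "min_fold_per_rep", "min_reads_per_rep"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("alpha_p", "alpha_fdr"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.gene_removal not in ("containment", "overlap"):
            raise ValueError("gene_removal must be 'containment' or 'overlap'")


#: overrides applied for the AGO4-RIP variant (single replicate, no NB test)
AGO4_OVERRIDES = dict(min_reads_combined=4, min_fold=6.0, variant="ago4")


def ago4_config(base: CallerConfig | None = None) -> CallerConfig:
    return replace(base or CallerConfig(), **AGO4_OVERRIDES)


@dataclass
class CallResult:
    calls: pd.DataFrame       # retained regions with counts, folds, p, q
    audit: pd.DataFrame       # every candidate with per-stage filter flags
    n_candidates: int
    config: CallerConfig = field(repr=False, default=None)


def select_calling_fragments(fragments: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Retain uniquely-mapped fragments with no overlap to any gene body
    (either strand)."""
    sub = fragments[fragments["unique"]]
    if len(genes):
        sub = sub[~overlaps_any(sub, genes)]
    return sub.reset_index(drop=True)


def call_candidates(fragments: pd.DataFrame, config: CallerConfig) -> pd.DataFrame:
    """Chain fragments into candidate regions, per chromosome and strand.

    Fragments whose gap to the running chain end is <= merge_gap extend
    the chain; a chain becomes a candidate spanning its fragments, kept if
    its fragment count reaches min_reads_combined.
    """
    rows = []
    for (chrom, strand), sub in fragments.groupby(["chrom", "strand"], sort=True):
        starts = np.sort(sub["start"].to_numpy())
        order = np.argsort(sub["start"].to_numpy(), kind="mergesort")
        ends = sub["end"].to_numpy()[order]
        run_end = np.maximum.accumulate(ends)
        new_chain = np.ones(len(sub), dtype=bool)
        new_chain[1:] = starts[1:] - run_end[:-1] > config.merge_gap
        chain_id = np.cumsum(new_chain) - 1
        for cid in range(chain_id[-1] + 1):
            sel = chain_id == cid
            n = int(sel.sum())
            ok = n > config.min_reads_combined if config.strict else n >= config.min_reads_combined
            if ok:
                rows.append((chrom, int(starts[sel].min()), int(ends[sel].max()), strand, n))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "n_chained"])


def _fold(num_count, num_lib, den_count, den_lib, pseudocount):
    """Pseudocounted RPM ratio; the pseudocount is added to both raw counts."""
    return ((np.asarray(num_count) + pseudocount) / num_lib) / (
        (np.asarray(den_count) + pseudocount) / den_lib
    )


def _count_one(candidates, frame):
    """Same-strand any-overlap counts; candidate intervals need not span
    every chromosome the library covers, so the unknown-chromosome warning
    of count_overlaps does not apply here."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return count_overlaps(candidates, frame, mode="any", stranded="same")


def _count(candidates, frag_sets, unique_only):
    """Pooled same-strand fragment counts over candidates for a list of
    libraries; returns (counts, total_library_size)."""
    total = np.zeros(len(candidates), dtype=np.int64)
    lib = 0
    for fs in frag_sets:
        frame = fs.frame[fs.frame["unique"]] if unique_only else fs.frame
        total += _count_one(candidates, frame)
        lib += fs.library_size
    return total, lib


def filter_candidates(
    candidates: pd.DataFrame,
    wt: list[FragmentSet],
    mut: list[FragmentSet],
    config: CallerConfig,
) -> pd.DataFrame:
    """Apply the density and the two fold-enrichment filters.

    Returns the candidate frame annotated with counts, folds and boolean
    flags ``pass_density``, ``pass_fold_unique``, ``pass_fold_all``; rows
    are not yet dropped (the audit trail keeps all of them).
    """
    cand = candidates.copy()
    if len(cand) == 0:
        for col in ("wt_unique", "mut_unique", "wt_all", "mut_all",
                    "density", "fold_unique", "fold_all"):
            cand[col] = pd.Series(dtype=float)
        for col in ("pass_density", "pass_fold_unique", "pass_fold_all"):
            cand[col] = pd.Series(dtype=bool)
        return cand
    lengths = (cand["end"] - cand["start"]).to_numpy()
    if (lengths <= 0).any():
        raise ValueError("zero-length candidate")
    wt_u, wt_lib = _count(cand, wt, unique_only=True)
    mut_u, mut_lib = _count(cand, mut, unique_only=True)
    wt_a, _ = _count(cand, wt, unique_only=False)
    mut_a, _ = _count(cand, mut, unique_only=False)
    cand["wt_unique"], cand["mut_unique"] = wt_u, mut_u
    cand["wt_all"], cand["mut_all"] = wt_a, mut_a
    cand["wt_rpm"] = rpm(wt_u, wt_lib)
    cand["mut_rpm"] = rpm(mut_u, mut_lib)
    cand["density"] = wt_u / lengths * 100.0
    cand["fold_unique"] = _fold(wt_u, wt_lib, mut_u, mut_lib, config.pseudocount)
    cand["fold_all"] = _fold(wt_a, wt_lib, mut_a, mut_lib, config.pseudocount)
    dens_ok = (
        cand["density"] > config.min_density
        if config.strict
        else cand["density"] >= config.min_density
    )
    cand["pass_density"] = dens_ok
    cand["pass_fold_unique"] = cand["fold_unique"] > config.min_fold
    cand["pass_fold_all"] = cand["fold_all"] > config.min_fold
    return cand


def finalize_calls(
    candidates: pd.DataFrame,
    wt: list[FragmentSet],
    mut: list[FragmentSet],
    genes: pd.DataFrame,
    config: CallerConfig,
) -> CallResult:
    """Gene removal, replicated NB test with BH-FDR, per-replicate filters.

    Candidates must already carry the filter_candidates annotations.  The
    NB stage requires >= 2 replicates in each group for the polV variant;
    the ago4 variant (single replicate) skips it.
    """
    cand = candidates.copy()
    nb_stage = config.variant != "ago4"
    if nb_stage and (len(wt) < 2 or len(mut) < 2):
        raise ValueError("the polV variant requires >= 2 replicates per genotype")
    if len(cand) == 0:
        cand["pass_gene"] = pd.Series(dtype=bool)
        cand["p_value"] = cand["q_value"] = pd.Series(dtype=float)
        cand["retained"] = pd.Series(dtype=bool)
        return CallResult(cand, cand, 0, config)

    if len(genes) == 0:
        cand["pass_gene"] = True
    elif config.gene_removal == "containment":
        cand["pass_gene"] = ~contains_any(cand, genes)
    else:
        cand["pass_gene"] = ~overlaps_any(cand, genes)

    # per-replicate unique same-strand counts
    rep_cols_wt, rep_cols_mut = [], []
    for i, fs in enumerate(wt, start=1):
        col = f"wt_rep{i}"
        cand[col] = _count_one(cand, fs.frame[fs.frame["unique"]])
        rep_cols_wt.append(col)
    for i, fs in enumerate(mut, start=1):
        col = f"mut_rep{i}"
        cand[col] = _count_one(cand, fs.frame[fs.frame["unique"]])
        rep_cols_mut.append(col)
    wt_libs = np.array([fs.library_size for fs in wt], dtype=float)
    mut_libs = np.array([fs.library_size for fs in mut], dtype=float)

    if nb_stage:
        counts = cand[rep_cols_wt + rep_cols_mut].to_numpy(dtype=float)
        labels = np.array(["wt"] * len(wt) + ["mut"] * len(mut))
        libs = np.concatenate([wt_libs, mut_libs])
        phi, _ = estimate_dispersion(counts, labels, libs)
        pvals = np.empty(len(cand))
        for j in range(len(cand)):
            res = nb_two_group_test(
                counts[j, : len(wt)], counts[j, len(wt):], wt_libs, mut_libs,
                dispersion=float(phi[j]), alternative="greater",
            )
            pvals[j] = res.p_value
        cand["p_value"] = pvals
        cand["q_value"] = bh_fdr(pvals)
        cand["pass_nb"] = (cand["p_value"] < config.alpha_p) & (
            cand["q_value"] < config.alpha_fdr
        )
    else:
        cand["p_value"] = np.nan
        cand["q_value"] = np.nan
        cand["pass_nb"] = True

    # per-replicate fold (replicate i of WT against replicate i of mutant,
    # cycled if the group sizes differ) and per-replicate minimum reads
    pass_rep = np.ones(len(cand), dtype=bool)
    if nb_stage:
        for i, wt_col in enumerate(rep_cols_wt):
            mut_col = rep_cols_mut[i % len(rep_cols_mut)]
            fold_i = _fold(
                cand[wt_col], wt_libs[i], cand[mut_col],
                mut_libs[i % len(mut_libs)], config.pseudocount,
            )
            fold_i = np.asarray(fold_i)
            cand[f"fold_rep{i + 1}"] = fold_i
            pass_rep &= fold_i > config.min_fold_per_rep
            pass_rep &= (cand[wt_col] > config.min_reads_per_rep).to_numpy()
    cand["pass_per_rep"] = pass_rep

    stage_flags = ["pass_density", "pass_fold_unique", "pass_fold_all",
                   "pass_gene", "pass_nb", "pass_per_rep"]
    cand["retained"] = cand[stage_flags].all(axis=1)
    calls = cand[cand["retained"]].reset_index(drop=True)
    return CallResult(calls=calls, audit=cand, n_candidates=len(cand), config=config)


def call_transcripts(
    wt: list[FragmentSet],
    mut: list[FragmentSet],
    genes: pd.DataFrame,
    config: CallerConfig | None = None,
) -> CallResult:
    """End-to-end region calling from replicated WT and mutant libraries."""
    config = config or CallerConfig()
    pooled = pd.concat([fs.frame for fs in wt], ignore_index=True)
    calling_frags = select_calling_fragments(pooled, genes)
    candidates = call_candidates(calling_frags, config)
    candidates = filter_candidates(candidates, wt, mut, config)
    return finalize_calls(candidates, wt, mut, genes, config)


def classify_dependence(
    calls: pd.DataFrame,
    wt: list[FragmentSet],
    pol_mut: list[FragmentSet],
    ago_mut: list[FragmentSet],
    min_fold: float = 4.0,
    pseudocount: int = 1,
) -> pd.Series:
    """Label each AGO4 call polymerase-dependent, -independent or
    unclassified from RPM ratios (WT/pol-mutant and pol-mutant/ago-mutant)."""
    wt_c, wt_lib = _count(calls, wt, unique_only=True)
    pol_c, pol_lib = _count(calls, pol_mut, unique_only=True)
    ago_c, ago_lib = _count(calls, ago_mut, unique_only=True)
    dep_ratio = _fold(wt_c, wt_lib, pol_c, pol_lib, pseudocount)
    indep_ratio = _fold(pol_c, pol_lib, ago_c, ago_lib, pseudocount)
    labels = np.where(
        dep_ratio >= min_fold, "dependent",
        np.where(indep_ratio >= min_fold, "independent", "unclassified"),
    )
    return pd.Series(labels, index=calls.index, name="dependence")


def call_ago4_variant(
    wt: list[FragmentSet],
    ago_mut: list[FragmentSet],
    pol_mut: list[FragmentSet],
    genes: pd.DataFrame,
    config: CallerConfig | None = None,
) -> CallResult:
    """AGO4-RIP calling (WT vs ago mutant, relaxed reads / stricter fold,
    no NB stage) plus polymerase-dependence classification of each call."""
    if not wt or not ago_mut or not pol_mut:
        raise ValueError("all three genotypes (WT, ago mutant, polymerase mutant) required")
    config = ago4_config(config)
    pooled = pd.concat([fs.frame for fs in wt], ignore_index=True)
    calling_frags = select_calling_fragments(pooled, genes)
    candidates = call_candidates(calling_frags, config)
    candidates = filter_candidates(candidates, wt, ago_mut, config)
    result = finalize_calls(candidates, wt, ago_mut, genes, config)
    result.calls = result.calls.copy()
    result.calls["dependence"] = classify_dependence(result.calls, wt, pol_mut, ago_mut)
    return result
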