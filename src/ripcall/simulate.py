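"""Synthetic genomes, annotations and assay libraries with planted ground
truth.

The generator emulates the structure of a stranded RIP-seq study of
polymerase-associated lncRNA regions in a plant genome: two genotypes
(wild type and a polymerase mutant that loses the signal) with two
replicates each, low uniform background, planted transcribed regions
(log-normal lengths, median ~700 bp) that are internally composed of
shorter consecutive RNAs (median ~200 nt), bidirectional transcription
with a configurable strand imbalance, directional transcription into
transposon bodies at TE edges, H3K9me2 domains > 1 kb, context-resolved
cytosine methylation that drops in the mutant inside planted regions, and
24-nt siRNA fragments over planted regions.

Every simulated quantity derives from a single master seed; replicate
seeds are spawned from (master seed, sample key), so datasets are byte
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FragmentSet, SampleKey
from . import io as rio


@dataclass
class SyntheticConfig:
    """Study conditions of the simulated experiment.

    Rates are fragments per kb per library; lengths in bp.  Length
    distributions are log-normal, parameterized by median and log-sigma.
    """

    seed: int = 0
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    # annotation
    n_genes: int = 300
    gene_length_median: float = 1500.0
    gene_length_sigma: float = 0.8
    short_gene_fraction: float = 0.15     # tRNA/miRNA-sized transcript class
    short_gene_length_median: float = 250.0
    short_gene_length_sigma: float = 0.4
    n_tes: int = 150
    te_length_median: float = 2000.0
    te_length_sigma: float = 0.8          # spans < 1 kb to > 4 kb
    # planted transcribed regions
    n_planted_regions: int = 200
    region_length_median: float = 700.0
    region_length_sigma: float = 0.45
    rna_length_median: float = 200.0      # internal RNA pieces
    rna_length_sigma: float = 0.25
    min_rna_length: int = 60
    enrichment: float = 10.0              # WT planted density over background
    strand_mix: float = 0.75              # sense fraction of region fragments
    te_edge_fraction: float = 0.4         # regions placed straddling TE edges
    edge_directionality: float = 0.9      # P(majority strand points into TE)
    mutant_residual: float = 0.0          # planted signal left in the mutant
    dispersion: float = 0.05              # NB over-dispersion of region counts
    # libraries
    background_rate: float = 20.0         # fragments per kb, genome-wide
    gene_rate: float = 50.0               # genic fragments per kb of gene
    fragment_size_median: float = 250.0   # library size selection
    fragment_size_sigma: float = 0.3
    min_fragment_length: int = 30
    frac_multi: float = 0.05              # multi-mapped fraction, planted/genic
    bg_unique_frac: float = 0.02          # uniquely-mappable fraction of background
    n_replicates: int = 2
    # heterochromatic domains
    n_domains: int = 40
    domain_length_median: float = 3000.0
    domain_length_sigma: float = 0.6
    h3k9me2_ratio: float = 10.0           # domain over background density
    h3k9me2_domain_rate: float | None = None  # frags/kb inside domains; overrides ratio
    h3_inside_ratio: float = 2.0          # H3 elevation inside domains
    sirna_rate: float = 100.0             # 24-nt siRNA fragments per kb of region
    # methylation
    cytosine_spacing: int = 20
    coverage: float = 50.0
    wt_chh_inside: float = 0.30
    mut_chh_inside: float = 0.03
    chh_background: float = 0.02
    cg_gene_level: float = 0.40           # gene-body CG, genotype-independent
    cg_background: float = 0.05
    chg_inside: float = 0.15
    chg_background: float = 0.02
    wt_genotype: str = "wt"
    pol_mutant: str = "polmut"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("enrichment", "background_rate", "mutant_residual", "dispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("strand_mix", "te_edge_fraction", "edge_directionality",
                     "frac_multi", "bg_unique_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class GroundTruth:
    """The planting record every downstream stage is scored against."""

    regions: pd.DataFrame   # chrom,start,end,strand,strand_mix,enrichment,rna_breaks,te_edge
    domains: pd.DataFrame
    genes: pd.DataFrame
    tes: pd.DataFrame
    chrom_sizes: dict[str, int]
    config: SyntheticConfig
    library_sizes: dict[str, int] = field(default_factory=dict)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rio.write_chrom_sizes(self.chrom_sizes, outdir / "chrom.sizes")
        genes = self.genes.assign(feature="gene")
        tes = self.tes.assign(feature="transposable_element")
        rio.write_gff3(pd.concat([genes, tes], ignore_index=True), outdir / "annotation.gff3")
        regions = self.regions.copy()
        regions["feature"] = "planted_region"
        rio.write_gff3(
            regions[["chrom", "start", "end", "strand", "feature", "enrichment", "strand_mix"]],
            outdir / "truth_regions.gff3",
        )
        rio.write_bed(self.domains, outdir / "truth_domains.bed")
        manifest = {
            "config": asdict(self.config),
            "library_sizes": self.library_sizes,
            "regions": self.regions.assign(
                rna_breaks=self.regions["rna_breaks"].map(
                    lambda b: ",".join(map(str, b))
                )
            ).to_dict(orient="records"),
            "domains": self.domains.to_dict(orient="records"),
        }
        (outdir / "truth.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    @classmethod
    def load(cls, outdir: str | Path) -> "GroundTruth":
        outdir = Path(outdir)
        manifest = json.loads((outdir / "truth.json").read_text())
        cfg = SyntheticConfig(**manifest["config"])
        regions = pd.DataFrame(manifest["regions"])
        if len(regions):
            regions["rna_breaks"] = regions["rna_breaks"].map(
                lambda s: [int(x) for x in s.split(",")] if s else []
            )
        domains = pd.DataFrame(manifest["domains"])
        ann = rio.read_gff3(outdir / "annotation.gff3")
        return cls(
            regions=regions,
            domains=domains,
            genes=ann[ann["feature"] == "gene"].reset_index(drop=True),
            tes=ann[ann["feature"] == "transposable_element"].reset_index(drop=True),
            chrom_sizes=rio.read_chrom_sizes(outdir / "chrom.sizes"),
            config=cfg,
            library_sizes=manifest["library_sizes"],
        )


# ---------------------------------------------------------------------------
# truth construction

def _lognormal_lengths(rng, n, median, sigma, lo=50):
    return np.maximum(rng.lognormal(np.log(median), sigma, size=n), lo).astype(np.int64)


class _Occupancy:
    """Per-chromosome sorted occupied intervals for rejection placement."""

    def __init__(self, chrom_sizes):
        self.by_chrom = {c: [] for c in chrom_sizes}

    def clashes(self, chrom, start, end, margin=0):
        for s, e in self.by_chrom[chrom]:
            if start - margin < e and end + margin > s:
                return True
        return False

    def add(self, chrom, start, end):
        self.by_chrom[chrom].append((start, end))


def _place(rng, chrom_sizes, length, occupied, margin, max_tries=200):
    chroms = list(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    for _ in range(max_tries):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        limit = chrom_sizes[chrom] - length
        if limit <= 0:
            continue
        start = int(rng.integers(0, limit + 1))
        if not occupied.clashes(chrom, start, start + length, margin):
            return chrom, start, start + length
    raise ValueError("genome too small to place requested features without overlap")


def _partition_rnas(rng, length, cfg: SyntheticConfig) -> list[int]:
    """Cut a region into consecutive internal RNA breakpoints (offsets from
    the region start, excluding 0, including the region length)."""
    breaks = []
    pos = 0
    while pos < length:
        piece = int(max(rng.lognormal(np.log(cfg.rna_length_median), cfg.rna_length_sigma),
                        cfg.min_rna_length))
        pos = min(pos + piece, length)
        breaks.append(pos)
    if len(breaks) > 1 and breaks[-1] - breaks[-2] < cfg.min_rna_length:
        del breaks[-2]  # absorb a runt tail into the previous RNA
    return breaks


def build_truth(config: SyntheticConfig) -> GroundTruth:
    """Place genes, TEs, planted regions and heterochromatic domains.

    Planted regions never overlap genes; a configurable fraction straddles
    a TE edge, with the majority strand pointing into the TE body (relative
    to TE orientation: sense at 5' edges, antisense at 3' edges) with
    probability ``edge_directionality``.  TE/edge pairs are cycled so edge
    coverage is even.
    """
    rng = np.random.default_rng([config.seed, 0xA11CE])
    occ = _Occupancy(config.chrom_sizes)

    def place_set(lengths, margin, strand=True):
        rows = []
        for L in lengths:
            chrom, s, e = _place(rng, config.chrom_sizes, int(L), occ, margin)
            occ.add(chrom, s, e)
            rows.append((chrom, s, e, rng.choice(["+", "-"]) if strand else "."))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])

    # gene lengths: a long-transcript bulk plus a short ncRNA-sized class,
    # so the fragment-length curve is anchored over the whole length range
    n_short = int(round(config.n_genes * config.short_gene_fraction))
    gene_lengths = np.concatenate([
        _lognormal_lengths(rng, config.n_genes - n_short,
                           config.gene_length_median, config.gene_length_sigma),
        _lognormal_lengths(rng, n_short, config.short_gene_length_median,
                           config.short_gene_length_sigma, lo=80),
    ])
    genes = place_set(gene_lengths, margin=500)
    tes = place_set(
        _lognormal_lengths(rng, config.n_tes, config.te_length_median,
                           config.te_length_sigma), margin=500)
    genes["name"] = [f"gene{i}" for i in range(len(genes))]
    tes["name"] = [f"te{i}" for i in range(len(tes))]

    # planted regions: TE-edge placements first (cycling TE x edge pairs)
    region_rows = []
    n_edge = int(round(config.n_planted_regions * config.te_edge_fraction))
    lengths = _lognormal_lengths(
        rng, config.n_planted_regions, config.region_length_median,
        config.region_length_sigma, lo=150,
    )
    edge_pairs = [(i, which) for i in range(len(tes)) for which in ("5p", "3p")]
    if edge_pairs:
        rng.shuffle(edge_pairs)
    gene_occ = _Occupancy(config.chrom_sizes)
    for _, g in genes.iterrows():
        gene_occ.add(g["chrom"], g["start"], g["end"])
    region_occ = _Occupancy(config.chrom_sizes)
    pair_idx = 0
    for k, L in enumerate(lengths):
        L = int(L)
        placed = False
        if k < n_edge and edge_pairs:
            for _ in range(len(edge_pairs)):
                te_i, which = edge_pairs[pair_idx % len(edge_pairs)]
                pair_idx += 1
                te = tes.iloc[te_i]
                left_edge = which == ("5p" if te["strand"] == "+" else "3p")
                edge = te["start"] if left_edge else te["end"]
                s = int(edge - L // 2)
                e = s + L
                chrom = te["chrom"]
                if s < 0 or e > config.chrom_sizes[chrom]:
                    continue
                if gene_occ.clashes(chrom, s, e) or region_occ.clashes(chrom, s, e, margin=1000):
                    continue
                into_te = "+" if left_edge else "-"  # genomic direction into the body
                if rng.random() < config.edge_directionality:
                    strand = into_te
                else:
                    strand = rng.choice(["+", "-"])
                region_rows.append((chrom, s, e, strand, True))
                region_occ.add(chrom, s, e)
                placed = True
                break
        if not placed:
            both = _Occupancy(config.chrom_sizes)
            both.by_chrom = {
                c: gene_occ.by_chrom[c] + region_occ.by_chrom[c] + occ.by_chrom[c]
                for c in config.chrom_sizes
            }
            chrom, s, e = _place(rng, config.chrom_sizes, L, both, margin=1000)
            region_rows.append((chrom, s, e, rng.choice(["+", "-"]), False))
            region_occ.add(chrom, s, e)
    regions = pd.DataFrame(
        region_rows, columns=["chrom", "start", "end", "strand", "te_edge"]
    )
    regions["strand_mix"] = config.strand_mix
    regions["enrichment"] = config.enrichment
    regions["rna_breaks"] = [
        _partition_rnas(rng, int(e - s), config)
        for s, e in zip(regions["start"], regions["end"])
    ]
    regions["name"] = [f"region{i}" for i in range(len(regions))]

    # heterochromatic domains, clear of genes and of each other
    dom_rows = []
    dom_occ = _Occupancy(config.chrom_sizes)
    dom_occ.by_chrom = {c: list(gene_occ.by_chrom[c]) for c in config.chrom_sizes}
    for L in _lognormal_lengths(rng, config.n_domains, config.domain_length_median,
                                config.domain_length_sigma, lo=300):
        chrom, s, e = _place(rng, config.chrom_sizes, int(L), dom_occ, margin=2000)
        dom_occ.add(chrom, s, e)
        dom_rows.append((chrom, s, e, "."))
    domains = pd.DataFrame(dom_rows, columns=["chrom", "start", "end", "strand"])

    return GroundTruth(
        regions=regions, domains=domains, genes=genes, tes=tes,
        chrom_sizes=dict(config.chrom_sizes), config=config,
    )


# ---------------------------------------------------------------------------
# fragment libraries

def _sample_rng(config: SyntheticConfig, sample: SampleKey) -> np.random.Generator:
    return np.random.default_rng([config.seed, sample.seed_offset()])


def _fragment_lengths(rng, n, cfg: SyntheticConfig):
    d = rng.lognormal(np.log(cfg.fragment_size_median), cfg.fragment_size_sigma, size=n)
    return np.clip(d, cfg.min_fragment_length, 3000).astype(np.int64)


def _background_fragments(rng, cfg, rate_per_kb, unique_frac=None):
    """Uniform background; its fragments are uniquely mappable only with
    probability ``bg_unique_frac`` (intergenic background in repeat-rich
    territory is dominated by multi-mapping alignments)."""
    if unique_frac is None:
        unique_frac = cfg.bg_unique_frac
    rows = []
    for chrom, size in cfg.chrom_sizes.items():
        n = rng.poisson(rate_per_kb * size / 1000.0)
        if n == 0:
            continue
        starts = rng.integers(0, size, size=n)
        lens = _fragment_lengths(rng, n, cfg)
        ends = np.minimum(starts + lens, size)
        keep = ends > starts
        strands = np.where(rng.random(n) < 0.5, "+", "-")
        unique = rng.random(n) < unique_frac
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts[keep], "end": ends[keep],
            "strand": strands[keep], "unique": unique[keep],
        }))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "strand", "unique"])
    return pd.concat(rows, ignore_index=True)


def _region_fragments(rng, cfg, region, n, strand_mix):
    """Fragments drawn from the internal RNAs of one planted region:
    each fragment lies within a single RNA, capped by the size selection."""
    breaks = np.asarray(region.rna_breaks, dtype=np.int64)
    starts_rna = np.concatenate(([0], breaks[:-1]))
    lens_rna = breaks - starts_rna
    picks = rng.choice(len(lens_rna), size=n, p=lens_rna / lens_rna.sum())
    cap = _fragment_lengths(rng, n, cfg)
    frag_len = np.minimum(cap, lens_rna[picks])
    offset_max = lens_rna[picks] - frag_len
    offsets = (rng.random(n) * (offset_max + 1)).astype(np.int64)
    s = region.start + starts_rna[picks] + offsets
    e = s + frag_len
    sense = rng.random(n) < strand_mix
    anti = {"+": "-", "-": "+"}[region.strand]
    return pd.DataFrame({
        "chrom": region.chrom, "start": s, "end": e,
        "strand": np.where(sense, region.strand, anti),
    })


def _interval_fragments(rng, cfg, frame, rate_per_kb, dispersion=0.0,
                        strand_mode="feature", frag_len_cap=None):
    """Poisson (optionally gamma-mixed) fragment counts per feature interval,
    fragments uniform within the feature."""
    rows = []
    for row in frame.itertuples():
        lam = rate_per_kb * (row.end - row.start) / 1000.0
        if dispersion > 0:
            lam *= rng.gamma(1.0 / dispersion, dispersion)
        n = rng.poisson(lam)
        if n == 0:
            continue
        lens = _fragment_lengths(rng, n, cfg)
        if frag_len_cap is not None:
            lens = np.minimum(lens, frag_len_cap)
        lens = np.minimum(lens, row.end - row.start)
        starts = row.start + (rng.random(n) * (row.end - row.start - lens + 1)).astype(np.int64)
        if strand_mode == "feature":
            strands = np.repeat(row.strand if row.strand in "+-" else ".", n)
        elif strand_mode == "random":
            strands = np.where(rng.random(n) < 0.5, "+", "-")
        else:
            strands = np.repeat(strand_mode, n)
        rows.append(pd.DataFrame({
            "chrom": row.chrom, "start": starts, "end": starts + lens, "strand": strands,
        }))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "strand"])
    return pd.concat(rows, ignore_index=True)


def _finish(rng, cfg, parts, sample, truth) -> FragmentSet:
    parts = [p for p in parts if len(p)]
    for p in parts:
        if "unique" not in p.columns:
            p["unique"] = rng.random(len(p)) >= cfg.frac_multi
    frame = pd.concat(parts, ignore_index=True) if parts else \
        pd.DataFrame(columns=["chrom", "start", "end", "strand", "unique"])
    frame["start"] = frame["start"].astype(np.int64)
    frame["end"] = frame["end"].astype(np.int64)
    frame["unique"] = frame["unique"].astype(bool)
    frame = frame.sort_values(["chrom", "start", "end", "strand"],
                              kind="mergesort").reset_index(drop=True)
    fs = FragmentSet(frame, sample)
    truth.library_sizes[str(sample)] = len(frame)
    return fs


def simulate_rip(truth: GroundTruth, sample: SampleKey,
                 config: SyntheticConfig | None = None) -> FragmentSet:
    """One RIP library: uniform background, genic fragments (capped by the
    transcript length — the substrate of the fragment-length regression),
    and planted-region fragments whose density is ``enrichment x background``
    in the wild type and ``mutant_residual`` of that in the polymerase
    mutant."""
    cfg = config or truth.config
    rng = _sample_rng(cfg, sample)
    parts = [_background_fragments(rng, cfg, cfg.background_rate)]
    parts.append(_interval_fragments(rng, cfg, truth.genes, cfg.gene_rate,
                                     strand_mode="feature"))
    factor = 1.0 if sample.genotype == cfg.wt_genotype else cfg.mutant_residual
    planted_rate = cfg.enrichment * cfg.background_rate * factor
    if planted_rate > 0:
        for row in truth.regions.itertuples():
            lam = planted_rate * (row.end - row.start) / 1000.0
            if cfg.dispersion > 0:
                lam *= rng.gamma(1.0 / cfg.dispersion, cfg.dispersion)
            n = rng.poisson(lam)
            if n:
                parts.append(_region_fragments(rng, cfg, row, n, row.strand_mix))
    return _finish(rng, cfg, parts, sample, truth)


TRACK_ASSAYS = ("H3K9me2", "H3", "AGO4", "siRNA")


def simulate_track(truth: GroundTruth, assay: str, sample: SampleKey,
                   config: SyntheticConfig | None = None) -> FragmentSet:
    """ChIP / siRNA libraries: H3K9me2 enriched over planted domains, H3
    near-uniform with a configurable elevation inside domains, AGO4 over
    planted regions (lost in the mutant genotype), siRNA as 24-nt
    strand-balanced fragments over planted regions."""
    cfg = config or truth.config
    if assay not in TRACK_ASSAYS:
        raise ValueError(f"unknown assay {assay!r}; expected one of {TRACK_ASSAYS}")
    rng = _sample_rng(cfg, sample)
    parts = [_background_fragments(rng, cfg, cfg.background_rate)]
    mutant = sample.genotype != cfg.wt_genotype
    if assay == "H3K9me2":
        rate = (cfg.h3k9me2_domain_rate if cfg.h3k9me2_domain_rate is not None
                else (cfg.h3k9me2_ratio - 1) * cfg.background_rate)
        parts.append(_interval_fragments(rng, cfg, truth.domains, rate,
                                         strand_mode="random"))
    elif assay == "H3":
        parts.append(_background_fragments(rng, cfg, 4 * cfg.background_rate))
        if cfg.h3_inside_ratio > 1:
            parts.append(_interval_fragments(
                rng, cfg, truth.domains,
                (cfg.h3_inside_ratio - 1) * 5 * cfg.background_rate,
                strand_mode="random"))
    elif assay == "AGO4":
        factor = cfg.mutant_residual if mutant else 1.0
        rate = cfg.enrichment * cfg.background_rate * factor
        if rate > 0:
            parts.append(_interval_fragments(rng, cfg, truth.regions, rate,
                                             dispersion=cfg.dispersion,
                                             strand_mode="random"))
    elif assay == "siRNA":
        factor = cfg.mutant_residual if mutant else 1.0
        rate = cfg.sirna_rate * factor
        if rate > 0:
            sub = _interval_fragments(rng, cfg, truth.regions, rate,
                                      strand_mode="random", frag_len_cap=24)
            sub["end"] = np.minimum(sub["start"] + 24, sub["end"])
            parts.append(sub)
    return _finish(rng, cfg, parts, sample, truth)


# ---------------------------------------------------------------------------
# methylation

def simulate_methylation(truth: GroundTruth, genotype: str,
                         config: SyntheticConfig | None = None) -> pd.DataFrame:
    """Per-cytosine binomial methylation calls on a fixed lattice
    (no sequence is simulated; contexts are assigned at random in
    proportions CG:CHG:CHH = 1:1:2).  CHH methylation is high inside
    planted regions in the wild type and drops in the polymerase mutant;
    gene-body CG methylation is genotype-independent; both strands are
    methylated symmetrically."""
    cfg = config or truth.config
    rng = np.random.default_rng([cfg.seed, SampleKey(genotype, "methylation").seed_offset()])
    frames = []
    for chrom, size in cfg.chrom_sizes.items():
        pos = np.arange(cfg.cytosine_spacing // 2, size, cfg.cytosine_spacing, dtype=np.int64)
        n = len(pos)
        context = rng.choice(["CG", "CHG", "CHH"], size=n, p=[0.25, 0.25, 0.5])
        strand = np.where(rng.random(n) < 0.5, "+", "-")

        in_region = np.zeros(n, dtype=bool)
        reg = truth.regions[truth.regions["chrom"] == chrom]
        for row in reg.itertuples():
            in_region |= (pos >= row.start) & (pos < row.end)
        in_gene = np.zeros(n, dtype=bool)
        gen = truth.genes[truth.genes["chrom"] == chrom]
        for row in gen.itertuples():
            in_gene |= (pos >= row.start) & (pos < row.end)

        chh_inside = cfg.wt_chh_inside if genotype == cfg.wt_genotype else cfg.mut_chh_inside
        p = np.full(n, cfg.chh_background)
        p[context == "CG"] = cfg.cg_background
        p[context == "CHG"] = cfg.chg_background
        p[(context == "CHH") & in_region] = chh_inside
        p[(context == "CHG") & in_region] = (
            cfg.chg_inside if genotype == cfg.wt_genotype else cfg.chg_background
        )
        p[(context == "CG") & in_gene] = cfg.cg_gene_level

        total = rng.poisson(cfg.coverage, size=n)
        keep = total > 0
        meth = rng.binomial(total[keep], p[keep])
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos[keep], "strand": strand[keep],
            "context": context[keep], "meth_count": meth, "total_count": total[keep],
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# dataset assembly and recovery scoring

def simulate_dataset(config: SyntheticConfig, outdir: str | Path | None = None):
    """Build truth and all RIP libraries (2 genotypes x n replicates);
    optionally write everything to ``outdir`` (BED fragments, GFF3
    annotation, truth manifest)."""
    truth = build_truth(config)
    samples = {}
    for genotype in (config.wt_genotype, config.pol_mutant):
        for rep in range(1, config.n_replicates + 1):
            key = SampleKey(genotype, "RIP", rep)
            samples[str(key)] = simulate_rip(truth, key, config)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, fs in samples.items():
            rio.write_fragments(fs, outdir / f"{name}.bed")
        truth.save(outdir)
    return truth, samples


def _reciprocal_matches(a: pd.DataFrame, b: pd.DataFrame, min_frac: float) -> np.ndarray:
    """Boolean per row of ``a``: some interval of ``b`` overlaps it with
    reciprocal overlap fraction >= min_frac."""
    out = np.zeros(len(a), dtype=bool)
    for chrom, sub_b in b.groupby("chrom"):
        sel = (a["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        bs = sub_b["start"].to_numpy()
        be = sub_b["end"].to_numpy()
        for idx in np.flatnonzero(sel):
            s, e = a["start"].iat[idx], a["end"].iat[idx]
            ov = np.minimum(be, e) - np.maximum(bs, s)
            frac_a = ov / (e - s)
            frac_b = ov / (be - bs)
            if np.any((frac_a >= min_frac) & (frac_b >= min_frac)):
                out[idx] = True
    return out


def score_recovery(truth_regions: pd.DataFrame, calls: pd.DataFrame,
                   min_reciprocal: float = 0.5) -> dict[str, float]:
    """Fraction of planted regions recovered by calls and fraction of calls
    matching no planted region, both at a reciprocal-overlap criterion."""
    if len(truth_regions) == 0:
        return {"recovery": float("nan"), "false_call_rate": float(len(calls) > 0),
                "n_calls": len(calls), "n_truth": 0}
    recovered = _reciprocal_matches(truth_regions, calls, min_reciprocal)
    matched = _reciprocal_matches(calls, truth_regions, min_reciprocal) if len(calls) else \
        np.zeros(0, dtype=bool)
    return {
        "recovery": float(recovered.mean()),
        "false_call_rate": float(1.0 - matched.mean()) if len(calls) else 0.0,
        "n_calls": int(len(calls)),
        "n_truth": int(len(truth_regions)),
    }
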