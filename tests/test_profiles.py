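"""Scaled metaprofiles, strand bias, TE edges, class enrichment, end
distances and chromosome density."""

import numpy as np
import pandas as pd
import pytest

from ripcall.intervals import SignalTrack, coverage_track
from ripcall.profiles import (
    chromosome_density,
    edge_direction_sign_test,
    end_distances,
    feature_class_enrichment,
    gene_methylation_classes,
    promoters,
    rebin,
    scaled_profile,
    select_euchromatic_tes,
    strand_bias_profile,
    te_edge_profiles,
    te_edge_strand_table,
    te_quartile_profiles,
)
from conftest import frame


class TestRebin:
    def test_matches_reshape_mean_on_exact_multiples(self):
        rng = np.random.default_rng(0)
        for n_bins, mult in [(10, 3), (100, 2), (7, 5)]:
            vals = rng.random(n_bins * mult)
            expect = vals.reshape(n_bins, mult).mean(axis=1)
            np.testing.assert_allclose(rebin(vals, n_bins), expect, atol=1e-9)

    def test_conserves_total_signal(self):
        rng = np.random.default_rng(1)
        for L, n_bins in [(173, 100), (50, 100), (999, 13)]:
            vals = rng.random(L)
            out = rebin(vals, n_bins)
            assert out.sum() * L / n_bins == pytest.approx(vals.sum())

    def test_short_vector_duplicates_values(self):
        out = rebin(np.array([2.0, 4.0]), 4)
        np.testing.assert_allclose(out, [2, 2, 4, 4])


class TestScaledProfile:
    sizes = {"chr1": 10_000}

    def test_constant_ratio_is_one(self):
        track = SignalTrack({"chr1": np.full(10_000, 5.0)})
        feats = frame([("chr1", 1000, 1500, "+"), ("chr1", 3000, 3300, "-")])
        mat = scaled_profile(track, feats, body_bins=50, flank=100,
                             signal="ratio", mutant_track=track)
        np.testing.assert_allclose(mat.matrix, 1.0)

    def test_body_bins_average_pairs_of_bases(self):
        rng = np.random.default_rng(2)
        arr = np.zeros(10_000)
        arr[1000:1200] = rng.random(200)
        track = SignalTrack({"chr1": arr})
        feats = frame([("chr1", 1000, 1200, "+")])
        mat = scaled_profile(track, feats, body_bins=100, flank=0, flank_bins=1)
        body = mat.matrix[0][1:-1]
        np.testing.assert_allclose(body, arr[1000:1200].reshape(100, 2).mean(axis=1),
                                   atol=1e-9)

    def test_agrees_with_per_base_oracle_on_planted_signal(self):
        rng = np.random.default_rng(3)
        feats = []
        arr = np.zeros(100_000)
        for i in range(20):
            start = 2000 + i * 4000
            L = 100 * rng.integers(2, 8)  # exact multiple of body_bins=100
            arr[start:start + L] = 1.0 + rng.random(L)
            feats.append(("chr1", start, start + L, rng.choice(["+", "-"])))
        track = SignalTrack({"chr1": arr})
        feats = frame(feats)
        mat = scaled_profile(track, feats, body_bins=100, flank=300)
        oracle_rows = []
        for r in feats.itertuples():
            L = r.end - r.start
            m = L // 100
            body = arr[r.start:r.end].reshape(100, m).mean(axis=1)
            left = arr[r.start - 300:r.start]
            right = arr[r.end:r.end + 300]
            row = np.concatenate([left, body, right])
            if r.strand == "-":
                row = row[::-1]
            oracle_rows.append(row)
        np.testing.assert_allclose(mat.matrix, np.vstack(oracle_rows), atol=1e-9)
        # elevated body, background flanks
        avg = mat.average
        assert avg[300:400].min() > 1.0
        assert avg[:300].max() == pytest.approx(0.0)

    def test_minus_strand_double_reversal_identity(self):
        rng = np.random.default_rng(4)
        arr = rng.random(5000)
        track = SignalTrack({"chr1": arr})
        plus = frame([("chr1", 1000, 1400, "+")])
        minus = frame([("chr1", 1000, 1400, "-")])
        a = scaled_profile(track, plus, body_bins=40, flank=100).matrix[0]
        b = scaled_profile(track, minus, body_bins=40, flank=100).matrix[0]
        np.testing.assert_allclose(a, b[::-1])

    def test_signal_conservation_row_sums(self):
        rng = np.random.default_rng(5)
        arr = rng.random(20_000)
        track = SignalTrack({"chr1": arr})
        feats = frame([("chr1", 5000, 5730, "+")])
        flank, body_bins = 300, 100
        mat = scaled_profile(track, feats, body_bins=body_bins, flank=flank)
        L = 730
        row = mat.matrix[0]
        total = (row[flank:flank + body_bins] * (L / body_bins)).sum() \
            + row[:flank].sum() + row[flank + body_bins:].sum()
        assert total == pytest.approx(arr[4700:6030].sum())

    def test_restrict_mask_zeroes_outside_positions(self):
        arr = np.ones(10_000)
        mask = SignalTrack({"chr1": np.zeros(10_000)})
        mask.data["chr1"][1100:1200] = 1.0
        track = SignalTrack({"chr1": arr})
        feats = frame([("chr1", 1000, 1400, "+")])
        mat = scaled_profile(track, feats, body_bins=4, flank=0, flank_bins=1,
                             restrict_to=mask)
        np.testing.assert_allclose(mat.matrix[0][1:-1], [0.0, 1.0, 0.0, 0.0])

    def test_heatmap_rows_sorted_by_length(self):
        track = SignalTrack({"chr1": np.ones(10_000)})
        feats = frame([("chr1", 0, 900, "+"), ("chr1", 2000, 2300, "+"),
                       ("chr1", 5000, 5600, "+")])
        mat = scaled_profile(track, feats, body_bins=10, flank=0, flank_bins=1)
        assert list(mat.sorted_by_length().lengths) == [300, 600, 900]


class TestStrandBias:
    sizes = {"chr1": 50_000}

    def _fragments(self, rows):
        f = frame(rows)
        f["unique"] = True
        return f

    def test_balanced_strands_give_near_zero_ratio(self):
        rng = np.random.default_rng(6)
        n = 12_000
        s = rng.integers(0, 49_000, size=n)
        frags = pd.DataFrame({"chrom": "chr1", "start": s, "end": s + 100,
                              "strand": np.where(rng.random(n) < 0.5, "+", "-"),
                              "unique": True})
        feats = frame([("chr1", i * 5000, i * 5000 + 1000, "+") for i in range(8)])
        res = strand_bias_profile(frags, feats, self.sizes, library_size=n,
                                  body_bins=50, flank_bins=30)
        assert np.abs(res.log2_ratio).max() < 0.5

    def test_sense_only_fragments(self):
        rows = [("chr1", 1000 + i * 30, 1100 + i * 30, "+") for i in range(31)]
        frags = self._fragments(rows)
        feats = frame([("chr1", 1000, 2000, "+")])
        res = strand_bias_profile(frags, feats, self.sizes, library_size=30)
        assert res.antisense.matrix.max() == 0.0
        body = res.log2_ratio[res.sense.flank_bins:-res.sense.flank_bins]
        assert body.min() > 0

    def test_strand_swap_negates_log_ratio_exactly(self):
        rng = np.random.default_rng(7)
        s = rng.integers(0, 49_000, size=500)
        strands = np.where(rng.random(500) < 0.7, "+", "-")
        frags = pd.DataFrame({"chrom": "chr1", "start": s, "end": s + 80,
                              "strand": strands, "unique": True})
        flipped = frags.copy()
        flipped["strand"] = np.where(strands == "+", "-", "+")
        feats = frame([("chr1", 2000, 3000, "+"), ("chr1", 10_000, 10_500, "-")])
        a = strand_bias_profile(frags, feats, self.sizes, library_size=500)
        b = strand_bias_profile(flipped, feats, self.sizes, library_size=500)
        np.testing.assert_allclose(a.log2_ratio, -b.log2_ratio, atol=1e-12)

    def test_unstranded_features_rejected(self):
        frags = self._fragments([("chr1", 0, 100, "+")])
        with pytest.raises(ValueError):
            strand_bias_profile(frags, frame([("chr1", 0, 100, ".")]),
                                self.sizes, library_size=1)


class TestTeEdges:
    def test_uniform_signal_gives_flat_edge_profiles(self):
        track = SignalTrack({"chr1": np.full(100_000, 1.5)})
        tes = frame([("chr1", 20_000, 30_000, "+"), ("chr1", 50_000, 60_000, "-")])
        prof = te_edge_profiles(track, tes, span=4000, window=50)
        np.testing.assert_allclose(prof["five_prime"], 1.5)
        np.testing.assert_allclose(prof["three_prime"], 1.5)

    def test_edge_confined_signal_peaks_at_edges(self):
        arr = np.zeros(200_000)
        tes = frame([("chr1", 20_000 + i * 30_000, 26_000 + i * 30_000, "+")
                     for i in range(5)])
        for r in tes.itertuples():
            arr[r.start:r.start + 500] = 1.0
            arr[r.end - 500:r.end] = 1.0
        prof = te_edge_profiles(SignalTrack({"chr1": arr}), tes, span=4000, window=50)
        n = len(prof)
        inside5 = prof["five_prime"].to_numpy()[n // 2: n // 2 + 10]
        outside5 = prof["five_prime"].to_numpy()[: n // 2]
        assert inside5.min() == pytest.approx(1.0)
        assert outside5.max() == pytest.approx(0.0)
        interior = prof["five_prime"].to_numpy()[n // 2 + 20:]
        assert interior.max() <= 0.5

    def test_into_te_transcription_sign_pattern(self):
        rng = np.random.default_rng(8)
        tes_rows, frag_rows = [], []
        for i in range(60):
            start = 10_000 + i * 12_000
            strand = "+" if i % 2 == 0 else "-"
            tes_rows.append(("chr1", start, start + 6000, strand))
            five_lo = start if strand == "+" else start + 6000 - 500
            three_lo = start + 6000 - 500 if strand == "+" else start
            for _ in range(12):
                s = int(rng.integers(five_lo, five_lo + 400))
                frag_rows.append(("chr1", s, s + 100, strand))       # sense at 5'
                s = int(rng.integers(three_lo, three_lo + 400))
                anti = "-" if strand == "+" else "+"
                frag_rows.append(("chr1", s, s + 100, anti))         # antisense at 3'
        frags = frame(frag_rows)
        frags["unique"] = True
        tes = frame(tes_rows)
        table = te_edge_strand_table(frags, tes, {"chr1": 800_000},
                                     library_size=len(frags))
        p = edge_direction_sign_test(table)
        assert p["log2_sense_antisense_5p"] < 0.01
        assert p["log2_sense_antisense_3p"] < 0.01

    def test_quartiles_split_and_filter(self):
        track = SignalTrack({"chr1": np.ones(200_000)})
        tes = frame([("chr1", i * 4000, i * 4000 + 300 + i * 60, "+") for i in range(40)])
        calls = frame([("chr1", i * 4000, i * 4000 + 200, "+") for i in range(20)])
        quartiles = te_quartile_profiles(track, tes, calls=calls, body_bins=10, flank=50)
        total = sum(len(m.lengths) for m in quartiles.values())
        assert total == 20  # only TEs overlapping calls
        assert max(quartiles[1].lengths) <= min(quartiles[4].lengths)
        with pytest.raises(ValueError):
            te_quartile_profiles(track, tes, calls=frame([("chr2", 0, 10, "+")]))

    def test_euchromatic_selection(self):
        sizes = {"chr1": 200_000, "chr2": 200_000}
        genes = frame([("chr1", i * 4000, i * 4000 + 1000, "+") for i in range(40)])
        tes = frame([
            ("chr1", 100_000, 105_000, "+"),   # big TE in gene-rich tile
            ("chr1", 110_000, 113_000, "+"),   # too short
            ("chr2", 50_000, 58_000, "-"),     # big TE but TE-majority tile
        ])
        out = select_euchromatic_tes(tes, genes, sizes)
        assert len(out) == 1 and out.loc[0, "start"] == 100_000


class TestClassEnrichment:
    sizes = {"chr1": 200_000}

    def test_calls_planted_in_tes(self):
        rng = np.random.default_rng(9)
        tes = frame([("chr1", i * 10_000, i * 10_000 + 3000, "+") for i in range(20)])
        genes = frame([("chr1", i * 10_000 + 5000, i * 10_000 + 6000, "+")
                       for i in range(20)])
        calls = frame([("chr1", i * 10_000 + 500, i * 10_000 + 900, "+")
                       for i in range(20)])
        table = feature_class_enrichment(calls, {"te": tes, "gene": genes},
                                         self.sizes, n_random=200, seed=0)
        te_row = table[table["class"] == "te"].iloc[0]
        gene_row = table[table["class"] == "gene"].iloc[0]
        assert te_row["ratio"] > 1 and te_row["p_enrichment"] < 0.01
        assert gene_row["ratio"] < 1

    def test_empty_class_skipped_with_warning(self):
        calls = frame([("chr1", 0, 100, "+")])
        with pytest.warns(UserWarning):
            table = feature_class_enrichment(
                calls, {"empty": calls.iloc[0:0], "ok": calls}, self.sizes,
                n_random=10, seed=0)
        assert table["class"].tolist() == ["ok"]

    def test_promoters_upstream_of_tss(self):
        genes = frame([("chr1", 5000, 8000, "+"), ("chr1", 20_000, 24_000, "-")])
        prom = promoters(genes, upstream=1000)
        assert (prom.loc[0, "start"], prom.loc[0, "end"]) == (4000, 5000)
        assert (prom.loc[1, "start"], prom.loc[1, "end"]) == (24_000, 25_000)

    def test_gene_methylation_class_assignment(self):
        genes = frame([("chr1", 0, 100, "+")])
        meth = pd.DataFrame({
            "chrom": ["chr1"] * 4, "pos": [10, 20, 30, 40], "strand": "+",
            "context": ["CHH", "CHH", "CG", "CG"],
            "meth_count": [5, 5, 50, 50], "total_count": [100, 100, 100, 100],
        })
        out = gene_methylation_classes(genes, meth)
        assert out.loc[0, "mean_chh"] == pytest.approx(0.05)
        assert out.loc[0, "mean_cg"] == pytest.approx(0.5)
        assert out.loc[0, "meth_class"] == "high_chh_high_cg"


class TestEndDistances:
    def test_identical_sets_give_zero_distances(self):
        a = frame([("chr1", 100, 600, "+"), ("chr1", 2000, 2400, "-")])
        table = end_distances(a, a)
        assert (table["d5"] == 0).all() and (table["d3"] == 0).all()

    def test_shifted_plus_strand_features(self):
        a = frame([("chr1", 100, 600, "+")])
        b = frame([("chr1", 110, 610, "+")])
        table = end_distances(a, b)
        assert table.loc[0, "d5"] == 10 and table.loc[0, "d3"] == 10
        # on the minus strand the same genomic shift is upstream
        am = frame([("chr1", 100, 600, "-")])
        bm = frame([("chr1", 110, 610, "-")])
        tm = end_distances(am, bm)
        assert tm.loc[0, "d5"] == -10

    def test_insufficient_overlap_excluded(self):
        a = frame([("chr1", 0, 1000, "+")])
        b = frame([("chr1", 900, 1300, "+")])  # overlap 100/400 = 0.25
        assert len(end_distances(a, b, min_overlap=0.5)) == 0
        assert len(end_distances(a, b, min_overlap=0.2)) == 1

    def test_opposite_orientation_pairing(self):
        a = frame([("chr1", 100, 600, "+")])
        b = frame([("chr1", 150, 650, "-")])
        assert len(end_distances(a, b, orientation="same")) == 0
        assert len(end_distances(a, b, orientation="opposite")) == 1


class TestChromosomeDensity:
    def test_midpoint_counting(self):
        sizes = {"chr1": 2_000_000}
        feats = frame([("chr1", i * 500_000 + 100, i * 500_000 + 200, "+")
                       for i in range(4)])
        straddler = frame([("chr1", 499_900, 500_300, "+")])  # midpoint 500100
        out = chromosome_density({"a": feats, "b": straddler, "empty": feats.iloc[0:0]},
                                 sizes, window=500_000)
        assert out["a"].tolist() == [1, 1, 1, 1]
        assert out["b"].tolist() == [0, 1, 0, 0]
        assert out["empty"].tolist() == [0, 0, 0, 0]
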