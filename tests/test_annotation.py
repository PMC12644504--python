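"""Feature assignment, TSS profiles, TE overlap and methylation summaries."""

import numpy as np
import pandas as pd
import pytest

from panacr.annotation import (
    FEATURE_CATEGORIES,
    assign_genomic_features,
    classify_te_acr_overlap,
    feature_region_sets,
    genome_background_features,
    methylation_context_summary,
    methylation_in_intervals,
    te_superfamily_enrichment,
    tss_meta_profile,
)
from panacr.errors import UsageError
from panacr.intervals import GenomeSpec, GeneModel, GenomicInterval, IntervalSet

from conftest import random_interval_set


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


def gene(gid, chrom, start, end, strand="+", exons=None):
    return GeneModel(gid, chrom, start, end, strand,
                     exons=IntervalSet(exons or [iv(chrom, start, end)]))


def brute_force_category(acr, genes, up=2000, down=2000):
    """Independent per-ACR classifier: check regions in precedence order."""
    regions = feature_region_sets(genes, up=up, down=down)
    for cat in ("upstream", "exon", "intron", "downstream"):
        for r in regions[cat]:
            if acr.overlap_bp(r) >= 1:
                return cat
    return "intergenic"


class TestAssignFeatures:
    def test_upstream_of_plus_strand_tss(self):
        g = gene("g1", "c", 5000, 8000, "+")
        labels, _ = assign_genomic_features(IntervalSet([iv("c", 3500, 4000)]), [g])
        assert labels == ["upstream"]

    def test_precedence_prefers_upstream_over_exon(self):
        g1 = gene("g1", "c", 0, 1000, "+")          # exon covers [0,1000)
        g2 = gene("g2", "c", 5000, 6000, "+")       # upstream [3000,5000)
        labels, _ = assign_genomic_features(IntervalSet([iv("c", 900, 3500)]), [g1, g2])
        assert labels == ["upstream"]

    def test_minus_strand_flanks(self):
        g = gene("g1", "c", 5000, 8000, "-")        # TSS at 7999, upstream right of gene
        labels, _ = assign_genomic_features(
            IntervalSet([iv("c", 8500, 8600), iv("c", 4500, 4600)]), [g]
        )
        assert labels == ["downstream", "upstream"]

    def test_fractions_sum_to_one_and_match_brute_force(self, rng):
        genes = [
            gene(f"g{i}", "chr1", 10_000 * i + 2000, 10_000 * i + 6000,
                 "+" if i % 2 == 0 else "-",
                 exons=[iv("chr1", 10_000 * i + 2000, 10_000 * i + 3000),
                        iv("chr1", 10_000 * i + 5000, 10_000 * i + 6000)])
            for i in range(8)
        ]
        acrs = random_interval_set(rng, 1000, chroms=("chr1",), length=90_000)
        labels, fractions = assign_genomic_features(acrs, genes)
        assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-9)
        expected = [brute_force_category(a, genes) for a in acrs]
        assert labels == expected

    def test_negative_flank_rejected(self):
        with pytest.raises(UsageError):
            assign_genomic_features(IntervalSet(), [], up=-1)


class TestBackgroundFeatures:
    def test_gene_free_genome_all_intergenic(self):
        f = genome_background_features([], GenomeSpec({"c": 100_000}))
        assert f["intergenic"] == 1.0

    def test_single_exon_gene_fraction(self):
        g = gene("g1", "c", 500_000, 501_000, "+")
        f = genome_background_features([g], GenomeSpec({"c": 1_000_000}), window=10)
        assert f["exon"] == pytest.approx(1000 / 1_000_000, abs=10 / 1_000_000)
        assert sum(f.values()) == pytest.approx(1.0, abs=1e-9)

    def test_matches_per_bp_oracle_within_one_window(self):
        genes = [gene("g1", "c", 3000, 6000, "+",
                      exons=[iv("c", 3000, 4000), iv("c", 5000, 6000)])]
        genome = GenomeSpec({"c": 20_000})
        f1 = genome_background_features(genes, genome, window=1)   # per-bp
        f10 = genome_background_features(genes, genome, window=10)
        for cat in FEATURE_CATEGORIES:
            assert f10[cat] == pytest.approx(f1[cat], abs=10 * 4 / 20_000)


class TestTssMetaProfile:
    def test_single_acr_at_tss(self):
        g = gene("g1", "c", 10_000, 12_000, "+")
        prof = tss_meta_profile(IntervalSet([iv("c", 10_000, 10_100)]), [g], flank=200)
        offsets = np.arange(-200, 201)
        assert (prof[(offsets >= 0) & (offsets <= 99)] == 1.0).all()
        assert prof.sum() == 100

    def test_minus_strand_profile_identical_after_flip(self):
        gp = gene("g1", "c", 10_000, 12_000, "+")
        gm = gene("g2", "c", 10_000, 12_000, "-")
        # ACR starting at the TSS, extending 100 bp in transcribed direction
        prof_p = tss_meta_profile(IntervalSet([iv("c", 10_000, 10_100)]), [gp], flank=200)
        prof_m = tss_meta_profile(IntervalSet([iv("c", 11_900, 12_000)]), [gm], flank=200)
        assert (prof_p == prof_m).all()

    def test_planted_offset_recovered_both_strands(self):
        genes, track = [], []
        for i in range(50):
            tss = 10_000 + 5000 * i
            if i % 2 == 0:
                genes.append(gene(f"g{i}", "c", tss, tss + 2000, "+"))
                track.append(iv("c", tss + 21, tss + 121))
            else:
                genes.append(gene(f"g{i}", "c", tss - 2000, tss + 1, "-"))
                track.append(iv("c", tss - 120, tss - 20))
        prof = tss_meta_profile(IntervalSet(track), genes, flank=500)
        assert int(np.argmax(prof)) - 500 == 21

    def test_no_genes_rejected(self):
        with pytest.raises(UsageError):
            tss_meta_profile(IntervalSet(), [], flank=10)


class TestTeAcrOverlap:
    @pytest.mark.parametrize(
        "te,acr,expected",
        [
            ((100, 200), (150, 250), "partial"),
            ((150, 200), (100, 250), "te_within_acr"),
            ((100, 600), (200, 300), "acr_within_te"),
            ((100, 200), (300, 400), "none"),
        ],
    )
    def test_containment_classes(self, te, acr, expected):
        labels, _, _ = classify_te_acr_overlap(
            IntervalSet([iv("c", *te)]), IntervalSet([iv("c", *acr)])
        )
        assert labels == [expected]

    def test_fractions_over_overlapping_tes_sum_to_100(self, rng):
        tes = random_interval_set(rng, 200)
        acrs = random_interval_set(rng, 100)
        _, counts, fractions = classify_te_acr_overlap(tes, acrs)
        if sum(counts.values()) - counts["none"] > 0:
            assert sum(fractions.values()) == pytest.approx(100.0, abs=1e-9)


class TestTeEnrichment:
    def test_fully_open_superfamily_matches_enumeration(self):
        # 3 'A' copies all inside ACRs, 9 'B' copies all outside:
        # p = C(3,3)C(9,0)/C(12,3) = 1/220
        tes = IntervalSet(
            [GenomicInterval("c", 100 + 1000 * i, 200 + 1000 * i,
                             extras={"superfamily": "A"}) for i in range(3)]
            + [GenomicInterval("c", 50_000 + 1000 * i, 50_100 + 1000 * i,
                               extras={"superfamily": "B"}) for i in range(9)]
        )
        acrs = IntervalSet([iv("c", 0, 4000)])
        df = te_superfamily_enrichment(tes, acrs)
        assert df.loc["A", "p_enriched"] == pytest.approx(1 / 220, abs=1e-12)
        assert df.loc["A", "label"] == "enriched"

    def test_zero_draws_p_enriched_one(self):
        tes = IntervalSet(
            [GenomicInterval("c", 100, 200, extras={"superfamily": "A"})]
        )
        df = te_superfamily_enrichment(tes, IntervalSet([iv("c", 5000, 5100)]))
        assert df.loc["A", "p_enriched"] == 1.0

    def test_proportional_distribution_mostly_neutral(self, rng):
        # TE copies placed uniformly; the hit rate per superfamily matches the
        # genome-wide rate, so at alpha=0.05 >= 95%-ish of null draws are neutral
        neutral = 0
        trials = 40
        for t in range(trials):
            r = np.random.default_rng(100 + t)
            tes = IntervalSet(
                [GenomicInterval("c", int(p), int(p) + 50,
                                 extras={"superfamily": "X"})
                 for p in r.integers(0, 99_000, 80)]
            )
            acrs = IntervalSet([iv("c", 0, 30_000)])
            # one tested family among a matching background family
            bg = IntervalSet(
                [GenomicInterval("c", int(p), int(p) + 50,
                                 extras={"superfamily": "Y"})
                 for p in r.integers(0, 99_000, 80)]
            )
            df = te_superfamily_enrichment(IntervalSet(list(tes) + list(bg)), acrs)
            neutral += (df.loc["X", "label"] == "neutral")
        assert neutral >= int(0.85 * trials)


def make_calls(spec):
    """spec: list of (context, n_sites, n_methylated)."""
    rows = []
    pos = 0
    for ctx, n, m in spec:
        for i in range(n):
            rows.append(("c", pos, "+", ctx, 10 if i < m else 0, 10))
            pos += 3
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "methylated", "total"]
    )


class TestMethylationSummary:
    def test_all_methylated(self):
        calls = make_calls([("CpG", 5, 5), ("CHH", 5, 5)])
        out = methylation_context_summary(calls)
        assert out["overall_pct"] == 100.0
        assert out["per_context"]["CpG"]["pct_methylated"] == 100.0

    def test_decomposition_sums_to_overall(self):
        # context mix whose per-context rates are ~75.77 / 41.64 / 5.47 %
        calls = make_calls([("CpG", 1065, 807), ("CHG", 1112, 463), ("CHH", 7825, 428)])
        out = methylation_context_summary(calls)
        d = out["decomposition_pct"]
        assert round(d["CpG"], 2) == 8.07
        assert round(d["CHG"], 2) == 4.63
        assert round(d["CHH"], 2) == 4.28
        assert round(out["overall_pct"], 2) == 16.98
        assert sum(d.values()) == pytest.approx(out["overall_pct"], abs=1e-9)
        assert round(out["per_context"]["CpG"]["pct_methylated"], 2) == 75.77

    def test_zero_coverage_sites_excluded_and_counted(self):
        calls = make_calls([("CpG", 4, 2)])
        calls.loc[0, "total"] = 0
        out = methylation_context_summary(calls)
        assert out["excluded_zero_coverage"] == 1
        assert out["sites"] == 3


class TestMethylationInIntervals:
    def test_whole_genome_regions_match_summary(self):
        calls = make_calls([("CpG", 100, 60), ("CHH", 200, 10)])
        regions = IntervalSet([iv("c", 0, 10_000)])
        out = methylation_in_intervals(calls, regions)
        summ = methylation_context_summary(calls)
        assert out["inside"]["pct_methylated"] == pytest.approx(summ["overall_pct"])

    def test_region_without_cytosines_not_available(self):
        calls = make_calls([("CpG", 10, 5)])
        out = methylation_in_intervals(calls, IntervalSet([iv("c", 90_000, 91_000)]))
        assert out["inside"]["sites"] == 0
        assert out["inside"]["pct_methylated"] is None

    def test_hypomethylated_regions_flagged_depleted(self):
        calls = make_calls([("CpG", 500, 400)])
        # first 150 sites (pos < 450) forced unmethylated, acting as open chromatin
        calls.loc[calls["pos"] < 450, "methylated"] = 0
        out = methylation_in_intervals(calls, IntervalSet([iv("c", 0, 450)]))
        assert out["inside"]["pct_methylated"] < out["outside"]["pct_methylated"]
        assert out["p_depleted"] < 0.05
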