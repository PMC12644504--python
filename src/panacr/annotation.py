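"""Genomic-landscape annotation of ACRs.

Feature-category assignment uses a single-label precedence rule
(upstream > exon > intron > downstream > intergenic) on any-bp overlap,
promoter-first because promoter-proximal ACRs are the biologically loaded
category. TSS meta-profiles are strand-aware (minus-strand genes are
flipped so positive offsets point in the transcribed direction).
TE/ACR relationships are reported both as containment classes and as
per-superfamily hypergeometric enrichment over TE copies. Methylation
summaries count a cytosine as methylated when its read fraction reaches a
threshold (default 0.5).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import UsageError
from .intervals import GenomeSpec, GeneModel, GenomicInterval, IntervalSet
from .stats import hypergeom_lower, hypergeom_upper

logger = logging.getLogger(__name__)

FEATURE_CATEGORIES = ("upstream", "exon", "intron", "downstream", "intergenic")
CONTEXTS = ("CpG", "CHG", "CHH")


def _clip(start: int, end: int, genome: GenomeSpec | None, chrom: str):
    lo = max(0, start)
    hi = end if genome is None else min(end, genome.contigs.get(chrom, end))
    return (lo, hi) if lo < hi else None


def feature_region_sets(
    genes: list[GeneModel], up: int = 2000, down: int = 2000,
    genome: GenomeSpec | None = None,
) -> dict[str, IntervalSet]:
    """Upstream/exon/intron/downstream interval sets from gene models."""
    if up < 0 or down < 0:
        raise UsageError("flank sizes must be non-negative")
    regions: dict[str, list[GenomicInterval]] = {
        "upstream": [], "exon": [], "intron": [], "downstream": [],
    }
    for g in genes:
        if g.strand == "+":
            ups = _clip(g.tss - up, g.tss, genome, g.chrom)
            dns = _clip(g.tts + 1, g.tts + 1 + down, genome, g.chrom)
        else:
            ups = _clip(g.tss + 1, g.tss + 1 + up, genome, g.chrom)
            dns = _clip(g.tts - down, g.tts, genome, g.chrom)
        if ups:
            regions["upstream"].append(GenomicInterval(g.chrom, *ups))
        if dns:
            regions["downstream"].append(GenomicInterval(g.chrom, *dns))
        regions["exon"].extend(g.exons)
        regions["intron"].extend(g.introns)
    return {k: IntervalSet(v).merge() for k, v in regions.items()}


def assign_genomic_features(
    acrs: IntervalSet,
    genes: list[GeneModel],
    up: int = 2000,
    down: int = 2000,
    genome: GenomeSpec | None = None,
) -> tuple[list[str], dict[str, float]]:
    """One category per ACR by precedence; returns labels (canonical ACR
    order) and category fractions summing to 1."""
    _warn_on_gene_overlap(genes)
    regions = feature_region_sets(genes, up=up, down=down, genome=genome)
    labels = np.array(["intergenic"] * len(acrs), dtype=object)
    unassigned = np.ones(len(acrs), dtype=bool)
    for cat in ("upstream", "exon", "intron", "downstream"):
        if not unassigned.any():
            break
        mask = acrs.overlap_mask(regions[cat], min_bp=1)
        take = mask & unassigned
        labels[take] = cat
        unassigned &= ~mask
    n = max(1, len(acrs))
    fractions = {c: float((labels == c).sum()) / n for c in FEATURE_CATEGORIES}
    return list(labels), fractions


def _warn_on_gene_overlap(genes: list[GeneModel]) -> None:
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        gs.sort(key=lambda g: g.start)
        for a, b in zip(gs, gs[1:]):
            if b.start < a.end:
                logger.warning(
                    "overlapping genes %s and %s on %s; precedence applies",
                    a.gene_id, b.gene_id, chrom,
                )


def genome_background_features(
    genes: list[GeneModel],
    genome: GenomeSpec,
    window: int = 10,
    up: int = 2000,
    down: int = 2000,
) -> dict[str, float]:
    """Category fractions for non-overlapping tiling windows over the genome,
    classified with the same any-bp precedence rule as ACRs."""
    if window < 1:
        raise UsageError(f"window must be >= 1, got {window}")
    regions = feature_region_sets(genes, up=up, down=down, genome=genome)
    # category codes, lowest precedence written first so higher overwrites
    order = ["downstream", "intron", "exon", "upstream"]
    code_of = {c: i + 1 for i, c in enumerate(order)}  # 0 = intergenic
    counts = np.zeros(5, dtype=np.int64)
    for chrom, length in genome.contigs.items():
        nwin = -(-length // window)
        codes = np.zeros(nwin, dtype=np.int8)
        for cat in order:
            for chrom2, (st, en) in regions[cat].by_chrom().items():
                if chrom2 != chrom:
                    continue
                w0 = st // window
                w1 = -(-en // window)
                for a, b in zip(w0, w1):
                    codes[a:b] = code_of[cat]
        counts += np.bincount(codes, minlength=5)
    total = counts.sum()
    names = {0: "intergenic", **{v: k for k, v in code_of.items()}}
    return {names[i]: float(counts[i]) / total for i in range(5)}


def tss_meta_profile(
    track: IntervalSet, genes: list[GeneModel], flank: int = 2000
) -> np.ndarray:
    """Fraction of genes covered by the track at each offset in
    [-flank, +flank] relative to the TSS (transcribed direction positive)."""
    if not genes:
        raise UsageError("need >= 1 gene")
    merged = track.merge().by_chrom()
    width = 2 * flank + 1
    acc = np.zeros(width, dtype=np.int64)
    for g in genes:
        cov = np.zeros(width, dtype=bool)
        w_start = g.tss - flank
        w_end = g.tss + flank + 1
        if g.chrom in merged:
            st, en = merged[g.chrom]
            lo = int(np.searchsorted(en, w_start, side="right"))
            hi = int(np.searchsorted(st, w_end, side="left"))
            for s, e in zip(st[lo:hi], en[lo:hi]):
                a = max(int(s), w_start) - w_start
                b = min(int(e), w_end) - w_start
                if a < b:
                    cov[a:b] = True
        if g.strand == "-":
            cov = cov[::-1]
        acc += cov
    return acc / len(genes)


# ------------------------------------------------------------------ TE overlap

TE_CLASSES = ("partial", "te_within_acr", "acr_within_te", "none")


def classify_te_acr_overlap(
    tes: IntervalSet, acrs: IntervalSet
) -> tuple[list[str], dict[str, int], dict[str, float]]:
    """Containment class per TE against the merged ACR union.

    te_within_acr: the TE lies entirely inside an ACR; acr_within_te: the
    TE contains an entire ACR; partial: >= 1 bp shared otherwise. Fractions
    are over ACR-overlapping TEs and sum to 100%.
    """
    merged = acrs.merge()
    amap = merged.by_chrom()
    labels = []
    for te in tes:
        label = "none"
        if te.chrom in amap:
            st, en = amap[te.chrom]
            lo = int(np.searchsorted(en, te.start, side="right"))
            hi = int(np.searchsorted(st, te.end, side="left"))
            if lo < hi:
                sub_s, sub_e = st[lo:hi], en[lo:hi]
                if ((sub_s <= te.start) & (sub_e >= te.end)).any():
                    label = "te_within_acr"
                elif ((sub_s >= te.start) & (sub_e <= te.end)).any():
                    label = "acr_within_te"
                else:
                    label = "partial"
        labels.append(label)
    counts = {c: labels.count(c) for c in TE_CLASSES}
    n_overlap = len(tes) - counts["none"]
    fractions = {
        c: (100.0 * counts[c] / n_overlap if n_overlap else float("nan"))
        for c in TE_CLASSES if c != "none"
    }
    return labels, counts, fractions


def te_superfamily_enrichment(
    tes: IntervalSet, acrs: IntervalSet, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-superfamily hypergeometric enrichment of TE copies in open chromatin.

    Urn: population = all TE copies, successes = copies of the superfamily,
    draws = TE copies overlapping ACRs (>= 1 bp), observed = superfamily
    copies overlapping ACRs. Raw labels at ``alpha`` plus a Bonferroni column.
    """
    sfs = [te.extras.get("superfamily", te.name or "NA") for te in tes]
    hit = tes.overlap_mask(acrs.merge(), min_bp=1)
    N = len(tes)
    n_draws = int(hit.sum())
    rows = []
    uniq = sorted(set(sfs))
    for sf in uniq:
        idx = np.array([s == sf for s in sfs])
        K = int(idx.sum())
        if K == 0:
            logger.warning("superfamily %s absent; skipped", sf)
            continue
        k = int((idx & hit).sum())
        p_enr = hypergeom_upper(k, N, K, n_draws)
        p_dep = hypergeom_lower(k, N, K, n_draws)
        rows.append(
            {
                "superfamily": sf,
                "copies": K,
                "in_acr": k,
                "expected": n_draws * K / N if N else float("nan"),
                "p_enriched": p_enr,
                "p_depleted": p_dep,
                "label": (
                    "enriched" if p_enr < alpha
                    else "depleted" if p_dep < alpha
                    else "neutral"
                ),
            }
        )
    df = pd.DataFrame(rows).set_index("superfamily")
    m = len(df)
    df["p_enriched_bonferroni"] = np.minimum(1.0, df["p_enriched"] * m)
    df["p_depleted_bonferroni"] = np.minimum(1.0, df["p_depleted"] * m)
    return df


# ----------------------------------------------------------------- methylation

def methylation_context_summary(calls: pd.DataFrame, tau: float = 0.5) -> dict:
    """Per-context and overall methylated-cytosine fractions (percent).

    ``calls`` columns: chrom, pos, strand, context, methylated, total.
    A site is methylated iff methylated/total >= tau. Sites with total = 0
    are excluded (and counted). The context decomposition of the overall
    fraction (methylated Cs of a context / all Cs) sums to the overall value.
    """
    usable = calls[calls["total"] > 0]
    n_excluded = len(calls) - len(usable)
    if n_excluded:
        logger.info("excluded %d site(s) with zero coverage", n_excluded)
    if len(usable) == 0:
        raise UsageError("no covered cytosine sites")
    is_meth = usable["methylated"] / usable["total"] >= tau
    n_all = len(usable)
    per_context = {}
    decomposition = {}
    for ctx in CONTEXTS:
        sel = usable["context"] == ctx
        n_ctx = int(sel.sum())
        n_m = int((sel & is_meth).sum())
        per_context[ctx] = {
            "sites": n_ctx,
            "methylated": n_m,
            "pct_methylated": 100.0 * n_m / n_ctx if n_ctx else float("nan"),
        }
        decomposition[ctx] = 100.0 * n_m / n_all
    overall = 100.0 * float(is_meth.sum()) / n_all
    return {
        "per_context": per_context,
        "decomposition_pct": decomposition,
        "overall_pct": overall,
        "sites": n_all,
        "excluded_zero_coverage": n_excluded,
    }


def _positions_in_regions(calls: pd.DataFrame, regions: IntervalSet) -> np.ndarray:
    rmap = regions.merge().by_chrom()
    inside = np.zeros(len(calls), dtype=bool)
    pos = calls["pos"].values.astype(np.int64)
    chroms = calls["chrom"].values
    for chrom, (st, en) in rmap.items():
        sel = np.flatnonzero(chroms == chrom)
        if len(sel) == 0:
            continue
        j = np.searchsorted(st, pos[sel], side="right") - 1
        ok = (j >= 0) & (pos[sel] < en[np.clip(j, 0, None)])
        inside[sel[ok]] = True
    return inside


def methylation_in_intervals(
    calls: pd.DataFrame, regions: IntervalSet, tau: float = 0.5
) -> dict:
    """Methylated fractions inside vs outside a region set, plus a
    hypergeometric enrichment report over cytosine positions and a bp-mode
    fraction (methylated Cs per region bp)."""
    usable = calls[calls["total"] > 0].reset_index(drop=True)
    if len(usable) == 0:
        raise UsageError("no covered cytosine sites")
    is_meth = (usable["methylated"] / usable["total"] >= tau).values
    inside = _positions_in_regions(usable, regions)
    region_bp = regions.merge().total_bp

    def _summ(mask):
        n = int(mask.sum())
        m = int((mask & is_meth).sum())
        return {
            "sites": n,
            "methylated": m,
            "pct_methylated": 100.0 * m / n if n else None,
        }

    N = len(usable)
    K = int(is_meth.sum())
    n = int(inside.sum())
    k = int((inside & is_meth).sum())
    return {
        "inside": _summ(inside),
        "outside": _summ(~inside),
        "bp_mode_pct": 100.0 * k / region_bp if region_bp else None,
        "p_enriched": hypergeom_upper(k, N, K, n),
        "p_depleted": hypergeom_lower(k, N, K, n),
    }
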