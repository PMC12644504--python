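"""Selective-sweep regions and their enrichment in differential ACRs.

Sweep regions are the top fraction (default 0.01%) of genome-wide sweep
statistic windows, selected per species with deterministic tie-breaking,
then merged. Enrichment of sweep bp inside dACR bp is a bp-granularity
hypergeometric test (population = genome bp, successes = sweep bp, draws =
dACR bp). Treating each bp as exchangeable ignores spatial autocorrelation;
results carry a caveat flag, and a block-placement permutation p-value is
available as a robustness check.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import IntegrityError, UsageError, ValidationError
from .intervals import GenomeSpec, GenomicInterval, IntervalSet
from .stats import hypergeom_upper


def sweep_regions_from_scores(
    windows: IntervalSet, top_fraction: float = 0.0001, include_ties: bool = False
) -> IntervalSet:
    """Merge the top-scoring k = max(1, floor(top_fraction * n)) windows.

    Ordering is (score descending, chrom, start) so the selection is
    deterministic; ``include_ties`` instead keeps every window whose score
    ties the k-th.
    """
    if len(windows) == 0:
        raise UsageError("need >= 1 scored window")
    if not (0.0 < top_fraction < 1.0):
        raise UsageError(f"top_fraction must be in (0, 1), got {top_fraction}")
    scores = []
    for i, w in enumerate(windows):
        if w.score is None or not math.isfinite(w.score):
            raise ValidationError(f"non-finite score at window {i} ({w.chrom}:{w.start})")
        scores.append(w.score)
    n = len(windows)
    k = max(1, int(math.floor(top_fraction * n)))
    order = sorted(range(n), key=lambda i: (-scores[i], windows[i].chrom, windows[i].start))
    if include_ties:
        cutoff = scores[order[k - 1]]
        chosen = [i for i in range(n) if scores[i] >= cutoff]
    else:
        chosen = order[:k]
    return IntervalSet([windows[i] for i in chosen]).merge()


def dacr_sweep_overlap(dacrs: IntervalSet, sweeps: IntervalSet) -> dict:
    """Fraction of dACRs sharing >= 1 bp with sweep regions, plus overlap bp."""
    if len(dacrs) == 0:
        return {"overlapping": 0, "total": 0, "fraction": None, "overlap_bp": 0}
    hit, _ = dacrs.overlaps_any(sweeps, min_bp=1) if len(sweeps) else (IntervalSet(), dacrs)
    overlap_bp = dacrs.intersect(sweeps).total_bp if len(sweeps) else 0
    return {
        "overlapping": len(hit),
        "total": len(dacrs),
        "fraction": len(hit) / len(dacrs),
        "overlap_bp": overlap_bp,
    }


def sweep_in_dacr_enrichment(
    dacrs: IntervalSet, sweeps: IntervalSet, genome: GenomeSpec,
    denominator: str = "effective",
) -> dict:
    """bp-level hypergeometric enrichment of sweep bp within dACR bp."""
    N = genome.effective_size if denominator == "effective" else genome.assembly_size
    K = sweeps.merge().total_bp
    n = dacrs.merge().total_bp
    k = dacrs.intersect(sweeps).total_bp
    if K > N or n > N:
        raise UsageError("sweep/dACR bp exceed the genome denominator")
    if k > min(K, n):
        raise IntegrityError("overlap bp exceeds min(sweep bp, dACR bp)")
    return {
        "observed_bp": k,
        "expected_bp": n * K / N if N else float("nan"),
        "sweep_bp": K,
        "dacr_bp": n,
        "genome_bp": N,
        "p_enriched": hypergeom_upper(k, N, K, n),
        "caveat": "bp treated as exchangeable units; spatial autocorrelation ignored",
    }


def block_permutation_p(
    dacrs: IntervalSet, sweeps: IntervalSet, genome: GenomeSpec,
    n_perm: int = 200, seed: int | None = None,
) -> float:
    """Robustness check: p-value from re-placing the sweep blocks uniformly
    at random on the genome and recomputing overlap bp."""
    rng = np.random.default_rng(seed)
    merged = sweeps.merge()
    observed = dacrs.intersect(merged).total_bp
    contigs = list(genome.contigs.items())
    lengths = np.array([l for _, l in contigs], dtype=float)
    probs = lengths / lengths.sum()
    hits = 0
    for _ in range(n_perm):
        placed = []
        for block in merged:
            ci = rng.choice(len(contigs), p=probs)
            chrom, clen = contigs[ci]
            if block.length >= clen:
                placed.append(GenomicInterval(chrom, 0, clen))
                continue
            start = int(rng.integers(0, clen - block.length))
            placed.append(GenomicInterval(chrom, start, start + block.length))
        perm_overlap = dacrs.intersect(IntervalSet(placed)).total_bp
        if perm_overlap >= observed:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def genes_near_intervals(
    query: IntervalSet, genes, dist: int = 2000
) -> tuple[set, list]:
    """Genes associated with query intervals: overlap of the gene body or an
    interval edge within ``dist`` bp of the TSS or TTS (inclusive at
    exactly ``dist``)."""
    if dist < 0:
        raise UsageError(f"dist must be >= 0, got {dist}")
    gene_ids = set()
    pairs = []
    for g in genes:
        for iv in query:
            if iv.chrom != g.chrom:
                continue
            body_overlap = min(iv.end, g.end) - max(iv.start, g.start) > 0
            near = False
            for point in (g.tss, g.tts):
                # gap between the interval's nearest edge and the point
                if iv.start <= point < iv.end:
                    d = 0
                elif point < iv.start:
                    d = iv.start - point
                else:
                    d = point - iv.end
                if d <= dist:
                    near = True
            if body_overlap or near:
                gene_ids.add(g.gene_id)
                pairs.append((iv, g.gene_id))
    return gene_ids, pairs


def normalized_depth_profile(
    depth: np.ndarray, window: GenomicInterval, acrs: IntervalSet
) -> tuple[np.ndarray, np.ndarray]:
    """Depth normalized by its window mean (output mean exactly 1), plus a
    boolean ACR mask aligned to the window."""
    depth = np.asarray(depth, dtype=float)
    if len(depth) != window.length:
        raise UsageError(
            f"depth length {len(depth)} != window length {window.length}"
        )
    mean = depth.mean()
    if mean <= 0:
        raise UsageError("cannot normalize an all-zero depth track")
    mask = np.zeros(window.length, dtype=bool)
    for iv in acrs.merge():
        if iv.chrom != window.chrom:
            continue
        a = max(iv.start, window.start) - window.start
        b = min(iv.end, window.end) - window.start
        if a < b:
            mask[a:b] = True
    return depth / mean, mask
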