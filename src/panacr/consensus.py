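"""Per-sample ACR filters and multi-sample consensus construction.

Filter order: length filter (peaks > 4 kb are putative false positives) ->
subtraction of peaks also called in whole-genome-sequencing controls
(mappability artifacts) -> cross-sample fusion with a minimum-support rule
(an ACR seen in only one sample is discarded). Support is counted as
distinct samples at the fusion-cluster level; a sample contributing two
peaks to one cluster counts once. Single-linkage fusion can chain staggered
peaks past 4 kb; the length rule applies to called peaks only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import UsageError, ValidationError
from .intervals import GenomicInterval, IntervalSet

logger = logging.getLogger(__name__)


@dataclass
class PeakSample:
    """One sample's peak calls plus its metadata."""

    sample_id: str
    accession: str
    species: str
    tissue: str
    peaks: IntervalSet = field(default_factory=IntervalSet)

    def __post_init__(self):
        for f in ("sample_id", "accession", "species", "tissue"):
            if not getattr(self, f):
                raise ValidationError(f"PeakSample.{f} must be non-empty")


@dataclass
class ConsensusACR:
    """A fused interval with the distinct samples supporting it."""

    interval: GenomicInterval
    support: frozenset
    tissues: frozenset
    scope: str = "run"

    @property
    def n_support(self) -> int:
        return len(self.support)


def filter_by_length(sample: PeakSample, max_len: int = 4000) -> PeakSample:
    """Drop peaks strictly longer than ``max_len`` bp (a 4000-bp peak is kept)."""
    if max_len <= 0:
        raise UsageError(f"max_len must be positive, got {max_len}")
    kept = [iv for iv in sample.peaks if iv.length <= max_len]
    removed = len(sample.peaks) - len(kept)
    if removed:
        logger.info(
            "%s: removed %d peak(s) longer than %d bp", sample.sample_id, removed, max_len
        )
    return replace(sample, peaks=IntervalSet(kept))


def subtract_wgs_artifacts(sample: PeakSample, wgs_peaks: IntervalSet) -> PeakSample:
    """Remove, entirely, every ATAC peak overlapping (>= 1 bp) a WGS control peak."""
    mask = sample.peaks.overlap_mask(wgs_peaks, min_bp=1)
    kept = [iv for iv, hit in zip(sample.peaks, mask) if not hit]
    removed = len(sample.peaks) - len(kept)
    if removed:
        logger.info(
            "%s: removed %d peak(s) overlapping WGS control peaks",
            sample.sample_id, removed,
        )
    return replace(sample, peaks=IntervalSet(kept))


def apply_sample_filters(
    samples: list[PeakSample],
    wgs_by_accession: dict[str, IntervalSet] | None = None,
    max_len: int = 4000,
) -> list[PeakSample]:
    """Length filter then WGS subtraction for every sample.

    ``wgs_by_accession`` maps accession id -> control peak set; a missing
    accession raises. Pass ``None`` to skip subtraction.
    """
    out = []
    if wgs_by_accession is not None:
        missing = sorted(
            {s.accession for s in samples} - set(wgs_by_accession)
        )
        if missing:
            raise ValidationError(
                f"no WGS control peak set for accession(s): {', '.join(missing)}"
            )
    for s in samples:
        s = filter_by_length(s, max_len=max_len)
        if wgs_by_accession is not None:
            s = subtract_wgs_artifacts(s, wgs_by_accession[s.accession])
        out.append(s)
    return out


# ------------------------------------------------------------- array clustering

def _pooled_arrays(samples: list[PeakSample], chrom_index: dict[str, int]):
    """Concatenate all samples' peaks into (gstart, gend, sample_idx) with
    chrom folded into the coordinate so one sweep covers the genome."""
    span = np.int64(1) << 40  # larger than any contig
    gs, ge, si = [], [], []
    for k, s in enumerate(samples):
        for chrom, (st, en) in s.peaks.by_chrom().items():
            base = chrom_index[chrom] * span
            gs.append(st + base)
            ge.append(en + base)
            si.append(np.full(len(st), k, dtype=np.int64))
    if not gs:
        z = np.empty(0, dtype=np.int64)
        return z, z, z
    return np.concatenate(gs), np.concatenate(ge), np.concatenate(si)


def cluster_intervals(gstart: np.ndarray, gend: np.ndarray):
    """Single-linkage clusters of intervals on a folded coordinate axis.

    Inputs need not be sorted. Returns (order, cluster_id_per_sorted_item,
    n_clusters) where ``order`` sorts the inputs by start. Bookended
    intervals share a cluster (half-open adjacency fuses).
    """
    order = np.argsort(gstart, kind="stable")
    s = gstart[order]
    e = gend[order]
    if len(s) == 0:
        return order, np.empty(0, dtype=np.int64), 0
    cummax = np.maximum.accumulate(e)
    breaks = s[1:] > cummax[:-1]
    cid = np.concatenate(([0], np.cumsum(breaks)))
    return order, cid, int(cid[-1]) + 1


def build_consensus(
    samples: list[PeakSample], min_support: int = 2, scope: str = "run"
) -> list[ConsensusACR]:
    """Fuse overlapping peaks across the pooled samples and keep clusters
    supported by >= ``min_support`` distinct samples.

    ``min_support=1`` reproduces the plain merged union. The result is
    invariant to sample order.
    """
    if min_support < 1:
        raise UsageError(f"min_support must be >= 1, got {min_support}")
    if not samples:
        logger.warning("build_consensus called with an empty sample list")
        return []
    chroms = sorted({c for s in samples for c in s.peaks.chroms})
    chrom_index = {c: i for i, c in enumerate(chroms)}
    gs, ge, si = _pooled_arrays(samples, chrom_index)
    order, cid, ncl = cluster_intervals(gs, ge)
    if ncl == 0:
        return []
    s_sorted, e_sorted, samp_sorted = gs[order], ge[order], si[order]
    first = np.flatnonzero(np.concatenate(([True], cid[1:] != cid[:-1])))
    bounds = np.append(first, len(cid))
    cl_start = s_sorted[first]
    cl_end = np.maximum.reduceat(e_sorted, first)
    span = np.int64(1) << 40
    out = []
    for c in range(ncl):
        members = samp_sorted[bounds[c]:bounds[c + 1]]
        samp_ids = {samples[int(m)].sample_id for m in members}
        if len(samp_ids) < min_support:
            continue
        tissues = {samples[int(m)].tissue for m in members}
        chrom = chroms[int(cl_start[c] // span)]
        start = int(cl_start[c] % span)
        end = int(cl_end[c] % span)
        out.append(
            ConsensusACR(
                interval=GenomicInterval(chrom, start, end),
                support=frozenset(samp_ids),
                tissues=frozenset(tissues),
                scope=scope,
            )
        )
    return out


def tissue_partition(
    leaf_consensus: list[ConsensusACR], seedling_consensus: list[ConsensusACR]
) -> dict:
    """Partition tissue-scope consensus ACRs into shared / leaf-only /
    seedling-only by >= 1 bp cross-tissue overlap.

    Returns both counting bases: per-tissue pre-fusion unit counts and the
    count of fused shared regions.
    """
    leaf = IntervalSet([c.interval for c in leaf_consensus])
    seed = IntervalSet([c.interval for c in seedling_consensus])
    leaf_hit, leaf_miss = leaf.overlaps_any(seed) if len(seed) else (IntervalSet(), leaf)
    seed_hit, seed_miss = seed.overlaps_any(leaf) if len(leaf) else (IntervalSet(), seed)
    shared = IntervalSet(list(leaf_hit) + list(seed_hit)).merge()
    return {
        "shared": shared,
        "leaf_only": leaf_miss,
        "seedling_only": seed_miss,
        "counts": {
            "leaf_shared_units": len(leaf_hit),
            "seedling_shared_units": len(seed_hit),
            "shared_fused": len(shared),
            "leaf_only": len(leaf_miss),
            "seedling_only": len(seed_miss),
        },
    }
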