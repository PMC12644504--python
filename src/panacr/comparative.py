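"""Cross-species pan-ACR index, sharing combinatorics and frequency spectra.

The pan-ACR index is the deduplicated union of species-level consensus ACR
sets: overlapping consensus intervals across species are single-linkage
fused into one pan-ACR with a coordinate-derived id, and a species is
"open" for a pan-ACR iff at least one of its consensus ACRs overlaps it.

The sharing table assigns every pan-ACR to exactly one of the 2^S - 1
non-empty species combinations. Its permutation null shuffles the
sample -> species assignment (whole peak files move between species, with
per-species sample counts preserved) and recomputes consensus, index and
counts each time. Two intervals are reported per combination: the t-based
confidence interval for the mean of the permuted counts (the headline
labeling rule, which is very narrow) and the empirical 2.5/97.5 permutation
percentiles, which is the interval whose coverage actually calibrates to
the confidence level under label exchangeability.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import ConsensusACR, PeakSample, cluster_intervals
from .errors import IntegrityError, UsageError, ValidationError
from .intervals import GenomeSpec, GenomicInterval, IntervalSet
from .stats import empirical_interval, t_mean_ci

_SPAN = np.int64(1) << 40


@dataclass
class PanACR:
    """A uniquely indexed cross-species ACR."""

    acr_id: str
    interval: GenomicInterval
    species_open: dict = field(default_factory=dict)  # species -> bool


def build_pan_index(
    per_species_consensus: dict[str, list[ConsensusACR]],
) -> tuple[list[PanACR], pd.DataFrame]:
    """Fuse species consensus ACRs into pan-ACRs; returns the index plus a
    binary presence matrix (rows: pan-ACR ids, columns: species)."""
    species = list(per_species_consensus)
    if len(set(species)) != len(species):
        raise UsageError("duplicate species keys")
    chroms = sorted(
        {c.interval.chrom for lst in per_species_consensus.values() for c in lst}
    )
    cidx = {c: i for i, c in enumerate(chroms)}
    gs, ge, sp = [], [], []
    for si, sname in enumerate(species):
        for acr in per_species_consensus[sname]:
            base = cidx[acr.interval.chrom] * _SPAN
            gs.append(base + acr.interval.start)
            ge.append(base + acr.interval.end)
            sp.append(si)
    if not gs:
        return [], pd.DataFrame(columns=species)
    gs = np.array(gs, dtype=np.int64)
    ge = np.array(ge, dtype=np.int64)
    sp = np.array(sp, dtype=np.int64)
    order, cid, ncl = cluster_intervals(gs, ge)
    s_sorted, e_sorted, sp_sorted = gs[order], ge[order], sp[order]
    first = np.flatnonzero(np.concatenate(([True], cid[1:] != cid[:-1])))
    cl_start = s_sorted[first]
    cl_end = np.maximum.reduceat(e_sorted, first)
    presence = np.zeros((ncl, len(species)), dtype=bool)
    presence[cid, sp_sorted] = True
    pan = []
    ids = []
    for c in range(ncl):
        chrom = chroms[int(cl_start[c] // _SPAN)]
        start = int(cl_start[c] % _SPAN)
        end = int(cl_end[c] % _SPAN)
        acr_id = f"{chrom}:{start}-{end}"
        ids.append(acr_id)
        pan.append(
            PanACR(
                acr_id=acr_id,
                interval=GenomicInterval(chrom, start, end),
                species_open={s: bool(presence[c, i]) for i, s in enumerate(species)},
            )
        )
    matrix = pd.DataFrame(presence.astype(np.int8), index=ids, columns=species)
    return pan, matrix


def combination_label(open_species: tuple[str, ...]) -> str:
    return "+".join(sorted(open_species))


def all_combinations(species: list[str]) -> list[str]:
    out = []
    for r in range(1, len(species) + 1):
        for combo in itertools.combinations(sorted(species), r):
            out.append("+".join(combo))
    return out


def sharing_combinations(matrix: pd.DataFrame) -> pd.Series:
    """Observed pan-ACR count per non-empty species combination.

    The counts sum to the number of pan-ACRs; all 2^S - 1 combinations are
    present (zero-filled).
    """
    if matrix.shape[1] < 2:
        raise UsageError("need >= 2 species")
    arr = matrix.values.astype(bool)
    if (~arr.any(axis=1)).any():
        raise IntegrityError("presence matrix contains an all-zero row")
    species = list(matrix.columns)
    labels = all_combinations(species)
    codes = arr @ (1 << np.arange(len(species)))
    counts = np.bincount(codes, minlength=1 << len(species))
    out = {}
    for label in labels:
        members = label.split("+")
        code = sum(1 << species.index(m) for m in members)
        out[label] = int(counts[code])
    return pd.Series(out, name="observed")


# ---------------------------------------------------------------- fast nulls

def _fold_sample(sample: PeakSample, cidx: dict[str, int]):
    gs, ge = [], []
    for chrom, (st, en) in sample.peaks.by_chrom().items():
        base = cidx[chrom] * _SPAN
        gs.append(st + base)
        ge.append(en + base)
    if not gs:
        z = np.empty(0, dtype=np.int64)
        return z, z
    return np.concatenate(gs), np.concatenate(ge)


def _species_consensus_folded(folded, members, min_support):
    """Supported fused clusters for one species given folded per-sample arrays."""
    if len(members) == 0:
        z = np.empty(0, dtype=np.int64)
        return z, z
    gs = np.concatenate([folded[m][0] for m in members])
    ge = np.concatenate([folded[m][1] for m in members])
    si = np.concatenate(
        [np.full(len(folded[m][0]), k, dtype=np.int64) for k, m in enumerate(members)]
    )
    order, cid, ncl = cluster_intervals(gs, ge)
    if ncl == 0:
        z = np.empty(0, dtype=np.int64)
        return z, z
    s_sorted, e_sorted = gs[order], ge[order]
    first = np.flatnonzero(np.concatenate(([True], cid[1:] != cid[:-1])))
    cl_start = s_sorted[first]
    cl_end = np.maximum.reduceat(e_sorted, first)
    key = np.sort(cid * np.int64(len(members) + 1) + si[order])
    uniq = np.concatenate(([True], key[1:] != key[:-1]))
    support = np.bincount(key[uniq] // np.int64(len(members) + 1), minlength=ncl)
    keep = support >= min_support
    return cl_start[keep], cl_end[keep]


def _sharing_counts_folded(per_species, species):
    """Combination-code counts from folded per-species consensus arrays."""
    gs = np.concatenate([per_species[s][0] for s in species])
    ge = np.concatenate([per_species[s][1] for s in species])
    sp = np.concatenate(
        [np.full(len(per_species[s][0]), i, dtype=np.int64) for i, s in enumerate(species)]
    )
    if len(gs) == 0:
        return np.zeros(1 << len(species), dtype=np.int64)
    order, cid, ncl = cluster_intervals(gs, ge)
    presence = np.zeros((ncl, len(species)), dtype=bool)
    presence[cid, sp[order]] = True
    codes = presence @ (1 << np.arange(len(species)))
    return np.bincount(codes, minlength=1 << len(species))


def permutation_null(
    samples: list[PeakSample],
    n_perm: int = 100,
    level: float = 0.95,
    seed: int | None = None,
    min_support: int = 2,
) -> pd.DataFrame:
    """Observed sharing counts with a sample-label permutation null.

    Each permutation shuffles which samples belong to which species (the
    multiset of per-species sample counts is preserved and asserted) and
    recomputes species consensus, pan index and combination counts.

    Returns a DataFrame indexed by combination label with columns:
    observed, perm_mean, perm_sd, ci_low, ci_high, label (t-CI based),
    emp_low, emp_high, label_empirical.
    """
    if n_perm < 2:
        raise UsageError(f"n_perm must be >= 2 (t quantile undefined), got {n_perm}")
    if not (0 < level < 1):
        raise UsageError(f"level must be in (0, 1), got {level}")
    rng = np.random.default_rng(seed)
    species = sorted({s.species for s in samples})
    if len(species) < 2:
        raise UsageError("need samples from >= 2 species")
    chroms = sorted({c for s in samples for c in s.peaks.chroms})
    cidx = {c: i for i, c in enumerate(chroms)}
    folded = [_fold_sample(s, cidx) for s in samples]
    labels0 = np.array([species.index(s.species) for s in samples])
    expected_counts = np.bincount(labels0, minlength=len(species))

    def counts_for(labels):
        per_species = {
            sname: _species_consensus_folded(
                folded, np.flatnonzero(labels == i), min_support
            )
            for i, sname in enumerate(species)
        }
        return _sharing_counts_folded(per_species, species)

    observed = counts_for(labels0)
    perms = np.empty((n_perm, 1 << len(species)), dtype=np.int64)
    for p in range(n_perm):
        labels = rng.permutation(labels0)
        if not np.array_equal(np.bincount(labels, minlength=len(species)), expected_counts):
            raise IntegrityError("permutation changed per-species sample counts")
        perms[p] = counts_for(labels)

    rows = []
    for label in all_combinations(species):
        members = label.split("+")
        code = sum(1 << species.index(m) for m in members)
        obs = int(observed[code])
        vals = perms[:, code].astype(float)
        lo, hi = t_mean_ci(vals, level=level)
        elo, ehi = empirical_interval(vals, level=level)
        rows.append(
            {
                "combination": label,
                "observed": obs,
                "perm_mean": float(vals.mean()),
                "perm_sd": float(vals.std(ddof=1)),
                "ci_low": lo,
                "ci_high": hi,
                "label": _classify(obs, lo, hi),
                "emp_low": elo,
                "emp_high": ehi,
                "label_empirical": _classify(obs, elo, ehi),
            }
        )
    return pd.DataFrame(rows).set_index("combination")


def _classify(obs: float, lo: float, hi: float) -> str:
    if obs > hi:
        return "enriched"
    if obs < lo:
        return "depleted"
    return "within"


# --------------------------------------------------------------- state changes

def pairwise_state_changes(
    pan: list[PanACR],
    a: str,
    b: str,
    genome: GenomeSpec,
    denominator: str = "effective",
) -> dict:
    """Chromatin opened/closed in species ``a`` relative to reference ``b``.

    opened: pan-ACRs open in a, closed in b; closed: the reverse.
    Percentages are summed pan-ACR lengths over the genome denominator.
    """
    for sp in (a, b):
        if pan and sp not in pan[0].species_open:
            raise UsageError(f"species {sp!r} not in the pan index")
    denom = genome.effective_size if denominator == "effective" else genome.assembly_size
    opened = [p for p in pan if p.species_open[a] and not p.species_open[b]]
    closed = [p for p in pan if p.species_open[b] and not p.species_open[a]]
    opened_bp = sum(p.interval.length for p in opened)
    closed_bp = sum(p.interval.length for p in closed)
    return {
        "opened_count": len(opened),
        "closed_count": len(closed),
        "opened_bp": opened_bp,
        "closed_bp": closed_bp,
        "opened_pct": 100.0 * opened_bp / denom,
        "closed_pct": 100.0 * closed_bp / denom,
    }


# ------------------------------------------------------- accession frequencies

def accession_frequency(
    pan: list[PanACR], samples: list[PeakSample]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species open-accession frequency per pan-ACR.

    An accession is open for a pan-ACR iff >= 1 of its samples has a peak
    overlapping it by >= 1 bp; frequency = open accessions / species
    accession count. Returns (frequency DataFrame indexed by acr id with
    species columns, accession-level boolean DataFrame).
    """
    acc_species: dict[str, str] = {}
    acc_samples: dict[str, list[PeakSample]] = {}
    for s in samples:
        prev = acc_species.setdefault(s.accession, s.species)
        if prev != s.species:
            raise ValidationError(
                f"accession {s.accession!r} mapped to both {prev!r} and {s.species!r}"
            )
        acc_samples.setdefault(s.accession, []).append(s)
    accessions = sorted(acc_species)
    pan_set = IntervalSet([p.interval for p in pan])
    # canonical order of pan_set may differ from input order; map ids
    order_ids = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in pan_set]
    open_mat = pd.DataFrame(False, index=order_ids, columns=accessions)
    for acc in accessions:
        union = IntervalSet(
            [iv for s in acc_samples[acc] for iv in s.peaks]
        ).merge()
        mask = pan_set.overlap_mask(union, min_bp=1)
        open_mat[acc] = mask
    species = sorted(set(acc_species.values()))
    freq = pd.DataFrame(index=order_ids, columns=species, dtype=float)
    for sp in species:
        cols = [a for a in accessions if acc_species[a] == sp]
        freq[sp] = open_mat[cols].mean(axis=1)
    ids = [p.acr_id for p in pan]
    return freq.loc[ids], open_mat.loc[ids]


def joint_spectrum(
    freq_a: pd.Series, freq_b: pd.Series, n_a: int, n_b: int
) -> pd.DataFrame:
    """2-D histogram of open-accession frequencies in two species.

    Axis bins are the attainable frequencies {0, 1/n, ..., 1}. The grand
    total equals the number of scored pan-ACRs and the marginals equal the
    per-species frequency histograms.
    """
    if not freq_a.index.equals(freq_b.index):
        raise UsageError("frequency vectors must be over the same pan-ACR ids")
    ia = np.rint(freq_a.values * n_a).astype(int)
    ib = np.rint(freq_b.values * n_b).astype(int)
    grid = np.zeros((n_a + 1, n_b + 1), dtype=np.int64)
    np.add.at(grid, (ia, ib), 1)
    return pd.DataFrame(
        grid,
        index=[i / n_a for i in range(n_a + 1)],
        columns=[j / n_b for j in range(n_b + 1)],
    )


def fixed_dacrs(freq_crop: pd.Series, freq_wild: pd.Series) -> dict[str, set]:
    """Fixed differential ACRs between a crop and the wild reference.

    fixed_open: frequency 1 in the crop and 0 in the wild; fixed_closed:
    the reverse. fixed_open(a, b) == fixed_closed(b, a).
    """
    if not freq_crop.index.equals(freq_wild.index):
        raise UsageError("frequency vectors must be over the same pan-ACR ids")
    fixed_open = set(freq_crop.index[(freq_crop == 1.0) & (freq_wild == 0.0)])
    fixed_closed = set(freq_crop.index[(freq_crop == 0.0) & (freq_wild == 1.0)])
    return {"fixed_open": fixed_open, "fixed_closed": fixed_closed}
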