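"""Synthetic multi-species ATAC peak sets with known ground truth.

The generator emulates the design of a five-species domestication panel:
three crop species, their wild ancestor and a second wild relative, with
3-4 accessions each and one to three samples per accession over two
tissues (42 samples / 18 accessions by default). Planted pan-ACRs belong
to sharing classes (core, species-specific, domesticate-shared,
wild-specific, and per-crop fixed-open / fixed-closed differential ACRs);
per-sample peak files add boundary jitter, sample dropout and
false-positive singleton peaks, and a set of mappability-artifact peaks is
injected into every sample and emitted as the matching WGS control sets.
Methylomes draw per-cytosine binary calls at context-dependent rates
(elevated inside TEs, depressed inside ACRs), and sweep-score tracks tile
the genome with background scores elevated over planted sweep intervals
covering a configured fraction of fixed dACRs.

Every output is a pure function of (config, seed): one root seed derives
an independent sub-stream per output, so adding outputs does not perturb
earlier ones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .consensus import PeakSample
from .errors import ConfigurationError
from .intervals import (
    GenomeSpec,
    GeneModel,
    GenomicInterval,
    IntervalSet,
    write_chrom_sizes,
    write_gff3,
    write_intervals,
)

CLASSES = (
    "core",
    "species_specific",
    "domesticate_shared",
    "wild_specific",
    "fixed_open",
    "fixed_closed",
)

# sub-stream tags for seed derivation
_STREAM_GENOME = 0
_STREAM_ACRS = 1
_STREAM_SAMPLES = 2
_STREAM_METHYLOME = 3
_STREAM_SWEEPS = 4


@dataclass
class SpeciesConfig:
    name: str
    role: str  # crop | wild_ancestor | wild
    n_accessions: int
    extra_leaf: int = 0
    extra_seedling: int = 0


def default_species() -> list[SpeciesConfig]:
    """Five-species panel: 18 accessions, 42 samples (22 leaf / 20 seedling)."""
    return [
        SpeciesConfig("caudatus", "crop", 4, extra_leaf=1, extra_seedling=1),
        SpeciesConfig("cruentus", "crop", 3, extra_leaf=1),
        SpeciesConfig("hypochondriacus", "crop", 4, extra_leaf=1, extra_seedling=1),
        SpeciesConfig("hybridus", "wild_ancestor", 3),
        SpeciesConfig("quitensis", "wild", 4, extra_leaf=1),
    ]


@dataclass
class SimulationConfig:
    seed: int = 42
    # genome
    n_chrom: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 400
    gene_len: tuple = (1000, 5000)
    exons_per_gene: tuple = (1, 5)
    gene_min_gap: int = 4000
    te_superfamilies: dict = field(
        default_factory=lambda: {
            "Gypsy": 900, "Copia": 700, "LINE": 250, "SINE": 150, "hAT": 200,
            "Mutator": 180, "CACTA": 120, "Harbinger": 90, "Helitron": 160,
            "Tc1-Mariner": 80,
        }
    )
    te_len: tuple = (100, 3000)
    # panel
    species: list = field(default_factory=default_species)
    tissues: tuple = ("leaf", "seedling")
    # planted pan-ACRs
    n_panacrs: int = 2000
    class_proportions: dict = field(
        default_factory=lambda: {
            "core": 0.48, "species_specific": 0.32, "domesticate_shared": 0.10,
            "wild_specific": 0.05, "fixed_open": 0.03, "fixed_closed": 0.02,
        }
    )
    species_specific_weights: dict | None = None  # species -> weight
    acr_len: tuple = (150, 3000)
    n_oversize: int = 0
    oversize_len: tuple = (4500, 6000)
    min_acr_gap: int = 300
    # within-species segregation of non-fixed classes: each nominally open
    # species has each accession open with this probability, conditioned on
    # >= 1 open accession (fixed classes stay at frequency 1/0)
    accession_open_prob: float = 0.5
    # per-sample noise
    jitter_sd: float = 20.0
    dropout: float = 0.05
    false_positive_rate: float = 0.02  # expected FP peaks / sample, x n_panacrs
    fp_len: tuple = (100, 600)
    # artifacts
    n_wgs_artifacts: int = 50
    artifact_len: tuple = (100, 1000)
    clearance: int = 1000  # FP/artifact distance from any true ACR
    # methylome
    cytosine_density: float = 0.02
    context_probs: dict = field(
        default_factory=lambda: {"CpG": 0.12, "CHG": 0.12, "CHH": 0.76}
    )
    methylation_rates: dict = field(
        default_factory=lambda: {"CpG": 0.7577, "CHG": 0.4164, "CHH": 0.0547}
    )
    te_meth_multiplier: float = 1.25
    acr_meth_multiplier: float = 0.1
    read_depth: int = 20
    # sweeps
    sweep_window: int = 250
    sweep_top_fraction: float = 0.0001
    sweep_elevation: float = 6.0
    sweep_cover_fraction: float = 0.5

    def validate(self) -> None:
        total = sum(self.class_proportions.get(c, 0.0) for c in CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"class proportions sum to {total}, expected 1")
        for name, v in (("dropout", self.dropout),):
            if not (0.0 <= v < 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1), got {v}")
        if not (0.0 < self.accession_open_prob <= 1.0):
            raise ConfigurationError("accession_open_prob must be in (0, 1]")
        if self.false_positive_rate < 0:
            raise ConfigurationError("false_positive_rate must be >= 0")
        for ctx, r in self.methylation_rates.items():
            if not (0.0 <= r <= 1.0):
                raise ConfigurationError(f"methylation rate for {ctx} outside [0, 1]: {r}")
        if self.sweep_window <= 0:
            raise ConfigurationError("sweep window size must be positive")
        for c in (self.n_chrom, self.chrom_length, self.n_panacrs):
            if c < 0:
                raise ConfigurationError("counts must be non-negative")
        if self.acr_len[1] > 4000:
            raise ConfigurationError(
                "acr_len max must be <= 4000 (oversize outliers are separate)"
            )

    def rng(self, *tags: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((int(self.seed),) + tags))

    def crops(self) -> list[str]:
        return [s.name for s in self.species if s.role == "crop"]

    def wild_ancestor(self) -> str:
        for s in self.species:
            if s.role == "wild_ancestor":
                return s.name
        raise ConfigurationError("no species has role 'wild_ancestor'")

    def wild_species(self) -> list[str]:
        return [s.name for s in self.species if s.role in ("wild_ancestor", "wild")]

    def accession_table(self) -> pd.DataFrame:
        """sample_id, accession, species, tissue rows; deterministic layout."""
        rows = []
        for sp in self.species:
            accs = [f"{sp.name}_acc{i + 1}" for i in range(sp.n_accessions)]
            for acc in accs:
                for tissue in self.tissues:
                    rows.append((f"{acc}_{tissue}1", acc, sp.name, tissue))
            for j in range(sp.extra_leaf):
                acc = accs[j % len(accs)]
                rows.append((f"{acc}_leaf2", acc, sp.name, "leaf"))
            for j in range(sp.extra_seedling):
                acc = accs[j % len(accs)]
                rows.append((f"{acc}_seedling2", acc, sp.name, "seedling"))
        return pd.DataFrame(rows, columns=["sample_id", "accession", "species", "tissue"])


@dataclass
class SimulationTruth:
    """Planted ground truth: the oracle for recovery tests."""

    acrs: pd.DataFrame  # acr_id, chrom, start, end, label, target_species
    states: pd.DataFrame  # index acr_id, columns accession ids (bool)
    accession_species: pd.Series  # accession -> species
    class_counts: dict
    wgs_artifacts: IntervalSet
    sweep_intervals: dict = field(default_factory=dict)  # species -> IntervalSet
    methylation_rates: dict = field(default_factory=dict)

    def species_states(self) -> pd.DataFrame:
        """Pan-ACR x species: open iff any accession of the species is open."""
        groups = self.accession_species.groupby(self.accession_species).groups
        out = pd.DataFrame(index=self.states.index)
        for sp, accs in groups.items():
            out[sp] = self.states[list(accs)].any(axis=1)
        return out.sort_index(axis=1)

    def sharing_counts(self) -> pd.Series:
        from .comparative import all_combinations

        ss = self.species_states()
        species = list(ss.columns)
        labels = ss.apply(
            lambda row: "+".join(sorted(sp for sp in species if row[sp])), axis=1
        )
        counts = labels.value_counts()
        return pd.Series(
            {c: int(counts.get(c, 0)) for c in all_combinations(species)},
            name="observed",
        )

    def accession_frequency(self) -> pd.DataFrame:
        groups = self.accession_species.groupby(self.accession_species).groups
        out = pd.DataFrame(index=self.states.index, dtype=float)
        for sp, accs in groups.items():
            out[sp] = self.states[list(accs)].mean(axis=1)
        return out.sort_index(axis=1)

    def fixed_sets(self, crop: str, wild: str) -> dict[str, set]:
        freq = self.accession_frequency()
        fc, fw = freq[crop], freq[wild]
        return {
            "fixed_open": set(freq.index[(fc == 1.0) & (fw == 0.0)]),
            "fixed_closed": set(freq.index[(fc == 0.0) & (fw == 1.0)]),
        }

    def acr_interval_set(self, ids=None) -> IntervalSet:
        df = self.acrs if ids is None else self.acrs[self.acrs["acr_id"].isin(set(ids))]
        return IntervalSet.from_arrays(df["chrom"], df["start"], df["end"])


# ------------------------------------------------------------------- placement

def _allocate_chroms(rng, chrom_lengths, n):
    probs = np.asarray(chrom_lengths, dtype=float)
    probs /= probs.sum()
    return rng.choice(len(chrom_lengths), size=n, p=probs)


def _place_on_chrom(rng, length, item_lengths, min_gap):
    """Place items in order along one contig with pairwise gaps > min_gap.

    Free bp are split into k+1 random gaps (multinomial), giving a uniform
    non-overlapping arrangement. Raises on infeasible packing.
    """
    k = len(item_lengths)
    if k == 0:
        return np.empty(0, dtype=np.int64)
    need = int(np.sum(item_lengths)) + (k - 1) * min_gap
    free = length - need
    if free < 0:
        raise ConfigurationError(
            f"infeasible packing: {k} items need {need} bp on a {length} bp contig"
        )
    gaps = rng.multinomial(free, [1.0 / (k + 1)] * (k + 1))
    starts = np.empty(k, dtype=np.int64)
    pos = 0
    for i in range(k):
        pos += gaps[i] + (min_gap if i > 0 else 0)
        starts[i] = pos
        pos += item_lengths[i]
    return starts


def _place_intervals(rng, chrom_names, chrom_lengths, item_lengths, min_gap):
    """Random non-overlapping placement genome-wide; returns (chrom, start) lists."""
    n = len(item_lengths)
    assign = _allocate_chroms(rng, chrom_lengths, n)
    order = np.argsort(assign, kind="stable")
    chroms_out = [None] * n
    starts_out = np.zeros(n, dtype=np.int64)
    for ci in range(len(chrom_names)):
        idx = order[assign[order] == ci]
        if len(idx) == 0:
            continue
        lens = np.array([item_lengths[i] for i in idx])
        perm = rng.permutation(len(idx))
        starts = _place_on_chrom(rng, chrom_lengths[ci], lens[perm], min_gap)
        for j, p in enumerate(perm):
            i = idx[p]
            chroms_out[i] = chrom_names[ci]
            starts_out[i] = starts[j]
    return chroms_out, starts_out


class _Occupancy:
    """Sorted occupied intervals per chrom, for clearance-aware rejection."""

    def __init__(self):
        self._data: dict[str, list[tuple[int, int]]] = {}

    def add(self, chrom, start, end):
        self._data.setdefault(chrom, []).append((start, end))
        self._data[chrom].sort()

    def add_many(self, intervals):
        for iv in intervals:
            self._data.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for c in self._data:
            self._data[c].sort()

    def clear_of(self, chrom, start, end, margin) -> bool:
        import bisect

        ivs = self._data.get(chrom, [])
        i = bisect.bisect_left(ivs, (start - margin, -1))
        for s, e in ivs[max(0, i - 1): i + 2]:
            if s < end + margin and e > start - margin:
                return False
        return True


def _rejection_place(rng, occ, chrom_names, chrom_lengths, lengths, margin, max_tries=2000):
    placed = []
    probs = np.asarray(chrom_lengths, dtype=float)
    probs /= probs.sum()
    for L in lengths:
        for _ in range(max_tries):
            ci = rng.choice(len(chrom_names), p=probs)
            if chrom_lengths[ci] <= L:
                continue
            start = int(rng.integers(0, chrom_lengths[ci] - L))
            if occ.clear_of(chrom_names[ci], start, start + L, margin):
                occ.add(chrom_names[ci], start, start + L)
                placed.append(GenomicInterval(chrom_names[ci], start, start + L))
                break
        else:
            raise ConfigurationError(
                "rejection placement failed; genome too crowded for clearance "
                f"{margin} bp"
            )
    return placed


# --------------------------------------------------------------------- genome

def simulate_genome(config: SimulationConfig):
    """Deterministic genome scaffold: GenomeSpec, gene models and a TE track.

    Genes are packed with >= ``gene_min_gap`` bp between bodies so 2-kb
    flanks never collide; TEs are placed uniformly and may overlap anything.
    """
    config.validate()
    rng = config.rng(_STREAM_GENOME)
    names = [f"chr{i + 1}" for i in range(config.n_chrom)]
    lengths = [config.chrom_length] * config.n_chrom
    genome = GenomeSpec(dict(zip(names, lengths)))

    gene_lens = rng.integers(config.gene_len[0], config.gene_len[1] + 1, config.n_genes)
    chroms, starts = _place_intervals(rng, names, lengths, gene_lens, config.gene_min_gap)
    genes = []
    for i in range(config.n_genes):
        start, glen = int(starts[i]), int(gene_lens[i])
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        # split the body into 2*n_ex - 1 alternating exon/intron chunks >= 50 bp
        n_chunks = 2 * n_ex - 1
        base = 50
        extra = rng.multinomial(glen - base * n_chunks, [1.0 / n_chunks] * n_chunks)
        sizes = base + extra
        exons = []
        pos = start
        for j, sz in enumerate(sizes):
            if j % 2 == 0:
                exons.append(GenomicInterval(chroms[i], pos, pos + int(sz)))
            pos += int(sz)
        genes.append(
            GeneModel(
                gene_id=f"gene{i + 1:04d}", chrom=chroms[i], start=start,
                end=start + glen, strand=strand, exons=IntervalSet(exons),
            )
        )

    te_items = []
    for sf, count in config.te_superfamilies.items():
        te_lens = rng.integers(config.te_len[0], config.te_len[1] + 1, count)
        for L in te_lens:
            ci = int(_allocate_chroms(rng, lengths, 1)[0])
            if lengths[ci] <= L:
                continue
            start = int(rng.integers(0, lengths[ci] - L))
            te_items.append(
                GenomicInterval(
                    names[ci], start, start + int(L), name=sf,
                    extras={"superfamily": sf},
                )
            )
    return genome, genes, IntervalSet(te_items)


# ------------------------------------------------------------------ panacrome

def _class_states(config, label, target, accession_species, rng):
    """True open state per accession for one planted pan-ACR.

    Non-fixed classes segregate within their open species (each accession
    open with ``accession_open_prob``, conditioned on >= 1 open accession);
    fixed classes are at frequency 1 in their open species and 0 elsewhere.
    """
    crops = set(config.crops())
    wilds = set(config.wild_species())
    ancestor = config.wild_ancestor()
    if label == "core":
        open_species = set(accession_species.unique())
    elif label == "species_specific":
        open_species = {target}
    elif label == "domesticate_shared":
        open_species = crops
    elif label == "wild_specific":
        open_species = wilds
    elif label == "fixed_open":
        open_species = {target}
    elif label == "fixed_closed":
        open_species = {ancestor}
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown class {label}")
    fixed = label in ("fixed_open", "fixed_closed")
    out = {}
    by_species: dict[str, list[str]] = {}
    for acc, sp in accession_species.items():
        by_species.setdefault(sp, []).append(acc)
        out[acc] = False
    for sp in open_species:
        accs = by_species[sp]
        if fixed:
            states = np.ones(len(accs), dtype=bool)
        else:
            states = rng.random(len(accs)) < config.accession_open_prob
            while not states.any():
                states = rng.random(len(accs)) < config.accession_open_prob
        for acc, st in zip(accs, states):
            out[acc] = bool(st)
    return out


def simulate_panacrome(config: SimulationConfig, genome: GenomeSpec):
    """Per-sample peak sets, WGS control sets and the ground truth."""
    config.validate()
    rng = config.rng(_STREAM_ACRS)
    names = list(genome.contigs)
    lengths = [genome.contigs[c] for c in names]
    meta = config.accession_table()
    accession_species = meta.drop_duplicates("accession").set_index("accession")["species"]

    n = config.n_panacrs
    class_names = list(CLASSES)
    probs = [config.class_proportions.get(c, 0.0) for c in class_names]
    counts = rng.multinomial(n, probs)
    labels = np.repeat(class_names, counts)
    rng.shuffle(labels)

    species_names = [s.name for s in config.species]
    if config.species_specific_weights:
        w = np.array([config.species_specific_weights.get(s, 1.0) for s in species_names])
    else:
        w = np.ones(len(species_names))
    w = w / w.sum()
    crops = config.crops()
    targets = []
    for lab in labels:
        if lab == "species_specific":
            targets.append(str(rng.choice(species_names, p=w)))
        elif lab in ("fixed_open", "fixed_closed"):
            targets.append(str(rng.choice(crops)))
        else:
            targets.append("")

    # lengths and placement (oversize outliers appended last)
    frac = rng.beta(1.2, 4.0, n)
    acr_lens = (config.acr_len[0] + frac * (config.acr_len[1] - config.acr_len[0])).astype(np.int64)
    if config.n_oversize:
        over = rng.integers(config.oversize_len[0], config.oversize_len[1] + 1, config.n_oversize)
        acr_lens = np.concatenate([acr_lens, over])
        labels = np.concatenate([labels, np.repeat(["core"], config.n_oversize)])
        targets = targets + [""] * config.n_oversize
    gap = max(config.min_acr_gap, int(8 * config.jitter_sd) + 2)
    chroms, starts = _place_intervals(rng, names, lengths, acr_lens, gap)

    acr_rows = []
    states = {}
    for i in range(len(acr_lens)):
        start, end = int(starts[i]), int(starts[i] + acr_lens[i])
        acr_id = f"{chroms[i]}:{start}-{end}"
        oversize = i >= n
        acr_rows.append(
            {
                "acr_id": acr_id, "chrom": chroms[i], "start": start, "end": end,
                "label": labels[i], "target_species": targets[i],
                "oversize": oversize,
            }
        )
        states[acr_id] = _class_states(config, labels[i], targets[i], accession_species, rng)
    acr_df = pd.DataFrame(acr_rows)
    state_df = pd.DataFrame.from_dict(states, orient="index")[list(accession_species.index)]
    state_df = state_df.loc[acr_df["acr_id"]]

    occ = _Occupancy()
    occ.add_many(
        GenomicInterval(r["chrom"], r["start"], r["end"]) for _, r in acr_df.iterrows()
    )
    art_rng = config.rng(_STREAM_ACRS, 1)
    art_lens = art_rng.integers(
        config.artifact_len[0], config.artifact_len[1] + 1, config.n_wgs_artifacts
    )
    artifacts = IntervalSet(
        _rejection_place(art_rng, occ, names, lengths, art_lens, config.clearance)
    )

    truth = SimulationTruth(
        acrs=acr_df, states=state_df.astype(bool),
        accession_species=accession_species,
        class_counts={c: int(k) for c, k in zip(class_names, counts)},
        wgs_artifacts=artifacts,
        methylation_rates=dict(config.methylation_rates),
    )

    samples = []
    fp_occ = occ  # false positives also avoid artifacts and one another
    for si, row in meta.iterrows():
        srng = config.rng(_STREAM_SAMPLES, int(si))
        open_ids = state_df.index[state_df[row["accession"]].astype(bool)]
        peaks = []
        sub = acr_df.set_index("acr_id").loc[open_ids]
        keep = srng.random(len(sub)) >= config.dropout
        for (acr_id, r), kp in zip(sub.iterrows(), keep):
            if not kp:
                continue
            start, end = int(r["start"]), int(r["end"])
            if config.jitter_sd > 0:
                start += int(round(srng.normal(0, config.jitter_sd)))
                end += int(round(srng.normal(0, config.jitter_sd)))
                lo_len = 50
                hi_len = 4000 if not r["oversize"] else max(4000, end - start)
                if end - start < lo_len:
                    mid = (start + end) // 2
                    start, end = mid - lo_len // 2, mid + lo_len - lo_len // 2
                elif end - start > hi_len:
                    end = start + hi_len
                start = max(0, start)
                end = min(genome.contigs[r["chrom"]], end)
            peaks.append(
                GenomicInterval(
                    r["chrom"], start, end, name=acr_id,
                    score=float(np.round(srng.uniform(100, 1000), 1)),
                    extras={
                        "signal": float(np.round(srng.uniform(2, 20), 3)),
                        "pvalue": float(np.round(srng.uniform(5, 50), 3)),
                        "qvalue": float(np.round(srng.uniform(2, 30), 3)),
                        "summit": (end - start) // 2,
                    },
                )
            )
        n_fp = int(srng.poisson(config.false_positive_rate * config.n_panacrs))
        if n_fp:
            fp_lens = srng.integers(config.fp_len[0], config.fp_len[1] + 1, n_fp)
            fps = _rejection_place(
                srng, fp_occ, names, lengths, fp_lens, config.clearance
            )
            for fp in fps:
                fp.name = "fp"
                fp.extras = {"signal": 1.0, "pvalue": 2.0, "qvalue": 2.0,
                             "summit": fp.length // 2}
                fp.score = 50.0
            peaks.extend(fps)
        peaks.extend(artifacts)  # mappability artifacts appear in every sample
        samples.append(
            PeakSample(
                sample_id=row["sample_id"], accession=row["accession"],
                species=row["species"], tissue=row["tissue"],
                peaks=IntervalSet(peaks),
            )
        )
    wgs_by_accession = {acc: artifacts for acc in accession_species.index}
    return samples, wgs_by_accession, truth


# ------------------------------------------------------------------ methylome

def simulate_methylome(
    config: SimulationConfig, genome: GenomeSpec, tes: IntervalSet,
    acr_intervals: IntervalSet,
) -> pd.DataFrame:
    """Per-cytosine binary methylation calls (chrom, pos, strand, context,
    methylated, total), with TE-elevated and ACR-depressed rates."""
    config.validate()
    rng = config.rng(_STREAM_METHYLOME)
    contexts = list(config.context_probs)
    cprobs = np.array([config.context_probs[c] for c in contexts], dtype=float)
    cprobs /= cprobs.sum()
    frames = []
    te_map = tes.merge().by_chrom()
    acr_map = acr_intervals.merge().by_chrom()
    for chrom, length in genome.contigs.items():
        n = int(round(config.cytosine_density * length))
        pos = np.unique(rng.integers(0, length, size=int(n * 1.08)))
        if len(pos) > n:
            pos = rng.choice(pos, size=n, replace=False)
            pos.sort()
        ctx = rng.choice(len(contexts), size=len(pos), p=cprobs)
        rates = np.array([config.methylation_rates[contexts[c]] for c in ctx])
        in_te = _member(pos, te_map.get(chrom))
        in_acr = _member(pos, acr_map.get(chrom))
        rates = np.where(in_te, np.minimum(1.0, rates * config.te_meth_multiplier), rates)
        rates = np.where(in_acr, rates * config.acr_meth_multiplier, rates)
        meth = rng.random(len(pos)) < rates
        total = rng.poisson(config.read_depth, len(pos))
        total = np.maximum(total, 1)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "strand": np.where(rng.random(len(pos)) < 0.5, "+", "-"),
                    "context": [contexts[c] for c in ctx],
                    "methylated": np.where(meth, total, 0),
                    "total": total,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _member(pos: np.ndarray, chrom_arrays) -> np.ndarray:
    if chrom_arrays is None or len(chrom_arrays[0]) == 0:
        return np.zeros(len(pos), dtype=bool)
    st, en = chrom_arrays
    j = np.searchsorted(st, pos, side="right") - 1
    return (j >= 0) & (pos < en[np.clip(j, 0, None)])


# --------------------------------------------------------------------- sweeps

def simulate_sweep_scores(
    config: SimulationConfig, genome: GenomeSpec, truth: SimulationTruth,
    elevation: float | None = None, seed_offset: int = 0,
    species_names: list | None = None,
) -> dict[str, IntervalSet]:
    """Per-species sweep-score window tracks.

    Windows overlapping planted sweep intervals — placed over a configured
    fraction of each crop's fixed dACRs — score above the background's
    top-fraction quantile. ``elevation=0`` leaves pure background.
    Planted intervals are recorded in ``truth.sweep_intervals``.
    """
    config.validate()
    elev = config.sweep_elevation if elevation is None else elevation
    wsize = config.sweep_window
    out = {}
    ancestor = config.wild_ancestor()
    for spi, sp in enumerate(config.species):
        if species_names is not None and sp.name not in species_names:
            continue
        rng = config.rng(_STREAM_SWEEPS, spi, seed_offset)
        windows = []
        bg_all = []
        for chrom, length in genome.contigs.items():
            edges = np.arange(0, length + wsize, wsize)
            edges[-1] = min(edges[-1], length)
            if edges[-1] == edges[-2]:
                edges = edges[:-1]
            scores = rng.gamma(2.0, 1.0, len(edges) - 1)
            bg_all.append(scores)
            windows.append((chrom, edges, scores))
        planted = IntervalSet()
        if elev > 0 and sp.role == "crop":
            fixed = truth.fixed_sets(sp.name, ancestor)
            ids = sorted(fixed["fixed_open"] | fixed["fixed_closed"])
            k = int(round(config.sweep_cover_fraction * len(ids)))
            chosen = list(rng.choice(ids, size=k, replace=False)) if k else []
            planted = truth.acr_interval_set(chosen)
            bg = np.concatenate(bg_all)
            cutoff = float(np.quantile(bg, 1.0 - config.sweep_top_fraction))
            pmap = planted.merge().by_chrom()
            for chrom, edges, scores in windows:
                if chrom not in pmap:
                    continue
                st, en = pmap[chrom]
                for s, e in zip(st, en):
                    w0 = int(s // wsize)
                    w1 = int(-(-e // wsize))
                    sl = slice(w0, min(w1, len(scores)))
                    nsl = sl.stop - sl.start
                    scores[sl] = cutoff + elev + rng.exponential(0.1, nsl)
        truth.sweep_intervals[sp.name] = planted
        ivs = []
        for chrom, edges, scores in windows:
            for i in range(len(scores)):
                ivs.append(
                    GenomicInterval(
                        chrom, int(edges[i]), int(edges[i + 1]),
                        score=float(scores[i]),
                    )
                )
        out[sp.name] = IntervalSet(ivs)
    return out


# ------------------------------------------------- calibration study designs

def exchangeable_config(seed: int) -> SimulationConfig:
    """A label-exchangeable panel for permutation-null calibration.

    Five species x one accession x two samples; every planted ACR is core
    and sample presence is iid Bernoulli via dropout, so species labels
    carry no information and permuting them leaves the sharing distribution
    invariant.
    """
    species = [
        SpeciesConfig(name, role, 1)
        for name, role in zip("ABCDE", ["crop", "crop", "crop", "wild_ancestor", "wild"])
    ]
    return dataclasses.replace(
        SimulationConfig(seed=seed),
        species=species, n_chrom=1, chrom_length=1_000_000,
        n_genes=0, te_superfamilies={},
        n_panacrs=250, acr_len=(150, 400), min_acr_gap=300,
        class_proportions={
            "core": 1.0, "species_specific": 0.0, "domesticate_shared": 0.0,
            "wild_specific": 0.0, "fixed_open": 0.0, "fixed_closed": 0.0,
        },
        jitter_sd=0.0, dropout=0.4, false_positive_rate=0.0, n_wgs_artifacts=0,
    )


def planted_excess_config(seed: int, excess_species: str = "A") -> SimulationConfig:
    """Like :func:`exchangeable_config` but with species-specific ACRs whose
    rate is doubled for one species — a planted singleton excess."""
    weights = {s: (2.0 if s == excess_species else 1.0) for s in "ABCDE"}
    return dataclasses.replace(
        exchangeable_config(seed),
        class_proportions={
            "core": 0.55, "species_specific": 0.45, "domesticate_shared": 0.0,
            "wild_specific": 0.0, "fixed_open": 0.0, "fixed_closed": 0.0,
        },
        species_specific_weights=weights,
        dropout=0.2,
    )


# -------------------------------------------------------------------- bundles

def write_bundle(
    outdir,
    genome: GenomeSpec,
    genes,
    tes: IntervalSet,
    samples,
    wgs_by_accession,
    truth: SimulationTruth,
    methylome: pd.DataFrame | None = None,
    sweeps: dict | None = None,
) -> None:
    """Write every simulated product as plain-text files under ``outdir``."""
    out = Path(outdir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    (out / "wgs").mkdir(exist_ok=True)
    write_chrom_sizes(genome, out / "genome.chrom.sizes")
    write_gff3(genes, out / "genes.gff3")
    write_intervals(tes, out / "te.bed", "te_bed")
    rows = []
    for s in samples:
        fn = f"peaks/{s.sample_id}.narrowPeak"
        write_intervals(s.peaks, out / fn, "narrowPeak")
        rows.append((s.sample_id, s.accession, s.species, s.tissue, fn))
    pd.DataFrame(
        rows, columns=["sample_id", "accession", "species", "tissue", "file"]
    ).to_csv(out / "samples.tsv", sep="\t", index=False)
    for acc, ws in wgs_by_accession.items():
        write_intervals(ws, out / "wgs" / f"{acc}.bed", "bed3")
    if methylome is not None:
        methylome.to_csv(out / "methylation.tsv", sep="\t", index=False, header=False)
    if sweeps is not None:
        for sp, track in sweeps.items():
            write_intervals(track, out / f"sweeps_{sp}.tsv", "sweep_table")
    payload = {
        "acrs": truth.acrs.to_dict(orient="records"),
        "accession_species": truth.accession_species.to_dict(),
        "class_counts": truth.class_counts,
        "states": {
            acr: "".join("1" if v else "0" for v in truth.states.loc[acr])
            for acr in truth.states.index
        },
        "state_columns": list(truth.states.columns),
        "wgs_artifacts": [
            [iv.chrom, iv.start, iv.end] for iv in truth.wgs_artifacts
        ],
        "sweep_intervals": {
            sp: [[iv.chrom, iv.start, iv.end] for iv in ivs]
            for sp, ivs in truth.sweep_intervals.items()
        },
        "methylation_rates": truth.methylation_rates,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1,
                  default=lambda o: o.item() if hasattr(o, "item") else str(o))


def load_samples(samples_tsv, base_dir=None) -> list[PeakSample]:
    """Read a samples.tsv metadata table and its narrowPeak files."""
    from .intervals import read_intervals

    base = Path(base_dir) if base_dir else Path(samples_tsv).parent
    meta = pd.read_csv(samples_tsv, sep="\t")
    out = []
    for _, r in meta.iterrows():
        out.append(
            PeakSample(
                sample_id=r["sample_id"], accession=r["accession"],
                species=r["species"], tissue=r["tissue"],
                peaks=read_intervals(base / r["file"], "narrowPeak"),
            )
        )
    return out


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["species"] = [dataclasses.asdict(s) for s in config.species]
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "species" in d:
        d["species"] = [SpeciesConfig(**s) for s in d["species"]]
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    for key in ("gene_len", "exons_per_gene", "te_len", "acr_len", "oversize_len",
                "fp_len", "artifact_len", "tissues"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return SimulationConfig(**d)
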