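"""Run orchestration: simulate -> consensus -> annotate -> compare -> enrich.

A run is configured by a :class:`RunConfig` (round-trips through YAML),
executes stages in dependency order, writes plain-text TSV/BED outputs and
finishes with a manifest recording the config hash, seed, per-stage output
checksums and wall-clock, so identical configs reproduce identical
checksums for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import (
    assign_genomic_features,
    classify_te_acr_overlap,
    methylation_context_summary,
    methylation_in_intervals,
    te_superfamily_enrichment,
    tss_meta_profile,
)
from .comparative import (
    accession_frequency,
    build_pan_index,
    fixed_dacrs,
    joint_spectrum,
    pairwise_state_changes,
    permutation_null,
)
from .consensus import apply_sample_filters, build_consensus
from .errors import ValidationError
from .intervals import GenomicInterval, IntervalSet, write_intervals
from .selection import (
    dacr_sweep_overlap,
    genes_near_intervals,
    sweep_in_dacr_enrichment,
    sweep_regions_from_scores,
)
from .simulate import (
    SimulationConfig,
    config_from_dict,
    config_to_dict,
    simulate_genome,
    simulate_methylome,
    simulate_panacrome,
    simulate_sweep_scores,
    write_bundle,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "panacr_run"
    seed: int = 42
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    max_len: int = 4000
    min_support: int = 2
    flank: int = 2000
    n_perm: int = 100
    level: float = 0.95
    top_fraction: float = 0.0001
    alpha: float = 0.05
    tau: float = 0.5
    denominator: str = "effective"
    run_methylome: bool = True
    run_sweeps: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = config_from_dict(sim)
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["simulation"] = config_to_dict(self.simulation)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["simulation"] = config_to_dict(self.simulation)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def validate_inputs(samples, genome, genes=None, tes=None) -> list[str]:
    """Cross-check contig names, coordinate bounds and metadata completeness.

    Returns a list of violation messages (empty when clean); never raises.
    """
    report = []
    for s in samples:
        for f in ("sample_id", "accession", "species", "tissue"):
            if not getattr(s, f, None):
                report.append(f"sample missing metadata field {f}")
        for iv in s.peaks:
            if iv.chrom not in genome.contigs:
                report.append(
                    f"{s.sample_id}: contig {iv.chrom!r} not in genome spec"
                )
                break
            if iv.end > genome.contigs[iv.chrom]:
                report.append(
                    f"{s.sample_id}: [{iv.start},{iv.end}) exceeds {iv.chrom} length"
                )
                break
    for label, track in (("genes", genes), ("TEs", tes)):
        if track is None:
            continue
        items = track if label == "genes" else list(track)
        for item in items:
            chrom = item.chrom
            end = item.end
            if chrom not in genome.contigs:
                report.append(f"{label}: contig {chrom!r} not in genome spec")
                break
            if end > genome.contigs[chrom]:
                report.append(f"{label}: feature exceeds {chrom} length")
                break
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic-data pipeline; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "warnings": [],
    }
    sim = dataclasses.replace(config.simulation, seed=config.seed)

    def stage(name):
        t0 = time.perf_counter()
        logger.info("stage %s started", name)
        return t0

    def done(name, t0, files):
        manifest["stages"][name] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "checksums": {f.name: _checksum(f) for f in files},
        }

    # simulate ---------------------------------------------------------------
    t0 = stage("simulate")
    genome, genes, tes = simulate_genome(sim)
    samples, wgs_by_accession, truth = simulate_panacrome(sim, genome)
    methylome = (
        simulate_methylome(sim, genome, tes, truth.acr_interval_set())
        if config.run_methylome else None
    )
    sweeps = (
        simulate_sweep_scores(sim, genome, truth) if config.run_sweeps else None
    )
    simdir = out / "simulated"
    write_bundle(simdir, genome, genes, tes, samples, wgs_by_accession, truth,
                 methylome=methylome, sweeps=sweeps)
    done("simulate", t0, sorted(simdir.rglob("*.tsv")) + sorted(simdir.rglob("*.bed")))

    violations = validate_inputs(samples, genome, genes=genes, tes=tes)
    manifest["warnings"].extend(violations)

    # consensus --------------------------------------------------------------
    t0 = stage("consensus")
    filtered = apply_sample_filters(samples, wgs_by_accession, max_len=config.max_len)
    species = sorted({s.species for s in filtered})
    per_species = {
        sp: build_consensus(
            [s for s in filtered if s.species == sp],
            min_support=config.min_support, scope=sp,
        )
        for sp in species
    }
    cons_dir = out / "consensus"
    cons_dir.mkdir(exist_ok=True)
    cons_files = []
    for sp, lst in per_species.items():
        p = cons_dir / f"{sp}.bed"
        write_intervals(IntervalSet([c.interval for c in lst]), p, "bed3")
        cons_files.append(p)
        sup = cons_dir / f"{sp}.support.tsv"
        with open(sup, "w") as fh:
            fh.write("acr_id\tn_support\tsample_ids\n")
            for c in lst:
                iv = c.interval
                fh.write(
                    f"{iv.chrom}:{iv.start}-{iv.end}\t{c.n_support}\t"
                    f"{','.join(sorted(c.support))}\n"
                )
        cons_files.append(sup)
    done("consensus", t0, cons_files)

    # compare ----------------------------------------------------------------
    t0 = stage("compare")
    pan, matrix = build_pan_index(per_species)
    sharing = permutation_null(
        filtered, n_perm=config.n_perm, level=config.level,
        seed=config.seed, min_support=config.min_support,
    )
    freq, _open_mat = accession_frequency(pan, filtered)
    wild = sim.wild_ancestor()
    acc_counts = truth.accession_species.value_counts()
    cmp_dir = out / "compare"
    cmp_dir.mkdir(exist_ok=True)
    write_intervals(IntervalSet([p.interval for p in pan]), cmp_dir / "pan_acrs.bed", "bed3")
    matrix.to_csv(cmp_dir / "presence_matrix.tsv", sep="\t")
    sharing.to_csv(cmp_dir / "sharing_table.tsv", sep="\t")
    state_rows = []
    fixed_by_crop = {}
    for crop in sim.crops():
        ch = pairwise_state_changes(pan, crop, wild, genome, denominator=config.denominator)
        ch["species"] = crop
        state_rows.append(ch)
        fx = fixed_dacrs(freq[crop], freq[wild])
        fixed_by_crop[crop] = fx
        spec = joint_spectrum(freq[crop], freq[wild], int(acc_counts[crop]), int(acc_counts[wild]))
        spec.to_csv(cmp_dir / f"spectrum_{crop}.tsv", sep="\t")
    pd.DataFrame(state_rows).to_csv(cmp_dir / "state_changes.tsv", sep="\t", index=False)
    id_to_iv = {p.acr_id: p.interval for p in pan}
    for crop, fx in fixed_by_crop.items():
        both = sorted(fx["fixed_open"] | fx["fixed_closed"])
        write_intervals(
            IntervalSet([id_to_iv[i] for i in both]),
            cmp_dir / f"fixed_dacrs_{crop}.bed", "bed3",
        )
    done("compare", t0, sorted(cmp_dir.iterdir()))

    # annotate ---------------------------------------------------------------
    t0 = stage("annotate")
    ann_dir = out / "annot"
    ann_dir.mkdir(exist_ok=True)
    pan_set = IntervalSet([p.interval for p in pan])
    labels, fractions = assign_genomic_features(
        pan_set, genes, up=config.flank, down=config.flank, genome=genome
    )
    pd.Series(fractions).to_csv(ann_dir / "feature_fractions.tsv", sep="\t", header=False)
    profile = tss_meta_profile(pan_set, genes, flank=config.flank)
    pd.DataFrame(
        {"offset": range(-config.flank, config.flank + 1), "coverage": profile}
    ).to_csv(ann_dir / "tss_profile.tsv", sep="\t", index=False)
    _, te_counts, te_fracs = classify_te_acr_overlap(tes, pan_set)
    te_enrich = te_superfamily_enrichment(tes, pan_set, alpha=config.alpha)
    te_enrich.to_csv(ann_dir / "te_enrichment.tsv", sep="\t")
    pd.Series(te_counts).to_csv(ann_dir / "te_classes.tsv", sep="\t", header=False)
    files = list(ann_dir.iterdir())
    if methylome is not None:
        summ = methylation_context_summary(methylome, tau=config.tau)
        inacr = methylation_in_intervals(methylome, pan_set, tau=config.tau)
        with open(ann_dir / "methylation_summary.json", "w") as fh:
            json.dump({"context_summary": summ, "in_acrs": inacr}, fh, indent=1, default=float)
        files = list(ann_dir.iterdir())
    done("annotate", t0, sorted(files))

    # enrich -----------------------------------------------------------------
    if sweeps is not None:
        t0 = stage("enrich")
        enr_dir = out / "enrich"
        enr_dir.mkdir(exist_ok=True)
        rows = []
        for crop in sim.crops():
            regions = sweep_regions_from_scores(sweeps[crop], top_fraction=config.top_fraction)
            write_intervals(regions, enr_dir / f"sweeps_{crop}.bed", "bed3")
            fx = fixed_by_crop[crop]
            dacr_set = IntervalSet(
                [id_to_iv[i] for i in sorted(fx["fixed_open"] | fx["fixed_closed"])]
            )
            ov = dacr_sweep_overlap(dacr_set, regions)
            enr = sweep_in_dacr_enrichment(dacr_set, regions, genome,
                                           denominator=config.denominator)
            in_sweeps, _ = (
                dacr_set.overlaps_any(regions) if len(dacr_set) else (IntervalSet(), dacr_set)
            )
            gene_ids, _pairs = genes_near_intervals(in_sweeps, genes, dist=config.flank)
            rows.append(
                {
                    "species": crop,
                    "dacrs": ov["total"],
                    "dacrs_in_sweeps": ov["overlapping"],
                    "fraction": ov["fraction"],
                    "overlap_bp": enr["observed_bp"],
                    "expected_bp": enr["expected_bp"],
                    "p_enriched": enr["p_enriched"],
                    "candidate_genes": len(gene_ids),
                }
            )
        pd.DataFrame(rows).to_csv(enr_dir / "enrichment.tsv", sep="\t", index=False)
        done("enrich", t0, sorted(enr_dir.iterdir()))

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    logger.info("pipeline complete; manifest at %s", manifest_path)
    return manifest
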