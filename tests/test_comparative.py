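"""Pan-ACR index, sharing table, permutation null, spectra and fixed dACRs."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from panacr.comparative import (
    accession_frequency,
    build_pan_index,
    fixed_dacrs,
    joint_spectrum,
    pairwise_state_changes,
    permutation_null,
    sharing_combinations,
)
from panacr.consensus import ConsensusACR, PeakSample, apply_sample_filters, build_consensus
from panacr.errors import IntegrityError, UsageError
from panacr.intervals import GenomeSpec, GenomicInterval, IntervalSet
from panacr.simulate import (
    SimulationConfig,
    exchangeable_config,
    simulate_genome,
    simulate_panacrome,
)


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


def cons(chrom, start, end, scope="sp"):
    return ConsensusACR(iv(chrom, start, end), frozenset({"x", "y"}), frozenset(), scope)


@pytest.fixture(scope="module")
def noiseless_run():
    cfg = dataclasses.replace(
        SimulationConfig(seed=17),
        n_chrom=1, chrom_length=2_000_000, n_genes=0, te_superfamilies={},
        n_panacrs=300, jitter_sd=0.0, dropout=0.0, false_positive_rate=0.0,
    )
    genome, _, _ = simulate_genome(cfg)
    samples, wgs, truth = simulate_panacrome(cfg, genome)
    filt = apply_sample_filters(samples, wgs)
    per = {
        sp: build_consensus([s for s in filt if s.species == sp], 2, sp)
        for sp in sorted({s.species for s in filt})
    }
    pan, matrix = build_pan_index(per)
    return cfg, genome, filt, truth, pan, matrix


class TestPanIndex:
    def test_cross_species_overlap_fuses(self):
        pan, matrix = build_pan_index(
            {"A": [cons("c", 100, 200)], "B": [cons("c", 150, 250)]}
        )
        assert len(pan) == 1
        assert pan[0].interval.key == ("c", 100, 250)
        assert pan[0].species_open == {"A": True, "B": True}
        assert pan[0].acr_id == "c:100-250"

    def test_disjoint_stay_separate(self):
        pan, matrix = build_pan_index(
            {"A": [cons("c", 100, 200)], "B": [cons("c", 500, 600)]}
        )
        assert len(pan) == 2
        assert matrix.values.sum() == 2

    def test_noiseless_recovery_matches_truth(self, noiseless_run):
        _, _, _, truth, pan, matrix = noiseless_run
        truth_keys = set(
            zip(truth.acrs["chrom"], truth.acrs["start"], truth.acrs["end"])
        )
        assert {p.interval.key for p in pan} == truth_keys
        ss = truth.species_states()
        for p in pan:
            assert p.species_open == ss.loc[p.acr_id].to_dict()


class TestSharingCombinations:
    def test_two_species_toy(self):
        m = pd.DataFrame(
            {"A": [1, 1, 1, 0, 0, 1, 1, 1, 1, 1], "B": [0, 0, 0, 1, 1, 1, 1, 1, 1, 1]},
            index=[f"a{i}" for i in range(10)],
        )
        counts = sharing_combinations(m)
        assert counts["A"] == 3 and counts["B"] == 2 and counts["A+B"] == 5
        assert counts.sum() == 10

    def test_all_open_single_cell(self):
        m = pd.DataFrame(np.ones((7, 5), dtype=int), columns=list("ABCDE"))
        counts = sharing_combinations(m)
        assert counts["A+B+C+D+E"] == 7 and counts.sum() == 7
        assert len(counts) == 31

    def test_all_zero_row_rejected(self):
        m = pd.DataFrame({"A": [1, 0], "B": [1, 0]})
        with pytest.raises(IntegrityError):
            sharing_combinations(m)

    def test_matches_truth_tallies(self, noiseless_run):
        _, _, _, truth, _, matrix = noiseless_run
        assert sharing_combinations(matrix).sort_index().equals(
            truth.sharing_counts().sort_index()
        )


class TestPermutationNull:
    def test_counts_sum_preserved_and_within_label(self, noiseless_run):
        _, _, filt, _, pan, matrix = noiseless_run
        tab = permutation_null(filt, n_perm=20, seed=1)
        assert tab["observed"].sum() == len(pan)
        assert set(tab["label"]) <= {"enriched", "depleted", "within"}

    def test_degenerate_constant_counts_zero_width_within(self):
        # two species, both samples of each carry the same single peak:
        # every permutation yields the identical table
        samples = [
            PeakSample(f"s{i}", f"a{i}", "A" if i < 2 else "B", "leaf",
                       IntervalSet([iv("c", 100, 200)]))
            for i in range(4)
        ]
        tab = permutation_null(samples, n_perm=10, seed=0)
        row = tab.loc["A+B"]
        assert row["ci_low"] == row["ci_high"] == row["observed"]
        assert row["label"] == "within"

    def test_n_perm_below_two_rejected(self):
        with pytest.raises(UsageError):
            permutation_null([], n_perm=1)

    def test_planted_singleton_excess_flagged_enriched(self):
        from panacr.simulate import planted_excess_config

        detected = 0
        for d in range(10):
            cfg = planted_excess_config(3000 + d)
            genome, _, _ = simulate_genome(cfg)
            samples, _, _ = simulate_panacrome(cfg, genome)
            tab = permutation_null(samples, n_perm=50, seed=d)
            detected += tab.loc["A", "label"] == "enriched"
        assert detected >= 9


class TestStateChanges:
    def _pan(self):
        pan, _ = build_pan_index(
            {
                "crop": [cons("c", 0, 1000), cons("c", 10_000, 10_500)],
                "wild": [cons("c", 5000, 7000), cons("c", 10_000, 10_500)],
            }
        )
        return pan

    def test_opened_closed_percentages(self):
        genome = GenomeSpec({"c": 100_000})
        out = pairwise_state_changes(self._pan(), "crop", "wild", genome)
        assert out["opened_count"] == 1 and out["closed_count"] == 1
        assert out["opened_pct"] == pytest.approx(1.0)
        assert out["closed_pct"] == pytest.approx(2.0)

    def test_self_comparison_zero(self):
        genome = GenomeSpec({"c": 100_000})
        out = pairwise_state_changes(self._pan(), "crop", "crop", genome)
        assert out["opened_count"] == out["closed_count"] == 0

    def test_unknown_species_rejected(self):
        with pytest.raises(UsageError):
            pairwise_state_changes(self._pan(), "crop", "nope", GenomeSpec({"c": 10}))

    def test_noiseless_counts_match_truth(self, noiseless_run):
        cfg, genome, _, truth, pan, _ = noiseless_run
        ss = truth.species_states()
        for crop in cfg.crops():
            out = pairwise_state_changes(pan, crop, cfg.wild_ancestor(), genome)
            expected_opened = int((ss[crop] & ~ss[cfg.wild_ancestor()]).sum())
            expected_closed = int((~ss[crop] & ss[cfg.wild_ancestor()]).sum())
            assert out["opened_count"] == expected_opened
            assert out["closed_count"] == expected_closed


class TestFrequenciesAndSpectra:
    def test_frequency_counts_open_accessions(self):
        pan, _ = build_pan_index({"A": [cons("c", 100, 200)]})
        samples = [
            PeakSample("s1", "a1", "A", "leaf", IntervalSet([iv("c", 100, 200)])),
            PeakSample("s2", "a2", "A", "leaf", IntervalSet([iv("c", 150, 250)])),
            PeakSample("s3", "a3", "A", "leaf", IntervalSet([])),
        ]
        freq, open_mat = accession_frequency(pan, samples)
        assert freq.loc["c:100-200", "A"] == pytest.approx(2 / 3)

    def test_noiseless_frequencies_match_truth(self, noiseless_run):
        _, _, filt, truth, pan, _ = noiseless_run
        freq, _ = accession_frequency(pan, filt)
        expected = truth.accession_frequency()
        assert np.allclose(
            freq.sort_index().values,
            expected.loc[freq.sort_index().index, freq.columns].values,
        )

    def test_joint_spectrum_toy(self):
        ids = ["r1", "r2", "r3", "r4"]
        fa = pd.Series([0.0, 0.0, 1.0, 1.0], index=ids)
        fb = pd.Series([1.0, 1.0, 0.0, 1.0], index=ids)
        grid = joint_spectrum(fa, fb, 1, 1)
        assert grid.loc[0.0, 1.0] == 2
        assert grid.loc[1.0, 0.0] == 1
        assert grid.loc[1.0, 1.0] == 1
        assert grid.values.sum() == 4

    def test_spectrum_matches_exhaustive_tally(self, rng):
        n_a, n_b = 4, 3
        ids = [f"r{i}" for i in range(500)]
        fa = pd.Series(rng.integers(0, n_a + 1, 500) / n_a, index=ids)
        fb = pd.Series(rng.integers(0, n_b + 1, 500) / n_b, index=ids)
        grid = joint_spectrum(fa, fb, n_a, n_b)
        assert grid.values.sum() == 500
        for i in range(n_a + 1):
            for j in range(n_b + 1):
                expected = int(((fa == i / n_a) & (fb == j / n_b)).sum())
                assert grid.iloc[i, j] == expected
        # marginals equal per-species histograms
        assert (grid.sum(axis=1).values == np.bincount(
            (fa * n_a).round().astype(int), minlength=n_a + 1)).all()

    def test_mismatched_ids_rejected(self):
        with pytest.raises(UsageError):
            joint_spectrum(
                pd.Series([0.0], index=["a"]), pd.Series([0.0], index=["b"]), 1, 1
            )


class TestFixedDacrs:
    def test_boundary_membership(self):
        ids = ["r1", "r2", "r3"]
        crop = pd.Series([1.0, 2 / 3, 0.0], index=ids)
        wild = pd.Series([0.0, 0.0, 1.0], index=ids)
        out = fixed_dacrs(crop, wild)
        assert out["fixed_open"] == {"r1"}
        assert out["fixed_closed"] == {"r3"}

    def test_argument_antisymmetry(self, rng):
        ids = [f"r{i}" for i in range(200)]
        a = pd.Series(rng.integers(0, 4, 200) / 3, index=ids)
        b = pd.Series(rng.integers(0, 4, 200) / 3, index=ids)
        ab, ba = fixed_dacrs(a, b), fixed_dacrs(b, a)
        assert ab["fixed_open"] == ba["fixed_closed"]
        assert ab["fixed_closed"] == ba["fixed_open"]

    def test_noiseless_sets_match_truth(self, noiseless_run):
        cfg, _, filt, truth, pan, _ = noiseless_run
        freq, _ = accession_frequency(pan, filt)
        for crop in cfg.crops():
            got = fixed_dacrs(freq[crop], freq[cfg.wild_ancestor()])
            expected = truth.fixed_sets(crop, cfg.wild_ancestor())
            assert got["fixed_open"] == expected["fixed_open"]
            assert got["fixed_closed"] == expected["fixed_closed"]
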