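"""QC diagnostics: length filtering, regions, periodicity, offsets, correlation."""

import numpy as np
import pandas as pd
import pytest

from ribote.counts import UnknownTranscriptError
from ribote.qc import (
    estimate_psite_offset,
    filter_by_length,
    frame_fractions,
    length_distribution,
    metagene_profile,
    periodicity_pvalue,
    region_fractions,
    replicate_correlation,
)
from ribote.simulate import SimConfig, make_transcriptome, simulate_reads
from ribote.transcripts import ReadRecord, TranscriptModel
from tests.conftest import make_count_matrix


def reads_at(tx_id, positions, length=30):
    return [ReadRecord(tx_id, p, length) for p in positions]


class TestLengthFilter:
    def test_retains_inclusive_window(self):
        reads = [ReadRecord("gA_T1", 0, l) for l in range(26, 34)]
        kept = filter_by_length(reads, 27, 32)
        assert [r.length for r in kept] == list(range(27, 33))

    def test_empty_input(self):
        assert filter_by_length([], 27, 32) == []

    def test_identity_when_all_in_window(self):
        reads = [ReadRecord("gA_T1", i, 28) for i in range(10)]
        assert filter_by_length(reads, 25, 40) == reads

    def test_idempotent(self):
        reads = [ReadRecord("gA_T1", 0, l) for l in range(20, 45)]
        once = filter_by_length(reads, 27, 32)
        assert filter_by_length(once, 27, 32) == once

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            filter_by_length([], 30, 27)


class TestLengthDistribution:
    def test_single_length(self):
        hist = length_distribution([ReadRecord("g", 0, 30)] * 3)
        assert hist.to_dict() == {30: 3}

    def test_gaps_reported_as_zero(self):
        hist = length_distribution(
            [ReadRecord("g", 0, 28), ReadRecord("g", 0, 31)]
        )
        assert hist.to_dict() == {28: 1, 29: 0, 30: 0, 31: 1}

    def test_empty(self):
        assert length_distribution([]).empty

    def test_simulator_mode_at_configured_peak(self, toy_models):
        cfg = SimConfig(seed=5)
        reads = simulate_reads(cfg, toy_models, assay="rpf", n_reads=20_000)
        assert length_distribution(reads).idxmax() == 30


class TestRegions:
    def test_all_cds(self, toy_models):
        fr, counts = region_fractions(reads_at("gA_T1", [100, 200]), toy_models, offset=0)
        assert fr["cds"] == 1.0 and counts["cds"] == 2

    def test_uniform_rna_matches_geometry(self, toy_models):
        cfg = SimConfig(seed=6)
        reads = simulate_reads(cfg, toy_models[:1], assay="rna", n_reads=50_000)
        fr, _ = region_fractions(reads, toy_models, offset=0)
        assert fr["cds"] == pytest.approx(0.75, abs=0.02)
        assert fr["utr5"] == pytest.approx(0.125, abs=0.02)
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-9)

    def test_unknown_transcript_raises_keyed_error(self, toy_models):
        with pytest.raises(UnknownTranscriptError) as err:
            region_fractions([ReadRecord("nope", 0, 30)], toy_models)
        assert "nope" in err.value.missing


class TestMetagene:
    def test_empty_reads_give_zero_profile(self, toy_models):
        prof = metagene_profile([], toy_models, anchor="start", window=(-20, 20))
        assert prof.mean_counts.sum() == 0 and prof.n_transcripts == 0

    def test_constructed_peak_at_minus_13(self, toy_models):
        reads = reads_at("gA_T1", [50 - 13] * 5) + reads_at("gB_T1", [50 - 13] * 3)
        prof = metagene_profile(reads, toy_models, anchor="start", window=(-20, 5))
        assert prof.positions[np.argmax(prof.mean_counts)] == -13
        assert prof.mean_counts.max() == 4.0  # mean of 5 and 3

    def test_simulated_rpfs_show_3nt_periodicity(self, toy_models):
        cfg = SimConfig(frame_probs=(0.9, 0.05, 0.05), psite_offset=13, seed=7)
        reads = simulate_reads(cfg, toy_models, assay="rpf", n_reads=50_000)
        prof = metagene_profile(reads, toy_models, anchor="start", window=(-13, 30))
        downstream = prof.mean_counts[prof.positions >= -13]
        frames = prof.frame_of_position[prof.positions >= -13]
        # dominant frame (position -13 has frame (-13) % 3 == 2) towers
        by_frame = [downstream[frames == f].mean() for f in range(3)]
        assert by_frame[2] > 3 * max(by_frame[0], by_frame[1])

    def test_stop_anchor_window(self, toy_models):
        # stop codon starts at 50 + 300 - 3 = 347; place reads 15 nt upstream
        reads = reads_at("gA_T1", [347 - 15] * 4)
        prof = metagene_profile(reads, toy_models, anchor="stop", window=(-20, 3))
        assert prof.positions[np.argmax(prof.mean_counts)] == -15


class TestFrames:
    def test_pure_frame0(self, toy_models):
        reads = reads_at("gA_T1", [50, 53, 56])
        (f0, f1, f2), chi2 = frame_fractions(reads, toy_models, offset=0)
        assert (f0, f1, f2) == (1.0, 0.0, 0.0)

    def test_uniform_gives_zero_statistic(self, toy_models):
        reads = (
            reads_at("gA_T1", [50 + 3 * i for i in range(100)])
            + reads_at("gA_T1", [51 + 3 * i for i in range(100)])
            + reads_at("gA_T1", [52 + 3 * i for i in range(100)])
        )
        fr, chi2 = frame_fractions(reads, toy_models, offset=0)
        assert chi2 == 0.0
        assert sum(fr) == pytest.approx(1.0, abs=1e-9)

    def test_simulated_fractions_within_pm_001(self, toy_models):
        cfg = SimConfig(frame_probs=(0.7, 0.2, 0.1), psite_offset=13, seed=8)
        reads = simulate_reads(cfg, toy_models, assay="rpf", n_reads=100_000)
        fr, _ = frame_fractions(reads, toy_models, offset=13)
        assert np.abs(np.array(fr) - np.array([0.7, 0.2, 0.1])).max() < 0.01

    def test_no_usable_reads_raises(self, toy_models):
        with pytest.raises(ValueError):
            frame_fractions(reads_at("gA_T1", [0]), toy_models, offset=0)

    def test_rna_reads_not_periodic(self, toy_models):
        cfg = SimConfig(seed=9)
        reads = simulate_reads(cfg, toy_models, assay="rna", n_reads=100_000)
        _, chi2 = frame_fractions(reads, toy_models, offset=0)
        assert periodicity_pvalue(chi2) > 0.01


class TestPsiteOffset:
    def test_recovers_simulated_offset_per_length(self, toy_models):
        cfg = SimConfig(psite_offset=13, seed=10)
        reads = simulate_reads(cfg, toy_models, assay="rpf", n_reads=200_000)
        offsets = estimate_psite_offset(reads, toy_models, per_length=True)
        from ribote.qc import OFFSET_SEARCH_RANGE

        support = {}
        for r in reads:
            d = 50 - r.five_prime_pos
            if d in OFFSET_SEARCH_RANGE:
                support[r.length] = support.get(r.length, 0) + 1
        for length, n in support.items():
            if n >= 500:
                assert offsets[length] == 13

    def test_tie_breaks_towards_smaller_offset(self, toy_models):
        reads = reads_at("gA_T1", [50 - 12] * 7 + [50 - 13] * 7)
        assert estimate_psite_offset(reads, toy_models, per_length=False) == 12

    def test_reads_at_start_codon_out_of_range(self, toy_models):
        with pytest.raises(ValueError):
            estimate_psite_offset(reads_at("gA_T1", [50, 50]), toy_models)


class TestReplicateCorrelation:
    def test_duplicated_library_correlates_perfectly(self):
        counts = np.array([[10, 10, 3, 5], [0, 0, 8, 1], [7, 7, 2, 9], [1, 1, 4, 4]])
        cm = make_count_matrix(counts, times=(0, 12), n_reps=1)
        corr = replicate_correlation(cm)
        assert corr.iloc[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)

    def test_matches_hand_computed_pearson(self):
        counts = np.array([[10, 4, 1, 2], [5, 6, 0, 3], [2, 9, 7, 1], [8, 3, 2, 0]])
        cm = make_count_matrix(counts, times=(0, 12), n_reps=1)
        corr = replicate_correlation(cm)
        a, b = np.log1p(counts[:, 0].astype(float)), np.log1p(counts[:, 2].astype(float))
        hand = ((a - a.mean()) * (b - b.mean())).sum() / np.sqrt(
            ((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()
        )
        assert corr.iloc[0, 2] == pytest.approx(hand, abs=1e-12)

    def test_replicates_agree_more_than_assays(self, small_config):
        from ribote.counts import drop_all_zero_genes
        from ribote.simulate import simulate_counts

        cm, _ = simulate_counts(small_config.replace(n_genes=400, lib_depth=500_000.0))
        corr = replicate_correlation(drop_all_zero_genes(cm))
        within = corr.loc["rna_t0_r1", "rna_t0_r2"]
        across = corr.loc["rna_t0_r1", "rpf_t0_r1"]
        assert within > across

    def test_single_library_rejected(self):
        from ribote.counts import CountMatrix

        cm = make_count_matrix(np.array([[1, 2], [3, 4]]), times=(0,), n_reps=1)
        one = CountMatrix(cm.counts.iloc[:, :1], cm.samples)
        with pytest.raises(ValueError):
            replicate_correlation(one)
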