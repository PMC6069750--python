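"""Synthetic transcriptome generation, read simulation and classification."""

import math

import numpy as np
import pytest

import stable_asm as sa
from helpers import random_seq


def single_isoform_pool(seed, n=5, length=(400, 900)):
    return sa.make_transcriptome(n, 1, length, (1, 1), 1.0, seed=seed)


class TestMakeTranscriptome:
    def test_single_isoform_is_exon_concatenation(self):
        genome, genes, expressed, annotated = sa.make_transcriptome(
            1, 1, (200, 300), (2, 3), 1.0, seed=1
        )
        gene = genes[0]
        seq = "".join(genome[s:e] for s, e in gene.exons)
        assert list(expressed.values()) == [seq]
        assert expressed == annotated

    def test_three_isoforms_two_expressed(self):
        genome, genes, expressed, annotated = sa.make_transcriptome(
            1, 3, (150, 250), (5, 6), 2 / 3, seed=4
        )
        gene = genes[0]
        assert len(gene.isoforms) == 3 and len(gene.expressed) == 2
        unexpressed = set(annotated) - set(expressed)
        assert len(unexpressed) == 1

    def test_isoforms_share_first_and_last_exon(self):
        _, genes, _, _ = sa.make_transcriptome(3, 3, (100, 200), (5, 7), 1.0, seed=2)
        for gene in genes:
            n_exons = len(gene.exons)
            for chain in gene.isoforms:
                assert chain[0] == 0 and chain[-1] == n_exons - 1
                assert list(chain) == sorted(chain)

    def test_exons_non_overlapping_and_ordered(self):
        _, genes, _, _ = sa.make_transcriptome(4, 1, (100, 200), (2, 4), 1.0, seed=3)
        for gene in genes:
            for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
                assert s1 < e1 <= s2 < e2

    def test_infeasible_isoform_count_rejected(self):
        with pytest.raises(ValueError, match="isoform"):
            sa.make_transcriptome(1, 3, (100, 200), (2, 2), 1.0, seed=0)


class TestSimulateReads:
    def test_read_count_follows_coverage(self):
        _, _, expressed, _ = sa.make_transcriptome(1, 1, (1500, 1500), (1, 1), 1.0, seed=0)
        reads, truth = sa.simulate_reads(expressed, sa.ReadSimParams(rng_seed=0))
        assert len(reads) == math.ceil(20 * 1500 / 150) == 200
        assert reads.uniform_length == 150
        assert len(truth) == len(reads)

    def test_zero_noise_reads_are_exact_substrings(self):
        _, _, expressed, _ = single_isoform_pool(7)
        reads, truth = sa.simulate_reads(
            expressed, sa.ReadSimParams(substitution_rate=0.0, rng_seed=7)
        )
        seqs = {k: v for k, v in expressed.items()}
        for read, (rid, tid, start) in zip(reads, truth):
            assert read.read_id == rid
            assert read.seq.to_string() == seqs[tid][start : start + 150]

    def test_total_bases_match_coverage_within_five_percent(self):
        _, _, expressed, _ = single_isoform_pool(11)
        reads, _ = sa.simulate_reads(expressed, sa.ReadSimParams(rng_seed=11))
        total_read = sum(len(r) for r in reads)
        total_ref = sum(len(s) for s in expressed.values())
        assert abs(total_read / total_ref - 20) / 20 < 0.05

    def test_too_short_transcript_skipped(self):
        reads, truth = sa.simulate_reads(
            {"tiny": "ACGT" * 10}, sa.ReadSimParams(rng_seed=0)
        )
        assert len(reads) == 0 and truth == []

    def test_substitution_rate_roughly_respected(self):
        _, _, expressed, _ = single_isoform_pool(13, n=3)
        rate = 0.01
        reads, truth = sa.simulate_reads(
            expressed, sa.ReadSimParams(substitution_rate=rate, rng_seed=13)
        )
        mismatches = 0
        for read, (_, tid, start) in zip(reads, truth):
            ref = sa.encode_sequence(expressed[tid][start : start + 150])
            mismatches += sa.hamming_2bit(read.seq, ref)
        observed = mismatches / (len(reads) * 150)
        assert 0.5 * rate < observed < 2.0 * rate


class TestClassification:
    def test_references_classify_as_tp_against_themselves(self):
        genome, genes, expressed, annotated = single_isoform_pool(21)
        results = [sa.AssembledTranscript(k, v) for k, v in expressed.items()]
        report, labels = sa.classify_reconstructions(
            results, expressed, annotated, genes, genome
        )
        assert all(l["label"] == "TP" for l in labels)
        assert report.n_fp == 0 and report.fpr == 0.0
        assert report.n_full == report.n_70 == report.n_refs
        assert report.s100 == report.s70 == 100.0

    def test_unexpressed_isoform_is_fpa(self):
        genome, genes, expressed, annotated = sa.make_transcriptome(
            1, 3, (150, 250), (5, 6), 2 / 3, seed=4
        )
        missing_id = next(iter(set(annotated) - set(expressed)))
        results = [sa.AssembledTranscript("x", annotated[missing_id])]
        report, labels = sa.classify_reconstructions(
            results, expressed, annotated, genes, genome
        )
        assert labels[0]["label"] == "FPA"
        assert report.n_fpa == 1 and report.n_fpb == 0

    def test_chimera_is_fpb(self, rng):
        genome, genes, expressed, annotated = single_isoform_pool(23)
        seqs = list(expressed.values())
        chimera = seqs[0][: len(seqs[0]) // 2] + seqs[1][len(seqs[1]) // 2 :]
        report, labels = sa.classify_reconstructions(
            [sa.AssembledTranscript("c", chimera)], expressed, annotated, genes, genome
        )
        assert labels[0]["label"] == "FPB"
        assert report.n_fpb == 1 and report.n_fpa == 0

    def test_single_isoform_genes_cannot_produce_fpa(self, rng):
        genome, genes, expressed, annotated = single_isoform_pool(29)
        seqs = list(expressed.values())
        results = [
            sa.AssembledTranscript("junk", random_seq(rng, 500)),
            sa.AssembledTranscript("chim", seqs[0][:300] + seqs[1][:300]),
            sa.AssembledTranscript("ok", seqs[2]),
        ]
        report, _ = sa.classify_reconstructions(
            results, expressed, annotated, genes, genome
        )
        assert report.n_fpa == 0
        assert report.n_fp == report.n_fpb

    def test_reverse_complement_result_is_tp(self):
        genome, genes, expressed, annotated = single_isoform_pool(31)
        seq = next(iter(expressed.values()))
        report, labels = sa.classify_reconstructions(
            [sa.AssembledTranscript("rc", sa.revcomp(seq))],
            expressed, annotated, genes, genome,
        )
        assert labels[0]["label"] == "TP"

    def test_partition_and_ordering_invariants(self, rng):
        genome, genes, expressed, annotated = single_isoform_pool(37)
        seqs = list(expressed.values())
        results = [
            sa.AssembledTranscript("a", seqs[0]),
            sa.AssembledTranscript("b", seqs[1][:350]),
            sa.AssembledTranscript("c", random_seq(rng, 400)),
        ]
        report, _ = sa.classify_reconstructions(
            results, expressed, annotated, genes, genome
        )
        assert report.n_fp == report.n_fpa + report.n_fpb
        assert report.n_fp <= report.n_results
        assert report.n_full <= report.n_70 <= report.n_refs
        assert report.s100 <= report.s70


class TestMetrics:
    @pytest.mark.parametrize(
        "args,s100,s70,fpr,decimals",
        [
            ((227, 1, 152, 161, 200), 76, 81, 0.44, 2),
            ((8906, 2285, 3295, 4179, 6309), 52, 66, 26, 0),
            ((100, 0, 0, 0, 50), 0, 0, 0, 0),
        ],
    )
    def test_metric_arithmetic(self, args, s100, s70, fpr, decimals):
        raw = sa.compute_metrics(*args)
        assert sa.round_half_up(raw[0], 0) == s100
        assert sa.round_half_up(raw[1], 0) == s70
        assert sa.round_half_up(raw[2], decimals) == fpr

    def test_zero_denominators_define_zero(self):
        assert sa.compute_metrics(0, 0, 0, 0, 0) == (0.0, 0.0, 0.0)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            sa.compute_metrics(5, 6, 0, 0, 10)
        with pytest.raises(ValueError):
            sa.compute_metrics(5, 0, 4, 3, 10)

    def test_round_half_up_is_half_up(self):
        assert sa.round_half_up(80.5, 0) == 81
        assert sa.round_half_up(0.125, 2) == 0.13
        assert sa.round_half_up(2.5, 0) == 3
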