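"""Glocal aligner, SAM ingestion and pileup construction."""

import numpy as np
import pytest

from _oracles import glocal_score_oracle, naive_pileup_oracle
from trnamod.align import (
    PileupMatrix,
    ReadAlignment,
    Scoring,
    UnassignedRead,
    align_and_pileup,
    align_read,
    align_reads,
    build_pileup,
    read_sam,
)
from trnamod.errors import AlignmentError, PileupError
from trnamod.simulate import RTSignatureModel, simulate_reads, standard_genotype_models


class TestAlignRead:
    def test_exact_substring_alignment(self, demo_genes):
        gene = demo_genes[0]
        read = gene.sequence[5:45]
        aln = align_read(read, demo_genes, read_id="r1")
        assert isinstance(aln, ReadAlignment)
        assert aln.gene_id == gene.gene_id
        assert aln.ref_start == 5
        assert aln.n_mismatches == 0
        assert aln.score == len(read)
        assert aln.aligned_pairs == [(i, 5 + i) for i in range(40)]

    def test_equal_best_score_on_two_references_is_multimapped(self, demo_genes):
        # identical references under two names
        twins = [demo_genes[0], demo_genes[0].__class__(
            gene_id="tRNA-Ala-AGC-2-1",
            amino_acid=demo_genes[0].amino_acid,
            anticodon=demo_genes[0].anticodon,
            sequence=demo_genes[0].sequence,
            anticodon_offset=demo_genes[0].anticodon_offset,
            has_cca=demo_genes[0].has_cca,
        )]
        result = align_read(twins[0].sequence[0:40], twins)
        assert isinstance(result, UnassignedRead)
        assert result.reason == "multimapped"

    def test_low_score_read_unassigned(self, demo_genes):
        result = align_read("ACGT" * 10, demo_genes[:1], min_score_fraction=0.95)
        if isinstance(result, UnassignedRead):
            assert result.reason == "low_score"
        else:  # a 40-mer repeat may happen to align well only if near-exact
            assert result.score >= 0.95 * 40

    def test_short_read_rejected(self, demo_genes):
        result = align_read("ACGTACGTAC", demo_genes)
        assert isinstance(result, UnassignedRead) and result.reason == "too_short"

    def test_non_acgtn_characters_error(self, demo_genes):
        with pytest.raises(AlignmentError):
            align_read("ACGTX" * 8, demo_genes)

    def test_revcomp_flag_recovers_antisense_reads(self, demo_genes):
        from trnamod.align import revcomp

        gene = demo_genes[0]
        read = revcomp(gene.sequence[10:50])
        assert isinstance(align_read(read, demo_genes), UnassignedRead)
        aln = align_read(read, demo_genes, try_revcomp=True)
        assert isinstance(aln, ReadAlignment)
        assert aln.gene_id == gene.gene_id
        assert aln.strand == "-"
        assert aln.ref_start == 10

    def test_score_equals_bruteforce_oracle_on_random_pairs(self):
        """Vectorised affine DP agrees with an independent recursive oracle
        on random read/reference pairs, including gap-inducing cases."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            read = "".join("ACGT"[i] for i in rng.integers(0, 4, size=rng.integers(8, 15)))
            ref = "".join("ACGT"[i] for i in rng.integers(0, 4, size=rng.integers(12, 26)))
            from trnamod.align import _batch_scores, _encode

            got = _batch_scores(_encode(read)[None, :], _encode(ref), Scoring())[0]
            assert got == glocal_score_oracle(read, ref)

    def test_traceback_score_matches_batch_score(self):
        from trnamod.align import _batch_scores, _encode, _single_alignment

        rng = np.random.default_rng(7)
        for _ in range(30):
            read = "".join("ACGT"[i] for i in rng.integers(0, 4, size=30))
            ref = "".join("ACGT"[i] for i in rng.integers(0, 4, size=60))
            enc_r, enc_f = _encode(read), _encode(ref)
            batch = _batch_scores(enc_r[None, :], enc_f, Scoring())[0]
            single, pairs, ref_start, _ = _single_alignment(enc_r, enc_f, Scoring())
            assert single == batch
            # every read base consumed exactly once (read-global)
            consumed = [q for q, _ in pairs if q is not None]
            assert consumed == list(range(30))

    def test_gapped_read_traceback(self, demo_genes):
        gene = demo_genes[0]
        read = gene.sequence[5:25] + gene.sequence[28:48]  # 3-nt deletion
        aln = align_read(read, demo_genes[:1])
        assert isinstance(aln, ReadAlignment)
        assert aln.score == 40 - 3 - 2 * 1  # 40 matches, open+2 extends
        assert aln.n_mismatches == 0
        dels = [r for q, r in aln.aligned_pairs if q is None]
        # a contiguous 3-base deletion; its exact placement may shift within
        # an equivalent-score repeat
        assert len(dels) == 3
        assert dels == list(range(dels[0], dels[0] + 3))
        assert abs(dels[0] - 25) <= 3


class TestTruthRecovery:
    def test_low_error_reads_recover_true_origin(self, demo_genes):
        """Reads with <=2 substitutions and no gaps map back to their source
        gene at the correct offset."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            gene = demo_genes[rng.integers(0, len(demo_genes))]
            start = int(rng.integers(0, len(gene.sequence) - 40))
            read = list(gene.sequence[start : start + 40])
            for pos in rng.choice(40, size=2, replace=False):
                read[pos] = "ACGT"[(("ACGT".index(read[pos])) + 1 + rng.integers(0, 3)) % 4]
            aln = align_read("".join(read), demo_genes)
            assert isinstance(aln, ReadAlignment)
            assert aln.gene_id == gene.gene_id
            assert aln.ref_start == start


class TestPileup:
    def test_error_free_full_length_reads(self, demo_genes):
        gene = demo_genes[0]
        reads = [(f"r{i}", gene.sequence) for i in range(10)]
        pile = build_pileup(align_reads(reads, demo_genes), demo_genes)
        mat = pile.counts[gene.gene_id]
        code = {"A": 0, "C": 1, "G": 2, "T": 3}
        for pos, base in enumerate(gene.sequence):
            assert mat[pos, code[base]] == 10
            assert mat[pos].sum() == 10  # column sums equal coverage

    def test_pileup_matches_naive_oracle(self, demo_genes):
        rt = RTSignatureModel.default(error_rate=0.02)
        model = standard_genotype_models(demo_genes)["wild_type"]
        sim = simulate_reads(demo_genes, model, rt, 100, seed=13)
        pile = build_pileup(align_reads(sim.reads, demo_genes), demo_genes)
        placements = [(rid.split("|")[0], 0, seq) for rid, seq in sim.reads]
        oracle = naive_pileup_oracle(placements, {g.gene_id: len(g.sequence) for g in demo_genes})
        code = {"A": 0, "C": 1, "G": 2, "T": 3}
        for g in demo_genes:
            mat = pile.counts[g.gene_id]
            for pos in range(len(g.sequence)):
                for base, idx in code.items():
                    assert mat[pos, idx] == oracle[g.gene_id][pos][base]

    def test_align_and_pileup_equals_objectwise_route(self, demo_genes):
        rt = RTSignatureModel.default(error_rate=0.02)
        model = standard_genotype_models(demo_genes)["trm5"]
        sim = simulate_reads(demo_genes, model, rt, 120, seed=21)
        via_objects = build_pileup(align_reads(sim.reads, demo_genes), demo_genes)
        via_batch = align_and_pileup(sim.reads, demo_genes)
        for g in demo_genes:
            np.testing.assert_array_equal(
                via_objects.counts[g.gene_id], via_batch.counts[g.gene_id]
            )
        assert via_batch.n_assigned == via_objects.n_assigned

    def test_conservation_total_counts(self, demo_genes):
        gene = demo_genes[0]
        reads = [(f"r{i}", gene.sequence[3:60]) for i in range(7)]
        alns = align_reads(reads, demo_genes)
        pile = build_pileup(alns, demo_genes)
        total = sum(int(m.sum()) for m in pile.counts.values())
        expected = sum(
            sum(1 for _, r in a.aligned_pairs if r is not None)
            for a in alns if isinstance(a, ReadAlignment)
        )
        assert total == expected

    def test_alignment_beyond_bounds_rejected(self, demo_genes):
        bad = ReadAlignment(
            read_id="r", gene_id=demo_genes[0].gene_id, ref_start=70,
            aligned_pairs=[(i, 70 + i) for i in range(30)],
            read_sequence="A" * 30, n_mismatches=0, score=30.0,
        )
        with pytest.raises(PileupError):
            build_pileup([bad], demo_genes)

    def test_pileup_frame_round_trip(self, demo_genes):
        rt = RTSignatureModel.default()
        model = standard_genotype_models(demo_genes)["tad1"]
        sim = simulate_reads(demo_genes, model, rt, 30, seed=1)
        pile = align_and_pileup(sim.reads, demo_genes)
        again = PileupMatrix.from_frame(pile.to_frame(demo_genes))
        for g in demo_genes:
            np.testing.assert_array_equal(pile.counts[g.gene_id], again.counts[g.gene_id])


SAM_TEMPLATE = """@HD\tVN:1.6\tSO:unknown
@SQ\tSN:{ref}\tLN:{ln}
{records}"""


class TestReadSam:
    def _sam(self, demo_genes, records):
        gene = demo_genes[0]
        return SAM_TEMPLATE.format(ref=gene.gene_id, ln=len(gene.sequence), records=records)

    def test_primary_record_position_is_zero_based(self, demo_genes):
        gene = demo_genes[0]
        seq = gene.sequence[5:45]
        rec = f"r1\t0\t{gene.gene_id}\t6\t60\t40M\t*\t0\t0\t{seq}\t{'I' * 40}"
        ingest = read_sam(self._sam(demo_genes, rec), demo_genes)
        (aln,) = ingest.alignments
        assert aln.ref_start == 5
        assert aln.n_mismatches == 0

    def test_secondary_dropped_and_counted(self, demo_genes):
        gene = demo_genes[0]
        seq = gene.sequence[5:45]
        recs = "\n".join([
            f"r1\t0\t{gene.gene_id}\t6\t60\t40M\t*\t0\t0\t{seq}\t{'I' * 40}",
            f"r1\t256\t{gene.gene_id}\t2\t60\t40M\t*\t0\t0\t{seq}\t{'I' * 40}",
            f"r2\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{'I' * 40}",
        ])
        ingest = read_sam(self._sam(demo_genes, recs), demo_genes)
        assert len(ingest.alignments) == 1
        assert ingest.n_secondary == 1
        assert ingest.n_unmapped == 1

    def test_unknown_reference_rejected(self, demo_genes):
        gene = demo_genes[0]
        sam = SAM_TEMPLATE.format(ref="tRNA-Mystery-NNN-1-1", ln=76, records=(
            f"r1\t0\ttRNA-Mystery-NNN-1-1\t1\t60\t40M\t*\t0\t0\t{'A' * 40}\t{'I' * 40}"
        ))
        with pytest.raises(AlignmentError):
            read_sam(sam, demo_genes)

    def test_deletion_cigar_counts_del_column(self, demo_genes):
        gene = demo_genes[0]
        seq = gene.sequence[0:20] + gene.sequence[23:43]
        rec = f"r1\t0\t{gene.gene_id}\t1\t60\t20M3D20M\t*\t0\t0\t{seq}\t{'I' * 40}"
        ingest = read_sam(self._sam(demo_genes, rec), demo_genes)
        pile = build_pileup(ingest.alignments, demo_genes)
        mat = pile.counts[gene.gene_id]
        assert mat[20, 4] == 1 and mat[21, 4] == 1 and mat[22, 4] == 1
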