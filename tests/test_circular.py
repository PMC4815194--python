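import numpy as np
import pytest

from adnapipe.circular import (
    CircularReference,
    ReadCategory,
    categorize,
    elongate_reference,
    process_sam,
    read_sidecar,
    rewrite,
)
from adnapipe.io import AlignmentRecord, FormatError, read_fasta, read_sam
from adnapipe.simulate import SimConfig, simulate_genome, simulate_reads, simulate_truth_sam


import re


def _aln(pos, cigar, seq=None, flags=0, mapq=37):
    n = sum(int(num) for num, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar)
            if op in "MIS=X")
    seq = seq or "A" * n
    return AlignmentRecord("r", flags, "chr", pos, mapq, cigar, seq, [30] * len(seq))


class TestElongate:
    def test_target_gets_first_k_bases_appended(self, tmp_path):
        ref = tmp_path / "ref.fasta"
        ref.write_text(">chrM\nACGTACGTAA\n")
        out = tmp_path / "el.fasta"
        side = tmp_path / "side.tsv"
        circ = elongate_reference(ref, out, "chrM", 4, sidecar_out=side)
        assert read_fasta(out) == [("chrM", "ACGTACGTAAACGT")]
        assert (circ.name, circ.length, circ.elongation) == ("chrM", 10, 4)
        assert vars(read_sidecar(side)) == vars(circ)

    def test_other_sequences_untouched(self, tmp_path):
        ref = tmp_path / "ref.fasta"
        ref.write_text(">chrM\nACGTACGTAA\n>chr1\nTTTTCCCCGG\n")
        out = tmp_path / "el.fasta"
        elongate_reference(ref, out, "chrM", 4)
        seqs = dict(read_fasta(out))
        assert seqs["chr1"] == "TTTTCCCCGG"
        assert seqs["chrM"] == "ACGTACGTAAACGT"

    def test_k_zero_and_unknown_target_rejected(self, tmp_path):
        ref = tmp_path / "ref.fasta"
        ref.write_text(">chrM\nACGTACGTAA\n")
        with pytest.raises(ValueError):
            elongate_reference(ref, tmp_path / "o", "chrM", 0)
        with pytest.raises(ValueError):
            elongate_reference(ref, tmp_path / "o", "nope", 4)
        with pytest.raises(ValueError):
            elongate_reference(ref, tmp_path / "o", "chrM", 11)


class TestCategorize:
    L, K = 100, 20

    @pytest.mark.parametrize("pos,span,expected", [
        (30, 20, ReadCategory.INTERIOR),   # 30..49, safely interior
        (105, 10, ReadCategory.EDGE),      # 105..114 in elongation window
        (95, 12, ReadCategory.JUNCTION),   # 95..106 spans the origin
        (5, 10, ReadCategory.EDGE),        # inside the first k bases
        (95, 6, ReadCategory.JUNCTION),    # 95..100 ends exactly at L: not junction
    ])
    def test_category_predicate(self, pos, span, expected):
        aln = _aln(pos, f"{span}M")
        got = categorize(aln, self.L, self.K)
        if pos == 95 and span == 6:
            assert got is not ReadCategory.JUNCTION  # end == L stays unsplit
        else:
            assert got is expected

    def test_junction_takes_precedence_over_edge(self):
        # starts inside the first k bases AND ends past L is impossible at
        # sane read lengths, but a start within [k+1, L] ending past L is
        # junction even though its end lies in the edge window
        assert categorize(_aln(95, "12M"), self.L, self.K) is ReadCategory.JUNCTION

    def test_end_past_elongated_length_rejected(self):
        with pytest.raises(FormatError):
            categorize(_aln(115, "10M"), self.L, self.K)

    def test_interval_arithmetic_oracle(self):
        # direct interval arithmetic over every (pos, span) on a small genome
        L, k = 50, 10
        for pos in range(1, L + k):
            for span in (1, 5, 12):
                if pos + span - 1 > L + k:
                    continue
                end = pos + span - 1
                exp = ("junction" if pos <= L < end
                       else "edge" if pos > L or end <= k
                       else "interior")
                assert categorize(_aln(pos, f"{span}M"), L, k).value == exp


class TestRewrite:
    L, K = 100, 20

    def test_interior_identical(self):
        aln = _aln(30, "20M")
        out = rewrite(aln, self.L, self.K)
        assert out == [aln]

    def test_edge_translated_by_L(self):
        out = rewrite(_aln(105, "10M"), self.L, self.K)
        assert len(out) == 1
        assert out[0].pos == 5 and out[0].cigar == "10M"

    def test_edge_in_first_k_unchanged_coords(self):
        out = rewrite(_aln(5, "10M"), self.L, self.K)
        assert out[0].pos == 5

    def test_ambiguous_edge_mapq_restored(self):
        out = rewrite(_aln(105, "10M", mapq=0), self.L, self.K, restored_mapq=37)
        assert out[0].mapq == 37
        # interior ambiguous records keep their mapper-assigned MAPQ
        out2 = rewrite(_aln(30, "10M", mapq=0), self.L, self.K)
        assert out2[0].mapq == 0

    def test_junction_split_positions_and_bases(self):
        seq = "ACGTACGTACGT"
        out = rewrite(_aln(95, "12M", seq=seq), self.L, self.K)
        assert len(out) == 2
        left, right = out
        assert (left.pos, left.cigar, left.sequence) == (95, "6M", seq[:6])
        assert (right.pos, right.cigar, right.sequence) == (1, "6M", seq[6:])
        assert right.flags & 0x800
        assert left.tags["XJ"] == right.tags["XJ"] == "r"

    def test_split_conserves_sequence_with_indels_and_clips(self):
        # 2S4M2I3M at pos 98: ref bases 98..104, junction after 3 ref bases
        seq = "TTACGTGGAAA"
        out = rewrite(_aln(98, "2S4M2I3M", seq=seq), self.L, self.K)
        left, right = out
        assert left.sequence + right.sequence == seq
        assert left.pos == 98 and right.pos == 1
        assert left.cigar == "2S3M"
        assert right.cigar == "1M2I3M"

    def test_boundary_insertion_stays_left(self):
        # 3M2I3M at pos 98: insertion falls exactly on the junction
        seq = "ACGTTAAA"
        out = rewrite(_aln(98, "3M2I3M", seq=seq), self.L, self.K)
        left, right = out
        assert left.cigar == "3M2I"
        assert right.cigar == "3M"
        assert left.sequence + right.sequence == seq

    def test_deletion_on_junction_becomes_right_offset(self):
        from adnapipe.circular import RewriteStats
        stats = RewriteStats()
        # deletion starts exactly on the junction: ref 101..104 == 1..4
        out = rewrite(_aln(97, "4M4D2M"), self.L, self.K, stats=stats)
        left, right = out
        assert left.cigar == "4M"
        assert stats.junction_deletions == 1
        assert right.pos == 5 and right.cigar == "2M"

    def test_deletion_crossing_junction_truncated(self):
        from adnapipe.circular import RewriteStats
        stats = RewriteStats()
        # 2M then 4D spanning ref 99..102: 2 deleted bases on each side
        out = rewrite(_aln(97, "2M4D4M"), self.L, self.K, stats=stats)
        left, right = out
        assert left.cigar == "2M2D"
        assert right.pos == 3 and right.cigar == "4M"
        assert stats.junction_deletions == 1
        assert left.sequence + right.sequence == "A" * 6


class TestProcessSam:
    def _sim(self, seed, tmp_path, n=200):
        cfg = SimConfig(seed=seed, genome_length=2000, n_fragments=n,
                        fragment_dist="fixed", fragment_mean=60, circular=True)
        name, genome, _ = simulate_genome(cfg)
        _, _, truth = simulate_reads(genome, cfg)
        sam = tmp_path / f"el{seed}.sam"
        simulate_truth_sam(name, 2000, truth, sam, "elongated", k=500)
        return name, genome, truth, sam

    def test_record_count_and_positions(self, tmp_path):
        name, genome, truth, sam = self._sim(31, tmp_path)
        out = tmp_path / "rw.sam"
        stats = process_sam(sam, out, CircularReference(name, 2000, 500))
        junctions = sum(1 for f in truth.fragments if f.spans_origin)
        header, records = read_sam(out)
        records = list(records)
        assert header["SQ"][0]["LN"] == 2000
        assert stats.junction == junctions
        assert len(records) == len(truth.fragments) + junctions
        for r in records:
            assert 1 <= r.pos and r.end <= 2000
        positions = [r.pos for r in records]
        assert positions == sorted(positions)

    def test_split_pairs_conserve_bases(self, tmp_path):
        name, genome, truth, sam = self._sim(32, tmp_path)
        out = tmp_path / "rw.sam"
        process_sam(sam, out, CircularReference(name, 2000, 500))
        _, records = read_sam(out)
        halves: dict[str, dict[int, str]] = {}
        for r in records:
            if "XJ" in r.tags:
                halves.setdefault(r.read_id, {})[r.pos] = r.sequence
        by_id = {("M_" + f.fragment_id): f for f in truth.fragments}
        assert halves  # some junction reads exist at this density
        for rid, parts in halves.items():
            frag = by_id[rid]
            left = parts[frag.origin]
            right = parts[1]
            assert left + right == frag.sequence

    def test_header_mismatch_rejected(self, tmp_path):
        name, genome, truth, sam = self._sim(33, tmp_path, n=20)
        with pytest.raises(FormatError):
            process_sam(sam, tmp_path / "o.sam", CircularReference(name, 2000, 400))

    def test_no_junction_reads_passthrough(self, tmp_path):
        cfg = SimConfig(seed=34, genome_length=2000, n_fragments=50,
                        fragment_dist="fixed", fragment_mean=60, circular=False)
        name, genome, _ = simulate_genome(cfg)
        _, _, truth = simulate_reads(genome, cfg)
        sam = tmp_path / "lin_as_el.sam"
        simulate_truth_sam(name, 2000, truth, sam, "elongated", k=500)
        out = tmp_path / "rw.sam"
        stats = process_sam(sam, out, CircularReference(name, 2000, 500))
        assert stats.junction == 0
        assert stats.records_out == 50


def test_coverage_evenness_after_rewrite(tmp_path):
    """Uniform circular fragments: the rewritten coverage near the origin is
    statistically flat, while linear-mode coverage collapses at the ends."""
    L, flen, n = 5000, 60, 2000
    cfg = SimConfig(seed=41, genome_length=L, n_fragments=n,
                    fragment_dist="fixed", fragment_mean=flen, circular=True)
    name, genome, _ = simulate_genome(cfg)
    _, _, truth = simulate_reads(genome, cfg)
    sam_el = tmp_path / "el.sam"
    simulate_truth_sam(name, L, truth, sam_el, "elongated", k=500)
    out = tmp_path / "rw.sam"
    process_sam(sam_el, out, CircularReference(name, L, 500))
    _, records = read_sam(out)
    cov = np.zeros(L + 1)
    for r in records:
        cov[r.pos - 1] += 1
        cov[min(r.end, L)] -= 1
    cov = np.cumsum(cov[:L])
    mean = n * flen / L
    sd = np.sqrt(n * (flen / L) * (1 - flen / L))
    near = np.r_[cov[:200], cov[-200:]]
    assert np.all(np.abs(near - mean) <= 4 * sd)

    sam_lin = tmp_path / "lin.sam"
    simulate_truth_sam(name, L, truth, sam_lin, "linear")
    _, lin_records = read_sam(sam_lin)
    lcov = np.zeros(L + 1)
    for r in lin_records:
        lcov[r.pos - 1] += 1
        lcov[r.end] -= 1
    lcov = np.cumsum(lcov[:L])
    # linear coverage ramps down toward the ends (half the mean over the
    # terminal window); the rewritten coverage dominates it pointwise since
    # it restores the origin-spanning fragments
    assert lcov[: flen - 1].mean() < 0.75 * mean
    assert lcov[-(flen - 1):].mean() < 0.75 * mean
    assert np.all(cov >= lcov)
    assert cov[: flen - 1].sum() > lcov[: flen - 1].sum()
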