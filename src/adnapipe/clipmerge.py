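"""Adapter clipping and merging of overlapping paired-end reads.

Ancient-DNA fragments are frequently shorter than the read length, so both
mates read through the insert into the sequencing adapter (negative insert
size) and overlap each other over the whole fragment. This module removes
adapter sequence by local alignment against the read 3' end, then collapses
each overlapping pair into a single merged read spanning the original
fragment; pairs that do not overlap are quality-trimmed and kept as a pair.

Adapter search is a gapless Smith-Waterman-style alignment (match +1,
mismatch -1; the nominal gap penalty of -5 makes gapped adapter hits
unprofitable, so candidates are enumerated gaplessly). A qualifying hit must
either reach the read's 3' end (partial adapter at the end) or start at
adapter position 0 (full adapter inside the read, i.e. read-through); the
clip point is shifted 5'-ward by any unaligned adapter prefix so no adapter
bases survive.

The overlap search walks candidate overlap lengths from the maximum
possible down to ``min_merge_overlap`` and accepts the first (therefore
maximal) overlap whose mismatch count, counting only positions where both
bases are confidently called, stays below the configured fraction of the
overlap length.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Iterable, Iterator, Optional

from .io import Mate, MERGED_PREFIX, ReadRecord, reverse_complement, read_fastq, write_fastq

# canonical Illumina TruSeq adapters, the common default for aDNA libraries
DEFAULT_ADAPTER_FWD = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
DEFAULT_ADAPTER_REV = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTA"


@dataclass
class ClipMergeConfig:
    adapter_fwd: str = DEFAULT_ADAPTER_FWD
    adapter_rev: str = DEFAULT_ADAPTER_REV
    min_adapter_overlap: int = 8
    max_adapter_mismatches: int = 1
    min_merge_overlap: int = 10
    max_overlap_edit_fraction: float = 0.05
    max_overlap_edits: Optional[int] = None  # absolute-count alternative
    low_quality_cutoff: int = 20
    trim_quality: int = 20
    min_read_length: int = 25
    sw_match: int = 1
    sw_mismatch: int = -1
    sw_gap: int = -5

    def __post_init__(self) -> None:
        if self.min_adapter_overlap < 1:
            raise ValueError("min_adapter_overlap must be >= 1")
        if self.min_merge_overlap < 1:
            raise ValueError("min_merge_overlap must be >= 1")
        if not 0.0 <= self.max_overlap_edit_fraction <= 1.0:
            raise ValueError("max_overlap_edit_fraction must be in [0, 1]")


@dataclass
class AdapterAlignment:
    """Accepted gapless adapter hit; ``clip_from`` is where clipping starts."""

    read_start: int  # 0-based index in the read
    adapter_start: int  # 0-based index in the adapter
    length: int
    mismatches: int
    score: int

    @property
    def clip_from(self) -> int:
        # unaligned adapter prefix shifts the clip point toward the 5' end
        return max(0, self.read_start - self.adapter_start)


class MergeStatus(str, Enum):
    MERGED = "merged"
    UNMERGED = "unmerged"
    BOTH_DISCARDED = "both_discarded"


@dataclass
class MergeResult:
    status: MergeStatus
    merged_read: Optional[ReadRecord] = None
    overlap_length: int = 0
    overlap_edit_distance: int = 0


@dataclass
class ClipMergeStats:
    pairs_in: int = 0
    merged: int = 0
    merged_discarded: int = 0
    unmerged_pairs: int = 0
    discarded_reads: int = 0

    @property
    def reads_out(self) -> int:
        return self.merged + 2 * self.unmerged_pairs

    def to_dict(self) -> dict:
        d = asdict(self)
        d["reads_out"] = self.reads_out
        return d


def _best_anchored(seq: str, adapter: str, read_start: int, adapter_start: int,
                   step: int, cfg: ClipMergeConfig) -> Optional[AdapterAlignment]:
    """Best gapless segment anchored at (read_start, adapter_start), walking
    forward (step=+1) or backward (step=-1); at most max mismatches."""
    n, m = len(seq), len(adapter)
    best: Optional[AdapterAlignment] = None
    score = 0
    mism = 0
    length = 0
    i, j = read_start, adapter_start
    while 0 <= i < n and 0 <= j < m:
        if seq[i] == adapter[j]:
            score += cfg.sw_match
        else:
            mism += 1
            if mism > cfg.max_adapter_mismatches:
                break
            score += cfg.sw_mismatch
        length += 1
        if length >= cfg.min_adapter_overlap:
            rs = min(read_start, i)
            as_ = min(adapter_start, j)
            cand = AdapterAlignment(rs, as_, length, mism, score)
            if best is None or (cand.score, cand.length, -cand.clip_from) > (
                best.score, best.length, -best.clip_from
            ):
                best = cand
        i += step
        j += step
    return best


def align_adapter(read: ReadRecord, adapter: str,
                  config: ClipMergeConfig) -> Optional[AdapterAlignment]:
    """Best qualifying adapter hit in the read, or None.

    Candidates are anchored either at the read's last base (3'-terminal
    partial adapter; any adapter offset) or at adapter position 0 (adapter
    appearing in full starting anywhere in the read). The highest-scoring
    candidate wins; ties prefer the longer hit, then the smaller clip point.
    """
    seq = read.sequence.upper()
    adapter = adapter.upper()
    n, m = len(seq), len(adapter)
    if n == 0 or m == 0:
        return None
    best: Optional[AdapterAlignment] = None

    def consider(cand: Optional[AdapterAlignment]) -> None:
        nonlocal best
        if cand is None:
            return
        if best is None or (cand.score, cand.length, -cand.clip_from) > (
            best.score, best.length, -best.clip_from
        ):
            best = cand

    # anchored at the read's 3' end, for every adapter offset of the last base
    for j in range(m):
        consider(_best_anchored(seq, adapter, n - 1, j, -1, config))
    # anchored at adapter start, for every read position
    for p in range(n):
        consider(_best_anchored(seq, adapter, p, 0, +1, config))
    return best


def clip_read(read: ReadRecord, aln: Optional[AdapterAlignment]) -> ReadRecord:
    """Remove every base from the (shifted) alignment start to the read end."""
    if aln is None:
        return read
    c = aln.clip_from
    return ReadRecord(read.read_id, read.sequence[:c], read.qualities[:c], read.mate)


def _edit_distance(fo: str, ro: str, fq: list[int], rq: list[int], cutoff: int) -> int:
    """Mismatches over the overlap; a base below the quality cutoff (or 'N')
    is undefined and never contributes."""
    d = 0
    for a, b, qa, qb in zip(fo, ro, fq, rq):
        if qa < cutoff or qb < cutoff or a == "N" or b == "N":
            continue
        if a != b:
            d += 1
    return d


def merge_pair(fwd: ReadRecord, rev: ReadRecord, config: ClipMergeConfig) -> MergeResult:
    """Collapse an overlapping pair into one read, or report it unmergeable.

    Overlaps between the forward read's 3' end and the reverse-complemented
    reverse read's 5' end are tried from the longest possible down to
    ``min_merge_overlap``; the first acceptable one (edit distance strictly
    below ceil(fraction x overlap length), or zero) is taken. Per overlap
    position the higher-quality base wins with quality max(q_F, q_R); on a
    quality tie the forward base is kept.
    """
    if len(fwd) == 0 or len(rev) == 0:
        return MergeResult(MergeStatus.UNMERGED)
    rrc = reverse_complement(rev.sequence)
    rrq = rev.qualities[::-1]
    f, fq = fwd.sequence, fwd.qualities
    max_olen = min(len(f), len(rrc))
    for olen in range(max_olen, config.min_merge_overlap - 1, -1):
        fo = f[len(f) - olen :]
        foq = fq[len(f) - olen :]
        ro = rrc[:olen]
        roq = rrq[:olen]
        dist = _edit_distance(fo, ro, foq, roq, config.low_quality_cutoff)
        if config.max_overlap_edits is not None:
            ok = dist <= config.max_overlap_edits
        else:
            ok = dist == 0 or dist < math.ceil(config.max_overlap_edit_fraction * olen)
        if not ok:
            continue
        cons_seq = []
        cons_qual = []
        for a, b, qa, qb in zip(fo, ro, foq, roq):
            if qb > qa:
                cons_seq.append(b)
            else:
                cons_seq.append(a)
            cons_qual.append(max(qa, qb))
        merged_seq = f[: len(f) - olen] + "".join(cons_seq) + rrc[olen:]
        merged_qual = fq[: len(f) - olen] + cons_qual + rrq[olen:]
        base_id = strip_mate_suffix(fwd.read_id)
        merged = ReadRecord(MERGED_PREFIX + base_id, merged_seq, merged_qual, Mate.MERGED)
        assert len(merged) == len(fwd) + len(rev) - olen
        return MergeResult(MergeStatus.MERGED, merged, olen, dist)
    return MergeResult(MergeStatus.UNMERGED)


def trim_quality(read: ReadRecord, threshold: int) -> ReadRecord:
    """Strip the longest 3' suffix of bases with quality below threshold."""
    end = len(read)
    while end > 0 and read.qualities[end - 1] < threshold:
        end -= 1
    if end == len(read):
        return read
    return ReadRecord(read.read_id, read.sequence[:end], read.qualities[:end], read.mate)


def strip_mate_suffix(read_id: str) -> str:
    base = read_id.split()[0]
    if base.endswith("/1") or base.endswith("/2"):
        base = base[:-2]
    return base


def process_pair(fwd: ReadRecord, rev: ReadRecord, config: ClipMergeConfig
                 ) -> tuple[MergeResult, Optional[tuple[ReadRecord, ReadRecord]]]:
    """Clip both mates, attempt the merge, quality-trim leftovers.

    Returns the MergeResult and, when the pair stays unmerged and both
    trimmed mates pass the length filter, the trimmed pair.
    """
    fc = clip_read(fwd, align_adapter(fwd, config.adapter_fwd, config))
    rc = clip_read(rev, align_adapter(rev, config.adapter_rev, config))
    res = merge_pair(fc, rc, config)
    if res.status is MergeStatus.MERGED:
        if len(res.merged_read) < config.min_read_length:
            return MergeResult(MergeStatus.BOTH_DISCARDED,
                               overlap_length=res.overlap_length,
                               overlap_edit_distance=res.overlap_edit_distance), None
        return res, None
    ft = trim_quality(fc, config.trim_quality)
    rt = trim_quality(rc, config.trim_quality)
    if len(ft) < config.min_read_length or len(rt) < config.min_read_length:
        return MergeResult(MergeStatus.BOTH_DISCARDED), None
    return res, (ft, rt)


def process_pairs(fastq_fwd, fastq_rev, config: ClipMergeConfig,
                  out_merged=None, out_unmerged1=None, out_unmerged2=None
                  ) -> tuple[list[ReadRecord], list[tuple[ReadRecord, ReadRecord]], ClipMergeStats]:
    """Run clip+merge over two record-synchronised FASTQ files.

    Output order equals input order. When output paths are given the
    merged/unmerged FASTQ files are written as a side effect; the records
    are returned either way together with the run statistics.
    """
    stats = ClipMergeStats()
    merged_out: list[ReadRecord] = []
    unmerged_out: list[tuple[ReadRecord, ReadRecord]] = []
    fwd_iter = read_fastq(fastq_fwd, Mate.FORWARD)
    rev_iter = read_fastq(fastq_rev, Mate.REVERSE)
    for i, (fwd, rev) in enumerate(_zip_strict(fwd_iter, rev_iter), start=1):
        if strip_mate_suffix(fwd.read_id) != strip_mate_suffix(rev.read_id):
            raise ValueError(
                f"mate files desynchronised at pair {i}: "
                f"{fwd.read_id!r} vs {rev.read_id!r}"
            )
        stats.pairs_in += 1
        res, pair = process_pair(fwd, rev, config)
        if res.status is MergeStatus.MERGED:
            stats.merged += 1
            merged_out.append(res.merged_read)
        elif pair is not None:
            stats.unmerged_pairs += 1
            unmerged_out.append(pair)
        else:
            stats.discarded_reads += 2
            if res.overlap_length:
                stats.merged_discarded += 1
    if out_merged is not None:
        write_fastq(out_merged, merged_out)
    if out_unmerged1 is not None:
        write_fastq(out_unmerged1, (p[0] for p in unmerged_out))
    if out_unmerged2 is not None:
        write_fastq(out_unmerged2, (p[1] for p in unmerged_out))
    return merged_out, unmerged_out, stats


def _zip_strict(a: Iterator, b: Iterator) -> Iterator:
    while True:
        ra = next(a, None)
        rb = next(b, None)
        if ra is None and rb is None:
            return
        if ra is None or rb is None:
            raise ValueError("mate files have unequal record counts")
        yield ra, rb


def write_stats(stats: ClipMergeStats, json_path=None, text_path=None,
                sample_name: Optional[str] = None) -> dict:
    d = stats.to_dict()
    if sample_name is not None:
        d["sample_name"] = sample_name
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(d, fh, indent=2)
            fh.write("\n")
    if text_path is not None:
        with open(text_path, "w") as fh:
            for k, v in d.items():
                fh.write(f"{k}={v}\n")
    return d
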