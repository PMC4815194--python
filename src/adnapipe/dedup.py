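"""PCR duplicate removal aware of both fragment endpoints.

Amplified ancient-DNA libraries contain many PCR copies of each original
molecule. For merged (collapsed) reads the whole fragment is sequenced, so
two reads are copies of the same molecule only when they share *both* the
start and the end coordinate; 5'-only schemes (samtools rmdup style)
collapse distinct fragments that merely share a start. Within each
identical fragment key the record with the highest sum of base qualities
is kept; ties keep the first record in file order. Unmerged reads fall
back to the single-end 5'-per-strand convention.

The sweep over a coordinate-sorted file is windowed: a key group is
decided once the sweep position has passed the group's closing coordinate
(its start for both-end and forward 5' keys; its end for reverse-strand 5'
keys), so memory stays bounded by the local pile-up depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from enum import Enum
from typing import Iterable, Iterator, Optional

from .io import AlignmentRecord, MERGED_PREFIX


class KeyMode(str, Enum):
    BOTH_ENDS = "both_ends"
    FIVE_PRIME_ONLY = "five_prime_only"


class MergedPolicy(str, Enum):
    AUTO = "auto"  # merged iff the read id carries the clip+merge marker
    ALL_MERGED = "all_merged"
    ALL_UNMERGED = "all_unmerged"


@dataclass(frozen=True)
class FragmentKey:
    ref_name: str
    start: int
    end: int
    strand: str
    keyed_mode: KeyMode

    @property
    def close_coord(self) -> int:
        """Sweep position after which no further member can appear."""
        if self.keyed_mode is KeyMode.BOTH_ENDS or self.strand == "+":
            return self.start
        return self.end  # reverse 5' keys stay open until their end passes


@dataclass
class DedupStats:
    total_mapped_in: int = 0
    removed: int = 0
    kept: int = 0

    @property
    def duplication_rate(self) -> float:
        return self.removed / self.total_mapped_in if self.total_mapped_in else 0.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["duplication_rate"] = self.duplication_rate
        return d


def is_merged(aln: AlignmentRecord, policy: MergedPolicy = MergedPolicy.AUTO) -> bool:
    if policy is MergedPolicy.ALL_MERGED:
        return True
    if policy is MergedPolicy.ALL_UNMERGED:
        return False
    return aln.read_id.startswith(MERGED_PREFIX)


def fragment_key(aln: AlignmentRecord,
                 policy: MergedPolicy = MergedPolicy.AUTO) -> FragmentKey:
    """Duplicate key of one mapped record.

    Merged reads key on (start, end, strand); unmerged reads on the
    strand's 5' coordinate only (start on +, end on -), with the unused
    coordinate zeroed so it cannot distinguish records.
    """
    strand = "-" if aln.is_reverse else "+"
    start, end = aln.pos, aln.end
    if is_merged(aln, policy):
        return FragmentKey(aln.ref_name, start, end, strand, KeyMode.BOTH_ENDS)
    if strand == "+":
        return FragmentKey(aln.ref_name, start, 0, strand, KeyMode.FIVE_PRIME_ONLY)
    return FragmentKey(aln.ref_name, 0, end, strand, KeyMode.FIVE_PRIME_ONLY)


def quality_sum(aln: AlignmentRecord) -> int:
    """Sum of per-base Phred scores; 0 when qualities are absent ('*')."""
    return sum(aln.qualities) if aln.qualities else 0


def dedup_stream(records: Iterable[AlignmentRecord],
                 policy: MergedPolicy = MergedPolicy.AUTO,
                 ref_order: Optional[dict[str, int]] = None,
                 stats: Optional[DedupStats] = None
                 ) -> Iterator[AlignmentRecord]:
    """Yield the surviving records of a coordinate-sorted stream, in order.

    Unmapped, secondary and supplementary records pass through unexamined.
    Raises on the first out-of-order record.
    """
    if stats is None:
        stats = DedupStats()
    # buffer of (record, key-or-None); winners maps key -> (qsum, buffer seq no)
    buffer: list[tuple[int, AlignmentRecord, Optional[FragmentKey]]] = []
    winners: dict[FragmentKey, tuple[int, int]] = {}
    seq_no = 0
    cur_ref: Optional[str] = None
    cur_pos = 0

    def flush(upto_ref: Optional[str], upto_pos: int) -> Iterator[AlignmentRecord]:
        # emit buffered records whose group can no longer grow
        while buffer:
            _, rec, key = buffer[0]
            if key is not None and rec.ref_name == upto_ref and key.close_coord >= upto_pos:
                break
            n, rec, key = buffer.pop(0)
            if key is None:
                yield rec
                continue
            if winners[key][1] == n:
                stats.kept += 1
                yield rec
            else:
                stats.removed += 1

    for rec in records:
        examined = rec.is_mapped and rec.is_primary
        if examined:
            if rec.ref_name == cur_ref and rec.pos < cur_pos:
                raise ValueError(
                    f"input not coordinate-sorted: {rec.read_id!r} at "
                    f"{rec.ref_name}:{rec.pos} after position {cur_pos}"
                )
            if rec.ref_name != cur_ref:
                yield from flush(None, 0)
                winners.clear()
                cur_ref = rec.ref_name
            cur_pos = rec.pos
            yield from flush(cur_ref, cur_pos)
            stats.total_mapped_in += 1
            key = fragment_key(rec, policy)
            qs = quality_sum(rec)
            best = winners.get(key)
            if best is None or qs > best[0]:
                winners[key] = (qs, seq_no)
            buffer.append((seq_no, rec, key))
        else:
            buffer.append((seq_no, rec, None))
        seq_no += 1
    yield from flush(None, 0)


def dedup_records(records: Iterable[AlignmentRecord],
                  policy: MergedPolicy = MergedPolicy.AUTO
                  ) -> tuple[list[AlignmentRecord], DedupStats]:
    """Convenience wrapper materialising dedup_stream."""
    stats = DedupStats()
    kept = list(dedup_stream(records, policy, stats=stats))
    return kept, stats


def write_stats(stats: DedupStats, json_path, sample_name: Optional[str] = None) -> dict:
    d = stats.to_dict()
    if sample_name is not None:
        d["sample_name"] = sample_name
    with open(json_path, "w") as fh:
        json.dump(d, fh, indent=2)
        fh.write("\n")
    return d
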