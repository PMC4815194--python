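"""Circular-genome support: reference elongation and alignment rewriting.

Linear mappers cannot place reads across the artificial origin of a
circular chromosome (bacterial genomes, the mitochondrion), so coverage
collapses within a read length of both reference ends. The fix is to map
against an elongated reference — the genome plus its own first k bases
appended — and afterwards fold the alignments back onto unmodified
coordinates. Mapped reads fall into three classes, made disjoint by the
precedence JUNCTION > EDGE > INTERIOR:

* INTERIOR: contained in [k+1, L] — no change needed;
* EDGE: entirely inside the first k bases or entirely inside the
  elongation window (L+1, L+k]. The elongation window is an exact copy of
  the genome start, so records mapped there are translated back by L;
  records a mapper flagged ambiguous (MAPQ 0) solely because the window
  duplicates the genome start get their MAPQ restored;
* JUNCTION: starts at or before L and ends after L — spans the origin and
  is split into a primary record (left part, up to position L) plus a
  supplementary record (right part, starting at position 1).

Sequence is conserved by the split: concatenating a split pair's bases
reproduces the read. An insertion falling exactly on the junction stays
with the left part (it consumes no reference); a deletion crossing the
junction is truncated there and the event is counted.
"""

from __future__ import annotations

import enum
import sys
from dataclasses import dataclass
from typing import Optional

from .io import (
    AlignmentRecord,
    FLAG_SUPPLEMENTARY,
    FormatError,
    format_cigar,
    parse_cigar,
    read_fasta,
    read_sam,
    write_fasta,
    write_sam,
)

DEFAULT_ELONGATION = 500
DEFAULT_RESTORED_MAPQ = 37

JUNCTION_TAG = "XJ"  # shared by both halves of a split read


@dataclass
class CircularReference:
    """A circular target: unmodified length L plus elongation k."""

    name: str
    length: int  # L
    elongation: int  # k

    def __post_init__(self) -> None:
        if not 1 <= self.elongation <= self.length:
            raise ValueError(
                f"elongation k={self.elongation} must satisfy 1 <= k <= L={self.length}"
            )


class ReadCategory(str, enum.Enum):
    INTERIOR = "interior"
    EDGE = "edge"
    JUNCTION = "junction"


@dataclass
class RewriteStats:
    interior: int = 0
    edge: int = 0
    junction: int = 0
    junction_deletions: int = 0
    records_out: int = 0


def elongate_reference(fasta_in, fasta_out, target_name: str, k: int,
                       sidecar_out=None, max_read_length: Optional[int] = None
                       ) -> CircularReference:
    """Append the target's first k bases to its end; other sequences pass through.

    Writes the elongated FASTA and a 3-column sidecar (name, L, k) that the
    rewrite step needs to undo the elongation.
    """
    if k < 1:
        raise ValueError("elongation k must be >= 1")
    seqs = read_fasta(fasta_in)
    names = [n for n, _ in seqs]
    if target_name not in names:
        raise ValueError(f"target sequence {target_name!r} not in reference ({names})")
    circ: Optional[CircularReference] = None
    out = []
    for name, seq in seqs:
        if name == target_name:
            if k > len(seq):
                raise ValueError(f"k={k} exceeds target length {len(seq)}")
            if max_read_length is not None and k < max_read_length:
                print(
                    f"warning: k={k} is below the maximal read length "
                    f"{max_read_length}; junction reads longer than k cannot "
                    "be represented",
                    file=sys.stderr,
                )
            out.append((name, seq + seq[:k]))
            circ = CircularReference(name, len(seq), k)
        else:
            out.append((name, seq))
    write_fasta(fasta_out, out)
    if sidecar_out is not None:
        write_sidecar(sidecar_out, circ)
    return circ


def write_sidecar(path, circ: CircularReference) -> None:
    with open(path, "w") as fh:
        fh.write(f"{circ.name}\t{circ.length}\t{circ.elongation}\n")


def read_sidecar(path) -> CircularReference:
    with open(path) as fh:
        name, length, k = fh.readline().split("\t")
    return CircularReference(name, int(length), int(k))


def categorize(aln: AlignmentRecord, L: int, k: int) -> ReadCategory:
    """Classify a record mapped to the elongated target (precedence
    JUNCTION > EDGE > INTERIOR)."""
    pos, end = aln.pos, aln.end
    if end > L + k:
        raise FormatError(
            f"record {aln.read_id!r} ends at {end}, beyond elongated length {L + k}"
        )
    if pos <= L < end:
        return ReadCategory.JUNCTION
    if pos > L or end <= k:
        return ReadCategory.EDGE
    return ReadCategory.INTERIOR


def _split_cigar_at(cigar: str, ref_left: int
                    ) -> tuple[list, list, int, int, bool, int]:
    """Split a CIGAR after ``ref_left`` reference bases.

    Returns (left_ops, right_ops, query_left, right_offset, del_event,
    right_ref_span). Insertions at the boundary stay with the left part
    (they consume no reference). A deletion at or crossing the boundary is
    truncated there: its portion past the junction becomes a start offset
    for the right record instead of an illegal leading-D CIGAR, and the
    event is flagged for logging.
    """
    left: list[tuple[int, str]] = []
    right: list[tuple[int, str]] = []
    remaining = ref_left
    query_left = 0
    right_offset = 0
    del_event = False
    for n, op in parse_cigar(cigar):
        consumes_ref = op in "MDN=X"
        consumes_query = op in "MIS=X"
        if remaining > 0:
            if not consumes_ref:
                left.append((n, op))
                if consumes_query:
                    query_left += n
                continue
            if n <= remaining:
                left.append((n, op))
                remaining -= n
                if consumes_query:
                    query_left += n
            else:
                take = remaining
                rest = n - take
                remaining = 0
                left.append((take, op))
                if consumes_query:
                    query_left += take
                    right.append((rest, op))
                else:
                    right_offset += rest
                    del_event = True
        else:
            if not right:
                if op == "I" or op == "S":
                    left.append((n, op))  # boundary insertion/clip stays left
                    query_left += n
                    continue
                if op in "DN":
                    right_offset += n  # deletion starting on the junction
                    del_event = True
                    continue
            right.append((n, op))
    right_span = sum(n for n, op in right if op in "MDN=X")
    return left, right, query_left, right_offset, del_event, right_span


def rewrite(aln: AlignmentRecord, L: int, k: int,
            restored_mapq: int = DEFAULT_RESTORED_MAPQ,
            stats: Optional[RewriteStats] = None) -> list[AlignmentRecord]:
    """Rewrite one record from elongated onto unmodified coordinates."""
    if stats is None:
        stats = RewriteStats()
    cat = categorize(aln, L, k)
    if cat is ReadCategory.INTERIOR:
        stats.interior += 1
        return [aln]
    if cat is ReadCategory.EDGE:
        stats.edge += 1
        out = AlignmentRecord(
            read_id=aln.read_id, flags=aln.flags, ref_name=aln.ref_name,
            pos=aln.pos - L if aln.pos > L else aln.pos,
            mapq=restored_mapq if aln.mapq == 0 else aln.mapq,
            cigar=aln.cigar, sequence=aln.sequence, qualities=aln.qualities,
            tags=dict(aln.tags), rnext=aln.rnext, pnext=aln.pnext, tlen=aln.tlen,
        )
        return [out]
    # JUNCTION: split after L - pos + 1 reference bases
    stats.junction += 1
    left_ops, right_ops, qleft, right_offset, del_event, right_span = _split_cigar_at(
        aln.cigar, L - aln.pos + 1
    )
    if del_event:
        stats.junction_deletions += 1
    tags = dict(aln.tags)
    tags[JUNCTION_TAG] = aln.read_id
    left = AlignmentRecord(
        read_id=aln.read_id, flags=aln.flags, ref_name=aln.ref_name, pos=aln.pos,
        mapq=aln.mapq, cigar=format_cigar(left_ops),
        sequence=aln.sequence[:qleft],
        qualities=aln.qualities[:qleft] if aln.qualities is not None else None,
        tags=tags, rnext=aln.rnext, pnext=aln.pnext, tlen=aln.tlen,
    )
    if right_span == 0:
        return [left]
    right = AlignmentRecord(
        read_id=aln.read_id, flags=aln.flags | FLAG_SUPPLEMENTARY,
        ref_name=aln.ref_name, pos=1 + right_offset, mapq=aln.mapq,
        cigar=format_cigar(right_ops),
        sequence=aln.sequence[qleft:],
        qualities=aln.qualities[qleft:] if aln.qualities is not None else None,
        tags=dict(tags), rnext=aln.rnext, pnext=aln.pnext, tlen=aln.tlen,
    )
    return [left, right]


def process_sam(sam_in, sam_out, circ: CircularReference,
                restored_mapq: int = DEFAULT_RESTORED_MAPQ) -> RewriteStats:
    """Rewrite a whole SAM from elongated to unmodified coordinates.

    The header's target length must equal L + k and is rewritten to L;
    coordinate sort order is re-established (splitting moves right parts
    to position 1).
    """
    header, records = read_sam(sam_in)
    L, k = circ.length, circ.elongation
    sqs = header.get("SQ", [])
    target_sq = next((sq for sq in sqs if sq.get("SN") == circ.name), None)
    if target_sq is None:
        raise FormatError(f"header lacks @SQ for target {circ.name!r}")
    if target_sq["LN"] != L + k:
        raise FormatError(
            f"header length {target_sq['LN']} for {circ.name!r} does not match "
            f"sidecar L+k={L + k}"
        )
    new_header = dict(header)
    new_header["SQ"] = [dict(sq) for sq in sqs]
    for sq in new_header["SQ"]:
        if sq["SN"] == circ.name:
            sq["LN"] = L
    stats = RewriteStats()
    out: list[AlignmentRecord] = []
    for aln in records:
        if aln.is_mapped and aln.ref_name == circ.name:
            out.extend(rewrite(aln, L, k, restored_mapq, stats))
        else:
            out.append(aln)
    order = {sq["SN"]: i for i, sq in enumerate(new_header["SQ"])}
    coord_sorted = header.get("HD", {}).get("SO") == "coordinate"
    if coord_sorted:
        out.sort(key=lambda a: (a.ref_name is None, order.get(a.ref_name, 0), a.pos))
    for a in out:
        if a.is_mapped and a.ref_name == circ.name and a.end > L:
            raise FormatError(f"rewritten record {a.read_id!r} extends past L={L}")
    stats.records_out = write_sam(sam_out, new_header, out)
    return stats
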