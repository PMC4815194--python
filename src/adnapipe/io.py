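"""Streaming readers and writers for FASTQ, FASTA, SAM and VCF.

All coordinates are 1-based inclusive, as in the SAM and VCF standards.
FASTQ qualities are Phred+33 only; SAM text (not BAM) is the contract
surface so every file in the pipeline stays diffable and bit-exact.
Parsing of SAM and VCF records is delegated to pysam; FASTA/FASTQ to
Biopython. The dataclasses below are the in-memory currency shared by
every stage.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Iterator, Optional

import pysam
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

MAX_PHRED = 93

# read-id prefix marking a merged (collapsed) read; dedup keys on it
MERGED_PREFIX = "M_"

FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Mate(str, Enum):
    FORWARD = "forward"
    REVERSE = "reverse"
    MERGED = "merged"
    SINGLE = "single"


class FormatError(ValueError):
    """Raised for malformed input files; the message names the offending record."""


@dataclass
class ReadRecord:
    """One sequencing read: id, bases and per-base Phred scores."""

    read_id: str
    sequence: str
    qualities: list[int]
    mate: Mate = Mate.SINGLE

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise FormatError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        for q in self.qualities:
            if not 0 <= q <= MAX_PHRED:
                raise FormatError(f"read {self.read_id!r}: quality {q} outside [0, {MAX_PHRED}]")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AlignmentRecord:
    """One SAM alignment line (mapped or unmapped)."""

    read_id: str
    flags: int
    ref_name: Optional[str]
    pos: int  # 1-based leftmost mapped position; 0 for unmapped
    mapq: int
    cigar: Optional[str]
    sequence: str
    qualities: Optional[list[int]]
    tags: dict[str, object] = field(default_factory=dict)
    rnext: Optional[str] = None
    pnext: int = 0
    tlen: int = 0

    @property
    def is_mapped(self) -> bool:
        return not self.flags & FLAG_UNMAPPED

    @property
    def is_reverse(self) -> bool:
        return bool(self.flags & FLAG_REVERSE)

    @property
    def is_primary(self) -> bool:
        return not self.flags & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY)

    @property
    def reference_span(self) -> int:
        """Reference bases consumed by the CIGAR (M/D/N/=/X)."""
        if self.cigar is None:
            return 0
        return sum(n for n, op in parse_cigar(self.cigar) if op in "MDN=X")

    @property
    def end(self) -> int:
        """1-based inclusive rightmost reference position."""
        return self.pos + self.reference_span - 1


@dataclass
class SiteCall:
    """One genotyped position extracted from an all-sites VCF."""

    ref_name: str
    pos: int
    ref_allele: str
    alt_allele: Optional[str]
    qual: float
    depth: int
    ref_support: int
    alt_support: int
    is_indel: bool = False


_CIGAR_OPS = "MIDNSHP=X"


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """CIGAR string -> list of (length, op)."""
    out: list[tuple[int, str]] = []
    n = 0
    for c in cigar:
        if c.isdigit():
            n = n * 10 + ord(c) - 48
        elif c in _CIGAR_OPS:
            if n == 0:
                raise FormatError(f"zero-length CIGAR op in {cigar!r}")
            out.append((n, c))
            n = 0
        else:
            raise FormatError(f"bad CIGAR {cigar!r}")
    if n:
        raise FormatError(f"trailing digits in CIGAR {cigar!r}")
    return out


def format_cigar(ops: Iterable[tuple[int, str]]) -> str:
    return "".join(f"{n}{op}" for n, op in ops)


def _open_text(path, mode: str = "rt") -> IO[str]:
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTQ

def read_fastq(source, mate: Mate = Mate.SINGLE) -> Iterator[ReadRecord]:
    """Yield ReadRecords from a FASTQ path or text handle (``.gz`` accepted).

    Streaming: one record is materialised at a time. Qualities are decoded
    as Phred+33; characters outside ``!``..``~`` (or above Phred 93) are
    rejected, which also catches files with broken encodings.
    """
    handle = _open_text(source) if isinstance(source, (str, os.PathLike)) else source
    own = handle is not source
    try:
        idx = 0
        for title, seq, qual in FastqGeneralIterator(handle):
            idx += 1
            if len(seq) != len(qual):
                raise FormatError(
                    f"FASTQ record {idx} ({title.split()[0]}): "
                    f"sequence/quality length mismatch"
                )
            quals = []
            for ch in qual:
                q = ord(ch) - 33
                if not 0 <= q <= MAX_PHRED:
                    raise FormatError(
                        f"FASTQ record {idx}: quality character {ch!r} outside Phred+33 range"
                    )
                quals.append(q)
            yield ReadRecord(title.split()[0], seq.upper(), quals, mate)
    except ValueError as exc:  # Biopython raises ValueError on truncation
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"malformed FASTQ near record {idx + 1}: {exc}") from exc
    finally:
        if own:
            handle.close()


def write_fastq(dest, reads: Iterable[ReadRecord]) -> int:
    handle = _open_text(dest, "wt") if isinstance(dest, (str, os.PathLike)) else dest
    own = handle is not dest
    n = 0
    try:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            handle.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")
            n += 1
    finally:
        if own:
            handle.close()
    return n


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(source) -> list[tuple[str, str]]:
    """Return [(name, sequence), ...] in file order (uppercased)."""
    handle = _open_text(source) if isinstance(source, (str, os.PathLike)) else source
    own = handle is not source
    try:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]
    finally:
        if own:
            handle.close()


def write_fasta(dest, sequences: Iterable[tuple[str, str]], width: int = 60) -> None:
    handle = _open_text(dest, "wt") if isinstance(dest, (str, os.PathLike)) else dest
    own = handle is not dest
    try:
        for name, seq in sequences:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
    finally:
        if own:
            handle.close()


# ---------------------------------------------------------------------------
# SAM

def _from_pysam(seg: pysam.AlignedSegment) -> AlignmentRecord:
    quals = list(seg.query_qualities) if seg.query_qualities is not None else None
    return AlignmentRecord(
        read_id=seg.query_name,
        flags=seg.flag,
        ref_name=seg.reference_name if seg.reference_id >= 0 else None,
        pos=seg.reference_start + 1 if seg.reference_start >= 0 else 0,
        mapq=seg.mapping_quality,
        cigar=seg.cigarstring,
        sequence=seg.query_sequence or "",
        qualities=quals,
        tags={k: v for k, v, in seg.get_tags()},
        rnext=seg.next_reference_name if seg.next_reference_id >= 0 else None,
        pnext=seg.next_reference_start + 1 if seg.next_reference_start >= 0 else 0,
        tlen=seg.template_length,
    )


def _to_pysam(rec: AlignmentRecord, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = rec.read_id
    seg.flag = rec.flags
    seg.reference_id = header.get_tid(rec.ref_name) if rec.ref_name else -1
    seg.reference_start = rec.pos - 1 if rec.pos >= 1 else -1
    seg.mapping_quality = rec.mapq
    seg.cigarstring = rec.cigar
    seg.query_sequence = rec.sequence or None
    if rec.qualities is not None:
        seg.query_qualities = rec.qualities
    if rec.rnext is not None:
        seg.next_reference_id = header.get_tid(rec.rnext)
    seg.next_reference_start = rec.pnext - 1 if rec.pnext >= 1 else -1
    seg.template_length = rec.tlen
    for key, val in rec.tags.items():
        seg.set_tag(key, val)
    return seg


def read_sam(path) -> tuple[dict, Iterator[AlignmentRecord]]:
    """Return ``(header_dict, record_iterator)`` for a SAM text file.

    A mapped record whose reference is absent from the @SQ header lines is
    rejected by the underlying parser, satisfying the missing-@SQ contract.
    """
    af = pysam.AlignmentFile(os.fspath(path), "r")
    header = af.header.to_dict()

    def gen() -> Iterator[AlignmentRecord]:
        with af:
            for seg in af:
                yield _from_pysam(seg)

    return header, gen()


def write_sam(path, header: dict, records: Iterable[AlignmentRecord]) -> int:
    n = 0
    with pysam.AlignmentFile(os.fspath(path), "wh", header=header) as out:
        for rec in records:
            out.write(_to_pysam(rec, out.header))
            n += 1
    return n


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path) -> Iterator[SiteCall]:
    """Yield one SiteCall per VCF row.

    Allele supports come from the per-sample AD field; if absent, from INFO
    DP4 (ref = fields 1+2, alt = 3+4). A site with neither is an error. At
    multi-allelic sites the alt with the highest support is kept. Indel rows
    are flagged (``is_indel``) so downstream code can skip them.
    """
    with pysam.VariantFile(os.fspath(path)) as vf:
        for row in vf:
            ref = row.ref
            alts = [a for a in (row.alts or []) if a is not None and a != "<*>"]
            ad = None
            if row.samples:
                sample = row.samples[0]
                if "AD" in sample and sample["AD"] is not None and sample["AD"][0] is not None:
                    ad = list(sample["AD"])
            if ad is not None:
                ref_support = int(ad[0])
                alt_supports = [int(x) for x in ad[1 : 1 + len(alts)]]
            elif "DP4" in row.info:
                dp4 = list(row.info["DP4"])
                ref_support = int(dp4[0]) + int(dp4[1])
                alt_supports = [int(dp4[2]) + int(dp4[3])] if alts else []
            else:
                raise FormatError(
                    f"VCF site {row.chrom}:{row.pos} lacks AD and DP4; "
                    "cannot derive allele supports"
                )
            if alts and alt_supports:
                best = max(range(len(alt_supports)), key=lambda i: alt_supports[i])
                alt, alt_support = alts[best], alt_supports[best]
            else:
                alt, alt_support = None, 0
            depth = int(row.info["DP"]) if "DP" in row.info else ref_support + alt_support
            is_indel = len(ref) != 1 or (alt is not None and len(alt) != 1)
            yield SiteCall(
                ref_name=row.chrom,
                pos=row.pos,
                ref_allele=ref[0].upper(),
                alt_allele=alt.upper() if alt is not None and len(alt) == 1 else alt,
                qual=float(row.qual) if row.qual is not None else 0.0,
                depth=depth,
                ref_support=ref_support,
                alt_support=alt_support,
                is_indel=is_indel,
            )


def write_vcf(dest, contigs: list[tuple[str, int]], rows: Iterable[SiteCall]) -> int:
    """Emit a minimal all-sites VCF v4.2 with one sample carrying GT:AD."""
    handle = _open_text(dest, "wt") if isinstance(dest, (str, os.PathLike)) else dest
    own = handle is not dest
    n = 0
    try:
        handle.write("##fileformat=VCFv4.2\n")
        for name, length in contigs:
            handle.write(f"##contig=<ID={name},length={length}>\n")
        handle.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        handle.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        handle.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for s in rows:
            alt = s.alt_allele if s.alt_allele else "."
            if s.alt_allele:
                gt = "1/1" if s.alt_support >= s.ref_support else "0/1"
                ad = f"{s.ref_support},{s.alt_support}"
            else:
                gt = "0/0" if s.ref_support else "./."
                ad = f"{s.ref_support}"
            qual = f"{s.qual:g}"
            handle.write(
                f"{s.ref_name}\t{s.pos}\t.\t{s.ref_allele}\t{alt}\t{qual}\t.\t"
                f"DP={s.depth}\tGT:AD\t{gt}:{ad}\n"
            )
            n += 1
    finally:
        if own:
            handle.close()
    return n
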