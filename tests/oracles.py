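"""Independent brute-force oracles used to cross-check the implementation.

These deliberately favour clarity over speed (exhaustive enumeration,
all-pairs grouping) and share no code with the package paths they check.
"""

from __future__ import annotations

import math
import re
from math import ceil


def oracle_adapter_alignment(read: str, adapter: str, min_overlap: int,
                             max_mismatches: int):
    """Enumerate every gapless (read_start, adapter_start, length) segment,
    keep the qualifying anchored ones, return the best as a tuple
    (score, length, read_start, adapter_start, mismatches, clip_from)."""
    n, m = len(read), len(adapter)
    best = None
    for rs in range(n):
        for asub in range(m):
            max_len = min(n - rs, m - asub)
            for length in range(min_overlap, max_len + 1):
                seg_r = read[rs : rs + length]
                seg_a = adapter[asub : asub + length]
                mism = sum(1 for a, b in zip(seg_r, seg_a) if a != b)
                if mism > max_mismatches:
                    continue
                if not (rs + length == n or asub == 0):
                    continue  # anchoring rule
                score = (length - mism) - mism
                clip_from = max(0, rs - asub)
                cand = (score, length, -clip_from, rs, asub, mism)
                if best is None or cand[:3] > best[:3]:
                    best = cand
    if best is None:
        return None
    score, length, negclip, rs, asub, mism = best
    return {"score": score, "length": length, "read_start": rs,
            "adapter_start": asub, "mismatches": mism, "clip_from": -negclip}


def oracle_merge(f_seq: str, f_qual: list[int], rrc_seq: str, rrc_qual: list[int],
                 min_overlap: int, max_frac: float, cutoff: int):
    """Exhaustive overlap search, longest first; returns (olen, dist) or None."""
    for olen in range(min(len(f_seq), len(rrc_seq)), min_overlap - 1, -1):
        fo = f_seq[len(f_seq) - olen:]
        foq = f_qual[len(f_seq) - olen:]
        ro = rrc_seq[:olen]
        roq = rrc_qual[:olen]
        dist = 0
        for a, b, qa, qb in zip(fo, ro, foq, roq):
            if qa >= cutoff and qb >= cutoff and a != "N" and b != "N" and a != b:
                dist += 1
        if dist == 0 or dist < ceil(max_frac * olen):
            return olen, dist
    return None


_CIG_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def oracle_ref_span(cigar: str) -> int:
    return sum(int(n) for n, op in _CIG_RE.findall(cigar) if op in "MDN=X")


def oracle_dedup(rows):
    """All-pairs duplicate grouping over (read_id, flags, ref, pos, cigar,
    qualities, merged) tuples; returns the set of surviving row indices."""
    keys = []
    for i, r in enumerate(rows):
        strand = "-" if r["flags"] & 0x10 else "+"
        start = r["pos"]
        end = r["pos"] + oracle_ref_span(r["cigar"]) - 1
        if r["merged"]:
            key = ("both", r["ref"], start, end, strand)
        elif strand == "+":
            key = ("five", r["ref"], start, strand)
        else:
            key = ("five", r["ref"], end, strand)
        keys.append(key)
    survivors = set()
    for i in range(len(rows)):
        beaten = False
        for j in range(len(rows)):
            if i == j or keys[i] != keys[j]:
                continue
            qi = sum(rows[i]["quals"] or [])
            qj = sum(rows[j]["quals"] or [])
            if qj > qi or (qj == qi and j < i):
                beaten = True
        if not beaten:
            survivors.add(i)
    return survivors


def oracle_classify(qual, ref_support, alt_support, has_alt,
                    min_qual=30.0, min_depth=5, min_fraction=0.90):
    """Straight transcription of the draft-call cascade, written if-by-if."""
    total = ref_support + alt_support
    if total == 0 or qual < min_qual:
        return "no_call"
    alt_major = has_alt and alt_support > ref_support
    if not has_alt:
        alt_frac = 0.0
    elif alt_major and ref_support == 1:
        alt_frac = 1.0
    else:
        alt_frac = alt_support / total
    if (not alt_major) and alt_support == 1:
        ref_frac = 1.0
    else:
        ref_frac = ref_support / total
    if has_alt and alt_support >= min_depth and alt_frac >= min_fraction:
        return "confident_snp"
    if ref_support >= min_depth and ref_frac >= min_fraction:
        return "confident_ref"
    if has_alt and alt_frac >= min_fraction and alt_support < min_depth:
        return "weak_snp"
    if ref_support >= alt_support:
        return "weak_ref"
    return "no_call"
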