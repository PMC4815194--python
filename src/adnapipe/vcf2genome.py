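"""Draft-genome construction from an all-sites VCF.

Each reference position receives exactly one character per draft, decided
by a confidence cascade over call quality, supporting-read depth and
allele fraction (defaults: quality >= 30, support >= 5, fraction >= 90%).
To avoid flooding low-coverage genomes with "N" because of stray
sequencing errors, the major allele counts as confirmed by 100% of reads
when exactly one read supports the minor allele.

Three drafts are produced, all of exact reference length:

* strict      — called base, "N" where no confident call was possible;
* ref_filled  — strict with every "N" replaced by the reference base;
* encoded     — uncertainty encoding: lowercase a/c/g/t where the reads
  unambiguously indicate a SNP that was rejected (e.g. low coverage), "R"
  for an uncertain reference call, "N" otherwise.

Indel rows are skipped (drafts keep reference coordinates); at
multi-allelic sites the best-supported alt is evaluated. Positions absent
from the VCF are no-calls — an all-sites VCF is expected, and a loud
warning fires when more than half of the genome is absent.
"""

from __future__ import annotations

import json
import sys
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

from .io import SiteCall, read_fasta, read_vcf, write_fasta


@dataclass
class CallPolicy:
    min_qual: float = 30.0
    min_depth: int = 5
    min_fraction: float = 0.90

    def __post_init__(self) -> None:
        if self.min_qual < 0:
            raise ValueError("min_qual must be >= 0")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0.0 < self.min_fraction <= 1.0:
            raise ValueError("min_fraction must be in (0, 1]")


class CallClass(str, Enum):
    CONFIDENT_REF = "confident_ref"
    CONFIDENT_SNP = "confident_snp"
    WEAK_SNP = "weak_snp"
    WEAK_REF = "weak_ref"
    NO_CALL = "no_call"


@dataclass
class DraftSet:
    strict: str
    ref_filled: str
    encoded: str


def effective_fraction(site: SiteCall) -> Optional[tuple[float, str]]:
    """(major fraction, major allele) with the single-minor-read rule.

    The fraction is major support over usable reads; when exactly one read
    supports the minor allele the major allele counts as 100% confirmed.
    Returns None when no usable reads exist (a no-call signal). Ties go to
    the reference allele.
    """
    total = site.ref_support + site.alt_support
    if total == 0:
        return None
    if site.alt_support > site.ref_support:
        major, major_support, minor_support = (
            site.alt_allele, site.alt_support, site.ref_support)
    else:
        major, major_support, minor_support = (
            site.ref_allele, site.ref_support, site.alt_support)
    if minor_support == 1:
        return 1.0, major
    return major_support / total, major


def classify_site(site: SiteCall, policy: CallPolicy = CallPolicy()) -> CallClass:
    """Apply the confidence cascade to one site."""
    if site.is_indel:
        return CallClass.NO_CALL
    total = site.ref_support + site.alt_support
    if total == 0:
        return CallClass.NO_CALL
    if site.qual < policy.min_qual:
        return CallClass.NO_CALL
    # single-minor-read rule only lifts the major allele (ties go to ref)
    alt_major = site.alt_allele is not None and site.alt_support > site.ref_support
    if site.alt_allele is None:
        alt_frac = 0.0
    elif alt_major and site.ref_support == 1:
        alt_frac = 1.0
    else:
        alt_frac = site.alt_support / total
    if not alt_major and site.alt_support == 1:
        ref_frac = 1.0
    else:
        ref_frac = site.ref_support / total
    if (site.alt_allele and site.alt_support >= policy.min_depth
            and alt_frac >= policy.min_fraction):
        return CallClass.CONFIDENT_SNP
    if site.ref_support >= policy.min_depth and ref_frac >= policy.min_fraction:
        return CallClass.CONFIDENT_REF
    if (site.alt_allele and alt_frac >= policy.min_fraction
            and site.alt_support < policy.min_depth):
        return CallClass.WEAK_SNP
    if site.ref_support >= site.alt_support:
        return CallClass.WEAK_REF
    return CallClass.NO_CALL


def draft_characters(site: Optional[SiteCall], ref_base: str,
                     policy: CallPolicy = CallPolicy()
                     ) -> tuple[CallClass, str, str]:
    """(class, strict char, encoded char) for one position.

    ``site=None`` means the position is absent from the VCF.
    """
    if site is None:
        return CallClass.NO_CALL, "N", "N"
    cls = classify_site(site, policy)
    if cls is CallClass.CONFIDENT_SNP:
        return cls, site.alt_allele, site.alt_allele
    if cls is CallClass.CONFIDENT_REF:
        return cls, ref_base, ref_base
    if cls is CallClass.WEAK_SNP:
        return cls, "N", site.alt_allele.lower()
    if cls is CallClass.WEAK_REF:
        return cls, "N", "R"
    return cls, "N", "N"


def build_drafts(sites: Iterable[SiteCall], ref_name: str, ref_seq: str,
                 policy: CallPolicy = CallPolicy(),
                 warn_stream=sys.stderr) -> tuple[DraftSet, Counter]:
    """Build the three drafts for one reference sequence.

    ``sites`` may cover any subset of positions; coverage of the full
    genome (an all-sites VCF) is expected and a warning is emitted when
    more than 50% of positions are absent.
    """
    L = len(ref_seq)
    strict = ["N"] * L
    encoded = ["N"] * L
    counts: Counter = Counter({c: 0 for c in CallClass})
    seen = 0
    skipped_indels = 0
    for site in sites:
        if site.ref_name != ref_name:
            raise ValueError(
                f"VCF contig {site.ref_name!r} does not match reference {ref_name!r}"
            )
        if not 1 <= site.pos <= L:
            raise ValueError(f"VCF position {site.pos} exceeds contig length {L}")
        i = site.pos - 1
        if site.is_indel:
            skipped_indels += 1
            continue
        if site.ref_allele != ref_seq[i]:
            raise ValueError(
                f"VCF ref allele {site.ref_allele} at {site.pos} does not match "
                f"reference base {ref_seq[i]}"
            )
        seen += 1
        cls, s_char, e_char = draft_characters(site, ref_seq[i], policy)
        counts[cls] += 1
        strict[i] = s_char
        encoded[i] = e_char
    absent = L - seen
    counts[CallClass.NO_CALL] += absent
    if absent > L / 2 and warn_stream is not None:
        print(
            f"warning: {absent}/{L} positions absent from the VCF; an "
            "all-sites VCF is expected for draft construction",
            file=warn_stream,
        )
    strict_s = "".join(strict)
    ref_filled = "".join(
        ref_seq[i] if strict[i] == "N" else strict[i] for i in range(L)
    )
    drafts = DraftSet(strict_s, ref_filled, "".join(encoded))
    counts["skipped_indels"] = skipped_indels
    return drafts, counts


def run(vcf_path, ref_path, out_prefix, policy: CallPolicy = CallPolicy(),
        sample_name: Optional[str] = None) -> dict:
    """File-level driver: VCF + reference FASTA -> three draft FASTAs + counts."""
    refs = read_fasta(ref_path)
    if len(refs) != 1:
        raise ValueError("draft construction expects a single-sequence reference")
    ref_name, ref_seq = refs[0]
    drafts, counts = build_drafts(read_vcf(vcf_path), ref_name, ref_seq, policy)
    write_fasta(f"{out_prefix}.fasta", [(f"{ref_name}_draft", drafts.strict)])
    write_fasta(f"{out_prefix}_refmod.fasta", [(f"{ref_name}_refmod", drafts.ref_filled)])
    write_fasta(
        f"{out_prefix}_uncertainty.fasta", [(f"{ref_name}_uncertainty", drafts.encoded)]
    )
    summary = {
        (k.value if isinstance(k, CallClass) else k): v for k, v in counts.items()
    }
    summary["reference_length"] = len(ref_seq)
    if sample_name is not None:
        summary["sample_name"] = sample_name
    with open(f"{out_prefix}_classes.json", "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
    return summary
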