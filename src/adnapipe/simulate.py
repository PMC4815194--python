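"""Seeded generator of ancient-DNA-like truth sets.

Emulates the properties that make aDNA data hard: short fragments (far
below the read length, so paired reads overlap and read through into
adapter), PCR duplicate copies, terminal deamination damage (C->T at the
5' end, mirrored G->A at the 3' end, decaying geometrically with distance
from the terminus) and random substitution errors. Every emitted read is
tied to a truth row, so read merging, duplicate removal, circular-origin
rewriting and draft construction are all testable without external data.

Reproducibility: every output draws from its own RNG stream derived from
``(seed, stream name)``, so identical configs produce identical bytes and
adding a new output never perturbs an existing one.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .clipmerge import DEFAULT_ADAPTER_FWD, DEFAULT_ADAPTER_REV
from .io import (
    AlignmentRecord,
    Mate,
    ReadRecord,
    SiteCall,
    reverse_complement,
    write_fasta,
    write_fastq,
    write_sam,
    write_vcf,
)

BASES = "ACGT"


@dataclass
class SimConfig:
    genome_length: int = 5000
    circular: bool = False
    n_fragments: int = 1000
    # fragment length model: lognormal(mean, sd) truncated to [min, max];
    # "uniform" draws uniformly on [min, max]; "fixed" always emits the mean
    fragment_dist: str = "lognormal"
    fragment_mean: float = 60.0
    fragment_sd: float = 15.0
    fragment_min: int = 20
    fragment_max: int = 500
    read_length: int = 100
    adapter_fwd: str = DEFAULT_ADAPTER_FWD
    adapter_rev: str = DEFAULT_ADAPTER_REV
    substitution_error: float = 0.0
    duplication_rate: float = 0.0
    dup_geom_p: float = 0.5  # extra copies ~ geometric(p)
    damage_rate: float = 0.0
    damage_decay: float = 0.5  # per-base geometric decay of the damage rate
    n_snps: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.substitution_error, self.duplication_rate, self.damage_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if self.fragment_dist not in ("lognormal", "uniform", "fixed"):
            raise ValueError(f"unknown fragment_dist {self.fragment_dist!r}")


@dataclass
class FragmentTruth:
    """One sequenced fragment copy and where it came from."""

    fragment_id: str
    origin: int  # 1-based start on the genome
    length: int
    strand: str
    dup_group: int
    copy_index: int
    spans_origin: bool
    sequence: str  # molecule sequence in reference orientation (damage applied)
    fwd_errors: list[int] = field(default_factory=list)
    rev_errors: list[int] = field(default_factory=list)
    damage_positions: list[int] = field(default_factory=list)


@dataclass
class TruthTable:
    fragments: list[FragmentTruth]
    snps: list[tuple[int, str, str]]  # (pos, ref, alt)

    @property
    def n_distinct_fragments(self) -> int:
        return len({f.dup_group for f in self.fragments})

    @property
    def n_distinct_endpoints(self) -> int:
        """Fragments distinguishable by (origin, length, strand) — what an
        endpoint-keyed duplicate remover can at best recover."""
        return len({(f.origin, f.length, f.strand) for f in self.fragments})

    def write_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["fragment_id", "origin", "length", "strand", "dup_group",
                        "copy_index", "spans_origin"])
            for f in self.fragments:
                w.writerow([f.fragment_id, f.origin, f.length, f.strand,
                            f.dup_group, f.copy_index, int(f.spans_origin)])

    def write_snp_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["pos", "ref", "alt"])
            for pos, ref, alt in self.snps:
                w.writerow([pos, ref, alt])


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """Independent RNG stream for one named output."""
    tag = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")
    return np.random.default_rng([int(seed), tag])


def simulate_genome(config: SimConfig) -> tuple[str, str, list[tuple[int, str, str]]]:
    """Uniform-random genome plus planted SNP truth: (name, sequence, snps)."""
    if config.genome_length < 100:
        raise ValueError("genome_length must be >= 100")
    if config.n_snps > config.genome_length:
        raise ValueError("n_snps exceeds genome_length")
    rng = stream_rng(config.seed, "genome")
    seq = "".join(BASES[i] for i in rng.integers(0, 4, config.genome_length))
    snps = []
    positions = rng.choice(config.genome_length, size=config.n_snps, replace=False)
    for pos0 in sorted(int(p) for p in positions):
        ref = seq[pos0]
        alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        snps.append((pos0 + 1, ref, alt))
    return "sim_genome", seq, snps


def _draw_length(rng: np.random.Generator, cfg: SimConfig) -> int:
    if cfg.fragment_dist == "fixed":
        return int(cfg.fragment_mean)
    if cfg.fragment_dist == "uniform":
        return int(rng.integers(cfg.fragment_min, cfg.fragment_max + 1))
    # lognormal parameterised by the desired arithmetic mean and sd
    cv2 = (cfg.fragment_sd / cfg.fragment_mean) ** 2
    sigma = np.sqrt(np.log1p(cv2))
    mu = np.log(cfg.fragment_mean) - sigma**2 / 2
    for _ in range(1000):
        x = int(round(rng.lognormal(mu, sigma)))
        if cfg.fragment_min <= x <= cfg.fragment_max:
            return x
    return int(np.clip(x, cfg.fragment_min, cfg.fragment_max))


def _apply_damage(seq: str, rng: np.random.Generator, cfg: SimConfig) -> tuple[str, list[int]]:
    """Deaminate a molecule: 5' C->T and 3' G->A, geometric decay inwards."""
    if cfg.damage_rate == 0.0:
        return seq, []
    out = list(seq)
    n = len(seq)
    hits = []
    for j in range(n):
        p5 = cfg.damage_rate * cfg.damage_decay**j
        p3 = cfg.damage_rate * cfg.damage_decay ** (n - 1 - j)
        if out[j] == "C" and rng.random() < p5:
            out[j] = "T"
            hits.append(j)
        elif out[j] == "G" and rng.random() < p3:
            out[j] = "A"
            hits.append(j)
    return "".join(out), hits


def _substitute(seq: str, rng: np.random.Generator, rate: float) -> tuple[str, list[int]]:
    if rate == 0.0:
        return seq, []
    out = list(seq)
    hits = []
    for j in range(len(out)):
        if rng.random() < rate:
            out[j] = BASES[(BASES.index(out[j]) + int(rng.integers(1, 4))) % 4]
            hits.append(j)
    return "".join(out), hits


def _read_qualities(n: int, error_positions: list[int],
                    rng: np.random.Generator) -> list[int]:
    # high baseline; erroneous bases get a telltale low quality half the time
    quals = [int(q) for q in rng.integers(38, 42, n)]
    for j in error_positions:
        if j < n and rng.random() < 0.5:
            quals[j] = int(rng.integers(2, 16))
    return quals


def _build_read(insert: str, adapter: str, read_length: int,
                error_rate: float, rng: np.random.Generator
                ) -> tuple[str, list[int], list[int]]:
    """One read: erroneous insert, then adapter, then random bases to length."""
    body, errors = _substitute(insert, rng, error_rate)
    read = body[:read_length]
    if len(read) < read_length:
        read += adapter[: read_length - len(read)]
    if len(read) < read_length:
        read += "".join(
            BASES[i] for i in rng.integers(0, 4, read_length - len(read))
        )
    quals = _read_qualities(read_length, errors, rng)
    return read, quals, errors


def simulate_reads(genome: str, config: SimConfig
                   ) -> tuple[list[ReadRecord], list[ReadRecord], TruthTable]:
    """Paired FASTQ records plus the truth table.

    Fragment start positions are uniform on the genome; on a circular
    genome fragments may wrap around the origin. Each fragment receives
    PCR copies (1 + geometric extras with probability ``duplication_rate``),
    damage is applied to the molecule (shared by both mates of a copy) and
    substitution errors independently per read.
    """
    rng = stream_rng(config.seed, "reads")
    L = len(genome)
    fwd_reads: list[ReadRecord] = []
    rev_reads: list[ReadRecord] = []
    truth_rows: list[FragmentTruth] = []
    for i in range(config.n_fragments):
        flen = _draw_length(rng, config)
        flen = min(flen, L)
        if config.circular:
            start0 = int(rng.integers(0, L))
            if start0 + flen <= L:
                frag = genome[start0 : start0 + flen]
            else:
                frag = genome[start0:] + genome[: start0 + flen - L]
        else:
            start0 = int(rng.integers(0, L - flen + 1))
            frag = genome[start0 : start0 + flen]
        strand = "+" if rng.random() < 0.5 else "-"
        molecule = frag if strand == "+" else reverse_complement(frag)
        copies = 1
        if config.duplication_rate > 0 and rng.random() < config.duplication_rate:
            copies += int(rng.geometric(config.dup_geom_p))
        for c in range(copies):
            dam_seq, dam_hits = _apply_damage(molecule, rng, config)
            ref_oriented = dam_seq if strand == "+" else reverse_complement(dam_seq)
            fid = f"frag{i:06d}_c{c}"
            fseq, fqual, ferr = _build_read(
                dam_seq, config.adapter_fwd, config.read_length,
                config.substitution_error, rng)
            rseq, rqual, rerr = _build_read(
                reverse_complement(dam_seq), config.adapter_rev, config.read_length,
                config.substitution_error, rng)
            fwd_reads.append(ReadRecord(fid, fseq, fqual, Mate.FORWARD))
            rev_reads.append(ReadRecord(fid, rseq, rqual, Mate.REVERSE))
            truth_rows.append(FragmentTruth(
                fragment_id=fid, origin=start0 + 1, length=flen, strand=strand,
                dup_group=i, copy_index=c,
                spans_origin=config.circular and start0 + flen > L,
                sequence=ref_oriented, fwd_errors=ferr, rev_errors=rerr,
                damage_positions=dam_hits,
            ))
    return fwd_reads, rev_reads, TruthTable(truth_rows, [])


def simulate_truth_sam(genome_name: str, L: int, truth: TruthTable, sam_out,
                       mode: str = "linear", k: int = 0,
                       merged_ids: bool = True) -> dict:
    """Truth alignments of the merged fragments, no aligner involved.

    ``elongated`` mode places origin-spanning fragments as single
    contiguous records inside the elongation window (positions may run past
    L, exactly what the circular rewrite step consumes); ``linear`` mode
    drops them and counts the loss, modelling a linear mapper's failure at
    the reference ends. Records are coordinate-sorted.
    """
    if mode not in ("linear", "elongated"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = stream_rng(0, f"truth_sam_{mode}")  # qualities only; truth fixed
    records: list[AlignmentRecord] = []
    dropped = 0
    for f in truth.fragments:
        if f.spans_origin:
            if mode == "linear":
                dropped += 1
                continue
            if f.length > k:
                raise ValueError(
                    f"fragment length {f.length} exceeds elongation k={k}; "
                    "cannot be represented as one elongated-window record"
                )
        quals = [int(q) for q in rng.integers(30, 41, f.length)]
        name = ("M_" if merged_ids else "") + f.fragment_id
        records.append(AlignmentRecord(
            read_id=name,
            flags=0x10 if f.strand == "-" else 0,
            ref_name=genome_name, pos=f.origin, mapq=37,
            cigar=f"{f.length}M", sequence=f.sequence, qualities=quals,
        ))
    records.sort(key=lambda a: a.pos)
    ref_len = L + k if mode == "elongated" else L
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": genome_name, "LN": ref_len}],
    }
    n = write_sam(sam_out, header, records)
    return {"records": n, "dropped_origin_spanning": dropped}


def simulate_allsites_vcf(genome: str, genome_name: str,
                          snps: list[tuple[int, str, str]], vcf_out,
                          depth_mean: float = 20.0, qual: float = 99.0,
                          seed: int = 0, noise_rate: float = 0.002) -> int:
    """All-sites VCF: one row per position, Poisson depth, planted SNPs.

    Non-SNP positions occasionally (``noise_rate``) carry a single stray
    alt-supporting read, exercising the single-minor-read rule downstream.
    """
    if depth_mean < 1:
        raise ValueError("depth_mean must be >= 1")
    rng = stream_rng(seed, "vcf")
    snp_map = {pos: (ref, alt) for pos, ref, alt in snps}
    rows = []
    for pos1 in range(1, len(genome) + 1):
        depth = int(rng.poisson(depth_mean))
        ref = genome[pos1 - 1]
        if pos1 in snp_map:
            _, alt = snp_map[pos1]
            rows.append(SiteCall(genome_name, pos1, ref, alt,
                                 qual if depth else 0.0, depth, 0, depth))
        elif depth > 0 and rng.random() < noise_rate:
            alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
            rows.append(SiteCall(genome_name, pos1, ref, alt, qual, depth,
                                 max(depth - 1, 0), min(1, depth)))
        else:
            rows.append(SiteCall(genome_name, pos1, ref, None,
                                 qual if depth else 0.0, depth, depth, 0))
    return write_vcf(vcf_out, [(genome_name, len(genome))], rows)


def run(config: SimConfig, out_dir, depth_mean: float = 20.0,
        vcf_qual: float = 99.0) -> dict:
    """Emit the full truth set into ``out_dir``; returns a manifest."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    name, genome, snps = simulate_genome(config)
    write_fasta(os.path.join(out_dir, "genome.fasta"), [(name, genome)])
    fwd, rev, truth = simulate_reads(genome, config)
    truth.snps = snps
    write_fastq(os.path.join(out_dir, "reads_1.fastq"), fwd)
    write_fastq(os.path.join(out_dir, "reads_2.fastq"), rev)
    truth.write_tsv(os.path.join(out_dir, "truth_fragments.tsv"))
    truth.write_snp_tsv(os.path.join(out_dir, "truth_snps.tsv"))
    manifest = {
        "genome_length": config.genome_length,
        "n_fragment_copies": len(truth.fragments),
        "n_distinct_fragments": truth.n_distinct_fragments,
        "n_snps": len(snps),
    }
    sam_linear = os.path.join(out_dir, "truth_linear.sam")
    manifest["linear_sam"] = simulate_truth_sam(name, len(genome), truth,
                                                sam_linear, "linear")
    if config.circular:
        k = max(config.fragment_max, 1)
        k = min(k, len(genome))
        sam_el = os.path.join(out_dir, "truth_elongated.sam")
        manifest["elongated_sam"] = simulate_truth_sam(
            name, len(genome), truth, sam_el, "elongated", k=k)
        manifest["elongation_k"] = k
    simulate_allsites_vcf(genome, name, snps,
                          os.path.join(out_dir, "allsites.vcf"),
                          depth_mean=depth_mean, qual=vcf_qual, seed=config.seed)
    return manifest
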