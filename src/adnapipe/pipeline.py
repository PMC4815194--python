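"""Pipeline driver: run the bespoke stages in order from one config file.

Stage order is clip+merge -> (external mapping, a documented seam: the
user supplies the SAM) -> circular rewrite -> duplicate removal -> draft
construction -> report. Every stage is independently skippable; a stage
requested without its input fails naming the gap. All outputs land in one
directory, each stage leaving a JSON stats artifact the report collects.
"""

from __future__ import annotations

import hashlib
import json
import os
from typing import Optional

import yaml

from . import __version__
from .clipmerge import ClipMergeConfig, process_pairs, write_stats as write_cm_stats
from .circular import DEFAULT_RESTORED_MAPQ, process_sam, read_sidecar
from .dedup import MergedPolicy, dedup_records, write_stats as write_dd_stats
from .io import read_fasta, read_sam, write_sam
from .report import collect, coverage_stats, render, SampleReport
from .vcf2genome import CallPolicy, run as vcf2genome_run

ALL_STAGES = ("clipmerge", "circular", "dedup", "vcf2genome", "report")


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _require(config: dict, key: str, stage: str):
    if key not in config or config[key] is None:
        raise ValueError(f"stage {stage!r} requested but config lacks {key!r}")
    return config[key]


def run_pipeline(config: dict, out_dir: Optional[str] = None) -> dict:
    """Execute the configured stages; returns a manifest of outputs."""
    out_dir = out_dir or config.get("out_dir") or "."
    os.makedirs(out_dir, exist_ok=True)
    stages = config.get("stages", list(ALL_STAGES))
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    sample = config.get("sample_name", "sample")
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    manifest: dict = {"sample_name": sample, "config_hash": cfg_hash,
                      "version": __version__, "stages": list(stages)}
    stats: dict[str, dict] = {}

    def outp(name: str) -> str:
        return os.path.join(out_dir, name)

    if "clipmerge" in stages:
        fq1 = _require(config, "fastq1", "clipmerge")
        fq2 = _require(config, "fastq2", "clipmerge")
        cm_keys = {f.name for f in ClipMergeConfig.__dataclass_fields__.values()}
        cm_cfg = ClipMergeConfig(**{
            k: v for k, v in config.get("clipmerge", {}).items() if k in cm_keys
        })
        _, _, cm_stats = process_pairs(
            fq1, fq2, cm_cfg,
            out_merged=outp("merged.fastq"),
            out_unmerged1=outp("unmerged_1.fastq"),
            out_unmerged2=outp("unmerged_2.fastq"),
        )
        stats["clipmerge"] = write_cm_stats(
            cm_stats, json_path=outp("clipmerge.json"),
            text_path=outp("clipmerge.txt"), sample_name=sample)
    sam_for_dedup = config.get("sam")
    if "circular" in stages:
        sam_in = _require(config, "sam", "circular")
        sidecar = _require(config, "sidecar", "circular")
        circ = read_sidecar(sidecar)
        rw = process_sam(sam_in, outp("rewritten.sam"), circ,
                         restored_mapq=config.get("restored_mapq",
                                                  DEFAULT_RESTORED_MAPQ))
        stats["circular"] = {
            "sample_name": sample, "interior": rw.interior, "edge": rw.edge,
            "junction": rw.junction, "records_out": rw.records_out,
        }
        with open(outp("circular.json"), "w") as fh:
            json.dump(stats["circular"], fh, indent=2)
            fh.write("\n")
        sam_for_dedup = outp("rewritten.sam")
    if "dedup" in stages:
        if sam_for_dedup is None:
            raise ValueError("stage 'dedup' requested but config lacks 'sam'")
        header, records = read_sam(sam_for_dedup)
        policy = MergedPolicy(config.get("merged_policy", "auto"))
        kept, dd_stats = dedup_records(records, policy)
        write_sam(outp("dedup.sam"), header, kept)
        stats["dedup"] = write_dd_stats(dd_stats, outp("dedup.json"), sample)
        ref_len = config.get("reference_length")
        if ref_len is None and header.get("SQ"):
            ref_len = header["SQ"][0]["LN"]
        if ref_len:
            cov = coverage_stats(kept, ref_len)
            cov["sample_name"] = sample
            stats["coverage"] = cov
            with open(outp("coverage.json"), "w") as fh:
                json.dump(cov, fh, indent=2)
                fh.write("\n")
    if "vcf2genome" in stages:
        vcf = _require(config, "vcf", "vcf2genome")
        ref = _require(config, "reference", "vcf2genome")
        pol_keys = {"min_qual", "min_depth", "min_fraction"}
        policy = CallPolicy(**{
            k: v for k, v in config.get("vcf2genome", {}).items() if k in pol_keys
        })
        stats["vcf2genome"] = vcf2genome_run(
            vcf, ref, outp("draft"), policy, sample_name=sample)
    if "report" in stages:
        rep = collect(stats, sample_name=sample)
        render([rep], tsv_out=outp("report.tsv"), html_out=outp("report.html"))
        manifest["report"] = rep.row()
    manifest["stats"] = stats
    with open(outp("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return manifest
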