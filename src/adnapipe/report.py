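"""Per-sample summary report: collection, rendering, coverage statistics.

Each pipeline stage writes a small JSON stats artifact; the report stage
collects whichever artifacts exist into one row per sample (absent stages
leave empty cells) and renders a TSV (the machine contract) plus a
cosmetic HTML table. Percentages are formatted half-up to two decimals.
"""

from __future__ import annotations

import html
import json
import os
from dataclasses import dataclass, fields
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional

import numpy as np

from .io import AlignmentRecord

REPORT_COLUMNS = [
    "sample_name",
    "raw_read_pairs",
    "merged_reads",
    "pct_merged",
    "reads_after_clipmerge",
    "mapped_reads_prior_dedup",
    "duplicates_removed",
    "mean_coverage",
    "pct_genome_covered_ge1",
]


def pct_2dp(numerator: float, denominator: float) -> str:
    """Percentage rounded half-up to 2 decimals, e.g. '94.78'."""
    if denominator == 0:
        return "0.00"
    value = Decimal(numerator) * 100 / Decimal(denominator)
    return str(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class SampleReport:
    sample_name: str = ""
    raw_read_pairs: Optional[int] = None
    merged_reads: Optional[int] = None
    pct_merged: Optional[str] = None
    reads_after_clipmerge: Optional[int] = None
    mapped_reads_prior_dedup: Optional[int] = None
    duplicates_removed: Optional[int] = None
    mean_coverage: Optional[str] = None
    pct_genome_covered_ge1: Optional[str] = None

    def row(self) -> list[str]:
        out = []
        for f in fields(self):
            v = getattr(self, f.name)
            out.append("" if v is None else str(v))
        return out


def coverage_stats(records: Iterable[AlignmentRecord], ref_length: int) -> dict:
    """Mean per-base depth and fraction of positions covered >= 1."""
    depth = np.zeros(ref_length + 1, dtype=np.int64)
    for rec in records:
        if not rec.is_mapped:
            continue
        start = rec.pos - 1
        end = min(rec.end, ref_length)
        depth[start] += 1
        depth[end] -= 1
    per_base = np.cumsum(depth[:ref_length])
    return {
        "mean_coverage": float(per_base.mean()) if ref_length else 0.0,
        "pct_genome_covered_ge1": (
            float((per_base >= 1).mean() * 100) if ref_length else 0.0
        ),
        "reference_length": ref_length,
    }


def collect(stats: dict[str, dict], sample_name: Optional[str] = None) -> SampleReport:
    """Assemble one report row from per-stage stats dicts.

    ``stats`` maps stage name ('clipmerge', 'dedup', 'coverage') to the
    dict that stage wrote; missing stages leave their cells empty. Sample
    names present in several artifacts must agree.
    """
    names = {d["sample_name"] for d in stats.values() if "sample_name" in d}
    if sample_name is not None:
        names.add(sample_name)
    if len(names) > 1:
        raise ValueError(f"conflicting sample names across stats files: {sorted(names)}")
    rep = SampleReport(sample_name=names.pop() if names else "")
    cm = stats.get("clipmerge")
    if cm is not None:
        rep.raw_read_pairs = cm["pairs_in"]
        rep.merged_reads = cm["merged"]
        rep.pct_merged = pct_2dp(cm["merged"], cm["pairs_in"])
        rep.reads_after_clipmerge = cm["reads_out"]
    dd = stats.get("dedup")
    if dd is not None:
        rep.mapped_reads_prior_dedup = dd["total_mapped_in"]
        rep.duplicates_removed = dd["removed"]
    cov = stats.get("coverage")
    if cov is not None:
        rep.mean_coverage = str(
            Decimal(cov["mean_coverage"]).quantize(Decimal("0.01"), ROUND_HALF_UP)
        )
        rep.pct_genome_covered_ge1 = pct_2dp(cov["pct_genome_covered_ge1"], 100)
    return rep


def collect_dir(stats_dir, sample_name: Optional[str] = None) -> SampleReport:
    """Collect from ``<stage>.json`` files in a directory."""
    stats = {}
    for stage in ("clipmerge", "dedup", "coverage", "vcf2genome"):
        path = os.path.join(stats_dir, f"{stage}.json")
        if os.path.exists(path):
            with open(path) as fh:
                stats[stage] = json.load(fh)
    return collect(stats, sample_name)


def render_tsv(reports: list[SampleReport]) -> str:
    lines = ["\t".join(REPORT_COLUMNS)]
    for rep in reports:
        lines.append("\t".join(rep.row()))
    return "\n".join(lines) + "\n"


def render_html(reports: list[SampleReport]) -> str:
    head = "".join(f"<th>{html.escape(c)}</th>" for c in REPORT_COLUMNS)
    body = "".join(
        "<tr>" + "".join(f"<td>{html.escape(v)}</td>" for v in rep.row()) + "</tr>"
        for rep in reports
    )
    return (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        "<title>Sample report</title></head><body>"
        f"<table border='1'><thead><tr>{head}</tr></thead>"
        f"<tbody>{body}</tbody></table></body></html>\n"
    )


def render(reports: list[SampleReport], tsv_out=None, html_out=None) -> str:
    if not reports:
        raise ValueError("at least one sample report is required")
    tsv = render_tsv(reports)
    if tsv_out is not None:
        with open(tsv_out, "w") as fh:
            fh.write(tsv)
    if html_out is not None:
        with open(html_out, "w") as fh:
            fh.write(render_html(reports))
    return tsv
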