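"""End-to-end orchestration: extract -> call -> classify -> coverage -> report.

One configured run consumes a SAM/BAM, a reference FASTA and a feature
annotation, persists every intermediate table, and writes a machine-readable
report (TSV + JSON).  Identical config and inputs give identical reports
apart from nothing at all — no timestamps are embedded.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from deletion_scope import io as dio
from deletion_scope import __version__
from deletion_scope.calling import (
    CallParams,
    annotate_calls,
    collapse_junctions,
    filter_support,
    restrict_calls,
)
from deletion_scope.coverage import depth_profile, detect_low_runs, reconcile
from deletion_scope.extraction import extract_junctions, read_alignments
from deletion_scope.model import Feature, JunctionCall
from deletion_scope.signatures import classify_junction, microhomology

logger = logging.getLogger(__name__)

SIZE_BINS = [(0, 1_000, "lt1kb"), (1_000, 10_000, "1-10kb"), (10_000, None, "ge10kb")]


@dataclass
class RunConfig:
    """Paths and stage parameters for one pipeline run."""

    bam: str
    fasta: str
    annotation: str
    out_dir: str
    regions: Optional[str] = None
    exclude: Optional[str] = None
    min_mapq: int = 60
    tol: int = 3
    flank: int = 50
    min_support: int = 1
    is_dist: int = 3
    min_mh: int = 2
    frac: float = 0.5
    min_run: int = 500
    slack: int = 100
    coverage_region: Optional[tuple[int, int]] = None

    def validate(self) -> None:
        for label in ("bam", "fasta", "annotation"):
            p = getattr(self, label)
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} path does not exist: {p}")
        for label in ("regions", "exclude"):
            p = getattr(self, label)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} path does not exist: {p}")
        Path(self.out_dir).mkdir(parents=True, exist_ok=True)


def report_deleted_features(call: JunctionCall, features: Sequence[Feature]) -> list[str]:
    """Feature ids fully contained in the deleted interval (half-open containment).

    A feature straddling a breakpoint is not listed here — it shows up as a
    boundary annotation on the call instead.
    """
    return [
        f.id
        for f in features
        if call.left_break <= f.start and f.end <= call.right_break
    ]


def _md5(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _size_bin(size: int) -> str:
    for lo, hi, label in SIZE_BINS:
        if size >= lo and (hi is None or size < hi):
            return label
    return "unknown"


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order and write the report; returns it as a dict."""
    config.validate()
    out = Path(config.out_dir)

    ref_seqs = dio.read_fasta(config.fasta)
    features, is_elements = dio.read_gff3(config.annotation)

    alignments = list(read_alignments(config.bam))
    raw = extract_junctions(alignments, min_mapq=config.min_mapq)
    dio.write_raw_junctions(raw, out / "raw_junctions.tsv")

    regions = None
    if config.regions:
        regions = [(s, e) for _, s, e, _ in dio.read_bed(config.regions)]

    calls: list[JunctionCall] = []
    for ref_name in sorted({j.ref_name for j in raw}):
        group = [j for j in raw if j.ref_name == ref_name]
        calls.extend(collapse_junctions(group, tol=config.tol))
    if regions:
        calls = restrict_calls(calls, regions)
    calls = filter_support(calls, config.min_support)
    all_features = features + [
        Feature(id=e.id, type="mobile_genetic_element", start=e.start, end=e.end)
        for e in is_elements
    ]
    calls = annotate_calls(calls, all_features, flank=config.flank)
    dio.write_calls(calls, out / "junction_calls.tsv")

    records = []
    for call in calls:
        ref = ref_seqs[call.ref_name]
        mh = microhomology(ref, call.left_break, call.right_break)
        cls = classify_junction(
            call, mh, is_elements, is_dist=config.is_dist, min_mh=config.min_mh
        )
        records.append(
            {
                "ref": call.ref_name,
                "left_break": call.left_break,
                "right_break": call.right_break,
                "size": call.size,
                "size_bin": _size_bin(call.size),
                "support": call.support,
                "mh_left": mh.left_ext,
                "mh_right": mh.right_ext,
                "mh_total": mh.total,
                "mh_seq": mh.mh_sequence,
                "class": cls.label,
                "element_id": cls.element_id or "",
                "end": cls.end or "",
                "distance": cls.distance if cls.distance is not None else "",
                "deleted_features": ",".join(report_deleted_features(call, all_features)),
                "annotations": ";".join(f"{i}:{t}:{e}" for i, t, e in call.annotations),
                "linked_span": "",
            }
        )

    # coverage over the configured region (default: around the calls, or whole ref)
    ref_name = next(iter(ref_seqs))
    ref_len = len(ref_seqs[ref_name])
    region = config.coverage_region or (0, ref_len)
    exclude = []
    if config.exclude:
        exclude = [(s, e) for _, s, e, _ in dio.read_bed(config.exclude)]
    spans = []
    profile = depth_profile(
        alignments, region=region, min_mapq=config.min_mapq, exclude=exclude,
        ref_name=ref_name,
    )
    dio.write_bedgraph(profile, out / "coverage.bedgraph")
    try:
        spans = detect_low_runs(profile, frac=config.frac, min_run=config.min_run)
    except ValueError as exc:
        logger.warning("coverage span detection skipped: %s", exc)
    links = reconcile(spans, calls, slack=config.slack)
    for row in links:
        if row["kind"] == "linked":
            for rec in records:
                if (
                    rec["left_break"] == row["call_left"]
                    and rec["right_break"] == row["call_right"]
                ):
                    rec["linked_span"] = f"{row['span_start']}-{row['span_end']}"
    dio.write_bed(
        [(ref_name, s.start, s.end, f"span_{i}") for i, s in enumerate(spans)],
        out / "spans.bed",
    )

    import pandas as pd

    report_df = pd.DataFrame(records)
    report_df.to_csv(out / "report.tsv", sep="\t", index=False)

    by_class: dict[str, int] = {}
    by_bin: dict[str, int] = {}
    for rec in records:
        by_class[rec["class"]] = by_class.get(rec["class"], 0) + 1
        by_bin[rec["size_bin"]] = by_bin.get(rec["size_bin"], 0) + 1
    report = {
        "version": __version__,
        "parameters": {
            k: v for k, v in asdict(config).items() if k not in ("out_dir",)
        },
        "input_checksums": {
            "bam": _md5(config.bam),
            "fasta": _md5(config.fasta),
            "annotation": _md5(config.annotation),
        },
        "n_alignments": len(alignments),
        "n_raw_junctions": len(raw),
        "n_calls": len(calls),
        "summary_by_class": by_class,
        "summary_by_size_bin": by_bin,
        "spans": [
            {"start": s.start, "end": s.end, "depth_ratio": s.depth_ratio} for s in spans
        ],
        "junctions": records,
    }
    if not calls:
        report["summary"] = "no junctions detected"
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
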