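"""File-format I/O at the pipeline boundaries.

All in-memory coordinates are 0-based half-open; GFF3 is written/read
1-based inclusive and BED 0-based half-open, with conversions confined to
this module.  FASTA goes through Bio.SeqIO.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from deletion_scope.model import Feature, GenomeModel, ISElement, JunctionCall, RawJunction

PathLike = Union[str, Path]


# --- FASTA -----------------------------------------------------------------

def write_fasta(genome: GenomeModel, path: PathLike) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.name, description="")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path: PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# --- GFF3 ------------------------------------------------------------------

def write_gff3(genome: GenomeModel, path: PathLike) -> None:
    """Write genes and IS elements (with terminal-repeat children) as GFF3."""
    lines = ["##gff-version 3", f"##sequence-region {genome.name} 1 {len(genome)}"]

    def row(ftype: str, start: int, end: int, attrs: str) -> str:
        return "\t".join(
            [genome.name, "deletion-scope", ftype, str(start + 1), str(end), ".", "+", ".", attrs]
        )

    for f in genome.features:
        lines.append(row(f.type, f.start, f.end, f"ID={f.id};Name={f.id}"))
    for e in genome.is_elements:
        lines.append(row("mobile_genetic_element", e.start, e.end, f"ID={e.id};Name={e.id}"))
        lines.append(
            row("terminal_inverted_repeat", e.irl[0], e.irl[1], f"ID={e.id}_IRL;Parent={e.id};end=IRL")
        )
        lines.append(
            row("terminal_inverted_repeat", e.irr[0], e.irr[1], f"ID={e.id}_IRR;Parent={e.id};end=IRR")
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _gff_attrs(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gff3(path: PathLike) -> tuple[list[Feature], list[ISElement]]:
    """Read features and IS elements (mobile_genetic_element + TIR children)."""
    features: list[Feature] = []
    elements: dict[str, dict] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        _, _, ftype, start1, end1, _, _, _, attr_field = cols
        start, end = int(start1) - 1, int(end1)
        attrs = _gff_attrs(attr_field)
        fid = attrs.get("ID", f"{ftype}_{start}")
        if ftype == "mobile_genetic_element":
            elements.setdefault(fid, {})["interval"] = (start, end)
        elif ftype == "terminal_inverted_repeat":
            parent = attrs.get("Parent")
            end_label = attrs.get("end", "IRL" if fid.endswith("IRL") else "IRR")
            if parent is None:
                raise ValueError(f"terminal_inverted_repeat without Parent: {line!r}")
            elements.setdefault(parent, {})[end_label.lower()] = (start, end)
        else:
            features.append(Feature(id=fid, type=ftype, start=start, end=end))
    is_elements = []
    for eid, parts in elements.items():
        if "interval" not in parts or "irl" not in parts or "irr" not in parts:
            raise ValueError(f"IS element {eid} missing interval or terminal repeats")
        s, e = parts["interval"]
        is_elements.append(ISElement(id=eid, start=s, end=e, irl=parts["irl"], irr=parts["irr"]))
    is_elements.sort(key=lambda x: x.start)
    return features, is_elements


# --- BED -------------------------------------------------------------------

def read_bed(path: PathLike) -> list[tuple[str, int, int, Optional[str]]]:
    """Read BED3/BED4 rows as (chrom, start, end, name), 0-based half-open."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise ValueError(f"malformed BED line: {line!r}")
        rows.append((cols[0], int(cols[1]), int(cols[2]), cols[3] if len(cols) > 3 else None))
    return rows


def write_bed(rows: Sequence[tuple[str, int, int, Optional[str]]], path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in rows:
            fields = [chrom, str(start), str(end)] + ([name] if name else [])
            fh.write("\t".join(fields) + "\n")


def read_features_bed(path: PathLike, default_type: str = "gene") -> list[Feature]:
    return [
        Feature(id=name or f"feat_{start}", type=default_type, start=start, end=end)
        for _, start, end, name in read_bed(path)
    ]


# --- junction / call tables ------------------------------------------------

RAW_JUNCTION_COLUMNS = ["ref", "del_start", "del_end", "read_id", "mapq"]


def write_raw_junctions(junctions: Sequence[RawJunction], path: PathLike) -> None:
    df = pd.DataFrame(
        [(j.ref_name, j.del_start, j.del_end, j.read_id, j.mapq) for j in junctions],
        columns=RAW_JUNCTION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_raw_junctions(path: PathLike) -> list[RawJunction]:
    df = pd.read_csv(path, sep="\t")
    return [
        RawJunction(r.ref, int(r.del_start), int(r.del_end), str(r.read_id), int(r.mapq))
        for r in df.itertuples()
    ]


def write_calls(calls: Sequence[JunctionCall], path: PathLike) -> None:
    rows = []
    for c in calls:
        rows.append(
            {
                "ref": c.ref_name,
                "left_break": c.left_break,
                "right_break": c.right_break,
                "size": c.size,
                "support": c.support,
                "representative_members": ",".join(f"{s}-{e}:{n}" for s, e, n in c.members),
                "annotations": ";".join(f"{i}:{t}:{end}" for i, t, end in c.annotations),
            }
        )
    pd.DataFrame(
        rows,
        columns=["ref", "left_break", "right_break", "size", "support",
                 "representative_members", "annotations"],
    ).to_csv(path, sep="\t", index=False)


def read_calls(path: PathLike) -> list[JunctionCall]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    calls = []
    for r in df.itertuples():
        members = []
        for part in str(r.representative_members).split(","):
            span, n = part.rsplit(":", 1)
            s, e = span.split("-")
            members.append((int(s), int(e), int(n)))
        anns = []
        if r.annotations:
            for part in str(r.annotations).split(";"):
                fid, ftype, end = part.split(":")
                anns.append((fid, ftype, end))
        calls.append(
            JunctionCall(
                ref_name=r.ref,
                left_break=int(r.left_break),
                right_break=int(r.right_break),
                support=int(r.support),
                members=members,
                annotations=anns,
            )
        )
    return calls


# --- coverage --------------------------------------------------------------

def write_bedgraph(profile, path: PathLike) -> None:
    """Write a depth profile as bedGraph, run-length collapsed; masked -> -1."""
    import numpy as np

    vals = profile.depth.copy()
    vals[profile.mask] = -1
    with open(path, "w") as fh:
        run_start = 0
        for i in range(1, len(vals) + 1):
            if i == len(vals) or vals[i] != vals[run_start]:
                fh.write(
                    f"{profile.ref_name}\t{profile.start + run_start}\t{profile.start + i}\t{int(vals[run_start])}\n"
                )
                run_start = i


# --- theta tracks ----------------------------------------------------------

SPOT_COLUMNS = [
    "video_id", "frame", "spot_x", "spot_y",
    "beadA_x", "beadA_y", "beadB_x", "beadB_y", "stretched",
]


def write_spot_frames(frames, path: PathLike) -> None:
    rows = [
        (f.video_id, f.frame, f.spot_xy[0], f.spot_xy[1], f.beadA_xy[0], f.beadA_xy[1],
         f.beadB_xy[0], f.beadB_xy[1], int(f.stretched))
        for f in frames
    ]
    pd.DataFrame(rows, columns=SPOT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_spot_frames(path: PathLike):
    from deletion_scope.tweezers import SpotFrame

    df = pd.read_csv(path, sep="\t")
    return [
        SpotFrame(
            video_id=str(r.video_id),
            frame=int(r.frame),
            spot_xy=(float(r.spot_x), float(r.spot_y)),
            beadA_xy=(float(r.beadA_x), float(r.beadA_y)),
            beadB_xy=(float(r.beadB_x), float(r.beadB_y)),
            stretched=bool(r.stretched),
        )
        for r in df.itertuples()
    ]
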