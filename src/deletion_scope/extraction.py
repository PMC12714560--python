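"""Junction-spanning read extraction from SAM/BAM alignments.

A spliced aligner represents a read that crosses a genomic deletion with an
N (reference-skip) CIGAR operation; the skipped interval is the deleted
sequence.  This stage walks each passing alignment's CIGAR with a
reference cursor and emits one raw junction per N operation, filtered on
mapping quality (default MAPQ >= 60, i.e. uniquely-placed reads only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import pysam

from deletion_scope.model import RawJunction

logger = logging.getLogger(__name__)

# pysam integer CIGAR op codes -> characters
CIGAR_OPS = "MIDNSHP=XB"

_REF_CONSUMING = set("MDN=X")

FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


@dataclass(frozen=True)
class AlignmentRecord:
    """A minimal mapped-alignment view (0-based leftmost coordinate)."""

    read_id: str
    ref_name: str
    pos0: int
    mapq: int
    cigar: tuple[tuple[str, int], ...]
    flags: int = 0

    def __post_init__(self) -> None:
        if self.pos0 < 0:
            raise ValueError("pos0 must be >= 0")
        if any(l <= 0 for _, l in self.cigar):
            raise ValueError("cigar lengths must be positive")


def read_alignments(path: Union[str, Path]) -> Iterator[AlignmentRecord]:
    """Stream mapped records from a SAM or BAM file (format auto-detected).

    POS is converted to 0-based; unmapped records are skipped.  A missing or
    invalid header, or a truncated file, raises instead of yielding a silent
    partial stream.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with pysam.AlignmentFile(str(path), check_sq=True) as af:
        for rec in af:
            if rec.is_unmapped or rec.cigartuples is None:
                continue
            cigar = tuple((CIGAR_OPS[op], length) for op, length in rec.cigartuples)
            yield AlignmentRecord(
                read_id=rec.query_name,
                ref_name=rec.reference_name,
                pos0=rec.reference_start,
                mapq=rec.mapping_quality,
                cigar=cigar,
                flags=rec.flag,
            )


def extract_junctions(
    alignments: Iterable[AlignmentRecord],
    min_mapq: int = 60,
    region: Optional[tuple[int, int]] = None,
    min_del_as_junction: Optional[int] = None,
    skip_secondary: bool = True,
) -> list[RawJunction]:
    """Extract per-read deletion junctions from N-containing CIGARs.

    For each alignment with ``mapq >= min_mapq``, the CIGAR is walked with
    a reference cursor starting at ``pos0``; every N operation of length b
    at cursor c yields ``RawJunction(del_start=c, del_end=c + b)``.
    M/D/=/X advance the cursor; I/S/H do not.  A read with several N
    operations yields several junctions.

    Parameters
    ----------
    region : optional 0-based half-open interval; only junctions with both
        ``del_start`` and ``del_end`` inside it are kept.
    min_del_as_junction : if set, D operations of at least this length are
        promoted to junctions as well (off by default: spliced aligners
        encode deletions of interest as N).
    skip_secondary : drop secondary/supplementary alignments so one read
        cannot contribute duplicate support.
    """
    if not 0 <= min_mapq <= 255:
        raise ValueError("min_mapq must be in [0, 255]")
    junctions: list[RawJunction] = []
    n_filtered = 0
    for rec in alignments:
        if skip_secondary and rec.flags & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY):
            n_filtered += 1
            continue
        if rec.mapq < min_mapq:
            n_filtered += 1
            continue
        cursor = rec.pos0
        for op, length in rec.cigar:
            is_junction = op == "N" or (
                min_del_as_junction is not None
                and op == "D"
                and length >= min_del_as_junction
            )
            if is_junction:
                j = RawJunction(
                    ref_name=rec.ref_name,
                    del_start=cursor,
                    del_end=cursor + length,
                    read_id=rec.read_id,
                    mapq=rec.mapq,
                )
                if region is None or (
                    region[0] <= j.del_start < region[1]
                    and region[0] <= j.del_end < region[1]
                ):
                    junctions.append(j)
            if op in _REF_CONSUMING:
                cursor += length
    if n_filtered:
        logger.info("extract_junctions: %d alignment(s) failed filters", n_filtered)
    return junctions
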