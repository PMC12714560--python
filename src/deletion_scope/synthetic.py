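"""Synthetic pooled-colony WGS generator.

Emulates whole-genome sequencing of pooled bacterial colonies in which
different lineages carry large chromosomal deletions: a reference genome
with multiple identical IS elements (each flanked by exact terminal
inverted repeats) and annotated genes, per-lineage planted deletions
(A-EJ microhomology-flanked, IS-repeat-bounded, or blunt), and single-end
reads drawn from each lineage's derived allele in proportion to its pool
fraction.  Reads that cross a deletion junction are emitted as spliced
alignments (``aM bN cM`` CIGARs), the representation the downstream
junction extractor keys on; a truth table records every planted junction
with its realized read support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from deletion_scope.model import (
    DeletionEvent,
    Feature,
    GenomeModel,
    ISElement,
    Lineage,
    SimulationParams,
    revcomp,
)
from deletion_scope.signatures import microhomology

BASES = np.array(list("ACGT"))

TRUTH_COLUMNS = [
    "lineage_id",
    "left_break",
    "right_break",
    "size",
    "mechanism",
    "mh_len",
    "element_id",
    "expected_support",
]


class PlacementError(RuntimeError):
    """Raised when features cannot be placed without overlap."""


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def _overlaps(start: int, end: int, placed: list[tuple[int, int]]) -> bool:
    return any(start < e and s < end for s, e in placed)


def build_genome(
    length: int,
    gc: float = 0.5,
    n_is: int = 4,
    is_length: int = 768,
    ir_length: int = 30,
    gene_spec: Sequence[tuple[str, int]] = (),
    seed: int = 0,
    name: str = "synthetic_chromosome",
    max_attempts: int = 1000,
) -> GenomeModel:
    """Build a random genome carrying identical IS elements and genes.

    One master IS sequence of ``is_length`` bp is generated with exact
    terminal inverted repeats (last ``ir_length`` bases equal the reverse
    complement of the first) and planted ``n_is`` times at random
    non-overlapping positions that also avoid genes — mirroring the
    multi-copy-identical-IS architecture that makes deletion boundaries
    ambiguous in real genomes.  Deterministic for a fixed seed.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    total_needed = n_is * is_length + sum(l for _, l in gene_spec)
    if length < total_needed:
        raise ValueError(
            f"genome length {length} cannot hold {total_needed} bp of features"
        )
    rng = np.random.default_rng(seed)
    seq = list(_random_seq(rng, length, gc))

    master_is = None
    if n_is > 0:
        if is_length < 2 * ir_length:
            raise ValueError("is_length must be at least 2 x ir_length")
        body = _random_seq(rng, is_length, gc)
        master_is = body[: is_length - ir_length] + revcomp(body[:ir_length])

    placed: list[tuple[int, int]] = []
    is_elements: list[ISElement] = []
    features: list[Feature] = []

    def place(flen: int) -> int:
        for _ in range(max_attempts):
            start = int(rng.integers(0, length - flen + 1))
            if not _overlaps(start, start + flen, placed):
                placed.append((start, start + flen))
                return start
        raise PlacementError(
            f"could not place a {flen} bp feature after {max_attempts} attempts"
        )

    for i in range(n_is):
        start = place(is_length)
        seq[start : start + is_length] = master_is
        is_elements.append(
            ISElement(
                id=f"IS1_{i + 1}",
                start=start,
                end=start + is_length,
                irl=(start, start + ir_length),
                irr=(start + is_length - ir_length, start + is_length),
            )
        )
    for gene_name, gene_len in gene_spec:
        start = place(gene_len)
        features.append(Feature(id=gene_name, type="gene", start=start, end=start + gene_len))

    is_elements.sort(key=lambda e: e.start)
    features.sort(key=lambda f: f.start)
    return GenomeModel(name=name, sequence="".join(seq), features=features, is_elements=is_elements)


def _check_edit_clear(genome: GenomeModel, start: int, end: int) -> None:
    for s, e in genome.all_feature_intervals():
        if start < e and s < end:
            raise ValueError(
                f"planting would overwrite bases in feature interval [{s}, {e})"
            )


def _feature_free_position(
    genome: GenomeModel, rng: np.random.Generator, size: int, margin: int, max_attempts: int = 1000
) -> int:
    """A left_break such that [left_break - margin, left_break + size + margin) avoids features."""
    n = len(genome)
    for _ in range(max_attempts):
        lb = int(rng.integers(margin, n - size - margin))
        if not _overlaps(lb - margin, lb + size + margin, genome.all_feature_intervals()):
            return lb
    raise PlacementError("no feature-free interval found for the requested deletion")


def plant_deletion(
    genome: GenomeModel,
    mechanism: str,
    size: int,
    anchor: Union[int, tuple[str, str], str, None] = None,
    mh_len: int = 0,
    seed: int = 0,
    mh_range: Optional[tuple[int, int]] = None,
) -> tuple[str, DeletionEvent]:
    """Plant one deletion on the genome and return (derived allele, event).

    The genome's reference sequence may be edited in place so the planted
    signature is verifiable on the reference:

    AEJ
        the ``mh_len`` bases immediately left of ``left_break`` are copied
        to the ``mh_len`` bases immediately left of ``right_break`` (inside
        the deleted interval), so the brute-force microhomology scan
        reports ``left_ext >= mh_len``.  ``anchor`` may give the left break
        position; otherwise a feature-free one is drawn.
    IS_BOUNDED
        one breakpoint is placed exactly at a terminal-repeat boundary of
        the anchor element: ``anchor=(element_id, "IRR")`` puts
        ``right_break`` at that element's IRR end; ``("IRL", ...)`` puts
        ``left_break`` at the IRL start.  ``anchor="auto"`` picks any
        element whose boundary admits the requested size.
    BLUNT
        deleted-interval edge bases are resampled until total
        microhomology is zero (edits stay inside the deleted interval, so
        the derived allele is unaffected).
    """
    rng = np.random.default_rng(seed)
    n = len(genome)
    if size < 1 or size > n:
        raise ValueError("deletion size out of range")
    seq = genome.sequence

    if mechanism == "AEJ":
        if mh_range is not None and not mh_range[0] <= mh_len <= mh_range[1]:
            raise ValueError(f"mh_len {mh_len} outside configured range {mh_range}")
        if mh_len < 1:
            raise ValueError("AEJ planting requires mh_len >= 1")
        if isinstance(anchor, int):
            left_break = anchor
        else:
            left_break = _feature_free_position(genome, rng, size, margin=mh_len + 5)
        right_break = left_break + size
        if left_break < mh_len or right_break > n:
            raise ValueError("AEJ deletion does not fit with its microhomology")
        _check_edit_clear(genome, right_break - mh_len, right_break)
        donor = seq[left_break - mh_len : left_break]
        seq = seq[: right_break - mh_len] + donor + seq[right_break:]
        event = DeletionEvent(left_break, right_break, "AEJ", planted_mh_len=mh_len)
        mh = microhomology(seq, left_break, right_break, max_m=max(50, mh_len))
        assert mh.left_ext >= mh_len, "planted microhomology not verifiable"
    elif mechanism == "IS_BOUNDED":
        candidates: list[tuple[ISElement, str]] = []
        if anchor == "auto" or anchor is None:
            for elem in genome.is_elements:
                candidates.append((elem, "IRR"))
                candidates.append((elem, "IRL"))
        else:
            elem_id, end = anchor
            matches = [e for e in genome.is_elements if e.id == elem_id]
            if not matches:
                raise ValueError(f"no IS element named {elem_id!r}")
            candidates.append((matches[0], end))
        chosen = None
        for elem, end in candidates:
            if end == "IRR":
                rb = elem.irr[1]
                lb = rb - size
            elif end == "IRL":
                lb = elem.irl[0]
                rb = lb + size
            else:
                raise ValueError("bounded_end must be IRL or IRR")
            if 0 <= lb < rb <= n:
                chosen = (elem, end, lb, rb)
                break
        if chosen is None:
            raise ValueError("no IS element boundary admits the requested deletion size")
        elem, end, left_break, right_break = chosen
        event = DeletionEvent(
            left_break,
            right_break,
            "IS_BOUNDED",
            bounded_element_id=elem.id,
            bounded_end=end,
        )
    elif mechanism == "BLUNT":
        if isinstance(anchor, int):
            left_break = anchor
        else:
            left_break = _feature_free_position(genome, rng, size, margin=5)
        right_break = left_break + size
        # Break chance homology by editing the first and last DELETED bases,
        # which cannot change the derived allele.
        s = list(seq)
        for _ in range(20):
            mh = microhomology("".join(s), left_break, right_break)
            if mh.total == 0:
                break
            if mh.left_ext > 0:
                pos = right_break - 1
                _check_edit_clear(genome, pos, pos + 1)
                avoid = {s[left_break - 1]}
                if right_break - 1 == left_break:
                    avoid.add(s[right_break] if right_break < n else "")
                s[pos] = rng.choice([c for c in "ACGT" if c not in avoid])
            else:
                pos = left_break
                _check_edit_clear(genome, pos, pos + 1)
                avoid = {s[right_break]} if right_break < n else set()
                if right_break - 1 == left_break and left_break > 0:
                    avoid.add(s[left_break - 1])
                s[pos] = rng.choice([c for c in "ACGT" if c not in avoid])
        seq = "".join(s)
        mh = microhomology(seq, left_break, right_break)
        assert mh.total == 0, "blunt planting failed to remove microhomology"
        event = DeletionEvent(left_break, right_break, "BLUNT")
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")

    genome.sequence = seq
    allele = seq[: event.left_break] + seq[event.right_break :]
    return allele, event


# ---------------------------------------------------------------------------
# Pooled read simulation


@dataclass
class SimulatedRead:
    """One emitted single-end alignment (all coordinates 0-based)."""

    read_id: str
    pos0: int
    mapq: int
    cigar: list[tuple[str, int]]  # ops over {M, N}
    seq: str

    def cigar_string(self) -> str:
        return "".join(f"{l}{op}" for op, l in self.cigar)

    def reference_span(self) -> int:
        return sum(l for op, l in self.cigar if op in "MDN=X")


@dataclass
class PoolResult:
    """Output of :func:`simulate_pool`."""

    sam_text: str
    truth: pd.DataFrame
    reads: list[SimulatedRead] = field(repr=False, default_factory=list)
    n_drawn: int = 0
    n_anchor_dropped: int = 0


def _retained_segments(n: int, deletions: Sequence[DeletionEvent]) -> list[tuple[int, int]]:
    segs = []
    cursor = 0
    for d in deletions:
        if d.left_break > cursor:
            segs.append((cursor, d.left_break))
        cursor = d.right_break
    if cursor < n:
        segs.append((cursor, n))
    return segs


def _read_pieces(
    segs: list[tuple[int, int]], offsets: list[int], s: int, read_len: int
) -> list[tuple[int, int]]:
    """Reference intervals covered by derived-coordinate read [s, s+read_len)."""
    pieces = []
    remaining = read_len
    # find first segment containing derived coordinate s
    import bisect

    i = bisect.bisect_right(offsets, s) - 1
    within = s - offsets[i]
    while remaining > 0:
        seg_start, seg_end = segs[i]
        take = min(remaining, (seg_end - seg_start) - within)
        pieces.append((seg_start + within, seg_start + within + take))
        remaining -= take
        within = 0
        i += 1
    return pieces


def simulate_pool(
    genome: GenomeModel,
    lineages: Sequence[Lineage],
    params: SimulationParams,
) -> PoolResult:
    """Draw pooled single-end reads and emit a coordinate-sorted SAM + truth table.

    Reads are drawn uniformly from each lineage's derived allele; the number
    drawn per lineage is ``ceil(depth * pool_fraction * retained_length /
    read_length)``.  A read whose alignment crosses one or more planted
    junctions is emitted with an ``aM bN cM`` spliced CIGAR where each N
    length equals the deleted interval; junction-crossing reads with fewer
    than ``min_anchor`` aligned bases in any M segment are dropped.  All
    reads get MAPQ 60 except a ``mapq_low_fraction`` emitted at MAPQ 1 to
    exercise downstream mapping-quality filters.
    """
    frac_sum = sum(l.pool_fraction for l in lineages)
    if abs(frac_sum - 1.0) > 1e-9:
        raise ValueError(f"pool fractions must sum to 1, got {frac_sum}")
    rng = np.random.default_rng(params.seed)
    n = len(genome)
    L = params.read_length

    reads: list[SimulatedRead] = []
    n_drawn = 0
    n_dropped = 0
    support: dict[tuple[str, int, int], int] = {}

    for lineage in lineages:
        segs = _retained_segments(n, lineage.deletions)
        seg_lens = [e - s for s, e in segs]
        offsets = list(np.concatenate([[0], np.cumsum(seg_lens)[:-1]])) if segs else [0]
        retained = sum(seg_lens)
        if retained < L:
            raise ValueError(f"lineage {lineage.id}: retained genome shorter than a read")
        junction_by_gap = {
            (d.left_break, d.right_break): d for d in lineage.deletions
        }
        n_reads = math.ceil(params.depth * lineage.pool_fraction * retained / L)
        n_drawn += n_reads
        starts = rng.integers(0, retained - L + 1, size=n_reads)
        mapq_low = (
            rng.random(n_reads) < params.mapq_low_fraction
            if params.mapq_low_fraction > 0
            else np.zeros(n_reads, dtype=bool)
        )
        for i, s in enumerate(starts):
            pieces = _read_pieces(segs, offsets, int(s), L)
            if len(pieces) > 1 and any(e - st < params.min_anchor for st, e in pieces):
                n_dropped += 1
                continue
            cigar: list[tuple[str, int]] = []
            crossed: list[tuple[int, int]] = []
            for j, (st, e) in enumerate(pieces):
                if j > 0:
                    prev_end = pieces[j - 1][1]
                    cigar.append(("N", st - prev_end))
                    crossed.append((prev_end, st))
                cigar.append(("M", e - st))
            seq = "".join(genome.sequence[st:e] for st, e in pieces)
            if params.substitution_rate > 0:
                seq = _mutate(seq, params.substitution_rate, rng)
            mapq = 1 if mapq_low[i] else 60
            reads.append(
                SimulatedRead(
                    read_id=f"{lineage.id}:r{i:06d}",
                    pos0=pieces[0][0],
                    mapq=mapq,
                    cigar=cigar,
                    seq=seq,
                )
            )
            if mapq >= 60:
                for gap in crossed:
                    if gap in junction_by_gap:
                        support[(lineage.id, *gap)] = support.get((lineage.id, *gap), 0) + 1

    reads.sort(key=lambda r: (r.pos0, r.read_id))

    lines = [
        "@HD\tVN:1.6\tSO:coordinate",
        f"@SQ\tSN:{genome.name}\tLN:{n}",
        "@PG\tID:deletion-scope\tPN:deletion-scope",
    ]
    for r in reads:
        lines.append(
            "\t".join(
                [
                    r.read_id,
                    "0",
                    genome.name,
                    str(r.pos0 + 1),
                    str(r.mapq),
                    r.cigar_string(),
                    "*",
                    "0",
                    "0",
                    r.seq,
                    "I" * len(r.seq),
                ]
            )
        )
    sam_text = "\n".join(lines) + "\n"

    rows = []
    for lineage in lineages:
        for d in lineage.deletions:
            rows.append(
                {
                    "lineage_id": lineage.id,
                    "left_break": d.left_break,
                    "right_break": d.right_break,
                    "size": d.size,
                    "mechanism": d.mechanism,
                    "mh_len": d.planted_mh_len,
                    "element_id": d.bounded_element_id or "",
                    "expected_support": support.get(
                        (lineage.id, d.left_break, d.right_break), 0
                    ),
                }
            )
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return PoolResult(
        sam_text=sam_text,
        truth=truth,
        reads=reads,
        n_drawn=n_drawn,
        n_anchor_dropped=n_dropped,
    )


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    s = list(seq)
    hits = np.nonzero(rng.random(len(s)) < rate)[0]
    for i in hits:
        s[i] = rng.choice([c for c in "ACGT" if c != s[i]])
    return "".join(s)
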