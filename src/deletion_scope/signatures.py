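"""Microhomology scoring, IS-repeat association and flanking-sequence logos.

Small bacterial deletions repaired by alternative end joining (A-EJ) carry
short identical sequences on the two sides of the junction; that shared
sequence makes the exact breakpoint placement ambiguous over an interval.
Large deletions in IS-rich genomes instead tend to terminate exactly at an
insertion-sequence terminal inverted repeat.  This module scores both
signatures for each junction call and builds position frequency matrices of
breakpoint-flanking sequence for logo display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from deletion_scope.model import ISElement, JunctionCall, revcomp

BASES = "ACGT"


@dataclass(frozen=True)
class MicrohomologyResult:
    """Breakpoint-shift microhomology at a deletion ``[a, b)``.

    left_ext: maximal m with ref[a-1-i] == ref[b-1-i] for all i < m
        (the retained left flank equals the right end of the deleted
        sequence, so the breakpoint could slide left).
    right_ext: maximal m with ref[a+i] == ref[b+i] for all i < m
        (the left end of the deleted sequence equals the retained right
        flank, so the breakpoint could slide right).
    Every left-break placement within ``ambiguity_interval`` yields an
    identical derived allele.
    """

    left_ext: int
    right_ext: int
    mh_sequence: str
    a: int
    b: int

    @property
    def total(self) -> int:
        return self.left_ext + self.right_ext

    @property
    def ambiguity_interval(self) -> tuple[int, int]:
        """Closed interval [a - left_ext, a + right_ext] of equivalent left breaks."""
        return (self.a - self.left_ext, self.a + self.right_ext)


@dataclass(frozen=True)
class RepairClass:
    """Inferred repair signature for one junction call."""

    label: str  # IS_ASSOCIATED | MICROHOMOLOGY | OTHER
    mh_total: int
    element_id: Optional[str] = None
    end: Optional[str] = None  # IRL | IRR
    distance: Optional[int] = None


@dataclass
class PositionFrequencyMatrix:
    """Per-position base counts over breakpoint flanks, with information content.

    ``counts`` is a 4 x window array in A,C,G,T row order; every column sums
    to ``n_sequences``.  ``information_content`` is the per-column Shannon
    information 2 + sum_b p_b log2 p_b in bits, without pseudocounts or
    small-sample correction (0 <= IC <= 2).
    """

    window: int
    counts: np.ndarray
    n_sequences: int

    @property
    def information_content(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            p = self.counts / self.counts.sum(axis=0, keepdims=True)
            plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
        return 2.0 + plogp.sum(axis=0)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=list(BASES))


def microhomology(ref: str, a: int, b: int, max_m: int = 50) -> MicrohomologyResult:
    """Score microhomology at the deletion of ``ref[a:b]``.

    Parameters
    ----------
    ref : reference sequence.
    a, b : 0-based half-open deleted interval, ``0 <= a < b <= len(ref)``.
    max_m : cap on each extension (breakpoints are only localized to within
        a few bases anyway; 50 bp covers any biologically plausible A-EJ MH).
    """
    n = len(ref)
    if not 0 <= a < b <= n:
        raise ValueError(f"require 0 <= a < b <= len(ref); got a={a}, b={b}, len={n}")
    left_ext = 0
    while left_ext < max_m and a - 1 - left_ext >= 0 and ref[a - 1 - left_ext] == ref[b - 1 - left_ext]:
        left_ext += 1
    right_ext = 0
    while right_ext < max_m and b + right_ext < n and ref[a + right_ext] == ref[b + right_ext]:
        right_ext += 1
    mh_seq = ref[a - left_ext : a] + ref[a : a + right_ext]
    return MicrohomologyResult(left_ext=left_ext, right_ext=right_ext, mh_sequence=mh_seq, a=a, b=b)


def classify_junction(
    call: JunctionCall,
    mh: MicrohomologyResult,
    is_elements: Sequence[ISElement],
    is_dist: int = 3,
    min_mh: int = 2,
) -> RepairClass:
    """Classify the repair signature of one junction call.

    Precedence: a breakpoint within ``is_dist`` of any terminal-repeat
    boundary coordinate (IRL/IRR start or end; nearest wins) classifies as
    IS_ASSOCIATED; otherwise total microhomology >= ``min_mh`` classifies
    as MICROHOMOLOGY; otherwise OTHER.  IS evidence takes precedence because
    >=2 bp of chance microhomology is common at random junctions while an
    exact repeat-boundary hit is not.
    """
    best: Optional[tuple[int, str, str]] = None  # (distance, element_id, end)
    for elem in is_elements:
        for end_label, coord in elem.boundary_coords():
            for brk in (call.left_break, call.right_break):
                d = abs(brk - coord)
                if best is None or d < best[0]:
                    best = (d, elem.id, end_label)
    if best is not None and best[0] <= is_dist:
        return RepairClass(
            label="IS_ASSOCIATED",
            mh_total=mh.total,
            element_id=best[1],
            end=best[2],
            distance=best[0],
        )
    if mh.total >= min_mh:
        return RepairClass(label="MICROHOMOLOGY", mh_total=mh.total)
    return RepairClass(label="OTHER", mh_total=mh.total)


def flank_matrix(
    calls: Sequence[JunctionCall],
    ref: str,
    side: str = "RIGHT",
    window: int = 30,
    orientation: str = "DOWNSTREAM",
) -> PositionFrequencyMatrix:
    """Build a position frequency matrix of breakpoint-flanking sequence.

    ``side`` picks the breakpoint (LEFT -> left_break, RIGHT -> right_break);
    ``orientation`` picks the direction: UPSTREAM extracts
    ``ref[pos-window:pos)``, DOWNSTREAM extracts ``ref[pos:pos+window)``,
    always on the forward strand.  Calls whose window would leave the
    sequence are skipped and excluded from ``n_sequences``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if side not in ("LEFT", "RIGHT"):
        raise ValueError("side must be LEFT or RIGHT")
    if orientation not in ("UPSTREAM", "DOWNSTREAM"):
        raise ValueError("orientation must be UPSTREAM or DOWNSTREAM")
    n = len(ref)
    counts = np.zeros((4, window), dtype=np.int64)
    base_index = {b: i for i, b in enumerate(BASES)}
    used = 0
    skipped = 0
    for call in calls:
        pos = call.left_break if side == "LEFT" else call.right_break
        if orientation == "DOWNSTREAM":
            lo, hi = pos, pos + window
        else:
            lo, hi = pos - window, pos
        if lo < 0 or hi > n:
            skipped += 1
            continue
        seq = ref[lo:hi].upper()
        for j, base in enumerate(seq):
            counts[base_index[base], j] += 1
        used += 1
    if used == 0:
        raise ValueError("no usable calls: every window left the reference bounds")
    if skipped:
        import warnings

        warnings.warn(f"{skipped} call(s) too close to a contig end were skipped")
    return PositionFrequencyMatrix(window=window, counts=counts, n_sequences=used)


def verify_inverted_repeats(
    element_seq: str, ir_length: int, max_mismatch: int = 0
) -> tuple[str, str, int]:
    """Compare an element's two ends as terminal inverted repeats.

    Returns (irl_seq, irr_seq, mismatches) where mismatches counts positions
    at which the first ``ir_length`` bases differ from the reverse complement
    of the last ``ir_length`` bases.  ``max_mismatch`` is the caller's
    tolerance and is not enforced here.
    """
    if len(element_seq) < 2 * ir_length:
        raise ValueError("element shorter than two terminal repeats")
    irl = element_seq[:ir_length]
    irr = element_seq[-ir_length:]
    rc = revcomp(irr)
    mismatches = sum(1 for x, y in zip(irl, rc) if x != y)
    return irl, irr, mismatches


def information_content_bits(column_counts: Sequence[int]) -> float:
    """IC of a single count column: 2 + sum p log2 p (bits), no pseudocounts."""
    total = sum(column_counts)
    if total == 0:
        raise ValueError("empty column")
    ic = 2.0
    for c in column_counts:
        if c:
            p = c / total
            ic += p * math.log2(p)
    return ic
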