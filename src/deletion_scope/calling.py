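"""Collapsing, interval restriction and feature annotation of junction calls.

Raw junctions from individual reads scatter by a few bases around the true
breakpoints (alignment jitter and microhomology ambiguity).  Near-identical
junctions are collapsed into calls by single-linkage clustering under an
endpoint tolerance, restricted to target intervals, and annotated with
features whose intervals fall within a flank window of either breakpoint.
Defaults follow the source analysis: tolerance 3 bp, flank 50 bp.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from deletion_scope.model import Feature, JunctionCall, RawJunction

logger = logging.getLogger(__name__)


@dataclass
class CallParams:
    """Junction-calling parameters (tolerance and flank follow the study defaults)."""

    tol: int = 3
    flank: int = 50
    min_support: int = 1
    regions: Optional[list[tuple[int, int]]] = None

    def __post_init__(self) -> None:
        if self.tol < 0 or self.flank < 0:
            raise ValueError("tol and flank must be >= 0")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def collapse_junctions(raw: Sequence[RawJunction], tol: int = 3) -> list[JunctionCall]:
    """Collapse near-identical raw junctions into calls by single linkage.

    Two junctions are linked iff both ``|d(del_start)| <= tol`` and
    ``|d(del_end)| <= tol``; clusters are connected components of that
    relation, so chains of junctions each within tolerance of the next
    merge into one call even when the extremes differ by more than ``tol``.
    The representative breakpoint pair is the member with the highest read
    count, ties broken by smallest del_start then smallest del_end.
    All junctions must be on one reference; callers group by reference.
    """
    if not raw:
        return []
    refs = {j.ref_name for j in raw}
    if len(refs) > 1:
        raise ValueError("collapse_junctions expects junctions on a single reference")
    ref_name = refs.pop()

    pair_counts = Counter((j.del_start, j.del_end) for j in raw)
    pairs = sorted(pair_counts)
    uf = _UnionFind(len(pairs))
    # sorted by del_start: only pairs within tol in del_start can link
    for i, (s1, e1) in enumerate(pairs):
        for j in range(i + 1, len(pairs)):
            s2, e2 = pairs[j]
            if s2 - s1 > tol:
                break
            if abs(e2 - e1) <= tol:
                uf.union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(len(pairs)):
        clusters.setdefault(uf.find(i), []).append(i)

    calls = []
    for idxs in clusters.values():
        members = [(pairs[i][0], pairs[i][1], pair_counts[pairs[i]]) for i in idxs]
        members.sort(key=lambda m: (m[0], m[1]))
        rep = min(members, key=lambda m: (-m[2], m[0], m[1]))
        calls.append(
            JunctionCall(
                ref_name=ref_name,
                left_break=rep[0],
                right_break=rep[1],
                support=sum(c for _, _, c in members),
                members=members,
            )
        )
    calls.sort(key=lambda c: (c.ref_name, c.left_break, c.right_break))
    return calls


def restrict_calls(
    calls: Sequence[JunctionCall], regions: Sequence[tuple[int, int]]
) -> list[JunctionCall]:
    """Keep calls whose breakpoints both lie inside one region.

    Membership is half-open: a breakpoint coordinate x is inside
    ``[start, end)`` iff ``start <= x < end``, and both left_break and
    right_break must fall in the SAME region.
    """
    if not regions:
        raise ValueError("restriction requested with an empty region list")
    kept = []
    for call in calls:
        if any(
            s <= call.left_break < e and s <= call.right_break < e for s, e in regions
        ):
            kept.append(call)
    if len(kept) < len(calls):
        logger.info("restrict_calls: dropped %d call(s)", len(calls) - len(kept))
    return kept


def filter_support(calls: Sequence[JunctionCall], min_support: int) -> list[JunctionCall]:
    """Keep calls with read support >= min_support."""
    return [c for c in calls if c.support >= min_support]


def annotate_calls(
    calls: Sequence[JunctionCall],
    features: Sequence[Feature],
    flank: int = 50,
    ref_length: Optional[int] = None,
) -> list[JunctionCall]:
    """Annotate each call with features near either breakpoint.

    A feature annotates a call if its interval overlaps the half-open
    window ``[breakpoint - flank, breakpoint + flank)`` of the left
    breakpoint (LEFT), the right breakpoint (RIGHT) or both (BOTH).
    Windows are clamped at zero.  Features outside the reference are
    skipped with a warning.
    """
    out = []
    for call in calls:
        lw = (max(0, call.left_break - flank), call.left_break + flank)
        rw = (max(0, call.right_break - flank), call.right_break + flank)
        anns = []
        for f in features:
            if ref_length is not None and f.end > ref_length:
                logger.warning("feature %s outside reference; skipped", f.id)
                continue
            hit_l = f.start < lw[1] and lw[0] < f.end
            hit_r = f.start < rw[1] and rw[0] < f.end
            if hit_l and hit_r:
                anns.append((f.id, f.type, "BOTH"))
            elif hit_l:
                anns.append((f.id, f.type, "LEFT"))
            elif hit_r:
                anns.append((f.id, f.type, "RIGHT"))
        out.append(call.replaced(annotations=anns))
    return out
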