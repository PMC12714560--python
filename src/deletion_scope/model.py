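"""Core domain types shared across pipeline stages.

Coordinate convention: every interval in memory is 0-based half-open
``[start, end)``.  SAM POS is converted to/from 1-based only at I/O
boundaries (pysam already exposes 0-based coordinates).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case-preserving)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """A typed genomic feature on the reference, 0-based half-open."""

    id: str
    type: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid feature interval [{self.start}, {self.end})")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class ISElement:
    """An insertion-sequence element with terminal inverted repeats.

    ``irl``/``irr`` are the left/right terminal inverted repeat intervals,
    contained within ``[start, end)``.  For IS1 the element is 768 bp with
    ~30 bp repeats; the left repeat reads as the reverse complement of the
    right repeat.
    """

    id: str
    start: int
    end: int
    irl: tuple[int, int]
    irr: tuple[int, int]

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("invalid IS element interval")
        il, ih = self.irl
        rl, rh = self.irr
        if not (self.start <= il < ih <= rl < rh <= self.end):
            raise ValueError(
                "terminal repeats must be contained in the element with IRL before IRR"
            )

    @property
    def element_length(self) -> int:
        return self.end - self.start

    @property
    def ir_length(self) -> int:
        return self.irl[1] - self.irl[0]

    def boundary_coords(self) -> list[tuple[str, int]]:
        """The four terminal-repeat boundary coordinates, labelled by end."""
        return [
            ("IRL", self.irl[0]),
            ("IRL", self.irl[1]),
            ("IRR", self.irr[0]),
            ("IRR", self.irr[1]),
        ]


@dataclass
class GenomeModel:
    """Reference sequence plus typed features; ground truth for simulation."""

    name: str
    sequence: str
    features: list[Feature] = field(default_factory=list)
    is_elements: list[ISElement] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for f in self.features:
            if f.end > n:
                raise ValueError(f"feature {f.id} extends past the sequence end")
        for e in self.is_elements:
            if e.end > n:
                raise ValueError(f"IS element {e.id} extends past the sequence end")

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        return self.sequence[start:end]

    def all_feature_intervals(self) -> list[tuple[int, int]]:
        """Feature + IS element intervals, used for overlap-free placement."""
        ivs = [(f.start, f.end) for f in self.features]
        ivs += [(e.start, e.end) for e in self.is_elements]
        return ivs


@dataclass(frozen=True)
class DeletionEvent:
    """A planted deletion: ``[left_break, right_break)`` removed from the reference."""

    left_break: int
    right_break: int
    mechanism: str  # AEJ | IS_BOUNDED | BLUNT
    planted_mh_len: int = 0
    bounded_element_id: Optional[str] = None
    bounded_end: Optional[str] = None  # IRL | IRR

    MECHANISMS = ("AEJ", "IS_BOUNDED", "BLUNT")

    def __post_init__(self) -> None:
        if not 0 <= self.left_break < self.right_break:
            raise ValueError("deletion must satisfy 0 <= left_break < right_break")
        if self.mechanism not in self.MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")

    @property
    def size(self) -> int:
        return self.right_break - self.left_break


@dataclass(frozen=True)
class Lineage:
    """One pooled colony lineage: its deletions and pool fraction."""

    id: str
    deletions: tuple[DeletionEvent, ...]
    pool_fraction: float

    def __post_init__(self) -> None:
        if not 0 < self.pool_fraction <= 1:
            raise ValueError("pool_fraction must be in (0, 1]")
        dels = sorted(self.deletions, key=lambda d: d.left_break)
        for a, b in zip(dels, dels[1:]):
            if b.left_break < a.right_break:
                raise ValueError("deletions within one lineage must not overlap")
        object.__setattr__(self, "deletions", tuple(dels))


@dataclass
class SimulationParams:
    """Pooled-WGS read simulation parameters.

    Defaults mirror the sequenced study conditions: ~30x mean depth,
    100 bp single-end reads, and a 10 bp minimum anchor on each side of a
    junction for a read to be reported as junction-spanning.
    """

    depth: float = 30.0
    read_length: int = 100
    min_anchor: int = 10
    large_del_range: tuple[int, int] = (13_100, 47_000)
    small_del_range: tuple[int, int] = (51, 255)
    mh_range: tuple[int, int] = (2, 11)
    mapq_low_fraction: float = 0.0
    substitution_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.read_length < 2 * self.min_anchor:
            raise ValueError("read_length must be at least 2 x min_anchor")
        for lo, hi in (self.large_del_range, self.small_del_range, self.mh_range):
            if not 0 < lo <= hi:
                raise ValueError("ranges must be positive and ordered")
        if not 0 <= self.mapq_low_fraction <= 1:
            raise ValueError("mapq_low_fraction must be in [0, 1]")


@dataclass(frozen=True)
class RawJunction:
    """One junction-spanning read's evidence: the skipped reference interval."""

    ref_name: str
    del_start: int
    del_end: int
    read_id: str
    mapq: int

    def __post_init__(self) -> None:
        if self.del_start >= self.del_end:
            raise ValueError("junction must have del_start < del_end")

    @property
    def size(self) -> int:
        return self.del_end - self.del_start


@dataclass
class JunctionCall:
    """A collapsed junction cluster with representative breakpoints.

    ``members`` holds the distinct (del_start, del_end) pairs of the cluster
    with their read counts; the representative is always a member.
    ``annotations`` are (feature_id, feature_type, overlap_end) triples with
    overlap_end in {LEFT, RIGHT, BOTH}.
    """

    ref_name: str
    left_break: int
    right_break: int
    support: int
    members: list[tuple[int, int, int]]
    annotations: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.support != sum(c for _, _, c in self.members):
            raise ValueError("support must equal the sum of member counts")
        if (self.left_break, self.right_break) not in {
            (s, e) for s, e, _ in self.members
        }:
            raise ValueError("representative breakpoints must be a cluster member")

    @property
    def size(self) -> int:
        return self.right_break - self.left_break

    def replaced(self, **kw) -> "JunctionCall":
        return dataclasses.replace(self, **kw)
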