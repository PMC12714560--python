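"""Per-base coverage with exclusion masking and reduced-coverage span detection.

In a pooled sample a deletion carried by a subset of lineages shows up as a
run of reduced (not necessarily zero) read depth.  Depth counts only
aligned bases (CIGAR M/=/X); N skips and deletions contribute nothing, so a
spliced junction read covers its anchors but not the gap.  Intervals that
must be ignored (e.g. a gene also present on an expression plasmid, which
would otherwise show inflated or misleading depth) are masked rather than
zeroed so they can neither create nor destroy spans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from deletion_scope.extraction import AlignmentRecord
from deletion_scope.model import JunctionCall


@dataclass
class CoverageProfile:
    """Counted depth over ``[start, end)`` with a boolean exclusion mask."""

    ref_name: str
    start: int
    end: int
    depth: np.ndarray
    mask: np.ndarray  # True = excluded from statistics
    starts: Optional[np.ndarray] = None  # per-position read-start counts

    def unmasked_depth(self) -> np.ndarray:
        return self.depth[~self.mask]

    def median_unmasked(self) -> float:
        d = self.unmasked_depth()
        if d.size == 0:
            raise ValueError("profile is entirely masked")
        return float(np.median(d))


@dataclass
class SpanCall:
    """A reduced-coverage run delimiting a candidate deletion span."""

    start: int
    end: int
    mean_depth_inside: float
    median_depth_flanks: float
    linked_junction: Optional[str] = None

    @property
    def depth_ratio(self) -> float:
        return self.mean_depth_inside / self.median_depth_flanks


def depth_profile(
    alignments: Iterable[AlignmentRecord],
    region: tuple[int, int],
    min_mapq: int = 60,
    exclude: Sequence[tuple[int, int]] = (),
    ref_name: Optional[str] = None,
) -> CoverageProfile:
    """Count per-base aligned depth over ``region``.

    Each alignment with ``mapq >= min_mapq`` adds 1 to every reference
    position consumed by an M/=/X operation; N and D advance the reference
    cursor without contributing; I/S/H consume no reference.  Positions in
    ``exclude`` intervals are masked.
    """
    start, end = region
    if not 0 <= start < end:
        raise ValueError("invalid region")
    depth = np.zeros(end - start, dtype=np.int64)
    starts = np.zeros(end - start, dtype=np.int64)
    name = ref_name
    for rec in alignments:
        if rec.mapq < min_mapq:
            continue
        if name is None:
            name = rec.ref_name
        if start <= rec.pos0 < end:
            starts[rec.pos0 - start] += 1
        cursor = rec.pos0
        for op, length in rec.cigar:
            if op in "M=X":
                lo = max(cursor, start)
                hi = min(cursor + length, end)
                if lo < hi:
                    depth[lo - start : hi - start] += 1
                cursor += length
            elif op in "DN":
                cursor += length
    mask = np.zeros(end - start, dtype=bool)
    for lo, hi in exclude:
        lo, hi = max(lo, start), min(hi, end)
        if lo < hi:
            mask[lo - start : hi - start] = True
    return CoverageProfile(
        ref_name=name or "", start=start, end=end, depth=depth, mask=mask, starts=starts
    )


def _moving_average(depth: np.ndarray, mask: np.ndarray, window: int) -> np.ndarray:
    """Mask-aware centred moving average; fully-masked windows become +inf."""
    if window <= 1:
        return depth.astype(float)
    kernel = np.ones(window)
    valid = (~mask).astype(float)
    num = np.convolve(depth * valid, kernel, mode="same")
    den = np.convolve(valid, kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.inf)


def _refine_boundary(depth: np.ndarray, mask: np.ndarray, guess: int, radius: int) -> int:
    """Best single step-change position near ``guess`` (two-segment mean fit).

    Minimizes the residual sum of squares of a piecewise-constant two-mean
    fit to the unmasked raw depth in ``[guess - radius, guess + radius)``;
    sharp deletion edges make this accurate to a few bases even when the
    coarse (smoothed) boundary is off by a fraction of the window.
    """
    n = depth.size
    lo, hi = max(0, guess - radius), min(n, guess + radius)
    idx = np.nonzero(~mask[lo:hi])[0]
    if idx.size < 4:
        return guess
    vals = depth[lo:hi][idx].astype(float)
    m = idx.size
    c1 = np.cumsum(vals)
    c2 = np.cumsum(vals**2)
    k = np.arange(1, m)  # split: left = vals[:k], right = vals[k:]
    s1, ss1 = c1[k - 1], c2[k - 1]
    s2, ss2 = c1[-1] - s1, c2[-1] - ss1
    sse = (ss1 - s1**2 / k) + (ss2 - s2**2 / (m - k))
    best = int(k[np.argmin(sse)])
    return lo + int(idx[best])


def _refine_boundary_poisson(
    counts: np.ndarray, mask: np.ndarray, guess: int, radius: int
) -> int:
    """Poisson maximum-likelihood changepoint on per-position event counts.

    Maximizes the profile log-likelihood of a two-rate model,
    ``c1 log(c1/n1) + c2 log(c2/n2)``, over split positions in
    ``[guess - radius, guess + radius)``.  Suited to sparse read-start
    counts, where a squared-error split is dominated by noise.
    """
    n = counts.size
    lo, hi = max(0, guess - radius), min(n, guess + radius)
    idx = np.nonzero(~mask[lo:hi])[0]
    if idx.size < 4:
        return guess
    vals = counts[lo:hi][idx].astype(float)
    m = idx.size
    csum = np.cumsum(vals)
    total = csum[-1]
    if total == 0:
        return guess
    k = np.arange(1, m)
    c1 = csum[k - 1]
    c2 = total - c1
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(c1 > 0, c1 * np.log(c1 / k), 0.0) + np.where(
            c2 > 0, c2 * np.log(c2 / (m - k)), 0.0
        )
    best = int(k[np.argmax(ll)])
    return lo + int(idx[best])


def detect_low_runs(
    profile: CoverageProfile,
    frac: float = 0.5,
    min_run: int = 500,
    smooth_window: int = 600,
) -> list[SpanCall]:
    """Detect maximal runs of reduced coverage delimiting deletion spans.

    The threshold is ``frac`` times the median of unmasked depth (a
    fractional threshold, default 0.5, detects the partial dropouts of
    pooled samples where some lineages retain the wild-type sequence).
    Candidate runs are maximal stretches whose unmasked positions fall
    below threshold; masked positions neither break nor extend a run and
    do not count toward ``min_run``.

    Raw integer depth at a residual of a few reads fluctuates above any
    threshold close to its mean, which would shatter runs, so detection
    uses a mask-aware moving average (``smooth_window`` positions, ~6 read
    lengths by default; 1 disables smoothing), after which each boundary
    is refined by a two-segment step fit on the raw depth so reported
    span edges track the true coverage step rather than the smoothing
    scale.
    """
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    median = profile.median_unmasked()
    if median <= 0:
        raise ValueError("unmasked median depth is zero; no baseline to threshold")
    t = frac * median
    smoothed = _moving_average(profile.depth, profile.mask, smooth_window)
    low = (smoothed < t) & ~profile.mask
    usable = ~profile.mask

    runs: list[tuple[int, int]] = []  # (first_low, last_low + 1)
    cur_start = None
    cur_last = None
    n = profile.end - profile.start
    for i in range(n):
        if profile.mask[i]:
            continue  # masks neither break nor extend
        if low[i]:
            if cur_start is None:
                cur_start = i
            cur_last = i
        else:
            if cur_start is not None:
                runs.append((cur_start, cur_last + 1))
            cur_start, cur_last = None, None
    if cur_start is not None:
        runs.append((cur_start, cur_last + 1))

    # a brief smoothed excursion above threshold inside a true span splits
    # it in two; gaps narrower than the smoothing scale are closed
    merged: list[tuple[int, int]] = []
    for lo, hi in runs:
        if merged and lo - merged[-1][1] < smooth_window:
            merged[-1] = (merged[-1][0], hi)
        else:
            merged.append((lo, hi))
    runs = merged

    # two-pass step fit: a wide window on depth first (the smoothed boundary
    # can sit a few hundred bp inside the span), then a tighter pass on
    # per-position read-START counts where available.  Depth is a 1-read-
    # length moving sum of starts, so its noise is correlated over ~100 bp
    # and a low shoulder can drag a depth-based split off the true edge;
    # start counts are independent Poisson with a step exactly at the
    # breakpoint, locating it to a few bases.
    radius1 = max(2 * smooth_window // 3, 1)
    radius2 = 450
    starts = profile.starts
    refined: list[tuple[int, int]] = []
    for lo, hi in runs:
        r_lo = _refine_boundary(profile.depth, profile.mask, lo, radius1)
        r_hi = _refine_boundary(profile.depth, profile.mask, hi, radius1)
        if starts is not None:
            # iterate: the first pass re-centres the window on the step,
            # the second localizes it
            for _ in range(2):
                r_lo = _refine_boundary_poisson(starts, profile.mask, r_lo, radius2)
                r_hi = _refine_boundary_poisson(starts, profile.mask, r_hi, radius2)
        if r_lo >= r_hi:
            r_lo, r_hi = lo, hi
        if int((usable[r_lo:r_hi]).sum()) >= min_run:
            refined.append((r_lo, r_hi))

    spans: list[SpanCall] = []
    in_any_run = np.zeros(n, dtype=bool)
    for lo, hi in refined:
        in_any_run[lo:hi] = True
    flank_sel = usable & ~in_any_run
    flank_median = float(np.median(profile.depth[flank_sel])) if flank_sel.any() else median
    for lo, hi in refined:
        inside = profile.depth[lo:hi][~profile.mask[lo:hi]]
        spans.append(
            SpanCall(
                start=profile.start + lo,
                end=profile.start + hi,
                mean_depth_inside=float(inside.mean()),
                median_depth_flanks=flank_median,
            )
        )
    return spans


def reconcile(
    spans: Sequence[SpanCall],
    calls: Sequence[JunctionCall],
    slack: int = 100,
) -> list[dict]:
    """Cross-link coverage spans with junction calls.

    A span links to a call when both span boundaries are within ``slack``
    bp of the call's breakpoints (one read length is a natural slack, since
    depth transitions are smeared by read placement).  Unlinked spans and
    unlinked calls are both reported.
    """
    rows: list[dict] = []
    linked_calls = set()
    for span in spans:
        best = None
        for k, call in enumerate(calls):
            d_left = abs(span.start - call.left_break)
            d_right = abs(span.end - call.right_break)
            if d_left <= slack and d_right <= slack:
                if best is None or d_left + d_right < best[0]:
                    best = (d_left + d_right, k, d_left, d_right)
        if best is not None:
            _, k, d_left, d_right = best
            call = calls[k]
            linked_calls.add(k)
            span.linked_junction = f"{call.left_break}-{call.right_break}"
            rows.append(
                {
                    "kind": "linked",
                    "span_start": span.start,
                    "span_end": span.end,
                    "call_left": call.left_break,
                    "call_right": call.right_break,
                    "offset_left": d_left,
                    "offset_right": d_right,
                }
            )
        else:
            rows.append(
                {
                    "kind": "unlinked_span",
                    "span_start": span.start,
                    "span_end": span.end,
                    "call_left": None,
                    "call_right": None,
                    "offset_left": None,
                    "offset_right": None,
                }
            )
    for k, call in enumerate(calls):
        if k not in linked_calls:
            rows.append(
                {
                    "kind": "unlinked_call",
                    "span_start": None,
                    "span_end": None,
                    "call_left": call.left_break,
                    "call_right": call.right_break,
                    "offset_left": None,
                    "offset_right": None,
                }
            )
    return rows
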