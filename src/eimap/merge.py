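"""Coordinate-based merging of the exact (Cng1) and inexact (Cng2) contigs.

No sequence alignment is involved: every contig carries its reference
interval, so merging is a left-to-right recursion over the interleaved
sets.  Exact contigs are trusted and inserted whole; inexact contigs lose
their k-extensions (the flanks the masking step deliberately restored into
covered territory) wherever they overlap exact territory, capped at k
reference columns per side.  Gaps bridged by no contig are filled with 'N'
so the final break reproduces the true fragmentation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .core import Contig

_NONN_RE = re.compile(r"[^N]+")


@dataclass
class Segment:
    """Provenance of one emitted stretch of the merged sequence."""

    source: int | None  # index into the interleaved contig list; None = gap fill
    trimmed_left: int
    trimmed_right: int
    text: str


@dataclass
class MergedSequence:
    seq: str
    provenance: list[Segment] = field(default_factory=list)
    start: int = 1  # reference coordinate of seq[0] (merge begins at the
    #                 first contig; positions before it are not represented)


def _check_strict(cng: list[Contig], label: str) -> None:
    for a, b in zip(cng, cng[1:]):
        if not (a.s < b.s and a.e < b.e):
            raise ValueError(
                f"{label}: contigs ({a.s},{a.e}) and ({b.s},{b.e}) violate "
                f"strictly increasing start/end order"
            )


def interleave(cng1: list[Contig], cng2: list[Contig]) -> list[Contig]:
    """Union of the two sets sorted by start; the strict s/e ordering must
    hold on each input and on the union."""
    _check_strict(cng1, "Cng1")
    _check_strict(cng2, "Cng2")
    union = sorted(cng1 + cng2, key=lambda c: (c.s, c.e))
    _check_strict(union, "interleaved union")
    return union


def _slice_positional(c: Contig, s: int, e: int) -> Contig | None:
    """Positional sub-contig of c covering reference [s, e] (sequence offsets
    approximate the interval when the contig carries net indels)."""
    if e < s:
        return None
    lo = max(0, s - c.s)
    hi = min(len(c.seq), lo + (e - s + 1))
    seq = c.seq[lo:hi]
    if not seq:
        return None
    return Contig(seq=seq, s=s, e=e, t=c.t, name=c.name)


def normalize_cng2(cng2: list[Contig], cng1: list[Contig], k: int) -> list[Contig]:
    """Split/trim inexact contigs so the union with Cng1 is strictly ordered.

    The k-extension merges uncovered runs closer than 2k into one mapping
    region, so an inexact contig can strictly contain a short exact contig
    that sat between two uncovered runs; the strict s/e ordering the merge
    recursion assumes then fails.  Exact territory wins: such a contig is
    split around each contained exact contig (keeping a flank of up to k
    reference columns into it, which the merge trims back), a piece lying
    wholly inside exact territory is dropped, and boundary ties are nudged
    by one column.
    """
    out: list[Contig] = []
    for c in cng2:
        pieces: list[Contig] = [c]
        for t1 in cng1:
            new: list[Contig] = []
            for p in pieces:
                if p.e < t1.s or p.s > t1.e:  # disjoint
                    new.append(p)
                    continue
                if t1.s <= p.s and p.e <= t1.e:
                    continue  # piece inside exact territory: nothing to add
                if p.s < t1.s and t1.e < p.e:
                    # exact contig strictly inside the piece: split around
                    # it, keeping at most a k-column flank into it
                    left = _slice_positional(
                        p, p.s, min(t1.s - 1 + k, t1.e - 1)
                    )
                    right = _slice_positional(
                        p, max(t1.e + 1 - k, t1.s + 1), p.e
                    )
                    new.extend(x for x in (left, right) if x is not None)
                    continue
                q: Contig | None = p
                if q.s < t1.s:  # overlap on the piece's right side
                    q = _slice_positional(
                        q, q.s, min(q.e, t1.s - 1 + k, t1.e - 1)
                    )
                else:  # overlap on the piece's left side
                    q = _slice_positional(
                        q, max(q.s, t1.e + 1 - k, t1.s + 1), q.e
                    )
                if q is not None:
                    new.append(q)
            pieces = new
        out.extend(pieces)
    out.sort(key=lambda c: (c.s, c.e))
    return out


def merge_contigs(cng: list[Contig], k: int) -> MergedSequence:
    """Left-to-right merge of an interleaved contig list.

    t=1 contigs append whole (preceded by an 'N' fill when a reference gap
    separates them from emitted territory).  t=2 contigs are trimmed by
    min(k, overlap) reference columns against the previously emitted
    interval on the left, and against the next t=1 contig's interval on the
    right, then appended; one lying entirely inside emitted territory
    contributes nothing.  Trim lengths count reference columns,
    approximated by sequence-length trims for contigs carrying indels.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    _check_strict(cng, "merge input")
    parts: list[str] = []
    segments: list[Segment] = []
    cur_end = 0  # last emitted reference coordinate (1-based; 0 = nothing)
    first = True
    for i, c in enumerate(cng):
        if not first and c.s > cur_end + 1:
            gap = "N" * (c.s - cur_end - 1)
            parts.append(gap)
            segments.append(Segment(None, 0, 0, gap))
            cur_end = c.s - 1
        if first:
            cur_end = c.s - 1
            first = False
        if c.t == 2:
            if c.e <= cur_end:
                continue  # entirely inside emitted territory
            overlap_left = max(0, cur_end - c.s + 1)
            trim_left = min(k, overlap_left, len(c.seq))
            nxt = cng[i + 1] if i + 1 < len(cng) else None
            trim_right = 0
            if nxt is not None and nxt.t == 1 and nxt.s <= c.e:
                trim_right = min(k, c.e - nxt.s + 1)
            keep = c.seq[trim_left : len(c.seq) - trim_right]
            if not keep:
                cur_end = max(cur_end, c.e - trim_right)
                continue
            parts.append(keep)
            segments.append(Segment(i, trim_left, trim_right, keep))
            cur_end = c.e - trim_right
        else:
            parts.append(c.seq)
            segments.append(Segment(i, 0, 0, c.seq))
            cur_end = c.e
    return MergedSequence(
        seq="".join(parts),
        provenance=segments,
        start=cng[0].s if cng else 1,
    )


def final_contigs(merged: MergedSequence) -> list[Contig]:
    """Break the merged sequence at every 'N'; maximal N-free runs become
    the pipeline's output contigs, with merged-sequence coordinates."""
    return [
        Contig(seq=m.group(0), s=m.start() + 1, e=m.end(), t=0,
               name=f"eim_{i}")
        for i, m in enumerate(_NONN_RE.finditer(merged.seq))
    ]
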