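"""Pileup construction and consensus calling from uniquely-mapped reads.

The consensus C has exactly the reference length; position i is 'N' where
no unique read covers it.  In v1 mode any ambiguous call collapses to 'N'
(as does any position where the reference itself holds an IUPAC letter);
in v2 mode ambiguity is emitted as the IUPAC code of the qualifying base
set, and IUPAC reference positions are called like any other.  Breaking C
at every 'N' yields the exact contig set Cng1 (origin tag t=1).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .core import (
    AMBIGUITY_LETTERS,
    SET_TO_IUPAC,
    AlignmentRecord,
    Contig,
    Genome,
    revcomp,
)

_BASES = "ACGT"
_BASE_IDX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _BASE_IDX[ord(_b)] = _i

_NONN_RE = re.compile(r"[^N]+")


@dataclass
class Pileup:
    """Per-position A/C/G/T counts over a reference, strand-collapsed."""

    counts: np.ndarray  # shape (4, n), int64

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def build_pileup(alignments: list[AlignmentRecord], ref: Genome) -> Pileup:
    """Accumulate uniquely-mapped, all-match alignments into a pileup.

    Minus-strand reads contribute their reverse complement.  Exact
    alignments cannot overhang the reference; one that does is an error.
    """
    n = len(ref.seq)
    counts = np.zeros((4, n), dtype=np.int64)
    for rec in alignments:
        if rec.map_class != "unique_exact":
            raise ValueError(
                f"pileup accepts unique_exact alignments only, got "
                f"'{rec.map_class}' for read '{rec.read_id}'"
            )
        k = len(rec.seq)
        if rec.cigar != f"{k}M":
            raise ValueError(
                f"exact alignment must be all-match ({k}M), got '{rec.cigar}'"
            )
        start = rec.pos - 1
        if start < 0 or start + k > n:
            raise ValueError(
                f"alignment of '{rec.read_id}' at pos {rec.pos} overruns the "
                f"reference (length {n})"
            )
        bases = revcomp(rec.seq) if rec.strand == "-" else rec.seq
        idx = _BASE_IDX[np.frombuffer(bases.encode(), dtype=np.uint8)]
        np.add.at(counts, (idx, np.arange(start, start + k)), 1)
    return Pileup(counts)


def call_column(
    column: np.ndarray,
    mode: str = "v2",
    min_depth: int = 1,
    het_fraction: float = 0.25,
    min_alt_count: int = 2,
) -> str:
    """Call one pileup column (length-4 A/C/G/T counts).

    Depth below ``min_depth`` → 'N'.  The qualifying set M holds every base
    with count ≥ het_fraction × depth; non-top bases must additionally
    reach ``min_alt_count`` observations.  |M| = 1 → that base; |M| ≥ 2 →
    IUPAC code in v2, 'N' in v1.
    """
    depth = int(column.sum())
    if depth < max(min_depth, 1):
        return "N"
    top = int(column.max())
    thr = het_fraction * depth
    members = frozenset(
        b
        for i, b in enumerate(_BASES)
        if column[i] >= thr and column[i] > 0
        and (column[i] == top or column[i] >= min_alt_count)
    )
    if not members:  # het_fraction > top/depth: fall back to the major base
        members = frozenset(b for i, b in enumerate(_BASES) if column[i] == top)
    if len(members) == 1:
        return next(iter(members))
    return SET_TO_IUPAC[members] if mode == "v2" else "N"


def call_consensus(
    pileup: Pileup,
    ref: Genome,
    mode: str = "v2",
    min_depth: int = 1,
    het_fraction: float = 0.25,
    min_alt_count: int = 2,
) -> str:
    """Call the consensus sequence C (length |ref|) from a pileup.

    Reference positions holding an IUPAC letter are forced to 'N' in v1
    mode regardless of the pileup; v2 calls them from the pileup like any
    other position.
    """
    if mode not in ("v1", "v2"):
        raise ValueError(f"mode must be 'v1' or 'v2', got '{mode}'")
    if pileup.length != len(ref.seq):
        raise ValueError(
            f"pileup length {pileup.length} != reference length {len(ref.seq)}"
        )
    counts = pileup.counts
    depth = pileup.depth
    top = counts.max(axis=0)
    out = np.full(pileup.length, "N", dtype="U1")

    # fast path: unanimous covered columns (the vast majority)
    unanimous = (depth >= max(min_depth, 1)) & (top == depth) & (depth > 0)
    argmax = counts.argmax(axis=0)
    base_arr = np.array(list(_BASES), dtype="U1")
    out[unanimous] = base_arr[argmax[unanimous]]

    # remaining covered columns: full rule
    rest = np.flatnonzero((depth >= max(min_depth, 1)) & ~unanimous)
    for i in rest:
        out[i] = call_column(counts[:, i], mode, min_depth, het_fraction,
                             min_alt_count)

    if mode == "v1":
        for i, c in enumerate(ref.seq):
            if c in AMBIGUITY_LETTERS or c == "N":
                out[i] = "N"
    return "".join(out)


def contigs_from_consensus(cons: str, tag: int) -> list[Contig]:
    """Break a consensus at every 'N'; maximal N-free runs become contigs
    with their 1-based reference interval and the given origin tag."""
    return [
        Contig(seq=m.group(0), s=m.start() + 1, e=m.end(), t=tag,
               name=f"cng{tag}_{i}")
        for i, m in enumerate(_NONN_RE.finditer(cons))
    ]
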