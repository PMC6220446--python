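"""Hash-indexed exact read mapping (no mismatches, no indels).

A seed table maps every ``seed_len``-mer of the reference to its offsets;
candidate placements from a seed lookup are verified base-by-base over the
full read length, so results are independent of the seed length.  Reads are
classified as uniquely-exactly-mapped, multi-mapping, or unmapped; the
latter two form the leftover set R' handed to the inexact phase.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .core import AlignmentRecord, Genome, Read, ReadSet, revcomp

_ACGT = frozenset("ACGT")

DEFAULT_SEED_CAP = 21  # seed_len = min(k, 21) unless overridden


@dataclass
class ExactIndex:
    """Seed-offset table over one reference sequence."""

    ref: Genome
    seed_len: int
    table: dict[str, np.ndarray]

    def offsets(self, seed: str) -> np.ndarray:
        """Sorted 0-based offsets of exact forward occurrences of ``seed``."""
        return self.table.get(seed, _EMPTY)


_EMPTY = np.empty(0, dtype=np.int64)


def build_index(ref: Genome, seed_len: int) -> ExactIndex:
    """Index every seed_len-mer of the reference.

    Seeds containing 'N' or IUPAC letters are not indexed: an {A,C,G,T}
    read can never exact-match them.
    """
    if not 1 <= seed_len <= len(ref.seq):
        raise ValueError(
            f"seed_len must be in [1, {len(ref.seq)}], got {seed_len}"
        )
    seq = ref.seq
    table: dict[str, list[int]] = defaultdict(list)
    # offsets of non-ACGT characters, to skip tainted windows cheaply
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_acgt = (
        (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
    )
    # number of clean chars in each window of length seed_len
    clean = np.convolve(is_acgt.astype(np.int32), np.ones(seed_len, dtype=np.int32),
                        mode="valid") == seed_len
    for i in np.flatnonzero(clean):
        table[seq[i : i + seed_len]].append(int(i))
    return ExactIndex(
        ref=ref,
        seed_len=seed_len,
        table={s: np.asarray(v, dtype=np.int64) for s, v in table.items()},
    )


def _verify_hits(query: str, index: ExactIndex) -> list[int]:
    """Offsets where ``query`` equals the reference substring exactly."""
    s = index.seed_len
    if len(query) < s:
        raise ValueError(f"read length {len(query)} shorter than seed_len {s}")
    seq = index.ref.seq
    hits = []
    for off in index.offsets(query[:s]):
        off = int(off)
        if seq[off : off + len(query)] == query:
            hits.append(off)
    return hits


def locate_exact(read: str, index: ExactIndex) -> list[tuple[int, str]]:
    """All exact placements of ``read`` on either strand.

    Returns 1-based (pos, strand) sorted by pos then strand.  A palindromic
    read (equal to its own reverse complement) reports each physical locus
    once, on the canonical '+' strand.  Reads containing 'N' are
    unplaceable and return [].
    """
    if set(read) - _ACGT:
        return []
    hits = [(off + 1, "+") for off in _verify_hits(read, index)]
    rc = revcomp(read)
    if rc != read:  # palindrome: '-' hits duplicate the '+' set
        hits += [(off + 1, "-") for off in _verify_hits(rc, index)]
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


@dataclass
class ClassifiedReads:
    """Output of the exact phase: unique alignments plus the leftover set R'."""

    unique: list[AlignmentRecord]
    leftover: list[Read]
    multi_count: int = 0
    unmapped_count: int = 0

    @property
    def unique_count(self) -> int:
        return len(self.unique)


def classify_and_map(
    reads: ReadSet,
    index: ExactIndex,
    pair_rescue: bool = False,
    insert_max: int = 1000,
) -> ClassifiedReads:
    """Classify every single read: exactly one exact hit → unique alignment
    (cigar kM, nm=0); ≥2 hits → multi; 0 hits → unmapped.  Multi and
    unmapped reads land in the leftover list R'.

    Mates are classified independently.  With ``pair_rescue`` a multi-hit
    mate is promoted to unique when exactly one of its hits lies within
    ``insert_max`` of its uniquely-mapped mate.
    """
    k = reads.k
    unique: list[AlignmentRecord] = []
    leftover: list[Read] = []
    multi_count = unmapped_count = 0

    for rid, (r1, r2) in zip(reads.ids, reads.pairs):
        hit_lists = [locate_exact(r1, index), locate_exact(r2, index)]
        seqs = (r1, r2)
        if pair_rescue:
            for me, other in ((0, 1), (1, 0)):
                if len(hit_lists[me]) > 1 and len(hit_lists[other]) == 1:
                    anchor = hit_lists[other][0][0]
                    near = [h for h in hit_lists[me] if abs(h[0] - anchor) <= insert_max]
                    if len(near) == 1:
                        hit_lists[me] = near
        for mate, (seq, hits) in enumerate(zip(seqs, hit_lists), start=1):
            if len(hits) == 1:
                pos, strand = hits[0]
                unique.append(
                    AlignmentRecord(rid, mate, index.ref.name, pos, strand,
                                    f"{k}M", 0, "unique_exact", seq)
                )
            else:
                if hits:
                    multi_count += 1
                else:
                    unmapped_count += 1
                leftover.append(Read(rid, mate, seq))

    unique.sort(key=lambda a: (a.pos, a.strand, a.read_id, a.mate))
    return ClassifiedReads(unique, leftover, multi_count, unmapped_count)


# --- multi-sequence exact search (contig sets, masked regions) ---------------


@dataclass
class CompositeIndex:
    """Exact index over a set of sequences (e.g. a contig set).

    Sequences are joined with runs of 'N' (which no {A,C,G,T} read can
    span), indexed once, and hits mapped back to (sequence index, offset).
    """

    index: ExactIndex
    starts: np.ndarray  # start offset of each sequence in the joined string
    lengths: np.ndarray
    pad: int

    def locate(self, read: str) -> list[tuple[int, int, str]]:
        """All exact placements as (seq_idx, 1-based pos, strand)."""
        out = []
        for pos, strand in locate_exact(read, self.index):
            off = pos - 1
            idx = int(np.searchsorted(self.starts, off, side="right")) - 1
            out.append((idx, off - int(self.starts[idx]) + 1, strand))
        return out

    def n_hits(self, read: str) -> int:
        return len(self.locate(read))


def build_composite_index(
    seqs: list[str], seed_len: int, pad: int = 512, name: str = "composite"
) -> CompositeIndex:
    if not seqs:
        raise ValueError("cannot index an empty sequence set")
    sep = "N" * pad
    starts, lengths, pieces = [], [], []
    cursor = 0
    for s in seqs:
        starts.append(cursor)
        lengths.append(len(s))
        pieces.append(s)
        cursor += len(s) + pad
    joined = sep.join(pieces)
    # sequences shorter than seed_len cannot host a read of length >= seed_len
    index = build_index(Genome(name, joined), seed_len)
    return CompositeIndex(
        index=index,
        starts=np.asarray(starts, dtype=np.int64),
        lengths=np.asarray(lengths, dtype=np.int64),
        pad=pad,
    )
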