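"""Inexact alignment of leftover reads against the masked target regions.

A seed-and-extend aligner anchors exact seed hits (both strands) and runs a
windowed end-to-end alignment of the read (affine gaps, default match +1 /
mismatch -1 / gap open -2 / gap extend -1).  Alternatively a third-party
SAM aligned against the region set can be imported.  Per-region pileups
honouring the CIGAR (insertions between columns, deletions as gap
evidence) yield the inexact contig set Cng2 (origin tag t=2).
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam
from Bio import Align

from .core import AlignmentRecord, Contig, Genome, Read, revcomp
from .consensus import call_column

_ACGT = frozenset("ACGT")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass
class InexactParams:
    """Tunables of the seed-and-extend phase (all per-read-length k)."""

    seed_len: int | None = None  # default max(11, k // 5)
    max_mismatch_frac: float = 0.1
    max_gap: int = 3
    band: int = 5
    min_score_frac: float = 0.9
    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_mismatch_frac <= 1.0:
            raise ValueError("max_mismatch_frac must lie in [0, 1]")
        if self.band < self.max_gap:
            raise ValueError("band must be >= max_gap")

    def effective_seed_len(self, k: int) -> int:
        s = self.seed_len if self.seed_len is not None else max(11, k // 5)
        return min(s, k)


class InexactAligner:
    """Seed table over a region set plus a configured pairwise aligner."""

    def __init__(self, regions: list[Contig], params: InexactParams, k: int):
        self.regions = regions
        self.params = params
        self.k = k
        self.s = params.effective_seed_len(k)
        self.table: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for ridx, region in enumerate(regions):
            seq = region.seq
            for off in range(len(seq) - self.s + 1):
                seed = seq[off : off + self.s]
                if set(seed) <= _ACGT:
                    self.table[seed].append((ridx, off))
        pw = Align.PairwiseAligner(mode="global")
        pw.match_score = params.match
        pw.mismatch_score = params.mismatch
        pw.open_gap_score = params.gap_open
        pw.extend_gap_score = params.gap_extend
        # free end gaps on the window side only: the read aligns end-to-end
        pw.open_left_insertion_score = 0
        pw.extend_left_insertion_score = 0
        pw.open_right_insertion_score = 0
        pw.extend_right_insertion_score = 0
        self.pw = pw

    def _seed_offsets(self) -> list[int]:
        offs = list(range(0, self.k - self.s + 1, self.s))
        if offs[-1] != self.k - self.s:
            offs.append(self.k - self.s)
        return offs

    def _align_window(
        self, query: str, ridx: int, anchor: int
    ) -> list[tuple[float, int, str, int]]:
        """Align query end-to-end into a band-widened window around anchor.

        Returns (score, region_pos0, cigar, nm) tuples, one per co-optimal
        placement surviving the mismatch/gap limits.
        """
        p = self.params
        rseq = self.regions[ridx].seq
        ws = max(0, anchor - p.band)
        we = min(len(rseq), anchor + self.k + p.band)
        window = rseq[ws:we]
        if not window:
            return []
        results = []
        # enumerate co-optimal alignments (bounded): equal-scoring
        # placements inside one window are distinct hits
        for i, aln in enumerate(self.pw.align(query, window)):
            if i >= 8:
                break
            res = self._alignment_to_hit(aln, query, window, ws)
            if res is not None:
                results.append(res)
        return results

    def _alignment_to_hit(
        self, aln, query: str, window: str, ws: int
    ) -> tuple[float, int, str, int] | None:
        p = self.params
        t_blocks, q_blocks = aln.aligned
        if len(t_blocks) == 0:
            return None
        ops: list[tuple[int, str]] = []
        mismatches = 0
        prev_t, prev_q = t_blocks[0][0], q_blocks[0][0]
        if prev_t > 0:  # read bases before the first aligned block
            ops.append((int(prev_t), "I"))
        for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks):
            if t0 > prev_t:
                ops.append((int(t0 - prev_t), "I"))
            if q0 > prev_q:
                ops.append((int(q0 - prev_q), "D"))
            ops.append((int(t1 - t0), "M"))
            mismatches += sum(
                a != b for a, b in zip(query[t0:t1], window[q0:q1])
            )
            prev_t, prev_q = t1, q1
        if prev_t < len(query):
            ops.append((int(len(query) - prev_t), "I"))
        # merge adjacent same-op runs
        merged: list[tuple[int, str]] = []
        for length, op in ops:
            if merged and merged[-1][1] == op:
                merged[-1] = (merged[-1][0] + length, op)
            else:
                merged.append((length, op))
        # terminal indels cannot exist on a real reference: a read overhanging
        # the window end is soft-clipped (S), a terminal deletion is dropped
        while merged and merged[0][1] == "D":
            merged.pop(0)
        while merged and merged[-1][1] == "D":
            merged.pop()
        if merged and merged[0][1] == "I":
            merged[0] = (merged[0][0], "S")
        if merged and merged[-1][1] == "I":
            merged[-1] = (merged[-1][0], "S")
        if not any(op == "M" for _, op in merged):
            return None
        gap_bases = sum(l for l, op in merged if op in "ID")
        max_gap_run = max((l for l, op in merged if op in "ID"), default=0)
        if mismatches > p.max_mismatch_frac * self.k or max_gap_run > p.max_gap:
            return None
        cigar = "".join(f"{l}{op}" for l, op in merged)
        region_pos0 = ws + int(q_blocks[0][0])
        return float(aln.score), region_pos0, cigar, mismatches + gap_bases

    def align(self, read: Read) -> list[AlignmentRecord]:
        """All acceptable placements of one read, best (primary) first."""
        p = self.params
        queries = [(read.seq, "+")]
        rc = revcomp(read.seq)
        if rc != read.seq:
            queries.append((rc, "-"))
        candidates: set[tuple[int, int, str]] = set()
        for query, strand in queries:
            if set(query) - _ACGT:
                continue
            for off in self._seed_offsets():
                seed = query[off : off + self.s]
                for ridx, rpos in self.table.get(seed, ()):
                    candidates.add((ridx, rpos - off, strand))
        best: dict[tuple[int, int, str], tuple] = {}
        for ridx, anchor, strand in candidates:
            query = read.seq if strand == "+" else rc
            for score, pos0, cigar, nm in self._align_window(query, ridx, anchor):
                if score < p.min_score_frac * self.k * p.match:
                    continue
                key = (ridx, pos0, strand)
                if key not in best or best[key][0] < score:
                    best[key] = (score, cigar, nm)
        if not best:
            return [
                AlignmentRecord(read.read_id, read.mate, "", 0, "+", "", 0,
                                "unmapped", read.seq)
            ]
        ranked = sorted(
            best.items(),
            key=lambda kv: (-kv[1][0], kv[0][1], kv[0][2] != "+", kv[0][0]),
        )
        records = []
        for i, ((ridx, pos0, strand), (score, cigar, nm)) in enumerate(ranked):
            records.append(
                AlignmentRecord(
                    read_id=read.read_id,
                    mate=read.mate,
                    ref_name=self.regions[ridx].name,
                    pos=pos0 + 1,
                    strand=strand,
                    cigar=cigar,
                    nm=nm,
                    map_class="inexact",
                    seq=read.seq,
                    primary=(i == 0),
                )
            )
        return records


def align_inexact(
    read: Read | str, regions: list[Contig], params: InexactParams, k: int | None = None
) -> list[AlignmentRecord]:
    """One-shot alignment of a single read (see :class:`InexactAligner`)."""
    if isinstance(read, str):
        read = Read("read", 1, read)
    k = k if k is not None else len(read.seq)
    if len(read.seq) != k:
        raise ValueError(f"read length {len(read.seq)} != k={k}")
    return InexactAligner(regions, params, k).align(read)


def align_all(
    reads: list[Read], regions: list[Contig], params: InexactParams, k: int
) -> tuple[list[AlignmentRecord], dict[str, int]]:
    """Align a leftover read list; returns all records plus placement stats
    (unique/multi/unmapped counts on the restricted regions)."""
    aligner = InexactAligner(regions, params, k)
    records: list[AlignmentRecord] = []
    stats = {"unique": 0, "multi": 0, "unmapped": 0}
    for read in reads:
        recs = aligner.align(read)
        records.extend(recs)
        if recs[0].map_class == "unmapped":
            stats["unmapped"] += 1
        elif len(recs) > 1:
            stats["multi"] += 1
        else:
            stats["unique"] += 1
    return records, stats


def import_external_sam(
    path: str | Path, regions: list[Contig]
) -> list[AlignmentRecord]:
    """Import a third-party SAM aligned against the region set.

    Records are re-expressed in region coordinates with map_class=inexact;
    secondary and supplementary lines are dropped.  A reference name not
    matching any region identifier is an error.
    """
    known = {r.name for r in regions}
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_secondary or a.is_supplementary:
                continue
            mate = 2 if (a.flag & 0x80) else 1
            seq = a.query_sequence or ""
            if a.is_unmapped:
                records.append(
                    AlignmentRecord(a.query_name, mate, "", 0, "+", "", 0,
                                    "unmapped", seq)
                )
                continue
            if a.reference_name not in known:
                raise ValueError(
                    f"{path}: reference '{a.reference_name}' matches no "
                    f"region identifier"
                )
            strand = "-" if a.is_reverse else "+"
            if strand == "-" and seq:
                seq = revcomp(seq)
            nm = int(a.get_tag("NM")) if a.has_tag("NM") else 0
            records.append(
                AlignmentRecord(a.query_name, mate, a.reference_name,
                                a.reference_start + 1, strand,
                                a.cigarstring or "", nm, "inexact", seq)
            )
    return records


def build_cng2(
    alignments: list[AlignmentRecord],
    regions: list[Contig],
    mode: str = "v2",
    min_depth: int = 1,
    het_fraction: float = 0.25,
    min_alt_count: int = 2,
) -> list[Contig]:
    """Per-region CIGAR-aware pileup and consensus; break at 'N' into Cng2.

    A deletion column is dropped when deletion evidence strictly exceeds
    het_fraction of the column depth (ties favour the reference); an
    insertion is emitted between two called columns when its evidence
    exceeds the same threshold.  Resulting contigs carry t=2 and reference
    coordinates offset by their region's start.
    """
    by_region: dict[str, list[AlignmentRecord]] = defaultdict(list)
    region_map = {r.name: r for r in regions}
    for rec in alignments:
        if rec.map_class == "unmapped" or not rec.primary:
            continue
        if rec.ref_name not in region_map:
            raise ValueError(f"alignment references unknown region "
                             f"'{rec.ref_name}'")
        by_region[rec.ref_name].append(rec)

    contigs: list[Contig] = []
    n_out = 0
    for region in regions:
        recs = by_region.get(region.name)
        if not recs:
            continue
        L = len(region.seq)
        counts = np.zeros((4, L), dtype=np.int64)
        del_cnt = np.zeros(L, dtype=np.int64)
        ins_ev: dict[int, Counter] = defaultdict(Counter)
        base_idx = {b: i for i, b in enumerate("ACGT")}
        for rec in recs:
            bases = revcomp(rec.seq) if rec.strand == "-" else rec.seq
            qpos, rpos = 0, rec.pos - 1
            for length, op in _CIGAR_RE.findall(rec.cigar):
                length = int(length)
                if op in "M=X":
                    for j in range(length):
                        col = rpos + j
                        if 0 <= col < L:
                            b = bases[qpos + j]
                            if b in base_idx:
                                counts[base_idx[b], col] += 1
                    qpos += length
                    rpos += length
                elif op == "I":
                    if 0 <= rpos <= L:
                        ins_ev[rpos][bases[qpos : qpos + length]] += 1
                    qpos += length
                elif op == "D":
                    lo, hi = max(0, rpos), min(L, rpos + length)
                    del_cnt[lo:hi] += 1
                    rpos += length
                elif op == "S":
                    qpos += length

        # per-column calls, deletion-aware
        emitted: list[tuple[str, int | None]] = []  # (char, source column)
        for col in range(L):
            total = int(counts[:, col].sum() + del_cnt[col])
            if (
                total > 0
                and del_cnt[col] > het_fraction * total
                and del_cnt[col] >= min_alt_count
            ):
                continue  # deletion consensus: drop the column
            ch = call_column(counts[:, col], mode, min_depth, het_fraction,
                             min_alt_count)
            emitted.append((ch, col))
            if col + 1 in ins_ev:
                junction = ins_ev[col + 1]
                ins_seq, cnt = junction.most_common(1)[0]
                depth_here = int(counts[:, col].sum())
                if (cnt > het_fraction * max(depth_here, 1)
                        and cnt >= min_alt_count and ch != "N"):
                    for c in ins_seq:
                        emitted.append((c, None))

        # break at 'N' (insertions attach to their left called column)
        run: list[tuple[str, int | None]] = []
        for ch, col in emitted + [("N", None)]:
            if ch != "N":
                run.append((ch, col))
                continue
            real_cols = [c for _, c in run if c is not None]
            if real_cols:
                contigs.append(
                    Contig(
                        seq="".join(c for c, _ in run),
                        s=region.s + min(real_cols),
                        e=region.s + max(real_cols),
                        t=2,
                        name=f"cng2_{n_out}",
                    )
                )
                n_out += 1
            run = []
    return contigs
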