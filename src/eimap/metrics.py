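"""Assembly evaluation metrics: Contigs-500, N50, Errors, IUPAC-codes,
Genome-Fraction, Remapped-Reads and GC-content.

Error counting and genome fraction use *anchored* alignment: each contig is
aligned (unit-cost edit distance via edlib, semi-global) against the target
window around its own reference interval, widened by a margin.  The
pipeline tracks coordinates throughout, so no whole-genome aligner is
needed.  A contig IUPAC letter whose base set contains the target base
counts as correct.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

from .core import AMBIGUITY_LETTERS, IUPAC_TO_SET, Contig, Genome, ReadSet
from .exact_mapper import build_composite_index

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

# edlib equalities: ambiguity letter vs any base of its set; 'N' in either
# sequence never counts as an error column
_IUPAC_EQUALITIES = [
    (code, base)
    for code, s in IUPAC_TO_SET.items()
    if len(s) > 1 and code != "N"
    for base in s
] + [("N", c) for c in "ACGT" + "".join(sorted(AMBIGUITY_LETTERS))] + [("N", "N")]


@dataclass
class MetricsReport:
    contigs_500: int
    n50: int
    errors: int
    iupac_codes: int
    genome_fraction: float
    remapped_reads: float | None = None
    gc_content: float | None = None

    def as_dict(self) -> dict:
        return {
            "Contigs-500": self.contigs_500,
            "N50": self.n50,
            "Errors": self.errors,
            "IUPAC-codes": self.iupac_codes,
            "Genome-Fraction": self.genome_fraction,
            "Remapped-Reads": self.remapped_reads,
            "GC-content": self.gc_content,
        }


def n50(contigs: list[Contig]) -> int:
    """Smallest contig among the fewest largest ones jointly reaching half
    the total assembly length."""
    if not contigs:
        raise ValueError("N50 of an empty contig set is undefined")
    lengths = sorted((len(c) for c in contigs), reverse=True)
    half = sum(lengths) / 2
    acc = 0
    for length in lengths:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


def contigs_over(contigs: list[Contig], threshold: int = 500) -> int:
    """Number of contigs strictly longer than the threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return sum(1 for c in contigs if len(c) > threshold)


def iupac_count(contigs: list[Contig]) -> int:
    """Total IUPAC ambiguity letters (excluding 'N') across the set."""
    return sum(sum(c.seq.count(l) for l in AMBIGUITY_LETTERS) for c in contigs)


def gc_content(seq: str) -> float:
    """Percent G+C among unambiguous A/C/G/T bases."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("GC-content undefined: no A/C/G/T bases in input")
    return 100.0 * (seq.count("G") + seq.count("C")) / acgt


def _align_contig(contig: Contig, target: Genome, margin: int):
    """Edlib semi-global alignment of a contig against its anchored target
    window; returns (edit_distance, cigar, window_start, locations)."""
    ws = max(0, contig.s - 1 - margin)
    we = min(len(target.seq), contig.e + margin)
    window = target.seq[ws:we]
    if not window:
        raise ValueError(
            f"contig '{contig.name}' interval ({contig.s},{contig.e}) lies "
            f"outside the target"
        )
    res = edlib.align(contig.seq, window, mode="HW", task="path",
                      additionalEqualities=_IUPAC_EQUALITIES)
    return res["editDistance"], res["cigar"], ws, res["locations"]


def count_errors(
    contigs: list[Contig],
    target: Genome,
    margin: int = 300,
    per_event: bool = False,
) -> tuple[int, list[dict]]:
    """Mismatch plus indel errors of every contig against its target window.

    By default each gap column counts one error (an indel of length 3 = 3
    errors); ``per_event`` counts each contiguous indel run once instead.
    """
    total = 0
    breakdown = []
    for contig in contigs:
        if contig.s < 1 or contig.e < contig.s:
            raise ValueError(f"contig '{contig.name}' carries no valid "
                             f"coordinates")
        ed, cigar, _, _ = _align_contig(contig, target, margin)
        if per_event:
            mism = gaps = 0
            for length, op in _CIGAR_RE.findall(cigar):
                if op == "X":
                    mism += int(length)
                elif op in "ID":
                    gaps += 1
            errors = mism + gaps
        else:
            errors = ed
        total += errors
        breakdown.append({"name": contig.name, "errors": errors})
    return total, breakdown


def genome_fraction(
    contigs: list[Contig], target: Genome, margin: int = 300
) -> float:
    """Percent of the target (its non-'N' positions) covered by the union
    of aligned contig spans."""
    denom = len(target.seq) - target.seq.count("N")
    if denom == 0:
        raise ValueError("target genome has no non-'N' positions")
    spans = []
    for contig in contigs:
        _, _, ws, locations = _align_contig(contig, target, margin)
        if locations:
            start, end = locations[0]
            spans.append((ws + start, ws + end + 1))  # half-open
    covered = 0
    for s, e in _merge_spans(spans):
        # target 'N' positions are excluded from numerator and denominator
        covered += (e - s) - target.seq.count("N", s, e)
    return 100.0 * covered / denom


def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def remapped_reads(reads: ReadSet, contigs: list[Contig]) -> float:
    """Percent of single reads with at least one exact hit (either strand)
    on the contig set."""
    if not contigs:
        return 0.0
    k = reads.k
    index = build_composite_index(
        [c.seq for c in contigs], seed_len=min(k, 21)
    )
    hit = sum(1 for r in reads.reads() if index.n_hits(r.seq) > 0)
    return 100.0 * hit / reads.n_reads


def compute_report(
    contigs: list[Contig],
    target: Genome,
    reads: ReadSet | None = None,
    margin: int = 300,
    threshold: int = 500,
    per_event: bool = False,
) -> MetricsReport:
    """The full evaluation suite for one contig set."""
    errors, _ = count_errors(contigs, target, margin, per_event)
    return MetricsReport(
        contigs_500=contigs_over(contigs, threshold),
        n50=n50(contigs) if contigs else 0,
        errors=errors,
        iupac_codes=iupac_count(contigs),
        genome_fraction=genome_fraction(contigs, target, margin) if contigs else 0.0,
        remapped_reads=remapped_reads(reads, contigs) if reads is not None else None,
        gc_content=gc_content("".join(c.seq for c in contigs)) if contigs else None,
    )
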