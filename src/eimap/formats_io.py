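"""Reading and writing of FASTA, FASTQ and SAM plus the contig sidecar format.

FASTA/FASTQ parsing is delegated to Bio.SeqIO and SAM to pysam; this module
adds the pipeline's validation (alphabet, equal read lengths, paired record
counts) and the contig-FASTA header convention carrying ``s= e= t=`` tokens.
"""

from __future__ import annotations

import re
from pathlib import Path

import pysam
from Bio import SeqIO

from .core import VALID_LETTERS, AlignmentRecord, Contig, Genome, Read, ReadSet, revcomp


class FormatError(ValueError):
    """Raised on malformed or inconsistent input files."""


def _bad_char_line(path: str | Path, bad: set[str]) -> int:
    """1-based line number of the first sequence line holding a bad char."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad:
                return lineno
    return 0


def read_fasta(path: str | Path) -> list[Genome]:
    """Parse a (possibly multi-record, line-wrapped) FASTA file.

    Sequences are uppercased; any character outside {A,C,G,T,N}+IUPAC is a
    :class:`FormatError` naming the offending line.  'U' is rejected (DNA
    only).
    """
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    genomes = []
    for rec in records:
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_LETTERS
        if bad:
            lineno = _bad_char_line(path, bad)
            raise FormatError(
                f"{path}:{lineno}: illegal sequence character(s) "
                f"{sorted(bad)} in record '{rec.id}'"
            )
        if not seq:
            raise FormatError(f"{path}: record '{rec.id}' has empty sequence")
        genomes.append(Genome(rec.id, seq))
    return genomes


def write_fasta(genomes: list[Genome], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.name}\n")
            for i in range(0, len(g.seq), width):
                fh.write(g.seq[i : i + width] + "\n")


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> ReadSet:
    """Load two mate FASTQ files into a ReadSet.

    Record counts must match and every read must share one length k.
    Qualities are parsed and discarded — no stage of the pipeline consumes
    them.
    """
    recs1 = list(SeqIO.parse(str(path1), "fastq"))
    recs2 = list(SeqIO.parse(str(path2), "fastq"))
    if len(recs1) != len(recs2):
        raise FormatError(
            f"mate files disagree on record count: {len(recs1)} vs {len(recs2)}"
        )
    if not recs1:
        raise FormatError(f"{path1}: no FASTQ records found")
    k = len(recs1[0].seq)
    pairs, ids = [], []
    for r1, r2 in zip(recs1, recs2):
        s1, s2 = str(r1.seq).upper(), str(r2.seq).upper()
        if len(s1) != k or len(s2) != k:
            raise FormatError(
                f"read length mismatch: expected k={k}, "
                f"got {len(s1)}/{len(s2)} at record '{r1.id}'"
            )
        pairs.append((s1, s2))
        ids.append(re.sub(r"/[12]$", "", r1.id))
    return ReadSet(pairs=pairs, k=k, ids=ids)


def write_fastq(reads: list[Read], path: str | Path) -> None:
    """Write single reads as 4-line FASTQ with constant high quality."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}/{r.mate}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def write_readset_fastq(reads: ReadSet, path1: str | Path, path2: str | Path) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for rid, (r1, r2) in zip(reads.ids, reads.pairs):
            f1.write(f"@{rid}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{rid}/2\n{r2}\n+\n{'I' * len(r2)}\n")


# --- contig sidecar FASTA (headers carry s=/e=/t= key-value tokens) ---------

_TOKEN_RE = re.compile(r"(\w+)=(-?\d+)")


def write_contigs_fasta(contigs: list[Contig], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(contigs):
            name = c.name or f"contig{i}"
            fh.write(f">{name} s={c.s} e={c.e} t={c.t}\n")
            for j in range(0, len(c.seq), width):
                fh.write(c.seq[j : j + width] + "\n")


def read_contigs_fasta(path: str | Path) -> list[Contig]:
    contigs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = dict(_TOKEN_RE.findall(rec.description))
        if "s" not in tokens or "e" not in tokens:
            raise FormatError(
                f"{path}: contig '{rec.id}' lacks s=/e= coordinate tokens"
            )
        contigs.append(
            Contig(
                seq=str(rec.seq).upper(),
                s=int(tokens["s"]),
                e=int(tokens["e"]),
                t=int(tokens.get("t", 0)),
                name=rec.id,
            )
        )
    return contigs


# --- SAM ---------------------------------------------------------------------

_FLAG_PAIRED = 0x1
_FLAG_UNMAPPED = 0x4
_FLAG_REVERSE = 0x10
_FLAG_MATE1 = 0x40
_FLAG_MATE2 = 0x80
_FLAG_SECONDARY = 0x100


def write_sam(
    records: list[AlignmentRecord], refs: list[Genome], path: str | Path
) -> None:
    """Write records as plain-text SAM v1 with @HD/@SQ headers.

    map_class is encoded through FLAG bits: unmapped → 0x4; multi-mapping
    reads emit one primary line plus 0x100 secondaries; exactness is
    recoverable from the NM:i tag.  Minus-strand records store the reverse
    complement SEQ, per the SAM convention.
    """
    ref_names = {g.name for g in refs}
    for rec in records:
        if rec.map_class != "unmapped" and rec.ref_name not in ref_names:
            raise FormatError(f"record '{rec.read_id}' names unknown reference "
                              f"'{rec.ref_name}'")
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": g.name, "LN": len(g.seq)} for g in refs],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(header)
            a.query_name = rec.read_id
            flag = _FLAG_PAIRED | (_FLAG_MATE1 if rec.mate == 1 else _FLAG_MATE2)
            if rec.map_class == "unmapped":
                flag |= _FLAG_UNMAPPED
                a.flag = flag
                a.query_sequence = rec.seq or None
                out.write(a)
                continue
            if rec.strand == "-":
                flag |= _FLAG_REVERSE
            if rec.map_class == "multi" and not rec.primary:
                flag |= _FLAG_SECONDARY
            a.flag = flag
            a.reference_id = header.get_tid(rec.ref_name)
            a.reference_start = rec.pos - 1
            a.cigarstring = rec.cigar
            a.mapping_quality = 255
            if rec.seq:
                a.query_sequence = revcomp(rec.seq) if rec.strand == "-" else rec.seq
            a.set_tag("NM", rec.nm, "i")
            out.write(a)


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Read plain SAM back into AlignmentRecords (inverse of write_sam)."""
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            mate = 2 if (a.flag & _FLAG_MATE2) else 1
            seq = a.query_sequence or ""
            if a.is_unmapped:
                records.append(
                    AlignmentRecord(a.query_name, mate, "", 0, "+", "", 0,
                                    "unmapped", seq)
                )
                continue
            strand = "-" if a.is_reverse else "+"
            if strand == "-" and seq:
                seq = revcomp(seq)  # restore original read orientation
            nm = int(a.get_tag("NM")) if a.has_tag("NM") else 0
            records.append(
                AlignmentRecord(
                    read_id=a.query_name,
                    mate=mate,
                    ref_name=a.reference_name,
                    pos=a.reference_start + 1,
                    strand=strand,
                    cigar=a.cigarstring or "",
                    nm=nm,
                    map_class="inexact" if nm > 0 else "unique_exact",
                    seq=seq,
                    primary=not a.is_secondary,
                )
            )
    # any (read_id, mate) group holding a secondary line is multi-mapping
    multi_keys = {
        (r.read_id, r.mate) for r in records if not r.primary
    }
    for r in records:
        if (r.read_id, r.mate) in multi_keys:
            r.map_class = "multi"
    return records
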