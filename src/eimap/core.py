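"""Core domain objects and nucleotide-alphabet helpers shared by all stages.

Coordinates follow the SAM convention at every I/O boundary (1-based,
inclusive); internal computations use 0-based half-open offsets and convert
exactly once, in the function that crosses the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

# IUPAC ambiguity codes (2-, 3- and 4-base sets).  'N' is reserved for
# "uncalled/uncovered" throughout the pipeline.
IUPAC_TO_SET: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "M": frozenset("AC"),
    "R": frozenset("AG"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "Y": frozenset("CT"),
    "K": frozenset("GT"),
    "V": frozenset("ACG"),
    "H": frozenset("ACT"),
    "D": frozenset("AGT"),
    "B": frozenset("CGT"),
    "N": frozenset("ACGT"),
}
SET_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_SET.items()}

AMBIGUITY_LETTERS = frozenset("RYSWKMBDHV")
VALID_LETTERS = frozenset("ACGTN") | AMBIGUITY_LETTERS

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv",
    "TGCANYRSWMKVHDBtgcanyrswmkvhdb",
)


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware (R<->Y, K<->M, B<->V, D<->H)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """A named nucleotide sequence over {A,C,G,T,N} plus IUPAC letters."""

    name: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


class Read(NamedTuple):
    """One single read (one mate of a pair)."""

    read_id: str
    mate: int  # 1 | 2
    seq: str


@dataclass
class ReadSet:
    """An ordered set of paired reads, all of one fixed length k."""

    pairs: list[tuple[str, str]]
    k: int
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ids:
            self.ids = [f"read{i}" for i in range(len(self.pairs))]
        for r1, r2 in self.pairs:
            if len(r1) != self.k or len(r2) != self.k:
                raise ValueError(
                    f"all reads must have length k={self.k}; "
                    f"got lengths {len(r1)},{len(r2)}"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    def reads(self) -> Iterator[Read]:
        """Iterate single reads, mate 1 then mate 2 per pair."""
        for rid, (r1, r2) in zip(self.ids, self.pairs):
            yield Read(rid, 1, r1)
            yield Read(rid, 2, r2)

    @property
    def n_reads(self) -> int:
        return 2 * len(self.pairs)


@dataclass
class AlignmentRecord:
    """One read placement: the SAM-row abstraction used between stages.

    ``pos`` is the 1-based leftmost reference coordinate.  ``seq`` holds the
    read in its *original* orientation; minus-strand records contribute their
    reverse complement to the reference.
    """

    read_id: str
    mate: int
    ref_name: str
    pos: int
    strand: str  # '+' | '-'
    cigar: str
    nm: int
    map_class: str  # unique_exact | multi | inexact | unmapped
    seq: str = ""
    primary: bool = True


@dataclass
class Contig:
    """A contig ⟨D, s, e, t⟩: sequence plus its 1-based reference interval.

    t = 1 for exact-phase (Cng1) contigs, 2 for inexact-phase (Cng2)
    contigs, 0 for untagged intervals (mapping targets, final output).
    For t=1 the sequence is strictly positional (len == e-s+1); t=2 contigs
    may differ in length by net indels.
    """

    seq: str
    s: int
    e: int
    t: int = 0
    name: str = ""

    def __len__(self) -> int:
        return len(self.seq)
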