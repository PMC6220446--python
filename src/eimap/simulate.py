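"""Read and mutation simulator for pipeline fixtures and experiments.

Emulates DWGSIM/ART-style inputs at desk scale: a random genome, rate- or
count-driven mutation (SNVs, insertions, deletions) with a ground-truth
record list, and uniform-coverage paired reads with substitution
sequencing errors.  Event counts are deterministic (round(rate x length))
by default so that rate-derived counts are exact; a Bernoulli mode
restores stochastic counts.  Qualities are emitted constant — nothing in
the pipeline consumes them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Genome, ReadSet, revcomp

_BASES = np.array(list("ACGT"))


@dataclass
class MutationRecord:
    """One ground-truth edit on the input genome (1-based position).

    SNV: ref and alt are single differing bases.  INS: ref is empty, alt is
    inserted *after* position pos.  DEL: alt is empty, ref is the deleted
    base(s) starting at pos.
    """

    kind: str  # SNV | INS | DEL
    pos: int
    ref: str
    alt: str


@dataclass
class SimConfig:
    """Simulation parameters (rates are per-base probabilities)."""

    snv_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    read_len: int = 150
    coverage: float = 20.0
    error_rate: float = 0.0
    insert_mean: int = 400
    insert_sd: int = 50
    seed: int = 0
    n_snv: int | None = None  # explicit-count overrides (authoritative
    n_ins: int | None = None  # when rate x length does not reconcile with
    n_del: int | None = None  # a published count)
    bernoulli: bool = False
    indel_len: int = 1

    def __post_init__(self) -> None:
        for name in ("snv_rate", "ins_rate", "del_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.insert_mean < 2 * self.read_len:
            raise ValueError("insert_mean must be >= 2 x read_len")


def _round_count(x: float) -> int:
    return int(np.floor(x + 0.5))


def random_genome(length: int, gc: float = 0.5, seed: int = 0,
                  name: str = "sim") -> Genome:
    """I.i.d. random genome with P(G) + P(C) = gc."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(_BASES, size=length, p=p))
    return Genome(name, seq)


def mutate_genome(g: Genome, cfg: SimConfig) -> tuple[Genome, list[MutationRecord]]:
    """Apply SNV/INS/DEL events at the configured rates (or explicit counts).

    Event positions are drawn uniformly without replacement, so no two
    events share a position; SNV alternates are uniform over the three
    non-reference bases.  Records come back sorted by position and are a
    faithful diff: applying them to g reproduces the mutated genome.
    """
    rng = np.random.default_rng(cfg.seed)
    L = len(g.seq)

    def count(n_explicit: int | None, rate: float) -> int:
        if n_explicit is not None:
            return n_explicit
        if cfg.bernoulli:
            return int(rng.binomial(L, rate))
        return _round_count(rate * L)

    n_snv = count(cfg.n_snv, cfg.snv_rate)
    n_ins = count(cfg.n_ins, cfg.ins_rate)
    n_del = count(cfg.n_del, cfg.del_rate)
    total = n_snv + n_ins + n_del
    if total > L:
        raise ValueError(f"{total} events requested on a {L} bp genome")

    positions = rng.choice(L, size=total, replace=False)
    records: list[MutationRecord] = []
    cursor = 0
    for kind, n in (("SNV", n_snv), ("INS", n_ins), ("DEL", n_del)):
        for pos0 in sorted(int(p) for p in positions[cursor : cursor + n]):
            ref_base = g.seq[pos0]
            if kind == "SNV":
                choices = [b for b in "ACGT" if b != ref_base]
                alt = choices[int(rng.integers(3))] if ref_base in "ACGT" \
                    else str(rng.choice(list("ACGT")))
                records.append(MutationRecord("SNV", pos0 + 1, ref_base, alt))
            elif kind == "INS":
                ins = "".join(rng.choice(_BASES, size=cfg.indel_len))
                records.append(MutationRecord("INS", pos0 + 1, "", ins))
            else:
                records.append(MutationRecord("DEL", pos0 + 1, ref_base, ""))
        cursor += n
    records.sort(key=lambda r: r.pos)
    mutated = apply_mutations(g, records)
    return mutated, records


def apply_mutations(g: Genome, records: list[MutationRecord]) -> Genome:
    """Apply a sorted mutation record list to a genome (the faithful-diff
    companion of :func:`mutate_genome`)."""
    pieces: list[str] = []
    cursor = 0
    for rec in records:
        pos0 = rec.pos - 1
        if rec.kind == "SNV":
            pieces.append(g.seq[cursor:pos0])
            pieces.append(rec.alt)
            cursor = pos0 + 1
        elif rec.kind == "INS":
            pieces.append(g.seq[cursor : pos0 + 1])
            pieces.append(rec.alt)
            cursor = pos0 + 1
        else:  # DEL
            pieces.append(g.seq[cursor:pos0])
            cursor = pos0 + len(rec.ref)
    pieces.append(g.seq[cursor:])
    return Genome(f"{g.name}_mut", "".join(pieces))


def simulate_reads(g: Genome, cfg: SimConfig) -> ReadSet:
    """Uniform-coverage paired reads with substitution sequencing errors.

    Pair count = round(coverage x |g| / (2k)).  Fragment lengths are
    Normal(insert_mean, insert_sd) rounded and clamped to [2k, |g|]; mate 1
    is the fragment prefix, mate 2 the reverse complement of its suffix.
    """
    rng = np.random.default_rng(cfg.seed)
    k = cfg.read_len
    L = len(g.seq)
    if L < cfg.insert_mean + 4 * cfg.insert_sd:
        raise ValueError(
            f"genome length {L} < insert_mean + 4 x insert_sd "
            f"({cfg.insert_mean + 4 * cfg.insert_sd})"
        )
    n_pairs = _round_count(cfg.coverage * L / (2 * k))
    flens = np.clip(
        np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, size=n_pairs)),
        2 * k, L,
    ).astype(np.int64)
    starts = (rng.random(n_pairs) * (L - flens + 1)).astype(np.int64)

    pairs: list[tuple[str, str]] = []
    for start, flen in zip(starts, flens):
        frag_start, frag_end = int(start), int(start + flen)
        r1 = g.seq[frag_start : frag_start + k]
        r2 = revcomp(g.seq[frag_end - k : frag_end])
        if cfg.error_rate > 0:
            r1 = _inject_errors(r1, cfg.error_rate, rng)
            r2 = _inject_errors(r2, cfg.error_rate, rng)
        pairs.append((r1, r2))
    return ReadSet(pairs=pairs, k=k)


def _inject_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    mask = rng.random(len(read)) < rate
    if not mask.any():
        return read
    chars = list(read)
    for i in np.flatnonzero(mask):
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[int(rng.integers(3))]
    return "".join(chars)
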