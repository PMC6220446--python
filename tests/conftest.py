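"""Shared fixtures and randomized-instance helpers."""

from __future__ import annotations

import numpy as np
import pytest

from eimap.core import Contig, Genome


@pytest.fixture
def toy_genome() -> Genome:
    return Genome("g", "ACGTACGTTT")


def naive_locate(read: str, ref: str) -> list[tuple[int, str]]:
    """Brute-force both-strand exact scan (the oracle for locate_exact)."""
    from eimap.core import revcomp

    k = len(read)
    rc = revcomp(read)
    hits = []
    for off in range(len(ref) - k + 1):
        window = ref[off : off + k]
        if window == read:
            hits.append((off + 1, "+"))
        if rc != read and window == rc:
            hits.append((off + 1, "-"))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def random_merge_instance(
    rng: np.random.Generator,
) -> tuple[list[Contig], list[Contig], int]:
    """A random indel-free (Cng1, Cng2, k) instance obeying the pipeline's
    geometry: t=2 contigs bridge (or partially fill) gaps between t=1
    contigs, extending at most k columns into each neighbour."""

    def rand_seq(n: int) -> str:
        return "".join(rng.choice(list("ACGT"), size=n))

    k = int(rng.integers(2, 9))
    cng1: list[Contig] = []
    pos = 1 + int(rng.integers(0, 5))
    for _ in range(int(rng.integers(0, 5))):
        length = int(rng.integers(3, 15))
        cng1.append(Contig(rand_seq(length), pos, pos + length - 1, 1))
        pos += length + int(rng.integers(2, 25))

    cng2: list[Contig] = []
    # candidate gaps: before the first, between neighbours, after the last
    bounds: list[tuple[Contig | None, Contig | None]] = []
    if cng1:
        bounds.append((None, cng1[0]))
        bounds.extend(zip(cng1, cng1[1:]))
        bounds.append((cng1[-1], None))
    else:
        bounds.append((None, None))
    for prev, nxt in bounds:
        if rng.random() > 0.7:
            continue
        gs = (prev.e + 1) if prev else max(1, int(rng.integers(1, 6)))
        ge = (nxt.s - 1) if nxt else gs + int(rng.integers(2, 20))
        if ge < gs:
            continue
        if rng.random() < 0.7:  # bridge: span the gap, extend into flanks
            ext_l = int(rng.integers(0, min(k, len(prev.seq) - 1) + 1)) if prev else 0
            ext_r = int(rng.integers(0, min(k, len(nxt.seq) - 1) + 1)) if nxt else 0
            s2, e2 = gs - ext_l, ge + ext_r
        else:  # standalone: a sub-interval of the gap
            s2 = gs + int(rng.integers(0, max(ge - gs, 1)))
            e2 = s2 + int(rng.integers(0, ge - s2 + 1))
        cng2.append(Contig(rand_seq(e2 - s2 + 1), s2, e2, 2))
    return cng1, cng2, k


def paint_oracle(cng1: list[Contig], cng2: list[Contig]) -> str:
    """Positional merge oracle: paint contigs onto a reference canvas, t=1
    painted last (so exact territory wins and extensions are erased)."""
    contigs = cng1 + cng2
    if not contigs:
        return ""
    lo = min(c.s for c in contigs)
    hi = max(c.e for c in contigs)
    canvas = ["N"] * (hi - lo + 1)
    for c in cng2:
        for j, ch in enumerate(c.seq):
            canvas[c.s - lo + j] = ch
    for c in cng1:
        for j, ch in enumerate(c.seq):
            canvas[c.s - lo + j] = ch
    return "".join(canvas)


def planted_duplication_genome(
    seed: int, length: int = 3000, seg: int = 400, divergence: float = 0.0
) -> Genome:
    """Random genome with a (possibly diverged) duplicated segment."""
    from eimap.simulate import random_genome

    rng = np.random.default_rng(seed)
    base = random_genome(length, 0.5, seed=seed, name="dup")
    src = length // 6
    segment = list(base.seq[src : src + seg])
    n_div = int(divergence * seg)
    if n_div:
        for p in rng.choice(seg, size=n_div, replace=False):
            segment[p] = [b for b in "ACGT" if b != segment[p]][int(rng.integers(3))]
    insert_at = 2 * length // 3
    return Genome("dup", base.seq[:insert_at] + "".join(segment)
                  + base.seq[insert_at:])
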