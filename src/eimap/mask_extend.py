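"""Masking of covered territory and k-extension of the uncovered remainder.

C' shows exactly the parts of the input genome G that no exact contig
covered (everything the consensus called is masked to 'N'); G^M restores up
to k genome bases on each flank of every uncovered run, so that leftover
reads straddling a run boundary still fit.  Breaking G^M at 'N' yields the
mapping target regions for the inexact phase.  All "revealed" bases come
from G itself, never from the consensus.
"""

from __future__ import annotations

import re

import numpy as np

from .core import Contig, Genome

_NONN_RE = re.compile(r"[^N]+")


def mask_covered(g: Genome, cons: str) -> str:
    """Build C': 'N' wherever the consensus called a base (IUPAC included),
    the genome base wherever the consensus is 'N'."""
    if len(cons) != len(g.seq):
        raise ValueError(
            f"consensus length {len(cons)} != genome length {len(g.seq)}"
        )
    cons_arr = np.frombuffer(cons.encode(), dtype=np.uint8)
    g_arr = np.frombuffer(g.seq.encode(), dtype=np.uint8)
    out = np.where(cons_arr == ord("N"), g_arr, ord("N")).astype(np.uint8)
    return out.tobytes().decode()


def extend_uncovered(c_prime: str, g: Genome, k: int) -> str:
    """Build G^M: keep every base of C'; additionally reveal g_i at any 'N'
    position within distance ≤ k of a C' base.  Positions farther than k
    from every base stay 'N'."""
    if len(c_prime) != len(g.seq):
        raise ValueError(
            f"C' length {len(c_prime)} != genome length {len(g.seq)}"
        )
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n = len(c_prime)
    cp = np.frombuffer(c_prime.encode(), dtype=np.uint8)
    g_arr = np.frombuffer(g.seq.encode(), dtype=np.uint8)
    is_base = cp != ord("N")
    idx = np.arange(n)
    # distance to the nearest C' base on each side (n if none)
    last = np.where(is_base, idx, -1)
    np.maximum.accumulate(last, out=last)
    dist_left = np.where(last >= 0, idx - last, n)
    nxt = np.where(is_base[::-1], idx, -1)
    np.maximum.accumulate(nxt, out=nxt)
    dist_right = np.where(nxt >= 0, idx - nxt, n)[::-1]
    rescued = ~is_base & (np.minimum(dist_left, dist_right) <= k)
    out = np.where(is_base | rescued, np.where(is_base, cp, g_arr), ord("N"))
    return out.astype(np.uint8).tobytes().decode()


def regions_from_masked(g_m: str) -> list[Contig]:
    """Break G^M at every 'N': maximal N-free runs become untagged mapping
    regions with their 1-based reference intervals, ordered by start."""
    return [
        Contig(seq=m.group(0), s=m.start() + 1, e=m.end(), t=0,
               name=f"region{i}")
        for i, m in enumerate(_NONN_RE.finditer(g_m))
    ]


def uncovered_bed(c_prime: str) -> list[tuple[int, int]]:
    """Uncovered intervals of C' as 0-based half-open (BED) tuples."""
    return [(m.start(), m.end()) for m in _NONN_RE.finditer(c_prime)]
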