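"""Seed-and-extend alignment, SAM import, and the phase-2 consensus."""

import re

import numpy as np
import pytest

from eimap.core import AlignmentRecord, Contig, Genome, Read
from eimap.formats_io import write_sam
from eimap.inexact_mapper import (
    InexactParams,
    align_inexact,
    build_cng2,
    import_external_sam,
)

_CIG = re.compile(r"(\d+)([MIDS])")


def nw_affine(a: str, b: str, match=1, mism=-1, open_=-2, ext=-1) -> float:
    """Global affine-gap alignment score (first gap residue costs open_,
    each further residue ext) — the independent scoring oracle."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (b consumed)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_ + (i - 1) * ext
    for j in range(1, m + 1):
        Y[0][j] = open_ + (j - 1) * ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mism
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + ext,
                          Y[i - 1][j] + open_)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + ext,
                          X[i][j - 1] + open_)
    return max(M[n][m], X[n][m], Y[n][m])


def glocal_best(query: str, target: str) -> float:
    """Best query-global score over every substring of the target."""
    best = float("-inf")
    for s in range(len(target)):
        for e in range(s + 1, len(target) + 1):
            best = max(best, nw_affine(query, target[s:e]))
    return best


def _score_from_record(rec: AlignmentRecord) -> float:
    ops = [(int(l), op) for l, op in _CIG.findall(rec.cigar)]
    assert not any(op == "S" for _, op in ops)
    gap_bases = sum(l for l, op in ops if op in "ID")
    m_len = sum(l for l, op in ops if op == "M")
    mismatches = rec.nm - gap_bases
    score = (m_len - mismatches) - mismatches
    for l, op in ops:
        if op in "ID":
            score += -2 - (l - 1)
    return float(score)


class TestAlignInexact:
    def _params(self, **kw):
        defaults = dict(seed_len=3, band=5, max_gap=3, max_mismatch_frac=0.5,
                        min_score_frac=0.0)
        defaults.update(kw)
        return InexactParams(**defaults)

    def test_single_mismatch(self):
        region = [Contig("ACGT", 1, 4, 0, "r0")]
        recs = align_inexact("ACGA", region, self._params(seed_len=2))
        best = recs[0]
        assert (best.pos, best.cigar, best.nm) == (1, "4M", 1)

    def test_identity(self):
        region = [Contig("ACGT", 1, 4, 0, "r0")]
        best = align_inexact("ACGT", region, self._params(seed_len=2))[0]
        assert (best.pos, best.cigar, best.nm) == (1, "4M", 0)

    def test_length_precondition(self):
        region = [Contig("ACGT", 1, 4, 0, "r0")]
        with pytest.raises(ValueError):
            align_inexact("ACGGT", region, self._params(), k=4)

    def test_no_hit_yields_unmapped(self):
        region = [Contig("ACGTACGT", 1, 8, 0, "r0")]
        recs = align_inexact(
            "TTTTTTTT", region, self._params(min_score_frac=0.9)
        )
        assert len(recs) == 1 and recs[0].map_class == "unmapped"

    def test_oracle_equivalence_planted_instances(self):
        """Best seed-and-extend score equals exhaustive DP over all
        placements, on reads planted into small regions with interior
        substitution edits."""
        rng = np.random.default_rng(11)
        params = self._params()
        for _ in range(60):
            m = int(rng.integers(20, 41))
            region_seq = "".join(rng.choice(list("ACGT"), size=m))
            q = int(rng.integers(8, 13))
            off = int(rng.integers(0, m - q + 1))
            read = list(region_seq[off : off + q])
            for p in rng.choice(np.arange(3, q - 1),
                                size=int(rng.integers(0, 2)), replace=False):
                read[p] = [b for b in "ACGT" if b != read[p]][int(rng.integers(3))]
            read = "".join(read)
            region = [Contig(region_seq, 1, m, 0, "r0")]
            recs = align_inexact(read, region, params, k=q)
            assert recs[0].map_class != "unmapped"
            from eimap.core import revcomp

            oracle = max(glocal_best(read, region_seq),
                         glocal_best(revcomp(read), region_seq))
            assert _score_from_record(recs[0]) == oracle

    def test_primary_tie_breaks_leftmost(self):
        region = [Contig("ACGTACGT", 1, 8, 0, "r0")]
        recs = align_inexact("ACGT", region, self._params(seed_len=2))
        assert recs[0].primary and recs[0].pos == 1
        assert {r.pos for r in recs} == {1, 5}
        assert sum(r.primary for r in recs) == 1


class TestImportSam:
    def test_import_and_secondary_dropped(self, tmp_path):
        regions = [Contig("ACGTACGT", 11, 18, 0, "r1")]
        records = [
            AlignmentRecord("a", 1, "r1", 3, "+", "4M", 1, "multi", "GTAC",
                            primary=True),
            AlignmentRecord("a", 1, "r1", 5, "+", "4M", 1, "multi", "GTAC",
                            primary=False),
        ]
        path = tmp_path / "x.sam"
        write_sam(records, [Genome("r1", "ACGTACGT")], path)
        back = import_external_sam(path, regions)
        assert len(back) == 1
        assert (back[0].pos, back[0].map_class) == (3, "inexact")

    def test_unknown_region_rejected(self, tmp_path):
        regions = [Contig("ACGTACGT", 11, 18, 0, "r1")]
        rec = AlignmentRecord("a", 1, "zz", 3, "+", "4M", 0, "unique_exact",
                              "GTAC")
        path = tmp_path / "x.sam"
        write_sam([rec], [Genome("zz", "ACGTACGT")], path)
        with pytest.raises(ValueError, match="zz"):
            import_external_sam(path, regions)


class TestBuildCng2:
    def test_error_free_tiling(self):
        region = Contig("CCGGTT", 3, 8, 0, "region0")
        recs = [
            AlignmentRecord("a", 1, "region0", 1, "+", "4M", 0, "inexact",
                            "CCGG"),
            AlignmentRecord("b", 1, "region0", 2, "+", "4M", 0, "inexact",
                            "CGGT"),
            AlignmentRecord("c", 1, "region0", 3, "+", "4M", 0, "inexact",
                            "GGTT"),
        ]
        (c,) = build_cng2(recs, [region], "v2")
        assert (c.seq, c.s, c.e, c.t) == ("CCGGTT", 3, 8, 2)

    def test_empty_region_contributes_nothing(self):
        region = Contig("CCGGTT", 3, 8, 0, "region0")
        assert build_cng2([], [region], "v2") == []

    def test_unanimous_substitution_beats_region(self):
        region = Contig("CCGGTT", 3, 8, 0, "region0")
        recs = [
            AlignmentRecord(n, 1, "region0", 1, "+", "6M", 1, "inexact",
                            "CAGGTT")
            for n in "abc"
        ]
        (c,) = build_cng2(recs, [region], "v2")
        assert c.seq == "CAGGTT"

    def test_majority_deletion_shortens_contig(self):
        region = Contig("CCGGTT", 3, 8, 0, "region0")
        recs = [
            AlignmentRecord(n, 1, "region0", 1, "+", "2M1D3M", 1, "inexact",
                            "CCGTT")
            for n in "abc"
        ]
        (c,) = build_cng2(recs, [region], "v2")
        assert c.seq == "CCGTT"
        assert (c.s, c.e) == (3, 8)  # reference interval keeps the column

    def test_supported_insertion_lengthens_contig(self):
        region = Contig("CCGGTT", 3, 8, 0, "region0")
        recs = [
            AlignmentRecord(n, 1, "region0", 1, "+", "3M1I3M", 1, "inexact",
                            "CCGAGTT")
            for n in "abc"
        ]
        (c,) = build_cng2(recs, [region], "v2")
        assert c.seq == "CCGAGTT"
        assert (c.s, c.e) == (3, 8)
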