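"""Evaluation metrics: worked identities, IUPAC compatibility, anchored
alignment behaviour, and split invariance."""

import numpy as np
import pytest

from eimap.core import Contig, Genome, ReadSet
from eimap.metrics import (
    compute_report,
    contigs_over,
    count_errors,
    gc_content,
    genome_fraction,
    iupac_count,
    n50,
    remapped_reads,
)


def _contigs(lengths):
    pos = 1
    out = []
    for L in lengths:
        out.append(Contig("A" * L, pos, pos + L - 1, 1))
        pos += L + 1
    return out


class TestN50:
    def test_worked_example(self):
        assert n50(_contigs([5, 4, 3])) == 4

    def test_single_contig(self):
        assert n50(_contigs([17])) == 17

    def test_even_split(self):
        assert n50(_contigs([10, 10])) == 10

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            n50([])

    def test_brute_force_equivalence(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            lengths = rng.integers(1, 100, size=rng.integers(1, 20)).tolist()
            got = n50(_contigs(lengths))
            desc = sorted(lengths, reverse=True)
            total = sum(desc)
            acc = 0
            for L in desc:
                acc += L
                if 2 * acc >= total:
                    assert got == L
                    break


class TestContigsOver:
    def test_strict_boundary(self):
        assert contigs_over(_contigs([600, 501, 500, 100]), 500) == 2
        assert contigs_over(_contigs([500]), 500) == 0
        assert contigs_over([], 500) == 0


class TestErrors:
    def test_single_mismatch(self):
        t = Genome("t", "ACCT")
        assert count_errors([Contig("ACGT", 1, 4, 1)], t, margin=0)[0] == 1

    def test_deletion_column(self):
        t = Genome("t", "ACGGT")
        assert count_errors([Contig("ACGT", 1, 5, 1)], t, margin=0)[0] == 1

    def test_iupac_compatible_is_correct(self):
        t = Genome("t", "ACGT")
        assert count_errors([Contig("AMGT", 1, 4, 1)], t, margin=0)[0] == 0

    def test_iupac_incompatible_counts(self):
        t = Genome("t", "ATGT")  # 'M' = {A,C} does not contain T
        assert count_errors([Contig("AMGT", 1, 4, 1)], t, margin=0)[0] == 1

    def test_per_event_indel_counting(self):
        # one interior 3 bp deletion: 3 gap columns but a single event
        t = Genome("t", "AAAACGGGCAAAA")
        contig = [Contig("AAAACCAAAA", 1, 13, 1)]
        per_column = count_errors(contig, t, margin=0)[0]
        per_event = count_errors(contig, t, margin=0, per_event=True)[0]
        assert per_column == 3 and per_event == 1

    def test_margin_allows_anchor_slack(self):
        t = Genome("t", "TTTTACGTTTTT")
        # coordinates off by two; the margin window still finds the match
        assert count_errors([Contig("ACGT", 7, 10, 1)], t, margin=4)[0] == 0


class TestGenomeFraction:
    def test_half_covered(self):
        t = Genome("t", "ACGTACGT")
        assert genome_fraction([Contig("ACGT", 1, 4, 1)], t, margin=0) == 50.0

    def test_full_tiling(self):
        t = Genome("t", "ACGTACGT")
        contigs = [Contig("ACGT", 1, 4, 1), Contig("ACGT", 5, 8, 1)]
        assert genome_fraction(contigs, t, margin=0) == 100.0

    def test_overlap_union(self):
        t = Genome("t", "ACGTACGT")
        contigs = [Contig("ACGT", 1, 4, 1), Contig("GTAC", 3, 6, 1)]
        assert genome_fraction(contigs, t, margin=0) == 75.0

    def test_target_n_excluded_from_denominator(self):
        t = Genome("t", "ACGTNNNN")
        assert genome_fraction([Contig("ACGT", 1, 4, 1)], t, margin=0) == 100.0

    def test_split_invariance(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        t = Genome("t", seq)
        whole = [Contig(seq, 1, 300, 1)]
        cut = int(rng.integers(50, 250))
        split = [
            Contig(seq[:cut], 1, cut, 1),
            Contig(seq[cut:], cut + 1, 300, 1),
        ]
        assert genome_fraction(whole, t) == genome_fraction(split, t)
        assert count_errors(whole, t)[0] == count_errors(split, t)[0] == 0


class TestIupacAndGC:
    def test_iupac_count(self):
        assert iupac_count([Contig("ACMGR", 1, 5, 1)]) == 2
        assert iupac_count([Contig("ACGT", 1, 4, 1)]) == 0
        assert iupac_count([Contig("MMMM", 1, 4, 1)]) == 4

    def test_gc_examples(self):
        assert gc_content("GGCCAT") == pytest.approx(66.67, abs=0.01)
        assert gc_content("AT") == 0.0
        assert gc_content("GCN") == 100.0

    def test_gc_all_n_rejected(self):
        with pytest.raises(ValueError):
            gc_content("NNN")


class TestRemappedReads:
    def test_half_remapped(self):
        reads = ReadSet(pairs=[("ACGT", "TTTT")], k=4)
        contigs = [Contig("ACGTACGT", 1, 8, 1)]
        assert remapped_reads(reads, contigs) == 50.0

    def test_empty_contig_set(self):
        reads = ReadSet(pairs=[("ACGT", "TTTT")], k=4)
        assert remapped_reads(reads, []) == 0.0

    def test_all_substrings(self):
        reads = ReadSet(pairs=[("ACGT", "CGTA")], k=4)
        contigs = [Contig("ACGTACGT", 1, 8, 1)]
        assert remapped_reads(reads, contigs) == 100.0


def test_report_assembles_all_metrics():
    t = Genome("t", "ACGTACGT")
    contigs = [Contig("ACGT", 1, 4, 1), Contig("ACGT", 5, 8, 1)]
    reads = ReadSet(pairs=[("ACGT", "TACG")], k=4)
    rep = compute_report(contigs, t, reads=reads, margin=0)
    assert rep.contigs_500 == 0
    assert rep.n50 == 4
    assert rep.errors == 0
    assert rep.genome_fraction == 100.0
    # mate 2 spans the junction between the two contigs, so only mate 1
    # remaps exactly
    assert rep.remapped_reads == 50.0
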