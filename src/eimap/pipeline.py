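"""End-to-end orchestration of the three pipeline phases.

ExactMapping (hash-based exact placement + consensus + Cng1) →
InExactMapping (masking, k-extension, seed-and-extend alignment of the
leftover reads, Cng2) → MergingContigs (coordinate-based merge, break at
'N').  Also hosts the multi-mapping-reduction diagnostic (leftover reads'
exact multi-hit rate on the whole genome vs on the restricted regions) and
a single-pass best-hit baseline for comparison experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .consensus import build_pileup, call_consensus, contigs_from_consensus
from .core import AlignmentRecord, Contig, Genome, Read, ReadSet
from .exact_mapper import (
    DEFAULT_SEED_CAP,
    ClassifiedReads,
    build_composite_index,
    build_index,
    classify_and_map,
    locate_exact,
)
from .formats_io import (
    write_contigs_fasta,
    write_fasta,
    write_fastq,
    write_sam,
)
from .inexact_mapper import (
    InexactParams,
    align_all,
    build_cng2,
    import_external_sam,
)
from .mask_extend import extend_uncovered, mask_covered, regions_from_masked
from .merge import (
    MergedSequence,
    final_contigs,
    interleave,
    merge_contigs,
    normalize_cng2,
)
from .metrics import MetricsReport, compute_report


@dataclass
class PipelineConfig:
    mode: str = "v2"  # v1: ambiguity -> 'N'; v2: ambiguity -> IUPAC code
    seed_len: int | None = None  # exact-phase seed length, min(k, 21)
    min_depth: int = 1
    het_fraction: float = 0.25
    min_alt_count: int = 2
    inexact: InexactParams = field(default_factory=InexactParams)
    external_sam: str | None = None
    pair_rescue: bool = False
    outdir: str | None = None
    seed: int = 0
    margin: int | None = None  # metrics anchor margin, default 2k

    def __post_init__(self) -> None:
        if self.mode not in ("v1", "v2"):
            raise ValueError(f"mode must be 'v1' or 'v2', got '{self.mode}'")


@dataclass
class PipelineResult:
    final_contigs: list[Contig]
    merged: MergedSequence
    cng1: list[Contig]
    cng2: list[Contig]
    regions: list[Contig]
    classified: ClassifiedReads
    consensus: str
    metrics: MetricsReport | None
    diagnostics: dict


def run_eim(
    ref: Genome,
    reads: ReadSet,
    cfg: PipelineConfig | None = None,
    target: Genome | None = None,
) -> PipelineResult:
    """Run the full pipeline; metrics are computed against ``target`` when
    given (falling back to the input genome).  Intermediates are written
    under ``cfg.outdir`` when set.  The pipeline proper is deterministic —
    randomness exists only in the simulator.
    """
    cfg = cfg or PipelineConfig()
    k = reads.k
    seed_len = cfg.seed_len if cfg.seed_len is not None else min(k, DEFAULT_SEED_CAP)

    # --- phase 1: exact mapping and consensus -------------------------------
    index = build_index(ref, seed_len)
    classified = classify_and_map(reads, index, pair_rescue=cfg.pair_rescue)
    pileup = build_pileup(classified.unique, ref)
    cons = call_consensus(
        pileup, ref, cfg.mode, cfg.min_depth, cfg.het_fraction, cfg.min_alt_count
    )
    cng1 = contigs_from_consensus(cons, tag=1)

    # --- phase 2: mask, extend, inexact mapping -----------------------------
    c_prime = mask_covered(ref, cons)
    g_m = extend_uncovered(c_prime, ref, k)
    regions = regions_from_masked(g_m)

    stats = {"unique": 0, "multi": 0, "unmapped": 0}
    if cfg.external_sam is not None:
        inexact_records = import_external_sam(cfg.external_sam, regions)
    elif regions and classified.leftover:
        inexact_records, stats = align_all(
            classified.leftover, regions, cfg.inexact, k
        )
    else:
        inexact_records = []
    cng2 = build_cng2(
        inexact_records, regions, cfg.mode, cfg.min_depth, cfg.het_fraction,
        cfg.min_alt_count,
    )

    # --- phase 3: merge ------------------------------------------------------
    merged = merge_contigs(interleave(cng1, normalize_cng2(cng2, cng1, k)), k)
    contigs = final_contigs(merged)

    eval_genome = target if target is not None else ref
    margin = cfg.margin if cfg.margin is not None else 2 * k
    metrics = (
        compute_report(contigs, eval_genome, reads=reads, margin=margin)
        if contigs
        else None
    )

    pct_whole, pct_regions = multimapping_report(
        classified.leftover, ref, regions, seed_len=seed_len,
        whole_index=index,
    )
    diagnostics = {
        "reads_total": reads.n_reads,
        "unique_exact": classified.unique_count,
        "multi": classified.multi_count,
        "unmapped": classified.unmapped_count,
        "pct_exact_mapped": 100.0 * classified.unique_count / max(reads.n_reads, 1),
        "regions": len(regions),
        "inexact_unique": stats["unique"],
        "inexact_multi": stats["multi"],
        "inexact_unmapped": stats["unmapped"],
        "pct_multi_whole": pct_whole,
        "pct_multi_regions": pct_regions,
    }

    if cfg.outdir is not None:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_sam(classified.unique, [ref], out / "exact.sam")
        write_fastq([r for r in classified.leftover if r.mate == 1],
                    out / "R_prime_1.fq")
        write_fastq([r for r in classified.leftover if r.mate == 2],
                    out / "R_prime_2.fq")
        write_fasta([Genome("consensus", cons)], out / "C.fa")
        write_contigs_fasta(regions, out / "regions.fa")
        write_contigs_fasta(cng1, out / "cng1.fa")
        write_contigs_fasta(cng2, out / "cng2.fa")
        write_contigs_fasta(contigs, out / "eim_contigs.fa")

    return PipelineResult(
        final_contigs=contigs,
        merged=merged,
        cng1=cng1,
        cng2=cng2,
        regions=regions,
        classified=classified,
        consensus=cons,
        metrics=metrics,
        diagnostics=diagnostics,
    )


def multimapping_report(
    leftover: list[Read],
    ref: Genome,
    regions: list[Contig],
    seed_len: int | None = None,
    whole_index=None,
) -> tuple[float, float]:
    """Percent of leftover reads with >= 2 exact hits on the whole genome vs
    on the restricted region set.  Restriction can only remove candidate
    loci, so the second number never exceeds the first."""
    if not leftover:
        return 0.0, 0.0
    k = len(leftover[0].seq)
    seed_len = seed_len if seed_len is not None else min(k, DEFAULT_SEED_CAP)
    if whole_index is None:
        whole_index = build_index(ref, seed_len)
    region_index = (
        build_composite_index([r.seq for r in regions], seed_len)
        if regions
        else None
    )
    multi_whole = multi_regions = 0
    for read in leftover:
        if len(locate_exact(read.seq, whole_index)) >= 2:
            multi_whole += 1
        if region_index is not None and region_index.n_hits(read.seq) >= 2:
            multi_regions += 1
    n = len(leftover)
    return 100.0 * multi_whole / n, 100.0 * multi_regions / n


def single_pass_baseline(
    ref: Genome,
    reads: ReadSet,
    params: InexactParams | None = None,
    mode: str = "v2",
    min_depth: int = 1,
    het_fraction: float = 0.25,
    min_alt_count: int = 2,
) -> list[Contig]:
    """One-pass best-hit mapping baseline: every read is placed once on the
    whole genome (exact where possible, ties broken leftmost, otherwise its
    best inexact alignment) and a single consensus is called and broken at
    'N'.  This is the conventional mapper-consensus route the two-phase
    pipeline is compared against."""
    params = params or InexactParams()
    k = reads.k
    index = build_index(ref, min(k, DEFAULT_SEED_CAP))
    whole_region = [Contig(seq=ref.seq, s=1, e=len(ref.seq), t=0, name="whole")]
    from .inexact_mapper import InexactAligner  # local to avoid cycle at import

    aligner = InexactAligner(whole_region, params, k)
    placements: list[AlignmentRecord] = []
    for read in reads.reads():
        hits = locate_exact(read.seq, index)
        if hits:
            pos, strand = hits[0]  # best-hit: leftmost on ties
            placements.append(
                AlignmentRecord(read.read_id, read.mate, "whole", pos, strand,
                                f"{k}M", 0, "inexact", read.seq)
            )
            continue
        recs = aligner.align(read)
        if recs[0].map_class != "unmapped":
            placements.append(recs[0])
    contigs = build_cng2(
        placements, whole_region, mode, min_depth, het_fraction, min_alt_count
    )
    for c in contigs:
        c.t = 0
    return contigs


def single_pass_consensus(
    ref: Genome,
    reads: ReadSet,
    params: InexactParams | None = None,
    mode: str = "v2",
) -> tuple[Genome, list[Contig]]:
    """Single-pass baseline consensus as a reference-length genome.

    Runs :func:`single_pass_baseline` and paints its contigs onto an 'N'
    canvas of reference length (coordinates are positional; the rare contig
    with net indels shifts its own tail only).  The painted genome is the
    conventional mapper-reconstructed consensus — exactly what the v2
    configuration substitutes for the raw reference as pipeline input.
    """
    contigs = single_pass_baseline(ref, reads, params, mode)
    canvas = ["N"] * len(ref.seq)
    for c in contigs:
        start = c.s - 1
        for j, ch in enumerate(c.seq):
            if start + j < len(canvas):
                canvas[start + j] = ch
    return Genome(f"{ref.name}_cns", "".join(canvas)), contigs
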