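# Methods

This note documents the model behind `eimap`, its tunable parameters, the
simulator's scope, and the numerical/design choices made where the
procedure left room.

## Model and assumptions

The pipeline reconstructs a target genome from short paired reads and a
*related* reference *G*. Its premise is that reads come in two kinds:
*exact* reads, which match the reference verbatim at exactly one locus, and
*inexact* reads, which either carry differences (variant alleles,
sequencing errors) or match at several loci (repeats). Exact reads are
placed by hashing with full-length verification; everything they cover is
then **excluded** from the search space of the inexact pass, which sees
only the uncovered runs of the reference extended by one read length *k*
per side. The extension is what lets a leftover read straddling a coverage
boundary still align end-to-end. Because the regions are genuine substrings
of *G*, any exact hit a leftover read has on a region it also has on *G* —
restriction can only remove candidate loci, never add them. This is the
mechanism by which multi-mapping ambiguity shrinks, and it is asserted as
an invariant (`pct_multi_regions <= pct_multi_whole`) rather than assumed.

Assumptions inherited from the model:

- all reads have one fixed length *k* (enforced at I/O);
- the reference and target are colinear (no structural rearrangements) —
  contigs carry reference intervals and the merge trusts them;
- base qualities carry no information the pipeline uses (they are parsed
  and ignored);
- mates are classified independently in the exact phase; pairing is only
  used by the optional `pair_rescue` heuristic (off by default), which
  promotes a multi-hit mate when exactly one hit lies within an insert
  length of its uniquely-placed mate.

## Consensus calling

A pileup column with depth *d* below `min_depth` (default 1, i.e. only
zero-coverage) is `N`. Otherwise the qualifying set *M* holds every base
with count ≥ `het_fraction`·*d* (default 0.25); a base that is not the
column maximum must additionally have at least `min_alt_count` = 2
observations, so a single stray read never creates ambiguity. |M| = 1 gives
that base; |M| ≥ 2 gives the IUPAC code of *M* in v2 mode and `N` in v1
mode. v1 additionally writes `N` wherever the *reference itself* holds an
IUPAC letter; v2 calls such positions from the pileup like any other. The
bare threshold rule and the `min_alt_count` guard are both exposed: with
`min_alt_count=1` the column {A:3, C:1} calls `M`, with the default it
calls `A`. The defaults emulate the diploid-style ambiguity emission of a
`bcftools call --keep-masked-ref`-style consensus without reimplementing
it; they are deliberate stand-ins, tunable on every surface (library, CLI).

Phase-2 consensus is CIGAR-aware and may change length: a deletion column
is dropped when deletion evidence strictly exceeds `het_fraction` of the
column depth (ties favour the reference) and reaches `min_alt_count`; an
insertion between two called columns is emitted under the mirrored rule.
Terminal indels cannot exist against a real reference, so the aligner
soft-clips a read overhanging a region boundary instead of emitting
terminal insertions — without this, several overhanging reads "insert" the
true genome continuation that the neighbouring exact contig already covers,
duplicating bases at every junction.

## Inexact aligner

Seed-and-extend: exact seeds of length `max(11, k/5)` (capped at *k*) taken
every seed-length along the read, both strands, anchor a windowed
end-to-end alignment (window = anchor ± `band`, default 5) under affine
scoring (match +1, mismatch −1, gap open −2, gap extend −1 — Bowtie2-like
end-to-end sensitivity at desk scale). Placements scoring at least
`min_score_frac` (0.9) of the perfect score *k* are kept, subject to
`max_mismatch_frac` (0.1·k) and `max_gap` (3) filters; co-optimal
placements within one window are enumerated (bounded) so tied loci are all
reported. The primary placement is the best score, ties broken by leftmost
position then '+' strand. Only primary alignments feed the pileup. A
third-party SAM aligned against the emitted regions can replace the
internal aligner (`import_external_sam`); secondary and supplementary
lines are dropped.

## Merge

Contigs merge by coordinates only — positions relative to *G* are known, so
no overlap alignment is needed. Exact contigs are inserted whole; an
inexact contig is trimmed by `min(k, overlap)` reference columns against
the previously emitted interval on its left and against the next exact
contig's interval on its right (its extensions were added toward exact
territory by construction, so `overlap = k` whenever a full flank existed);
reference gaps bridged by nothing are filled with `N` so the final breaking
reproduces the true fragmentation. Trim lengths count reference columns and
are approximated by sequence-length trims when a phase-2 contig carries net
indels.

One geometry needs preprocessing: two uncovered runs closer than 2*k* merge
into a single mapping region (a direct consequence of the extension rule),
so an inexact contig can contain — or overlap by more than *k* — the short
exact contig that sat between the runs, violating the strictly-increasing
start/end order the merge recursion requires. `normalize_cng2` restores the
invariant before interleaving: exact territory wins, inexact contigs are
split around contained exact contigs and clipped so that no overlap with an
exact interval exceeds *k*. The strict contract (and its error behaviour)
is preserved for direct API use; an indel-free merge is verified against an
independent positional oracle (paint inexact contigs on a reference canvas,
paint exact contigs last) on randomized instances.

## Metrics

Errors and Genome-Fraction use *anchored* alignment: each contig is aligned
semi-globally (contig global, window flanks free) against the target window
`[s − margin, e + margin]`, `margin` defaulting to 2*k*. This replaces a
whole-genome aligner and is exact at the scales the pipeline tracks, since
every contig carries its interval. Unit-cost edit distance equals mismatch
columns + gap columns, which is the default error count (an indel of length
3 = 3 errors); `per_event` counts each indel run once instead — the
published convention is ambiguous between the two, so both are provided
with per-column as default. A contig IUPAC letter whose base set contains
the target base counts as correct (otherwise every reported ambiguity would
double-count as an IUPAC *and* an error). Genome-Fraction's denominator
excludes target `N` positions. Remapped-Reads re-uses the exact mapper with
the contig set as reference: the percentage of single reads with at least
one exact hit.

## Simulator

The generator emulates DWGSIM/ART-style inputs: i.i.d. random genomes with
a GC parameter; SNV/insertion/deletion mutation with a ground-truth record
list (a faithful diff — re-applying the records reproduces the mutated
genome); uniform-coverage paired reads (pair count = coverage·|G|/2k,
fragment length Normal(`insert_mean`=400, `insert_sd`=50) clamped to
[2k, |G|]; mate 2 is the reverse complement of the fragment suffix) with
per-base substitution errors. Event counts are deterministic
(`round(rate × length)`) so rate-derived counts are exact — at the 4,639,675
bp scale an SNV rate of 0.1% yields exactly 4640 records; `--bernoulli`
restores stochastic counts, and explicit `--n-snv/--n-ins/--n-del`
overrides exist because published indel counts do not always reconcile with
their nominal rates. Insert-size defaults are typical of Illumina
TruSeq-like libraries; qualities are constant.

What the simulator does **not** model: coverage bias (GC or otherwise),
indel sequencing errors, quality-profile decay along the read, PCR
duplicates, adapter contamination, or structural variation. Passing tests
therefore demonstrate the pipeline's behaviour under uniform coverage with
substitution-only noise; on real libraries, coverage troughs would enlarge
the uncovered runs and shift work toward the inexact phase.

## Study-condition experiments

Problem sizes were chosen so that each experiment exercises the full
pipeline while completing in seconds: the end-to-end recovery run uses a
50 kb genome with 0.1% SNVs and 50× error-free 150 bp reads against the
unmutated reference; the search-space restriction experiment uses one
hundred 3.4 kb genomes each carrying a 400 bp duplication diverged by 2%,
with 8× 60 bp reads at 1% error; the baseline comparison uses ten 22 kb
genomes with a 2 kb duplication diverged by 1%, 0.1% target SNVs, and 30×
150 bp reads at 0.2% error.

In the baseline comparison, EIM(v2) runs in the configuration the method is
designed for: the single-pass best-hit consensus (the conventional
mapper-reconstruction route, `single_pass_consensus`) serves as the
pipeline's *input genome*, and both reconstructions are scored against the
target. Run instead on the raw reference, the exact phase can be poisoned
by cross-mapped unique-exact reads from the diverged duplicate — a read
whose true locus differs from the reference by a variant may match the
other copy verbatim — fixing wrong alleles at columns the inexact phase
never revisits; feeding the mapper consensus removes precisely this failure
mode, which is why that substitution is part of the method.

## Known limitations

- The exact mapper holds its seed table in memory as a Python dict; fine to
  tens of megabases, not engineered for mammalian genomes.
- Coordinate-based merging requires colinearity; an inversion or
  translocation between reference and target would merge incorrectly
  rather than fail loudly.
- Phase-2 contig intervals after indels are positional approximations;
  merge trims by sequence length in that case.
- The v1/v2 switch governs consensus emission only; reads never
  exact-match IUPAC letters, so with an ambiguity-rich input genome those
  positions always fall to the inexact phase.
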