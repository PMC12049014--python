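# Methods

## Pipeline model

rhtmap maps one read at a time through four stages: (1) window indexing,
(2) seed voting, (3) candidate extension and anchor chaining, (4) exact
base-level alignment and best-hit selection.  The design assumes long
(kilobase-scale) reads whose middle `L_win/2` bases are representative of
the whole molecule — a single mid-read seed locates the candidate windows
and the base-level DP does the rest.  Both read orientations are searched
independently (seed, candidates, alignment) and the higher-scoring
placement wins; ties prefer the forward strand, then the lower reference
coordinate, so output is deterministic.

### Indexing

Windows start at every multiple of `L_win/2`, are clamped at the reference
end, and are dropped only when shorter than `k` (they could not host a
k-mer); every reference base is therefore covered by at least one window.
Reference k-mers are sampled every `k` bases *within each window* — the
sampling grid restarts at each window start, so the two windows covering a
position sample different phases.  Duplicate (k-mer, window) occurrences
are retained so seed votes reflect multiplicity.  The dense PointerList
needs `4^k + 1` int32 slots (268 MiB at `k = 13`); a guard rejects k that
would exceed a configurable memory cap.  The index file (versioned, custom
format) also stores the reference sequence so alignment needs no separate
FASTA.

### Scoring scheme

| parameter | default | meaning |
|---|---|---|
| match / mismatch | +2 / −4 | substitution scores (any pair involving N scores mismatch) |
| p_o, p_e | 4, 2 | first affine piece: short-gap open/extend |
| p_o', p_e' | 24, 1 | second piece: long-gap open/extend |

A gap of length `l` costs `min{p_o + l·p_e, p_o' + l·p_e'}`; the pieces
cross at `l = 20` under the defaults.  These are the conventional
parameters for insertion-dominated SMRT error profiles, and everything is
configurable.  `H` maximizes over the diagonal move and all four gap
states; restricting the maximization to the first piece only
(`strict_eq1=True`) is kept for comparison, because under that restriction
the stated two-piece gap cost is not attainable.  Scores are integers
throughout so cross-implementation equality is exact, and the
impossible-state sentinel (−2²⁸) is far enough from the int32 limit that
repeated penalty subtraction cannot underflow.

### Wavefront layout

The anti-diagonal implementation re-indexes cells by `r = i + j, t = i`.
All cells of diagonal `r` are independent and are updated with bulk
elementwise operations over contiguous lane buffers; the `(r−1, t−1)` and
`(r−2, t−1)` accesses are one-lane shifts, realized as offset views into
the previous-diagonal buffers (the public `lane_shift` primitive documents
the contract: element 0 receives an explicit fill value, everything else
moves up one slot).  Undefined lanes are filled with the sentinel, not 0,
preserving exact global-alignment semantics at the borders.  Diagonals are
scattered into ordinary row–column matrices so that a single traceback
routine serves both implementations — which also makes the five-matrix
equality between layouts directly testable.

### Traceback and piecewise alignment

Traceback ties prefer M over D over I, and gap extension over re-opening;
CIGARs are therefore deterministic.  Within a candidate region, anchors
(exact shared k-mers) are chained by DP over the collinearity DAG: an edge
`u → v` exists when `v` starts at or after `u`'s end on both sequences,
anchors reward `k·match`, and an edge costs the gap penalty of the offset
difference.  Chain ties prefer more anchors, then the earliest anchors in
(read, reference) order.  Anchors become exact M runs; head, inter-anchor
and tail pairs are aligned globally with the wavefront DP.  Because the
candidate region is deliberately larger than the read, the unused flank
appears as a leading/trailing deletion run: those runs are trimmed, the
alignment start is shifted accordingly, and the score is recomputed from
the trimmed path, turning the global region alignment into a read-glocal
one.  The tail piece is aligned on reversed sequences so that, among
equal-score paths, surplus flank settles into a trailing run the trim can
remove (scores are invariant under simultaneous reversal).  This
global-plus-trim construction is a heuristic: a lucky flank match can
still absorb part of the flank into the alignment, which slightly shifts
the reported start without affecting the audited DP scores.

### Candidate extension

Candidates are extended by `L_ext` (default 400 bp) on both sides.  When
the read length is known, the extension grows by the read's expected
overhang past its seed window, `max(0, (|read| − L_win/2)/2)`: the seed
sits in the middle of the read, so a read longer than the window
necessarily continues beyond it, and with a fixed 400 bp extension reads
over ≈ `L_win` cannot be contained by any candidate region — their
placement then shifts by up to half the overhang.  The bare `L_ext`
behaviour remains available by omitting the read length.

### MAPQ

MAPQ is the score gap between the best placement and the best placement at
a *distinct* locus (start positions more than `L_win/2` apart), capped at
60.  Overlapping candidate windows rediscovering the same placement do not
count as competitors; a read with no distinct competitor gets 60.  This is
a package convention, not a calibrated error probability.

## Scheduler

Byte ranges are half-open.  `static_split` uses the floor convention
`[⌊V·i/p⌋, ⌊V·(i+1)/p⌋)`; `refine_split` advances every start to the next
record head (a `@` line whose `+` line follows two lines later and whose
quality line matches the sequence length — the length check guards against
`@` opening a quality string) and sets each end to the successor's start.
The ILB plan statically splits the first `⌊α·n⌋` records by bytes and
batches the remainder; batches are served from a single shared queue in
file order.  Workers are threads in one process: the distribution
semantics (static share first, then batch pulling) are exactly preserved,
per-worker wall times feed the `S_p`/`E_p` metrics, and results are
re-ordered by input index before SAM emission, so output is independent of
`p` and of batch interleaving.  Wall-clock speedups measured through this
pool reflect scheduling only, not parallel compute, and are reported but
never asserted.  The communication cost model is analytic: blocking
`2·O_c + (D_send+D_recv)/G + T_cpu`, non-blocking the same with `T_dev`,
and the overlapped short-to-accelerator assignment `O_c + T_send + T_dev +
O_c + T_recv`; transfer volume grows as `L²` (the DP matrix), which is why
assigning long reads to the accelerator class inflates every term.

## Synthetic data

`simdata` emulates a PacBio-CLR-like channel: uniform i.i.d. reference,
read origins uniform, lengths truncated-normal (default 3000 ± 500 bp,
floor 50), per-base substitution/insertion/deletion rates 0.02/0.09/0.04
(≈15% total, insertion-dominated), half the reads reverse-complemented,
constant quality strings (the pipeline never reads qualities).  Everything
is deterministic given the seed.  It does **not** model: non-uniform base
composition or repeats (so seed voting faces fewer decoys than a real
genome), length–quality correlation, burst indels, or chimeric molecules.
Passing the mapping-recall tests therefore demonstrates the machinery on
clean geometry, not genome-scale specificity.

## Problem sizes and verification

The standard study conditions used by the tests and `scripts/acceptance.py`
are a 100 kb reference with the default index (k = 13, L_win = 2048) and
200 reads per condition — large enough that every pipeline stage
(including multi-window candidates, reverse strand and decoy windows) is
exercised, while a full audited run stays within minutes on one CPU.  The
wavefront implementation is verified three ways: five-matrix equality and
score/CIGAR equality against the row–column reference (exhaustive tiny
pairs, seeded random pairs, random schemes); score equality of both
implementations against an O(n³) oracle that enumerates every gap length
explicitly; and a per-invocation audit during full pipeline runs
(`DPAudit`), whose exact-agreement percentage is the DP-exactness recall
the evaluation reports.  The row–column reference's fill loop is
numba-compiled for speed but keeps strict row-major order, so it shares no
update-order logic with the lane implementation it checks.

## Known limitations

Single-contig references (the first FASTA record is indexed); one primary
placement per read — no secondary/supplementary records, split reads or
chimera handling; no banding in the DP (full matrices, memory ≈ 5·L_t·L_q
int32); MAPQ is uncalibrated; the scheduler models distribution semantics,
not real multi-node transport.
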