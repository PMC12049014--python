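"""Per-read mapping: anchors, collinear chaining, piecewise base-level
alignment of candidate regions, best-hit selection and SAM emission.

Within each candidate region, exact shared k-mers between region and read
become anchors; a sparse DP over the anchor DAG (edges only between
collinear, non-overlapping anchors) picks the best chain; anchors become
exact match runs and each inter-anchor gap pair — plus the head and tail
flanks — is aligned globally with the wavefront DP.  Candidate regions are
deliberately larger than the read (L_ext padding), so leading/trailing
target-gap runs produced by the flanks are trimmed rather than penalized,
turning the global region alignment into a read-glocal one.

Both read orientations are searched; the global best wins (ties prefer the
forward strand, then the lower reference start).  MAPQ is the best-vs-
second-best score gap capped at 60.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .align_core import (
    AlignmentResult,
    Cigar,
    ScoringScheme,
    align_antidiag,
    gap_cost,
    rowcol_score,
    score_cigar,
    _merge_runs,
)
from .io_formats import SamRecord, SequenceRecord, reverse_complement
from .rht_index import RegionalHashTable, base_codes, rolling_kmer_codes
from .seed_extend import CandidateRegion, MapParams, count_window_hits, extract_seed


@dataclass(frozen=True)
class Anchor:
    read_pos: int
    ref_pos: int
    length: int


@dataclass
class AnchorChain:
    anchors: list[Anchor]
    chain_score: int


@dataclass
class MappedRead:
    read_id: str
    best: Optional[AlignmentResult]
    region: Optional[CandidateRegion]
    strand: str
    sam_pos: int  # 1-based; 0 when unmapped
    mapq: int
    is_mapped: bool


class DPAudit:
    """Counts base-level DP invocations and how many of the wavefront
    scores agree with the independent row-column (SWG-role) score."""

    def __init__(self, scheme: ScoringScheme):
        import threading

        self.scheme = scheme
        self.total = 0
        self.exact = 0
        self._lock = threading.Lock()

    def record(self, target: str, query: str, wavefront_score: int) -> None:
        ok = rowcol_score(target, query, self.scheme) == wavefront_score
        with self._lock:
            self.total += 1
            if ok:
                self.exact += 1

    @property
    def recall_pct(self) -> float:
        return 100.0 * self.exact / self.total if self.total else 0.0


def find_anchors(region: str, read: str, k: int) -> list[Anchor]:
    """All (read_pos, ref_pos) pairs sharing an exact N-free k-mer,
    sorted by (read_pos, ref_pos)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rvals, rvalid = rolling_kmer_codes(base_codes(region), k)
    kmer_positions: dict[int, list[int]] = {}
    for pos in np.flatnonzero(rvalid):
        kmer_positions.setdefault(int(rvals[pos]), []).append(int(pos))
    qvals, qvalid = rolling_kmer_codes(base_codes(read), k)
    anchors: list[Anchor] = []
    for qpos in np.flatnonzero(qvalid):
        positions = kmer_positions.get(int(qvals[qpos]))
        if positions:
            anchors.extend(Anchor(int(qpos), rp, k) for rp in positions)
    return anchors


def chain_anchors(anchors: list[Anchor], s: ScoringScheme) -> AnchorChain:
    """Best collinear chain by sparse DP over the anchor DAG.

    Edges run u -> v only when v starts at or after u's end on both
    sequences; each anchor is rewarded k*match and an edge costs
    gap_cost(|dread - dref|) when the inter-anchor offsets differ.  Ties
    prefer chains with more anchors, then the earliest anchors in
    (read_pos, ref_pos) order.
    """
    if not anchors:
        return AnchorChain([], 0)
    n = len(anchors)
    k = anchors[0].length
    rp = np.array([a.read_pos for a in anchors], dtype=np.int64)
    fp = np.array([a.ref_pos for a in anchors], dtype=np.int64)
    reward = k * s.match
    dp = np.zeros(n, dtype=np.int64)
    cnt = np.zeros(n, dtype=np.int64)
    parent = np.full(n, -1, dtype=np.int64)
    for j in range(n):
        dp[j] = reward
        cnt[j] = 1
        valid = (rp[:j] + k <= rp[j]) & (fp[:j] + k <= fp[j])
        if valid.any():
            dr = rp[j] - (rp[:j] + k)
            df = fp[j] - (fp[:j] + k)
            delta = np.abs(dr - df)
            cost = np.where(
                delta > 0,
                np.minimum(s.p_o + delta * s.p_e, s.p_o2 + delta * s.p_e2),
                0,
            )
            cand = np.where(valid, dp[:j] - cost, np.int64(-(1 << 60)))
            best = int(cand.max())
            if best >= 0:  # attaching never loses; on a tie prefer more anchors
                sel = np.flatnonzero(cand == best)
                sel = sel[cnt[sel] == cnt[sel].max()]
                pick = int(sel[0])
                dp[j] = reward + best
                cnt[j] = cnt[pick] + 1
                parent[j] = pick
    end = int(np.lexsort((np.arange(n), -cnt, -dp))[0])
    chain: list[Anchor] = []
    node = end
    while node != -1:
        chain.append(anchors[node])
        node = int(parent[node])
    chain.reverse()
    return AnchorChain(chain, int(dp[end]))


def _align_piece(
    target: str,
    query: str,
    s: ScoringScheme,
    audit: Optional[DPAudit],
    reverse: bool = False,
) -> Cigar:
    """Globally align one gap pair.  Tail flank pieces are aligned on the
    reversed sequences (and the CIGAR reversed back) so that, among
    equal-score paths, surplus target flank settles into a trailing run the
    caller can trim; the score is unaffected."""
    if not target and not query:
        return []
    if not target:
        return [(len(query), "I")]
    if not query:
        return [(len(target), "D")]
    if reverse:
        target, query = target[::-1], query[::-1]
    res = align_antidiag(target, query, s)
    if audit is not None:
        audit.record(target, query, res.score)
    return res.cigar[::-1] if reverse else res.cigar


def align_candidate(
    region: str,
    read: str,
    chain: AnchorChain,
    s: ScoringScheme,
    audit: Optional[DPAudit] = None,
) -> AlignmentResult:
    """Piecewise base-level alignment of a read against a candidate region.

    Chained anchors become exact M runs; head, inter-anchor and tail pairs
    are aligned globally; leading/trailing D runs (unused region flank) are
    trimmed and the target span adjusted, and the score is recomputed from
    the trimmed path so flanks are never penalized.
    """
    k = chain.anchors[0].length if chain.anchors else 0
    for a in chain.anchors:
        if a.read_pos + a.length > len(read) or a.ref_pos + a.length > len(region):
            raise ValueError("chain anchor outside region/read bounds")
    pieces: Cigar = []
    if not chain.anchors:
        pieces = _align_piece(region, read, s, audit)
    else:
        first = chain.anchors[0]
        pieces.extend(
            _align_piece(region[: first.ref_pos], read[: first.read_pos], s, audit)
        )
        for u, v in zip(chain.anchors, chain.anchors[1:]):
            pieces.append((k, "M"))
            pieces.extend(
                _align_piece(
                    region[u.ref_pos + k : v.ref_pos],
                    read[u.read_pos + k : v.read_pos],
                    s,
                    audit,
                )
            )
        last = chain.anchors[-1]
        pieces.append((k, "M"))
        pieces.extend(
            _align_piece(
                region[last.ref_pos + k :],
                read[last.read_pos + k :],
                s,
                audit,
                reverse=True,
            )
        )
    cigar = _merge_runs(pieces)
    t_start, t_end = 0, len(region)
    if cigar and cigar[0][1] == "D":
        t_start = cigar[0][0]
        cigar = cigar[1:]
    if cigar and cigar[-1][1] == "D":
        t_end -= cigar[-1][0]
        cigar = cigar[:-1]
    score = score_cigar(cigar, region[t_start:t_end], read, s) if cigar else 0
    return AlignmentResult(
        score=score, cigar=cigar, t_span=(t_start, t_end), q_span=(0, len(read))
    )


def map_read(
    rht: RegionalHashTable,
    reference: SequenceRecord,
    read: SequenceRecord,
    params: MapParams = MapParams(),
    audit: Optional[DPAudit] = None,
) -> MappedRead:
    """Map one read: seed, count window hits, align the candidate regions of
    both orientations, and keep the best-scoring result."""
    from .seed_extend import select_candidates

    ref_seq = reference.sequence
    k = rht.params.k
    scored: list[tuple[int, int, int, CandidateRegion, str, AlignmentResult]] = []
    for strand_rank, (strand, read_seq) in enumerate(
        (("+", read.sequence), ("-", reverse_complement(read.sequence)))
    ):
        oriented = SequenceRecord(id=read.id, sequence=read_seq)
        seed = extract_seed(oriented, rht.params)
        hits = count_window_hits(rht, seed)
        candidates = select_candidates(
            hits, params, rht, strand, read_length=len(read_seq)
        )
        for cand in candidates:
            region = ref_seq[cand.ref_start : cand.ref_end]
            anchors = find_anchors(region, read_seq, k)
            chain = chain_anchors(anchors, params.scoring)
            res = align_candidate(region, read_seq, chain, params.scoring, audit)
            scored.append(
                (res.score, strand_rank, cand.ref_start, cand, strand, res)
            )
    if not scored:
        return MappedRead(read.id, None, None, "+", 0, 0, False)
    scored.sort(key=lambda x: (-x[0], x[1], x[2]))
    best_score, _, _, best_cand, best_strand, best_res = scored[0]
    sam_pos = best_cand.ref_start + best_res.t_span[0] + 1
    # MAPQ from the score gap to the best alignment at a *distinct* locus;
    # overlapping candidate windows rediscovering the same placement do not
    # count as competitors
    second = None
    for sc, _, _, cand, _, res in scored[1:]:
        start = cand.ref_start + res.t_span[0] + 1
        if abs(start - sam_pos) > rht.params.L_win // 2:
            second = sc
            break
    mapq = 60 if second is None else min(60, max(0, best_score - second))
    return MappedRead(
        read_id=read.id,
        best=best_res,
        region=best_cand,
        strand=best_strand,
        sam_pos=sam_pos,
        mapq=mapq,
        is_mapped=True,
    )


def to_sam_record(
    mapped: MappedRead,
    read: SequenceRecord,
    reference_name: str,
    read_index: int = 0,
) -> SamRecord:
    """Build the SAM record for a mapped (or unmapped) read."""
    qual = read.quality if read.quality else "*"
    if not mapped.is_mapped:
        return SamRecord(
            qname=read.id,
            flag=0x4,
            rname="*",
            pos=0,
            mapq=0,
            cigar="*",
            seq=read.sequence,
            qual=qual,
            read_index=read_index,
        )
    if mapped.strand == "-":
        seq = reverse_complement(read.sequence)
        qual = qual[::-1] if qual != "*" else "*"
        flag = 0x10
    else:
        seq = read.sequence
        flag = 0
    assert mapped.best is not None
    return SamRecord(
        qname=read.id,
        flag=flag,
        rname=reference_name,
        pos=mapped.sam_pos,
        mapq=mapped.mapq,
        cigar=mapped.best.cigar_string(),
        seq=seq,
        qual=qual,
        score=mapped.best.score,
        read_index=read_index,
    )
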