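"""Seed extraction, per-window k-mer hit counting and candidate selection.

One seed of length L_win/2 is taken from the middle of each read (the whole
read when shorter).  Every overlapping k-mer of the seed (step 1 on the read
side, to maximize sensitivity) is looked up in the regional hash table and
each returned window id increments that window's tally.  The N_top windows
with the most hits become candidate regions after extension by L_ext on
both sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align_core import ScoringScheme
from .io_formats import SequenceRecord
from .rht_index import IndexParams, RegionalHashTable, base_codes, rolling_kmer_codes


@dataclass(frozen=True)
class Seed:
    read_id: str
    seed_sequence: str
    offset_in_read: int


@dataclass(frozen=True)
class CandidateRegion:
    window_id: int
    hit_count: int
    ref_start: int  # extension-clamped, 0-based
    ref_end: int  # exclusive
    strand: str  # '+' or '-'


@dataclass(frozen=True)
class MapParams:
    """Mapping-stage knobs: N_top candidate windows (default 5), L_ext
    extension in bp (default 400), the short/long read threshold used by the
    scheduler's non-equal distribution (default 1024 bp), and the scoring
    scheme."""

    N_top: int = 5
    L_ext: int = 400
    nesd_threshold: int = 1024
    scoring: ScoringScheme = field(default_factory=ScoringScheme)

    def __post_init__(self) -> None:
        if self.N_top < 1:
            raise ValueError("N_top must be >= 1")
        if self.L_ext < 0:
            raise ValueError("L_ext must be >= 0")


def extract_seed(read: SequenceRecord, params: IndexParams) -> Seed:
    """Seed of length min(L_win/2, |read|) centered in the read
    (left-biased when the surplus is odd)."""
    if not read.sequence:
        raise ValueError("read is empty")
    seed_len = min(params.L_win // 2, len(read.sequence))
    offset = (len(read.sequence) - seed_len) // 2
    return Seed(
        read_id=read.id,
        seed_sequence=read.sequence[offset : offset + seed_len],
        offset_in_read=offset,
    )


def count_window_hits(rht: RegionalHashTable, seed: Seed) -> dict[int, int]:
    """Tally, per reference window, how many seed k-mers hit it.

    Every overlapping seed k-mer (N-containing ones skipped) contributes
    one count to every window occurrence the index returns for its code.
    """
    k = rht.params.k
    codes = base_codes(seed.seed_sequence)
    vals, valid = rolling_kmer_codes(codes, k)
    if not vals.size:
        return {}
    hits: list[np.ndarray] = []
    ptr = rht.pointer_list
    wl = rht.window_list
    for code in vals[valid]:
        lo, hi = ptr[code], ptr[code + 1]
        if hi > lo:
            hits.append(wl[lo:hi])
    if not hits:
        return {}
    counts = np.bincount(np.concatenate(hits), minlength=rht.n_windows)
    nz = np.flatnonzero(counts)
    return {int(w): int(counts[w]) for w in nz}


def effective_extension(read_length: int, params: MapParams, index: IndexParams) -> int:
    """Candidate extension that also covers the read's overhang beyond its
    seed.  The seed (length L_win/2) lands inside the hit window, but the
    read extends ~(|read| - L_win/2)/2 beyond it on each side; without this
    term reads longer than the window cannot be placed accurately."""
    overhang = max(0, (read_length - index.L_win // 2 + 1) // 2)
    return params.L_ext + overhang


def select_candidates(
    hits: dict[int, int],
    params: MapParams,
    rht: RegionalHashTable,
    strand: str = "+",
    read_length: int | None = None,
) -> list[CandidateRegion]:
    """Top-N_top windows by (hit count desc, window id asc), extended and
    clamped to the reference.  With a read_length the extension grows by
    the read's expected overhang past the seed window; otherwise the bare
    L_ext is used."""
    if read_length is None:
        ext = params.L_ext
    else:
        ext = effective_extension(read_length, params, rht.params)
    ranked = sorted(hits.items(), key=lambda kv: (-kv[1], kv[0]))[: params.N_top]
    regions = []
    for wid, count in ranked:
        start, end = rht.window_span(wid)
        regions.append(
            CandidateRegion(
                window_id=wid,
                hit_count=count,
                ref_start=max(0, start - ext),
                ref_end=min(rht.ref_length, end + ext),
                strand=strand,
            )
        )
    return regions
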