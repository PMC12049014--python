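"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the recurrence structure of the implementations
they check: the alignment oracle enumerates every gap length explicitly
through the 2-piece gap cost (O(n^3)), and the index oracle re-extracts
step-k k-mers from every window by plain string slicing.
"""

from __future__ import annotations

import numpy as np

from rhtmap import ScoringScheme, gap_cost
from rhtmap.rht_index import IndexParams, RegionalHashTable, encode_kmer, partition_windows


def gap_enumeration_score(target: str, query: str, s: ScoringScheme) -> int:
    """Optimal global score with explicit enumeration of every gap length."""
    Lt, Lq = len(target), len(query)
    ninf = -(10**9)
    H = np.full((Lt + 1, Lq + 1), ninf, dtype=np.int64)
    H[0, 0] = 0
    for i in range(Lt + 1):
        for j in range(Lq + 1):
            if i == 0 and j == 0:
                continue
            best = ninf
            if i > 0 and j > 0:
                mat = (
                    s.match
                    if target[i - 1] == query[j - 1] and target[i - 1] in "ACGT"
                    else s.mismatch
                )
                best = H[i - 1, j - 1] + mat
            for g in range(1, i + 1):
                best = max(best, H[i - g, j] - gap_cost(g, s))
            for g in range(1, j + 1):
                best = max(best, H[i, j - g] - gap_cost(g, s))
            H[i, j] = best
    return int(H[Lt, Lq])


def brute_force_window_lists(reference: str, params: IndexParams) -> dict[int, list[int]]:
    """code -> window ids by re-extracting step-k k-mers from every window."""
    out: dict[int, list[int]] = {}
    for w in partition_windows(len(reference), params):
        for off in range(0, (w.end - w.start) - params.k + 1, params.step):
            code = encode_kmer(reference[w.start + off : w.start + off + params.k])
            if code is not None:
                out.setdefault(code, []).append(w.window_id)
    return out


def random_dna(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))
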