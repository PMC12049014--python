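"""Exact global alignment under a 2-piece affine gap penalty.

A gap of length k costs min{p_o + k*p_e, p_o2 + k*p_e2}: the first affine
piece prices short gaps, the second (high open, cheap extend) prices the
long indels typical of SMRT reads, approximating a concave gap cost.  The
dynamic program keeps five matrices: H (best score), E/E2 (gaps consuming
target bases, one per affine piece) and F/F2 (gaps consuming query bases).
H maximizes over the diagonal move and all four gap states; the
``strict_eq1`` flag restricts the maximization to E and F only, for
comparison (under that restriction the stated two-piece gap cost is not
attainable).

Two independent implementations fill the same recurrences:

* :func:`align_rowcol` — plain row-by-row, column-by-column order (the
  Smith-Waterman-Gotoh-style reference; its inner loop is numba-compiled).
* :func:`align_antidiag` — the wavefront layout.  Cells are reindexed by
  r = i + j, t = i so that every cell of an anti-diagonal r depends only on
  diagonals r-1 and r-2; a diagonal is then updated with bulk elementwise
  numpy operations on contiguous arrays plus :func:`lane_shift` (the
  abstract form of a SIMD byte shift).

Scores are integers throughout so exact equality between the two layouts is
well defined.  Boundary and out-of-band lanes hold a large negative
sentinel (not zero), preserving exact global-alignment semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .rht_index import base_codes

#: impossible-state sentinel; far below any reachable score yet safe from
#: int32 underflow after repeated penalty subtraction
NEG_INF = -(1 << 28)

Cigar = list[tuple[int, str]]


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch scores and the two affine gap pieces.

    Defaults (2, -4, 4/2, 24/1) are the conventional two-piece parameters
    for PacBio-style noisy reads; the second piece makes long indels cheap
    to extend once opened.
    """

    match: int = 2
    mismatch: int = -4
    p_o: int = 4
    p_e: int = 2
    p_o2: int = 24
    p_e2: int = 1
    neg_inf: int = NEG_INF

    def __post_init__(self) -> None:
        if self.p_e <= 0 or self.p_e2 <= 0:
            raise ValueError("gap extension penalties must be positive")
        if self.p_o < 0 or self.p_o2 < 0:
            raise ValueError("gap open penalties must be non-negative")
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")


def gap_cost(length: int, s: ScoringScheme) -> int:
    """Cost of a gap of the given length: the cheaper of the two pieces."""
    if length < 1:
        raise ValueError("gap length must be >= 1")
    return min(s.p_o + length * s.p_e, s.p_o2 + length * s.p_e2)


def lane_shift(values: np.ndarray, fill: int) -> np.ndarray:
    """Shift a lane vector one position toward higher indices.

    result[0] = fill and result[i] = values[i-1]; the vector analogue of a
    one-element logical shift of a SIMD register.
    """
    out = np.empty_like(values)
    if out.size:
        out[0] = fill
        out[1:] = values[:-1]
    return out


@dataclass
class AlignmentResult:
    """Global alignment score, CIGAR and aligned spans.

    CIGAR ops: M (match or mismatch column), I (query-only base),
    D (target-only base).
    """

    score: int
    cigar: Cigar
    t_span: tuple[int, int]
    q_span: tuple[int, int]

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for n, op in self.cigar) if self.cigar else "*"


@dataclass
class DPStateDiag:
    """The five DP matrices with diagonal addressing.

    ``diagonal(r)`` returns the H/E/F/E2/F2 values of anti-diagonal
    r = i + j indexed by t = i; cell (r, t) equals row-column cell
    (i=t, j=r-t).
    """

    H: np.ndarray
    E: np.ndarray
    F: np.ndarray
    E2: np.ndarray
    F2: np.ndarray

    @property
    def L_t(self) -> int:
        return self.H.shape[0] - 1

    @property
    def L_q(self) -> int:
        return self.H.shape[1] - 1

    def diagonal(self, r: int) -> dict[str, np.ndarray]:
        t = np.arange(max(0, r - self.L_q), min(r, self.L_t) + 1)
        j = r - t
        return {
            name: getattr(self, name)[t, j] for name in ("H", "E", "F", "E2", "F2")
        }


# ---------------------------------------------------------------------------
# row-column reference implementation (SWG role)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _nb_fill_rowcol(tc, qc, match, mismatch, po, pe, po2, pe2, strict, H, E, F, E2, F2):
    Lt = tc.size
    Lq = qc.size
    H[0, 0] = 0
    for i in range(1, Lt + 1):
        H[i, 0] = -min(po + i * pe, po2 + i * pe2)
    for j in range(1, Lq + 1):
        H[0, j] = -min(po + j * pe, po2 + j * pe2)
    for i in range(1, Lt + 1):
        ti = tc[i - 1]
        for j in range(1, Lq + 1):
            e = max(H[i - 1, j] - po, E[i - 1, j]) - pe
            e2 = max(H[i - 1, j] - po2, E2[i - 1, j]) - pe2
            f = max(H[i, j - 1] - po, F[i, j - 1]) - pe
            f2 = max(H[i, j - 1] - po2, F2[i, j - 1]) - pe2
            if ti == qc[j - 1] and ti < 4:
                m = H[i - 1, j - 1] + match
            else:
                m = H[i - 1, j - 1] + mismatch
            E[i, j] = e
            E2[i, j] = e2
            F[i, j] = f
            F2[i, j] = f2
            h = max(m, e, f)
            if not strict:
                h = max(h, e2, f2)
            H[i, j] = h


@njit(cache=False)
def _nb_score_rowcol(tc, qc, match, mismatch, po, pe, po2, pe2, strict):
    Lt = tc.size
    Lq = qc.size
    ninf = NEG_INF
    Hp = np.empty(Lq + 1, dtype=np.int64)
    Ep = np.full(Lq + 1, ninf, dtype=np.int64)
    E2p = np.full(Lq + 1, ninf, dtype=np.int64)
    Hp[0] = 0
    for j in range(1, Lq + 1):
        Hp[j] = -min(po + j * pe, po2 + j * pe2)
    for i in range(1, Lt + 1):
        Hc = np.empty(Lq + 1, dtype=np.int64)
        Ec = np.empty(Lq + 1, dtype=np.int64)
        E2c = np.empty(Lq + 1, dtype=np.int64)
        Hc[0] = -min(po + i * pe, po2 + i * pe2)
        Ec[0] = ninf
        E2c[0] = ninf
        f = ninf
        f2 = ninf
        ti = tc[i - 1]
        for j in range(1, Lq + 1):
            e = max(Hp[j] - po, Ep[j]) - pe
            e2 = max(Hp[j] - po2, E2p[j]) - pe2
            f = max(Hc[j - 1] - po, f) - pe
            f2 = max(Hc[j - 1] - po2, f2) - pe2
            if ti == qc[j - 1] and ti < 4:
                m = Hp[j - 1] + match
            else:
                m = Hp[j - 1] + mismatch
            h = max(m, e, f)
            if not strict:
                h = max(h, e2, f2)
            Hc[j] = h
            Ec[j] = e
            E2c[j] = e2
        Hp, Ep, E2p = Hc, Ec, E2c
    return Hp[Lq]


def _fill_rowcol_matrices(
    target: str, query: str, s: ScoringScheme, strict_eq1: bool = False
) -> DPStateDiag:
    tc = base_codes(target)
    qc = base_codes(query)
    shape = (tc.size + 1, qc.size + 1)
    mats = [np.full(shape, s.neg_inf, dtype=np.int32) for _ in range(5)]
    H, E, F, E2, F2 = mats
    _nb_fill_rowcol(
        tc, qc, s.match, s.mismatch, s.p_o, s.p_e, s.p_o2, s.p_e2, strict_eq1,
        H, E, F, E2, F2,
    )
    return DPStateDiag(H=H, E=E, F=F, E2=E2, F2=F2)


def rowcol_score(target: str, query: str, s: ScoringScheme, strict_eq1: bool = False) -> int:
    """Optimal global score only, via the row-column fill (O(L_q) memory)."""
    return int(
        _nb_score_rowcol(
            base_codes(target), base_codes(query),
            s.match, s.mismatch, s.p_o, s.p_e, s.p_o2, s.p_e2, strict_eq1,
        )
    )


# ---------------------------------------------------------------------------
# traceback (shared by both layouts; walks the stored matrices)
# ---------------------------------------------------------------------------

def _merge_runs(ops: list[tuple[int, str]]) -> Cigar:
    merged: Cigar = []
    for n, op in ops:
        if merged and merged[-1][1] == op:
            merged[-1] = (merged[-1][0] + n, op)
        else:
            merged.append((n, op))
    return merged


def _traceback(
    state: DPStateDiag, tc: np.ndarray, qc: np.ndarray, s: ScoringScheme, strict_eq1: bool
) -> Cigar:
    H, E, F, E2, F2 = state.H, state.E, state.F, state.E2, state.F2
    i, j = tc.size, qc.size
    ops: list[tuple[int, str]] = []  # built back-to-front
    st = "H"
    while i > 0 or j > 0:
        if st == "H":
            if i == 0:
                ops.append((j, "I"))
                j = 0
                continue
            if j == 0:
                ops.append((i, "D"))
                i = 0
                continue
            h = int(H[i, j])
            m = s.match if (tc[i - 1] == qc[j - 1] and tc[i - 1] < 4) else s.mismatch
            # tie preference: M over D (E-type) over I (F-type)
            if h == int(H[i - 1, j - 1]) + m:
                ops.append((1, "M"))
                i -= 1
                j -= 1
            elif h == int(E[i, j]):
                st = "E"
            elif not strict_eq1 and h == int(E2[i, j]):
                st = "E2"
            elif h == int(F[i, j]):
                st = "F"
            elif not strict_eq1 and h == int(F2[i, j]):
                st = "F2"
            else:  # pragma: no cover - would indicate a fill bug
                raise AssertionError(f"traceback stuck at ({i}, {j})")
        elif st in ("E", "E2"):
            M, pe = (E, s.p_e) if st == "E" else (E2, s.p_e2)
            ops.append((1, "D"))
            # prefer gap extension over re-opening
            if i > 1 and int(M[i, j]) == int(M[i - 1, j]) - pe:
                i -= 1
            else:
                i -= 1
                st = "H"
        else:  # F / F2
            M, pe = (F, s.p_e) if st == "F" else (F2, s.p_e2)
            ops.append((1, "I"))
            if j > 1 and int(M[i, j]) == int(M[i, j - 1]) - pe:
                j -= 1
            else:
                j -= 1
                st = "H"
    ops.reverse()
    return _merge_runs(ops)


def align_rowcol(
    target: str, query: str, s: ScoringScheme = ScoringScheme(), strict_eq1: bool = False
) -> AlignmentResult:
    """Global 2-piece affine alignment, row-column fill order (oracle role)."""
    state = _fill_rowcol_matrices(target, query, s, strict_eq1)
    cigar = _traceback(state, base_codes(target), base_codes(query), s, strict_eq1)
    return AlignmentResult(
        score=int(state.H[len(target), len(query)]),
        cigar=cigar,
        t_span=(0, len(target)),
        q_span=(0, len(query)),
    )


# ---------------------------------------------------------------------------
# anti-diagonal (wavefront) implementation
# ---------------------------------------------------------------------------

def _fill_antidiag_matrices(
    target: str, query: str, s: ScoringScheme, strict_eq1: bool = False
) -> DPStateDiag:
    """Fill the five DP matrices one anti-diagonal at a time.

    Every anti-diagonal r is updated with bulk elementwise operations over
    contiguous lane buffers indexed by t; the (r-1, t-1) and (r-2, t-1)
    accesses are the :func:`lane_shift` contract, realized as offset views
    into the previous-diagonal lanes (no data movement).  Lane cells
    outside the valid t range hold the neg_inf sentinel; H boundary lanes
    carry the leading-gap costs.  The diagonals are scattered into full
    row-column matrices so traceback is shared with the reference
    implementation.
    """
    tc = base_codes(target)
    qc = base_codes(query)
    Lt, Lq = tc.size, qc.size
    ninf = s.neg_inf
    shape = (Lt + 1, Lq + 1)
    H = np.empty(shape, dtype=np.int32)
    E, F, E2, F2 = (np.empty(shape, dtype=np.int32) for _ in range(4))
    for mat in (E, F, E2, F2):  # gap states undefined on the borders
        mat[0, :] = ninf
        mat[:, 0] = ninf
    H[0, 0] = 0
    qc_rev = qc[::-1]
    ts_all = np.arange(Lt + 1)

    # rotating per-diagonal lanes indexed by t in [0, Lt] (+1 pad slot so the
    # b+1 sentinel reset below never goes out of bounds); the four gap
    # states are stacked as rows E, E2, F, F2 so one broadcast ufunc
    # updates a pair of affine pieces at once
    Hm2, Hm1, spare_h = (np.full(Lt + 2, ninf, dtype=np.int64) for _ in range(3))
    Hm1[0] = 0  # diagonal r = 0
    G_m1 = np.full((4, Lt + 2), ninf, dtype=np.int64)
    G_cur = np.full((4, Lt + 2), ninf, dtype=np.int64)
    open_col = np.array([[s.p_o], [s.p_o2]], dtype=np.int64)
    ext_col = np.array([[s.p_e], [s.p_e2]], dtype=np.int64)

    for r in range(1, Lt + Lq + 1):
        Hc = spare_h
        a = max(1, r - Lq)
        b = min(r - 1, Lt)
        if a <= b:
            sl = slice(a, b + 1)
            sh = slice(a - 1, b)  # lane-shifted view: (.., t-1)
            ev = G_cur[:2, sl]  # E / E2: gaps consuming target, need t-1
            np.subtract(Hm1[sh], open_col, out=ev)
            np.maximum(ev, G_m1[:2, sh], out=ev)
            np.subtract(ev, ext_col, out=ev)
            fv = G_cur[2:, sl]  # F / F2: gaps consuming query, same t
            np.subtract(Hm1[sl], open_col, out=fv)
            np.maximum(fv, G_m1[2:, sl], out=fv)
            np.subtract(fv, ext_col, out=fv)
            eq = tc[a - 1 : b] == qc_rev[Lq - r + a : Lq - r + b + 1]
            if (tc[a - 1 : b] >= 4).any():
                eq = eq & (tc[a - 1 : b] < 4)
            m = np.where(eq, s.match, s.mismatch)
            np.add(m, Hm2[sh], out=m)
            h = Hc[sl]
            if strict_eq1:
                np.maximum(ev[0], fv[0], out=h)
            else:
                np.maximum.reduce(G_cur[:, sl], axis=0, out=h)
            np.maximum(h, m, out=h)
        # sentinel edges first (next diagonals read neg_inf outside the
        # valid lane range), then the boundary cells overwrite where needed
        Hc[a - 1] = ninf
        Hc[b + 1] = ninf
        G_cur[:, a - 1] = ninf
        G_cur[:, b + 1] = ninf
        if r <= Lq:
            Hc[0] = -gap_cost(r, s)
        if r <= Lt:
            Hc[r] = -gap_cost(r, s)
        # scatter diagonal r into the row-column matrices
        tlo = max(0, r - Lq)
        thi = min(r, Lt)
        ts = ts_all[tlo : thi + 1]
        js = r - ts
        H[ts, js] = Hc[tlo : thi + 1]
        if a <= b:
            ti = ts_all[a : b + 1]
            ji = r - ti
            E[ti, ji] = G_cur[0, sl]
            E2[ti, ji] = G_cur[1, sl]
            F[ti, ji] = G_cur[2, sl]
            F2[ti, ji] = G_cur[3, sl]
        spare_h = Hm2
        Hm2 = Hm1
        Hm1 = Hc
        G_m1, G_cur = G_cur, G_m1

    return DPStateDiag(H=H, E=E, F=F, E2=E2, F2=F2)


def align_antidiag(
    target: str, query: str, s: ScoringScheme = ScoringScheme(), strict_eq1: bool = False
) -> AlignmentResult:
    """Global 2-piece affine alignment in the diagonal-antidiagonal layout.

    Produces the same score (and an equal-score CIGAR) as
    :func:`align_rowcol` for every input.
    """
    state = _fill_antidiag_matrices(target, query, s, strict_eq1)
    cigar = _traceback(state, base_codes(target), base_codes(query), s, strict_eq1)
    return AlignmentResult(
        score=int(state.H[len(target), len(query)]),
        cigar=cigar,
        t_span=(0, len(target)),
        q_span=(0, len(query)),
    )


# ---------------------------------------------------------------------------
# CIGAR re-scoring (validation of traceback)
# ---------------------------------------------------------------------------

def score_cigar(cigar: Cigar, target: str, query: str, s: ScoringScheme) -> int:
    """Score an alignment path: mat over M columns, gap_cost per maximal
    I run and per maximal D run.  The path must consume both sequences
    exactly."""
    tc = base_codes(target)
    qc = base_codes(query)
    i = j = 0
    score = 0
    for n, op in cigar:
        if op == "M":
            for _ in range(n):
                if tc[i] == qc[j] and tc[i] < 4:
                    score += s.match
                else:
                    score += s.mismatch
                i += 1
                j += 1
        elif op == "D":
            score -= gap_cost(n, s)
            i += n
        elif op == "I":
            score -= gap_cost(n, s)
            j += n
        else:
            raise ValueError(f"unsupported CIGAR op {op!r}")
    if i != len(target) or j != len(query):
        raise ValueError(
            f"CIGAR consumes ({i}, {j}) of sequences of length "
            f"({len(target)}, {len(query)})"
        )
    return score
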