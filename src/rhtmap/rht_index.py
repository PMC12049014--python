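"""The Regional Hash Table (RHT): overlapping reference windows plus a
CSR-style k-mer -> window-number index.

The reference is cut into windows of length L_win (default 2048 bp) that
overlap by half (stride L_win/2).  Within each window, k-mers are sampled at
a step of k bases and each non-ambiguous k-mer contributes one
(code, window_id) pair.  The pairs are stored in compressed sparse row form:
``pointer_list`` (length 4^k + 1) holds, for every k-mer code, the offset of
its first entry in ``window_list``; the slice
``window_list[pointer_list[c] : pointer_list[c + 1]]`` is the sorted list of
windows containing code ``c`` (with multiplicity).
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io_formats import SequenceRecord

_MAGIC = b"RHTI"
_VERSION = 2

# 2-bit base codes; anything that is not ACGT (i.e. N) maps to 4.
_BASE_LUT = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_LUT[_b] = _i


def base_codes(seq: str) -> np.ndarray:
    """Per-base integer codes A=0 C=1 G=2 T=3, N(or other)=4."""
    return _BASE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def rolling_kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Big-endian 2-bit codes of every length-k window of a base-code array.

    Returns (values, valid) where valid[i] is False when the k-mer starting
    at i contains an ambiguous base.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    win = sliding_window_view(codes.astype(np.int64), k)
    valid = (win < 4).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    values = win @ powers
    values[~valid] = -1
    return values, valid


def encode_kmer(seq: str, k: Optional[int] = None) -> Optional[int]:
    """Big-endian 2-bit code of a k-mer (first base most significant).

    Returns None when the k-mer contains N.  Raises on a length mismatch
    with the expected k.
    """
    if k is not None and len(seq) != k:
        raise ValueError(f"expected k-mer of length {k}, got {len(seq)}")
    codes = base_codes(seq)
    if (codes >= 4).any():
        return None
    code = 0
    for c in codes:
        code = (code << 2) | int(c)
    return code


@dataclass(frozen=True)
class IndexParams:
    """Window / k-mer parameters of the regional hash table.

    k is the k-mer length (dense tables need 4^k pointer slots, so k <= 13
    by default); L_win the window length in bp.  The window stride is fixed
    at L_win/2 and the in-window reference k-mer sampling step defaults to k
    (set ref_kmer_step to override).
    """

    k: int = 13
    L_win: int = 2048
    ref_kmer_step: int = 0  # 0 means "use k"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.L_win < 2 or self.L_win % 2 != 0:
            raise ValueError("L_win must be a positive even length")
        if self.ref_kmer_step < 0:
            raise ValueError("ref_kmer_step must be >= 0")

    @property
    def window_stride(self) -> int:
        return self.L_win // 2

    @property
    def step(self) -> int:
        return self.ref_kmer_step if self.ref_kmer_step else self.k


@dataclass(frozen=True)
class Window:
    window_id: int
    start: int
    end: int  # exclusive, clamped to the reference length


def partition_windows(ref_length: int, params: IndexParams) -> list[Window]:
    """Overlapping windows at starts 0, stride, 2*stride, ... < ref_length.

    Ends are clamped to the reference; windows too short to host a single
    k-mer are dropped.
    """
    if ref_length < 1:
        raise ValueError("ref_length must be >= 1")
    windows = []
    wid = 0
    for start in range(0, ref_length, params.window_stride):
        end = min(start + params.L_win, ref_length)
        if end - start >= params.k:
            windows.append(Window(window_id=wid, start=start, end=end))
            wid += 1
    return windows


@dataclass
class RegionalHashTable:
    params: IndexParams
    ref_name: str
    ref_length: int
    n_windows: int
    pointer_list: np.ndarray  # int32, length 4^k + 1
    window_list: np.ndarray  # int32 window ids
    reference: Optional[str] = None  # carried so mapping needs no extra FASTA

    def window_span(self, window_id: int) -> tuple[int, int]:
        if not (0 <= window_id < self.n_windows):
            raise ValueError(f"window id {window_id} out of range")
        start = window_id * self.params.window_stride
        return start, min(start + self.params.L_win, self.ref_length)

    def validate(self, full: bool = False) -> None:
        p = self.pointer_list
        if p[0] != 0 or p[-1] != self.window_list.size:
            raise ValueError("pointer_list endpoints inconsistent")
        # the monotonicity scan touches all 4^k+1 slots; run it on demand
        # (and always for small tables)
        if full or p.size <= (1 << 22):
            if (np.diff(p) < 0).any():
                raise ValueError("pointer_list not monotone")
        if self.window_list.size and (
            self.window_list.min() < 0 or self.window_list.max() >= self.n_windows
        ):
            raise ValueError("window_list entry out of range")


def build_rht(
    reference: SequenceRecord,
    params: IndexParams = IndexParams(),
    max_pointer_bytes: int = 1 << 30,
) -> RegionalHashTable:
    """Construct the regional hash table of a reference sequence.

    Each window contributes its step-k k-mers (duplicates kept, so hit
    counts downstream reflect occurrence multiplicity); the (code, window)
    pairs are counted, prefix-summed and filled into CSR arrays.
    """
    if not reference.sequence:
        raise ValueError("reference is empty")
    n_slots = 4**params.k + 1
    if n_slots * 4 > max_pointer_bytes:
        raise ValueError(
            f"k={params.k} needs {n_slots * 4 / 2**20:.0f} MiB of dense "
            "pointer storage; use a smaller k"
        )
    ref_len = len(reference.sequence)
    windows = partition_windows(ref_len, params)
    codes = base_codes(reference.sequence)
    kmer_vals, kmer_valid = rolling_kmer_codes(codes, params.k)

    all_codes: list[np.ndarray] = []
    all_wids: list[np.ndarray] = []
    for w in windows:
        # in-window offsets 0, step, 2*step, ... with offset + k <= window length
        offs = np.arange(0, (w.end - w.start) - params.k + 1, params.step)
        positions = w.start + offs
        vals = kmer_vals[positions]
        ok = kmer_valid[positions]
        if ok.any():
            all_codes.append(vals[ok])
            all_wids.append(np.full(int(ok.sum()), w.window_id, dtype=np.int32))

    if all_codes:
        cat_codes = np.concatenate(all_codes)
        cat_wids = np.concatenate(all_wids)
    else:
        cat_codes = np.empty(0, dtype=np.int64)
        cat_wids = np.empty(0, dtype=np.int32)

    # count -> prefix-sum over the dense code space; a sparse delta keeps the
    # only unavoidable full-table pass down to one int32 cumsum
    uniq, cnts = np.unique(cat_codes, return_counts=True)
    delta = np.zeros(n_slots, dtype=np.int32)
    delta[uniq + 1] = cnts.astype(np.int32)
    pointer_list = np.cumsum(delta, dtype=np.int32)
    # stable sort by code keeps window ids ascending within each code slice,
    # completing the count -> prefix-sum -> fill construction
    order = np.argsort(cat_codes, kind="stable")
    window_list = cat_wids[order]

    rht = RegionalHashTable(
        params=params,
        ref_name=reference.id,
        ref_length=ref_len,
        n_windows=len(windows),
        pointer_list=pointer_list,
        window_list=window_list,
        reference=reference.sequence,
    )
    rht.validate()
    return rht


def query_windows(rht: RegionalHashTable, code: int) -> np.ndarray:
    """Window ids containing a k-mer code (with repeats), sorted ascending."""
    if not (0 <= code < 4**rht.params.k):
        raise ValueError(f"code {code} out of range for k={rht.params.k}")
    return rht.window_list[rht.pointer_list[code] : rht.pointer_list[code + 1]]


# ---------------------------------------------------------------------------
# on-disk format: magic, version, k, L_win, step, ref_length, n_windows,
# name/window-list/sequence lengths, then little-endian arrays and the
# reference sequence bytes
# ---------------------------------------------------------------------------

_HEADER = struct.Struct("<4sHHIIqqIqI")


def save_rht(rht: RegionalHashTable, path: str) -> None:
    name = rht.ref_name.encode()
    seq = (rht.reference or "").encode()
    with open(path, "wb") as fh:
        fh.write(
            _HEADER.pack(
                _MAGIC,
                _VERSION,
                rht.params.k,
                rht.params.L_win,
                rht.params.ref_kmer_step,
                rht.ref_length,
                int(rht.window_list.size),
                rht.n_windows,
                len(seq),
                len(name),
            )
        )
        fh.write(name)
        fh.write(rht.pointer_list.astype("<i4").tobytes())
        fh.write(rht.window_list.astype("<i4").tobytes())
        fh.write(seq)


def load_rht(path: str) -> RegionalHashTable:
    with open(path, "rb") as fh:
        magic, version, k, L_win, step, ref_length, wl_size, n_windows, seq_len, name_len = (
            _HEADER.unpack(fh.read(_HEADER.size))
        )
        if magic != _MAGIC:
            raise ValueError(f"{path}: not an rhtmap index")
        if version != _VERSION:
            raise ValueError(f"{path}: unsupported index version {version}")
        name = fh.read(name_len).decode()
        params = IndexParams(k=k, L_win=L_win, ref_kmer_step=step)
        pointer_list = np.frombuffer(fh.read((4**k + 1) * 4), dtype="<i4").astype(np.int32)
        window_list = np.frombuffer(fh.read(wl_size * 4), dtype="<i4").astype(np.int32)
        seq = fh.read(seq_len).decode() if seq_len else None
    rht = RegionalHashTable(
        params=params,
        ref_name=name,
        ref_length=ref_length,
        n_windows=n_windows,
        pointer_list=pointer_list,
        window_list=window_list,
        reference=seq,
    )
    rht.validate()
    return rht
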