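"""Work distribution for FASTQ shards: static byte-range splitting with
precise record-head relocation, the integrated static+batched-dynamic plan,
length-threshold (non-equal) partitioning, the host/device communication
cost model, and execution over an in-process worker pool.

The static sequence distribution (SSD) first cuts the file into p equal
byte ranges (range i = [V*i/p, V*(i+1)/p)), then relocates every boundary
forward to the head of its record so each worker parses whole records.  The
integrated load balancing (ILB) plan applies SSD to the first alpha
fraction of records (default 0.8) and serves the remainder in batches of bs
records (default 128) from a shared pull-queue, so workers that finish
their static share early keep pulling work.  The analytic cost model prices
blocking / non-blocking host-device communication and the two non-equal
sequence distribution variants; transfer volume grows with the square of
the sequence length (the DP matrix), which is why the short-to-accelerator
assignment (NESD-s) wins.
"""

from __future__ import annotations

import queue
import threading
import time
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .io_formats import (
    ByteRange,
    SequenceRecord,
    _locate_head,
    read_fastq_range,
    scan_record_offsets,
)

__all__ = [
    "ByteRange",
    "DistributionPlan",
    "CostModelParams",
    "RunMetrics",
    "static_split",
    "refine_split",
    "make_ilb_plan",
    "nesd_partition",
    "model_runtime",
    "transmission_time",
    "run_parallel",
    "parallel_metrics",
]


def static_split(V_fastq: int, p: int) -> list[ByteRange]:
    """Equal byte-volume pre-split: range i = [floor(V*i/p), floor(V*(i+1)/p))."""
    if p < 1:
        raise ValueError("p must be >= 1")
    if V_fastq < 0:
        raise ValueError("V_fastq must be >= 0")
    return [
        ByteRange(V_fastq * i // p, V_fastq * (i + 1) // p) for i in range(p)
    ]


def refine_split(path: str, ranges: Sequence[ByteRange]) -> list[ByteRange]:
    """Advance every range start to the next record head; each end becomes
    the successor's refined start.  Empty refined ranges are allowed."""
    with open(path, "rb") as fh:
        data = fh.read()
    starts = [_locate_head(data, r.start) for r in ranges]
    last_end = _locate_head(data, ranges[-1].end)
    ends = starts[1:] + [last_end]
    return [ByteRange(s, e) for s, e in zip(starts, ends)]


@dataclass
class DistributionPlan:
    """SSD byte ranges for the static prefix plus dynamic record batches."""

    path: str
    V_fastq: int
    p: int
    alpha: float
    bs: int
    static_ranges: list[ByteRange]
    dynamic_batches: list[tuple[int, int]]  # record-index ranges, half-open
    record_offsets: np.ndarray  # head offsets of every record + file size
    n_static: int

    @property
    def n_records(self) -> int:
        return self.record_offsets.size - 1

    def validate(self) -> None:
        offs = self.record_offsets
        heads = set(int(o) for o in offs)
        covered = 0
        prev_end = 0
        for r in self.static_ranges:
            if r.start not in heads:
                raise ValueError(f"static range start {r.start} is not a record head")
            if r.start < prev_end:
                raise ValueError("static ranges overlap")
            prev_end = r.end
            covered += int(
                np.searchsorted(offs[:-1], r.end) - np.searchsorted(offs[:-1], r.start)
            )
        if covered != self.n_static:
            raise ValueError("static ranges do not cover the static prefix exactly")
        idx = self.n_static
        for i, (lo, hi) in enumerate(self.dynamic_batches):
            if lo != idx:
                raise ValueError("dynamic batches are not consecutive")
            if hi - lo > self.bs or (hi - lo != self.bs and i != len(self.dynamic_batches) - 1):
                raise ValueError("dynamic batch has wrong size")
            idx = hi
        if idx != self.n_records:
            raise ValueError("plan does not cover every record exactly once")


def make_ilb_plan(path: str, p: int, alpha: float = 0.8, bs: int = 128) -> DistributionPlan:
    """Integrated load balancing: SSD over the first floor(alpha*n) records,
    batches of bs records for the rest."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    if bs < 1:
        raise ValueError("bs must be >= 1")
    if p < 1:
        raise ValueError("p must be >= 1")
    offsets = scan_record_offsets(path)
    n = offsets.size - 1
    V = int(offsets[-1])
    n_static = int(alpha * n)
    static_end = int(offsets[n_static])
    naive = static_split(static_end, p)
    refined = refine_split(path, naive) if static_end > 0 else [
        ByteRange(0, 0) for _ in range(p)
    ]
    batches = [(i, min(i + bs, n)) for i in range(n_static, n, bs)]
    plan = DistributionPlan(
        path=path,
        V_fastq=V,
        p=p,
        alpha=alpha,
        bs=bs,
        static_ranges=refined,
        dynamic_batches=batches,
        record_offsets=offsets,
        n_static=n_static,
    )
    plan.validate()
    return plan


def nesd_partition(
    records: Sequence[SequenceRecord], threshold: int = 1024
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Split records into (short, long) by length < threshold, preserving
    order.  Short reads go to the accelerator-class workers (NESD-s)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    short = [r for r in records if len(r.sequence) < threshold]
    long_ = [r for r in records if len(r.sequence) >= threshold]
    return short, long_


@dataclass(frozen=True)
class CostModelParams:
    """Host/device communication cost model terms.

    O_c: communication startup overhead; G: transfer bandwidth (bytes per
    unit time); D_send/D_recv: transfer volumes; T_cpu/T_dev: host and
    device compute times.  For the long-to-accelerator (NESD-l) analysis,
    supply the primed (larger) values in the same fields.
    """

    O_c: float
    G: float
    D_send: float
    D_recv: float
    T_cpu: float = 0.0
    T_dev: float = 0.0

    def __post_init__(self) -> None:
        if self.G <= 0:
            raise ValueError("bandwidth G must be > 0")
        for name in ("O_c", "D_send", "D_recv", "T_cpu", "T_dev"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def T_send(self) -> float:
        return self.D_send / self.G

    @property
    def T_recv(self) -> float:
        return self.D_recv / self.G


def model_runtime(mode: str, cp: CostModelParams) -> float:
    """Closed-form total runtime of one host/device alignment round.

    blocking:    2*O_c + (D_send + D_recv)/G + T_cpu
    nonblocking: 2*O_c + (D_send + D_recv)/G + T_dev
    nesd_s:      O_c + T_cpu where T_cpu = T_send + T_dev + O_c + T_recv
                 (communication fully hidden behind host compute)
    nesd_l:      the same closed form evaluated under the primed (larger)
                 assignment the caller supplies in cp.
    """
    comm = cp.T_send + cp.T_recv
    if mode == "blocking":
        return 2 * cp.O_c + comm + cp.T_cpu
    if mode == "nonblocking":
        return 2 * cp.O_c + comm + cp.T_dev
    if mode in ("nesd_s", "nesd_l"):
        return cp.O_c + cp.T_send + cp.T_dev + cp.O_c + cp.T_recv
    raise ValueError(f"unknown mode {mode!r}")


def transmission_time(L: float, G: float) -> float:
    """DP-matrix transfer time for a length-L sequence: L^2 / G.

    Doubling the read length quadruples the volume, which is the reason
    long reads stay on the host."""
    if G <= 0:
        raise ValueError("bandwidth G must be > 0")
    if L < 0:
        raise ValueError("L must be >= 0")
    return (L * L) / G


@dataclass
class RunMetrics:
    """Speedup S_p = T_s/T_p and efficiency E_p = S_p/p."""

    T_s: float
    T_p: float
    p: int
    S_p: float
    E_p: float
    per_worker_times: list[float]


def parallel_metrics(T_s: float, per_worker_times: Sequence[float]) -> RunMetrics:
    if not per_worker_times:
        raise ValueError("per_worker_times is empty")
    if T_s <= 0 or any(t <= 0 for t in per_worker_times):
        raise ValueError("times must be > 0")
    p = len(per_worker_times)
    T_p = max(per_worker_times)
    S_p = T_s / T_p
    return RunMetrics(
        T_s=T_s, T_p=T_p, p=p, S_p=S_p, E_p=S_p / p,
        per_worker_times=list(per_worker_times),
    )


def run_parallel(
    plan: DistributionPlan,
    mapper: Callable[[SequenceRecord], object],
    p: Optional[int] = None,
) -> tuple[list[object], RunMetrics]:
    """Execute a distribution plan over an in-process worker pool.

    Each worker first consumes its static byte range, then pulls dynamic
    batches from a shared queue until exhaustion.  Results are returned
    re-ordered by input record index, so the output is independent of
    worker scheduling.  The returned metrics use the summed per-worker busy
    time as the serial-equivalent T_s; compute exact speedup from a
    measured single-worker baseline with :func:`parallel_metrics`.
    """
    if p is None:
        p = plan.p
    if p != len(plan.static_ranges):
        raise ValueError(f"plan was built for p={len(plan.static_ranges)}, got p={p}")
    offsets = plan.record_offsets
    n = plan.n_records
    results: list[object] = [None] * n
    batch_q: queue.SimpleQueue = queue.SimpleQueue()
    for batch in plan.dynamic_batches:
        batch_q.put(batch)
    times = [0.0] * p
    errors: list[BaseException] = []

    def consume(first_idx: int, records: list[SequenceRecord]) -> None:
        for i, rec in enumerate(records):
            try:
                results[first_idx + i] = mapper(rec)
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(f"mapper failed on record {rec.id!r}") from exc

    def worker(widx: int) -> None:
        t0 = time.perf_counter()
        try:
            rng = plan.static_ranges[widx]
            first = int(np.searchsorted(offsets[:-1], rng.start))
            consume(first, read_fastq_range(plan.path, rng))
            while True:
                try:
                    lo, hi = batch_q.get_nowait()
                except queue.Empty:
                    break
                rng = ByteRange(int(offsets[lo]), int(offsets[hi]))
                consume(lo, read_fastq_range(plan.path, rng))
        except BaseException as exc:  # noqa: BLE001
            errors.append(exc)
        finally:
            times[widx] = time.perf_counter() - t0

    threads = [threading.Thread(target=worker, args=(w,)) for w in range(p)]
    for t in threads:
        t.start()
    for t in threads:
        t.join()
    if errors:
        raise errors[0]
    busy = [max(t, 1e-9) for t in times]
    return results, parallel_metrics(sum(busy), busy)
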