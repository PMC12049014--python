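"""Synthetic references and SMRT-like noisy reads with ground truth, plus
evaluation of mapping recall and DP-exactness recall.

The read simulator emulates a PacBio-CLR-like error profile: reads are
substrings of the reference at uniform positions, lengths drawn from a
truncated normal, and an insertion-dominated error channel applied per base
(defaults 2% substitution / 9% insertion / 4% deletion, ~15% total).  Half
of the reads are reverse-complemented.  Everything is deterministic given
the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_formats import SequenceRecord, reverse_complement
from .read_mapper import DPAudit, MappedRead

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

TRUTH_HEADER = "read_id\tref_start\tref_end\tstrand\tn_errors"


@dataclass(frozen=True)
class SimConfig:
    ref_length: int = 100_000
    n_reads: int = 200
    read_length_mean: int = 3000
    read_length_sd: int = 500
    sub_rate: float = 0.02
    ins_rate: float = 0.09
    del_rate: float = 0.04
    rc_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            r = getattr(self, name)
            if not (0.0 <= r < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.sub_rate + self.ins_rate + self.del_rate >= 1.0:
            raise ValueError("total error rate must be < 1")
        if not (0.0 <= self.rc_prob <= 1.0):
            raise ValueError("rc_prob must be in [0, 1]")
        if self.ref_length < self.read_length_mean:
            raise ValueError("reference shorter than the mean read length")


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    ref_start: int
    ref_end: int  # exclusive
    strand: str
    n_errors_introduced: int


def simulate_reference(length: int, seed: int) -> SequenceRecord:
    """I.i.d. uniform {A,C,G,T} sequence, deterministic given the seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=length).tobytes().decode("ascii")
    return SequenceRecord(id=f"ref_sim_{seed}", sequence=seq)


def _mutate(
    source: str, rng: np.random.Generator, cfg: SimConfig
) -> tuple[str, int, int, int]:
    """Apply the per-base error channel; returns (read, subs, ins, dels)."""
    lut = np.full(256, -1, dtype=np.int8)
    for bi, bb in enumerate(_BASES):
        lut[bb] = bi
    src = np.frombuffer(source.encode("ascii"), dtype=np.uint8)
    n = src.size
    u = rng.random(n)
    ins_mask = rng.random(n) < cfg.ins_rate
    out = bytearray()
    subs = ins = dels = 0
    del_hi = cfg.del_rate
    sub_hi = cfg.del_rate + cfg.sub_rate
    for i in range(n):
        if u[i] < del_hi:
            dels += 1
        elif u[i] < sub_hi:
            # substitute with one of the three other bases
            idx = int(lut[src[i]])
            if idx < 0:
                out.append(int(_BASES[rng.integers(4)]))
            else:
                out.append(int(_BASES[(idx + 1 + int(rng.integers(3))) % 4]))
            subs += 1
        else:
            out.append(int(src[i]))
        if ins_mask[i]:
            out.append(int(_BASES[rng.integers(4)]))
            ins += 1
    return out.decode("ascii"), subs, ins, dels


def simulate_reads(
    ref: SequenceRecord, cfg: SimConfig
) -> tuple[list[SequenceRecord], list[TruthRecord]]:
    """Draw noisy reads from a reference with recorded ground truth."""
    rng = np.random.default_rng(cfg.seed)
    ref_len = len(ref.sequence)
    reads: list[SequenceRecord] = []
    truths: list[TruthRecord] = []
    for i in range(cfg.n_reads):
        length = int(round(rng.normal(cfg.read_length_mean, cfg.read_length_sd)))
        length = max(50, min(length, ref_len))
        start = int(rng.integers(0, ref_len - length + 1))
        source = ref.sequence[start : start + length]
        read_seq, subs, ins, dels = _mutate(source, rng, cfg)
        strand = "-" if rng.random() < cfg.rc_prob else "+"
        if strand == "-":
            read_seq = reverse_complement(read_seq)
        read_id = f"read_{i:05d}"
        reads.append(
            SequenceRecord(id=read_id, sequence=read_seq, quality="I" * len(read_seq))
        )
        truths.append(
            TruthRecord(
                read_id=read_id,
                ref_start=start,
                ref_end=start + length,
                strand=strand,
                n_errors_introduced=subs + ins + dels,
            )
        )
    return reads, truths


def write_truth(truths: Iterable[TruthRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(TRUTH_HEADER + "\n")
        for t in truths:
            fh.write(
                f"{t.read_id}\t{t.ref_start}\t{t.ref_end}\t{t.strand}"
                f"\t{t.n_errors_introduced}\n"
            )


def read_truth(path: str) -> list[TruthRecord]:
    truths = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != TRUTH_HEADER:
            raise ValueError(f"{path}: unexpected truth header {header!r}")
        for line in fh:
            rid, s, e, strand, n_err = line.rstrip("\n").split("\t")
            truths.append(TruthRecord(rid, int(s), int(e), strand, int(n_err)))
    return truths


def evaluate(
    mapped: Sequence[MappedRead],
    truth: Sequence[TruthRecord],
    tolerance: int = 1024,
    audit: Optional[DPAudit] = None,
) -> dict:
    """Mapping recall (correct position within tolerance and correct
    strand), unmapped counts, and — when an audit is supplied — the
    DP-exactness recall of the wavefront scores against the row-column
    oracle."""
    truth_by_id = {t.read_id: t for t in truth}
    n_correct = 0
    n_mapped = 0
    for m in mapped:
        if m.read_id not in truth_by_id:
            raise ValueError(f"mapped read {m.read_id!r} absent from truth")
        if not m.is_mapped:
            continue
        n_mapped += 1
        t = truth_by_id[m.read_id]
        if m.strand == t.strand and abs((m.sam_pos - 1) - t.ref_start) <= tolerance:
            n_correct += 1
    n = len(truth)
    report = {
        "n_reads": n,
        "n_mapped": n_mapped,
        "n_unmapped": n - n_mapped,
        "mapping_recall_pct": 100.0 * n_correct / n if n else 0.0,
        "tolerance_bp": tolerance,
    }
    if audit is not None:
        report.update(
            dp_invocations=audit.total,
            dp_exact=audit.exact,
            dp_exactness_recall_pct=audit.recall_pct,
        )
    return report
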