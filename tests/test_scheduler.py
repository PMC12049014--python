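import numpy as np
import pytest

from conftest import FASTQ4
from rhtmap import (
    ByteRange,
    CostModelParams,
    SequenceRecord,
    make_ilb_plan,
    model_runtime,
    nesd_partition,
    parallel_metrics,
    read_fastq,
    refine_split,
    run_parallel,
    static_split,
    transmission_time,
    write_fastq,
)


def _write_uniform_fastq(tmp_path, n, seq_len=20, name="many.fq"):
    rng = np.random.default_rng(n)
    recs = [
        SequenceRecord(
            id=f"q{i:05d}",
            sequence="".join("ACGT"[b] for b in rng.integers(0, 4, seq_len)),
            quality="I" * seq_len,
        )
        for i in range(n)
    ]
    path = tmp_path / name
    write_fastq(recs, str(path))
    return str(path), recs


class TestStaticSplit:
    def test_even_split(self):
        assert [(r.start, r.end) for r in static_split(1000, 4)] == [
            (0, 250), (250, 500), (500, 750), (750, 1000),
        ]

    def test_single_worker_identity(self):
        assert [(r.start, r.end) for r in static_split(1000, 1)] == [(0, 1000)]

    def test_floor_convention(self):
        assert [(r.start, r.end) for r in static_split(10, 3)] == [(0, 3), (3, 6), (6, 10)]

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            static_split(100, 0)


class TestRefineSplit:
    def test_boundaries_relocated_to_heads(self, fastq4):
        refined = refine_split(
            fastq4, [ByteRange(0, 24), ByteRange(24, 48), ByteRange(48, 72)]
        )
        assert [(r.start, r.end) for r in refined] == [(0, 36), (36, 52), (52, 72)]
        from rhtmap import read_fastq_range

        counts = [len(read_fastq_range(fastq4, r)) for r in refined]
        assert counts == [2, 1, 1]

    def test_head_aligned_boundaries_unchanged(self, fastq4):
        ranges = [ByteRange(0, 36), ByteRange(36, 72)]
        assert refine_split(fastq4, ranges) == ranges

    def test_more_workers_than_records_conserves_records(self, fastq4):
        refined = refine_split(fastq4, static_split(len(FASTQ4), 9))
        from rhtmap import read_fastq_range

        counts = [len(read_fastq_range(fastq4, r)) for r in refined]
        assert sum(counts) == 4
        assert all(r.start <= r.end for r in refined)


class TestIlbPlan:
    def test_default_arithmetic_1000_records(self, tmp_path):
        path, _ = _write_uniform_fastq(tmp_path, 1000)
        plan = make_ilb_plan(path, p=4, alpha=0.8, bs=128)
        assert plan.n_static == 800
        assert [hi - lo for lo, hi in plan.dynamic_batches] == [128, 72]
        plan.validate()
        # uniform records: each worker's static share holds ~200 records
        sizes = [
            int(np.searchsorted(plan.record_offsets[:-1], r.end))
            - int(np.searchsorted(plan.record_offsets[:-1], r.start))
            for r in plan.static_ranges
        ]
        assert sum(sizes) == 800
        assert all(abs(s - 200) <= 1 for s in sizes)

    def test_pure_ssd(self, tmp_path):
        path, _ = _write_uniform_fastq(tmp_path, 50)
        plan = make_ilb_plan(path, p=3, alpha=1.0, bs=128)
        assert plan.dynamic_batches == []
        assert plan.n_static == 50

    def test_pure_dynamic(self, tmp_path):
        path, _ = _write_uniform_fastq(tmp_path, 17)
        plan = make_ilb_plan(path, p=2, alpha=0.0, bs=1)
        assert plan.n_static == 0
        assert len(plan.dynamic_batches) == 17

    def test_invalid_parameters(self, tmp_path):
        path, _ = _write_uniform_fastq(tmp_path, 4)
        with pytest.raises(ValueError):
            make_ilb_plan(path, p=1, alpha=1.5)
        with pytest.raises(ValueError):
            make_ilb_plan(path, p=1, bs=0)


class TestNesdPartition:
    def test_threshold_is_strict_less(self):
        recs = [SequenceRecord(id=str(n), sequence="A" * n) for n in (500, 1024, 2000)]
        short, long_ = nesd_partition(recs, 1024)
        assert [len(r.sequence) for r in short] == [500]
        assert [len(r.sequence) for r in long_] == [1024, 2000]

    def test_zero_threshold_everything_long(self):
        recs = [SequenceRecord(id="a", sequence="AC")]
        short, long_ = nesd_partition(recs, 0)
        assert short == [] and len(long_) == 1

    def test_set_partition(self):
        rng = np.random.default_rng(3)
        recs = [
            SequenceRecord(id=str(i), sequence="A" * int(rng.integers(1, 3000)))
            for i in range(50)
        ]
        short, long_ = nesd_partition(recs)
        assert len(short) + len(long_) == 50
        assert {r.id for r in short} | {r.id for r in long_} == {r.id for r in recs}


class TestCostModel:
    def _cp(self, **kw):
        base = dict(O_c=1.0, G=100.0, D_send=100.0, D_recv=100.0, T_cpu=10.0, T_dev=8.0)
        base.update(kw)
        return CostModelParams(**base)

    def test_closed_forms(self):
        cp = self._cp()
        assert model_runtime("blocking", cp) == 14.0
        assert model_runtime("nonblocking", cp) == 12.0
        # T_send=1, T_dev=8, O_c=1, T_recv=1 -> hidden-communication total 12
        assert model_runtime("nesd_s", cp) == 12.0

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            model_runtime("magic", self._cp())

    def test_nonblocking_never_slower_when_device_faster(self):
        for t_dev in (0.0, 5.0, 10.0):
            cp = self._cp(T_dev=t_dev)
            assert model_runtime("nonblocking", cp) <= model_runtime("blocking", cp)

    def test_long_to_accelerator_assignment_is_slower(self):
        cp_s = self._cp()
        # primed quantities: T'_acc > T_dev, T'_send/recv > T_send/recv
        cp_l = self._cp(T_dev=20.0, D_send=400.0, D_recv=400.0, T_cpu=15.0)
        assert model_runtime("nesd_l", cp_l) > model_runtime("nesd_s", cp_s)

    def test_transmission_quadratic_law(self):
        assert transmission_time(10, 100) == 1.0
        assert transmission_time(0, 7) == 0.0
        for L in (1, 13, 500):
            for n in (2, 3, 10):
                assert transmission_time(n * L, 5.0) == pytest.approx(
                    n * n * transmission_time(L, 5.0)
                )
        with pytest.raises(ValueError):
            transmission_time(10, 0)


class TestParallelMetrics:
    def test_ideal_speedup(self):
        m = parallel_metrics(100.0, [25.0, 25.0, 25.0, 25.0])
        assert (m.S_p, m.E_p) == (4.0, 1.0)

    def test_slowest_worker_bound(self):
        m = parallel_metrics(100.0, [50.0, 10.0, 10.0, 10.0])
        assert (m.S_p, m.E_p) == (2.0, 0.5)

    def test_single_worker_identity(self):
        m = parallel_metrics(100.0, [100.0])
        assert (m.S_p, m.E_p) == (1.0, 1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            parallel_metrics(1.0, [])


class TestRunParallel:
    @pytest.mark.parametrize("p", [1, 2, 4])
    @pytest.mark.parametrize("alpha", [0.0, 0.8, 1.0])
    @pytest.mark.parametrize("bs", [1, 128])
    def test_every_record_processed_exactly_once(self, tmp_path, p, alpha, bs):
        path, recs = _write_uniform_fastq(tmp_path, 37)
        plan = make_ilb_plan(path, p=p, alpha=alpha, bs=bs)
        plan.validate()
        results, metrics = run_parallel(plan, lambda r: r.id, p=p)
        assert results == [r.id for r in recs]
        assert metrics.p == p

    def test_single_worker_equals_sequential(self, tmp_path):
        path, recs = _write_uniform_fastq(tmp_path, 11)
        plan = make_ilb_plan(path, p=1)
        results, _ = run_parallel(plan, lambda r: (r.id, r.sequence))
        assert results == [(r.id, r.sequence) for r in read_fastq(path)]

    def test_worker_failure_names_record(self, tmp_path):
        path, _ = _write_uniform_fastq(tmp_path, 5)
        plan = make_ilb_plan(path, p=2)

        def bomb(rec):
            if rec.id == "q00003":
                raise RuntimeError("boom")
            return rec.id

        with pytest.raises(RuntimeError, match="q00003"):
            run_parallel(plan, bomb, p=2)
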