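"""Campaign configuration, sweep expansion, fault injection, parallelism
and read mapping."""

import json
import os
import random

import pytest

from strandsim.channel import IIDErrorModel, inject_iid
from strandsim.pipeline import encode
from strandsim.pipelines import rs_pipeline
from strandsim.simulator import (
    ConfigError,
    expand_campaigns,
    expand_sweep,
    map_reads,
    run_campaign,
    run_fault_injection,
    validate_config,
)
from strandsim.stats import RunStats

BASE = {
    "input": {"random_bytes": 100},
    "pipeline": {"family": "rs", "inner_parity": 9, "payload_bytes": 47},
    "fault_model": {"kind": "iid", "rate": 0.0},
    "copy_model": {"kind": "constant", "depth": 1},
    "iterations": 2,
    "master_seed": 5,
}


def cfg(**over):
    out = json.loads(json.dumps(BASE))
    for k, v in over.items():
        sect, _, leaf = k.partition("__")
        if leaf:
            out[sect][leaf] = v
        else:
            out[sect] = v
    return out


class TestSweep:
    def test_cross_product_counts(self):
        c = cfg(fault_model__rate=[0.01, 0.05, 0.1], copy_model__depth=[3, 30])
        assert len(expand_sweep(c)) == 6

    def test_no_lists_single_run(self):
        assert len(expand_sweep(cfg())) == 1

    def test_deterministic_order_and_dirnames(self):
        c = cfg(fault_model__rate=[0.01, 0.1], copy_model__depth=[3, 9])
        names = [r.dirname for r in expand_sweep(c)]
        assert names == [
            "run_depth=3__rate=0.01",
            "run_depth=3__rate=0.1",
            "run_depth=9__rate=0.01",
            "run_depth=9__rate=0.1",
        ]
        assert names == [r.dirname for r in expand_sweep(c)]

    def test_distinct_derived_seeds(self):
        c = cfg(copy_model__depth=[1, 2, 3])
        seeds = [r.seed for r in expand_sweep(c)]
        assert len(set(seeds)) == 3

    def test_schema_violations_listed(self):
        bad = cfg()
        bad["pipeline"]["family"] = "nonsense"
        del bad["master_seed"]
        with pytest.raises(ConfigError) as exc:
            expand_sweep(bad)
        msg = str(exc.value)
        assert "pipeline.family" in msg and "master_seed" in msg

    def test_validate_config_returns_fields(self):
        problems = validate_config({"pipeline": {"family": "rs"}})
        assert any("input" in p for p in problems)

    def test_bundled_campaign_is_240_runs(self):
        """The bundled full case-study config expands to the published
        batch-job count: RS 4x4x7 + HEDGES 4x4x1 + HEDGES-MSA 4x4x7 = 240."""
        path = os.path.join(
            os.path.dirname(__file__), "..", "examples", "configs",
            "case_study_full.json",
        )
        with open(path) as fh:
            cfgs = json.load(fh)
        runs = expand_campaigns(cfgs)
        assert len(runs) == 240
        assert len({r.dirname + str(r.params["pipeline.family"]) for r in runs}) == 240


class TestFaultInjection:
    def test_zero_error_rate_never_fails(self):
        run = expand_sweep(cfg(copy_model__depth=2))[0]
        stats = run_fault_injection(run)
        assert stats.counters["file_failure"] == 0
        assert stats.counters["strand_success"] == stats.counters["strands_processed"]

    def test_full_dropout_no_parity_fails_every_iteration(self):
        c = cfg(copy_model={"kind": "constant", "depth": 1, "dropout": 1.0})
        run = expand_sweep(c)[0]
        stats = run_fault_injection(run)
        assert stats.counters["file_failure"] == c["iterations"]
        assert stats.counters["strand_erasure"] == stats.counters["strands_processed"]

    def test_stats_conservation(self):
        c = cfg(fault_model__rate=0.03, copy_model__depth=3, iterations=4)
        stats = run_fault_injection(expand_sweep(c)[0])
        tallies = sum(
            stats.counters.get(k, 0)
            for k in ("strand_success", "strand_erasure", "strand_silent")
        )
        assert tallies == stats.counters["strands_processed"]
        injected = sum(
            stats.counters.get(f"injected_{k}", 0) for k in ("sub", "ins", "del")
        )
        assert sum(stats.histograms["base_errors_by_position"].values()) == injected

    def test_worker_count_invariance(self, tmp_path):
        c = cfg(fault_model__rate=0.02, copy_model__depth=2, iterations=4)
        run = expand_sweep(c)[0]
        run_fault_injection(run, workers=1, out_dir=str(tmp_path / "w1"))
        run_fault_injection(run, workers=2, out_dir=str(tmp_path / "w2"))
        assert (tmp_path / "w1" / "stats.json").read_bytes() == (
            tmp_path / "w2" / "stats.json"
        ).read_bytes()

    def test_campaign_writes_run_dirs(self, tmp_path):
        c = cfg(copy_model__depth=[1, 2])
        results = run_campaign(c, str(tmp_path))
        assert set(results) == {"run_depth=1", "run_depth=2"}
        for name in results:
            assert (tmp_path / name / "params.json").is_file()
            assert (tmp_path / name / "stats.json").is_file()
        assert (tmp_path / "campaign_stats.json").is_file()


class TestStatsMerge:
    def _random_stats(self, seed):
        rng = random.Random(seed)
        s = RunStats()
        for _ in range(20):
            s.incr(rng.choice("abc"), rng.randint(1, 5))
            s.record("h", rng.randint(0, 10))
        return s

    def test_merge_is_sum_and_commutative(self):
        a, b, c = (self._random_stats(i) for i in range(3))
        lhs = RunStats().merge(a).merge(b).merge(c)
        rhs = RunStats().merge(c).merge(a).merge(b)
        assert lhs.to_json() == rhs.to_json()
        assert lhs.counters["a"] == a.counters["a"] + b.counters["a"] + c.counters["a"]

    def test_json_round_trip(self):
        s = self._random_stats(9)
        assert RunStats.from_dict(json.loads(s.to_json())).to_json() == s.to_json()


class TestMapReads:
    def _library(self, n=20, seed=0):
        rng = random.Random(seed)
        spec = rs_pipeline(9, 47)
        data = bytes(rng.randrange(256) for _ in range(47 * n - 10))
        return encode(spec, data)

    def test_exact_reads_map_to_own_origin(self):
        lib = self._library()
        reads = [(f"r{s.origin_index}", s.dna) for s in lib]
        rows = map_reads(reads, lib, mode="by_alignment")
        for row, s in zip(rows, lib):
            assert row["assigned"] == s.origin_index
            assert row["distance"] == 0

    def test_equidistant_read_unassigned(self):
        lib = self._library(n=3)
        # a read equidistant to two references: mutate one base that differs
        a, b = lib[0].dna, lib[1].dna
        rows = map_reads([("amb", a)], lib[:1] + [lib[0]], mode="by_alignment")
        assert rows[0]["assigned"] is None
        assert "ambiguous" in rows[0]["reason"]

    def test_noisy_reads_mostly_assigned_correctly(self):
        """100 reads at 3% i.i.d. total error from a 20-strand library:
        at least 95 assigned to their true origin by best alignment."""
        lib = self._library(n=20, seed=1)
        model = IIDErrorModel.from_total_rate(0.03)
        rng = random.Random(2)
        reads, truth = [], []
        for i in range(100):
            s = lib[rng.randrange(len(lib))]
            noisy, _ = inject_iid(s.dna, model, i)
            reads.append((f"r{i}", noisy))
            truth.append(s.origin_index)
        rows = map_reads(reads, lib, mode="by_alignment")
        correct = sum(r["assigned"] == t for r, t in zip(rows, truth))
        assert correct >= 95

    def test_by_index_mapping(self):
        spec = rs_pipeline(9, 47)
        lib = self._library(n=5)
        rows = map_reads(
            [("a", lib[3].dna)], lib, mode="by_index", spec=spec
        )
        assert rows[0]["assigned"] == 3

    def test_malformed_records_skipped_with_count(self):
        lib = self._library(n=3)
        rows = map_reads([("bad", "ACGN"), ("ok", lib[0].dna)], lib)
        assert any("skipped 1" in (r.get("reason") or "") for r in rows)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            map_reads([("a", "ACGT")], [])
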