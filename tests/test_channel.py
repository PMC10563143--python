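"""Channel models: copy sampling, error injection, calibration, replay."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from strandsim.channel import (
    ContextErrorModel,
    ContextRates,
    CopyModel,
    IIDErrorModel,
    inject_contextual,
    inject_iid,
    replay_edit_log,
    sample_copies,
    synthetic_nanopore_model,
)

DNA = st.text(alphabet="ACGT", min_size=0, max_size=300)


class TestCopyModel:
    def test_constant_depth_no_dropout(self):
        m = CopyModel(kind="constant", mean_depth=5)
        assert len(sample_copies(m, rng_seed=1)) == 5

    def test_full_dropout(self):
        m = CopyModel(kind="constant", mean_depth=5, dropout_prob=1.0)
        assert all(sample_copies(m, rng_seed=s) == [] for s in range(20))

    def test_poisson_mean_within_3_sigma(self):
        m = CopyModel(kind="poisson", mean_depth=10)
        n = 10_000
        total = sum(len(sample_copies(m, rng_seed=s)) for s in range(n))
        mean = total / n
        sigma = math.sqrt(10 / n)
        assert abs(mean - 10) < 3 * sigma

    def test_non_integer_constant_depth_rejected(self):
        with pytest.raises(ValueError):
            CopyModel(kind="constant", mean_depth=2.5)

    def test_deterministic_under_fixed_seed(self):
        m = CopyModel(kind="poisson", mean_depth=7, dropout_prob=0.1)
        assert sample_copies(m, 42) == sample_copies(m, 42)


class TestIIDInjection:
    def test_zero_rates_identity(self):
        noisy, log = inject_iid("ACGTACGT", IIDErrorModel(), rng_seed=0)
        assert noisy == "ACGTACGT" and log == []

    def test_all_deletions_empty(self):
        noisy, log = inject_iid("ACGTACGT", IIDErrorModel(p_del=1.0), rng_seed=0)
        assert noisy == ""
        assert sum(1 for k, _, _ in log if k == "del") == 8

    def test_calibration_3_sigma_at_1e5_bases(self):
        """Per-type event frequencies over 10^5 injected bases stay within
        3-sigma binomial bounds of the nominal 1% rates."""
        model = IIDErrorModel(p_sub=0.01, p_ins=0.01, p_del=0.01)
        strand = "ACGT" * 250
        n_strands = 100  # 100 * 1000 = 1e5 bases
        counts = {"sub": 0, "ins": 0, "del": 0}
        for seed in range(n_strands):
            _, log = inject_iid(strand, model, seed)
            for kind, _, _ in log:
                counts[kind] += 1
        n = n_strands * len(strand)
        for kind in ("sub", "del"):
            # deletion happens w.p. p_del; substitution w.p. (1-p_del)*p_sub
            p = 0.01 if kind == "del" else 0.99 * 0.01
            sigma = math.sqrt(n * p * (1 - p))
            assert abs(counts[kind] - n * p) < 3 * sigma, kind
        # insertions: geometric expected count p/(1-p) per opportunity,
        # (n+1 opportunities per strand)
        opportunities = n_strands * (len(strand) + 1)
        mean_ins = opportunities * 0.01 / 0.99
        assert abs(counts["ins"] - mean_ins) < 4 * math.sqrt(mean_ins)

    @given(
        dna=DNA,
        seed=st.integers(0, 2**32),
        rates=st.tuples(
            st.floats(0, 0.3), st.floats(0, 0.3), st.floats(0, 0.3)
        ),
    )
    @settings(max_examples=60, deadline=None)
    def test_edit_log_replay_identity(self, dna, seed, rates):
        model = IIDErrorModel(*rates)
        noisy, log = inject_iid(dna, model, seed)
        assert replay_edit_log(dna, log) == noisy

    def test_identical_seed_identical_library(self):
        model = IIDErrorModel(0.05, 0.05, 0.05)
        a = inject_iid("ACGT" * 50, model, 77)
        b = inject_iid("ACGT" * 50, model, 77)
        assert a == b


class TestContextualInjection:
    def test_default_only_table_runs(self):
        m = ContextErrorModel(
            k=3, table={"default": ContextRates(0.01, 0.01, 0.01)}
        )
        noisy, log = inject_contextual("ACGT" * 30, m, rng_seed=1)
        assert replay_edit_log("ACGT" * 30, log) == noisy

    def test_uniform_table_statistically_matches_iid(self):
        """With burst_continue 0 and one rate everywhere, contextual and
        i.i.d. injection produce event counts from the same distribution
        (two-sample z-test on totals over many strands)."""
        rate = 0.02
        m_ctx = ContextErrorModel(
            k=2,
            table={"default": ContextRates(rate, rate, rate)},
            burst_continue=0.0,
        )
        m_iid = IIDErrorModel(rate, rate, rate)
        strand = "ACGTTGCA" * 50
        n = 150
        c_ctx = sum(len(inject_contextual(strand, m_ctx, s)[1]) for s in range(n))
        c_iid = sum(len(inject_iid(strand, m_iid, s + 10_000)[1]) for s in range(n))
        # each total is a sum of ~n*L*3 rare events; compare with 4-sigma
        expect = n * len(strand) * rate * 3
        sigma = math.sqrt(2 * expect)
        assert abs(c_ctx - c_iid) < 4 * sigma

    def test_burst_mean_length(self):
        """burst_continue 0.5 gives geometric bursts with mean 2.0.

        The trigger rate is kept low (0.4%) so that independent bursts
        rarely start adjacent to one another and merge into a longer
        observed run, which would bias the mean upward."""
        m = ContextErrorModel(
            k=1,
            table={"default": ContextRates(0.0, 0.0, 0.004)},
            burst_continue=0.5,
        )
        strand = "ACGT" * 625
        bursts = []
        for seed in range(400):
            _, log = inject_contextual(strand, m, seed)
            run = 0
            last = None
            for kind, pos, _ in log:
                if kind != "del":
                    continue
                if last is not None and pos == last + 1:
                    run += 1
                else:
                    if run:
                        bursts.append(run)
                    run = 1
                last = pos
            if run:
                bursts.append(run)
        mean = sum(bursts) / len(bursts)
        # geometric(p=1/2): mean 2, var 2
        sigma = math.sqrt(2.0 / len(bursts))
        assert abs(mean - 2.0) < 3.5 * sigma

    def test_requires_default_row(self):
        with pytest.raises(ValueError):
            ContextErrorModel(k=2, table={"AA": ContextRates(0, 0, 0)})

    def test_synthetic_nanopore_model_is_deletion_heavy(self):
        m = synthetic_nanopore_model(base_rate=0.05)
        strand = "ACGT" * 200
        counts = {"sub": 0, "ins": 0, "del": 0}
        for seed in range(50):
            _, log = inject_contextual(strand, m, seed)
            for kind, _, _ in log:
                counts[kind] += 1
        assert counts["del"] > counts["sub"] > counts["ins"]


def test_context_table_tsv_round_trip(tmp_path):
    path = tmp_path / "table.tsv"
    path.write_text(
        "context\tp_sub\tp_ins\tp_del\tsub_A\tsub_C\tsub_G\tsub_T\n"
        "default\t0.01\t0.005\t0.02\t0.25\t0.25\t0.25\t0.25\n"
        "AAA\t0.02\t0.005\t0.08\t0.0\t0.4\t0.4\t0.2\n"
    )
    from strandsim.channel import load_context_table

    m = load_context_table(str(path))
    assert m.k == 3
    assert m.rates_for("AAA").p_del == 0.08
    assert m.rates_for("CGT").p_del == 0.02  # falls back to default
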