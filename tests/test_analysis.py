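"""Rate estimation, outer-code provisioning and Pareto extraction."""

import itertools
import math
import random

import pytest
from scipy.stats import multinomial
from statsmodels.stats.proportion import proportion_confint

from strandsim.analysis import (
    DensityPoint,
    StrandRates,
    compute_densities,
    estimate_rates,
    packet_failure_prob,
    pareto_front,
    provision_outer,
    wilson_interval,
)
from strandsim.stats import RunStats


def rates(succ, era, sil, n=1000):
    k_s, k_e = round(succ * n), round(era * n)
    return StrandRates.from_counts(k_s, k_e, n - k_s - k_e)


class TestEstimateRates:
    def test_all_success(self):
        st = RunStats()
        st.incr("strand_success", 100)
        r = estimate_rates(st)
        assert r.p_success == 1.0
        assert r.ci_success[1] == 1.0

    def test_wilson_matches_statsmodels(self):
        for k, n in [(50, 100), (1, 30), (999, 1000), (0, 10)]:
            lo, hi = wilson_interval(k, n)
            slo, shi = proportion_confint(k, n, method="wilson")
            assert math.isclose(lo, slo, abs_tol=1e-9)
            assert math.isclose(hi, shi, abs_tol=1e-9)

    def test_half_split_interval(self):
        lo, hi = wilson_interval(50, 100)
        assert 0.40 < lo < 0.41 and 0.59 < hi < 0.60

    def test_proportions_sum_to_one(self):
        r = StrandRates.from_counts(90, 8, 2)
        assert (r.p_success, r.p_erasure, r.p_silent) == (0.9, 0.08, 0.02)

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            estimate_rates(RunStats())


class TestPacketFailureProb:
    def test_perfect_rates_zero(self):
        assert packet_failure_prob(10, 4, rates(1, 0, 0)) == 0.0

    def test_single_strand_no_parity(self):
        assert math.isclose(
            packet_failure_prob(1, 0, rates(0.9, 0.1, 0)), 0.1, rel_tol=1e-9
        )

    @pytest.mark.parametrize(
        "k,c,pe,ps",
        [(10, 4, 0.08, 0.02), (5, 5, 0.2, 0.1), (12, 3, 0.01, 0.03), (8, 7, 0.3, 0.0)],
    )
    def test_matches_multinomial_oracle(self, k, c, pe, ps):
        """Exact equality with an independent scipy multinomial summation
        for packets of up to 15 strands."""
        n = k + c
        r = StrandRates(1 - pe - ps, pe, ps, 1000, (0, 1))
        expected = 0.0
        for s in range(n + 1):
            for e in range(n - s + 1):
                if 2 * s + e > c:
                    expected += multinomial.pmf(
                        [s, e, n - s - e], n, [ps, pe, 1 - ps - pe]
                    )
        assert math.isclose(packet_failure_prob(k, c, r), expected, rel_tol=1e-9)

    def test_matches_exhaustive_vector_enumeration(self):
        """Brute force over all 3^n outcome vectors for a small packet."""
        k, c, pe, ps = 5, 3, 0.1, 0.05
        n = k + c
        r = StrandRates(1 - pe - ps, pe, ps, 1000, (0, 1))
        probs = {"ok": 1 - pe - ps, "era": pe, "sil": ps}
        expected = 0.0
        for outcome in itertools.product(("ok", "era", "sil"), repeat=n):
            s = outcome.count("sil")
            e = outcome.count("era")
            if 2 * s + e > c:
                p = 1.0
                for o in outcome:
                    p *= probs[o]
                expected += p
        assert math.isclose(packet_failure_prob(k, c, r), expected, rel_tol=1e-9)

    def test_monotone_decreasing_in_c(self):
        r = rates(0.9, 0.08, 0.02)
        vals = [packet_failure_prob(10, c, r) for c in range(0, 12)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestProvisionOuter:
    def test_perfect_rates_need_no_parity(self):
        res = provision_outer(rates(1, 0, 0))
        assert res.c == 0 and res.feasible

    def test_minimality_and_self_consistency(self):
        r = rates(0.99, 0.01, 0.0)
        res = provision_outer(r, k=200)
        assert res.feasible
        target = 1e-9
        assert res.failure_prob_per_access <= target
        if res.c > 0:
            pf = packet_failure_prob(res.k, res.c - 1, r)
            assert 1 - (1 - pf) ** res.packets_per_file > target

    def test_matches_exhaustive_c_search(self):
        r = rates(0.99, 0.01, 0.0)
        res = provision_outer(r, k=200)
        best = None
        for c in range(0, 56):
            pf = packet_failure_prob(200, c, r)
            if 1 - (1 - pf) ** res.packets_per_file <= 1e-9:
                best = c
                break
        assert res.c == best

    def test_c_nonincreasing_as_success_improves(self):
        cs = [
            provision_outer(rates(p, 1 - p, 0.0), k=100).c
            for p in (0.95, 0.97, 0.99, 0.999, 1.0)
        ]
        assert all(a >= b for a, b in zip(cs, cs[1:]))

    def test_infeasible_flagged(self):
        res = provision_outer(rates(0.3, 0.6, 0.1), k=200)
        assert not res.feasible

    def test_dropout_folding_increases_parity(self):
        r = rates(0.995, 0.005, 0.0)
        base = provision_outer(r, k=100).c
        folded = provision_outer(r, k=100, fold_dropout=0.02).c
        assert folded > base


class TestDensities:
    def _prov(self, k=200, c=0):
        from strandsim.analysis import ProvisionResult

        return ProvisionResult(k=k, c=c, packets_per_file=10,
                               failure_prob_per_access=0.0, feasible=True)

    def test_rs_1_55_write_density(self):
        # 55 payload bytes = 440 bits on a 240-base strand, no outer parity
        pt = compute_densities(55, 240, self._prov(), depth=1)
        assert math.isclose(pt.write_density, 440 / 240, rel_tol=1e-12)
        assert pt.read_density == pt.write_density

    def test_depth_scales_read_density(self):
        pt = compute_densities(55, 240, self._prov(), depth=10)
        assert math.isclose(pt.read_density, pt.write_density / 10, rel_tol=1e-12)

    def test_outer_parity_lowers_both_densities(self):
        a = compute_densities(55, 240, self._prov(c=10), depth=2)
        b = compute_densities(55, 240, self._prov(c=20), depth=2)
        assert b.write_density < a.write_density
        assert b.read_density < a.read_density


def _oracle_front(points):
    def dominates(p, q):
        return (
            p.read_density >= q.read_density
            and p.write_density >= q.write_density
            and (p.read_density > q.read_density or p.write_density > q.write_density)
        )

    uniq = []
    seen = set()
    for p in points:
        key = (p.read_density, p.write_density)
        if key not in seen:
            seen.add(key)
            uniq.append(p)
    return sorted(
        (p for p in uniq if not any(dominates(q, p) for q in uniq)),
        key=lambda p: (p.read_density, p.write_density),
    )


class TestParetoFront:
    def test_strict_domination(self):
        pts = [DensityPoint(1, 1), DensityPoint(2, 2)]
        front = pareto_front(pts)
        assert [(p.write_density, p.read_density) for p in front] == [(2, 2)]

    def test_incomparable_points_retained(self):
        pts = [DensityPoint(1, 3), DensityPoint(3, 1)]
        assert len(pareto_front(pts)) == 2

    def test_matches_quadratic_oracle_on_200_random_points(self):
        rng = random.Random(12)
        pts = [
            DensityPoint(rng.uniform(0, 2), rng.uniform(0, 2), label=str(i))
            for i in range(200)
        ]
        ours = [(p.read_density, p.write_density) for p in pareto_front(pts)]
        oracle = [(p.read_density, p.write_density) for p in _oracle_front(pts)]
        assert ours == oracle

    def test_idempotent_and_permutation_invariant(self):
        rng = random.Random(3)
        pts = [DensityPoint(rng.uniform(0, 1), rng.uniform(0, 1)) for _ in range(50)]
        front = pareto_front(pts)
        assert pareto_front(front) == front
        rng.shuffle(pts)
        assert [
            (p.read_density, p.write_density) for p in pareto_front(pts)
        ] == [(p.read_density, p.write_density) for p in front]


def test_plot_density_fronts_writes_figure(tmp_path):
    import pandas as pd

    from strandsim.analysis import plot_density_fronts

    df = pd.DataFrame(
        {
            "error_rate": [0.01, 0.01, 0.1],
            "family": ["rs", "hedges", "rs"],
            "feasible": [True, True, True],
            "read_density": [0.5, 0.8, 0.05],
            "write_density": [1.5, 0.8, 0.9],
            "on_front": [True, True, True],
        }
    )
    out = tmp_path / "fronts.png"
    plot_density_fronts(df, str(out))
    assert out.stat().st_size > 0
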