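"""Run a small fault-injection sweep and estimate per-strand decode rates.

A 2x2 sweep (error rate x sequencing depth) over the RS pipeline: each run
encodes a 200-byte input, injects i.i.d. errors into sampled strand copies,
decodes via ideal clustering + star-MSA consensus, and tallies per-strand
outcomes. The success rate is what the outer code is later provisioned
against; the Wilson interval shows the statistical resolution of the run.
"""

from strandsim import estimate_rates
from strandsim.simulator import expand_sweep, run_fault_injection

config = {
    "input": {"random_bytes": 200},
    "pipeline": {"family": "rs", "inner_parity": 9, "payload_bytes": 47},
    "fault_model": {"kind": "iid", "rate": [0.01, 0.05]},
    "copy_model": {"kind": "constant", "depth": [3, 9]},
    "iterations": 50,
    "master_seed": 7,
}

for run in expand_sweep(config):
    stats = run_fault_injection(run)
    rates = estimate_rates(stats)
    lo, hi = rates.ci_success
    print(
        f"{run.dirname}: strand success {rates.p_success:.3f} "
        f"(95% CI {lo:.3f}-{hi:.3f}, n={rates.n_samples}), "
        f"file failures {stats.counters['file_failure']}/{stats.counters['iterations']}"
    )
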