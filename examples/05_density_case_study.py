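"""Read/write-density trade-off across three pipeline designs.

Runs a reduced version of the density case study (30 fault-injection
iterations instead of 100, to keep this demo around a minute), provisions
each configuration's outer Reed-Solomon code to a 10^9-access MTTF on 1 MB,
and prints which points form the Pareto frontier at each error rate. Higher
densities are cheaper: write density counts synthesis, read density counts
sequencing.
"""

from strandsim.casestudy import run_case_study

df = run_case_study(master_seed=17, iterations=30, out_csv="pareto.csv")

for err, group in df.groupby("error_rate"):
    print(f"\n=== i.i.d. total error rate {err:.0%} ===")
    cols = ["config", "p_success", "outer_parity", "write_density",
            "read_density", "on_front"]
    print(group[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\nfull table written to pareto.csv")

from strandsim.analysis import plot_density_fronts

plot_density_fronts(df, "pareto.png")
print("frontier figure written to pareto.png")
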