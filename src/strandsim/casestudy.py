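"""A scaled-down read/write-density case study.

Compares three designs that spend sequencing depth differently — Reed-
Solomon inner code behind MSA consensus, a hash-convolutional code decoding
every copy independently (sequenced at depth 1), and the convolutional code
applied to the MSA consensus — across i.i.d. channel error rates, then
provisions each configuration's outer code to a mean-time-to-failure target
and extracts the Pareto frontier over read and write density.

Problem sizes are deliberately desk-scale (a 120-byte input, 100 fault-
injection iterations, two error rates, three depths); the pipelines, channel
and analysis are exactly the ones a full-scale campaign would use.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .analysis import (
    compute_densities,
    estimate_rates,
    pareto_front,
    provision_outer,
)
from .pipeline import inner_encode
from .simulator import build_pipeline, expand_campaigns, run_fault_injection


def case_study_configs(
    master_seed: int = 17,
    input_bytes: int = 120,
    iterations: int = 100,
    error_rates: tuple[float, ...] = (0.01, 0.1),
    depths: tuple[int, ...] = (3, 9, 15),
) -> list[dict]:
    """Campaign configs for the scaled-down sweep.

    The convolutional-only pipeline runs at depth 1 (each strand sequenced
    once, so read density equals write density); the MSA-based pipelines
    sweep the depth grid.
    """
    common = {
        "input": {"random_bytes": input_bytes},
        "iterations": iterations,
        "master_seed": master_seed,
    }
    return [
        dict(
            common,
            pipeline={"family": "rs", "inner": ["1,55", "9,47"]},
            fault_model={"kind": "iid", "rate": list(error_rates)},
            copy_model={"kind": "constant", "depth": list(depths)},
        ),
        dict(
            common,
            pipeline={"family": "hedges", "inner": "0.5,24"},
            fault_model={"kind": "iid", "rate": list(error_rates)},
            copy_model={"kind": "constant", "depth": 1},
        ),
        dict(
            common,
            pipeline={"family": "hedges_msa", "inner": "0.5,24"},
            fault_model={"kind": "iid", "rate": list(error_rates)},
            copy_model={"kind": "constant", "depth": list(depths)},
        ),
    ]


def run_case_study(
    master_seed: int = 17,
    *,
    input_bytes: int = 120,
    iterations: int = 100,
    workers: int = 1,
    k: int = 50,
    mttf: float = 1e9,
    file_bits: int = 8_000_000,
    out_csv: Optional[str] = None,
) -> pd.DataFrame:
    """Run the sweep and return the density table with per-error-rate
    Pareto-front flags; optionally also written as CSV.

    ``k`` is the data-strand packet size used for provisioning. It is kept
    well below the 255-strand field limit so that configurations with
    non-negligible erasure or silent rates can still be provisioned (a
    silent strand costs two parity strands) instead of dropping out of the
    comparison as infeasible.
    """
    rows = []
    for run in expand_campaigns(case_study_configs(master_seed, input_bytes, iterations)):
        stats = run_fault_injection(run, workers=workers)
        rates = estimate_rates(stats)
        spec = build_pipeline(run.params)
        strand_len = len(inner_encode(spec, bytes(spec.serialized_bytes))[0])
        payload = spec.payload_bytes
        prov = provision_outer(
            rates,
            file_bits=file_bits,
            mttf=mttf,
            k=k,
            payload_bytes_per_strand=payload,
        )
        depth = float(run.params["copy_model.depth"])
        row = {
            "config": f"{spec.name}@d{int(depth)}",
            "family": run.params["pipeline.family"],
            "inner": spec.name,
            "depth": depth,
            "error_rate": run.params["fault_model.rate"],
            "p_success": rates.p_success,
            "p_erasure": rates.p_erasure,
            "p_silent": rates.p_silent,
            "n_samples": rates.n_samples,
            "outer_parity": prov.c,
            "feasible": prov.feasible,
            "write_density": float("nan"),
            "read_density": float("nan"),
        }
        if prov.feasible:
            pt = compute_densities(payload, strand_len, prov, depth, row["config"])
            row["write_density"] = pt.write_density
            row["read_density"] = pt.read_density
        rows.append(row)
    df = pd.DataFrame(rows)
    df["on_front"] = False
    from .analysis import DensityPoint

    for err, group in df.groupby("error_rate"):
        feas = group[group["feasible"]]
        pts = [
            DensityPoint(r.write_density, r.read_density, r.config, r.depth)
            for r in feas.itertuples()
        ]
        front = {(p.read_density, p.write_density) for p in pareto_front(pts)}
        for i, r in feas.iterrows():
            if (r["read_density"], r["write_density"]) in front:
                df.loc[i, "on_front"] = True
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
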