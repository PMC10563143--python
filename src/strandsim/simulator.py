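"""Fault-injection campaign driver.

A campaign is described by a JSON configuration with three parameter
categories — encoder/decoder parameters, fault-distribution parameters and
copy-distribution parameters — any of which may be list-valued. List-valued
fields participate in a cross-product sweep: each unique combination becomes
one *run* with its own derived seed and output directory named after the
swept parameter values.

One run executes N independent fault-injection iterations: encode the input
once, then per iteration sample copy counts, inject channel errors, decode,
compare against ground truth and update mergeable statistics. Every random
draw is seeded by hashing (master seed, iteration, strand, copy), so results
are bit-identical regardless of worker count or execution order.
"""

from __future__ import annotations

import itertools
import multiprocessing
import os
from dataclasses import dataclass
from functools import partial
from typing import Callable, Optional, Sequence

import edlib

from .channel import (
    CopyModel,
    IIDErrorModel,
    inject_contextual,
    inject_iid,
    load_context_table,
    sample_copies,
    synthetic_nanopore_model,
)
from .io import spec_fingerprint, write_manifest
from .pipeline import PipelineSpec, decode_detailed, encode
from .pipelines import (
    hedges_msa_pipeline,
    hedges_pipeline,
    rot3_pipeline,
    rs_pipeline,
)
from .rs import DecodeStatus
from .seeds import derive_seed
from .stats import RunStats
from .types import EncodedStrand


class ConfigError(ValueError):
    def __init__(self, problems: list[str]) -> None:
        super().__init__("invalid campaign config: " + "; ".join(problems))
        self.problems = problems


_PIPELINE_FAMILIES = ("rs", "hedges", "hedges_msa", "rot3")

_DEFAULTS = {
    "pipeline.index_width": 4,
    "pipeline.strands_per_packet": 200,
    "pipeline.outer_parity_strands": 0,
    "pipeline.beam_width": 16,
    "fault_model.kind": "iid",
    "copy_model.kind": "constant",
    "copy_model.depth": 1,
    "copy_model.dropout": 0.0,
    "iterations": 1,
    "workers": 1,
}


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        else:
            out[key] = v
    return out


def validate_config(cfg: dict) -> list[str]:
    """Return schema problems (field paths with reasons); empty = valid."""
    problems = []
    flat = _flatten(cfg)

    def scalars(key):
        v = flat.get(key)
        return v if isinstance(v, list) else [v]

    for fam in scalars("pipeline.family"):
        if fam not in _PIPELINE_FAMILIES:
            problems.append(
                f"pipeline.family: {fam!r} not one of {_PIPELINE_FAMILIES}"
            )
    if "input.random_bytes" not in flat and "input.path" not in flat:
        problems.append("input: needs random_bytes or path")
    for it in scalars("iterations"):
        if it is not None and (not isinstance(it, int) or it < 1):
            problems.append("iterations: must be a positive integer")
    if not isinstance(flat.get("master_seed"), int):
        problems.append("master_seed: required integer")
    for d in scalars("copy_model.depth"):
        if d is not None and (not isinstance(d, (int, float)) or d < 0):
            problems.append("copy_model.depth: must be >= 0")
    for r in scalars("fault_model.rate"):
        if r is not None and not (0 <= r <= 1):
            problems.append("fault_model.rate: must be in [0, 1]")
    fams = scalars("pipeline.family")
    if "pipeline.inner" not in flat:
        if any(f in ("rs", "rot3") for f in fams):
            if "pipeline.payload_bytes" not in flat:
                problems.append("pipeline.payload_bytes: required for rs/rot3")
        if "rs" in fams and "pipeline.inner_parity" not in flat:
            problems.append("pipeline.inner_parity: required for rs")
        if any(f in ("hedges", "hedges_msa") for f in fams):
            if "pipeline.rate" not in flat or "pipeline.payload_bytes" not in flat:
                problems.append("pipeline.rate/payload_bytes: required for hedges")
    return problems


@dataclass
class RunConfig:
    """One concrete parameter combination of a campaign sweep."""

    run_id: int
    params: dict  # flat dotted-key -> scalar value
    swept: dict  # the subset that was swept, for the directory name
    seed: int

    @property
    def dirname(self) -> str:
        if not self.swept:
            return f"run_{self.run_id:04d}"
        parts = "__".join(
            f"{k.split('.')[-1]}={v}" for k, v in sorted(self.swept.items())
        )
        return f"run_{parts}"


def expand_sweep(cfg: dict) -> list[RunConfig]:
    """Cross-product expansion of list-valued fields, deterministic order."""
    problems = validate_config(cfg)
    if problems:
        raise ConfigError(problems)
    flat = dict(_DEFAULTS)
    flat.update(_flatten(cfg))
    sweep_keys = sorted(k for k, v in flat.items() if isinstance(v, list))
    runs = []
    grids = [flat[k] for k in sweep_keys]
    for run_id, combo in enumerate(itertools.product(*grids)):
        params = dict(flat)
        swept = {}
        for k, v in zip(sweep_keys, combo):
            params[k] = v
            swept[k] = v
        runs.append(
            RunConfig(
                run_id=run_id,
                params=params,
                swept=swept,
                seed=derive_seed(flat["master_seed"], run_id),
            )
        )
    return runs


def expand_campaigns(cfgs: Sequence[dict]) -> list[RunConfig]:
    """Expand a list of campaign configs into one flat run list."""
    runs = []
    for cfg in cfgs:
        base = len(runs)
        for r in expand_sweep(cfg):
            r.run_id += base
            runs.append(r)
    return runs


# ---------------------------------------------------------------------------
# building the concrete objects of one run


def _apply_compound_params(params: dict) -> dict:
    """Expand compound sweep values into their scalar fields.

    ``pipeline.inner`` pairs the two inner-code knobs so they sweep together:
    ``"x,y"`` means (parity bytes, payload bytes) for the rs family and
    (rate, payload bytes) for the hedges families. ``fault_model.spec``
    couples kind and rate: ``"iid:0.05"`` or ``"contextual:nanopore:0.05"``.
    """
    params = dict(params)
    inner = params.get("pipeline.inner")
    if inner is not None:
        a, b = str(inner).split(",")
        if params["pipeline.family"] in ("rs", "rot3"):
            params["pipeline.inner_parity"] = int(a)
            params["pipeline.payload_bytes"] = int(b)
        else:
            params["pipeline.rate"] = float(a)
            params["pipeline.payload_bytes"] = int(b)
    fault = params.get("fault_model.spec")
    if fault is not None:
        parts = str(fault).split(":")
        params["fault_model.kind"] = parts[0]
        if parts[0] == "iid":
            params["fault_model.rate"] = float(parts[1])
        elif parts[0] == "contextual":
            if len(parts) > 2:
                params["fault_model.rate"] = float(parts[2])
    return params


def build_pipeline(params: dict) -> PipelineSpec:
    params = _apply_compound_params(params)
    fam = params["pipeline.family"]
    common = dict(
        index_width=params["pipeline.index_width"],
        strands_per_packet=params["pipeline.strands_per_packet"],
        outer_parity_strands=params["pipeline.outer_parity_strands"],
    )
    if fam == "rs":
        return rs_pipeline(
            params["pipeline.inner_parity"],
            params["pipeline.payload_bytes"],
            **common,
        )
    if fam == "rot3":
        return rot3_pipeline(params["pipeline.payload_bytes"], **common)
    maker = hedges_pipeline if fam == "hedges" else hedges_msa_pipeline
    return maker(
        params["pipeline.rate"],
        params["pipeline.payload_bytes"],
        beam_width=params["pipeline.beam_width"],
        **common,
    )


def build_copy_model(params: dict) -> CopyModel:
    return CopyModel(
        kind=params["copy_model.kind"],
        mean_depth=float(params["copy_model.depth"]),
        dropout_prob=float(params["copy_model.dropout"]),
    )


def build_injector(params: dict) -> Callable[[str, int], tuple[str, list]]:
    params = _apply_compound_params(params)
    kind = params["fault_model.kind"]
    if kind == "iid":
        if "fault_model.rate" in params and params["fault_model.rate"] is not None:
            model = IIDErrorModel.from_total_rate(float(params["fault_model.rate"]))
        else:
            model = IIDErrorModel(
                p_sub=float(params.get("fault_model.p_sub", 0.0)),
                p_ins=float(params.get("fault_model.p_ins", 0.0)),
                p_del=float(params.get("fault_model.p_del", 0.0)),
            )
        return lambda dna, seed: inject_iid(dna, model, seed)
    if kind == "contextual":
        if "fault_model.table" in params:
            cmodel = load_context_table(params["fault_model.table"])
        else:
            cmodel = synthetic_nanopore_model(
                base_rate=float(params.get("fault_model.rate", 0.05)),
                burst_continue=float(params.get("fault_model.burst_continue", 0.4)),
            )
        return lambda dna, seed: inject_contextual(dna, cmodel, seed)
    raise ConfigError([f"fault_model.kind: unknown kind {kind!r}"])


def load_input(params: dict) -> bytes:
    if params.get("input.path"):
        with open(params["input.path"], "rb") as fh:
            return fh.read()
    import numpy as np

    n = int(params["input.random_bytes"])
    rng = np.random.default_rng(derive_seed(params["master_seed"], 0xDA7A))
    return rng.integers(0, 256, size=n, dtype=np.uint8).tobytes()


# ---------------------------------------------------------------------------
# one fault-injection iteration (module-level for picklability)

_WORKER_STATE: dict = {}


def _init_worker(run_params: dict) -> None:
    spec = build_pipeline(run_params)
    data = load_input(run_params)
    strands = encode(spec, data)
    _WORKER_STATE.update(
        spec=spec,
        data=data,
        strands=strands,
        copy_model=build_copy_model(run_params),
        injector=build_injector(run_params),
        seed=run_params["__run_seed__"],
        truth={
            s.origin_index: payload
            for s, payload in zip(
                strands, _truth_payloads(spec, data, strands)
            )
        },
    )


def _truth_payloads(
    spec: PipelineSpec, data: bytes, strands: Sequence[EncodedStrand]
) -> list[bytes]:
    from .pipeline import assign_indices, partition_file
    from .codecs import outer_rs_encode

    packets = partition_file(data, spec.payload_bytes, spec.strands_per_packet)
    if spec.outer_stages:
        for p in packets:
            outer_rs_encode(p, spec.outer_stages[0].n_parity_strands)
    indexed = assign_indices(packets, spec.index_width)
    return [seq.payload for seq in indexed]


def _run_iteration(it: int) -> dict:
    st = _WORKER_STATE
    spec: PipelineSpec = st["spec"]
    strands: list[EncodedStrand] = st["strands"]
    stats = RunStats()
    reads: list[str] = []
    origins: list[int] = []
    for s in strands:
        copies = sample_copies(
            st["copy_model"], derive_seed(st["seed"], it, s.origin_index, -1)
        )
        for ci in copies:
            noisy, log = st["injector"](
                s.dna, derive_seed(st["seed"], it, s.origin_index, ci)
            )
            for kind, pos, _base in log:
                stats.record("base_errors_by_position", pos)
                stats.incr(f"injected_{kind}")
            stats.incr("injected_bases", len(s.dna))
            reads.append(noisy)
            origins.append(s.origin_index)
    expected_total = len(strands)
    out, dec_stats, consolidated = decode_detailed(
        spec,
        reads,
        expected_total,
        origins=origins,
        original_length=len(st["data"]),
    )
    stats.merge(dec_stats)
    truth: dict[int, bytes] = st["truth"]
    for idx in range(expected_total):
        o = consolidated.get(idx)
        if o is None or o.status is not DecodeStatus.SUCCESS:
            stats.incr("strand_erasure")
        elif o.recovered.payload == truth[idx]:
            stats.incr("strand_success")
        else:
            stats.incr("strand_silent")
            for j, (a, b) in enumerate(zip(o.recovered.payload, truth[idx])):
                if a != b:
                    stats.record("byte_errors_by_position", j)
    stats.incr("strands_processed", expected_total)
    stats.incr("iterations", 1)
    if out != st["data"]:
        stats.incr("file_corrupt")
    return stats.to_dict()


def _safe_iteration(it: int) -> tuple[int, Optional[dict], Optional[str]]:
    try:
        return it, _run_iteration(it), None
    except Exception as exc:  # noqa: BLE001 - recorded, campaign continues
        return it, None, f"{type(exc).__name__}: {exc}"


def parallel_map(
    fn: Callable[[int], tuple[int, Optional[dict], Optional[str]]],
    units: Sequence[int],
    workers: int,
    init: Callable[[], None],
) -> list[tuple[int, Optional[dict], Optional[str]]]:
    """Deterministic process-pool map: results are returned in unit order and
    must not depend on worker count (unit seeds are derived, not drawn).
    Failed units are retried once in the parent, then marked failed."""
    if workers <= 1:
        init()
        results = [fn(u) for u in units]
    else:
        ctx = multiprocessing.get_context("fork")
        with ctx.Pool(workers, initializer=init) as pool:
            results = pool.map(fn, units)
        init()  # parent state for retries
    retried = []
    for it, res, err in results:
        if res is None:
            retried.append(fn(it))
        else:
            retried.append((it, res, err))
    return retried


def run_fault_injection(
    run: RunConfig, workers: int = 1, out_dir: Optional[str] = None
) -> RunStats:
    """Execute one concrete run: N iterations of encode/inject/decode."""
    params = dict(run.params)
    params["__run_seed__"] = run.seed
    iterations = int(params["iterations"])
    init = partial(_init_worker, params)
    results = parallel_map(_safe_iteration, list(range(iterations)), workers, init)
    total = RunStats()
    for it, res, err in sorted(results, key=lambda r: r[0]):
        if res is None:
            total.incr("iterations_failed")
        else:
            total.merge(RunStats.from_dict(res))
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        record = {k: v for k, v in run.params.items()}
        record["__fingerprint__"] = spec_fingerprint(record)
        record["__seed__"] = run.seed
        write_manifest(os.path.join(out_dir, "params.json"), record)
        with open(os.path.join(out_dir, "stats.json"), "w") as fh:
            fh.write(total.to_json())
            fh.write("\n")
    return total


def run_campaign(
    cfgs: Sequence[dict] | dict,
    out_dir: str,
    workers: int = 1,
) -> dict[str, RunStats]:
    """Expand and execute a campaign; one subdirectory per run plus a merged
    campaign-level statistics file."""
    if isinstance(cfgs, dict):
        cfgs = [cfgs]
    runs = expand_campaigns(cfgs)
    out: dict[str, RunStats] = {}
    merged = RunStats()
    for run in runs:
        stats = run_fault_injection(
            run, workers=workers, out_dir=os.path.join(out_dir, run.dirname)
        )
        out[run.dirname] = stats
        merged.merge(stats)
    with open(os.path.join(out_dir, "campaign_stats.json"), "w") as fh:
        fh.write(merged.to_json())
        fh.write("\n")
    return out


# ---------------------------------------------------------------------------
# NGS read mapping


def map_reads(
    reads: Sequence[tuple[str, str]],
    library: Sequence[EncodedStrand],
    mode: str = "by_alignment",
    spec: Optional[PipelineSpec] = None,
) -> list[dict]:
    """Assign sequencing reads to the encoded strands they originated from.

    ``by_index`` runs the inner decode on each read and reports the decoded
    strand index; ``by_alignment`` reports the argmin-edit-distance library
    strand, leaving ties unassigned with a reason.
    """
    if not library:
        raise ValueError("library must be nonempty")
    if mode not in ("by_index", "by_alignment"):
        raise ValueError(f"unknown mapping mode {mode!r}")
    if mode == "by_index" and spec is None:
        raise ValueError("by_index mapping requires the pipeline spec")
    rows = []
    skipped = 0
    for read_id, dna in reads:
        if not dna or any(c not in "ACGT" for c in dna):
            skipped += 1
            continue
        if mode == "by_index":
            from .pipeline import inner_decode

            outcome = inner_decode(spec, dna)
            if outcome.status is DecodeStatus.SUCCESS:
                rows.append(
                    {"read_id": read_id, "assigned": outcome.recovered.index,
                     "reason": "decoded"}
                )
            else:
                rows.append(
                    {"read_id": read_id, "assigned": None,
                     "reason": "inner decode failed"}
                )
        else:
            dists = [
                edlib.align(dna, s.dna, mode="NW")["editDistance"]
                for s in library
            ]
            dmin = min(dists)
            argmins = [i for i, d in enumerate(dists) if d == dmin]
            if len(argmins) > 1:
                rows.append(
                    {"read_id": read_id, "assigned": None, "distance": dmin,
                     "reason": f"ambiguous: {len(argmins)} equidistant strands"}
                )
            else:
                rows.append(
                    {"read_id": read_id,
                     "assigned": library[argmins[0]].origin_index,
                     "distance": dmin, "reason": "best alignment"}
                )
    if skipped:
        rows.append(
            {"read_id": None, "assigned": None,
             "reason": f"skipped {skipped} malformed records"}
        )
    return rows
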