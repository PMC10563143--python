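"""Read/write-density trade-off analysis.

From fault-injection statistics this layer estimates per-strand decode
rates, provisions the outer code so a file meets a mean-time-to-failure
target, converts the resulting redundancy into read and write densities
(bits per base synthesized/sequenced), and extracts the Pareto frontier
over those two costs.

The outer code is a Reed-Solomon errors-and-erasures code across strands: a
strand that fails detectably (or never arrives) is an *erasure* consuming
one parity strand; an undetected wrong payload is a *silent* error consuming
two. A packet of k data + c parity strands therefore fails when
``2*S + E > c`` with (S, E) the silent/erasure counts among the k+c strands,
modelled as a trinomial draw from the measured per-strand rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .stats import RunStats


@dataclass
class StrandRates:
    """Per-strand decode outcome proportions with Wilson 95% intervals."""

    p_success: float
    p_erasure: float
    p_silent: float
    n_samples: int
    ci_success: tuple[float, float]

    @classmethod
    def from_counts(
        cls, n_success: int, n_erasure: int, n_silent: int
    ) -> "StrandRates":
        n = n_success + n_erasure + n_silent
        if n < 1:
            raise ValueError("need at least one strand sample")
        return cls(
            p_success=n_success / n,
            p_erasure=n_erasure / n,
            p_silent=n_silent / n,
            n_samples=n,
            ci_success=wilson_interval(n_success, n),
        )


def wilson_interval(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    """Wilson score 95% interval for a binomial proportion."""
    if n == 0:
        raise ValueError("zero samples")
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


def estimate_rates(stats: RunStats) -> StrandRates:
    """Maximum-likelihood outcome proportions from run statistics."""
    c = stats.counters
    return StrandRates.from_counts(
        c.get("strand_success", 0),
        c.get("strand_erasure", 0),
        c.get("strand_silent", 0),
    )


def packet_failure_prob(k: int, c: int, rates: StrandRates) -> float:
    """P[2*S + E > c] for a packet of k data + c parity strands.

    S (silent) and E (erasure) counts over the n = k + c strands follow a
    trinomial with the measured per-strand probabilities; the probability is
    computed by exact summation over the joint support.
    """
    if k + c > 255:
        raise ValueError("k + c exceeds 255")
    n = k + c
    p_e, p_s = rates.p_erasure, rates.p_silent
    p_ok = max(0.0, 1.0 - p_e - p_s)
    if p_e == 0 and p_s == 0:
        return 0.0
    # P[S=s, E=e] = C(n,s) C(n-s,e) p_s^s p_e^e p_ok^(n-s-e)
    total_fail = 0.0
    log_ps = math.log(p_s) if p_s > 0 else -math.inf
    log_pe = math.log(p_e) if p_e > 0 else -math.inf
    log_pok = math.log(p_ok) if p_ok > 0 else -math.inf
    for s in range(n + 1):
        if p_s == 0 and s > 0:
            break
        for e in range(n - s + 1):
            if 2 * s + e <= c:
                continue
            if p_e == 0 and e > 0:
                break
            lp = (
                _log_comb(n, s)
                + _log_comb(n - s, e)
                + s * (log_ps if s else 0.0)
                + e * (log_pe if e else 0.0)
                + (n - s - e) * (log_pok if n - s - e else 0.0)
            )
            total_fail += math.exp(lp)
    return min(1.0, total_fail)


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


@dataclass
class ProvisionResult:
    k: int
    c: int
    packets_per_file: int
    failure_prob_per_access: float
    feasible: bool


def provision_outer(
    rates: StrandRates,
    file_bits: int = 8_000_000,
    mttf: float = 1e9,
    k: int = 200,
    payload_bytes_per_strand: int = 55,
    fold_dropout: float = 0.0,
) -> ProvisionResult:
    """Smallest parity strand count c meeting the reliability target.

    The file fails an access when any of its packets fails; the target is a
    per-access failure probability of at most 1/mttf. Infeasible when c
    would push the packet beyond the 255-strand field limit.

    Physical strand dropout is excluded by default (the channel decode rate
    already reflects sequencing errors only); a fixed dropout probability can
    be folded into the erasure rate via ``fold_dropout``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if fold_dropout:
        p_era = 1.0 - (1.0 - rates.p_erasure) * (1.0 - fold_dropout)
        rates = replace(rates, p_erasure=p_era, p_success=max(0.0, 1.0 - p_era - rates.p_silent))
    data_bytes = file_bits // 8
    packets = math.ceil(
        math.ceil(data_bytes / payload_bytes_per_strand) / k
    )
    target = 1.0 / mttf
    for c in range(0, 256 - k):
        pf = packet_failure_prob(k, c, rates)
        file_fail = 1.0 - (1.0 - pf) ** packets
        if file_fail <= target:
            return ProvisionResult(k, c, packets, file_fail, True)
    pf = packet_failure_prob(k, 255 - k, rates)
    return ProvisionResult(
        k, 255 - k, packets, 1.0 - (1.0 - pf) ** packets, False
    )


@dataclass
class DensityPoint:
    """A (write density, read density) cost point in bits/base."""

    write_density: float
    read_density: float
    label: str = ""
    depth: float = 1.0

    def dominates(self, other: "DensityPoint") -> bool:
        ge = (
            self.read_density >= other.read_density
            and self.write_density >= other.write_density
        )
        gt = (
            self.read_density > other.read_density
            or self.write_density > other.write_density
        )
        return ge and gt


def compute_densities(
    payload_bytes: int,
    strand_length_bases: int,
    provision: ProvisionResult,
    depth: float,
    label: str = "",
) -> DensityPoint:
    """Densities in bits/base for a provisioned configuration.

    Only user payload counts as "bits" (index, inner parity and outer parity
    are overhead); all synthesized strands count as bases written, and depth
    scales the bases read.
    """
    if not provision.feasible:
        raise ValueError("cannot compute densities for an infeasible provision")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    k, c = provision.k, provision.c
    data_bits = payload_bytes * 8 * k
    total_bases = strand_length_bases * (k + c)
    write_density = data_bits / total_bases
    return DensityPoint(
        write_density=write_density,
        read_density=write_density / depth,
        label=label,
        depth=depth,
    )


def pareto_front(points: Iterable[DensityPoint]) -> list[DensityPoint]:
    """Maximal non-dominated subset under (max read, max write) density.

    Duplicate coordinate pairs collapse to one representative (first in
    input order); output is sorted by read density ascending.
    """
    pts = list(points)
    seen: set[tuple[float, float]] = set()
    uniq: list[DensityPoint] = []
    for p in pts:
        key = (p.read_density, p.write_density)
        if key not in seen:
            seen.add(key)
            uniq.append(p)
    front = [
        p
        for p in uniq
        if not any(q.dominates(p) for q in uniq)
    ]
    return sorted(front, key=lambda p: (p.read_density, p.write_density))


def density_table(
    entries: Sequence[dict],
) -> "object":
    """Assemble a pandas DataFrame of density points with an ``on_front``
    flag, mirroring the CSV layout of the analysis CLI.

    Each entry needs keys: config, depth, inner, write_density, read_density.
    """
    import pandas as pd

    df = pd.DataFrame(entries)
    pts = [
        DensityPoint(
            write_density=row["write_density"],
            read_density=row["read_density"],
            label=str(row["config"]),
            depth=row["depth"],
        )
        for _, row in df.iterrows()
    ]
    front = pareto_front(pts)
    front_keys = {(p.read_density, p.write_density) for p in front}
    df["on_front"] = [
        (p.read_density, p.write_density) in front_keys for p in pts
    ]
    return df


def plot_density_fronts(df, path: str) -> None:
    """Scatter the density points of a case-study table, one series per
    pipeline family, with the per-error-rate Pareto front drawn through the
    non-dominated points."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    error_rates = sorted(df["error_rate"].unique())
    fig, axes = plt.subplots(
        1, len(error_rates), figsize=(5 * len(error_rates), 4), squeeze=False
    )
    for ax, err in zip(axes[0], error_rates):
        group = df[(df["error_rate"] == err) & df["feasible"]]
        for fam, sub in group.groupby("family"):
            ax.scatter(sub["read_density"], sub["write_density"], label=fam)
        front = group[group["on_front"]].sort_values("read_density")
        ax.plot(front["read_density"], front["write_density"], "k--", lw=1)
        ax.set_xlabel("read density (bits/base)")
        ax.set_ylabel("write density (bits/base)")
        ax.set_title(f"i.i.d. total error rate {err:.0%}")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
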