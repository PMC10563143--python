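"""Storage/sequencing channel simulation.

Two layers model what happens between synthesis and the decoder input:

* a **copy model** — how many sequenced copies each encoded strand yields
  (constant or Poisson depth, with an optional whole-strand dropout
  probability modelling molecules lost from the pool entirely); and
* an **error model** — per-copy injection of substitutions, insertions and
  deletions, either i.i.d. per base or conditioned on the preceding k-mer
  with geometric deletion bursts (a nanopore-like error structure).

Every injection returns an edit log describing exactly which events were
applied at which position of the clean strand; replaying the log against the
clean strand reproduces the noisy copy bit-for-bit, which pins down the
event-ordering convention and keeps statistics honest.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .types import DNA_ALPHABET, validate_dna

EditLog = list[tuple[str, int, str]]  # (kind, clean-strand position, base)


@dataclass(frozen=True)
class CopyModel:
    """Sequencing-depth distribution for one encoded strand."""

    kind: str = "constant"  # constant | poisson
    mean_depth: float = 1.0
    dropout_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "poisson"):
            raise ValueError(f"unknown copy model kind {self.kind!r}")
        if self.kind == "constant" and self.mean_depth != int(self.mean_depth):
            raise ValueError("constant copy model requires integer depth")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ValueError("dropout_prob must be in [0, 1]")


def sample_copies(model: CopyModel, rng_seed: int) -> list[int]:
    """Return the copy slots (0..n-1) for one strand; empty on dropout."""
    rng = np.random.default_rng(rng_seed)
    if model.dropout_prob > 0 and rng.random() < model.dropout_prob:
        return []
    if model.kind == "constant":
        n = int(model.mean_depth)
    else:
        n = int(rng.poisson(model.mean_depth))
    return list(range(n))


@dataclass(frozen=True)
class IIDErrorModel:
    p_sub: float = 0.0
    p_ins: float = 0.0
    p_del: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_sub", "p_ins", "p_del"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_sub + self.p_del > 1.0:
            raise ValueError("p_sub + p_del must be <= 1 (exclusive events)")

    @classmethod
    def from_total_rate(cls, rate: float) -> "IIDErrorModel":
        """Split a total per-base event rate equally over sub/ins/del."""
        return cls(p_sub=rate / 3, p_ins=rate / 3, p_del=rate / 3)


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in DNA_ALPHABET if b != base]
    return choices[int(rng.integers(3))]


def inject_iid(dna: str, m: IIDErrorModel, rng_seed: int) -> tuple[str, EditLog]:
    """Inject i.i.d. errors, scanning the clean strand left to right.

    Before each position (and once after the last base) a geometric number of
    uniform-base insertions is applied; the position itself is then deleted
    with probability ``p_del``, else substituted with probability ``p_sub``
    (uniform over the three other bases).
    """
    rng = np.random.default_rng(rng_seed)
    out: list[str] = []
    log: EditLog = []
    n = len(dna)
    for i in range(n + 1):
        if m.p_ins > 0:
            while rng.random() < m.p_ins:
                b = DNA_ALPHABET[int(rng.integers(4))]
                out.append(b)
                log.append(("ins", i, b))
        if i == n:
            break
        u = rng.random()
        if u < m.p_del:
            log.append(("del", i, dna[i]))
        elif u < m.p_del + m.p_sub:
            b = _other_base(rng, dna[i])
            out.append(b)
            log.append(("sub", i, b))
        else:
            out.append(dna[i])
    return "".join(out), log


@dataclass(frozen=True)
class ContextRates:
    p_sub: float
    p_ins: float
    p_del: float
    sub_dist: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)


@dataclass
class ContextErrorModel:
    """k-mer-conditional error model with geometric deletion bursts.

    ``table`` maps a k-mer context (the k clean bases preceding the current
    position) to its rates; the mandatory ``default`` row covers unseen
    contexts. A triggered deletion extends to following bases with
    probability ``burst_continue`` each, giving geometric burst lengths with
    mean 1/(1-burst_continue).
    """

    k: int
    table: dict[str, ContextRates]
    burst_continue: float = 0.0

    def __post_init__(self) -> None:
        if "default" not in self.table:
            raise ValueError("context table requires a 'default' row")
        if not (0.0 <= self.burst_continue < 1.0):
            raise ValueError("burst_continue must be in [0, 1)")

    def rates_for(self, context: str) -> ContextRates:
        return self.table.get(context, self.table["default"])


def load_context_table(path: str) -> ContextErrorModel:
    """Read a contextual model from TSV with columns
    context, p_sub, p_ins, p_del, sub_A, sub_C, sub_G, sub_T."""
    table: dict[str, ContextRates] = {}
    k = 0
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            ctx = row["context"]
            if ctx != "default":
                validate_dna(ctx)
                k = max(k, len(ctx))
            table[ctx] = ContextRates(
                float(row["p_sub"]),
                float(row["p_ins"]),
                float(row["p_del"]),
                tuple(float(row[f"sub_{b}"]) for b in DNA_ALPHABET),
            )
    return ContextErrorModel(k=k or 1, table=table)


def synthetic_nanopore_model(
    base_rate: float = 0.05, burst_continue: float = 0.4, k: int = 3
) -> ContextErrorModel:
    """A synthetic nanopore-like parameter table (not fitted to real reads):
    deletion-heavy overall, with extra deletions after homopolymer contexts
    and geometric deletion bursts."""
    default = ContextRates(
        p_sub=base_rate * 0.35, p_ins=base_rate * 0.15, p_del=base_rate * 0.5
    )
    table = {"default": default}
    for b in DNA_ALPHABET:
        homo = b * k
        table[homo] = ContextRates(
            p_sub=base_rate * 0.3,
            p_ins=base_rate * 0.15,
            p_del=min(0.9, base_rate * 1.2),
        )
    return ContextErrorModel(k=k, table=table, burst_continue=burst_continue)


def _draw_sub(rng: np.random.Generator, base: str, dist) -> str:
    # condition the substitution distribution on differing from the original
    weights = [w if DNA_ALPHABET[i] != base else 0.0 for i, w in enumerate(dist)]
    total = sum(weights)
    if total <= 0:
        return _other_base(rng, base)
    u = rng.random() * total
    acc = 0.0
    for i, w in enumerate(weights):
        acc += w
        if u < acc:
            return DNA_ALPHABET[i]
    return DNA_ALPHABET[3]


def inject_contextual(
    dna: str, m: ContextErrorModel, rng_seed: int
) -> tuple[str, EditLog]:
    """Like :func:`inject_iid` but with per-position rates looked up by the
    preceding k clean bases, and burst-extended deletions."""
    rng = np.random.default_rng(rng_seed)
    out: list[str] = []
    log: EditLog = []
    n = len(dna)
    i = 0
    while i <= n:
        ctx = dna[max(0, i - m.k) : i]
        r = m.rates_for(ctx)
        if r.p_ins > 0:
            while rng.random() < r.p_ins:
                b = DNA_ALPHABET[int(rng.integers(4))]
                out.append(b)
                log.append(("ins", i, b))
        if i == n:
            break
        u = rng.random()
        if u < r.p_del:
            log.append(("del", i, dna[i]))
            i += 1
            # geometric burst continuation
            while i < n and rng.random() < m.burst_continue:
                log.append(("del", i, dna[i]))
                i += 1
            continue
        elif u < r.p_del + r.p_sub:
            b = _draw_sub(rng, dna[i], r.sub_dist)
            out.append(b)
            log.append(("sub", i, b))
        else:
            out.append(dna[i])
        i += 1
    return "".join(out), log


def replay_edit_log(clean: str, log: Iterable[tuple[str, int, str]]) -> str:
    """Apply an edit log to the clean strand; inverse check for injectors."""
    by_pos: dict[int, list[tuple[str, str]]] = {}
    for kind, pos, base in log:
        by_pos.setdefault(pos, []).append((kind, base))
    out: list[str] = []
    for i in range(len(clean) + 1):
        events = by_pos.get(i, [])
        deleted = False
        substituted: Optional[str] = None
        for kind, base in events:
            if kind == "ins":
                out.append(base)
            elif kind == "del":
                deleted = True
            elif kind == "sub":
                substituted = base
        if i == len(clean):
            break
        if deleted:
            continue
        out.append(substituted if substituted is not None else clean[i])
    return "".join(out)
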