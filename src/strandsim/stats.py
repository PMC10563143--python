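"""Mergeable statistics counters for fault-injection runs.

A :class:`RunStats` is a bag of named counters plus named position-indexed
histograms. Merging is associative and commutative (plain addition), so
per-iteration statistics computed by parallel workers fold into the same
totals regardless of order or worker count. Serialization is canonical
(sorted keys) so equal statistics produce byte-identical JSON.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field


@dataclass
class RunStats:
    counters: Counter = field(default_factory=Counter)
    histograms: dict[str, Counter] = field(default_factory=dict)

    def incr(self, name: str, n: int = 1) -> None:
        self.counters[name] += n

    def record(self, hist: str, position: int, n: int = 1) -> None:
        self.histograms.setdefault(hist, Counter())[int(position)] += n

    def merge(self, other: "RunStats") -> "RunStats":
        self.counters.update(other.counters)
        for name, h in other.histograms.items():
            self.histograms.setdefault(name, Counter()).update(h)
        return self

    def to_dict(self) -> dict:
        return {
            "counters": {k: self.counters[k] for k in sorted(self.counters)},
            "histograms": {
                name: {str(k): h[k] for k in sorted(h)}
                for name, h in sorted(self.histograms.items())
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "RunStats":
        stats = cls()
        stats.counters.update(d.get("counters", {}))
        for name, h in d.get("histograms", {}).items():
            stats.histograms[name] = Counter({int(k): v for k, v in h.items()})
        return stats
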