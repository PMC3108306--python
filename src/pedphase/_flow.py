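"""Plain s-t flow network container shared by the solver and the oracle.

Holds directed arcs with capacities and current flow values.  Undirected
edges are represented by two opposite arcs; multiple sources or sinks are
absorbed into super-terminals with unbounded capacity by the caller.
The container itself implements no algorithm: Edmonds-Karp lives in
:mod:`pedphase.gber`, exhaustive cut enumeration in :mod:`pedphase.oracle`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable

Node = Hashable


@dataclass
class FlowNetwork:
    source: Node
    sink: Node
    capacity: dict[tuple[Node, Node], float] = field(default_factory=dict)
    flow: dict[tuple[Node, Node], float] = field(default_factory=dict)

    def add_arc(self, u: Node, v: Node, cap: float) -> None:
        if u == v:
            return
        key = (u, v)
        self.capacity[key] = self.capacity.get(key, 0.0) + cap
        self.flow.setdefault(key, 0.0)

    def add_undirected(self, u: Node, v: Node, cap: float) -> None:
        self.add_arc(u, v, cap)
        self.add_arc(v, u, cap)

    @property
    def nodes(self) -> list[Node]:
        seen: dict[Node, None] = {self.source: None, self.sink: None}
        for u, v in self.capacity:
            seen.setdefault(u, None)
            seen.setdefault(v, None)
        return list(seen)

    def reset_flow(self) -> None:
        for key in self.flow:
            self.flow[key] = 0.0

    def cut_value(self, source_side: frozenset) -> float:
        """Total capacity of arcs leaving ``source_side``."""
        total = 0.0
        for (u, v), cap in self.capacity.items():
            if u in source_side and v not in source_side:
                total += cap
        return total

    def validate(self) -> None:
        if self.source == self.sink:
            raise ValueError("source and sink must differ")
        for (u, v), cap in self.capacity.items():
            if cap < 0:
                raise ValueError(f"negative capacity on arc ({u!r}, {v!r})")
            f = self.flow.get((u, v), 0.0)
            if f < -1e-9 or (not math.isinf(cap) and f > cap + 1e-9):
                raise ValueError(f"flow violates capacity on arc ({u!r}, {v!r})")
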