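"""Single-temperature Metropolis chain over tripartite hypergraphs.

The chain walks on *all* simple hypergraphs over the fixed vertex classes,
not only the realizations of the target degree sequence: its stationary
law is the Boltzmann distribution ``pi_T(H) \\propto exp(-energy(H, D)/T)``
where the energy is the L1 deviation of H's degree sequence from D.

Each step draws one of three operation kinds with equal probability (the
mixture is a config knob):

* switch  -- two edges drawn independently and uniformly (with
  replacement) and a uniformly drawn class; the class's vertices are
  swapped between the edges.  Degree-preserving, so a valid switch is
  always accepted.
* hinge flip -- a uniform edge, a uniform class, and a uniform replacement
  vertex from that class excluding the edge's current one.
* toggle -- a uniform cell of the ``n1 x n2 x n3`` grid; the edge there is
  deleted if present, inserted otherwise.

A proposal that would duplicate an existing edge (or that cannot be formed,
e.g. a switch on an empty edge set or a repeated edge draw) is an *invalid*
proposal: the chain stays put but the step is counted, keeping the
proposal kernel symmetric.  Acceptance follows the Metropolis rule on the
energy difference.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Sequence

from .hypergraph import (DegreeSequence, EditOp, TripartiteHypergraph,
                         apply_op)

__all__ = ["ChainStats", "MetropolisChain", "propose", "metropolis_step",
           "run_chain"]

_KINDS = ("switch", "hinge", "toggle")


@dataclass
class ChainStats:
    """Per-kind proposal bookkeeping: proposed = invalid + accepted + rejected."""

    proposed: dict = field(default_factory=lambda: dict.fromkeys(_KINDS, 0))
    invalid: dict = field(default_factory=lambda: dict.fromkeys(_KINDS, 0))
    accepted: dict = field(default_factory=lambda: dict.fromkeys(_KINDS, 0))
    rejected: dict = field(default_factory=lambda: dict.fromkeys(_KINDS, 0))

    def merge(self, other: "ChainStats") -> None:
        for k in _KINDS:
            self.proposed[k] += other.proposed[k]
            self.invalid[k] += other.invalid[k]
            self.accepted[k] += other.accepted[k]
            self.rejected[k] += other.rejected[k]

    def acceptance_rate(self, kind: str) -> float:
        p = self.proposed[kind]
        return self.accepted[kind] / p if p else math.nan

    def invalid_rate(self, kind: str) -> float:
        p = self.proposed[kind]
        return self.invalid[kind] / p if p else math.nan

    def as_dict(self) -> dict:
        return {"proposed": dict(self.proposed), "invalid": dict(self.invalid),
                "accepted": dict(self.accepted),
                "rejected": dict(self.rejected)}


class MetropolisChain:
    """Mutable chain state: hypergraph, target, temperature, statistics.

    Keeps an indexed edge list for O(1) uniform edge draws and per-vertex
    degree arrays for O(1) incremental energy updates; ``delta_g`` always
    equals the full energy recomputation (integers, no drift).
    """

    def __init__(self, H: TripartiteHypergraph, D: DegreeSequence,
                 temperature: float, rng: random.Random | int | None = None,
                 weights: Sequence[float] = (1 / 3, 1 / 3, 1 / 3)) -> None:
        if temperature <= 0:
            raise ValueError("temperature must be positive")
        if H.shape != D.shape:
            raise ValueError("H and D shapes differ")
        if len(weights) != 3 or abs(sum(weights) - 1) > 1e-9 \
                or min(weights) < 0:
            raise ValueError("op mixture must be 3 non-negative probs "
                             "summing to 1")
        self.H = H
        self.D = D
        self.T = float(temperature)
        self.rng = rng if isinstance(rng, random.Random) else random.Random(rng)
        self.w_switch = float(weights[0])
        self.w_hinge = float(weights[0]) + float(weights[1])
        self.stats = ChainStats()
        self._edge_list = list(H.edges)
        self._edge_pos = {e: i for i, e in enumerate(self._edge_list)}
        self._cur = (H.degrees(0), H.degrees(1), H.degrees(2))
        self._tgt = (D.dA, D.dB, D.dC)
        self.delta_g = sum(abs(c - t) for cur, tgt in zip(self._cur, self._tgt)
                           for c, t in zip(cur, tgt))
        self._acc_cache: dict[int, float] = {}

    # -- edge-index maintenance ---------------------------------------
    def _add(self, e) -> None:
        self.H.add_edge(e)
        self._edge_pos[e] = len(self._edge_list)
        self._edge_list.append(e)
        for c in range(3):
            self._bump(c, e[c], +1)

    def _remove(self, e) -> None:
        self.H.remove_edge(e)
        pos = self._edge_pos.pop(e)
        last = self._edge_list.pop()
        if last != e:
            self._edge_list[pos] = last
            self._edge_pos[last] = pos
        for c in range(3):
            self._bump(c, e[c], -1)

    def _bump(self, c: int, v: int, dv: int) -> None:
        cur = self._cur[c][v]
        t = self._tgt[c][v]
        self.delta_g += abs(cur + dv - t) - abs(cur - t)
        self._cur[c][v] = cur + dv

    def _vertex_delta(self, c: int, v: int, dv: int) -> int:
        cur = self._cur[c][v]
        t = self._tgt[c][v]
        return abs(cur + dv - t) - abs(cur - t)

    def _accept_prob(self, d: int) -> float:
        p = self._acc_cache.get(d)
        if p is None:
            p = math.exp(-d / self.T)
            self._acc_cache[d] = p
        return p

    # -- one step ------------------------------------------------------
    def step(self) -> bool:
        """Advance the chain by one step; True iff the state changed."""
        rng = self.rng
        H = self.H
        u = rng.random()
        if u < self.w_switch:
            self.stats.proposed["switch"] += 1
            ne = len(self._edge_list)
            if ne == 0:
                self.stats.invalid["switch"] += 1
                return False
            e1 = self._edge_list[rng.randrange(ne)]
            e2 = self._edge_list[rng.randrange(ne)]
            if e1 == e2:
                self.stats.invalid["switch"] += 1
                return False
            cls = rng.randrange(3)
            f1 = list(e1)
            f2 = list(e2)
            f1[cls], f2[cls] = e2[cls], e1[cls]
            f1 = tuple(f1)
            f2 = tuple(f2)
            if f1 in H or f2 in H:
                self.stats.invalid["switch"] += 1
                return False
            # degrees are untouched: always accepted
            self._remove(e1)
            self._remove(e2)
            self._add(f1)
            self._add(f2)
            self.stats.accepted["switch"] += 1
            return True
        if u < self.w_hinge:
            self.stats.proposed["hinge"] += 1
            ne = len(self._edge_list)
            if ne == 0:
                self.stats.invalid["hinge"] += 1
                return False
            e = self._edge_list[rng.randrange(ne)]
            cls = rng.randrange(3)
            size = H.shape[cls]
            if size == 1:
                self.stats.invalid["hinge"] += 1
                return False
            x = rng.randrange(size - 1)
            if x >= e[cls]:
                x += 1
            f = list(e)
            f[cls] = x
            f = tuple(f)
            if f in H:
                self.stats.invalid["hinge"] += 1
                return False
            d = (self._vertex_delta(cls, e[cls], -1)
                 + self._vertex_delta(cls, x, +1))
            if d > 0 and rng.random() >= self._accept_prob(d):
                self.stats.rejected["hinge"] += 1
                return False
            self._remove(e)
            self._add(f)
            self.stats.accepted["hinge"] += 1
            return True
        # toggle
        self.stats.proposed["toggle"] += 1
        n1, n2, n3 = H.shape
        cell = rng.randrange(n1 * n2 * n3)
        k = cell % n3
        j = (cell // n3) % n2
        i = cell // (n2 * n3)
        e = (i, j, k)
        if e in H:
            d = sum(self._vertex_delta(c, e[c], -1) for c in range(3))
            if d > 0 and rng.random() >= self._accept_prob(d):
                self.stats.rejected["toggle"] += 1
                return False
            self._remove(e)
        else:
            d = sum(self._vertex_delta(c, e[c], +1) for c in range(3))
            if d > 0 and rng.random() >= self._accept_prob(d):
                self.stats.rejected["toggle"] += 1
                return False
            self._add(e)
        self.stats.accepted["toggle"] += 1
        return True

    def run(self, n_steps: int, energy_trace: list | None = None) -> None:
        step = self.step
        if energy_trace is None:
            for _ in range(n_steps):
                step()
        else:
            append = energy_trace.append
            for _ in range(n_steps):
                step()
                append(self.delta_g)

    # swap support for Parallel Tempering: exchange the *states* of two
    # chains while each keeps its temperature and statistics
    def swap_state_with(self, other: "MetropolisChain") -> None:
        for attr in ("H", "_edge_list", "_edge_pos", "_cur", "delta_g"):
            a, b = getattr(self, attr), getattr(other, attr)
            setattr(self, attr, b)
            setattr(other, attr, a)


# ---------------------------------------------------------------------------
# functional API mirroring the class (convenient for one-off draws/tests)


def propose(H: TripartiteHypergraph, rng: random.Random,
            weights: Sequence[float] = (1 / 3, 1 / 3, 1 / 3)
            ) -> tuple[str, EditOp | None]:
    """Draw one proposal; returns (kind, op) with op None for a self-loop.

    Mirrors :meth:`MetropolisChain.step`'s proposal draw exactly (same
    random variates in the same order).
    """
    w_switch = weights[0]
    w_hinge = weights[0] + weights[1]
    u = rng.random()
    edges = sorted(H.edges)
    if u < w_switch:
        ne = len(edges)
        if ne == 0:
            return "switch", None
        e1 = edges[rng.randrange(ne)]
        e2 = edges[rng.randrange(ne)]
        if e1 == e2:
            return "switch", None
        cls = rng.randrange(3)
        op = EditOp.switch(e1, e2, cls)
        if any(f in H for f in op.added):
            return "switch", None
        return "switch", op
    if u < w_hinge:
        ne = len(edges)
        if ne == 0:
            return "hinge", None
        e = edges[rng.randrange(ne)]
        cls = rng.randrange(3)
        size = H.shape[cls]
        if size == 1:
            return "hinge", None
        x = rng.randrange(size - 1)
        if x >= e[cls]:
            x += 1
        op = EditOp.hinge(e, cls, x)
        if op.added[0] in H:
            return "hinge", None
        return "hinge", op
    n1, n2, n3 = H.shape
    cell = rng.randrange(n1 * n2 * n3)
    e = (cell // (n2 * n3), (cell // n3) % n2, cell % n3)
    return "toggle", EditOp.toggle(H, e)


def metropolis_step(H: TripartiteHypergraph, D: DegreeSequence, T: float,
                    rng: random.Random) -> TripartiteHypergraph:
    """One in-place Metropolis step on ``H``; returns ``H``."""
    from .hypergraph import EnergyTracker

    kind, op = propose(H, rng)
    if op is None:
        return H
    tracker = EnergyTracker(H, D)
    d = tracker.delta_if(op)
    if d > 0 and rng.random() >= math.exp(-d / T):
        return H
    return apply_op(H, op)


def run_chain(H0: TripartiteHypergraph, D: DegreeSequence, T: float,
              n_steps: int, rng: random.Random | int | None = None,
              weights: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
              energy_trace: list | None = None,
              trace_file=None) -> tuple[TripartiteHypergraph, ChainStats]:
    """Run a fresh chain for ``n_steps`` from a copy of ``H0``.

    Reproducible under a fixed integer seed; the final state and the
    per-kind statistics are returned.  ``energy_trace`` (if a list is
    passed) receives the post-step energy at every step; ``trace_file``
    (path or handle) gets a TSV of (step, energy, kind, outcome) rows.
    """
    chain = MetropolisChain(H0.copy(), D, T, rng, weights)
    if trace_file is None:
        chain.run(n_steps, energy_trace)
        return chain.H, chain.stats
    fh = open(trace_file, "w") if isinstance(trace_file, (str, bytes)) \
        or hasattr(trace_file, "__fspath__") else trace_file
    try:
        fh.write("step\tenergy\tkind\toutcome\n")
        prev = {k: dict(d) for k, d in chain.stats.as_dict().items()}
        for step in range(n_steps):
            chain.step()
            cur = chain.stats.as_dict()
            for kind in _KINDS:
                for outcome in ("accepted", "rejected", "invalid"):
                    if cur[outcome][kind] != prev[outcome][kind]:
                        fh.write(f"{step}\t{chain.delta_g}\t{kind}\t"
                                 f"{outcome}\n")
            prev = {k: dict(d) for k, d in cur.items()}
            if energy_trace is not None:
                energy_trace.append(chain.delta_g)
    finally:
        if fh is not trace_file:
            fh.close()
    return chain.H, chain.stats
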