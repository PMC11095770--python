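"""Shared fixtures and independent brute-force oracles for the test suite.

The helpers here are deliberately written as naive enumerations, separate
from the package's own (already brute-force but optimized) oracle module,
so that sampler and constructor results can be checked against code that
shares no logic with them.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import settings

import trisample as ts

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


@pytest.fixture
def counterexample_degrees() -> ts.DegreeSequence:
    """The tripartite sequence with two switch-disconnected realizations."""
    return ts.DegreeSequence((2, 4, 7), (2, 4, 7), (2, 4, 7))


def all_hypergraphs(n1: int, n2: int, n3: int):
    """Every simple hypergraph on the given classes (2^(n1 n2 n3) states)."""
    cells = list(itertools.product(range(n1), range(n2), range(n3)))
    for r in range(len(cells) + 1):
        for sub in itertools.combinations(cells, r):
            yield ts.TripartiteHypergraph(n1, n2, n3, sub)


def exact_boltzmann(D: ts.DegreeSequence, T: float) -> dict:
    """Exact Boltzmann law by full state-space enumeration (tiny shapes)."""
    n1, n2, n3 = D.shape
    probs = {}
    for H in all_hypergraphs(n1, n2, n3):
        probs[H.canonical_signature()] = math.exp(-ts.energy(H, D) / T)
    z = sum(probs.values())
    return {k: v / z for k, v in probs.items()}


def total_variation(empirical: dict, exact: dict, n: int) -> float:
    keys = set(empirical) | set(exact)
    return 0.5 * sum(abs(empirical.get(k, 0) / n - exact.get(k, 0.0))
                     for k in keys)


def enumerate_fiber(row_sums, col_sums) -> list[np.ndarray]:
    """All non-negative integer tables with the given margins."""
    R, C = list(row_sums), list(col_sums)
    nb, nc = len(R), len(C)
    out: list[np.ndarray] = []
    rows: list[list[int]] = []

    def row_options(total, caps):
        if len(caps) == 1:
            if total <= caps[0]:
                yield [total]
            return
        for v in range(min(total, caps[0]) + 1):
            for rest in row_options(total - v, caps[1:]):
                yield [v] + rest

    def rec(i, colrem):
        if i == nb:
            if all(c == 0 for c in colrem):
                out.append(np.array(rows, dtype=np.int64))
            return
        for row in row_options(R[i], colrem):
            rows.append(row)
            rec(i + 1, [c - v for c, v in zip(colrem, row)])
            rows.pop()

    rec(0, C)
    return out


def proposal_kernel(H: ts.TripartiteHypergraph) -> dict:
    """Exact one-step proposal distribution of the chain (pre-acceptance).

    Enumerates every random draw of the mixture kernel: both edge choices
    and the class for a switch, the edge/class/replacement vertex for a
    hinge flip, and the cell for a toggle.  Self-loops are dropped;
    returns {neighbor signature: probability}.
    """
    out: dict = {}
    edges = sorted(H.edges)
    ne = len(edges)
    n1, n2, n3 = H.shape

    def add(sig, p):
        out[sig] = out.get(sig, 0.0) + p

    if ne:
        p_pair = (1 / 3) * (1 / ne) * (1 / ne) * (1 / 3)
        for e1 in edges:
            for e2 in edges:
                if e1 == e2:
                    continue
                for cls in range(3):
                    op = ts.EditOp.switch(e1, e2, cls)
                    if all(f not in H for f in op.added):
                        G = H.copy()
                        ts.apply_op(G, op)
                        add(G.canonical_signature(), p_pair)
        for e in edges:
            for cls in range(3):
                size = H.shape[cls]
                if size == 1:
                    continue
                p_h = (1 / 3) * (1 / ne) * (1 / 3) * (1 / (size - 1))
                for x in range(size):
                    if x == e[cls]:
                        continue
                    op = ts.EditOp.hinge(e, cls, x)
                    if op.added[0] not in H:
                        G = H.copy()
                        ts.apply_op(G, op)
                        add(G.canonical_signature(), p_h)
    p_t = (1 / 3) * (1 / (n1 * n2 * n3))
    for cell in itertools.product(range(n1), range(n2), range(n3)):
        G = H.copy()
        ts.apply_op(G, ts.EditOp.toggle(H, cell))
        add(G.canonical_signature(), p_t)
    return out
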