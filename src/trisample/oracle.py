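"""Ground-truth brute force at desk scale.

Everything here is exhaustive and therefore only usable on tiny inputs,
guarded by explicit size limits.  The module serves three purposes:

* enumerate (or count) *all* realizations of a tripartite degree sequence,
  used to certify the polynomial constructor and the samplers;
* the same for general (non-partite) 3-uniform hypergraphs, which is where
  the classic switch-irreducibility counterexample lives;
* the reduction from the numerical 3-dimensional matching problem to
  tripartite graphicality, together with a brute-force 3DM solver, so the
  reduction can be validated in both directions on small instances.

Guards are configuration values with conservative defaults; exceeding a
guard raises :class:`GuardExceeded` rather than silently truncating.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Sequence

import numpy as np

from .hypergraph import DegreeSequence, TripartiteHypergraph

__all__ = [
    "GuardExceeded",
    "ThreeDMInstance",
    "ReductionOutput",
    "enumerate_partite_realizations",
    "count_partite_realizations",
    "count_nonpartite_3uniform_realizations",
    "enumerate_nonpartite_3uniform_realizations",
    "reduction_degree_sequence",
    "solve_3dm_brute_force",
    "symmetric_difference",
]


class GuardExceeded(Exception):
    """The instance is larger than the oracle's configured size guard."""


def _partite_search(D: DegreeSequence, collect: bool,
                    max_cells: int):
    n1, n2, n3 = D.shape
    if n2 * n3 > max_cells:
        raise GuardExceeded(
            f"slice size {n2}*{n3} exceeds guard {max_cells}; "
            "raise max_cells explicitly if this is intended")
    if not D.is_class_balanced or not D.within_capacity():
        return ([], 0)
    cells = [(j, k) for j in range(n2) for k in range(n3)]
    rb = list(D.dB)
    rc = list(D.dC)
    out: list[TripartiteHypergraph] = []
    count = 0
    chosen: list[tuple[int, int]] = []

    def feasible(remaining_a: int) -> bool:
        # each later A-vertex can cover b_j at most n3 times, c_k at most n2
        cap_b = remaining_a * n3
        cap_c = remaining_a * n2
        return (all(x <= cap_b for x in rb) and all(x <= cap_c for x in rc))

    def rec(i: int) -> None:
        nonlocal count
        if i == n1:
            if all(x == 0 for x in rb) and all(x == 0 for x in rc):
                count += 1
                if collect:
                    edges = []
                    pos = 0
                    for a, d in enumerate(D.dA):
                        for (j, k) in chosen[pos:pos + d]:
                            edges.append((a, j, k))
                        pos += d
                    out.append(TripartiteHypergraph(n1, n2, n3, edges))
            return
        d = D.dA[i]
        usable = [c for c in cells if rb[c[0]] > 0 and rc[c[1]] > 0]
        if len(usable) < d:
            return
        for slice_cells in combinations(usable, d):
            for (j, k) in slice_cells:
                rb[j] -= 1
                rc[k] -= 1
            if feasible(n1 - i - 1):
                chosen.extend(slice_cells)
                rec(i + 1)
                del chosen[len(chosen) - d:]
            for (j, k) in slice_cells:
                rb[j] += 1
                rc[k] += 1

    rec(0)
    return (out, count)


def enumerate_partite_realizations(D: DegreeSequence, max_cells: int = 30
                                   ) -> list[TripartiteHypergraph]:
    """All simple tripartite realizations of ``D``, duplicate-free.

    Backtracks over the A-vertices' incidence slices (subsets of the
    ``n2 x n3`` cell grid of the prescribed size) with running B/C
    capacity pruning.  The guard bounds the slice grid ``n2 * n3``.
    """
    out, _ = _partite_search(D, collect=True, max_cells=max_cells)
    return out


def count_partite_realizations(D: DegreeSequence, max_cells: int = 30) -> int:
    """Number of realizations of ``D`` (no hypergraphs materialized)."""
    _, count = _partite_search(D, collect=False, max_cells=max_cells)
    return count


def symmetric_difference(H1: TripartiteHypergraph,
                         H2: TripartiteHypergraph) -> int:
    """Number of hyperedges present in exactly one of the two hypergraphs."""
    return len(H1.edges ^ H2.edges)


# ---------------------------------------------------------------------------
# non-partite 3-uniform enumeration (constraint propagation over triples)


def _nonpartite_search(degrees: Sequence[int], collect: bool, max_n: int):
    n = len(degrees)
    if n > max_n:
        raise GuardExceeded(f"{n} vertices exceeds guard {max_n}")
    total = sum(degrees)
    if total % 3 != 0:
        return ([], 0)
    # relabel vertices by descending degree so the most constrained links
    # (the near-complete ones) are fixed first
    order = sorted(range(n), key=lambda v: -degrees[v])
    inv = {w: v for v, w in enumerate(order)}
    deg = [degrees[w] for w in order]
    triples = list(combinations(range(n), 3))
    m = len(triples)
    incident: list[list[int]] = [[] for _ in range(n)]
    for t_idx, t in enumerate(triples):
        for v in t:
            incident[v].append(t_idx)

    # state: -1 undecided, 0 out, 1 in
    state = [-1] * m
    rem = list(deg)              # remaining degree demand per vertex
    avail = [len(incident[v]) for v in range(n)]  # undecided incident count
    count = 0
    solutions: list[list[int]] = []

    from math import comb

    def set_state(t_idx: int, val: int, trail: list[int]) -> bool:
        """Decide a triple; returns False on an immediate contradiction."""
        if state[t_idx] != -1:
            return state[t_idx] == val
        state[t_idx] = val
        trail.append(t_idx)
        ok = True
        for v in triples[t_idx]:  # apply to all three before reporting
            avail[v] -= 1
            if val == 1:
                rem[v] -= 1
            if rem[v] < 0 or rem[v] > avail[v]:
                ok = False
        return ok

    def undo(trail: list[int], mark: int = 0) -> None:
        while len(trail) > mark:
            t_idx = trail.pop()
            val = state[t_idx]
            state[t_idx] = -1
            for v in triples[t_idx]:
                avail[v] += 1
                if val == 1:
                    rem[v] += 1

    def pick_vertex() -> int | None:
        """Undecided vertex with the fewest consistent link completions."""
        best, best_cost = None, None
        for v in range(n):
            if avail[v] == 0:
                continue
            if rem[v] < 0 or rem[v] > avail[v]:
                return v  # infeasible vertex; rec() fails immediately
            cost = comb(avail[v], min(rem[v], avail[v] - rem[v]))
            if best_cost is None or cost < best_cost:
                best, best_cost = v, cost
        return best

    def rec() -> None:
        nonlocal count
        v = pick_vertex()
        if v is None:
            if all(r == 0 for r in rem):
                count += 1
                if collect:
                    solutions.append([i for i in range(m) if state[i] == 1])
            return
        undecided = [t for t in incident[v] if state[t] == -1]
        # branch on the whole link of v: which of its undecided incident
        # triples are kept; enumerate the smaller side of the choice
        r = rem[v]
        if r < 0 or r > len(undecided):
            return
        for keep in combinations(undecided, r):
            keep_set = set(keep)
            trail: list[int] = []
            ok = True
            for t in undecided:
                if not set_state(t, 1 if t in keep_set else 0, trail):
                    ok = False
                    break
            if ok:
                rec()
            undo(trail)

    rec()
    edge_lists = [
        sorted(tuple(sorted(order[v] for v in triples[t])) for t in sol)
        for sol in solutions
    ]
    del inv
    return (edge_lists, count)


def count_nonpartite_3uniform_realizations(degrees: Sequence[int],
                                           max_n: int = 9) -> int:
    """Exact number of simple 3-uniform hypergraphs with these degrees.

    Constraint-propagation search over the ``C(n, 3)`` candidate triples:
    a vertex whose remaining demand hits zero forces its undecided triples
    out, one whose demand equals its undecided incidences forces them in,
    and branching always targets the most constrained vertex.
    """
    _, count = _nonpartite_search(degrees, collect=False, max_n=max_n)
    return count


def enumerate_nonpartite_3uniform_realizations(degrees: Sequence[int],
                                               max_n: int = 9
                                               ) -> list[list[tuple]]:
    """The realizations themselves, each a sorted list of vertex triples."""
    sols, _ = _nonpartite_search(degrees, collect=True, max_n=max_n)
    return sols


# ---------------------------------------------------------------------------
# numerical 3-dimensional matching and the reduction to graphicality


@dataclass(frozen=True)
class ThreeDMInstance:
    """Numerical 3-dimensional matching instance.

    The ground set is ``[n]`` with ``n = 3k``, partitioned into classes
    ``A``, ``B``, ``C`` of size ``k`` (0-based element indices); ``weights``
    assigns an integer to every element and ``bound`` is the prescribed
    per-triple weight sum.  A solution is a perfect matching: k disjoint
    triples, one element per class, each with weight sum ``bound``.
    """

    classes: tuple[tuple[int, ...], tuple[int, ...], tuple[int, ...]]
    weights: tuple[int, ...]
    bound: int

    def __post_init__(self) -> None:
        classes = tuple(tuple(int(x) for x in c) for c in self.classes)
        object.__setattr__(self, "classes", classes)
        object.__setattr__(self, "weights",
                           tuple(int(w) for w in self.weights))
        n = len(self.weights)
        k = len(classes[0])
        flat = sorted(x for c in classes for x in c)
        if not (len(classes[1]) == len(classes[2]) == k and n == 3 * k
                and flat == list(range(n))):
            raise ValueError("classes must partition [n] into equal thirds")
        if self.bound < 0:
            raise ValueError("bound must be non-negative")

    @property
    def k(self) -> int:
        return len(self.classes[0])

    @property
    def n(self) -> int:
        return len(self.weights)

    def balance_holds(self) -> bool:
        """The necessary total-weight condition 3*sum(a) == n*bound."""
        return 3 * sum(self.weights) == self.n * self.bound

    def to_json(self) -> str:
        return json.dumps({"classes": [list(c) for c in self.classes],
                           "weights": list(self.weights), "b": self.bound})

    @classmethod
    def from_json(cls, text: str) -> "ThreeDMInstance":
        obj = json.loads(text)
        return cls(tuple(tuple(c) for c in obj["classes"]),
                   tuple(obj["weights"]), int(obj["b"]))

    @classmethod
    def from_class_weights(cls, wA: Sequence[int], wB: Sequence[int],
                           wC: Sequence[int], bound: int
                           ) -> "ThreeDMInstance":
        k = len(wA)
        return cls((tuple(range(k)), tuple(range(k, 2 * k)),
                    tuple(range(2 * k, 3 * k))),
                   tuple(wA) + tuple(wB) + tuple(wC), bound)


@dataclass(frozen=True)
class ReductionOutput:
    """Degree sequence derived from a numerical 3DM instance.

    With ``w = 3a - b*1`` the degree of every element is one plus the
    number of triples (one element per class) whose total ``w``-weight is
    positive; the instance is solvable iff the resulting tripartite degree
    sequence is graphic.
    """

    w: tuple[int, ...]
    degrees: tuple[int, ...]          # indexed by ground-set element
    degree_sequence: DegreeSequence   # per-class view, class order A, B, C
    certified_no: bool = False        # total-weight condition violated

    @property
    def positive_triple_count(self) -> int:
        return (sum(self.degrees) - len(self.degrees)) // 3


def reduction_degree_sequence(inst: ThreeDMInstance) -> ReductionOutput:
    """Map a numerical 3DM instance to a tripartite degree sequence.

    If the necessary balance condition fails the instance has no solution
    and no meaningful sequence exists; the output is flagged
    ``certified_no`` and carries an all-zero sequence.
    """
    n, k = inst.n, inst.k
    w = tuple(3 * a - inst.bound for a in inst.weights)
    if not inst.balance_holds():
        zero = DegreeSequence((0,) * k, (0,) * k, (0,) * k)
        return ReductionOutput(w, (0,) * n, zero, certified_no=True)
    deg = [1] * n
    A, B, C = inst.classes
    for x in A:
        for y in B:
            for z in C:
                if w[x] + w[y] + w[z] > 0:
                    deg[x] += 1
                    deg[y] += 1
                    deg[z] += 1
    D = DegreeSequence(tuple(deg[x] for x in A), tuple(deg[y] for y in B),
                       tuple(deg[z] for z in C))
    return ReductionOutput(w, tuple(deg), D)


def solve_3dm_brute_force(inst: ThreeDMInstance, all_solutions: bool = False,
                          max_k: int = 5):
    """Exhaustive numerical 3DM solver.

    Scans the ``(k!)^2`` pairings of B and C elements to the A elements and
    keeps those whose every triple sums to the bound.  Returns one solution
    (list of index triples) or ``None``; with ``all_solutions=True``, the
    list of all solutions (canonically sorted, duplicate-free).
    """
    if inst.k > max_k:
        raise GuardExceeded(f"k={inst.k} exceeds guard {max_k}")
    if not inst.balance_holds():
        return [] if all_solutions else None
    A, B, C = inst.classes
    w = inst.weights
    b = inst.bound
    found: list[tuple] = []
    wC = sorted(w[z] for z in C)
    for permB in permutations(B):
        # the multiset of C weights needed by this A-B pairing must be
        # exactly the available multiset
        needed = [b - w[a] - w[x] for a, x in zip(A, permB)]
        if sorted(needed) != wC:
            continue
        for permC in permutations(C):
            if all(w[a] + w[x] + w[y] == b
                   for a, x, y in zip(A, permB, permC)):
                sol = tuple(sorted((a, x, y)
                                   for a, x, y in zip(A, permB, permC)))
                if not all_solutions:
                    return [list(t) for t in sol]
                if sol not in found:
                    found.append(sol)
    if all_solutions:
        return [[list(t) for t in sol] for sol in sorted(found)]
    return None
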