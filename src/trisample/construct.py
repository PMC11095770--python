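"""Deciding and constructing realizations of third almost-regular sequences.

A tripartite degree sequence is *third almost-regular* when every degree in
its first class equals ``k`` or ``k - 1`` for some ``k``.  For such
sequences graphicality is decidable -- and a realization constructible --
in polynomial time, by the following pipeline:

1. realize ``(dA, dB)`` as a bipartite *multigraph* (trivial: any
   non-negative matrix with those margins, here north-west-corner filling);
2. rebalance the multiplicity matrix by degree-preserving exchanges until
   every column holds only two values differing by 1 (*B-balanced*); for an
   almost-regular first class the balanced matrix is unique up to which
   rows carry the ceiling value, and its entries are forced column by
   column;
3. read the balanced entries as the degrees of the ``n1 * n2``
   pair-vertices, and realize the bipartite *simple* graph between
   pair-vertices and the C class with a Gale-Ryser / Havel-Hakimi greedy
   construction (or certify infeasibility);
4. lift the shadow graph back to a hypergraph.

The sequence is graphic iff step 3 succeeds.  The module also provides the
hinge-flip flattening that turns an arbitrary realization into one whose
first class is almost-regular, which underpins the irreducibility of the
sampler's move set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .hypergraph import (DegreeSequence, ProjectionMatrix, ShadowGraph,
                         TripartiteHypergraph, lift_shadow, is_b_balanced)

__all__ = [
    "Infeasible",
    "BalancedProjection",
    "ShadowDegreeSequence",
    "is_third_almost_regular",
    "realize_bipartite_multigraph",
    "balance_projection",
    "gale_ryser_realize",
    "lift_shadow",
    "realize_third_almost_regular",
    "flatten_class_by_hinge_flips",
    "flat_target",
]


@dataclass(frozen=True)
class Infeasible:
    """Typed negative answer carrying the violated condition.

    ``reason`` is one of ``class_sums`` (the three class sums differ),
    ``sum_mismatch`` (bipartite margins disagree), ``capacity`` (a degree
    exceeds its co-class product) or ``gale_ryser`` (the bipartite
    inequalities fail; ``detail`` holds the witnessing vertex).
    """

    reason: str
    detail: object = None

    def __bool__(self) -> bool:
        return False


def is_third_almost_regular(D: DegreeSequence | Sequence[int]
                            ) -> tuple[bool, int]:
    """Whether the first class's degrees all lie in {k, k-1}; returns k.

    For an all-equal first class k is that common value.  The second
    element is meaningful only when the first is True.
    """
    dA = D.dA if isinstance(D, DegreeSequence) else tuple(D)
    k = max(dA)
    return (k - min(dA) <= 1, k)


def realize_bipartite_multigraph(dA: Sequence[int], dB: Sequence[int]
                                 ) -> ProjectionMatrix | Infeasible:
    """Any non-negative integer matrix with row sums dA and column sums dB.

    North-west-corner filling: walk the cells in row-major order, placing
    the largest amount the two remaining margins allow.  Margins with equal
    sums are always feasible.
    """
    if sum(dA) != sum(dB):
        return Infeasible("sum_mismatch", (sum(dA), sum(dB)))
    m = np.zeros((len(dA), len(dB)), dtype=np.int64)
    row = list(dA)
    col = list(dB)
    for i in range(len(dA)):
        for j in range(len(dB)):
            x = min(row[i], col[j])
            m[i, j] = x
            row[i] -= x
            col[j] -= x
    return ProjectionMatrix(m, "AB")


@dataclass(frozen=True)
class BalancedProjection:
    """A B-balanced multiplicity matrix with its per-column structure.

    ``ceil_values[j]`` is the column's large value ``l_j`` and
    ``ceil_counts[j]`` how many rows carry it (the rest carry ``l_j - 1``),
    the unique split solving ``c*l + (n1 - c)*(l - 1) = colsum``.
    """

    counts: np.ndarray
    ceil_values: tuple[int, ...]
    ceil_counts: tuple[int, ...]
    n_exchanges: int = 0

    def as_projection(self) -> ProjectionMatrix:
        return ProjectionMatrix(self.counts, "AB")


def _column_targets(active_sums: list[int], col: np.ndarray
                    ) -> tuple[list[int], int, int]:
    """Prescribed balanced entries for one column, by row-sum class.

    Rows whose running (unprocessed) sum is the larger value ``k`` are
    served first with the ceiling entry; ties break at the lowest index.
    """
    n1 = len(active_sums)
    s = int(col.sum())
    l = -(-s // n1)
    n_ceil = s - n1 * (l - 1)  # count of l's in the balanced column
    k = max(active_sums)
    k_rows = [i for i in range(n1) if active_sums[i] == k]
    low_rows = [i for i in range(n1) if active_sums[i] != k]
    target = [l - 1] * n1
    if n_ceil <= len(k_rows):
        for i in k_rows[:n_ceil]:
            target[i] = l
    else:
        for i in k_rows:
            target[i] = l
        for i in low_rows[:n_ceil - len(k_rows)]:
            target[i] = l
    return target, l, n_ceil


def balance_projection(P: ProjectionMatrix | np.ndarray
                       ) -> BalancedProjection:
    """Rebalance a multiplicity matrix with almost-regular row sums.

    Columns are processed in ascending index order.  Within a column, a
    too-large entry (lowest row index first) and a too-small entry are
    adjusted by 1 each, compensated in a witness column where the
    increased row is over-represented; each exchange preserves all margins
    and lowers the column's L1 deviation from its balanced target by 2, so
    the loop terminates within half the initial total deviation.
    """
    m = (P.counts if isinstance(P, ProjectionMatrix) else
         np.asarray(P, dtype=np.int64)).copy()
    n1, n2 = m.shape
    row_sums = m.sum(axis=1)
    if row_sums.max() - row_sums.min() > 1:
        raise ValueError("row sums must be almost-regular (values k, k-1)")
    active = [int(x) for x in row_sums]
    unprocessed = list(range(n2))
    ceil_values: list[int] = []
    ceil_counts: list[int] = []
    moves = 0
    for j in range(n2):
        unprocessed.remove(j)
        target, l, n_ceil = _column_targets(active, m[:, j])
        ceil_values.append(l)
        ceil_counts.append(n_ceil)
        while True:
            over = [i for i in range(n1) if m[i, j] > target[i]]
            if not over:
                break
            under = [i for i in range(n1) if m[i, j] < target[i]]
            i = over[0]
            i2 = under[0]
            for j2 in unprocessed:
                if m[i2, j2] > m[i, j2]:
                    break
            else:
                raise RuntimeError(
                    "no compensating column; input row sums inconsistent")
            m[i, j] -= 1
            m[i2, j] += 1
            m[i2, j2] -= 1
            m[i, j2] += 1
            moves += 1
        for i in range(n1):
            active[i] -= int(m[i, j])
    assert is_b_balanced(m)
    return BalancedProjection(m, tuple(ceil_values), tuple(ceil_counts),
                              moves)


@dataclass(frozen=True)
class ShadowDegreeSequence:
    """Bipartite degree sequence of a shadow graph.

    ``pair_degrees[i, j]`` prescribes the degree of pair-vertex (i, j)
    towards the C class; ``dC`` the degrees of the C vertices.
    """

    pair_degrees: np.ndarray
    dC: tuple[int, ...]

    def __post_init__(self) -> None:
        pd = np.asarray(self.pair_degrees, dtype=np.int64)
        object.__setattr__(self, "pair_degrees", pd)
        object.__setattr__(self, "dC", tuple(int(x) for x in self.dC))
        if pd.ndim != 2 or (pd < 0).any():
            raise ValueError("pair degrees must be a non-negative matrix")


def gale_ryser_realize(dPairs: ShadowDegreeSequence
                       ) -> ShadowGraph | Infeasible:
    """Simple bipartite realization of (pair-degrees, dC), or a certificate.

    Greedy maximal-degree-first construction: repeatedly take the
    pair-vertex with the largest remaining demand and join it to the C
    vertices with the largest remaining demands (descending, stable by
    index).  The greedy step fails exactly when the Gale-Ryser
    inequalities do, so a failure certifies infeasibility.
    """
    pd = dPairs.pair_degrees
    n1, n2 = pd.shape
    n3 = len(dPairs.dC)
    if int(pd.sum()) != sum(dPairs.dC):
        return Infeasible("sum_mismatch", (int(pd.sum()), sum(dPairs.dC)))
    if int(pd.max(initial=0)) > n3:
        ij = np.unravel_index(int(pd.argmax()), pd.shape)
        return Infeasible("capacity", ("pair", tuple(int(x) for x in ij)))
    if any(d > n1 * n2 for d in dPairs.dC):
        return Infeasible("capacity", ("C", max(range(n3),
                                                key=lambda k: dPairs.dC[k])))
    pairs = sorted(((int(pd[i, j]), i, j) for i in range(n1)
                    for j in range(n2)), key=lambda t: (-t[0], t[1], t[2]))
    rc = list(dPairs.dC)
    edges: list[tuple[int, int, int]] = []
    for d, i, j in pairs:
        if d == 0:
            continue
        order = sorted(range(n3), key=lambda k: (-rc[k], k))
        if rc[order[d - 1]] <= 0:
            return Infeasible("gale_ryser", ("pair", (i, j)))
        for k in order[:d]:
            rc[k] -= 1
            edges.append((i, j, k))
    if any(x != 0 for x in rc):  # pragma: no cover - sums already matched
        return Infeasible("gale_ryser", ("C", rc))
    return ShadowGraph(n1, n2, n3, frozenset(edges))


def realize_third_almost_regular(D: DegreeSequence
                                 ) -> TripartiteHypergraph | Infeasible:
    """Decide graphicality of a third almost-regular D; build a realization.

    Returns a hypergraph realizing ``D`` or an :class:`Infeasible`
    certificate.  Raises ``ValueError`` if the first class is not
    almost-regular (that regime is for the stochastic sampler, not this
    constructor).
    """
    ok, _k = is_third_almost_regular(D)
    if not ok:
        raise ValueError("first class is not almost-regular; "
                         "use the Parallel Tempering sampler instead")
    if not D.is_class_balanced:
        return Infeasible("class_sums", D.class_sums)
    if not D.within_capacity():
        return Infeasible("capacity", "degree exceeds co-class product")
    P = realize_bipartite_multigraph(D.dA, D.dB)
    if isinstance(P, Infeasible):  # pragma: no cover - class sums checked
        return P
    bal = balance_projection(P)
    G = gale_ryser_realize(ShadowDegreeSequence(bal.counts, D.dC))
    if isinstance(G, Infeasible):
        return G
    H = lift_shadow(G)
    assert H.degree_sequence() == D
    return H


def flat_target(n_vertices: int, n_edges: int) -> tuple[int, ...]:
    """Canonical almost-regular sequence of length n summing to n_edges.

    ``k = ceil(n_edges / n_vertices)`` appears ``m`` times with
    ``m*k + (n - m)*(k - 1) = n_edges``; ceiling values come first.
    """
    k = -(-n_edges // n_vertices) if n_edges > 0 else 0
    if k == 0:
        return (0,) * n_vertices
    m = n_edges - n_vertices * (k - 1)
    return (k,) * m + (k - 1,) * (n_vertices - m)


def flatten_class_by_hinge_flips(H: TripartiteHypergraph,
                                 target_a: Sequence[int]
                                 ) -> tuple[TripartiteHypergraph, int]:
    """Hinge-flip H's first class onto an almost-regular target.

    Repeatedly moves one hyperedge from the largest-index vertex above its
    target to the smallest-index vertex below it (such a free (b, c) slot
    always exists because the surplus vertex covers strictly more pairs).
    B and C degrees are untouched.  Returns a flipped copy and the number
    of flips, which is half the initial L1 distance.
    """
    target = [int(x) for x in target_a]
    if len(target) != H.n1:
        raise ValueError("target length must equal |A|")
    if sum(target) != len(H):
        raise ValueError("target must sum to the edge count")
    if target and max(target) - min(target) > 1:
        raise ValueError("target must be almost-regular")
    H = H.copy()
    flips = 0
    while True:
        cur = H.degrees(0)
        surplus = [i for i in range(H.n1) if cur[i] > target[i]]
        if not surplus:
            break
        i = surplus[-1]
        j = min(i2 for i2 in range(H.n1) if cur[i2] < target[i2])
        moved = False
        for (a, b, c) in sorted(H.edges):
            if a == i and (j, b, c) not in H:
                H.remove_edge((i, b, c))
                H.add_edge((j, b, c))
                flips += 1
                moved = True
                break
        if not moved:  # pragma: no cover - guaranteed by counting argument
            raise RuntimeError("no hinge flip available")
    return H, flips
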