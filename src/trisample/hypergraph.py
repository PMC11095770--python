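"""Core data model for partite 3-uniform hypergraphs.

A partite 3-uniform hypergraph has three disjoint vertex classes ``A``,
``B``, ``C`` and every hyperedge takes exactly one vertex from each class,
so an edge is an index triple ``(i, j, k)``.  Hypergraphs here are always
*simple*: no parallel hyperedges.  Vertices are 0-based integer indices;
string labels live only in the I/O layer (:mod:`trisample.synth`).

The module provides

* :class:`TripartiteHypergraph` -- the Markov chain's state, a hash set of
  triples plus per-vertex degree arrays;
* :class:`DegreeSequence` -- the prescribed per-class degree lists;
* the three elementary edit operations (switch, hinge flip, toggle) as
  :class:`EditOp`, applied in place by :func:`apply_op`;
* the energy ``sum_v |d(v) - d_H(v)``, i.e. the L1 deviation of the current
  degree sequence from the prescribed one, maintained incrementally by
  :class:`EnergyTracker`;
* pairwise projections (bipartite multigraph multiplicity matrices), the
  shadow bipartite graph between pair-vertices and the third class, and the
  trace of a balanced projection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "TripartiteHypergraph",
    "DegreeSequence",
    "EditOp",
    "EnergyTracker",
    "ProjectionMatrix",
    "ShadowGraph",
    "InvalidOperation",
    "apply_op",
    "degree_sequence_of",
    "energy",
    "project",
    "shadow",
    "trace",
    "is_b_balanced",
    "read_edge_list",
    "write_edge_list",
]

Triple = tuple[int, int, int]

# class-pair labels accepted by project(); the third letter is the class
# that is collapsed into edge multiplicities
_PAIRS = {"AB": (0, 1, 2), "BC": (1, 2, 0), "AC": (0, 2, 1)}


class InvalidOperation(Exception):
    """An edit operation cannot be applied to the current hypergraph.

    In the Markov chain this signals a rejected (self-loop) proposal, not a
    programming error.
    """


class TripartiteHypergraph:
    """Simple partite 3-uniform hypergraph on classes of sizes ``n1, n2, n3``.

    Edges are stored in a set of index triples; per-vertex degrees are kept
    alongside so that edit operations are O(1).
    """

    __slots__ = ("n1", "n2", "n3", "_edges", "_dA", "_dB", "_dC")

    def __init__(self, n1: int, n2: int, n3: int,
                 edges: Iterable[Triple] = ()) -> None:
        if min(n1, n2, n3) < 1:
            raise ValueError("class sizes must be positive")
        self.n1, self.n2, self.n3 = int(n1), int(n2), int(n3)
        self._edges: set[Triple] = set()
        self._dA = [0] * self.n1
        self._dB = [0] * self.n2
        self._dC = [0] * self.n3
        for e in edges:
            self.add_edge(e)

    # -- basic container protocol -------------------------------------
    def __contains__(self, e: Triple) -> bool:
        return e in self._edges

    def __len__(self) -> int:
        return len(self._edges)

    def __iter__(self) -> Iterator[Triple]:
        return iter(self._edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TripartiteHypergraph):
            return NotImplemented
        return (self.shape == other.shape and self._edges == other._edges)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"TripartiteHypergraph({self.n1}, {self.n2}, {self.n3}, "
                f"|E|={len(self._edges)})")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n1, self.n2, self.n3)

    @property
    def n_cells(self) -> int:
        """Number of potential hyperedges, ``n1 * n2 * n3``."""
        return self.n1 * self.n2 * self.n3

    @property
    def edges(self) -> frozenset[Triple]:
        return frozenset(self._edges)

    def edge_set(self) -> set[Triple]:
        """The live edge set.  Mutate only through add/remove/apply."""
        return self._edges

    # -- mutation ------------------------------------------------------
    def _check_range(self, e: Triple) -> None:
        i, j, k = e
        if not (0 <= i < self.n1 and 0 <= j < self.n2 and 0 <= k < self.n3):
            raise ValueError(f"triple {e} out of range for shape {self.shape}")

    def add_edge(self, e: Triple) -> None:
        e = (int(e[0]), int(e[1]), int(e[2]))
        self._check_range(e)
        if e in self._edges:
            raise InvalidOperation(f"duplicate hyperedge {e}")
        self._edges.add(e)
        self._dA[e[0]] += 1
        self._dB[e[1]] += 1
        self._dC[e[2]] += 1

    def remove_edge(self, e: Triple) -> None:
        if e not in self._edges:
            raise InvalidOperation(f"hyperedge {e} not present")
        self._edges.remove(e)
        self._dA[e[0]] -= 1
        self._dB[e[1]] -= 1
        self._dC[e[2]] -= 1

    def copy(self) -> "TripartiteHypergraph":
        h = TripartiteHypergraph.__new__(TripartiteHypergraph)
        h.n1, h.n2, h.n3 = self.n1, self.n2, self.n3
        h._edges = set(self._edges)
        h._dA = list(self._dA)
        h._dB = list(self._dB)
        h._dC = list(self._dC)
        return h

    # -- views ---------------------------------------------------------
    def degree_sequence(self) -> "DegreeSequence":
        return DegreeSequence(tuple(self._dA), tuple(self._dB), tuple(self._dC))

    def degrees(self, cls: int) -> list[int]:
        """Current degree list of class 0 (A), 1 (B) or 2 (C)."""
        return list((self._dA, self._dB, self._dC)[cls])

    def canonical_signature(self) -> tuple[Triple, ...]:
        """Lexicographically sorted edge tuple; hashable identity."""
        return tuple(sorted(self._edges))

    def indicator_vector(self) -> np.ndarray:
        """0-1 vector of length ``n_cells`` in C-order over (i, j, k)."""
        v = np.zeros(self.n_cells, dtype=np.int8)
        n2, n3 = self.n2, self.n3
        for (i, j, k) in self._edges:
            v[(i * n2 + j) * n3 + k] = 1
        return v

    @classmethod
    def complete(cls, n1: int, n2: int, n3: int) -> "TripartiteHypergraph":
        return cls(n1, n2, n3,
                   ((i, j, k) for i in range(n1) for j in range(n2)
                    for k in range(n3)))


@dataclass(frozen=True)
class DegreeSequence:
    """Prescribed degree lists ``(dA, dB, dC)`` for the three classes."""

    dA: tuple[int, ...]
    dB: tuple[int, ...]
    dC: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "dA", tuple(int(x) for x in self.dA))
        object.__setattr__(self, "dB", tuple(int(x) for x in self.dB))
        object.__setattr__(self, "dC", tuple(int(x) for x in self.dC))
        for d in (self.dA, self.dB, self.dC):
            if any(x < 0 for x in d):
                raise ValueError("degrees must be non-negative")
        if min(len(self.dA), len(self.dB), len(self.dC)) < 1:
            raise ValueError("each class needs at least one vertex")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.dA), len(self.dB), len(self.dC))

    @property
    def class_sums(self) -> tuple[int, int, int]:
        return (sum(self.dA), sum(self.dB), sum(self.dC))

    @property
    def is_class_balanced(self) -> bool:
        """True iff the three class sums agree (necessary for graphicality)."""
        s = self.class_sums
        return s[0] == s[1] == s[2]

    def within_capacity(self) -> bool:
        """Each degree fits in the co-class product (necessary condition)."""
        n1, n2, n3 = self.shape
        return (all(d <= n2 * n3 for d in self.dA)
                and all(d <= n1 * n3 for d in self.dB)
                and all(d <= n1 * n2 for d in self.dC))

    def to_json(self) -> str:
        return json.dumps({"dA": list(self.dA), "dB": list(self.dB),
                           "dC": list(self.dC)})

    @classmethod
    def from_json(cls, text: str) -> "DegreeSequence":
        obj = json.loads(text)
        return cls(tuple(obj["dA"]), tuple(obj["dB"]), tuple(obj["dC"]))

    @classmethod
    def regular(cls, n1: int, n2: int, n3: int, degree_a: int,
                degree_b: int, degree_c: int) -> "DegreeSequence":
        return cls((degree_a,) * n1, (degree_b,) * n2, (degree_c,) * n3)


def degree_sequence_of(H: TripartiteHypergraph) -> DegreeSequence:
    """Per-class degree lists of ``H``; each class sums to ``|E|``."""
    return H.degree_sequence()


def energy(H: TripartiteHypergraph, D: DegreeSequence) -> int:
    """L1 deviation of H's degree sequence from the prescribed D.

    Zero exactly when H realizes D.  This is the (hypothetical) energy that
    the Boltzmann distribution ``pi_T(H) \\propto exp(-energy/T)`` is built
    on; the partition function is never needed because only energy
    differences enter the samplers.
    """
    if H.shape != D.shape:
        raise ValueError(f"shape mismatch: H {H.shape} vs D {D.shape}")
    cur = H.degree_sequence()
    return (sum(abs(a - b) for a, b in zip(cur.dA, D.dA))
            + sum(abs(a - b) for a, b in zip(cur.dB, D.dB))
            + sum(abs(a - b) for a, b in zip(cur.dC, D.dC)))


@dataclass(frozen=True)
class EditOp:
    """One elementary edit: removed and added triples.

    kind is one of ``switch`` (2 removed / 2 added, degrees unchanged),
    ``hinge`` (1/1, two degrees in one class move by -1/+1), ``toggle_in``
    (0/1) or ``toggle_out`` (1/0).  ``cls`` is the affected class for
    switch/hinge (0=A, 1=B, 2=C).
    """

    kind: str
    removed: tuple[Triple, ...]
    added: tuple[Triple, ...]
    cls: int | None = None

    _SHAPES = {"switch": (2, 2), "hinge": (1, 1),
               "toggle_in": (0, 1), "toggle_out": (1, 0)}

    def __post_init__(self) -> None:
        if self.kind not in self._SHAPES:
            raise ValueError(f"unknown op kind {self.kind!r}")
        shape = (len(self.removed), len(self.added))
        if shape != self._SHAPES[self.kind]:
            raise ValueError(f"{self.kind} needs removed/added counts "
                             f"{self._SHAPES[self.kind]}, got {shape}")

    @staticmethod
    def switch(e1: Triple, e2: Triple, cls: int) -> "EditOp":
        """Swap the class-``cls`` vertices of two hyperedges."""
        f1, f2 = list(e1), list(e2)
        f1[cls], f2[cls] = e2[cls], e1[cls]
        return EditOp("switch", (e1, e2), (tuple(f1), tuple(f2)), cls)

    @staticmethod
    def hinge(e: Triple, cls: int, new_vertex: int) -> "EditOp":
        """Move the class-``cls`` vertex of ``e`` to ``new_vertex``."""
        f = list(e)
        f[cls] = new_vertex
        return EditOp("hinge", (e,), (tuple(f),), cls)

    @staticmethod
    def toggle(H: TripartiteHypergraph, e: Triple) -> "EditOp":
        """Toggle ``e`` out if present in ``H``, in otherwise."""
        if e in H:
            return EditOp("toggle_out", (e,), ())
        return EditOp("toggle_in", (), (e,))

    def inverse(self) -> "EditOp":
        inv = {"switch": "switch", "hinge": "hinge",
               "toggle_in": "toggle_out", "toggle_out": "toggle_in"}
        return EditOp(inv[self.kind], self.added, self.removed, self.cls)


def apply_op(H: TripartiteHypergraph, op: EditOp,
             tracker: "EnergyTracker | None" = None) -> TripartiteHypergraph:
    """Apply ``op`` to ``H`` in place (and update ``tracker`` if given).

    Raises :class:`InvalidOperation` if a removed triple is absent or an
    added triple is already present; the hypergraph is left unchanged in
    that case.  Simplicity is preserved by construction.
    """
    for e in op.removed:
        if e not in H:
            raise InvalidOperation(f"cannot remove absent {e}")
    for e in op.added:
        if e in H:
            raise InvalidOperation(f"cannot add present {e}")
    if len(set(op.added)) != len(op.added):
        raise InvalidOperation("added triples coincide")
    for e in op.removed:
        H.remove_edge(e)
    for e in op.added:
        H.add_edge(e)
    if tracker is not None:
        tracker.update(op)
    return H


class EnergyTracker:
    """Incrementally maintained energy of a hypergraph against a target.

    Keeps the current per-vertex degrees and the L1 deviation ``delta_g``;
    :meth:`delta_if` prices an edit without applying it, which is what the
    Metropolis acceptance rule needs.  Degrees and energy are integers, so
    incremental updates are exact; :meth:`recompute` is a debugging check.
    """

    __slots__ = ("target", "_cur", "delta_g")

    def __init__(self, H: TripartiteHypergraph, D: DegreeSequence) -> None:
        if H.shape != D.shape:
            raise ValueError(f"shape mismatch: H {H.shape} vs D {D.shape}")
        self.target = D
        self._cur = (H.degrees(0), H.degrees(1), H.degrees(2))
        self.delta_g = energy(H, D)

    def _vertex_deltas(self, op: EditOp) -> dict[tuple[int, int], int]:
        d: dict[tuple[int, int], int] = {}
        for e in op.removed:
            for c in range(3):
                key = (c, e[c])
                d[key] = d.get(key, 0) - 1
        for e in op.added:
            for c in range(3):
                key = (c, e[c])
                d[key] = d.get(key, 0) + 1
        return d

    def delta_if(self, op: EditOp) -> int:
        """Energy change if ``op`` were applied; state is not modified."""
        tgt = (self.target.dA, self.target.dB, self.target.dC)
        change = 0
        for (c, v), dv in self._vertex_deltas(op).items():
            if dv == 0:
                continue
            cur = self._cur[c][v]
            t = tgt[c][v]
            change += abs(cur + dv - t) - abs(cur - t)
        return change

    def update(self, op: EditOp) -> int:
        """Commit ``op``'s effect on the tracked degrees; return new energy."""
        tgt = (self.target.dA, self.target.dB, self.target.dC)
        for (c, v), dv in self._vertex_deltas(op).items():
            if dv == 0:
                continue
            cur = self._cur[c][v]
            t = tgt[c][v]
            self.delta_g += abs(cur + dv - t) - abs(cur - t)
            self._cur[c][v] = cur + dv
        return self.delta_g

    def recompute(self, H: TripartiteHypergraph) -> int:
        """Full recomputation from ``H``; equals ``delta_g`` at all times."""
        return energy(H, self.target)


# ---------------------------------------------------------------------------
# projections, shadows, traces


@dataclass(frozen=True)
class ProjectionMatrix:
    """Multiplicity matrix of a pairwise projection.

    ``counts[i, j]`` is the number of hyperedges joining vertex ``i`` of the
    pair's first class with vertex ``j`` of its second class, i.e. the
    number of parallel edges in the projected bipartite multigraph.  Row
    sums are the first class's hypergraph degrees, column sums the
    second's, and the total is ``|E|``.
    """

    counts: np.ndarray
    pair: str = "AB"

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or (c < 0).any():
            raise ValueError("projection counts must be a non-negative matrix")
        object.__setattr__(self, "counts", c)
        if self.pair not in _PAIRS:
            raise ValueError(f"pair must be one of {sorted(_PAIRS)}")

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ShadowGraph:
    """Bipartite simple graph between pair-vertices (i, j) and the third class.

    An edge ``((i, j), k)`` is present iff ``(i, j, k)`` is a hyperedge of
    the source hypergraph, so lifting a shadow back to a hypergraph is a
    bijection.  Edges are stored as raw triples for convenience.
    """

    n1: int
    n2: int
    n3: int
    edges: frozenset[Triple] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", frozenset(self.edges))
        for (i, j, k) in self.edges:
            if not (0 <= i < self.n1 and 0 <= j < self.n2 and 0 <= k < self.n3):
                raise ValueError(f"shadow edge ({i},{j},{k}) out of range")

    def pair_degrees(self) -> np.ndarray:
        """Degrees of the pair-vertices as an (n1, n2) matrix."""
        m = np.zeros((self.n1, self.n2), dtype=np.int64)
        for (i, j, _k) in self.edges:
            m[i, j] += 1
        return m

    def third_degrees(self) -> np.ndarray:
        d = np.zeros(self.n3, dtype=np.int64)
        for (_i, _j, k) in self.edges:
            d[k] += 1
        return d


def project(H: TripartiteHypergraph, pair: str = "AB") -> ProjectionMatrix:
    """Pairwise projection of ``H``: multiplicities of the collapsed class."""
    try:
        r, c, _ = _PAIRS[pair]
    except KeyError:
        raise ValueError(f"pair must be one of {sorted(_PAIRS)}") from None
    sizes = H.shape
    m = np.zeros((sizes[r], sizes[c]), dtype=np.int64)
    for e in H:
        m[e[r], e[c]] += 1
    return ProjectionMatrix(m, pair)


def shadow(H: TripartiteHypergraph) -> ShadowGraph:
    """(A, B)-shadow: pair-vertices (i, j) joined to each incident k."""
    return ShadowGraph(H.n1, H.n2, H.n3, frozenset(H.edges))


def lift_shadow(G: ShadowGraph) -> TripartiteHypergraph:
    """Inverse of :func:`shadow`: each shadow edge becomes a hyperedge."""
    return TripartiteHypergraph(G.n1, G.n2, G.n3, G.edges)


def is_b_balanced(P: ProjectionMatrix | np.ndarray) -> bool:
    """True iff every column's entries take at most two values differing by 1.

    Equivalently each column j holds only ``l_j`` and ``l_j - 1`` where
    ``l_j = ceil(colsum_j / n_rows)``.
    """
    m = P.counts if isinstance(P, ProjectionMatrix) else np.asarray(P)
    if m.size == 0:
        return True
    return bool((m.max(axis=0) - m.min(axis=0) <= 1).all())


def trace(P: ProjectionMatrix | np.ndarray) -> np.ndarray:
    """0-1 matrix marking the ceiling entries of a balanced projection.

    In each column, the larger of the (at most two) values present maps to
    1 and the smaller to 0; a column whose entries are all equal maps to
    all ones (its value is both floor and ceiling of the column mean).
    Raises ``ValueError`` on a non-balanced projection.
    """
    m = P.counts if isinstance(P, ProjectionMatrix) else np.asarray(P)
    if not is_b_balanced(m):
        raise ValueError("trace is defined only for B-balanced projections")
    n1 = m.shape[0]
    out = np.zeros_like(m)
    for j in range(m.shape[1]):
        col = m[:, j]
        s = int(col.sum())
        l = -(-s // n1)  # ceil
        out[:, j] = (col == l).astype(m.dtype) if l > 0 else (col == 0)
    return out


# ---------------------------------------------------------------------------
# text I/O: one "i j k" triple per line, 0-based, '#' comments


def write_edge_list(H: TripartiteHypergraph, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# shape {H.n1} {H.n2} {H.n3}\n")
        for (i, j, k) in sorted(H.edges):
            fh.write(f"{i} {j} {k}\n")


def read_edge_list(path, shape: tuple[int, int, int] | None = None
                   ) -> TripartiteHypergraph:
    """Read an edge-list file; duplicates are rejected.

    The writer records the class sizes in a ``# shape n1 n2 n3`` comment;
    pass ``shape`` explicitly for files without one (sizes then default to
    the maximal index + 1 in each coordinate).
    """
    triples: list[Triple] = []
    file_shape = shape
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if line.startswith("# shape") and file_shape is None:
                parts = line.split()
                file_shape = (int(parts[2]), int(parts[3]), int(parts[4]))
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"line {lineno}: expected 'i j k'")
            triples.append((int(parts[0]), int(parts[1]), int(parts[2])))
    if len(set(triples)) != len(triples):
        raise ValueError("duplicate triples in edge list")
    if file_shape is None:
        file_shape = tuple(max(t[c] for t in triples) + 1 for c in range(3)) \
            if triples else (1, 1, 1)
    return TripartiteHypergraph(*file_shape, triples)
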