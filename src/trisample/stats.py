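"""Aggregation index and the three chi-square tests.

For a tripartite hypergraph whose classes are (agents, event types, time
points), *aggregation* is the association of event types with time points
in the (B, C)-projection.  The aggregation index is the Pearson chi-square
statistic of that projection's contingency table against its
margin-product expectation.  Three null distributions give three tests:

* theoretical -- the chi-square distribution with (n_b - 1)(n_c - 1)
  degrees of freedom;
* exact -- the generalized hypergeometric (multivariate Fisher) law over
  integer tables with the observed margins, sampled by a Metropolis chain
  on 2x2 checkerboard moves;
* hypergraph-based exact -- the uniform law over hypergraphs with the
  observed *degree sequence* (agent activity held fixed), sampled with the
  Parallel Tempering sampler.

When every agent has degree 1 the last two tests coincide: each table T
with the prescribed margins is the projection of exactly
``multinomial(N; t_11, ..., t_bc)`` hypergraphs.  With more active agents
the hypergraph null shifts towards smaller chi-square values (an agent's
entries cannot repeat a cell it already filled at the same time slot,
spreading the table), which is what makes the hypergraph-based test more
sensitive on small samples.

p-values are one-sided upper tails (aggregation means a large statistic);
for the two sampled nulls the tail is read from a normal fit to the null
sample (sample mean, unbiased SD), with the empirical exceedance fraction
reported alongside.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

from .hypergraph import DegreeSequence, TripartiteHypergraph, project

__all__ = [
    "ContingencyTable",
    "TestResult",
    "expected_counts",
    "aggregation_index",
    "theoretical_chi2_test",
    "hypergeometric_log_prob",
    "sample_tables",
    "exact_chi2_test",
    "hypergraph_exact_chi2_test",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Non-negative integer matrix with its margins."""

    t: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.t, dtype=np.int64)
        if m.ndim != 2 or (m < 0).any():
            raise ValueError("table must be a non-negative integer matrix")
        object.__setattr__(self, "t", m)

    @property
    def row_sums(self) -> np.ndarray:
        return self.t.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.t.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.t.sum())

    @classmethod
    def from_hypergraph(cls, H: TripartiteHypergraph) -> "ContingencyTable":
        """The (B, C)-projection of H: rows are event types, columns times."""
        return cls(project(H, "BC").counts)

    @classmethod
    def from_csv(cls, path) -> "ContingencyTable":
        import pandas as pd

        df = pd.read_csv(path, header=None)
        return cls(df.to_numpy(dtype=np.int64))

    def to_csv(self, path) -> None:
        np.savetxt(path, self.t, fmt="%d", delimiter=",")


def _as_table(t) -> ContingencyTable:
    return t if isinstance(t, ContingencyTable) else ContingencyTable(t)


def expected_counts(t) -> np.ndarray:
    """Margin-product expectations ``e_ij = R_i * C_j / N``.

    Cells in an all-zero row or column get expectation 0 (and are skipped
    by the chi-square sum).  The expectations total N.
    """
    tab = _as_table(t)
    if tab.total == 0:
        raise ValueError("empty table")
    return np.outer(tab.row_sums, tab.col_sums) / tab.total


def aggregation_index(t) -> float:
    """Pearson chi-square of a table (or of a hypergraph's (B, C)-projection).

    Zero exactly on tables proportional to their margin products (rank-1
    integer tables); cells with zero expectation contribute nothing.
    """
    if isinstance(t, TripartiteHypergraph):
        t = ContingencyTable.from_hypergraph(t)
    tab = _as_table(t)
    e = expected_counts(tab)
    mask = e > 0
    diff = tab.t[mask] - e[mask]
    return float((diff * diff / e[mask]).sum())


@dataclass(frozen=True)
class TestResult:
    """Outcome of one chi-square test.

    ``p_value`` is the one-sided upper-tail probability; for the sampled
    methods it comes from a normal fit to the null sample (``null_mean``,
    ``null_sd``) and ``empirical_exceedance`` is the raw fraction of null
    draws at or above the observed statistic.  ``degenerate`` flags a
    zero-variance null (p then falls back to the empirical fraction).
    """

    statistic: float
    method: str
    p_value: float
    null_mean: float | None = None
    null_sd: float | None = None
    n_null: int | None = None
    empirical_exceedance: float | None = None
    degenerate: bool = False
    tail: str = "upper"

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValueError("p-value outside [0, 1]")
        if self.statistic < 0:
            raise ValueError("chi-square statistic must be non-negative")

    def to_json(self, **extra) -> str:
        obj = {"statistic": self.statistic, "method": self.method,
               "p_value": self.p_value, "tail": self.tail,
               "null_mean": self.null_mean, "null_sd": self.null_sd,
               "n_null": self.n_null,
               "empirical_exceedance": self.empirical_exceedance,
               "degenerate": self.degenerate}
        obj.update(extra)
        return json.dumps(obj)


def theoretical_chi2_test(t) -> TestResult:
    """Upper-tail p from chi-square with (n_b - 1)(n_c - 1) df."""
    tab = _as_table(t)
    nb, nc = tab.t.shape
    df = (nb - 1) * (nc - 1)
    if df == 0:
        raise ValueError("degenerate table: zero degrees of freedom")
    stat = aggregation_index(tab)
    return TestResult(stat, "theoretical", float(sps.chi2.sf(stat, df)))


def hypergeometric_log_prob(t) -> float:
    """Log generalized hypergeometric probability of a table given margins.

    ``prod_i R_i! prod_j C_j! / (N! prod_ij a_ij!)``; sums to 1 over the
    fiber of tables sharing the margins.
    """
    tab = _as_table(t)
    return float(gammaln(tab.row_sums + 1).sum()
                 + gammaln(tab.col_sums + 1).sum()
                 - gammaln(tab.total + 1)
                 - gammaln(tab.t + 1).sum())


def sample_tables(row_sums: Sequence[int], col_sums: Sequence[int],
                  n_samples: int, rng: random.Random | int | None = None,
                  spacing: int | None = None, burn: int | None = None,
                  initial: np.ndarray | None = None) -> list[np.ndarray]:
    """Tables with the given margins, ~ generalized hypergeometric law.

    Metropolis chain on the fiber: each move picks an ordered pair of rows
    and of columns and a sign, and adds the +-1 checkerboard on that 2x2
    subrectangle; moves that would create a negative entry are invalid
    self-loops.  Acceptance uses the factorial ratio of the four changed
    cells.  ``spacing`` thins the chain (default: N moves); ``burn``
    defaults to 10 N.
    """
    R = [int(x) for x in row_sums]
    C = [int(x) for x in col_sums]
    if sum(R) != sum(C):
        raise ValueError("margins must have equal totals")
    if min(R, default=0) < 0 or min(C, default=0) < 0:
        raise ValueError("margins must be non-negative")
    rng = rng if isinstance(rng, random.Random) else random.Random(rng)
    nb, nc = len(R), len(C)
    N = sum(R)
    if initial is None:
        # north-west-corner start: any member of the fiber works
        t = np.zeros((nb, nc), dtype=np.int64)
        rr, cc = list(R), list(C)
        for i in range(nb):
            for j in range(nc):
                x = min(rr[i], cc[j])
                t[i, j] = x
                rr[i] -= x
                cc[j] -= x
    else:
        t = np.asarray(initial, dtype=np.int64).copy()
        if (list(t.sum(axis=1)) != R) or (list(t.sum(axis=0)) != C):
            raise ValueError("initial table margins disagree")
    if nb < 2 or nc < 2:
        # single-row/column fiber has one element
        return [t.copy() for _ in range(n_samples)]
    spacing = max(1, N) if spacing is None else spacing
    burn = 10 * max(1, N) if burn is None else burn
    lg = [math.lgamma(x + 1) for x in range(int(t.max()) + N + 2)]
    out: list[np.ndarray] = []
    moves_done = 0
    next_keep = burn + spacing
    while len(out) < n_samples:
        i1 = rng.randrange(nb)
        i2 = rng.randrange(nb - 1)
        if i2 >= i1:
            i2 += 1
        j1 = rng.randrange(nc)
        j2 = rng.randrange(nc - 1)
        if j2 >= j1:
            j2 += 1
        s = 1 if rng.random() < 0.5 else -1
        a, b, c, d = t[i1, j1], t[i2, j2], t[i1, j2], t[i2, j1]
        if min(a + s, b + s, c - s, d - s) >= 0:
            # log ratio of 1/prod(a_ij!) over the four changed cells
            logr = (lg[a] + lg[b] + lg[c] + lg[d]
                    - lg[a + s] - lg[b + s] - lg[c - s] - lg[d - s])
            if logr >= 0 or rng.random() < math.exp(logr):
                t[i1, j1] += s
                t[i2, j2] += s
                t[i1, j2] -= s
                t[i2, j1] -= s
        moves_done += 1
        if moves_done >= next_keep:
            out.append(t.copy())
            next_keep += spacing
    return out


def _normal_tail_result(method: str, stat: float,
                        null_stats: np.ndarray) -> TestResult:
    n = len(null_stats)
    mean = float(null_stats.mean())
    sd = float(null_stats.std(ddof=1)) if n > 1 else 0.0
    exceed = float(np.mean(null_stats >= stat - 1e-12))
    if sd == 0:
        return TestResult(stat, method, exceed, mean, sd, n, exceed,
                          degenerate=True)
    p = float(sps.norm.sf(stat, loc=mean, scale=sd))
    return TestResult(stat, method, p, mean, sd, n, exceed)


def exact_chi2_test(t, n_samples: int = 2000,
                    rng: random.Random | int | None = None,
                    spacing: int | None = None) -> TestResult:
    """Monte-Carlo exact test: null tables share the observed margins."""
    tab = _as_table(t)
    stat = aggregation_index(tab)
    null = sample_tables(tab.row_sums, tab.col_sums, n_samples, rng,
                         spacing=spacing, initial=tab.t)
    null_stats = np.asarray([aggregation_index(x) for x in null])
    return _normal_tail_result("exact", stat, null_stats)


def hypergraph_exact_chi2_test(H: TripartiteHypergraph,
                               n_samples: int = 2000,
                               rng: random.Random | int | None = None,
                               **sampler_kwargs) -> TestResult:
    """Exact test under the uniform law on same-degree-sequence hypergraphs.

    The null sample comes from the Parallel Tempering sampler on
    ``degree_sequence_of(H)``; extra keyword arguments are forwarded to
    :func:`trisample.tempering.sample_realizations` (ladder, spacing,
    step budget...).  A sampler timeout propagates to the caller.
    """
    from .tempering import sample_realizations

    if len(H) == 0:
        raise ValueError("empty hypergraph")
    stat = aggregation_index(H)
    run = sample_realizations(H.degree_sequence(), n_samples, rng=rng,
                              **sampler_kwargs)
    null_stats = np.asarray([aggregation_index(h) for h in run.samples])
    return _normal_tail_result("hypergraph", stat, null_stats)
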