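"""Synthetic generators and triplet-table I/O.

Real inputs are tables of (agent, event type, time point) records -- e.g.
(user, topic, day) triples of social-media posts, or (patient, diagnosis,
week) triples from a registry.  Distinct labels become vertices, each
unique record a hyperedge (duplicate records collapse: hypergraphs are
simple), and the per-vertex record counts become the degree sequence that
the null models fix.

The generators provide:

* Erdos-Renyi hypergraphs (every cell independently with probability p) --
  the infinite-temperature reference distribution;
* regular degree sequences and their uniform samples;
* planted-aggregation triplet tables: agents of prescribed activity place
  (event, time) records, where a concentration parameter theta moves each
  event type's records onto a preferred time point.  theta = 0 gives
  independent placement (no aggregation), large theta strong aggregation.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .hypergraph import DegreeSequence, TripartiteHypergraph

__all__ = [
    "TripletTable",
    "read_triplets",
    "write_triplets",
    "random_er_hypergraph",
    "regular_degree_sequence",
    "zipf_activity",
    "planted_aggregation_table",
]


@dataclass
class TripletTable:
    """String-labelled (agent, event type, time point) records.

    ``records`` keeps the raw rows (duplicates included);
    :meth:`to_hypergraph` collapses duplicates and returns the label
    maps used for the index encoding.
    """

    records: list[tuple[str, str, str]]
    deduplicated: bool = False

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_unique(self) -> int:
        return len(set(self.records))

    def dedup(self) -> "TripletTable":
        """Collapse duplicate records, preserving first-seen order."""
        return TripletTable(list(dict.fromkeys(self.records)),
                            deduplicated=True)

    def label_maps(self) -> tuple[dict, dict, dict]:
        """Label -> index per class, in order of first appearance."""
        maps: tuple[dict, dict, dict] = ({}, {}, {})
        for rec in self.records:
            for c in range(3):
                if rec[c] not in maps[c]:
                    maps[c][rec[c]] = len(maps[c])
        return maps

    def to_hypergraph(self) -> tuple[TripartiteHypergraph,
                                     tuple[dict, dict, dict]]:
        """Encode as a simple hypergraph plus the label maps."""
        if not self.records:
            raise ValueError("empty triplet table")
        maps = self.label_maps()
        edges = {(maps[0][a], maps[1][b], maps[2][c])
                 for (a, b, c) in self.records}
        H = TripartiteHypergraph(len(maps[0]), len(maps[1]), len(maps[2]),
                                 edges)
        return H, maps


def read_triplets(path, columns: Sequence = (0, 1, 2),
                  header: bool = False) -> TripletTable:
    """Read a TSV of records, taking three columns as (agent, event, time)."""
    df = pd.read_csv(path, sep="\t", header=0 if header else None,
                     dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise ValueError("triplet table needs at least 3 columns")
    if df.shape[0] == 0:
        raise ValueError("empty triplet table")
    cols = [df.columns[c] if isinstance(c, int) else c for c in columns]
    recs = [tuple(row) for row in df[cols].itertuples(index=False)]
    return TripletTable(recs)


def write_triplets(tbl: TripletTable, path) -> None:
    pd.DataFrame(tbl.records).to_csv(path, sep="\t", header=False,
                                     index=False)


def random_er_hypergraph(n1: int, n2: int, n3: int, p: float,
                         rng: np.random.Generator | int | None = None
                         ) -> TripartiteHypergraph:
    """Each of the ``n1*n2*n3`` potential hyperedges present with prob p."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    mask = rng.random((n1, n2, n3)) < p
    edges = [tuple(int(x) for x in idx) for idx in zip(*np.nonzero(mask))]
    return TripartiteHypergraph(n1, n2, n3, edges)


def regular_degree_sequence(n1: int, n2: int, n3: int,
                            total_edges: int) -> DegreeSequence:
    """Regular sequence on each class with the given total; errors unless
    every class size divides the total."""
    for n in (n1, n2, n3):
        if total_edges % n != 0:
            raise ValueError(f"{total_edges} edges not divisible by "
                             f"class size {n}")
    return DegreeSequence((total_edges // n1,) * n1,
                          (total_edges // n2,) * n2,
                          (total_edges // n3,) * n3)


def zipf_activity(n_agents: int, total: int, exponent: float = 1.0
                  ) -> list[int]:
    """Deterministic Zipf-like activity profile summing to ``total``.

    Weight of agent r is (r+1)^-exponent; counts are the largest-remainder
    rounding of the normalized weights.  Mimics the heavy-tailed activity
    of social-media users.
    """
    w = np.arange(1, n_agents + 1, dtype=float) ** -exponent
    raw = w / w.sum() * total
    counts = np.floor(raw).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return [int(c) for c in counts]


def planted_aggregation_table(n_agents: int, n_events: int, n_times: int,
                              activity: int | Sequence[int],
                              theta: float = 0.0,
                              rng: random.Random | int | None = None
                              ) -> TripletTable:
    """Triplet table with tunable event-time aggregation.

    Each agent ``a`` places ``activity[a]`` records (an int means the same
    count for everyone).  The event type is uniform; the time point is
    drawn with weight ``1 + theta`` on the event's preferred time
    (``event mod n_times``) and 1 elsewhere, so ``theta = 0`` places
    events and times independently and large theta concentrates each
    event on its own time point.  Duplicate records are kept (they
    collapse only when the table becomes a hypergraph, mirroring how
    repeated real-world records behave).
    """
    if theta < 0:
        raise ValueError("theta must be non-negative")
    rng = rng if isinstance(rng, random.Random) else random.Random(rng)
    counts = [int(activity)] * n_agents if isinstance(activity, int) \
        else [int(x) for x in activity]
    if len(counts) != n_agents or min(counts, default=0) < 0:
        raise ValueError("activity profile must give a non-negative count "
                         "per agent")
    denom = n_times + theta
    records: list[tuple[str, str, str]] = []
    for a in range(n_agents):
        for _ in range(counts[a]):
            e = rng.randrange(n_events)
            pref = e % n_times
            if rng.random() < (1 + theta) / denom:
                t = pref
            else:
                t = rng.randrange(n_times - 1)
                if t >= pref:
                    t += 1
            records.append((f"agent{a}", f"event{e}", f"time{t}"))
    return TripletTable(records)


def generator_manifest(path, **params) -> None:
    """Echo generator parameters to a JSON manifest for provenance."""
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
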