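"""Polynomial constructor: balancing, Gale-Ryser, lifting, flattening."""

import random

import numpy as np
import pytest

import trisample as ts
from trisample.construct import (Infeasible, ShadowDegreeSequence,
                                 balance_projection, flat_target,
                                 gale_ryser_realize,
                                 realize_bipartite_multigraph)


@pytest.mark.parametrize("dA, ok, k", [
    ((3, 3, 2, 3), True, 3),
    ((4, 2, 3), False, None),
    ((5, 5, 5), True, 5),
])
def test_is_third_almost_regular(dA, ok, k):
    res, witness = ts.is_third_almost_regular(
        ts.DegreeSequence(dA, (1,), (1,)))
    assert res is ok
    if ok:
        assert witness == k


class TestBipartiteMultigraph:
    @pytest.mark.parametrize("dA, dB, expected", [
        ((2, 1), (1, 1, 1), [[1, 1, 0], [0, 0, 1]]),
        ((0, 0), (0, 0), [[0, 0], [0, 0]]),
        ((3,), (1, 2), [[1, 2]]),
    ])
    def test_north_west_corner(self, dA, dB, expected):
        P = realize_bipartite_multigraph(dA, dB)
        assert P.counts.tolist() == expected

    def test_unequal_sums_infeasible(self):
        res = realize_bipartite_multigraph((2,), (3,))
        assert isinstance(res, Infeasible)
        assert res.reason == "sum_mismatch"


class TestBalanceProjection:
    def test_forced_two_by_two(self):
        # rows (3,3), cols (4,2): the only balanced matrix is [[2,1],[2,1]]
        bal = balance_projection(np.array([[3, 0], [1, 2]]))
        assert bal.counts.tolist() == [[2, 1], [2, 1]]
        assert bal.n_exchanges >= 1

    def test_already_balanced_unchanged(self):
        m = np.array([[2, 1], [2, 1]])
        bal = balance_projection(m)
        assert bal.counts.tolist() == m.tolist()
        assert bal.n_exchanges == 0

    def test_single_column_is_row_degrees(self):
        m = np.array([[3], [2], [3]])
        bal = balance_projection(m)
        assert bal.counts.tolist() == m.tolist()

    def test_margins_preserved_and_bounded_moves(self):
        rng = random.Random(7)
        for _ in range(50):
            n1, n2 = rng.randint(1, 5), rng.randint(1, 5)
            k = rng.randint(1, 6)
            rows = [k - rng.randint(0, 1) for _ in range(n1)]
            P = realize_bipartite_multigraph(
                rows, _random_composition(sum(rows), n2, rng))
            assert not isinstance(P, Infeasible)
            before = P.counts.copy()
            bal = balance_projection(P)
            assert ts.is_b_balanced(bal.counts)
            assert (bal.counts.sum(axis=1) == before.sum(axis=1)).all()
            assert (bal.counts.sum(axis=0) == before.sum(axis=0)).all()
            deviation = int(np.abs(bal.counts - before).sum())
            assert bal.n_exchanges <= deviation  # each move shifts 4 cells

    def test_irregular_rows_rejected(self):
        with pytest.raises(ValueError):
            balance_projection(np.array([[3, 0], [0, 1]]))


def _random_composition(total, parts, rng):
    cuts = sorted(rng.randint(0, total) for _ in range(parts - 1))
    return [b - a for a, b in zip([0] + cuts, cuts + [total])]


class TestGaleRyser:
    def test_both_pairs_to_single_c(self):
        G = gale_ryser_realize(ShadowDegreeSequence([[1, 1]], (2,)))
        assert G.edges == frozenset({(0, 0, 0), (0, 1, 0)})

    def test_one_pair_to_both_c(self):
        G = gale_ryser_realize(ShadowDegreeSequence([[2]], (1, 1)))
        assert G.edges == frozenset({(0, 0, 0), (0, 0, 1)})

    def test_capacity_violation_certified(self):
        res = gale_ryser_realize(ShadowDegreeSequence([[3]], (2, 1)))
        assert isinstance(res, Infeasible) and res.reason == "capacity"

    def test_feasible_variants(self):
        for pd, dC in ([[[2, 0]], (1, 1)], [[[1, 1]], (2, 0)]):
            G = gale_ryser_realize(ShadowDegreeSequence(pd, dC))
            assert not isinstance(G, Infeasible)
            assert (G.pair_degrees() == np.array(pd)).all()
            assert G.third_degrees().tolist() == list(dC)

    def test_matches_gale_ryser_inequalities(self):
        # independent feasibility oracle: sorted p, feasible iff for all k
        # sum_{i<=k} p_i <= sum_j min(dC_j, k) (and totals agree)
        def feasible(pairs, dC):
            p = sorted(pairs, reverse=True)
            if sum(p) != sum(dC):
                return False
            return all(sum(p[:k]) <= sum(min(d, k) for d in dC)
                       for k in range(1, len(p) + 1))

        rng = random.Random(11)
        realized = certified = 0
        for _ in range(200):
            n_p, n3 = rng.randint(1, 5), rng.randint(1, 4)
            pd = [rng.randint(0, n3 + 1) for _ in range(n_p)]
            dC = _random_composition(sum(pd), n3, rng)
            ours = gale_ryser_realize(
                ShadowDegreeSequence([pd], tuple(dC)))
            assert (not isinstance(ours, Infeasible)) == feasible(pd, dC)
            if isinstance(ours, Infeasible):
                certified += 1
            else:
                realized += 1
                assert ours.pair_degrees().tolist() == [pd]
                assert ours.third_degrees().tolist() == dC
        assert realized >= 20 and certified >= 20


def test_realize_examples():
    D = ts.DegreeSequence((1,), (1,), (1,))
    H = ts.realize_third_almost_regular(D)
    assert H.edges == frozenset({(0, 0, 0)})
    res = ts.realize_third_almost_regular(ts.DegreeSequence((2,), (1,), (1,)))
    assert isinstance(res, Infeasible)
    H2 = ts.realize_third_almost_regular(
        ts.DegreeSequence((1, 1), (1, 1), (2, 0)))
    assert H2.degree_sequence() == ts.DegreeSequence((1, 1), (1, 1), (2, 0))


def test_realize_rejects_irregular_first_class():
    with pytest.raises(ValueError):
        ts.realize_third_almost_regular(
            ts.DegreeSequence((3, 1), (2, 2), (2, 2)))


def test_decision_agrees_with_exhaustive_oracle():
    """On 200+ random third almost-regular sequences (classes <= 4), the
    constructor finds a realization exactly when enumeration finds one."""
    rng = random.Random(31)
    n_cases = agreements = graphic_cases = 0
    while n_cases < 200:
        n1, n2, n3 = (rng.randint(1, 4) for _ in range(3))
        k = rng.randint(0, max(1, n2 * n3 - 1))
        dA = tuple(max(0, k - rng.randint(0, 1)) for _ in range(n1))
        total = sum(dA)
        if total > 10:
            continue
        dB = tuple(_random_composition(total, n2, rng))
        dC = tuple(_random_composition(total, n3, rng))
        D = ts.DegreeSequence(dA, dB, dC)
        n_cases += 1
        oracle_count = ts.count_partite_realizations(D, max_cells=64)
        res = ts.realize_third_almost_regular(D)
        if isinstance(res, Infeasible):
            assert oracle_count == 0, (D, res)
        else:
            assert oracle_count > 0, D
            assert res.degree_sequence() == D
            graphic_cases += 1
        agreements += 1
    assert agreements == n_cases >= 200
    assert graphic_cases >= 50  # the case mix actually exercises both arms


def test_balanced_realizations_switch_connected():
    """All B-balanced realizations of a tiny third almost-regular sequence
    form one component under switches (BFS over the enumerated set)."""
    D = ts.DegreeSequence((2, 1), (2, 1), (1, 1, 1))
    sols = ts.enumerate_partite_realizations(D, max_cells=64)
    balanced = [h for h in sols
                if ts.is_b_balanced(ts.project(h, "AB"))]
    assert len(balanced) >= 2
    sigs = {h.canonical_signature(): i for i, h in enumerate(balanced)}

    def switch_neighbors(h):
        edges = sorted(h.edges)
        for a in range(len(edges)):
            for b in range(len(edges)):
                if a == b:
                    continue
                for cls in range(3):
                    op = ts.EditOp.switch(edges[a], edges[b], cls)
                    if all(f not in h for f in op.added):
                        g = h.copy()
                        ts.apply_op(g, op)
                        s = g.canonical_signature()
                        if s in sigs:
                            yield s

    seen = {balanced[0].canonical_signature()}
    frontier = [balanced[0]]
    while frontier:
        h = frontier.pop()
        for s in switch_neighbors(h):
            if s not in seen:
                seen.add(s)
                frontier.append(ts.TripartiteHypergraph(*h.shape,
                                                        dict.fromkeys(s)))
    assert seen == set(sigs)


class TestFlattening:
    def test_single_flip(self):
        H = ts.TripartiteHypergraph(2, 2, 2, [(0, 0, 0), (0, 1, 1)])
        flat, flips = ts.flatten_class_by_hinge_flips(H, (1, 1))
        assert flat.degrees(0) == [1, 1]
        assert flips == 1
        assert flat.degrees(1) == H.degrees(1)
        assert flat.degrees(2) == H.degrees(2)

    def test_already_flat_zero_flips(self):
        H = ts.TripartiteHypergraph(2, 2, 2, [(0, 0, 0), (1, 1, 1)])
        flat, flips = ts.flatten_class_by_hinge_flips(H, (1, 1))
        assert flips == 0 and flat == H

    def test_flip_count_is_half_l1_distance(self):
        rng = random.Random(5)
        for _ in range(40):
            H = ts.random_er_hypergraph(3, 3, 3, 0.5, rng.randrange(2 ** 30))
            if len(H) == 0:
                continue
            target = flat_target(3, len(H))
            l1 = sum(abs(c - t) for c, t in zip(H.degrees(0), target))
            flat, flips = ts.flatten_class_by_hinge_flips(H, target)
            assert flat.degrees(0) == list(target)
            assert flat.degrees(1) == H.degrees(1)
            assert flat.degrees(2) == H.degrees(2)
            assert flips == l1 // 2

    def test_flat_target_structure(self):
        assert flat_target(3, 6) == (2, 2, 2)
        assert flat_target(3, 7) == (3, 2, 2)
        assert flat_target(4, 0) == (0, 0, 0, 0)

    def test_bad_target_sum_rejected(self):
        H = ts.TripartiteHypergraph(2, 2, 2, [(0, 0, 0)])
        with pytest.raises(ValueError):
            ts.flatten_class_by_hinge_flips(H, (1, 1))
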