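"""Parallel Tempering: ladder design, swaps, harvesting, diagnostics."""

import math
import random
from collections import Counter

import numpy as np
import pytest

import trisample as ts
from trisample.tempering import select_endpoints
from .conftest import exact_boltzmann, total_variation


def _synthetic_curves(temps, lower, upper, **kw):
    return ts.QuartileCurves(tuple(temps), tuple(lower), tuple(upper),
                             tuple(lower), tuple(upper),
                             tuple(0.0 for _ in temps),
                             tuple((a + b) / 2 for a, b in zip(lower, upper)),
                             steps_per_temperature=0, burn_fraction=0.0)


class TestInfiniteTemperatureEnergy:
    def test_matches_er_half_mean_energy(self):
        D = ts.DegreeSequence((3, 1), (2, 2), (2, 2))
        est = ts.infinite_temperature_energy(D)
        rng = np.random.default_rng(4)
        sims = [ts.energy(ts.random_er_hypergraph(2, 2, 2, 0.5, rng), D)
                for _ in range(4000)]
        # the estimate drops the |binomial - mean| fluctuation term, so it
        # is a lower bound within ~sqrt(max degree) per vertex
        assert est <= np.mean(sims) < est + 6 * math.sqrt(4)


class TestProbe:
    def test_cold_quartiles_vanish_for_graphic_target(self):
        D = ts.DegreeSequence((2, 1), (1, 1, 1), (2, 1))
        curves = ts.probe_quartiles(D, T_grid=[1e-3], steps_per_T=4000,
                                    rng=2)
        assert curves.lower[0] == 0.0 and curves.upper[0] == 0.0
        assert curves.zero_frac[0] > 0.9

    def test_hot_median_near_infinite_temperature_estimate(self):
        D = ts.DegreeSequence((2, 1), (1, 1, 1), (2, 1))
        e_inf = ts.infinite_temperature_energy(D)
        curves = ts.probe_quartiles(D, T_grid=[500.0], steps_per_T=8000,
                                    rng=2)
        assert curves.median[0] >= 0.6 * e_inf

    def test_curves_are_monotone(self):
        D = ts.DegreeSequence((2, 2), (2, 2), (2, 2))
        curves = ts.probe_quartiles(D, steps_per_T=1500, rng=6, n_grid=20)
        assert all(b >= a for a, b in zip(curves.lower, curves.lower[1:]))
        assert all(b >= a for a, b in zip(curves.upper, curves.upper[1:]))
        assert all(u >= l for l, u in zip(curves.lower, curves.upper))


class TestBuildLadder:
    def test_flat_curves_fall_back_to_endpoints(self):
        curves = _synthetic_curves([0.1, 1.0, 10.0], [5, 5, 5], [5, 5, 5])
        with pytest.warns(UserWarning, match="flat"):
            ladder = ts.build_ladder(curves, 0.1, 10.0)
        assert ladder.temperatures == (0.1, 10.0)
        assert ladder.fallback_geometric

    def test_linear_curves_give_equal_log_spacing(self):
        # lower(logT) = logT, upper(logT) = logT + 1 on a dense grid:
        # the staircase recurrence steps by exactly 1 in log-temperature
        logts = np.linspace(0.0, 10.0, 401)
        curves = _synthetic_curves(np.exp(logts), logts, logts + 1)
        ladder = ts.build_ladder(curves, math.exp(1.0), math.exp(9.0))
        gaps = np.diff(np.log(ladder.temperatures))
        assert np.allclose(gaps[:-1], 1.0, atol=1e-6)
        assert ladder.temperatures[-1] == pytest.approx(math.exp(9.0))

    def test_designed_ladder_is_strictly_increasing(
            self, counterexample_degrees):
        curves = ts.probe_quartiles(counterexample_degrees,
                                    steps_per_T=2000, rng=3, n_grid=40)
        T_min, T_max = select_endpoints(
            curves,
            E_inf=ts.infinite_temperature_energy(counterexample_degrees))
        ladder = ts.build_ladder(curves, T_min, T_max)
        temps = ladder.temperatures
        assert len(temps) >= 3
        assert all(b > a for a, b in zip(temps, temps[1:]))
        assert temps[0] == T_min and temps[-1] == pytest.approx(T_max)


class TestPTStep:
    def test_equal_energies_always_swap(self):
        D = ts.DegreeSequence((1,), (1,), (1,))
        pt = ts.ParallelTempering(D, ts.TemperatureLadder((0.5, 2.0)),
                                  rng=1)
        # whenever a swap is attempted between equal-energy states the
        # ratio is exactly 1, so the attempt must succeed
        checked = 0
        for _ in range(400):
            equal = pt.chains[0].delta_g == pt.chains[1].delta_g
            att, acc = pt.swap_attempts[0], pt.swap_accepts[0]
            pt.step()
            if equal and pt.swap_attempts[0] > att:
                assert pt.swap_accepts[0] == acc + 1
                checked += 1
        assert checked > 20

    def test_hotter_state_colder_chain_swap_certain(self):
        """If the colder chain holds the higher energy, the swap ratio is
        >= 1 and the attempt always succeeds."""
        D = ts.DegreeSequence((2,), (1, 1), (1, 1))
        pt = ts.ParallelTempering(D, ts.TemperatureLadder((0.3, 3.0)),
                                  rng=8)
        checked = 0
        for _ in range(4000):
            ga, gb = pt.chains[0].delta_g, pt.chains[1].delta_g
            att = pt.swap_attempts[0]
            acc = pt.swap_accepts[0]
            pt.step()
            if pt.swap_attempts[0] > att and ga >= gb:
                assert pt.swap_accepts[0] == acc + 1
                checked += 1
        assert checked > 50

    def test_coldest_marginal_matches_boltzmann(self):
        """With swaps in play, the coldest coordinate still follows its
        own Boltzmann law (checked on the enumerable (1,2,2) space)."""
        D = ts.DegreeSequence((2,), (1, 1), (1, 1))
        pt = ts.ParallelTempering(D, ts.TemperatureLadder((1.0, 4.0)),
                                  rng=11)
        exact = exact_boltzmann(D, 1.0)
        counts = Counter()
        n = 300000
        for _ in range(n):
            pt.step()
            counts[pt.coldest.H.canonical_signature()] += 1
        assert total_variation(counts, exact, n) < 0.03


class TestSampleRealizations:
    def test_all_samples_realize_target(self):
        D = ts.DegreeSequence((2, 2, 2), (2, 2, 2), (2, 2, 2))
        run = ts.sample_realizations(D, 25, rng=5, probe_steps=1500,
                                     probe_grid=25)
        assert len(run.samples) == 25
        for h in run.samples:
            assert h.degree_sequence() == D
        assert run.zero_energy_fraction > 0.5
        assert len(run.chain_stats) == len(run.ladder)

    def test_seeded_determinism(self):
        D = ts.DegreeSequence((2, 1), (1, 1, 1), (2, 1))
        runs = [ts.sample_realizations(D, 10, rng=99, probe_steps=1000,
                                       probe_grid=20) for _ in range(2)]
        sigs = [[h.canonical_signature() for h in r.samples] for r in runs]
        assert sigs[0] == sigs[1]
        assert runs[0].ladder.temperatures == runs[1].ladder.temperatures
        assert runs[0].total_steps == runs[1].total_steps

    def test_timeout_on_nongraphic_target(self):
        # reduction of an unsolvable numerical 3DM instance: class-balanced
        # but with zero realizations, so zero energy is never reached
        inst = ts.ThreeDMInstance.from_class_weights((0, 0, 6), (1, 2, 3),
                                                     (1, 2, 3), 6)
        red = ts.reduction_degree_sequence(inst)
        assert ts.count_partite_realizations(red.degree_sequence) == 0
        with pytest.raises(ts.SamplerTimeout) as exc_info:
            ts.sample_realizations(red.degree_sequence, 1, rng=3,
                                   max_steps=30000, probe_steps=800,
                                   probe_grid=15)
        assert exc_info.value.best_energy >= 1
        assert exc_info.value.samples == []


class TestAutocorrelationDiagnostics:
    def test_identical_samples_flagged(self):
        H = ts.TripartiteHypergraph(2, 2, 2, [(0, 0, 0)])
        rep = ts.autocorrelation_diagnostics([H.copy() for _ in range(12)])
        assert rep.zero_variance
        assert np.isnan(rep.autocorrelations[0, 1])

    def test_alternating_samples_anticorrelate(self, counterexample_degrees):
        sols = ts.enumerate_partite_realizations(counterexample_degrees)
        seq = [sols[i % 2] for i in range(40)]
        rep = ts.autocorrelation_diagnostics(seq, max_lag=3)
        assert rep.autocorrelations[0, 1] == pytest.approx(-1.0, abs=0.1)

    def test_iid_samples_have_low_autocorrelation(self):
        D = ts.DegreeSequence((1, 1), (1, 1), (1, 1))
        sols = ts.enumerate_partite_realizations(D)
        rng = random.Random(12)
        seq = [sols[rng.randrange(len(sols))] for _ in range(400)]
        rep = ts.autocorrelation_diagnostics(seq, max_lag=5)
        assert np.all(np.abs(rep.autocorrelations[:, 1:]) < 0.15)

    def test_too_few_samples_rejected(self):
        H = ts.TripartiteHypergraph(1, 1, 1, [(0, 0, 0)])
        with pytest.raises(ValueError):
            ts.autocorrelation_diagnostics([H] * 5)
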