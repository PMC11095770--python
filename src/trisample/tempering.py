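"""Parallel Tempering over hypergraph space, with ladder design and diagnostics.

A stack of Metropolis chains (see :mod:`trisample.chain`) runs at
temperatures ``T_1 < ... < T_k``.  Each composite step either advances one
uniformly chosen chain or proposes to swap the states of a uniformly
chosen adjacent pair, accepted with the Boltzmann ratio
``exp((G_i - G_{i+1}) (1/T_i - 1/T_{i+1}))`` so that every marginal stays
at its own Boltzmann law.  Cold chains then tunnel between energy minima
(realizations) that the degree-preserving switch moves alone cannot
connect.

Ladder design follows a quartile-matching rule: probe the energy
distribution with independent chains on a log-spaced temperature grid,
smooth the lower/upper quartile curves isotonically, and walk a staircase
where each next temperature's lower quartile equals the current one's
upper quartile.  Adjacent chains then overlap enough that with probability
at least (1/4)^2 the colder state is the more energetic one and the swap
is auto-accepted, bounding the long-run swap acceptance below by 6.25%.

Realizations of the target degree sequence are harvested from the coldest
chain whenever its energy is zero, with a minimum spacing in coldest-chain
proposals (default: the edge count, i.e. roughly one proposed touch per
hyperedge between harvests).
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .chain import ChainStats, MetropolisChain
from .hypergraph import DegreeSequence, TripartiteHypergraph

__all__ = [
    "QuartileCurves",
    "TemperatureLadder",
    "ParallelTempering",
    "SampleRun",
    "SamplerTimeout",
    "AutocorrelationReport",
    "infinite_temperature_energy",
    "probe_quartiles",
    "build_ladder",
    "sample_realizations",
    "autocorrelation_diagnostics",
]


def infinite_temperature_energy(D: DegreeSequence) -> float:
    """Expected energy of a uniform (ER 1/2) hypergraph against D.

    At infinite temperature every cell is occupied with probability 1/2,
    so each vertex's degree concentrates at half its maximal degree; the
    estimate is the sum of |prescribed - max/2| over all vertices.
    """
    n1, n2, n3 = D.shape
    return (sum(abs(d - n2 * n3 / 2) for d in D.dA)
            + sum(abs(d - n1 * n3 / 2) for d in D.dB)
            + sum(abs(d - n1 * n2 / 2) for d in D.dC))


@dataclass(frozen=True)
class QuartileCurves:
    """Probe of the Boltzmann energy distribution along a temperature grid.

    ``lower``/``upper`` are the isotonically smoothed post-burn-in energy
    quartiles (monotone non-decreasing in T); ``zero_frac`` the fraction of
    zero-energy visits and ``median`` the energy median, both per probe
    temperature.  Raw (unsmoothed) quartiles are retained for diagnostics.
    """

    temperatures: tuple[float, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]
    raw_lower: tuple[float, ...]
    raw_upper: tuple[float, ...]
    zero_frac: tuple[float, ...]
    median: tuple[float, ...]
    steps_per_temperature: int
    burn_fraction: float
    seed: object = None

    def _interp(self, T: float, values: tuple[float, ...]) -> float:
        return float(np.interp(math.log(T), [math.log(t) for t in
                                             self.temperatures], values))

    def lower_at(self, T: float) -> float:
        """Smoothed lower quartile at T (log-linear interpolation)."""
        return self._interp(T, self.lower)

    def upper_at(self, T: float) -> float:
        return self._interp(T, self.upper)


def probe_quartiles(D: DegreeSequence,
                    T_grid=None,
                    steps_per_T: int = 4000,
                    rng: random.Random | int | None = None,
                    burn_frac: float = 0.2,
                    n_grid: int = 100,
                    weights=(1 / 3, 1 / 3, 1 / 3)) -> QuartileCurves:
    """Estimate Boltzmann energy quartiles with independent chains.

    One chain per grid temperature (default: ``n_grid`` log-spaced points
    from 0.1 up to the infinite-temperature energy estimate); the first
    ``burn_frac`` of each trace is discarded.  Chains run coldest first and
    each starts from the previous temperature's final state (the coldest
    from the empty hypergraph), which keeps the short probes near
    equilibrium.  Quartile curves are made monotone in log-temperature by
    isotonic regression, as befits the true Boltzmann quartiles.
    """
    seed_obj = rng
    rng = rng if isinstance(rng, random.Random) else random.Random(rng)
    if T_grid is None:
        t_hi = max(10.0, infinite_temperature_energy(D))
        T_grid = np.geomspace(0.1, t_hi, n_grid)
    T_grid = [float(t) for t in T_grid]
    if any(t <= 0 for t in T_grid) or sorted(T_grid) != T_grid:
        raise ValueError("temperature grid must be positive and ascending")
    n1, n2, n3 = D.shape
    burn = int(burn_frac * steps_per_T)
    lo, hi, zf, med = [], [], [], []
    start = TripartiteHypergraph(n1, n2, n3)
    for T in T_grid:
        chain = MetropolisChain(start, D, T, rng, weights)
        trace: list[int] = []
        chain.run(steps_per_T, trace)
        start = chain.H.copy()
        post = np.asarray(trace[burn:])
        lo.append(float(np.percentile(post, 25)))
        hi.append(float(np.percentile(post, 75)))
        zf.append(float(np.mean(post == 0)))
        med.append(float(np.median(post)))
    logT = np.log(T_grid)
    iso = IsotonicRegression(increasing=True)
    lo_s = iso.fit_transform(logT, lo)
    hi_s = IsotonicRegression(increasing=True).fit_transform(logT, hi)
    # the upper quartile can never sit below the lower one
    hi_s = np.maximum(lo_s, hi_s)
    return QuartileCurves(tuple(T_grid), tuple(map(float, lo_s)),
                          tuple(map(float, hi_s)), tuple(lo), tuple(hi),
                          tuple(zf), tuple(med), steps_per_T, burn_frac,
                          seed_obj if not isinstance(seed_obj, random.Random)
                          else None)


@dataclass(frozen=True)
class TemperatureLadder:
    """Strictly increasing temperatures with their design provenance."""

    temperatures: tuple[float, ...]
    curves: QuartileCurves | None = None
    fallback_geometric: bool = False

    def __post_init__(self) -> None:
        ts = tuple(float(t) for t in self.temperatures)
        object.__setattr__(self, "temperatures", ts)
        if len(ts) < 1 or any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("temperatures must be strictly increasing")
        if ts[0] <= 0:
            raise ValueError("temperatures must be positive")

    def __len__(self) -> int:
        return len(self.temperatures)


def select_endpoints(curves: QuartileCurves,
                     zero_occupancy: float = 0.9,
                     median_tolerance: float = 0.05,
                     E_inf: float | None = None) -> tuple[float, float]:
    """Coldest and warmest temperatures from the probe.

    T_min: the smallest probed temperature whose zero-energy occupancy
    exceeds ``zero_occupancy`` (so realizations dominate the coldest
    Boltzmann distribution); T_max: the smallest probed temperature whose
    energy median is within ``median_tolerance`` of the infinite-
    temperature estimate (so the warmest chain is essentially uniform).
    Falls back to the grid endpoints when no probe point qualifies.
    """
    ts = curves.temperatures
    T_min = ts[0]
    for t, z in zip(ts, curves.zero_frac):
        if z > zero_occupancy:
            T_min = t
            break
    T_max = ts[-1]
    if E_inf is not None and E_inf > 0:
        for t, m in zip(ts, curves.median):
            if m >= (1 - median_tolerance) * E_inf:
                T_max = t
                break
    if T_max <= T_min:
        T_max = ts[-1] if ts[-1] > T_min else T_min * 2
    return T_min, T_max


def build_ladder(curves: QuartileCurves, T_min: float, T_max: float,
                 max_rungs: int = 1024) -> TemperatureLadder:
    """Quartile-matched staircase from T_min to T_max.

    Starting at T_min, each next temperature is where the (smoothed,
    monotone) lower-quartile curve reaches the current temperature's upper
    quartile, found by inverting the log-linear interpolant.  The energy
    is integer-valued, so the smoothed curves can have flat stretches
    where the inverse stalls; progress is then clamped to the next probe
    grid point, i.e. the ladder never skips less than the probe's
    resolution.  Entirely flat curves carry no quartile information and
    trigger a geometric-spacing fallback (the two endpoints) with a
    warning.
    """
    if T_min <= 0 or T_max <= T_min:
        raise ValueError("need 0 < T_min < T_max")
    logts = np.asarray([math.log(t) for t in curves.temperatures])
    lo = np.asarray(curves.lower)
    if np.any(np.diff(lo) < -1e-9):
        raise ValueError("lower-quartile curve is not monotone")
    if np.ptp(lo) == 0 and np.ptp(curves.upper) == 0:
        warnings.warn("flat quartile curves; falling back to geometric "
                      "spacing", stacklevel=2)
        return TemperatureLadder((T_min, T_max), curves,
                                 fallback_geometric=True)
    temps = [T_min]
    while temps[-1] < T_max and len(temps) < max_rungs:
        target = curves.upper_at(temps[-1])
        if curves.lower_at(T_max) <= target:
            # the remaining gap already overlaps at quartile level
            if T_max > temps[-1]:
                temps.append(T_max)
            break
        # invert the lower-quartile interpolant at the target level
        idx = int(np.searchsorted(lo, target, side="right"))
        if idx == 0:
            t_next = curves.temperatures[0]
        elif idx >= len(lo):  # pragma: no cover - handled by overlap test
            t_next = T_max
        else:
            x0, x1 = logts[idx - 1], logts[idx]
            y0, y1 = lo[idx - 1], lo[idx]
            x = x1 if y1 == y0 else x0 + (target - y0) * (x1 - x0) / (y1 - y0)
            t_next = math.exp(x)
        if t_next <= temps[-1] * (1 + 1e-12):
            # flat stretch: advance by one probe grid step instead
            above = [t for t in curves.temperatures
                     if t > temps[-1] * (1 + 1e-12)]
            if not above:  # pragma: no cover - T_max below handles this
                temps.append(T_max)
                break
            t_next = above[0]
        temps.append(min(t_next, T_max))
    if temps[-1] < T_max:
        warnings.warn(f"ladder capped at {max_rungs} rungs before reaching "
                      f"T_max={T_max}", stacklevel=2)
    return TemperatureLadder(tuple(temps), curves)


def design_ladder(D: DegreeSequence, rng=None, steps_per_T: int = 4000,
                  n_grid: int = 60, weights=(1 / 3, 1 / 3, 1 / 3)
                  ) -> TemperatureLadder:
    """Probe + endpoint selection + staircase in one call."""
    curves = probe_quartiles(D, steps_per_T=steps_per_T, rng=rng,
                             n_grid=n_grid, weights=weights)
    T_min, T_max = select_endpoints(curves,
                                    E_inf=infinite_temperature_energy(D))
    return build_ladder(curves, T_min, T_max)


class SamplerTimeout(Exception):
    """The sampler exhausted its step budget before harvesting enough.

    Finding any realization is NP-hard in general, so a budget overrun is
    a legitimate outcome; the exception carries the best (lowest) energy
    seen and whatever samples were harvested.
    """

    def __init__(self, msg: str, best_energy: int, samples: list) -> None:
        super().__init__(msg)
        self.best_energy = best_energy
        self.samples = samples


@dataclass
class ParallelTempering:
    """Composite chain: one Metropolis chain per ladder temperature.

    All randomness (intra-chain moves, chain selection, swap decisions)
    flows through the single ``rng``, so runs are bit-reproducible under a
    fixed seed.
    """

    D: DegreeSequence
    ladder: TemperatureLadder
    rng: random.Random | int | None = None
    weights: tuple = (1 / 3, 1 / 3, 1 / 3)
    chains: list = field(init=False)
    swap_attempts: list = field(init=False)
    swap_accepts: list = field(init=False)
    coldest_proposals: int = field(init=False, default=0)
    steps: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        if len(self.ladder) < 2:
            raise ValueError("Parallel Tempering needs at least 2 rungs")
        if not isinstance(self.rng, random.Random):
            self.rng = random.Random(self.rng)
        n1, n2, n3 = self.D.shape
        self.chains = [MetropolisChain(TripartiteHypergraph(n1, n2, n3),
                                       self.D, T, self.rng, self.weights)
                       for T in self.ladder.temperatures]
        self.swap_attempts = [0] * (len(self.ladder) - 1)
        self.swap_accepts = [0] * (len(self.ladder) - 1)

    @property
    def coldest(self) -> MetropolisChain:
        return self.chains[0]

    def step(self) -> None:
        """One composite move: intra-chain step or adjacent swap attempt."""
        rng = self.rng
        self.steps += 1
        if rng.random() < 0.5:
            i = rng.randrange(len(self.chains))
            self.chains[i].step()
            if i == 0:
                self.coldest_proposals += 1
        else:
            i = rng.randrange(len(self.chains) - 1)
            self.swap_attempts[i] += 1
            a, b = self.chains[i], self.chains[i + 1]
            log_ratio = (a.delta_g - b.delta_g) * (1 / a.T - 1 / b.T)
            if log_ratio >= 0 or rng.random() < math.exp(log_ratio):
                a.swap_state_with(b)
                self.swap_accepts[i] += 1

    def swap_acceptance_rates(self) -> list[float]:
        return [acc / att if att else math.nan
                for acc, att in zip(self.swap_accepts, self.swap_attempts)]


@dataclass
class SampleRun:
    """Harvest of realizations with the run's diagnostics."""

    samples: list
    ladder: TemperatureLadder
    swap_attempts: list
    swap_accepts: list
    chain_stats: list          # ChainStats per temperature, coldest first
    zero_energy_fraction: float
    total_steps: int
    spacing: int
    seed: object = None

    def swap_acceptance_rates(self) -> list[float]:
        return [a / t if t else math.nan
                for a, t in zip(self.swap_accepts, self.swap_attempts)]


def sample_realizations(D: DegreeSequence, n_samples: int,
                        ladder: TemperatureLadder | None = None,
                        spacing: int | None = None,
                        rng: random.Random | int | None = None,
                        max_steps: int | None = None,
                        weights=(1 / 3, 1 / 3, 1 / 3),
                        probe_steps: int = 4000,
                        probe_grid: int = 60) -> SampleRun:
    """Harvest ``n_samples`` (approximately uniform) realizations of D.

    The sampler doubles as a stochastic search: it starts from empty
    hypergraphs and needs no a-priori realization.  States are harvested
    from the coldest chain whenever its energy is zero and at least
    ``spacing`` coldest-chain proposals have elapsed since the previous
    harvest (default spacing: the target edge count, so that each
    hyperedge is expected to be proposed for modification about once
    between harvests).  Raises :class:`SamplerTimeout` when ``max_steps``
    composite moves pass before the harvest completes.
    """
    seed_obj = None if isinstance(rng, random.Random) else rng
    rng = rng if isinstance(rng, random.Random) else random.Random(rng)
    if ladder is None:
        ladder = design_ladder(D, rng=rng, steps_per_T=probe_steps,
                               n_grid=probe_grid, weights=weights)
    n_edges = sum(D.dA)
    if spacing is None:
        spacing = max(1, n_edges)
    k = len(ladder)
    if max_steps is None:
        # heuristic budget: burn-in plus the expected harvest time, with
        # ample headroom for the stochastic search phase
        max_steps = 200_000 + 60 * n_samples * spacing * k
    pt = ParallelTempering(D, ladder, rng, tuple(weights))
    samples: list[TripartiteHypergraph] = []
    last_harvest = -spacing  # allow an immediate first harvest
    zero_visits = 0
    counted = 0
    seen_zero = False
    best = pt.coldest.delta_g
    while len(samples) < n_samples:
        if pt.steps >= max_steps:
            raise SamplerTimeout(
                f"no complete harvest within {max_steps} steps "
                f"(best energy {best})", best, samples)
        pt.step()
        g = pt.coldest.delta_g
        if g < best:
            best = g
        if seen_zero:
            counted += 1
            if g == 0:
                zero_visits += 1
        elif g == 0:
            seen_zero = True
        if g == 0 and pt.coldest_proposals - last_harvest >= spacing:
            samples.append(pt.coldest.H.copy())
            last_harvest = pt.coldest_proposals
    return SampleRun(samples, ladder, list(pt.swap_attempts),
                     list(pt.swap_accepts), [c.stats for c in pt.chains],
                     zero_visits / counted if counted else 0.0,
                     pt.steps, spacing, seed_obj)


@dataclass(frozen=True)
class AutocorrelationReport:
    """First two principal coordinates of the harvested states and their ACFs."""

    coordinates: np.ndarray      # (n_samples, 2)
    autocorrelations: np.ndarray  # (2, max_lag + 1), lag 0 first
    explained_variance: tuple[float, float]
    zero_variance: bool


def _acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        return np.full(max_lag + 1, np.nan)
    return np.asarray([1.0] + [float(x[:-l] @ x[l:]) / denom
                               for l in range(1, max_lag + 1)])


def autocorrelation_diagnostics(samples: list, max_lag: int | None = None
                                ) -> AutocorrelationReport:
    """PCA the harvested hypergraphs as 0-1 hyperedge indicator vectors.

    Low autocorrelation of the leading principal coordinates across the
    harvest order is evidence that consecutive samples are close to
    independent.  All-identical samples yield a ``zero_variance`` flag and
    NaN autocorrelations.
    """
    if len(samples) < 10:
        raise ValueError("need at least 10 samples for diagnostics")
    X = np.stack([h.indicator_vector().astype(float) for h in samples])
    X -= X.mean(axis=0)
    if max_lag is None:
        max_lag = min(50, len(samples) // 2)
    if not X.any():
        n = len(samples)
        return AutocorrelationReport(np.zeros((n, 2)),
                                     np.full((2, max_lag + 1), np.nan),
                                     (0.0, 0.0), True)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    pcs = U[:, :2] * s[:2]
    if pcs.shape[1] < 2:  # pragma: no cover - at least 2 cells in practice
        pcs = np.pad(pcs, ((0, 0), (0, 2 - pcs.shape[1])))
    var = s ** 2 / max(1, len(samples) - 1)
    total = float(var.sum())
    explained = (float(var[0] / total), float(var[1] / total)
                 if len(var) > 1 else 0.0)
    ac = np.stack([_acf(pcs[:, 0], max_lag), _acf(pcs[:, 1], max_lag)])
    return AutocorrelationReport(pcs, ac, explained, False)
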