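"""Benchmark machinery comparing the three protocols on a known ensemble.

Four instruments, all operating on replicate in silico experiments with a
fixed number of cells N and overall efficiency eps:

* :func:`replicate_correlation` — mean pairwise Pearson r between k
  independent replicate maps; grows with N and plateaus at 1.
* :func:`find_min_cells` — the minimal cell number M where r crosses the
  reproducibility threshold r_t = 0.9, located by bisection on a log-spaced
  candidate grid.
* :func:`noise_to_signal` — per-entry sigma/mu across replicates, aggregated
  by genomic distance; by the central limit theorem the aggregate scales as
  N^(-1/2) and M itself scales approximately as eps^(-2).
* :func:`clt_diagnostics` — the CLT-side quantities: the mean squared
  signal-to-noise of single-cell entries rho(eps) = <mu^2/sigma^2>, the
  CLT cell-number estimate L(eps) = delta^-2 / rho(eps), and the power-law /
  linearity fits tying M to L and to eps.

``method`` arguments accept "hic" | "sprite" | "gam" or any object
implementing the simulator protocol (``empty_map``, ``accumulate``,
``normalize``) — the latter is how closed-form oracles are injected in
tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ensembles import Ensemble
from .gam import GamGeometry, GamParams, GamSimulator
from .hic import HicParams, HicSimulator
from .sprite import SpriteParams, SpriteSimulator


class ThresholdUnreachableError(RuntimeError):
    """The replicate-correlation threshold is not reached by n_max cells."""


def make_simulator(ensemble: Ensemble, method, efficiency: float = 1.0,
                   d: float = 1.3, geometry: GamGeometry | None = None,
                   placement: str = "nuclear"):
    """Resolve a method: a name ("hic" | "sprite" | "gam"), a ready
    simulator object (has ``empty_map``), or a factory callable
    ``f(ensemble, efficiency) -> simulator``."""
    if not isinstance(method, str):
        if hasattr(method, "empty_map"):
            return method
        if callable(method):
            return method(ensemble, efficiency)
        raise TypeError(f"cannot interpret method {method!r}")
    if method == "hic":
        return HicSimulator(ensemble, HicParams.from_efficiency(efficiency, d),
                            placement, geometry)
    if method == "sprite":
        return SpriteSimulator(ensemble,
                               SpriteParams.from_efficiency(efficiency, d),
                               placement, geometry)
    if method == "gam":
        return GamSimulator(ensemble, GamParams.from_efficiency(efficiency),
                            geometry)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Replicate similarity
# ---------------------------------------------------------------------------

@dataclass
class ReplicateSet:
    method: str
    n_cells: int
    efficiency: float
    maps: list = field(default_factory=list)


def replicate_maps(ensemble: Ensemble, method, n_cells: int,
                   efficiency: float, k: int,
                   rng: np.random.Generator | int | None = None,
                   **sim_kwargs) -> ReplicateSet:
    """k independent replicate experiments; the pool of N cells is redrawn
    independently for every replicate."""
    sim = make_simulator(ensemble, method, efficiency, **sim_kwargs)
    rng = np.random.default_rng(rng)
    maps = []
    for child in rng.spawn(k):
        acc = sim.empty_map()
        sim.accumulate(acc, n_cells, child)
        maps.append(sim.normalize(acc, n_cells))
    name = method if isinstance(method, str) else getattr(method, "method",
                                                          "custom")
    return ReplicateSet(method=name, n_cells=n_cells, efficiency=efficiency,
                        maps=maps)


def _mean_pairwise_pearson(maps) -> float:
    iu = np.triu_indices(maps[0].shape[0], k=1)
    vectors = [np.asarray(m, float)[iu] for m in maps]
    usable = [v for v in vectors if np.ptp(v) > 0]
    dropped = len(vectors) - len(usable)
    if dropped:
        warnings.warn(f"excluded {dropped} degenerate (constant) replicate "
                      f"map(s) from the correlation")
    if len(usable) < 2:
        raise ValueError("fewer than 2 usable replicate maps")
    corr = np.corrcoef(np.stack(usable))
    return float(corr[np.triu_indices(len(usable), k=1)].mean())


def replicate_correlation(ensemble: Ensemble, method, n_cells: int,
                          efficiency: float, k: int,
                          rng: np.random.Generator | int | None = None,
                          **sim_kwargs) -> float:
    """Mean Pearson correlation between all k(k-1)/2 pairs of replicate
    contact maps at fixed N and efficiency."""
    if k < 2:
        raise ValueError("need k >= 2 replicates")
    reps = replicate_maps(ensemble, method, n_cells, efficiency, k, rng,
                          **sim_kwargs)
    return _mean_pairwise_pearson(reps.maps)


# ---------------------------------------------------------------------------
# Minimal cell number M
# ---------------------------------------------------------------------------

@dataclass
class MinCellsResult:
    m: int
    bracket: tuple
    r_at_m: float
    evaluations: dict  # candidate N -> mean replicate correlation


class _ReplicateStreams:
    """k cumulative cell streams with snapshots at candidate grid points.

    Extending all streams to the largest bracketing N and snapshotting every
    intermediate grid point makes each r(N) evaluation a prefix lookup, so
    the bisection costs k * N_max simulated cells in total.  Each r(N) is
    still the mean pairwise Pearson over k mutually independent N-cell
    replicates.
    """

    def __init__(self, sim, k: int, rng: np.random.Generator):
        self.sim = sim
        self.rngs = rng.spawn(k)
        self.accs = [sim.empty_map() for _ in range(k)]
        self.n_done = 0
        self.snapshots: dict[int, list] = {}

    def extend(self, grid_points) -> None:
        for g in grid_points:
            if g <= self.n_done:
                continue
            for acc, child in zip(self.accs, self.rngs):
                self.sim.accumulate(acc, g - self.n_done, child)
            self.n_done = g
            self.snapshots[g] = [a.copy() for a in self.accs]

    def correlation_at(self, g: int) -> float:
        maps = [self.sim.normalize(a, g) for a in self.snapshots[g]]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return _mean_pairwise_pearson(maps)
        except ValueError:
            return float("nan")


def candidate_grid(n_max: int, points_per_decade: int = 8) -> np.ndarray:
    """Strictly increasing integer grid, log-spaced, starting at 1."""
    exps = np.arange(0, int(np.ceil(np.log10(n_max) * points_per_decade)) + 1)
    vals = np.unique(np.rint(10.0 ** (exps / points_per_decade)).astype(int))
    return vals[vals <= n_max]


def find_min_cells(ensemble: Ensemble, method, efficiency: float,
                   r_t: float = 0.9, k: int = 15,
                   rng: np.random.Generator | int | None = None,
                   n_max: int = 1_000_000, points_per_decade: int = 8,
                   **sim_kwargs) -> MinCellsResult:
    """Minimal number of cells M for replicate reproducibility.

    M is the smallest N on the log-spaced candidate grid where the mean
    pairwise Pearson correlation between k replicates reaches ``r_t``,
    bracketed by scanning geometrically (half-decade milestones) upward and
    then bisecting grid indices inside the bracketing interval.
    """
    if r_t <= 0:
        return MinCellsResult(m=1, bracket=(1, 1), r_at_m=float("nan"),
                              evaluations={})
    sim = make_simulator(ensemble, method, efficiency, **sim_kwargs)
    rng = np.random.default_rng(rng)
    grid = candidate_grid(n_max, points_per_decade)
    streams = _ReplicateStreams(sim, k, rng)
    evaluations: dict[int, float] = {}
    half_step = max(1, points_per_decade // 2)
    milestones = [int(g) for g in grid[::half_step]]
    if milestones[-1] != int(grid[-1]):
        milestones.append(int(grid[-1]))
    lo_idx = None
    hi_idx = None
    for m in milestones:
        m_idx = int(np.searchsorted(grid, m))
        streams.extend(grid[: m_idx + 1])
        r = streams.correlation_at(m)
        evaluations[int(m)] = r
        if np.isfinite(r) and r >= r_t:
            hi_idx = m_idx
            break
        lo_idx = m_idx
    if hi_idx is None:
        finite = [v for v in evaluations.values() if np.isfinite(v)]
        best = max(finite) if finite else float("nan")
        raise ThresholdUnreachableError(
            f"r_t={r_t} not reached by N={n_max} cells "
            f"(max correlation attained: {best:.3f})"
        )
    if lo_idx is None:  # already reproducible at N = 1
        return MinCellsResult(m=1, bracket=(1, 1),
                              r_at_m=evaluations[1], evaluations=evaluations)
    while hi_idx - lo_idx > 1:
        mid = (lo_idx + hi_idx) // 2
        r = streams.correlation_at(int(grid[mid]))
        evaluations[int(grid[mid])] = r
        if np.isfinite(r) and r >= r_t:
            hi_idx = mid
        else:
            lo_idx = mid
    return MinCellsResult(
        m=int(grid[hi_idx]),
        bracket=(int(grid[lo_idx]), int(grid[hi_idx])),
        r_at_m=evaluations[int(grid[hi_idx])],
        evaluations=evaluations,
    )


# ---------------------------------------------------------------------------
# Noise-to-signal
# ---------------------------------------------------------------------------

@dataclass
class NoiseProfile:
    """Per-entry mean and standard deviation across replicate experiments."""

    mu: np.ndarray
    sigma: np.ndarray
    n_replicates: int
    n_cells: int
    efficiency: float
    resolution_bp: int

    def ratio_matrix(self) -> np.ndarray:
        out = np.full_like(self.mu, np.nan)
        np.divide(self.sigma, self.mu, out=out, where=self.mu > 0)
        return out

    def mean_ratio_at(self, separation_bins: int) -> float:
        """Mean sigma/mu over entries at one genomic separation, excluding
        entries never observed (mu = 0)."""
        ratio = np.diagonal(self.ratio_matrix(), offset=separation_bins)
        ratio = ratio[np.isfinite(ratio)]
        if ratio.size == 0:
            return float("nan")
        return float(ratio.mean())

    def curve_by_distance(self):
        """(separation_bp, mean sigma/mu) over all separations."""
        n = self.mu.shape[0]
        seps = np.arange(1, n)
        vals = np.array([self.mean_ratio_at(int(s)) for s in seps])
        return seps * self.resolution_bp, vals


def noise_to_signal(ensemble: Ensemble, method, n_cells: int,
                    efficiency: float, n_replicates: int,
                    rng: np.random.Generator | int | None = None,
                    **sim_kwargs) -> NoiseProfile:
    """Per-entry mu and sigma over ``n_replicates`` replicate experiments
    (streaming accumulation; sigma uses the sample standard deviation)."""
    if n_replicates < 2:
        raise ValueError("need n_replicates >= 2")
    sim = make_simulator(ensemble, method, efficiency, **sim_kwargs)
    rng = np.random.default_rng(rng)
    s1 = s2 = None
    for child in rng.spawn(n_replicates):
        acc = sim.empty_map()
        sim.accumulate(acc, n_cells, child)
        m = np.asarray(sim.normalize(acc, n_cells), float)
        if s1 is None:
            s1 = np.zeros_like(m)
            s2 = np.zeros_like(m)
        s1 += m
        s2 += m * m
    mu = s1 / n_replicates
    var = (s2 - n_replicates * mu * mu) / (n_replicates - 1)
    sigma = np.sqrt(np.clip(var, 0.0, None))
    return NoiseProfile(mu=mu, sigma=sigma, n_replicates=n_replicates,
                        n_cells=n_cells, efficiency=efficiency,
                        resolution_bp=ensemble.resolution_bp)


def fit_power_law(x, y):
    """Least-squares exponent of y ~ x^a in log-log space; returns
    (exponent, prefactor, R^2).  Nonpositive values are rejected."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("power-law fit needs positive data")
    if x.size < 2:
        return float("nan"), float(y[0]), float("nan")
    res = stats.linregress(np.log(x), np.log(y))
    return float(res.slope), float(np.exp(res.intercept)), float(res.rvalue**2)


# ---------------------------------------------------------------------------
# CLT diagnostics
# ---------------------------------------------------------------------------

@dataclass
class CltDiagnostics:
    efficiencies: np.ndarray
    rho: np.ndarray          # <mu^2/sigma^2> over single-cell entries
    L: np.ndarray            # delta^-2 / rho
    delta: float
    m_values: np.ndarray | None
    m_vs_l_fit: tuple | None       # (slope, intercept, R^2)
    m_exponent: float | None       # log M vs log eps
    inv_rho_exponent: float        # log rho^-1 vs log eps


def single_cell_rho(ensemble: Ensemble, method, efficiency: float,
                    n_single: int = 2000,
                    rng: np.random.Generator | int | None = None,
                    **sim_kwargs) -> float:
    """Mean squared signal-to-noise <mu^2/sigma^2> of single-cell map
    entries, averaged over upper-triangle entries with sigma > 0."""
    profile = noise_to_signal(ensemble, method, 1, efficiency, n_single, rng,
                              **sim_kwargs)
    iu = np.triu_indices(profile.mu.shape[0], k=1)
    mu, sigma = profile.mu[iu], profile.sigma[iu]
    ok = sigma > 0
    if not ok.any():
        raise ValueError("all single-cell entries have zero variance")
    return float(np.mean((mu[ok] / sigma[ok]) ** 2))


def clt_diagnostics(ensemble: Ensemble, method, efficiencies,
                    delta: float = 1.0,
                    rng: np.random.Generator | int | None = None,
                    n_single: int = 2000, m_values=None, r_t: float = 0.9,
                    k: int = 15, n_max: int = 1_000_000,
                    **sim_kwargs) -> CltDiagnostics:
    """rho(eps), L(eps) = delta^-2 / rho(eps), and their relation to the
    heuristic minimal cell number M across an efficiency grid.

    If ``m_values`` is not supplied, M is estimated per efficiency with
    :func:`find_min_cells`.  Returns the linear fit of M against L (the CLT
    consistency check) and the power-law exponents of M and rho^-1 vs eps.
    """
    efficiencies = np.asarray(efficiencies, float)
    rng = np.random.default_rng(rng)
    rho = np.empty_like(efficiencies)
    for i, eps in enumerate(efficiencies):
        rho[i] = single_cell_rho(ensemble, method, float(eps), n_single,
                                 rng.spawn(1)[0], **sim_kwargs)
    L = delta**-2 / rho
    if m_values is None:
        m_values = np.array([
            find_min_cells(ensemble, method, float(eps), r_t=r_t, k=k,
                           rng=rng.spawn(1)[0], n_max=n_max, **sim_kwargs).m
            for eps in efficiencies
        ], dtype=float)
    else:
        m_values = np.asarray(m_values, float) if m_values is not False else None
    m_vs_l_fit = None
    m_exponent = None
    if m_values is not None:
        res = stats.linregress(L, m_values)
        m_vs_l_fit = (float(res.slope), float(res.intercept),
                      float(res.rvalue**2))
        m_exponent = fit_power_law(efficiencies, m_values)[0]
    inv_rho_exponent = fit_power_law(efficiencies, 1.0 / rho)[0]
    return CltDiagnostics(
        efficiencies=efficiencies, rho=rho, L=L, delta=delta,
        m_values=None if m_values is None else np.asarray(m_values, float),
        m_vs_l_fit=m_vs_l_fit, m_exponent=m_exponent,
        inv_rho_exponent=inv_rho_exponent,
    )
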