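"""In silico SPRITE: crosslinking, split-pool tag retention and 2/n-weighted
pair counting.

Crosslinking and digestion are exactly the Hi-C steps (shared
:class:`~silicomap.hic.ClusterEngine`).  Split-pool tagging is not simulated
explicitly — cluster identity is already known in silico — but tag loss is:
each cluster bead keeps its tag with probability ``p_s`` and is sequenced
with probability ``p_d``.  For each cluster, every unordered pair of
distinct bins touched by its detected beads receives weight ``2/n``.  By
default ``n`` counts the *detected* fragments of the cluster, mirroring the
experimental weighting applied to sequenced cluster reads; set
``weight_basis="cluster"`` to count all crosslinked fragments instead.

The overall efficiency p_c * p_s * p_d maps onto the per-bead crosslink
inclusion step p_c (:meth:`SpriteParams.from_efficiency`): incomplete
crosslinking fragments the proximity graph before clustering, which keeps
the simulated cluster-size statistics at working efficiencies comparable
to the small sequenced clusters of real experiments, whereas pure tag loss
would leave intact, locus-spanning complexes whose co-occurrence signal is
unrealistically reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensembles import CellSample, ContactMap, Ensemble
from .gam import GamGeometry
from .hic import ClusterEngine, _param_dict


@dataclass(frozen=True)
class SpriteParams:
    """Crosslink range (sigma), per-step probabilities, and the cluster-size
    convention used in the 2/n weight."""

    d: float = 1.3
    p_c: float = 1.0
    p_s: float = 1.0
    p_d: float = 1.0
    weight_basis: str = "detected"  # | "cluster"

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("d must be positive")
        for name in ("p_c", "p_s", "p_d"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.weight_basis not in ("detected", "cluster"):
            raise ValueError(f"unknown weight_basis {self.weight_basis!r}")

    @property
    def efficiency(self) -> float:
        return self.p_c * self.p_s * self.p_d

    @classmethod
    def from_efficiency(cls, eps: float, d: float = 1.3) -> "SpriteParams":
        """Load an overall efficiency onto the per-bead crosslink-inclusion
        step (incomplete crosslinking fragments complexes, as in real
        experiments)."""
        return cls(d=d, p_c=eps)


class SpriteSimulator:
    """Reusable SPRITE simulator bound to one ensemble and parameter set."""

    method = "sprite"

    def __init__(self, ensemble: Ensemble, params: SpriteParams | None = None,
                 placement: str = "nuclear",
                 geometry: GamGeometry | None = None):
        self.params = params or SpriteParams()
        self.engine = ClusterEngine(ensemble, self.params.d, placement,
                                    geometry)
        self.n_bin = ensemble.n_bin

    def accumulate_cell(self, acc: np.ndarray, ia: int, ib: int,
                        rng: np.random.Generator) -> None:
        p = self.params
        engine = self.engine
        _, labels = engine.cell_state(ia, ib, p.p_c, rng, need_labels=True)
        members = labels >= 0
        if not members.any():
            return
        n2 = labels.size
        detected = members.copy()
        if p.p_s < 1.0:
            detected &= rng.random(n2) < p.p_s
        if p.p_d < 1.0:
            detected &= rng.random(n2) < p.p_d
        det_idx = np.flatnonzero(detected)
        if det_idx.size < 2:
            return
        det_labels = labels[det_idx]
        order = np.argsort(det_labels, kind="stable")
        det_idx = det_idx[order]
        det_labels = det_labels[order]
        starts = np.flatnonzero(np.r_[True, np.diff(det_labels) > 0])
        bounds = np.r_[starts, det_labels.size]
        if p.weight_basis == "cluster":
            cluster_sizes = np.bincount(labels[members])
        bins2 = engine.bins2
        for s, e in zip(bounds[:-1], bounds[1:]):
            group = det_idx[s:e]
            if group.size < 2:
                continue
            bins = np.unique(bins2[group])
            if bins.size < 2:
                continue
            if p.weight_basis == "detected":
                n_frag = group.size
            else:
                n_frag = int(cluster_sizes[det_labels[s]])
            w = 2.0 / n_frag
            acc[np.ix_(bins, bins)] += w
            acc[bins, bins] -= w

    def cell_map(self, ia: int, ib: int,
                 rng: np.random.Generator) -> np.ndarray:
        acc = np.zeros((self.n_bin, self.n_bin))
        self.accumulate_cell(acc, ia, ib, rng)
        return acc

    def accumulate(self, acc: np.ndarray, n_cells: int,
                   rng: np.random.Generator) -> None:
        n_conf = self.engine.ensemble.n_conformations
        for _ in range(n_cells):
            ia, ib = rng.integers(n_conf, size=2)
            self.accumulate_cell(acc, int(ia), int(ib), rng)

    def sample_map(self, n_cells: int, rng: np.random.Generator) -> np.ndarray:
        acc = np.zeros((self.n_bin, self.n_bin))
        self.accumulate(acc, n_cells, rng)
        return acc

    def empty_map(self) -> np.ndarray:
        return np.zeros((self.n_bin, self.n_bin))

    @staticmethod
    def normalize(acc: np.ndarray, n_cells: int) -> np.ndarray:
        """SPRITE maps are weighted count totals; no per-cell normalization."""
        return acc


def sprite_single_cell(
    ensemble: Ensemble,
    cell: CellSample,
    params: SpriteParams | None = None,
    rng: np.random.Generator | int | None = None,
    placement: str = "nuclear",
    geometry: GamGeometry | None = None,
) -> ContactMap:
    """Weighted single-cell SPRITE contact map of one in silico cell."""
    cell.validate(ensemble)
    sim = SpriteSimulator(ensemble, params, placement, geometry)
    rng = np.random.default_rng(rng)
    acc = sim.cell_map(cell.allele_a, cell.allele_b, rng)
    return ContactMap(matrix=acc, method="sprite", n_cells=1,
                      params=_param_dict(sim.params, placement))


def sprite_map(
    ensemble: Ensemble,
    n_cells: int,
    params: SpriteParams | None = None,
    rng: np.random.Generator | int | None = None,
    placement: str = "nuclear",
    geometry: GamGeometry | None = None,
) -> ContactMap:
    """Sum of ``n_cells`` independent weighted single-cell SPRITE maps."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    sim = SpriteSimulator(ensemble, params, placement, geometry)
    rng = np.random.default_rng(rng)
    acc = sim.sample_map(n_cells, rng)
    return ContactMap(matrix=acc, method="sprite", n_cells=n_cells,
                      params=_param_dict(sim.params, placement))


def discretize_for_rank(cmap: ContactMap | np.ndarray) -> ContactMap:
    """Rescale a weighted SPRITE map so its minimum positive entry maps to 1
    and round to integers (zeros preserved), making its rank structure
    comparable with the integer-valued Hi-C and GAM maps."""
    matrix = cmap.matrix if isinstance(cmap, ContactMap) else np.asarray(cmap)
    positive = matrix[matrix > 0]
    if positive.size == 0:
        out = matrix.astype(np.int64)
    else:
        out = np.rint(matrix / positive.min()).astype(np.int64)
    if isinstance(cmap, ContactMap):
        return ContactMap(matrix=out, method=cmap.method,
                          n_cells=cmap.n_cells, params=dict(cmap.params))
    return ContactMap(matrix=out, method="sprite")
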