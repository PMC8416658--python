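"""In silico Hi-C: crosslinking, digestion, biotinylation, ligation, detection.

One in silico cell is a pair of independently drawn conformations (the two
alleles), placed at random in a shared spherical nucleus by default so that
inter-allele crosslinks are possible but rare.  Crosslinking joins same-color
beads closer than the interaction range ``d`` (each bead enters the
crosslinked material with probability ``p_c``) into clusters — connected
components of the proximity graph, discarding singletons.  Digestion splits
the chain into individual beads, so clusters are the only structure that
survives.  Each cluster bead then survives biotinylation with probability
``p_b`` and is eligible for ligation with probability ``p_l``; eligible
beads are paired by repeated uniform random selection of mutually-proximal
pairs without replacement (a uniform random maximal matching of the
within-cluster proximity graph), and each ligated pair is finally counted
into its bin-pair entry with detection probability ``p_d``.

The product p_c * p_b * p_l * p_d is the overall efficiency.  A single
overall efficiency is mapped onto the per-bead biotinylation step
(:meth:`HicParams.from_efficiency`), keeping the efficiency a per-bead
survival probability, so that a contact requires two independent survivals
and the expected single-cell signal scales as eps^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .ensembles import CellSample, ContactMap, Ensemble
from .gam import GamGeometry, random_rotation, uniform_in_ball


@dataclass(frozen=True)
class HicParams:
    """Crosslink range (sigma) and the four per-step probabilities."""

    d: float = 1.3
    p_c: float = 1.0
    p_b: float = 1.0
    p_l: float = 1.0
    p_d: float = 1.0

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("d must be positive")
        for name in ("p_c", "p_b", "p_l", "p_d"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def efficiency(self) -> float:
        return self.p_c * self.p_b * self.p_l * self.p_d

    @classmethod
    def from_efficiency(cls, eps: float, d: float = 1.3) -> "HicParams":
        """Load an overall efficiency onto the per-bead biotinylation step."""
        return cls(d=d, p_b=eps)


@dataclass
class CrosslinkClusters:
    """Disjoint monochromatic bead clusters of one cell; beads with pooled
    index >= n_beads_per_allele belong to the second allele."""

    clusters: list
    n_beads_per_allele: int

    def allele_of(self, bead_index: int) -> int:
        return int(bead_index >= self.n_beads_per_allele)


# ---------------------------------------------------------------------------
# Crosslinking primitives
# ---------------------------------------------------------------------------

def _proximity_edges(coords: np.ndarray, colors: np.ndarray,
                     d: float) -> np.ndarray:
    """Upper-triangle pairs of same-color beads within distance d."""
    x = np.asarray(coords, float)
    diff = x[:, None, :] - x[None, :, :]
    close = (diff**2).sum(axis=-1) <= d * d
    same = colors[:, None] == colors[None, :]
    return np.argwhere(np.triu(close & same, k=1))


def _cross_edges(xa: np.ndarray, xb: np.ndarray, colors_a, colors_b,
                 d: float) -> np.ndarray:
    diff = xa[:, None, :] - xb[None, :, :]
    close = (diff**2).sum(axis=-1) <= d * d
    same = np.asarray(colors_a)[:, None] == np.asarray(colors_b)[None, :]
    return np.argwhere(close & same)


def _component_labels(n: int, edges: np.ndarray):
    """Connected-component labels keeping only components of size >= 2
    (singletons cannot ligate); returns (labels with -1 for discarded
    beads, number of clusters)."""
    if len(edges) == 0:
        return np.full(n, -1, dtype=int), 0
    graph = coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
    )
    _, raw = connected_components(graph, directed=False)
    sizes = np.bincount(raw)
    keep = sizes >= 2
    mapping = np.full(len(sizes), -1, dtype=int)
    mapping[keep] = np.arange(int(keep.sum()))
    return mapping[raw], int(keep.sum())


def crosslink(
    coords: np.ndarray,
    colors: np.ndarray,
    d: float,
    p_c: float,
    rng: np.random.Generator,
    n_beads_per_allele: int | None = None,
) -> CrosslinkClusters:
    """Crosslink the pooled beads of one cell.

    Each bead enters the crosslinked material independently with probability
    ``p_c``; retained same-color beads closer than ``d`` are joined and the
    clusters are the connected components of that proximity graph
    (single-linkage, minimum cluster size 2).
    """
    coords = np.asarray(coords, float)
    colors = np.asarray(colors, int)
    n = coords.shape[0]
    retained = np.ones(n, dtype=bool)
    if p_c < 1.0:
        retained = rng.random(n) < p_c
    edges = _proximity_edges(coords, colors, d)
    if p_c < 1.0:
        edges = edges[retained[edges[:, 0]] & retained[edges[:, 1]]]
    labels, n_clusters = _component_labels(n, edges)
    clusters = [np.flatnonzero(labels == k) for k in range(n_clusters)]
    return CrosslinkClusters(
        clusters=clusters,
        n_beads_per_allele=n_beads_per_allele if n_beads_per_allele else n,
    )


# ---------------------------------------------------------------------------
# Shared per-cell engine (Hi-C and SPRITE)
# ---------------------------------------------------------------------------

class ClusterEngine:
    """Per-cell crosslink machinery with per-conformation caching.

    Intra-allele proximity edges are rigid-motion invariant, so they are
    computed once per conformation; under the default nuclear placement the
    two alleles only interact when their bounding spheres come within ``d``
    of each other, in which case explicit placed coordinates are drawn and
    inter-allele edges added.
    """

    def __init__(self, ensemble: Ensemble, d: float,
                 placement: str = "nuclear",
                 geometry: GamGeometry | None = None):
        if placement not in ("nuclear", "native"):
            raise ValueError(f"unknown placement {placement!r}")
        self.ensemble = ensemble
        self.d = float(d)
        self.placement = placement
        self.geometry = geometry or GamGeometry()
        self.n_bead = ensemble.n_bead
        self.bins2 = np.concatenate([ensemble.bin_of_bead] * 2)
        means = ensemble.coords.mean(axis=1, keepdims=True)
        self.centered = ensemble.coords - means
        self.radii = np.sqrt((self.centered**2).sum(axis=2).max(axis=1))
        if placement == "nuclear" and self.radii.max() >= self.geometry.R:
            raise ValueError(
                f"largest conformation (radius {self.radii.max():.2f}) does "
                f"not fit in a nucleus of radius {self.geometry.R}"
            )
        self._edge_cache: dict[int, np.ndarray] = {}
        self._label_cache: dict[int, tuple] = {}

    def conf_edges(self, i: int) -> np.ndarray:
        cached = self._edge_cache.get(i)
        if cached is None:
            cached = _proximity_edges(self.centered[i], self.ensemble.colors,
                                      self.d)
            self._edge_cache[i] = cached
        return cached

    def conf_labels(self, i: int):
        cached = self._label_cache.get(i)
        if cached is None:
            cached = _component_labels(self.n_bead, self.conf_edges(i))
            self._label_cache[i] = cached
        return cached

    def cell_state(self, ia: int, ib: int, p_c: float,
                   rng: np.random.Generator, need_labels: bool):
        """Crosslink one cell; returns (edges over pooled bead indices,
        cluster labels or None)."""
        n, d = self.n_bead, self.d
        inter = None
        if self.placement == "nuclear":
            geo = self.geometry
            c_a = uniform_in_ball(geo.R - self.radii[ia], rng)
            c_b = uniform_in_ball(geo.R - self.radii[ib], rng)
            if np.linalg.norm(c_a - c_b) <= self.radii[ia] + self.radii[ib] + d:
                ya = self.centered[ia] @ random_rotation(rng).T + c_a
                yb = self.centered[ib] @ random_rotation(rng).T + c_b
                inter = _cross_edges(ya, yb, self.ensemble.colors,
                                     self.ensemble.colors, d)
        else:  # native: raw coordinate frames, alleles may overlap
            inter = _cross_edges(self.ensemble.coords[ia],
                                 self.ensemble.coords[ib],
                                 self.ensemble.colors, self.ensemble.colors, d)
        parts = [self.conf_edges(ia), self.conf_edges(ib) + n]
        if inter is not None and len(inter):
            inter = inter.copy()
            inter[:, 1] += n
            parts.append(inter)
        else:
            inter = None
        edges = np.vstack(parts) if len(parts) > 1 else parts[0]
        if p_c < 1.0:
            retained = rng.random(2 * n) < p_c
            edges = edges[retained[edges[:, 0]] & retained[edges[:, 1]]]
        labels = None
        if need_labels:
            if p_c == 1.0 and inter is None:
                la, ka = self.conf_labels(ia)
                lb, kb = self.conf_labels(ib)
                labels = np.concatenate(
                    [la, np.where(lb >= 0, lb + ka, -1)]
                )
            else:
                labels, _ = _component_labels(2 * n, edges)
        return edges, labels


def _random_maximal_matching(edges: np.ndarray, n_beads: int,
                             rng: np.random.Generator) -> list:
    """Uniform random maximal matching: repeatedly draw a uniform pair among
    those whose endpoints are both still free (realized by a single uniform
    permutation of the candidate pairs, which induces the same law).
    Returns the matched endpoints as two parallel lists."""
    if len(edges) == 0:
        return [], []
    perm = rng.permutation(len(edges))
    left = edges[perm, 0].tolist()
    right = edges[perm, 1].tolist()
    used = bytearray(n_beads)
    out_a, out_b = [], []
    for a, b in zip(left, right):
        if not used[a] and not used[b]:
            used[a] = used[b] = 1
            out_a.append(a)
            out_b.append(b)
    return out_a, out_b


# ---------------------------------------------------------------------------
# Hi-C protocol
# ---------------------------------------------------------------------------

class HicSimulator:
    """Reusable Hi-C simulator bound to one ensemble and parameter set."""

    method = "hic"

    def __init__(self, ensemble: Ensemble, params: HicParams | None = None,
                 placement: str = "nuclear",
                 geometry: GamGeometry | None = None):
        self.params = params or HicParams()
        self.engine = ClusterEngine(ensemble, self.params.d, placement,
                                    geometry)
        self.n_bin = ensemble.n_bin

    def accumulate_cell(self, counts: np.ndarray, ia: int, ib: int,
                        rng: np.random.Generator) -> None:
        p = self.params
        engine = self.engine
        edges, _ = engine.cell_state(ia, ib, p.p_c, rng, need_labels=False)
        n2 = 2 * engine.n_bead
        if p.p_b < 1.0 or p.p_l < 1.0:
            eligible = np.ones(n2, dtype=bool)
            if p.p_b < 1.0:
                eligible &= rng.random(n2) < p.p_b
            if p.p_l < 1.0:
                eligible &= rng.random(n2) < p.p_l
            edges = edges[eligible[edges[:, 0]] & eligible[edges[:, 1]]]
        lig_a, lig_b = _random_maximal_matching(edges, n2, rng)
        if not lig_a:
            return
        bins2 = engine.bins2
        i = bins2[lig_a]
        j = bins2[lig_b]
        if p.p_d < 1.0:
            keep = rng.random(i.size) < p.p_d
            i, j = i[keep], j[keep]
        np.add.at(counts, (i, j), 1)
        off = i != j
        np.add.at(counts, (j[off], i[off]), 1)

    def cell_map(self, ia: int, ib: int,
                 rng: np.random.Generator) -> np.ndarray:
        counts = np.zeros((self.n_bin, self.n_bin), dtype=np.int64)
        self.accumulate_cell(counts, ia, ib, rng)
        return counts

    def accumulate(self, counts: np.ndarray, n_cells: int,
                   rng: np.random.Generator) -> None:
        n_conf = self.engine.ensemble.n_conformations
        for _ in range(n_cells):
            ia, ib = rng.integers(n_conf, size=2)
            self.accumulate_cell(counts, int(ia), int(ib), rng)

    def sample_map(self, n_cells: int, rng: np.random.Generator) -> np.ndarray:
        counts = np.zeros((self.n_bin, self.n_bin), dtype=np.int64)
        self.accumulate(counts, n_cells, rng)
        return counts

    def empty_map(self) -> np.ndarray:
        return np.zeros((self.n_bin, self.n_bin), dtype=np.int64)

    @staticmethod
    def normalize(counts: np.ndarray, n_cells: int) -> np.ndarray:
        """Hi-C maps are raw counts; no per-cell normalization."""
        return counts


def hic_single_cell(
    ensemble: Ensemble,
    cell: CellSample,
    params: HicParams | None = None,
    rng: np.random.Generator | int | None = None,
    placement: str = "nuclear",
    geometry: GamGeometry | None = None,
) -> ContactMap:
    """Integer single-cell Hi-C contact map of one in silico cell."""
    cell.validate(ensemble)
    sim = HicSimulator(ensemble, params, placement, geometry)
    rng = np.random.default_rng(rng)
    counts = sim.cell_map(cell.allele_a, cell.allele_b, rng)
    return ContactMap(matrix=counts, method="hic", n_cells=1,
                      params=_param_dict(sim.params, placement))


def hic_map(
    ensemble: Ensemble,
    n_cells: int,
    params: HicParams | None = None,
    rng: np.random.Generator | int | None = None,
    placement: str = "nuclear",
    geometry: GamGeometry | None = None,
) -> ContactMap:
    """Sum of ``n_cells`` independent single-cell Hi-C maps; cells are drawn
    as independent uniform conformation pairs with replacement."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    sim = HicSimulator(ensemble, params, placement, geometry)
    rng = np.random.default_rng(rng)
    counts = sim.sample_map(n_cells, rng)
    return ContactMap(matrix=counts, method="hic", n_cells=n_cells,
                      params=_param_dict(sim.params, placement))


def _param_dict(params, placement: str) -> dict:
    out = {k: getattr(params, k) for k in params.__dataclass_fields__}
    out["efficiency"] = params.efficiency
    out["placement"] = placement
    return out
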