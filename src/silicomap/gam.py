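"""In silico GAM: nuclear slicing, cosegregation and NPMI.

A cell nucleus is modelled as a sphere of radius ``R`` (units of sigma)
containing the two alleles of the locus, each an independently chosen
conformation given a uniform random rotation and a uniform random centroid
position that keeps it fully inside the nucleus.  One randomly oriented
planar slab of thickness ``h`` is cut per cell; beads inside the slab are
detected with probability ``p_d`` (the overall GAM bead efficiency), and a
genomic bin is called positive when at least one of its beads is detected,
with the two alleles pooled.  Cosegregation frequencies are co-occurrence
counts over slices divided by the number of slices — including slices that
miss the locus entirely, as in the experiment.

The module also hosts the bead-to-window efficiency mapping: a window of
``n`` beads per allele (2n per cell) that intersects a slab with ``k``
beads inside is detected with probability 1 - (1 - eps)^k, and averaging k
uniformly over 1..2n gives

    eps_GAM = 1 - ((1 - eps)/eps) * (1 - (1 - eps)^(2n)) / (2n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensembles import CellSample, ContactMap, Ensemble


@dataclass(frozen=True)
class GamGeometry:
    """Nuclear radius and slice thickness, in units of sigma.

    Defaults (R = 120, h = 6) correspond to a ~4.6 um nuclear radius and
    ~220 nm slices at sigma = 38 nm.
    """

    R: float = 120.0
    h: float = 6.0

    def __post_init__(self) -> None:
        if not 0 < self.h < 2 * self.R:
            raise ValueError("need 0 < h < 2R")


@dataclass(frozen=True)
class GamParams:
    """Bead detection probability; this is the overall GAM efficiency."""

    p_d: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.p_d <= 1:
            raise ValueError("p_d must be in [0, 1]")

    @property
    def efficiency(self) -> float:
        return self.p_d

    @classmethod
    def from_efficiency(cls, eps: float) -> "GamParams":
        return cls(p_d=eps)


@dataclass
class SliceProfile:
    """Genomic bins called positive in one nuclear slice."""

    positive_bins: np.ndarray
    cell_id: int = -1


# ---------------------------------------------------------------------------
# Random-placement primitives (shared with the Hi-C/SPRITE cell assembly)
# ---------------------------------------------------------------------------

def scaled_geometry(ensemble: Ensemble, h: float = 6.0,
                    rg_over_r: float = 0.11) -> GamGeometry:
    """Nuclear geometry scaled to the locus under study.

    The protocol sets nuclear radius and slice thickness, in units of
    sigma, to match the experimental scales of the system considered.  For
    a full-size ~6-Mb locus model (gyration radius ~0.5 um in a ~4.6 um
    nucleus) the polymer occupies ~0.11 of the nuclear radius; this helper
    reproduces that occupancy ratio for an arbitrary (e.g. toy-scale)
    ensemble, keeping the slice statistics comparable across system sizes.
    """
    from .ensembles import gyration_radius

    mean_rg = float(np.mean([gyration_radius(c) for c in ensemble.coords]))
    return GamGeometry(R=mean_rg / rg_over_r, h=h)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (via random unit quaternion)."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def uniform_in_ball(radius: float, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    v /= np.linalg.norm(v)
    return v * radius * rng.random() ** (1.0 / 3.0)


def bounding_radius(conformation: np.ndarray) -> float:
    """Largest bead distance from the conformation centroid."""
    x = np.asarray(conformation, float)
    return float(np.sqrt(((x - x.mean(axis=0)) ** 2).sum(axis=1).max()))


def place_in_nucleus(
    ensemble: Ensemble,
    cell: CellSample,
    geometry: GamGeometry,
    rng: np.random.Generator,
) -> np.ndarray:
    """Place the two alleles of a cell in the nucleus frame.

    Each allele is centered, uniformly rotated, and its centroid placed
    uniformly in the sub-sphere of radius ``R - bounding_radius`` that
    guarantees full containment.  Returns pooled coordinates of shape
    ``(2 * N_bead, 3)`` (allele A first).
    """
    cell.validate(ensemble)
    placed = []
    for idx in (cell.allele_a, cell.allele_b):
        conf = ensemble.coords[idx]
        centered = conf - conf.mean(axis=0)
        r = float(np.sqrt((centered**2).sum(axis=1).max()))
        if r >= geometry.R:
            raise ValueError(
                f"conformation {idx} (bounding radius {r:.2f}) does not fit in "
                f"a nucleus of radius {geometry.R}; increase R"
            )
        rot = random_rotation(rng)
        center = uniform_in_ball(geometry.R - r, rng)
        placed.append(centered @ rot.T + center)
    return np.vstack(placed)


def cut_slice(
    placed: np.ndarray,
    bin_of_bead: np.ndarray,
    geometry: GamGeometry,
    params: GamParams,
    rng: np.random.Generator,
    cell_id: int = -1,
) -> SliceProfile:
    """Cut one randomly oriented slab through the nucleus.

    The slab normal is uniform on the sphere and the slab center offset is
    uniform in (-R, R) along it; a bead is inside iff its signed projection
    lies within h/2 of the offset.  In-slab beads are detected independently
    with probability ``p_d``; ``positive_bins`` are the bins with at least
    one detected bead (alleles pooled).  Empty profiles are legitimate: most
    slices miss a small locus.
    """
    placed = np.asarray(placed, float)
    bins = np.asarray(bin_of_bead, int)
    if len(bins) != placed.shape[0]:
        raise ValueError("bin_of_bead must cover all pooled beads")
    normal = rng.standard_normal(3)
    normal /= np.linalg.norm(normal)
    offset = rng.uniform(-geometry.R, geometry.R)
    in_slab = np.abs(placed @ normal - offset) <= geometry.h / 2.0
    idx = np.flatnonzero(in_slab)
    if idx.size and params.p_d < 1.0:
        idx = idx[rng.random(idx.size) < params.p_d]
    elif params.p_d == 0.0:
        idx = idx[:0]
    return SliceProfile(positive_bins=np.unique(bins[idx]), cell_id=cell_id)


# ---------------------------------------------------------------------------
# Cosegregation
# ---------------------------------------------------------------------------

def coseg_from_profiles(profiles, n_bin: int, n_slices: int | None = None):
    """Tally slice profiles into cosegregation frequencies.

    Returns ``(p_pair, p_bin)`` where ``p_pair[i, j]`` is the fraction of
    slices with both bins positive (diagonal equals ``p_bin``) and
    ``p_bin[i]`` the fraction of slices with bin i positive.
    """
    if n_slices is None:
        n_slices = len(profiles)
    if n_slices < 1:
        raise ValueError("need at least one slice")
    counts = np.zeros((n_bin, n_bin))
    for prof in profiles:
        pos = prof.positive_bins if isinstance(prof, SliceProfile) else np.asarray(prof)
        if pos.size:
            counts[np.ix_(pos, pos)] += 1.0
    return counts / n_slices, np.diag(counts) / n_slices


class _GamEngine:
    """Lean per-cell GAM simulator used by the high-throughput loops.

    Precomputes centered coordinates and bounding radii; per cell it draws
    the same placement and slab variables as :func:`place_in_nucleus` +
    :func:`cut_slice` but only ever projects beads onto the slab normal.
    """

    def __init__(self, ensemble: Ensemble, geometry: GamGeometry,
                 params: GamParams):
        self.geometry = geometry
        self.params = params
        self.bins = ensemble.bin_of_bead
        self.n_bin = ensemble.n_bin
        means = ensemble.coords.mean(axis=1, keepdims=True)
        self.centered = ensemble.coords - means
        self.radii = np.sqrt((self.centered**2).sum(axis=2).max(axis=1))
        if self.radii.max() >= geometry.R:
            raise ValueError(
                f"largest conformation (radius {self.radii.max():.2f}) does "
                f"not fit in a nucleus of radius {geometry.R}; increase R"
            )

    def positive_bins(self, ia: int, ib: int, rng: np.random.Generator):
        geo, p_d = self.geometry, self.params.p_d
        # placement variables, drawn in the same order as place_in_nucleus
        rots, centers = [], []
        for idx in (ia, ib):
            rots.append(random_rotation(rng))
            centers.append(uniform_in_ball(geo.R - self.radii[idx], rng))
        normal = rng.standard_normal(3)
        normal /= np.linalg.norm(normal)
        offset = rng.uniform(-geo.R, geo.R)
        half = geo.h / 2.0
        pos_parts = []
        for conf_idx, rot, center in zip((ia, ib), rots, centers):
            proj = self.centered[conf_idx] @ (rot.T @ normal) + center @ normal
            idx = np.flatnonzero(np.abs(proj - offset) <= half)
            if idx.size and p_d < 1.0:
                idx = idx[rng.random(idx.size) < p_d]
            elif p_d == 0.0:
                idx = idx[:0]
            pos_parts.append(self.bins[idx])
        if not pos_parts[0].size and not pos_parts[1].size:
            return pos_parts[0]
        return np.unique(np.concatenate(pos_parts))


class GamSimulator:
    """Reusable GAM simulator with the same accumulate/normalize protocol as
    the Hi-C and SPRITE simulators; one slice per in silico cell, maps are
    co-occurrence counts normalized by the number of slices."""

    method = "gam"

    def __init__(self, ensemble: Ensemble, params: GamParams | None = None,
                 geometry: GamGeometry | None = None):
        self.params = params or GamParams()
        self.geometry = geometry or GamGeometry()
        self.engine = _GamEngine(ensemble, self.geometry, self.params)
        self.n_bin = ensemble.n_bin
        self._n_conf = ensemble.n_conformations

    def accumulate_cell(self, counts: np.ndarray, ia: int, ib: int,
                        rng: np.random.Generator) -> None:
        pos = self.engine.positive_bins(ia, ib, rng)
        if pos.size:
            counts[np.ix_(pos, pos)] += 1.0

    def cell_map(self, ia: int, ib: int,
                 rng: np.random.Generator) -> np.ndarray:
        counts = np.zeros((self.n_bin, self.n_bin))
        self.accumulate_cell(counts, ia, ib, rng)
        return counts

    def accumulate(self, counts: np.ndarray, n_cells: int,
                   rng: np.random.Generator) -> None:
        for _ in range(n_cells):
            ia, ib = rng.integers(self._n_conf, size=2)
            self.accumulate_cell(counts, int(ia), int(ib), rng)

    def sample_map(self, n_cells: int, rng: np.random.Generator) -> np.ndarray:
        counts = np.zeros((self.n_bin, self.n_bin))
        self.accumulate(counts, n_cells, rng)
        return counts

    def empty_map(self) -> np.ndarray:
        return np.zeros((self.n_bin, self.n_bin))

    @staticmethod
    def normalize(counts: np.ndarray, n_cells: int) -> np.ndarray:
        """Co-occurrence counts over slices to cosegregation frequencies."""
        return counts / n_cells


def gam_cosegregation(
    ensemble: Ensemble,
    n_slices: int,
    geometry: GamGeometry | None = None,
    params: GamParams | None = None,
    rng: np.random.Generator | int | None = None,
):
    """Run a full in silico GAM experiment: one slice per in silico cell.

    Returns ``(ContactMap, p_bin)`` with cosegregation frequencies (counts
    over slices divided by ``n_slices``; slices that miss the locus still
    count) and per-bin detection frequencies.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    geometry = geometry or GamGeometry()
    params = params or GamParams()
    rng = np.random.default_rng(rng)
    engine = _GamEngine(ensemble, geometry, params)
    n_conf, n_bin = ensemble.n_conformations, ensemble.n_bin
    counts = np.zeros((n_bin, n_bin))
    for _ in range(n_slices):
        ia, ib = rng.integers(n_conf, size=2)
        pos = engine.positive_bins(int(ia), int(ib), rng)
        if pos.size:
            counts[np.ix_(pos, pos)] += 1.0
    p_pair = counts / n_slices
    cmap = ContactMap(
        matrix=p_pair,
        method="gam_coseg",
        n_cells=n_slices,
        params={"R": geometry.R, "h": geometry.h, "p_d": params.p_d},
    )
    return cmap, np.diag(p_pair).copy()


# ---------------------------------------------------------------------------
# NPMI and the efficiency mapping
# ---------------------------------------------------------------------------

def npmi(p_pair: np.ndarray, p_bin: np.ndarray) -> ContactMap:
    """Normalized pointwise mutual information of cosegregation data.

    PMI = log(p(i,j) / (p(i) p(j))), NPMI = -PMI / log p(i,j), bounded in
    [-1, 1].  Pairs with p(i,j) = 0 or p(i) p(j) = 0 are undefined and
    emitted as NaN; p(i,j) = 1 (which forces p(i) = p(j) = 1) is perfect
    co-occurrence and maps to 1.
    """
    p_pair = np.asarray(p_pair, float)
    p_bin = np.asarray(p_bin, float)
    marg = np.outer(p_bin, p_bin)
    out = np.full_like(p_pair, np.nan)
    defined = (p_pair > 0) & (marg > 0)
    strict = defined & (p_pair < 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(p_pair[strict] / marg[strict])
        out[strict] = -pmi / np.log(p_pair[strict])
    out[defined & (p_pair >= 1)] = 1.0
    out = np.clip(out, -1.0, 1.0, where=~np.isnan(out), out=out)
    return ContactMap(matrix=out, method="gam_npmi")


def gam_efficiency(eps: float, n: int) -> float:
    """Map the bead-level GAM efficiency ``eps`` onto the window-level
    (experimental) efficiency for ``n`` beads per bin:

        eps_GAM = 1 - ((1 - eps)/eps) * (1 - (1 - eps)^(2n)) / (2n)

    which averages the window detection probability 1 - (1 - eps)^k over
    the number k of in-slab window beads, uniform on 1..2n (both alleles).
    Monotone increasing in eps and n; eps = 1 maps to 1.  The formula is
    singular at eps = 0, where the limit value 0 is returned.
    """
    if not 0 <= eps <= 1:
        raise ValueError("eps must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    if eps == 0.0:
        return 0.0
    q = 1.0 - eps
    return 1.0 - (q / eps) * (1.0 - q ** (2 * n)) / (2 * n)
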