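"""Polymer conformation ensembles: data model, geometry and file I/O.

An :class:`Ensemble` holds a set of single-molecule 3D conformations of the
same chromatin polymer, expressed in units of the bead diameter ``sigma``,
together with the per-bead binding-site color and the bead-to-genomic-bin
assignment.  Everything downstream (the in silico Hi-C/SPRITE/GAM protocols,
distance matrices, structural matching) operates on this container.

Distances are Euclidean; bead-level distance matrices are coarse-grained to
bin level by averaging all bead-pair distances that fall in the same bin
pair.  Structural comparison uses the minimal RMSD over proper rotations
after centering (Kabsch superposition, reflections excluded to preserve
chirality).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform


class EnsembleFormatError(ValueError):
    """Raised when an on-disk ensemble is malformed."""


class EnsembleValidationError(ValueError):
    """Raised when ensemble components are mutually inconsistent."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Ensemble:
    """A set of single-molecule conformations with colors and genomic binning.

    Parameters
    ----------
    coords
        Array of shape ``(n_conformations, N_bead, 3)``, units of sigma.
    colors
        Integer binding-site type per bead, shape ``(N_bead,)``.
    bin_of_bead
        0-based genomic bin index per bead, shape ``(N_bead,)``; must cover
        ``0..N_bin-1`` without gaps.
    resolution_bp
        Genomic size of one bin in base pairs.
    sigma_nm
        Physical bead diameter in nanometres.
    locus_label
        Free-text locus description, e.g. ``"chr11:109000000-115000000"``.
    """

    coords: np.ndarray
    colors: np.ndarray
    bin_of_bead: np.ndarray
    resolution_bp: int = 40_000
    sigma_nm: float = 38.0
    locus_label: str = "synthetic"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.colors = np.asarray(self.colors, dtype=int)
        self.bin_of_bead = np.asarray(self.bin_of_bead, dtype=int)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise EnsembleValidationError(
                f"coords must be (n_conf, N_bead, 3), got {self.coords.shape}"
            )
        if not np.isfinite(self.coords).all():
            raise EnsembleValidationError("coordinates must be finite")
        n_bead = self.coords.shape[1]
        if self.colors.shape != (n_bead,) or self.bin_of_bead.shape != (n_bead,):
            raise EnsembleValidationError(
                "colors and bin_of_bead must have one entry per bead"
            )
        if (self.colors < 0).any():
            raise EnsembleValidationError("colors must be non-negative")
        bins = self.bin_of_bead
        if bins.min() < 0:
            raise EnsembleValidationError("bin indices must be >= 0")
        n_bin = int(bins.max()) + 1
        present = np.bincount(bins, minlength=n_bin)
        if (present == 0).any():
            missing = int(np.flatnonzero(present == 0)[0])
            raise EnsembleValidationError(
                f"bin_of_bead is not surjective: bin {missing} has no beads"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def n_conformations(self) -> int:
        return self.coords.shape[0]

    @property
    def n_bead(self) -> int:
        return self.coords.shape[1]

    @property
    def n_bin(self) -> int:
        return int(self.bin_of_bead.max()) + 1

    @property
    def n_per_bin(self) -> int:
        """Beads per bin for uniform binning (raises otherwise)."""
        counts = np.bincount(self.bin_of_bead, minlength=self.n_bin)
        if not (counts == counts[0]).all():
            raise EnsembleValidationError("binning is not uniform")
        return int(counts[0])

    @property
    def conformations(self) -> list[np.ndarray]:
        return list(self.coords)

    def validate_bins(self, n_bin_expected: int) -> None:
        if self.n_bin != n_bin_expected:
            raise EnsembleValidationError(
                f"binning covers {self.n_bin} bins, manifest declares "
                f"{n_bin_expected}"
            )


@dataclass(frozen=True)
class CellSample:
    """One in silico cell: two independently sampled conformation indices."""

    allele_a: int
    allele_b: int

    def validate(self, ensemble: Ensemble) -> None:
        n = ensemble.n_conformations
        for idx in (self.allele_a, self.allele_b):
            if not 0 <= idx < n:
                raise EnsembleValidationError(
                    f"conformation index {idx} out of range 0..{n - 1}"
                )


@dataclass
class DistanceMap:
    """Symmetric pairwise-distance matrix, bead- or bin-level, units of sigma."""

    matrix: np.ndarray
    level: str  # "bead" | "bin"
    kind: str = "single_molecule"  # | "ensemble_mean"


@dataclass
class ContactMap:
    """Symmetric N_bin x N_bin matrix produced by one of the protocols.

    ``method`` is one of ``hic`` (integer counts), ``sprite`` (2/n-weighted
    counts), ``gam_raw`` (slice co-occurrence counts), ``gam_coseg``
    (cosegregation frequencies) or ``gam_npmi``.
    """

    matrix: np.ndarray
    method: str
    n_cells: int = 0
    params: dict = field(default_factory=dict)


@dataclass
class MatchResult:
    """One-to-one structural assignment of query conformations to references."""

    assignment: np.ndarray  # assignment[q] = reference index
    rmsd_values: np.ndarray  # per query, same order

    def __post_init__(self) -> None:
        if len(np.unique(self.assignment)) != len(self.assignment):
            raise EnsembleValidationError("assignment must be injective")


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def distance_matrix(conformation: np.ndarray) -> DistanceMap:
    """Bead-level Euclidean distance matrix of one conformation."""
    x = np.asarray(conformation, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"conformation must be (N_bead, 3), got {x.shape}")
    if not np.isfinite(x).all():
        raise ValueError("coordinates must be finite")
    if x.shape[0] == 1:
        return DistanceMap(np.zeros((1, 1)), level="bead")
    return DistanceMap(squareform(pdist(x)), level="bead")


def coarse_grain(dmap: DistanceMap, bin_of_bead: np.ndarray) -> DistanceMap:
    """Average a bead-level distance map over bin pairs.

    Entry (I, J) with I != J is the mean over all bead pairs with bins
    (I, J); the diagonal (I, I) averages over distinct bead pairs within
    bin I (0 for single-bead bins).
    """
    if dmap.level != "bead":
        raise ValueError("coarse_grain expects a bead-level map")
    return DistanceMap(
        _coarse_grain_matrix(dmap.matrix, np.asarray(bin_of_bead, dtype=int)),
        level="bin",
        kind=dmap.kind,
    )


def _coarse_grain_matrix(d: np.ndarray, bins: np.ndarray) -> np.ndarray:
    n_bin = int(bins.max()) + 1
    one_hot = np.zeros((n_bin, len(bins)))
    one_hot[bins, np.arange(len(bins))] = 1.0
    sums = one_hot @ d @ one_hot.T
    counts = np.bincount(bins, minlength=n_bin).astype(float)
    denom = np.outer(counts, counts)
    # diagonal: distinct ordered pairs n*(n-1); D_ii = 0 so sums already
    # exclude the self term
    np.fill_diagonal(denom, counts * (counts - 1))
    out = np.zeros_like(sums)
    np.divide(sums, denom, out=out, where=denom > 0)
    return out


def mean_distance_matrix(ensemble: Ensemble) -> DistanceMap:
    """Ensemble-average bin-level distance matrix."""
    if ensemble.n_conformations == 0:
        raise ValueError("ensemble has no conformations")
    acc = np.zeros((ensemble.n_bin, ensemble.n_bin))
    for conf in ensemble.coords:
        acc += _coarse_grain_matrix(squareform(pdist(conf)), ensemble.bin_of_bead)
    acc /= ensemble.n_conformations
    return DistanceMap(acc, level="bin", kind="ensemble_mean")


def gyration_radius(conformation: np.ndarray) -> float:
    """Root mean squared distance of beads from their centroid."""
    x = np.asarray(conformation, dtype=float)
    if x.shape[0] < 1:
        raise ValueError("need at least one bead")
    centered = x - x.mean(axis=0)
    return float(np.sqrt((centered**2).sum(axis=1).mean()))


def kabsch_rmsd(conf_a: np.ndarray, conf_b: np.ndarray) -> float:
    """Minimal RMSD between two structures over translations and proper
    rotations (Kabsch superposition; reflections excluded)."""
    a = np.asarray(conf_a, dtype=float)
    b = np.asarray(conf_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"bead counts differ: {a.shape} vs {b.shape}")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.ones(3)
    d[-1] = sign
    rot = vt.T @ np.diag(d) @ u.T
    diff = a @ rot.T - b
    return float(np.sqrt((diff**2).sum(axis=1).mean()))


def pairwise_rmsd_matrix(query: Ensemble, reference: Ensemble) -> np.ndarray:
    """All-against-all Kabsch RMSD, shape (n_query, n_reference)."""
    if query.n_bead != reference.n_bead:
        raise ValueError("query and reference must have equal bead counts")
    out = np.empty((query.n_conformations, reference.n_conformations))
    for i, qa in enumerate(query.coords):
        for j, rb in enumerate(reference.coords):
            out[i, j] = kabsch_rmsd(qa, rb)
    return out


def best_match_assignment(
    query: Ensemble,
    reference: Ensemble,
    method: str = "greedy",
    rmsd_matrix: np.ndarray | None = None,
) -> MatchResult:
    """Univocally associate each query structure with a reference structure
    by minimal RMSD.

    ``method="greedy"`` repeatedly takes the global minimum among unassigned
    pairs (the default); ``method="optimal"`` solves the bipartite assignment
    problem minimizing the total RMSD.
    """
    if rmsd_matrix is None:
        rmsd_matrix = pairwise_rmsd_matrix(query, reference)
    r = np.asarray(rmsd_matrix, dtype=float)
    nq, nr = r.shape
    if nq > nr:
        raise ValueError(
            f"query ({nq}) larger than reference ({nr}); cannot assign injectively"
        )
    if method == "optimal":
        from scipy.optimize import linear_sum_assignment

        rows, cols = linear_sum_assignment(r)
        assignment = np.empty(nq, dtype=int)
        assignment[rows] = cols
    elif method == "greedy":
        work = r.copy()
        assignment = np.full(nq, -1, dtype=int)
        for _ in range(nq):
            i, j = np.unravel_index(np.argmin(work), work.shape)
            assignment[i] = j
            work[i, :] = np.inf
            work[:, j] = np.inf
    else:
        raise ValueError(f"unknown method {method!r}")
    return MatchResult(assignment=assignment,
                       rmsd_values=r[np.arange(nq), assignment])


def fraction_below_first_tertile(values_a, values_b) -> float:
    """Share of ``values_a`` strictly below the first tertile of ``values_b``.

    The tertile is the 33.33rd percentile computed with linear interpolation
    between order statistics.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("inputs must be nonempty")
    tertile = np.percentile(b, 100.0 / 3.0)
    return float(np.mean(a < tertile))


# ---------------------------------------------------------------------------
# File I/O: multi-frame XYZ + TSV sidecar + JSON manifest
# ---------------------------------------------------------------------------

def save_ensemble(
    ensemble: Ensemble,
    coords_path: str | Path,
    sidecar_path: str | Path,
    manifest_path: str | Path,
) -> None:
    """Write an ensemble as multi-frame XYZ + sidecar TSV + JSON manifest.

    Coordinates are written with full round-trip precision so that
    ``load_ensemble`` reproduces them bit-exactly.
    """
    with open(coords_path, "w") as fh:
        for frame, conf in enumerate(ensemble.coords):
            fh.write(f"{ensemble.n_bead}\n")
            fh.write(f"conformation {frame}\n")
            for x, y, z in conf:
                fh.write(f"B {float(x)!r} {float(y)!r} {float(z)!r}\n")
    with open(sidecar_path, "w") as fh:
        fh.write("bead\tcolor\tbin\n")
        for i in range(ensemble.n_bead):
            fh.write(f"{i}\t{ensemble.colors[i]}\t{ensemble.bin_of_bead[i]}\n")
    manifest = {
        "locus": ensemble.locus_label,
        "resolution_bp": int(ensemble.resolution_bp),
        "sigma_nm": float(ensemble.sigma_nm),
        "N_bin": int(ensemble.n_bin),
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")


def load_ensemble(
    coords_path: str | Path,
    sidecar_path: str | Path,
    manifest_path: str | Path,
) -> Ensemble:
    """Load an ensemble written by :func:`save_ensemble` (deterministic
    frame order; validation against the manifest)."""
    frames = _read_multiframe_xyz(coords_path)
    beads, colors, bins = _read_sidecar(sidecar_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    n_bead = frames.shape[1]
    if len(beads) != n_bead:
        raise EnsembleFormatError(
            f"sidecar has {len(beads)} rows but frames have {n_bead} beads"
        )
    if not np.array_equal(beads, np.arange(n_bead)):
        raise EnsembleFormatError("sidecar bead indices must be 0..N_bead-1 in order")
    n_bin = int(manifest["N_bin"])
    if bins.max() >= n_bin:
        raise EnsembleValidationError(
            f"sidecar bin index {int(bins.max())} exceeds manifest N_bin={n_bin}"
        )
    ens = Ensemble(
        coords=frames,
        colors=colors,
        bin_of_bead=bins,
        resolution_bp=int(manifest["resolution_bp"]),
        sigma_nm=float(manifest["sigma_nm"]),
        locus_label=str(manifest["locus"]),
    )
    ens.validate_bins(n_bin)
    return ens


def _read_multiframe_xyz(path: str | Path) -> np.ndarray:
    frames: list[np.ndarray] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise EnsembleFormatError(
                f"{path}: expected bead count at line {i + 1}"
            ) from exc
        if i + 1 + n >= len(lines) + 1:
            raise EnsembleFormatError(f"{path}: truncated frame at line {i + 1}")
        block = lines[i + 2 : i + 2 + n]
        if len(block) != n:
            raise EnsembleFormatError(f"{path}: truncated frame at line {i + 1}")
        coords = np.empty((n, 3))
        for k, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise EnsembleFormatError(
                    f"{path}: malformed atom line {i + 3 + k}"
                )
            coords[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise EnsembleFormatError(f"{path}: no frames found")
    counts = {f.shape[0] for f in frames}
    if len(counts) > 1:
        raise EnsembleFormatError(
            f"{path}: frames disagree on bead count: {sorted(counts)}"
        )
    return np.stack(frames)


def _read_sidecar(path: str | Path):
    rows = np.loadtxt(path, skiprows=1, dtype=int, ndmin=2)
    if rows.shape[1] != 3:
        raise EnsembleFormatError(f"{path}: expected columns bead, color, bin")
    return rows[:, 0], rows[:, 1], rows[:, 2]


# ---------------------------------------------------------------------------
# Matrix and BED I/O
# ---------------------------------------------------------------------------

def write_dense_tsv(matrix: np.ndarray, path: str | Path,
                    provenance: dict | None = None) -> None:
    """Dense TSV matrix with a '#'-prefixed provenance comment block."""
    with open(path, "w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}\t{value}\n")
        for row in np.asarray(matrix):
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_dense_tsv(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, comments="#", ndmin=2)


def write_triplet(matrix: np.ndarray, path: str | Path,
                  provenance: dict | None = None) -> None:
    """Sparse upper-triangle 'i<TAB>j<TAB>value' text with shape header."""
    m = np.asarray(matrix)
    with open(path, "w") as fh:
        fh.write(f"# shape\t{m.shape[0]}\n")
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}\t{value}\n")
        ii, jj = np.nonzero(np.triu(m))
        for i, j in zip(ii, jj):
            fh.write(f"{i}\t{j}\t{float(m[i, j])!r}\n")


def read_triplet(path: str | Path) -> np.ndarray:
    n = None
    entries = []
    with open(path) as fh:
        for ln in fh:
            if ln.startswith("#"):
                parts = ln[1:].split()
                if parts and parts[0] == "shape":
                    n = int(parts[1])
                continue
            i, j, v = ln.split()
            entries.append((int(i), int(j), float(v)))
    if n is None:
        raise EnsembleFormatError(f"{path}: missing '# shape' header")
    out = np.zeros((n, n))
    for i, j, v in entries:
        out[i, j] = v
        out[j, i] = v
    return out


_LOCUS_RE = re.compile(r"^(?P<chrom>[^:\s]+):(?P<start>\d+)-(?P<end>\d+)$")


def write_bins_bed(ensemble: Ensemble, path: str | Path) -> None:
    """0-based half-open BED of bin coordinates.

    If ``locus_label`` parses as ``chrom:start-end`` the bins are offset
    accordingly; otherwise the label is used as the chromosome name with
    bins starting at 0.
    """
    m = _LOCUS_RE.match(ensemble.locus_label)
    chrom = m.group("chrom") if m else ensemble.locus_label.replace(" ", "_")
    offset = int(m.group("start")) if m else 0
    res = ensemble.resolution_bp
    with open(path, "w") as fh:
        for b in range(ensemble.n_bin):
            fh.write(f"{chrom}\t{offset + b * res}\t{offset + (b + 1) * res}\tbin_{b}\n")
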