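"""Similarity statistics between contact/distance maps.

Implements the four map-comparison statistics used throughout the
benchmark — Pearson r, Spearman r_s, the genomic-distance-corrected Pearson
r' (per-diagonal means removed from each matrix before correlating, which
cancels the average distance-decay trend shared by all chromatin maps), and
a stratum-adjusted correlation coefficient (scc) in the spirit of HiCRep:
both maps are mean-filter smoothed, entries are stratified by genomic
distance |i - j|, and the per-stratum Pearson correlations are combined
with weights N_k * s_Ak * s_Bk — plus a bootstrap null for scc and the
Mann-Whitney U test used for RMSD distribution comparisons.

Conventions: the default mask is the off-diagonal upper triangle (the main
diagonal is trivially self-similar); undefined entries (NaN, e.g. NPMI of
never-cosegregating pairs) are dropped pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats


class DegenerateCorrelationError(ValueError):
    """Raised when a correlation is undefined (constant input, no data)."""


@dataclass
class CorrelationResult:
    statistic: str  # "r" | "r_s" | "r_prime" | "scc"
    value: float
    n_entries: int
    mask: str


@dataclass
class BootstrapNull:
    """Null scc distribution from distance-preserving bootstrap."""

    null_values: np.ndarray  # sorted
    percentile_90: float


def _as_matrix(m) -> np.ndarray:
    m = np.asarray(getattr(m, "matrix", m), dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square matrix")
    return m


def _masked_entries(a: np.ndarray, b: np.ndarray, mask: str):
    if a.shape != b.shape:
        raise ValueError("maps must have equal shape")
    if mask == "offdiag-upper":
        iu = np.triu_indices(a.shape[0], k=1)
        va, vb = a[iu], b[iu]
    elif mask == "all-upper":
        iu = np.triu_indices(a.shape[0], k=0)
        va, vb = a[iu], b[iu]
    else:
        raise ValueError(f"unknown mask {mask!r}")
    ok = np.isfinite(va) & np.isfinite(vb)
    return va[ok], vb[ok]


def correlate(map_a, map_b, method: str = "pearson",
              mask: str = "offdiag-upper") -> CorrelationResult:
    """Pearson or Spearman correlation over masked matrix entries.

    Spearman uses average ranks for ties.  Raises
    :class:`DegenerateCorrelationError` on constant input or fewer than 3
    usable entries.
    """
    a, b = _masked_entries(_as_matrix(map_a), _as_matrix(map_b), mask)
    if a.size < 3:
        raise DegenerateCorrelationError("fewer than 3 masked entries")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateCorrelationError("constant input, correlation undefined")
    if method == "pearson":
        value = stats.pearsonr(a, b).statistic
        name = "r"
    elif method == "spearman":
        value = stats.spearmanr(a, b).statistic
        name = "r_s"
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(name, float(value), int(a.size), mask)


def _subtract_diagonal_means(m: np.ndarray) -> np.ndarray:
    n = m.shape[0]
    out = m.copy()
    idx = np.arange(n)
    offsets = idx[None, :] - idx[:, None]
    for k in range(-(n - 1), n):
        sel = offsets == k
        vals = out[sel]
        good = np.isfinite(vals)
        if good.any():
            out[sel] = vals - vals[good].mean()
    return out


def distance_corrected_pearson(map_a, map_b,
                               mask: str = "offdiag-upper") -> CorrelationResult:
    """Genomic-distance-corrected Pearson r': each matrix first has the mean
    of every diagonal subtracted (removing the average effect of genomic
    separation), then the residuals are correlated."""
    ra = _subtract_diagonal_means(_as_matrix(map_a))
    rb = _subtract_diagonal_means(_as_matrix(map_b))
    a, b = _masked_entries(ra, rb, mask)
    if a.size < 3:
        raise DegenerateCorrelationError("fewer than 3 masked entries")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateCorrelationError("constant residuals, r' undefined")
    return CorrelationResult("r_prime", float(stats.pearsonr(a, b).statistic),
                             int(a.size), mask)


# ---------------------------------------------------------------------------
# Stratum-adjusted correlation (HiCRep-style)
# ---------------------------------------------------------------------------

def _smooth(m: np.ndarray, h: int) -> np.ndarray:
    """(2h+1)^2 mean filter; edges and NaNs average over available entries."""
    if h == 0:
        return m
    finite = np.isfinite(m)
    filled = np.where(finite, m, 0.0)
    size = 2 * h + 1
    num = ndimage.uniform_filter(filled, size=size, mode="constant")
    den = ndimage.uniform_filter(finite.astype(float), size=size,
                                 mode="constant")
    out = np.full_like(m, np.nan)
    np.divide(num, den, out=out, where=den > 0)
    out[~finite] = np.nan
    return out


def scc(map_a, map_b, smooth_half_width: int = 1,
        max_distance_bins: int | None = None) -> CorrelationResult:
    """Stratum-adjusted correlation coefficient.

    Both maps are smoothed with a (2h+1)^2 mean filter, entries are
    stratified by |i - j| from 1 up to ``max_distance_bins`` (default half
    the matrix size), and scc = sum_k w_k rho_k / sum_k w_k with rho_k the
    per-stratum Pearson correlation and w_k = N_k * s_Ak * s_Bk (population
    standard deviations).  Zero-variance strata are skipped.
    """
    a = _smooth(_as_matrix(map_a), smooth_half_width)
    b = _smooth(_as_matrix(map_b), smooth_half_width)
    if a.shape != b.shape:
        raise ValueError("maps must have equal shape")
    n = a.shape[0]
    if max_distance_bins is None:
        max_distance_bins = max(1, n // 2)
    num = den = 0.0
    n_used = 0
    for k in range(1, min(max_distance_bins, n - 1) + 1):
        va = np.diagonal(a, offset=k)
        vb = np.diagonal(b, offset=k)
        ok = np.isfinite(va) & np.isfinite(vb)
        va, vb = va[ok], vb[ok]
        if va.size < 2:
            continue
        s_a, s_b = va.std(), vb.std()
        if s_a == 0 or s_b == 0:
            continue
        rho = float(np.corrcoef(va, vb)[0, 1])
        w = va.size * s_a * s_b
        num += w * rho
        den += w
        n_used += va.size
    if den == 0:
        raise DegenerateCorrelationError("all strata degenerate, scc undefined")
    return CorrelationResult("scc", num / den, n_used,
                             f"strata 1..{max_distance_bins}")


def scc_bootstrap_null(map_a, map_b, n_boot: int = 100,
                       rng: np.random.Generator | int | None = None,
                       smooth_half_width: int = 1,
                       max_distance_bins: int | None = None) -> BootstrapNull:
    """Distance-preserving bootstrap null for scc.

    For each of ``n_boot`` draws, every diagonal of each matrix is resampled
    with replacement within itself (independently for the two maps),
    destroying positional structure while keeping the distance-decay
    profile; scc is computed on each randomized pair.
    """
    a = _as_matrix(map_a)
    b = _as_matrix(map_b)
    rng = np.random.default_rng(rng)
    nulls = np.empty(n_boot)
    for t in range(n_boot):
        ra = _bootstrap_diagonals(a, rng)
        rb = _bootstrap_diagonals(b, rng)
        nulls[t] = scc(ra, rb, smooth_half_width, max_distance_bins).value
    nulls.sort()
    return BootstrapNull(null_values=nulls,
                         percentile_90=float(np.percentile(nulls, 90)))


def _bootstrap_diagonals(m: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = m.shape[0]
    out = np.empty_like(m)
    idx = np.arange(n)
    out[idx, idx] = m[idx, idx]
    for k in range(1, n):
        rows = idx[: n - k]
        cols = rows + k
        vals = m[rows, cols]
        pick = vals[rng.integers(vals.size, size=vals.size)]
        out[rows, cols] = pick
        out[cols, rows] = pick
    return out


def mann_whitney_u(values_a, values_b):
    """Two-sided Mann-Whitney U test (rank sum with tie correction).

    Exact enumeration for small tie-free samples (both n < 20), normal
    approximation otherwise.  Returns (U statistic of the first sample,
    two-sided p value).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if a.size < 20 and b.size < 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
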