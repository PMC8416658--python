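"""Shared independent oracles for the test suite."""

import numpy as np

from silicomap.ensembles import Ensemble


def grid_search_rmsd(a, b):
    """Minimal RMSD over proper rotations by exhaustive grid search:
    a 6-degree Euler scan followed by 2- and 0.5-degree local refinements
    around the best cell (vectorized over rotation batches)."""
    from scipy.spatial.transform import Rotation

    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)

    def batch_rmsd(angles):
        rots = Rotation.from_euler("zyz", angles, degrees=True)
        rotated = np.einsum("rij,nj->rni", rots.as_matrix(), ac)
        return np.sqrt(((rotated - bc) ** 2).sum(axis=2).mean(axis=1))

    def scan(grid1, grid2, grid3):
        angles = np.array(np.meshgrid(grid1, grid2, grid3,
                                      indexing="ij")).reshape(3, -1).T
        rmsds = batch_rmsd(angles)
        k = int(np.argmin(rmsds))
        return float(rmsds[k]), angles[k]

    best, center = scan(np.arange(0, 360, 6.0), np.arange(0, 180.01, 6.0),
                        np.arange(0, 360, 6.0))
    for step in (2.0, 0.5):
        grids = [np.arange(c - 4 * step, c + 4.001 * step, step)
                 for c in center]
        cand, cand_center = scan(*grids)
        if cand < best:
            best, center = cand, cand_center
    return best


def chain_cluster_ensemble(n):
    """Conformation 0: n beads on a line at unit spacing (one single-linkage
    cluster spanning n distinct bins); conformation 1: spread far apart."""
    line = np.arange(n)[:, None] * np.array([1.0, 0.0, 0.0])
    far = np.arange(n)[:, None] * np.array([30.0, 0.0, 0.0])
    return Ensemble(coords=np.stack([line, far]),
                    colors=np.zeros(n, int), bin_of_bead=np.arange(n))
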