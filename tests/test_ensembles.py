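"""Core data model: distance maps, coarse-graining, geometry, matching, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

import silicomap as sm
from silicomap.ensembles import (
    EnsembleFormatError,
    EnsembleValidationError,
    _coarse_grain_matrix,
)

settings.register_profile("suite", deadline=None, max_examples=25,
                          derandomize=True)
settings.load_profile("suite")

coords_strategy = arrays(
    float, st.tuples(st.integers(2, 12), st.just(3)),
    elements=st.floats(-50, 50, allow_nan=False),
)


def random_conf(n, rng):
    return rng.standard_normal((n, 3)) * 3.0


# ---------------------------------------------------------------------------
# Construction and I/O
# ---------------------------------------------------------------------------

class TestEnsembleModel:
    def test_construction_counts(self, rng):
        ens = sm.Ensemble(
            coords=rng.standard_normal((2, 6, 3)),
            colors=np.zeros(6, int),
            bin_of_bead=np.array([0, 0, 1, 1, 2, 2]),
        )
        assert ens.n_conformations == 2
        assert ens.n_bead == 6
        assert ens.n_bin == 3
        assert ens.n_per_bin == 2

    def test_non_surjective_binning_rejected(self, rng):
        with pytest.raises(EnsembleValidationError):
            sm.Ensemble(
                coords=rng.standard_normal((1, 4, 3)),
                colors=np.zeros(4, int),
                bin_of_bead=np.array([0, 0, 2, 2]),  # bin 1 empty
            )

    def test_nonfinite_coordinates_rejected(self):
        coords = np.zeros((1, 3, 3))
        coords[0, 1, 2] = np.nan
        with pytest.raises(EnsembleValidationError):
            sm.Ensemble(coords=coords, colors=np.zeros(3, int),
                        bin_of_bead=np.arange(3))

    def test_round_trip_is_bit_exact(self, tmp_path, rng):
        ens = sm.Ensemble(
            coords=rng.standard_normal((3, 6, 3)) * 7.3,
            colors=np.array([0, 0, 1, 1, 2, 2]),
            bin_of_bead=np.array([0, 0, 1, 1, 2, 2]),
            locus_label="chr1:1000000-1240000",
        )
        paths = [tmp_path / n for n in ("e.xyz", "e.beads.tsv", "e.json")]
        sm.save_ensemble(ens, *paths)
        back = sm.load_ensemble(*paths)
        assert np.array_equal(back.coords, ens.coords)
        assert np.array_equal(back.colors, ens.colors)
        assert np.array_equal(back.bin_of_bead, ens.bin_of_bead)
        assert back.resolution_bp == ens.resolution_bp

    def test_bin_index_exceeding_manifest_rejected(self, tmp_path, rng):
        ens = sm.Ensemble(
            coords=rng.standard_normal((1, 4, 3)),
            colors=np.zeros(4, int),
            bin_of_bead=np.array([0, 1, 2, 5 - 2]),
        )
        paths = [tmp_path / n for n in ("e.xyz", "e.beads.tsv", "e.json")]
        sm.save_ensemble(ens, *paths)
        manifest = paths[2]
        manifest.write_text(
            manifest.read_text().replace('"N_bin": 4', '"N_bin": 3')
        )
        with pytest.raises(EnsembleValidationError):
            sm.load_ensemble(*paths)

    def test_mismatched_sidecar_rejected(self, tmp_path, rng):
        ens = sm.Ensemble(coords=rng.standard_normal((1, 4, 3)),
                          colors=np.zeros(4, int), bin_of_bead=np.arange(4))
        paths = [tmp_path / n for n in ("e.xyz", "e.beads.tsv", "e.json")]
        sm.save_ensemble(ens, *paths)
        lines = paths[1].read_text().splitlines()
        paths[1].write_text("\n".join(lines[:-1]) + "\n")  # drop one bead
        with pytest.raises(EnsembleFormatError):
            sm.load_ensemble(*paths)

    def test_matrix_io_round_trips(self, tmp_path, rng):
        m = rng.random((5, 5))
        m = m + m.T
        sm.write_dense_tsv(m, tmp_path / "m.tsv", {"seed": 1})
        assert np.array_equal(sm.read_dense_tsv(tmp_path / "m.tsv"), m)
        sm.write_triplet(m, tmp_path / "m.trip.tsv")
        assert np.allclose(sm.read_triplet(tmp_path / "m.trip.tsv"), m)

    def test_bed_export_offsets_by_locus_start(self, tmp_path, rng):
        ens = sm.Ensemble(coords=rng.standard_normal((1, 4, 3)),
                          colors=np.zeros(4, int),
                          bin_of_bead=np.array([0, 0, 1, 1]),
                          resolution_bp=40_000,
                          locus_label="chr11:109000000-109080000")
        sm.write_bins_bed(ens, tmp_path / "bins.bed")
        rows = (tmp_path / "bins.bed").read_text().splitlines()
        assert rows[0].split("\t") == ["chr11", "109000000", "109040000",
                                       "bin_0"]
        assert rows[1].split("\t") == ["chr11", "109040000", "109080000",
                                       "bin_1"]


# ---------------------------------------------------------------------------
# Distance maps and coarse-graining
# ---------------------------------------------------------------------------

class TestDistanceMaps:
    def test_three_four_five(self):
        d = sm.distance_matrix(np.array([[0, 0, 0], [3, 4, 0]], float))
        assert d.matrix[0, 1] == pytest.approx(5.0)

    def test_single_bead_is_zero(self):
        assert sm.distance_matrix(np.zeros((1, 3))).matrix.shape == (1, 1)

    def test_matches_pairwise_loop_oracle(self, rng):
        x = random_conf(10, rng)
        got = sm.distance_matrix(x).matrix
        expected = np.zeros((10, 10))
        for i in range(10):
            for j in range(10):
                expected[i, j] = np.sqrt(((x[i] - x[j]) ** 2).sum())
        assert np.allclose(got, expected)

    @given(coords_strategy)
    def test_symmetric_zero_diagonal(self, x):
        m = sm.distance_matrix(x).matrix
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0)
        assert (m >= 0).all()

    def test_coarse_grain_identity_for_single_bead_bins(self, rng):
        x = random_conf(2, rng)
        bead = sm.distance_matrix(x)
        binned = sm.coarse_grain(bead, np.array([0, 1]))
        assert np.allclose(binned.matrix, bead.matrix)

    def test_coarse_grain_diagonal_uses_distinct_pairs(self):
        x = np.array([[0, 0, 0], [2, 0, 0]], float)
        binned = sm.coarse_grain(sm.distance_matrix(x), np.array([0, 0]))
        assert binned.matrix[0, 0] == pytest.approx(2.0)

    def test_coarse_grain_matches_enumeration(self, rng):
        x = random_conf(4, rng)
        bins = np.array([0, 0, 1, 1])
        got = sm.coarse_grain(sm.distance_matrix(x), bins).matrix
        d = sm.distance_matrix(x).matrix
        assert got[0, 1] == pytest.approx(
            np.mean([d[0, 2], d[0, 3], d[1, 2], d[1, 3]]))
        assert got[0, 0] == pytest.approx(d[0, 1])
        assert got[1, 1] == pytest.approx(d[2, 3])

    def test_mean_distance_matches_accumulation_oracle(self, rng):
        coords = np.stack([random_conf(9, rng) for _ in range(10)])
        bins = np.arange(9) // 3
        ens = sm.Ensemble(coords=coords, colors=np.zeros(9, int),
                          bin_of_bead=bins)
        got = sm.mean_distance_matrix(ens).matrix
        acc = np.zeros((3, 3))
        for conf in coords:
            acc += _coarse_grain_matrix(sm.distance_matrix(conf).matrix, bins)
        assert np.allclose(got, acc / 10)

    def test_identical_conformations_mean_equals_single(self, rng):
        conf = random_conf(6, rng)
        ens = sm.Ensemble(coords=np.stack([conf, conf]),
                          colors=np.zeros(6, int),
                          bin_of_bead=np.arange(6) // 2)
        single = sm.coarse_grain(sm.distance_matrix(conf),
                                 ens.bin_of_bead).matrix
        assert np.allclose(sm.mean_distance_matrix(ens).matrix, single)

    def test_coarse_grain_commutes_with_ensemble_mean(self, rng):
        # linearity: mean of coarse-grained == coarse-grained of bead-mean
        coords = np.stack([random_conf(8, rng) for _ in range(5)])
        bins = np.arange(8) // 2
        per_conf = np.mean(
            [_coarse_grain_matrix(sm.distance_matrix(c).matrix, bins)
             for c in coords], axis=0)
        bead_mean = np.mean(
            [sm.distance_matrix(c).matrix for c in coords], axis=0)
        assert np.allclose(per_conf, _coarse_grain_matrix(bead_mean, bins))


# ---------------------------------------------------------------------------
# Gyration radius and Kabsch RMSD
# ---------------------------------------------------------------------------

def random_rotation_matrix(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


class TestGeometry:
    def test_gyration_trivial_cases(self):
        assert sm.gyration_radius(np.zeros((5, 3))) == 0.0
        two = np.array([[0, 0, 0], [2, 0, 0]], float)
        assert sm.gyration_radius(two) == pytest.approx(1.0)

    def test_gyration_matches_definition_oracle(self, rng):
        x = random_conf(20, rng)
        centroid = x.mean(axis=0)
        expected = np.sqrt(np.mean([((p - centroid) ** 2).sum() for p in x]))
        assert sm.gyration_radius(x) == pytest.approx(expected)

    @given(st.floats(0.1, 10.0))
    def test_gyration_scales_linearly(self, c):
        x = np.random.default_rng(5).standard_normal((12, 3))
        assert sm.gyration_radius(c * x) == pytest.approx(
            c * sm.gyration_radius(x))

    def test_kabsch_identical_is_zero(self, rng):
        x = random_conf(8, rng)
        assert sm.kabsch_rmsd(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_kabsch_rigid_motion_invariance(self, rng):
        x = random_conf(15, rng)
        moved = x @ random_rotation_matrix(rng).T + np.array([5.0, -2.0, 9.0])
        assert sm.kabsch_rmsd(x, moved) == pytest.approx(0.0, abs=1e-9)
        y = random_conf(15, rng)
        r1 = sm.kabsch_rmsd(x, y)
        assert sm.kabsch_rmsd(y, x) == pytest.approx(r1, abs=1e-9)
        assert sm.kabsch_rmsd(
            x @ random_rotation_matrix(rng).T + 3.0, y
        ) == pytest.approx(r1, abs=1e-9)

    def test_kabsch_unequal_lengths_rejected(self, rng):
        with pytest.raises(ValueError):
            sm.kabsch_rmsd(random_conf(4, rng), random_conf(5, rng))

    def test_kabsch_matches_rotation_grid_oracle(self, rng):
        from tests_support_grid import grid_search_rmsd

        a = random_conf(4, rng)
        b = random_conf(4, rng)
        got = sm.kabsch_rmsd(a, b)
        assert grid_search_rmsd(a, b) == pytest.approx(got, abs=1e-3)

    def test_kabsch_agrees_with_scipy_alignment(self, rng):
        from scipy.spatial.transform import Rotation

        a = random_conf(9, rng)
        b = random_conf(9, rng)
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        rot, _ = Rotation.align_vectors(bc, ac)
        expected = np.sqrt(((rot.apply(ac) - bc) ** 2).sum(axis=1).mean())
        assert sm.kabsch_rmsd(a, b) == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# Structural best-match assignment and tertile statistic
# ---------------------------------------------------------------------------

class TestBestMatch:
    def _mini_ensemble(self, coords):
        n = coords.shape[1]
        return sm.Ensemble(coords=coords, colors=np.zeros(n, int),
                           bin_of_bead=np.arange(n))

    def test_permuted_copy_matches_itself(self, rng):
        confs = np.stack([random_conf(6, rng) for _ in range(4)])
        perm = np.array([2, 0, 3, 1])
        query = self._mini_ensemble(confs)
        reference = self._mini_ensemble(confs[perm])
        res = sm.best_match_assignment(query, reference)
        assert np.allclose(res.rmsd_values, 0.0, atol=1e-9)
        assert np.array_equal(perm[res.assignment], np.arange(4))

    def test_greedy_on_hand_enumerated_matrix(self):
        r = np.array([[1.0, 2, 3], [2, 1, 3], [3, 3, 1]])
        query = self._mini_ensemble(np.zeros((3, 2, 3)))
        reference = self._mini_ensemble(np.zeros((3, 2, 3)))
        res = sm.best_match_assignment(query, reference, rmsd_matrix=r)
        assert np.array_equal(res.assignment, [0, 1, 2])

    def test_single_query_takes_argmin(self, rng):
        refs = np.stack([random_conf(5, rng) for _ in range(5)])
        query = self._mini_ensemble(refs[3:4] + 1e-8)
        res = sm.best_match_assignment(query, self._mini_ensemble(refs))
        assert res.assignment[0] == 3

    def test_query_larger_than_reference_rejected(self, rng):
        q = self._mini_ensemble(np.stack([random_conf(4, rng)
                                          for _ in range(3)]))
        r = self._mini_ensemble(np.stack([random_conf(4, rng)
                                          for _ in range(2)]))
        with pytest.raises(ValueError):
            sm.best_match_assignment(q, r)

    def test_optimal_never_worse_in_total(self, rng):
        rm = rng.random((5, 8))
        q = self._mini_ensemble(np.zeros((5, 2, 3)))
        r = self._mini_ensemble(np.zeros((8, 2, 3)))
        greedy = sm.best_match_assignment(q, r, rmsd_matrix=rm)
        optimal = sm.best_match_assignment(q, r, method="optimal",
                                           rmsd_matrix=rm)
        assert optimal.rmsd_values.sum() <= greedy.rmsd_values.sum() + 1e-12


class TestTertileFraction:
    def test_all_below_gives_one(self):
        assert sm.fraction_below_first_tertile([1, 2], [10, 20, 30]) == 1.0

    def test_same_continuous_sample_near_third(self, rng):
        x = rng.random(3000)
        assert sm.fraction_below_first_tertile(x, x) == pytest.approx(
            1 / 3, abs=0.02)

    def test_hand_computed_example(self):
        # 33.33rd percentile of [3, 6, 9] by linear interpolation is 5.0;
        # 1 and 2 fall below it, 10 does not.
        assert sm.fraction_below_first_tertile(
            [1, 2, 10], [3, 6, 9]) == pytest.approx(2 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sm.fraction_below_first_tertile([], [1.0])
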