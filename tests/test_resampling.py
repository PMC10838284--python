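import numpy as np
import pytest

from radbench import (
    ConfigError,
    FeatureTable,
    ResamplerSpec,
    all_knn,
    edited_nn,
    random_oversample,
    random_undersample,
    resample,
    resampler_grid,
    smote,
    svm_smote,
    tomek_links,
)

from .conftest import make_table, random_imbalanced_table
from .oracles import (
    all_knn_kept_oracle,
    enn_removals_oracle,
    majority_label,
    tomek_removals_oracle,
)


def counts(table: FeatureTable) -> tuple[int, int]:
    return table.n_pos, table.n_neg


class TestDispatcher:
    def test_none_is_identity(self, imbalanced_table):
        res = resample(imbalanced_table, ResamplerSpec("none"))
        np.testing.assert_array_equal(res.table.X, imbalanced_table.X)
        assert res.n_synthetic == 0
        assert list(res.kept_indices) == list(range(imbalanced_table.n))

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigError):
            ResamplerSpec("adasyn")

    def test_k_validation(self):
        with pytest.raises(ConfigError):
            ResamplerSpec("smote", k=4)
        with pytest.raises(ConfigError):
            ResamplerSpec("tomek", k=3)
        with pytest.raises(ConfigError):
            ResamplerSpec("enn", k=5)

    def test_smote_tomek_equals_tomek_after_smote(self, imbalanced_table):
        combined = resample(imbalanced_table, ResamplerSpec("smote_tomek", k=3, seed=5))
        stage1 = smote(imbalanced_table, k=3, seed=5)
        stage2 = tomek_links(stage1.table)
        np.testing.assert_array_equal(combined.table.X, stage2.table.X)
        np.testing.assert_array_equal(combined.table.y, stage2.table.y)

    def test_grid_has_19_method_variants(self):
        grid = resampler_grid()
        assert len(grid) == 19
        assert len({s.label for s in grid}) == 19


class TestRandomResamplers:
    def test_undersample_equalizes_with_originals_only(self, imbalanced_table):
        res = random_undersample(imbalanced_table, seed=1)
        assert counts(res.table) == (10, 10)
        assert res.n_synthetic == 0
        assert set(res.table.sample_ids) <= set(imbalanced_table.sample_ids)

    def test_oversample_duplicates_minority(self, imbalanced_table):
        res = random_oversample(imbalanced_table, seed=1)
        assert counts(res.table) == (30, 30)
        assert res.n_synthetic == 20
        minority_rows = imbalanced_table.X[imbalanced_table.y == 1]
        for row in res.table.X[res.table.y == 1][-20:]:
            assert any(np.array_equal(row, m) for m in minority_rows)

    def test_balanced_input_untouched(self, rng):
        t = make_table(rng.normal(size=(20, 3)), [0] * 10 + [1] * 10)
        for fn in (random_undersample, random_oversample):
            res = fn(t, seed=3)
            np.testing.assert_array_equal(res.table.X, t.X)

    def test_determinism(self, imbalanced_table):
        a = random_undersample(imbalanced_table, seed=7)
        b = random_undersample(imbalanced_table, seed=7)
        np.testing.assert_array_equal(a.kept_indices, b.kept_indices)


class TestSmote:
    def test_counts_and_synthetic_total(self, imbalanced_table):
        res = smote(imbalanced_table, k=5, seed=2)
        assert counts(res.table) == (30, 30)
        assert res.n_synthetic == 20

    def test_two_point_minority_generates_on_segment(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]] + [[10 + i, 0] for i in range(4)])
        t = make_table(X, [1, 1, 0, 0, 0, 0])
        res = smote(t, k=3, seed=0)
        synth = res.table.X[len(t.X):]
        for p in synth:
            assert p[0] == pytest.approx(p[1], abs=1e-12)  # on the diagonal
            assert -1e-12 <= p[0] <= 1 + 1e-12

    def test_synthetics_lie_on_minority_segments(self, rng):
        """Every synthetic point is x + u (x' - x) for two minority originals."""
        for trial in range(10):
            t = random_imbalanced_table(rng, n_min=6, n_maj=14, d=3)
            res = smote(t, k=3, seed=trial)
            minority = t.X[t.y == majority_label(t.y) ^ 1]
            for p in res.table.X[t.n:]:
                best = np.inf
                for i in range(len(minority)):
                    for j in range(len(minority)):
                        if i == j:
                            continue
                        a, b = minority[i], minority[j]
                        ab = b - a
                        u = np.dot(p - a, ab) / np.dot(ab, ab)
                        if -1e-9 <= u <= 1 + 1e-9:
                            best = min(best, np.linalg.norm(p - (a + u * ab)))
                assert best < 1e-9

    def test_minority_of_one_falls_back_to_duplication(self):
        t = make_table(np.arange(12.0).reshape(6, 2), [0, 0, 0, 0, 0, 1])
        with pytest.warns(UserWarning, match="falling back"):
            res = smote(t, k=3, seed=0)
        assert counts(res.table) == (1 + 4, 5)
        np.testing.assert_array_equal(res.table.X[-1], t.X[5])

    def test_determinism(self, imbalanced_table):
        a = smote(imbalanced_table, k=5, seed=11)
        b = smote(imbalanced_table, k=5, seed=11)
        np.testing.assert_array_equal(a.table.X, b.table.X)


class TestSvmSmote:
    def test_counts_and_determinism(self, imbalanced_table):
        a = svm_smote(imbalanced_table, k=3, seed=4)
        b = svm_smote(imbalanced_table, k=3, seed=4)
        assert counts(a.table) == (30, 30)
        np.testing.assert_array_equal(a.table.X, b.table.X)

    def test_safe_interior_seeds_extrapolate(self, rng):
        # far-apart, linearly separated clusters: minority neighborhoods are
        # all-minority, so every generated point uses the outward branch
        X = np.vstack([
            rng.normal(0, 0.3, size=(8, 2)),        # minority, tight cluster
            rng.normal(50, 0.3, size=(20, 2)),      # majority, far away
        ])
        t = make_table(X, [1] * 8 + [0] * 20)
        res = svm_smote(t, k=3, seed=1)
        log = " ".join(res.log)
        assert "interpolated=0" in log
        assert counts(res.table) == (20, 20)

    def test_original_rows_untouched(self, imbalanced_table):
        res = svm_smote(imbalanced_table, k=5, seed=9)
        np.testing.assert_array_equal(res.table.X[:imbalanced_table.n],
                                      imbalanced_table.X)


class TestCleaningUndersamplers:
    def test_enn_removes_surrounded_majority_point(self):
        # a lone majority point inside a minority cluster, plus a safe
        # majority cluster far away
        X = np.array([[0.0, 0], [0.1, 0], [0, 0.1], [0.05, 0.05],
                      [10, 10], [10.2, 10], [10, 10.2], [10.1, 10.1]])
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0])
        t = make_table(X, y)
        res = edited_nn(t, k=3)
        assert "s3" not in res.table.sample_ids
        assert {"s4", "s5", "s6", "s7"} <= set(res.table.sample_ids)

    def test_homogeneous_clusters_untouched(self):
        X = np.array([[0.0, 0], [0.1, 0], [0, 0.1],
                      [10, 10], [10.1, 10], [10, 10.1], [10.05, 10.05]])
        y = np.array([1, 1, 1, 0, 0, 0, 0])
        res = edited_nn(make_table(X, y), k=3)
        assert res.table.n == 7

    def test_minority_never_removed(self, rng):
        for trial in range(20):
            t = random_imbalanced_table(rng, n_min=5, n_maj=12, d=2, spread=0.5)
            maj = majority_label(t.y)
            for res in (edited_nn(t, k=3), all_knn(t, k_max=3), tomek_links(t)):
                kept_labels = t.y[res.kept_indices]
                n_min_in = int((t.y != maj).sum())
                assert int((kept_labels != maj).sum()) == n_min_in

    def test_enn_matches_bruteforce_oracle(self, rng):
        for trial in range(50):
            t = random_imbalanced_table(rng, n_min=rng.integers(4, 9),
                                        n_maj=rng.integers(9, 20),
                                        d=int(rng.integers(2, 5)), spread=0.8)
            maj = majority_label(t.y)
            expected = enn_removals_oracle(t.X, t.y, maj, 3)
            res = edited_nn(t, k=3)
            got = set(range(t.n)) - set(res.kept_indices)
            assert got == expected

    def test_all_knn_matches_sequential_oracle(self, rng):
        for trial in range(30):
            t = random_imbalanced_table(rng, n_min=rng.integers(4, 8),
                                        n_maj=rng.integers(8, 16),
                                        d=2, spread=0.8)
            maj = majority_label(t.y)
            expected = all_knn_kept_oracle(t.X, t.y, maj, 3)
            res = all_knn(t, k_max=3)
            assert list(res.kept_indices) == expected

    def test_all_knn_kmax1_equals_enn_k1(self, rng):
        t = random_imbalanced_table(rng, n_min=6, n_maj=14, d=2, spread=0.7)
        a = all_knn(t, k_max=1)
        b = edited_nn(t, k=1)
        np.testing.assert_array_equal(a.kept_indices, b.kept_indices)

    def test_all_knn_removals_monotone_in_kmax(self, rng):
        for trial in range(10):
            t = random_imbalanced_table(rng, n_min=6, n_maj=18, d=2, spread=0.6)
            removed_prev: set = set()
            for k_max in range(1, 8):
                res = all_knn(t, k_max=k_max)
                removed = set(range(t.n)) - set(res.kept_indices)
                assert removed_prev <= removed
                removed_prev = removed

    def test_tomek_removes_forced_link(self):
        X = np.array([[0.0, 0], [0.1, 0], [6, 6], [7, 7], [8, 8], [9, 9]])
        y = np.array([0, 1, 0, 0, 0, 0])  # (0,0) maj and (0.1,0) min are mutual NNs
        res = tomek_links(make_table(X, y))
        assert "s0" not in res.table.sample_ids
        assert "s1" in res.table.sample_ids

    def test_tomek_well_separated_no_removals(self):
        X = np.array([[0.0, 0], [0.2, 0], [0, 0.2], [50, 50], [50.2, 50], [50, 50.2]])
        y = np.array([1, 1, 1, 0, 0, 0])
        res = tomek_links(make_table(X, y))
        assert res.table.n == 6

    def test_tomek_matches_pairwise_oracle(self, rng):
        for trial in range(50):
            t = random_imbalanced_table(rng, n_min=rng.integers(4, 10),
                                        n_maj=rng.integers(10, 20),
                                        d=int(rng.integers(2, 5)), spread=0.6)
            maj = majority_label(t.y)
            expected = tomek_removals_oracle(t.X, t.y, maj)
            res = tomek_links(t)
            got = set(range(t.n)) - set(res.kept_indices)
            assert got == expected


class TestGlobalInvariants:
    def test_oversamplers_keep_all_originals(self, imbalanced_table):
        for spec in (ResamplerSpec("random_over"), ResamplerSpec("smote", k=3),
                     ResamplerSpec("svm_smote", k=3)):
            res = resample(imbalanced_table, spec)
            np.testing.assert_array_equal(
                res.table.X[:imbalanced_table.n], imbalanced_table.X)
            assert counts(res.table) == (30, 30)

    def test_undersamplers_never_create_rows(self, imbalanced_table):
        for spec in (ResamplerSpec("random_under"), ResamplerSpec("enn"),
                     ResamplerSpec("all_knn", k=3), ResamplerSpec("tomek")):
            res = resample(imbalanced_table, spec)
            assert res.n_synthetic == 0
            assert set(res.table.sample_ids) <= set(imbalanced_table.sample_ids)

    def test_pure_function_of_inputs(self, imbalanced_table):
        for spec in resampler_grid(seed=13):
            a = resample(imbalanced_table, spec)
            b = resample(imbalanced_table, spec)
            np.testing.assert_array_equal(a.table.X, b.table.X)
            np.testing.assert_array_equal(a.table.y, b.table.y)
            assert a.table.sample_ids == b.table.sample_ids
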