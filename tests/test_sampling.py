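"""Undersampling algorithms vs brute-force oracles."""

import numpy as np
import pytest

from fracrisk import (
    cluster_knn_undersample,
    one_sided_selection,
    random_undersample,
    tomek_links,
    undersample,
)
from fracrisk.sampling import cluster_sizes, standardize
from .conftest import toy_table


def _random_imbalanced(rng, n_min=3, n_maj=12, d=3, spread=1.0):
    x = np.vstack([rng.normal(0, spread, size=(n_min, d)),
                   rng.normal(0.5, spread, size=(n_maj, d))])
    labels = np.r_[np.ones(n_min, dtype=int), np.zeros(n_maj, dtype=int)]
    perm = rng.permutation(len(labels))
    return toy_table(x[perm], labels[perm])


def _brute_force_tomek(table):
    """O(n^2) oracle scanning all cross-class mutual nearest neighbours."""
    z = standardize(table.matrix())
    y = table.labels
    n = len(y)
    d = np.linalg.norm(z[:, None, :] - z[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    nn = [min(range(n), key=lambda j, i=i: (d[i, j], j)) for i in range(n)]
    pairs = set()
    for i in range(n):
        j = nn[i]
        if nn[j] == i and y[i] != y[j]:
            mino, maj = (i, j) if y[i] == 1 else (j, i)
            pairs.add((mino, maj))
    return pairs


class TestRandomUndersample:
    def test_balanced_output_and_replayed_draw(self):
        rng = np.random.default_rng(9)
        table = _random_imbalanced(rng, n_min=3, n_maj=9)
        res = random_undersample(table, seed=42)
        assert res.sampled.n == 6
        # oracle: replay the documented stream
        maj = table.class_indices(0)
        expected = np.random.default_rng(42).choice(maj, size=3, replace=False)
        kept_maj = [i for i in res.kept_indices if table.labels[i] == 0]
        assert sorted(kept_maj) == sorted(expected)

    def test_already_balanced_input_returned_unchanged(self):
        table = toy_table(np.arange(8, dtype=float), [0, 1] * 4)
        res = random_undersample(table, seed=0)
        assert res.sampled.equals(table)

    def test_no_minority_errors(self):
        table = toy_table(np.arange(4, dtype=float), [0] * 4)
        with pytest.raises(ValueError):
            random_undersample(table, seed=0)


class TestClusterKnnUndersample:
    def test_cluster_size_multiset_m7_m3(self):
        rng = np.random.default_rng(1)
        table = _random_imbalanced(rng, n_min=3, n_maj=7)
        assert list(cluster_sizes(table, seed=0)) == [2, 2, 3]

    def test_equal_counts_give_identity(self):
        rng = np.random.default_rng(2)
        table = _random_imbalanced(rng, n_min=4, n_maj=4)
        res = cluster_knn_undersample(table, seed=0)
        assert res.sampled.equals(table)

    def test_separated_blob_representatives_match_brute_force(self):
        rng = np.random.default_rng(3)
        blobs = [rng.normal(c, 0.05, size=(4, 2))
                 for c in ((-10, 0), (0, 10), (10, 0))]
        x = np.vstack(blobs + [rng.normal((0, -10), 0.05, size=(3, 2))])
        labels = np.r_[np.zeros(12, dtype=int), np.ones(3, dtype=int)]
        table = toy_table(x, labels)
        res = cluster_knn_undersample(table, seed=0)
        kept_maj = [i for i in res.kept_indices if labels[i] == 0]
        assert len(kept_maj) == 3
        # oracle: per blob, the point nearest its own centroid (standardized)
        z = standardize(x)
        expected = set()
        for b in range(3):
            members = np.arange(4 * b, 4 * b + 4)
            centroid = z[members].mean(axis=0)
            expected.add(members[np.argmin(
                np.linalg.norm(z[members] - centroid, axis=1))])
        assert set(kept_maj) == expected

    def test_balanced_size_at_scale(self, small_cohort):
        res = cluster_knn_undersample(small_cohort, seed=1)
        _, m = small_cohort.class_counts()
        assert res.sampled.n == 2 * m
        assert int(res.sampled.labels.sum()) == m


class TestTomekLinks:
    def test_wide_margin_has_no_links(self):
        x = np.r_[np.linspace(0, 1, 5), np.linspace(100, 101, 5)]
        table = toy_table(x, [1] * 5 + [0] * 5)
        assert tomek_links(table) == []

    def test_one_dimensional_hand_enumeration(self):
        table = toy_table([0.0, 0.4, 3.0], [1, 0, 0])
        links = tomek_links(table)
        assert len(links) == 1
        assert (links[0].minority_index, links[0].majority_index) == (0, 1)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 51))
        n_min = int(rng.integers(2, n // 2))
        x = rng.normal(size=(n, int(rng.integers(1, 5))))
        labels = np.r_[np.ones(n_min, dtype=int), np.zeros(n - n_min, dtype=int)]
        rng.shuffle(labels)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        table = toy_table(x, labels)
        got = {(l.minority_index, l.majority_index) for l in tomek_links(table)}
        assert got == _brute_force_tomek(table)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            tomek_links(toy_table([0.0, 1.0], [0, 0]))


def _oracle_oss(table, seed):
    """Independent re-derivation: 1-NN condensation in input order from all
    minority plus one seeded majority record, then Tomek cleaning."""
    z = standardize(table.matrix())
    y = table.labels
    maj = np.flatnonzero(y == 0)
    c = sorted(np.flatnonzero(y == 1).tolist())
    first = int(np.random.default_rng(seed).choice(maj))
    c.append(first)
    for j in maj:
        if j == first:
            continue
        best = min(c, key=lambda i: (np.linalg.norm(z[i] - z[j]), i))
        if y[best] != y[j]:
            c.append(j)
    kept = sorted(c)
    sub = table.subset(kept)
    if sub.labels.min() != sub.labels.max():
        drop = {kept[p.majority_index] for p in tomek_links(sub)}
        kept = [i for i in kept if i not in drop]
    return kept


class TestOneSidedSelection:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_trace(self, seed):
        rng = np.random.default_rng(100 + seed)
        table = _random_imbalanced(rng, n_min=4, n_maj=8, d=2, spread=1.5)
        res = one_sided_selection(table, seed=seed)
        assert list(res.kept_indices) == _oracle_oss(table, seed)

    def test_minority_never_removed(self):
        rng = np.random.default_rng(7)
        table = _random_imbalanced(rng, n_min=5, n_maj=30, spread=2.0)
        res = one_sided_selection(table, seed=3)
        assert int(res.sampled.labels.sum()) == 5
        orig_min = table.features.to_numpy()[table.labels == 1]
        kept_min = res.sampled.features.to_numpy()[res.sampled.labels == 1]
        assert np.array_equal(np.sort(orig_min, axis=0), np.sort(kept_min, axis=0))

    def test_separated_clusters_collapse_majority(self):
        rng = np.random.default_rng(8)
        x = np.vstack([rng.normal(-5, 0.1, size=(4, 2)),
                       rng.normal(5, 0.1, size=(20, 2))])
        table = toy_table(x, [1] * 4 + [0] * 20)
        res = one_sided_selection(table, seed=0)
        assert int((res.sampled.labels == 0).sum()) == 1

    def test_overlapping_data_stays_imbalanced(self):
        """On heavily overlapping 1:9 data the cleaning step cannot balance
        the classes — the qualitative failure mode of informed undersampling."""
        rng = np.random.default_rng(9)
        x = rng.normal(size=(300, 4))
        labels = np.r_[np.ones(30, dtype=int), np.zeros(270, dtype=int)]
        table = toy_table(x, labels)
        res = one_sided_selection(table, seed=1)
        n_maj = int((res.sampled.labels == 0).sum())
        assert n_maj >= 1.5 * 30  # far from the 1:1 the other samplers give


class TestSharedProperties:
    @pytest.mark.parametrize("method", ["random", "cluster_knn", "one_sided"])
    def test_minority_rows_byte_identical(self, method, small_cohort):
        res = undersample(small_cohort, method, seed=2)
        orig = small_cohort.features.to_numpy()[small_cohort.labels == 1]
        kept = res.sampled.features.to_numpy()[res.sampled.labels == 1]
        assert np.array_equal(orig, kept)
        assert len(np.unique(res.kept_indices)) == len(res.kept_indices)

    def test_unknown_method_lists_valid_names(self, small_cohort):
        with pytest.raises(ValueError, match="random"):
            undersample(small_cohort, "smote", seed=0)

    def test_cluster_sizes_never_differ_by_more_than_one(self):
        """Spot grid of (M, m); the exhaustive sweep lives in the
        acceptance suite."""
        rng = np.random.default_rng(10)
        for big_m, m in [(7, 3), (10, 10), (23, 5), (50, 7), (13, 1)]:
            table = _random_imbalanced(rng, n_min=m, n_maj=big_m, d=2)
            sizes = cluster_sizes(table, seed=0)
            assert sizes.sum() == big_m and len(sizes) == m
            assert sizes.max() - sizes.min() <= 1
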