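"""Undersampling of the majority (non-fracture) class.

Three algorithms produce reduced training sets from an imbalanced cohort:

* random undersampling — m majority records drawn uniformly without
  replacement (m = minority count), giving a balanced 2m-record set;
* cluster-based kNN undersampling — the M majority records are partitioned
  into m near-equal clusters (sizes floor(M/m) or floor(M/m)+1) and the
  record nearest each cluster's centre of gravity is kept;
* one-sided selection — Kubat–Matwin condensation (grow a 1-NN-consistent
  subset from all minority records plus one seed majority record) followed
  by removal of majority members of Tomek links.

All distances are Euclidean on features standardised to zero mean / unit
variance over the input table (binary flags included), so dose columns
cannot dominate.  Minority records are never removed or modified.
Nearest-neighbour and nearest-to-centroid ties break toward the lowest
record index; a record is never its own nearest neighbour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .cohort import CohortTable

SAMPLER_NAMES = ("random", "cluster_knn", "one_sided")


@dataclass
class SamplingResult:
    """A reduced training set plus the indices kept from the input."""

    sampled: CohortTable
    method: str
    kept_indices: np.ndarray
    seed: int


@dataclass(frozen=True)
class TomekPair:
    """A cross-class pair of mutual nearest neighbours (a borderline pair)."""

    minority_index: int
    majority_index: int
    distance: float


def standardize(x: np.ndarray) -> np.ndarray:
    """Zero-mean / unit-variance scaling; constant columns map to zero."""
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std[std == 0.0] = 1.0
    return (x - mean) / std


def _result(train: CohortTable, kept: np.ndarray, method: str,
            seed: int) -> SamplingResult:
    kept = np.sort(np.asarray(kept, dtype=np.int64))
    return SamplingResult(sampled=train.subset(kept), method=method,
                          kept_indices=kept, seed=seed)


def random_undersample(train: CohortTable, seed: int = 0) -> SamplingResult:
    """Keep all m minority records plus m uniformly drawn majority records."""
    maj = train.class_indices(0)
    mino = train.class_indices(1)
    m, big_m = len(mino), len(maj)
    if m == 0:
        raise ValueError("no minority records to balance against")
    if big_m <= m:
        if big_m < m:
            warnings.warn(
                f"majority count {big_m} <= minority count {m}; "
                "returning the input unchanged", stacklevel=2)
        return _result(train, np.arange(train.n), "random", seed)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(maj, size=m, replace=False)
    return _result(train, np.concatenate([mino, chosen]), "random", seed)


def _equal_size_clusters(z: np.ndarray, m: int, seed: int) -> np.ndarray:
    """Partition the rows of ``z`` into m clusters whose sizes differ by at
    most one: k-means (k-means++ seeding), then greedy reassignment of the
    overflow of each over-full cluster, farthest-from-centroid first, to the
    nearest cluster with spare capacity.  Centroids stay fixed during the
    repair so the result is deterministic.  Returns cluster labels."""
    big_m = len(z)
    if m == big_m:
        return np.arange(big_m)
    if m == 1:
        return np.zeros(big_m, dtype=np.int64)
    km = KMeans(n_clusters=m, init="k-means++", n_init=1,
                random_state=seed % (2 ** 31)).fit(z)
    labels = km.labels_.astype(np.int64)
    centers = km.cluster_centers_
    dist = cdist(z, centers)

    base, extra = divmod(big_m, m)
    sizes = np.bincount(labels, minlength=m)
    # the `extra` currently-largest clusters get capacity base+1 (ties by
    # lower cluster id), the rest base
    order = np.lexsort((np.arange(m), -sizes))
    caps = np.full(m, base, dtype=np.int64)
    caps[order[:extra]] = base + 1

    for c in range(m):
        while sizes[c] > caps[c]:
            members = np.flatnonzero(labels == c)
            mover = members[np.argmax(dist[members, c])]
            open_clusters = np.flatnonzero(sizes < caps)
            target = open_clusters[np.argmin(dist[mover, open_clusters])]
            labels[mover] = target
            sizes[c] -= 1
            sizes[target] += 1
    return labels


def cluster_knn_undersample(train: CohortTable, seed: int = 0) -> SamplingResult:
    """Cluster the majority into m equal-size clusters and keep the record
    nearest each cluster's centre of gravity, plus all minority records."""
    maj = train.class_indices(0)
    mino = train.class_indices(1)
    m, big_m = len(mino), len(maj)
    if m == 0:
        raise ValueError("no minority records to balance against")
    if big_m < m:
        raise ValueError(f"majority count {big_m} < minority count {m}")
    z_all = standardize(train.matrix())
    z = z_all[maj]
    labels = _equal_size_clusters(z, m, seed)
    reps = np.empty(m, dtype=np.int64)
    for c in range(m):
        members = np.flatnonzero(labels == c)
        gravity = z[members].mean(axis=0)
        d = np.linalg.norm(z[members] - gravity, axis=1)
        reps[c] = maj[members[np.argmin(d)]]
    return _result(train, np.concatenate([mino, reps]), "cluster_knn", seed)


def cluster_sizes(train: CohortTable, seed: int = 0) -> np.ndarray:
    """Cluster-size multiset of the majority partition used by
    :func:`cluster_knn_undersample` (diagnostic helper)."""
    maj = train.class_indices(0)
    m = len(train.class_indices(1))
    z = standardize(train.matrix())[maj]
    labels = _equal_size_clusters(z, m, seed)
    return np.sort(np.bincount(labels, minlength=m))


def _nearest_neighbours(z: np.ndarray) -> np.ndarray:
    """Index of each row's nearest other row; ties to the lowest index."""
    d = cdist(z, z)
    np.fill_diagonal(d, np.inf)
    return d.argmin(axis=1)  # argmin takes the first (lowest-index) minimum


def tomek_links(table: CohortTable) -> list[TomekPair]:
    """All cross-class mutual-nearest-neighbour pairs of the table."""
    if table.n < 2:
        raise ValueError("need at least 2 records")
    y = table.labels
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    z = standardize(table.matrix())
    nn = _nearest_neighbours(z)
    pairs: list[TomekPair] = []
    for i in range(table.n):
        j = nn[i]
        if i < j and nn[j] == i and y[i] != y[j]:
            mino, maj = (i, j) if y[i] == 1 else (j, i)
            pairs.append(TomekPair(minority_index=int(mino),
                                   majority_index=int(maj),
                                   distance=float(np.linalg.norm(z[i] - z[j]))))
    return pairs


def one_sided_selection(train: CohortTable, seed: int = 0) -> SamplingResult:
    """One-sided selection: 1-NN condensation, then Tomek-link cleaning.

    Step 1 grows a consistent subset C from all minority records plus one
    seed-chosen majority record, adding each majority record (in input
    order) misclassified by 1-NN against the current C.  Step 2 removes
    every majority member of a Tomek link of the condensed set.  Minority
    records are never removed.
    """
    y = train.labels
    if y.min() == y.max() if train.n else True:
        raise ValueError("both classes must be present")
    maj = train.class_indices(0)
    mino = train.class_indices(1)
    z = standardize(train.matrix())

    rng = np.random.default_rng(seed)
    first = int(rng.choice(maj))
    in_c = np.zeros(train.n, dtype=bool)
    in_c[mino] = True
    in_c[first] = True
    for j in maj:
        if in_c[j]:
            continue
        members = np.flatnonzero(in_c)
        d = np.linalg.norm(z[members] - z[j], axis=1)
        nearest = members[np.flatnonzero(d == d.min())[0]]  # members ascending
        if y[nearest] != y[j]:  # misclassified by the current subset
            in_c[j] = True

    condensed = np.flatnonzero(in_c)
    sub = train.subset(condensed)
    drop = set()
    if sub.labels.min() != sub.labels.max() and sub.n >= 2:
        for pair in tomek_links(sub):
            drop.add(condensed[pair.majority_index])
    kept = np.array([i for i in condensed if i not in drop], dtype=np.int64)
    return _result(train, kept, "one_sided", seed)


def undersample(train: CohortTable, method: str, seed: int = 0) -> SamplingResult:
    """Dispatch by sampler name (``random``, ``cluster_knn``, ``one_sided``)."""
    aliases = {"random": random_undersample, "cluster": cluster_knn_undersample,
               "cluster_knn": cluster_knn_undersample,
               "oss": one_sided_selection, "one_sided": one_sided_selection}
    if method not in aliases:
        raise ValueError(
            f"unknown sampler {method!r}; expected one of {sorted(aliases)}")
    return aliases[method](train, seed=seed)
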