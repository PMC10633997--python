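"""Artificial out-of-distribution scenario construction.

Two grouping routes produce "molecules the model has never seen":

* PCA percentile bins — z-score the full descriptor matrix, take the top
  principal components, cut each into five equal-count bins, and excise one
  bin at a time from the training and validation sets (the test set is left
  untouched).  Three components x five bins gives fifteen scenarios.
* Butina sphere-exclusion clustering on a pairwise similarity matrix.

Also here: maximum-similarity-to-training scoring of candidate molecules,
downsampling a pool to a similarity distribution uniform over [0, 1], and
the within/between group mean-distance diagnostic on the 2*(1 - similarity)
scale (range [0, 2]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from moluq.errors import (ConfigurationError, DegenerateError,
                          InfeasibleSampleError, InputError)
from moluq.synthetic import MoleculeTable, similarity_matrix


@dataclass
class BinAssignment:
    """Equal-count percentile bins of one principal component."""

    pc_index: int                 # 1-based component index
    bin_edges: np.ndarray         # the 20/40/60/80 percentile cuts
    bin_of: np.ndarray            # per-row labels in 1..n_bins

    @property
    def n_bins(self) -> int:
        return int(self.bin_of.max())

    def members(self, bin_index: int) -> np.ndarray:
        return np.flatnonzero(self.bin_of == bin_index)


@dataclass
class LeaveBinOutSplit:
    """A train/val/test split with one PCA bin excised from train and val."""

    pc_index: int
    bin_index: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    removed_idx: np.ndarray

    def to_dict(self) -> dict:
        return {"pc_index": self.pc_index, "bin_index": self.bin_index,
                "train_idx": self.train_idx.tolist(),
                "val_idx": self.val_idx.tolist(),
                "test_idx": self.test_idx.tolist(),
                "removed_idx": self.removed_idx.tolist()}


@dataclass
class OODPool:
    """Candidate molecules scored by maximum similarity to the training set."""

    pool: MoleculeTable
    similarity: np.ndarray = field(default=None)

    def __post_init__(self):
        self.similarity = np.asarray(self.similarity, float)
        if len(self.similarity) != len(self.pool):
            raise InputError("similarity vector not aligned with pool")
        if np.any((self.similarity < 0) | (self.similarity > 1)):
            raise InputError("similarity scores must lie in [0, 1]")

    def __len__(self):
        return len(self.pool)


def _rank_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-count binning by rank with stable index tie-breaking.

    Sorting with a stable key and splitting the rank sequence into
    ``n_bins`` runs guarantees bin sizes equal within +-1 even under ties.
    """
    n = len(values)
    order = np.argsort(values, kind="stable")
    sizes = np.full(n_bins, n // n_bins)
    sizes[: n % n_bins] += 1
    labels = np.empty(n, dtype=int)
    start = 0
    for b, size in enumerate(sizes, start=1):
        labels[order[start:start + size]] = b
        start += size
    return labels


def pca_top_bins(X: np.ndarray, n_components: int = 3,
                 n_bins: int = 5) -> list[BinAssignment]:
    """Percentile bins of the top principal components of z-scored descriptors.

    One :class:`BinAssignment` per component; with the defaults this defines
    the 15 leave-bin-out scenarios (3 components x 5 bins).
    """
    X = np.asarray(X, float)
    if X.shape[0] < n_bins:
        raise InputError("need at least n_bins rows")
    sd = X.std(axis=0)
    if np.all(sd == 0):
        raise DegenerateError("constant feature matrix: PCA is degenerate")
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    scores = PCA(n_components=n_components, random_state=0).fit_transform(Z)
    cuts = np.arange(1, n_bins) * 100.0 / n_bins
    return [
        BinAssignment(pc_index=c + 1,
                      bin_edges=np.percentile(scores[:, c], cuts),
                      bin_of=_rank_bins(scores[:, c], n_bins))
        for c in range(n_components)
    ]


def leave_bin_out(full_split, assignment: BinAssignment,
                  bin_index: int) -> LeaveBinOutSplit:
    """Purge one bin's members from the train and val index sets.

    ``full_split`` is a ``(train_idx, val_idx, test_idx)`` triple over rows
    of the matrix the assignment was computed on.  The test set is returned
    unchanged; ``removed_idx`` holds the excised train/val indices.
    """
    if not 1 <= bin_index <= assignment.n_bins:
        raise ConfigurationError(f"bin_index must be in 1..{assignment.n_bins}")
    train_idx, val_idx, test_idx = (np.asarray(a, int) for a in full_split)
    members = set(assignment.members(bin_index).tolist())
    new_train = np.array([i for i in train_idx if i not in members], int)
    new_val = np.array([i for i in val_idx if i not in members], int)
    removed = np.array([i for i in np.concatenate([train_idx, val_idx])
                        if i in members], int)
    if len(new_train) == 0:
        raise ConfigurationError("removing the bin empties the training set")
    return LeaveBinOutSplit(assignment.pc_index, bin_index, new_train,
                            new_val, test_idx.copy(), removed)


def similarity_to_training(query_reps: np.ndarray, train, subset_size:
                           int = 1000, seed: int = 0) -> np.ndarray:
    """Maximum bounded cosine similarity to a random training subset.

    Mirrors maximum-fingerprint-similarity scoring: each query molecule is
    scored by its best match within ``subset_size`` randomly chosen training
    molecules (all of them when the training set is smaller).
    """
    train_reps = train.X if isinstance(train, MoleculeTable) else np.asarray(
        train, float)
    if subset_size <= 0:
        raise ConfigurationError("subset_size must be positive")
    n = train_reps.shape[0]
    if n == 0:
        raise ConfigurationError("empty training set")
    if subset_size < n:
        idx = np.random.default_rng(seed).choice(n, size=subset_size,
                                                 replace=False)
        train_reps = train_reps[idx]
    return similarity_matrix(np.asarray(query_reps, float),
                             train_reps).max(axis=1)


def uniform_similarity_sample(pool: OODPool, n_out: int, n_strata: int = 10,
                              seed: int = 0) -> OODPool:
    """Downsample a pool so similarity scores are uniform over [0, 1].

    Scores are stratified into ``n_strata`` equal-width intervals; each
    stratum contributes an equal count (within +-1).  If any stratum cannot
    supply its quota the sample is infeasible and the error names the
    deficient strata.
    """
    if n_out <= 0:
        raise ConfigurationError("n_out must be positive")
    stratum = np.minimum((pool.similarity * n_strata).astype(int),
                         n_strata - 1)
    quotas = np.full(n_strata, n_out // n_strata)
    quotas[: n_out % n_strata] += 1
    rng = np.random.default_rng(seed)
    chosen = []
    deficient = []
    for s in range(n_strata):
        members = np.flatnonzero(stratum == s)
        if len(members) < quotas[s]:
            deficient.append(s)
        elif quotas[s] > 0:
            chosen.append(rng.choice(members, size=quotas[s], replace=False))
    if deficient:
        raise InfeasibleSampleError(
            f"cannot draw a uniform sample of {n_out}: similarity strata "
            f"{deficient} (width {1.0 / n_strata:g}) lack members",
            empty_strata=deficient)
    idx = np.sort(np.concatenate(chosen))
    return OODPool(pool.pool.subset(idx), pool.similarity[idx])


def butina_clusters(similarity: np.ndarray, threshold: float) -> np.ndarray:
    """Taylor-Butina sphere-exclusion clustering on a similarity matrix.

    Repeatedly selects the unassigned item with the most unassigned
    neighbors at similarity >= threshold as a cluster centroid, assigns
    those neighbors to it, removes them, and repeats; ties break toward the
    lowest index.  Singletons are allowed.  Returns integer labels in order
    of cluster creation.
    """
    S = np.asarray(similarity, float)
    if not 0.0 < threshold < 1.0:
        raise ConfigurationError("threshold must lie strictly inside (0, 1)")
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise InputError("similarity matrix must be square")
    if not np.allclose(S, S.T):
        raise InputError("similarity matrix must be symmetric")
    if not np.allclose(np.diag(S), 1.0):
        raise InputError("similarity matrix must have a unit diagonal")
    n = S.shape[0]
    adj = (S >= threshold)
    np.fill_diagonal(adj, False)
    labels = np.full(n, -1, dtype=int)
    unassigned = np.ones(n, dtype=bool)
    cluster = 0
    while unassigned.any():
        counts = (adj & unassigned).sum(axis=1)
        counts[~unassigned] = -1
        centroid = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(adj[centroid] & unassigned)
        labels[centroid] = cluster
        labels[members] = cluster
        unassigned[centroid] = False
        unassigned[members] = False
        cluster += 1
    return labels


def group_mean_distance(reps_a: np.ndarray, reps_b: np.ndarray | None = None,
                        within: bool = False) -> float:
    """Mean pairwise distance 2*(1 - similarity), in [0, 2].

    ``within=True`` averages over unordered pairs inside ``reps_a``;
    otherwise over all pairs between ``reps_a`` and ``reps_b``.
    """
    A = np.asarray(reps_a, float)
    if A.ndim != 2 or A.shape[0] == 0:
        raise InputError("group A must be a nonempty matrix")
    if within:
        if A.shape[0] < 2:
            raise InputError("within-group distance needs at least 2 rows")
        D = 2.0 * (1.0 - similarity_matrix(A, A))
        iu = np.triu_indices(A.shape[0], k=1)
        return float(D[iu].mean())
    B = np.asarray(reps_b, float) if reps_b is not None else None
    if B is None or B.ndim != 2 or B.shape[0] == 0:
        raise InputError("group B must be a nonempty matrix")
    return float((2.0 * (1.0 - similarity_matrix(A, B))).mean())
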