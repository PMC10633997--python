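"""Synthetic clustered descriptor datasets with known ground truth.

Emulates the structure of curated QSAR regression sets: molecules fall into
structural clusters in a high-dimensional descriptor space, a lower-dimensional
"embedding" block is a correlated linear view of the descriptors, and the
target property is a smooth nonlinear function of the descriptors with
heteroscedastic Gaussian noise of known per-molecule scale.  Because the
noise scale and the teacher function are known, every downstream stage
(calibration metrics, OOD scoring, leave-bin-out retraining, active
learning) can be tested without external downloads.

Geometry.  Cluster centers are placed inside a cone around a fixed random
unit direction ``u0`` so that the whole training distribution occupies a
half-space.  An out-of-distribution pool is produced by displacing points
along ``-u0`` by graded multiples of ``ood_displacement``; as the multiple
grows, the maximum cosine similarity of a pool point to the training data
sweeps continuously from ~1 down to ~0, which is what lets the pool be
downsampled to a similarity distribution uniform over [0, 1].
"""

from __future__ import annotations

import dataclasses
import functools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from moluq.errors import ConfigurationError, DomainError, InputError

_TEACHER_HIDDEN = 16
_TEACHER_GAIN = 0.5   # pre-activation gain: keeps the teacher smooth enough
                      # that a desk-scale network reaches near-noise error
_REFERENCE_N = 2000
_CENTER_DIST = 30.0     # |mean of cluster centers| in units of cluster_spread
_CENTER_SPAN = 24.0     # total extent of centers along the structural axis
_CENTER_JITTER = 1.0    # isotropic jitter of each center, same units
_POOL_GRADES = 8      # displacement multiples are j/_POOL_GRADES, j = 0..4*_POOL_GRADES

# named substream indices: every source of randomness gets its own stream so
# that e.g. re-drawing noise never perturbs the cluster geometry
_STREAMS = {
    "geometry": 0,
    "centers": 1,
    "assign": 2,
    "points": 3,
    "teacher": 4,
    "reference": 5,
    "noise": 6,
    "noise_shape": 7,
    "embedding": 8,
    "pool": 9,
    "embedding_noise_data": 10,
    "embedding_noise_pool": 11,
}


def _stream(seed: int, purpose: str) -> np.random.Generator:
    """Named, independent random stream derived from the config seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[purpose],))
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic molecular dataset generator.

    Attributes
    ----------
    n_molecules : number of rows to generate.
    n_features : descriptor dimension p.
    n_embedding : embedding dimension q (q << p mimics learned embeddings).
    n_clusters : number of Gaussian structural clusters.
    cluster_spread : per-coordinate standard deviation within a cluster.
    noise_base : homoscedastic floor of the target noise sd.
    noise_hetero : amplitude of the structure-dependent noise sd component.
    ood_displacement : unit displacement distance used by :func:`make_ood_pool`.
    seed : master seed; all named substreams derive from it.
    """

    n_molecules: int = 2000
    n_features: int = 32
    n_embedding: int = 8
    n_clusters: int = 5
    cluster_spread: float = 1.0
    noise_base: float = 0.1
    noise_hetero: float = 0.6
    ood_displacement: float = 15.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_molecules", "n_features", "n_embedding", "n_clusters"):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be a positive integer")
        if self.n_clusters > self.n_molecules:
            raise ConfigurationError("n_clusters cannot exceed n_molecules")
        if self.cluster_spread <= 0:
            raise ConfigurationError("cluster_spread must be positive")
        for name in ("noise_base", "noise_hetero", "ood_displacement"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")


@dataclass
class MoleculeTable:
    """A molecules-by-features regression table with known noise scale.

    Rows of ``ids``, ``X`` (descriptors), ``E`` (embeddings), ``y`` (target),
    ``cluster`` and ``sigma_true`` are aligned; ids are unique.
    """

    ids: list[str]
    X: np.ndarray
    E: np.ndarray
    y: np.ndarray
    cluster: np.ndarray
    sigma_true: np.ndarray
    config: SyntheticConfig | None = field(default=None, repr=False)

    def __post_init__(self):
        n = len(self.ids)
        for name in ("X", "E", "y", "cluster", "sigma_true"):
            arr = getattr(self, name)
            if arr.shape[0] != n:
                raise InputError(f"{name} has {arr.shape[0]} rows, expected {n}")
        if len(set(self.ids)) != n:
            raise InputError("molecule ids must be unique")
        if np.any(self.sigma_true < 0):
            raise InputError("sigma_true must be nonnegative")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "MoleculeTable":
        """Row-subset view (copies) preserving alignment."""
        idx = np.asarray(idx)
        return MoleculeTable(
            ids=[self.ids[i] for i in idx],
            X=self.X[idx],
            E=self.E[idx],
            y=self.y[idx],
            cluster=self.cluster[idx],
            sigma_true=self.sigma_true[idx],
            config=self.config,
        )

    def to_frame(self) -> pd.DataFrame:
        p, q = self.X.shape[1], self.E.shape[1]
        data = {"id": self.ids}
        for j in range(p):
            data[f"f_{j:03d}"] = self.X[:, j]
        for j in range(q):
            data[f"e_{j:03d}"] = self.E[:, j]
        data["y"] = self.y
        data["cluster"] = self.cluster
        data["sigma_true"] = self.sigma_true
        return pd.DataFrame(data)

    def save(self, path: str | Path) -> None:
        """Write the table as CSV plus a JSON config sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if self.config is not None:
            sidecar = path.with_suffix(path.suffix + ".config.json")
            sidecar.write_text(json.dumps(dataclasses.asdict(self.config), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "MoleculeTable":
        path = Path(path)
        df = pd.read_csv(path)
        fcols = sorted(c for c in df.columns if c.startswith("f_"))
        ecols = sorted(c for c in df.columns if c.startswith("e_"))
        sidecar = path.with_suffix(path.suffix + ".config.json")
        config = None
        if sidecar.exists():
            config = SyntheticConfig(**json.loads(sidecar.read_text()))
        return cls(
            ids=[str(v) for v in df["id"]],
            X=df[fcols].to_numpy(float),
            E=df[ecols].to_numpy(float),
            y=df["y"].to_numpy(float),
            cluster=df["cluster"].to_numpy(int),
            sigma_true=df["sigma_true"].to_numpy(float),
            config=config,
        )


@functools.lru_cache(maxsize=32)
def _world(config: SyntheticConfig) -> dict:
    """Deterministic latent structure shared by dataset and OOD pool.

    Everything here is a pure function of the config: the cone axis u0, the
    cluster centers, the teacher network, the noise-shape direction, the
    embedding projection and its column scales (estimated once on a fixed
    reference sample so that train tables and pools use identical maps).
    """
    p, k, c = config.n_features, config.n_clusters, config.cluster_spread

    rng_g = _stream(config.seed, "geometry")
    u0 = rng_g.normal(size=p)
    u0 /= np.linalg.norm(u0)
    v0 = rng_g.normal(size=p)
    v0 -= (v0 @ u0) * u0          # structural axis, orthogonal to the cone axis
    v0 /= np.linalg.norm(v0)
    mean_center = _CENTER_DIST * c * u0

    # centers sit on a line along v0 with spacing >> within-cluster spread, so
    # the top principal component separates the clusters and its percentile
    # bins pick out structural regions; gaps grow geometrically so clusters
    # differ in how isolated they are (as real structural families do)
    rng_c = _stream(config.seed, "centers")
    gaps = 1.5 ** np.arange(max(k - 1, 1))
    offsets = np.concatenate([[0.0], np.cumsum(gaps[: k - 1])])
    if k > 1:
        offsets *= _CENTER_SPAN * c / offsets[-1]
    offsets -= offsets.mean()
    centers = (mean_center + offsets[:, None] * v0
               + _CENTER_JITTER * c * rng_c.normal(size=(k, p)) / np.sqrt(p))

    rng_t = _stream(config.seed, "teacher")
    W1 = rng_t.normal(size=(p, _TEACHER_HIDDEN))
    b1 = rng_t.normal(scale=0.5, size=_TEACHER_HIDDEN)
    w2 = rng_t.normal(size=_TEACHER_HIDDEN) / np.sqrt(_TEACHER_HIDDEN)

    w_g = _stream(config.seed, "noise_shape").normal(size=p)

    rng_e = _stream(config.seed, "embedding")
    P = rng_e.normal(size=(p, config.n_embedding)) / np.sqrt(p)

    # fixed reference sample from the mixture: sets the teacher output scale
    # (std 1) and the embedding noise scale, independent of any one dataset
    rng_r = _stream(config.seed, "reference")
    ref_lab = rng_r.integers(0, k, size=_REFERENCE_N)
    ref_X = centers[ref_lab] + c * rng_r.normal(size=(_REFERENCE_N, p))

    def raw_f(X):
        h = np.tanh(_TEACHER_GAIN * ((X - mean_center) @ W1 / np.sqrt(p)) + b1)
        return h @ w2

    ref_f = raw_f(ref_X)
    out_scale = 1.0 / max(float(np.std(ref_f)), 1e-12)
    emb_scales = np.maximum(np.std(ref_X @ P, axis=0), 1e-12)

    return {
        "u0": u0, "mean_center": mean_center, "centers": centers,
        "W1": W1, "b1": b1, "w2": w2, "out_scale": out_scale,
        "w_g": w_g, "P": P, "emb_scales": emb_scales,
    }


def teacher_predict(config: SyntheticConfig, X: np.ndarray) -> np.ndarray:
    """Noise-free target of the fixed teacher: a seeded 2-layer tanh network."""
    w = _world(config)
    h = np.tanh(_TEACHER_GAIN * ((X - w["mean_center"]) @ w["W1"]
                                 / np.sqrt(config.n_features)) + w["b1"])
    return w["out_scale"] * (h @ w["w2"])


def noise_scale(config: SyntheticConfig, X: np.ndarray) -> np.ndarray:
    """Per-row true noise sd: noise_base + noise_hetero * sigmoid(w_g . x)."""
    w = _world(config)
    z = (X - w["mean_center"]) @ w["w_g"] / np.sqrt(config.n_features)
    g = 1.0 / (1.0 + np.exp(-z))
    return config.noise_base + config.noise_hetero * g


def _embed(config: SyntheticConfig, X: np.ndarray,
           rng: np.random.Generator) -> np.ndarray:
    """Seeded linear projection of descriptors plus 5% relative Gaussian noise."""
    w = _world(config)
    E = X @ w["P"]
    return E + 0.05 * w["emb_scales"] * rng.normal(size=E.shape)


def generate_dataset(config: SyntheticConfig) -> MoleculeTable:
    """Draw a clustered descriptor dataset from the configured mixture.

    Descriptors come from ``n_clusters`` Gaussian clusters whose centers are
    far apart relative to ``cluster_spread``; embeddings are a fixed seeded
    linear projection of the descriptors with small noise; the target is the
    teacher value plus heteroscedastic Gaussian noise of known scale.
    Bit-identical output for identical configs.
    """
    w = _world(config)
    n, p = config.n_molecules, config.n_features

    cluster = _stream(config.seed, "assign").integers(0, config.n_clusters, size=n)
    X = w["centers"][cluster] + config.cluster_spread * _stream(
        config.seed, "points").normal(size=(n, p))

    f = teacher_predict(config, X)
    sigma = noise_scale(config, X)
    y = f + sigma * _stream(config.seed, "noise").normal(size=n)
    E = _embed(config, X, _stream(config.seed, "embedding_noise_data"))

    return MoleculeTable(
        ids=[f"mol_{i:06d}" for i in range(n)],
        X=X, E=E, y=y, cluster=cluster, sigma_true=sigma, config=config,
    )


def pairwise_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Bounded similarity (1 + cos(a, b)) / 2 in [0, 1].

    The analogue of a fingerprint Tanimoto score: 1 for positively
    proportional vectors, 0 for antipodal ones; the induced distance
    2 * (1 - similarity) spans [0, 2].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InputError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise DomainError("similarity undefined for a zero vector")
    cos = float(np.dot(a, b) / (na * nb))
    return 0.5 * (1.0 + min(1.0, max(-1.0, cos)))


def similarity_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Vectorized pairwise_similarity for row blocks: |A| x |B| matrix."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise DomainError("similarity undefined for a zero vector")
    cos = np.clip((A @ B.T) / np.outer(na, nb), -1.0, 1.0)
    return 0.5 * (1.0 + cos)


def make_ood_pool(config: SyntheticConfig, train: MoleculeTable,
                  n_pool: int) -> MoleculeTable:
    """Generate a candidate pool spanning in- to out-of-distribution.

    Each pool molecule starts at a cluster center plus within-cluster noise
    and is displaced along the negative cone axis by a graded multiple
    (j / 8, j = 0..32) of ``ood_displacement``.  Targets still come from the
    same teacher, so pool labels are usable for active learning.  With the
    default geometry the maximum similarity to the training set spans [0, 1]:
    multiple 0 is indistinguishable from training data, the largest multiple
    lands nearly antipodal to the whole training cone.
    """
    if n_pool <= 0:
        raise ConfigurationError("n_pool must be positive")
    w = _world(config)
    p = config.n_features
    rng = _stream(config.seed, "pool")

    cluster = rng.integers(0, config.n_clusters, size=n_pool)
    base = w["centers"][cluster] + config.cluster_spread * rng.normal(
        size=(n_pool, p))
    grade = rng.integers(0, 4 * _POOL_GRADES + 1, size=n_pool) / _POOL_GRADES
    X = base - (grade * config.ood_displacement)[:, None] * w["u0"]

    f = teacher_predict(config, X)
    sigma = noise_scale(config, X)
    y = f + sigma * rng.normal(size=n_pool)
    E = _embed(config, X, _stream(config.seed, "embedding_noise_pool"))

    return MoleculeTable(
        ids=[f"pool_{i:06d}" for i in range(n_pool)],
        X=X, E=E, y=y, cluster=cluster, sigma_true=sigma, config=config,
    )
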