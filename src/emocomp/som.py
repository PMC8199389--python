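"""Kohonen self-organizing map and competitiveness categorization.

A rectangular lattice of weight vectors is trained by competitive
learning: at each iteration an input vector is presented, the best
matching unit (BMU, Euclidean-nearest node) is found, and every node is
pulled toward the input in proportion to a Gaussian neighborhood kernel
γ centered on the BMU, with both the learning rate β and the
neighborhood radius α decaying exponentially with the iteration count
(time constant λ).  No hard radius cutoff is applied: γ itself makes
updates beyond the radius negligible.

After training, the codebook is partitioned into four clusters with
K-means (delegated to scikit-learn, seeded, 20 restarts), and each
organization is assigned the cluster of its BMU.  Competitiveness
categories come from two independent rules that the study design makes
consistent: organizational rank (1–5 high, 6–8 moderate, 9–10 low) and
dominant emotion (happy/excited → high, neutral → moderate, angry →
low).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from emocomp.datagen import EMOTIONS

#: emotion index -> competitiveness category
EMOTION_CATEGORY: dict[str, str] = {
    "neutral": "moderate", "happy": "high", "excited": "high", "angry": "low",
}

#: tie-break priority when fractions are equal (pessimistic first)
TIE_PRIORITY: tuple[str, ...] = ("angry", "neutral", "happy", "excited")


@dataclass
class SOMConfig:
    """Lattice dimensions and decay schedule."""

    rows: int = 10
    cols: int = 10
    n_iter: int | None = None       # total presentations o; default 1000 * n_inputs
    alpha0: float | None = None     # initial radius; default max(rows, cols)/2
    beta0: float = 0.5              # initial learning rate
    lam: float | None = None        # time constant; default o / log(alpha0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows * self.cols < 4:
            raise ValueError("lattice needs at least 4 nodes")
        if not 0 < self.beta0 <= 1:
            raise ValueError("beta0 must be in (0, 1]")


@dataclass
class SOMGrid:
    """Trained lattice: weights (rows, cols, dim) plus its schedule."""

    weights: np.ndarray
    alpha0: float
    beta0: float
    lam: float
    n_iter: int
    seed: int
    quantization_errors: list[float] = field(default_factory=list)

    @property
    def rows(self) -> int:
        return self.weights.shape[0]

    @property
    def cols(self) -> int:
        return self.weights.shape[1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j in range(self.rows):
            for k in range(self.cols):
                rows.append({"row": j, "col": k,
                             **{f"w{d}": self.weights[j, k, d]
                                for d in range(self.weights.shape[2])}})
        return pd.DataFrame(rows)


@dataclass
class OrgProfile:
    """Aggregated emotion composition of one organization."""

    org_rank: int
    n_employees: int
    emotion_fractions: np.ndarray    # order: neutral, happy, excited, angry

    def __post_init__(self) -> None:
        self.emotion_fractions = np.asarray(self.emotion_fractions, dtype=float)
        if np.any(self.emotion_fractions < 0):
            raise ValueError("fractions must be non-negative")
        if abs(self.emotion_fractions.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


@dataclass
class CompetitivenessReport:
    """Per-organization cluster/category assignment plus cluster summaries."""

    per_org: pd.DataFrame      # org_rank, n_employees, fractions, cluster, category, dominant_emotion
    per_cluster: pd.DataFrame  # cluster, centroid fractions, member org ranks

    def to_csv(self, path) -> None:
        self.per_org.to_csv(path, index=False)


def euclidean_distance(y: np.ndarray, x: np.ndarray) -> float:
    """√Σ (y_t − x_t)²."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError("vectors must have equal length")
    return float(np.sqrt(np.sum((y - x) ** 2)))


def find_bmu(grid: SOMGrid | np.ndarray, y: np.ndarray) -> tuple[int, int]:
    """Best matching unit: node minimizing Euclidean distance to ``y``.

    Ties resolve to the smallest (row, col) in row-major order.
    """
    W = grid.weights if isinstance(grid, SOMGrid) else np.asarray(grid, dtype=float)
    if W.ndim != 3:
        raise ValueError("grid weights must be (rows, cols, dim)")
    d2 = np.sum((W - np.asarray(y, dtype=float)) ** 2, axis=2)
    flat = int(np.argmin(d2))          # argmin takes the first minimum: row-major tie-break
    return flat // W.shape[1], flat % W.shape[1]


def decayed(value0: float, t: float, lam: float) -> float:
    """Exponential decay value0 · exp(−t/λ)."""
    if lam <= 0:
        raise ValueError("time constant must be > 0")
    return float(value0 * np.exp(-t / lam))


def neighborhood(e: float, alpha_t: float) -> float:
    """Gaussian lattice kernel exp(−e² / (2 α(t)²))."""
    if alpha_t <= 0:
        raise ValueError("radius must be > 0")
    return float(np.exp(-(e ** 2) / (2.0 * alpha_t ** 2)))


def _lattice_distances(rows: int, cols: int, bmu: tuple[int, int]) -> np.ndarray:
    jj, kk = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.sqrt((jj - bmu[0]) ** 2 + (kk - bmu[1]) ** 2)


def update_weights(grid: SOMGrid, y: np.ndarray, bmu: tuple[int, int], t: int) -> SOMGrid:
    """One competitive-learning step x(t+1) = x(t) + β(t)·γ(t)·(y − x(t)) on all nodes."""
    beta_t = decayed(grid.beta0, t, grid.lam)
    alpha_t = decayed(grid.alpha0, t, grid.lam)
    e = _lattice_distances(grid.rows, grid.cols, bmu)
    gamma = np.exp(-(e ** 2) / (2.0 * alpha_t ** 2))
    grid.weights += (beta_t * gamma)[:, :, None] * (np.asarray(y, dtype=float) - grid.weights)
    return grid


def quantization_error(grid: SOMGrid, X: np.ndarray) -> float:
    """Mean Euclidean distance from each input to its BMU."""
    W = grid.weights.reshape(-1, grid.weights.shape[2])
    d = np.sqrt(((np.asarray(X, dtype=float)[:, None, :] - W[None]) ** 2).sum(axis=2))
    return float(d.min(axis=1).mean())


def train_som(inputs, config: SOMConfig | None = None) -> SOMGrid:
    """Train a SOM on profile vectors (or any 2D array of inputs).

    Presentations follow a seeded cyclic order (one random permutation,
    cycled); the quantization error is recorded after every full pass.
    """
    config = config or SOMConfig()
    if hasattr(inputs[0], "emotion_fractions"):
        X = np.array([p.emotion_fractions for p in inputs], dtype=float)
    else:
        X = np.asarray(inputs, dtype=float)
    if X.ndim != 2 or len(X) < 1:
        raise ValueError("need at least one input vector")
    n, dim = X.shape
    o = config.n_iter if config.n_iter is not None else 1000 * n
    if o <= 0:
        raise ValueError("iteration budget must be positive")
    alpha0 = config.alpha0 if config.alpha0 is not None else max(config.rows, config.cols) / 2.0
    lam = config.lam if config.lam is not None else o / max(np.log(alpha0), 1e-9)

    rng = np.random.default_rng(config.seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    W = lo + rng.random((config.rows, config.cols, dim)) * span
    grid = SOMGrid(weights=W, alpha0=alpha0, beta0=config.beta0, lam=lam,
                   n_iter=o, seed=config.seed)
    grid.quantization_errors.append(quantization_error(grid, X))  # pre-training QE
    order = rng.permutation(n)
    for t in range(o):
        y = X[order[t % n]]
        bmu = find_bmu(grid, y)
        update_weights(grid, y, bmu, t)
        if (t + 1) % n == 0:
            grid.quantization_errors.append(quantization_error(grid, X))
    if len(grid.quantization_errors) == 1:
        grid.quantization_errors.append(quantization_error(grid, X))
    return grid


def kmeans_partition(grid: SOMGrid, k: int = 4, seed: int = 0) -> np.ndarray:
    """Partition the codebook vectors into ``k`` clusters.

    Returns a (rows, cols) array of cluster ids.  Seeded k-means++ with
    20 restarts, best inertia kept; scikit-learn guarantees non-empty
    clusters by re-seeding from distant points.
    """
    n_nodes = grid.rows * grid.cols
    if k > n_nodes:
        raise ValueError("k cannot exceed the number of nodes")
    km = KMeans(n_clusters=k, n_init=20, random_state=seed)
    labels = km.fit_predict(grid.weights.reshape(n_nodes, -1))
    return labels.reshape(grid.rows, grid.cols)


def rank_to_category(org_rank: int) -> str:
    """Rank rule: 1–5 → high, 6–8 → moderate, 9–10 → low."""
    if not 1 <= org_rank <= 10:
        raise ValueError(f"org_rank must be in [1, 10], got {org_rank}")
    if org_rank <= 5:
        return "high"
    if org_rank <= 8:
        return "moderate"
    return "low"


def _dominant_emotion(fractions: np.ndarray) -> str:
    best = max(TIE_PRIORITY, key=lambda e: (fractions[EMOTIONS.index(e)],
                                            -TIE_PRIORITY.index(e)))
    return best


def build_org_profiles(ranks: np.ndarray, emotion_labels: np.ndarray) -> list[OrgProfile]:
    """Aggregate per-employee predicted emotions into per-rank profiles."""
    ranks = np.asarray(ranks, dtype=int)
    labels = np.asarray(emotion_labels, dtype=int)
    profiles = []
    for r in sorted(set(ranks.tolist())):
        mask = ranks == r
        frac = np.bincount(labels[mask], minlength=len(EMOTIONS)).astype(float)
        frac /= frac.sum()
        profiles.append(OrgProfile(org_rank=int(r), n_employees=int(mask.sum()),
                                   emotion_fractions=frac))
    return profiles


def categorize_competitiveness(
    profiles: list[OrgProfile],
    grid: SOMGrid | None = None,
    cluster_map: np.ndarray | None = None,
) -> CompetitivenessReport:
    """Assign each organization a cluster and a competitiveness category.

    With a trained grid and cluster map, the category comes from the
    dominant emotion of the organization's cluster centroid (the mean
    profile of member organizations); without them, directly from the
    organization's own dominant emotion.  Ties resolve pessimistically
    (angry > neutral > happy > excited).
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    P = np.array([p.emotion_fractions for p in profiles])

    if grid is not None and cluster_map is not None:
        clusters = np.array([cluster_map[find_bmu(grid, p)] for p in P])
    else:
        clusters = np.full(len(profiles), -1)

    centroid: dict[int, np.ndarray] = {}
    members: dict[int, list[int]] = {}
    for c in sorted(set(clusters.tolist())):
        mask = clusters == c
        centroid[c] = P[mask].mean(axis=0)
        members[c] = [profiles[i].org_rank for i in np.flatnonzero(mask)]

    org_rows = []
    for p, c in zip(profiles, clusters):
        basis = centroid[c] if c >= 0 else p.emotion_fractions
        dom = _dominant_emotion(basis)
        org_rows.append({
            "org_rank": p.org_rank, "n_employees": p.n_employees,
            **{f"frac_{e}": p.emotion_fractions[i] for i, e in enumerate(EMOTIONS)},
            "cluster": int(c), "dominant_emotion": dom,
            "category": EMOTION_CATEGORY[dom],
        })
    cluster_rows = []
    for c in sorted(centroid):
        dom = _dominant_emotion(centroid[c])
        cluster_rows.append({
            "cluster": int(c),
            **{f"centroid_{e}": centroid[c][i] for i, e in enumerate(EMOTIONS)},
            "dominant_emotion": dom, "category": EMOTION_CATEGORY[dom],
            "member_orgs": ",".join(str(r) for r in members[c]),
        })
    return CompetitivenessReport(per_org=pd.DataFrame(org_rows),
                                 per_cluster=pd.DataFrame(cluster_rows))


def u_matrix(grid: SOMGrid) -> np.ndarray:
    """Mean distance of each node's weight to its 4-neighborhood (for plotting)."""
    W = grid.weights
    rows, cols = grid.rows, grid.cols
    U = np.zeros((rows, cols))
    for j in range(rows):
        for k in range(cols):
            ds = []
            for dj, dk in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                jj, kk = j + dj, k + dk
                if 0 <= jj < rows and 0 <= kk < cols:
                    ds.append(np.linalg.norm(W[j, k] - W[jj, kk]))
            U[j, k] = float(np.mean(ds))
    return U
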