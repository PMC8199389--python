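"""Synthetic study-population generator.

The study population is 1200 employee observations spread over 10
organizations (ranked 1–10 by competitiveness), each observation carrying
demographics (gender, age, height, weight, BMI), wearable physiological
features (blood volume pulse, galvanic skin response, skin temperature),
the two circumplex affect scores (valence, arousal) and one of four
emotion labels: neutral, happy, excited, angry.

Only per-class marginal moments (mean ± SD) and pairwise Pearson
correlations of the seven continuous features were published, so each
emotion class is modeled as a multivariate Gaussian with the published
mean/SD vectors and the published correlation matrix projected to the
nearest positive-semidefinite matrix (the printed pairwise values need
not form a valid joint correlation matrix; for these tables they do, and
the projection is then an exact identity).  Height is not published:
it is drawn as N(170, 10) cm and weight back-derived from the sampled BMI
so that the BMI = weight/height² identity holds exactly.

All sampling is driven by :class:`numpy.random.Generator` seeded
explicitly; identical seeds give byte-identical datasets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Emotion labels in integer-encoding order: neutral→0, happy→1,
#: excited→2, angry→3.
EMOTIONS: tuple[str, ...] = ("neutral", "happy", "excited", "angry")

#: The seven continuous features with published per-class statistics.
STAT_FEATURES: tuple[str, ...] = ("age", "bmi", "bvp", "gsr", "skt", "valence", "arousal")

#: Published class sizes at n=1200 (neutral, happy, excited, angry).
CLASS_COUNTS: dict[str, int] = {"neutral": 320, "happy": 349, "excited": 295, "angry": 236}

#: Published per-rank participant counts for ranks 1..10 (sum 1200).
RANK_COUNTS: tuple[int, ...] = (130, 131, 121, 127, 123, 135, 100, 125, 110, 98)

#: Published per-class mean and SD for each of STAT_FEATURES.
CLASS_MOMENTS: dict[str, dict[str, tuple[float, float]]] = {
    "angry": {
        "age": (39.72, 14.38), "bmi": (22.50, 3.50), "bvp": (34.81, 1.43),
        "gsr": (5.67, 0.67), "skt": (29.14, 0.18), "valence": (2.45, 0.82),
        "arousal": (7.41, 0.85),
    },
    "happy": {
        "age": (46.26, 11.50), "bmi": (22.94, 4.27), "bvp": (35.30, 0.69),
        "gsr": (6.19, 0.05), "skt": (29.08, 0.20), "valence": (7.28, 0.60),
        "arousal": (5.74, 0.41),
    },
    "excited": {
        "age": (41.88, 7.84), "bmi": (22.64, 3.14), "bvp": (35.88, 0.42),
        "gsr": (8.15, 0.70), "skt": (28.69, 0.01), "valence": (9.28, 0.23),
        "arousal": (6.71, 0.45),
    },
    "neutral": {
        "age": (47.40, 10.47), "bmi": (22.75, 3.68), "bvp": (36.19, 0.61),
        "gsr": (4.95, 0.07), "skt": (29.02, 0.01), "valence": (5.38, 0.72),
        "arousal": (5.29, 0.44),
    },
}

#: Published pairwise Pearson correlations per class. Unlisted pairs are 0.
CLASS_CORRELATIONS: dict[str, dict[tuple[str, str], float]] = {
    "angry": {
        ("age", "bmi"): 0.49, ("age", "bvp"): -0.08, ("age", "gsr"): -0.05,
        ("age", "skt"): 0.13, ("age", "valence"): 0.14, ("age", "arousal"): -0.09,
        ("bmi", "bvp"): -0.12, ("bmi", "gsr"): 0.03, ("bmi", "skt"): 0.12,
        ("bmi", "valence"): 0.09, ("bmi", "arousal"): -0.09,
        ("bvp", "gsr"): 0.07, ("bvp", "skt"): -0.23, ("bvp", "valence"): -0.14,
        ("bvp", "arousal"): 0.08,
        ("gsr", "skt"): 0.34, ("gsr", "valence"): -0.06, ("gsr", "arousal"): -0.05,
        ("skt", "valence"): 0.10, ("skt", "arousal"): -0.49,
        ("valence", "arousal"): -0.53,
    },
    "happy": {
        ("age", "bmi"): 0.28, ("age", "bvp"): 0.06, ("age", "gsr"): 0.01,
        ("age", "skt"): 0.03, ("age", "valence"): -0.06, ("age", "arousal"): -0.04,
        ("bmi", "bvp"): 0.01, ("bmi", "gsr"): 0.06, ("bmi", "skt"): -0.06,
        ("bmi", "valence"): -0.04, ("bmi", "arousal"): 0.04,
        ("bvp", "gsr"): 0.03, ("bvp", "skt"): 0.03, ("bvp", "valence"): 0.16,
        ("bvp", "arousal"): -0.17,
        ("gsr", "skt"): -0.19, ("gsr", "valence"): 0.16, ("gsr", "arousal"): 0.09,
        ("skt", "valence"): -0.42, ("skt", "arousal"): -0.08,
        ("valence", "arousal"): 0.62,
    },
    "excited": {
        ("age", "bmi"): 0.19, ("age", "bvp"): 0.01, ("age", "gsr"): -0.04,
        ("age", "skt"): -0.03, ("age", "valence"): 0.01, ("age", "arousal"): 0.15,
        ("bmi", "bvp"): -0.08, ("bmi", "gsr"): 0.02, ("bmi", "skt"): 0.06,
        ("bmi", "valence"): 0.05, ("bmi", "arousal"): 0.13,
        ("bvp", "gsr"): 0.02, ("bvp", "skt"): 0.18, ("bvp", "valence"): -0.10,
        ("bvp", "arousal"): -0.30,
        ("gsr", "skt"): 0.01, ("gsr", "valence"): 0.06, ("gsr", "arousal"): 0.08,
        ("skt", "valence"): -0.03, ("skt", "arousal"): -0.36,
        ("valence", "arousal"): 0.35,
    },
    "neutral": {
        ("age", "bmi"): 0.24, ("age", "bvp"): -0.14, ("age", "gsr"): 0.04,
        ("age", "skt"): 0.04, ("age", "valence"): -0.11, ("age", "arousal"): -0.01,
        ("bmi", "bvp"): -0.08, ("bmi", "gsr"): 0.10, ("bmi", "skt"): 0.09,
        ("bmi", "valence"): -0.13, ("bmi", "arousal"): 0.01,
        ("bvp", "gsr"): -0.14, ("bvp", "skt"): -0.14, ("bvp", "valence"): -0.006,
        ("bvp", "arousal"): -0.005,
        ("gsr", "skt"): 0.94, ("gsr", "valence"): 0.16, ("gsr", "arousal"): 0.09,
        ("skt", "valence"): 0.19, ("skt", "arousal"): 0.11,
        ("valence", "arousal"): 0.02,
    },
}

#: Plausibility clipping ranges applied after sampling/jittering.
DEFAULT_CLIP_RANGES: dict[str, tuple[float, float]] = {
    "age": (18.0, 70.0),
    "gsr": (1e-6, np.inf),
    "skt": (25.0, 40.0),
    "valence": (1.0, 10.0),
    "arousal": (1.0, 10.0),
}

#: Fixed order of the 13 model-input features (one-hot gender expands the
#: published column list to the 13 input nodes of the classifier).
FEATURE_COLUMNS: tuple[str, ...] = (
    "org_rank", "gender_male", "gender_female", "age", "height", "weight",
    "bmi", "bvp", "gsr", "skt", "valence", "arousal", "subject_index_scaled",
)

#: Columns of the on-disk delimited table (13 raw columns + label).
CSV_COLUMNS: tuple[str, ...] = (
    "subject_id", "org_rank", "gender", "age", "height", "weight", "bmi",
    "bvp", "gsr", "skt", "valence", "arousal", "emotion",
)


@dataclass
class EmotionRecord:
    """One employee observation."""

    subject_id: str
    org_rank: int
    gender: str
    age: float
    height: float
    weight: float
    bmi: float
    bvp: float
    gsr: float
    skt: float
    valence: float
    arousal: float
    emotion: str

    def __post_init__(self) -> None:
        if not 1 <= self.org_rank <= 10:
            raise ValueError(f"org_rank must be in [1, 10], got {self.org_rank}")
        if self.emotion not in EMOTIONS:
            raise ValueError(f"unknown emotion {self.emotion!r}")


@dataclass
class ClassStatistics:
    """Gaussian parameterization of one emotion class."""

    emotion: str
    mean: np.ndarray          # 7-vector over STAT_FEATURES
    sd: np.ndarray            # 7-vector, strictly positive
    corr: np.ndarray          # 7x7 symmetric, unit diagonal
    proportion: float

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.corr = np.asarray(self.corr, dtype=float)
        if np.any(self.sd <= 0):
            raise ValueError("standard deviations must be strictly positive")
        if not np.allclose(self.corr, self.corr.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.corr), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(self.corr) > 1 + 1e-12):
            raise ValueError("correlation entries must lie in [-1, 1]")


@dataclass
class GeneratorConfig:
    """Sampling conditions of the emulated study."""

    n_base: int = 1200
    n_augmented: int = 5000
    male_fraction: float = 0.522
    rank_counts: tuple[int, ...] = RANK_COUNTS
    seed: int = 0
    clip_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLIP_RANGES))
    augment_noise_scale: float = 0.05

    def __post_init__(self) -> None:
        if self.n_augmented < self.n_base:
            raise ValueError("n_augmented must be >= n_base")
        if len(self.rank_counts) != 10:
            raise ValueError("rank_counts must have 10 entries")


def build_class_statistics() -> dict[str, ClassStatistics]:
    """Return the per-emotion Gaussian parameters embedded from the study tables.

    Correlation matrices carry the published pairwise values verbatim
    (PSD projection is applied later, at sampling time, so the raw
    published numbers remain inspectable here).
    """
    total = sum(CLASS_COUNTS.values())
    out: dict[str, ClassStatistics] = {}
    idx = {f: i for i, f in enumerate(STAT_FEATURES)}
    for emotion in EMOTIONS:
        moments = CLASS_MOMENTS[emotion]
        mean = np.array([moments[f][0] for f in STAT_FEATURES])
        sd = np.array([moments[f][1] for f in STAT_FEATURES])
        corr = np.eye(len(STAT_FEATURES))
        for (a, b), r in CLASS_CORRELATIONS[emotion].items():
            corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
        out[emotion] = ClassStatistics(
            emotion=emotion, mean=mean, sd=sd, corr=corr,
            proportion=CLASS_COUNTS[emotion] / total)
    return out


def nearest_psd(corr: np.ndarray, tol: float = 1e-10, max_iter: int = 200) -> np.ndarray:
    """Project a symmetric unit-diagonal matrix to the nearest valid correlation matrix.

    Alternates eigenvalue clipping (the Frobenius-nearest PSD matrix) with
    unit-diagonal renormalization until the minimum eigenvalue exceeds
    ``-tol``.  Already-PSD inputs are returned unchanged.
    """
    A = np.asarray(corr, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("input must be symmetric")
    B = A.copy()
    for _ in range(max_iter):
        w, V = np.linalg.eigh(B)
        if w.min() >= -tol:
            break
        B = (V * np.clip(w, 0.0, None)) @ V.T
        d = np.sqrt(np.clip(np.diag(B), 1e-12, None))
        B = B / np.outer(d, d)
        B = (B + B.T) / 2.0
        np.fill_diagonal(B, 1.0)
    return B


def _correlated_normals(n: int, corr_psd: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw n rows from N(0, corr_psd) via a symmetric eigen factor."""
    w, V = np.linalg.eigh(corr_psd)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n, corr_psd.shape[0]))
    return z @ L.T


def _clip_features(x: np.ndarray, clip_ranges: dict[str, tuple[float, float]]) -> np.ndarray:
    for f, (lo, hi) in clip_ranges.items():
        if f in STAT_FEATURES:
            j = STAT_FEATURES.index(f)
            x[:, j] = np.clip(x[:, j], lo, hi)
    return x


def sample_class(
    emotion: str,
    n: int,
    seed: int,
    *,
    male_fraction: float = 0.522,
    clip_ranges: dict[str, tuple[float, float]] | None = None,
    org_rank: int = 1,
    subject_start: int = 0,
) -> list[EmotionRecord]:
    """Sample ``n`` observations of one emotion class.

    The seven continuous features are drawn jointly Gaussian with the
    class mean/SD vectors and the PSD-projected class correlation matrix,
    then clipped to the plausibility ranges.  Height is N(170, 10) cm and
    weight follows from the sampled BMI.
    """
    if emotion not in EMOTIONS:
        raise ValueError(f"unknown emotion {emotion!r}")
    if n == 0:
        return []
    stats = build_class_statistics()[emotion]
    clip = dict(DEFAULT_CLIP_RANGES) if clip_ranges is None else clip_ranges
    rng = np.random.default_rng(seed)

    corr = nearest_psd(stats.corr)
    x = stats.mean + stats.sd * _correlated_normals(n, corr, rng)
    x = _clip_features(x, clip)

    male = rng.random(n) < male_fraction
    height = np.clip(rng.normal(170.0, 10.0, size=n), 140.0, 210.0)
    bmi = x[:, STAT_FEATURES.index("bmi")]
    weight = bmi * (height / 100.0) ** 2

    records = []
    for i in range(n):
        records.append(EmotionRecord(
            subject_id=f"S{subject_start + i:06d}",
            org_rank=org_rank,
            gender="male" if male[i] else "female",
            age=float(x[i, 0]), height=float(height[i]), weight=float(weight[i]),
            bmi=float(x[i, 1]), bvp=float(x[i, 2]), gsr=float(x[i, 3]),
            skt=float(x[i, 4]), valence=float(x[i, 5]), arousal=float(x[i, 6]),
            emotion=emotion,
        ))
    return records


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights`` (largest remainder)."""
    quotas = weights / weights.sum() * total
    base = np.floor(quotas).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    base[order[:rem]] += 1
    return base


def generate_dataset(config: GeneratorConfig | None = None) -> list[EmotionRecord]:
    """Generate the base study dataset (default 1200 records).

    Class counts are allocated deterministically by largest-remainder
    rounding of the published class proportions — at n=1200 this
    reproduces the published counts (320, 349, 295, 236) exactly.
    Organizational ranks are dealt per the published rank distribution and
    shuffled across records so that rank is independent of emotion.
    """
    config = config or GeneratorConfig()
    # Custom rank counts must partition the dataset; the default study
    # counts (which sum to 1200) are rescaled proportionally for other n.
    if sum(config.rank_counts) != config.n_base and tuple(config.rank_counts) != RANK_COUNTS:
        raise ValueError("rank_counts must sum to n_base")
    rank_counts = _largest_remainder(
        np.asarray(config.rank_counts, dtype=float), config.n_base)

    props = np.array([CLASS_COUNTS[e] for e in EMOTIONS], dtype=float)
    class_n = _largest_remainder(props, config.n_base)

    rng = np.random.default_rng(config.seed)
    records: list[EmotionRecord] = []
    offset = 0
    for emotion, n_e in zip(EMOTIONS, class_n):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        records.extend(sample_class(
            emotion, int(n_e), sub_seed,
            male_fraction=config.male_fraction,
            clip_ranges=config.clip_ranges,
            subject_start=offset))
        offset += int(n_e)

    ranks = np.repeat(np.arange(1, 11), rank_counts)
    rng.shuffle(ranks)
    for rec, rank in zip(records, ranks):
        rec.org_rank = int(rank)
    return records


def augment(
    records: list[EmotionRecord],
    target_n: int,
    noise_scale: float = 0.05,
    seed: int = 0,
    clip_ranges: dict[str, tuple[float, float]] | None = None,
) -> list[EmotionRecord]:
    """Grow a dataset to ``target_n`` records by jittered resampling.

    Added records are resampled (with replacement) within their emotion
    class and jittered with Gaussian noise of ``noise_scale`` times the
    empirical per-class, per-feature SD; weight is re-derived from the
    jittered BMI so the BMI identity is preserved.  The per-class share of
    added records follows the original class proportions, so class
    proportions change by at most one record per class.
    """
    if target_n < len(records):
        raise ValueError("target_n must be >= len(records)")
    if not records and target_n > 0:
        raise ValueError("cannot augment an empty dataset")
    clip = dict(DEFAULT_CLIP_RANGES) if clip_ranges is None else clip_ranges
    rng = np.random.default_rng(seed)

    by_class: dict[str, list[EmotionRecord]] = {e: [] for e in EMOTIONS}
    for rec in records:
        by_class[rec.emotion].append(rec)
    counts = np.array([len(by_class[e]) for e in EMOTIONS], dtype=float)
    extra = _largest_remainder(counts, target_n - len(records))

    out = list(records)
    next_id = len(records)
    jitter_feats = [f for f in STAT_FEATURES]
    for emotion, n_extra in zip(EMOTIONS, extra):
        pool = by_class[emotion]
        if n_extra and not pool:
            raise ValueError(f"no source records for class {emotion!r}")
        if not n_extra:
            continue
        feat = np.array([[getattr(r, f) for f in jitter_feats] for r in pool])
        sds = feat.std(axis=0, ddof=1) if len(pool) > 1 else np.zeros(len(jitter_feats))
        picks = rng.integers(0, len(pool), size=int(n_extra))
        noise = rng.standard_normal((int(n_extra), len(jitter_feats))) * (noise_scale * sds)
        for row, pick in enumerate(picks):
            src = pool[pick]
            x = feat[pick] + noise[row]
            x = _clip_features(x[None, :], clip)[0]
            bmi = float(x[1])
            out.append(EmotionRecord(
                subject_id=f"A{next_id:06d}",
                org_rank=src.org_rank, gender=src.gender,
                age=float(x[0]), height=src.height,
                weight=bmi * (src.height / 100.0) ** 2,
                bmi=bmi, bvp=float(x[2]), gsr=float(x[3]), skt=float(x[4]),
                valence=float(x[5]), arousal=float(x[6]),
                emotion=emotion,
            ))
            next_id += 1
    return out


def to_feature_matrix(records: list[EmotionRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Encode records as the 13-column standardized feature matrix + labels.

    Columns follow :data:`FEATURE_COLUMNS`; every column is standardized
    to zero mean / unit variance (constant columns are left at 0).  Labels
    are integer-encoded neutral→0, happy→1, excited→2, angry→3.
    """
    if not records:
        raise ValueError("records must be non-empty")
    n = len(records)
    X = np.empty((n, len(FEATURE_COLUMNS)))
    y = np.empty(n, dtype=int)
    denom = max(n - 1, 1)
    for i, r in enumerate(records):
        X[i] = (
            r.org_rank,
            1.0 if r.gender == "male" else 0.0,
            1.0 if r.gender == "female" else 0.0,
            r.age, r.height, r.weight, r.bmi, r.bvp, r.gsr, r.skt,
            r.valence, r.arousal, i / denom,
        )
        y[i] = EMOTIONS.index(r.emotion)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    X = (X - mu) / sd_safe
    X[:, sd == 0] = 0.0
    return X, y


def records_to_frame(records: list[EmotionRecord]) -> pd.DataFrame:
    """Tabulate records as a DataFrame with the on-disk column order."""
    return pd.DataFrame([dataclasses.asdict(r) for r in records], columns=CSV_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[EmotionRecord]:
    return [EmotionRecord(**{k: row[k] for k in CSV_COLUMNS}) for _, row in df.iterrows()]


def write_csv(records: list[EmotionRecord], path) -> None:
    """Write records as a comma-separated UTF-8 table (lossless round-trip)."""
    records_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def read_csv(path) -> list[EmotionRecord]:
    return frame_to_records(pd.read_csv(path))
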