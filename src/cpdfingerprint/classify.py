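"""Classifier-based TFBS calling from CPD fingerprint features.

A candidate motif occurrence is represented by induction and floored-log2
ratio values at a small set of motif-frame offsets (10 attributes for the
CCAAT/Hap2-3-5 schema, 8 for the CTTCC/Gcr1 schema).  Known bound sites are
positives; motif instances deep inside open reading frames, which are very
unlikely to be bound, serve as negatives.  Random forest, multilayer
perceptron, logistic regression, and Gaussian naive Bayes back ends are
provided; attribute usefulness can be ranked by information gain after
recursive entropy-minimization discretization with the MDL stopping rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler

from .fingerprint import InductionTrack, _offset_position
from .genome_io import GenomeSequence, GenomicInterval, MotifOccurrence, scan_motif

logger = logging.getLogger(__name__)

ALGORITHMS = ("random_forest", "multilayer_perceptron", "logistic", "naive_bayes")

MODEL_FORMAT_VERSION = 1

# Default schemas: offsets relative to the motif anchor, both data channels.
HAP235_OFFSETS = (-1.5, 0.5, 2.5, 3.5, 4.5)
GCR1_OFFSETS = (-1.5, -0.5, 0.5, 1.5)


@dataclass(frozen=True)
class FeatureSchema:
    motif_id: str
    offsets: tuple[float, ...]
    channels: tuple[str, ...] = ("induction", "log2_floored")

    def __post_init__(self) -> None:
        for ch in self.channels:
            if ch not in ("induction", "log2_floored"):
                raise ValueError(f"unknown channel {ch!r}")

    @property
    def n_attributes(self) -> int:
        return len(self.offsets) * len(self.channels)

    @property
    def attribute_names(self) -> list[str]:
        return [f"{ch}@{o:+g}" for ch in self.channels for o in self.offsets]


def hap235_schema() -> FeatureSchema:
    return FeatureSchema("CCAAT", HAP235_OFFSETS)


def gcr1_schema() -> FeatureSchema:
    return FeatureSchema("MTTCC", GCR1_OFFSETS)


@dataclass
class TrainingSet:
    schema: FeatureSchema
    X: np.ndarray
    y: np.ndarray  # 1 = bound, 0 = not_bound
    site_ids: list[str]
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValueError("duplicate site ids in training set")
        if self.X.shape[1] != self.schema.n_attributes:
            raise ValueError("feature matrix does not conform to schema")

    @property
    def n_positive(self) -> int:
        return int(self.y.sum())

    @property
    def n_negative(self) -> int:
        return int(len(self.y) - self.y.sum())


@dataclass
class ClassifierModel:
    algorithm: str
    schema: FeatureSchema
    estimator: object
    seed: int | None
    hyperparameters: dict

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Bound-class probability for each row."""
        proba = self.estimator.predict_proba(np.asarray(X, dtype=float))
        bound_col = list(self.estimator.classes_).index(1)
        return proba[:, bound_col]


@dataclass
class CVReport:
    k: int
    auc: float
    roc_points: list[tuple[float, float]]
    confusion: np.ndarray  # [[TN, FP], [FN, TP]]
    seed: int | None
    oof_probabilities: np.ndarray

    @property
    def specificity(self) -> float:
        tn, fp = self.confusion[0]
        return tn / (tn + fp)

    @property
    def sensitivity(self) -> float:
        fn, tp = self.confusion[1]
        return tp / (tp + fn)


@dataclass
class PredictionSet:
    schema: FeatureSchema
    calls: list[tuple[MotifOccurrence, float, str]]  # (site, probability, label)
    threshold: float = 0.5

    @property
    def bound_sites(self) -> list[MotifOccurrence]:
        return [site for site, _, label in self.calls if label == "bound"]


def extract_features(
    track: InductionTrack,
    genome: GenomeSequence,
    site: MotifOccurrence,
    schema: FeatureSchema,
) -> np.ndarray:
    """Channel-major feature vector at the schema offsets.

    Minus-strand sites are mirrored through the anchor exactly as in profile
    construction, so a site and its reverse-complement twin share a vector.
    """
    channels = {"induction": track.induction, "log2_floored": track.log2_floored}
    values = []
    chrom_len = genome.length(site.chrom)
    for ch in schema.channels:
        data = channels[ch]
        for o in schema.offsets:
            h = _offset_position(site, o)
            p = int(h - 0.5)
            if p < 0 or p + 2 > chrom_len:
                raise ValueError(
                    f"site {site.site_id} too close to chromosome edge for offset {o}"
                )
            values.append(
                data.get((site.chrom, "+", h), 0.0)
                + data.get((site.chrom, "-", h), 0.0)
            )
    return np.asarray(values)


def intragenic_occurrences(
    occurrences: list[MotifOccurrence],
    orfs: list[GenomicInterval],
    pattern_length: int,
    margin: int = 100,
) -> list[MotifOccurrence]:
    """Occurrences whose full match span lies >= margin bp inside an ORF."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for orf in orfs:
        if orf.end - orf.start > 2 * margin:
            trees.setdefault(orf.chrom, IntervalTree()).addi(
                orf.start + margin, orf.end - margin
            )
    kept = []
    for occ in occurrences:
        tree = trees.get(occ.chrom)
        if tree is None:
            continue
        s, e = occ.match_start, occ.match_start + pattern_length
        if any(iv.begin <= s and e <= iv.end for iv in tree.overlap(s, e)):
            kept.append(occ)
    return kept


def build_training_set(
    positives: list[MotifOccurrence],
    orfs: list[GenomicInterval],
    genome: GenomeSequence,
    pattern: str,
    track: InductionTrack,
    schema: FeatureSchema,
    n_negatives: int = 7000,
    margin: int = 100,
    seed: int = 0,
    anchor_index: int | None = None,
) -> TrainingSet:
    """Positives plus seeded uniform sample of deep-intragenic negatives."""
    if not positives:
        raise ValueError("no positive sites")
    uniq_pos: dict[str, MotifOccurrence] = {}
    for site in positives:
        if site.site_id in uniq_pos:
            logger.warning("duplicate positive site %s collapsed", site.site_id)
        uniq_pos[site.site_id] = site
    positives = list(uniq_pos.values())

    if anchor_index is None:
        anchor_index = len(pattern) // 2
    candidates = scan_motif(genome, pattern, anchor_index)
    pool = intragenic_occurrences(candidates, orfs, len(pattern), margin)
    pos_ids = set(uniq_pos)
    pool = [occ for occ in pool if occ.site_id not in pos_ids]
    if len(pool) < n_negatives:
        raise ValueError(
            f"only {len(pool)} qualifying intragenic motifs, need {n_negatives}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n_negatives, replace=False)
    negatives = [pool[i] for i in sorted(chosen)]

    sites = positives + negatives
    X = np.vstack([extract_features(track, genome, s, schema) for s in sites])
    y = np.array([1] * len(positives) + [0] * len(negatives))
    return TrainingSet(schema, X, y, [s.site_id for s in sites], seed=seed)


# ---------------------------------------------------------------------------
# Information gain with Fayyad-Irani MDL discretization
# ---------------------------------------------------------------------------

def _entropy(y: np.ndarray) -> float:
    if len(y) == 0:
        return 0.0
    _, counts = np.unique(y, return_counts=True)
    p = counts / len(y)
    return float(-np.sum(p * np.log2(p)))


def _best_cut(values: np.ndarray, y: np.ndarray) -> tuple[float, int] | None:
    """Cut index minimizing weighted class entropy (values pre-sorted)."""
    n = len(values)
    best = None
    best_ent = np.inf
    for i in range(1, n):
        if values[i] == values[i - 1]:
            continue
        ent = (i * _entropy(y[:i]) + (n - i) * _entropy(y[i:])) / n
        if ent < best_ent - 1e-12:
            best_ent = ent
            best = i
    if best is None:
        return None
    return best_ent, best


def _mdl_accepts(y: np.ndarray, y_left: np.ndarray, y_right: np.ndarray) -> bool:
    n = len(y)
    ent = _entropy(y)
    ent_l = _entropy(y_left)
    ent_r = _entropy(y_right)
    gain = ent - (len(y_left) * ent_l + len(y_right) * ent_r) / n
    k = len(np.unique(y))
    k_l = len(np.unique(y_left))
    k_r = len(np.unique(y_right))
    delta = math.log2(3**k - 2) - (k * ent - k_l * ent_l - k_r * ent_r)
    return gain > (math.log2(n - 1) + delta) / n


def _mdl_cut_points(values: np.ndarray, y: np.ndarray) -> list[float]:
    if len(np.unique(y)) < 2 or len(values) < 2:
        return []
    found = _best_cut(values, y)
    if found is None:
        return []
    _, i = found
    if not _mdl_accepts(y, y[:i], y[i:]):
        return []
    cut = (values[i - 1] + values[i]) / 2
    return (
        _mdl_cut_points(values[:i], y[:i])
        + [cut]
        + _mdl_cut_points(values[i:], y[i:])
    )


def information_gain(values: np.ndarray, y: np.ndarray) -> float:
    """Class-entropy reduction after MDL-stopped entropy discretization (bits)."""
    order = np.argsort(values, kind="stable")
    v, yy = np.asarray(values, dtype=float)[order], np.asarray(y)[order]
    cuts = _mdl_cut_points(v, yy)
    if not cuts:
        return 0.0
    bins = np.searchsorted(cuts, v, side="left")
    n = len(yy)
    cond = sum(
        np.sum(bins == b) * _entropy(yy[bins == b]) for b in np.unique(bins)
    ) / n
    return max(_entropy(yy) - cond, 0.0)


def rank_attributes_information_gain(ts: TrainingSet) -> list[tuple[str, float]]:
    """Attributes ranked by information gain, descending; ties keep schema order."""
    if len(np.unique(ts.y)) < 2:
        raise ValueError("both classes must be present")
    names = ts.schema.attribute_names
    gains = [(names[j], information_gain(ts.X[:, j], ts.y)) for j in range(ts.X.shape[1])]
    return sorted(gains, key=lambda t: -t[1])


# ---------------------------------------------------------------------------
# Training, cross-validation, prediction
# ---------------------------------------------------------------------------

def _make_estimator(algorithm: str, n_attributes: int, seed: int | None, hyper: dict):
    if algorithm == "random_forest":
        params = dict(
            n_estimators=100,
            max_features=int(math.floor(math.log2(n_attributes))) + 1,
            random_state=seed,
        )
        params.update(hyper)
        return RandomForestClassifier(**params)
    if algorithm == "multilayer_perceptron":
        params = dict(
            hidden_layer_sizes=(math.ceil((n_attributes + 2) / 2),),
            activation="logistic",
            solver="sgd",
            learning_rate_init=0.3,
            momentum=0.2,
            max_iter=500,
            # fixed-epoch training: no convergence-based early stop
            tol=0.0,
            n_iter_no_change=500,
            random_state=seed,
        )
        params.update(hyper)
        return Pipeline([
            ("scale", MinMaxScaler(feature_range=(-1, 1))),
            ("mlp", MLPClassifier(**params)),
        ])
    if algorithm == "logistic":
        params = dict(max_iter=1000, random_state=seed)
        params.update(hyper)
        return LogisticRegression(**params)
    if algorithm == "naive_bayes":
        return GaussianNB(**hyper)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def train(
    ts: TrainingSet,
    algorithm: str = "random_forest",
    hyperparameters: dict | None = None,
    seed: int = 0,
) -> ClassifierModel:
    if len(np.unique(ts.y)) < 2:
        raise ValueError("training set must contain both classes")
    hyper = dict(hyperparameters or {})
    est = _make_estimator(algorithm, ts.schema.n_attributes, seed, hyper)
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        est.fit(ts.X, ts.y)
    return ClassifierModel(algorithm, ts.schema, est, seed, hyper)


def cross_validate(
    ts: TrainingSet,
    algorithm: str = "random_forest",
    k: int = 5,
    seed: int = 0,
    hyperparameters: dict | None = None,
    threshold: float = 0.5,
) -> CVReport:
    """Stratified k-fold CV with pooled out-of-fold probabilities.

    AUC is the rank-based (Mann-Whitney) area under the pooled ROC; the
    confusion matrix is taken at the given probability threshold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    minority = min(ts.n_positive, ts.n_negative)
    if k > minority:
        raise ValueError(
            f"k={k} exceeds minority class count {minority}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.empty(len(ts.y))
    for train_idx, test_idx in skf.split(ts.X, ts.y):
        fold_ts = TrainingSet(
            ts.schema, ts.X[train_idx], ts.y[train_idx],
            [ts.site_ids[i] for i in train_idx], seed=ts.seed,
        )
        model = train(fold_ts, algorithm, hyperparameters, seed=seed)
        oof[test_idx] = model.predict_proba(ts.X[test_idx])
    auc = float(roc_auc_score(ts.y, oof))
    fpr, tpr, _ = roc_curve(ts.y, oof)
    pred = (oof >= threshold).astype(int)
    tn = int(np.sum((pred == 0) & (ts.y == 0)))
    fp = int(np.sum((pred == 1) & (ts.y == 0)))
    fn = int(np.sum((pred == 0) & (ts.y == 1)))
    tp = int(np.sum((pred == 1) & (ts.y == 1)))
    return CVReport(
        k=k,
        auc=auc,
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        confusion=np.array([[tn, fp], [fn, tp]]),
        seed=seed,
        oof_probabilities=oof,
    )


def predict_genome(
    model: ClassifierModel,
    candidates: list[MotifOccurrence],
    track: InductionTrack,
    genome: GenomeSequence,
    threshold: float = 0.5,
) -> PredictionSet:
    """Score every candidate occurrence; calls sorted by probability descending.

    Candidates whose feature window runs off a chromosome end are skipped
    (counted in the log).  Training sites present among the candidates are
    scored like any other.
    """
    if model.schema.motif_id and candidates and candidates[0].motif_id != model.schema.motif_id:
        raise ValueError(
            f"schema motif {model.schema.motif_id!r} does not match "
            f"candidate motif {candidates[0].motif_id!r}"
        )
    usable: list[MotifOccurrence] = []
    vectors: list[np.ndarray] = []
    skipped = 0
    for site in candidates:
        try:
            vectors.append(extract_features(track, genome, site, model.schema))
        except ValueError:
            skipped += 1
            continue
        usable.append(site)
    if skipped:
        logger.info("predict_genome: skipped %d edge candidates", skipped)
    if not usable:
        return PredictionSet(model.schema, [], threshold)
    probs = model.predict_proba(np.vstack(vectors))
    calls = [
        (site, float(p), "bound" if p >= threshold else "not_bound")
        for site, p in zip(usable, probs)
    ]
    calls.sort(key=lambda c: -c[1])
    n_bound = sum(1 for _, _, label in calls if label == "bound")
    logger.info(
        "predict_genome: %d/%d candidates called bound at threshold %g",
        n_bound, len(calls), threshold,
    )
    return PredictionSet(model.schema, calls, threshold)


def save_model(model: ClassifierModel, path) -> None:
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "algorithm": model.algorithm,
            "schema": model.schema,
            "estimator": model.estimator,
            "seed": model.seed,
            "hyperparameters": model.hyperparameters,
        },
        str(path),
    )


def load_model(path) -> ClassifierModel:
    blob = joblib.load(str(path))
    if blob.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format in {path}")
    return ClassifierModel(
        blob["algorithm"], blob["schema"], blob["estimator"],
        blob["seed"], blob["hyperparameters"],
    )
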