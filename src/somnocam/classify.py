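"""Four-stage sleep classification and leave-one-recording-out evaluation.

Stages follow the standard pediatric collapse of AASM scoring: W -> Wake,
N1/N2 -> Light, N3 -> Deep, R -> REM.  An extremely-randomized-trees
ensemble is trained on the six standardized per-epoch parameters, pooled
across the recordings of one age group (0-2 or 3-6 years), and evaluated
with leave-one-recording-out cross-validation: each fold holds out one
night, trains on the rest, and scores the held-out night's hypnogram.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion

from .features import FeatureMatrix, Z_COLUMNS

logger = logging.getLogger(__name__)

#: Canonical stage order used for confusion matrices and reports.
STAGES = ("Wake", "Light", "Deep", "REM")

_AASM_MAP = {
    "W": "Wake",
    "N1": "Light",
    "N2": "Light",
    "N3": "Deep",
    "R": "REM",
    # single-letter four-stage tokens used in hypnogram CSVs
    "L": "Light",
    "D": "Deep",
    # already-collapsed names pass through
    "WAKE": "Wake",
    "LIGHT": "Light",
    "DEEP": "Deep",
    "REM": "REM",
}


class LabelError(ValueError):
    """Unknown sleep-stage token."""


def map_aasm_to_four(label: str) -> str:
    """Collapse an AASM stage token to one of Wake/Light/Deep/REM.

    W -> Wake, N1 and N2 -> Light, N3 -> Deep, R -> REM.  Case-insensitive;
    four-stage tokens (W/L/D/R or full names) pass through unchanged.
    """
    token = str(label).strip().upper()
    try:
        return _AASM_MAP[token]
    except KeyError:
        raise LabelError(f"unknown sleep-stage token: {label!r}") from None


@dataclass
class Hypnogram:
    """Ordered per-30 s-epoch stage labels."""

    stages: list[str]

    def __post_init__(self) -> None:
        self.stages = [map_aasm_to_four(s) for s in self.stages]
        if not self.stages:
            raise ValueError("hypnogram must contain at least one epoch")

    def __len__(self) -> int:
        return len(self.stages)


@dataclass
class Recording:
    """One night: standardized features plus the reference hypnogram.

    When feature rows and hypnogram epochs disagree in count (video and PSG
    start asynchronously in practice) the longer side is trimmed to the
    shorter, with a warning.
    """

    recording_id: str
    age_group: str
    features: FeatureMatrix
    hypnogram: Hypnogram

    def __post_init__(self) -> None:
        n_feat, n_hyp = len(self.features), len(self.hypnogram)
        if n_feat != n_hyp:
            n = min(n_feat, n_hyp)
            warnings.warn(
                f"recording {self.recording_id}: {n_feat} feature epochs vs "
                f"{n_hyp} hypnogram epochs; trimming both to {n}",
                stacklevel=2,
            )
            self.features = FeatureMatrix(
                self.features.data.iloc[:n].reset_index(drop=True),
                recording_id=self.features.recording_id,
            )
            self.hypnogram = Hypnogram(self.hypnogram.stages[:n])


@dataclass
class EvaluationReport:
    """Confusion matrix and metrics for one fold (or a pooled evaluation)."""

    recording_id: str
    confusion: np.ndarray  # 4x4, rows = reference, columns = predicted
    per_stage: dict[str, dict[str, float]]
    total_accuracy: float  # percent
    kappa: float
    #: recording ids the fold's model was trained on (cross-validation audit)
    training_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "recording_id": self.recording_id,
            "stage_order": list(STAGES),
            "confusion": self.confusion.tolist(),
            "per_stage": self.per_stage,
            "total_accuracy": self.total_accuracy,
            "kappa": self.kappa,
            "training_ids": list(self.training_ids),
        }


def _pool(recordings: list[Recording]) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([rec.features.standardized for rec in recordings])
    y = np.concatenate([np.array(rec.hypnogram.stages) for rec in recordings])
    return X, y


def train(
    recordings: list[Recording],
    seed: int = 0,
    n_trees: int = 100,
) -> ExtraTreesClassifier:
    """Fit an extremely-randomized-trees ensemble on pooled epoch rows.

    All six standardized features are candidates at every split (the trees
    randomize the split thresholds); depth is unlimited.  Deterministic for
    a fixed seed.
    """
    if not recordings:
        raise ValueError("training set is empty")
    groups = {rec.age_group for rec in recordings}
    if len(groups) > 1:
        raise ValueError(f"recordings span multiple age groups: {sorted(groups)}")
    X, y = _pool(recordings)
    if np.isnan(X).any():
        raise ValueError("training features contain NaN")
    model = ExtraTreesClassifier(
        n_estimators=n_trees,
        max_features=None,
        random_state=seed,
    )
    model.fit(X, y)
    return model


def predict(model: ExtraTreesClassifier, features: FeatureMatrix) -> Hypnogram:
    """Predict one stage label per feature row."""
    X = features.standardized
    if X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature count mismatch: {X.shape[1]} vs model's {model.n_features_in_}"
        )
    return Hypnogram(list(model.predict(X)))


def confusion_counts(reference: Hypnogram, predicted: Hypnogram) -> np.ndarray:
    """4x4 confusion matrix (rows = reference, columns = predicted)."""
    if len(reference) != len(predicted):
        raise ValueError("reference and predicted hypnograms differ in length")
    return _sk_confusion(reference.stages, predicted.stages, labels=list(STAGES))


def per_stage_metrics(confusion: np.ndarray) -> dict[str, dict[str, float]]:
    """One-vs-rest accuracy, sensitivity and specificity per stage, in percent.

    A ratio with zero denominator (e.g. sensitivity of a stage absent from
    the reference) is reported as NaN and excluded from aggregates.
    """
    confusion = np.asarray(confusion)
    if confusion.shape != (4, 4) or (confusion < 0).any():
        raise ValueError("confusion must be a non-negative 4x4 count matrix")
    total = confusion.sum()
    out: dict[str, dict[str, float]] = {}
    for s, stage in enumerate(STAGES):
        tp = confusion[s, s]
        fn = confusion[s, :].sum() - tp
        fp = confusion[:, s].sum() - tp
        tn = total - tp - fn - fp
        out[stage] = {
            "accuracy": 100.0 * (tp + tn) / total if total else float("nan"),
            "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": 100.0 * tn / (tn + fp) if tn + fp else float("nan"),
        }
    return out


def cohens_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement from a confusion matrix.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement
    (trace/total) and p_e the agreement expected from the marginals.
    Returns 1.0 in the degenerate perfect-agreement case p_o = p_e = 1.
    """
    confusion = np.asarray(confusion, dtype=float)
    total = confusion.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    p_o = np.trace(confusion) / total
    p_e = float(confusion.sum(axis=1) @ confusion.sum(axis=0)) / total**2
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def evaluate_fold(reference: Hypnogram, predicted: Hypnogram, recording_id: str = "") -> EvaluationReport:
    confusion = confusion_counts(reference, predicted)
    total = confusion.sum()
    return EvaluationReport(
        recording_id=recording_id,
        confusion=confusion,
        per_stage=per_stage_metrics(confusion),
        total_accuracy=100.0 * np.trace(confusion) / total,
        kappa=cohens_kappa(confusion),
    )


def _nan_mean_sd(values: list[float]) -> dict[str, float]:
    arr = np.array(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return {"mean": float("nan"), "sd": float("nan")}
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return {"mean": float(arr.mean()), "sd": sd}


def aggregate_reports(reports: list[EvaluationReport]) -> dict:
    """Mean +/- SD over folds of total accuracy, kappa and per-stage metrics."""
    agg: dict = {
        "n_folds": len(reports),
        "total_accuracy": _nan_mean_sd([r.total_accuracy for r in reports]),
        "kappa": _nan_mean_sd([r.kappa for r in reports]),
        "per_stage": {},
    }
    for stage in STAGES:
        agg["per_stage"][stage] = {
            metric: _nan_mean_sd([r.per_stage[stage][metric] for r in reports])
            for metric in ("accuracy", "sensitivity", "specificity")
        }
    return agg


def loocv(
    recordings: list[Recording],
    seed: int = 0,
    n_trees: int = 100,
) -> tuple[list[EvaluationReport], dict]:
    """Leave-one-recording-out cross-validation within one age group.

    Fold f trains on every recording except f and evaluates on f alone.
    Standardization is per recording, so held-out nights need nothing from
    the training set and no information leaks across folds.
    """
    if len(recordings) < 2:
        raise ValueError("leave-one-out needs at least 2 recordings")
    reports = []
    for held_out in recordings:
        training = [rec for rec in recordings if rec.recording_id != held_out.recording_id]
        model = train(training, seed=seed, n_trees=n_trees)
        predicted = predict(model, held_out.features)
        report = evaluate_fold(held_out.hypnogram, predicted, held_out.recording_id)
        report.training_ids = [rec.recording_id for rec in training]
        reports.append(report)
        logger.info(
            "fold %s: accuracy %.1f%%, kappa %.3f",
            held_out.recording_id, reports[-1].total_accuracy, reports[-1].kappa,
        )
    return reports, aggregate_reports(reports)


def pca_projection(features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project pooled standardized features onto the top two principal components.

    Returns (coordinates of shape (n, 2), explained-variance fractions of
    the two components).  Used to visualize how the four stages occupy the
    six-parameter space.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] < 3:
        raise ValueError("need a 2-D matrix with at least 3 rows")
    centered = features - features.mean(axis=0)
    if not np.any(centered):
        raise ValueError("feature matrix has rank 0 (all rows identical)")
    pca = PCA(n_components=2)
    coords = pca.fit_transform(features)
    return coords, pca.explained_variance_ratio_
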