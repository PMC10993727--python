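"""Per-disease risk models: training protocol, 0–100 risk-score mapping and
prevalence-guided thresholds.

Each disease gets an independent one-vs-rest binary classifier (any estimator
with a ``predict_proba`` raw score in [0, 1] plugs in). Model selection keeps
the candidates that identify every validation positive (zero false negatives
at their operating threshold) and picks the one with the fewest false
positives. Raw scores are mapped onto a 0–100 scale through the empirical CDF
of a healthy calibration cohort, and the high-risk threshold is set so that
the expected flag rate among healthy subjects is ``recall_multiplier`` times
the disease prevalence.
"""

from __future__ import annotations

import json
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import select_features
from .registry import DiseaseDefinition

HIGH_RISK = "high"
LOW_RISK = "low"


class RiskModelError(ValueError):
    pass


# --------------------------------------------------------------------------
# Algorithm registry: the nine classical families plus anything the user adds.

def _make_algorithms() -> dict[str, Callable[[int], object]]:
    return {
        "logistic_regression": lambda seed: make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed)
        ),
        "linear_discriminant_analysis": lambda seed: LinearDiscriminantAnalysis(),
        "decision_tree": lambda seed: DecisionTreeClassifier(random_state=seed),
        "random_forest": lambda seed: RandomForestClassifier(
            n_estimators=100, random_state=seed, n_jobs=1
        ),
        "extra_trees": lambda seed: ExtraTreesClassifier(
            n_estimators=100, random_state=seed, n_jobs=1
        ),
        "gradient_boosting": lambda seed: HistGradientBoostingClassifier(random_state=seed),
        "adaboost": lambda seed: AdaBoostClassifier(random_state=seed),
        "svm": lambda seed: make_pipeline(
            StandardScaler(), SVC(probability=True, random_state=seed)
        ),
        "knn": lambda seed: KNeighborsClassifier(),
    }


ALGORITHMS: dict[str, Callable[[int], object]] = _make_algorithms()

#: Fast default subset used by the end-to-end pipeline.
DEFAULT_ALGORITHMS: tuple[str, ...] = ("logistic_regression", "random_forest", "gradient_boosting")


def register_algorithm(algorithm_id: str, factory: Callable[[int], object]) -> None:
    """Register a custom classifier factory (``factory(seed) -> estimator``)."""
    ALGORITHMS[algorithm_id] = factory


# --------------------------------------------------------------------------
# Train/test split

def split_train_test(
    frame: pd.DataFrame,
    ratio: float = 0.8,
    stratify_by: Sequence | None = None,
    seed: int = 0,
    strict: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test split (default 8:2), stratified.

    With stratification every stratum contributes ``round(ratio * n)`` rows to
    the training side and at least one row to each side. A stratum with fewer
    than 2 members cannot appear on both sides; with ``strict=True`` this is
    an error (simulate a larger cohort), otherwise such rows are pooled with
    the background stratum.
    """
    if not 0 < ratio < 1:
        raise RiskModelError(f"ratio must lie in (0, 1), got {ratio}")
    n = len(frame)
    rng = np.random.default_rng(seed)
    if stratify_by is None:
        strata = pd.Series(["_all"] * n, index=frame.index)
    else:
        strata = pd.Series(list(stratify_by), index=frame.index).fillna("_background")
        counts = strata.value_counts()
        small = counts[(counts < 2) & (counts.index != "_background")]
        if len(small):
            msg = (
                f"strata with < 2 members: {dict(small)}; "
                "simulate a larger (or more enriched) cohort"
            )
            if strict:
                raise RiskModelError(msg)
            warnings.warn(msg + "; pooling with background", stacklevel=2)
            strata = strata.where(~strata.isin(small.index), "_background")
    train_idx: list = []
    test_idx: list = []
    for value in sorted(strata.unique(), key=str):
        members = strata.index[strata == value].to_numpy()
        perm = rng.permutation(len(members))
        k = int(round(ratio * len(members)))
        if len(members) >= 2:
            k = min(max(k, 1), len(members) - 1)
        train_idx.extend(members[perm[:k]])
        test_idx.extend(members[perm[k:]])
    return frame.loc[sorted(train_idx)], frame.loc[sorted(test_idx)]


# --------------------------------------------------------------------------
# Models

@dataclass
class TrainedDiseaseModel:
    disease: str
    algorithm: str
    features: tuple[str, ...]
    estimator: object
    seed: int
    #: Raw-score threshold used during model selection (zero-FN point).
    operating_threshold: float | None = None

    def score(self, features: pd.DataFrame) -> np.ndarray:
        """Raw risk score in [0, 1] for each row."""
        X = features.loc[:, list(self.features)].to_numpy(dtype=float)
        proba = self.estimator.predict_proba(X)
        classes = list(getattr(self.estimator, "classes_", [0, 1]))
        return np.clip(proba[:, classes.index(1)], 0.0, 1.0)


def fit_disease_model(
    features: pd.DataFrame,
    labels: Sequence,
    algorithm: str = "random_forest",
    seed: int = 0,
    disease: str = "",
    feature_subset: Sequence[str] | None = None,
) -> TrainedDiseaseModel:
    """Fit one binary disease scorer on a feature matrix."""
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise RiskModelError(f"{disease or 'model'}: training labels contain a single class")
    if algorithm not in ALGORITHMS:
        raise RiskModelError(
            f"unknown algorithm {algorithm!r}; registered: {sorted(ALGORITHMS)}"
        )
    cols = list(feature_subset) if feature_subset is not None else list(features.columns)
    est = ALGORITHMS[algorithm](seed)
    est.fit(features.loc[:, cols].to_numpy(dtype=float), y)
    return TrainedDiseaseModel(
        disease=disease, algorithm=algorithm, features=tuple(cols), estimator=est, seed=seed
    )


def zero_fn_threshold(positive_scores: np.ndarray) -> float:
    """Largest raw threshold that still flags every positive."""
    if len(positive_scores) == 0:
        raise RiskModelError("no positive scores to derive a zero-FN threshold")
    return float(np.min(positive_scores))


def select_best_model(
    candidates: Sequence[TrainedDiseaseModel],
    features_val: pd.DataFrame,
    labels_val: Sequence,
    set_thresholds: bool = True,
) -> TrainedDiseaseModel:
    """Pick the candidate with zero validation false negatives and the fewest
    false positives (ties broken by algorithm id).

    With ``set_thresholds=True`` each candidate's operating threshold is first
    set to its zero-FN point on the validation positives. If no candidate
    achieves zero FN at its threshold, fall back to maximum sensitivity, then
    minimum FP, with a warning.
    """
    if not candidates:
        raise RiskModelError("no candidate models")
    y = np.asarray(labels_val).astype(int)
    stats = []
    for model in candidates:
        scores = model.score(features_val)
        if set_thresholds and y.sum() > 0:
            model.operating_threshold = zero_fn_threshold(scores[y == 1])
        thr = model.operating_threshold if model.operating_threshold is not None else 0.5
        predicted = scores >= thr
        fn = int(np.sum(y[~predicted] == 1))
        fp = int(np.sum(y[predicted] == 0))
        stats.append((model, fn, fp))
    zero_fn = [s for s in stats if s[1] == 0]
    if zero_fn:
        pool = zero_fn
    else:
        warnings.warn(
            "no candidate reached zero false negatives on validation; "
            "falling back to maximum sensitivity",
            stacklevel=2,
        )
        min_fn = min(s[1] for s in stats)
        pool = [s for s in stats if s[1] == min_fn]
    pool.sort(key=lambda s: (s[2], s[0].algorithm))
    return pool[0][0]


# --------------------------------------------------------------------------
# Risk-score mapping and thresholds

@dataclass(frozen=True)
class RiskCalibration:
    """Sorted raw scores of a healthy calibration cohort."""

    healthy_scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.sort(np.asarray(self.healthy_scores, dtype=float))
        if scores.size == 0:
            raise RiskModelError("empty risk-score calibration")
        if scores.size < 1000:
            warnings.warn(
                f"risk calibration built from only {scores.size} healthy scores "
                "(>= 1000 recommended)",
                stacklevel=3,
            )
        object.__setattr__(self, "healthy_scores", scores)


def map_risk_score(raw_score, calibration: RiskCalibration):
    """Map raw scores onto [0, 100] via the healthy-cohort empirical CDF.

    The ECDF is linearly interpolated between the plotting positions
    ``(i + 0.5) / n``; scores below every healthy score map to 0 and scores at
    or above the healthy maximum map to 100. The mapping is monotone
    non-decreasing in the raw score by construction.
    """
    s = calibration.healthy_scores
    n = s.size
    positions = (np.arange(n) + 0.5) / n * 100.0
    raw = np.asarray(raw_score, dtype=float)
    mapped = np.interp(raw, s, positions, left=0.0, right=100.0)
    mapped = np.where(raw >= s[-1], 100.0, mapped)
    mapped = np.where(raw < s[0], 0.0, mapped)
    return float(mapped) if np.isscalar(raw_score) else mapped


def calibrate_threshold(
    mapped_scores: Sequence[float],
    prevalence: float,
    recall_multiplier: float = 5.0,
) -> float:
    """Smallest 0–100 score whose exceedance in the healthy calibration cohort
    is at most ``recall_multiplier × prevalence``.

    Flagging at this threshold gives an expected healthy flag rate of about
    ``recall_multiplier × prevalence``. When even the top calibration score is
    too frequent, 100.0 is returned (only scores at the ceiling flag).
    """
    if recall_multiplier < 1:
        raise RiskModelError("recall_multiplier must be >= 1")
    target = recall_multiplier * prevalence
    if target >= 1:
        raise RiskModelError("recall_multiplier × prevalence must be < 1")
    scores = np.sort(np.asarray(mapped_scores, dtype=float))
    n = scores.size
    if n == 0:
        raise RiskModelError("empty calibration scores")
    allowed = int(np.floor(target * n))
    # tail counts at each distinct value: count(scores >= v)
    for v in np.unique(scores):
        tail = n - np.searchsorted(scores, v, side="left")
        if tail <= allowed:
            return float(v)
    return 100.0


@dataclass(frozen=True)
class RiskAssessment:
    record_id: str
    disease: str
    raw_score: float
    mapped_score: float
    classification: str


def assess_cohort(
    features: pd.DataFrame,
    models: Mapping[str, TrainedDiseaseModel],
    calibrations: Mapping[str, RiskCalibration],
    thresholds: Mapping[str, float],
    record_ids: Sequence[str] | None = None,
    diseases: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Score every (record, disease) pair; one row each.

    Returns a frame with ``record_id, disease, raw_score, mapped_score,
    classification``; a record is screen-positive when any disease is high.
    """
    names = list(diseases) if diseases is not None else sorted(models)
    missing = [d for d in names if d not in models]
    if missing:
        raise RiskModelError(f"missing trained model for disease(s): {', '.join(missing)}")
    ids = list(record_ids) if record_ids is not None else [str(i) for i in range(len(features))]
    chunks = []
    for d in names:
        raw = models[d].score(features)
        mapped = map_risk_score(raw, calibrations[d])
        chunks.append(
            pd.DataFrame(
                {
                    "record_id": ids,
                    "disease": d,
                    "raw_score": raw,
                    "mapped_score": mapped,
                    "classification": np.where(mapped >= thresholds[d], HIGH_RISK, LOW_RISK),
                }
            )
        )
    if not chunks:
        return pd.DataFrame(
            columns=["record_id", "disease", "raw_score", "mapped_score", "classification"]
        )
    return pd.concat(chunks, ignore_index=True)


def record_positive(assessments: pd.DataFrame) -> pd.Series:
    """Record-level result: positive iff any disease is classified high."""
    if len(assessments) == 0:
        return pd.Series(dtype=bool)
    return (
        assessments.assign(high=assessments["classification"] == HIGH_RISK)
        .groupby("record_id", sort=False)["high"]
        .any()
    )


# --------------------------------------------------------------------------
# High-level training over a registry

@dataclass
class RiskModelBundle:
    models: dict[str, TrainedDiseaseModel]
    calibrations: dict[str, RiskCalibration]
    thresholds: dict[str, float]
    selected_features: dict[str, tuple[str, ...]]
    skipped: tuple[str, ...] = ()
    #: False negatives of each selected model on its validation positives at
    #: the operating threshold (zero unless the fallback selection fired).
    validation_fn: dict[str, int] = field(default_factory=dict)


def train_risk_models(
    features: pd.DataFrame,
    truth_disease: Sequence,
    registry: Sequence[DiseaseDefinition],
    algorithms: Sequence[str] = DEFAULT_ALGORITHMS,
    seed: int = 0,
    ratio: float = 0.8,
    ig_threshold: float = 0.001,
    redundancy_r: float = 0.95,
    recall_multiplier: float = 5.0,
    min_positives: int = 2,
) -> RiskModelBundle:
    """Full training protocol over all registry diseases.

    The feature matrix is split 8:2 stratified by true disease; per disease,
    features are selected by information gain on the training side, each
    candidate algorithm is fitted, the zero-FN/min-FP rule picks the winner on
    the held-out side, and the winner is calibrated on held-out healthy
    subjects. Diseases with fewer than ``min_positives`` positives are skipped
    with a warning.
    """
    truth = pd.Series(list(truth_disease)).reset_index(drop=True)
    feats = features.reset_index(drop=True)
    train_f, test_f = split_train_test(
        feats, ratio=ratio, stratify_by=truth, seed=seed, strict=False
    )
    truth_train = truth.loc[train_f.index]
    truth_test = truth.loc[test_f.index]
    healthy_test = test_f.loc[truth_test.isna() | (truth_test == "")]

    ss = np.random.SeedSequence(seed)
    disease_seeds = ss.generate_state(len(registry) * len(algorithms)) % (2**31)

    bundle = RiskModelBundle({}, {}, {}, {}, ())
    skipped = []
    k = 0
    for d in registry:
        y_train = (truth_train == d.abbreviation).to_numpy()
        y_test = (truth_test == d.abbreviation).to_numpy()
        if y_train.sum() < 1 or y_test.sum() < 1 or (y_train.sum() + y_test.sum()) < min_positives:
            warnings.warn(
                f"{d.abbreviation}: fewer than {min_positives} positives in the "
                "training cohort; no model trained (simulate a larger or more "
                "enriched cohort)",
                stacklevel=2,
            )
            skipped.append(d.abbreviation)
            k += len(algorithms)
            continue
        selected = select_features(
            train_f, y_train, ig_threshold=ig_threshold, redundancy_r=redundancy_r
        )
        if not selected:
            selected = list(train_f.columns)
        candidates = []
        for algo in algorithms:
            candidates.append(
                fit_disease_model(
                    train_f,
                    y_train,
                    algorithm=algo,
                    seed=int(disease_seeds[k]),
                    disease=d.abbreviation,
                    feature_subset=selected,
                )
            )
            k += 1
        best = select_best_model(candidates, test_f, y_test)
        val_scores = best.score(test_f)
        bundle.validation_fn[d.abbreviation] = int(
            np.sum(val_scores[y_test] < best.operating_threshold)
        )
        calibration = RiskCalibration(best.score(healthy_test))
        mapped_healthy = map_risk_score(calibration.healthy_scores, calibration)
        threshold = calibrate_threshold(
            mapped_healthy, d.prevalence, recall_multiplier=recall_multiplier
        )
        bundle.models[d.abbreviation] = best
        bundle.calibrations[d.abbreviation] = calibration
        bundle.thresholds[d.abbreviation] = threshold
        bundle.selected_features[d.abbreviation] = tuple(selected)
    bundle.skipped = tuple(skipped)
    return bundle


# --------------------------------------------------------------------------
# Bundle persistence (pickle per model + JSON sidecar)

def save_bundle(bundle: RiskModelBundle, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sidecar = {}
    for abbr, model in bundle.models.items():
        stem = abbr.replace("/", "_")
        with open(directory / f"{stem}.pkl", "wb") as fh:
            pickle.dump(model, fh)
        sidecar[abbr] = {
            "file": f"{stem}.pkl",
            "algorithm": model.algorithm,
            "features": list(model.features),
            "seed": model.seed,
            "operating_threshold": model.operating_threshold,
            "threshold": bundle.thresholds[abbr],
            "calibration_scores": bundle.calibrations[abbr].healthy_scores.tolist(),
        }
    (directory / "bundle.json").write_text(
        json.dumps({"models": sidecar, "skipped": list(bundle.skipped)}, indent=1)
    )


def load_bundle(directory: str | Path) -> RiskModelBundle:
    directory = Path(directory)
    meta = json.loads((directory / "bundle.json").read_text())
    bundle = RiskModelBundle({}, {}, {}, {}, tuple(meta.get("skipped", ())))
    for abbr, entry in meta["models"].items():
        with open(directory / entry["file"], "rb") as fh:
            model = pickle.load(fh)
        bundle.models[abbr] = model
        bundle.thresholds[abbr] = entry["threshold"]
        bundle.calibrations[abbr] = RiskCalibration(np.asarray(entry["calibration_scores"]))
        bundle.selected_features[abbr] = tuple(entry["features"])
    return bundle
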