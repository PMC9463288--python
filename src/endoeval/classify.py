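"""Distance-based feature selection and endoscope-type classification.

The learner roster mirrors a standard interactive classification toolbox:
six SVM variants (linear, quadratic, cubic and fine/medium/coarse Gaussian
kernel scales), six k-nearest-neighbour variants (fine/medium/coarse k,
cosine and cubic Minkowski metrics, distance weighting), a decision tree and
five tree/subspace ensembles. Kernel scales and neighbour counts follow the
toolbox's fine/medium/coarse conventions (kernel scale sqrt(P)/4, sqrt(P),
4 sqrt(P) for P features; k = 1, 10, 100).

Feature selection keeps a metric iff any cell of its row in the full median
distance map reaches the upper 15% of distance values, i.e. at least 85% of
the map's maximum cell.

Evaluation is stratified k-fold cross-validated accuracy on min-max
normalised tables, with fold assignments fixed by seed and shared across
learners. Folds split by attempt, matching the row-wise table construction;
a participant-grouped mode (the statistically safer choice, since attempts
of one participant are correlated) is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    RandomForestClassifier,
)
from sklearn.metrics import accuracy_score
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .distance import DistanceMap
from .table import ANNOTATION_COLS, canonical_columns

__all__ = [
    "LEARNER_FAMILIES",
    "LearnerSpec",
    "ClassificationReport",
    "make_learner",
    "select_top_distance",
    "train_eval",
    "evaluate_roster",
    "report",
]

LEARNER_FAMILIES = (
    "svm-linear",
    "svm-quadratic",
    "svm-cubic",
    "svm-rbf-fine",
    "svm-rbf-medium",
    "svm-rbf-coarse",
    "knn-fine",
    "knn-medium",
    "knn-coarse",
    "knn-cosine",
    "knn-cubic-metric",
    "knn-weighted",
    "tree",
    "bagged-trees",
    "boosted-trees",
    "subspace-discriminant",
    "subspace-knn",
    "rus-boosted-trees",
)


@dataclass(frozen=True)
class LearnerSpec:
    family: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in LEARNER_FAMILIES:
            raise ValueError(f"unknown learner family {self.family!r}")


def _rbf_gamma(n_features: int, scale_factor: float) -> float:
    # toolbox kernel scale s -> rbf gamma = 1 / (2 s^2), s = factor * sqrt(P)
    s = scale_factor * np.sqrt(n_features)
    return 1.0 / (2.0 * s * s)


def make_learner(spec: LearnerSpec | str, n_features: int, seed: int = 0):
    """Instantiate a seeded scikit-learn estimator for a roster family."""
    if isinstance(spec, str):
        spec = LearnerSpec(spec)
    fam, hp = spec.family, dict(spec.hyperparameters)
    if fam == "svm-linear":
        return SVC(kernel="linear", C=hp.get("C", 1.0), random_state=seed)
    if fam in ("svm-quadratic", "svm-cubic"):
        deg = 2 if fam == "svm-quadratic" else 3
        return SVC(
            kernel="poly", degree=deg, coef0=1.0, gamma="scale",
            C=hp.get("C", 1.0), random_state=seed,
        )
    if fam.startswith("svm-rbf"):
        factor = {"fine": 0.25, "medium": 1.0, "coarse": 4.0}[fam.rsplit("-", 1)[1]]
        return SVC(kernel="rbf", gamma=_rbf_gamma(n_features, factor),
                   C=hp.get("C", 1.0), random_state=seed)
    if fam.startswith("knn"):
        kind = fam.split("-", 1)[1]
        k = {"fine": 1, "medium": 10, "coarse": 100}.get(kind, 10)
        kw: dict = {"n_neighbors": hp.get("k", k)}
        if kind == "cosine":
            kw["metric"] = "cosine"
        elif kind == "cubic-metric":
            kw.update(metric="minkowski", p=3)
        elif kind == "weighted":
            kw["weights"] = "distance"
        return KNeighborsClassifier(**kw)
    if fam == "tree":
        return DecisionTreeClassifier(random_state=seed)
    if fam == "bagged-trees":
        return RandomForestClassifier(n_estimators=hp.get("n_estimators", 30),
                                      random_state=seed)
    if fam == "boosted-trees":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=3, random_state=seed),
            n_estimators=hp.get("n_estimators", 30), random_state=seed,
        )
    if fam == "subspace-discriminant":
        return BaggingClassifier(
            estimator=LinearDiscriminantAnalysis(),
            n_estimators=hp.get("n_estimators", 30),
            max_features=hp.get("max_features", 0.5),
            bootstrap=False, random_state=seed,
        )
    if fam == "subspace-knn":
        return BaggingClassifier(
            estimator=KNeighborsClassifier(n_neighbors=1),
            n_estimators=hp.get("n_estimators", 30),
            max_features=hp.get("max_features", 0.5),
            bootstrap=False, random_state=seed,
        )
    if fam == "rus-boosted-trees":
        # boosting on a seeded random undersample of the majority class
        return _RusBoost(n_estimators=hp.get("n_estimators", 30), seed=seed)
    raise AssertionError(fam)


class _RusBoost:
    """AdaBoost on a random-undersampled (class-balanced) training set."""

    def __init__(self, n_estimators: int = 30, seed: int = 0):
        self.n_estimators = n_estimators
        self.seed = seed
        self._model = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=3, random_state=seed),
            n_estimators=n_estimators, random_state=seed,
        )

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        rng = np.random.default_rng(self.seed)
        classes, counts = np.unique(y, return_counts=True)
        n_min = counts.min()
        keep = np.concatenate(
            [rng.choice(np.flatnonzero(y == c), size=n_min, replace=False)
             for c in classes]
        )
        keep.sort()
        self._model.fit(X[keep], y[keep])
        return self

    def predict(self, X):
        return self._model.predict(X)

    def get_params(self, deep=True):  # allows sklearn.clone
        return {"n_estimators": self.n_estimators, "seed": self.seed}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        self.__init__(self.n_estimators, self.seed)
        return self


def select_top_distance(dmap: DistanceMap, fraction: float = 0.15) -> list[str]:
    """Metrics whose full-map row reaches the upper ``fraction`` of distances.

    A metric is retained iff any cell in its row is at least
    ``(1 - fraction) * max cell`` of the full map. Falls back to all metrics
    (with a warning) if nothing qualifies.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    cells = dmap.full.to_numpy()
    maxval = np.nanmax(cells)
    threshold = (1.0 - fraction) * maxval
    keep = np.nanmax(cells, axis=1) >= threshold
    selected = [m for m, k in zip(dmap.full.index, keep) if k]
    if not selected:
        warnings.warn("top-distance selection is empty; keeping all features")
        return list(dmap.full.index)
    return selected


def _folds(tbl: pd.DataFrame, y, folds: int, seed: int, group_by_participant: bool):
    if group_by_participant:
        cv = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
        return list(cv.split(np.zeros(len(y)), y, groups=tbl["participant"]))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(cv.split(np.zeros(len(y)), y))


def train_eval(
    tbl: pd.DataFrame,
    spec: LearnerSpec | str,
    features: list[str] | None = None,
    folds: int = 5,
    seed: int = 0,
    group_by_participant: bool = False,
    _splits=None,
) -> float:
    """Cross-validated accuracy (%) of one learner predicting the endoscope mode.

    ``tbl`` must be a normalised feature table with both classes present;
    the stratified fold split is fixed by ``seed`` so every learner of a
    roster sees identical folds.
    """
    y = tbl["endoscope"].to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("classification needs both endoscope classes")
    if features is None:
        features = [c for c in canonical_columns() if c in tbl.columns]
    X = tbl[features].to_numpy(dtype=float)
    splits = _splits or _folds(tbl, y, folds, seed, group_by_participant)
    accs = []
    for tr, te in splits:
        model = make_learner(spec, n_features=X.shape[1], seed=seed)
        if isinstance(model, KNeighborsClassifier) and model.n_neighbors > len(tr):
            model.set_params(n_neighbors=len(tr))
        model.fit(X[tr], y[tr])
        accs.append(accuracy_score(y[te], model.predict(X[te])))
    return 100.0 * float(np.mean(accs))


def evaluate_roster(
    tbl: pd.DataFrame,
    features_all: list[str] | None = None,
    features_top: list[str] | None = None,
    roster: tuple[str, ...] = LEARNER_FAMILIES,
    folds: int = 5,
    seed: int = 0,
    group_by_participant: bool = False,
) -> pd.DataFrame:
    """Accuracy of every roster learner with all features and the top-15% subset.

    Returns a frame indexed by learner with columns ``all`` (and ``top15``
    when a subset is supplied); identical fold splits across learners.
    """
    y = tbl["endoscope"].to_numpy()
    splits = _folds(tbl, y, folds, seed, group_by_participant)
    rows = {}
    for fam in roster:
        row = {
            "all": train_eval(tbl, fam, features_all, folds, seed, _splits=splits)
        }
        if features_top is not None:
            row["top15"] = train_eval(tbl, fam, features_top, folds, seed, _splits=splits)
        rows[fam] = row
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class ClassificationReport:
    """Per-exercise accuracy grid with the best learner flagged per column."""

    accuracies: pd.DataFrame  # index: learner; columns: (exercise, feature set)
    folds: int
    seed: int

    @property
    def best(self) -> pd.Series:
        return self.accuracies.idxmax(axis=0)


def report(per_exercise: dict[int, pd.DataFrame], folds: int = 5, seed: int = 0) -> ClassificationReport:
    """Combine per-exercise roster results into one report table."""
    frames = {ex: df for ex, df in sorted(per_exercise.items())}
    combined = pd.concat(frames, axis=1)  # columns: (exercise, set)
    return ClassificationReport(accuracies=combined, folds=folds, seed=seed)
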