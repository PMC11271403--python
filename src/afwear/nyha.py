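"""End-of-trial NYHA class prediction from wearable embeddings or clinic measures.

Three feature sets are compared: the 32-dimensional first-week wearable
embedding; conventional trial measures (ECG heart rate plus 6-minute-walk
distance, time and speed); and the embedding combined with clinical
factors (age, gender, BMI).  The classifier is an L2-regularized
(ridge) logistic regression trained against label-smoothed targets,
evaluated strictly out-of-fold so no prediction comes from a model that
saw that patient.

NYHA is binarized by default — class I/II (mild) versus III/IV (marked
limitation) — which keeps a single F1 and AUROC well-defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.model_selection import StratifiedKFold

from .cohort import PatientProfile
from .ssl import PatientEmbedding

logger = logging.getLogger(__name__)

CONVENTIONAL_FEATURES = ("ecg_hr_bpm", "smw_distance_m", "smw_time_s", "smw_speed_m_s")
CLINICAL_FEATURES = ("age_years", "gender_woman", "bmi_kg_m2")
NYHA_ORDER = ("I", "II", "III", "IV")
L2_GRID = (0.01, 0.1, 1.0, 10.0)


@dataclass
class FeatureSet:
    name: str
    patient_ids: list[str]
    matrix: np.ndarray
    feature_names: list[str]


@dataclass
class ClassifierFit:
    weights: np.ndarray           # last outer fold's (intercept, coefs)
    l2_strength: float
    label_smoothing_eps: float
    classes: tuple[str, ...]
    cv_scheme: str


@dataclass
class PredictionResult:
    """Out-of-fold per-patient predictions for a binary NYHA target."""

    patient_ids: list[str]
    true_class: np.ndarray        # 0 = NYHA I/II, 1 = NYHA III/IV
    predicted_class: np.ndarray
    predicted_probability: np.ndarray   # P(class 1)

    def __post_init__(self) -> None:
        if not (len(self.patient_ids) == len(self.true_class)
                == len(self.predicted_class) == len(self.predicted_probability)):
            raise ValueError("prediction arrays must align")
        if np.any((self.predicted_probability < 0) | (self.predicted_probability > 1)):
            raise ValueError("probabilities must lie in [0, 1]")


def binarize_nyha(nyha_class: str) -> int:
    if nyha_class not in NYHA_ORDER:
        raise ValueError(f"unknown NYHA class {nyha_class!r}")
    return int(NYHA_ORDER.index(nyha_class) >= 2)


def make_features(profiles: list[PatientProfile],
                  embeddings: dict[str, PatientEmbedding] | None,
                  which: str) -> FeatureSet:
    """Assemble a feature matrix; column order fixed as documented.

    ``wearable``: e1..e32.  ``conventional``: ECG HR, 6MW distance, time,
    speed.  ``wearable_plus_clinical``: e1..e32, age, woman indicator,
    BMI.  Patients missing a required embedding are excluded with a
    logged reason.  Standardization is deferred to fitting time (training-
    fold statistics only).
    """
    needs_embedding = which in ("wearable", "wearable_plus_clinical")
    if needs_embedding and not embeddings:
        raise ValueError(f"feature set '{which}' needs embeddings")
    rows, ids = [], []
    for p in profiles:
        if needs_embedding and p.patient_id not in embeddings:
            logger.info("patient %s excluded from '%s' features: no embedding",
                        p.patient_id, which)
            continue
        clinical = {"age_years": p.age_years,
                    "gender_woman": float(p.gender == "woman"),
                    "bmi_kg_m2": p.bmi_kg_m2}
        if which == "wearable":
            rows.append(embeddings[p.patient_id].vector)
        elif which == "conventional":
            rows.append([getattr(p, f) for f in CONVENTIONAL_FEATURES])
        elif which == "wearable_plus_clinical":
            rows.append(np.concatenate([embeddings[p.patient_id].vector,
                                        [clinical[f] for f in CLINICAL_FEATURES]]))
        else:
            raise ValueError(f"unknown feature set {which!r}")
        ids.append(p.patient_id)
    matrix = np.asarray(rows, dtype=float)
    if which == "wearable":
        names = [f"e{i+1}" for i in range(matrix.shape[1])]
    elif which == "conventional":
        names = list(CONVENTIONAL_FEATURES)
    else:
        names = [f"e{i+1}" for i in range(matrix.shape[1] - 3)] + list(CLINICAL_FEATURES)
    return FeatureSet(name=which, patient_ids=ids, matrix=matrix, feature_names=names)


def _fit_smoothed_logistic(X: np.ndarray, y_smooth: np.ndarray,
                           l2: float) -> np.ndarray:
    """Minimize mean BCE against smoothed targets + (l2/2)||w||^2 (no
    penalty on the intercept).  Returns (intercept, w)."""
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])

    def obj(theta):
        z = Xd @ theta
        # stable log(1+e^z) and sigmoid
        ll = np.mean(np.logaddexp(0.0, z) - y_smooth * z)
        pen = 0.5 * l2 * np.sum(theta[1:] ** 2)
        prob = 1.0 / (1.0 + np.exp(-z))
        grad = Xd.T @ (prob - y_smooth) / n
        grad[1:] += l2 * theta[1:]
        return ll + pen, grad

    res = minimize(obj, np.zeros(p + 1), jac=True, method="L-BFGS-B",
                   options={"maxiter": 500})
    return res.x


def _standardize(Xtr, X):
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (Xtr - mu) / sd, (X - mu) / sd


def fit_ridge_logistic(features: FeatureSet, labels: dict[str, str] | np.ndarray,
                       l2: float | None = None, eps_smooth: float = 0.1,
                       cv_folds: int = 5, seed: int = 0
                       ) -> tuple[ClassifierFit, PredictionResult]:
    """Out-of-fold label-smoothed ridge-logistic predictions.

    Targets are binary NYHA (III/IV = 1) smoothed as
    ``y' = y (1 - eps) + eps/2``.  When ``l2`` is None, it is chosen per
    outer fold by an inner 3-fold log-loss grid over {0.01, 0.1, 1, 10}.
    Features are standardized with training-fold statistics only.
    """
    X = features.matrix
    if isinstance(labels, dict):
        y = np.array([binarize_nyha(labels[pid]) for pid in features.patient_ids])
    else:
        y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class")
    if not 0.0 <= eps_smooth <= 1.0:
        raise ValueError("eps_smooth must lie in [0, 1]")

    n = len(y)
    folds = min(cv_folds, int(np.bincount(y).min()))
    if folds < 2:
        raise ValueError("too few patients in the minority class for CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    prob_oof = np.full(n, np.nan)
    theta_last, l2_last = None, l2
    for tr, te in skf.split(X, y):
        l2_fold = l2 if l2 is not None else _select_l2(X[tr], y[tr], eps_smooth, seed)
        Xtr, Xte = _standardize(X[tr], X[te])
        y_smooth = y[tr] * (1.0 - eps_smooth) + eps_smooth / 2.0
        theta = _fit_smoothed_logistic(Xtr, y_smooth, l2_fold)
        prob_oof[te] = 1.0 / (1.0 + np.exp(-(np.column_stack(
            [np.ones(len(te)), Xte]) @ theta)))
        theta_last, l2_last = theta, l2_fold

    fit = ClassifierFit(weights=theta_last, l2_strength=float(l2_last),
                        label_smoothing_eps=eps_smooth,
                        classes=("I-II", "III-IV"),
                        cv_scheme=f"stratified {folds}-fold, seed {seed}")
    preds = PredictionResult(patient_ids=list(features.patient_ids),
                             true_class=y,
                             predicted_class=(prob_oof >= 0.5).astype(int),
                             predicted_probability=prob_oof)
    return fit, preds


def _select_l2(X, y, eps_smooth, seed, grid=L2_GRID, inner_folds=3):
    folds = min(inner_folds, int(np.bincount(y).min()))
    if folds < 2:
        return grid[len(grid) // 2]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + 1)
    best, best_loss = grid[0], np.inf
    for l2 in grid:
        losses = []
        for tr, te in skf.split(X, y):
            Xtr, Xte = _standardize(X[tr], X[te])
            y_smooth = y[tr] * (1.0 - eps_smooth) + eps_smooth / 2.0
            theta = _fit_smoothed_logistic(Xtr, y_smooth, l2)
            z = np.column_stack([np.ones(len(te)), Xte]) @ theta
            losses.append(np.mean(np.logaddexp(0.0, z) - y[te] * z))
        if np.mean(losses) < best_loss:
            best, best_loss = l2, float(np.mean(losses))
    return best
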