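"""Classifier evaluation: F1, AUROC, bootstrap CIs, chance level, model comparison.

F1 and AUROC are computed from confusion counts and ranks directly (they
are called hundreds of thousands of times inside bootstrap and
permutation loops); both are cross-checked against scikit-learn and
brute-force enumeration in the test suite.  Confidence intervals are
patient-level percentile bootstrap; the chance F1 level is the expected
F1 when predictions are a random permutation of the true labels; and two
models are compared by a paired patient-level bootstrap of their F1
difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial

import numpy as np
from scipy.stats import rankdata

from .nyha import PredictionResult


@dataclass
class F1Result:
    f1: float
    ci95: tuple[float, float]
    n_boot: int
    averaging: str
    seed: int

    def __post_init__(self) -> None:
        if not self.ci95[0] - 1e-12 <= self.f1 <= self.ci95[1] + 1e-12:
            raise ValueError("point estimate outside its CI")


@dataclass
class ComparisonResult:
    model_a: str
    model_b: str
    delta_f1: float
    p_value: float
    method: str


def _as_arrays(preds) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    if isinstance(preds, PredictionResult):
        return (np.asarray(preds.true_class), np.asarray(preds.predicted_class),
                np.asarray(preds.predicted_probability))
    y, yhat = preds
    return np.asarray(y), np.asarray(yhat), None


def _binary_f1(y: np.ndarray, yhat: np.ndarray, positive=1) -> float:
    tp = np.sum((yhat == positive) & (y == positive))
    fp = np.sum((yhat == positive) & (y != positive))
    fn = np.sum((yhat != positive) & (y == positive))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom > 0 else 0.0   # zero-division convention: 0


def f1_score(preds, averaging: str = "binary") -> float:
    """F1 = 2 * precision * recall / (precision + recall).

    ``binary`` scores the positive class (label 1); ``macro`` and
    ``weighted`` average one-vs-rest F1 over the classes present in the
    true labels.  Empty input is an error; a class never predicted
    contributes 0 (zero-division convention).
    """
    y, yhat, _ = _as_arrays(preds)
    if y.size == 0:
        raise ValueError("no predictions to score")
    if averaging == "binary":
        return float(_binary_f1(y, yhat))
    classes = np.unique(y)
    per_class = np.array([_binary_f1(y, yhat, positive=c) for c in classes])
    if averaging == "macro":
        return float(per_class.mean())
    if averaging == "weighted":
        w = np.array([(y == c).sum() for c in classes], dtype=float)
        return float((per_class * w).sum() / w.sum())
    raise ValueError(f"unknown averaging {averaging!r}")


def bootstrap_ci(preds, metric=f1_score, n_boot: int = 2000,
                 seed: int = 0, level: float = 0.95) -> tuple[float, float]:
    """Patient-level percentile bootstrap CI for a metric.

    Resamples patients with replacement; resamples on which the metric is
    undefined (for example a single-class draw for AUROC) are skipped and
    counted, and an error is raised if every resample degenerates.
    """
    y, yhat, prob = _as_arrays(preds)
    if y.size < 2:
        raise ValueError("need >= 2 patients to bootstrap")
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(y.size, size=y.size)
        try:
            if prob is not None and metric is auroc:
                vals.append(metric((y[idx], prob[idx])))
            else:
                vals.append(metric((y[idx], yhat[idx])))
        except ValueError:
            continue
    if not vals:
        raise ValueError("all bootstrap resamples were degenerate")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def f1_with_ci(preds, averaging: str = "binary", n_boot: int = 2000,
               seed: int = 0) -> F1Result:
    point = f1_score(preds, averaging=averaging)
    lo, hi = bootstrap_ci(preds, metric=lambda p: f1_score(p, averaging=averaging),
                          n_boot=n_boot, seed=seed)
    return F1Result(f1=point, ci95=(min(lo, point), max(hi, point)),
                    n_boot=n_boot, averaging=averaging, seed=seed)


def chance_f1(labels, n_perm: int = 10_000, seed: int = 0,
              averaging: str = "binary") -> float:
    """Expected F1 when predictions are a random permutation of the labels.

    Exact enumeration of distinct permutations when feasible (n <= 8),
    Monte-Carlo otherwise.  This is the chance line against which model
    F1 is judged.
    """
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("chance level undefined for a single class")
    n = y.size
    n_distinct = factorial(n)
    for c in np.unique(y):
        n_distinct //= factorial(int((y == c).sum()))
    if n <= 8:
        perms = set(permutations(y.tolist()))
        return float(np.mean([f1_score((y, np.array(p)), averaging=averaging)
                              for p in perms]))
    rng = np.random.default_rng(seed)
    return float(np.mean([f1_score((y, rng.permutation(y)), averaging=averaging)
                          for _ in range(n_perm)]))


def permutation_pvalue(preds, n_perm: int = 2000, seed: int = 0,
                       averaging: str = "binary") -> float:
    """P(F1 under label permutation >= observed F1), one-sided."""
    y, yhat, _ = _as_arrays(preds)
    obs = f1_score((y, yhat), averaging=averaging)
    rng = np.random.default_rng(seed)
    hits = sum(f1_score((rng.permutation(y), yhat), averaging=averaging) >= obs
               for _ in range(n_perm))
    return float((hits + 1) / (n_perm + 1))


def compare_models_paired(preds_a: PredictionResult, preds_b: PredictionResult,
                          n_boot: int = 10_000, seed: int = 0,
                          averaging: str = "binary") -> ComparisonResult:
    """Paired patient-level bootstrap of the F1 difference of two models.

    Both models must be evaluated on the same patients.  The two-sided
    p-value is ``2 * min(P(delta <= 0), P(delta >= 0))`` over the
    bootstrap distribution, clipped to 1.
    """
    if list(preds_a.patient_ids) != list(preds_b.patient_ids):
        raise ValueError("patient sets differ between the two models")
    y = np.asarray(preds_a.true_class)
    if np.any(y != np.asarray(preds_b.true_class)):
        raise ValueError("true labels differ between the two models")
    a, b = np.asarray(preds_a.predicted_class), np.asarray(preds_b.predicted_class)
    delta_obs = (f1_score((y, a), averaging=averaging)
                 - f1_score((y, b), averaging=averaging))
    rng = np.random.default_rng(seed)
    deltas = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(y.size, size=y.size)
        deltas[i] = (f1_score((y[idx], a[idx]), averaging=averaging)
                     - f1_score((y[idx], b[idx]), averaging=averaging))
    p = 2.0 * min(np.mean(deltas <= 0.0), np.mean(deltas >= 0.0))
    return ComparisonResult(model_a="a", model_b="b", delta_f1=float(delta_obs),
                            p_value=float(min(p, 1.0)),
                            method=f"paired patient bootstrap, {n_boot} resamples")


def auroc(preds) -> float:
    """Rank-based (Mann-Whitney) AUROC with tie correction.

    The probability that a random positive outranks a random negative;
    tied scores contribute 1/2.
    """
    if isinstance(preds, PredictionResult):
        y = np.asarray(preds.true_class)
        score = np.asarray(preds.predicted_probability)
    else:
        y, score = (np.asarray(a) for a in preds)
    pos, neg = int((y == 1).sum()), int((y == 0).sum())
    if pos == 0 or neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = rankdata(score)                    # midranks handle ties
    return float((ranks[y == 1].sum() - pos * (pos + 1) / 2.0) / (pos * neg))
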