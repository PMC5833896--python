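"""Mondrian inductive conformal binary classifier over a linear scorer.

The underlying model is a linear SVM (squared-hinge loss, L2 penalty) fit
with L-BFGS, capped at 50 optimizer iterations by default; a model that has
not converged within the cap is used as-is, with a warning. Nonconformity
is the negated signed decision value toward the hypothesized class:
``alpha(x, 1) = -d(x)`` and ``alpha(x, 0) = +d(x)`` where ``d > 0`` favors
class 1. Calibration is class-conditional (mondrian): each class keeps its
own sorted list of calibration nonconformities and gets its own p-value

    p_l = (#{alpha_i >= alpha_new} + 1) / (n_l + 1)

unsmoothed, with ties counted on the >= side — both choices make the
predictor deterministic and (weakly) conservative. The prediction set at
significance ``epsilon`` is {l : p_l > epsilon}; with a confidence level of
1 - epsilon the true label is excluded on average at most an epsilon
fraction of the time, per class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, sparse

from .errors import DegenerateDataError, InsufficientClassError

DEFAULT_EPSILON = 0.2          # screening operating point: 80% confidence
DEFAULT_CALIBRATION_FRACTION = 0.1
DEFAULT_MAX_OPT_ITERATIONS = 50
DEFAULT_REG = 1e-2


# ---------------------------------------------------------------------------
# Underlying scorer
# ---------------------------------------------------------------------------

@dataclass
class LinearScorer:
    """Linear decision function d(x) = x . w + b; d > 0 favors class 1."""

    weights: np.ndarray
    intercept: float
    n_iter: int = 0
    converged: bool = True

    def decision(self, X) -> np.ndarray:
        d = X @ self.weights
        return np.asarray(d).ravel() + self.intercept


def train_underlying(X, y: np.ndarray,
                     seed: int = 0,
                     max_opt_iterations: int = DEFAULT_MAX_OPT_ITERATIONS,
                     reg: float = DEFAULT_REG) -> LinearScorer:
    """Fit a linear SVM by L-BFGS on the squared-hinge loss.

    Objective: reg/2 ||w||^2 + mean(max(0, 1 - s_i d_i)^2) with s in {-1,+1}
    and an unpenalized intercept. Deterministic: weights start at zero, so
    ``seed`` only documents the interface shared with stochastic scorers.
    """
    y = np.asarray(y)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be 0/1")
    if len(np.unique(y)) < 2:
        raise InsufficientClassError("both classes required for training")
    s = 2.0 * y - 1.0
    n, d = X.shape
    Xc = sparse.csr_matrix(X) if sparse.issparse(X) else np.asarray(X, dtype=float)

    def objective(theta):
        w, b = theta[:d], theta[d]
        margin = np.asarray(Xc @ w).ravel() + b
        slack = np.maximum(0.0, 1.0 - s * margin)
        loss = 0.5 * reg * (w @ w) + np.mean(slack ** 2)
        coef = (-2.0 / n) * s * slack
        grad_w = np.asarray(coef @ Xc).ravel() + reg * w
        grad_b = float(np.sum(coef))
        return loss, np.concatenate([grad_w, [grad_b]])

    res = optimize.minimize(
        objective, np.zeros(d + 1), jac=True, method="L-BFGS-B",
        options={"maxiter": max_opt_iterations})
    if not res.success:
        warnings.warn(
            f"L-BFGS stopped after {res.nit} iterations without converging; "
            "using the current model", stacklevel=2)
    return LinearScorer(weights=res.x[:d], intercept=float(res.x[d]),
                        n_iter=int(res.nit), converged=bool(res.success))


# ---------------------------------------------------------------------------
# Calibration and p-values
# ---------------------------------------------------------------------------

def split_calibration(y: np.ndarray,
                      fraction: float = DEFAULT_CALIBRATION_FRACTION,
                      seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Random stratified split into (proper-training, calibration) indices.

    Per class, the calibration share is round(n_class * fraction), clamped
    so both sides keep at least one example. A class with fewer than two
    examples cannot be split and raises :class:`InsufficientClassError`.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    train_parts, cal_parts = [], []
    for label in np.unique(y):
        idx = np.flatnonzero(y == label)
        if idx.size < 2:
            raise InsufficientClassError(
                f"class {label} has {idx.size} example(s); need >= 2")
        n_cal = int(round(idx.size * fraction))
        n_cal = min(max(n_cal, 1), idx.size - 1)
        perm = rng.permutation(idx)
        cal_parts.append(perm[:n_cal])
        train_parts.append(perm[n_cal:])
    return (np.sort(np.concatenate(train_parts)),
            np.sort(np.concatenate(cal_parts)))


def nonconformity(decision: float | np.ndarray, label: int) -> float | np.ndarray:
    """Negated signed decision toward the hypothesized class."""
    if label == 1:
        return -decision
    if label == 0:
        return +decision
    raise ValueError("label must be 0 or 1")


def p_value(alpha_new: float, alphas_class: np.ndarray) -> float:
    """Unsmoothed conformal p-value: (#{alpha_i >= alpha_new} + 1) / (n + 1)."""
    alphas = np.asarray(alphas_class)
    if alphas.size == 0:
        raise DegenerateDataError("empty calibration list")
    n_ge = alphas.size - np.searchsorted(np.sort(alphas), alpha_new, side="left")
    return float((n_ge + 1) / (alphas.size + 1))


@dataclass(frozen=True)
class PredictionSet:
    """Conformal prediction set for one example: {0}, {1}, {0,1} or {}."""

    labels: frozenset
    p0: float
    p1: float

    @property
    def is_singleton(self) -> bool:
        return len(self.labels) == 1


@dataclass
class ICPClassifier:
    """Mondrian ICP: shared scorer + per-class sorted calibration alphas."""

    scorer: LinearScorer
    alphas_0: np.ndarray
    alphas_1: np.ndarray
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must be in (0, 1)")
        if len(self.alphas_0) == 0 or len(self.alphas_1) == 0:
            raise DegenerateDataError("both calibration lists must be non-empty")
        self.alphas_0 = np.sort(np.asarray(self.alphas_0, dtype=float))
        self.alphas_1 = np.sort(np.asarray(self.alphas_1, dtype=float))

    # -- construction ------------------------------------------------------

    @classmethod
    def from_calibration(cls, scorer: LinearScorer, X_cal, y_cal,
                         epsilon: float = DEFAULT_EPSILON) -> "ICPClassifier":
        """Calibrate an already-trained scorer on held-out labeled data."""
        y_cal = np.asarray(y_cal)
        d = scorer.decision(X_cal)
        return cls(scorer=scorer,
                   alphas_0=nonconformity(d[y_cal == 0], 0),
                   alphas_1=nonconformity(d[y_cal == 1], 1),
                   epsilon=epsilon)

    @classmethod
    def fit(cls, X, y,
            epsilon: float = DEFAULT_EPSILON,
            calibration_fraction: float = DEFAULT_CALIBRATION_FRACTION,
            seed: int = 0,
            max_opt_iterations: int = DEFAULT_MAX_OPT_ITERATIONS,
            reg: float = DEFAULT_REG) -> "ICPClassifier":
        """Stratified split, train the scorer, calibrate per class."""
        train_idx, cal_idx = split_calibration(y, calibration_fraction, seed)
        scorer = train_underlying(X[train_idx], np.asarray(y)[train_idx],
                                  seed=seed,
                                  max_opt_iterations=max_opt_iterations,
                                  reg=reg)
        return cls.from_calibration(scorer, X[cal_idx],
                                    np.asarray(y)[cal_idx], epsilon)

    # -- prediction --------------------------------------------------------

    def p_values(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized per-class p-values for a batch of feature rows."""
        d = self.scorer.decision(X)
        n0, n1 = self.alphas_0.size, self.alphas_1.size
        ge0 = n0 - np.searchsorted(self.alphas_0, d, side="left")
        ge1 = n1 - np.searchsorted(self.alphas_1, -d, side="left")
        return (ge0 + 1) / (n0 + 1), (ge1 + 1) / (n1 + 1)

    def predict(self, X) -> list[PredictionSet]:
        p0, p1 = self.p_values(X)
        eps = self.epsilon
        out = []
        for a, b in zip(p0, p1):
            labels = frozenset(
                l for l, p in ((0, a), (1, b)) if p > eps)
            out.append(PredictionSet(labels=labels, p0=float(a), p1=float(b)))
        return out

    def predict_set(self, x) -> PredictionSet:
        """Prediction set for a single feature row."""
        return self.predict(x.reshape(1, -1) if hasattr(x, "reshape")
                            and not sparse.issparse(x) else x)[0]

    # -- persistence -------------------------------------------------------

    FORMAT_VERSION = 1

    def save(self, path) -> None:
        """Serialize the full model state to one versioned .npz archive."""
        np.savez(path,
                 format_version=self.FORMAT_VERSION,
                 weights=self.scorer.weights,
                 intercept=self.scorer.intercept,
                 alphas_0=self.alphas_0,
                 alphas_1=self.alphas_1,
                 epsilon=self.epsilon)

    @classmethod
    def load(cls, path) -> "ICPClassifier":
        with np.load(path) as data:
            version = int(data["format_version"])
            if version != cls.FORMAT_VERSION:
                raise ValueError(f"unsupported model format version {version}")
            scorer = LinearScorer(weights=data["weights"],
                                  intercept=float(data["intercept"]))
            return cls(scorer=scorer,
                       alphas_0=data["alphas_0"],
                       alphas_1=data["alphas_1"],
                       epsilon=float(data["epsilon"]))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def efficiency(prediction_sets: Sequence[PredictionSet]) -> float:
    """Fraction of prediction sets containing exactly one label."""
    sets = list(prediction_sets)
    if not sets:
        raise DegenerateDataError("efficiency of zero predictions is undefined")
    return sum(1 for s in sets if len(s.labels) == 1) / len(sets)


@dataclass
class ErrorRates:
    """True-label exclusion rates, overall and conditioned on each class."""

    overall: float
    per_class: dict[int, float]


def error_rate(prediction_sets: Sequence[PredictionSet],
               true_labels: Iterable[int]) -> ErrorRates:
    """Fraction of examples whose true label is NOT in the prediction set."""
    sets = list(prediction_sets)
    y = np.asarray(list(true_labels))
    if len(sets) != y.size or not sets:
        raise ValueError("prediction sets and labels must align and be non-empty")
    excluded = np.array([int(lab) not in s.labels
                         for s, lab in zip(sets, y)])
    per_class = {}
    for label in (0, 1):
        mask = y == label
        if mask.any():
            per_class[label] = float(excluded[mask].mean())
    return ErrorRates(overall=float(excluded.mean()), per_class=per_class)


def export_predictions_csv(ids: Iterable[str],
                           prediction_sets: Sequence[PredictionSet],
                           path) -> None:
    """Dump one prediction round as (id, p0, p1, set) rows."""
    set_names = {frozenset(): "{}", frozenset({0}): "{0}",
                 frozenset({1}): "{1}", frozenset({0, 1}): "{0,1}"}
    with open(path, "w") as fh:
        fh.write("id,p0,p1,set\n")
        for mol_id, ps in zip(ids, prediction_sets):
            fh.write(f"{mol_id},{ps.p0!r},{ps.p1!r},"
                     f"\"{set_names[ps.labels]}\"\n")


def singleton_accuracy(prediction_sets: Sequence[PredictionSet],
                       true_labels: Iterable[int]) -> float:
    """Correct singleton predictions over all singleton predictions."""
    y = list(true_labels)
    singles = [(s, lab) for s, lab in zip(prediction_sets, y)
               if len(s.labels) == 1]
    if not singles:
        raise DegenerateDataError("no singleton predictions")
    return sum(1 for s, lab in singles if int(lab) in s.labels) / len(singles)
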