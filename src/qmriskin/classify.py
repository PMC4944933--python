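"""Control-vs-OI classification: univariate Mahalanobis rule and RBF-SVM.

Two classifiers, each evaluated by leave-one-out (LOO) cross-validation
over the 18-sample cohort:

* **Univariate Mahalanobis rule.** A sample with parameter value x is
  assigned to the group g minimizing ``|x - mu_g| / sigma_g``, i.e. the
  distance to each group mean normalized by that group's standard
  deviation. Unequal group SDs shift the decision boundary toward the
  tighter group — the property that makes T2 (control SD nearly twice the
  OI SD in the study) classify better than a nearest-mean rule would.

* **RBF-kernel SVM.** Feature columns are normalized by training-fold SDs,
  then a soft-margin SVM with Gaussian kernel is trained; the kernel
  breadth (gamma) and misclassification penalty (C) are selected per outer
  fold by an inner leave-one-out search over an exponentially spaced grid,
  gamma in [2^-6, 2^3] and C in [2^-1.5, 2^4]. All parameter subsets of
  size >= 2 (26 combinations of the five parameters) are scored.

Metrics follow the clinical convention with OI as the positive class:
sensitivity = correctly assigned OI / all OI, specificity = correctly
assigned control / all control, accuracy = correct / all (for balanced
groups, the mean of sensitivity and specificity). Test metrics pool the
held-out assignments over folds; training metrics are per-fold
resubstitution rates averaged across folds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._svm import fit_predict_rbf
from .cohort import PARAM_COLUMNS

__all__ = [
    "GroupStatsPair",
    "SVMConfig",
    "ClassificationMetrics",
    "mahalanobis_assign",
    "loo_univariate",
    "normalize_features",
    "enumerate_combinations",
    "svm_loo",
    "compute_metrics",
    "loo_driver",
]

LABELS = ("control", "OI")
POSITIVE = "OI"


@dataclass(frozen=True)
class GroupStatsPair:
    """Per-group mean and SD of one parameter (SDs must be positive)."""

    mu_control: float
    sd_control: float
    mu_oi: float
    sd_oi: float

    def __post_init__(self) -> None:
        if not (self.sd_control > 0 and self.sd_oi > 0):
            raise ValueError("group SDs must be positive (degenerate group)")


@dataclass(frozen=True)
class SVMConfig:
    """RBF-SVM grid-search settings.

    ``gamma_range`` and ``c_range`` are searched on exponentially spaced
    grids of ``n_grid`` points per axis. ``normalization`` is ``"pooled"``
    (divide each column by its training-fold SD over both groups) or
    ``"group_mean"`` (divide by the mean of the two per-group SDs).
    """

    gamma_range: tuple = (2.0 ** -6, 2.0 ** 3)
    c_range: tuple = (2.0 ** -1.5, 2.0 ** 4)
    n_grid: int = 10
    normalization: str = "pooled"

    def __post_init__(self) -> None:
        for lo, hi in (self.gamma_range, self.c_range):
            if not (0 < lo <= hi):
                raise ValueError("grid bounds must be positive and ordered")
        if self.n_grid < 1:
            raise ValueError("need at least one grid point per axis")
        if self.normalization not in ("pooled", "group_mean"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def gammas(self) -> np.ndarray:
        return np.geomspace(*self.gamma_range, self.n_grid)

    @property
    def cs(self) -> np.ndarray:
        return np.geomspace(*self.c_range, self.n_grid)


@dataclass
class ClassificationMetrics:
    """Sensitivity/specificity/accuracy for training and test sets of one
    leave-one-out experiment, with per-fold assignments for audit."""

    method: str
    parameters: tuple
    test_sensitivity: float
    test_specificity: float
    test_accuracy: float
    train_sensitivity: float
    train_specificity: float
    train_accuracy: float
    folds: list = field(default_factory=list)

    def as_row(self) -> dict:
        return {
            "parameters": "/".join(self.parameters),
            "train_sensitivity": self.train_sensitivity,
            "train_specificity": self.train_specificity,
            "train_accuracy": self.train_accuracy,
            "test_sensitivity": self.test_sensitivity,
            "test_specificity": self.test_specificity,
            "test_accuracy": self.test_accuracy,
        }


def compute_metrics(y_true, y_pred, positive: str = POSITIVE) -> dict:
    """Sensitivity, specificity and accuracy from (true, predicted) labels.

    All three are exact rational counts; rounding happens only in the
    report layer.
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    if not y_true:
        raise ValueError("no assignments")
    bad = set(y_true) | set(y_pred)
    if not bad <= set(LABELS):
        raise ValueError(f"labels outside {LABELS}: {bad - set(LABELS)}")
    pos = [(t, p) for t, p in zip(y_true, y_pred) if t == positive]
    neg = [(t, p) for t, p in zip(y_true, y_pred) if t != positive]
    n_correct = sum(t == p for t, p in zip(y_true, y_pred))
    out = {"accuracy": n_correct / len(y_true)}
    out["sensitivity"] = (
        sum(t == p for t, p in pos) / len(pos) if pos else np.nan)
    out["specificity"] = (
        sum(t == p for t, p in neg) / len(neg) if neg else np.nan)
    return out


def mahalanobis_assign(x: float, stats: GroupStatsPair) -> str:
    """Assign a value to the group with the smaller SD-normalized distance.

    Ties assign to control (deterministic and conservative).
    """
    d_control = abs(x - stats.mu_control) / stats.sd_control
    d_oi = abs(x - stats.mu_oi) / stats.sd_oi
    return "OI" if d_oi < d_control else "control"


def _group_stats(values: np.ndarray, groups: np.ndarray) -> GroupStatsPair:
    vc = values[groups == "control"]
    vo = values[groups == "OI"]
    if len(vc) < 1 or len(vo) < 1:
        raise ValueError("both groups must be represented in the training set")
    return GroupStatsPair(
        mu_control=float(vc.mean()),
        sd_control=float(vc.std(ddof=1)),
        mu_oi=float(vo.mean()),
        sd_oi=float(vo.std(ddof=1)),
    )


def _resolve_columns(table: pd.DataFrame, parameters) -> list:
    cols = []
    for p in parameters:
        col = PARAM_COLUMNS.get(p, p)
        if col not in table.columns:
            raise KeyError(f"unknown parameter {p!r}")
        cols.append(col)
    return cols


def _aggregate(method, parameters, fold_records) -> ClassificationMetrics:
    test = compute_metrics([f["true"] for f in fold_records],
                           [f["predicted"] for f in fold_records])
    train = {k: float(np.mean([f["train_metrics"][k] for f in fold_records]))
             for k in ("sensitivity", "specificity", "accuracy")}
    return ClassificationMetrics(
        method=method,
        parameters=tuple(parameters),
        test_sensitivity=test["sensitivity"],
        test_specificity=test["specificity"],
        test_accuracy=test["accuracy"],
        train_sensitivity=train["sensitivity"],
        train_specificity=train["specificity"],
        train_accuracy=train["accuracy"],
        folds=fold_records,
    )


def loo_driver(table: pd.DataFrame, build_rule, method: str,
               parameters: tuple) -> ClassificationMetrics:
    """Classifier-agnostic leave-one-out driver.

    ``build_rule(train_table)`` must return a callable mapping one row
    (a Series) to a label. Each sample is held out in turn; the rule is
    built from the remaining samples, the held-out sample is classified,
    and the rule's resubstitution performance on the training samples
    gives the per-fold training metrics.
    """
    groups = table["group"].to_numpy()
    for g in LABELS:
        if (groups == g).sum() < 2:
            raise ValueError(f"need >= 2 subjects per group, {g!r} too small")
    n = len(table)
    fold_records = []
    for i in range(n):
        tr = np.arange(n) != i
        train = table.iloc[tr]
        rule = build_rule(train)
        pred = rule(table.iloc[i])
        train_pred = [rule(row) for _, row in train.iterrows()]
        fold_records.append({
            "fold": i,
            "held_out": str(table["subject_id"].iloc[i])
            if "subject_id" in table else str(i),
            "true": groups[i],
            "predicted": pred,
            "train_metrics": compute_metrics(groups[tr], train_pred),
        })
    return _aggregate(method, tuple(parameters), fold_records)


def loo_univariate(table: pd.DataFrame, parameter: str) -> ClassificationMetrics:
    """Leave-one-out Mahalanobis classification on one parameter."""
    col = _resolve_columns(table, [parameter])[0]

    def build_rule(train):
        stats = _group_stats(train[col].to_numpy(dtype=float),
                             train["group"].to_numpy())
        return lambda row: mahalanobis_assign(float(row[col]), stats)

    return loo_driver(table, build_rule, "mahalanobis", (parameter,))


def normalize_features(table: pd.DataFrame, mode: str = "pooled",
                       parameters=None, train_index=None):
    """Divide each parameter column by its group-SD normalizer.

    The normalizer is computed on ``train_index`` rows only (all rows if
    omitted) so that a held-out sample never influences its own scaling:

    * ``pooled`` — SD of the column over the training rows, both groups
      together;
    * ``group_mean`` — mean of the two per-group training SDs.

    Returns ``(normalized table, {column: sd})``.
    """
    parameters = list(parameters or PARAM_COLUMNS)
    cols = _resolve_columns(table, parameters)
    train = table if train_index is None else table.loc[train_index]
    out = table.copy()
    sds = {}
    for col in cols:
        tv = train[col].to_numpy(dtype=float)
        if mode == "pooled":
            sd = float(np.std(tv, ddof=1))
        elif mode == "group_mean":
            g = train["group"].to_numpy()
            sd = float(np.mean([np.std(tv[g == lab], ddof=1)
                                for lab in LABELS]))
        else:
            raise ValueError(f"unknown normalization mode {mode!r}")
        if not sd > 0:
            raise ValueError(f"zero SD for column {col!r}")
        out[col] = out[col] / sd
        sds[col] = sd
    return out, sds


def enumerate_combinations(parameters=tuple(PARAM_COLUMNS), min_size: int = 2
                           ) -> list:
    """All parameter subsets of size >= ``min_size``, canonically ordered.

    Five parameters give 26 combinations (10 pairs, 10 triples,
    5 quadruples, 1 quintuple).
    """
    parameters = tuple(parameters)
    out = []
    for k in range(min_size, len(parameters) + 1):
        out.extend(itertools.combinations(parameters, k))
    return out


def _grid_search_loo(X: np.ndarray, y: np.ndarray, config: SVMConfig):
    """Inner leave-one-out accuracy over the (gamma, C) grid.

    Ties resolve toward the smallest penalty, then the smallest breadth
    (the smoother model). Returns (gamma, C).
    """
    n = len(y)
    idx = np.arange(n)
    best = None  # (accuracy, C, gamma)
    for gamma in config.gammas:
        for c in config.cs:
            correct = 0
            for j in range(n):
                tr = idx != j
                pred = fit_predict_rbf(X[tr], y[tr], X[j:j + 1], c, gamma)
                correct += int(pred[0] == y[j])
            acc = correct / n
            key = (-acc, c, gamma)
            if best is None or key < best:
                best = key
    return best[2], best[1]


def svm_loo(table: pd.DataFrame, combination, config: SVMConfig = SVMConfig(),
            seed=None) -> ClassificationMetrics:
    """Leave-one-out RBF-SVM classification on a parameter combination.

    Per outer fold: normalize features by training-fold SDs, select
    (gamma, C) by inner leave-one-out on the training samples, train the
    final model, and classify the held-out sample. The held-out sample
    never enters normalization or hyperparameter selection. ``seed`` is
    accepted for interface symmetry; the procedure is deterministic.
    """
    combination = tuple(combination)
    if len(combination) < 2:
        raise ValueError("multivariate combination needs >= 2 parameters")
    cols = _resolve_columns(table, combination)
    groups = table["group"].to_numpy()
    for g in LABELS:
        if (groups == g).sum() < 2:
            raise ValueError(f"need >= 2 subjects per group, {g!r} too small")
    X_raw = table[cols].to_numpy(dtype=float)
    y = (groups == POSITIVE).astype(int)
    n = len(y)
    idx = np.arange(n)

    fold_records = []
    for i in range(n):
        tr = idx != i
        if len(np.unique(y[tr])) < 2:
            raise ValueError("degenerate fold: single-class training set")
        sds = np.empty(len(cols))
        for k, col in enumerate(cols):
            tv = X_raw[tr, k]
            if config.normalization == "pooled":
                sd = tv.std(ddof=1)
            else:
                sd = np.mean([tv[groups[tr] == lab].std(ddof=1)
                              for lab in LABELS])
            if not sd > 0:
                raise ValueError(f"zero training SD for column {col!r}")
            sds[k] = sd
        Xn = X_raw / sds  # scaling factors from the training fold only
        gamma, c = _grid_search_loo(Xn[tr], y[tr], config)
        pred = fit_predict_rbf(Xn[tr], y[tr], Xn[i:i + 1], c, gamma)[0]
        train_pred = fit_predict_rbf(Xn[tr], y[tr], Xn[tr], c, gamma)
        to_label = np.array(LABELS)
        fold_records.append({
            "fold": i,
            "held_out": str(table["subject_id"].iloc[i])
            if "subject_id" in table else str(i),
            "true": groups[i],
            "predicted": str(to_label[pred]),
            "gamma": float(gamma),
            "C": float(c),
            "train_metrics": compute_metrics(
                groups[tr], list(to_label[train_pred])),
        })
    return _aggregate("svm_rbf", combination, fold_records)
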