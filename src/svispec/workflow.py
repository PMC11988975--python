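"""Evaluation protocol: 2:1 split, 10-fold CV model selection, metrics.

The protocol for every task is: randomly split samples 2:1 into training
and test (stratified by class for classification, by brand or level for
regression, so 15-class designs cannot lose a class from the test set);
select hyperparameters by 10-fold cross-validation on the training set
(pooled out-of-fold RMSE for regression, pooled accuracy for
classification; ties go to the first candidate in grid order); refit on
the full training set; predict the held-out test set.

Min-max normalization is fitted on training rows only and, during CV,
refitted inside each fold on that fold's training part, so no statistic
of held-out rows ever reaches a fit. ``paper_compat=True`` instead
normalizes once over all samples up front (the mildly leaky but common
order of operations in applied chemometrics work).

Metric subscripts follow chemometrics convention: _CV for pooled
cross-validation metrics, _P for held-out prediction (test) metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import models as m
from .spectra import MinMaxNormalizer, SpectraDataset
from .synth import CLASSIFICATION_TASKS, TASK_LABEL_COLUMN

__all__ = [
    "SplitPlan",
    "CVResult",
    "EvalReport",
    "StratificationError",
    "TaskConfigurationError",
    "UndefinedMetricError",
    "split_train_test",
    "make_folds",
    "cross_validate",
    "compute_metrics",
    "run_task",
    "default_grid",
    "MODEL_FAMILIES",
]

MODEL_FAMILIES = ("plsr", "plsda", "kelm")
MAX_LATENT_VARIABLES = 10
DEFAULT_FOLDS = 10


class StratificationError(ValueError):
    """A stratum is too small to appear in both halves of a split."""


class TaskConfigurationError(ValueError):
    """Dataset labels do not match the requested task/model combination."""


class UndefinedMetricError(ValueError):
    """R^2 requested for a constant true response."""


# ---------------------------------------------------------------------------
# Splitting and folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int


def _stratified_counts(sizes: list[int], target: int) -> list[int]:
    """Per-stratum training counts: floor(2/3) each, remainder distributed
    by largest fractional part (never emptying a stratum's test half)."""
    base = [int(math.floor(2 * s / 3)) for s in sizes]
    fracs = [2 * s / 3 - b for s, b in zip(sizes, base)]
    extra = target - sum(base)
    order = sorted(range(len(sizes)), key=lambda i: (-fracs[i], i))
    for i in order:
        if extra <= 0:
            break
        if base[i] < sizes[i] - 1:
            base[i] += 1
            extra -= 1
    # pathological leftover (all strata capped): place wherever room remains
    for i in range(len(sizes)):
        while extra > 0 and base[i] < sizes[i]:
            base[i] += 1
            extra -= 1
    return base


def split_train_test(n: int, seed: int = 0, strata=None) -> SplitPlan:
    """2:1 train/test split: ceil(2n/3) training rows, seeded.

    With ``strata`` (one hashable key per row) the split is drawn within
    each stratum; every stratum needs >= 2 members.
    """
    if n < 3:
        raise ValueError(f"need at least 3 samples to split 2:1, got {n}")
    target = math.ceil(2 * n / 3)
    rng = np.random.default_rng(seed)
    if strata is None:
        perm = rng.permutation(n)
        train = np.sort(perm[:target])
        test = np.sort(perm[target:])
    else:
        strata = np.asarray(strata)
        if strata.shape[0] != n:
            raise ValueError("strata length does not match n")
        keys = pd.unique(strata)
        groups = [np.flatnonzero(strata == k) for k in keys]
        for k, g in zip(keys, groups):
            if len(g) < 2:
                raise StratificationError(
                    f"stratum {k!r} has {len(g)} member(s); needs >= 2"
                )
        counts = _stratified_counts([len(g) for g in groups], target)
        train_parts, test_parts = [], []
        for g, c in zip(groups, counts):
            perm = rng.permutation(len(g))
            train_parts.append(g[perm[:c]])
            test_parts.append(g[perm[c:]])
        train = np.sort(np.concatenate(train_parts))
        test = np.sort(np.concatenate(test_parts))
    return SplitPlan(train_idx=train, test_idx=test, seed=seed)


def make_folds(n: int, k: int, seed: int = 0, strata=None) -> list[np.ndarray]:
    """k disjoint fold index arrays that exactly partition range(n);
    stratified round-robin when ``strata`` is given."""
    if not 2 <= k <= n:
        raise ValueError(f"fold count must be in [2, {n}], got {k}")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    if strata is None:
        perm = rng.permutation(n)
        for j, chunk in enumerate(np.array_split(perm, k)):
            folds[j].extend(chunk.tolist())
    else:
        strata = np.asarray(strata)
        pos = 0
        for key in pd.unique(strata):
            g = np.flatnonzero(strata == key)
            g = g[rng.permutation(len(g))]
            for idx in g:
                folds[pos % k].append(int(idx))
                pos += 1
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def compute_metrics(y_true, y_pred, kind: str, classes: list | None = None) -> dict:
    """RMSE/MAE/R^2 for regression; accuracy and a confusion matrix (fixed
    class order) for classification. R^2 = 1 - SS_res/SS_tot with SS_tot
    about the mean of ``y_true`` in the evaluated set."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape[0] != y_pred.shape[0] or y_true.shape[0] < 1:
        raise ValueError("y_true and y_pred must have equal, nonzero length")
    if kind == "regression":
        y_true = y_true.astype(np.float64)
        y_pred = y_pred.astype(np.float64)
        resid = y_true - y_pred
        rmse = float(np.sqrt(np.mean(resid**2)))
        mae = float(np.mean(np.abs(resid)))
        ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
        if ss_tot == 0.0:
            raise UndefinedMetricError("R^2 undefined: y_true is constant")
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        return {"rmse": rmse, "mae": mae, "r2": r2}
    if kind == "classification":
        if classes is None:
            classes = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
        index = {c: j for j, c in enumerate(classes)}
        conf = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred):
            conf[index[t], index[p]] += 1
        acc = float(np.mean(y_true == y_pred))
        return {"accuracy": acc, "classes": list(classes),
                "confusion": conf.tolist()}
    raise ValueError(f"kind must be 'regression' or 'classification', got {kind!r}")


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    family: str
    kind: str
    table: pd.DataFrame            # one row per candidate: params + pooled metrics
    selected: dict                 # hyperparameters of the winner
    cv_metrics: dict               # pooled out-of-fold metrics at the winner
    k: int
    seed: int


def default_grid(family: str):
    if family in ("plsr", "plsda"):
        return list(range(1, MAX_LATENT_VARIABLES + 1))
    if family == "kelm":
        return m.grid_candidates()
    raise ValueError(f"unknown model family {family!r}; expected one of {MODEL_FAMILIES}")


def _family_kind(family: str, y: np.ndarray) -> str:
    if family == "plsda":
        return "classification"
    if family == "plsr":
        return "regression"
    return "classification" if y.dtype.kind in "OUS" else "regression"


def _pls_cap(grid: list[int], n_fit: int, p: int) -> list[int]:
    amax = min(n_fit - 1, p)
    return [a for a in grid if a <= amax]


def cross_validate(
    X_train: np.ndarray,
    y_train: np.ndarray,
    family: str,
    grid=None,
    k: int = DEFAULT_FOLDS,
    seed: int = 0,
    refit_normalizer: bool = True,
) -> CVResult:
    """Pooled k-fold CV over the candidate grid.

    ``X_train`` is the raw (un-normalized) training matrix when
    ``refit_normalizer`` is true: min-max scaling is then refitted on each
    fold's fit-part so held-out rows never leak into it. With
    ``refit_normalizer`` false the matrix is used as given (pre-normalized
    upstream).
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    y_train = np.asarray(y_train)
    n = X_train.shape[0]
    if grid is None:
        grid = default_grid(family)
    if len(grid) == 0:
        raise ValueError("candidate grid is empty")
    if k > n:
        raise ValueError(f"fold count {k} exceeds training size {n}")
    kind = _family_kind(family, y_train)
    classes = sorted(set(y_train.tolist())) if kind == "classification" else None

    strata = y_train if kind == "classification" else None
    folds = make_folds(n, k, seed=seed, strata=strata)

    if family in ("plsr", "plsda"):
        grid = _pls_cap(list(grid), n - max(len(f) for f in folds), X_train.shape[1])
        if not grid:
            raise ValueError("no feasible latent-variable counts for this fold size")
        oof = {a: _empty_pred(y_train, kind, classes) for a in grid}
    else:
        grid = list(grid)
        oof = {cs: _empty_pred(y_train, kind, classes) for cs in grid}

    for fold in folds:
        fit_idx = np.setdiff1d(np.arange(n), fold)
        Xf, Xv = X_train[fit_idx], X_train[fold]
        yf = y_train[fit_idx]
        if refit_normalizer:
            norm = MinMaxNormalizer().fit(Xf)
            Xf, Xv = norm.transform(Xf), norm.transform(Xv)
        if family == "plsr":
            model = m.fit_plsr(Xf, yf.astype(np.float64), max(grid))
            for a in grid:
                oof[a][fold] = m.predict_plsr(model, Xv, n_components=a)
        elif family == "plsda":
            model = m.fit_plsda(Xf, yf, max(grid))
            for a in grid:
                oof[a][fold] = predict_from_scores(
                    m.predict_plsda_scores(model, Xv, n_components=a), model.classes
                )
        else:  # kelm
            T = (m.one_hot(yf, classes) if kind == "classification"
                 else yf.astype(np.float64))
            for C, sigma in grid:
                model = m.fit_kelm(Xf, T, C, sigma)
                pred = m.predict_kelm(model, Xv)
                if kind == "classification":
                    oof[(C, sigma)][fold] = predict_from_scores(pred, classes)
                else:
                    oof[(C, sigma)][fold] = pred

    rows = []
    for cand in grid:
        met = compute_metrics(y_train, oof[cand], kind, classes=classes)
        row = (
            {"n_components": cand} if family in ("plsr", "plsda")
            else {"C": cand[0], "sigma": cand[1]}
        )
        row.update({k_: v for k_, v in met.items() if isinstance(v, (int, float))})
        rows.append((row, met))
    table = pd.DataFrame([r for r, _ in rows])

    score_key = "accuracy" if kind == "classification" else "rmse"
    best_i = 0
    for i in range(1, len(rows)):
        cur, best = rows[i][0][score_key], rows[best_i][0][score_key]
        if (kind == "classification" and cur > best) or (
            kind == "regression" and cur < best
        ):
            best_i = i
    selected_row, selected_metrics = rows[best_i]
    selected = {k_: v for k_, v in selected_row.items()
                if k_ in ("n_components", "C", "sigma")}
    return CVResult(family=family, kind=kind, table=table, selected=selected,
                    cv_metrics=selected_metrics, k=k, seed=seed)


def _empty_pred(y: np.ndarray, kind: str, classes) -> np.ndarray:
    if kind == "regression":
        return np.full(y.shape[0], np.nan)
    return np.empty(y.shape[0], dtype=object)


def predict_from_scores(scores: np.ndarray, classes: list) -> np.ndarray:
    """Argmax decision over per-class score columns (first max wins)."""
    idx = np.argmax(np.asarray(scores), axis=1)
    return np.asarray([classes[i] for i in idx], dtype=object)


# ---------------------------------------------------------------------------
# Task runners
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    task: int
    model_family: str
    kind: str
    seed: int
    n_train: int
    n_test: int
    selected: dict
    cv_metrics: dict
    test_metrics: dict
    paper_compat: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def _task_labels(task: int, dataset: SpectraDataset) -> tuple[np.ndarray, str]:
    col = TASK_LABEL_COLUMN.get(task)
    if col is None:
        raise TaskConfigurationError(f"task must be 1..5, got {task}")
    if col not in dataset.meta.columns:
        raise TaskConfigurationError(f"dataset metadata lacks the {col!r} column")
    y = dataset.meta[col].to_numpy()
    kind = "classification" if task in CLASSIFICATION_TASKS else "regression"
    if kind == "classification":
        if any(not isinstance(v, str) or v == "" for v in y):
            raise TaskConfigurationError(f"task {task} needs class labels in {col!r}")
        y = y.astype(object)
    else:
        y = y.astype(np.float64)
        if not np.all(np.isfinite(y)):
            raise TaskConfigurationError(f"task {task} needs numeric labels in {col!r}")
    return y, kind


def _check_family(task: int, family: str, kind: str) -> None:
    if family not in MODEL_FAMILIES:
        raise TaskConfigurationError(
            f"unknown model family {family!r}; expected one of {MODEL_FAMILIES}"
        )
    if family == "plsda" and kind == "regression":
        raise TaskConfigurationError(f"plsda is a classifier; task {task} is regression")
    if family == "plsr" and kind == "classification":
        raise TaskConfigurationError(f"plsr is a regressor; task {task} is classification")


def _strata_for(task: int, dataset: SpectraDataset, y: np.ndarray):
    if task in CLASSIFICATION_TASKS:
        return y
    if task in (2, 3):
        return dataset.meta["brand"].to_numpy()
    return dataset.meta["level"].to_numpy()  # task 5


def _fit_final(family: str, X: np.ndarray, y: np.ndarray, selected: dict, classes):
    if family == "plsr":
        return m.fit_plsr(X, y.astype(np.float64), selected["n_components"])
    if family == "plsda":
        return m.fit_plsda(X, y, selected["n_components"])
    T = m.one_hot(y, classes) if classes is not None else y.astype(np.float64)
    return m.fit_kelm(X, T, selected["C"], selected["sigma"])


def _predict_final(family: str, model, X: np.ndarray, classes):
    if family == "plsr":
        return m.predict_plsr(model, X)
    if family == "plsda":
        return m.predict_plsda(model, X)
    pred = m.predict_kelm(model, X)
    if classes is not None:
        return predict_from_scores(pred, classes)
    return pred


def run_task(
    task: int,
    dataset: SpectraDataset,
    model_family: str,
    seed: int = 0,
    k: int = DEFAULT_FOLDS,
    grid=None,
    paper_compat: bool = False,
    return_model: bool = False,
):
    """Full protocol for one task: split, CV-select, refit, test, report.

    All randomness (split and fold assignment) derives from ``seed``.
    ``paper_compat`` switches to one global min-max normalization over all
    samples before the split, instead of the default leakage-free order.
    Returns the :class:`EvalReport`, plus ``(model, normalizer)`` when
    ``return_model`` is set.
    """
    y, kind = _task_labels(task, dataset)
    _check_family(task, model_family, kind)
    classes = sorted(set(y.tolist())) if kind == "classification" else None

    X = dataset.X
    strata = _strata_for(task, dataset, y)
    plan = split_train_test(dataset.n_samples, seed=seed, strata=strata)
    X_train_raw, X_test_raw = X[plan.train_idx], X[plan.test_idx]
    y_train, y_test = y[plan.train_idx], y[plan.test_idx]

    norm = MinMaxNormalizer()
    if paper_compat:
        Xn = norm.fit_transform(X)
        X_train, X_test = Xn[plan.train_idx], Xn[plan.test_idx]
        cv = cross_validate(X_train, y_train, model_family, grid=grid, k=k,
                            seed=seed, refit_normalizer=False)
    else:
        norm.fit(X_train_raw)
        X_train = norm.transform(X_train_raw)
        X_test = norm.transform(X_test_raw)
        cv = cross_validate(X_train_raw, y_train, model_family, grid=grid, k=k,
                            seed=seed, refit_normalizer=True)

    model = _fit_final(model_family, X_train, y_train, cv.selected, classes)
    y_pred = _predict_final(model_family, model, X_test, classes)
    test_metrics = compute_metrics(y_test, y_pred, kind, classes=classes)

    report = EvalReport(
        task=task, model_family=model_family, kind=kind, seed=seed,
        n_train=len(plan.train_idx), n_test=len(plan.test_idx),
        selected=cv.selected, cv_metrics=cv.cv_metrics,
        test_metrics=test_metrics, paper_compat=paper_compat,
    )
    if return_model:
        return report, model, norm
    return report
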