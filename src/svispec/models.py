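"""Chemometrics models: PLSR, PLS-DA and the kernel extreme learning machine.

All three are implemented from first principles.

PLSR extracts latent variables maximising predictor/response covariance
(NIPALS with X-deflation, one PLS1 fit per response column). The number of
latent variables A is the hyperparameter, conventionally searched in 1..10.

PLS-DA is PLSR on a one-hot class indicator matrix with an argmax decision
rule; ties break to the lowest class index.

K-ELM is a kernel ridge-style learner: output weights solve
(I/C + K) alpha = T, with the RBF kernel K(u, v) = exp(-||u - v||^2 / sigma).
C (regularisation) and sigma (kernel width) are both searched over the
logarithmic grid 2^1 .. 2^10.

Predictors are column-mean-centred inside PLS (covariance maximisation
presumes centring); any scaling such as min-max normalization happens
upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "PLSModel",
    "PLSDAModel",
    "KELMModel",
    "DegenerateFitError",
    "fit_plsr",
    "predict_plsr",
    "fit_plsda",
    "predict_plsda",
    "predict_plsda_scores",
    "fit_kelm",
    "predict_kelm",
    "rbf_kernel",
    "grid_candidates",
    "model_to_dict",
    "model_from_dict",
]

MODEL_FORMAT_VERSION = 1

_RANK_TOL = 1e-12


class DegenerateFitError(ValueError):
    """The response carries no variance to regress on."""


# ---------------------------------------------------------------------------
# PLS regression (NIPALS, PLS1 per response column)
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    n_components: int
    x_mean: np.ndarray          # (p,)
    y_mean: np.ndarray          # (m,)
    # per response column: weights W (p, a), loadings P (p, a), y-loadings q (a,)
    weights: list[np.ndarray]
    loadings: list[np.ndarray]
    y_loadings: list[np.ndarray]
    y_was_1d: bool

    @property
    def n_responses(self) -> int:
        return len(self.weights)

    def coefficients(self, n_components: int | None = None) -> np.ndarray:
        """Regression coefficients B (p, m) for centred X and y, using the
        first ``n_components`` latent variables (default: all fitted)."""
        a_req = self.n_components if n_components is None else n_components
        if not 1 <= a_req <= self.n_components:
            raise ValueError(
                f"n_components must be in [1, {self.n_components}], got {a_req}"
            )
        p = self.x_mean.shape[0]
        B = np.zeros((p, self.n_responses))
        for j in range(self.n_responses):
            W, P, q = self.weights[j], self.loadings[j], self.y_loadings[j]
            a = min(a_req, W.shape[1])  # rank may have exhausted earlier
            if a == 0:
                continue
            Wa, Pa, qa = W[:, :a], P[:, :a], q[:a]
            B[:, j] = Wa @ np.linalg.solve(Pa.T @ Wa, qa)
        return B


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, A: int):
    """Sequential NIPALS extraction on centred X (n,p) and y (n,).

    Returns W (p,a), P (p,a), q (a,) with a <= A (fewer if the predictor
    rank is exhausted). Successive scores t_a = X_a w_a are mutually
    orthogonal by construction of the deflation X <- X - t p'.
    """
    X = Xc.copy()
    y = yc.copy()
    p = X.shape[1]
    W = np.empty((p, 0))
    P = np.empty((p, 0))
    q = np.empty(0)
    for _ in range(A):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < _RANK_TOL:
            break
        w = w / nw
        t = X @ w
        tt = float(t @ t)
        if tt < _RANK_TOL:
            break
        pl = X.T @ t / tt
        ql = float(y @ t) / tt
        X -= np.outer(t, pl)
        y = y - ql * t
        W = np.column_stack([W, w])
        P = np.column_stack([P, pl])
        q = np.append(q, ql)
    return W, P, q


def fit_plsr(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit PLSR with ``n_components`` latent variables.

    ``y`` may be a vector (single response) or an (n, m) matrix; matrix
    responses are fitted one PLS1 model per column.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    y_was_1d = y.ndim == 1
    Y = y.reshape(-1, 1) if y_was_1d else y
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("X and y have different numbers of rows")
    amax = min(n - 1, p)
    if not 1 <= n_components <= amax:
        raise ValueError(
            f"n_components must be in [1, {amax}] for an {n}x{p} matrix, "
            f"got {n_components}"
        )
    if np.any(Y.std(axis=0) < _RANK_TOL):
        raise DegenerateFitError("a response column has zero variance")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    weights, loadings, y_loadings = [], [], []
    for j in range(Y.shape[1]):
        W, P, q = _nipals_pls1(Xc, Y[:, j] - y_mean[j], n_components)
        weights.append(W)
        loadings.append(P)
        y_loadings.append(q)
    return PLSModel(
        n_components=n_components, x_mean=x_mean, y_mean=y_mean,
        weights=weights, loadings=loadings, y_loadings=y_loadings,
        y_was_1d=y_was_1d,
    )


def predict_plsr(
    model: PLSModel, X_new: np.ndarray, n_components: int | None = None
) -> np.ndarray:
    """Predict responses; ``n_components`` truncates to a smaller model
    (the NIPALS components are nested, so this is the model that would
    have been fitted with that A)."""
    X_new = np.asarray(X_new, dtype=np.float64)
    B = model.coefficients(n_components)
    pred = (X_new - model.x_mean) @ B + model.y_mean
    return pred[:, 0] if model.y_was_1d else pred


# ---------------------------------------------------------------------------
# PLS discriminant analysis
# ---------------------------------------------------------------------------

@dataclass
class PLSDAModel:
    pls: PLSModel
    classes: list

    @property
    def n_components(self) -> int:
        return self.pls.n_components


def one_hot(labels: np.ndarray, classes: list) -> np.ndarray:
    """Dummy indicator matrix in the fixed class order of ``classes``."""
    index = {c: j for j, c in enumerate(classes)}
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        Y[i, index[lab]] = 1.0
    return Y


def fit_plsda(X: np.ndarray, labels, n_components: int) -> PLSDAModel:
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least 2 classes")
    Y = one_hot(labels, classes)
    return PLSDAModel(pls=fit_plsr(X, Y, n_components), classes=classes)


def predict_plsda_scores(
    model: PLSDAModel, X_new: np.ndarray, n_components: int | None = None
) -> np.ndarray:
    """Predicted dummy-variable scores, one column per class."""
    return predict_plsr(model.pls, X_new, n_components)


def predict_plsda(
    model: PLSDAModel, X_new: np.ndarray, n_components: int | None = None
) -> np.ndarray:
    """Predicted class labels: argmax over dummy columns, ties to the
    lowest class index."""
    scores = predict_plsda_scores(model, X_new, n_components)
    idx = np.argmax(scores, axis=1)  # first max = lowest class index
    return np.asarray([model.classes[i] for i in idx])


# ---------------------------------------------------------------------------
# Kernel extreme learning machine
# ---------------------------------------------------------------------------

def _sqdist(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances, clipped at 0 against roundoff."""
    aa = np.sum(A * A, axis=1)[:, None]
    bb = np.sum(B * B, axis=1)[None, :]
    return np.maximum(aa + bb - 2.0 * (A @ B.T), 0.0)


def rbf_kernel(A: np.ndarray, B: np.ndarray, sigma: float) -> np.ndarray:
    """K(u, v) = exp(-||u - v||^2 / sigma)."""
    return np.exp(-_sqdist(A, B) / sigma)


@dataclass
class KELMModel:
    C: float
    sigma: float
    X_train: np.ndarray
    alpha: np.ndarray           # (n, m) output weights
    t_was_1d: bool


def fit_kelm(X: np.ndarray, T: np.ndarray, C: float, sigma: float) -> KELMModel:
    """Solve (I/C + K) alpha = T for the output weights.

    ``T`` is an (n,) or (n, m) real target matrix (one column for
    regression, a one-hot dummy matrix for classification). The system is
    symmetric positive definite for any finite C > 0, so a Cholesky solve
    is used rather than explicit inversion.
    """
    if C <= 0 or sigma <= 0:
        raise ValueError(f"C and sigma must be positive, got C={C}, sigma={sigma}")
    X = np.asarray(X, dtype=np.float64)
    T = np.asarray(T, dtype=np.float64)
    t_was_1d = T.ndim == 1
    Tm = T.reshape(-1, 1) if t_was_1d else T
    n = X.shape[0]
    if Tm.shape[0] != n:
        raise ValueError("X and T have different numbers of rows")
    K = rbf_kernel(X, X, sigma)
    if not np.all(np.isfinite(K)):
        raise FloatingPointError("non-finite kernel entries")
    A = K + np.eye(n) / C
    alpha = cho_solve(cho_factor(A), Tm)
    return KELMModel(C=float(C), sigma=float(sigma), X_train=X.copy(),
                     alpha=alpha, t_was_1d=t_was_1d)


def predict_kelm(model: KELMModel, X_new: np.ndarray) -> np.ndarray:
    X_new = np.asarray(X_new, dtype=np.float64)
    pred = rbf_kernel(X_new, model.X_train, model.sigma) @ model.alpha
    return pred[:, 0] if model.t_was_1d else pred


def grid_candidates() -> list[tuple[float, float]]:
    """Cartesian (C, sigma) grid over {2^1..2^10} x {2^1..2^10}: 100 pairs,
    C-major order (the tie-break order for model selection)."""
    exps = [2.0**i for i in range(1, 11)]
    return [(c, s) for c in exps for s in exps]


# ---------------------------------------------------------------------------
# JSON-friendly serialization
# ---------------------------------------------------------------------------

def model_to_dict(model) -> dict:
    """Serialize any fitted model to a JSON-compatible dict."""
    d: dict = {"format_version": MODEL_FORMAT_VERSION}
    if isinstance(model, PLSModel):
        d.update(
            kind="plsr",
            n_components=model.n_components,
            x_mean=model.x_mean.tolist(),
            y_mean=model.y_mean.tolist(),
            weights=[w.tolist() for w in model.weights],
            loadings=[p.tolist() for p in model.loadings],
            y_loadings=[q.tolist() for q in model.y_loadings],
            y_was_1d=model.y_was_1d,
        )
    elif isinstance(model, PLSDAModel):
        d.update(kind="plsda", classes=list(model.classes),
                 pls=model_to_dict(model.pls))
    elif isinstance(model, KELMModel):
        d.update(
            kind="kelm", C=model.C, sigma=model.sigma,
            X_train=model.X_train.tolist(), alpha=model.alpha.tolist(),
            t_was_1d=model.t_was_1d,
        )
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    return d


def model_from_dict(d: dict):
    kind = d["kind"]
    if kind == "plsr":
        return PLSModel(
            n_components=d["n_components"],
            x_mean=np.asarray(d["x_mean"]),
            y_mean=np.asarray(d["y_mean"]),
            weights=[np.asarray(w) for w in d["weights"]],
            loadings=[np.asarray(p) for p in d["loadings"]],
            y_loadings=[np.asarray(q) for q in d["y_loadings"]],
            y_was_1d=d["y_was_1d"],
        )
    if kind == "plsda":
        return PLSDAModel(pls=model_from_dict(d["pls"]), classes=d["classes"])
    if kind == "kelm":
        return KELMModel(
            C=d["C"], sigma=d["sigma"],
            X_train=np.asarray(d["X_train"]),
            alpha=np.asarray(d["alpha"]),
            t_was_1d=d["t_was_1d"],
        )
    raise ValueError(f"unknown model kind {kind!r}")
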