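"""From ROI frame stacks to spectrum-like data.

Each acquisition of F frames becomes a length-3F feature vector: the mean
R, G and B colour level of the ROI in every frame, concatenated as an
R block (positions 0..F-1), a G block (F..2F-1) and a B block (2F..3F-1).
With the canonical F = 177 this is the 531-variable representation that
downstream chemometrics models treat like a spectrum.

Also here: the dataset container (feature matrix + per-sample metadata),
per-variable min-max normalization fitted on training rows only, and PCA
for visualising class separability.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ingest import FrameSequence, FrameFormatError

__all__ = [
    "frames_to_spectrum",
    "SpectraDataset",
    "MinMaxNormalizer",
    "PCAModel",
    "pca_project",
]


def frames_to_spectrum(seq: FrameSequence) -> np.ndarray:
    """Mean ROI colour level per frame and channel, laid out R | G | B.

    The mean is over all ROI pixels, so the result is invariant to any
    within-frame pixel permutation. Means are kept real-valued (no
    re-quantization to integer colour levels).
    """
    means = seq.frames.astype(np.float64).mean(axis=(1, 2))  # (F, 3)
    return np.concatenate([means[:, 0], means[:, 1], means[:, 2]])


@dataclass
class SpectraDataset:
    """n×p spectra matrix with aligned labels and per-sample metadata."""

    X: np.ndarray                  # (n, p) float
    meta: pd.DataFrame             # n rows; sample_id, task, brand, adulterant, level, fat, energy
    y: np.ndarray | None = None    # optional task label (class or numeric), aligned with rows

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if len(self.meta) != self.X.shape[0]:
            raise ValueError(
                f"meta has {len(self.meta)} rows but X has {self.X.shape[0]}"
            )
        if self.y is not None:
            self.y = np.asarray(self.y)
            if self.y.shape[0] != self.X.shape[0]:
                raise ValueError("y length does not match X rows")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_variables(self) -> int:
        return self.X.shape[1]

    def to_csv(self, path: str | os.PathLike) -> None:
        """Write one row per sample: columns ``v1..vp`` then metadata columns."""
        cols = [f"v{j + 1}" for j in range(self.n_variables)]
        df = pd.DataFrame(self.X, columns=cols)
        meta = self.meta.reset_index(drop=True)
        df = pd.concat([df, meta], axis=1)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "SpectraDataset":
        df = pd.read_csv(path)
        vcols = [c for c in df.columns if c.startswith("v") and c[1:].isdigit()]
        vcols.sort(key=lambda c: int(c[1:]))
        if not vcols:
            raise ValueError(f"{path}: no feature columns v1..vp found")
        meta = df[[c for c in df.columns if c not in vcols]]
        return cls(X=df[vcols].to_numpy(dtype=np.float64), meta=meta)


class MinMaxNormalizer:
    """Per-variable min-max scaling to [0, 1], fitted on training rows only.

    Apply maps x -> (x - min) / (max - min). Variables with zero training
    range map to 0 (keeps the value inside [0, 1] without dividing by
    zero). Test rows are NOT clipped, so out-of-range values land outside
    [0, 1]; this preserves their ordering for regression.
    """

    def __init__(self) -> None:
        self.mins_: np.ndarray | None = None
        self.maxs_: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.mins_ is not None

    def fit(self, X: np.ndarray) -> "MinMaxNormalizer":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D training matrix with >= 2 rows")
        self.mins_ = X.min(axis=0)
        self.maxs_ = X.max(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("normalizer must be fitted before transform")
        X = np.asarray(X, dtype=np.float64)
        rng = self.maxs_ - self.mins_
        out = np.zeros_like(X)
        nz = rng > 0
        out[:, nz] = (X[:, nz] - self.mins_[nz]) / rng[nz]
        return out

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def inverse_transform(self, Xn: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("normalizer must be fitted before inverse_transform")
        Xn = np.asarray(Xn, dtype=np.float64)
        rng = self.maxs_ - self.mins_
        return Xn * rng + self.mins_

    def to_dict(self) -> dict:
        if not self.fitted:
            raise RuntimeError("cannot serialize an unfitted normalizer")
        return {"mins": self.mins_.tolist(), "maxs": self.maxs_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "MinMaxNormalizer":
        m = cls()
        m.mins_ = np.asarray(d["mins"], dtype=np.float64)
        m.maxs_ = np.asarray(d["maxs"], dtype=np.float64)
        return m


@dataclass
class PCAModel:
    """Principal components of a centred data matrix (via SVD).

    ``components`` rows are orthonormal loadings; ``explained_variance_ratio``
    is each component's share of the total variance, non-increasing.
    """

    mean: np.ndarray
    components: np.ndarray              # (k, p)
    explained_variance_ratio: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray, k: int) -> "PCAModel":
        X = np.asarray(X, dtype=np.float64)
        n, p = X.shape
        kmax = min(n - 1, p)
        if not 1 <= k <= kmax:
            raise ValueError(f"k must be in [1, {kmax}] for an {n}x{p} matrix, got {k}")
        mean = X.mean(axis=0)
        _, s, vt = np.linalg.svd(X - mean, full_matrices=False)
        var = s**2
        total = var.sum()
        ratio = var[:k] / total if total > 0 else np.zeros(k)
        return cls(mean=mean, components=vt[:k], explained_variance_ratio=ratio)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.mean) @ self.components.T


def pca_project(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Scores of the top-k principal components and their variance fractions."""
    model = PCAModel.fit(X, k)
    return model.transform(X), model.explained_variance_ratio
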