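"""PCA dimensionality reduction with a strict train/test contract.

Principal axes are fitted on the training rows only (covariance PCA on the
raw, unstandardised features by default — with heterogeneous feature
magnitudes one component typically carries almost all variance, which is the
regime the downstream 3-input classifier expects).  Held-out rows are
*projected* onto the training axes; the model is never re-fitted on test
data.  Component signs are fixed so the largest-magnitude loading of each
axis is positive, making repeated fits bit-comparable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "PCAModel",
    "fit_pca",
    "cumulative_variance",
    "select_n_components",
    "project",
]


@dataclass
class PCAModel:
    mean: np.ndarray  # (d,)
    components: np.ndarray  # (d, k_max), orthonormal columns
    explained_variance_ratio: np.ndarray  # descending, sums to <= 1
    k_selected: int = 3
    standardize: bool = False
    scale: np.ndarray | None = None  # per-feature SD when standardize

    @property
    def k_max(self) -> int:
        return self.components.shape[1]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "k_selected": self.k_selected,
            "standardize": self.standardize,
            "scale": None if self.scale is None else self.scale.tolist(),
        }
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            mean=np.asarray(doc["mean"]),
            components=np.asarray(doc["components"]),
            explained_variance_ratio=np.asarray(doc["explained_variance_ratio"]),
            k_selected=int(doc["k_selected"]),
            standardize=bool(doc["standardize"]),
            scale=None if doc["scale"] is None else np.asarray(doc["scale"]),
        )


def fit_pca(
    train_features: np.ndarray, standardize: bool = False, k_selected: int = 3
) -> PCAModel:
    """Fit principal axes of the training covariance.

    Deterministic: axes come from the SVD of the centred data and each
    column's sign is flipped so its largest-magnitude loading is positive.
    """
    X = np.asarray(train_features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    mean = X.mean(axis=0)
    Xc = X - mean
    scale = None
    if standardize:
        scale = Xc.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
        Xc = Xc / scale
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    components = vt.T  # (d, k_max)
    # sign fix: largest-|loading| entry of each component made positive
    flip = np.sign(components[np.argmax(np.abs(components), axis=0), np.arange(components.shape[1])])
    flip[flip == 0] = 1.0
    components = components * flip
    var = s**2 / (X.shape[0] - 1)
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    k_selected = min(k_selected, components.shape[1])
    return PCAModel(
        mean=mean,
        components=components,
        explained_variance_ratio=ratio,
        k_selected=k_selected,
        standardize=standardize,
        scale=scale,
    )


def cumulative_variance(model: PCAModel) -> np.ndarray:
    """Running sum of explained-variance ratios (non-decreasing, ends at 1)."""
    return np.cumsum(model.explained_variance_ratio)


def select_n_components(
    cumulative: Sequence[float], threshold: float = 0.9999
) -> int:
    """Smallest k whose cumulative explained variance reaches the threshold."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    cum = np.asarray(cumulative, dtype=float)
    hits = np.nonzero(cum >= threshold - 1e-12)[0]
    if hits.size == 0:
        import warnings

        warnings.warn(
            "cumulative variance never reaches the threshold; keeping all "
            "components",
            stacklevel=2,
        )
        return int(cum.size)
    return int(hits[0] + 1)


def project(model: PCAModel, features: np.ndarray, k: int | None = None) -> np.ndarray:
    """Project rows onto the leading-k training axes (no re-fitting)."""
    k = model.k_selected if k is None else k
    if k > model.k_max:
        raise ValueError(f"k={k} exceeds the fitted {model.k_max} components")
    X = np.asarray(features, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} != model dimension {model.mean.shape[0]}"
        )
    Xc = X - model.mean
    if model.standardize and model.scale is not None:
        Xc = Xc / model.scale
    scores = Xc @ model.components[:, :k]
    return scores[0] if single else scores
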