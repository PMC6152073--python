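"""Bi-gram transition features from PSSMs and PCA dimensionality reduction.

The bi-gram probability descriptor summarizes a protein profile as the 400
pairwise transition weights between consecutive positions:

    B[m, n] = sum_{i=1..L-1} P[i, m] * P[i+1, n],   m, n in 1..20

flattened row-major (all transitions out of amino acid 1 first) into a
400-vector.  Feature matrices assembled over many proteins are then reduced
from 400 to 350 dimensions with centered PCA before classification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

from .pssm_io import PSSM

BIGRAM_DIM = 400


@dataclass(frozen=True)
class BigramVector:
    """400-dimensional bi-gram transition descriptor of one protein.

    Entry u = 20*(m-1) + n (1-based m, n) holds the transition weight from
    amino acid m to amino acid n.
    """

    protein_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (BIGRAM_DIM,):
            raise ValueError(
                f"bi-gram vector must have exactly {BIGRAM_DIM} entries, "
                f"got shape {self.values.shape}"
            )


@dataclass
class FeatureMatrix:
    """A labelled n_samples x d feature matrix."""

    ids: List[str]
    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if len(self.ids) != self.X.shape[0]:
            raise ValueError(
                f"{len(self.ids)} ids but {self.X.shape[0]} feature rows"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains NaN or Inf entries")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def to_csv(self, path: Union[str, Path]) -> None:
        df = pd.DataFrame(self.X, columns=[f"f{j+1}" for j in range(self.d)])
        df.insert(0, "id", self.ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "FeatureMatrix":
        df = pd.read_csv(path)
        if "id" not in df.columns:
            raise ValueError(f"{path}: missing 'id' column")
        return cls(ids=df["id"].astype(str).tolist(),
                   X=df.drop(columns="id").to_numpy(dtype=float))


def bigram_features(p: PSSM) -> BigramVector:
    """Compute the 400-d bi-gram transition vector of one PSSM.

    For a single-row PSSM the sum over consecutive position pairs is empty
    and the result is the zero vector.
    """
    P = p.scores
    if P.shape[0] < 2:
        values = np.zeros(BIGRAM_DIM)
    else:
        values = (P[:-1].T @ P[1:]).ravel()  # row-major: (m, n) -> 20*(m-1)+n
    return BigramVector(protein_id=p.protein_id, values=values)


def bigram_matrix(pssms: Sequence[PSSM]) -> FeatureMatrix:
    """Stack bi-gram vectors of many PSSMs into a FeatureMatrix."""
    vecs = [bigram_features(p) for p in pssms]
    return FeatureMatrix(ids=[v.protein_id for v in vecs],
                         X=np.vstack([v.values for v in vecs]))


@dataclass
class PCAModel:
    """Centered PCA with a deterministic per-component sign convention.

    Components are eigenvectors of the sample covariance ordered by
    decreasing eigenvalue; the largest-magnitude loading of each component
    is forced positive so projections are reproducible across linear
    algebra backends.
    """

    mean: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray
    n_components: int = field(default=350)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.components = np.asarray(self.components, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        if self.components.shape[0] != self.n_components:
            raise ValueError("components row count must equal n_components")
        if np.any(np.diff(self.explained_variance) > 1e-9):
            raise ValueError("explained_variance must be non-increasing")

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps({
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "n_components": int(self.n_components),
        }))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "PCAModel":
        obj = json.loads(Path(path).read_text())
        return cls(mean=np.array(obj["mean"]),
                   components=np.array(obj["components"]),
                   explained_variance=np.array(obj["explained_variance"]),
                   n_components=obj["n_components"])


def _fix_signs(components: np.ndarray) -> np.ndarray:
    out = components.copy()
    for row in out:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1.0
    return out


def fit_pca(X: Union[FeatureMatrix, np.ndarray], n_components: int = 350) -> PCAModel:
    """Fit centered PCA; requires strictly more samples than components."""
    A = X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    n, d = A.shape
    if n <= n_components:
        raise ValueError(
            f"PCA needs n_samples > n_components; got {n} samples for "
            f"{n_components} components — lower n_components"
        )
    if d < n_components:
        raise ValueError(
            f"n_components={n_components} exceeds feature dimension {d}"
        )
    sk = _SkPCA(n_components=n_components, svd_solver="full")
    sk.fit(A)
    return PCAModel(
        mean=sk.mean_,
        components=_fix_signs(sk.components_),
        explained_variance=sk.explained_variance_,
        n_components=n_components,
    )


def transform_pca(model: PCAModel,
                  X: Union[FeatureMatrix, np.ndarray]) -> Union[FeatureMatrix, np.ndarray]:
    """Project rows onto the principal axes: X' = (X - mean) @ components.T."""
    A = X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    if A.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"dimension mismatch: data has {A.shape[1]} features, "
            f"model expects {model.mean.shape[0]}"
        )
    Y = (A - model.mean) @ model.components.T
    if isinstance(X, FeatureMatrix):
        return FeatureMatrix(ids=list(X.ids), X=Y)
    return Y


def inverse_transform_pca(model: PCAModel, Y: np.ndarray) -> np.ndarray:
    """Map projected points back into the original feature space."""
    return np.asarray(Y, dtype=float) @ model.components + model.mean
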