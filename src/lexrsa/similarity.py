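"""Word-by-word similarity structures and their vectorized (RDM) form.

A :class:`SimilarityMatrix` is the square, symmetric container every model in
this package produces: affective space, word embeddings, phonology, taxonomy,
and the neural similarity computed inside each searchlight.  Rank-based RSA
only ever consumes the flattened off-diagonal upper triangle, so the matrix
round-trips losslessly through :class:`RdmVector` with a single fixed pair
ordering (row-major, ``i < j``) shared by every module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "SimilarityMatrix",
    "RdmVector",
    "vectorize_rdm",
    "devectorize_rdm",
    "model_correlogram",
]

#: Absolute symmetry tolerance for a valid similarity matrix.
SYMMETRY_TOL = 1e-12

Orientation = Literal["similarity", "dissimilarity"]


@dataclass
class SimilarityMatrix:
    """Square symmetric matrix of pairwise word (dis)similarities.

    Parameters
    ----------
    labels : sequence of str
        Word labels, one per row/column, in matrix order.
    values : ndarray of shape (n, n)
        Symmetric matrix of pairwise values.
    metric : str
        Name of the metric that produced the matrix (e.g. ``"cosine"``).
    orientation : {"similarity", "dissimilarity"}
        Whether larger values mean more similar or more dissimilar.  Rank
        correlations downstream negate dissimilarity matrices so that all
        models enter the RSA with a common sign convention.
    """

    labels: list[str]
    values: np.ndarray
    metric: str = "unnamed"
    orientation: Orientation = "similarity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = [str(w) for w in self.labels]
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        diff = np.abs(self.values - self.values.T)
        finite = np.isfinite(diff)
        asym = diff[finite].max() if finite.any() else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(f"matrix asymmetric: max |S - S.T| = {asym:g}")
        if self.orientation not in ("similarity", "dissimilarity"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def n_items(self) -> int:
        return len(self.labels)

    def subset(self, words: Sequence[str]) -> "SimilarityMatrix":
        """Restrict the matrix to ``words``, in the given order."""
        idx = []
        pos = {w: i for i, w in enumerate(self.labels)}
        missing = [w for w in words if w not in pos]
        if missing:
            raise KeyError(f"words absent from matrix: {missing}")
        idx = [pos[w] for w in words]
        return SimilarityMatrix(
            labels=list(words),
            values=self.values[np.ix_(idx, idx)],
            metric=self.metric,
            orientation=self.orientation,
        )

    # -- plumbing to/from the vectorized form --------------------------------

    def vectorize(self) -> "RdmVector":
        return vectorize_rdm(self)

    # -- delimited-text round trip -------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write the matrix as labelled CSV plus a JSON metadata sidecar."""
        path = Path(path)
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)
        meta = {"metric": self.metric, "orientation": self.orientation}
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SimilarityMatrix":
        path = Path(path)
        df = pd.read_csv(path, index_col=0)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(
            labels=list(df.index.astype(str)),
            values=df.to_numpy(),
            metric=meta.get("metric", "unnamed"),
            orientation=meta.get("orientation", "similarity"),
        )


@dataclass
class RdmVector:
    """Flattened off-diagonal upper triangle of a :class:`SimilarityMatrix`.

    The pair ordering is row-major with ``i < j`` — ``(0,1), (0,2), …,
    (n-2, n-1)`` — fixed once for the whole package so model and neural
    vectors always align.
    """

    labels: list[str]
    values: np.ndarray
    metric: str = "unnamed"
    orientation: Orientation = "similarity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n * (n - 1) // 2,):
            raise ValueError(
                f"vector length {self.values.size} != n(n-1)/2 for n={n}"
            )

    @property
    def n_pairs(self) -> int:
        return self.values.size

    def signed(self) -> np.ndarray:
        """Values on a common sign convention (dissimilarities negated)."""
        return -self.values if self.orientation == "dissimilarity" else self.values

    def devectorize(self, diagonal: float = 1.0) -> SimilarityMatrix:
        return devectorize_rdm(self, diagonal=diagonal)


def vectorize_rdm(matrix: SimilarityMatrix) -> RdmVector:
    """Flatten a similarity matrix to its upper-triangle pair vector."""
    n = matrix.n_items
    iu = np.triu_indices(n, k=1)
    return RdmVector(
        labels=list(matrix.labels),
        values=matrix.values[iu].copy(),
        metric=matrix.metric,
        orientation=matrix.orientation,
    )


def devectorize_rdm(vec: RdmVector, diagonal: float = 1.0) -> SimilarityMatrix:
    """Reconstruct the symmetric matrix from an upper-triangle vector."""
    n = len(vec.labels)
    out = np.full((n, n), float(diagonal))
    iu = np.triu_indices(n, k=1)
    out[iu] = vec.values
    out[(iu[1], iu[0])] = vec.values
    return SimilarityMatrix(
        labels=list(vec.labels),
        values=out,
        metric=vec.metric,
        orientation=vec.orientation,
    )


def _pairwise_correlation(vectors: np.ndarray, method: str) -> np.ndarray:
    if method == "spearman":
        vectors = rankdata(vectors, axis=1)
    elif method != "pearson":
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    return np.corrcoef(vectors)


def model_correlogram(
    models: Sequence[SimilarityMatrix],
    method: str = "pearson",
    names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pairwise correlations between the RDM vectors of several models.

    Models built from different sources may cover slightly different word
    sets (a word can be absent from a taxonomy or a norms database); the
    correlogram is computed on the intersection of all label sets, in the
    order of the first model.  Orientation flags are honoured: dissimilarity
    vectors are negated before correlating, so a positive entry always means
    "these models agree on which pairs are similar".

    Parameters
    ----------
    models : sequence of SimilarityMatrix
    method : {"pearson", "spearman"}
    names : optional sequence of row/column names; defaults to metric names.

    Returns
    -------
    DataFrame
        Symmetric table of pairwise correlations.
    """
    if len(models) < 2:
        raise ValueError("need at least two models")
    common = [w for w in models[0].labels if all(w in set(m.labels) for m in models)]
    if len(common) < 3:
        raise ValueError(
            f"label intersection across models has {len(common)} words; need >= 3"
        )
    vectors = np.stack([m.subset(common).vectorize().signed() for m in models])
    corr = _pairwise_correlation(vectors, method)
    if names is None:
        names = []
        for i, m in enumerate(models):
            name = m.metric if m.metric != "unnamed" else f"model_{i}"
            while name in names:  # metric names may repeat
                name += "_"
            names.append(name)
    return pd.DataFrame(corr, index=list(names), columns=list(names))
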