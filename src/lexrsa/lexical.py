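"""Lexical similarity models and model-level statistics.

Builds every word-pair similarity matrix the pipeline consumes, from plain
tabular inputs:

* **affective space** — pairwise Euclidean distance between words in the 3-D
  space of valence, dominance and arousal ratings (1–7 scale), normalised by
  the maximum pairwise distance and converted to a similarity by ``1 - d``;
* **word embeddings** — cosine similarity between embedding vectors (e.g.
  300-dim co-occurrence or association-derived vectors);
* **phonology** — length-normalised Levenshtein similarity between
  phonological transcriptions, and the absolute difference in phonological
  neighbourhood density (a dissimilarity);
* **taxonomy** — Wu–Palmer similarity on a rooted taxonomy,
  ``2·depth(LCS) / (depth(a) + depth(b))`` with ``depth(root) = 1``.

Also provides the two summary statistics used when comparing models and
checking stimulus matching: the Pearson–Filon z test for two dependent
overlapping correlations, and a one-way ANOVA computed from per-group
summary statistics alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f as f_dist
from scipy.stats import norm

from .similarity import SimilarityMatrix

__all__ = [
    "WordSet",
    "AffectiveRatings",
    "EmbeddingTable",
    "PhonologicalData",
    "TaxonomyGraph",
    "ModelComparisonResult",
    "AnovaSummaryResult",
    "affective_similarity",
    "embedding_similarity",
    "phonological_similarity",
    "neighbourhood_density_dissimilarity",
    "wu_palmer_similarity",
    "pearson_filon_overlapping_z",
    "anova_from_summary",
]

VALENCE_CLASSES = ("positive", "neutral", "negative")


@dataclass
class WordSet:
    """Ordered stimulus word list with valence-class labels.

    The reference design uses 66 nouns distributed evenly over positive,
    neutral and negative valence classes (22 each); any class-balanced or
    unbalanced set is accepted as long as labels come from the 3-level set.
    """

    words: list[str]
    valence_class: list[str]
    attributes: pd.DataFrame | None = None  # matched covariates (AoA, frequency, ...)

    def __post_init__(self) -> None:
        if len(set(self.words)) != len(self.words):
            raise ValueError("words must be unique")
        if len(self.valence_class) != len(self.words):
            raise ValueError("one valence class per word required")
        bad = sorted(set(self.valence_class) - set(VALENCE_CLASSES))
        if bad:
            raise ValueError(f"unknown valence classes: {bad}")

    def __len__(self) -> int:
        return len(self.words)

    def class_members(self, cls: str) -> list[str]:
        return [w for w, c in zip(self.words, self.valence_class) if c == cls]


@dataclass
class AffectiveRatings:
    """Per-word valence/dominance/arousal ratings on a 1–7 scale."""

    words: list[str]
    valence: np.ndarray
    dominance: np.ndarray
    arousal: np.ndarray

    def __post_init__(self) -> None:
        self.valence = np.asarray(self.valence, dtype=float)
        self.dominance = np.asarray(self.dominance, dtype=float)
        self.arousal = np.asarray(self.arousal, dtype=float)
        n = len(self.words)
        for name in ("valence", "dominance", "arousal"):
            v = getattr(self, name)
            if v.shape != (n,):
                raise ValueError(f"{name} must have one value per word")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite values")
            if np.any(v < 1) or np.any(v > 7):
                raise ValueError(f"{name} outside the 1-7 rating scale")

    @property
    def vda(self) -> np.ndarray:
        """(n, 3) array of (valence, dominance, arousal) coordinates."""
        return np.column_stack([self.valence, self.dominance, self.arousal])


@dataclass
class EmbeddingTable:
    """Word-by-dimension real embedding matrix (rows ordered as the WordSet)."""

    words: list[str]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.words):
            raise ValueError("vectors must be a (n_words, n_dims) matrix")

    @property
    def n_dims(self) -> int:
        return self.vectors.shape[1]


@dataclass
class PhonologicalData:
    """Phonological transcriptions and neighbourhood densities per word."""

    words: list[str]
    transcriptions: list[str]
    densities: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.transcriptions) != len(self.words):
            raise ValueError("one transcription per word required")
        empty = [w for w, t in zip(self.words, self.transcriptions) if len(t) == 0]
        if empty:
            raise ValueError(f"empty transcription for: {empty}")
        if self.densities is not None:
            self.densities = np.asarray(self.densities)
            if self.densities.shape != (len(self.words),):
                raise ValueError("one density per word required")
            if np.any(self.densities < 0):
                raise ValueError("neighbourhood densities must be >= 0")


class TaxonomyGraph:
    """Rooted taxonomy with a word→node mapping.

    Stored as a :class:`networkx.DiGraph` with edges parent→child.  Node
    depth is counted in nodes from the root, ``depth(root) = 1``, the common
    WordNet convention that keeps Wu–Palmer similarities strictly positive.
    """

    def __init__(self, tree: nx.DiGraph, root: str, word_to_node: Mapping[str, str]):
        if not nx.is_directed_acyclic_graph(tree):
            raise ValueError("taxonomy must be acyclic")
        roots = [n for n in tree.nodes if tree.in_degree(n) == 0]
        if roots != [root]:
            raise ValueError(f"taxonomy must have the single root {root!r}, found {roots}")
        self.tree = tree
        self.root = root
        self.word_to_node = dict(word_to_node)
        # depth via BFS layers; along tree edges depth(child) = depth(parent)+1
        self._depth = {root: 1}
        for parent, child in nx.bfs_edges(tree, root):
            self._depth[child] = self._depth[parent] + 1
        unreachable = set(self.word_to_node.values()) - set(self._depth)
        if unreachable:
            raise ValueError(f"mapped nodes unreachable from root: {sorted(unreachable)}")

    def depth(self, node: str) -> int:
        return self._depth[node]

    def ancestors_with_self(self, node: str) -> set[str]:
        return nx.ancestors(self.tree, node) | {node}

    def lcs(self, node_a: str, node_b: str) -> str:
        """Least common subsumer: the deepest shared ancestor."""
        shared = self.ancestors_with_self(node_a) & self.ancestors_with_self(node_b)
        return max(shared, key=lambda n: (self._depth[n], n))


@dataclass
class ModelComparisonResult:
    """Result of a dependent overlapping-correlation comparison."""

    z: float
    p_value: float
    r12: float
    r13: float
    r23: float
    n: int


@dataclass
class AnovaSummaryResult:
    """One-way ANOVA computed from per-group summary statistics."""

    f: float
    df_between: int
    df_within: int
    p_value: float


# ---------------------------------------------------------------------------
# similarity constructors
# ---------------------------------------------------------------------------


def affective_similarity(ratings: AffectiveRatings) -> SimilarityMatrix:
    """Affective-space similarity: ``1 - d`` with max-normalised Euclidean d.

    Pairwise Euclidean distances in the (valence, dominance, arousal) space
    are divided by the maximum pairwise distance in the set, so the most
    distant pair has similarity exactly 0 and identical words similarity 1.
    """
    if len(ratings.words) < 2:
        raise ValueError("need at least 2 words")
    d = pdist(ratings.vda)
    dmax = d.max()
    if dmax == 0:
        raise ValueError(
            "all words identical in (valence, dominance, arousal); "
            "distance normalizer is zero"
        )
    s = 1.0 - squareform(d / dmax)
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(ratings.words, s, metric="affective", orientation="similarity")


def _cosine_matrix(vectors: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    unit = vectors / norms
    s = unit @ unit.T
    s = (s + s.T) / 2.0  # kill rounding asymmetry from the GEMM
    np.clip(s, -1.0, 1.0, out=s)
    np.fill_diagonal(s, 1.0)
    return s


def embedding_similarity(emb: EmbeddingTable, metric: str = "cosine") -> SimilarityMatrix:
    """Pairwise cosine similarity between embedding rows."""
    norms = np.linalg.norm(emb.vectors, axis=1)
    zero = [w for w, nz in zip(emb.words, norms == 0) if nz]
    if zero:
        raise ValueError(f"zero-norm embedding rows for: {zero}")
    return SimilarityMatrix(
        emb.words, _cosine_matrix(emb.vectors), metric=metric, orientation="similarity"
    )


def levenshtein_distance(a: str, b: str) -> int:
    """Plain Levenshtein edit distance (unit-cost substitution/indel)."""
    return edlib.align(a, b, task="distance")["editDistance"]


def phonological_similarity(phon: PhonologicalData) -> SimilarityMatrix:
    """Length-normalised Levenshtein similarity between transcriptions.

    ``s = 1 - lev(a, b) / max(len(a), len(b))`` — bounded in [0, 1] with 1
    for identical strings.
    """
    n = len(phon.words)
    s = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = phon.transcriptions[i], phon.transcriptions[j]
            s[i, j] = s[j, i] = 1.0 - levenshtein_distance(a, b) / max(len(a), len(b))
    return SimilarityMatrix(phon.words, s, metric="phonological", orientation="similarity")


def neighbourhood_density_dissimilarity(phon: PhonologicalData) -> SimilarityMatrix:
    """Absolute difference in phonological neighbourhood density.

    Kept as a *dissimilarity* (orientation flag) rather than remapped to
    [0, 1]: Spearman correlations downstream are invariant to monotone
    transforms, so only the sign convention matters, and the raw count
    difference is the interpretable quantity.
    """
    if phon.densities is None:
        raise ValueError("phonological data has no neighbourhood densities")
    dens = np.asarray(phon.densities, dtype=float)
    d = np.abs(dens[:, None] - dens[None, :])
    return SimilarityMatrix(
        phon.words, d, metric="neighbourhood_density", orientation="dissimilarity"
    )


def wu_palmer_similarity(
    tax: TaxonomyGraph, words: Sequence[str] | None = None
) -> SimilarityMatrix:
    """Wu–Palmer taxonomy similarity for all word pairs.

    ``WPsim(a, b) = 2·depth(LCS(a, b)) / (depth(a) + depth(b))`` with node
    depths counted from the root (``depth(root) = 1``), so values lie in
    (0, 1] and a word with itself scores exactly 1.

    Words absent from the taxonomy raise with the full list of offenders, so
    callers can drop them and intersect labels at correlogram time.
    """
    if words is None:
        words = list(tax.word_to_node)
    unmapped = [w for w in words if w not in tax.word_to_node]
    if unmapped:
        raise KeyError(f"words not mapped to any taxonomy node: {unmapped}")
    nodes = [tax.word_to_node[w] for w in words]
    depths = np.array([tax.depth(n) for n in nodes], dtype=float)
    n = len(words)
    s = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            lcs = tax.lcs(nodes[i], nodes[j])
            s[i, j] = s[j, i] = 2.0 * tax.depth(lcs) / (depths[i] + depths[j])
    return SimilarityMatrix(list(words), s, metric="wu_palmer", orientation="similarity")


# ---------------------------------------------------------------------------
# model-level statistics
# ---------------------------------------------------------------------------


def pearson_filon_overlapping_z(
    r12: float, r13: float, r23: float, n: int
) -> ModelComparisonResult:
    """Pearson–Filon z for two dependent overlapping correlations.

    Compares ``r12`` against ``r13`` — two correlations sharing variable 1 —
    given the overlap correlation ``r23`` between variables 2 and 3, on a
    common sample of size ``n``:

    .. math::

        z = \\frac{(r_{12} - r_{13})\\,\\sqrt{n}}
                 {\\sqrt{(1-r_{12}^2)^2 + (1-r_{13}^2)^2 - 2k}},

    with ``k = r23·(1 - r12² - r13²) - ½·r12·r13·(1 - r12² - r13² - r23²)``.
    The two-sided p-value is from the standard normal.
    """
    for name, r in (("r12", r12), ("r13", r13), ("r23", r23)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} must lie strictly in (-1, 1), got {r}")
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    k = r23 * (1 - r12**2 - r13**2) - 0.5 * r12 * r13 * (1 - r12**2 - r13**2 - r23**2)
    denom = np.sqrt((1 - r12**2) ** 2 + (1 - r13**2) ** 2 - 2 * k)
    z = (r12 - r13) * np.sqrt(n) / denom
    p = 2.0 * norm.sf(abs(z))
    return ModelComparisonResult(z=float(z), p_value=float(p), r12=r12, r13=r13, r23=r23, n=n)


def anova_from_summary(
    means: Sequence[float], sds: Sequence[float], ns: Sequence[int]
) -> AnovaSummaryResult:
    """One-way ANOVA F from per-group means, SDs and sizes alone.

    Useful when only printed summary statistics are available (e.g. checking
    that arousal is matched across valence classes).  Between-group and
    within-group mean squares are reconstructed exactly from the summaries:
    F = MS_between / MS_within with df = (k-1, N-k).
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    k = means.size
    if k < 2:
        raise ValueError("need at least 2 groups")
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2")
    n_total = int(ns.sum())
    grand = float((ns * means).sum() / n_total)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    if ss_within == 0:
        raise ValueError("zero within-group variance in all groups")
    df_b, df_w = k - 1, n_total - k
    f = (ss_between / df_b) / (ss_within / df_w)
    return AnovaSummaryResult(
        f=float(f),
        df_between=df_b,
        df_within=df_w,
        p_value=float(f_dist.sf(f, df_b, df_w)),
    )
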