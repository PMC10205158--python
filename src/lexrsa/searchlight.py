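"""Whole-brain searchlight RSA with plain and partial rank correlations.

Each grey-matter voxel becomes the center of a fixed-size neighbourhood (the
``k`` nearest in-mask voxels by millimetre distance; ``k = 200`` in the
reference design, roughly an 11 mm sphere at 2 mm voxels).  Within every
searchlight the condition patterns are (optionally) centred by subtracting
the across-condition mean pattern, pairwise cosine similarities form the
neural RDM, and its Spearman correlation with a model RDM — possibly partial,
controlling for covariate model RDMs — is written to the center voxel.  The
resulting per-subject maps are Fisher r-to-z transformed and smoothed before
group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .activation import ConditionPatterns, GreyMatterMask
from .similarity import RdmVector, SimilarityMatrix, vectorize_rdm

__all__ = [
    "SearchlightSpec",
    "SearchlightMap",
    "SubjectRsaMap",
    "define_searchlights",
    "neural_similarity",
    "rsa_correlation",
    "searchlight_rsa",
    "searchlight_rsa_multi",
    "fisher_z_map",
    "smooth_volume",
]

#: FWHM → Gaussian sigma conversion factor, 2*sqrt(2*ln 2).
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class SearchlightSpec:
    """Searchlight geometry: fixed voxel count ``k``, optional radius cap."""

    k: int = 200
    max_radius_mm: float | None = None
    centring: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("searchlight needs k >= 2 voxels")


@dataclass
class SearchlightMap:
    """Neighbourhood membership for every in-mask center voxel.

    ``members[c]`` lists indices (into ``voxel_coords``, which is the mask's
    voxel list in C order) of the ``k`` nearest in-mask voxels to center
    ``c``; the center itself is always first.
    """

    voxel_coords: np.ndarray  # (n_mask, 3) integer voxel indices, C order
    members: np.ndarray  # (n_mask, k) indices into voxel_coords
    shape: tuple[int, int, int]
    affine: np.ndarray

    @property
    def n_centers(self) -> int:
        return self.members.shape[0]

    @property
    def k(self) -> int:
        return self.members.shape[1]

    def flat_indices(self) -> np.ndarray:
        """Flat (C-order) volume indices of the mask voxels."""
        return np.ravel_multi_index(self.voxel_coords.T, self.shape)


@dataclass
class SubjectRsaMap:
    """Per-voxel (partial) rank-correlation volume for one subject and model."""

    values: np.ndarray  # 3D; NaN outside the mask or where degenerate
    model: str
    covariates: list[str] = field(default_factory=list)
    subject: str = ""
    affine: np.ndarray | None = None
    statistic: str = "rho"  # "rho" before, "z" after the Fisher transform

    def __post_init__(self) -> None:
        if self.affine is None:
            self.affine = np.eye(4)


def define_searchlights(mask: GreyMatterMask, spec: SearchlightSpec) -> SearchlightMap:
    """k-nearest-neighbour searchlight membership for every mask voxel.

    Distances are Euclidean in millimetres (through the affine); ties are
    broken by lexicographic voxel index, which makes the neighbourhoods
    deterministic across runs and platforms.  If the mask holds fewer than
    ``k`` voxels, every neighbourhood is the whole mask.
    """
    coords = np.argwhere(mask.mask)  # C order == lexicographic voxel index
    n = coords.shape[0]
    mm = coords @ mask.affine[:3, :3].T + mask.affine[:3, 3]
    k = min(spec.k, n)
    members = np.empty((n, k), dtype=np.intp)
    chunk = max(1, int(2**25 // max(n, 1)))  # keep the distance block ~256 MB max
    sq = np.einsum("ij,ij->i", mm, mm)
    for start in range(0, n, chunk):
        block = mm[start : start + chunk]
        d2 = sq[start : start + chunk, None] + sq[None, :] - 2.0 * block @ mm.T
        # stable sort on distance: ties fall back to column (= lexicographic) order
        order = np.argsort(np.maximum(d2, 0.0), axis=1, kind="stable")[:, :k]
        members[start : start + chunk] = order
    if spec.max_radius_mm is not None:
        far = np.linalg.norm(mm[members] - mm[:, None, :], axis=2) > spec.max_radius_mm
        if far.any():
            raise ValueError(
                f"{int(far.any(axis=1).sum())} searchlights exceed "
                f"max radius {spec.max_radius_mm} mm at k={k}"
            )
    return SearchlightMap(
        voxel_coords=coords, members=members, shape=mask.mask.shape, affine=mask.affine
    )


def _cosine_rdm(patterns: np.ndarray, centring: bool) -> np.ndarray:
    """Condition-by-condition cosine similarity of (n_cond, n_vox) patterns.

    Rows with zero norm (possible after centring) yield NaN entries.
    """
    x = patterns - patterns.mean(axis=0, keepdims=True) if centring else patterns
    norms = np.linalg.norm(x, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        unit = x / norms[:, None]
    s = unit @ unit.T
    s = (s + s.T) / 2.0
    np.clip(s, -1.0, 1.0, out=s)
    np.fill_diagonal(s, 1.0)
    s[norms == 0, :] = np.nan
    s[:, norms == 0] = np.nan
    return s


def neural_similarity(
    patterns: np.ndarray,
    words: Sequence[str] | None = None,
    centring: bool = True,
) -> SimilarityMatrix:
    """Cosine neural similarity between condition patterns.

    Parameters
    ----------
    patterns : (n_conditions, n_voxels) array
    words : labels for the conditions; defaults to ``w0..w{n-1}``
    centring : subtract the across-condition mean pattern first (the
        recommended centring for cosine-based RDMs).
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2 or patterns.shape[0] < 3 or patterns.shape[1] < 2:
        raise ValueError("need a (>=3 conditions, >=2 voxels) pattern matrix")
    if words is None:
        words = [f"w{i}" for i in range(patterns.shape[0])]
    return SimilarityMatrix(
        labels=list(words),
        values=_cosine_rdm(patterns, centring),
        metric="neural_cosine",
        orientation="similarity",
    )


# ---------------------------------------------------------------------------
# rank correlation with optional partialling
# ---------------------------------------------------------------------------


def _rank(v: np.ndarray) -> np.ndarray:
    return rankdata(v, axis=-1)


def _residualize(x: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Residual of rows of ``x`` after least-squares projection on columns of ``z``."""
    q, _ = np.linalg.qr(z)
    return x - (x @ q) @ q.T


def _covariate_design(cov_ranks: np.ndarray) -> np.ndarray:
    n = cov_ranks.shape[-1]
    return np.column_stack([np.ones(n), cov_ranks.reshape(-1, n).T])


def rsa_correlation(
    neural: SimilarityMatrix,
    model: SimilarityMatrix,
    covariates: Sequence[SimilarityMatrix] = (),
    method: str = "spearman",
) -> float:
    """(Partial) rank correlation between a neural and a model RDM.

    All matrices are vectorized on the common fixed pair ordering,
    dissimilarities are negated, and values are rank-transformed (average
    ranks on ties).  Without covariates this is plain Spearman; with
    covariates, target and model ranks are residualized on the covariate
    ranks by least squares and the residuals are Pearson-correlated — the
    standard partial Spearman.
    """
    if method != "spearman":
        raise ValueError("only spearman rank correlation is supported")
    if list(neural.labels) != list(model.labels):
        raise ValueError("neural and model labels do not match")
    x = _rank(vectorize_rdm(neural).signed())
    y = _rank(vectorize_rdm(model).signed())
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant RDM vector: zero rank variance")
    if covariates:
        for cov in covariates:
            if list(cov.labels) != list(model.labels):
                raise ValueError("covariate labels do not match")
        cov_ranks = np.stack([_rank(vectorize_rdm(c).signed()) for c in covariates])
        z = _covariate_design(cov_ranks)
        x0, y0 = x, y
        x = _residualize(x[None, :], z)[0]
        y = _residualize(y[None, :], z)[0]
        # a vector fully explained by the covariates has no unique variance
        # left: the partial correlation is 0, not numerical noise
        tol = 1e-10
        if np.linalg.norm(x) <= tol * np.linalg.norm(x0):
            return 0.0
        if np.linalg.norm(y) <= tol * np.linalg.norm(y0):
            return 0.0
    x = x - x.mean()
    y = y - y.mean()
    return float(x @ y / np.sqrt((x @ x) * (y @ y)))


# ---------------------------------------------------------------------------
# the searchlight sweep
# ---------------------------------------------------------------------------


def _searchlight_neural_rdms(
    flat_patterns: np.ndarray, maps: SearchlightMap, centring: bool
) -> np.ndarray:
    """Neural RDM vector (upper triangle) per searchlight center.

    Returns a (n_centers, n_pairs) float32 array; rows with any NaN
    (degenerate searchlights) are left as NaN.
    """
    n_cond = flat_patterns.shape[0]
    iu = np.triu_indices(n_cond, k=1)
    out = np.empty((maps.n_centers, iu[0].size), dtype=np.float32)
    for c in range(maps.n_centers):
        s = _cosine_rdm(flat_patterns[:, maps.members[c]], centring)
        out[c] = s[iu]
    return out


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return rankdata(a, axis=1).astype(np.float64)


def _rowwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``x`` with the vector ``y``."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    num = xc @ yc
    den = np.sqrt(np.einsum("ij,ij->i", xc, xc) * (yc @ yc))
    with np.errstate(divide="ignore", invalid="ignore"):
        return num / den


def searchlight_rsa_multi(
    patterns: ConditionPatterns,
    maps: SearchlightMap,
    analyses: Mapping[str, tuple[SimilarityMatrix, Sequence[SimilarityMatrix]]],
    spec: SearchlightSpec | None = None,
    subject: str = "",
) -> dict[str, SubjectRsaMap]:
    """Run several (model, covariates) RSAs over one searchlight sweep.

    The neural RDMs — the expensive part — are computed once per center and
    reused for every requested analysis, so mapping a model plainly and
    partially costs little more than mapping it once.

    Parameters
    ----------
    analyses : mapping of output name -> (model matrix, covariate matrices)
    """
    spec = spec or SearchlightSpec(k=maps.k)
    if patterns.data.shape[1:] != maps.shape:
        raise ValueError("pattern grid does not match the searchlight mask grid")
    flat = patterns.data.reshape(patterns.data.shape[0], -1)[:, maps.flat_indices()]
    for name, (model, covs) in analyses.items():
        if list(model.labels) != list(patterns.words):
            raise ValueError(f"model {name!r} labels do not match the pattern words")
        for cov in covs:
            if list(cov.labels) != list(patterns.words):
                raise ValueError(f"covariate of {name!r} does not match the pattern words")

    rdms = _searchlight_neural_rdms(flat, maps, spec.centring)
    good = ~np.isnan(rdms).any(axis=1)
    # degenerate (constant) neural RDMs have zero rank variance -> NaN later
    neural_ranks = np.empty_like(rdms, dtype=np.float64)
    neural_ranks[good] = _rank_rows(rdms[good])

    results: dict[str, SubjectRsaMap] = {}
    flat_idx = maps.flat_indices()
    for name, (model, covs) in analyses.items():
        y = _rank(vectorize_rdm(model).signed())
        if covs:
            cov_ranks = np.stack([_rank(vectorize_rdm(c).signed()) for c in covs])
            z = _covariate_design(cov_ranks)
            q, _ = np.linalg.qr(z)
            x = neural_ranks[good] - (neural_ranks[good] @ q) @ q.T
            yr = y - q @ (q.T @ y)
            if np.linalg.norm(yr) <= 1e-10 * np.linalg.norm(y):
                yr = np.zeros_like(yr)  # model fully explained by covariates
        else:
            x, yr = neural_ranks[good], y
        rho = _rowwise_pearson(x, yr) if np.any(yr) else np.zeros(x.shape[0])
        vol = np.full(maps.shape, np.nan)
        vals = np.full(maps.n_centers, np.nan)
        vals[good] = rho
        vol.ravel()[flat_idx] = vals
        results[name] = SubjectRsaMap(
            values=vol,
            model=model.metric,
            covariates=[c.metric for c in covs],
            subject=subject,
            affine=maps.affine,
            statistic="rho",
        )
    return results


def searchlight_rsa(
    patterns: ConditionPatterns,
    maps: SearchlightMap,
    model: SimilarityMatrix,
    covariates: Sequence[SimilarityMatrix] = (),
    spec: SearchlightSpec | None = None,
    subject: str = "",
) -> SubjectRsaMap:
    """Searchlight map of (partial) Spearman RSA for a single model."""
    return searchlight_rsa_multi(
        patterns, maps, {"map": (model, list(covariates))}, spec=spec, subject=subject
    )["map"]


def fisher_z_map(rsa: SubjectRsaMap) -> SubjectRsaMap:
    """Fisher r-to-z (atanh) transform; |rho| = 1 becomes NaN."""
    if rsa.statistic != "rho":
        raise ValueError("map is already z-transformed")
    vals = rsa.values.copy()
    vals[np.abs(vals) >= 1.0] = np.nan
    with np.errstate(invalid="ignore"):
        z = np.arctanh(vals)
    return SubjectRsaMap(
        values=z,
        model=rsa.model,
        covariates=list(rsa.covariates),
        subject=rsa.subject,
        affine=rsa.affine,
        statistic="z",
    )


def smooth_volume(
    vol: np.ndarray,
    fwhm_mm: float,
    affine: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Gaussian smoothing with mask-renormalized kernel weights.

    NaN voxels (and voxels outside ``mask``) contribute nothing; the kernel
    is renormalized over the valid voxels so a constant field stays constant
    near edges.  Output is NaN wherever the input was invalid.
    """
    if fwhm_mm <= 0:
        raise ValueError("FWHM must be positive")
    vol = np.asarray(vol, dtype=float)
    affine = np.eye(4) if affine is None else affine
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    sigma_vox = fwhm_mm / FWHM_TO_SIGMA / spacing
    valid = np.isfinite(vol)
    if mask is not None:
        valid &= mask.astype(bool)
    filled = np.where(valid, vol, 0.0)
    num = ndimage.gaussian_filter(filled, sigma=sigma_vox)
    den = ndimage.gaussian_filter(valid.astype(float), sigma=sigma_vox)
    out = np.full_like(vol, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        out[valid] = num[valid] / den[valid]
    return out
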