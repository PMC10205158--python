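"""Group-level inference on per-subject RSA maps.

Voxelwise one-sample and paired t tests on Fisher-z maps, plus cluster-extent
familywise-error control.  FWE correction uses sign-flipping permutations of
the subject maps: under the null of a symmetric zero-centred distribution at
every voxel, flipping the sign of whole subject maps is exchangeable, and the
maximum suprathreshold cluster size across flips yields the corrected
cluster p-value.  Clusters are formed by 18-neighbour connectivity at a
one-sided voxel-forming threshold (p < 0.001 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import t as t_dist

from .searchlight import SubjectRsaMap

__all__ = [
    "GroupResult",
    "one_sample_ttest",
    "paired_ttest",
    "cluster_inference",
    "roi_mean_ci",
]

#: 18-neighbour connectivity (faces + edges), the SPM cluster convention.
CONNECTIVITY_18 = ndimage.generate_binary_structure(3, 2)


@dataclass
class GroupResult:
    """Thresholded group analysis: t volume, cluster table, thresholds used."""

    t_map: np.ndarray
    df: int
    clusters: pd.DataFrame
    voxel_p: float
    cluster_fwe_p: float
    n_permutations: int
    cluster_labels: np.ndarray | None = None


def _stack_maps(maps: Sequence[SubjectRsaMap] | Sequence[np.ndarray]) -> np.ndarray:
    vols = [m.values if isinstance(m, SubjectRsaMap) else np.asarray(m, float) for m in maps]
    shapes = {v.shape for v in vols}
    if len(shapes) != 1:
        raise ValueError(f"subject maps have mismatched shapes: {shapes}")
    return np.stack(vols)


def _tmap(data: np.ndarray) -> np.ndarray:
    """Voxelwise one-sample t over axis 0; NaN where any subject is missing
    or the across-subject SD is zero."""
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[sd == 0] = np.nan
    return t


def one_sample_ttest(maps: Sequence[SubjectRsaMap] | Sequence[np.ndarray]) -> tuple[np.ndarray, int]:
    """Voxelwise one-sample t test against zero.

    Returns the t volume and df = N - 1.  A voxel is NaN if missing in any
    subject or if the across-subject SD is zero.
    """
    data = _stack_maps(maps)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    return _tmap(data), data.shape[0] - 1


def paired_ttest(
    maps_a: Sequence[SubjectRsaMap] | Sequence[np.ndarray],
    maps_b: Sequence[SubjectRsaMap] | Sequence[np.ndarray],
) -> tuple[np.ndarray, int]:
    """Voxelwise paired t test: one-sample t on the subjectwise differences A − B."""
    if len(maps_a) != len(maps_b):
        raise ValueError("paired test needs matched subject lists")
    for a, b in zip(maps_a, maps_b):
        if (
            isinstance(a, SubjectRsaMap)
            and isinstance(b, SubjectRsaMap)
            and a.subject != b.subject
        ):
            raise ValueError(f"subject mismatch: {a.subject!r} vs {b.subject!r}")
    diff = _stack_maps(maps_a) - _stack_maps(maps_b)
    if diff.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    return _tmap(diff), diff.shape[0] - 1


def _sign_matrix(n_subjects: int, n_permutations: int, rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """All 2^N sign patterns when N <= 12, else random patterns. Returns
    (signs, exhaustive)."""
    if n_subjects <= 12:
        signs = np.array(list(product((1.0, -1.0), repeat=n_subjects)))
        return signs, True
    return rng.choice([1.0, -1.0], size=(n_permutations, n_subjects)), False


def _max_cluster_sizes(
    t_flat: np.ndarray,
    t_crit: float,
    valid_idx: np.ndarray,
    shape: tuple[int, int, int],
) -> int:
    vol = np.zeros(shape, dtype=bool)
    vol.ravel()[valid_idx] = t_flat > t_crit
    if not vol.any():
        return 0
    labels, n = ndimage.label(vol, structure=CONNECTIVITY_18)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def cluster_inference(
    maps: Sequence[SubjectRsaMap] | Sequence[np.ndarray],
    voxel_p: float = 0.001,
    cluster_fwe_p: float = 0.05,
    n_permutations: int = 1000,
    seed: int | np.random.Generator = 0,
    affine: np.ndarray | None = None,
) -> GroupResult:
    """Cluster-extent FWE inference by sign-flipping permutation.

    The observed one-sample t map is thresholded at the one-sided voxelwise
    ``voxel_p`` (positive effects); suprathreshold voxels are grouped into
    18-connected clusters.  The null distribution of the maximum cluster size
    is built by flipping the signs of whole subject maps — all ``2^N`` flips
    when N <= 12, else ``n_permutations`` random flips drawn with ``seed``.
    Each observed cluster's corrected p is the proportion of null maxima at
    least as large (with the observed statistic counted into the null when
    flips are sampled randomly).

    An empty cluster table is a legitimate outcome, not an error.
    """
    data = _stack_maps(maps)
    n = data.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    df = n - 1
    shape = data.shape[1:]
    valid = np.isfinite(data).all(axis=0)
    valid_idx = np.flatnonzero(valid.ravel())
    x = data.reshape(n, -1)[:, valid_idx]  # (N, V_valid)
    t_crit = float(t_dist.isf(voxel_p, df))

    t_map = _tmap(data)
    supra = np.zeros(shape, dtype=bool)
    supra.ravel()[valid_idx] = t_map.ravel()[valid_idx] > t_crit
    labels, n_clusters = ndimage.label(supra, structure=CONNECTIVITY_18)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    signs, exhaustive = _sign_matrix(n, n_permutations, rng)
    # sum of squares is sign-invariant: only the mean changes per flip
    sumsq = np.einsum("ij,ij->j", x, x)
    null_max = np.empty(signs.shape[0], dtype=np.intp)
    for p_idx in range(signs.shape[0]):
        mean_p = signs[p_idx] @ x / n
        var_p = (sumsq - n * mean_p**2) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_p = mean_p / np.sqrt(var_p / n)
        t_p[var_p <= 0] = 0.0
        null_max[p_idx] = _max_cluster_sizes(t_p, t_crit, valid_idx, shape)

    rows = []
    if affine is None:
        affine = maps[0].affine if isinstance(maps[0], SubjectRsaMap) else np.eye(4)
    for lab in range(1, n_clusters + 1):
        members = np.argwhere(labels == lab)
        size = members.shape[0]
        if exhaustive:
            p_fwe = float((null_max >= size).mean())
        else:
            p_fwe = float((1 + (null_max >= size).sum()) / (len(null_max) + 1))
        t_members = t_map[tuple(members.T)]
        peak = members[int(np.nanargmax(t_members))]
        peak_mm = affine[:3, :3] @ peak + affine[:3, 3]
        rows.append(
            {
                "size": size,
                "p_fwe": p_fwe,
                "peak_i": int(peak[0]),
                "peak_j": int(peak[1]),
                "peak_k": int(peak[2]),
                "peak_x_mm": float(peak_mm[0]),
                "peak_y_mm": float(peak_mm[1]),
                "peak_z_mm": float(peak_mm[2]),
                "peak_t": float(np.nanmax(t_members)),
            }
        )
    clusters = pd.DataFrame(
        rows,
        columns=[
            "size", "p_fwe", "peak_i", "peak_j", "peak_k",
            "peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_t",
        ],
    )
    if len(clusters):
        clusters = clusters[clusters["p_fwe"] < cluster_fwe_p].reset_index(drop=True)
        clusters = clusters.sort_values("size", ascending=False, ignore_index=True)
    return GroupResult(
        t_map=t_map,
        df=df,
        clusters=clusters,
        voxel_p=voxel_p,
        cluster_fwe_p=cluster_fwe_p,
        n_permutations=len(null_max),
        cluster_labels=labels,
    )


def roi_mean_ci(
    maps: Sequence[SubjectRsaMap] | Sequence[np.ndarray],
    voxel: tuple[int, int, int],
    ci: float = 0.95,
) -> tuple[float, float, float]:
    """Across-subject mean of a map value at one voxel with a t-based CI.

    Useful for reporting the group-average correlation (and its 95% CI) at a
    peak voxel; returns (mean, lower, upper).
    """
    data = _stack_maps(maps)[(slice(None), *voxel)]
    data = data[np.isfinite(data)]
    n = data.size
    if n < 2:
        raise ValueError("need at least 2 finite subject values")
    m = float(data.mean())
    half = float(t_dist.ppf(0.5 + ci / 2, n - 1) * data.std(ddof=1) / np.sqrt(n))
    return m, m - half, m + half
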