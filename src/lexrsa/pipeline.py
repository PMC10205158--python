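"""End-to-end subject pipeline: QC → trial AUC → pooling → searchlight RSA.

Chains the building blocks in the order the analysis prescribes: motion QC
drops whole runs whose maximum framewise displacement exceeds the threshold,
surviving runs yield per-trial AUC maps that are pooled into one pattern per
word, and the searchlight sweep maps each model's (partial) Spearman
correlation, optionally Fisher-z transformed and smoothed for group stats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .activation import (
    BoldRun,
    ConditionPatterns,
    GreyMatterMask,
    MotionTrace,
    QCReport,
    framewise_displacement,
    pool_conditions,
    qc_exclude_runs,
    trial_auc_maps,
)
from .searchlight import (
    SearchlightMap,
    SearchlightSpec,
    SubjectRsaMap,
    define_searchlights,
    fisher_z_map,
    searchlight_rsa_multi,
    smooth_volume,
)
from .similarity import SimilarityMatrix

__all__ = ["SubjectResult", "run_subject_pipeline"]


@dataclass
class SubjectResult:
    """Everything the subject-level pipeline produced."""

    qc: QCReport
    patterns: ConditionPatterns
    searchlights: SearchlightMap
    rho_maps: dict[str, SubjectRsaMap]
    z_maps: dict[str, SubjectRsaMap]


def run_subject_pipeline(
    runs: Sequence[BoldRun],
    motion: Sequence[MotionTrace],
    grey_matter: GreyMatterMask,
    analyses: Mapping[str, tuple[SimilarityMatrix, Sequence[SimilarityMatrix]]],
    words: Sequence[str] | None = None,
    spec: SearchlightSpec | None = None,
    fd_threshold_mm: float = 1.0,
    auc_window: tuple[float, float] = (2.0, 8.0),
    smooth_fwhm_mm: float | None = 8.0,
    searchlights: SearchlightMap | None = None,
    subject: str = "",
) -> SubjectResult:
    """Run one subject through QC, AUC extraction, pooling and searchlight RSA.

    Parameters
    ----------
    analyses : mapping of output name -> (model, covariates); every analysis
        shares one searchlight sweep.
    smooth_fwhm_mm : FWHM for the post-z smoothing; ``None`` skips smoothing.
    searchlights : precomputed neighbourhood map (reused across subjects that
        share a mask); computed from ``grey_matter`` when omitted.
    """
    if len(runs) != len(motion):
        raise ValueError("one motion trace per run required")
    spec = spec or SearchlightSpec()
    qc = qc_exclude_runs([framewise_displacement(m) for m in motion], fd_threshold_mm)
    kept = [run for run, bad in zip(runs, qc.excluded) if not bad]
    if not kept:
        raise ValueError("all runs excluded by motion QC")
    trial_maps = [trial_auc_maps(run, window=auc_window) for run in kept]
    patterns = pool_conditions(trial_maps, words=words)
    slmap = searchlights or define_searchlights(grey_matter, spec)
    rho_maps = searchlight_rsa_multi(patterns, slmap, analyses, spec=spec, subject=subject)
    z_maps = {}
    for name, rho in rho_maps.items():
        z = fisher_z_map(rho)
        if smooth_fwhm_mm is not None:
            z.values = smooth_volume(
                z.values, smooth_fwhm_mm, affine=grey_matter.affine, mask=grey_matter.mask
            )
        z_maps[name] = z
    return SubjectResult(
        qc=qc, patterns=patterns, searchlights=slmap, rho_maps=rho_maps, z_maps=z_maps
    )
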