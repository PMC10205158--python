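"""From preprocessed 4D runs to quality-controlled condition patterns.

The single-trial response summary is deliberately model-free: instead of a
GLM, each trial's activation is the area under the BOLD curve (AUC) from 2 to
8 s after word onset, baseline-corrected by the signal value at onset.  With
a 1 s repetition time the trapezoidal rule on the sample grid (with linear
interpolation at fractional onsets) is exact for piecewise-linear signals.

Motion quality control operates on whole runs: a run is excluded when its
maximum framewise displacement (sum of absolute differentiated realignment
parameters, rotations converted to mm on a configurable sphere) exceeds a
threshold (1 mm in the reference design).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BoldRun",
    "MotionTrace",
    "FDSeries",
    "TrialActivationMaps",
    "ConditionPatterns",
    "GreyMatterMask",
    "QCReport",
    "framewise_displacement",
    "qc_exclude_runs",
    "trial_auc_maps",
    "pool_conditions",
    "tsnr_map",
    "grey_matter_mask",
]

#: Event-table columns every BoldRun must carry.
EVENT_COLUMNS = ("onset", "word", "modality", "task", "trial_type")


@dataclass
class BoldRun:
    """One preprocessed 4D run: data (x, y, z, t), TR in seconds, events.

    The event table has columns ``onset`` (s), ``word``, ``modality``
    (visual/auditory), ``task`` (overt/covert) and ``trial_type``
    (word/control).
    """

    data: np.ndarray
    tr: float
    events: pd.DataFrame
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("run data must be 4D (x, y, z, t)")
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise ValueError(f"event table missing columns: {missing}")
        duration = (self.data.shape[-1] - 1) * self.tr
        if (self.events["onset"] < 0).any() or (self.events["onset"] > duration).any():
            raise ValueError("event onsets fall outside the run")
        if self.affine is None:
            self.affine = np.eye(4)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]


@dataclass
class MotionTrace:
    """Per-volume realignment parameters: 3 translations (mm), 3 rotations (rad)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion parameters must be (n_volumes, 6)")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("non-finite motion parameters")


@dataclass
class FDSeries:
    """Per-volume framewise displacement (mm); first volume is 0 by definition."""

    values: np.ndarray

    @property
    def max(self) -> float:
        return float(self.values.max())


@dataclass
class TrialActivationMaps:
    """Per-trial 3D AUC volumes (signal · s) with trial metadata carried through."""

    data: np.ndarray  # (n_trials, x, y, z)
    events: pd.DataFrame
    affine: np.ndarray

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.events):
            raise ValueError("one event row per trial map required")


@dataclass
class ConditionPatterns:
    """Word-by-voxel activation patterns (pooled over trials/tasks/modalities)."""

    words: list[str]
    data: np.ndarray  # (n_words, x, y, z)
    affine: np.ndarray
    n_trials_per_word: np.ndarray | None = None


@dataclass
class GreyMatterMask:
    """Binary grey-matter mask from a probability map (strict > threshold)."""

    probability: np.ndarray
    threshold: float
    mask: np.ndarray
    affine: np.ndarray

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class QCReport:
    """Run-level motion QC outcome."""

    max_fd: np.ndarray
    excluded: np.ndarray
    threshold_mm: float

    @property
    def n_runs(self) -> int:
        return self.max_fd.size

    @property
    def n_excluded(self) -> int:
        return int(self.excluded.sum())

    @property
    def percent_excluded(self) -> float:
        return 100.0 * self.n_excluded / self.n_runs

    def summary(self) -> str:
        return (
            f"{self.n_excluded} of {self.n_runs} runs excluded "
            f"({self.percent_excluded:.1f}%) at max FD > {self.threshold_mm:g} mm"
        )


def framewise_displacement(
    motion: MotionTrace, rotation_radius_mm: float = 50.0
) -> FDSeries:
    """Framewise displacement: sum of absolute differentiated parameters.

    Rotations (radians) are converted to arc length on a sphere of
    ``rotation_radius_mm`` (default 50 mm, the common convention).  The first
    volume has FD = 0 by definition.
    """
    p = motion.params.copy()
    if p.shape[0] < 2:
        raise ValueError("need at least 2 volumes for framewise displacement")
    p[:, 3:] *= rotation_radius_mm
    fd = np.zeros(p.shape[0])
    fd[1:] = np.abs(np.diff(p, axis=0)).sum(axis=1)
    return FDSeries(values=fd)


def qc_exclude_runs(
    fd_series: Sequence[FDSeries], threshold_mm: float = 1.0
) -> QCReport:
    """Flag runs whose maximum framewise displacement exceeds the threshold."""
    if len(fd_series) == 0:
        raise ValueError("need at least one run")
    max_fd = np.array([fd.max for fd in fd_series])
    return QCReport(max_fd=max_fd, excluded=max_fd > threshold_mm, threshold_mm=threshold_mm)


def _interp_weights(time_s: float, tr: float, n_volumes: int) -> tuple[int, float]:
    """Frame index and fractional weight for linear interpolation at ``time_s``."""
    f = time_s / tr
    i = int(np.floor(f))
    frac = f - i
    if i >= n_volumes - 1:  # exactly at (or within eps of) the last frame
        return n_volumes - 2, 1.0
    return i, frac


def trial_auc_maps(
    run: BoldRun, window: tuple[float, float] = (2.0, 8.0)
) -> TrialActivationMaps:
    """Per-trial AUC volumes over ``[onset + window[0], onset + window[1]]``.

    For every trial the voxelwise signal is baseline-corrected by subtracting
    its (interpolated) value at trial onset, then integrated with the
    trapezoidal rule over the window, sampling the linearly-interpolated
    signal on the TR grid.  Trials whose window runs past the end of the run
    are dropped with a warning.

    The whole computation reduces to one weight vector per trial over volume
    indices, so all trials are extracted with a single matrix product.
    """
    w0, w1 = window
    if not w1 > w0:
        raise ValueError("window end must exceed window start")
    t_end = (run.n_volumes - 1) * run.tr
    onsets = run.events["onset"].to_numpy(dtype=float)
    keep = onsets + w1 <= t_end + 1e-9
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} trial(s) whose AUC window exceeds the run",
            stacklevel=2,
        )
    events = run.events.loc[keep].reset_index(drop=True)
    onsets = onsets[keep]

    n_vol = run.n_volumes
    weights = np.zeros((len(onsets), n_vol))
    for t, onset in enumerate(onsets):
        # sample times on the TR grid, always including both window edges
        times = np.arange(onset + w0, onset + w1, run.tr)
        times = np.append(times, onset + w1)
        # trapezoid coefficients for (possibly irregular) sample spacing
        coef = np.zeros_like(times)
        dt = np.diff(times)
        coef[:-1] += dt / 2.0
        coef[1:] += dt / 2.0
        for s, c in zip(times, coef):
            i, frac = _interp_weights(s, run.tr, n_vol)
            weights[t, i] += c * (1.0 - frac)
            weights[t, i + 1] += c * frac
        # baseline: subtract onset-time value times the window length
        i, frac = _interp_weights(onset, run.tr, n_vol)
        weights[t, i] -= (w1 - w0) * (1.0 - frac)
        weights[t, i + 1] -= (w1 - w0) * frac

    shape = run.data.shape[:3]
    flat = run.data.reshape(-1, n_vol).T  # (t, voxels)
    auc = (weights @ flat.astype(np.float64)).reshape((len(onsets),) + shape)
    return TrialActivationMaps(data=auc, events=events, affine=run.affine)


def pool_conditions(
    maps: Sequence[TrialActivationMaps], words: Sequence[str] | None = None
) -> ConditionPatterns:
    """Average each word's trial maps into one condition pattern.

    Control trials (``trial_type != "word"``) are excluded; word trials are
    pooled over runs, tasks and modalities by the voxelwise mean.  Rows follow
    ``words`` when given (the WordSet order), else first-appearance order.
    """
    if len(maps) == 0:
        raise ValueError("no trial maps to pool")
    events = pd.concat([m.events.assign(_run=i) for i, m in enumerate(maps)], ignore_index=True)
    data = np.concatenate([m.data for m in maps], axis=0)
    is_word = events["trial_type"] == "word"
    events, data = events.loc[is_word], data[is_word.to_numpy()]
    if words is None:
        words = list(dict.fromkeys(events["word"]))
    counts, pooled = [], []
    for w in words:
        sel = (events["word"] == w).to_numpy()
        if not sel.any():
            raise ValueError(f"word {w!r} has no retained trials")
        pooled.append(data[sel].mean(axis=0))
        counts.append(int(sel.sum()))
    return ConditionPatterns(
        words=list(words),
        data=np.stack(pooled),
        affine=maps[0].affine,
        n_trials_per_word=np.array(counts),
    )


def tsnr_map(residual_series: np.ndarray) -> np.ndarray:
    """Temporal SNR: voxelwise mean of the series divided by its SD.

    Voxels with zero temporal SD get NaN rather than raising — a flat voxel
    is a data feature (e.g. outside the head), not an error.
    """
    series = np.asarray(residual_series, dtype=float)
    if series.ndim != 4 or series.shape[-1] < 2:
        raise ValueError("need a 4D series with at least 2 time points")
    mean = series.mean(axis=-1)
    sd = series.std(axis=-1, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tsnr = mean / sd
    tsnr[sd == 0] = np.nan
    return tsnr


def grey_matter_mask(
    probability: np.ndarray, threshold: float = 0.3, affine: np.ndarray | None = None
) -> GreyMatterMask:
    """Binarize a grey-matter probability map at a strict ``> threshold``."""
    prob = np.asarray(probability, dtype=float)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    mask = prob > threshold
    if not mask.any():
        raise ValueError(f"empty mask at threshold {threshold}")
    return GreyMatterMask(
        probability=prob,
        threshold=threshold,
        mask=mask,
        affine=np.eye(4) if affine is None else affine,
    )
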