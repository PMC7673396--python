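"""Block-design GLM activation mapping and the task reference signal.

A block design (onsets/durations) is convolved with the canonical
double-gamma hemodynamic response function to form the task regressor;
ordinary least squares per voxel gives a t-map for the task effect.
Suprathreshold voxels are grouped by 26-connectivity and small clusters
discarded; the mean time series within the surviving mask is the
``task_mean`` reference signal used for lag mapping inside the activated
region.

Notes on scope: inference here uses a configurable voxel-level
t-threshold plus a cluster-extent rule, which is a deterministic masking
rule suited to synthetic data; serial correlation in the GLM noise is
ignored (OLS) by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.stats

from .exceptions import ParameterError
from .preprocess import BoldRun, ReferenceSignal

__all__ = [
    "TaskDesign",
    "ActivationResult",
    "task1_design",
    "task2_design",
    "canonical_hrf",
    "build_design_matrix",
    "fit_glm",
    "activation_mask_and_reference",
]


@dataclass
class TaskDesign:
    """Block-design timing: stimulus onsets and durations in seconds."""

    onsets: np.ndarray
    durations: np.ndarray
    run_length: int  # frames
    tr: float

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float).ravel()
        self.durations = np.asarray(self.durations, dtype=float).ravel()
        if self.onsets.size == 0:
            raise ParameterError("design has no events")
        if self.onsets.size != self.durations.size:
            raise ParameterError("onsets and durations differ in length")
        if not np.all(np.diff(self.onsets) >= 0):
            raise ParameterError("onsets must be sorted")
        if np.any(self.onsets + self.durations > self.run_length * self.tr):
            raise ParameterError("events extend beyond the run")

    @property
    def n_events(self) -> int:
        return len(self.onsets)

    def to_tsv(self, path: str, condition: str = "task") -> None:
        pd.DataFrame({"onset": self.onsets, "duration": self.durations,
                      "condition": condition}).to_csv(path, sep="\t",
                                                      index=False)

    @classmethod
    def from_tsv(cls, path: str, run_length: int, tr: float) -> "TaskDesign":
        df = pd.read_csv(path, sep="\t")
        return cls(onsets=df["onset"].to_numpy(),
                   durations=df["duration"].to_numpy(),
                   run_length=run_length, tr=tr)


def task1_design(tr: float = 0.75, run_length: int = 392) -> TaskDesign:
    """Checkerboard task 1: 12 s on / 36 s off, six cycles.

    11 s of pre-scan plus 6 s of control precede the first block.
    """
    onsets = 17.0 + 48.0 * np.arange(6)
    return TaskDesign(onsets=onsets, durations=np.full(6, 12.0),
                      run_length=run_length, tr=tr)


def task2_design(tr: float = 0.75, run_length: int = 408) -> TaskDesign:
    """Checkerboard task 2: 6 s on / 24 s off, ten cycles."""
    onsets = 17.0 + 30.0 * np.arange(10)
    return TaskDesign(onsets=onsets, durations=np.full(10, 6.0),
                      run_length=run_length, tr=tr)


def canonical_hrf(tr: float, time_length: float = 32.0, peak_delay: float = 6.0,
                  undershoot_delay: float = 16.0, undershoot_ratio: float = 1.0 / 6.0,
                  dispersion: float = 1.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at TR, unit peak.

    Difference of two gamma densities: a response peaking ~5 s after
    onset and an undershoot peaking ~15 s later at one sixth the
    amplitude, truncated at ``time_length`` seconds where the tail is
    below 1 % of the peak.
    """
    if not tr > 0:
        raise ParameterError("tr must be positive")
    t = np.arange(0, time_length, tr)
    peak = scipy.stats.gamma.pdf(t, peak_delay / dispersion, scale=dispersion)
    under = scipy.stats.gamma.pdf(t, undershoot_delay / dispersion,
                                  scale=dispersion)
    h = peak - undershoot_ratio * under
    return h / h.max()


def _cosine_drift(n_frames: int, tr: float, high_pass: float) -> np.ndarray:
    """Orthonormal DCT-II drift basis implementing a high-pass cut.

    Columns are the discrete cosines with frequency below ``high_pass``
    (plus the constant term), the standard drift model for block-design
    GLMs.
    """
    order = int(np.floor(2 * n_frames * tr * high_pass))
    t = np.arange(n_frames)
    cols = [np.full(n_frames, 1.0 / np.sqrt(n_frames))]
    for j in range(1, order + 1):
        cols.append(np.sqrt(2.0 / n_frames)
                    * np.cos(np.pi * j * (2 * t + 1) / (2 * n_frames)))
    return np.column_stack(cols)


def task_regressor(design: TaskDesign, tr: float | None = None,
                   hrf: np.ndarray | None = None,
                   oversample: int = 16) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at the run's frames."""
    tr = design.tr if tr is None else tr
    dt = tr / oversample
    n_fine = design.run_length * oversample
    box = np.zeros(n_fine)
    for onset, dur in zip(design.onsets, design.durations):
        i0 = int(round(onset / dt))
        i1 = int(round((onset + dur) / dt))
        box[i0:i1] = 1.0
    kern = canonical_hrf(dt) if hrf is None else np.asarray(hrf, float)
    resp = np.convolve(box, kern)[:n_fine]
    resp = resp / max(resp.max(), np.finfo(float).tiny)
    return resp[::oversample][: design.run_length].copy()


def build_design_matrix(design: TaskDesign, tr: float | None = None,
                        hrf: np.ndarray | None = None,
                        nuisance: np.ndarray | None = None,
                        high_pass: float = 1.0 / 128.0) -> pd.DataFrame:
    """Assemble the GLM design: task regressor, nuisance, drift terms.

    Columns: the HRF-convolved task regressor, optional nuisance
    regressors (e.g. motion parameters), and a mutually orthonormal
    cosine drift set implementing the high-pass cut (1/128 Hz default),
    including the intercept.
    """
    tr = design.tr if tr is None else tr
    cols = {"task": task_regressor(design, tr=tr, hrf=hrf)}
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != design.run_length:
            nuisance = nuisance.T
        if nuisance.shape[0] != design.run_length:
            raise ParameterError("nuisance length must match run frames")
        for i in range(nuisance.shape[1]):
            cols[f"nuisance_{i}"] = nuisance[:, i]
    drift = _cosine_drift(design.run_length, tr, high_pass)
    for j in range(drift.shape[1]):
        cols[f"drift_{j}"] = drift[:, j]
    X = pd.DataFrame(cols)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the collinear columns for the error message
        _, r = np.linalg.qr(X.to_numpy())
        bad = [X.columns[i] for i in range(X.shape[1])
               if abs(r[min(i, r.shape[0] - 1), i]) < 1e-10]
        raise ParameterError(f"design matrix is rank deficient "
                             f"(collinear columns: {bad})")
    return X


def fit_glm(run: BoldRun, design_matrix: pd.DataFrame,
            task_col: str = "task") -> np.ndarray:
    """Per-voxel OLS; t = estimate / SE for the task column.

    Returns a 3D t-map with NaN outside the valid mask and at
    zero-variance voxels (their t is undefined).
    """
    X = design_matrix.to_numpy()
    if X.shape[0] != run.n_timepoints:
        raise ParameterError("design rows must match run frames")
    c = np.zeros(X.shape[1])
    c[design_matrix.columns.get_loc(task_col)] = 1.0
    Y = run.timeseries().T  # (T, V)
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * float(c @ xtx_inv @ c))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (c @ beta) / se
    t[Y.std(axis=0) == 0] = np.nan
    t_map = np.full(run.shape, np.nan)
    t_map[run.valid_mask] = t
    return t_map


@dataclass
class ActivationResult:
    """Task activation: t-map, cluster-filtered mask, mean reference."""

    t_map: np.ndarray
    activation_mask: np.ndarray
    reference: ReferenceSignal


def activation_mask_and_reference(t_map: np.ndarray, run: BoldRun,
                                  threshold: float,
                                  min_cluster: int = 10) -> ActivationResult:
    """Threshold a t-map, keep clusters larger than ``min_cluster``.

    Suprathreshold voxels are grouped by 26-connectivity; clusters of
    more than ``min_cluster`` voxels survive.  The reference signal is
    the mean in-mask time series (label ``task_mean``).
    """
    t_map = np.asarray(t_map, dtype=float)
    supra = np.nan_to_num(t_map, nan=-np.inf) > threshold
    labels, n_lab = scipy.ndimage.label(supra, structure=np.ones((3, 3, 3)))
    mask = np.zeros_like(supra)
    for lab in range(1, n_lab + 1):
        comp = labels == lab
        if comp.sum() > min_cluster:
            mask |= comp
    if not mask.any():
        raise ParameterError(
            "activation mask is empty; lower the t-threshold or the "
            "minimum cluster size")
    ref = ReferenceSignal(values=run.data[mask].mean(axis=0), tr=run.tr,
                          label="task_mean")
    return ActivationResult(t_map=t_map, activation_mask=mask, reference=ref)
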