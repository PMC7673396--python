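"""Temporal cleaning of BOLD runs and reference-signal construction.

A :class:`BoldRun` is the unit every analysis stage consumes: a 4D
voxel-by-time array with its repetition time (TR) and a validity mask.
Cleaning follows the conventional resting-state recipe -- remove linear
trends, then band-pass to the 0.01-0.1 Hz range where systemic
low-frequency oscillations live.  The filter is applied forward and
backward (zero phase): any group delay introduced here would corrupt the
time-lag estimates downstream, so a zero-phase realization is mandatory,
not a stylistic choice.

The global mean signal (GMS) is the unweighted average time series over a
gray-matter mask; it serves as the canonical reference signal for lag
mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
import scipy.signal

from .exceptions import ParameterError

__all__ = [
    "BoldRun",
    "ReferenceSignal",
    "detrend_linear",
    "bandpass",
    "preprocess_run",
    "make_gray_mask",
    "compute_gms",
    "concatenate_runs",
    "deconcatenate",
]

REFERENCE_LABELS = ("GMS", "IC", "task_mean", "arterial")


@dataclass
class BoldRun:
    """A 4D voxel-by-time dataset with repetition time and validity mask.

    Parameters
    ----------
    data : ndarray, shape (X, Y, Z, T)
        Signal values. Must be finite within ``valid_mask``.
    tr : float
        Repetition time in seconds (sampling interval of the time axis).
    valid_mask : ndarray of bool, shape (X, Y, Z), optional
        Voxels carrying usable signal. Defaults to all-true.
    run_id : str
        Free-form label used in provenance and concatenation bookkeeping.
    """

    data: np.ndarray
    tr: float
    valid_mask: np.ndarray | None = None
    run_id: str = ""
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ParameterError("BoldRun.data must be 4D (X, Y, Z, T)")
        if not self.tr > 0:
            raise ParameterError("tr must be positive")
        if self.data.shape[-1] < 2:
            raise ParameterError("a run needs at least 2 time points")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.data.shape[:3], dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.data.shape[:3]:
            raise ParameterError("valid_mask shape must match the voxel grid")
        if not np.isfinite(self.data[self.valid_mask]).all():
            raise ParameterError("non-finite values inside valid_mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[-1]

    def timeseries(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Return the (V, T) matrix of in-mask voxel time courses."""
        mask = self.valid_mask if mask is None else np.asarray(mask, bool)
        return self.data[mask]

    def to_nifti(self, path: str) -> None:
        img = nib.Nifti1Image(self.data, self.affine)
        img.header.set_zooms((*img.header.get_zooms()[:3], self.tr))
        nib.save(img, path)

    @classmethod
    def from_nifti(cls, path: str, tr: float | None = None,
                   valid_mask: np.ndarray | None = None,
                   run_id: str = "") -> "BoldRun":
        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=float)
        if tr is None:
            tr = float(img.header.get_zooms()[3])
        return cls(data=data, tr=tr, valid_mask=valid_mask, run_id=run_id,
                   affine=np.asarray(img.affine))


@dataclass
class ReferenceSignal:
    """A labeled 1D time series at a run's sampling rate.

    ``label`` records what the series is -- the global mean signal
    (``GMS``), an independent-component time course (``IC``), the mean
    series of a task-activation mask (``task_mean``), or an arterial ROI
    signal (``arterial``).
    """

    values: np.ndarray
    tr: float
    label: str = "GMS"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not self.tr > 0:
            raise ParameterError("tr must be positive")
        if self.label not in REFERENCE_LABELS:
            raise ParameterError(
                f"label must be one of {REFERENCE_LABELS}, got {self.label!r}")
        if not np.isfinite(self.values).all():
            raise ParameterError("reference signal contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    def to_tsv(self, path: str) -> None:
        t = np.arange(len(self.values)) * self.tr
        pd.DataFrame({"time_s": t, "value": self.values}).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str, label: str = "GMS") -> "ReferenceSignal":
        df = pd.read_csv(path, sep="\t")
        t = df["time_s"].to_numpy()
        tr = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
        return cls(values=df["value"].to_numpy(), tr=tr, label=label)


def detrend_linear(series: np.ndarray) -> np.ndarray:
    """Remove the least-squares line from a series (last axis).

    The output has (numerically) zero mean and zero correlation with the
    time index; applying the operation twice is the same as applying it
    once.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[-1] < 3:
        raise ParameterError("detrend_linear needs at least 3 time points")
    return scipy.signal.detrend(series, axis=-1, type="linear")


def _bandpass_sos(tr: float, low: float, high: float, order: int):
    nyq = 0.5 / tr
    if not (0.0 < low < high < nyq):
        raise ParameterError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyq:.4g} Hz)")
    return scipy.signal.butter(order, [low, high], btype="bandpass",
                               fs=1.0 / tr, output="sos")


def bandpass(series: np.ndarray, tr: float, low: float = 0.01,
             high: float = 0.1, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    A forward-backward (``sosfiltfilt``) pass squares the magnitude
    response and cancels the phase response exactly, so pass-band
    components keep their timing.  The input is reflect-padded by roughly
    one settling length of the low cutoff before filtering to suppress
    edge transients that would otherwise masquerade as lags at run
    boundaries.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    sos = _bandpass_sos(tr, low, high, order)
    padlen = min(n - 1, int(np.ceil(1.0 / (low * tr))))
    return scipy.signal.sosfiltfilt(sos, series, axis=-1, padlen=padlen)


def preprocess_run(run: BoldRun, low: float = 0.01, high: float = 0.1,
                   order: int = 4) -> BoldRun:
    """Detrend then band-pass every voxel series of a run.

    Voxels whose filtered series has zero variance are dropped from the
    validity mask: their correlations downstream would be undefined.
    """
    out = np.zeros_like(run.data)
    mask = run.valid_mask.copy()
    ts = run.timeseries(mask)
    ts = bandpass(detrend_linear(ts), run.tr, low=low, high=high, order=order)
    out[mask] = ts
    sd = ts.std(axis=-1)
    dead = sd <= 1e-10 * max(sd.max(), 1.0)  # constant up to roundoff
    if dead.any():
        idx = np.argwhere(mask)
        mask[tuple(idx[dead].T)] = False
    return BoldRun(data=out, tr=run.tr, valid_mask=mask,
                   run_id=run.run_id, affine=run.affine)


def make_gray_mask(probability_map: np.ndarray,
                   threshold: float = 0.3) -> np.ndarray:
    """Threshold a gray-matter probability map into a binary mask.

    A voxel is included iff its probability is >= ``threshold`` (the
    conventional 30 % cut by default).
    """
    p = np.asarray(probability_map, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ParameterError("probabilities must lie in [0, 1]")
    mask = p >= threshold
    if not mask.any():
        warnings.warn("gray-matter mask is empty at this threshold")
    return mask


def compute_gms(run: BoldRun, gray_mask: np.ndarray) -> ReferenceSignal:
    """Global mean signal: unweighted mean over in-mask voxels per frame."""
    gray_mask = np.asarray(gray_mask, dtype=bool)
    if gray_mask.shape != run.shape:
        raise ParameterError("gray mask shape must match run grid")
    joint = gray_mask & run.valid_mask
    if not joint.any():
        raise ParameterError("gray mask has no valid voxels")
    return ReferenceSignal(values=run.data[joint].mean(axis=0),
                           tr=run.tr, label="GMS")


def concatenate_runs(runs: list[BoldRun]) -> tuple[BoldRun, list[tuple[int, int]]]:
    """Temporally concatenate runs sharing a grid and TR.

    Returns the concatenated run and the half-open frame intervals
    ``[(start, stop), ...]`` of each input run, in order, so the result
    can be de-concatenated exactly.
    """
    if not runs:
        raise ParameterError("need at least one run")
    first = runs[0]
    for r in runs[1:]:
        if r.shape != first.shape:
            raise ParameterError("all runs must share the same voxel grid")
        if not np.isclose(r.tr, first.tr):
            raise ParameterError("all runs must share the same TR")
    boundaries: list[tuple[int, int]] = []
    start = 0
    for r in runs:
        boundaries.append((start, start + r.n_timepoints))
        start += r.n_timepoints
    data = np.concatenate([r.data for r in runs], axis=-1)
    mask = np.logical_and.reduce([r.valid_mask for r in runs])
    run_id = "+".join(r.run_id for r in runs if r.run_id)
    return BoldRun(data=data, tr=first.tr, valid_mask=mask, run_id=run_id,
                   affine=first.affine), boundaries


def deconcatenate(series: np.ndarray,
                  boundaries: list[tuple[int, int]]) -> list[np.ndarray]:
    """Split a concatenated time axis back into per-run segments."""
    series = np.asarray(series)
    out = []
    for start, stop in boundaries:
        if stop > series.shape[-1]:
            raise ParameterError("boundaries exceed series length")
        out.append(series[..., start:stop].copy())
    return out
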