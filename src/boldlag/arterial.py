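"""Extracranial artery ROI signals and their coupling to the GMS.

Large arteries appear bright on EPI/T1 images because of the
time-of-flight inflow effect, so an arterial ROI can be extracted
semi-automatically by thresholding intensity inside a search region.  A
peripheral ROI -- the dilation shell around the artery -- provides the
tissue comparison; artery-vs-periphery mean intensities are compared
with a paired t-test across arteries.

Unlike voxelwise lag mapping (which accepts only positive correlation
peaks), the artery-vs-GMS cross-correlation searches both signs and
reports both signed extrema: the physiological finding of interest is a
*negative* coupling (the arterial signal is an inverted, earlier copy of
the global signal), and a positive-only rule would mask it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage
import scipy.stats

from .exceptions import ConstructionError, ParameterError
from .lagcore import xcorr_function
from .preprocess import BoldRun

__all__ = [
    "ArterialResult",
    "PairedComparison",
    "extract_artery_roi",
    "peripheral_roi",
    "compare_artery_periphery",
    "artery_gms_xcorr",
]

_CROSS6 = scipy.ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class ArterialResult:
    """Artery-vs-GMS cross-correlation summary.

    ``peak_lag``/``peak_r`` is the extremum of largest \\|r\\| on the
    symmetric lag grid; the signed extrema are reported separately
    (``None`` when the curve never takes that sign).  ``lag > 0`` means
    the artery series occurs later than the GMS.
    """

    xcorr_lags: np.ndarray
    xcorr_r: np.ndarray
    peak_lag: float
    peak_r: float
    positive_peak: tuple[float, float] | None
    negative_peak: tuple[float, float] | None


@dataclass
class PairedComparison:
    """Artery-vs-periphery temporal-mean comparison across arteries."""

    mean_artery: np.ndarray
    mean_periphery: np.ndarray
    t_stat: float
    p_two_tailed: float


def extract_artery_roi(mean_intensity_image: np.ndarray,
                       search_region: np.ndarray,
                       intensity_threshold: float) -> np.ndarray:
    """Threshold intensity inside a search region; keep the largest blob.

    Ties in component size are broken deterministically by lexicographic
    order of the component's first voxel.  A result covering more than
    half the search region is flagged as suspicious (the threshold is
    probably below the tissue intensity).
    """
    img = np.asarray(mean_intensity_image, dtype=float)
    region = np.asarray(search_region, dtype=bool)
    if not region.any():
        raise ParameterError("search region is empty")
    candidate = region & (img > intensity_threshold)
    if not candidate.any():
        raise ParameterError(
            "no voxels above the intensity threshold; lower it")
    labels, n_lab = scipy.ndimage.label(candidate,
                                        structure=np.ones((3, 3, 3)))
    best_lab, best_size, best_anchor = 0, -1, None
    for lab in range(1, n_lab + 1):
        comp = labels == lab
        size = int(comp.sum())
        anchor = tuple(np.argwhere(comp)[0])
        if size > best_size or (size == best_size and anchor < best_anchor):
            best_lab, best_size, best_anchor = lab, size, anchor
    mask = labels == best_lab
    if mask.sum() > 0.5 * region.sum():
        warnings.warn("arterial ROI covers more than half the search "
                      "region; threshold may be too low")
    return mask


def peripheral_roi(artery_mask: np.ndarray,
                   radius_voxels: int = 2) -> np.ndarray:
    """Dilation shell: inflate the arterial ROI, subtract the original.

    Dilation uses a 6-connectivity structuring element applied
    ``radius_voxels`` times.  The shell is disjoint from the artery by
    construction; if the dilation reaches the image boundary the shell
    is clipped there with a warning.
    """
    artery = np.asarray(artery_mask, dtype=bool)
    if radius_voxels < 1:
        raise ParameterError("radius must be >= 1")
    inflated = scipy.ndimage.binary_dilation(artery, structure=_CROSS6,
                                             iterations=radius_voxels)
    edge = np.zeros_like(inflated)
    edge[0, :, :] = edge[-1, :, :] = True
    edge[:, 0, :] = edge[:, -1, :] = True
    edge[:, :, 0] = edge[:, :, -1] = True
    if (inflated & edge).any() and not (artery & edge).any():
        warnings.warn("peripheral ROI clipped at the image boundary")
    return inflated & ~artery


def compare_artery_periphery(
        pairs: list[tuple[BoldRun, np.ndarray, np.ndarray]]
) -> PairedComparison:
    """Paired t-test of artery vs periphery mean intensity over arteries.

    Each pair contributes the temporal-mean intensity averaged within
    its artery and periphery masks.  Requires at least two pairs; a
    zero-variance difference (degenerate t) is flagged with NaN.
    """
    if len(pairs) < 2:
        raise ParameterError("need at least 2 artery/periphery pairs")
    art, per = [], []
    for run, a_mask, p_mask in pairs:
        a_mask = np.asarray(a_mask, dtype=bool)
        p_mask = np.asarray(p_mask, dtype=bool)
        if (a_mask & p_mask).any():
            raise ConstructionError("artery and periphery masks overlap")
        art.append(float(run.data[a_mask].mean()))
        per.append(float(run.data[p_mask].mean()))
    art_arr, per_arr = np.array(art), np.array(per)
    diff = art_arr - per_arr
    if np.std(diff, ddof=1) == 0:
        warnings.warn("zero-variance paired difference; t undefined")
        return PairedComparison(art_arr, per_arr, float("nan"), float("nan"))
    t, p = scipy.stats.ttest_rel(art_arr, per_arr)
    return PairedComparison(art_arr, per_arr, float(t), float(p))


def artery_gms_xcorr(artery_series: np.ndarray, gms: np.ndarray, tr: float,
                     search_halfwidth: float = 5.8,
                     factor: int = 4) -> ArterialResult:
    """Full artery-vs-GMS cross-correlation on the upsampled lag grid.

    The overall peak is the extremum of largest \\|r\\|; the positive and
    negative extrema are both reported so neither sign of coupling is
    masked.  ``lag > 0`` means the artery signal occurs later than the
    GMS.
    """
    lags, r = xcorr_function(artery_series, gms, tr,
                             search_halfwidth=search_halfwidth,
                             factor=factor)
    i_peak = int(np.nanargmax(np.abs(r)))
    i_pos = int(np.nanargmax(r))
    i_neg = int(np.nanargmin(r))
    positive = (float(lags[i_pos]), float(r[i_pos])) if r[i_pos] > 0 else None
    negative = (float(lags[i_neg]), float(r[i_neg])) if r[i_neg] < 0 else None
    return ArterialResult(xcorr_lags=lags, xcorr_r=r,
                          peak_lag=float(lags[i_peak]),
                          peak_r=float(r[i_peak]),
                          positive_peak=positive, negative_peak=negative)
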