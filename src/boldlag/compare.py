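"""Lag-map comparison statistics and composite-map assembly.

Two lag maps are compared by the Pearson correlation of their
(mean-centered) lag values over the intersection of their valid masks.
Per-run correlations are Fisher-Z transformed and tested against zero
with a two-tailed one-sample t-test over runs.

A composite map superimposes several IC lag maps into one: each IC's
lags are first offset so that the midpoint of its lag range matches the
midpoint of the GMS lag range (offsets are per-IC constants, so
within-IC lag contrasts are never altered), and voxels covered by
several ICs are assigned to the IC with the highest magnitude there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .exceptions import ParameterError
from .lagcore import LagMap

__all__ = [
    "ComparisonStats",
    "CompositeLagMap",
    "center_lags",
    "compare_lag_maps",
    "group_test",
    "build_composite",
    "pooled_histogram",
]


@dataclass
class ComparisonStats:
    """Group-level lag-map similarity: per-run r, Fisher Z, t, p."""

    per_run_r: np.ndarray
    fisher_z: np.ndarray
    t_stat: float
    p_two_tailed: float
    n_voxels_per_run: np.ndarray
    joint_mask_rule: str = "intersection"


@dataclass
class CompositeLagMap:
    """One lag map assembled from several IC maps.

    ``contributor`` holds the index of the IC assigned to each valid
    voxel (-1 where no IC is valid); ``offsets_applied`` records the
    per-IC constant added during range-midpoint alignment.
    """

    lag: np.ndarray
    contributor: np.ndarray
    offsets_applied: np.ndarray
    valid_mask: np.ndarray


def center_lags(lag_map: LagMap) -> LagMap:
    """Shift valid-voxel lags to mean zero (idempotent).

    Zero-centering removes the arbitrary overall offset of a relative
    lag map before comparison; only the mean over valid voxels is
    removed, never any spatial trend.
    """
    if lag_map.n_valid < 2:
        raise ParameterError("need at least 2 valid voxels to center")
    lag = lag_map.lag.copy()
    lag[lag_map.valid_mask] -= lag[lag_map.valid_mask].mean()
    return LagMap(lag=lag, magnitude=lag_map.magnitude.copy(),
                  valid_mask=lag_map.valid_mask.copy(),
                  reference_label=lag_map.reference_label,
                  search_halfwidth=lag_map.search_halfwidth,
                  grid_step=lag_map.grid_step)


def _joint_values(map_a: LagMap, map_b: LagMap
                  ) -> tuple[np.ndarray, np.ndarray]:
    if map_a.lag.shape != map_b.lag.shape:
        raise ParameterError("lag maps must share a grid")
    joint = map_a.valid_mask & map_b.valid_mask
    if not joint.any():
        raise ParameterError("joint valid mask is empty")
    return map_a.lag[joint], map_b.lag[joint]


def compare_lag_maps(map_a: LagMap, map_b: LagMap) -> float:
    """Pearson correlation of two lag maps over their joint valid mask.

    Centering is implicit in the Pearson formula, so the result is
    invariant to adding a constant to either map and symmetric in its
    arguments.  A joint mask under 10 voxels is flagged low-confidence.
    """
    a, b = _joint_values(map_a, map_b)
    if len(a) < 10:
        warnings.warn(f"joint mask has only {len(a)} voxels; "
                      "correlation is low-confidence")
    if a.std() == 0 or b.std() == 0:
        raise ParameterError("a lag map is constant over the joint mask")
    return float(scipy.stats.pearsonr(a, b).statistic)


def group_test(per_run_r: np.ndarray,
               n_voxels_per_run: np.ndarray | None = None) -> ComparisonStats:
    """Two-tailed one-sample t-test of Fisher-Z transformed r over runs."""
    r = np.asarray(per_run_r, dtype=float)
    if len(r) < 2:
        raise ParameterError("need at least 2 runs")
    if np.any(np.abs(r) >= 1):
        raise ParameterError("|r| = 1 gives infinite Fisher Z")
    z = np.arctanh(r)
    if np.std(z, ddof=1) == 0:
        t_stat, p = (0.0, 1.0) if z.mean() == 0 else (np.inf, 0.0)
    else:
        res = scipy.stats.ttest_1samp(z, 0.0)
        t_stat, p = float(res.statistic), float(res.pvalue)
    n_vox = (np.zeros(len(r), dtype=int) if n_voxels_per_run is None
             else np.asarray(n_voxels_per_run, dtype=int))
    return ComparisonStats(per_run_r=r, fisher_z=z, t_stat=t_stat,
                           p_two_tailed=p, n_voxels_per_run=n_vox)


def _range_stat(values: np.ndarray, stat: str) -> float:
    if stat == "midpoint":
        return 0.5 * (float(values.min()) + float(values.max()))
    if stat == "mean":
        return float(values.mean())
    raise ParameterError(f"unknown offset statistic {stat!r}")


def build_composite(ic_lag_maps: list[LagMap], gms_lag_map: LagMap,
                    offset_stat: str = "midpoint") -> CompositeLagMap:
    """Superimpose IC lag maps, aligned to the GMS lag range.

    Per IC, the offset ``range-stat(GMS lags) - range-stat(IC lags)`` is
    added to the IC's lags (``offset_stat`` is the midpoint of the
    valid-lag range by default, the mean as an alternative read-out).
    Voxels covered by several ICs go to the IC with the highest
    magnitude there.
    """
    if not ic_lag_maps:
        raise ParameterError("need at least one IC lag map")
    if not gms_lag_map.valid_mask.any():
        raise ParameterError("GMS lag map has no valid voxels")
    shape = gms_lag_map.lag.shape
    gms_center = _range_stat(gms_lag_map.lag[gms_lag_map.valid_mask],
                             offset_stat)

    offsets = np.zeros(len(ic_lag_maps))
    lag = np.full(shape, np.nan)
    contributor = np.full(shape, -1, dtype=int)
    best_mag = np.full(shape, -np.inf)
    any_valid = np.zeros(shape, dtype=bool)
    for i, icm in enumerate(ic_lag_maps):
        if icm.lag.shape != shape:
            raise ParameterError("IC maps must share the GMS grid")
        if not icm.valid_mask.any():
            continue
        offsets[i] = gms_center - _range_stat(icm.lag[icm.valid_mask],
                                              offset_stat)
        take = icm.valid_mask & (np.nan_to_num(icm.magnitude, nan=-np.inf)
                                 > best_mag)
        lag[take] = icm.lag[take] + offsets[i]
        contributor[take] = i
        best_mag[take] = icm.magnitude[take]
        any_valid |= icm.valid_mask
    if not any_valid.any():
        raise ParameterError("no IC map has valid voxels")
    return CompositeLagMap(lag=lag, contributor=contributor,
                           offsets_applied=offsets, valid_mask=any_valid)


def pooled_histogram(map_pairs: list[tuple[LagMap, LagMap]],
                     grid_step: float | None = None,
                     search_halfwidth: float | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """2D histogram of pooled (lag_a, lag_b) voxel pairs across runs.

    Bin edges are aligned to the upsampled lag grid (each grid value
    sits at a bin center), so identical maps put all mass on the
    diagonal and the total count equals the summed joint-mask sizes.
    Returns ``(counts, edges)`` with shared x/y edges.
    """
    if not map_pairs:
        raise ParameterError("need at least one map pair")
    first_a = map_pairs[0][0]
    step = first_a.grid_step if grid_step is None else grid_step
    half = (first_a.search_halfwidth if search_halfwidth is None
            else search_halfwidth)
    k = int(np.ceil(half / step)) + 1
    edges = (np.arange(-k, k + 1) + 0.5) * step
    counts = np.zeros((len(edges) - 1, len(edges) - 1))
    for map_a, map_b in map_pairs:
        a, b = _joint_values(map_a, map_b)
        h, _, _ = np.histogram2d(a, b, bins=[edges, edges])
        counts += h
    return counts, edges
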