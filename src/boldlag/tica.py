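"""Two-stage temporal ICA with Icasso-style reproducibility clustering.

The decomposition follows the two-stage strategy used for large
concatenated resting-state datasets: a group spatial ICA first reduces
the data to a manageable set of time courses, then a temporal ICA on
those time courses extracts temporally independent components.  Because
ICA estimates depend on their random initialization, the temporal stage
is repeated many times; all estimates are pooled and clustered by
absolute correlation, each cluster's *centrotype* (the member most
similar to the rest of its cluster) is returned as the component, and
the cluster-quality index ``iq`` -- mean intra-cluster minus mean
extra-cluster similarity -- quantifies how reproducible the component
is.  Tight clusters (iq near 1) mean the component is found again and
again regardless of initialization.

Components are labeled ``global`` when their magnitude map covers most
of the gray-matter mask and ``local`` when it is confined to a
subregion; the coverage cutoff is a configurable heuristic, not a
principled decision rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .exceptions import ParameterError
from .lagcore import LagMap, compute_lag_map
from .preprocess import BoldRun, ReferenceSignal

__all__ = [
    "ICADecomposition",
    "group_spatial_ica",
    "temporal_ica_icasso",
    "magnitude_and_lag_per_ic",
    "classify_components",
    "select_reliable_components",
]


@dataclass
class ICADecomposition:
    """Temporal ICs with reproducibility indices and spatial labels."""

    timecourses: np.ndarray  # (T, n_components), unit variance columns
    iq: np.ndarray  # (n_components,) cluster quality in [0, 1]
    spatial_maps: list[np.ndarray] | None = None  # per-IC magnitude grids
    labels: list[str] = field(default_factory=list)
    n_components: int = 0

    def __post_init__(self) -> None:
        self.timecourses = np.asarray(self.timecourses, dtype=float)
        self.iq = np.asarray(self.iq, dtype=float)
        if self.n_components == 0:
            self.n_components = self.timecourses.shape[1]
        if self.timecourses.shape[1] != self.n_components:
            raise ParameterError("timecourse columns != n_components")
        if len(self.iq) != self.n_components:
            raise ParameterError("iq length != n_components")
        if not self.labels:
            self.labels = ["unclassified"] * self.n_components


def group_spatial_ica(concatenated_run: BoldRun, n_spatial_components: int,
                      seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Group spatial ICA: independent spatial maps + their time courses.

    Voxel time series are demeaned over time, whitened by an SVD across
    voxels, and rotated by FastICA so the resulting *spatial* maps are
    maximally independent; the associated time courses (least-squares
    projection of the data onto the maps) feed the temporal stage.
    Whitening is done explicitly rather than inside FastICA: the library
    default would subtract the instantaneous spatial mean, which is
    exactly the global component this analysis must preserve.

    Returns ``(spatial_components, timecourses)`` with shapes
    ``(n, X, Y, Z)`` and ``(T, n)``.  If the data rank cannot support
    the requested model order, the order is reduced with a warning.
    """
    X = concatenated_run.timeseries()  # (V, T)
    n_comp = int(n_spatial_components)
    if n_comp < 1:
        raise ParameterError("need at least one component")
    if n_comp >= concatenated_run.n_timepoints:
        raise ParameterError("n_spatial_components must be < n_timepoints")
    Xc = X - X.mean(axis=-1, keepdims=True)
    U, sv, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int((sv > sv[0] * 1e-10).sum())
    if n_comp > rank:
        warnings.warn(f"requested {n_comp} spatial components but data "
                      f"rank is {rank}; reducing")
        n_comp = rank
    white = U[:, :n_comp] * np.sqrt(X.shape[0])  # (V, n), unit variance
    if n_comp > 1:
        ica = FastICA(random_state=seed, whiten=False, max_iter=1000)
        sources = ica.fit_transform(white)  # (V, n) spatial maps
    else:
        sources = white
    sources = sources / sources.std(axis=0, keepdims=True)
    timecourses = np.linalg.lstsq(sources, Xc, rcond=None)[0].T  # (T, n)
    maps = np.zeros((n_comp, *concatenated_run.shape))
    for i in range(n_comp):
        maps[i][concatenated_run.valid_mask] = sources[:, i]
    return maps, timecourses


def _standardize_columns(mat: np.ndarray) -> np.ndarray:
    mat = mat - mat.mean(axis=0, keepdims=True)
    sd = mat.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return mat / sd


def temporal_ica_icasso(timecourses: np.ndarray, n_components: int,
                        n_repeats: int = 20, seed: int = 0,
                        fun: str = "logcosh", algorithm: str = "parallel",
                        bootstrap: bool = True) -> ICADecomposition:
    """Temporal ICA repeated under resampling, clustered for stability.

    Each repeat bootstraps the time points (ICA is invariant to sample
    order, so resampling rows is legitimate), fits FastICA with a seed
    derived from the master seed by a simple counter, and evaluates the
    learned unmixing on the full data so all estimates share a time
    axis.  All estimated components are pooled, clustered by
    average-linkage agglomeration on dissimilarity ``1 - |r|`` into
    ``n_components`` clusters, and each cluster's centrotype is
    returned.  Reproducible components survive resampling and cluster
    tightly (iq near 1); components fitting noise wander from repeat to
    repeat and earn a low iq.  Non-convergent repeats are dropped; more
    than half dropping is an error.
    """
    Y = np.asarray(timecourses, dtype=float)
    if Y.ndim != 2:
        raise ParameterError("timecourses must be (T, channels)")
    if n_repeats < 10:
        raise ParameterError("need at least 10 repeats for clustering")
    pooled = []
    n_failed = 0
    boot_rng = np.random.default_rng((seed, 0x1CA550))
    for rep in range(n_repeats):
        if bootstrap:
            rows = boot_rng.integers(0, Y.shape[0], Y.shape[0])
            fit_data = Y[rows]
        else:
            fit_data = Y
        ica = FastICA(n_components=n_components, random_state=seed + rep,
                      whiten="unit-variance", fun=fun, algorithm=algorithm,
                      max_iter=500)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                ica.fit(fit_data)
                src = ica.transform(Y)  # (T, n) on the shared time axis
            except Exception:
                n_failed += 1
                continue
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            n_failed += 1
            continue
        pooled.append(_standardize_columns(src))
    if n_failed > n_repeats / 2:
        raise ParameterError(
            f"{n_failed}/{n_repeats} ICA repeats failed to converge")
    allc = np.concatenate(pooled, axis=1)  # (T, R*n)
    sim = np.abs(np.corrcoef(allc.T))
    clust = AgglomerativeClustering(n_clusters=n_components,
                                    metric="precomputed",
                                    linkage="average")
    assign = clust.fit_predict(1.0 - sim)

    centrotypes = np.zeros((Y.shape[0], n_components))
    iq = np.zeros(n_components)
    for c in range(n_components):
        members = np.flatnonzero(assign == c)
        others = np.flatnonzero(assign != c)
        sub = sim[np.ix_(members, members)]
        centro = members[int(np.argmax(sub.sum(axis=1)))]
        centrotypes[:, c] = allc[:, centro]
        if len(members) > 1:
            intra = (sub.sum() - len(members)) / (len(members) ** 2
                                                  - len(members))
        else:
            intra = 1.0
        extra = sim[np.ix_(members, others)].mean() if len(others) else 0.0
        iq[c] = float(np.clip(intra - extra, 0.0, 1.0))
    order = np.argsort(-iq)
    return ICADecomposition(
        timecourses=_standardize_columns(centrotypes[:, order]),
        iq=iq[order])


def magnitude_and_lag_per_ic(run: BoldRun, decomposition: ICADecomposition,
                             search_halfwidth: float = 5.8,
                             r_threshold: float = 0.3,
                             factor: int = 4) -> list[LagMap]:
    """One lag/magnitude map per IC, computed against each IC reference.

    The IC time courses must already be at the run's frame count
    (de-concatenated if the decomposition came from concatenated data).
    The per-IC magnitude grids are stored back on the decomposition for
    spatial classification.
    """
    if decomposition.timecourses.shape[0] != run.n_timepoints:
        raise ParameterError(
            "IC time courses must match the run's frame count "
            "(de-concatenate first)")
    maps = []
    for i in range(decomposition.n_components):
        ref = ReferenceSignal(values=decomposition.timecourses[:, i],
                              tr=run.tr, label="IC")
        maps.append(compute_lag_map(run, ref,
                                    search_halfwidth=search_halfwidth,
                                    r_threshold=r_threshold, factor=factor))
    decomposition.spatial_maps = [m.magnitude for m in maps]
    return maps


def classify_components(decomposition: ICADecomposition,
                        gray_mask: np.ndarray, r_threshold: float = 0.3,
                        coverage_cutoff: float = 0.5) -> list[str]:
    """Label each IC local or global by gray-matter coverage.

    A component is ``global`` when the fraction of gray-mask voxels
    whose magnitude exceeds ``r_threshold`` is above
    ``coverage_cutoff``; otherwise ``local``.  This is a coverage
    heuristic standing in for visual spatial-pattern judgment.
    """
    if decomposition.spatial_maps is None:
        raise ParameterError("magnitude maps missing; run "
                             "magnitude_and_lag_per_ic first")
    gray_mask = np.asarray(gray_mask, dtype=bool)
    labels = []
    for mag in decomposition.spatial_maps:
        covered = np.nan_to_num(mag[gray_mask], nan=0.0) > r_threshold
        frac = covered.mean() if covered.size else 0.0
        labels.append("global" if frac > coverage_cutoff else "local")
    decomposition.labels = labels
    return labels


def select_reliable_components(magnitude_maps_per_run: list[list[np.ndarray]],
                               r_threshold: float = 0.3) -> list[int]:
    """Indices of ICs with a voxel surviving the threshold in every run.

    The inclusion rule for downstream analysis: an IC is retained iff at
    least one voxel's magnitude consistently exceeds ``r_threshold``
    across all runs.
    """
    if not magnitude_maps_per_run:
        raise ParameterError("no runs given")
    n_ics = len(magnitude_maps_per_run[0])
    keep = []
    for i in range(n_ics):
        survive = np.ones_like(
            np.asarray(magnitude_maps_per_run[0][i], dtype=float), dtype=bool)
        for run_maps in magnitude_maps_per_run:
            survive &= np.nan_to_num(np.asarray(run_maps[i], dtype=float),
                                     nan=0.0) > r_threshold
        if survive.any():
            keep.append(i)
    return keep
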