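"""Synthetic 4D BOLD-like data with known hemodynamic delay fields.

The generator emulates the statistical structure the lag analysis
assumes: band-limited (0.01-0.1 Hz) global and network source signals, a
smooth voxelwise delay field spanning a few seconds (with optional late
"watershed-like" zones at perfusion-territory borders), additive noise,
block-design task responses shifted by the same delay field, and a
bright arterial voxel cluster whose signal is an inverted, time-shifted
copy of the global source.

The signal model for a resting voxel v is

    y_v(t) = sum_k w_kv * s_k(t - d_v) + eps_v(t)

-- a set of synchronous sources whose local expression is delayed by the
voxel's hemodynamic delay d_v.  Sub-sample delays are applied by
frequency-domain phase shifting (with reflect padding to handle the
periodic boundary), never by nearest-sample rounding, so the stored
ground truth is finer than the estimator's quarter-TR grid.

Sources are built by band-pass filtering white Gaussian noise, then
passed through a pointwise cubic nonlinearity and re-filtered.  The
final filter guarantees the band limit; the nonlinearity leaves each
source clearly super-Gaussian, which is what makes the mixture
identifiable for the temporal ICA stage (band-limited Gaussian sources
with identical spectra would be unrecoverable in principle).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConstructionError, ParameterError
from .preprocess import BoldRun, bandpass
from .taskglm import TaskDesign, canonical_hrf

__all__ = [
    "SourceSet",
    "DelayField",
    "ArterialParams",
    "GroundTruth",
    "make_sources",
    "make_delay_field",
    "default_network_weights",
    "make_ground_truth",
    "render_resting_run",
    "render_task_run",
    "render_arterial_voxels",
    "default_active_mask",
]

DEFAULT_BAND = (0.01, 0.1)
DEFAULT_SHAPE = (20, 20, 12)


@dataclass
class SourceSet:
    """Band-limited unit-variance source signals: one global + networks.

    ``extended``, when present, holds the same sources on a longer
    support (``margin`` extra samples on each side); the stored sources
    are its central segment.  Rendering uses the extended support so
    that time-shifted copies near the run edges draw on real signal
    content instead of a reflected surrogate -- the underlying
    physiological signal exists outside the scan window.
    """

    n_timepoints: int
    tr: float
    global_source: np.ndarray
    network_sources: list[np.ndarray]
    band: tuple[float, float] = DEFAULT_BAND
    margin: int = 0
    extended: np.ndarray | None = None  # (K, n + 2*margin), global first

    def __post_init__(self) -> None:
        self.global_source = np.asarray(self.global_source, dtype=float)
        self.network_sources = [np.asarray(s, dtype=float)
                                for s in self.network_sources]
        for s in [self.global_source, *self.network_sources]:
            if len(s) != self.n_timepoints:
                raise ConstructionError("source length mismatch")
        if self.extended is not None:
            self.extended = np.asarray(self.extended, dtype=float)
            k = len(self.network_sources) + 1
            if self.extended.shape != (k, self.n_timepoints
                                       + 2 * self.margin):
                raise ConstructionError("extended support shape mismatch")

    @property
    def all_sources(self) -> np.ndarray:
        """(K, T) stack: global source first, then network sources."""
        return np.vstack([self.global_source, *self.network_sources]) \
            if self.network_sources else self.global_source[None, :]

    def extended_or_padded(self) -> tuple[np.ndarray, int]:
        """(K, L) support used for rendering shifts, and its margin."""
        if self.extended is not None:
            return self.extended, self.margin
        m = max(16, int(np.ceil(8.0 / self.tr)))
        return np.pad(self.all_sources, ((0, 0), (m, m)),
                      mode="reflect"), m


@dataclass
class DelayField:
    """A smooth 3D grid of per-voxel hemodynamic delays in seconds."""

    values: np.ndarray
    range: tuple[float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        lo, hi = self.range
        if self.values.min() < lo - 1e-9 or self.values.max() > hi + 1e-9:
            raise ConstructionError("delay values outside stated range")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass
class ArterialParams:
    """Arterial signal model: gain * global(t - shift) + intensity offset.

    ``gain < 0`` (inverted coupling) and ``shift < 0`` (the artery leads
    the global signal) in the default scenario; ``intensity_offset > 0``
    models the time-of-flight inflow brightening of arteries relative to
    surrounding tissue.
    """

    gain: float = -1.0
    shift: float = -2.7
    intensity_offset: float = 20.0


@dataclass
class GroundTruth:
    """Everything needed to render a scenario and score recovery."""

    delay_field: DelayField
    sources: SourceSet
    weights: np.ndarray  # (K, X, Y, Z), global weights first
    noise_sigma: float
    arterial: ArterialParams = field(default_factory=ArterialParams)
    noise_ar1: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        k = len(self.sources.network_sources) + 1
        if self.weights.shape != (k, *self.delay_field.shape):
            raise ConstructionError(
                "weights must be shaped (n_sources, *delay grid)")

    def to_json(self, path: str) -> None:
        doc = {
            "seed": self.seed,
            "noise_sigma": self.noise_sigma,
            "noise_ar1": self.noise_ar1,
            "arterial": {"gain": self.arterial.gain,
                         "shift": self.arterial.shift,
                         "intensity_offset": self.arterial.intensity_offset},
            "delay_field": {"values": self.delay_field.values.tolist(),
                            "range": list(self.delay_field.range)},
            "sources": {
                "n_timepoints": self.sources.n_timepoints,
                "tr": self.sources.tr,
                "band": list(self.sources.band),
                "global_source": self.sources.global_source.tolist(),
                "network_sources": [s.tolist()
                                    for s in self.sources.network_sources],
                "margin": self.sources.margin,
                "extended": (None if self.sources.extended is None
                             else self.sources.extended.tolist()),
            },
            "weights": self.weights.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            doc = json.load(fh)
        src = doc["sources"]
        sources = SourceSet(
            n_timepoints=src["n_timepoints"], tr=src["tr"],
            global_source=np.array(src["global_source"]),
            network_sources=[np.array(s) for s in src["network_sources"]],
            band=tuple(src["band"]), margin=src.get("margin", 0),
            extended=(None if src.get("extended") is None
                      else np.array(src["extended"])))
        fld = DelayField(values=np.array(doc["delay_field"]["values"]),
                         range=tuple(doc["delay_field"]["range"]))
        art = ArterialParams(**doc["arterial"])
        return cls(delay_field=fld, sources=sources,
                   weights=np.array(doc["weights"]),
                   noise_sigma=doc["noise_sigma"], arterial=art,
                   noise_ar1=doc["noise_ar1"], seed=doc["seed"])


def _band_limited_nongaussian(rng: np.random.Generator, n: int, tr: float,
                              band: tuple[float, float]) -> np.ndarray:
    """One unit-variance band-limited super-Gaussian source.

    The generation filter edges sit slightly inside the stated band so
    that the Butterworth transition-band leakage stays inside it too,
    keeping >= 95 % of the power within the stated band.
    """
    low, high = band
    gen = (1.2 * low, 0.85 * high)
    x = bandpass(rng.standard_normal(n), tr, *gen)
    x = x / x.std()
    # winsorized cube: sparsifies without letting a single extreme sample
    # dominate the series (a near-delta source is as bad for ICA as a
    # Gaussian one); cubing widens the spectrum ...
    x = np.clip(x, -2.5, 2.5) ** 3
    x = bandpass(x, tr, *gen)  # ... so re-impose the band last
    return x / x.std()


def make_sources(n_timepoints: int, tr: float,
                 band: tuple[float, float] = DEFAULT_BAND,
                 n_networks: int = 3, seed: int = 0) -> SourceSet:
    """Generate one global and ``n_networks`` network source signals.

    All sources are unit variance with >= 95 % of their power inside
    ``band``; network sources are exactly decorrelated among themselves
    by symmetric orthogonalization (a near-identity linear mix, so their
    higher-order independence is essentially preserved).  Deterministic
    given ``seed``.
    """
    if n_timepoints < 128:
        raise ParameterError("need at least 128 time points")
    nyq = 0.5 / tr
    if not (0.0 < band[0] < band[1] < nyq):
        raise ParameterError(f"band {band} outside (0, Nyquist={nyq:.4g})")
    rng = np.random.default_rng(seed)
    margin = max(16, int(np.ceil(16.0 / tr)))
    n_ext = n_timepoints + 2 * margin
    ext = np.vstack([_band_limited_nongaussian(rng, n_ext, tr, band)
                     for _ in range(n_networks + 1)])
    if n_networks >= 2:
        # exact decorrelation of the network sources over the run window
        central = ext[1:, margin:margin + n_timepoints]
        c = np.corrcoef(central)
        evals, evecs = np.linalg.eigh(c)
        w = evecs @ np.diag(evals ** -0.5) @ evecs.T
        ext[1:] = w @ ext[1:]
    central = ext[:, margin:margin + n_timepoints]
    ext = ext / central.std(axis=-1, keepdims=True)
    central = ext[:, margin:margin + n_timepoints]
    return SourceSet(n_timepoints=n_timepoints, tr=tr,
                     global_source=central[0],
                     network_sources=[row for row in central[1:]],
                     band=band, margin=margin, extended=ext)


def make_delay_field(shape: tuple[int, int, int] = DEFAULT_SHAPE,
                     pattern: str = "gradient",
                     delay_range: tuple[float, float] = (-2.0, 2.0),
                     seed: int = 0, search_halfwidth: float = 5.8,
                     max_neighbor_step: float = 0.5) -> DelayField:
    """Build a smooth ground-truth delay field.

    Patterns: ``constant`` (the range midpoint everywhere), ``gradient``
    (monotone ramp along the first axis), ``watershed`` (ramp plus late
    Gaussian zones emulating border-zone regions that respond last).
    The span of ``delay_range`` must fit inside the downstream search
    window; neighboring voxels should differ by at most
    ``max_neighbor_step`` seconds (checked, warning on violation).
    """
    import warnings

    lo, hi = delay_range
    if hi < lo:
        raise ParameterError("delay range must have min <= max")
    if hi - lo > 2 * search_halfwidth:
        raise ParameterError("delay range wider than the search window")
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3:
        raise ParameterError("shape must be a 3D grid")

    if pattern == "constant":
        values = np.full(shape, 0.5 * (lo + hi))
    elif pattern == "gradient":
        ramp = np.linspace(lo, hi, shape[0])
        values = np.broadcast_to(ramp[:, None, None], shape).copy()
    elif pattern == "watershed":
        rng = np.random.default_rng(seed)
        ramp = np.linspace(lo, hi, shape[0])
        values = np.broadcast_to(ramp[:, None, None], shape).copy()
        centers = np.array([[0.30, 0.50, 0.50], [0.75, 0.35, 0.50]])
        centers = centers + rng.uniform(-0.05, 0.05, centers.shape)
        sigma = max(shape) / 5.0
        grid = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                                    indexing="ij"), axis=-1).astype(float)
        span = hi - lo if hi > lo else 1.0
        for c in centers:
            d2 = ((grid - c * np.array(shape)) ** 2).sum(axis=-1)
            values = values + 0.5 * span * np.exp(-0.5 * d2 / sigma ** 2)
        if values.max() > values.min():  # affine rescale back into range
            values = lo + (hi - lo) * (values - values.min()) \
                / (values.max() - values.min())
    else:
        raise ParameterError(f"unknown pattern {pattern!r}")

    for axis in range(3):
        if shape[axis] > 1:
            step = np.abs(np.diff(values, axis=axis)).max()
            if step > max_neighbor_step + 1e-9:
                warnings.warn(
                    f"delay field neighbor step {step:.3g}s exceeds "
                    f"{max_neighbor_step}s along axis {axis}")
    return DelayField(values=values, range=(lo, hi))


def default_network_weights(shape: tuple[int, int, int], n_networks: int,
                            seed: int = 0) -> np.ndarray:
    """Smooth compact spatial blobs, one per network source.

    Blob centers are spread along the first axis with widths chosen so
    that pairwise voxel overlap (both weights above 10 % of peak) stays
    small -- emulating "local" components confined to subregions.
    """
    shape = tuple(int(s) for s in shape)
    rng = np.random.default_rng(seed)
    grid = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                                indexing="ij"), axis=-1).astype(float)
    w = np.zeros((n_networks, *shape))
    centers_x = np.linspace(0.15, 0.85, n_networks)
    sigma = shape[0] / (2.5 * n_networks)
    for i, cx in enumerate(centers_x):
        center = np.array([cx * shape[0],
                           rng.uniform(0.35, 0.65) * shape[1],
                           rng.uniform(0.35, 0.65) * shape[2]])
        d2 = ((grid - center) ** 2).sum(axis=-1)
        w[i] = np.exp(-0.5 * d2 / sigma ** 2)
        w[i][w[i] < 0.05] = 0.0
    return w


def make_ground_truth(shape: tuple[int, int, int] = DEFAULT_SHAPE,
                      n_timepoints: int = 600, tr: float = 0.72,
                      band: tuple[float, float] = DEFAULT_BAND,
                      n_networks: int = 0,
                      pattern: str = "watershed",
                      delay_range: tuple[float, float] = (-2.0, 2.0),
                      noise_sigma: float = 1.33,
                      global_weight: float = 1.0,
                      noise_ar1: float = 0.0,
                      arterial: ArterialParams | None = None,
                      seed: int = 0) -> GroundTruth:
    """Assemble a complete scenario with sources, delays, and weights.

    The default noise level (sigma = 1.33 per unit-variance signal)
    puts the raw voxel-to-source correlation near 0.6, a realistic
    mid-range magnitude for resting-state lag mapping.
    """
    sources = make_sources(n_timepoints, tr, band=band,
                           n_networks=n_networks, seed=seed)
    fld = make_delay_field(shape, pattern=pattern, delay_range=delay_range,
                           seed=seed)
    weights = np.zeros((n_networks + 1, *fld.shape))
    weights[0] = global_weight
    if n_networks:
        weights[1:] = default_network_weights(fld.shape, n_networks,
                                              seed=seed)
    return GroundTruth(delay_field=fld, sources=sources, weights=weights,
                       noise_sigma=noise_sigma, noise_ar1=noise_ar1,
                       arterial=arterial or ArterialParams(), seed=seed)


def _phase_shift_rows(mat: np.ndarray, delays: np.ndarray,
                      tr: float) -> np.ndarray:
    """Delay each row of (V, T) ``mat`` by its own ``delays[v]`` seconds.

    Implemented as a frequency-domain phase shift on a reflect-padded
    copy (padding absorbs the periodic boundary), so sub-sample delays
    are exact for band-limited content.
    """
    mat = np.atleast_2d(np.asarray(mat, dtype=float))
    delays = np.asarray(delays, dtype=float).ravel()
    n = mat.shape[-1]
    max_d = float(np.max(np.abs(delays))) if delays.size else 0.0
    if max_d >= n * tr / 4:
        raise ParameterError("delay exceeds the series support")
    pad = max(16, int(np.ceil(max_d / tr)) + 8)
    padded = np.pad(mat, ((0, 0), (pad, pad)), mode="reflect")
    L = padded.shape[-1]
    freqs = np.fft.rfftfreq(L, d=tr)
    spectrum = np.fft.rfft(padded, axis=-1)
    spectrum = spectrum * np.exp(-2j * np.pi * freqs[None, :] * delays[:, None])
    shifted = np.fft.irfft(spectrum, n=L, axis=-1)
    return shifted[:, pad:pad + n]


def _noise(rng: np.random.Generator, shape: tuple[int, ...], sigma: float,
           ar1: float) -> np.ndarray:
    """i.i.d. Gaussian noise, optionally AR(1) with unit marginal SD."""
    eps = rng.standard_normal(shape)
    if ar1:
        import scipy.signal
        eps = scipy.signal.lfilter([1.0], [1.0, -ar1], eps, axis=-1)
        eps *= np.sqrt(1.0 - ar1 ** 2)
    return sigma * eps


def render_resting_run(gt: GroundTruth,
                       run_id: str = "synthetic-rest") -> BoldRun:
    """Render a resting run: delayed source mixture plus noise.

    The noiseless version, lag-mapped against the global source,
    recovers the delay field up to the estimator's grid quantization.
    Bit-identical output for a fixed ``GroundTruth``.
    """
    shape = gt.delay_field.shape
    ext, margin = gt.sources.extended_or_padded()  # (K, L)
    W = gt.weights.reshape(ext.shape[0], -1)  # (K, V)
    mixed = W.T @ ext  # (V, L)
    shifted = _phase_shift_rows(mixed, gt.delay_field.values.ravel(),
                                gt.sources.tr)
    shifted = shifted[:, margin:margin + gt.sources.n_timepoints]
    rng = np.random.default_rng((gt.seed, 0xB01D))
    data = shifted + _noise(rng, shifted.shape, gt.noise_sigma, gt.noise_ar1)
    return BoldRun(data=data.reshape(*shape, gt.sources.n_timepoints),
                   tr=gt.sources.tr, run_id=run_id)


def default_active_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Central ellipsoid covering roughly a quarter of the volume."""
    shape = tuple(int(s) for s in shape)
    grid = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                                indexing="ij"), axis=-1).astype(float)
    center = (np.array(shape) - 1) / 2.0
    radii = np.maximum(np.array(shape) / 3.0, 1.0)
    return (((grid - center) / radii) ** 2).sum(axis=-1) <= 1.0


def render_task_run(design: TaskDesign, delay_field: DelayField,
                    hrf_params: dict | None = None, noise_sigma: float = 0.0,
                    seed: int = 0, active_mask: np.ndarray | None = None,
                    amplitude: float = 1.0,
                    oversample: int = 16) -> BoldRun:
    """Render a block-design task run with voxelwise-delayed responses.

    Active voxels carry the HRF-convolved block response shifted by
    their delay; inactive voxels carry noise only.  The response is
    built on a grid ``oversample`` times finer than TR and sampled at
    each voxel's delayed frame times.
    """
    shape = delay_field.shape
    if active_mask is None:
        active_mask = default_active_mask(shape)
    active_mask = np.asarray(active_mask, dtype=bool)
    if active_mask.shape != shape:
        raise ConstructionError("active mask must match the delay grid")
    tr = design.tr
    n = design.run_length
    max_d = float(np.abs(delay_field.values).max())
    if max_d >= n * tr / 4:
        raise ParameterError("delay exceeds the series support")
    dt = tr / oversample
    margin = max_d + 32.0  # covers HRF length + delay excursions
    t_fine = np.arange(-margin, n * tr + margin, dt)
    box = ((t_fine[None, :] >= design.onsets[:, None])
           & (t_fine[None, :] < (design.onsets + design.durations)[:, None])
           ).any(axis=0).astype(float)
    kern = canonical_hrf(dt, **(hrf_params or {}))
    resp = np.convolve(box, kern)[: len(t_fine)]
    resp = amplitude * resp / max(resp.max(), np.finfo(float).tiny)

    t_frames = np.arange(n) * tr
    delays = delay_field.values[active_mask]
    series = np.interp(t_frames[None, :] - delays[:, None], t_fine, resp)

    rng = np.random.default_rng((seed, 0x7A5C))
    data = _noise(rng, (*shape, n), noise_sigma, 0.0)
    data[active_mask] += series
    return BoldRun(data=data, tr=tr, run_id="synthetic-task")


def render_arterial_voxels(gt: GroundTruth,
                           shape: tuple[int, int, int] = (9, 9, 10),
                           baseline: float = 100.0,
                           radius_voxels: int = 2,
                           ) -> tuple[BoldRun, np.ndarray, np.ndarray]:
    """Render a patch containing a bright artery tube and its periphery.

    Artery voxels: ``baseline + intensity_offset + gain * global(t -
    shift) + noise`` -- an inverted, time-shifted copy of the global
    source riding on an elevated baseline (the inflow brightening).
    Periphery voxels (a dilation shell around the tube): baseline +
    noise.  The two masks are disjoint by construction.
    """
    from .arterial import peripheral_roi

    if gt.arterial.gain == 0:
        raise ParameterError("arterial gain must be nonzero")
    shape = tuple(int(s) for s in shape)
    artery = np.zeros(shape, dtype=bool)
    cx, cy = shape[0] // 2, shape[1] // 2
    artery[cx, cy, 1:shape[2] - 1] = True
    periphery = peripheral_roi(artery, radius_voxels=radius_voxels)
    if (artery & periphery).any():
        raise ConstructionError("artery and periphery masks overlap")

    ext, margin = gt.sources.extended_or_padded()
    n = gt.sources.n_timepoints
    shifted = _phase_shift_rows(ext[:1], [gt.arterial.shift],
                                gt.sources.tr)[0][margin:margin + n]
    rng = np.random.default_rng((gt.seed, 0xA57))
    data = baseline + _noise(rng, (*shape, n), gt.noise_sigma,
                             gt.noise_ar1)
    data[artery] += gt.arterial.intensity_offset \
        + gt.arterial.gain * shifted
    run = BoldRun(data=data, tr=gt.sources.tr, run_id="synthetic-artery")
    return run, artery, periphery
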