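# boldlag

Voxelwise time-lag mapping for BOLD fMRI, with the surrounding apparatus
needed to study where the lag pattern comes from: temporal ICA of
resting-state data, block-design task references, arterial signal
analysis, and a synthetic 4D data generator with known hemodynamic delay
fields so every stage can be tested against ground truth.

## Who this is for

Researchers working on the resting-state BOLD "time lag" phenomenon —
the observation that the global mean signal (GMS) appears to sweep
through the brain over several seconds, tracing the pattern of vascular
perfusion. The central scientific question the pipeline supports: is
that lag a *traveling signal*, or does a synchronous source simply get
expressed with regionally varying hemodynamic delay? The package lets
you compare lag maps computed against very different reference signals
(GMS, network IC time courses, task-evoked responses, arterial signals)
on data where the answer is known by construction.

## The method

For each voxel time series $y_v$ and a reference series $s$ (both
detrended and band-passed to 0.01–0.1 Hz with a zero-phase filter), the
**lag** is the shift $t$ maximizing the Pearson correlation

$$\hat{t}_v = \arg\max_{|t| \le T_w,\ r > 0} \; \mathrm{corr}\big(y_v(\cdot),\ s(\cdot - t)\big),$$

searched on a grid upsampled to 1/4 TR (0.18 s at TR = 0.72 s) within a
window $T_w = 5.8$ s (= 8 TR), with the correlation recomputed over the
overlapping segment at each shift. Only positive peaks count; a voxel
with none is invalid. The correlation at the best shift is the voxel's
**magnitude**, thresholded at $r > 0.3$ (with an autocorrelation-adjusted
$Z > 3$ score available as a diagnostic — smooth series carry fewer
effective degrees of freedom, so the same $r$ earns a smaller $Z$).

Around that core:

* **`synthetic_data`** — renders resting runs
  $y_v(t) = \sum_k w_{kv}\, s_k(t - d_v) + \varepsilon$ from band-limited
  sources, a smooth delay field $d_v$ (with "watershed-like" late zones),
  task runs with HRF-convolved, voxelwise-delayed block responses, and a
  bright artery whose signal is an inverted, time-shifted copy of the
  global source. Ground truth serializes to a JSON sidecar.
* **`preprocess`** — detrend, zero-phase Butterworth band-pass,
  gray-matter masks, GMS, run concatenation/de-concatenation.
* **`lagcore`** — the lag/magnitude maps and the adjusted-Z statistic.
* **`tica`** — group spatial ICA followed by temporal FastICA repeated
  under bootstrap resampling with Icasso-style clustering; each
  component's cluster-quality index iq measures its reproducibility.
* **`taskglm`** — canonical double-gamma HRF, cosine-drift design
  matrices, per-voxel OLS t-maps, cluster-extent activation masks, and
  the task-mean reference.
* **`arterial`** — intensity-threshold artery ROIs, dilation-shell
  peripheries, paired artery-vs-tissue tests, and the full signed
  artery-vs-GMS cross-correlation function.
* **`compare`** — lag-map correlations over joint masks, Fisher-Z group
  tests over runs, composite maps assembled from several IC maps
  (range-midpoint offset alignment, overlap resolved by magnitude), and
  pooled 2D lag histograms.

## Worked example

Recover a known delay field end-to-end from synthetic data:

```python
import numpy as np
from boldlag import (make_ground_truth, render_resting_run, preprocess_run,
                     compute_gms, compute_lag_map)
from boldlag.compare import center_lags

gt = make_ground_truth(shape=(16, 16, 10), n_timepoints=600, tr=0.72,
                       n_networks=0, pattern="watershed",
                       delay_range=(-2.0, 2.0), noise_sigma=1.0, seed=42)
run = render_resting_run(gt)                      # 4D BOLD-like data
clean = preprocess_run(run)                       # detrend + 0.01-0.1 Hz
gms = compute_gms(clean, np.ones(clean.shape, bool))
lag_map = center_lags(compute_lag_map(clean, gms, search_halfwidth=5.8))

v = lag_map.valid_mask
truth = gt.delay_field.values - gt.delay_field.values[v].mean()
print(f"valid voxels : {v.sum()} / {v.size}")
print(f"median r     : {np.median(lag_map.magnitude[v]):.3f}")
print(f"lag vs truth : r = {np.corrcoef(lag_map.lag[v], truth[v])[0, 1]:.3f}")
print(f"median |err| : {np.median(np.abs(lag_map.lag[v] - truth[v])):.3f} s")
```

```
valid voxels : 2560 / 2560
median r     : 0.935
lag vs truth : r = 0.991
median |err| : 0.095 s
```

All 2560 voxels survive the r > 0.3 threshold at this noise level; the
estimated lag map correlates with the injected delay field at r = 0.99,
and the typical voxel's lag error (0.095 s) is about half the 0.18 s
estimation grid step.

The same stages are available from the shell:

```bash
boldlag simulate resting --shape 16,16,10 --frames 600 --seed 42 --out sim
boldlag preprocess --in sim_bold.nii.gz --tr 0.72 --graymask gray.nii.gz --out clean.nii.gz
boldlag lagmap --in clean.nii.gz --tr 0.72 --ref clean_gms.tsv --out-prefix lm
boldlag compare --a lm --b other_lm --out stats.json
```

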