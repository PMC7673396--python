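"""Generator contracts: band limits, delay fields, rendering, ground truth."""

import numpy as np
import pytest

from boldlag import (ArterialParams, ConstructionError, GroundTruth,
                     ParameterError, bandpass, make_delay_field,
                     make_ground_truth, make_sources, render_arterial_voxels,
                     render_resting_run, render_task_run, task1_design,
                     task2_design)
from boldlag.synthetic_data import default_network_weights
from boldlag.taskglm import task_regressor

from oracles import brute_force_lag

TR = 0.72


class TestMakeSources:
    def test_shape_and_count(self):
        ss = make_sources(1200, TR, (0.01, 0.1), n_networks=3, seed=1)
        assert ss.n_timepoints == 1200
        assert len(ss.global_source) == 1200
        assert len(ss.network_sources) == 3

    def test_band_power_concentration(self):
        # >= 95 % of spectral power inside the analysis band.  The Welch
        # estimate cannot resolve the 0.01 Hz edge sharper than its own
        # frequency resolution, so the band is widened by two bins --
        # a resolution limit of the measurement, not a loosening of the
        # generator's contract (whose final operation is the band-pass
        # filter itself).
        import scipy.signal
        for seed in (1, 2, 3):
            ss = make_sources(600, TR, n_networks=2, seed=seed)
            for s in [ss.global_source, *ss.network_sources]:
                f, p = scipy.signal.welch(s, fs=1 / TR, nperseg=300)
                df = f[1] - f[0]
                in_band = p[(f >= 0.01 - 2 * df)
                            & (f <= 0.1 + 2 * df)].sum() / p.sum()
                assert in_band >= 0.95

    def test_network_sources_decorrelated(self):
        ss = make_sources(800, TR, n_networks=3, seed=4)
        c = np.corrcoef(np.vstack(ss.network_sources))
        off = c[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.2

    def test_deterministic_given_seed(self):
        a = make_sources(256, TR, seed=9)
        b = make_sources(256, TR, seed=9)
        assert np.array_equal(a.global_source, b.global_source)
        assert np.array_equal(a.extended, b.extended)

    def test_unit_variance(self):
        ss = make_sources(512, TR, n_networks=2, seed=5)
        for s in [ss.global_source, *ss.network_sources]:
            assert s.std() == pytest.approx(1.0, rel=1e-9)

    def test_invalid_band_rejected(self):
        with pytest.raises(ParameterError):
            make_sources(256, TR, band=(0.01, 1.0))

    def test_too_short_rejected(self):
        with pytest.raises(ParameterError):
            make_sources(100, TR)


class TestDelayField:
    def test_gradient_spans_range(self):
        fld = make_delay_field((20, 20, 12), "gradient", (-2.0, 2.0))
        assert fld.values.min() == pytest.approx(-2.0)
        assert fld.values.max() == pytest.approx(2.0)

    def test_constant_zero_range_is_all_zero(self):
        fld = make_delay_field((5, 5, 4), "constant", (0.0, 0.0))
        assert np.all(fld.values == 0.0)

    def test_neighbor_steps_bounded(self):
        # exhaustive scan along every axis for the default geometry
        fld = make_delay_field((20, 20, 12), "watershed", (-2.0, 2.0),
                               seed=0)
        for axis in range(3):
            assert np.abs(np.diff(fld.values, axis=axis)).max() <= 0.5 + 1e-9

    def test_range_wider_than_window_rejected(self):
        with pytest.raises(ParameterError):
            make_delay_field((5, 5, 5), "gradient", (-8.0, 8.0),
                             search_halfwidth=5.8)

    def test_unknown_pattern_rejected(self):
        with pytest.raises(ParameterError):
            make_delay_field((5, 5, 5), pattern="spiral")


class TestRenderResting:
    def test_zero_delay_noiseless_voxels_match_source(self):
        gt = make_ground_truth(shape=(4, 4, 3), n_timepoints=200,
                               n_networks=0, pattern="constant",
                               delay_range=(0.0, 0.0), noise_sigma=0.0,
                               seed=2)
        run = render_resting_run(gt)
        for v in run.data.reshape(-1, 200):
            r = np.corrcoef(v, gt.sources.global_source)[0, 1]
            assert r > 1 - 1e-9

    def test_known_shift_recovered_by_bruteforce_oracle(self):
        gt = make_ground_truth(shape=(3, 1, 1), n_timepoints=400,
                               n_networks=0, pattern="constant",
                               delay_range=(1.44, 1.44), noise_sigma=0.0,
                               seed=6)
        run = render_resting_run(gt)
        lag, r = brute_force_lag(run.data[1, 0, 0],
                                 gt.sources.global_source, TR, 5.8)
        assert abs(lag - 1.44) <= TR / 4 + 1e-9
        assert r > 0.999

    def test_bit_identical_given_seed(self):
        gt = make_ground_truth(shape=(4, 4, 2), n_timepoints=200,
                               n_networks=1, noise_sigma=0.7, seed=8)
        assert np.array_equal(render_resting_run(gt).data,
                              render_resting_run(gt).data)

    def test_excessive_delay_rejected(self):
        gt = make_ground_truth(shape=(3, 3, 2), n_timepoints=200,
                               n_networks=0, pattern="constant",
                               delay_range=(0.0, 0.0), seed=1)
        gt.delay_field.values[:] = 100.0
        gt.delay_field.range = (100.0, 100.0)
        with pytest.raises(ParameterError):
            render_resting_run(gt)


class TestRenderTask:
    def test_task1_regressor_has_six_epochs(self):
        reg = task_regressor(task1_design())
        plateaus = np.diff((reg > 0.5 * reg.max()).astype(int))
        assert (plateaus == 1).sum() == 6

    def test_task2_regressor_has_ten_epochs(self):
        reg = task_regressor(task2_design())
        plateaus = np.diff((reg > 0.5 * reg.max()).astype(int))
        assert (plateaus == 1).sum() == 10

    def test_zero_delay_noiseless_matches_regressor(self):
        des = task1_design()
        fld = make_delay_field((4, 4, 3), "constant", (0.0, 0.0))
        run = render_task_run(des, fld, noise_sigma=0.0, seed=0,
                              active_mask=np.ones((4, 4, 3), bool))
        reg = task_regressor(des)
        v = run.data[0, 0, 0]
        r = np.corrcoef(v, reg)[0, 1]
        assert r > 0.999

    def test_inactive_voxels_are_noise_only(self):
        des = task2_design()
        fld = make_delay_field((4, 4, 3), "constant", (0.0, 0.0))
        mask = np.zeros((4, 4, 3), bool)
        mask[0, 0, 0] = True
        run = render_task_run(des, fld, noise_sigma=1.0, seed=3,
                              active_mask=mask)
        reg = task_regressor(des)
        rs = [abs(np.corrcoef(run.data[i, j, k], reg)[0, 1])
              for i in range(4) for j in range(4) for k in range(3)
              if not mask[i, j, k]]
        assert np.mean(rs) < 0.15

    def test_empty_design_rejected(self):
        with pytest.raises(ParameterError):
            task1_design().__class__(onsets=[], durations=[],
                                     run_length=100, tr=0.75)


class TestRenderArterial:
    def test_inflow_offset_brightens_artery(self):
        gt = make_ground_truth(shape=(9, 9, 10), n_timepoints=200,
                               n_networks=0, pattern="constant",
                               delay_range=(0.0, 0.0), noise_sigma=0.5,
                               seed=4)
        run, artery, periphery = render_arterial_voxels(gt)
        assert not (artery & periphery).any()
        assert run.data[artery].mean() > run.data[periphery].mean()

    def test_inverted_shift_found_by_oracle(self):
        gt = make_ground_truth(
            shape=(9, 9, 10), n_timepoints=400, n_networks=0,
            pattern="constant", delay_range=(0.0, 0.0), noise_sigma=0.0,
            arterial=ArterialParams(gain=-1.0, shift=-2.7,
                                    intensity_offset=20.0), seed=5)
        run, artery, _ = render_arterial_voxels(gt)
        series = run.data[artery].mean(axis=0)
        # negate so the brute-force positive-fit oracle can locate it
        lag, r = brute_force_lag(-(series - series.mean()),
                                 gt.sources.global_source, TR, 5.8)
        assert abs(lag + 2.7) <= TR / 4 + 1e-9
        assert r > 0.999

    def test_positive_gain_zero_shift_peaks_at_zero(self):
        gt = make_ground_truth(
            shape=(9, 9, 10), n_timepoints=300, n_networks=0,
            pattern="constant", delay_range=(0.0, 0.0), noise_sigma=0.0,
            arterial=ArterialParams(gain=1.0, shift=0.0,
                                    intensity_offset=10.0), seed=6)
        run, artery, _ = render_arterial_voxels(gt)
        series = run.data[artery].mean(axis=0)
        lag, r = brute_force_lag(series - series.mean(),
                                 gt.sources.global_source, TR, 5.8)
        assert lag == 0.0
        assert r > 1 - 1e-6

    def test_zero_gain_rejected(self):
        gt = make_ground_truth(shape=(9, 9, 10), n_timepoints=200,
                               n_networks=0, pattern="constant",
                               delay_range=(0.0, 0.0),
                               arterial=ArterialParams(gain=0.0), seed=1)
        with pytest.raises(ParameterError):
            render_arterial_voxels(gt)


class TestGroundTruthSidecar:
    def test_json_round_trip_lossless(self, tmp_path):
        gt = make_ground_truth(shape=(5, 4, 3), n_timepoints=160,
                               n_networks=2, noise_sigma=0.9,
                               noise_ar1=0.4, seed=12)
        path = tmp_path / "gt.json"
        gt.to_json(str(path))
        back = GroundTruth.from_json(str(path))
        assert np.array_equal(back.delay_field.values, gt.delay_field.values)
        assert np.array_equal(back.weights, gt.weights)
        assert np.array_equal(back.sources.global_source,
                              gt.sources.global_source)
        assert np.array_equal(back.sources.extended, gt.sources.extended)
        for a, b in zip(back.sources.network_sources,
                        gt.sources.network_sources):
            assert np.array_equal(a, b)
        assert back.arterial == gt.arterial
        assert back.noise_sigma == gt.noise_sigma
        assert back.noise_ar1 == gt.noise_ar1
        assert back.seed == gt.seed

    def test_default_arterial_gain_is_negative(self):
        assert ArterialParams().gain < 0

    def test_network_weights_are_compact_blobs(self):
        w = default_network_weights((20, 20, 12), 3, seed=0)
        support = w > 0.1
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = (support[i] & support[j]).sum()
                assert overlap <= 0.2 * min(support[i].sum(),
                                            support[j].sum())
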