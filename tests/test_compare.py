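"""Lag-map comparison, group statistics, composites, pooled histograms."""

import numpy as np
import pytest
import scipy.stats

from boldlag import (ParameterError, build_composite, center_lags,
                     compare_lag_maps, group_test, pooled_histogram)
from boldlag.lagcore import LagMap

STEP = 0.18


def _lag_map(values, valid=None, magnitude=None):
    values = np.asarray(values, dtype=float)
    valid = np.ones(values.shape, bool) if valid is None else valid
    mag = np.full(values.shape, 0.8) if magnitude is None else magnitude
    return LagMap(lag=values, magnitude=mag, valid_mask=valid,
                  search_halfwidth=5.8, grid_step=STEP)


def _grid_noise(rng, shape, sd):
    """Zero-mean noise rounded onto the lag grid."""
    return np.round(rng.normal(0, sd, shape) / STEP) * STEP


class TestCenterLags:
    def test_constant_map_becomes_zero(self):
        lm = center_lags(_lag_map(np.full((4, 4, 2), 1.26)))
        assert np.allclose(lm.lag, 0.0)

    def test_valid_mean_exactly_zero(self, rng):
        vals = _grid_noise(rng, (5, 5, 3), 1.0) + 0.72
        valid = rng.random((5, 5, 3)) > 0.3
        valid[0, 0, 0] = valid[0, 0, 1] = True
        lm = center_lags(_lag_map(vals, valid))
        assert abs(lm.lag[valid].mean()) < 1e-12

    def test_idempotent(self, rng):
        lm = _lag_map(_grid_noise(rng, (4, 4, 2), 1.0))
        once = center_lags(lm)
        twice = center_lags(once)
        assert np.allclose(once.lag, twice.lag)

    def test_too_few_valid_rejected(self):
        valid = np.zeros((3, 3, 1), bool)
        valid[0, 0, 0] = True
        with pytest.raises(ParameterError):
            center_lags(_lag_map(np.zeros((3, 3, 1)), valid))


class TestCompareLagMaps:
    def test_self_correlation_is_one(self, rng):
        lm = _lag_map(_grid_noise(rng, (5, 5, 2), 1.0))
        assert compare_lag_maps(lm, lm) == pytest.approx(1.0)

    def test_negation_gives_minus_one(self, rng):
        vals = _grid_noise(rng, (5, 5, 2), 1.0)
        assert compare_lag_maps(_lag_map(vals), _lag_map(-vals)) == \
            pytest.approx(-1.0)

    def test_constant_offset_invariance(self, rng):
        vals = _grid_noise(rng, (5, 5, 2), 1.0)
        r0 = compare_lag_maps(_lag_map(vals), _lag_map(vals * 0.5))
        r1 = compare_lag_maps(_lag_map(vals + 3.6), _lag_map(vals * 0.5))
        assert r0 == pytest.approx(r1)

    def test_symmetry(self, rng):
        a = _lag_map(_grid_noise(rng, (5, 5, 2), 1.0))
        b = _lag_map(_grid_noise(rng, (5, 5, 2), 1.0))
        assert compare_lag_maps(a, b) == pytest.approx(compare_lag_maps(b, a))

    def test_attenuation_matches_known_noise_prediction(self, rng):
        # two noisy reads of one field: r ~ var_t / (var_t + var_n)
        truth = rng.normal(0, 1.0, (12, 12, 6))
        sd_n = 0.5
        a = _lag_map(truth + rng.normal(0, sd_n, truth.shape))
        b = _lag_map(truth + rng.normal(0, sd_n, truth.shape))
        predicted = truth.var() / (truth.var() + sd_n ** 2)
        assert compare_lag_maps(a, b) == pytest.approx(predicted, abs=0.08)

    def test_small_joint_mask_flagged(self, rng):
        valid = np.zeros((3, 3, 1), bool)
        valid[0, :3, 0] = True
        a = _lag_map(rng.normal(0, 1, (3, 3, 1)), valid)
        b = _lag_map(rng.normal(0, 1, (3, 3, 1)), valid)
        with pytest.warns(UserWarning, match="low-confidence"):
            compare_lag_maps(a, b)

    def test_disjoint_masks_rejected(self, rng):
        va = np.zeros((3, 3, 1), bool)
        vb = np.zeros((3, 3, 1), bool)
        va[0], vb[2] = True, True
        with pytest.raises(ParameterError):
            compare_lag_maps(_lag_map(np.ones((3, 3, 1)), va),
                             _lag_map(np.ones((3, 3, 1)), vb))


class TestGroupTest:
    def test_all_zero_r_gives_t_zero_p_one(self):
        res = group_test(np.zeros(5))
        assert res.t_stat == 0.0
        assert res.p_two_tailed == 1.0

    def test_matches_hand_computed_three_run_example(self):
        r = np.array([0.2, 0.3, 0.4])
        z = np.arctanh(r)
        t_hand = z.mean() / (z.std(ddof=1) / np.sqrt(3))
        p_hand = 2 * scipy.stats.t.sf(abs(t_hand), df=2)
        res = group_test(r)
        assert res.t_stat == pytest.approx(t_hand, rel=1e-12)
        assert res.p_two_tailed == pytest.approx(p_hand, rel=1e-12)
        assert np.allclose(res.fisher_z, z)

    def test_null_p_uniform(self, rng):
        ps = [group_test(np.tanh(rng.normal(0, 0.2, 8))).p_two_tailed
              for _ in range(200)]
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01

    def test_power_grows_with_runs(self, rng):
        p_few = np.median([group_test(
            np.clip(0.3 + rng.normal(0, 0.1, 4), -0.99, 0.99)
        ).p_two_tailed for _ in range(50)])
        p_many = np.median([group_test(
            np.clip(0.3 + rng.normal(0, 0.1, 16), -0.99, 0.99)
        ).p_two_tailed for _ in range(50)])
        assert p_many < p_few

    def test_perfect_correlation_rejected(self):
        with pytest.raises(ParameterError):
            group_test(np.array([0.5, 1.0]))


class TestComposite:
    def test_single_ic_identical_to_gms_reproduces_it(self, rng):
        vals = _grid_noise(rng, (6, 6, 3), 1.0)
        gms = _lag_map(vals)
        comp = build_composite([_lag_map(vals)], gms)
        comp_lm = _lag_map(np.nan_to_num(comp.lag), comp.valid_mask)
        assert compare_lag_maps(comp_lm, gms) == pytest.approx(1.0)
        assert comp.offsets_applied[0] == pytest.approx(0.0)

    def test_overlap_resolved_by_magnitude(self):
        vals = np.zeros((2, 1, 1))
        strong = _lag_map(vals + 0.36, magnitude=np.full((2, 1, 1), 0.8))
        weak = _lag_map(vals - 0.36, magnitude=np.full((2, 1, 1), 0.4))
        gms = _lag_map(vals)
        comp = build_composite([weak, strong], gms)
        assert np.all(comp.contributor == 1)

    def test_offsets_do_not_change_within_ic_contrasts(self, rng):
        vals = _grid_noise(rng, (6, 6, 3), 1.0)
        ic = _lag_map(vals + 1.8)
        comp = build_composite([ic], _lag_map(_grid_noise(rng, (6, 6, 3),
                                                          1.0)))
        diffs_in = ic.lag - ic.lag[0, 0, 0]
        diffs_out = comp.lag - comp.lag[0, 0, 0]
        assert np.allclose(diffs_in, diffs_out, atol=1e-12)

    def test_no_valid_voxels_rejected(self, rng):
        empty = _lag_map(np.zeros((3, 3, 1)),
                         valid=np.zeros((3, 3, 1), bool))
        gms = _lag_map(_grid_noise(rng, (3, 3, 1), 1.0))
        with pytest.raises(ParameterError):
            build_composite([empty], gms)


class TestPooledHistogram:
    def test_identical_maps_mass_on_diagonal(self, rng):
        lm = _lag_map(_grid_noise(rng, (6, 6, 3), 1.0))
        counts, edges = pooled_histogram([(lm, lm)])
        total = counts.sum()
        assert total == lm.n_valid
        assert np.trace(counts) == total

    def test_total_count_conserved_across_pairs(self, rng):
        pairs = []
        for _ in range(3):
            a = _lag_map(_grid_noise(rng, (5, 5, 2), 1.0),
                         valid=rng.random((5, 5, 2)) > 0.3)
            b = _lag_map(_grid_noise(rng, (5, 5, 2), 1.0),
                         valid=rng.random((5, 5, 2)) > 0.3)
            pairs.append((a, b))
        counts, _ = pooled_histogram(pairs)
        expected = sum((a.valid_mask & b.valid_mask).sum()
                       for a, b in pairs)
        assert counts.sum() == expected

    def test_histogram_correlation_matches_direct(self, rng):
        truth = _grid_noise(rng, (10, 10, 5), 1.0)
        a = _lag_map(truth)
        b = _lag_map(np.clip(truth + _grid_noise(rng, truth.shape, 0.4),
                             -5.6, 5.6))
        counts, edges = pooled_histogram([(a, b)])
        centers = 0.5 * (edges[:-1] + edges[1:])
        gx, gy = np.meshgrid(centers, centers, indexing="ij")
        w = counts.ravel()
        mx = np.average(gx.ravel(), weights=w)
        my = np.average(gy.ravel(), weights=w)
        cov = np.average((gx.ravel() - mx) * (gy.ravel() - my), weights=w)
        sx = np.sqrt(np.average((gx.ravel() - mx) ** 2, weights=w))
        sy = np.sqrt(np.average((gy.ravel() - my) ** 2, weights=w))
        r_hist = cov / (sx * sy)
        assert r_hist == pytest.approx(compare_lag_maps(a, b), abs=0.02)
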