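"""Set correlation / CCA, the one-to-one variant, lag scanning, ROI pairs,
and canonical-variate assessment."""

import numpy as np
import pytest
from scipy import stats as sstats

from interbrain.coupling import (CanonicalSpectrum, LaggedCouplingEngine,
                                 coupling_spectrum, count_significant_variates,
                                 default_rois, lag_scan, lag_scan_ensemble,
                                 make_lag_grid, r2_one_to_one, roi_scan,
                                 set_correlation)
from interbrain.exceptions import RankDeficiencyError
from interbrain.listener import content_component

from conftest import make_toy_ensemble


def _orthonormal_columns(n, k, seed=0):
    """Exactly orthonormal zero-mean columns (centered before QR, so sample
    correlations between distinct columns are exactly zero)."""
    x = np.random.default_rng(seed).standard_normal((n, k))
    q, _ = np.linalg.qr(x - x.mean(axis=0))
    return q


class TestSetCorrelation:
    def test_identical_sets_share_everything(self):
        x = np.random.default_rng(0).standard_normal((300, 4))
        r2, spec = set_correlation(x, x)
        assert r2 == pytest.approx(1.0)
        assert np.allclose(spec.correlations, 1.0, atol=1e-8)

    def test_orthogonal_sets_share_nothing(self):
        q = _orthonormal_columns(400, 6)
        r2, spec = set_correlation(q[:, :3], q[:, 3:])
        assert r2 == pytest.approx(0.0, abs=1e-10)

    def test_2x2_grid_search_oracle(self):
        """Canonical correlations match a dense grid search over unit
        weight vectors, and the set R2 matches the Wilks-determinant
        closed form."""
        rng = np.random.default_rng(1)
        z = rng.standard_normal((2000, 2))
        x = z @ rng.standard_normal((2, 2)) + 0.5 * rng.standard_normal((2000, 2))
        y = z @ rng.standard_normal((2, 2)) + 0.8 * rng.standard_normal((2000, 2))
        r2, spec = set_correlation(x, y)

        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        angles = np.linspace(0, np.pi, 2001)
        best = 0.0
        for ta in angles:
            a = np.array([np.cos(ta), np.sin(ta)])
            u = xc @ a
            vb = yc.T @ u  # optimal b direction given a, up to scaling
            proj = yc @ np.linalg.solve(yc.T @ yc, vb)
            r = abs(np.corrcoef(u, proj)[0, 1])
            best = max(best, r)
        assert spec.correlations[0] == pytest.approx(best, abs=1e-3)

        s_xx, s_yy, s_xy = xc.T @ xc, yc.T @ yc, xc.T @ yc
        full = np.block([[s_xx, s_xy], [s_xy.T, s_yy]])
        wilks = np.linalg.det(full) / (np.linalg.det(s_xx) * np.linalg.det(s_yy))
        assert r2 == pytest.approx(1.0 - wilks, abs=1e-10)

    def test_invariance_under_invertible_transforms(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((200, 3))
        y = x @ rng.standard_normal((3, 3)) + rng.standard_normal((200, 3))
        r2, spec = set_correlation(x, y)
        a = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        b = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        r2_t, spec_t = set_correlation(x @ a, y @ b)
        assert r2_t == pytest.approx(r2, abs=1e-8)
        assert np.allclose(spec_t.correlations, spec.correlations, atol=1e-8)

    def test_univariate_reduces_to_pearson(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(500)
        y = 0.6 * x + 0.8 * rng.standard_normal(500)
        r2, _ = set_correlation(x, y)
        assert r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-12)
        assert r2 == pytest.approx(r2_one_to_one(x, y), abs=1e-12)

    def test_rank_deficiency_detected_without_ridge(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((300, 3))
        x = np.column_stack([x, x[:, 0]])  # duplicated column
        with pytest.raises(RankDeficiencyError):
            set_correlation(x, rng.standard_normal((300, 2)), reg=0.0)

    def test_auto_ridge_warns_on_short_samples(self):
        rng = np.random.default_rng(5)
        with pytest.warns(RuntimeWarning, match="ridge"):
            set_correlation(rng.standard_normal((30, 4)),
                            rng.standard_normal((30, 4)))

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            set_correlation(rng.standard_normal((5, 3)),
                            rng.standard_normal((5, 3)), reg=0.0)

    def test_extra_noise_channel_cannot_raise_population_share(self):
        rng = np.random.default_rng(7)
        z = rng.standard_normal(5000)
        x = np.column_stack([z + rng.standard_normal(5000),
                             rng.standard_normal(5000)])
        y = np.column_stack([z + rng.standard_normal(5000),
                             rng.standard_normal(5000)])
        r2_base, _ = set_correlation(x, y)
        y_aug = np.column_stack([y, rng.standard_normal(5000)])
        r2_aug, _ = set_correlation(x, y_aug)
        assert r2_aug <= r2_base + 0.02  # within sampling error


class TestOneToOne:
    def test_identical_sets(self):
        x = np.random.default_rng(0).standard_normal((200, 3))
        assert r2_one_to_one(x, x) == pytest.approx(1.0)

    def test_rotated_channels_defeat_one_to_one_but_not_cca(self):
        q = _orthonormal_columns(500, 2, seed=1)
        x = q  # two exactly orthogonal channels
        y = x[:, [1, 0]]  # same subspace, channels swapped
        assert r2_one_to_one(x, y) == pytest.approx(0.0, abs=1e-10)
        r2_set, _ = set_correlation(x, y)
        assert r2_set == pytest.approx(1.0)

    def test_planted_channel_correlations_product_formula(self):
        rng = np.random.default_rng(2)
        x = _orthonormal_columns(4000, 4, seed=2)[:, :2]
        e1 = _orthonormal_columns(4000, 4, seed=2)[:, 2]
        e2 = _orthonormal_columns(4000, 4, seed=2)[:, 3]
        y = np.column_stack([0.6 * x[:, 0] + np.sqrt(1 - 0.36) * e1, e2])
        val = r2_one_to_one(x, y)
        assert val == pytest.approx(1 - (1 - 0.36) * (1 - 0.0), abs=1e-9)

    def test_unequal_channel_counts_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            r2_one_to_one(rng.standard_normal((100, 3)),
                          rng.standard_normal((100, 2)))

    def test_never_exceeds_one(self):
        rng = np.random.default_rng(4)
        for seed in range(5):
            x = rng.standard_normal((50, 4))
            y = rng.standard_normal((50, 4))
            assert r2_one_to_one(x, y) <= 1.0


class TestCountSignificantVariates:
    def _spectrum(self, r, p, q, n):
        return CanonicalSpectrum(correlations=np.asarray(r, dtype=float),
                                 x_weights=np.zeros((p, len(r))),
                                 y_weights=np.zeros((q, len(r))),
                                 n_samples=n)

    def test_all_zero_correlations(self):
        assert count_significant_variates(
            self._spectrum([0.0, 0.0], 2, 2, 500)) == 0

    def test_single_strong_correlation(self):
        spec = self._spectrum([0.9, 0.01], 2, 2, 500)
        assert count_significant_variates(spec) == 1
        # chi-square quantile oracle for the k=0 test
        stat = -(500 - (2 + 2 + 3) / 2) * (np.log(1 - 0.81) + np.log(1 - 1e-4))
        assert stat > sstats.chi2.ppf(0.95, 4)

    def test_identical_data_sets_all_variates(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((300, 3))
        _, spec = set_correlation(x, x)
        assert count_significant_variates(spec) == 3

    def test_sample_size_guard(self):
        with pytest.raises(ValueError):
            count_significant_variates(self._spectrum([0.5], 3, 3, 6))


class TestLagGrid:
    def test_default_grid_has_45_points(self):
        grid = make_lag_grid()
        assert len(grid) == 45
        assert grid[0] == -2.0 and grid[-1] == 20.0
        assert np.allclose(np.diff(grid), 0.5)

    def test_bad_step_rejected(self):
        with pytest.raises(ValueError):
            make_lag_grid(0, 10, 0)


class TestLagScan:
    def test_planted_lag_recovered(self, planted_ensemble):
        comp = content_component(planted_ensemble)["S1"]
        curve = lag_scan(planted_ensemble.speakers["S1"], comp,
                         make_lag_grid(-1.0, 4.0, 0.5))
        assert curve.peak_lag == pytest.approx(2.0, abs=0.5)

    def test_grid_exceeding_length_rejected(self, planted_ensemble):
        comp = content_component(planted_ensemble)["S1"]
        with pytest.raises(ValueError):
            lag_scan(planted_ensemble.speakers["S1"], comp,
                     np.array([0.0, 100.0]))

    def test_time_reversal_mirrors_curve(self, planted_ensemble):
        """Reversing both series maps the pairing at lag +l onto the exact
        sample pairs of lag -l, so the curve mirrors exactly."""
        comp = content_component(planted_ensemble)["S1"]
        spk = planted_ensemble.speakers["S1"]
        grid = make_lag_grid(-2.0, 2.0, 0.5)
        fwd = lag_scan(spk, comp, grid)
        rev = lag_scan(spk.copy_with(data=spk.data[::-1]), comp[::-1], grid)
        assert np.allclose(rev.r2, fwd.r2[::-1], atol=1e-9)


class TestLaggedCouplingEngine:
    def test_identity_matches_direct_set_correlation(self, planted_ensemble):
        lags = np.array([0.0, 2.0, 3.5])
        engine = LaggedCouplingEngine(planted_ensemble, lags_s=lags, ridge=0.0)
        dist_set, dist_one = engine.scan([engine.observed])
        comp = content_component(planted_ensemble)
        n = planted_ensemble.n_times
        fs = planted_ensemble.fs
        for li, lag in enumerate(lags):
            m = int(round(lag * fs))
            vals_set, vals_one = [], []
            for sid in planted_ensemble.speaker_ids:
                spk = planted_ensemble.speakers[sid].data[:n - m]
                c = comp[sid][m:]
                r2, _ = set_correlation(spk, c, reg=0.0)
                vals_set.append(r2)
                vals_one.append(r2_one_to_one(spk, c))
            assert dist_set.values[0, li] == pytest.approx(
                np.mean(vals_set), abs=1e-7)
            assert dist_one.values[0, li] == pytest.approx(
                np.mean(vals_one), abs=1e-7)

    def test_full_scan_recovers_planted_lag_with_significance(self,
                                                              planted_ensemble):
        curves = lag_scan_ensemble(planted_ensemble,
                                   lags_s=make_lag_grid(-1.0, 4.0, 0.5))
        c = curves["set"]
        assert c.peak_lag == pytest.approx(2.0, abs=0.5)
        assert c.p_corrected[int(np.argmax(c.delta_r2))] <= 0.05
        assert np.all(c.p_corrected >= c.p_uncorrected - 1e-12)

    def test_null_ensemble_shows_no_significant_lag(self, null_ensemble):
        curves = lag_scan_ensemble(null_ensemble,
                                   lags_s=make_lag_grid(-1.0, 3.0, 1.0))
        assert np.all(curves["set"].p_corrected > 0.05)


class TestRoiScan:
    def test_seven_by_seven_yields_49_estimates(self):
        names = [f"ch{i:02d}" for i in range(63)]
        rois = default_rois(names)
        assert len(rois.names) == 7
        assert all(len(v) == 9 for v in rois.rois.values())

    def test_planted_roi_pair_is_maximal(self):
        """Coupling planted from speaker ROI 0 into listener ROI 1 only."""
        rng = np.random.default_rng(8)
        n_t, n_c = 3000, 63
        z = rng.standard_normal((n_t, 3))
        spk = {"S1": 0.3 * rng.standard_normal((n_t, n_c)),
               "S2": 0.3 * rng.standard_normal((n_t, n_c))}
        spk["S1"][:, 0:9] += z @ rng.standard_normal((3, 9))
        sigs = {}
        for i in range(4):
            noise = 0.6 * rng.standard_normal((n_t, n_c))
            if i < 2:  # group attending S1 carries z in ROI index 1
                noise[:, 9:18] += 0.5 * z @ rng.standard_normal((3, 9))
            sigs[f"L{i}"] = noise
        ens = make_toy_ensemble(sigs, speaker_signals=spk)
        rois = default_rois([f"ch{i + 1:02d}" for i in range(n_c)])
        out = roi_scan(ens, rois, lag_s=0.0, inference=False)
        r2 = out["r2"]
        assert r2.shape == (7, 7)
        assert (0, 1) == np.unravel_index(np.argmax(r2), r2.shape)

    def test_null_roi_matrix_unbiased(self):
        rng = np.random.default_rng(0)
        n_t, n_c = 1500, 63
        sigs = {f"L{i}": rng.standard_normal((n_t, n_c)) for i in range(4)}
        ens = make_toy_ensemble(sigs)
        rois = default_rois([f"ch{i + 1:02d}" for i in range(n_c)])
        out = roi_scan(ens, rois, lag_s=0.0)
        assert np.abs(out["delta_r2"]).max() < 0.05
        assert np.all(out["p_corrected"] > 0.05)


class TestCouplingSpectrum:
    def test_variates_detected_on_planted_ensemble(self, planted_ensemble):
        spec = coupling_spectrum(planted_ensemble, lag_s=2.0, speaker_id="S1")
        assert spec.correlations[0] > spec.correlations[-1]
        assert count_significant_variates(spec) >= 1
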