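"""Listener variance decomposition: content component, R2_L, channel and
frequency decompositions."""

import numpy as np
import pytest

from interbrain.exceptions import DegenerateInputError
from interbrain.listener import (ListenerAnova, content_component,
                                 decompose_by_channel, decompose_by_frequency,
                                 r2_listener, r2_listener_stat)

from conftest import make_toy_ensemble


class TestContentComponent:
    def test_identical_groups_give_zero(self):
        rng = np.random.default_rng(0)
        sig = rng.standard_normal((50, 2))
        ens = make_toy_ensemble({f"L{i}": sig + i % 2 * 0.0 for i in range(4)})
        comps = content_component(ens)
        for c in comps.values():
            assert np.allclose(c, 0.0, atol=1e-12)

    def test_antisymmetric_groups(self):
        s = np.sin(np.linspace(0, 4 * np.pi, 100))[:, None]
        ens = make_toy_ensemble({"L1": s, "L2": s, "L3": -s, "L4": -s})
        comps = content_component(ens)
        assert np.allclose(comps["S1"], s, atol=1e-12)
        assert np.allclose(comps["S2"], -s, atol=1e-12)

    def test_hand_worked_toy(self):
        """1 channel, 2 samples, 2+2 listeners; direct means oracle."""
        ens = make_toy_ensemble({
            "L1": [[2.0], [0.0]], "L2": [[0.0], [2.0]],
            "L3": [[-2.0], [0.0]], "L4": [[0.0], [-2.0]],
        })
        comps = content_component(ens, center=False)
        assert np.allclose(comps["S1"][:, 0], [1.0, 1.0])
        assert np.allclose(comps["S2"][:, 0], [-1.0, -1.0])

    def test_weighted_sum_over_groups_is_zero(self, planted_ensemble):
        comps = content_component(planted_ensemble)
        sizes = {sid: len(m) for sid, m in
                 planted_ensemble.group_members().items()}
        total = sum(sizes[sid] * comps[sid] for sid in comps)
        assert np.allclose(total, 0.0, atol=1e-9)


class TestR2Listener:
    def test_identical_groups_zero(self):
        rng = np.random.default_rng(1)
        sigs = [rng.standard_normal((40, 3)) for _ in range(3)]
        ens = make_toy_ensemble({f"L{i}": sigs[i % 3] for i in range(6)},
                                group={f"L{i}": ("S1" if i < 3 else "S2")
                                       for i in range(6)})
        assert r2_listener(ens, inference=False).r2 == pytest.approx(0.0, abs=1e-12)

    def test_pure_between_group_variance_gives_one(self):
        ens = make_toy_ensemble({
            "L1": np.ones((20, 1)), "L2": np.ones((20, 1)),
            "L3": -np.ones((20, 1)), "L4": -np.ones((20, 1)),
        })
        est = ListenerAnova(ens, center=False)
        assert est.r2(est.observed) == pytest.approx(1.0)

    def test_hand_worked_anova_sums(self):
        """SS_between = 8, SS_total = 16 => R2_L = 0.5."""
        ens = make_toy_ensemble({
            "L1": [[2.0], [0.0]], "L2": [[0.0], [2.0]],
            "L3": [[-2.0], [0.0]], "L4": [[0.0], [-2.0]],
        })
        x = ens.listener_array()
        assert r2_listener_stat(x, ens.group_labels(),
                                center=False) == pytest.approx(0.5)
        eng = ListenerAnova(ens, center=False)
        assert eng.r2(eng.observed) == pytest.approx(0.5)

    def test_zero_total_variance_degenerate(self):
        ens = make_toy_ensemble({f"L{i}": np.zeros((10, 1)) for i in range(4)})
        with pytest.raises(DegenerateInputError):
            r2_listener(ens, inference=False)

    def test_gram_fast_path_matches_direct_route(self, planted_ensemble):
        eng = ListenerAnova(planted_ensemble)
        direct = r2_listener_stat(planted_ensemble.listener_array(),
                                  planted_ensemble.group_labels())
        assert eng.r2(eng.observed) == pytest.approx(direct, rel=1e-10)
        # also under a non-identity relabeling
        perm = tuple([0, 1, 4, 5])
        labels = np.asarray(["S2"] * eng.n_listeners)
        labels[list(perm)] = "S1"
        direct_p = r2_listener_stat(planted_ensemble.listener_array(), labels)
        assert eng.r2(perm) == pytest.approx(direct_p, rel=1e-10)

    def test_rotation_invariance(self, planted_ensemble):
        """R2_L is invariant under a common channel-wise orthonormal rotation."""
        from scipy.stats import ortho_group

        q = ortho_group.rvs(planted_ensemble.n_channels, random_state=3)
        x = planted_ensemble.listener_array()
        labels = planted_ensemble.group_labels()
        r_orig = r2_listener_stat(x, labels)
        r_rot = r2_listener_stat(x @ q, labels)
        assert r_rot == pytest.approx(r_orig, rel=1e-10)

    def test_shared_signal_leaves_ss_between_unchanged(self, planted_ensemble):
        """Adding an identical (sensory-like) signal to every listener does
        not change the between-group sum of squares."""
        x = planted_ensemble.listener_array()
        labels = planted_ensemble.group_labels()
        rng = np.random.default_rng(4)
        shared = rng.standard_normal(x.shape[1:])

        def ss_between(arr):
            arr = arr - arr.mean(axis=1, keepdims=True)
            grand = arr.mean(axis=0)
            return sum(np.sum((arr[labels == g].mean(axis=0) - grand) ** 2)
                       * np.sum(labels == g) for g in np.unique(labels))

        assert ss_between(x + shared) == pytest.approx(ss_between(x), rel=1e-9)

    def test_inference_attaches_permutation_quantities(self, planted_ensemble):
        est = r2_listener(planted_ensemble)
        assert est.extra["n_permutations"] == 70  # C(8, 4)
        assert est.delta_r2 < est.r2
        assert est.p_uncorrected >= 2 / 70  # statistic symmetric under label swap


class TestDecomposeByChannel:
    def _two_channel_planted(self, ratio=2.0, n=2000, seed=5):
        rng = np.random.default_rng(seed)
        diff1 = rng.standard_normal(n)
        diff2 = rng.standard_normal(n)
        sigs = {}
        for i in range(6):
            noise = 0.5 * rng.standard_normal((n, 3))
            sign = 1.0 if i < 3 else -1.0
            base = np.zeros((n, 3))
            base[:, 0] = sign * np.sqrt(ratio) * diff1
            base[:, 1] = sign * diff2
            sigs[f"L{i}"] = base + noise
        return make_toy_ensemble(sigs, group={f"L{i}": ("S1" if i < 3 else "S2")
                                              for i in range(6)})

    def test_effect_confined_to_one_channel(self):
        ens = self._two_channel_planted(ratio=0.0)  # only channel 1 differs
        out = decompose_by_channel(ens)
        # a no-effect channel's raw ratio sits at the null level
        # (g-1)/(n-1) = 0.2; the bias-corrected value is what vanishes
        assert out["delta_r2"][1] > 0.3
        assert abs(out["delta_r2"][2]) < 0.1

    def test_planted_two_to_one_ordering(self):
        ens = self._two_channel_planted(ratio=2.0)
        out = decompose_by_channel(ens)
        assert out["r2"][0] > out["r2"][1] > out["r2"][2]
        # direct per-channel ANOVA oracle
        x = ens.listener_array()
        labels = ens.group_labels()
        for c in range(3):
            oracle = r2_listener_stat(x[:, :, c:c + 1], labels)
            assert out["r2"][c] == pytest.approx(oracle, rel=1e-10)

    def test_null_deltas_near_zero(self):
        """Exchangeable (no-effect) listeners: bias-corrected channel values
        scatter around zero and nothing reaches corrected significance."""
        rng = np.random.default_rng(9)
        ens = make_toy_ensemble({f"L{i}": rng.standard_normal((500, 3))
                                 for i in range(6)},
                                group={f"L{i}": ("S1" if i < 3 else "S2")
                                       for i in range(6)})
        out = decompose_by_channel(ens)
        assert np.all(np.abs(out["delta_r2"]) < 0.1)
        assert not out["significant"].any()

    def test_dead_channel_flagged_and_excluded(self):
        rng = np.random.default_rng(10)
        sigs = {f"L{i}": np.column_stack([rng.standard_normal(100),
                                          np.zeros(100)]) for i in range(4)}
        out = decompose_by_channel(make_toy_ensemble(sigs))
        assert out["dead"][1] and not out["dead"][0]
        assert not out["significant"][1]


class TestDecomposeByFrequency:
    def test_contributions_sum_to_global_r2(self, planted_ensemble):
        out = decompose_by_frequency(planted_ensemble, bin_hz=1.0)
        global_r2 = r2_listener(planted_ensemble, inference=False).r2
        assert np.sum(out["contribution"]) == pytest.approx(global_r2,
                                                            rel=1e-10)

    def test_pure_tone_difference_lands_in_its_bin(self):
        fs, n = 20.0, 400
        t = np.arange(n) / fs
        tone = np.sin(2 * np.pi * 2.0 * t)[:, None]
        rng = np.random.default_rng(11)
        sigs = {}
        for i in range(4):
            sign = 1.0 if i < 2 else -1.0
            sigs[f"L{i}"] = sign * tone + 0.1 * rng.standard_normal((n, 1))
        ens = make_toy_ensemble(sigs, fs=fs)
        out = decompose_by_frequency(ens, bin_hz=1.0)
        centers = out["bin_centers_hz"]
        two_hz_bin = int(np.argmin(np.abs(centers - 2.5)))  # bin [2, 3) Hz
        share = out["contribution"][two_hz_bin] / out["contribution"].sum()
        assert share > 0.95

    def test_matches_filter_bank_oracle(self, planted_ensemble):
        """Per-bin contributions match band-filtering then direct ANOVA."""
        bin_hz = 5.0
        out = decompose_by_frequency(planted_ensemble, bin_hz=bin_hz)
        x = planted_ensemble.listener_array()
        x = x - x.mean(axis=1, keepdims=True)
        labels = planted_ensemble.group_labels()
        grand = x.mean(axis=0)
        ss_total = np.sum((x - grand) ** 2)
        n_t = x.shape[1]
        freqs = np.fft.rfftfreq(n_t, d=1.0 / planted_ensemble.fs)
        f = np.fft.rfft(x, axis=1)
        for b in range(len(out["bin_centers_hz"])):
            mask = (freqs >= b * bin_hz) & (freqs < (b + 1) * bin_hz)
            if b == len(out["bin_centers_hz"]) - 1:
                mask |= freqs >= (b + 1) * bin_hz  # fold Nyquist remainder
            fb = np.where(mask[None, :, None], f, 0.0)
            xb = np.fft.irfft(fb, n=n_t, axis=1)
            grand_b = xb.mean(axis=0)
            ss_b = sum(np.sum((xb[labels == g].mean(axis=0) - grand_b) ** 2)
                       * np.sum(labels == g) for g in np.unique(labels))
            assert out["contribution"][b] == pytest.approx(ss_b / ss_total,
                                                           rel=1e-6)

    def test_bin_wider_than_nyquist_rejected(self, planted_ensemble):
        with pytest.raises(ValueError):
            decompose_by_frequency(planted_ensemble, bin_hz=1000.0)
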