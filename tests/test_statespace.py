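"""State-space construction, distances, decoding and lag tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ortho_group

from ieegdyn import statespace
from ieegdyn.sigproc import Epochs
from conftest import make_epochs


def planted_epochs(seed, n_tr=90, n_ch=8, T=154, fs=256.0, ctx_latent=2, act_latent=4,
                   strength=2.0):
    """Channels mix orthonormal latents; context/action signals live in two
    designated latents with distinct variances (predictable PC ranks)."""
    rng = np.random.default_rng(seed)
    times = np.arange(T) / fs
    ctx = rng.permutation(np.repeat([0, 1, 2], n_tr // 3))
    rt = rng.permutation(np.repeat([0.03, 0.07, 0.11], n_tr // 3))
    sds = np.linspace(3.0, 0.6, n_ch)
    lat = rng.standard_normal((n_tr, n_ch, T)) * sds[None, :, None]
    prof_c = np.exp(-(((times - 0.2) / 0.1) ** 2))
    prof_a = np.exp(-(((times - 0.45) / 0.1) ** 2))
    lat[:, ctx_latent, :] += strength * (ctx[:, None] - 1) * prof_c[None, :]
    act = statespace.rt_terciles(rt)
    lat[:, act_latent, :] += strength * (act[:, None] - 1) * prof_a[None, :]
    W = ortho_group.rvs(n_ch, random_state=seed)
    data = np.einsum("ij,tjs->tis", W, lat)
    ep = make_epochs(data, fs=fs, times=times, context=ctx.astype(float), rt=rt)
    return ep, ctx, rt, W


class TestBuildStateSpace:
    def test_rank_one_data_concentrates_variance(self):
        rng = np.random.default_rng(0)
        trace = rng.standard_normal((10, 1, 300))
        weights = rng.uniform(0.5, 2.0, 6)
        data = trace * weights[None, :, None]
        space = statespace.build_state_space(make_epochs(data))
        assert space.explained_variance[0] > 0.999

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(1)
        space = statespace.build_state_space(make_epochs(rng.standard_normal((8, 5, 100))))
        np.testing.assert_allclose(
            space.loadings.T @ space.loadings, np.eye(5), atol=1e-8
        )

    def test_kept_components_cover_99_percent(self):
        rng = np.random.default_rng(2)
        space = statespace.build_state_space(make_epochs(rng.standard_normal((20, 6, 80))))
        assert space.explained_variance[: space.kept].sum() >= 0.99


class TestTrajectoryDistance:
    def test_identical_condition_means_give_zero(self):
        rng = np.random.default_rng(0)
        half = rng.standard_normal((10, 3, 200))
        data = np.concatenate([half, half])
        labels = np.repeat([0, 1], 10)
        _, dist = statespace.trajectory_distance(make_epochs(data), labels)
        np.testing.assert_allclose(dist, 0.0, atol=1e-10)

    def test_constant_offset_hand_oracle(self):
        data = np.zeros((20, 2, 200))
        labels = np.repeat([0, 1], 10)
        data[10:, 0, :] += 1.5  # one condition offset in one channel
        _, dist = statespace.trajectory_distance(make_epochs(data), labels, smooth=0.0)
        np.testing.assert_allclose(dist, 1.5, atol=1e-10)

    def test_three_conditions_sum_over_pairs(self):
        data = np.zeros((30, 1, 100))
        labels = np.repeat([0, 1, 2], 10)
        data[10:20, 0, :] = 1.0
        data[20:, 0, :] = 3.0
        _, dist = statespace.trajectory_distance(make_epochs(data), labels, smooth=0.0)
        np.testing.assert_allclose(dist, 1.0 + 3.0 + 2.0, atol=1e-10)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((24, 5, 120))
        labels = np.repeat([0, 1, 2], 8)
        _, d1 = statespace.trajectory_distance(make_epochs(data), labels)
        R = ortho_group.rvs(5, random_state=1)
        _, d2 = statespace.trajectory_distance(
            make_epochs(np.einsum("ij,tjs->tis", R, data)), labels
        )
        np.testing.assert_allclose(d1, d2, rtol=1e-9)


class TestStateTransitions:
    def test_constant_trial_gives_zero(self):
        data = np.ones((4, 3, 300))
        _, trans = statespace.state_transitions(make_epochs(data))
        np.testing.assert_allclose(trans, 0.0, atol=1e-12)

    def test_linear_ramp_closed_form(self):
        fs = 512.0
        t = np.arange(512) / fs
        s = 4.0
        data = (s * t)[None, None, :]
        _, trans = statespace.state_transitions(make_epochs(data, fs=fs, times=t))
        step = round(0.030 * fs) / fs  # realized center spacing on the grid
        np.testing.assert_allclose(trans, s * step, rtol=1e-6)

    def test_white_noise_transitions_stationary(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((50, 4, 1024))
        _, trans = statespace.state_transitions(make_epochs(data))
        mean_per_time = trans.mean(axis=0)
        assert (mean_per_time > 0).all()
        assert mean_per_time.std() / mean_per_time.mean() < 0.1


class TestDecoding:
    def test_rt_terciles_ties_fall_low(self):
        rt = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0, 3.0, 3.0, 3.0])
        lab = statespace.rt_terciles(rt)
        assert lab.tolist() == [0, 0, 0, 1, 1, 1, 2, 2, 2]

    def test_lda_agrees_with_sklearn(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(0)
        x = rng.standard_normal(90) + np.repeat([0.0, 1.0, 2.5], 30)
        y = np.repeat([0, 1, 2], 30)
        xt = rng.standard_normal(60) * 1.5 + 1.0
        mine = statespace._lda1d_predict(
            x[:, None], y, xt[:, None], np.array([0, 1, 2]), 0.0
        )[:, 0]
        ref = (
            LinearDiscriminantAnalysis(priors=[1 / 3] * 3)
            .fit(x[:, None], y)
            .predict(xt[:, None])
        )
        assert (mine == ref).all()

    def test_perfectly_separable_classes_decode_fully(self):
        labels = np.repeat([0, 1, 2], 10)
        scores = np.tile(labels[:, None] * 5.0, (1, 40)) + 0.01 * np.random.default_rng(
            0
        ).standard_normal((30, 40))
        acc = statespace.decode_timecourse(scores, labels, rng=np.random.default_rng(1))
        np.testing.assert_allclose(acc, 1.0, atol=1e-9)

    def test_permuted_labels_decode_at_chance(self):
        rng = np.random.default_rng(2)
        scores = rng.standard_normal((90, 60))
        labels = np.repeat([0, 1, 2], 30)
        accs = [
            statespace.decode_timecourse(scores, rng.permutation(labels), rng=rng).mean()
            for _ in range(10)
        ]
        assert np.mean(accs) == pytest.approx(1 / 3, abs=0.03)

    def test_planted_subspace_recovered(self):
        ep, ctx, rt, W = planted_epochs(seed=0)
        space = statespace.build_state_space(ep)
        dim = statespace.find_coding_dimension(space, ctx, "context", n_perm=20, seed=0)
        pc_expected = int(np.argmax(np.abs(space.loadings.T @ W[:, 2])))
        assert dim.pc_index == pc_expected
        assert dim.valid


class TestCrossRegionGeneralization:
    def test_identity_transfer_matches_within_region(self):
        ep, ctx, rt, W = planted_epochs(seed=1)
        space = statespace.build_state_space(ep)
        dim = statespace.find_coding_dimension(space, ctx, "context", n_perm=10, seed=0)
        tr = space.scores[:, dim.pc_index, :]
        out = statespace.cross_region_generalization(tr, tr.copy(), ctx, n_perm=20, seed=0)
        diag = np.diag(out["accuracy"])
        peak = np.argmax(diag)
        assert diag[peak] > 0.6
        assert out["significant"].any()

    def test_independent_target_region_stays_at_chance(self):
        rng = np.random.default_rng(2)
        labels = np.repeat([0, 1, 2], 20)
        src = labels[:, None] * 2.0 + 0.3 * rng.standard_normal((60, 40))
        tgt = rng.standard_normal((60, 40))
        out = statespace.cross_region_generalization(src, tgt, labels, n_perm=30, seed=1)
        assert abs(out["accuracy"].mean() - 1 / 3) < 0.05

    def test_planted_delay_displaces_accuracy_ridge(self):
        rng = np.random.default_rng(3)
        labels = np.repeat([0, 1, 2], 20)
        T, shift = 80, 20
        prof = np.exp(-(((np.arange(T) - 30) / 6.0) ** 2))
        src = (labels[:, None] - 1) * prof[None, :] + 0.4 * rng.standard_normal((60, T))
        prof_d = np.exp(-(((np.arange(T) - 30 - shift) / 6.0) ** 2))
        tgt = (labels[:, None] - 1) * prof_d[None, :] + 0.4 * rng.standard_normal((60, T))
        out = statespace.cross_region_generalization(src, tgt, labels, n_perm=10, seed=2)
        t_train, t_test = np.unravel_index(np.argmax(out["accuracy"]), out["accuracy"].shape)
        assert t_test - t_train == pytest.approx(shift, abs=6)


class TestTrajectoryLag:
    def test_delayed_copy_gives_negative_lag(self):
        from scipy.ndimage import uniform_filter1d

        rng = np.random.default_rng(0)
        fs, T, shift = 512.0, 512, int(0.05 * 512)
        base = uniform_filter1d(rng.standard_normal((30, T + shift)), 25, axis=1)
        lag, _ = statespace.trajectory_lag(base[:, shift:], base[:, :T], fs)
        assert lag == pytest.approx(-0.050, abs=0.01)

    def test_identical_traces_zero_lag(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((10, 256))
        lag, lags = statespace.trajectory_lag(a, a.copy(), 512.0)
        assert lag == 0.0

    def test_lag_estimate_concentrates_with_trials(self):
        """Standard error of the mean lag shrinks roughly as 1/sqrt(n)."""
        from scipy.ndimage import uniform_filter1d

        fs, T, shift = 512.0, 512, 26
        rng = np.random.default_rng(0)
        base = uniform_filter1d(rng.standard_normal((320, T + shift)), 25, axis=1)
        noise = 2.0 * uniform_filter1d(rng.standard_normal((320, T)), 25, axis=1)
        _, lags = statespace.trajectory_lag(base[:, shift:], base[:, :T] + noise, fs)
        assert lags.std() > 0
        small = lags.reshape(40, 8).mean(axis=1)  # means of 8 trials
        big = lags.reshape(10, 32).mean(axis=1)  # means of 32 trials
        assert big.std() < small.std()


class TestThetaPc:
    def test_planted_theta_component_found(self):
        rng = np.random.default_rng(0)
        fs, T, n_tr, n_ch = 256.0, 1024, 12, 5
        t = np.arange(T) / fs
        sds = np.linspace(2.0, 0.5, n_ch)
        lat = rng.standard_normal((n_tr, n_ch, T)) * sds[None, :, None]
        lat[:, 2, :] += 3.0 * np.sin(
            2 * np.pi * 5.0 * t[None, :] + rng.uniform(0, 6, (n_tr, 1))
        )
        W = ortho_group.rvs(n_ch, random_state=3)
        ep = make_epochs(np.einsum("ij,tjs->tis", W, lat), fs=fs, times=t)
        space = statespace.build_state_space(ep)
        pc, powers = statespace.find_theta_pc(space)
        expected = int(np.argmax(np.abs(space.loadings.T @ W[:, 2])))
        assert pc == expected

    def test_white_noise_band_powers_comparable(self):
        rng = np.random.default_rng(1)
        ep = make_epochs(rng.standard_normal((10, 5, 1024)), fs=256.0,
                         times=np.arange(1024) / 256.0)
        space = statespace.build_state_space(ep)
        _, powers = statespace.find_theta_pc(space)
        assert powers.max() / np.median(powers) < 2.0
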