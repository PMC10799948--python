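"""Preprocessing, HFA extraction, peaks, ramping, PTA and IPI tests."""

import numpy as np
import pandas as pd
import pytest

from ieegdyn import sigproc, synthgen
from ieegdyn.errors import UndefinedResultError
from conftest import make_epochs


def _recording(signal, fs=512.0, rois=None, names=None, bipolar=True, trials=None):
    n_ch = signal.shape[0]
    if trials is None:
        trials = synthgen.simulate_behavior(
            synthgen.SimConfig(n_trials_per_context=1, seed=0)
        )
    return synthgen.RawRecording(
        signal=signal,
        fs=fs,
        roi_labels=rois or ["pfc"] * n_ch,
        trials=trials,
        ch_names=names,
        bipolar=bipolar,
    )


class TestPreprocess:
    def test_constant_channel_zeroed(self):
        raw = _recording(np.full((2, 4096), 3.7))
        out = sigproc.preprocess(raw)
        assert np.abs(out.signal).max() < 1e-8

    def test_pure_line_noise_removed(self):
        t = np.arange(8192) / 512.0
        x = np.sin(2 * np.pi * 50.0 * t)
        raw = _recording(np.vstack([x, x * 0.5]))
        out = sigproc.preprocess(raw)
        # ignore filter edges
        core = out.signal[:, 1000:-1000]
        assert np.sqrt((core**2).mean()) < 0.01 * np.sqrt((x**2).mean())

    def test_identical_contacts_give_zero_bipolar(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(4096)
        raw = _recording(
            np.vstack([x, x]), names=["A1", "A2"], bipolar=False
        )
        out = sigproc.preprocess(raw, bipolar=True)
        assert out.n_channels == 1
        assert np.abs(out.signal).max() < 1e-8

    def test_single_contact_shaft_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        raw = _recording(
            rng.standard_normal((3, 4096)), names=["A1", "A2", "B1"], bipolar=False
        )
        with pytest.warns(UserWarning, match="single-contact"):
            out = sigproc.preprocess(raw, bipolar=True)
        assert out.ch_names == ["A1-A2"]

    def test_resampling_to_target_rate(self):
        t = np.arange(10240) / 1024.0
        raw = _recording(np.sin(2 * np.pi * 7 * t)[None, :], fs=1024.0)
        out = sigproc.preprocess(raw)
        assert out.fs == 512.0
        assert out.n_samples == 5120


class TestEpoch:
    def test_stop_trials_and_pre_hll_releases_excluded(self):
        cfg = synthgen.SimConfig(n_trials_per_context=20, n_channels={"pfc": 1, "motor": 1}, seed=8)
        raw, _ = synthgen.simulate_session(cfg)
        trials = raw.trials
        # force one go trial's release before the HLL
        go_idx = trials.index[~trials.is_stop][0]
        trials.loc[go_idx, "t_release"] = trials.loc[go_idx, "t_hll"] - 0.010
        ep = sigproc.epoch(raw, "hll", (-1.0, 0.5))
        n_stop = int(trials.is_stop.sum())
        assert ep.n_trials == len(trials) - n_stop - 1
        assert not ep.trial_meta.is_stop.any()
        assert (ep.trial_meta.t_release >= ep.trial_meta.t_hll).all()

    def test_alignment_identity_at_t0(self):
        """The sample at t=0 equals the raw sample nearest the lock event."""
        cfg = synthgen.SimConfig(n_trials_per_context=3, n_channels={"pfc": 1, "motor": 1}, seed=9)
        raw, _ = synthgen.simulate_session(cfg)
        ep = sigproc.epoch(raw, "hll", (-0.5, 0.5))
        i0 = int(np.argmin(np.abs(ep.times)))
        for k, row in enumerate(ep.trial_meta.itertuples()):
            j = int(round(row.t_hll * raw.fs))
            assert ep.data[k, 0, i0] == raw.signal[0, j]

    def test_edge_trials_dropped_with_warning(self):
        rng = np.random.default_rng(0)
        trials = synthgen.simulate_behavior(
            synthgen.SimConfig(n_trials_per_context=2, seed=1)
        )
        short = rng.standard_normal((1, int(trials.t_hll.iloc[2] * 512)))
        raw = _recording(short, trials=trials)
        with pytest.warns(UserWarning, match="edge"):
            ep = sigproc.epoch(raw, "hll", (-1.0, 1.0))
        assert ep.n_trials < (~trials.is_stop).sum()


class TestExtractHfa:
    def test_scale_invariance(self, small_session):
        _, raw, _ = small_session
        ep = sigproc.epoch(raw, "hll", (-3.0, 0.5))
        a = sigproc.extract_hfa(ep, seed=3)
        ep_scaled = make_scaled = sigproc.epoch(
            synthgen.RawRecording(
                signal=raw.signal * 37.5, fs=raw.fs, roi_labels=raw.roi_labels,
                trials=raw.trials, ch_names=raw.ch_names, bipolar=raw.bipolar,
            ),
            "hll", (-3.0, 0.5),
        )
        b = sigproc.extract_hfa(ep_scaled, seed=3)
        np.testing.assert_allclose(a.data, b.data, rtol=1e-9, atol=1e-9)

    def test_bootstrap_z_matches_analytic_baseline_oracle(self):
        """On a fixture with a known stationary envelope, the bootstrap z
        agrees with the direct (pooled mean/SD) z within bootstrap error."""
        rng = np.random.default_rng(4)
        pool = rng.gamma(4.0, 1.0, size=5000)
        data = rng.gamma(4.0, 1.0, size=(20, 300)) + 2.0
        z = sigproc.bootstrap_baseline_z(data, pool, n_boot=1000, rng=np.random.default_rng(0))
        direct = (data - pool.mean()) / pool.std()
        # bootstrap error of mean/SD with 1000 draws ~ pool SD / sqrt(1000)
        assert np.abs(z - direct).max() < 0.2

    def test_flat_envelope_gives_near_zero_z(self, small_hfa):
        """Pre-cue samples sit at baseline level: |mean z| small."""
        ep, hfa = small_hfa
        m = (hfa.times > -2.95) & (hfa.times < -2.6)
        assert abs(hfa.data[:, :, m].mean()) < 0.3

    def test_context_gain_raises_peri_hll_z(self, small_hfa):
        ep, hfa = small_hfa
        ctx = hfa.trial_meta["context"].to_numpy()
        m = (hfa.times > -0.2) & (hfa.times < 0.1)
        z0 = hfa.data[ctx == 0.0][:, :, m].mean()
        z75 = hfa.data[ctx == 0.75][:, :, m].mean()
        assert z75 > z0 + 0.5


class TestPeaks:
    def test_peak_count_tracks_envelope_modulation_rate(self):
        """A 5 Hz-modulated envelope yields about 5 peaks per second."""
        fs = 512.0
        t = np.arange(int(2 * fs)) / fs
        rng = np.random.default_rng(0)
        x = (1 + np.cos(2 * np.pi * 5 * t)) + 0.05 * rng.standard_normal(t.size)
        hfa = make_epochs(np.tile(x, (3, 1, 1)), fs=fs, times=t - 1.0)
        peaks = sigproc.detect_hfa_peaks(hfa, 0.5, 0.05)
        per_trial = peaks.table.groupby("trial").size()
        assert all(8 <= n <= 12 for n in per_trial)  # ~5 Hz over 2 s

    def test_monotone_ramp_has_no_interior_peak(self):
        x = np.linspace(0, 3, 512)
        hfa = make_epochs(x[None, None, :])
        peaks = sigproc.detect_hfa_peaks(hfa, 0.1, 0.01)
        assert peaks.table.empty

    def test_close_peaks_resolve_to_higher_one(self):
        fs = 1000.0
        x = np.zeros(500)
        x[100] = 1.0
        x[120] = 2.0  # 20 ms apart
        hfa = make_epochs(x[None, None, :], fs=fs, times=np.arange(500) / fs)
        peaks = sigproc.detect_hfa_peaks(hfa, 0.5, 0.05)
        assert len(peaks.table) == 1
        assert peaks.table.amplitude.iloc[0] == 2.0

    def test_identical_trials_nothing_trimmed(self):
        rows = [(i, 0, 0.1, 1.0) for i in range(100)]
        ps = sigproc.PeakSet(
            table=pd.DataFrame(rows, columns=["trial", "channel", "time", "amplitude"]),
            fs=512.0, min_prominence_z=0.5, min_separation_s=0.05,
        )
        table, unusable = sigproc.peak_metrics(ps)
        assert len(table) == 100 and not unusable

    def test_single_latency_outlier_removed(self):
        rng = np.random.default_rng(0)
        lat = rng.normal(0.1, 0.01, 100)
        lat[17] = 0.1 + 10 * 0.01 * 10  # +100 SD
        rows = [(i, 0, lat[i], 1.0 + rng.normal(0, 0.01)) for i in range(100)]
        ps = sigproc.PeakSet(
            table=pd.DataFrame(rows, columns=["trial", "channel", "time", "amplitude"]),
            fs=512.0, min_prominence_z=0.5, min_separation_s=0.05,
        )
        table, _ = sigproc.peak_metrics(ps)
        assert 17 not in table.trial.values

    def test_trim_rate_matches_order_statistics(self):
        """Independent normal amplitudes/latencies: ~5% trimmed per metric,
        never more than ~10% overall."""
        rng = np.random.default_rng(1)
        rows = [(i, 0, rng.normal(), rng.normal()) for i in range(1000)]
        ps = sigproc.PeakSet(
            table=pd.DataFrame(rows, columns=["trial", "channel", "time", "amplitude"]),
            fs=512.0, min_prominence_z=0.5, min_separation_s=0.05,
        )
        table, _ = sigproc.peak_metrics(ps)
        frac = 1 - len(table) / 1000
        assert 0.05 <= frac <= 0.11


class TestRampingSlope:
    def test_exact_line_recovered(self):
        t = np.arange(512) / 512.0
        hfa = make_epochs((2.0 * t)[None, None, :], times=t - 0.8)
        s = sigproc.ramping_slope(hfa, t_start=-0.7, t_end=-0.4)
        assert s[0, 0] == pytest.approx(2.0, abs=1e-9)

    def test_robust_to_single_outlier(self):
        t = np.linspace(0, 1, 200)
        y = 1.5 * t.copy()
        y[50] += 30.0
        huber = sigproc.huber_slope(t, y)
        ols = np.polyfit(t, y, 1)[0]
        assert abs(huber - 1.5) < abs(ols - 1.5)
        assert abs(huber - 1.5) < 0.05

    def test_equals_ols_when_no_outliers(self):
        rng = np.random.default_rng(2)
        t = np.linspace(0, 1, 100)
        # residuals clipped at 1 SD: all inside the Huber threshold (1.345)
        y = 0.7 * t + 0.01 * np.clip(rng.standard_normal(t.size), -1, 1)
        huber = sigproc.huber_slope(t, y)
        ols = np.polyfit(t, y, 1)[0]
        assert huber == pytest.approx(ols, abs=1e-6)

    def test_agrees_with_statsmodels_rlm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        t = np.linspace(0, 1, 150)
        y = 2.0 * t + rng.standard_normal(t.size) * 0.3
        y[10] += 5.0
        ours = sigproc.huber_slope(t, y)
        ref = sm.RLM(y, sm.add_constant(t), M=sm.robust.norms.HuberT()).fit()
        assert ours == pytest.approx(ref.params[1], abs=0.02)

    def test_short_window_rejected(self):
        hfa = make_epochs(np.zeros((1, 1, 512)))
        with pytest.raises(ValueError):
            sigproc.ramping_slope(hfa, t_start=-0.001, t_end=0.0)

    def test_planted_slope_ordering_recovered(self):
        """With gains and exponents equalized, group-mean slopes follow the
        planted ordering and the 0% context shows no ramp."""
        from scipy import stats as st

        means = []
        for seed in range(8):
            cfg = synthgen.SimConfig(
                n_trials_per_context=12, n_channels={"pfc": 2, "motor": 2}, seed=seed,
                hfa_gain_by_context={0.0: 1.0, 0.25: 1.0, 0.75: 1.0},
                aperiodic_exponent_by_context={0.0: 1.85, 0.25: 1.85, 0.75: 1.85},
            )
            raw, _ = synthgen.simulate_session(cfg)
            ep = sigproc.epoch(sigproc.preprocess(raw), "hll", (-3.0, 1.0))
            hfa = sigproc.extract_hfa(ep, seed=seed)
            ctx = hfa.trial_meta["context"].to_numpy()
            sl = sigproc.ramping_slope(hfa)
            means.append([sl[ctx == c].mean() for c in (0.0, 0.25, 0.75)])
        means = np.asarray(means)
        g = means.mean(axis=0)
        assert g[0] < g[2] < g[1]  # planted 0 < 0.8 < 1.2
        t = st.ttest_1samp(means[:, 0], 0, alternative="greater")
        assert t.pvalue > 0.05  # no ramping without uncertainty
        t25 = st.ttest_1samp(means[:, 1], 0, alternative="greater")
        assert t25.pvalue < 0.01


class TestPtaAndIpi:
    def test_noiseless_cosine_fit_exact(self):
        fs = 512.0
        lags = np.arange(-256, 257) / fs
        pta = np.cos(2 * np.pi * 4.0 * lags)
        # route through the public API with synthetic peaks at segment centers
        raw = make_epochs(np.tile(pta, (12, 1, 1)), fs=fs, times=lags)
        rows = [(i, 0, 0.0, 1.0) for i in range(12)]
        ps = sigproc.PeakSet(
            table=pd.DataFrame(rows, columns=["trial", "channel", "time", "amplitude"]),
            fs=fs, min_prominence_z=0.5, min_separation_s=0.05,
        )
        _, _, fit = sigproc.peak_triggered_average(raw, ps, half_width=0.49)
        assert fit["converged"]
        assert fit["frequency"] == pytest.approx(4.0, abs=1e-3)
        assert fit["phase"] == pytest.approx(0.0, abs=1e-3)

    def test_random_peaks_in_noise_average_out(self):
        fs = 512.0
        rng = np.random.default_rng(0)
        data = rng.standard_normal((1, 1, int(40 * fs)))
        times = np.arange(data.shape[-1]) / fs - 20.0
        raw = make_epochs(data, fs=fs, times=times)
        for n_peaks, level in ((20, None), (500, None)):
            rows = [(0, 0, rng.uniform(-19, 19), 1.0) for _ in range(n_peaks)]
            ps = sigproc.PeakSet(
                table=pd.DataFrame(rows, columns=["trial", "channel", "time", "amplitude"]),
                fs=fs, min_prominence_z=0.5, min_separation_s=0.05,
            )
            _, pta, _ = sigproc.peak_triggered_average(raw, ps)
            if n_peaks == 20:
                rms_small = np.sqrt((pta**2).mean())
            else:
                rms_big = np.sqrt((pta**2).mean())
        assert rms_big < rms_small

    def test_ipi_arithmetic(self):
        rows = [(0, 0, t, 1.0) for t in (0.1, 0.3, 0.35)]
        ps = sigproc.PeakSet(
            table=pd.DataFrame(rows, columns=["trial", "channel", "time", "amplitude"]),
            fs=512.0, min_prominence_z=0.5, min_separation_s=0.01,
        )
        freqs, mean = sigproc.inter_peak_interval(ps)
        assert sorted(np.round(freqs, 6)) == [5.0, 20.0]
        assert mean == pytest.approx(12.5)

    def test_ipi_undefined_without_adjacent_peaks(self):
        rows = [(0, 0, 0.1, 1.0), (1, 0, 0.4, 1.0)]
        ps = sigproc.PeakSet(
            table=pd.DataFrame(rows, columns=["trial", "channel", "time", "amplitude"]),
            fs=512.0, min_prominence_z=0.5, min_separation_s=0.01,
        )
        with pytest.raises(UndefinedResultError):
            sigproc.inter_peak_interval(ps)
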