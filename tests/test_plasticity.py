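"""Evoked-potential plasticity: baselines, amplitudes, decay fits, LMMs."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from pallidyn.plasticity import (
    FEPSession,
    _double_exp,
    compare_halflife,
    fep_amplitude,
    lfp_rms_baseline,
    longterm_plasticity,
    longterm_site_table,
    normalize_session,
    shortterm_decay,
    shortterm_from_sessions,
)
from pallidyn.simulate import DEFAULT_FEP_PARAMS, FEPGenParams, gen_fep_cohort, gen_fep_session

FS = 1000.0


def _session(pre=10.0, post=12.0, patient="p0", disease="PD", site="s0",
             baseline=1.0, normalized=True):
    trains = np.tile(np.linspace(pre, pre / 4, 200), (4, 1))
    return FEPSession(patient, disease, site,
                      np.full(10, pre), np.full(10, post), trains,
                      baseline_rms=baseline, normalized=normalized)


class TestRMSBaseline:
    def test_constant_signal(self):
        assert lfp_rms_baseline(np.full(2000, 7.5), FS) == pytest.approx(7.5)

    def test_sine_rms(self):
        t = np.arange(int(10 * FS)) / FS
        x = 3.0 * np.sin(2 * np.pi * 10.0 * t)
        assert lfp_rms_baseline(x, FS) == pytest.approx(3.0 / np.sqrt(2),
                                                        rel=0.01)

    def test_white_noise_filtered_variance(self):
        # oracle: variance of filtered white noise = sigma^2 * power gain
        # of the squared-magnitude (forward-backward) low-pass response
        rng = np.random.default_rng(0)
        sigma = 2.0
        x = rng.normal(0, sigma, int(30 * FS))
        sos = signal.butter(4, 50.0, btype="lowpass", fs=FS, output="sos")
        w, h = signal.sosfreqz(sos, worN=4096, fs=FS)
        gain = np.mean(np.abs(h) ** 4)  # |H|^2 squared by filtfilt
        expected = sigma * np.sqrt(gain)
        assert lfp_rms_baseline(x, FS) == pytest.approx(expected, rel=0.05)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            lfp_rms_baseline(np.ones(100), FS)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            lfp_rms_baseline(np.zeros(5000), FS)


class TestFepAmplitude:
    def _trace_with_bump(self, height=50.0, latency_ms=5.0, fs=20_000.0,
                         noise_sd=0.0, seed=0, baseline=0.0):
        rng = np.random.default_rng(seed)
        n = int(0.05 * fs)
        t = np.arange(n) / fs
        stim = 0.02
        x = np.full(n, baseline) + rng.normal(0, noise_sd, n)
        x += height * np.exp(-0.5 * ((t - stim - latency_ms * 1e-3) / 8e-4) ** 2)
        return x, stim, fs

    def test_noiseless_bump_recovered(self):
        x, stim, fs = self._trace_with_bump()
        amp = fep_amplitude(x, fs, stim)
        assert amp == pytest.approx(50.0, rel=0.01)

    def test_flat_trace_zero(self):
        x = np.zeros(1000)
        assert fep_amplitude(x, 20_000.0, 0.02) == 0.0

    def test_baseline_subtracted(self):
        x, stim, fs = self._trace_with_bump(baseline=12.0)
        assert fep_amplitude(x, fs, stim) == pytest.approx(50.0, rel=0.01)

    def test_noisy_mean_close(self):
        amps = []
        for s in range(100):
            x, stim, fs = self._trace_with_bump(noise_sd=2.0, seed=s)
            amps.append(fep_amplitude(x, fs, stim))
        assert abs(np.mean(amps) - 50.0) < 2.0

    def test_window_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            fep_amplitude(np.zeros(100), 20_000.0, 0.004)


class TestNormalizeSession:
    def test_divides_by_baseline(self):
        s = _session(pre=10.0, post=20.0, baseline=5.0, normalized=False)
        out = normalize_session(s)
        assert np.allclose(out.pre_lfs_amps, 2.0)
        assert np.allclose(out.post_lfs_amps, 4.0)
        assert out.normalized

    def test_double_normalization_rejected(self):
        s = _session(normalized=True)
        with pytest.raises(ValueError):
            normalize_session(s)

    def test_downstream_scale_invariance(self):
        # scaling raw amplitudes and baseline by c leaves statistics unchanged
        s1 = _session(pre=10.0, post=13.0, baseline=2.0, normalized=False)
        c = 7.3
        s2 = FEPSession(s1.patient_id, s1.disease, s1.site_id,
                        s1.pre_lfs_amps * c, s1.post_lfs_amps * c,
                        s1.hfs_trains * c, baseline_rms=s1.baseline_rms * c,
                        normalized=False)
        t1 = longterm_site_table([normalize_session(s1)])
        t2 = longterm_site_table([normalize_session(s2)])
        pd.testing.assert_frame_equal(t1, t2)


class TestShorttermDecay:
    def test_exact_halving(self):
        r = shortterm_decay([1.0, 0.5, 0.25, 0.125, 0.0625])
        assert r.half_life_pulses == pytest.approx(1.0, abs=1e-4)
        assert r.half_life_ms == pytest.approx(10.0, abs=1e-3)
        assert not r.no_depression

    def test_noiseless_round_trip(self):
        k = np.arange(1, 6, dtype=float)
        y = _double_exp(k, 0.6, 0.7, 5.0)
        r = shortterm_decay(y)
        assert r.half_life_pulses == pytest.approx(0.7 * np.log(2), abs=1e-3)
        assert r.tau_fast == pytest.approx(0.7, abs=1e-3)
        assert r.tau_slow == pytest.approx(5.0, rel=1e-2)
        assert r.weight_fast == pytest.approx(0.6, abs=1e-3)

    def test_flat_sequence_flagged(self):
        r = shortterm_decay([1.0, 1.0, 1.0, 1.0, 1.0])
        assert r.no_depression
        assert np.isinf(r.half_life_pulses)

    def test_recovery_grid(self):
        # zero-noise recovery whenever tau_fast <= 2 and tau_slow/tau_fast >= 3
        k = np.arange(1, 6, dtype=float)
        for tau_f in (0.3, 0.7, 1.2, 2.0):
            for ratio in (3.0, 6.0, 12.0):
                for w in (0.35, 0.6, 0.85):
                    y = _double_exp(k, w, tau_f, tau_f * ratio)
                    r = shortterm_decay(y)
                    assert r.tau_fast == pytest.approx(tau_f, abs=1e-3), \
                        (tau_f, ratio, w)

    def test_halflife_monotone_in_tau_fast(self):
        k = np.arange(1, 6, dtype=float)
        hls = [shortterm_decay(_double_exp(k, 0.6, tf, 8.0)).half_life_pulses
               for tf in (0.4, 0.8, 1.4, 2.0)]
        assert all(b > a for a, b in zip(hls, hls[1:]))

    def test_nonpositive_first_amp_rejected(self):
        with pytest.raises(ValueError):
            shortterm_decay([0.0, 0.5, 0.2, 0.1, 0.05])

    def test_normalizes_to_first_pulse(self):
        r1 = shortterm_decay([1.0, 0.5, 0.3, 0.25, 0.22])
        r2 = shortterm_decay([8.0, 4.0, 2.4, 2.0, 1.76])
        assert r1.half_life_pulses == pytest.approx(r2.half_life_pulses)


class TestLongterm:
    def _noiseless_sessions(self, delta=5.0):
        sessions = []
        for p in range(4):
            for s in range(2):
                pre = 10.0 + 2.0 * p + 0.5 * s
                trains = np.tile(np.linspace(pre, pre / 4, 200), (4, 1))
                sessions.append(FEPSession(
                    f"p{p}", "PD", f"p{p}_s{s}",
                    np.full(10, pre), np.full(10, pre + delta), trains,
                    baseline_rms=1.0, normalized=True))
        return sessions

    def test_noiseless_epoch_effect_exact(self):
        sessions = self._noiseless_sessions(delta=5.0)
        table = longterm_site_table(sessions)
        assert np.allclose(table["pct_change"],
                           100.0 * 5.0 / table.median_pre)
        # within-disease LMM on balanced noiseless data: effect exactly 5
        dys = [FEPSession(s.patient_id + "d", "dystonia", s.site_id + "d",
                          s.pre_lfs_amps, s.post_lfs_amps, s.hfs_trains,
                          1.0, True) for s in sessions]
        per_disease, _cross = longterm_plasticity(sessions + dys)
        assert per_disease["PD"].fit.fixed_effect == pytest.approx(5.0,
                                                                   abs=1e-6)

    def test_epoch_effect_recovery_simulation(self):
        # truth 5.42, patient intercept SD 2, residual SD 2, 10 patients
        # x 13 sites: estimate within 2 SE of truth in >= 93/100 runs
        import statsmodels.formula.api as smf
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            rows = []
            for site in range(13):
                pat = site % 10
                b = rng.normal(0, 2.0)
                rows.append((pat, 0, 20.0 + b * 0 + rng.normal(0, 2.0), site))
            # build long format with shared patient intercepts
            intercepts = rng.normal(0, 2.0, 10)
            rows = []
            for site in range(13):
                pat = site % 10
                for epoch in (0, 1):
                    rows.append(dict(patient_id=f"p{pat}", epoch=epoch,
                                     amp=20.0 + intercepts[pat]
                                     + 5.42 * epoch + rng.normal(0, 2.0)))
            df = pd.DataFrame(rows)
            from pallidyn.plasticity import _fit_lmm
            fit = _fit_lmm(df, "amp", "epoch")
            hits += abs(fit.fixed_effect - 5.42) <= 2 * fit.se
        assert hits >= 93

    def test_type_one_error_controlled(self):
        from pallidyn.plasticity import _fit_lmm
        false = 0
        n_runs = 200
        for seed in range(n_runs):
            rng = np.random.default_rng(10_000 + seed)
            intercepts = rng.normal(0, 2.0, 10)
            rows = [dict(patient_id=f"p{s % 10}", epoch=e,
                         amp=20.0 + intercepts[s % 10] + rng.normal(0, 2.0))
                    for s in range(13) for e in (0, 1)]
            fit = _fit_lmm(pd.DataFrame(rows), "amp", "epoch")
            false += fit.p < 0.05
        assert false / n_runs <= 0.10

    def test_unnormalized_sessions_rejected(self):
        with pytest.raises(ValueError):
            longterm_site_table([_session(normalized=False)])


class TestCompareHalflife:
    def test_exact_unit_shift(self):
        rows = []
        for p in range(4):
            for disease, hl in (("PD", 1.5 + 0.1 * p), ("dystonia", 2.5 + 0.1 * p)):
                rows.append(dict(site_id=f"{disease}{p}",
                                 patient_id=f"{disease}_p{p}",
                                 disease=disease, half_life_pulses=hl,
                                 no_depression=False))
        fit = compare_halflife(pd.DataFrame(rows))
        assert fit.fixed_effect == pytest.approx(1.0, abs=1e-6)

    def test_effect_recovery_at_printed_size(self):
        # truth 1.04 pulses; noise scaled for SE near 0.37
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            rows = []
            for disease, n_pat, n_site, base in (("PD", 10, 13, 0.52),
                                                 ("dystonia", 8, 12, 1.56)):
                ints = rng.normal(0, 0.4, n_pat)
                for s in range(n_site):
                    pat = s % n_pat
                    rows.append(dict(
                        site_id=f"{disease}{s}", patient_id=f"{disease}{pat}",
                        disease=disease, no_depression=False,
                        half_life_pulses=max(
                            0.05, base + ints[pat] + rng.normal(0, 0.6))))
            fit = compare_halflife(pd.DataFrame(rows))
            hits += abs(fit.fixed_effect - 1.04) <= 2 * fit.se
        assert hits >= 93

    def test_label_permutation_null(self):
        rng = np.random.default_rng(77)
        false = 0
        n_runs = 200
        for _ in range(n_runs):
            rows = []
            labels = rng.permutation(["PD"] * 13 + ["dystonia"] * 12)
            for s, disease in enumerate(labels):
                rows.append(dict(site_id=f"s{s}", patient_id=f"p{s % 9}",
                                 disease=disease, no_depression=False,
                                 half_life_pulses=max(0.05, rng.normal(1.0, 0.5))))
            fit = compare_halflife(pd.DataFrame(rows))
            false += fit.p < 0.05
        assert false / n_runs <= 0.10

    def test_flagged_sites_excluded_and_all_flagged_rejected(self):
        rows = [dict(site_id="a", patient_id="p1", disease="PD",
                     half_life_pulses=np.inf, no_depression=True)]
        with pytest.raises(ValueError):
            compare_halflife(pd.DataFrame(rows))


class TestGenerators:
    def test_session_protocol_structure(self):
        s, truth = gen_fep_session(FEPGenParams(), seed=0)
        assert s.pre_lfs_amps.shape == (10,)
        assert s.post_lfs_amps.shape == (10,)
        assert s.hfs_trains.shape == (4, 200)

    def test_noiseless_potentiation_exact(self):
        p = FEPGenParams(pre_amp_mean=20.0, potentiation_pct=25.0,
                         noise_sd=0.0, patient_intercept_sd=0.0)
        s, _ = gen_fep_session(p, seed=1)
        table = longterm_site_table([s])
        assert table["pct_change"].iloc[0] == pytest.approx(25.0, abs=1e-9)

    def test_noiseless_halflife_round_trip(self):
        p = FEPGenParams(tau_fast=0.7, tau_slow=5.0, noise_sd=0.0,
                         patient_intercept_sd=0.0)
        s, _ = gen_fep_session(p, seed=2)
        r = shortterm_decay(s.hfs_trains[0][:5])
        assert r.half_life_pulses == pytest.approx(0.7 * np.log(2), abs=1e-3)

    def test_cohort_layout_and_reproducibility(self):
        s1, t1 = gen_fep_cohort(seed=5)
        s2, t2 = gen_fep_cohort(seed=5)
        assert len(s1) == 13 + 12
        assert len({s.patient_id for s in s1 if s.disease == "PD"}) == 10
        for a, b in zip(s1, s2):
            assert np.array_equal(a.pre_lfs_amps, b.pre_lfs_amps)
            assert np.array_equal(a.hfs_trains, b.hfs_trains)

    def test_shared_patient_intercepts(self):
        sessions, truth = gen_fep_cohort(seed=6)
        by_pat = {}
        for sid, t in truth["sites"].items():
            pid = sid.split("_site")[0]
        # patients with two sites share one intercept
        sess_by_pat = {}
        for s, (sid, t) in zip(sessions, truth["sites"].items()):
            sess_by_pat.setdefault(s.patient_id, []).append(
                t["patient_intercept"])
        for pid, ints in sess_by_pat.items():
            assert len(set(ints)) == 1
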