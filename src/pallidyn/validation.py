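"""Cohort-scale validation routines.

Self-contained checks that exercise the analysis end to end on synthetic
data with known ground truth: oracle equivalence of the rank tests, null
calibration of the testing procedures, parameter recovery for the burst
index, oscillation-band assignment, depression half-life and the mixed
models, and reproduction of the qualitative disease-direction pattern on
calibrated cohorts.  Used by the test suite and the acceptance script.
"""

from __future__ import annotations

import warnings
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, spearmanr

from pallidyn import simulate as sim
from pallidyn import stats as st
from pallidyn.features import (
    DEFAULT_BANDS,
    SpikeSegment,
    burst_index,
    lomb_band_power,
    spiketrain_autocorr,
)
from pallidyn.pipeline import PipelineConfig, _feature_table, patient_summary_table
from pallidyn.plasticity import (
    _fit_lmm,
    compare_halflife,
    longterm_plasticity,
    shortterm_decay,
    shortterm_from_sessions,
    _double_exp,
)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(n)]


# ---------------------------------------------------------------------------
# oracle equivalence

def mwu_exact_max_deviation(seed: int = 0) -> float:
    """Max |p - oracle p| of the MWU test over all pooled sizes <= 12.

    Oracle: scipy's exact Mann-Whitney distribution on tie-free draws.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for nx in range(2, 11):
        for ny in range(2, 13 - nx):
            x = rng.normal(size=nx)
            y = rng.normal(size=ny)
            ours = st.mwu_test(x, y).p_raw
            ref = mannwhitneyu(x, y, alternative="two-sided",
                               method="exact").pvalue
            worst = max(worst, abs(ours - ref))
    return worst


def spearman_perm_enum_deviation(seed: int = 0, n_draws: int = 10) -> float:
    """Max |Monte Carlo p - exhaustive p| for n = 5 paired samples."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_draws):
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        rho_obs = spearmanr(x, y).statistic
        exact = np.mean([
            abs(spearmanr(x, np.asarray(p)).statistic) >= abs(rho_obs) - 1e-12
            for p in permutations(y)])
        mc = st.spearman_perm(x, y, n_perm=5000,
                              seed=int(rng.integers(2**31 - 1))).p_raw
        worst = max(worst, abs(mc - exact))
    return worst


# ---------------------------------------------------------------------------
# null calibration

def perm_test_type1(n_runs: int = 600, n: int = 20, alpha: float = 0.05,
                    n_perm: int = 1000, seed: int = 0) -> float:
    """Empirical type-I error of the permutation Spearman test."""
    seeds = _child_seeds(seed, n_runs)
    rng = np.random.default_rng(seed + 1)
    hits = 0
    for s in seeds:
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        hits += st.spearman_perm(x, y, n_perm=n_perm, seed=s).p_raw < alpha
    return hits / n_runs


def mwu_type1(n_runs: int = 1000, n: int = 20, alpha: float = 0.05,
              seed: int = 0) -> float:
    """Empirical type-I error of the two-tailed MWU group comparison."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_runs):
        hits += st.mwu_test(rng.normal(size=n), rng.normal(size=n)).p_raw < alpha
    return hits / n_runs


# ---------------------------------------------------------------------------
# parameter recovery

def bi_recovery(seed: int = 0, n_per_mode: int = 1000,
                isi_short_s: float = 0.005, isi_long_s: float = 0.100,
                log_sd: float = 0.1) -> float:
    """Burst index recovered from a bimodal log-ISI construction.

    Ground truth: geometric-mean ISI ratio isi_long / isi_short.
    """
    rng = np.random.default_rng(seed)
    logs = np.concatenate([
        rng.normal(np.log(isi_short_s), log_sd, n_per_mode),
        rng.normal(np.log(isi_long_s), log_sd, n_per_mode)])
    rng.shuffle(logs)
    times = np.concatenate([[0.0], np.cumsum(np.exp(logs))])
    seg = SpikeSegment(times, times[-1] + 1.0)
    return burst_index(seg)


def band_assignment_rate(freq_hz: float, band: str, n_runs: int = 100,
                         seed: int = 0, base_rate: float = 60.0,
                         duration_s: float = 30.0,
                         mod_depth: float = 0.5) -> float:
    """Fraction of runs in which the injected modulation wins its band."""
    seeds = _child_seeds(seed, n_runs)
    wins = 0
    for s in seeds:
        seg, _ = sim.gen_spike_train(
            sim.SpikeGenParams(base_rate=base_rate, duration_s=duration_s,
                               osc_freq=freq_hz, mod_depth=mod_depth),
            seed=s)
        lags, acf = spiketrain_autocorr(seg)
        bp = lomb_band_power(lags, acf)
        wins += max(bp, key=bp.get) == band
    return wins / n_runs


def halflife_recovery_error(tau_fast: float = 0.7, tau_slow: float = 5.0,
                            weight_fast: float = 0.6) -> float:
    """|fitted - true| fast half-life (pulses) on noiseless model data."""
    k = np.arange(1, 6, dtype=float)
    y = _double_exp(k, weight_fast, tau_fast, tau_slow)
    fit = shortterm_decay(y)
    return abs(fit.half_life_pulses - tau_fast * np.log(2.0))


def lmm_epoch_recovery(n_runs: int = 100, effect: float = 5.42,
                       intercept_sd: float = 2.0, resid_sd: float = 2.0,
                       n_patients: int = 10, n_sites: int = 13,
                       seed: int = 0) -> float:
    """Fraction of runs with the epoch effect within 2 SE of truth."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_runs):
        intercepts = rng.normal(0.0, intercept_sd, n_patients)
        rows = [dict(patient_id=f"p{site % n_patients}", epoch=epoch,
                     amp=20.0 + intercepts[site % n_patients]
                     + effect * epoch + rng.normal(0.0, resid_sd))
                for site in range(n_sites) for epoch in (0, 1)]
        fit = _fit_lmm(pd.DataFrame(rows), "amp", "epoch")
        hits += abs(fit.fixed_effect - effect) <= 2.0 * fit.se
    return hits / n_runs


# ---------------------------------------------------------------------------
# analytic identities

def gamma_cv_identity_error(shape: float = 4.0, n: int = 100_000,
                            seed: int = 0) -> float:
    """Relative error of ISI CV vs 1/sqrt(shape) for a gamma renewal train."""
    seg, _ = sim.gen_spike_train(
        sim.SpikeGenParams(base_rate=100.0, duration_s=n / 100.0,
                           gamma_shape=shape, refractory_ms=0.0), seed=seed)
    from pallidyn.features import isi_cv
    expected = 1.0 / np.sqrt(shape)
    return abs(isi_cv(seg) - expected) / expected


def rectified_sine_rms_error(amp: float = 3.0, freq: float = 10.0,
                             fs: float = 1000.0, dur: float = 10.0) -> float:
    """Relative error of the LFP RMS baseline vs A/sqrt(2) for a sine."""
    from pallidyn.plasticity import lfp_rms_baseline
    t = np.arange(int(dur * fs)) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    expected = amp / np.sqrt(2.0)
    return abs(lfp_rms_baseline(x, fs) - expected) / expected


def lomb_classical_max_relerr(seed: int = 0) -> float:
    """Max relative Lomb-vs-classical-periodogram error, even sampling.

    Compared at the Fourier frequencies of the lag span, where the two
    are mathematically equivalent.
    """
    from pallidyn.features import DEFAULT_FREQ_GRID, lomb_periodogram
    rng = np.random.default_rng(seed)
    lags = (np.arange(500) + 0.5) * 0.002
    y = np.cos(2 * np.pi * 6.0 * lags) + 0.3 * rng.normal(size=lags.size)
    freqs = DEFAULT_FREQ_GRID
    p = lomb_periodogram(lags, y, freqs)
    yc = y - y.mean()
    classical = np.abs(np.exp(-2j * np.pi * np.outer(freqs, lags)) @ yc) ** 2 \
        / (lags.size * yc.var())
    fourier = np.abs(freqs - np.round(freqs)) < 1e-9
    denom = np.maximum(classical[fourier], 1e-3 * classical.max())
    return float(np.max(np.abs(p[fourier] - classical[fourier]) / denom))


# ---------------------------------------------------------------------------
# direction reproduction on calibrated cohorts

DIRECTION_CONDITIONS = ("fr_pd_gt_dys", "bi_dys_gt_pd", "cv_dys_gt_pd",
                        "potentiation_pd_gt_dys", "depression_pd_faster",
                        "theta_severity_dys_positive")


def one_cohort_directions(seed: int, config: PipelineConfig | None = None
                          ) -> dict[str, bool]:
    """Direction pattern of one synthetic cohort (spiketrain + fEP arms)."""
    cfg = config or PipelineConfig()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        segments, scores, _ = sim.gen_cohort(
            sim.CohortConfig(n_pd=cfg.n_pd, n_dystonia=cfg.n_dystonia,
                             segments_per_patient=tuple(cfg.segments_per_patient),
                             segment_duration_s=cfg.segment_duration_s),
            seed=seed)
        feature_df = _feature_table(segments, cfg)
        band_names = [b[0] for b in cfg.bands]
        summaries = patient_summary_table(feature_df, scores, band_names)
        pd_s = summaries[summaries.disease == "PD"]
        dy_s = summaries[summaries.disease == "dystonia"]
        theta_rho = spearmanr(dy_s["theta_p90"],
                              dy_s["clinical_score_pct"]).statistic

        # plasticity directions via the cross-disease mixed-model effects,
        # the same readout the findings themselves use: percent-change
        # effect (PD - dystonia) and half-life effect (dystonia - PD)
        sessions, _ = sim.gen_fep_cohort(seed=seed + 1)
        _, cross = longterm_plasticity(sessions)
        st_table = shortterm_from_sessions(sessions)
        hl_fit = compare_halflife(st_table)
    return {
        "fr_pd_gt_dys": bool(pd_s["fr_median"].median()
                             > dy_s["fr_median"].median()),
        "bi_dys_gt_pd": bool(dy_s["bi_p90"].median() > pd_s["bi_p90"].median()),
        "cv_dys_gt_pd": bool(dy_s["cv_p90"].median() > pd_s["cv_p90"].median()),
        "potentiation_pd_gt_dys": bool(cross.fixed_effect > 0),
        "depression_pd_faster": bool(hl_fit.fixed_effect > 0),
        "theta_severity_dys_positive": bool(theta_rho > 0),
    }


def direction_reproduction(n_cohorts: int = 20, seed: int = 0
                           ) -> dict[str, float]:
    """Fraction of cohorts reproducing each (and every) disease direction."""
    seeds = _child_seeds(seed, n_cohorts)
    rows = [one_cohort_directions(s) for s in seeds]
    df = pd.DataFrame(rows)
    out = {k: float(df[k].mean()) for k in DIRECTION_CONDITIONS}
    out["all_conditions"] = float(df.all(axis=1).mean())
    return out


# ---------------------------------------------------------------------------
# cohort correlation recovery (light cohorts, firing rate only)

def fr_severity_recovery(n_cohorts: int = 100, seed: int = 0) -> float:
    """Mean recovered FR-severity Spearman rho across light dystonia cohorts."""
    seeds = _child_seeds(seed, n_cohorts)
    rhos = []
    for s in seeds:
        c = sim.CohortConfig(n_pd=1, n_dystonia=19,
                             segments_per_patient=(1, 1),
                             segment_duration_s=10.0)
        segments, scores, _ = sim.gen_cohort(c, seed=s)
        frs = {g.patient_id: g.n_spikes / g.duration_s
               for g in segments if g.disease == "dystonia"}
        sub = scores[scores.disease == "dystonia"]
        rhos.append(spearmanr([frs[p] for p in sub.patient_id],
                              sub.clinical_score_pct).statistic)
    return float(np.mean(rhos))
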