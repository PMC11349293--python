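"""Evoked-field-potential plasticity quantification.

A plasticity session probes one GPi recording site with 10
low-frequency (1 Hz) stimulation pulses, a tetanizing protocol of four
2-s trains of 100 Hz high-frequency stimulation (HFS) separated by 8 s,
and 10 post-HFS low-frequency pulses.  Field-evoked potential (fEP)
amplitudes are normalized by the RMS of the rectified pre-stimulation
LFP (low-pass filtered at 50 Hz).

Long-term plasticity-like effects are the per-site change in median
normalized fEP amplitude pre- vs. post-HFS, tested with a linear mixed
model (epoch fixed effect, patient random intercept); percent change is
compared across diseases with another patient-clustered LMM.

Short-term plasticity is the within-train synaptic depression: the
first five fEP amplitudes of the first HFS train, normalized to the
first pulse, are fit with a double-exponential decay and summarized by
the half-life of the fast component (in pulses; x10 ms at 100 Hz).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.optimize import least_squares
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

N_LFS = 10
N_TRAINS = 4
PULSES_PER_TRAIN = 200
PULSE_INTERVAL_MS = 10.0  # 100 Hz

#: fEP amplitude measurement defaults (ms relative to the stimulus).
DEFAULT_BLANK_MS = 1.0
DEFAULT_WINDOW_MS = (1.0, 10.0)
DEFAULT_BASELINE_MS = 5.0


@dataclass
class FEPSession:
    """One recording site's evoked-potential amplitudes across epochs."""

    patient_id: str
    disease: str
    site_id: str
    pre_lfs_amps: np.ndarray
    post_lfs_amps: np.ndarray
    hfs_trains: np.ndarray  # (N_TRAINS, PULSES_PER_TRAIN)
    baseline_rms: float
    normalized: bool = False

    def __post_init__(self) -> None:
        self.pre_lfs_amps = np.asarray(self.pre_lfs_amps, dtype=float)
        self.post_lfs_amps = np.asarray(self.post_lfs_amps, dtype=float)
        self.hfs_trains = np.asarray(self.hfs_trains, dtype=float)
        if self.pre_lfs_amps.shape != (N_LFS,):
            raise ValueError(f"expected {N_LFS} pre-LFS amplitudes")
        if self.post_lfs_amps.shape != (N_LFS,):
            raise ValueError(f"expected {N_LFS} post-LFS amplitudes")
        if self.hfs_trains.shape != (N_TRAINS, PULSES_PER_TRAIN):
            raise ValueError(
                f"expected {N_TRAINS} HFS trains of {PULSES_PER_TRAIN} pulses")
        if self.baseline_rms <= 0:
            raise ValueError("baseline_rms must be positive")
        if self.normalized and (np.any(self.pre_lfs_amps < 0)
                                or np.any(self.post_lfs_amps < 0)):
            raise ValueError("normalized amplitudes must be non-negative")


@dataclass(frozen=True)
class MixedModelFit:
    """Fixed-effect summary of a patient-clustered linear mixed model."""

    fixed_effect: float
    se: float
    p: float
    random_intercept_sd: float
    n_obs: int
    n_groups: int
    method: str = "lmm"


@dataclass(frozen=True)
class ShortTermResult:
    """Double-exponential depression fit for one site's first HFS train."""

    site_id: str
    tau_fast: float
    tau_slow: float
    weight_fast: float
    half_life_pulses: float
    half_life_ms: float
    fit_residual: float
    no_depression: bool = False


@dataclass(frozen=True)
class LongTermResult:
    """Per-disease long-term plasticity summary."""

    disease: str
    site_table: pd.DataFrame  # site_id, patient_id, median_pre, median_post, pct_change
    fit: MixedModelFit


def lfp_rms_baseline(pre_stim_lfp, sampling_rate: float,
                     lowpass_hz: float = 50.0, order: int = 4) -> float:
    """RMS amplitude of the rectified, low-pass filtered pre-stimulation LFP.

    The signal is low-pass filtered (zero-phase Butterworth, 50 Hz by
    default), full-wave rectified, and reduced to its root-mean-square.
    Used as the per-site normalization constant for fEP amplitudes.
    """
    x = np.asarray(pre_stim_lfp, dtype=float)
    if x.size < sampling_rate:
        raise ValueError("need at least 1 s of pre-stimulation signal")
    if lowpass_hz >= sampling_rate / 2:
        raise ValueError("lowpass_hz must be below the Nyquist frequency")
    sos = signal.butter(order, lowpass_hz, btype="lowpass", fs=sampling_rate,
                        output="sos")
    filt = signal.sosfiltfilt(sos, x)
    rms = float(np.sqrt(np.mean(np.abs(filt) ** 2)))
    if rms == 0.0:
        raise ValueError("degenerate baseline: filtered signal is all zero")
    return rms


def fep_amplitude(evoked_trace, sampling_rate: float, stim_time: float,
                  window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
                  blank_ms: float = DEFAULT_BLANK_MS,
                  baseline_ms: float = DEFAULT_BASELINE_MS,
                  smooth_ms: float = 0.3) -> float:
    """Amplitude of one positive-going evoked field potential.

    Maximum positive deflection from the local pre-stimulus baseline
    (mean of ``baseline_ms`` before the stimulus) within the
    post-stimulus window, after an artifact blanking period.  A short
    moving average (``smooth_ms``) precedes the peak search; without it
    the max-over-window rule is positively biased by noise.
    """
    x = np.asarray(evoked_trace, dtype=float)
    n_sm = int(round(smooth_ms * 1e-3 * sampling_rate))
    if n_sm > 1:
        x = np.convolve(x, np.ones(n_sm) / n_sm, mode="same")
    lo = max(window_ms[0], blank_ms) * 1e-3
    hi = window_ms[1] * 1e-3
    i_stim = int(round(stim_time * sampling_rate))
    i_lo = i_stim + int(round(lo * sampling_rate))
    i_hi = i_stim + int(round(hi * sampling_rate))
    i_base = max(0, i_stim - int(round(baseline_ms * 1e-3 * sampling_rate)))
    if not (0 <= i_lo < i_hi <= x.size):
        raise ValueError("measurement window outside the trace")
    baseline = float(x[i_base:i_stim].mean()) if i_stim > i_base else 0.0
    return float(max(0.0, np.max(x[i_lo:i_hi]) - baseline))


def normalize_session(s: FEPSession) -> FEPSession:
    """Divide every amplitude in a session by its baseline RMS."""
    if s.normalized:
        raise ValueError(f"session {s.site_id} is already normalized")
    c = s.baseline_rms
    return replace(
        s,
        pre_lfs_amps=s.pre_lfs_amps / c,
        post_lfs_amps=s.post_lfs_amps / c,
        hfs_trains=s.hfs_trains / c,
        normalized=True,
    )


def _fit_lmm(df: pd.DataFrame, response: str, fixed: str,
             group: str = "patient_id") -> MixedModelFit:
    """Random-intercept LMM; falls back to OLS if the mixed fit fails.

    The fixed-effect p-value uses a t reference with n_groups - 1
    degrees of freedom (between-cluster df): the REML Wald z is
    anti-conservative at the cohort sizes this analysis sees.
    """
    from scipy.stats import t as _tdist

    formula = f"{response} ~ {fixed}"
    n_groups = df[group].nunique()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = smf.mixedlm(formula, df, groups=df[group]).fit(reml=True)
            z = float(fit.params[fixed]) / float(fit.bse[fixed])
            p = float(2.0 * _tdist.sf(abs(z), max(1, n_groups - 1)))
            return MixedModelFit(
                fixed_effect=float(fit.params[fixed]),
                se=float(fit.bse[fixed]),
                p=p,
                random_intercept_sd=float(np.sqrt(max(fit.cov_re.iloc[0, 0], 0.0))),
                n_obs=len(df),
                n_groups=n_groups,
                method="lmm",
            )
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("mixed model failed (%s); downgrading to OLS", exc)
            ols = smf.ols(formula, df).fit()
            return MixedModelFit(
                fixed_effect=float(ols.params[fixed]),
                se=float(ols.bse[fixed]),
                p=float(ols.pvalues[fixed]),
                random_intercept_sd=float("nan"),
                n_obs=len(df),
                n_groups=df[group].nunique(),
                method="ols_fallback",
            )


def longterm_site_table(sessions: Iterable[FEPSession]) -> pd.DataFrame:
    """Per-site medians of the 10 pre- and 10 post-HFS amplitudes.

    Sessions must already be normalized.  percent change is
    100 * (post - pre) / pre.
    """
    rows = []
    for s in sessions:
        if not s.normalized:
            raise ValueError(f"session {s.site_id} must be normalized first")
        pre = float(np.median(s.pre_lfs_amps))
        post = float(np.median(s.post_lfs_amps))
        rows.append({
            "site_id": s.site_id,
            "patient_id": s.patient_id,
            "disease": s.disease,
            "median_pre": pre,
            "median_post": post,
            "pct_change": 100.0 * (post - pre) / pre,
        })
    if not rows:
        raise ValueError("no sessions given")
    return pd.DataFrame(rows)


def longterm_plasticity(sessions: Sequence[FEPSession]
                        ) -> tuple[dict[str, LongTermResult], MixedModelFit]:
    """Long-term plasticity per disease, plus the cross-disease comparison.

    Within each disease: LMM with per-site median normalized amplitude as
    response, epoch (pre=0, post=1) as fixed effect and patient as random
    intercept.  Across diseases: LMM on per-site percent change with
    disease (PD=1, dystonia=0) as fixed effect.
    """
    table = longterm_site_table(sessions)
    per_disease: dict[str, LongTermResult] = {}
    for disease, grp in table.groupby("disease", sort=True):
        long_df = pd.concat([
            grp.assign(epoch=0, amp=grp["median_pre"]),
            grp.assign(epoch=1, amp=grp["median_post"]),
        ], ignore_index=True)
        fit = _fit_lmm(long_df, "amp", "epoch")
        per_disease[disease] = LongTermResult(disease, grp.reset_index(drop=True), fit)
    diseases = sorted(table["disease"].unique())
    if len(diseases) == 2:
        table = table.assign(
            is_pd=(table["disease"] == "PD").astype(float))
        cross = _fit_lmm(table, "pct_change", "is_pd")
    else:
        raise ValueError("cross-disease comparison requires exactly 2 diseases")
    return per_disease, cross


# ---------------------------------------------------------------------------
# short-term depression

_N_FIT_PULSES = 5

# fixed multi-start grid over (weight_fast, tau_fast, tau_slow/tau_fast)
_STARTS = [
    (0.3, 0.5, 5.0), (0.7, 0.5, 5.0),
    (0.3, 2.0, 5.0), (0.7, 2.0, 5.0),
    (0.3, 0.5, 30.0), (0.7, 0.5, 30.0),
    (0.5, 1.0, 10.0), (0.9, 0.3, 20.0),
]


def _double_exp(k: np.ndarray, w: float, tau_f: float, tau_s: float
                ) -> np.ndarray:
    return w * np.exp(-(k - 1) / tau_f) + (1 - w) * np.exp(-(k - 1) / tau_s)


def shortterm_decay(train_amps, pulse_interval_ms: float = PULSE_INTERVAL_MS,
                    site_id: str = "") -> ShortTermResult:
    """Fit within-train fEP depression and return its fast half-life.

    The first five amplitudes are normalized to the first pulse
    (y1 = 1) and fit with
    y(k) = w exp(-(k-1)/tau_fast) + (1-w) exp(-(k-1)/tau_slow),
    k = 1..5, by bounded least squares with tau_fast <= tau_slow and
    w in [0, 1], from 8 fixed starting points (ties broken by lowest
    residual, then lowest tau_fast).  Half-life = tau_fast * ln 2 in
    pulses (x pulse interval for ms).  A non-decaying sequence is
    flagged ``no_depression`` with an infinite half-life.
    """
    y = np.asarray(train_amps, dtype=float)[:_N_FIT_PULSES]
    if y.size < _N_FIT_PULSES:
        raise ValueError(f"need {_N_FIT_PULSES} amplitudes")
    if y[0] <= 0:
        raise ValueError("first fEP amplitude must be positive")
    y = y / y[0]
    k = np.arange(1, _N_FIT_PULSES + 1, dtype=float)

    if y[1:].mean() >= 1.0:
        logger.info("site %s: no within-train depression detected", site_id)
        return ShortTermResult(site_id, float("inf"), float("inf"), 0.0,
                               float("inf"), float("inf"),
                               float(np.sqrt(np.mean((y - 1.0) ** 2))),
                               no_depression=True)

    def resid(theta):
        w, tau_f, ratio = theta
        return _double_exp(k, w, tau_f, tau_f * ratio) - y

    def effective(theta):
        # A component with (near-)zero weight carries no amplitude and its
        # time constant is unidentifiable; reduce to contributing components
        # before labeling fast vs slow.
        w, tau_f, ratio = theta
        comps = [(w, tau_f), (1.0 - w, tau_f * ratio)]
        comps = [c for c in comps if c[0] > 1e-3]
        if not comps:
            return 0.0, tau_f, tau_f * ratio
        taus = sorted(t for _, t in comps)
        w_fast = next(w_ for w_, t in comps if t == taus[0])
        return (w_fast, taus[0], taus[-1])

    best = None
    for start in _STARTS:
        sol = least_squares(resid, start,
                            bounds=([0.0, 1e-3, 1.0], [1.0, 50.0, 1e3]),
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        eff = effective(sol.x)
        key = (round(sol.cost, 12), round(eff[1], 9))
        if best is None or key < best[0]:
            best = (key, sol, eff)
    _, sol, (w, tau_f, tau_s) = best
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    hl = float(tau_f * np.log(2.0))
    return ShortTermResult(site_id, float(tau_f), float(tau_s), float(w),
                           hl, hl * pulse_interval_ms, rms)


def shortterm_from_sessions(sessions: Iterable[FEPSession]) -> pd.DataFrame:
    """Short-term depression fits for the first HFS train of each site."""
    rows = []
    for s in sessions:
        r = shortterm_decay(s.hfs_trains[0], site_id=s.site_id)
        rows.append({
            "site_id": s.site_id,
            "patient_id": s.patient_id,
            "disease": s.disease,
            "tau_fast": r.tau_fast,
            "tau_slow": r.tau_slow,
            "weight_fast": r.weight_fast,
            "half_life_pulses": r.half_life_pulses,
            "half_life_ms": r.half_life_ms,
            "fit_residual": r.fit_residual,
            "no_depression": r.no_depression,
        })
    if not rows:
        raise ValueError("no sessions given")
    return pd.DataFrame(rows)


def compare_halflife(halflife_table: pd.DataFrame) -> MixedModelFit:
    """Cross-disease comparison of fast-component half-lives.

    LMM with half-life (pulses) as response, disease as fixed effect
    (dystonia=1, PD=0, so a positive effect means slower depression in
    dystonia) and patient as random intercept.  Sites flagged as
    non-depressing are excluded with a log entry.
    """
    df = halflife_table
    flagged = df["no_depression"] | ~np.isfinite(df["half_life_pulses"])
    if flagged.any():
        logger.warning("excluding %d non-depressing sites", int(flagged.sum()))
        df = df[~flagged]
    if df.empty:
        raise ValueError("all sites flagged non-depressing")
    for disease, grp in df.groupby("disease"):
        if grp["patient_id"].nunique() < 2:
            raise ValueError(f"need >= 2 patients per disease, {disease} has "
                             f"{grp['patient_id'].nunique()}")
    df = df.assign(is_dystonia=(df["disease"] == "dystonia").astype(float),
                   hl=df["half_life_pulses"])
    return _fit_lmm(df, "hl", "is_dystonia")
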