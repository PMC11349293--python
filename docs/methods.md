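# Methods

This note documents the models, estimators and design choices behind
`pallidyn`, and what the synthetic-data generators do and do not emulate.

## Segment quality control

Segments enter the analysis only with signal-to-noise ratio above 4 and an
interspike-interval (ISI) violation fraction below 1%, both strict
inequalities. SNR is defined as peak-to-peak amplitude of the mean spike
template divided by twice the noise standard deviation — a common
microelectrode convention, monotone in the intuitive quantity. The
refractory bound for ISI violations defaults to 1.0 ms (configurable), a
standard absolute-refractory figure for high-frequency-discharge GPi
units. Band-pass filtering (300–3000 Hz default) is a 4th-order
Butterworth applied forward-backward (`sosfiltfilt`), so the response is
zero-phase and spike times are not biased. Spike detection thresholds at
4 robust noise SDs (median absolute deviation / 0.6745), aligns events to
the negative peak, and accepts an event when its Pearson correlation with
the running mean template reaches 0.8; all three constants are
configurable. This is a deliberately simple single-unit matcher: no
clustering, no drift correction.

## Spike-train features

- **Firing rate**: spike count / segment duration (Hz).
- **CV**: sample SD of ISIs over their mean.
- **Burst index**: a two-component Gaussian mixture is fit to the
  natural-log ISI distribution and BI = exp(μ_long − μ_short), i.e. the
  ratio of the two components' geometric-mean ISIs, ordered so BI ≥ 1.
  The exp of the log-mean difference is unit-free, reduces to the
  intuitive long/short ISI ratio, and is strictly monotone in mode
  separation. The fit uses scikit-learn's EM with k-means
  initialization, tolerance 1e-6 and up to 2000 iterations; in one
  dimension with two components the k-means-seeded EM lands on the same
  optimum across restarts (verified against multiple initialization
  strategies), so the default is a single initialization with the
  restart count configurable. The fit is declared degenerate — BI
  reported as 1 with a flag — when the component log-means are closer
  than 0.05 or either weight falls below 0.02; fewer than 20 ISIs is an
  error.
- **Oscillatory power**: the spike-train autocorrelation function (all
  positive pairwise spike-time differences, 2 ms bins, 1 s maximum lag,
  normalized per reference spike, zero-lag excluded) is mean-subtracted
  and submitted to the Lomb periodogram on a 1–100 Hz grid at 0.25 Hz
  (≥ 16 grid points per band). Power is normalized by the ACF sample
  variance (Scargle convention), which makes the Lomb spectrum equal the
  classical periodogram |DFT|²/(N·var) on evenly sampled input — the
  property the test suite asserts at the Fourier frequencies of the lag
  span. The per-band statistic is the maximum normalized power in
  [lo, hi): oscillations are narrowband peaks and a band mean dilutes
  them (a mean statistic is available). Default bands are theta 4–8,
  alpha 8–12, low-beta 12–21 and high-beta 21–30 Hz; a delta band
  (1–4 Hz) is available via configuration but not in the default family.

Patient summaries use the median (FR) and the 90th percentile with linear
interpolation (BI, CV, band powers) across a patient's segments.

## Statistics

- **Group comparison**: two-tailed Mann–Whitney U per feature on
  patient-level summaries. With pooled n ≤ 12 the p-value is computed by
  exact enumeration of all group assignments (ties handled by average
  ranks); otherwise by the tie-corrected normal approximation with
  continuity correction. If the tie-corrected variance is zero
  (all values identical) the p-value is 1. The family threshold is
  Bonferroni α/m over the tested features (α = 0.05, m = 7 for FR, BI,
  CV and four bands gives 0.0071).
- **Clinical correlations**: Spearman rho (Pearson on average ranks) with
  a Monte Carlo permutation p-value — one margin shuffled n_perm = 5000
  times within the disease group, two-sided on |rho|, add-one rule
  p = (1 + #{|rho_perm| ≥ |rho_obs|}) / (n_perm + 1), which is unbiased
  and never returns zero. Benjamini–Hochberg FDR at α = 0.05 is applied
  across all disease × feature tests together by default (per-disease
  families are configurable); the BH rejection set always contains the
  Bonferroni set at the same α.
- **Mixed models**: random-intercept linear mixed models (statsmodels
  MixedLM, REML) with patient as the grouping factor. The fixed-effect
  p-value uses a t reference with n_groups − 1 degrees of freedom rather
  than the Wald normal: at the cohort sizes this analysis sees (10–18
  patients, 12–26 observations) the Wald z is anti-conservative
  (empirical type-I ≈ 0.11 at nominal 0.05 in simulation; the
  between-cluster t brings it to ≈ 0.085). If the mixed fit fails
  (e.g. a single patient), the model downgrades to OLS with a logged
  warning and a `method` marker in the result.

## Plasticity

fEP amplitudes are normalized per site by the RMS of the full-wave
rectified pre-stimulation LFP, low-pass filtered at 50 Hz (zero-phase
4th-order Butterworth). The single-pulse amplitude measurement is
baseline-to-positive-peak: maximum positive deflection from the local
pre-stimulus baseline (5 ms mean) in a 1–10 ms post-stimulus window after
1 ms artifact blanking, with a 0.3 ms moving average before the peak
search (the raw max-over-window rule is positively biased by noise); all
windows are configurable. The peak-to-peak convention and exact window
used on the original recordings are not recoverable from the available
description, so these defaults bracket reported striato-pallidal fEP
latencies.

**Long-term**: per site, the median of the 10 pre-LFS and 10 post-LFS
normalized amplitudes; within each disease an LMM of site-median
amplitude on epoch (pre = 0, post = 1) with patient random intercepts; on
balanced noiseless data the epoch estimate equals the arithmetic
pre/post difference exactly. Across diseases, an LMM of per-site percent
change 100·(post − pre)/pre on disease (PD = 1). The whole chain is
scale-invariant: multiplying raw amplitudes and baseline by any c > 0
changes nothing downstream.

**Short-term**: the first five amplitudes of the first HFS train (the
protocol's within-train depression readout), normalized to the first
pulse, are fit with y(k) = w·e^(−(k−1)/τ_f) + (1−w)·e^(−(k−1)/τ_s),
k = 1..5. Five points cannot constrain four free parameters plus an
offset, so the weight constraint fixes y(1) = 1 and there is no offset
term — the minimal identifiable model consistent with first-pulse
normalization. Fitting is bounded least squares over (w, τ_f, τ_s/τ_f)
with w ∈ [0,1], τ_f ∈ [1e-3, 50], ratio ∈ [1, 1e3], from 8 fixed starting
points, ties broken by lowest residual then lowest τ_f. A component whose
weight is (near) zero carries no amplitude and its time constant is
unidentifiable, so components with weight ≤ 1e-3 are dropped before
labeling fast vs slow. The readout is the fast half-life τ_f·ln 2 in
pulses (× 10 ms per pulse at 100 Hz). A sequence whose later amplitudes
average at or above the first pulse is flagged `no_depression` with an
infinite half-life and excluded from the cross-disease LMM with a log
entry. Fitting in pulse index rather than absolute time matches the
per-pulse protocol; other trains are retained in the data model.

## Synthetic data

The generators define the study conditions under which the pipeline is
validated.

**Spike trains** are gamma-renewal processes (unit-mean gamma ISIs,
CV = 1/√shape) mapped through time rescaling so the instantaneous rate is
r(t) = r₀(1 + m·sin 2πft) — oscillations are injected as rate
modulation, matching the rate-encoding interpretation of spike-train
oscillations, not as jittered periodic spikes. Bursts are superimposed
fixed-length runs (4 spikes at 3.5–4 ms ISIs with 10% jitter; exact
periodicity is neither physiological nor numerically benign for the
log-ISI mixture), which produces the bimodal log-ISI structure the burst
index assumes, with controllable mode separation. An absolute refractory
period (1 ms) is enforced by deletion.

**Cohorts** default to 44 PD and 19 dystonia patients with 4–8 segments
of 20 s each. Disease profiles: PD 85 ± 15 Hz, shape 3, 0.8 bursts/s,
15 Hz modulation 0.25 ± 0.10; dystonia 65 ± 15 Hz, shape 1.8,
2.5 bursts/s, 6 Hz modulation 0.42 ± 0.22 — rates and regularity in the
range reported for human GPi, directions matching the hypo/hyperkinetic
dichotomy. Feature–severity dependence is injected through a Gaussian
copula: each patient draws a severity latent z₀ (severity = Φ(z₀),
mapped to the disease's clinical scale — UPDRS-III for PD, TWSTRS or
BFMDRS for dystonia) and driver latents ρz₀ + √(1−ρ²)ε for rate,
irregularity (lowers renewal shape, raises burst rate) and modulation
depth. The latent couplings (dystonia: rate −0.52, irregularity +0.25,
depth +0.65; PD: depth +0.30) are calibrated so the *measured*
cohort-level Spearman correlations land near the target values −0.49
(FR), +0.48 (CV), +0.51 (theta) and +0.30 (low-beta): a latent coupling
must exceed its measured target because periodogram estimation noise and
the covariation of rate and burstiness with severity attenuate the
observed correlation (e.g. higher burstiness inflates ACF variance and
so deflates the normalized theta peak). Calibration used 20 fresh-seed
cohorts per setting.

**fEP sessions** follow the frozen protocol (10 pre-LFS at 1 Hz, 4 trains
of 2 s at 100 Hz separated by 8 s — 200 pulses per train — 10 post-LFS)
in already-normalized units. Pre-LFS amplitudes are 20 ± 2 around a
patient-level intercept (SD 2, shared across a patient's sites); trains
decay from the pre level by the double-exponential model; post-LFS
amplitudes sit at the potentiated level. Disease conditions: PD 27%
potentiation, τ_f = 0.75, τ_s = 5, w = 0.7; dystonia 14% potentiation,
τ_f = 2.25, τ_s = 8, w = 0.6. These place the within-disease epoch
effects near 5.4 and 2.8 normalized units, the cross-disease
percent-change difference near 13 points, and the half-life difference
at (2.25 − 0.75)·ln 2 ≈ 1.04 pulses — the magnitudes the analysis is
expected to resolve. The cohort layout is 10 PD patients / 13 sites and
8 dystonia patients / 12 sites, with patients cycling over sites so some
contribute two sites.

**What the generators do not emulate**: biophysical membrane dynamics,
electrode drift, stimulation artifacts beyond a blanked window, LFP
synthesis, multi-unit contamination, dystonia subtypes, and any
non-monotone severity relationships. Passing tests therefore demonstrate
that the estimators and statistics behave correctly under the stated
generative assumptions — not that real recordings satisfy those
assumptions.

## Validation problem sizes

The validation suite uses: exact-enumeration comparisons over all pooled
sample sizes ≤ 12; 600 permutation-test and 1000 MWU null simulations for
type-I calibration; 100 seeded runs for band assignment (30 s trains at
60 Hz, depth 0.5) and for LMM epoch-effect recovery (truth 5.42,
intercept SD 2, residual SD 2, 13 sites over 10 patients); a 2000-ISI
bimodal construction (modes 5 and 100 ms, ratio 20) for the burst index;
100 light cohorts for correlation recovery; and 20 full cohorts for
direction reproduction. Direction signs for the plasticity arm are read
from the cross-disease mixed-model fixed effects — the same statistic the
findings report — because per-site 5-point half-life fits are heavy-
tailed and a group-median readout is unstable at 12–13 sites per group.

## Known limitations

- The SNR definition, ISI refractory bound, fEP measurement window and
  BI mean convention are defensible defaults, not recoverable facts;
  results on real data will shift with these choices.
- The burst index inherits EM's sensitivity to heavy one-sided tails;
  the degeneracy guard reports 1 rather than an arbitrary split.
- MixedLM p-values use a between-cluster t approximation, which is still
  slightly anti-conservative in simulation (~0.085 at nominal 0.05 for
  13 sites / 10 patients); Kenward–Roger-type corrections are not
  available in the dependency stack.
- The permutation p-value is conservative under heavy rank ties (small
  samples), by construction of the add-one tie-inclusive count.
- Short-term fits use only the first five pulses of the first train;
  the remaining 195 pulses and trains 2–4 are carried in the data model
  but not modeled.
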