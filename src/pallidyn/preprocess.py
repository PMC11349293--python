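"""Raw-trace preprocessing and segment quality control.

Turns extracellular microelectrode traces into quality-controlled spike
segments.  Segments are band-pass filtered (300-3000 Hz), spikes are
detected by amplitude threshold and accepted by correlation with a
running mean template, and a segment is included in downstream analyses
only if it shows a signal-to-noise ratio above 4 and fewer than 1%
interspike-interval violations (strict inequalities on both).

SNR here is peak-to-peak amplitude of the mean spike template divided by
twice the standard deviation of the background noise, a common
microelectrode convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

#: QC inclusion thresholds (strict inequalities).
SNR_THRESHOLD = 4.0
ISI_VIOLATION_THRESHOLD = 0.01

#: Default absolute refractory period used to count ISI violations (ms).
DEFAULT_REFRACTORY_MS = 1.0

MIN_SAMPLING_RATE = 10_000.0


@dataclass
class RawTrace:
    """A single-channel extracellular voltage trace.

    Parameters
    ----------
    samples : ndarray
        Voltage samples in microvolts.
    sampling_rate : float
        Sampling rate in Hz; recordings are acquired at >= 10 kHz.
    patient_id : str
        Patient identifier.
    """

    samples: np.ndarray
    sampling_rate: float
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.sampling_rate < MIN_SAMPLING_RATE:
            raise ValueError(
                f"sampling_rate must be >= {MIN_SAMPLING_RATE} Hz, "
                f"got {self.sampling_rate}"
            )

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class WaveformSet:
    """Detected spike waveforms from one segment.

    ``waveforms`` is an (n_spikes, n_samples) matrix of extracted
    snippets (microvolts), ``spike_times`` the corresponding spike times
    in seconds (strictly ascending, aligned to the negative peak), and
    ``template`` the mean waveform.
    """

    waveforms: np.ndarray
    spike_times: np.ndarray
    template: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.waveforms = np.atleast_2d(np.asarray(self.waveforms, dtype=float))
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.waveforms.shape[0] != self.spike_times.size:
            raise ValueError("one spike time per waveform row required")
        if self.spike_times.size > 1 and not np.all(np.diff(self.spike_times) > 0):
            raise ValueError("spike_times must be strictly ascending")
        if self.template is None:
            self.template = (
                self.waveforms.mean(axis=0)
                if self.waveforms.size
                else np.zeros(self.waveforms.shape[1])
            )
        self.template = np.asarray(self.template, dtype=float)
        if self.template.size != self.waveforms.shape[1]:
            raise ValueError("template length must match waveform length")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass(frozen=True)
class QCMetrics:
    """Segment quality metrics and the resulting inclusion decision."""

    snr: float
    isi_violation_fraction: float

    @property
    def passed(self) -> bool:
        return (self.snr > SNR_THRESHOLD) and (
            self.isi_violation_fraction < ISI_VIOLATION_THRESHOLD
        )


def bandpass_filter(trace: RawTrace, lo: float = 300.0, hi: float = 3000.0,
                    order: int = 4) -> RawTrace:
    """Zero-phase band-pass filter (forward-backward Butterworth).

    Forward-backward application gives a zero-phase response, so spike
    times are not shifted by filtering.

    Parameters
    ----------
    trace : RawTrace
    lo, hi : float
        Corner frequencies in Hz; must satisfy 0 < lo < hi < Nyquist.
    order : int
        Butterworth order of the one-way filter (default 4).
    """
    nyq = trace.sampling_rate / 2.0
    if not (0.0 < lo < hi < nyq):
        raise ValueError(
            f"corner frequencies must satisfy 0 < lo < hi < {nyq} Hz "
            f"(got lo={lo}, hi={hi})"
        )
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=trace.sampling_rate,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, trace.samples)
    return RawTrace(filtered, trace.sampling_rate, trace.patient_id)


def _noise_sigma(x: np.ndarray) -> float:
    # Median-absolute-deviation estimate; robust to the spikes themselves.
    return float(np.median(np.abs(x - np.median(x))) / 0.6745)


def detect_spikes_template(trace: RawTrace, threshold_k: float = 4.0,
                           template_halfwidth_ms: float = 0.6,
                           min_correlation: float = 0.8,
                           n_refine: int = 2) -> WaveformSet:
    """Threshold-based spike detection with template-matching acceptance.

    Candidate events are negative threshold crossings at ``threshold_k``
    times the robust noise scale, aligned to their negative peak.  A mean
    template is formed from the candidates and events are accepted when
    their Pearson correlation with the running mean template reaches
    ``min_correlation``; the template is refined ``n_refine`` times from
    the accepted set.

    Returns a :class:`WaveformSet`; with no accepted events the waveform
    matrix is empty.
    """
    x = trace.samples
    half = int(round(template_halfwidth_ms * 1e-3 * trace.sampling_rate))
    if half < 1 or x.size < 2 * half + 1:
        raise ValueError("trace shorter than one template window")

    sigma = _noise_sigma(x)
    if sigma == 0.0:
        sigma = float(np.std(x)) or 1.0
    thresh = -threshold_k * sigma

    below = x < thresh
    if not below.any():
        return WaveformSet(np.empty((0, 2 * half + 1)), np.empty(0),
                           np.zeros(2 * half + 1))

    # Contiguous sub-threshold runs -> one candidate per run, at the minimum.
    padded = np.concatenate(([False], below, [False]))
    d = np.diff(padded.astype(int))
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)
    peaks = np.array([s + np.argmin(x[s:e]) for s, e in zip(run_starts, run_ends)])
    peaks = peaks[(peaks >= half) & (peaks < x.size - half)]
    if peaks.size == 0:
        return WaveformSet(np.empty((0, 2 * half + 1)), np.empty(0),
                           np.zeros(2 * half + 1))
    # Enforce a dead time of one template half-width between events.
    keep = [0]
    for i in range(1, peaks.size):
        if peaks[i] - peaks[keep[-1]] > half:
            keep.append(i)
    peaks = peaks[keep]

    wfs = np.stack([x[p - half:p + half + 1] for p in peaks])
    accepted = np.ones(peaks.size, dtype=bool)
    template = wfs.mean(axis=0)
    for _ in range(n_refine):
        t_c = template - template.mean()
        t_norm = np.linalg.norm(t_c)
        if t_norm == 0:
            break
        w_c = wfs - wfs.mean(axis=1, keepdims=True)
        w_norm = np.linalg.norm(w_c, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (w_c @ t_c) / (w_norm * t_norm)
        corr = np.nan_to_num(corr)
        accepted = corr >= min_correlation
        if not accepted.any():
            break
        template = wfs[accepted].mean(axis=0)

    wfs = wfs[accepted]
    times = peaks[accepted] / trace.sampling_rate
    if wfs.shape[0] == 0:
        return WaveformSet(np.empty((0, 2 * half + 1)), np.empty(0),
                           np.zeros(2 * half + 1))
    return WaveformSet(wfs, times, wfs.mean(axis=0))


def compute_snr(wf: WaveformSet, noise_samples: np.ndarray) -> float:
    """Signal-to-noise ratio of a waveform set.

    SNR = peak-to-peak(mean template) / (2 * SD(noise_samples)).
    """
    noise = np.asarray(noise_samples, dtype=float)
    if wf.n_spikes < 1:
        raise ValueError("need at least one waveform")
    if noise.size < 100:
        raise ValueError("need at least 100 noise samples")
    sd = float(np.std(noise))
    if sd == 0.0:
        raise ValueError("noise samples have zero variance")
    return float(np.ptp(wf.template) / (2.0 * sd))


def isi_violation_fraction(spike_times: np.ndarray,
                           refractory_ms: float = DEFAULT_REFRACTORY_MS) -> float:
    """Fraction of interspike intervals shorter than the refractory period."""
    t = np.asarray(spike_times, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 spikes")
    isis = np.diff(t)
    if np.any(isis < 0):
        raise ValueError("spike times must be ascending")
    return float(np.mean(isis < refractory_ms * 1e-3))


def qc_filter(snr: float, isi_violations: float) -> bool:
    """Segment inclusion decision: SNR > 4 and ISI violations < 1%.

    Both inequalities are strict; a segment at exactly the threshold is
    excluded.
    """
    return QCMetrics(snr, isi_violations).passed
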