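"""Traditional perturbation and periodicity measures.

Native implementations of glottal-cycle tracking, relative jitter (%),
shimmer (dB), the autocorrelation harmonics-to-noise ratio (HNR), and the
smoothed cepstral peak prominence (CPPS).  All four are deterministic
functions of the waveform.

Definitions
-----------
jitter (%)   : 100 * mean(|T_i - T_{i-1}|) / mean(T) over glottal periods T.
shimmer (dB) : mean(|20 log10(A_{i+1} / A_i)|) over cycle peak amplitudes A.
HNR (dB)     : 10 log10(r / (1 - r)) per voiced frame, where r is the peak of
               the normalized autocorrelation within the f0 lag range;
               averaged over voiced frames and clamped to [-10, 40] dB.
CPPS (dB)    : height of the cepstral peak in the f0 quefrency band above a
               regression line fitted to the smoothed cepstrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft
from scipy.ndimage import uniform_filter1d

from ..audio_io import Recording
from ..errors import InputError, InsufficientVoicingError

__all__ = [
    "CycleMarks",
    "track_cycles",
    "jitter_percent",
    "shimmer_db",
    "hnr_db",
    "cpps_db",
]

VOICING_THRESHOLD = 0.5  # minimum normalized autocorrelation peak for voicing
HNR_CLAMP = (-10.0, 40.0)


@dataclass
class CycleMarks:
    """Per-glottal-cycle period and peak-amplitude series."""

    periods: np.ndarray      # seconds, one per cycle
    amplitudes: np.ndarray   # dimensionless peak |amplitude|, one per cycle
    voiced_fraction: float   # proportion of analysis frames judged voiced

    def __post_init__(self):
        self.periods = np.asarray(self.periods, dtype=np.float64)
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        if len(self.periods) != len(self.amplitudes):
            raise InputError("periods and amplitudes must have equal length")
        if np.any(self.periods <= 0):
            raise InputError("periods must be positive")
        if np.any(self.amplitudes < 0):
            raise InputError("amplitudes must be non-negative")

    def __len__(self) -> int:
        return len(self.periods)


def _norm_autocorr_peak(frame: np.ndarray, lag_min: int, lag_max: int):
    """Peak of the length-normalized autocorrelation within [lag_min, lag_max].

    r(tau) = sum x[n] x[n+tau] / sqrt(sum_{0..N-tau} x^2 * sum_{tau..N} x^2),
    which is bounded by 1 (Cauchy-Schwarz) and robust to amplitude scale.
    Returns (r_peak, lag_refined) with parabolic sub-sample refinement.
    """
    x = frame - frame.mean()
    n = len(x)
    lag_max = min(lag_max, n - 2)
    if lag_max <= lag_min or np.allclose(x, 0):
        return 0.0, float(lag_min)
    nfft = next_fast_len(2 * n)
    spec = rfft(x, nfft)
    raw = irfft(spec * np.conj(spec), nfft)[: n]  # sum x[n] x[n+tau]
    csum = np.concatenate(([0.0], np.cumsum(x * x)))
    total = csum[-1]
    taus = np.arange(lag_min, lag_max + 1)
    head = csum[n - taus] - csum[0]        # sum_{0..n-tau-1} x^2
    tail = total - csum[taus]              # sum_{tau..n-1} x^2
    denom = np.sqrt(head * tail)
    denom[denom <= 0] = np.inf
    r = raw[taus] / denom
    # for a periodic signal every period multiple scores ~equally: prefer
    # the smallest lag among near-maximal local peaks (avoids subharmonics)
    k = int(np.argmax(r))
    if len(r) > 2:
        rmax = r[k]
        interior = (r[1:-1] >= r[:-2]) & (r[1:-1] >= r[2:]) & \
                   (r[1:-1] >= 0.9 * rmax)
        cand = np.nonzero(interior)[0]
        if len(cand):
            k = int(cand[0]) + 1
    r_pk = float(r[k])
    lag = float(taus[k])
    if 0 < k < len(r) - 1:  # parabolic interpolation around the peak
        a, b, c = r[k - 1], r[k], r[k + 1]
        denom2 = a - 2 * b + c
        if denom2 < 0:
            delta = 0.5 * (a - c) / denom2
            if abs(delta) < 1:
                lag += delta
                r_pk = float(b - 0.25 * (a - c) * delta)
    return min(r_pk, 1.0), lag


def _voiced_frames(rec: Recording, f0_min: float, f0_max: float):
    """Frame-wise (r_peak, lag) plus voicing decisions."""
    rate = rec.rate
    frame_len = int(round(4 * rate / f0_min))  # four longest candidate periods
    hop = frame_len // 2
    x = rec.samples
    if len(x) < frame_len:
        raise InputError("recording too short for f0 analysis")
    lag_min = max(2, int(np.floor(rate / f0_max)))
    lag_max = int(np.ceil(rate / f0_min))
    starts = range(0, len(x) - frame_len + 1, hop)
    peaks, lags = [], []
    for s in starts:
        r, lag = _norm_autocorr_peak(x[s:s + frame_len], lag_min, lag_max)
        peaks.append(r)
        lags.append(lag)
    peaks = np.array(peaks)
    lags = np.array(lags)
    voiced = peaks > VOICING_THRESHOLD
    return peaks, lags, voiced


def track_cycles(rec: Recording, f0_min: float = 60.0,
                 f0_max: float = 400.0) -> CycleMarks:
    """Locate glottal cycles and measure per-cycle periods and amplitudes.

    Frame-wise f0 comes from the autocorrelation peak within the candidate
    lag range; cycle boundaries are then found by picking one waveform peak
    per estimated period, and each period is refined to sub-sample precision
    by cross-correlating neighbouring cycles.  Unvoiced input yields empty
    marks with ``voiced_fraction < 0.5``.
    """
    if rec.duration_s < 0.5:
        raise InputError("need at least 0.5 s of audio to track cycles")
    peaks, lags, voiced = _voiced_frames(rec, f0_min, f0_max)
    voiced_fraction = float(voiced.mean()) if len(voiced) else 0.0
    if voiced_fraction < 0.5:
        return CycleMarks(np.empty(0), np.empty(0), voiced_fraction)

    rate = rec.rate
    t0 = float(np.median(lags[voiced]))  # samples per period
    x = rec.samples - np.mean(rec.samples)

    # octave check: cycle-alternating perturbations (period-2 patterns) can
    # make the lag-2T0 autocorrelation edge out the true period; prefer the
    # half lag when it explains the signal almost as well
    half = t0 / 2.0
    if half >= max(2.0, rate / 500.0):
        lo, hi = int(half) - 3, int(half) + 4
        r_half, lag_half = _norm_autocorr_peak(x, max(lo, 2), hi)
        r_full, _ = _norm_autocorr_peak(x, int(t0) - 3, int(t0) + 4)
        if r_half >= 0.9 * r_full:
            t0 = lag_half
    s = x if np.max(x) >= np.max(-x) else -x  # analyse dominant polarity

    # one peak per period, marching outward from the global maximum
    anchor = int(np.argmax(s))
    peaks_idx = [anchor]
    p = anchor
    while True:
        lo, hi = int(p + 0.7 * t0), int(p + 1.3 * t0) + 1
        if hi > len(s):
            break
        p = lo + int(np.argmax(s[lo:hi]))
        peaks_idx.append(p)
    p = anchor
    while True:
        lo, hi = int(p - 1.3 * t0), int(p - 0.7 * t0) + 1
        if lo < 0:
            break
        p = lo + int(np.argmax(s[lo:hi]))
        peaks_idx.insert(0, p)
    peaks_idx = np.array(sorted(peaks_idx))
    if len(peaks_idx) < 2:
        return CycleMarks(np.empty(0), np.empty(0), voiced_fraction)

    # sub-sample period refinement by cross-correlating neighbouring cycles;
    # the window spans a whole period so additive noise averages out
    w = int(0.48 * t0)
    periods = []
    for p0, p1 in zip(peaks_idx[:-1], peaks_idx[1:]):
        lag0 = p1 - p0
        best_lag = float(lag0)
        if p0 - w >= 0 and p1 + w + 2 < len(s):
            a = x[p0 - w:p0 + w + 1]
            cc = []
            for d in (-2, -1, 0, 1, 2):
                b = x[p1 - w + d:p1 + w + 1 + d]
                cc.append(float(np.dot(a, b)))
            cc = np.array(cc)
            k = int(np.argmax(cc))
            best_lag = lag0 + (k - 2)
            if 0 < k < 4:
                den = cc[k - 1] - 2 * cc[k] + cc[k + 1]
                if den < 0:
                    best_lag += 0.5 * (cc[k - 1] - cc[k + 1]) / den
        periods.append(best_lag / rate)

    # per-cycle peak amplitude with parabolic refinement
    amps = []
    for p0 in peaks_idx[:-1]:
        a = float(s[p0])
        if 0 < p0 < len(s) - 1:
            l, c, r_ = s[p0 - 1], s[p0], s[p0 + 1]
            den = l - 2 * c + r_
            if den < 0:
                delta = 0.5 * (l - r_) / den
                a = float(c - 0.25 * (l - r_) * delta)
        amps.append(max(a, 0.0))

    periods = np.array(periods)
    amps = np.array(amps)
    if len(periods) > 4:  # trim onset/offset cycles (filter transients)
        periods, amps = periods[1:-1], amps[1:-1]
    return CycleMarks(periods, amps, voiced_fraction)


def jitter_percent(marks: CycleMarks) -> float:
    """Relative jitter: 100 * mean absolute period difference / mean period."""
    if len(marks) < 3:
        raise InsufficientVoicingError("need at least 3 cycles for jitter")
    t = marks.periods
    return float(100.0 * np.mean(np.abs(np.diff(t))) / np.mean(t))


def shimmer_db(marks: CycleMarks) -> float:
    """Shimmer: mean absolute dB ratio of consecutive cycle peak amplitudes."""
    if len(marks) < 3:
        raise InsufficientVoicingError("need at least 3 cycles for shimmer")
    a = marks.amplitudes
    ok = (a[:-1] > 0) & (a[1:] > 0)
    if not np.all(ok):
        warnings.warn("zero-amplitude cycles excluded from shimmer")
    if not np.any(ok):
        raise InsufficientVoicingError("no usable amplitude pairs")
    ratios = 20.0 * np.log10(a[1:][ok] / a[:-1][ok])
    return float(np.mean(np.abs(ratios)))


def hnr_db(rec: Recording, f0_min: float = 60.0, f0_max: float = 400.0) -> float:
    """Harmonics-to-noise ratio in dB from the frame autocorrelation peak.

    The normalized autocorrelation peak r estimates the fraction of frame
    power that is periodic, so 10 log10(r / (1 - r)) is the per-frame dB
    ratio of periodic to aperiodic power.  Frames and the recording value
    are clamped to [-10, 40] dB.
    """
    peaks, _, voiced = _voiced_frames(rec, f0_min, f0_max)
    if not np.any(voiced):
        raise InsufficientVoicingError("no voiced frames for HNR")
    r = np.clip(peaks[voiced], 1e-9, 1 - 1e-9)
    frame_hnr = np.clip(10.0 * np.log10(r / (1.0 - r)), *HNR_CLAMP)
    return float(np.clip(np.mean(frame_hnr), *HNR_CLAMP))


def cpps_db(rec: Recording, f0_min: float = 60.0, f0_max: float = 400.0,
            frame_len: int = 1024, hop_ms: float = 2.0,
            time_smooth: int = 10, quef_smooth: int = 10) -> float:
    """Smoothed cepstral peak prominence in dB.

    Frame-wise real cepstra of the dB log-magnitude spectrum are averaged
    over ``time_smooth`` frames and ``quef_smooth`` quefrency bins; per
    smoothed frame the peak within the f0 quefrency band is measured against
    a least-squares line fitted over quefrencies from 1 ms to the maximum
    lag, and the prominences are averaged over frames.  Invariant to global
    amplitude scaling (a gain shifts only the zero-quefrency bin).
    """
    if rec.duration_s < 1.0:
        raise InputError("need at least 1 s of audio for CPPS")
    rate = rec.rate
    hop = max(1, int(round(hop_ms * 1e-3 * rate)))
    x = rec.samples
    if len(x) < frame_len:
        raise InputError("recording shorter than the CPPS frame length")
    n_frames = (len(x) - frame_len) // hop + 1
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * np.hamming(frame_len)
    spec_db = 20.0 * np.log10(np.abs(rfft(frames, axis=1)) + 1e-12)
    # power cepstrum of the dB spectrum, smoothed in the linear domain,
    # then expressed in dB for the peak-vs-trend measurement
    ceps = irfft(spec_db, axis=1)[:, : frame_len // 2 + 1] ** 2
    ceps = uniform_filter1d(ceps, size=time_smooth, axis=0, mode="nearest")
    ceps = uniform_filter1d(ceps, size=quef_smooth, axis=1, mode="nearest")
    ceps = 10.0 * np.log10(ceps + 1e-12)

    q_lo = int(np.ceil(rate / f0_max))
    q_hi = int(np.floor(rate / f0_min))
    q_hi = min(q_hi, ceps.shape[1] - 1)
    reg_lo = int(round(1e-3 * rate))
    quefs = np.arange(reg_lo, ceps.shape[1])

    # per-frame least-squares trend line over the regression quefrencies
    y = ceps[:, reg_lo:]
    qmean = quefs.mean()
    qvar = np.mean((quefs - qmean) ** 2)
    slope = (y @ (quefs - qmean)) / (len(quefs) * qvar)
    intercept = y.mean(axis=1) - slope * qmean

    band = ceps[:, q_lo:q_hi + 1]
    pk = np.argmax(band, axis=1) + q_lo
    peak_val = band[np.arange(len(band)), pk - q_lo]
    trend = intercept + slope * pk
    return float(np.mean(peak_val - trend))
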