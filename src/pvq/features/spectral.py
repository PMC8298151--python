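"""Filterbank cepstral (GFCC) and linear-prediction statistical (LCQA) features.

GFCC: frame power spectra are weighted by a 128-channel ERB-spaced
Gammatone filterbank, log-compressed and decorrelated by an orthonormal
DCT-II; frame-averaged static cepstra c1..c30 and their first-order time
differences give the 60-dimensional feature vector.

LCQA: per 20 ms non-overlapping frame, an 18th-order LP model (autocorrelation
method, Levinson recursion) yields five descriptors — spectral flatness,
excitation variance, signal variance, spectral centroid and spectral
dynamics — plus their first time-derivatives; the mean, variance, skew and
kurtosis of each of the 10 per-frame series form the 40-dimensional vector.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.fft import rfft
from scipy.fft import dct as _dct
from scipy.linalg import solve_toeplitz
from scipy.stats import kurtosis, skew

from ..audio_io import Recording, frame_signal
from ..errors import InputError

__all__ = [
    "erb_space",
    "gammatone_weights",
    "gfcc_features",
    "lp_frame",
    "lcqa_features",
    "GFCC_NAMES",
    "LCQA_NAMES",
]

GFCC_NAMES = [f"gfcc_{i:02d}" for i in range(1, 31)] + \
             [f"dgfcc_{i:02d}" for i in range(1, 31)]

_LCQA_DESCRIPTORS = ["flatness", "excitation_var", "signal_var",
                     "centroid", "dynamics"]
_LCQA_STATS = ["mean", "var", "skew", "kurt"]
# canonical order: descriptors then their deltas, 4 stats each -> lcqa_01..40
LCQA_NAMES = [f"lcqa_{i:02d}" for i in range(1, 41)]
LCQA_LONG_NAMES = [f"{d}_{s}" for d in _LCQA_DESCRIPTORS +
                   [f"d_{d}" for d in _LCQA_DESCRIPTORS] for s in _LCQA_STATS]


# ---------------------------------------------------------------------------
# Gammatone / ERB filterbank cepstra
# ---------------------------------------------------------------------------

def _hz_to_erb_number(f):
    return 21.4 * np.log10(1.0 + 4.37e-3 * f)


def _erb_number_to_hz(e):
    return (10.0 ** (e / 21.4) - 1.0) / 4.37e-3


def erb_space(fmin: float, fmax: float, n: int) -> np.ndarray:
    """n centre frequencies equally spaced on the ERB-number scale."""
    return _erb_number_to_hz(np.linspace(_hz_to_erb_number(fmin),
                                         _hz_to_erb_number(fmax), n))


def gammatone_weights(freqs: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """(n_filters, n_bins) squared-magnitude responses of 4th-order gammatones.

    |H(f)|^2 = [1 + ((f - fc) / b)^2]^(-4) with b = 1.019 * ERB(fc),
    peak-normalized per filter.
    """
    erb = 24.7 * (1.0 + 4.37e-3 * centers)
    b = 1.019 * erb
    x = (freqs[None, :] - centers[:, None]) / b[:, None]
    return (1.0 + x * x) ** -4


def gfcc_features(rec: Recording, n_filters: int = 128, n_cep: int = 30,
                  fmin: float = 50.0, fmax: float = None,
                  frame_len: int = 256, hop: int = 156) -> pd.Series:
    """60 Gammatone-filterbank cepstral features (30 statics + 30 deltas).

    Coefficient 0 (frame energy) is excluded; the statics are the frame
    averages of c1..c30 and the deltas the frame averages of their
    first-order time differences.
    """
    if rec.duration_s < 1.0:
        raise InputError("need at least 1 s of audio for GFCC")
    fmax = fmax or rec.rate / 2.0
    frames = frame_signal(rec, frame_len, hop, "hamming").frames
    power = np.abs(rfft(frames, axis=1)) ** 2
    freqs = np.fft.rfftfreq(frame_len, 1.0 / rec.rate)
    centers = erb_space(fmin, fmax, n_filters)
    fb = gammatone_weights(freqs, centers)
    energies = power @ fb.T
    if np.all(energies == 0):
        warnings.warn("silent input: filterbank energies floored")
    log_e = np.log(np.maximum(energies, 1e-10))
    cep = _dct(log_e, type=2, norm="ortho", axis=1)
    statics = cep[:, 1:n_cep + 1]
    deltas = np.diff(statics, axis=0)
    static_mean = statics.mean(axis=0)
    delta_mean = deltas.mean(axis=0) if len(deltas) else np.zeros(n_cep)
    values = np.concatenate([static_mean, delta_mean])
    names = [f"gfcc_{i:02d}" for i in range(1, n_cep + 1)] + \
            [f"dgfcc_{i:02d}" for i in range(1, n_cep + 1)]
    return pd.Series(values, index=names)


# ---------------------------------------------------------------------------
# LP-based LCQA features
# ---------------------------------------------------------------------------

def lp_frame(frame: np.ndarray, order: int = 18):
    """LP coefficients and residual power via the autocorrelation method.

    Solves the normal equations with the Levinson recursion
    (scipy.linalg.solve_toeplitz) and applies a light bandwidth expansion
    (gamma = 0.996) so the synthesis filter is safely stable.
    Returns ``(a, excitation_variance, frame_variance)`` with prediction
    polynomial A(z) = 1 - sum a_k z^-k.
    """
    x = np.asarray(frame, float)
    n = len(x)
    if n <= order:
        raise InputError("frame shorter than LP order")
    r = np.correlate(x, x, mode="full")[n - 1:n + order]
    frame_var = r[0] / n
    if r[0] <= 0:
        raise InputError("zero-energy frame")
    r = r / n
    r0 = r[0] * (1.0 + 1e-9)
    a = solve_toeplitz((np.r_[r0, r[1:order]], np.r_[r0, r[1:order]]), r[1:])
    exc_var = float(r0 - a @ r[1:])
    exc_var = max(exc_var, 1e-15 * r0)
    gamma = 0.996
    a = a * gamma ** np.arange(1, order + 1)
    return a, exc_var, float(frame_var)


def _lp_spectrum(a, exc_var, nfft=1024):
    """One-sided LP model power spectrum on an nfft/2-bin grid."""
    poly = np.r_[1.0, -a]
    A = rfft(poly, nfft)[: nfft // 2]
    return exc_var / np.maximum(np.abs(A) ** 2, 1e-30)


def _stats(v: np.ndarray) -> list:
    """mean, population variance, Fisher skew, excess kurtosis."""
    return [float(np.mean(v)), float(np.var(v)),
            float(skew(v)), float(kurtosis(v))]


def lcqa_features(rec: Recording, order: int = 18, frame_ms: float = 20.0,
                  nfft: int = 1024) -> pd.Series:
    """40 LP-derived statistical features (lcqa_01..lcqa_40).

    Ordering: for each per-frame descriptor in (spectral flatness,
    excitation variance, signal variance, spectral centroid, spectral
    dynamics) followed by its first time-derivative, the statistics (mean,
    variance, skew, kurtosis) are appended in turn.
    """
    if rec.duration_s < 1.0:
        raise InputError("need at least 1 s of audio for LCQA")
    flen = int(round(frame_ms * 1e-3 * rec.rate))
    x = rec.samples
    n_frames = len(x) // flen
    freqs = np.fft.rfftfreq(nfft, 1.0 / rec.rate)[: nfft // 2]
    rows = []
    skipped = 0
    prev_log_s = None
    for i in range(n_frames):
        frame = x[i * flen:(i + 1) * flen]
        power = float(np.mean(frame ** 2))
        if power < 1e-14:
            skipped += 1
            continue
        a, exc_var, frame_var = lp_frame(frame, order)
        s = _lp_spectrum(a, exc_var, nfft)
        log_s = np.log(s)
        flatness = float(np.exp(np.mean(log_s)) / np.mean(s))
        centroid = float(np.sum(freqs * s) / np.sum(s))
        dynamics = (float(np.mean((log_s - prev_log_s) ** 2))
                    if prev_log_s is not None else np.nan)
        prev_log_s = log_s
        rows.append([flatness, exc_var, frame_var, centroid, dynamics])
    if skipped:
        warnings.warn(f"{skipped} zero-energy frames skipped")
    if len(rows) < 10:
        raise InputError("fewer than 10 usable frames for LCQA")
    d = np.asarray(rows)
    d[0, 4] = d[1, 4]  # dynamics assigned to the later frame; backfill frame 0
    deltas = np.diff(d, axis=0)
    deltas = np.vstack([deltas[0], deltas])  # replicate first delta
    per_frame = np.hstack([d, deltas])       # 10 descriptors per frame
    values = []
    for j in range(per_frame.shape[1]):
        values.extend(_stats(per_frame[:, j]))
    return pd.Series(values, index=LCQA_NAMES)
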