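"""Modulation-envelope metrics: SRMR and ModA.

SRMR passes the signal through a 23-channel ERB-spaced Gammatone filterbank
(125 Hz to the Nyquist frequency), extracts each channel's temporal envelope
as the analytic-signal magnitude, resamples the envelopes to 256 Hz, and
integrates their power over 8 overlapping modulation bands log-spaced from
4 to 128 Hz.  SRMR is the energy in modulation bands 1-4 over the energy in
bands 5-8.

ModA decomposes the signal into 4 octave-wide acoustic bands (300-4800 Hz),
downsamples each band envelope to 20 Hz, normalizes it to modulation depth
(so the metric reflects envelope shape, not loudness), integrates its
modulation spectrum over 11 third-octave-wide bands spanning 0.5-8 Hz, and
averages the per-band areas taken on a log-frequency axis.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.fft import fft, ifft, next_fast_len, rfft
from scipy.signal import resample_poly

from ..audio_io import Recording
from ..errors import InputError
from .spectral import erb_space, gammatone_weights

__all__ = ["srmr", "moda", "modulation_energy_grid"]

_EPS = 1e-10


def _band_envelopes(x: np.ndarray, rate: int, weights: np.ndarray) -> np.ndarray:
    """Envelopes of zero-phase filtered bands via the analytic signal.

    ``weights`` holds per-band squared-magnitude responses on the rfft grid;
    the analytic band signal is built directly from the one-sided spectrum.
    """
    n = len(x)
    nfft = next_fast_len(n)
    spec = np.fft.rfft(x, nfft)
    h = np.sqrt(weights)  # magnitude response
    envs = np.empty((len(h), n))
    for k in range(len(h)):
        full = np.zeros(nfft, dtype=complex)
        one_sided = spec * h[k]
        full[: len(one_sided)] = 2.0 * one_sided
        full[0] *= 0.5
        if nfft % 2 == 0:
            full[nfft // 2] *= 0.5
        envs[k] = np.abs(ifft(full)[:n])
    return envs


def _mod_band_weights(freqs: np.ndarray, centers: np.ndarray,
                      q: float = 2.0) -> np.ndarray:
    """Squared magnitudes of 2nd-order bandpass filters (unit peak, Q=2)."""
    w = np.zeros((len(centers), len(freqs)))
    nz = freqs > 0
    for j, fc in enumerate(centers):
        x = q * (freqs[nz] / fc - fc / freqs[nz])
        w[j, nz] = 1.0 / (1.0 + x * x)
    return w


def modulation_energy_grid(rec: Recording, n_channels: int = 23,
                           fmin: float = 125.0, env_rate: int = 256,
                           mod_fmin: float = 4.0, mod_fmax: float = 128.0,
                           n_mod_bands: int = 8) -> np.ndarray:
    """Acoustic-band x modulation-band energy matrix used by SRMR."""
    x = rec.samples - np.mean(rec.samples)
    centers = erb_space(fmin, rec.rate / 2.0, n_channels)
    freqs = np.fft.rfftfreq(next_fast_len(len(x)), 1.0 / rec.rate)
    weights = gammatone_weights(freqs, centers)
    envs = _band_envelopes(x, rec.rate, weights)
    # envelope frequencies range 0..128 Hz -> resample to 256 Hz
    up, down = env_rate, rec.rate
    g = np.gcd(up, down)
    envs = resample_poly(envs, up // g, down // g, axis=1)
    mod_centers = mod_fmin * (mod_fmax / mod_fmin) ** (
        np.arange(n_mod_bands) / (n_mod_bands - 1))
    nfft = next_fast_len(envs.shape[1])
    mfreqs = np.fft.rfftfreq(nfft, 1.0 / env_rate)
    mw = _mod_band_weights(mfreqs, mod_centers)
    env_spec = np.abs(rfft(envs - envs.mean(axis=1, keepdims=True),
                           nfft, axis=1)) ** 2
    grid = env_spec @ mw.T  # (n_channels, n_mod_bands)
    return np.maximum(grid, 0.0)


def srmr(rec: Recording, n_channels: int = 23, fmin: float = 125.0,
         env_rate: int = 256, mod_fmin: float = 4.0, mod_fmax: float = 128.0,
         n_mod_bands: int = 8) -> float:
    """Speech-to-reverberation modulation energy ratio.

    Ratio of total modulation energy in the low bands (1-4) to the high
    bands (5-8); exactly invariant to global gain.  Silent input returns 0
    with a warning.
    """
    if rec.duration_s < 1.0:
        raise InputError("need at least 1 s of audio for SRMR")
    if not np.any(rec.samples - np.mean(rec.samples)):
        warnings.warn("silent input: SRMR = 0")
        return 0.0
    grid = modulation_energy_grid(rec, n_channels, fmin, env_rate,
                                  mod_fmin, mod_fmax, n_mod_bands)
    half = n_mod_bands // 2
    num = float(grid[:, :half].sum())
    den = float(grid[:, half:].sum())
    return num / max(den, _EPS)


def moda(rec: Recording,
         band_edges=((300.0, 600.0), (600.0, 1200.0),
                     (1200.0, 2400.0), (2400.0, 4800.0)),
         env_rate: int = 20, mod_fmin: float = 0.5, mod_fmax: float = 8.0,
         n_centers: int = 11) -> float:
    """Modulation area: mean area under the low-frequency modulation spectrum.

    Per acoustic band the 20 Hz envelope is normalized by its mean (so gain
    cancels), its modulation spectrum is integrated over third-octave-wide
    bands at ``n_centers`` log-spaced centres in [0.5, 8] Hz, and the area
    is the trapezoidal integral of those band energies over log2 frequency.
    """
    if rec.duration_s < 1.0:
        raise InputError("need at least 1 s of audio for ModA")
    x = rec.samples - np.mean(rec.samples)
    if not np.any(x):
        warnings.warn("silent input: ModA = 0")
        return 0.0
    n = len(x)
    nfft = next_fast_len(n)
    freqs = np.fft.rfftfreq(nfft, 1.0 / rec.rate)
    weights = np.stack([
        1.0 / (1.0 + (freqs / hi) ** 8) *
        np.where(freqs > 0, 1.0 / (1.0 + (lo / np.maximum(freqs, 1e-6)) ** 8), 0.0)
        for lo, hi in band_edges])
    envs = _band_envelopes(x, rec.rate, weights)
    g = np.gcd(env_rate, rec.rate)
    envs = resample_poly(envs, env_rate // g, rec.rate // g, axis=1)

    centers = np.geomspace(mod_fmin, mod_fmax, n_centers)
    lo_edges, hi_edges = centers / 2 ** (1 / 6), centers * 2 ** (1 / 6)
    pad = 512  # zero-padded spectrum for sub-bin band integration
    mfreqs = np.fft.rfftfreq(pad, 1.0 / env_rate)
    areas = []
    for env in envs:
        mu = env.mean()
        if mu <= _EPS:
            areas.append(0.0)
            continue
        depth = env / mu - 1.0
        spec = np.abs(rfft(depth, pad)) ** 2 / len(depth)
        energies = np.array([
            spec[(mfreqs >= lo) & (mfreqs < hi)].sum()
            for lo, hi in zip(lo_edges, hi_edges)])
        areas.append(float(np.trapezoid(energies, np.log2(centers))))
    return float(np.mean(areas))
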