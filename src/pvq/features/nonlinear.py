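"""Recurrence period density entropy (RPDE).

The signal is embedded in a time-delay phase space; for each reference point
the time of the first return into a ball of fixed radius — after first
leaving it — is recorded (close-returns semantics, which suppresses trivial
T = 1 mass from points lingering inside the ball).  The normalized Shannon
entropy of the recurrence-period density is near 0 for perfectly periodic
signals and near 1 for aperiodic ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from ..audio_io import Recording
from ..errors import InputError

__all__ = ["RpdeResult", "rpde"]


@dataclass
class RpdeResult:
    """Normalized recurrence-period entropy with its density and parameters."""

    H_norm: float
    density: np.ndarray   # probability mass over T = 1..t_max
    T_max: int
    embed_dim: int
    delay: int
    radius: float

    def __post_init__(self):
        if not 0.0 <= self.H_norm <= 1.0:
            raise InputError("H_norm outside [0, 1]")


@njit(cache=True)
def _recurrence_histogram(emb, r2, stride, t_max):  # pragma: no cover
    n = emb.shape[0]
    dim = emb.shape[1]
    counts = np.zeros(t_max + 1)
    for i in range(0, n, stride):
        exited = False
        jmax = min(n, i + t_max + 1)
        for j in range(i + 1, jmax):
            d2 = 0.0
            for k in range(dim):
                diff = emb[j, k] - emb[i, k]
                d2 += diff * diff
            if not exited:
                if d2 > r2:
                    exited = True
            elif d2 <= r2:
                counts[j - i] += 1.0
                break
    return counts


def rpde(rec: Recording, embed_dim: int = 4, delay: int = 35,
         radius: float = 0.12, t_max: int = 1000,
         stride: int = 2) -> RpdeResult:
    """Recurrence period density entropy of a recording.

    The signal is normalized to unit peak amplitude (the usual convention
    in voice analysis), so ``radius`` is expressed relative to the peak and
    the result is invariant to global amplitude scaling.  Reference points
    are subsampled by ``stride`` when the recording is 2 s or longer.  If
    no recurrences are found, H_norm = 1 by convention.
    """
    x = np.asarray(rec.samples, float)
    x = x - np.mean(x)
    peak = np.max(np.abs(x))
    if peak == 0:
        raise InputError("constant signal: RPDE undefined")
    x = x / peak
    n_emb = len(x) - (embed_dim - 1) * delay
    if n_emb < t_max:
        raise InputError("recording too short for the requested embedding")
    emb = np.empty((n_emb, embed_dim))
    for k in range(embed_dim):
        emb[:, k] = x[k * delay:k * delay + n_emb]
    eff_stride = stride if rec.duration_s >= 2.0 else 1
    counts = _recurrence_histogram(emb, radius * radius, eff_stride, t_max)
    total = counts[1:].sum()
    if total == 0:
        warnings.warn("no recurrences found: H_norm = 1 by convention")
        density = np.full(t_max, 1.0 / t_max)
        return RpdeResult(1.0, density, t_max, embed_dim, delay, radius)
    density = counts[1:] / total
    nz = density[density > 0]
    h = float(-np.sum(nz * np.log(nz)))
    h_norm = min(h / np.log(t_max), 1.0)
    return RpdeResult(h_norm, density, t_max, embed_dim, delay, radius)
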