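"""Pipeline configuration.

Every numeric constant that the extraction and modelling stages depend on is
collected in :class:`PipelineConfig` so a run can be reproduced from a single
serialized document.  Defaults follow the standard analysis protocol for
sustained vowels: 256-sample frames with 100-sample overlap for the filterbank
cepstral features, a 128-channel ERB-spaced Gammatone filterbank, an 18th-order
linear-prediction model on 20 ms frames, a 23-channel auditory filterbank with
4-128 Hz modulation bands for SRMR, a 95% variance threshold for PCA, and an
80/20 train/test split.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .errors import InputError


@dataclass
class PipelineConfig:
    # -- audio / framing -------------------------------------------------
    target_rate: int = 16000          # Hz, analysis sample rate
    segment_s: float = 2.0            # s, mid-vowel segment length
    frame_len: int = 256              # samples, filterbank cepstral framing
    frame_overlap: int = 100          # samples; hop = frame_len - frame_overlap
    window_name: str = "hamming"

    # -- f0 search range (covers adult male and female voices) ----------
    f0_min: float = 60.0              # Hz
    f0_max: float = 400.0             # Hz

    # -- Gammatone filterbank cepstra -----------------------------------
    n_erb_filters: int = 128
    gfcc_fmin: float = 50.0           # Hz
    gfcc_fmax: float = 8000.0         # Hz
    n_gfcc: int = 30                  # static cepstra kept (c1..c30); + deltas = 60

    # -- LP-based (LCQA) features ---------------------------------------
    lp_order: int = 18
    lcqa_frame_ms: float = 20.0       # ms, non-overlapping
    lcqa_nfft: int = 1024             # -> 512-bin one-sided LP spectrum grid

    # -- smoothed cepstral peak prominence ------------------------------
    cpps_frame_len: int = 1024        # samples
    cpps_hop_ms: float = 2.0          # ms
    cpps_time_smooth: int = 10        # frames
    cpps_quef_smooth: int = 10        # bins

    # -- modulation metrics ---------------------------------------------
    srmr_n_channels: int = 23
    srmr_fmin: float = 125.0          # Hz; top channel at rate/2
    envelope_rate: int = 256          # Hz, envelope resampling rate
    mod_fmin: float = 4.0             # Hz, lowest modulation band centre
    mod_fmax: float = 128.0           # Hz, highest modulation band centre
    n_mod_bands: int = 8
    moda_band_edges: tuple = ((300.0, 600.0), (600.0, 1200.0),
                              (1200.0, 2400.0), (2400.0, 4800.0))
    moda_env_rate: int = 20           # Hz
    moda_n_centers: int = 11          # modulation centres spanning 0.5-8 Hz

    # -- recurrence period density entropy ------------------------------
    rpde_dim: int = 4
    rpde_delay: int = 35              # samples (~2.2 ms at 16 kHz)
    rpde_radius: float = 0.12         # in units of the signal SD
    rpde_tmax: int = 1000             # samples
    rpde_stride: int = 2              # reference-point subsampling for long input

    # -- modelling -------------------------------------------------------
    test_frac: float = 0.2
    pca_threshold: float = 0.95
    mc_iters: int = 2000
    mc_inner_val_frac: float = 0.25
    mc_inner_splits: int = 10
    svr_c: float = 10.0
    svr_epsilon: float = 1.0          # VAS units

    @property
    def frame_hop(self) -> int:
        return self.frame_len - self.frame_overlap

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["moda_band_edges"] = [list(e) for e in self.moda_band_edges]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "moda_band_edges" in d:
            d["moda_band_edges"] = tuple(tuple(e) for e in d["moda_band_edges"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the full configuration, for provenance blocks."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


DEFAULT_CONFIG = PipelineConfig()
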