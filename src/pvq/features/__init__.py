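"""Acoustic feature families for sustained-vowel quality estimation.

Families and their column counts: ``traditional`` (jitter_pct, shimmer_db,
hnr_db, cpps_db), ``gfcc`` (60), ``lcqa`` (40), ``srmr`` (1), ``moda`` (1),
``rpde`` (1) — 107 columns in total.
"""

from __future__ import annotations

import pandas as pd

from ..audio_io import Recording
from ..config import DEFAULT_CONFIG, PipelineConfig
from ..errors import InputError, InsufficientVoicingError
from .modulation import moda, srmr
from .nonlinear import RpdeResult, rpde
from .spectral import GFCC_NAMES, LCQA_NAMES, gfcc_features, lcqa_features
from .traditional import (CycleMarks, cpps_db, hnr_db, jitter_percent,
                          shimmer_db, track_cycles)

ALL_FAMILIES = ("traditional", "gfcc", "lcqa", "srmr", "moda", "rpde")

__all__ = [
    "ALL_FAMILIES",
    "extract_features",
    "extract_table",
    "CycleMarks", "track_cycles", "jitter_percent", "shimmer_db",
    "hnr_db", "cpps_db", "gfcc_features", "lcqa_features",
    "srmr", "moda", "rpde", "RpdeResult",
]


def extract_features(rec: Recording, families=ALL_FAMILIES,
                     config: PipelineConfig = None) -> pd.Series:
    """Extract the requested feature families from one recording."""
    cfg = config or DEFAULT_CONFIG
    parts = []
    for fam in families:
        if fam == "traditional":
            marks = track_cycles(rec, cfg.f0_min, cfg.f0_max)
            parts.append(pd.Series({
                "jitter_pct": jitter_percent(marks),
                "shimmer_db": shimmer_db(marks),
                "hnr_db": hnr_db(rec, cfg.f0_min, cfg.f0_max),
                "cpps_db": cpps_db(rec, cfg.f0_min, cfg.f0_max,
                                   cfg.cpps_frame_len, cfg.cpps_hop_ms,
                                   cfg.cpps_time_smooth, cfg.cpps_quef_smooth),
            }))
        elif fam == "gfcc":
            parts.append(gfcc_features(
                rec, cfg.n_erb_filters, cfg.n_gfcc, cfg.gfcc_fmin,
                cfg.gfcc_fmax, cfg.frame_len, cfg.frame_hop))
        elif fam == "lcqa":
            parts.append(lcqa_features(rec, cfg.lp_order, cfg.lcqa_frame_ms,
                                       cfg.lcqa_nfft))
        elif fam == "srmr":
            parts.append(pd.Series({"srmr": srmr(
                rec, cfg.srmr_n_channels, cfg.srmr_fmin, cfg.envelope_rate,
                cfg.mod_fmin, cfg.mod_fmax, cfg.n_mod_bands)}))
        elif fam == "moda":
            parts.append(pd.Series({"moda": moda(
                rec, cfg.moda_band_edges, cfg.moda_env_rate,
                n_centers=cfg.moda_n_centers)}))
        elif fam == "rpde":
            parts.append(pd.Series({"rpde": rpde(
                rec, cfg.rpde_dim, cfg.rpde_delay, cfg.rpde_radius,
                cfg.rpde_tmax, cfg.rpde_stride).H_norm}))
        else:
            raise InputError(f"unknown feature family: {fam}")
    return pd.concat(parts)


def extract_table(recordings, families=ALL_FAMILIES, config=None,
                  on_error: str = "drop"):
    """Extract a feature table from many recordings.

    Returns ``(DataFrame indexed by source_id, drop_manifest)`` where the
    manifest lists recordings whose extraction failed (when
    ``on_error='drop'``; with ``'raise'`` the error propagates).
    """
    rows, dropped = {}, {}
    for rec in recordings:
        try:
            rows[rec.source_id] = extract_features(rec, families, config)
        except Exception as exc:
            if on_error == "raise":
                raise
            dropped[rec.source_id] = str(exc)
    df = pd.DataFrame(rows).T
    df.index.name = "source_id"
    return df, dropped
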