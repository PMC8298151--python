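"""Shared fixtures: synthetic vowels, ladders, and the default cohort."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import pvq
from pvq.audio_io import Recording
from pvq.features import extract_table

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

HNR_LADDER = (5.0, 10.0, 20.0, 30.0)
JITTER_LADDER = (0.25, 0.5, 1.0, 2.0)


@pytest.fixture(scope="session")
def clean_vowel():
    """Noiseless, unperturbed 150 Hz vowel (2 s at 16 kHz)."""
    rec, marks = pvq.synth_vowel(pvq.SynthesisSpec(f0=150.0, hnr_db=np.inf, seed=11))
    return rec, marks


@pytest.fixture(scope="session")
def noisy_vowel():
    rec, marks = pvq.synth_vowel(
        pvq.SynthesisSpec(f0=150.0, jitter_pct=1.0, shimmer_db=0.5,
                          hnr_db=15.0, seed=12))
    return rec, marks


@pytest.fixture(scope="session")
def white_noise_rec():
    rng = np.random.default_rng(7)
    return Recording(rng.standard_normal(32000) * 0.1, 16000, "noise")


@pytest.fixture(scope="session")
def hnr_ladder_recs():
    """Vowels at fixed f0/seed differing only in HNR (no jitter/shimmer)."""
    return {h: pvq.synth_vowel(pvq.SynthesisSpec(f0=150.0, hnr_db=h, seed=21))[0]
            for h in HNR_LADDER}


@pytest.fixture(scope="session")
def cohort():
    """Default 113-vowel synthetic cohort with rated panel.

    Feature extraction covers the composite inputs (LCQA + HNR + CPPS) and
    every scalar metric; GFCC is exercised separately to keep the suite fast.
    """
    recs, truth = pvq.synth_cohort(113, seed=0)
    ratings = pvq.synth_ratings(truth, pvq.RaterPanelSpec(seed=0))
    families = ("traditional", "lcqa", "srmr", "moda", "rpde")
    df, dropped = extract_table(recs, families)
    assert not dropped
    return {"recordings": recs, "truth": truth, "ratings": ratings,
            "features": pvq.FeatureTable(df)}
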