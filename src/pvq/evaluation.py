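"""Benchmarking statistics for objective vowel-quality metrics.

Pearson correlation with significance, the standard deviation of prediction
error SDPE = sigma_s * sqrt(1 - rho^2) (sigma_s being the SD of the
subjective scores), Steiger's Z for comparing two dependent correlations
sharing one variable, intraclass correlation for rater reliability, the
paired t-test, and averaging of correlations over repeated random
train/test splits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .modeling import FeatureTable, RatingSet, VowelQualityModel, split_dataset

__all__ = [
    "EvalReport",
    "pearson_r",
    "sdpe",
    "steiger_z",
    "icc",
    "paired_t",
    "report_from_scores",
    "repeated_split_eval",
    "significance_stars",
]


@dataclass
class EvalReport:
    """Correlation and SDPE of one metric on one data partition."""

    rho: float
    p_value: float
    sigma_s: float       # SD of the subjective scores (population convention)
    sdpe: float          # VAS units
    partition: str
    n: int

    def __post_init__(self):
        if not -1.0 <= self.rho <= 1.0:
            raise InputError("rho outside [-1, 1]")
        expected = self.sigma_s * np.sqrt(1.0 - self.rho ** 2)
        if abs(self.sdpe - expected) > 1e-10:
            raise InputError("SDPE inconsistent with sigma_s * sqrt(1 - rho^2)")


def pearson_r(a, b) -> Tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-test p-value (n-2 df)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) != len(b) or len(a) < 3:
        raise InputError("need equal-length sequences with n >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise InputError("correlation undefined for zero-variance input")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def sdpe(sigma_s: float, rho: float) -> float:
    """Standard deviation of prediction error: sigma_s * sqrt(1 - rho^2)."""
    if sigma_s < 0:
        raise InputError("sigma_s must be non-negative")
    if abs(rho) > 1:
        raise InputError("|rho| must not exceed 1")
    return float(sigma_s * np.sqrt(1.0 - rho ** 2))


def invert_sdpe(sdpe_value: float, rho: float) -> float:
    """Recover sigma_s from a printed (rho, SDPE) pair."""
    if abs(rho) >= 1:
        raise InputError("|rho| must be < 1 to invert")
    return float(sdpe_value / np.sqrt(1.0 - rho ** 2))


def steiger_z(r_1y: float, r_2y: float, r_12: float, n: int) -> Tuple[float, float]:
    """Steiger's Z for two dependent correlations sharing the variable y.

    Fisher-transforms r_1y and r_2y and standardizes their difference using
    the covariance implied by the inter-metric correlation r_12:

        Z = (z1 - z2) * sqrt((n - 3) / (2 * (1 - s))),

    where s is the correlation between the two dependent correlation
    estimates, computed from r_12 and the mean of r_1y and r_2y.  The
    p-value is two-sided standard normal.
    """
    if n < 4:
        raise InputError("need n >= 4")
    for r in (r_1y, r_2y, r_12):
        if abs(r) > 1:
            raise InputError("correlations must lie in [-1, 1]")
    if abs(r_1y) == 1 and abs(r_2y) == 1:
        raise InputError("degenerate: both correlations are +/-1")
    # the three correlations must be jointly realizable (PSD 3x3 matrix)
    det = (1 + 2 * r_1y * r_2y * r_12 - r_1y ** 2 - r_2y ** 2 - r_12 ** 2)
    if det < -1e-12:
        raise InputError("correlations are not jointly realizable")
    rbar2 = (0.5 * (r_1y + r_2y)) ** 2  # squared mean correlation
    psi = r_12 * (1.0 - 2.0 * rbar2) - 0.5 * rbar2 * (1.0 - 2.0 * rbar2 - r_12 ** 2)
    s = psi / (1.0 - rbar2) ** 2
    if s >= 1.0:
        raise InputError("degenerate correlation structure")
    z1, z2 = np.arctanh(r_1y), np.arctanh(r_2y)
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - s)))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def icc(per_rater, flavor: str = "consistency_random") -> float:
    """Average-measures intraclass correlation from a two-way ANOVA.

    ``agreement_mixed`` is the absolute-agreement average-measures ICC
    (ICC(A,k)); ``consistency_random`` is the consistency average-measures
    ICC (ICC(C,k)).  Rows are targets (recordings), columns raters.
    """
    x = np.asarray(per_rater, float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise InputError("need an m x k matrix with m >= 2, k >= 2")
    if np.all(x == x.flat[0]):
        raise InputError("ICC undefined for a constant matrix")
    m, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = m * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (m - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((m - 1) * (k - 1))
    if flavor == "consistency_random":
        if msr == 0:
            raise InputError("ICC undefined: no between-target variance")
        return float((msr - mse) / msr)
    if flavor == "agreement_mixed":
        denom = msr + (msc - mse) / m
        if denom == 0:
            raise InputError("ICC undefined")
        return float((msr - mse) / denom)
    raise InputError(f"unknown ICC flavor: {flavor}")


def paired_t(off, on) -> Tuple[float, float]:
    """Paired-sample t-test (two-sided, n-1 df)."""
    off = np.asarray(off, float)
    on = np.asarray(on, float)
    if len(off) != len(on) or len(off) < 3:
        raise InputError("need equal-length sequences with n >= 3")
    d = off - on
    if np.std(d) == 0:
        if np.all(d == 0):
            return 0.0, 1.0
        raise InputError("zero-variance differences: t undefined")
    res = stats.ttest_rel(off, on)
    return float(res.statistic), float(res.pvalue)


def significance_stars(p: float) -> str:
    """Conventional marks: ** for p < 0.01, * for p < 0.05."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def report_from_scores(y_true, y_pred, partition: str = "train") -> EvalReport:
    """Build an :class:`EvalReport` from subjective and predicted scores."""
    y_true = np.asarray(y_true, float)
    rho, p = pearson_r(y_true, y_pred)
    sigma = float(np.std(y_true))  # population (1/n) SD
    return EvalReport(rho=rho, p_value=p, sigma_s=sigma,
                      sdpe=sdpe(sigma, rho), partition=partition,
                      n=len(y_true))


def repeated_split_eval(table: FeatureTable, ratings: RatingSet,
                        pipelines: Dict[str, dict], n_repeats: int = 20,
                        base_seed: int = 0, test_frac: float = 0.2,
                        config=None) -> pd.DataFrame:
    """Average train/test correlations over repeated random 80/20 splits.

    ``pipelines`` maps a metric name to a spec dict with keys ``columns``
    (feature names to use), ``mapper`` ("lr"/"svr") and ``reduction``
    ("none"/"pca"/"mc").  For each repeat a fresh seeded split is drawn, the
    full pipeline (including any selection) is fitted on the training
    partition only, and both partitions are scored.  Returns a DataFrame of
    means indexed by metric, with per-repeat values in ``df.attrs["runs"]``.
    """
    ratings = ratings.aligned_to(table)
    rows = []
    for rep in range(n_repeats):
        seed = base_seed + rep
        (ftr, rtr), (fte, rte) = split_dataset(table, ratings,
                                               test_frac=test_frac, seed=seed)
        assert not set(ftr.source_ids) & set(fte.source_ids)
        for name, spec in pipelines.items():
            cols = spec.get("columns") or table.feature_names
            sub_tr = FeatureTable(ftr.df[cols])
            sub_te = fte.df[cols]
            model = VowelQualityModel(sub_tr, rtr,
                                      mapper=spec.get("mapper", "lr"),
                                      reduction=spec.get("reduction", "none"),
                                      config=config)
            res = model.fit(seed=seed)
            rep_tr = report_from_scores(res.y_train, res.fittedvalues, "train")
            yhat_te = res.predict(sub_te)
            rep_te = report_from_scores(rte.y.to_numpy(), yhat_te, "test")
            rows.append({"metric": name, "repeat": rep, "seed": seed,
                         "train_r": rep_tr.rho, "train_sdpe": rep_tr.sdpe,
                         "test_r": rep_te.rho, "test_sdpe": rep_te.sdpe})
    runs = pd.DataFrame(rows)
    means = runs.groupby("metric")[
        ["train_r", "train_sdpe", "test_r", "test_sdpe"]].mean()
    means = means.loc[list(pipelines)]
    means.attrs["runs"] = runs
    return means
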