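"""Feature-to-quality mapping: y = f(theta, X) + b.

The feature matrix X (m recordings x n named acoustic features) is mapped to
consensus VAS ratings y with either multivariate linear regression (LR) or
epsilon-insensitive RBF support vector regression (SVR), optionally preceded
by PCA or by correlation-ranked Monte Carlo feature selection.

The statsmodels-style surface is :class:`VowelQualityModel` (built from a
feature table and a rating set; ``fit()`` returns a
:class:`VowelQualityResults` carrying parameters, residuals, diagnostics and
``summary()``).  The individual pipeline stages are also exposed as
module-level functions (:func:`split_dataset`, :func:`rank_features`,
:func:`monte_carlo_select`, :func:`pca_reduce`, :func:`fit_mapper`,
:func:`predict`, :func:`assemble_composite`).

Feature selection is performed strictly inside the training partition: each
candidate subset is scored by its mean validation MSE over a fixed panel of
seeded inner train/validation splits of the training rows.  Scoring a subset
on a fixed split panel (rather than one fresh split per draw) makes the
selection objective a deterministic function of the subset, so the Monte
Carlo search provably agrees with exhaustive enumeration when it visits
every subset.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.svm import SVR

from .errors import InputError

__all__ = [
    "FeatureTable",
    "RatingSet",
    "SelectionResult",
    "PcaTransform",
    "MappingModel",
    "split_dataset",
    "rank_features",
    "monte_carlo_select",
    "inner_splits",
    "pca_reduce",
    "fit_mapper",
    "predict",
    "assemble_composite",
    "COMPOSITE_COLUMNS",
    "VowelQualityModel",
    "VowelQualityResults",
]

LCQA_COLUMNS = [f"lcqa_{i:02d}" for i in range(1, 41)]
COMPOSITE_COLUMNS = LCQA_COLUMNS + ["hnr_db", "cpps_db"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """m x n matrix of named acoustic features, indexed by source_id."""

    df: pd.DataFrame

    def __post_init__(self):
        if len(self.df) < 2:
            raise InputError("FeatureTable needs at least 2 recordings")
        if self.df.columns.duplicated().any():
            raise InputError("duplicate feature names")
        if self.df.isna().any().any():
            warnings.warn("missing feature values imputed with column medians")
            self.df = self.df.fillna(self.df.median()).fillna(0.0)

    @property
    def X(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    @property
    def feature_names(self) -> list:
        return list(self.df.columns)

    @property
    def source_ids(self) -> list:
        return list(self.df.index)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class RatingSet:
    """Per-recording, per-rater VAS scores; consensus y is the row mean."""

    per_rater: pd.DataFrame

    def __post_init__(self):
        if self.per_rater.isna().any().any():
            raise InputError("rating matrix contains missing values")

    @property
    def y(self) -> pd.Series:
        return self.per_rater.mean(axis=1).rename("mean_vas")

    @property
    def n_raters(self) -> int:
        return self.per_rater.shape[1]

    def aligned_to(self, table: FeatureTable) -> "RatingSet":
        missing = set(table.source_ids) - set(self.per_rater.index)
        if missing:
            raise InputError(f"ratings missing for: {sorted(missing)[:5]} ...")
        return RatingSet(self.per_rater.loc[table.source_ids])

    def __len__(self) -> int:
        return len(self.per_rater)


@dataclass
class SelectionResult:
    """Outcome of correlation ranking and Monte Carlo subset search."""

    ranked_indices: np.ndarray          # feature indices by |r| descending
    chosen: np.ndarray                  # selected subset (subset of ranked)
    cv_mse: float
    n_iterations: int
    seed: Optional[int]
    correlations: np.ndarray = field(default=None)  # |r| in ranked order

    def __post_init__(self):
        self.ranked_indices = np.asarray(self.ranked_indices, dtype=int)
        self.chosen = np.asarray(self.chosen, dtype=int)
        if not set(self.chosen).issubset(set(self.ranked_indices)):
            raise InputError("chosen must be a subset of ranked_indices")
        if self.cv_mse < 0:
            raise InputError("cv_mse must be non-negative")


@dataclass
class PcaTransform:
    """Principal-component reduction keeping a cumulative-variance threshold."""

    components: np.ndarray               # (n_kept, n) rows = components
    explained_variance_fractions: np.ndarray  # all fractions, descending
    n_kept: int
    mean: np.ndarray                     # column means removed before projection

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) @ self.components.T


@dataclass
class MappingModel:
    """A fitted feature mapper with its stored preprocessing constants.

    Prediction always runs from the stored arrays (never from a live
    scikit-learn estimator), so serialization round-trips are exact and
    predict-time behaviour cannot drift from fit time.
    """

    kind: str                           # "lr" | "svr"
    mean: np.ndarray                    # training column means
    scale: np.ndarray                   # training column SDs (1 where zero)
    params: dict                        # mapper state (plain arrays)
    b: np.ndarray                       # training residuals y - yhat
    feature_names: Optional[list] = None

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, float) - self.mean) / self.scale
        if self.kind == "lr":
            return Z @ self.params["coef"] + self.params["intercept"]
        sv = self.params["support_vectors"]
        dual = self.params["dual_coef"]
        gamma = self.params["gamma"]
        d2 = (np.sum(Z * Z, axis=1)[:, None] + np.sum(sv * sv, axis=1)[None, :]
              - 2.0 * Z @ sv.T)
        return np.exp(-gamma * np.maximum(d2, 0.0)) @ dual + self.params["intercept"]

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "params": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                       for k, v in self.params.items()},
            "b": self.b.tolist(),
            "feature_names": self.feature_names,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MappingModel":
        params = {k: (np.asarray(v, float) if isinstance(v, list) else v)
                  for k, v in d["params"].items()}
        return cls(kind=d["kind"], mean=np.asarray(d["mean"], float),
                   scale=np.asarray(d["scale"], float), params=params,
                   b=np.asarray(d["b"], float),
                   feature_names=d.get("feature_names"))


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def split_dataset(table: FeatureTable, ratings: RatingSet,
                  test_frac: float = 0.2, seed: int = 0):
    """Seeded shuffle split into train/test pairs (test = floor(frac * m))."""
    m = len(table)
    if m < 5:
        raise InputError("need at least 5 recordings to split")
    n_test = int(np.floor(test_frac * m))
    if n_test < 1:
        raise InputError("test fraction yields an empty test set")
    ratings = ratings.aligned_to(table)
    perm = np.random.default_rng(seed).permutation(m)
    test_idx, train_idx = np.sort(perm[:n_test]), np.sort(perm[n_test:])
    assert len(set(test_idx) & set(train_idx)) == 0
    df = table.df
    pr = ratings.per_rater
    train = (FeatureTable(df.iloc[train_idx]), RatingSet(pr.iloc[train_idx]))
    test = (FeatureTable(df.iloc[test_idx]), RatingSet(pr.iloc[test_idx]))
    return train, test


def rank_features(X: np.ndarray, y: np.ndarray) -> SelectionResult:
    """Rank feature columns by |Pearson correlation with y|, descending.

    Zero-variance columns get r = 0 with a warning; ties break on the
    original column index.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.shape[0] < 3:
        raise InputError("need at least 3 samples to rank features")
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc * xc, axis=0))
    sy = np.sqrt(np.sum(yc * yc))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ yc) / (sx * sy)
    bad = ~np.isfinite(r)
    if bad.any():
        warnings.warn("zero-variance columns assigned correlation 0")
        r[bad] = 0.0
    order = np.lexsort((np.arange(X.shape[1]), -np.abs(r)))
    return SelectionResult(ranked_indices=order, chosen=order, cv_mse=0.0,
                           n_iterations=0, seed=None,
                           correlations=np.abs(r)[order])


def inner_splits(m: int, n_splits: int, val_frac: float, seed: int):
    """Fixed panel of seeded train/validation index splits of m rows."""
    rng = np.random.default_rng(seed)
    n_val = max(1, int(round(val_frac * m)))
    if n_val >= m:
        raise InputError("validation fraction leaves no training rows")
    splits = []
    for _ in range(n_splits):
        perm = rng.permutation(m)
        splits.append((perm[n_val:], perm[:n_val]))
    return splits


def _lstsq_val_mse(X, y, cols, splits):
    """Mean and standard error of the validation MSE of an intercept LR."""
    mses = np.empty(len(splits))
    for i, (tr, va) in enumerate(splits):
        A = np.column_stack([np.ones(len(tr)), X[np.ix_(tr, cols)]])
        coef, *_ = np.linalg.lstsq(A, y[tr], rcond=None)
        Av = np.column_stack([np.ones(len(va)), X[np.ix_(va, cols)]])
        resid = y[va] - Av @ coef
        mses[i] = np.mean(resid ** 2)
    return float(mses.mean()), float(mses.std(ddof=1) / np.sqrt(len(mses)))


def monte_carlo_select(X_ranked: np.ndarray, y: np.ndarray,
                       n_iter: int = 2000, inner_val_frac: float = 0.25,
                       seed: int = 0, n_inner_splits: int = 10) -> SelectionResult:
    """Monte Carlo search for the feature subset minimizing validation MSE.

    ``X_ranked`` must have its columns ordered by correlation rank
    (descending |r|); sampling is biased toward high-ranked columns with
    weight proportional to ``n - rank``.  Each distinct subset is scored
    once (memoized) by mean LR validation MSE over a fixed panel of seeded
    inner splits; the minimum-MSE subset wins, with ties preferring
    smaller, then lexicographically earlier, subsets.  Deterministic
    given the seed.
    """
    if n_iter < 1:
        raise InputError("n_iter must be >= 1")
    X = np.asarray(X_ranked, float)
    y = np.asarray(y, float)
    m, n = X.shape
    if m < 10:
        raise InputError("need at least 10 training rows for selection")
    rng = np.random.default_rng(seed)
    splits = inner_splits(m, n_inner_splits, inner_val_frac, seed)
    weights = (n - np.arange(n)).astype(float)
    weights /= weights.sum()
    cache = {}
    for _ in range(n_iter):
        size = int(rng.integers(1, n + 1))
        subset = tuple(sorted(rng.choice(n, size=size, replace=False, p=weights)))
        if subset not in cache:
            cache[subset] = _lstsq_val_mse(X, y, list(subset), splits)
    subset = min(cache, key=lambda s: (cache[s][0], len(s), s))
    return SelectionResult(ranked_indices=np.arange(n),
                           chosen=np.array(subset, dtype=int),
                           cv_mse=cache[subset][0], n_iterations=n_iter,
                           seed=seed)


def pca_reduce(X: np.ndarray, variance_threshold: float = 0.95) -> PcaTransform:
    """PCA on (already standardized) X keeping the cumulative-variance threshold."""
    if not 0.0 < variance_threshold <= 1.0:
        raise InputError("variance_threshold must be in (0, 1]")
    X = np.asarray(X, float)
    pca = PCA()
    pca.fit(X)
    frac = pca.explained_variance_ratio_
    cum = np.cumsum(frac)
    n_kept = int(np.searchsorted(cum, variance_threshold - 1e-9) + 1)
    n_kept = min(n_kept, len(frac))
    return PcaTransform(components=pca.components_[:n_kept].copy(),
                        explained_variance_fractions=frac.copy(),
                        n_kept=n_kept, mean=pca.mean_.copy())


def fit_mapper(X: np.ndarray, y: np.ndarray, kind: str = "lr",
               feature_names: Optional[Sequence[str]] = None,
               svr_c: float = 10.0, svr_epsilon: float = 1.0,
               ridge_alpha: float = 1.0) -> MappingModel:
    """Fit the feature mapper y = f(theta, X) + b.

    LR is ordinary least squares with intercept (ridge fallback when the
    system is underdetermined, logged); SVR is an epsilon-insensitive RBF
    machine with C, epsilon and kernel width 1/n_features fixed in config.
    Columns are standardized internally using training statistics.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    if X.shape[0] != len(y):
        raise InputError("X and y lengths differ")
    if X.size == 0 or not np.any(X):
        raise InputError("degenerate (rank-0) feature matrix")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale
    m, n = Z.shape
    if kind == "lr":
        if m > n:
            est = LinearRegression().fit(Z, y)
        else:
            warnings.warn("underdetermined LR; falling back to ridge")
            est = Ridge(alpha=ridge_alpha).fit(Z, y)
        params = {"coef": est.coef_.astype(float),
                  "intercept": float(est.intercept_)}
    elif kind == "svr":
        est = SVR(kernel="rbf", C=svr_c, epsilon=svr_epsilon, gamma=1.0 / n)
        est.fit(Z, y)
        params = {"support_vectors": est.support_vectors_.astype(float),
                  "dual_coef": est.dual_coef_.ravel().astype(float),
                  "intercept": float(est.intercept_[0]),
                  "gamma": 1.0 / n}
    else:
        raise InputError(f"unknown mapper kind: {kind}")
    model = MappingModel(kind=kind, mean=mean, scale=scale, params=params,
                         b=np.empty(0),
                         feature_names=list(feature_names) if feature_names
                         is not None else None)
    model.b = y - model.predict_raw(X)
    return model


def predict(model: MappingModel, X_new, clip: bool = False) -> np.ndarray:
    """Predict VAS scores for new rows.

    Accepts a DataFrame (columns validated and reordered against the
    model's expected feature names) or a plain array.  ``clip=True`` bounds
    reported scores to [0, 100]; unclipped values should be used for
    correlation computation.
    """
    if isinstance(X_new, pd.DataFrame):
        if model.feature_names is None:
            X = X_new.to_numpy(dtype=float)
        else:
            missing = [c for c in model.feature_names if c not in X_new.columns]
            if missing:
                raise InputError(f"missing feature columns: {missing}")
            X = X_new[model.feature_names].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(X_new, float))
    yhat = model.predict_raw(X)
    return np.clip(yhat, 0.0, 100.0) if clip else yhat


def assemble_composite(table: FeatureTable) -> FeatureTable:
    """Assemble the 42-column composite table (lcqa_01..40, hnr_db, cpps_db)."""
    missing = [c for c in COMPOSITE_COLUMNS if c not in table.df.columns]
    if missing:
        raise InputError(f"missing required columns: {missing}")
    return FeatureTable(table.df[COMPOSITE_COLUMNS].copy())


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class VowelQualityModel:
    """Maps acoustic features of sustained vowels to perceived VAS quality.

    Parameters
    ----------
    features : FeatureTable or DataFrame
        Training feature matrix (rows = recordings).
    ratings : RatingSet, Series or array
        Consensus VAS scores (a RatingSet is reduced to its row mean).
    mapper : {"lr", "svr"}
    reduction : {"none", "pca", "mc"}
        Optional dimensionality reduction: PCA at a cumulative-variance
        threshold, or correlation-ranked Monte Carlo subset selection.
    """

    def __init__(self, features, ratings, mapper: str = "lr",
                 reduction: str = "none", config=None):
        from .config import DEFAULT_CONFIG
        self.config = config or DEFAULT_CONFIG
        if isinstance(features, FeatureTable):
            self.table = features
        else:
            self.table = FeatureTable(pd.DataFrame(features))
        if isinstance(ratings, RatingSet):
            ratings = ratings.aligned_to(self.table)
            y = ratings.y
        else:
            y = pd.Series(np.asarray(ratings, float), index=self.table.df.index)
        if len(y) != len(self.table):
            raise InputError("features and ratings misaligned")
        self.y = y
        if mapper not in ("lr", "svr"):
            raise InputError(f"unknown mapper: {mapper}")
        if reduction not in ("none", "pca", "mc"):
            raise InputError(f"unknown reduction: {reduction}")
        self.mapper = mapper
        self.reduction = reduction

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, ratings, **kwargs):
        return cls(FeatureTable(df), ratings, **kwargs)

    def fit(self, seed: int = 0) -> "VowelQualityResults":
        cfg = self.config
        X = self.table.X
        y = self.y.to_numpy(dtype=float)
        names = self.table.feature_names
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        Z = (X - mean) / scale

        selection = None
        pca = None
        if self.reduction == "mc":
            ranking = rank_features(Z, y)
            order = ranking.ranked_indices
            sel = monte_carlo_select(
                Z[:, order], y, n_iter=cfg.mc_iters,
                inner_val_frac=cfg.mc_inner_val_frac, seed=seed,
                n_inner_splits=cfg.mc_inner_splits)
            chosen = np.sort(order[sel.chosen])
            selection = SelectionResult(
                ranked_indices=order, chosen=chosen, cv_mse=sel.cv_mse,
                n_iterations=sel.n_iterations, seed=seed,
                correlations=ranking.correlations)
            Zr = Z[:, chosen]
            used_names = [names[i] for i in chosen]
        elif self.reduction == "pca":
            pca = pca_reduce(Z, cfg.pca_threshold)
            Zr = pca.transform(Z)
            used_names = [f"pc_{i + 1}" for i in range(pca.n_kept)]
        else:
            Zr = Z
            used_names = list(names)

        mapping = fit_mapper(Zr, y, kind=self.mapper,
                             feature_names=used_names,
                             svr_c=cfg.svr_c, svr_epsilon=cfg.svr_epsilon)
        return VowelQualityResults(
            model=self, input_names=names, mean=mean, scale=scale,
            reduction=self.reduction, selection=selection, pca=pca,
            mapping=mapping, y_train=y, seed=seed)


class VowelQualityResults:
    """Fitted vowel-quality estimator: parameters, residuals, diagnostics."""

    def __init__(self, model, input_names, mean, scale, reduction,
                 selection, pca, mapping, y_train, seed):
        self.model = model
        self.input_names = list(input_names)
        self.mean = np.asarray(mean, float)
        self.scale = np.asarray(scale, float)
        self.reduction = reduction
        self.selection = selection
        self.pca = pca
        self.mapping = mapping
        self.y_train = np.asarray(y_train, float)
        self.seed = seed
        self.fittedvalues = self._predict_array(
            None, use_train_cache=True)
        self.resid = self.y_train - self.fittedvalues

    # -- prediction ------------------------------------------------------
    def _reduce(self, Z: np.ndarray) -> np.ndarray:
        if self.reduction == "mc":
            return Z[:, self.selection.chosen]
        if self.reduction == "pca":
            return self.pca.transform(Z)
        return Z

    def _predict_array(self, X, use_train_cache=False):
        if use_train_cache:
            X = self.model.table.X
        Z = (np.asarray(X, float) - self.mean) / self.scale
        return self.mapping.predict_raw(self._reduce(Z))

    def predict(self, features, clip: bool = False) -> np.ndarray:
        """Predict VAS for new recordings (FeatureTable, DataFrame or array)."""
        if isinstance(features, FeatureTable):
            features = features.df
        if isinstance(features, pd.DataFrame):
            missing = [c for c in self.input_names if c not in features.columns]
            if missing:
                raise InputError(f"missing feature columns: {missing}")
            X = features[self.input_names].to_numpy(dtype=float)
        else:
            X = np.atleast_2d(np.asarray(features, float))
            if X.shape[1] != len(self.input_names):
                raise InputError("feature count mismatch")
        yhat = self._predict_array(X)
        return np.clip(yhat, 0.0, 100.0) if clip else yhat

    # -- diagnostics -----------------------------------------------------
    @property
    def params(self) -> pd.Series:
        """Mapper weights (LR) or dual-coefficient magnitudes summary (SVR)."""
        if self.mapping.kind == "lr":
            s = pd.Series(self.mapping.params["coef"],
                          index=self.mapping.feature_names, name="weight")
            s.loc["intercept"] = self.mapping.params["intercept"]
            return s
        dual = self.mapping.params["dual_coef"]
        return pd.Series({"n_support": len(dual),
                          "intercept": self.mapping.params["intercept"],
                          "dual_coef_l1": float(np.sum(np.abs(dual)))})

    def eval_report(self, y_true=None, y_pred=None, partition: str = "train"):
        """Pearson rho / p, subjective-score SD and SDPE for a partition."""
        from .evaluation import report_from_scores
        if y_true is None:
            y_true, y_pred = self.y_train, self.fittedvalues
        return report_from_scores(y_true, y_pred, partition=partition)

    def summary(self) -> str:
        rep = self.eval_report()
        n_used = len(self.mapping.mean)
        lines = [
            "Vowel Quality Mapping Results",
            "=" * 46,
            f"mapper:            {self.mapping.kind.upper()}",
            f"reduction:         {self.reduction}",
            f"n recordings:      {len(self.y_train)}",
            f"n input features:  {len(self.input_names)}",
            f"n used features:   {n_used}",
            f"train rho:         {rep.rho:8.4f}  (p = {rep.p_value:.3g})",
            f"train SDPE:        {rep.sdpe:8.4f}  VAS units",
            f"subjective SD:     {rep.sigma_s:8.4f}  VAS units",
        ]
        if self.selection is not None:
            chosen_names = [self.input_names[i] for i in self.selection.chosen]
            lines.append(f"selected features: {', '.join(chosen_names)}")
            lines.append(f"selection CV MSE:  {self.selection.cv_mse:.4f}")
        if self.pca is not None:
            lines.append(f"PCA components:    {self.pca.n_kept}")
        return "\n".join(lines)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "input_names": self.input_names,
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "reduction": self.reduction,
            "mapping": self.mapping.to_dict(),
            "seed": self.seed,
        }
        if self.selection is not None:
            d["chosen"] = self.selection.chosen.tolist()
        if self.pca is not None:
            d["pca"] = {
                "components": self.pca.components.tolist(),
                "explained": self.pca.explained_variance_fractions.tolist(),
                "n_kept": self.pca.n_kept,
                "mean": self.pca.mean.tolist(),
            }
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "VowelQualityResults":
        obj = cls.__new__(cls)
        obj.model = None
        obj.input_names = list(d["input_names"])
        obj.mean = np.asarray(d["mean"], float)
        obj.scale = np.asarray(d["scale"], float)
        obj.reduction = d["reduction"]
        obj.mapping = MappingModel.from_dict(d["mapping"])
        obj.seed = d.get("seed")
        obj.selection = None
        obj.pca = None
        if "chosen" in d:
            chosen = np.asarray(d["chosen"], int)
            obj.selection = SelectionResult(
                ranked_indices=np.arange(len(obj.input_names)), chosen=chosen,
                cv_mse=0.0, n_iterations=0, seed=None)
        if "pca" in d:
            p = d["pca"]
            obj.pca = PcaTransform(
                components=np.asarray(p["components"], float),
                explained_variance_fractions=np.asarray(p["explained"], float),
                n_kept=int(p["n_kept"]), mean=np.asarray(p["mean"], float))
        obj.y_train = np.asarray(obj.mapping.b, float) * np.nan
        obj.fittedvalues = None
        obj.resid = None
        return obj

    @classmethod
    def load(cls, path) -> "VowelQualityResults":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
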