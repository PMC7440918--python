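"""Preprocessing, PCA-order selection and Gaussian-mixture subtyping.

The clustering recipe: log-transform the skewed count/latency features,
discard cells carrying any value farther than 5 interquartile ranges from
the feature median, min-max scale every feature to [0, 1], choose the
number of principal components (1-9) and then the number of mixture
components (1-7) by minimizing fivefold cross-validated BIC, and read the
subtype labels off the maximum-responsibility assignment of the final
mixture refit on all cells.

"Cross-validated BIC" is defined here as the held-out log-likelihood of
each fold under the model fit to the remaining folds, penalized with the
model's parameter count, averaged over folds; the PCA likelihood is the
probabilistic-PCA observation model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import KFold

__all__ = [
    "FeatureMatrix",
    "PreprocessReport",
    "ClusterModel",
    "preprocess",
    "select_pca_order",
    "fit_gmm",
    "assign_new_cells",
    "name_clusters",
    "cluster_cells",
    "DEFAULT_LOG1P_FEATURES",
    "DEFAULT_LOG_FEATURES",
]

#: count-like features: natural log of (x + 1)
DEFAULT_LOG1P_FEATURES = ("spike_count_rheo", "spike_count_sat", "adp_latency")
#: strictly positive latency features: natural log
DEFAULT_LOG_FEATURES = ("first_spike_latency_rheo", "first_spike_latency_sat")

IQR_MULTIPLE = 5.0


@dataclass
class FeatureMatrix:
    """Cells x features table with optional per-cell metadata."""

    values: pd.DataFrame
    age_group: pd.Series | None = None
    true_labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate feature names")

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PreprocessReport:
    """Record of the preprocessing applied, sufficient to freeze it."""

    log_transformed: dict[str, str]  # feature -> "log" | "log1p"
    outlier_cell_ids: list
    feature_min: pd.Series
    feature_range: pd.Series
    dropped_columns: list = field(default_factory=list)

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        """Apply the frozen transform (log + scaling) to new cells."""
        out = df.drop(columns=self.dropped_columns, errors="ignore").astype(float)
        for col, kind in self.log_transformed.items():
            if col in out:
                out[col] = np.log1p(out[col]) if kind == "log1p" else np.log(out[col])
        out = (out[self.feature_min.index] - self.feature_min) / self.feature_range
        return out


def preprocess(
    features: FeatureMatrix | pd.DataFrame,
    log1p_features: Sequence[str] = DEFAULT_LOG1P_FEATURES,
    log_features: Sequence[str] = DEFAULT_LOG_FEATURES,
    iqr_multiple: float = IQR_MULTIPLE,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Log-transform, reject outlier cells, and min-max scale to [0, 1].

    A cell is an outlier when any of its (transformed, unscaled) values
    lies more than ``iqr_multiple`` interquartile ranges from the feature
    median; the pass runs once.  Constant columns are dropped with a
    warning.  Raises on missing values.
    """
    df = features.values if isinstance(features, FeatureMatrix) else features
    df = df.astype(float).copy()
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing values in features: {bad}")

    applied: dict[str, str] = {}
    for col in log1p_features:
        if col in df:
            df[col] = np.log1p(df[col])
            applied[col] = "log1p"
    for col in log_features:
        if col in df:
            if (df[col] <= 0).any():
                raise ValueError(f"non-positive values in log feature {col!r}")
            df[col] = np.log(df[col])
            applied[col] = "log"

    med = df.median()
    iqr = df.quantile(0.75) - df.quantile(0.25)
    dev = (df - med).abs()
    limit = iqr_multiple * iqr
    outlier_mask = (dev > limit).any(axis=1)
    outliers = df.index[outlier_mask].tolist()
    kept = df.loc[~outlier_mask]

    dropped = []
    fmin = kept.min()
    frange = kept.max() - kept.min()
    for col in kept.columns:
        if frange[col] == 0:
            dropped.append(col)
    if dropped:
        warnings.warn(f"dropping constant feature columns: {dropped}")
        kept = kept.drop(columns=dropped)
        fmin = fmin.drop(dropped)
        frange = frange.drop(dropped)

    scaled = (kept - fmin) / frange
    report = PreprocessReport(
        log_transformed=applied,
        outlier_cell_ids=outliers,
        feature_min=fmin,
        feature_range=frange,
        dropped_columns=dropped,
    )
    return scaled, report


# ---------------------------------------------------------------------------
# model-order selection
# ---------------------------------------------------------------------------


def _ppca_n_params(d: int, k: int) -> int:
    """Free parameters of the probabilistic-PCA observation model."""
    return d * k - k * (k - 1) // 2 + d + 1  # loadings + mean + noise var


def _gmm_n_params(d: int, n_components: int) -> int:
    cov = n_components * d * (d + 1) // 2
    return cov + n_components * d + (n_components - 1)


def select_pca_order(
    scaled: pd.DataFrame | np.ndarray,
    kmax: int = 9,
    folds: int = 5,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Choose the PCA order by fold-averaged held-out BIC (k = 1..kmax).

    For each candidate k a probabilistic PCA is fit on the training folds
    and its log-likelihood evaluated on the held-out fold; BIC is
    ``-2 LL + p ln(n_test)`` with p the PPCA parameter count.  Returns the
    argmin order and the BIC curve (index 0 = one component).
    """
    X = np.asarray(scaled, dtype=float)
    n, d = X.shape
    if n < folds:
        raise ValueError("fewer cells than folds")
    kmax = min(kmax, d, n - 1)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    curve = np.zeros(kmax)
    for k in range(1, kmax + 1):
        bics = []
        for train, test in kf.split(X):
            pca = PCA(n_components=k, svd_solver="full")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pca.fit(X[train])
                ll = pca.score(X[test]) * len(test)
            if not np.isfinite(ll):  # degenerate covariance
                warnings.warn(f"regularizing degenerate PPCA fit at k={k}")
                ll = -1e12
            p = _ppca_n_params(d, k)
            bics.append(-2.0 * ll + p * np.log(len(test)))
        curve[k - 1] = float(np.mean(bics))
    return int(np.argmin(curve)) + 1, curve


@dataclass
class ClusterModel:
    """Frozen preprocessing + PCA + Gaussian-mixture subtype model."""

    n_pcs: int
    loadings: np.ndarray  # features x n_pcs, orthonormal columns
    pca_mean: np.ndarray
    explained_variance_fractions: np.ndarray
    weights: np.ndarray
    means: np.ndarray  # K x n_pcs
    covariances: np.ndarray  # K x n_pcs x n_pcs
    bic_curve_pca: np.ndarray
    bic_curve_gmm: np.ndarray
    labels: pd.Series  # 1-based component labels per cell
    seed: int
    cluster_names: dict[int, str] | None = None

    @property
    def n_components(self) -> int:
        return self.weights.size

    def project(self, scaled: pd.DataFrame | np.ndarray) -> np.ndarray:
        X = np.asarray(scaled, dtype=float)
        return (X - self.pca_mean) @ self.loadings

    def responsibilities(self, scores: np.ndarray) -> np.ndarray:
        from scipy.stats import multivariate_normal

        dens = np.column_stack(
            [
                w * multivariate_normal.pdf(scores, mean=m, cov=c, allow_singular=True)
                for w, m, c in zip(self.weights, self.means, self.covariances)
            ]
        )
        dens = np.atleast_2d(dens)
        total = dens.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        return dens / total

    def predict(self, scores: np.ndarray) -> np.ndarray:
        """1-based component labels by maximum responsibility."""
        return np.argmax(self.responsibilities(scores), axis=1) + 1

    def save(self, path) -> None:
        payload = {
            "n_pcs": self.n_pcs,
            "loadings": self.loadings.tolist(),
            "pca_mean": self.pca_mean.tolist(),
            "explained_variance_fractions": self.explained_variance_fractions.tolist(),
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "bic_curve_pca": self.bic_curve_pca.tolist(),
            "bic_curve_gmm": self.bic_curve_gmm.tolist(),
            "labels": {str(k): int(v) for k, v in self.labels.items()},
            "seed": self.seed,
            "cluster_names": self.cluster_names,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "ClusterModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            n_pcs=p["n_pcs"],
            loadings=np.array(p["loadings"]),
            pca_mean=np.array(p["pca_mean"]),
            explained_variance_fractions=np.array(p["explained_variance_fractions"]),
            weights=np.array(p["weights"]),
            means=np.array(p["means"]),
            covariances=np.array(p["covariances"]),
            bic_curve_pca=np.array(p["bic_curve_pca"]),
            bic_curve_gmm=np.array(p["bic_curve_gmm"]),
            labels=pd.Series(p["labels"]).astype(int),
            seed=p["seed"],
            cluster_names=(
                {int(k): v for k, v in p["cluster_names"].items()}
                if p["cluster_names"]
                else None
            ),
        )


def _cv_bic_gmm(
    X: np.ndarray,
    n_components: int,
    folds: int,
    seed: int,
    n_init: int,
    reg_covar: float,
) -> float:
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    bics = []
    for train, test in kf.split(X):
        gm = GaussianMixture(
            n_components=n_components,
            covariance_type="full",
            n_init=n_init,
            reg_covar=reg_covar,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(X[train])
        ll = gm.score(X[test]) * len(test)
        p = _gmm_n_params(X.shape[1], n_components)
        bics.append(-2.0 * ll + p * np.log(len(test)))
    return float(np.mean(bics))


def fit_gmm(
    scores: pd.DataFrame | np.ndarray,
    krange: Sequence[int] = range(1, 8),
    folds: int = 5,
    seed: int = 0,
    n_init: int = 10,
    reg_covar: float = 1e-6,
    max_retries: int = 3,
) -> tuple[int, np.ndarray, GaussianMixture]:
    """Select the number of mixture components by fold-averaged BIC and
    refit the winning model on all cells.

    Returns ``(K, bic_curve, fitted_mixture)``; the curve is indexed by
    position in ``krange``.  An empty component in the final refit triggers
    reinitialization with a shifted seed, up to ``max_retries`` times.
    """
    X = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("scores contain non-finite values")
    krange = [k for k in krange if k <= X.shape[0]]
    curve = np.array(
        [_cv_bic_gmm(X, k, folds, seed, n_init, reg_covar) for k in krange]
    )
    best_k = krange[int(np.argmin(curve))]
    for attempt in range(max_retries + 1):
        gm = GaussianMixture(
            n_components=best_k,
            covariance_type="full",
            n_init=n_init,
            reg_covar=reg_covar,
            random_state=seed + attempt,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(X)
        labels = gm.predict(X)
        if len(np.unique(labels)) == best_k or attempt == max_retries:
            break
        warnings.warn("empty mixture component; refitting with new initialization")
    return best_k, curve, gm


def cluster_cells(
    features: FeatureMatrix | pd.DataFrame,
    kmax_pca: int = 9,
    krange_gmm: Sequence[int] = range(1, 8),
    folds: int = 5,
    seed: int = 0,
    n_pcs: int | None = None,
) -> tuple[ClusterModel, PreprocessReport]:
    """Full subtyping pipeline: preprocess, pick PCA order, pick K, label.

    ``n_pcs`` overrides the BIC-selected PCA order when given.
    """
    scaled, report = preprocess(features)
    chosen, bic_pca = select_pca_order(scaled, kmax=kmax_pca, folds=folds, seed=seed)
    if n_pcs is not None:
        chosen = n_pcs
    pca = PCA(n_components=chosen, svd_solver="full").fit(scaled.to_numpy())
    scores = pca.transform(scaled.to_numpy())
    best_k, bic_gmm, gm = fit_gmm(scores, krange=krange_gmm, folds=folds, seed=seed)
    labels = pd.Series(gm.predict(scores) + 1, index=scaled.index, name="label")
    model = ClusterModel(
        n_pcs=chosen,
        loadings=pca.components_.T,
        pca_mean=pca.mean_,
        explained_variance_fractions=pca.explained_variance_ratio_,
        weights=gm.weights_,
        means=gm.means_,
        covariances=gm.covariances_,
        bic_curve_pca=bic_pca,
        bic_curve_gmm=bic_gmm,
        labels=labels,
        seed=seed,
    )
    return model, report


def assign_new_cells(
    model: ClusterModel,
    report: PreprocessReport,
    new_features: FeatureMatrix | pd.DataFrame,
    mode: str = "frozen",
    original_features: FeatureMatrix | pd.DataFrame | None = None,
) -> pd.Series:
    """Label additional cells under an existing subtype model.

    ``mode="frozen"`` applies the stored log/scaling transform and PCA
    loadings, then assigns each cell to the maximum-responsibility mixture
    component.  ``mode="joint"`` pools the new cells with
    ``original_features`` and reruns the full pipeline, returning labels
    for every cell (component numbering may differ from the frozen model).
    """
    df = new_features.values if isinstance(new_features, FeatureMatrix) else new_features
    expected = set(report.feature_min.index) | set(report.dropped_columns)
    if not expected <= set(df.columns):
        missing = expected - set(df.columns)
        raise ValueError(f"new cells missing features: {sorted(missing)}")
    if mode == "frozen":
        scaled = report.transform(df)
        scores = model.project(scaled)
        return pd.Series(model.predict(scores), index=df.index, name="label")
    if mode == "joint":
        if original_features is None:
            raise ValueError("joint mode requires original_features")
        orig = (
            original_features.values
            if isinstance(original_features, FeatureMatrix)
            else original_features
        )
        pooled = pd.concat([orig, df[orig.columns]], axis=0)
        joint_model, _ = cluster_cells(pooled, seed=model.seed, n_pcs=model.n_pcs)
        return joint_model.labels
    raise ValueError(f"unknown mode {mode!r}")


def name_clusters(
    model: ClusterModel, features: FeatureMatrix | pd.DataFrame
) -> dict[int, str]:
    """Map mixture components to subtype names (ADP / HFF / Delayed).

    The component with the largest mean afterdepolarization is named ADP,
    the largest mean initial maximal rate HFF, and the longest mean
    first-spike latency at saturation Delayed; conflicts resolve in that
    priority order with a warning.  Models with K != 3 get generic names.
    """
    df = features.values if isinstance(features, FeatureMatrix) else features
    k = model.n_components
    if k != 3:
        names = {i + 1: f"cluster_{i + 1}" for i in range(k)}
        model.cluster_names = names
        return names
    sub = df.loc[model.labels.index]
    crit = {
        "ADP": sub.groupby(model.labels)["adp_amplitude"].mean(),
        "HFF": sub.groupby(model.labels)["fmax_init"].mean(),
        "Delayed": sub.groupby(model.labels)["first_spike_latency_sat"].mean(),
    }
    names: dict[int, str] = {}
    taken: set[int] = set()
    for subtype in ("ADP", "HFF", "Delayed"):  # priority order
        ranked = crit[subtype].sort_values(ascending=False)
        winner = next((c for c in ranked.index if c not in taken), None)
        if winner is None:  # pragma: no cover - k==3 guarantees a winner
            continue
        if winner != ranked.index[0]:
            warnings.warn(
                f"cluster {ranked.index[0]} wins two naming criteria; "
                f"{subtype} falls back to cluster {winner}"
            )
        names[int(winner)] = subtype
        taken.add(int(winner))
    model.cluster_names = names
    return names
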