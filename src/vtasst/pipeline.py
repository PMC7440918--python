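"""Cluster summary tables, group statistics, and the end-to-end pipeline.

``cluster_summary`` reproduces the style of a per-subtype summary table:
mean ± SEM per feature and cluster, plus an *unweighted* grand-mean row
(the arithmetic mean of the cluster means, not the pooled mean — the
convention used when quoting "average somatostatin-neuron" properties
across subtypes of very different sizes; a pooled, n-weighted variant is
available behind a flag).

``group_compare`` is a one-way ANOVA with Tukey HSD post-hoc pairwise
comparisons (Tukey-Kramer, valid for unequal group sizes).

``run_pipeline`` chains feature extraction (or a precomputed feature
table), preprocessing, PCA-order selection, mixture fitting, cluster
naming and summary generation, writing all artifacts to a directory.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import FeatureMatrix, cluster_cells, name_clusters

__all__ = ["cluster_summary", "grand_means", "group_compare", "run_pipeline"]

logger = logging.getLogger("vtasst")


def cluster_summary(
    features: FeatureMatrix | pd.DataFrame,
    labels: pd.Series | Sequence,
    weighted_grand_mean: bool = False,
) -> pd.DataFrame:
    """Per-cluster mean ± SEM table with a grand-mean row.

    Returns a DataFrame with a two-level column index (cluster, statistic)
    over ``mean``, ``sem`` and ``n``; the final ``grand_mean`` block holds
    the unweighted average of cluster means (or the pooled mean when
    ``weighted_grand_mean``).  Clusters with fewer than two cells get NaN
    SEM.
    """
    df = features.values if isinstance(features, FeatureMatrix) else features
    labels = pd.Series(np.asarray(labels), index=df.index, name="cluster")
    if labels.isna().any():
        raise ValueError("every cell must carry a cluster label")
    groups = df.groupby(labels)
    means = groups.mean()
    sems = groups.sem(ddof=1)
    ns = groups.size()
    for cl, n in ns.items():
        if n < 2:
            sems.loc[cl] = np.nan
    blocks = {}
    for cl in means.index:
        blocks[(str(cl), "mean")] = means.loc[cl]
        blocks[(str(cl), "sem")] = sems.loc[cl]
        blocks[(str(cl), "n")] = float(ns.loc[cl])
    if weighted_grand_mean:
        blocks[("grand_mean", "mean")] = df.mean()
    else:
        blocks[("grand_mean", "mean")] = means.mean(axis=0)
    out = pd.DataFrame(blocks)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["cluster", "stat"])
    return out


def grand_means(cluster_means: pd.DataFrame | Mapping[str, Sequence[float]]) -> pd.Series:
    """Unweighted grand mean across per-cluster feature means.

    Accepts a clusters x features frame (or feature -> per-cluster values
    mapping) and averages across clusters with equal weight.
    """
    df = pd.DataFrame(cluster_means)
    return df.mean(axis=0)


def group_compare(
    values: Sequence[float] | pd.Series,
    labels: Sequence,
    alpha: float = 0.05,
) -> dict:
    """One-way ANOVA with Tukey HSD pairwise post-hoc comparisons.

    Returns ``{"F", "p", "df_between", "df_within", "tukey"}`` where
    ``tukey`` is a tidy frame of pairwise mean differences and adjusted
    p-values.  When every group is constant with equal means, F is
    undefined and reported as NaN with p = 1.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least two groups")
    groups = [values[labels == g] for g in uniq]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least two observations")
    df_between = uniq.size - 1
    df_within = values.size - uniq.size
    if all(np.allclose(g, g[0]) for g in groups):
        if np.allclose([g[0] for g in groups], groups[0][0]):
            return {
                "F": np.nan,
                "p": 1.0,
                "df_between": df_between,
                "df_within": df_within,
                "tukey": None,
            }
    F, p = stats.f_oneway(*groups)
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    tukey = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    return {
        "F": float(F),
        "p": float(p),
        "df_between": df_between,
        "df_within": df_within,
        "tukey": tukey,
    }


_KNOWN_STAGES = {"extract", "cluster", "summary"}


def run_pipeline(config: Mapping | str | Path, out_dir=None) -> Path:
    """Run extract → preprocess → PCA selection → GMM → naming → summary.

    ``config`` is a mapping (or a YAML file path) with keys:

    * ``seed`` (int) — controls fold assignment and mixture initialization;
    * ``out_dir`` — artifact directory (may also be passed directly);
    * input: either ``features_csv`` (a cells x features table, index
      column ``cell_id``) or ``synthetic: {subtypes: ..., seed: ...}`` to
      generate a cohort with the built-in generator;
    * optional ``stages`` — subset of ``{"extract", "cluster", "summary"}``;
    * optional ``ladder_glob`` — HDF5 sweep-ladder files for the extract
      stage.

    Writes ``features.csv``, ``labels.csv``, ``model.json``,
    ``summary.json`` and ``pipeline.log``; returns the artifact directory.
    Reruns with the same inputs and seed are byte-identical.
    """
    import yaml

    if not isinstance(config, Mapping):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = dict(config)
    stages = set(cfg.get("stages", _KNOWN_STAGES))
    unknown = stages - _KNOWN_STAGES
    if unknown:
        raise ValueError(f"unknown pipeline stages: {sorted(unknown)}")
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("out_dir", "vtasst_out"))
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    try:
        # ------------------------------------------------------ input stage
        truth = None
        if "features_csv" in cfg:
            df = pd.read_csv(cfg["features_csv"], index_col="cell_id")
            features = FeatureMatrix(values=df)
        elif "ladder_glob" in cfg and "extract" in stages:
            from .features import extract_features, features_to_frame
            from .io import read_sweep_ladder

            paths = sorted(Path().glob(cfg["ladder_glob"]))
            if not paths:
                raise FileNotFoundError(f"no ladders match {cfg['ladder_glob']}")
            vecs, ids = [], []
            for p in paths:
                ladder = read_sweep_ladder(p, "hdf5")
                vecs.append(extract_features(ladder))
                ids.append(ladder.cell_id)
            features = FeatureMatrix(values=features_to_frame(vecs, ids))
        else:
            from .synthetic import default_cohort, synth_feature_table

            syn = cfg.get("synthetic", {})
            features = synth_feature_table(
                specs=syn.get("subtypes", default_cohort()),
                seed=int(syn.get("seed", seed)),
            )
            truth = features.true_labels
        logger.info("features: %d cells x %d columns", *features.values.shape)
        features.values.to_csv(out / "features.csv", index_label="cell_id")

        # ---------------------------------------------------- cluster stage
        if "cluster" in stages:
            try:
                model, report = cluster_cells(features, seed=seed)
            except Exception as exc:
                raise RuntimeError(f"stage 'cluster' failed: {exc}") from exc
            names = name_clusters(model, features)
            labels = model.labels.map(names).rename("subtype")
            pd.DataFrame(
                {"label": model.labels, "subtype": labels}
            ).to_csv(out / "labels.csv", index_label="cell_id")
            model.save(out / "model.json")
            logger.info(
                "clustering: %d PCs, K=%d, %d outliers removed",
                model.n_pcs,
                model.n_components,
                len(report.outlier_cell_ids),
            )
        else:
            model = labels = None

        # ---------------------------------------------------- summary stage
        if "summary" in stages and model is not None:
            table = cluster_summary(
                features.values.loc[model.labels.index], labels
            )
            summary = {
                "n_cells": int(features.values.shape[0]),
                "n_outliers": len(report.outlier_cell_ids),
                "n_pcs": int(model.n_pcs),
                "n_clusters": int(model.n_components),
                "cluster_names": {str(k): v for k, v in names.items()},
                "cluster_sizes": {
                    v: int((labels == v).sum()) for v in sorted(set(labels))
                },
                "explained_variance_fractions": [
                    round(float(f), 4) for f in model.explained_variance_fractions
                ],
                "grand_means": {
                    k: round(float(v), 4)
                    for k, v in table[("grand_mean", "mean")].items()
                },
            }
            if truth is not None:
                from sklearn.metrics import adjusted_rand_score

                summary["ari_vs_truth"] = round(
                    float(adjusted_rand_score(truth.loc[labels.index], labels)), 4
                )
            with open(out / "summary.json", "w") as fh:
                json.dump(summary, fh, indent=2, sort_keys=True)
            logger.info("summary: %s", summary["cluster_sizes"])
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
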