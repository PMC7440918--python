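"""Patch-seq quality control, depth normalization and cluster assignment.

The stages mirror a Patch-seq transcriptomic workflow downstream of
alignment and gene counting:

1. **QC** — discard cells with fewer than 75,500 total reads, then cells
   with alignment below 50% (both strict inequalities).
2. **Depth normalization** — find genes that are both significantly
   correlated with the molecular count in a reference single-cell dataset
   and detected (count >= 1) in every Patch-seq cell; reduce the Patch-seq
   expression of that gene set to its first principal component, orient it
   to increase with sequencing depth, and divide each cell's counts by
   (PC1 + 1).
3. **Assignment** — score each cell against reference cluster centroids by
   correlation and calibrate the scores with a label-permutation bootstrap;
   a cell may be assigned to several clusters (p < 0.05) or to none.
4. **Cross-dataset comparison** — rescale per-dataset gene means so the
   somatostatin (Sst) gene sits at 1000, making regional datasets
   comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PatchSeqDataset",
    "ReferenceDataset",
    "NormalizationFactors",
    "qc_filter",
    "normalization_factors",
    "normalize_counts",
    "bootstrap_assign",
    "sst_normalized_means",
    "read_counts_csv",
    "write_counts_csv",
    "read_counts_mtx",
    "write_counts_mtx",
]

MIN_TOTAL_READS = 75_500
MIN_ALIGNMENT_RATE = 0.5


@dataclass
class PatchSeqDataset:
    """Gene x cell count matrix with per-cell sequencing metadata."""

    counts: np.ndarray  # genes x cells, nonnegative
    gene_names: list
    cell_ids: list
    total_reads: np.ndarray
    alignment_rate: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.total_reads = np.asarray(self.total_reads, dtype=float)
        self.alignment_rate = np.asarray(self.alignment_rate, dtype=float)
        g, c = self.counts.shape
        if len(self.gene_names) != g or len(self.cell_ids) != c:
            raise ValueError("counts shape inconsistent with gene/cell names")
        if self.total_reads.shape != (c,) or self.alignment_rate.shape != (c,):
            raise ValueError("metadata length inconsistent with cell count")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if np.any((self.alignment_rate < 0) | (self.alignment_rate > 1)):
            raise ValueError("alignment rates must lie in [0, 1]")

    def subset_cells(self, cell_ids: Sequence[str]) -> "PatchSeqDataset":
        idx = [self.cell_ids.index(c) for c in cell_ids]
        return PatchSeqDataset(
            counts=self.counts[:, idx],
            gene_names=list(self.gene_names),
            cell_ids=list(cell_ids),
            total_reads=self.total_reads[idx],
            alignment_rate=self.alignment_rate[idx],
        )


@dataclass
class ReferenceDataset:
    """Cluster-labelled reference expression dataset."""

    expression: np.ndarray  # genes x cells
    gene_names: list
    cell_ids: list
    cluster_labels: np.ndarray
    molecular_count: np.ndarray  # per-cell total molecules (UMIs)

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.cluster_labels = np.asarray(self.cluster_labels)
        self.molecular_count = np.asarray(self.molecular_count, dtype=float)
        g, c = self.expression.shape
        if len(self.gene_names) != g or len(self.cell_ids) != c:
            raise ValueError("expression shape inconsistent with gene/cell names")
        if self.cluster_labels.shape != (c,):
            raise ValueError("one cluster label per cell required")

    def centroids(self) -> pd.DataFrame:
        """Mean expression per cluster (genes x clusters)."""
        df = pd.DataFrame(self.expression, index=self.gene_names)
        return df.T.groupby(self.cluster_labels).mean().T


@dataclass
class NormalizationFactors:
    """PC1-derived per-cell depth-normalization factors."""

    gene_set: list
    pc1: pd.Series
    factors: pd.Series  # pc1 + 1, all > 0


def qc_filter(
    ds: PatchSeqDataset,
    min_reads: int = MIN_TOTAL_READS,
    min_alignment: float = MIN_ALIGNMENT_RATE,
) -> tuple[list, dict]:
    """Two-stage sequencing QC.

    Cells with ``total_reads < min_reads`` are discarded first; among the
    survivors, cells with ``alignment_rate < min_alignment`` are discarded.
    Both comparisons are strict, so a cell at exactly the floor is kept.
    Returns ``(kept_ids, {discarded_id: reason})``.
    """
    kept, discarded = [], {}
    for cid, reads, align in zip(ds.cell_ids, ds.total_reads, ds.alignment_rate):
        if reads < min_reads:
            discarded[cid] = "low_reads"
        elif align < min_alignment:
            discarded[cid] = "low_alignment"
        else:
            kept.append(cid)
    return kept, discarded


def normalization_factors(
    ds: PatchSeqDataset,
    ref: ReferenceDataset,
    alpha: float = 0.05,
    score_scale: str = "half_max_abs",
) -> NormalizationFactors:
    """Derive per-cell depth-normalization factors from a reference dataset.

    The gene set is the intersection of (a) genes whose reference
    expression correlates with the per-cell molecular count (Pearson,
    Benjamini-Hochberg adjusted p < ``alpha``) and (b) genes detected at
    least once in every Patch-seq cell.  Patch-seq expression restricted to
    the set is reduced to its first principal component, the component is
    oriented to correlate positively with per-cell total counts, and the
    factor is PC1 + 1.

    ``score_scale="half_max_abs"`` (default) rescales the PC1 scores to
    half their maximum absolute value before adding 1, which keeps every
    factor positive while preserving the ordering; ``"raw"`` uses the raw
    scores, in which case any factor <= 0 is a hard error naming the cells.
    """
    common = [g for g in ds.gene_names if g in set(ref.gene_names)]
    if not common:
        raise ValueError("no shared genes between Patch-seq and reference")
    ref_idx = {g: i for i, g in enumerate(ref.gene_names)}
    ps_idx = {g: i for i, g in enumerate(ds.gene_names)}

    pvals = np.array(
        [
            stats.pearsonr(ref.expression[ref_idx[g]], ref.molecular_count).pvalue
            for g in common
        ]
    )
    significant = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    corr_genes = {g for g, s in zip(common, significant) if s}
    ubiquitous = {g for g in common if np.all(ds.counts[ps_idx[g]] >= 1)}
    gene_set = sorted(corr_genes & ubiquitous)
    if not gene_set:
        raise ValueError("empty intersection of correlated and ubiquitous genes")

    X = ds.counts[[ps_idx[g] for g in gene_set]].T.astype(float)  # cells x genes
    pc1 = PCA(n_components=1, svd_solver="full").fit_transform(X)[:, 0]
    totals = ds.counts.sum(axis=0)
    orient = np.corrcoef(pc1, totals)[0, 1]
    if orient < 0:
        pc1 = -pc1
    if score_scale == "half_max_abs":
        m = np.max(np.abs(pc1))
        if m > 0:
            pc1 = pc1 / (2.0 * m)
    elif score_scale != "raw":
        raise ValueError(f"unknown score_scale {score_scale!r}")
    factors = pc1 + 1.0
    if np.any(factors <= 0):
        bad = [ds.cell_ids[i] for i in np.flatnonzero(factors <= 0)]
        raise ValueError(f"nonpositive normalization factors for cells {bad}")
    idx = pd.Index(ds.cell_ids, name="cell_id")
    return NormalizationFactors(
        gene_set=gene_set,
        pc1=pd.Series(pc1, index=idx, name="pc1"),
        factors=pd.Series(factors, index=idx, name="factor"),
    )


def normalize_counts(ds: PatchSeqDataset, factors: NormalizationFactors) -> pd.DataFrame:
    """Divide each cell's counts by its normalization factor."""
    missing = [c for c in ds.cell_ids if c not in factors.factors.index]
    if missing:
        raise KeyError(f"no normalization factor for cells {missing}")
    f = factors.factors.loc[ds.cell_ids].to_numpy()
    return pd.DataFrame(
        ds.counts / f[None, :], index=ds.gene_names, columns=ds.cell_ids
    )


def bootstrap_assign(
    profiles: pd.DataFrame,
    ref: ReferenceDataset,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    min_shared_genes: int = 50,
    null: str = "gene_perm",
) -> pd.DataFrame:
    """Assign cells to reference clusters with permutation-calibrated
    correlation scores.

    ``profiles`` is genes x cells (normalized expression).  The score of a
    cell against a cluster is the Pearson correlation of the cell profile
    with the cluster centroid over the shared genes.  The default null
    (``null="gene_perm"``) rescores each cell against gene-permuted
    centroids, which calibrates the score spread a structureless profile
    would attain; ``null="label_perm"`` instead recomputes centroids from
    permuted reference cell labels (note that permuted-label centroids
    collapse toward the global mean profile, giving an anti-conservative
    test — retained for comparison only).  The p-value is the fraction of
    null scores at least as large as the observed one.  A cell is assigned
    to every cluster with p < ``alpha`` and marked unassigned when none
    passes.

    Returns a tidy DataFrame with columns ``cell_id, cluster, score,
    p_value, assigned``.
    """
    shared = [g for g in profiles.index if g in set(ref.gene_names)]
    if len(shared) < min_shared_genes:
        raise ValueError(
            f"only {len(shared)} shared genes; need at least {min_shared_genes}"
        )
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives coarse p-values")
    rng = np.random.default_rng(seed)

    ref_expr = pd.DataFrame(ref.expression, index=ref.gene_names).loc[shared].to_numpy()
    cells = profiles.loc[shared].to_numpy()  # genes x cells
    labels = np.asarray(ref.cluster_labels)
    clusters = [c for c in pd.unique(labels)]

    def _centroids(lab: np.ndarray) -> np.ndarray:
        return np.column_stack([ref_expr[:, lab == c].mean(axis=1) for c in clusters])

    def _zscore(a: np.ndarray) -> np.ndarray:
        return (a - a.mean(axis=0)) / np.maximum(a.std(axis=0), 1e-12)

    n_genes = len(shared)
    cz = _zscore(cells)  # constant across permutations

    def _corr_with(b: np.ndarray) -> np.ndarray:
        """cells x clusters correlation matrix against centroid columns."""
        return cz.T @ _zscore(b) / n_genes

    cent = _centroids(labels)
    degenerate = cent.std(axis=0) < 1e-12
    if degenerate.any():
        warnings.warn(
            f"skipping degenerate centroids: {[c for c, d in zip(clusters, degenerate) if d]}"
        )
    observed = _corr_with(cent)  # cells x clusters

    exceed = np.zeros_like(observed)
    if null == "gene_perm":
        bz = _zscore(cent)
        for _ in range(n_boot):
            perm = rng.permutation(n_genes)
            exceed += (cz.T @ bz[perm] / n_genes) >= observed
    elif null == "label_perm":
        for _ in range(n_boot):
            perm = rng.permutation(labels)
            exceed += _corr_with(_centroids(perm)) >= observed
    else:
        raise ValueError(f"unknown null scheme {null!r}")
    pvals = (exceed + 1.0) / (n_boot + 1.0)

    records = []
    for i, cid in enumerate(profiles.columns):
        for j, cl in enumerate(clusters):
            if degenerate[j]:
                continue
            records.append(
                {
                    "cell_id": cid,
                    "cluster": cl,
                    "score": observed[i, j],
                    "p_value": pvals[i, j],
                    "assigned": bool(pvals[i, j] < alpha),
                }
            )
    return pd.DataFrame.from_records(records)


def sst_normalized_means(
    datasets: Sequence[tuple[str, pd.Series]],
    sst_gene: str = "Sst",
    target: float = 1000.0,
) -> pd.DataFrame:
    """Scale per-dataset gene means so the Sst gene equals ``target``.

    ``datasets`` is a list of (name, gene-mean Series).  The output table
    is aligned on the union of genes; genes absent from a dataset are NaN.
    """
    cols = {}
    for name, vec in datasets:
        if sst_gene not in vec.index:
            raise KeyError(f"dataset {name!r} lacks the {sst_gene!r} gene")
        sst = float(vec[sst_gene])
        if sst <= 0:
            raise ValueError(f"dataset {name!r} has nonpositive {sst_gene!r} mean")
        cols[name] = vec * (target / sst)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------


def write_counts_csv(ds: PatchSeqDataset, counts_path, metadata_path) -> None:
    """Dense CSV counts (genes x cells) plus a per-cell metadata CSV."""
    pd.DataFrame(ds.counts, index=ds.gene_names, columns=ds.cell_ids).to_csv(
        counts_path, index_label="gene"
    )
    pd.DataFrame(
        {
            "cell_id": ds.cell_ids,
            "total_reads": ds.total_reads,
            "alignment_rate": ds.alignment_rate,
        }
    ).to_csv(metadata_path, index=False)


def read_counts_csv(counts_path, metadata_path) -> PatchSeqDataset:
    counts = pd.read_csv(counts_path, index_col="gene")
    meta = pd.read_csv(metadata_path).set_index("cell_id").loc[counts.columns]
    return PatchSeqDataset(
        counts=counts.to_numpy(),
        gene_names=list(counts.index),
        cell_ids=list(counts.columns),
        total_reads=meta["total_reads"].to_numpy(),
        alignment_rate=meta["alignment_rate"].to_numpy(),
    )


def write_counts_mtx(ds: PatchSeqDataset, prefix) -> None:
    """MatrixMarket triple: ``<prefix>.mtx``, ``<prefix>.genes.txt``,
    ``<prefix>.barcodes.txt`` plus ``<prefix>.metadata.csv``."""
    from pathlib import Path

    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    prefix = Path(prefix)
    mmwrite(str(prefix) + ".mtx", csr_matrix(ds.counts))
    Path(str(prefix) + ".genes.txt").write_text("\n".join(map(str, ds.gene_names)) + "\n")
    Path(str(prefix) + ".barcodes.txt").write_text("\n".join(map(str, ds.cell_ids)) + "\n")
    pd.DataFrame(
        {
            "cell_id": ds.cell_ids,
            "total_reads": ds.total_reads,
            "alignment_rate": ds.alignment_rate,
        }
    ).to_csv(str(prefix) + ".metadata.csv", index=False)


def read_counts_mtx(prefix) -> PatchSeqDataset:
    from pathlib import Path

    from scipy.io import mmread

    prefix = Path(prefix)
    counts = np.asarray(mmread(str(prefix) + ".mtx").todense())
    genes = Path(str(prefix) + ".genes.txt").read_text().splitlines()
    cells = Path(str(prefix) + ".barcodes.txt").read_text().splitlines()
    meta = pd.read_csv(str(prefix) + ".metadata.csv").set_index("cell_id").loc[cells]
    return PatchSeqDataset(
        counts=counts,
        gene_names=genes,
        cell_ids=cells,
        total_reads=meta["total_reads"].to_numpy(),
        alignment_rate=meta["alignment_rate"].to_numpy(),
    )
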