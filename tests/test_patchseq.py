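"""Patch-seq QC, depth normalization, bootstrap assignment, and the
cross-dataset Sst-anchored comparison."""

import numpy as np
import pandas as pd
import pytest

import vtasst as v
from vtasst.patchseq import PatchSeqDataset, ReferenceDataset


def _tiny_ds(reads, aligns):
    n = len(reads)
    return PatchSeqDataset(
        counts=np.ones((4, n), dtype=int),
        gene_names=[f"g{i}" for i in range(4)],
        cell_ids=[f"c{i}" for i in range(n)],
        total_reads=np.array(reads, dtype=float),
        alignment_rate=np.array(aligns, dtype=float),
    )


class TestQcFilter:
    def test_read_floor_is_strict(self):
        ds = _tiny_ds([75_499, 75_500], [0.9, 0.9])
        kept, disc = v.qc_filter(ds)
        assert kept == ["c1"]
        assert disc == {"c0": "low_reads"}

    def test_alignment_floor_is_strict(self):
        ds = _tiny_ds([1e6, 1e6], [0.50, 0.499])
        kept, disc = v.qc_filter(ds)
        assert kept == ["c0"]
        assert disc == {"c1": "low_alignment"}

    def test_default_synthetic_cohort_keeps_61_of_69(self, patchseq_data):
        ps, _, truth = patchseq_data
        kept, disc = v.qc_filter(ps)
        assert len(ps.cell_ids) == 69 and len(kept) == 61
        assert sorted(c for c, r in disc.items() if r == "low_reads") == sorted(
            truth["low_read_cells"]
        )
        assert sorted(c for c, r in disc.items() if r == "low_alignment") == sorted(
            truth["low_alignment_cells"]
        )

    def test_monotone_in_both_thresholds(self, patchseq_data):
        ps, _, _ = patchseq_data
        base = len(v.qc_filter(ps)[0])
        assert len(v.qc_filter(ps, min_reads=200_000)[0]) <= base
        assert len(v.qc_filter(ps, min_alignment=0.8)[0]) <= base


class TestNormalization:
    def test_constructed_twenty_gene_set_recovered(self):
        """Exactly 20 reference genes correlate with molecular count and are
        ubiquitous in the query cells; brute-force per-gene correlation
        confirms the selected set."""
        rng = np.random.default_rng(0)
        n_genes, n_ref, n_cells = 200, 150, 30
        depth = rng.lognormal(0, 0.5, n_ref)
        expr = rng.poisson(5.0, (n_genes, n_ref)).astype(float)
        expr[:20] = rng.poisson(30.0 * depth[None, :], (20, n_ref))
        ref = ReferenceDataset(
            expression=expr,
            gene_names=[f"g{i}" for i in range(n_genes)],
            cell_ids=[f"r{i}" for i in range(n_ref)],
            cluster_labels=np.repeat(["a", "b", "c"], 50),
            molecular_count=expr.sum(axis=0),
        )
        counts = rng.poisson(2.0, (n_genes, n_cells))
        counts[:20] += 5  # ubiquitous in every query cell
        counts[20:][rng.random((180, n_cells)) < 0.4] = 0
        ds = PatchSeqDataset(
            counts=counts,
            gene_names=ref.gene_names,
            cell_ids=[f"c{i}" for i in range(n_cells)],
            total_reads=np.full(n_cells, 1e6),
            alignment_rate=np.full(n_cells, 0.9),
        )
        nf = v.normalization_factors(ds, ref)
        from scipy import stats

        oracle = {
            g
            for i, g in enumerate(ref.gene_names)
            if stats.pearsonr(expr[i], ref.molecular_count).pvalue < 1e-4
            and np.all(counts[i] >= 1)
        }
        assert set(nf.gene_set) >= {f"g{i}" for i in range(20)} & oracle
        assert len(set(nf.gene_set) - {f"g{i}" for i in range(20)}) <= 3

    def test_factors_positive_and_centered(self, patchseq_data):
        ps, ref, truth = patchseq_data
        kept, _ = v.qc_filter(ps)
        nf = v.normalization_factors(ps.subset_cells(kept), ref)
        assert (nf.factors > 0).all()
        # pc1 = 0 -> factor exactly 1 (identity point of the transform)
        assert np.allclose(nf.factors - nf.pc1, 1.0)
        # designated depth-gene set is recovered almost completely
        recovered = set(nf.gene_set) & set(truth["depth_genes"])
        assert len(recovered) >= 0.9 * len(truth["depth_genes"])
        # factors track the latent per-cell depth factor
        depth = pd.Series(truth["depth_factor"], index=ps.cell_ids).loc[kept]
        assert np.corrcoef(nf.factors, depth)[0, 1] > 0.8

    def test_normalize_counts_arithmetic(self):
        ds = _tiny_ds([1e6, 1e6], [0.9, 0.9])
        ds.counts = np.array([[4, 6], [0, 2], [8, 0], [2, 2]])
        nf = v.NormalizationFactors(
            gene_set=["g0"],
            pc1=pd.Series([1.0, 0.0], index=ds.cell_ids),
            factors=pd.Series([2.0, 1.0], index=ds.cell_ids),
        )
        out = v.normalize_counts(ds, nf)
        assert list(out["c0"]) == [2.0, 0.0, 4.0, 1.0]
        assert list(out["c1"]) == [6.0, 2.0, 0.0, 2.0]
        # zero pattern preserved
        assert ((out.to_numpy() == 0) == (ds.counts == 0)).all()

    def test_missing_factor_is_schema_error(self):
        ds = _tiny_ds([1e6, 1e6], [0.9, 0.9])
        nf = v.NormalizationFactors(
            gene_set=[], pc1=pd.Series([0.0], index=["c0"]),
            factors=pd.Series([1.0], index=["c0"]),
        )
        with pytest.raises(KeyError, match="c1"):
            v.normalize_counts(ds, nf)


@pytest.fixture(scope="module")
def normalized(patchseq_data):
    ps, ref, truth = patchseq_data
    kept, _ = v.qc_filter(ps)
    sub = ps.subset_cells(kept)
    nf = v.normalization_factors(sub, ref)
    return v.normalize_counts(sub, nf), ref, truth, kept


class TestBootstrapAssign:
    def test_cells_match_their_generating_cluster(self, normalized):
        norm, ref, truth, kept = normalized
        res = v.bootstrap_assign(norm, ref, n_boot=300, seed=0)
        lab = pd.Series(
            truth["patchseq_clusters"],
            index=[f"ps{i:03d}" for i in range(len(truth["patchseq_clusters"]))],
        ).loc[kept]
        hits = sum(
            lab[c] in set(res[(res.cell_id == c) & res.assigned]["cluster"])
            for c in kept
        )
        assert hits >= 0.95 * len(kept)

    def test_centroid_profile_assigned_to_its_cluster(self, normalized):
        _, ref, _, _ = normalized
        cent = ref.centroids()
        probe = cent.iloc[:, [0]]
        probe.columns = ["probe"]
        res = v.bootstrap_assign(probe, ref, n_boot=300, seed=1)
        row = res[(res.cell_id == "probe") & (res.cluster == cent.columns[0])]
        assert bool(row["assigned"].iloc[0]) and float(row["p_value"].iloc[0]) < 0.05

    def test_blended_profile_assigned_to_both_parents(self, normalized):
        norm, ref, _, _ = normalized
        cent = ref.centroids()
        blend = 0.5 * cent.iloc[:, 0] + 0.5 * cent.iloc[:, 1]
        probe = pd.DataFrame({"blend": blend})
        res = v.bootstrap_assign(probe, ref, n_boot=300, seed=2)
        assigned = set(res[res.assigned]["cluster"])
        assert {cent.columns[0], cent.columns[1]} <= assigned

    def test_too_few_shared_genes_rejected(self, normalized):
        norm, ref, _, _ = normalized
        with pytest.raises(ValueError, match="shared genes"):
            v.bootstrap_assign(norm.iloc[:10], ref, n_boot=100)


class TestSstNormalizedMeans:
    def test_scaling_to_target(self):
        vec = pd.Series({"Sst": 500.0, "geneX": 50.0})
        out = v.sst_normalized_means([("ctx", vec)])
        assert out.loc["Sst", "ctx"] == 1000.0
        assert out.loc["geneX", "ctx"] == 100.0

    def test_already_normalized_unchanged(self):
        vec = pd.Series({"Sst": 1000.0, "geneY": 3.0})
        out = v.sst_normalized_means([("mid", vec)])
        assert out.loc["geneY", "mid"] == 3.0

    def test_union_alignment_and_sst_anchor(self):
        a = pd.Series({"Sst": 10.0, "g1": 1.0})
        b = pd.Series({"Sst": 2000.0, "g2": 4.0})
        c = pd.Series({"Sst": 77.0, "g1": 7.0, "g2": 7.0})
        out = v.sst_normalized_means([("A", a), ("B", b), ("C", c)])
        assert (out.loc["Sst"] == 1000.0).all()
        assert np.isnan(out.loc["g2", "A"])

    def test_zero_sst_is_an_error(self):
        with pytest.raises(ValueError):
            v.sst_normalized_means([("bad", pd.Series({"Sst": 0.0}))])
        with pytest.raises(KeyError):
            v.sst_normalized_means([("worse", pd.Series({"Gad1": 5.0}))])


def test_mtx_and_csv_round_trips(tmp_path, patchseq_data):
    ps, _, _ = patchseq_data
    v.patchseq.write_counts_csv(ps, tmp_path / "c.csv", tmp_path / "m.csv")
    back = v.patchseq.read_counts_csv(tmp_path / "c.csv", tmp_path / "m.csv")
    assert np.array_equal(back.counts, ps.counts)
    assert back.cell_ids == ps.cell_ids

    v.patchseq.write_counts_mtx(ps, tmp_path / "ps")
    back2 = v.patchseq.read_counts_mtx(tmp_path / "ps")
    assert np.array_equal(back2.counts, ps.counts)
    assert back2.gene_names == ps.gene_names
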