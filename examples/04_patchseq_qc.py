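"""Patch-seq quality control, depth normalization, and cluster assignment.

Generates a 69-cell Patch-seq cohort with the stated sequencing-QC margins
(5 cells under the 75,500-read floor, 3 under 50% alignment) plus a
cluster-labelled reference dataset; then filters, derives the PC1-based
per-cell depth-normalization factors from reference-correlated genes,
normalizes, and assigns cells to reference clusters with a
permutation-calibrated bootstrap.
"""

import pandas as pd

import vtasst as v

ps, ref, truth = v.synth_patchseq(seed=3)
kept, discarded = v.qc_filter(ps)
print(f"QC: kept {len(kept)}/{len(ps.cell_ids)} cells "
      f"({pd.Series(list(discarded.values())).value_counts().to_dict()})")

sub = ps.subset_cells(kept)
nf = v.normalization_factors(sub, ref)
print(f"depth-normalization gene set: {len(nf.gene_set)} genes; "
      f"factors span {nf.factors.min():.2f}..{nf.factors.max():.2f} (all > 0)")

norm = v.normalize_counts(sub, nf)
res = v.bootstrap_assign(norm, ref, n_boot=500, seed=0)
per_cell = res[res.assigned].groupby("cell_id")["cluster"].apply(list)
multi = (per_cell.str.len() > 1).sum()
unassigned = len(kept) - len(per_cell)
print(f"assignment: {len(per_cell)} cells assigned "
      f"({multi} to more than one cluster), {unassigned} unassigned")
print(per_cell.head(5).to_string())
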