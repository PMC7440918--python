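# Methods notes

This note records the models, conventions and numerical choices behind
`vtasst`, in the spirit of a statistical-software methods appendix: what is
computed, what was genuinely a design choice, and what passing the test
suite does and does not demonstrate.

## Current-clamp protocol and containers

A *sweep ladder* is one cell's set of voltage responses to square current
steps (defaults: 800 ms steps, −100 → +600 pA in 10 pA increments,
10 kHz sampling). Structural invariants — equal trace lengths, strictly
increasing currents with a constant increment, positive dt — are enforced
at construction. The canonical on-disk form is HDF5
(`/cells/<id>/voltage` with attribute arrays), chosen because one
self-describing container holds a whole experiment; a CSV long format
(`cell_id,sweep_index,current_pa,time_ms,voltage_mv`) round-trips to six
decimals for interchange. Recording-level QC excludes depolarized cells
(RMP above −50 mV) and unstable cells (per-sweep baseline SD above 6 mV);
both are strict inequalities. The per-sweep baseline is the pre-step
segment [0, step_onset), the only segment guaranteed current-free; whether
the original convention measured baselines there or on inter-sweep holding
periods is not recoverable, so this is a documented choice.

## Spike detection and the 25 features

dV/dt is computed by central differences after 3-point moving-average
smoothing; bare differencing at 10 kHz is noise-dominated. The AP
threshold is the first sample of the suprathreshold (>10 mV/ms) run
preceding a peak, refined forward to the first raw-slope crossing to undo
the one-sample bias the smoothing introduces. A deflection counts as a
spike only if its peak rises ≥20 mV above threshold (rejects ADP bumps and
noise) and dominates the following 2 ms (the absolute refractory period;
rejects split detection runs on steep inter-spike recoveries). The AHP
trough is located on the smoothed trace and refined on raw samples (±2)
to undo the corner bias. The ADP search runs from the trough to the next
spike threshold, the trough + 100 ms, or the step end, whichever is first;
the decision uses a ~2 ms moving average, and a maximum counts as a bump
only if it exceeds the trough by ≥0.5 mV **and** the trace falls ≥0.5 mV
below it again inside the window — without the fall-back condition, any
noisy monotone recovery toward baseline would register as a spurious ADP
in every non-ADP cell. Half-width is measured by linear interpolation of
the level crossings at threshold + amplitude/2.

Passive properties: input resistance is the least-squares slope of
steady-state voltage (last 50 ms of the step) against injected current
over all spike-free sweeps; sag is the ratio of that steady-state mean to
the most negative voltage of the −100 pA step (the literal
absolute-voltage reading; a deflection-relative variant would be a
one-line change); τ is a single-exponential fit over [2, 200] ms of the
−100 pA step onset, excluding the first 2 ms of capacitive transient.

The saturated sweep is the one with the most spikes, ties broken toward
the lowest current. F<sub>max,ss</sub> uses the last four ISIs; with fewer
than five spikes it degrades to the mean of all ISIs, and with fewer than
two spikes the rate fields are flagged missing. The 25-feature roster
(passive 5, rheobase-sweep 10, saturated-sweep 10) includes the
saturated-sweep AP amplitude, AHP amplitude and ISI coefficient of
variation; the roster is configurable since the original 25 are not
individually enumerated anywhere authoritative.

## Subtype clustering

Preprocessing: natural-log transforms — log(x+1) for counts and the ADP
latency (which can be 0), log(x) for strictly positive latencies; a single
outlier pass discards any cell farther than 5 IQR from a feature median on
the transformed-but-unscaled scale; min-max scaling to [0, 1]; constant
columns are dropped with a warning.

"BIC with cross-validation" is made precise as: for each candidate model
order, fit on four folds, evaluate the held-out log-likelihood on the
fifth, penalize with the full model's parameter count
(−2·LL + p·ln n<sub>test</sub>), and average over folds. The PCA
likelihood is the probabilistic-PCA observation model (as implemented by
scikit-learn's `PCA.score`), with p = dk − k(k−1)/2 + d + 1; the mixture
uses full covariances with 10 initializations and 1e−6 diagonal
regularization. Both selections are verified in the tests against an
independent brute-force enumeration of the same criterion. Fold assignment
and initialization derive from the user seed, making the pipeline
deterministic; labels are stable (ARI = 1) under cell- and feature-order
permutation.

Cluster naming is a deterministic heuristic: largest mean ADP amplitude →
ADP, largest mean initial rate → HFF, longest mean saturated latency →
Delayed, resolved in that priority order with a warning on conflicts
(which do occur in synthetic cohorts, because the delayed subtype's
initial-rate spread is enormous). New cells can be labelled either under
the frozen transform + mixture (posterior assignment) or by pooled refit.

## Synthetic cohorts and trace templates

The feature-table generator draws each feature independently from a
Gaussian truncated at physical bounds, per subtype, with SD = SEM·√n where
the source statistic is a standard error. Inter-feature correlation is
deliberately ignored by default (no covariances are reported to emulate);
a covariance hook exists. Features missing from the published summary
received one-time realistic defaults (membrane τ 15/12/18 ms, ADP latency
20 ms, saturated AP amplitude ≈ rheobase amplitude − 15 mV, saturated AHP
20/28/18 mV, ISI CV 0.45/0.35/0.15), chosen for plausibility and left
alone thereafter.

Trace ladders are rendered from closed-form piecewise templates so that
every feature has an exact ground truth: linear spike flanks whose
geometry encodes threshold, amplitude, half-width, decay and AHP depth; a
half-cosine ADP bump; a 5 ms linear "foot" (4 mV/ms, below the detection
slope) leading into each isolated spike; geometric ISI ramps ending in
four steady-state ISIs so that the early-ISI and late-ISI rate definitions
are exact; RC relaxations for passive segments. The −100 pA sweep charges
single-exponentially to its trough for 200 ms and only then relaxes to the
sag steady state, so the stated τ-fit window sees a pure exponential —
a deliberate idealization (real sag peaks earlier). Spike anchors snap to
the sample grid so peaks and troughs are representable; the emitted truth
uses the snapped values and the realized (possibly step-truncated)
schedules. Additive white noise (default 0.2 mV) emulates recording noise.

What the templates do **not** emulate: biophysical spike-shape variability
within a sweep, channel noise correlations, electrode artifacts, sag
kinetics, bursting, or depolarization block. Parameter-recovery tests
therefore show that the extractor measures what the formulas define — on
real recordings the formulas face waveforms these templates idealize.

Measurement tolerances: noiseless extraction matches truth within one
sample or 2% on every feature; under 0.2 mV noise the per-feature
tolerances asserted in the tests (e.g. ±1.5 mV on spike voltages, ±0.5 ms
on latencies, ±2.5 ms on decay/ADP latency, 2% on rates) were set from a
pilot at roughly 1.7× the observed worst-case errors.

## Optical maps

Footprints and input maps implement the ≥2/3-of-trials rule; areas are
pixel counts × pitch² (256 µm² at 16 µm). An IPSC trial counts as an event
when its amplitude exceeds max(5 pA, 3× the session noise SD estimated
from sub-floor amplitudes) — the original event criterion is unstated, and
the 5 pA floor sits safely under the smallest reported evoked IPSC (8 pA).
Discrete input clusters are counted with 4-connectivity. Pixel centers are
row-major, 0-based, at (i + 0.5)·pitch. The convergence summary reports
medians, IQRs and the input/footprint median ratio only; inferring the
number of presynaptic cells is out of scope. The Nernst helper returns
(RT/zF)·ln([out]/[in]) in mV, and the solution-chloride helper sums
stoichiometric Cl⁻ per salt (the standard recipes give 145 mM internal vs
135 mM external, hence +1.8 mV at 24 °C).

## Patch-seq stages

QC drops cells with <75,500 total reads, then cells with <50% alignment
(strict at both boundaries; defaults reproduce a 61-of-69 survivor
margin). Depth normalization: "significantly correlated with molecular
count" is made precise as Pearson correlation with Benjamini–Hochberg
control at α = 0.05 (neither the test nor the correction is stated
anywhere authoritative); the gene set intersects those genes with the
genes detected at least once in every query cell; PC1 is computed on raw
counts restricted to the set and oriented to correlate positively with
per-cell totals so that "+1" behaves as intended. Because raw-count PC1
scores are not naturally bounded above −1, the default rescales scores to
half their maximum absolute value before adding 1 — every factor is then
positive and centered on 1 with the ordering preserved; `score_scale="raw"`
gives the literal scores with a hard error on any factor ≤ 0.

Cluster assignment scores each cell against cluster centroids by Pearson
correlation over shared genes. The null distribution is built by rescoring
against gene-permuted centroids (equivalently, permuting the cell's gene
profile), which reproduces the score spread of a structureless profile;
the alternative of permuting reference cell labels was implemented and
measured, but its permuted centroids collapse toward the global mean
profile, making the test anti-conservative (≈35% false assignment at
α = 0.05 versus ≈4% for the gene-permutation null), so it is retained only
as an explicit option. Cells may be assigned to several clusters — with
cluster-structured counts sharing a large common expression base,
multiple assignment is the norm rather than the exception — or to none.

The cross-dataset comparison rescales per-dataset gene means so the Sst
gene equals 1000, aligning on the gene union with absent genes marked NaN.

## Counts and co-expression

Whole-structure totals are counted/sampled% × 100, kept unrounded with a
rounded display value; the sampling percentages (40% for the
immunostaining series, 9% for the hybridization series) are user inputs
because their derivation from section geometry is not exactly
reconstructible. Co-expression categories follow the reporting
granularity GABA / Glu / GABA+Glu / DA / other (all remaining
marker-positive combinations) / none, with "none" warned as a likely
staining failure; the per-cell table retains full combinations.
Rostro-caudal profiles sort sections rostral→caudal (descending bregma)
and report the sign of the least-squares trend of count against caudal
distance.

## Summary statistics

Cluster summary tables report mean ± SEM per feature with an *unweighted*
grand-mean row (the arithmetic mean of cluster means): this is the
convention that reproduces the quoted cross-subtype figures
(849 MΩ, 92 mV, 1.1 ms, −67.5 mV from the per-subtype means), and it is
inconsistent with n-weighted pooling, which is available behind a flag.
Group comparisons are one-way ANOVA with Tukey HSD post-hoc tests in the
Tukey–Kramer form, valid for the unequal subtype sizes. When all groups
are constant with equal means, F is 0/0 and is reported as NaN with p = 1.

## Problem sizes and determinism

The test suite runs the full pipeline at the recorded cohort scale
(392 cells, 71 sweeps × 10,000 samples per cell) and the generators at
their default sizes: 50-cell recovery batches, 10-seed clustering
replicates, 200-cell calibration batches with 1000 bootstrap permutations.
Every stochastic step is a pure function of an explicit seed; reruns of
the pipeline with the same inputs and seed are byte-identical.

## Known limitations

* Independent feature draws overstate cluster separability relative to
  real recordings with correlated features; the ARI = 1 recovery on
  synthetic cohorts is an upper bound, not a field expectation.
* The extractor's conventions (threshold slope 10 mV/ms, 20 mV minimum
  amplitude, window bounds) are faithful to the documented recipe but any
  such fixed thresholds can misread pathological waveforms.
* The bootstrap assignment is a documented simplification of gene-set
  enrichment bootstrapping, not a reimplementation of it.
* Reference-dataset clustering is consumed as given labels; no
  transcriptomic clustering is performed here.
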