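# Methods

This note documents the models, estimators and numerical conventions behind
`rgctools`, the choices made where the design was genuinely open, and what
the synthetic generators do and do not emulate.

## Dual-pulse cell-cycle kinetics

**Model.** Two thymidine analogs (BrdU, then EdU an interval `Ti` later,
sacrifice a chase `Tchase` after the second injection; defaults 1 h and
0.5 h) partition the labelled population of ventricular-zone (VZ)
progenitors into staining classes. The plug-in estimators are

    Ts = (N[BrdU+EdU+] / N[BrdU+EdU-]) * Ti
    Tc = Ts / ( N[EdU+] / (N[GFP+] * GF) )
    GF = N[GFP+ marker+] / N[GFP+]

where `GF` (growth fraction) is the marker-positive share of the labelled
population, with Mcm2 or Ki67 as the proliferation marker. Both markers are
supported and neither is privileged: Ki67 is absent in quiescent cells and
early G1, Mcm2 also covers early-G1 and temporarily quiescent
replication-competent cells, so `GF(Ki67) <= GF(Mcm2)` and hence
`Tc(Ki67) <= Tc(Mcm2)` on the same table. Which marker defines "cycling" is
a scientific judgement the package leaves to the caller (`marker=` on every
entry point).

**Assumptions.** The estimators assume an asynchronous population at steady
state (cycle position uniform on `[0, Tc)`), a common cycle length across
cells, and — critically — that every cell in S phase at the *second*
injection also carries the *first* label. That last condition holds when the
first analog remains bioavailable up to the second injection; under strictly
instantaneous labelling the double-labelled class shrinks to
`(Ts - Ti)/Tc` of the population and the ratio estimator recovers `Ts - Ti`
rather than `Ts`. The simulator therefore defaults to "bridge" availability
(each analog labels S-phase cells until the next injection; the last is
instantaneous), which is the regime in which the printed formulas are
unbiased and which matches the classical derivation of the dual-pulse
method. `label_windows` is fully configurable, including fully
instantaneous labelling, precisely so the bias can be studied; a dedicated
test pins the `(Ts - Ti)/Tc` closed form for that case.

**Uncertainty.** Publications report SEM across animals. Per-animal data are
not part of this package's inputs, so its uncertainty contract is a
cell-level bootstrap (percentile CIs, default 2000 resamples). Resamples on
which an estimator is undefined (an empty count class) are dropped and
counted; more than 20% drops raises a warning. Degenerate full-table classes
raise explicit `EstimatorUndefinedError`s rather than returning infinities.

## Population simulator

`simulate_population` draws each cycling cell's cycle position uniformly at
the first injection, advances it deterministically to sacrifice, and scores:

* **labels** — analog `j` iff the cell is in S, and still cycling, at some
  instant of `[injection_j, injection_j + window_j]`;
* **Ki67** — positive for cycling cells except within an early-G1 window
  after mitosis (default 2 h; the true duration is not established, so it is
  a free parameter, not a claimed constant);
* **Mcm2** — positive for all cycling cells plus a configurable fraction
  (default 1.0) of non-cycling cells;
* **pVim** — positive iff in M phase at sacrifice;
* **cycle exit** — at each division the tracked daughter leaves the cycle
  with `exit_probability`, retaining labels acquired while cycling; exited
  cells score Ki67-negative. One row per input cell (mass conservation).

Phase durations default to `G1 7.0, S 5.31, G2 2.0, M 0.83` hours (a
15.14 h cycle, the control regime of the study design this emulates); G2 and
M are held at generic embryonic-cortex values when only `Ts` and `Tc` are
specified, since the estimators are insensitive to the G2/M split. All cells
sit in the VZ with depth uniform on `[0, 0.25)`; spatial structure beyond
the zone label is not modelled (no migration, no lineage trees).

The steady-state uniform age structure matches the estimator's assumption
and keeps closed forms available for testing; an exponentially growing age
structure is *not* implemented — with it the class fractions deviate from
the simple closed forms and the plug-in estimators acquire a bias that is a
research question in its own right, outside this package's scope.

## Fluorescence and laminar quantification

Corrected mean fluorescence intensity (MFI) on the 0–255 a.u. scale:
`((raw - background) / (255 - background)) * 100`, with the per-section
background supplied per cell. Negative values (raw below background) are
preserved and flagged, never clipped — clipping would bias group means
upward. Group summaries average per animal first (the publication unit);
SEM is reported across animal means and omitted for a single animal. The
all-cell frequency distribution is also emitted.

Depth runs 0 (apical/ventricular) to 1 (basal/pial) everywhere in the
package. Laminar histograms use equal-width bins indexed basal-to-apical
(bin 1 most basal), via `bin = n_bins - floor(depth * n_bins)`: an interior
boundary joins the bin covering larger depths, and depth exactly 1 closes
into bin 1. Zone schemes (VZ/SVZ/IZ/CP, or UL/LL postnatally) are
user-supplied boundary fractions — in tissue they are drawn morphologically,
which is not computationally reproducible — with an optional equal
inner/outer split of the first zone (IVZ/OVZ).

## Single-cell pipeline

QC keeps cells with >= 300 detected genes, then genes detected in >= 3
surviving cells — in that order; the reverse order changes results, so the
order is part of the contract and recorded in `uns['qc']`. Normalization is
LogNormalize: `ln(1 + count / total * 1e4)`; per-cell `expm1` sums equal the
scale factor exactly, which is asserted in tests. HVG selection is
mean/dispersion binning (scanpy's seurat flavor); optional per-gene linear
regression against covariates precedes unit-variance scaling clipped at
±10; PCA keeps 10 components by default with a deterministic sign
convention (largest-magnitude loading positive). Clustering is modularity
community detection (Leiden) on a k=20 nearest-neighbour graph in PC space,
seeded. Leiden optimises the same modularity objective as Louvain on the
same graph; it is the maintained implementation in the scanpy ecosystem.

Differential expression is a two-sided Wilcoxon rank-sum test per gene.
For pooled sizes <= 12 (and whenever a group has fewer than 3 cells, with a
warning) the p value is enumerated exactly over all assignments using
midranks, so ties are handled; larger samples use the tie-corrected normal
approximation with continuity correction, vectorised across genes. log2
fold changes are computed on de-logged (`expm1`) normalized means with a
pseudocount of 1 — the era of the original toolchain is ambiguous on this
convention, so the choice is recorded in the result's metadata. Adjustment
is Benjamini-Hochberg across all tested genes; significance is
`adj_p < 0.05` and `|log2FC| > 0.3`.

Cluster annotation scores each type as the mean over its marker genes of
cluster-mean expression, each gene rescaled by its maximum cluster mean so
genes contribute comparably; a runner-up within 0.05 of the top score
yields "unassigned". Marker sets default to RGC (Hes5, Pax6, Nes),
IP (Eomes, Hes6), EN (Neurod6, Tubb3, Dcx, Snap25). t-SNE and other
visual embeddings are deliberately outside the computational contract.

## Count-matrix generator

`simulate_counts` produces negative-binomial counts (gamma-Poisson, shared
dispersion, default theta 2.0) over lognormal relative gene abundances, with
lognormal library sizes (default median 10^4). Marker genes of each type are
elevated by `marker_logfc` (default 2.0 in log2) in that type's cells.
Default design: two promoter groups of 384 (CAG) and 731 (Hes5) cells with
type compositions (RGC/IP/EN) of 14.84/19.79/65.37% and 77.29/17.92/4.79%
respectively — the composition the real experiment observed, used here as
the generator's ground truth so the pipeline's composition table can be
checked against a known answer. The generator does not emulate ambient RNA,
doublets, batch effects, dropout beyond NB sampling, or gene-gene
correlation within a type; passing tests therefore demonstrate estimator
correctness under the stated model, not robustness to those artefacts.

## Regulon inference and master-regulator analysis

Mutual information between two expression vectors is estimated by
equal-frequency binning on ranks with `b = ceil(sqrt(n/5))` bins by default
(about 5 observations per marginal bin; estimator and bin count are
recorded in the edge table's metadata and configurable — no published value
exists for either). The binned estimator carries a positive finite-sample
bias of roughly `(b-1)^2 / (2n)` nats on independent data; the permutation
null absorbs this bias, which is why significance is never judged against
zero.

Per TF, the null is built by permuting the TF's cell labels (1000
permutations by default) and recomputing MI against every candidate target;
the empirical p uses +1 smoothing, `p = (1 + #{null >= obs}) / (1 + nperm)`,
so p is never exactly zero, and is BH-adjusted across that TF's targets.
Note the resolution limit this implies: with `m` candidate targets, the
smallest achievable adjusted p is about `m/(k * (nperm+1))` for `k` true
edges, so a few hundred permutations cannot clear `alpha = 0.05` against a
genome-scale target list — 1000 permutations is a floor, not a convention.

Bootstrap stability resamples cells with replacement (default 100 times);
an edge is re-detected on a resample when its MI reaches the (1-alpha)
quantile of its permutation null, and survives at consensus
`support >= 0.95` (the consensus threshold is not published; the default is
recorded in the output metadata). An optional data-processing-inequality
prune removes, within each fully connected (tf1, tf2, target) triangle, the
weakest edge when its MI falls below `min(other two) * (1 - epsilon)`; it
is off by default since there is no evidence it was applied with nonzero
tolerance in the workflow this mirrors. Every stage only removes edges.

Master-regulator analysis tests each regulon for enrichment of a query gene
list with a one-sided Fisher's exact test (enrichment only — MRA asks about
over-representation) on the 2x2 in/out-regulon by in/out-query table over a
supplied universe, BH-adjusted across regulons; `is_master` flags
`adj_p < 0.01`. The Fisher p is checked against an exact integer
hypergeometric tail sum to 1e-12 in tests.

`simulate_regnet` plants disjoint regulons: each target is
`strength * TF + noise_sd * eps` with independent standard-normal TFs and
background genes (defaults: 10 TFs x 10 targets, 50 background genes, 500
cells, strength 0.8, noise 0.5). Dependencies are linear (a monotone `f`);
non-monotone regulation, indirect cascades and TF-TF combinatorics are not
emulated.

## Summary statistics

`t_from_raw` is the pooled-variance unpaired Student t (Welch behind a
flag); `t_from_summary` rebuilds the same statistic from published
(mean, SEM, n) pairs — for equal n it reduces exactly to
`(m1 - m2) / sqrt(sem1^2 + sem2^2)` with `df = 2n - 2`; for unequal n the
pooled variance is reconstructed from the implied SDs with a warning. Sign
follows first-listed minus second; published tables are inconsistent in
sign, so comparisons against printed values use magnitudes. Reconstructed t
values are asserted to ±0.02 absolute, the slack induced by 2-decimal
rounding of the printed means and SEMs. A handful of printed t values are
*not* reproducible from their own printed summaries (they differ by more
than rounding can explain, one by a likely SEM duplication); those
comparisons are excluded from assertions rather than loosened.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use: 30k–50k cells per simulated
population (8 replicate "animals" for the headline Ts/Tc recovery), a
2000-gene x 600-cell matrix for DEG recovery, the 384+731-cell study-sized
design for the full pipeline composition, 1000 permutations / 100 bootstraps
for network inference, and 50 replicates for the MI null-cutoff rate. These
sizes put every stochastic check several standard errors inside its
asserted band while keeping a full run in minutes. All randomness flows
from `numpy.random.default_rng` seeds: generators take a seed in their
config; multi-stage drivers derive child seeds from one top-level seed.
Fixed seed implies byte-identical output everywhere, asserted in tests.

## Known limitations

* No per-animal hierarchy anywhere: cells are the resampling unit.
* The population simulator has no spatial dynamics, no lineage structure,
  and a single shared cycle length; quiescent cells never re-enter.
* Cumulative-labelling (saturation) designs for Tc are not implemented.
* The count generator's independence-within-type assumption makes DEG
  recovery easier than on real data.
* Regulon inference assumes a cells-as-samples expression matrix; no
  regulon activity scoring per cell.
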