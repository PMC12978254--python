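# Methods

This note documents the statistical models implemented in `cinmn`, the
choices made where the methodology was genuinely open, what the synthetic
data emulate, and the package's known limitations.

## In-situ cGAS⁺ MN scoring

Candidate foci detected in the cGAS channel are filtered on area with an
inclusive 0.25–7.5 µm² window (micronuclei are small; larger objects are
primary nuclei, smaller ones noise) and on mean intensity against a
per-tumor threshold. The threshold is deliberately an explicit input: in
practice it is tuned per tumor against the staining background. The
optional `otsu_intensity_threshold` helper offers a reproducible two-class
variance split as a starting point and is flagged as a heuristic. The score
is 100 × (tumor-compartment foci) / (tumor-cell detections); artifact-class
cells are excluded from the denominator and stromal foci from the
numerator. A focus carries exactly one compartment label — objects
straddling the tumor/stroma boundary must be resolved upstream.

## Spatial hotspot enrichment

MN positions are smoothed with a product-Gaussian KDE on a regular grid
(default 100 × 100). The per-axis bandwidth follows the normal-reference
rule h = 1.06 · min(σ, IQR/1.34) · n^(−1/5), floored at 2 µm so coincident
detections cannot collapse the kernel. Tumors with ≤ 10 MN are excluded
(`min_points = 11`): a density estimate from a handful of points defines no
meaningful hotspot. The tissue mask is the convex hull of the cell
centroids dilated by one grid cell; percentiles (integer 1% bins, computed
as ⌈100 · rank/N⌉ over masked nodes) and all downstream counting are
restricted to it. Cells map to their **nearest grid node** — interpolation
was rejected deliberately so that hotspot membership is a pure counting
operation and the optimized threshold sweep can be verified *exactly*
against a brute-force per-threshold count (a standing test). Fold
enrichment uses proportions of all classified cells, and a cell type
without representation on either side of a threshold yields no record
there. The per-threshold one-sample t tests (FE vs 1, thresholds 25–95)
are reported marginally without multiplicity correction; the sweep is a
descriptive profile, and its familywise behavior under the null is
documented by test (≈5% of (type, threshold) combinations reject at
α = 0.05). An alternative convention — percentiles over cell-assigned
densities rather than grid nodes — exists; grid-node percentiles were
fixed here.

## Karyotype scores

All three scores are linear scans over the cell × bin matrix; their value
is in the exact conventions. Aneuploidy weights |CN − expected| by bin
size; the expected euploid state is per-bin configurable (sex chromosomes,
whole-genome-doubled samples via a raised expected ploidy). Heterogeneity
counts *any* copy-number difference between a cell pair as discordant —
not distance from the modal state — matching the pairwise-comparison
definition. Breakpoints are adjacent same-chromosome bin pairs with
differing CN, normalized by genome length in Mb. Library QC keeps cells
averaging ≥ 10 reads per bin per chromosome copy, skipping zero-copy bins;
without read counts the QC is skipped with a warning. Cross-caller
concordance curation is out of scope: one call matrix in, scores out.

## Negative-binomial differential expression

The DE engine is a compact reimplementation, not a wrapper: median-of-ratios
size factors; per-gene method-of-moments dispersions from within-group
residual variance of normalized counts; a parametric mean–dispersion trend
α(µ) = a₀ + a₁/µ fitted on the variance scale (fitting after per-gene
division by µ̂² would bias the trend downward, since the estimation noise in
µ̂² correlates with the sample variance); and shrinkage of each raw
estimate toward the trend by an arithmetic weighted average (weight 0.8 on
the trend — with 2–3 replicates the per-gene moment carries little
information, and geometric averaging would re-introduce a downward Jensen
bias). The Wald test comes from a per-gene NB GLM with log link solved by
vectorized IRLS, BH-corrected. Under null simulations at the design sizes
used here (3 + 3 replicates) the observed type-I error is ≈ 0.05–0.06.
This machinery approximates, and does not replicate, full
shrinkage-estimation DE packages; an independent cross-check against
pydeseq2 on simulated inductions (median |Δlog₂FC| < 0.1, > 80% overlap of
strong calls) is part of the test suite, and all quantitative guarantees
are stated via parameter recovery on synthetic truth.

## cGAS-dependence classification

A gene is *cGAS-dependent induced* iff (i) padj ≤ 0.01 and log₂FC > 0 for
MPS1i vs DMSO in cGAS-proficient cells, (ii) the two-sided paired t test
(paired by batch) comparing per-batch log₂ fold changes between genotypes
gives p ≤ 0.05, and (iii) mean lfc(proficient) > mean lfc(knockout). Gate
(iii) makes the implied directionality explicit, since a two-sided test
alone would also flag *stronger* induction in the knockout; the suppressed
class is the mirror image. Per-batch fold changes use normalized counts
with a 0.5 pseudocount (negligible at the 16–1000+ count depths generated).
Batch structure is handled by the pairing itself plus per-sample size
factors rather than by an explicit batch-correction transform of the
counts.

**Power ceiling.** With three batches the paired t has df = 2, and a
per-gene NB dispersion of 0.05 puts a ≈ 22% floor on the biological CV of
each count. For a fully attenuated gene induced 4-fold, the noncentrality
works out to ≈ 5.3 and the analytic power of the df-2 test to ≈ 0.73–0.75;
simulated recovery lands at ≈ 0.63–0.75 sensitivity depending on seed,
with a false-positive rate of ~10⁻³ (two independent gates). Sensitivity
of this design is limited by the paired test, not by the DE gate (whose
sensitivity on induced genes is ≈ 0.99). Detecting subtler dependence
reliably requires more batches.

## MN-burden mixed models and the CIN^MN signature

Counts are filtered (total ≥ 50, expressed in ≥ 4 samples) and transformed
to log₂(normalized + 1). This stand-in for a full variance-stabilizing
transform is close to affine in log expression at the retained depths; the
residual curvature at low counts slightly attenuates slopes (≈ 2–6% for
baselines of 16–1000 counts) and is accepted because all guarantees are
recovery-based.

The per-gene model is `expression ~ MN + (1 | clone/batch)` with the MN
burden entering as the clone-level measurement. Because MN is constant
within clones, the correct reference distribution for the MN effect uses
**between-clone degrees of freedom** (n_clones − 2) — the number a
Satterthwaite-type ANOVA would assign to a cluster-constant covariate.
An observation-level Wald z is badly anti-conservative at a dozen clones,
and the REML clone-variance component truncating at zero makes it worse;
the package therefore reports the slope from the mixed fit and the p from
the exact between-clone t. In the balanced clone-constant-MN layout the
mixed model's GLS slope coincides with OLS on clone means, which enables a
closed-form vectorized path for matrix-wide sweeps; its exact agreement
with the per-gene iterative mixed fit (slopes, p values, variance
components) is a standing test. With one observation per clone × batch
cell the nested batch component is confounded with the residual and is
only estimated when replication exists; degenerate fits fall back to OLS
with clone-clustered errors and are flagged. Null-gene p values from this
construction pass a KS test against uniform.

The CIN^MN signature takes the k = 70 positive-slope genes with smallest
p, ties broken by larger slope (a deterministic rule; the tie-break is a
package decision). ssGSEA scores use the standard construction: per-sample
ranking (ties broken by gene order for determinism), weighted in-set CDF
with exponent 0.25, score = sum of the running in/out CDF difference,
normalized by the score range across samples. Both the exponent and the
range normalization are the method's published defaults, fixed here by
decision. My:Ly skew = myeloid − lymphoid ssGSEA score. Compartment marker
signatures take the top 50 genes (by worst-case padj) *exclusively*
significantly up-regulated in one compartment: up (padj ≤ 0.05, lfc > 0)
in every pairwise table of that compartment's clusters against non-member
clusters, and qualifying for no other compartment — a strict reading of
"exclusively up-regulated", chosen because it is enumerable and testable.

## Pseudobulk correlation and preranked GSEA

Raw single-nucleus counts are summed per (compartment, sample) — an
operation that preserves group totals exactly — then median-of-ratios
normalized across samples within each compartment, and correlated
gene-by-gene with tumor MN scores (Pearson, ≥ 3 samples; constant genes
are reported missing, not zero).

Preranked GSEA is the classic weighted Kolmogorov–Smirnov running sum with
weight |metric| (exponent 1). The null permutes gene labels — the only
exchangeable unit for preranked input — implemented as random placement of
the set positions, with ES evaluated only at hit boundaries (an exact
O(|set|) reduction of the full running sum). NES divides ES by the mean
|null ES| of matching sign; FDR q uses the standard positive/negative
pooled-null tail ratio. Nominal p values use the unbiased (b+1)/(B+1)
permutation estimator, which is exactly uniform under exchangeability —
the classic b/B convention is zero-inflated and would fail calibration
tests. Ties in the metric are broken by stable gene-name order. Group
meta-enrichment reruns the same machinery with gene sets as items ranked
by first-pass NES (the specific metric is a package decision; the ES/NES
sign convention makes it the natural carrier of direction).

## Cohort models and survival

Response interactions are OLS fits of Feature ~ MN × Response over
responder (regression grades 1–2) and nonresponder (4–5) tumors;
intermediate grades are excluded. The interaction coefficient *is* the
nonresponder-minus-responder slope difference; a response class with
constant MN is flagged degenerate. The per-gene
CIN^MN × cGAS–STING model shares one design matrix across genes and is
solved as a single batched least-squares problem; "CIN-enriched,
cGAS–STING-dependent" requires both the CIN main term and the interaction
to be significantly positive at α = 0.05 (mirror rule for depletion), so
pure-noise genes enter the class at roughly α² rate.

Kaplan–Meier, log-rank and Cox fits delegate to lifelines (Efron handling
of tied event times in the partial likelihood); hazard ratios are reported
from the max-stat dichotomy with the log-rank p alongside, and the
continuous-score entry points remain available. The maximally selected
rank statistic scans every unique score value inside the 10th–90th
percentile window, computing the standardized two-group log-rank z for
each "score > cut" split via precomputed at-risk/event incidence matrices
(one matrix product per candidate set). Because the maximum over
correlated splits is not χ²-distributed, the p value comes from ≥ 1000
label permutations of the score vector (the asymptotic improved-Bonferroni
correction varies between software versions and was deliberately not
reproduced); under the null the permutation p is uniform while the naive
best-split p rejects several-fold too often. Nested stratification splits
at the CIN-score median and then at the skew median within each half, with
values exactly at a median assigned to the low stratum (ties-low is a
package decision).

## Synthetic data: what it emulates and what it does not

The generators define the conditions under which every guarantee above is
demonstrated; one integer seed per call drives all randomness, and seeded
runs are bit-reproducible.

- **Tissue** (`make_tissue`): cells uniform over a 1 × 1 mm field;
  "hotspots" are hard discs of radius 2σ around random centers inside
  which tumor cells micronucleate at `mn_rate_hotspot` (default 0.15/cell
  vs 0.02 background) and stromal type frequencies are re-weighted by the
  configured multipliers. The hard-disc membership — rather than a
  literal Gaussian intensity profile — was chosen so the generator's true
  fold enrichment has the closed form FE(t) = m_t / Σ p_s m_s, recorded in
  the ground truth. Foci carry areas with a configurable out-of-window
  fraction (default 15%), plus dim decoys and stromal false detections,
  so the filters reject something real. Real tumors have irregular
  hotspot geometry, segmentation errors and spatially varying cell
  density; passing tests demonstrate correct counting, calibration and
  recovery, not tissue realism.
- **Isogenic counts** (`make_isogenic_counts`): four genotypes spanning
  2–40 MN per 100 cells (near-stable to highly unstable), 3 clones × 3
  batches, log₂ baselines uniform on [4, 10], 10% of genes with slopes
  ~N(0, 0.03 log₂ units per MN%), clone/batch/residual SDs
  0.15/0.10/0.20, NB dispersion 0.05, lognormal(0, 0.15) library sizes.
  Batch effects are drawn per (clone, batch) — independent replicate
  preps — making the generator consistent with the nested analysis model,
  so the null calibration it demonstrates is a property of the method,
  not of a fortunate mismatch.
- **Knockout experiment** (`make_ko_experiment`): the 2 × 2
  genotype × treatment design with one sample per condition per batch;
  induced genes gain `lfc` (log₂) under treatment in proficient cells,
  attenuated by the configured factor in the knockout; batch effects are
  shared across conditions within a batch and therefore cancel in the
  paired analysis.
- **Karyotypes** (`make_karyotypes`): ~1 Mb lognormal bins over 22
  chromosomes, Poisson whole-chromosome and segmental ±1 events, read
  counts scaled so a configurable fraction of cells fail library QC. The
  truth stores the exact matrix, so every score has a closed-form oracle.
- **Cohort** (`make_cohort`): lognormal MN scores; myeloid fractions with
  response-class-specific MN slopes (an unbounded STING-like protein
  feature carries the slope contrast used for interaction recovery, since
  abundance fractions clip at [0, 1]); exponential survival with
  log-hazard linear in standardized CIN score and My:Ly skew; independent
  exponential censoring calibrated to the target rate. Real cohorts have
  non-proportional hazards, correlated covariates and informative
  censoring; none of these are modeled.

## Problem sizes and numerical choices

End-to-end checks run at sizes chosen to exercise the statistics at
realistic scale: 20-tissue cohorts of ~1,600 cells for enrichment
(200 cohort replicates for null calibration of the sweep t tests),
2,000-gene panels for the mixed-model and dependence recoveries (10 seeds
for the classifier), 500 random-metric simulations for GSEA calibration,
n = 1,000 for Cox recovery and 50–60 replicates for max-stat calibration.
IRLS runs 30 damped iterations with dispersions clipped to [10⁻⁸, 10];
KDE bandwidths are floored at 2 µm; permutation p values use (b+1)/(B+1)
throughout; all tie-breaks (signature p ties, ssGSEA/GSEA metric ties,
median splits) are deterministic and documented above.

## Limitations

- Image segmentation, registration estimation, copy-number calling,
  clustering/integration of single-cell data, and batch-correcting count
  transforms are out of scope; the package consumes their outputs.
- The DE engine is a calibrated approximation (see above), not a
  re-implementation of any specific published tool.
- The paired three-batch dependence design caps sensitivity near 0.7 for
  4-fold fully attenuated inductions; this is a property of the design,
  reported honestly by the recovery metrics.
- ssGSEA scores are range-normalized within the scored cohort, so scores
  are comparable within a matrix, not across independent cohorts.
- The max-stat p is permutation-based; at B permutations its resolution is
  1/(B+1).
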