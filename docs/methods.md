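# Methods

This note documents the statistical models implemented in `gexmorph`, the
assumptions behind the synthetic-data generator, and the numerical and
design choices a user should know before trusting (or extending) the
pipeline.

## Longitudinal GLM with sandwich variance (`gexmorph.glm`)

The response is a per-scan regional GMV vector. The model is a *marginal*
regression: coefficients are estimated by ordinary least squares per region,
and the within-subject dependence of repeated scans enters only through the
variance estimate,

    V = (XᵀX)⁻¹ ( Σ_s Xₛᵀ eₛ eₛᵀ Xₛ ) (XᵀX)⁻¹,

where the sum runs over subjects and eₛ is the residual block of subject s.
This is the classic cluster-robust sandwich with an identity working
covariance: consistent under arbitrary within-subject correlation and
heteroskedasticity, at some small-sample cost.

Design (10 columns): intercept; group indicator (case = 1, so positive
contrast t means case > control); age centered at the grand mean over
included scans *before* squaring and interacting; centered age²; group×age;
sex, IQ, brain size, SES (all grand-mean centered); and severity, coded 0
for controls and mean-centered within the case group only — this removes
severity-related variance without contaminating the group contrast.
A main (linear) age column is included alongside the quadratic term and the
interaction: without it the group×age term is not interpretable, and its
omission is not standard practice for a quadratic expansion.

Inference: t = cᵀβ̂ / √(cᵀVc) on df = n_subjects − rank(X). This
cluster-count df rule is deliberately conservative; the sandwich literature
offers a range of small-sample corrections, and a CR1-style scale factor
(G/(G−1) · (N−1)/(N−p)) is available via `adjust="cr1"`, but the default is
the plain estimator. In the packaged calibration experiments (200 subjects,
1–4 visits each) the empirical type-I error at nominal 0.05 sits near
0.05–0.07 and 95% CI coverage near 0.93–0.95, i.e. the usual mild
liberality of an unadjusted sandwich at moderate cluster counts.

Degenerate inputs: constant design columns raise immediately (naming the
column); a generally rank-deficient design is flagged at build time and
refused at fit time; regions with zero response variance are flagged and
excluded from the t map rather than failing the run.

## Cluster-extent simulation (`gexmorph.clustersim`)

Smoothness is parametrized by the Gaussian autocorrelation convention,
acf(d) = exp(−4 ln2 d²/FWHM²). White noise convolved with a Gaussian kernel
of FWHM f_k has acf FWHM √2·f_k, so the simulator applies a kernel of
FWHM/√2 to hit the stated field smoothness. Boundaries are periodic (the
field stays stationary on small grids; no edge-variance bias), fields are
standardized empirically to unit variance, thresholding is two-sided by
default (|z| > z₁₋p/2) since both GMV increases and decreases are of
interest, and connectivity defaults to face adjacency (configurable to
include edges/corners). The real-data practice of fitting a mixed
Gaussian-plus-exponential acf to residual images is out of scope: the
residual smoothness of any particular study is not an input the package
has, so published cluster thresholds (e.g. k > 316 voxels at p < 0.005 on a
1.5 mm grid) are not reproduction targets; what the package verifies
instead is the estimator's *behavior* — k_min monotone in FWHM and α, and
family-wise error on fresh null fields within Monte-Carlo tolerance of α.

## Regionization (`gexmorph.expression`)

Probe symbols are filtered against a whitelist emulating approved-symbol
databases; probes of one gene are arithmetically averaged per sample; the
region summary is the **median** over assigned samples, which is what makes
the downstream rank correlation robust to single aberrant samples. Donor
pooling is the primary mode: all donors' samples enter one median per
region. The wording of the underlying procedure is ambiguous about whether
per-donor aggregation precedes the median; pooling was chosen because it
yields the single aggregate expression map the primary analysis needs,
while the per-donor mode (`scope=<donor>`) remains available for the
donor-variability analysis. `min_samples` defaults to 1 (no minimum is
imposed by the procedure being emulated); underpopulated regions are
dropped with a warning, never silently.

Sample assignment uses the NIfTI affine with 0-based voxel indices and MNI
mm externally. A coordinate landing on a background voxel falls back to the
nearest labeled voxel center within `max_dist_mm` (default 3 mm);
coordinates outside the volume are left unassigned with a warning. When
hemisphere flags are absent, left is x < 0.

## Spearman screen, FDR, percentiles (`gexmorph.association`)

ρ is the Pearson correlation of midranks (average ranks on ties). P values
use t = ρ√((n−2)/(1−ρ²)) on n−2 df; at n = 46 regions this approximation is
accurate far beyond the FDR resolution, and exact permutation — feasible
only at tiny n — is available (`method="exact"`, n ≤ 8 by default). Two-
sided p values are the default since both correlation signs are reported.
BH-FDR follows the step-up definition q₍ᵢ₎ = min_{j≥i}(p₍ⱼ₎·n/j) capped at
1. Percentile cutoffs use linear interpolation between order statistics
(the common statistical-software default; documented because percentile
conventions differ). Genes with constant regional expression have undefined
ρ and are excluded with a log entry.

## Enrichment (`gexmorph.enrichment`)

One-sided over-representation only (depletion is not tested). The selection
is floor(fraction·n) genes from the requested tail, with boundary ties
broken lexicographically by gene id so reruns are reproducible. Categories
are intersected with the background before testing; `min_category` defaults
to 3 background members. No ontology-graph propagation or redundancy
collapsing is performed — every tested category is reported.

## Synthetic data (`gexmorph.synthetic`)

The generator defines the study conditions the tests run under.

**Cohort.** Defaults mirror a longitudinal pediatric cohort: 44 control, 26
persistent, 17 recovered subjects; 1–4 visits uniformly, spaced 1 year;
first-visit ages uniform on 3.0–10.8 years. Covariates are Gaussian with
plausible population values (IQ 110 ± 14; brain volume 1150 ± 90 cm³; SES
50 ± 10); severity scores are drawn only for stuttering groups (persistent
21 ± 8.3 clipped to [10.5, 48]; recovered 13 ± 2.9 clipped to [7, 19]) and
held constant across a subject's visits. Regional responses are baseline
(uniform 0.4–0.8 volume units) + subject effect + covariate terms + group
effect + group×age slope + N(0, noise_sd) with noise_sd = subject_sd = 0.05.
Within-subject variance components are not reported for the emulated study;
these defaults are stated, not fitted. Subject effects are drawn
independently per (subject, region): shared across a subject's visits —
preserving the within-subject correlation the sandwich estimator exists
for — but independent across regions, so that multi-region calibration
experiments (type-I error bands, CI coverage) see approximately independent
regional replicates. Group effects apply to the persistent group only; the
default effect map spaces magnitudes linearly from 0 to 0.06 volume units
across regions with alternating signs, giving the rank link a full dynamic
range and exercising the absolute-value summary.

**Expression.** The causal-gene link is built in rank space because the
downstream statistic is rank-based: with u the standardized midrank of
|effect| across regions, a causal gene's regional signal is
coupling·u + √(1−coupling²)·v with gene-specific spatial noise v, so the
expected gene–map correlation is governed directly by `coupling`
(default 0.7; exactly 1 when coupling = 1 and measurement noise vanishes).
Probes of a gene share the gene signal plus a probe offset (SD 0.3);
samples add N(0, 0.5) measurement noise. Default scale is desk-sized — 500
genes, 25 causal, 2 probes/gene, 3 samples/region, 6 donors, whitelist
covering 90% of symbols — with the full-scale dimensions (21,000 genes
whitelisted to 19,174) used in the acceptance script. Four genes are always
present by name: GNPTG and NAGPA as causal entries, GNPTAB and AP4E1 as
null entries, so named association statistics can be reported. Samples are
placed inside their region's extent of a synthetic AAL-like label volume
(90 supratentorial parcels + cerebellum on a coarse grid, left at x < 0)
and distributed round-robin over donors.

**What the generator does not emulate:** realistic MRI geometry,
segmentation or registration error, microarray normalization artifacts,
spatial autocorrelation *between* regions (regions are exchangeable given
the effect map), donor-specific expression biases, and gene–gene
co-expression structure. Passing tests therefore demonstrate correctness of
the estimators and plumbing under known ground truth — not robustness to
the idiosyncrasies of real scans and microarray releases. In particular,
genuinely spatially autocorrelated maps would need autocorrelation-
preserving null models (spin tests), which are intentionally out of scope.

**Catalogs.** Planted enriched categories draw ≥ 80% (default 90%) of
members from the causal set; remaining categories are uniform draws from
the universe.

## Reproducibility

All randomness flows from one root seed through named substreams
(`numpy.random.SeedSequence.spawn`), so a config + seed pins every output;
rerunning a config writes byte-identical tables. Tables carry a
`# gexmorph.<kind>.v1` format line and reload losslessly through the
package's own readers.

## Problem sizes

The packaged experiments use desk-scale sizes chosen to make the checks
statistically meaningful while staying comfortably interactive: 1,000
regions for the type-I band (99% binomial band ±0.018), 300 regions for CI
coverage, 10 generator seeds for end-to-end recovery, 600 + 600 Monte-Carlo
iterations for the cluster threshold and its family-wise-error audit, and
the full 19,174-gene universe in the acceptance script (the screen itself
is vectorized and cheap; the expensive parts are deliberately small).
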