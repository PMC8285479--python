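# Methods

This note documents the models behind each pipeline stage, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical conventions adopted where the procedures are
genuinely open.

## Drug-screen scoring

Raw per-well viability is normalised per plate with the normalised
percentage inhibition (NPI): `v' = (v − mean_pos) / (mean_neg − mean_pos)`,
where the positive controls are full-kill wells and the negative controls
vehicle-only wells, laid out alternately by row parity in two dedicated
plate columns (default 2 and 23 of a 16×24 plate). NPI is exact at the
control means by construction and invariant to per-plate affine rescaling
of the raw signal, so plate-to-plate gain and offset drift cancel.

Differential survival for a compound × concentration is the mean of the
treated-arm normalized triplicates minus the vehicle-arm mean. The
replicate values feed a two-sided t-test; p-values are Benjamini–Hochberg
adjusted across compounds (delegated to `statsmodels`); sensitized hits
require `Padj < 0.05` and differential `< −0.3`, tolerant hits use the
symmetric `> +0.3` cut (the positive threshold is a package default
exposed as a parameter; only the sensitization cut is fixed by the assay definition).

**Welch vs pooled t.** The default is the unequal-variance Welch test, the
safer choice when arm variances are not constrained equal. At 3 replicates
per arm, however, the Welch–Satterthwaite degrees-of-freedom approximation
is tail-conservative: on iid normal null data the empirical `p < 0.05`
rate is ≈ 0.035, not 0.05. The pooled-variance Student t-test
(`welch=False`) is exactly calibrated when variances are equal, and is the
variant used for the null-calibration checks, whose simulated arms have
equal variance by construction. Both are exposed; results tables record
only the p-values.

**Degenerate inputs.** When both arms are exactly constant the t statistic
is undefined; the package returns p = 1 for equal means and p = 0
otherwise, a convention that only arises on noise-free synthetic data.
NaN wells are dropped with a logged count, never imputed.

## Signature activity and stratification

The activity score of a sample is the mean over signature genes of the
per-gene z-score computed across samples (sample sd, ddof = 1; `sum`
offered as an alternative aggregation). Genes absent from the matrix are
skipped with a logged count; zero-variance genes are excluded. The score
is invariant to per-gene affine rescaling of the expression matrix, so it
is insensitive to gene-level units as long as values are on a continuous
(ideally log) scale; z-scores are always computed within the supplied
matrix.

Stratification schemes: `quartile-extremes` labels the top and bottom 25 %
of samples `high`/`low` and excludes the middle (the quartile split used to
compare cohort extremes); `tertiles` makes three equal-count groups.
Ties are resolved by stable sample order; fully tied scores are refused
rather than split arbitrarily.

Group comparison uses the Wilcoxon rank-sum test: exact enumeration when
both groups have ≤ 8 observations and no ties, otherwise the normal
approximation with continuity correction and mid-rank ties. The exact and
approximate branches agree to ≈ 0.01 for n = 8 + 8 (the exhaustive
worst-case gap of the continuity-corrected approximation over the whole
null support is 0.0109, reached only in the far tail).

A null-uniformity property holds only when group labels are assigned
independently of the scores (as when groups come from mutation status);
comparing score-derived extreme quartiles of the same scores is by
construction not a null comparison.

## Enhancer–gene linkage

All correlations are Spearman with mid-rank ties (Pearson selectable).
The candidate enhancer's accessibility–expression correlation ρ is ranked
within the ρ values of the background enhancers via the tie-aware
mid-quantile `(#{ρ_bg < ρ} + 0.5·#{ρ_bg = ρ}) / N`; at least 20 background
enhancers are required for the quantile to mean anything, and constant
background rows are dropped with a logged count. The background set is
user-supplied (a vicinity catalogue), not recomputed. Background
correlations are computed by rank-transforming the whole matrix and taking
vectorised inner products — identical to per-row `spearmanr` (cross-checked
in tests) but hundreds of times faster.

Neighbour-gene specificity reports the same estimator against each
neighbouring gene's expression. The conditioned-correlation curve
re-estimates ρ after retaining, for each removal fraction f in
{0, 0.1, …, 0.8}, the `ceil((1−f)·n)` samples with the highest
conditioning-gene expression (stable order on ties); f = 0 reproduces the
unconditioned ρ exactly, and the curve truncates with a warning below 4
retained samples. The decile grid and 80 % stop are package choices; the
qualitative object of interest is monotone growth of ρ when the linkage is
gated by the conditioning gene.

## 4C region comparison

Profiles hold normalized contact signal per restriction fragment,
condition and replicate (normalization upstream, e.g. by peakC, is out of
scope). Printed coordinates such as `chr11: 2773921-2812270` are treated
as 1-based inclusive; a fragment belongs to a region iff its midpoint
falls inside it (inclusive at both ends), which is unambiguous for
fragments straddling a boundary. Per fragment the replicate means of the
two conditions are paired; their differences feed the Wilcoxon signed-rank
test (zeros dropped; exact enumeration for ≤ 20 non-zero differences
without tied magnitudes, otherwise normal approximation with continuity
correction). The paired variant is the default because both conditions
share one fragment grid; an unpaired rank-sum variant is exposed. The
statistic is invariant to a common multiplicative rescaling of both
conditions. Regions need ≥ 5 fragments; all-zero differences return
p = 1 with zero effect.

## LFQ proteomics post-processing

Two valid-value filters are provided: `overall-fraction` (e.g. ≥ 66 %
observed across all samples) and `per-group-count` (e.g. ≥ 2 of 3 in both
conditions, or in at least one, selectable). Imputation replaces missing
entries per sample column with draws from
`Normal(µ − 1.8σ, (0.3σ)²)`, µ and σ being that column's observed mean and
sd — the standard downshifted-normal model for missing-not-at-random
dropouts of low-abundance peptides. Imputation is deterministic given a
seed.

Differential calling uses a two-sided Welch t-test per protein with
`P ≤ 0.05` and `|log2 difference| ≥ 1.5`. The fold-change cut is read on
the log2-difference scale (the symmetric `≤ −1.5` bound implies a log
scale); the ratio-scale reading `|difference| ≥ log2(1.5)` is selectable.
Proteins fully observed in one group and fully missing in the other are
flagged on/off and bypass testing; `run_differential` detects them on the
unfiltered matrix so the valid-value filter cannot discard them, then
filters, imputes and tests the rest.

Enrichment calling against an IgG control requires both a log2-enrichment
cut and a `−log10 p` cut; presets `GR` (2.5 / 2) and `p57` (1.5 / 1.3)
encode the two standard rule boundaries for these assays. Optional IgG correction
subtracts each protein's mean IgG intensity (a flag disables it).

**Sensitivity under missingness.** With realistic intensity-dependent
missingness (~20 % overall), recall of injected 2-log2 shifts drops well
below the complete-data value (~0.97): rows failing the 2-of-3 filter in
the down-shifted group are untestable, and imputed values drawn 1.8
column-sd below the mean inflate within-group variance for partially
missing rows. This deflation is a property of the downshifted-imputation
workflow itself, not of this implementation; recall oracles are therefore
stated on complete matrices at the stated effect size and noise.

## Immunofluorescence quantification

The nuclear channel is background-subtracted with a rolling ball of 40 µm
radius, implemented as grayscale opening with a hemispherical structuring
function — the surface traced by rolling a ball under the intensity
landscape. For radii above 16 px the image is block-min-shrunk by an
integer factor and the background bilinearly interpolated back (the
classic large-ball speed trade-off; the estimate is clamped below the
image). A median filter with a 1.5 µm disk follows. All spatial
parameters are specified in microns and converted with the pixel size, so
results agree across magnifications within discretisation error.

Foreground pixels must exceed the local mean over an 8 µm disk plus 4×
the background standard deviation. The background sd is estimated from
pixels at or below the global median of the corrected image (a background
proxy in sparsely seeded fields); if that set is degenerate (e.g. clipped
at zero) a robust MAD-based scale over the whole image is used. The mask
is split by watershed on the negated Euclidean distance transform, seeded
at regional maxima of a lightly smoothed distance map with a 4 µm minimum
peak separation — enough to split pairs overlapping 10–20 % of a radius
without shattering single nuclei. Components below 20 µm² are removed
(set `min_area_um2=None` for strict fidelity to the original macro, which
has no such filter).

Positivity: a nucleus is positive iff its mean marker intensity strictly
exceeds the threshold. The threshold is either supplied explicitly or
calibrated as the 99th percentile of per-nucleus means in untreated
control images (`mean+3sd` offered as an alternative; the specific
calibration statistic is a package choice — the assay definition fixes only
that the threshold comes from untreated controls). The protein expression index is the number of
positive nuclei times the average marker intensity over positive nuclei
(zero when none are positive); averaging over positive rather than all
cells is a package choice, documented here because the printed formula
does not specify it. Edge-touching nuclei are retained.

## Synthetic-data generators

All generators are deterministic given (config, seed) and emit ground
truth as sidecar objects the pipelines never read.

* **Plates**: raw signal `kill_floor + v·(baseline − kill_floor) + ε·span`
  with v the compound's true fractional viability (clipped N(0.85, 0.15²))
  plus any arm-specific interaction shift, and ε per-well N(0, 0.05²) by
  default (well noise expressed in normalized-viability units). The
  anchored form means NPI recovers v exactly in expectation. Controls
  alternate by row parity in columns 2 and 23. Because all compounds on a
  plate share that plate's control-estimation error, hit statistics are
  weakly correlated within plates — as in a real screen — so the null
  `p < 0.05` rate fluctuates slightly more than a binomial count.
* **Cohort**: latent activity a ~ N(0,1) drives 253 signature genes
  (`loading·a + noise`) and a noisy GR (NR3C1) readout. The candidate
  enhancer and target gene share a component with weight 1.2 by default
  (implied correlation β²/(β²+1) ≈ 0.59, the regime of interest); with
  `gr_gated=True` the component is active only in the top half of GR
  expression, producing the rising conditioned-correlation curve. The 306
  background enhancers and 4 neighbour genes (named after the CDKN1C
  neighbours KCNQ1, SLC22A18, PHLDA2, NAP1L4) are independent noise, so
  with `linkage_effect=0` the candidate is exchangeable with background.
* **4C**: 120 fragments of 1.5 kb tiling chr11 around the locus, baseline
  contact decaying exponentially with distance from the viewpoint,
  log-normal replicate noise, and declared multiplicative condition
  effects inside printed regions.
* **LFQ**: protein abundances N(25, 3²) on the log2 scale, injected group
  shifts, and missing-not-at-random dropout whose probability decreases
  logistically with intensity, scaled to an overall missing rate
  (0 ⇒ complete matrix).
* **Images**: cosine-tapered disks (radius 4–6.5 µm) over a low-frequency
  additive background gradient, Gaussian pixel noise (nuclear SNR ≈ 50 at
  defaults), touching pairs overlapping 10–20 % of radius, and a
  deterministic first-k marker-positive assignment with class-constant
  marker means.

What the generators do **not** emulate: sequencing-level counts and their
overdispersion, batch effects and normalization artefacts in cohort
matrices, spatially correlated camera noise, optical blur between touching
nuclei, mitotic/apoptotic morphologies, or peptide-level effects upstream
of the protein matrix. Passing tests therefore demonstrate correctness of
the statistics and their implementation on data satisfying each method's
assumptions, not robustness to every failure mode of real instruments.

## Problem sizes

Simulation-based checks use: 1056 null and 352 partially shifted compounds
for screen calibration/power; cohorts of 200 samples (253 signature genes,
306 background enhancers) with 100–500 seeds depending on the property;
50-seed LFQ recall at 200 proteins; 60–100 synthetic fields of 384×384 px
with 25 nuclei for count accuracy. These sizes give Monte-Carlo error
comfortably below each property's margin while keeping a full run to a
few minutes on one CPU.
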