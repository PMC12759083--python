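# Methods

This note documents the models behind each module, the defaults and why,
and what the synthetic-data generators do and do not emulate.

## Screen simulation and scoring

### Generative model

Each screen sorts a pooled CRISPRi library by a single-cell reporter into a
high and a low bin (default `sort_fraction` 0.30 each, mirroring a
top-30 %/bottom-30 % sort). The generator models, per cell, a reporter
value on the log2 scale:

    reporter = shift(gene) × efficacy(guide) + ε,   ε ~ N(0, reporter_sd²)

`efficacy` cycles through (1.0, 0.8, 0.6, 0.4, 0.2) over a gene's guides —
heterogeneous guide potency is the stress case for guide→gene aggregation.
Bin cut-offs are the empirical `sort_fraction` quantiles of the pooled
mixture (equal-weight normal mixture over guides, solved numerically), so
planted effects in one gene slightly shift the cut-offs for everyone, as in
a real sort. A guide's expected reads per bin scale with its bin-occupancy
probability, normalised so a null guide lands at `baseline_mean` (default
500 reads); counts are negative-binomial with variance μ + μ²/α
(`dispersion` α = 5, a moderately overdispersed screen library). Defaults:
`reporter_sd` 1.0 log2 units — wide single-cell reporter distributions are
what makes 30 % bins informative rather than saturating.

Consequences worth knowing: a strongly shifted, fully efficacious guide can
have an expected high-bin count ≪ 1; its zero counts are then removed by
the zero-count filter, exactly as in real data, so recovery rests on the
mid-efficacy guides.

### Guide-level test

Counts from both bins are size-normalised per replicate column by
median-of-ratios against the per-guide geometric-mean reference (guides
with any zero are excluded from the median). The guide log2FC is
`log2(mean norm high + 0.5) − log2(mean norm low + 0.5)` (pseudocount 0.5
stabilises low counts). The p value is a two-sided test of the
per-replicate normalised log-ratios against zero with the replicate
variance **pooled across all guides** (df = Σ_g (R−1)). With two
replicates a per-guide variance has one degree of freedom, whose t
distribution is Cauchy: no effect, however large, can then clear a
Bonferroni threshold over thousands of guides. Pooling is justified here
because after median-of-ratios normalisation the replicate noise of the
log-ratio is approximately exchangeable across guides at similar depth, and
planted effects do not inflate the pooled estimate (within-guide deviations
are location-free). With a single replicate per bin the p value falls back
to the empirical permutation null over guide labels. This test is a
deliberately transparent stand-in for the sgRNA-level output of ranked
screen-analysis pipelines; the package's contribution is everything
downstream of the sgRNA table, which is why the test only needs honest
calibration (null type-I ≈ 5 %) and reasonable power.

### Correction, score, aggregation, classification

* Bonferroni is `min(1, p·m)` over the m tested guides (`standard`). An
  `as_printed` mode that *divides* p by m is exposed because that wording
  circulates in methods sections; division is not a multiplicity correction
  and the mode exists for traceability only.
* Gene score = (−log₁₀ p_adj) × log₂FC; p_adj = 0 is clamped to the
  smallest positive float with a warning.
* Guide→gene aggregation (`best_guide_pair`, default): gene log2FC is the
  mean of the two largest-|score| guides agreeing in sign; gene p_adj the
  max of the pair; ties broken lexicographically by guide id for
  reproducibility. Requiring two independent agreeing guides suppresses
  single-guide artifacts; plain `mean` aggregation is available.
  "Significant" means gene-level Bonferroni p_adj < 0.05.
* The hit rule set is applied on the six screens keyed
  `{HeLa_Parkin, HeLa_noParkin, HEK293} × {NT, AO}`; thresholds −1 / −1.25
  / +1 are config values defaulting to the published cuts. The
  facilitator's "at least greater than 1 compared to" is implemented as a
  difference-of-log2FC > 1 against both comparators, parallel to the
  activator's explicit difference rule. Regulator categories exclude
  activators/facilitators, in that order.

## Flow statistics

Population summaries are arithmetic means of raw intensities (medians are
an option). The degradation statistic is computed exactly as published:

    degradation % = 100 · (normint⁺ − normint⁻) / normint⁺

Note the sign convention: when Parkin degrades MFN2 in the Parkin⁺
population, normint⁺ < normint⁻ and the printed formula is negative. The
formula is preserved as printed; the flow generator defines its planted
`true_degradation_pct` *through the same formula* (Parkin⁺ at the CTRL
level, Parkin⁻ scaled to 1 − pct/100), so simulator and estimator are
consistent by construction rather than by a sign fix.

mt-Keima gating subtracts `spillover` (default 0.10) × the ex488–em528
channel from the neutral ex488–em611 channel, floored at 0 (negative
corrected intensities are non-physical for gating), then counts events in a
polygon gate on the (corrected neutral, acidic) plane. Gate vertices are
config; the package does not learn gates.

Quadrant analysis: the guide-negative reference population (PINK1-YFP and
BFP both below their cut-offs, i.e. non-transduced cells) yields a
normalisation factor ref_sample/ref_CTRL; sample MMP values are divided by
it and PINK1 is untouched. The MMP cut-off is **dimensionless**, a fold of
the guide-negative reference level: an event is MMP-high when its raw MMP
is ≥ cut × (sample reference mean), equivalently when its normalised MMP is
≥ cut × (CTRL reference mean). This is the same fixed-cutoff-per-sample
procedure with the cut-off's units made explicit, and it makes the
fractions exactly invariant to instrument gain — a cut-off stated in raw
units would silently depend on the CTRL's staining scale. Boundary events
(value = cut-off) go to the high side, deterministically. The default MMP
cut-off 0.5 reflects the observation that PINK1 stabilises once MMP falls
to roughly half the control level. The BFP threshold separating
guide-positive cells is config (default from a no-guide control's upper
tail); event tables are CSV — FCS parsing is out of scope.

## Image quantification

Channels are zeroed outside the cell ROI polygon, linearly rescaled
per-channel to 8 bits (min→0, max→255 — the reproducible reading of a
display-range-dependent "downgrade to 8 bits"), and thresholded inclusively
at (80, 255). Mask algebra, exactly as published:

    mito = MTS_mask ∪ MMP_mask
    partition_a = mito \ MMP_mask
    partition_b = mito \ partition_a

**Label caveat**: the source macro calls `partition_a` ("mito minus dye
mask") the *high* MMP partition, although a potential-dependent dye marks
*polarised* mitochondria, making `partition_a` the dye-negative/depolarised
set under dye logic. The algebra is computed as published and the naming
lives only in the `PARTITION_LABELS` constant; quantitative results are
keyed by partition, not by label, and tests validate against planted truth
via partitions. Connected components use 8-connectivity (the default of
common particle analysis); ROI means use raw, pre-quantisation intensities.

"R over background" is Pearson's r over in-ROI pixels minus the mean r of
`n_rand` (default 20) randomised controls. The published plugin's
randomisation kernel is unspecified; the default here is a Costes-style
block shuffle (blocks of `block_size` = 5 px ≈ object width, permuted among
blocks fully inside the ROI) with a seeded generator, and a pure per-pixel
shuffle as a flag. Block shuffling preserves local autocorrelation, giving
a conservative null for structured images; per-pixel shuffling destroys it
and inflates R over background for any spatially smooth signal.

## Proteomics

Tests are classical equal-variance two-sided t tests on log2 abundances
(Welch exposed as an option); log2FC is the log-ratio of linear condition
means; BH FDR is computed over all tested proteins; the significance flag
is FDR < 0.05 ∧ |log2FC| > cut with cut 1.0 (0.5 for the whole-lysate LFQ
experiments). Proteins with < 2 observed replicates, or missing in more
than half of either condition, are excluded and logged — distribution-based
imputation is deliberately out of scope, which means proteins absent in one
condition (on/off cases) are not tested rather than imputed to an extreme.
Zero-variance identical-mean cases get p = 1. The non-mitochondrial-median
normalisation divides each sample column by its median over
non-mitochondrial proteins (post-condition: that median is exactly 1),
removing loading differences while leaving mitochondrial mass shifts
intact. The strong-presequence flag is a pure function of four annotation
fields: mitochondrial ∧ ¬OMM ∧ MTS score ≥ 2 ∧ start < 20, with missing
fields flagging False.

## What the generators do and do not emulate

The screen generator captures sorting-induced count asymmetry, NB
overdispersion, guide-potency heterogeneity and zero-count dropout; it does
not model sequencing error, guide cross-mapping, copy-number effects or
growth-rate selection between transduction and sort. The flow generator
captures lognormal channel distributions and subpopulation mixtures at
configurable fractions; it does not model doublets, autofluorescence
baselines or spectral spillover beyond the single mt-Keima term. The image
generator produces disjoint curvilinear objects (random-walk skeletons
dilated to 3–5 px) with class-dependent gains and optional additive
Gaussian noise; real confocal data add out-of-focus light, shading,
touching organelles and segmentation ambiguity. Passing recovery tests on
these simulations therefore validates the *statistical machinery* — not
robustness to optical artifacts, which the upstream experiment must
control.

## Problem sizes and numerics

The standard verification runs use 1000 genes × 5 guides × 2 replicates
per screen, 50 k events per flow sample with 100 seeds per degradation
level, 256 × 256 images with 20 objects, and 20-control colocalisation
nulls — sizes at which the Monte-Carlo margins in the tests are comfortably
resolved on a single CPU in well under a minute per stage. Numerical
choices: pseudocount 0.5; p_adj clamp at the smallest positive double;
compensation floor at 0; boundary-to-high quadrant convention; lexicographic
tie-breaks in guide selection; NB sampling via the (α, α/(α+μ))
parameterisation with μ = 0 yielding exact zeros. All generators are
deterministic given (config, seed).

## Known limitations

* The guide-level test is a calibrated stand-in, not a reimplementation of
  ranked-aggregation screen pipelines; rank-based gene p values (α-RRA) are
  out of scope.
* Permutation-based FDR for AP-MS interaction calling is not implemented;
  only the BH branch is.
* Image ROIs are inputs (as with manual polygon selection); there is no
  cell segmentation, deconvolution or 3D support.
* The `as_printed` Bonferroni mode reproduces a printed description that is
  not a valid correction; it should only be used to trace legacy numbers.
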