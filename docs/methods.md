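# Methods

`paleotroph` reconstructs the trophic ecology of fossil sharks from the
nitrogen isotope composition of enameloid-bound organic matter (δ15N_EB).
This note records the model, its assumptions, the parameter choices, and the
limits of what the synthetic tests demonstrate.

## The isotopic model

Animal tissue δ15N exceeds diet δ15N by a trophic discrimination factor
(TDF). Stacking this enrichment up a food chain,

    δ15N_tissue(TL) = δ15N_baseline + (TL − 1) · TDF,

where the baseline is the δ15N of nitrogen entering the food web (TL 1,
primary producers). Three tissues are linked by fixed offsets measured on
modern sharks: enameloid-bound organic nitrogen is on average 1.7‰ above
dentin collagen, and muscle is 1.9‰ above dentin collagen. The package
anchors the chain on **dentin collagen** — dentin sits at
`baseline + (TL − 1)·TDF`, EB at +1.7‰, muscle at +1.9‰, and diet one TDF
step below dentin. This choice makes the diet estimator

    δ15N_diet = δ15N_EB − 1.7‰ − TDF_dentin (2.5‰)

an exact inverse of the generating model. Anchoring on muscle instead would
shift every diet estimate by the 1.9‰ muscle−dentin offset; the ambiguity is
real (the three offsets cannot all be consistent with a single per-level
TDF) and is resolved here in favor of the estimator actually used
downstream.

Absolute trophic levels never use the baseline directly. Instead, for each
epoch the pooled δ15N_EB of piscivorous ("fish-eating") shark teeth defines
a reference assumed to hold trophic level 4.4 — the estimated level of the
modern sand tiger shark — through time. For a species group in that epoch:

    Δδ15N = mean_group − mean_piscivores        (SDs added in quadrature)
    trophic offset = Δδ15N / TDF
    TL = 4.4 + trophic offset

The TDF is genuinely uncertain (shark muscle estimates span 2.3–5.5‰), so
every estimate is reported at the range endpoints and a mid value of 2.5‰.

**Assumptions.** (i) Piscivores hold their trophic level across epochs and
regions, so their δ15N_EB tracks baseline variation; the
`baseline_consistency` screen checks that piscivore genus means differ by
less than a threshold (default 3‰) across epochs and regions before this
assumption is leaned on. (ii) Tissue offsets measured on modern sand tigers
apply to extinct taxa. (iii) Diagenesis has not fractionated the preserved
nitrogen; the `diagenesis_screen` flags the loss-with-fractionation
signature (a significantly negative δ15N–N-content correlation) and reports
modern vs. fossil N-content means.

## Raw-measurement reduction

One analysis oxidizes the organic matter of a dissolved enameloid aliquot
to nitrate and measures its δ15N via the denitrifier method. Corrections,
in order:

1. **Scale calibration.** A two-point line through the batch-mean measured
   values of IAEA-NO3 (4.7‰) and USGS34 (−1.8‰). These references bypass
   the oxidation, so they carry no blank; the line is applied to all other
   analyses of the batch. The order (calibrate, then blank-correct) is a
   package choice: the blank model is defined on air-scale values shared by
   reference and sample analyses.
2. **Blank estimation.** The oxidation contributes a blank of n_b nmol
   (measured; batch mean applied to all samples) at unknown δ_b. Under mass
   balance, each amino-acid reference (USGS40 −4.5‰, USGS65 20.68‰, run at
   5–50 nmol) satisfies δ_meas = (1 − f)·δ_cert + f·δ_b with f = n_b/n_tot.
   δ_b is the least-squares solution across the batch's references —
   small-aliquot references carry the most weight. Degenerate designs
   (several references all at one N amount and one certified value) are
   rejected as unidentifiable; a single reference yields the direct
   mass-balance solution. If the references show zero misfit the batch is
   flagged "no detectable blank" and the isotope correction becomes the
   identity (the blank's N is still subtracted from N content, since the
   measured blank size is real even when its isotopic leverage is nil).
3. **Blank correction and N content.**
   δ_sample = (δ_meas·n_tot − δ_b·n_b)/(n_tot − n_b); N content
   = (n_tot − n_b)/mass (nmol/mg ≡ μmol N/g). Re-mixing reproduces the
   measurement to 1e-9‰; a blank ≥ total N is an error, and a blank above
   10% of total N only warns (a quality flag, not a rejection).

Replicates of a specimen are averaged after correction (SD kept when ≥2).
QC statistics from in-house standard triplicates: within-batch SD per
batch, their average ("average variability within batches"), and the SD of
all replicate values pooled across batches ("long-term"). The long-term
value exceeds the within-batch value when batch-level effects (e.g. the
cleaning chemistry) move whole batches together.

## Tissue ground-truthing

Paired EB/dentin values from modern teeth are fit by Deming regression —
errors-in-variables with the error-variance ratio fixed at the square of
the analytical SD ratio, λ = (0.7/0.2)² = 12.25. (The published procedure
states the *ratio of errors* 3.5 defined by the two SDs; a
`ratio_is_variance` switch accepts the other reading.) The slope has the
closed form b = [s_yy − λ s_xx + √((s_yy − λ s_xx)² + 4 λ s_xy²)]/(2 s_xy);
as λ → ∞ (all error on the EB axis) it reduces to OLS of EB on dentin.
Confidence intervals are 95% percentile intervals from a case-resampling
bootstrap (pairs resampled with replacement, B = 10,000 by default, fixed
seed). Percentile/B are package choices — the bootstrap variant is not
prescribed by the procedure being reproduced; BCa was judged unnecessary at
these n. Resamples with zero x-variance are dropped from the percentile
computation. Dentin collagen is the predictor axis.

The Pearson test uses t = r·√((n−2)/(1−r²)) with n−2 df; |r| within 1e-12
of 1 is reported as an infinite-t sentinel with p = 0.

## Synthetic data generator

The generator exists so that every stage can be tested against known
truth. It emulates, with defaults equal to the study conditions described
throughout: Gaussian biological scatter between teeth of a species
(SD 1.0‰ by default — the inter-individual component is not separable from
analytical noise in published summaries, so this split is a free choice
typical of within-species tissue δ15N spreads); Gaussian analytical noise
(0.7‰ EB, 0.2‰ dentin, 0.05‰ for reference materials, whose dedicated
nitrate analyses are far more precise than the whole-method figure);
per-batch oxidation blanks uniform on 0.3–0.5 nmol at a fixed δ_b (5‰ by
default); a linear instrument-scale distortion (default: instrument reads
0.3‰ high); N content by preservation class (modern 7.4 ± 1.9, fossil
4.8 ± 2.0 μmol N/g, truncated at 0.5) multiplied by a 2–5 mg dissolved mass
to give sample N; standard triplicates with a batch-level cleaning effect
(between-batch SD 0.6‰, within 0.37‰, so the long-term SD lands near
√(0.6² + 0.37²) ≈ 0.7‰); and crown heights from inverse-linear length
functions plus 0.1 cm noise, lengths drawn from N(8, 1.5²) m truncated to
[5.5, 11]. The default species list spans Late Cretaceous to modern with
piscivores at TL 4.4 and megatooth-lineage trophic levels rising from 4.6
to 8.8, placing species means where the fossil record puts them
(piscivores ≈ 16.5‰, megatooth maxima ≈ 24–25‰).

What the generator does **not** emulate: diagenetic N-loss kinetics (the
fossil/modern N-content contrast is imposed, not evolved), spatial baseline
fields (only constant per-region shifts), non-Gaussian noise, correlated
replicates, and ontogenetic δ15N trends. Passing recovery tests therefore
demonstrate the *estimators* are correct and calibrated under the assumed
noise model — not that the assumptions hold for any particular fossil
dataset.

Randomness: one `numpy` generator per operation, seeded by the config seed
plus a fixed per-operation salt; a fixed seed gives byte-identical output
tables. Columns prefixed `true_` carry ground truth for tests and are never
read by the analysis code.

## Body size

Total length = intercept + slope × crown height, per tooth-position class.
Exact position labels select their function; ambiguous labels take the
candidate giving the smallest length at that crown height (the conservative
rule), ties broken by class-name order. The shipped coefficients are
synthetic placeholders (source tag `synthetic-placeholder`) chosen only so
the simulated cohort lands in a mid-size range; the published regressions
for living white sharks are configuration data the user supplies
(`length_functions.csv`). Units are fixed: cm in, m out.

## Literature comparison

Observations arrive at mixed granularity (individuals and group
summaries). Family pooling uses the pooled-moments identity — n-weighted
mean, and variance from within-observation SS plus between-observation SS
over (N−1) — so pooled moments equal those of the fully expanded data.
Coverage fractions treat each observation as a point mass of weight n at
its mean, making them invariant to splitting observations. Density curves
are n-weighted Gaussian KDEs (Scott bandwidth, configurable); weighting by
n is the default since observations summarize very different numbers of
individuals.

## Numerical and scale choices

Simulation sizes in the tests and acceptance script: 100 seeded replicates
at 20 teeth/species for trophic-level recovery, 13-pair tissue datasets with
B = 1000 bootstrap for CI coverage, 10,000-replicate null for Welch-test
calibration, 1000 random draws for mass-balance round trips. Headline
values are conventionally read at 1 decimal; outputs always retain full
precision. CSV writers use a fixed `%.9g` float format so a fixed-seed run
is byte-reproducible. No multiple-testing correction is applied to the
per-species Welch tests by default (each is reported with its p-value);
piscivore groups are carried through the estimates table flagged, with
their Δ taken against the pool that includes them.

## Known limitations

* The piscivore-baseline anchor transfers a modern trophic-level estimate
  (4.4) to extinct taxa; any drift in piscivore ecology maps directly into
  absolute levels (differences between taxa within an epoch are unaffected).
* The TDF is the dominant systematic uncertainty; results are reported
  across 2.3–5.5‰ rather than as a single number.
* Deming CIs are percentile bootstrap at small n (13 pairs); coverage is
  checked by simulation to sit in the low-to-mid 90s, not guaranteed
  nominal.
* The blank model assumes one blank size and δ per batch; per-sample blank
  variation is not modeled (a pooled-across-batches option exists).
* Length estimates inherit whatever bias the supplied crown-height
  regressions carry; the package only implements selection and arithmetic.
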