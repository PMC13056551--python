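# Methods

This package reimplements, as a tested pipeline, the statistical analysis
linking empiric azithromycin exposure to changes in the upper-airway
microbiome and expressed resistome measured by nasal-swab metatranscriptomics.
The pipeline starts from post-alignment report tables (per-sample taxon
counts with alignment metadata; per-sample ARG read counts, coverage breadth
and mean depth) — read-level processing, assembly and database alignment are
out of scope and are emulated by the synthetic generator.

## Abundance units

Sequencing depth varies between samples, and ARGs vary in length, so two
normalized units are used throughout:

* **RPM** (reads per million): `reads * 1e6 / total_reads`, where
  `total_reads` is the per-sample post-host-removal microbial read count
  carried in the sample metadata. The upstream pipeline subsamples each
  library to 2 million microbial reads, so the generator defaults
  `total_reads` to 2e6 with small noise. Whether the denominator should be
  the subsampled or pre-subsampling total is not derivable from the report
  tables; it is an explicit metadata column, not an inference.
* **DPM** (depth per million): `mean_depth * 1e6 / total_reads`, where
  `mean_depth` is read depth averaged over the gene's length, so DPM also
  corrects for gene-length differences between ARGs.

Coverage breadth is stored as a fraction in [0, 1]; the CARD-RGI-style
report dialect prints percent, converted at I/O only.

## Negative-binomial decontamination

Water controls sequenced in each of the four processing batches (26 in
total) define a contamination null. For each `(batch, feature)` cell the
null mean is the arithmetic mean of the feature's counts over that batch's
controls; a single dispersion `theta` (NB size; `Var = mu + mu^2/theta`) is
shared across all features and estimated by maximizing the pooled profile
log-likelihood of all control counts with cell means fixed at their sample
means. Cells with zero control mean contribute only a point mass at zero
and are excluded from the `theta` optimization. The 1-D search runs on
`log(theta)` bounded to `[1e-3, 1e6]`; zero-variance data pushes the
estimate to the Poisson limit, which is capped and reported
(`theta_at_boundary`).

Each biological count is then tested against its batch cell with the NB
upper tail `P(X >= x)`. Benjamini–Hochberg adjustment is applied **within
each sample, across that sample's observed features** (a global family is a
config switch); features with `q < 0.1` are retained, the rest zeroed.
Retention is a per-sample-profile decision downstream, which is why the
per-sample family is the default. A feature never seen in the batch's
controls carries no contamination evidence: any positive count is retained
and flagged `unseen_in_controls` rather than entering the BH family, which
avoids `p = 0` artifacts dominating the step-up. Counts are compared on the
raw post-subsampling scale (the upstream pipeline equalizes depth).
Microbiome and resistome tables are decontaminated in two separate runs.

## Per-sample QC filters

After decontamination, spurious hits are removed per record, exactly as the
inequalities read:

* taxa retained iff NT alignments >= 10 AND NR alignments >= 1 AND NT
  alignment length >= 50 bases;
* ARGs **excluded** iff coverage breadth < 5% AND (gene prevalence <= 5% of
  samples-with-ARGs OR (DPM <= 1 AND CARD alignments <= 10)).

Prevalence is computed once over samples having at least one ARG record
after decontamination — a single pass, no iterative re-filtering. Both
filters are deterministic, order-equivariant and monotone in each metric.

## Cohort design

Patients with fully captured antibiotic dates are partitioned: any
azithromycin day -> Azithro (other drugs allowed); else any antibiotic day ->
Other-Abx; else No-Abx. Two single-timepoint windows are defined by
cumulative whole days of the group-defining exposure at sample collection:
early = 1 ± 1 days ({0,1,2}) and late = 5 ± 1 days ({4,5,6}); under whole-day
counting these cannot overlap. Treated-group samples collected before any
dose are moved to the No-Abx pool and flagged. No-Abx comparators are
matched on hospital day (early: <= 40; late: 3–40); samples qualifying for
both windows are split evenly by alternating over sorted sample ids (a
deterministic stand-in for an unstated rule), and the No-Abx pool is then
rarefied to 50% (`floor(n/2)` discarded uniformly with a required seed) to
balance group sizes. Whether exposure days are calendar days or 24-hour
periods from first dose is not determinable from day-resolution data;
calendar days are used.

## Diversity

Shannon diversity uses the natural log (the convention of the common
ecology toolkits; log2 is a switch) on genus-level RPM for the microbiome
and gene-level DPM for the resistome. Beta diversity is Bray–Curtis,
`sum|u-v| / sum(u+v)`. PCoA is classical scaling (double-center `-D^2/2`,
eigendecompose, scale by sqrt eigenvalue) with negative eigenvalues dropped
and reported. The permutational test is the one-factor special case: a
pseudo-F from between/within sums of squared distances with
`p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)`, seeded; an exhaustive mode
enumerates all label permutations at small n. Covariate-adjusted
multi-factor PERMANOVA is deliberately out of scope and the one-factor test
says so in its docs.

## Association statistics

* **BH**: step-up with monotonicity enforcement, order-invariant.
* **Rank-sum test**: Wilcoxon rank-sum with midranks; exact enumeration of
  all label assignments when combined n <= 12 (two-sided
  `p = 2 * min(tail masses)`, capped at 1), tie-corrected normal
  approximation with continuity correction otherwise.
* **Fold change**: ratio of arithmetic group means (the source analyses
  report FC without defining it; a median-ratio switch exists).
* **Group model**: linear mixed model of the metric on group (reference
  No-Abx) plus age quintile, sex, trajectory group, days from admission and
  steroid receipt, with an enrolment-site random intercept, fitted by REML;
  group-contrast p-values BH-adjusted within the metric family run
  together. With the random effect off it reduces to OLS (tested).
* **Exposure trend**: additive model with natural cubic-spline smooths
  (basis size 4, knots at quantiles) for azithromycin days and each of the
  six common co-antibiotics (vancomycin, ceftriaxone, cefepime,
  piperacillin-tazobactam, doxycycline, meropenem), a smooth for days from
  admission, linear covariate terms and a patient random intercept. Samples
  are restricted to the first 10 hospital days and 5 exposure days (longer
  courses are rare). The azithromycin smooth is tested by a likelihood-ratio
  comparison of nested ML fits — REML likelihoods are not comparable across
  fixed-effect structures — with chi-squared df equal to the basis columns
  dropped. The basis is unpenalized: at k = 4 the smooth has 3 effective
  columns, and the smoothing-penalty machinery of a full GAMM adds little at
  that dimension while complicating the LRT; this is a deliberate design
  choice documented here. Degenerate covariates shrink gracefully (linear
  for 2–3 unique values, dropped with a warning for constants). The fitted
  exposure-response curve and pointwise 95% interval come from the
  fixed-effect covariance with other terms held at sample means.
* **Correlation network**: Spearman (midranks) between the 30 most abundant
  genera by summed RPM and MLS gene DPM over matched samples; two-sided p
  per pair, BH across all pairs, edges where rho > 0.2 AND q < 0.05 (the
  rule is one-sided positive). Constant vectors are flagged undefined and
  excluded from the BH family.

## Resistome summaries

"Detectably expressed" = DPM > 0 after the full retention cascade
(decontamination then QC), with no additional threshold; richness counts
distinct genes (not allele variants). Class proportions divide per-class
summed DPM by total DPM; a zero-DPM sample returns an explicit empty result,
never silent zeros. The persistence window selects samples 7–10 days after
the last azithromycin day for the paired comparison against the late window.

## Synthetic data generator

The generator emulates the post-pipeline data layout of the study: a
multi-site cohort (defaults: 1,164 patients; Azithro/Other-Abx/No-Abx
enrolment fractions 366/324/474; 15 sites; 4 batches), azithromycin courses
with median 2 days starting shortly after admission, ceftriaxone (77%) and
vancomycin (19%) as dominant co-drugs, six visits at target days
0/4/7/14/21/28 with 80% retention, 26 water controls across the batches,
and ~2e6 total reads per sample.

Contaminant features (sequencing-reagent genera such as *Ralstonia* and
*Bradyrhizobium*, plus a few mobile-element ARGs) are drawn
NB(per-batch:feature mean, theta = 2) identically in biological samples and
controls; genuine biology never appears in controls. True genus abundances
are log-normal per patient with AR(1) temporal autocorrelation (rho = 0.6)
on the log scale. Every patient carries every ARG at a latent expression
level — overt carriage well above the detection limit, the rest below it —
and a gene is emitted only when its depth yields at least one read over the
gene's length. Azithromycin exposure multiplies MLS-gene depth by
`azithro_effect` (default 1.4) per cumulative exposure day (capped at 5
days), which both raises expressed levels and pushes sub-detection genes
above the limit, reproducing the rise in detectable MLS richness; bacterial
reads are mildly suppressed (0.96/day). Gene baselines put the unexposed
MLS share of resistome depth near a quarter, and each gene's expression
co-varies with its host genus's abundance (staphylococcal genes with
*Staphylococcus*, streptococcal with *Streptococcus*), giving the
correlation network its documented structure. A configurable fraction of
records (5%) deliberately violates each QC rule so the filters always have
work to do.

What the generator does **not** emulate: realistic phylogenetic
composition, read-level error processes, viral dynamics, site-level
enrolment imbalance, informative dropout, or any coupling between disease
severity and the microbiome. Passing tests therefore demonstrate that the
statistical machinery is correct and calibrated under the stated model, not
that the biological effect sizes of any real cohort are recovered.

## Problem sizes and numerics

Tests and the acceptance script run the pipeline at 40–200 patients (the
package's own desk-scale choice; the cohort-scale defaults remain the
generator's). Calibration suites use 400 simulations for type-I error
(3-sigma binomial bands), 50 simulations for decontamination FDR control,
and 25 seeded runs for effect detection. Numerical tolerances: 1e-10 to
1e-12 against closed forms and enumeration oracles, 1e-6 for the Poisson
limit at theta = 1e6, 1e-8 for Euclidean PCoA recovery. Mixed-model fits
fall back across optimizers (lbfgs, bfgs, powell, cg) on numerical failure.

## Known limitations

* The FDR family for decontamination (per sample vs global) is not stated
  in the source analysis; both are implemented, per-sample is the default,
  and neither is claimed to be the original.
* The one-factor permutational test documents its divergence from the
  covariate-adjusted original.
* Cohort-scale headline numbers (e.g. exact fold changes or the exact MLS
  proportion shift) depend on the restricted clinical dataset and are not
  reproduced numerically; the pipeline reproduces the qualitative findings
  on synthetic data at desk scale.
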