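# airway-resistome

Statistical pipeline for studying how empiric antibiotic exposure —
azithromycin in particular — reshapes the upper-respiratory microbiome and
its expressed antimicrobial resistance genes (the *resistome*), as measured
by longitudinal nasal-swab metatranscriptomics in a multi-site hospital
cohort.

The package is aimed at analysts working with CZ-ID-style taxon reports and
CARD-RGI-style ARG reports plus clinical metadata. It covers the full
statistical chain downstream of read alignment:

1. **Decontamination** — a negative-binomial null fitted to water controls
   per processing batch: mean `mu_{batch,feature}` per cell, one shared
   dispersion `theta` (`Var = mu + mu²/theta`) by pooled profile likelihood;
   a count `x` is kept when its upper tail `P(X >= x)` survives
   Benjamini–Hochberg at FDR < 0.1.
2. **QC filters** — taxa need >= 10 NT alignments, >= 1 NR alignment and
   >= 50 aligned bases; ARGs with < 5% coverage breadth are dropped when
   rare (<= 5% of samples-with-ARGs) or weakly supported (DPM <= 1 and
   <= 10 alignments).
3. **Abundance and diversity** — RPM = reads·10⁶/total reads,
   DPM = mean depth·10⁶/total reads; Shannon `H = -Σ p_i ln p_i`;
   Bray–Curtis `Σ|u−v| / Σ(u+v)`; classical PCoA; one-factor PERMANOVA.
4. **Cohort design** — Azithro / Other-Abx / No-Abx groups; 1 ± 1-day and
   5 ± 1-day exposure windows with day-matched, 50%-rarefied No-Abx
   comparators.
5. **Models** — site-random-intercept linear mixed models for group
   contrasts; additive exposure-trend models with cubic-spline smooths
   (k = 4) per antibiotic and a patient random intercept, tested by
   likelihood ratio; Spearman taxa × ARG networks (edges: rho > 0.2,
   q < 0.05).
6. **Synthetic data** — a seeded generator emulating the whole study
   (batch-specific contamination in 26 water controls, 6 timepoints over
   28 days, exposure-dependent MLS-gene enrichment), so every stage is
   testable without any restricted clinical download.

See `docs/methods.md` for the full model descriptions and assumptions.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (150 patients, seed 1) and write their tables under `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_decontaminate.py
python analysis/03_qc_filter.py
python analysis/04_cohort_design.py
python analysis/05_diversity.py
python analysis/06_single_timepoint.py
python analysis/07_longitudinal_trends.py
python analysis/08_correlation_network.py
```

Selected output (verbatim):

```
taxa: theta = 2.68; 20074 of 26183 biological records retained
PERMANOVA (azithro-exposed vs unexposed): F = 5.49, p = 0.001 (259 vs 502 samples)
late  mls_richness  Azithro vs No-Abx  estimate 2.3785  q 0.0000  fold_change 1.7802
mls_richness: azithromycin smooth LRT p = 8.95e-10 (stat 45.07, df 3); day-0 -> day-5 rise = 1.986 over 761 samples
persistence: late-window MLS richness (n=61, mean 5.31) vs 7-10 d post-cessation (n=21, mean 4.43), rank-sum p = 0.0216
6 edges (rho > 0.2, q < 0.05) among 180 taxon x gene pairs over 735 samples
t_Staphylococcus ermC 0.487 ...
```

Reading: the decontamination null has moderate overdispersion
(theta ≈ 2.7); azithromycin-exposed samples differ in community composition
(PERMANOVA p = 0.001); after 5 ± 1 days of azithromycin the number of
detectably expressed MLS resistance genes is ~1.8-fold that of unexposed
controls and rises by ~2 genes over five exposure days (LRT p ≈ 1e-9);
elevated richness persists 7–10 days after the last dose (mean 4.4 vs a
~2.7 unexposed baseline); and MLS gene expression correlates with its host
genera (*Staphylococcus* with *ermC/mphC/msrA/ermA*, *Streptococcus* with
*mefA/ermB*).

The same stages are scriptable from the shell:

```bash
airway-resistome simulate --seed 1 --n-patients 100 --out data/
airway-resistome decontam --taxa data/taxon_report.tsv --args data/arg_report.tsv \
    --meta data/metadata.csv --out decontam/
airway-resistome qc-filter --taxa decontam/taxa_decontaminated.tsv \
    --args decontam/args_decontaminated.tsv --meta data/metadata.csv --out filtered/
airway-resistome pipeline --seed 1 --out report/
```

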