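# Methods

`lipidscreen` re-creates, as reusable and tested code, the analysis chain of
a serum-lipidomics screening study for pancreatic ductal adenocarcinoma
(PDAC): internal-standard quantitation of lipid species from centroided
mass-spectral peak lists, cohort-level preprocessing, gender-stratified
OPLS-DA classification of cases versus healthy controls, univariate
dysregulation statistics, comparison/combination with the CA 19-9 tumor
marker, and survival analysis on median-dichotomized lipid concentrations.
Because clinical raw data cannot ship with the package, a first-class
synthetic-cohort generator reproduces the statistical structure the
analysis assumes, and every stage is validated against it.

## Quantitation model

A peak list is a centroided m/z–intensity table for one sample and one
lipid-class scan window. Processing follows four steps:

1. **Extraction.** Peaks with intensity strictly above 3000 counts are
   retained.
2. **Identification.** Each peak is assigned to the nearest database
   species of its class window when |Δm/z| ≤ 5 mDa (boundary inclusive;
   equidistant ties go to the lower exact m/z; each species keeps its most
   intense qualifying peak). Database entries closer than twice the
   tolerance trigger a logged warning.
3. **Isotope correction.** Type II first: in ESI lipidomics the M+2
   isotopologue of the species with one more double bond lies only 8.9 mDa
   below a species' monoisotopic peak and is co-assigned at typical
   centroid resolution, so its contribution — computed from the donor's
   isotope envelope — is subtracted (processed in ascending donor mass so
   corrections chain; results floored at 0). Type I then divides each
   intensity by the monoisotopic fraction of the species' envelope.
   Envelopes are computed from the molecular formula by truncated
   convolution of per-element isotope distributions using NIST natural
   abundances (M+0…M+2). The exact algorithm used by the original
   laboratory software is unpublished; this I/II scheme is a documented
   stand-in validated by round trip against the spectrum generator.
4. **Quantitation.** concentration = (corrected intensity of analyte /
   corrected intensity of the class internal standard) × spiked IS
   concentration, in nmol/mL. A missing or zero IS makes the whole class
   *missing* (never zero) with a warning.

Unassigned species are stored as missing with provenance `absent`;
per-cell provenance (`measured`/`imputed`/`absent`) travels with the
concentration matrix.

## Preprocessing

- **Presence filter:** species observed (positive, non-missing) in fewer
  than 25% of samples are excluded; exactly 25% is retained.
- **Imputation:** remaining zero/missing cells become 80% of the species'
  minimum positive value across *all* samples (not per group), flagged
  `imputed`. Imputation runs after filtering, so it can never rescue an
  excluded species.
- **NIST harmonization:** when several methods measured the same cohort,
  each value is rescaled by (cross-method mean of the NIST SRM 1950 value
  for that species) / (this method's NIST value), preserving nmol/mL.
  Anchoring to the cross-method mean is this package's choice; the source
  study does not state its formula.
- **Transformation:** natural log, then centering and unit-variance or
  Pareto scaling (divide by √sd). Scaling parameters are fitted on the
  training set only and re-applied verbatim to validation data.
- **Split:** a seeded permutation within each group × gender stratum;
  1-based positions 6, 12, 18, … become the validation set ("every 6th
  sample"). The original study's physical sample ordering is unknown, so
  published per-phase validation counts are not reproduced exactly — a
  documented limitation.

## OPLS-DA

Single-response orthogonal projections to latent structures (Trygg–Wold
NIPALS formulation). The predictive weight is the normalized covariance
direction w ∝ X′y. Each orthogonal component takes the current loading p,
removes its projection on w (w_o ∝ p − (w′p/w′w)·w), deflates X by the
orthogonal score/loading pair, and the final predictive component is
computed on the filtered X. With zero orthogonal components the model is
exactly one-component PLS1 (asserted to 1e-8 against scikit-learn in
tests). The predictive score is oriented so the case-class mean is
positive. Commercial chemometrics software keeps its internals
proprietary; exact numeric agreement with it is not a goal.

- **Q²** = 1 − PRESS/SS via 7-fold venetian-blind cross-validation on a
  seeded permutation, refitting scaling per fold when requested.
- **Orthogonal component count** is selected automatically: components are
  added while Q² improves by more than 0.01 (overridable).
- **Classification:** a sample is called cancer iff predicted Y > 0.5
  (0.5 itself is non-cancer). Sensitivity/specificity/accuracy are
  reported in percent; ROC/AUC uses a threshold sweep with tie handling
  equal to the Mann–Whitney statistic.
- **VIP** sums the per-component explained-Y share over predictive and
  orthogonal components (the latter contribute ~0 by construction);
  mean(VIP²) = 1 exactly. **S-plot** coordinates are the covariance (p1)
  and Pearson correlation (p(corr)1) of each variable with the predictive
  score.

## Dysregulation statistics

Welch's unequal-variance two-sided t-test per species (delegated to
scipy; cross-checked against the closed-form Welch–Satterthwaite formula
in tests), Bonferroni correction with m = number of species tested in the
stratum, and fold change formalized symmetrically: percent change =
(max(r, 1/r) − 1)×100 with r = mean_T/mean_N, so a ratio of 0.80 is a 25%
change. A species is *relevant* iff p < 0.05 (strict), VIP > 1 (strict)
and percent change ≥ 20% (inclusive); Bonferroni-surviving species are
*especially significant*. Box-plot summaries use type-7 quartiles and, as
in the source figures, whiskers spanning 1.5·IQR from the **median**
(clipped to the data range); the common from-quartile Tukey convention is
available as an option.

## Survival analysis

Concentrations are coded 0/1 against the median over all samples (ties →
0, configurable only by recoding). Kaplan–Meier estimation, the two-sided
log-rank test (hypergeometric variance), and Cox proportional hazards by
Newton–Raphson partial-likelihood maximization are implemented here, with
Breslow tie handling by default and Efron optional; lifelines serves as
the independent cross-check in the test suite, never as the
implementation. Standard errors come from the inverse observed
information; CI95 = exp(β ± 1.96·SE); HR > 1 means poorer survival for the
above-median group. Separation (monotone likelihood) is detected when a
coefficient passes |β| > 20 and raises; singular information (duplicated
covariates) raises. Per-lipid models are univariate by default; a joint
model is available.

## Synthetic cohorts

The generator emulates what the analysis assumes about real serum data;
defaults are this package's choices (no public source gives serum lipid
concentration distributions) and are fixed in `CohortConfig`:

- **Concentrations** are lognormal per species. Baseline geometric means
  are drawn once per species from a lognormal centered at 5 nmol/mL
  (ln-sigma 1.2, spanning ≈0.2–100 nmol/mL); within-group coefficient of
  variation is 0.30. Group effects act multiplicatively on the geometric
  mean, so configured fold changes are recovered in expectation.
- **Markers:** seven species (SM 41:1, SM 42:1, SM 39:1, Cer 41:1,
  Cer 42:1, LPC 18:2, PC O-36:3) are downregulated in cases with
  geometric-mean ratios 0.45–0.65; the remaining species are null.
  Pancreatitis samples are drawn from the control distribution.
- **Metadata:** gender (default half female, optional per-species gender
  effect), age uniform per group (cases 45–85, controls 35–80), stage
  T1–T4 assigned to cases independently of lipid effects, four collection
  sites, a diabetes flag, and lognormal CA 19-9 (ln-params: controls
  (2.3, 0.8) ≈ median 10 U/mL; cases (4.0, 1.2) ≈ median 55 U/mL, i.e.
  most cases above the 37 U/mL cut-off).
- **Survival:** cases draw exponential times with hazard
  h0·exp(Σβ_j·z_j), h0 = 1/24 per month, z_j the above-median code;
  administrative censoring at 60 months; LPC 18:2 is protective
  (β = −0.7) in the default pipeline configuration.
- **Spectra:** sticks at database m/z with Gaussian jitter (sd 1 mDa,
  clipped at 3σ), intensity = concentration × response factor
  (10^4 counts per nmol/mL), optional M+0…M+2 isotopologues from the
  formula, per-class internal standards at their spiked concentrations,
  and a few noise peaks below 3× the noise floor placed away from analyte
  peaks. Sticks closer than 15 mDa merge into one intensity-weighted
  centroid, which reproduces the double-bond M+2 co-assignment that type
  II correction removes. No chromatographic peak shapes, profile-mode
  spectra, or batch effects beyond a single drift term are simulated.

What passing tests show — and what they do not: round trips and recovery
simulations demonstrate internal consistency of quantitation, modelling,
and survival estimation under the generator's lognormal,
independent-species world. Real serum adds correlated lipid classes,
batch and instrument drift, non-lognormal tails, and preanalytical
variation that the generator does not model, so synthetic performance
numbers (e.g. validation sensitivity/specificity near 100%) characterize
the pipeline, not clinical accuracy.

## Numerical choices

- Natural log everywhere; any fixed base is equivalent after scaling.
- PCA via SVD, sign fixed by making each loading's largest-magnitude
  entry positive.
- Matching tolerance boundary inclusive; ties to the lower exact m/z.
- Isotope envelopes truncated at M+2 (exact for retained terms).
- Quartiles by linear interpolation (type 7).
- Cox Newton–Raphson with step-halving, convergence at step < 1e-9 or
  Δlog-likelihood < 1e-12, at most 100 iterations.
- Zero-variance variables: centered with scale 1 (warning); correlation
  reported missing in S-plots; constant CA 19-9 dropped before combining.
- Problem sizes in tests and the acceptance script (e.g. 300+300-sample
  cohorts, 10–100 simulation replicates, 2000 replicates for the
  log-rank type-I check) are chosen to make Monte-Carlo bands tight at
  desk scale while keeping the default suite fast.

## Known limitations

- The isotope-correction scheme is a stand-in for unpublished laboratory
  software; it is validated only against this package's own generator.
- The every-6th split operates on a seeded permutation, not the original
  acquisition order.
- NIST harmonization assumes a stable cross-method mean anchor; per-gender
  harmonization is available as a flag but off by default.
- CA 19-9 combination appends log CA 19-9 as one extra scaled variable —
  an interpretation, since the original combination mechanism is unstated.
- No multiclass models, time-varying covariates, stratified Cox, or
  pathway enrichment.
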