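# Methods

This note documents the models, defaults and numerical choices behind each
stage, what the synthetic generator does and does not emulate, and the
design decisions taken where more than one reasonable convention exists.

## Bioenergetic profile

**Data model.** A flux plate is a long table of per-well OCR/ECAR
measurements: three cycles per section (basal, post-injection-1,
post-injection-2), three injection schemes (A: oligomycin then
rotenone/antimycin A; B: FCCP then rotenone/antimycin A; C: oligomycin
then 2-deoxy-D-glucose), plus a layout mapping wells to subject, group and
scheme. Validation rejects unknown schemes/sections, wells present in only
one of trace/layout, ragged cycle counts, and (unless `allow_negative` is
set) negative OCR, which can only arise as instrument noise.

**Section summaries.** Each well's three cycles per section are collapsed
by a configurable `SummaryPolicy`. Default: basal = mean of the three
cycles; the plateau after an inhibitor is taken at its extreme (minimum
after oligomycin, rotenone/antimycin and 2-DG; maximum after FCCP). The
extremes convention matches vendor report generators and is robust to
injection lag. Note the oligomycin rule is applied uniformly, including
scheme C where the summarised signal is ECAR; some glycolysis-stress
conventions take the maximum ECAR after oligomycin instead — use
`SummaryPolicy.from_mapping({"C:inj1": "max"})` for that reading. On
noise-free (constant-cycle) data all policies coincide.

**The 14 parameters.** Schemes contribute per-well parameters as follows
(each scheme's own rotenone/antimycin plateau corrects its own wells; no
baseline is transferred across wells):

| parameter | formula | source |
|---|---|---|
| basal_respiration | basal − nonmito OCR | A |
| nonmito_respiration | post-rot/AA OCR | A |
| atp_linked_respiration | basal − post-oligomycin OCR | A |
| proton_leak | post-oligomycin − nonmito OCR | A |
| coupling_efficiency (%) | 100 × ATP-linked / basal_respiration | A |
| maximal_respiration | post-FCCP − nonmito OCR | B |
| spare_respiratory_capacity | maximal / basal_respiration (ratio) | B |
| atp_linked_to_maximal | subject mean ATP-linked / subject mean maximal | A×B |
| basal_ecar | basal ECAR | C |
| glycolysis | basal ECAR − nonglycolytic | C |
| glycolytic_capacity | post-oligomycin ECAR − nonglycolytic | C |
| glycolytic_reserve | capacity / glycolysis (ratio) | C |
| nonglycolytic_acidification | post-2-DG ECAR | C |
| ocr_ecar_ratio | subject mean basal OCR / basal ECAR (A∪B wells) | A,B |

Spare capacity and glycolytic reserve are ratios (difference variants can
be derived trivially from the emitted columns). Division by a non-positive
denominator yields NaN, flagged, never a silent number; negative corrected
values from noise are retained, not clipped, because clipping would bias
group means upward.

**Pooling and group statistics.** Replicate wells are pooled per subject:
mean and sample SD (ddof = 1; SD is NaN for a single well). The two
cross-scheme ratios are computed from subject-level means because the
schemes live in different wells and admit no natural pairing. Group
comparison is a two-sample Student *t* (equal variance; Welch behind
`welch=True`) on subject means, fold change = patient mean / control mean,
with Bonferroni adjustment `min(1, 14p)` across the parameter family. Both
raw and adjusted p are always reported: at n = 6 vs 4 a real
coupling-efficiency difference can be nominally significant (raw p ≈ 0.04)
yet not survive ×14, so significance labelling of exploratory outputs
follows the raw p and the adjusted column quantifies the multiplicity
cost. Wells whose layout group is neither `patient` nor `control` (e.g. an
inter-experiment calibrator sample) are profiled and logged but excluded
from the statistics.

## Protein screen

Inclusion requires ≥ 2 unique peptides and ≥ 5 quantitative scans (both
inclusive). Fold-change thresholds come from the control group's own
technical variability: per-protein CV = SD/mean over control channels,
upper threshold = 1 + 2 × median CV, lower = 1/upper (reciprocal, i.e.
symmetric on the log scale; with a median CV of 0.06 this gives 1.12 and
0.893 ≈ 0.89 at display precision). Classification uses full precision
with *inclusive* comparisons (FC ≥ upper, FC ≤ lower) — a published table
that prints FC = 1.12 or 0.89 rows as hits is only consistent with
inclusive bounds at printed precision. FC is the ratio of arithmetic group
means on the linear scale; the *t*-test runs on log₂ abundances (common
TMT practice; both are the defaults rather than options because the
alternative conventions change results only in the third decimal at these
noise levels). The pathway group test is the minimal reading of a
one-line description: a one-sample Student *t* of member proteins' log₂
fold changes against zero. The packaged mitochondrial gene list is a small
curated subset for offline tests and demos; pass a full inventory (e.g. a
MitoCarta export) via `--mito-list` for real analyses.

## Metabolomics

Pipeline order is fixed: QC filter → minimum/5 imputation → glog →
Pareto. The QC filter is a deliberately simple two-rule surrogate (drop a
compound if QC-replicate CV > 0.25 or missingness > 0.3, applied
independently per LC/FIA platform) for the much richer vendor QC cascade
that produces tables like these upstream; it is not claimed to reproduce
any particular cascade's retention count on real data. Missing values are
treated as left-censored at the limit of detection, which is exactly the
regime where replacing them by one fifth of the compound's minimal
positive value is a sensible constant. The glog offset `a` defaults to one
tenth of the smallest positive value in the matrix (the transform's
authors leave it free; this keeps the transform ≈ log₂ over the observed
range while taming the censored tail) and is recorded in the
`PreprocessReport`. Pareto scaling centres each compound and divides by
√SD. Fold-change screening (strictly > 1.3 or < 0.77, matching the
convention that prints those bounds as strict) runs on raw concentrations,
while *t*-tests (Benjamini–Hochberg FDR via statsmodels) and PCA (SVD of
the already-centred scaled matrix; loadings orthonormal) run on the
transformed/scaled values. Compounds with raw p < 0.05 but adjusted
p ≥ q are labelled `nominal_only`.

## Clinical scores

FSMC total = motor + cognitive subscales (enforced), severe fatigue above
63. Pearson correlations use the exact *t* transform for two-sided p,
pairwise-complete cases per pair (so n can drop when a subject's
questionnaire is incomplete), and no multiple-testing correction by
default (a BH column is available behind `fdr=True`). The COMPASS-31
weighted total is an input, not recomputed — item-level scoring of all
three instruments is out of scope since the analyses operate on domain
scores only. `group_compare` (fold change, Student *t*, per-group CV) is
the generic two-group comparison used for carbonyl- and steroid-like
per-subject measures.

## Synthetic cohort generator

Defaults are the study conditions the package targets: 6 patients vs 4
controls; a 0.87 multiplicative effect on the patients' ATP-linked
fraction; 3300 proteins with 13 up-spiked (FC 1.5) and 9 down-spiked
(FC 0.7); a 408-compound panel (42 LC / 366 FIA) with 1.2% missingness;
questionnaire correlation target 0.93. Per-scheme well counts are not a
published quantity; the default of 8 wells per subject per scheme is a
typical plate allocation and is configurable.

**Flux.** Control truth: basal OCR 100 pmol O₂/min, non-mitochondrial
fraction 0.20, ATP-linked fraction 0.75 of mitochondrial basal, maximal =
2× mitochondrial basal; basal ECAR 30 mpH/min, non-glycolytic fraction
0.25, capacity 1.6× glycolysis. The patient effect multiplies only the
ATP-linked fraction, so the expected group coupling-efficiency fold change
equals `coupling_effect` exactly, proton leak moves in the opposite
direction, and all other parameters are null — matching a study in which
coupling efficiency is the only significant bioenergetic difference. Well
measurements are the true section mean times i.i.d. log-normal noise with
CV `noise_cv` (multiplicative noise preserves positivity and matches the
CV parameterisation of flux data). Between-subject biological variability
defaults to **off** (`between_subject_cv = 0`): heterogeneity then enters
only through measurement noise, which makes recovery and type-I
calibration exactly interpretable; turn it on for more realistic cohorts.
Consequently, passing recovery tests demonstrate estimator correctness
under the stated noise model, not robustness to biological heterogeneity,
outliers, or plate effects — none of which are simulated.

**Proteins.** Log-normal baselines (log-scale SD 1 around 10⁶), per-channel
log-normal noise with CV `protein_noise_cv` (default 0.06, the
variability that yields control-CV-derived thresholds near 1.12/0.89; note
the *sample* median CV of 4 controls is ~11% below the generating CV, so
derived thresholds on synthetic data land at ≈ 1.11). Spiked proteins
multiply patient channels by the spiked FC and always pass the inclusion
filter; a `filter_fail_rate` fraction of null proteins is engineered to
fail it (half by peptides, half by scans). A `mito_fraction` of proteins
(default 0.085 ≈ 280 of 3300) is flagged mitochondrial and given symbols
from the packaged list so gene-based subsetting is exercisable.

**Metabolites.** Log-normal concentrations with per-compound baselines
spread log-uniformly over three decades; each compound's limit of
detection sits at the `missing_rate` quantile of its own sampling
distribution, so censoring is missing-not-at-random by value and the
marginal missing probability per cell equals `missing_rate`. Three QC
replicate columns at CV `qc_cv`; `n_fail_qc` compounds are engineered to
fail the QC filter deterministically (half by a fixed wide replicate
spread, CV ≈ 0.68; half by forced missingness), so a panel of 200 with 19
engineered failures retains exactly 181.

**Questionnaires.** A latent severity is N(0,1) for controls and
N(gap, 1) for patients (gap default 3). Each instrument is an affine map
of severity anchored at calibrated group means (the packaged questionnaire
reference fixture) plus Gaussian noise. `questionnaire_corr` targets the
*between-instrument* correlation: each instrument receives correlation
√`questionnaire_corr` with severity, so any two instruments correlate at
the target through their shared latent — this is the observable the
correlation analyses measure (e.g. fatigue total vs autonomic score).
Because FSMC is emitted as the sum of two subscales, subscale noise is
inflated (ρ_sub = 1/√(1 + 2(1/ρ² − 1))) so the *total* carries the
instrument-level correlation. Scores are clamped to instrument ranges
(FSMC subscales 10–50, SF-36 domains and COMPASS-31 0–100); clamping
attenuates the realised correlation slightly (≈ 0.01 at the defaults) and
a warning is logged if the attenuation exceeds 0.1 rather than raising.

## Numerical choices and degenerate inputs

- Sample SD everywhere (ddof = 1); SD of a single replicate is NaN, flagged.
- Ratios guard their denominators: non-positive → NaN + flag, never raise.
- Zero-variance compounds are centred but not Pareto-scaled (warning);
  constant correlation inputs give a flagged undefined result.
- A pathway whose members' log₂ FCs are exactly all zero is reported with
  t = 0, p = 1 (no evidence) instead of the *t*-test's 0/0.
- Degenerate thresholds (median control CV = 0 → bounds (1, 1)) warn and
  make every p-passing protein a hit, matching the inclusive-bound limit.
- Seeding: every generator draws from an independent substream
  `default_rng([seed, layer])`, so layers are reproducible independently
  and jointly.

## Problem sizes used by tests and the acceptance script

Recovery and calibration quantities are estimated at sizes chosen to make
the Monte-Carlo error small relative to the quantity's acceptance band:
coupling-efficiency recovery over 20 cohorts; flux type-I error over 72
null cohorts × 14 parameters (1008 tests); DAP spike recovery over 20
cohorts of 3300 proteins; null raw-p calibration over 20 × 1000 proteins;
questionnaire correlation at n = 200 over 5 seeds (median); metabolite
missingness over 10 panels of 181 × 10 cells. The acceptance script's
carbonyl fold change uses the same ratio-of-group-means estimator as the
group comparison; at within-group CV 0.5 with 4 controls this estimator is
upward-biased by ≈ 6% (small-sample bias of 1/mean), which is a property
of the estimator, not of the simulation.

## Known limitations

- The QC surrogate, not being the vendor cascade, will not reproduce a
  real study's compound retention on real exports.
- The generator simulates neither raw spectra, reporter-ion structure,
  chromatograms, instrument drift, plate/batch effects, nor item-level
  questionnaire responses; per-cell normalisation and instrument-level
  flux corrections (background wells, pH drift) are out of scope.
- The packaged mitochondrial list is a ~55-gene subset; mitochondrial
  summaries on real data require a full inventory file.
- With 6 vs 4 subjects the screens are exploratory by construction: the
  DAP screen's raw-p criterion admits the expected ~5% false positives,
  and the correlation analyses report raw p-values.
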