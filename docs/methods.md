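# Methods

`kormeth` implements a targeted bisulfite-sequencing differential-methylation
analysis of the *OPRK1* (kappa-opioid receptor) promoter comparing women with
borderline personality disorder (BPD, n = 47) against healthy controls (HC,
n = 48). The pipeline starts at per-CpG read counts (Bismark coverage dialect)
and runs three analysis parts: (1a) covariate-adjusted group comparison of a
priori promoter regions, (1b) a coverage-aware per-CpG screen with FDR
control and DMR calling, and (2, 3) association of DMR methylation with
symptom severity and childhood-trauma measures. Because the subject-level
study data are not publicly deposited, a synthetic-cohort generator provides
inputs with the statistical structure the analysis assumes; it is first-class,
tested code.

## Coordinates and orientation

All coordinates are hg38, 1-based, both-ends inclusive, on chr8. The target
window chr8:53246080–53256098 spans 5 kb either side of the translation start
(chr8:53251036) and contains 189 designed CpG sites. *OPRK1* is on the
reverse strand, so "upstream" in gene terms means a *higher* genomic
coordinate, and CG identifiers increase 5′→3′ along the gene, i.e. with
decreasing position (CG17 at 53254514 precedes CG34 at 53252198). The a
priori regions are CGI-1 (53251468–53251883; 416 bp inclusive, 52 CpGs),
CGI-2 (53250744–53251285; 542 bp, 62 CpGs) and the enhancer EH1
(53253201–53254400; 4 CpGs). Published region sizes mix length conventions —
the island sizes are inclusive (end − start + 1) while the DMR's 184 bp is the
coordinate difference — so the registry stores raw coordinates and reports
both conventions, labelled.

## Coverage filter

Cells (subject × site) with fewer than 25 reads are masked; the filter is
per cell, not per site, because the downstream per-site model weights
subjects by coverage anyway. A site is dropped entirely only when fewer than
3 unmasked subjects remain in either group (configurable). Under the default
generator, 15 poor-capture sites fall below the filter everywhere, so 189
designed sites reduce to 174 analyzed — reproducing the designed→analyzed
bookkeeping of the study (the intermediate 175 is the post-filter candidate
count before the per-group minimum is enforced).

## Statistical models

**Region tests.** For each subject, the region methylation is the unweighted
mean of per-site rates over unmasked member CpGs. Group differences are
tested by OLS of the mean rate (percentage scale; no logit transform) on a
BPD indicator, age (years) and BMI (kg/m²); the statistic is the t of the
group coefficient with residual df = n_complete − 4, and adjusted group means
are model predictions at the sample-mean covariates (their difference equals
the group coefficient exactly). Residual normality (Shapiro–Wilk) and
homoscedasticity (Breusch–Pagan) are checked at α = 0.05; a nonparametric
case-resampling bootstrap (default 10,000 replicates; percentile 95% CI;
two-sided p = twice the smaller tail fraction at zero) is computed for every
region and is the headline result wherever a diagnostic fires. Bootstrap
replicates missing one group or with a singular design are discarded and
counted; >10% discards raises a warning. Constant covariates are dropped from
the design rather than failing (the model then reduces to the plain
two-sample comparison; df adjusts accordingly).

**Per-CpG screen.** Each testable site is fit with a binomial
(events/trials) logistic regression of per-subject (methylated,
unmethylated) counts on group + age + BMI, so information scales with read
coverage. The reported statistic is the group log-odds difference over its
standard error, referenced to a t distribution with df = n_used − 4 (the
asymptotic-normal p is emitted alongside). The odds ratio is oriented
odds(HC)/odds(BPD): OR > 1 means BPD-hypomethylated. This orientation is
fixed by the published table, where every BPD-hypomethylated site has OR > 1
and the single BPD-hypermethylated site (CG175) has OR 0.898 < 1. Raw p
values are Benjamini–Hochberg adjusted across all tested sites jointly;
significance is p_adjusted ≤ 0.05. Sites with complete separation (a group
entirely methylated or unmethylated), non-convergence, or fewer than 3
usable subjects in a group are reported untestable, with a flag, and are
excluded from the FDR family. Default inference is plain binomial, matching
the source analysis; real bisulfite data are overdispersed, and the
generator can produce such data (see below), but a variance-inflation option
is deliberately not the default.

**DMR calling.** Candidate DMRs are maximal runs of *consecutive tested*
sites (adjacency is positional among post-filter sites, not base-pair
distance — the published run spans 184 bp with uneven spacing) that are
FDR-significant with a common effect sign and length ≥ 3 (two-site runs are
considered artifact-prone; the published run has 5). Shorter significant
sites are reported as solitary. A run is accepted when the median pairwise
Pearson correlation of member-site rates across subjects is ≥ 0.6; no
published threshold exists, so the full correlation matrix is always
emitted and the gate is configurable (a threshold of 0 disables it). The
accepted DMR's per-subject mean (unweighted over members) is tested between
groups with the same adjusted linear model as the a priori regions. That
test ignores coverage, so it can be less powerful than the per-site screen —
a documented property of the two-stage design, not an inconsistency.

**Associations.** The DMR mean rate (%) is regressed on one predictor at a
time + age + BMI, pooled across groups (per-group subsets available).
Symptom scales (BSL-23, ZAN-BPD, DES, BIS and its motor / attentional /
non-planning subscales) and CTQ measures enter as raw mean scores, so slopes
are percentage points of methylation per scale unit. CTQ subscales are also
modelled categorically via the published exposure cutoffs (strictly greater
than: EA > 2.4, PA > 1.8, SA > 1.4, EN > 2.8, PN > 2.4). Missing phenotype
values are handled by complete-case analysis per model. No multiple-testing
correction is applied across this exploratory family; outputs carry raw p
values and say so.

**Descriptives.** Phenotype scales are compared with Welch's
unequal-variance t (Welch–Satterthwaite df). Recomputing the published
descriptive table from its printed summaries matches the printed statistics
distinctly better under Welch than under the pooled test (DES: Welch 8.819
vs pooled ≈ 8.91 against a printed 8.822), so Welch is the default and
pooled is behind a flag. Symptom scales are one-sided (BPD hypothesized
higher), the matching covariates age and BMI two-sided, following the
published table's footnote.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are not tuning
knobs.

* **Phenotypes.** Per-group zero-truncated normals with the published
  (mean, SD) for age, BMI, BSL-23, ZAN-BPD, BIS, DES and CTQ total. BIS and
  CTQ subscale summaries are not published; their defaults are stated
  assumptions (plausible for a severe clinical cohort vs screened controls).
  Scales are drawn independently given group — the inter-scale correlation
  structure is not reported and is not modelled. Truncation at zero shifts
  the realized mean upward only where the mean is within ~2 SD of zero
  (e.g. HC BSL-23 0.10 ± 0.17 realizes ≈ 0.18); the published clinical-group
  means are ≥ 2.8 SD above zero and unaffected. Per-scale missingness
  (≈ 0.5–4%) mirrors the published per-scale ns of 44–48.
* **Counts.** Coverage is negative binomial per cell (floor 1 read).
  The default per-site mean is 240 reads, dispersion 12: the published
  per-site statistics (t ≈ 3.5 at OR ≈ 1.1 with n = 95) imply an effective
  binomial information of ≈ 240 reads/site, so this default reproduces the
  printed t magnitudes. Fifteen sites default to mean 8 reads to emulate
  poor capture. The latent methylation probability is
  inv-logit(baseline + group effect + age·slope + BMI·slope + shared
  subject effect on DMR sites); methylated reads are beta-binomial with
  concentration 1000 (near-binomial, matching the analysis model; finite
  concentrations produce honest overdispersion, ∞ gives exact binomial).
* **Injected effects.** The eight published differential sites sit at their
  real coordinates with baseline = printed HC rate and group log-odds
  difference = −log(printed OR). All other sites follow a baseline profile
  emulating the promoter methylation gap (flanks ≈ 80–92%, islands ≈ 4–5%,
  slopes between). The five DMR sites share a per-subject random effect
  (SD 0.25 logit units), chosen from r = s²/(s² + p(1−p)/cov) so member-site
  rates correlate at ≈ 0.8 across subjects ("highly correlated"), plus
  slightly larger common age/BMI slopes.
* **Determinism.** All draws come from seeded PCG64 generators; the global
  seed fans out to per-stage substreams (SeedSequence spawn keys), so stages
  rerun identically in isolation. The site map itself is a deterministic
  constant (fixed internal construction seed).

What the generator does **not** emulate: read-level artifacts (sequencing
error, incomplete bisulfite conversion, strand effects), cell-type
heterogeneity of whole blood, spatial autocorrelation outside the DMR block,
and phenotype–methylation confounding beyond age/BMI. Passing tests
therefore demonstrate correctness and calibration of the statistical
machinery under the assumed data-generating model, not robustness to those
real-data features.

## Power at the study's effect sizes

The published DMR effects are small (OR 1.09–1.13 per site) and the
published adjusted p values (0.016–0.04) sit just under the threshold: the
study operates at the detection boundary. Monte-Carlo runs of the full
screen → run detection → correlation gate recover the injected DMR in
roughly half of realizations at the default coverage of 240 reads
(calibrated to the published statistics), and far less often at 100 reads, where the binomial information
bound caps the expected per-site t near 2.3 while the BH threshold across a
174-site screen requires |t| ≈ 3. Single-seed end-to-end runs may therefore
recover all, some, or none of the eight sites; this is the faithful
behaviour of the design at these effect sizes, and the pipeline reports the
realized counts rather than asserting recovery.

## Numerical choices and degenerate inputs

* GLM fits use IRLS to tolerance 1e-10 (max 200 iterations); the
  covariate-free fit on aggregated counts then equals the closed-form 2×2
  log odds ratio to < 1e-8.
* Zero-coverage cells have undefined rates and must be masked; region means
  over zero usable sites are missing (the subject drops from that model).
* Correlations are computed pairwise over subjects with both sites unmasked
  (≥ 3 required); constant-rate sites yield an undefined (NaN) entry which
  never counts toward the median gate.
* BH adjustment preserves input order, enforces step-up monotonicity and
  caps at 1; raising any raw p never lowers any adjusted p.
* Bootstrap p values are fraction-based and therefore granular at 1/reps;
  with the default 10,000 replicates the granularity is 2e-4.
* Registry files must declare `#coords=1-based-inclusive` on their first
  line so half-open BED intervals cannot be ingested silently.

## Problem sizes used by the test suite

The statistical suites run at the study's n (47/48) with reduced replicate
counts chosen to keep Monte-Carlo error well inside the asserted margins:
null calibration over ≥ 2000 simulated null sites and 100 null screens of
100 sites; DMR recovery over 200 replicates of a 189-site screen at mean
coverage 100; bootstrap-vs-parametric agreement over 100 datasets × 2000
replicates. The bootstrap default of 10,000 replicates applies to analysis
runs.

## Known limitations

* The per-CpG model is plain binomial; with strongly overdispersed real
  data its t statistics are anti-conservative. The generator can produce
  such data for sensitivity checks, but a quasi-binomial correction is not
  the default because the reference analysis did not use one.
* The DMR correlation gate (median r ≥ 0.6) and the run-length rule
  (≥ 3) are operationalizations of a verbal description; both are exposed
  as configuration and the correlation matrix is always emitted.
* Complete-case analysis assumes missingness unrelated to methylation given
  covariates; with ≤ 4% missingness per scale the impact is negligible in
  simulation but untested on real data.
* The generator's site map, baseline profile and subscale phenotype
  parameters are fixed assumptions where the source material is silent;
  they are constants of this package, documented above, not fitted
  quantities.
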