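# Methods

This note documents the statistical model behind `pkdpeptidome`, the
choices made where the design was genuinely open, and what the
synthetic-data results do and do not show about real data.

## Data model

A CE-MS run of one urine sample yields a peak list of deconvolved
peptide ions: monoisotopic mass (Da, analyzed window 800–20,000),
migration time (min, normalized 18–45 scale) and signal intensity
(arbitrary units, strictly positive). After calibration and
cross-sample matching the cohort is a samples × peptides matrix of
normalized intensities in which 0 encodes "not detected" — peak files
never carry zero-intensity rows; absence is a property of the matrix.
Peaks are canonically ordered by (mass, time) and matrix columns by
peptide id, so all artifacts are byte-reproducible.

## Calibration

Each sample is normalized against a reference panel of internal-standard
peptides ("housekeeping" peptides present in essentially all urines).
Standards are located in the raw peaks by mass (within the relative
mass tolerance; nearest mass wins, ties to the more intense peak).
The time map is the least-squares line from observed standard times to
reference times; a linear (two-parameter) form is the minimal choice
given that no functional form is prescribed for the drift. The
intensity factor is the median of reference/observed intensity ratios
over matched standards — median, not mean, for robustness to a
mis-matched standard. Samples matching fewer than `min_standards`
(default 3) standards are excluded and logged rather than guessed at.
Normalization is idempotent to 1e-9 by construction.

## Cross-sample matching

Calibrated peaks are pooled, sorted by (mass, time, intensity, sample),
and clustered in one greedy pass: a peak joins the open cluster whose
intensity-weighted centroid lies within the relative mass tolerance
(default ±100 ppm) *and* the absolute time tolerance (default
±0.5 min), nearest-in-time when several qualify; otherwise it opens a
new cluster. Clusters whose centroid falls outside the mass window of
the current peak are closed permanently (input is mass-sorted, so this
is safe). One peak per sample per cluster; the most intense wins —
duplicate in-tolerance peaks from one sample are treated as
deconvolution artifacts. Greedy single-pass clustering is an
approximation to a global assignment, chosen for determinism and
near-linear cost; the deterministic pooled ordering makes the result
invariant to the order samples are supplied in. The default tolerances
are configuration, not dogma: they match the resolution implied by
4-significant-figure masses and sub-minute time reproducibility of
CE-TOF instruments.

## Differential discovery

For each peptide detected in ≥ `min_freq` (default 0.3) of at least one
group and at least twice per group:

* **p-value** — two-sample Welch statistic on the natural-log
  intensities of *detected* samples, referred to the standard normal
  ("Gaussian approximation" of the t reference). ln 0 is undefined, so
  zeros cannot enter the test; this split (test on detected, fold on
  all) is deliberate and config-visible.
* **fold change** — mean case intensity / mean control intensity over
  *all* samples, zeros included, matching the convention of regulation
  factors computed from group mean signal intensities. Fold is
  undefined (flagged) when the control mean is 0.
* **AUC** — midrank Mann–Whitney probability over all samples.

Near-constant columns (e.g. the internal standards) can acquire
~1e-16 variances from floating-point accumulation and hence absurd
z-values; a relative-epsilon guard assigns p = 1 when both the pooled
standard error and the mean difference are at numerical noise level.

Benjamini–Hochberg adjustment is the step-up rule
`adj(i) = min_{j≥i} min(1, (m/j)·p(j))`, implemented directly and
tested against a brute-force enumeration oracle. Markers are the
testable peptides with adjusted p below the FDR threshold (default
0.05).

Because the test is referred to the normal rather than the t
distribution, it is mildly anti-conservative at moderate detected
counts; in the default synthetic design the realized false-discovery
proportion is ≈ 0.07 at a nominal q = 0.05 — within the q·m₀/m ≈ 0.044
ideal plus the normal-approximation inflation, and documented rather
than corrected because the approximation is part of the method being
implemented.

## Diagnostic SVM score

Features are `ln(1+x)` transformed and min–max scaled to [0, 1] with
constants estimated on the training samples only — the log matches the
testing scale, and scaling is added because the RBF width γ is
scale-sensitive. The score of a sample is its signed distance from the
separating hyperplane in kernel feature space,
`score(x) = f(x)/‖w‖` with `‖w‖² = Σᵢⱼ αᵢαⱼyᵢyⱼK(xᵢ,xⱼ)`, so scores are
in margin units and comparable across refits. Class weights are
balanced (inverse prevalence) because the design is strongly unbalanced
(41 vs 189); an unweighted SVM can otherwise drift toward the majority
class.

"Total cross-validation" is leave-one-out (feasible at a few hundred
samples; stratified k-fold is available for speed). The (C, γ) grid
(C doubling over 2⁻⁵…2¹³, γ decades over 10⁻⁷…10) is searched by
cross-validated AUC; ties break toward the smallest C then the largest
γ (mildest model). The published preset C = 640, γ = 3·10⁻⁶ ships as
`PRESET_C` / `PRESET_GAMMA`. One caveat discovered during development
and worth knowing: that γ belongs to *unscaled* intensity space. On
min–max-scaled features it makes the kernel nearly constant, and then
leave-one-out scores reflect only the class balance of the training
fold (the classic LOO pathology where removing a case lowers every
score). The preset is therefore appropriate for panels of hundreds of
strongly informative scaled features (where the tiny kernel curvature
still separates the classes), while small panels should use the
`"scale"` gamma (`1/(p·Var)`).

### Take-one-out panel reduction

The published feature-reduction step is under-specified; it is
implemented as greedy backward elimination: at each step remove the
marker whose removal maximizes the cross-validated AUC; stop when no
removal gains more than 1e-4, or continue to a requested `target_size`
(142 is offered as a preset, not a claim about recoverable panels).
Exact AUC ties break toward removing the marker with the weakest
univariate AUC, i.e. the least "consistently altered" one. An
alternative reduction (frequency of selection across folds) is noted
here but not implemented as default. Backward elimination can only
identify a harmful feature when its harm exceeds the Monte-Carlo noise
of the CV AUC estimate; with small cohorts and redundant panels the
per-removal AUC differences sit below that noise, which is why the
noise-elimination benchmark uses complementary markers (each
informative feature flags a different case subgroup).

### Operating cutoff

The cutoff maximizes the Youden index J = sensitivity + specificity − 1
over midpoints of adjacent sorted *cross-validated* scores (never
resubstitution scores); J ties break toward higher specificity. Calls
are score ≥ cutoff → positive.

## Severity model

Screening: Spearman rank correlation of each peptide's `ln(1+x)` with
htTKV, zeros entering as lowest midrank ties — absence is informative
and all detectable peptides participate. Peptides with |r| above the
threshold (default 0.25) survive. Rank-based screening is invariant to
monotone intensity transforms.

Combination: "linear model" is read as least squares on standardized
`ln(1+x)` of the screened peptides. With p ≈ 99 survivors and
n ≈ 134 patients plain OLS is fragile, so a ridge penalty chosen by
SVD-based generalized cross-validation replaces OLS whenever p ≥ n/2 or
the design's condition number exceeds 1e8; `ridge_lambda=0` forces OLS
and is refused outright when p ≥ n. A signed-sum variant
(Σ sign(r) · z-scored intensity, affinely calibrated to the response)
is available as a sensitivity analysis. Training and held-out
performance are reported as both Pearson and Spearman correlations,
since either convention is defensible for a skewed response like htTKV.

## Evaluation

* AUC: midrank Mann–Whitney (equals trapezoidal ROC area), CI from the
  DeLong placement-variance estimator. Exact binomial machinery is
  reserved for proportions, as stated for sensitivity/specificity.
* Sensitivity/specificity: exact Clopper–Pearson 95% CIs
  (beta-quantile form; 0/n and n/n handled closed-form).
* Cohort pooling: confusion counts are summed across disjoint cohorts
  sharing one cutoff, then proportions recomputed — verified to commute
  with concatenating the underlying score vectors.
* Subgroups: age dichotomized at 30 with the boundary in the upper
  group; unknown genotypes count in "all" but not in genotype columns.
  Specificity is computed once per cutoff on the full control set
  (the same controls serve every genotype column).
* TKV growth: absolute rate is the least-squares slope of TKV on years;
  relative rate is `(exp(slope of ln TKV) − 1)·100` %/yr; htTKV is the
  first TKV over height. Rates need ≥ `min_points` (default 2)
  measurements; htTKV is returned regardless.

## Peptide annotation

Charge at pH 2 = 1 (N-terminal amine) + #R + #K (hydroxylysine `k`
counted like lysine, as the modification notation implies) + #H.
Histidine is counted fully charged (pKa ≈ 6 ≫ 2); aspartate/glutamate
side chains are neutral at pH 2. The migration-time model is a log-log
least-squares reconstruction, `ln t = β₀ + β₁ ln(mass) + β₂ ln(charge)`
fit on ≥ 10 calibrants; a sequence assignment is flagged implausible
when |observed − predicted| > 1 min (the acceptance rule taken as
given). Cleavage-site comparison counts a peptide as overlapping when
parents match and position intervals intersect, and as terminus-sharing
when start (N) or stop (C) positions coincide.

## Synthetic cohort generator

The generator defines the study conditions for every Monte-Carlo
result in this package:

* 5,000 peptides (plus 29 internal standards); masses log-uniform over
  the analyzed window; times uniform on 18–45 min; baseline
  ln-intensity N(ln 500, 1); per-peptide detection frequency
  Beta(2, 1).
* Detection is Bernoulli per sample, independent of intensity — the
  simplest structure that exercises frequency thresholds; real censoring
  is intensity-dependent, so this is a known, deliberate simplification.
* Diagnostic markers: 12% of peptides, drawn among those with detection
  frequency ≥ 0.4 (a marker must be observable to be discoverable);
  fold log-uniform on 1.5–6×; 80% down-regulated, emulating the
  predominance of down-regulated collagen fragments.
* Severity: a latent per-patient factor f ~ N(0,1) drives both
  ln TKV = μ + σ(r·f + √(1−r²)·ε) with r = `severity_r_target` (default
  0.6) and the 99 severity peptides' ln-intensities (loadings 1.2–1.8 ×
  the ln-intensity SD, 70% negative, on peptides with detection
  frequency ≥ 0.8). Consequently r is the *ceiling* of any
  peptide-based predictor's correlation with htTKV, and the loadings
  are sized so the planted peptides clear the |r| > 0.25 screen at
  n = 134 — the generator realizes the stated design in which the
  screen recovers the severity panel. TKV is log-normal with mean
  1078 ml and SD 647 ml; heights uniform 1.5–2.0 m; htTKV = TKV/height.
* Run drift: per-sample time scale 0.95–1.05, time shift ±2 min,
  intensity scale 0.5–2×, plus per-peak 10 ppm mass and 0.05 min time
  jitter. Standards are exempt from jitter (they are identified
  species) but share the drift, which calibration must undo.
* All draws come from a single seeded generator; identical
  (config, seed) reproduces cohorts byte-identically.

What passing synthetic tests shows: the pipeline's statistics are
implemented correctly, calibrated under the generator's assumptions,
and powerful under the planted effect sizes. What it does not show:
performance on real urine, where intensities are not log-normal,
detection is censored by abundance, drift is nonlinear, and marker
effects are far weaker and correlated — the near-perfect synthetic
AUCs are a property of the planted design, not a clinical claim.

## Problem sizes and numerics

Monte-Carlo suites use the study's sample designs (41 vs 189 discovery;
134/158 severity split; 224 + 86 validation) with peptide counts of
5,000 for discovery and 2,000 elsewhere — the diagnostic and severity
conclusions are insensitive to the peptide count once the planted panel
sizes are fixed. Ridge GCV scans 40 log-spaced penalties through one
SVD. The BH, AUC and Clopper–Pearson primitives are tested against
brute-force oracles; kernel-space norms guard against zero with a
1e-300 floor; all tolerances quoted above (1e-9 idempotence, 1e-6
calibration recovery, 1e-12 AUC equality) are asserted in the test
suite.

## Known limitations

* Detection independent of intensity (see above).
* Greedy matching can over-split peptides whose jittered masses straddle
  a tolerance boundary (~1% extra clusters in the worked example).
* The normal-referred Welch test is anti-conservative at small detected
  counts; the realized FDR (~0.07 at q = 0.05) is reported, not hidden.
* No covariate adjustment (age/sex) in discovery, no permutation tests,
  no probability calibration of the SVM score, and no longitudinal
  GFR/TKV prediction — all out of scope.
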