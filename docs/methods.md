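# Methods

## The measurement model

The pipeline treats the animal as the experimental unit throughout: every
quantity is computed per animal from that animal's raw measurements, and
groups are compared on the per-animal values. This ordering matters for the
nonlinear quantities (ratios, TLST): the group mean of per-animal values is
not the value computed from group means, and plug-in checks against
published group summaries are therefore consistency checks, not identities.

**Tubule morphometry.** STD and GEH are arithmetic means over the measured
circular cross sections (30 per animal). A profile is valid only if the
epithelium fits inside the tubule (2·GEH ≤ STD).

**Volume densities.** Point-count fields (10 per animal, 400 points each by
default) are pooled before converting to percentages, so every counted
point has equal weight; percentages sum to 100 exactly. The tubular
compartment is lumen + germinative epithelium + tunica propria; the
intertubular compartment is Leydig + vessels + connective tissue.

**Tubule length.** `TLST = V·f_tub / (π (STD/2)²)`, with parenchyma volume
`V = TW(1 − f_np)/ρ` for the testis pair. Defaults: tissue density
ρ = 1.0 g/mL and non-parenchyma fraction f_np = 0 (no separate albuginea
weighing); both configurable. TLST is computed for the pair and TLST/g
divides by paired testis mass. The estimator is exact on a cylinder
phantom of known length, which the test suite verifies in closed form.

**Thickness correction.** Raw profile counts are multiplied by
`T/(T + D)`. The Sertoli correction uses the *nucleolar* diameter, because
Sertoli cells are counted by nucleolus. The factor is validated against an
independent 3D sphere–slab sectioning simulation (uniform sphere centers
along the sectioning axis; profiles = spheres intersecting the slab;
agreement within 2% for D/T up to 5).

**Production estimates.** A tubule of length L cut into sections of
thickness T yields L/T cross sections, so whole-testis populations are
`corrected count · TLST/T`: NSCT from the Sertoli count, TSR from the
round-spermatid count at stage 1. DSP divides TSR by a time-equivalent of
10.5 days. That divisor is an internal-consistency choice, not a measured
cycle length: the published control TSR/DSP median ratio is 10.515, which
pins the value to within 0.2%; it is configurable
(`StereologyConfig.sec_duration_days`).

**Yields and indices.** Ratios use the convention 0/0 → 0 (matching the
"1:0.00 ± 0.00" reporting for arrested groups) and x/0 with x > 0 →
undefined (NaN, excluded from group summaries with a warning). The chain
identity A:Ar = A:PL · PL:PQ · PQ:Ar and the additivity
S:CG = S:A + S:PL + S:PQ + S:Ar hold per animal whenever defined.
Theoretical expansions: 256 round spermatids per type-A spermatogonium,
4 per pachytene spermatocyte, 1 pachytene per pre-leptotene; the general
yield and meiotic-loss percentages are measured against these, with the
loss clamped at 0 when observed yield exceeds theory.

## Group statistics

Normality is assessed by Shapiro–Wilk on the pooled within-group residuals
rather than per group: with n = 10 per group, per-group tests are badly
underpowered, and the residual-based check is the conventional ANOVA
diagnostic (per-group checking remains available). Parametric branch:
one-way ANOVA + Tukey HSD, summaries mean ± SD. Nonparametric branch:
Kruskal–Wallis + Dunn's pairwise z-tests with tie correction and Holm
adjustment, summaries median ± IQR. Dunn–Holm is implemented in
`groupstats` directly (z on mean ranks; Holm via statsmodels) and is
verified against a hand-computed no-ties fixture.

Compact letters use insert-and-absorb: start with one column holding all
groups, split any column containing a significantly different pair, drop
absorbed (subset) columns, assign letters in group order. The display
satisfies the biconditional exactly — two groups share a letter iff their
pairwise p ≥ α — which a property test checks on random p-matrices.

Degenerate variables (zero within-group variance everywhere, e.g. DSP when
every group is arrested) skip the omnibus test: identical constants share
"a", distinct constants are lettered by exact-tie classes, and the result
carries an explanatory note. Variables undefined for most animals are
reported untested with blank letters.

Both branches hold their nominal size: under the null (3 × n = 10) the
measured type-I error over 2000 replicates is ~0.044–0.049 for ANOVA and
~0.043–0.045 for Kruskal–Wallis, which the acceptance tests bound inside
[0.03, 0.07].

## The synthetic cohort generator

The generator emulates the study's measurement protocol (three groups of
ten; 30 profiles, 10 point fields of 400 points, 10 stage-1 cross sections
per animal; 3 µm sections), with distribution families chosen for
positivity and the overdispersion visible in the published SDs:

* masses lognormal (parameterized by arithmetic mean/SD; per-testis mean =
  TW/2, SD = TW-SD/√2);
* tubule diameter and epithelium height hierarchical normal: animal means
  from the published between-animal mean/SD, profiles around them with
  within-animal SDs of 8% and 10% of the group mean (the profile-level
  scatter is not published; these are typical measurement CVs, and the
  per-animal mean of 30 profiles is dominated by the between-animal SD, so
  calibration is insensitive to the choice). Heights are clipped to the
  tubule radius;
* point fields Dirichlet-multinomial: one composition per animal
  (precision 15, matched to the published dispersion of the germinative
  epithelium fraction), then multinomial tallies per field;
* stage-1 counts hierarchical negative binomial: a gamma intensity per
  animal (CV 0.15) times the group's raw-count mean, Poisson per tubule.
  Raw-count means are the published corrected populations passed through
  the inverse thickness correction, so the pipeline recovers the published
  corrected means exactly in expectation regardless of the nuclear
  diameters assumed (the correction round-trips). Nuclear diameters are
  field-typical ovine values (A 6.8, PL 6.6, PQ 9.0, Ar 5.4 µm; S
  nucleolus 2.4 µm) since none are published.

Body mass is not published; it is back-solved per group from testis weight
and gonadosomatic index (e.g. control: 109.78 g / 0.66% → ≈16.6 kg), with
a 10% CV and the lognormal ratio-bias factor (1 + CV²) applied so the
expected TW/body ratio hits the GSI target exactly. The published volume
proportions do not sum to 100 (some rows are medians); the generator
normalizes them, and its calibration targets are the normalized
percentages. The vaccinated groups' pachytene and round-spermatid means
are set to zero — arrested spermatogenesis — which propagates exactly to
zero DSP/TSR and the "1:0.00" yield pattern.

A single RNG stream seeded from the cohort seed is consumed animal by
animal in group order, so a seed fully determines the dataset (identical
CSV bytes).

**What the generator does not emulate:** left–right testis mass
correlation (testes drawn independently), correlation between body mass
and testis response, measurement error on nuclear diameters, stage
misclassification, spatial field structure within a slide, and any
longitudinal (pre/post vaccination) dynamics. Passing tests show the
estimators and statistics behave correctly under the published group-level
structure; they cannot validate robustness to those unmodelled features of
real slides.

## Published-value inconsistencies

The published LSI (0.0036%), TSI (0.28%) and TLST (3835.7 m control,
~15,000 m vaccinated; 11.06 m/g) are mutually inconsistent with the
published TW, GSI and volume proportions under any single standard
formula: plugging control group means into the standard length estimator
gives ≈3078 m (and ≈28 m/g), and the vaccinated groups' TW/STD values
imply TLST close to control rather than four times it. The package
implements the standard formulas and does not reverse-engineer unstated
constants; these variables are therefore excluded from generator
calibration targets, and plug-in agreement is asserted only where it holds
(NSCT within 5%, TSR/DSP ratio within 1%). The simulated cohorts
nonetheless reproduce the *direction* of the published TLST/g effect
(higher in vaccinated groups).

## Numerical and testing choices

* Rendering rounds half-even at the configured decimals; production
  estimates display in 1e9 (1e6 for per-gram DSP/TSR) units.
* Zero-variance and empty inputs are rejected with named errors at the
  boundaries (`ParameterError`, `RawDataError` with row diagnostics).
* Parameter-recovery testing simulates 200 animals per group and checks
  group means against the generator's own calibration targets within 2
  standard errors for the primary targets (masses, STD, GEH, GSI and the
  five corrected populations). The 18 compositional volume-density targets
  are checked jointly (max |z| ≤ 3.5, at most 3 beyond 2 SE): the minority
  compartments (~1–3% fractions) have strongly right-skewed per-animal
  distributions, so individual 2-SE t-intervals undercover and a perfectly
  calibrated generator would fail ~2 of 45 independent 2-SE checks by
  construction; the family-level bound holds the intended confidence
  without loosening the calibration itself.
* Statistical calibration uses 2000 null replicates per branch and 400
  simulated cohorts per variable for the letter-pattern power checks;
  these sizes keep the full suite within a few minutes while leaving the
  Monte-Carlo error well below the decision margins.
* The letter-pattern power check targets TW, STD and GEH at the published
  means/SDs; the true a/b/b recovery rate for STD is ≈95.3% (the ~5%
  misses split the two vaccine doses a/b/c, driven by their small true
  diameter difference), so results at the 95% threshold are seed-dependent
  in small replicate counts — the acceptance test uses a fixed seed and
  400 replicates.

## Limitations

* Calibration targets are published group summaries, not raw data; the
  generator reproduces first and second moments per group, not the joint
  per-animal distribution of the real cohort.
* The 10.5-day DSP divisor is a consistency-derived constant, not a
  measured seminiferous-cycle length for these lambs.
* No shrinkage correction for histological processing is applied (none was
  reported), and stage-1 identification is assumed done upstream.
* The Kruskal–Wallis post-hoc used in the original analysis is unstated;
  Dunn + Holm is the package's choice (pairwise Mann–Whitney + Bonferroni
  is available via `nonparametric_compare(..., posthoc="mannwhitney")`),
  so printed p-values are not expected to match exactly.
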