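# Methods

`honeynmr` implements a targeted quantitative ¹H-NMR workflow for honey and
the chemometric models used to discriminate a binary geographic class
(e.g. domestic vs imported honey) from the resulting concentration table.
This note documents the models, their assumptions, the tunable parameters,
and the design choices made where the design was genuinely open.

## 1. Quantitation model

A processed absorption spectrum is referenced so the TMSP methyl singlet
sits at 0.0 ppm (axis shift only; intensities untouched; referencing is
idempotent to within one grid step). Peak "areas" are plain sums of the
intensity values at the grid points inside each analyte's integration
region, inclusive at both endpoints — no baseline fit and no deconvolution.
Endpoint inclusivity matters at low resolution, so it is fixed and
documented here.

With TMSP (9 protons) as the internal standard at a verified concentration
`C_TMSP` (default 0.966 mM; the nominal 1.00 mM is available by
configuration), the molar concentration of analyte *a* is

    C_a (mM) = (A_a / N_eff,a) / (A_TMSP / 9) · C_TMSP · s_a

- `A_a` — the region area, or the sum over regions when the analyte's
  `combine_rule` is `sum_regions`;
- `N_eff,a` — effective protons per molecule represented by the region(s);
- `s_a` — back-calculation scaling factor: the inverse α-anomer fraction
  when only the H-1α resonance of a reducing sugar is integrated
  (5.15–5.55 ppm window), 1.0 when the region covers all forms.

Mass units follow the 50 mg / 1 mL sample preparation:
`mg/kg = C_a · MW_a · V_mL / (mass_mg · 10⁻³)` (= `C_a · MW_a · 20` at the
defaults) and `g/100 g = mg/kg / 10⁴`. Fructose and glucose report in
g/100 g, everything else in mg/kg.

**Fructose.** Free fructose equilibrates between β-pyranose (68.2%),
β-furanose (22.3%), α-furanose (6.3%) and α-pyranose + keto (3.2%). Its
concentration is the sum over three regions (4.098–4.130, 4.013–4.050,
3.985–4.013 ppm) whose proton equivalents are derived from those fractions
(2·0.223 + 0.063 = 0.509; 2·0.682 = 1.364; 0.682 + 0.063 = 0.745; total
2.618). A nominal convention of exactly 2.0 proton equivalents is available
via `fructose_proton_mode="nominal2"`; the simulator and the quantifier
always use the same convention, so round trips hold under either. The
tautomer arithmetic (2.618) is the default because it follows directly from
the stated equilibrium fractions.

**Glucose.** Quantified on the overlapping H-4α/H-4β window at 3.41 ppm:
each glucose molecule contributes exactly one H-4 proton there regardless
of anomer, so `N_eff = 1` and `s = 1`. Contributions of minor sugars to the
fructose/glucose windows are treated as negligible (concentration orders of
magnitude apart).

**LOQ.** The base limit is the molar concentration of a one-proton singlet
at S/N 10:1 (0.01 mM for a 700 MHz cryoprobe configuration), adjusted per
analyte: `LOQ = 0.01 mM · (penalty / n_protons) · MW · 20`. The proline
default is stored directly as 230 mg/kg. LOQ flags annotate values — they
never censor; flagged values stay in the matrix.

**Panel provenance.** The integration windows fixed by the method (fructose
triplet, glucose 3.41 ppm, the minor-sugar anomeric windows inside
5.15–5.55 ppm, TMSP 0.0 ppm) are encoded verbatim. Every other window,
anomeric ratio (default 1/0.40 = 2.5 for the reducing minor sugars),
multiplicity penalty and derived LOQ is a **synthetic placeholder**: the
authoritative laboratory values were never published. Placeholders were
chosen to be chemically plausible and mutually disjoint, and all are
user-overridable through a YAML or CSV panel file.

## 2. Synthetic data

**Spectra.** The simulator places one Lorentzian singlet (FWHM 1.0 Hz at
700.15 MHz, ≈ 1.4·10⁻³ ppm) centered in each region of every analyte with a
nonzero concentration, plus the 9-proton TMSP singlet. Amplitudes are
obtained by solving a small linear system so that the *measured*
(sum-over-region) area of every region — including the Cauchy tails all
other peaks leak into it — equals `C · N_eff / s` in one common
proportionality unit. This makes the simulator the exact forward model of
the integration rule: quantifying a noiseless simulated spectrum recovers
every input concentration to well under 0.5% (residual error is grid
discretisation, ~10⁻⁴ relative at the default 2¹⁵-point grid over
−0.5…9.5 ppm). Gaussian noise (sd expressed as a fraction of the TMSP apex)
and a baseline polynomial are added last. One singlet per region, rather
than literature multiplets, is deliberate: sum-integration only sees areas,
so multiplet realism adds nothing to what these tests can show.

**Cohorts.** `simulate_cohort` draws a 424 × 33 concentration matrix with
105 positive-class ("Canadian") and 319 negative-class samples, lognormal
by default (honey analytes are positive and right-skewed; a truncated
normal is available for sensitivity checks), optionally with a Gaussian
copula-style correlation on the log scale. The class structure mirrors the
reported marker pattern: trigonelline mean 35 vs 8 mg/kg (most positive
samples above 20 mg/kg), proline elevated (600 vs 280 mg/kg), and ethanol,
succinate, MGDH, MGMH, leptosperin, HPLA, 1,3-butanediol, lactate, alanine
and phenylalanine below half the negative-class mean; trehalose and
isoleucine are near-null. CVs are 0.35–0.4 for the three strong markers and
0.5–0.6 elsewhere — large, reflecting the biological diversity of survey
honey. All means and CVs are repo constants labelled synthetic: they
reproduce the qualitative marker structure, not the unpublished survey
values. What passing tests show is therefore that the *pipeline* behaves
correctly on data with this structure — not that real honey is classified
with these exact error rates. Real data additionally carry inter-analyte
correlations, floral subpopulations, and quantitation noise that the
default cohort does not emulate.

## 3. Chemometrics

All multivariate models operate on the SD-scaled concentration matrix
(each column divided by its sample SD, ddof = 1; constant columns are
rejected by name). PCA defaults to *uncentered* scaled data — on
all-positive concentration data the first component then absorbs the common
"overall composition" direction, which is why it explains > 90% of the sum
of squares while carrying no class information. PLS centers X and y
(standard autoscaling); both choices are exposed and recorded.

**PLS-DA** is PLS1 regression of a 0/1 class vector, by the deterministic
NIPALS sequence (first weight vector ∝ Xᵀy, no random initialisation).
Classification thresholds the continuous prediction at 0.4; a tie at the
threshold is called positive (deterministic and immaterial for continuous
predictions). Complexity is selected by contiguous-block cross-validation:
samples are split in stored row order into seven near-equal contiguous
blocks (sizes differing by at most one, larger blocks first; 300 samples →
43·6 + 42), RMSECV pools the held-out predictions, Q² = 1 − PRESS/TSS about
the overall class-vector mean, and the chosen count is the first minimum of
RMSECV (parsimony on ties). Folds whose training part is single-class are
skipped with a warning. A shuffle-then-block mode exists but is off by
default, because contiguous blocks are the defined procedure. The ROC
module reports, besides the per-threshold sensitivity/specificity, the
threshold maximising min(sens, spec) — the "high and comparable" operating
point.

**SIMCA** fits a PCA on the class members only, after class-local
autoscaling (each class modelled separately; a global-scaler mode exists).
Each sample is scored by leverage (Hotelling T² over the retained score
variances) and Q residual (squared reconstruction error). Critical values:
T² from the F-distribution for a new observation on (k, n−k) degrees of
freedom; Q from the Jackson–Mudholkar approximation on the discarded
eigenvalues (Box g·χ² fallback when the JM exponent degenerates).
The acceptance region is rectangular — both statistics below their limits,
matching the leverage/residual plot axes — with the per-statistic level
Šidák-split (`1 − √(1−α)` each) so the joint in-class acceptance is ≈ 1 − α;
two literal α-level limits would only cover ≈ 90% jointly at α = 0.05.
Monte-Carlo checks confirm 95% ± 2% coverage on Gaussian in-class draws.
A combined normalised-distance boundary is available by configuration.
Component count is selected by contiguous-block cross-validated PRESS,
computed element-wise (each held-out sample's each variable imputed from
the remaining variables through the fold's loadings): naive re-projection
PRESS is monotone in the component count and cannot select, whereas the
element-wise form has a genuine minimum at the supported dimensionality.
When an out-of-class set is supplied, the alternative criterion maximising
the geometric mean of CV sensitivity and specificity is reported alongside.
Note the Gaussian-theory limits under-cover on strongly right-skewed
(lognormal) classes, particularly at small class sizes — in-class
acceptance around 85% rather than 95% is expected there and is visible in
the synthetic-cohort results.

**Replacement Method (RM).** A deterministic local search for the
d-variable subset minimising RMSECV: from a random d-subset, repeatedly try
replacing one slot's variable with every non-member and keep the swap that
most reduces RMSECV, sweeping the slots until the subset is stable. Each of
the d slots defines a path (where replacement starts); the search runs all
d paths from each of `n_starts` random starts (default 10) and keeps the
best subset found. Ties keep the incumbent; among improving challengers the
lowest column index wins — both rules chosen for determinism. The RMSECV of
a candidate subset re-selects its own LV count (capped at min(d, max_lv)):
a 3-variable model cannot support 5 latent variables. Subset scores are
cached, so on small p the search effectively enumerates. An exhaustive
enumerator (budget-guarded) provides the global-optimum oracle; on planted
3-of-12 signals RM matches it in ≥ 90% of seeded instances.

**Volcano statistics.** Per analyte: fold change = positive-class mean /
negative-class mean, p-value from Welch's unequal-variance t-test (pooled
Student available by flag), significance at raw p < 0.05 (no multiplicity
correction by default; Benjamini–Hochberg q-values by flag). Under a null
simulation the p-values are uniform and ~5% fall below 0.05.

**Repeated splits.** `repeat_split_frequency` runs k (default 10)
unstratified random 300/remainder train/validation splits, fits PLS-DA at a
fixed LV count, and tallies each sample's false-positive/false-negative
counts — separately for runs where the sample was in training vs
validation, since the two are not comparable.

## 4. Numerical choices and degenerate inputs

- Referencing ties (flat window) resolve to the point nearest the reference
  shift, with a warning.
- NIPALS stops early when the residual covariance vanishes; regression
  vectors beyond the achieved rank repeat the last one, so RMSEC is
  non-increasing by construction.
- `frequency_distribution` uses relative-width bins (default 1% of the
  observed range → 100 bins spanning [min, max]); all-equal input collapses
  to a single bin with a warning; bins entirely at or below the LOQ are
  flagged.
- Histogram, report and model exports use fixed float formats so
  regeneration from identical inputs is byte-identical.
- Problem sizes in the validation suites (e.g. 50 planted RM instances at
  n = 100, p = 12; 5,000-draw coverage checks; ten 300-sample splits of the
  424-sample cohort) are chosen to give stable Monte-Carlo estimates on a
  single CPU in a few minutes.

## 5. Known limitations

- The shipped panel's non-anchored regions, anomeric ratios and LOQ
  penalties are placeholders; results on real spectra require a laboratory
  panel file.
- No deconvolution: overlapping resonances bias sum-integration on real
  spectra (the simulator's disjoint-region layout sidesteps this by
  construction).
- SIMCA critical limits assume approximate multivariate normality of the
  scaled class; strongly skewed classes are accepted at less than the
  nominal rate.
- Marker recovery by RM is a property of the data, not only of the
  algorithm: on cohort draws where a weak marker happens to rival proline,
  RM correctly selects the better-predicting subset.
- Multiclass PLS-DA, kernel/sparse PLS, multi-class SIMCA distance
  measures, and permutation validation are out of scope.
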