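# Methods

## Scope and data model

`cardiomir` implements a four-stage clinical analysis chain for
myocardial-infarction cohorts — microarray preprocessing, differential
miRNA screening, echocardiographic energetics, and Kaplan–Meier survival
comparison — together with a simulator that generates every input the
chain consumes. The in-memory containers are deliberately plain: intensity
matrices are pandas DataFrames (miRNA rows × sample columns), record
tables are DataFrames or lists of frozen dataclasses
(`EchoRecord`, `SurvivalRecord`), and all files are UTF-8 TSV/CSV/JSON.

## The simulator

The simulator defines the study conditions; its defaults are the
conditions under which all recovery results are reported.

**Expression.** Four groups (NHF, AMHF, AMNHF, OMHF) of 10 patients. Each
planted miRNA has control-group mean 1000 fluorescence units and
case-group mean 1000 × FC, with the planted FC table defaulting to the
published top-5 up/down screens of the three case-vs-NHF comparisons
(`PLANTED_EFFECTS`). 200 background (non-differential) miRNAs get row
baselines spread log-uniformly over ±0.7 decades around 1000, and 10% of
all rows are drawn with baselines between 0.4× and 0.9× the 50-unit
detection floor so the filter stage has real work. Measurement noise is
multiplicative log-normal per cell with CV 0.15, mean-corrected
(σ² = ln(1 + CV²), μ = −σ²/2) so the expected intensity equals the target
mean and the ratio-of-means fold-change estimator is unbiased to first
order. The CV was fixed at 0.15 because at n = 10 per group it places the
planted sub-unity fold changes (0.765, 0.643, …) firmly in the p < .05
regime, matching the p-values the published screens report; no
distributional information about the original arrays exists. The emitted
matrix represents the already replicate-averaged array; per-read stacks
for exercising the averaging step carry CV·√R per read so their mean
matches. At `noise_cv=0` the planted fold changes are reproduced to
machine precision — the zero-noise cohort is the fixture for all
exactness tests.

**Echo records.** Per-group truncated-normal draws. Contractility is
parameterized by ejection fraction and fractional shortening, and volumes
and diameters are derived from them (LVESV = LVEDV·(1 − EF),
LVIDs = LVIDd·(1 − FS)), so the invariants LVESV < LVEDV and
LVIDs < LVIDd hold by construction rather than by rejection. Heart-failure
groups get dilated ventricles (LVEDV ≈ 170 vs 110 mL), depressed EF
(≈ 0.33 vs 0.65), lower SBP, shorter ejection time and faster heart
rate — textbook systolic-failure physiology. Heights and weights target
the cohort demographics (1.62/1.64/1.65/1.65 m and
55.3/55.9/52.8/57.5 kg for NHF/AMHF/AMNHF/OMHF); heights are stored in cm
because the BSA formula's coefficients are in the cm/kg convention.

**Survival.** 30 patients, half assigned to a high-expression group whose
exponential hazard is `hazard_ratio` (default 3) times the baseline
(default 0.05 per abstract time unit). Expression levels cluster at 1
(low) and 3 (high) so a median split recovers the planted groups.
Censoring is independent uniform on (0, τ); τ is solved by bisection from
E[P(C < T)] = censor_rate pooled over the two hazards, which makes the
faster-failing high group retain more observed events — the property the
downstream direction tests rely on. The exponential/uniform choice is the
package's own: no distributional statement exists for the original
cohort.

**Viability.** OD-490 trajectories interpolate linearly from a day-1
value of 2.4 down to the assay endpoint (1.75 or 1.76 on day 5) across 4
replicate wells with Gaussian well noise (default SD 0.03). The start
value is a plausible plate-reader level for healthy cardiomyocytes; only
the day-5 endpoints are anchored externally.

**Seeding.** Every generator consumes a `numpy.random.SeedSequence`; the
pipeline expands one global seed into four per-stage sub-seeds
(expression/echo/survival/OD) so adding or dropping a stage never
perturbs another stage's draws, and equal seeds give byte-identical
outputs.

## Preprocessing

Stage order is average → filter → normalize. The floor is inclusive
(min across samples ≥ 50 retains the row) and is applied to the averaged
matrix. "Median normalization" is per-column multiplicative scaling to a
common target, defaulting to the global median of the pre-normalization
column medians; it preserves non-negativity and within-column ranks, and
a zero-median column is an error rather than a silent division. No
background subtraction, quantile or loess variant is offered.

## The screen

Test selection follows the decision rule: per-group Shapiro–Wilk at
α = .05 and Levene at α = .05; two groups → Student's t (both pass) or
Welch's t; more groups → one-way ANOVA or Welch's ANOVA. Welch's ANOVA is
implemented in-house (the n/s²-weighted F* with Welch–Satterthwaite
denominator df) and is cross-checked against `pingouin.welch_anova` in the
test suite. The "modified t-test" of the decision rule is taken to be
Welch's unequal-variance t — the standard correction when homogeneity
fails.

Significance is the strict compound rule: FC strictly above 1.5 or
strictly below 1/1.5, and p strictly below .05; FC = 1.5 at p = .01 and
FC = 2.0 at p = .05 are both non-hits. p-values are raw (the screens this
reproduces report raw p); Benjamini–Hochberg is available via
`ScreenParams(adjust_bh=True)`. p-value underflow is capped at 1e-300
before the volcano log. Degenerate zero-variance groups (possible only in
noise-free simulations) map NaN test output to p = 1 for equal means and
p = 0 for distinct means, i.e. the infinite-precision limit.

**Top tables.** Candidates for the top-5 up/down tables are gated on
direction and p < α only — *not* on the full compound rule — because the
published down-regulated hits (FC 0.412–0.865) lie mostly inside the
1.5× band and a compound-rule gate would discard the very rows the tables
print, including miR-320 itself. `require_fc_threshold=True` restores the
strict gate. Both lists select by fold-change extremity and are presented
fold-change descending with ties broken by ascending p then id, which
reproduces the published table order (down lists headed by miR-320, then
miR-204). Fold change is linear throughout, as the sub-unity published
values imply.

## Energetics

The six indices are pure functions of one record; the suite checks them
against an independently coded sympy oracle on 1000 random valid records
at 1e-9 relative tolerance.

Two printed-formula peculiarities are implemented as printed, with
conventional alternatives behind flags:

* The mass formula uses 0.8 × **1.4** where the Devereux convention is
  0.8 × 1.04; the printed constant is the default
  (`wall_constant=1.04` selects the conventional one).
* The label "LVFS" is attached to LVM/BSA — conventionally the LV mass
  index, not fractional shortening. It is exposed as `lvfs_printed`;
  the ordinary (LVIDd − LVIDs)/LVIDd × 100 is `fractional_shortening`.

The cESS expression is typographically garbled in its source; it is
reconstructed here as the standard midwall (Gaasch-type) circumferential
end-systolic wall-stress form SBP·a²·(1 + b²/c²)/(b² − a²) with
a = LVIDs/2, b = a + PWTs, c = a + PWTs/2 — the unique standard formula
consistent with every fragment of the printed string. The reconstruction
is a documented judgement, not a claim about the original authors' exact
intent. Units: dimensions cm, SBP mmHg, LVET s, LVSV mL, HR min⁻¹; the
4.3×10⁻⁷ MEE constant is applied verbatim and MEE is reported in raw
formula units, as no unit system that makes the constant dimensionally
meaningful is stated anywhere.

Batch processing validates each record, collects per-record failures with
their positions, and still returns results for the valid remainder.

## Survival

Median split with ties (and the median itself) assigned to the low group.
The product-limit estimator processes events before censorings at tied
times (the standard convention); with no censoring it equals the
empirical survival function exactly, and on censored data it matches both
a brute-force risk-set recursion and `lifelines` in the tests. The
comparison test is the classic two-sample log-rank chi-square on 1 df
(hypergeometric variance at each event time); no test is named by the
analysis this reproduces, and log-rank is the field default. Median
overall survival is the smallest time with S(t) ≤ 0.5, undefined (None)
when the curve never crosses it. No Cox regression, covariates or
competing risks.

## Problem sizes and what the tests show

Recovery results are reported over 20 simulated cohorts of 225 miRNAs ×
40 samples — small enough that the whole suite runs in about a minute on
one CPU, large enough that the mean fold-change estimate for every
planted miRNA lands within 5% of truth (Monte-Carlo SE of the mean ratio
at CV 0.15, n = 10, 20 seeds is ≈ 1%). The log-rank type-I error is
checked over 500 null cohorts of n = 30 against a ±2% band around 5%.

Passing tests demonstrate internal correctness and parameter recovery
under the simulator's assumptions: log-normal cell noise, exchangeable
samples, no batch or array-spatial effects, no probe cross-hybridization,
exponential hazards. They do not validate the clinical findings on real
patients — the original cohort data are not deposited, so the clinical
figures (apoptosis rates, before/after-treatment indices, the real
survival curves, demographics) are covered only as qualitative
direction-of-effect properties on synthetic ground truth.

## Known limitations

* The simulator plants each differential effect in one case group at a
  time; correlated effects across groups (e.g. a miRNA down in all three
  case groups with correlated noise) are representable via `de_table` but
  not defaulted.
* `select_test`'s normality gate is noisy at n = 10; the reported
  `test_used` is a property of the sample, not the population.
* The uniform-censoring horizon is calibrated in expectation, not per
  realization; small cohorts can deviate noticeably from the nominal
  censor rate.
* Echo profiles are group-mean realistic but not covariance-realistic:
  parameters are drawn independently within a patient apart from the
  derived volume/diameter identities.
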