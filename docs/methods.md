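# Methods

## Problem setting

A small-cohort untargeted lipidomics screen: `N` lipid ions identified
and quantified across a handful of tissue samples in two or more groups.
The pipeline answers three questions per ordered group pair: which
lipids differ (volcano screen), whether the collection of small
p-values exceeds chance (overabundance analysis), and how the
significant calls distribute over lipid classes (trend summary).

## Differential screen

For each lipid and comparison `(group1, group2)`:

- **t test.** Two-sided two-sample t test on the raw intensities.
  Default is the classical pooled-variance Student test with
  `df = n1 + n2 - 2`; Welch (Satterthwaite df) is available via
  `variant="welch"` for users worried about unequal variances. The
  statistic is computed from the explicit formulas; only the t
  distribution's survival function comes from scipy. Tests default to
  the raw intensity scale; `log_scale=True` switches the t test to
  log10 intensities as a sensitivity analysis (fold changes are always
  raw-scale).
- **Fold change.** `FC = mean(group1) / mean(group2)` on raw
  intensities (arithmetic means). Requires a positive denominator mean.
- **Volcano call.** `up` iff `p < 0.05` and `log2(FC) > 1`; `down` iff
  `p < 0.05` and `log2(FC) < -1`; otherwise `not_significant`. Both
  thresholds are configurable; inequalities are strict. The symmetric
  band `-1..1` in log2 fold change is an exclusion band: lipids inside
  it are never called, however small their p-value.

Degenerate inputs are handled totally: identical constant groups give
`t = 0, p = 1`; constant groups with different means are un-testable
and raise; groups with fewer than two observed values raise, naming the
group and lipid. Missing values (NaN) are excluded from both the test
and the fold change when imputation is off.

## Overabundance analysis and FDR

Under a global null with independent tests, p-values are uniform on
(0,1), so of `N` compounds about `N*alpha` fall below any threshold
`alpha`. The analysis compares the observed count `k(alpha)` (strict
inequality `p < alpha`) with this expectation over a threshold grid
(default `{0.0005, 0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.5, 1.0}`), and
draws `B = 2000` same-size null experiments (N independent uniforms) to
form an empirical envelope (default central 99%). The FDR estimate at a
threshold is expected-over-observed discoveries,

    FDR(alpha) = min(1, N * alpha / k(alpha)),

reported rounded half-up to two decimals for display (e.g. 0.4667 →
0.47, 0.042 → 0.04) while CSV output keeps six significant digits.
`k = 0` yields a flagged "no discoveries" value (NaN / `NA`) rather
than a number. The null model deliberately ignores inter-lipid
correlation; with correlated features the envelope is anti-conservative.
Benjamini–Hochberg q-values are provided as a clearly separate optional
extra (`benjamini_hochberg`), not as part of the primary path. The
curve is represented as counts versus alpha, which is the most directly
testable representation of the observed/expected comparison.

## Lipid nomenclature

Grammar: `CLASS(chain{/chain}*)[(rep)]` with `chain = [d]INT:INT[e|p]`.
The `e` → ether and `p` → plasmalogen (vinyl-ether) mapping is a
documented convention of this package; vendor exports do not define the
suffixes. `(rep)` marks a second measured ion of the same base lipid
and is kept as a distinct row throughout (duplicate names without
`(rep)` are a validation error). Class codes map case-sensitively to
categories (DG; TG; Cer; CerG2; PC/PE/PI/PS; LPC/LPE/LPI/LPS); unknown
codes parse fine and classify as `other`, keeping the pipeline usable
on richer exports. Formatting a parsed name reproduces the input
byte-for-byte.

## Synthetic data generator

The generator emulates the structure of a 13-sample skin-cancer study:
groups cSCC:4, BCC:6, Healthy:3 (the healthy samples drawn from two
donors, so 12 patients give 13 samples), 309 lipid ions of which 168
carry grade A/B, with a fixed class composition among the reliable ions
(65 TG, 25 PC, 20 DG, 12 Cer, 12 LPC, 10 PI, 8 PS, 6 LPE, 5 CerG2,
5 LPI).

Intensity model, per lipid `i` and sample `j` in group `g`:

    log10 I_ij = b_i + e(class_i, g) * log10(2) + eps_ij,
    b_i  ~ Normal(baseline_log_mean, baseline_log_sd)
    eps_ij ~ Normal(0, noise_sd)

i.e. log-normal intensities with a multiplicative planted group effect
`e` expressed in log2 units relative to the reference (Healthy) group.
Defaults: `baseline_log_mean = 6.0`, `baseline_log_sd = 1.0` (typical
instrument-unit magnitudes around 10^6 spanning a few decades),
`noise_sd = 0.1` (≈ 26 % coefficient of variation, a realistic
within-group spread for tissue lipidomics), `missing_rate = 0.02`,
`replicate_rate = 0.03`. Planted trends: DG −2 log2 in both tumor
groups, PC/PI/PS +1.5 log2 in BCC, LPC/LPE/LPI +1.5 log2 in cSCC, TG
and everything else null. Grades are assigned independently of effect
size; `(rep)` twins share their base lipid's baseline and effects but
get independent noise. Missingness is re-drawn per row until every
group keeps at least two observed values, so every lipid remains
testable in every comparison without imputation.

What the generator does *not* emulate: patient-level random effects
(patient ids are carried but unused, matching the analysis), intensity
dependence of missingness, instrument drift, adduct ambiguity,
isotopes, and inter-lipid correlation. Passing calibration/recovery
tests on this generator therefore demonstrates correctness of the
statistical machinery under clean log-normal assumptions, not
performance on real acquisitions.

## Calibration and recovery checks

With all planted effects removed, the type-I error of the default
raw-scale Student test at alpha = 0.05, aggregated over 200 generator
seeds x 168 lipids x 3 comparisons, stays within [0.03, 0.07] despite
groups as small as 3 — at `noise_sd = 0.1` the log-normal skew is mild
enough that the raw-scale test remains near-nominal (the log-scale
option makes the data exactly normal). The same runs keep the observed
overabundance curve inside the 99 % null envelope at ≥ 95 % of grid
points. With the default planted trends, ≥ 90 % of planted lipids are
volcano-called in the correct direction (typically ≈ 96–98 %) with
specificity ≈ 1.

## Numerical and design choices

- Statistics run on intensities as exported: no normalization across
  samples, no logging by default, no moderated/shrinkage variance, no
  covariate or paired adjustments — matching the plain two-group screen
  this pipeline implements.
- Default imputation for the `impute_missing` helper is half the
  per-lipid minimum (the usual below-detection-limit convention); the
  pipeline default is `none` because the t test and fold change handle
  missing values by using observed values only, and because vendor
  exports often arrive already imputed.
- Output determinism: result rows sort by ascending p then lipid name;
  CSV floats are fixed at 6 significant digits; the Monte-Carlo null
  band is seeded from the run config. Two runs with the same config and
  inputs are byte-identical, and a JSON manifest records config plus
  SHA-256 input checksums.
- Problem sizes used in the shipped checks (309 ions, 168 reliable, 13
  samples, 200 calibration seeds, B = 2000 null replicates) are the
  defaults of the generator and analysis; they run in well under a
  minute on a single core.

## Limitations

- The FDR estimator `N*alpha/k` is a population-level expected/observed
  ratio, not a per-feature q-value; it is upward-biased when many
  features are truly differential (alternative p-values also land below
  alpha) — visible in the worked example where strong planted signal
  still yields FDR ≈ 0.34 at alpha 0.05.
- The uniform, independent null ignores correlation between lipids of
  the same class; real envelopes are wider.
- Arithmetic-mean fold changes on raw intensities are dominated by
  high-intensity samples in tiny groups; the log-scale t-test option
  mitigates only the test, not the fold-change summary.
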