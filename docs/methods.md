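# Methods

This note documents the statistical model behind `coagplane`, the
synthetic study conditions it is exercised on, and the numerical and
design choices a maintainer would want to know about.

## The derivation pipeline

**Gating.** All estimation happens on records with fibrinogen strictly
below 170 mg/dL, the previously established failure point of the
coagulation system in massive delivery hemorrhage (237 mg/dL marks the
onset of coagulopathy and is used only for display windows). The
inequality is strict, matching the clinical rule's phrasing.

**Screening.** Factors are compared between the hematuria (organ
dysfunction) and non-hematuria groups with a two-sided pooled-variance
Student t-test and a two-sided Mann–Whitney test. The pooled (not
Welch) form is used because only it reproduces the reference p-values
from the printed group summaries; recomputing the fibrinogen row
(59.67 ± 20.6, n=3 vs 122.82 ± 34.2, n=20) gives p = 0.0057 under the
pooled form and ~10⁻¹⁴ under Welch. The Mann–Whitney test uses the
exact null when n₁·n₂ ≤ 400 and the data are tie-free, and the
tie-corrected normal approximation otherwise. No multiple-testing
correction is applied (none was in the reference analysis).

**Contribution rate and partition.** The contribution rate is the
squared Pearson correlation r² — the coefficient of determination of
the simple linear regression — making the thresholds 0.49 and 0.64
equivalent to |r| > 0.7 and |r| < 0.8. Relatedness to an anchor
requires cr > 0.49; membership does not additionally require screening
significance (exposed as an option, off by default, since the two
criteria select the same factors on faithful cohorts). Pruning is
greedy: while any within-set pair has cr ≥ 0.64, the worst-offending
pair is found and its lower-priority member dropped. Priority is the
ascending univariate t-test p-value with alphabetical tie-break;
p-values are rounded to 10 significant digits first so that exactly
collinear factors (identical tests up to float noise) genuinely tie.
This rule reproduces the reference survivors (PT-sec over PT-INR,
D-dimer over PIC) and the five-factor vector
(fbg, fdp, hgb_fbg, pt_sec, dd) of the published discriminant.

**Projection.** Auxiliaries are regressed on their anchors by OLS with
intercept (P members on fibrinogen, Q on FDP, R on both). Standard
errors are heteroskedasticity-robust (HC3): the cohorts this package
analyses — real or synthetic — have auxiliary residual spread that
scales with the analyte's level, and classical standard errors
demonstrably under-cover the slope of the D-dimer regression in the
package's own parameter-recovery simulations (0.79 observed 2-SE
coverage versus 0.94 with HC3). Substitution of the fitted predictions
into a trained classifier gives the plane probability p(α, β);
regressions are evaluated over the full plotting window, i.e.
extrapolated below the fitted fibrinogen range (the display grid
reaches fibrinogen = 0).

**Classifiers.** The reference platform's automatic hyperparameters are
not reproducible, so the package fixes documented defaults: logistic
regression — unpenalised maximum likelihood; SVM — linear kernel,
C = 1, Platt-scaled probabilities; nearest neighbors — k = 3 with
inverse-distance probabilities; random forest — 100 trees, seeded;
naive Bayes — Gaussian per class; neural network — one hidden layer of
8 logistic units, L-BFGS, seeded. Logistic regression and the SVM use
class weights inverse to class frequency: with 3 positives against 20
negatives an unweighted fit can collapse to the majority class, which
would contradict the non-empty hematuria regions the method is meant to
produce. Features are z-scored for the SVM, nearest neighbors and the
network; trees and naive Bayes see the raw scale.

**Boundary extraction.** The probability field is sampled on a uniform
grid (fibrinogen 0–170 step 1, FDP 0–150 step 1 by default; fibrinogen
on the first axis ascending, FDP on the second ascending) and the 0.5
level set extracted with marching squares (linear interpolation on
cell edges). The crude region is the tightest axis-aligned half-plane
description of the super-level set ("FDP > x", "fibrinogen < y"),
omitting bounds that coincide with the window edge. A total
least-squares line through all boundary vertices provides the linear
form a·fbg + b·fdp + c = 0, oriented so the positive side is the
hematuria side and normalised to b = 1 when possible; its RMS vertex
residual indicates how linear the boundary actually is.

**Discriminant.** Two-class Fisher discriminant with pooled covariance
and the midpoint threshold. The sign convention follows the published
function: the score is positive on the non-hematuria side, so
hematuria is called when the score is negative (equivalently, the
higher-FDP side has the more negative score). Separation is reported
as η², the between-group share of the score's total sum of squares
(identical to the squared correlation between score and label for two
groups), and as a normal-theory error probability Φ(−Δ/2) with Δ the
pooled-covariance Mahalanobis distance between the class means — the
natural reading of a single "error probability" for a two-Gaussian
model with equal priors. A singular pooled covariance is
ridge-stabilised with ε = 10⁻⁸·tr(S)/d and a warning. Because the
substituted regressions are linear, the discriminant's zero set on the
plane is exactly a straight line; it is reported by its endpoints at
fibrinogen 0 and 170 mg/dL.

**One-dimensional criteria.** For FDP-only settings, fibrinogen is
predicted from FDP by the single regression α̃ = f(β) (OLS, classical
standard errors — its recovery tests use homoskedastic constructions)
and q(FDP) = p(f(FDP), FDP) is scanned over [0, 150] at 0.1 mg/dL
resolution; the smallest 0.5-crossing is bisected to a 10⁻⁶ tolerance.
The smallest crossing is chosen deliberately: probability fields of
tree ensembles can be non-monotone, and a clinical alarm threshold
should err on the early side. If q never crosses 0.5 the criterion is
reported absent with a diagnostic rather than raising.

**Metrics.** Resubstitution is the default evaluation scheme: the
reference performance rows are exactly consistent with confusion
matrices on the 23 gated records (e.g. accuracy 22/23 = 0.9565), which
cross-validation cannot guarantee; leave-one-out is available as an
option. The accuracy's ± is the binomial standard error
√(acc·(1−acc)/N), which reproduces the printed ±0.04 and ±0.06 at
22/23 and 21/23. AUC is the rank (Mann–Whitney) statistic with ties
counting one half. Class mean class entropy is the per-class mean of
−ln p̂(true class), averaged across the two classes, natural
logarithm; probabilities are clamped at 10⁻¹² with a warning. In the
one-dimensional report (pipeline `table4.csv`), the hard FDP rule is
scored with pseudo-probabilities clipped to [0.02, 0.98] so the
entropy column remains finite for a deterministic rule.

## Synthetic study conditions

The generator's defaults are the study conditions: 3 hematuria and 20
non-hematuria records below the gate plus 84 padding records above it
(107 enrolled), and labels assigned by group.

*Marginals.* Each directly sampled factor (the anchors, TAT, FMC, AP,
AT, APTT, Plt, Hct) follows a truncated normal on the published
per-group [min, max], with location and scale solved numerically so
the *post-truncation* mean matches the published group mean and the SD
comes as close as the support allows. The tiny hematuria group prints
sample SDs that no distribution on the printed range can attain (e.g.
FDP 95.58 ± 0.73 on [94.73, 96]), so mean fidelity is weighted far
above SD fidelity in the fit. TAT in the hematuria group is degenerate
at the 120 ceiling (SD 0); both ceilings (TAT 120, FMC 250) are
enforced by censoring.

*Couplings.* The published anchor regressions are generative truth:
Hgb/fbg = 174.41 − 0.898·fbg, PT-sec = 19.681 − 0.048·fbg,
D-dimer = −9.535 + 3.4946·FDP. PT-INR and PIC are near-collinear
shadows of PT-sec and D-dimer (target correlations 0.98 and 0.97,
linear maps interpolated from the printed group means) so the pruning
stage has genuine multicollinearity to remove. Hemoglobin is derived
as hgb = hgb_fbg·fbg/1000, keeping the ratio invariant exact — the
×10³ scale of the ratio is inferred from the printed magnitudes
(7.37 g/dL / 59.67 mg/dL ≈ 124 matches the printed 139 ± 73 order).
Hemoglobin's own marginal is therefore implied rather than targeted,
and hematocrit is sampled independently of hemoglobin.

*Residual noise.* Nominal residual SDs are set so each coupling would
reproduce its published R² over the gated 3 + 20 anchor mixture
(resid_sd = |slope|·sd_anchor·√((1−R²)/R²) ≈ 22.6, 1.6, 69 for the
three couplings). Because analytes cannot be negative while the
D-dimer prediction near the low end of the FDP range is close to zero,
the noise is a Gaussian truncated symmetrically at ± the linear
prediction: values stay in [0, 2·prediction] and the conditional mean
of the residual is exactly zero, so OLS on generated cohorts remains
an unbiased estimator of the generative coefficients. The truncation
removes variance where predictions are small, so realised R² on gated
cohorts runs higher (≈ 0.85/0.61/0.89) than the published values; the
noise is correspondingly heteroskedastic, which is why the projection
stage reports HC3 standard errors. The sampled FDP range is floored at
2.74 mg/dL (the zero of the D-dimer coupling) instead of the printed
0.72 so the coupling stays nonnegative; padding-record fibrinogen is
drawn in [170, 185] for the same reason with respect to the ratio
coupling.

*What passing tests do and do not show.* The generator emulates
marginals, the printed linear couplings, class imbalance and ceilings —
not the real joint distribution within groups, not skewness or
measurement error, and not any causal structure. Recovery of the
five-factor vector and of coupling coefficients on these cohorts
demonstrates that the pipeline's selection, pruning, projection and
boundary machinery is correct under the documented conditions; it does
not validate the published thresholds on real patients, and the exact
published boundary geometries and FDP criteria (84.96…101.16 mg/dL)
are not reproducible without the raw cohort.

## Numerical choices and degenerate inputs

- Truncated-normal moment matching: Levenberg–Marquardt on
  (mean error × 100, SD error), cached per (mean, SD, min, max).
- Contribution rate requires length ≥ 3 and non-constant inputs;
  constant factors simply cannot join a related set.
- Greedy pruning always terminates (each step removes one member) and
  returns a maximal valid subset under the priority order.
- Marching-squares vertices are linearly interpolated, so along any
  crossed grid edge the interpolated probability passes through the
  level; analytic fields recover their level sets to well under one
  grid step.
- Bisection for the 1-D criterion starts from a 1501-point bracketing
  scan; a scan point landing exactly on 0.5 is returned directly.
- Single-class cohorts are rejected by screening, partition derivation,
  classifier training and the discriminant (ValueError), not silently
  tolerated.
- Rejection sampling for separable cohorts batches candidate draws and
  aborts with a RuntimeError after a bounded number of attempts when
  the rule and margin leave no room in the window.

## Known limitations

- The generator's group marginals are independent within group apart
  from the documented couplings; real panels are jointly dependent.
- Platt scaling inside the SVM on 23 records with 3 positives is
  noisy; the extracted SVM boundary is stable but its probability
  calibration is not meaningful far from the boundary.
- The discriminant's error probability assumes two Gaussians with a
  common covariance — with 3 positive records this is a reporting
  convention, not an inference.
- Figure rendering is best-effort display code; the serialised geometry
  JSON is the tested artifact.
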