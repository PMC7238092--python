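# Methods

## Problem and scope

`cadfusion` evaluates how a per-plane computer-aided-diagnosis (CAD)
system changes radiologists' BI-RADS assessments of breast lesions on
ultrasound. The CAD device is treated as a black-box binary classifier:
for every stored imaging plane of a lesion it outputs "possibly benign"
or "possibly malignant". The package covers everything downstream of that
output — decision fusion across planes, mechanical adjustment of a
reader's BI-RADS category, the paired diagnostic-accuracy statistics, and
a calibrated cohort simulator. Image acquisition, lesion segmentation and
the classifier internals are out of scope.

## Fusion and category adjustment

Lesions are rated on the ordinal scale 3 < 4A < 4B < 4C < 5 (ranks 0–4);
"positive for cancer" means category ≥ 4B. When a reader rates by
counting malignant ultrasound signs, the count maps monotonically to the
scale: 0 → 3, 1 → 4A, 2 → 4B, 3 → 4C, ≥ 4 → 5. A count of exactly 4 maps
to 5: the enumeration the rule comes from skips that value, and monotone
closure is the only order-preserving completion.

Two k-of-n fusion rules aggregate plane calls:

* **cross-planes**: longitudinal + transverse; positive iff ≥ 1 plane is
  malignant (k = 1 of 2);
* **quadri-planes**: the orthogonal pair plus two oblique planes at 45°;
  positive iff ≥ k planes are malignant, k = 2 by default.

A positive fused verdict upgrades the reader's category one level; an
all-benign plane set downgrades one level; a quadri set with exactly one
malignant plane is neutral (the defining enumeration covers only the
≥ 2-positive and all-benign branches; leaving the category unchanged is
the conservative completion). The scale saturates: upgrades from 5 stay
5, downgrades from 3 stay 3. Consequences that the property tests
enforce: the adjusted rank never moves more than one level; flipping a
benign plane to malignant never lowers the output; plane order is
irrelevant; and duplicating both calls of a cross set makes the 2-of-4
rule coincide with the 1-of-2 rule.

The "combined mode" dichotomization is defined as
`dichotomize(adjust(category, planes))`. The management decision-change
audit counts exactly the lesions whose category crossed the 4A/4B
boundary (under ±1-level adjustment those are exactly the 4A→4B and
4B→4A transitions): an upgrade is correct iff the lesion is malignant, a
downgrade correct iff benign, and the four cells partition the set of
lesions whose dichotomous verdict flipped.

## Statistics

All proportions are held as exact rationals (`fractions.Fraction`) and
rounded only at the reporting edge, half away from zero to one decimal,
which is what lets printed table cells be reproduced digit-for-digit.

* **2×2 metrics** — closed-form sens/spec/PPV/NPV/accuracy; a metric with
  a zero denominator is reported as undefined (with a warning) rather
  than failing the whole panel.
* **McNemar** — exact two-sided binomial tail
  `min(1, 2·P(X ≤ min(b,c)))` over the `b + c` discordants, or the
  continuity-corrected `(|b−c|−1)²/(b+c)` chi-square; the `auto` mode
  switches to the asymptotic form at 25 discordants. The variant used by
  the original analysis is not recorded anywhere; 25 is the conventional
  crossover.
* **Cohen's kappa** — exact rational computation with the usual
  interpretation bands (≤ 0.2 poor, ≤ 0.4 fair, ≤ 0.6 moderate, ≤ 0.8
  good, ≤ 1 perfect, read as half-open intervals on the exact value).
* **Empirical ROC** — one operating point per achievable threshold over
  the distinct ordinal score values, trapezoidal AUC (equal to the
  tie-corrected pairwise statistic), Hanley–McNeil SE
  (`Q1 = A/(2−A)`, `Q2 = 2A²/(1+A)`), and the Youden-optimal cutoff
  reported as the midpoint between the two adjacent achievable scores —
  hence cutoffs like 2.5 on a 0–4 plane-count scale. Tie detection on J
  uses a 1e-12 absolute tolerance (rationally equal J values computed
  from different cumulative sums can differ in the last float bit), and
  ties break toward higher sensitivity.
* **Correlated-AUC comparison** — the z-test
  `z = (A₁−A₂)/√(se₁² + se₂² − 2r·se₁se₂)`. The correlation input `r`
  the method needs is never published with study tables, so it is
  estimated as the average of the Spearman rank correlations between the
  two score sets within positives and within negatives, clipped to
  [0, 1]; callers may override `r` directly.
* **Two-proportion comparison** — Pearson chi-square without continuity
  correction, with an exact conditional (Fisher) fallback when any
  expected cell is below 5 **or** any observed cell is empty; the
  observed-zero clause covers degenerate tables whose expected counts are
  all ≥ 5 yet the chi-square approximation is clearly inappropriate.

All tests are two-sided; 0.05 is the significance convention in the
reporting layer.

## Synthetic cohorts

The simulator produces lesion-level data with the three couplings the
analysis depends on, each of which is a config knob:

1. **Pathology and severity.** Malignancy is Bernoulli(prevalence);
   each lesion carries a latent severity, standard normal within class,
   with malignant lesions shifted up by `class_separation` SD.
2. **Plane calls.** The four calls threshold an equicorrelated Gaussian
   vector `Z_i = √ρ·U + √(1−ρ)·ε_i` at the class-specific quantile of the
   target marginal rate, so the class-conditional per-plane positive
   probability is exact at any ρ — the reason this construction was
   chosen over, e.g., a beta-binomial. The shared factor `U` is the
   within-class standardized severity, which ties CAD calls to reader
   scores and makes combined-mode gains non-trivial.
3. **Readers.** Reader *r* observes `severity + N(0, σ_r²)` and bins it
   with four fixed thresholds into the five categories — an
   ordered-probit reader model in which experience is a single noise
   parameter rather than a free 2×5 table.

`fused_positive_rate(p, k, rho)` gives the exact k-of-4 positivity rate:
the binomial tail at ρ = 0, and a Gauss–Hermite quadrature (80 nodes)
over the shared factor otherwise. `calibrate_to_fused_targets` inverts it
by Brent root finding to residuals below 1e-9 (in practice ~1e-16);
its default ρ = 0 matches the closed-form binomial inversion.

### Default configuration

The packaged default reproduces the published study's conditions:

| parameter | default | origin |
|---|---|---|
| prevalence | 0.391 | 200/512 malignant lesions |
| fused 2-of-4 target | sens 0.875, spec 0.814 | quadri-planes CAD column |
| per-plane sens / FPR | 0.727 / 0.181 | calibrated at ρ = 0.3 |
| plane ρ | 0.3 | placeholder — no inter-plane correlation is published; "same lesion, different probe angle" dependence |
| class separation d | ≈ 2.27 SD | probit inversion, see below |
| experienced reader | σ = 0.3 | targets 76.0% / 92.9% without CAD |
| novice reader | σ ≈ 1.46 | targets 60.0% / 84.9% without CAD |

The reader parameters come from inverting the ordered-probit model at
the published without-CAD operating points: with total score SD
`s = √(1+σ²)`, a reader achieving (sens, spec) implies
`s = d/(z_spec − z_(1−sens))` and 4B-cutpoint `c2 = z_spec·s`. Fixing
the experienced reader's noise at σ = 0.3 (an experienced reader is
nearly calibrated to the latent severity) determines d ≈ 2.27; the
novice's σ then follows from their operating point. The remaining
cutpoints are spaced at 0.9 (below) and 0.8, 1.6 (above) observed-scale
SDs around c2 — values chosen once to give plausible category mass at
the scale ends; they affect only the audit granularity, not the
dichotomized metrics.

### What the simulator does and does not emulate

It reproduces prevalence, class-conditional correlated plane calls, and
ordinal reader scores stochastically ordered by pathology, with
CAD–reader dependence through the shared severity. It does **not**
model lesion size or histological subtype covariates, reader drift or
learning, per-lesion difficulty beyond the single severity axis, or
readers overriding the mechanical adjustment rule (the published
combined-mode categories were produced by humans applying the rule;
the pipeline applies it mechanically). Passing simulation-based tests
therefore validates the statistical machinery under the stated model,
not the device's clinical performance.

## Reproduction targets and their limits

From the printed summary tables alone the package recomputes: the full
six-mode metric panel (all cells match after rounding, with two
documented printing inconsistencies — the experienced reader's
without-CAD specificity prints 93.0 where 290/312 = 92.9, and one
abstract figure disagrees with its own table), the two agreement kappas
(0.63 "good" for the combined pairing; 0.5648 computed where 0.57 is
printed — the package reports the computed value), and the
decision-change proportions with their comparisons. The published AUCs
(0.73–0.87), their confidence intervals, the Youden index 0.68 at
cutoff 2.5, and the lesion-paired McNemar p-values are **not**
desk-reproducible: they require per-lesion ordinal scores that were
never published. For those, the machinery is validated against
independent oracles (brute-force pairwise AUC, exhaustive threshold
search, binomial mass summation, lesion-level bootstrap) instead.

Problem sizes used in the checked examples — cohorts of 400–5000
lesions, 400 bootstrap replicates, 100–200 random ROC instances — were
chosen as the smallest sizes at which Monte-Carlo tolerances (3
simulation SEs; 25% relative on the bootstrap-vs-analytic SE, which also
absorbs the Hanley–McNeil exponential-model approximation for ordinal
data) are comfortably discriminating.

## Known limitations

* The Hanley–McNeil SE assumes the negative-exponential ROC model; for
  coarse ordinal scores it is approximate, which is why the paired
  comparison is cross-checked by bootstrap rather than asserted exactly.
* The estimated correlation input `r` is a pragmatic stand-in for the
  original method's tabulated value; it feeds the same z formula.
* κ interpretation bands are a convention, not an inference.
* The simulator's ρ default is a placeholder (see table) and parameter
  recovery for ρ itself is not implemented — only the marginal rates are
  recovered.
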