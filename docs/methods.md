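# Methods

## Stimulus space and grammars

Strings are six CV syllables. Two grammars differ only in the orientation of
the two regularities: `di_first` strings are /di/ABCDD (affix initial,
repetition final), `di_last` strings are AABCD/di/. Positions are 1-based
over syllables; "edge" means slot 1 or slot 6, and the grammatical
repetition occupies the adjacent slot pair at the non-affix edge.

Syllable categories A/B share one pool of 24 syllables (6 consonants × 4
vowels) and C/D another; the test phase exchanges the consonant sets
between the pools so the two phases share no content syllable. Together
with the constant /di/, the union over both phases contains 97 distinct
syllables — this count is what the Bayesian model uses for S. Phone labels
are X-SAMPA-style ASCII and a diphthong is a single phone, so every item is
exactly 12 phones; at the default 116 ms per phone an item lasts 1392 ms,
rendered as MBROLA `.pho` text with a flat 135 Hz pitch target. We emit the
synthesis text only; running a synthesizer is out of scope.

Generation is constraint satisfaction by rejection sampling from a single
seeded PCG64 generator (resample cap 10 000, then an error): within an
item, the A and B syllables must differ in both consonant and vowel, as
must the two distinct final-zone categories (C and D) — the source design
describes this constraint with respect to an "E" category that does not
exist during familiarization, and we read it as applying to the two
final-zone content categories. The repeated syllable is an exact
self-repeat. Foil slots (E/F) in ungrammatical templates cycle through
categories A–D across the 9 items of a type (counterbalancing), are never
assigned the category of a template-adjacent slot, and every item is
re-checked so that no unintended adjacent repetition survives and the
classifier reproduces the intended item type. Generated sets contain
distinct strings; generation is a pure function of (grammar, mode, seed).

`classify_item` is total on 6-tuples: it checks each regularity for
presence anywhere and presence at its grammatical edge, maps the edge
checks to the four item types, and calls a violation `presence` if any
violated regularity is absent from the string altogether, `position` if
every violated regularity is present but displaced.

## Size-principle model

Hypotheses and extension sizes: default S⁶, edge repetition S⁵, edge affix
S⁵, conjunction S⁴. The prior is uniform over the included hypotheses (no
prior is otherwise motivated). All familiarization items are consistent
with all hypotheses by design, so after |T| items the posterior is
p(h|T) ∝ |h|⁻ᴵᵀᴵ and the predictive of a test item sums p(h|T)/|h| over the
hypotheses its class satisfies: grammatical items satisfy all four,
single-violation items the default plus the unviolated single rule, double
violations only the default. Item classes are abstract consistency vectors;
classifying concrete strings is the stimulus module's job. Defaults S = 97
and |T| = 36 are the study conditions.

Everything is computed in natural-log space with log-sum-exp; at the
default configuration the smallest weights are of order 97⁻²¹⁶ ≈ 10⁻⁴²⁸,
far below double-precision underflow, so no linear-scale intermediate is
ever formed. Ratios are reported as log10. Surprisal is in nats; every
comparison of interest is a ratio and hence base-invariant. The enumeration
oracle materializes all S⁶ strings for S ∈ {2..5}, counts extensions
extensionally, and evaluates representative strings (built over symbols
{0, 1} so they exist at S = 2) by membership scans; it exists solely to
validate the closed form and agrees with it to 1e-12 in log space.

The model predicts identical behaviour for presence and position
violations, and for repetition vs /di/ violations — it has no notion of
salience. Surprisal-based rejection-rate ratios depend on unpublished
computation parameters and are deliberately not asserted anywhere; the
asserted surprisal property is the ordering double > single > grammatical.

## Response simulator

The generative model for judgments is fixed-effects logistic: treatment
coding with reference levels order = di-repetition, violation mode =
presence, no violations; predictors are the two main factors, the two
violation indicators, and the four interactions (order × each violation,
mode × /di/ violation, repetition × /di/ violation). Default coefficients
are the published combined-analysis estimates (intercept −1.67, order
−0.54, mode −0.11, repetition violation 2.03, /di/ violation 2.19,
interactions −0.62, 0.96, 0.55, −0.90, log-odds scale); under them the
rejection rates are graded — double > each single > grammatical in every
design cell — which is the qualitative signature the simulator exists to
emulate. The participant random-intercept sd defaults to 0 because no
variance estimate was published; any nonzero default would be invented. It
is configurable for robustness checks, in which case fitting remains
fixed-effects-only and recovered magnitudes are attenuated toward zero —
documented here rather than "fixed" with quadrature.

Design defaults: 20 participants per (order × mode) cell, 9 trials per item
class per participant (36 trials each), single violations split evenly
between repetition- and /di/-violations. What the simulator does **not**
emulate: item-level random effects, reaction times, learning within the
familiarization phase, order-of-presentation effects. Passing recovery
tests therefore show that the analysis code is correct and well-calibrated
for this generative family, not that real participants satisfy it.

## Analysis battery

- One-sample t vs the 50% chance level, Cohen's d = (mean − chance)/sd,
  Bonferroni family defaulting to 4 (the four item types tested per
  condition; the alternative family of 8 across orders is configurable).
- Paired t; the effect size is Cohen's d corrected for dependence between
  means, d_rm = (mean diff / sd diff)·√(2(1−r)).
- 2×2 mixed ANOVA (within regularity × between order) via
  `pingouin.mixed_anova`, reporting partial η² = SS_eff/(SS_eff+SS_err);
  a hand-written sums-of-squares decomposition cross-checks it in the tests.
- Trial-level logistic regression on the same design matrix as the
  simulator via `statsmodels.Logit`, with Wald z/p (matching the published
  Z columns). Perfect separation raises an error naming a separating
  covariate found by a conditional-constancy scan (a heuristic: it names a
  sufficient culprit, not necessarily the unique one).
- Zero-variance inputs raise `DegenerateVarianceError`; "zero" means sd
  below 1e-10 of the data scale, absorbing float cancellation in paired
  differences.

Validation is by parameter recovery: with ~10⁵ trials (700 participants per
cell) every coefficient is recovered within ±0.15 of its generating value;
closed-form fixtures pin the t/F paths. Published human-data tables are not
reproduction targets — the trial-level data were never deposited.

## Pipeline

`run_pipeline` wires stimuli → predictions (both model variants) →
simulation → analysis under one seed; per-stage seeds are spawned from a
`SeedSequence` and kept below 2³¹. The manifest records the seed, a config
hash and every file written; stage failures propagate with the stage name
and leave a manifest flagging the failed stage. All outputs except the
manifest (which carries wall-clock timings) are byte-identical across
reruns of the same config and seed.

## Problem sizes

Tests and examples run the model at full scale (it is closed-form and
instant); simulation-based checks use 120–700 participants per cell,
chosen so Monte-Carlo error (∝ n⁻¹ᐟ²) sits comfortably inside the asserted
tolerances while the whole suite stays fast. The enumeration oracle is
capped at S ≤ 5 (S⁶ strings are materialized).

## Known limitations

- The full hypothesis space over all positional predicates is out of scope;
  only the four rules above are modelled, with a uniform prior.
- The paper-printed familiarization timeline (inter-stimulus intervals,
  total duration) is not modelled.
- Mixed-effects estimation (nonzero random-intercept fitting) is out of
  scope; see the attenuation note above.
- The `.pho` output targets a SAMPA-style phone alphabet but has not been
  validated against any specific synthesizer voice inventory.
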