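# Methods

This note documents the statistical model behind `normtext`, the design of
the synthetic-study generator, the numerical choices, and what the test
suite does and does not demonstrate.

## The scoring model

The shared-word score of two responses is the size of the intersection of
their distinct content-word sets. Content words are produced by: NFC
normalisation and case folding; tokenisation into runs of letters with
internal hyphens and apostrophes kept ("jell-o", "isn't" are single tokens)
and pure-number tokens dropped; deletion of a stopword list. The packaged
default list contains standard English function words plus spoken
interjections ("um", "uh", "yeah", …) that occur in transcribed speech; it
deliberately keeps "like", which is content-bearing in scene descriptions.
Any list can be substituted from a plain-text file. No stemming, spelling
correction or synonym expansion is applied: raw-token matching is the method
— composite or semantically smoothed scores are out of scope by design.

Take-one-out validation scores each response against every *other* response
in the dataset, separately for same-clip and other-clip comparisons, giving
per-response `mean_same` and `mean_other`. A response is never compared to
itself; means with no comparison responses are reported missing (NaN), never
zero. The other-clip comparison set is *all* responses to all other clips —
no sampling, since exact computation is cheap (the implementation aggregates
binary term incidence per clip, making the whole procedure linear in the
number of response–word pairs; tests require exact equality with a naive
double loop). By default a participant's own responses to other clips stay
in the comparison set (a flag excludes them). Cross-dataset scoring replaces
the comparison set with a reference dataset; pooled scoring concatenates
datasets and keeps each response's dataset label for the factorial analysis.

## Vocabulary comparisons

Word frequency is the corpus-level token count with repeats inside a
response included; a singleton is a word of total frequency 1. Word length
counts letters only (hyphens and apostrophes excluded). Rarefaction draws
whole responses without replacement (default 1000 replicates, seed
mandatory) so corpora of different sizes can be compared at a common size;
at full size it returns the exact vocabulary with zero variance.

## Inference

* Welch's unequal-variance t with Satterthwaite df for two-sample length
  and score contrasts.
* The same/other × dataset analysis treats each response's two scores as
  observations in a two-way fixed-effects model with interaction (OLS +
  type-II ANOVA). This mirrors a denominator df of 2·n−4. A paired
  alternative (and the automatic single-dataset reduction) reports F = t²
  from a paired t test.
* Contingency tables use Pearson's chi-square *without* continuity
  correction (Fisher's exact test is available for 2×2); a warning is
  raised when an expected count falls below 5.
* Demographic effects use a linear mixed model with fixed effects for age
  (years, centered), gender (female reference; the reported term is
  `male`), ordinal education (5 levels), and random intercepts for
  participant and clip as fully crossed factors. statsmodels' `MixedLM`
  has no first-class crossed factors, so the model is fitted as one
  super-group with two variance components — the standard construction —
  by L-BFGS under REML (ML available for nested-model comparisons).
  Fixed-effect p-values and confidence intervals are Wald (normal)
  approximations. The implementation is cross-checked against R `lme4` in
  the test suite (agreement to ~4 decimals on a shared fixture).
  Rank-deficient fixed-effect designs raise an error naming the collinear
  terms.

## The synthetic-study generator

No public corpus of normative clip descriptions accompanies this method, so
the generator produces studies with the structure the analysis assumes.
Defaults describe a two-source study: 200 clips; a crowdsourced-style
dataset (99 participants, free choice of volume, 20 responses per clip,
4000 total, mean 33 content words, typed) and a lab-style dataset (60
participants in an age-stratified balanced design, 40 clips each, 12 per
clip, 2400 total, mean 28 content words).

Mechanisms, and the real-data features they emulate:

* **Vocabulary.** A global background vocabulary (6000 words) with
  Zipf-distributed frequencies, exponent per dataset (1.10 crowdsourced,
  1.00 lab — the flatter lab distribution yields the more varied
  vocabulary and higher singleton counts seen in transcribed speech), plus
  40 topic words per clip, pairwise disjoint across clips, with per-clip
  Zipf concentration drawn from U(0.7, 1.3). Token names are synthetic
  letter codes, disjoint from every stopword.
* **Clip signal.** Each content token is a clip-topic word with
  probability ρ_c, else a background word. ρ_c is clip-specific: drawn
  around the configured `clip_signal` (default 0.5) on the logit scale
  (sd 1.3) and *shared by all datasets* — the generator's model of clips
  differing in how much common vocabulary they elicit, which is what makes
  per-clip homogeneity correlate across datasets (~0.5 at defaults).
* **Participants.** Crowdsourced ages follow a shifted lognormal (median
  35, range 20–66, long right tail), 63% female; lab ages are stratified
  into three bands (23–59, 60–70, 71–85) crossed with gender in equal
  cells. Education is ordinal with per-dataset level probabilities.
  Latents: a lognormal verbosity multiplier (log-sd 0.25, unit mean) and a
  normal score intercept (sd 0.5 score units).
* **Assignment.** Free mode draws lognormal volumes (log-sd 1.5, calibrated
  so the most prolific 20% of participants contribute ≈60% of responses on
  average across seeds; a single 99-participant realisation varies roughly
  0.48–0.66), capped at one response per clip, then fills clips to exactly
  their quota by a most-constrained-first greedy. Balanced mode deals each
  participant a cyclic block of distinct clips so every clip is covered
  equally by every demographic cell; infeasible configurations raise.
* **Lengths.** Response content length is negative binomial (shape 12)
  around a per-participant mean; the realised dataset means match the
  configured 33/28 within cluster-aware Monte-Carlo error. Because
  responses cluster by participant (verbosity × heavy-tailed volume), the
  Monte-Carlo SE of a dataset mean is the cluster-linearised one, not
  sd/√n; the length-calibration test uses it.
* **Demographic effects** are configured in *outcome units* (shared words
  per year of age, per male, per education level; words of length
  likewise). Length effects add directly to the participant's length mean.
  Score effects are injected through length as well: the generator computes
  the expected same-clip score as a function of a response's mean length
  (closed-form negative-binomial presence probabilities, population
  verbosity integrated by Gauss–Hermite quadrature) and inverts that curve
  so each participant's *expected score* moves by exactly the configured
  shift. Length is the channel because it is the dominant empirical driver
  of this score (the score–length correlation is ~0.7 in generated data)
  and because the expected score is nearly flat in ρ above the 0.5 default
  (same-clip overlap cannot exceed what the comparison side says), so a
  ρ-based injection has almost no upward headroom. The inversion is convex,
  which would drift mean length upward; a constant per-dataset recentring
  restores the configured mean without affecting between-participant
  contrasts. Effects are centered at the realised sample means, so injected
  coefficients tilt individuals without moving dataset-level means.
* **Emitted text** is space-joined tokens with stopword fillers interleaved
  (45% of raw tokens) and split across the two prompt fields, so the full
  preprocessing path is exercised end to end. Everything (vocabularies,
  participants, assignment, lengths, tokens) derives from one seed;
  identical configs produce byte-identical files.

What the generator does **not** model: real word semantics and syntax,
spelling errors, transcription noise, within-participant drift over
sessions, and clip-demographic interactions. Passing tests therefore
demonstrate correctness of the *pipeline* and recoverability of effects
under the assumed structure, not performance on natural language.

## Problem sizes and numerical choices

* Discrimination/null and calibration tests run at the full default design
  (6400 responses). Effect-recovery simulations use 100 replicates of a
  100-clip, 99-participant study (the SE of participant-level effects is
  dominated by participant count, so fewer clips sacrifice little power);
  the null-calibration arm uses 250 replicates of a 60-clip design with 8
  responses per clip, where the Wald test's type-I error is ≈5%.
* Mixed-model convergence: L-BFGS, maxiter 200; the degenerate
  constant-outcome case short-circuits to zero effects.
* Rarefaction and all simulations take `numpy` `Generator` seeds; the
  pipeline manifest records every seed, the config hash and package
  versions.
* Ties in distinctive-word tables break lexicographically; vocabularies are
  sorted, so all outputs are byte-stable across runs.

## Known limitations

* Wald p-values from the crossed mixed model are mildly anticonservative
  for small numbers of participants; with ~60 balanced participants the
  empirical type-I error is ≈7%. Use larger designs or treat borderline
  p-values with care.
* The same/other factorial treats a response's two scores as independent
  observations (by design, to mirror the 2·n−4 denominator df); the paired
  alternative is available and more conservative.
* `same_other_ratio` is a ratio of grand means; it is reported as `inf`
  with a warning when no cross-clip sharing exists.
* Score-unit demographic effects being length-mediated means a configured
  score effect induces a proportional (small) length effect; the two
  outcome models are therefore not orthogonal, as in real data.
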