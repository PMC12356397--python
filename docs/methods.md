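# Methods

This note documents the models and procedures implemented in `srbias`, the
parameters that matter, and the design decisions taken where the design was
genuinely open. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Stimuli

Letters are rendered from deterministic block-stroke bitmaps on a 5×5
stroke grid, scaled to a requested glyph height (85 px by default, centred
in a 100×100 field). The Sloan typeface used in acuity charts is not
bundled (it is not freely redistributable); the replacement glyphs were
designed so that the *confusability structure* of the stimulus set is
preserved: each letter's nearest neighbour by Jaccard pixel overlap is its
cross-category confusion partner (C↔O, E↔B, H↔U). This is the property the
paradigm depends on — errors should cross the category boundary — and it is
asserted by the test suite rather than assumed.

The noise ladder is `[0] + geomspace(σ_min, σ_max, k)`; with σ_min = 0.25,
σ_max = 64, k = 6 it reproduces the seven-level ladder 0, 0.25, 0.76, 2.30,
6.96, 21.11, 64 (values rounded to 2 dp for display only). Frames are
`clip(background + increment·mask + noise_t, 0, 255)` with a fresh noise
field per frame (60 Hz; 60 frames for a 1-s trial). Clipping behaviour at
extreme σ is a package choice: a real display clips at its gamut, so we
clip rather than wrap or rescale. Coordinates are row-major with origin
top-left; noise covers the whole square, letter pixels included, which is
the natural reading of per-pixel display noise.

## QUEST staircase

The staircase maintains a discretized posterior over the log10 threshold T
of a Weibull psychometric function

p(x) = δγ + (1−δ)[1 − (1−γ)·exp(−10^{β(x−T)})]

with γ = 1/6 (6AFC guess rate), target p = 0.70, and intensity x = log10 of
the letter increment over the fixed background (the background never
changes, so absolute luminance adds nothing). Class defaults are β = 3.5,
δ = 0.01, a Gaussian prior with SD 1.0, and a 201-point grid spanning ±2.5
log units; both trial placement and the final estimate use the posterior
mean, clamped to the grid. These are conventional staircase settings; all
are exposed in `QuestParams`.

The *experiment pipeline* overrides two of them in its config
(`QuestConfig`): prior mean 1.5 with SD 0.5 — a pilot-informed prior
centred on the threshold region of the default observer — and δ = 0.05,
because the synthetic observer's ceiling error rate (lapses plus decision
noise, about 5–7 %) otherwise drags the posterior mean upward when an
error occurs at high intensity. Both remain user-configurable.

### Titration precision

The accuracy delivered by a 50-trial titration has an irreducible spread.
A binary trial at the threshold carries Fisher information
p′²/(p(1−p)) about T, so the best achievable accuracy-scale error after
50 trials is √(p(1−p)/50) ≈ 0.066 (6.6 accuracy points), and a 200-trial
probe adds √(p(1−p)/200) ≈ 0.033 — a combined SD of ≈ 7.3 points around
the 70 % target, independent of the psychometric slope. The staircase
therefore lands within ±10 points in roughly 83 % of runs, which is the
theoretical limit for this trial budget; the experimental protocol's
Block-2 rerun rule exists precisely to catch the remaining runs and
re-titrate them.

## Synthetic observer

The generator is the minimal mechanism that produces the three empirical
signatures the analysis is built to detect — an inverted-U accuracy profile
over σ, a positive baseline criterion, and a criterion reduction where
accuracy peaks:

1. **Hard transduction threshold θ** (grey units). Per frame, a pixel
   contributes its deviation from background only if the deviation exceeds
   θ; the percept map is the mean contribution over the integrated frames.
   With increment < θ the letter is invisible at σ = 0 and becomes visible
   when noise co-activates letter pixels — the canonical SR nonlinearity.
2. **Internal pixel noise** (SD 10 by default), present at every external
   noise level. This smooths the otherwise step-like psychometric function
   at σ = 0 so that a 70 % point exists for QUEST to find, and it plays the
   role of the sensory noise a human brings to the task.
3. **Template matching**: normalized (mean-subtracted, unit-norm)
   cross-correlation of the percept with the six letter templates; a zero
   or constant percept yields zero evidence for every letter.
4. **Late decision noise** (SD 0.07 on the correlation scale). Without it,
   matching over thousands of independent pixels is a near-ideal observer
   that still reads letters through σ = 64 noise; bounded central
   efficiency is what makes performance collapse at the top of the ladder,
   as it does for human observers.
5. **Category prior**: an additive bonus w·log π(k) on each letter's
   evidence, with π splitting probability `category_prior` (0.8) equally
   over the three letters of the observer's preferred category. w > 0
   produces the positive criterion; because the prior bonus is fixed while
   stimulus-driven evidence grows with transmission, the bias loses
   leverage exactly where noise helps — the criterion-reduction signature.
6. **Lapses**: a uniformly random letter with probability 0.02.

Defaults (θ = 50, internal SD 10, w = 0.03, decision SD 0.07, lapse 0.02,
12 integrated frames) were fixed once, by design calibration of the
generator against the target structure: QUEST titrates such an observer to
a letter increment of roughly 25–32 grey levels (sub-threshold, ≈ 0.6–0.75
letter-exact accuracy), category accuracy then runs from ≈ 0.80 at σ = 0 to
a peak ≈ 0.94 at σ ≈ 7–21 and falls at σ = 64, with a baseline criterion
near +0.4 to +0.5 that shrinks at the accuracy peak. Twelve integrated
frames (not the display's 60) keep a full cohort simulation at desk scale;
the parameter is configurable.

Cohorts draw per-participant θ ~ N(50, 4) and w ~ N(0.03, 0.012) (truncated
at 0.005), and 75 % of participants prefer consonants. Heterogeneity in w
spreads the criterion across participants the way real observers spread;
observers with near-zero w occasionally show no block-3 bias and are then
excluded by the same rule as human participants.

What the generator does **not** emulate: learning or fatigue across blocks,
reaction times, letter-frequency effects within a category, any explicit
"give up and guess" mode at extreme noise, and the idiosyncratic template
shapes of individual observers. Passing tests therefore show that the
*analysis chain* detects SR and bias reduction when they are present with
realistic effect sizes — not that the observer model is a quantitative
account of human letter identification.

## Block design

Practice (18 trials, 6 letters × 3, easy luminance 132), QUEST (50 trials,
uniform random letters), Block 2 (48 trials, consonants frequent, base
rates undisclosed), Block 3 (48 trials, base rates flipped toward the
participant's observed bias and disclosed), Blocks 4–5 (240 trials each
over the noise ladder). Two reconciliations the printed design requires:

- A 48-trial block cannot realize 80/20 with equal per-letter counts
  (48·0.8 = 38.4); the closest equal-count split 39/9 (13 per frequent
  letter, 3 per rare) is used and logged as an effective 81.25/18.75.
- The noise block is described both as "8 noise levels × 30 trials" and as
  six nonzero levels plus a zero-noise baseline; these are reconciled by
  giving the zero level two of the eight 30-trial slots, so each block has
  240 trials, nonzero levels get 30 per block (60 across blocks 4+5), and
  the baseline gets 120 pooled trials.

Bias assignment after Block 2 uses the criterion sign (vowel rare:
c ≥ 0 → consonant-preferring); the QUEST rerun rule triggers when
letter-exact Block-2 accuracy leaves [0.60, 0.80], boundary inclusive, with
at most two reruns before the session proceeds; the exclusion rule drops
participants whose Block-3 criterion is ≤ 0.

## SDT conventions

The criterion is computed as c = −(z(HR)+z(FAR))/2, the standard additive
form: sensitivity and bias are then orthogonal, and the identities
z(HR) = d′/2 − c, z(FAR) = −d′/2 − c hold exactly (property-tested).
Extreme rates use the 1/(2N) replacement (Macmillan–Creelman); with only
12 rare trials per nonzero noise level per block, 0/1 cells are common, so
the correction is flagged per summary row. Note that any count-based
correction makes corrected rates depend on N: pooling more identical data
moves a corrected rate toward its boundary. Blocks 4 and 5 are pooled
before summarizing, so the zero-noise rows of both blocks form one baseline.

## Inference

- RM-ANOVA: classical within-subject decomposition,
  F = MS_levels/MS_(levels×subjects), df = (k−1, (k−1)(n−1)), no sphericity
  correction. With k = 7 levels and n participants the error df are
  6(n−1); sums of squares at float-noise level are treated as zero.
- Post-hocs: one-tailed paired t against the zero-noise baseline —
  "greater" for accuracy and d′, "less" for criterion — BH-FDR adjusted
  within each measure; Cohen's d = mean(diff)/SD(diff).
- One-sample t of the baseline criterion against 0, with d = mean/SD.
- JZS one-sample Bayes factor: marginal likelihood under a Cauchy(0, r)
  effect prior (r = 0.707 by default), computed by adaptive quadrature over
  the variance mixing parameter g with an inverse-χ²(1) weight; reported as
  ln BF10. Cross-checked in tests against an importance-sampling estimate
  and against an independent implementation.
- Correlation Bayes factor: stretched-beta(1/κ, 1/κ) prior on ρ (κ = 1 →
  uniform), marginalizing the exact sampling density of the Pearson r
  (hypergeometric form) by log-offset quadrature — the offset keeps the
  integral finite for |r| → 1.
- Power: smallest n whose noncentral-t tail probability at noncentrality
  d·√n reaches the target power, scanned exactly; no normal approximation.

Degenerate inputs fail loudly rather than silently: zero-variance
contrasts, constant correlation inputs, one-sided SDT cells and malformed
trial logs all raise with a specific message.

## Reproducibility and problem sizes

All randomness descends from one root seed via named `SeedSequence`
substreams (participant index × stream role), so identical seeds give
byte-identical trial logs and growing the cohort never changes earlier
participants. The packaged default run — 22 participants × ≥ 644 trials,
12 frames of 100×100 pixels per trial — simulates and analyses in about a
minute on one core; the test suite uses the same sizes for the end-to-end
check and smaller fields (48×48) where only mechanics are under test.

## Known limitations

- The observer's SR peak sits at σ ≈ 7–21 on the default ladder, somewhat
  higher than a human peak would imply for these stimuli; the peak location
  is governed by θ and the internal noise SD and can be moved in config.
- Corrected hit/false-alarm rates depend on cell counts (see above), so
  criterion values at extreme-bias cells are compressed relative to an
  uncorrected analysis.
- The Greenhouse–Geisser correction is not applied anywhere; with k = 7
  levels, strong sphericity violations would inflate the omnibus F.
- Re-analysis of human datasets is supported only through the canonical
  trial-log CSV; no download or format adapters are bundled.
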