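# Methods

This note documents the models implemented in `protolex`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the design was genuinely
open.

## Orthography-to-phonology conversion

Spanish orthography is transparent enough that a finite table of
context-sensitive rewrite rules covers it. The shipped table
(`protolex/data/spanish_g2p.tsv`) applies rules longest-match-first,
left to right, with optional left/right character contexts ("#" marks a
word boundary). It handles the digraphs ⟨ch, ll, rr, qu, gu+e/i, gü⟩,
silent ⟨h⟩, context-dependent ⟨c, g, r, y⟩, and maps accented vowels to
the same phoneme as their plain counterparts. The default dialect is
seseo (⟨c⟩+front vowel and ⟨z⟩ → /s/); `dialect="distincion"` yields /θ/.
Stress is deliberately *not* represented phonologically: the presence of
an accented character ⟨á é í ó ú ñ⟩ is a separate orthographic covariate,
because visual salience of such characters is modeled as its own effect
on ratings. A conversion failure names the offending character and
position; the table as shipped covers the full Spanish alphabet. Users
whose phonological forms carry extra symbols (e.g. stress marks from an
external converter) can admit them via `load_rules(extra_symbols=...)`.

Limitations: no syllabification, prosody, or allophony; ⟨x⟩ → /ks/ means
the orthography-to-phoneme length bound (phonemes ≤ letters + 1) holds
only for forms with at most one ⟨x⟩.

## Trigram phonotactic scoring

Conditional probabilities use interpolated Witten-Bell smoothing,

P(w | h) = (c(hw) + T(h) · P(w | h′)) / (c(h·) + T(h)),

recursing from trigram to bigram to unigram and bottoming out in the
uniform distribution over Σ ∪ {END}; an entirely unseen history backs
off to the lower order directly. Forms are padded ⟨⟨…⟩, so the first
symbol is conditioned on a double word boundary. Training is type-based
(each distinct form once); nonnegative weights support frequency-weighted
training where wanted (morph token counts). The phonotactic score is the
base-10 average conditional log-probability per symbol. The END
transition is excluded from both the sum and the length by default — the
score is over the symbols *in* the form — with `include_end=True`
available since either convention appears in practice. Scores of
stimuli containing symbols unattested in a small training sample are
handled by the same backoff (no form is unscorable if the model was
built with the full alphabet).

## MDL morph segmentation

The morph learner minimizes a two-part code length over the corpus of
word types:

* lexicon cost: each distinct morph type is encoded per symbol under a
  fixed unigram symbol model (estimated once from the corpus), plus a
  geometric length prior with continuation probability 1 − p_end
  (default p_end = 0.2, i.e. mean morph length 5 symbols);
* corpus cost: −Σ over morph usages of log(count(m)/N), the usual
  unigram token code.

Words are visited in seeded random order. For each word, the learner
compares keeping the string whole against every binary split point
(halves evaluated jointly as whole morphs), recurses into an accepted
split, and accepts only strict cost decreases. Because re-splitting a
half shifts counts, the realized cost of a recursive placement is
re-checked against the whole-morph alternative, and a word's previous
analysis is restored if re-analysis would raise the total cost; the
objective is therefore non-increasing by construction (asserted at every
step, and exposed as `cost_history`). Passes repeat until no change
(cap: 10 passes). The procedure is greedy and order-dependent, hence
the seed; it is deterministic given (corpus, seed).

After learning, each morph receives a token frequency — Σ over the word
types containing it of word frequency × occurrences within the word —
used as the weight for frequency-weighted morph sampling. The Viterbi
parser segments any form by maximizing Σ log(token_freq(m)/N) over
segmentations, admitting unseen substrings only as single-symbol
fallback morphs at 0.5 × the smallest morph probability (configurable);
ties break toward fewer parts. Parsed phonotactic scoring segments the
stimulus against the *sampled* morph set and restarts the trigram
context (fresh ⟨⟨ padding) at each boundary, dividing the total log
probability by the total symbol count; unparsed scoring treats the
stimulus as one morph.

## Stimulus construction

Words are binned by occurrences per million: low < 10, mid 10–100
(boundaries inclusive in mid), high > 100. A candidate nonword must
match its word in orthographic length, phonemic length, and the exact
positions of accented characters; among eligible candidates (minus any
vetoed by a pluggable predicate standing in for native-speaker
judgment) the one minimizing |Δ phonotactic score| is selected, ties
broken lexicographically for determinism. The bundled candidate
generator performs within-class constituent swaps (consonant for
consonant, vowel for vowel) and is a deliberately simple stand-in — the
selection logic, not candidate generation, is the specified computation.

Sessions hold 240 critical trials in random order. Word-identification
sessions sample 120 word/nonword pairs with per-(length, frequency-bin)
quotas proportional to group pool sizes, rounded by largest remainder so
quotas sum exactly to 120; wellformedness sessions sample 240 nonwords
proportional to length groups. Six attention checks are inserted one
per sixth of the session at a seeded position within the block,
targeting the leftmost, middle, and rightmost buttons twice each in
random order.

Post-hoc exclusion drops (with logged reasons) any pair containing a
stimulus orthographically identical to an English word — unless
allowlisted as a recognizable borrowing — and any pair whose within-pair
score difference was ≤ tol under the selection-time scoring system but
> tol under the analysis-time system. The tolerance is a configuration
value.

## Cumulative-link models

The proportional-odds model P(Y ≤ k) = logistic(θ_k − η) is fit by
Newton's method with analytic gradient and Hessian (the likelihood is
log-concave, so Newton with step-halving converges globally). Extreme
categories use pseudo-infinite thresholds (±30 on the logistic scale),
which keeps the row-level derivative algebra uniform. Predictors are
standardized internally; thresholds, coefficients, and their covariance
(inverse observed information) are transformed back to the original
scale. Aggregated data are supported through nonnegative case weights,
which is what makes the Monte Carlo refits cheap (510 stimuli × 5
rating levels instead of ~10⁴ trials). Convergence failures (e.g.
separation) raise rather than returning silently.

Mixed models add crossed random intercepts (and optional slopes) with
independent variances per term. For candidate variance parameters σ the
joint penalized likelihood is maximized over (θ, β, u) by the same
sparse Newton solver, and the Laplace marginal likelihood

ℓ(σ) = ℓ_pen(v̂) − ½ log det D − ½ log det(−H_uu + D⁻¹)

is optimized over log σ by Nelder-Mead (warm-starting the inner solver).
Profiling the fixed effects at the joint mode rather than maximizing the
Laplace objective over them directly is an approximation (the
log-determinant's dependence on β is ignored); it is exact in the σ → 0
limit, where the fit provably collapses onto the fixed-effects solution
— the test suite checks this to 10⁻³ — and coefficient recovery under
the generator's ground truth is the end-to-end check of its accuracy.
Variances are bounded in [10⁻⁴, 25]; an estimate at the lower bound is
flagged `singular`. AIC counts thresholds, coefficients, and variance
parameters. Standard errors for fixed effects come from the
corresponding block of the inverse penalized Hessian.

Marginal contrasts are linear functions of the coefficients: the effect
of a factor with interacting terms set either to specified levels or to
their observed design-column means (the reference grid), with
delta-method standard errors — exact here, since the contrast is linear.
Bootstrap intervals are percentile intervals of the mean over seeded
resamples. Backward elimination (`select_model`) removes interaction
terms that are neither individually significant (Wald, α = 0.05) nor
supported by a likelihood-ratio test, one at a time.

## Monte Carlo proto-lexicon inference

For each inventory size in the grid, R sub-inventories are drawn either
uniformly or frequency-weighted. Weighted sampling is *without*
replacement via exponential sort keys (Exp(1)/wᵢ, keep the k smallest),
which is distributionally identical to successive draws proportional to
the remaining items' weights — verified in the test suite against an
explicit sequential oracle; a with-replacement flag exists. Each sample
retrains the trigram model over the *full* alphabet (so stimuli always
score via backoff), rescores all stimuli (parsed or unparsed for morph
units), and refits the weighted fixed-effects rating model
(`rating ~ score + accent` by default; configurable). Per-replicate
seeds derive from the config seed via `SeedSequence` spawn keys, so runs
are bitwise reproducible and replicates are independent of grid order.
Failed fits are recorded and excluded from means, never silently
dropped. Summaries report mean AIC, 95% bootstrap percentile intervals,
and ΔAIC against the full-inventory baseline. A representative
(population-averaged) scoring system — the per-stimulus mean of a size's
sampled scores — feeds a single mixed-effects fit per size.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume,
at reduced scale:

* **Lexicon.** Stems of 2–3 syllables from CV/CVC/V/VC templates over a
  restricted alphabet (onsets b d f l m n p s t, vowels a e i o u, codas
  n s) chosen so each grapheme maps to exactly one phoneme and no
  digraphs can arise — morph boundaries in orthography then correspond
  exactly to phoneme-space boundaries, and ground-truth segmentations
  are emitted with the lexicon. Words are bare stems, stem+suffix
  (probability 0.6, from a 12-suffix paradigm), or stem+stem compounds
  (default rate 0.02 — suffix-heavy, compound-poor; the compounding rate
  is raised to 0.3 for the concatenative-lexicon study so that morphs
  recur across words). Type frequencies are Zipf: rank-1 at 20,000 per
  million with exponent 1 by default. Rank is assigned by morphological
  complexity plus standard normal noise (weight 3.0): frequent words
  tend to be bare stems, rare words inflected or compound forms. This
  coupling is essential — it is what makes the scoring system of a
  frequency-weighted sub-lexicon systematically different from that of
  the full lexicon, the signal the size-recovery analysis detects.
* **Participants.** Items A–F load (weight 1.3, noise 0.9) on three
  independent latent traits (Spanish value, nationalism, exposure) and
  are cut to 1–5; composites are sums by default (polarity is
  configuration), and centered copies are provided for interaction
  terms.
* **Ratings.** η = x′β + u_participant + v_item (+ optional by-item
  slopes on participant covariates), cut at fixed thresholds through
  the cumulative logistic. Default β: score 2.178, accent 0.884;
  thresholds (−4.6, −3.4, −2.0, −0.6), placed so that ratings center
  mid-scale given the score range the generator produces; σ_participant
  0.5, σ_item 0.3.

What passing the simulation studies shows: the pipeline recovers known
generating structure — coefficients within 2 SE in ≥ 90% of replicates;
the mean-AIC minimum of the word-based Monte Carlo at the true
sub-lexicon size (within one grid step); frequency-weighted sampling
dominating unweighted when the truth is frequency-weighted; parsed
scoring dominating unparsed when ratings are generated from parsed
scores. What it does not show: anything about real rating data —
real lexicons have richer phonotactics, allomorphy breaks the clean
concatenative structure the generator uses, and human raters are not a
proportional-odds model with logistic noise.

### Problem sizes

The studies run at reduced scale, chosen once as part of the study
design: size recovery uses a 10,000-type lexicon with a 2,000-word
frequency-weighted truth, grid {500, 1000, 2000, 4000, 8000}, 100
replicates per (scheme, size), 255 matched nonword stimuli, and 40
participants × 240 trials; coefficient recovery uses 50 replicates of
40 × 240; the morph study uses a 4,000-type concatenative lexicon
(learned inventory ≈ 650 morphs), matched sizes {150, 300, 600}, and
100 replicates per mode. For the size-recovery study the lexicon's Zipf
exponent is raised to 2.0 and the complexity bias to 4.0: a 10,000-type
lexicon holds an order of magnitude fewer types than a realistic
frequency database, and without re-concentrating the frequency mass a
frequency-weighted draw of the true size is far less determined at
reduced scale than at full scale, washing out the size signal that the
analysis is designed to detect.

## Known limitations

* The Laplace-with-profiled-fixed-effects mixed fit mildly shrinks
  variance estimates relative to a full Laplace or quadrature fit;
  fixed-effect coverage is validated by simulation, variance components
  should be read as approximate.
* The MDL learner is greedy; it finds a good segmentation, not the
  global optimum, and differently seeded runs can differ in rarely-used
  morphs.
* The rewrite-rule table is a documented simplification of Spanish
  spelling-to-sound conventions, not a full TTS rule set.
* Polychoric correlation uses the two-step estimator (thresholds from
  margins), not full joint maximum likelihood; the difference is
  negligible at questionnaire sample sizes.
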