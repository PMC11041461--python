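# Methods

This note documents the models in `eupkit`, the choices made where the
design was genuinely open, the synthetic worlds the package is validated
on, and what those validations do and do not establish.

## 1. Linguistic uncertainty scorer

The scorer is a corpus-trained probabilistic n-gram model.  On a
hedge-annotated corpus (sentence-level `uncertain` flag, token-level cue
flags), every n-gram key *w* accumulates three counts:

* *F_s* — occurrences anywhere in the corpus;
* *F_u* — occurrences inside sentences flagged uncertain;
* *F_m* — occurrences **as a marker**: an n-gram counts toward *F_m* only
  when every token in the window carries a cue flag.

By construction *F_m ≤ F_u ≤ F_s* per key.  The marker probability is
*p(c|w) = F_m/F_s*; unseen keys score 0 rather than raising, because the
scorer must run on open-vocabulary post text.

**Confidence weighting.**  Raw conditional probabilities are unstable for
rare keys, so each contribution is weighted by
*conf(w) = 1 − (1 − λ)^{F_s}* with λ = 0.1 by default: zero at *F_s* = 0,
strictly increasing in *F_s*, bounded below 1.  It can be read as the
probability of having seen at least one informative occurrence when each
occurrence is informative with probability λ.  λ is a configuration field
(`confidence_lambda`), not a fitted quantity.

**Features and pooling.**  A scoring feature is a quadruplet *(type ∈
{lemma, token}, size ∈ {1,2,3}, context ∈ {uncertainty-marker,
uncertain-sentence}, aggregation ∈ {sum, mean, max})*.  The context selects
the probability (*F_m/F_s* vs *F_u/F_s*); the aggregation combines the
per-n-gram *p·conf* contributions over the sentence.  The default set is
the eight quadruplets {lemma, token} × {1, 2} × both contexts, with sum
aggregation for unigrams and max for bigrams — sum makes unigram scores
grow with the amount of hedging, max makes the sparse bigram features
robust to length.  The sentence score is the mean of the per-feature
scores after min-max normalization with bounds fitted **on the training
corpus only**, clipped to [0, 1] at apply time.  Min-max scaling was chosen
over standardization because it yields a bounded score with an
interpretable 0 (no evidence of hedging) without assuming any score
distribution.

**Text processing.**  Tokenization is Unicode word boundaries; the default
lemmatizer is identity lowercasing, so the reference pipeline is
dictionary-free and exactly reproducible.  A real lemmatizer can be plugged
in via the `lemmatizer` argument.

## 2. Text embeddings

The reference encoder is a signed feature-hashing bag of lemmas
(salted 64-bit blake2b → coordinate and sign), L2-normalized, dimension
d = 256 by default; empty text maps to the zero vector and cosine against a
zero vector is defined as 0.  The hash is keyed by an explicit seed and is
stable across processes and platforms.  Pretrained sentence encoders plug
in through the same `TextEncoder` / `BaselineAdapter` protocols but are
deliberately outside the test path: the hashing encoder makes every
experiment deterministic and download-free.  The reference baseline
adapter (for the fused model) is a one-hidden-layer bag-of-embeddings
classifier whose hidden activations serve as the baseline feature **o**
(d_o = 64 by default).

## 3. Environments and channel representations

For a post at time *t_p*:

* **macro window** M: all news with 0 ≤ t_p − t_e ≤ T·86400 s (closed
  interval, seconds arithmetic; day identity elsewhere is the UTC calendar
  date).  T is in days, default 3.
* **micro window** C: the same time filter over tweets gives C′, then the
  k = max(⌈r·|C′|⌉, min(c_min, |C′|)) most cosine-similar tweets are kept
  (defaults r = 0.1, c_min = 10).  The ceiling guarantees k ≥ 1 whenever
  C′ is non-empty; the floor c_min is capped by |C′|.  Ties on equal
  similarity break deterministically: later timestamp first, then
  lexicographic document id.

Each environment yields two d-vectors: the similarity representation
S = meanᵢ sᵢ·(p ⊙ eᵢ) and the uncertainty representation
U = meanᵢ uᵢ·eᵢ, where sᵢ is the cosine to the post, uᵢ the scorer's
uncertainty of the item text, and ⊙ the Hadamard product.  Averaging
(rather than summing) makes the representations invariant to environment
size, which varies with T and r; empty environments give zero vectors, and
every downstream quantity stays finite.

The four channels are projected to a common hidden dimension h (affine
projectors trained end-to-end with the classifier):

* I_M = W_M(S_M ⊕ U_M) + b_M, and likewise I_C;
* I_F = W_F(u_p·p) + b_F with u_p the post's own uncertainty score;
* I_P = W_P((f·I_M) ⊕ (f·I_C) ⊕ (f·I_F)) + b_P, where f is the day's
  physical factor.

The physical factor of day *i* is
f_i = Norm(ln(1 + |ΔN_cases|) · ln(1 + |ΔN_news|)) over day-over-day
changes in new-case counts and news volume; the first day of a series has
no factor.  Natural logarithms are used; normalization is min-max with
bounds fitted on the **training fold's dates** and clipped to [0, 1], so no
test-fold information leaks into the scaling.  Scaling by *f* is applied to
the already-projected channels (all dimension h), and a 3h → h projector
brings I_P back to the common dimension required by the gated sum.

## 4. Classifiers and training

`EUPClassifier` concatenates (I_M, I_C, I_F, I_P) in that fixed order and
applies one tanh hidden layer of width h followed by a 2-unit softmax.
`GatedFusionClassifier` additionally takes a baseline feature **o**; each
channel is scaled elementwise by a gate g_X = σ(Linear(**o** ⊕ I_X)) —
every gate coordinate strictly in (0, 1) — and the fused vector
I = Σ g_X ⊙ I_X is concatenated with **o** before the same head shape.
With all gate biases driven to +∞ the fusion reduces exactly to the plain
channel sum; at −∞ it vanishes — a property used as a correctness check.

Training minimizes mean cross-entropy with minibatch Adam
(lr 5·10⁻⁴, batch 32, up to 150 epochs) and early stopping on validation
macro-F1 with patience 15; the best-epoch weights are restored.  All
randomness (initialization, shuffling) flows from one integer seed, and the
forward/backward passes are plain single-threaded numpy, so runs are
bit-reproducible.  Single-class training labels are an error.

**Channel ablation** zeroes the projected channel vector everywhere it is
used — including inside I_P's input — rather than shrinking the
architecture, so parameter counts are identical across ablations and
"without channel X" means "channel X carries no information", not "a
smaller model".

**Data splits.**  The pipeline splits by *contiguous 7-day blocks* of
calendar days (train/validation/test ≈ 60/20/20, block-to-fold assignment
stratified by block label rate).  Post-level splits are available
(`split_indices`) but are not used by the pipeline: when labels are coupled
to the day's environment, a post-level (or even day-level) split lets a
classifier memorize or temporally interpolate per-day label rates through
any day-identifying feature, inflating scores and destroying the
attribution of signal to channels.  Temporal blocking is the standard guard
against this leakage.

## 5. Synthetic worlds

The generator produces everything the pipeline consumes — hedge corpus,
case/news timeline, news and tweet streams, labeled posts — from one seed.

* **Hedge corpus.**  5,000 sentences; per-sentence hedge rates are
  Beta-distributed (mean 0.15) so the corpus spans plainly factual through
  heavily hedged sentences, and sentence length ~ 3 + Poisson(17) keeps the
  feature-normalization bounds wide enough that long, heavily hedged posts
  do not saturate the score.  Each hedge lemma *w* has a marker propensity
  π_w ∈ (0.55, 0.95): the probability that an occurrence is annotated as a
  cue.  Because *F_m/F_s* estimates exactly π_w, scorer recovery can be
  checked against ground truth.
* **Timeline.**  90 days: exponential rise (20 d) to a plateau (20 d) and
  decay, Poisson-noised, with a weekend reporting dip (Sat/Sun multipliers
  0.45/0.40) as in real case curves; news volume follows the curve.  The
  day-level physical factor is computed from the generated series with the
  same log-product formula the pipeline uses.
* **Streams.**  News (40/day) and tweets (80/day) mix topic words (a
  global pool of 10 topics — deliberately *not* day-keyed, so no content
  feature identifies the calendar day) with hedge lemmas; the
  hedge-insertion rate is 0.01 + 0.14 · (day latent).  Under the default
  `shared` coupling both streams' latents are the physical factor itself,
  so the generative coupling targets exactly the quantity the pipeline
  extracts.  Under `independent` coupling each stream gets its own latent
  series.
* **Posts.**  4,000 posts (~30 tokens) with idiosyncratic framing
  uncertainty u ~ Beta(0.3, 0.3) (bimodal: posts tend to be either
  confidently phrased or heavily hedged) driving their hedge rate.  Labels
  are Bernoulli draws from a logistic model over the generator's latent
  channel intensities — the post's u, the mean stream latents over the
  post's exact trailing seconds window (computed from the generated
  document timestamps), and the day's factor — with slope 3 per channel by
  default and an auto-centred intercept (≈50 % base rate).  Spread labels
  use an identical, separately drawn model; retweet counts are 0 for low
  and 1 + Poisson(2) for high, so the label/count invariant holds.  The
  returned ground-truth table reproduces every label probability exactly.

**Single-signal worlds** (`single_signal_world(channel, strength)`) zero
every slope except one and are the fixture for ablation attribution.  They
additionally use an *orthogonal design*: iid, sharpness-3 (bimodal) day
latents per stream, residualized against each other and the physical
factor in the trailing-window-mean domain.  Two independent latent
processes over ~90 days can show realized correlations large enough for one
channel to substitute for another; orthogonalizing the realized drivers —
not just their distributions — is what makes "exactly one informative
channel" true in the sample the classifier sees, and the labels couple to
the window-mean latent (window = 3 days, matching the default T) so the
informative channel's measured quantity is the label's driver.

**What the generator does not emulate.**  Language is a token soup over a
synthetic vocabulary: no syntax, no topic drift, no multilingual text, no
sarcasm or negated hedges ("definitely not uncertain").  There is no
user/network structure, no retweet cascades, and stream volumes are
homogeneous Poisson within a day.  Passing the end-to-end checks therefore
shows that the pipeline recovers the couplings it is designed to measure
when they are present — not that those couplings have the same strength, or
that the scorer's lexical model is adequate, in real social-media data.

## 6. Numerical and degenerate-case conventions

* Unseen n-grams contribute 0; a feature whose training bounds collapse
  (max = min) maps to 0.
* Cosine with any zero vector is 0; empty environments give zero
  representation vectors.
* A flat timeline (or a training fold with a constant raw factor)
  normalizes to f ≡ 0.
* Softmax is computed with max-subtraction; cross-entropy clips
  probabilities at 1e−12.
* Gate logits use a numerically stable split sigmoid; biases of ±50
  saturate to machine precision.
* ROC ties are collapsed into single threshold steps (the standard
  empirical-ROC convention); the partial area up to FPR = q interpolates
  linearly at the cut, and the standardized partial AUC is
  ½·(1 + (pAUC − q²/2)/(q − q²/2)), so chance = 0.5 and perfection = 1
  for any q.  Ratio subsampling keeps every majority item and
  `round(n_majority/ratio)` minority items, capping at the available
  minority only when the shortfall is within rounding.
* Derived seeds are reduced modulo 2³¹ − 1.

## 7. Problem sizes used in validation

The test suite and the acceptance script run at the generator defaults
(4,000 posts over 90 days, ~3,600 news and ~7,200 tweets, 5,000-sentence
corpus) for the end-to-end checks, with training-seed averaging (3 seeds)
for any quantity subject to optimization noise; unit and property tests run
on miniature worlds (hundreds of posts) and hand-built fixtures.  These
sizes keep a full validation cycle in the tens of minutes on one CPU while
leaving the end-to-end accuracies several points above the thresholds they
are checked against.

## 8. Known limitations

* The exact closed forms of the confidence weight, the per-feature
  combination, and the two environment representations are this package's
  own renderings of a framework whose published description leaves them
  under-specified; they are isolated behind the `uncertainty_model` and
  `eup_features` interfaces so alternatives can be swapped in.
* The hashing encoder ignores word order and semantics; cosine similarity
  between hashed bags is a lexical-overlap proxy.  With a real sentence
  encoder the similarity structure — and the micro-environment selection —
  would change.
* Min-max normalization of the physical factor is sensitive to single
  extreme training days (a robust quantile scaling would be less so but
  departs from the stated formula).
* The gated-fusion model is validated for mechanics (gradients, gate
  saturation, determinism) and smoke-tested end-to-end, but the synthetic
  worlds contain no baseline signal beyond the channels themselves, so no
  claim is made about fusion gains over strong baselines.
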