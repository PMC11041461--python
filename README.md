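# eupkit

Environmental-uncertainty features for misinformation detection and spread
prediction on social media.

During a health crisis, misinformation does not appear in a vacuum: it
emerges from an *information environment* — the day's epidemic dynamics, the
news cycle, the ambient social-media conversation — and that environment's
level of **uncertainty** is itself a predictive signal.  `eupkit` implements
an environmental-uncertainty-perception pipeline that represents a post's
environment at four scales and feeds them to a classifier, for two binary
tasks:

* **detection** — is the post real (0) or fake (1)?
* **spread prediction** — will the post be retweeted at all
  (low = 0 retweets, high = ≥ 1)?

It is aimed at researchers in infodemiology / computational social science
who want a download-free, fully reproducible testbed for these
environment-level features: every experiment in this package runs on seeded
synthetic worlds with known generative couplings, so recovery and ablation
claims can be checked against ground truth.

## The model

**Linguistic uncertainty scorer.**  From a hedge-annotated corpus, each
n-gram *w* gets three counts: occurrences in the corpus (*F_s*), in
uncertain sentences (*F_u*), and as an uncertainty marker (*F_m*).  The
marker probability is *p(c|w) = F_m / F_s*, discounted by a confidence
weight *conf(w) = 1 − (1 − λ)^{F_s}* so that rare n-grams carry little
weight.  A scoring feature is a quadruplet *(type, size, context,
aggregation)*; each feature aggregates *p·conf* over a sentence's n-grams,
and the sentence score *F(s) ∈ [0, 1]* is the mean of the min-max-normalized
feature scores (bounds fitted on the training corpus).

**Four environment representations.**  For a post with embedding **p**
(feature-hashed bag of lemmas, L2-normalized, by default):

| channel | construction |
| --- | --- |
| macro-media *I_M* | all news **e** with 0 ≤ t_p − t_e ≤ T days; S_M = mean_i S(p,e_i)·(p ⊙ e_i), U_M = mean_i F(e_i)·e_i; I_M = MLP(S_M ⊕ U_M) |
| micro-communicative *I_C* | tweets in the same window, keep the k = max(⌈r·|C′|⌉, min(c_min, |C′|)) most cosine-similar; S_C, U_C, I_C as above |
| message framing *I_F* | I_F = MLP(F(p)·**p**) — the post's own hedging |
| physical *I_P* | daily factor f = Norm(ln(1+\|ΔN_cases\|)·ln(1+\|ΔN_news\|)); I_P = MLP((f·I_M) ⊕ (f·I_C) ⊕ (f·I_F)) |

**Classifiers** (model/results idiom, `fit()` returns a results object):

* `EUPClassifier` — softmax head on I_M ⊕ I_C ⊕ I_F ⊕ I_P (the standalone
  model);
* `GatedFusionClassifier` — wraps any baseline's penultimate feature **o**:
  each channel is scaled by a gate g_X = σ(Linear(**o** ⊕ I_X)) and the sum
  I = Σ g_X ⊙ I_X is concatenated with **o** before the head.

Both minimize cross-entropy (minibatch Adam, early stopping on validation
macro-F1).  Defaults: T = 3 days, r = 0.1, c_min = 10, d = 256, h = 32.

## Worked example

```python
from eupkit import RunConfig, WorldConfig, generate_world, prepare, train_eval

world = generate_world(WorldConfig(seed=1, n_posts=1000, n_days=60,
                                   news_per_day=20, tweets_per_day=40,
                                   n_hedge_sentences=2000))
prepared = prepare(world, RunConfig())       # scorer + features for every post
out = train_eval(prepared, task="detect", seed=0)
print(out.results.summary())
for key, value in out.metrics.items():
    print(f"{key:12s} {value:.3f}")
```

prints

```
EUP classifier results
========================================
observations (train):   593
hidden dimension h:     32
embedding dimension d:  256
parameters:             48354
seed:                   2
epochs run:             37
best epoch:             20
channels dropped:       none
best val macro-F1:      0.7568
final train loss:       0.2263

accuracy     0.833
macro_f1     0.833
f1_class1    0.823
f1_class0    0.843
sp_auc       0.854
```

The world couples each post's fake probability to its own hedging, the
uncertainty of its news and tweet environment, and the day's physical
factor (logistic model, slope 3 per channel).  `train_eval` splits posts
into temporally blocked train/validation/test folds, trains the standalone
classifier and reports held-out accuracy, per-class and macro F1, and the
standardized partial AUC at FPR ≤ 0.1 (0.5 = chance, 1.0 = perfect).
Labels here are `0 = real / 1 = fake`, so `f1_class1` is F1 on the fake
class.  Channel ablations (`drop_channels=("framing",)`), the gated-fusion
mode (`mode="fused"`), window sweeps (`eupkit.sweep`) and imbalanced
evaluation (`eupkit.imbalance_harness`) hang off the same two calls, and
the `eup` command line exposes the whole flow (`eup simulate`, `eup
train-uncertainty`, `eup train`, `eup evaluate`, `eup ablate`, `eup
sweep`), with reusable single-file JSON model checkpoints
(`eup train --checkpoint model.json`, then
`eup predict --checkpoint model.json`).

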