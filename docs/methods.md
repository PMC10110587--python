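# Methods

## The problem and the estimator

A polygraph screening couples ten physiological channels (31 Hz) with a
table of question events; each repetition of a question carries three
timestamps (question start, question end, answer).  An examiner issues a
per-topic DI/NDI conclusion.  `polyverify` treats examiner-conclusion
prediction as a supervised binary classification problem at the
(screening, test, topic) level and uses the resulting out-of-fold (OOF)
probability of DI as a *second opinion*: NDI conclusions with the
highest model scores are flagged for human QA.  Crucially, the goal is
not a perfect mimic of the examiner — the flagging step exists precisely
because the labels contain a small fraction of examiner errors the model
is not expected to learn.

### Feature construction

Analysis windows are half-open, `[t_question_start, t_answer + post)`
with `post = 5 s` by default: stimulus-locked electrodermal and
cardiovascular responses peak seconds after the answer, so a window
ending at the answer would truncate them.  Sample indexing rounds
`time × rate` at both ends, so window length is `round(rate × duration)`
within one sample.

Per window: min, max, mean, population standard deviation (population,
so single-sample windows give 0 rather than NaN), amplitude = max − min.
Per question, across repetition-ordered values: min, max, mean, and
`diff = first − mean(subsequent)`, defined as 0 for a single repetition;
`diff` captures habituation — a response that shrinks over repetitions —
which plain order statistics miss.  Per (test, topic), across questions:
min, max, mean.  The factorization 10 × 5 × 4 × 3 = 600 names the
features `CHANNEL_basestat_repagg_qagg`.  The standard deviation is
deliberately *not* used as an aggregator (only as a base statistic):
with it the count would not be 600, and no aggregator-position std
appears in the observed feature-name grammar.  Only relevant questions
feed the tree (they carry topics); an optional comparison-centering step
subtracts the test's mean comparison-question statistics per (channel,
statistic) before aggregation, off by default to keep the canonical
semantics.

### Stacking ensemble

Folds are assigned at screening level: screenings are shuffled with the
configured seed, stably sorted by their any-topic DI label and dealt
round-robin over K = 5 folds.  This greedy stratifier balances fold
sizes to within one screening and DI shares to within one screening per
fold; exact stratified-group assignment is NP-hard and unnecessary at
these sizes.  The group key is the screening id — one examinee per
screening in the synthetic cohorts; with repeat examinees the same
mechanism would group by examinee id.

Level 1 is a LightGBM classifier on the 600 features (balanced class
weights — DI prevalence is < 7 % in the emulated archive).  Each fold's
model scores the rows of its held-out fold, giving every test row
exactly one OOF score.  Level 2 reduces the per-test OOF scores of each
(screening, topic) to `pred_proba_min/max/mean` and
`pred_proba_diff = max − mean`, joins the whitelisted covariates, and
fits a second LightGBM per fold on the meta-rows of the other folds.
The second-level model for fold *f* therefore never sees fold-*f*
screenings, and the meta-features of any screening come from a
first-level model that never saw that screening: the OOF guarantee
holds end to end.  Categorical covariates (sex, job fields, examiner
id, weather condition) are declared as pandas categories with frozen
levels and an explicit unseen bucket; the random-forest variant, which
lacks native categorical support, one-hot encodes the same frozen
levels.

Variants: *basic* is topic-blind (the topic code is withheld from both
levels; an opt-in `topic_as_feature` adds it to level 2).  *one-topic*
filters the training rows of both levels to a single topic but scores
any topic.  *random_forest* is the basic architecture with
`RandomForestClassifier(max_depth=5, class_weight="balanced")` at both
levels.  The *universal* ensemble averages the confidences of basic-
with-covariates, one-topic-with-covariates (anchored by default on the
drug-abuse topic, the topic with the most minority labels in the
emulated archive), and the basic random forest, all sharing one fold
assignment so the average remains OOF.  Unseen screenings are scored by
all K fold chains and the outputs averaged; screenings present in
training are always answered with their stored OOF score (leak guard).

Hyperparameters: balanced class weights everywhere and the depth-5
random forest are the modelling choices; remaining learner settings are
library defaults except speed/determinism knobs pinned in
`TrainConfig` (LightGBM `max_bin=63`, `feature_fraction=0.5`,
`deterministic=true`, single-threaded), chosen so a full cohort fits in
seconds without measurably changing OOF AUC.

### Operating point and metric battery

The deployment constraint is a false-positive budget: flagged
conclusions cost examiner hours.  `operating_point` returns the
smallest threshold whose realized FPR is ≤ `max_fpr` (default 0.05); a
threshold above every score always qualifies, so the function is total.
The per-topic report chooses the threshold independently on every
(topic, fold) slice — and per pooled fold for the "all topics" row — so
the realized FPR obeys the budget slice by slice; the battery (ROC AUC,
Recall, Precision, F1, Accuracy, TNR, FPR) is reported as mean (std)
over folds with per-topic DI counts.  AUC is the rank statistic with
ties counted ½.  Zero-denominator conventions (no predicted positives →
Precision 0; no negatives → FPR 0) log a warning instead of raising.

### Flagging and recovery

Only NDI conclusions are eligible — erroneous DI labels are too scarce
to validate, and the tool's purpose is missed deception.  Selection
rules: per-topic top-k (the field workflow's fixed QA budget per topic),
a score threshold, or a global top fraction.  Ties break by score
descending then screening id ascending.  Flags always use OOF scores,
never refit scores.  `recovery_report` evaluates flags against injected
errors: precision@k and enrichment = precision / base error rate among
eligible NDI conclusions (enrichment 1 ⇒ no better than random
auditing; both defined as 0 when no errors exist).

## The synthetic cohort generator

The generator emulates the structure of a field screening archive, not
its physiology; units are arbitrary.  Per channel:

    x(t) = baseline + slow sinusoidal drift + periodic component
           + AR(1) noise + Σ_events A_event · kernel(t − t_start)

The kernel is a gamma-shaped rise–decay (shape 2, scale 1.2 s) starting
0.5 s after question onset with an 8 s support, peak-normalized.  Event
amplitude is `gain_ch · R_subject,ch · jitter_event · (1 + δ)`, where
the `(1 + δ)` factor applies only to relevant questions of truly
deceptive (subject, topic) pairs.  Reactivity
`R = exp(0.30·z_shared + 0.30·z_channel)` and event jitter
`exp(0.25·z)` make between-subject amplitude variation — not sample
noise — the binding constraint on separability, which is what makes the
classification problem non-trivial.  Channel gains are signed (EDA and
heart rate rise, blood volume and respiration amplitude fall).  AR(1)
noise uses coefficient 0.95 with the *stationary* SD fixed per channel.
These values were fixed once against the package's design targets — a
strong effect (δ = 2) must be recoverable at OOF AUC ≥ 0.9, a null
effect (δ = 0) and stimulus-detached windows must sit at chance, and
flagging at δ = 1.5 must strongly enrich for injected errors — and are
not tuned per experiment.

Deception is drawn per (subject, topic) at the configured prevalence
(default 0.06, matching the minority-class share of the emulated
archive) and is constant across tests; an optional per-test dropout
emulates subjects who do not express deception in every test.  Examiner
labels equal the truth and are then corrupted at rate ε, either
symmetrically or in `ndi_only` mode (true-DI → NDI flips only, the
validated error class).  Covariates: age uniform 22–60, sex balanced,
job fields from small pools, one city, date-keyed seasonal weather
shared by same-day screenings, a skewed 0–9 geomagnetic index, and a
small examiner pool.  Covariates carry no signal; they exercise the
alternative-data plumbing and ablations, not covariate effects.

What passing tests on this generator do **not** show: that the feature
set or ensemble separates deception in real recordings, where responses
are non-stationary, artifact-laden, counter-measure-prone, and where
label noise is structured rather than independent.  The synthetic
results validate the machinery — leak-free OOF scoring, the 600-feature
contract, operating-point behavior, and the flagging workflow's ability
to surface label errors when the signal exists.

## Problem sizes and numerical choices

The shipped tests and `scripts/acceptance.py` use cohorts of 300
screenings (prevalence 0.2) for the effect-size sweep and permutation
null, and 500 screenings (prevalence 0.06, ε = 0.05, δ = 1.5) for
error-recovery runs — large enough for stable OOF AUCs and non-empty
error sets, small enough for desk-scale runtimes.  The acceptance
script averages enrichment over 3 seeds; the test suite uses 10.
Determinism: every stochastic component takes an explicit seed;
cohort generation spawns per-screening child seeds from one root
`SeedSequence`, and LightGBM runs single-threaded deterministic, so
identical configs reproduce artifacts byte for byte.  Degenerate
inputs are defined, not rejected: single-repetition `diff` is 0,
single-sample windows have std 0, zero-denominator metrics return 0
with a warning, and an all-identical score vector yields a threshold
above all scores (FPR = TPR = 0).

## Known limitations

* The NCCA-ASCII-style dialect is self-contained and documented but is
  not a bit-level implementation of any vendor's format; real archives
  would need a reader shim.
* Three of the ten canonical channel names are plausible completions of
  the observed seven; the channel set is configuration-driven.
* Probabilities are not calibrated; scores order conclusions but are
  not error rates.
* The one-topic member of the universal ensemble uses a single anchor
  topic; per-topic one-topic members are possible but not built.
* Weather joins screenings by date within a single city; multi-city
  confounding (city-unbalanced label prevalence) is not modeled.
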