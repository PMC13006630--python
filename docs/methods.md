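# Methods

`fedgait` simulates an edge-device federated learning (FL) system that
predicts Parkinson's disease motor severity — the MDS-UPDRS Part III
score, an integer on 0–132 — from daily real-world gait measures, and
contrasts it with a conventional centralized neural network. Because the
underlying clinical dataset is access-restricted, the package ships a
synthetic cohort generator that reproduces the statistical structure the
analysis depends on; every experiment, test and diagnostic in the
package runs on such cohorts.

## The prediction model

A fully connected network maps a 91-dimensional input (88 daily gait
measures plus age, sex and BMI) to a single sigmoid output, the severity
score scaled to [0, 1] by the instrument's theoretical range (÷132):

    input(91) → GaussianNoise(σ = 0.6)
              → Dense(272, ReLU) → Dropout(0.5)
              → Dense(152, ReLU) → Dropout(0.5)
              → Dense(70,  ReLU) → Dropout(0.5)
              → Dense(1, sigmoid)

for exactly 77,301 trainable parameters with 91 inputs. The published
architecture figure does not legibly give the hidden widths; (272, 152,
70) is the descending-width choice satisfying the published parameter
count, which is the only printed architectural checksum. Kernels are
Glorot-uniform with zero biases (the common framework default; small
initial pre-activations keep the sigmoid away from saturation, which
matters for the stability of repeated short local fits).

Training is Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) on mean squared
error, optionally per-sample weighted, batch size 32, with early
stopping: the monitored set's MAE is evaluated with stochastic layers
disabled after every epoch and at epoch 0, training stops after
`patience` (20) epochs without improvement or at `max_epochs` (150), and
the best monitored epoch's weights are returned. Including epoch 0 among
rollback candidates means training can never worsen the monitored MAE.
Input noise and dropout are active only during weight updates, so
prediction is a pure function of (weights, inputs). Training arithmetic
is single precision (the loop is matmul-bound and float32 gradients are
ample); weights are exchanged and aggregated in double precision.

## Centralized baseline

Participant-wise 10-fold cross-validation: per fold, 10% of participants
are test, a further 10% validation (the early-stopping monitor), 80%
training. Splitting is by participant, so no person's days ever cross
roles. Missing values are imputed with the fit population's per-feature
median and features standardized to its mean/SD (zero-variance features
keep scale 1 and are centered only); preprocessing statistics are fitted
on training participants only. Test predictions are inverse-scaled to
0–132 and pooled over folds for the headline metrics; per-fold MAEs are
reported alongside. Pooling (rather than averaging fold metrics) is a
deliberate choice; both views are available.

## Federated simulation

Each client holds one participant's data — the extreme non-IID setting —
keeps a random 20% of its days as a local holdout, and fits its own
preprocessing statistics on its local training days (so a client-constant
input such as sex standardizes to a constant 0, and a feature with no
observed value locally enters the same way; no external statistics may
cross the client boundary). Per round:

1. every client trains the received global weights on its local training
   data (learning rate 1e-3, early stopping monitored on the local
   *training* MAE — a one-participant client has no validation cohort);
2. the server aggregates the returned weights with FedAvg — the
   per-parameter mean weighted by client sample counts;
3. each client fine-tunes a copy of the new global model at learning
   rate 1e-4 (*personalisation*) and reports its holdout MAE; these
   personalised weights are discarded and never aggregated;
4. the global model is evaluated on the fold's withheld test
   participants, whose imputation and standardization statistics come
   from the withheld cohort itself (the privacy-preserving choice, at
   the cost of a little test-side information reuse).

After the last round the global weights roll back to the round with the
lowest global test MAE. This follows the published protocol and is
test-set selection; it is reproduced deliberately, and a configuration
switch (`rollback_on="tuning"`) allows rollback on a server-held tuning
set instead. Early stopping is applied per round, and each round's local
training restarts from the freshly aggregated global weights.

Two data-sharing remedies for the global model's underfitting:

* **Server-side training** — 8% of the training participants (round to
  nearest, minimum 1) are withheld from the client pool; after every
  FedAvg the server fine-tunes the aggregate on their pooled data at
  learning rate 1e-4.
* **Client-side data** — the same withheld participants' raw samples are
  instead copied into every client's training pool once, before round 1,
  and never transmitted thereafter; during personalisation each client's
  own samples are weighted 4:1 against the shared ones. (With no shared
  samples a uniform weight only rescales the loss, so the ratio is inert
  in the other modes.)

Every artifact crossing a client boundary is recorded in a transmission
audit log; after initialisation only weight vectors and scalar MAEs
appear in it, and the client-side provisioning is the single raw-data
event, logged at round 0.

## Evaluation metrics

MAE and Pearson r (two-sided t-transform p) on the 0–132 scale, and two
agreement views treating the true scores and a model's predictions as
two raters over participant-visit targets (day-level predictions are
averaged per target first): the average-measures absolute-agreement
ICC(2,k) — the default, since "average raters' absolute" agreement is
what the evaluation calls for — and the consistency form ICC(3,k), which
some reports label for the same quantity; both are computed (via
pingouin's two-way ANOVA decomposition) and reported. Bland–Altman bias
and 95% limits of agreement (bias ± 1.96 × sample SD of the differences)
complete the report. Degenerate inputs (zero-variance truth) yield NaN
correlation/ICC entries rather than aborting.

## Shapley attributions

Feature importance is examined with Shapley values on the scaled (0–1)
model output: a feature's value for one prediction is its average
marginal contribution over feature-reveal orders, unrevealed features
drawn from a background population. Exact enumeration over all 2^p
coalitions is used for p ≤ 12; otherwise antithetic permutation sampling
(each sampled permutation paired with its reverse), seeded and with
per-attribution Monte-Carlo standard errors. Both estimators are
averages of telescoping permutation walks, so efficiency — attributions
summing to prediction minus base value — holds to numerical precision,
and a feature constant at the same value in samples and background gets
exactly zero. Mean absolute SHAP (MAS) across explained samples ranks
features.

Backgrounds follow each model's information set: a centralized model is
attributed against its training fold; a client's personalised model
against the client's local training data. A global federated model has
no accessible pooled training data (privacy), so the fold's test cohort
— which the simulation server already holds for evaluation — serves as
both explanation samples and background for every global model, keeping
rankings comparable across modes; the background is recorded in each
result's metadata.

The diagnostic at the heart of the experiment: sex is constant within
any one participant, so after client-local standardization it reaches
every local model as a constant and earns exactly zero attribution; the
global aggregate's sex weights are then essentially inherited noise, and
its sex MAS collapses relative to the centralized model. Sharing a few
participants' data with every client (client-side mode) makes sex vary
inside local training pools and restores its importance — provided the
shared participants include both sexes, which at the reduced scale's
three shared participants fails in roughly a third of random draws.

## Synthetic cohort generator

The generator emulates the study's longitudinal structure; defaults are
the study conditions where published, field-realistic choices otherwise.

* **Cohort**: 89 participants, 67.4% male, age 69 ± 9 years at the first
  used visit (month 18); visits at months 18, 36, 54, 72; wear days per
  visit `min(7, 1 + Binomial(6, 0.9))` (mean ≈ 6.4, calibrated to the
  published per-visit sample counts totalling 1,476); per-visit
  participation probabilities calibrated to the published per-visit
  participant counts (47, 64, 57, 49)/89.
* **Labels**: one score per visit, shared by all its days:
  `updrs3 = round(clip(30 + 0.35·(age − 69) + 5·male + 8·severity + ε, 0, 132))`
  with visit-level noise ε ~ N(0, 3²) and a latent severity per
  participant (intercept ~ N(0, 1), slope ~ N(0.35, 0.25²) per visit).
  These coefficients put the marginal label distribution at roughly
  10–70 with SD ≈ 10–11, matching the published score range, and give
  age and sex real predictive value, which the attribution contrast
  requires.
* **Gait features**: 88 = 22 base measures × 4 bout strata (all, short
  10–30 s, moderate 30–60 s, long > 60 s). The published taxonomy
  enumerates 21 measures; a 22nd (`medianBoutDuration`) completes the
  stated panel size. Features load on 8 latent gait domains (macro
  amount/pattern/variability; pace, rhythm, variability, asymmetry,
  postural control): per day,
  `x_f = loading_f·severity + sign_f·(u_domain + η_domain) + u_feature + ε_f`
  with domain random effect SD 1.0, shared daily domain noise SD 0.5,
  per-feature random effect SD 0.2 and noise SD 0.3, loadings ±0.15
  (pace/amount decline with severity, variability/asymmetry/rhythm
  rise). Two properties motivate this structure: real-world gait
  measures are highly reliable across days (test–retest ICC ≈ 0.8:
  between-person spread dominates daily variation), and they are
  strongly inter-correlated within domains, so the panel carries modest
  aggregate severity information — consistent with the published
  centralized performance (r ≈ 0.26, MAE at about the label-SD level)
  rather than with 88 independent severity channels.
* **Missingness**: per-visit participation as above (no participant
  loses all visits); gait cells masked at 5%; on low-activity days
  (lowest step-count quartile) long-bout measures masked at an extra
  25% (long walking bouts are rare on inactive days); BMI missing per
  visit at 10%, then carried forward from the most recent earlier visit.

What the generator does **not** emulate: raw accelerometer signals and
bout detection; within-day medication-state fluctuation; real units and
physiological ranges of gait measures (features are latent-scale);
informative dropout. Passing directional tests on these cohorts shows
the pipeline reproduces the *mechanisms* (local collapse of
client-constant features, personalisation gains, data-sharing
trade-offs) — not that the numeric results would transfer to the
clinical data.

## Problem sizes and profiles

The default experiment profile is reduced-scale: 40 participants, k = 5
cross-validation with one fold executed, 30 federated rounds, chosen as
the package's standard desk-scale configuration; the full study protocol
(89 participants, k = 10, all folds, 100 rounds) is available as
`full_scale_config()`. The early-stopping budget (150 epochs, patience
20) is identical in both profiles — it is part of the training protocol,
not the problem size. At the reduced scale the directional contrasts are
noisy: the shared cohort in the data-sharing modes is only ~3
participants, single-fold test sets hold ~8 participants, and the
client-side global model's test MAE is often still improving at round
30, so directional claims are evaluated by majority over several seeds.

## Determinism and numerical choices

A master seed derives per-stage seeds by hashing `"{seed}:{stage}"`
(SHA-256, reduced below 2³¹), so adding a stage never perturbs another's
stream. All generators are numpy `default_rng`. Identical configuration
yields byte-identical metrics JSON. Zero-variance standardization falls
back to scale 1; target scaling uses the instrument range rather than
data min–max so unseen extremes cannot escape [0, 1]; FedAvg and all
weight exchange are double precision (the aggregation oracle equivalence
holds to 1e-12) while the inner training loop is single precision.

## Known limitations

Local holdout days share visit labels with local training days, so local
personalised MAEs are optimistic (acknowledged in the study design).
Rollback on the fold-test MAE is test-set selection, reproduced
deliberately with an opt-out. The reduced scale under-trains the
client-side mode relative to the 100-round protocol. Shapley sampling
with small backgrounds and few permutations carries Monte-Carlo noise
that can perturb importance ranks of near-zero features. On synthetic
cohorts the conventional global model ends up a noisy aggregate rather
than a near-constant underfit predictor, so conventional personalisation
is weaker than on the clinical data and the *local*-performance ordering
between conventional and data-sharing modes is not stable at reduced
scale — the directional tests reflect this: the local-vs-global and
attribution-restoration contrasts reproduce robustly, the
point-estimate MAE trade-offs between federated modes only marginally.
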