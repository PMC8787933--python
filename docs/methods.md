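# Methods

## Data model

A registry is a flat table of admitted-after-ROSC OHCA patients. Every model
input is categorical with a closed vocabulary: 23 prehospital/arrest
features for the coronary-angiography (CA) decision task, those 23 plus the
CA flag for the survival task (binarized Cerebral Performance Category:
Class 0 = CPC 1/2 functional, Class 1 = CPC 3/4/5). Hospital identity and
the outcome are never model inputs. Records are split uniformly at random
(no stratification) into train / validation / test / cohort-analysis sets
with proportions 0.40 / 0.10 / 0.25 / 0.25; realized sizes follow
largest-remainder rounding, which at n = 2398 gives 959 / 240 / 600 / 599.
(Published analyses of this design report 957 / 241 / 600 / 600 for the same
nominal fractions; the discrepancy is a documented rounding/exclusion
difference, and the sizes here are configurable rather than hard-coded.)

Encodings preserve schema order everywhere: one-hot columns follow feature
order then level order (all levels kept, no reference drop), and index
encodings use the level's schema position. A stable layout is a correctness
requirement, not a convenience — embedding transfer between the two tasks is
only meaningful if row r of a feature's table denotes the same level in both
networks. Unknown levels are an error by default (`permissive=True` maps
them to the feature's first level with a warning).

## Synthetic registry generator

The generator emulates the statistical structure the analysis needs, with
everything observable retained in a latent-truth sidecar:

1. hospital ~ categorical(volume weights); 33 hospitals, of which 15
   high-volume hospitals carry ~93% of patients and clear a 75-instance
   threshold at n = 2398, while 18 low-volume hospitals (~9 patients each)
   do not — mirroring a metropolitan receiving-hospital system;
2. covariates ~ independent per-feature marginals (mildly non-uniform,
   Dirichlet-style weights). Independence keeps the Bayes-optimal AUROC
   computable and the generator auditable; a `covariate_sampler` hook
   accepts a user-supplied joint sampler when dependence matters;
3. CA ~ Bernoulli(σ(β₀ + Σ_f β_f[x_f] + u_h)), with per-hospital decision
   offsets u_h;
4. Class 1 ~ Bernoulli(σ(γ₀ + Σ_f γ_f[x_f] + τ·CA + q_h)), with
   per-hospital quality offsets q_h and a CA effect τ.

Default effect structure (units: log-odds): per-feature coefficient vectors
are centered under the marginals and scaled 1.5·exp(−rank/7) — a handful of
strong predictors and a decaying tail — giving Bayes-optimal AUROC ceilings
of ~0.90 (decision) and ~0.92 (outcome), in the range a well-specified
registry model attains. Hospital quality offsets have sd 0.7; decision
offsets are −1.3·q_h plus noise (sd 0.25), so better hospitals provide CA
more readily; τ = −1.3 (CA reduces the odds of a non-functional outcome
substantially). These scales were fixed once, chosen so the tertile
structure and the counterfactual audit are non-degenerate at study scale
(tertile CPC1/2 rates spread roughly 15–33%, double-digit flip counts);
weaker hospital effects collapse the audit to near-zero counts.

Intercepts β₀ and γ₀ are calibrated by Brent root-finding against a
Monte-Carlo estimate (n = 100,000, common random numbers) of the marginal
rates, targeting the study's marginals: 21.5% CA and 20.8% Class 0, matched
within half a percentage point at large n. The outcome marginal averages
over the CA *propensity* rather than a CA realization so the objective is
smooth and deterministic.

The sidecar stores each patient's true CA propensity and Class-1
probabilities under both CA values. `bayes_auroc` scores those true
probabilities against the realized labels — the ceiling no trained model can
beat in expectation — which turns "is the model good?" into the testable
"is the model within ε of the ceiling?".

What the generator does **not** emulate: covariate dependence, temporal
drift, missing data, hospital effects beyond additive intercept shifts, and
any real demographic distribution. Passing tests therefore demonstrate that
the pipeline recovers structure it is pointed at, not that it would achieve
comparable numbers on a real registry.

## The EFCN pair and transfer

Each feature f has an embedding table of dimension
d_f = min(16, ⌈(levels+1)/2⌉) (small vocabularies, small data). Embeddings
are concatenated in schema order into a single-channel 1-D sequence;
convolution blocks (kernel widths ≥ 1, batch normalization, ReLU), global
average pooling and a logistic head follow. The default stack is the
canonical fully convolutional classifier (128/256/128 filters, kernels
8/5/3); `EFCNArchitecture.compact()` (two 32-filter blocks) is the preset
used by the analysis scripts, the test suite, and the acceptance script —
at n ≈ 1,000–20,000 training rows the compact stack reaches the same
distance from the Bayes ceiling at a fraction of the cost, and all sizes
are configurable.

Training: binary cross-entropy, Adam (lr 1e-3), batch 64 (128 for the large
synthetic runs), early stopping with patience on a validation criterion,
best-epoch weights and batch-norm statistics restored. The criterion is
validation AUROC for model fitting (matching selection-by-AUROC elsewhere)
and optionally validation loss (`monitor="loss"`) for cohort fine-tuning,
where the downstream audit thresholds raw probabilities and calibration —
not ranking — is what adaptation mostly changes (hospital effects being
intercept shifts, within-cohort ranking is already right). Class imbalance
(~21% positive) is handled by plain cross-entropy; class weighting sits
behind a flag. Everything is deterministic given seeds under single-threaded
execution; the implementation is numpy with hand-written backpropagation,
verified against finite differences during development.

Transfer: the survival network copies every shared embedding table
bit-for-bit from the trained decision network; the CA table and all
non-embedding layers are freshly initialized. `transfer_all=True` also
copies the convolutional stack and head — supported because the
embeddings-only reading of the protocol is an interpretation, not the only
one. The decision model is deep-copied before survival training; mutation
of the stored decision weights is a tested contract violation.

## Baseline harness

Nine classical families on one-hot inputs, exhaustively grid searched and
selected by validation AUROC with first-in-grid tie-breaking. The default
grids are small, documented stand-ins (tree depth {3,5,7,∞}, estimators
{100,300}, k ∈ {5,11,21}, C ∈ {0.01,0.1,1,10}, two dense topologies);
callers supply their own grids for serious tuning. The SVM is included in
the harness even though comparison tables in this design space sometimes
omit it.

## Metrics

AUROC is computed exactly via the Mann–Whitney rank identity (ties counted
1/2), never by curve interpolation, and is tested against an all-pairs
brute-force oracle at 1e-12. AUPRC uses the step-wise precision envelope
with the leftmost envelope precision at recall 0. Threshold metrics
(accuracy, F1, MCC, confusion) classify score ≥ threshold as positive —
ties inclusive — at a default threshold of 0.5 (the analysis never states
one; it is configurable). MCC is defined as 0 when a denominator factor
vanishes; Brier is the plain mean squared probability error.

Attribution is a seeded permutation-sampling approximation to Shapley
values at the granularity of the whole categorical feature (a feature's
one-hot block or embedding toggles as a unit), with coalitions filled from
a background sample. It satisfies local accuracy up to sampling error and
is tested against exact coalition enumeration on a 3-feature model. The
variant is a declared choice; no claim is made that it matches any
particular library's estimator.

## Cohort counterfactual audit

Hospitals with at least `min_instances` (default 75) patients **over the
whole study period** qualify; their CPC1/2 rates are computed on the
combined train+validation records, and the ranked list is cut into
`n_cohorts` (3) groups of `hospitals_per_cohort` (5). Ties break by larger
volume, then lexical id. If more than n·k hospitals qualify, the top n·k by
rate are used and the remainder recorded as excluded with a reason.

Fine-tuning warm-starts both networks from the full-data weights (never
from random re-initialization) and re-optimizes on Cohort 1's train split
with early stopping on its validation split; `max_epochs=0` is the identity.
The audit then walks the *held-out cohort-analysis split only* (a tested
leakage guard): for each target-cohort patient without CA, the Cohort-1
decision model's score ≥ threshold flips the decision; flipped patients are
scored by the Cohort-1 fine-tuned survival model under CA=0 and CA=1
(the full-data survival model is available behind a flag, and every table
records which was used). Only the CA=0→CA=1 direction is audited; patients
who received CA are never counterfactually denied it. Percentages render
with half-up rounding (flip rate at 2 decimals, change rates at 1,
matching the convention of published audit tables); zero denominators
render as undefined rather than 0.

Uncertainty: percentile bootstrap, patient-level resampling within the
target cohort, 1,000 replicates by default, deterministic given the seed;
degenerate resamples are skipped and counted. The interval method is a
declared choice — analyses of this design rarely state theirs — and no
claim of equivalence to any published interval construction is made. The
audit involves no propensity adjustment or instrumental structure: it
re-scores decisions predictively, and its output should be read as a
quality-improvement signal, not a causal effect estimate.

## Orchestration and reproducibility

`run_pipeline` executes generate → split → train EFCN pair → leaderboard →
cohort assignment → Cohort-1 fine-tuning → audit, writing CSV/JSON
artifacts and a manifest (config hash, per-stage seeds and wall times,
split sizes, artifact paths). One global seed fans out through
`SeedSequence([seed, stage_index])` so each stage is independently
reproducible; re-running a config reproduces the leaderboard and audit
tables byte-for-byte on one thread. `make_report` assembles the
human-readable summary strictly from artifact files.

## Problem sizes used by the suite and acceptance script

Generator calibration checks run at n = 50,000; model-vs-ceiling checks at
20,000 train / 2,500 validation / 5,000 test with the compact architecture;
cohort-recovery checks at n = 15,000 (≥500 patients per qualifying
hospital) over 10 seeds; the study-scale pipeline at n = 2,398. These sizes
are the package's own trade-off between sampling error and run time; all
are parameters.

## Known limitations

* Hospital effects are additive intercept shifts, so cohort fine-tuning
  cannot improve within-cohort *ranking* in expectation — only
  calibration. Real inter-hospital variation plausibly includes
  feature-interaction differences the generator does not model.
* The audit's "positive change" counts depend on the survival model's
  calibration near the threshold; they are model statements, not outcome
  guarantees.
* The generator's covariate independence overstates how much signal
  flexible models can extract relative to real registries with correlated
  covariates.
* Real-registry performance numbers are out of reach by construction; the
  package validates arithmetic, protocol and recoverable structure, not
  published real-data values.
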