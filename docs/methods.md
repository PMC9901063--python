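# Methods

This note documents the model, the numerical and design choices, and the
limitations of the `regimen_rl` pipeline. Nothing here reports an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The decision process

Each patient's clinic history is modelled as a finite Markov decision
process. Visits are mapped to discrete disease states, medications to six
action classes, and the per-visit MMSE change is the reward. Consecutive
visits are treated as uniform MDP steps — calendar spacing between visits
is deliberately ignored, matching the per-visit formulation of the source
data. The discount factor defaults to γ = 0.3, so the return
`G_t = Σ_k γ^k r_{t+k}` is dominated by the next one or two visits; this
encodes the clinical prior that a prescription is mostly judged by the next
assessment.

The reward of a visit pair (i, i+1) is attributed to the action recorded at
visit i — the prescription presumed to drive the observed change. The
alternative attribution (to the later visit's action) is defensible but was
not adopted; it would shift every trajectory by one step.

## Cohort construction

Inclusion requires at least two visits and complete assessment data after
forward-filling each missing assessment from the same patient's most recent
earlier visit. "Complete history" is operationalized as *no missing
assessment cell after repair*; patients who still have gaps (in practice:
leading missingness) are dropped whole. Visits are never dropped
individually, so step rewards always telescope to the patient's total MMSE
change within a trajectory segment.

Comorbidity cohorts are overlapping by construction: a patient with both
hypertension and depression appears in both single-comorbidity cohorts and
in the dual cohort. Train/validation/test splits are drawn at the patient
level (never the visit level) with largest-remainder rounding, so the
default 60/20/20 fractions are honored to within one patient.

## State discretization

1. OLS of MMSE on the candidate assessments (age, ADAS13, RAVLT immediate
   and learning, CDRSB, MoCA, FDG); candidates that do not increase the
   design-matrix rank are dropped with a warning; predictors with
   coefficient p < `alpha_select` (default 0.05) are kept.
2. A squared-error regression tree predicts MMSE from the selected
   predictors. Growth is capped at `tree_max_depth` (default 4) and nodes
   below `2·min_leaf_count` visits are not split, with a hard leaf floor of
   `min_leaf_count // 2`. Coarse disease staging wants on the order of ten
   states; an unconstrained CART on ~10,000 visits produces well over a
   hundred leaves, which both defeats the purpose of staging and starves
   the downstream transition counts (measured directly during development:
   ~140 states without the depth cap, 13–16 with it).
3. Leaves with at least `min_leaf_count` training visits (default 50;
   sweeps use 50/100/200) receive state ids 0..S−1 in left-to-right order.
   Rarer leaves are *ignored*: they keep their region of feature space but
   get no id, and visits routed there are flagged unassigned. Unassigned
   visits truncate trajectories; the remaining visits restart as a new
   segment, so no transition is fabricated across an ignored state.

Splits use half-open intervals — values ≤ threshold route left — matching
the `(lo, hi]` notation of the human-readable rules dump. The tree is
fitted on training visits only (the regression too); both are exposed so a
user can refit on all data if they prefer.

## MDP estimation

Transition probabilities are empirical counts, optionally with additive
smoothing; rewards are count-weighted means. A state-action pair never
observed in the log gets a **pessimistic self-loop** whose reward is the
worst step reward observed anywhere. This prevents policy iteration from
exploiting an unobserved action through an optimistic default — the
standard failure mode of model-based planning on sparse logs.

## Policy learning

* **Policy iteration** alternates exact iterative evaluation (sweeps to a
  Bellman residual below 1e-10; the direct linear solve is kept as a test
  oracle) with greedy improvement; argmax ties break to the lowest action
  id, i.e. `no_drugs` first, making the fixed point unique.
* **Q-learning** replays the pooled logged transitions, shuffled per epoch
  under a seed, with the standard update and α = 0.05 by default. The
  final step of each trajectory uses the target `r` alone (no
  bootstrapping past the log). The learner never touches the estimated
  transition tensor. Fifty epochs ≈ fifty passes over the data by default.
  In the experiment harness, `n_train_repeats` (default 50)
  independently-seeded learners are trained and the greedy policy with the
  best validation step-WIS value is carried to testing.
* The **clinician** policy is one evaluation-improvement cycle applied to
  the empirical behavior policy. By the policy-improvement theorem it
  weakly dominates the behavior policy *in the fitted MDP*; it is a
  data-driven idealization, not a claim about what clinicians would do, so
  behavior and clinician values are always reported separately.
* **Zero** (always `no_drugs`) and **uniform random** policies complete the
  comparison set.

Value iteration exists only as the Q* oracle for tests.

## Off-policy evaluation

The headline estimator is per-decision (stepwise) weighted importance
sampling. With cumulative ratios ρ and the convention that trajectories
shorter than t contribute ρ = r = 0,

    V̂ = Σ_t γ^t (Σ_i ρ^i_{0:t} r^i_t) / (Σ_i ρ^i_{0:t}),

summing over steps where at least one trajectory is alive and the
denominator is positive. Self-normalization makes the estimate invariant
to rescaling all ratios by a constant; with target = behavior it reduces to
the on-policy empirical value, and step-WIS and ordinary IS agree exactly
on equal-length trajectory sets. Ordinary trajectory-wise IS is provided
for variance comparison.

Deterministic target policies are evaluated as probability-1 rows: logged
actions off the target's support zero the weight from that step onward.
When the learned policy prescribes drug classes that are rare in the log
(the realistic regime — effective AD drugs are a few percent of logged
prescriptions), few test trajectories carry weight and the estimate can
collapse to a handful of contributors. The reported effective sample size
(Kish `(Σw)²/Σw²` of the first-step weights) makes this visible — an ESS
near zero means the value rests on almost no data. The behavior policy used
in the ratios is estimated from training trajectories with additive
smoothing 0.5, which guarantees coverage of every logged action; ratio
clipping is available but off by default.

Uncertainty is a bootstrap over whole trajectories (default 100
replicates); a single replicate reports sd 0 by convention.

## Synthetic cohort generator

The generator is the package's stand-in for the access-restricted registry
its schema mirrors. It emulates:

* cohort scale — 1,736 patients by default, 1 + Poisson(5.42) visits per
  patient (mean 6.42), six-month visit spacing;
* medication frequencies — per-visit prescription probabilities matching
  the registry's relative class frequencies (supplements and no-drugs each
  ≈45%, ChEI ≈4%, antihypertensive ≈2.7% — tilted upward for hypertensive
  patients — memantine ≈1.7%, combination ≈1.4%);
* progression — MMSE evolves as
  `MMSE_{t+1} = clip(MMSE_t + effect(action) + N(0, noise_sd), 0, 30)`,
  rounded to integers, with per-action mean effects between −2 and +1
  MMSE points per visit (default decline ≈1 point per visit, noise sd 1.5);
* correlated assessments — ADAS13 is a decreasing affine function of MMSE
  plus noise (the coupling the state tree exploits); RAVLT, CDRSB, MoCA
  and FDG are analogous affine functions;
* comorbidity strata — constant within-patient hypertension (prevalence
  0.30) and depression (0.28) flags, drawn independently;
* missingness — each assessment cell is blanked independently with
  probability `missing_rate` (default 0.05); identifiers, months and
  medications are never blanked. The true missingness mechanism of the
  registry is uncharacterized; uniform missingness is an assumption, and
  leading-missing patients are the ones inclusion filtering removes.

Each patient has an independent random stream keyed by (seed, patient
index), so cohorts are byte-reproducible and stable under reordering.

What the generator does **not** emulate: state-dependent prescribing
(actions are drawn independently of disease state, whereas clinicians treat
sicker patients differently), visit-interval irregularity, measurement
floor/ceiling artifacts beyond clipping, informative missingness, and any
imaging or biomarker signal. Passing tests therefore demonstrate that the
pipeline recovers known dynamics and orders policies correctly under these
idealized conditions — not that it reproduces any number obtainable only
from the restricted registry.

A second generator rolls trajectories directly from an explicit tabular
ground-truth MDP (uniform initial states, behavior-policy action draws,
deterministic expected rewards), which is what the estimator-recovery and
OPE-consistency tests use.

## Problem sizes and numerical conventions

Tests and the acceptance script run at sizes chosen to make Monte-Carlo
checks sharp while staying quick on one CPU: 200 random MDPs (|S| ≤ 4,
|A| ≤ 3) for planner/brute-force agreement; a 5-state 3-action
deterministic toy with every pair covered ≥100 times for Q-learning;
20 replicates at n ∈ {100, 1,000, 10,000} trajectories for OPE
consistency; 2,000-patient cohorts for end-to-end runs. Policy evaluation
tolerance is 1e-10 (residuals checked at 1e-8); Q-tables initialize at
zero; all argmax ties break to the lowest action id; seeds for every
stochastic component derive from a master seed via CRC-keyed
`SeedSequence` paths and stay below 2³¹.

## Known limitations

* Step-WIS with deterministic targets and rare logged actions is
  high-variance at realistic cohort sizes; inspect the reported ESS and
  bootstrap sd before reading anything into a point value.
* The clinician policy inherits every bias of the fitted MDP; its
  improvement guarantee holds only inside that model.
* Unassigned-visit truncation discards the (observable) MMSE change into
  ignored states rather than modelling it.
* The six-action vocabulary collapses dose, duration and within-class drug
  differences; the bundled lexicon is editable YAML and unknown names fall
  back to `supplements_other` by design.
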