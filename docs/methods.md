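# Methods

`newsreason` compares parametric cognitive models of the decision to
accept or reject a news headline, at the level of the individual
decision maker.  This note documents the models, the fitting and
evaluation procedures, the synthetic-data generator, and the numerical
and design choices behind them.

## Setting and notation

Data are trials: one row per participant × news item, with a binary
Accept/Reject response.  Participants carry a Cognitive Reflection Test
score `CRT_i ∈ [0, 1]` (mean fraction of correct answers), a
conservatism rating on the study scale, education, and optionally PANAS
positive/negative affect scores.  Items carry a truth label (real or
fake), pretest partisanship and familiarity aggregates — one value
aggregated over Republican-leaning pretest raters, one over
Democrat-leaning raters, plus their mean — and optionally
importance/worrying/excitingness aggregates and a sentiment vector.

Every model computes an **expected prediction** `P_m(t, i) ∈ [0, 1]`:
the probability of responding Accept on item `t` by participant `i`,
obtained by clipping the model's raw score to the unit interval
(`max(0, min(x, 1))`).  The binary decision is Accept iff `P ≥ 0.5`
(the boundary goes to Accept, consistent with the sentiment model's
inclusive `≥ 0` rule).

Derived features, computed once per dataset before any fitting:

* **participant group** — Republican iff conservatism strictly exceeds
  the dataset mean, else Democrat (ties at the mean go to Democrat: a
  deterministic rule affecting only measure-zero cases on a continuous
  scale);
* **item class** — an item is NEUTRAL when its mean pretest
  partisanship lies within a half-width band (default 0.5 scale units,
  boundary inclusive) of the scale midpoint, else
  Republican-/Democrat-favorable by which side of the midpoint it sits
  on.  The half-width is configurable because no canonical cut exists
  for the pretest scale;
* **own-group resolution** — models consume the pretest aggregate
  matching the participant's group; fast-and-frugal trees additionally
  see the two-group mean;
* **response binarization** — 4-point accuracy ratings split at the
  scale midpoint: 1–2 Reject, 3–4 Accept;
* **reaction-time standardization** — z-scored within participant, so
  the reaction-time weight in CR&time is scale-free (raw seconds mode
  is available).

## The model zoo

| name | form (per truth class R/F where split) | free params | fitting scope |
|---|---|---|---|
| `cr` | `κ + α·CRT_i` | 4 | global, closed form (OLS) |
| `cr_time` | `P_CR + reac·α` | 2 | per individual |
| `ms2r` | `κ_C + α_C·CRT` matched, `κ_N + α_N·CRT` mismatched, 0.5 neutral | 4 | global |
| `wm_suppression` | `P_CR + |PANAS_p − PANAS_n|·α` | 2 | per individual |
| `wm_improvement` | `P_CR + (PANAS_p − PANAS_n)·α` | 2 | per individual |
| `recognition` | `1 iff FAM_t > κ_i` (strict) | 1 | per individual |
| `recognition_linear` | `κ_i + α_i·FAM_t` | 2 | per individual |
| `sentiments` | `1 iff Σ_c s_c(t)·α_{c,i} ≥ 0` | 10 | per individual |
| `party` | `κ + α·part′_t` | 4 | global (excluded from defaults) |
| `van_bavel` | `α·FAM_t + κ + β·part_i + γ·part′_t + κ_p·[matched]` | 8 | per individual |
| `fft_max`, `fft_zigzag` | fast-and-frugal tree | — | global (one tree per dataset) |

Baselines: `random` (0.5 everywhere), `always_reject` (0),
`correct_categorization` (the truth oracle), and the leave-one-out
`item_mean` recommender (the degenerate pooled recommender that
similarity-weighted recommenders converge to).

Notes on individual models:

* **Classical Reasoning** is fitted in closed form: ordinary least
  squares of each participant's mean acceptance rate on CRT, separately
  for real and fake items, over all participants.  It is the base of
  the CR&time and mood extensions, whose per-individual weights are
  fitted on top of the frozen global CR line.
* **CR & reaction time** is implemented additively
  (`P_CR + reac·α` per truth class): the theory's point is that time
  spent indexes System-2 engagement, and the additive form is the one
  that actually uses reaction time.  A multiplicative variant
  (`P_CR · α`, no reaction-time term) is retained behind
  `variant="multiplicative"` as an alternative written form.
* **MS2R** returns exactly 0.5 for neutral items or unresolved groups:
  identity-protective reasoning makes no prediction without a
  congruence relation.
* **Recognition (threshold)** uses a strict inequality; familiarity
  exactly at the threshold is not recognized.
* **Weighted sentiments** consumes per-item category scores.  Headline
  scoring is lexicon-based: lowercase, split on non-alphabetic
  characters; the score of a category is the fraction of tokens mapped
  to it.  The 10 categories most frequently detected across item
  headlines (ties broken lexicographically) are retained — enough for
  discrimination without letting category combinations memorize
  individual items.  The packaged lexicon
  (`data/synthetic_lexicon.yaml`) is a small hand-written synthetic
  fixture; any word → categories mapping (e.g. exported from a trained
  sentiment lexicon) can be substituted, and precomputed sentiment
  columns bypass scoring entirely.
* **By-partisanship** is implemented for completeness but excluded from
  default model lists: fitted on study-like data it converges to the
  truth oracle (accept real, reject fake), so it tests nothing about
  partisanship.
* **Van Bavel** is implemented exactly as the displayed formula (no CRT
  term).  `part_i` is the participant's conservatism scale value,
  `part′_t` the own-group item partisanship aggregate, and `κ_p` is
  added when the item's partisanship class matches the participant's
  group.

## Fast-and-frugal trees

Cues are binarized numeric features: for each feature the
validity-maximizing (threshold, direction, exit) combination is chosen,
thresholds searched over midpoints between consecutive distinct values.
Validity is the Take-The-Best measure: the fraction of firing trials
whose response equals the cue's exit.  Tie rule: lower threshold, then
`>` before `≤`, then Accept before Reject; cross-feature ties break
lexicographically by feature name.  Constant features yield no cue.

**Max** picks the highest-validity cue at each level (its own best
exit); **ZigZag Z+** forces exits to alternate Accept, Reject, …
starting with Accept, choosing the highest-validity unused cue with the
required exit.  Both re-score validity on the trials remaining after
earlier nodes resolved theirs (dynamic re-ranking; Max has a static
mode that ranks once on the full sample, since the source literature is
ambiguous between the two).  Neither imposes a depth limit: building
stops only when no admissible cue remains, every admissible cue must
fire on at least one remaining trial and leave at least one unresolved,
and no feature is used twice.  The final leaf is the majority response
of the unresolved trials for Max (ties to Reject, matching the
majority-reject base rates of this kind of data) and the opposite of
the last exit for ZigZag.  Trees are fitted globally — one per dataset;
with a few dozen items per participant, per-participant trees would
overfit badly, and per-individual FFT fitting is refused.

## Parameter fitting

All free-parameter models are fitted by the same regime: scipy's
basin-hopping from a zero initial vector with 200 random perturbations
(default), Metropolis temperature T = 5, perturbation step size 1.0,
and a derivative-free Nelder-Mead local search (adaptive simplex
coefficients, tolerance 1e-6, evaluation cap 600·dim).  One master seed
expands into per-participant seeds keyed on the participant id, so fits
are deterministic and invariant to participant ordering; the returned
loss never exceeds the loss at the zero start.

The fitted objective is the trial-level mean squared error between the
expected prediction and the 0/1 response.  Discrete accuracy is
piecewise constant in the parameters and defeats local optimization;
MSE is its natural smooth surrogate and reproduces the
linear-approximation behavior of the closed-form CR fit.  A discrete
objective is available behind `objective="discrete"`.  No parameter
bounds are imposed — clipping bounds the prediction.

## Evaluation

Each model is scored per participant on that participant's full trial
set, with training and test sets identical.  With one to ten free
parameters per participant, a handful of dozen items, and models unable
to memorize responses, this train = test regime measures how well a
person's decisions can be *explained within* a model; splitting would
leave unusably small and incomparable sets.  Accuracy defaults to the
**expected** form — the mean matched probability, `P` on accepted and
`1 − P` on rejected trials — under which the random baseline scores
exactly 0.5 for every participant (median 0.5, MAD 0.00); discrete
0/1-prediction accuracy coincides with it for deterministic models and
is available as a mode.

Reports aggregate per-participant accuracies as mean, standard
deviation (n−1), median, and MAD — the **median absolute deviation
about the median**, not the mean absolute deviation; the headline
"predictive performance" figure is the median.  Hybrid models assign to
each participant the member model with the highest accuracy
(max-pooling; ties to the first member in list order), optionally after
exclusions; all unordered two-model hybrids are enumerated and ranked
by median, then mean.  Correlation matrices are Pearson over all trials
between model expected predictions and trial-level features, binary
columns entering as 0/1 and constant columns reported as undefined
(NaN), never zero.  Figures-equivalent outputs are data tables.

## Synthetic data

The generator emulates the experiments' schema at configurable size
(item shapes restricted to the studies' 15/15, 12/12 or 18/18
real/fake): CRT ~ Beta(2, 2); conservatism uniform over its scale;
PANAS ~ truncated normal on 10–50; familiarity ~ truncated normal
(2.0, 0.5) on the 1–3 pretest scale per group; partisan items near the
scale poles (sd 0.3) with a configurable neutral fraction (default 1/3)
at the midpoint, per-group aggregates jittered around the item mean;
sparse non-negative sentiment vectors (10 categories, 25% fill);
log-normal reaction times.  No population distributions are reported
for the original studies, so these defaults are documented choices —
the recovery contracts do not depend on them.

Responses come from a **responder mixture**: each participant is
assigned one generating model with ground-truth parameters (fixed, or
drawn per participant), answers Accept with the model's expected
prediction, and the response is flipped with probability `noise_rate`
(default 0.1, an ordinary lapse rate; recovery scenarios use 0).  The
ground truth is serialized next to the dataset; recovery tests read it,
the pipeline under test never does.  With a deterministic responder and
zero noise, regenerated responses equal the model's predictions
exactly.

What the generator does **not** emulate: real headline text (synthetic
items carry sentiment vectors directly), item-level selection effects,
participant attrition, response-order and fatigue effects, or any
coupling between item content and pretest aggregates beyond the
configured distributions.  Passing recovery tests therefore shows the
estimation machinery is correct under the stated generating process,
not that the models are true of human data.

## Parameter recovery: what is and is not identifiable

Recovery is measured as the **median across participants** of each
recovered parameter against its generating value: individual estimates
from ~36 binary responses are necessarily noisy, but MSE fits are
unbiased where clipping is inactive, so medians over 200 participants
concentrate.

* The closed-form CR fit agrees with textbook normal-equation OLS to
  1e-6 by construction.
* Recognition thresholds (deterministic responders) recover to within
  a few hundredths: any threshold inside the gap between the largest
  rejected and smallest accepted familiarity is loss-optimal, and the
  gaps are narrow on the 1–3 scale with ~30 items.
* For the Van Bavel model, the weights that multiply quantities varying
  *within* a participant's trials — the familiarity slope α, the item
  partisanship slopes γ_R/γ_F, and the congruence bonus κ_p — recover
  in the median to within ±0.05 at zero noise.  The intercepts κ_R/κ_F
  and the participant-partisanship weights β_R/β_F are **exactly
  collinear within an individual** (conservatism is constant across one
  person's trials): only the composite κ + β·cons_i is identifiable per
  person, and even that composite cannot be pinned to ±0.05 from ~36
  binary trials — the intercept direction is near-collinear with
  α·FAM_t on the narrow 1–3 familiarity scale, and exact per-individual
  OLS already misses that band.  This is an information limit of the
  experiment shape, not an optimizer artifact; the corresponding
  acceptance assertions are expected to fail and say so.

## Problem sizes and runtime choices

The default test and script runs use 200 simulated participants with
the 18/18 item shape.  Basin-hopping perturbation counts are scaled to
the fit at hand: 50 for the 1-parameter recognition threshold (a
piecewise-constant objective that benefits from restarts), 5–10 for the
smooth near-convex multi-parameter fits (more restarts were verified
not to change the recovered medians), while `FitConfig` defaults remain
the full regime (200 perturbations, T = 5).  All randomness flows from
a single seed.

## Known limitations

* The loader's example column mappings are templates: the deposited
  study tables' exact headers must be mapped by the user.
* The sentiment scorer is a fixture lexicon, not a trained model;
  absolute sentiment-model accuracies on real headlines depend entirely
  on the lexicon supplied.
* The mood models are indistinguishable from each other under
  per-individual fitting (the affect imbalance is constant within a
  participant, so the sign is absorbed by the fitted weight); they
  separate only under constrained or global fits.
* Hybrid composition max-pools observed accuracies; it is an upper
  envelope, not a cross-validated model-selection procedure.
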