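# newsreason

Cognitive models of the individual decision to accept or reject a news
headline as accurate.

When people judge whether a headline is true, which account best
predicts a *particular person's* answer before they give it — analytic
reflection, identity-protective reasoning, mood, sheer familiarity,
the emotional tone of the words, or a simple decision tree?
`newsreason` implements a zoo of such accounts as parametric
expected-prediction functions, fits them per individual or globally
with basin-hopping, scores them per participant, and composes them into
hybrid "adaptive toolbox" models.  It is aimed at decision scientists
and computational cognitive modelers who want individual-level
predictive comparison rather than population-average correlations.

## The models

Every model maps a (news item `t`, participant `i`) pair to an
**expected prediction** `P_m(t, i) = max(0, min(·, 1))` — the
probability of an Accept response; the decision is Accept iff
`P ≥ 0.5`.  Among others (see `docs/methods.md` for the full zoo):

- **Classical Reasoning** — analytic thinking improves accuracy:
  `P = κ_R + α_R·CRT_i` for real items, `κ_F + α_F·CRT_i` for fake,
  fitted globally as an OLS line through per-participant acceptance
  rates (`CRT_i` is the Cognitive Reflection Test score in [0, 1]).
- **Motivated System-2 Reasoning** — analytic thinking amplifies
  acceptance of identity-congruent items: separate linear CRT terms for
  matched vs. mismatched partisanship, 0.5 when item or person is
  neutral.
- **Recognition heuristic** — accept what is familiar:
  `P = 1 iff FAM_t > κ_i` (strict threshold, per individual), plus a
  linear variant `κ_i + α_i·FAM_t`.
- **Weighted sentiments** — accept iff a per-individual weighted sum of
  the headline's sentiment-category scores is `≥ 0` (top-10 categories
  across the item set).
- **Identity-based (Van Bavel-style) model** —
  `α·FAM_t + κ + β·part_i + γ·part′_t + κ_p·[congruent]` per truth
  class, 8 parameters per individual.
- **Fast-and-frugal trees** — binarized cues ordered by Take-The-Best
  validity; `Max` (greedy best exit) and `ZigZag Z+` (exits forced to
  alternate Accept/Reject starting with Accept), one global tree per
  dataset, no depth limit.
- Baselines: random (0.5), always-reject, the truth oracle, and a
  leave-one-out item-mean recommender.

Free parameters are trained by scipy basin-hopping (200 perturbations,
T = 5, zero init by default) on trial-level mean squared error.
Evaluation is per participant with train = test (the models are too
small to memorize); reports give mean, σ, median and MAD of
per-participant accuracies, the median being the headline number.
Hybrids assign each participant their best member model.

## Worked example

Simulate a 60-participant study (mixed responder population: classical
reasoners, recognition users, motivated reasoners, sentiment readers
and identity-based responders, with 10% response noise), then fit and
evaluate a model selection:

```bash
newsreason simulate --seed 7 --n-participants 60 --out demo
newsreason evaluate --data demo/dataset.csv \
    --models cr,cr_time,recognition,sentiments,van_bavel,random \
    --seed 7 --n-perturbations 10 --out demo/eval
```

which prints:

```
      model     mean       sd   median      mad
 sentiments 0.708796 0.105371 0.722222 0.083333
  van_bavel 0.709870 0.150145 0.650457 0.087894
recognition 0.581481 0.149969 0.555556 0.083333
    cr_time 0.536576 0.037532 0.526240 0.016130
         cr 0.503905 0.009655 0.503551 0.004501
     random 0.500000 0.000000 0.500000 0.000000
```

Each row aggregates one model's per-participant predictive accuracies
(expected accuracy: the probability the model assigns to the response
actually given).  The random baseline sits at exactly 0.5 with MAD
0.00 by construction.  Here the sentiment and identity-based models
explain the most participants — unsurprising, since the simulated
population contains such responders — while the global CR line, fitted
across a heterogeneous population, barely beats chance for any single
person.  Composing the models,

```bash
newsreason hybrid --data demo/dataset.csv \
    --models cr,cr_time,recognition,sentiments,van_bavel \
    --seed 7 --n-perturbations 10 --out demo/hybrid
# hybrid median 0.773 (MAD=0.10) over 5 members
```

the best-of-5 hybrid (median 0.773) beats every single model, the
signature of a population using different cognitive tools.
`newsreason pairs` ranks all two-model hybrids and `newsreason
correlate` writes the Pearson matrix of model predictions against task
and participant features.

The same loop is available as a library:

```python
from newsreason import SyntheticConfig, generate_dataset, evaluate_models, FitConfig

ds, truth = generate_dataset(SyntheticConfig(n_participants=60, seed=7))
reports, models = evaluate_models(["cr", "recognition", "van_bavel"], ds,
                                  FitConfig(n_perturbations=10, seed=7))
print(reports["recognition"].median, reports["recognition"].mad)
```

Real study tables load through a user-edited column mapping
(`examples/mappings/`): `load_dataset("table.csv", "exp3.yaml")`.

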