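"""The decision-model zoo: closed-form expected-prediction functions.

Every model maps a (news item, participant) pair to an *expected
prediction* — the probability in [0, 1] of responding "Accept" —
obtained by clipping a raw linear/threshold score to the unit interval.
The binary decision is ACCEPT iff the expected prediction is >= 0.5.

Two layers are provided:

* scalar ``predict_*`` functions with explicit parameter dataclasses,
  mirroring the written model formulas one-to-one;
* :class:`Model` subclasses with a uniform contract
  (``bind`` -> ``pre_train`` -> ``predict_probability`` / ``predict``)
  and vectorized evaluation over a :class:`TrialTable`, which is what
  the fitting and evaluation machinery uses.

Model families
--------------
Classical Reasoning (CR) ties correct classification to analytic
thinking (CRT); CR&time adds reaction time as a System-2 marker;
Motivated System-2 Reasoning (MS2R) makes CRT amplify acceptance of
identity-congruent items; the mood models modulate CR by the PANAS
affect imbalance; the recognition heuristic accepts familiar items
(threshold or linear in familiarity); the weighted-sentiments model
thresholds a per-individual linear combination of headline sentiment
scores; the partisanship-only and Van Bavel models use item and
participant partisanship directly.  Baselines (random, always-reject,
correct categorization) and a leave-one-out item-mean recommender
complete the zoo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data_model import (
    Dataset,
    FeatureError,
    Group,
    ItemClass,
    NewsItem,
    Participant,
    Response,
    Trial,
    Truth,
)
from .feature_prep import (
    PartisanshipBands,
    SentimentSelection,
    classify_item,
    prepare_dataset,
    resolve_group_feature,
)

GLOBAL = "global"
PER_INDIVIDUAL = "per_individual"


def clip_unit(x: float) -> float:
    """Clip a raw model score to [0, 1]; rejects non-finite input."""
    if not math.isfinite(x):
        raise ValueError(f"cannot clip non-finite value {x!r}")
    return max(0.0, min(float(x), 1.0))


def _clip_vec(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Parameter records


@dataclass
class CRParams:
    kappa_R: float
    alpha_R: float
    kappa_F: float
    alpha_F: float


@dataclass
class CRTimeParams:
    base: CRParams
    alpha_R_t: float
    alpha_F_t: float


@dataclass
class MS2RParams:
    kappa_C: float
    alpha_C: float
    kappa_N: float
    alpha_N: float


@dataclass
class MoodParams:
    base: CRParams
    alpha_R_m: float
    alpha_F_m: float


@dataclass
class RecognitionParams:
    kappa_i: float = 0.0
    alpha_i: float = 0.0


@dataclass
class SentimentParams:
    alphas: np.ndarray


@dataclass
class PartyParams:
    kappa_R: float
    alpha_R: float
    kappa_F: float
    alpha_F: float


@dataclass
class VanBavelParams:
    alpha: float
    kappa_R: float
    beta_R: float
    gamma_R: float
    kappa_F: float
    beta_F: float
    gamma_F: float
    kappa_p: float


# ---------------------------------------------------------------------------
# Scalar expected-prediction functions


def predict_cr(item: NewsItem, participant: Participant, p: CRParams) -> float:
    """Classical Reasoning: truth-class-specific linear function of CRT."""
    if item.truth is Truth.REAL:
        return clip_unit(p.kappa_R + p.alpha_R * participant.crt)
    return clip_unit(p.kappa_F + p.alpha_F * participant.crt)


def predict_cr_time(
    item: NewsItem,
    participant: Participant,
    trial: Trial,
    p: CRTimeParams,
    variant: str = "additive",
    use_z: bool = True,
) -> float:
    """CR extended by reaction time.

    The default additive form adds reac * alpha (per truth class) to the
    CR expected prediction; reaction times are standardized within
    participant unless ``use_z`` is False.  The ``multiplicative``
    variant instead scales the CR prediction by alpha per truth class
    (an alternative written form that does not use reaction time).
    """
    pcr = predict_cr(item, participant, p.base)
    alpha = p.alpha_R_t if item.truth is Truth.REAL else p.alpha_F_t
    if variant == "multiplicative":
        return clip_unit(pcr * alpha)
    reac = trial.reaction_z if use_z else trial.reaction_time
    if reac is None:
        raise FeatureError("reaction time absent for CR&time prediction")
    return clip_unit(pcr + reac * alpha)


def predict_ms2r(
    item: NewsItem,
    participant: Participant,
    p: MS2RParams,
    bands: PartisanshipBands | None = None,
) -> float:
    """Motivated System-2 Reasoning: CRT effect split by identity congruence.

    Matched partisanship -> kappa_C + alpha_C*CRT; mismatched ->
    kappa_N + alpha_N*CRT; a neutral item (or unassigned participant
    group) carries no prediction and returns exactly 0.5.
    """
    iclass = item.item_class
    if iclass is None:
        if bands is None:
            raise FeatureError("item not classified and no bands supplied")
        iclass = classify_item(item, bands)
    if iclass is ItemClass.NEUTRAL or participant.group is None:
        return 0.5
    if iclass.value == participant.group.value:
        return clip_unit(p.kappa_C + p.alpha_C * participant.crt)
    return clip_unit(p.kappa_N + p.alpha_N * participant.crt)


def predict_mood(
    item: NewsItem, participant: Participant, p: MoodParams, variant: str
) -> float:
    """Mood-modulated CR using the PANAS positive-negative imbalance.

    SUPPRESSION uses the absolute imbalance |PANAS_p - PANAS_n| (intense
    mood of either valence taxes working memory); IMPROVEMENT uses the
    signed difference (negative mood aids systematic processing).
    """
    if participant.panas_p is None or participant.panas_n is None:
        raise FeatureError("PANAS scores absent; mood models unavailable")
    pcr = predict_cr(item, participant, p.base)
    diff = participant.panas_p - participant.panas_n
    mood = abs(diff) if variant == "SUPPRESSION" else diff
    if variant not in ("SUPPRESSION", "IMPROVEMENT"):
        raise ValueError(f"unknown mood variant {variant!r}")
    alpha = p.alpha_R_m if item.truth is Truth.REAL else p.alpha_F_m
    return clip_unit(pcr + mood * alpha)


def predict_recognition(
    item: NewsItem,
    participant: Participant,
    p: RecognitionParams,
    variant: str = "THRESHOLD",
) -> float:
    """Recognition heuristic on own-group familiarity.

    THRESHOLD accepts (1) iff familiarity strictly exceeds kappa_i,
    else rejects (0); LINEAR clips kappa_i + alpha_i * FAM.
    """
    fam = resolve_group_feature(item, participant, "fam", "own_group")
    if variant == "THRESHOLD":
        return 1.0 if fam > p.kappa_i else 0.0
    if variant == "LINEAR":
        return clip_unit(p.kappa_i + p.alpha_i * fam)
    raise ValueError(f"unknown recognition variant {variant!r}")


def predict_sentiments(
    item: NewsItem, p: SentimentParams, sel: SentimentSelection
) -> float:
    """Weighted sentiments: accept iff the weighted score sum is >= 0."""
    if item.sentiments is None:
        raise FeatureError(f"item {item.id} has no sentiment vector")
    s = np.asarray(item.sentiments, dtype=float)
    alphas = np.asarray(p.alphas, dtype=float)
    if len(s) != len(alphas) or len(alphas) != sel.k:
        raise ValueError(
            f"sentiment vector length {len(s)} / weights {len(alphas)} "
            f"do not match selection k={sel.k}")
    return 1.0 if float(s @ alphas) >= 0.0 else 0.0


def predict_party(item: NewsItem, p: PartyParams) -> float:
    """Partisanship-only model: linear in the item's distinctive partisanship.

    Fitting this model on study-like data degenerates to the truth
    oracle (always accept real, reject fake), so it is excluded from the
    default model lists and kept for completeness.
    """
    part = item.part_mean
    if item.truth is Truth.REAL:
        return clip_unit(p.kappa_R + p.alpha_R * part)
    return clip_unit(p.kappa_F + p.alpha_F * part)


def predict_van_bavel(
    item: NewsItem,
    participant: Participant,
    p: VanBavelParams,
    bands: PartisanshipBands | None = None,
) -> float:
    """Identity-based model after Van Bavel's misinformation risk factors.

    alpha*FAM_t + [kappa + beta*part_i + gamma*part'_t per truth class]
    + kappa_p when the item's partisanship class matches the
    participant's group.  part_i is the participant's conservatism scale
    value; part'_t the own-group item partisanship aggregate.
    """
    fam = resolve_group_feature(item, participant, "fam", "own_group")
    part_t = resolve_group_feature(item, participant, "part", "own_group")
    iclass = item.item_class
    if iclass is None:
        if bands is None:
            raise FeatureError("item not classified and no bands supplied")
        iclass = classify_item(item, bands)
    if item.truth is Truth.REAL:
        lin = p.kappa_R + p.beta_R * participant.conservatism + p.gamma_R * part_t
    else:
        lin = p.kappa_F + p.beta_F * participant.conservatism + p.gamma_F * part_t
    matched = participant.group is not None and iclass.value == participant.group.value
    return clip_unit(p.alpha * fam + lin + (p.kappa_p if matched else 0.0))


def predict_baseline(item: NewsItem, kind: str) -> float:
    """Data baselines: RANDOM (0.5), ALWAYS_REJECT (0), CORRECT_CATEGORIZATION."""
    if kind == "RANDOM":
        return 0.5
    if kind == "ALWAYS_REJECT":
        return 0.0
    if kind == "CORRECT_CATEGORIZATION":
        return 1.0 if item.truth is Truth.REAL else 0.0
    raise ValueError(f"unknown baseline kind {kind!r}")


def predict_item_mean(item: NewsItem, participant: Participant, ds: Dataset) -> float:
    """Leave-one-out item-mean recommender.

    The mean acceptance rate of all *other* participants on this item —
    the degenerate pooled recommender that per-item pooling converges to.
    """
    n = acc = 0
    for t in ds.trials:
        if t.item_id == item.id and t.participant_id != participant.id:
            n += 1
            acc += t.response is Response.ACCEPT
    if n == 0:
        raise FeatureError(f"item {item.id}: no responses from other participants")
    return acc / n


# ---------------------------------------------------------------------------
# Vectorized trial table


@dataclass
class TrialTable:
    """Per-trial feature arrays for vectorized model evaluation."""

    ds: Dataset
    participant_ids: list[str]
    trial_pidx: np.ndarray          # participant index per trial
    y: np.ndarray                   # 1.0 = ACCEPT
    truth_real: np.ndarray          # boolean
    crt: np.ndarray
    conservatism: np.ndarray
    education: np.ndarray
    panas_p: np.ndarray | None
    panas_n: np.ndarray | None
    fam_own: np.ndarray
    fam_mean: np.ndarray
    part_own: np.ndarray
    part_mean: np.ndarray
    matched: np.ndarray             # boolean, participant group == item class
    neutral: np.ndarray             # boolean, item class NEUTRAL
    reac: np.ndarray | None
    reac_z: np.ndarray | None
    sentiments: np.ndarray | None   # (n_trials, k)
    extra: dict[str, np.ndarray] = field(default_factory=dict)
    _rows_by_pidx: list[np.ndarray] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.y)

    def rows_of(self, pidx: int) -> np.ndarray:
        return self._rows_by_pidx[pidx]


def build_trial_table(ds: Dataset, bands: PartisanshipBands | None = None) -> TrialTable:
    """Flatten a (prepared) dataset into aligned per-trial arrays."""
    if any(p.group is None for p in ds.participants.values()) or any(
        i.item_class is None for i in ds.items.values()
    ):
        prepare_dataset(ds, bands)

    pids = list(ds.participants)
    pindex = {pid: k for k, pid in enumerate(pids)}
    n = len(ds.trials)

    trial_pidx = np.empty(n, dtype=int)
    y = np.empty(n)
    truth_real = np.empty(n, dtype=bool)
    crt = np.empty(n)
    cons = np.empty(n)
    edu = np.zeros(n)
    fam_own = np.empty(n)
    fam_mean = np.empty(n)
    part_own = np.empty(n)
    part_mean = np.empty(n)
    matched = np.empty(n, dtype=bool)
    neutral = np.empty(n, dtype=bool)

    has_panas = ds.schema.has_panas
    panas_p = np.empty(n) if has_panas else None
    panas_n = np.empty(n) if has_panas else None
    has_rt = ds.schema.has_reaction_time
    reac = np.empty(n) if has_rt else None
    reac_z = np.empty(n) if has_rt else None
    k_sent = len(ds.schema.sentiment_categories) if ds.schema.has_sentiments else 0
    if not k_sent:
        sample = next(iter(ds.items.values()), None)
        if sample is not None and sample.sentiments is not None:
            k_sent = len(sample.sentiments)
    sent = np.zeros((n, k_sent)) if k_sent else None

    for k, t in enumerate(ds.trials):
        p = ds.participants[t.participant_id]
        item = ds.items[t.item_id]
        trial_pidx[k] = pindex[t.participant_id]
        y[k] = 1.0 if t.response is Response.ACCEPT else 0.0
        truth_real[k] = item.truth is Truth.REAL
        crt[k] = p.crt
        cons[k] = p.conservatism
        edu[k] = p.education if p.education is not None else 0.0
        is_rep = p.group is Group.REP
        fam_own[k] = item.fam_rep if is_rep else item.fam_dem
        fam_mean[k] = item.fam_mean
        part_own[k] = item.part_rep if is_rep else item.part_dem
        part_mean[k] = item.part_mean
        neutral[k] = item.item_class is ItemClass.NEUTRAL
        matched[k] = (not neutral[k]) and item.item_class.value == p.group.value
        if has_panas:
            panas_p[k] = p.panas_p if p.panas_p is not None else np.nan
            panas_n[k] = p.panas_n if p.panas_n is not None else np.nan
        if has_rt:
            reac[k] = t.reaction_time if t.reaction_time is not None else np.nan
            reac_z[k] = t.reaction_z if t.reaction_z is not None else np.nan
        if sent is not None and item.sentiments is not None:
            sent[k] = item.sentiments

    rows = [np.flatnonzero(trial_pidx == i) for i in range(len(pids))]
    return TrialTable(
        ds=ds, participant_ids=pids, trial_pidx=trial_pidx, y=y,
        truth_real=truth_real, crt=crt, conservatism=cons, education=edu,
        panas_p=panas_p, panas_n=panas_n, fam_own=fam_own, fam_mean=fam_mean,
        part_own=part_own, part_mean=part_mean, matched=matched,
        neutral=neutral, reac=reac, reac_z=reac_z, sentiments=sent,
        _rows_by_pidx=rows,
    )


# ---------------------------------------------------------------------------
# Uniform model contract


class Model:
    """Uniform model contract over a bound dataset.

    Lifecycle: ``bind(ds)`` precomputes per-trial feature arrays;
    ``pre_train(fit_config, scope)`` estimates parameters (delegated to
    :mod:`newsreason.fitting`); ``predict_probability(trial)`` returns
    the expected prediction and ``predict(trial)`` the binary decision
    (ACCEPT iff P >= 0.5).
    """

    name: str = "model"
    n_params: int = 0
    default_scope: str | None = None
    param_names: tuple[str, ...] = ()

    def __init__(self) -> None:
        self.table: TrialTable | None = None
        self.global_params: np.ndarray | None = None
        self.individual_params: dict[str, np.ndarray] = {}
        self.fitted_scope: str | None = None

    # -- binding -----------------------------------------------------------
    def bind(self, ds: Dataset, bands: PartisanshipBands | None = None,
             table: TrialTable | None = None) -> "Model":
        self.check_features(ds)
        self.table = table if table is not None else build_trial_table(ds, bands)
        self._post_bind()
        return self

    def check_features(self, ds: Dataset) -> None:
        """Refuse at construction if a required feature is absent."""

    def _post_bind(self) -> None:
        pass

    # -- vectorized core ---------------------------------------------------
    def predict_vec(self, params: np.ndarray, rows: np.ndarray) -> np.ndarray:
        """Expected predictions for the given trial rows."""
        raise NotImplementedError

    # -- fitting -----------------------------------------------------------
    def pre_train(self, fit_config=None, scope: str | None = None):
        from . import fitting  # local import: fitting builds on models

        return fitting.fit_model(self, scope=scope, config=fit_config)

    def params_for_row(self, row: int) -> np.ndarray:
        if self.fitted_scope == PER_INDIVIDUAL:
            pid = self.table.participant_ids[self.table.trial_pidx[row]]
            return self.individual_params[pid]
        if self.global_params is not None:
            return self.global_params
        return np.zeros(self.n_params)

    def predict_table(self) -> np.ndarray:
        """Expected predictions for every trial, using the fitted parameters."""
        t = self.table
        if self.fitted_scope == PER_INDIVIDUAL:
            out = np.empty(t.n_trials)
            for k, pid in enumerate(t.participant_ids):
                rows = t.rows_of(k)
                if len(rows):
                    out[rows] = self.predict_vec(self.individual_params[pid], rows)
            return out
        params = self.global_params if self.global_params is not None \
            else np.zeros(self.n_params)
        return self.predict_vec(params, np.arange(t.n_trials))

    # -- scalar interface --------------------------------------------------
    def _row_of_trial(self, trial: Trial) -> int:
        for k, t in enumerate(self.table.ds.trials):
            if t is trial or (t.participant_id == trial.participant_id
                              and t.item_id == trial.item_id):
                return k
        raise KeyError("trial not part of the bound dataset")

    def predict_probability(self, trial: Trial) -> float:
        row = self._row_of_trial(trial)
        return float(self.predict_vec(self.params_for_row(row), np.asarray([row]))[0])

    def predict(self, trial: Trial) -> Response:
        return Response.ACCEPT if self.predict_probability(trial) >= 0.5 else Response.REJECT


class _CRBased(Model):
    """Shared machinery for models that embed the global CR prediction."""

    def _cr_vec(self, cr: np.ndarray, rows: np.ndarray) -> np.ndarray:
        t = self.table
        kR, aR, kF, aF = cr
        raw = np.where(t.truth_real[rows], kR + aR * t.crt[rows], kF + aF * t.crt[rows])
        return _clip_vec(raw)


class CRModel(_CRBased):
    """Classical Reasoning; fitted globally by OLS of acceptance rate on CRT."""

    name = "cr"
    n_params = 4
    default_scope = GLOBAL
    param_names = ("kappa_R", "alpha_R", "kappa_F", "alpha_F")
    closed_form = True

    def predict_vec(self, params, rows):
        return self._cr_vec(params, rows)


class CRTimeModel(_CRBased):
    """CR plus a per-individual reaction-time term."""

    name = "cr_time"
    n_params = 2
    default_scope = PER_INDIVIDUAL
    param_names = ("alpha_R_t", "alpha_F_t")

    def __init__(self, variant: str = "additive", use_z: bool = True) -> None:
        super().__init__()
        self.variant = variant
        self.use_z = use_z
        self.base_cr: np.ndarray | None = None

    def check_features(self, ds: Dataset) -> None:
        if not ds.schema.has_reaction_time:
            raise FeatureError("CR&time requires reaction times")

    def predict_vec(self, params, rows):
        t = self.table
        base = self.base_cr if self.base_cr is not None else np.zeros(4)
        pcr = self._cr_vec(base, rows)
        alpha = np.where(t.truth_real[rows], params[0], params[1])
        if self.variant == "multiplicative":
            return _clip_vec(pcr * alpha)
        reac = t.reac_z[rows] if self.use_z else t.reac[rows]
        return _clip_vec(pcr + reac * alpha)


class MS2RModel(Model):
    """Motivated System-2 Reasoning; fitted globally like CR for fairness."""

    name = "ms2r"
    n_params = 4
    default_scope = GLOBAL
    param_names = ("kappa_C", "alpha_C", "kappa_N", "alpha_N")

    def predict_vec(self, params, rows):
        t = self.table
        kC, aC, kN, aN = params
        raw = np.where(t.matched[rows], kC + aC * t.crt[rows], kN + aN * t.crt[rows])
        return np.where(t.neutral[rows], 0.5, _clip_vec(raw))


class MoodModel(_CRBased):
    """Suppression/Improvement by Mood over the global CR prediction."""

    n_params = 2
    default_scope = PER_INDIVIDUAL
    param_names = ("alpha_R_m", "alpha_F_m")

    def __init__(self, variant: str) -> None:
        super().__init__()
        if variant not in ("SUPPRESSION", "IMPROVEMENT"):
            raise ValueError(f"unknown mood variant {variant!r}")
        self.variant = variant
        self.name = "wm_suppression" if variant == "SUPPRESSION" else "wm_improvement"
        self.base_cr: np.ndarray | None = None

    def check_features(self, ds: Dataset) -> None:
        if not ds.schema.has_panas:
            raise FeatureError("mood models require PANAS scores")

    def predict_vec(self, params, rows):
        t = self.table
        base = self.base_cr if self.base_cr is not None else np.zeros(4)
        pcr = self._cr_vec(base, rows)
        diff = t.panas_p[rows] - t.panas_n[rows]
        mood = np.abs(diff) if self.variant == "SUPPRESSION" else diff
        alpha = np.where(t.truth_real[rows], params[0], params[1])
        return _clip_vec(pcr + mood * alpha)


class RecognitionModel(Model):
    """Threshold recognition heuristic on own-group familiarity."""

    name = "recognition"
    n_params = 1
    default_scope = PER_INDIVIDUAL
    param_names = ("kappa_i",)

    def predict_vec(self, params, rows):
        return (self.table.fam_own[rows] > params[0]).astype(float)


class RecognitionLinearModel(Model):
    """Linear recognition variant: clip(kappa_i + alpha_i * FAM)."""

    name = "recognition_linear"
    n_params = 2
    default_scope = PER_INDIVIDUAL
    param_names = ("kappa_i", "alpha_i")

    def predict_vec(self, params, rows):
        return _clip_vec(params[0] + params[1] * self.table.fam_own[rows])


class SentimentsModel(Model):
    """Weighted sentiments: accept iff the weighted category sum is >= 0."""

    name = "sentiments"
    default_scope = PER_INDIVIDUAL

    def check_features(self, ds: Dataset) -> None:
        if not any(i.sentiments is not None for i in ds.items.values()):
            raise FeatureError("sentiments model requires item sentiment vectors")

    def _post_bind(self) -> None:
        if self.table.sentiments is None:
            raise FeatureError("bound dataset carries no sentiment vectors")
        self.n_params = self.table.sentiments.shape[1]
        self.param_names = tuple(f"alpha_{c}" for c in
                                 (self.table.ds.schema.sentiment_categories
                                  or range(self.n_params)))

    def predict_vec(self, params, rows):
        score = self.table.sentiments[rows] @ np.asarray(params, dtype=float)
        return (score >= 0.0).astype(float)


class PartyModel(Model):
    """Partisanship-only model (kept out of default lists; see predict_party)."""

    name = "party"
    n_params = 4
    default_scope = GLOBAL
    param_names = ("kappa_R", "alpha_R", "kappa_F", "alpha_F")

    def predict_vec(self, params, rows):
        t = self.table
        kR, aR, kF, aF = params
        raw = np.where(t.truth_real[rows], kR + aR * t.part_mean[rows],
                       kF + aF * t.part_mean[rows])
        return _clip_vec(raw)


class VanBavelModel(Model):
    """Identity-based risk-factor model, per-individual 8-parameter fit."""

    name = "van_bavel"
    n_params = 8
    default_scope = PER_INDIVIDUAL
    param_names = ("alpha", "kappa_R", "beta_R", "gamma_R",
                   "kappa_F", "beta_F", "gamma_F", "kappa_p")

    def _post_bind(self) -> None:
        t = self.table
        real = t.truth_real.astype(float)
        fake = 1.0 - real
        # columns follow param_names; linear model => precompute the design matrix
        self._design = np.column_stack([
            t.fam_own, real, real * t.conservatism, real * t.part_own,
            fake, fake * t.conservatism, fake * t.part_own,
            t.matched.astype(float),
        ])

    def predict_vec(self, params, rows):
        return _clip_vec(self._design[rows] @ np.asarray(params, dtype=float))


class BaselineModel(Model):
    """Data baselines: random coin, always reject, or the truth oracle."""

    n_params = 0
    default_scope = None

    def __init__(self, kind: str) -> None:
        super().__init__()
        if kind not in ("RANDOM", "ALWAYS_REJECT", "CORRECT_CATEGORIZATION"):
            raise ValueError(f"unknown baseline kind {kind!r}")
        self.kind = kind
        self.name = kind.lower()

    def predict_vec(self, params, rows):
        if self.kind == "RANDOM":
            return np.full(len(rows), 0.5)
        if self.kind == "ALWAYS_REJECT":
            return np.zeros(len(rows))
        return self.table.truth_real[rows].astype(float)


class ItemMeanModel(Model):
    """Leave-one-out item-mean recommender (pooled 'similar others')."""

    name = "item_mean"
    n_params = 0
    default_scope = None

    def _post_bind(self) -> None:
        t = self.table
        item_ids = [tr.item_id for tr in t.ds.trials]
        uniq = {iid: k for k, iid in enumerate(dict.fromkeys(item_ids))}
        idx = np.asarray([uniq[iid] for iid in item_ids])
        sums = np.bincount(idx, weights=t.y, minlength=len(uniq))
        counts = np.bincount(idx, minlength=len(uniq))
        if np.any(counts < 2):
            raise FeatureError("item-mean recommender needs >= 2 responses per item")
        self._loo = (sums[idx] - t.y) / (counts[idx] - 1)

    def predict_vec(self, params, rows):
        return self._loo[rows]


# ---------------------------------------------------------------------------
# Registry

MODEL_REGISTRY: dict[str, type | object] = {}


def register(name: str, factory) -> None:
    MODEL_REGISTRY[name] = factory


def make_model(name: str, **kwargs) -> Model:
    """Instantiate a registered model by name."""
    if name not in MODEL_REGISTRY:
        raise KeyError(f"unknown model {name!r}; known: {sorted(MODEL_REGISTRY)}")
    return MODEL_REGISTRY[name](**kwargs)


register("cr", CRModel)
register("cr_time", CRTimeModel)
register("ms2r", MS2RModel)
register("wm_suppression", lambda **kw: MoodModel("SUPPRESSION", **kw))
register("wm_improvement", lambda **kw: MoodModel("IMPROVEMENT", **kw))
register("recognition", RecognitionModel)
register("recognition_linear", RecognitionLinearModel)
register("sentiments", SentimentsModel)
register("party", PartyModel)
register("van_bavel", VanBavelModel)
register("random", lambda **kw: BaselineModel("RANDOM", **kw))
register("always_reject", lambda **kw: BaselineModel("ALWAYS_REJECT", **kw))
register("correct_categorization", lambda **kw: BaselineModel("CORRECT_CATEGORIZATION", **kw))
register("item_mean", ItemMeanModel)

#: Models entering default evaluations; 'party' is excluded because its fit
#: degenerates to the truth oracle, and FFT models register from newsreason.fft.
DEFAULT_MODELS = [
    "cr", "cr_time", "ms2r", "recognition", "recognition_linear",
    "sentiments", "van_bavel",
]
DEFAULT_MODELS_PANAS = DEFAULT_MODELS + ["wm_suppression", "wm_improvement"]
BASELINES = ["random", "always_reject", "correct_categorization"]
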