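"""Per-participant evaluation harness, hybrid composition, correlations.

Each model is fitted per its scope and then scored per participant on
that participant's full trial set — the train = test regime: with only
a few dozen items per participant and models of one to ten parameters,
splitting would leave unusably small sets, and the resulting score
measures how well a participant's decisions can be *explained within*
a model.  Reports aggregate per-participant accuracies as mean, standard
deviation, median and MAD (median absolute deviation about the median);
the headline "predictive performance" number is the median.

Hybrid models embody the adaptive-toolbox idea: assign to each
participant the member model that predicts them best (max-pooling),
optionally excluding models, and enumerate all two-model hybrids.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import Dataset, FeatureError
from .feature_prep import PartisanshipBands
from .fitting import FitConfig, accuracy_score, fit_model
from .models import Model, TrialTable, build_trial_table, make_model


@dataclass
class ParticipantScore:
    participant_id: str
    model_name: str
    accuracy: float


def median_abs_deviation(x: Sequence[float]) -> float:
    """Median absolute deviation about the median."""
    arr = np.asarray(x, dtype=float)
    return float(np.median(np.abs(arr - np.median(arr))))


@dataclass
class ModelReport:
    """Per-participant accuracies of one model plus their aggregates."""

    model_name: str
    scores: list[ParticipantScore]
    mean: float = 0.0
    sd: float = 0.0
    median: float = 0.0
    mad: float = 0.0
    assignment: dict[str, str] | None = None  # hybrids: participant -> chosen model

    @classmethod
    def from_scores(cls, model_name: str, scores: list[ParticipantScore],
                    assignment: dict[str, str] | None = None) -> "ModelReport":
        acc = np.asarray([s.accuracy for s in scores], dtype=float)
        return cls(
            model_name=model_name,
            scores=scores,
            mean=float(acc.mean()) if len(acc) else float("nan"),
            sd=float(acc.std(ddof=1)) if len(acc) > 1 else 0.0,
            median=float(np.median(acc)) if len(acc) else float("nan"),
            mad=median_abs_deviation(acc) if len(acc) else float("nan"),
            assignment=assignment,
        )

    @property
    def accuracies(self) -> dict[str, float]:
        return {s.participant_id: s.accuracy for s in self.scores}

    def aggregate_row(self) -> dict:
        return {"model": self.model_name, "mean": self.mean, "sd": self.sd,
                "median": self.median, "mad": self.mad}

    def to_dict(self) -> dict:
        out = self.aggregate_row()
        out["scores"] = {s.participant_id: s.accuracy for s in self.scores}
        if self.assignment is not None:
            out["assignment"] = dict(self.assignment)
        return out


@dataclass
class HybridSpec:
    member_models: list[str]
    exclusions: list[str]
    assignment: dict[str, str]


def evaluate_model(
    model: Model | str,
    ds: Dataset,
    fit_config: FitConfig | None = None,
    mode: str = "EXPECTED",
    table: TrialTable | None = None,
    bands: PartisanshipBands | None = None,
) -> ModelReport:
    """Fit a model per its scope and score it per participant (train = test).

    ``mode`` EXPECTED scores the mean matched probability (the random
    baseline is then exactly 0.5 for every participant); DISCRETE counts
    binarized matches.  Participants without trials are excluded.
    """
    if isinstance(model, str):
        model = make_model(model)
    if model.table is None:
        model.bind(ds, bands=bands, table=table)
    if model.fitted_scope is None:
        fit_model(model, config=fit_config)
    t = model.table
    p_all = model.predict_table()
    scores: list[ParticipantScore] = []
    for k, pid in enumerate(t.participant_ids):
        rows = t.rows_of(k)
        if len(rows) == 0:
            continue
        acc = accuracy_score(p_all[rows], t.y[rows], mode)
        scores.append(ParticipantScore(pid, model.name, acc))
    return ModelReport.from_scores(model.name, scores)


def evaluate_models(
    names: Iterable[str],
    ds: Dataset,
    fit_config: FitConfig | None = None,
    mode: str = "EXPECTED",
    bands: PartisanshipBands | None = None,
    model_options: dict[str, dict] | None = None,
) -> tuple[dict[str, ModelReport], dict[str, Model]]:
    """Evaluate several models over one shared trial table."""
    table = build_trial_table(ds, bands)
    reports: dict[str, ModelReport] = {}
    models: dict[str, Model] = {}
    for name in names:
        opts = (model_options or {}).get(name, {})
        model = make_model(name, **opts)
        try:
            model.bind(ds, bands=bands, table=table)
        except FeatureError:
            continue  # model unavailable for this dataset's schema
        reports[name] = evaluate_model(model, ds, fit_config, mode, table=table)
        models[name] = model
    return reports, models


def hybrid_best_of(
    reports: Sequence[ModelReport] | dict[str, ModelReport],
    exclusions: Sequence[str] = (),
    name: str = "hybrid",
) -> tuple[ModelReport, HybridSpec]:
    """Best-of-k hybrid: per participant, the member model that scores highest.

    Ties break by member order.  ``exclusions`` removes models before
    maximization (e.g. re-running the hybrid without the Van Bavel model).
    """
    if isinstance(reports, dict):
        reports = list(reports.values())
    members = [r for r in reports if r.model_name not in set(exclusions)]
    if not members:
        raise ValueError("hybrid needs at least one member model")
    pids = [s.participant_id for s in members[0].scores]
    for r in members[1:]:
        if [s.participant_id for s in r.scores] != pids:
            raise ValueError("member reports must cover the same participants")
    lookup = [r.accuracies for r in members]
    assignment: dict[str, str] = {}
    scores: list[ParticipantScore] = []
    for pid in pids:
        accs = [lk[pid] for lk in lookup]
        best = int(np.argmax(accs))  # argmax takes the first maximum: member order
        assignment[pid] = members[best].model_name
        scores.append(ParticipantScore(pid, name, accs[best]))
    spec = HybridSpec(member_models=[r.model_name for r in members],
                      exclusions=list(exclusions), assignment=assignment)
    return ModelReport.from_scores(name, scores, assignment=assignment), spec


def enumerate_pair_hybrids(
    reports: Sequence[ModelReport] | dict[str, ModelReport],
    exclusions: Sequence[str] = (),
) -> pd.DataFrame:
    """Score every unordered pair of models as a two-member hybrid.

    Returns one row per pair with mean/sd/median/MAD, sorted by
    descending median then mean.
    """
    if isinstance(reports, dict):
        reports = list(reports.values())
    members = [r for r in reports if r.model_name not in set(exclusions)]
    if len(members) < 2:
        raise ValueError("pair enumeration needs at least two member models")
    rows = []
    for a, b in itertools.combinations(members, 2):
        rep, _ = hybrid_best_of([a, b], name=f"{a.model_name}+{b.model_name}")
        rows.append({"model_a": a.model_name, "model_b": b.model_name,
                     **{k: v for k, v in rep.aggregate_row().items() if k != "model"}})
    frame = pd.DataFrame(rows)
    return frame.sort_values(["median", "mean"], ascending=False,
                             kind="mergesort").reset_index(drop=True)


DEFAULT_CORR_FEATURES = (
    "real_news", "accept", "crt", "conservatism", "education",
    "fam_own", "fam_mean", "part_own", "part_mean", "reaction_time",
    "panas_p", "panas_n",
)


def correlation_matrix(
    ds: Dataset,
    models: dict[str, Model],
    features: Sequence[str] = DEFAULT_CORR_FEATURES,
    table: TrialTable | None = None,
) -> pd.DataFrame:
    """Pearson correlations over all trials between model predictions and features.

    Columns are the fitted models' expected predictions plus trial-level
    features (truth label and observed response enter as 0/1).  Constant
    columns yield NaN (undefined), not zero.
    """
    t = table if table is not None else build_trial_table(ds)
    if t.n_trials < 2:
        raise ValueError("correlation requires at least two trials")
    cols: dict[str, np.ndarray] = {}
    for name, model in models.items():
        cols[name] = model.predict_table()
    getters = {
        "real_news": lambda: t.truth_real.astype(float),
        "accept": lambda: t.y,
        "crt": lambda: t.crt,
        "conservatism": lambda: t.conservatism,
        "education": lambda: t.education,
        "fam_own": lambda: t.fam_own,
        "fam_mean": lambda: t.fam_mean,
        "part_own": lambda: t.part_own,
        "part_mean": lambda: t.part_mean,
        "reaction_time": lambda: t.reac,
        "panas_p": lambda: t.panas_p,
        "panas_n": lambda: t.panas_n,
    }
    for feat in features:
        if feat not in getters:
            raise FeatureError(f"unknown correlation feature {feat!r}")
        arr = getters[feat]()
        if arr is not None:
            cols[feat] = np.asarray(arr, dtype=float)
    names = list(cols)
    mat = np.vstack([cols[n] for n in names])
    sd = mat.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.atleast_2d(np.corrcoef(mat))
    corr[sd == 0, :] = np.nan  # constant columns: correlation undefined
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, np.where(sd == 0, np.nan, 1.0))
    return pd.DataFrame(corr, index=names, columns=names)


def reports_frame(reports: dict[str, ModelReport]) -> pd.DataFrame:
    """Aggregate table (one row per model) sorted by descending median."""
    frame = pd.DataFrame([r.aggregate_row() for r in reports.values()])
    return frame.sort_values(["median", "mean"], ascending=False,
                             kind="mergesort").reset_index(drop=True)
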