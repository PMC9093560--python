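"""Domain types and tabular I/O for news-acceptance trial data.

The central container is :class:`Dataset`: participants (with CRT,
conservatism, optional PANAS affect scores), news items (truth label,
pretest partisanship and familiarity aggregates per political group,
optional sentiment vectors) and trials (one Accept/Reject response per
participant x item pair, with reaction time).

Input tables are long-format delimited text, one row per participant x
item pair, with participant- and item-level columns repeated across
rows.  Because deposited study tables use differing column names, a
column-mapping config (YAML, ``field: column`` pairs) translates the
source layout into the canonical schema.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)


class Group(str, Enum):
    """Participant political group from the conservatism mean split."""

    REP = "REP"
    DEM = "DEM"


class Truth(str, Enum):
    REAL = "REAL"
    FAKE = "FAKE"


class Response(str, Enum):
    ACCEPT = "ACCEPT"
    REJECT = "REJECT"


class ItemClass(str, Enum):
    """Partisanship class of a news item (pretest aggregate)."""

    REP = "REP"
    DEM = "DEM"
    NEUTRAL = "NEUTRAL"


class SchemaError(ValueError):
    """A required column is missing from the source table or mapping."""


class IntegrityError(ValueError):
    """The table violates a dataset invariant (e.g. duplicated pair)."""


class FeatureError(ValueError):
    """A model or operation requires a feature the dataset lacks."""


@dataclass
class Participant:
    """A test person.

    ``crt`` is the mean fraction of correct answers on the cognitive
    reflection test, in [0, 1].  ``conservatism`` is on the study scale
    (1-7 or 1-5 depending on the experiment).  PANAS positive/negative
    affect scores are either both present or both absent.  ``group`` is
    derived by :func:`newsreason.feature_prep.split_participants`.
    """

    id: str
    crt: float
    conservatism: float
    education: float | None = None
    panas_p: float | None = None
    panas_n: float | None = None
    group: Group | None = None


@dataclass
class NewsItem:
    """A news headline task with pretest aggregates.

    Partisanship aggregates are on the pretest scale (high values =
    Republican-favorable); familiarity likewise is a pretest aggregate.
    ``*_rep`` / ``*_dem`` are aggregated over pretest respondents
    identified as Republican resp. Democrat; ``*_mean`` averages the two.
    ``sentiments`` is an optional vector of non-negative category scores.
    """

    id: str
    truth: Truth
    part_rep: float
    part_dem: float
    part_mean: float
    fam_rep: float
    fam_dem: float
    fam_mean: float
    headline: str | None = None
    importance_rep: float | None = None
    importance_dem: float | None = None
    worrying_rep: float | None = None
    worrying_dem: float | None = None
    exciting_rep: float | None = None
    exciting_dem: float | None = None
    sentiments: np.ndarray | None = None
    item_class: ItemClass | None = None


@dataclass
class Trial:
    """One (participant, item) presentation and the recorded response."""

    participant_id: str
    item_id: str
    response: Response
    raw_rating: int | None = None
    reaction_time: float | None = None
    reaction_z: float | None = None


@dataclass
class FeatureSchema:
    """Presence flags for optional columns plus scale bounds."""

    has_panas: bool = False
    has_extra_pretest: bool = False  # importance / worrying / exciting
    has_raw_ratings: bool = False
    has_headlines: bool = False
    has_sentiments: bool = False
    has_reaction_time: bool = True
    conservatism_scale: tuple[float, float] = (1.0, 7.0)
    partisanship_scale: tuple[float, float] = (1.0, 5.0)
    familiarity_scale: tuple[float, float] = (1.0, 3.0)
    sentiment_categories: tuple[str, ...] = ()


@dataclass
class Dataset:
    """Participants, items and trials of one experiment.

    Invariants: every trial references an existing participant and item;
    at most one trial exists per (participant, item) pair; the design is
    complete (equal per-participant trial counts).
    """

    participants: dict[str, Participant]
    items: dict[str, NewsItem]
    trials: list[Trial]
    schema: FeatureSchema = field(default_factory=FeatureSchema)
    n_dropped_rows: int = 0

    def trials_of(self, participant_id: str) -> list[Trial]:
        return [t for t in self.trials if t.participant_id == participant_id]

    @property
    def participant_ids(self) -> list[str]:
        return list(self.participants)


# ---------------------------------------------------------------------------
# Loading

MANDATORY_FIELDS = (
    "participant_id",
    "item_id",
    "crt",
    "conservatism",
    "truth",
    "part_rep",
    "part_dem",
    "fam_rep",
    "fam_dem",
)

OPTIONAL_FIELDS = (
    "response",
    "raw_rating",
    "reaction_time",
    "education",
    "panas_p",
    "panas_n",
    "headline",
    "part_mean",
    "fam_mean",
    "importance_rep",
    "importance_dem",
    "worrying_rep",
    "worrying_dem",
    "exciting_rep",
    "exciting_dem",
)

_TRUTH_ALIASES = {
    "real": Truth.REAL, "true": Truth.REAL, "1": Truth.REAL,
    "fake": Truth.FAKE, "false": Truth.FAKE, "0": Truth.FAKE,
}
_RESPONSE_ALIASES = {
    "accept": Response.ACCEPT, "1": Response.ACCEPT, "true": Response.ACCEPT,
    "reject": Response.REJECT, "0": Response.REJECT, "false": Response.REJECT,
}


def _sniff_sep(path: Path) -> str:
    header = path.open("r", encoding="utf-8").readline()
    return "\t" if "\t" in header else ","


def load_mapping(mapping: str | Path | Mapping[str, str]) -> dict[str, str]:
    """Load a ``field: source-column`` mapping from YAML or pass a dict through."""
    if isinstance(mapping, (str, Path)):
        with open(mapping, "r", encoding="utf-8") as fh:
            mapping = yaml.safe_load(fh)
    if not isinstance(mapping, Mapping):
        raise SchemaError("column mapping must be a mapping of field -> column")
    return {str(k): str(v) for k, v in mapping.items() if v is not None}


def load_dataset(
    table_path: str | Path,
    mapping: str | Path | Mapping[str, str],
    *,
    sentiment_prefix: str | None = None,
    conservatism_scale: tuple[float, float] = (1.0, 7.0),
    partisanship_scale: tuple[float, float] = (1.0, 5.0),
    familiarity_scale: tuple[float, float] = (1.0, 3.0),
) -> Dataset:
    """Read a long-format delimited table into a validated :class:`Dataset`.

    ``mapping`` names, for every canonical field, the source column that
    carries it.  Either ``response`` (binary) or ``raw_rating`` (1-4 scale,
    binarized downstream) must be mapped.  Rows missing a mandatory field
    are dropped and counted; a duplicated (participant, item) pair raises
    :class:`IntegrityError`.  ``sentiment_prefix`` collects columns named
    ``<prefix><category>`` into per-item sentiment vectors.
    """
    table_path = Path(table_path)
    colmap = load_mapping(mapping)
    df = pd.read_csv(table_path, sep=_sniff_sep(table_path))

    for fld in MANDATORY_FIELDS:
        if fld not in colmap:
            raise SchemaError(f"mapping does not name a column for mandatory field {fld!r}")
        if colmap[fld] not in df.columns:
            raise SchemaError(f"source table has no column {colmap[fld]!r} (field {fld!r})")
    if "response" not in colmap and "raw_rating" not in colmap:
        raise SchemaError("mapping must name a column for 'response' or 'raw_rating'")

    present = {f: c for f, c in colmap.items() if c in df.columns}
    sent_cols: list[str] = []
    if sentiment_prefix:
        sent_cols = sorted(c for c in df.columns if c.startswith(sentiment_prefix))

    response_fields = [f for f in ("response", "raw_rating") if f in present]
    required_cols = [present[f] for f in MANDATORY_FIELDS] + [present[f] for f in response_fields]
    n_source = len(df)
    kept = df.dropna(subset=required_cols)
    n_dropped = n_source - len(kept)
    if n_dropped:
        logger.info("load_dataset: dropped %d of %d rows with missing mandatory fields",
                    n_dropped, n_source)

    participants: dict[str, Participant] = {}
    items: dict[str, NewsItem] = {}
    trials: list[Trial] = []
    seen_pairs: set[tuple[str, str]] = set()

    def _opt(row, fld):
        col = present.get(fld)
        if col is None:
            return None
        v = row[col]
        return None if pd.isna(v) else v

    for _, row in kept.iterrows():
        pid = str(row[present["participant_id"]])
        iid = str(row[present["item_id"]])
        if (pid, iid) in seen_pairs:
            raise IntegrityError(f"duplicate trial for pair ({pid!r}, {iid!r})")
        seen_pairs.add((pid, iid))

        if pid not in participants:
            panas_p, panas_n = _opt(row, "panas_p"), _opt(row, "panas_n")
            participants[pid] = Participant(
                id=pid,
                crt=float(row[present["crt"]]),
                conservatism=float(row[present["conservatism"]]),
                education=_maybe_float(_opt(row, "education")),
                panas_p=_maybe_float(panas_p),
                panas_n=_maybe_float(panas_n),
            )
        if iid not in items:
            part_rep = float(row[present["part_rep"]])
            part_dem = float(row[present["part_dem"]])
            fam_rep = float(row[present["fam_rep"]])
            fam_dem = float(row[present["fam_dem"]])
            part_mean = _maybe_float(_opt(row, "part_mean"))
            fam_mean = _maybe_float(_opt(row, "fam_mean"))
            sent = None
            if sent_cols:
                sent = np.asarray([float(row[c]) for c in sent_cols], dtype=float)
            items[iid] = NewsItem(
                id=iid,
                truth=_parse_truth(row[present["truth"]]),
                part_rep=part_rep, part_dem=part_dem,
                part_mean=part_mean if part_mean is not None else (part_rep + part_dem) / 2.0,
                fam_rep=fam_rep, fam_dem=fam_dem,
                fam_mean=fam_mean if fam_mean is not None else (fam_rep + fam_dem) / 2.0,
                headline=_maybe_str(_opt(row, "headline")),
                importance_rep=_maybe_float(_opt(row, "importance_rep")),
                importance_dem=_maybe_float(_opt(row, "importance_dem")),
                worrying_rep=_maybe_float(_opt(row, "worrying_rep")),
                worrying_dem=_maybe_float(_opt(row, "worrying_dem")),
                exciting_rep=_maybe_float(_opt(row, "exciting_rep")),
                exciting_dem=_maybe_float(_opt(row, "exciting_dem")),
                sentiments=sent,
            )

        raw = _opt(row, "raw_rating")
        raw_rating = int(raw) if raw is not None else None
        if "response" in present:
            response = _parse_response(row[present["response"]])
        else:
            from .feature_prep import binarize_response  # late import, no cycle at module load
            response = binarize_response(raw_rating)
        trials.append(Trial(
            participant_id=pid, item_id=iid, response=response,
            raw_rating=raw_rating,
            reaction_time=_maybe_float(_opt(row, "reaction_time")),
        ))

    any_part = next(iter(participants.values()), None)
    schema = FeatureSchema(
        has_panas=any_part is not None and any_part.panas_p is not None,
        has_extra_pretest=any(i.importance_rep is not None for i in items.values()),
        has_raw_ratings="raw_rating" in present,
        has_headlines=any(i.headline is not None for i in items.values()),
        has_sentiments=bool(sent_cols),
        has_reaction_time=any(t.reaction_time is not None for t in trials),
        conservatism_scale=conservatism_scale,
        partisanship_scale=partisanship_scale,
        familiarity_scale=familiarity_scale,
        sentiment_categories=tuple(c[len(sentiment_prefix):] for c in sent_cols)
        if sentiment_prefix else (),
    )
    return Dataset(participants=participants, items=items, trials=trials,
                   schema=schema, n_dropped_rows=n_dropped)


def _maybe_float(v) -> float | None:
    return None if v is None else float(v)


def _maybe_str(v) -> str | None:
    return None if v is None else str(v)


def _parse_truth(v) -> Truth:
    key = str(v).strip().lower()
    if key in _TRUTH_ALIASES:
        return _TRUTH_ALIASES[key]
    raise SchemaError(f"unrecognized truth label {v!r}")


def _parse_response(v) -> Response:
    key = str(v).strip().lower()
    if key in _RESPONSE_ALIASES:
        return _RESPONSE_ALIASES[key]
    raise SchemaError(f"unrecognized response value {v!r}")


# ---------------------------------------------------------------------------
# Validation


def validate_dataset(ds: Dataset) -> list[str]:
    """Check every dataset invariant; return one message per violation.

    An empty list means the dataset is valid.  Checks: CRT range,
    finite pretest aggregates, PANAS consistency, orphan trial
    references, duplicated pairs and completeness of the design.
    """
    report: list[str] = []
    for p in ds.participants.values():
        if not (0.0 <= p.crt <= 1.0):
            report.append(f"participant {p.id}: crt {p.crt} outside [0, 1]")
        if (p.panas_p is None) != (p.panas_n is None):
            report.append(f"participant {p.id}: PANAS fields must be both present or both absent")
        if not math.isfinite(p.conservatism):
            report.append(f"participant {p.id}: non-finite conservatism")
    for item in ds.items.values():
        for name in ("part_rep", "part_dem", "part_mean", "fam_rep", "fam_dem", "fam_mean"):
            if not math.isfinite(getattr(item, name)):
                report.append(f"item {item.id}: non-finite {name}")
        if item.sentiments is not None:
            ncat = len(ds.schema.sentiment_categories)
            if ncat and len(item.sentiments) != ncat:
                report.append(f"item {item.id}: sentiment vector length {len(item.sentiments)} "
                              f"!= schema length {ncat}")
            if np.any(np.asarray(item.sentiments) < 0):
                report.append(f"item {item.id}: negative sentiment score")

    seen: set[tuple[str, str]] = set()
    counts: dict[str, int] = {}
    for t in ds.trials:
        if t.participant_id not in ds.participants:
            report.append(f"trial references unknown participant {t.participant_id!r}")
        if t.item_id not in ds.items:
            report.append(f"trial references unknown item {t.item_id!r}")
        pair = (t.participant_id, t.item_id)
        if pair in seen:
            report.append(f"duplicate trial for pair {pair!r}")
        seen.add(pair)
        counts[t.participant_id] = counts.get(t.participant_id, 0) + 1
        if t.reaction_time is not None and t.reaction_time < 0:
            report.append(f"trial {pair!r}: negative reaction time")
        if t.raw_rating is not None and t.raw_rating not in (1, 2, 3, 4):
            report.append(f"trial {pair!r}: raw rating {t.raw_rating} outside 1..4")
    if counts and len(set(counts.values())) > 1:
        report.append(f"incomplete design: per-participant trial counts differ {sorted(set(counts.values()))}")
    return report


# ---------------------------------------------------------------------------
# Report I/O


def write_report(report, path: str | Path, format: str = "delimited") -> None:
    """Write an evaluation report to disk.

    ``delimited`` writes the aggregate table (one row per model) as CSV
    with full-precision floats; ``structured`` writes JSON that also
    carries per-participant scores and, for hybrids, the chosen
    sub-model per participant.  Reading the file back reproduces every
    numeric field exactly (shortest round-trip float formatting).
    """
    from .evaluation import ModelReport  # avoid import cycle at module load

    reports = [report] if isinstance(report, ModelReport) else list(report)
    path = Path(path)
    if format == "delimited":
        rows = [r.aggregate_row() for r in reports]
        frame = pd.DataFrame(rows, columns=["model", "mean", "sd", "median", "mad"])
        frame.to_csv(path, index=False, float_format=lambda x: repr(float(x)))
    elif format == "structured":
        payload = [r.to_dict() for r in reports]
        with path.open("w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: str = "delimited"):
    """Read back a report written by :func:`write_report`."""
    path = Path(path)
    if format == "delimited":
        return pd.read_csv(path, float_precision="round_trip")
    if format == "structured":
        with path.open("r", encoding="utf-8") as fh:
            return json.load(fh)
    raise ValueError(f"unknown report format {format!r}")
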