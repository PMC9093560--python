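"""Derived features the decision models consume.

Covers the participant partisanship mean-split, item partisanship
classification with a neutral band, own-group resolution of pretest
aggregates, binarization of 1-4 accuracy ratings, lexicon-based
sentiment scoring of headlines and top-k sentiment category selection.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .data_model import (
    Dataset,
    FeatureError,
    Group,
    ItemClass,
    NewsItem,
    Participant,
    Response,
)

logger = logging.getLogger(__name__)

_TOKEN_SPLIT = re.compile(r"[^a-z]+")


@dataclass
class PartisanshipBands:
    """Neutral band around the item-partisanship scale midpoint.

    Items whose mean pretest partisanship lies within ``neutral_halfwidth``
    of the scale midpoint are classed NEUTRAL (boundary inclusive); above
    the band they are Republican-favorable, below Democrat-favorable.
    """

    neutral_halfwidth: float = 0.5
    scale: tuple[float, float] = (1.0, 5.0)

    def __post_init__(self) -> None:
        lo, hi = self.scale
        if self.neutral_halfwidth < 0 or self.neutral_halfwidth >= (hi - lo) / 2.0:
            raise ValueError("neutral_halfwidth must be in [0, half the scale range)")

    @property
    def midpoint(self) -> float:
        lo, hi = self.scale
        return (lo + hi) / 2.0


@dataclass
class SentimentSelection:
    """The retained sentiment categories and the lexicon that scores them."""

    k: int
    categories: list[str]
    lexicon: dict[str, set[str]] = field(default_factory=dict)


def split_participants(
    participants: Iterable[Participant], scale: tuple[float, float] | None = None
) -> dict[str, Group]:
    """Assign each participant REP or DEM by a mean split on conservatism.

    A participant is REP iff their conservatism strictly exceeds the
    dataset mean; ties (= mean) go to DEM.  Mutates ``group`` in place
    and returns the id -> group map.
    """
    participants = list(participants)
    if not participants:
        raise ValueError("cannot split an empty participant set")
    mean = float(np.mean([p.conservatism for p in participants]))
    out: dict[str, Group] = {}
    for p in participants:
        p.group = Group.REP if p.conservatism > mean else Group.DEM
        out[p.id] = p.group
    return out


def classify_item(item: NewsItem, bands: PartisanshipBands) -> ItemClass:
    """Class an item NEUTRAL / REP / DEM from its mean pretest partisanship."""
    delta = item.part_mean - bands.midpoint
    if abs(delta) <= bands.neutral_halfwidth:
        return ItemClass.NEUTRAL
    return ItemClass.REP if delta > 0 else ItemClass.DEM


_GROUP_FEATURES = ("part", "fam", "importance", "worrying", "exciting")


def resolve_group_feature(
    item: NewsItem,
    participant: Participant | None,
    feature_name: str,
    mode: str = "own_group",
):
    """Resolve a per-group pretest aggregate for one participant.

    ``own_group`` returns the REP or DEM aggregate matching the
    participant's group; ``mean`` returns the two-group mean; ``both``
    returns ``(own_group, mean)``.
    """
    if feature_name not in _GROUP_FEATURES:
        raise FeatureError(f"unknown per-group feature {feature_name!r}")

    def _get(suffix: str):
        if feature_name == "part" and suffix == "mean":
            return item.part_mean
        if feature_name == "fam" and suffix == "mean":
            return item.fam_mean
        value = getattr(item, f"{feature_name}_{suffix}", None)
        if value is None:
            raise FeatureError(f"item {item.id}: aggregate {feature_name}_{suffix} absent")
        return value

    if mode == "mean":
        if feature_name in ("importance", "worrying", "exciting"):
            return (_get("rep") + _get("dem")) / 2.0
        return _get("mean")
    if mode in ("own_group", "both"):
        if participant is None or participant.group is None:
            raise FeatureError("participant group must be assigned before own-group resolution")
        own = _get("rep" if participant.group is Group.REP else "dem")
        if mode == "own_group":
            return own
        return (own, resolve_group_feature(item, participant, feature_name, "mean"))
    raise ValueError(f"unknown resolution mode {mode!r}")


def binarize_response(raw_rating: int) -> Response:
    """Map a 1-4 accuracy rating to Accept/Reject at the scale midpoint.

    Ratings 1-2 ("not at all / not very accurate") map to REJECT,
    3-4 ("somewhat / very accurate") to ACCEPT.
    """
    if raw_rating not in (1, 2, 3, 4):
        raise ValueError(f"raw rating must be in 1..4, got {raw_rating!r}")
    return Response.ACCEPT if raw_rating >= 3 else Response.REJECT


def tokenize(text: str) -> list[str]:
    """Lowercase and split on non-alphabetic characters."""
    return [t for t in _TOKEN_SPLIT.split(text.lower()) if t]


def load_lexicon(path: str | Path) -> dict[str, set[str]]:
    """Load a word -> categories lexicon from YAML."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return {str(w): set(map(str, cats)) for w, cats in raw.items()}


def builtin_lexicon() -> dict[str, set[str]]:
    """The packaged synthetic fixture lexicon (small, hand-written)."""
    return load_lexicon(Path(__file__).parent / "data" / "synthetic_lexicon.yaml")


def score_sentiments(
    headline: str | None,
    lexicon: Mapping[str, set[str]],
    categories: Sequence[str] | None = None,
) -> dict[str, float] | np.ndarray:
    """Score a headline against lexicon categories.

    The score of category ``c`` is the number of headline tokens mapped
    to ``c`` divided by the total token count, so each score lies in
    [0, 1].  An empty headline yields zeros.  When ``categories`` is
    given, returns a vector in that order; otherwise a dict over every
    category seen.
    """
    if not lexicon:
        raise ValueError("lexicon must be non-empty")
    tokens = tokenize(headline or "")
    counts: dict[str, int] = {}
    for tok in tokens:
        for cat in lexicon.get(tok, ()):
            counts[cat] = counts.get(cat, 0) + 1
    n = len(tokens)
    scores = {c: cnt / n for c, cnt in counts.items()} if n else {}
    if categories is None:
        return scores
    return np.asarray([scores.get(c, 0.0) for c in categories], dtype=float)


def select_top_sentiments(
    items: Iterable[NewsItem],
    lexicon: Mapping[str, set[str]],
    k: int = 10,
) -> SentimentSelection:
    """Retain the k categories most frequently detected across item headlines.

    Categories are ranked by the number of items with a non-zero score;
    ties break lexicographically by category name.  If fewer than ``k``
    categories are ever detected, all detected ones are retained with a
    warning.  The choice of 10 keeps the weighted-sentiments model
    comparable across datasets of different sizes.
    """
    item_counts: dict[str, int] = {}
    for item in items:
        scores = score_sentiments(item.headline, lexicon)
        for cat, val in scores.items():
            if val > 0:
                item_counts[cat] = item_counts.get(cat, 0) + 1
    ranked = sorted(item_counts, key=lambda c: (-item_counts[c], c))
    if len(ranked) < k:
        logger.warning("only %d sentiment categories detected; requested top %d",
                       len(ranked), k)
    chosen = ranked[:k]
    return SentimentSelection(k=len(chosen), categories=chosen, lexicon=dict(lexicon))


def attach_sentiments(ds: Dataset, selection: SentimentSelection) -> None:
    """Score every item headline on the selected categories, in place."""
    for item in ds.items.values():
        item.sentiments = score_sentiments(item.headline, selection.lexicon,
                                           selection.categories)
    ds.schema.has_sentiments = True
    ds.schema.sentiment_categories = tuple(selection.categories)


def prepare_dataset(ds: Dataset, bands: PartisanshipBands | None = None) -> Dataset:
    """Compute all derived features in place: groups, item classes, RT z-scores.

    Group membership and item classes are computed once per dataset,
    before any fitting.  Reaction times are standardized within each
    participant (z-score); a participant with constant reaction times
    gets zeros.
    """
    if bands is None:
        bands = PartisanshipBands(scale=ds.schema.partisanship_scale)
    split_participants(ds.participants.values())
    for item in ds.items.values():
        item.item_class = classify_item(item, bands)

    by_pid: dict[str, list] = {}
    for t in ds.trials:
        if t.reaction_time is not None:
            by_pid.setdefault(t.participant_id, []).append(t)
    for trials in by_pid.values():
        arr = np.asarray([t.reaction_time for t in trials], dtype=float)
        mu, sd = float(arr.mean()), float(arr.std())
        for t, rt in zip(trials, arr):
            t.reaction_z = 0.0 if sd == 0 else float((rt - mu) / sd)
    return ds
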