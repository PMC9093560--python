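"""Shared fixtures: small hand-built datasets and helpers."""

from __future__ import annotations

import numpy as np
import pytest

from newsreason.data_model import (
    Dataset,
    FeatureSchema,
    NewsItem,
    Participant,
    Response,
    Trial,
    Truth,
)
from newsreason.feature_prep import prepare_dataset


def make_participant(pid="p1", crt=0.5, conservatism=3.0, **kw) -> Participant:
    return Participant(id=pid, crt=crt, conservatism=conservatism, **kw)


def make_item(iid="i1", truth=Truth.REAL, part=3.0, fam=2.0, **kw) -> NewsItem:
    defaults = dict(part_rep=part, part_dem=part, part_mean=part,
                    fam_rep=fam, fam_dem=fam, fam_mean=fam)
    defaults.update(kw)
    return NewsItem(id=iid, truth=truth, **defaults)


def build_dataset(participants, items, responses, reaction_times=None,
                  schema=None, prepare=True) -> Dataset:
    """Assemble a complete-design dataset from a (participant x item) response grid."""
    trials = []
    for a, p in enumerate(participants):
        for b, item in enumerate(items):
            rt = reaction_times[a][b] if reaction_times is not None else 1.0
            trials.append(Trial(participant_id=p.id, item_id=item.id,
                                response=responses[a][b], reaction_time=rt))
    ds = Dataset(participants={p.id: p for p in participants},
                 items={i.id: i for i in items},
                 trials=trials,
                 schema=schema or FeatureSchema(partisanship_scale=(1.0, 5.0)))
    if prepare:
        prepare_dataset(ds)
    return ds


A, R = Response.ACCEPT, Response.REJECT


@pytest.fixture
def toy_dataset() -> Dataset:
    """2 participants x 4 items (2 real, 2 fake), varied features."""
    participants = [
        make_participant("p1", crt=0.2, conservatism=2.0),
        make_participant("p2", crt=0.8, conservatism=6.0),
    ]
    items = [
        make_item("r1", Truth.REAL, part=4.5, fam=2.5),
        make_item("r2", Truth.REAL, part=1.5, fam=1.2),
        make_item("f1", Truth.FAKE, part=3.0, fam=2.8),
        make_item("f2", Truth.FAKE, part=4.0, fam=1.5),
    ]
    responses = [[A, R, A, R], [A, A, R, R]]
    rts = [[1.0, 2.0, 3.0, 4.0], [2.0, 2.0, 1.0, 5.0]]
    return build_dataset(participants, items, responses, rts,
                         schema=FeatureSchema(conservatism_scale=(1, 7)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
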