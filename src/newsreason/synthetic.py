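"""Synthetic datasets with the statistical structure of the news-judgment studies.

The generator emulates the deposited experiments' schema: participants
with CRT scores, conservatism, optionally PANAS affect; real and fake
news items with per-group pretest partisanship and familiarity
aggregates and sparse sentiment vectors; one trial per participant x
item with reaction time.  Responses are produced by a configurable
*responder mixture*: each participant is assigned one generating model
(with ground-truth parameters, possibly drawn per participant) and
answers ACCEPT with the model's expected prediction, then the response
is flipped with probability ``noise_rate``.  The mixture embodies the
adaptive-toolbox hypothesis that different participants employ
different cognitive tools.

The ground truth (assignment and parameters per participant) is always
returned and serializable alongside the dataset; recovery tests read
it, the pipeline under test never does.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_model import (
    Dataset,
    FeatureSchema,
    NewsItem,
    Participant,
    Response,
    Trial,
    Truth,
)
from .feature_prep import prepare_dataset
from .models import build_trial_table, make_model

#: Experiment-like item shapes: 15/15, 12/12 or 18/18 real/fake items.
ALLOWED_SHAPES = {(15, 15), (12, 12), (18, 18)}

#: Default ground-truth responder mixture spanning the model families.
#: Scalar parameter entries are fixed; ("uniform", lo, hi) and
#: ("normal", mu, sd) are drawn per participant.
DEFAULT_MIXTURE: list[tuple[str, dict, float]] = [
    ("cr", {"kappa_R": 0.45, "alpha_R": 0.35, "kappa_F": 0.45, "alpha_F": -0.30}, 0.30),
    ("recognition", {"kappa_i": ("uniform", 1.6, 2.4)}, 0.25),
    ("ms2r", {"kappa_C": 0.35, "alpha_C": 0.50, "kappa_N": 0.45, "alpha_N": -0.30}, 0.15),
    ("sentiments", {"alphas": ("normal", 0.0, 1.0)}, 0.15),
    ("van_bavel", {"alpha": 0.12, "kappa_R": 0.20, "beta_R": 0.02, "gamma_R": 0.04,
                   "kappa_F": -0.05, "beta_F": 0.02, "gamma_F": 0.03,
                   "kappa_p": 0.08}, 0.15),
]


@dataclass
class SyntheticConfig:
    """Generating distributions and responder mixture.

    Defaults emulate the third experiment's shape: 18 real and 18 fake
    items, PANAS present, conservatism on a 1-5 scale.  CRT ~ Beta(2, 2)
    on [0, 1]; conservatism uniform over its scale; familiarity a
    truncated normal on the 1-3 pretest scale; partisan items sit near
    the scale poles and neutral items at the midpoint; reaction times
    are log-normal.  ``noise_rate`` is the probability of flipping a
    generated response (0.1 by default — an ordinary lapse rate; recovery
    scenarios set it to 0).
    """

    n_participants: int = 200
    n_real_items: int = 18
    n_fake_items: int = 18
    crt_distribution: tuple = ("beta", 2.0, 2.0)
    conservatism_scale: tuple[float, float] = (1.0, 5.0)
    conservatism_distribution: tuple | None = None  # default: uniform over scale
    panas_enabled: bool = True
    panas_distribution: tuple = ("truncnorm", 30.0, 7.0, 10.0, 50.0)
    partisanship_scale: tuple[float, float] = (1.0, 5.0)
    p_neutral_items: float = 1.0 / 3.0
    partisan_pole_sd: float = 0.30
    group_disagreement_sd: float = 0.10
    familiarity_scale: tuple[float, float] = (1.0, 3.0)
    familiarity_distribution: tuple = ("truncnorm", 2.0, 0.5, 1.0, 3.0)
    sentiment_dim: int = 10
    sentiment_sparsity: float = 0.25  # probability a category score is non-zero
    reaction_time_distribution: tuple = ("lognormal", 1.8, 0.4)
    responder_mixture: list[tuple[str, dict, float]] = field(
        default_factory=lambda: [tuple(m) for m in DEFAULT_MIXTURE])
    noise_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.n_real_items, self.n_fake_items) not in ALLOWED_SHAPES:
            raise ValueError(
                f"item shape {(self.n_real_items, self.n_fake_items)} is not one of "
                f"the experiment shapes {sorted(ALLOWED_SHAPES)}")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must lie in [0, 1]")
        total = sum(w for _, _, w in self.responder_mixture)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture weights sum to {total}, expected 1")


def _draw(rng: np.random.Generator, spec: tuple, size=None) -> np.ndarray | float:
    family, *args = spec
    if family == "beta":
        return rng.beta(args[0], args[1], size=size)
    if family == "uniform":
        return rng.uniform(args[0], args[1], size=size)
    if family == "normal":
        return rng.normal(args[0], args[1], size=size)
    if family == "truncnorm":
        mu, sd, lo, hi = args
        out = rng.normal(mu, sd, size=size)
        return np.clip(out, lo, hi)
    if family == "lognormal":
        return rng.lognormal(args[0], args[1], size=size)
    if family == "constant":
        return np.full(size, args[0]) if size else args[0]
    raise ValueError(f"unknown distribution family {family!r}")


def _resolve_param(rng: np.random.Generator, value, size: int | None = None):
    """Fixed numbers pass through; tuple specs are drawn per participant."""
    if isinstance(value, tuple):
        return _draw(rng, value, size=size)
    if isinstance(value, (list, np.ndarray)):
        return np.asarray(value, dtype=float)
    return float(value) if size is None else np.full(size, float(value))


def _param_vector(model_name: str, model, resolved: dict) -> np.ndarray:
    if model_name == "sentiments":
        return np.asarray(resolved["alphas"], dtype=float)
    return np.asarray([resolved[n] for n in model.param_names], dtype=float)


def generate_dataset(cfg: SyntheticConfig) -> tuple[Dataset, dict]:
    """Generate a dataset plus its ground-truth record, fully seed-determined."""
    rng = np.random.default_rng(cfg.seed)

    # Participants ---------------------------------------------------------
    participants: dict[str, Participant] = {}
    cons_spec = cfg.conservatism_distribution or ("uniform", *cfg.conservatism_scale)
    for k in range(cfg.n_participants):
        pid = f"p{k:04d}"
        panas_p = panas_n = None
        if cfg.panas_enabled:
            panas_p = float(_draw(rng, cfg.panas_distribution))
            panas_n = float(_draw(rng, cfg.panas_distribution))
        participants[pid] = Participant(
            id=pid,
            crt=float(_draw(rng, cfg.crt_distribution)),
            conservatism=float(_draw(rng, cons_spec)),
            education=float(rng.integers(1, 9)),
            panas_p=panas_p,
            panas_n=panas_n,
        )

    # Items ----------------------------------------------------------------
    lo, hi = cfg.partisanship_scale
    mid = (lo + hi) / 2.0
    items: dict[str, NewsItem] = {}
    for truth, count, prefix in ((Truth.REAL, cfg.n_real_items, "r"),
                                 (Truth.FAKE, cfg.n_fake_items, "f")):
        for k in range(count):
            iid = f"{prefix}{k:03d}"
            if rng.random() < cfg.p_neutral_items:
                part_mean = float(np.clip(rng.normal(mid, 0.1), lo, hi))
            else:
                pole = lo + 0.5 if rng.random() < 0.5 else hi - 0.5
                part_mean = float(np.clip(rng.normal(pole, cfg.partisan_pole_sd), lo, hi))
            d = rng.normal(0.0, cfg.group_disagreement_sd)
            part_rep = float(np.clip(part_mean + d, lo, hi))
            part_dem = float(np.clip(part_mean - d, lo, hi))
            fam_rep = float(_draw(rng, cfg.familiarity_distribution))
            fam_dem = float(_draw(rng, cfg.familiarity_distribution))
            nz = rng.random(cfg.sentiment_dim) < cfg.sentiment_sparsity
            sent = np.where(nz, rng.uniform(0.05, 0.4, cfg.sentiment_dim), 0.0)
            extra = {}
            if cfg.panas_enabled:
                for name in ("importance", "worrying", "exciting"):
                    extra[f"{name}_rep"] = float(_draw(rng, ("truncnorm", 3.0, 0.8, 1.0, 5.0)))
                    extra[f"{name}_dem"] = float(_draw(rng, ("truncnorm", 3.0, 0.8, 1.0, 5.0)))
            items[iid] = NewsItem(
                id=iid, truth=truth,
                part_rep=part_rep, part_dem=part_dem,
                part_mean=(part_rep + part_dem) / 2.0,
                fam_rep=fam_rep, fam_dem=fam_dem,
                fam_mean=(fam_rep + fam_dem) / 2.0,
                sentiments=sent, **extra,
            )

    # Trials (responses filled below) ---------------------------------------
    trials = [
        Trial(participant_id=pid, item_id=iid, response=Response.REJECT,
              reaction_time=float(_draw(rng, cfg.reaction_time_distribution)))
        for pid in participants for iid in items
    ]
    schema = FeatureSchema(
        has_panas=cfg.panas_enabled,
        has_extra_pretest=cfg.panas_enabled,
        has_sentiments=True,
        has_reaction_time=True,
        conservatism_scale=cfg.conservatism_scale,
        partisanship_scale=cfg.partisanship_scale,
        familiarity_scale=cfg.familiarity_scale,
        sentiment_categories=tuple(f"c{k}" for k in range(cfg.sentiment_dim)),
    )
    ds = Dataset(participants=participants, items=items, trials=trials, schema=schema)
    prepare_dataset(ds)
    table = build_trial_table(ds)

    # Responder assignment and response generation --------------------------
    weights = np.asarray([w for _, _, w in cfg.responder_mixture])
    component = rng.choice(len(weights), size=cfg.n_participants, p=weights)
    model_cache: dict[str, object] = {}
    truth_record: dict = {
        "seed": cfg.seed, "noise_rate": cfg.noise_rate, "participants": {}}
    pids = list(participants)
    for k, pid in enumerate(pids):
        name, param_spec, _ = cfg.responder_mixture[component[k]]
        if name not in model_cache:
            model_cache[name] = make_model(name).bind(ds, table=table)
        model = model_cache[name]
        resolved = {}
        for pname, value in param_spec.items():
            if pname == "alphas":
                resolved[pname] = (_draw(rng, value, size=cfg.sentiment_dim)
                                   if isinstance(value, tuple)
                                   else np.asarray(value, dtype=float))
            elif pname == "base":
                resolved[pname] = np.asarray(value, dtype=float)
            else:
                resolved[pname] = _resolve_param(rng, value)
        if "base" in resolved:  # CR-extension responders carry their CR base
            model.base_cr = resolved["base"]
        pvec = _param_vector(name, model, resolved)
        rows = table.rows_of(k)
        p = model.predict_vec(pvec, rows)
        accept = rng.random(len(rows)) < p
        flip = rng.random(len(rows)) < cfg.noise_rate
        accept = accept ^ flip
        for r, a in zip(rows, accept):
            ds.trials[r].response = Response.ACCEPT if a else Response.REJECT
        truth_record["participants"][pid] = {
            "model": name,
            "params": {pn: (v.tolist() if isinstance(v, np.ndarray) else float(v))
                       for pn, v in resolved.items()},
        }
    return ds, truth_record


def save_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1), encoding="utf-8")


def dataset_to_frame(ds: Dataset):
    """Flatten a dataset to the long-format table `load_dataset` consumes."""
    import pandas as pd

    rows = []
    for t in ds.trials:
        p = ds.participants[t.participant_id]
        i = ds.items[t.item_id]
        row = {
            "subject": p.id, "item": i.id,
            "response": t.response.value,
            "rt": t.reaction_time,
            "crt_score": p.crt, "conservatism": p.conservatism,
            "education": p.education,
            "veracity": i.truth.value,
            "part_rep": i.part_rep, "part_dem": i.part_dem,
            "fam_rep": i.fam_rep, "fam_dem": i.fam_dem,
        }
        if p.panas_p is not None:
            row["panas_pos"], row["panas_neg"] = p.panas_p, p.panas_n
        if i.sentiments is not None:
            for c, v in zip(ds.schema.sentiment_categories, i.sentiments):
                row[f"s_{c}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


#: Column mapping matching `dataset_to_frame` output.
SYNTHETIC_MAPPING = {
    "participant_id": "subject", "item_id": "item", "response": "response",
    "reaction_time": "rt", "crt": "crt_score", "conservatism": "conservatism",
    "education": "education", "truth": "veracity",
    "part_rep": "part_rep", "part_dem": "part_dem",
    "fam_rep": "fam_rep", "fam_dem": "fam_dem",
    "panas_p": "panas_pos", "panas_n": "panas_neg",
}


def generate_recovery_suite(
    cfg: SyntheticConfig | None = None,
    noise_rates: Sequence[float] = (0.0, 0.1),
) -> dict[str, tuple[Dataset, dict]]:
    """A battery of pure-responder and mixed-toolbox scenarios.

    Each model family appears once as the sole responder (parameters as
    in :data:`DEFAULT_MIXTURE`), plus a two-model mixture scenario, at
    every noise rate in ``noise_rates``.
    """
    base = cfg or SyntheticConfig()
    scenarios: dict[str, list[tuple[str, dict, float]]] = {
        f"pure_{name}": [(name, params, 1.0)]
        for name, params, _ in DEFAULT_MIXTURE
    }
    scenarios["toolbox_cr_recognition"] = [
        ("cr", DEFAULT_MIXTURE[0][1], 0.5),
        ("recognition", DEFAULT_MIXTURE[1][1], 0.5),
    ]
    suite: dict[str, tuple[Dataset, dict]] = {}
    for sname, mixture in scenarios.items():
        for j, noise in enumerate(noise_rates):
            cfg_s = SyntheticConfig(
                n_participants=base.n_participants,
                n_real_items=base.n_real_items,
                n_fake_items=base.n_fake_items,
                crt_distribution=base.crt_distribution,
                conservatism_scale=base.conservatism_scale,
                panas_enabled=base.panas_enabled,
                sentiment_dim=base.sentiment_dim,
                responder_mixture=mixture,
                noise_rate=noise,
                seed=base.seed + 1000 * j + (zlib.crc32(sname.encode()) % 997),
            )
            suite[f"{sname}@noise{noise}"] = generate_dataset(cfg_s)
    return suite
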