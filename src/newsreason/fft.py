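"""Fast-and-Frugal Tree induction with Take-The-Best cue ordering.

An FFT is an ordered list of binarized cues, each with one exit leaf,
plus a final leaf.  Cue *validity* is the Take-The-Best measure: the
fraction of training trials on which the cue fires whose response
equals the cue's exit label.  Two builders are provided:

* ``Max`` — at every level pick the highest-validity cue outright (its
  own best exit); may yield "rake" trees where almost all exits share
  one label;
* ``ZigZag Z+`` — exits are forced to alternate ACCEPT, REJECT,
  ACCEPT, ... starting with ACCEPT; at each level the highest-validity
  unused cue with the required exit is chosen.

Both builders re-score validity on the trials remaining after earlier
nodes resolved theirs (dynamic re-ranking), never reuse a feature, and
impose no depth limit: construction stops only when no admissible cue
remains or no trials are left unresolved.  Trees are fitted globally
(one per dataset) — with only a few dozen items per participant,
per-participant trees would overfit badly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .data_model import Dataset, FeatureError, Group, Response
from .models import GLOBAL, Model, TrialTable, build_trial_table, register

logger = logging.getLogger(__name__)

_DIR_RANK = {"GT": 0, "LE": 1}
_EXIT_RANK = {Response.ACCEPT: 0, Response.REJECT: 1}


@dataclass(frozen=True)
class Cue:
    """A binarized feature test with a single exit leaf.

    The cue *fires* on a trial when the feature value is on the
    ``direction`` side of ``threshold`` (GT: value > threshold, LE:
    value <= threshold); firing trials exit with ``exit_label``.
    """

    feature_name: str
    threshold: float
    direction: str  # GT or LE
    exit_label: Response
    validity: float

    def fires(self, values: np.ndarray) -> np.ndarray:
        if self.direction == "GT":
            return np.asarray(values) > self.threshold
        return np.asarray(values) <= self.threshold


@dataclass
class FFTree:
    nodes: list[Cue]
    final_leaf: Response

    @property
    def depth(self) -> int:
        return len(self.nodes)


def fft_feature_table(ds: Dataset, table: TrialTable | None = None) -> dict[str, np.ndarray]:
    """Per-trial numeric feature columns used as FFT cue candidates.

    All relevant measured features enter: participant-level CRT,
    conservatism, education (and PANAS when present), trial reaction
    time, and — unlike the other models — pretest aggregates both for
    the participant's own group *and* as the two-group mean.
    """
    t = table if table is not None else build_trial_table(ds)
    feats: dict[str, np.ndarray] = {
        "crt": t.crt,
        "conservatism": t.conservatism,
        "education": t.education,
        "fam_own": t.fam_own,
        "fam_mean": t.fam_mean,
        "part_own": t.part_own,
        "part_mean": t.part_mean,
    }
    if t.reac is not None and not np.any(np.isnan(t.reac)):
        feats["reaction_time"] = t.reac
    if t.panas_p is not None:
        feats["panas_p"] = t.panas_p
        feats["panas_n"] = t.panas_n
    if ds.schema.has_extra_pretest:
        is_rep = np.asarray([
            ds.participants[tr.participant_id].group is Group.REP for tr in ds.trials
        ])
        for name in ("importance", "worrying", "exciting"):
            rep = np.asarray([getattr(ds.items[tr.item_id], f"{name}_rep")
                              for tr in ds.trials], dtype=float)
            dem = np.asarray([getattr(ds.items[tr.item_id], f"{name}_dem")
                              for tr in ds.trials], dtype=float)
            feats[f"{name}_own"] = np.where(is_rep, rep, dem)
            feats[f"{name}_mean"] = (rep + dem) / 2.0
    return feats


def cue_validity(cue: Cue, values: np.ndarray, responses: np.ndarray) -> float:
    """Fraction of firing trials whose response equals the cue's exit.

    ``responses`` is 1.0 for ACCEPT.  Raises if the cue never fires.
    """
    fires = cue.fires(values)
    n_fire = int(fires.sum())
    if n_fire == 0:
        raise ValueError("cue never fires on the given trials")
    want = 1.0 if cue.exit_label is Response.ACCEPT else 0.0
    return float(np.sum(fires & (np.asarray(responses) == want)) / n_fire)


def _best_cue_for_feature(
    name: str,
    values: np.ndarray,
    y: np.ndarray,
    allowed_exits: Sequence[Response],
    require_unresolved: bool,
) -> Cue | None:
    """Best (threshold, direction, exit) for one feature by validity.

    Thresholds are the midpoints between consecutive distinct sorted
    values.  Ties break by lower threshold, then GT before LE, then
    ACCEPT before REJECT.  Returns None for constant features or when
    no admissible cue fires (and, when ``require_unresolved``, leaves
    at least one trial unresolved).
    """
    distinct = np.unique(values)
    if len(distinct) < 2:
        return None
    thresholds = (distinct[:-1] + distinct[1:]) / 2.0
    n = len(values)
    best: tuple | None = None  # sort key
    best_cue: Cue | None = None
    fires_gt = values[None, :] > thresholds[:, None]  # (m, n)
    accept_mask = y == 1.0
    for direction in ("GT", "LE"):
        fires = fires_gt if direction == "GT" else ~fires_gt
        n_fire = fires.sum(axis=1)
        ok = n_fire >= 1
        if require_unresolved:
            ok &= n_fire < n
        if not np.any(ok):
            continue
        n_acc = (fires & accept_mask[None, :]).sum(axis=1)
        for exit_label in allowed_exits:
            with np.errstate(invalid="ignore", divide="ignore"):
                v = np.where(ok, n_acc / np.maximum(n_fire, 1), -1.0)
                if exit_label is Response.REJECT:
                    v = np.where(ok, 1.0 - v, -1.0)
            vmax = v.max()
            if vmax < 0:
                continue
            # flatnonzero is ascending, so the first max index has the lowest threshold
            i = int(np.flatnonzero(v == vmax)[0])
            key = (-v[i], thresholds[i], _DIR_RANK[direction], _EXIT_RANK[exit_label])
            if best is None or key < best:
                best = key
                best_cue = Cue(name, float(thresholds[i]), direction,
                               exit_label, float(v[i]))
    return best_cue


def candidate_cues(
    features: Mapping[str, np.ndarray],
    y: np.ndarray,
    allowed_exits: Sequence[Response] = (Response.ACCEPT, Response.REJECT),
    require_unresolved: bool = True,
) -> list[Cue]:
    """Best cue per feature, sorted by descending validity.

    Constant features are skipped with a warning.  Cross-feature ties
    break lexicographically by feature name.
    """
    cues: list[Cue] = []
    for name in features:
        cue = _best_cue_for_feature(name, np.asarray(features[name], dtype=float),
                                    np.asarray(y, dtype=float),
                                    allowed_exits, require_unresolved)
        if cue is None:
            logger.warning("feature %r yields no admissible cue (constant?)", name)
        else:
            cues.append(cue)
    return sorted(cues, key=lambda c: (-c.validity, c.feature_name, c.threshold,
                                       _DIR_RANK[c.direction], _EXIT_RANK[c.exit_label]))


def _majority_leaf(y: np.ndarray) -> Response:
    if len(y) == 0:
        return Response.REJECT
    n_acc = float(np.sum(y == 1.0))
    return Response.ACCEPT if n_acc > len(y) - n_acc else Response.REJECT  # tie -> REJECT


def build_fft_max(
    features: Mapping[str, np.ndarray], y: np.ndarray, dynamic: bool = True
) -> FFTree:
    """Max construction: greedy highest-validity cue at each level.

    Each node keeps its own best exit label; trials it resolves are
    removed before ranking deeper cues (``dynamic``; set False for a
    single static ranking on the full training set).  The final leaf is
    the majority response of the remaining trials (tie -> REJECT).
    """
    y = np.asarray(y, dtype=float)
    remaining = np.arange(len(y))
    used: set[str] = set()
    nodes: list[Cue] = []
    static_ranking = None if dynamic else candidate_cues(features, y)
    while len(remaining) > 0:
        if dynamic:
            sub = {n: np.asarray(v, dtype=float)[remaining]
                   for n, v in features.items() if n not in used}
            ranked = candidate_cues(sub, y[remaining])
        else:
            ranked = [c for c in static_ranking if c.feature_name not in used
                      and _admissible(c, features, remaining)]
        if not ranked:
            break
        cue = ranked[0]  # static mode keeps the full-sample ranking validity
        nodes.append(cue)
        used.add(cue.feature_name)
        fires = cue.fires(np.asarray(features[cue.feature_name], dtype=float)[remaining])
        remaining = remaining[~fires]
    if not nodes:
        raise ValueError("no admissible cue: cannot build an FFT")
    return FFTree(nodes=nodes, final_leaf=_majority_leaf(y[remaining]))


def _admissible(cue: Cue, features, remaining) -> bool:
    fires = cue.fires(np.asarray(features[cue.feature_name], dtype=float)[remaining])
    return 0 < int(fires.sum()) < len(remaining)


def build_fft_zigzag_zplus(features: Mapping[str, np.ndarray], y: np.ndarray) -> FFTree:
    """ZigZag Z+ construction: exits alternate ACCEPT, REJECT, ... from ACCEPT.

    At each level the highest-validity unused cue with the required exit
    label is chosen, re-scoring validity on the remaining trials; the
    build stops when no such cue fires, and the final leaf is the
    opposite of the last exit.
    """
    y = np.asarray(y, dtype=float)
    remaining = np.arange(len(y))
    used: set[str] = set()
    nodes: list[Cue] = []
    want = Response.ACCEPT
    while len(remaining) > 0:
        sub = {n: np.asarray(v, dtype=float)[remaining]
               for n, v in features.items() if n not in used}
        ranked = candidate_cues(sub, y[remaining], allowed_exits=(want,))
        if not ranked:
            break
        cue = ranked[0]
        nodes.append(cue)
        used.add(cue.feature_name)
        fires = cue.fires(np.asarray(features[cue.feature_name], dtype=float)[remaining])
        remaining = remaining[~fires]
        want = Response.REJECT if want is Response.ACCEPT else Response.ACCEPT
    if not nodes:
        raise ValueError("no ACCEPT-exit cue fires at the root: cannot build Z+ tree")
    last = nodes[-1].exit_label
    leaf = Response.REJECT if last is Response.ACCEPT else Response.ACCEPT
    return FFTree(nodes=nodes, final_leaf=leaf)


def fft_predict(tree: FFTree, feature_row: Mapping[str, float]) -> Response:
    """Traverse the tree: first firing cue's exit, else the final leaf."""
    for cue in tree.nodes:
        if cue.feature_name not in feature_row:
            raise FeatureError(f"feature {cue.feature_name!r} unresolvable for this trial")
        value = feature_row[cue.feature_name]
        fired = value > cue.threshold if cue.direction == "GT" else value <= cue.threshold
        if fired:
            return cue.exit_label
    return tree.final_leaf


def fft_predict_vec(tree: FFTree, features: Mapping[str, np.ndarray],
                    rows: np.ndarray) -> np.ndarray:
    """Vectorized traversal; returns 1.0 for ACCEPT."""
    n = len(rows)
    out = np.full(n, 1.0 if tree.final_leaf is Response.ACCEPT else 0.0)
    undecided = np.ones(n, dtype=bool)
    for cue in tree.nodes:
        vals = np.asarray(features[cue.feature_name], dtype=float)[rows]
        fires = cue.fires(vals) & undecided
        out[fires] = 1.0 if cue.exit_label is Response.ACCEPT else 0.0
        undecided &= ~fires
    return out


# ---------------------------------------------------------------------------
# Serialization (structured text, round-trip exact via repr floats)


def tree_to_text(tree: FFTree) -> str:
    lines = [f"node\t{c.feature_name}\t{c.threshold!r}\t{c.direction}\t"
             f"{c.exit_label.value}\t{c.validity!r}" for c in tree.nodes]
    lines.append(f"leaf\t{tree.final_leaf.value}")
    return "\n".join(lines) + "\n"


def tree_from_text(text: str) -> FFTree:
    nodes: list[Cue] = []
    leaf: Response | None = None
    for line in text.strip().splitlines():
        parts = line.rstrip("\n").split("\t")
        if parts[0] == "node":
            _, name, thr, direction, exit_label, validity = parts
            nodes.append(Cue(name, float(thr), direction, Response(exit_label),
                             float(validity)))
        elif parts[0] == "leaf":
            leaf = Response(parts[1])
    if leaf is None:
        raise ValueError("tree text has no leaf line")
    return FFTree(nodes=nodes, final_leaf=leaf)


def save_tree(tree: FFTree, path: str | Path) -> None:
    Path(path).write_text(tree_to_text(tree), encoding="utf-8")


def load_tree(path: str | Path) -> FFTree:
    return tree_from_text(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# Model-contract wrapper


class FFTModel(Model):
    """FFT as a registered model; fitted globally (one tree per dataset)."""

    n_params = 0
    default_scope = GLOBAL

    def __init__(self, algorithm: str = "zigzag", dynamic: bool = True) -> None:
        super().__init__()
        if algorithm not in ("max", "zigzag"):
            raise ValueError(f"unknown FFT algorithm {algorithm!r}")
        self.algorithm = algorithm
        self.dynamic = dynamic
        self.name = f"fft_{algorithm}"
        self.tree: FFTree | None = None
        self._features: dict[str, np.ndarray] | None = None

    def _post_bind(self) -> None:
        self._features = fft_feature_table(self.table.ds, self.table)

    def fit_special(self, config=None, scope: str | None = None) -> FFTree:
        if scope not in (None, GLOBAL):
            raise ValueError("FFT models are fitted globally; per-individual trees "
                             "overfit the few dozen items per participant")
        y = self.table.y
        if self.algorithm == "max":
            self.tree = build_fft_max(self._features, y, dynamic=self.dynamic)
        else:
            self.tree = build_fft_zigzag_zplus(self._features, y)
        self.fitted_scope = GLOBAL
        return self.tree

    def predict_vec(self, params, rows):
        if self.tree is None:
            raise RuntimeError("FFT model not fitted; call pre_train/fit_special first")
        return fft_predict_vec(self.tree, self._features, np.asarray(rows))


register("fft_max", lambda **kw: FFTModel("max", **kw))
register("fft_zigzag", lambda **kw: FFTModel("zigzag", **kw))
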