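"""Parameter estimation: basin-hopping fits, losses, and the closed-form CR fit.

All free-parameter models are trained with the same regime: scipy's
basin-hopping global optimizer run from a zero initial vector, with a
configurable number of random perturbations (default 200) and Metropolis
temperature T = 5, each followed by a derivative-free Nelder-Mead local
search.  The fitted objective is the trial-level mean squared error
between the expected prediction and the 0/1 response — discrete accuracy
is piecewise constant and defeats local optimization, while MSE is its
natural smooth surrogate and reproduces the linear-approximation
behavior of the Classical Reasoning fit.  Fits are either global (one
parameter vector for the whole dataset) or per individual (one vector
per participant, fitted on that participant's trials), following each
model's declared scope.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import basinhopping

from .data_model import Dataset
from .models import (
    GLOBAL,
    PER_INDIVIDUAL,
    CRParams,
    Model,
    TrialTable,
    build_trial_table,
)

logger = logging.getLogger(__name__)


@dataclass
class FitConfig:
    """Basin-hopping regime.

    ``n_perturbations`` local searches at random perturbations around
    the incumbent (default 200), Metropolis ``temperature`` 5, initial
    coordinates at zero, Nelder-Mead local tolerance ``local_tol`` and
    perturbation ``stepsize`` 1.0 (features are on unit-ish scales; CR&time
    uses per-participant standardized reaction times).
    """

    n_perturbations: int = 200
    temperature: float = 5.0
    init: np.ndarray | None = None
    seed: int = 0
    local_tol: float = 1e-6
    stepsize: float = 1.0
    objective: str = "mse"  # or "discrete"

    def __post_init__(self) -> None:
        if self.n_perturbations < 1:
            raise ValueError("n_perturbations must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


@dataclass
class FitResult:
    params: np.ndarray
    loss: float
    n_evals: int
    scope: str


def loss_mse(model: Model, params: np.ndarray, rows: np.ndarray | None = None) -> float:
    """Mean squared error of expected predictions against 0/1 responses."""
    rows = np.arange(model.table.n_trials) if rows is None else np.asarray(rows)
    if len(rows) == 0:
        raise ValueError("loss is undefined on an empty trial set")
    p = model.predict_vec(np.asarray(params, dtype=float), rows)
    return float(np.mean((p - model.table.y[rows]) ** 2))


def accuracy_score(p: np.ndarray, y: np.ndarray, mode: str = "EXPECTED") -> float:
    """Predictive accuracy of expected predictions ``p`` against responses ``y``.

    DISCRETE binarizes at 0.5 (boundary to ACCEPT) and counts matches;
    EXPECTED is the mean matched probability, ``mean(p if y==1 else 1-p)``
    — for deterministic 0/1 predictions the two coincide.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(p) == 0:
        raise ValueError("accuracy is undefined on an empty trial set")
    if mode == "DISCRETE":
        return float(np.mean((p >= 0.5) == (y == 1.0)))
    if mode == "EXPECTED":
        return float(np.mean(np.where(y == 1.0, p, 1.0 - p)))
    raise ValueError(f"unknown accuracy mode {mode!r}")


def accuracy(model: Model, params: np.ndarray, rows: np.ndarray | None = None,
             mode: str = "EXPECTED") -> float:
    """Predictive accuracy of a model at given parameters on given trials."""
    rows = np.arange(model.table.n_trials) if rows is None else np.asarray(rows)
    p = model.predict_vec(np.asarray(params, dtype=float), rows)
    return accuracy_score(p, model.table.y[rows], mode)


def basin_hop(objective: Callable[[np.ndarray], float], dim: int,
              config: FitConfig | None = None) -> FitResult:
    """Basin-hopping minimization from a zero start.

    Runs the local Nelder-Mead minimizer at the initial coordinates and
    at ``n_perturbations`` random perturbations with Metropolis
    acceptance at the configured temperature; deterministic given the
    seed.  The returned loss never exceeds the objective at the initial
    point.
    """
    config = config or FitConfig()
    x0 = np.zeros(dim) if config.init is None else np.asarray(config.init, dtype=float)
    if len(x0) != dim:
        raise ValueError(f"init vector has length {len(x0)}, expected {dim}")

    n_evals = 0

    def wrapped(x: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        return float(objective(x))

    f0 = wrapped(x0)
    if not np.isfinite(f0):
        raise ValueError("objective is non-finite at the initial coordinates")

    result = basinhopping(
        wrapped,
        x0,
        niter=config.n_perturbations,
        T=config.temperature,
        stepsize=config.stepsize,
        minimizer_kwargs={
            "method": "Nelder-Mead",
            # adaptive simplex coefficients: markedly better convergence for dim > 2
            "options": {"xatol": config.local_tol, "fatol": config.local_tol,
                        "adaptive": True, "maxfev": 600 * max(dim, 1)},
        },
        rng=np.random.default_rng(config.seed),
    )
    params, loss = np.asarray(result.x, dtype=float), float(result.fun)
    if loss > f0:  # guard the optimizer contract
        params, loss = x0, f0
    return FitResult(params=params, loss=loss, n_evals=n_evals, scope=GLOBAL)


def _child_seed(master: int, participant_id: str) -> int:
    """Per-participant seed from the master seed and the participant's id.

    Keying on the id (not the list position) makes fits invariant to
    participant ordering.
    """
    key = zlib.crc32(str(participant_id).encode("utf-8"))
    return int(np.random.SeedSequence(entropy=master, spawn_key=(key,))
               .generate_state(1)[0] % (2**31 - 1))


def _objective_fn(model: Model, rows: np.ndarray, kind: str) -> Callable:
    if kind == "mse":
        return lambda x: loss_mse(model, x, rows)
    if kind == "discrete":
        return lambda x: 1.0 - accuracy(model, x, rows, mode="DISCRETE")
    raise ValueError(f"unknown objective {kind!r}")


def fit_model(model: Model, scope: str | None = None,
              config: FitConfig | None = None):
    """Fit a bound model per its scope; stores parameters on the model.

    GLOBAL yields one parameter vector minimizing the loss over all
    trials; PER_INDIVIDUAL one vector per participant over that
    participant's trials (with per-participant seeds expanded from the
    master seed).  Models with closed-form or special fits (CR's OLS,
    FFT tree construction) dispatch to those; models without free
    parameters (baselines, item-mean) need no fitting.  CR-extension
    models (CR&time, mood) first receive the global closed-form CR base.
    """
    if model.table is None:
        raise RuntimeError("model must be bound to a dataset before fitting")
    config = config or FitConfig()
    scope = scope or model.default_scope

    if hasattr(model, "fit_special"):
        return model.fit_special(config, scope)

    if hasattr(model, "base_cr"):
        model.base_cr = _cr_vector(fit_cr_closed_form(model.table))

    if model.n_params == 0:
        model.fitted_scope = scope
        return None

    if getattr(model, "closed_form", False):
        cr = fit_cr_closed_form(model.table)
        params = _cr_vector(cr)
        model.global_params = params
        model.fitted_scope = GLOBAL
        return FitResult(params=params, loss=loss_mse(model, params),
                         n_evals=0, scope=GLOBAL)

    if scope == GLOBAL:
        res = basin_hop(_objective_fn(model, np.arange(model.table.n_trials),
                                      config.objective),
                        model.n_params, config)
        model.global_params = res.params
        model.fitted_scope = GLOBAL
        return res

    if scope == PER_INDIVIDUAL:
        results: dict[str, FitResult] = {}
        for k, pid in enumerate(model.table.participant_ids):
            rows = model.table.rows_of(k)
            if len(rows) == 0:
                logger.warning("participant %s has no trials; skipped", pid)
                continue
            cfg_k = FitConfig(
                n_perturbations=config.n_perturbations,
                temperature=config.temperature,
                init=config.init,
                seed=_child_seed(config.seed, pid),
                local_tol=config.local_tol,
                stepsize=config.stepsize,
                objective=config.objective,
            )
            res = basin_hop(_objective_fn(model, rows, config.objective),
                            model.n_params, cfg_k)
            res.scope = PER_INDIVIDUAL
            results[pid] = res
            model.individual_params[pid] = res.params
        model.fitted_scope = PER_INDIVIDUAL
        return results

    raise ValueError(f"unknown fitting scope {scope!r}")


def fit_cr_closed_form(data: Dataset | TrialTable) -> CRParams:
    """Closed-form Classical Reasoning fit.

    Ordinary least squares of each participant's mean acceptance rate on
    their CRT score, separately for real and fake items, globally over
    all participants.  With a single distinct CRT value the slope is 0
    and the intercept the grand mean (with a warning).
    """
    table = data if isinstance(data, TrialTable) else build_trial_table(data)
    crt = np.asarray([table.crt[table.rows_of(k)[0]]
                      for k in range(len(table.participant_ids))])
    out: list[float] = []
    for real in (True, False):
        rates = np.empty(len(table.participant_ids))
        for k in range(len(table.participant_ids)):
            rows = table.rows_of(k)
            sel = rows[table.truth_real[rows] == real]
            rates[k] = np.mean(table.y[sel]) if len(sel) else np.nan
        valid = ~np.isnan(rates)
        if len(np.unique(crt[valid])) < 2:
            logger.warning("all CRT values equal; CR slope set to 0")
            kappa, alpha = float(np.nanmean(rates)), 0.0
        else:
            alpha, kappa = np.polyfit(crt[valid], rates[valid], 1)
        out += [float(kappa), float(alpha)]
    return CRParams(kappa_R=out[0], alpha_R=out[1], kappa_F=out[2], alpha_F=out[3])


def _cr_vector(p: CRParams) -> np.ndarray:
    return np.asarray([p.kappa_R, p.alpha_R, p.kappa_F, p.alpha_F])
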