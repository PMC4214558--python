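"""Kinetic-parameter estimation from time-course and dose-response data.

The global stage is a seeded evolutionary search (differential
evolution) in log-parameter space — rate constants span decades — and
the local stage is a derivative-free simplex polish.  The objective is
the sum of squared residuals, weighted by per-point standard errors
when the dataset provides them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import differential_evolution, minimize

from .metrics import hill_coefficient
from .model_core import KineticParameters, RATE_FIELDS, SystemTotals
from .simulate import SteadyStateError, signal_response, steady_state
from .synthetic_data import Dataset, model_fractions

__all__ = ["FitResult", "fit", "fit_ches_effect", "predict", "objective"]

#: default search bounds relative to the base value
BOUNDS_FOLD = 100.0

#: evolutionary-stage defaults (population members = popsize * n_params)
DEFAULT_POPSIZE = 50
DEFAULT_MAXITER = 200

#: objective value assigned to candidates whose simulation fails
PENALTY = 1e12


@dataclass
class FitResult:
    """Estimated parameters and optimisation metadata."""

    params: KineticParameters
    estimates: dict[str, float]
    objective: float
    n_evaluations: int
    converged: bool
    seed: int
    free_params: tuple[str, ...]
    bounds: dict[str, tuple[float, float]]
    extra: dict = field(default_factory=dict)


def predict(
    dataset: Dataset, params: KineticParameters, totals: SystemTotals
) -> np.ndarray:
    """Model predictions aligned with ``dataset.table`` rows."""
    t = dataset.table
    if dataset.kind == "timecourse":
        times = np.unique(t["time"].to_numpy(float))
        species = list(dict.fromkeys(t["species"]))
        model = model_fractions(
            params, totals, times, species, drive_signal=dataset.drive_signal
        )
        lut = {(r.species, r.time): r.value for r in model.itertuples()}
        return np.array([lut[(s, tt)] for s, tt in zip(t["species"], t["time"])])
    signals = t["signal"].to_numpy(float)
    order = np.argsort(signals)
    out = np.empty_like(signals)
    prev = None
    for i in order:
        st = steady_state(params, totals, float(signals[i]), dataset.signal_kind,
                          x0=prev)
        prev = st
        out[i] = st["RR2p"]
    return out


def objective(
    dataset: Dataset, params: KineticParameters, totals: SystemTotals
) -> float:
    """(Weighted) sum of squared residuals of the model against the data."""
    pred = predict(dataset, params, totals)
    obs = dataset.table["value"].to_numpy(float)
    resid = pred - obs
    if "se" in dataset.table.columns:
        se = dataset.table["se"].to_numpy(float)
        # SEs at or below float noise (e.g. np.std of nominally identical
        # replicates) are rounding artifacts, not information: treat them
        # as unweighted instead of giving the point near-infinite weight
        floor = 1e-9 * max(float(np.max(np.abs(obs))), 1e-300)
        good = np.isfinite(se) & (se > floor)
        w = np.ones_like(se)
        np.divide(1.0, se, out=w, where=good)
        resid = resid * w
    return float(np.sum(resid**2))


def _default_bounds(base: KineticParameters, free: Sequence[str]):
    out = {}
    for name in free:
        b = getattr(base, name)
        if b <= 0:
            raise ValueError(
                f"no default bounds for {name}: base value is zero; pass bounds"
            )
        out[name] = (b / BOUNDS_FOLD, b * BOUNDS_FOLD)
    return out


def fit(
    dataset: Dataset,
    free_params: Sequence[str],
    base_params: KineticParameters,
    totals: SystemTotals,
    seed: int = 0,
    bounds: dict[str, tuple[float, float]] | None = None,
    popsize: int = DEFAULT_POPSIZE,
    maxiter: int = DEFAULT_MAXITER,
) -> FitResult:
    """Estimate ``free_params`` by evolutionary search plus local polish.

    Deterministic for a fixed ``seed``.  Candidates whose simulation
    fails are penalised, not fatal.
    """
    free = tuple(free_params)
    unknown = [f for f in free if f not in RATE_FIELDS]
    if unknown:
        raise ValueError(f"not kinetic parameters: {unknown}")
    if not free:
        return FitResult(
            params=base_params,
            estimates={},
            objective=objective(dataset, base_params, totals),
            n_evaluations=1,
            converged=True,
            seed=seed,
            free_params=(),
            bounds={},
        )
    bnds = dict(_default_bounds(base_params, free))
    if bounds:
        bnds.update(bounds)
    log_bounds = [(np.log10(bnds[f][0]), np.log10(bnds[f][1])) for f in free]
    n_eval = 0

    def loss(theta: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        p = base_params.replace(**{f: 10.0 ** v for f, v in zip(free, theta)})
        try:
            return objective(dataset, p, totals)
        except (SteadyStateError, ValueError, FloatingPointError):
            return PENALTY

    de = differential_evolution(
        loss,
        log_bounds,
        seed=seed,
        popsize=popsize,
        maxiter=maxiter,
        tol=1e-10,
        polish=False,
        init="sobol",
        updating="deferred",
    )
    local = minimize(
        loss,
        de.x,
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-14, "maxiter": 4000},
    )
    best = local if local.fun <= de.fun else de
    theta = np.clip(best.x, [b[0] for b in log_bounds], [b[1] for b in log_bounds])
    estimates = {f: float(10.0 ** v) for f, v in zip(free, theta)}
    fitted = base_params.replace(**estimates)
    return FitResult(
        params=fitted,
        estimates=estimates,
        objective=float(loss(theta)),
        n_evaluations=n_eval,
        converged=bool(de.success or local.success),
        seed=seed,
        free_params=free,
        bounds=bnds,
    )


def fit_ches_effect(
    dataset_with: Dataset,
    dataset_without: Dataset,
    mode: str,
    base_params: KineticParameters,
    totals: SystemTotals,
    seed: int = 0,
    **fit_kwargs,
) -> FitResult:
    """Fit the CheS-modified dose-response curve.

    The without-CheS curve stays at the base parameters; the with-CheS
    curve is fitted by freeing the sink phosphotransfer rate ``kS``
    and/or the sink autodephosphorylation rate ``khS`` (``mode`` one of
    ``kS_only``, ``khS_only``, ``both``).  The result carries the Hill
    coefficients of the fitted and base curves.
    """
    for ds in (dataset_with, dataset_without):
        if ds.kind != "dose_response":
            raise ValueError("CheS fitting expects dose-response datasets")
    if not np.array_equal(
        dataset_with.table["signal"].to_numpy(), dataset_without.table["signal"].to_numpy()
    ):
        raise ValueError("the two datasets must share one signal grid")
    free = {"kS_only": ("kS",), "khS_only": ("khS",), "both": ("kS", "khS")}[mode]
    result = fit(dataset_with, free, base_params, totals, seed=seed, **fit_kwargs)
    result.extra["objective_without"] = objective(dataset_without, base_params, totals)
    grid = dataset_with.table["signal"].to_numpy(float)
    lo, hi = grid[grid > 0].min(), grid.max()
    span = np.geomspace(lo / 10.0, hi * 10.0, 80)
    kind = dataset_with.signal_kind
    for key, p in (("hill_with", result.params), ("hill_without", base_params)):
        try:
            result.extra[key] = hill_coefficient(
                signal_response(p, totals, kind, span)
            ).hill
        except (SteadyStateError, ValueError):
            # annotation only; the fit itself is already done
            result.extra[key] = float("nan")
    return result
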