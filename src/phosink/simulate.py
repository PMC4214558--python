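"""Time-course integration, steady states, and signal-response curves.

The signal of the motif is either the HK autophosphorylation rate
constant ``ka`` (the model's natural signal) or the clamped ATP
concentration (the experimental proxy used in the in vitro assays, with
``ka`` held at its configured value).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq, root

from .model_core import (
    KineticParameters,
    SystemState,
    SystemTotals,
    full_to_reduced,
    reduced_residual,
    reduced_to_full,
    rhs_vector,
    species_names,
    unphosphorylated_state,
)

__all__ = [
    "TimeCourse",
    "SignalResponseCurve",
    "SteadyStateError",
    "integrate",
    "steady_state",
    "signal_response",
    "find_signal_for_level",
]

#: default integration tolerances (stiff-capable solver)
RTOL = 1e-8
ATOL = 1e-10

#: steady state means the full RHS norm is below this (µM/s)
STEADY_RESIDUAL = 1e-10

#: plateau rule: output saturated when a 10-fold signal increase moves
#: the steady output RR-p level by less than this relative amount
PLATEAU_RELTOL = 1e-3

#: hard cap for automatic signal-grid extension
SIGNAL_CAP = 1e9


class SteadyStateError(RuntimeError):
    """Raised when no steady state meets the residual criterion."""

    def __init__(self, message, best_residual=None, best_state=None):
        super().__init__(message)
        self.best_residual = best_residual
        self.best_state = best_state


def _signal_kwargs(signal_kind: str, signal: float | None) -> dict:
    if signal is None:
        return {}
    if signal_kind == "ka":
        return {"ka": signal}
    if signal_kind == "ATP":
        return {"atp": signal}
    if signal_kind == "source":
        # lumped first-order HK -> HK-p drive of the analytic treatment;
        # the ATP-binding pathway is switched off so the complex is empty
        return {"source": signal, "ka": 0.0, "atp": 0.0}
    raise ValueError(f"unknown signal kind {signal_kind!r}")


def _residual_tol(params, totals, kw: dict) -> float:
    """Scale-aware steady-state acceptance tolerance (µM/s).

    The RHS at a steady state is a cancellation of gross one-way fluxes,
    so the achievable residual floor scales with the largest gross flux,
    not with an absolute number.  The tolerance is STEADY_RESIDUAL times
    the largest characteristic flux (never below STEADY_RESIDUAL).
    """
    atp = kw.get("atp", totals.ATP)
    ka = kw.get("ka", params.ka)
    source = kw.get("source", 0.0)
    hk, rr1, rr2 = totals.HK_tot, totals.RR1_tot, totals.RR2_tot
    gross = max(
        params.k1 * hk * atp,
        params.k2 * hk,
        ka * hk,
        source * hk,
        params.kS * hk * rr1,
        params.krS * hk * rr1,
        params.kM * hk * rr2,
        params.krM * hk * rr2,
        params.khS * rr1,
        params.khM * rr2,
    )
    return STEADY_RESIDUAL * max(1.0, gross)


@dataclass
class TimeCourse:
    """Trajectory of all species on a strictly increasing time grid."""

    t: np.ndarray
    y: np.ndarray  # shape (n_species, n_times)
    species: tuple[str, ...]
    params: KineticParameters
    totals: SystemTotals
    dense: Callable[[float], np.ndarray] | None = None

    def state_at(self, i: int) -> SystemState:
        return SystemState(self.y[:, i].copy(), self.species, float(self.t[i]))

    @property
    def final_state(self) -> SystemState:
        return self.state_at(len(self.t) - 1)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.y[self.species.index(name)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: time, species, value."""
        recs = []
        for j, s in enumerate(self.species):
            recs.append(pd.DataFrame({"time": self.t, "species": s, "value": self.y[j]}))
        return pd.concat(recs, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {"params": self.params.to_dict(), "totals": self.totals.to_dict()}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2) + "\n"
        )


@dataclass
class SignalResponseCurve:
    """Steady-state phospho-RR levels on a strictly increasing signal grid."""

    signal_kind: str
    signals: np.ndarray
    rr1p: np.ndarray
    rr2p: np.ndarray
    plateau: float
    params: KineticParameters | None = None
    totals: SystemTotals | None = None
    #: continuous steady-state map signal -> RR2-p; solved on demand when
    #: the curve came from the model, analytic for synthetic curves
    evaluator: Callable[[float], float] | None = None

    def __post_init__(self):
        self.signals = np.asarray(self.signals, float)
        self.rr1p = np.asarray(self.rr1p, float)
        self.rr2p = np.asarray(self.rr2p, float)
        if np.any(np.diff(self.signals) <= 0):
            raise ValueError("signal grid must be strictly increasing")

    @classmethod
    def from_function(
        cls, f: Callable[[float], float], signals: Sequence[float], plateau: float,
        signal_kind: str = "ka",
    ) -> "SignalResponseCurve":
        signals = np.asarray(signals, float)
        vals = np.array([f(s) for s in signals])
        return cls(signal_kind, signals, np.zeros_like(vals), vals, plateau, evaluator=f)

    def response_at(self, signal: float) -> float:
        """RR2-p at an arbitrary signal: exact map if available, else a
        monotone (PCHIP) interpolant of the grid."""
        if self.evaluator is not None:
            return float(self.evaluator(signal))
        interp = PchipInterpolator(self.signals, self.rr2p)
        return float(interp(signal))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"signal": self.signals, "RR1p": self.rr1p, "RR2p": self.rr2p}
        )

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {
            "signal_kind": self.signal_kind,
            "plateau": self.plateau,
            "params": self.params.to_dict() if self.params else None,
            "totals": self.totals.to_dict() if self.totals else None,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2) + "\n"
        )


def integrate(
    params: KineticParameters,
    totals: SystemTotals,
    initial: SystemState | None = None,
    t_end: float = 1e4,
    signal: float | None = None,
    signal_kind: str = "ka",
    t_eval: Sequence[float] | None = None,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> TimeCourse:
    """Integrate the ODEs with a stiff-capable solver (dense output kept)."""
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if initial is None:
        initial = unphosphorylated_state(params, totals)
    kw = _signal_kwargs(signal_kind, signal)
    fun = lambda t, y: rhs_vector(y, params, totals, **kw)
    # LSODA first; Radau as a fallback for regimes where LSODA's
    # stiffness switching gives up (e.g. extreme clamped-ATP levels)
    for method in ("LSODA", "Radau"):
        sol = solve_ivp(
            fun,
            (0.0, float(t_end)),
            initial.concentrations,
            method=method,
            rtol=rtol,
            atol=atol,
            dense_output=True,
            t_eval=None if t_eval is None else np.asarray(t_eval, float),
        )
        if sol.success:
            break
    if not sol.success:
        raise SteadyStateError(
            f"integration failed: {sol.message}",
            best_state=SystemState(sol.y[:, -1], species_names(params), sol.t[-1]),
        )
    return TimeCourse(sol.t, sol.y, species_names(params), params, totals, sol.sol)


def _newton_polish(
    x0: np.ndarray,
    params: KineticParameters,
    totals: SystemTotals,
    kw: dict,
) -> tuple[np.ndarray, float]:
    res = root(
        lambda x: reduced_residual(x, params, totals, **kw), x0, method="hybr",
        options={"xtol": 1e-13},
    )
    y = reduced_to_full(res.x, params, totals)
    norm = float(np.linalg.norm(rhs_vector(y, params, totals, **kw)))
    return y, norm


def steady_state(
    params: KineticParameters,
    totals: SystemTotals,
    signal: float | None = None,
    signal_kind: str = "ka",
    x0: SystemState | np.ndarray | None = None,
) -> SystemState:
    """Steady state at a fixed signal: integrate-then-refine.

    Long integration from the unphosphorylated state (or a Newton start
    from ``x0`` when warm-starting) followed by a Newton polish in
    reduced coordinates; the result must satisfy ‖rhs‖ below a
    flux-scale-aware tolerance (1e-10 µM/s at unit flux scale).
    """
    if signal is not None and signal < 0:
        raise ValueError("signal must be >= 0")
    kw = _signal_kwargs(signal_kind, signal)
    tol = _residual_tol(params, totals, kw)
    best_y, best_norm = None, np.inf
    if x0 is not None:
        y0 = x0.concentrations if isinstance(x0, SystemState) else np.asarray(x0, float)
        y, norm = _newton_polish(full_to_reduced(y0, params), params, totals, kw)
        if norm < tol and np.all(y > -1e-12):
            return SystemState(np.maximum(y, 0.0), species_names(params))
        best_y, best_norm = y, norm
    t_end = 1e4
    start = unphosphorylated_state(params, totals)
    while t_end <= 1e8:
        tc = integrate(params, totals, start, t_end=t_end, signal=signal,
                       signal_kind=signal_kind, rtol=1e-10, atol=1e-12)
        y, norm = _newton_polish(
            full_to_reduced(tc.y[:, -1], params), params, totals, kw
        )
        if norm < tol and np.all(y > -1e-10):
            return SystemState(np.maximum(y, 0.0), species_names(params))
        if norm < best_norm:
            best_y, best_norm = y, norm
        start, t_end = tc.final_state, t_end * 10
    raise SteadyStateError(
        f"no steady state below residual {tol:.3g} (best {best_norm:.3g})",
        best_residual=best_norm,
        best_state=SystemState(best_y, species_names(params)),
    )


def _log_grid(lo: float, hi: float, per_decade: int = 10) -> np.ndarray:
    n = max(2, int(round(np.log10(hi / lo) * per_decade)) + 1)
    return np.geomspace(lo, hi, n)


def signal_response(
    params: KineticParameters,
    totals: SystemTotals,
    signal_kind: str = "ka",
    grid: Sequence[float] | None = None,
    auto_extend: bool = True,
) -> SignalResponseCurve:
    """Steady-state signal-response curve by numerical continuation.

    Each grid point is warm-started from the previous one.  If the output
    has not saturated at the top of the grid (a further 10-fold signal
    increase still moves RR2-p by >=0.1%), the grid is extended decade by
    decade up to a hard cap.
    """
    if grid is None:
        grid = _log_grid(1e-3, 1e3)
    grid = np.asarray(grid, float)
    if np.any(np.diff(grid) <= 0) or np.any(grid < 0):
        raise ValueError("grid must be strictly increasing and non-negative")

    signals, rr1p, rr2p = [], [], []
    prev = None
    for s in grid:
        st = steady_state(params, totals, s, signal_kind, x0=prev)
        prev = st
        signals.append(s)
        rr1p.append(st["RR1p"])
        rr2p.append(st["RR2p"])

    # plateau detection / automatic extension
    while True:
        probe_sig = signals[-1] * 10.0
        probe = steady_state(params, totals, probe_sig, signal_kind, x0=prev)
        if abs(probe["RR2p"] - rr2p[-1]) < PLATEAU_RELTOL * max(probe["RR2p"], 1e-300):
            plateau = probe["RR2p"]
            break
        if not auto_extend or probe_sig > SIGNAL_CAP:
            raise SteadyStateError(
                f"output plateau not reached below signal {SIGNAL_CAP:g}"
            )
        for s in _log_grid(signals[-1], probe_sig)[1:]:
            st = steady_state(params, totals, s, signal_kind, x0=prev)
            prev = st
            signals.append(s)
            rr1p.append(st["RR1p"])
            rr2p.append(st["RR2p"])

    curve = SignalResponseCurve(
        signal_kind, np.array(signals), np.array(rr1p), np.array(rr2p),
        float(plateau), params, totals,
    )

    def _solve(sig: float, _cache={"x0": None}) -> float:
        st = steady_state(params, totals, sig, signal_kind, x0=_cache["x0"])
        _cache["x0"] = st
        return st["RR2p"]

    curve.evaluator = _solve
    return curve


def find_signal_for_level(
    params: KineticParameters,
    totals: SystemTotals,
    target_fraction: float,
    signal_kind: str = "ka",
    tol: float = 1e-4,
) -> float:
    """Signal at which steady RR2-p equals ``target_fraction``·RR2_tot.

    Bisection on the monotone steady-state map; used e.g. to pick the
    drive that phosphorylates 90% of the output RR before a
    signal-termination experiment.
    """
    if target_fraction == 0:
        return 0.0
    if not 0 < target_fraction < 1:
        raise ValueError("target_fraction must be in (0, 1)")
    target = target_fraction * totals.RR2_tot

    warm = {"x0": None}

    def f(log_s: float) -> float:
        st = steady_state(params, totals, 10.0 ** log_s, signal_kind, x0=warm["x0"])
        warm["x0"] = st
        return st["RR2p"] - target

    lo, hi = -6.0, 0.0
    while f(hi) < 0:
        hi += 1.0
        if hi > np.log10(SIGNAL_CAP):
            raise ValueError(
                f"target fraction {target_fraction} exceeds the output plateau"
            )
    while f(lo) > 0:
        lo -= 2.0
        if lo < -30:
            raise ValueError("target fraction reached at vanishing signal")
    log_s = brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16)
    sig = 10.0 ** log_s
    achieved = steady_state(params, totals, sig, signal_kind)["RR2p"] / totals.RR2_tot
    if abs(achieved - target_fraction) > tol:
        raise SteadyStateError(
            f"bisection achieved {achieved:.6f}, wanted {target_fraction:.6f}"
        )
    return sig
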