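"""Parameter-sensitivity scans and numeric multistationarity detection.

The sensitivity scans vary one or two rate constants (or totals) around
a base point — 10-fold down to 10-fold up by default — and record the
Hill coefficient of the resulting signal-response curve, reproducing
the heat-map style of analysis used for the sink motif.

Multistationarity is probed numerically: many random feasible states
are refined by Newton's method at a fixed signal, converged roots are
deduplicated, and each distinct root is stability-checked through the
eigenvalues of the steady-state Jacobian.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root

from .metrics import NonMonotoneCurveError, hill_coefficient
from .model_core import (
    KineticParameters,
    RATE_FIELDS,
    SystemState,
    SystemTotals,
    full_to_reduced,
    reduced_residual,
    reduced_to_full,
    rhs_vector,
    sample_feasible_state,
    species_names,
)
from .simulate import SteadyStateError, signal_response

__all__ = [
    "ScanGrid",
    "MultistabilityReport",
    "scan_2d",
    "threshold_shift",
    "multistationarity_scan",
    "multistart_roots",
]


@dataclass
class ScanGrid:
    """Hill coefficients on a 2-D grid of parameter values."""

    axis_names: tuple[str, str]
    axis_values: tuple[np.ndarray, np.ndarray]
    hill: np.ndarray            # shape (len(axis1), len(axis2)); NaN where flagged
    flags: np.ndarray           # object array of '' | 'non-monotone' | 'no-plateau'
    base_params: KineticParameters
    base_totals: SystemTotals

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        df = pd.DataFrame(
            self.hill,
            index=pd.Index(self.axis_values[0], name=self.axis_names[0]),
            columns=pd.Index(self.axis_values[1], name=self.axis_names[1]),
        )
        df.to_csv(path)
        sidecar = {
            "axes": {
                self.axis_names[0]: list(map(float, self.axis_values[0])),
                self.axis_names[1]: list(map(float, self.axis_values[1])),
            },
            "params": self.base_params.to_dict(),
            "totals": self.base_totals.to_dict(),
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2) + "\n"
        )

    def plot(self, path: str | Path) -> None:
        """Optional heat-map rendering (requires matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        x, y = self.axis_values[0], self.axis_values[1]
        m = ax.pcolormesh(x, y, self.hill.T, shading="nearest", cmap="viridis")
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel(self.axis_names[0])
        ax.set_ylabel(self.axis_names[1])
        fig.colorbar(m, ax=ax, label="Hill coefficient")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


@dataclass
class MultistabilityReport:
    """Distinct steady states found at one signal level."""

    signal: float
    params: KineticParameters
    totals: SystemTotals
    states: list[SystemState]
    stable: list[bool]
    n_failed_starts: int = 0

    @property
    def count(self) -> int:
        return len(self.states)


def _apply_axis(params, totals, name: str, value: float):
    if name in RATE_FIELDS or hasattr(params, name):
        return params.replace(**{name: value}), totals
    if hasattr(totals, name):
        return params, totals.replace(**{name: value})
    raise ValueError(f"unknown parameter or total {name!r}")


def _axis_grid(base: float, resolution: int, fold: float) -> np.ndarray:
    if base <= 0:
        raise ValueError("axis base value must be positive for a log-fold scan")
    return np.geomspace(base / fold, base * fold, resolution)


def scan_2d(
    params: KineticParameters,
    totals: SystemTotals,
    axis1: str,
    axis2: str,
    resolution: int = 21,
    fold: float = 10.0,
    values1: Sequence[float] | None = None,
    values2: Sequence[float] | None = None,
) -> ScanGrid:
    """Hill coefficient over a log grid spanning ``fold``× around base.

    Cells whose curve is non-monotone or never saturates are flagged and
    set to NaN rather than dropped.
    """
    def base_of(name: str) -> float:
        if hasattr(params, name):
            return getattr(params, name)
        if hasattr(totals, name):
            return getattr(totals, name)
        raise ValueError(f"unknown parameter or total {name!r}")
    v1 = np.asarray(values1, float) if values1 is not None else _axis_grid(
        base_of(axis1), resolution, fold
    )
    v2 = np.asarray(values2, float) if values2 is not None else _axis_grid(
        base_of(axis2), resolution, fold
    )
    hill = np.full((v1.size, v2.size), np.nan)
    flags = np.full((v1.size, v2.size), "", dtype=object)
    for i, a in enumerate(v1):
        for j, b in enumerate(v2):
            p, t = _apply_axis(params, totals, axis1, float(a))
            p, t = _apply_axis(p, t, axis2, float(b))
            try:
                curve = signal_response(p, t)
                hill[i, j] = hill_coefficient(curve).hill
            except NonMonotoneCurveError:
                flags[i, j] = "non-monotone"
            except (SteadyStateError, ValueError):
                flags[i, j] = "no-plateau"
    return ScanGrid((axis1, axis2), (v1, v2), hill, flags, params, totals)


def threshold_shift(
    params: KineticParameters,
    totals: SystemTotals,
    rr1_tot_values: Sequence[float],
) -> list[float]:
    """S50 (signal at half-plateau) for each sink-RR total.

    The threshold of the sigmoidal response tracks the amount of sink
    present, so S50 is non-decreasing in RR1_tot.
    """
    out = []
    for rr1 in rr1_tot_values:
        if rr1 < 0:
            raise ValueError("RR1_tot must be >= 0")
        t = totals.replace(RR1_tot=float(rr1))
        curve = signal_response(params, t)
        target = 0.5 * curve.plateau
        i = int(np.searchsorted(curve.rr2p, target))
        lo = np.log10(curve.signals[max(i - 1, 0)])
        hi = np.log10(curve.signals[min(i, curve.signals.size - 1)])
        if lo == hi:
            lo -= 1.0
        s50 = 10.0 ** brentq(
            lambda e: curve.response_at(10.0 ** e) - target, lo, hi, xtol=1e-13
        )
        out.append(float(s50))
    return out


def multistart_roots(
    residual: Callable[[np.ndarray], np.ndarray],
    sampler: Callable[[np.random.Generator], np.ndarray],
    n_starts: int,
    rng: np.random.Generator,
    residual_tol: float = 1e-9,
    distinct_rtol: float = 1e-4,
    accept: Callable[[np.ndarray], bool] | None = None,
) -> tuple[list[np.ndarray], int]:
    """Distinct roots of ``residual`` from ``n_starts`` random starts.

    Generic machinery: Newton (hybr) refinement, convergence filter,
    optional feasibility filter, and relative deduplication.  Returns
    the distinct roots and the number of non-convergent starts.
    """
    roots, n_failed = [], 0
    for _ in range(n_starts):
        x0 = sampler(rng)
        sol = root(residual, x0, method="hybr", options={"xtol": 1e-12})
        x = sol.x
        if np.linalg.norm(residual(x)) > residual_tol or (
            accept is not None and not accept(x)
        ):
            n_failed += 1
            continue
        scale = max(float(np.max(np.abs(x))), 1.0)
        if not any(
            np.max(np.abs(x - r)) <= distinct_rtol * scale for r in roots
        ):
            roots.append(x)
    return roots, n_failed


def _jacobian_fd(f, x, h_scale):
    n = x.size
    J = np.empty((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = h_scale
        J[:, j] = (f(x + e) - f(x - e)) / (2 * h_scale)
    return J


def multistationarity_scan(
    params: KineticParameters,
    totals: SystemTotals,
    signals: Sequence[float],
    n_starts: int = 50,
    seed: int = 0,
) -> list[MultistabilityReport]:
    """Count distinct steady states at each signal by multistart Newton.

    Works for the basic model (where a single state is expected; the
    bimolecular motif admits no bistability) and for extended models
    with phosphotransfer/dead-end complexes (where some regimes may).
    Every reported root is verified as a steady state and
    stability-classified via the Jacobian's leading eigenvalue.
    Reproducible for a fixed ``seed``.
    """
    rng = np.random.default_rng(seed)
    names = species_names(params)
    scale = max(totals.HK_tot, totals.RR1_tot, totals.RR2_tot, 1.0)
    reports = []
    for sig in signals:
        resid = lambda x: reduced_residual(x, params, totals, ka=float(sig))
        sampler = lambda r: full_to_reduced(
            sample_feasible_state(params, totals, r).concentrations, params
        )
        feasible = lambda x: bool(
            np.all(reduced_to_full(x, params, totals) >= -1e-9)
        )
        roots, n_failed = multistart_roots(
            resid, sampler, n_starts, rng, accept=feasible
        )
        states, stable = [], []
        for x in roots:
            y = np.maximum(reduced_to_full(x, params, totals), 0.0)
            states.append(SystemState(y, names))
            J = _jacobian_fd(resid, x, 1e-6 * scale)
            stable.append(bool(np.max(np.linalg.eigvals(J).real) < 0))
        reports.append(
            MultistabilityReport(float(sig), params, totals, states, stable, n_failed)
        )
    return reports
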