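"""Sigmoidality measures and signal-termination half-times.

Sigmoidality of a signal-response curve is quantified by the operational
Hill coefficient ln(81)/ln(S90/S10), where S10 and S90 are the signal
levels giving 10% and 90% of output saturation.  Saturation is the curve
plateau (the steady output once a further 10-fold signal increase no
longer moves it), not the total amount of output RR — curves need not
reach full phosphorylation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model_core import KineticParameters, SystemTotals
from .simulate import (
    SignalResponseCurve,
    find_signal_for_level,
    integrate,
    steady_state,
)

__all__ = [
    "HillResult",
    "TerminationResult",
    "NonMonotoneCurveError",
    "hill_coefficient",
    "response_coefficient_max",
    "termination_half_time",
    "termination_fold_change",
]

#: dense-output sampling step for half-time interpolation (s)
HALF_TIME_RESOLUTION = 0.01


class NonMonotoneCurveError(ValueError):
    pass


@dataclass(frozen=True)
class HillResult:
    """Operational Hill coefficient and the signals that define it."""

    hill: float
    S10: float
    S90: float
    plateau: float


@dataclass(frozen=True)
class TerminationResult:
    """Output-RR dephosphorylation half-times after signal removal."""

    half_time_with_sink: float
    half_time_without_sink: float

    @property
    def fold_change(self) -> float:
        return self.half_time_without_sink / self.half_time_with_sink


def _check_monotone(curve: SignalResponseCurve, rtol: float = 1e-6) -> None:
    r = curve.rr2p
    scale = max(float(np.max(np.abs(r))), 1e-300)
    drops = np.where(np.diff(r) < -rtol * scale)[0]
    if drops.size:
        i = int(drops[0])
        raise NonMonotoneCurveError(
            f"RR2-p decreases on signal interval "
            f"[{curve.signals[i]:.6g}, {curve.signals[i + 1]:.6g}]"
        )


def _locate(curve: SignalResponseCurve, target: float) -> float:
    """Signal where the continuous steady-state map crosses ``target``.

    The grid supplies the bracket; the crossing is then solved by
    bisection on the continuous map (never snapped to a grid point).
    """
    r = curve.rr2p
    above = np.where(r >= target)[0]
    if above.size == 0 or above[0] == 0:
        # bracket extends below the grid
        lo_exp = np.log10(curve.signals[0]) - 1.0
        hi_exp = np.log10(curve.signals[above[0]] if above.size else curve.signals[-1])
        f = lambda e: curve.response_at(10.0 ** e) - target
        while f(lo_exp) > 0:
            lo_exp -= 1.0
            if lo_exp < -30:
                raise ValueError("target level reached at vanishing signal")
        return 10.0 ** brentq(f, lo_exp, hi_exp, xtol=1e-14, rtol=8.9e-16)
    i = int(above[0])
    f = lambda e: curve.response_at(10.0 ** e) - target
    lo, hi = np.log10(curve.signals[i - 1]), np.log10(curve.signals[i])
    return 10.0 ** brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16)


def hill_coefficient(curve: SignalResponseCurve) -> HillResult:
    """ln(81)/ln(S90/S10) with S10/S90 at 10%/90% of the curve plateau."""
    _check_monotone(curve)
    plateau = curve.plateau
    if plateau <= 0:
        raise ValueError("curve plateau is zero; no response to measure")
    if curve.rr2p[-1] < 0.9 * plateau:
        raise ValueError("curve grid does not reach 90% of its plateau")
    S10 = _locate(curve, 0.1 * plateau)
    S90 = _locate(curve, 0.9 * plateau)
    return HillResult(float(np.log(81.0) / np.log(S90 / S10)), S10, S90, plateau)


def response_coefficient_max(curve: SignalResponseCurve) -> float:
    """Maximum logarithmic sensitivity d ln(RR2-p)/d ln(signal).

    Centered differences on the log-log curve; an alternative
    sigmoidality measure that ranks parameter sets like the Hill
    coefficient does.
    """
    _check_monotone(curve)
    mask = (curve.signals > 0) & (curve.rr2p > 0)
    ls = np.log(curve.signals[mask])
    lr = np.log(curve.rr2p[mask])
    if ls.size < 3:
        raise ValueError("need at least 3 positive points on the curve")
    dldl = (lr[2:] - lr[:-2]) / (ls[2:] - ls[:-2])
    return float(np.max(dldl))


def termination_half_time(
    params: KineticParameters,
    totals: SystemTotals,
    with_sink: bool = True,
    target_fraction: float = 0.9,
) -> float:
    """Half-time of output-RR dephosphorylation after signal removal.

    Protocol: find the ka that phosphorylates ``target_fraction`` of the
    output RR at steady state, equilibrate there, set ka to zero at t=0,
    and report the (interpolated) time at which RR2-p first falls to
    half its pre-shift steady value.  ``with_sink=False`` removes the
    sink entirely (RR1_tot = 0).
    """
    if not with_sink:
        totals = totals.replace(RR1_tot=0.0)
    ka90 = find_signal_for_level(params, totals, target_fraction)
    start = steady_state(params, totals, ka90)
    y0 = start["RR2p"]
    t_end = 10.0
    while True:
        tc = integrate(params, totals, start, t_end=t_end, signal=0.0)
        i = tc.species.index("RR2p")
        ts = np.arange(0.0, tc.t[-1], HALF_TIME_RESOLUTION)
        vals = tc.dense(ts)[i]
        below = np.where(vals <= 0.5 * y0)[0]
        if below.size:
            hi = ts[below[0]]
            lo = ts[below[0] - 1] if below[0] > 0 else 0.0
            return float(brentq(lambda t: tc.dense(t)[i] - 0.5 * y0, lo, hi,
                                xtol=1e-12))
        t_end *= 10.0
        if t_end > 1e7:
            raise RuntimeError("RR2-p never decayed to half its initial value")


def termination_fold_change(
    params: KineticParameters,
    totals: SystemTotals,
    target_fraction: float = 0.9,
) -> TerminationResult:
    """Half-times with and without the sink under matched 90% drive."""
    return TerminationResult(
        half_time_with_sink=termination_half_time(params, totals, True, target_fraction),
        half_time_without_sink=termination_half_time(params, totals, False, target_fraction),
    )
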