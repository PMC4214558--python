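"""Analytic sigmoidality test and necessary-condition predicates.

A hyperbolic signal-response curve has a non-positive second derivative
everywhere on the positive signal axis, while a sigmoidal one starts
convex; the sign of d²(RR2-p)/d(signal)² at zero signal therefore
classifies the curve.  Two necessary conditions on the basic model for a
positive value are (i) kS·khS·[RR1]_tot ≠ 0 (the sink must exist and
turn over) and (ii) kS > krS (forward sink transfer beats reverse).
With explicit phosphotransfer complexes the second condition relaxes to
kS/krS > 1 or kS/krS > (kyM − kyS)/kyrS.

The second derivative is computed two independent ways: implicit
differentiation of the steady-state equations at zero signal (exact
linear algebra; the mass-action residual is quadratic in the state and
linear in the signal, so every directional derivative used is exact up
to roundoff), and Richardson-extrapolated finite differences of the
numerically continued steady-state map near zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import (
    ExtendedParameters,
    KineticParameters,
    SystemTotals,
    full_to_reduced,
    reduced_residual,
    species_names,
)
from .simulate import steady_state

__all__ = [
    "SigmoidalityVerdict",
    "second_derivative_at_zero",
    "second_derivative_fd",
    "check_conditions",
]

#: condition number above which the zero-signal Jacobian is rejected
MAX_CONDITION = 1e12


def _reduced_index(params: KineticParameters, name: str) -> int:
    reduced = [s for s in species_names(params) if s not in ("HK", "RR1", "RR2")]
    return reduced.index(name)


def _zero_signal_point(params, totals, signal_kind="ka") -> np.ndarray:
    st = steady_state(params, totals, signal=0.0, signal_kind=signal_kind)
    return full_to_reduced(st.concentrations, params)


def second_derivative_at_zero(
    params: KineticParameters,
    totals: SystemTotals,
    signal_kind: str = "ka",
    cross_check: bool = False,
) -> float:
    """d²(steady RR2-p)/dka² at ka = 0 (µM·s²) by implicit differentiation.

    Differentiating F(x(ka), ka) = 0 twice at ka = 0 gives
    x' = -J⁻¹ F_ka and x'' = -J⁻¹ (H[x', x'] + 2 F_{ka,x} x'); the
    reported value is the RR2-p component of x''.  With
    ``cross_check=True`` the finite-difference route is also run and a
    sign disagreement raises.
    """
    if signal_kind not in ("ka", "source"):
        raise ValueError("the zero-signal test is defined for ka or source")
    x0 = _zero_signal_point(params, totals, signal_kind)
    if signal_kind == "ka":
        F = lambda x, s: reduced_residual(x, params, totals, ka=s)
    else:
        F = lambda x, s: reduced_residual(
            x, params, totals, ka=0.0, atp=0.0, source=s
        )
    n = x0.size

    # Jacobian by central differences (exact for a quadratic residual)
    J = np.empty((n, n))
    scale = max(totals.HK_tot, totals.RR1_tot, totals.RR2_tot, 1.0)
    h = 1e-4 * scale
    for j in range(n):
        e = np.zeros(n)
        e[j] = h
        J[:, j] = (F(x0 + e, 0.0) - F(x0 - e, 0.0)) / (2 * h)
    if not np.all(np.isfinite(J)) or np.linalg.cond(J) > MAX_CONDITION:
        raise np.linalg.LinAlgError(
            "steady-state Jacobian at zero signal is ill-conditioned"
        )

    # F is linear in ka, and its ka-slope is linear in x: both exact
    F_ka = F(x0, 1.0) - F(x0, 0.0)
    x1 = np.linalg.solve(J, -F_ka)
    Hvv = 2.0 * (F(x0 + x1, 0.0) - F(x0, 0.0) - J @ x1)
    F_kax_x1 = (F(x0 + x1, 1.0) - F(x0 + x1, 0.0)) - F_ka
    x2 = np.linalg.solve(J, -(Hvv + 2.0 * F_kax_x1))
    value = float(x2[_reduced_index(params, "RR2p")])

    if cross_check:
        fd = second_derivative_fd(params, totals, signal_kind=signal_kind)
        if np.sign(fd) != np.sign(value) and max(abs(fd), abs(value)) > 1e-12:
            raise ArithmeticError(
                f"implicit ({value:.4g}) and finite-difference ({fd:.4g}) "
                "second derivatives disagree in sign"
            )
    return value


def second_derivative_fd(
    params: KineticParameters,
    totals: SystemTotals,
    signal_kind: str = "ka",
    rtol: float = 0.01,
    max_refine: int = 40,
) -> float:
    """Richardson-extrapolated finite-difference d²(RR2-p)/d(signal)² at zero.

    Uses the one-sided second difference (R(2h) - 2R(h))/h² (the
    response is exactly zero at zero signal) with step halving.  The
    quadratic regime of the response can start many decades below the
    scale at which the response itself is measurable, so a single
    agreement between successive Richardson extrapolations is not
    trusted: convergence requires two consecutive agreements to
    ``rtol``, which rules out accidental coincidences during the
    pre-asymptotic drift.
    """
    # every evaluation is warm-started from the nearest previous solution
    # (starting from the zero-signal state), so each call is a cheap
    # Newton solve rather than a long integration
    warm = {"x0": steady_state(params, totals, 0.0, signal_kind)}

    def R(sig: float) -> float:
        st = steady_state(params, totals, sig, signal_kind, x0=warm["x0"])
        warm["x0"] = st
        return st["RR2p"]

    # pick a step at which the response is small but well above solver
    # noise: probe at a tiny signal where the response is linear, then
    # jump straight to the target response level via the measured slope
    noise_floor = 1e3 * np.finfo(float).eps * max(totals.RR2_tot, 1.0)
    h = 1e-6
    r = R(h)
    for _ in range(20):
        if r > noise_floor:
            break
        h *= 10.0
        r = R(h)
    h = min(max(h * (1e-4 * totals.RR2_tot) / r, h), 1e12)
    r = R(h)
    for _ in range(20):  # secant correction if the jump overshot linearity
        if 1e-5 * totals.RR2_tot <= r <= 1e-3 * totals.RR2_tot:
            break
        h *= 0.3 if r > 1e-3 * totals.RR2_tot else 3.0
        r = R(h)

    def D(step: float) -> float:
        return (R(2 * step) - 2.0 * R(step)) / step**2

    rich_values = []
    d_h = D(h)
    for _ in range(max_refine):
        d_h2 = D(h / 2.0)
        rich_values.append(2.0 * d_h2 - d_h)  # cancels the O(h) error term
        if len(rich_values) >= 3:
            a, b, c = rich_values[-3:]
            denom = max(abs(a), abs(b), abs(c), 1e-300)
            if abs(c - b) <= rtol * denom and abs(b - a) <= rtol * denom:
                return float(c)
        d_h, h = d_h2, h / 2.0
        if R(h) < 1e3 * np.finfo(float).eps * max(totals.RR2_tot, 1.0):
            break  # response below solver noise; stop refining
    return float(rich_values[-1])


@dataclass(frozen=True)
class SigmoidalityVerdict:
    """Second-derivative classification plus the analytic predicates."""

    second_derivative: float
    condition_i: bool           # kS*khS*RR1_tot != 0
    condition_ii: bool          # kS > krS
    auxiliary: bool             # krS/kS < krM/(kM + krM)
    extended_condition: bool | None  # kS/krS>1 or kS/krS>(kyM-kyS)/kyrS
    classification: str         # "sigmoidal" | "hyperbolic"

    def to_dict(self) -> dict:
        return {
            "second_derivative": self.second_derivative,
            "condition_i": self.condition_i,
            "condition_ii": self.condition_ii,
            "auxiliary": self.auxiliary,
            "extended_condition": self.extended_condition,
            "classification": self.classification,
        }


def check_conditions(
    params: KineticParameters, totals: SystemTotals
) -> SigmoidalityVerdict:
    """Evaluate the necessary-condition predicates and classify the curve.

    Classification uses the zero-signal second derivative with respect
    to the lumped phosphorylation source (``signal_kind='source'``),
    which is the signal variable of the analytic treatment the
    conditions were derived for.  Driving through the explicit HK·ATP
    binding step instead reparametrizes the signal axis and adds an
    ATP-sequestration-relief effect that can flip the curvature at zero
    independently of the sink mechanism.
    """
    p = params
    cond_i = (p.kS * p.khS * totals.RR1_tot) != 0.0
    cond_ii = p.kS > p.krS
    if p.kS == 0:
        aux = False
    else:
        aux = (p.krS / p.kS) < (p.krM / (p.kM + p.krM) if (p.kM + p.krM) > 0 else np.inf)
    extended = None
    if isinstance(p, ExtendedParameters) and None not in (p.kyS, p.kyM, p.kyrS):
        ratio = np.inf if p.krS == 0 else p.kS / p.krS
        if p.kyrS > 0:
            bound = (p.kyM - p.kyS) / p.kyrS
        else:
            bound = np.inf if p.kyM > p.kyS else -np.inf
        extended = bool(ratio > 1.0 or ratio > bound)
    d2 = second_derivative_at_zero(p, totals, signal_kind="source")
    return SigmoidalityVerdict(
        second_derivative=d2,
        condition_i=bool(cond_i),
        condition_ii=bool(cond_ii),
        auxiliary=bool(aux),
        extended_condition=extended,
        classification="sigmoidal" if d2 > 0 else "hyperbolic",
    )
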