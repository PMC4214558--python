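"""Reaction network of the one-HK / two-RR phosphate-sink motif.

A single histidine kinase (HK) autophosphorylates from an HK·ATP complex
and passes the phosphoryl group reversibly to two response regulators: a
sink RR (RR1, e.g. CheY1 in *Sinorhizobium meliloti*) and an output RR
(RR2, e.g. CheY2).  Both phospho-RRs hydrolyse spontaneously.  The basic
model treats every phosphotransfer as a bimolecular collision; the
extended model routes each transfer through an explicit enzyme–substrate
complex and optionally adds dead-end HK·RR complexes.

All concentrations are in µM, all times in seconds.  ATP is clamped
(buffered): its binding to HK is explicit but it is never depleted and
ADP is not tracked.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "KineticParameters",
    "ExtendedParameters",
    "SystemTotals",
    "SystemState",
    "species_names",
    "ode_rhs",
    "ode_rhs_extended",
    "rhs_vector",
    "reduced_residual",
    "reduced_to_full",
    "full_to_reduced",
    "conservation_groups",
    "unphosphorylated_state",
    "sample_feasible_state",
    "load_system",
    "save_system",
    "table1_system",
    "invivo_system",
]

RATE_FIELDS = ("k1", "k2", "ka", "kS", "krS", "kM", "krM", "khS", "khM")
TOTAL_FIELDS = ("HK_tot", "RR1_tot", "RR2_tot", "ATP")

#: species of the basic model, in state-vector order
BASIC_SPECIES = ("HK", "HK_ATP", "HKp", "RR1", "RR1p", "RR2", "RR2p")

#: transfer complexes of the extended model: name -> (Michaelis field,
#: effective bimolecular rate field, substrate pair, product pair)
TRANSFER_COMPLEXES = {
    "HKp.RR1": ("kyS", "kS", ("HKp", "RR1"), ("HK", "RR1p")),
    "HKp.RR2": ("kyM", "kM", ("HKp", "RR2"), ("HK", "RR2p")),
    "HK.RR1p": ("kyrS", "krS", ("HK", "RR1p"), ("HKp", "RR1")),
    "HK.RR2p": ("kyrM", "krM", ("HK", "RR2p"), ("HKp", "RR2")),
}

#: dead-end complexes allowed in the bistability scenario
DEAD_END_PAIRS = {
    "HK:RR1": ("HK", "RR1"),
    "HK:RR2": ("HK", "RR2"),
    "HKp:RR1p": ("HKp", "RR1p"),
    "HKp:RR2p": ("HKp", "RR2p"),
}


def _check_nonnegative(obj, names) -> None:
    for name in names:
        v = getattr(obj, name)
        if v is not None and v < 0:
            raise ValueError(f"{name} must be >= 0, got {v!r}")


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the basic bimolecular motif.

    ``k1``/``k2`` are the HK·ATP association ((µM·s)⁻¹) and dissociation
    (s⁻¹) constants, ``ka`` the autophosphorylation rate constant (s⁻¹,
    the model's signal), ``kS``/``krS`` the forward/reverse sink-RR
    phosphotransfer constants, ``kM``/``krM`` the same for the output RR
    (all (µM·s)⁻¹), and ``khS``/``khM`` the phospho-RR
    autodephosphorylation constants (s⁻¹).
    """

    k1: float = 1.0
    k2: float = 100.0
    ka: float = 1.0
    kS: float = 1.0
    krS: float = 0.01
    kM: float = 2.0
    krM: float = 1.0
    khS: float = 0.056
    khM: float = 0.066

    def __post_init__(self):
        _check_nonnegative(self, RATE_FIELDS)

    def replace(self, **kwargs) -> "KineticParameters":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in RATE_FIELDS}


@dataclass(frozen=True)
class ExtendedParameters(KineticParameters):
    """Basic rates plus complex-formation constants.

    ``kyS``, ``kyM``, ``kyrS``, ``kyrM`` are inverse Michaelis constants
    (µM⁻¹) of the phosphotransfer complexes; a value of ``None`` leaves
    the corresponding transfer bimolecular.  ``complex_reversibility`` is
    the ratio of the complex's unproductive dissociation rate to its
    catalytic rate (dimensionless; the Michaelis constant and effective
    bimolecular rate are preserved for any value).  ``dead_end`` lists
    optional (name, kon, koff) triples for the four HK·RR binding
    complexes of the bistability scenario.
    """

    kyS: float | None = None
    kyM: float | None = None
    kyrS: float | None = None
    kyrM: float | None = None
    complex_reversibility: float = 1.0
    dead_end: tuple[tuple[str, float, float], ...] = ()

    def __post_init__(self):
        super().__post_init__()
        _check_nonnegative(self, ("kyS", "kyM", "kyrS", "kyrM", "complex_reversibility"))
        for name, kon, koff in self.dead_end:
            if name not in DEAD_END_PAIRS:
                raise ValueError(f"unknown dead-end complex {name!r}")
            if kon < 0 or koff < 0:
                raise ValueError(f"dead-end {name}: kon/koff must be >= 0")

    @property
    def enabled_transfer_complexes(self) -> tuple[str, ...]:
        out = []
        for cname, (ky_field, _, _, _) in TRANSFER_COMPLEXES.items():
            ky = getattr(self, ky_field)
            if ky is not None and ky > 0:
                out.append(cname)
        return tuple(out)

    def to_dict(self) -> dict:
        d = super().to_dict()
        for k in ("kyS", "kyM", "kyrS", "kyrM"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        d["complex_reversibility"] = self.complex_reversibility
        if self.dead_end:
            d["dead_end"] = [list(t) for t in self.dead_end]
        return d


@dataclass(frozen=True)
class SystemTotals:
    """Conserved protein totals and the clamped ATP concentration (µM)."""

    HK_tot: float = 10.0
    RR1_tot: float = 2.5
    RR2_tot: float = 2.5
    ATP: float = 10.0

    def __post_init__(self):
        _check_nonnegative(self, TOTAL_FIELDS)

    def replace(self, **kwargs) -> "SystemTotals":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in TOTAL_FIELDS}


def species_names(params: KineticParameters) -> tuple[str, ...]:
    """State-vector species order for the model variant of ``params``."""
    names = list(BASIC_SPECIES)
    if isinstance(params, ExtendedParameters):
        names += list(params.enabled_transfer_complexes)
        names += [name for name, _, _ in params.dead_end]
    return tuple(names)


@dataclass
class SystemState:
    """Concentrations (µM) of every species at one time point."""

    concentrations: np.ndarray
    species: tuple[str, ...] = BASIC_SPECIES
    time: float = 0.0

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.concentrations.shape != (len(self.species),):
            raise ValueError("state length does not match species list")

    def __getitem__(self, name: str) -> float:
        return float(self.concentrations[self.species.index(name)])

    def as_dict(self) -> dict:
        return dict(zip(self.species, map(float, self.concentrations)))

    def validate(self, totals: SystemTotals, rtol: float = 1e-6) -> None:
        """Check non-negativity and the three conservation sums."""
        if np.any(self.concentrations < -1e-12):
            bad = [s for s, c in self.as_dict().items() if c < -1e-12]
            raise ValueError(f"negative concentrations: {bad}")
        for label, target, members in conservation_groups(self.species, totals):
            got = sum(self[m] for m in members)
            scale = max(abs(target), 1.0)
            if abs(got - target) > rtol * scale:
                raise ValueError(
                    f"conservation violated for {label}: sum={got:.8g}, total={target:.8g}"
                )


def conservation_groups(species: Sequence[str], totals: SystemTotals):
    """The three conserved sums: (label, total, member species)."""
    hk, rr1, rr2 = [], [], []
    for s in species:
        parts = s.replace(":", ".").split(".")
        forms = {p for p in parts}
        if forms & {"HK", "HK_ATP", "HKp"}:
            hk.append(s)
        if forms & {"RR1", "RR1p"}:
            rr1.append(s)
        if forms & {"RR2", "RR2p"}:
            rr2.append(s)
    return [
        ("HK", totals.HK_tot, tuple(hk)),
        ("RR1", totals.RR1_tot, tuple(rr1)),
        ("RR2", totals.RR2_tot, tuple(rr2)),
    ]


# ---------------------------------------------------------------------------
# right-hand sides
# ---------------------------------------------------------------------------

def _complex_rates(params: ExtendedParameters, cname: str) -> tuple[float, float, float]:
    """(kon, koff, kcat) for a transfer complex.

    Chosen so that the Michaelis constant is 1/ky and the effective
    bimolecular rate (kon·kcat/(koff+kcat)) equals the basic-model
    constant: kcat = k_eff/ky, koff = r·kcat, kon = k_eff·(1+r).
    """
    ky_field, k_field, _, _ = TRANSFER_COMPLEXES[cname]
    ky = getattr(params, ky_field)
    k_eff = getattr(params, k_field)
    r = params.complex_reversibility
    kcat = k_eff / ky
    return k_eff * (1.0 + r), r * kcat, kcat


def rhs_vector(
    y: np.ndarray,
    params: KineticParameters,
    totals: SystemTotals,
    ka: float | None = None,
    atp: float | None = None,
    source: float = 0.0,
) -> np.ndarray:
    """Mass-action time derivatives (µM/s) for the raw state vector ``y``.

    ``ka``/``atp`` override the corresponding values in ``params``/
    ``totals`` (used when either is being treated as the signal).
    ``source`` adds a first-order HK -> HK-p drive (s⁻¹): the lumped
    phosphorylation source of the analytic treatment, which bypasses
    the ATP-binding step.
    """
    p = params
    ka = p.ka if ka is None else ka
    atp = totals.ATP if atp is None else atp
    names = species_names(p)
    idx = {s: i for i, s in enumerate(names)}
    HK, C, HKp = y[0], y[1], y[2]
    RR1, RR1p, RR2, RR2p = y[3], y[4], y[5], y[6]
    dy = np.zeros_like(y)

    v_bind = p.k1 * HK * atp - p.k2 * C
    v_auto = ka * C
    dy[0] += -v_bind
    dy[1] += v_bind - v_auto
    dy[2] += v_auto
    if source:
        v_src = source * HK
        dy[0] -= v_src
        dy[2] += v_src

    extended = isinstance(p, ExtendedParameters)
    enabled = p.enabled_transfer_complexes if extended else ()

    # phosphotransfer: bimolecular unless routed through a complex
    if "HKp.RR1" not in enabled:
        v = p.kS * HKp * RR1
        dy[2] -= v; dy[3] -= v; dy[0] += v; dy[4] += v
    if "HK.RR1p" not in enabled:
        v = p.krS * HK * RR1p
        dy[0] -= v; dy[4] -= v; dy[2] += v; dy[3] += v
    if "HKp.RR2" not in enabled:
        v = p.kM * HKp * RR2
        dy[2] -= v; dy[5] -= v; dy[0] += v; dy[6] += v
    if "HK.RR2p" not in enabled:
        v = p.krM * HK * RR2p
        dy[0] -= v; dy[6] -= v; dy[2] += v; dy[5] += v

    dy[4] -= p.khS * RR1p
    dy[3] += p.khS * RR1p
    dy[6] -= p.khM * RR2p
    dy[5] += p.khM * RR2p

    if extended:
        for cname in enabled:
            kon, koff, kcat = _complex_rates(p, cname)
            _, _, (sub_a, sub_b), (pr_a, pr_b) = TRANSFER_COMPLEXES[cname]
            i_c = idx[cname]
            v_on = kon * y[idx[sub_a]] * y[idx[sub_b]] - koff * y[i_c]
            v_cat = kcat * y[i_c]
            dy[idx[sub_a]] -= v_on
            dy[idx[sub_b]] -= v_on
            dy[i_c] += v_on - v_cat
            dy[idx[pr_a]] += v_cat
            dy[idx[pr_b]] += v_cat
        for name, kon, koff in p.dead_end:
            a, b = DEAD_END_PAIRS[name]
            i_c = idx[name]
            v = kon * y[idx[a]] * y[idx[b]] - koff * y[i_c]
            dy[idx[a]] -= v
            dy[idx[b]] -= v
            dy[i_c] += v
    return dy


def ode_rhs(
    state: SystemState,
    params: KineticParameters,
    totals: SystemTotals,
    ka: float | None = None,
) -> np.ndarray:
    """Time derivatives (µM/s) of the basic 7-species model."""
    if isinstance(params, ExtendedParameters):
        raise TypeError("use ode_rhs_extended for ExtendedParameters")
    if np.any(state.concentrations < -1e-12):
        raise ValueError("negative concentration in state")
    return rhs_vector(state.concentrations, params, totals, ka=ka)


def ode_rhs_extended(
    state: SystemState,
    params: ExtendedParameters,
    totals: SystemTotals,
    ka: float | None = None,
) -> np.ndarray:
    """Time derivatives with explicit phosphotransfer/dead-end complexes."""
    if np.any(state.concentrations < -1e-12):
        raise ValueError("negative concentration in state")
    if state.species != species_names(params):
        raise ValueError("state species do not match the enabled complexes")
    return rhs_vector(state.concentrations, params, totals, ka=ka)


# ---------------------------------------------------------------------------
# reduced coordinates (conservation laws eliminated) for steady-state solving
# ---------------------------------------------------------------------------

def _reduced_indices(species: Sequence[str]) -> list[int]:
    # independent species: everything except the free HK, RR1, RR2 pools
    return [i for i, s in enumerate(species) if s not in ("HK", "RR1", "RR2")]


def reduced_to_full(
    x: np.ndarray, params: KineticParameters, totals: SystemTotals
) -> np.ndarray:
    names = species_names(params)
    y = np.zeros(len(names))
    red = _reduced_indices(names)
    y[red] = x
    groups = conservation_groups(names, totals)
    for (label, total, members), free in zip(groups, ("HK", "RR1", "RR2")):
        bound = sum(y[names.index(m)] for m in members if m != free)
        y[names.index(free)] = total - bound
    return y


def full_to_reduced(y: np.ndarray, params: KineticParameters) -> np.ndarray:
    return np.asarray(y)[_reduced_indices(species_names(params))]


def reduced_residual(
    x: np.ndarray,
    params: KineticParameters,
    totals: SystemTotals,
    ka: float | None = None,
    atp: float | None = None,
    source: float = 0.0,
) -> np.ndarray:
    """Steady-state residual in reduced coordinates."""
    y = reduced_to_full(x, params, totals)
    dy = rhs_vector(y, params, totals, ka=ka, atp=atp, source=source)
    return dy[_reduced_indices(species_names(params))]


def unphosphorylated_state(
    params: KineticParameters, totals: SystemTotals
) -> SystemState:
    """All protein unphosphorylated and unbound (HK·ATP empty)."""
    names = species_names(params)
    y = np.zeros(len(names))
    y[names.index("HK")] = totals.HK_tot
    y[names.index("RR1")] = totals.RR1_tot
    y[names.index("RR2")] = totals.RR2_tot
    return SystemState(y, names, 0.0)


def sample_feasible_state(
    params: KineticParameters, totals: SystemTotals, rng: np.random.Generator
) -> SystemState:
    """Random state satisfying non-negativity and all conservation sums.

    Each conserved pool is split over its member species with a Dirichlet
    draw; complexes (members of two pools) take the smaller of their two
    proposed shares so neither pool overflows.
    """
    names = species_names(params)
    y = np.zeros(len(names))
    groups = conservation_groups(names, totals)
    shares = {}
    for label, total, members in groups:
        frac = rng.dirichlet(np.ones(len(members)))
        for m, f in zip(members, frac):
            amount = f * total
            shares[m] = min(shares.get(m, np.inf), amount)
    budget = {label: total for label, total, _ in groups}
    member_of = {}
    for label, _, members in groups:
        for m in members:
            member_of.setdefault(m, []).append(label)
    # place complexes first (they draw on two budgets), then bound forms;
    # the free pools absorb whatever remains of each budget
    placeable = [s for s in shares if s not in ("HK", "RR1", "RR2")]
    for s in sorted(placeable, key=lambda s: -len(member_of[s])):
        amt = min([shares[s]] + [budget[g] for g in member_of[s]])
        y[names.index(s)] = amt
        for g in member_of[s]:
            budget[g] -= amt
    for g, free in (("HK", "HK"), ("RR1", "RR1"), ("RR2", "RR2")):
        y[names.index(free)] = budget[g]
    return SystemState(y, names, 0.0)


# ---------------------------------------------------------------------------
# parameter-file I/O and bundled fixtures
# ---------------------------------------------------------------------------

_DATA_DIR = Path(__file__).parent / "data"


def _split_mapping(d: Mapping) -> tuple[KineticParameters, SystemTotals]:
    d = {k: v for k, v in d.items() if v is not None}
    totals = SystemTotals(**{k: float(d.pop(k)) for k in TOTAL_FIELDS if k in d})
    extended_keys = {"kyS", "kyM", "kyrS", "kyrM", "complex_reversibility", "dead_end"}
    if extended_keys & set(d):
        if "dead_end" in d:
            d["dead_end"] = tuple(tuple(t) for t in d["dead_end"])
        params = ExtendedParameters(**d)
    else:
        params = KineticParameters(**d)
    return params, totals


def load_system(path: str | Path) -> tuple[KineticParameters, SystemTotals]:
    """Read a flat YAML/JSON parameter file (rates + totals in one map)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: expected a flat mapping of parameters")
    return _split_mapping(data)


def save_system(
    path: str | Path, params: KineticParameters, totals: SystemTotals
) -> None:
    path = Path(path)
    data = {**params.to_dict(), **totals.to_dict()}
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def table1_system() -> tuple[KineticParameters, SystemTotals]:
    """*S. meliloti* rates with the in vitro totals 10:2.5:2.5 µM."""
    return load_system(_DATA_DIR / "smeliloti_table1.yaml")


def invivo_system() -> tuple[KineticParameters, SystemTotals]:
    """Same rates at the in vivo stoichiometry 1.5:20:20 µM."""
    return load_system(_DATA_DIR / "smeliloti_invivo.yaml")
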