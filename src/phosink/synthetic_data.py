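"""In-silico analogues of the radiolabel phosphotransfer measurements.

Real data for this motif come from SDS-PAGE/phosphorimager
quantification of ³²P-labelled proteins: fractional phosphorylation
time courses and steady-state phospho-output levels across ATP doses,
typically averaged over three independent experiments.  The generators
here simulate the model and apply multiplicative lognormal noise (gel
quantification errors scale with band intensity) plus an optional
additive floor (background), and always record the generating
parameters so every dataset is reproducible from (params, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model_core import KineticParameters, SystemTotals
from .simulate import integrate, steady_state

__all__ = ["NoiseModel", "Dataset", "make_timecourse_dataset", "make_dose_response_dataset"]


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal noise with an optional additive floor.

    ``sigma`` is the lognormal scale (dimensionless; 0.05 default
    emulates replicate scatter of gel quantification), ``floor`` the
    standard deviation of additive background (µM or fraction units,
    matching the measurement).  ``sigma=0, floor=0`` reproduces the
    model exactly.
    """

    sigma: float = 0.05
    floor: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0 or self.floor < 0:
            raise ValueError("sigma and floor must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, float)
        out = values * np.exp(self.sigma * rng.standard_normal(values.shape))
        if self.floor > 0:
            out = out + self.floor * rng.standard_normal(values.shape)
        return np.clip(out, 0.0, None)


@dataclass
class Dataset:
    """Tabular measurements for fitting, with generating truth attached.

    ``table`` columns: ``time`` (timecourse) or ``signal``
    (dose_response), ``species``, ``value``, ``se``.  Time-course values
    are phospho-fractions of the respective protein total;
    dose-response values are steady phospho-RR2 in µM.
    """

    kind: str
    table: pd.DataFrame
    signal_kind: str = "ka"
    drive_signal: float | None = None  # fixed signal of a time course
    n_replicates: int = 1
    truth: dict | None = None

    def __post_init__(self):
        if self.kind not in ("timecourse", "dose_response"):
            raise ValueError(f"unknown dataset kind {self.kind!r}")
        if len(self.table) < 4:
            raise ValueError("a dataset needs at least 4 points")
        if self.kind == "timecourse" and not (
            (self.table["value"] >= 0) & (self.table["value"] <= 1)
        ).all():
            raise ValueError("time-course fractions must lie in [0, 1]")

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.table.to_csv(path, index=False)
        meta = {
            "kind": self.kind,
            "signal_kind": self.signal_kind,
            "drive_signal": self.drive_signal,
            "n_replicates": self.n_replicates,
            "truth": self.truth,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=2) + "\n"
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Dataset":
        path = Path(path)
        table = pd.read_csv(path)
        meta_path = path.with_suffix(path.suffix + ".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        kind = meta.get(
            "kind", "timecourse" if "time" in table.columns else "dose_response"
        )
        return cls(
            kind=kind,
            table=table,
            signal_kind=meta.get("signal_kind", "ka"),
            drive_signal=meta.get("drive_signal"),
            n_replicates=meta.get("n_replicates", 1),
            truth=meta.get("truth"),
        )


_FRACTION_TOTAL = {"HKp": "HK_tot", "RR1p": "RR1_tot", "RR2p": "RR2_tot"}


def model_fractions(
    params: KineticParameters,
    totals: SystemTotals,
    times: Sequence[float],
    species: Sequence[str],
    drive_signal: float | None = None,
) -> pd.DataFrame:
    """Noise-free phospho-fractions of ``species`` along a time course."""
    times = np.asarray(times, float)
    tc = integrate(
        params, totals, t_end=float(times[-1]) if times[-1] > 0 else 1.0,
        signal=drive_signal, t_eval=times,
    )
    recs = []
    for sp in species:
        tot = getattr(totals, _FRACTION_TOTAL[sp])
        if tot == 0:
            raise ValueError(f"{sp}: zero total, fraction undefined")
        recs.append(
            pd.DataFrame({"time": times, "species": sp, "value": tc[sp] / tot})
        )
    return pd.concat(recs, ignore_index=True)


def make_timecourse_dataset(
    params: KineticParameters,
    totals: SystemTotals,
    times: Sequence[float],
    species: Sequence[str] = ("HKp", "RR1p", "RR2p"),
    noise: NoiseModel = NoiseModel(sigma=0.0, floor=0.0),
    drive_signal: float | None = None,
) -> Dataset:
    """Phospho-fraction time course sampled at aliquot times, with noise."""
    times = np.asarray(times, float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    table = model_fractions(params, totals, times, species, drive_signal)
    rng = noise.rng()
    table = table.assign(
        value=np.minimum(noise.apply(table["value"].to_numpy(), rng), 1.0),
        se=np.nan,
    )
    return Dataset(
        kind="timecourse",
        table=table,
        signal_kind="ka",
        drive_signal=drive_signal if drive_signal is not None else params.ka,
        n_replicates=1,
        truth={"params": params.to_dict(), "totals": totals.to_dict(),
               "seed": noise.seed},
    )


def make_dose_response_dataset(
    params: KineticParameters,
    totals: SystemTotals,
    signal_kind: str,
    grid: Sequence[float],
    n_replicates: int = 3,
    noise: NoiseModel = NoiseModel(sigma=0.05, floor=0.0),
) -> Dataset:
    """Replicate-averaged steady phospho-RR2 (µM) across a signal grid."""
    grid = np.asarray(grid, float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("signal grid must be strictly increasing")
    rng = noise.rng()
    prev = None
    means, ses = [], []
    for s in grid:
        st = steady_state(params, totals, float(s), signal_kind, x0=prev)
        prev = st
        reps = noise.apply(np.full(n_replicates, st["RR2p"]), rng)
        means.append(float(np.mean(reps)))
        ses.append(
            float(np.std(reps, ddof=1) / np.sqrt(n_replicates))
            if n_replicates > 1 else 0.0
        )
    table = pd.DataFrame(
        {"signal": grid, "species": "RR2p", "value": means, "se": ses}
    )
    return Dataset(
        kind="dose_response",
        table=table,
        signal_kind=signal_kind,
        n_replicates=n_replicates,
        truth={"params": params.to_dict(), "totals": totals.to_dict(),
               "seed": noise.seed},
    )
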