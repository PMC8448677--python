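"""Synthetic pre-equilibrium titration datasets and raw progress traces.

Emulates the structure of the plate-based assay: the inhibitor is laid out
as a serial dilution (twofold by default) plus a no-inhibitor control well,
the enzyme is pre-incubated with inhibitor for several distinct times, the
substrate is then added and an initial hydrolysis rate measured per well.
Noise enters as additive Gaussian scatter on the rates, sized as a fraction
of the uninhibited rate — the simplest generator consistent with the
equal-weighting least-squares fit downstream.

Everything is seeded; there is no module-level RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .model import AssayConditions, BindingParameters, residual_rate_preeq
from .traces import ProgressTrace

__all__ = [
    "SimulationSpec",
    "TitrationDataset",
    "dilution_series",
    "simulate_titration",
    "simulate_progress_trace",
    "DEFAULT_TIMEPOINTS_S",
]

#: default incubation schedule (s): spans pre-equilibrium through
#: near-equilibrium curves for nanomolar-range binders
DEFAULT_TIMEPOINTS_S = (300.0, 900.0, 2700.0, 7200.0)


def dilution_series(top_I0: float, factor: float = 2.0, n: int = 11) -> list[float]:
    """Serial dilution concentrations plus the no-inhibitor control.

    Returns ``[top_I0, top_I0/factor, ..., top_I0/factor**(n-1), 0.0]``,
    i.e. ``n`` diluted wells and one control — length ``n + 1``.
    """
    if not (top_I0 > 0):
        raise ValueError(f"top_I0 must be > 0, got {top_I0}")
    if not (factor > 1):
        raise ValueError(f"dilution factor must be > 1, got {factor}")
    if not (n >= 1):
        raise ValueError(f"n must be >= 1, got {n}")
    return [top_I0 / factor**i for i in range(n)] + [0.0]


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one simulated titration experiment.

    ``noise_sd`` is the standard deviation of the additive rate noise as a
    fraction of ``v_0_true`` (default 2%, the scale of well-to-well scatter
    in replicate plate assays).  ``seed`` is mandatory: fixtures must be
    reproducible.
    """

    params: BindingParameters
    conditions: AssayConditions
    top_I0: float
    seed: int
    dilution_factor: float = 2.0
    n_dilutions: int = 11
    v_0_true: float = 1.0
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if not (self.dilution_factor > 1):
            raise ValueError("dilution_factor must be > 1")
        if not (self.n_dilutions >= 4):
            raise ValueError("n_dilutions must be >= 4")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (self.v_0_true > 0):
            raise ValueError("v_0_true must be > 0")
        if not (self.top_I0 > 0):
            raise ValueError("top_I0 must be > 0")


@dataclass
class TitrationDataset:
    """Initial rates indexed by (incubation time, inhibitor concentration).

    ``records`` is a tidy frame with columns ``time_s``,
    ``inhibitor_conc_M`` and ``rate`` (one measured well per row).  Every
    timepoint carries at least one no-inhibitor control row, which anchors
    the uninhibited rate v_0 in the fit.
    """

    records: pd.DataFrame
    conditions: AssayConditions
    provenance: str = "unspecified"

    REQUIRED_COLUMNS = ("time_s", "inhibitor_conc_M", "rate")

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in self.REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"records missing column(s): {', '.join(missing)}")
        if not np.all(np.isfinite(df["rate"])):
            raise ValueError("rates must be finite")
        if np.any(df["inhibitor_conc_M"] < 0):
            raise ValueError("inhibitor concentrations must be >= 0")
        known = set(self.conditions.timepoints)
        present = set(float(t) for t in df["time_s"].unique())
        unknown = present - known
        if unknown:
            raise ValueError(f"records contain timepoint(s) not in conditions: {sorted(unknown)}")
        for tp, grp in df.groupby("time_s"):
            if not np.any(grp["inhibitor_conc_M"] == 0):
                raise ValueError(f"timepoint {tp} s has no I_0 = 0 control row")

    @property
    def timepoints(self) -> list[float]:
        return sorted(float(t) for t in self.records["time_s"].unique())

    def at_timepoint(self, t: float) -> "TitrationDataset":
        """Single-timepoint slice (e.g. for an equilibrium-model fit)."""
        sub = self.records[self.records["time_s"] == t].reset_index(drop=True)
        if sub.empty:
            raise ValueError(f"no records at timepoint {t} s")
        cond = AssayConditions(
            E_0=self.conditions.E_0,
            timepoints=(float(t),),
            S=self.conditions.S,
            K_m=self.conditions.K_m,
        )
        return TitrationDataset(records=sub, conditions=cond, provenance=self.provenance)


def simulate_titration(spec: SimulationSpec) -> TitrationDataset:
    """Generate one titration dataset from a simulation spec.

    Rates are the integrated-rate-law predictions plus seeded Gaussian
    noise of SD ``noise_sd * v_0_true``; with ``noise_sd = 0`` the records
    are exact model values.  Identical specs give identical datasets.
    """
    concs = dilution_series(spec.top_I0, spec.dilution_factor, spec.n_dilutions)
    rng = np.random.default_rng(spec.seed)
    rows = []
    for tp in spec.conditions.timepoints:
        clean = residual_rate_preeq(
            spec.v_0_true, tp, spec.conditions.E_0, np.array(concs), spec.params
        )
        noise = rng.normal(0.0, spec.noise_sd * spec.v_0_true, size=len(concs)) if spec.noise_sd > 0 else np.zeros(len(concs))
        for I0, r in zip(concs, clean + noise):
            rows.append({"time_s": float(tp), "inhibitor_conc_M": float(I0), "rate": float(r)})
    df = pd.DataFrame(rows, columns=list(TitrationDataset.REQUIRED_COLUMNS))
    return TitrationDataset(
        records=df,
        conditions=spec.conditions,
        provenance=f"simulated(seed={spec.seed}, noise_sd={spec.noise_sd})",
    )


def simulate_progress_trace(
    v_true: float,
    duration: float,
    dt: float,
    baseline: float = 0.0,
    noise_sd_signal: float = 0.0,
    seed: int = 0,
    well_id: str = "sim",
    substrate_conc: Optional[float] = None,
    signal_per_product: Optional[float] = None,
) -> ProgressTrace:
    """Linear fluorescence progress trace with additive Gaussian noise.

    signal(t) = baseline + v_true * t + N(0, noise_sd_signal); linear by
    construction, so a windowed least-squares slope must recover ``v_true``.
    """
    if not (duration > 0 and dt > 0):
        raise ValueError("duration and dt must be > 0")
    times = np.arange(0.0, duration + dt / 2, dt)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd_signal, size=times.size) if noise_sd_signal > 0 else 0.0
    return ProgressTrace(
        times=times,
        signal=baseline + v_true * times + noise,
        well_id=well_id,
        substrate_conc=substrate_conc,
        signal_per_product=signal_per_product,
    )
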