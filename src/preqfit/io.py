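"""File contracts, run configuration and the simulate/rates/fit pipeline.

All tabular exchange uses tidy long-format CSV (one measurement per row);
concentration columns carry a declared unit (config ``conc_unit``) and are
converted to SI mol/L on read.  Internally everything is SI; human-facing
report files convert k_on to M^-1 s^-1, k_off to s^-1 and K_i to nM.

Rates CSV contract (the fit's input): columns ``time_s``,
``inhibitor_conc``, ``rate`` plus optional ``replicate`` and ``qc_pass``.
Progress-trace CSV contract: ``time_s``, ``fluorescence_au``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from .fitting import (
    EquilibriumFitResult,
    FitOptions,
    FitResult,
    equilibration_bias_report,
    fit_preequilibrium,
)
from .model import AssayConditions, BindingParameters
from .simulate import SimulationSpec, TitrationDataset, simulate_titration
from .traces import ProgressTrace, fit_initial_rate

__all__ = [
    "CONC_UNIT_FACTORS",
    "RunConfig",
    "read_rates_csv",
    "write_rates_csv",
    "read_trace_csv",
    "write_trace_csv",
    "write_fit_report",
    "run_pipeline",
]

logger = logging.getLogger("preqfit")

CONC_UNIT_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12}

_FLOAT_FMT = "%.12g"  # 12 significant digits: value-preserving round trips


def _unit_factor(conc_unit: str) -> float:
    try:
        return CONC_UNIT_FACTORS[conc_unit]
    except KeyError:
        raise ValueError(
            f"unknown concentration unit {conc_unit!r}; expected one of "
            f"{sorted(CONC_UNIT_FACTORS)}"
        ) from None


def read_rates_csv(
    path: str | Path,
    E_0: float,
    conc_unit: str = "M",
    conditions: AssayConditions | None = None,
) -> TitrationDataset:
    """Read a tidy rates CSV into a validated SI dataset.

    Rows with ``qc_pass`` false (if the column is present) are excluded,
    with the exclusion count logged.  ``conditions`` defaults to the
    timepoints found in the file with the supplied enzyme concentration.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = ["time_s", "inhibitor_conc", "rate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    for col in required:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[col][vals.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(f"{path}: unparseable numeric value(s) in {col!r}: {list(bad[:3])}")
        df[col] = vals
    if df[required].isna().any().any():
        raise ValueError(f"{path}: missing values in required columns")

    if "qc_pass" in df.columns:
        qc = df["qc_pass"].astype(bool)
        n_excluded = int((~qc).sum())
        if n_excluded:
            logger.info("stage=read_rates excluded_qc_failures=%d file=%s", n_excluded, path)
        df = df[qc]
    if df.empty:
        raise ValueError(f"{path}: no rows left after QC filtering")
    if not np.any(df["inhibitor_conc"] == 0):
        raise ValueError(f"{path}: no I_0 = 0 (no-inhibitor control) rows present")

    factor = _unit_factor(conc_unit)
    records = pd.DataFrame(
        {
            "time_s": df["time_s"].to_numpy(float),
            "inhibitor_conc_M": df["inhibitor_conc"].to_numpy(float) * factor,
            "rate": df["rate"].to_numpy(float),
        }
    )
    if conditions is None:
        conditions = AssayConditions(
            E_0=E_0, timepoints=tuple(sorted(records["time_s"].unique()))
        )
    ds = TitrationDataset(records=records, conditions=conditions, provenance=str(path))
    logger.info("stage=read_rates n_records=%d file=%s", len(records), path)
    return ds


def write_rates_csv(
    dataset: TitrationDataset, path: str | Path, conc_unit: str = "M"
) -> Path:
    """Write a dataset to the tidy rates CSV contract in the given unit."""
    path = Path(path)
    factor = _unit_factor(conc_unit)
    out = pd.DataFrame(
        {
            "time_s": dataset.records["time_s"],
            "inhibitor_conc": dataset.records["inhibitor_conc_M"] / factor,
            "rate": dataset.records["rate"],
        }
    )
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)
    logger.info("stage=write_rates n_records=%d file=%s", len(out), path)
    return path


def write_trace_csv(trace: ProgressTrace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": trace.times, "fluorescence_au": trace.signal}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )
    return path


def read_trace_csv(
    path: str | Path,
    well_id: str | None = None,
    substrate_conc: float | None = None,
    signal_per_product: float | None = None,
) -> ProgressTrace:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ("time_s", "fluorescence_au") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    return ProgressTrace(
        times=df["time_s"].to_numpy(float),
        signal=df["fluorescence_au"].to_numpy(float),
        well_id=well_id or path.stem,
        substrate_conc=substrate_conc,
        signal_per_product=signal_per_product,
    )


def _report_rows(result: FitResult) -> list[dict[str, Any]]:
    rows = [
        {
            "parameter": "k_on",
            "value": result.params.k_on,
            "unit": "M^-1 s^-1",
            "stderr": result.stderr.get("k_on"),
            "cv_percent": result.cv_percent.get("k_on"),
        },
        {
            "parameter": "k_off",
            "value": result.params.k_off,
            "unit": "s^-1",
            "stderr": result.stderr.get("k_off"),
            "cv_percent": result.cv_percent.get("k_off"),
        },
        {
            "parameter": "K_i",
            "value": result.K_i / 1e-9,
            "unit": "nM",
            "stderr": (result.stderr.get("K_i") or np.nan) / 1e-9,
            "cv_percent": result.cv_percent.get("K_i"),
        },
    ]
    if result.options.e0_mode == "shared-adjustable":
        rows.append(
            {
                "parameter": "E_0",
                "value": result.E_0 / 1e-9,
                "unit": "nM",
                "stderr": (result.stderr.get("E_0") or np.nan) / 1e-9,
                "cv_percent": result.cv_percent.get("E_0"),
            }
        )
    seen = set()
    for tp, v0 in result.v_0.items():
        name = "v_0" if result.options.v0_mode == "shared" else f"v_0({tp:g} s)"
        if name in seen:
            continue
        seen.add(name)
        key = "v0" if result.options.v0_mode == "shared" else None
        se = result.stderr.get(key) if key else None
        rows.append(
            {
                "parameter": name,
                "value": v0,
                "unit": "signal/s",
                "stderr": se,
                "cv_percent": None,
            }
        )
    return rows


def write_fit_report(result: FitResult, outdir: str | Path, label: str = "fit") -> dict[str, Path]:
    """Write fit_report.csv, fit_report.txt and kon_koff_scatter.csv.

    The scatter file carries one (k_on, k_off, K_i) row per fit for
    rate-constant-plane plots across compound series.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = _report_rows(result)
    csv_path = outdir / "fit_report.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False, float_format=_FLOAT_FMT)

    txt_path = outdir / "fit_report.txt"
    lines = [
        f"Global pre-equilibrium fit: {label}",
        f"  points: {result.n_points}   RSS: {result.rss:.6g}   converged: {result.success}",
        f"  E_0 mode: {result.options.e0_mode}   v_0 mode: {result.options.v0_mode}   weighting: equal",
        f"  winning start: k_on={result.start[0]:g} M^-1 s^-1, k_off={result.start[1]:g} s^-1",
        "",
    ]
    for r in rows:
        se = f" +/- {r['stderr']:.3g}" if r["stderr"] is not None and np.isfinite(r["stderr"] or np.nan) else ""
        cv = f" (CV {r['cv_percent']:.1f}%)" if r["cv_percent"] is not None else ""
        lines.append(f"  {r['parameter']:>12s} = {r['value']:.6g} {r['unit']}{se}{cv}")
    if result.diagnostics:
        lines += ["", "  diagnostics: " + ", ".join(result.diagnostics)]
    txt_path.write_text("\n".join(lines) + "\n")

    scatter_path = outdir / "kon_koff_scatter.csv"
    pd.DataFrame(
        [
            {
                "label": label,
                "k_on_M-1s-1": result.params.k_on,
                "k_off_s-1": result.params.k_off,
                "K_i_nM": result.K_i / 1e-9,
            }
        ]
    ).to_csv(scatter_path, index=False, float_format=_FLOAT_FMT)
    return {"csv": csv_path, "txt": txt_path, "scatter": scatter_path}


@dataclass
class RunConfig:
    """Validated run configuration for one pipeline invocation.

    Built from a YAML file (nested key/value) optionally overridden by CLI
    flags.  ``conc_unit`` applies to every concentration column read or
    written.  All randomness flows from ``seed``.
    """

    mode: str
    output: Path
    seed: int = 0
    conc_unit: str = "M"
    conditions: Optional[AssayConditions] = None
    params: Optional[BindingParameters] = None
    simulation: dict[str, Any] = field(default_factory=dict)
    fit_options: FitOptions = field(default_factory=FitOptions)
    input: Optional[Path] = None
    manifest: Optional[Path] = None
    rates_options: dict[str, Any] = field(default_factory=dict)
    bias: dict[str, Any] = field(default_factory=dict)

    MODES = ("simulate", "rates", "fit", "bias-report")

    def __post_init__(self) -> None:
        if self.mode not in self.MODES:
            raise ValueError(f"mode must be one of {self.MODES}, got {self.mode!r}")
        _unit_factor(self.conc_unit)
        self.output = Path(self.output)
        if self.input is not None:
            self.input = Path(self.input)
        if self.manifest is not None:
            self.manifest = Path(self.manifest)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        cond = d.pop("conditions", None)
        if cond is not None:
            cond = AssayConditions(
                E_0=float(cond["E_0"]),
                timepoints=tuple(float(t) for t in cond["timepoints"]),
                S=float(cond.get("S", 0.0)),
                K_m=(float(cond["K_m"]) if cond.get("K_m") is not None else None),
            )
        params = d.pop("params", None)
        if params is not None:
            params = BindingParameters(k_on=float(params["k_on"]), k_off=float(params["k_off"]))
        fit = d.pop("fit", None)
        fit_options = FitOptions(**fit) if fit else FitOptions()
        return cls(conditions=cond, params=params, fit_options=fit_options, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(d)


def _stage_simulate(config: RunConfig) -> None:
    if config.conditions is None or config.params is None:
        raise ValueError("simulate mode requires 'conditions' and 'params'")
    sim = dict(config.simulation)
    spec = SimulationSpec(
        params=config.params,
        conditions=config.conditions,
        top_I0=float(sim.get("top_I0", 8.0 * config.conditions.E_0)),
        seed=config.seed,
        dilution_factor=float(sim.get("dilution_factor", 2.0)),
        n_dilutions=int(sim.get("n_dilutions", 11)),
        v_0_true=float(sim.get("v_0_true", 1.0)),
        noise_sd=float(sim.get("noise_sd", 0.02)),
    )
    ds = simulate_titration(spec)
    write_rates_csv(ds, config.output, conc_unit=config.conc_unit)
    logger.info(
        "stage=simulate status=ok n_records=%d seed=%d out=%s",
        len(ds.records),
        config.seed,
        config.output,
    )


def _stage_rates(config: RunConfig) -> None:
    if config.manifest is None:
        raise ValueError("rates mode requires a 'manifest' CSV (well_id, path, time_s, inhibitor_conc)")
    man = pd.read_csv(config.manifest)
    missing = [c for c in ("path", "time_s", "inhibitor_conc") if c not in man.columns]
    if missing:
        raise ValueError(f"{config.manifest}: missing manifest column(s): {', '.join(missing)}")
    opts = dict(config.rates_options)
    window = opts.get("window")
    window = tuple(float(w) for w in window) if window is not None else None
    rows = []
    for _, entry in man.iterrows():
        trace = read_trace_csv(
            Path(config.manifest).parent / str(entry["path"]),
            well_id=str(entry.get("well_id", Path(str(entry["path"])).stem)),
            substrate_conc=opts.get("substrate_conc"),
            signal_per_product=opts.get("signal_per_product"),
        )
        est = fit_initial_rate(
            trace,
            window=window,
            r2_threshold=float(opts.get("r2_threshold", 0.98)),
        )
        rows.append(
            {
                "time_s": float(entry["time_s"]),
                "inhibitor_conc": float(entry["inhibitor_conc"]),
                "rate": est.rate,
                "r_squared": est.r_squared,
                "hydrolysis_fraction": est.hydrolysis_fraction,
                "qc_pass": est.qc_pass,
                "well_id": est.well_id,
            }
        )
    out = pd.DataFrame(rows)
    out.to_csv(config.output, index=False, float_format=_FLOAT_FMT)
    n_fail = int((~out["qc_pass"].astype(bool)).sum())
    logger.info(
        "stage=rates status=ok n_wells=%d n_qc_fail=%d out=%s", len(out), n_fail, config.output
    )


def _stage_fit(config: RunConfig) -> None:
    if config.input is None:
        raise ValueError("fit mode requires 'input' (rates CSV)")
    if config.conditions is None:
        raise ValueError("fit mode requires 'conditions' (for E_0)")
    ds = read_rates_csv(
        config.input, E_0=config.conditions.E_0, conc_unit=config.conc_unit
    )
    result = fit_preequilibrium(ds, options=config.fit_options)
    paths = write_fit_report(result, config.output)
    logger.info(
        "stage=fit status=%s n_points=%d rss=%.6g k_on=%.4g k_off=%.4g Ki_nM=%.4g out=%s",
        "ok" if result.success else "failed",
        result.n_points,
        result.rss,
        result.params.k_on,
        result.params.k_off,
        result.K_i / 1e-9,
        paths["txt"],
    )


def _stage_bias_report(config: RunConfig) -> None:
    if config.params is None:
        raise ValueError("bias-report mode requires 'params'")
    bias = dict(config.bias)
    E_0 = float(bias.get("E_0", config.conditions.E_0 if config.conditions else 2e-9))
    t = float(bias.get("t", 900.0))
    report = equilibration_bias_report(config.params, E_0=E_0, t=t)
    config.output.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        "Equilibration bias report",
        f"  E_0 = {E_0 / 1e-9:g} nM, incubation time t = {t:g} s",
        f"  K_i,app fitted at t        = {report.K_i_app_at_t / 1e-9:.2f} nM",
        f"  K_i,app fitted at t = inf  = {report.K_i_app_equilibrium_fit / 1e-9:.2f} nM",
        f"  K_i true (k_off/k_on)      = {report.K_i_true / 1e-9:.2f} nM",
        f"  bias ratio (fitted/true)   = {report.bias_ratio:.2f}",
        "",
        "An equilibrium-model fit of a curve recorded before binding",
        "equilibrium overestimates K_i by the bias ratio above.",
    ]
    config.output.write_text("\n".join(lines) + "\n")
    logger.info(
        "stage=bias-report status=ok Ki_app_t_nM=%.4g Ki_true_nM=%.4g ratio=%.3f out=%s",
        report.K_i_app_at_t / 1e-9,
        report.K_i_true / 1e-9,
        report.bias_ratio,
        config.output,
    )


def run_pipeline(config: RunConfig) -> int:
    """Run one pipeline stage; returns 0 on success, raises on failure."""
    stage = {
        "simulate": _stage_simulate,
        "rates": _stage_rates,
        "fit": _stage_fit,
        "bias-report": _stage_bias_report,
    }[config.mode]
    stage(config)
    return 0
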