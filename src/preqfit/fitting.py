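"""Global fitting of pre-equilibrium inhibition curves.

The shape of a tight-binding titration curve recorded *before* binding
equilibrium depends on k_on and k_off separately, not only on their ratio.
Fitting the integrated rate law to all incubation-time curves of one
experiment simultaneously — with k_on, k_off and E_0 shared across curves,
and v_0 shared or free per curve — therefore yields both rate constants and
K_i = k_off/k_on from a single dataset.  A conventional equilibrium
(Morrison) fit of a single curve is also provided, both for standard K_i
determination and to quantify the bias incurred by fitting the equilibrium
model to not-yet-equilibrated data.

Optimization runs over log10(k_on) and log10(k_off): positivity is
structural and the objective is far better conditioned across the decades
the constants span.  Minimization uses bounded trust-region least squares
with equal weighting (plain sum of squared rate residuals), launched from a
small log-spaced multistart grid because near-equilibrated curve families
make the objective multimodal along the k_off/k_on ridge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import lmfit
import numpy as np
import pandas as pd

from .model import (
    AssayConditions,
    BindingParameters,
    ei_concentration,
    ei_equilibrium,
    ki_from_rates,
    residual_rate_eq,
    residual_rate_preeq,
)
from .simulate import TitrationDataset, dilution_series

__all__ = [
    "FitOptions",
    "FitResult",
    "EquilibriumFitResult",
    "BiasReport",
    "fit_preequilibrium",
    "fit_equilibrium",
    "equilibration_bias_report",
]

LN10 = np.log(10.0)
#: |correlation(log10 k_on, log10 k_off)| above which only the ratio
#: k_off/k_on is considered determined by the data
RATIO_ONLY_CORRELATION = 0.999


@dataclass(frozen=True)
class FitOptions:
    """Options controlling the global pre-equilibrium fit.

    ``e0_mode``: "fixed" uses the known enzyme concentration (the default,
    as in routine practice); "shared-adjustable" estimates one E_0 shared
    by all curves.  ``v0_mode``: "shared" fits a single uninhibited rate;
    "per-timepoint" gives each incubation-time curve its own v_0 to absorb
    plate-to-plate rate variability.  Weighting is equal (unweighted sum of
    squared absolute residuals) — the only supported mode.
    """

    e0_mode: str = "fixed"
    v0_mode: str = "shared"
    weighting: str = "equal"
    kon_starts: tuple[float, ...] = (1e4, 1e5, 1e6, 1e7)
    koff_starts: tuple[float, ...] = (1e-5, 1e-4, 1e-3, 1e-2)
    kon_bounds: tuple[float, float] = (1e2, 1e10)
    koff_bounds: tuple[float, float] = (1e-8, 1e2)
    tol: float = 1e-12
    max_nfev: int = 5000

    def __post_init__(self) -> None:
        if self.e0_mode not in ("fixed", "shared-adjustable"):
            raise ValueError(f"invalid e0_mode: {self.e0_mode!r}")
        if self.v0_mode not in ("shared", "per-timepoint"):
            raise ValueError(f"invalid v0_mode: {self.v0_mode!r}")
        if self.weighting != "equal":
            raise ValueError("only equal weighting is supported")
        if len(self.kon_starts) < 1 or len(self.koff_starts) < 1:
            raise ValueError("multistart grids need >= 1 point")


@dataclass
class FitResult:
    """Outcome of a global pre-equilibrium fit.

    Estimates are SI (k_on in M^-1 s^-1, k_off in s^-1, K_i in M);
    ``stderr`` and ``cv_percent`` (100*SE/estimate) carry entries for
    "k_on", "k_off", "K_i", optionally "E_0" and one per v_0 parameter.
    ``diagnostics`` lists identifiability flags, e.g. "ratio-only" when
    the curves are so equilibrated that only k_off/k_on is determined.
    """

    params: BindingParameters
    K_i: float
    E_0: float
    v_0: dict[float, float]
    stderr: dict[str, Optional[float]]
    cv_percent: dict[str, Optional[float]]
    rss: float
    residuals: np.ndarray
    n_points: int
    success: bool
    message: str
    start: tuple[float, float]
    diagnostics: list[str]
    correlation_kon_koff: Optional[float]
    options: FitOptions


def _predict_preeq(pars, t_arr, I_arr, tp_of_row, v0_names):
    kon = 10.0 ** pars["log10_kon"].value
    koff = 10.0 ** pars["log10_koff"].value
    E0 = 10.0 ** pars["log10_E0"].value
    bp = BindingParameters(k_on=kon, k_off=koff)
    ei = ei_concentration(t_arr, E0, I_arr, bp)
    v0 = np.array([pars[v0_names[tp]].value for tp in tp_of_row])
    return v0 * (E0 - ei) / E0


def fit_preequilibrium(
    data: TitrationDataset,
    options: FitOptions | None = None,
    E_0: float | None = None,
) -> FitResult:
    """Globally fit k_on and k_off to all inhibition curves of a dataset.

    All (timepoint, concentration, rate) records form one objective; k_on,
    k_off (and E_0 in shared-adjustable mode) take a single value across
    curves.  The best of a log-spaced multistart grid is returned, with
    ties in residual sum of squares broken toward smaller k_off.

    Raises
    ------
    ValueError
        If a timepoint has fewer than 4 concentrations.
    RuntimeError
        If every multistart attempt fails to converge.
    """
    options = options or FitOptions()
    E0_known = float(E_0 if E_0 is not None else data.conditions.E_0)

    df = data.records
    timepoints = data.timepoints
    if len(timepoints) < 2:
        warnings.warn(
            "only one incubation timepoint: k_on and k_off are weakly "
            "identified; two or more timepoints are recommended"
        )
    for tp, grp in df.groupby("time_s"):
        if grp["inhibitor_conc_M"].nunique() < 4:
            raise ValueError(
                f"timepoint {tp} s has fewer than 4 distinct concentrations"
            )

    t_arr = df["time_s"].to_numpy(float)
    I_arr = df["inhibitor_conc_M"].to_numpy(float)
    y = df["rate"].to_numpy(float)
    tp_of_row = [float(t) for t in t_arr]

    if options.v0_mode == "per-timepoint":
        v0_names = {tp: f"v0_{i}" for i, tp in enumerate(timepoints)}
    else:
        v0_names = {tp: "v0" for tp in timepoints}

    def make_params(kon0: float, koff0: float) -> lmfit.Parameters:
        pars = lmfit.Parameters()
        pars.add(
            "log10_kon",
            value=np.log10(kon0),
            min=np.log10(options.kon_bounds[0]),
            max=np.log10(options.kon_bounds[1]),
        )
        pars.add(
            "log10_koff",
            value=np.log10(koff0),
            min=np.log10(options.koff_bounds[0]),
            max=np.log10(options.koff_bounds[1]),
        )
        pars.add(
            "log10_E0",
            value=np.log10(E0_known),
            vary=options.e0_mode == "shared-adjustable",
            min=np.log10(E0_known) - 2,
            max=np.log10(E0_known) + 2,
        )
        for tp in timepoints:
            name = v0_names[tp]
            if name not in pars:
                # start at the mean of the control (I_0 = 0) rates it governs
                if options.v0_mode == "per-timepoint":
                    sel = (t_arr == tp) & (I_arr == 0)
                else:
                    sel = I_arr == 0
                pars.add(name, value=float(y[sel].mean()), min=1e-300)
        return pars

    def residual(pars):
        return _predict_preeq(pars, t_arr, I_arr, tp_of_row, v0_names) - y

    attempts = []
    failures = []
    for kon0 in options.kon_starts:
        for koff0 in options.koff_starts:
            try:
                with warnings.catch_warnings():
                    # singular covariances surface as sqrt-of-negative noise
                    warnings.simplefilter("ignore", RuntimeWarning)
                    res = lmfit.minimize(
                        residual,
                        make_params(kon0, koff0),
                        method="least_squares",
                        xtol=options.tol,
                        ftol=options.tol,
                        gtol=options.tol,
                        max_nfev=options.max_nfev,
                    )
            except Exception as exc:  # pragma: no cover - solver pathologies
                failures.append(f"start(k_on={kon0:g}, k_off={koff0:g}): {exc}")
                continue
            if res.success:
                attempts.append(((kon0, koff0), res))
            else:
                failures.append(
                    f"start(k_on={kon0:g}, k_off={koff0:g}): {res.message}"
                )
    if not attempts:
        raise RuntimeError(
            "global fit failed from every start:\n" + "\n".join(failures)
        )

    def rss_of(item):
        return float(np.sum(item[1].residual**2))

    best_start, best = min(attempts, key=rss_of)
    best_rss = rss_of((best_start, best))
    for start, res in attempts:
        # ties broken toward smaller k_off (slower, more conservative kinetics)
        if (
            abs(rss_of((start, res)) - best_rss) < 1e-12 * max(best_rss, 1e-300)
            and res.params["log10_koff"].value < best.params["log10_koff"].value
        ):
            best_start, best = start, res

    return _package_fit(best, best_start, timepoints, v0_names, options, len(y), t_arr, I_arr)


def _finite_or_none(x: Optional[float]) -> Optional[float]:
    return float(x) if x is not None and np.isfinite(x) else None


def _package_fit(res, start, timepoints, v0_names, options, n_points, t_arr, I_arr) -> FitResult:
    p = res.params
    kon = 10.0 ** p["log10_kon"].value
    koff = 10.0 ** p["log10_koff"].value
    E0 = 10.0 ** p["log10_E0"].value
    bp = BindingParameters(k_on=kon, k_off=koff)
    v0 = {tp: float(p[v0_names[tp]].value) for tp in timepoints}

    stderr: dict[str, Optional[float]] = {}
    # delta method: SE(x) = x ln10 SE(log10 x)
    se_lkon = _finite_or_none(p["log10_kon"].stderr)
    se_lkoff = _finite_or_none(p["log10_koff"].stderr)
    stderr["k_on"] = kon * LN10 * se_lkon if se_lkon is not None else None
    stderr["k_off"] = koff * LN10 * se_lkoff if se_lkoff is not None else None
    corr = None
    ki = ki_from_rates(kon, koff)
    if se_lkon is not None and se_lkoff is not None:
        correl = p["log10_kon"].correl or {}
        corr = _finite_or_none(correl.get("log10_koff"))
        cov = (corr or 0.0) * se_lkon * se_lkoff
        var_lki = se_lkoff**2 + se_lkon**2 - 2.0 * cov
        stderr["K_i"] = ki * LN10 * float(np.sqrt(max(var_lki, 0.0)))
    else:
        stderr["K_i"] = None
    if options.e0_mode == "shared-adjustable":
        se_le0 = _finite_or_none(p["log10_E0"].stderr)
        stderr["E_0"] = E0 * LN10 * se_le0 if se_le0 is not None else None
    for tp in timepoints:
        name = v0_names[tp]
        if name not in stderr:
            stderr[name] = _finite_or_none(p[name].stderr)

    estimates = {"k_on": kon, "k_off": koff, "K_i": ki, "E_0": E0}
    estimates.update({v0_names[tp]: v0[tp] for tp in timepoints})
    cv = {
        k: (100.0 * se / estimates[k] if se is not None and estimates.get(k, 0) > 0 else None)
        for k, se in stderr.items()
    }

    diagnostics: list[str] = []
    if se_lkon is None or se_lkoff is None:
        diagnostics.append("no-covariance")
    # relaxation rate b at the fitted constants; if even the slowest-relaxing
    # well has b*t >> 1 every curve is equilibrated and only k_off/k_on is
    # determined (the k_on/k_off Jacobian directions collapse onto a ridge)
    pos = I_arr > 0
    if np.any(pos):
        from .model import _b_radicand

        b = np.sqrt(_b_radicand(E0, I_arr[pos], kon, koff))
        min_bt = float(np.min(b * t_arr[pos]))
    else:
        min_bt = np.inf
    if (corr is not None and abs(corr) > RATIO_ONLY_CORRELATION) or min_bt >= 10.0:
        diagnostics.append("ratio-only")
    for name, bound in (("log10_kon", options.kon_bounds), ("log10_koff", options.koff_bounds)):
        v = p[name].value
        if v - np.log10(bound[0]) < 1e-6 or np.log10(bound[1]) - v < 1e-6:
            diagnostics.append(f"bound-hit:{name.removeprefix('log10_')}")

    return FitResult(
        params=bp,
        K_i=ki,
        E_0=E0,
        v_0=v0,
        stderr=stderr,
        cv_percent=cv,
        rss=float(np.sum(res.residual**2)),
        residuals=np.asarray(res.residual),
        n_points=n_points,
        success=bool(res.success),
        message=str(res.message),
        start=start,
        diagnostics=diagnostics,
        correlation_kon_koff=corr,
        options=options,
    )


@dataclass
class EquilibriumFitResult:
    """Morrison-model fit of a single titration curve.

    ``K_i_app`` is None when the data show no inhibition (the constant is
    then unbounded above); the condition is reported in ``diagnostics``.
    """

    K_i_app: Optional[float]
    v_0: float
    E_0: float
    stderr: dict[str, Optional[float]]
    rss: float
    n_points: int
    success: bool
    diagnostics: list[str]


#: relative rate drop below which a titration is treated as showing no inhibition
NO_INHIBITION_REL_DROP = 1e-3


def fit_equilibrium(
    curve: TitrationDataset,
    E_0: float | None = None,
    e0_mode: str = "fixed",
) -> EquilibriumFitResult:
    """Fit the equilibrium tight-binding (Morrison) model to one curve.

    ``curve`` must hold a single timepoint (slice a multi-time dataset with
    :meth:`TitrationDataset.at_timepoint`).  Estimates K_i,app and v_0;
    E_0 is fixed at its known value unless ``e0_mode="shared-adjustable"``.
    """
    if e0_mode not in ("fixed", "shared-adjustable"):
        raise ValueError(f"invalid e0_mode: {e0_mode!r}")
    df = curve.records
    if df["time_s"].nunique() > 1:
        raise ValueError("equilibrium fit takes a single-timepoint curve")
    if df["inhibitor_conc_M"].nunique() < 4:
        raise ValueError("need >= 4 distinct concentrations including I_0 = 0")
    E0_known = float(E_0 if E_0 is not None else curve.conditions.E_0)

    I_arr = df["inhibitor_conc_M"].to_numpy(float)
    y = df["rate"].to_numpy(float)
    v0_est = float(y[I_arr == 0].mean())
    top = I_arr.max()
    drop = (v0_est - float(y[I_arr == top].mean())) / v0_est if v0_est > 0 else 0.0
    if drop < NO_INHIBITION_REL_DROP:
        return EquilibriumFitResult(
            K_i_app=None,
            v_0=v0_est,
            E_0=E0_known,
            stderr={"K_i_app": None, "v_0": None},
            rss=float(np.sum((y - v0_est) ** 2)),
            n_points=len(y),
            success=False,
            diagnostics=["no-inhibition"],
        )

    def residual(pars):
        K = 10.0 ** pars["log10_Ki"].value
        E0 = 10.0 ** pars["log10_E0"].value
        ei = ei_equilibrium(E0, I_arr, K)
        return pars["v0"].value * (E0 - ei) / E0 - y

    attempts = []
    for lk0 in np.log10(E0_known) + np.array([-2.0, -1.0, 0.0, 1.0, 2.0]):
        pars = lmfit.Parameters()
        pars.add("log10_Ki", value=float(lk0), min=-15.0, max=0.0)
        pars.add(
            "log10_E0",
            value=np.log10(E0_known),
            vary=e0_mode == "shared-adjustable",
            min=np.log10(E0_known) - 2,
            max=np.log10(E0_known) + 2,
        )
        pars.add("v0", value=v0_est, min=1e-300)
        res = lmfit.minimize(
            residual, pars, method="least_squares", xtol=1e-14, ftol=1e-14, gtol=1e-14
        )
        if res.success:
            attempts.append(res)
    if not attempts:
        raise RuntimeError("equilibrium fit failed from every start")
    best = min(attempts, key=lambda r: float(np.sum(r.residual**2)))

    p = best.params
    K = 10.0 ** p["log10_Ki"].value
    se_lk = p["log10_Ki"].stderr
    stderr = {
        "K_i_app": K * LN10 * se_lk if se_lk is not None else None,
        "v_0": p["v0"].stderr,
    }
    diagnostics = []
    if p["log10_Ki"].value < -14.99:
        diagnostics.append("bound-hit:K_i_app")
    return EquilibriumFitResult(
        K_i_app=K,
        v_0=float(p["v0"].value),
        E_0=10.0 ** p["log10_E0"].value,
        stderr=stderr,
        rss=float(np.sum(best.residual**2)),
        n_points=len(y),
        success=True,
        diagnostics=diagnostics,
    )


@dataclass
class BiasReport:
    """Bias of an equilibrium-model fit applied to pre-equilibrium data.

    ``K_i_app_at_t`` is the Morrison fit of a noiseless curve generated by
    the integrated rate law at incubation time ``t``; ``K_i_true`` is
    k_off/k_on; ``bias_ratio`` their quotient (1 means fully equilibrated).
    ``K_i_app_equilibrium_fit`` is the Morrison fit of the t -> infinity
    curve on the same grid, a consistency check on the fitting route.
    """

    K_i_app_at_t: float
    K_i_true: float
    bias_ratio: float
    K_i_app_equilibrium_fit: float
    t: float
    E_0: float
    grid: list[float]


def equilibration_bias_report(
    params: BindingParameters,
    E_0: float,
    t: float,
    grid: Sequence[float] | None = None,
    v_0: float = 1.0,
) -> BiasReport:
    """Quantify the K_i overestimate from incomplete equilibration.

    Simulates a noiseless titration at incubation time ``t`` with the
    integrated rate law, fits the equilibrium tight-binding model to it,
    and compares the fitted apparent K_i with the true k_off/k_on.  The
    default concentration grid is an 11-point twofold dilution from
    8 * E_0 plus the no-inhibitor control.
    """
    if grid is None:
        grid = dilution_series(8.0 * E_0, 2.0, 11)
    grid = [float(g) for g in grid]

    def fit_curve(rates: np.ndarray, tp: float) -> float:
        df = pd.DataFrame(
            {"time_s": tp, "inhibitor_conc_M": grid, "rate": rates}
        )
        ds = TitrationDataset(
            records=df,
            conditions=AssayConditions(E_0=E_0, timepoints=(tp,)),
            provenance="bias-report",
        )
        res = fit_equilibrium(ds, E_0=E_0)
        if res.K_i_app is None:
            raise RuntimeError("bias report: no inhibition in simulated curve")
        return res.K_i_app

    rates_t = residual_rate_preeq(v_0, float(t), E_0, np.array(grid), params)
    ki_at_t = fit_curve(rates_t, float(t))
    ki_true = params.K_i
    rates_eq = residual_rate_eq(v_0, E_0, np.array(grid), ki_true)
    ki_eq_fit = fit_curve(rates_eq, 1.0)
    return BiasReport(
        K_i_app_at_t=ki_at_t,
        K_i_true=ki_true,
        bias_ratio=ki_at_t / ki_true,
        K_i_app_equilibrium_fit=ki_eq_fit,
        t=float(t),
        E_0=E_0,
        grid=grid,
    )
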