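"""Initial-rate extraction from raw fluorescence progress traces.

A plate reader records product fluorescence vs. time per well; the
observable fed to the titration fit is the initial rate — the slope of the
early, linear portion of that trace.  Two validity guards apply: the fitted
window must be linear (r^2 threshold), and no more than 10% of the substrate
may have been hydrolyzed over the recorded trace, otherwise substrate
depletion biases the slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = ["ProgressTrace", "RateEstimate", "fit_initial_rate", "hydrolysis_fraction", "subtract_blank"]

#: trace fraction of substrate hydrolyzed above which the rate is not "initial"
MAX_HYDROLYSIS_FRACTION = 0.10
#: default linearity bar for the windowed least-squares fit
DEFAULT_R2_THRESHOLD = 0.98
#: default fitting window (s) from the start of the trace
DEFAULT_WINDOW_S = 60.0


@dataclass(frozen=True)
class ProgressTrace:
    """Raw fluorescence vs. time for one well.

    ``substrate_conc`` (mol/L) and ``signal_per_product`` (signal units per
    mol/L of product) are optional calibration inputs; without them the
    hydrolysis-fraction guard cannot be evaluated and is reported unknown.
    """

    times: np.ndarray
    signal: np.ndarray
    well_id: str = "well"
    substrate_conc: Optional[float] = None
    signal_per_product: Optional[float] = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        signal = np.asarray(self.signal, dtype=float)
        if times.ndim != 1 or signal.shape != times.shape:
            raise ValueError("times and signal must be 1-D arrays of equal length")
        if times.size < 4:
            raise ValueError(f"trace needs >= 4 points, got {times.size}")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(signal)):
            raise ValueError("signal contains non-finite values")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "signal", signal)


@dataclass(frozen=True)
class RateEstimate:
    """Initial rate for one well, with fit and QC diagnostics.

    ``hydrolysis_fraction`` is None when the trace carries no calibration
    (fraction unknown); QC then rests on linearity alone.
    """

    rate: float
    intercept: float
    r_squared: float
    stderr: float
    hydrolysis_fraction: Optional[float]
    window: tuple[float, float]
    qc_pass: bool
    n_points: int
    well_id: str = "well"


def hydrolysis_fraction(trace: ProgressTrace) -> float:
    """Fraction of substrate converted over the recorded trace.

    (max signal - min signal) / (signal_per_product * substrate_conc).
    """
    if trace.substrate_conc is None or trace.signal_per_product is None:
        raise ValueError("substrate_conc and signal_per_product are required")
    if trace.substrate_conc <= 0:
        raise ValueError(f"substrate_conc must be > 0, got {trace.substrate_conc}")
    if trace.signal_per_product <= 0:
        raise ValueError(f"signal_per_product must be > 0, got {trace.signal_per_product}")
    delta = float(np.max(trace.signal) - np.min(trace.signal))
    return delta / (trace.signal_per_product * trace.substrate_conc)


def fit_initial_rate(
    trace: ProgressTrace,
    window: tuple[float, float] | None = None,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    max_hydrolysis: float = MAX_HYDROLYSIS_FRACTION,
) -> RateEstimate:
    """Ordinary least-squares slope of the trace over a time window.

    Parameters
    ----------
    window : (t_start, t_end), optional
        Defaults to the first 60 s of the trace.
    r2_threshold : float
        QC fails when the windowed r^2 falls below this.
    max_hydrolysis : float
        QC fails when more than this fraction of substrate was consumed
        (evaluated over the whole trace, only if calibration is present;
        the boundary value itself passes).

    Returns
    -------
    RateEstimate
    """
    if window is None:
        window = (float(trace.times[0]), float(trace.times[0]) + DEFAULT_WINDOW_S)
    t0, t1 = float(window[0]), float(window[1])
    if t1 <= t0:
        raise ValueError(f"empty window ({t0}, {t1})")
    mask = (trace.times >= t0) & (trace.times <= t1)
    if int(mask.sum()) < 4:
        raise ValueError(f"window ({t0}, {t1}) contains {int(mask.sum())} points; >= 4 required")
    t = trace.times[mask]
    y = trace.signal[mask]
    if np.var(t) == 0:
        raise ValueError("zero time variance in window")

    if np.ptp(y) == 0:
        # constant signal: exact zero-slope fit, residuals identically zero
        slope, intercept, stderr, r2 = 0.0, float(y[0]), 0.0, 1.0
    else:
        res = stats.linregress(t, y)
        slope, intercept, stderr = float(res.slope), float(res.intercept), float(res.stderr)
        r2 = float(res.rvalue**2)

    frac: Optional[float]
    if trace.substrate_conc is not None and trace.signal_per_product is not None:
        frac = hydrolysis_fraction(trace)
    else:
        frac = None

    qc = r2 >= r2_threshold and (frac is None or frac <= max_hydrolysis)
    return RateEstimate(
        rate=slope,
        intercept=intercept,
        r_squared=r2,
        stderr=stderr,
        hydrolysis_fraction=frac,
        window=(float(t[0]), float(t[-1])),
        qc_pass=bool(qc),
        n_points=int(mask.sum()),
        well_id=trace.well_id,
    )


def subtract_blank(trace: ProgressTrace, blank: ProgressTrace) -> ProgressTrace:
    """Pointwise subtraction of a no-enzyme blank trace (same time grid)."""
    if blank.times.shape != trace.times.shape or not np.allclose(blank.times, trace.times):
        raise ValueError("blank trace must share the sample's time grid")
    return ProgressTrace(
        times=trace.times,
        signal=trace.signal - blank.signal,
        well_id=trace.well_id,
        substrate_conc=trace.substrate_conc,
        signal_per_product=trace.signal_per_product,
    )
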