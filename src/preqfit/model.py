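"""Closed-form kinetics of reversible 1:1 enzyme-inhibitor binding.

This module implements the integrated rate law for the bimolecular
association/dissociation scheme

    E + I  <-- k_on / k_off -->  EI

with total (not free) concentrations ``E_0`` and ``I_0``, i.e. without the
classical simplification ``I_free ~ I_0`` that breaks down for tight-binding
inhibitors (``I_0 ~ E_0``).  The occupancy at incubation time ``t`` follows

    d[EI]/dt = k_on (E_0 - [EI]) (I_0 - [EI]) - k_off [EI],   [EI]_0 = 0

whose closed-form solution, with

    a = k_on (E_0 + I_0) + k_off
    b = sqrt(a^2 - 4 k_on^2 E_0 I_0)
    c = ((a - b)/(a + b)) exp(-b t)

is  [EI]_t = (a (1 - c) - b (1 + c)) / (2 k_on (1 - c)).

Internally we evaluate the algebraically identical form

    [EI]_t = 2 k_on E_0 I_0 u / (a u + b (2 - u)),   u = 1 - exp(-b t),

which has no 0/0 at t = 0, cannot overflow, and degrades gracefully into the
b -> 0 limit  a^2 t / (2 k_on (2 + a t))  (reached only when k_off = 0 and
E_0 = I_0).  The radicand of ``b`` is expanded as

    k_on^2 (E_0 - I_0)^2 + k_off^2 + 2 k_off k_on (E_0 + I_0),

a sum of nonnegative terms, so ``b`` is computed without catastrophic
cancellation even at stoichiometric equivalence with slow dissociation.

At equilibrium the occupancy reduces to the Morrison tight-binding root

    [EI]_eq = ((E_0 + I_0 + K) - sqrt((E_0 + I_0 + K)^2 - 4 E_0 I_0)) / 2

with K the apparent inhibition constant; residual enzymatic activity relates
to occupancy through  v_i = v_0 (E_0 - [EI]) / E_0  (pure competitive
readout: the bound enzyme fraction is fully inactive).

All quantities are SI: mol/L, s, L mol^-1 s^-1.  Human-facing reports
convert to nM elsewhere; this module never does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "BindingParameters",
    "AssayConditions",
    "OccupancyPoint",
    "ModelIntermediates",
    "ei_concentration",
    "ei_equilibrium",
    "residual_rate_preeq",
    "residual_rate_eq",
    "apparent_from_true",
    "true_from_apparent",
    "ki_from_rates",
    "ei_ode_oracle",
]


@dataclass(frozen=True)
class BindingParameters:
    """Rate constants of one enzyme-inhibitor pair.

    Attributes
    ----------
    k_on : float
        Second-order association rate constant, L mol^-1 s^-1.
    k_off : float
        First-order dissociation rate constant, s^-1.  ``1/k_off`` is the
        drug-target residence time.
    """

    k_on: float
    k_off: float

    def __post_init__(self) -> None:
        if not (self.k_on > 0):
            raise ValueError(f"k_on must be > 0, got {self.k_on}")
        if not (self.k_off >= 0):
            raise ValueError(f"k_off must be >= 0, got {self.k_off}")

    @property
    def K_i(self) -> float:
        """Equilibrium inhibition constant k_off/k_on, mol/L."""
        return self.k_off / self.k_on


@dataclass(frozen=True)
class AssayConditions:
    """Assay-level constants: enzyme, substrate and incubation schedule.

    ``S`` and ``K_m`` matter only for the competitive apparent/true
    correction; with ``S = 0`` (the default, appropriate when S << K_m)
    apparent and true parameters coincide.
    """

    E_0: float
    timepoints: tuple[float, ...]
    S: float = 0.0
    K_m: float | None = None

    def __post_init__(self) -> None:
        if not (self.E_0 > 0):
            raise ValueError(f"E_0 must be > 0, got {self.E_0}")
        if not (self.S >= 0):
            raise ValueError(f"S must be >= 0, got {self.S}")
        if self.K_m is not None and not (self.K_m > 0):
            raise ValueError(f"K_m must be > 0, got {self.K_m}")
        tp = tuple(float(t) for t in self.timepoints)
        if len(tp) == 0:
            raise ValueError("at least one timepoint required")
        if any(t <= 0 for t in tp):
            raise ValueError("timepoints must be strictly positive")
        if any(t2 <= t1 for t1, t2 in zip(tp, tp[1:])):
            raise ValueError("timepoints must be strictly increasing")
        object.__setattr__(self, "timepoints", tp)


@dataclass(frozen=True)
class OccupancyPoint:
    """One (inhibitor concentration, occupancy, rate) observation."""

    I_0: float
    EI_t: float
    v_i: float
    v_0: float


@dataclass(frozen=True)
class ModelIntermediates:
    """The intermediates a, b, c of the integrated rate law at one (t, I_0)."""

    a: float
    b: float
    c: float

    @classmethod
    def compute(
        cls, t: float, E_0: float, I_0: float, params: BindingParameters
    ) -> "ModelIntermediates":
        _check_domain(t, E_0, I_0)
        a = params.k_on * (E_0 + I_0) + params.k_off
        b = float(np.sqrt(_b_radicand(E_0, I_0, params.k_on, params.k_off)))
        ratio = (a - b) / (a + b) if (a + b) > 0 else 0.0
        c = ratio * float(np.exp(-min(b * t, 745.0)))
        return cls(a=a, b=b, c=c)


def _check_domain(t, E_0, I_0) -> None:
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be >= 0")
    if not (E_0 > 0):
        raise ValueError(f"E_0 must be > 0, got {E_0}")
    if np.any(np.asarray(I_0) < 0):
        raise ValueError("I_0 must be >= 0")


def _b_radicand(E_0, I_0, k_on, k_off):
    # a^2 - 4 k_on^2 E_0 I_0 expanded into nonnegative terms
    return (k_on * (E_0 - I_0)) ** 2 + k_off**2 + 2.0 * k_off * k_on * (E_0 + I_0)


def ei_concentration(t, E_0: float, I_0, params: BindingParameters):
    """Enzyme-inhibitor complex concentration [EI]_t, mol/L.

    Evaluates the integrated 1:1 binding law starting from [EI]_0 = 0.
    ``t`` and ``I_0`` may be scalars or arrays (broadcast together).

    Parameters
    ----------
    t : float or array
        Incubation time, s.  Must be >= 0.
    E_0 : float
        Total enzyme concentration, mol/L.
    I_0 : float or array
        Total inhibitor concentration, mol/L.
    params : BindingParameters

    Returns
    -------
    float or ndarray
        [EI]_t, guaranteed within [0, min(E_0, I_0)], nondecreasing in t.
    """
    _check_domain(t, E_0, I_0)
    t = np.asarray(t, dtype=float)
    I0 = np.asarray(I_0, dtype=float)
    k_on, k_off = params.k_on, params.k_off

    a = k_on * (E_0 + I0) + k_off
    b = np.sqrt(_b_radicand(E_0, I0, k_on, k_off))
    u = -np.expm1(-b * t)  # 1 - exp(-b t), exact at both ends
    denom = a * u + b * (2.0 - u)
    with np.errstate(divide="ignore", invalid="ignore"):
        ei = np.where(denom > 0, 2.0 * k_on * E_0 * I0 * u / np.where(denom > 0, denom, 1.0), 0.0)

    # degenerate b == 0 (k_off = 0 and E_0 = I_0): limit a^2 t/(2 k_on (2 + a t))
    deg = (b == 0) & (t > 0) & (I0 > 0)
    if np.any(deg):
        ei = np.where(deg, 2.0 * k_on * E_0 * I0 * t / (a * t + 2.0), ei)

    ei = np.where((t == 0) | (I0 == 0), 0.0, ei)
    ei = np.clip(ei, 0.0, np.minimum(E_0, I0))
    return ei if ei.ndim else float(ei)


def ei_equilibrium(E_0: float, I_0, K_i_app: float):
    """Equilibrium complex concentration from the tight-binding quadratic.

    This is the root term subtracted from ``E_0`` in the Morrison residual
    activity expression; it equals the t -> infinity limit of
    :func:`ei_concentration` when ``K_i_app = k_off/k_on``.
    """
    if not (E_0 > 0):
        raise ValueError(f"E_0 must be > 0, got {E_0}")
    if np.any(np.asarray(I_0) < 0) or K_i_app < 0:
        raise ValueError("I_0 and K_i_app must be >= 0")
    I0 = np.asarray(I_0, dtype=float)
    s = E_0 + I0 + K_i_app
    # stable expansion of s^2 - 4 E_0 I_0; mathematically >= 0
    rad = (E_0 - I0) ** 2 + K_i_app**2 + 2.0 * K_i_app * (E_0 + I0)
    neg = rad < 0
    if np.any(neg):  # unreachable with the expansion above; kept as a guard
        warnings.warn("negative radicand clamped to zero in ei_equilibrium")
        rad = np.where(neg, 0.0, rad)
    # smaller quadratic root via the numerically stable co-root form
    ei = 2.0 * E_0 * I0 / (s + np.sqrt(rad))
    ei = np.clip(ei, 0.0, np.minimum(E_0, I0))
    return ei if ei.ndim else float(ei)


def residual_rate_preeq(v_0: float, t, E_0: float, I_0, params: BindingParameters):
    """Inhibited initial rate v_i after incubation time t (pre-equilibrium).

    v_i = v_0 (E_0 - [EI]_t)/E_0, combining the integrated binding law with
    the proportionality of rate to free enzyme.
    """
    if not (v_0 > 0):
        raise ValueError(f"v_0 must be > 0, got {v_0}")
    ei = ei_concentration(t, E_0, I_0, params)
    return v_0 * (E_0 - ei) / E_0


def residual_rate_eq(v_0: float, E_0: float, I_0, K_i_app: float):
    """Inhibited rate at binding equilibrium (Morrison tight-binding curve)."""
    if not (v_0 > 0):
        raise ValueError(f"v_0 must be > 0, got {v_0}")
    ei = ei_equilibrium(E_0, I_0, K_i_app)
    return v_0 * (E_0 - ei) / E_0


def apparent_from_true(params: BindingParameters, S: float, K_m: float) -> BindingParameters:
    """Apparent rate constants under competitive inhibition at substrate S.

    k_on,app = k_on/(1 + S/K_m);  k_off,app = k_off;  hence
    K_i,app = K_i (1 + S/K_m).  Identity at S = 0.
    """
    if not (K_m > 0):
        raise ValueError(f"K_m must be > 0, got {K_m}")
    if S < 0:
        raise ValueError(f"S must be >= 0, got {S}")
    return BindingParameters(k_on=params.k_on / (1.0 + S / K_m), k_off=params.k_off)


def true_from_apparent(params: BindingParameters, S: float, K_m: float) -> BindingParameters:
    """Inverse of :func:`apparent_from_true`."""
    if not (K_m > 0):
        raise ValueError(f"K_m must be > 0, got {K_m}")
    if S < 0:
        raise ValueError(f"S must be >= 0, got {S}")
    return BindingParameters(k_on=params.k_on * (1.0 + S / K_m), k_off=params.k_off)


def ki_from_rates(k_on: float, k_off: float) -> float:
    """Equilibrium inhibition constant K_i = k_off/k_on, mol/L."""
    if not (k_on > 0):
        raise ValueError(f"k_on must be > 0, got {k_on}")
    if k_off < 0:
        raise ValueError(f"k_off must be >= 0, got {k_off}")
    return k_off / k_on


def ei_ode_oracle(
    t: float,
    E_0: float,
    I_0: float,
    params: BindingParameters,
    rtol: float = 1e-10,
) -> float:
    """[EI]_t by direct numerical integration of the binding ODE.

    Brute-force reference implementation used to validate the closed form;
    integrates d[EI]/dt = k_on (E_0 - [EI])(I_0 - [EI]) - k_off [EI] from
    [EI]_0 = 0 with a stiff-capable solver.
    """
    _check_domain(t, E_0, I_0)
    if t == 0 or I_0 == 0:
        return 0.0
    k_on, k_off = params.k_on, params.k_off

    def rhs(_t, y):
        ei = y[0]
        return [k_on * (E_0 - ei) * (I_0 - ei) - k_off * ei]

    atol = rtol * min(E_0, I_0) * 1e-3
    sol = solve_ivp(rhs, (0.0, float(t)), [0.0], method="Radau", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message} (t={t}, E_0={E_0}, I_0={I_0})")
    return float(sol.y[0, -1])
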