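"""Irreversible two-tissue-compartment FDG kinetics and SUV conversion.

The model is the standard Sokoloff-type description of FDG in brain:
plasma tracer Cp(t) exchanges with a free tissue pool C1 (rates K1 in,
k2 out) and is phosphorylated into a trapped pool C2 by hexokinase at
rate k3; dephosphorylation k4 is fixed at 0, a good approximation over
scan horizons of up to ~3 h::

    dC1/dt = K1*Cp(t) - (k2 + k3)*C1,   C1(0) = 0
    dC2/dt = k3*C1,                     C2(0) = 0
    Ct(t)  = C1(t) + C2(t)

With alpha = k2 + k3 and the Patlak influx rate Ki = K1*k3/alpha the
total tissue activity admits the equivalent integral form

    Ct(t) = Ki * int_0^t Cp(s) ds
          + (K1*k2/alpha) * int_0^t exp(-alpha*(t-s)) * Cp(s) ds

which is what this module evaluates.  For the tri-exponential (Feng)
plasma input both integrals have exact closed forms, used directly; for
tabulated inputs they are computed by adaptive quadrature.  A tissue
density of 1 g/mL reconciles per-gram rate constants with per-mL image
units.

Activities are treated as decay-corrected to injection time throughout
(standard scanner output), which is why SUV can rise between an early
and a delayed scan.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

__all__ = [
    "PlasmaInput",
    "KineticParams",
    "InfluxRate",
    "ScanProtocol",
    "plasma_concentration",
    "tissue_activity",
    "patlak_ki",
    "suv_from_activity",
    "tac_table",
]

logger = logging.getLogger(__name__)

#: Default Feng-style tri-exponential input coefficients (kBq/mL scale).
#: Literature-style values for a bolus FDG injection; configurable.
DEFAULT_FENG = dict(A1=851.1, A2=21.9, A3=20.8, l1=-4.134, l2=-0.1191, l3=-0.0104)


@dataclass(frozen=True)
class PlasmaInput:
    """Arterial plasma FDG concentration model.

    mode "feng": Cp(t) = (A1*t - A2 - A3)*e^{l1 t} + A2*e^{l2 t} + A3*e^{l3 t}
    with all eigenvalues negative; Cp(0) = 0 by construction.

    mode "tabulated": linear interpolation of (times, concentrations)
    samples, zero outside the sampled range (a warning is logged past the
    last sample).
    """

    mode: str = "feng"
    A1: float = DEFAULT_FENG["A1"]
    A2: float = DEFAULT_FENG["A2"]
    A3: float = DEFAULT_FENG["A3"]
    l1: float = DEFAULT_FENG["l1"]
    l2: float = DEFAULT_FENG["l2"]
    l3: float = DEFAULT_FENG["l3"]
    times: tuple = field(default=())
    concentrations: tuple = field(default=())

    def __post_init__(self):
        if self.mode not in ("feng", "tabulated"):
            raise ValueError(f"unknown plasma input mode {self.mode!r}")
        if self.mode == "feng":
            if not (self.l1 < 0 and self.l2 < 0 and self.l3 < 0):
                raise ValueError("feng eigenvalues l1, l2, l3 must all be negative")
        else:
            t = np.asarray(self.times, dtype=float)
            c = np.asarray(self.concentrations, dtype=float)
            if t.size < 2 or t.size != c.size:
                raise ValueError("tabulated input needs >= 2 matching samples")
            if np.any(np.diff(t) <= 0):
                raise ValueError("tabulated times must be strictly increasing")
            if np.any(c < 0):
                raise ValueError("tabulated concentrations must be non-negative")


@dataclass(frozen=True)
class KineticParams:
    """Regional rate constants: K1 (mL/min/g), k2, k3 (1/min); k4 fixed 0."""

    K1: float
    k2: float
    k3: float

    def __post_init__(self):
        if self.K1 < 0 or self.k2 < 0 or self.k3 < 0:
            raise ValueError("rate constants must be non-negative")
        if self.k3 > 0 and self.k2 + self.k3 <= 0:
            raise ValueError("k2 + k3 must be positive when k3 > 0")

    def scaled(self, K1_factor: float = 1.0, k2_factor: float = 1.0, k3_factor: float = 1.0) -> "KineticParams":
        return KineticParams(self.K1 * K1_factor, self.k2 * k2_factor, self.k3 * k3_factor)


@dataclass(frozen=True)
class InfluxRate:
    """Patlak net influx rate Ki = K1*k3/(k2+k3), mL/min/g."""

    Ki: float


@dataclass(frozen=True)
class ScanProtocol:
    """Injection and acquisition protocol: dose per kg and the two delays."""

    dose_per_kg: float = 3.7  # MBq/kg
    t_early: float = 43.44  # min post injection
    t_delayed: float = 160.46  # min

    def __post_init__(self):
        if not (0 < self.t_early < self.t_delayed):
            raise ValueError("need 0 < t_early < t_delayed")
        if self.dose_per_kg <= 0:
            raise ValueError("dose_per_kg must be positive")


def plasma_concentration(inp: PlasmaInput, t):
    """Plasma concentration Cp(t) in kBq/mL at time(s) t (min post injection)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if inp.mode == "feng":
        cp = (
            (inp.A1 * t - inp.A2 - inp.A3) * np.exp(inp.l1 * t)
            + inp.A2 * np.exp(inp.l2 * t)
            + inp.A3 * np.exp(inp.l3 * t)
        )
        cp = np.maximum(cp, 0.0)
    else:
        times = np.asarray(inp.times, dtype=float)
        conc = np.asarray(inp.concentrations, dtype=float)
        if np.any(t > times[-1]):
            logger.warning(
                "plasma_concentration: time beyond last tabulated sample (%g min); returning 0",
                times[-1],
            )
        cp = np.interp(t, times, conc, left=0.0, right=0.0)
    return cp if cp.ndim else float(cp)


def _int_exp(lam, t):
    """int_0^t e^{lam s} ds, stable as lam -> 0."""
    lam = np.asarray(lam, dtype=float)
    t = np.asarray(t, dtype=float)
    small = np.abs(lam * t) < 1e-8
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(small, t * (1 + lam * t / 2), (np.expm1(lam * t)) / np.where(lam == 0, 1.0, lam))
    return out


def _int_t_exp(lam, t):
    """int_0^t s e^{lam s} ds, stable as lam -> 0."""
    lam = np.asarray(lam, dtype=float)
    t = np.asarray(t, dtype=float)
    small = np.abs(lam * t) < 1e-6
    lam_safe = np.where(lam == 0, 1.0, lam)
    exact = (t * np.exp(lam * t)) / lam_safe - np.expm1(lam * t) / lam_safe**2
    series = t**2 / 2 * (1 + 2 * lam * t / 3)
    return np.where(small, series, exact)


def _feng_integrals(inp: PlasmaInput, t, alpha: float):
    """(int_0^t Cp, int_0^t e^{-alpha (t-s)} Cp(s) ds) for the feng mode."""
    t = np.asarray(t, dtype=float)
    B = -(inp.A2 + inp.A3)  # constant companion of the A1*t term
    # I1 = A1*T(l1) + B*E(l1) + A2*E(l2) + A3*E(l3)
    i1 = (
        inp.A1 * _int_t_exp(inp.l1, t)
        + B * _int_exp(inp.l1, t)
        + inp.A2 * _int_exp(inp.l2, t)
        + inp.A3 * _int_exp(inp.l3, t)
    )
    # I2 = e^{-alpha t} * [A1*T(l1+alpha) + B*E(l1+alpha) + A2*E(l2+alpha) + A3*E(l3+alpha)]
    damp = np.exp(-alpha * t)
    i2 = damp * (
        inp.A1 * _int_t_exp(inp.l1 + alpha, t)
        + B * _int_exp(inp.l1 + alpha, t)
        + inp.A2 * _int_exp(inp.l2 + alpha, t)
        + inp.A3 * _int_exp(inp.l3 + alpha, t)
    )
    return i1, i2


def tissue_activity(kp: KineticParams, inp: PlasmaInput, t, quad_tol: float = 1e-6):
    """Total tissue activity Ct(t) = C1(t) + C2(t) in kBq/mL.

    Closed-form evaluation for the feng input mode; adaptive quadrature
    (absolute tolerance `quad_tol` kBq/mL) for tabulated inputs.
    Accepts scalar or array t.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    if kp.K1 == 0:
        out = np.zeros_like(t_arr)
        return out if t_arr.ndim else 0.0
    alpha = kp.k2 + kp.k3
    ki = kp.K1 * kp.k3 / alpha if alpha > 0 else 0.0

    if inp.mode == "feng":
        i1, i2 = _feng_integrals(inp, t_arr, alpha)
    else:
        flat = np.atleast_1d(t_arr)
        i1 = np.empty(flat.shape)
        i2 = np.empty(flat.shape)
        for j, tj in enumerate(flat):
            i1[j] = integrate.quad(
                lambda s: plasma_concentration(inp, s), 0, tj, epsabs=quad_tol, limit=200
            )[0]
            i2[j] = integrate.quad(
                lambda s: math.exp(-alpha * (tj - s)) * plasma_concentration(inp, s),
                0,
                tj,
                epsabs=quad_tol,
                limit=200,
            )[0]
        i1 = i1.reshape(t_arr.shape)
        i2 = i2.reshape(t_arr.shape)

    if alpha > 0:
        ct = ki * i1 + (kp.K1 * kp.k2 / alpha) * i2
    else:
        # k2 = k3 = 0: pure unidirectional transport into the free pool
        ct = kp.K1 * i1
    return ct if t_arr.ndim else float(ct)


def patlak_ki(kp: KineticParams) -> InfluxRate:
    """Net FDG influx (trapping) rate Ki = K1*k3/(k2+k3)."""
    if kp.k2 + kp.k3 <= 0:
        raise ValueError("patlak_ki requires k2 + k3 > 0")
    return InfluxRate(Ki=kp.K1 * kp.k3 / (kp.k2 + kp.k3))


def suv_from_activity(activity, dose_MBq: float, weight_kg: float):
    """Standardized uptake value from activity concentration.

    SUV = activity [kBq/mL] * body weight [g] / injected dose [kBq];
    with weight in kg and dose in MBq the unit factors of 1000 cancel,
    so numerically SUV = activity * weight / dose.  Activities are
    assumed decay-corrected to injection time.
    """
    if dose_MBq <= 0 or weight_kg <= 0:
        raise ValueError("dose and weight must be positive")
    activity = np.asarray(activity, dtype=float)
    suv = activity * weight_kg / dose_MBq
    return suv if suv.ndim else float(suv)


def tac_table(kp: KineticParams, inp: PlasmaInput, times, dose_MBq: float, weight_kg: float):
    """Time-activity curve as a pandas DataFrame (t_min, Cp, Ct, SUV)."""
    import pandas as pd

    times = np.asarray(times, dtype=float)
    cp = plasma_concentration(inp, times)
    ct = tissue_activity(kp, inp, times)
    return pd.DataFrame(
        {
            "t_min": times,
            "Cp_kBq_per_mL": np.atleast_1d(cp),
            "Ct_kBq_per_mL": np.atleast_1d(ct),
            "SUV": np.atleast_1d(suv_from_activity(ct, dose_MBq, weight_kg)),
        }
    )
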