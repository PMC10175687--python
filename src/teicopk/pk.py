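"""Two-compartment intravenous-infusion kinetics.

Deterministic layer: given one set of disposition parameters (CL, V1, Q, V2)
and a list of timed infusions, compute the central-compartment concentration
at arbitrary times by analytic superposition of biexponential infusion
responses, and the area under the curve either analytically or by the linear
trapezoidal rule.

The closed form is the production path; a numerical ODE integration of the
same system is kept in the test suite as an independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "StructuralParams",
    "MicroRates",
    "DoseEvent",
    "ConcProfile",
    "micro_rates",
    "conc_at",
    "conc_profile",
    "auc",
]


@dataclass(frozen=True)
class StructuralParams:
    """Disposition parameters of one subject.

    CL : clearance, L/h
    V1 : central volume of distribution, L
    Q  : intercompartmental clearance, L/h
    V2 : peripheral volume of distribution, L
    """

    CL: float
    V1: float
    Q: float
    V2: float

    def __post_init__(self) -> None:
        for name in ("CL", "V1", "Q", "V2"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive and finite, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.CL, self.V1, self.Q, self.V2], dtype=float)


@dataclass(frozen=True)
class MicroRates:
    """First-order micro rate constants and hybrid disposition constants (1/h)."""

    k10: float
    k12: float
    k21: float
    alpha: float
    beta: float

    @property
    def terminal_half_life(self) -> float:
        """Terminal (beta-phase) half-life in hours."""
        return math.log(2.0) / self.beta


@dataclass(frozen=True)
class DoseEvent:
    """One intravenous infusion: start time (h from first dose), amount (mg), duration (h)."""

    start: float
    amount: float
    duration: float = 1.0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"dose start must be >= 0, got {self.start}")
        if self.amount < 0:
            raise ValueError(f"dose amount must be >= 0, got {self.amount}")
        if self.duration <= 0:
            raise ValueError(f"infusion duration must be > 0, got {self.duration}")


@dataclass(frozen=True)
class ConcProfile:
    """A concentration-time grid (times h, conc mg/L)."""

    times: np.ndarray
    conc: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be a strictly increasing 1-D grid")


def micro_rates(p: StructuralParams) -> MicroRates:
    """Convert (CL, V1, Q, V2) to micro constants and hybrid constants.

    k10 = CL/V1, k12 = Q/V1, k21 = Q/V2; alpha/beta are the roots of
    s^2 - (k10+k12+k21) s + k10*k21 with alpha > beta > 0.
    """
    k10 = p.CL / p.V1
    k12 = p.Q / p.V1
    k21 = p.Q / p.V2
    s = k10 + k12 + k21
    disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    # numerically safer beta: alpha*beta = k10*k21
    if alpha > 0:
        beta = k10 * k21 / alpha
    return MicroRates(k10=k10, k12=k12, k21=k21, alpha=alpha, beta=beta)


def _dose_arrays(doses: Iterable[DoseEvent]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ds = list(doses)
    if not ds:
        z = np.zeros(0)
        return z, z.copy(), z.copy()
    starts = np.array([d.start for d in ds], dtype=float)
    amounts = np.array([d.amount for d in ds], dtype=float)
    durations = np.array([d.duration for d in ds], dtype=float)
    return starts, amounts, durations


def _hybrid_arrays(params: np.ndarray):
    """Batched hybrid constants from a (..., 4) parameter array.

    Returns alpha, beta, coefA, coefB with coefA = (alpha-k21)/(alpha-beta),
    coefB = (k21-beta)/(alpha-beta) (bolus coefficients; coefA+coefB = 1).
    """
    CL, V1, Q, V2 = (params[..., i] for i in range(4))
    k10 = CL / V1
    k12 = Q / V1
    k21 = Q / V2
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = k10 * k21 / alpha
    denom = alpha - beta
    coefA = (alpha - k21) / denom
    coefB = (k21 - beta) / denom
    return alpha, beta, coefA, coefB, V1


def _conc_batch_numpy(params, times, starts, amts, durs):
    alpha, beta, coefA, coefB, V1 = _hybrid_arrays(params)  # (S,)
    tau = times[:, :, None] - starts[:, None, :]  # (S, T, D)
    tau_on = np.clip(tau, 0.0, durs[:, None, :])
    tau_off = np.maximum(tau - durs[:, None, :], 0.0)
    rate = amts / durs  # mg/h, (S, D)
    a = alpha[:, None, None]
    b = beta[:, None, None]
    term = (coefA[:, None, None] / a) * (-np.expm1(-a * tau_on)) * np.exp(-a * tau_off)
    term += (coefB[:, None, None] / b) * (-np.expm1(-b * tau_on)) * np.exp(-b * tau_off)
    return np.einsum("std,sd->st", term, rate) / V1[:, None]


try:  # pragma: no cover - exercised indirectly through conc_batch
    import numba

    @numba.njit(cache=True)
    def _conc_kernel(params, times, starts, amts, durs, out):  # pragma: no cover
        S, T = times.shape
        D = starts.shape[1]
        for s in range(S):
            CL = params[s, 0]
            V1 = params[s, 1]
            Q = params[s, 2]
            V2 = params[s, 3]
            ok = (
                math.isfinite(CL) and math.isfinite(V1)
                and math.isfinite(Q) and math.isfinite(V2)
                and CL > 0.0 and V1 > 0.0 and Q > 0.0 and V2 > 0.0
            )
            if not ok:
                for t in range(T):
                    out[s, t] = math.nan
                continue
            k10 = CL / V1
            k12 = Q / V1
            k21 = Q / V2
            ssum = k10 + k12 + k21
            disc = math.sqrt(max(ssum * ssum - 4.0 * k10 * k21, 0.0))
            al = 0.5 * (ssum + disc)
            be = k10 * k21 / al
            den = al - be
            cA = (al - k21) / den
            cB = (k21 - be) / den
            for t in range(T):
                tt = times[s, t]
                acc = 0.0
                for d in range(D):
                    amt = amts[s, d]
                    if amt <= 0.0:
                        continue
                    tau = tt - starts[s, d]
                    if tau <= 0.0:
                        continue
                    dur = durs[s, d]
                    ton = tau if tau < dur else dur
                    toff = tau - dur if tau > dur else 0.0
                    ea = cA / al * (-math.expm1(-al * ton)) * math.exp(-al * toff)
                    eb = cB / be * (-math.expm1(-be * ton)) * math.exp(-be * toff)
                    acc += (ea + eb) * amt / dur
                out[s, t] = acc / V1

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def conc_batch(
    params: np.ndarray,
    times: np.ndarray,
    dose_starts: np.ndarray,
    dose_amounts: np.ndarray,
    dose_durations: np.ndarray,
) -> np.ndarray:
    """Vectorized central concentration.

    params : (S, 4) array of (CL, V1, Q, V2) rows.
    times : (T,) shared grid or (S, T) per-row times.
    dose_* : (D,) shared schedule or (S, D) per-row schedules.
    Returns (S, T) concentrations in mg/L.

    A dose contributes zero at its own start time, so evaluating exactly at a
    dose time yields the pre-dose (trough) concentration.
    """
    params = np.atleast_2d(np.asarray(params, dtype=float))
    times = np.asarray(times, dtype=float)
    if params.shape[0] == 1 and times.ndim == 2 and times.shape[0] > 1:
        params = np.broadcast_to(params, (times.shape[0], 4))
    S = params.shape[0]
    if times.ndim == 1:
        times = np.broadcast_to(times, (S, times.shape[0]))
    elif times.shape[0] != S:
        raise ValueError(
            f"parameter rows ({S}) and time rows ({times.shape[0]}) do not match"
        )
    starts = np.asarray(dose_starts, dtype=float)
    amts = np.asarray(dose_amounts, dtype=float)
    durs = np.asarray(dose_durations, dtype=float)
    if starts.ndim == 1:
        starts = np.broadcast_to(starts, (S, starts.shape[0]))
        amts = np.broadcast_to(amts, (S, amts.shape[0]))
        durs = np.broadcast_to(durs, (S, durs.shape[0]))
    if starts.shape[1] == 0:
        return np.zeros(times.shape)
    if _HAVE_NUMBA:
        out = np.empty(times.shape)
        _conc_kernel(
            np.ascontiguousarray(params),
            np.ascontiguousarray(times),
            np.ascontiguousarray(starts),
            np.ascontiguousarray(amts),
            np.ascontiguousarray(durs),
            out,
        )
        return out
    return _conc_batch_numpy(params, times, starts, amts, durs)


def _auc_single_batch(t, alpha, beta, coefA, coefB, durs):
    """Integral from dose start of the unit-rate infusion response, batched.

    t : (S, D) elapsed time since each dose start (clipped >= 0 by caller).
    Returns (S, D) integral of the response (before division by V1 and
    multiplication by rate).
    """
    out = np.zeros_like(t)
    for X, x in ((coefA, alpha), (coefB, beta)):
        x = x[:, None]
        X = X[:, None]
        te = np.minimum(t, durs)          # time integrated during infusion
        tp = np.maximum(t - durs, 0.0)    # time past infusion end
        on = te + np.expm1(-x * te) / x
        off = (-np.expm1(-x * te)) * (-np.expm1(-x * tp)) / x
        out += (X / x) * (on + off)
    return out


def auc_batch(
    params: np.ndarray,
    t0: float,
    t1: float,
    dose_starts: np.ndarray,
    dose_amounts: np.ndarray,
    dose_durations: np.ndarray,
) -> np.ndarray:
    """Analytic AUC of the central concentration over [t0, t1] for each parameter row."""
    params = np.atleast_2d(np.asarray(params, dtype=float))
    alpha, beta, coefA, coefB, V1 = _hybrid_arrays(params)
    S = params.shape[0]
    starts = np.asarray(dose_starts, dtype=float)
    amts = np.asarray(dose_amounts, dtype=float)
    durs = np.asarray(dose_durations, dtype=float)
    if starts.ndim == 1:
        starts = np.broadcast_to(starts, (S, starts.shape[0]))
        amts = np.broadcast_to(amts, (S, amts.shape[0]))
        durs = np.broadcast_to(durs, (S, durs.shape[0]))
    if starts.shape[1] == 0:
        return np.zeros(S)
    rate = amts / durs
    hi = np.maximum(t1 - starts, 0.0)
    lo = np.maximum(t0 - starts, 0.0)
    F = _auc_single_batch(hi, alpha, beta, coefA, coefB, durs) - _auc_single_batch(
        lo, alpha, beta, coefA, coefB, durs
    )
    return np.einsum("sd,sd->s", F, rate) / V1


def conc_at(p: StructuralParams, doses: Sequence[DoseEvent], t) -> float | np.ndarray:
    """Central concentration (mg/L) at time(s) ``t`` (h) under multi-dose superposition.

    Evaluating at a dose start time returns the trough immediately before
    that dose (the starting infusion has contributed nothing yet).
    """
    starts, amounts, durations = _dose_arrays(doses)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    out = conc_batch(p.as_array()[None, :], t_arr, starts, amounts, durations)[0]
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out[0])
    return out


def conc_profile(p: StructuralParams, doses: Sequence[DoseEvent], times) -> ConcProfile:
    """Concentration-time profile on an explicit grid."""
    times = np.asarray(times, dtype=float)
    return ConcProfile(times=times, conc=np.asarray(conc_at(p, doses, times)))


def auc(
    p: StructuralParams,
    doses: Sequence[DoseEvent],
    t0: float,
    t1: float,
    method: str = "analytic",
    grid_step: float = 0.1,
) -> float:
    """Area under the central concentration curve over [t0, t1], mg*h/L.

    method="analytic" integrates the closed-form solution exactly;
    method="trapezoid" applies the linear trapezoidal rule on a uniform grid
    of step ``grid_step`` h (default 0.1 h, <0.2% error vs analytic).
    ``t1 = inf`` is allowed for the analytic method.
    """
    if t0 < 0:
        raise ValueError("t0 must be >= 0")
    if not t1 > t0:
        raise ValueError(f"need t1 > t0, got [{t0}, {t1}]")
    starts, amounts, durations = _dose_arrays(doses)
    if starts.size == 0:
        return 0.0
    if method == "analytic":
        if math.isinf(t1):
            # limit of the closed form: each dose contributes amount/CL
            total = float(np.sum(amounts))
            tail = float(
                auc_batch(p.as_array()[None, :], t0, 0.0, starts, amounts, durations)[0]
            )  # -AUC(0, t0)
            return total / p.CL + tail
        return float(auc_batch(p.as_array()[None, :], t0, t1, starts, amounts, durations)[0])
    if method == "trapezoid":
        if math.isinf(t1):
            raise ValueError("trapezoid method requires a finite t1")
        n = max(int(math.ceil((t1 - t0) / grid_step)), 1)
        grid = np.linspace(t0, t1, n + 1)
        c = conc_at(p, doses, grid)
        return float(np.trapezoid(c, grid))
    raise ValueError(f"unknown AUC method {method!r}")
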