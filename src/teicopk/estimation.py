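"""Nonlinear mixed-effects estimation and model validation.

The marginal likelihood of each subject's sparse concentration data is
approximated by the Laplace method: the per-subject random-effect vector is
optimized to its conditional mode (empirical Bayes estimate) and the
objective function value (OFV, -2 log marginal likelihood) combines the
joint deviance at the mode with the log-determinant of the conditional
Hessian. The eta-epsilon interaction is honored by evaluating the
proportional-error variance at the conditional prediction. Population
parameters are optimized in log space by quasi-Newton iteration.

Validation operations: stepwise covariate selection with likelihood-ratio
thresholds (forward 3.84, backward 10.828), nonparametric subject-level
bootstrap, goodness-of-fit residuals (PRED/IPRED/CWRES via first-order
linearization at the conditional mode), and the prediction-corrected visual
predictive check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.optimize

from .cohort import Dataset
from .pk import conc_batch
from .population import (
    PARAM_NAMES,
    CovariateEffect,
    PopulationModel,
    _covariate_matrix,
)

__all__ = [
    "FitResult",
    "DiagnosticsTable",
    "VpcResult",
    "ofv",
    "fit",
    "covariate_step",
    "bootstrap",
    "compute_diagnostics",
    "pcvpc",
]

_VAR_FLOOR = 1e-12
_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# compiled data

class _CompiledData:
    """Dense padded arrays for batched per-subject likelihood evaluation."""

    def __init__(self, dataset: Dataset, exclude_blq: bool = True):
        d = dataset.without_blq() if exclude_blq else dataset
        subs = [s for s in d.subjects if s.observations]
        dropped = len(d.subjects) - len(subs)
        if dropped:
            warnings.warn(f"{dropped} subject(s) without usable observations dropped")
        if not subs:
            raise ValueError("dataset has no subjects with observations")
        self.ids = [s.id for s in subs]
        S = len(subs)
        J = max(len(s.observations) for s in subs)
        D = max(len(s.doses) for s in subs)
        self.y = np.zeros((S, J))
        self.tobs = np.zeros((S, J))
        self.mask = np.zeros((S, J), dtype=bool)
        self.dose_start = np.zeros((S, D))
        self.dose_amt = np.zeros((S, D))
        self.dose_dur = np.ones((S, D))
        cov_names = sorted(subs[0].covariates)
        self.cov = {c: np.zeros(S) for c in cov_names}
        for i, s in enumerate(subs):
            for j, o in enumerate(s.observations):
                self.y[i, j] = o.conc
                self.tobs[i, j] = o.time
                self.mask[i, j] = True
            for k, dose in enumerate(s.doses):
                self.dose_start[i, k] = dose.start
                self.dose_amt[i, k] = dose.amount
                self.dose_dur[i, k] = dose.duration
            for c in cov_names:
                self.cov[c][i] = s.covariates[c]
        # an observation with no prior dose has zero prediction for every
        # parameter value -> the proportional-error likelihood is undefined
        has_prior = (self.dose_start[:, None, :] < self.tobs[:, :, None]) & (
            self.dose_amt[:, None, :] > 0
        )
        bad = self.mask & ~has_prior.any(axis=2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"zero predicted concentration: subject {self.ids[i]} has an "
                f"observation at {self.tobs[i, j]} h with no preceding dose"
            )
        self.S, self.J, self.D = S, J, D
        self.n_obs = int(self.mask.sum())

    def conc(self, params: np.ndarray) -> np.ndarray:
        return conc_batch(params, self.tobs, self.dose_start, self.dose_amt, self.dose_dur)


# ---------------------------------------------------------------------------
# Laplace objective

def _tv_matrix(model: PopulationModel, data: _CompiledData) -> np.ndarray:
    tv = _covariate_matrix(model, {k: v for k, v in data.cov.items()})
    if tv.shape[0] == 1 and data.S > 1:  # no covariates recorded
        tv = np.tile(tv, (data.S, 1))
    return tv


class _RowProblem:
    """Joint per-subject likelihood machinery, batched over (model, subject) rows.

    Several candidate models (e.g. a finite-difference stencil over the
    population parameters) are evaluated in one shot: row r = (model k,
    subject i). All models must share the random-effect pattern.
    """

    def __init__(self, models: list[PopulationModel], data: _CompiledData):
        self.data = data
        self.active = np.flatnonzero(models[0].omega2_array() > 0)
        for m in models[1:]:
            if not np.array_equal(np.flatnonzero(m.omega2_array() > 0), self.active):
                raise ValueError("all models in a batch must share the IIV pattern")
        K, S = len(models), data.S
        self.K, self.S = K, S
        self.q = self.active.size
        self.R = K * S
        self.tv = np.concatenate([_tv_matrix(m, data) for m in models], axis=0)
        if self.q:
            self.om = np.concatenate(
                [np.tile(m.omega2_array()[self.active], (S, 1)) for m in models], axis=0
            )
            self.log_om_const = np.sum(np.log(2.0 * np.pi * self.om), axis=1)
        else:
            self.om = np.zeros((self.R, 0))
            self.log_om_const = np.zeros(self.R)
        self.sig2 = np.concatenate(
            [np.full(S, max(m.sigma2_prop, _VAR_FLOOR)) for m in models]
        )
        self.y = np.tile(data.y, (K, 1))
        self.mask = np.tile(data.mask, (K, 1))
        self._tobs = np.tile(data.tobs, (K, 1))
        self._dstart = np.tile(data.dose_start, (K, 1))
        self._damt = np.tile(data.dose_amt, (K, 1))
        self._ddur = np.tile(data.dose_dur, (K, 1))
        self._tiles: dict[int, tuple] = {}

    def _tiled(self, n: int):
        if n not in self._tiles:
            self._tiles[n] = tuple(
                np.tile(a, (n, 1))
                for a in (self._tobs, self._dstart, self._damt, self._ddur, self.tv)
            )
        return self._tiles[n]

    def conc(self, eta: np.ndarray) -> np.ndarray:
        """Concentrations for eta of shape (R, q) or a stencil (n, R, q)."""
        stacked = eta.ndim == 3
        n = eta.shape[0] if stacked else 1
        ea = eta.reshape(n * self.R, -1)
        tobs, ds, da, dd, tv = self._tiled(n)
        etaf = np.zeros((n * self.R, 4))
        if self.q:
            etaf[:, self.active] = ea
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            f = conc_batch(tv * np.exp(etaf), tobs, ds, da, dd)
        return f.reshape(n, self.R, -1) if stacked else f

    def gval(self, f: np.ndarray, eta: np.ndarray) -> np.ndarray:
        """Negative joint log density from precomputed concentrations."""
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            var = np.maximum(self.sig2[..., None] * f * f, _VAR_FLOOR)
            r = self.y - f
            data_term = 0.5 * np.sum(
                np.where(self.mask, r * r / var + np.log(2.0 * np.pi * var), 0.0), axis=-1
            )
            if self.q:
                prior = 0.5 * (np.sum(eta * eta / self.om, axis=-1) + self.log_om_const)
            else:
                prior = 0.0
            out = data_term + prior
        return np.where(np.isfinite(out), out, np.inf)

    def g(self, eta: np.ndarray) -> np.ndarray:
        return self.gval(self.conc(eta), eta)

    def subset(self, idx: np.ndarray) -> "_RowProblem":
        """A view of selected rows (rows are independent per-subject problems)."""
        p = object.__new__(_RowProblem)
        p.data = self.data
        p.active = self.active
        p.K, p.S = 1, len(idx)
        p.q = self.q
        p.R = len(idx)
        p.tv = self.tv[idx]
        p.om = self.om[idx]
        p.log_om_const = self.log_om_const[idx]
        p.sig2 = self.sig2[idx]
        p.y = self.y[idx]
        p.mask = self.mask[idx]
        p._tobs = self._tobs[idx]
        p._dstart = self._dstart[idx]
        p._damt = self._damt[idx]
        p._ddur = self._ddur[idx]
        p._tiles = {}
        return p


def _fd_grad_hess(g, eta, g0, h=1e-4):
    """Central-difference gradient and Hessian, all stencil points in one batched call."""
    S, q = eta.shape
    pairs = [(k, l) for k in range(q) for l in range(k + 1, q)]
    K = 2 * q + 4 * len(pairs)
    stencil = np.broadcast_to(eta, (K, S, q)).copy()
    idx = 0
    for k in range(q):
        stencil[idx, :, k] += h
        stencil[idx + 1, :, k] -= h
        idx += 2
    for k, l in pairs:
        for sk, sl in ((h, h), (h, -h), (-h, h), (-h, -h)):
            stencil[idx, :, k] += sk
            stencil[idx, :, l] += sl
            idx += 1
    vals = g(stencil)  # (K, S)
    grad = np.zeros((S, q))
    hess = np.zeros((S, q, q))
    for k in range(q):
        gp, gm = vals[2 * k], vals[2 * k + 1]
        grad[:, k] = (gp - gm) / (2 * h)
        hess[:, k, k] = (gp + gm - 2 * g0) / (h * h)
    base = 2 * q
    for m, (k, l) in enumerate(pairs):
        vpp, vpm, vmp, vmm = vals[base + 4 * m: base + 4 * m + 4]
        cross = (vpp - vpm - vmp + vmm) / (4 * h * h)
        hess[:, k, l] = cross
        hess[:, l, k] = cross
    return grad, hess


_MAX_ETA_STEP = 2.0  # cap on one inner step in eta space (log-parameter units)
_FD_H = 1e-4


def _damped_newton(prob, eta, f, val, make_gh, tol, maxiter, idx0=None):
    """Damped-Newton loop with exact row dropout.

    Rows are independent per-subject problems, so rows whose gradient
    max-norm falls below ``tol`` are removed from the working set for good;
    all evaluations then run on the shrinking subset. ``make_gh(sub, eta,
    f, val)`` returns (gradient, Hessian-like curvature) for a subset
    problem. Returns the updated master arrays and the indices still live
    at exit (empty on full convergence).
    """
    q = prob.q
    eye = np.eye(q)
    idx = np.arange(prob.R) if idx0 is None else np.asarray(idx0)
    lam_m = np.full(prob.R, 1e-5)
    fails = np.zeros(prob.R, dtype=int)  # consecutive no-step counts
    stalled: list[np.ndarray] = []
    for _ in range(maxiter):
        if idx.size == 0:
            break
        sub = prob if idx.size == prob.R else prob.subset(idx)
        e_s, f_s, v_s = eta[idx], f[idx], val[idx]
        grad, H = make_gh(sub, e_s, f_s, v_s)
        bad = ~np.isfinite(grad).all(axis=1) | ~np.isfinite(H.reshape(len(idx), -1)).all(axis=1)
        grad[bad] = 0.0
        H[bad] = eye
        gn = np.abs(grad).max(axis=1)
        live = (gn > tol) & ~bad
        keep = np.flatnonzero(live)
        idx = idx[keep]
        if idx.size == 0:
            break
        e_s, f_s, v_s = e_s[keep], f_s[keep], v_s[keep]
        grad, H = grad[keep], H[keep]
        lam = lam_m[idx]
        v_before = v_s.copy()
        # try steps on a shrinking set: rows drop out once they accept
        work = np.arange(idx.size)
        for _attempt in range(8):
            if work.size == 0:
                break
            sub_w = prob.subset(idx[work])
            Hd = H[work] + lam[work, None, None] * eye
            try:
                step = np.linalg.solve(Hd, -grad[work, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                lam[work] = np.minimum(lam[work] * 10 + 1e-6, 1e10)
                continue
            norm = np.linalg.norm(step, axis=1, keepdims=True)
            with np.errstate(invalid="ignore"):
                step = np.where(norm > _MAX_ETA_STEP, step * (_MAX_ETA_STEP / norm), step)
            trial = e_s[work] + step
            tf = sub_w.conc(trial)
            tval = sub_w.gval(tf, trial)
            move = tval < v_s[work] - 1e-13
            mi = work[move]
            e_s[mi] = trial[move]
            f_s[mi] = tf[move]
            v_s[mi] = tval[move]
            lam[mi] = np.maximum(lam[mi] * 0.25, 1e-9)
            rest = work[~move]
            lam[rest] = np.minimum(lam[rest] * 8.0, 1e10)
            work = rest
        eta[idx], f[idx], val[idx], lam_m[idx] = e_s, f_s, v_s, lam
        # rows making no meaningful progress are evicted after 2 rounds and
        # handed to the caller (typically a more exact curvature phase)
        slow = (v_before - v_s) < 1e-9
        fails[idx[slow]] += 1
        fails[idx[~slow]] = 0
        tired = fails[idx] >= 2
        if tired.any():
            stalled.append(idx[tired])
        idx = idx[~tired]
    leftover = np.concatenate([idx] + stalled) if stalled else idx
    return eta, f, val, np.unique(leftover)


def _solve_modes(prob: _RowProblem, eta0=None, tol=1e-6):
    """Batched search for the per-row conditional modes.

    Phase 1: damped Gauss-Newton with the analytic objective gradient and
    J' W J + Omega^-1 curvature (cheap: one concentration-Jacobian call per
    iteration) to get near the mode. Phase 2: damped Newton with the full
    finite-difference Hessian of the joint objective for quadratic terminal
    convergence. Steps are norm-clipped to avoid overflow in exp(eta).
    """
    R, q = prob.R, prob.q
    eta = np.zeros((R, q)) if eta0 is None else eta0.copy()
    f = prob.conc(eta)
    val = prob.gval(f, eta)
    if eta0 is not None:
        # never start worse than the prior mode
        f0 = prob.conc(np.zeros((R, q)))
        v0 = prob.gval(f0, np.zeros((R, q)))
        use0 = v0 < val
        eta[use0] = 0.0
        f = np.where(use0[:, None], f0, f)
        val = np.minimum(val, v0)
    def gn_grad_hess(sub, eta, f, val):
        Rs, qs = sub.R, sub.q
        stencil = np.broadcast_to(eta, (2 * qs, Rs, qs)).copy()
        for k in range(qs):
            stencil[2 * k, :, k] += _FD_H
            stencil[2 * k + 1, :, k] -= _FD_H
        fs = sub.conc(stencil)  # (2q, R, J)
        Jc = np.stack(
            [(fs[2 * k] - fs[2 * k + 1]) / (2 * _FD_H) for k in range(qs)], axis=2
        )  # (R, J, q)
        inv_om = 1.0 / sub.om
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            fsafe = np.maximum(f, 1e-12)
            var = np.maximum(sub.sig2[:, None] * f * f, _VAR_FLOOR)
            r = sub.y - f
            dtdf = np.where(sub.mask, -r / var - r * r / (var * fsafe) + 1.0 / fsafe, 0.0)
            grad = np.einsum("rj,rjq->rq", dtdf, Jc) + eta * inv_om
            # exact second derivative of the per-observation deviance wrt f
            # (includes the log-variance curvature); clipped to keep H PSD
            yv = sub.y
            d2 = (
                yv * yv / (var * fsafe * fsafe)
                + 2.0 * yv * (yv / fsafe - 1.0) / (var * fsafe)
                - 1.0 / (fsafe * fsafe)
            )
            W = np.where(sub.mask, np.maximum(d2, 0.0), 0.0)
            H = np.einsum("rjq,rj,rjp->rqp", Jc, W, Jc)
        H[:, np.arange(qs), np.arange(qs)] += inv_om
        return grad, H

    def full_grad_hess(sub, eta, f, val):
        return _fd_grad_hess(sub.g, eta, val)

    eta, f, val, live = _damped_newton(prob, eta, f, val, gn_grad_hess, tol=tol, maxiter=15)
    if live.size:
        eta, f, val, _ = _damped_newton(
            prob, eta, f, val, full_grad_hess, tol=tol, maxiter=15, idx0=live
        )
    return eta, val


def _logdet_psd(hess: np.ndarray) -> np.ndarray:
    w = np.linalg.eigvalsh(hess)
    return np.sum(np.log(np.clip(w, 1e-10, None)), axis=1)


def _ofv_models(models: list[PopulationModel], data: _CompiledData, eta0=None, tol=1e-6):
    """Laplace OFV for several models sharing one dataset, in one batched solve.

    ``tol`` is the gradient tolerance of the conditional-mode search; the
    OFV error from an imperfect mode is second order in the residual
    gradient, so a loose tolerance (~1e-3) still yields ~1e-6 OFV accuracy
    and is much cheaper inside optimization loops.
    Returns (ofv values (K,), eta rows (K*S, q), per-row contributions).
    """
    prob = _RowProblem(models, data)
    if prob.q == 0:
        val = prob.g(np.zeros((prob.R, 0)))
        per_row = 2.0 * val
        return per_row.reshape(prob.K, prob.S).sum(axis=1), np.zeros((prob.R, 0)), per_row
    eta, val = _solve_modes(prob, eta0=eta0, tol=tol)
    # exact (finite-difference) Hessian of the joint objective at the mode,
    # for the Laplace log-determinant
    _, hess = _fd_grad_hess(prob.g, eta, val)
    bad = ~np.isfinite(hess.reshape(prob.R, -1)).all(axis=1)
    hess[bad] = np.eye(prob.q)
    per_row = 2.0 * val + _logdet_psd(hess) - prob.q * _LOG2PI
    return per_row.reshape(prob.K, prob.S).sum(axis=1), eta, per_row


def _laplace_ofv(model: PopulationModel, data: _CompiledData, eta0=None):
    """Single-model Laplace OFV; returns (ofv, eta_hat (S, 4), per-subject)."""
    active = np.flatnonzero(model.omega2_array() > 0)
    e0 = None if eta0 is None else eta0[:, active]
    vals, eta, per_row = _ofv_models([model], data, eta0=e0)
    eta_full = np.zeros((data.S, 4))
    if active.size:
        eta_full[:, active] = eta
    return float(vals[0]), eta_full, per_row


def ofv(model: PopulationModel, dataset: Dataset, exclude_blq: bool = True) -> float:
    """Laplace-approximate OFV (-2 log marginal likelihood) of a model on a dataset."""
    data = _CompiledData(dataset, exclude_blq=exclude_blq)
    return _laplace_ofv(model, data)[0]


# ---------------------------------------------------------------------------
# population fit

_OMEGA_BOUNDS = (math.log(1e-8), math.log(25.0))
_SIGMA_BOUNDS = (math.log(1e-8), math.log(4.0))


class _Parameterization:
    """Maps a PopulationModel to/from a flat optimizer vector.

    Typical values and variances are optimized on the log scale; covariate
    coefficients on the natural scale. ``fixed`` lists parameter names to
    hold at their initial values: "tv.CL", "beta.CL.GFR", "omega2.V1",
    "sigma2".
    """

    def __init__(self, init: PopulationModel, fixed: tuple[str, ...] = ()):
        self.init = init
        self.fixed = set(fixed)
        names: list[str] = []
        for p in PARAM_NAMES:
            names.append(f"tv.{p}")
        for e in init.covariate_effects:
            names.append(f"beta.{e.parameter}.{e.covariate}")
        for p in PARAM_NAMES:
            names.append(f"omega2.{p}")
        names.append("sigma2")
        unknown = self.fixed - set(names)
        if unknown:
            raise ValueError(f"unknown fixed parameter name(s): {sorted(unknown)}")
        self.free_names = [n for n in names if n not in self.fixed]
        if not self.free_names:
            raise ValueError("at least one parameter must be free")

    def pack(self, m: PopulationModel) -> np.ndarray:
        vec = []
        for n in self.free_names:
            kind, *rest = n.split(".")
            if kind == "tv":
                vec.append(math.log(m.typical_values[rest[0]]))
            elif kind == "beta":
                eff = next(
                    e for e in m.covariate_effects
                    if e.parameter == rest[0] and e.covariate == rest[1]
                )
                vec.append(eff.beta)
            elif kind == "omega2":
                vec.append(math.log(max(m.omega2[rest[0]], 1e-8)))
            else:
                vec.append(math.log(max(m.sigma2_prop, 1e-8)))
        return np.array(vec)

    def unpack(self, theta: np.ndarray) -> PopulationModel:
        tv = dict(self.init.typical_values)
        om = dict(self.init.omega2)
        sigma2 = self.init.sigma2_prop
        effects = list(self.init.covariate_effects)
        for n, v in zip(self.free_names, theta):
            kind, *rest = n.split(".")
            if kind == "tv":
                tv[rest[0]] = math.exp(v)
            elif kind == "beta":
                for i, e in enumerate(effects):
                    if e.parameter == rest[0] and e.covariate == rest[1]:
                        effects[i] = replace(e, beta=float(v))
            elif kind == "omega2":
                om[rest[0]] = math.exp(v)
            else:
                sigma2 = math.exp(v)
        return PopulationModel(
            typical_values=tv, covariate_effects=tuple(effects), omega2=om,
            sigma2_prop=sigma2, name=self.init.name,
        )

    def bounds(self) -> list[tuple[float, float]]:
        out = []
        for n in self.free_names:
            kind = n.split(".")[0]
            if kind == "tv":
                out.append((math.log(1e-3), math.log(1e4)))
            elif kind == "beta":
                out.append((-10.0, 10.0))
            elif kind == "omega2":
                out.append(_OMEGA_BOUNDS)
            else:
                out.append(_SIGMA_BOUNDS)
        return out


@dataclass
class FitResult:
    """Result of a population fit."""

    model: PopulationModel
    ofv: float
    converged: bool
    eta_hat: pd.DataFrame            # empirical Bayes modes, one row per subject
    n_subjects: int
    n_obs: int
    message: str = ""
    n_ofv_evals: int = 0

    def estimates(self) -> dict[str, float]:
        out = {f"tv.{p}": self.model.typical_values[p] for p in PARAM_NAMES}
        for e in self.model.covariate_effects:
            out[f"beta.{e.parameter}.{e.covariate}"] = e.beta
        out.update({f"omega2.{p}": self.model.omega2[p] for p in PARAM_NAMES})
        out["sigma2"] = self.model.sigma2_prop
        return out


def fit(
    dataset: Dataset,
    init: PopulationModel,
    fixed: tuple[str, ...] = (),
    exclude_blq: bool = True,
    maxiter: int = 200,
    multi_start: int = 3,
    jitter_seed: int = 0,
) -> FitResult:
    """Maximum (approximate marginal) likelihood fit of a population model.

    Quasi-Newton (L-BFGS-B) minimization of the Laplace OFV over
    log-transformed parameters; the objective and its finite-difference
    gradient come from one batched conditional-mode solve per evaluation.
    On apparent non-convergence up to ``multi_start``-1 jittered restarts
    are tried and the best iterate is returned (flagged via ``converged``).
    """
    data = _CompiledData(dataset, exclude_blq=exclude_blq)
    par = _Parameterization(init, fixed)
    theta0 = par.pack(init)
    rng = np.random.default_rng(jitter_seed)
    n_free = len(par.free_names)
    eps = 1e-5

    state = {"evals": 0, "best": (np.inf, None)}

    def fun_and_grad(theta):
        # objective and forward-difference gradient in one batched Laplace
        # solve over (1 + n_free) candidate models; conditional modes are
        # cold-started so the objective is a deterministic function of theta
        thetas = [theta] + [theta + eps * np.eye(n_free)[k] for k in range(n_free)]
        try:
            models = [par.unpack(t) for t in thetas]
            vals, _, _ = _ofv_models(models, data, tol=2e-4)
        except (ValueError, FloatingPointError, OverflowError, np.linalg.LinAlgError):
            return 1e12, np.zeros(n_free)
        state["evals"] += len(models)
        f0 = vals[0]
        if not np.isfinite(f0) or f0 > 1e8:
            # cap pathological values: astronomically large objectives wreck
            # the line-search interpolation without ordering points any better
            return 1e8, np.zeros(n_free)
        grad = (vals[1:] - f0) / eps
        grad = np.where(np.isfinite(grad), grad, 0.0)
        if f0 < state["best"][0]:
            state["best"] = (f0, theta.copy())
        return f0, grad

    def _minimize_polished(start):
        """L-BFGS-B with restarts from its own optimum until no further gain.

        Restarting resets the quasi-Newton memory, which reliably escapes
        the premature flat-valley terminations this likelihood provokes.
        """
        best = None
        x = start
        for _round in range(6):
            res = scipy.optimize.minimize(
                fun_and_grad, x, jac=True, method="L-BFGS-B", bounds=par.bounds(),
                options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 5e-2},
            )
            if best is None or res.fun < best.fun - 1e-9:
                gain = np.inf if best is None else best.fun - res.fun
                best = res
                x = res.x
                if gain < 0.01:
                    break
            else:
                break
        return best

    best_res = None
    start = theta0
    for attempt in range(max(multi_start, 1)):
        res = _minimize_polished(start)
        if best_res is None or res.fun < best_res.fun:
            best_res = res
        if res.success and attempt + 1 >= min(multi_start, 2):
            break
        start = theta0 + rng.normal(0.0, 0.2, size=theta0.shape)

    best_ofv, best_theta = state["best"]
    if best_theta is None:
        raise RuntimeError("fit failed: objective never evaluated finitely")
    model_hat = par.unpack(best_theta)
    # refresh the conditional modes at the optimum; the reported OFV is this
    # deterministic cold-start recompute so OFVs are comparable across fits
    final_ofv, eta_hat, _ = _laplace_ofv(model_hat, data)
    eta_df = pd.DataFrame(eta_hat, columns=[f"eta_{p}" for p in PARAM_NAMES])
    eta_df.insert(0, "ID", data.ids)
    return FitResult(
        model=model_hat,
        ofv=float(final_ofv),
        converged=bool(best_res.success),
        eta_hat=eta_df,
        n_subjects=data.S,
        n_obs=data.n_obs,
        message=str(best_res.message),
        n_ofv_evals=state["evals"],
    )


# ---------------------------------------------------------------------------
# covariate selection

def ebe_beta_init(fit_result: FitResult, dataset: Dataset, eff: CovariateEffect) -> float:
    """Initial covariate coefficient from the empirical-Bayes eta estimates.

    Under a missing covariate effect the conditional modes absorb it:
    eta_p,i ~ beta * x_i with x = log(COV/reference) (power form) or x = COV
    (binary form). The least-squares slope is the standard screening
    estimate and a far better starting value than zero — the profile in
    beta can be multimodal, and quasi-Newton search from zero stalls.
    """
    eta_col = f"eta_{eff.parameter}"
    eta_by_id = dict(zip(fit_result.eta_hat["ID"], fit_result.eta_hat[eta_col]))
    xs, es = [], []
    for s in dataset.subjects:
        if s.id not in eta_by_id or eff.covariate not in s.covariates:
            continue
        cov = s.covariates[eff.covariate]
        if eff.form == "power":
            if cov <= 0:
                continue
            xs.append(math.log(cov / eff.reference))
        else:
            xs.append(float(cov))
        es.append(eta_by_id[s.id])
    x = np.asarray(xs)
    e = np.asarray(es)
    if x.size < 3 or np.allclose(x, x.mean()):
        return 0.0
    xc = x - x.mean()
    return float(np.dot(xc, e - e.mean()) / np.dot(xc, xc))


def _add_effect(m: PopulationModel, eff: CovariateEffect) -> PopulationModel:
    return replace(m, covariate_effects=tuple(m.covariate_effects) + (eff,))


def _drop_effect(m: PopulationModel, eff: CovariateEffect) -> PopulationModel:
    kept = tuple(
        e for e in m.covariate_effects
        if not (e.parameter == eff.parameter and e.covariate == eff.covariate)
    )
    return replace(m, covariate_effects=kept)


def covariate_step(
    dataset: Dataset,
    base: PopulationModel,
    candidates: list[CovariateEffect],
    forward_dofv: float = 3.84,
    backward_dofv: float = 10.828,
    **fit_kwargs,
) -> tuple[PopulationModel, pd.DataFrame]:
    """Stepwise covariate selection by likelihood-ratio screening.

    Forward: candidates are tested one at a time against the current model;
    the best is included while its OFV drop exceeds ``forward_dofv`` (3.84,
    P=0.05, chi-square df 1). Backward: included effects are removed one at
    a time and retained only if removal raises the OFV by more than
    ``backward_dofv`` (10.828, P=0.001). Returns the selected model and an
    audit trail of every tested delta-OFV.
    """
    audit: list[dict] = []
    current_fit = fit(dataset, base, **fit_kwargs)
    current, current_ofv = current_fit.model, current_fit.ofv
    remaining = list(candidates)
    included: list[CovariateEffect] = []

    step = 0
    while remaining:
        step += 1
        trials = []
        for orig in remaining:
            cand = replace(orig, beta=ebe_beta_init(current_fit, dataset, orig))
            trial_fit = fit(dataset, _add_effect(current, cand), **fit_kwargs)
            dofv = current_ofv - trial_fit.ofv
            audit.append({
                "phase": "forward", "step": step,
                "parameter": orig.parameter, "covariate": orig.covariate,
                "dofv": dofv, "ofv": trial_fit.ofv, "selected": False,
            })
            trials.append((dofv, orig, trial_fit))
        trials.sort(key=lambda t: -t[0])
        best_dofv, best_cand, best_fit = trials[0]
        if best_dofv > forward_dofv:
            for rec in audit:
                if (rec["phase"], rec["step"]) == ("forward", step) and rec["covariate"] == best_cand.covariate and rec["parameter"] == best_cand.parameter:
                    rec["selected"] = True
            fitted_eff = next(
                e for e in best_fit.model.covariate_effects
                if e.parameter == best_cand.parameter and e.covariate == best_cand.covariate
            )
            included.append(fitted_eff)
            current, current_ofv, current_fit = best_fit.model, best_fit.ofv, best_fit
            remaining = [c for c in remaining if c is not best_cand]
        else:
            break

    removed = True
    while removed and included:
        removed = False
        step += 1
        for eff in list(included):
            trial_fit = fit(dataset, _drop_effect(current, eff), **fit_kwargs)
            dofv = trial_fit.ofv - current_ofv
            keep = dofv > backward_dofv
            audit.append({
                "phase": "backward", "step": step,
                "parameter": eff.parameter, "covariate": eff.covariate,
                "dofv": dofv, "ofv": trial_fit.ofv, "selected": keep,
            })
            if not keep:
                included = [
                    e for e in included
                    if not (e.parameter == eff.parameter and e.covariate == eff.covariate)
                ]
                current, current_ofv = trial_fit.model, trial_fit.ofv
                removed = True
                break

    return current, pd.DataFrame(audit)


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap(
    dataset: Dataset,
    model: PopulationModel,
    n_boot: int,
    rng: np.random.Generator,
    indices_list: list[np.ndarray] | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Nonparametric bootstrap: resample subjects with replacement and refit.

    Returns per-parameter median and 2.5/97.5 percentiles over successful
    replicates, with the success count in the DataFrame attrs. Failed
    replicate fits are counted and excluded. ``indices_list`` overrides the
    random resampling (one index array per replicate), mainly for testing.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    from .cohort import SubjectRecord  # local import to avoid cycle confusion

    subs = dataset.subjects
    S = len(subs)
    estimates: list[dict[str, float]] = []
    failures = 0
    for b in range(n_boot):
        idx = (
            indices_list[b]
            if indices_list is not None
            else rng.integers(0, S, size=S)
        )
        resampled = [
            SubjectRecord(
                id=k + 1,
                covariates=dict(subs[i].covariates),
                doses=list(subs[i].doses),
                observations=list(subs[i].observations),
            )
            for k, i in enumerate(idx)
        ]
        try:
            res = fit(Dataset(subjects=resampled), model, **fit_kwargs)
            if not np.isfinite(res.ofv):
                raise RuntimeError("non-finite OFV")
            estimates.append(res.estimates())
        except Exception:
            failures += 1
    if not estimates:
        raise RuntimeError(f"all {n_boot} bootstrap replicates failed to fit")
    df = pd.DataFrame(estimates)
    out = pd.DataFrame(
        {"median": df.median(), "p2.5": df.quantile(0.025), "p97.5": df.quantile(0.975)}
    )
    out.attrs["n_success"] = len(estimates)
    out.attrs["n_boot"] = n_boot
    return out


# ---------------------------------------------------------------------------
# diagnostics

@dataclass
class DiagnosticsTable:
    """Per-observation goodness-of-fit quantities, aligned 1:1 with observations."""

    table: pd.DataFrame  # columns: ID, TIME, DV, PRED, IPRED, CWRES


def compute_diagnostics(
    model: PopulationModel, dataset: Dataset, exclude_blq: bool = True
) -> DiagnosticsTable:
    """PRED (population), IPRED (conditional) and CWRES residuals.

    CWRES decorrelates the residuals with the first-order covariance
    linearized at the conditional mode: V = G Omega G' + diag(sigma2 *
    IPRED^2), with first-order mean f(eta_hat) - G eta_hat.
    """
    data = _CompiledData(dataset, exclude_blq=exclude_blq)
    active = np.flatnonzero(model.omega2_array() > 0)
    tv = _tv_matrix(model, data)
    _, eta_hat, _ = _laplace_ofv(model, data)
    pred = data.conc(tv)
    ipred = data.conc(tv * np.exp(eta_hat))
    sigma2 = model.sigma2_prop

    # dF/deta by central differences on the active random-effect dimensions
    q = active.size
    G = np.zeros((data.S, data.J, q))
    h = 1e-5
    for a, pidx in enumerate(active):
        e = np.zeros((data.S, 4))
        e[:, pidx] = h
        fp = data.conc(tv * np.exp(eta_hat + e))
        fm = data.conc(tv * np.exp(eta_hat - e))
        G[:, :, a] = (fp - fm) / (2 * h)

    om = model.omega2_array()[active]
    rows = []
    for i in range(data.S):
        J = int(data.mask[i].sum())
        Gi = G[i, :J, :]
        fi = ipred[i, :J]
        yi = data.y[i, :J]
        Vi = Gi @ np.diag(om) @ Gi.T + np.diag(np.maximum(sigma2 * fi * fi, _VAR_FLOOR))
        mean = fi - Gi @ eta_hat[i, active]
        resid = yi - mean
        w, U = np.linalg.eigh(Vi)
        w = np.clip(w, _VAR_FLOOR, None)
        cwres = U @ np.diag(1.0 / np.sqrt(w)) @ U.T @ resid
        if np.max(np.abs(resid)) < 1e-9:
            cwres = np.zeros_like(cwres)
        for j in range(J):
            rows.append({
                "ID": data.ids[i], "TIME": data.tobs[i, j], "DV": yi[j],
                "PRED": pred[i, j], "IPRED": fi[j], "CWRES": cwres[j],
            })
    return DiagnosticsTable(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# pc-VPC

@dataclass
class VpcResult:
    """Prediction-corrected VPC summary.

    ``table`` has one row per time bin: observed prediction-corrected
    percentiles (2.5/50/97.5), the simulation-based 95% CI of each
    percentile, and the pooled simulated 95% band. ``frac_in_band`` is the
    fraction of observations inside the pooled band (calibration ~0.95 under
    a well-specified model).
    """

    table: pd.DataFrame
    n_sim: int
    frac_in_band: float


def _assign_bins(times: np.ndarray, min_per_bin: int = 2) -> np.ndarray:
    """Bin observation times at their unique values, merging sparse bins."""
    rounded = np.round(times, 6)
    edges = list(np.unique(rounded))
    counts = [int(np.sum(rounded == u)) for u in edges]
    # merge any unique time with too few observations into its left neighbor
    groups: list[list[float]] = []
    for u, c in zip(edges, counts):
        if groups and c < min_per_bin:
            groups[-1].append(u)
        else:
            groups.append([u])
    if len(groups) > 1 and sum(counts[: len(groups[0])]) < min_per_bin:
        first = groups.pop(0)
        groups[0] = first + groups[0]
    labels = np.zeros(times.shape, dtype=int)
    for gi, gr in enumerate(groups):
        for u in gr:
            labels[np.round(times, 6) == u] = gi
    return labels


def pcvpc(
    model: PopulationModel,
    dataset: Dataset,
    n_sim: int = 200,
    rng: np.random.Generator | None = None,
    exclude_blq: bool = True,
) -> VpcResult:
    """Prediction-corrected visual predictive check.

    Each observed and simulated value is rescaled by (bin median PRED /
    subject PRED); observed percentiles are compared with the spread of the
    same percentiles over ``n_sim`` datasets simulated under the model with
    the original design (IIV plus untruncated proportional residual).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    data = _CompiledData(dataset, exclude_blq=exclude_blq)
    active = np.flatnonzero(model.omega2_array() > 0)
    tv = _tv_matrix(model, data)
    pred = data.conc(tv)

    flat = data.mask.ravel()
    times = np.broadcast_to(data.tobs, data.y.shape).ravel()[flat]
    y = data.y.ravel()[flat]
    pred_f = pred.ravel()[flat]
    labels = _assign_bins(times)

    bin_med_pred = np.zeros(labels.max() + 1)
    for b in range(labels.max() + 1):
        bin_med_pred[b] = np.median(pred_f[labels == b])
    pc_obs = y * bin_med_pred[labels] / np.maximum(pred_f, _VAR_FLOOR)

    # simulate replicates under the model with the original design
    sd = np.sqrt(model.omega2_array())
    eta = rng.normal(0.0, sd, size=(n_sim, data.S, 4))
    eta[:, :, model.omega2_array() == 0] = 0.0
    sims = np.empty((n_sim, data.S, data.J))
    for r in range(n_sim):
        f = data.conc(tv * np.exp(eta[r]))
        eps = rng.normal(0.0, math.sqrt(model.sigma2_prop), size=f.shape)
        sims[r] = f * (1.0 + eps)
    sims_f = sims.reshape(n_sim, -1)[:, flat]
    pc_sim = sims_f * (bin_med_pred[labels] / np.maximum(pred_f, _VAR_FLOOR))[None, :]

    pcts = (2.5, 50.0, 97.5)
    rows = []
    inside = 0
    for b in range(labels.max() + 1):
        sel = labels == b
        obs_p = np.percentile(pc_obs[sel], pcts)
        sim_p = np.percentile(pc_sim[:, sel], pcts, axis=1)  # (3, n_sim)
        band_lo, band_hi = np.percentile(pc_sim[:, sel].ravel(), [2.5, 97.5])
        inside += int(np.sum((pc_obs[sel] >= band_lo) & (pc_obs[sel] <= band_hi)))
        row = {
            "bin": b,
            "time": float(np.median(times[sel])),
            "n_obs": int(sel.sum()),
            "band_lo": band_lo,
            "band_hi": band_hi,
        }
        for name, ov, sv in zip(("p2.5", "p50", "p97.5"), obs_p, sim_p):
            row[f"obs_{name}"] = ov
            row[f"sim_{name}_lo"] = np.percentile(sv, 2.5)
            row[f"sim_{name}_hi"] = np.percentile(sv, 97.5)
        rows.append(row)
    table = pd.DataFrame(rows)
    return VpcResult(table=table, n_sim=n_sim, frac_in_band=inside / len(pc_obs))
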