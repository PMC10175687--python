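"""Independent numerical oracles: stiff-ODE kinetics and 1-D quadrature OFV."""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import logsumexp

from teicopk import DoseEvent, StructuralParams


def ode_concentration(p: StructuralParams, doses: list[DoseEvent], times) -> np.ndarray:
    """Independent two-compartment oracle: stiff ODE integration.

    Integrates the mass-balance system piecewise between infusion on/off
    breakpoints with tight tolerances, evaluating the central concentration
    at the requested times from the dense solution.
    """
    times = np.asarray(times, dtype=float)
    k10 = p.CL / p.V1
    k12 = p.Q / p.V1
    k21 = p.Q / p.V2

    def rate_in(t: float) -> float:
        total = 0.0
        for d in doses:
            if d.start <= t < d.start + d.duration:
                total += d.amount / d.duration
        return total

    def rhs(t, y):
        a1, a2 = y
        return [rate_in(t) - (k10 + k12) * a1 + k21 * a2, k12 * a1 - k21 * a2]

    breaks = sorted({0.0, *[d.start for d in doses], *[d.start + d.duration for d in doses],
                     float(times.max())})
    breaks = [b for b in breaks if b <= times.max() + 1e-12]
    if breaks[-1] < times.max():
        breaks.append(float(times.max()))
    out = np.zeros_like(times)
    y = [0.0, 0.0]
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        if hi <= lo:
            continue
        sol = solve_ivp(rhs, (lo, hi), y, method="LSODA", dense_output=True,
                        rtol=1e-11, atol=1e-13, max_step=hi - lo)
        sel = (times > lo) & (times <= hi)
        if sel.any():
            out[sel] = sol.sol(times[sel])[0]
        y = sol.y[:, -1]
    out[times <= 0] = 0.0
    return out / p.V1


def quadrature_ofv_1d(
    tv: dict, omega2_cl: float, sigma2: float,
    doses: list[DoseEvent], times: list[float], y: np.ndarray,
    n_nodes: int = 201,
) -> float:
    """Adaptive Gauss-Hermite oracle for a 1-subject, IIV-on-CL-only model.

    Locates the conditional mode by dense search + refinement and integrates
    exp(joint log density) with Hermite nodes centered and scaled at the
    mode. Entirely independent of the package's estimation code (uses only
    the analytic concentration function).
    """
    from numpy.polynomial.hermite_e import hermegauss

    from teicopk import conc_at

    y = np.asarray(y, dtype=float)

    def neg_joint(eta: float) -> float:
        p = StructuralParams(tv["CL"] * np.exp(eta), tv["V1"], tv["Q"], tv["V2"])
        f = np.asarray(conc_at(p, doses, np.asarray(times, dtype=float)))
        var = sigma2 * f ** 2
        return float(
            0.5 * np.sum((y - f) ** 2 / var + np.log(2 * np.pi * var))
            + 0.5 * (eta ** 2 / omega2_cl + np.log(2 * np.pi * omega2_cl))
        )

    # mode by grid + golden refinement
    grid = np.linspace(-5 * np.sqrt(omega2_cl), 5 * np.sqrt(omega2_cl), 801)
    vals = np.array([neg_joint(e) for e in grid])
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(neg_joint, bracket=(lo, grid[i], hi))
    mode = float(res.x)
    h = 1e-4
    curv = (neg_joint(mode + h) + neg_joint(mode - h) - 2 * neg_joint(mode)) / h ** 2
    scale = 1.0 / np.sqrt(max(curv, 1e-12))

    z, w = hermegauss(n_nodes)  # weight exp(-z^2/2)
    etas = mode + scale * z
    logs = np.array([-neg_joint(e) + 0.5 * zz ** 2 for e, zz in zip(etas, z)])
    log_integral = logsumexp(logs + np.log(w)) + np.log(scale)
    return float(-2.0 * log_integral)


def grid_ofv_2d(
    tv: dict, omega2: dict, sigma2: float,
    doses, times, y, half_width: float = 6.0, n_grid: int = 241,
) -> float:
    """Brute-force 2-D marginal OFV for IIV on CL and V1 only.

    Dense tensor-grid log-sum-exp integration of the joint density over
    (eta_CL, eta_V1); independent of the package's Laplace machinery.
    """
    from teicopk import conc_at

    y = np.asarray(y, dtype=float)
    om_cl, om_v1 = omega2["CL"], omega2["V1"]
    g1 = np.linspace(-half_width * np.sqrt(om_cl), half_width * np.sqrt(om_cl), n_grid)
    g2 = np.linspace(-half_width * np.sqrt(om_v1), half_width * np.sqrt(om_v1), n_grid)
    ll = np.empty((n_grid, n_grid))
    t_arr = np.asarray(times, dtype=float)
    for i, e1 in enumerate(g1):
        for j, e2 in enumerate(g2):
            p = StructuralParams(tv["CL"] * np.exp(e1), tv["V1"] * np.exp(e2),
                                 tv["Q"], tv["V2"])
            f = np.asarray(conc_at(p, doses, t_arr))
            var = sigma2 * f ** 2
            ll[i, j] = (
                -0.5 * np.sum((y - f) ** 2 / var + np.log(2 * np.pi * var))
                - 0.5 * (e1 ** 2 / om_cl + np.log(2 * np.pi * om_cl))
                - 0.5 * (e2 ** 2 / om_v1 + np.log(2 * np.pi * om_v1))
            )
    d1, d2 = g1[1] - g1[0], g2[1] - g2[0]
    return float(-2.0 * (logsumexp(ll) + np.log(d1 * d2)))
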