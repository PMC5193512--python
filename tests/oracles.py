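"""Independent brute-force oracles used only by the tests.

These re-derive the quantities the package computes, by different routes:
explicit enumeration for the network joints and conditionals, dense
numerical integration for the mixed-model marginal likelihood, and a
density-grid construction for highest-density intervals.  They share no
code with the implementation paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import optimize, stats


def brute_force_joint(params) -> dict:
    """8-cell joint by direct evaluation of the factorized probabilities."""
    from discaug.cbn import CausalStructure, IntegrationRule

    cells = {}
    for p, q, r in itertools.product((False, True), repeat=3):
        if params.structure is CausalStructure.COMMON_EFFECT:
            if params.rule is IntegrationRule.NOISY_OR:
                q_prob = 1.0 - (1.0 - params.w_a) * (1.0 - params.w_p) ** int(p) * (
                    1.0 - params.w_r
                ) ** int(r)
            else:
                q_prob = 1.0 - (1.0 - params.w_a) * (1.0 - params.w_pr) ** (
                    int(p) * int(r)
                )
            joint = (
                (params.pr_p if p else 1 - params.pr_p)
                * (params.pr_r if r else 1 - params.pr_r)
                * (q_prob if q else 1 - q_prob)
            )
        else:
            p_prob = 1.0 - (1.0 - params.w_a) * (1.0 - params.w_p) ** int(q)
            r_prob = 1.0 - (1.0 - params.w_a) * (1.0 - params.w_r) ** int(q)
            joint = (
                (params.pr_q if q else 1 - params.pr_q)
                * (p_prob if p else 1 - p_prob)
                * (r_prob if r else 1 - r_prob)
            )
        cells[(p, q, r)] = joint
    return cells


def brute_force_query(cells: dict, target: dict, given: dict) -> float:
    """Pr(target | given) by filtering the 8 enumerated assignments."""

    def match(cell, constraints):
        values = dict(zip("pqr", cell))
        return all(values[k] == v for k, v in constraints.items())

    denom = sum(v for c, v in cells.items() if match(c, given))
    if denom <= 0:
        raise ZeroDivisionError("zero-probability conditioning event")
    if any(k in given and given[k] != v for k, v in target.items()):
        return 0.0
    num = sum(v for c, v in cells.items() if match(c, {**given, **target}))
    return num / denom


def grid_hdi(pdf, support, mass=0.95, n=200_001):
    """Density-based HDI: waterfill the density to the requested mass."""
    xs = np.linspace(support[0], support[1], n)
    dens = pdf(xs)
    order = np.argsort(dens)[::-1]
    dx = xs[1] - xs[0]
    csum = np.cumsum(dens[order]) * dx
    k = int(np.searchsorted(csum, mass)) + 1
    inside = np.sort(xs[order[:k]])
    return float(inside[0]), float(inside[-1])


def _cat_logprob(y, eta, t1, t2):
    upper = np.where(y == 0, t1 - eta, np.where(y == 1, t2 - eta, np.inf))
    lower = np.where(y == 0, -np.inf, np.where(y == 1, t1 - eta, t2 - eta))
    uf = np.clip(np.where(np.isfinite(upper), upper, 0.0), -37, 37)
    lf = np.clip(np.where(np.isfinite(lower), lower, 0.0), -37, 37)
    prob = np.where(
        y == 0,
        stats.norm.cdf(uf),
        np.where(y == 1, stats.norm.cdf(uf) - stats.norm.cdf(lf), stats.norm.sf(lf)),
    )
    return np.log(np.clip(prob, 1e-300, 1.0))


def dense_quadrature_clmm(frame, n_grid=1001, span=8.0):
    """ML fit of CR ~ CD + (1|participant) with trapezoid-rule integration.

    Maximizes the exact marginal likelihood (random intercept integrated on a
    dense grid) with a derivative-free simplex search from neutral starting
    values.  Returns (theta1, theta2, beta_cd, sigma_participant, loglik).
    """
    y = frame["rating"].to_numpy(dtype=int) + 1
    cd = np.where(frame["causal_direction"].to_numpy() == "CE", 1.0, -1.0)
    _, idx = np.unique(frame["participant_id"].to_numpy(), return_inverse=True)
    n_groups = idx.max() + 1
    grid = np.linspace(-span, span, n_grid)
    gauss = stats.norm.pdf(grid)

    def negll(psi):
        t1 = psi[0]
        t2 = t1 + math.exp(psi[1])
        beta, sigma = psi[2], math.exp(psi[3])
        total = 0.0
        for g in range(n_groups):
            mask = idx == g
            eta = beta * cd[mask]
            lp = _cat_logprob(
                y[mask][:, None], eta[:, None] + sigma * grid[None, :], t1, t2
            ).sum(axis=0)
            total += math.log(max(np.trapezoid(np.exp(lp) * gauss, grid), 1e-300))
        return -total

    p1 = np.clip(np.mean(y == 0), 1e-6, 1 - 1e-6)
    p2 = np.clip(np.mean(y <= 1), 1e-6, 1 - 1e-6)
    t1 = stats.norm.ppf(p1)
    t2 = max(stats.norm.ppf(p2), t1 + 0.05)
    start = np.array([t1, math.log(t2 - t1), 0.0, math.log(0.7)])
    res = optimize.minimize(
        negll,
        start,
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 5000, "maxfev": 8000},
    )
    theta1 = res.x[0]
    theta2 = theta1 + math.exp(res.x[1])
    return theta1, theta2, res.x[2], math.exp(res.x[3]), -res.fun
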