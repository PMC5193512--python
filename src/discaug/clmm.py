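"""Cumulative-link (mixed) models with a probit link for 3-point change ratings.

The observation model is an ordered probit: a latent continuum

    y*_ij = x_ij' beta + z_ij' b + eps_ij,   eps ~ N(0, 1)

cut by ordered thresholds theta1 < theta2 into the categories -1 / 0 / +1.
Fixed effects are the design factors CD (causal direction, CE = +1, EC = -1),
C (consequent, C = +1, NC = -1) and their product; random effects b are
Gaussian intercepts (and optionally slopes) for participants and items,
which may be crossed.

Estimation is maximum marginal likelihood.  Random effects are integrated
out by a joint Laplace approximation (mode + curvature of the penalized
log-likelihood over the stacked random-effect vector); when the model has a
single random-intercept factor the one-dimensional integrals are instead
evaluated by adaptive Gauss-Hermite quadrature (15 nodes by default).  With
no random effects the model reduces to an ordered probit whose
intercept-only ML thresholds are the probit-transformed empirical cumulative
category proportions -- which is also where the optimizer starts.

Everything is deterministic given the data and specification: fixed starting
values (closed-form thresholds, zero coefficients, variances 0.5) and fixed
optimizer tolerances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special, stats

from .conditions import CONDITIONS, Condition
from .simulate import TrialRecord, records_to_frame

__all__ = [
    "RandomTerm",
    "ClmSpec",
    "ClmFit",
    "EmmResult",
    "fit_clm",
    "loglik_ratio_test",
    "emmeans_simple_effects",
    "EXPT1_LADDER",
    "EXPT2_LADDER",
]

_FIXED_TERMS = ("CD", "C", "CDxC")
_FACTOR_SHORT = {"participant": "P", "item": "I"}

_NORM = stats.norm


@dataclass(frozen=True)
class RandomTerm:
    """One random-effects term: intercept plus optional slopes for a factor."""

    factor: str  # "participant" or "item"
    slopes: Tuple[str, ...] = ()
    correlated: bool = True  # joint covariance for intercept+slopes vs diagonal

    def __post_init__(self) -> None:
        if self.factor not in _FACTOR_SHORT:
            raise ValueError(f"unknown grouping factor {self.factor!r}")
        for s in self.slopes:
            if s not in _FIXED_TERMS:
                raise ValueError(f"unknown slope covariate {s!r}")

    @property
    def dim(self) -> int:
        return 1 + len(self.slopes)

    @property
    def n_var_params(self) -> int:
        d = self.dim
        return d + (d * (d - 1) // 2 if self.correlated else 0)

    @property
    def label(self) -> str:
        inner = " + ".join(("1",) + self.slopes)
        return f"({inner}|{_FACTOR_SHORT[self.factor]})"


@dataclass(frozen=True)
class ClmSpec:
    """Model specification: fixed terms and random structure; probit link."""

    fixed: Tuple[str, ...] = ()
    random: Tuple[RandomTerm, ...] = ()
    link: str = "probit"

    def __post_init__(self) -> None:
        if self.link != "probit":
            raise ValueError("only the probit link is supported")
        for t in self.fixed:
            if t not in _FIXED_TERMS:
                raise ValueError(f"unknown fixed term {t!r}")
        if len(set(self.fixed)) != len(self.fixed):
            raise ValueError("duplicate fixed terms")
        factors = [t.factor for t in self.random]
        if len(set(factors)) != len(factors):
            raise ValueError("one random term per grouping factor")
        for t in self.random:
            for s in t.slopes:
                if s not in self.fixed:
                    # slopes over covariates absent from the fixed part are
                    # allowed (the published ladder's final model keeps a CD
                    # slope with no CD fixed effect), so only validate the
                    # covariate name itself.
                    pass

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.fixed) if self.fixed else "1"
        rand = " + ".join(t.label for t in self.random)
        return f"CR ~ {rhs}" + (f" + {rand}" if rand else "")

    @property
    def n_params(self) -> int:
        return 2 + len(self.fixed) + sum(t.n_var_params for t in self.random)


def _codes(frame: pd.DataFrame) -> Dict[str, np.ndarray]:
    cd = np.where(frame["causal_direction"].to_numpy() == "CE", 1.0, -1.0)
    c = np.where(frame["consequent"].to_numpy() == "C", 1.0, -1.0)
    return {"CD": cd, "C": c, "CDxC": cd * c}


class _Design:
    """Numeric design assembled from trial records for one specification."""

    def __init__(self, frame: pd.DataFrame, spec: ClmSpec):
        self.spec = spec
        self.y = frame["rating"].to_numpy(dtype=int) + 1  # categories 0,1,2
        if len(np.unique(self.y)) < 2:
            raise ValueError("need at least 2 rating categories present")
        self.n = len(self.y)
        codes = _codes(frame)
        self.X = (
            np.column_stack([codes[t] for t in spec.fixed])
            if spec.fixed
            else np.zeros((self.n, 0))
        )
        self.participants = frame["participant_id"].to_numpy()
        self.n_participants = len(np.unique(self.participants))
        # random-effects design: one dense Z block per term
        self.term_levels: List[int] = []
        self.term_group_idx: List[np.ndarray] = []
        self.term_covs: List[np.ndarray] = []  # (n, d) covariate values
        col = {"participant": "participant_id", "item": "item_id"}
        for term in spec.random:
            labels, idx = np.unique(frame[col[term.factor]].to_numpy(), return_inverse=True)
            self.term_levels.append(len(labels))
            self.term_group_idx.append(idx)
            covs = np.column_stack(
                [np.ones(self.n)] + [codes[s] for s in term.slopes]
            )
            self.term_covs.append(covs)
        self.q = sum(
            L * t.dim for L, t in zip(self.term_levels, spec.random)
        )
        self.Z = self._build_z()

    def _build_z(self) -> np.ndarray:
        Z = np.zeros((self.n, self.q))
        offset = 0
        rows = np.arange(self.n)
        for term, L, idx, covs in zip(
            self.spec.random, self.term_levels, self.term_group_idx, self.term_covs
        ):
            d = term.dim
            for k in range(d):
                Z[rows, offset + idx * d + k] = covs[:, k]
            offset += L * d
        return Z

    def start_thresholds(self) -> Tuple[float, float]:
        p1 = np.mean(self.y == 0)
        p2 = np.mean(self.y <= 1)
        t1 = _NORM.ppf(np.clip(p1, 1e-10, 1 - 1e-10))
        t2 = _NORM.ppf(np.clip(p2, 1e-10, 1 - 1e-10))
        if t2 <= t1 + 1e-6:
            t2 = t1 + 0.1
        return float(t1), float(t2)


def _unpack(psi: np.ndarray, design: _Design):
    """psi -> (theta1, theta2, beta, per-term covariance matrices)."""
    spec = design.spec
    theta1 = psi[0]
    theta2 = theta1 + math.exp(psi[1])
    k = 2 + len(spec.fixed)
    beta = psi[2:k]
    sigmas = []
    pos = k
    for term in spec.random:
        d = term.dim
        if term.correlated:
            Lmat = np.zeros((d, d))
            Lmat[np.diag_indices(d)] = np.exp(psi[pos:pos + d])
            pos += d
            off = d * (d - 1) // 2
            if off:
                Lmat[np.tril_indices(d, -1)] = psi[pos:pos + off]
                pos += off
            sigmas.append(Lmat @ Lmat.T)
        else:
            sd = np.exp(psi[pos:pos + d])
            pos += d
            sigmas.append(np.diag(sd ** 2))
    return theta1, theta2, beta, sigmas


def _cat_logprob_terms(y: np.ndarray, eta: np.ndarray, theta1: float, theta2: float):
    """Per-observation log P(y|eta) and its first/second derivatives in eta.

    P(y=0) = Phi(theta1 - eta); P(y=1) = Phi(theta2 - eta) - Phi(theta1 - eta);
    P(y=2) = 1 - Phi(theta2 - eta).  Tail categories use the survival function
    so far-out linear predictors keep relative accuracy.
    """
    upper = np.where(y == 0, theta1 - eta, np.where(y == 1, theta2 - eta, np.inf))
    lower = np.where(y == 0, -np.inf, np.where(y == 1, theta1 - eta, theta2 - eta))
    # |z| > 37 saturates the double-precision normal tail; clamping keeps the
    # derivative ratios (pdf/prob) bounded instead of overflowing
    upper_f = np.clip(np.where(np.isfinite(upper), upper, 0.0), -37.0, 37.0)
    lower_f = np.clip(np.where(np.isfinite(lower), lower, 0.0), -37.0, 37.0)
    # middle category: difference of CDFs in the lower tail, of survival
    # functions in the upper tail, so either far tail keeps relative accuracy
    mid = np.where(
        upper_f <= 0.0,
        _NORM.cdf(upper_f) - _NORM.cdf(lower_f),
        _NORM.sf(lower_f) - _NORM.sf(upper_f),
    )
    prob = np.where(
        y == 0, _NORM.cdf(upper_f), np.where(y == 1, mid, _NORM.sf(lower_f))
    )
    prob = np.clip(prob, 1e-300, 1.0)
    pdf_u = np.where(np.isfinite(upper), _NORM.pdf(upper_f), 0.0)
    pdf_l = np.where(np.isfinite(lower), _NORM.pdf(lower_f), 0.0)
    logp = np.log(prob)
    # d/d eta: the derivative of both cutpoints w.r.t. eta is -1
    grad = (pdf_l - pdf_u) / prob
    hess = (lower_f * pdf_l - upper_f * pdf_u) / prob - grad ** 2
    return logp, grad, hess


def _lambda_inv_logdet(design: _Design, sigmas: List[np.ndarray]):
    """Block-diagonal precision of the stacked random effects and log|Lambda|."""
    blocks = []
    logdet = 0.0
    for term, L, sigma in zip(design.spec.random, design.term_levels, sigmas):
        sign, ld = np.linalg.slogdet(sigma)
        if sign <= 0:
            raise linalg.LinAlgError("singular random-effect covariance")
        inv = np.linalg.inv(sigma)
        logdet += L * ld
        blocks.extend([inv] * L)
    if not blocks:
        return np.zeros((0, 0)), 0.0
    return linalg.block_diag(*blocks), logdet


def _laplace_loglik(psi: np.ndarray, design: _Design, b_cache: dict) -> float:
    theta1, theta2, beta, sigmas = _unpack(psi, design)
    offset = design.X @ beta
    if design.q == 0:
        logp, _, _ = _cat_logprob_terms(design.y, offset, theta1, theta2)
        return float(np.sum(logp))
    try:
        lam_inv, lam_logdet = _lambda_inv_logdet(design, sigmas)
    except linalg.LinAlgError:
        return -1e10
    Z = design.Z
    b = b_cache.get("b")
    if b is None or len(b) != design.q:
        b = np.zeros(design.q)

    def inner(bvec):
        eta = offset + Z @ bvec
        logp, grad, hess = _cat_logprob_terms(design.y, eta, theta1, theta2)
        h = float(np.sum(logp)) - 0.5 * float(bvec @ lam_inv @ bvec)
        return h, logp, grad, hess

    h, logp, grad, hess = inner(b)
    if not np.isfinite(h):
        return -1e10
    for _ in range(100):
        g = Z.T @ grad - lam_inv @ b
        if np.max(np.abs(g)) < 1e-9:
            break
        W = np.minimum(hess, -1e-10)  # guard: curvature must stay negative
        A = lam_inv - (Z * W[:, None]).T @ Z
        try:
            cho = linalg.cho_factor(A)
            step = linalg.cho_solve(cho, g)
        except (linalg.LinAlgError, ValueError):
            return -1e10
        # damped Newton: halve until the penalized log-likelihood improves
        t = 1.0
        for _ in range(30):
            b_new = b + t * step
            h_new, logp_n, grad_n, hess_n = inner(b_new)
            if h_new >= h - 1e-12:
                break
            t *= 0.5
        else:
            break
        b, h, logp, grad, hess = b_new, h_new, logp_n, grad_n, hess_n
    b_cache["b"] = b
    W = np.minimum(hess, -1e-10)
    A = lam_inv - (Z * W[:, None]).T @ Z
    sign, ld_a = np.linalg.slogdet(A)
    if sign <= 0:
        return -1e10
    out = h - 0.5 * lam_logdet - 0.5 * ld_a
    return out if math.isfinite(out) else -1e10


_GH_NODES: Dict[int, Tuple[np.ndarray, np.ndarray]] = {}


def _gh(n: int):
    if n not in _GH_NODES:
        _GH_NODES[n] = np.polynomial.hermite.hermgauss(n)
    return _GH_NODES[n]


def _agq_loglik(psi: np.ndarray, design: _Design, n_nodes: int) -> float:
    """Adaptive Gauss-Hermite marginal log-likelihood, one intercept factor.

    All groups are processed simultaneously: the per-group integrand modes
    are found by a vectorized Newton iteration, then each quadrature node is
    one vectorized pass over the observations.
    """
    theta1, theta2, beta, sigmas = _unpack(psi, design)
    sigma2 = sigmas[0][0, 0]
    offset = design.X @ beta if design.X.shape[1] else np.zeros(design.n)
    if sigma2 < 1e-12:
        logp, _, _ = _cat_logprob_terms(design.y, offset, theta1, theta2)
        return float(np.sum(logp))
    idx = design.term_group_idx[0]
    L = design.term_levels[0]
    nodes, weights = _gh(n_nodes)

    def group_terms(u_by_group):
        logp, grad, hess = _cat_logprob_terms(
            design.y, offset + u_by_group[idx], theta1, theta2
        )
        val = (
            np.bincount(idx, weights=logp, minlength=L)
            - 0.5 * u_by_group ** 2 / sigma2
            - 0.5 * math.log(2 * math.pi * sigma2)
        )
        g1 = np.bincount(idx, weights=grad, minlength=L) - u_by_group / sigma2
        g2 = np.bincount(idx, weights=hess, minlength=L) - 1.0 / sigma2
        return val, g1, g2

    u_hat = np.zeros(L)
    val, g1, g2 = group_terms(u_hat)
    for _ in range(50):
        if np.max(np.abs(g1)) < 1e-10:
            break
        step = np.clip(-g1 / np.minimum(g2, -1e-10), -10.0, 10.0)
        t = np.ones(L)
        for _ in range(30):
            cand = u_hat + t * step
            v_new, g1_new, g2_new = group_terms(cand)
            worse = v_new < val - 1e-12
            if not np.any(worse):
                break
            t = np.where(worse, 0.5 * t, t)
        u_hat, val, g1, g2 = cand, v_new, g1_new, g2_new
    s_hat = 1.0 / np.sqrt(np.maximum(-g2, 1e-10))
    logvals = np.empty((n_nodes, L))
    for k, x in enumerate(nodes):
        logvals[k] = group_terms(u_hat + math.sqrt(2.0) * s_hat * x)[0]
    log_terms = np.log(weights)[:, None] + (nodes ** 2)[:, None] + logvals
    per_group = np.log(math.sqrt(2.0) * s_hat) + special.logsumexp(log_terms, axis=0)
    total = float(np.sum(per_group))
    return total if math.isfinite(total) else -1e10


@dataclass
class ClmFit:
    """A fitted cumulative-link (mixed) model."""

    spec: ClmSpec
    thresholds: Tuple[float, float]
    coefficients: Dict[str, float]
    variance_components: Dict[str, float]
    loglik: float
    n_obs: int
    n_params: int
    n_participants: int
    converged: bool
    message: str
    method: str
    _psi: np.ndarray = field(repr=False, default=None)
    _objective: object = field(repr=False, default=None)
    _vcov: Optional[np.ndarray] = field(repr=False, default=None)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * math.log(self.n_obs)

    def param_vcov(self) -> np.ndarray:
        """Covariance of all free parameters from the numerical Hessian of -loglik."""
        if self._vcov is None:
            psi = self._psi
            p = len(psi)
            H = np.zeros((p, p))
            h = 1e-4
            f0 = self._objective(psi)
            for i in range(p):
                for j in range(i, p):
                    ei = np.zeros(p); ei[i] = h
                    ej = np.zeros(p); ej[j] = h
                    fpp = self._objective(psi + ei + ej)
                    fpm = self._objective(psi + ei - ej)
                    fmp = self._objective(psi - ei + ej)
                    fmm = self._objective(psi - ei - ej)
                    H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
            # objective is -loglik, so H approximates the information matrix
            try:
                vcov = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                vcov = np.linalg.pinv(H)
            self._vcov = vcov
        return self._vcov

    def beta_vcov(self) -> np.ndarray:
        k = len(self.spec.fixed)
        return self.param_vcov()[2:2 + k, 2:2 + k]


def fit_clm(
    records: Sequence[TrialRecord],
    spec: ClmSpec,
    method: str = "auto",
    n_agq: int = 15,
) -> ClmFit:
    """Fit one cumulative-probit (mixed) model by maximum marginal likelihood.

    ``method``: "auto" picks adaptive Gauss-Hermite quadrature for a single
    random-intercept factor and the joint Laplace approximation otherwise;
    "laplace"/"agq" force one.  Deterministic given data and spec.
    """
    if n_agq < 7:
        raise ValueError("adaptive quadrature needs at least 7 nodes")
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    design = _Design(frame, spec)
    single_intercept = (
        len(spec.random) == 1 and spec.random[0].dim == 1 and design.q > 0
    )
    if method == "auto":
        use_agq = single_intercept
    elif method == "agq":
        if not single_intercept:
            raise ValueError("quadrature requires a single random-intercept factor")
        use_agq = True
    elif method == "laplace":
        use_agq = False
    else:
        raise ValueError(f"unknown method {method!r}")

    b_cache: dict = {}
    if use_agq:
        def objective(psi):
            return -_agq_loglik(psi, design, n_agq)
    else:
        def objective(psi):
            return -_laplace_loglik(psi, design, b_cache)

    t1, t2 = design.start_thresholds()
    psi0 = [t1, math.log(max(t2 - t1, 1e-3))] + [0.0] * len(spec.fixed)
    bounds: List[Tuple[Optional[float], Optional[float]]] = [(None, None)] * len(psi0)
    log_sd0 = 0.5 * math.log(0.5)  # starting variances 0.5
    for term in spec.random:
        d = term.dim
        psi0 += [log_sd0] * d
        bounds += [(-6.0, 4.0)] * d
        if term.correlated and d > 1:
            off = d * (d - 1) // 2
            psi0 += [0.0] * off
            bounds += [(-10.0, 10.0)] * off
    psi0 = np.asarray(psi0)

    res = optimize.minimize(
        objective,
        psi0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 1000, "maxfun": 20000, "ftol": 1e-12, "gtol": 1e-7},
    )
    if design.q == 0 or not res.success:
        # simplex polish: removes finite-difference gradient noise near the
        # optimum (intercept-only thresholds must hit the closed form to
        # ~1e-9) and cleans up line-search failures L-BFGS-B reports on an
        # essentially converged surface
        polish = optimize.minimize(
            objective,
            res.x,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": 4000},
        )
        if polish.fun <= res.fun:
            res = polish
    if not res.success:
        warnings.warn(
            f"CLMM fit did not fully converge for {spec.formula}: {res.message}",
            RuntimeWarning,
        )

    theta1, theta2, beta, sigmas = _unpack(res.x, design)
    coefficients = {name: float(b) for name, b in zip(spec.fixed, beta)}
    var_comp: Dict[str, float] = {}
    for term, sigma in zip(spec.random, sigmas):
        names = ("intercept",) + term.slopes
        for k, nk in enumerate(names):
            var_comp[f"{term.factor}_{nk}_sd"] = float(math.sqrt(sigma[k, k]))
        if term.correlated and term.dim > 1:
            for a in range(term.dim):
                for b2 in range(a + 1, term.dim):
                    denom = math.sqrt(sigma[a, a] * sigma[b2, b2])
                    var_comp[f"{term.factor}_corr_{names[a]}_{names[b2]}"] = (
                        float(sigma[a, b2] / denom) if denom > 0 else 0.0
                    )
    return ClmFit(
        spec=spec,
        thresholds=(float(theta1), float(theta2)),
        coefficients=coefficients,
        variance_components=var_comp,
        loglik=float(-res.fun),
        n_obs=design.n,
        n_params=spec.n_params,
        n_participants=design.n_participants,
        converged=bool(res.success),
        message=str(res.message),
        method="agq" if use_agq else ("laplace" if design.q else "fixed"),
        _psi=res.x.copy(),
        _objective=objective,
    )


def _is_nested(small: ClmSpec, large: ClmSpec) -> bool:
    if not set(small.fixed) <= set(large.fixed):
        return False
    large_terms = {t.factor: t for t in large.random}
    for t in small.random:
        big = large_terms.get(t.factor)
        if big is None or not set(t.slopes) <= set(big.slopes):
            return False
    return True


def loglik_ratio_test(
    fit_small: ClmFit, fit_large: ClmFit, allow_nonnested: bool = False
) -> Tuple[float, int, float]:
    """G^2 likelihood-ratio test of two fits on the same data.

    Returns (G2, df, p) with G2 = 2(loglik_large - loglik_small) and a
    chi-square upper-tail p-value.  Requires nested specifications unless
    ``allow_nonnested`` (then G2 and df use absolute differences and the
    p-value is the same heuristic chi-square tail the ladder tables report).
    """
    if fit_small.n_obs != fit_large.n_obs:
        raise ValueError("fits must be on the same data")
    if fit_small.n_params > fit_large.n_params:
        fit_small, fit_large = fit_large, fit_small
    nested = _is_nested(fit_small.spec, fit_large.spec)
    if not nested and not allow_nonnested:
        raise ValueError(
            f"specs are not nested: {fit_small.spec.formula} vs {fit_large.spec.formula}"
        )
    g2 = 2.0 * (fit_large.loglik - fit_small.loglik)
    if not nested:
        g2 = abs(g2)
    g2 = max(g2, 0.0)
    df = fit_large.n_params - fit_small.n_params
    p = float(stats.chi2.sf(g2, df)) if df > 0 else (1.0 if g2 == 0 else 0.0)
    return float(g2), int(df), p


@dataclass
class EmmResult:
    """Estimated marginal means on the latent scale, with simple effects."""

    cell_means: pd.DataFrame  # condition, mean, se
    pairwise: pd.DataFrame  # a, b, estimate, se, z, p
    vs_zero: pd.DataFrame  # condition, mean, se, t, df, p, d


def _cell_contrast(spec: ClmSpec, condition: Condition) -> np.ndarray:
    codes = {
        "CD": 1.0 if condition.causal_direction == "CE" else -1.0,
        "C": 1.0 if condition.consequent == "C" else -1.0,
    }
    codes["CDxC"] = codes["CD"] * codes["C"]
    return np.array([codes[t] for t in spec.fixed])


def emmeans_simple_effects(fit: ClmFit) -> EmmResult:
    """Latent-scale cell means, pairwise z-ratios, and one-sample tests vs 0.

    Cell means are linear combinations of the fixed-effect coefficients
    under the sum-to-zero coding (thresholds excluded, as on the latent
    scale zero is "no change").  One-sample t-tests use the estimated mean
    and its standard error with df = n_participants - 1; the standardized
    effect is d = 2|t| / sqrt(df).
    """
    beta = np.array([fit.coefficients[t] for t in fit.spec.fixed])
    vbeta = fit.beta_vcov() if len(beta) else np.zeros((0, 0))
    means, ses = {}, {}
    for cond in CONDITIONS:
        c = _cell_contrast(fit.spec, cond)
        means[cond] = float(c @ beta) if len(beta) else 0.0
        var = float(c @ vbeta @ c) if len(beta) else 0.0
        ses[cond] = math.sqrt(max(var, 0.0))
    cell_rows = [
        {"condition": c.value, "mean": means[c], "se": ses[c]} for c in CONDITIONS
    ]
    pair_rows = []
    for i, a in enumerate(CONDITIONS):
        for b in CONDITIONS[i + 1:]:
            ca, cb = _cell_contrast(fit.spec, a), _cell_contrast(fit.spec, b)
            diff = means[a] - means[b]
            var = float((ca - cb) @ vbeta @ (ca - cb)) if len(beta) else 0.0
            se = math.sqrt(max(var, 0.0))
            z = diff / se if se > 0 else 0.0
            pair_rows.append(
                {
                    "a": a.value,
                    "b": b.value,
                    "estimate": diff,
                    "se": se,
                    "z": z,
                    "p": 2.0 * float(_NORM.sf(abs(z))),
                }
            )
    df_t = fit.n_participants - 1
    zero_rows = []
    for cond in CONDITIONS:
        t = means[cond] / ses[cond] if ses[cond] > 0 else 0.0
        d = 2.0 * abs(t) / math.sqrt(df_t) if df_t > 0 else 0.0
        zero_rows.append(
            {
                "condition": cond.value,
                "mean": means[cond],
                "se": ses[cond],
                "t": t,
                "df": df_t,
                "p": 2.0 * float(stats.t.sf(abs(t), df_t)),
                "d": d,
            }
        )
    return EmmResult(
        cell_means=pd.DataFrame(cell_rows),
        pairwise=pd.DataFrame(pair_rows),
        vs_zero=pd.DataFrame(zero_rows),
    )


def _term(factor: str, *slopes: str, correlated: bool = True) -> RandomTerm:
    return RandomTerm(factor=factor, slopes=tuple(slopes), correlated=correlated)


#: The published model ladder for the first study (Models 1-5).
EXPT1_LADDER: Tuple[Tuple[str, ClmSpec], ...] = (
    ("CR ~ 1 + (1|P)", ClmSpec(fixed=(), random=(_term("participant"),))),
    ("CR ~ CD + C + (1|P)", ClmSpec(fixed=("CD", "C"), random=(_term("participant"),))),
    (
        "CR ~ CD + C + (1|P) + (1|I)",
        ClmSpec(fixed=("CD", "C"), random=(_term("participant"), _term("item"))),
    ),
    (
        "CR ~ CD + C + (1 + CD|P) + (1|I)",
        ClmSpec(
            fixed=("CD", "C"),
            random=(_term("participant", "CD"), _term("item")),
        ),
    ),
    (
        "CR ~ C + (1 + CD|P) + (1|I)",
        ClmSpec(fixed=("C",), random=(_term("participant", "CD"), _term("item"))),
    ),
)

#: The published model ladder for the second study (Models 1-4).
EXPT2_LADDER: Tuple[Tuple[str, ClmSpec], ...] = (
    ("CR ~ 1 + (1|P)", ClmSpec(fixed=(), random=(_term("participant"),))),
    ("CR ~ CD + (1|P)", ClmSpec(fixed=("CD",), random=(_term("participant"),))),
    (
        "CR ~ CD + (1|P) + (1|I)",
        ClmSpec(fixed=("CD",), random=(_term("participant"), _term("item"))),
    ),
    (
        "CR ~ CD + C + (1|P) + (1|I)",
        ClmSpec(fixed=("CD", "C"), random=(_term("participant"), _term("item"))),
    ),
)
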