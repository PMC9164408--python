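"""Random-intercept regression models for TTO utility valuations.

Seven model families relate thermometer-coded DLQI severity dummies to TTO
utilities, all with an individual (respondent-level) Gaussian random intercept
integrated out of the likelihood by adaptive Gauss-Hermite quadrature:

``linear``
    y = a + x'b + u + v, v ~ N(0, sigma_v^2).
``censored``
    the same latent regression observed with two-sided censoring at y_L = 0 and
    y_U = 1 (a random-intercept Tobit); boundary observations contribute normal
    tail probabilities.
``ordinal``
    an equidistant random-intercept ordered probit over the 21 response-grid
    categories, thresholds kappa_j = kappa_0 + j * delta; one category step
    corresponds to 0.05 utility, which fixes the conversion of latent-scale
    coefficients to utility units (coef_y = coef_latent * 0.05 / delta).
``beta``
    y | u ~ Beta with probit mean link mu = Phi(a + x'b + u) and constant
    precision phi; coefficients are reported as average partial effects so they
    are comparable with the other families.
``scalable_linear`` / ``scalable_censored`` / ``scalable_beta``
    two-part models: each trader's effective scale range is proxied by
    lambda* = 1 - y(worst) and relative disutilities z* = (1 - y)/(1 - y(worst))
    are regressed on the dummies (the censored variant censors on the left at
    z_L = 0 only, since z*(worst) = 1 by construction). Utility-scale
    coefficients are recovered by combining the z-scale fit with the empirical
    lambda* distribution (see :func:`combine_scalable`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special
from scipy.special import log_ndtr, ndtr

from .design import DummyDesign, design_matrix
from .valueset import lambda_combine

__all__ = [
    "FAMILIES",
    "FitResult",
    "TTORandomIntercept",
    "TTORandomInterceptResults",
    "scalable_transform",
    "combine_scalable",
    "fit_linear_re",
    "fit_censored_re",
    "fit_ordinal_re",
    "fit_beta_re",
    "fit_scalable",
    "fit_indices",
    "explanatory_power_shares",
]

FAMILIES = (
    "linear", "censored", "ordinal", "beta",
    "scalable_linear", "scalable_censored", "scalable_beta",
)
_SCALABLE = {"scalable_linear": "linear", "scalable_censored": "censored", "scalable_beta": "beta"}

_SQRT_2PI = np.sqrt(2.0 * np.pi)
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class FitResult:
    """One model fit expressed as intercept + incremental dummy coefficients.

    `scale` is "utility" for directly comparable coefficients (negative =
    disutility) or "z" for the relative-disutility scale of the two-part
    models before combination with the lambda* distribution.
    """

    family: str
    alpha: float
    beta: dict[tuple[int, int], float]
    se_alpha: float | None
    se_beta: dict[tuple[int, int], float] | None
    sigma_u: float
    sigma_v: float | None
    phi: float | None
    delta: float | None
    scale: str
    loglik: float
    n_obs: int
    n_respondents: int
    converged: bool
    design: DummyDesign | None = None

    def beta_vector(self) -> np.ndarray:
        return np.array([self.beta[d] for d in self.design.active])

    def to_dict(self, units: float = 1.0) -> dict:
        return {
            "family": self.family,
            "scale": self.scale,
            "alpha": self.alpha / units,
            "beta": {f"D{i:02d}_L{l}": v / units for (i, l), v in self.beta.items()},
            "se_beta": None if self.se_beta is None
            else {f"D{i:02d}_L{l}": v / units for (i, l), v in self.se_beta.items()},
            "sigma_u": self.sigma_u, "sigma_v": self.sigma_v,
            "phi": self.phi, "delta": self.delta,
            "loglik": self.loglik, "n_obs": self.n_obs,
            "n_respondents": self.n_respondents, "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# Conditional log-likelihoods and their derivatives in the linear predictor
# ---------------------------------------------------------------------------

def _mills(a: np.ndarray) -> np.ndarray:
    """phi(a) / Phi(a), computed stably via log densities."""
    return np.exp(-0.5 * a * a - _LOG_SQRT_2PI - log_ndtr(a))


class _LinearFam:
    """v ~ N(0, s); supports optional censoring bounds (lo, hi)."""

    def __init__(self, y: np.ndarray, lo: float | None = None, hi: float | None = None):
        self.y = y
        self.lo, self.hi = lo, hi
        self.m_lo = np.zeros_like(y, dtype=bool) if lo is None else (y <= lo)
        self.m_hi = np.zeros_like(y, dtype=bool) if hi is None else (y >= hi)
        self.m_in = ~(self.m_lo | self.m_hi)

    def ll(self, m: np.ndarray, s: float, idx=None) -> np.ndarray:
        y = self.y if idx is None else self.y[idx]
        m_lo = self.m_lo if idx is None else self.m_lo[idx]
        m_hi = self.m_hi if idx is None else self.m_hi[idx]
        out = np.empty_like(m)
        r = (y - m) / s
        out[...] = -0.5 * r * r - np.log(s) - _LOG_SQRT_2PI
        if m_lo.any():
            out[m_lo] = log_ndtr(((self.lo - m) / s)[m_lo])
        if m_hi.any():
            out[m_hi] = log_ndtr(((m - self.hi) / s)[m_hi])
        return out

    def d12(self, m: np.ndarray, s: float) -> tuple[np.ndarray, np.ndarray]:
        d1 = (self.y - m) / s**2
        d2 = np.full_like(m, -1.0 / s**2)
        if self.m_lo.any():
            a = ((self.lo - m) / s)[self.m_lo]
            r = _mills(a)
            d1[self.m_lo] = -r / s
            d2[self.m_lo] = (-a * r - r * r) / s**2
        if self.m_hi.any():
            b = ((m - self.hi) / s)[self.m_hi]
            r = _mills(b)
            d1[self.m_hi] = r / s
            d2[self.m_hi] = (-b * r - r * r) / s**2
        return d1, d2

    def dlogscale(self, m: np.ndarray, s: float) -> np.ndarray:
        r = (self.y - m) / s
        out = r * r - 1.0
        if self.m_lo.any():
            a = ((self.lo - m) / s)[self.m_lo]
            out[self.m_lo] = -a * _mills(a)
        if self.m_hi.any():
            b = ((m - self.hi) / s)[self.m_hi]
            out[self.m_hi] = -b * _mills(b)
        return out


class _OrdinalFam:
    """Equidistant ordered probit on 21 grid categories; unit latent error.

    `m` excludes the thresholds: category j has interval
    (kappa0 + (j-1) delta, kappa0 + j delta) on the latent scale.
    """

    def __init__(self, cat: np.ndarray, n_cat: int = 21):
        self.cat = cat
        self.n_cat = n_cat
        self.lo_idx = cat - 1.0  # threshold index below; -1 -> -inf
        self.hi_idx = cat.astype(float)  # threshold index above; n_cat-1 -> +inf
        self.is_bottom = cat == 0
        self.is_top = cat == n_cat - 1

    def _bounds(self, m, kappa0, delta, idx=None):
        lo_idx = self.lo_idx if idx is None else self.lo_idx[idx]
        hi_idx = self.hi_idx if idx is None else self.hi_idx[idx]
        bottom = self.is_bottom if idx is None else self.is_bottom[idx]
        top = self.is_top if idx is None else self.is_top[idx]
        a = kappa0 + lo_idx * delta - m
        b = kappa0 + hi_idx * delta - m
        a = np.where(bottom, -np.inf, a)
        b = np.where(top, np.inf, b)
        return a, b

    def ll(self, m: np.ndarray, kappa0: float, delta: float, idx=None) -> np.ndarray:
        a, b = self._bounds(m, kappa0, delta, idx)
        p = ndtr(b) - ndtr(a)
        return np.log(np.clip(p, 1e-300, None))

    def d12(self, m: np.ndarray, kappa0: float, delta: float):
        a, b = self._bounds(m, kappa0, delta)
        p = np.clip(ndtr(b) - ndtr(a), 1e-300, None)
        pa = np.where(np.isfinite(a), np.exp(-0.5 * a * a) / _SQRT_2PI, 0.0)
        pb = np.where(np.isfinite(b), np.exp(-0.5 * b * b) / _SQRT_2PI, 0.0)
        d1 = np.clip((pa - pb) / p, -1e6, 1e6)
        apa = np.where(np.isfinite(a), a, 0.0) * pa
        bpb = np.where(np.isfinite(b), b, 0.0) * pb
        d2 = (apa - bpb) / p - d1 * d1
        return d1, np.clip(d2, -1e12, -1e-12)

    def dthresholds(self, m: np.ndarray, kappa0: float, delta: float):
        """(d ll / d kappa0, d ll / d log delta) per observation."""
        a, b = self._bounds(m, kappa0, delta)
        p = np.clip(ndtr(b) - ndtr(a), 1e-300, None)
        pa = np.where(np.isfinite(a), np.exp(-0.5 * a * a) / _SQRT_2PI, 0.0)
        pb = np.where(np.isfinite(b), np.exp(-0.5 * b * b) / _SQRT_2PI, 0.0)
        dk = np.clip((pb - pa) / p, -1e6, 1e6)
        lo = np.where(np.isfinite(a), self.lo_idx, 0.0)
        hi = np.where(np.isfinite(b), self.hi_idx, 0.0)
        dd = np.clip((pb * hi - pa * lo) * delta / p, -1e8, 1e8)
        return dk, dd


class _BetaFam:
    """Beta conditional distribution, probit mean link, constant precision."""

    _EPS = 1e-7

    def __init__(self, y: np.ndarray):
        self.y = y
        self.logy = np.log(y)
        self.log1y = np.log1p(-y)

    def ll(self, m: np.ndarray, phi: float, idx=None) -> np.ndarray:
        logy = self.logy if idx is None else self.logy[idx]
        log1y = self.log1y if idx is None else self.log1y[idx]
        mu = np.clip(ndtr(m), self._EPS, 1.0 - self._EPS)
        return (special.gammaln(phi) - special.gammaln(mu * phi)
                - special.gammaln((1.0 - mu) * phi)
                + (mu * phi - 1.0) * logy + ((1.0 - mu) * phi - 1.0) * log1y)

    def d12(self, m: np.ndarray, phi: float):
        mu = np.clip(ndtr(m), self._EPS, 1.0 - self._EPS)
        p = np.exp(-0.5 * m * m) / _SQRT_2PI
        g = phi * (-special.digamma(mu * phi) + special.digamma((1.0 - mu) * phi)
                   + self.logy - self.log1y)
        G = -phi**2 * (special.polygamma(1, mu * phi) + special.polygamma(1, (1.0 - mu) * phi))
        d1 = g * p
        d2 = G * p * p - g * m * p
        return d1, np.minimum(d2, -1e-12)

    def dlogscale(self, m: np.ndarray, phi: float) -> np.ndarray:
        mu = np.clip(ndtr(m), self._EPS, 1.0 - self._EPS)
        return phi * (special.digamma(phi) - mu * special.digamma(mu * phi)
                      - (1.0 - mu) * special.digamma((1.0 - mu) * phi)
                      + mu * self.logy + (1.0 - mu) * self.log1y)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

def scalable_transform(df: pd.DataFrame, drop_zero_scale_range: bool = False) -> pd.DataFrame:
    """Per-respondent scale ranges lambda* = 1 - y(worst) and relative
    disutilities z* = (1 - y) / lambda* for a trader dataset.

    The input must hold one worst-state (all level 3) valuation per respondent
    with y(worst) < 1; non-traders must have been screened out beforehand.
    Respondents with y(worst) = 1 leave the decomposition undefined
    (lambda* = 0); by default they raise, with ``drop_zero_scale_range=True``
    they are dropped instead. Returns a copy with `lambda_star` and `z_star`
    columns.
    """
    qcols = [f"q{i}" for i in range(1, 11)]
    df = df.copy()
    is_worst = (df[qcols] == 3).all(axis=1)
    worst = df[is_worst].set_index("respondent_id")["y"]
    missing = set(df["respondent_id"]) - set(worst.index)
    if missing:
        raise ValueError(f"respondents without a worst-state valuation: {sorted(missing)[:5]} ...")
    if (worst >= 1.0).any():
        bad = worst[worst >= 1.0].index
        if not drop_zero_scale_range:
            raise ValueError(
                f"respondents with y(worst) = 1 must be screened out first: {bad.tolist()[:5]} ..."
            )
        df = df[~df["respondent_id"].isin(bad)]
        worst = worst[worst < 1.0]
        is_worst = is_worst.loc[df.index]
    lam = 1.0 - df["respondent_id"].map(worst)
    df["lambda_star"] = lam
    df["z_star"] = (1.0 - df["y"]) / lam
    return df


class TTORandomIntercept:
    """Random-intercept regression of TTO valuations on DLQI severity dummies.

    Parameters
    ----------
    endog : response vector (utilities y, or relative disutilities z* for the
        scalable families; ordinal expects y on the 0.05 grid).
    exog : thermometer-coded 0/1 dummy matrix (without constant).
    groups : respondent identifiers (the random-intercept grouping).
    family : one of :data:`FAMILIES`.
    design : the :class:`DummyDesign` the columns of `exog` correspond to.
    lambda_star : per-observation lambda* values (scalable families only);
        their per-respondent uniques form the empirical scale-range
        distribution used in :func:`combine_scalable`.
    n_quad : number of adaptive Gauss-Hermite nodes for the random intercept.
    """

    def __init__(self, endog, exog, groups, family: str = "censored",
                 design: DummyDesign | None = None,
                 lambda_star=None, n_quad: int = 15):
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        endog = np.asarray(endog, dtype=float)
        exog = np.asarray(exog, dtype=float)
        groups = np.asarray(groups)
        order = np.argsort(groups, kind="stable")
        self._order = order
        self.endog = endog[order]
        self.exog = exog[order]
        self.family = family
        self.design = design
        self.n_quad = int(n_quad)
        g = groups[order]
        _, self.group_idx, counts = np.unique(g, return_inverse=True, return_counts=True)
        self.n_groups = len(counts)
        self.n_obs = len(endog)
        self.lambda_star = None
        if lambda_star is not None:
            ls = np.asarray(lambda_star, dtype=float)[order]
            # one lambda* per respondent
            first = np.r_[0, np.cumsum(counts)[:-1]]
            self.lambda_star = ls[first]

        base = _SCALABLE.get(family, family)
        if base == "linear" and family == "linear":
            self._fam = _LinearFam(self.endog)
        elif family == "scalable_linear":
            self._fam = _LinearFam(self.endog)
        elif family == "censored":
            if np.all(self.endog >= 1.0) or np.all(self.endog <= 0.0):
                raise ValueError("all observations censored at one bound; likelihood degenerate")
            self._fam = _LinearFam(self.endog, lo=0.0, hi=1.0)
        elif family == "scalable_censored":
            self._fam = _LinearFam(self.endog, lo=0.0, hi=None)
        elif family == "ordinal":
            cat = np.round(self.endog * 20.0).astype(int)
            if not np.allclose(cat / 20.0, self.endog, atol=1e-9):
                raise ValueError("ordinal family requires y on the 0.05 response grid")
            if len(np.unique(cat)) < 2:
                raise ValueError("ordinal family requires at least 2 distinct categories")
            self._fam = _OrdinalFam(cat)
        else:  # beta families: compress boundary values into (0, 1)
            y = np.clip(self.endog, 0.0, 1.0)
            n = len(y)
            self._fam = _BetaFam((y * (n - 1) + 0.5) / n)

        k = self.exog.shape[1]
        self.k_exog = k
        if family == "ordinal":
            self.param_names = ["kappa0"] + self._beta_names() + ["log_sigma_u", "log_delta"]
        elif base == "beta":
            self.param_names = ["alpha"] + self._beta_names() + ["log_sigma_u", "log_phi"]
        else:
            self.param_names = ["alpha"] + self._beta_names() + ["log_sigma_u", "log_sigma_v"]
        self.k_params = len(self.param_names)
        nodes, weights = hermgauss(self.n_quad)
        self._nodes, self._logw = nodes, np.log(weights)
        self._u_cache = None

    def _beta_names(self) -> list[str]:
        if self.design is not None and len(self.design) == self.k_exog:
            return self.design.labels
        return [f"x{j}" for j in range(self.k_exog)]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, design: DummyDesign,
                       family: str = "censored", n_quad: int = 15) -> "TTORandomIntercept":
        """Build from a long-format trader dataset (columns respondent_id,
        q1..q10, y). Scalable families derive lambda*/z* internally."""
        qcols = [f"q{i}" for i in range(1, design.n_items + 1)]
        if family in _SCALABLE:
            tr = scalable_transform(df, drop_zero_scale_range=True)
            X = design_matrix(tr[qcols].to_numpy(dtype=np.int8), design)
            return cls(tr["z_star"].to_numpy(), X, tr["respondent_id"].to_numpy(),
                       family=family, design=design,
                       lambda_star=tr["lambda_star"].to_numpy(), n_quad=n_quad)
        X = design_matrix(df[qcols].to_numpy(dtype=np.int8), design)
        return cls(df["y"].to_numpy(dtype=float), X, df["respondent_id"].to_numpy(),
                   family=family, design=design, n_quad=n_quad)

    # -- likelihood ------------------------------------------------------
    def _unpack(self, params: np.ndarray):
        loc = params[0]
        beta = params[1:1 + self.k_exog]
        sigma_u = np.exp(np.clip(params[-2], -12.0, 4.0))
        scale = np.exp(np.clip(params[-1], -12.0, 6.0))
        return loc, beta, sigma_u, scale

    def _cond_ll(self, m: np.ndarray, loc: float, scale: float, idx=None) -> np.ndarray:
        if self.family == "ordinal":
            return self._fam.ll(m, loc, scale, idx)
        return self._fam.ll(loc + m, scale, idx)

    def _cond_d12(self, m: np.ndarray, loc: float, scale: float):
        if self.family == "ordinal":
            return self._fam.d12(m, loc, scale)
        return self._fam.d12(loc + m, scale)

    def _group_sum(self, x: np.ndarray) -> np.ndarray:
        return np.bincount(self.group_idx, weights=x, minlength=self.n_groups)

    def _posterior_modes(self, eta: np.ndarray, loc, sigma_u, scale,
                         n_iter: int = 25):
        """Vectorized Newton search for the mode and curvature of each
        respondent's integrand log p(y_g | u) + log p(u).

        Warm-started from the modes of the previous evaluation (parameter
        changes between optimizer steps are small); the converged mode does
        not depend on the starting point.
        """
        u = self._u_cache if self._u_cache is not None else np.zeros(self.n_groups)
        u = u.copy()
        inv_var = 1.0 / max(sigma_u, 1e-12) ** 2
        h2 = None
        for _ in range(n_iter):
            d1, d2 = self._cond_d12(eta + u[self.group_idx], loc, scale)
            h1 = self._group_sum(d1) - u * inv_var
            h2 = self._group_sum(d2) - inv_var
            step = h1 / h2
            np.clip(step, -5.0 * sigma_u - 1.0, 5.0 * sigma_u + 1.0, out=step)
            u_new = u - step
            done = np.max(np.abs(u_new - u)) < 1e-9
            u = u_new
            if done:
                break
        d1, d2 = self._cond_d12(eta + u[self.group_idx], loc, scale)
        h2 = self._group_sum(d2) - inv_var
        self._u_cache = u
        return u, 1.0 / np.sqrt(np.clip(-h2, 1e-12, 1e24))

    def loglike(self, params: np.ndarray) -> float:
        """Marginal log-likelihood via adaptive Gauss-Hermite quadrature."""
        loc, beta, sigma_u, scale = self._unpack(np.asarray(params, dtype=float))
        eta = self.exog @ beta
        if sigma_u < 1e-8:
            return float(np.sum(self._cond_ll(eta, loc, scale)))
        mode, sd = self._posterior_modes(eta, loc, sigma_u, scale)
        acc = np.full((self.n_quad, self.n_groups), -np.inf)
        log_prior_const = -np.log(sigma_u) - _LOG_SQRT_2PI
        for k, (x, lw) in enumerate(zip(self._nodes, self._logw)):
            u = mode + np.sqrt(2.0) * sd * x
            ll_obs = self._cond_ll(eta + u[self.group_idx], loc, scale)
            h = self._group_sum(ll_obs) - 0.5 * (u / sigma_u) ** 2 + log_prior_const
            acc[k] = lw + x * x + h
        ll_g = special.logsumexp(acc, axis=0) + 0.5 * np.log(2.0) + np.log(sd)
        return float(np.sum(ll_g))

    def _cond_dscale(self, m: np.ndarray, loc: float, scale: float):
        """Per-observation derivatives of the conditional log-likelihood with
        respect to (loc-parameter, log scale-parameter); the derivative in the
        linear predictor is handled separately through _cond_d12."""
        if self.family == "ordinal":
            return self._fam.dthresholds(m, loc, scale)
        return None, self._fam.dlogscale(loc + m, scale)

    def loglike_grad(self, params: np.ndarray) -> tuple[float, np.ndarray]:
        """Marginal log-likelihood and its gradient.

        The gradient uses the Fisher identity: the derivative of each group's
        marginal log-likelihood is the posterior expectation (over the random
        intercept) of the derivative of the joint log-density, evaluated with
        the same adaptive quadrature nodes and posterior node weights.
        """
        p = np.asarray(params, dtype=float)
        loc, beta, sigma_u, scale = self._unpack(p)
        eta = self.exog @ beta
        grad = np.zeros(self.k_params)
        if sigma_u < 1e-8:
            ll_obs = self._cond_ll(eta, loc, scale)
            d1, _ = self._cond_d12(eta, loc, scale)
            dloc, dsc = self._cond_dscale(eta, loc, scale)
            grad[0] = np.sum(d1 if dloc is None else dloc)
            grad[1:1 + self.k_exog] = self.exog.T @ d1
            grad[-1] = np.sum(dsc)
            return float(np.sum(ll_obs)), grad
        mode, sd = self._posterior_modes(eta, loc, sigma_u, scale)
        K = self.n_quad
        acc = np.empty((K, self.n_groups))
        d1_all = np.empty((K, self.n_obs))
        dsc_all = np.empty((K, self.n_obs))
        dloc_all = np.empty((K, self.n_obs)) if self.family == "ordinal" else None
        dsu_all = np.empty((K, self.n_groups))
        log_prior_const = -np.log(sigma_u) - _LOG_SQRT_2PI
        sqrt2 = np.sqrt(2.0)
        for k, (x, lw) in enumerate(zip(self._nodes, self._logw)):
            u = mode + sqrt2 * sd * x
            m = eta + u[self.group_idx]
            ll_obs = self._cond_ll(m, loc, scale)
            acc[k] = (lw + x * x + self._group_sum(ll_obs)
                      - 0.5 * (u / sigma_u) ** 2 + log_prior_const)
            d1_all[k], _ = self._cond_d12(m, loc, scale)
            dloc, dsc_all[k] = self._cond_dscale(m, loc, scale)
            if dloc_all is not None:
                dloc_all[k] = dloc
            dsu_all[k] = (u / sigma_u) ** 2 - 1.0
        ll_g = special.logsumexp(acc, axis=0)
        w = np.exp(acc - ll_g)  # posterior node weights per group, columns sum to 1
        w_obs = w[:, self.group_idx]
        d1_post = np.sum(w_obs * d1_all, axis=0)
        grad[0] = (np.sum(d1_post) if dloc_all is None
                   else float(np.sum(w_obs * dloc_all)))
        grad[1:1 + self.k_exog] = self.exog.T @ d1_post
        grad[-2] = float(np.sum(w * dsu_all))
        grad[-1] = float(np.sum(w_obs * dsc_all))
        return float(np.sum(ll_g) + self.n_groups * (0.5 * np.log(2.0)) + np.sum(np.log(sd))), grad

    # -- fitting ---------------------------------------------------------
    def _start_params(self) -> np.ndarray:
        X = np.column_stack([np.ones(self.n_obs), self.exog])
        coef, *_ = np.linalg.lstsq(X, self.endog, rcond=None)
        resid = self.endog - X @ coef
        grp_mean = self._group_sum(resid) / self._group_sum(np.ones(self.n_obs))
        between = float(np.var(grp_mean))
        within = float(np.var(resid - grp_mean[self.group_idx]))
        su = np.sqrt(max(between, 1e-4))
        sv = np.sqrt(max(within, 1e-4))
        a, b = coef[0], coef[1:]
        fam = self.family
        if fam in ("linear", "censored", "scalable_linear", "scalable_censored"):
            return np.r_[a, b, np.log(su), np.log(sv)]
        if fam == "ordinal":
            s = sv
            return np.r_[(0.025 - a) / s, b / s, np.log(su / s), np.log(0.05 / s)]
        # beta families
        mbar = float(np.clip(np.mean(self.endog), 0.05, 0.95))
        dens = np.exp(-0.5 * special.ndtri(mbar) ** 2) / _SQRT_2PI
        phi0 = max(mbar * (1 - mbar) / max(within + between, 1e-4) - 1.0, 2.0)
        return np.r_[special.ndtri(mbar) + (a - mbar) / dens, b / dens,
                     np.log(max(su / dens, 1e-3)), np.log(phi0)]

    def fit(self, start_params=None, maxiter: int = 300, gtol: float = 1e-5,
            compute_se: bool = True) -> "TTORandomInterceptResults":
        x0 = np.asarray(start_params, dtype=float) if start_params is not None else self._start_params()
        if len(x0) != self.k_params:
            raise ValueError("start_params has wrong length")

        def neg_ll(p):
            v = self.loglike(p)
            return -v if np.isfinite(v) else 1e12

        def neg_ll_grad(p):
            v, g = self.loglike_grad(p)
            if not np.isfinite(v) or not np.all(np.isfinite(g)):
                return 1e12, np.zeros_like(g)
            return -v, -g

        res = optimize.minimize(neg_ll_grad, x0, method="L-BFGS-B", jac=True,
                                options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-10})
        params = res.x
        cov = None
        if compute_se:
            try:
                from statsmodels.tools.numdiff import approx_hess1

                hess = approx_hess1(params, neg_ll)
                cov = np.linalg.inv(hess)
                if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
                    cov = None
            except np.linalg.LinAlgError:
                cov = None
        return TTORandomInterceptResults(self, params, -res.fun, bool(res.success), cov)

    # -- brute-force oracle (tiny datasets; used by tests) ----------------
    def loglike_bruteforce(self, params: np.ndarray) -> float:
        """Marginal log-likelihood by direct numerical integration over u."""
        from scipy.integrate import quad

        loc, beta, sigma_u, scale = self._unpack(np.asarray(params, dtype=float))
        eta = self.exog @ beta
        total = 0.0
        for g in range(self.n_groups):
            sel = self.group_idx == g

            def integrand(u, sel=sel):
                ll = self._cond_ll(eta[sel] + u, loc, scale, idx=sel).sum()
                return np.exp(ll - 0.5 * (u / sigma_u) ** 2) / (sigma_u * _SQRT_2PI)

            # locate the (possibly very narrow) peak by grid scan so the
            # adaptive integrator does not step over it
            lo, hi = -10 * sigma_u, 10 * sigma_u
            grid = np.linspace(lo, hi, 4001)
            peak = grid[int(np.argmax([integrand(u) for u in grid]))]
            val, _ = quad(integrand, lo, hi, points=[peak], limit=400,
                          epsabs=1e-13, epsrel=1e-11)
            total += np.log(val)
        return float(total)


class TTORandomInterceptResults:
    """Estimates, uncertainties and diagnostics for one fitted family."""

    def __init__(self, model: TTORandomIntercept, params: np.ndarray,
                 llf: float, converged: bool, cov_params: np.ndarray | None):
        self.model = model
        self.params = params
        self.llf = llf
        self.converged = converged
        self.cov_params = cov_params
        loc, beta, sigma_u, scale = model._unpack(params)
        self.loc = float(loc)
        self.beta_native = beta
        self.sigma_u = float(sigma_u)
        self.scale_param = float(scale)

    @property
    def bse(self) -> np.ndarray | None:
        if self.cov_params is None:
            return None
        return np.sqrt(np.diag(self.cov_params))

    # -- scale conversions -------------------------------------------------
    def _utility_conversion(self) -> tuple[float, float, np.ndarray]:
        """(alpha_y, slope factor, beta_y) on the utility scale (one-part
        families) or the z scale (two-part families, identity)."""
        fam = self.model.family
        if fam in ("linear", "censored", "scalable_linear", "scalable_censored"):
            return self.loc, 1.0, self.beta_native
        if fam == "ordinal":
            f = 0.05 / self.scale_param
            return 0.025 - 0.05 * self.loc / self.scale_param, f, self.beta_native * f
        # beta families: average partial effects
        factor = self._beta_ape_factor()
        return self._beta_ape_intercept(), factor, self.beta_native * factor

    def _gh_mean(self, func) -> np.ndarray:
        nodes, w = self.model._nodes, np.exp(self.model._logw)
        vals = sum(wk * func(np.sqrt(2.0) * self.sigma_u * xk) for xk, wk in zip(nodes, w))
        return vals / np.sqrt(np.pi)

    def _beta_ape_intercept(self) -> float:
        return float(self._gh_mean(lambda u: ndtr(self.loc + u)))

    def _beta_ape_factor(self) -> float:
        eta = self.loc + self.model.exog @ self.beta_native
        dens = self._gh_mean(lambda u: np.exp(-0.5 * (eta + u) ** 2) / _SQRT_2PI)
        return float(np.mean(dens))

    def as_fit_result(self) -> FitResult:
        """Express the fit as intercept + incremental dummy coefficients.

        One-part families are returned on the utility scale; two-part families
        on the z scale (use :func:`combine_scalable` for utility units).
        """
        m = self.model
        fam = m.family
        if fam in _SCALABLE:
            return self._z_scale_fit_result()
        alpha_y, factor, beta_y = self._utility_conversion()
        se = self.bse
        se_beta = se_alpha = None
        if se is not None:
            # conversion SEs ignore the covariance with the scale parameter
            se_alpha = float(se[0]) if fam != "ordinal" else float(se[0]) * 0.05 / self.scale_param
            se_beta = dict(zip(m.design.active, se[1:1 + m.k_exog] * factor)) if m.design else None
            if fam == "beta":
                se_alpha = float(se[0]) * abs(factor)
        sigma_v = {"linear": self.scale_param, "censored": self.scale_param,
                   "ordinal": 0.05 / self.scale_param}.get(fam)
        sigma_u_y = self.sigma_u * (0.05 / self.scale_param if fam == "ordinal" else 1.0)
        return FitResult(
            family=fam, alpha=float(alpha_y),
            beta=dict(zip(m.design.active, beta_y)) if m.design else dict(enumerate(beta_y)),
            se_alpha=se_alpha, se_beta=se_beta,
            sigma_u=float(sigma_u_y), sigma_v=sigma_v,
            phi=self.scale_param if fam == "beta" else None,
            delta=self.scale_param if fam == "ordinal" else None,
            scale="utility", loglik=self.llf, n_obs=m.n_obs,
            n_respondents=m.n_groups, converged=self.converged, design=m.design,
        )

    def _z_scale_fit_result(self) -> FitResult:
        m = self.model
        fam = m.family
        se = self.bse
        base = _SCALABLE[fam]
        if base == "beta":
            alpha_z, factor, beta_z = self._beta_ape_intercept(), self._beta_ape_factor(), None
            beta_z = self.beta_native * self._beta_ape_factor()
        else:
            alpha_z, factor, beta_z = self.loc, 1.0, self.beta_native
        return FitResult(
            family=fam, alpha=float(alpha_z),
            beta=dict(zip(m.design.active, beta_z)) if m.design else dict(enumerate(beta_z)),
            se_alpha=None if se is None else float(se[0] * abs(factor)),
            se_beta=None if se is None or m.design is None
            else dict(zip(m.design.active, se[1:1 + m.k_exog] * abs(factor))),
            sigma_u=self.sigma_u,
            sigma_v=self.scale_param if base != "beta" else None,
            phi=self.scale_param if base == "beta" else None, delta=None,
            scale="z", loglik=self.llf, n_obs=m.n_obs,
            n_respondents=m.n_groups, converged=self.converged, design=m.design,
        )

    # -- prediction --------------------------------------------------------
    def predict_z(self, X: np.ndarray) -> np.ndarray:
        """Predicted relative disutility for new states (two-part families)."""
        base = _SCALABLE.get(self.model.family)
        if base is None:
            raise ValueError("predict_z applies to scalable families only")
        eta = self.loc + np.asarray(X, dtype=float) @ self.beta_native
        if base == "beta":
            return self._gh_mean(lambda u: ndtr(eta + u))
        return eta

    def predict_utility(self, X: np.ndarray) -> np.ndarray:
        """Population-averaged predicted utility for states coded in X."""
        m = self.model
        fam = m.family
        X = np.asarray(X, dtype=float)
        if fam in _SCALABLE:
            z = self.predict_z(X)
            lam = self.model.lambda_star
            return np.clip(1.0 - lam[None, :] * z[:, None], 0.0, 1.0).mean(axis=1)
        eta = self.loc + X @ self.beta_native
        if fam == "linear":
            return eta
        if fam == "censored":
            s = np.hypot(self.sigma_u, self.scale_param)
            a, b = (0.0 - eta) / s, (1.0 - eta) / s
            pa, pb = ndtr(a), ndtr(b)
            da = np.exp(-0.5 * a * a) / _SQRT_2PI
            db = np.exp(-0.5 * b * b) / _SQRT_2PI
            return (1.0 - pb) + eta * (pb - pa) - s * (db - da)
        if fam == "ordinal":
            s = np.hypot(self.sigma_u, 1.0)
            j = np.arange(21)
            thr = self.loc + np.arange(20) * self.scale_param  # kappa0 + j*delta
            eta_lat = X @ self.beta_native  # kappa0 lives in the thresholds
            cdf = ndtr((thr[None, :] - eta_lat[:, None]) / s)
            p = np.diff(np.concatenate([np.zeros((len(eta), 1)), cdf, np.ones((len(eta), 1))], axis=1))
            return p @ (j * 0.05)
        # beta
        return np.array([self._gh_mean(lambda u, e=e: ndtr(e + u)) for e in eta])

    def share_right_censored(self) -> float:
        """Share of observations with effective right-censoring under the fit
        (latent value above the upper bound), censored family only."""
        if self.model.family != "censored":
            raise ValueError("right-censoring share applies to the censored family")
        eta = self.loc + self.model.exog @ self.beta_native
        s = np.hypot(self.sigma_u, self.scale_param)
        return float(np.mean(1.0 - ndtr((1.0 - eta) / s)))

    def summary(self) -> str:
        m = self.model
        lines = [
            f"Random-intercept TTO model  family={m.family}",
            f"  n_obs={m.n_obs}  n_respondents={m.n_groups}  loglik={self.llf:.3f}"
            f"  converged={self.converged}",
            f"  sigma_u={self.sigma_u:.4f}  scale={self.scale_param:.4f}",
            f"  {'param':<10s}{'estimate':>12s}{'std err':>12s}",
        ]
        se = self.bse
        for i, name in enumerate(m.param_names):
            s = f"{se[i]:>12.4f}" if se is not None else f"{'':>12s}"
            lines.append(f"  {name:<10s}{self.params[i]:>12.4f}{s}")
        fr = self.as_fit_result()
        lines.append(f"  [{fr.scale} scale] intercept={fr.alpha:.4f}")
        for (i, l), v in sorted(fr.beta.items()):
            lines.append(f"    D{i:02d}_L{l}  {v:+.4f}")
        return "\n".join(lines)


def combine_scalable(fit_z: FitResult | TTORandomInterceptResults,
                     lambda_star: np.ndarray | None = None,
                     design: DummyDesign | None = None) -> FitResult:
    """Combine a z-scale two-part fit with the empirical lambda* distribution.

    The utility prediction for a state x is mean over lambda* of
    clip(1 - lambda * z(x), 0, 1); the reported utility-scale intercept and
    incremental coefficients are the implied average partial effects (finite
    differences of that prediction along each item's severity path), making
    two-part fits directly averageable with the one-part families.
    """
    if isinstance(fit_z, TTORandomInterceptResults):
        results = fit_z
        design = design or results.model.design
        lambdas = results.model.lambda_star if lambda_star is None else np.asarray(lambda_star)
        zfit = results.as_fit_result()

        def z_of(levels):
            X = design_matrix(levels[None, :], design)
            return float(results.predict_z(X)[0])
    else:
        zfit = fit_z
        if zfit.scale != "z":
            raise ValueError("combine_scalable expects a z-scale fit")
        design = design or zfit.design
        lambdas = np.asarray(lambda_star, dtype=float)
        beta_vec = np.array([zfit.beta[d] for d in design.active])

        def z_of(levels):
            X = design_matrix(levels[None, :], design)[0]
            return zfit.alpha + float(X @ beta_vec)

    if lambdas is None or np.size(lambdas) == 0:
        raise ValueError("empty lambda* sample")
    alpha_y, incr_y = lambda_combine(z_of, design, lambdas)
    lam_mean = float(np.mean(lambdas))
    se_beta = None
    if zfit.se_beta is not None:
        # conditional on lambda*; scales z-scale SEs by the mean scale range
        se_beta = {k: v * lam_mean for k, v in zfit.se_beta.items()}
    return FitResult(
        family=zfit.family, alpha=alpha_y, beta=incr_y,
        se_alpha=None if zfit.se_alpha is None else zfit.se_alpha * lam_mean,
        se_beta=se_beta,
        sigma_u=zfit.sigma_u * lam_mean,
        sigma_v=None if zfit.sigma_v is None else zfit.sigma_v * lam_mean,
        phi=zfit.phi, delta=None, scale="utility",
        loglik=zfit.loglik, n_obs=zfit.n_obs, n_respondents=zfit.n_respondents,
        converged=zfit.converged, design=design,
    )


# ---------------------------------------------------------------------------
# Convenience fitting functions
# ---------------------------------------------------------------------------

def _fit(family, y, X, groups, **kwargs):
    fit_kw = {k: kwargs.pop(k) for k in ("start_params", "maxiter", "compute_se") if k in kwargs}
    model = TTORandomIntercept(y, X, groups, family=family, **kwargs)
    return model.fit(**fit_kw)


def fit_linear_re(y, X, groups, **kwargs):
    """Maximum-likelihood random-intercept linear fit (coefficients on the y scale)."""
    return _fit("linear", y, X, groups, **kwargs)


def fit_censored_re(y, X, groups, **kwargs):
    """Random-intercept Tobit with two-sided censoring at y_L = 0, y_U = 1."""
    return _fit("censored", y, X, groups, **kwargs)


def fit_ordinal_re(y, X, groups, **kwargs):
    """Equidistant random-intercept ordered probit on the 21 grid categories."""
    return _fit("ordinal", y, X, groups, **kwargs)


def fit_beta_re(y, X, groups, **kwargs):
    """Random-intercept beta regression, probit mean link, constant precision."""
    return _fit("beta", y, X, groups, **kwargs)


def fit_scalable(z_star, X, groups, part2_family: str = "left_censored", **kwargs):
    """Random-intercept fit of the relative-disutility regression on pooled z*.

    `part2_family`: 'linear', 'left_censored' (censoring at z_L = 0 only), or
    'beta'. Returns a z-scale results object; use :func:`combine_scalable` to
    express it in utility units.
    """
    fam = {"linear": "scalable_linear", "left_censored": "scalable_censored",
           "beta": "scalable_beta"}[part2_family]
    return _fit(fam, z_star, X, groups, **kwargs)


# ---------------------------------------------------------------------------
# Fit indices
# ---------------------------------------------------------------------------

def fit_indices(fitted: np.ndarray, df: pd.DataFrame) -> dict[str, float]:
    """Correlation and mean-absolute-difference fit measures.

    Compares per-row fitted utilities with (a) individual valuations, (b)
    per-state mean utilities, (c) per-state median utilities; also reports the
    squared correlations vs individuals and vs means.
    """
    fitted = np.asarray(fitted, dtype=float)
    y = df["y"].to_numpy(dtype=float)

    def _corr(a, b):
        if np.std(a) < 1e-12 or np.std(b) < 1e-12:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    out = {
        "corr_individual": _corr(fitted, y),
        "mad_individual": float(np.mean(np.abs(fitted - y))),
    }
    grp = df.assign(_fit=fitted).groupby("state_id")
    obs_mean = grp["y"].mean()
    obs_median = grp["y"].median()
    fit_state = grp["_fit"].mean()
    out["corr_mean"] = _corr(fit_state.to_numpy(), obs_mean.to_numpy())
    out["mad_mean"] = float(np.mean(np.abs(fit_state.to_numpy() - obs_mean.to_numpy())))
    out["corr_median"] = _corr(fit_state.to_numpy(), obs_median.to_numpy())
    out["mad_median"] = float(np.mean(np.abs(fit_state.to_numpy() - obs_median.to_numpy())))
    out["r2_individual"] = out["corr_individual"] ** 2
    out["r2_mean"] = out["corr_mean"] ** 2
    return out


def explanatory_power_shares(r2_model: float, r2_benchmark: float,
                             r2_unidimensional: float) -> dict[str, float]:
    """Relative explanatory power of a model against a saturated benchmark and
    a total-score-only baseline.

    Returns the model/benchmark ratio and the share of the benchmark's
    incremental explanatory power over the uni-dimensional model that the
    model captures: (R2_m - R2_u) / (R2_b - R2_u).
    """
    return {
        "relative_performance": r2_model / r2_benchmark,
        "incremental_share": (r2_model - r2_unidimensional) / (r2_benchmark - r2_unidimensional),
    }
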