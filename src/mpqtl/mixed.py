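"""Linear mixed model with two crossed random factors (injection date, RIL).

The workhorse for the vial-level model

    y[i,j,k] = X beta + date[i] + RIL[j] + eps[i,j,k]

with date ~ N(0, s2_date), RIL ~ N(0, s2_ril), eps ~ N(0, s2_resid).

REML/ML estimation uses Henderson's mixed-model equations with the large
RIL block absorbed through a Schur complement, so each likelihood
evaluation costs O(n + n_ril * (p + n_date)^2) — fast enough for
replicate-heavy recovery experiments.  A conjugate Gibbs sampler provides
the Bayesian route used for variance decomposition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

_LOG_2PI = math.log(2.0 * math.pi)
_LG_BOUNDS = (-18.0, 10.0)  # bounds on log variance ratios


def full_rank_columns(X: np.ndarray, names: Sequence[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Drop linearly dependent columns (QR with pivoting).

    Returns the reduced matrix, kept names and dropped names.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    drop = [names[i] for i in sorted(piv[rank:])]
    return X[:, keep], [names[i] for i in keep], drop


class MixedData:
    """Pre-aggregated sufficient statistics for the crossed model."""

    def __init__(self, y, X, dates, rils, fixed_names=None):
        y = np.asarray(y, dtype=np.float64)
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in response or design")
        n = len(y)
        if X.shape[0] != n:
            raise ValueError("X rows must match y")
        names = list(fixed_names) if fixed_names is not None else [f"x{i}" for i in range(X.shape[1])]
        X, names, dropped = full_rank_columns(X, names)
        self.dropped_fixed = dropped

        d_codes, d_levels = pd.factorize(pd.Index(dates), sort=True)
        r_codes, r_levels = pd.factorize(pd.Index(rils), sort=True)
        self.include_date = len(d_levels) > 1
        if not self.include_date:
            warnings.warn("single injection date: date variance fixed at 0")

        self.y, self.X, self.fixed_names = y, X, names
        self.n, self.p = n, X.shape[1]
        self.d_codes, self.date_levels = d_codes, list(d_levels)
        self.r_codes, self.ril_levels = r_codes, list(r_levels)
        self.d, self.r = len(d_levels), len(r_levels)

        self.yty = float(y @ y)
        self.Xty = X.T @ y
        self.XtX = X.T @ X
        self.cd = np.bincount(d_codes, minlength=self.d).astype(float)
        self.cr = np.bincount(r_codes, minlength=self.r).astype(float)
        self.Zdy = np.bincount(d_codes, weights=y, minlength=self.d)
        self.Zry = np.bincount(r_codes, weights=y, minlength=self.r)
        self.XtZd = np.vstack([np.bincount(d_codes, weights=X[:, j], minlength=self.d)
                               for j in range(self.p)])
        self.XtZr = np.vstack([np.bincount(r_codes, weights=X[:, j], minlength=self.r)
                               for j in range(self.p)])
        Ndr = np.zeros((self.d, self.r))
        np.add.at(Ndr, (d_codes, r_codes), 1.0)
        self.Ndr = Ndr

    # -- likelihood machinery -------------------------------------------
    def _solve(self, gam_d: Optional[float], gam_r: float):
        """Schur-complement solve of the MME for given variance ratios.

        Returns (quad, logdetC, u_top, v, S_chol) where quad = y'P y in
        residual-variance-free units and u_top stacks [beta, date effects].
        """
        Dg = self.cr + 1.0 / gam_r
        if gam_d is not None and self.include_date:
            A = np.block([
                [self.XtX, self.XtZd],
                [self.XtZd.T, np.diag(self.cd + 1.0 / gam_d)],
            ])
            B = np.vstack([self.XtZr, self.Ndr])
            rhs_top = np.concatenate([self.Xty, self.Zdy])
        else:
            A = self.XtX.copy()
            B = self.XtZr
            rhs_top = self.Xty.copy()
        BD = B / Dg
        S = A - BD @ B.T
        rhs = rhs_top - BD @ self.Zry
        cho = linalg.cho_factor(S, lower=True, check_finite=False)
        u_top = linalg.cho_solve(cho, rhs, check_finite=False)
        v = (self.Zry - B.T @ u_top) / Dg
        quad = self.yty - float(u_top @ rhs_top) - float(v @ self.Zry)
        logdetC = float(np.log(Dg).sum()) + 2.0 * float(np.log(np.diag(cho[0])).sum())
        return quad, logdetC, u_top, v, cho

    def _logdet_zz(self, gam_d: Optional[float], gam_r: float) -> float:
        """log|Z'Z + G^-1| for the ML likelihood."""
        Dg = self.cr + 1.0 / gam_r
        if gam_d is not None and self.include_date:
            Az = np.diag(self.cd + 1.0 / gam_d)
            Bz = self.Ndr
            S = Az - (Bz / Dg) @ Bz.T
            sign, ld = np.linalg.slogdet(S)
            return float(np.log(Dg).sum()) + float(ld)
        return float(np.log(Dg).sum())

    def neg2ll(self, gam_d: Optional[float], gam_r: float, method: str = "reml") -> float:
        """-2 log (restricted) likelihood profiled over the residual variance."""
        quad, logdetC, _, _, _ = self._solve(gam_d, gam_r)
        quad = max(quad, 1e-300)
        pen = self.r * math.log(gam_r)
        if gam_d is not None and self.include_date:
            pen += self.d * math.log(gam_d)
        if method == "reml":
            nn = self.n - self.p
            s2 = quad / nn
            return nn * (math.log(s2) + 1.0 + _LOG_2PI) + logdetC + pen
        else:
            s2 = quad / self.n
            logdetH = pen + self._logdet_zz(gam_d, gam_r)
            return self.n * (math.log(s2) + 1.0 + _LOG_2PI) + logdetH


@dataclass
class MixedFit:
    """REML/ML fit of the crossed date/RIL mixed model."""

    beta: np.ndarray
    fixed_names: list
    cov_beta: np.ndarray
    sigma2_date: float
    sigma2_ril: float
    sigma2_resid: float
    date_effects: pd.Series
    ril_effects: pd.Series
    loglik: float
    method: str
    n: int
    converged: bool
    degenerate: bool = False
    dropped_fixed: list = field(default_factory=list)
    data: Optional[MixedData] = None  # retained for profiling / simulation

    @property
    def intercept(self) -> float:
        return float(self.beta[0])


def _optimize_gammas(data: MixedData, method: str) -> tuple[Optional[float], float, bool]:
    """Maximise the (restricted) likelihood over log variance ratios."""
    lo, hi = _LG_BOUNDS
    grid = np.array([-14.0, -7.0, -3.5, -1.5, 0.0, 1.5, 3.5])
    if data.include_date:
        def f(z):
            return data.neg2ll(math.exp(z[0]), math.exp(z[1]), method)
        best, best_val = None, np.inf
        for a in grid:
            for b in grid:
                v = f((a, b))
                if v < best_val:
                    best, best_val = (a, b), v
        res = optimize.minimize(f, best, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 600})
        z = np.clip(res.x, lo, hi)
        return math.exp(z[0]), math.exp(z[1]), bool(res.success)
    else:
        def f1(z):
            return data.neg2ll(None, math.exp(z), method)
        vals = [f1(a) for a in grid]
        z0 = grid[int(np.argmin(vals))]
        res = optimize.minimize_scalar(f1, bracket=None, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-8})
        return None, math.exp(float(np.clip(res.x, lo, hi))), True


def fit_crossed(y, X, dates, rils, method: str = "reml",
                fixed_names: Optional[Sequence[str]] = None) -> MixedFit:
    """Fit the crossed mixed model by REML (default) or ML.

    Parameters
    ----------
    y : array-like
        Vial-level response.
    X : array-like (n, p)
        Fixed-effect design (first column conventionally the intercept).
        Linearly dependent columns are dropped with a record.
    dates, rils : array-like
        Factor labels per observation.
    """
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")
    data = MixedData(y, X, dates, rils, fixed_names)
    if data.r < 2:
        raise ValueError("need at least 2 RILs")

    # degenerate: no residual variation at all
    if np.ptp(data.y) == 0.0 or np.var(data.y) < 1e-26:
        beta = np.zeros(data.p)
        beta[0] = data.y[0] if data.p else 0.0
        return MixedFit(
            beta=beta, fixed_names=data.fixed_names, cov_beta=np.zeros((data.p, data.p)),
            sigma2_date=0.0, sigma2_ril=0.0, sigma2_resid=0.0,
            date_effects=pd.Series(0.0, index=data.date_levels),
            ril_effects=pd.Series(0.0, index=data.ril_levels),
            loglik=math.inf, method=method, n=data.n, converged=True,
            degenerate=True, dropped_fixed=data.dropped_fixed, data=data)

    gam_d, gam_r, ok = _optimize_gammas(data, method)
    quad, logdetC, u_top, v, cho = data._solve(gam_d, gam_r)
    nn = data.n - data.p if method == "reml" else data.n
    s2e = max(quad / nn, 0.0)
    s2d = (gam_d * s2e) if (gam_d is not None and data.include_date) else 0.0
    s2r = gam_r * s2e
    # zero out ratios pinned at the lower boundary
    if gam_d is not None and gam_d <= math.exp(_LG_BOUNDS[0]) * 1.01:
        s2d = 0.0
    if gam_r <= math.exp(_LG_BOUNDS[0]) * 1.01:
        s2r = 0.0

    beta = u_top[:data.p]
    if gam_d is not None and data.include_date:
        date_eff = pd.Series(u_top[data.p:], index=data.date_levels)
    else:
        date_eff = pd.Series(0.0, index=data.date_levels)
    ril_eff = pd.Series(v, index=data.ril_levels)
    Sinv = linalg.cho_solve(cho, np.eye(u_top.shape[0]), check_finite=False)
    cov_beta = s2e * Sinv[:data.p, :data.p]
    loglik = -0.5 * data.neg2ll(gam_d, gam_r, method)
    return MixedFit(
        beta=beta, fixed_names=data.fixed_names, cov_beta=cov_beta,
        sigma2_date=s2d, sigma2_ril=s2r, sigma2_resid=s2e,
        date_effects=date_eff, ril_effects=ril_eff,
        loglik=loglik, method=method, n=data.n, converged=ok,
        dropped_fixed=data.dropped_fixed, data=data)


# ---------------------------------------------------------------------------
# profile likelihood for the repeatability R = s2_ril / (s2_ril + s2_resid)
# ---------------------------------------------------------------------------

def profile_repeatability_ci(fit: MixedFit, level: float = 0.95,
                             n_boot_fallback: int = 1000,
                             seed: int = 0) -> tuple[float, float]:
    """Profile-likelihood confidence interval for the repeatability.

    R maps one-to-one to the variance ratio gam_r = R/(1-R); for each
    candidate R the likelihood is maximised over the date ratio and the
    residual variance, and the CI is the set of R whose -2 log likelihood
    is within the chi-square(1) quantile of the optimum.  Falls back to a
    parametric bootstrap when the profile is too flat to bracket a bound.
    """
    from scipy.stats import chi2

    data = fit.data
    if data is None:
        raise ValueError("fit was created without retained data")
    if fit.degenerate:
        raise ValueError("repeatability undefined: no residual variation")
    crit = chi2.ppf(level, 1)
    method = fit.method

    def prof(R: float) -> float:
        R = min(max(R, 1e-9), 1 - 1e-9)
        gr = R / (1.0 - R)
        if data.include_date:
            res = optimize.minimize_scalar(
                lambda z: data.neg2ll(math.exp(z), gr, method),
                bounds=_LG_BOUNDS, method="bounded", options={"xatol": 1e-7})
            return float(res.fun)
        return data.neg2ll(None, gr, method)

    tot = fit.sigma2_ril + fit.sigma2_resid
    Rhat = fit.sigma2_ril / tot if tot > 0 else 0.0
    base = prof(Rhat)

    def diff(R: float) -> float:
        return prof(R) - base - crit

    eps = 1e-7
    lo_edge, hi_edge = eps, 1 - eps
    lo: Optional[float] = None
    hi: Optional[float] = None
    if diff(lo_edge) > 0:
        lo = optimize.brentq(diff, lo_edge, max(Rhat, 2 * eps), xtol=1e-6)
    if diff(hi_edge) > 0:
        hi = optimize.brentq(diff, min(Rhat, 1 - 2 * eps), hi_edge, xtol=1e-6)

    if lo is None or hi is None:
        boot = _bootstrap_repeatability(fit, n_boot_fallback, seed)
        alpha = (1 - level) / 2
        blo, bhi = np.quantile(boot, [alpha, 1 - alpha])
        lo = float(blo) if lo is None else lo
        hi = float(bhi) if hi is None else hi
    return float(lo), float(hi)


def _bootstrap_repeatability(fit: MixedFit, n_boot: int, seed: int) -> np.ndarray:
    """Parametric bootstrap of R under the fitted model."""
    data = fit.data
    rng = np.random.default_rng(seed)
    out = np.empty(n_boot)
    mu = data.X @ fit.beta
    for b in range(n_boot):
        u = rng.normal(0, math.sqrt(fit.sigma2_date), data.d) if fit.sigma2_date > 0 else np.zeros(data.d)
        v = rng.normal(0, math.sqrt(fit.sigma2_ril), data.r)
        yb = mu + u[data.d_codes] + v[data.r_codes] + rng.normal(0, math.sqrt(fit.sigma2_resid), data.n)
        fb = fit_crossed(yb, data.X, np.asarray(data.date_levels)[data.d_codes],
                         np.asarray(data.ril_levels)[data.r_codes], method=fit.method)
        tot = fb.sigma2_ril + fb.sigma2_resid
        out[b] = fb.sigma2_ril / tot if tot > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# Gibbs sampler (Bayesian route for variance decomposition)
# ---------------------------------------------------------------------------

@dataclass
class McmcSettings:
    """Chain settings for the Gaussian crossed-model Gibbs sampler.

    Weak inverse-gamma(0.001, 0.001) priors on all variances, flat prior on
    fixed effects.
    """

    n_iter: int = 13_000
    burn_in: int = 3_000
    thin: int = 10
    prior_shape: float = 0.001
    prior_rate: float = 0.001
    min_ess: float = 100.0


def gibbs_crossed(y, X, dates, rils, settings: McmcSettings = McmcSettings(),
                  seed: int = 0) -> dict:
    """Gibbs sampler for the crossed mixed model.

    Returns thinned posterior draws of the three variance components and
    the fixed effects, plus effective sample sizes for the variances.
    """
    data = MixedData(y, X, dates, rils)
    rng = np.random.default_rng(seed)
    n, p, d, r = data.n, data.p, data.d, data.r
    X_, yv = data.X, data.y
    XtX_cho = linalg.cho_factor(data.XtX + 1e-12 * np.eye(p), lower=True)
    Lx = linalg.cholesky(linalg.cho_solve(XtX_cho, np.eye(p)), lower=True)

    a0, b0 = settings.prior_shape, settings.prior_rate
    include_date = data.include_date

    beta = linalg.cho_solve(XtX_cho, data.Xty)
    u = np.zeros(d)
    v = np.zeros(r)
    s2d, s2r, s2e = 1.0, max(np.var(yv), 1e-6), max(np.var(yv), 1e-6)

    keep = [(i - settings.burn_in) % settings.thin == 0 and i >= settings.burn_in
            for i in range(settings.n_iter)]
    n_keep = sum(keep)
    out_s2d = np.empty(n_keep)
    out_s2r = np.empty(n_keep)
    out_s2e = np.empty(n_keep)
    out_beta = np.empty((n_keep, p))

    k = 0
    for it in range(settings.n_iter):
        # fixed effects
        resid = yv - (u[data.d_codes] if include_date else 0.0) - v[data.r_codes]
        mean = linalg.cho_solve(XtX_cho, X_.T @ resid)
        beta = mean + math.sqrt(s2e) * (Lx @ rng.standard_normal(p))
        xb = X_ @ beta
        # date effects
        if include_date:
            resid_d = np.bincount(data.d_codes, weights=yv - xb - v[data.r_codes], minlength=d)
            prec = data.cd / s2e + 1.0 / s2d
            u = resid_d / s2e / prec + rng.standard_normal(d) / np.sqrt(prec)
            s2d = 1.0 / rng.gamma(a0 + d / 2.0, 1.0 / (b0 + 0.5 * float(u @ u)))
        # RIL effects
        resid_r = np.bincount(data.r_codes, weights=yv - xb - (u[data.d_codes] if include_date else 0.0),
                              minlength=r)
        prec = data.cr / s2e + 1.0 / s2r
        v = resid_r / s2e / prec + rng.standard_normal(r) / np.sqrt(prec)
        s2r = 1.0 / rng.gamma(a0 + r / 2.0, 1.0 / (b0 + 0.5 * float(v @ v)))
        # residual
        e = yv - xb - (u[data.d_codes] if include_date else 0.0) - v[data.r_codes]
        s2e = 1.0 / rng.gamma(a0 + n / 2.0, 1.0 / (b0 + 0.5 * float(e @ e)))
        if keep[it]:
            out_s2d[k], out_s2r[k], out_s2e[k] = s2d if include_date else 0.0, s2r, s2e
            out_beta[k] = beta
            k += 1

    return {
        "sigma2_date": out_s2d,
        "sigma2_ril": out_s2r,
        "sigma2_resid": out_s2e,
        "beta": out_beta,
        "fixed_names": data.fixed_names,
        "ess_sigma2_ril": effective_sample_size(out_s2r),
        "ess_sigma2_resid": effective_sample_size(out_s2e),
    }


def effective_sample_size(x: np.ndarray) -> float:
    """ESS from the initial positive sequence of autocorrelations."""
    x = np.asarray(x, dtype=float)
    m = len(x)
    if m < 4 or np.var(x) == 0:
        return float(m)
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[m - 1:] / m
    rho = acov / acov[0]
    # Geyer initial positive sequence on pair sums
    s = 0.0
    t = 1
    while t + 1 < m:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        s += pair
        t += 2
    ess = m / (1.0 + 2.0 * s)
    return float(min(max(ess, 1.0), m))
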