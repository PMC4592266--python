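"""Maximum-likelihood GLM/GLMM fitting with random intercepts.

One engine covers the four response families the breeding-success
analyses need: Gaussian, Poisson (log link), binomial with exposure-day
trials (logit link on the daily failure probability, fractional trials
allowed), and cumulative-logit for ordinal fledgling counts.  Random
intercepts (one or more grouping factors, e.g. farm and nest) are
integrated out with a Laplace approximation to the marginal likelihood:
the mode of the joint log-density in the random effects is found by
Newton iteration and the curvature term supplies the correction.  For a
Gaussian response the joint density is exactly quadratic in the random
effects, so the Laplace approximation is exact and the fit agrees with a
conventional ML linear mixed model.

All fits are ML (never REML) so information-criterion comparisons across
fixed-effect structures are valid.  The binomial-exposure log-likelihood
drops the combinatorial constant (it is undefined for fractional trials
and cancels in every likelihood-ratio and AICc difference); the
convention is applied consistently across all fits of that family.

Parameter count ``k_params`` follows the model-selection convention:
fixed coefficients + ordinal thresholds + residual variance (Gaussian)
+ one variance component per random grouping factor.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, gammaln

from statsmodels.tools.numdiff import approx_hess1

__all__ = [
    "Gaussian",
    "Poisson",
    "BinomialExposure",
    "CumulativeLogit",
    "MixedModel",
    "MixedModelResults",
    "r2_nakagawa",
    "mcfadden_r2",
]

_LOGIT_CLIP = 30.0


def _clip_eta(eta):
    return np.clip(eta, -_LOGIT_CLIP, _LOGIT_CLIP)


class Family:
    """Per-observation log-likelihood and its derivatives in eta."""

    n_extra = 0
    name = "family"
    has_intercept = True

    def extra_start(self, endog):
        return np.empty(0)

    def loglike_obs(self, endog, eta, extra):
        raise NotImplementedError

    def d1(self, endog, eta, extra):
        raise NotImplementedError

    def d2(self, endog, eta, extra):
        raise NotImplementedError


class Gaussian(Family):
    """Normal response, identity link; extra parameter is log residual variance."""

    n_extra = 1
    name = "gaussian"

    def extra_start(self, endog):
        return np.array([np.log(max(np.var(endog), 1e-8))])

    def loglike_obs(self, endog, eta, extra):
        s2 = np.exp(extra[0])
        return -0.5 * (np.log(2 * np.pi * s2) + (endog - eta) ** 2 / s2)

    def d1(self, endog, eta, extra):
        return (endog - eta) / np.exp(extra[0])

    def d2(self, endog, eta, extra):
        return np.full(len(eta), -1.0 / np.exp(extra[0]))


class Poisson(Family):
    """Poisson counts, log link."""

    name = "poisson"

    def loglike_obs(self, endog, eta, extra):
        eta = _clip_eta(eta)
        return endog * eta - np.exp(eta) - gammaln(endog + 1.0)

    def d1(self, endog, eta, extra):
        return endog - np.exp(_clip_eta(eta))

    def d2(self, endog, eta, extra):
        return -np.exp(_clip_eta(eta))


class BinomialExposure(Family):
    """Binomial with exposure-day trials; logit link on daily failure.

    ``endog`` is a two-column array ``[failures, exposure_days]`` per
    nest; failures are 0/1, exposure days may be fractional (half-day
    midpoints).  The log-likelihood kernel is
    ``f log h + (t - f) log(1 - h)`` with ``h = expit(eta)``.
    """

    name = "binomial-exposure"

    def loglike_obs(self, endog, eta, extra):
        f, t = endog[:, 0], endog[:, 1]
        eta = _clip_eta(eta)
        h = expit(eta)
        return f * np.log(h) + (t - f) * np.log1p(-h)

    def d1(self, endog, eta, extra):
        f, t = endog[:, 0], endog[:, 1]
        return f - t * expit(_clip_eta(eta))

    def d2(self, endog, eta, extra):
        t = endog[:, 1]
        h = expit(_clip_eta(eta))
        return -t * h * (1.0 - h)


class CumulativeLogit(Family):
    """Proportional-odds model for ordinal responses.

    ``endog`` holds category codes 0..K-1.  The linear predictor carries
    no intercept; K-1 ordered thresholds are parametrised as the first
    threshold plus log-increments so ordering is unconstrained during
    optimisation.  P(y = k) = F(theta_k - eta) - F(theta_{k-1} - eta)
    with F the logistic CDF.
    """

    name = "ordinal-cumulative-logit"
    has_intercept = False

    def __init__(self, n_levels: int):
        if n_levels < 2:
            raise ValueError("ordinal response needs >= 2 observed levels")
        self.n_levels = n_levels
        self.n_extra = n_levels - 1

    def thresholds(self, extra):
        th = np.empty(self.n_extra)
        th[0] = extra[0]
        if self.n_extra > 1:
            th[1:] = extra[0] + np.cumsum(np.exp(extra[1:]))
        return th

    def extra_start(self, endog):
        # thresholds from marginal cumulative proportions
        counts = np.bincount(endog.astype(int), minlength=self.n_levels)
        p = np.clip(np.cumsum(counts)[:-1] / counts.sum(), 1e-4, 1 - 1e-4)
        th = np.log(p / (1 - p))
        th = np.maximum.accumulate(th)
        out = np.empty(self.n_extra)
        out[0] = th[0]
        if self.n_extra > 1:
            out[1:] = np.log(np.maximum(np.diff(th), 1e-3))
        return out

    def _bounds(self, endog, eta, extra):
        th = self.thresholds(extra)
        k = endog.astype(int)
        upper = np.where(k < self.n_extra, th[np.minimum(k, self.n_extra - 1)], np.inf)
        lower = np.where(k > 0, th[np.maximum(k - 1, 0)], -np.inf)
        return lower - eta, upper - eta

    @staticmethod
    def _F(x):
        return expit(np.clip(x, -_LOGIT_CLIP, _LOGIT_CLIP))

    @staticmethod
    def _f(x):
        p = expit(np.clip(x, -_LOGIT_CLIP, _LOGIT_CLIP))
        return p * (1 - p)

    @staticmethod
    def _fp(x):
        p = expit(np.clip(x, -_LOGIT_CLIP, _LOGIT_CLIP))
        return p * (1 - p) * (1 - 2 * p)

    def _pieces(self, endog, eta, extra):
        lo, hi = self._bounds(endog, eta, extra)
        Fhi = np.where(np.isinf(hi), 1.0, self._F(hi))
        Flo = np.where(np.isinf(lo), 0.0, self._F(lo))
        fhi = np.where(np.isinf(hi), 0.0, self._f(hi))
        flo = np.where(np.isinf(lo), 0.0, self._f(lo))
        fphi = np.where(np.isinf(hi), 0.0, self._fp(hi))
        fplo = np.where(np.isinf(lo), 0.0, self._fp(lo))
        P = np.clip(Fhi - Flo, 1e-12, 1.0)
        return P, fhi, flo, fphi, fplo

    def loglike_obs(self, endog, eta, extra):
        P, *_ = self._pieces(endog, eta, extra)
        return np.log(P)

    def d1(self, endog, eta, extra):
        P, fhi, flo, _, _ = self._pieces(endog, eta, extra)
        return -(fhi - flo) / P

    def d2(self, endog, eta, extra):
        P, fhi, flo, fphi, fplo = self._pieces(endog, eta, extra)
        dP = -(fhi - flo)
        d2P = fphi - fplo
        return d2P / P - (dP / P) ** 2


def _make_family(family, endog):
    if isinstance(family, Family):
        return family
    if family == "gaussian":
        return Gaussian()
    if family == "poisson":
        return Poisson()
    if family == "binomial-exposure":
        return BinomialExposure()
    if family == "ordinal-cumulative-logit":
        return CumulativeLogit(int(np.max(endog)) + 1)
    raise ValueError(f"unknown family {family!r}")


class MixedModel:
    """GLM with optional random intercepts, fitted by (Laplace) ML.

    Parameters
    ----------
    endog : array
        Response.  Two columns ``[failures, exposure]`` for the
        binomial-exposure family; integer codes 0..K-1 for the ordinal
        family; a plain vector otherwise.
    exog : 2-D array
        Fixed-effects design matrix (include the intercept column
        yourself; the ordinal family must not have one).
    family : str or Family
        One of ``gaussian``, ``poisson``, ``binomial-exposure``,
        ``ordinal-cumulative-logit`` or a Family instance.
    groups : dict[str, array] or None
        Random-intercept grouping factors mapped to per-observation
        labels; each factor contributes one variance component.
    exog_names : sequence of str, optional
    """

    def __init__(self, endog, exog, family, groups=None, exog_names=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != len(self.endog):
            raise ValueError("endog and exog lengths differ")
        self.nobs = self.exog.shape[0]
        self.k_exog = self.exog.shape[1]
        self.family = _make_family(family, self.endog)
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{i}" for i in range(self.k_exog)]
        )
        if self.k_exog:
            r = np.linalg.matrix_rank(self.exog)
            if r < self.k_exog:
                raise ValueError(
                    f"fixed-effects design is rank deficient (rank {r} < {self.k_exog}); "
                    "drop aliased terms"
                )
        self.group_names: list[str] = []
        self._Z = None
        self._group_sizes: list[int] = []
        self._u_warm = None  # warm start for the inner Laplace mode search
        if groups:
            zs = []
            for name, labels in groups.items():
                codes, levels = pd.factorize(np.asarray(labels))
                q = len(levels)
                z = sparse.csr_matrix(
                    (np.ones(self.nobs), (np.arange(self.nobs), codes)),
                    shape=(self.nobs, q),
                )
                zs.append(z)
                self.group_names.append(name)
                self._group_sizes.append(q)
            self._Z = sparse.hstack(zs, format="csr")
        self.n_vc = len(self.group_names)
        self.k_params = self.k_exog + self.family.n_extra + self.n_vc

    # ---- likelihood -------------------------------------------------

    def _unpack(self, params):
        p, m = self.k_exog, self.family.n_extra
        return params[:p], params[p : p + m], params[p + m :]

    def _prior_prec(self, log_s2):
        prec = np.concatenate(
            [
                np.full(q, 1.0 / np.exp(ls2))
                for q, ls2 in zip(self._group_sizes, log_s2)
            ]
        )
        return prec

    def _laplace(self, beta, extra, log_s2, u0=None):
        """Marginal log-likelihood via Laplace; returns (llf, u_hat)."""
        Z = self._Z
        q = Z.shape[1]
        prec = self._prior_prec(log_s2)
        xb = self.exog @ beta if self.k_exog else np.zeros(self.nobs)
        u = np.zeros(q) if u0 is None else u0.copy()

        def pen(u):
            eta = xb + Z @ u
            ll = self.family.loglike_obs(self.endog, eta, extra).sum()
            return ll - 0.5 * np.sum(prec * u**2)

        val = pen(u)
        for _ in range(100):
            eta = xb + Z @ u
            g = Z.T @ self.family.d1(self.endog, eta, extra) - prec * u
            W = -self.family.d2(self.endog, eta, extra)
            H = (Z.T @ sparse.diags(np.maximum(W, 1e-12)) @ Z).toarray()
            H[np.diag_indices_from(H)] += prec
            c, low = cho_factor(H)
            step = cho_solve((c, low), g)
            # backtracking line search on the penalized objective
            t = 1.0
            for _ in range(30):
                u_new = u + t * step
                val_new = pen(u_new)
                if val_new >= val - 1e-12:
                    break
                t *= 0.5
            if not np.isfinite(val_new):
                return -np.inf, u
            moved = np.max(np.abs(u_new - u))
            u, val = u_new, val_new
            if moved < 1e-10 or abs(val_new - val) < 1e-12 and moved < 1e-8:
                break

        eta = xb + Z @ u
        W = -self.family.d2(self.endog, eta, extra)
        H = (Z.T @ sparse.diags(np.maximum(W, 1e-12)) @ Z).toarray()
        H[np.diag_indices_from(H)] += prec
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:
            return -np.inf, u
        joint = val - 0.5 * np.sum(np.log(2 * np.pi / prec))
        llf = joint + 0.5 * q * np.log(2 * np.pi) - 0.5 * logdet
        return llf, u

    def loglike(self, params):
        beta, extra, log_s2 = self._unpack(params)
        if self._Z is None:
            eta = self.exog @ beta if self.k_exog else np.zeros(self.nobs)
            ll = self.family.loglike_obs(self.endog, eta, extra).sum()
            return ll if np.isfinite(ll) else -np.inf
        llf, u = self._laplace(beta, extra, log_s2, u0=self._u_warm)
        self._u_warm = u
        return llf

    # ---- fitting ----------------------------------------------------

    def _start_params(self):
        fam = self.family
        extra0 = fam.extra_start(self.endog)
        beta0 = np.zeros(self.k_exog)
        if isinstance(fam, Gaussian) and self.k_exog:
            beta0, *_ = np.linalg.lstsq(self.exog, self.endog, rcond=None)
            resid = self.endog - self.exog @ beta0
            extra0 = np.array([np.log(max(np.mean(resid**2), 1e-8))])
        elif isinstance(fam, Poisson) and self.k_exog:
            has_const = np.all(self.exog[:, 0] == 1.0)
            if has_const:
                beta0[0] = np.log(max(np.mean(self.endog), 1e-8))
        log_s2_0 = np.full(self.n_vc, np.log(0.25))
        return np.concatenate([beta0, extra0, log_s2_0])

    def fit(self, maxiter=500, tol=1e-12, start_params=None) -> "MixedModelResults":
        """Maximise the (marginal) log-likelihood; deterministic given data."""
        if isinstance(self.family, Gaussian) and self._Z is None:
            return self._fit_gaussian_ols()
        x0 = self._start_params() if start_params is None else np.asarray(start_params)

        def nll(p):
            v = self.loglike(p)
            return np.inf if not np.isfinite(v) else -v

        res = optimize.minimize(
            nll,
            x0,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-9},
        )
        if not np.isfinite(res.fun):
            raise RuntimeError(f"model fit failed to converge: {res.message}")
        # polish with Nelder-Mead if L-BFGS-B stalled early
        if not res.success:
            res2 = optimize.minimize(
                nll, res.x, method="Nelder-Mead",
                options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
            )
            if res2.fun <= res.fun:
                res = res2
        params = res.x
        llf = -res.fun
        cov = self._cov_params(params)
        return MixedModelResults(self, params, llf, cov)

    def _fit_gaussian_ols(self):
        """Closed-form ML for the fixed-effects Gaussian model."""
        beta, *_ = np.linalg.lstsq(self.exog, self.endog, rcond=None)
        resid = self.endog - self.exog @ beta
        s2 = float(np.mean(resid**2))
        s2 = max(s2, 1e-300)
        llf = -0.5 * self.nobs * (np.log(2 * np.pi * s2) + 1.0)
        params = np.concatenate([beta, [np.log(s2)]])
        xtx = self.exog.T @ self.exog
        cov_beta = s2 * np.linalg.inv(xtx)
        cov = np.full((self.k_params, self.k_params), np.nan)
        cov[: self.k_exog, : self.k_exog] = cov_beta
        cov[-1, -1] = 2.0 / self.nobs  # var of log sigma^2 (ML)
        return MixedModelResults(self, params, llf, cov)

    def _cov_params(self, params):
        try:
            H = approx_hess1(params, lambda p: -self.loglike(p))
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            if np.any(d <= 0) or not np.all(np.isfinite(d)):
                raise np.linalg.LinAlgError
            return cov
        except np.linalg.LinAlgError:
            pass
        # a variance component at its boundary makes the full information
        # singular; condition on the variance components and invert the
        # fixed-effect (+family extras) block instead
        nb = self.k_exog + self.family.n_extra
        tail = params[nb:]

        def nll_beta(b):
            return -self.loglike(np.concatenate([b, tail]))

        try:
            Hb = approx_hess1(params[:nb], nll_beta)
            covb = np.linalg.inv(Hb)
            d = np.diag(covb)
            if np.any(d <= 0) or not np.all(np.isfinite(d)):
                raise np.linalg.LinAlgError
            cov = np.full((len(params), len(params)), np.nan)
            cov[:nb, :nb] = covb
            return cov
        except np.linalg.LinAlgError:
            warnings.warn(
                "observed information not positive definite; "
                "standard errors unavailable for some parameters"
            )
            return np.full((len(params), len(params)), np.nan)


class MixedModelResults:
    """Fitted-model container: estimates, SEs, logLik, parameter count."""

    def __init__(self, model, params_all, llf, cov_all):
        self.model = model
        self.params_all = params_all
        self.llf = float(llf)
        self.cov_all = cov_all
        self.nobs = model.nobs
        self.k_params = model.k_params
        p, m = model.k_exog, model.family.n_extra
        self.params = pd.Series(params_all[:p], index=model.exog_names)
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(cov_all))
        self.bse = pd.Series(se[:p], index=model.exog_names)
        self.extra = params_all[p : p + m]
        self.vcomp = pd.Series(
            np.exp(params_all[p + m :]), index=model.group_names, dtype=float
        )
        if isinstance(model.family, Gaussian):
            self.scale = float(np.exp(self.extra[0]))
        else:
            self.scale = None

    @property
    def fittedvalues_fixed(self):
        if self.model.k_exog == 0:
            return np.zeros(self.nobs)
        return self.model.exog @ self.params.to_numpy()

    def conf_int(self, alpha=0.05):
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        tab = pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "lower_ci": ci["lower"],
                "upper_ci": ci["upper"],
            }
        )
        tab.attrs["llf"] = self.llf
        tab.attrs["k"] = self.k_params
        tab.attrs["nobs"] = self.nobs
        tab.attrs["family"] = self.model.family.name
        return tab


def r2_nakagawa(results: MixedModelResults) -> tuple[float, float]:
    """Marginal and conditional R-squared by variance partitioning.

    Marginal R2 is the fixed-effect variance over the total of fixed,
    random-intercept and residual variance; conditional R2 adds the
    random-intercept variance to the numerator.  The residual variance is
    family specific: the ML residual variance for Gaussian, the
    lognormal approximation ``ln(1/mean + 1)`` for Poisson (log link)
    and the logistic-distribution variance ``pi^2 / 3`` for binomial
    (logit link).
    """
    fam = results.model.family
    var_f = float(np.var(results.fittedvalues_fixed))
    var_r = float(results.vcomp.sum()) if len(results.vcomp) else 0.0
    if isinstance(fam, Gaussian):
        var_e = results.scale
    elif isinstance(fam, Poisson):
        lam = float(np.mean(results.model.endog))
        if lam <= 0:
            raise ValueError("Poisson R2 needs a positive mean count")
        var_e = np.log(1.0 / lam + 1.0)
    elif isinstance(fam, BinomialExposure):
        var_e = np.pi**2 / 3.0
    else:
        raise ValueError(
            f"variance-partition R2 undefined for family {fam.name!r}; "
            "use mcfadden_r2 for ordinal fits"
        )
    tot = var_f + var_r + var_e
    return var_f / tot, (var_f + var_r) / tot


def mcfadden_r2(results: MixedModelResults, null_results: MixedModelResults) -> float:
    """McFadden's pseudo R-squared, 1 - logLik(model)/logLik(null)."""
    return 1.0 - results.llf / null_results.llf
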