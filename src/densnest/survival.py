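"""Nest-visit reduction and exposure-day survival models.

Nests are followed by periodic visits (at most 3 days apart) recording
whether the nest is active with eggs or nestlings, empty but intact,
damaged, or depredated.  Apparent success over-states survival because
failed nests are found less often; the exposure-day (Mayfield) approach
instead models the *daily* failure hazard using the days each nest was
actually at risk while under observation.

Exposure for a failed nest runs from the first visit to the midpoint of
the last visit at which it was active and the first at which it was not
("Last Active-B"); a successful or censored nest accrues exposure to its
last observed active day.  Exposure splits into egg and nestling stage
at the (observed or estimated) hatch day.

The covariate model — :class:`LogisticExposure` — treats each nest as a
binomial observation with trials equal to its exposure days and at most
one "success" (the failure indicator), with a logit link on the daily
failure probability.  Its intercept-only maximum-likelihood estimate is
algebraically the classic Mayfield estimator
``1 - total failures / total exposure``.

Fledging rule: a nest that held nestlings at the day-7 check and was
empty but intact at the day-10 check is deemed to have fledged; a
damaged nest is deemed to have failed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .glmm import BinomialExposure, MixedModel, MixedModelResults

__all__ = [
    "ACTIVE_STATUSES",
    "NestOutcome",
    "classify_outcome",
    "exposure_days",
    "split_exposure",
    "summarize_nest",
    "summarize_exposures",
    "mayfield_dsr",
    "period_survival",
    "LogisticExposure",
    "SeparationWarning",
]

STATUS_EGGS = "active-eggs"
STATUS_NESTLINGS = "active-nestlings"
STATUS_EMPTY = "empty-intact"
STATUS_DAMAGED = "damaged"
STATUS_DEPREDATED = "depredated"
ACTIVE_STATUSES = frozenset({STATUS_EGGS, STATUS_NESTLINGS})
ALL_STATUSES = ACTIVE_STATUSES | {STATUS_EMPTY, STATUS_DAMAGED, STATUS_DEPREDATED}

FLEDGE_CHECK_AGE = 7  # nestling age of the "nestlings present" check
EMPTY_CHECK_AGE = 10  # nestling age at/after which empty-intact means fledged


class SeparationWarning(UserWarning):
    """Raised when the failure outcome is perfectly separated."""


def _prep_visits(visits: pd.DataFrame) -> pd.DataFrame:
    if len(visits) < 2:
        raise ValueError("need at least two visits per nest")
    v = visits.sort_index() if visits["day"].is_monotonic_increasing else visits
    days = v["day"].to_numpy()
    if np.any(np.diff(days) <= 0):
        raise ValueError("visit days must be strictly increasing within a nest")
    unknown = set(v["status"]) - ALL_STATUSES
    if unknown:
        raise ValueError(f"unknown visit status values: {sorted(unknown)}")
    return v


@dataclass(frozen=True)
class NestOutcome:
    """Outcome of one visit history: fate, fledgling count, brood reduction."""

    fledged: bool
    failed: bool
    unknown: bool
    n_fledged: int
    brood_reduced: float  # 1.0 / 0.0 / nan when brood size never observed twice
    last_active_day: float
    first_inactive_day: float  # nan if still active at the final visit


def classify_outcome(visits: pd.DataFrame, hatch_day: float | None = None) -> NestOutcome:
    """Apply the fledging/failure rules to one nest's visit history.

    Parameters
    ----------
    visits : DataFrame
        Columns ``day``, ``status`` and (optionally) ``n_eggs``,
        ``n_nestlings`` for one nest.
    hatch_day : float, optional
        Study day of hatching; defaults to the first visit at which
        nestlings were recorded.
    """
    v = _prep_visits(visits)
    days = v["day"].to_numpy(dtype=float)
    status = v["status"].to_numpy()
    active = np.isin(status, list(ACTIVE_STATUSES))
    if not active.any():
        return NestOutcome(False, False, True, 0, np.nan, np.nan, np.nan)
    last_active_idx = np.max(np.nonzero(active)[0])
    last_active_day = days[last_active_idx]
    after = np.nonzero(~active & (days > last_active_day))[0]
    first_inactive_idx = after[0] if len(after) else None

    if hatch_day is None:
        nestling_visits = np.nonzero(status == STATUS_NESTLINGS)[0]
        hatch_day = days[nestling_visits[0]] if len(nestling_visits) else np.nan

    counts = (
        v["n_nestlings"].to_numpy(dtype=float)
        if "n_nestlings" in v.columns
        else np.full(len(v), np.nan)
    )
    nest_counts = counts[status == STATUS_NESTLINGS]
    nest_counts = nest_counts[~np.isnan(nest_counts)]
    brood_reduced = (
        float(nest_counts[-1] < nest_counts[0]) if len(nest_counts) >= 2 else np.nan
    )

    if first_inactive_idx is None:
        # still active at the final visit: censored
        return NestOutcome(False, False, True, 0, brood_reduced, last_active_day, np.nan)

    first_inactive_day = days[first_inactive_idx]
    inactive_status = status[first_inactive_idx]
    had_nestlings_at_7 = (
        status[last_active_idx] == STATUS_NESTLINGS
        and np.isfinite(hatch_day)
        and last_active_day - hatch_day >= FLEDGE_CHECK_AGE
    )
    if inactive_status in (STATUS_DAMAGED, STATUS_DEPREDATED):
        fledged, failed, unk = False, True, False
    elif inactive_status == STATUS_EMPTY:
        if had_nestlings_at_7 and first_inactive_day - hatch_day >= EMPTY_CHECK_AGE:
            fledged, failed, unk = True, False, False
        elif not had_nestlings_at_7:
            fledged, failed, unk = False, True, False
        else:
            # empty too soon after the day-7 check to apply the rule
            fledged, failed, unk = False, False, True
    else:  # pragma: no cover - statuses are exhaustive
        fledged, failed, unk = False, False, True

    n_fledged = int(nest_counts[-1]) if fledged and len(nest_counts) else 0
    return NestOutcome(
        fledged, failed, unk, n_fledged, brood_reduced, last_active_day, first_inactive_day
    )


def exposure_days(visits: pd.DataFrame, hatch_day: float | None = None) -> float:
    """Total exposure days for one nest ("Last Active-B").

    Failed nests accrue exposure from the first visit to the midpoint of
    the last-active and first-inactive visit days; successful or
    censored nests to the last observed active day.
    """
    out = classify_outcome(visits, hatch_day=hatch_day)
    first_day = float(_prep_visits(visits)["day"].iloc[0])
    if out.failed:
        end = 0.5 * (out.last_active_day + out.first_inactive_day)
    else:
        end = out.last_active_day
    return end - first_day


def split_exposure(
    visits: pd.DataFrame, hatch_day: float | None
) -> tuple[float, float]:
    """Egg- and nestling-stage exposure days for one nest.

    Exposure before ``hatch_day`` accrues to the egg stage, after it to
    the nestling stage.  ``hatch_day=None`` (nest never aged, failed at
    egg stage) assigns all exposure to the egg stage.
    """
    v = _prep_visits(visits)
    first_day = float(v["day"].iloc[0])
    last_day = float(v["day"].iloc[-1])
    total = exposure_days(visits, hatch_day=hatch_day)
    if hatch_day is None:
        return total, 0.0
    if not first_day <= hatch_day <= last_day:
        raise ValueError(
            f"hatch_day {hatch_day} outside the monitored window "
            f"[{first_day}, {last_day}]"
        )
    end = first_day + total
    egg = min(max(hatch_day - first_day, 0.0), total)
    nestling = max(end - max(hatch_day, first_day), 0.0)
    return egg, nestling


def summarize_nest(
    visits: pd.DataFrame, hatch_day: float | None = None
) -> dict:
    """Reduce one visit history to its exposure summary row."""
    out = classify_outcome(visits, hatch_day=hatch_day)
    if hatch_day is None:
        v = _prep_visits(visits)
        nest_idx = np.nonzero(v["status"].to_numpy() == STATUS_NESTLINGS)[0]
        hatch = float(v["day"].iloc[nest_idx[0]]) if len(nest_idx) else None
    else:
        hatch = hatch_day
    egg, nestling = split_exposure(visits, hatch)
    egg_failed = int(out.failed and nestling == 0.0)
    nestling_failed = int(out.failed and nestling > 0.0)
    return {
        "egg_exposure": egg,
        "nestling_exposure": nestling,
        "egg_failed": egg_failed,
        "nestling_failed": nestling_failed,
        "fledged": int(out.fledged),
        "unknown": int(out.unknown),
        "n_fledged": out.n_fledged,
        "brood_reduced": out.brood_reduced,
        "hatch_day": hatch if hatch is not None else np.nan,
    }


def summarize_exposures(
    visits: pd.DataFrame, hatch_days: pd.Series | dict | None = None
) -> pd.DataFrame:
    """Exposure summaries for every nest in a combined visit table.

    Parameters
    ----------
    visits : DataFrame
        Columns ``nest_id``, ``day``, ``status``, optional counts.
    hatch_days : mapping nest_id -> study day, optional
    """
    rows = []
    for nest_id, grp in visits.groupby("nest_id", sort=False):
        hd = None
        if hatch_days is not None and nest_id in hatch_days:
            hd = hatch_days[nest_id]
            if hd is not None and not np.isfinite(hd):
                hd = None
        row = summarize_nest(grp.sort_values("day"), hatch_day=hd)
        row["nest_id"] = nest_id
        rows.append(row)
    df = pd.DataFrame(rows)
    return df[["nest_id"] + [c for c in df.columns if c != "nest_id"]]


def mayfield_dsr(total_failures: float, total_exposure: float) -> tuple[float, float]:
    """Classic Mayfield daily survival rate and its standard error.

    DSR = 1 - failures/exposure; the SE is the binomial standard error
    of the daily failure proportion, sqrt(p (1-p) / exposure).
    """
    if total_exposure <= 0:
        raise ValueError("total exposure must be positive")
    if total_failures < 0 or total_failures > total_exposure:
        raise ValueError("failures must lie in [0, exposure]")
    p = total_failures / total_exposure
    dsr = 1.0 - p
    se = float(np.sqrt(p * (1.0 - p) / total_exposure))
    return dsr, se


def period_survival(dsr: float, t: float) -> float:
    """Probability of surviving ``t`` days at daily survival rate ``dsr``."""
    if not 0.0 <= dsr <= 1.0:
        raise ValueError("dsr must be a probability")
    return dsr**t


class LogisticExposure:
    """Covariate model for daily nest failure with exposure-day trials.

    Each nest contributes a binomial observation with trials equal to its
    (possibly fractional) exposure days and successes equal to its 0/1
    failure indicator; the daily failure probability follows a logit-
    linear model in the covariates.  With only an intercept, the MLE
    reproduces the Mayfield estimator exactly.

    Parameters
    ----------
    failures : array of 0/1
    exposure : array of positive exposure days
    exog : 2-D array
        Design matrix including the intercept column.
    groups : dict[str, array], optional
        Random-intercept grouping (e.g. farm identity); the marginal
        likelihood is then maximised via the Laplace approximation.
    likelihood : {"binomial", "interval"}
        ``binomial`` (default) is the exposure-trials form above;
        ``interval`` scores each failed nest by the probability of
        failing at least once in its exposure window, 1 - (1-h)^t.
    """

    def __init__(
        self,
        failures,
        exposure,
        exog,
        groups=None,
        exog_names=None,
        likelihood="binomial",
    ):
        failures = np.asarray(failures, dtype=float)
        exposure = np.asarray(exposure, dtype=float)
        if np.any(exposure <= 0):
            raise ValueError("every nest must have positive exposure")
        if not np.all(np.isin(failures, [0.0, 1.0])):
            raise ValueError("failures must be 0/1 indicators")
        if likelihood not in ("binomial", "interval"):
            raise ValueError("likelihood must be 'binomial' or 'interval'")
        self.likelihood = likelihood
        self.failures = failures
        self.exposure = exposure
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{i}" for i in range(self.exog.shape[1])]
        )
        self.groups = groups
        endog = np.column_stack([failures, exposure])
        fam = _IntervalFamily() if likelihood == "interval" else BinomialExposure()
        self._mm = MixedModel(
            endog, self.exog, fam, groups=groups, exog_names=self.exog_names
        )

    def fit(self, maxiter=200, tol=1e-8) -> "LogisticExposureResults":
        if self.groups is None and self.likelihood == "binomial":
            params, llf, cov, penalized = self._fit_newton(maxiter, tol)
            res = MixedModelResults(self._mm, params, llf, cov)
        else:
            res = self._mm.fit(maxiter=maxiter, tol=tol)
            penalized = False
        return LogisticExposureResults(self, res, penalized)

    def _fit_newton(self, maxiter, tol, ridge=0.0):
        f, t, X = self.failures, self.exposure, self.exog
        beta = np.zeros(X.shape[1])
        if np.all(X[:, 0] == 1.0):
            p = np.clip(f.sum() / t.sum(), 1e-10, 1 - 1e-10)
            beta[0] = logit(p)
        penalized = False
        if f.sum() == 0 or f.sum() == len(f):
            warnings.warn(
                "all nests share the same outcome: the intercept is not "
                "identified (separation); fitting with a ridge penalty",
                SeparationWarning,
            )
            return self._fit_newton_ridged(maxiter, tol)
        llf_old = -np.inf
        for _ in range(maxiter):
            eta = np.clip(X @ beta, -30, 30)
            h = expit(eta)
            llf = float(f @ np.log(h) + (t - f) @ np.log1p(-h)) - ridge * beta @ beta
            g = X.T @ (f - t * h) - 2 * ridge * beta
            W = t * h * (1 - h)
            H = X.T @ (X * W[:, None]) + 2 * ridge * np.eye(X.shape[1])
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                return self._fit_newton_ridged(maxiter, tol)
            # dampen huge steps (possible quasi-separation)
            norm = np.max(np.abs(step))
            if norm > 5.0:
                step *= 5.0 / norm
            beta = beta + step
            if np.max(np.abs(beta)) > 25.0:
                warnings.warn(
                    "coefficients diverging: outcome appears separated; "
                    "fitting with a ridge penalty",
                    SeparationWarning,
                )
                return self._fit_newton_ridged(maxiter, tol)
            if abs(llf - llf_old) < tol and np.max(np.abs(step)) < 1e-8:
                break
            llf_old = llf
        else:
            raise RuntimeError(
                f"logistic-exposure fit did not converge in {maxiter} iterations "
                f"(last logLik change {abs(llf - llf_old):.3g})"
            )
        eta = np.clip(X @ beta, -30, 30)
        h = expit(eta)
        llf = float(f @ np.log(h) + (t - f) @ np.log1p(-h))
        W = t * h * (1 - h)
        H = X.T @ (X * W[:, None])
        cov = np.zeros((self._mm.k_params, self._mm.k_params))
        cov[: X.shape[1], : X.shape[1]] = np.linalg.inv(H)
        params = beta  # no extras, no variance components
        return params, llf, cov, penalized

    def _fit_newton_ridged(self, maxiter, tol):
        f, t, X = self.failures, self.exposure, self.exog
        ridge = 1e-2

        def nll(b):
            eta = np.clip(X @ b, -30, 30)
            h = expit(eta)
            return -(f @ np.log(h) + (t - f) @ np.log1p(-h)) + ridge * b @ b

        from scipy import optimize

        res = optimize.minimize(nll, np.zeros(X.shape[1]), method="BFGS")
        beta = res.x
        eta = np.clip(X @ beta, -30, 30)
        h = expit(eta)
        llf = float(f @ np.log(h) + (t - f) @ np.log1p(-h))
        W = t * h * (1 - h)
        H = X.T @ (X * W[:, None]) + 2 * ridge * np.eye(X.shape[1])
        cov = np.linalg.inv(H)
        return beta, llf, cov, True


class _IntervalFamily(BinomialExposure):
    """Interval likelihood: a failed nest contributes 1 - (1-h)^t."""

    name = "binomial-interval"

    def loglike_obs(self, endog, eta, extra):
        f, t = endog[:, 0], endog[:, 1]
        h = expit(np.clip(eta, -30, 30))
        log_surv = t * np.log1p(-h)
        with np.errstate(divide="ignore"):
            log_fail = np.log(-np.expm1(log_surv))
        return np.where(f > 0, log_fail, log_surv)

    def d1(self, endog, eta, extra):  # numeric fallback via central differences
        e = 1e-6
        return (
            self.loglike_obs(endog, eta + e, extra)
            - self.loglike_obs(endog, eta - e, extra)
        ) / (2 * e)

    def d2(self, endog, eta, extra):
        e = 1e-5
        return (
            self.loglike_obs(endog, eta + e, extra)
            - 2 * self.loglike_obs(endog, eta, extra)
            + self.loglike_obs(endog, eta - e, extra)
        ) / e**2


class LogisticExposureResults:
    """Results wrapper exposing daily-failure-scale convenience methods."""

    def __init__(self, model, mm_results: MixedModelResults, penalized: bool):
        self.model = model
        self._res = mm_results
        self.penalized = penalized
        self.params = mm_results.params
        self.bse = mm_results.bse
        self.llf = mm_results.llf
        self.nobs = mm_results.nobs
        self.k_params = (
            model.exog.shape[1]
            + (len(model.groups) if model.groups else 0)
        )
        self.vcomp = mm_results.vcomp

    def conf_int(self, alpha=0.05):
        return self._res.conf_int(alpha)

    def daily_failure(self, exog=None) -> np.ndarray:
        """Fitted daily failure probability at given covariates."""
        X = self.model.exog if exog is None else np.atleast_2d(exog)
        return expit(np.clip(X @ self.params.to_numpy(), -30, 30))

    def dsr(self, exog=None) -> np.ndarray:
        """Fitted daily survival rate, 1 - daily failure."""
        return 1.0 - self.daily_failure(exog)

    def summary(self) -> pd.DataFrame:
        tab = self._res.summary()
        tab.attrs["likelihood"] = self.model.likelihood
        tab.attrs["penalized"] = self.penalized
        return tab
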