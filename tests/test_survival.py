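"""Visit-history reduction and exposure-day survival models."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.special import expit

import statsmodels.api as sm

from densnest.survival import (
    LogisticExposure,
    SeparationWarning,
    classify_outcome,
    exposure_days,
    mayfield_dsr,
    period_survival,
    split_exposure,
    summarize_exposures,
)


def visits(*rows):
    return pd.DataFrame(rows, columns=["day", "status", "n_eggs", "n_nestlings"])


class TestExposure:
    def test_failed_nest_uses_last_active_midpoint(self):
        v = visits(
            (10, "active-eggs", 3, None),
            (20, "active-eggs", 3, None),
            (24, "depredated", None, None),
        )
        assert exposure_days(v) == pytest.approx(12.0)

    def test_censored_nest_runs_to_last_active_day(self):
        v = visits(
            (10, "active-eggs", 3, None),
            (19, "active-eggs", 3, None),
        )
        assert exposure_days(v) == pytest.approx(9.0)

    def test_half_day_midpoint(self):
        v = visits(
            (10, "active-eggs", 3, None),
            (20, "active-eggs", 3, None),
            (21, "depredated", None, None),
        )
        assert exposure_days(v) == pytest.approx(10.5)

    def test_too_few_or_nonmonotone_visits_error(self):
        with pytest.raises(ValueError, match="two visits"):
            exposure_days(visits((3, "active-eggs", 3, None)))
        with pytest.raises(ValueError, match="strictly increasing"):
            exposure_days(
                visits((5, "active-eggs", 3, None), (5, "active-eggs", 3, None))
            )


class TestSplitExposure:
    def test_additive_split_across_hatch(self):
        v = visits(
            (0, "active-eggs", 3, None),
            (3, "active-eggs", 3, None),
            (6, "active-nestlings", None, 3),
            (9, "active-nestlings", None, 3),
            (11, "depredated", None, None),
        )
        egg, nestling = split_exposure(v, hatch_day=6)
        assert egg == pytest.approx(6.0)
        assert nestling == pytest.approx(4.0)  # midpoint day 10
        assert egg + nestling == pytest.approx(exposure_days(v, hatch_day=6))

    def test_egg_stage_failure_has_zero_nestling_exposure(self):
        v = visits(
            (0, "active-eggs", 3, None),
            (3, "active-eggs", 3, None),
            (5, "depredated", None, None),
        )
        egg, nestling = split_exposure(v, hatch_day=None)
        assert (egg, nestling) == (4.0, 0.0)

    def test_found_at_nestling_stage_zero_egg_exposure(self):
        v = visits(
            (0, "active-nestlings", None, 3),
            (3, "active-nestlings", None, 3),
        )
        egg, nestling = split_exposure(v, hatch_day=0)
        assert egg == 0.0
        assert nestling == pytest.approx(3.0)

    def test_hatch_outside_window_is_error(self):
        v = visits((0, "active-eggs", 3, None), (3, "active-eggs", 3, None))
        with pytest.raises(ValueError, match="outside the monitored window"):
            split_exposure(v, hatch_day=99)


class TestClassifyOutcome:
    def fledge_history(self):
        return visits(
            (0, "active-eggs", 3, None),
            (3, "active-nestlings", None, 3),
            (6, "active-nestlings", None, 3),
            (10, "active-nestlings", None, 3),
            (13, "empty-intact", None, None),
        )

    def test_fledged_when_present_day7_and_empty_intact_day10(self):
        out = classify_outcome(self.fledge_history(), hatch_day=3)
        assert out.fledged and not out.failed
        assert out.n_fledged == 3

    def test_damaged_after_day7_means_failed(self):
        v = self.fledge_history()
        v.loc[v.index[-1], "status"] = "damaged"
        out = classify_outcome(v, hatch_day=3)
        assert out.failed and not out.fledged

    def test_empty_before_day7_means_failed(self):
        v = visits(
            (0, "active-nestlings", None, 3),
            (3, "active-nestlings", None, 3),
            (6, "empty-intact", None, None),
        )
        out = classify_outcome(v, hatch_day=0)
        assert out.failed

    def test_brood_reduction_flag(self):
        v = visits(
            (0, "active-nestlings", None, 4),
            (7, "active-nestlings", None, 3),
            (10, "empty-intact", None, None),
        )
        out = classify_outcome(v, hatch_day=0)
        assert out.fledged
        assert out.brood_reduced == 1.0
        assert out.n_fledged == 3

    def test_still_active_is_censored_unknown(self):
        v = visits(
            (0, "active-eggs", 3, None),
            (3, "active-eggs", 3, None),
        )
        out = classify_outcome(v)
        assert out.unknown and not out.failed and not out.fledged


class TestMayfield:
    def test_closed_forms(self):
        dsr, se = mayfield_dsr(1, 50)
        assert dsr == pytest.approx(0.98)
        assert period_survival(dsr, 21) == pytest.approx(0.98**21)
        assert 0.98**21 == pytest.approx(0.6543, abs=1e-4)
        dsr5, _ = mayfield_dsr(5, 100)
        assert dsr5 == pytest.approx(0.95)

    def test_zero_failures_boundary(self):
        dsr, se = mayfield_dsr(0, 80)
        assert dsr == 1.0 and se == 0.0

    def test_zero_exposure_is_error(self):
        with pytest.raises(ValueError):
            mayfield_dsr(0, 0)

    def test_period_survival_monotone(self):
        assert period_survival(0.98, 10) > period_survival(0.98, 20)
        assert period_survival(0.99, 10) > period_survival(0.95, 10)


class TestLogisticExposure:
    def simulate(self, rng, n=400, beta=(-3.0, 0.6), T=20):
        z = rng.normal(size=n)
        h = expit(beta[0] + beta[1] * z)
        # geometric failure day, censored at T days of observation
        day = rng.geometric(h)
        f = (day <= T).astype(float)
        t = np.minimum(day, T).astype(float)
        X = np.column_stack([np.ones(n), z])
        return f, t, X

    def test_intercept_only_reproduces_mayfield_exactly(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 60))
            t = rng.uniform(0.5, 25.0, n)
            f = (rng.random(n) < 0.3).astype(float)
            if f.sum() in (0, n):
                continue
            res = LogisticExposure(f, t, np.ones((n, 1))).fit()
            assert res.daily_failure()[0] == pytest.approx(
                f.sum() / t.sum(), abs=1e-10
            )
            dsr, _ = mayfield_dsr(f.sum(), t.sum())
            assert res.dsr()[0] == pytest.approx(dsr, abs=1e-10)

    def test_matches_statsmodels_glm_on_integer_trials(self, rng):
        f, t, X = self.simulate(rng)
        mine = LogisticExposure(f, t, X, exog_names=["const", "z"]).fit()
        glm = sm.GLM(
            np.column_stack([f, t - f]), X, family=sm.families.Binomial()
        ).fit()
        assert np.allclose(mine.params.to_numpy(), glm.params, atol=1e-6)
        assert np.allclose(mine.bse.to_numpy(), glm.bse, atol=1e-5)

    def test_loglik_matches_numeric_optimizer_oracle(self, rng):
        f, t, X = self.simulate(rng, n=120)
        mine = LogisticExposure(f, t, X).fit()

        def nll(b):
            h = expit(X @ b)
            return -(f @ np.log(h) + (t - f) @ np.log1p(-h))

        oracle = optimize.minimize(nll, np.zeros(2), method="Nelder-Mead",
                                   options={"xatol": 1e-10, "fatol": 1e-12})
        assert mine.llf == pytest.approx(-oracle.fun, abs=1e-6)

    def test_fractional_exposure_days_accepted(self):
        f = np.array([1.0, 0.0, 0.0])
        t = np.array([10.5, 7.5, 12.0])
        res = LogisticExposure(f, t, np.ones((3, 1))).fit()
        assert res.daily_failure()[0] == pytest.approx(1.0 / 30.0, abs=1e-10)

    def test_all_successes_raise_separation_warning(self):
        f = np.zeros(10)
        t = np.full(10, 12.0)
        with pytest.warns(SeparationWarning):
            res = LogisticExposure(f, t, np.ones((10, 1))).fit()
        assert res.penalized

    def test_parameter_recovery_quick(self, rng):
        """Coverage spot-check at a handful of replicates (full check in
        the acceptance suite)."""
        hits = 0
        reps = 20
        for _ in range(reps):
            f, t, X = self.simulate(rng, n=800, beta=(-3.5, 0.8), T=25)
            res = LogisticExposure(f, t, X).fit()
            ci = res.conf_int()
            ok = (
                ci.iloc[0, 0] <= -3.5 <= ci.iloc[0, 1]
                and ci.iloc[1, 0] <= 0.8 <= ci.iloc[1, 1]
            )
            hits += ok
        assert hits >= reps - 4

    def test_interval_likelihood_close_to_binomial_at_low_hazard(self, rng):
        f, t, X = self.simulate(rng, n=500, beta=(-4.0, 0.5))
        a = LogisticExposure(f, t, X).fit()
        b = LogisticExposure(f, t, X, likelihood="interval").fit()
        assert np.allclose(a.params, b.params, atol=0.15)

    def test_random_intercept_shrinks_toward_pooled_when_no_heterogeneity(self, rng):
        f, t, X = self.simulate(rng, n=300)
        g = np.repeat(np.arange(30), 10)
        pooled = LogisticExposure(f, t, X).fit()
        mixed = LogisticExposure(f, t, X, groups={"farm": g}).fit()
        assert np.allclose(pooled.params, mixed.params, atol=0.1)
        assert mixed.vcomp.iloc[0] < 0.5


class TestSummarizeExposures:
    def test_round_trip_over_a_small_table(self):
        v = pd.concat(
            [
                visits(
                    (0, "active-eggs", 3, None),
                    (3, "active-nestlings", None, 3),
                    (10, "active-nestlings", None, 3),
                    (13, "empty-intact", None, None),
                ).assign(nest_id="n1"),
                visits(
                    (5, "active-eggs", 4, None),
                    (8, "depredated", None, None),
                ).assign(nest_id="n2"),
            ]
        )
        out = summarize_exposures(v, hatch_days={"n1": 3, "n2": None}).set_index(
            "nest_id"
        )
        assert out.loc["n1", "fledged"] == 1
        assert out.loc["n1", "egg_exposure"] + out.loc["n1", "nestling_exposure"] == (
            pytest.approx(10.0)
        )
        assert out.loc["n2", "egg_failed"] == 1
        assert out.loc["n2", "egg_exposure"] == pytest.approx(1.5)
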