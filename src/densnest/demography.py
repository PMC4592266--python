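"""Two-age-class demographic projection for a multi-brooded passerine.

Converts per-nest productivity and annual survival into the number of
young produced per ``n_pairs`` breeding pairs and the implied annual
percentage change of the adult population.  The accounting treats
``n_pairs`` pairs as ``2 * n_pairs`` adults, both sexes surviving at the
same adult rate, with fledged young recruiting at the juvenile rate and
no density dependence, immigration or sex-ratio adjustment:

    successful nests / pair = renest_rate * nest_success
    young produced          = n_pairs * successful nests/pair * young/successful nest
    adults next year        = 2 * n_pairs * S_ad + young * S_juv
    annual change (%)       = 100 * (adults next year - 2 n_pairs) / (2 n_pairs)

All arithmetic is at full float precision; rounding to one decimal is a
presentation choice left to the caller (``summary`` rounds).
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["DemographicParams", "DemographicResult", "DemographicProjection", "project"]


@dataclass(frozen=True)
class DemographicParams:
    """Inputs of the projection.

    renest_rate is nesting attempts per pair per season; nest_success the
    probability an attempt fledges at least one young;
    young_per_successful_nest the mean brood fledged from a successful
    attempt; survival rates are annual probabilities.
    """

    renest_rate: float
    nest_success: float
    young_per_successful_nest: float
    adult_survival: float
    juvenile_survival: float
    n_pairs: int = 100

    def __post_init__(self) -> None:
        for name in ("nest_success", "adult_survival", "juvenile_survival"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        for name in ("renest_rate", "young_per_successful_nest"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_pairs <= 0:
            raise ValueError("n_pairs must be positive")


@dataclass(frozen=True)
class DemographicResult:
    """Projection outputs; ``annual_change_pct`` is bounded below by -100."""

    params: DemographicParams
    successful_nests_per_pair: float
    young_total: float
    adults_next_year: float
    annual_change_pct: float

    def summary(self) -> pd.Series:
        """One-row presentation of the projection, rounded to 1 decimal
        (successful nests per pair to 3, matching field convention)."""
        return pd.Series(
            {
                "n_pairs": self.params.n_pairs,
                "successful_nests_per_pair": round(self.successful_nests_per_pair, 3),
                "young_total": round(self.young_total, 1),
                "adults_next_year": round(self.adults_next_year, 1),
                "annual_change_pct": round(self.annual_change_pct, 1),
            }
        )


class DemographicProjection:
    """Deterministic projection model built from :class:`DemographicParams`."""

    def __init__(self, params: DemographicParams):
        self.params = params

    @classmethod
    def from_rates(cls, **kwargs) -> "DemographicProjection":
        return cls(DemographicParams(**kwargs))

    def project(self) -> DemographicResult:
        p = self.params
        spp = p.renest_rate * p.nest_success
        young = p.n_pairs * spp * p.young_per_successful_nest
        adults0 = 2.0 * p.n_pairs
        adults1 = adults0 * p.adult_survival + young * p.juvenile_survival
        change = 100.0 * (adults1 - adults0) / adults0
        return DemographicResult(p, spp, young, adults1, change)

    # alias so the object quacks like the other Model classes
    fit = project

    def sensitivity(self, vary: str, grid: Iterable[float]) -> pd.DataFrame:
        """Re-project over a grid of one parameter.

        Returns a DataFrame with the varied value and every output column;
        each output is monotone in each single input, so a sorted grid
        yields sorted outputs.
        """
        valid = {f.name for f in fields(DemographicParams)}
        if vary not in valid:
            raise ValueError(f"unknown parameter {vary!r}; one of {sorted(valid)}")
        rows = []
        for v in grid:
            res = DemographicProjection(replace(self.params, **{vary: v})).project()
            rows.append(
                {
                    vary: v,
                    "successful_nests_per_pair": res.successful_nests_per_pair,
                    "young_total": res.young_total,
                    "adults_next_year": res.adults_next_year,
                    "annual_change_pct": res.annual_change_pct,
                }
            )
        return pd.DataFrame(rows)


def project(params: DemographicParams) -> DemographicResult:
    """Functional shorthand for ``DemographicProjection(params).project()``."""
    return DemographicProjection(params).project()
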