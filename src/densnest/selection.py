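"""Multimodel inference: AICc ranking, all-subsets search, averaging.

A global model is declared as a :class:`ModelSpec` — response, family,
term list (main effects, ``A^2`` quadratics, ``A:B`` interactions),
locked terms that every candidate must keep, and random-intercept
grouping columns.  :func:`dredge` enumerates every submodel that
respects marginality (a quadratic or interaction enters only with its
parents present), fits each by ML, and ranks them by the small-sample
Akaike criterion

    AICc = -2 logL + 2k + 2k(k+1) / (n - k - 1).

Models within ``delta`` (default 2) AICc units of the best form the top
set; :func:`average_top_set` renormalises their Akaike weights and
averages coefficients across them.  The default is conditional (subset)
averaging — each term averaged over the models that contain it — with
unconditional standard errors combining within- and between-model
variance (SE = sum w_i sqrt(SE_i^2 + (b_i - b_bar)^2)).  Full-model
(zero-substitution) averaging is available via ``method="full"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd

from .glmm import CumulativeLogit, MixedModel, MixedModelResults, r2_nakagawa

__all__ = [
    "ModelSpec",
    "aicc",
    "akaike_weights",
    "build_design",
    "fit_spec",
    "dredge",
    "DredgeResults",
    "ModelAverage",
    "average_top_set",
]

Z_95 = 1.96  # conventional Wald multiplier for 95% intervals


def aicc(llf: float, k: int, n: int) -> float:
    """Second-order Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined: need n > k + 1 (n={n}, k={k})")
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights exp(-delta/2) normalised to sum to one."""
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


@dataclass(frozen=True)
class ModelSpec:
    """Declaration of one candidate (or global) model.

    Terms are column names of the data table, optionally ``A^2`` for the
    square of centred ``A`` or ``A:B`` for a product interaction.
    Categorical (non-numeric) columns are dummy-coded against their
    first level.  ``locked`` terms appear in every candidate during a
    dredge; ``groups`` are random-intercept grouping columns.
    """

    response: str
    family: str
    terms: tuple = ()
    locked: tuple = ()
    groups: tuple = ()
    exposure: str | None = None  # exposure-days column (binomial-exposure)

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))
        object.__setattr__(self, "locked", tuple(self.locked))
        object.__setattr__(self, "groups", tuple(self.groups))
        missing = set(self.locked) - set(self.terms)
        if missing:
            raise ValueError(f"locked terms not among terms: {sorted(missing)}")
        for t in self.terms:
            for p in term_parents(t):
                if p not in self.terms:
                    raise ValueError(
                        f"term {t!r} requires its parent {p!r} among the terms"
                    )

    def with_terms(self, terms) -> "ModelSpec":
        return replace(self, terms=tuple(terms))


def term_parents(term: str) -> tuple:
    """Marginality parents of a term ('' main effects have none)."""
    if term.endswith("^2"):
        return (term[:-2],)
    if ":" in term:
        return tuple(term.split(":"))
    return ()


def _encode_column(data: pd.DataFrame, name: str):
    """Numeric column as-is; categorical dummy-coded (first level ref)."""
    col = data[name]
    if pd.api.types.is_numeric_dtype(col) and not isinstance(
        col.dtype, pd.CategoricalDtype
    ):
        return {name: col.to_numpy(dtype=float)}
    codes, levels = pd.factorize(col, sort=True)
    if (codes < 0).any():
        raise ValueError(f"column {name!r} contains missing values")
    out = {}
    for j, lev in enumerate(levels[1:], start=1):
        out[f"{name} ({lev})"] = (codes == j).astype(float)
    return out


def build_design(
    data: pd.DataFrame, terms, add_intercept: bool = True
) -> tuple[np.ndarray, list, dict]:
    """Design matrix for a term list.

    Returns ``(X, column_names, term_of_column)``.  Quadratic terms
    square the mean-centred parent; interactions multiply the encoded
    parent columns (all pairs when a parent is categorical).
    """
    cols: dict[str, np.ndarray] = {}
    term_of: dict[str, str] = {}
    if add_intercept:
        cols["Intercept"] = np.ones(len(data))
        term_of["Intercept"] = "Intercept"

    def encoded(name):
        return _encode_column(data, name)

    for term in terms:
        if term.endswith("^2"):
            parent = term[:-2]
            x = data[parent].to_numpy(dtype=float)
            cols[term] = (x - x.mean()) ** 2
            term_of[term] = term
        elif ":" in term:
            a, b = term.split(":")
            for na, xa in encoded(a).items():
                for nb, xb in encoded(b).items():
                    cname = f"{na}:{nb}"
                    cols[cname] = xa * xb
                    term_of[cname] = term
        else:
            for cname, x in encoded(term).items():
                cols[cname] = x
                term_of[cname] = term
    names = list(cols)
    X = np.column_stack([cols[c] for c in names]) if names else np.empty((len(data), 0))
    return X, names, term_of


def _drop_aliased(X, names, term_of):
    """Greedily drop columns that make the design rank deficient."""
    keep, dropped = [], []
    for j in range(X.shape[1]):
        trial = keep + [j]
        if np.linalg.matrix_rank(X[:, trial]) == len(trial):
            keep.append(j)
        else:
            dropped.append(names[j])
    if dropped:
        import warnings

        warnings.warn(f"dropping aliased design columns: {dropped}")
    names2 = [names[j] for j in keep]
    return X[:, keep], names2, {n: term_of[n] for n in names2}


def fit_spec(spec: ModelSpec, data: pd.DataFrame, drop_aliased=False):
    """Fit one ModelSpec by ML; returns (MixedModelResults, term_of_column)."""
    fam = spec.family
    ordinal = fam == "ordinal-cumulative-logit"
    X, names, term_of = build_design(data, spec.terms, add_intercept=not ordinal)
    if drop_aliased:
        X, names, term_of = _drop_aliased(X, names, term_of)
    if fam == "binomial-exposure":
        if spec.exposure is None:
            raise ValueError("binomial-exposure spec needs an exposure column")
        endog = np.column_stack(
            [
                data[spec.response].to_numpy(dtype=float),
                data[spec.exposure].to_numpy(dtype=float),
            ]
        )
        family = "binomial-exposure"
    elif ordinal:
        y = data[spec.response].to_numpy()
        levels = np.unique(y)
        if len(levels) < 2:
            raise ValueError("ordinal response has fewer than 2 observed levels")
        endog = np.searchsorted(levels, y).astype(float)
        family = CumulativeLogit(len(levels))
    else:
        endog = data[spec.response].to_numpy(dtype=float)
        family = fam
    groups = {g: data[g].to_numpy() for g in spec.groups} or None
    model = MixedModel(endog, X, family, groups=groups, exog_names=names)
    return model.fit(), term_of


def admissible_subsets(free_terms, locked=()):
    """All subsets of ``free_terms`` respecting marginality given ``locked``."""
    free = list(free_terms)
    base = set(locked)
    out = []
    for r in range(len(free) + 1):
        for comb in combinations(free, r):
            present = base | set(comb)
            if all(
                all(p in present for p in term_parents(t)) for t in comb
            ):
                out.append(tuple(comb))
    return out


class DredgeResults:
    """Ranked candidate set from an all-subsets search."""

    def __init__(self, spec, table: pd.DataFrame, fits: list, term_of: dict):
        self.spec = spec
        self.table = table
        self.fits = fits  # MixedModelResults, aligned with table rows
        self.term_of = term_of

    @property
    def best(self) -> MixedModelResults:
        return self.fits[0]

    def r2(self):
        """Marginal/conditional R2 of the top-ranked model (pre-averaging)."""
        return r2_nakagawa(self.best)

    def average(self, delta: float = 2.0, method: str = "conditional"):
        return average_top_set(self, delta=delta, method=method)


def dredge(
    spec: ModelSpec,
    data: pd.DataFrame,
    max_free_terms: int = 20,
    override_guard: bool = False,
) -> DredgeResults:
    """Fit every admissible submodel of a global model and rank by AICc."""
    free = [t for t in spec.terms if t not in spec.locked]
    if len(free) > max_free_terms and not override_guard:
        raise ValueError(
            f"{len(free)} free terms would need {2 ** len(free)}+ fits; "
            "pass override_guard=True to proceed"
        )
    _, _, term_of_global = build_design(
        data, spec.terms, add_intercept=spec.family != "ordinal-cumulative-logit"
    )
    rows, fits = [], []
    for subset in admissible_subsets(free, spec.locked):
        terms = tuple(t for t in spec.terms if t in spec.locked or t in subset)
        sub = spec.with_terms(terms)
        res, _ = fit_spec(sub, data)
        rows.append(
            {
                "terms": terms,
                "k": res.k_params,
                "llf": res.llf,
                "aicc": aicc(res.llf, res.k_params, res.nobs),
            }
        )
        fits.append(res)
    table = pd.DataFrame(rows)
    order = np.lexsort((table.index, table["aicc"].to_numpy()))
    table = table.iloc[order].reset_index(drop=True)
    fits = [fits[i] for i in order]
    table["delta_aicc"] = table["aicc"] - table["aicc"].iloc[0]
    table["weight"] = akaike_weights(table["aicc"].to_numpy())
    return DredgeResults(spec, table, fits, term_of_global)


class ModelAverage:
    """Averaged coefficients over a top model set."""

    def __init__(self, table: pd.DataFrame, model_table: pd.DataFrame, delta, method):
        self.table = table
        self.model_table = model_table
        self.delta = delta
        self.method = method

    def summary(self) -> pd.DataFrame:
        return self.table.copy()

    def __repr__(self):
        return (
            f"<ModelAverage: {len(self.model_table)} models (delta AICc < "
            f"{self.delta}), {self.method} averaging>\n{self.table}"
        )


def average_top_set(
    dredge_results: DredgeResults, delta: float = 2.0, method: str = "conditional"
) -> ModelAverage:
    """Average coefficients over the models with delta AICc strictly < ``delta``.

    Conditional averaging (default) averages each coefficient over the
    top-set models containing it, with weights renormalised within that
    subset; full averaging substitutes zero where a model omits the
    coefficient.  Standard errors use the unconditional form combining
    within-model sampling variance and between-model spread; confidence
    intervals are Wald, estimate +/- 1.96 SE.
    """
    if method not in ("conditional", "full"):
        raise ValueError("method must be 'conditional' or 'full'")
    tab = dredge_results.table
    mask = (tab["delta_aicc"] < delta).to_numpy()
    top = tab.loc[mask].reset_index(drop=True)
    fits = [f for f, m in zip(dredge_results.fits, mask) if m]
    w = top["weight"].to_numpy()
    w = w / w.sum()

    # collect coefficient names in first-appearance order across the set
    coef_names: list[str] = []
    for f in fits:
        for n in f.params.index:
            if n not in coef_names:
                coef_names.append(n)

    rows = []
    for name in coef_names:
        present = np.array([name in f.params.index for f in fits])
        betas = np.array(
            [f.params[name] if name in f.params.index else 0.0 for f in fits]
        )
        ses = np.array([f.bse[name] if name in f.params.index else 0.0 for f in fits])
        if method == "conditional":
            wi = w[present] / w[present].sum()
            b, s = betas[present], ses[present]
        else:
            wi, b, s = w, betas, ses
        est = float(wi @ b)
        se = float(wi @ np.sqrt(s**2 + (b - est) ** 2))
        rows.append(
            {
                "term": name,
                "n_models": int(present.sum()),
                "estimate": est,
                "se": se,
                "lower_ci": est - Z_95 * se,
                "upper_ci": est + Z_95 * se,
            }
        )
    columns = ["term", "n_models", "estimate", "se", "lower_ci", "upper_ci"]
    out = pd.DataFrame(rows, columns=columns).set_index("term")
    out["significant"] = (out["lower_ci"] > 0) | (out["upper_ci"] < 0)
    model_table = top[["terms", "k", "llf", "aicc", "delta_aicc"]].copy()
    model_table["weight"] = w
    return ModelAverage(out, model_table, delta, method)
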