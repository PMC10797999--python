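"""Response-surface modeling and Factor's Contribution rankings.

Per strain and measure a full quadratic response surface is fitted by ordinary
least squares on the coded factors: intercept, main effects for every factor,
quadratic terms for the numeric factors, and all two-factor interactions.
The ANOVA partition uses Type II (partial) sums of squares — each term is
judged against the model containing every term that does not include it —
which on this balanced design coincides with sequential SS for the main
effects and is the convention of standard DoE software.

The Factor's Contribution table condenses the partition into one percentage
per experimental variable (a numeric factor pools its linear and quadratic
SS), expressed relative to the total model SS.  Interaction terms stay in the
denominator but are not displayed, so the displayed percentages can sum to
less than 100 when interactions carry signal.  Each variable gets a direction
sign (+ means the response rises toward the +1 level / with increasing numeric
factor, from the linear or main coefficient) and a significance flag.
Contribution tables of a TF strain can be normalized against the control's as
percentage-point deltas.

Two modeling modes are supported: ``raw`` (per-culture responses over the
replicated run plan) and ``fc`` (one fold-change value per condition variant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import Factor
from .errors import ModelError

__all__ = [
    "RSMFit",
    "term_names",
    "build_model_matrix",
    "fit_rsm",
    "type2_anova",
    "factor_contribution",
    "contribution_delta",
    "signed_level_contribution",
    "predict_grid",
]

ALPHA = 0.05


def term_names(factors: list[Factor], interactions: bool = True) -> list[str]:
    """Model terms in canonical order: intercept, mains, quadratics, interactions."""
    names = ["1"] + [f.name for f in factors]
    names += [f"{f.name}^2" for f in factors if f.kind == "numeric"]
    if interactions:
        for i, a in enumerate(factors):
            for b in factors[i + 1:]:
                names.append(f"{a.name}:{b.name}")
    return names


def _term_column(term: str, coded: pd.DataFrame) -> np.ndarray:
    if term == "1":
        return np.ones(len(coded))
    if term.endswith("^2"):
        return coded[term[:-2]].to_numpy() ** 2
    if ":" in term:
        a, b = term.split(":")
        return coded[a].to_numpy() * coded[b].to_numpy()
    return coded[term].to_numpy()


def build_model_matrix(coded: pd.DataFrame, terms: list[str]) -> np.ndarray:
    """Assemble the design matrix column-by-column for the given term list."""
    return np.column_stack([_term_column(t, coded) for t in terms])


def _term_factors(term: str) -> frozenset[str]:
    if term == "1":
        return frozenset()
    if ":" in term:
        return frozenset(term.split(":"))
    if term.endswith("^2"):
        return frozenset([term])  # quadratic treated as its own factor
    return frozenset([term])


@dataclass
class RSMFit:
    """A fitted response surface with its ANOVA partition.

    ``anova`` has one row per non-intercept term: sum_sq, df, F, p.  The model
    SS recorded here is the regression SS from the OLS fit; ``ss_terms`` is
    the Type II partition used by the contribution tables.
    """

    strain: str
    measure: str
    mode: str  # "raw" | "fc"
    terms: list[str]
    coefficients: pd.Series
    anova: pd.DataFrame
    ss_model: float
    ss_resid: float
    ss_total: float
    df_resid: int
    f_model: float
    p_model: float
    r2: float
    factors: list[Factor]

    def predict(self, coded: pd.DataFrame) -> np.ndarray:
        X = build_model_matrix(coded, self.terms)
        return X @ self.coefficients.to_numpy()


def type2_anova(y: np.ndarray, coded: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Type II (partial) sum of squares per non-intercept term.

    SS(term) = RSS(model without the term and without any term containing it)
             - RSS(that model plus the term); every term here is single-df, so
    F = SS / (RSS_full / df_resid).
    """
    X = build_model_matrix(coded, terms)
    n, p = X.shape
    rss_full = _rss(X, y)
    df_resid = n - p
    if df_resid <= 0:
        raise ModelError("no residual degrees of freedom for the full model")
    mse = rss_full / df_resid

    rows = []
    for term in terms:
        if term == "1":
            continue
        fac = _term_factors(term)
        keep = [t for t in terms if t != term and not (_term_factors(t) > fac)]
        base = [t for t in keep if t != term]
        with_t = base + [term]
        ss = _rss(build_model_matrix(coded, base), y) - _rss(build_model_matrix(coded, with_t), y)
        ss = max(ss, 0.0)
        f = ss / mse if mse > 0 else np.inf if ss > 0 else np.nan
        p_val = float(stats.f.sf(f, 1, df_resid)) if np.isfinite(f) else np.nan
        rows.append((term, ss, 1, f, p_val))
    return pd.DataFrame(rows, columns=["term", "sum_sq", "df", "F", "p"]).set_index("term")


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    return float(resid @ resid)


def fit_rsm(
    data: pd.DataFrame,
    response: str,
    factors: list[Factor],
    mode: str = "raw",
    strain: str = "",
    measure: str = "",
    interactions: bool = True,
) -> RSMFit:
    """Fit the full quadratic response surface by OLS on coded factors.

    ``data`` must carry one ``coded_<factor>`` column per factor and the
    ``response`` column (raw per-culture values in ``raw`` mode, one FC per
    variant in ``fc`` mode).  Raises on a rank-deficient design, naming the
    aliased terms.
    """
    if mode not in ("raw", "fc"):
        raise ModelError(f"unknown mode {mode!r}")
    coded = data[[f"coded_{f.name}" for f in factors]].copy()
    coded.columns = [f.name for f in factors]
    y = data[response].to_numpy(dtype=float)

    terms = term_names(factors, interactions=interactions)
    X = build_model_matrix(coded, terms)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = _aliased_terms(X, terms)
        raise ModelError(f"rank-deficient design: aliased terms {aliased}")
    if X.shape[0] - X.shape[1] < 1:
        raise ModelError("no residual degrees of freedom for the full model")

    with np.errstate(divide="ignore", invalid="ignore"):
        res = sm.OLS(y, X).fit()
        r2 = float(res.rsquared) if res.centered_tss > 0 else 0.0
        f_model, p_model = float(res.fvalue), float(res.f_pvalue)
    anova = type2_anova(y, coded, terms)
    return RSMFit(
        strain=strain,
        measure=measure,
        mode=mode,
        terms=terms,
        coefficients=pd.Series(res.params, index=terms),
        anova=anova,
        ss_model=float(res.ess),
        ss_resid=float(res.ssr),
        ss_total=float(res.centered_tss),
        df_resid=int(res.df_resid),
        f_model=f_model,
        p_model=p_model,
        r2=r2,
        factors=list(factors),
    )


def _aliased_terms(X: np.ndarray, terms: list[str]) -> list[str]:
    """Terms whose column adds no rank beyond the preceding columns."""
    aliased, cols = [], []
    for j, t in enumerate(terms):
        trial = np.column_stack(cols + [X[:, j]]) if cols else X[:, [j]]
        if np.linalg.matrix_rank(trial) == len(cols):
            aliased.append(t)
        else:
            cols.append(X[:, j])
    return aliased


def factor_contribution(fit: RSMFit, alpha: float = ALPHA) -> pd.DataFrame:
    """Percentage Factor's Contribution per experimental variable.

    percent = 100 * SS(variable) / SS(all model terms), where a numeric
    variable pools its linear and quadratic Type II SS and interactions enter
    only the denominator.  direction is '+' when the linear/main coefficient
    is positive (response rises toward the +1 level), '-' otherwise;
    significant when any pooled term has p < alpha.  If the model carries no
    signal at all (SS = 0) every percentage is zero.
    """
    ss_all = float(fit.anova["sum_sq"].sum())
    rows = []
    for f in fit.factors:
        pooled = [f.name] + ([f"{f.name}^2"] if f.kind == "numeric" else [])
        ss = float(fit.anova.loc[pooled, "sum_sq"].sum())
        percent = 100.0 * ss / ss_all if ss_all > 0 else 0.0
        coef = float(fit.coefficients[f.name])
        pvals = fit.anova.loc[pooled, "p"]
        rows.append({
            "factor": f.name,
            "percent": percent,
            "direction": "+" if coef >= 0 else "-",
            "significant": bool((pvals < alpha).any()),
        })
    table = pd.DataFrame(rows).set_index("factor")
    if ss_all == 0:
        warnings.warn("model sum of squares is zero; contribution table is all-zero")
    return table


def contribution_delta(tf_table: pd.DataFrame, control_table: pd.DataFrame) -> pd.DataFrame:
    """Control-normalized contributions: TF percent minus control percent,
    in percentage points, carrying the TF strain's direction label."""
    if list(tf_table.index) != list(control_table.index):
        raise ModelError("contribution tables cover different factor sets")
    out = tf_table.copy()
    out["delta_vs_control"] = tf_table["percent"] - control_table["percent"]
    return out


def signed_level_contribution(table: pd.DataFrame, factor: str, toward: int = -1) -> float:
    """Contribution percentage signed toward one level of a variable.

    Positive when the variable's effect pushes the response up at the given
    coded level (e.g. ``toward=-1`` for low oxygen availability): a '-'
    direction means the response is higher at the -1 level.
    """
    row = table.loc[factor]
    sign = 1.0 if row["direction"] == "+" else -1.0
    return float(row["percent"] * sign * (1.0 if toward > 0 else -1.0))


def predict_grid(
    fit: RSMFit,
    numeric_grid: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Evaluate the fitted surface over every categoric panel x numeric grid.

    Defaults to the three coded levels (-1, 0, +1) per numeric factor, giving
    the 8-panel x 3x3 layout of the heat maps.  Grid values must lie inside
    the coded faces [-1, +1]; the model is not extrapolated.
    """
    import itertools

    numeric = [f for f in fit.factors if f.kind == "numeric"]
    categoric = [f for f in fit.factors if f.kind == "categoric"]
    grid = numeric_grid or {f.name: np.array([-1.0, 0.0, 1.0]) for f in numeric}
    for name, vals in grid.items():
        arr = np.asarray(vals, dtype=float)
        if (arr < -1).any() or (arr > 1).any():
            raise ModelError(f"grid for {name!r} extrapolates beyond the coded faces")

    panels = list(itertools.product((-1.0, 1.0), repeat=len(categoric))) or [()]
    rows = []
    for panel in panels:
        for combo in itertools.product(*(grid[f.name] for f in numeric)):
            row = {f"coded_{f.name}": lvl for f, lvl in zip(categoric, panel)}
            row.update({f"coded_{f.name}": v for f, v in zip(numeric, combo)})
            rows.append(row)
    frame = pd.DataFrame(rows)
    coded = frame.copy()
    coded.columns = [c.removeprefix("coded_") for c in frame.columns]
    frame["predicted"] = build_model_matrix(coded, fit.terms) @ fit.coefficients.to_numpy()
    return frame
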