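"""Baseline comparison and survival modelling for the ICD cohort.

Continuous baseline variables are compared with the Mann-Whitney U test,
categorical ones with Pearson's chi-square (no continuity correction);
predictors are screened with univariable Cox regression and carried into
one joint multivariable Cox model when their univariable p-value is below
0.100 (ENTER selection: all retained covariates are entered
simultaneously, no stepwise add/remove).  Multicollinearity is gauged by
variance inflation factors.  All p-values are two-sided; Cox fits use
Efron tie handling with Wald confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats as sct

from .errors import (
    DegenerateTableError,
    EmptyModelError,
    InestimableError,
    InvalidParameterError,
)

SCREEN_ALPHA = 0.100


@dataclass(frozen=True)
class BaselineRow:
    """One line of the baseline characteristics table."""

    variable: str
    group_a: str        # summary, e.g. "62.9 +/- 10.6" or "185 (26.3%)"
    group_b: str
    test: str           # "mann-whitney" | "chi2"
    p_value: float
    n_a: int            # per-variable complete-case denominators
    n_b: int


@dataclass(frozen=True)
class CoxResult:
    """Hazard ratio with Wald 95% CI and p-value for one covariate term."""

    covariate: str
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    model: str          # "univariable" | "multivariable"
    endpoint: str
    n_events: int

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.hazard_ratio <= self.ci_upper):
            raise ValueError("CI must bracket the hazard ratio")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be positive")


def chi_square_2x2(
    a_events: int, a_total: int, b_events: int, b_total: int
) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction, 1 df."""
    if min(a_events, b_events) < 0 or a_events > a_total or b_events > b_total:
        raise InvalidParameterError("events must satisfy 0 <= events <= total")
    if a_total <= 0 or b_total <= 0:
        raise InvalidParameterError("group totals must be positive")
    table = np.array(
        [[a_events, a_total - a_events], [b_events, b_total - b_events]]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError("contingency table has a zero margin")
    res = sct.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact null distribution when the combined
    sample is below 20, otherwise the tie-corrected normal approximation."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidParameterError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if combined.size < 20 and not has_ties else "asymptotic"
    res = sct.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _expand_categorical(
    df: pd.DataFrame, covariate: str
) -> tuple[pd.DataFrame, list[str]]:
    """Dummy-code a categorical column against its lowest level (reference)."""
    levels = np.sort(df[covariate].unique())
    cols = []
    out = df.drop(columns=[covariate]).copy()
    for lv in levels[1:]:
        name = f"{covariate}_{lv:g}" if isinstance(lv, float) else f"{covariate}_{lv}"
        out[name] = (df[covariate] == lv).astype(float)
        cols.append(name)
    return out, cols


def _fit_cox(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariate_cols: list[str],
    allow_ridge_fallback: bool = False,
) -> CoxPHFitter:
    from lifelines.exceptions import ConvergenceError

    data = df[[duration_col, event_col, *covariate_cols]].dropna()
    n_events = int(data[event_col].sum())
    if n_events == 0:
        raise InestimableError("no events observed")
    for c in covariate_cols:
        if data[c].nunique() < 2:
            raise InestimableError(f"covariate {c} is constant")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph = CoxPHFitter()
            cph.fit(data, duration_col=duration_col, event_col=event_col)
            return cph
        except ConvergenceError as exc:
            if not allow_ridge_fallback:
                raise InestimableError(
                    f"Cox fit did not converge: {exc}"
                ) from exc
            # near-separated sparse indicator: stabilise with a weak ridge
            cph = CoxPHFitter(penalizer=0.1, l1_ratio=0.0)
            try:
                cph.fit(data, duration_col=duration_col, event_col=event_col)
            except ConvergenceError as exc2:  # pragma: no cover - defensive
                raise InestimableError(
                    f"Cox fit did not converge even with ridge: {exc2}"
                ) from exc2
            return cph


def cox_univariable(
    df: pd.DataFrame,
    covariate: str,
    duration_col: str,
    event_col: str,
    endpoint: str = "",
    categorical: bool = False,
) -> list[CoxResult]:
    """Single-covariate proportional-hazards fit.

    Categorical covariates are expanded against their lowest level and
    return one result row per non-reference level.  Requires at least 10
    events.
    """
    if int(df[event_col].sum()) < 10:
        raise InestimableError("fewer than 10 events")
    work, cols = (
        _expand_categorical(df, covariate) if categorical else (df, [covariate])
    )
    cph = _fit_cox(work, duration_col, event_col, cols)
    return _results_from_fit(cph, cols, "univariable", endpoint)


def _results_from_fit(
    cph: CoxPHFitter, cols: list[str], model: str, endpoint: str
) -> list[CoxResult]:
    s = cph.summary
    out = []
    for c in cols:
        out.append(
            CoxResult(
                covariate=c,
                hazard_ratio=float(s.loc[c, "exp(coef)"]),
                ci_lower=float(s.loc[c, "exp(coef) lower 95%"]),
                ci_upper=float(s.loc[c, "exp(coef) upper 95%"]),
                p_value=float(s.loc[c, "p"]),
                model=model,
                endpoint=endpoint,
                n_events=int(cph.event_observed.sum()),
            )
        )
    return out


def _block_p_value(
    df: pd.DataFrame, duration_col: str, event_col: str, cols: list[str]
) -> float:
    """Likelihood-ratio p for a block of terms (used to screen categoricals)."""
    full = _fit_cox(df, duration_col, event_col, cols)
    return float(full.log_likelihood_ratio_test().p_value)


def cox_multivariable_enter(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    candidates: list[str],
    screen_alpha: float = SCREEN_ALPHA,
    endpoint: str = "",
    categorical: tuple[str, ...] = ("nyha",),
    force_include: tuple[str, ...] = (),
) -> list[CoxResult]:
    """Univariable screening at ``screen_alpha`` followed by one joint fit.

    All covariates passing the screen are entered simultaneously (ENTER
    method); categorical candidates are screened by a likelihood-ratio
    block test and expanded against their lowest (reference) level.
    Covariates in ``force_include`` enter the joint model regardless of
    their univariable p-value (the exposure of interest is always
    reported).  A warning is issued when fewer than 10 events per
    retained covariate are available.
    """
    retained_cols: list[str] = []
    work = df.copy()
    for cand in candidates:
        if cand in force_include:
            continue
        if cand in categorical:
            expanded, cols = _expand_categorical(df, cand)
            try:
                p = _block_p_value(expanded, duration_col, event_col, cols)
            except InestimableError:
                continue
            if p < screen_alpha:
                for c in cols:
                    work[c] = expanded[c]
                retained_cols.extend(cols)
        else:
            try:
                res = cox_univariable(
                    df, cand, duration_col, event_col, endpoint=endpoint
                )
            except InestimableError:
                continue
            if res[0].p_value < screen_alpha:
                retained_cols.append(cand)
    for cand in force_include:
        if cand not in retained_cols:
            retained_cols.append(cand)
    if not retained_cols:
        raise EmptyModelError(
            f"no candidate passed univariable screening at p < {screen_alpha}"
        )
    n_events = int(work[event_col].sum())
    if n_events < 10 * len(retained_cols):
        warnings.warn(
            f"only {n_events} events for {len(retained_cols)} covariates",
            stacklevel=2,
        )
    cph = _fit_cox(
        work, duration_col, event_col, retained_cols, allow_ridge_fallback=True
    )
    return _results_from_fit(cph, retained_cols, "multivariable", endpoint)


def compute_vif(X) -> pd.Series:
    """Variance inflation factor per column: 1 / (1 - R^2) from regressing
    each covariate on all others (with intercept).  Perfect collinearity is
    flagged as ``inf`` rather than raised."""
    X = pd.DataFrame(X)
    n, p = X.shape
    if n <= p:
        raise InvalidParameterError("need more rows than covariates")
    vals = X.to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(X.columns):
        y = vals[:, j]
        if np.std(y) < 1e-12:
            raise InvalidParameterError(f"column {name} is constant")
        others = np.delete(vals, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 > 1.0 - 1e-10 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def baseline_table(
    df: pd.DataFrame,
    group_col: str,
    continuous: list[str],
    categorical: list[str],
) -> list[BaselineRow]:
    """Mean +/- SD with Mann-Whitney p for continuous variables and n (%)
    with chi-square p for categorical ones, complete-case per variable.
    Group A is ``group_col == 0``; group B is ``group_col == 1``."""
    ga = df[df[group_col] == 0]
    gb = df[df[group_col] == 1]
    if len(ga) == 0 or len(gb) == 0:
        raise InvalidParameterError("both comparison groups must be non-empty")
    rows: list[BaselineRow] = []
    for var in continuous:
        a = ga[var].dropna()
        b = gb[var].dropna()
        _, p = mann_whitney(a, b)
        rows.append(
            BaselineRow(
                variable=var,
                group_a=f"{a.mean():.1f} +/- {a.std():.1f}",
                group_b=f"{b.mean():.1f} +/- {b.std():.1f}",
                test="mann-whitney",
                p_value=p,
                n_a=len(a),
                n_b=len(b),
            )
        )
    for var in categorical:
        a = ga[var].dropna()
        b = gb[var].dropna()
        ea, eb = int(a.sum()), int(b.sum())
        _, p = chi_square_2x2(ea, len(a), eb, len(b))
        rows.append(
            BaselineRow(
                variable=var,
                group_a=f"{ea} ({100 * ea / len(a):.1f}%)",
                group_b=f"{eb} ({100 * eb / len(b):.1f}%)",
                test="chi2",
                p_value=p,
                n_a=len(a),
                n_b=len(b),
            )
        )
    return rows
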