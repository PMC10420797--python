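"""Association analyses: stepwise regression with collinearity screening,
stepwise binary logistic regression with goodness-of-fit diagnostics, and
tertile ANCOVA with eta-squared effect sizes.

The three procedures mirror a conventional SPSS-style workflow:

* forward **stepwise OLS** — at each step the candidate with the smallest
  t-test p-value enters if it passes the entry threshold (default 0.05);
  retained predictors whose p rises above the removal threshold (default
  0.10) are dropped; a predictor whose variance inflation factor reaches
  the VIF limit (default 5) is excluded outright.  Results report
  unstandardized B, standardized beta (B * sd(x)/sd(y)), cumulative R²
  and per-predictor ΔR² in entry order, Bonferroni-corrected p and VIF.
* forward **stepwise logistic regression** — entry by likelihood-ratio
  test; odds ratios with Wald 95% CIs, an omnibus LR chi-square of the
  final model against the null, and the Hosmer-Lemeshow statistic on ten
  groups of fitted risk with g-2 degrees of freedom.
* **ANCOVA** — an exposure tertile (3 levels) as fixed factor with
  numeric covariates; the factor F is the extra-sum-of-squares test of
  the factor after the covariates, eta-squared is classical
  (SS_factor / SS_total), adjusted group means are model predictions at
  the covariate means, and pairwise post hoc comparisons of adjusted
  means are mapped to significance tiers.

Categorical covariates (city, study mode) enter as their integer codes by
default (``strict_paper=True``), matching the source workflow; with
``strict_paper=False`` they are dummy-expanded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class ModelSpec:
    outcome: str
    candidates: list[str]
    entry_p: float = 0.05
    removal_p: float = 0.10
    vif_limit: float = 5.0
    bonferroni_family: Optional[int] = None  # default: final model size
    strict_paper: bool = True
    categorical: tuple[str, ...] = ("city", "mode")

    def __post_init__(self) -> None:
        if not self.entry_p < self.removal_p:
            raise ValueError("entry_p must be smaller than removal_p")
        if not self.vif_limit > 1:
            raise ValueError("vif_limit must exceed 1")


@dataclass
class LinearModelResult:
    outcome: str
    table: pd.DataFrame  # predictor, B, beta, R2_cum, dR2, p, p_bonf, VIF
    r2: float
    n: int
    empty: bool = False
    excluded_collinear: list[str] = field(default_factory=list)


@dataclass
class LogisticModelResult:
    outcome: str
    table: pd.DataFrame  # predictor, B, OR, ci_low, ci_high, p, p_bonf
    omnibus_chi2: float
    omnibus_df: int
    omnibus_p: float
    hl_chi2: float
    hl_df: int
    hl_p: float
    n: int
    empty: bool = False
    separated: list[str] = field(default_factory=list)


@dataclass
class AncovaResult:
    outcome: str
    groups: pd.DataFrame  # tertile, n, adj_mean, sd
    f: float
    p: float
    eta_sq: float
    posthoc: pd.DataFrame  # pair, diff, p, tier


def bonferroni_adjust(p_values, family_size: int) -> np.ndarray:
    """min(1, p * m) per p-value."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * family_size)


# --------------------------------------------------------------------------
# design-matrix helpers
# --------------------------------------------------------------------------


def _expand(df: pd.DataFrame, cols: Sequence[str], spec: ModelSpec) -> pd.DataFrame:
    """Design columns for the chosen predictors; categorical covariates are
    dummy-expanded only when strict_paper is off."""
    if spec.strict_paper:
        return df[list(cols)].astype(float)
    parts = []
    for c in cols:
        if c in spec.categorical:
            dummies = pd.get_dummies(
                df[c].astype(int), prefix=c, drop_first=True, dtype=float
            )
            parts.append(dummies)
        else:
            parts.append(df[[c]].astype(float))
    return pd.concat(parts, axis=1)


def _vif(X: pd.DataFrame) -> np.ndarray:
    """Variance inflation factors, 1/(1-R²) of each column on the others."""
    Xc = X.to_numpy(dtype=float)
    n, k = Xc.shape
    if k == 1:
        return np.ones(1)
    out = np.empty(k)
    for j in range(k):
        y = Xc[:, j]
        Z = np.column_stack([np.ones(n), np.delete(Xc, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ beta
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            out[j] = np.inf
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        out[j] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return out


def _fit_ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


# --------------------------------------------------------------------------
# stepwise OLS
# --------------------------------------------------------------------------


def stepwise_ols(data: pd.DataFrame, spec: ModelSpec) -> LinearModelResult:
    """Forward stepwise linear regression with VIF screening.

    Rows with missing values in the outcome or any candidate are dropped.
    Returns the final model in entry order; an empty model (no candidate
    passed entry) is flagged rather than raised.
    """
    cols = [spec.outcome] + list(spec.candidates)
    df = data[cols].dropna().reset_index(drop=True)
    n = len(df)
    if n <= len(spec.candidates) + 10:
        raise ValueError("too few complete rows for stepwise selection")
    y = df[spec.outcome].to_numpy(dtype=float)

    selected: list[str] = []
    excluded: list[str] = []
    while True:
        remaining = [
            c for c in spec.candidates if c not in selected and c not in excluded
        ]
        best_c, best_p = None, np.inf
        for c in remaining:
            X = _expand(df, selected + [c], spec)
            if np.allclose(np.var(X[X.columns[-1]]), 0):
                excluded.append(c)
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = _fit_ols(y, X)
            # p of the block the candidate contributed (last column(s))
            p = float(res.pvalues.iloc[-1])
            if p < best_p:
                best_c, best_p = c, p
        if best_c is None or best_p >= spec.entry_p:
            break
        trial = selected + [best_c]
        vifs = _vif(_expand(df, trial, spec))
        if np.any(vifs >= spec.vif_limit):
            excluded.append(best_c)
            continue
        selected.append(best_c)
        # backward removal pass (never removes the variable just entered)
        changed = True
        while changed and len(selected) > 1:
            changed = False
            res = _fit_ols(y, _expand(df, selected, spec))
            pv = res.pvalues.iloc[1:]
            worst = pv.idxmax()
            if pv.max() > spec.removal_p and worst != best_c:
                owner = next(
                    c for c in selected if worst == c or worst.startswith(c + "_")
                )
                selected.remove(owner)
                changed = True

    if not selected:
        empty_table = pd.DataFrame(
            columns=["predictor", "B", "beta", "R2_cum", "dR2", "p", "p_bonf", "VIF"]
        )
        return LinearModelResult(spec.outcome, empty_table, 0.0, n, True, excluded)

    table, r2 = _ols_entry_table(df, y, selected, spec)
    return LinearModelResult(spec.outcome, table, r2, n, False, excluded)


def fit_ols_structure(
    data: pd.DataFrame, outcome: str, predictors: Sequence[str],
    spec: ModelSpec | None = None,
) -> LinearModelResult:
    """Fit a fixed (non-stepwise) linear model structure and report the
    same table as :func:`stepwise_ols`, predictors in the given order."""
    spec = spec or ModelSpec(outcome=outcome, candidates=list(predictors))
    df = data[[outcome] + list(predictors)].dropna().reset_index(drop=True)
    y = df[outcome].to_numpy(dtype=float)
    table, r2 = _ols_entry_table(df, y, list(predictors), spec)
    return LinearModelResult(outcome, table, r2, len(df), False, [])


def _ols_entry_table(df, y, selected, spec):
    res = _fit_ols(y, _expand(df, selected, spec))
    r2_cum = []
    for i in range(1, len(selected) + 1):
        r2_cum.append(_fit_ols(y, _expand(df, selected[:i], spec)).rsquared)
    d_r2 = np.diff([0.0] + r2_cum)
    sy = np.std(y, ddof=1)
    vifs = _vif(_expand(df, selected, spec))
    m = spec.bonferroni_family or len(selected)
    rows = []
    for i, c in enumerate(selected):
        cols = [
            j for j, name in enumerate(res.params.index)
            if name == c or name.startswith(c + "_")
        ]
        j = cols[0]
        b = float(res.params.iloc[j])
        sx = float(np.std(_expand(df, [c], spec).iloc[:, 0], ddof=1))
        rows.append(
            {
                "predictor": c,
                "B": b,
                "beta": b * sx / sy,
                "R2_cum": r2_cum[i],
                "dR2": d_r2[i],
                "p": float(res.pvalues.iloc[j]),
                "p_bonf": float(bonferroni_adjust([res.pvalues.iloc[j]], m)[0]),
                "VIF": float(vifs[i]),
            }
        )
    return pd.DataFrame(rows), float(res.rsquared)


# --------------------------------------------------------------------------
# stepwise logistic regression
# --------------------------------------------------------------------------


def _fit_logit(y, X):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(
            disp=0, maxiter=200
        )


def _logit_ok(res, X) -> bool:
    """Reject fits showing separation: non-convergence or exploding SEs."""
    if not res.mle_retvals.get("converged", True):
        return False
    return bool(np.all(np.abs(res.params) < 50) and np.all(res.bse < 1e3))


def hosmer_lemeshow(y, fitted, groups: int = 10) -> tuple[float, int, float]:
    """Hosmer-Lemeshow statistic on decile groups of fitted risk.

    Returns (chi2, df, p) with df = g - 2 where g is the number of
    non-empty groups after tied-quantile merging.
    """
    y = np.asarray(y, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    bins = pd.qcut(fitted, groups, duplicates="drop")
    tab = pd.DataFrame({"y": y, "p": fitted, "g": bins}).groupby(
        "g", observed=True
    ).agg(n=("y", "size"), obs=("y", "sum"), exp=("p", "sum"))
    g = len(tab)
    if g < 3:
        raise ValueError("too few distinct risk groups for the HL test")
    o1, e1, nn = tab["obs"].to_numpy(), tab["exp"].to_numpy(), tab["n"].to_numpy()
    denom = e1 * (1.0 - e1 / nn)
    chi2 = float(np.sum((o1 - e1) ** 2 / denom))
    df = g - 2
    return chi2, df, float(stats.chi2.sf(chi2, df))


def stepwise_logistic(data: pd.DataFrame, spec: ModelSpec) -> LogisticModelResult:
    """Forward stepwise binary logistic regression (likelihood-ratio
    entry/removal tests) with omnibus and Hosmer-Lemeshow diagnostics.

    A candidate producing quasi-complete separation is dropped with a
    flag rather than fit with a penalty, since plain odds ratios are
    reported.
    """
    cols = [spec.outcome] + list(spec.candidates)
    df = data[cols].dropna().reset_index(drop=True)
    y = df[spec.outcome].to_numpy(dtype=float)
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("outcome must be binary 0/1 with both classes present")
    n = len(df)

    null_llf = _fit_logit(y, pd.DataFrame(index=df.index)).llf
    selected: list[str] = []
    separated: list[str] = []
    cur_llf = null_llf
    while True:
        remaining = [
            c for c in spec.candidates if c not in selected and c not in separated
        ]
        best = None
        for c in remaining:
            X = _expand(df, selected + [c], spec)
            try:
                res = _fit_logit(y, X)
            except Exception:
                separated.append(c)
                continue
            if not _logit_ok(res, X):
                separated.append(c)
                continue
            k = X.shape[1] - _expand(df, selected, spec).shape[1] if selected else X.shape[1]
            lr = 2.0 * (res.llf - cur_llf)
            p = stats.chi2.sf(max(lr, 0.0), k)
            if best is None or p < best[1]:
                best = (c, p, res)
        if best is None or best[1] >= spec.entry_p:
            break
        selected.append(best[0])
        cur_llf = best[2].llf
        # removal pass by LR test, sparing the newest entrant
        changed = True
        while changed and len(selected) > 1:
            changed = False
            full = _fit_logit(y, _expand(df, selected, spec))
            for c in [s for s in selected if s != best[0]]:
                reduced = _fit_logit(
                    y, _expand(df, [s for s in selected if s != c], spec)
                )
                k = _expand(df, selected, spec).shape[1] - _expand(
                    df, [s for s in selected if s != c], spec
                ).shape[1]
                p = stats.chi2.sf(2.0 * (full.llf - reduced.llf), k)
                if p > spec.removal_p:
                    selected.remove(c)
                    cur_llf = reduced.llf
                    changed = True
                    break

    if not selected:
        empty = pd.DataFrame(
            columns=["predictor", "B", "OR", "ci_low", "ci_high", "p", "p_bonf"]
        )
        return LogisticModelResult(
            spec.outcome, empty, 0.0, 0, 1.0, np.nan, 0, np.nan, n, True, separated
        )

    X = _expand(df, selected, spec)
    res = _fit_logit(y, X)
    omnibus = 2.0 * (res.llf - null_llf)
    om_df = X.shape[1]
    m = spec.bonferroni_family or len(selected)
    rows = []
    for c in selected:
        j = next(
            i for i, name in enumerate(res.params.index)
            if name == c or name.startswith(c + "_")
        )
        b = float(res.params.iloc[j])
        se = float(res.bse.iloc[j])
        rows.append(
            {
                "predictor": c,
                "B": b,
                "OR": float(np.exp(b)),
                "ci_low": float(np.exp(b - 1.959963984540054 * se)),
                "ci_high": float(np.exp(b + 1.959963984540054 * se)),
                "p": float(res.pvalues.iloc[j]),
                "p_bonf": float(bonferroni_adjust([res.pvalues.iloc[j]], m)[0]),
            }
        )
    try:
        hl_chi2, hl_df, hl_p = hosmer_lemeshow(y, res.predict())
    except ValueError:
        # fewer than 3 distinct risk levels: the HL statistic is undefined
        hl_chi2, hl_df, hl_p = np.nan, 0, np.nan
    return LogisticModelResult(
        spec.outcome, pd.DataFrame(rows),
        float(omnibus), om_df, float(stats.chi2.sf(omnibus, om_df)),
        hl_chi2, hl_df, hl_p, n, False, separated,
    )


# --------------------------------------------------------------------------
# ANCOVA
# --------------------------------------------------------------------------

_TIERS = ((0.0001, "<0.0001"), (0.001, "<0.001"), (0.01, "<0.01"), (0.05, "<0.05"))


def _tier(p: float) -> str:
    for cut, label in _TIERS:
        if p < cut:
            return label
    return "ns"


def ancova_by_tertile(
    data: pd.DataFrame,
    outcome: str,
    tertile_col: str,
    covariates: Sequence[str],
    posthoc: str = "lsd",
) -> AncovaResult:
    """Covariate-adjusted comparison of an outcome across exposure tertiles.

    The factor F is the extra sum of squares of the tertile dummies after
    the covariates over the full-model residual mean square; eta-squared
    is classical, SS_factor / SS_total.  Adjusted means are full-model
    predictions at the grand covariate means; reported SDs are raw
    within-group SDs.  ``posthoc`` is ``"lsd"`` (unadjusted pairwise
    tests of adjusted means) or ``"bonferroni"``.
    """
    cols = [outcome, tertile_col] + list(covariates)
    df = data[cols].dropna().reset_index(drop=True)
    levels = np.sort(df[tertile_col].unique())
    if len(levels) != 3:
        raise ValueError(
            f"{tertile_col} must have exactly 3 non-empty levels, got {len(levels)}"
        )
    y = df[outcome].to_numpy(dtype=float)
    n = len(df)

    dummies = pd.get_dummies(
        df[tertile_col].astype(int), prefix="t", drop_first=True, dtype=float
    )
    Xcov = df[list(covariates)].astype(float)
    if len(covariates):
        rank_check = np.linalg.matrix_rank(
            np.column_stack([np.ones(n), dummies, Xcov])
        )
        if rank_check < 1 + dummies.shape[1] + Xcov.shape[1]:
            raise ValueError("covariates collinear with the tertile factor")
    X_full = pd.concat([dummies, Xcov], axis=1)
    full = _fit_ols(y, X_full)
    reduced = _fit_ols(y, Xcov) if len(covariates) else _fit_ols(
        y, pd.DataFrame(index=df.index)
    )
    ss_factor = float(reduced.ssr - full.ssr)
    df_factor = dummies.shape[1]
    df_res = int(full.df_resid)
    ms_res = full.ssr / df_res
    f = (ss_factor / df_factor) / ms_res
    p = float(stats.f.sf(f, df_factor, df_res))
    ss_total = float(np.sum((y - y.mean()) ** 2))
    eta_sq = ss_factor / ss_total

    cov_means = Xcov.mean().to_numpy() if len(covariates) else np.empty(0)
    params = full.params
    cov_b = params[list(covariates)].to_numpy() if len(covariates) else np.empty(0)
    base = float(params["const"]) + float(cov_means @ cov_b)
    adj = {int(levels[0]): base}
    for lv in levels[1:]:
        adj[int(lv)] = base + float(params[f"t_{int(lv)}"])

    rows = []
    for lv in levels:
        sel = df[tertile_col] == lv
        rows.append(
            {
                "tertile": int(lv),
                "n": int(sel.sum()),
                "adj_mean": adj[int(lv)],
                "sd": float(np.std(y[sel.to_numpy()], ddof=1)),
            }
        )

    cov = full.cov_params()
    pairs = []
    names = {int(lv): (f"t_{int(lv)}" if lv != levels[0] else None) for lv in levels}
    combos = [(int(levels[i]), int(levels[j]))
              for i in range(3) for j in range(i + 1, 3)]
    for a, b in combos:
        L = pd.Series(0.0, index=params.index)
        if names[a]:
            L[names[a]] += 1.0
        if names[b]:
            L[names[b]] -= 1.0
        diff = float(L @ params)
        se = float(np.sqrt(L @ cov @ L))
        t = diff / se
        pp = 2.0 * stats.t.sf(abs(t), df_res)
        if posthoc == "bonferroni":
            pp = float(bonferroni_adjust([pp], len(combos))[0])
        pairs.append(
            {"pair": f"{a}-{b}", "diff": diff, "p": float(pp), "tier": _tier(pp)}
        )

    return AncovaResult(
        outcome, pd.DataFrame(rows), float(f), p, float(eta_sq),
        pd.DataFrame(pairs),
    )
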