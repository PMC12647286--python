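"""Statistical battery: FDR-corrected Pearson correlation grids,
standardized multiple regression with VIF, bootstrap causal mediation
(ACME / ADE / total effect), and one-sample t-tests against isotropy.

All tests are two-sided at alpha = 0.05.  Missing data are handled by
complete-case analysis per model.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import variance_inflation_factor
import statsmodels.api as sm

__all__ = [
    "strength_category",
    "bh_adjust",
    "pearson_matrix_fdr",
    "standardized_ols",
    "MediationResult",
    "mediate",
    "mediation_battery",
    "MEDIATION_PATHS",
    "one_sample_t",
    "fd_alps_check",
]

ALPHA = 0.05

_STRENGTH_BANDS = [
    (0.20, "very weak"),
    (0.40, "weak"),
    (0.60, "moderate"),
    (0.80, "strong"),
    (1.0 + 1e-12, "very strong"),
]


def strength_category(r: float) -> str:
    """Correlation strength band from |r|: 0-0.19 very weak, 0.20-0.39
    weak, 0.40-0.59 moderate, 0.60-0.79 strong, 0.80-1.00 very strong."""
    a = abs(r)
    for upper, name in _STRENGTH_BANDS:
        if a < upper:
            return name
    raise ValueError(f"|r| = {a} outside [0, 1]")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values:
    q_(i) = min_{j >= i} p_(j) * m / j."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def _check_variable(df: pd.DataFrame, name: str) -> None:
    x = df[name].dropna()
    if x.nunique() <= 1:
        raise ValueError(f"zero-variance variable: {name}")


def pearson_matrix_fdr(
    table: pd.DataFrame,
    row_vars: list[str],
    col_vars: list[str] | None = None,
    family: str = "panel",
) -> pd.DataFrame:
    """Pairwise complete-case Pearson correlations with BH-FDR q-values.

    If ``col_vars`` is None the unique unordered pairs of ``row_vars``
    are tested; otherwise every row x column pair.  BH adjustment is
    applied across all tests of the call (one declared family, the
    ``family`` string is recorded per row).
    """
    if col_vars is None:
        pairs = list(combinations(row_vars, 2))
    else:
        pairs = [(a, b) for a in row_vars for b in col_vars if a != b]
    records = []
    for a, b in pairs:
        _check_variable(table, a)
        _check_variable(table, b)
        sub = table[[a, b]].dropna()
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 complete pairs for ({a}, {b})")
        r, p = sps.pearsonr(sub[a], sub[b])
        records.append(
            dict(var1=a, var2=b, r=float(r), p=float(p), n=len(sub),
                 category=strength_category(r), family=family)
        )
    out = pd.DataFrame(records)
    out["q"] = bh_adjust(out["p"])
    return out[["var1", "var2", "r", "p", "q", "n", "category", "family"]]


def _is_binary(x: pd.Series) -> bool:
    vals = set(pd.unique(x.dropna()))
    return vals <= {0, 1, 0.0, 1.0, True, False}


def standardized_ols(
    table: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    covariates: list[str] | None = None,
    standardize_outcome: bool = True,
    normal_ci: bool = True,
) -> pd.DataFrame:
    """Standardized multiple regression.

    Continuous variables (outcome included unless
    ``standardize_outcome=False``) are z-scored; 0/1 dummy covariates
    are left as-is.  Returns one row per non-intercept predictor with
    the standardized coefficient, 95% CI (normal approximation by
    default), p-value and VIF.
    """
    covariates = list(covariates or [])
    cols = [outcome] + list(predictors) + covariates
    data = table[cols].dropna().copy()
    n_coef = len(predictors) + len(covariates) + 1
    if len(data) <= n_coef + 1:
        raise ValueError("too few complete cases for the requested model")

    for c in cols:
        if _is_binary(data[c]):
            continue
        if c == outcome and not standardize_outcome:
            continue
        sd = data[c].std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero-variance variable: {c}")
        data[c] = (data[c] - data[c].mean()) / sd

    X = data[list(predictors) + covariates]
    corr = X.corr().to_numpy()
    iu = np.triu_indices_from(corr, k=1)
    dup = np.where(np.isclose(np.abs(corr[iu]), 1.0, atol=1e-12))[0]
    if dup.size:
        i, j = iu[0][dup[0]], iu[1][dup[0]]
        raise ValueError(
            f"perfect collinearity between predictors "
            f"{X.columns[i]!r} and {X.columns[j]!r}"
        )

    Xc = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(data[outcome], Xc).fit()
    z = sps.norm.ppf(1 - ALPHA / 2)
    rows = []
    exog = np.asarray(Xc, dtype=float)
    for k, name in enumerate(Xc.columns):
        if name == "const":
            continue
        beta = fit.params[name]
        se = fit.bse[name]
        lo, hi = (beta - z * se, beta + z * se) if normal_ci else tuple(
            fit.conf_int(alpha=ALPHA).loc[name]
        )
        rows.append(
            dict(outcome=outcome, predictor=name, beta=float(beta),
                 ci_low=float(lo), ci_high=float(hi), se=float(se),
                 p=float(fit.pvalues[name]),
                 vif=float(variance_inflation_factor(exog, k)),
                 n=int(fit.nobs), significant=bool(lo > 0 or hi < 0))
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# mediation


@dataclass
class MediationResult:
    """Bootstrap mediation decomposition for one X -> M -> Y model.

    In the linear two-equation system

        M = a X + covariates
        Y = c' X + b M + covariates

    the indirect effect ACME = a*b, the direct effect ADE = c', and
    the total effect = a*b + c' (an algebraic identity of nested
    least-squares fits on the same sample).  Confidence intervals are
    percentile intervals over case resamples.
    """

    x: str
    m: str
    y: str
    acme: float
    acme_ci: tuple[float, float]
    ade: float
    ade_ci: tuple[float, float]
    total: float
    total_ci: tuple[float, float]
    prop_mediated: float
    a_path: float
    a_p: float
    b_path: float
    b_p: float
    n: int
    n_boot: int
    seed: int | None
    n_redraws: int = 0

    def as_dict(self) -> dict:
        return {
            "path": f"{self.x} -> {self.m} -> {self.y}",
            "ACME": self.acme, "ACME_lo": self.acme_ci[0], "ACME_hi": self.acme_ci[1],
            "ADE": self.ade, "ADE_lo": self.ade_ci[0], "ADE_hi": self.ade_ci[1],
            "total": self.total, "total_lo": self.total_ci[0], "total_hi": self.total_ci[1],
            "prop_mediated": self.prop_mediated,
            "a_path": self.a_path, "a_p": self.a_p,
            "b_path": self.b_path, "b_p": self.b_p,
            "n": self.n, "n_boot": self.n_boot,
        }


def _ols_coef(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(X, y, rcond=None)[0]


def _mediation_point(xm: np.ndarray, ym: np.ndarray, x: np.ndarray,
                     m: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """a, b, c' from the two nested fits; columns of xm are
    [1, x, covs], of ym [1, x, m, covs]."""
    a = _ols_coef(xm, m)[1]
    coefs = _ols_coef(ym, y)
    cprime, b = coefs[1], coefs[2]
    return float(a), float(b), float(cprime)


def mediate(
    table: pd.DataFrame,
    x: str,
    m: str,
    y: str,
    covariates: list[str] | None = None,
    n_boot: int = 1000,
    seed: int | None = 0,
    standardize: bool = False,
) -> MediationResult:
    """Nonparametric-bootstrap mediation for one X -> M -> Y model.

    Case resampling with percentile 95% CIs; degenerate resamples
    (zero variance in X or M) are redrawn and counted, with an error
    if more than 10% of draws degenerate.  Deterministic under seed.
    """
    covariates = list(covariates or [])
    cols = [x, m, y] + covariates
    data = table[cols].dropna()
    n = len(data)
    if n < 20:
        raise ValueError(f"need >= 20 complete cases, got {n}")
    arr = data.to_numpy(dtype=float)
    if standardize:
        sd = arr.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance variable in mediation model")
        arr = (arr - arr.mean(axis=0)) / sd
    for j, name in enumerate(cols[:3]):
        if np.std(arr[:, j]) == 0:
            raise ValueError(f"zero-variance variable: {name}")

    ones = np.ones((n, 1))
    covs = arr[:, 3:]
    xm_design = np.column_stack([ones, arr[:, [0]], covs])
    ym_design = np.column_stack([ones, arr[:, [0]], arr[:, [1]], covs])
    a, b, cprime = _mediation_point(xm_design, ym_design,
                                    arr[:, 0], arr[:, 1], arr[:, 2])
    acme, ade = a * b, cprime
    total = acme + ade

    # a/b-path p-values from the analytic OLS fits
    a_fit = sm.OLS(arr[:, 1], xm_design).fit()
    y_fit = sm.OLS(arr[:, 2], ym_design).fit()
    a_p, b_p = float(a_fit.pvalues[1]), float(y_fit.pvalues[2])

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, 3))
    redraws = 0
    max_redraws = max(1, int(0.1 * n_boot))
    i = 0
    while i < n_boot:
        take = rng.integers(0, n, n)
        sub = arr[take]
        if np.std(sub[:, 0]) == 0 or np.std(sub[:, 1]) == 0:
            redraws += 1
            if redraws > max_redraws:
                raise ValueError("more than 10% of bootstrap draws degenerate")
            continue
        o = np.ones((n, 1))
        c = sub[:, 3:]
        ab, bb, cb = _mediation_point(
            np.column_stack([o, sub[:, [0]], c]),
            np.column_stack([o, sub[:, [0]], sub[:, [1]], c]),
            sub[:, 0], sub[:, 1], sub[:, 2],
        )
        boot[i] = (ab * bb, cb, ab * bb + cb)
        i += 1

    ci = np.percentile(boot, [2.5, 97.5], axis=0)
    prop = acme / total if abs(total) > 1e-12 else float("nan")
    return MediationResult(
        x=x, m=m, y=y,
        acme=acme, acme_ci=(float(ci[0, 0]), float(ci[1, 0])),
        ade=ade, ade_ci=(float(ci[0, 1]), float(ci[1, 1])),
        total=total, total_ci=(float(ci[0, 2]), float(ci[1, 2])),
        prop_mediated=prop, a_path=a, a_p=a_p, b_path=b, b_p=b_p,
        n=n, n_boot=n_boot, seed=seed, n_redraws=redraws,
    )


# The ten X -> M -> Y models of the corpus-callosum mediation battery,
# in report order: intra-regional models in the association and
# projection areas first, then the corpus-callosum-body mediators.
MEDIATION_PATHS: list[tuple[str, str, str]] = [
    ("assocDxx", "assocDyy", "ALPS"),
    ("assocDxx", "assocDzz", "ALPS"),
    ("projDxx", "projDyy", "ALPS"),
    ("projDxx", "projDzz", "ALPS"),
    ("assocDxx", "ccbDxx", "ALPS"),
    ("assocDxx", "ccbDyy", "ALPS"),
    ("assocDxx", "ccbDzz", "ALPS"),
    ("projDxx", "ccbDxx", "ALPS"),
    ("projDxx", "ccbDyy", "ALPS"),
    ("projDxx", "ccbDzz", "ALPS"),
]


def mediation_battery(
    table: pd.DataFrame,
    covariates: list[str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    standardize: bool = False,
) -> pd.DataFrame:
    """Run the fixed ten-model battery (age-adjusted by default) with a
    shared seed and return one row per path in the canonical order."""
    covariates = ["age"] if covariates is None else list(covariates)
    needed = {v for path in MEDIATION_PATHS for v in path}
    missing = sorted(needed - set(table.columns))
    if missing:
        raise ValueError(f"missing variables for mediation battery: {missing}")
    rows = []
    for x, m, y in MEDIATION_PATHS:
        res = mediate(table, x, m, y, covariates=covariates,
                      n_boot=n_boot, seed=seed, standardize=standardize)
        rows.append(res.as_dict())
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# one-sample tests and motion check


def one_sample_t(values, reference: float = 1.0) -> tuple[float, int, float]:
    """Two-tailed one-sample t-test: t = (mean - ref) / (SD / sqrt(n)),
    df = n - 1."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate sample: zero standard deviation")
    t = (x.mean() - reference) / (sd / np.sqrt(x.size))
    df = x.size - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def fd_alps_check(table: pd.DataFrame, fd_col: str = "mean_fd",
                  alps_col: str = "ALPS") -> dict:
    """Single pre-specified motion check: Pearson r between mean FD and
    the ALPS index (no FDR family), with a Fisher-z 95% CI for r."""
    for c in (fd_col, alps_col):
        _check_variable(table, c)
    sub = table[[fd_col, alps_col]].dropna()
    n = len(sub)
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    r, p = sps.pearsonr(sub[fd_col], sub[alps_col])
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = sps.norm.ppf(1 - ALPHA / 2) / np.sqrt(n - 3)
    return {
        "r": float(r), "p": float(p), "n": n,
        "ci_low": float(np.tanh(z - half)), "ci_high": float(np.tanh(z + half)),
        "category": strength_category(r),
    }
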