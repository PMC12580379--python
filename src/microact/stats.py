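"""Group-comparison statistics: covariate adjustment, t-tests, chi-square,
effect sizes, correlations, and Benjamini-Hochberg FDR.

The subgroup workflow residualizes each outcome on the covariates (OLS with
intercept), then runs a pooled two-sample t-test on the adjusted values and
corrects the outcome family with BH-FDR.  An alternative mode tests the
group term directly inside the linear model.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupComparisonResult:
    """Two-sample comparison of one variable."""

    variable: str
    t_statistic: float
    df: float
    p_value: float
    cohens_d: float
    group_ns: tuple[int, int]
    q_value: float | None = None
    cohens_d_raw: float | None = None


@dataclass
class CorrelationResult:
    """Pearson or Spearman association between two paired variables."""

    method: str
    r: float
    p_value: float
    n: int


# ---------------------------------------------------------------------------
# Covariate adjustment
# ---------------------------------------------------------------------------

def adjust_covariates(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residualize ``y`` on the covariates (plus intercept), keep the mean.

    Returns residuals + grand mean so adjusted values stay on the original
    scale.  Raises on rank-deficient covariate matrices, naming the
    offending columns.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    if X.shape[0] != len(y):
        raise ValueError("covariate rows must match y")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need more subjects than covariates + intercept")
    design = np.column_stack([np.ones(len(y)), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        deficient = _rank_deficient_columns(design)
        raise ValueError(f"covariate matrix is rank deficient (columns {deficient})")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    residuals = y - design @ beta
    return residuals + y.mean()


def _rank_deficient_columns(design: np.ndarray) -> list[int]:
    cols = []
    for j in range(1, design.shape[1]):
        others = np.delete(design, j, axis=1)
        if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(design):
            cols.append(j - 1)  # report in covariate indexing (intercept excluded)
    return cols


# ---------------------------------------------------------------------------
# Two-sample tests
# ---------------------------------------------------------------------------

def two_sample_t(
    x1: np.ndarray, x2: np.ndarray, variant: str = "pooled", variable: str = ""
) -> GroupComparisonResult:
    """Two-sample t-test (pooled/Student by default, or Welch)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("each group needs n >= 2")
    if variant == "pooled":
        if np.var(x1, ddof=1) == 0 and np.var(x2, ddof=1) == 0:
            raise ValueError("zero pooled variance: t undefined")
        t, p = sps.ttest_ind(x1, x2, equal_var=True)
        df = len(x1) + len(x2) - 2
    elif variant == "welch":
        t, p = sps.ttest_ind(x1, x2, equal_var=False)
        df = _welch_df(x1, x2)
    else:
        raise ValueError(f"unknown variant {variant!r}; expected pooled|welch")
    return GroupComparisonResult(
        variable=variable,
        t_statistic=float(t),
        df=float(df),
        p_value=float(p),
        cohens_d=cohens_d(x1, x2),
        group_ns=(len(x1), len(x2)),
    )


def _welch_df(x1, x2):
    v1, v2 = np.var(x1, ddof=1), np.var(x2, ddof=1)
    n1, n2 = len(x1), len(x2)
    num = (v1 / n1 + v2 / n2) ** 2
    den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    return num / den


def t_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int, variable: str = ""
) -> GroupComparisonResult:
    """Pooled two-sample t from summary statistics (mean, SD, n per group)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("zero pooled variance: t undefined")
    t, p = sps.ttest_ind_from_stats(m1, sd1, n1, m2, sd2, n2, equal_var=True)
    sp = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    return GroupComparisonResult(
        variable=variable,
        t_statistic=float(t),
        df=float(n1 + n2 - 2),
        p_value=float(p),
        cohens_d=float((m1 - m2) / sp),
        group_ns=(n1, n2),
    )


def chi_square_2x2(
    a: int, b: int, c: int, d: int, continuity: bool = True
) -> tuple[float, float]:
    """2x2 chi-square test (Yates continuity correction by default).

    Returns (statistic, upper-tail p at df=1).  Raises when a marginal is
    zero (expected counts undefined).
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0) or table.sum() == 0:
        raise ValueError("counts must be nonnegative with positive total")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal: chi-square undefined")
    stat, p, _dof, _exp = sps.chi2_contingency(table, correction=continuity)
    return float(stat), float(p)


def cohens_d(x1: np.ndarray, x2: np.ndarray) -> float:
    """Cohen's d with the df-weighted pooled SD."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    sp2 = ((n1 - 1) * np.var(x1, ddof=1) + (n2 - 1) * np.var(x2, ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled SD: d undefined")
    return float((x1.mean() - x2.mean()) / np.sqrt(sp2))


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def correlate(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> CorrelationResult:
    """Pearson on raw values or Spearman on mid-ranks; two-tailed p.

    Spearman p uses the t-approximation with df = n - 2 (ties get average
    ranks); for n <= 9 an exact permutation p over all orderings is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired series with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    n = len(x)
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        r = float(np.corrcoef(rx, ry)[0, 1])
        if n <= 9:
            p = _exact_spearman_p(rx, ry, r)
        else:
            with np.errstate(divide="ignore"):
                t = r * np.sqrt((n - 2) / max(1e-300, 1.0 - r * r))
            p = float(2 * sps.t.sf(abs(t), n - 2)) if abs(r) < 1 else 0.0
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(method=method, r=float(r), p_value=float(p), n=n)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, r_obs: float) -> float:
    from itertools import permutations

    n = len(rx)
    count = 0
    total = 0
    for perm in permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        count += abs(r) >= abs(r_obs) - 1e-12
        total += 1
    return count / total


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Subgroup workflow
# ---------------------------------------------------------------------------

def run_subgroup_analysis(
    table: pd.DataFrame,
    split: tuple[str, float],
    outcomes: list[str],
    covariates: list[str] | None = None,
    variant: str = "pooled",
    mode: str = "residualize",
) -> list[GroupComparisonResult]:
    """Compare outcomes between the two sides of ``split`` (var, cutoff).

    Subjects with variable > cutoff form group 1; the rest group 2.  Each
    outcome is covariate-adjusted (``mode='residualize'``: OLS residuals;
    ``mode='glm'``: group term tested inside the linear model), tested with
    a pooled t, given Cohen's d on adjusted (primary) and raw values, and
    the whole outcome family is BH-FDR corrected.  Output order follows the
    input outcome order.
    """
    missing = [c for c in [split[0], *outcomes, *(covariates or [])] if c not in table.columns]
    if missing:
        raise KeyError(f"columns not in table: {missing}")
    mask = table[split[0]].to_numpy(float) > split[1]
    n1, n2 = int(mask.sum()), int((~mask).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError(
            f"degenerate split: {split[0]} > {split[1]} yields groups of {n1} and {n2}"
        )
    results = []
    for outcome in outcomes:
        y = table[outcome].to_numpy(float)
        d_raw = cohens_d(y[mask], y[~mask])
        if covariates and mode == "residualize":
            y_adj = adjust_covariates(y, table[covariates].to_numpy(float))
            res = two_sample_t(y_adj[mask], y_adj[~mask], variant=variant, variable=outcome)
        elif covariates and mode == "glm":
            res = _glm_group_term(y, mask, table[covariates].to_numpy(float), outcome)
        else:
            res = two_sample_t(y[mask], y[~mask], variant=variant, variable=outcome)
        res.cohens_d_raw = d_raw
        results.append(res)
    qs = bh_fdr([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return results


def _glm_group_term(
    y: np.ndarray, mask: np.ndarray, covariates: np.ndarray, variable: str
) -> GroupComparisonResult:
    g = mask.astype(float)
    X = np.column_stack([np.ones(len(y)), g, covariates])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(X.T @ X)
    t = float(beta[1] / np.sqrt(cov[1, 1]))
    p = float(2 * sps.t.sf(abs(t), df))
    return GroupComparisonResult(
        variable=variable,
        t_statistic=t,
        df=float(df),
        p_value=p,
        cohens_d=float(beta[1] / np.sqrt(s2)),
        group_ns=(int(mask.sum()), int((~mask).sum())),
    )


def correlation_table(
    table: pd.DataFrame, pairs: list[tuple[str, str]], method: str = "pearson"
) -> pd.DataFrame:
    """Tidy correlation results for named column pairs (NaN rows dropped)."""
    rows = []
    for xcol, ycol in pairs:
        sub = table[[xcol, ycol]].dropna()
        res = correlate(sub[xcol].to_numpy(), sub[ycol].to_numpy(), method=method)
        rows.append(
            {"pair": f"{xcol}~{ycol}", "method": method, "r": res.r, "p": res.p_value, "n": res.n}
        )
    return pd.DataFrame(rows)


def permutation_t_p(x1: np.ndarray, x2: np.ndarray) -> float:
    """Exhaustive two-sided permutation p for the pooled-t statistic.

    Enumerates every split of the pooled sample into groups of the original
    sizes; intended for tiny instances as an independent oracle.
    """
    pooled = np.concatenate([x1, x2])
    n1 = len(x1)
    obs = abs(two_sample_t(x1, x2).t_statistic)
    idx = range(len(pooled))
    count = 0
    total = 0
    for comb in combinations(idx, n1):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(comb)] = True
        t = two_sample_t(pooled[sel], pooled[~sel]).t_statistic
        count += abs(t) >= obs - 1e-12
        total += 1
    return count / total
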