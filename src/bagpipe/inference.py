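"""Statistical layer: descriptive group tests, covariate-adjusted
regressions, and Benjamini–Hochberg FDR control.

Conventions, chosen to match how such cohort tables are conventionally
analysed (and validated against in-table worked examples):

* group differences in continuous variables use the pooled-variance
  Student t-test (a Welch option exists but is off by default);
* categorical variables use the Pearson chi-square for contingency
  tables *without* continuity correction;
* group comparisons of outcomes are multiple linear regressions with a
  carrier indicator plus the analysis's covariate scheme (age, sex and
  head coil; plus intracranial volume for volumetric outcomes);
* the BH step-up procedure is applied at Q = 0.1 across all outcomes of
  one analysis table as a single family, using the standard `<=`
  comparison of the sorted p-values against (i/m)Q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .tables_io import TableFormatError

__all__ = [
    "TestResult",
    "RegressionResult",
    "FDRResult",
    "two_sample_t_summary",
    "chi_square_test",
    "ols_fit",
    "bh_fdr",
    "compare_groups",
    "COVARIATE_SCHEMES",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    method: str


@dataclass(frozen=True)
class RegressionResult:
    outcome: str
    term: str
    beta: float
    se: float
    p: float
    r_squared: float
    n: int
    covariates: str


@dataclass
class FDRResult:
    """Benjamini–Hochberg step-up over one family of tests.

    ``significant`` is reported in the input order of ``pvals``; the
    step-up property guarantees that if the test with sorted rank i is
    flagged, every smaller p is flagged too."""

    m: int
    q: float
    pvals: list[float]
    ranks: list[int]  # rank of each input p (1 = smallest)
    criticals: list[float]  # (rank/m) * q, in input order
    significant: list[bool]
    family: str = ""


def two_sample_t_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int, welch: bool = False
) -> TestResult:
    """Two-sample t-test from summary statistics (pooled by default).

    With zero pooled variance: equal means give t=0, p=1; unequal means
    are an error (the statistic would be infinite).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0:
        if m1 == m2:
            return TestResult(0.0, n1 + n2 - 2, 1.0, "student-t (degenerate)")
        raise ValueError("zero variance with unequal means: t is infinite")
    res = stats.ttest_ind_from_stats(m1, sd1, n1, m2, sd2, n2, equal_var=not welch)
    if welch:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        df = n1 + n2 - 2
    return TestResult(
        statistic=float(res.statistic),
        df=float(df),
        p=float(res.pvalue),
        method="welch-t" if welch else "student-t",
    )


def chi_square_test(table) -> TestResult:
    """Pearson chi-square for an r x c contingency table, no continuity
    correction; df = (r-1)(c-1).  Zero marginals are an error."""
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or min(counts.shape) < 2:
        raise ValueError("contingency table must be at least 2 x 2")
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    res = stats.chi2_contingency(counts, correction=False)
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.dof),
        p=float(res.pvalue),
        method="pearson-chi2",
    )


def ols_fit(
    outcome: np.ndarray,
    design: pd.DataFrame,
    outcome_name: str = "outcome",
    covariate_label: str | None = None,
) -> list[RegressionResult]:
    """OLS of ``outcome`` on the design columns (intercept added).

    Returns one result row per design term (intercept excluded), each
    carrying the model R² and n.  SEs use the unbiased residual
    variance; p-values are two-sided from t with df = n - parameters.
    Rank-deficient designs raise, naming the collinear columns.
    """
    y = np.asarray(outcome, dtype=float)
    X = design.astype(float)
    n, p_cols = len(y), X.shape[1] + 1
    if n <= p_cols:
        raise ValueError(f"n={n} too small for {p_cols} parameters")
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # identify offending columns by rank growth
        bad = []
        cols: list[str] = []
        for c in Xc.columns:
            trial = Xc[cols + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(c)
            else:
                cols.append(c)
        raise ValueError(f"design is rank-deficient; collinear columns: {bad}")
    fit = sm.OLS(y, Xc).fit()
    label = covariate_label or ",".join(design.columns)
    out = []
    for term in design.columns:
        p_val = float(fit.pvalues[term])
        if fit.ssr == 0.0:
            p_val = 0.0  # zero residual variance; flagged p
        out.append(
            RegressionResult(
                outcome=outcome_name,
                term=str(term),
                beta=float(fit.params[term]),
                se=float(fit.bse[term]),
                p=p_val,
                r_squared=float(fit.rsquared),
                n=n,
                covariates=label,
            )
        )
    return out


def bh_fdr(pvals, q: float = 0.1, family: str = "") -> FDRResult:
    """Benjamini–Hochberg step-up at FDR level ``q``.

    Sort ascending, rank i = 1..m, critical value (i/m)q; the largest
    rank k with p_(k) <= (k/m)q and everything below it is significant.
    Results are reported in input order.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p))):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return FDRResult(0, q, [], [], [], [], family)
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    sorted_p = p[order]
    crit_sorted = (np.arange(1, m + 1) / m) * q
    passing = np.nonzero(sorted_p <= crit_sorted)[0]
    k = passing[-1] + 1 if len(passing) else 0
    sig_sorted = np.arange(m) < k
    significant = np.empty(m, dtype=bool)
    significant[order] = sig_sorted
    return FDRResult(
        m=m,
        q=q,
        pvals=p.tolist(),
        ranks=ranks.tolist(),
        criticals=(ranks / m * q).tolist(),
        significant=significant.tolist(),
        family=family,
    )


#: covariate scheme per analysis: volumetric outcomes additionally
#: adjust for total intracranial volume.
COVARIATE_SCHEMES: dict[str, list[str]] = {
    "bag": ["age", "sex", "head_coil"],
    "volumes": ["icv", "age", "sex", "head_coil"],
    "thickness": ["age", "sex", "head_coil"],
    "dti": ["age", "sex", "head_coil"],
}


def _encode_covariates(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    out = {}
    for cov in covariates:
        if cov not in df.columns:
            raise TableFormatError(f"required covariate {cov!r} missing")
        col = df[cov]
        if cov == "sex":
            out[cov] = (col == "male").astype(float)
        elif cov == "head_coil":
            out[cov] = (col == "8HRBRAIN").astype(float)
        else:
            vals = pd.to_numeric(col, errors="coerce")
            if vals.isna().any():
                raise TableFormatError(f"covariate {cov!r} has missing values")
            out[cov] = vals.astype(float)
    return pd.DataFrame(out, index=df.index)


def compare_groups(
    data: pd.DataFrame,
    outcomes: list[str],
    analysis: str = "bag",
    q: float = 0.1,
    group_col: str = "apoe_e4",
) -> tuple[pd.DataFrame, FDRResult]:
    """Carrier vs non-carrier comparison of ``outcomes`` with the
    analysis's covariate scheme, BH-corrected as one family.

    ``data`` holds one row per subject with the outcomes, covariates and
    the 0/1 carrier column.  Returns the full regression table (all
    terms, every outcome) plus the FDR result over the group-term
    p-values, and adds an ``fdr_significant`` column on group rows.
    """
    if analysis not in COVARIATE_SCHEMES:
        raise ValueError(f"unknown analysis {analysis!r}; expected {list(COVARIATE_SCHEMES)}")
    if group_col not in data.columns or data[group_col].isna().any():
        raise TableFormatError(
            f"group column {group_col!r} must be present for every subject"
        )
    covariates = COVARIATE_SCHEMES[analysis]
    cov_df = _encode_covariates(data, covariates)
    group = pd.to_numeric(data[group_col]).astype(float)
    rows = []
    group_ps = []
    for outcome in outcomes:
        if outcome not in data.columns:
            raise TableFormatError(f"outcome column {outcome!r} missing")
        design = pd.concat([group.rename(group_col), cov_df], axis=1)
        results = ols_fit(
            data[outcome].to_numpy(dtype=float),
            design,
            outcome_name=outcome,
            covariate_label="+".join(covariates),
        )
        for r in results:
            rows.append(r.__dict__)
        group_ps.append(next(r.p for r in results if r.term == group_col))
    fdr = bh_fdr(group_ps, q=q, family=analysis)
    table = pd.DataFrame(rows)
    sig_map = dict(zip(outcomes, fdr.significant))
    table["fdr_significant"] = [
        bool(sig_map[row.outcome]) if row.term == group_col else None
        for row in table.itertuples()
    ]
    return table, fdr
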