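"""Contingency-table epidemiology for smoking prevalence and missingness.

Implements the statistics behind the descriptive and analytic tables:
prevalence cross-tabulations, the Pearson chi-squared test for
heterogeneity, the Cochran–Armitage chi-squared test for linear trend in
proportions (one degree of freedom), cross-product odds ratios with Woolf
(log-scale normal approximation) 95% confidence intervals, and binomial
logistic regression fitted by iteratively reweighted least squares, with
identical results for grouped and row-expanded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class ContingencyTable:
    """Labelled counts: one row per category, one column per outcome."""

    row_labels: list[str]
    col_labels: list[str]
    counts: Union[Sequence[Sequence[int]], np.ndarray]
    ordinal: bool = False  # rows carry a natural order (age bands, tertiles)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


@dataclass(frozen=True)
class ORResult:
    """Odds ratio with a Woolf 95% confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    log_se: float

    def __post_init__(self) -> None:
        if not (0 < self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("confidence interval does not bracket the estimate")


# ---------------------------------------------------------------------------
# Cross-tabulation
# ---------------------------------------------------------------------------

def crosstab(
    frame: pd.DataFrame,
    factor: str,
    outcome: str = "current",
    ordinal: Optional[bool] = None,
) -> ContingencyTable:
    """Tabulate a binary outcome against a categorical factor.

    Complete-case: rows with the factor or outcome missing/unknown are
    dropped.  Categories with no observations are omitted with a warning.
    Columns are (outcome present, outcome absent).
    """
    import logging

    data = frame[[factor, outcome]].copy()
    data[outcome] = data[outcome].astype("object")
    data = data.dropna()
    if isinstance(data[factor].dtype, pd.CategoricalDtype):
        data = data[data[factor].astype(str) != "unknown"]
        levels = [c for c in data[factor].cat.categories if c != "unknown"]
        if ordinal is None:
            ordinal = bool(data[factor].cat.ordered)
    else:
        levels = sorted(data[factor].unique())
    rows, labels = [], []
    for level in levels:
        sub = data[data[factor] == level]
        if len(sub) == 0:
            logging.getLogger("smokestat").warning(
                "crosstab: category %r of %s has n=0; omitted", level, factor
            )
            continue
        k = int(sub[outcome].astype(bool).sum())
        rows.append([k, len(sub) - k])
        labels.append(str(level))
    return ContingencyTable(
        row_labels=labels,
        col_labels=[outcome, f"not_{outcome}"],
        counts=rows,
        ordinal=bool(ordinal),
    )


def proportions(table: ContingencyTable, col: int = 0) -> np.ndarray:
    """Per-row proportion in one outcome column."""
    return table.counts[:, col] / table.row_totals


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

def pearson_chi2(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-squared test for heterogeneity: (statistic, df, p)."""
    if (table.row_totals == 0).any() or (table.col_totals == 0).any():
        raise ValueError("zero marginal total: expected counts undefined")
    if len(table.row_labels) < 2 or len(table.col_labels) < 2:
        raise ValueError("heterogeneity test needs at least a 2x2 table")
    res = st.chi2_contingency(table.counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def cochran_armitage(
    table: ContingencyTable, scores: Optional[Sequence[float]] = None
) -> tuple[float, float]:
    """Cochran–Armitage chi-squared test for linear trend in proportions.

    Rows are ordered exposure categories (scored 0,1,2,... by default) and
    columns a binary outcome; returns the one-degree-of-freedom chi-squared
    statistic and its p-value.  The statistic is invariant under affine
    rescaling of the scores.
    """
    counts = table.counts
    k = counts.shape[0]
    if k < 3:
        raise ValueError("trend is undefined for fewer than 3 ordered categories")
    if counts.shape[1] != 2:
        raise ValueError("trend test requires a k x 2 table")
    s = np.asarray(scores if scores is not None else np.arange(k), dtype=float)
    if len(s) != k:
        raise ValueError("one score per row required")
    n_i = table.row_totals
    r_i = counts[:, 0]
    n = n_i.sum()
    r = r_i.sum()
    if r == 0 or r == n:
        return 0.0, 1.0
    p_bar = r / n
    t = float(np.sum(s * (r_i - n_i * p_bar)))
    var = p_bar * (1 - p_bar) * (np.sum(s**2 * n_i) - np.sum(s * n_i) ** 2 / n)
    if var <= 0:
        return 0.0, 1.0
    stat = t * t / var
    return float(stat), float(st.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# Odds ratios
# ---------------------------------------------------------------------------

def odds_ratio(
    table: ContingencyTable, reference: Union[int, str] = 1, haldane: bool = False
) -> ORResult:
    """Cross-product odds ratio of the exposed row against the reference row
    of a 2x2 table, with the Woolf 95% confidence interval
    exp(ln OR ± 1.96 · sqrt(Σ 1/cell)).

    ``haldane`` adds 0.5 to every cell (off by default); without it a zero
    cell is an error.
    """
    if table.counts.shape != (2, 2):
        raise ValueError("odds_ratio requires a 2x2 table")
    ref = table.row_labels.index(reference) if isinstance(reference, str) else reference
    exp_row = 1 - ref
    cells = table.counts.copy()
    if haldane:
        cells = cells + 0.5
    if (cells == 0).any():
        raise ValueError(
            "zero cell: odds ratio undefined; pass haldane=True for a "
            "0.5 continuity correction"
        )
    a, b = cells[exp_row]
    c, d = cells[ref]
    log_or = np.log(a * d / (b * c))
    se = float(np.sqrt((1.0 / cells).sum()))
    return ORResult(
        estimate=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - Z_95 * se)),
        ci_high=float(np.exp(log_or + Z_95 * se)),
        log_se=se,
    )


# ---------------------------------------------------------------------------
# Logistic regression (IRLS via GLM, binomial family)
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    """A fitted binomial logistic regression on the log-odds scale."""

    params: pd.Series
    cov: pd.DataFrame
    n_used: int
    converged: bool
    _failure: Optional[str] = field(default=None, repr=False)

    def _check(self) -> None:
        if not self.converged:
            raise RuntimeError(
                f"logistic fit did not converge ({self._failure or 'IRLS limit'}); "
                "no estimates reported"
            )

    @property
    def coefficients(self) -> pd.Series:
        self._check()
        return self.params

    def odds_ratios(self, include_intercept: bool = False) -> pd.DataFrame:
        """Exponentiated coefficients with Wald 95% confidence intervals."""
        self._check()
        se = pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)
        out = pd.DataFrame(
            {
                "or": np.exp(self.params),
                "ci_low": np.exp(self.params - Z_95 * se),
                "ci_high": np.exp(self.params + Z_95 * se),
                "log_se": se,
            }
        )
        if not include_intercept and "intercept" in out.index:
            out = out.drop(index="intercept")
        return out


def _encode_terms(data: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    """Design matrix: numeric columns pass through; categorical columns are
    dummy-coded against their first level (the reference)."""
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(data))}
    for term in terms:
        col = data[term]
        if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
            cat = col.astype("category")
            levels = [lv for lv in cat.cat.categories if (cat == lv).any()]
            for level in levels[1:]:
                cols[f"{term}[{level}]"] = (cat == level).astype(float).to_numpy()
        else:
            cols[term] = col.astype(float).to_numpy()
    return pd.DataFrame(cols, index=data.index)


def fit_logistic(
    data: pd.DataFrame,
    outcome: str,
    terms: Sequence[str],
    trials: Optional[str] = None,
    maxiter: int = 50,
    tol: float = 1e-12,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS.

    With ``trials`` unset, ``outcome`` is a per-record 0/1 indicator; with
    ``trials`` set, records are grouped binomial (``outcome`` = successes,
    ``trials`` = group size) and the fit is identical to the one on the
    equivalent row-expanded individual data.  Complete-case: records with
    any required column missing are dropped; ``n_used`` counts individuals.
    Separation or non-convergence is flagged and no estimates are reported.
    """
    needed = [outcome, *terms] + ([trials] if trials else [])
    data = data[needed].dropna()
    X = _encode_terms(data, terms)
    if trials is None:
        endog = data[outcome].astype(float).to_numpy()
        if not np.isin(endog, (0.0, 1.0)).all():
            raise ValueError("individual-level outcome must be binary 0/1")
        n_used = len(data)
    else:
        succ = data[outcome].astype(float).to_numpy()
        tot = data[trials].astype(float).to_numpy()
        if (succ > tot).any() or (succ < 0).any():
            raise ValueError("successes must lie in [0, trials]")
        endog = np.column_stack([succ, tot - succ])
        n_used = int(tot.sum())

    model = sm.GLM(endog, X.to_numpy(), family=sm.families.Binomial())
    failure: Optional[str] = None
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            # saturated grouped fits trip this warning spuriously; genuine
            # separation is caught below by the diverging-coefficient check
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=maxiter, tol=tol)
        converged = bool(getattr(res, "converged", True))
        params = pd.Series(res.params, index=X.columns)
        cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
        diverged = (
            not np.isfinite(params).all()
            or np.abs(params).max() > 30  # |log-odds| > 30 is not a real effect
            or not np.isfinite(np.diag(cov)).all()
            or np.sqrt(np.diag(cov)).max() > 100
        )
        if diverged:
            converged, failure = False, "separation suspected (diverging coefficients)"
    except Exception as exc:  # perfect separation, singular design, ...
        converged, failure = False, str(exc)
        params = pd.Series(np.nan, index=X.columns)
        cov = pd.DataFrame(np.nan, index=X.columns, columns=X.columns)
    return LogisticFit(params=params, cov=cov, n_used=n_used, converged=converged,
                       _failure=failure)


def _safe_chi2(table: ContingencyTable) -> tuple[float, int, float]:
    """Heterogeneity test that treats a constant outcome (a zero column
    marginal) as no evidence of heterogeneity rather than an error."""
    if (table.col_totals == 0).any() and not (table.row_totals == 0).any():
        df = (len(table.row_labels) - 1) * (len(table.col_labels) - 1)
        return 0.0, df, 1.0
    return pearson_chi2(table)


# ---------------------------------------------------------------------------
# Missingness correlates
# ---------------------------------------------------------------------------

def missingness_table(
    frame: pd.DataFrame, factors: Sequence[str]
) -> dict[str, dict]:
    """Per-factor tabulation of missing smoking information with a
    heterogeneity p-value, and a linear-trend p-value for ordinal factors.

    ``frame`` is a cohort frame (one row per patient, ``missing`` flag set);
    complete-case per factor.
    """
    out: dict[str, dict] = {}
    for factor in factors:
        table = crosstab(frame, factor, outcome="missing")
        entry: dict = {"table": table}
        if len(table.row_labels) >= 2:
            stat, df, p = _safe_chi2(table)
            entry.update(chi2=stat, df=df, p_heterogeneity=p)
        if table.ordinal and len(table.row_labels) >= 3:
            stat_t, p_t = cochran_armitage(table)
            entry.update(trend_chi2=stat_t, p_trend=p_t)
        out[factor] = entry
    return out


# ---------------------------------------------------------------------------
# Table-5-style odds-ratio summaries
# ---------------------------------------------------------------------------

#: regression terms: age dichotomised at 65, sex (ref male), marital status
#: (ref single), deprivation as a single ordinal per-tertile term, and
#: diagnosis (ref schizophrenia).
REGRESSION_TERMS = ("age_65_plus", "sex", "marital", "deprivation_score", "diagnosis")


def _complete_case(frame: pd.DataFrame) -> pd.DataFrame:
    """Known-status patients; 'unknown' factor levels become missing so each
    fit is complete-case on its own terms."""
    data = frame[frame["current"].notna()].copy()
    data["current"] = data["current"].astype(float)
    for col in ("marital", "deprivation"):
        if isinstance(data[col].dtype, pd.CategoricalDtype) and "unknown" in data[col].cat.categories:
            # set_categories (not remove_categories) so the declared level
            # order — and with it the reference level — is preserved
            keep = [c for c in data[col].cat.categories if c != "unknown"]
            data[col] = data[col].cat.set_categories(keep)
    return data


def unadjusted_odds_ratios(frame: pd.DataFrame) -> pd.DataFrame:
    """One single-term logistic fit per factor: the unadjusted column."""
    data = _complete_case(frame)
    rows = []
    for term in REGRESSION_TERMS:
        fit = fit_logistic(data, "current", [term])
        ors = fit.odds_ratios()
        for name, r in ors.iterrows():
            rows.append({"term": name, "or": r["or"], "ci_low": r["ci_low"],
                         "ci_high": r["ci_high"], "n": fit.n_used})
    return pd.DataFrame(rows).set_index("term")


def adjusted_odds_ratios(frame: pd.DataFrame) -> LogisticFit:
    """All covariates simultaneously entered: the mutually adjusted column."""
    data = _complete_case(frame)
    return fit_logistic(data, "current", list(REGRESSION_TERMS))


# ---------------------------------------------------------------------------
# Full analysis (the five standard tables)
# ---------------------------------------------------------------------------

PREVALENCE_FACTORS = ("age_band", "sex", "marital", "deprivation", "diagnosis")


def run_analysis(
    cohort,
    resolved,
    structured,
    years: Optional[Sequence[int]] = None,
    tables: Sequence[int] = (1, 2, 3, 4, 5),
) -> dict:
    """Compute the selected standard tables for a resolved cohort.

    1: coverage by information source; 2: coverage by referral year with a
    trend test; 3: missingness correlates; 4: current-smoking prevalence by
    factor with heterogeneity/trend tests; 5: unadjusted and mutually
    adjusted odds ratios.
    """
    from .patient_pipeline import cohort_frame, coverage_by_source, coverage_by_year

    frame = cohort_frame(cohort, resolved)
    out: dict = {"n_cohort": len(cohort), "n_with_status": int((~frame["missing"]).sum())}
    if 1 in tables:
        out["coverage_by_source"] = coverage_by_source(cohort, resolved, structured)
    if 2 in tables:
        if years is None:
            years = sorted(frame["referral_year"].unique())
        out["coverage_by_year"] = coverage_by_year(cohort, resolved, structured, years)
    if 3 in tables:
        out["missingness"] = missingness_table(frame, PREVALENCE_FACTORS)
    if 4 in tables:
        prevalence = {}
        for factor in PREVALENCE_FACTORS:
            table = crosstab(frame, factor)
            entry: dict = {"table": table}
            if len(table.row_labels) >= 2:
                stat, df, p = _safe_chi2(table)
                entry.update(chi2=stat, df=df, p_heterogeneity=p)
            if table.ordinal and len(table.row_labels) >= 3:
                stat_t, p_t = cochran_armitage(table)
                entry.update(trend_chi2=stat_t, p_trend=p_t)
            prevalence[factor] = entry
        known = frame[frame["current"].notna()]
        out["prevalence"] = prevalence
        out["prevalence_overall"] = (
            100.0 * known["current"].astype(bool).sum() / len(known) if len(known) else float("nan")
        )
    if 5 in tables:
        out["unadjusted_or"] = unadjusted_odds_ratios(frame)
        out["adjusted_fit"] = adjusted_odds_ratios(frame)
    return out


def render_report(results: dict) -> str:
    """Human-readable report mirroring the layout of the standard tables."""
    lines = [
        f"Cohort n={results['n_cohort']}; "
        f"with smoking status n={results['n_with_status']}",
        "",
    ]
    if "coverage_by_source" in results:
        lines.append("== Coverage by information source ==")
        for _, r in results["coverage_by_source"].iterrows():
            lines.append(
                f"{r['source']:<22} {int(r['n_with_status']):>6} / "
                f"{int(r['cohort_n'])} ({r['percent']:.1f}%)"
            )
        lines.append("")
    if "coverage_by_year" in results:
        df = results["coverage_by_year"]
        lines.append("== Coverage by referral year ==")
        for _, r in df.iterrows():
            lines.append(
                f"{int(r['year'])}  n={int(r['n']):>6}  structured "
                f"{r['structured_only_pct']:.1f}%  all sources {r['all_sources_pct']:.1f}%"
            )
        for regime in ("structured_only", "all_sources"):
            key = f"trend_p_{regime}"
            if key in df.attrs:
                lines.append(f"trend p ({regime}): {format_p(df.attrs[key])}")
        lines.append("")
    if "missingness" in results:
        lines.append("== Missing smoking information by factor ==")
        for factor, entry in results["missingness"].items():
            lines.append(f"-- {factor} --")
            lines.append(format_table(entry["table"]))
            if "p_heterogeneity" in entry:
                lines.append(f"heterogeneity p = {format_p(entry['p_heterogeneity'])}")
            if "p_trend" in entry:
                lines.append(f"trend p = {format_p(entry['p_trend'])}")
        lines.append("")
    if "prevalence" in results:
        lines.append(
            f"== Current smoking by factor (overall prevalence "
            f"{results['prevalence_overall']:.1f}%) =="
        )
        for factor, entry in results["prevalence"].items():
            lines.append(f"-- {factor} --")
            lines.append(format_table(entry["table"]))
            if "p_heterogeneity" in entry:
                lines.append(f"heterogeneity p = {format_p(entry['p_heterogeneity'])}")
            if "p_trend" in entry:
                lines.append(f"trend p = {format_p(entry['p_trend'])}")
        lines.append("")
    if "unadjusted_or" in results:
        lines.append("== Odds ratios for current smoking ==")
        unadj = results["unadjusted_or"]
        fit = results["adjusted_fit"]
        adj = fit.odds_ratios() if fit.converged else None
        for term, r in unadj.iterrows():
            left = f"{term:<30} unadjusted {r['or']:.2f} ({r['ci_low']:.2f}-{r['ci_high']:.2f})"
            if adj is not None and term in adj.index:
                a = adj.loc[term]
                left += f"   adjusted {a['or']:.2f} ({a['ci_low']:.2f}-{a['ci_high']:.2f})"
            lines.append(left)
        lines.append(f"adjusted model n = {fit.n_used}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Report formatting
# ---------------------------------------------------------------------------

def format_p(p: float) -> str:
    """Report convention: two decimals, '<0.001' below threshold."""
    return "<0.001" if p < 0.001 else f"{p:.2f}"


def format_table(table: ContingencyTable, percent_col: int = 0) -> str:
    """Human-readable rendering: n per category with count (%) in the first
    outcome column to one decimal."""
    lines = []
    width = max((len(r) for r in table.row_labels), default=8)
    for label, row in zip(table.row_labels, table.counts):
        n = row.sum()
        k = row[percent_col]
        pct = 100.0 * k / n if n else float("nan")
        lines.append(f"{label:<{width}}  n={int(n):>6}  {int(k):>6} ({pct:.1f}%)")
    return "\n".join(lines)
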